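"""Geometric measurement of tubes, apertures, rings and vesicles.

Operators recovering the printed geometry of the tail-tube system from
density volumes: hollow-cylinder radii from radial density profiles
(half-maximum crossings), tube length and axis from segmented external
density, exit-angle deflection from the vertex radial axis, vertex
aperture diameter from the shell's low-density cap, crowning-ring
detection from per-slice radial profiles, and vesicle surface area /
enclosed volume with percent reductions between morphologies.

All lengths are nm and all angles degrees, folded to [0, 90] (axes are
unsigned).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .phantoms import VoxelVolume

__all__ = [
    "TubeGeometry",
    "VesicleMetrics",
    "radial_profile",
    "fit_hollow_cylinder",
    "measure_tube_length",
    "tube_axis",
    "exit_angle",
    "aperture_diameter",
    "detect_ring",
    "vesicle_area_volume",
    "percent_reduction",
]


@dataclass
class TubeGeometry:
    r1: float                  # inner radius, nm
    r2: float                  # outer radius, nm
    length: float | None = None
    exit_angle: float | None = None
    ring_z: float | None = None
    ring_diameter: float | None = None

    @property
    def r(self) -> float:
        """Average radius (r1 + r2) / 2."""
        return (self.r1 + self.r2) / 2.0

    @property
    def wall(self) -> float:
        return self.r2 - self.r1


@dataclass
class VesicleMetrics:
    area: float     # nm^2
    volume: float   # nm^3


# ---------------------------------------------------------------------------
# Radial profiles and hollow-cylinder fitting
# ---------------------------------------------------------------------------

def radial_profile(vol: VoxelVolume, axis: str | int = "z",
                   z_range: tuple | None = None):
    """Mean density in cylindrical annuli about a grid axis.

    ``z_range`` limits the slices (indices along the chosen axis) that are
    averaged; bin width is one voxel.  Returns ``(radii_nm, profile)``.
    """
    axmap = {"x": 0, "y": 1, "z": 2}
    ax = axmap.get(axis, axis)
    data = np.moveaxis(vol.data, ax, 2)
    n = data.shape[0]
    if z_range is not None:
        lo, hi = int(z_range[0]), int(z_range[1])
        if hi <= lo:
            raise ValueError("empty z_range")
        data = data[:, :, lo:hi]
    c = n // 2
    i, j = np.meshgrid(np.arange(n) - c, np.arange(n) - c, indexing="ij")
    rpix = np.sqrt(i**2 + j**2)
    rbin = np.round(rpix).astype(int)
    nb = c
    mean_z = data.mean(axis=2)
    sums = np.bincount(rbin.ravel(), weights=mean_z.ravel(), minlength=nb)
    counts = np.bincount(rbin.ravel(), minlength=nb)
    prof = sums[:nb] / np.maximum(counts[:nb], 1)
    radii = np.arange(nb) * vol.voxel_size
    return radii, prof


def fit_hollow_cylinder(radii: np.ndarray, profile: np.ndarray) -> TubeGeometry:
    """Inner/outer radii from half-maximum crossings of the wall peak.

    The wall peak is the profile maximum; r1 and r2 are the half-maximum
    crossings on either side, linearly interpolated.  Raises when the
    profile has no wall (monotone).
    """
    profile = np.asarray(profile, dtype=float)
    base = float(profile.min())
    prof = profile - base
    k = int(np.argmax(prof))
    if k == 0 or k == len(prof) - 1 or prof[k] <= 0:
        raise ValueError("profile has no interior wall peak")
    half = prof[k] / 2.0

    def cross(i0, step):
        i = k
        while 0 <= i + step < len(prof) and prof[i + step] > half:
            i += step
        j = i + step
        if not 0 <= j < len(prof):
            raise ValueError("half-maximum never crossed (monotone profile)")
        # linear interpolation between i and j
        f = (prof[i] - half) / (prof[i] - prof[j])
        return radii[i] + f * (radii[j] - radii[i])

    r1 = cross(k, -1)
    r2 = cross(k, +1)
    return TubeGeometry(r1=float(r1), r2=float(r2))


# ---------------------------------------------------------------------------
# Tube segmentation, axis, length, exit angle
# ---------------------------------------------------------------------------

def _segment(vol: VoxelVolume, threshold: float | None = None) -> np.ndarray:
    if threshold is None:
        from skimage.filters import threshold_otsu
        d = vol.data
        if d.max() <= d.min():
            raise ValueError("flat volume cannot be segmented")
        threshold = threshold_otsu(d)
    return vol.data > threshold


def measure_tube_length(vol: VoxelVolume, capsid_surface_radius: float = 0.0,
                        clearance_radius: float | None = None,
                        threshold: float | None = None) -> float:
    """Length (nm) of the tube protruding beyond the capsid surface.

    Voxels above threshold (Otsu by default) at radial distance beyond
    ``clearance_radius`` (which should clear the capsid's outermost
    density; defaults to ``capsid_surface_radius``) are taken as tube and
    their principal axis fitted.  The length is measured from the capsid
    surface: the maximal axis coordinate minus ``capsid_surface_radius``.
    For a free-standing tube (``capsid_surface_radius`` 0) the full extent
    along the axis is returned instead.
    """
    if clearance_radius is None:
        clearance_radius = capsid_surface_radius
    m = _segment(vol, threshold)
    X, Y, Z = vol.physical_coords()
    r = np.sqrt(X**2 + Y**2 + Z**2)
    m = m & (r > clearance_radius)
    if not m.any():
        raise ValueError("no density beyond the capsid surface")
    axis = tube_axis(vol, mask=m)
    coords = np.stack([X[m], Y[m], Z[m]], axis=1)
    t = coords @ axis
    if capsid_surface_radius > 0:
        return float(t.max() - capsid_surface_radius)
    return float(t.max() - t.min())


def tube_axis(vol: VoxelVolume, mask: np.ndarray | None = None,
              threshold: float | None = None) -> np.ndarray:
    """Principal direction of the intensity-weighted second moment.

    Returns a unit vector (sign chosen toward the centroid's hemisphere).
    Raises for degenerate (near-spherical) segments.
    """
    if mask is None:
        mask = _segment(vol, threshold)
    if not mask.any():
        raise ValueError("empty tube segment")
    X, Y, Z = vol.physical_coords()
    w = vol.data[mask].astype(float)
    w = np.maximum(w, 0) + 1e-12
    pts = np.stack([X[mask], Y[mask], Z[mask]], axis=1)
    mu = (pts * w[:, None]).sum(0) / w.sum()
    q = pts - mu
    cov = (q[:, :, None] * q[:, None, :] * w[:, None, None]).sum(0) / w.sum()
    vals, vecs = np.linalg.eigh(cov)
    if vals[-1] < 1.5 * vals[-2]:
        raise ValueError("degenerate (near-spherical) segment, no unique axis")
    axis = vecs[:, -1]
    if np.dot(axis, mu) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def exit_angle(tube_axis_vec: np.ndarray, vertex_axis: np.ndarray) -> float:
    """Angle (degrees) between tube and vertex axes, folded to [0, 90]."""
    a = np.asarray(tube_axis_vec, float)
    b = np.asarray(vertex_axis, float)
    c = abs(float(np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))))
    return float(np.degrees(np.arccos(np.clip(c, 0.0, 1.0))))


# ---------------------------------------------------------------------------
# Vertex aperture
# ---------------------------------------------------------------------------

def aperture_diameter(capsid_vol: VoxelVolume, vertex_direction: np.ndarray,
                      max_half_angle_deg: float = 30.0) -> float:
    """Chord diameter (nm) of the low-density aperture at a vertex.

    The shell is reduced to a direction map by taking, for each direction
    in a cap around the vertex axis, the maximum density along the radius;
    the aperture is the angular extent around the vertex where this map
    stays below half of the surrounding shell level, converted to a chord
    at the local shell radius.  Returns 0.0 for an intact vertex.
    """
    u = np.asarray(vertex_direction, float)
    u = u / np.linalg.norm(u)
    n = capsid_vol.data.shape[0]
    half_nm = (n // 2) * capsid_vol.voxel_size

    # orthonormal frame about the vertex axis
    ref = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)

    thetas = np.deg2rad(np.arange(0.25, max_half_angle_deg, 0.25))
    phis = np.linspace(0, 2 * np.pi, 72, endpoint=False)
    rads = np.arange(0.3 * half_nm, 0.98 * half_nm, capsid_vol.voxel_size / 2)

    from scipy.ndimage import map_coordinates
    c = n // 2
    vs = capsid_vol.voxel_size

    def shell_stats(dirs):
        # dirs: (m, 3) unit vectors -> max density along radius + argmax radius
        pts = dirs[:, None, :] * rads[None, :, None]   # (m, nr, 3)
        ijk = pts / vs + c
        vals = map_coordinates(capsid_vol.data.astype(float),
                               [ijk[..., 0], ijk[..., 1], ijk[..., 2]],
                               order=1, mode="constant", cval=0.0)
        peak = vals.max(axis=1)
        peak_r = rads[np.argmax(vals, axis=1)]
        return peak, peak_r

    # azimuth-averaged shell presence vs polar angle from the vertex
    presence = np.empty(len(thetas))
    peak_radius = np.empty(len(thetas))
    for i, th in enumerate(thetas):
        d = (np.cos(th) * u[None, :]
             + np.sin(th) * (np.cos(phis)[:, None] * e1[None, :]
                             + np.sin(phis)[:, None] * e2[None, :]))
        pk, pr = shell_stats(d)
        presence[i] = pk.mean()
        peak_radius[i] = pr.mean()

    pk0, _ = shell_stats(u[None, :])
    presence = np.concatenate([[float(pk0[0])], presence])
    thetas = np.concatenate([[0.0], thetas])

    level = np.percentile(presence, 90)
    if level <= 0:
        raise ValueError("no shell found around the vertex")
    half = level / 2.0
    if presence[0] >= half:
        return 0.0                 # intact vertex
    above = np.where(presence >= half)[0]
    if len(above) == 0:
        raise ValueError("no shell rim found within the search cap")
    i = above[0]
    # interpolate the crossing between i-1 (below) and i (above)
    f = (half - presence[i - 1]) / (presence[i] - presence[i - 1])
    alpha = thetas[i - 1] + f * (thetas[i] - thetas[i - 1])
    rim_r = peak_radius[min(i, len(peak_radius) - 1)]
    return float(2.0 * rim_r * np.sin(alpha))


# ---------------------------------------------------------------------------
# Ring detection
# ---------------------------------------------------------------------------

def detect_ring(tube_average: VoxelVolume, min_excess_voxels: float = 2.0,
                rel_height: float = 0.2):
    """Find a crowning ring on a tube whose axis lies along z.

    Per-slice radial profiles are scanned for their outermost significant
    peak; slices whose outer peak radius exceeds the tube-body median by
    at least ``min_excess_voxels`` voxels form the ring band.  Returns
    ``{"z": nm (from volume center), "diameter": nm}`` or ``None``.
    """
    n = tube_average.data.shape[0]
    vs = tube_average.voxel_size
    outer = np.full(n, np.nan)
    profs = []
    for z in range(n):
        profs.append(_slice_radial_profile(tube_average.data[:, :, z], vs))
    global_max = max(p.max() for _, p in profs)
    if global_max <= 0:
        return None
    for z, (radii, prof) in enumerate(profs):
        # skip near-empty slices (smoothing tails beyond the tube ends)
        if prof.max() < 0.25 * global_max:
            continue
        peaks, _ = find_peaks(prof, height=rel_height * prof.max())
        if len(peaks):
            outer[z] = radii[peaks[-1]]
    valid = ~np.isnan(outer)
    if valid.sum() < 3:
        return None
    body_median = np.nanmedian(outer)
    excess = outer - body_median
    ring_slices = np.where(valid & (excess >= min_excess_voxels * vs))[0]
    if len(ring_slices) == 0:
        return None
    diam = 2.0 * float(np.nanmax(outer[ring_slices]))
    zc = float((ring_slices.mean() - n // 2) * vs)
    return {"z": zc, "diameter": diam}


def _slice_radial_profile(img: np.ndarray, voxel_size: float):
    n = img.shape[0]
    c = n // 2
    i, j = np.meshgrid(np.arange(n) - c, np.arange(n) - c, indexing="ij")
    rbin = np.round(np.sqrt(i**2 + j**2)).astype(int)
    nb = c
    sums = np.bincount(rbin.ravel(), weights=img.ravel(), minlength=nb)
    counts = np.bincount(rbin.ravel(), minlength=nb)
    prof = sums[:nb] / np.maximum(counts[:nb], 1)
    return np.arange(nb) * voxel_size, prof


# ---------------------------------------------------------------------------
# Vesicle metrics
# ---------------------------------------------------------------------------

def vesicle_area_volume(mask: VoxelVolume) -> VesicleMetrics:
    """Surface area (nm^2) and enclosed volume (nm^3) of a binary mask.

    Volume by voxel counting; area by marching-cubes triangulation of the
    0.5 isosurface.  The mask must be nonempty and closed (not touching
    the box faces).
    """
    m = mask.data > 0.5
    if not m.any():
        raise ValueError("empty mask")
    if (m[0].any() or m[-1].any() or m[:, 0].any() or m[:, -1].any()
            or m[:, :, 0].any() or m[:, :, -1].any()):
        raise ValueError("mask touches the box boundary (open surface)")
    vs = mask.voxel_size
    volume = float(m.sum()) * vs**3
    from skimage.measure import marching_cubes, mesh_surface_area
    from scipy.ndimage import gaussian_filter
    # smooth the binary mask so the isosurface is not a staircase (which
    # systematically overestimates area)
    smoothed = gaussian_filter(m.astype(float), 1.0)
    verts, faces, _, _ = marching_cubes(smoothed, level=0.5,
                                        spacing=(vs, vs, vs))
    area = float(mesh_surface_area(verts, faces))
    return VesicleMetrics(area=area, volume=volume)


def percent_reduction(before: VesicleMetrics, after: VesicleMetrics) -> dict:
    """Percent reduction in area and volume between two morphologies."""
    return {
        "area_pct": 100.0 * (1.0 - after.area / before.area),
        "volume_pct": 100.0 * (1.0 - after.volume / before.volume),
    }
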