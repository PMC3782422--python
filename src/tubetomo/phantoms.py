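"""Parametric phantoms of tailed membrane-containing virions.

Generates ground-truthed 3D density volumes of an icosahedral capsid shell
with an internal membrane vesicle and a protruding hollow membranous tail
tube, plus 2D tube cross-section images with k-fold rotational symmetry.
These phantoms drive every downstream stage (tilt-series simulation,
subtomogram alignment, classification, symmetry and geometry analysis), so
all geometric defaults are the quantities the analysis is later asked to
recover: tube inner/outer diameters 4.5 / 14 nm, tube length 51.4 +/- 9.4 nm,
vertex aperture 15 nm, exit deflection 20 degrees, crowning ring 18 nm.

Conventions
-----------
* Volume arrays are cubic, indexed ``(x, y, z)``; the grid center is the
  voxel ``N // 2`` on each axis (0-based) and physical coordinates are
  ``(index - N // 2) * voxel_size`` in nm.
* The tube vertex is rendered along +z; a nonzero deflection tilts the tube
  axis away from +z within the x-z plane.
* Surfaces are rendered from signed distances smoothed by a Gaussian of
  width one voxel (an anti-aliased soft indicator), so half-maximum
  crossings of density edges sit on the geometric surface.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.special import erf

GOLDEN = (1.0 + np.sqrt(5.0)) / 2.0
#: inradius / circumradius ratio of the icosahedron
INRADIUS_RATIO = GOLDEN**2 / (np.sqrt(3.0) * np.sqrt(GOLDEN**2 + 1.0))

#: default voxel edge in nm (camera pixel size of the source tomograms)
DEFAULT_VOXEL_SIZE = 0.88
#: default pixel size of 2D tube cross-sections in nm
CROSS_SECTION_PIXEL_SIZE = 0.28

__all__ = [
    "VoxelVolume",
    "Image2D",
    "TubeSpec",
    "VesicleSpec",
    "PhantomSpec",
    "PopulationSpec",
    "icosahedron_vertices",
    "icosahedron_faces",
    "rasterize_phantom",
    "vesicle_enclosed_mask",
    "make_cross_section_images",
    "make_symmetry_mixture",
    "sample_tube_population",
    "canonical_tube_spec",
    "canonical_capsid_spec",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class VoxelVolume:
    """A cubic 3D scalar density grid with isotropic voxel size in nm."""

    data: np.ndarray
    voxel_size: float = DEFAULT_VOXEL_SIZE

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3 or len(set(self.data.shape)) != 1:
            raise ValueError(f"volume must be cubic, got shape {self.data.shape}")
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def center(self) -> int:
        """Index of the center voxel (same on all axes)."""
        return self.data.shape[0] // 2

    def copy(self) -> "VoxelVolume":
        return VoxelVolume(self.data.copy(), self.voxel_size)

    def physical_coords(self):
        """Return (x, y, z) coordinate grids in nm, centered on the center voxel."""
        n = self.data.shape[0]
        ax = (np.arange(n) - n // 2) * self.voxel_size
        return np.meshgrid(ax, ax, ax, indexing="ij")


@dataclass
class Image2D:
    """A square 2D scalar image with pixel size in nm."""

    data: np.ndarray
    pixel_size: float = CROSS_SECTION_PIXEL_SIZE

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 2 or self.data.shape[0] != self.data.shape[1]:
            raise ValueError(f"image must be square, got shape {self.data.shape}")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")


@dataclass
class TubeSpec:
    """Hollow-cylinder tail tube: radii and wall from the averaged maps.

    ``inner_diameter``/``outer_diameter`` are 2*r1 / 2*r2 of the
    hollow-cylinder parameterization; ``deflection_deg`` tilts the tube
    axis away from the vertex radial (5-fold) axis.  ``n_strands`` > 0
    decorates the mid-wall circle with Gaussian rods (an ordered
    multi-strand wall); 0 gives a featureless cylinder.  ``ring_diameter``
    adds a wider annulus crowning the tube near its distal end.
    """

    inner_diameter: float = 4.5
    outer_diameter: float = 14.0
    length: float = 51.4
    deflection_deg: float = 0.0
    n_strands: int = 0
    strand_sigma: float = 0.8          # Gaussian rod radius, nm
    twist_deg_per_nm: float = 0.0
    ring_diameter: float | None = None
    ring_z_offset: float | None = None  # from tube base; default near the tip
    ring_thickness: float = 2.0         # radial, nm
    ring_height: float = 3.0            # axial, nm

    def __post_init__(self) -> None:
        if not 0 < self.inner_diameter < self.outer_diameter:
            raise ValueError("need 0 < inner_diameter < outer_diameter")
        if not self.length > 0:
            raise ValueError("tube length must be positive")
        if not 0 <= self.deflection_deg < 90:
            raise ValueError("deflection must be in [0, 90) degrees")
        if self.n_strands < 0:
            raise ValueError("n_strands must be >= 0")


@dataclass
class VesicleSpec:
    """Internal membrane vesicle: icosahedral, spherical, or 'map-pin'.

    The map-pin model is the collapsed late-ejection morphology: a smaller
    spherical head whose membrane continues as a narrow neck toward the
    tube vertex.
    """

    model: Literal["icosahedral", "sphere", "map_pin"] = "icosahedral"
    radius: float = 23.0          # outer radius (circumradius if icosahedral), nm
    thickness: float = 5.0        # membrane thickness, nm
    head_radius: float = 15.0     # map-pin head outer radius, nm
    neck_outer_radius: float = 4.0
    neck_thickness: float = 1.5

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.thickness <= 0:
            raise ValueError("vesicle radius and thickness must be positive")


@dataclass
class PhantomSpec:
    """Full parametric ground truth for one particle."""

    capsid_circumradius: float = 33.3   # vertex-to-vertex distance ~35 nm
    capsid_thickness: float = 5.0
    decapped_vertices: Sequence[int] = ()
    aperture_diameter: float = 15.0
    vesicle: VesicleSpec | None = None
    tube: TubeSpec | None = None
    tube_vertex: int = 0
    capsid_amplitude: float = 1.0
    vesicle_amplitude: float = 0.8
    tube_amplitude: float = 1.0
    strand_amplitude: float = 0.6
    ring_amplitude: float = 1.0
    include_capsid: bool = True

    def __post_init__(self) -> None:
        if self.include_capsid and self.capsid_circumradius <= 0:
            raise ValueError("capsid circumradius must be positive")
        if self.aperture_diameter >= 2 * self.capsid_circumradius:
            raise ValueError("aperture cannot exceed the capsid diameter")
        for v in self.decapped_vertices:
            if not 0 <= int(v) <= 11:
                raise ValueError("vertex indices must be in 0..11")
        if not 0 <= int(self.tube_vertex) <= 11:
            raise ValueError("tube_vertex must be in 0..11")


@dataclass
class PopulationSpec:
    """Population model for particles-with-tube: lengths and orientations."""

    n: int = 70
    length_mean: float = 51.4
    length_sd: float = 9.4
    orientation_model: Literal["uniform", "cone"] = "uniform"
    cone_half_angle_deg: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.length_sd < 0:
            raise ValueError("length_sd must be >= 0")


# ---------------------------------------------------------------------------
# Icosahedral geometry
# ---------------------------------------------------------------------------

def icosahedron_vertices(circumradius: float) -> np.ndarray:
    """The 12 icosahedron vertices at the given circumradius (nm).

    Vertices follow the golden-ratio construction in a fixed, documented
    order: cyclic permutations of ``(0, +/-1, +/-phi)`` with sign order
    ``(+,+), (+,-), (-,+), (-,-)``:

    ``0..3``  -> (0, +/-1, +/-phi); ``4..7`` -> (+/-1, +/-phi, 0);
    ``8..11`` -> (+/-phi, 0, +/-1), so vertex indices are stable across runs.
    """
    if not circumradius > 0:
        raise ValueError("circumradius must be positive")
    p = GOLDEN
    base = []
    for a, b in [(1, p), (1, -p), (-1, p), (-1, -p)]:
        base.append((0.0, a, b))
    for a, b in [(1, p), (1, -p), (-1, p), (-1, -p)]:
        base.append((a, b, 0.0))
    for a, b in [(p, 1), (p, -1), (-p, 1), (-p, -1)]:
        base.append((a, 0.0, b))
    verts = np.asarray(base, dtype=float)
    verts *= circumradius / np.linalg.norm(verts[0])
    return verts


def icosahedron_faces(vertices: np.ndarray) -> np.ndarray:
    """Outward unit normals of the 20 triangular faces (one row each)."""
    n = len(vertices)
    d = np.linalg.norm(vertices[:, None] - vertices[None, :], axis=-1)
    edge = np.min(d[d > 1e-9])
    normals = []
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(j + 1, n):
                if (d[i, j] < edge * 1.05 and d[i, k] < edge * 1.05
                        and d[j, k] < edge * 1.05):
                    c = (vertices[i] + vertices[j] + vertices[k]) / 3.0
                    normals.append(c / np.linalg.norm(c))
    normals = np.asarray(normals)
    assert normals.shape == (20, 3)
    return normals


def _vertex_frame_rotation(vertices: np.ndarray, vertex: int) -> np.ndarray:
    """Rotation matrix carrying the chosen vertex direction onto +z."""
    u = vertices[vertex] / np.linalg.norm(vertices[vertex])
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(u, z)
    s = np.linalg.norm(v)
    c = float(np.dot(u, z))
    if s < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)


# ---------------------------------------------------------------------------
# Density rendering helpers
# ---------------------------------------------------------------------------

def _soft_indicator(signed_distance: np.ndarray, sigma: float) -> np.ndarray:
    """Smoothed inside-indicator: 1 deep inside, 0 outside, 0.5 on the surface."""
    return 0.5 * (1.0 - erf(signed_distance / (sigma * np.sqrt(2.0))))


def _support_distance(X, Y, Z, normals: np.ndarray) -> np.ndarray:
    """max_f (p . n_f), computed with a running maximum to bound memory."""
    s = np.full(X.shape, -np.inf)
    for nf in normals:
        np.maximum(s, X * nf[0] + Y * nf[1] + Z * nf[2], out=s)
    return s


def _capsid_density(X, Y, Z, spec: PhantomSpec, R: np.ndarray, sigma: float):
    verts = icosahedron_vertices(spec.capsid_circumradius) @ R.T
    normals = icosahedron_faces(verts)
    inradius = spec.capsid_circumradius * INRADIUS_RATIO
    # signed distance to the icosahedral surface (support-function form,
    # exact near faces which is where the shell lives)
    s = _support_distance(X, Y, Z, normals) - inradius
    shell = _soft_indicator(np.abs(s) - spec.capsid_thickness / 2.0, sigma)

    # de-capping: smooth cylindrical bore of the aperture diameter along
    # each de-capped vertex axis, so the chord on the shell equals the
    # requested diameter regardless of local shell radius
    for v in spec.decapped_vertices:
        u = verts[int(v)] / np.linalg.norm(verts[int(v)])
        t = X * u[0] + Y * u[1] + Z * u[2]
        rho = np.sqrt(np.maximum(X**2 + Y**2 + Z**2 - t**2, 0.0))
        bore = _soft_indicator(rho - spec.aperture_diameter / 2.0, sigma)
        shell *= 1.0 - bore * (t > 0)
    return shell * spec.capsid_amplitude


def _tube_density(X, Y, Z, tube: TubeSpec, start: np.ndarray, axis: np.ndarray,
                  sigma: float, spec: PhantomSpec):
    r1 = tube.inner_diameter / 2.0
    r2 = tube.outer_diameter / 2.0
    px = X - start[0]
    py = Y - start[1]
    pz = Z - start[2]
    t = px * axis[0] + py * axis[1] + pz * axis[2]
    rho2 = px**2 + py**2 + pz**2 - t**2
    rho = np.sqrt(np.maximum(rho2, 0.0))
    # hollow-cylinder wall as a signed distance (intersection of half-spaces)
    sd = np.maximum.reduce([rho - r2, r1 - rho, -t, t - tube.length])
    dens = _soft_indicator(sd, sigma) * spec.tube_amplitude

    if tube.n_strands > 0:
        rm = (r1 + r2) / 2.0
        u, v = _perp_coords(px, py, pz, axis)
        phi = np.arctan2(v, u)
        in_t = _soft_indicator(np.maximum(-t, t - tube.length), sigma)
        for k in range(tube.n_strands):
            phi_k = 2 * np.pi * k / tube.n_strands + np.deg2rad(
                tube.twist_deg_per_nm) * t
            # distance in the cross-section plane to the rod center
            dx = rho * np.cos(phi - phi_k) - rm
            dy = rho * np.sin(phi - phi_k)
            dens += (spec.strand_amplitude
                     * np.exp(-(dx**2 + dy**2) / (2 * tube.strand_sigma**2))
                     * in_t)

    if tube.ring_diameter is not None:
        rr = tube.ring_diameter / 2.0
        z0 = (tube.ring_z_offset if tube.ring_z_offset is not None
              else tube.length - 2.0)
        sd_ring = np.maximum(np.abs(rho - rr) - tube.ring_thickness / 2.0,
                             np.abs(t - z0) - tube.ring_height / 2.0)
        dens += _soft_indicator(sd_ring, sigma) * spec.ring_amplitude
    return dens


def _perp_coords(px, py, pz, axis):
    """Coordinates in a fixed plane orthogonal to the tube axis."""
    ref = np.array([1.0, 0.0, 0.0])
    if abs(axis[0]) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    u = px * e1[0] + py * e1[1] + pz * e1[2]
    v = px * e2[0] + py * e2[1] + pz * e2[2]
    return u, v


def _vesicle_density(X, Y, Z, ves: VesicleSpec, sigma: float,
                     spec: PhantomSpec, R: np.ndarray):
    r = np.sqrt(X**2 + Y**2 + Z**2)
    if ves.model == "sphere":
        sd = np.abs(r - (ves.radius - ves.thickness / 2.0)) - ves.thickness / 2.0
        return _soft_indicator(sd, sigma) * spec.vesicle_amplitude
    if ves.model == "icosahedral":
        verts = icosahedron_vertices(ves.radius) @ R.T
        normals = icosahedron_faces(verts)
        inradius = ves.radius * INRADIUS_RATIO
        s = _support_distance(X, Y, Z, normals) - inradius
        return _soft_indicator(np.abs(s) - ves.thickness / 2.0,
                               sigma) * spec.vesicle_amplitude
    if ves.model == "map_pin":
        # head sphere offset toward the tube vertex (+z), plus a thin neck
        inr = spec.capsid_circumradius * INRADIUS_RATIO
        cz = inr - spec.capsid_thickness / 2.0 - ves.head_radius
        rh = np.sqrt(X**2 + Y**2 + (Z - cz)**2)
        sd_head = np.abs(rh - (ves.head_radius - ves.thickness / 2.0)) \
            - ves.thickness / 2.0
        dens = _soft_indicator(sd_head, sigma)
        rho = np.sqrt(X**2 + Y**2)
        zlo = cz + ves.head_radius - ves.thickness
        zhi = inr
        sd_neck = np.maximum.reduce([
            np.abs(rho - (ves.neck_outer_radius - ves.neck_thickness / 2.0))
            - ves.neck_thickness / 2.0, zlo - Z, Z - zhi])
        dens = np.maximum(dens, _soft_indicator(sd_neck, sigma))
        return dens * spec.vesicle_amplitude
    raise ValueError(f"unknown vesicle model {ves.model!r}")


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def rasterize_phantom(spec: PhantomSpec, box_size: int = 96,
                      voxel_size: float = DEFAULT_VOXEL_SIZE) -> VoxelVolume:
    """Render a phantom spec onto a cubic grid.

    The tube vertex is carried onto +z; the tube axis is tilted by the
    deflection angle within the x-z plane.  Raises if the phantom does not
    fit inside the grid.
    """
    half = box_size // 2 * voxel_size
    reach = 0.0
    if spec.include_capsid:
        reach = spec.capsid_circumradius + spec.capsid_thickness
    if spec.tube is not None:
        surf = spec.capsid_circumradius if spec.include_capsid \
            else -spec.tube.length / 2.0
        reach = max(reach, surf + spec.tube.length,
                    spec.tube.outer_diameter / 2.0 + 2)
        if spec.tube.ring_diameter is not None:
            reach = max(reach, spec.tube.ring_diameter / 2.0 + 2)
    if reach > half:
        raise ValueError(
            f"phantom (reach {reach:.1f} nm) exceeds grid half-extent "
            f"{half:.1f} nm; increase box_size")

    n = box_size
    sigma = voxel_size  # 1-voxel Gaussian edge smoothing
    dens = _static_density(spec, n, voxel_size).copy()

    if spec.tube is not None:
        d = np.deg2rad(spec.tube.deflection_deg)
        axis = np.array([np.sin(d), 0.0, np.cos(d)])
        if spec.include_capsid:
            # tube base on the shell mid-surface at the vertex, so the
            # protruding length equals the requested length
            start = np.array([0.0, 0.0, spec.capsid_circumradius])
        else:
            # free-standing tube: centered, so deflection pivots about the
            # volume center like a global rotation would
            start = -spec.tube.length / 2.0 * axis
        # render only inside the tube's bounding box (plus smoothing margin)
        tube = spec.tube
        rmax = tube.outer_diameter / 2.0
        if tube.ring_diameter is not None:
            rmax = max(rmax, tube.ring_diameter / 2.0)
        margin = rmax + 5 * sigma
        ends = np.stack([start, start + tube.length * axis])
        lo_nm = ends.min(axis=0) - margin
        hi_nm = ends.max(axis=0) + margin
        lo = np.clip(np.floor(lo_nm / voxel_size).astype(int) + n // 2, 0, n)
        hi = np.clip(np.ceil(hi_nm / voxel_size).astype(int) + n // 2 + 1, 0, n)
        axes = [(np.arange(lo[k], hi[k]) - n // 2) * voxel_size
                for k in range(3)]
        Xs, Ys, Zs = np.meshgrid(*axes, indexing="ij")
        dens[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += _tube_density(
            Xs, Ys, Zs, tube, start, axis, sigma, spec)

    return VoxelVolume(np.maximum(dens, 0.0).astype(np.float32), voxel_size)


_STATIC_CACHE: dict = {}


def _static_key(spec: PhantomSpec, box_size: int, voxel_size: float):
    base = dataclasses.replace(spec, tube=None,
                               decapped_vertices=tuple(spec.decapped_vertices))
    return (dataclasses.astuple(base), box_size, voxel_size)


def _static_density(spec: PhantomSpec, n: int, voxel_size: float) -> np.ndarray:
    """Capsid + vesicle density (everything except the tube), cached:
    populations share one static render and differ only in their tubes."""
    key = _static_key(spec, n, voxel_size)
    hit = _STATIC_CACHE.get(key)
    if hit is not None:
        return hit
    ax = (np.arange(n) - n // 2) * voxel_size
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    sigma = voxel_size
    dens = np.zeros((n, n, n), dtype=np.float64)
    verts0 = icosahedron_vertices(1.0)
    R = _vertex_frame_rotation(verts0, spec.tube_vertex)
    if spec.include_capsid:
        dens += _capsid_density(X, Y, Z, spec, R, sigma)
    if spec.vesicle is not None:
        dens += _vesicle_density(X, Y, Z, spec.vesicle, sigma, spec, R)
    if len(_STATIC_CACHE) >= 2:       # bound memory
        _STATIC_CACHE.pop(next(iter(_STATIC_CACHE)))
    _STATIC_CACHE[key] = dens
    return dens


def vesicle_enclosed_mask(spec: PhantomSpec, box_size: int = 96,
                          voxel_size: float = DEFAULT_VOXEL_SIZE) -> VoxelVolume:
    """Boolean-valued volume (0/1) of the region enclosed by the vesicle
    membrane's outer surface (head + neck for the map-pin model)."""
    if spec.vesicle is None:
        raise ValueError("spec has no vesicle")
    n = box_size
    ax = (np.arange(n) - n // 2) * voxel_size
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    ves = spec.vesicle
    if ves.model == "sphere":
        inside = X**2 + Y**2 + Z**2 <= ves.radius**2
    elif ves.model == "icosahedral":
        verts0 = icosahedron_vertices(1.0)
        R = _vertex_frame_rotation(verts0, spec.tube_vertex)
        verts = icosahedron_vertices(ves.radius) @ R.T
        normals = icosahedron_faces(verts)
        inradius = ves.radius * INRADIUS_RATIO
        pts = np.stack([X, Y, Z], axis=-1)
        inside = np.max(pts @ normals.T, axis=-1) <= inradius
    elif ves.model == "map_pin":
        inr = spec.capsid_circumradius * INRADIUS_RATIO
        cz = inr - spec.capsid_thickness / 2.0 - ves.head_radius
        head = X**2 + Y**2 + (Z - cz)**2 <= ves.head_radius**2
        rho = np.sqrt(X**2 + Y**2)
        neck = ((rho <= ves.neck_outer_radius)
                & (Z >= cz + ves.head_radius - ves.thickness) & (Z <= inr))
        inside = head | neck
    else:
        raise ValueError(f"unknown vesicle model {ves.model!r}")
    return VoxelVolume(inside.astype(np.float32), voxel_size)


# ---------------------------------------------------------------------------
# Canonical specs (the defaults the measurements are asked to recover)
# ---------------------------------------------------------------------------

def canonical_tube_spec(length: float = 51.4, n_strands: int = 0,
                        ring: bool = False, deflection_deg: float = 0.0) -> PhantomSpec:
    """Tube-alone phantom: hollow cylinder 2r1 = 4.5 nm, 2r2 = 14 nm."""
    tube = TubeSpec(length=length, n_strands=n_strands,
                    deflection_deg=deflection_deg,
                    ring_diameter=18.0 if ring else None)
    return PhantomSpec(tube=tube, include_capsid=False)


def canonical_capsid_spec(tube: bool = True, decapped: bool = True,
                          deflection_deg: float = 0.0,
                          vesicle: str | None = None,
                          tube_length: float = 51.4) -> PhantomSpec:
    """Capsid (+ optional vesicle and tube) phantom at the published geometry."""
    ves = VesicleSpec(model=vesicle) if vesicle else None
    return PhantomSpec(
        tube=TubeSpec(length=tube_length, deflection_deg=deflection_deg)
        if tube else None,
        decapped_vertices=(0,) if decapped else (),
        vesicle=ves,
    )


# ---------------------------------------------------------------------------
# 2D cross-section images
# ---------------------------------------------------------------------------

def _annulus_image(size: int, pixel_size: float, order: int, phase: float,
                   lobe_contrast: float = 0.6,
                   r_inner: float = 2.25, r_outer: float = 7.0) -> np.ndarray:
    ax = (np.arange(size) - size // 2) * pixel_size
    X, Y = np.meshgrid(ax, ax, indexing="ij")
    rho = np.sqrt(X**2 + Y**2)
    phi = np.arctan2(Y, X)
    sigma = 2.0 * pixel_size
    ring = (0.5 * (1 - erf((rho - r_outer) / (sigma * np.sqrt(2))))
            * 0.5 * (1 + erf((rho - r_inner) / (sigma * np.sqrt(2)))))
    if order >= 2:
        ring = ring * (1.0 + lobe_contrast * np.cos(order * (phi - phase)))
    return ring


def make_cross_section_images(order: int, n_images: int,
                              noise_sd: float = 0.0, seed: int = 0,
                              size: int = 80,
                              pixel_size: float = CROSS_SECTION_PIXEL_SIZE,
                              lobe_contrast: float = 0.6) -> list[Image2D]:
    """Centered tube cross-sections with k-fold rotational symmetry.

    ``order`` 0 renders a plain annulus; ``order >= 2`` modulates the wall
    as ``1 + c*cos(k*(phi - phase))`` with a random phase per image.
    ``order`` 1 is rejected: it is not a rotational symmetry of a closed
    tube wall.  Noise is additive white Gaussian with the given sd relative
    to a unit wall amplitude.
    """
    if order == 1:
        raise ValueError("order 1 is not a rotational symmetry of a tube wall")
    if order < 0:
        raise ValueError("order must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_images):
        phase = rng.uniform(0, 2 * np.pi) if order >= 2 else 0.0
        img = _annulus_image(size, pixel_size, order, phase, lobe_contrast)
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, img.shape)
        out.append(Image2D(img.astype(np.float32), pixel_size))
    return out


#: symmetry-class mixture of the procapsid tube cross-section population:
#: fractions labeled 3-fold, 2-fold, higher (4..9, together) and spurious
DEFAULT_SYMMETRY_MIXTURE = {"3": 0.18, "2": 0.28, "higher": 0.19,
                            "spurious": 0.35}
DEFAULT_MIXTURE_NOISE_SD = 0.35


def make_symmetry_mixture(n_images: int = 1758,
                          proportions: dict[str, float] | None = None,
                          noise_sd: float = DEFAULT_MIXTURE_NOISE_SD,
                          seed: int = 0, size: int = 80,
                          pixel_size: float = CROSS_SECTION_PIXEL_SIZE):
    """Population of cross-sections at the reported symmetry-class mixture.

    Returns ``(images, labels)`` where labels are the ground-truth class
    strings ``"2"``, ``"3"``, ``"higher"``, ``"spurious"``.  The "higher"
    class is spread uniformly over orders 4..7; "spurious" images are plain
    annuli (their angular modulation is noise only).
    """
    props = dict(proportions or DEFAULT_SYMMETRY_MIXTURE)
    total = sum(props.values())
    rng = np.random.default_rng(seed)
    counts = {k: int(round(n_images * v / total)) for k, v in props.items()}
    # fix rounding drift on the largest class
    drift = n_images - sum(counts.values())
    counts[max(counts, key=counts.get)] += drift

    images: list[Image2D] = []
    labels: list[str] = []
    higher_orders = [4, 5, 6, 7]
    for cls, cnt in counts.items():
        for i in range(cnt):
            if cls == "spurious":
                order = 0
            elif cls == "higher":
                order = higher_orders[i % len(higher_orders)]
            else:
                order = int(cls)
            sub = rng.integers(0, 2**31 - 1)
            img = make_cross_section_images(order, 1, noise_sd, int(sub),
                                            size, pixel_size)[0]
            images.append(img)
            labels.append(cls)
    # shuffle so class blocks are not contiguous
    perm = rng.permutation(len(images))
    return [images[i] for i in perm], [labels[i] for i in perm]


# ---------------------------------------------------------------------------
# Tube population sampler
# ---------------------------------------------------------------------------

def sample_tube_population(pop: PopulationSpec, base: PhantomSpec):
    """Draw ``pop.n`` phantom specs with truncated-normal tube lengths.

    Lengths are normal(mean, sd) truncated to > 0 (redrawn on rejection);
    orientations are random rotations (uniform over SO(3), or restricted to
    a cone of directions about +z).  Returns ``(specs, table)`` where
    ``table`` is a list of dicts recording every drawn parameter.
    """
    if base.tube is None:
        raise ValueError("base spec must contain a tube")
    rng = np.random.default_rng(pop.seed)
    specs, table = [], []
    for i in range(pop.n):
        if pop.length_sd == 0:
            length = pop.length_mean
        else:
            length = -1.0
            while length <= 0:
                length = rng.normal(pop.length_mean, pop.length_sd)
        if pop.orientation_model == "uniform":
            angles = _random_euler(rng)
        else:
            angles = _cone_euler(rng, pop.cone_half_angle_deg)
        tube = dataclasses.replace(base.tube, length=float(length))
        specs.append(dataclasses.replace(base, tube=tube))
        table.append({"particle": i, "length_nm": float(length),
                      "euler_phi": angles[0], "euler_theta": angles[1],
                      "euler_psi": angles[2]})
    return specs, table


def _random_euler(rng) -> tuple:
    phi = float(rng.uniform(0, 360))
    theta = float(np.degrees(np.arccos(rng.uniform(-1, 1))))
    psi = float(rng.uniform(0, 360))
    return (phi, theta, psi)


def _cone_euler(rng, half_angle_deg: float) -> tuple:
    cmin = np.cos(np.deg2rad(half_angle_deg))
    phi = float(rng.uniform(0, 360))
    theta = float(np.degrees(np.arccos(rng.uniform(cmin, 1))))
    psi = float(rng.uniform(0, 360))
    return (phi, theta, psi)
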