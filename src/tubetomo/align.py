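"""Missing-wedge-aware subtomogram alignment and averaging.

Alignment maximizes the constrained cross-correlation — correlation over
only those Fourier components sampled in both volumes' wedges — so that
the missing wedge cannot drive two subtomograms toward spurious agreement.
The rotational search is coarse-to-fine: a cone of directions sampled
quasi-uniformly (Fibonacci-sphere points clipped to the cone) crossed with
in-plane azimuth steps, then local re-scans that halve the angular
sampling around the running best.  Translations are found through the
correlation theorem and limited per axis.  Averages are wedge-compensated:
Fourier sums divided voxelwise by the summed rotated wedge masks.

Euler angles are intrinsic Z-Y-Z triplets in degrees, rotating the
reference frame onto the particle frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .phantoms import VoxelVolume
from .tomosim import WedgeMask

__all__ = [
    "EulerTriplet",
    "SearchSchedule",
    "AlignmentResult",
    "euler_to_matrix",
    "matrix_to_euler",
    "compose_euler",
    "invert_euler",
    "rotation_distance_deg",
    "rotate_shift",
    "rotate_wedge_mask",
    "spherical_shell_mask",
    "cylinder_mask",
    "angular_grid",
    "constrained_cc",
    "align_particle",
    "average_wedge_compensated",
    "iterative_refine",
    "subbox",
]

EulerTriplet = tuple  # (phi, theta, psi) degrees, intrinsic ZYZ

IDENTITY: EulerTriplet = (0.0, 0.0, 0.0)


def euler_to_matrix(euler: EulerTriplet) -> np.ndarray:
    return Rotation.from_euler("ZYZ", euler, degrees=True).as_matrix()


def matrix_to_euler(m: np.ndarray) -> EulerTriplet:
    import warnings
    with warnings.catch_warnings():
        # gimbal lock at theta=0 is routine for cone-grid members
        warnings.simplefilter("ignore", UserWarning)
        return tuple(Rotation.from_matrix(m).as_euler("ZYZ", degrees=True))


def compose_euler(a: EulerTriplet, b: EulerTriplet) -> EulerTriplet:
    """Euler triplet of rotation a followed by b (matrix product Ra @ Rb)."""
    return matrix_to_euler(euler_to_matrix(a) @ euler_to_matrix(b))


def invert_euler(e: EulerTriplet) -> EulerTriplet:
    return matrix_to_euler(euler_to_matrix(e).T)


def rotation_distance_deg(a: EulerTriplet, b: EulerTriplet) -> float:
    """Geodesic angle between two rotations, degrees."""
    r = Rotation.from_matrix(euler_to_matrix(a).T @ euler_to_matrix(b))
    return float(np.degrees(r.magnitude()))


@dataclass
class SearchSchedule:
    """Coarse-to-fine rotational/translational search parameters.

    The global stage pivots inside a cone (full aperture, degrees) with a
    full azimuth range at ``initial_sampling``; each of ``n_refinements``
    local stages halves the sampling.  The reference is low-pass filtered
    at ``lowpass_nm`` before matching.
    """

    cone_aperture: float = 60.0
    azimuth_range: float = 360.0
    initial_sampling: float = 15.0
    n_refinements: int = 3
    shift_limits: tuple = (4, 4, 4)   # voxels per axis
    lowpass_nm: float | None = 8.0

    def __post_init__(self) -> None:
        if not self.initial_sampling > 0:
            raise ValueError("sampling must be positive")
        if self.n_refinements < 0:
            raise ValueError("n_refinements must be >= 0")

    @property
    def final_sampling(self) -> float:
        return self.initial_sampling / 2**self.n_refinements


@dataclass
class AlignmentResult:
    euler: EulerTriplet
    shift: tuple
    cc: float


# ---------------------------------------------------------------------------
# Volume transforms
# ---------------------------------------------------------------------------

def rotate_shift(vol: VoxelVolume, euler: EulerTriplet,
                 shift: Sequence[float] = (0.0, 0.0, 0.0)) -> VoxelVolume:
    """Rotate about the center voxel then translate, trilinear, zero fill.

    ``out(x) = in(R^-1 (x - c - s) + c)`` with R the ZYZ rotation.
    """
    R = euler_to_matrix(euler)
    c = np.array([d // 2 for d in vol.data.shape], dtype=float)
    s = np.asarray(shift, dtype=float)
    Rinv = R.T
    offset = c - Rinv @ (c + s)
    out = ndimage.affine_transform(vol.data, Rinv, offset=offset, order=1,
                                   mode="constant", cval=0.0, prefilter=False)
    return VoxelVolume(out.astype(np.float32), vol.voxel_size)


def rotate_wedge_mask(wedge: WedgeMask, euler: EulerTriplet) -> np.ndarray:
    """Rotate a wedge mask (natural FFT layout) by the particle rotation.

    Rotating a volume in real space rotates its Fourier transform by the
    same rotation, so the particle's accessibility region follows its
    alignment.  Returns a float array in natural FFT layout.
    """
    shifted = np.fft.fftshift(wedge.mask)
    R = euler_to_matrix(euler)
    c = np.array([d // 2 for d in shifted.shape], dtype=float)
    out = ndimage.affine_transform(shifted, R.T, offset=c - R.T @ c, order=1,
                                   mode="constant", cval=0.0, prefilter=False)
    out = np.clip(out, 0.0, 1.0)
    return np.fft.ifftshift(out).astype(np.float32)


# ---------------------------------------------------------------------------
# Real-space masks
# ---------------------------------------------------------------------------

def spherical_shell_mask(shape, voxel_size: float, inner_nm: float,
                         outer_nm: float, soft_nm: float = 1.0) -> np.ndarray:
    """Soft spherical-shell mask (e.g. the loose 16-49 nm alignment mask)."""
    n = shape[0]
    ax = (np.arange(n) - n // 2) * voxel_size
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    r = np.sqrt(X**2 + Y**2 + Z**2)
    from scipy.special import erf
    lo = 0.5 * (1 + erf((r - inner_nm) / (soft_nm * np.sqrt(2))))
    hi = 0.5 * (1 - erf((r - outer_nm) / (soft_nm * np.sqrt(2))))
    return (lo * hi).astype(np.float32)


def cylinder_mask(shape, voxel_size: float, radius_nm: float,
                  half_length_nm: float, soft_nm: float = 1.0) -> np.ndarray:
    """Soft cylindrical mask along z about the center (tube-only mask T)."""
    n = shape[0]
    ax = (np.arange(n) - n // 2) * voxel_size
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    rho = np.sqrt(X**2 + Y**2)
    from scipy.special import erf
    rad = 0.5 * (1 - erf((rho - radius_nm) / (soft_nm * np.sqrt(2))))
    axl = 0.5 * (1 - erf((np.abs(Z) - half_length_nm) / (soft_nm * np.sqrt(2))))
    return (rad * axl).astype(np.float32)


# ---------------------------------------------------------------------------
# Angular grids
# ---------------------------------------------------------------------------

def _fibonacci_directions(n_points: int) -> np.ndarray:
    i = np.arange(n_points)
    z = 1.0 - 2.0 * (i + 0.5) / n_points
    r = np.sqrt(np.maximum(1 - z**2, 0.0))
    golden_angle = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden_angle * i
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def angular_grid(schedule_or_sampling, center: EulerTriplet = IDENTITY,
                 cone_aperture: float | None = None,
                 azimuth_range: float | None = None) -> list:
    """Deterministic quasi-uniform orientation grid about a center.

    Directions are Fibonacci-sphere points clipped to the cone (full
    aperture ``cone_aperture`` about the center's z-axis; 0 keeps only the
    axis itself), each combined with azimuth steps over ``azimuth_range``.
    The center orientation is always element 0.
    """
    if isinstance(schedule_or_sampling, SearchSchedule):
        s = schedule_or_sampling.initial_sampling
        cone = schedule_or_sampling.cone_aperture if cone_aperture is None \
            else cone_aperture
        azr = schedule_or_sampling.azimuth_range if azimuth_range is None \
            else azimuth_range
    else:
        s = float(schedule_or_sampling)
        cone = 60.0 if cone_aperture is None else cone_aperture
        azr = 360.0 if azimuth_range is None else azimuth_range

    half = cone / 2.0
    dirs = [np.array([0.0, 0.0, 1.0])]
    if half > 0:
        s_rad = np.deg2rad(s)
        m = int(np.ceil(6.0 * 4.0 * np.pi / s_rad**2))  # dense, then clipped
        pts = _fibonacci_directions(m)
        keep = pts[:, 2] >= np.cos(np.deg2rad(half))
        # thin to ~s spacing: greedy pick with minimum angular separation
        cand = pts[keep]
        order = np.argsort(-cand[:, 2])
        chosen = [np.array([0.0, 0.0, 1.0])]
        min_dot = np.cos(np.deg2rad(s) * 0.8)
        for p in cand[order]:
            if all(np.dot(p, q) < min_dot for q in chosen):
                chosen.append(p)
        dirs = chosen

    if azr >= 360.0:
        azimuths = np.arange(0.0, 360.0, s)
    else:
        azimuths = np.arange(-azr / 2.0, azr / 2.0 + s / 2.0, s)
        if 0.0 not in azimuths:
            azimuths = np.sort(np.append(azimuths, 0.0))

    Rc = euler_to_matrix(center)
    grid: list = []
    for d in dirs:
        theta = float(np.degrees(np.arccos(np.clip(d[2], -1, 1))))
        phi = float(np.degrees(np.arctan2(d[1], d[0])))
        for a in azimuths:
            local = euler_to_matrix((phi, theta, float(a) - phi))
            grid.append(matrix_to_euler(Rc @ local))
    return grid


# ---------------------------------------------------------------------------
# Constrained cross-correlation
# ---------------------------------------------------------------------------

def constrained_cc(a: VoxelVolume, b: VoxelVolume,
                   wedge_a: np.ndarray | None = None,
                   wedge_b: np.ndarray | None = None,
                   mask: np.ndarray | None = None) -> float:
    """Correlation over the intersection of both volumes' sampled regions.

    Both volumes are masked in real space, transformed, restricted to the
    voxelwise intersection of their (already rotated) wedge masks with the
    DC term removed (mean subtraction), and normalized over that support.
    """
    if a.data.shape != b.data.shape:
        raise ValueError("volumes must have equal shapes")
    da = a.data * mask if mask is not None else a.data
    db = b.data * mask if mask is not None else b.data
    W = np.ones(a.data.shape, dtype=np.float32)
    if wedge_a is not None:
        W = W * (np.asarray(wedge_a) > 0.5)
    if wedge_b is not None:
        W = W * (np.asarray(wedge_b) > 0.5)
    W.flat[0] = 0.0  # remove DC == mean subtraction over the support
    if not W.any():
        raise ValueError("empty wedge intersection")
    Fa = np.fft.fftn(da) * W
    Fb = np.fft.fftn(db) * W
    num = float(np.real(np.vdot(Fa, Fb)))
    den = float(np.linalg.norm(Fa) * np.linalg.norm(Fb))
    if den == 0:
        return 0.0
    return float(np.clip(num / den, -1.0, 1.0))


def _cc_map(particle_f: np.ndarray, ref: np.ndarray, W: np.ndarray,
            norm_p: float) -> np.ndarray:
    """Wedge-constrained correlation map over all translations of ref."""
    Fr = np.fft.fftn(ref) * W
    den = norm_p * float(np.linalg.norm(Fr))
    if den == 0:
        return np.zeros(ref.shape)
    cc = np.fft.ifftn(particle_f * np.conj(Fr)).real * particle_f.size
    return cc / den


def _best_shift(cc: np.ndarray, shift_limits) -> tuple:
    """Arg-max of a correlation map restricted to |shift| <= limits."""
    n = cc.shape[0]
    sl = [int(s) for s in shift_limits]
    idx = [np.r_[0:s + 1, n - s:n] if s > 0 else np.r_[0:1] for s in sl]
    sub = cc[np.ix_(idx[0], idx[1], idx[2])]
    k = np.unravel_index(np.argmax(sub), sub.shape)
    shift = []
    for d in range(3):
        i = idx[d][k[d]]
        shift.append(int(i if i <= n // 2 else i - n))
    return tuple(shift), float(sub[k])


def align_particle(particle: VoxelVolume, wedge: WedgeMask | np.ndarray | None,
                   reference: VoxelVolume, schedule: SearchSchedule,
                   mask: np.ndarray | None = None,
                   center: EulerTriplet = IDENTITY) -> AlignmentResult:
    """Exhaustive coarse-to-fine search for the best (rotation, shift).

    Scans ``angular_grid`` x translations (via the correlation theorem,
    limited by ``shift_limits``), then ``n_refinements`` local re-scans
    halving the sampling around the running best.  The returned Euler/shift
    maps the reference onto the particle: ``rotate_shift(reference, euler,
    shift) ~ particle``.
    """
    if not np.any(particle.data):
        raise ValueError("degenerate all-zero particle")
    ref = reference
    if schedule.lowpass_nm is not None:
        from .resolution import lowpass
        ref = lowpass(ref, schedule.lowpass_nm)
    wmask = wedge.mask if isinstance(wedge, WedgeMask) else wedge
    if wmask is None:
        wmask = np.ones(particle.data.shape, dtype=np.float32)
    W = (wmask > 0.5).astype(np.float32)
    W.flat[0] = 0.0
    pdata = particle.data * mask if mask is not None else particle.data
    Fp = np.fft.fftn(pdata) * W
    norm_p = float(np.linalg.norm(Fp))

    best = AlignmentResult(center, (0, 0, 0), -np.inf)
    sampling = schedule.initial_sampling
    cone = schedule.cone_aperture
    azr = schedule.azimuth_range
    ctr = center
    for stage in range(schedule.n_refinements + 1):
        grid = angular_grid(sampling, ctr, cone_aperture=cone,
                            azimuth_range=azr)
        for euler in grid:
            rot = rotate_shift(ref, euler)
            rdata = rot.data * mask if mask is not None else rot.data
            cc = _cc_map(Fp, rdata, W, norm_p)
            shift, score = _best_shift(cc, schedule.shift_limits)
            if score > best.cc:
                best = AlignmentResult(tuple(float(x) for x in euler),
                                       shift, score)
        ctr = best.euler
        cone = 2.0 * sampling
        azr = 2.0 * sampling
        sampling = sampling / 2.0
    return best


# ---------------------------------------------------------------------------
# Averaging
# ---------------------------------------------------------------------------

def average_wedge_compensated(particles: Sequence[VoxelVolume],
                              wedges: Sequence[WedgeMask | np.ndarray] | None,
                              alignments: Sequence[AlignmentResult] | None = None,
                              eps_factor: float = 0.1) -> VoxelVolume:
    """Wedge-compensated average in the reference frame.

    Each particle is mapped back to the reference frame by the inverse of
    its alignment; Fourier sums are divided voxelwise by the summed rotated
    wedge masks floored at ``eps_factor * n_particles`` to bound noise
    amplification where no particle contributed.
    """
    if len(particles) == 0:
        raise ValueError("empty particle set")
    n = len(particles)
    shape = particles[0].data.shape
    fsum = np.zeros(shape, dtype=np.complex128)
    wsum = np.zeros(shape, dtype=np.float64)
    for i, p in enumerate(particles):
        if alignments is not None:
            a = alignments[i]
            inv_e = invert_euler(a.euler)
            Rinv = euler_to_matrix(inv_e)
            inv_s = tuple((-Rinv @ np.asarray(a.shift, float)).tolist())
            back = rotate_shift(p, inv_e, inv_s)
        else:
            inv_e = IDENTITY
            back = p
        fsum += np.fft.fftn(back.data)
        if wedges is not None:
            w = wedges[i]
            wm = w if isinstance(w, np.ndarray) else w.mask
            if alignments is not None and inv_e != IDENTITY:
                wm = rotate_wedge_mask(WedgeMask(wm, None) if not
                                       isinstance(w, WedgeMask) else w, inv_e)
            wsum += wm
        else:
            wsum += 1.0
    eps = eps_factor * n
    avg = np.fft.ifftn(fsum / np.maximum(wsum, eps)).real
    return VoxelVolume(avg.astype(np.float32), particles[0].voxel_size)


def iterative_refine(particles: Sequence[VoxelVolume],
                     wedges: Sequence[WedgeMask | np.ndarray] | None,
                     initial_reference: VoxelVolume,
                     schedule: SearchSchedule, n_iter: int = 4,
                     keep_factor: float = 0.5,
                     mask: np.ndarray | None = None):
    """Alternate align-all / re-average; drop low-cc particles at the end.

    After the final iteration, particles with cc below ``keep_factor`` times
    the mean cc are excluded (the "cross-correlation higher than 0.5 of
    the mean" selection rule, read multiplicatively) and the average is
    recomputed from the kept subset.  Returns ``(average, alignments,
    kept_indices)``.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    ref = initial_reference
    alignments: list[AlignmentResult] = []
    for _ in range(n_iter):
        alignments = []
        for i, p in enumerate(particles):
            w = None if wedges is None else wedges[i]
            alignments.append(align_particle(p, w, ref, schedule, mask=mask))
        ref = average_wedge_compensated(particles, wedges, alignments)
    ccs = np.array([a.cc for a in alignments])
    keep = np.where(ccs >= keep_factor * ccs.mean())[0]
    if len(keep) == 0:
        raise ValueError("all particles dropped by the keep rule")
    avg = average_wedge_compensated([particles[i] for i in keep],
                                    None if wedges is None else
                                    [wedges[i] for i in keep],
                                    [alignments[i] for i in keep])
    return avg, alignments, keep


def subbox(particles: Sequence[VoxelVolume],
           alignments: Sequence[AlignmentResult],
           offset: Sequence[float], new_box: int):
    """Re-extract a sub-region of each particle around a reference-frame point.

    The reference-frame offset (voxels from the box center) is mapped
    through each particle's alignment (``p = R o + s``) and a ``new_box``
    cube is extracted around it; the particle's rotation is carried along
    so its wedge mask can be reused.  Raises if the region leaves the box.
    """
    o = np.asarray(offset, dtype=float)
    out = []
    for p, a in zip(particles, alignments):
        R = euler_to_matrix(a.euler)
        c = p.data.shape[0] // 2
        pos = R @ o + np.asarray(a.shift, float) + c
        lo = np.round(pos).astype(int) - new_box // 2
        hi = lo + new_box
        if np.any(lo < 0) or np.any(hi > p.data.shape[0]):
            raise ValueError("subbox region exits the particle box")
        sub = p.data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        out.append(VoxelVolume(sub.copy(), p.voxel_size))
    return out
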