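"""Rotational symmetry analysis of 2D tube cross-sections.

Each cross-section image is resampled to polar coordinates about its
center and the energy of angular Fourier harmonics 1..9 is integrated over
an annular radial window (r-weighted so annuli contribute by area) and
normalized to sum 100 — the rotational power spectrum.  Spectra are
grouped on a 5x5 self-organizing map and each node is labeled by its
dominant harmonic (2-fold, 3-fold, higher 4..9, or spurious when no
harmonic dominates clearly), giving population fractions per symmetry
class.  The harmonic n=0 (the pure radial profile) carries no symmetry
information and is excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .phantoms import Image2D

__all__ = [
    "RotationalSpectrum",
    "SOMGrid",
    "HARMONICS",
    "rotational_spectrum",
    "preprocess",
    "som_train",
    "label_clusters",
    "population_fractions",
]

HARMONICS = np.arange(1, 10)
N_ANGULAR = 128


@dataclass
class RotationalSpectrum:
    """Normalized angular-harmonic energies P_n, n = 1..9, summing to 100.

    ``angular_fraction`` is the raw energy in harmonics 1..9 as a percent
    of the total including the purely radial n=0 term: it distinguishes a
    genuinely modulated wall from a plain annulus whose normalized
    spectrum is only spread-out numerical residue.
    """

    energies: np.ndarray       # length 9
    r_min: float               # px
    r_max: float               # px
    angular_fraction: float = 100.0

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        if self.energies.shape != (9,):
            raise ValueError("expected 9 harmonic energies")
        if np.any(self.energies < -1e-9):
            raise ValueError("energies must be nonnegative")


@dataclass
class SOMGrid:
    """5x5 lattice of prototype spectra trained by a batch SOM."""

    rows: int = 5
    cols: int = 5
    epochs: int = 30
    sigma_start: float = 2.0
    sigma_end: float = 0.4
    seed: int = 0
    prototypes: np.ndarray | None = None       # (rows*cols, 9)
    node_mean: np.ndarray | None = None
    node_var: np.ndarray | None = None
    node_count: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return self.rows * self.cols


def rotational_spectrum(img: Image2D, r_min: float, r_max: float) -> RotationalSpectrum:
    """Rotational power spectrum of an image about its center pixel."""
    n = img.data.shape[0]
    half = n // 2
    if not 0 < r_min < r_max < half:
        raise ValueError("need 0 < r_min < r_max < half image size")
    radii = np.arange(r_min, r_max + 1e-9, 1.0)
    ang = np.linspace(0, 2 * np.pi, N_ANGULAR, endpoint=False)
    rr, aa = np.meshgrid(radii, ang, indexing="ij")
    x = half + rr * np.cos(aa)
    y = half + rr * np.sin(aa)
    polar = ndimage.map_coordinates(img.data.astype(float), [x, y], order=1,
                                    mode="constant", cval=0.0)
    coeff = np.fft.fft(polar, axis=1) / N_ANGULAR
    power = np.abs(coeff[:, 0:10]) ** 2          # n = 0..9
    pw = (radii[:, None] * power).sum(axis=0)    # area weighting
    p = pw[1:]
    total = p.sum()
    if total <= 0:
        return RotationalSpectrum(np.zeros(9), r_min, r_max, 0.0)
    frac = 100.0 * total / (total + pw[0])
    return RotationalSpectrum(100.0 * p / total, r_min, r_max, float(frac))


def preprocess(images: list[Image2D], lowpass_nm: float = 1.5) -> list[Image2D]:
    """Normalize (zero mean, unit variance) then low-pass filter.

    Constant images cannot be normalized and come back all-zero.  The
    low-pass is a radial raised-cosine at 1/lowpass_nm in the image's
    frequency units.
    """
    out = []
    for img in images:
        d = img.data.astype(float)
        sd = d.std()
        if sd == 0:
            out.append(Image2D(np.zeros_like(d, dtype=np.float32),
                               img.pixel_size))
            continue
        d = (d - d.mean()) / sd
        n = d.shape[0]
        f = np.fft.fftfreq(n, d=img.pixel_size)
        FX, FY = np.meshgrid(f, f, indexing="ij")
        freq = np.sqrt(FX**2 + FY**2)
        fc = 1.0 / lowpass_nm
        width = 2.0 / (n * img.pixel_size)
        resp = np.ones_like(freq)
        hi = freq >= fc + width
        mid = (freq > fc - width) & ~hi
        resp[hi] = 0.0
        resp[mid] = 0.5 * (1 + np.cos(np.pi * (freq[mid] - (fc - width))
                                      / (2 * width)))
        filt = np.fft.ifft2(np.fft.fft2(d) * resp).real
        out.append(Image2D(filt.astype(np.float32), img.pixel_size))
    return out


def som_train(spectra: list[RotationalSpectrum] | np.ndarray,
              grid: SOMGrid | None = None):
    """Batch SOM with a Gaussian neighborhood shrinking over epochs.

    Deterministic under the grid's seed.  Returns ``(trained_grid,
    assignments)`` where assignments maps each spectrum to its best node;
    the trained grid carries per-node mean spectra, variances and counts.
    """
    if grid is None:
        grid = SOMGrid()
    X = np.asarray([s.energies if isinstance(s, RotationalSpectrum) else s
                    for s in spectra], dtype=float)
    if len(X) == 0:
        raise ValueError("empty spectrum set")
    import warnings
    if len(X) < grid.n_nodes:
        warnings.warn(f"only {len(X)} spectra for {grid.n_nodes} SOM nodes")

    rng = np.random.default_rng(grid.seed)
    k = grid.n_nodes
    proto = X[rng.integers(0, len(X), size=k)].astype(float)
    proto += rng.normal(0, 1e-3, proto.shape)
    pos = np.array([(i // grid.cols, i % grid.cols) for i in range(k)],
                   dtype=float)
    # squared lattice distances between nodes
    dist2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1)

    for epoch in range(grid.epochs):
        t = epoch / max(grid.epochs - 1, 1)
        sigma = grid.sigma_start * (grid.sigma_end / grid.sigma_start) ** t
        d = ((X[:, None, :] - proto[None, :, :]) ** 2).sum(-1)
        bmu = np.argmin(d, axis=1)
        H = np.exp(-dist2 / (2 * sigma**2))          # (k, k) neighborhood
        W = H[:, bmu]                                # (k, n) weights
        denom = W.sum(axis=1, keepdims=True)
        nonzero = denom[:, 0] > 1e-12
        proto[nonzero] = (W[nonzero] @ X) / denom[nonzero]

    d = ((X[:, None, :] - proto[None, :, :]) ** 2).sum(-1)
    assignments = np.argmin(d, axis=1)
    mean = np.zeros_like(proto)
    var = np.zeros_like(proto)
    count = np.zeros(k, dtype=int)
    for node in range(k):
        members = X[assignments == node]
        count[node] = len(members)
        if len(members):
            mean[node] = members.mean(axis=0)
            var[node] = members.var(axis=0)
        else:
            mean[node] = proto[node]
    trained = SOMGrid(grid.rows, grid.cols, grid.epochs, grid.sigma_start,
                      grid.sigma_end, grid.seed, prototypes=proto,
                      node_mean=mean, node_var=var, node_count=count)
    return trained, assignments


#: symmetry class labels, exhaustive and exclusive
LABELS = ("2-fold", "3-fold", "higher", "spurious")


def label_clusters(trained: SOMGrid, dominance_ratio: float = 1.5) -> list[str]:
    """Label each node by its dominant harmonic.

    A node is labeled with harmonic h when P_h is maximal and at least
    ``dominance_ratio`` times the second-largest energy; h=2 -> "2-fold",
    h=3 -> "3-fold", h in 4..9 -> "higher"; otherwise "spurious".  Labels
    use the node mean spectrum of assigned members (the prototype for
    empty nodes).
    """
    if trained.node_mean is None:
        raise ValueError("grid is not trained")
    labels = []
    for node in range(trained.n_nodes):
        p = trained.node_mean[node]
        order = np.argsort(p)[::-1]
        top, second = p[order[0]], p[order[1]]
        h = HARMONICS[order[0]]
        if second <= 0 or top < dominance_ratio * second or h == 1:
            labels.append("spurious")
        elif h == 2:
            labels.append("2-fold")
        elif h == 3:
            labels.append("3-fold")
        else:
            labels.append("higher")
    return labels


def population_fractions(assignments: np.ndarray, labels: list[str]) -> dict:
    """Percent of images per symmetry label; fractions sum to 100."""
    assignments = np.asarray(assignments)
    n = len(assignments)
    if n == 0:
        raise ValueError("no assignments")
    out = {lab: 0.0 for lab in LABELS}
    for node, lab in enumerate(labels):
        out[lab] += float(np.sum(assignments == node))
    return {lab: 100.0 * v / n for lab, v in out.items()}
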