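"""Heterogeneity pruning and multireference classification of subtomograms.

Two complementary tools: (1) PCA on the constrained-covariance (Gram)
matrix — pairwise constrained cross-correlations of aligned particles over
the intersections of their rotated wedges — to embed particles and drop
structural outliers; (2) iterative multireference alignment/classification
seeded from featureless cylindrical-shell templates, assigning each
particle to the best-correlating class average and re-averaging until the
labels stabilize.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantoms import VoxelVolume
from .align import (AlignmentResult, SearchSchedule, align_particle,
                    average_wedge_compensated, constrained_cc, invert_euler,
                    rotate_shift, rotate_wedge_mask, euler_to_matrix)
from .tomosim import WedgeMask

__all__ = [
    "ClassAssignment",
    "constrained_covariance",
    "pca_select",
    "multireference_classify",
    "class_cc_matrix",
    "cylindrical_shell_references",
]


@dataclass
class ClassAssignment:
    labels: np.ndarray                 # per-particle class index
    class_averages: list               # VoxelVolume per class
    class_mean_cc: np.ndarray
    cc_matrix: np.ndarray              # class-vs-class cc, unit diagonal
    alignments: list | None = None     # per-particle AlignmentResult


def _aligned_back(particle: VoxelVolume, wedge, alignment: AlignmentResult):
    """Particle and wedge mapped back into the reference frame."""
    inv_e = invert_euler(alignment.euler)
    Rinv = euler_to_matrix(inv_e)
    inv_s = tuple((-Rinv @ np.asarray(alignment.shift, float)).tolist())
    back = rotate_shift(particle, inv_e, inv_s)
    wm = None
    if wedge is not None:
        w = wedge if isinstance(wedge, WedgeMask) else WedgeMask(wedge, None)
        wm = rotate_wedge_mask(w, inv_e)
    return back, wm


def constrained_covariance(particles, wedges, alignments,
                           mask: np.ndarray | None = None) -> np.ndarray:
    """Gram matrix of pairwise constrained cross-correlations.

    Entry (i, j) is the constrained cc of aligned particles i and j over
    the intersection of their rotated wedge masks within the real-space
    mask.  Symmetric with unit diagonal.
    """
    if mask is not None and not np.any(mask):
        raise ValueError("empty mask")
    n = len(particles)
    backs, wms = [], []
    for i in range(n):
        w = None if wedges is None else wedges[i]
        a = alignments[i] if alignments is not None else \
            AlignmentResult((0.0, 0.0, 0.0), (0, 0, 0), 1.0)
        b, wm = _aligned_back(particles[i], w, a)
        backs.append(b)
        wms.append(wm)
    C = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            c = constrained_cc(backs[i], backs[j], wms[i], wms[j], mask)
            C[i, j] = C[j, i] = c
    return C


def pca_select(cov_matrix: np.ndarray, n_components: int = 3,
               keep_rule: str = "2means") -> np.ndarray:
    """Indices of particles kept after PCA embedding of the Gram matrix.

    Particles are embedded on the top eigenvectors (scaled by sqrt of the
    eigenvalues).  The default rule runs 2-means on the embedding and
    keeps the larger cluster, but only when the two clusters are actually
    separated (centroid distance exceeding the pooled within-cluster
    spread); otherwise the set is treated as homogeneous and everything is
    retained.
    """
    C = np.asarray(cov_matrix, dtype=float)
    if C.shape[0] != C.shape[1] or not np.allclose(C, C.T, atol=1e-6):
        raise ValueError("covariance matrix must be symmetric")
    n = C.shape[0]
    if n_components >= n:
        raise ValueError("n_components must be < n_particles")
    vals, vecs = np.linalg.eigh((C + C.T) / 2)
    idx = np.argsort(vals)[::-1][:n_components]
    emb = vecs[:, idx] * np.sqrt(np.maximum(vals[idx], 0.0))
    if keep_rule == "all":
        return np.arange(n)
    if keep_rule != "2means":
        raise ValueError(f"unknown keep_rule {keep_rule!r}")
    from sklearn.cluster import KMeans
    km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(emb)
    lab = km.labels_
    # structure gate on the correlation scale of the Gram matrix itself:
    # a genuine sub-population correlates much less with the other group
    # than either group does internally
    off = ~np.eye(n, dtype=bool)
    between = C[(lab[:, None] != lab[None, :])].mean()
    withins = []
    for g in (0, 1):
        sel = (lab[:, None] == g) & (lab[None, :] == g) & off
        if sel.any():
            withins.append(C[sel].mean())
    if not withins or between >= 0.7 * min(withins):
        return np.arange(n)     # homogeneous: no real structure
    larger = int(np.sum(lab == 1) > np.sum(lab == 0))
    return np.where(lab == larger)[0]


def cylindrical_shell_references(box_size: int, voxel_size: float,
                                 r1_nm: float = 2.25, r2_nm: float = 7.0,
                                 length_nm: float = 51.4,
                                 k: int = 4) -> list:
    """Featureless cylindrical-shell starting references.

    The default set of 4 spans +/- 1 voxel in wall radii and +/- 20% in
    length around the canonical tube dimensions.
    """
    from .phantoms import PhantomSpec, TubeSpec, rasterize_phantom
    dr = voxel_size
    variations = [(0.0, 1.0), (dr, 1.0), (0.0, 0.8), (-dr, 1.2)]
    refs = []
    for i in range(k):
        d_r, f_l = variations[i % len(variations)]
        tube = TubeSpec(inner_diameter=2 * max(r1_nm + d_r, 0.5),
                        outer_diameter=2 * (r2_nm + d_r),
                        length=length_nm * f_l)
        spec = PhantomSpec(tube=tube, include_capsid=False)
        refs.append(rasterize_phantom(spec, box_size, voxel_size))
    return refs


def multireference_classify(particles, wedges, references,
                            schedule: SearchSchedule, n_iter: int = 3,
                            mask: np.ndarray | None = None) -> ClassAssignment:
    """Iterative multireference alignment and classification.

    Each iteration aligns every particle to every reference, assigns it to
    the arg-max cc (ties to the lowest class index), and recomputes class
    averages as the next references.  Stops at ``n_iter`` or when labels
    stabilize.  An emptied class is re-seeded from the particles fitting
    their current class worst.
    """
    if len(references) < 1:
        raise ValueError("need at least one reference")
    k = len(references)
    refs = list(references)
    n = len(particles)
    labels = -np.ones(n, dtype=int)
    aligns: list = [None] * n
    ccs = np.zeros(n)
    for _ in range(n_iter):
        new_labels = np.empty(n, dtype=int)
        for i, p in enumerate(particles):
            w = None if wedges is None else wedges[i]
            results = [align_particle(p, w, r, schedule, mask=mask)
                       for r in refs]
            scores = np.array([r.cc for r in results])
            best = int(np.argmax(scores))       # argmax takes lowest on ties
            new_labels[i] = best
            aligns[i] = results[best]
            ccs[i] = scores[best]
        # re-seed emptied classes from the worst-fitting particles
        for c in range(k):
            if not np.any(new_labels == c):
                worst = int(np.argmin(ccs))
                new_labels[worst] = c
        if np.array_equal(new_labels, labels):
            labels = new_labels
            break
        labels = new_labels
        for c in range(k):
            members = np.where(labels == c)[0]
            refs[c] = average_wedge_compensated(
                [particles[i] for i in members],
                None if wedges is None else [wedges[i] for i in members],
                [aligns[i] for i in members])
    mean_cc = np.array([ccs[labels == c].mean() if np.any(labels == c)
                        else 0.0 for c in range(k)])
    return ClassAssignment(labels, refs, mean_cc,
                           class_cc_matrix(refs, mask), aligns)


def class_cc_matrix(class_averages, mask: np.ndarray | None = None) -> np.ndarray:
    """Pairwise full-wedge cc between class averages within a mask."""
    k = len(class_averages)
    M = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            c = constrained_cc(class_averages[i], class_averages[j],
                               None, None, mask)
            M[i, j] = M[j, i] = c
    return M
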