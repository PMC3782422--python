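"""Canonical phantom-recovery computations.

Each function generates the relevant default phantom, runs the
corresponding measurement chain, and returns the recovered quantity —
the package's self-checks that every printed geometric number is
recovered by the machinery that would measure it on real data.
"""

from __future__ import annotations

import numpy as np

from . import geometry as ge
from . import phantoms
from . import symmetry2d as s2
from . import tomosim

VOXEL = phantoms.DEFAULT_VOXEL_SIZE
CAPSID_R = 33.3
#: radial cut clearing all capsid density: circumradius + half thickness
#: + smoothing margin (nm)
CLEARANCE = CAPSID_R + 2.5 + 1.5

__all__ = [
    "tube_radii",
    "symmetry_fractions",
    "mean_tube_length",
    "exit_deflection",
    "vertex_aperture",
    "ring_diameter",
]


def tube_radii(box_size: int = 96):
    """Inner/outer tube diameter (nm) from the half-maximum fit on the
    wedge-affected canonical tube phantom (upright, no noise)."""
    vol = phantoms.rasterize_phantom(phantoms.canonical_tube_spec(),
                                     box_size, VOXEL)
    wedge = tomosim.make_wedge_mask(vol.data.shape, tomosim.TiltGeometry())
    degraded = tomosim.apply_wedge(vol, wedge)
    n = degraded.data.shape[2]
    radii, prof = ge.radial_profile(degraded, "z", (n // 2 - 20, n // 2 + 20))
    fit = ge.fit_hollow_cylinder(radii, prof)
    return 2 * fit.r1, 2 * fit.r2, fit.wall


def symmetry_fractions(seed: int = 0, n_images: int = 1758) -> dict:
    """Population symmetry fractions of the default cross-section mixture
    through the full spectra -> SOM -> dominant-harmonic chain."""
    imgs, _ = phantoms.make_symmetry_mixture(n_images=n_images, seed=seed)
    imgs = s2.preprocess(imgs, lowpass_nm=1.5)
    spectra = [s2.rotational_spectrum(im, 8, 30) for im in imgs]
    trained, assign = s2.som_train(spectra, s2.SOMGrid(seed=seed + 1))
    labels = s2.label_clusters(trained)
    return s2.population_fractions(assign, labels)


def mean_tube_length(seed: int = 0, n: int = 70):
    """Mean measured protruding tube length (nm) over a sampled population
    of particles-with-tube at the default length distribution."""
    pop = phantoms.PopulationSpec(n=n, seed=seed)
    specs, table = phantoms.sample_tube_population(
        pop, phantoms.canonical_capsid_spec())
    max_len = max(r["length_nm"] for r in table)
    # one shared box so the static capsid render is computed once
    box = int(np.ceil(2 * (CAPSID_R + max_len + 8) / VOXEL / 16)) * 16
    measured = []
    for spec in specs:
        vol = phantoms.rasterize_phantom(spec, box, VOXEL)
        measured.append(ge.measure_tube_length(
            vol, capsid_surface_radius=CAPSID_R,
            clearance_radius=CLEARANCE))
    return float(np.mean(measured)), measured


def exit_deflection(deflection_deg: float = 20.0) -> float:
    """Measured exit angle (degrees) of the deflected capsid+tube phantom."""
    spec = phantoms.canonical_capsid_spec(deflection_deg=deflection_deg,
                                          tube_length=40.0)
    vol = phantoms.rasterize_phantom(spec, 176, VOXEL)
    X, Y, Z = vol.physical_coords()
    mask = (vol.data > 0.3) & (np.sqrt(X**2 + Y**2 + Z**2) > CLEARANCE)
    axis = ge.tube_axis(vol, mask=mask)
    return ge.exit_angle(axis, [0.0, 0.0, 1.0])


def vertex_aperture() -> float:
    """Measured aperture chord diameter (nm) of the de-capped phantom."""
    vol = phantoms.rasterize_phantom(
        phantoms.canonical_capsid_spec(tube=False, decapped=True), 96, VOXEL)
    return ge.aperture_diameter(vol, [0.0, 0.0, 1.0])


def ring_diameter() -> float:
    """Detected crowning-ring diameter (nm) on the ringed tube phantom."""
    vol = phantoms.rasterize_phantom(
        phantoms.canonical_tube_spec(length=40.0, ring=True), 96, VOXEL)
    hit = ge.detect_ring(vol)
    if hit is None:
        raise RuntimeError("ring not detected on the ringed phantom")
    return hit["diameter"]
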