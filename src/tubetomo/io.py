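"""File formats, run configuration and the end-to-end pipeline driver.

Volumes travel as MRC/CCP4 maps (32-bit float, voxel size recorded in the
header, via gemmi); tilt series as an MRC stack plus a plain-text angle
file (one angle per line); tabular results (ground truth, alignments,
measurements, spectra, fractions) as CSV; runs are configured by YAML with
an explicit seed for every stochastic stage.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .phantoms import VoxelVolume, DEFAULT_VOXEL_SIZE

log = logging.getLogger("tubetomo")

__all__ = [
    "read_volume",
    "write_volume",
    "write_tilt_series",
    "read_tilt_series",
    "write_table",
    "read_table",
    "load_config",
    "save_config",
    "default_config",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# MRC volumes (via gemmi's CCP4/MRC map support)
# ---------------------------------------------------------------------------

def write_volume(vol: VoxelVolume, path) -> None:
    """Write a volume as a 32-bit float MRC map with its voxel size."""
    import gemmi
    data = np.ascontiguousarray(vol.data.astype(np.float32))
    grid = gemmi.FloatGrid(data)
    n = data.shape
    a = n[0] * vol.voxel_size * 10.0   # gemmi cells are in Angstrom
    b = n[1] * vol.voxel_size * 10.0
    c = n[2] * vol.voxel_size * 10.0
    grid.set_unit_cell(gemmi.UnitCell(a, b, c, 90, 90, 90))
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header(2, True)   # mode 2 = float32
    m.write_ccp4_map(str(path))


def read_volume(path) -> VoxelVolume:
    """Read a 32-bit float MRC map; voxel size from the header."""
    import gemmi
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, OSError) as e:
        raise ValueError(f"cannot read MRC map {path}: {e}") from e
    if m.header_i32(4) != 2:
        raise ValueError(f"unsupported MRC mode {m.header_i32(4)} (need 2)")
    data = np.array(m.grid, copy=True).astype(np.float32)
    vs = m.grid.unit_cell.a / (data.shape[0] * 10.0)
    return VoxelVolume(data, float(vs))


def write_tilt_series(ts, stack_path, angles_path) -> None:
    """MRC image stack plus a plain-text angle file (one angle per line)."""
    import gemmi
    data = np.ascontiguousarray(ts.images.astype(np.float32))
    grid = gemmi.FloatGrid(data)
    grid.set_unit_cell(gemmi.UnitCell(data.shape[0], data.shape[1] * ts.pixel_size * 10,
                                      data.shape[2] * ts.pixel_size * 10, 90, 90, 90))
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header(2, True)
    m.write_ccp4_map(str(stack_path))
    Path(angles_path).write_text(
        "".join(f"{a:.3f}\n" for a in ts.angles))


def read_tilt_series(stack_path, angles_path, pixel_size: float = DEFAULT_VOXEL_SIZE):
    import gemmi
    from .tomosim import TiltSeries
    m = gemmi.read_ccp4_map(str(stack_path))
    data = np.array(m.grid, copy=True).astype(np.float32)
    angles = np.array([float(x) for x in
                       Path(angles_path).read_text().split()])
    return TiltSeries(data, angles, pixel_size)


# ---------------------------------------------------------------------------
# Tables and configuration
# ---------------------------------------------------------------------------

def write_table(rows, path) -> None:
    """Rows (list of dicts or DataFrame) to CSV with a stable column order."""
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(rows)
    df.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def default_config(seed: int = 0) -> dict:
    """Small-box demonstration configuration covering every stage."""
    return {
        "seed": seed,
        "voxel_size_nm": DEFAULT_VOXEL_SIZE,
        "box_size": 48,
        "tilt": {"theta_min": -64.0, "theta_max": 64.0, "increment": 3.0},
        "simulate": {"n_particles": 6, "snr": 2.0, "tube_length_nm": 30.0},
        "align": {"cone_aperture": 20.0, "azimuth_range": 20.0,
                  "initial_sampling": 10.0, "n_refinements": 1,
                  "shift_limits": [2, 2, 2], "lowpass_nm": 8.0,
                  "n_iter": 2, "keep_factor": 0.5},
        "classify": {"enabled": False, "k": 2, "n_iter": 2},
        "symmetry": {"n_images": 200, "noise_sd": 0.35, "r_min": 8,
                     "r_max": 30, "lowpass_nm": 1.5, "som_epochs": 30},
        "measure": {"enabled": True},
        "stages": ["simulate", "align", "average", "fsc", "symmetry",
                   "measure"],
    }


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if "seed" not in cfg:
        raise ValueError("config must set an explicit seed")
    return cfg


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------

def run_pipeline(config: dict, out_dir) -> Path:
    """Execute the configured stages end to end into a result directory.

    Stages: simulate -> align -> average -> fsc -> symmetry -> measure.
    Each stage writes its volumes/tables under ``out_dir`` and a
    ``run_log.json`` records parameters and seeds.  A stage whose inputs
    are missing raises a ValueError naming the stage.
    """
    from . import phantoms, tomosim, align as align_mod, resolution, \
        symmetry2d, geometry

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages", [])
    seed = int(config["seed"])
    vs = float(config.get("voxel_size_nm", DEFAULT_VOXEL_SIZE))
    box = int(config.get("box_size", 48))
    geom = tomosim.TiltGeometry(**config.get("tilt", {}))

    state: dict = {}
    logpath = out / "run_log.json"
    runlog = {"config": config}

    if "simulate" in stages:
        sim = config.get("simulate", {})
        n_par = int(sim.get("n_particles", 6))
        snr = float(sim.get("snr", 2.0))
        spec = phantoms.canonical_tube_spec(
            length=float(sim.get("tube_length_nm", 30.0)))
        rng = np.random.default_rng(seed)
        parts, wedges, truths = [], [], []
        for i in range(n_par):
            euler = phantoms._random_euler(rng)
            v, w = tomosim.simulate_subtomogram(
                spec, euler, geom, snr=snr, seed=seed + 1000 + i,
                box_size=box, voxel_size=vs)
            parts.append(v)
            wedges.append(w)
            truths.append({"particle": i, "phi": euler[0],
                           "theta": euler[1], "psi": euler[2]})
            write_volume(v, out / f"particle_{i:03d}.mrc")
        write_table(truths, out / "ground_truth.csv")
        state["particles"], state["wedges"] = parts, wedges
        state["spec"] = spec

    if "align" in stages:
        if "particles" not in state:
            raise ValueError("stage 'align' requires stage 'simulate'")
        acfg = dict(config.get("align", {}))
        n_iter = int(acfg.pop("n_iter", 2))
        keep = float(acfg.pop("keep_factor", 0.5))
        acfg["shift_limits"] = tuple(acfg.get("shift_limits", (2, 2, 2)))
        schedule = align_mod.SearchSchedule(**acfg)
        ref = phantoms.rasterize_phantom(state["spec"], box, vs)
        avg, alignments, kept = align_mod.iterative_refine(
            state["particles"], state["wedges"], ref, schedule,
            n_iter=n_iter, keep_factor=keep)
        rows = [{"particle": i, "phi": a.euler[0], "theta": a.euler[1],
                 "psi": a.euler[2], "sx": a.shift[0], "sy": a.shift[1],
                 "sz": a.shift[2], "cc": a.cc, "kept": int(i in set(kept))}
                for i, a in enumerate(alignments)]
        write_table(rows, out / "alignments.csv")
        state["alignments"], state["kept"], state["average"] = \
            alignments, kept, avg

    if "average" in stages:
        if "average" not in state:
            raise ValueError("stage 'average' requires stage 'align'")
        write_volume(state["average"], out / "average.mrc")

    if "fsc" in stages:
        if "alignments" not in state:
            raise ValueError("stage 'fsc' requires stage 'align'")
        kept = list(state["kept"])
        even = kept[0::2]
        odd = kept[1::2]
        if len(odd) == 0:
            raise ValueError("stage 'fsc' needs at least two kept particles")
        half = []
        for sel in (even, odd):
            half.append(align_mod.average_wedge_compensated(
                [state["particles"][i] for i in sel],
                [state["wedges"][i] for i in sel],
                [state["alignments"][i] for i in sel]))
        curve = resolution.fsc(half[0], half[1])
        res, crossed = resolution.resolution_at(curve)
        write_table(pd.DataFrame({"freq_inv_nm": curve.frequencies,
                                  "fsc": curve.values}), out / "fsc.csv")
        runlog["fsc_resolution_nm"] = res
        runlog["fsc_crossed"] = bool(crossed)
        runlog["fsc_mask"] = "none"
        log.info("FSC 0.5 resolution: %.2f nm (crossed=%s, mask=none)",
                 res, crossed)

    if "symmetry" in stages:
        scfg = config.get("symmetry", {})
        imgs, labels_true = phantoms.make_symmetry_mixture(
            n_images=int(scfg.get("n_images", 200)),
            noise_sd=float(scfg.get("noise_sd", 0.35)), seed=seed + 7)
        imgs = symmetry2d.preprocess(imgs, float(scfg.get("lowpass_nm", 1.5)))
        spectra = [symmetry2d.rotational_spectrum(
            im, float(scfg.get("r_min", 8)), float(scfg.get("r_max", 30)))
            for im in imgs]
        grid = symmetry2d.SOMGrid(epochs=int(scfg.get("som_epochs", 30)),
                                  seed=seed + 8)
        trained, assign = symmetry2d.som_train(spectra, grid)
        labels = symmetry2d.label_clusters(trained)
        fracs = symmetry2d.population_fractions(assign, labels)
        write_table([{"image": i, "node": int(a),
                      "label": labels[int(a)], "true_class": labels_true[i]}
                     for i, a in enumerate(assign)],
                    out / "symmetry_assignments.csv")
        write_table(pd.DataFrame(trained.node_mean,
                                 columns=[f"P{n}" for n in range(1, 10)]),
                    out / "som_prototypes.csv")
        write_table([{"label": k, "percent": v} for k, v in fracs.items()],
                    out / "symmetry_fractions.csv")
        runlog["symmetry_fractions"] = fracs

    if "measure" in stages:
        spec = phantoms.canonical_tube_spec(
            length=float(config.get("simulate", {}).get("tube_length_nm", 30.0)))
        vol = phantoms.rasterize_phantom(spec, box, vs)
        nz = vol.data.shape[2]
        radii, prof = radial_profile_safe(vol, (nz // 2 - nz // 6,
                                                nz // 2 + nz // 6))
        fit = geometry.fit_hollow_cylinder(radii, prof)
        length = geometry.measure_tube_length(vol)
        write_table([{"inner_diameter_nm": 2 * fit.r1,
                      "outer_diameter_nm": 2 * fit.r2,
                      "wall_nm": fit.wall, "length_nm": length}],
                    out / "measurements.csv")
        runlog["measurements"] = {"2r1": 2 * fit.r1, "2r2": 2 * fit.r2}

    with open(logpath, "w") as fh:
        json.dump(runlog, fh, indent=2, default=float)
    return out


def radial_profile_safe(vol, z_range):
    from .geometry import radial_profile
    return radial_profile(vol, "z", z_range)
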