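"""Config-driven orchestration of the retrieval workflow.

Stages: ``simulate-lut`` -> ``rank-vis`` -> ``select-vis`` -> ``synth-survey``
-> ``train`` -> ``invert`` -> ``map``.  Each stage reads its upstream
artifacts from the output directory, writes plain CSV/JSON/TIFF artifacts,
and appends digests to ``manifest.json``.  A single global seed fans out to
per-stage seeds by stable hashing of the stage name.
"""

from __future__ import annotations

import copy
import hashlib
import json
import time as _time
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import canopy_scene as cs
from . import hybrid_inversion as hi
from . import shadow_resistance as sr
from . import synthetic_orchard as so
from .spectral_indices import BAND_NAMES, compute_all

__all__ = [
    "DEFAULT_CONFIG",
    "load_config",
    "stage_seed",
    "run_stage",
    "run_all",
    "map_traits",
    "STAGES",
    "StageError",
]


class StageError(RuntimeError):
    pass


DEFAULT_CONFIG = {
    "seed": 0,
    "scene": {
        "rows": 3,
        "trees_per_row": 3,
        "row_spacing": 4.0,
        "tree_spacing": 2.5,
        "crown_ax": 1.5,
        "crown_ay": 1.5,
        "crown_az": 1.2,
        "crown_base_height": 0.8,
    },
    "grid": {
        "counts": [8, 70, 4, 9],
        "times": [9, 10, 11, 12, 13, 14, 15, 16],
        "resolution": 0.06,
        "supersample": 2,
        "fesc_photons": 5000,
        "noise_std": 0.01,
    },
    "mixing": {"skyl": 0.35, "p0": 0.45, "p1": 0.30, "p_max": 0.95},
    "ranking": {"families": ["linear", "quadratic"]},
    "selection": {"k_max": 8, "rel_tol": 0.01, "max_train": 500, "n_restarts": 1},
    "gpr": {"max_train": 1000, "n_restarts": 2, "ard": False},
    "survey": {
        "preset": "mini",
        "row_spacing": 4.0,
        "tree_spacing": 2.5,
        "jitter": 0.2,
        "time": 12.0,
        "resolution": 0.04,
        "noise_std": 0.01,
        "lcc_dist": [60.0, 10.0, 40.0, 85.0],
        "lai_dist": [3.5, 0.8, 1.0, 6.0],
        "lai_calibration_trees": 85,
        "lai_measurement_noise": 0.3,
    },
}


def _deep_update(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in (override or {}).items():
        if key not in base:
            raise KeyError(f"unknown config key: {key!r}")
        if isinstance(val, dict) and isinstance(base[key], dict):
            out[key] = _deep_update(base[key], val)
        else:
            out[key] = val
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Materialise the full config: defaults <- YAML file <- overrides."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _deep_update(cfg, user)
    if overrides:
        cfg = _deep_update(cfg, overrides)
    return cfg


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed derived by stable hashing of the stage name."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).hexdigest()
    return int(digest[:8], 16)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _manifest_path(outdir: Path) -> Path:
    return outdir / "manifest.json"


def _update_manifest(outdir: Path, stage: str, seed: int, artifacts, elapsed: float, config):
    path = _manifest_path(outdir)
    manifest = {"config": config, "stages": {}}
    if path.exists():
        manifest = json.loads(path.read_text())
        manifest["config"] = config
    manifest["stages"][stage] = {
        "seed": seed,
        "elapsed_s": round(elapsed, 3),
        "artifacts": {str(Path(a).name): _sha256(Path(a)) for a in artifacts},
    }
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _require(outdir: Path, fname: str, producer: str) -> Path:
    path = outdir / fname
    if not path.exists():
        raise StageError(
            f"missing upstream artifact {fname!r}; run the {producer!r} stage first"
        )
    return path


def _scene_from_config(cfg: dict) -> cs.OrchardScene:
    s = cfg["scene"]
    crown = cs.CrownShape(
        ax=s["crown_ax"],
        ay=s["crown_ay"],
        az=s["crown_az"],
        base_height=s["crown_base_height"],
    )
    return cs.OrchardScene.grid(
        rows=s["rows"],
        trees_per_row=s["trees_per_row"],
        row_spacing=s["row_spacing"],
        tree_spacing=s["tree_spacing"],
        crown=crown,
    )


def _mixing_from_config(cfg: dict) -> cs.MixingParams:
    return cs.MixingParams(**cfg["mixing"])


# ---------------------------------------------------------------- stages


def _stage_simulate_lut(cfg, outdir, seed):
    g = cfg["grid"]
    grid = cs.ParameterGrid.from_counts(tuple(g["counts"]))
    lut = cs.build_lut(
        grid,
        times=tuple(g["times"]),
        scene=_scene_from_config(cfg),
        seed=seed,
        mixing=_mixing_from_config(cfg),
        resolution=g["resolution"],
        supersample=g["supersample"],
        fesc_photons=g["fesc_photons"],
        noise_std=g["noise_std"],
    )
    path = outdir / "lut.csv"
    lut.to_csv(path, index=False)
    return [path]


def _stage_rank_vis(cfg, outdir, seed):
    lut = pd.read_csv(_require(outdir, "lut.csv", "simulate-lut"))
    ranking = sr.ranking_from_lut(
        lut, families=tuple(cfg["ranking"]["families"])
    )
    path = outdir / "ranking.csv"
    ranking.to_csv(path, index_label="vi")
    report = outdir / "ranking.txt"
    report.write_text(sr.render_ranking_report(ranking) + "\n")
    return [path, report]


def _stage_select_vis(cfg, outdir, seed):
    lut = pd.read_csv(_require(outdir, "lut.csv", "simulate-lut"))
    ranking = pd.read_csv(
        _require(outdir, "ranking.csv", "rank-vis"), index_col="vi"
    )
    vis = compute_all(lut[list(BAND_NAMES)])
    sel = hi.iterative_vi_selection(
        list(ranking.index),
        vis,
        lut["cab"].to_numpy(),
        seed=seed,
        k_max=cfg["selection"]["k_max"],
        rel_tol=cfg["selection"]["rel_tol"],
        max_train=cfg["selection"]["max_train"],
        n_restarts=cfg["selection"]["n_restarts"],
    )
    path = outdir / "selection.json"
    path.write_text(json.dumps(sel.to_dict(), indent=2))
    return [path]


def _stage_synth_survey(cfg, outdir, seed):
    sv = cfg["survey"]
    preset = so.ORCHARD_PRESETS[sv["preset"]]
    layout = so.generate_orchard(
        rows=preset["rows"],
        trees_per_row=preset["trees_per_row"],
        row_spacing=sv["row_spacing"],
        tree_spacing=sv["tree_spacing"],
        jitter=sv["jitter"],
        seed=seed,
    )
    truth = so.sample_truth(
        layout.n_trees,
        lcc_dist=tuple(sv["lcc_dist"]),
        lai_dist=tuple(sv["lai_dist"]),
        seed=seed + 1,
    )
    s = cfg["scene"]
    crown = cs.CrownShape(
        ax=s["crown_ax"], ay=s["crown_ay"], az=s["crown_az"],
        base_height=s["crown_base_height"],
    )
    survey = so.render_survey(
        layout,
        truth,
        time=sv["time"],
        resolution=sv["resolution"],
        noise_std=sv["noise_std"],
        seed=seed + 2,
        crown=crown,
        mixing=_mixing_from_config(cfg),
    )
    paths = survey.write(outdir)
    refl = so.extract_crown_reflectance(survey)
    refl_path = outdir / "crown_reflectance.csv"
    refl.to_csv(refl_path, index=False)
    # crown labels are needed downstream for masked-mode comparisons
    labels_path = outdir / "labels.tif"
    tifffile.imwrite(labels_path, survey.four_component.labels)
    return [*paths.values(), refl_path, labels_path]


def _stage_train(cfg, outdir, seed):
    lut = pd.read_csv(_require(outdir, "lut.csv", "simulate-lut"))
    selection = json.loads(
        _require(outdir, "selection.json", "select-vis").read_text()
    )
    truth = pd.read_csv(_require(outdir, "truth.csv", "synth-survey"))
    refl = pd.read_csv(_require(outdir, "crown_reflectance.csv", "synth-survey"))

    gcfg = cfg["gpr"]
    vis_lut = compute_all(lut[list(BAND_NAMES)])
    chosen = selection["chosen"]
    ok = np.isfinite(vis_lut[chosen].to_numpy()).all(axis=1)
    model_lcc = hi.train_gpr(
        vis_lut.loc[ok, chosen],
        lut.loc[ok, "cab"].to_numpy(),
        seed=seed,
        max_train=gcfg["max_train"],
        n_restarts=gcfg["n_restarts"],
        ard=gcfg["ard"],
    )

    # LAI model calibrated on noisy "measured" LAI for a tree subset
    sv = cfg["survey"]
    rng = np.random.default_rng(seed + 1)
    n_cal = min(int(sv["lai_calibration_trees"]), len(truth))
    cal_idx = np.sort(rng.choice(len(truth), size=n_cal, replace=False))
    vis_tree = compute_all(refl[list(BAND_NAMES)])
    lai_measured = truth["lai"].to_numpy()[cal_idx] + rng.normal(
        0.0, sv["lai_measurement_noise"], n_cal
    )
    lai_features = list(hi.LAI_FEATURES)
    Xcal = vis_tree[lai_features].iloc[cal_idx]
    okc = np.isfinite(Xcal.to_numpy()).all(axis=1)
    model_lai = hi.train_gpr(
        Xcal[okc],
        lai_measured[okc],
        seed=seed + 2,
        max_train=gcfg["max_train"],
        n_restarts=gcfg["n_restarts"],
        ard=gcfg["ard"],
    )

    lcc_path = outdir / "model_lcc.pkl"
    lai_path = outdir / "model_lai.pkl"
    sidecar = outdir / "models.json"
    model_lcc.save(lcc_path)
    model_lai.save(lai_path)
    sidecar.write_text(
        json.dumps(
            {"lcc": model_lcc.hyperparameters, "lai": model_lai.hyperparameters},
            indent=2,
        )
    )
    return [lcc_path, lai_path, sidecar]


def _stage_invert(cfg, outdir, seed):
    refl = pd.read_csv(_require(outdir, "crown_reflectance.csv", "synth-survey"))
    model_lcc = hi.GPRModel.load(_require(outdir, "model_lcc.pkl", "train"))
    model_lai = hi.GPRModel.load(_require(outdir, "model_lai.pkl", "train"))
    vis_tree = compute_all(refl[list(BAND_NAMES)])
    estimates = hi.predict_traits(
        model_lcc, model_lai, vis_tree, tree_ids=refl["tree_id"].to_numpy()
    )
    path = outdir / "predictions.csv"
    estimates.to_csv(path, index=False)

    truth = pd.read_csv(_require(outdir, "truth.csv", "synth-survey"))
    merged = truth.merge(estimates, on="tree_id", suffixes=("_true", "_est"))
    metrics = {
        "lcc": hi.evaluate(merged["lcc_true"], merged["lcc_est"]).to_dict(),
        "lai": hi.evaluate(merged["lai_true"], merged["lai_est"]).to_dict(),
        "ccc": hi.evaluate(merged["ccc_true"], merged["ccc_est"]).to_dict(),
    }
    mpath = outdir / "metrics.json"
    mpath.write_text(json.dumps(metrics, indent=2))
    return [path, mpath]


def _stage_map(cfg, outdir, seed):
    estimates = pd.read_csv(_require(outdir, "predictions.csv", "invert"))
    crown_id = tifffile.imread(_require(outdir, "crown_id.tif", "synth-survey"))
    lcc_map, ccc_map = map_traits(estimates, crown_id)
    lcc_path = outdir / "lcc_map.tif"
    ccc_path = outdir / "ccc_map.tif"
    tifffile.imwrite(lcc_path, lcc_map.astype(np.float32))
    tifffile.imwrite(ccc_path, ccc_map.astype(np.float32))
    return [lcc_path, ccc_path]


def map_traits(estimates: pd.DataFrame, crown_id: np.ndarray):
    """Paint per-tree LCC/CCC onto the crown-ID raster (background = NaN)."""
    present = np.unique(crown_id)
    present = present[present > 0]
    known = set(estimates["tree_id"].astype(int))
    orphans = sorted(int(t) for t in present if int(t) not in known)
    if orphans:
        raise StageError(f"crown ids without estimates: {orphans}")
    n_max = int(estimates["tree_id"].max())
    lcc_lookup = np.full(n_max + 1, np.nan)
    ccc_lookup = np.full(n_max + 1, np.nan)
    for _, row in estimates.iterrows():
        lcc_lookup[int(row["tree_id"])] = row["lcc"]
        ccc_lookup[int(row["tree_id"])] = row["ccc"]
    cid = np.clip(crown_id.astype(int), 0, n_max)
    lcc_map = np.where(crown_id > 0, lcc_lookup[cid], np.nan)
    ccc_map = np.where(crown_id > 0, ccc_lookup[cid], np.nan)
    return lcc_map, ccc_map


STAGES = {
    "simulate-lut": _stage_simulate_lut,
    "rank-vis": _stage_rank_vis,
    "select-vis": _stage_select_vis,
    "synth-survey": _stage_synth_survey,
    "train": _stage_train,
    "invert": _stage_invert,
    "map": _stage_map,
}


def run_stage(stage: str, config: dict, outdir) -> list:
    """Run one stage; writes artifacts and appends to the manifest."""
    if stage not in STAGES:
        raise StageError(f"unknown stage {stage!r}; valid: {', '.join(STAGES)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = stage_seed(int(config["seed"]), stage)
    start = _time.perf_counter()
    artifacts = STAGES[stage](config, outdir, seed)
    elapsed = _time.perf_counter() - start
    _update_manifest(outdir, stage, seed, artifacts, elapsed, config)
    return artifacts


def run_all(config: dict, outdir) -> dict:
    """Run every stage in dependency order; returns stage -> artifacts."""
    results = {}
    for stage in STAGES:
        results[stage] = run_stage(stage, config, outdir)
    return results
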