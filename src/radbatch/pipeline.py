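"""End-to-end desk-scale study: simulate -> extract -> screen -> harmonize -> evaluate.

One YAML/JSON config drives the whole run.  A single global seed fans out to
per-stage seeds through ``numpy.random.SeedSequence([global_seed, stage])``
(stage 0 = phantom truth, 1 = acquisition noise, 2 = clustering, 3 = clinical
cohort), so reruns with the same config and seed are bit-identical for the
deterministic stages.

Stage outputs are plain CSV/JSON in the run directory, each re-runnable from
the previous stage's files alone:

* ``features_resampled.csv`` / ``features_native.csv`` — one row per
  (material, protocol), 93 feature columns plus metadata;
* ``icc_reports.csv`` and ``icc_summary.csv`` — per-pair per-feature ICCs and
  robust-percentage summaries, before/after resampling;
* ``batches.json`` — the acquisition variables flagged as batches;
* ``purity_phantom.json`` / ``purity_clinical.json`` — clustering purity
  before and after ComBat/SVD correction;
* ``run.json`` — config echo, seed, and a content hash for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError
from .evaluation import kmeans_purity
from .features import FEATURE_NAMES, extract_all
from .harmonization import combat, svd_correct
from .image_io import VoxelGrid, resample_grid
from .robustness import ICCReport, icc_pairwise, identify_batches, robustness_summary
from .synthetic import (
    GAMMEX_MATERIALS,
    KERNELS,
    AcquisitionProtocol,
    default_clinical_cohort,
    make_phantom_truth,
    rasterize_rod_masks,
    simulate_acquisition,
)

__all__ = ["DEFAULT_CONFIG", "load_config", "run_pipeline"]

log = logging.getLogger("radbatch")

#: Sweep variables, in study order.
SWEEP_VARIABLES = (
    "pixel_size",
    "slice_spacing",
    "slice_thickness",
    "kernel_id",
    "voltage",
    "current",
)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "phantom": {
        "materials": "all",  # or a list of material_ids
        "rod_diameter": 6.0,
        "grid_spacing": 0.35,
        "rod_height": 10.0,
    },
    "baseline": {
        "voltage": 120.0,
        "current": 200.0,
        "slice_thickness": 2.0,
        "slice_spacing": 1.0,
        "pixel_size": 0.78,
        "kernel_id": "A",
    },
    "sweeps": {
        "pixel_size": [0.39, 0.78, 1.0],
        "slice_spacing": [1.0, 1.25, 2.0, 2.5, 5.0],
        "slice_thickness": [2.0, 3.0, 5.0],
        "kernel_id": ["A", "B", "C", "D", "E"],
        "voltage": [90.0, 120.0, 140.0],
        "current": [100.0, 200.0, 400.0],
    },
    "features": {"bin_width": 50.0, "target": 1.0, "also_native": True},
    "robustness": {"icc_threshold": 0.8, "rule_threshold": 80.0},
    "evaluation": {
        "materials": ["brain", "liver"],
        "cross": {"slice_thickness": [2.0, 3.0, 5.0], "kernel_id": ["A", "B", "C", "D", "E"]},
        "k": 2,
        "iterations": 1000,
        "freq_threshold": 0.2,
        "svd_alpha": 0.001,
    },
    "clinical": {"enabled": True, "n_features": 93},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(base.get(key), dict):
            out[key] = _merge(base[key], val)
        else:
            out[key] = val
    return out


def load_config(path: str | None = None, overrides: dict | None = None) -> dict:
    """Load a YAML/JSON config, layered over the defaults, and validate it."""
    cfg = DEFAULT_CONFIG
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    _validate(cfg)
    return cfg


def _validate(cfg: dict) -> None:
    kernels = set(cfg["sweeps"].get("kernel_id", [])) | {cfg["baseline"]["kernel_id"]}
    kernels |= set(cfg["evaluation"].get("cross", {}).get("kernel_id", []))
    unknown = kernels - set(KERNELS)
    if unknown:
        raise ConfigError(f"unknown convolution kernel(s): {sorted(unknown)}")
    mat_ids = {m.material_id for m in GAMMEX_MATERIALS}
    sel = cfg["phantom"]["materials"]
    if sel != "all":
        missing = set(sel) - mat_ids
        if missing:
            raise ConfigError(f"unknown material(s): {sorted(missing)}")
    for mid in cfg["evaluation"]["materials"]:
        if mid not in mat_ids:
            raise ConfigError(f"evaluation material not in phantom: {mid!r}")
    thr = cfg["robustness"]
    if not (0 < thr["icc_threshold"] < 1) or not (0 < thr["rule_threshold"] <= 100):
        raise ConfigError("robustness thresholds out of range")
    unknown_vars = set(cfg["sweeps"]) - set(SWEEP_VARIABLES)
    if unknown_vars:
        raise ConfigError(f"unknown sweep variable(s): {sorted(unknown_vars)}")


def _stage_seed(global_seed: int, stage: int) -> int:
    return int(np.random.SeedSequence([global_seed, stage]).generate_state(1)[0] % (2**31))


def _protocol_grid(cfg: dict) -> dict[str, AcquisitionProtocol]:
    """One-variable-at-a-time sweeps around the baseline, deduplicated."""
    base = cfg["baseline"]
    protos: dict[str, AcquisitionProtocol] = {}
    for var, values in cfg["sweeps"].items():
        for v in values:
            p = AcquisitionProtocol(**{**base, var: v})
            protos.setdefault(p.label(), p)
    return protos


def _cross_protocols(cfg: dict) -> dict[str, AcquisitionProtocol]:
    cross = cfg["evaluation"]["cross"]
    base = cfg["baseline"]
    keys = list(cross)
    protos = {}
    for combo in itertools.product(*(cross[k] for k in keys)):
        p = AcquisitionProtocol(**{**base, **dict(zip(keys, combo))})
        protos[p.label()] = p
    return protos


def _extract_table(
    grids: dict[str, VoxelGrid],
    layout,
    materials,
    bin_width: float,
    target: float | None,
    protocol_meta: dict[str, dict],
) -> pd.DataFrame:
    """Feature rows for every (protocol, material).

    The volume is resampled once per protocol and rod masks are rasterized
    analytically on the final grid, so the same physical VOI is used across
    protocols (no mask interpolation, no per-rod resampling).
    """
    rows = []
    for label, grid in grids.items():
        work = (
            resample_grid(grid, (target,) * 3, order=3) if target is not None else grid
        )
        masks = rasterize_rod_masks(layout, work)
        for mat, mask in zip(materials, masks):
            feats = extract_all(
                work, mask, bin_width=bin_width, target=None,
                sample_id=f"{mat.material_id}@{label}",
            )
            rows.append(
                {"material": mat.material_id, "protocol": label,
                 **protocol_meta[label], **feats}
            )
    return pd.DataFrame(rows)


def _icc_stage(
    table: pd.DataFrame, cfg: dict, protos: dict[str, AcquisitionProtocol]
) -> dict[str, list[ICCReport]]:
    """All within-variable protocol pair comparisons on one feature table."""
    base = cfg["baseline"]
    feature_cols = list(FEATURE_NAMES)
    reports: dict[str, list[ICCReport]] = {}
    for var, values in cfg["sweeps"].items():
        if len(values) < 2:
            continue
        reports[var] = []
        for va, vb in itertools.combinations(values, 2):
            pa = AcquisitionProtocol(**{**base, var: va}).label()
            pb = AcquisitionProtocol(**{**base, var: vb}).label()
            if pa == pb:
                continue
            rep = icc_pairwise(table, pa, pb, feature_cols)
            rep.icc_threshold = cfg["robustness"]["icc_threshold"]
            reports[var].append(rep)
    return reports


def _reports_frame(reports: dict[str, list[ICCReport]], tag: str) -> pd.DataFrame:
    rows = []
    for var, reps in reports.items():
        for r in reps:
            rows.append(
                {
                    "data": tag,
                    "variable": var,
                    "pair": f"{r.protocol_pair[0]} vs {r.protocol_pair[1]}",
                    "robust_count": r.robust_count,
                    "n_features": r.n_features,
                    "robust_fraction": round(r.robust_fraction, 2),
                }
            )
    return pd.DataFrame(rows)


def _phantom_purity_stage(cfg: dict, truth, layout, materials, seed: int, out: Path) -> dict:
    """Two-material clustering purity before/after harmonization.

    Samples are (material, protocol) feature vectors over the thickness x
    kernel cross grid; batches are thickness, kernel and their combination.
    """
    protos = _cross_protocols(cfg)
    rng = np.random.default_rng(seed)
    grids = {
        lbl: simulate_acquisition(truth, p, seed=int(rng.integers(2**31 - 1)))
        for lbl, p in protos.items()
    }
    meta = {
        lbl: {
            "slice_thickness": p.slice_thickness,
            "kernel_id": p.kernel_id,
            "thickness_kernel": f"{p.slice_thickness:g}-{p.kernel_id}",
        }
        for lbl, p in protos.items()
    }
    mats = [m for m in materials if m.material_id in cfg["evaluation"]["materials"]]
    fcfg = cfg["features"]
    table = _extract_table(grids, layout, mats, fcfg["bin_width"], fcfg["target"], meta)
    table.to_csv(out / "features_evaluation.csv", index=False)
    ev = cfg["evaluation"]
    feature_cols = list(FEATURE_NAMES)

    def _purity(tab, tag):
        res = kmeans_purity(
            tab, feature_cols, class_column="material", k=ev["k"],
            iterations=ev["iterations"], freq_threshold=ev["freq_threshold"],
            seed=_stage_seed(cfg["seed"], 2),
        )
        log.info("phantom purity [%s] = %.4f", tag, res.selected_purity)
        return res

    results = {"initial": _purity(table, "initial")}
    for batch in ("thickness_kernel", "kernel_id", "slice_thickness"):
        corrected = combat(table, feature_cols, batch_col=batch)
        results[f"combat_{batch}"] = _purity(corrected, f"combat {batch}")
    svd_tab, svd_info = svd_correct(
        table, feature_cols, ["slice_thickness", "kernel_id"], alpha=ev["svd_alpha"]
    )
    results["svd_thickness_kernel"] = _purity(svd_tab, "svd")
    return {
        "svd_removed_components": [int(c) for c in svd_info.removed_components],
        **{
            name: {
                "selected_purity": r.selected_purity,
                "selected_frequency": r.selected_frequency,
            }
            for name, r in results.items()
        },
    }


def _clinical_stage(cfg: dict, out: Path) -> dict:
    table = default_clinical_cohort(
        seed=_stage_seed(cfg["seed"], 3), n_features=cfg["clinical"]["n_features"]
    )
    table.to_csv(out / "clinical_cohort.csv", index=False)
    feature_cols = [c for c in table.columns if c.startswith("f")]
    ev = cfg["evaluation"]

    def _purity(tab):
        return kmeans_purity(
            tab, feature_cols, class_column="class_label", k=2,
            iterations=ev["iterations"], freq_threshold=ev["freq_threshold"],
            seed=_stage_seed(cfg["seed"], 2),
        )

    initial = _purity(table)
    corrected = combat(table, feature_cols, batch_col="batch")
    after = _purity(corrected)
    corrected.to_csv(out / "clinical_cohort_combat.csv", index=False)
    svd_tab, svd_info = svd_correct(table, feature_cols, ["batch"], alpha=ev["svd_alpha"])
    after_svd = _purity(svd_tab)
    return {
        "initial": initial.selected_purity,
        "combat": after.selected_purity,
        "svd": after_svd.selected_purity,
        "svd_removed_components": [int(c) for c in svd_info.removed_components],
    }


def run_pipeline(config: dict, out_dir: str | Path) -> Path:
    """Run the full study described by ``config`` into ``out_dir``."""
    _validate(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    t0 = time.time()
    try:
        seed = int(config["seed"])
        cfg_text = yaml.safe_dump(config, sort_keys=True)
        (out / "config_used.yaml").write_text(cfg_text)
        log.info("radbatch %s, seed %d", __version__, seed)

        pcfg = config["phantom"]
        sel = pcfg["materials"]
        materials = list(GAMMEX_MATERIALS) if sel == "all" else [
            m for m in GAMMEX_MATERIALS if m.material_id in sel
        ]
        truth, _, layout = make_phantom_truth(
            materials,
            rod_diameter=pcfg["rod_diameter"],
            grid_spacing=pcfg["grid_spacing"],
            rod_height=pcfg["rod_height"],
            seed=_stage_seed(seed, 0),
        )
        log.info("phantom truth: %s voxels, %d rods", truth.shape, len(materials))

        protos = _protocol_grid(config)
        rng = np.random.default_rng(_stage_seed(seed, 1))
        grids = {
            lbl: simulate_acquisition(truth, p, seed=int(rng.integers(2**31 - 1)))
            for lbl, p in protos.items()
        }
        log.info("simulated %d protocols", len(grids))
        meta = {lbl: {v: getattr(p, v) for v in SWEEP_VARIABLES} for lbl, p in protos.items()}

        fcfg = config["features"]
        table_res = _extract_table(
            grids, layout, materials, fcfg["bin_width"], fcfg["target"], meta
        )
        table_res.to_csv(out / "features_resampled.csv", index=False)
        tables = {"resampled": table_res}
        if fcfg.get("also_native", True):
            table_nat = _extract_table(
                grids, layout, materials, fcfg["bin_width"], None, meta
            )
            table_nat.to_csv(out / "features_native.csv", index=False)
            tables["native"] = table_nat
        log.info("extracted %d feature vectors per table", len(table_res))

        frames = []
        summaries = {}
        batch_vars = {}
        for tag, tab in tables.items():
            reports = _icc_stage(tab, config, protos)
            frames.append(_reports_frame(reports, tag))
            summaries[tag] = robustness_summary(reports).to_dict()
            batch_vars[tag] = identify_batches(
                reports, config["robustness"]["rule_threshold"]
            )
        pd.concat(frames, ignore_index=True).to_csv(out / "icc_reports.csv", index=False)
        pd.DataFrame(summaries).to_csv(out / "icc_summary.csv")
        (out / "batches.json").write_text(json.dumps(batch_vars, indent=2))
        log.info("batch variables: %s", batch_vars)

        purity_phantom = _phantom_purity_stage(
            config, truth, layout, materials, _stage_seed(seed, 1) + 1, out
        )
        (out / "purity_phantom.json").write_text(json.dumps(purity_phantom, indent=2))

        results: dict = {"phantom_purity": purity_phantom}
        if config["clinical"]["enabled"]:
            purity_clin = _clinical_stage(config, out)
            (out / "purity_clinical.json").write_text(json.dumps(purity_clin, indent=2))
            results["clinical_purity"] = purity_clin

        run_info = {
            "version": __version__,
            "seed": seed,
            "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
            "elapsed_s": round(time.time() - t0, 1),
            "batch_variables": batch_vars,
            "robust_fraction_means": summaries,
        }
        (out / "run.json").write_text(json.dumps(run_info, indent=2))
        log.info("done in %.1f s", time.time() - t0)
    finally:
        log.removeHandler(handler)
        handler.close()
    return out
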