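"""Pipeline configuration and orchestration.

``run`` executes the stages in method order — synthesize (or load) →
extract temporal radiomics → significance filter → 13-method selection →
composite-score benchmark → mRSRF + SurvF fusion → three-situation outcome
evaluation — writing machine-readable artifacts and a manifest with seeds
and content hashes into the run directory.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .benchmark import benchmark_feature_sets, model_registry
from .features import FeatureConfig, TemporalFeatureTable, build_table
from .outcomes import evaluate_outcomes
from .preprocess import read_mask, read_series
from .selection import ALL_METHODS, SelectorParams, select_features
from .significance import filter_significant
from .survival import SurvivalConfig
from .synth import SynthConfig, generate_cohort

__all__ = ["DEFAULT_CONFIG", "load_config", "validate_config", "run"]

log = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "seed": 0,
    "synthetic": True,
    "situations": [2, 4, 7],
    "inputs": {                      # used when synthetic is false
        "series": [],                # list of 4D NIfTI paths
        "lt_masks": [],              # matching 3D NIfTI lesion masks
        "cti": None,                 # clinical CSV
        "mrs": None,                 # labels CSV with an 'mrs7' column
    },
    "synth": {
        "n_patients": 80,
        "n_timepoints": 50,
        "volume_shape": [6, 16, 16],
        "baseline_intensity": 300.0,
        "bolus_amplitude_nt": 150.0,
        "bolus_amplitude_lt": 60.0,
        "bolus_onset_nt": 12.0,
        "bolus_delay_lt": 4.0,
        "noise_sd": 20.0,
    },
    "preprocess": {"smooth": True},
    "radiomics": {
        "enabled_classes": ["First-order"],
        "bin_width": 25.0,
    },
    "significance": {"alpha": 0.05, "norm_mode": "range"},
    "selection": {
        "methods": list(ALL_METHODS),
        "mi_bins": 10,
        "mifs_beta": 0.5,
        "knn_k": 5,
        "mcfs_clusters": 2,
        "lasso_lambda": 1.0,
        "max_features": 20,
        "score_threshold": 0.9,
        "lasso_coef_threshold": 0.02,
    },
    "benchmark": {"folds": 10, "repeats": 1, "profile": "fast"},
    "survival": {
        "epochs": 300,
        "batch_size": 20,
        "hidden_layout": [32, 16],
        "learning_rate": 0.001,
        "event_threshold": 3,
    },
    "evaluate": {"test_ratio": 0.3, "profile": "fast",
                 "survf_fit": "train_only"},
}


def validate_config(cfg: dict, defaults: dict = DEFAULT_CONFIG,
                    path: str = "") -> dict:
    """Merge user settings over the defaults, rejecting unknown keys."""
    out = copy.deepcopy(defaults)
    for key, val in cfg.items():
        if key not in defaults:
            raise KeyError(f"unknown config key {path + key!r}")
        if isinstance(defaults[key], dict) and isinstance(val, dict):
            out[key] = validate_config(val, defaults[key], f"{path}{key}.")
        else:
            out[key] = val
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    cfg = {}
    if path is not None:
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
    if overrides:
        cfg = {**cfg, **overrides}
    return validate_config(cfg)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_inputs(cfg: dict):
    inp = cfg["inputs"]
    if not inp["series"]:
        raise FileNotFoundError("synthetic is false but no input series "
                                "paths are configured")
    from .preprocess import RoiPair, mirror_roi

    series, rois = [], []
    for spath, mpath in zip(inp["series"], inp["lt_masks"]):
        if not Path(spath).exists():
            raise FileNotFoundError(f"missing series file: {spath}")
        if not Path(mpath).exists():
            raise FileNotFoundError(f"missing mask file: {mpath}")
        s = read_series(spath)
        lt = read_mask(mpath, expected_shape=s.spatial_shape)
        rois.append(RoiPair(lt_mask=lt, nt_mask=mirror_roi(lt)))
        series.append(s)
    cti = pd.read_csv(inp["cti"])
    mrs7 = pd.read_csv(inp["mrs"])["mrs7"].to_numpy(dtype=int)
    return series, rois, cti, mrs7


def run(config: dict, outdir) -> dict:
    """Execute the full pipeline; returns the manifest dictionary."""
    cfg = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    artifacts: dict = {}

    def emit(name: str, path: Path):
        artifacts[name] = {"path": path.name, "sha256": _sha256(path)}

    # ---- stage 1: data --------------------------------------------------
    if cfg["synthetic"]:
        syn = SynthConfig(seed=seed, **{
            k: (tuple(v) if isinstance(v, list) else v)
            for k, v in cfg["synth"].items()})
        cohort = generate_cohort(syn)
        series, rois, cti, mrs7 = (cohort.series, cohort.rois, cohort.cti,
                                   cohort.mrs7)
    else:
        series, rois, cti, mrs7 = _load_inputs(cfg)
    cti.to_csv(outdir / "cti.csv", index=False)
    pd.DataFrame({"mrs7": mrs7}).to_csv(outdir / "mrs7.csv", index=False)
    emit("cti", outdir / "cti.csv")
    emit("labels", outdir / "mrs7.csv")
    log.info("stage data: %d series", len(series))

    # ---- stage 2: temporal radiomics ------------------------------------
    fc = FeatureConfig(
        enabled_classes=tuple(cfg["radiomics"]["enabled_classes"]),
        bin_width=float(cfg["radiomics"]["bin_width"]))
    table = build_table(series, rois, fc,
                        smooth=cfg["preprocess"]["smooth"])
    table.values.to_csv(outdir / "features.csv", index=False)
    table.column_meta.to_json(outdir / "column_meta.json", orient="records")
    table.row_meta.to_csv(outdir / "row_meta.csv", index=False)
    emit("features", outdir / "features.csv")
    log.info("stage extract: %s feature table", table.values.shape)

    # ---- stage 3: significance filter -----------------------------------
    sig, reduced = filter_significant(
        table, alpha=float(cfg["significance"]["alpha"]),
        norm_mode=cfg["significance"]["norm_mode"])
    sig.table.to_csv(outdir / "significance.csv", index=False)
    reduced.to_csv(outdir / "reduced_features.csv", index=False)
    emit("significance", outdir / "significance.csv")
    emit("reduced_features", outdir / "reduced_features.csv")
    tissue = table.row_meta["tissue"].to_numpy()
    log.info("stage filter: kept %d/%d features", reduced.shape[1],
             table.values.shape[1])

    # ---- stage 4: the 13 selectors ---------------------------------------
    sp_kwargs = {k: v for k, v in cfg["selection"].items() if k != "methods"}
    sparams = SelectorParams(seed=seed, **sp_kwargs)
    feature_sets = {}
    for method in cfg["selection"]["methods"]:
        fs = select_features(method, reduced, tissue, sparams)
        fs.to_json(outdir / f"featureset_{method}.json")
        emit(f"featureset_{method}", outdir / f"featureset_{method}.json")
        feature_sets[method] = fs
    log.info("stage select: %d methods", len(feature_sets))

    # ---- stage 5: composite-score benchmark ------------------------------
    models = model_registry(cfg["benchmark"]["profile"], seed)
    report = benchmark_feature_sets(
        feature_sets, reduced, tissue, models=models,
        folds=int(cfg["benchmark"]["folds"]), seed=seed,
        repeats=int(cfg["benchmark"]["repeats"]))
    bench = {
        "cs": report.cs,
        "best_method": report.best_method,
        "matrices": {m: report.matrices[m].to_dict() for m in report.matrices},
    }
    (outdir / "benchmark_report.json").write_text(
        json.dumps(bench, indent=2, sort_keys=True))
    emit("benchmark_report", outdir / "benchmark_report.json")
    log.info("stage benchmark: best method %s (CS=%.3f)",
             report.best_method, report.cs[report.best_method])

    # ---- stages 6-7: outstanding pool, fusion and evaluation -------------
    outstanding_cols = [c for c in reduced.columns
                        if any(c in fs.features
                               for fs in feature_sets.values())]
    # outcome prediction uses the lesion-tissue rows: one sample per scan,
    # aligned with the per-scan mRS labels
    outstanding = (reduced.loc[tissue == 1, outstanding_cols]
                   .reset_index(drop=True))
    surv = SurvivalConfig(seed=seed, **{
        k: (tuple(v) if isinstance(v, list) else v)
        for k, v in cfg["survival"].items()})
    eval_models = model_registry(cfg["evaluate"]["profile"], seed)
    collect: dict = {}
    pred = evaluate_outcomes(
        cti, outstanding, mrs7, best_method=report.best_method,
        models=eval_models, selector_params=sparams, survival_config=surv,
        test_ratio=float(cfg["evaluate"]["test_ratio"]), seed=seed,
        situations=tuple(cfg["situations"]),
        survf_fit=cfg["evaluate"]["survf_fit"], collect=collect)
    for scheme, extras in collect.items():
        pd.DataFrame({"survf": extras["survf"]}).to_csv(
            outdir / f"survf_mRS_{scheme}.csv", index=False)
        emit(f"survf_mRS_{scheme}", outdir / f"survf_mRS_{scheme}.csv")
        (outdir / f"mrsrf_mRS_{scheme}.json").write_text(
            json.dumps({"features": extras["mrsrf"]}, indent=2))
        emit(f"mrsrf_mRS_{scheme}", outdir / f"mrsrf_mRS_{scheme}.json")
    pred.cells.to_csv(outdir / "prediction_report.csv", index=False)
    pred.group_means.to_csv(outdir / "prediction_group_means.csv",
                            index=False)
    emit("prediction_report", outdir / "prediction_report.csv")
    emit("prediction_group_means", outdir / "prediction_group_means.csv")
    log.info("stage evaluate: %d report cells", len(pred.cells))

    manifest = {
        "version": __version__,
        "seed": seed,
        "config": cfg,
        "n_series": len(series),
        "best_method": report.best_method,
        "artifacts": artifacts,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
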