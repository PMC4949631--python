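"""Pipeline orchestration: configuration, staging, logging, manifests.

A single YAML config drives the full chain:
generate norms -> conceptual statistics -> train/evaluate the network grid
-> trajectory analyses -> synthetic behavioral data -> speed-sensitivity
analyses.  Every stochastic stage receives its own seed derived
deterministically from the global seed, and a manifest records the config
hash, derived seeds, stage runtimes and outputs so a run can be reproduced
bit for bit.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavioral import SpeedSensitivityModel
from .network import NetworkConfig, run_grid
from .norms import (
    concept_statistics,
    feature_correlations,
    feature_statistics,
    sharedness_bands,
    write_norms,
)
from .simanalysis import TickRegression, band_contrasts, band_trajectories
from .synth import BehavioralGenConfig, NormsGenConfig, generate_behavioral

__all__ = ["DEFAULT_CONFIG", "validate_config", "run_pipeline", "ConfigError"]

log = logging.getLogger("semdyn")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "runs/demo",
    "norms": {
        "n_concepts": 60,
        "n_categories": 6,
        "features_per_concept": [10, 14],
        "p_distinguishing": 0.25,
        "category_feature_pool": 14,
        "cross_category_pool": 10,
        "freq_law": ["poisson", 5.0],
    },
    "stats": {
        "alpha": 0.05,
        "positive_only": True,
    },
    "network": {
        "n_input": 30,
        "t_input": 30,
        "t_total": 50,
        "lr": 0.01,
        "epochs": 2000,
        "momentum": 0.9,
        "input_baseline": 0.0,
        "frequency_weighted_targets": False,
    },
    "grid": {
        "n_pattern_sets": 3,
        "c_values": [0.16, 0.2, 0.24],
        "eval_runs": 5,
    },
    "analysis": {
        "alpha": 0.05,
        "predictors": ["mean_distinctiveness", "mean_cs_log"],
    },
    "behavioral": {
        "n_subjects": 34,
        "speed_cs_slope": -0.06,
        "subject_sd": 0.12,
        "rt_noise": 0.12,
        "rt_base": 800.0,
        "bootstrap": 10000,
        "permutations": 10000,
    },
}


class ConfigError(ValueError):
    """Raised for schema violations, with the offending key path."""


def _merge(default, supplied, path=""):
    if not isinstance(supplied, dict):
        raise ConfigError(f"{path or 'config'}: expected a mapping")
    out = copy.deepcopy(default)
    for key, value in supplied.items():
        here = f"{path}.{key}" if path else key
        if key not in default:
            raise ConfigError(f"unknown config key: {here}")
        if isinstance(default[key], dict):
            out[key] = _merge(default[key], value, here)
        else:
            out[key] = value
    return out


def validate_config(source) -> dict:
    """Load and schema-check a pipeline config, filling defaults.

    ``source`` may be a path to a YAML file or an already-parsed mapping.
    Unknown keys are rejected with their full path; invariants on key
    values (e.g. integration rates in (0, 1]) are enforced here so stage
    code can assume a valid config.
    """
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            supplied = yaml.safe_load(fh) or {}
    else:
        supplied = source or {}
    cfg = _merge(DEFAULT_CONFIG, supplied)
    for c in cfg["grid"]["c_values"]:
        if not (0.0 < c <= 1.0):
            raise ConfigError(f"grid.c_values: {c} outside (0, 1]")
    if cfg["network"]["t_input"] > cfg["network"]["t_total"]:
        raise ConfigError("network.t_input exceeds network.t_total")
    if cfg["grid"]["n_pattern_sets"] < 1:
        raise ConfigError("grid.n_pattern_sets must be >= 1")
    if cfg["behavioral"]["n_subjects"] < 2:
        raise ConfigError("behavioral.n_subjects must be >= 2")
    if not cfg["analysis"]["predictors"]:
        raise ConfigError("analysis.predictors must be non-empty")
    return cfg


def _derive_seed(global_seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(cfg: dict, outdir: str | Path | None = None) -> Path:
    """Execute every stage of the pipeline; returns the run directory."""
    cfg = validate_config(cfg)
    outdir = Path(outdir or cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = {
        stage: _derive_seed(cfg["seed"], stage)
        for stage in ("norms", "grid", "behavioral", "evaluate")
    }
    manifest = {
        "package_version": __version__,
        "config": cfg,
        "config_hash": _config_hash(cfg),
        "derived_seeds": seeds,
        "stages": {},
    }

    def _stage(name):
        log.info("stage %s", name)
        manifest["stages"][name] = {"started": time.time()}
        return time.time()

    def _done(name, t0, **info):
        manifest["stages"][name].update(runtime_s=time.time() - t0, **info)

    try:
        t0 = _stage("norms")
        ncfg = NormsGenConfig(
            n_concepts=cfg["norms"]["n_concepts"],
            n_categories=cfg["norms"]["n_categories"],
            features_per_concept=tuple(cfg["norms"]["features_per_concept"]),
            p_distinguishing=cfg["norms"]["p_distinguishing"],
            category_feature_pool=cfg["norms"]["category_feature_pool"],
            cross_category_pool=cfg["norms"]["cross_category_pool"],
            freq_law=tuple(cfg["norms"]["freq_law"]),
            seed=seeds["norms"],
        )
        from .synth import generate_norms

        norms = generate_norms(ncfg)
        write_norms(norms, outdir / "norms.tsv")
        _done("norms", t0, n_concepts=len(norms.concepts),
              n_features=len(norms.features))

        t0 = _stage("stats")
        fstats = sharedness_bands(feature_statistics(norms))
        corr = feature_correlations(
            norms, alpha=cfg["stats"]["alpha"],
            positive_only=cfg["stats"]["positive_only"],
        )
        cstats = concept_statistics(norms, fstats, corr)
        fstats.to_csv(outdir / "feature_stats.csv")
        cstats.to_csv(outdir / "concept_stats.csv")
        _done("stats", t0, n_sig_pairs=int(corr["significant"].sum()))

        t0 = _stage("grid")
        net = NetworkConfig(
            n_input=cfg["network"]["n_input"],
            n_semantic=len(norms.features),
            t_input=cfg["network"]["t_input"],
            t_total=cfg["network"]["t_total"],
            lr=cfg["network"]["lr"],
            epochs=cfg["network"]["epochs"],
            momentum=cfg["network"]["momentum"],
            input_baseline=cfg["network"]["input_baseline"],
            frequency_weighted_targets=cfg["network"]["frequency_weighted_targets"],
        )
        cells = run_grid(
            norms,
            n_pattern_sets=cfg["grid"]["n_pattern_sets"],
            c_values=tuple(cfg["grid"]["c_values"]),
            base_seed=seeds["grid"],
            cfg=net,
            eval_runs=cfg["grid"]["eval_runs"],
        )
        losses = pd.DataFrame(
            {
                f"set{c['pattern_set']}_c{c['c']}": c["results"].loss_history
                for c in cells
            }
        )
        losses.to_csv(outdir / "loss_history.csv", index_label="epoch")
        _done("grid", t0, n_models=len(cells),
              cell_seeds=[c["seed"] for c in cells])

        t0 = _stage("analysis")
        band_frames = [
            band_trajectories(c["trajectory"], norms, fstats) for c in cells
        ]
        bands = pd.concat(
            [f.assign(member=i) for i, f in enumerate(band_frames)],
            ignore_index=True,
        )
        bands.to_csv(outdir / "band_means.csv", index=False)
        if len(band_frames) >= 2:
            contrasts = band_contrasts(band_frames, alpha=cfg["analysis"]["alpha"])
            contrasts.to_csv(outdir / "band_contrasts.csv", index=False)
        ticks = TickRegression(
            [c["trajectory"] for c in cells], norms, cstats,
            predictors=cfg["analysis"]["predictors"],
        ).fit()
        ticks.table.to_csv(outdir / "tick_betas.csv", index=False)
        _done("analysis", t0, n_members=len(band_frames))

        t0 = _stage("behavioral")
        bcfg = BehavioralGenConfig(
            n_subjects=cfg["behavioral"]["n_subjects"],
            speed_cs_slope=cfg["behavioral"]["speed_cs_slope"],
            subject_sd=cfg["behavioral"]["subject_sd"],
            rt_noise=cfg["behavioral"]["rt_noise"],
            rt_base=cfg["behavioral"]["rt_base"],
            seed=seeds["behavioral"],
        )
        bdata = generate_behavioral(bcfg, cstats)
        bdata.to_csv(outdir / "behavioral.csv", index=False)
        model = SpeedSensitivityModel(
            bdata, predictors=["mean_distinctiveness", "mean_cs_log", "nof"]
        )
        res = model.fit()
        res.subject_betas.to_csv(outdir / "subject_betas.csv", index=False)
        ci = res.bootstrap_ci(
            "mean_cs_log", B=cfg["behavioral"]["bootstrap"],
            seed=seeds["behavioral"],
        )
        diff, perm_p = res.permutation_diff(
            "mean_cs_log", "mean_distinctiveness",
            P=cfg["behavioral"]["permutations"], seed=seeds["behavioral"],
        )
        summary = {
            "condition_index": res.condition_index,
            "n_subjects": res.n_subjects,
            "correlations": res.correlations.to_dict(orient="records"),
            "mean_cs_log_bootstrap_ci": list(ci),
            "contrast_observed": diff,
            "contrast_permutation_p": perm_p,
        }
        with open(outdir / "behavioral_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        _done("behavioral", t0, n_rows=len(bdata))
    except Exception as exc:
        failed = [k for k, v in manifest["stages"].items() if "runtime_s" not in v]
        stage = failed[-1] if failed else "unknown"
        log.error("pipeline halted in stage %r: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=_json_default)
    return outdir


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
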