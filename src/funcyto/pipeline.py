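"""End-to-end orchestration: input files to effect tables, profiles, figures.

``run_pipeline`` drives the stages (extract or load traces, ratio,
normalize, baseline-correct, quantify, profile, cluster) from a single
configuration mapping, writes every intermediate as CSV so each stage can be
re-run independently, and records a machine-readable manifest (config hash,
package versions, per-stage cell/frame counts, dropped cells).
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path

import yaml

from . import __version__
from .baseline import METHODS, fit_baseline, subtract_baseline
from .clustering import hierarchical_profile, kmeans_profile, pca_contributions
from .effects import EFFECT_METHODS, build_expanded_regions, effect_table
from .profiling import effect_correlations, rank_cells, sorting_statistic, split_population
from .roi import DetectionParams, TimeLapseStack, average_projection, detect_rois, extract_traces
from .traces import (
    TimestampSchedule,
    compute_ratio,
    normalize_to_initial,
    read_trace_csv,
    write_trace_csv,
)

logger = logging.getLogger("funcyto")


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


class DataError(ValueError):
    """Input data inconsistent with the configuration."""


DEFAULTS = {
    "baseline_method": "piecewise_linear",
    "effect_method": "linear",
    "n_initial": 5,
    "n_post": 20,
    "detection": {"prominence": 100.0, "tolerance": 200.0, "max_linear_size_um": 30.0},
    "clustering": {"k_min": 1, "k_max": 10, "n_init": 25},
    "seed": 0,
}


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return cfg


def _config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(canon).hexdigest()


def _require(config: dict, key: str):
    if key not in config:
        raise ConfigError(f"config is missing required key {key!r}")
    return config[key]


def run_pipeline(config: dict, out_dir) -> dict:
    """Run all stages; returns the manifest (also written to manifest.json).

    Required config keys: ``schedule`` (path) and either ``acceptor_tiff`` +
    ``donor_tiff`` (with ``pixel_size_um``, ``frame_interval_s``) or
    ``acceptor_csv`` + ``donor_csv``, or ``ratio_csv`` for single-fluorophore
    data that enters directly as R.  Optional keys override DEFAULTS;
    ``marker`` enables the population split and correlations.
    """
    cfg = {**DEFAULTS, **(config or {})}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "funcyto_version": __version__,
        "config": cfg,
        "config_hash": _config_hash(cfg),
        "stages": {},
    }

    schedule_path = _require(cfg, "schedule")
    if not Path(schedule_path).exists():
        raise ConfigError(f"schedule file not found: {schedule_path}")
    schedule = TimestampSchedule.from_yaml(schedule_path)

    if cfg.get("baseline_method") not in METHODS:
        raise ConfigError(f"baseline_method must be one of {METHODS}")
    if cfg.get("effect_method") not in EFFECT_METHODS:
        raise ConfigError(f"effect_method must be one of {EFFECT_METHODS}")

    # ---- stage 1: traces -------------------------------------------------
    if "acceptor_tiff" in cfg:
        det = {**DEFAULTS["detection"], **cfg.get("detection", {})}
        pixel = float(_require(cfg, "pixel_size_um"))
        interval = float(cfg.get("frame_interval_s", schedule.frame_interval_s))
        for key in ("acceptor_tiff", "donor_tiff"):
            if not Path(_require(cfg, key)).exists():
                raise ConfigError(f"{key} file not found: {cfg[key]}")
        acc = TimeLapseStack.from_tiff(cfg["acceptor_tiff"], pixel, interval, "acceptor")
        don = TimeLapseStack.from_tiff(cfg["donor_tiff"], pixel, interval, "donor")
        rois = detect_rois(
            average_projection(acc),
            DetectionParams(det["prominence"], det["tolerance"], det["max_linear_size_um"]),
            pixel,
        )
        rois.to_csv(out / "rois.csv")
        acceptor = extract_traces(acc, rois)
        donor = extract_traces(don, rois)
        manifest["stages"]["roi_extraction"] = {"n_rois": len(rois)}
        logger.info("detected %d ROIs", len(rois))
    elif "acceptor_csv" in cfg:
        acceptor, _ = read_trace_csv(_require(cfg, "acceptor_csv"))
        donor, _ = read_trace_csv(_require(cfg, "donor_csv"))
    elif "ratio_csv" in cfg:
        acceptor = None
        donor = None
    else:
        raise ConfigError(
            "config must provide acceptor_tiff/donor_tiff, acceptor_csv/donor_csv "
            "or ratio_csv"
        )

    # ---- stage 2: ratio + normalization ---------------------------------
    try:
        if "ratio_csv" in cfg:
            ratio, _ = read_trace_csv(cfg["ratio_csv"])
        else:
            ratio = compute_ratio(acceptor, donor)
        if len(ratio) != schedule.total_frames:
            raise DataError(
                f"trace matrix has {len(ratio)} frames but schedule covers "
                f"{schedule.total_frames}"
            )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            norm = normalize_to_initial(ratio, n_initial=int(cfg["n_initial"]))
        dropped = [str(w.message) for w in caught]
    except ValueError as exc:
        raise DataError(f"normalization stage failed: {exc}") from exc
    write_trace_csv(out / "normalized.csv", norm.data, schedule.frame_interval_s)
    manifest["stages"]["normalize"] = {
        "n_frames": int(len(norm.data)),
        "n_cells": int(norm.data.shape[1]),
        "dropped_cells": dropped,
    }

    # ---- stage 3: baseline correction -----------------------------------
    model = fit_baseline(norm, schedule, method=cfg["baseline_method"])
    corrected = subtract_baseline(norm, model)
    write_trace_csv(out / "corrected.csv", corrected, schedule.frame_interval_s)
    (out / "baseline_meta.json").write_text(
        json.dumps(
            {
                "method": cfg["baseline_method"],
                "n_fallback": int(model.diagnostics["fallback"].sum()),
            },
            indent=2,
        )
    )
    manifest["stages"]["baseline"] = {
        "method": cfg["baseline_method"],
        "n_fallback": int(model.diagnostics["fallback"].sum()),
    }

    # ---- stage 4: effect quantification ---------------------------------
    regions = build_expanded_regions(schedule, n_post=int(cfg["n_post"]))
    effects, diagnostics = effect_table(corrected, regions, method=cfg["effect_method"])
    effects.to_csv(out / "effects.csv", index_label="cell")
    diagnostics.to_csv(out / "effect_diagnostics.csv", index=False)
    manifest["stages"]["effects"] = {
        "method": cfg["effect_method"],
        "n_conditions": len(regions),
        "n_fallback": int(diagnostics["fallback"].sum()),
    }

    # ---- stage 5: profiling ---------------------------------------------
    marker = cfg.get("marker")
    if marker is not None:
        stat = sorting_statistic(corrected, schedule, marker)
        ranked, order = rank_cells(corrected, stat)
        stat.values.rename("sorting_statistic").to_csv(out / "sorting_statistic.csv")
        split = split_population(effects, marker, float(cfg.get("split_threshold", 0.0)))
        split.classes.rename("class").to_csv(out / "population_split.csv")
        pairs = [tuple(p) for p in cfg.get("correlation_pairs", [])]
        if pairs:
            corr = effect_correlations(effects, split, pairs)
            corr.to_csv(out / "effect_correlations.csv", index=False)
        manifest["stages"]["profiling"] = {
            "marker": marker,
            "n_alpha_like": int((split.classes == "alpha_like").sum()),
            "n_beta_like": int((split.classes == "beta_like").sum()),
        }

    # ---- stage 6: clustering --------------------------------------------
    clu = cfg.get("clustering", {})
    clu = {**DEFAULTS["clustering"], **clu}
    if effects.shape[0] >= clu["k_max"] and effects.shape[1] >= 2:
        result = kmeans_profile(
            effects,
            (int(clu["k_min"]), int(clu["k_max"])),
            seed=int(cfg["seed"]),
            n_init=int(clu["n_init"]),
        )
        result.assignment.rename("cluster").to_csv(out / "cluster_assignment.csv")
        result.within_ss.rename("within_ss").to_csv(out / "within_ss.csv", index_label="k")
        dend = hierarchical_profile(effects, axis="conditions")
        (out / "condition_dendrogram.nwk").write_text(dend.to_newick() + "\n")
        pca = pca_contributions(effects)
        pca.to_csv(out / "pca_contributions.csv", index_label="condition")
        manifest["stages"]["clustering"] = {
            "elbow_k": int(result.k),
            "within_ss": {int(k): v for k, v in result.within_ss.items()},
        }

    manifest["checksums"] = {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(out.iterdir())
        if p.suffix in (".csv", ".nwk", ".json") and p.name != "manifest.json"
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
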