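"""Reproducible benchmark harnesses for the whole pipeline.

Each function simulates data under the package's standard study conditions
(an 8-agent perifusion protocol, 600 one-minute frames, exponential
two-channel photobleaching, 3% read noise, amplitudes in [-0.5, 0.8], a
sign-opposed marker agent in 25% of cells), runs the pipeline, and scores it
against the generator's ground truth:

* amplitude recovery RMSE of the two-region and sigmoid estimators;
* the signal-to-noise gain of normalization and piecewise-linear baseline
  correction (with paired significance across cells);
* RMS deviation of every single-region estimator from the two-region
  reference;
* ROI detection on planted Gaussian blobs, including the oversized-artefact
  exclusion;
* marker-based population splitting and variance-based ranking;
* k-means elbow selection and condition-dendrogram structure on planted
  cluster/latent-factor effect tables.

All randomness derives from the single ``seed`` argument.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

from . import synthetic as syn
from .baseline import compute_snr, fit_baseline, subtract_baseline
from .clustering import hierarchical_profile, kmeans_profile
from .effects import build_expanded_regions, compare_methods_rms, effect_table
from .profiling import sorting_statistic, split_population
from .roi import DetectionParams, average_projection, detect_rois
from .traces import compute_ratio, normalize_to_initial

MARKER = "agent_7"


def standard_recording(seed: int, n_cells: int = 200):
    """Simulate the standard study conditions and run correction.

    Returns a dict with the schedule, planted truth, per-cell subpopulation
    labels, and raw/normalized/corrected matrices.
    """
    schedule = syn.standard_schedule(n_conditions=8)
    cells = syn.make_population(n_cells, schedule, seed=seed, marker_label=MARKER)
    donor, acceptor, truth = syn.simulate_traces(
        cells, schedule, syn.default_drift(0.03), schedule.total_frames, seed=seed
    )
    ratio = compute_ratio(acceptor, donor)
    norm = normalize_to_initial(ratio)
    model = fit_baseline(norm, schedule, method="piecewise_linear")
    corrected = subtract_baseline(norm, model)
    return {
        "schedule": schedule,
        "cells": cells,
        "truth": truth,
        "ratio": ratio,
        "normalized": norm.data,
        "corrected": corrected,
        "regions": build_expanded_regions(schedule),
    }


def amplitude_recovery(rec: dict) -> dict:
    """RMSE of recovered vs planted plateau amplitudes, per estimator."""
    out = {}
    for method in ("two_region", "sigmoid"):
        table, _ = effect_table(rec["corrected"], rec["regions"], method=method)
        err = table.to_numpy() - rec["truth"].to_numpy()
        out[method] = float(np.sqrt((err**2).mean()))
    out["n"] = int(rec["truth"].size)
    return out


def snr_benchmark(rec: dict) -> dict:
    """Mean SNR of raw, normalized and corrected data plus paired p-values."""
    reference = rec["truth"].abs().mean(axis=0).idxmax()
    reports = {
        "raw": compute_snr(rec["ratio"], rec["schedule"], reference),
        "normalized": compute_snr(rec["normalized"], rec["schedule"], reference),
        "piecewise_linear": compute_snr(rec["corrected"], rec["schedule"], reference),
    }
    p_raw_norm = stats.wilcoxon(
        reports["raw"].per_cell, reports["normalized"].per_cell, alternative="less"
    ).pvalue
    p_norm_corr = stats.wilcoxon(
        reports["normalized"].per_cell,
        reports["piecewise_linear"].per_cell,
        alternative="less",
    ).pvalue
    return {
        "means": {k: r.mean for k, r in reports.items()},
        "sems": {k: r.sem for k, r in reports.items()},
        "p_raw_vs_normalized": float(p_raw_norm),
        "p_normalized_vs_corrected": float(p_norm_corr),
        "n": reports["raw"].n_cells,
    }


def rms_benchmark(rec: dict) -> pd.DataFrame:
    """RMS deviation of each single-region estimator from two_region."""
    return compare_methods_rms(rec["corrected"], rec["regions"])


def roi_benchmark(seed: int) -> dict:
    """Detection of 50 valid (8-25 um) and 5 oversized (>30 um) blobs."""
    rng = np.random.default_rng(seed)
    # jittered grid for the valid cells, oversized artefacts in a separate
    # band: planted objects are well separated (clearance > 2 x FWHM), as in
    # a sparsely labelled tissue image
    positions = [(40 + 60 * i, 40 + 60 * j) for j in range(7) for i in range(8)][:50]
    blobs = []
    for x, y in positions:
        x += rng.uniform(-8, 8)
        y += rng.uniform(-8, 8)
        blobs.append((x, y, rng.uniform(8, 25) / 2.0, 1000.0))
    for i in range(5):
        blobs.append((60.0 + 95 * i, 480.0, rng.uniform(36, 44) / 2.0, 1000.0))
    stack = syn.simulate_image_stack(
        blobs, frame_count=20, pixel_size_um=1.0, noise_sd=20.0, seed=seed
    )
    rois = detect_rois(
        average_projection(stack), DetectionParams(prominence=300.0, tolerance=500.0), 1.0
    )
    valid = np.array([(b[0], b[1]) for b in blobs[:50]])
    oversized = np.array([(b[0], b[1]) for b in blobs[50:]])
    got = np.array([r.centroid for r in rois]) if len(rois) else np.empty((0, 2))
    d_valid = cdist(got, valid) if len(got) else np.empty((0, 50))
    n_matched = int((d_valid.min(axis=1) < 1.0).sum()) if len(got) else 0
    max_err = float(d_valid.min(axis=1).max()) if len(got) else np.nan
    n_near_oversized = (
        int((cdist(got, oversized).min(axis=1) < 10.0).sum()) if len(got) else 0
    )
    return {
        "n_detected": len(rois),
        "n_valid_matched": n_matched,
        "n_oversized_detected": n_near_oversized,
        "max_centroid_error_px": max_err,
    }


def split_benchmark(rec: dict) -> dict:
    """Marker-based classification accuracy and Eq.-5 ranking separation."""
    effects, _ = effect_table(rec["corrected"], rec["regions"], method="two_region")
    split = split_population(effects, MARKER)
    true_classes = np.array(
        [
            "alpha_like" if c.subpopulation_label == "alpha-like" else "beta_like"
            for c in rec["cells"]
        ]
    )
    accuracy = float((split.classes.to_numpy() == true_classes).mean())

    stat = sorting_statistic(rec["corrected"], rec["schedule"], MARKER)
    # restrict the separation claim to cells whose marker amplitude exceeds
    # five times their own basal noise level
    basal = rec["schedule"].basal_frames()
    noise = rec["corrected"].iloc[basal].std(axis=0, ddof=0).to_numpy()
    amp = rec["truth"][MARKER].to_numpy()
    strong = np.abs(amp) / np.maximum(noise, 1e-12) >= 5.0
    s = stat.values.to_numpy()
    pos, neg = strong & (amp > 0), strong & (amp < 0)
    separated = bool(s[pos].min() > s[neg].max()) if pos.any() and neg.any() else False
    return {
        "accuracy": accuracy,
        "ranking_separated": separated,
        "n": len(true_classes),
        "n_strong": int(strong.sum()),
    }


def cluster_benchmark(seed: int, n_runs: int = 10, n_cells: int = 2000) -> dict:
    """Elbow-k and ARI on planted 4-cluster effect tables; clade recovery of
    three latent-factor-sharing conditions, over seeded repeats."""
    from sklearn.metrics import adjusted_rand_score

    rng = np.random.default_rng(seed)
    centers = rng.uniform(-0.5, 0.8, (4, 6))
    labels = [f"cond{j}" for j in range(6)]
    elbow_hits = 0
    clade_hits = 0
    aris = []
    for i in range(n_runs):
        sub_seed = (seed * 1000 + i) % (2**31 - 1)
        effects, truth = syn.simulate_effect_clusters(
            n_cells, labels, centers, within_sd=0.08, seed=sub_seed
        )
        res = kmeans_profile(effects, (1, 10), seed=sub_seed, n_init=10)
        elbow_hits += res.k == 4
        aris.append(adjusted_rand_score(truth, res.assignments_by_k[4]))
        latent = syn.simulate_latent_factor_effects(
            500,
            ["glp_1pM", "glp_100pM", "glp_10nM"],
            ["gip_100pM", "adrenaline", "forskolin"],
            seed=sub_seed,
        )
        dend = hierarchical_profile(latent, axis="conditions")
        clade_hits += dend.is_clade(["glp_1pM", "glp_100pM", "glp_10nM"])
    return {
        "elbow_hits": int(elbow_hits),
        "clade_hits": int(clade_hits),
        "n_runs": n_runs,
        "min_ari_at_k4": float(min(aris)),
        "mean_ari_at_k4": float(np.mean(aris)),
    }


def oracle_deviations(seed: int) -> dict:
    """Max deviation of vectorized core operations from brute-force loops."""
    from .effects import ExpandedRegion, quantify_effect
    from .roi import TimeLapseStack

    rng = np.random.default_rng(seed)
    devs = {}

    voxels = rng.uniform(0, 100, (5, 20, 10))
    proj = average_projection(TimeLapseStack(voxels))
    loop = np.zeros((20, 10))
    for t in range(5):
        for y in range(20):
            for x in range(10):
                loop[y, x] += voxels[t, y, x] / 5
    devs["average_projection"] = float(np.abs(proj - loop).max())

    a = pd.DataFrame(rng.uniform(1, 10, (20, 10)))
    d = pd.DataFrame(rng.uniform(1, 10, (20, 10)))
    ratio = compute_ratio(a, d)
    loop_r = np.array(
        [[a.iloc[i, j] / d.iloc[i, j] for j in range(10)] for i in range(20)]
    )
    devs["compute_ratio"] = float(np.abs(ratio.to_numpy() - loop_r).max())

    norm = normalize_to_initial(ratio)
    loop_n = np.array(
        [
            [
                ratio.iloc[i, j] / (sum(ratio.iloc[k, j] for k in range(5)) / 5)
                for j in range(10)
            ]
            for i in range(20)
        ]
    )
    devs["normalize_to_initial"] = float(np.abs(norm.data.to_numpy() - loop_n).max())

    region = ExpandedRegion("x", np.arange(0, 10), np.arange(10, 20))
    x = pd.DataFrame(rng.uniform(0.5, 1.5, (20, 10)))
    two = quantify_effect(x, region, method="two_region").amplitude.to_numpy()
    loop_t = np.array(
        [
            sum(x.iloc[i, j] for i in range(15, 20)) / 5
            - sum(x.iloc[i, j] for i in range(5, 10)) / 5
            for j in range(10)
        ]
    )
    devs["two_region"] = float(np.abs(two - loop_t).max())

    u = rng.normal(0, 1, 20)
    v = 0.5 * u + rng.normal(0, 1, 20)
    r_lib = stats.pearsonr(u, v).statistic
    mu_u, mu_v = sum(u) / 20, sum(v) / 20
    num = sum((a_ - mu_u) * (b_ - mu_v) for a_, b_ in zip(u, v))
    den = np.sqrt(sum((a_ - mu_u) ** 2 for a_ in u) * sum((b_ - mu_v) ** 2 for b_ in v))
    devs["pearson_r"] = float(abs(r_lib - num / den))
    return devs
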