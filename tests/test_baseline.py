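"""Baseline drift fitting, subtraction and the SNR benchmark."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from funcyto import synthetic as syn
from funcyto.baseline import METHODS, compute_snr, fit_baseline, subtract_baseline
from funcyto.traces import Condition, TimestampSchedule, compute_ratio, normalize_to_initial


def schedule_3cond():
    return TimestampSchedule(
        [Condition("a", 20, 40), Condition("b", 60, 80), Condition("c", 100, 120)],
        total_frames=140,
    )


def drifting_matrix(slope, n_frames=140, n_cells=5, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames)[:, None]
    base = 1.0 + slope * t + rng.normal(0, noise, (n_frames, n_cells))
    return pd.DataFrame(np.broadcast_to(base, (n_frames, n_cells)).copy())


@pytest.mark.parametrize("method", METHODS)
def test_constant_input_gives_unit_baseline_and_zero_residual(method):
    sched = schedule_3cond()
    x = pd.DataFrame(np.ones((140, 3)))
    model = fit_baseline(x, sched, method=method)
    assert np.allclose(model.baseline, 1.0, atol=1e-8)
    assert np.allclose(subtract_baseline(x, model), 1.0, atol=1e-8)


def test_piecewise_linear_recovers_planted_slope_per_cell():
    sched = schedule_3cond()
    slope = -1e-3
    x = drifting_matrix(slope)
    model = fit_baseline(x, sched, method="piecewise_linear")
    fitted_slope = np.diff(model.baseline.to_numpy(), axis=0).mean(axis=0)
    assert np.allclose(fitted_slope, slope, rtol=0.01)


def test_piecewise_linear_is_exact_on_linear_drift():
    """Drift linear across every anchor-to-anchor span (here: globally) is
    removed to float tolerance on every frame, not just basal ones."""
    sched = schedule_3cond()
    x = drifting_matrix(-2e-3)
    corrected = subtract_baseline(x, fit_baseline(x, sched, method="piecewise_linear"))
    assert np.allclose(corrected.to_numpy(), 1.0, atol=1e-9)


def test_polynomial_degree_equals_basal_regions_minus_one():
    """With 4 basal regions a cubic drift is captured exactly."""
    sched = schedule_3cond()
    t = np.arange(sched.total_frames, dtype=float)
    cubic = 1 + 1e-3 * t - 2e-5 * t**2 + 8e-8 * t**3
    x = pd.DataFrame(np.tile(cubic[:, None], (1, 2)))
    model = fit_baseline(x, sched, method="polynomial")
    assert len(sched.basal_regions()) == 4
    assert np.allclose(model.baseline.to_numpy()[:, 0], cubic, atol=1e-6)


def test_insufficient_basal_regions_rejected_by_name():
    sched = TimestampSchedule([], total_frames=50)
    x = pd.DataFrame(np.ones((50, 2)))
    with pytest.raises(ValueError, match="linear"):
        fit_baseline(x, sched, method="linear")


def test_exponential_falls_back_to_linear_when_it_cannot_converge():
    sched = schedule_3cond()
    rng = np.random.default_rng(0)
    x = pd.DataFrame(rng.normal(0.0, 1.0, (140, 3)))  # signless noise, no trend
    model = fit_baseline(x, sched, method="exponential", max_iter=1)
    assert model.diagnostics["fallback"].any()
    assert (~model.diagnostics["converged"] == model.diagnostics["fallback"]).all()


def test_baseline_uses_only_basal_frames():
    """Permuting values inside condition intervals must not change the fit."""
    sched = schedule_3cond()
    rng = np.random.default_rng(5)
    x = drifting_matrix(-5e-4, noise=0.01, seed=2)
    shuffled = x.copy()
    for cond in sched.conditions:
        idx = np.arange(cond.start, cond.end)
        shuffled.iloc[idx] = shuffled.iloc[rng.permutation(idx)].to_numpy()
    for method in METHODS:
        b1 = fit_baseline(x, sched, method=method).baseline
        b2 = fit_baseline(shuffled, sched, method=method).baseline
        assert np.allclose(b1, b2), method


@pytest.mark.parametrize("method", METHODS)
def test_correction_never_worse_than_constant_fit_on_basal_frames(method):
    sched = schedule_3cond()
    x = drifting_matrix(-8e-4, noise=0.005, seed=3)
    model = fit_baseline(x, sched, method=method)
    basal = sched.basal_frames()
    Y = x.to_numpy()[basal]
    resid_const = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    resid_fit = ((Y - model.baseline.to_numpy()[basal]) ** 2).sum(axis=0)
    assert (resid_fit <= resid_const + 1e-12).all()


def test_subtraction_preserves_planted_step_height():
    sched = schedule_3cond()
    x = drifting_matrix(-1e-3, noise=0.0)
    step = np.zeros((140, 5))
    cond = sched.conditions[1]
    step[cond.start : cond.end] = 0.4
    x = x + step
    corrected = subtract_baseline(x, fit_baseline(x, sched, method="piecewise_linear"))
    inside = corrected.to_numpy()[cond.start + 5 : cond.end].mean()
    outside = corrected.to_numpy()[5 : cond.start - 1].mean()
    assert inside - outside == pytest.approx(0.4, abs=1e-6)
    assert outside == pytest.approx(1.0, abs=1e-6)


class TestSNR:
    def test_planted_step_over_known_noise(self):
        """Step 0.5 against basal noise SD 0.05 gives SNR near 10."""
        sched = schedule_3cond()
        rng = np.random.default_rng(7)
        x = np.ones((140, 300)) + rng.normal(0, 0.05, (140, 300))
        cond = sched.conditions[0]
        x[cond.start : cond.end] += 0.5
        report = compute_snr(pd.DataFrame(x), sched, "a")
        assert report.mean == pytest.approx(10.0, rel=0.1)
        assert report.n_cells == 300

    def test_zero_noise_degenerate_case_excludes_cells(self):
        sched = schedule_3cond()
        x = np.ones((140, 4))
        x[20:40] += 0.3
        report = compute_snr(pd.DataFrame(x), sched, "a")
        assert report.n_cells == 0
        assert report.n_excluded == 4

    def test_snr_improves_raw_to_normalized_to_corrected(self, sim_recording):
        schedule, cells, donor, acceptor, truth = sim_recording
        ratio = compute_ratio(acceptor, donor)
        norm = normalize_to_initial(ratio)
        corrected = subtract_baseline(
            norm, fit_baseline(norm, schedule, method="piecewise_linear")
        )
        ref = truth.abs().mean(axis=0).idxmax()
        r_raw = compute_snr(ratio, schedule, ref)
        r_norm = compute_snr(norm.data, schedule, ref)
        r_corr = compute_snr(corrected, schedule, ref)
        assert r_raw.mean < r_norm.mean < r_corr.mean
        p1 = stats.wilcoxon(r_raw.per_cell, r_norm.per_cell, alternative="less").pvalue
        p2 = stats.wilcoxon(r_norm.per_cell, r_corr.per_cell, alternative="less").pvalue
        assert p1 < 0.01 and p2 < 0.01
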