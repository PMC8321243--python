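"""Sorting statistic, cell ranking, marker split and effect correlations."""

import numpy as np
import pandas as pd
import pytest

from funcyto.profiling import (
    effect_correlations,
    rank_cells,
    sorting_statistic,
    split_population,
)
from funcyto.traces import Condition, TimestampSchedule


def window_schedule():
    return TimestampSchedule([Condition("adr", 20, 40)], 60)


def trace_with_step(height, n_cells=1):
    x = np.ones((60, n_cells))
    x[20:40] += height
    return pd.DataFrame(x)


class TestSortingStatistic:
    def test_flat_trace_scores_zero(self):
        stat = sorting_statistic(pd.DataFrame(np.ones((60, 3))), window_schedule(), "adr")
        assert (stat.values == 0).all()

    def test_step_at_window_midpoint_equals_half_step_sd(self):
        """10 frames at 1 and 10 at 1.5: S = +SD of a balanced two-level set."""
        stat = sorting_statistic(trace_with_step(0.5), window_schedule(), "adr")
        assert stat.values.iloc[0] == pytest.approx(0.25)  # sd of {1,1.5} balanced

    def test_sign_symmetry_of_opposite_steps(self):
        up = sorting_statistic(trace_with_step(0.5), window_schedule(), "adr").values.iloc[0]
        down = sorting_statistic(trace_with_step(-0.4), window_schedule(), "adr").values.iloc[0]
        sym = sorting_statistic(trace_with_step(0.4), window_schedule(), "adr").values.iloc[0]
        assert up > 0 > down
        assert down == pytest.approx(-sym)

    def test_invariant_under_frame_permutation_within_window(self, rng):
        x = pd.DataFrame(rng.uniform(0.5, 1.5, (60, 5)))
        stat = sorting_statistic(x, window_schedule(), "adr")
        shuffled = x.copy()
        idx = np.arange(10, 30)
        shuffled.iloc[idx] = shuffled.iloc[rng.permutation(idx)].to_numpy()
        stat2 = sorting_statistic(shuffled, window_schedule(), "adr")
        assert np.allclose(stat.values, stat2.values)

    def test_out_of_bounds_window_rejected(self):
        sched = TimestampSchedule([Condition("adr", 5, 20)], 60)
        with pytest.raises(ValueError, match="out of bounds"):
            sorting_statistic(pd.DataFrame(np.ones((60, 2))), sched, "adr")


class TestRankCells:
    def test_sorted_input_is_identity(self):
        heights = [0.5, 0.3, 0.1, -0.2]
        x = pd.DataFrame(np.ones((60, 4)), columns=list("abcd"))
        for j, h in enumerate(heights):
            x.iloc[20:40, j] += h
        stat = sorting_statistic(x, window_schedule(), "adr")
        ranked, order = rank_cells(x, stat)
        assert order.tolist() == [0, 1, 2, 3]

    def test_reversed_input_reverses(self):
        x = pd.DataFrame(np.ones((60, 3)), columns=list("abc"))
        for j, h in enumerate([-0.2, 0.1, 0.4]):
            x.iloc[20:40, j] += h
        stat = sorting_statistic(x, window_schedule(), "adr")
        _, order = rank_cells(x, stat)
        assert order.tolist() == [2, 1, 0]

    def test_matches_independent_sort_oracle_and_is_bijective(self, rng):
        x = pd.DataFrame(rng.uniform(0.8, 1.4, (60, 20)))
        stat = sorting_statistic(x, window_schedule(), "adr")
        ranked, order = rank_cells(x, stat)
        expected = sorted(range(20), key=lambda j: -stat.values.iloc[j])
        assert order.tolist() == expected
        assert sorted(order.tolist()) == list(range(20))
        # ranking already-ranked data with recomputed statistics is idempotent
        stat2 = sorting_statistic(ranked, window_schedule(), "adr")
        ranked2, order2 = rank_cells(ranked, stat2)
        assert ranked2.columns.tolist() == ranked.columns.tolist()


class TestSplitPopulation:
    def test_signs_map_to_classes(self):
        effects = pd.DataFrame({"adr": [0.3, -0.3]}, index=["p", "n"])
        split = split_population(effects, "adr")
        assert split.classes["p"] == "alpha_like"
        assert split.classes["n"] == "beta_like"

    def test_missing_marker_rejected(self):
        with pytest.raises(ValueError, match="marker"):
            split_population(pd.DataFrame({"x": [1.0]}), "adr")

    def test_mixture_fraction_recovered(self, rng):
        n = 2000
        is_pos = rng.random(n) < 0.3
        amp = np.where(is_pos, rng.uniform(0.2, 0.5, n), -rng.uniform(0.2, 0.5, n))
        effects = pd.DataFrame({"adr": amp + rng.normal(0, 0.03, n)})
        split = split_population(effects, "adr")
        frac = (split.classes == "alpha_like").mean()
        assert frac == pytest.approx(0.3, abs=3 * np.sqrt(0.3 * 0.7 / n))


class TestEffectCorrelations:
    def make_split(self, n_alpha, n_beta):
        classes = pd.Series(
            ["alpha_like"] * n_alpha + ["beta_like"] * n_beta,
            index=range(n_alpha + n_beta),
        )
        from funcyto.profiling import PopulationSplit

        return PopulationSplit(classes=classes, marker="adr", threshold=0.0)

    def test_exact_linear_relation_gives_r_one(self, rng):
        x = rng.normal(0, 1, 20)
        effects = pd.DataFrame({"a": x, "b": 2 * x})
        out = effect_correlations(effects, self.make_split(10, 10), [("a", "b")])
        assert np.allclose(out["r"], 1.0)
        assert np.allclose(out["slope"], 2.0)

    def test_independent_noise_gives_near_zero_r(self, rng):
        effects = pd.DataFrame({"a": rng.normal(0, 1, 2000), "b": rng.normal(0, 1, 2000)})
        out = effect_correlations(effects, self.make_split(1000, 1000), [("a", "b")])
        assert (out["r"].abs() < 0.1).all()

    def test_planted_latent_factor_in_one_class_only(self, rng):
        n = 400
        latent = rng.normal(0, 1, n)
        a = np.where(np.arange(n) >= n // 2, latent, rng.normal(0, 1, n))
        b = np.where(np.arange(n) >= n // 2, latent + rng.normal(0, 0.3, n), rng.normal(0, 1, n))
        effects = pd.DataFrame({"a": a, "b": b})
        out = effect_correlations(effects, self.make_split(n // 2, n // 2), [("a", "b")])
        r_alpha = out.loc[out["class"] == "alpha_like", "r"].iloc[0]
        r_beta = out.loc[out["class"] == "beta_like", "r"].iloc[0]
        assert r_beta > r_alpha

    def test_zero_variance_column_reports_nan(self):
        effects = pd.DataFrame({"a": np.ones(10), "b": np.arange(10.0)})
        out = effect_correlations(effects, self.make_split(5, 5), [("a", "b")])
        assert out["r"].isna().all()

    def test_too_few_cells_rejected(self):
        effects = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="fewer than 3"):
            effect_correlations(effects, self.make_split(1, 2), [("a", "b")])
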