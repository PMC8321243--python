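"""Cell ranking, marker-based population splitting and effect correlations.

Cells are ranked by a sorting statistic computed over a window straddling
the addition of a chosen agent: S = sgn(window mean - 1) * window SD of the
corrected R/R0 trace.  A response of either sign inflates the SD of the
20-frame window, and the sign of the mean's deviation from the basal level
1 carries the direction, so sorting by S separates cells that were excited
by the agent from those it inhibited.  The marker compound (adrenaline in
islets: cAMP up in alpha-cells, down in beta-cells) then splits the
population by the sign of its fitted effect, and incretin effects can be
correlated per cell within each class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .baseline import _as_frame
from .traces import TimestampSchedule

__all__ = [
    "SortingStatistic",
    "PopulationSplit",
    "sorting_statistic",
    "rank_cells",
    "split_population",
    "effect_correlations",
]


@dataclass
class SortingStatistic:
    values: pd.Series  # S per cell, signed
    window: tuple[int, int]  # [start, stop) frames
    window_mean: pd.Series
    window_sd: pd.Series


@dataclass
class PopulationSplit:
    classes: pd.Series  # per cell: 'alpha_like' | 'beta_like'
    marker: str
    threshold: float

    def cells(self, cls: str) -> pd.Index:
        return self.classes.index[self.classes == cls]


def sorting_statistic(
    x,
    schedule: TimestampSchedule,
    condition: str,
    n_before: int = 10,
    n_after: int = 10,
) -> SortingStatistic:
    """S = sgn(mean - 1) * SD over the frames around the agent addition."""
    data = _as_frame(x)
    cond = schedule.condition(condition)
    start, stop = cond.start - n_before, cond.start + n_after
    if start < 0 or stop > len(data):
        raise ValueError(
            f"window [{start}, {stop}) around {condition!r} is out of bounds "
            f"for {len(data)} frames"
        )
    window = data.iloc[start:stop]
    mean = window.mean(axis=0)
    sd = window.std(axis=0, ddof=0)
    s = np.sign(mean - 1.0) * sd
    return SortingStatistic(values=s, window=(start, stop), window_mean=mean, window_sd=sd)


def rank_cells(x, stat: SortingStatistic) -> tuple[pd.DataFrame, np.ndarray]:
    """Reorder columns by descending sorting statistic (stable for ties).

    Returns the reordered matrix and the permutation of column positions,
    which can also be applied to EffectTable rows.
    """
    data = _as_frame(x)
    if not stat.values.index.equals(pd.Index(data.columns)):
        raise ValueError("sorting statistic does not cover the matrix columns")
    order = np.argsort(-stat.values.to_numpy(), kind="stable")
    return data.iloc[:, order], order


def split_population(
    effects: pd.DataFrame,
    marker: str,
    threshold: float = 0.0,
) -> PopulationSplit:
    """alpha_like iff the marker-compound amplitude exceeds the threshold."""
    if marker not in effects.columns:
        raise ValueError(f"marker condition {marker!r} not in effect table")
    classes = pd.Series(
        np.where(effects[marker] > threshold, "alpha_like", "beta_like"),
        index=effects.index,
    )
    return PopulationSplit(classes=classes, marker=marker, threshold=threshold)


def effect_correlations(
    effects: pd.DataFrame,
    split: PopulationSplit,
    pairs: list[tuple[str, str]],
    adjust: bool = False,
) -> pd.DataFrame:
    """Pearson correlation of per-cell amplitudes, per class and pair.

    Rows: (class, condition_a, condition_b, n, r, p, slope, intercept).
    Zero-variance columns give an undefined r (NaN).  ``adjust=True`` adds
    Benjamini-Hochberg adjusted p-values across the table.
    """
    rows = []
    for cls in ("alpha_like", "beta_like"):
        cells = split.cells(cls)
        if len(cells) < 3:
            raise ValueError(f"class {cls!r} has fewer than 3 cells")
        sub = effects.loc[cells]
        for a, b in pairs:
            xa = sub[a].to_numpy(dtype=float)
            xb = sub[b].to_numpy(dtype=float)
            if xa.std() == 0 or xb.std() == 0:
                r, p, slope, intercept = np.nan, np.nan, np.nan, np.nan
            else:
                r, p = stats.pearsonr(xa, xb)
                fit = stats.linregress(xa, xb)
                slope, intercept = fit.slope, fit.intercept
            rows.append(
                {
                    "class": cls,
                    "condition_a": a,
                    "condition_b": b,
                    "n": len(cells),
                    "r": r,
                    "p": p,
                    "slope": slope,
                    "intercept": intercept,
                }
            )
    out = pd.DataFrame(rows)
    if adjust:
        mask = out["p"].notna()
        adj = np.full(len(out), np.nan)
        if mask.any():
            adj[mask.to_numpy()] = stats.false_discovery_control(out.loc[mask, "p"])
        out["p_adj"] = adj
    return out
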