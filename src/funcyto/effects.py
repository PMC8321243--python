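"""Per-cell quantification of (ant)agonist effects from corrected traces.

Each condition is scored over an *expanded region*: the basal region that
precedes the agent plus the first ``n_post`` (default 20) frames after its
addition, so the window contains both the pre-effect and post-effect signal.
Six amplitude estimators are provided; ``two_region`` (difference of the
post-addition and basal plateau means) is the reference against which the
single-region fits are benchmarked, and ``linear`` is the default working
method because the transcendental fits occasionally fail to converge on
noisy cells (they then fall back to the linear estimate, flagged).

Sign convention: positive amplitude = the signal rises when the agent is
added, so inhibitory agents (adrenaline in beta-cells) score negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .baseline import _as_frame
from .traces import TimestampSchedule

__all__ = [
    "ExpandedRegion",
    "EffectResult",
    "build_expanded_regions",
    "quantify_effect",
    "effect_table",
    "compare_methods_rms",
    "EFFECT_METHODS",
]

EFFECT_METHODS = ("two_region", "linear", "square", "end_start", "sigmoid", "hill")


@dataclass
class ExpandedRegion:
    """Quantification window for one condition: basal + early-condition frames."""

    label: str
    basal_frames: np.ndarray
    condition_frames: np.ndarray

    def __post_init__(self) -> None:
        if len(self.basal_frames) < 1 or len(self.condition_frames) < 1:
            raise ValueError(
                f"expanded region {self.label!r} needs at least one basal and one "
                "condition frame"
            )

    @property
    def frames(self) -> np.ndarray:
        return np.concatenate([self.basal_frames, self.condition_frames])

    @property
    def addition_frame(self) -> int:
        return int(self.condition_frames[0])


@dataclass
class EffectResult:
    label: str
    method: str
    amplitude: pd.Series  # per cell, signed
    converged: pd.Series  # per cell, bool
    fallback: pd.Series  # per cell, bool: linear fallback used
    residual_ss: pd.Series


def build_expanded_regions(
    schedule: TimestampSchedule, n_post: int = 20
) -> list[ExpandedRegion]:
    """One region per condition: preceding basal frames plus the first
    ``n_post`` frames of agent application (clipped at the condition's end,
    the next condition's start and the end of the record)."""
    regions = []
    basal = schedule.basal_regions()
    starts = [c.start for c in schedule.conditions]
    for i, cond in enumerate(schedule.conditions):
        preceding = [r for r in basal if r[1] <= cond.start]
        if not preceding:
            raise ValueError(f"condition {cond.label!r} has no preceding basal frames")
        b0, b1 = max(preceding, key=lambda r: r[1])
        stop = min(cond.start + n_post, cond.end, schedule.total_frames)
        if i + 1 < len(starts):
            stop = min(stop, starts[i + 1])
        regions.append(
            ExpandedRegion(cond.label, np.arange(b0, b1), np.arange(cond.start, stop))
        )
    return regions


def _plateau(frames: np.ndarray, fraction: float = 0.5) -> np.ndarray:
    """Latter part of a window, skipping onset/washout kinetics."""
    k = max(1, int(np.ceil(len(frames) * fraction)))
    return frames[-k:]


def quantify_effect(
    x,
    region: ExpandedRegion,
    method: str = "linear",
    smoothing_window: int = 3,
    max_nfev: int = 500,
) -> EffectResult:
    """Signed per-cell amplitude of one condition's effect.

    two_region
        mean over the post-addition plateau minus mean over the basal
        plateau (latter halves of each sub-window).
    linear
        least-squares slope over the whole region times its span.
    square
        quadratic onset model ``base + a*(t - t_add)^2`` for frames after
        the addition (base before), fitted over the region; amplitude is the
        model's rise by the region end.  A plain end-minus-start of an
        unconstrained quadratic would be *identical* to the linear estimator
        on a uniform frame grid (the quadratic term is orthogonal to the
        linear one on a symmetric design), so the onset form is used; it
        overshoots saturating responses at the window end, which is this
        method's characteristic artefact.
    end_start
        last minus first frame of the region after a short moving-average
        smoothing.
    sigmoid / hill
        logistic / Hill curve in time; amplitude is the fitted curve's net
        change across the window (equal to the asymptote parameter when the
        onset is resolved, but bounded when it is not).  On non-convergence
        the linear estimate is used and flagged.
    """
    data = _as_frame(x)
    if method not in EFFECT_METHODS:
        raise ValueError(f"unknown effect method {method!r}; choose from {EFFECT_METHODS}")
    frames = region.frames
    if frames.max() >= len(data):
        raise ValueError(f"region {region.label!r} extends past the trace matrix")
    Y = data.to_numpy(dtype=float)
    n_cells = Y.shape[1]
    converged = np.ones(n_cells, dtype=bool)
    fallback = np.zeros(n_cells, dtype=bool)
    residual_ss = np.zeros(n_cells)

    if method == "two_region":
        amp = (
            Y[_plateau(region.condition_frames)].mean(axis=0)
            - Y[_plateau(region.basal_frames)].mean(axis=0)
        )
    elif method == "linear":
        amp = _linear_amplitude(Y, frames)
    elif method == "square":
        t = frames.astype(float)
        dt2 = np.clip(t - region.addition_frame, 0.0, None) ** 2
        design = np.stack([np.ones_like(t), dt2], axis=1)
        beta, *_ = np.linalg.lstsq(design, Y[frames], rcond=None)
        amp = beta[1] * dt2[-1]
    elif method == "end_start":
        sm = (
            pd.DataFrame(Y[frames])
            .rolling(smoothing_window, center=True, min_periods=1)
            .mean()
            .to_numpy()
        )
        amp = sm[-1] - sm[0]
    else:
        if len(frames) < 4:
            raise ValueError(f"method {method!r} needs at least 4 points in the region")
        # the logistic/Hill models assume a settled base before the onset, so
        # drop the leading basal frames still relaxing from the previous
        # washout; the crude estimators above use the raw window as-is
        fit_frames = np.concatenate([_plateau(region.basal_frames), region.condition_frames])
        amp = np.empty(n_cells)
        lin = _linear_amplitude(Y, frames)
        two_reg = (
            Y[_plateau(region.condition_frames)].mean(axis=0)
            - Y[_plateau(region.basal_frames)].mean(axis=0)
        )
        t = fit_frames.astype(float)
        t_add = float(region.addition_frame)
        span = t[-1] - t[0]
        for j in range(n_cells):
            y = Y[fit_frames, j]
            a, ok, rss = _fit_transcendental(t, y, method, two_reg[j], t_add, span, max_nfev)
            residual_ss[j] = rss
            if ok:
                amp[j] = a
            else:
                amp[j] = lin[j]
                converged[j] = False
                fallback[j] = True
    return EffectResult(
        label=region.label,
        method=method,
        amplitude=pd.Series(amp, index=data.columns),
        converged=pd.Series(converged, index=data.columns),
        fallback=pd.Series(fallback, index=data.columns),
        residual_ss=pd.Series(residual_ss, index=data.columns),
    )


def _linear_amplitude(Y: np.ndarray, frames: np.ndarray) -> np.ndarray:
    t = frames.astype(float)
    coef = np.polyfit(t, Y[frames], 1)
    return coef[0] * (t[-1] - t[0])


def _sigmoid(t, base, a, t50, tau):
    return base + a / (1.0 + np.exp(-(t - t50) / tau))


def _fit_transcendental(t, y, method, a0, t_add, span, max_nfev):
    base0 = float(y[t < t_add].mean()) if (t < t_add).any() else float(y[0])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            if method == "sigmoid":
                p0 = (base0, a0 if a0 != 0 else 1e-3, t_add + 5.0, 3.0)
                # midpoint inside the window, time constant shorter than it:
                # the onset must be resolvable within the expanded region
                bounds = (
                    [-np.inf, -np.inf, t[0], 0.1],
                    [np.inf, np.inf, t[-1], span / 2.0],
                )
                popt, _ = optimize.curve_fit(
                    _sigmoid, t, y, p0=p0, bounds=bounds, max_nfev=max_nfev
                )
                pred = _sigmoid(t, *popt)
            else:  # hill, onset clamped at the addition frame
                def _hill(tt, base, a, k, h):
                    dt = np.clip(tt - t_add, 0.0, None)
                    return base + a * dt**h / (k**h + dt**h)

                p0 = (base0, a0 if a0 != 0 else 1e-3, 5.0, 2.0)
                bounds = ([-np.inf, -np.inf, 0.1, 0.2], [np.inf, np.inf, 10 * span, 10.0])
                popt, _ = optimize.curve_fit(
                    _hill, t, y, p0=p0, bounds=bounds, max_nfev=max_nfev
                )
                pred = _hill(t, *popt)
        # amplitude = fitted net change across the window (bounded, unlike
        # the asymptote parameter when the onset is not resolved)
        a = pred[-1] - pred[0]
        data_range = float(y.max() - y.min())
        if (
            not np.isfinite(a)
            or not np.isfinite(pred).all()
            or abs(a) > 5.0 * max(data_range, 1e-12)
        ):
            # runaway amplitude: the curve explains the data only through an
            # unresolvable extrapolation; treat as non-converged
            return np.nan, False, np.nan
        return float(a), True, float(((y - pred) ** 2).sum())
    except (RuntimeError, ValueError):
        return np.nan, False, np.nan


def effect_table(
    x,
    regions: list[ExpandedRegion],
    method: str = "linear",
    **kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cells x conditions amplitude table plus per-entry diagnostics.

    Diagnostics rows are (cell, condition) with convergence/fallback flags;
    non-converged transcendental fits carry the linear fallback amplitude,
    never a silent zero.
    """
    data = _as_frame(x)
    amps = {}
    diag_rows = []
    for region in regions:
        res = quantify_effect(data, region, method=method, **kwargs)
        amps[region.label] = res.amplitude
        for cell in data.columns:
            diag_rows.append(
                {
                    "cell": cell,
                    "condition": region.label,
                    "method": method,
                    "converged": bool(res.converged[cell]),
                    "fallback": bool(res.fallback[cell]),
                    "residual_ss": float(res.residual_ss[cell]),
                }
            )
    table = pd.DataFrame(amps, index=data.columns)
    return table, pd.DataFrame(diag_rows)


def compare_methods_rms(
    x,
    regions: list[ExpandedRegion],
    methods: tuple[str, ...] = ("linear", "square", "end_start", "sigmoid", "hill"),
    reference: str = "two_region",
    **kwargs,
) -> pd.DataFrame:
    """RMS deviation of each estimator from the reference, over all
    converged (cell, condition) pairs; non-converged pairs are dropped
    pairwise and counted."""
    data = _as_frame(x)
    ref_tab, _ = effect_table(data, regions, method=reference, **kwargs)
    rows = {}
    for method in methods:
        diffs = []
        n_pairs = 0
        n_dropped = 0
        for region in regions:
            res = quantify_effect(data, region, method=method, **kwargs)
            ok = res.converged.to_numpy() & ~res.fallback.to_numpy()
            ref = ref_tab[region.label].to_numpy()
            d = res.amplitude.to_numpy()[ok] - ref[ok]
            diffs.append(d)
            n_pairs += int(ok.sum())
            n_dropped += int((~ok).sum())
        if n_pairs == 0:
            raise ValueError(f"no converged estimates for method {method!r}")
        all_d = np.concatenate(diffs)
        rows[method] = {
            "rms": float(np.sqrt((all_d**2).mean())),
            "n_pairs": n_pairs,
            "n_dropped": n_dropped,
        }
    out = pd.DataFrame(rows).T
    out.index.name = "method"
    return out
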