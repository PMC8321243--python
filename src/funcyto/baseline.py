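"""Per-cell baseline drift estimation anchored on basal regions.

Recurrent returns to agent-free (basal) conditions are assumed to restore
the true analyte level, so any trend visible across the basal regions is
instrumental drift (dominated by channel-wise photobleaching, which a
ratiometric sensor does not cancel because the two fluorophores bleach at
different rates).  A baseline trace is fitted per cell to basal-region data
only and subtracted; six strategies are provided:

``linear`` / ``exponential``
    a line, or ``a*exp(b*t) + c``, through the data of the first and last
    basal regions only;
``spline``
    an interpolating cubic B-spline through the per-region basal means;
``polynomial``
    least squares over all basal data, degree = number of basal regions - 1;
``piecewise_linear`` / ``piecewise_square``
    per non-basal region, a line / quadratic fitted to the two flanking
    basal regions; basal regions follow their own local fit, with a one-frame
    blend at the joints to keep the baseline continuous.

The piecewise-linear variant is the method of choice: it tracks slow
non-stationary drift without smearing small responses across the record.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.interpolate import make_interp_spline

from .traces import NormalizedTraces, TimestampSchedule

__all__ = ["BaselineModel", "SNRReport", "fit_baseline", "subtract_baseline", "compute_snr"]

METHODS = ("linear", "exponential", "spline", "polynomial", "piecewise_linear", "piecewise_square")


@dataclass
class BaselineModel:
    method: str
    baseline: pd.DataFrame  # frames x cells, same layout as the input
    diagnostics: pd.DataFrame  # per cell: residual_ss_basal, converged, fallback

    def __post_init__(self) -> None:
        if not np.isfinite(self.baseline.to_numpy()).all():
            raise ValueError("baseline trace contains non-finite values")


@dataclass
class SNRReport:
    method: str
    per_cell: pd.Series
    mean: float
    sem: float
    n_cells: int
    n_excluded: int


def _as_frame(x) -> pd.DataFrame:
    return x.data if isinstance(x, NormalizedTraces) else x


def _region_frames(regions: list[tuple[int, int]]) -> np.ndarray:
    return np.concatenate([np.arange(s, e) for s, e in regions])


def _trim_region(s: int, e: int, trim: float) -> np.ndarray:
    """Drop the leading ``trim`` fraction of a basal region.

    The first frames of a basal region still carry the washout relaxation of
    the preceding agent, so anchoring the drift fit on the settled tail of
    the region keeps response kinetics out of the baseline.  At least one
    frame is always kept.
    """
    k = min(int(np.floor((e - s) * trim)), e - s - 1)
    return np.arange(s + k, e)


def fit_baseline(
    x,
    schedule: TimestampSchedule,
    method: str = "piecewise_linear",
    basal_trim: float = 0.5,
    **options,
) -> BaselineModel:
    """Fit a per-cell drift trace using only basal-frame data.

    ``x`` is a frames x cells DataFrame (or :class:`NormalizedTraces`).
    Method-specific requirements on the number of basal regions are checked
    up front; a non-convergent exponential fit falls back to linear for that
    cell and is flagged in the diagnostics.  ``basal_trim`` is the leading
    fraction of every basal region excluded from the fit data (washout
    relaxation frames); the fitted baseline still covers all frames.
    """
    data = _as_frame(x)
    if method not in METHODS:
        raise ValueError(f"unknown baseline method {method!r}; choose from {METHODS}")
    regions = schedule.basal_regions()
    if method in ("linear", "exponential", "spline", "polynomial") and len(regions) < 2:
        raise ValueError(f"method {method!r} needs at least 2 basal regions, got {len(regions)}")
    if method.startswith("piecewise"):
        for cond in schedule.conditions:
            before = [r for r in regions if r[1] <= cond.start]
            after = [r for r in regions if r[0] >= cond.end]
            if not before or not after:
                raise ValueError(
                    f"method {method!r} needs a basal region before and after "
                    f"condition {cond.label!r}"
                )

    Y = data.to_numpy(dtype=float)
    n_frames, n_cells = Y.shape
    t_all = np.arange(n_frames, dtype=float)
    converged = np.ones(n_cells, dtype=bool)
    fallback = np.zeros(n_cells, dtype=bool)

    anchors = [_trim_region(s, e, basal_trim) for s, e in regions]
    if method == "linear":
        baseline = _fit_global_poly(Y, t_all, [anchors[0], anchors[-1]], degree=1)
    elif method == "exponential":
        baseline, converged, fallback = _fit_exponential(
            Y, t_all, [anchors[0], anchors[-1]], **options
        )
    elif method == "polynomial":
        baseline = _fit_global_poly(Y, t_all, anchors, degree=len(regions) - 1)
    elif method == "spline":
        baseline = _fit_spline(Y, t_all, anchors)
    else:
        degree = 1 if method == "piecewise_linear" else 2
        baseline = _fit_piecewise(Y, schedule, regions, anchors, degree)

    basal = np.concatenate(anchors)
    resid = Y[basal] - baseline[basal]
    diagnostics = pd.DataFrame(
        {
            "residual_ss_basal": (resid**2).sum(axis=0),
            "converged": converged,
            "fallback": fallback,
        },
        index=data.columns,
    )
    return BaselineModel(method, pd.DataFrame(baseline, index=data.index, columns=data.columns), diagnostics)


def _polyval_cols(coef: np.ndarray, t: np.ndarray | float) -> np.ndarray:
    """Evaluate per-cell polynomials (coef: (deg+1, m), highest power first)."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.zeros((len(t), coef.shape[1]))
    for c in coef:
        out = out * t[:, None] + c[None, :]
    return out


def _fit_global_poly(Y, t_all, anchors, degree) -> np.ndarray:
    frames = np.concatenate(anchors)
    degree = min(degree, len(frames) - 1)
    # center/scale the abscissa for conditioning at high degree
    t0, sc = t_all.mean(), max(t_all.std(), 1.0)
    coef = np.polyfit((frames - t0) / sc, Y[frames], degree)
    return _polyval_cols(coef, (t_all - t0) / sc)


def _fit_spline(Y, t_all, anchors) -> np.ndarray:
    # knots at anchor centers, values = per-anchor means (per cell)
    centers = np.array([fr.mean() for fr in anchors])
    means = np.stack([Y[fr].mean(axis=0) for fr in anchors])
    k = min(3, len(centers) - 1)
    spl = make_interp_spline(centers, means, k=k, axis=0)
    return np.asarray(spl(t_all))


def _fit_exponential(Y, t_all, anchors, tol: float = 1e-8, max_iter: int = 200):
    frames = np.concatenate(anchors)
    n_cells = Y.shape[1]
    baseline = np.empty((len(t_all), n_cells))
    converged = np.ones(n_cells, dtype=bool)
    fallback = np.zeros(n_cells, dtype=bool)
    lin = _fit_global_poly(Y, t_all, anchors, degree=1)

    def model(t, a, b, c):
        return a * np.exp(b * t) + c

    # initial decay rate from the two region means (log-linear)
    m0 = Y[anchors[0]].mean(axis=0)
    m1 = Y[anchors[-1]].mean(axis=0)
    t0 = anchors[0].mean()
    t1 = anchors[-1].mean()
    for j in range(n_cells):
        d0, d1 = m0[j], m1[j]
        with np.errstate(all="ignore"):
            b0 = np.log(abs(d1) / abs(d0)) / (t1 - t0) if d0 != 0 and d1 != 0 else -1e-3
        if not np.isfinite(b0) or b0 == 0:
            b0 = -1e-3
        p0 = (d0 - 0.0, b0, 0.0)
        try:
            popt, _ = optimize.curve_fit(
                model, frames, Y[frames, j], p0=p0, maxfev=max_iter * 4, ftol=tol, xtol=tol
            )
            pred = model(t_all, *popt)
            if not np.isfinite(pred).all():
                raise RuntimeError("non-finite prediction")
            baseline[:, j] = pred
        except (RuntimeError, optimize.OptimizeWarning, ValueError):
            baseline[:, j] = lin[:, j]
            converged[j] = False
            fallback[j] = True
    return baseline, converged, fallback


def _segment_fit(Y, frames, degree):
    """Polynomial coefficients (per cell) over the given frames."""
    deg = min(degree, len(frames) - 1)
    return np.polyfit(frames.astype(float), Y[frames], deg)


def _fit_piecewise(Y, schedule: TimestampSchedule, regions, anchors, degree) -> np.ndarray:
    n_frames, n_cells = Y.shape
    baseline = np.empty((n_frames, n_cells))
    # order segments along time: basal regions use their own local fit,
    # condition regions the fit through the two flanking basal anchors
    segments: list[tuple[int, int, np.ndarray]] = []
    for (s, e), fr in zip(regions, anchors):
        coef = _segment_fit(Y, fr, degree)
        segments.append((s, e, coef))
    for cond in schedule.conditions:
        i_before = max(
            (i for i, r in enumerate(regions) if r[1] <= cond.start),
            key=lambda i: regions[i][1],
        )
        i_after = min(
            (i for i, r in enumerate(regions) if r[0] >= cond.end),
            key=lambda i: regions[i][0],
        )
        anchor = np.concatenate([anchors[i_before], anchors[i_after]])
        coef = _segment_fit(Y, anchor, degree)
        segments.append((cond.start, cond.end, coef))
    segments.sort(key=lambda seg: seg[0])
    for s, e, coef in segments:
        t = np.arange(s, e, dtype=float)
        baseline[s:e] = _polyval_cols(coef, t)
    # continuity: blend the two local fits over one frame at each joint
    for (s0, e0, c0), (s1, e1, c1) in zip(segments, segments[1:]):
        j = float(s1)
        baseline[s1] = 0.5 * (_polyval_cols(c0, j)[0] + _polyval_cols(c1, j)[0])
    return baseline


def subtract_baseline(x, model: BaselineModel) -> pd.DataFrame:
    """Remove the fitted drift, re-anchoring the basal level at 1.

    Output = x - baseline + 1, so deviations from 1 read directly as
    fractional responses.
    """
    data = _as_frame(x)
    if data.shape != model.baseline.shape:
        raise ValueError("data and baseline shapes differ")
    return data - model.baseline + 1.0


def compute_snr(
    x,
    schedule: TimestampSchedule,
    reference_condition: str,
    plateau_fraction: float = 0.5,
    basal_trim: float = 0.5,
) -> SNRReport:
    """Signal-to-noise ratio of the reference response, reported mean +- SEM.

    Signal (per cell): |mean over the plateau frames of the reference
    condition - mean over the adjacent preceding basal frames|.  Noise: the
    pooled standard deviation of settled basal-frame entries about the
    pooled basal mean, taken across all cells and basal frames, so it
    reflects per-cell intensity spread, residual drift and read noise alike.
    Plateau frames are the last ``plateau_fraction`` of the condition
    interval, skipping the onset kinetics; basal windows are trimmed by
    ``basal_trim`` from the front to skip washout relaxation, which is
    signal kinetics rather than noise.
    """
    data = _as_frame(x)
    cond = schedule.condition(reference_condition)
    regions = schedule.basal_regions()
    preceding = [r for r in regions if r[1] <= cond.start]
    if not preceding:
        raise ValueError(f"no basal region precedes condition {reference_condition!r}")
    b0, b1 = max(preceding, key=lambda r: r[1])

    Y = data.to_numpy(dtype=float)
    plateau = np.arange(cond.start + int(np.floor((cond.end - cond.start) * (1 - plateau_fraction))), cond.end)
    basal_adj = _trim_region(b0, b1, basal_trim)
    signal = np.abs(Y[plateau].mean(axis=0) - Y[basal_adj].mean(axis=0))

    basal_all = Y[np.concatenate([_trim_region(s, e, basal_trim) for s, e in regions])]
    noise_sd = float(basal_all.std())
    if noise_sd == 0:
        return SNRReport(
            method="", per_cell=pd.Series(dtype=float), mean=np.nan, sem=np.nan,
            n_cells=0, n_excluded=data.shape[1],
        )
    snr = pd.Series(signal / noise_sd, index=data.columns)
    return SNRReport(
        method="",
        per_cell=snr,
        mean=float(snr.mean()),
        sem=float(snr.std(ddof=1) / np.sqrt(len(snr))) if len(snr) > 1 else 0.0,
        n_cells=len(snr),
        n_excluded=0,
    )
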