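"""Synthetic two-channel recordings with known ground truth.

The generator emulates what the analysis pipeline assumes about a perifusion
time-lapse of a FRET biosensor in tissue:

* per-cell sensor expression scales both emission channels by the same
  (log-normal) factor;
* slow monotone photobleaching drift, multiplicative on raw intensities and
  *different* between donor and acceptor, so the ratio drifts too;
* reversible responses to sequentially applied agents: saturating
  ``1 - exp(-t/onset_tau)`` onset to a plateau ``1 + amplitude`` of the
  normalized ratio while the agent is present, exponential relaxation back to
  baseline after washout;
* additive Gaussian read noise on the raw intensity scale;
* heterogeneous subpopulations, including sign-opposed responses to a marker
  compound (adrenaline raises cAMP in alpha-cells and lowers it in
  beta-cells).

Everything is seeded and bit-reproducible; each simulator returns the planted
ground truth alongside the data so recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .roi import TimeLapseStack
from .traces import TimestampSchedule

__all__ = [
    "CellSpec",
    "DriftSpec",
    "default_drift",
    "response_profile",
    "simulate_traces",
    "simulate_image_stack",
    "make_population",
    "standard_schedule",
    "simulate_effect_clusters",
    "simulate_latent_factor_effects",
]

# Baseline raw intensities; the acceptor (YFP) channel is the brighter one.
DONOR_LEVEL = 1000.0
ACCEPTOR_LEVEL = 2000.0


def default_drift(noise_sd_rel: float = 0.03) -> "DriftSpec":
    """Photobleaching defaults for a multi-hour recording at 1-min frames.

    Channel bleaching rates of 2e-4 and 4e-4 per frame leave the raw ratio
    down ~11% after 600 frames (10 h): barely visible over the first couple
    of hours, clearly drifting after that, which is the regime in which
    baseline correction matters.  ``noise_sd_rel`` is read noise relative to
    the donor intensity (0.03 = 3%), i.e. about 3% SD on the normalized
    ratio for a median-expression cell.
    """
    return DriftSpec(
        model="exponential",
        donor_rate=-2e-4,
        acceptor_rate=-4e-4,
        noise_sd=noise_sd_rel * DONOR_LEVEL,
    )


@dataclass
class CellSpec:
    """Ground-truth description of one simulated cell."""

    cell_id: int
    expression_scale: float = 1.0
    response_amplitudes: dict[str, float] = field(default_factory=dict)
    onset_tau: float = 3.0
    relax_tau: float = 3.0
    subpopulation_label: str = "beta-like"
    # per-cell baseline acceptor/donor ratio multiplier: cell-to-cell spread
    # of the resting FRET ratio (optical path, sensor state) that the R/R0
    # normalization removes; expression_scale alone cancels in the ratio
    ratio_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.expression_scale <= 0:
            raise ValueError("expression_scale must be positive")
        if self.ratio_scale <= 0:
            raise ValueError("ratio_scale must be positive")
        if self.onset_tau <= 0 or self.relax_tau <= 0:
            raise ValueError("onset_tau and relax_tau must be positive")


@dataclass
class DriftSpec:
    """Channel-wise slow drift plus additive read noise.

    ``model='exponential'`` gives ``exp(rate * t)`` bleaching factors,
    ``model='linear'`` gives ``1 + rate * t``; rates are per frame and may
    differ between channels (so the ratio drifts even though the sensor is
    ratiometric).
    """

    model: str = "exponential"
    donor_rate: float = 0.0
    acceptor_rate: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.model not in ("linear", "exponential"):
            raise ValueError(f"unknown drift model {self.model!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def factors(self, n_frames: int) -> tuple[np.ndarray, np.ndarray]:
        t = np.arange(n_frames, dtype=float)
        if self.model == "exponential":
            donor = np.exp(self.donor_rate * t)
            acceptor = np.exp(self.acceptor_rate * t)
        else:
            donor = 1.0 + self.donor_rate * t
            acceptor = 1.0 + self.acceptor_rate * t
        if (donor <= 0).any() or (acceptor <= 0).any():
            raise ValueError("drift factors must stay strictly positive")
        return donor, acceptor


def response_profile(cell: CellSpec, schedule: TimestampSchedule, n_frames: int) -> np.ndarray:
    """Planted normalized-ratio curve for one cell (drift- and noise-free).

    1 at baseline; during each condition the deviation ramps towards the
    planted plateau amplitude with time constant ``onset_tau`` and relaxes
    exponentially with ``relax_tau`` after removal.
    """
    t = np.arange(n_frames, dtype=float)
    r = np.ones(n_frames)
    for cond in schedule.conditions:
        a = cell.response_amplitudes.get(cond.label, 0.0)
        if a == 0.0:
            continue
        during = (t >= cond.start) & (t < cond.end)
        r[during] += a * (1.0 - np.exp(-(t[during] - cond.start) / cell.onset_tau))
        level_at_end = a * (1.0 - np.exp(-(cond.end - cond.start) / cell.onset_tau))
        after = t >= cond.end
        r[after] += level_at_end * np.exp(-(t[after] - cond.end) / cell.relax_tau)
    return r


def simulate_traces(
    cells: list[CellSpec],
    schedule: TimestampSchedule,
    drift: DriftSpec,
    n_frames: int,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate donor and acceptor trace matrices plus the ground truth.

    Returns ``(donor, acceptor, truth)`` where the trace matrices are
    frames x cells DataFrames and ``truth`` is the cells x conditions table
    of planted plateau amplitudes.
    """
    if n_frames < 10:
        raise ValueError("n_frames must be at least 10")
    for cond in schedule.conditions:
        if cond.end > n_frames:
            raise ValueError(
                f"schedule interval {cond.label!r} [{cond.start}, {cond.end}) "
                f"does not fit in n_frames={n_frames}"
            )
    for cell in cells:
        unknown = set(cell.response_amplitudes) - set(schedule.labels)
        if unknown:
            raise ValueError(
                f"cell {cell.cell_id}: amplitudes for unscheduled condition(s) {sorted(unknown)}"
            )

    rng = np.random.default_rng(seed)
    drift_d, drift_a = drift.factors(n_frames)
    donor = np.empty((n_frames, len(cells)))
    acceptor = np.empty_like(donor)
    for j, cell in enumerate(cells):
        r = response_profile(cell, schedule, n_frames)
        donor[:, j] = cell.expression_scale * DONOR_LEVEL * drift_d
        acceptor[:, j] = (
            cell.expression_scale * cell.ratio_scale * ACCEPTOR_LEVEL * drift_a * r
        )
    if drift.noise_sd > 0:
        donor += rng.normal(0.0, drift.noise_sd, donor.shape)
        acceptor += rng.normal(0.0, drift.noise_sd, acceptor.shape)

    ids = [c.cell_id for c in cells]
    truth = pd.DataFrame(
        [[c.response_amplitudes.get(lab, 0.0) for lab in schedule.labels] for c in cells],
        index=ids,
        columns=schedule.labels,
        dtype=float,
    )
    donor_df = pd.DataFrame(donor, columns=ids)
    acceptor_df = pd.DataFrame(acceptor, columns=ids)
    return donor_df, acceptor_df, truth


def simulate_image_stack(
    cells_xy: list[tuple[float, float, float, float]],
    frame_count: int,
    pixel_size_um: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    shape: tuple[int, int] = (512, 512),
    channel: str = "acceptor",
    per_frame_scale: np.ndarray | None = None,
) -> TimeLapseStack:
    """Render Gaussian blobs into a time-lapse stack.

    Each entry of ``cells_xy`` is ``(x_px, y_px, radius_um, peak_intensity)``.
    The blob is a 2-D Gaussian whose intensity falls to half the peak at a
    distance ``radius_um`` from the center, so its equivalent linear size
    (full width at half maximum) is ``2 * radius_um``.  Frames are identical
    up to noise unless a per-frame intensity scale is supplied
    (``per_frame_scale``: frames x blobs array).
    """
    ny, nx = shape
    frame = np.zeros((ny, nx))
    yy, xx = np.mgrid[0:ny, 0:nx]
    for x, y, radius_um, peak in cells_xy:
        if not (0 <= x < nx and 0 <= y < ny):
            raise ValueError(f"blob center ({x}, {y}) outside frame {shape}")
        if radius_um <= 0:
            raise ValueError("blob radius must be positive")
        sigma_px = radius_um / pixel_size_um / np.sqrt(2.0 * np.log(2.0))
        frame += peak * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2.0 * sigma_px**2))

    if per_frame_scale is not None:
        per_frame_scale = np.asarray(per_frame_scale, dtype=float)
        if per_frame_scale.shape != (frame_count, len(cells_xy)):
            raise ValueError("per_frame_scale must have shape (frame_count, n_blobs)")
        voxels = np.zeros((frame_count, ny, nx))
        for t in range(frame_count):
            f = np.zeros((ny, nx))
            for (x, y, radius_um, peak), s in zip(cells_xy, per_frame_scale[t]):
                sigma_px = radius_um / pixel_size_um / np.sqrt(2.0 * np.log(2.0))
                f += s * peak * np.exp(
                    -((xx - x) ** 2 + (yy - y) ** 2) / (2.0 * sigma_px**2)
                )
            voxels[t] = f
    else:
        voxels = np.broadcast_to(frame, (frame_count, ny, nx)).copy()
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        voxels += rng.normal(0.0, noise_sd, voxels.shape)
    return TimeLapseStack(
        voxels=voxels, pixel_size_um=pixel_size_um, frame_interval_s=1.0, channel=channel
    )


def standard_schedule(
    n_conditions: int = 8,
    basal_frames: int = 40,
    condition_frames: int = 30,
    washout_frames: int = 40,
    labels: list[str] | None = None,
    frame_interval_s: float = 60.0,
) -> TimestampSchedule:
    """A perifusion-style protocol: basal, then agent/washout cycles.

    Defaults mimic the kind of multi-agonist experiment the pipeline targets:
    eight sequential agents, each application followed by a return to basal
    conditions, 1-minute frames.  Total length is
    ``basal_frames + n_conditions * (condition_frames + washout_frames)``.
    """
    from .traces import Condition

    if labels is None:
        labels = [f"agent_{i + 1}" for i in range(n_conditions)]
    if len(labels) != n_conditions:
        raise ValueError("labels length must match n_conditions")
    conditions = []
    cursor = basal_frames
    for lab in labels:
        conditions.append(Condition(lab, cursor, cursor + condition_frames))
        cursor += condition_frames + washout_frames
    return TimestampSchedule(conditions, cursor, frame_interval_s)


def make_population(
    n_cells: int,
    schedule: TimestampSchedule,
    seed: int,
    marker_label: str | None = None,
    marker_positive_frac: float = 0.25,
    marker_amplitude_range: tuple[float, float] = (0.2, 0.5),
    amplitude_range: tuple[float, float] = (-0.5, 0.8),
    onset_tau: float = 3.0,
    relax_tau: float = 3.0,
    expression_sigma: float = 0.4,
    ratio_sigma: float = 0.3,
) -> list[CellSpec]:
    """Draw a heterogeneous cell population for a given protocol.

    Non-marker amplitudes are uniform over ``amplitude_range``; expression
    scales and baseline-ratio multipliers are log-normal (median 1).  If ``marker_label`` is given, a
    fraction of cells responds to it with a positive amplitude drawn from
    ``marker_amplitude_range`` ("alpha-like", adrenaline-positive) and the
    rest with the negated range ("beta-like"), mimicking a marker compound
    with sign-opposed effects in the two populations.
    """
    rng = np.random.default_rng(seed)
    cells = []
    for i in range(n_cells):
        amps = {
            lab: float(rng.uniform(*amplitude_range))
            for lab in schedule.labels
            if lab != marker_label
        }
        label = "beta-like"
        if marker_label is not None:
            lo, hi = marker_amplitude_range
            if rng.random() < marker_positive_frac:
                amps[marker_label] = float(rng.uniform(lo, hi))
                label = "alpha-like"
            else:
                amps[marker_label] = float(-rng.uniform(lo, hi))
        cells.append(
            CellSpec(
                cell_id=i,
                expression_scale=float(rng.lognormal(0.0, expression_sigma)),
                ratio_scale=float(rng.lognormal(0.0, ratio_sigma)),
                response_amplitudes=amps,
                onset_tau=onset_tau,
                relax_tau=relax_tau,
                subpopulation_label=label,
            )
        )
    return cells


def simulate_effect_clusters(
    n_cells: int,
    labels: list[str],
    centers: np.ndarray,
    within_sd: float,
    seed: int,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Effect table drawn from ``k`` Gaussian blobs in effect space.

    ``centers`` is a k x len(labels) array; cells are assigned to blobs
    uniformly.  Returns the table and the true blob index per cell.
    """
    centers = np.asarray(centers, dtype=float)
    if centers.ndim != 2 or centers.shape[1] != len(labels):
        raise ValueError("centers must be k x n_conditions")
    rng = np.random.default_rng(seed)
    assignment = rng.integers(0, len(centers), n_cells)
    values = centers[assignment] + rng.normal(0.0, within_sd, (n_cells, len(labels)))
    return pd.DataFrame(values, columns=labels), assignment


def simulate_latent_factor_effects(
    n_cells: int,
    factor_labels: list[str],
    independent_labels: list[str],
    seed: int,
    loading: float = 1.0,
    noise_sd: float = 0.3,
) -> pd.DataFrame:
    """Effect table where ``factor_labels`` share one per-cell latent factor.

    Conditions in ``factor_labels`` equal ``loading * latent + noise`` (so
    they correlate strongly across cells, like responses to three doses of
    the same agonist); ``independent_labels`` are pure noise.
    """
    rng = np.random.default_rng(seed)
    latent = rng.normal(0.0, 1.0, n_cells)
    cols = {}
    for lab in factor_labels:
        cols[lab] = loading * latent + rng.normal(0.0, noise_sd, n_cells)
    for lab in independent_labels:
        cols[lab] = rng.normal(0.0, 1.0, n_cells)
    return pd.DataFrame(cols)
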