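"""Timestamp schedules, channel ratios and initial-value normalization.

The central data layout throughout the package is the intensity-vs-time
matrix: a :class:`pandas.DataFrame` with one row per frame and one column per
cell (ROI).  The acceptor/donor ratio and its normalization to the mean of
the first few timepoints share this layout, so downstream stages (baseline
correction, effect quantification, profiling) all operate on plain frames ×
cells DataFrames.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Condition",
    "TimestampSchedule",
    "NormalizedTraces",
    "compute_ratio",
    "normalize_to_initial",
    "read_trace_csv",
    "write_trace_csv",
]


@dataclass(frozen=True)
class Condition:
    """One agent-application interval, half-open in frames: [start, end)."""

    label: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"condition {self.label!r}: invalid interval [{self.start}, {self.end})"
            )

    @property
    def frames(self) -> np.ndarray:
        return np.arange(self.start, self.end)


@dataclass
class TimestampSchedule:
    """Ordered record of which agent was applied over which frames.

    The complement of the condition intervals defines the *basal* regions
    (no agent applied); these anchor baseline correction and effect
    quantification.  A schedule must leave at least one basal frame before
    the first condition and after the last one.
    """

    conditions: list[Condition]
    total_frames: int
    frame_interval_s: float = 1.0

    def __post_init__(self) -> None:
        self.conditions = sorted(self.conditions, key=lambda c: c.start)
        prev_end = None
        for c in self.conditions:
            if c.end > self.total_frames:
                raise ValueError(
                    f"condition {c.label!r} [{c.start}, {c.end}) exceeds "
                    f"total_frames={self.total_frames}"
                )
            if prev_end is not None and c.start < prev_end:
                raise ValueError(f"overlapping condition intervals at {c.label!r}")
            prev_end = c.end
        if self.conditions:
            if self.conditions[0].start == 0:
                raise ValueError("schedule must start with at least one basal frame")
            if self.conditions[-1].end == self.total_frames:
                raise ValueError("schedule must end with at least one basal frame")

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.conditions]

    def condition(self, label: str) -> Condition:
        for c in self.conditions:
            if c.label == label:
                return c
        raise KeyError(f"no condition labelled {label!r} in schedule")

    def basal_regions(self) -> list[tuple[int, int]]:
        """Maximal half-open frame intervals with no agent applied."""
        regions: list[tuple[int, int]] = []
        cursor = 0
        for c in self.conditions:
            if c.start > cursor:
                regions.append((cursor, c.start))
            cursor = c.end
        if cursor < self.total_frames:
            regions.append((cursor, self.total_frames))
        return regions

    def basal_frames(self) -> np.ndarray:
        if not self.conditions:
            return np.arange(self.total_frames)
        return np.concatenate([np.arange(s, e) for s, e in self.basal_regions()])

    def condition_frames(self) -> np.ndarray:
        if not self.conditions:
            return np.array([], dtype=int)
        return np.concatenate([c.frames for c in self.conditions])

    # ---- file round trip ------------------------------------------------

    @classmethod
    def from_yaml(cls, path) -> "TimestampSchedule":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "TimestampSchedule":
        interval = float(doc.get("frame_interval_s", 1.0))
        total = doc.get("total_frames")
        conditions = []
        for entry in doc.get("conditions", []):
            label = entry.get("label")
            if label is None:
                agent = entry["agent"]
                conc = entry.get("concentration")
                label = f"{agent} @ {conc}" if conc else str(agent)
            if "start_frame" in entry:
                start, end = int(entry["start_frame"]), int(entry["end_frame"])
            else:
                # timestamps in seconds, round-to-nearest frame
                start = int(round(float(entry["start_s"]) / interval))
                end = int(round(float(entry["end_s"]) / interval))
            conditions.append(Condition(label, start, end))
        if total is None:
            raise ValueError("schedule document must state total_frames")
        return cls(conditions, int(total), interval)

    def to_dict(self) -> dict:
        return {
            "total_frames": self.total_frames,
            "frame_interval_s": self.frame_interval_s,
            "conditions": [
                {"label": c.label, "start_frame": c.start, "end_frame": c.end}
                for c in self.conditions
            ],
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class NormalizedTraces:
    """R/R0 matrix plus the per-cell initial ratios it was divided by."""

    data: pd.DataFrame
    r0: pd.Series = field(repr=False)


def compute_ratio(acceptor: pd.DataFrame, donor: pd.DataFrame) -> pd.DataFrame:
    """Element-wise acceptor/donor intensity ratio (frames x cells).

    Both matrices must share shape and cell ids.  Non-positive donor
    intensities would make the ratio meaningless, so they are rejected with
    the offending (cell, frame) coordinates.
    """
    if acceptor.shape != donor.shape or list(acceptor.columns) != list(donor.columns):
        raise ValueError("acceptor and donor matrices must share shape and cell ids")
    bad = donor.to_numpy() <= 0
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-positive donor intensity at cell {donor.columns[j]!r}, "
            f"frame {donor.index[i]} (and {bad.sum() - 1} more)"
        )
    return acceptor / donor


def normalize_to_initial(ratio: pd.DataFrame, n_initial: int = 5) -> NormalizedTraces:
    """Divide each cell's trace by the mean of its first ``n_initial`` frames.

    This removes the per-cell scale set by sensor expression level.  Cells
    whose initial mean is not positive cannot be normalized; they are dropped
    with a warning rather than imputed.
    """
    if not (1 <= n_initial <= len(ratio)):
        raise ValueError(f"n_initial={n_initial} out of range for {len(ratio)} frames")
    r0 = ratio.iloc[:n_initial].mean(axis=0)
    bad = ~(r0 > 0)
    if bad.any():
        dropped = list(ratio.columns[bad])
        warnings.warn(
            f"dropping {len(dropped)} cell(s) with non-positive initial ratio: "
            f"{dropped[:5]}{'...' if len(dropped) > 5 else ''}",
            stacklevel=2,
        )
        ratio = ratio.loc[:, ~bad]
        r0 = r0[~bad]
    return NormalizedTraces(data=ratio / r0, r0=r0)


def read_trace_csv(path) -> tuple[pd.DataFrame, float]:
    """Read a trace matrix CSV (first column = time in seconds, header = cell ids).

    Returns the frames x cells matrix (integer frame index) and the frame
    interval inferred from the time column.
    """
    df = pd.read_csv(path)
    time_s = df.iloc[:, 0].to_numpy(dtype=float)
    data = df.iloc[:, 1:]
    data.index = pd.RangeIndex(len(data))
    interval = float(np.median(np.diff(time_s))) if len(time_s) > 1 else 1.0
    return data, interval


def write_trace_csv(path, data: pd.DataFrame, frame_interval_s: float = 1.0) -> None:
    out = data.copy()
    out.insert(0, "time_s", np.arange(len(data)) * frame_interval_s)
    out.to_csv(path, index=False)
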