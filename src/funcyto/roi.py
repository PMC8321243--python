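"""Cell detection and trace extraction from time-lapse stacks.

Cells are found on the time-averaged projection of the (brighter) acceptor
channel: prominent local intensity maxima seed a flood fill within a
tolerance of the peak, each filled patch becomes a region of interest (ROI),
and implausibly large objects (default equivalent linear size > 30 um) are
discarded as artefacts.  The per-ROI mean intensity over time, taken with the
same ROI set on both channels, yields the frames x cells trace matrix that
the rest of the pipeline consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
from skimage import measure, morphology

__all__ = [
    "TimeLapseStack",
    "DetectionParams",
    "ROI",
    "ROISet",
    "average_projection",
    "detect_rois",
    "extract_traces",
    "align_channels",
]


@dataclass
class TimeLapseStack:
    """One channel of a recording: (t, y, x) intensities plus calibration."""

    voxels: np.ndarray
    pixel_size_um: float = 1.0
    frame_interval_s: float = 1.0
    channel: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3 or self.voxels.shape[0] < 1:
            raise ValueError("stack must be a (t, y, x) array with at least one frame")
        if not np.isfinite(self.voxels).all():
            raise ValueError("stack contains non-finite intensities")
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ValueError("pixel_size_um and frame_interval_s must be positive")

    @property
    def n_frames(self) -> int:
        return self.voxels.shape[0]

    @classmethod
    def from_tiff(cls, path, pixel_size_um: float, frame_interval_s: float,
                  channel: str = "") -> "TimeLapseStack":
        voxels = tifffile.imread(path)
        if voxels.ndim == 2:
            voxels = voxels[None]
        return cls(voxels.astype(float), pixel_size_um, frame_interval_s, channel)

    def to_tiff(self, path) -> None:
        tifffile.imwrite(path, self.voxels.astype(np.float32))


@dataclass
class DetectionParams:
    """Maxima/flood-fill detection knobs.

    prominence
        Minimum intensity difference between a local maximum and the highest
        saddle connecting it to higher ground; smaller bumps are merged.
    tolerance
        Flood-fill threshold: a pixel joins an ROI if it is connected to the
        seed maximum and within ``tolerance`` below its intensity.
    max_linear_size_um
        ROIs whose equivalent circular diameter exceeds this are discarded
        as artefacts (default 30 um, about twice an islet-cell diameter).
    """

    prominence: float
    tolerance: float
    max_linear_size_um: float = 30.0

    def __post_init__(self) -> None:
        if self.prominence <= 0 or self.tolerance <= 0:
            raise ValueError("prominence and tolerance must be positive")


@dataclass
class ROI:
    roi_id: int
    pixels: tuple[np.ndarray, np.ndarray]  # (rows, cols) index arrays
    centroid: tuple[float, float]  # (x, y), intensity-weighted
    size_um: float  # equivalent circular diameter

    @property
    def area_px(self) -> int:
        return len(self.pixels[0])


@dataclass
class ROISet:
    rois: list[ROI] = field(default_factory=list)
    pixel_size_um: float = 1.0

    def __len__(self) -> int:
        return len(self.rois)

    def __iter__(self):
        return iter(self.rois)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.roi_id for r in self.rois],
                "centroid_x": [r.centroid[0] for r in self.rois],
                "centroid_y": [r.centroid[1] for r in self.rois],
                "area_px": [r.area_px for r in self.rois],
                "size_um": [r.size_um for r in self.rois],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def average_projection(stack: TimeLapseStack) -> np.ndarray:
    """Mean over time of every pixel: the 2-D pattern image for detection."""
    return stack.voxels.mean(axis=0)


def _prominent_maxima(image: np.ndarray, prominence: float) -> list[tuple[int, int]]:
    """Seed pixels of local maxima with topographic prominence >= threshold."""
    if image.max() - image.min() < prominence:
        return []
    # morphological h-maxima: plateaus that stand at least `prominence` above
    # the saddle connecting them to anything higher
    hmax = morphology.h_maxima(image, prominence)
    labels = measure.label(hmax, connectivity=2)
    seeds = []
    for lab in range(1, labels.max() + 1):
        rows, cols = np.nonzero(labels == lab)
        k = np.argmax(image[rows, cols])
        seeds.append((int(rows[k]), int(cols[k])))
    # descending seed intensity; deterministic tie-break on position
    seeds.sort(key=lambda rc: (-image[rc], rc))
    return seeds


def detect_rois(
    projection: np.ndarray, params: DetectionParams, pixel_size_um: float
) -> ROISet:
    """Detect cells on a projection image.

    Prominent maxima (8-connected) seed flood fills that claim every
    connected pixel within ``params.tolerance`` of the seed intensity;
    overlapping claims go to the higher maximum (processed first).  ROIs
    larger than ``params.max_linear_size_um`` in equivalent circular
    diameter are removed afterwards.
    """
    projection = np.asarray(projection, dtype=float)
    if not np.isfinite(projection).all():
        raise ValueError("projection contains non-finite pixels")
    claimed = np.full(projection.shape, -1, dtype=int)
    rois: list[ROI] = []
    next_id = 0
    for seed in _prominent_maxima(projection, params.prominence):
        if claimed[seed] >= 0:
            continue  # already absorbed by a higher maximum
        seed_val = projection[seed]
        mask = (projection >= seed_val - params.tolerance) & (claimed < 0)
        comp = measure.label(mask, connectivity=2)
        region = comp == comp[seed]
        rows, cols = np.nonzero(region)
        size_um = _equivalent_diameter(len(rows), pixel_size_um)
        if size_um > params.max_linear_size_um:
            claimed[region] = -2  # oversized artefact: remove, do not re-claim
            continue
        # centroid from the bright core of the patch, weighted by intensity
        # above the flood threshold: the pedestal under the patch and faint
        # rim pixels (where a neighbor's tail leaks in) carry no reliable
        # position information
        excess = projection[rows, cols] - (seed_val - params.tolerance)
        core = excess >= 0.5 * excess.max()
        weights = np.where(core, excess, 0.0)
        wsum = weights.sum()
        if wsum <= 0:
            weights = np.ones_like(weights)
            wsum = weights.sum()
        cx = float((cols * weights).sum() / wsum)
        cy = float((rows * weights).sum() / wsum)
        claimed[region] = next_id
        rois.append(ROI(next_id, (rows, cols), (cx, cy), size_um))
        next_id += 1
    return ROISet(rois, pixel_size_um)


def _equivalent_diameter(area_px: int, pixel_size_um: float) -> float:
    """Diameter of the circle with the same area, in micrometers."""
    return 2.0 * np.sqrt(area_px / np.pi) * pixel_size_um


def extract_traces(stack: TimeLapseStack, rois: ROISet) -> pd.DataFrame:
    """Mean ROI intensity per frame: the intensity-vs-time matrix.

    The ROI set is defined once (on the acceptor projection) and reused for
    both channels, so columns line up across channels by construction.
    """
    nt, ny, nx = stack.voxels.shape
    flat = stack.voxels.reshape(nt, ny * nx)
    out = {}
    for roi in rois:
        rows, cols = roi.pixels
        if len(rows) == 0:
            raise ValueError(f"ROI {roi.roi_id} has no pixels")
        if rows.max() >= ny or cols.max() >= nx:
            raise ValueError(f"ROI {roi.roi_id} extends outside the stack")
        out[roi.roi_id] = flat[:, rows * nx + cols].mean(axis=1)
    return pd.DataFrame(out)


def align_channels(
    a: TimeLapseStack, b: TimeLapseStack, max_shift_px: int = 5
) -> tuple[int, int]:
    """Integer-pixel displacement (dx, dy) of ``b``'s content relative to ``a``'s.

    Exhaustive search over +-max_shift_px maximizing the Pearson correlation
    of the overlapping region of the two average projections; ties resolve
    toward the smaller shift (zero shift is always a candidate).  Apply the
    opposite shift to ``b`` to register the channels.
    """
    if a.voxels.shape[1:] != b.voxels.shape[1:]:
        raise ValueError("stacks must share frame dimensions")
    pa = average_projection(a)
    pb = average_projection(b)
    ny, nx = pa.shape
    best = (0, 0)
    best_score = -np.inf
    shifts = sorted(
        (
            (dx, dy)
            for dx in range(-max_shift_px, max_shift_px + 1)
            for dy in range(-max_shift_px, max_shift_px + 1)
        ),
        key=lambda s: (abs(s[0]) + abs(s[1]), max(abs(s[0]), abs(s[1])), s),
    )
    for dx, dy in shifts:
        # hypothesis: b's content is a's shifted by (dx, dy), so
        # b[y, x] ~ a[y - dy, x - dx] over the overlap
        ay0, ay1 = max(dy, 0), ny + min(dy, 0)
        ax0, ax1 = max(dx, 0), nx + min(dx, 0)
        if ay1 - ay0 < 2 or ax1 - ax0 < 2:
            continue
        wb = pb[ay0:ay1, ax0:ax1].ravel()
        wa = pa[ay0 - dy : ay1 - dy, ax0 - dx : ax1 - dx].ravel()
        sa, sb = wa.std(), wb.std()
        if sa == 0 or sb == 0:
            score = 0.0
        else:
            score = float(np.corrcoef(wa, wb)[0, 1])
        if score > best_score + 1e-12:
            best_score = score
            best = (dx, dy)
    return best
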