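"""Average projection, maxima/flood-fill ROI detection, trace extraction."""

import numpy as np
import pytest

from funcyto import synthetic as syn
from funcyto.roi import (
    ROI,
    ROISet,
    DetectionParams,
    TimeLapseStack,
    align_channels,
    average_projection,
    detect_rois,
    extract_traces,
)


class TestAverageProjection:
    def test_constant_stack_projects_to_single_frame(self, rng):
        frame = rng.uniform(0, 10, (6, 6))
        stack = TimeLapseStack(np.repeat(frame[None], 4, axis=0))
        assert np.allclose(average_projection(stack), frame)

    def test_two_frame_mean(self):
        stack = TimeLapseStack(np.stack([np.full((3, 3), 2.0), np.full((3, 3), 4.0)]))
        assert np.allclose(average_projection(stack), 3.0)

    def test_matches_brute_force_accumulation(self, rng):
        voxels = rng.uniform(0, 100, (5, 8, 8))
        proj = average_projection(TimeLapseStack(voxels))
        for y in range(8):
            for x in range(8):
                acc = 0.0
                for t in range(5):
                    acc += voxels[t, y, x]
                assert proj[y, x] == pytest.approx(acc / 5, abs=1e-12)

    def test_projection_is_linear_in_the_stack(self, rng):
        s1 = rng.uniform(0, 1, (4, 5, 5))
        s2 = rng.uniform(0, 1, (4, 5, 5))
        lhs = average_projection(TimeLapseStack(3 * s1 + 2 * s2))
        rhs = 3 * average_projection(TimeLapseStack(s1)) + 2 * average_projection(
            TimeLapseStack(s2)
        )
        assert np.allclose(lhs, rhs)

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            TimeLapseStack(np.empty((0, 4, 4)))


class TestDetectRois:
    params = DetectionParams(prominence=50.0, tolerance=100.0)

    def test_uniform_image_yields_no_rois(self):
        assert len(detect_rois(np.full((32, 32), 7.0), self.params, 1.0)) == 0

    def test_two_separated_blobs_found_with_accurate_centroids(self):
        stack = syn.simulate_image_stack(
            [(20.0, 24.0, 4.0, 500.0), (70.0, 60.0, 4.0, 500.0)],
            1,
            shape=(96, 96),
            noise_sd=2.0,
            seed=0,
        )
        rois = detect_rois(average_projection(stack), DetectionParams(100.0, 250.0), 1.0)
        assert len(rois) == 2
        got = sorted(r.centroid for r in rois)
        for (cx, cy), (px, py) in zip(got, [(20.0, 24.0), (70.0, 60.0)]):
            assert abs(cx - px) < 1.0 and abs(cy - py) < 1.0

    def test_oversized_object_excluded_by_default_filter(self):
        # equivalent linear size 40 um > 30 um default cut
        stack = syn.simulate_image_stack([(64.0, 64.0, 20.0, 500.0)], 1, shape=(128, 128))
        rois = detect_rois(average_projection(stack), DetectionParams(100.0, 250.0), 1.0)
        assert len(rois) == 0

    def test_size_filter_is_a_strict_post_filter(self):
        """Dropping the size cut can only add ROIs, never remove any."""
        blobs = [(30.0, 30.0, 4.0, 500.0), (90.0, 90.0, 18.0, 500.0)]
        proj = average_projection(syn.simulate_image_stack(blobs, 1, shape=(128, 128)))
        strict = detect_rois(proj, DetectionParams(100.0, 250.0, max_linear_size_um=30), 1.0)
        loose = detect_rois(proj, DetectionParams(100.0, 250.0, max_linear_size_um=1e9), 1.0)
        assert len(loose) >= len(strict)
        assert len(strict) == 1 and len(loose) == 2


class TestExtractTraces:
    def test_single_pixel_roi_returns_that_time_series(self, rng):
        voxels = rng.uniform(0, 1, (7, 4, 4))
        stack = TimeLapseStack(voxels)
        roi = ROI(0, (np.array([2]), np.array([3])), (3.0, 2.0), 1.0)
        traces = extract_traces(stack, ROISet([roi]))
        assert np.allclose(traces[0], voxels[:, 2, 3])

    def test_constant_stack_gives_constant_traces(self):
        stack = TimeLapseStack(np.full((5, 6, 6), 3.5))
        roi = ROI(0, (np.array([0, 1]), np.array([0, 1])), (0.5, 0.5), 2.0)
        assert np.allclose(extract_traces(stack, ROISet([roi])), 3.5)

    def test_matches_per_frame_pixel_average_loop(self, rng):
        voxels = rng.uniform(0, 9, (6, 10, 10))
        rows = np.array([1, 1, 2, 5])
        cols = np.array([3, 4, 4, 7])
        roi = ROI(7, (rows, cols), (0, 0), 2.0)
        traces = extract_traces(TimeLapseStack(voxels), ROISet([roi]))
        for t in range(6):
            acc = sum(voxels[t, r, c] for r, c in zip(rows, cols))
            assert traces.loc[t, 7] == pytest.approx(acc / 4, abs=1e-12)

    def test_empty_roi_rejected(self, rng):
        stack = TimeLapseStack(rng.uniform(0, 1, (3, 4, 4)))
        roi = ROI(0, (np.array([], dtype=int), np.array([], dtype=int)), (0, 0), 0.0)
        with pytest.raises(ValueError, match="no pixels"):
            extract_traces(stack, ROISet([roi]))


def test_detection_pipeline_recovers_planted_intensity_schedules():
    """projection -> detection -> extraction reproduces each blob's planted
    per-frame intensity schedule up to a constant factor."""
    schedules = np.stack([np.linspace(1, 2, 8), np.full(8, 1.0), 1 + 0.5 * np.sin(np.arange(8))], axis=1)
    blobs = [(24.0, 24.0, 4.0, 400.0), (72.0, 24.0, 4.0, 400.0), (48.0, 72.0, 4.0, 400.0)]
    stack = syn.simulate_image_stack(blobs, 8, shape=(96, 96), per_frame_scale=schedules)
    rois = detect_rois(average_projection(stack), DetectionParams(100.0, 200.0), 1.0)
    assert len(rois) == 3
    traces = extract_traces(stack, rois)
    for roi in rois:
        cx, cy = roi.centroid
        k = int(np.argmin([(cx - b[0]) ** 2 + (cy - b[1]) ** 2 for b in blobs]))
        tr = traces[roi.roi_id].to_numpy()
        ratio = tr / schedules[:, k]
        assert np.allclose(ratio, ratio[0], rtol=1e-8)


class TestAlignChannels:
    def test_identical_stacks_align_at_zero(self, rng):
        v = rng.uniform(0, 1, (3, 20, 20))
        s = TimeLapseStack(v)
        assert align_channels(s, s, max_shift_px=3) == (0, 0)

    def test_planted_integer_shift_recovered(self, rng):
        frame = rng.uniform(0, 1, (40, 40))
        shifted = np.roll(np.roll(frame, 1, axis=0), 2, axis=1)  # dy=1, dx=2
        a = TimeLapseStack(frame[None])
        b = TimeLapseStack(shifted[None])
        dx, dy = align_channels(a, b, max_shift_px=4)
        assert (dx, dy) == (2, 1)

    def test_uncorrelated_noise_returns_bounded_shift(self, rng):
        a = TimeLapseStack(rng.uniform(0, 1, (2, 16, 16)))
        b = TimeLapseStack(rng.uniform(0, 1, (2, 16, 16)))
        dx, dy = align_channels(a, b, max_shift_px=2)
        assert abs(dx) <= 2 and abs(dy) <= 2
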