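# Methods

`funcyto` analyses time-lapse recordings of fluorescent biosensors in intact
tissue — the motivating system is pancreatic islets of Langerhans expressing
a ratiometric PKA-activity reporter (CFP donor / YFP acceptor) or a
single-fluorophore cAMP sensor — in experiments where pharmacological agents
are applied and washed out sequentially under perifusion.  The goal is a
per-cell *functional profile*: a signed amplitude for every agent, for every
cell, robust enough to support population-level statistics (sorting,
classification by a marker compound, correlation and cluster analysis).

## Data model

The recording enters either as two multi-frame TIFF stacks (one per emission
channel) or as pre-extracted intensity-vs-time CSV matrices.  All stages
operate on a frames × cells matrix.  The experiment protocol is a timestamp
schedule: an ordered list of half-open frame intervals `[start, end)`, one
per agent application.  Frames covered by no interval are *basal*: no agent
present, and the analyte is assumed to return to its resting level there.
A valid schedule has basal frames before the first and after the last
application; the basal complement of the schedule drives both baseline
correction and effect quantification.

## ROI detection and trace extraction

Cells are detected on the time-average projection of the brighter acceptor
channel (per-pixel mean over frames).  Detection follows a maxima/flood-fill
scheme:

1. local maxima with topographic prominence ≥ `prominence` (morphological
   h-maxima, 8-connected);
2. for each maximum, in descending intensity, a flood fill claims every
   connected pixel within `tolerance` below the seed intensity; pixels
   claimed by a higher maximum are not re-claimed, so contested territory
   goes to the brighter cell;
3. regions whose equivalent circular diameter (from pixel area and the pixel
   size) exceeds `max_linear_size_um` (default 30 µm, roughly twice an islet
   cell) are discarded as artefacts.  This is a pure post-filter: removing
   it can only add ROIs.

Centroids are computed from the bright core of each patch (pixels above half
of the patch's above-threshold excess), weighted by that excess.  The
pedestal under a patch and its faint rim carry no position information and,
when a neighbouring object's tail leaks into the rim, would bias a plain
intensity-weighted centroid.

The same ROI set is applied to both channels, giving one trace matrix per
channel; a per-ROI mean is used rather than pixel-wise ratios to suppress
channel misalignment noise.  An optional integer-pixel alignment utility
estimates the channel offset by exhaustive cross-correlation of the two
projections (ties resolve to the smaller shift); non-rigid motion is out of
scope.

## Ratio and normalization

For FRET data the per-element ratio R = acceptor / donor is formed (donor
values ≤ 0 are rejected with coordinates).  Each cell's ratio trace is then
divided by R₀, its mean over the first five timepoints, removing the
per-cell scale set by sensor expression and optical path.  Cells with a
non-positive R₀ are dropped with a warning, never imputed.
Single-fluorophore recordings skip the ratio and enter as R directly.

## Baseline drift correction

Photobleaching rates of the two fluorophores differ, so the ratio drifts
slowly even though the sensor is ratiometric.  Because every washout is
assumed to restore the resting level, basal-region data trace the drift.
A baseline is fitted per cell to basal data only and subtracted, with the
result re-anchored at 1 (`corrected = data − baseline + 1`), so deviations
from 1 read as fractional responses.

One subtlety: the first frames of a basal region still carry the previous
agent's washout relaxation, which is response kinetics, not drift.  All
baseline fits therefore anchor on the *settled* part of each basal region —
by default the latter half (`basal_trim = 0.5`).

Six strategies are implemented:

| method | fit | basal data used |
|---|---|---|
| `linear` | least-squares line | first and last regions |
| `exponential` | `a·exp(b·t) + c` (Levenberg–Marquardt; log-linear init; falls back to linear per cell on non-convergence, flagged) | first and last regions |
| `spline` | interpolating cubic B-spline through per-region means | all regions |
| `polynomial` | degree = (number of basal regions − 1) | all regions |
| `piecewise_linear` | per condition interval, a line through the two flanking regions; basal intervals follow their own local fit | flanking regions |
| `piecewise_square` | as above with quadratics | flanking regions |

Piecewise baselines are made continuous by averaging the two local fits at
each joint frame.  `piecewise_linear` is the default: it tracks
non-stationary drift without smearing small effects across the record.

**Known limitation.** Bleaching is multiplicative while the correction is
subtractive, so a response riding on drift factor *g(t)* survives correction
scaled by *g(t)*.  With the default simulated drift (≈11% ratio loss over
600 frames) this attenuates late-protocol amplitudes by up to ~10%, which is
the dominant term in the recovery error below.

### SNR benchmark

To compare correction strategies, each stage's output is scored as
`SNR_i = |plateau mean − adjacent basal mean|_i / σ_pooled`, where the
plateau is the last half of a reference condition (largest mean response —
the forskolin/IBMX positive control in a real protocol), and `σ_pooled` is
the SD of all settled basal entries across cells and frames about their
common mean.  The pooled noise term is deliberate: a purely per-cell SNR is
invariant under the per-cell rescaling that R/R₀ performs, and so cannot
register the (large) gain from removing per-cell intensity spread.  With the
pooled term, σ reflects per-cell spread for raw data, residual drift for
normalized data, and read noise after correction, which is exactly the
progression the benchmark is meant to expose.  Reported as mean ± SEM across
cells, in arbitrary units; a degenerate zero σ excludes cells with a count.

## Effect quantification

Each condition is scored over an *expanded region*: the preceding basal
region plus the first 20 post-addition frames (clipped at the condition's
removal, the next application, and the end of the record).  Estimators:

- `two_region` — mean over the post-addition plateau minus mean over the
  settled basal window (latter halves of each part, consistent with the
  conventions above).  Exact on ideal steps; the reference estimator.
- `linear` — least-squares slope over the raw window × span.  Crude (it
  overshoots a step by up to 1.5×) but never diverges; the default for
  unsupervised batch use.
- `square` — quadratic *onset* model `base + a·(t − t_add)²` (base before
  addition), amplitude = rise by the window end.  An unconstrained
  quadratic's end-minus-start is algebraically identical to the linear
  estimator on a uniform grid (on a symmetric design the quadratic basis is
  orthogonal to the linear one), so the onset form is used; its
  characteristic failure is endpoint overshoot on saturating responses.
- `end_start` — last minus first frame after 3-frame moving-average
  smoothing (window configurable).  Cheap and fragile: its first point sits
  on the previous washout tail.
- `sigmoid` — logistic in time, `base + A/(1 + exp(−(t − t½)/τ))`, with t½
  bounded inside the window and τ below half its span.
- `hill` — `base + A·Δt^h/(k^h + Δt^h)` with onset clamped at the addition
  frame.

The transcendental fits assume a settled base, so they use the trimmed basal
window; initialisation is A = two-region estimate, t½ = addition + 5 frames,
τ = 3 frames, with positivity bounds and ≤ 500 function evaluations.  Their
reported amplitude is the fitted curve's net change across the window — equal
to the asymptote when the onset is resolved, but bounded when it is not (a
raw Hill asymptote is unidentifiable when k runs past the window).  A fit
that fails, returns non-finite values, or claims an amplitude beyond 5× the
observed data range is treated as non-converged: the cell falls back to the
linear estimate and is flagged, never silently zeroed.  An RMS harness
scores every estimator against `two_region` over all converged
(cell, condition) pairs.

Under the standard synthetic conditions the measured ordering is
sigmoid ≈ hill ≪ linear < square < end_start: the end_start estimator is
dominated by washout-tail contamination of its first sample (~0.74 × the
previous amplitude at the window start for a 3-frame relaxation constant),
which exceeds any quadratic's bias.  A configuration in which a quadratic
estimator is the *worst* of the five would require either an indefensible
amplitude definition or sub-frame washout kinetics.

## Population profiling

Cells are ranked by the sorting statistic
`S = sgn(window mean − 1) × window SD` over a 20-frame window (10 before,
10 after) straddling the marker addition: any response inflates the SD and
the mean's sign carries direction.  The population splits into
`alpha_like` (marker amplitude > 0) and `beta_like` (≤ 0) — adrenaline
raises cAMP in α-cells and lowers it in β-cells, so its effect sign is a
functional cell-type label requiring no staining.  Within each class,
per-cell amplitudes of chosen condition pairs are correlated (Pearson r,
two-sided p, least-squares line); p-values are unadjusted by default with an
optional Benjamini–Hochberg column.

## Cluster analysis

The cells × conditions amplitude table is z-scored per condition and mined
three ways:

- **k-means** (k-means++, `n_init = 25`, seeded) over k = 1…10.  The elbow
  is the k maximising the second difference of **log** within-cluster SS —
  curvature in relative drops.  (The raw-scale second difference peaks at
  the steepest absolute drop, i.e. always at small k, and never finds a
  planted k > 2.)  Identical profiles force k = 1 with a warning.
- **Ward hierarchical clustering** of cells (rows) or conditions (columns of
  the z-scored table), Euclidean distance; dendrograms export to Newick and
  render above a per-row z-scored heatmap.
- **PCA**: contribution of condition j to component c as
  `loading²(j,c)/Σⱼloading²(j,c) × 100`; zero-variance conditions are
  excluded with a warning.

## Synthetic data

The generator is the test bed for everything above.  Per cell it plants:
a log-normal expression scale (σ = 0.4) multiplying both channels; a
log-normal baseline-ratio multiplier (σ = 0.3) on the acceptor only,
emulating the per-cell resting-FRET spread that R/R₀ removes (expression
alone cancels in the ratio); response amplitudes per condition (uniform in
[−0.5, 0.8] by default); and saturating onset / exponential relaxation
kinetics (`1 − exp(−t/τ_on)` toward the plateau, decay with τ_off after
removal; both default to 3 frames).  Channel intensities are
`scale · level · drift(t)` with the acceptor additionally multiplied by the
ratio multiplier and the response curve; drift is multiplicative
(exponential by default, −2×10⁻⁴ and −4×10⁻⁴ per frame for donor and
acceptor — ≈11% ratio loss over a 600-frame, 10-hour recording, barely
visible over the first two hours); read noise is additive Gaussian on the
raw intensity scale (default 3% of the donor level).  The standard protocol
is 40 basal frames then eight cycles of 30 frames agent / 40 frames washout
(600 frames at 60 s).  A marker condition gives 25% of cells a positive
amplitude in [0.2, 0.5] ("alpha-like") and the rest the negated range.

Image fixtures render cells as 2-D Gaussians whose half-maximum circle has
the stated radius (so FWHM = stated linear size), on a jittered grid with
clearance above twice the largest FWHM, plus oversized artefact blobs in a
separate band; frames are identical up to noise unless a per-frame intensity
schedule is supplied.

What the generator does **not** emulate — tissue motion, out-of-focus light,
FRET photophysics beyond channel-wise bleaching, spatially correlated noise,
non-reversible responses — bounds what green tests mean for real data: they
validate the numerics and the statistical machinery under the model's
assumptions, not robustness to violations of those assumptions.

## Benchmarks and problem sizes

`funcyto.benchmarks` fixes the study conditions used by the test suite and
`scripts/acceptance.py`: 200 cells × 600 frames for recovery/SNR/RMS scoring
(amplitude-recovery RMSE of the reference estimator is ≈0.035, dominated by
the multiplicative-drift attenuation noted above); a 512×512×20 stack with
50 valid and 5 oversized blobs for detection; 2,000-cell four-cluster tables
(within-cluster SD 0.08, ten seeded repeats) for elbow/ARI scoring; and
500-cell latent-factor tables for condition-dendrogram structure.  These
sizes keep a full benchmark run around a minute on one CPU while leaving
sampling error well inside the margins being asserted.

## Numerical choices and degenerate inputs

- Frames are 0-based, intervals half-open; file timestamps in seconds are
  converted with round-to-nearest using the frame interval.
- High-degree polynomial baselines fit on a centred/scaled abscissa for
  conditioning; spline order drops to the number of knots − 1 when regions
  are few.
- A flat projection yields an empty ROI set (not an error); an all-flat
  effect table forces k = 1; zero basal SD excludes cells from SNR with a
  count; zero-variance columns make Pearson r NaN, reported as such.
- All stochastic components (generator, k-means) take explicit seeds; rerun
  manifests are checksum-identical.
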