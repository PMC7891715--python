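# Methods

This note records the models, parameter choices, and numerical decisions
behind `soundscapeir`, and what the synthetic validation does and does not
demonstrate about real deployments.

## Long-term spectral average and prewhitening

Each fixed-duration clip (default 30 s) is reduced to one LTSA column: the
magnitude spectrogram uses a Hamming window with frame length equal to the
FFT size and zero overlap (a trailing partial frame is discarded), and the
column is `10·log10` of the time-mean magnitude per bin. Frequency
resolution is therefore `sample_rate / fft_size` and is not independently
configurable. Bins whose mean magnitude is exactly zero are floored at
−120 dB so the grid stays bounded; prewhitening maps such cells to zero
anyway. Levels are uncalibrated relative dB — every downstream stage
consumes only relative structure, so hydrophone sensitivity never enters.

The noise floor is the per-row 10th percentile, computed with linear
interpolation between order statistics (the conventional default; the
percentile definition only shifts the floor by a sub-dB amount). Because
subtraction is per-row, prewhitening is exactly invariant to adding a
constant to any frequency row, and roughly the lowest tenth of every row
becomes exactly zero. Clip timestamps are parsed from `YYYYMMDD_HHMMSS`
filenames by default with a pluggable parser; missing clips leave gaps in
the time axis — nothing is imputed, and phenology operates on actual
timestamps.

## PC-NMF

**Folding.** The grid is folded into non-overlapping patches of
`frames_per_patch` columns (default 30 frames = 15 min at 30-s clips),
vectorized frequency-major per frame; the final partial patch is
zero-padded and unfolding discards the padding. The patch length bounds how
much time-dependent structure one spectral feature can encode.

**Layer 1.** `V ≈ W H` under squared Euclidean error. `H` uses the standard
multiplicative update, which cannot increase the objective. `W` takes a
projected-gradient step with backtracking: the step is halved until the
objective does not increase, each column is rescaled to its pre-step L2
norm and projected onto the set of nonnegative vectors with Hoyer
sparseness exactly equal to the target (default 0.5). The projection
preserves the L2 norm bit-for-bit (≤1e-9 drift measured) and hits the
sparseness target within 1e-6; it is the classic alternating
L1-adjust/clip-negatives construction and is verified in the tests against
an independent constrained-optimizer oracle on short vectors. Together the
two updates make the training objective monotone non-increasing, which the
test suite asserts on every run. Initial `H` scales with the grid mean and
the first `W` step size with the gradient norm, making the whole iteration
path homogeneous in the input scale: scaling the grid by `c` scales every
reconstructed channel by `c` exactly. Training runs 200 iterations by
default (the prediction-phase count, adopted for training as well); after
training, `W` columns are L2-normalized with the scale folded into `H` so
indicator magnitudes are comparable across features. An alternative
KL-divergence layer 1 was evaluated and separated the chorus band
noticeably worse on the reference scene, so the Euclidean pairing stands.

**Periodicity and layer 2.** Each activation row maps to a periodicity
vector: magnitude DFT with the DC bin removed (DC encodes loudness, not
recurrence) and unit-sum normalization (making layer 2 scale-invariant).
The periodicity matrix is factorized by plain multiplicative-update NMF
into `n_sources` periodicity features and per-feature source indicators.
This factorization is tiny but its local optimum decides the grouping, so
it is restarted 10 times from seeded initializations and the lowest
reconstruction error kept — single-start layer 2 misgrouped features on a
third of seeds. Features are assigned to `argmax` over indicators; NumPy's
argmax already resolves ties toward the lowest source index, and ties are
logged. Manual overrides (`adjust_indicators`) are recorded separately from
the automatic assignment so the audit trail survives; reconstruction honors
overrides.

**Reconstruction.** Per source, `P_s = P̌ ∘ (W_s H_s)/(W H)` on the folded
grid, with the mask defined as 0 where the model support `W H` is at or
below `1e-12 × max(W H)`. Masks sum to one on the support, so channels
conserve the mixture there (asserted at 1e-6 relative); a source with no
assigned features yields an all-zero channel with a warning.

**Evaluation.** `evaluate_detection` sweeps all score thresholds (ROC) and
returns the best true-positive rate whose false-positive rate stays at or
under the cap (default 5%). `match_channels` solves the
channel-to-true-source assignment that maximizes shared frame energy;
`channel_purity` is the fraction of a channel's integrated energy falling
in frames where its matched source is truly active. Purity is defined at
frame level because the generator's ground truth is per-frame activity —
the same resolution at which detection, phenology, and event extraction
operate.

## Synthetic scenes

The generator emulates the statistical structure the separation relies on:
additive sources with fixed spectral envelopes and source-specific
occupancy schedules, on a grid that represents *prewhitened*
(above-ambient) levels. Default sources, chosen once as the package's
reference conditions:

- **abiotic** — broadband with low-frequency emphasis (exponential decay
  across the band), aperiodic smoothed-noise schedule with a 6-h
  correlation time. The schedule is floor-referenced at its 35% quantile so
  the source appears as episodic excursions above its own ambient level;
  a continuously-present component would contradict what percentile
  prewhitening produces (and the grid's ≥10%-zeros-per-row invariant).
- **fish_chorus** — 0.5–3 kHz band with Gaussian peaks at 750 and 2500 Hz,
  diurnal Gaussian occupancy centered at 20:00 (width 1.5 h), continuously
  active while scheduled, peak level 18 dB above floor.
- **cetacean** — ≥ 4 kHz up to just below Nyquist, nocturnal occupancy
  centered at 01:00 (width 3 h), intermittent (`event_rate` 0.5, i.e. half
  the scheduled frames carry a transient), 18 dB.
- **electrical** — fixed-frequency tonal peaks, near-constant schedule with
  10% dropouts, 12 dB.

Per-frame amplitudes multiply the schedule by a Bernoulli activity draw and
mean-one lognormal jitter; cells carry a small multiplicative speckle
(σ = 0.05 — an LTSA cell averages thousands of spectrogram frames, so
cell-level sampling variability is physically small). Ground truth marks a
frame active when the source's integrated energy exceeds 5% of its maximum,
matching the 0.05 relative detection threshold used downstream. The default
desk-scale rate is 16 kHz with a 256-point FFT (62.5-Hz bins); biotic bands
fit this range unchanged, and higher rates are honored if configured. WAV
scenes synthesize band-filtered Gaussian noise (chorus-like sources) or
exponentially decaying tone pulses (transient sources) over an optional
stationary colored background, as 16-bit PCM with timestamped filenames.

What passing tests show: the pipeline recovers sources whose spectra
overlap partially and whose recurrence patterns differ, at the stated
rates, under additive mixing with stationary per-source spectra. What they
do not show: robustness to propagation effects, spectrally drifting
sources, clock drift, or instrument idiosyncrasies beyond fixed tonal
peaks — real deployments still need the manual indicator review that the
model exposes.

## Phenology

Intensity series are per-column sums of a separated grid, with optional
masked time ranges zeroed *before* min–max normalization (a constant series
degenerates to all zeros with a warning). Correlations are Pearson on raw
normalized intensities at every integer-frame lag up to the maximum, on
pairwise-complete samples; a lag is reported only when at least half of its
nominal overlap exists. The envelope is a centered moving maximum (default
window 1 day — intended for lunar/seasonal lags; diurnal peaks are read
from the raw scores, since a window as long as the period flattens its
peaks). Peak lists are strict local maxima with 0.01 minimum prominence,
using plateau midpoints, which recover the true recurrence lag exactly for
well-separated peaks. A `pooled` helper averages the series into fixed bins
(e.g. 10 min) before correlation, mirroring the binning used for diurnal
cycle models and averaging down frame-level jitter.

Cycle models pool values into 144 ten-minute bins by time of day (diurnal),
30 lunar-day bins folded on the 29.530588-d synodic month from a
configurable reference new moon (default 2000-01-06 18:14 UTC), or 52
weekly bins on the calendar year (seasonal), requiring at least two full
cycles. Each bin carries the 95th percentile (the spline target), mean, and
standard deviation; a periodic cubic spline interpolates the percentiles,
with empty bins filled by circular linear interpolation first. Bin indices
use an epsilon guard so samples landing exactly on a bin edge are assigned
deterministically.

## Acoustic diversity

Events are runs of frames with relative intensity at or above 0.05; runs
separated by a silent gap of *more than* 10 minutes split (a gap of exactly
10 minutes merges), and events shorter than 1 minute are discarded. Event
duration spans first detection to last detection plus one frame. The mean
spectrum pools the separated grid over the event's detected frames
(arithmetic mean) and is min–max normalized.

Clustering reduces event spectra by PCA, keeping the smallest component
count explaining more than 90% of variance, then runs k-means (10 seeded
restarts, best objective) for each k. Dispersions are recomputed from the
final assignments with mean centroids so that
`R_k = 100·(1 − ΣD_i/D_1)` is exactly consistent with its definition;
`R_1 = 0` and `R_n = 100` hold exactly. `choose_k` returns the smallest k
with R at or above the threshold (default 93%), falling back to the point
of maximum curvature of the R-vs-k curve with a logged warning. Cluster
summaries are duration-weighted: hourly and monthly detection-probability
vectors divide detected duration per time category by each cluster's total,
so rows sum to one.

## Pipeline

`run_pipeline` chains input acquisition (WAV directory, saved grid, or
synthetic scene), prewhitening, training with optional overrides,
prediction, reconstruction, phenology, and diversity. Configuration is a
flat key=value file; mask ranges are per-source (`label/start/end`, `*` for
all). Every artifact filename carries a SHA-256 hash of the configuration,
and the JSON report's own hash certifies end-to-end determinism — all
randomness flows from explicit seeds through `numpy.random.default_rng`
and seeded scikit-learn estimators.

## Problem sizes

The reference validation scene spans 7 days of 30-s frames (20 160 columns,
129 bins at 16 kHz/256-point FFT), separated with 30 features — a
deliberate desk-scale configuration that keeps a 10-seed recovery study and
the full test suite in a few minutes while preserving the structure the
method exploits (multi-day recurrence at 15-min patch resolution). The
end-to-end determinism check uses a 3-day scene with 20 features for the
same reason.
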