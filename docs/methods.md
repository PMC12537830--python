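# Methods

## Data model and region assignment

A session is a set of sorted spike trains (times in seconds, 64-bit floats;
sample counts from sorter output are converted at read time), merged movement
intervals, an optional drug-injection time and a state label (WT, WT+l-dopa,
PD, LID). Each cluster carries a depth below the pial surface and is assigned
to a region by closed depth bands: L2/3 = [0, 350] µm, L5 = [450, 1000] µm,
striatum = [1500, 3500] µm. Depths in the two gaps are BORDERLINE and beyond
3500 µm OUT; both are excluded from analysis but always reported, never
silently dropped. Ties at band edges go to the named region; the bands are a
configurable dataclass. In the sorter-directory adapter, cluster depth
defaults to the vertical coordinate of the channel with the largest mean
template amplitude (a centroid-based alternative would plug into the same
field); the plain-text session bundle stores the resolved depth directly and
is the canonical interchange format because it is diffable and needs no
binary fixtures.

## Unit quality control

Five criteria, all of which must pass:

1. **Label** — curation label equals the accept label ("good"),
   case-insensitive.
2. **Waveform stability** — per-spike amplitude and half-width are compared
   between the first and last 20% of spikes (two-group one-way ANOVA per
   measure). `stability_alpha` (default 0.05) is the *unit-level* error rate
   and is split across the two measures (Bonferroni, α/2 each), so the
   false-rejection rate on stationary units calibrates to α; this is
   verified empirically in the test suite. Units with fewer than 10 spikes
   per segment are untestable and fail, with the reason logged.
3. **Refractory** — the fraction of ISIs below 2 ms must not exceed 0.5%.
   The fractional rule (rather than literal zero tolerance) avoids rejecting
   hour-long recordings for a single artifact coincidence; a zero-tolerance
   mode is a config switch.
4. **ISI shape** — ISIs beyond the refractory period are histogrammed into 16
   log-spaced bins up to their 95th percentile; the log of the density
   estimate (count/width) is regressed on the bin centre. An exponential ISI
   density is exactly linear there, so R² ≥ 0.8 passes. Bins with fewer than
   5 counts are dropped (their log-counts are dominated by shot noise); with
   fewer than 5 usable bins the histogram is degenerate and scores R² = 0,
   which correctly fails strictly periodic and strongly bursty trains.
5. **Separation** — a two-group multivariate location test (Hotelling T²,
   the two-group case of Wilks' Λ) between the unit's waveform-feature cloud
   and each neighbour within 40 µm depth; p < α against *every* neighbour
   passes. With no neighbours the criterion passes vacuously and is flagged.
   The bundle-driven pipeline uses the per-spike (amplitude, half-width)
   plane as the feature space since full waveforms are not retained in the
   interchange format; the API takes arbitrary feature matrices (e.g. three
   waveform PCs).

QC decisions are deterministic given data and config and independent across
units; every rejection names at least one failing criterion.

## Quiet epochs and the synchrony statistic

Quiet windows are the complement of the movement intervals within the
session span, shrunk by `margin_s` (default 1 s) on every side that faces a
movement; leading/trailing segments keep their outer edge. Windows shorter
than two bins are dropped. When a session contains an injection, synchrony is
additionally restricted to pre-injection time so the drug response cannot
masquerade as stationary correlation structure.

Counts use `bin_width_s` = 25 ms bins tiled from each window's own start
(trailing partial bins discarded; bins never span windows). For a pair of
units the statistic is the signed maximum over integer lags within
±`max_lag_s` (default 100 ms, i.e. ±4 bins) of the Pearson correlation of
the lag-aligned pooled count vectors. Lags shift one series against the other
*within* windows with edge truncation — no wrap-around, no cross-window
shifts. Ties between lags prefer smaller |lag|, then the negative lag. A
series with zero variance at some lag contributes r = 0 at that lag, keeping
sparse low-rate units comparable rather than undefined. Units with fewer than
10 quiet-time spikes are excluded and listed. Bin width and lag range are not
canonical constants of the method; they are explicit configuration echoed
into every output, and the statistic's scale depends on them.

Pair results aggregate into six region pair classes (L23–L23, L23–L5, L5–L5,
L23–STR, L5–STR, STR–STR) as plain means with SEM and pair counts; empty
classes are reported as missing, not zero. One and the same statistic is used
for all six classes. Published inter-regional (L5–striatum) correlations an
order of magnitude above intra-layer values suggest a different normalisation
or pair selection was used there historically; this implementation
deliberately does not special-case inter-regional pairs, and the synthetic
generator builds cross-region populations independent (their class means
reflect only the small positive bias of maximising over lags).

Because the statistic is a maximum over 2·4+1 lags, its null expectation is
slightly positive (order `E[max of 9 correlated standard normals]/√n_bins`);
all recovery tests compare against the closed form at the generator's
parameters rather than against zero.

## Peri-injection response classification

Each unit's 1 s rate histogram spans the session. The baseline is the 600 s
immediately before the injection; its unsmoothed mean and SD set the
thresholds (up = max(mean + 2·SD, 1.5·mean); down = 0.5·mean), while the
3600 s post-injection series is Gaussian-smoothed (σ = 30 s) before the
excursion scan, so the thresholds are robust to Poisson bin noise and the
scan is robust to brief flickers. Supra-threshold runs separated by less than
120 s are merged; merged excursions of at least 60 s count. One excursion →
MONO, two or more → MULTI; with none, a sustained (≥ 60 s) dip below the down
threshold → SUPP; otherwise NONE. MONO/MULTI take precedence over SUPP for
mixed profiles, treating the categories as exclusive. A silent baseline with
post-injection activity is classified against an absolute floor (0.05 Hz) and
flagged. All window lengths, smoothing and thresholds are artifact decisions
(no operational rule is canonical) and are echoed into every report.

Class proportions are computed per recording and averaged across recordings
(mean ± SEM at recording-level degrees of freedom, not unit-level); rate
magnitudes per class are unit-level means.

## State statistics and behaviour

Recording-level values are compared with the classical paired t-test
(df = n − 1), one-tailed for directional contrasts (PD → LID synchrony
increase) and two-tailed otherwise; the tail choice is recorded in every
output row. Constant-difference inputs have no within-pair variance and are
flagged degenerate rather than given a fabricated p. Percent change is
100·(after − before)/before, undefined (flagged) for non-positive baselines.

Rotations are counted as completed net 2π heading excursions with an anchored
hysteresis counter (the anchor advances one full turn per count), which makes
the count invariant to heading offset and to sampling refinement and immune
to jitter around a crossing; counts are normalised per 10 min. Path length is
the summed Euclidean step length of the tracked positions.

## Synthetic ground truth

The generator's defaults are the study conditions, not tuning knobs:

- **Correlated populations** (MIP): mother Poisson at rate/p, children keep
  each mother spike with probability p and jitter it (σ = 3 ms in session
  presets; 2 ms in the recovery checks). Expected pairwise binned-count
  correlation is the closed form r = p·γ(b, σ) with
  γ = 2Φ(b/s) − 1 − (2s²/b)(φ_s(0) − φ_s(b)), s = √2·σ — the probability two
  jittered copies of one mother spike share a bin. The closed form is cross-
  checked against numerical integration and Monte-Carlo in the tests.
- **State presets**: PD-like and LID-like sessions share identical quiet
  rates (0.6 Hz cortex, 0.9 Hz striatum) while intra-layer copy probability
  differs (0.04 vs 0.11); the WT pair shares correlation 0.057 so l-dopa
  alone changes nothing. Sub-hertz quiet cortical rates and correlations of a
  few hundredths match the regime the pipeline targets.
- **Movement bouts**: Poisson onsets (1/min) with 3 s bouts; activity gains
  ×3 multiplicatively during bouts (independent extra spikes), which makes
  the quiet-epoch restriction consequential in tests.
- **Responses**: MONO is a gamma-shaped bump (peak gain 7 at 600 s), MULTI
  2–3 Gaussian bumps (gain 8, σ 150 s), SUPP a ×0.2 step for 1500 s — each
  sampled by thinning an inhomogeneous Poisson profile; the planted class is
  recorded in the ground truth.
- **Waveforms**: per-spike amplitude/half-width at 5% CV; planted drift units
  decay linearly by the configured fraction and must fail stability QC.
- **Refractoriness**: emitted sessions enforce a 2.5 ms dead time by dropping
  violating spikes (≈0.2% of spikes at these rates) so clean units pass the
  refractory criterion by construction; the pure MIP sampler used for the
  correlation-recovery oracle applies no dead time, keeping the closed form
  exact.
- **Determinism**: one child seed stream per component (spikes, waveforms,
  schedule, trajectory, responses) spawned from the master seed; bundles are
  byte-identical across runs for equal configs.

What the generator does **not** emulate: real spike-sorting errors
(contamination, drift correction, split/merge artifacts), oscillatory or
bursty temporal structure beyond Poisson statistics, movement-specific
kinematics, cell types, and any inter-regional correlation. Passing tests
therefore demonstrate the estimators' correctness and calibration under the
stated model, not robustness to every failure mode of in-vivo data.

## Problem sizes and numerical choices

Validation runs use 20-unit populations over 600 s of quiet time at 1 Hz
(190 pairs per replicate; six replicates per state for the paired contrast),
200 template units for response recovery, and 500/200 stationary/drifting
units for QC calibration — sizes at which the Monte-Carlo error of every
checked quantity is comfortably below its acceptance band. Pearson r uses
`np.corrcoef`; equality with the brute-force oracle is asserted to 1e-12.
Time is float64 seconds throughout; interval merging treats touching
intervals as one.
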