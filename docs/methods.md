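# Methods

`sbdecode` implements a single-trial state-decoding analysis for
parcellated M/EEG source signals. The scientific setting is a meditation
protocol in which practitioners alternate between a non-meditative resting
state, self-boundary dissolution (SB−, a deliberate weakening of the
experienced self/world boundary) and self-boundary maintenance (SB+, a
control meditation with a deliberately clear boundary). The package asks:
can SB− be told apart from rest and from SB+ on single epochs of brain
activity, using spectral and complexity features?

Real recordings of this kind are not publicly distributable, so the package
pairs the analysis pipeline with a synthetic generator that plants known
effects. Every stage is validated by parameter recovery against that ground
truth and by closed-form oracles.

## Session protocol

A session is an ordered list of contiguous state segments with whole-second
durations. The default layout mirrors the two-block design: each block opens
with 100 s of rest followed by five 60 s alternations between SB− and SB+,
and a third 100 s rest closes the session, so each state accumulates exactly
300 s. The precise alternation order within blocks is not uniquely
determined by the published description; the default (block 1 starts with
SB−, block 2 with SB+) is one consistent reading and any layout with the
right totals can be supplied instead.

At the default 300 Hz sampling rate this yields, per state, 300 one-second
epochs for spectral features and 75 four-second epochs for complexity
features. 300 Hz keeps the full 1–100 Hz analysis band below Nyquist while
staying cheap; the final analysis rate of the original recordings is not
documented beyond an intermediate 300 Hz downsampling step, so this is a
package choice.

## Synthetic signal model

Per region r and state s, a segment is

    x = (1 − w)·s_struct + w·n_white,
    s_struct ∝ onef(χ(s,r)) + a_α·b_α + a_β·m(s,r)·b_β

* `onef(χ)` — 1/f-shaped noise with exponent χ, synthesized by spectral
  shaping (white noise → FFT → amplitudes × f^(−χ/2) → inverse FFT), so the
  planted exponent holds by construction.
* `b_α`, `b_β` — band-limited noise (4th-order zero-phase Butterworth,
  8–12 Hz and 25–29 Hz) rather than sinusoids, giving peaks with realistic
  bandwidth. Default amplitudes a_α = 0.5, a_β = 0.4 relative to the unit-SD
  1/f background produce visible but not dominant peaks.
* `m(s,r)` — the beta-amplitude multiplier carrying the oscillatory
  self-boundary effect (reduced in SB−).
* `w ∈ [0,1]` — the "complexity drive": the mixing weight of broadband
  white noise against the structured component. Raising w provably raises
  normalized Lempel-Ziv complexity in expectation, giving a monotone handle
  on the planted complexity effect. All components are unit-SD so w trades
  structure for stochasticity at roughly constant amplitude.
* An optional row-normalized region × region mixing matrix induces
  inter-regional correlation (identity by default).

Segments are generated independently, so epochs never straddle state
boundaries and no filtering bleeds across them.

The `study_like` preset plants SB− effects in the empirically reported
directions — beta power down, broadband complexity up, SB+ intermediate —
with magnitudes calibrated once so the LZc SB−-vs-rest Cohen's d lands in
the small-to-medium band (≈ 0.2–0.4) reported for the real data
(multiplier 0.95, drive 0.21 vs 0.20 at rest). Cohorts draw
participant-level parameters around the preset (log-normal jitter on the
beta multiplier, additive on exponent and drive, one draw per state shared
across regions); `between_participant_sd = 0` gives an exactly homogeneous
cohort.

What the generator does *not* emulate: inter-regional leakage of a real
beamformer, artifacts (cardiac, ocular, muscle), non-stationary drifts
within segments, and the strong spatial correlation structure of real
source estimates. Because the planted effects are independent across
regions, multivariate classifiers aggregate them more efficiently than is
possible on real data — planted-cohort accuracies are therefore expected to
exceed the published real-data regimes, and passing tests demonstrate
correctness of the machinery, not field-realistic effect sizes.

## Spectral features

1 s epochs per state segment → linear detrend → Hanning taper → FFT at the
native 1 Hz resolution, Parseval-consistent scaling (summed power recovers
the detrended variance after taper compensation). The detrend matters: slow
1/f components otherwise leak through the taper sidelobes into the 1–3 Hz
bins and bias the aperiodic fit by ≈ +0.15.

The aperiodic (1/f) component is fit as a robust line in log10-power vs
log10-frequency over 1–90 Hz: one ordinary fit, then a single refit
excluding bins whose residual lies more than 2.5 median absolute deviations
*above* the line (one-sided, so only oscillatory peaks are rejected; if
fewer than 5 bins would remain the first fit is kept). This deliberately
lightweight alternative to full peak-plus-background spectral
parameterization recovers a planted exponent of 1.5 within ±0.1 from 60 s
of signal, which is all the downstream analysis needs: only the exponent
and the residual band means are consumed.

Corrected band power is the mean of (log10 power − log10 aperiodic model)
over a band's integer bins — the periodic residual in log space, which may
be negative and is exactly invariant to overall signal gain. An uncorrected
mode (plain log10 band power) is available for comparison. Default bands:
delta 1–4, theta 4–8, alpha 8–13, beta 13–30, low gamma 30–60, high gamma
60–90, and a dedicated "27 Hz" band at 25–29 Hz around the beta peak most
associated with self-boundary dissolution. The exact published band table
is not available; these canonical bounds are explicit configuration, not
reproduced facts. The per-region aperiodic exponent is kept as an
additional feature set.

## Complexity features

The time series is band-passed 1–100 Hz (zero-phase Butterworth, applied
per segment after demeaning), cut into non-overlapping 4 s epochs within
state segments (4 s being the shortest length at which LZc estimates
stabilize), linearly detrended per epoch, and binarized at the epoch mean —
strictly above → 1, ties → 0 (the tie rule is arbitrary but fixed; a
relative 1e-10 epsilon guards against float noise flipping ties on
near-constant epochs).

The binary sequence is parsed with the LZ76 exhaustive history
(Kaspar–Schuster production counting, self-referential copies allowed, the
trailing incomplete phrase counts). The count c is normalized by
T/log2(T): constant signals tend to 0 as T grows, i.i.d. random binary
signals tend to 1 (slightly above 1 at finite T; ≈ 1.02 at T = 10⁵). The
kernel is JIT-compiled when numba is importable and falls back to the same
pure-Python loop otherwise; an independently written quadratic brute-force
parser serves as the oracle in the tests.

## Parcellation

Voxel values aggregate to atlas regions by unweighted means. The packaged
merge table follows the merged-AAL scheme — small neighbouring regions
merged, all Cerebellum and Vermis labels excluded — yielding 62 regions.
The published supplementary list of merges is not reproduced in the main
text, so the shipped table is a reconstruction with the correct cardinality
and naming conventions (it contains every merged name appearing in the
published coefficient tables); downstream stages depend only on label
cardinality and consistency, and the TSV is editable data, not code.

## Decoding

Within-participant splits are chronological: the recording (restricted to
the two contrast states) is halved, and in each half the first 80% of rows
train and the last 20% evaluate (40/10/40/10 overall). At each train/eval
junction the train-side adjacent row is removed, so no evaluation epoch is
chronologically adjacent to a training epoch. Across-participant splits
assign whole participants at random (round-half-up of 80% to training), so
no individual appears on both sides.

Class imbalance is corrected by SMOTE (synthetic rows interpolated between
a minority row and one of its 5 nearest minority neighbours), applied
separately per split side. Evaluation-side SMOTE follows the original
protocol; it is methodologically unusual (synthetic rows enter the test
set) and can be disabled with a flag. Standard scaling is fit on the
(balanced) training rows only — a deliberate strengthening over an
ambiguous description, avoiding leakage.

Four families: L1 logistic regression (liblinear; the primary,
interpretable model), RBF-kernel SVC, random forest, Gaussian naive Bayes.
Hyper-parameters come from grid search with stratified 5-fold CV on the
training side maximizing accuracy; the published grids are not specified,
so decade-spaced defaults are used (C ∈ {0.01 … 100}, gamma ∈ {0.001 … 1},
trees ∈ {100, 300}, depth ∈ {None, 5, 10}, min-split ∈ {2, 10}). CV ties
resolve to the earliest grid point, i.e. the simplest model, making tuning
deterministic. Feature importance is read from the L1 coefficients of the
standard-scaled model, ranked by magnitude with signs preserved.

## Statistical evaluation

* Univariate benchmark: per region, a grand-mean threshold classifier (the
  boundary is the mean over all observations of both classes) with an a
  priori direction — oscillatory power below the boundary in SB−,
  complexity above. Its accuracy converges to Φ(d/2) for equal-variance
  Gaussian classes, which the tests verify, and a boundary sweep reports
  how little an optimized boundary improves on the grand mean.
* Cohen's d with the pooled standard deviation.
* Exact two-sided binomial tests of k correct out of n against 0.5,
  two-sided by the minimum-likelihood rule (every outcome no more likely
  than the observed one). The counts fed to the test are never inflated by
  synthetic rows: k/n encode the class-balanced accuracy over original
  evaluation rows on a variance-matched effective sample size
  (n = 4/(1/n₁ + 1/n₂) for class counts n₁, n₂ — the binomial n whose
  variance at chance equals that of the balanced accuracy). Reported
  *accuracies* still follow the original protocol (balanced evaluation
  set); only the inference counts are corrected.
* Fisher's method across participants: χ² = −2Σln p on 2k degrees of
  freedom (zero p-values are clipped to the smallest positive float with a
  warning).
* Benjamini-Hochberg FDR, applied independently to the univariate and
  multivariate families; a corrected p < 0.05 is flagged.
* Cohort means are reported with 95% t-intervals over participant means.
* Covariate correlations (e.g. lifetime practice hours): IQR outlier
  removal (1.5 × IQR fences on either variable), Spearman's ρ, and the
  default correlation Bayes factor — the exact sampling density of r under
  a stretched-beta(1,1) prior on ρ (width 1), integrated numerically and
  applied to rank-transformed data. The implementation agrees with
  pingouin's published routine to four decimals.

## Orchestration and determinism

`run_all` drives simulate → features → decode → statistics from one config.
The global seed expands into per-stage child seeds via
`numpy.random.SeedSequence` (cohort first, then one child per decoding task
in listed order), so identical configs reproduce byte-identical summary
JSON; the results bundle carries a manifest with SHA-256 hashes of every
output file.

## Problem sizes

Defaults are the study's own scales: 300 s per state per session, 62
regions, 300/75 epochs per state, and (for the null-calibration check) a
10-participant cohort. Unit and property tests run on quarter-scale
protocols and 2–8 regions, which leave every planted effect detectable
while keeping the suite quick; the scales used are stated in each test.

## Known limitations

* The aperiodic fit models no peak shapes; strongly overlapping broad peaks
  would bias the exponent more than the tested ±0.1.
* Per-epoch (1 s) aperiodic fits are noisy; exponent features carry that
  noise by design, as in the original pipeline.
* The Bayes factor integrates the Pearson-r density over ranks; for small n
  and many ties this is an approximation to a fully rank-based likelihood.
* With evaluation-side SMOTE enabled, reported accuracies average over
  synthetic rows (faithful to the original procedure); the binomial
  inference counts exclude them, so headline accuracy and its p-value are
  computed on slightly different row sets. The variance-matched effective n
  assumes real evaluation epochs are independent; residual within-segment
  correlation makes per-participant tests mildly anticonservative at small
  evaluation sizes.
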