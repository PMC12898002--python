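# Methods

This package implements an analysis chain for wakefulness tracheal breathing
sounds (TBS) as biomarkers of obstructive sleep apnea (OSA) severity: from
raw breath audio to interpretable multi-domain features, bootstrap-CI gap
regions, stability-ranked selection, and 1-vs-1 severity classifiers under a
covariate-balanced stratified cross-validation. Because clinical TBS
recordings are access-restricted, a synthetic cohort generator provides the
test bed; its scope and limits are described below.

## Synthetic cohort model

**Anthropometrics.** Subjects are drawn per severity class (Non, Mild,
Moderate, Severe; AHI bounds <5, 5–15, 15–30, ≥30 events/h). Continuous
fields (AHI, age, BMI, neck circumference) follow truncated normals whose
*underlying* (mu, sigma) are solved numerically so the truncated
distribution's mean/SD equal the class-conditional summary statistics of a
199-subject referred clinical cohort (74/35/50/40 per class). When the
targets are infeasible on the class support — the Non class's AHI
(mean 1.2, SD 1.3 on [0, 5)) is the one such case — the sampler minimizes the
squared moment error and records the achieved moments in each record's
metadata; tests compare against those achieved moments. Sex and Mallampati
score are categorical draws from the reference proportions.

**Breath audio.** Each recording is five breath cycles
(inspiration/expiration alternating, 1.5 s per phase) separated by 0.3 s
silence over a −40 dB microphone noise floor, at fs = 10 240 Hz (the
recording hardware's rate is not standardized; anything ≥ 6 kHz preserves
the 75–3000 Hz analysis band). A breath phase is band-shaped noise — an
AR(2) resonator mixed with broadband bandpass noise — under a raised-cosine
envelope, with slow multiplicative amplitude modulation and Poisson
impulsive bursts. Severity acts through a monotone parameter ladder
(centroid shift 0→250 Hz, bandwidth scale 1→1.6, burst rate 0→6 per phase,
amplitude CV 0.05→0.35, spectral regularity 0.90→0.68), encoding the
escalation of turbulence, bandwidth and impulsiveness with airway
collapsibility. Each subject carries a continuous severity latent (class
index + Gaussian jitter, SD 0.5 class steps) and receives the ladder
interpolated at that coordinate, so adjacent classes overlap acoustically
the way clinical cohorts do while extreme classes remain well separated.

These profiles are engineered fixtures, not airway physiology: passing tests
demonstrate that the pipeline detects and ranks class-dependent acoustic
structure, not that it would reach the same operating points on clinical
recordings. The generator contains no snoring, vocal artifacts, posture
effects, or sensor variability.

## Preprocessing

Zero-phase (forward-backward) 4th-order Butterworth bandpass at 75–3000 Hz;
the bidirectional pass doubles the effective order but preserves envelope
timing for segmentation. Segmentation thresholds the log-variance envelope
(50 ms frames, 50% overlap) at the midpoint of its 5th/95th percentiles;
supra-threshold runs shorter than 200 ms are discarded, sub-threshold gaps
shorter than 100 ms merged; retained runs are labelled alternately
inspiration/expiration from the protocol's known first phase (no airflow
channel exists; configurable for recordings starting mid-cycle). Per-segment
SNR against the sub-threshold noise floor gates retention at 5 dB.
Recordings with less than ~5 dB of envelope dynamic range are treated as
all-silent and yield no segments. Feature extraction uses the mid-flow
window: the central 50% of each phase centred on the envelope peak.

Feature normalization is chosen per training fold by maximizing the mean
mutual information between normalized columns and class labels over four
candidates (mean-range, z-score, min-max, robust scaling). MI uses
equal-frequency binning with ceil(sqrt(n)) bins — deterministic, no tuning.
Since all four candidates are strictly monotone per-column maps, binned MI
is often tied; ties resolve by the fixed order mean-range > z-score >
min-max > robust. Zero-variance columns pass through unscaled and are
flagged.

## Feature families and naming

Per route-phase condition (NoseInspiration, NoseExpiration,
MouthInspiration, MouthExpiration), segment-averaged:

- **Spectral** (Welch PSD, Hann, nperseg 1024, 50% overlap — ~10 Hz
  resolution at fs 10 240): power-weighted centroid/bandwidth/skewness/
  kurtosis, normalized entropy, crest, mean/peak power, peak frequency, and
  the 150–450 Hz vs 450–3000 Hz band power ratio.
- **Flux**: mean L2 distance of successive L1-normalized STFT magnitude
  frames (gain-invariant).
- **Time-domain**: ZCR, RMS, envelope coefficient of variation; jitter,
  shimmer and noise-to-harmonics ratio when an autocorrelation pitch
  (60–400 Hz, peak correlation ≥ 0.5) exists, flagged undefined otherwise —
  breath noise is typically aperiodic and the absence is preserved, not
  fabricated.
- **Nonlinear/fractal/recurrence** on the mid-flow signal decimated to
  ≤ 1500 samples (bounds the O(n²) phase-space work): Katz and Higuchi
  fractal dimensions, R/S Hurst exponent, Rosenstein largest Lyapunov
  exponent, and RQA (recurrence rate, determinism, laminarity, longest
  diagonal, diagonal entropy) at embedding m=3, delay = first
  autocorrelation zero, radius 0.1 of the cloud diameter, Theiler window =
  delay.
- **Wavelet** (db4, 5 levels): per-level relative energies and log-energy
  entropy.
- **MFCC** (26-filter mel bank on 75–3000 Hz, DCT-II, 13 coefficients):
  per-coefficient frame mean and SD.
- **Constant-Q** (24 bins/octave from 75 Hz): per-octave mean, SD and
  energy ratio.

Names follow `Condition[_Context]_Descriptor`; `Average` is the mean of a
descriptor across the four conditions; contexts `Range` and `BBox` mark
gap-region features (below). Descriptors are single CamelCase tokens, so
every name parses back uniquely.

## Gap regions (class-pair spectral contrasts)

For each 1-vs-1 contrast and training fold, subject-level mean spectra per
class are bootstrap-resampled (subjects are the exchangeable unit; 1000
resamples, percentile method) to obtain per-bin 95% CIs of the class mean.
*Gap bands* are maximal runs (≥ 2 bins) of PSD bins where the two classes'
CIs are disjoint; *gap boxes* are tight bounding boxes of 8-connected
components (≥ 4 bins) of the disjoint-CI mask on the bispectral bifrequency
grid. The bispectrum uses the direct FFT estimator (Hann, nperseg 256, 50%
overlap) averaged over mid-flow segments; its magnitude is symmetric in
(f1, f2) by construction and vanishes for Gaussian signals, so boxes mark
class differences in quadratic phase coupling.

`Range` features evaluate the spectral descriptor family on the union of a
condition's gap-band bins (falling back to the full 75–3000 Hz band when a
contrast produces no gap). `BBox` features cut the largest box from each
subject's bispectrum and compute value statistics (moments, quantiles,
entropy, energy, intensity-weighted centroids, frequency-calibrated
centroid/bandwidth), binary topology after Otsu thresholding (area,
bounding-box geometry with corner-to-corner diagonal, exposed-edge
perimeter, compactness, 8-connected components, 4-connected holes, Euler
number = components − holes, box-counting fractal dimension), and GLCM
texture (8 levels, distance-1 offsets, symmetric normalized co-occurrence;
energy is the sum of squared probabilities). Boxes are indexed generically
by component size with coordinates kept in metadata — the study-specific
box coordinates of any one dataset are not meaningful elsewhere.

Gap regions are learned from training subjects only and frozen before any
held-out subject is touched; the tests assert this by corrupting held-out
spectra and requiring bit-identical regions.

## Selection and evaluation

Three-stage per-pair selection inside each training fold: (1) univariate
filter keeping the 200 features with largest |AUC − 0.5| (rank-sum
formulation, ties lexical); (2) ranking by mean |Shapley attribution| under
a bagged ensemble of 100 unlimited-depth CART trees (exact path-dependent
tree Shapley values; additivity to the ensemble margin is asserted at 1e-6);
(3) recursive elimination of the lowest-attribution 10% per iteration to a
fixed 35-feature subset. Rank aggregation uses minimum-rank ties and the
overall rank is the arithmetic mean of correlation- and SHAP-based ranks.

Cross-validation is stratified by severity and balanced on age, BMI, neck
circumference, sex and Mallampati score: within each class subjects are
sorted by a composite z-score and snake-dealt to k folds (k=3 default),
then within-class pairwise swaps are accepted while they reduce a balance
cost (squared standardized fold-mean deviations plus chi-square-style
categorical divergence, all criteria equally weighted after
standardization). Swaps preserve per-class fold counts, so the partition
and totals are conserved by construction; fold sizes stay within ±1 per
class of the snake deal.

Per-feature stability uses the train/test deltas averaged over folds:
stable if |ΔAUC| ≤ 0.01 and |Δr| ≤ 0.1; slightly unstable if |ΔAUC| ≤ 0.01
and |Δr| ≤ 0.15; otherwise unstable, where r is the Pearson correlation
between the feature and the binary pair label. Feature-anthropometric
Pearson correlations are computed independently within each fold's subject
subset, for reporting only — they never feed back into selection or
training.

## Numerical choices and degenerate inputs

- AUC is the Mann–Whitney rank statistic; ties credit 0.5.
- Bootstrap CI bounds are clamped to bracket the class sample mean (the
  percentile method can otherwise exclude it on skewed small samples).
- Percentile bootstrap at ~30 subjects undercovers slightly; the coverage
  test accepts 90–98% around the nominal 95%.
- All-zero regions, constant columns, aperiodic segments and empty masks
  yield flagged (NaN) descriptors, never fabricated values; the pipeline
  imputes flagged cells with training-fold medians and drops columns
  unusable on the training fold.
- Segments whose mid-flow window is shorter than the PSD analysis window
  (split phases, spurious bursts) are excluded from condition averages;
  families needing longer supports (MFCC, CQT) flag rather than fail.
- Box-counting uses box sizes 1, 2, 4, … and a least-squares slope.
- Every stochastic component (samplers, bootstraps, bagging, splitter
  swaps) is seeded; identical seeds give bit-identical outputs.

## Problem sizes used in the shipped tests

Module tests run on constructed micro-inputs. The end-to-end evaluation
uses a 40-subject cohort (10 per class) with k=2 folds and default
parameters elsewhere — a desk-scale configuration chosen so the whole suite
runs on one CPU in minutes; the acceptance script's cohort-level targets use
the full 199-subject class structure, which only requires anthropometrics
and the splitter.

## Known limitations

- The generator's severity profiles are monotone fixtures; effect sizes on
  real cohorts will differ, and reported AUCs on synthetic data say nothing
  about clinical operating points.
- Phase labelling relies on protocol order; a recording starting
  mid-cycle needs the `first_phase` configuration.
- Jitter/shimmer/NHR are usually undefined on breath noise and survive to
  the feature table only when a pitched component exists.
- Only energy/SNR gating is automated; vocal-artifact screening of real
  recordings is out of scope.
- The six 1-vs-1 models are evaluated as pairs; no fused multiclass
  decision rule is produced.
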