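# Methods

## The problem

`fnirs_upb` implements an end-to-end analysis for detecting unplanned purchase
behavior (UPB) from prefrontal functional near-infrared spectroscopy (fNIRS).
The experimental paradigm is a two-condition online-shopping block design: in
Task 1 products are offered under a Buy-One-Get-One-Free (BOGOF) promotion
(the UPB-eliciting condition), in Task 2 the same shopping task runs without
the promotion. Each task comprises 5 trials (1 s cue, 25 s task, 30 s rest)
recorded at 8.138 Hz on a 15-channel montage (5 sources, 7 detectors, 3 cm
separation) covering five prefrontal ROIs: DLPFC, left/right VLPFC, mPFC and
OFC. The pipeline classifies single trials as UPB vs non-UPB per subject and
reports whether the classifier is reliable enough to "detect UPB patterns"
(accuracy strictly above 80%).

Because the package must be fully testable without any external recordings,
a synthetic-data generator is a first-class module: it produces
dual-wavelength (780/850 nm) optical-density recordings, purchase-count
tables and Likert self-report tables with the statistical structure the
analysis assumes.

## Signal model (generator)

Per channel, task-locked ΔHbO is a boxcar over each 25 s task interval
convolved with a canonical double-gamma hemodynamic response (gamma-pdf
difference, shapes 6 and 16 with unit scale, undershoot ratio 1/6; peak
≈ 5–6 s, undershoot ≈ 16 s), peak-normalized per trial and scaled by a
condition × ROI amplitude map (µM). ΔHbR is −⅓·ΔHbO plus white noise
(0.01 µM), the typical empirical ratio; it is carried through the
Beer–Lambert algebra but unused downstream, since the analysis is HbO-only.
Concentrations map to optical density through the forward modified
Beer–Lambert model — the exact inverse of the preprocessing step — and noise
is added in OD units:

* cardiac (≈1.1 Hz, amplitude 4·10⁻³ OD), respiratory (≈0.3 Hz, 2·10⁻³) and
  Mayer-wave (≈0.1 Hz, 1·10⁻³) sinusoids, each with ±10 % frequency jitter
  and a random phase per channel and wavelength;
* slow drift: three sub-band sinusoids (0.002/0.005/0.008 Hz, total 5·10⁻³ OD)
  with random phases — energy the 0.01–0.1 Hz analysis band-pass is designed
  to remove;
* white Gaussian noise (10⁻³ OD per sample).

Trial-to-trial response variability is multiplicative Gaussian gain jitter
(SD 0.15) per trial and channel.

**ROI amplitude defaults.** The amplitude map encodes the study's qualitative
activation topography: under the promotion the prefrontal cortex is weakly
activated except the left VLPFC (reward system), while the control task
drives strong OFC and moderate mPFC/VLPFC activation with DLPFC weakest —
and overall prefrontal activity is lower under the promotion than the
control. Defaults (peak ΔHbO, µM):

| ROI | Task 1 (BOGOF) | Task 2 (control) |
|---|---|---|
| DLPFC | 0.02 | 0.35 |
| VLPFC left | 0.25 | 0.55 |
| VLPFC right | 0.03 | 0.55 |
| mPFC | 0.04 | 0.60 |
| OFC | 0.05 | 0.80 |

Every Task-2 amplitude exceeds every Task-1 amplitude. This matters because
the classifier's sample unit is one (channel, trial) epoch without channel
identity: rows are separable only if the two conditions' amplitude
distributions overlap little across ROIs. No absolute µM values are published
for this paradigm; these magnitudes are in the usual range of block-design
prefrontal responses and are ordinary config parameters.

**Timing.** Trials are blocked by condition (each task is its own ~5 minute
block, as in the protocol, with the self-report administered in the break).
Onset-to-onset spacing is 62 s (cue 1 + task 25 + rest 30 + inter-trial 6),
so the −1…60 s epoch never overlaps the next trial. The recording is padded
with 120 s of rest before the first block, between the blocks and after the
last trial. The padding equals the ≈1/0.01 Hz settling scale of the band-pass
filter; it keeps zero-phase filtering edge artifacts away from every epoch,
and — because both blocks then carry identical onset/offset filter
transients — it makes trial-position effects symmetric across conditions.
Without the inter-block gap, the first/last trials of the *recording* are
condition-specific and a within-recording classifier can exploit them; with
it, a zero-contrast simulation classifies at chance, which is the designed
null behavior of the generator/pipeline pair.

**Randomness.** One root seed; subject `i` draws from the child stream
`SeedSequence((seed, i))`; the behavior and Likert tables use
`(seed, 1_000_001)` and `(seed, 1_000_002)`. Identical seeds give
bit-identical output, and any subject can be regenerated alone.

## Behavioral model

Purchase counts are Binomial(4, p) per clothing category (5 categories of 4
products, totals 0–20 per task), with p = 0.3335 (promotion) and 0.168
(control) so expected totals are ≈ 6.67 and ≈ 3.36. Note the binomial is
slightly under-dispersed relative to real subjects (between-subject SDs of
≈ 2.1/1.7 vs the ≈ 2.3/2.4 a heterogeneous population produces), so the
synthetic group t statistic on totals runs somewhat above its empirical
counterpart; the means are matched.

Likert responses (3 items, 1–5 scale) come from a subject-level latent score
~ N(mean, SD) — defaults 3.53 ± 0.80 (promotion) and 2.40 ± 0.90 (control),
the configured SD being a *between-subject* SD, matching how group summaries
are reported — plus item-level noise (SD 0.3), rounded to integers and
clipped to the scale. A subject's condition score is the item mean.

## Preprocessing

Fixed order, enforced by provenance flags: band-pass filter → Beer–Lambert →
epoch → baseline-correct.

* **Band-pass** 0.01–0.1 Hz, zero-phase (forward–backward) order-4
  Butterworth — the conventional fNIRS choice; family and order are
  configurable. Filtering is applied to optical density by default (the
  order the acquisition pipeline describes), with a switch for the
  concentration-domain order; the two are equivalent under the linear
  Beer–Lambert map and a test asserts it.
* **Modified Beer–Lambert law**: per sample and channel the 2×2 system
  ΔOD(λ) = [ε_HbO(λ)·ΔHbO + ε_HbR(λ)·ΔHbR]·d·DPF(λ) is solved for
  (ΔHbO, ΔHbR) in µM, with d = 3 cm, DPF = 6.0 at both wavelengths and
  standard tabulated extinction coefficients (780 nm: 736/1102; 850 nm:
  1058/691 cm⁻¹ M⁻¹). All four constants are explicit config; absolute µM
  scaling cancels downstream because features are min-max rescaled.
* **Epoching**: −1…60 s around each task onset; t = 0 is the first sample at
  or after the onset; sample counts follow N = floor(1·fs) + floor(60·fs)
  (= 8 + 488 = 496 at 8.138 Hz). Trials without enough pre/post data are
  rejected and logged, not fatal.
* **Baseline**: subtract the mean of the half-open [−1, 0) s reference
  interval (the 8 pre-onset samples); the corrected reference mean is 0 to
  1e-12 and the operation is idempotent.

## Features and rescaling

Six time-domain features per epoch, computed on the baseline-corrected
[0, 60] s window: mean (SM), variance (SV, denominator N−1), kurtosis (KR)
and skewness (SK) as raw standardized 4th/3rd moments with σ = √SV (the only
dimensionless reading), slope (SS) as the mean of per-sample slopes — which
telescopes to the endpoint slope; a least-squares slope is available — and
signed rectangle-rule area (SA). Constant epochs (SV = 0) return KR = SK = 0
with an explicit degeneracy flag, never silent NaN.

The sample unit is one (channel, trial) epoch: 15 × 5 = 75 rows per condition
per subject. Five trials per task cannot support a 10-fold scheme if a trial
were one sample; per-channel rows are the reading that makes the published
cross-validation arithmetic work, and a per-trial concatenated 90-dimensional
alternative is available by config.

Min-max rescaling maps each feature column to [0, 1] with extrema fitted on
the cross-validation *training* rows only and applied to the test rows (which
may therefore fall outside [0, 1]; the scaler never clips, so extrapolation
stays visible). Constant columns map to 0 with a logged warning. A pooled
"global" mode (the literal rescale-everything reading) exists for comparison;
being a label-blind affine map it cannot by itself move accuracy, which a
regression test demonstrates alongside the measurable inflation caused by
genuine training-fold contamination.

## Classification and evaluation

A maximum-margin SVM, linear kernel, C = 1.0 (both configurable; RBF
available). For the linear kernel the model exposes the weight vector, offset
and margin 2/‖w‖, with a closed-form test fixture verifying the geometry.
The repeated scheme is 30 stratified shuffled 80 %/20 % train/test splits per
subject (the "8 train / 2 test of 10 folds, tested 30 times" protocol), with
the rescaler re-fitted inside every split; classic stratified 10-fold × 3 is
the alternative mode. Reported per subject: mean accuracy, SD and
SEM = SD/√30. Classifiers are per-subject (a pooled mode exists but is
secondary).

Reliability is ROC/AUC over the pooled out-of-fold decision scores across the
30 splits, with the promotion condition as positive class: TPR = TP/(TP+FN),
FPR = FP/(FP+TN) (zero denominators raise, never silently return 0), ROC by
threshold sweep with diagonal tie segments, AUC by trapezoidal integration —
equal to the Mann–Whitney pairwise-ranking probability, which an independent
brute-force oracle checks. The AUC report aggregates per-subject values with
mean, sample SD, SEM, min and max, displayed with half-up 2-decimal rounding.

The detection verdict is READY iff accuracy strictly exceeds the threshold
(default 0.80); exactly 80 % is NOT_READY because the criterion is
"exceeds".

## Behavioral statistics

Independent-samples pooled-variance (Student) t-tests with df = n1 + n2 − 2,
two-sided p from the t distribution — pooled rather than Welch because the
published df (64 with 33 + 33) implies it, and the two conditions are treated
as independent groups even though the design is within-subject, mirroring the
original analysis (both choices are deliberate fidelity, not statistical
recommendations). `t_from_summary` works directly from (mean, SD, n) so
printed tables can be checked; raw-data paths reduce to it exactly.

## Problem sizes and what the tests show

The test suite and the acceptance script run the imaging pipeline at 10
synthetic subjects (≈ 0.1 s per subject), the null calibration at 50
single-subject seeds and the behavioral statistics at the study's 33 subjects
(averaged over 100 replicate draws in the acceptance script for a stable
estimate). Under the default configuration the synthetic analog lands in the
published regime: grand mean accuracy ≈ 94 %, all subjects READY, mean AUC
≈ 0.99 with per-subject accuracies ≈ 91–98 %.

The generator emulates block-design hemodynamics, stationary sinusoidal
physiological noise, drift, and white noise. It does **not** emulate motion
artifacts, skin/scalp optics, short-channel systemic contamination,
habituation across trials, or inter-subject anatomical variability — so
passing tests demonstrate that the *analysis* is correct and calibrated
(chance-level on null data, high accuracy under the programmed contrast),
not that real recordings of this paradigm would reach any particular
accuracy.

## Numerical and degenerate-input choices

* Filter contracts are asserted past the settling region (300 s edge trim on
  1200 s probes): DC and 1.0 Hz attenuated to ≤ 1 %, 0.05 Hz preserved ≥ 90 %.
* Signals shorter than the filtfilt padding raise with the minimum length.
* Singular extinction matrices and non-positive DPF/separation raise
  configuration errors before any algebra runs.
* Ties in ROC scores produce diagonal steps (Mann–Whitney-consistent).
* Contradictory SVM inputs (identical points, opposite labels) train without
  crashing at ≤ 50 % accuracy; single-class inputs raise.
* All stochastic stages are seeded; rerunning a pipeline with the same config
  and seed reproduces result JSONs byte-for-byte.

## Known limitations

* Per-(channel,trial) rows within one recording are not fully independent;
  row-level splits therefore measure within-session discriminability, not
  generalization to new sessions (this mirrors the original protocol).
* The binomial purchase model reproduces group means but slightly
  under-disperses totals, inflating the synthetic purchase t relative to a
  heterogeneous population.
* The SNIRF writer/reader covers the minimal subset needed for exchange of
  these recordings (one CW-amplitude data block, stim groups, schematic probe
  geometry), not the full standard.
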