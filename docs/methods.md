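# Methods

`ecgkit` processes 10-second, 500 Hz, 12-lead resting ECG records stored as
CSV (5000 rows x 12 lead columns, microvolts) together with a per-record
diagnostics table (rhythm label, demographics, and vendor summary
measurements).  It implements four stages — denoising, consistency QC,
interpretable feature extraction, and rhythm-group classification
evaluation — plus a synthetic generator that provides exact ground truth
for all of them.  This note records the models, the defaults and why they
were chosen, and the limits of what the synthetic tests demonstrate.

## Denoising

Each lead is processed independently through a fixed three-stage sequence.

**Zero-phase Butterworth low-pass.**  Constraints: passband edge 50 Hz,
stopband edge 60 Hz, at most 1.0 dB passband ripple, at least 2.5 dB
stopband attenuation (the normal diagnostic ECG band ends near 50 Hz).
The order is the ceiling of the analytic Butterworth expression

    n >= log10[(10^(As/10) - 1)/(10^(Ap/10) - 1)] / (2 log10(fs_stop/fs_pass))

evaluated on the stated edge frequencies, which gives n = 4; the digital
cutoff is then placed (after bilinear prewarping) so the passband edge
meets the ripple bound exactly, leaving the 60 Hz edge at about -3.6 dB.
Note that a design that selects the order *after* prewarping would return
n = 3 for these constraints; we deliberately keep the classical
edge-frequency formula as the order rule so the reported order matches the
textbook computation.  The filter is realized in cascaded second-order
sections for numerical stability and applied forward and backward
(reflective edge padding of 3x the order), so the net phase is zero and the
effective magnitude response is the square of the single-pass response.

**Robust LOESS baseline removal.**  Baseline wander (respiration/motion
drift below ~0.5 Hz) is estimated by locally weighted polynomial regression
and subtracted.  Defaults: span 0.15 of the record (a 1.5 s window at
500 Hz — wider than one beat, so QRS complexes behave as outliers to the
trend), local degree 2, 4 robustness iterations, cut at 6 robust scale
units.  Each iteration scores residuals against the **median** absolute
residual: points beyond 6x that scale get zero weight, points within get
bisquare weights.  Using the median is the classical robust-lowess
("rloess") convention — whose documentation habitually phrases the cut as
"six mean absolute deviations" — and it matters here: a mean-based scale is
inflated by the QRS residuals, the cut then never rejects the P/T waves,
and the estimated trend rides the wave mass instead of the isoelectric
line.  With the median scale the trend on a clean record is a few uV RMS
and detrending is near-idempotent.  Local fits use tricube distance
weights, a scaled regressor for conditioning, and boundary windows that
shift (rather than shrink) at the record edges.

**Non-local means (NLM).**  The residual broadband noise is removed by
patch-based averaging: each output sample is the weighted mean of input
samples within a search neighborhood, with weights decaying exponentially
in the squared distance between the patches surrounding the two samples,

    S(i) = (1/Z(i)) sum_{j in N(i)} w(i,j) D(j),
    w(i,j) = exp( - sum_d g(d) [D(i+d) - D(j+d)]^2 / (2 L lambda^2) ).

Defaults: patch half-width 10 samples (L = 21), search half-width 300
samples (0.6 s), smoothness lambda = 0.6 x a robust noise-SD estimate
(1.4826 x median absolute successive difference / sqrt 2), following the
ECG-NLM literature; tying lambda to the estimated noise makes the stage
scale-free.  The patch taper g is a Gaussian over patch offsets with SD =
half-width/2, normalized to total mass L so lambda is on the same scale as
with the uniform (untapered) kernel; both kernels are available because
"a Gaussian kernel as weight function" can be read either as the patch
taper or as the exponential weight itself.  At the record ends, patches and
search windows are truncated to valid samples — nothing is padded — and L
is replaced by the retained kernel mass.  A useful side effect of the
0.6 s search window: at physiological heart rates the neighboring beat's
QRS lies outside the window, so R peaks find few similar patches and are
left nearly untouched rather than smeared.

The stage order is fixed (low-pass, then detrend, then NLM) and not
reorderable through configuration.  No explicit high-pass stage exists;
the LOESS detrend plays that role.

## Quality control

Two linear constraints tie the limb leads together: lead II = lead I +
lead III (Einthoven) and aVR + aVL + aVF = 0 (Goldberger).  A record passes
a check when the fraction of samples whose residual exceeds `tol_uv` is at
most `max_violation_frac`.  Defaults anchor to the A/D step of 4.88 uV per
bit: tol = 3 LSB (14.64 uV), violation fraction 0.01.  A lead is flagged
flat when sliding 2 s windows with sample variance at most (4.88 uV)^2
cover at least 90% of the record (an electrode that slipped off leaves a
straight line).  A record is excluded iff any check fails.

An LA/RA arm-electrode swap is *not* detectable from these identities: the
swap negates lead I, exchanges II with III and aVR with aVL, and both
identities survive.  A heuristic advisory (negative net deflection in
lead I) is reported but never excludes, to avoid overclaiming what the
identity checks can do.

## Feature extraction

The 230-entry vector decomposes as 12 + 216 + 2 (this decomposition is the
package's reconstruction of the stated total):

* **12 rhythm-lead values** from lead II: ventricular rate (BPM), atrial
  rate (BPM), QRS duration (ms), QT interval (ms), R axis, T axis, QRS
  count, Q onset, Q offset (0-based sample indices), RR mean (s), RR
  variance (s^2, unbiased), RR interval count.  Ventricular rate, RR
  statistics and QRS count are computed from the signal via the R-peak
  detector; atrial rate, axes, intervals and onsets are vendor (cart)
  measurements passed through from the diagnostics table — recomputing
  electrical axes or QT from the signal is a different research problem.
* **216 morphology values**: per lead, detected extrema are partitioned
  into QRS peaks (within ±50 ms of an R peak), non-QRS peaks, and valleys;
  each subset contributes mean and unbiased variance of height, width and
  prominence (12 leads x 3 subsets x 3 measures x 2 statistics).
* **age** (years) and **gender** (FEMALE = 0, MALE = 1).

Extrema are strict local maxima/minima with plateau centers reported
(left-center on even plateaus); valleys are peaks of the negated signal and
their heights are sign-flipped.  Prominence is the standard topographic
definition (height above the lowest enclosing contour line); width is full
width at half prominence, in samples, by linear interpolation.  Extrema
with prominence below 2 LSB (9.76 uV) are treated as quantization chatter
and dropped.  Empty subsets yield NaN; variance needs at least two members.
Missing values are NaN throughout, never 0 (0 is a legal rate or axis).

The R-peak detector is deterministic: 5-15 Hz zero-phase band-pass,
difference filter, squaring, 150 ms moving-window integration, candidate
maxima at least 200 ms apart thresholded at 30% of the 95th percentile of
candidate energies, each detection refined to the raw-signal maximum
within ±100 ms.  On clean synthetic records it recovers the generator's
R-peak indices exactly.

## Labels and evaluation

The 11 rhythm acronyms merge into 4 groups: SB stays SB; AFIB and AF merge
to AFIB; SVT, AT, SAAWR, ST, AVNRT and AVRT merge to GSVT; SR and SI merge
to SR.  Applied to the published per-rhythm frequencies this gives GSVT
2,307 of 10,646 total.  (The published merged-count table transposes the
AFIB and SB totals relative to what the per-rhythm frequencies imply —
3,889 vs 2,225; the grand total agrees either way.  The package follows
the stated merge rules and surfaces, rather than silently fixes, the
transposition.)

Splitting is stratified with per-group train size = round(0.8 x group
size) to the nearest integer; this reproduces the published 80/20 pairs
(1,780/445, 1,846/461, 3,111/778).  Metrics are one-vs-rest precision,
recall and F1 = 2PR/(P+R) per class, with macro (unweighted mean), micro
(pooled counts; equal to overall accuracy for single-label multiclass) and
support-weighted averages.  Zero-denominator cases report 0 with a logged
note.  "k-fold cross-validation with 20% testing data" is realized as a
stratified 80/20 split with stratified k-fold CV inside the training
portion; both the pooled CV metrics and the held-out test metrics are
reported.  The classifier is pluggable (anything with fit/predict); the
default is a gradient-boosted tree (100 trees, depth 6, learning rate 0.3,
histogram method) with hyperparameters as configuration, since the
package's contribution is the surrounding pipeline and metrics, not the
learner.  NaN entries are imputed with training-fold column means before
fitting so arbitrary learners need not handle missing values.

## Synthetic generator

Beats are sums of Gaussian bumps for P, Q, R, S, T (amplitude, center
offset from R, width), placed at R times drawn from a rhythm model:
constant RR, Gaussian-jitter RR, or irregularly-irregular RR (uniform
0.65-1.35 x mean, no serial correlation, P waves absent) emulating atrial
fibrillation at the signal level.  R times are rounded to the sample grid
before rendering, so the returned R-peak indices are exact.  Default wave
widths give realistic durations (P ~ 120 ms, QRS ~ 70 ms, T ~ 200 ms) and
a true isoelectric baseline between beats.  Leads I and II use independent
amplitude sets; III, aVR, aVL, aVF are derived so the lead identities hold
to machine precision, and V1-V6 are affine combinations of I and II with a
progressive R-wave transition.

Noise defaults (the conditions under which the denoising-efficacy property
is stated): 50 Hz power line at 50 uV, baseline wander as sinusoids at
0.15/0.30/0.45 Hz with 300/150/75 uV, white noise SD 20 uV, band-limited
(20-120 Hz) muscle artifact SD 20 uV — wander-dominated contamination as in
ambulatory recordings, all drawn independently per lead from a seeded
generator.  Corruption modes reproduce the QC failure cases: flatline lead,
broken lead-II identity (independent noise on one limb lead), and the
LA/RA swap algebra.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: real 12-lead torso geometry (precordials are
affine in the limb sources), beat-to-beat morphology variation, ectopy and
conduction abnormalities, pacing spikes, electrode-motion transients, and
correlated cross-lead noise.  Synthetic recovery demonstrates algorithmic
correctness under the stated noise model, not clinical performance; the
published headline classification score (overall F1 0.97 on the full
10,646-record database) requires the real data and is out of scope here.

## Numerical choices and degenerate inputs

* Filter application requires signal length > 3x order; shorter inputs
  raise rather than pad.
* LOESS solves 3x3 weighted normal equations per window with a ridge of
  1e-12 guarding windows whose robust weights wiped out support; a zero
  robust scale (perfect fit) stops the iterations.
* NLM with auto-lambda on a constant signal would give lambda = 0; a tiny
  positive floor makes all weights 1 and returns the constant unchanged.
  Output values are convex combinations of inputs within the search
  window, so the output range never exceeds the local input range.
* The ECG CSV writer emits integers when the matrix is integer-valued, so
  write -> read round trips are exact for raw A/D data.
* Out-of-range diagnostics values (e.g. QRS count above 254) become
  per-row warnings, not crashes; rows without a FileName are rejected with
  a logged reason.
* Per-stage seeds are spawned from the single user-facing seed via
  numpy's SeedSequence, keeping stages isolated but the whole run
  reproducible.

## Problem sizes

Tests and the acceptance checks run on synthetic records of the database
shape (5000 samples x 12 leads): oracle-equivalence suites use hundreds to
a thousand small random signals; the denoising-efficacy property uses 20
seeded full-noise records (lead II); the QC discrimination fixture uses 50
records.  These sizes were chosen to exercise every code path at full
record scale while keeping the suite fast to iterate on.

## Known limitations

* The A/D description in the source material is internally inconsistent
  (a "32-bit" converter with ±32,767 limits and 4.88 uV per bit); the
  package stores microvolts as floats and does not resolve this.
* Whether rhythm-lead features should be computed from raw or denoised
  signal is unspecified upstream; the pipeline computes them from the
  denoised signal, and the functions accept either.
* The swap advisory is a heuristic; genuinely dextrocardic patients would
  trigger it.
* QT intervals, axes and atrial rate are never validated against the
  signal — they are opaque vendor measurements.
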