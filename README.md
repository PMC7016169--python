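# ecgkit

Denoising, lead-consistency quality control, interpretable feature
extraction and rhythm-classification evaluation for 10-second, 500 Hz,
12-lead ECG records — the processing chain used to curate large resting-ECG
arrhythmia databases — together with a synthetic 12-lead generator that
provides exact ground truth, so the whole chain is testable without any
data download.

It is aimed at researchers working with 12-lead ECG CSV exports (5000 rows
x 12 lead columns, microvolts, plus a diagnostics table of rhythm labels
and cart measurements) who need a reproducible, inspectable alternative to
vendor black boxes.

## What it computes

**Denoising** runs each lead through a fixed three-stage sequence:

1. a zero-phase low-pass Butterworth filter (passband 50 Hz, stopband
   60 Hz, ≤ 1.0 dB ripple, ≥ 2.5 dB stopband attenuation; minimum order 4
   by the analytic order formula), applied forward and backward so the
   phase is untouched;
2. robust LOESS baseline estimation and subtraction (1.5 s tricube window,
   local quadratic fits, bisquare robustness with a six-MAD rejection cut)
   to remove sub-0.5 Hz baseline wander;
3. non-local means: every sample is replaced by a weighted average of
   samples whose surrounding patches look alike,

       S(i) = (1/Z(i)) Σ_{j∈N(i)} w(i,j) D(j),
       w(i,j) = exp( − Σ_δ [D(i+δ) − D(j+δ)]² / (2 L_Δ λ²) ),

   with λ tied to a robust noise estimate by default.

**QC** enforces the physical lead identities II = I + III and
aVR + aVL + aVF = 0 (tolerances anchored to the 4.88 uV A/D step) and
detects flatlined leads from slipped electrodes; inconsistent records are
excluded with per-record reports.

**Features** builds a named 230-dimensional vector per record: 12 lead-II
rhythm/interval values (ventricular rate, RR statistics and QRS count
computed from the signal by a deterministic R-peak detector; cart
measurements passed through), mean and variance of height, width and
prominence for QRS peaks, non-QRS peaks and valleys on each of the 12
leads (216 values), plus age and gender.

**Evaluation** merges the 11 rhythm labels into 4 groups (SB; AFIB+AF;
SVT/AT/SAAWR/ST/AVNRT/AVRT → GSVT; SR+SI), splits 80/20 stratified,
cross-validates a pluggable classifier (gradient-boosted trees by
default), and reports per-class and macro/micro/weighted precision,
recall and F1 = 2PR/(P+R) with confusion matrices.

See `docs/methods.md` for the full model description, defaults, and
limitations.

## Worked example

```python
import numpy as np
from ecgkit import synth, denoise, qc, features, labels_eval

# a sinus-rhythm record with known R peaks, plus realistic contamination
rec, r_peaks = synth.generate_clean_record(seed=7)
noisy = synth.add_noise(rec, synth.noise_preset("full", seed=8))

den = denoise.denoise_signal(noisy.lead("II"), fs=rec.fs)
clean = rec.lead("II")
rms_in = np.sqrt(np.mean((noisy.lead("II") - clean) ** 2))
rms_out = np.sqrt(np.mean((den - clean) ** 2))
print(f"lead II RMS error: {rms_in:.1f} uV raw -> {rms_out:.1f} uV denoised "
      f"({100 * (1 - rms_out / rms_in):.0f}% reduction)")

report = qc.qc_record(synth.corrupt(rec, "flatline_lead", "V3"))
print("QC excluded:", report.excluded, "| reasons:", report.reasons)

meta = synth.synthetic_diagnostics(rec, r_peaks, "SR", age=61, gender="FEMALE")
fv = features.build_feature_vector(rec, meta)
print(f"{len(fv)} features; ventricular rate "
      f"{fv['ventricular_rate_bpm']:.1f} BPM, RR variance {fv['rr_variance_s2']:.4f} s^2")
print("merge_rhythm('AF') ->", labels_eval.merge_rhythm("AF"))
```

prints

```
lead II RMS error: 257.8 uV raw -> 33.5 uV denoised (87% reduction)
QC excluded: True | reasons: ['flatline lead(s): V3']
230 features; ventricular rate 75.3 BPM, RR variance 0.0004 s^2
merge_rhythm('AF') -> AFIB
```

The denoiser removed ~87% of the injected RMS error on lead II (power-line
hum, baseline wander, white noise and muscle artifact); QC caught the
flatlined precordial lead; the feature stage recovered the generator's 75
BPM heart rate and near-zero RR variance; and atrial flutter maps into the
AFIB group.

## Command line

```sh
ecgkit simulate --rhythm afib --noise-preset full --seed 3 --out raw/
ecgkit qc       --in raw/ --report qc_report.csv
ecgkit denoise  --in raw/ --out denoised/
ecgkit features --ecg-dir denoised/ --diagnostics raw/Diagnostics.csv --out features.csv
ecgkit evaluate --features features.csv --diagnostics raw/Diagnostics.csv \
                --folds 10 --seed 3 --report report.csv
ecgkit pipeline --in raw/ --diagnostics raw/Diagnostics.csv --out out/   # qc->denoise->features
```

Every stage default can be overridden with `--config file.ini` (sections
`[lowpass]`, `[loess]`, `[nlm]`, `[qc]`, `[features]`); runs write a
provenance log (effective config, seed, versions, record counts).

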