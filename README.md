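# pulsebp

Beat-by-beat fiducial detection on concurrent ECG/PPG and cuffless
blood-pressure estimation by log-linear regression.

Cuff-based sphygmomanometry interrupts the patient and samples blood
pressure only intermittently. A widely studied alternative derives
pressure from the **pulse arrival time** (PAT) — the delay between the
ECG R peak and a distal landmark of the photoplethysmogram in the same
cardiac cycle — but PAT alone under-determines pressure. `pulsebp`
implements a pipeline for researchers working on this problem:

1. **Haar-wavelet delineation** of every beat of both channels at a
   1200 samples/s working rate. Detail coefficients of a multilevel
   orthonormal Haar transform act as a multiscale derivative: level 3
   brackets the QRS complex (and the PPG pulse), level 5 the
   low-frequency P/T waves and the diastolic wave, and
   wavelet-transform modulus maxima mark the remaining singularities.
   ECG yields P, Q, R, S, T and the QRS onset/offset; PPG (in
   transmission-intensity orientation) yields the systolic point SP,
   dicrotic notch DN, diastolic peak DP and end of beat EB.
2. **Adaptive windowing (AWWT)**: the analysis window is re-sized every
   beat from the local R-R (ECG) or beat-to-beat (PPG) interval, slid
   until it holds exactly one complete cycle (anchor peak near the
   window centre, enough modulus-maxima points on both sides). A fixed
   1100-sample window (FWWT) is provided as the baseline it improves on.
3. **32 interval features per beat pair** — 5 ECG-only, 7 PPG-only and
   20 cross-channel transit times `T_iA/T_iB/T_iN1/T_iN2`
   (i ∈ {P,Q,R,S,T}; `T_RN2` is PAT) — aggregated per ~one-minute
   segment by a mean ± SD outlier filter.
4. **Log-linear regression** `ln(BP) = β₀ + Σ βⱼxⱼ` for SBP and DBP,
   with R² screening and wrapper feature selection, and evaluation by
   ME/MAE/SD, Bland–Altman pairs, BHS cumulative-error grading and the
   AAMI |ME| ≤ 5, SD ≤ 8 mmHg criterion.

A synthetic paired-signal generator with exact per-beat ground truth
(programmable heart rate, variability, PAT, morphology, noise, and BP
labels tied to true features through a known log-linear map) makes
every stage testable without clinical data. See `docs/methods.md` for
the models, parameters and limitations.

## Worked example

Simulate a small cohort, delineate, extract features and estimate BP —
every stage is a CLI subcommand over the library:

```
$ pulsebp simulate --subjects 30 --seed 5 --duration 80 --out sim
wrote 30 subjects to sim

$ pulsebp detect-ecg --in sim/S000_ecg.csv --out beats_ecg.csv
88 beats -> beats_ecg.csv

$ pulsebp detect-ppg --in sim/S000_ppg.csv --out beats_ppg.csv
86 beats -> beats_ppg.csv

$ pulsebp extract --ecg sim/S000_ecg.csv --ppg sim/S000_ppg.csv --out feats.csv
71 beat pairs -> feats.csv
```

`beats_ecg.csv` holds one row per beat with the sample index and time
of each wave point; `feats.csv` holds one row of the 32 named interval
features (seconds). 88 detected beats over the 80 s recording at this
subject's heart rate means essentially every programmed beat was
segregated; 71 pairs survive the concurrent pairing inside the
one-minute analysis segment.

Fitting and evaluating on the per-subject feature vectors (one row per
subject in `features.csv`, the simulated reference pressures from
`labels.csv` as `bp.csv`):

```
$ pulsebp fit --features features.csv --bp bp.csv --target sbp \
      --select r2 --out model.json
sbp model on 20 features -> model.json

$ pulsebp predict --model model.json --features features.csv --out pred.csv
$ pulsebp evaluate --pred pred.csv --ref bp.csv --column sbp
{
  "me": -0.008809059865167512,
  "mae": 1.2688766655563612,
  "sd": 1.62803096643062,
  "n": 30,
  "bhs": {
    "within5": 100.0,
    "within10": 100.0,
    "within15": 100.0,
    "grade": "A"
  },
  "aami_pass": true
}
```

R² screening kept 20 of the 32 features (many intervals co-vary with
pressure through heart rate and PAT). The mean error (−0.01 mmHg),
mean absolute error (1.27 mmHg) and error SD (1.63 mmHg) describe
in-sample agreement with the simulated reference pressures; every
subject falls within 5 mmHg, which is BHS grade A, and the AAMI
mean-error/SD criterion passes. On synthetic data these numbers
reflect the generator's label noise and the fidelity of the detection
chain — not clinical accuracy; held-out evaluation on fresh cohorts is
what `scripts/acceptance.py` reports.

The same pipeline runs in-process via `pulsebp.io.read_recording` and
`pulsebp.io.run_pipeline`, and the estimator is scikit-learn
compatible:

```python
from pulsebp import LogLinearRegression
model = LogLinearRegression(target="sbp", features=["T_RN2", "Trr", "Tn2n1"])
model.fit(X, y)          # X: feature table, y: reference SBP (mmHg)
model.predict(X)         # exp(beta0 + X @ betas), always positive
```

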