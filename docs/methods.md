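# Methods

`pulsebp` estimates systolic and diastolic blood pressure (SBP/DBP)
continuously from concurrent single-lead ECG and transmission PPG. The
chain is: wavelet-based beat-by-beat fiducial detection on both channels
→ 32 interval features per beat pair, robustly aggregated per ~one-minute
segment → a log-linear regression from segment features to pressure.
This note documents the models, the parameters that matter, the
synthetic test bed, and the design choices made where the design was
genuinely open.

## Working representation

Both channels are brought to a common working rate of 1200 samples/s by
linear interpolation (ECG typically 200 Hz → factor 6, PPG 75 Hz →
factor 16). 1200 is chosen so that five halvings of the Haar cascade
still leave useful resolution; every window entering modulus-maxima
analysis must hold at least 128 samples (≥ 4 level-5 coefficients).
Linear interpolation is used because it preserves monotonicity and the
ordering of extrema and adds no ringing near the QRS complex. One
consequence matters downstream: an interpolated stream is piecewise
linear, with a slope kink at every native sample. These kinks are
genuine level-1 singularities, so modulus-maxima analysis applies
non-maximum suppression with an 18-sample radius (covering the
16-sample native spacing of 75 Hz PPG) — one surviving maximum per
physical singularity.

## Wavelet layer

The DWT is the orthonormal Haar filter pair
`cA_k = (x_{2k} + x_{2k+1})/√2`, `cD_k = (x_{2k} − x_{2k+1})/√2`
(delegated to PyWavelets per level), so energy is conserved exactly —
a testable invariant. Odd-length levels are right-padded with their
last sample, which cannot create an artificial edge singularity.
Detail coefficients of a smooth signal are proportional to the negated
local slope at that scale; the detectors use them only through
argmin/argmax and sign changes, so detection is invariant under
amplitude scaling and DC offset of the input.

Modulus maxima are strict local maxima of the level-1 detail modulus
(leftmost sample of a plateau), thresholded at a fraction (default
0.05) of the window's maximum modulus — a relative threshold, hence
scale-invariant. Coefficient index `k` at level `l` maps to signal
index `k·2^l` (left edge of support); searches that end at a
coefficient include that coefficient's full support.

## ECG delineation

Within a window holding one cardiac cycle:

1. `t1`/`t2` = signal locations of the level-3 detail minimum and
   maximum (sorted). These flank the steep QRS limbs; R is the raw
   maximum between them.
2. Modulus maxima give `t3` (last before `t1`) and `t4` (first after
   `t2`). The QRS limbs themselves carry maxima that can land a few
   samples outside the level-3-quantised bracket, so one level-3
   support (8 samples) of clearance is kept; Q is the raw minimum on
   `[t3, R)`, S on `(R, t4]`.
3. QRS onset/offset: the boundary is threshold-defined, not an
   extremum. Scanning outward from Q (resp. S), the boundary is the
   first point where the smoothed first difference (moving average 9
   samples) stays below θ = 0.05 × the window's maximum |difference|
   for 5 consecutive samples. The sustained-run requirement stops a
   momentary dip at the limb foot from truncating the complex; scanning
   outward from Q/S (rather than from R) is the only reading consistent
   with the ordering `qrs_on < q < r < s < qrs_off`.
4. P and T: level-5 detail extrema restricted to the pre-onset and
   post-offset segments bracket the low-frequency waves; the apex is
   the raw maximum between them, refined by a least-squares parabola
   vertex (±24 samples). The P search is bounded to 0.3 windows before
   QRS onset so the previous beat's T limb, which may overlap the
   window start, cannot capture the bracket.

A window counts as a beat only when R was found, R lies within 10% of
the window size from the centre, and more than two modulus-maxima
points lie on each side of R (presence of P and T).

## PPG delineation

The core operates on transmission-intensity PPG: systole absorbs
light, so each pulse is a deep systolic trough (SP), the dicrotic
notch crest (DN), a shallower diastolic trough (DP), and the
end-of-beat crest (EB). Conventional volume-oriented input is inverted
on load (`ppg_orientation="volume"`).

1. EB: on the level-3 detail (3+-tap averaged against noise; the tap
   count grows with the window since slope widths scale with the beat
   period), the pulse appears as a strong rise (recovery out of SP)
   followed one period later by the strong fall into the next trough.
   The bracket is the **first** strong rise to the **last** strong fall
   (strong = beyond 0.6 of the extreme coefficient). Using first/last
   rather than the global extrema matters: a window covering two
   near-identical systolic troughs would otherwise bracket a single
   trough whenever the two flank slopes tie. A bracket narrower than a
   quarter window, or whose maximum is not a genuine local crest, is
   rejected and the window slides on.
2. DP: level-5 detail coefficients act as a coarse negated slope.
   Walking left from EB, the walk first enters the rise toward EB
   (coefficients clearly below −τ, τ = 0.1 of the pre-EB extreme) and
   stops at the first coefficient above +τ — the slope zero-crossing
   at the diastolic trough, with hysteresis so near-zero plateau noise
   cannot stop the walk early. The crossing is refined to the raw
   minimum (smoothed coarse search + parabola vertex) over its support.
3. SP = argmin of the window before DP. No wide parabola refinement:
   the trough is asymmetric (steep drop, slow recovery) and a fitted
   vertex would be biased toward the wide side.
4. DN: requires a modulus-maxima point — the notch's own slope
   singularity — within 0.2·(DP−SP) of the SP–DP midpoint; a beat
   without a dicrotic wave still carries maxima between the troughs
   (recovery, pre-trough fall) but they hug the troughs. The crest is
   the raw maximum of the open interval, accepted only if interior and
   prominent (falls away on both sides by ≥ 2% of the window range).
   Beats without an acceptable crest carry a null DN and DN-dependent
   features are skipped.

SP and DN additionally get a three-point parabola through *native*
sample vertices (spacing 16 at 1200 Hz): extrema of a piecewise-linear
stream snap to native vertices, and this sub-quantum refinement removes
the native-rate quantisation from interval features — without it,
per-beat SP→DN intervals take a handful of discrete values and the
mean ± SD filter becomes unstable (whole quantisation bins flip in or
out of the band).

Window validity mirrors the ECG: EB detected, EB within 10% of the
centre, more than three maxima before EB and more than two after.

## Stream loops and adaptive windowing

Adaptive mode (AWWT) re-estimates the window size before every beat:
R peaks (ECG) or end-of-beat crests (PPG) are found in a 2400-sample
block by amplitude thresholding of the mean-removed block (threshold
0.6 × block maximum, 240-sample refractory; PPG additionally keeps only
crests within 75% of the tallest, which separates end-of-beat crests
from dicrotic crests), and the window is the median adjacent peak
distance grown by 25%. When a block holds fewer than two peaks the last
successful adaptive size is reused (initially the fixed 1100-sample
size). Fixed mode (FWWT) always uses 1100 samples.

Invalid windows slide forward by 10 samples within a retry budget of
2 × window/step; when a beat was delineated but sits off-centre, the
loop may also re-centre the window on the detected anchor directly (at
most three times per beat search) — forward sliding alone cannot
recover an anchor left of centre. After a success the ECG search resumes
just past the T apex; the PPG search resumes one tenth of a window
before the next pulse's beginning, seeded from the current EB. Budget
exhaustion skips one window and continues; a flat or beat-free stream
yields an empty beat list.

The fixed window reproduces its expected failure mode: at rates where
1100 samples hold more than one beat (high HR), FWWT recall collapses
(~66% at 110 bpm in the acceptance run) while AWWT stays at ~100%. At
low rates the compact beat morphology used by the generator still fits
in 1100 samples, so the degradation shows on the crowded side only.

## Features and aggregation

Each PPG beat's DP back-traces to the latest preceding R peak; each R
pairs at most once. Per pair, 32 interval features in seconds: 5
ECG-only (`Tqrs, Tpr, Tst, Trr, Tpt`), 7 PPG-only (`Tab, Tbb, Taa,
Tn1b, Tn2b, Tn2n1, Tn2a`), and 20 cross-channel transit times
`T_{i}{A,B,N1,N2}` (ECG wave i → DP/EB/DN/SP, i ∈ {P,Q,R,S,T});
`T_RN2` is the pulse arrival time. Cross features are signed (PPG minus
ECG landmark); intra-channel features are later-minus-earlier. The
inter-beat intervals look forward and are null on the last beat; any
feature touching a null fiducial is null.

A segment is the first 80 000 working-rate samples (~67 s) after a
10 000-sample settling skip. Each feature column is filtered to
[mean − SD, mean + SD] (sample SD, applied once, not iterated) and the
survivors averaged. Segments with fewer than 20 beat pairs are
rejected.

## Blood-pressure model

`ln(BP) = β₀ + Σ βⱼ xⱼ`, fitted by OLS; predictions are exponentials,
hence always positive. The log-linear form reflects the
inverse-exponential relation between pulse transit time and pressure.
Feature screening keeps features whose univariate R² against ln(BP)
exceeds 0.3 (interpreted per-feature; a component-variance reading of
the same screening is possible but less direct). The wrapper stage
grows a subset greedily by 5-fold cross-validated MAE and stops when
the best candidate improves the score by less than 5% relative —
without a minimum improvement, irrelevant features enter on
chance-level CV gains; a seeded random-subset mode is provided as an
alternative. Default feature sets are the published 9 (SBP) and 14
(DBP = SBP set + 5 PPG-only intervals).

Agreement metrics: ME = Σ(p−y)/n, MAE = Σ|p−y|/n,
SD = √(Σ((p−y)−ME)²/(n−1)), Bland–Altman pairs ((p+y)/2, p−y), BHS
cumulative percentages of |error| ≤ 5/10/15 mmHg with the standard
grade table (A = 60/85/95, B = 50/75/90, C = 40/65/85, else D), and
the AAMI criterion |ME| ≤ 5 and SD ≤ 8 mmHg.

## Synthetic test bed

The generator emulates paired acquisition: ECG at 200 and PPG at 75
samples/s, additive white noise at a configurable SNR applied at the
native rate, then interpolation to 1200 samples/s — the same path real
recordings take.

* **ECG**: five Gaussian bumps per beat. QRS offsets are fixed in
  seconds (Q/S at ±35 ms, σ 8–10 ms); P and T offsets *and widths*
  scale linearly with the local R-R interval (P at 0.16·RR, T at
  0.30·RR of a reference 0.8 s period), mimicking rate-dependent
  interval shortening and keeping the morphology feasible from 40 to
  180 bpm.
* **PPG**: baseline minus a skewed systolic trough (steep drop ×0.7,
  slow recovery ×1.1 — the inverted systolic upstroke of real
  transmission PPG; the asymmetry is also what makes the
  first-rise/last-fall bracketing well-posed) minus a diastolic trough
  (depth 0.35) plus a dicrotic crest (amp 0.16, σ 35 ms) and an
  end-of-beat crest (amp 0.25). Landmark offsets are fractions of the
  pulse period (DN 0.17, DP 0.31, EB 0.58 by default); the DN timing
  additionally jitters beat to beat (σ 1.2% of the period), as real
  dicrotic timing does — this also spreads per-beat intervals over
  several native quanta so the mean ± SD filter behaves smoothly.
  Morphology validity is checked by numerically probing one beat: every
  landmark must be an interior extremum of its expected interval.
* **Ground truth** indices are numeric extrema of the clean
  working-rate signal around the programmed times — exact for the
  waveform the detectors actually see. The dicrotic crest uses the same
  locator as the detector so truth marks DN exactly where the realised
  waveform carries a usable crest. QRS boundaries, being
  threshold-defined, are located on the clean signal by the same rule
  the detector uses; one definition governs both sides.
* **Blood pressure** labels come from a log-linear map of three true
  features — `ln(SBP) = 5.6047 − 1.8·T_RN2 − 0.25·Trr − 0.8·Tn2n1`,
  `ln(DBP) = 4.8352 − 1.2·T_RN2 − 0.15·Trr − 0.5·Tn2n1` — plus
  N(0, 0.02) log-scale label noise. The negative PAT coefficient is the
  physiologically expected sign; the numbers are a recovery target for
  the regression stage, not a physiological claim. Map inputs are the
  robustly aggregated features of the true beat indices, i.e. exactly
  the quantity the pipeline estimates. Cohorts draw SBP targets from
  N(128.45, 15.34²) mmHg and solve each subject's PAT from the map
  (clipped to 0.12–0.45 s); heart rate ~ N(75, 10²) bpm clipped to
  55–100; landmark fractions and wave amplitudes jitter across subjects
  so the three map features vary independently (dicrotic fraction
  0.155–0.21 uniform).

What passing tests on this bed do **not** show: robustness to baseline
wander, motion artefacts, ectopy/arrhythmia, waveform morphologies far
from the Gaussian-bump family, or sensor-specific distortions. The bed
establishes algorithmic correctness (exact truth, controlled noise),
not clinical performance.

## Problem sizes and numerical choices

Acceptance runs use 62 s recordings per heart rate (50–110 bpm grid)
at 20 dB SNR for detection scoring, a 60-subject noiseless cohort for
coefficient recovery and a 40-subject cohort at the default 25 dB for
held-out accuracy — sizes chosen to keep a full run in a few minutes
while leaving statistical headroom against the stated bounds.
Detection scoring excludes beats within one window (~1600 samples) of
the stream edges, where no valid centred window exists by construction.
Comparisons of extracted features against truth use one native PPG
sample period (1/75 s) as the equality tolerance. Ties in plateau
maxima keep the leftmost sample; floating-point plateaus are detected
with a 1e-12 relative tolerance. Degenerate inputs (flat windows,
empty search ranges) reject with the failing step named rather than
guessing.

## Known limitations

* The delineators assume the beat morphologies described above; ECG
  polarity is handled (t1/t2 are sorted) but e.g. deeply inverted T
  waves would shift the T bracket.
* The derivative-plus-threshold windowing variant mentioned alongside
  AWWT/FWWT in the source literature is not implemented: its empirical
  thresholds were never published, and guessing them would fabricate a
  baseline.
* U waves are not detected.
* WFDB input is not supported; CSV is the interchange format.
* Beat-level BP is not produced; the estimator maps one aggregated
  segment (≈ one minute) to one SBP/DBP pair.
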