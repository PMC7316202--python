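"""Synthetic paired ECG/PPG generator with exact ground truth.

Stands in for a clinical cohort: every recording carries programmable
physiology (heart rate and its beat-to-beat variability, pulse arrival
time, per-wave morphology, additive noise) and exact per-beat landmark
ground truth, so every stage of the detection and estimation pipeline is
testable without patient data.

Waveform model
--------------
* ECG beats are sums of five Gaussian bumps (P, Q, R, S, T).  QRS bump
  offsets are fixed in seconds; the P and T offsets scale linearly with
  the local R-R interval, mimicking rate-dependent interval shortening.
* PPG beats are generated in transmission-intensity orientation: a
  baseline minus a deep systolic trough (SP) and a shallower diastolic
  trough (DP), plus a small dicrotic-notch crest (DN) between them and a
  broader end-of-beat crest (EB).  Landmark offsets are fractions of the
  local pulse period; the systolic trough trails the ECG R peak by the
  pulse arrival time (PAT).
* Channels are synthesised at the native acquisition rates (ECG 200,
  PPG 75 samples/s), noise is added there, and both are linearly
  interpolated to the 1200 samples/s working rate — the same path real
  recordings take.

Ground truth indices are located on the clean working-rate signal
(numeric extrema around the programmed landmark times), so they are
exact for the waveform the detectors actually see; programmed times are
kept alongside for analytic feature values.

Blood pressure labels come from a configurable log-linear map of three
true features (the R->SP delay ``T_RN2`` i.e. PAT, the R-R interval
``Trr`` and the SP->DN interval ``Tn2n1``) plus log-scale noise, making
the map coefficients a known recovery target for the regression stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .fiducial_ecg import EcgFiducials
from .fiducial_ppg import PpgFiducials, locate_dicrotic_crest, native_parabola_refine
from .wavelet_core import SignalStream, WORKING_FS, resample_to

__all__ = [
    "EcgMorphology",
    "PpgMorphology",
    "BpMap",
    "SubjectProfile",
    "GroundTruth",
    "CohortSubject",
    "synth_ecg",
    "synth_ppg",
    "synth_paired",
    "synth_cohort",
    "empirical_snr_db",
    "ECG_NATIVE_FS",
    "PPG_NATIVE_FS",
]

ECG_NATIVE_FS = 200.0
PPG_NATIVE_FS = 75.0

#: Beat period (s) at which morphology widths are specified; widths of the
#: rate-dependent waves scale linearly with the local period relative to it.
REF_PERIOD = 0.8


@dataclass
class EcgMorphology:
    """Gaussian-bump ECG beat template.

    Amplitudes are in arbitrary units relative to R = 1; widths are
    Gaussian sigmas in seconds.  ``p_frac``/``t_frac`` place the P and T
    bumps at that fraction of the local R-R interval before/after R;
    ``q_off``/``s_off`` are fixed offsets in seconds.
    """

    p_amp: float = 0.15
    q_amp: float = -0.10
    r_amp: float = 1.0
    s_amp: float = -0.15
    t_amp: float = 0.35
    p_frac: float = 0.16
    t_frac: float = 0.30
    q_off: float = 0.035
    s_off: float = 0.035
    p_width: float = 0.020
    q_width: float = 0.008
    r_width: float = 0.010
    s_width: float = 0.008
    t_width: float = 0.040

    def validate(self, min_rr: float) -> None:
        """Reject morphologies whose wave supports overlap at ``min_rr``.

        P and T offsets and widths scale with the local R-R interval
        (relative to :data:`REF_PERIOD`), so the checks are evaluated at
        the shortest programmed beat.
        """
        scale = min_rr / REF_PERIOD
        p_off = self.p_frac * min_rr
        t_off = self.t_frac * min_rr
        pw = self.p_width * scale
        tw = self.t_width * scale
        if not p_off - 2 * pw > self.q_off + 2 * self.q_width:
            raise ValueError("P and Q wave supports overlap")
        if not t_off - 2 * tw > self.s_off + 2 * self.s_width:
            raise ValueError("S and T wave supports overlap")
        if not t_off + 3 * tw < min_rr - p_off - 3 * pw:
            raise ValueError("T wave overlaps the next beat's P wave")


@dataclass
class PpgMorphology:
    """Intensity-orientation PPG beat template.

    The systolic trough (depth ``sys_depth``) sits at the beat anchor;
    the dicrotic crest, diastolic trough and end-of-beat crest follow at
    ``dn_frac``/``dp_frac``/``eb_frac`` of the local pulse period.
    Setting ``notch_amp`` to 0 produces beats without a dicrotic notch
    (ground truth marks DN null).
    """

    sys_depth: float = 1.0
    sys_width: float = 0.050
    sys_skew: tuple[float, float] = (0.7, 1.1)
    dia_depth: float = 0.35
    dia_width: float = 0.060
    notch_amp: float = 0.16
    notch_width: float = 0.035
    eb_amp: float = 0.25
    eb_width: float = 0.050
    dn_frac: float = 0.170
    dp_frac: float = 0.310
    eb_frac: float = 0.580
    dn_jitter: float = 0.012
    baseline: float = 1.0

    def validate(self, min_period: float) -> None:
        # all widths scale with the pulse period, so the geometry is
        # period-independent; probe one beat numerically and require every
        # landmark to be a well-defined extremum in its expected interval
        if min_period <= 0:
            raise ValueError("pulse period must be positive")
        if not 0 < self.dn_frac < self.dp_frac < self.eb_frac < 0.85:
            raise ValueError("landmark fractions must satisfy 0 < dn < dp < eb < 0.85")
        T = REF_PERIOD
        t = np.arange(-0.3 * T, 1.1 * T, 1e-3)
        wt = _ppg_wave_times(np.array([0.0]), np.array([T]), self)
        x = _ppg_eval_on(t, wt, self)

        def _interior_ext(lo_t, hi_t, find_max, name):
            seg = (t >= lo_t) & (t <= hi_t)
            idx = np.flatnonzero(seg)
            vals = x[idx]
            j = int(np.argmax(vals) if find_max else np.argmin(vals))
            if j == 0 or j == vals.size - 1:
                raise ValueError(f"{name} is not an interior extremum of its interval")
            return t[idx[j]]

        _interior_ext(-0.1 * T, self.dn_frac * T, False, "systolic trough")
        if self.notch_amp > 0:
            _interior_ext(0.02 * T, self.dp_frac * T, True, "dicrotic notch")
        _interior_ext(self.dn_frac * T, self.eb_frac * T, False, "diastolic trough")
        _interior_ext(self.dp_frac * T, T, True, "end-of-beat crest")


@dataclass
class BpMap:
    """Ground-truth log-linear map from features to blood pressure.

    ``ln(BP) = beta0 + sum(beta_j * feature_j) + eps`` with
    ``eps ~ N(0, label_noise_sd)``.  Default coefficients give roughly
    128/78 mmHg at PAT 0.25 s and 75 bpm, with the physiologically
    expected negative PAT coefficient; they are a recovery target, not a
    physiological claim.
    """

    feature_names: tuple[str, ...] = ("T_RN2", "Trr", "Tn2n1")
    sbp_beta0: float = 5.6047
    sbp_betas: tuple[float, ...] = (-1.8, -0.25, -0.8)
    dbp_beta0: float = 4.8352
    dbp_betas: tuple[float, ...] = (-1.2, -0.15, -0.5)
    label_noise_sd: float = 0.02

    def _linpred(self, beta0: float, betas: Sequence[float], feats: dict) -> float:
        return beta0 + sum(b * feats[name] for b, name in zip(betas, self.feature_names))

    def sbp(self, feats: dict, rng: Optional[np.random.Generator] = None) -> float:
        eps = rng.normal(0.0, self.label_noise_sd) if rng is not None else 0.0
        return float(np.exp(self._linpred(self.sbp_beta0, self.sbp_betas, feats) + eps))

    def dbp(self, feats: dict, rng: Optional[np.random.Generator] = None) -> float:
        eps = rng.normal(0.0, self.label_noise_sd) if rng is not None else 0.0
        return float(np.exp(self._linpred(self.dbp_beta0, self.dbp_betas, feats) + eps))


@dataclass
class SubjectProfile:
    """Programmable physiology of one synthetic subject."""

    hr_mean: float = 75.0
    hr_jitter: float = 0.03
    pat: float = 0.25
    noise_snr: Optional[float] = 25.0
    sbp: Optional[float] = None
    dbp: Optional[float] = None
    seed: int = 0
    ecg: EcgMorphology = field(default_factory=EcgMorphology)
    ppg: PpgMorphology = field(default_factory=PpgMorphology)

    def __post_init__(self) -> None:
        if not 40 <= self.hr_mean <= 180:
            raise ValueError(f"hr_mean must be in [40, 180] bpm, got {self.hr_mean}")
        if not self.pat > 0:
            raise ValueError("pat must be positive")
        if self.sbp is not None and self.dbp is not None and not self.sbp > self.dbp:
            raise ValueError("sbp must exceed dbp")


@dataclass
class GroundTruth:
    """Exact per-beat landmark truth and subject-level labels."""

    fs: float
    ecg: list[EcgFiducials] = field(default_factory=list)
    ppg: list[PpgFiducials] = field(default_factory=list)
    ecg_times: dict[str, np.ndarray] = field(default_factory=dict)
    ppg_times: dict[str, np.ndarray] = field(default_factory=dict)
    beat_features: Optional[pd.DataFrame] = None
    features: dict[str, float] = field(default_factory=dict)
    sbp: Optional[float] = None
    dbp: Optional[float] = None


def truth_index_features(truth: GroundTruth) -> dict[str, float]:
    """Per-subject mean interval features computed from truth *indices*.

    The analytic features use programmed landmark times; the waveform's
    actual extrema sit a few milliseconds off those centres where
    neighbouring waves overlap.  Features derived from the truth indices
    describe the waveform as realised — the appropriate ground truth for
    anything that measures the signal itself.
    """
    from .features import BeatPair, feature_matrix, robust_mean

    ecg_by_id = {b.beat_id: b for b in truth.ecg}
    ppg_by_id = {b.beat_id: b for b in truth.ppg}
    pairs = []
    for bid in sorted(set(ecg_by_id) & set(ppg_by_id)):
        e, p = ecg_by_id[bid], ppg_by_id[bid]
        if e.r < p.dp:
            pairs.append(BeatPair(ecg=e, ppg=p, pair_id=len(pairs)))
    if len(pairs) < 2:
        raise ValueError("too few aligned truth beats")
    table = feature_matrix(pairs, truth.fs)
    # aggregate exactly as the pipeline does (mean after the mean +/- SD
    # filter), so truth and extracted segment values are commensurable
    out = {
        name: robust_mean(table[name].to_numpy()) for name in table.columns
    }
    return {k: v for k, v in out.items() if not np.isnan(v)}


@dataclass
class CohortSubject:
    subject_id: str
    ecg: SignalStream
    ppg: SignalStream
    truth: GroundTruth
    sbp: float
    dbp: float
    profile: SubjectProfile


# ---------------------------------------------------------------------------
# waveform evaluation


def _gauss(t: np.ndarray, center: float, width: float, amp: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((t - center) / width) ** 2)


def _beat_grid(
    profile: SubjectProfile, duration_s: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Programmed R times and per-beat R-R intervals.

    Beat-to-beat variability is lognormal around the mean period; beats
    whose P or T support would fall outside the recording are dropped.
    """
    rr_mean = 60.0 / profile.hr_mean
    m = profile.ecg
    times = []
    t = 0.5 * rr_mean
    while t < duration_s:
        times.append(t)
        t += rr_mean * math.exp(rng.normal(0.0, profile.hr_jitter))
    times = np.asarray(times)
    if times.size < 2:
        raise ValueError("duration too short for two beats")
    rr = np.diff(times)
    rr = np.append(rr, rr[-1] if rr.size else rr_mean)
    sc = rr / REF_PERIOD
    keep = (times - m.p_frac * rr - 4 * m.p_width * sc >= 0) & (
        times + m.t_frac * rr + 4 * m.t_width * sc <= duration_s
    )
    return times[keep], rr[keep]


def _ecg_wave_times(
    r_times: np.ndarray, rr: np.ndarray, m: EcgMorphology
) -> dict[str, np.ndarray]:
    return {
        "p": r_times - m.p_frac * rr,
        "q": r_times - m.q_off,
        "r": r_times,
        "s": r_times + m.s_off,
        "t": r_times + m.t_frac * rr,
        "qrs_on": r_times - m.q_off - 3 * m.q_width,
        "qrs_off": r_times + m.s_off + 3 * m.s_width,
        "_period": rr,
    }


def _numeric_qrs_bounds(
    clean: np.ndarray,
    fs: float,
    wt: dict[str, np.ndarray],
    theta_frac: float = 0.05,
    smooth_width_1200: int = 9,
) -> tuple[np.ndarray, np.ndarray]:
    """QRS onset/offset times located on the clean signal.

    The QRS boundary has no waveform extremum of its own — it is defined,
    as in the detector, by the smoothed first difference dropping below
    ``theta_frac`` of its beat maximum when scanning outward from Q / S.
    Locating it numerically here keeps truth and detection governed by
    one definition.
    """
    from .fiducial_ecg import _qrs_bound_scan, _smoothed_diff

    width = max(1, int(round(smooth_width_1200 * fs / WORKING_FS)))
    if width % 2 == 0:
        width += 1
    on_t = np.empty(wt["r"].size)
    off_t = np.empty(wt["r"].size)
    for k in range(wt["r"].size):
        lo = max(0, int(wt["p"][k] * fs))
        hi = min(clean.size, int(wt["t"][k] * fs) + 1)
        dx = _smoothed_diff(clean[lo:hi], width)
        theta = theta_frac * np.abs(dx).max()
        q_i = int(round(wt["q"][k] * fs)) - lo
        s_i = int(round(wt["s"][k] * fs)) - lo
        on_i = _qrs_bound_scan(dx, q_i - 1, theta, step=-1)
        off_i = _qrs_bound_scan(dx, s_i, theta, step=+1)
        if on_i is None:
            on_i = q_i - 1
        if off_i is None:
            off_i = s_i + 1
        on_t[k] = (lo + on_i) / fs
        off_t[k] = (lo + off_i) / fs
    return on_t, off_t


def _ecg_eval(t: np.ndarray, wave_times: dict[str, np.ndarray], m: EcgMorphology) -> np.ndarray:
    x = np.zeros_like(t)
    scales = wave_times["_period"] / REF_PERIOD
    # QRS widths are rate-independent; the low-frequency P and T waves
    # widen/narrow with the local beat period
    spec = (
        ("p", m.p_amp, m.p_width, True),
        ("q", m.q_amp, m.q_width, False),
        ("r", m.r_amp, m.r_width, False),
        ("s", m.s_amp, m.s_width, False),
        ("t", m.t_amp, m.t_width, True),
    )
    dt = t[1] - t[0] if t.size > 1 else 1.0
    for name, amp, width0, scaled in spec:
        for c, sc in zip(wave_times[name], scales):
            width = width0 * sc if scaled else width0
            lo = max(0, int((c - 5 * width - t[0]) / dt))
            hi = min(t.size, int((c + 5 * width - t[0]) / dt) + 2)
            if hi > lo:
                x[lo:hi] += _gauss(t[lo:hi], c, width, amp)
    return x


def _ppg_wave_times(
    sp_times: np.ndarray,
    periods: np.ndarray,
    m: PpgMorphology,
    rng: Optional[np.random.Generator] = None,
) -> dict[str, np.ndarray]:
    # the dicrotic notch timing fluctuates beat to beat (dn_jitter, as a
    # fraction of the period), clipped so the notch stays well clear of
    # the troughs on either side
    dn_frac = np.full(periods.size, m.dn_frac)
    if rng is not None and m.dn_jitter > 0:
        dn_frac = dn_frac + np.clip(
            rng.normal(0.0, m.dn_jitter, size=periods.size),
            -2.0 * m.dn_jitter,
            2.0 * m.dn_jitter,
        )
        dn_frac = np.clip(dn_frac, 0.15, m.dp_frac - 0.11)
    return {
        "sp": sp_times,
        "dn": sp_times + dn_frac * periods,
        "dp": sp_times + m.dp_frac * periods,
        "eb": sp_times + m.eb_frac * periods,
        "_period": periods,
    }


def _skew_gauss(
    t: np.ndarray, center: float, w_left: float, w_right: float, amp: float
) -> np.ndarray:
    """Two-sided Gaussian: different widths left/right of the extremum."""
    out = np.empty_like(t)
    left = t < center
    out[left] = amp * np.exp(-0.5 * ((t[left] - center) / w_left) ** 2)
    out[~left] = amp * np.exp(-0.5 * ((t[~left] - center) / w_right) ** 2)
    return out


def _ppg_eval_on(
    t: np.ndarray, wave_times: dict[str, np.ndarray], m: PpgMorphology
) -> np.ndarray:
    """Evaluate the PPG model on an arbitrary (uniform) time grid.

    The systolic trough is skewed — the drop into it (the inverted
    systolic upstroke) is steeper than the diastolic recovery out of it,
    as in real transmission PPG.
    """
    x = np.full_like(t, float(m.baseline))
    dt = t[1] - t[0] if t.size > 1 else 1.0
    scales = wave_times["_period"] / REF_PERIOD
    wl, wr = m.sys_skew
    for c, sc in zip(wave_times["sp"], scales):
        width = m.sys_width * sc
        lo = max(0, int((c - 5 * width * wl - t[0]) / dt))
        hi = min(t.size, int((c + 5 * width * wr - t[0]) / dt) + 2)
        if hi > lo:
            x[lo:hi] += _skew_gauss(
                t[lo:hi], c, width * wl, width * wr, -m.sys_depth
            )
    spec = (
        ("dp", -m.dia_depth, m.dia_width),
        ("dn", m.notch_amp, m.notch_width),
        ("eb", m.eb_amp, m.eb_width),
    )
    for name, amp, width0 in spec:
        if amp == 0:
            continue
        for c, sc in zip(wave_times[name], scales):
            width = width0 * sc
            lo = max(0, int((c - 5 * width - t[0]) / dt))
            hi = min(t.size, int((c + 5 * width - t[0]) / dt) + 2)
            if hi > lo:
                x[lo:hi] += _gauss(t[lo:hi], c, width, amp)
    return x


def _ppg_eval(t: np.ndarray, wave_times: dict[str, np.ndarray], m: PpgMorphology) -> np.ndarray:
    return _ppg_eval_on(t, wave_times, m)


def _add_noise(
    clean: np.ndarray, snr_db: Optional[float], rng: np.random.Generator
) -> np.ndarray:
    if snr_db is None or not np.isfinite(snr_db):
        return clean.copy()
    power = np.var(clean)
    sigma = math.sqrt(power / 10.0 ** (snr_db / 10.0))
    return clean + rng.normal(0.0, sigma, size=clean.shape)


# ---------------------------------------------------------------------------
# ground-truth index location


def _argext(
    x: np.ndarray, fs: float, center_t: float, half_w: float, find_max: bool
) -> Optional[int]:
    lo = max(0, int(round((center_t - half_w) * fs)))
    hi = min(x.size, int(round((center_t + half_w) * fs)) + 1)
    if hi - lo < 1:
        return None
    seg = x[lo:hi]
    return lo + int(np.argmax(seg) if find_max else np.argmin(seg))


def _ecg_truth_indices(
    clean: np.ndarray, fs: float, wt: dict[str, np.ndarray], m: EcgMorphology
) -> list[EcgFiducials]:
    beats = []
    n_beats = wt["r"].size
    for k in range(n_beats):
        sc = wt["_period"][k] / REF_PERIOD
        idx = {
            "p": _argext(clean, fs, wt["p"][k], 2 * m.p_width * sc, True),
            "q": _argext(clean, fs, wt["q"][k], 2 * m.q_width, False),
            "r": _argext(clean, fs, wt["r"][k], 0.03, True),
            "s": _argext(clean, fs, wt["s"][k], 2 * m.s_width, False),
            "t": _argext(clean, fs, wt["t"][k], 2 * m.t_width * sc, True),
            "qrs_on": int(round(wt["qrs_on"][k] * fs)),
            "qrs_off": int(round(wt["qrs_off"][k] * fs)),
        }
        if any(v is None for v in idx.values()):
            continue
        # QRS bounds are threshold-defined; clip them so truth always
        # satisfies the ordering invariant around the located Q/S
        idx["qrs_on"] = min(idx["qrs_on"], idx["q"] - 1)
        idx["qrs_off"] = max(idx["qrs_off"], idx["s"] + 1)
        if not idx["p"] < idx["qrs_on"] or not idx["t"] > idx["qrs_off"]:
            continue
        beats.append(EcgFiducials(beat_id=k, **idx))
    return beats


def _ppg_truth_indices(
    clean: np.ndarray, fs: float, wt: dict[str, np.ndarray], m: PpgMorphology
) -> list[PpgFiducials]:
    beats = []
    for k in range(wt["sp"].size):
        sc = wt["_period"][k] / REF_PERIOD
        sp = _argext(clean, fs, wt["sp"][k], 1.2 * m.sys_width * sc, False)
        if sp is not None:
            sp = native_parabola_refine(clean, sp, find_max=False)
        dp = _argext(clean, fs, wt["dp"][k], 1.2 * m.dia_width * sc, False)
        eb = _argext(clean, fs, wt["eb"][k], 1.5 * m.eb_width * sc, True)
        if sp is None or dp is None or eb is None:
            continue
        if not sp < dp < eb:
            continue
        if m.notch_amp > 0:
            # same crest criterion as the detector, so truth marks DN
            # exactly where the realised waveform carries a usable crest
            seg_lo = max(0, sp - 120)
            seg_hi = min(clean.size, eb + 120)
            dn = locate_dicrotic_crest(
                clean, sp, dp, range_ref=float(np.ptp(clean[seg_lo:seg_hi]))
            )
        else:
            dn = None
        if dn is not None and not sp < dn < dp:
            dn = None
        beats.append(PpgFiducials(sp=sp, dn=dn, dp=dp, eb=eb, beat_id=k))
    return beats


# ---------------------------------------------------------------------------
# analytic per-beat features (from programmed times, in seconds)


def _analytic_beat_features(
    ecg_t: Optional[dict[str, np.ndarray]], ppg_t: Optional[dict[str, np.ndarray]]
) -> pd.DataFrame:
    from .features import FEATURE_NAMES  # local import to avoid cycle at import time

    n = ecg_t["r"].size if ecg_t is not None else ppg_t["sp"].size
    out = pd.DataFrame(np.nan, index=range(n), columns=list(FEATURE_NAMES))
    if ecg_t is not None:
        out["Tqrs"] = ecg_t["qrs_off"] - ecg_t["qrs_on"]
        out["Tpr"] = ecg_t["r"] - ecg_t["p"]
        out["Tst"] = ecg_t["t"] - ecg_t["s"]
        out["Tpt"] = ecg_t["t"] - ecg_t["p"]
        out.loc[: n - 2, "Trr"] = np.diff(ecg_t["r"])
    if ppg_t is not None:
        out["Tab"] = ppg_t["eb"] - ppg_t["dp"]
        out["Tn1b"] = ppg_t["eb"] - ppg_t["dn"]
        out["Tn2b"] = ppg_t["eb"] - ppg_t["sp"]
        out["Tn2n1"] = ppg_t["dn"] - ppg_t["sp"]
        out["Tn2a"] = ppg_t["dp"] - ppg_t["sp"]
        out.loc[: n - 2, "Tbb"] = np.diff(ppg_t["eb"])
        out.loc[: n - 2, "Taa"] = np.diff(ppg_t["dp"])
    if ecg_t is not None and ppg_t is not None:
        targets = {"A": "dp", "B": "eb", "N1": "dn", "N2": "sp"}
        for i in "PQRST":
            for suffix, ppg_name in targets.items():
                out[f"T_{i}{suffix}"] = ppg_t[ppg_name] - ecg_t[i.lower()]
    return out


# ---------------------------------------------------------------------------
# public generators


def synth_ecg(
    profile: SubjectProfile, duration_s: float, fs: float = WORKING_FS
) -> tuple[SignalStream, GroundTruth]:
    """Synthesise a single-lead ECG stream with ground truth at ``fs``."""
    rng = np.random.default_rng(profile.seed)
    rr_min = (60.0 / profile.hr_mean) * math.exp(-3 * profile.hr_jitter)
    profile.ecg.validate(rr_min)
    r_times, rr = _beat_grid(profile, duration_s, rng)
    wt = _ecg_wave_times(r_times, rr, profile.ecg)
    t = np.arange(int(round(duration_s * fs))) / fs
    clean = _ecg_eval(t, wt, profile.ecg)
    wt["qrs_on"], wt["qrs_off"] = _numeric_qrs_bounds(clean, fs, wt)
    noisy = _add_noise(clean, profile.noise_snr, rng)
    truth = GroundTruth(
        fs=fs,
        ecg=_ecg_truth_indices(clean, fs, wt, profile.ecg),
        ecg_times=wt,
        beat_features=_analytic_beat_features(wt, None),
        sbp=profile.sbp,
        dbp=profile.dbp,
    )
    truth.features = truth.beat_features.mean(skipna=True).dropna().to_dict()
    return SignalStream(noisy, fs, kind="ecg"), truth


def synth_ppg(
    profile: SubjectProfile, duration_s: float, fs: float = WORKING_FS
) -> tuple[SignalStream, GroundTruth]:
    """Synthesise an intensity-orientation PPG stream with ground truth."""
    rng = np.random.default_rng(profile.seed + 1)
    period_min = (60.0 / profile.hr_mean) * math.exp(-3 * profile.hr_jitter)
    profile.ppg.validate(period_min)
    r_times, rr = _beat_grid(profile, duration_s, rng)
    sp_times = r_times  # standalone PPG: beat anchor is the systolic trough
    wt = _ppg_wave_times(sp_times, rr, profile.ppg, rng)
    keep = wt["eb"] + 4 * profile.ppg.eb_width <= duration_s
    wt = {k: v[keep] for k, v in wt.items()}
    t = np.arange(int(round(duration_s * fs))) / fs
    clean = _ppg_eval(t, wt, profile.ppg)
    noisy = _add_noise(clean, profile.noise_snr, rng)
    truth = GroundTruth(
        fs=fs,
        ppg=_ppg_truth_indices(clean, fs, wt, profile.ppg),
        ppg_times=wt,
        beat_features=_analytic_beat_features(None, wt),
        sbp=profile.sbp,
        dbp=profile.dbp,
    )
    truth.features = truth.beat_features.mean(skipna=True).dropna().to_dict()
    return SignalStream(noisy, fs, kind="ppg"), truth


def synth_paired(
    profile: SubjectProfile, duration_s: float
) -> tuple[SignalStream, SignalStream, GroundTruth]:
    """Synthesise concurrent ECG and PPG at native rates, resampled to 1200.

    The channels share one beat clock; beat ``k``'s systolic trough is
    placed ``pat`` seconds after its R peak.  ECG is generated at 200 and
    PPG at 75 samples/s, noise added natively, then both are linearly
    interpolated to the working rate — the same preprocessing path real
    recordings follow.
    """
    rng = np.random.default_rng(profile.seed)
    rr_mean = 60.0 / profile.hr_mean
    if profile.pat >= rr_mean * math.exp(-3 * profile.hr_jitter):
        raise ValueError(
            f"pat={profile.pat}s must be shorter than the beat period (~{rr_mean:.2f}s)"
        )
    profile.ecg.validate(rr_mean * math.exp(-3 * profile.hr_jitter))
    profile.ppg.validate(rr_mean * math.exp(-3 * profile.hr_jitter))

    r_times, rr = _beat_grid(profile, duration_s, rng)
    ecg_wt = _ecg_wave_times(r_times, rr, profile.ecg)
    sp_times = r_times + profile.pat
    ppg_wt = _ppg_wave_times(sp_times, rr, profile.ppg, rng)
    keep = ppg_wt["eb"] + 4 * profile.ppg.eb_width <= duration_s
    ecg_wt = {k: v[keep] for k, v in ecg_wt.items()}
    ppg_wt = {k: v[keep] for k, v in ppg_wt.items()}

    t_ecg = np.arange(int(round(duration_s * ECG_NATIVE_FS))) / ECG_NATIVE_FS
    t_ppg = np.arange(int(round(duration_s * PPG_NATIVE_FS))) / PPG_NATIVE_FS
    ecg_clean = _ecg_eval(t_ecg, ecg_wt, profile.ecg)
    ppg_clean = _ppg_eval(t_ppg, ppg_wt, profile.ppg)
    ecg_noisy = _add_noise(ecg_clean, profile.noise_snr, rng)
    ppg_noisy = _add_noise(ppg_clean, profile.noise_snr, rng)

    ecg_stream = resample_to(SignalStream(ecg_noisy, ECG_NATIVE_FS, "ecg"), WORKING_FS)
    ppg_stream = resample_to(SignalStream(ppg_noisy, PPG_NATIVE_FS, "ppg"), WORKING_FS)
    ecg_clean_w = resample_to(SignalStream(ecg_clean, ECG_NATIVE_FS, "ecg"), WORKING_FS)
    ppg_clean_w = resample_to(SignalStream(ppg_clean, PPG_NATIVE_FS, "ppg"), WORKING_FS)
    ecg_wt["qrs_on"], ecg_wt["qrs_off"] = _numeric_qrs_bounds(
        ecg_clean_w.samples, WORKING_FS, ecg_wt
    )

    truth = GroundTruth(
        fs=WORKING_FS,
        ecg=_ecg_truth_indices(ecg_clean_w.samples, WORKING_FS, ecg_wt, profile.ecg),
        ppg=_ppg_truth_indices(ppg_clean_w.samples, WORKING_FS, ppg_wt, profile.ppg),
        ecg_times=ecg_wt,
        ppg_times=ppg_wt,
        beat_features=_analytic_beat_features(ecg_wt, ppg_wt),
        sbp=profile.sbp,
        dbp=profile.dbp,
    )
    truth.features = truth.beat_features.mean(skipna=True).dropna().to_dict()
    return ecg_stream, ppg_stream, truth


def synth_cohort(
    n_subjects: int,
    bp_generator: Optional[BpMap] = None,
    seed: int = 0,
    duration_s: float = 80.0,
    noise_snr: Optional[float] = 25.0,
    hr_range: tuple[float, float] = (55.0, 100.0),
) -> list[CohortSubject]:
    """Sample a cohort of paired recordings with BP labels.

    Reference SBP targets are drawn from N(128.45, 15.34^2) mmHg and the
    subject's PAT is solved from the ground-truth log-linear map so that
    the cohort reproduces those moments; DBP follows from its own map.
    Morphology and landmark fractions jitter mildly across subjects so
    the map features vary independently.  Deterministic per seed.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    bp_map = bp_generator or BpMap()
    rng = np.random.default_rng(seed)
    cohort: list[CohortSubject] = []
    for i in range(n_subjects):
        hr = float(np.clip(rng.normal(75.0, 10.0), *hr_range))
        trr = 60.0 / hr
        dn_frac = rng.uniform(0.155, 0.21)
        dp_frac = dn_frac + rng.uniform(0.13, 0.16)
        eb_frac = dp_frac + rng.uniform(0.24, 0.28)
        sbp_target = float(np.clip(rng.normal(128.45, 15.34), 90.0, 185.0))
        expect = {"T_RN2": 0.0, "Trr": trr, "Tn2n1": dn_frac * trr}
        # invert the SBP map for PAT at this subject's rate
        resid = math.log(sbp_target) - bp_map.sbp_beta0
        resid -= bp_map.sbp_betas[1] * expect["Trr"]
        resid -= bp_map.sbp_betas[2] * expect["Tn2n1"]
        pat = float(np.clip(resid / bp_map.sbp_betas[0], 0.12, 0.45))
        amp = lambda base: base * rng.uniform(0.9, 1.1)
        profile = SubjectProfile(
            hr_mean=hr,
            hr_jitter=0.03,
            pat=pat,
            noise_snr=noise_snr,
            seed=int(rng.integers(0, 2**31 - 1)),
            ecg=EcgMorphology(
                p_amp=amp(0.15), q_amp=-amp(0.10), s_amp=-amp(0.15), t_amp=amp(0.35)
            ),
            ppg=PpgMorphology(
                dia_depth=amp(0.35),
                notch_amp=amp(0.16),
                eb_amp=amp(0.25),
                dn_frac=dn_frac,
                dp_frac=dp_frac,
                eb_frac=eb_frac,
            ),
        )
        ecg, ppg, truth = synth_paired(profile, duration_s)
        idx_feats = truth_index_features(truth)
        feats = {name: idx_feats[name] for name in bp_map.feature_names}
        label_rng = np.random.default_rng(profile.seed + 7)
        sbp = bp_map.sbp(feats, label_rng if bp_map.label_noise_sd > 0 else None)
        dbp = bp_map.dbp(feats, label_rng if bp_map.label_noise_sd > 0 else None)
        truth.sbp, truth.dbp = sbp, dbp
        profile.sbp, profile.dbp = sbp, dbp
        cohort.append(
            CohortSubject(
                subject_id=f"S{i:03d}",
                ecg=ecg,
                ppg=ppg,
                truth=truth,
                sbp=sbp,
                dbp=dbp,
                profile=profile,
            )
        )
    return cohort


def empirical_snr_db(clean: np.ndarray, noisy: np.ndarray) -> float:
    """Empirical SNR (dB) of a noisy realisation against its clean pair."""
    noise = noisy - clean
    return float(10.0 * np.log10(np.var(clean) / np.var(noise)))
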