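"""Beat pairing, the 32 interval features, and robust aggregation.

Simultaneous ECG and PPG beats are paired by back-tracing: each PPG
beat's diastolic trough (DP) is matched with the latest preceding R
peak.  Every pair yields 32 interval features in seconds —

* 5 ECG-only: ``Tqrs, Tpr, Tst, Trr, Tpt``;
* 7 PPG-only: ``Tab, Tbb, Taa, Tn1b, Tn2b, Tn2n1, Tn2a``;
* 20 cross-channel transit times ``T_iA / T_iB / T_iN1 / T_iN2``
  (i peak to DP / EB / DN / SP) for i in {P, Q, R, S, T}; ``T_RN2`` is
  the pulse arrival time.

Cross-channel intervals are signed (PPG landmark minus ECG landmark);
intra-channel intervals are later-minus-earlier and nonnegative.
Inter-beat intervals (``Trr, Tbb, Taa``) look forward to the next beat
and are null on the last one; features touching a missing fiducial
(e.g. a null dicrotic notch) are null.

Per analysis segment, each feature column is filtered to
``[mean - SD, mean + SD]`` and the surviving values are averaged,
giving one robust feature vector per segment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .fiducial_ecg import EcgFiducials, WindowPolicy, detect_ecg_stream
from .fiducial_ppg import PpgFiducials, default_ppg_policy, detect_ppg_stream
from .wavelet_core import SignalStream

__all__ = [
    "ECG_ONLY_FEATURES",
    "PPG_ONLY_FEATURES",
    "CROSS_FEATURES",
    "FEATURE_NAMES",
    "BeatPair",
    "FeatureVector",
    "SegmentRejected",
    "pair_beats",
    "compute_beat_features",
    "feature_matrix",
    "robust_mean",
    "aggregate_segment",
]

ECG_ONLY_FEATURES = ("Tqrs", "Tpr", "Tst", "Trr", "Tpt")
PPG_ONLY_FEATURES = ("Tab", "Tbb", "Taa", "Tn1b", "Tn2b", "Tn2n1", "Tn2a")
CROSS_FEATURES = tuple(
    f"T_{i}{suffix}" for i in "PQRST" for suffix in ("A", "B", "N1", "N2")
)
#: Canonical ordering of the 32 feature columns.
FEATURE_NAMES = ECG_ONLY_FEATURES + PPG_ONLY_FEATURES + CROSS_FEATURES

#: Default settling skip and analysis segment length (working-rate samples).
SETTLE_SAMPLES = 10_000
SEGMENT_SAMPLES = 80_000


class SegmentRejected(ValueError):
    """An analysis segment failed a precondition (too short / too few beats)."""


@dataclass
class BeatPair:
    """A simultaneous ECG/PPG beat pair (R precedes the paired DP)."""

    ecg: EcgFiducials
    ppg: PpgFiducials
    pair_id: int = 0

    def __post_init__(self) -> None:
        if not self.ecg.r < self.ppg.dp:
            raise ValueError(
                f"paired R ({self.ecg.r}) must precede DP ({self.ppg.dp})"
            )


@dataclass
class FeatureVector:
    """Robustly aggregated per-segment feature values (seconds)."""

    values: dict[str, float]
    counts: dict[str, int]
    n_pairs: int = 0

    def as_series(self) -> pd.Series:
        return pd.Series(self.values).reindex(FEATURE_NAMES)


def pair_beats(
    ecg_beats: Sequence[EcgFiducials], ppg_beats: Sequence[PpgFiducials]
) -> list[BeatPair]:
    """Pair each PPG beat with the latest preceding R peak.

    The R peak is back-traced from the beat's DP; PPG beats with no
    preceding R, or whose candidate R is already taken by an earlier
    beat, are dropped.  Each R pairs at most once.
    """
    r_indices = np.asarray([b.r for b in ecg_beats])
    used: set[int] = set()
    pairs: list[BeatPair] = []
    for pb in ppg_beats:
        k = int(np.searchsorted(r_indices, pb.dp)) - 1
        if k < 0 or k in used:
            continue
        used.add(k)
        pairs.append(BeatPair(ecg=ecg_beats[k], ppg=pb, pair_id=len(pairs)))
    return pairs


def compute_beat_features(
    pair: BeatPair, fs: float, next_pair: Optional[BeatPair] = None
) -> dict[str, float]:
    """The 32 interval features of one beat pair, in seconds.

    ``next_pair`` supplies the following beat for the inter-beat
    intervals ``Trr``, ``Tbb`` and ``Taa``; they are null without it.
    Any feature touching a null fiducial is null.
    """
    if not fs > 0:
        raise ValueError("fs must be positive")
    e, p = pair.ecg, pair.ppg
    out: dict[str, float] = dict.fromkeys(FEATURE_NAMES, np.nan)

    out["Tqrs"] = (e.qrs_off - e.qrs_on) / fs
    out["Tpr"] = (e.r - e.p) / fs
    out["Tst"] = (e.t - e.s) / fs
    out["Tpt"] = (e.t - e.p) / fs
    out["Tab"] = (p.eb - p.dp) / fs
    out["Tn2b"] = (p.eb - p.sp) / fs
    out["Tn2a"] = (p.dp - p.sp) / fs
    if p.dn is not None:
        out["Tn1b"] = (p.eb - p.dn) / fs
        out["Tn2n1"] = (p.dn - p.sp) / fs
    if next_pair is not None:
        out["Trr"] = (next_pair.ecg.r - e.r) / fs
        out["Tbb"] = (next_pair.ppg.eb - p.eb) / fs
        out["Taa"] = (next_pair.ppg.dp - p.dp) / fs

    ppg_targets = {"A": p.dp, "B": p.eb, "N1": p.dn, "N2": p.sp}
    for i in "PQRST":
        ecg_idx = getattr(e, i.lower())
        for suffix, ppg_idx in ppg_targets.items():
            if ppg_idx is not None:
                out[f"T_{i}{suffix}"] = (ppg_idx - ecg_idx) / fs
    return out


def feature_matrix(pairs: Sequence[BeatPair], fs: float) -> pd.DataFrame:
    """Per-beat feature table: one row per pair, the 32 canonical columns."""
    rows = [
        compute_beat_features(
            pair, fs, pairs[k + 1] if k + 1 < len(pairs) else None
        )
        for k, pair in enumerate(pairs)
    ]
    return pd.DataFrame(rows, columns=list(FEATURE_NAMES))


def robust_mean(values: np.ndarray | Sequence[float]) -> float:
    """Mean after dropping values outside ``[mean - SD, mean + SD]``.

    SD uses the sample (n-1) convention; with a single value or zero
    variance the plain mean is returned.  All-null input yields NaN.
    The filter is idempotent on its own output in the sense that a
    single surviving mean passes through unchanged.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        return float("nan")
    if arr.size == 1:
        return float(arr[0])
    m = arr.mean()
    s = arr.std(ddof=1)
    if s == 0:
        return float(m)
    kept = arr[(arr >= m - s) & (arr <= m + s)]
    if kept.size == 0:  # cannot happen for s > 0, but stay safe
        return float(m)
    return float(kept.mean())


def aggregate_segment(
    ecg: SignalStream,
    ppg: SignalStream,
    policy: WindowPolicy | None = None,
    ppg_policy: WindowPolicy | None = None,
    settle_samples: int = SETTLE_SAMPLES,
    segment_samples: int = SEGMENT_SAMPLES,
    min_pairs: int = 20,
) -> FeatureVector:
    """One robust feature vector from a concurrent recording segment.

    The first ``settle_samples`` are discarded (sensor settling), the
    next ``segment_samples`` (~one minute) are delineated on both
    channels, beats are paired, and each feature column is aggregated
    with :func:`robust_mean`.  Rejects segments shorter than
    ``settle + segment`` samples or with fewer than ``min_pairs`` pairs.
    """
    if ecg.fs != ppg.fs:
        raise SegmentRejected(
            f"channel rates differ ({ecg.fs} vs {ppg.fs}); resample first"
        )
    needed = settle_samples + segment_samples
    if len(ecg) < needed or len(ppg) < needed:
        raise SegmentRejected(
            f"recording too short: need {needed} samples at {ecg.fs} Hz, "
            f"have {min(len(ecg), len(ppg))}"
        )
    fs = ecg.fs
    seg_ecg = SignalStream(
        ecg.samples[settle_samples : settle_samples + segment_samples],
        fs,
        "ecg",
        ecg.t0 + settle_samples / fs,
    )
    seg_ppg = SignalStream(
        ppg.samples[settle_samples : settle_samples + segment_samples],
        fs,
        "ppg",
        ppg.t0 + settle_samples / fs,
    )
    ecg_beats = detect_ecg_stream(seg_ecg, policy or WindowPolicy())
    ppg_beats = detect_ppg_stream(seg_ppg, ppg_policy or default_ppg_policy())
    pairs = pair_beats(ecg_beats, ppg_beats)
    if len(pairs) < min_pairs:
        raise SegmentRejected(
            f"only {len(pairs)} beat pairs (need >= {min_pairs})"
        )
    table = feature_matrix(pairs, fs)
    values = {name: robust_mean(table[name].to_numpy()) for name in FEATURE_NAMES}
    counts = {name: int(table[name].notna().sum()) for name in FEATURE_NAMES}
    return FeatureVector(values=values, counts=counts, n_pairs=len(pairs))
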