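"""Haar wavelet machinery shared by the ECG and PPG detectors.

The detectors work on short signal windows at a common working rate of
1200 samples/s.  Within a window they use

* a multilevel orthonormal Haar DWT (levels 1..5),
* modulus-maxima analysis of the level-1 detail coefficients to locate
  singularities, and
* a fixed left-edge-of-support convention to map coefficient indices back
  to signal indices.

Windows shorter than :data:`WTMM_MIN_SAMPLES` are rejected before any
modulus-maxima call; the cascade halves the sample count at each of the
five levels, so 128 samples guarantee at least four level-5 coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pywt

__all__ = [
    "WORKING_FS",
    "WTMM_MIN_SAMPLES",
    "SignalStream",
    "SignalWindow",
    "DwtLevels",
    "MaximaSet",
    "haar_dwt",
    "coeff_to_signal_index",
    "signal_to_coeff_index",
    "modulus_maxima",
    "resample_to",
]

#: Common working sampling rate (Hz) both channels are interpolated to.
WORKING_FS = 1200.0

#: Minimum window length for wavelet-transform modulus-maxima analysis.
WTMM_MIN_SAMPLES = 128

MAX_LEVEL = 5


@dataclass
class SignalStream:
    """A uniformly sampled physiological waveform.

    Parameters
    ----------
    samples : ndarray
        Amplitude values in arbitrary units (detection is invariant under
        scaling and DC offset).
    fs : float
        Sampling rate in Hz, > 0.
    kind : str
        Channel kind, ``"ecg"`` or ``"ppg"``.
    t0 : float
        Start time in seconds; sample ``i`` sits at ``t0 + i / fs``.
    """

    samples: np.ndarray
    fs: float
    kind: str = "ecg"
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.kind not in ("ecg", "ppg"):
            raise ValueError(f"kind must be 'ecg' or 'ppg', got {self.kind!r}")

    def __len__(self) -> int:
        return self.samples.size

    def time_of(self, index: int | np.ndarray) -> float | np.ndarray:
        """Time in seconds of a 0-based sample index."""
        return self.t0 + np.asarray(index) / self.fs


@dataclass
class SignalWindow:
    """A contiguous view ``[start, start + size)`` into a parent stream."""

    parent: SignalStream
    start: int
    size: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError("window start must be >= 0")
        if self.size < 1:
            raise ValueError("window size must be >= 1")
        if self.start + self.size > len(self.parent):
            raise ValueError(
                f"window [{self.start}, {self.start + self.size}) exceeds "
                f"stream length {len(self.parent)}"
            )

    @property
    def samples(self) -> np.ndarray:
        return self.parent.samples[self.start : self.start + self.size]

    def to_stream_index(self, local: int) -> int:
        return self.start + int(local)


@dataclass
class DwtLevels:
    """Per-level Haar coefficients up to ``level``.

    ``cA[l - 1]`` / ``cD[l - 1]`` hold the approximation / detail
    coefficients of level ``l``; each level halves the (edge-padded)
    length of the previous one.
    """

    level: int
    cA: list[np.ndarray] = field(default_factory=list)
    cD: list[np.ndarray] = field(default_factory=list)

    def approx(self, level: int) -> np.ndarray:
        return self.cA[level - 1]

    def detail(self, level: int) -> np.ndarray:
        return self.cD[level - 1]


@dataclass
class MaximaSet:
    """Signal-coordinate locations of level-1 detail modulus maxima."""

    indices: np.ndarray
    threshold_frac: float

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)

    def __len__(self) -> int:
        return self.indices.size

    def count_before(self, index: int) -> int:
        return int(np.sum(self.indices < index))

    def count_after(self, index: int) -> int:
        return int(np.sum(self.indices > index))


def haar_dwt(window: SignalWindow | np.ndarray, max_level: int) -> DwtLevels:
    """Multilevel orthonormal Haar DWT of a window.

    Uses the orthonormal filters ``cA_k = (x_{2k} + x_{2k+1}) / sqrt(2)``,
    ``cD_k = (x_{2k} - x_{2k+1}) / sqrt(2)``.  Odd-length inputs are padded
    on the right with their last sample at each level, which never creates
    an artificial detail maximum at the edge.

    Parameters
    ----------
    window : SignalWindow or ndarray
        Samples to decompose.
    max_level : int
        Deepest level, 1..5; the window must hold at least ``2**max_level``
        samples.
    """
    x = window.samples if isinstance(window, SignalWindow) else np.asarray(window, float)
    if not 1 <= max_level <= MAX_LEVEL:
        raise ValueError(f"max_level must be in 1..{MAX_LEVEL}, got {max_level}")
    if x.size < 2**max_level:
        raise ValueError(
            f"window of {x.size} samples is too short for a level-{max_level} "
            f"transform (needs >= {2 ** max_level})"
        )
    out = DwtLevels(level=max_level)
    approx = x.astype(float)
    for _ in range(max_level):
        # pywt 'constant' mode replicates the edge sample, so an odd-length
        # level is effectively right-padded with its last value.
        cA, cD = pywt.dwt(approx, "haar", mode="constant")
        out.cA.append(cA)
        out.cD.append(cD)
        approx = cA
    return out


def coeff_to_signal_index(level: int, k: int | np.ndarray) -> int | np.ndarray:
    """Left edge of the support of coefficient ``k`` at ``level``: ``k * 2**level``."""
    if not 1 <= level <= MAX_LEVEL:
        raise ValueError(f"level must be in 1..{MAX_LEVEL}")
    k_arr = np.asarray(k)
    if np.any(k_arr < 0):
        raise ValueError("coefficient index must be >= 0")
    result = k_arr * (1 << level)
    return int(result) if np.isscalar(k) or result.ndim == 0 else result


def signal_to_coeff_index(level: int, i: int | np.ndarray) -> int | np.ndarray:
    """Inverse of :func:`coeff_to_signal_index`: ``floor(i / 2**level)``."""
    if not 1 <= level <= MAX_LEVEL:
        raise ValueError(f"level must be in 1..{MAX_LEVEL}")
    i_arr = np.asarray(i)
    if np.any(i_arr < 0):
        raise ValueError("signal index must be >= 0")
    result = i_arr // (1 << level)
    return int(result) if np.isscalar(i) or result.ndim == 0 else result


def _plateau_local_maxima(m: np.ndarray) -> np.ndarray:
    """Strict local maxima of ``m``, keeping the leftmost sample of plateaus.

    A plateau is a maximal run of equal values (up to a relative
    floating-point tolerance); it counts as one maximum when the values
    immediately before and after the run are both strictly smaller.
    Runs touching either array edge are excluded.
    """
    n = m.size
    if n < 3:
        return np.empty(0, dtype=int)
    tol = 1e-12 * m.max()
    diff = np.diff(m)
    # run-length encode, treating near-equal values as a plateau
    change = np.flatnonzero(np.abs(diff) > tol)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change, [n - 1]))  # inclusive
    keep = []
    for s, e in zip(starts, ends):
        if s == 0 or e == n - 1:
            continue
        if m[s] > m[s - 1] + tol and m[e] > m[e + 1] + tol:
            keep.append(s)
    return np.asarray(keep, dtype=int)


def modulus_maxima(
    window: SignalWindow | np.ndarray,
    threshold_frac: float = 0.05,
    min_separation: int = 18,
) -> MaximaSet:
    """Locate singularities as maxima of the level-1 detail modulus.

    Returns signal-coordinate indices where ``|cD_l1|`` is a strict local
    maximum (leftmost sample of any plateau) and at least ``threshold_frac``
    times the global maximum modulus.  The threshold is relative, so the
    result is invariant under amplitude scaling of the window.

    ``min_separation`` (signal samples) applies non-maximum suppression:
    of any two candidates closer than this, only the larger modulus
    survives.  Streams interpolated up from a coarser acquisition rate
    are piecewise linear and carry a slope kink at every native sample;
    the default radius of 18 samples covers the widest native spacing at
    the 1200 samples/s working rate (16 samples for 75 Hz PPG), so only
    one maximum per genuine singularity remains.
    """
    x = window.samples if isinstance(window, SignalWindow) else np.asarray(window, float)
    if x.size < WTMM_MIN_SAMPLES:
        raise ValueError(
            f"modulus maxima require at least {WTMM_MIN_SAMPLES} samples, "
            f"got {x.size}"
        )
    if not 0 <= threshold_frac <= 1:
        raise ValueError("threshold_frac must be in [0, 1]")
    cD1 = haar_dwt(x, 1).detail(1)
    m = np.abs(cD1)
    peak = m.max()
    if peak == 0:
        return MaximaSet(np.empty(0, dtype=int), threshold_frac)
    cand = _plateau_local_maxima(m)
    cand = cand[m[cand] >= threshold_frac * peak]
    if min_separation > 1 and cand.size > 1:
        # greedy suppression, tallest first; ties keep the leftmost
        order = np.lexsort((cand, -m[cand]))
        sep_coeff = min_separation / 2.0  # coefficient-domain distance
        kept: list[int] = []
        for j in order:
            if all(abs(cand[j] - k) >= sep_coeff for k in kept):
                kept.append(int(cand[j]))
        cand = np.sort(np.asarray(kept, dtype=int))
    return MaximaSet(coeff_to_signal_index(1, cand), threshold_frac)


def resample_to(stream: SignalStream, fs_target: float) -> SignalStream:
    """Linearly interpolate a stream onto a uniform ``fs_target`` grid.

    The new grid spans the same time interval ``[t0, t0 + (n-1)/fs]``; the
    length scales by ``fs_target / fs`` (200 -> 1200 Hz is the factor-6
    interpolation of the ECG channel, 75 -> 1200 Hz factor 16 for PPG).
    Downsampling is rejected.
    """
    if fs_target < stream.fs * (1.0 - 1e-6):
        raise ValueError(
            f"downsampling ({stream.fs} -> {fs_target} Hz) is not supported"
        )
    if abs(fs_target - stream.fs) <= 1e-6 * stream.fs:
        # same rate up to timestamp rounding noise
        return SignalStream(stream.samples.copy(), fs_target, stream.kind, stream.t0)
    n = len(stream)
    duration = (n - 1) / stream.fs
    n_new = int(round(duration * fs_target)) + 1
    t_old = np.arange(n) / stream.fs
    t_new = np.arange(n_new) / fs_target
    samples = np.interp(t_new, t_old, stream.samples)
    return SignalStream(samples, fs_target, stream.kind, stream.t0)
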