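"""Beat-by-beat ECG delineation (P, Q, R, S, T, QRS onset/offset).

A single beat is delineated inside a window holding one complete cardiac
cycle:

1. level-3 Haar detail coefficients bracket the QRS complex — their
   minimum and maximum (``t1``/``t2``) flank the steep QRS slopes and the
   R peak is the raw maximum between them;
2. modulus maxima of the window give the singularities ``t3`` (last
   before ``t1``) and ``t4`` (first after ``t2``) that bound the Q and S
   search ranges;
3. QRS onset/offset are where the smoothed first difference falls below
   an adaptive threshold when scanning outward from Q and S;
4. level-5 detail coefficients, restricted to the pre-onset and
   post-offset segments, bracket the low-frequency P and T waves, whose
   apices are raw maxima between the coefficient extrema.

For continuous streams the window is re-sized every beat from the local
R-R interval (adaptive mode, AWWT) or held at a fixed 1100 samples
(FWWT); a window only counts as a beat when the R peak sits near its
centre and enough modulus-maxima points surround it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .wavelet_core import (
    MaximaSet,
    SignalStream,
    SignalWindow,
    WTMM_MIN_SAMPLES,
    coeff_to_signal_index,
    haar_dwt,
    modulus_maxima,
)

__all__ = [
    "EcgFiducials",
    "WindowPolicy",
    "BeatRejected",
    "estimate_ecg_window_size",
    "detect_ecg_beat",
    "check_ecg_window",
    "detect_ecg_stream",
    "ecg_annotations",
]

logger = logging.getLogger(__name__)

ECG_FIDUCIAL_NAMES = ("p", "q", "r", "s", "t", "qrs_on", "qrs_off")


class BeatRejected(ValueError):
    """A delineation sub-step found an empty or degenerate search range."""

    def __init__(self, step: str, message: str = ""):
        self.step = step
        super().__init__(f"{step}: {message}" if message else step)


@dataclass
class EcgFiducials:
    """Per-beat ECG wave point indices (0-based stream coordinates).

    Satisfies ``qrs_on < q < r < s < qrs_off``, ``p < qrs_on`` and
    ``t > qrs_off``.
    """

    p: int
    q: int
    r: int
    s: int
    t: int
    qrs_on: int
    qrs_off: int
    beat_id: int = 0

    def __post_init__(self) -> None:
        if not (self.qrs_on < self.q < self.r < self.s < self.qrs_off):
            raise ValueError(
                "QRS ordering violated: "
                f"on={self.qrs_on} q={self.q} r={self.r} s={self.s} off={self.qrs_off}"
            )
        if not self.p < self.qrs_on:
            raise ValueError(f"p={self.p} must precede qrs_on={self.qrs_on}")
        if not self.t > self.qrs_off:
            raise ValueError(f"t={self.t} must follow qrs_off={self.qrs_off}")

    def shifted(self, offset: int, beat_id: int | None = None) -> "EcgFiducials":
        """Translate window-local indices into stream coordinates."""
        return EcgFiducials(
            p=self.p + offset,
            q=self.q + offset,
            r=self.r + offset,
            s=self.s + offset,
            t=self.t + offset,
            qrs_on=self.qrs_on + offset,
            qrs_off=self.qrs_off + offset,
            beat_id=self.beat_id if beat_id is None else beat_id,
        )


@dataclass
class WindowPolicy:
    """Windowing and validity parameters for beat detection.

    Parameters
    ----------
    mode : str
        ``"awwt"`` re-estimates the window size from the local beat
        period before every beat; ``"fwwt"`` always uses ``fwwt_size``.
    slide_step : int
        Samples the window slides forward after a failed validity check.
    vicinity_frac : float
        The anchor peak (R for ECG, EB for PPG) must lie within this
        fraction of the window size from the window centre.
    min_mmt_before, min_mmt_after : int
        Minimum counts of modulus-maxima points required strictly before
        and after the anchor peak (ECG needs > 2 on each side, i.e. 3).
    fwwt_size : int
        Fixed window size, also the fallback when the adaptive estimate
        finds fewer than two peaks.
    buffer_frac : float
        Safety margin added to the adaptive beat-period estimate.
    threshold_frac : float
        Relative modulus-maxima floor (fraction of the global maximum).
    qrs_theta_frac : float
        QRS boundary threshold as a fraction of the maximum smoothed
        first difference within the window (theta1 = theta2).
    smooth_width : int
        Moving-average width (samples) applied before differencing for
        the QRS boundary scan; odd.
    peak_height_frac, refractory, est_block : float, int, int
        Amplitude threshold (fraction of block max, mean removed),
        minimum peak separation and block length used when estimating
        the beat period for the adaptive window.
    """

    mode: str = "awwt"
    slide_step: int = 10
    vicinity_frac: float = 0.10
    min_mmt_before: int = 3
    min_mmt_after: int = 3
    fwwt_size: int = 1100
    buffer_frac: float = 0.25
    threshold_frac: float = 0.05
    mmt_separation: int = 18
    qrs_theta_frac: float = 0.05
    smooth_width: int = 9
    peak_height_frac: float = 0.6
    refractory: int = 240
    est_block: int = 2400

    def __post_init__(self) -> None:
        if self.mode not in ("awwt", "fwwt"):
            raise ValueError(f"mode must be 'awwt' or 'fwwt', got {self.mode!r}")
        if self.slide_step < 1:
            raise ValueError("slide_step must be >= 1")
        if not 0 < self.vicinity_frac < 0.5:
            raise ValueError("vicinity_frac must be in (0, 0.5)")


def _refine_extremum(
    x: np.ndarray,
    lo: int,
    hi: int,
    find_max: bool,
    smooth_width: int = 0,
    fit_half: int = 24,
) -> int:
    """Arg-extremum of ``x[lo:hi)`` robust to sampling noise.

    Optionally smooths with an edge-safe moving average before the
    coarse search, then refines with a least-squares parabola vertex
    fitted to the raw samples within ``fit_half`` of the coarse
    extremum.  Falls back to the coarse index when the fit has the
    wrong curvature or its vertex leaves the fitted span.
    """
    if hi - lo < 1:
        raise BeatRejected("refine", "empty search range")
    if smooth_width > 1:
        pad = smooth_width
        s_lo, s_hi = max(0, lo - pad), min(x.size, hi + pad)
        kernel = np.ones(smooth_width) / smooth_width
        sm = np.convolve(x[s_lo:s_hi], kernel, mode="same")
        seg = sm[lo - s_lo : hi - s_lo]
    else:
        seg = x[lo:hi]
    i0 = lo + int(np.argmax(seg) if find_max else np.argmin(seg))
    a, b = max(lo, i0 - fit_half), min(hi, i0 + fit_half + 1)
    if b - a >= 5:
        tt = np.arange(a, b, dtype=float)
        c2, c1, _ = np.polyfit(tt, x[a:b], 2)
        if c2 != 0 and (c2 < 0) == find_max:
            v = -c1 / (2.0 * c2)
            if a <= v <= b - 1:
                return int(round(np.clip(v, lo, hi - 1)))
    return i0


def _smoothed_diff(x: np.ndarray, width: int) -> np.ndarray:
    """First difference of a moving-average smoothed copy of ``x``."""
    if width > 1:
        kernel = np.ones(width) / width
        xs = np.convolve(x, kernel, mode="same")
    else:
        xs = x
    return np.diff(xs)


def _qrs_bound_scan(
    dx: np.ndarray,
    start: int,
    theta: float,
    step: int,
    max_skip: int = 60,
    hold: int = 5,
) -> Optional[int]:
    """QRS boundary index scanning outward from Q (step=-1) or S (step=+1).

    The slope at the Q/S trough itself is near zero, so the scan first
    leaves the trough (sub-threshold run, bounded by ``max_skip``), then
    crosses the Q/S limb (supra-threshold run) and stops at the first
    point where the smoothed |first difference| stays below ``theta``
    for ``hold`` consecutive samples — a momentary dip at the limb foot
    does not count as the boundary.  Returns the boundary index into
    ``dx``'s parent signal, or ``None`` when the scan exhausts the array.
    """
    sub = np.abs(dx) < theta

    def _sustained(i: int) -> bool:
        if step > 0:
            return bool(np.all(sub[i : min(i + hold, sub.size)]))
        return bool(np.all(sub[max(i - hold + 1, 0) : i + 1]))

    i = start
    skipped = 0
    while 0 <= i < dx.size and sub[i] and skipped < max_skip:
        i += step
        skipped += 1
    while 0 <= i < dx.size and not (sub[i] and _sustained(i)):
        i += step
    if not 0 <= i < dx.size:
        return None
    # dx[i] = x[i+1] - x[i]; report the sample on the outward side
    return i if step < 0 else i + 1


def estimate_ecg_window_size(
    stream: SignalStream,
    at: int,
    policy: WindowPolicy | None = None,
    fallback: int | None = None,
) -> int:
    """Adaptive window size from the local R-R interval.

    R peaks inside the ``est_block``-sample block starting at ``at`` are
    found by amplitude thresholding of the mean-removed block; the window
    size is the median adjacent R-R distance grown by ``buffer_frac``.
    With fewer than two peaks (e.g. a flat block) the fixed ``fwwt_size``
    is returned as fallback.
    """
    policy = policy or WindowPolicy()
    if fallback is None:
        fallback = policy.fwwt_size
    block = stream.samples[at : at + policy.est_block]
    if block.size < policy.est_block:
        raise ValueError(
            f"need {policy.est_block} samples at index {at}, have {block.size}"
        )
    xm = block - block.mean()
    top = xm.max()
    if top <= 0:
        return fallback
    peaks, _ = find_peaks(
        xm, height=policy.peak_height_frac * top, distance=policy.refractory
    )
    if peaks.size < 2:
        return fallback
    rr = float(np.median(np.diff(peaks)))
    return int(round(rr * (1.0 + policy.buffer_frac)))


def _band_extrema_bracket(
    cd: np.ndarray, level: int, lo: int, hi: int, size: int
) -> tuple[int, int]:
    """Signal-coordinate interval spanned by the extrema of ``cd`` whose
    left-edge support falls in ``[lo, hi)``; ``(a, b)`` with ``a < b``."""
    k_lo = max(0, (lo + (1 << level) - 1) >> level)
    k_hi = min(cd.size, hi >> level)
    if k_hi - k_lo < 2:
        raise BeatRejected("band_extrema", f"segment [{lo}, {hi}) too short")
    seg = cd[k_lo:k_hi]
    k1 = k_lo + int(np.argmin(seg))
    k2 = k_lo + int(np.argmax(seg))
    a, b = sorted(
        (coeff_to_signal_index(level, k1), coeff_to_signal_index(level, k2))
    )
    if a == b:
        raise BeatRejected("band_extrema", "coefficient extrema coincide")
    # include the support of the right coefficient, clipped to the segment
    return a, min(b + (1 << level), hi, size)


def _delineate(
    window: SignalWindow, policy: WindowPolicy
) -> tuple[EcgFiducials, MaximaSet]:
    x = window.samples
    size = x.size
    if size < WTMM_MIN_SAMPLES:
        raise BeatRejected("precondition", f"window of {size} < {WTMM_MIN_SAMPLES}")

    levels = haar_dwt(x, 5)
    cd3 = levels.detail(3)
    if np.ptp(cd3) == 0:
        raise BeatRejected("t1t2", "level-3 detail is constant")
    t1, t2 = sorted(
        (
            coeff_to_signal_index(3, int(np.argmin(cd3))),
            coeff_to_signal_index(3, int(np.argmax(cd3))),
        )
    )
    if t2 <= t1:
        raise BeatRejected("t1t2", "degenerate bracket")

    r = t1 + int(np.argmax(x[t1 : min(t2 + 1, size)]))

    maxima = modulus_maxima(x, policy.threshold_frac, policy.mmt_separation)
    # the QRS slopes themselves carry modulus maxima that can land a few
    # samples outside the (level-3 quantised) t1/t2 bracket; keep one
    # level-3 support of clearance so t3/t4 bound the Q and S searches
    # from the neighbouring waves, not from the R upstroke/downstroke
    guard = 1 << 3
    before = maxima.indices[maxima.indices < t1 - guard]
    after = maxima.indices[maxima.indices > t2 + guard]
    if before.size == 0:
        raise BeatRejected("t3", "no modulus maximum before t1")
    if after.size == 0:
        raise BeatRejected("t4", "no modulus maximum after t2")
    t3 = int(before[-1])
    t4 = int(after[0])

    if t3 >= r:
        raise BeatRejected("q", "empty [t3, R) range")
    q = t3 + int(np.argmin(x[t3:r]))
    if r + 1 > t4:
        raise BeatRejected("s", "empty (R, t4] range")
    s = r + 1 + int(np.argmin(x[r + 1 : min(t4 + 1, size)]))

    dx = _smoothed_diff(x, policy.smooth_width)
    theta = policy.qrs_theta_frac * np.abs(dx).max()
    qrs_on = _qrs_bound_scan(dx, q - 1, theta, step=-1)
    if qrs_on is None or qrs_on < 1 or qrs_on >= q:
        raise BeatRejected("qrs_onset", "no sub-threshold slope before Q")
    qrs_off = _qrs_bound_scan(dx, s, theta, step=+1)
    if qrs_off is None or qrs_off >= size - 1 or qrs_off <= s:
        raise BeatRejected("qrs_offset", "no sub-threshold slope after S")

    cd5 = levels.detail(5)
    # the P wave sits within ~0.3 window of the QRS onset; bounding the
    # search keeps the previous beat's T wave (possibly overlapping the
    # window start) out of the P bracket
    p_lo = max(0, qrs_on - int(0.3 * size))
    a, b = _band_extrema_bracket(cd5, 5, p_lo, qrs_on, size)
    p = _refine_extremum(x, a, b, find_max=True)
    if p >= qrs_on:
        raise BeatRejected("p", "P search collapsed into QRS onset")
    a, b = _band_extrema_bracket(cd5, 5, qrs_off + 1, size, size)
    t = _refine_extremum(x, a, b, find_max=True)
    if t <= qrs_off:
        raise BeatRejected("t", "T search collapsed into QRS offset")

    try:
        fid = EcgFiducials(p=p, q=q, r=r, s=s, t=t, qrs_on=qrs_on, qrs_off=qrs_off)
    except ValueError as exc:
        raise BeatRejected("ordering", str(exc)) from exc
    return fid, maxima


def detect_ecg_beat(
    window: SignalWindow, policy: WindowPolicy | None = None
) -> EcgFiducials:
    """Delineate the single beat contained in ``window``.

    Returns window-local indices; raises :class:`BeatRejected` naming the
    failing sub-step when any search range is empty or degenerate.
    """
    fid, _ = _delineate(window, policy or WindowPolicy())
    return fid


def check_ecg_window(
    window: SignalWindow,
    r: int | None,
    maxima: MaximaSet,
    policy: WindowPolicy | None = None,
) -> tuple[bool, str]:
    """Window validity predicate for one complete ECG cycle.

    Valid iff (i) an R peak was detected, (ii) R lies within
    ``vicinity_frac`` of the window size from the centre, and (iii) more
    than two modulus-maxima points lie on each side of R (guaranteeing a
    P and a T wave inside the window).
    """
    policy = policy or WindowPolicy()
    if r is None:
        return False, "no R peak"
    size = window.size
    if abs(r - size / 2) > policy.vicinity_frac * size:
        return False, "vicinity"
    if maxima.count_before(r) < policy.min_mmt_before:
        return False, "MMT before"
    if maxima.count_after(r) < policy.min_mmt_after:
        return False, "MMT after"
    return True, "ok"


def _window_size_at(
    stream: SignalStream, pos: int, policy: WindowPolicy, fallback: int | None = None
) -> int:
    """Window size at ``pos``: adaptive estimate, or ``fallback`` (the last
    successful adaptive size, else ``fwwt_size``) when none is available."""
    fallback = fallback or policy.fwwt_size
    if policy.mode == "fwwt":
        return policy.fwwt_size
    if pos + policy.est_block <= len(stream):
        est = estimate_ecg_window_size(stream, pos, policy, fallback=0)
        if est > 0:
            return max(est, WTMM_MIN_SAMPLES)
    return fallback


def detect_ecg_stream(
    stream: SignalStream, policy: WindowPolicy | None = None
) -> list[EcgFiducials]:
    """Delineate every beat of a continuous ECG stream at 1200 samples/s.

    The window is sized per beat (AWWT) or fixed (FWWT), slid forward by
    ``slide_step`` until the validity conditions hold, and the next beat
    search starts from the current beat's T wave.  Beats are emitted in
    strictly increasing R order; a flat or beat-free stream yields an
    empty list.
    """
    policy = policy or WindowPolicy()
    n = len(stream)
    out: list[EcgFiducials] = []
    pos = 0
    last_size: int | None = None
    while True:
        size = _window_size_at(stream, pos, policy, fallback=last_size)
        if pos + size > n:
            break
        budget = max(1, int(2 * size / policy.slide_step))
        found: Optional[EcgFiducials] = None
        tries = 0
        floor = pos
        snaps = 0
        while tries <= budget and pos + size <= n:
            window = SignalWindow(stream, pos, size)
            try:
                fid, maxima = _delineate(window, policy)
                ok, reason = check_ecg_window(window, fid.r, maxima, policy)
            except BeatRejected:
                ok = False
                fid = None
                reason = "rejected"
            if ok and fid is not None:
                found = fid
                break
            tries += 1
            new_pos = pos + policy.slide_step
            if fid is not None and reason == "vicinity" and snaps < 3:
                # re-centre the window on the detected R: forward sliding
                # alone cannot recover an R left of the centre
                snap_pos = max(floor, pos + fid.r - size // 2)
                if snap_pos != pos:
                    snaps += 1
                    new_pos = snap_pos
            pos = new_pos
            if policy.mode == "awwt":
                size = _window_size_at(stream, pos, policy, fallback=last_size)
        if found is None:
            logger.debug("ECG retry budget exhausted at %d; skipping a window", pos)
            pos += size
            continue
        fid_global = found.shifted(pos, beat_id=len(out))
        if out and fid_global.r <= out[-1].r:
            pos += policy.slide_step
            continue
        out.append(fid_global)
        last_size = size
        # resume just past the T apex; the bounded P search keeps the
        # remaining T limb out of the next beat's P bracket
        pos = max(pos + found.t + policy.slide_step, pos + 1)
    return out


def ecg_annotations(
    beats: list[EcgFiducials], stream: SignalStream
) -> pd.DataFrame:
    """Tabular per-beat annotation (indices and times) for CSV export."""
    rows = []
    for b in beats:
        row: dict[str, float] = {"beat_id": b.beat_id}
        for name in ECG_FIDUCIAL_NAMES:
            idx = getattr(b, name)
            row[name] = idx
            row[f"{name}_time_s"] = float(stream.time_of(idx))
        rows.append(row)
    return pd.DataFrame(rows, columns=["beat_id"] + [c for n in ECG_FIDUCIAL_NAMES for c in (n, f"{n}_time_s")])
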