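"""Beat-by-beat PPG delineation (SP, DN, DP, EB).

The detector operates on transmission-intensity PPG, in which systole
absorbs more light: each pulse is a deep trough (systolic point, SP)
followed by the dicrotic notch (DN, a small crest), a shallower
diastolic trough (DP) and the end-of-beat crest (EB), the window's
amplitude maximum.  Conventional volume-oriented PPG is handled by
inverting it on load (:func:`to_intensity`).

Per window:

1. the level-3 detail coefficients (a coarse negated slope) show the
   pulse as a strong rise followed, one period later, by the strong
   fall into the next trough; EB is the raw maximum inside the
   first-rise-to-last-fall bracket;
2. the diastolic trough DP is found from the level-5 detail
   coefficients as the slope zero-crossing reached by walking left
   from the rise toward EB, refined to the local raw minimum;
3. SP is the raw minimum before DP;
4. DN requires a modulus-maxima point (the notch's slope singularity)
   near the SP-DP midpoint and is the interval's interior crest; a
   beat without a locatable crest carries a null DN and downstream DN
   features are skipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .fiducial_ecg import (
    BeatRejected,
    WindowPolicy,
    _refine_extremum,
    _smoothed_diff,
)
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
    "PpgFiducials",
    "native_parabola_refine",
    "locate_dicrotic_crest",
    "default_ppg_policy",
    "to_intensity",
    "detect_ppg_beat",
    "check_ppg_window",
    "estimate_ppg_window_size",
    "detect_ppg_stream",
    "ppg_annotations",
]

logger = logging.getLogger(__name__)

PPG_FIDUCIAL_NAMES = ("sp", "dn", "dp", "eb")


@dataclass
class PpgFiducials:
    """Per-beat PPG wave point indices (0-based stream coordinates).

    ``sp < dn < dp < eb``; ``dn`` may be ``None`` when no dicrotic crest
    could be located, in which case DN-dependent features are skipped.
    """

    sp: int
    dn: Optional[int]
    dp: int
    eb: int
    beat_id: int = 0

    def __post_init__(self) -> None:
        if not self.sp < self.dp < self.eb:
            raise ValueError(
                f"ordering violated: sp={self.sp} dp={self.dp} eb={self.eb}"
            )
        if self.dn is not None and not self.sp < self.dn < self.dp:
            raise ValueError(
                f"dn={self.dn} must lie strictly between sp={self.sp} and dp={self.dp}"
            )

    def shifted(self, offset: int, beat_id: int | None = None) -> "PpgFiducials":
        return PpgFiducials(
            sp=self.sp + offset,
            dn=None if self.dn is None else self.dn + offset,
            dp=self.dp + offset,
            eb=self.eb + offset,
            beat_id=self.beat_id if beat_id is None else beat_id,
        )


def default_ppg_policy(**overrides) -> WindowPolicy:
    """Window policy with the PPG validity counts (> 3 maxima before EB,
    > 2 after) instead of the ECG ones."""
    params = dict(min_mmt_before=4, min_mmt_after=3)
    params.update(overrides)
    return WindowPolicy(**params)


def to_intensity(stream: SignalStream, orientation: str = "intensity") -> SignalStream:
    """Return the stream in transmission-intensity orientation.

    ``orientation`` describes the *input*: ``"intensity"`` passes through,
    ``"volume"`` (conventional pulse-volume PPG) is inverted so that
    systole becomes a trough.
    """
    if orientation == "intensity":
        return stream
    if orientation == "volume":
        return SignalStream(-stream.samples, stream.fs, stream.kind, stream.t0)
    raise ValueError(f"orientation must be 'intensity' or 'volume', got {orientation!r}")


def _find_dp(
    x: np.ndarray, cd5: np.ndarray, eb: int, smooth_width: int
) -> int:
    """Diastolic trough from the level-5 detail coefficients.

    ``cd5`` is proportional to the negated local slope.  Within the pulse
    (left of EB) the steepest rise toward EB is the most negative
    coefficient; scanning left from it, the first non-negative
    coefficient marks the slope zero-crossing at the diastolic trough,
    which is then refined to the raw minimum over that support.
    """
    k_eb = eb >> 5
    if k_eb < 2:
        raise BeatRejected("dp", "no coefficients before EB")
    pre = cd5[:k_eb]
    if pre.size >= 3:  # 3-tap average: halves coefficient noise
        pre = np.convolve(pre, np.ones(3) / 3.0, mode="same")
    amp = np.abs(pre).max()
    if amp == 0:
        raise BeatRejected("dp", "no rising segment before EB")
    # detail coefficients are a negated coarse slope: walk left from EB
    # into the rise toward it (coefficients clearly below -tau), then on
    # to the slope zero-crossing at the diastolic trough; the crossing
    # must clear +tau (hysteresis) so plateau noise does not stop the walk
    tau = 0.1 * amp
    k = k_eb - 1
    while k >= 0 and pre[k] >= -tau:
        k -= 1
    if k < 0:
        raise BeatRejected("dp", "no rising segment before EB")
    while k >= 0 and pre[k] < tau:
        k -= 1
    if k < 0:
        raise BeatRejected("dp", "no slope zero-crossing before EB")
    lo = max(0, coeff_to_signal_index(5, k) - 64)
    hi = min(coeff_to_signal_index(5, k + 2) + 32, eb)
    if hi <= lo:
        raise BeatRejected("dp", "empty refinement span")
    return _refine_extremum(
        x, lo, hi, find_max=False, smooth_width=smooth_width, fit_half=30
    )


def native_parabola_refine(
    x: np.ndarray, j: int, spacing: int = 16, find_max: bool = True
) -> int:
    """Sub-quantum refinement of an extremum of an interpolated stream.

    Streams interpolated up from a native rate are piecewise linear, so
    their local extrema snap to native sample vertices (every
    ``spacing`` working-rate samples).  A three-point parabola through
    the extremum vertex and its native neighbours recovers the
    continuous extremum location to within a working-rate sample,
    removing the native quantisation from interval features.
    """
    if j - spacing < 0 or j + spacing >= x.size:
        return j
    y_l, y_c, y_r = x[j - spacing], x[j], x[j + spacing]
    denom = y_l - 2.0 * y_c + y_r
    if denom == 0 or ((denom < 0) != find_max):
        return j
    delta = 0.5 * (y_l - y_r) / denom
    delta = float(np.clip(delta, -0.6, 0.6))
    return int(round(j + delta * spacing))


def locate_dicrotic_crest(
    x: np.ndarray,
    sp: int,
    dp: int,
    smooth_width: int = 9,
    range_ref: Optional[float] = None,
) -> Optional[int]:
    """The dicrotic crest between a systolic and a diastolic trough.

    Takes the raw maximum of the open interval — the notch is its unique
    crest — and accepts it only when it is interior and falls away on
    both sides by a visible fraction of the signal range (``range_ref``,
    default the peak-to-peak of ``x``): a prominence test that rejects
    the flat watershed left when the beat carries no dicrotic wave.
    Plain argmax: on clean signals it is exact, and a parabola vertex on
    the asymmetric crest would carry a morphology-dependent bias.
    """
    if dp - sp < 8:
        return None
    lo, hi = sp + 1, dp
    j = lo + int(np.argmax(x[lo:hi]))
    margin = max(4, (dp - sp) // 20)
    if j < lo + margin or j >= hi - margin:
        return None
    delta = max(8, int(0.15 * (dp - sp)))
    w = max(smooth_width, 9)
    pad = w
    s_lo, s_hi = max(0, lo - pad), min(x.size, hi + pad)
    sm = np.convolve(x[s_lo:s_hi], np.ones(w) / w, mode="same")
    off = j - s_lo
    left = sm[max(off - delta, lo - s_lo)]
    right = sm[min(off + delta, hi - 1 - s_lo)]
    drop = sm[off] - max(left, right)
    if range_ref is None:
        range_ref = float(np.ptp(x))
    if drop < 0.02 * range_ref:
        return None
    return native_parabola_refine(x, j, find_max=True)


def _find_dn(
    x: np.ndarray, maxima: MaximaSet, sp: int, dp: int, smooth_width: int
) -> Optional[int]:
    """Dicrotic notch: requires a modulus-maxima point — the notch's own
    slope singularity — near the SP-DP midpoint, then locates the crest.

    A beat without a dicrotic wave still carries modulus maxima between
    the troughs (the recovery and the pre-trough fall), but they hug the
    troughs; only a real notch puts one near the midpoint.
    """
    cand = maxima.indices[(maxima.indices > sp) & (maxima.indices < dp)]
    if cand.size == 0:
        return None
    mid = (sp + dp) / 2.0
    if np.min(np.abs(cand - mid)) > 0.2 * (dp - sp):
        return None
    return locate_dicrotic_crest(x, sp, dp, smooth_width)


def detect_ppg_beat(
    window: SignalWindow, policy: WindowPolicy | None = None
) -> PpgFiducials:
    """Delineate the single pulse contained in ``window``.

    Returns window-local indices; raises :class:`BeatRejected` naming the
    failing sub-step on degenerate input (e.g. a constant window).
    """
    policy = policy or default_ppg_policy()
    fid, _ = _delineate_ppg(window, policy)
    return fid


def _delineate_ppg(
    window: SignalWindow, policy: WindowPolicy
) -> tuple[PpgFiducials, MaximaSet]:
    x = window.samples
    size = x.size
    if size < WTMM_MIN_SAMPLES:
        raise BeatRejected("precondition", f"window of {size} < {WTMM_MIN_SAMPLES}")

    levels = haar_dwt(x, 5)
    cd3 = levels.detail(3)
    # average neighbouring coefficients against noise; wider windows
    # (slower rhythms) have proportionally wider slopes, so scale the tap
    # count with the window
    ntap = max(3, (size // 450) * 2 + 1)
    if cd3.size >= ntap:
        cd3 = np.convolve(cd3, np.ones(ntap) / ntap, mode="same")
    if np.ptp(cd3) == 0 or cd3.min() >= 0 or cd3.max() <= 0:
        raise BeatRejected("t1t2", "level-3 detail carries no full pulse")
    # detail coefficients are a negated coarse slope, so the pulse shows
    # up as a strong rise (recovery out of the systolic trough, cd3 << 0)
    # followed, one period later, by the strong fall into the next trough
    # (cd3 >> 0).  Bracket with the FIRST strong rise and the LAST strong
    # fall: that spans exactly one pulse even when the window covers two
    # near-identical systolic troughs whose global extrema would tie.
    strong_rise = np.flatnonzero(cd3 <= 0.6 * cd3.min())
    strong_fall = np.flatnonzero(cd3 >= 0.6 * cd3.max())
    t1 = coeff_to_signal_index(3, int(strong_rise[0]))
    t2 = coeff_to_signal_index(3, int(strong_fall[-1]))
    if t2 <= t1:
        raise BeatRejected("t1t2", "degenerate bracket")
    if t2 - t1 < size // 4:
        # both slopes flank the same systolic trough; the window does not
        # yet bracket one full pulse — slide on
        raise BeatRejected("t1t2", "bracket too narrow for a pulse")
    eb = _refine_extremum(
        x, t1, min(t2 + 1, size), find_max=True,
        smooth_width=policy.smooth_width, fit_half=30,
    )
    # EB must be a genuine crest, not the rising edge of a truncated
    # bracket; compare against a smoothed argmax so sampling noise in the
    # flat crest neighbourhood cannot spoof the check
    a, b = max(0, eb - 56), min(size, eb + 57)
    pad = 25
    s_lo, s_hi = max(0, a - pad), min(size, b + pad)
    sm = np.convolve(x[s_lo:s_hi], np.ones(pad) / pad, mode="same")
    j = a + int(np.argmax(sm[a - s_lo : b - s_lo]))
    if abs(j - eb) > 20:
        raise BeatRejected("eb", "bracket maximum is not a local crest")

    dp = _find_dp(x, levels.detail(5), eb, policy.smooth_width)
    if dp <= 0:
        raise BeatRejected("sp", "empty pre-DP range")
    # argmin plus native-grid refinement; a wide parabola fit would be
    # biased by the trough's asymmetry (steep drop, slow recovery)
    sp = native_parabola_refine(x, int(np.argmin(x[:dp])), find_max=False)

    maxima = modulus_maxima(x, policy.threshold_frac, policy.mmt_separation)
    dn = _find_dn(x, maxima, sp, dp, policy.smooth_width)

    try:
        fid = PpgFiducials(sp=sp, dn=dn, dp=dp, eb=eb)
    except ValueError as exc:
        raise BeatRejected("ordering", str(exc)) from exc
    return fid, maxima


def check_ppg_window(
    window: SignalWindow,
    eb: int | None,
    maxima: MaximaSet,
    policy: WindowPolicy | None = None,
) -> tuple[bool, str]:
    """Window validity for one complete PPG pulse.

    Valid iff (i) EB was detected, (ii) EB lies within ``vicinity_frac``
    of the window size from the centre, (iii) more than three
    modulus-maxima points precede EB (guaranteeing SP and DN) and
    (iv) more than two follow it.
    """
    policy = policy or default_ppg_policy()
    if eb is None:
        return False, "no EB peak"
    size = window.size
    if abs(eb - size / 2) > policy.vicinity_frac * size:
        return False, "vicinity"
    if maxima.count_before(eb) < policy.min_mmt_before:
        return False, "MMT before"
    if maxima.count_after(eb) < policy.min_mmt_after:
        return False, "MMT after"
    return True, "ok"


def estimate_ppg_window_size(
    stream: SignalStream,
    at: int,
    policy: WindowPolicy | None = None,
    fallback: int | None = None,
) -> int:
    """Adaptive window size from the local pulse period.

    Prominent maxima (end-of-beat crests) of the mean-removed block give
    the peak-to-peak pulse period; the window is that period grown by
    ``buffer_frac``, with ``fwwt_size`` as the fallback when fewer than
    two crests are found.
    """
    policy = policy or default_ppg_policy()
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
    peaks, props = find_peaks(
        xm, height=policy.peak_height_frac * top, distance=policy.refractory
    )
    if peaks.size >= 2:
        # keep only crests of the tallest class: the dicrotic notch also
        # rises above the mean but stays well below the end-of-beat crest
        heights = props["peak_heights"]
        peaks = peaks[heights >= 0.75 * heights.max()]
    if peaks.size < 2:
        return fallback
    period = float(np.median(np.diff(peaks)))
    return int(round(period * (1.0 + policy.buffer_frac)))


def _ppg_window_size_at(
    stream: SignalStream, pos: int, policy: WindowPolicy, fallback: int | None = None
) -> int:
    fallback = fallback or policy.fwwt_size
    if policy.mode == "fwwt":
        return policy.fwwt_size
    if pos + policy.est_block <= len(stream):
        est = estimate_ppg_window_size(stream, pos, policy, fallback=0)
        if est > 0:
            return max(est, WTMM_MIN_SAMPLES)
    return fallback


def detect_ppg_stream(
    stream: SignalStream, policy: WindowPolicy | None = None
) -> list[PpgFiducials]:
    """Delineate every pulse of a continuous intensity-PPG stream.

    As the ECG loop, except that after a successful beat the next window
    starts one-tenth of the window size before the beginning of the next
    pulse, which is seeded from the current beat's EB.
    """
    policy = policy or default_ppg_policy()
    n = len(stream)
    out: list[PpgFiducials] = []
    pos = 0
    last_size: int | None = None
    while True:
        size = _ppg_window_size_at(stream, pos, policy, fallback=last_size)
        if pos + size > n:
            break
        budget = max(1, int(2 * size / policy.slide_step))
        found: Optional[PpgFiducials] = None
        tries = 0
        floor = pos
        snaps = 0
        while tries <= budget and pos + size <= n:
            window = SignalWindow(stream, pos, size)
            try:
                fid, maxima = _delineate_ppg(window, policy)
                ok, reason = check_ppg_window(window, fid.eb, maxima, policy)
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
                # re-centre the window on the detected EB (see ECG loop)
                snap_pos = max(floor, pos + fid.eb - size // 2)
                if snap_pos != pos:
                    snaps += 1
                    new_pos = snap_pos
            pos = new_pos
            if policy.mode == "awwt":
                size = _ppg_window_size_at(stream, pos, policy, fallback=last_size)
        if found is None:
            logger.debug("PPG retry budget exhausted at %d; skipping a window", pos)
            pos += size
            continue
        fid_global = found.shifted(pos, beat_id=len(out))
        if out and fid_global.eb <= out[-1].eb:
            pos += policy.slide_step
            continue
        out.append(fid_global)
        last_size = size
        # next pulse begins at the current EB; pre-roll by one-tenth window
        pos = max(fid_global.eb - size // 10, pos + 1)
    return out


def ppg_annotations(
    beats: list[PpgFiducials], stream: SignalStream
) -> pd.DataFrame:
    """Tabular per-beat annotation (indices and times) for CSV export."""
    rows = []
    for b in beats:
        row: dict[str, object] = {"beat_id": b.beat_id}
        for name in PPG_FIDUCIAL_NAMES:
            idx = getattr(b, name)
            row[name] = np.nan if idx is None else idx
            row[f"{name}_time_s"] = (
                np.nan if idx is None else float(stream.time_of(idx))
            )
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=["beat_id"]
        + [c for n in PPG_FIDUCIAL_NAMES for c in (n, f"{n}_time_s")],
    )
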