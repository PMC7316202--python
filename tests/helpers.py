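"""Shared test utilities: independent oracles and detection scoring."""

from __future__ import annotations

import numpy as np

from pulsebp.synthetic import SubjectProfile, synth_paired
from pulsebp.fiducial_ecg import WindowPolicy, detect_ecg_stream
from pulsebp.fiducial_ppg import default_ppg_policy, detect_ppg_stream

WORK_FS = 1200.0


def haar_cascade_oracle(x: np.ndarray, max_level: int):
    """Brute-force orthonormal Haar cascade: explicit 2-tap filters plus
    downsampling per level, right-padding odd lengths with the last
    sample.  Independent of the implementation under test."""
    s = np.asarray(x, dtype=float)
    cAs, cDs = [], []
    for _ in range(max_level):
        if s.size % 2:
            s = np.append(s, s[-1])
        a = np.empty(s.size // 2)
        d = np.empty(s.size // 2)
        for k in range(s.size // 2):
            a[k] = (s[2 * k] + s[2 * k + 1]) / np.sqrt(2.0)
            d[k] = (s[2 * k] - s[2 * k + 1]) / np.sqrt(2.0)
        cAs.append(a)
        cDs.append(d)
        s = a
    return cAs, cDs


def match_beats(dets, truths, anchor: str, names, fs: float = WORK_FS, tol: int = 120):
    """Match detected beats to truth beats on ``anchor`` and collect
    per-landmark absolute errors in milliseconds.

    Returns (recall, {name: list_of_abs_errors_ms}).  A truth beat counts
    as recalled when a detection's anchor lies within ``tol`` samples.
    """
    if not truths:
        return float("nan"), {}
    d_anchor = np.asarray([getattr(d, anchor) for d in dets], dtype=float)
    errs: dict[str, list[float]] = {n: [] for n in names}
    hits = 0
    for tb in truths:
        ta = getattr(tb, anchor)
        if d_anchor.size == 0:
            continue
        j = int(np.argmin(np.abs(d_anchor - ta)))
        if abs(d_anchor[j] - ta) > tol:
            continue
        hits += 1
        det = dets[j]
        for n in names:
            dv, tv = getattr(det, n), getattr(tb, n)
            if dv is not None and tv is not None:
                errs[n].append(abs(dv - tv) / fs * 1e3)
    return hits / len(truths), errs


def interior_truth(truths, anchor: str, n_samples: int, margin: int = 1600):
    """Truth beats whose anchor a full detection window can contain."""
    return [
        b for b in truths
        if margin <= getattr(b, anchor) <= n_samples - margin
    ]


def detection_scores(hr: float, seed: int, snr, duration: float = 62.0):
    """Run both stream detectors on one synthetic subject and score them."""
    prof = SubjectProfile(
        hr_mean=hr, hr_jitter=0.03, pat=0.25, noise_snr=snr, seed=seed
    )
    ecg, ppg, truth = synth_paired(prof, duration)
    ecg_dets = detect_ecg_stream(ecg, WindowPolicy())
    ppg_dets = detect_ppg_stream(ppg, default_ppg_policy())
    t_ecg = interior_truth(truth.ecg, "r", len(ecg))
    t_ppg = interior_truth(truth.ppg, "eb", len(ppg))
    rec_e, err_e = match_beats(ecg_dets, t_ecg, "r", ("p", "q", "r", "s", "t"))
    rec_p, err_p = match_beats(ppg_dets, t_ppg, "eb", ("sp", "dn", "dp", "eb"))
    return {
        "ecg_recall": rec_e,
        "ppg_recall": rec_p,
        "ecg_errors": err_e,
        "ppg_errors": err_p,
        "n_ecg_truth": len(t_ecg),
        "n_ppg_truth": len(t_ppg),
    }
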