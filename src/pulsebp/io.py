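"""Recording input/output, pipeline configuration and the full pipeline.

CSV is the canonical interchange format: a recording channel is a
two-column ``time,value`` table at a uniform sampling rate.  Channels
are validated (uniform timestamps, no missing values), resampled to the
1200 samples/s working rate and, for PPG, normalised to
transmission-intensity orientation before detection.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .bp_model import LogLinearRegression
from .features import FeatureVector, aggregate_segment
from .fiducial_ecg import WindowPolicy
from .fiducial_ppg import default_ppg_policy, to_intensity
from .wavelet_core import SignalStream, WORKING_FS, resample_to

__all__ = [
    "RecordingBundle",
    "PipelineConfig",
    "PipelineResult",
    "read_signal_csv",
    "write_signal_csv",
    "read_recording",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


@dataclass
class RecordingBundle:
    """A concurrent ECG/PPG recording with optional reference pressures."""

    ecg: SignalStream
    ppg: SignalStream
    subject_id: str = ""
    reference_sbp: Optional[float] = None
    reference_dbp: Optional[float] = None


@dataclass
class PipelineConfig:
    """End-to-end pipeline parameters.

    Defaults reproduce the working constants of the detection chain: a
    1200 samples/s working rate, a 10000-sample settling skip, an
    80000-sample (~one minute) analysis segment, and the adaptive window
    policies of the two channels.
    """

    working_fs: float = WORKING_FS
    settle_samples: int = 10_000
    segment_samples: int = 80_000
    min_pairs: int = 20
    ppg_orientation: str = "intensity"
    seed: int = 0
    ecg_policy: WindowPolicy = field(default_factory=WindowPolicy)
    ppg_policy: WindowPolicy = field(default_factory=default_ppg_policy)

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a config from JSON or YAML; keyword overrides win."""
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yml", ".yaml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        data.update(overrides)
        ecg_policy = WindowPolicy(**data.pop("ecg_policy", {}))
        ppg_policy = default_ppg_policy(**data.pop("ppg_policy", {}))
        return cls(ecg_policy=ecg_policy, ppg_policy=ppg_policy, **data)


def read_signal_csv(
    path: str | Path,
    kind: str,
    fs: Optional[float] = None,
    rel_tol: float = 1e-3,
) -> SignalStream:
    """Read a two-column ``time,value`` CSV as a uniformly sampled stream.

    ``fs`` may be given to override the rate inferred from timestamps.
    Rejects non-uniform timestamps (beyond ``rel_tol`` of the median
    step) and missing values, naming the offending row.
    """
    frame = pd.read_csv(path)
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: need two columns (time, value)")
    t = frame.iloc[:, 0].to_numpy(dtype=float)
    v = frame.iloc[:, 1].to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(v))
    if bad.size:
        raise ValueError(f"{path}: missing/invalid value at data row {bad[0]}")
    bad = np.flatnonzero(~np.isfinite(t))
    if bad.size:
        raise ValueError(f"{path}: missing/invalid time at data row {bad[0]}")
    if t.size < 2:
        raise ValueError(f"{path}: need at least 2 samples")
    dt = np.diff(t)
    step = float(np.median(dt))
    if step <= 0:
        raise ValueError(f"{path}: timestamps are not increasing")
    off = np.flatnonzero(np.abs(dt - step) > rel_tol * step)
    if off.size:
        raise ValueError(
            f"{path}: non-uniform sampling at data row {off[0] + 1} "
            f"(dt={dt[off[0]]:.6g}, expected {step:.6g})"
        )
    return SignalStream(v, fs if fs is not None else 1.0 / step, kind, t0=float(t[0]))


def write_signal_csv(stream: SignalStream, path: str | Path) -> None:
    """Write a stream as a two-column ``time,value`` CSV."""
    t = stream.t0 + np.arange(len(stream)) / stream.fs
    pd.DataFrame({"time_s": t, "value": stream.samples}).to_csv(path, index=False)


def read_recording(
    ecg_path: str | Path,
    ppg_path: str | Path,
    fs_ecg: Optional[float] = None,
    fs_ppg: Optional[float] = None,
    config: Optional[PipelineConfig] = None,
    subject_id: str = "",
    reference_sbp: Optional[float] = None,
    reference_dbp: Optional[float] = None,
) -> RecordingBundle:
    """Load a concurrent two-channel recording and bring it to the
    working rate (e.g. 200 Hz ECG is interpolated by 6, 75 Hz PPG by 16).
    """
    config = config or PipelineConfig()
    ecg = read_signal_csv(ecg_path, "ecg", fs_ecg)
    ppg = read_signal_csv(ppg_path, "ppg", fs_ppg)
    ppg = to_intensity(ppg, config.ppg_orientation)
    ecg = resample_to(ecg, config.working_fs)
    ppg = resample_to(ppg, config.working_fs)
    return RecordingBundle(
        ecg=ecg,
        ppg=ppg,
        subject_id=subject_id,
        reference_sbp=reference_sbp,
        reference_dbp=reference_dbp,
    )


@dataclass
class PipelineResult:
    features: FeatureVector
    sbp_pred: Optional[float] = None
    dbp_pred: Optional[float] = None
    timings_s: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "features": self.features.values,
            "beat_counts": self.features.counts,
            "n_pairs": self.features.n_pairs,
            "sbp_pred": self.sbp_pred,
            "dbp_pred": self.dbp_pred,
            "timings_s": self.timings_s,
        }


def run_pipeline(
    bundle: RecordingBundle,
    config: Optional[PipelineConfig] = None,
    sbp_model: Optional[LogLinearRegression] = None,
    dbp_model: Optional[LogLinearRegression] = None,
) -> PipelineResult:
    """Settle-skip, delineate both channels, pair beats, extract the
    robust feature vector, and predict BP when models are supplied.

    Raises :class:`pulsebp.features.SegmentRejected` when the recording
    is too short or yields too few paired beats.
    """
    config = config or PipelineConfig()
    t0 = time.perf_counter()
    fv = aggregate_segment(
        bundle.ecg,
        bundle.ppg,
        policy=config.ecg_policy,
        ppg_policy=config.ppg_policy,
        settle_samples=config.settle_samples,
        segment_samples=config.segment_samples,
        min_pairs=config.min_pairs,
    )
    t_extract = time.perf_counter() - t0
    logger.info(
        "extract: %d beat pairs in %.2f s (subject %s)",
        fv.n_pairs, t_extract, bundle.subject_id or "?",
    )
    result = PipelineResult(features=fv, timings_s={"extract": t_extract})
    t1 = time.perf_counter()
    series = fv.as_series()
    if sbp_model is not None:
        result.sbp_pred = float(sbp_model.predict(series.to_frame().T)[0])
    if dbp_model is not None:
        result.dbp_pred = float(dbp_model.predict(series.to_frame().T)[0])
    result.timings_s["predict"] = time.perf_counter() - t1
    return result
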