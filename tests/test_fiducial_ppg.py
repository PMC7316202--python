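"""PPG delineation: single pulses, validity conditions, the stream loop,
and the intensity/volume orientation round trip."""

import numpy as np
import pytest
from dataclasses import replace

from helpers import interior_truth, match_beats
from pulsebp.fiducial_ecg import BeatRejected, WindowPolicy
from pulsebp.fiducial_ppg import (
    check_ppg_window,
    default_ppg_policy,
    detect_ppg_beat,
    detect_ppg_stream,
    estimate_ppg_window_size,
    to_intensity,
)
from pulsebp.synthetic import PpgMorphology, SubjectProfile, synth_ppg, synth_paired
from pulsebp.wavelet_core import MaximaSet, SignalStream, SignalWindow


def _centered_window(stream, truth_beat, period_samples, buffer_frac=0.25):
    size = int(period_samples * (1 + buffer_frac))
    start = truth_beat.eb - size // 2
    return SignalWindow(stream, start, size), start


class TestDetectBeat:
    def test_noiseless_pulse_hits_landmarks(self, paired_clean):
        _, ppg, truth = paired_clean
        period = 1200 * 60 / 75
        beat = truth.ppg[5]
        window, start = _centered_window(ppg, beat, period)
        fid = detect_ppg_beat(window).shifted(start)
        assert abs(fid.eb - beat.eb) <= 24  # 20 ms
        assert abs(fid.sp - beat.sp) <= 36  # 30 ms
        assert abs(fid.dp - beat.dp) <= 36
        assert fid.sp < fid.dp < fid.eb
        if fid.dn is not None:
            assert fid.sp < fid.dn < fid.dp

    def test_constant_window_rejected(self):
        stream = SignalStream(np.full(4000, 2.0), 1200.0, "ppg")
        with pytest.raises(BeatRejected):
            detect_ppg_beat(SignalWindow(stream, 0, 1200))

    def test_notchless_beat_has_null_dn(self):
        prof = SubjectProfile(
            hr_mean=75.0, hr_jitter=0.0, pat=0.25, noise_snr=None, seed=3,
            ppg=PpgMorphology(notch_amp=0.0),
        )
        stream, truth = synth_ppg(prof, 20.0)
        assert all(b.dn is None for b in truth.ppg)
        beat = truth.ppg[5]
        window, start = _centered_window(stream, beat, 1200 * 60 / 75)
        fid = detect_ppg_beat(window)
        assert fid.dn is None
        assert abs(fid.shifted(start).eb - beat.eb) <= 24

    def test_detection_invariant_under_scaling_and_offset(self, paired_clean):
        _, ppg, truth = paired_clean
        beat = truth.ppg[4]
        window, start = _centered_window(ppg, beat, 1200 * 60 / 75)
        base = detect_ppg_beat(window)
        scaled = SignalStream(ppg.samples * 12.0 - 3.0, ppg.fs, "ppg")
        other = detect_ppg_beat(SignalWindow(scaled, start, window.size))
        assert base == other


class TestCheckWindow:
    def _maxima(self, positions):
        return MaximaSet(np.asarray(positions, dtype=int), 0.05)

    def test_four_before_three_after_valid(self, flat_stream):
        window = SignalWindow(flat_stream, 0, 1000)
        ok, why = check_ppg_window(
            window, 500, self._maxima([50, 150, 250, 350, 650, 750, 850])
        )
        assert ok and why == "ok"

    def test_three_before_invalid(self, flat_stream):
        window = SignalWindow(flat_stream, 0, 1000)
        ok, why = check_ppg_window(
            window, 500, self._maxima([150, 250, 350, 650, 750, 850])
        )
        assert not ok and why == "MMT before"

    def test_eb_outside_vicinity_invalid(self, flat_stream):
        window = SignalWindow(flat_stream, 0, 1000)
        ok, why = check_ppg_window(
            window, 200, self._maxima([20, 50, 80, 110, 650, 750, 850])
        )
        assert not ok and why == "vicinity"


class TestWindowSize:
    def test_tracks_programmed_pulse_period(self):
        prof = SubjectProfile(hr_mean=72.0, hr_jitter=0.0, noise_snr=None, seed=2)
        stream, _ = synth_ppg(prof, 10.0)
        size = estimate_ppg_window_size(stream, 0)
        assert abs(size - 1250) <= 25  # 1000-sample period * 1.25

    def test_flat_block_falls_back(self, flat_stream):
        policy = default_ppg_policy()
        assert estimate_ppg_window_size(flat_stream, 0, policy) == policy.fwwt_size

    def test_jittered_stream_within_band(self):
        prof = SubjectProfile(hr_mean=72.0, hr_jitter=0.10, noise_snr=None, seed=4)
        stream, truth = synth_ppg(prof, 20.0)
        ebs = np.asarray([b.eb for b in truth.ppg])
        for at in (0, 4000, 8000):
            size = estimate_ppg_window_size(stream, at)
            # the estimate reflects the periods inside its 2400-sample block
            local = np.diff(ebs[(ebs >= at - 300) & (ebs <= at + 2700)])
            local_mean = float(np.mean(local))
            assert 0.9 * 1.25 * local_mean <= size <= 1.1 * 1.25 * local_mean


class TestStream:
    def test_60s_stream_recovers_beats(self):
        prof = SubjectProfile(hr_mean=72.0, hr_jitter=0.02, noise_snr=30.0, seed=6)
        stream, truth = synth_ppg(prof, 60.0)
        dets = detect_ppg_stream(stream)
        interior = interior_truth(truth.ppg, "eb", len(stream))
        recall, errs = match_beats(dets, interior, "eb", ("eb",))
        assert recall >= 0.95
        assert np.mean(errs["eb"]) <= 20.0  # ms

    def test_flat_line_yields_empty_list(self, flat_stream):
        assert detect_ppg_stream(flat_stream) == []

    def test_stream_starting_mid_beat_emits_only_complete_cycles(self):
        prof = SubjectProfile(hr_mean=75.0, hr_jitter=0.0, noise_snr=None, seed=8)
        stream, truth = synth_ppg(prof, 30.0)
        # chop mid-beat: start halfway between an SP and its EB
        cut = (truth.ppg[2].sp + truth.ppg[2].eb) // 2
        chopped = SignalStream(stream.samples[cut:], stream.fs, "ppg")
        dets = detect_ppg_stream(chopped)
        assert len(dets) > 10
        first = dets[0]
        assert first.sp < first.dp < first.eb  # a full cycle, no partials
        assert first.sp >= 0

    def test_ordering_invariant_for_every_emitted_beat(self):
        prof = SubjectProfile(hr_mean=85.0, hr_jitter=0.04, noise_snr=20.0, seed=10)
        stream, _ = synth_ppg(prof, 30.0)
        dets = detect_ppg_stream(stream)
        assert len(dets) > 10
        ebs = [d.eb for d in dets]
        assert all(b > a for a, b in zip(ebs, ebs[1:]))
        for d in dets:
            assert d.sp < d.dp < d.eb
            if d.dn is not None:
                assert d.sp < d.dn < d.dp


class TestOrientation:
    def test_volume_round_trip_gives_identical_indices(self, paired_clean):
        _, ppg, truth = paired_clean
        volume = SignalStream(-ppg.samples, ppg.fs, "ppg")  # conventional PPG
        restored = to_intensity(volume, "volume")
        a = detect_ppg_stream(ppg)
        b = detect_ppg_stream(restored)
        assert [(x.sp, x.dn, x.dp, x.eb) for x in a] == [
            (x.sp, x.dn, x.dp, x.eb) for x in b
        ]

    def test_unknown_orientation_rejected(self, paired_clean):
        _, ppg, _ = paired_clean
        with pytest.raises(ValueError, match="orientation"):
            to_intensity(ppg, "sideways")
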