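"""Beat pairing, the 32-feature table, the robust aggregator, and
segment-level extraction."""

import numpy as np
import pandas as pd
import pytest

from pulsebp.features import (
    CROSS_FEATURES,
    ECG_ONLY_FEATURES,
    FEATURE_NAMES,
    PPG_ONLY_FEATURES,
    BeatPair,
    SegmentRejected,
    aggregate_segment,
    compute_beat_features,
    feature_matrix,
    pair_beats,
    robust_mean,
)
from pulsebp.fiducial_ecg import EcgFiducials
from pulsebp.fiducial_ppg import PpgFiducials
from pulsebp.synthetic import SubjectProfile, synth_paired
from pulsebp.wavelet_core import SignalStream


def _ecg(r, beat_id=0):
    return EcgFiducials(
        p=r - 190, q=r - 42, r=r, s=r + 42, t=r + 360,
        qrs_on=r - 65, qrs_off=r + 65, beat_id=beat_id,
    )


def _ppg(eb, beat_id=0, dn_offset=-420):
    return PpgFiducials(
        sp=eb - 560, dn=None if dn_offset is None else eb + dn_offset,
        dp=eb - 290, eb=eb, beat_id=beat_id,
    )


class TestPairing:
    def test_each_dp_takes_latest_preceding_r(self):
        ecg = [_ecg(600, 0), _ecg(1800, 1)]
        ppg = [_ppg(1140, 0), _ppg(2350, 1)]  # dp at 850, 2060
        pairs = pair_beats(ecg, ppg)
        assert [(p.ecg.r, p.ppg.dp) for p in pairs] == [(600, 850), (1800, 2060)]

    def test_dp_before_first_r_dropped(self):
        ecg = [_ecg(600)]
        ppg = [_ppg(500)]  # dp at 210 < first R
        assert pair_beats(ecg, ppg) == []

    def test_two_rs_one_dp_uses_later_r(self):
        ecg = [_ecg(600, 0), _ecg(1800, 1)]
        ppg = [_ppg(2350, 0)]  # dp 2060 follows both Rs
        pairs = pair_beats(ecg, ppg)
        assert len(pairs) == 1 and pairs[0].ecg.r == 1800

    def test_each_r_pairs_at_most_once(self):
        ecg = [_ecg(600)]
        ppg = [_ppg(1140, 0), _ppg(1500, 1)]  # both DPs after the only R
        pairs = pair_beats(ecg, ppg)
        assert len(pairs) == 1


class TestBeatFeatures:
    def test_qrs_duration_from_indices(self):
        e = EcgFiducials(p=20, q=100, r=120, s=140, t=300, qrs_on=90, qrs_off=150)
        p = PpgFiducials(sp=420, dn=500, dp=560, eb=700)
        out = compute_beat_features(BeatPair(e, p), fs=1200.0)
        assert out["Tqrs"] == pytest.approx((150 - 90) / 1200.0)

    def test_pulse_arrival_time_is_r_to_sp(self):
        e = EcgFiducials(p=20, q=100, r=120, s=140, t=300, qrs_on=90, qrs_off=150)
        p = PpgFiducials(sp=420, dn=500, dp=560, eb=700)
        out = compute_beat_features(BeatPair(e, p), fs=1200.0)
        assert out["T_RN2"] == pytest.approx(0.25)

    def test_null_dn_nullifies_dn_features_only(self):
        e = _ecg(600)
        p = _ppg(1140, dn_offset=None)
        out = compute_beat_features(BeatPair(e, p), fs=1200.0)
        dn_feats = ["Tn1b", "Tn2n1"] + [f"T_{i}N1" for i in "PQRST"]
        for name in dn_feats:
            assert np.isnan(out[name]), name
        present = [
            n for n in FEATURE_NAMES
            if n not in dn_feats and n not in ("Trr", "Tbb", "Taa")
        ]
        for name in present:
            assert not np.isnan(out[name]), name

    def test_inter_beat_intervals_need_next_pair(self):
        a = BeatPair(_ecg(600), _ppg(1140))
        b = BeatPair(_ecg(1800, 1), _ppg(2350, 1), pair_id=1)
        with_next = compute_beat_features(a, 1200.0, next_pair=b)
        assert with_next["Trr"] == pytest.approx(1.0)
        assert with_next["Tbb"] == pytest.approx((2350 - 1140) / 1200.0)
        last = compute_beat_features(b, 1200.0)
        assert np.isnan(last["Trr"]) and np.isnan(last["Tbb"]) and np.isnan(last["Taa"])


class TestStructure:
    def test_exactly_32_canonical_columns(self):
        assert len(FEATURE_NAMES) == 32
        assert len(set(FEATURE_NAMES)) == 32
        assert len(ECG_ONLY_FEATURES) == 5
        assert len(PPG_ONLY_FEATURES) == 7
        assert len(CROSS_FEATURES) == 20

    def test_matrix_has_canonical_columns(self):
        pairs = [BeatPair(_ecg(600), _ppg(1140))]
        table = feature_matrix(pairs, 1200.0)
        assert list(table.columns) == list(FEATURE_NAMES)
        assert len(table) == 1


class TestRobustMean:
    def test_outlier_dropped_by_mean_sd_filter(self):
        # mean 26.5, SD 49.0 -> 100 falls outside [mean-SD, mean+SD]
        assert robust_mean([1.0, 2.0, 3.0, 100.0]) == pytest.approx(2.0)

    def test_zero_variance_returns_plain_mean(self):
        assert robust_mean([5.0, 5.0, 5.0]) == 5.0

    def test_pair_inside_band_keeps_both(self):
        assert robust_mean([2.0, 4.0]) == pytest.approx(3.0)

    def test_single_value_passes_through(self):
        assert robust_mean([7.25]) == 7.25

    def test_all_null_returns_nan(self):
        assert np.isnan(robust_mean([np.nan, np.nan]))

    def test_idempotent_on_own_output(self):
        rng = np.random.default_rng(3)
        v = rng.normal(size=50)
        once = robust_mean(v)
        assert robust_mean([once]) == once


class TestAggregateSegment:
    def test_recovers_programmed_pat(self, paired_80s_clean):
        ecg, ppg, truth = paired_80s_clean
        fv = aggregate_segment(ecg, ppg)
        assert fv.n_pairs >= 20
        assert abs(fv.values["T_RN2"] - 0.25) <= 0.010  # within 10 ms

    def test_noiseless_features_match_programmed_values(self, paired_80s_clean):
        """Extracted interval features agree with the generator's analytic
        values to within one native PPG sample period."""
        ecg, ppg, truth = paired_80s_clean
        fv = aggregate_segment(ecg, ppg)
        for name, true_val in truth.features.items():
            got = fv.values[name]
            assert abs(got - true_val) <= 1.0 / 75.0, (name, got, true_val)

    def test_short_recording_rejected(self, paired_clean):
        ecg, ppg, _ = paired_clean  # 20 s < settle + segment
        with pytest.raises(SegmentRejected, match="too short"):
            aggregate_segment(ecg, ppg)

    def test_rate_mismatch_rejected(self, paired_80s_clean):
        ecg, ppg, _ = paired_80s_clean
        bad = SignalStream(ppg.samples, 600.0, "ppg")
        with pytest.raises(SegmentRejected, match="rates"):
            aggregate_segment(ecg, bad)

    def test_outlier_filter_limits_corrupted_beat_drift(self):
        """Spiking 5% of beats moves each robust feature by < 2%."""
        prof = SubjectProfile(
            hr_mean=75.0, hr_jitter=0.02, pat=0.25, noise_snr=None, seed=31
        )
        ecg, ppg, truth = synth_paired(prof, 80.0)
        clean = aggregate_segment(ecg, ppg)

        rng = np.random.default_rng(99)
        beats = [b for b in truth.ecg if 12_000 < b.r < 88_000]
        bad = rng.choice(len(beats), size=max(1, len(beats) // 20), replace=False)
        ecg_c = SignalStream(ecg.samples.copy(), ecg.fs, "ecg")
        ppg_c = SignalStream(ppg.samples.copy(), ppg.fs, "ppg")
        for j in bad:
            r = beats[j].r
            ecg_c.samples[r - 30 : r + 30] += rng.normal(0, 1.5, size=60)
            ppg_c.samples[r + 200 : r + 260] += rng.normal(0, 1.0, size=60)
        corrupted = aggregate_segment(ecg_c, ppg_c)

        for name in FEATURE_NAMES:
            a, b = clean.values[name], corrupted.values[name]
            if np.isnan(a) or np.isnan(b):
                continue
            # relative band plus a one-sample absolute floor: signed
            # cross intervals can sit near zero where 2% is sub-sample
            assert abs(b - a) <= 0.02 * abs(a) + 1.0 / 1200.0, (name, a, b)
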