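"""Generator contracts: RR models, waveforms, class mixes, detector sims."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal as sps

import afibvote as av
from afibvote.synthetic import (
    DetectorProfile,
    largest_remainder_counts,
    matched_pair,
    simulate_detector_matrix,
)


def lag1_autocorr(x: np.ndarray) -> float:
    return float(np.corrcoef(x[:-1], x[1:])[0, 1])


class TestRRSeries:
    def test_sinus_mean_rr_matches_heart_rate(self):
        params = av.RhythmParams("sinus", 60.0, 0.03)
        rr = av.generate_rr_series(params, 30.0, seed=1)
        assert 28 <= rr.n_beats <= 32
        assert abs(rr.rr_ms.mean() - 1000.0) < 50.0

    @pytest.mark.parametrize("rhythm", sorted(av.RHYTHM_PRESETS))
    @pytest.mark.parametrize("seed", [0, 3])
    def test_duration_coverage(self, rhythm, seed):
        rr = av.generate_rr_series(av.RHYTHM_PRESETS[rhythm], 30.0, seed)
        total = rr.rr_ms.sum() / 1000.0
        assert 30.0 - rr.rr_ms.max() / 1000.0 <= total <= 30.0 + rr.rr_ms.max() / 1000.0

    @pytest.mark.parametrize("rhythm", ["sinus", "afib", "bigeminy"])
    @pytest.mark.parametrize("seed", [2, 5, 9])
    def test_realized_cv_near_target(self, rhythm, seed):
        params = av.RHYTHM_PRESETS[rhythm]
        rr = av.generate_rr_series(params, 60.0, seed)
        assert rr.n_beats >= 30
        cv = rr.rr_ms.std(ddof=1) / rr.rr_ms.mean()
        assert abs(cv - params.rr_cv) / params.rr_cv < 0.30

    def test_afib_serial_structure_is_weak(self):
        """AFib RR sequences are exchangeable: lag-1 autocorrelation is
        centred at zero, unlike the strongly autocorrelated sinus model."""
        af_acs = [lag1_autocorr(
            av.generate_rr_series(av.RHYTHM_PRESETS["afib"], 60.0, s).rr_ms)
            for s in range(10)]
        si_acs = [lag1_autocorr(
            av.generate_rr_series(av.RHYTHM_PRESETS["sinus"], 60.0, s).rr_ms)
            for s in range(10)]
        assert abs(np.mean(af_acs)) < 0.10
        assert np.mean(si_acs) > np.mean(af_acs) + 0.2

    @pytest.mark.parametrize("seed", range(6))
    def test_afib_more_irregular_than_sinus(self, seed):
        cv = {}
        for rhythm in ("afib", "sinus"):
            rr = av.generate_rr_series(av.RHYTHM_PRESETS[rhythm], 30.0, seed)
            cv[rhythm] = rr.rr_ms.std(ddof=1) / rr.rr_ms.mean()
        assert cv["afib"] > cv["sinus"]

    def test_deterministic(self):
        a = av.generate_rr_series(av.RHYTHM_PRESETS["afib"], 30.0, 7)
        b = av.generate_rr_series(av.RHYTHM_PRESETS["afib"], 30.0, 7)
        np.testing.assert_array_equal(a.peak_times, b.peak_times)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="rhythm_class"):
            av.RhythmParams("wiggle", 60, 0.05)
        with pytest.raises(ValueError, match="duration"):
            av.generate_rr_series(av.RHYTHM_PRESETS["sinus"], 0.0, 1)


def band_power(rec: av.ECGRecord, lo: float, hi: float) -> float:
    f, p = sps.welch(rec.samples - rec.samples.mean(), fs=rec.fs,
                     nperseg=2048)
    m = (f >= lo) & (f <= hi)
    return float(np.trapezoid(p[m], f[m]))


class TestWaveforms:
    def test_one_r_peak_per_beat(self):
        params = av.RhythmParams("sinus", 60.0, 0.03)
        rr = av.generate_rr_series(params, 30.0, seed=4)
        rec = av.synthesize_record(rr, params, noise_level=0.0, seed=5)
        x = rec.samples
        is_max = (x[1:-1] > x[:-2]) & (x[1:-1] > x[2:]) & (x[1:-1] > 0.5)
        n_beats_in_window = int(np.sum(rr.peak_times <= rec.duration_s))
        assert int(is_max.sum()) == n_beats_in_window

    @pytest.mark.parametrize("seed", [1, 3, 8])
    def test_afib_has_more_fibrillatory_band_power(self, seed):
        af, si = matched_pair("afib", "sinus", seed=seed, noise_level=0.0)
        assert band_power(af, 4.0, 9.0) > band_power(si, 4.0, 9.0)

    def test_p_wave_presence(self):
        """Sinus beats carry a P deflection ~180 ms before R; AFib omits it."""
        for rhythm, expect_p in (("sinus", True), ("afib", False)):
            params = av.RhythmParams(rhythm, 60.0,
                                     0.03 if rhythm == "sinus" else 0.2)
            rr = av.generate_rr_series(params, 30.0, seed=6)
            rec = av.synthesize_record(rr, params, 0.0, seed=7)
            idx = (rr.peak_times[2:10] - 0.18) * rec.fs
            p_amp = np.mean([rec.samples[int(i)] for i in idx])
            assert (p_amp > 0.08) == expect_p

    def test_record_length_and_empty_rr(self):
        params = av.RhythmParams("sinus", 60.0, 0.03)
        rr = av.generate_rr_series(params, 10.0, seed=0)
        rec = av.synthesize_record(rr, params, 0.1, seed=1, duration_s=10.0)
        assert rec.samples.size == 3000
        with pytest.raises(ValueError, match="empty"):
            av.synthesize_record(av.RRSeries.from_peak_times([]), params, 0, 1)


class TestNoiseRecords:
    def test_contract(self):
        rec = av.generate_noise_record(seed=1)
        assert rec.label == "noise"
        assert rec.fs == 300 and rec.samples.size == 9000

    def test_distinct_seeds_differ(self):
        a = av.generate_noise_record(seed=1)
        b = av.generate_noise_record(seed=2)
        assert not np.array_equal(a.samples, b.samples)

    @pytest.mark.parametrize("seed", [1, 4, 9])
    def test_gated_by_detector_or_quality(self, seed):
        rec = av.generate_noise_record(seed=seed)
        n_peaks = av.detect_r_peaks(rec).n_beats
        quality = av.compute_signal_quality(rec)
        assert n_peaks < 15 or n_peaks > 90 or quality < 0.3


class TestGenerateDataset:
    def test_published_prevalence_counts(self):
        mix = {"AFib": 0.166, "non-AFib": 0.828, "noise": 0.006}
        ds = av.generate_dataset(1000, mix, "ds2_like", seed=0)
        labels = ds.labels
        assert int(np.sum(labels == "AFib")) == 166
        assert int(np.sum(labels == "non-AFib")) == 828
        assert int(np.sum(labels == "noise")) == 6

    def test_degenerate_mix(self):
        ds = av.generate_dataset(50, {"AFib": 1.0}, "train_like", seed=0)
        assert all(r.label == "AFib" for r in ds)

    def test_bit_reproducible(self):
        mix = {"AFib": 0.2, "non-AFib": 0.7, "noise": 0.1}
        a = av.generate_dataset(40, mix, "apple_like", seed=3)
        b = av.generate_dataset(40, mix, "apple_like", seed=3)
        assert [r.record_id for r in a] == [r.record_id for r in b]
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.samples, rb.samples)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            av.generate_dataset(10, {"AFib": 0.5, "non-AFib": 0.4}, "ds3_like")

    @given(n=st.integers(1, 500),
           w=st.lists(st.floats(0.01, 1.0), min_size=2, max_size=5))
    @settings(max_examples=50, deadline=None)
    def test_largest_remainder_rounding(self, n, w):
        fr = np.array(w) / np.sum(w)
        counts = largest_remainder_counts(n, fr)
        assert counts.sum() == n
        assert np.all(counts >= 0)
        assert np.all(np.abs(counts - n * fr) < 1.0)


class TestSimulatedDetectors:
    def test_perfect_detector_reproduces_truth(self, sim_labels_2000):
        mat = simulate_detector_matrix(
            sim_labels_2000, [DetectorProfile("p", 1.0, 1.0)], seed=0)
        np.testing.assert_array_equal(
            mat.features["p"].to_numpy(),
            (sim_labels_2000 == "AFib").astype(float))

    def test_uninformative_detector_accuracy_half(self):
        rng = np.random.default_rng(0)
        labels = rng.choice(["AFib", "non-AFib"], size=10_000)
        mat = simulate_detector_matrix(
            labels, [DetectorProfile("d", 0.5, 0.5)], seed=1)
        calls = mat.features["d"].to_numpy() >= 0.5
        se = 3 * np.sqrt(0.25 / 5000)
        for cls in ("AFib", "non-AFib"):
            m = labels == cls
            correct = calls[m] if cls == "AFib" else ~calls[m]
            assert abs(correct.mean() - 0.5) < se

    def test_correlation_increases_shared_errors(self):
        rng = np.random.default_rng(3)
        labels = rng.choice(["AFib", "non-AFib"], size=10_000)
        truth = labels == "AFib"
        overlap = {}
        for rho in (0.0, 0.9):
            mat = simulate_detector_matrix(
                labels,
                [DetectorProfile("a", 0.8, 0.8),
                 DetectorProfile("b", 0.8, 0.8)],
                seed=5, correlation=rho)
            err_a = (mat.features["a"] >= 0.5).to_numpy() != truth
            err_b = (mat.features["b"] >= 0.5).to_numpy() != truth
            overlap[rho] = np.mean(err_a & err_b)
        assert overlap[0.9] > overlap[0.0]

    def test_correlation_range_checked(self, sim_labels_2000):
        with pytest.raises(ValueError, match="correlation"):
            simulate_detector_matrix(sim_labels_2000,
                                     [DetectorProfile("d", 0.8, 0.8)],
                                     correlation=1.5)


class TestDatasetIO:
    def test_csv_round_trip(self, tmp_path):
        ds = av.generate_dataset(8, {"AFib": 0.25, "non-AFib": 0.5,
                                     "noise": 0.25}, "train_like", seed=2)
        av.write_dataset(ds, tmp_path)
        back = av.read_dataset(tmp_path, name=ds.name)
        assert [r.record_id for r in back] == [r.record_id for r in ds]
        for ra, rb in zip(ds, back):
            assert ra.label == rb.label and ra.fs == rb.fs
            np.testing.assert_allclose(ra.samples, rb.samples, atol=5e-7)
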