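"""Synthetic generator: ground-truth fidelity and determinism."""
import numpy as np
import pytest

from conftest import beat_recovery
from wearval import cardio, synth
from wearval.types import DeviceModel, ScrShape


class TestSimulateRR:
    def test_zero_variability_exact_intervals(self):
        rr = synth.simulate_rr_series(60, 60, None, seed=1)
        assert rr.interval_ms.size == 60
        assert np.all(rr.interval_ms == 1000.0)

    def test_seed_determinism(self):
        var = synth.RRVariability(20, 30, 10)
        a = synth.simulate_rr_series(600, 75, var, seed=7)
        b = synth.simulate_rr_series(600, 75, var, seed=7)
        np.testing.assert_array_equal(a.interval_ms, b.interval_ms)

    def test_different_seeds_differ(self):
        var = synth.RRVariability(jitter_sd_ms=10)
        a = synth.simulate_rr_series(60, 75, var, seed=1)
        b = synth.simulate_rr_series(60, 75, var, seed=2)
        assert not np.array_equal(a.interval_ms, b.interval_ms)

    def test_mean_hr_within_2pct(self):
        var = synth.RRVariability(25, 35, 8)
        for hr in (50, 75, 110):
            rr = synth.simulate_rr_series(120, hr, var, seed=4)
            assert abs(rr.mean_hr_bpm - hr) / hr < 0.02

    def test_rmssd_matches_definition_oracle(self):
        # independent brute-force RMSSD over the emitted intervals
        var = synth.RRVariability(hf_amp_ms=40)
        rr = synth.simulate_rr_series(300, 60, var, seed=3)
        iv = rr.interval_ms
        sq = [(iv[i + 1] - iv[i]) ** 2 for i in range(iv.size - 1)]
        oracle = float(np.sqrt(sum(sq) / len(sq)))
        assert cardio.cardio_parameters(iv).rmssd_ms == pytest.approx(oracle, rel=1e-12)

    @pytest.mark.parametrize("duration,hr", [(-1, 60), (60, 20), (60, 200)])
    def test_invalid_arguments(self, duration, hr):
        with pytest.raises(ValueError):
            synth.simulate_rr_series(duration, hr, None, seed=0)


class TestRenderEcg:
    def test_argmax_at_beat_times(self, ecg_clean_100):
        truth = np.array(ecg_clean_100.meta["beat_times_s"])
        x = ecg_clean_100.data[0]
        fs = ecg_clean_100.fs_hz
        for tb in truth[1:-1]:
            c = int(round(tb * fs))
            w = x[c - 30 : c + 30]
            assert abs((c - 30 + np.argmax(w)) / fs - tb) <= 1.0 / fs

    def test_gain_scales_noiseless_signal(self, rr_steady_60):
        r1 = synth.render_ecg(rr_steady_60, 100, DeviceModel(gain=1), duration_s=60, seed=0)
        r2 = synth.render_ecg(rr_steady_60, 100, DeviceModel(gain=2), duration_s=60, seed=0)
        np.testing.assert_allclose(r2.data, 2 * r1.data, atol=1e-12)

    def test_noisy_beats_recoverable_by_standard_detector(self, ecg_noisy_1000):
        # independent oracle: smoothed find_peaks with refractory distance
        from scipy import signal as sps

        x = ecg_noisy_1000.data[0]
        sm = np.convolve(x, np.ones(9) / 9, "same")
        idx, _ = sps.find_peaks(sm, height=0.5 * np.percentile(sm, 99.9), distance=250)
        truth = ecg_noisy_1000.meta["beat_times_s"]
        assert beat_recovery(idx / 1000.0, truth) >= 0.99

    def test_out_of_duration_beats_truncated_with_warning(self, rr_steady_60):
        with pytest.warns(UserWarning, match="truncated"):
            rec = synth.render_ecg(rr_steady_60, 100, DeviceModel(), duration_s=30, seed=0)
        assert max(rec.meta["beat_times_s"]) < 30


class TestRenderPpg:
    def test_identical_devices_identical_channels(self, rr_steady_60):
        rec = synth.render_ppg(rr_steady_60, 100, None, 0.2, duration_s=60, seed=0)
        np.testing.assert_array_equal(rec.data[0], rec.data[1])
        np.testing.assert_array_equal(rec.data[1], rec.data[2])

    def test_wrong_device_count_rejected(self, rr_steady_60):
        with pytest.raises(ValueError, match="3 device"):
            synth.render_ppg(rr_steady_60, 100, (DeviceModel(),) * 2, duration_s=60)

    def test_pulse_delay_recovered_by_lag_scan(self, rr_steady_60):
        # oracle: cross-correlate detected ECG/PPG peak impulse trains
        ecg = synth.render_ecg(rr_steady_60, 100, DeviceModel(), duration_s=60, seed=0)
        ppg = synth.render_ppg(rr_steady_60, 100, None, 0.25, duration_s=60, seed=0)
        pe = cardio.detect_peaks(ecg.data[0], 100, "brammer")
        pp = cardio.detect_peaks(ppg.data[0], 100, "elgendi_dual_ma", modality="ppg")
        n = ecg.n_samples
        tr_e, tr_p = np.zeros(n), np.zeros(n)
        tr_e[np.clip(np.round(pe.peak_times_s * 100).astype(int), 0, n - 1)] = 1
        tr_p[np.clip(np.round(pp.peak_times_s * 100).astype(int), 0, n - 1)] = 1
        lags = np.arange(0, 51)
        cc = [np.dot(tr_e[: n - l], tr_p[l:]) for l in lags]
        assert lags[int(np.argmax(cc))] / 100.0 == pytest.approx(0.25, abs=0.02)

    def test_averaged_snr_between_best_and_worst(self, rr_steady_60):
        devs_clean = (DeviceModel(),) * 3
        clean = synth.render_ppg(rr_steady_60, 100, devs_clean, 0.2, duration_s=60, seed=0)
        devs = (
            DeviceModel(noise_sd=0.05),
            DeviceModel(noise_sd=0.5),
            DeviceModel(noise_sd=0.05),
        )
        noisy = synth.render_ppg(rr_steady_60, 100, devs, 0.2, duration_s=60, seed=1)
        sig_var = clean.data[0].var()
        snr = [sig_var / (noisy.data[i] - clean.data[i]).var() for i in range(3)]
        avg_resid = (noisy.data.mean(axis=0) - clean.data.mean(axis=0)).var()
        snr_avg = sig_var / avg_resid
        assert min(snr) < snr_avg < max(snr)


class TestRenderEdaPair:
    def test_flat_tonic_identity_devices(self):
        ra, rb = synth.render_eda_pair(30, 15, 15, tonic_level_uS=5.0, seed=0)
        np.testing.assert_allclose(ra.data, 5.0, atol=1e-12)
        np.testing.assert_allclose(rb.data, 5.0, atol=1e-12)

    def test_peak_normalized_amplitude(self):
        ra, _ = synth.render_eda_pair(
            60, 100, 15, 5.0, 0.0, [(20.0, ScrShape(amplitude_uS=0.5))], seed=0
        )
        assert ra.data[0].max() - 5.0 == pytest.approx(0.5, abs=1e-3)

    def test_affine_device_transform(self):
        events = [(15.0, ScrShape(amplitude_uS=0.4)), (40.0, ScrShape(amplitude_uS=0.6))]
        dev_b = DeviceModel(gain=0.3, offset=-1.0, noise_sd=0.005)
        ra, rb = synth.render_eda_pair(
            60, 15, 15, 6.0, 0.01, events, DeviceModel(), dev_b, seed=2
        )
        expected = 0.3 * ra.data[0].mean() - 1.0
        assert rb.data[0].mean() == pytest.approx(expected, abs=0.01)

    def test_conservation_against_ground_truth(self):
        # noiseless identity render equals tonic + phasic truth to 1e-9
        events = [(10.0, ScrShape(amplitude_uS=0.5)), (12.0, ScrShape(amplitude_uS=0.3))]
        ra, _ = synth.render_eda_pair(30, 15, 15, 4.0, 0.02, events, seed=0)
        t = np.arange(ra.n_samples) / 15.0
        truth = 4.0 + 0.02 * t
        for t_ev, s in events:
            truth = truth + synth.bateman_kernel(t - t_ev, s)
        np.testing.assert_allclose(ra.data[0], truth, atol=1e-9)

    def test_event_outside_duration_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            synth.render_eda_pair(30, 15, 15, 5.0, 0.0, [(40.0, ScrShape())])


class TestInjectArtifacts:
    def test_empty_spec_identity(self, ecg_clean_100):
        out = synth.inject_artifacts(ecg_clean_100, [])
        np.testing.assert_array_equal(out.data, ecg_clean_100.data)

    def test_untouched_samples_bit_identical(self, ecg_clean_100):
        out = synth.inject_artifacts(ecg_clean_100, [synth.Flatline(20, 24)])
        i0, i1 = 2000, 2400
        np.testing.assert_array_equal(out.data[:, :i0], ecg_clean_100.data[:, :i0])
        np.testing.assert_array_equal(out.data[:, i1:], ecg_clean_100.data[:, i1:])
        assert np.all(out.data[0, i0:i1] == out.data[0, i0])

    def test_overlapping_flatlines_merged(self, ecg_clean_100):
        a = synth.inject_artifacts(
            ecg_clean_100, [synth.Flatline(20, 24), synth.Flatline(22, 26)]
        )
        b = synth.inject_artifacts(ecg_clean_100, [synth.Flatline(20, 26)])
        np.testing.assert_array_equal(a.data, b.data)

    def test_window_outside_recording_rejected(self, ecg_clean_100):
        with pytest.raises(ValueError, match="outside"):
            synth.inject_artifacts(ecg_clean_100, [synth.Flatline(55, 65)])


class TestGeneratorInvariants:
    def test_render_determinism(self, rr_variable):
        kw = dict(duration_s=120, seed=9)
        a = synth.render_ecg(rr_variable, 250, DeviceModel(noise_sd=0.1), **kw)
        b = synth.render_ecg(rr_variable, 250, DeviceModel(noise_sd=0.1), **kw)
        np.testing.assert_array_equal(a.data, b.data)

    def test_hr_recovery_within_1bpm(self, rr_variable):
        rec = synth.render_ecg(rr_variable, 250, DeviceModel(), duration_s=120, seed=0)
        pk = cardio.detect_peaks(rec.data[0], 250, "nabian_window")
        est = cardio.cardio_parameters(cardio.peak_intervals(pk)).mean_hr_bpm
        assert abs(est - rr_variable.mean_hr_bpm) < 1.0
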