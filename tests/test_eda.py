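"""EDA cleaning, decomposition, SCR detection and plausibility screen."""
import numpy as np
import pytest

from wearval import eda, synth
from wearval.types import EdaParams, ScrShape


def phasic_with_events(events, duration_s=120.0, fs=15.0):
    t = np.arange(int(duration_s * fs)) / fs
    x = np.zeros_like(t)
    for t_ev, shape in events:
        x += synth.bateman_kernel(t - t_ev, shape)
    return x


class TestCleanEda:
    def test_dc_passes(self):
        x = np.full(900, 5.0)
        for m in ("nk3hz", "biosppy5hz"):
            np.testing.assert_allclose(eda.clean_eda(x, 15, m), 5.0, rtol=1e-6)

    def test_6hz_attenuated_by_3hz_lowpass(self):
        t = np.arange(4500) / 15.0
        x = np.sin(2 * np.pi * 6 * t)
        y = eda.clean_eda(x, 15, "nk3hz")
        mid = slice(300, 4200)
        out_amp = np.sqrt(2 * np.mean(y[mid] ** 2))
        assert out_amp < 0.1  # > 90% attenuation

    def test_none_identity(self):
        x = np.random.default_rng(0).normal(size=300)
        np.testing.assert_array_equal(eda.clean_eda(x, 15, "none"), x)

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            eda.clean_eda(np.zeros(300), 6, "biosppy5hz")


class TestDecompose:
    @pytest.mark.parametrize("method", ["highpass005", "median4s"])
    def test_constant_signal(self, method):
        x = np.full(900, 5.0)
        dec = eda.decompose_eda(x, 15, method)
        np.testing.assert_allclose(dec.tonic, 5.0, atol=1e-6)
        np.testing.assert_allclose(dec.phasic, 0.0, atol=1e-6)

    @pytest.mark.parametrize("method", ["highpass005", "median4s"])
    def test_subtractive_conservation(self, method):
        rng = np.random.default_rng(1)
        x = 5 + np.cumsum(rng.normal(0, 0.01, size=1800))
        dec = eda.decompose_eda(x, 15, method)
        np.testing.assert_allclose(dec.tonic + dec.phasic, x, atol=1e-9)

    def test_median4s_fast_scr_amplitude(self):
        # slow ramp + fast SCR: rolling-median tonic barely absorbs the event
        fs = 15.0
        t = np.arange(int(60 * fs)) / fs
        x = 5 + 0.01 * t + synth.bateman_kernel(t - 20.0, ScrShape(0.15, 0.5, 0.5))
        dec = eda.decompose_eda(x, fs, "median4s")
        assert dec.phasic.max() == pytest.approx(0.5, rel=0.15)

    def test_median4s_needs_8s(self):
        with pytest.raises(ValueError, match="8 s"):
            eda.decompose_eda(np.zeros(60), 15, "median4s")

    def test_cvx_raises_not_implemented(self):
        with pytest.raises(NotImplementedError, match="cvx"):
            eda.decompose_eda(np.full(900, 5.0), 15, "cvx")


class TestDetectScrs:
    @pytest.mark.parametrize("method", eda.EDA_PEAK_METHODS)
    def test_zero_phasic_no_events(self, method):
        assert eda.detect_scrs(np.zeros(900), 15, method) == []

    @pytest.mark.parametrize("method", eda.EDA_PEAK_METHODS)
    def test_single_event_recovery(self, method):
        x = phasic_with_events([(40.0, ScrShape(amplitude_uS=0.5))], 90.0)
        events = eda.detect_scrs(x, 15, method)
        assert len(events) == 1
        ev = events[0]
        assert ev.amplitude_uS == pytest.approx(0.5, rel=0.2)
        t_peak_truth = 40.0 + 0.75 * 2.0 / (2.0 - 0.75) * np.log(2.0 / 0.75)
        assert abs(ev.peak_s - t_peak_truth) < 1.0

    def test_nabian_rejects_below_10pct_of_max(self):
        x = phasic_with_events(
            [(30.0, ScrShape(amplitude_uS=1.0)), (80.0, ScrShape(amplitude_uS=0.05))]
        )
        events = eda.detect_scrs(x, 15, "nabian")
        assert len(events) == 1
        assert events[0].amplitude_uS == pytest.approx(1.0, rel=0.1)

    def test_nabian_amplitude_recovery_small_events(self):
        for amp in (0.1, 0.3, 1.0):
            x = phasic_with_events([(40.0, ScrShape(amplitude_uS=amp))], 90.0)
            events = eda.detect_scrs(x, 15, "nabian")
            assert len(events) == 1
            assert events[0].amplitude_uS == pytest.approx(amp, rel=0.1)

    @pytest.mark.parametrize("method", eda.EDA_PEAK_METHODS)
    def test_events_time_ordered(self, method):
        x = phasic_with_events(
            [(t, ScrShape(amplitude_uS=0.4)) for t in (20.0, 45.0, 70.0, 95.0)]
        )
        events = eda.detect_scrs(x, 15, method)
        times = [e.peak_s for e in events]
        assert times == sorted(times)

    def test_count_nondecreasing_in_event_count(self):
        # averaged over seeds, more injected events never means fewer detected
        counts = []
        for n_events in (2, 5, 9):
            per_seed = []
            for seed in range(20):
                rng = np.random.default_rng(seed)
                times = np.sort(rng.uniform(10, 170, size=n_events))
                x = phasic_with_events(
                    [(float(t), ScrShape(amplitude_uS=0.5)) for t in times], 180.0
                )
                x = x + rng.normal(0, 0.01, size=x.size)
                per_seed.append(len(eda.detect_scrs(x, 15, "nabian")))
            counts.append(np.mean(per_seed))
        assert counts[0] <= counts[1] <= counts[2]


class TestEdaParameters:
    @staticmethod
    def _decomp(tonic):
        from wearval.types import EdaDecomposition

        return EdaDecomposition(
            tonic=np.asarray(tonic, float),
            phasic=np.zeros(len(tonic)),
            method="highpass005",
            fs_hz=15.0,
        )

    def test_rate_example(self):
        from wearval.types import ScrEvent

        events = [ScrEvent(i * 30.0, i * 30.0 + 2, 0.3) for i in range(12)]
        p = eda.eda_parameters(self._decomp(np.full(100, 5.0)), events, 360.0)
        assert p.scr_per_min == pytest.approx(2.0)

    def test_constant_tonic(self):
        p = eda.eda_parameters(self._decomp(np.full(100, 5.0)), [], 60.0)
        assert p.scl_mean_uS == pytest.approx(5.0)
        assert p.scl_sd_uS == pytest.approx(0.0)
        assert np.isnan(p.scr_amp_mean_uS)

    def test_amplitude_mean(self):
        from wearval.types import ScrEvent

        events = [ScrEvent(1.0, 3.0, 0.2), ScrEvent(10.0, 12.0, 0.4)]
        p = eda.eda_parameters(self._decomp(np.full(100, 5.0)), events, 60.0)
        assert p.scr_amp_mean_uS == pytest.approx(0.3)

    def test_rate_stable_under_duration_doubling(self):
        # same event density at double duration: rate within 5%
        shape = ScrShape(amplitude_uS=0.5)
        for dur, n in ((180.0, 6), (360.0, 12)):
            times = np.linspace(15, dur - 20, n)
            x = phasic_with_events([(float(t), shape) for t in times], dur)
            events = eda.detect_scrs(x, 15, "nabian")
            rate = len(events) / (dur / 60.0)
            assert rate == pytest.approx(2.0, rel=0.05)


class TestPlausibilityScreen:
    @staticmethod
    def _params(rate, amp):
        return EdaParams(5.0, 0.1, rate, amp, 3.0)

    def test_overestimation_excluded(self):
        v = eda.screen_pipeline_plausibility([self._params(35.0, 0.3)] * 4)
        assert v.excluded and "overestimation" in v.reason

    def test_plausible_retained(self):
        v = eda.screen_pipeline_plausibility([self._params(2.0, 0.3)] * 4)
        assert not v.excluded

    def test_near_zero_amplitudes_excluded(self):
        v = eda.screen_pipeline_plausibility([self._params(2.0, 5e-4)] * 4)
        assert v.excluded and "near-zero" in v.reason

    def test_empty_amplitudes_excluded(self):
        v = eda.screen_pipeline_plausibility([self._params(0.0, float("nan"))] * 3)
        assert v.excluded

    def test_no_runs_rejected(self):
        with pytest.raises(ValueError):
            eda.screen_pipeline_plausibility([])
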