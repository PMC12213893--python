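"""Per-epoch SQI rules, template correlation, good-epoch harmonization."""
import numpy as np
import pytest

from wearval import cardio, quality, synth
from wearval.quality import EpochReport, EpochRow, UnusableRunError
from wearval.types import DeviceModel, PeakSeries, QualityThresholds, Recording


def run_sqi(rec, method="brammer", modality="ecg", thresholds=None):
    pk = cardio.detect_peaks(rec.data[0], rec.fs_hz, method, modality=modality)
    return quality.assess_quality(rec, pk, modality, thresholds)


class TestEpochSignal:
    def test_trailing_partial_discarded(self):
        rec = Recording(np.zeros((1, 9500)), 100.0)
        pk = PeakSeries(np.arange(0, 95, 1.0))
        assert len(quality.epoch_signal(rec, pk, 10.0)) == 9

    def test_partition_of_samples(self):
        rec = Recording(np.arange(10000, dtype=float)[None, :], 100.0)
        pk = PeakSeries(np.arange(0, 100, 1.0))
        eps = quality.epoch_signal(rec, pk, 10.0)
        assert len(eps) == 10
        np.testing.assert_array_equal(
            np.concatenate([e.signal for e in eps]), rec.data[0]
        )

    def test_boundary_peak_goes_to_later_epoch(self):
        rec = Recording(np.zeros((1, 3000)), 100.0)
        pk = PeakSeries(np.array([9.0, 10.0, 11.0]))
        eps = quality.epoch_signal(rec, pk, 10.0)
        assert list(eps[0].peak_times_s) == [9.0]
        assert list(eps[1].peak_times_s) == [10.0, 11.0]

    def test_short_run_warns_and_empty(self):
        rec = Recording(np.zeros((1, 500)), 100.0)
        with pytest.warns(UserWarning, match="shorter"):
            assert quality.epoch_signal(rec, PeakSeries(np.array([])), 10.0) == []


class TestPhysiologicalChecks:
    def test_regular_intervals_pass(self):
        assert quality.physiological_checks(np.full(9, 1000.0)) == set()

    def test_interval_ratio_rule(self):
        assert quality.physiological_checks(np.array([500.0, 1200.0])) == {
            "interval_ratio"
        }

    def test_max_gap_rule(self):
        failed = quality.physiological_checks(np.array([1000.0, 3200.0, 1000.0]))
        assert "max_gap" in failed

    def test_hr_range_rule(self):
        assert "hr_range" in quality.physiological_checks(np.full(10, 250.0))
        assert "hr_range" in quality.physiological_checks(np.full(3, 2500.0))

    def test_too_few_peaks(self):
        assert quality.physiological_checks(np.array([])) == {"too_few_peaks"}


class TestTemplateCorrelation:
    @staticmethod
    def _pulse_epoch(n_beats=8, negate=()):
        fs = 100.0
        t = np.arange(int((n_beats + 1) * fs)) / fs
        x = np.zeros_like(t)
        peaks = []
        for k in range(n_beats):
            tb = 0.5 + k
            sign = -1.0 if k in negate else 1.0
            x += sign * np.exp(-0.5 * ((t - tb) / 0.06) ** 2)
            peaks.append(tb)
        return x, np.array(peaks), fs

    def test_identical_pulses_r_one(self):
        x, peaks, fs = self._pulse_epoch()
        r, n = quality.pulse_template_correlation(x, peaks, fs)
        assert n == 8
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_negated_beat_drops_below_ecg_floor(self):
        x, peaks, fs = self._pulse_epoch(n_beats=5, negate={2})
        r, _ = quality.pulse_template_correlation(x, peaks, fs)
        assert r < 0.66

    def test_white_noise_mean_r_small(self):
        rs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=2000)
            peaks = np.arange(0.5, 19.5, 1.0)  # 19 windows of pure noise
            r, _ = quality.pulse_template_correlation(x, peaks, 100.0)
            rs.append(r)
        assert abs(np.mean(rs)) < 0.3

    def test_constant_windows_score_zero(self):
        x = np.ones(1000)
        r, _ = quality.pulse_template_correlation(x, np.array([3.0, 5.0, 7.0]), 100.0)
        assert r == 0.0


class TestAssessQuality:
    def test_clean_run_fully_good(self, rr_variable):
        rec = synth.render_ecg(rr_variable, 100, DeviceModel(), duration_s=120, seed=0)
        rep = run_sqi(rec)
        assert rep.n_epochs == 12
        assert rep.good_fraction == 1.0

    def test_flatline_epoch_fails_max_gap(self, rr_variable):
        rec = synth.render_ecg(rr_variable, 100, DeviceModel(), duration_s=120, seed=0)
        bad = synth.inject_artifacts(rec, [synth.Flatline(33.0, 37.0)])
        rep = run_sqi(bad)
        assert not rep.rows[3].good
        assert "max_gap" in rep.rows[3].failed_rules
        assert all(r.good for r in rep.rows if r.index != 3)

    def test_corr_floor_straddles_modalities(self):
        thr = QualityThresholds()
        assert thr.min_template_corr("ecg") < 0.70 < thr.min_template_corr("ppg")

    def test_verdicts_order_independent(self, rr_variable):
        # epoch verdicts depend only on that epoch's content: corrupting a
        # late epoch leaves earlier verdicts untouched
        rec = synth.render_ecg(rr_variable, 100, DeviceModel(), duration_s=120, seed=0)
        bad = synth.inject_artifacts(rec, [synth.BurstNoise(100.0, 110.0, 5.0, seed=1)])
        pk = cardio.detect_peaks(rec.data[0], 100, "brammer")
        r_clean = quality.assess_quality(rec, pk, "ecg")
        r_bad = quality.assess_quality(bad, pk, "ecg")
        for a, b in zip(r_clean.rows[:10], r_bad.rows[:10]):
            assert a.good == b.good and a.failed_rules == b.failed_rules

    def test_good_fraction_monotone_in_noise(self, rr_variable):
        fracs = []
        for noise in (0.05, 0.4, 1.2):
            per_seed = []
            for seed in range(20):
                rec = synth.render_ecg(
                    rr_variable, 100, DeviceModel(noise_sd=noise), duration_s=60,
                    seed=seed,
                )
                per_seed.append(run_sqi(rec).good_fraction)
            fracs.append(np.mean(per_seed))
        assert fracs[0] >= fracs[1] >= fracs[2]
        assert fracs[0] > fracs[2]


def _report(goods, intervals=None, spans=None):
    rows = []
    for i, g in enumerate(goods):
        iv = np.asarray(intervals[i], dtype=float) if intervals else np.full(9, 1000.0)
        rows.append(
            EpochRow(
                index=i,
                t_begin_s=10.0 * i,
                t_end_s=10.0 * (i + 1),
                good=g,
                failed_rules=() if g else ("max_gap",),
                template_corr=1.0,
                intervals_ms=iv,
                first_spans_prev=(spans[i] if spans else i > 0),
            )
        )
    return EpochReport(rows, "ecg", QualityThresholds())


class TestHarmonize:
    def test_min_rule(self):
        a = _report([True] * 28)
        b = _report([True] * 25 + [False] * 3)
        iv_a, iv_b = quality.harmonize_good_epochs(a, b)
        assert iv_a.size == iv_b.size

    def test_equal_counts_unchanged(self):
        a = _report([True] * 5)
        b = _report([True] * 5)
        iv_a, iv_b = quality.harmonize_good_epochs(a, b)
        assert iv_a.size == 5 * 9 and iv_b.size == 5 * 9

    def test_truncation_keeps_first_good_epochs(self):
        a = _report([False, True, True, False, True])
        b = _report([False, True, True, True, True])
        iv_a, iv_b = quality.harmonize_good_epochs(a, b)
        # b keeps its first 3 good epochs (1, 2, 3); epoch 1 follows the
        # rejected epoch 0 so its spanning interval is dropped, while the
        # intervals spanning into epochs 2 and 3 survive
        assert iv_b.size == 8 + 9 + 9
        # a keeps (1, 2, 4); epoch 4 follows the rejected epoch 3
        assert iv_a.size == 8 + 9 + 8

    def test_zero_good_epochs_unusable(self):
        with pytest.raises(UnusableRunError):
            quality.harmonize_good_epochs(_report([False] * 3), _report([True] * 3))

    def test_concatenated_params_match_whole_run(self, rr_variable):
        rec = synth.render_ecg(rr_variable, 100, DeviceModel(), duration_s=120, seed=0)
        pk = cardio.detect_peaks(rec.data[0], 100, "brammer")
        rep = quality.assess_quality(rec, pk, "ecg")
        assert rep.good_fraction == 1.0
        iv_a, _ = quality.harmonize_good_epochs(rep, rep)
        whole = cardio.cardio_parameters(cardio.peak_intervals(pk))
        concat = cardio.cardio_parameters(iv_a)
        assert concat.mean_hr_bpm == pytest.approx(whole.mean_hr_bpm, rel=0.01)
        assert concat.sd_intervals_ms == pytest.approx(whole.sd_intervals_ms, rel=0.01)
        assert concat.rmssd_ms == pytest.approx(whole.rmssd_ms, rel=0.01)


def test_report_serialization_round_trip(tmp_path, rr_variable):
    rec = synth.render_ecg(rr_variable, 100, DeviceModel(), duration_s=60, seed=0)
    rep = run_sqi(rec)
    df = rep.to_dataframe()
    assert set(df.columns) >= {"epoch", "good", "failed_rules", "template_corr"}
    rep.to_csv(tmp_path / "sqi.csv")
    assert (tmp_path / "sqi.csv").exists()
    d = rep.to_json_dict()
    assert d["good_fraction"] == rep.good_fraction
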