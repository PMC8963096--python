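"""Vitals extraction: beats, heart rate, AC/DC geometry, SpO2, spectra."""

import dataclasses

import numpy as np
import pytest

import ppgkit as pk
from ppgkit.errors import InvalidParameterError, UndefinedResultError
from ppgkit.fixtures import spo2_97_ground_truth


def manual_segmentation(peaks, valleys, fs):
    peaks = np.asarray(peaks)
    ibis = np.diff(peaks) / fs * 1000.0
    return pk.BeatSegmentation(peaks, np.ones(peaks.size, dtype=bool),
                               np.asarray(valleys), ibis, fs)


class TestBeatDetection:
    def test_constant_trace_has_no_beats(self):
        with pytest.warns(RuntimeWarning):
            seg = pk.detect_beats(np.ones(1000), 100.0)
        assert seg.n_accepted == 0

    def test_noiseless_beat_count(self, clean_ir_trace):
        seg = pk.detect_beats(clean_ir_trace)
        assert abs(seg.n_accepted - 72) <= 1

    def test_artifact_spike_rejected_by_ibi_rule(self, clean_ir_trace):
        x = clean_ir_trace.samples.copy()
        fs = clean_ir_trace.sample_rate_hz
        # place a 3x-amplitude spike midway between two systolic peaks
        mid = int((30.0 + 0.15 + 0.5 * 60 / 72) * fs)
        amp = np.ptp(x)
        x[mid - 2:mid + 3] += 3.0 * amp
        seg = pk.detect_beats(x, fs, smooth_s=0.0)
        assert seg.n_rejected >= 1
        assert mid in seg.peak_indices[~seg.accepted] or \
            any(abs(p - mid) <= 3 for p in seg.peak_indices[~seg.accepted])
        clean_count = pk.detect_beats(clean_ir_trace).n_accepted
        assert abs(seg.n_accepted - clean_count) <= 1

    def test_valleys_alternate_with_accepted_peaks(self, clean_ir_trace):
        seg = pk.detect_beats(clean_ir_trace)
        merged = np.sort(np.concatenate([seg.accepted_peaks, seg.valley_indices]))
        kinds = np.isin(merged, seg.accepted_peaks)
        assert np.all(kinds[:-1] != kinds[1:])  # strict alternation

    def test_short_trace_rejected(self):
        with pytest.raises(InvalidParameterError):
            pk.detect_beats(np.ones(100), 100.0)


class TestHeartRate:
    def test_uniform_second_intervals(self):
        seg = manual_segmentation([0, 100, 200, 300], [50, 150, 250], 100.0)
        assert pk.compute_hr(seg) == pytest.approx(60.0)

    def test_mixed_intervals(self):
        seg = manual_segmentation([0, 80, 165], [40, 120], 100.0)
        # intervals 800 and 850 ms -> 60000 / 825
        assert pk.compute_hr(seg) == pytest.approx(72.7, abs=0.05)

    def test_single_peak_is_undefined(self):
        seg = manual_segmentation([10], [0, 20], 100.0)
        with pytest.raises(UndefinedResultError):
            pk.compute_hr(seg)

    def test_planted_rate_recovered(self):
        gt = pk.PhysioGroundTruth(heart_rate_bpm=95.0, duration_s=60.0,
                                  noise_white_sigma_uA=0.0, seed=2)
        tr = pk.synthesize_channel(gt, 940)
        assert pk.compute_hr(pk.detect_beats(tr)) == pytest.approx(95.0, abs=1.0)


class TestValleyLineACDC:
    def test_horizontal_valley_line(self):
        x = np.array([1.0, 1.5, 1.0])
        seg = manual_segmentation([1], [0, 2], 2.0)
        est = pk.estimate_ac_dc_time(x, seg)
        assert est.dc == pytest.approx(1.0)
        assert est.ac == pytest.approx(0.5)
        assert est.pi_percent == pytest.approx(50.0)

    def test_sloped_valley_line_hand_geometry(self):
        # valleys (0 s, 1.0) and (1 s, 1.2), peak (0.5 s, 1.6)
        x = np.array([1.0, 1.6, 1.2])
        seg = manual_segmentation([1], [0, 2], 2.0)
        est = pk.estimate_ac_dc_time(x, seg)
        assert est.dc == pytest.approx(1.1)
        assert est.ac == pytest.approx(0.5)

    def test_perpendicular_mode_on_horizontal_chord_matches_vertical(self):
        x = np.array([1.0, 1.5, 1.0])
        seg = manual_segmentation([1], [0, 2], 2.0)
        v = pk.estimate_ac_dc_time(x, seg, projection="vertical")
        p = pk.estimate_ac_dc_time(x, seg, projection="perpendicular")
        assert p.dc == pytest.approx(v.dc)
        assert p.ac == pytest.approx(v.ac)

    def test_aggregate_is_mean_of_per_beat(self, clean_ir_trace):
        seg = pk.detect_beats(clean_ir_trace)
        est = pk.estimate_ac_dc_time(clean_ir_trace.samples, seg)
        assert est.ac == pytest.approx(np.mean([b[1] for b in est.per_beat]))
        assert est.dc == pytest.approx(np.mean([b[2] for b in est.per_beat]))

    def test_matches_independent_geometry_oracle_on_single_beat(self):
        """Closed-form valley-line computation vs the implementation, <= 1e-6."""
        fs, period = 250.0, 0.8
        tpl = pk.generate_beat_template(pk.PulseShape(), period, fs)
        dc_level, ac_amp = 1.0, 0.04
        x = np.concatenate([dc_level + ac_amp * tpl] * 3)
        n = tpl.size
        peak = n + int(np.argmax(tpl))
        # valleys: signal minima in the cycles before and after the peak
        v1 = int(np.argmin(x[:peak]))
        v2 = peak + int(np.argmin(x[peak:peak + n]))
        seg = manual_segmentation([peak], [v1, v2], fs)
        est = pk.estimate_ac_dc_time(x, seg)
        slope = (x[v2] - x[v1]) / ((v2 - v1) / fs)
        dc_oracle = x[v1] + slope * ((peak - v1) / fs)
        ac_oracle = x[peak] - dc_oracle
        assert est.dc == pytest.approx(dc_oracle, rel=1e-9)
        assert est.ac == pytest.approx(ac_oracle, rel=1e-6)


class TestRatioAndCalibration:
    def _pe(self, ac, dc):
        return pk.PerfusionEstimate(ac, dc, 100 * ac / dc, [])

    def test_identical_estimates_give_unity(self):
        e = self._pe(0.02, 1.0)
        assert pk.ratio_of_ratios(e, e) == pytest.approx(1.0)

    def test_planted_perfusion_arithmetic(self):
        r = pk.ratio_of_ratios(self._pe(0.0175, 1.0), self._pe(0.0425, 1.0))
        assert r == pytest.approx(7 / 17, rel=1e-12)

    def test_zero_red_ac_gives_zero(self):
        assert pk.ratio_of_ratios(self._pe(0.0, 1.0), self._pe(0.04, 1.0)) == 0.0

    def test_zero_ir_perfusion_is_undefined(self):
        with pytest.raises(UndefinedResultError):
            pk.ratio_of_ratios(self._pe(0.02, 1.0), self._pe(0.0, 1.0))

    def test_scale_invariance_of_r(self, clean_gt):
        red, ir = pk.synthesize_pair(clean_gt)
        base = pk.spo2_time_domain(red.samples, ir.samples, 125.0)
        for c in (0.03, 1000.0):
            scaled = pk.spo2_time_domain(c * red.samples, c * ir.samples, 125.0)
            assert scaled.r_value == pytest.approx(base.r_value, rel=1e-9)

    def test_curvilinear_mapping(self):
        assert pk.spo2_from_r(7 / 17) == pytest.approx(97.0)
        assert pk.spo2_from_r(0.0) == 100.0  # 104 pre-clamp
        assert pk.spo2_from_r(1.0) == pytest.approx(87.0)

    def test_linear_mapping_uses_k(self):
        cal = pk.SpO2Calibration(mode="linear", k=110.0, clamp_range=(0, 110))
        assert pk.spo2_from_r(0.5, cal) == pytest.approx(55.0)

    def test_lut_exact_at_knots_and_boundary_warning(self):
        cal = pk.SpO2Calibration.default_lut()
        assert pk.spo2_from_r(0.4, cal) == pytest.approx(104 - 17 * 0.4)
        with pytest.warns(RuntimeWarning):
            out = pk.spo2_from_r(5.0, cal)
        assert out == pytest.approx(104 - 17 * 1.2)

    def test_non_monotone_lut_rejected(self):
        with pytest.raises(InvalidParameterError):
            pk.SpO2Calibration(mode="lut",
                               lut=np.array([[0.2, 90.0], [0.4, 95.0]]))


class TestSpectrum:
    def test_sinusoid_amplitude_calibration(self):
        fs, nfft = 125.0, 4096
        f0 = 40 * fs / nfft  # exactly on a zero-padded bin
        t = np.arange(5000) / fs
        x = 2.0 + 0.5 * np.sin(2 * np.pi * f0 * t)
        spec = pk.compute_amplitude_spectrum(x, fs)
        i = np.argmin(np.abs(spec.frequencies_hz - f0))
        assert spec.amplitude_density[i] == pytest.approx(0.5, rel=0.01)
        assert spec.dc_level == pytest.approx(2.0, rel=1e-3)

    def test_constant_signal_concentrates_at_zero(self):
        spec = pk.compute_amplitude_spectrum(np.full(1000, 3.0), 125.0)
        assert spec.amplitude_density[0] == pytest.approx(3.0)
        assert spec.amplitude_density[1:].max() < 1e-9

    def test_realized_overlap(self):
        x = np.random.default_rng(0).standard_normal(2000)
        spec = pk.compute_amplitude_spectrum(x, 125.0, window_samples=310,
                                             overlap_percent=93.54)
        assert spec.overlap_percent == pytest.approx(100 * (310 - 20) / 310)

    def test_window_longer_than_trace_rejected(self):
        with pytest.raises(InvalidParameterError):
            pk.compute_amplitude_spectrum(np.ones(100), 125.0, window_samples=310)

    def test_two_tones_in_cardiac_band_larger_wins(self):
        fs = 125.0
        t = np.arange(8000) / fs
        x = (1.0 + 0.02 * np.sin(2 * np.pi * 0.2 * t)
             + 0.01 * np.sin(2 * np.pi * 1.0 * t)
             + 0.03 * np.sin(2 * np.pi * 2.5 * t))
        spec = pk.find_physio_peaks(pk.compute_amplitude_spectrum(x, fs))
        assert spec.cardiac_peak[0] == pytest.approx(2.5, abs=0.05)

    def test_single_cardiac_tone_flags_low_confidence_respiration(self):
        fs = 125.0
        t = np.arange(8000) / fs
        x = 1.0 + 0.02 * np.sin(2 * np.pi * 1.4 * t)
        spec = pk.find_physio_peaks(pk.compute_amplitude_spectrum(x, fs))
        assert not spec.respiratory_confident

    def test_overlapping_bands_rejected(self):
        spec = pk.compute_amplitude_spectrum(np.random.default_rng(0)
                                             .standard_normal(1000), 125.0)
        with pytest.raises(InvalidParameterError):
            pk.find_physio_peaks(spec, resp_band=(0.1, 0.9),
                                 cardiac_band=(0.7, 3.5))


class TestSpO2Pipelines:
    def test_time_domain_recovers_planted_saturation(self):
        gt = spo2_97_ground_truth(seed=5)
        red, ir = pk.synthesize_pair(gt)
        res = pk.spo2_time_domain(red.samples, ir.samples, 125.0)
        assert res.spo2_percent == pytest.approx(97.0, abs=1.0)
        assert res.method == "time-curvilinear"

    def test_lut_and_curvilinear_agree_when_lut_samples_the_curve(self):
        gt = spo2_97_ground_truth(seed=5)
        red, ir = pk.synthesize_pair(gt)
        curv = pk.spo2_time_domain(red.samples, ir.samples, 125.0)
        lut = pk.spo2_time_domain(red.samples, ir.samples, 125.0, method="lut")
        assert lut.spo2_percent == pytest.approx(curv.spo2_percent, abs=1e-9)

    def test_identical_channels_give_unity_ratio(self, clean_ir_trace):
        x = clean_ir_trace.samples
        res = pk.spo2_time_domain(x, x, 125.0)
        assert res.r_value == pytest.approx(1.0, rel=1e-12)
        assert res.spo2_percent == pytest.approx(pk.spo2_from_r(1.0))
        resf = pk.spo2_frequency_domain(x, x, 125.0, dc_source="zero_bin")
        assert resf.r_value == pytest.approx(1.0, rel=1e-9)

    def test_frequency_domain_recovery_with_zero_bin_dc(self):
        gt = spo2_97_ground_truth(seed=5, duration_s=60.0)
        red, ir = pk.synthesize_pair(gt)
        res = pk.spo2_frequency_domain(red.samples, ir.samples, 125.0,
                                       dc_source="zero_bin")
        assert res.spo2_percent == pytest.approx(97.0, abs=1.0)

    def test_time_and_frequency_methods_agree_on_clean_signals(self):
        gt = dataclasses.replace(spo2_97_ground_truth(seed=8, duration_s=60.0),
                                 noise_white_sigma_uA=0.0)
        red, ir = pk.synthesize_pair(gt)
        t_res = pk.spo2_time_domain(red.samples, ir.samples, 125.0)
        f_res = pk.spo2_frequency_domain(red.samples, ir.samples, 125.0,
                                         dc_source="zero_bin")
        assert abs(t_res.spo2_percent - f_res.spo2_percent) <= 2.0

    def test_pulseless_red_channel_saturates_the_curvilinear_map(self):
        fs = 125.0
        t = np.arange(8000) / fs
        ir = 1.0 + 0.01 * np.sin(2 * np.pi * 0.25 * t) \
            + 0.04 * np.abs(np.sin(2 * np.pi * 0.625 * t)) ** 8
        red = np.full_like(ir, 1.0)
        res = pk.spo2_frequency_domain(red, ir, fs, dc_source="zero_bin")
        assert res.r_value < 0.05
        assert res.spo2_percent >= 99.0

    def test_missing_respiratory_peak_is_undefined_for_peak_dc(self):
        fs = 125.0
        t = np.arange(8000) / fs
        x = 1.0 + 0.02 * np.sin(2 * np.pi * 1.4 * t)
        with pytest.raises(UndefinedResultError):
            pk.spo2_frequency_domain(x, x, fs, dc_source="respiratory_peak")

    def test_noise_robust_hr_at_20db_snr(self):
        """HR within 3 bpm in at least 95% of 20 seeded noisy runs."""
        hits = 0
        for seed in range(20):
            gt = pk.PhysioGroundTruth(heart_rate_bpm=72.0, duration_s=60.0,
                                      perfusion_index_percent={940: 4.25},
                                      dc_photocurrent_uA={940: 1.0},
                                      noise_white_sigma_uA=0.00425,  # AC/sigma = 10
                                      seed=seed)
            tr = pk.synthesize_channel(gt, 940)
            try:
                hr = pk.compute_hr(pk.detect_beats(tr))
            except UndefinedResultError:
                continue
            hits += abs(hr - 72.0) <= 3.0
        assert hits >= 19
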