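"""Synthetic-data generator: ECG model, chest motion, radar channels, dataset."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal as sps

from radarecg.synthdata import (
    EcgModelParams, InvalidParameterError, ConfigurationError, RadarSimConfig,
    SCENARIO_COUNTS_7521, SCENARIO_NAMES, SCENARIO_PROPORTIONS, ScenarioSpec,
    default_scenarios, generate_chest_displacement, generate_dataset,
    generate_ecg, largest_remainder_apportion, radar_modulate)

FS = 100.0


def equal_scenarios():
    return [ScenarioSpec(n, 1.0, 0.25, 4.0, "eupnea", 0.0, 1.0 / 7)
            for n in SCENARIO_NAMES]


class TestGenerateEcg:
    def test_zero_variance_rate_gives_metronomic_beats(self):
        ecg, r = generate_ecg(EcgModelParams(hr_mean=60, hr_sd=0), 10.0, seed=0)
        assert len(r) in (10, 11)
        assert np.allclose(np.diff(r), 1.0, atol=1e-12)
        assert ecg.shape == (1000,)

    def test_seeded_determinism(self):
        a = generate_ecg(EcgModelParams(), 10.0, seed=42)
        b = generate_ecg(EcgModelParams(), 10.0, seed=42)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_mean_rr_matches_requested_rate(self):
        # oracle: brute-force tally of the generated peak list
        _, r = generate_ecg(EcgModelParams(hr_mean=75, hr_sd=3), 60.0, seed=1)
        rr = np.diff(r)
        assert abs(rr.mean() - 0.8) < 3 * rr.std() / np.sqrt(len(rr))

    def test_output_is_z_normalized(self):
        ecg, _ = generate_ecg(EcgModelParams(), 10.0, seed=3)
        assert abs(ecg.mean()) < 1e-12 and abs(ecg.std() - 1.0) < 1e-12

    @pytest.mark.parametrize("bad", [
        EcgModelParams(hr_mean=30.0),
        EcgModelParams(hr_mean=float("nan")),
        EcgModelParams(wave_widths=(0.2, -0.1, 0.1, 0.1, 0.4)),
        EcgModelParams(hrv_corr=1.0),
        EcgModelParams(wave_amplitudes=(2.0, -0.1, 1.0, -0.2, 0.3)),
    ])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(InvalidParameterError):
            generate_ecg(bad, 10.0, seed=0)

    def test_r_peaks_line_up_with_waveform_maxima(self):
        ecg, r = generate_ecg(EcgModelParams(hr_mean=66, hr_sd=1), 10.0, seed=7)
        for tk in r:
            k = int(round(tk * FS))
            lo, hi = max(k - 4, 0), min(k + 5, len(ecg))
            assert ecg[lo:hi].max() == ecg[max(k - 1, 0):k + 2].max()


class TestChestDisplacement:
    def test_single_impulse_reproduces_kernel(self):
        sc = ScenarioSpec("Sitting-CR-Eu", 1.0, 0.25, 0.0, "eupnea", 0.0, 1.0)
        x = generate_chest_displacement(np.array([5.0]), sc, 0.3, seed=0)
        # analytic unit-peak kernel scaled by cardiac_amp; sampled peak may
        # fall between grid points
        assert np.all(x[:500] == 0.0)
        assert 0.29 <= np.abs(x).max() <= 0.3 + 1e-12
        assert np.argmax(np.abs(x)) in (501, 502)

    def test_apnea_has_breath_hold_of_at_least_3s(self):
        sc = ScenarioSpec("Supine-CSR-Ap", 0.5, 0.2, 4.0, "apnea", 15.0, 1.0)
        x = generate_chest_displacement(np.array([]), sc, 1e-9, seed=4)
        zero = np.abs(x) < 1e-6
        runs = np.diff(np.flatnonzero(np.diff(np.r_[0, zero, 0])))[::2]
        assert runs.max() >= 3.0 * FS

    def test_eupnea_dominant_frequency(self):
        sc = ScenarioSpec("Sitting-CR-Eu", 1.0, 0.25, 4.0, "eupnea", 0.0, 1.0)
        x = generate_chest_displacement(np.array([]), sc, 1e-9, seed=2)
        f, p = sps.periodogram(x, fs=FS)     # independent periodogram oracle
        assert abs(f[np.argmax(p)] - 0.25) < 0.06

    def test_rapid_shallow_scales_frequency_and_amplitude(self):
        base = ScenarioSpec("Supine-CSR-Eu", 0.5, 0.2, 4.0, "eupnea", 0.0, 1.0)
        rsb = ScenarioSpec("Supine-CSR-RSB", 0.5, 0.2, 4.0, "rapid_shallow",
                           25.0, 1.0)
        xb = generate_chest_displacement(np.array([]), base, 1e-9, seed=9)
        xr = generate_chest_displacement(np.array([]), rsb, 1e-9, seed=9)
        f, pb = sps.periodogram(xb, fs=FS)
        _, pr = sps.periodogram(xr, fs=FS)
        assert f[np.argmax(pr)] > 2.0 * f[np.argmax(pb)]
        assert np.abs(xr).max() < 0.5 * np.abs(xb).max()

    def test_unknown_pattern_rejected(self):
        sc = ScenarioSpec("Sitting-CR-Eu", 1.0, 0.25, 4.0, "sigh", 0.0, 1.0)
        with pytest.raises(ConfigurationError):
            generate_chest_displacement(np.array([]), sc, 0.3, seed=0)


class TestRadarModulate:
    CFG = RadarSimConfig(constant_phase=0.0, phase_noise_sd=0.0, awgn_sd=0.0)

    def test_zero_displacement_zero_phase(self):
        i, q = radar_modulate(np.zeros(1000), self.CFG, seed=0)
        assert np.allclose(i, self.CFG.amplitude) and np.allclose(q, 0.0)

    def test_amplitude_constancy_noiseless(self):
        t = np.arange(1000) / FS
        x = 0.3 * np.sin(2 * np.pi * 1.1 * t) + 3 * np.sin(2 * np.pi * 0.2 * t)
        i, q = radar_modulate(x, self.CFG, seed=0)
        assert np.abs(i ** 2 + q ** 2 - self.CFG.amplitude ** 2).max() < 1e-10

    def test_peak_phase_excursion_closed_form(self):
        t = np.arange(1000) / FS
        x = 0.2 * np.sin(2 * np.pi * 1.2 * t)
        i, q = radar_modulate(x, self.CFG, seed=0)
        phase = np.unwrap(np.arctan2(q, i))
        analytic = 4 * np.pi * 0.2 / self.CFG.wavelength   # 0.8378 rad
        assert round(analytic, 4) == 0.8378
        # sampled maximum is grid-limited but must agree closely
        assert abs(phase.max() - analytic) < 1e-3
        assert np.allclose(phase, 4 * np.pi * x / self.CFG.wavelength,
                           atol=1e-9)

    def test_invalid_wavelength(self):
        with pytest.raises(ConfigurationError):
            radar_modulate(np.zeros(10),
                           RadarSimConfig(wavelength=-1.0), seed=0)


class TestApportionment:
    def test_reference_campaign_counts(self):
        counts = largest_remainder_apportion(7521, SCENARIO_PROPORTIONS)
        assert tuple(counts) == SCENARIO_COUNTS_7521
        assert counts.sum() == 7521
        # 7521 segments of 1000 frames ~ 7.52 million frames
        assert counts.sum() * 1000 == 7_521_000

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(n=st.integers(1, 10_000),
           raw=st.lists(st.floats(0.01, 1.0), min_size=2, max_size=9))
    def test_counts_always_sum_to_n(self, n, raw):
        p = np.asarray(raw) / np.sum(raw)
        counts = largest_remainder_apportion(n, p)
        assert counts.sum() == n
        assert np.all(counts >= np.floor(n * p).astype(int))

    def test_bad_proportions_rejected(self):
        with pytest.raises(ConfigurationError):
            largest_remainder_apportion(10, [0.5, 0.4])


class TestGenerateDataset:
    def test_equal_proportions_small_case(self):
        ds = generate_dataset(2, 14, equal_scenarios(), seed=3)
        from collections import Counter
        assert Counter(s.scenario for s in ds.segments) == {
            n: 2 for n in SCENARIO_NAMES}
        assert len(ds) == 14

    def test_regeneration_is_bit_identical(self):
        a = generate_dataset(2, 14, equal_scenarios(), seed=3)
        b = generate_dataset(2, 14, equal_scenarios(), seed=3)
        for s1, s2 in zip(a.segments, b.segments):
            assert s1.subject_id == s2.subject_id
            assert s1.scenario == s2.scenario
            for f in ("t", "i_chan", "q_chan", "displacement", "ecg",
                      "r_peak_times"):
                assert np.array_equal(getattr(s1, f), getattr(s2, f))

    def test_noiseless_envelope_identity(self):
        cfg = RadarSimConfig(phase_noise_sd=0.0, awgn_sd=0.0)
        ds = generate_dataset(2, 7, equal_scenarios(), cfg=cfg, seed=1)
        for seg in ds.segments:
            dev = np.abs(seg.i_chan ** 2 + seg.q_chan ** 2
                         - cfg.amplitude ** 2)
            assert dev.max() < 1e-10

    def test_segment_invariants(self, small_dataset):
        for seg in small_dataset.segments:
            seg.validate()
            assert len(seg.ecg) == 1000
            assert np.all(np.diff(seg.r_peak_times) > 0)
            assert seg.r_peak_times.min() >= 0
            assert seg.r_peak_times.max() < 10.0

    def test_default_scenarios_are_valid_and_sum_to_one(self):
        scen = default_scenarios()
        assert abs(sum(s.proportion for s in scen) - 1.0) < 1e-6
        for s in scen:
            s.validate()

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_dataset(1, 10, equal_scenarios(), seed=0)
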