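"""Metrics, wave detection, peak matching and report aggregation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from radarecg.evaluation import (UndefinedMetricError, WaveAnnotation,
                                 detect_waves, localization_errors, mae, pcc,
                                 rmse, summarize)
from radarecg.synthdata import EcgModelParams, generate_ecg

FS = 100.0


class TestMorphologyMetrics:
    def test_pcc_identity_and_inversion(self):
        y = np.sin(np.linspace(0, 6, 100))
        assert pcc(y, y) == pytest.approx(1.0)
        assert pcc(-y, y) == pytest.approx(-1.0)

    def test_pcc_affine_invariance(self):
        y = np.random.default_rng(0).standard_normal(500)
        assert pcc(3.2 * y + 7.0, y) == pytest.approx(1.0, abs=1e-12)

    def test_pcc_zero_variance_raises(self):
        with pytest.raises(UndefinedMetricError):
            pcc(np.zeros(10), np.arange(10.0))

    def test_mae_rmse_hand_examples(self):
        y_hat = np.array([1.0, 2.0, 3.0])
        y = np.ones(3)
        assert mae(y_hat, y) == pytest.approx(1.0)
        assert rmse(y_hat, y) == pytest.approx(np.sqrt(5.0 / 3.0))
        assert mae(y, y) == 0.0 and rmse(y, y) == 0.0

    def test_rmse_dominates_mae(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a, b = rng.standard_normal((2, 64))
            assert rmse(a, b) >= mae(a, b) - 1e-12


class TestDetectWaves:
    def test_r_peaks_match_generator_truth(self):
        for hr, seed in [(62, 0), (75, 1), (88, 2)]:
            ecg, r_true = generate_ecg(
                EcgModelParams(hr_mean=hr, hr_sd=1.5), 10.0, seed=seed)
            ann = detect_waves(ecg, FS)
            assert len(ann.r_times) == len(r_true)
            assert np.abs(ann.r_times - r_true).max() <= 0.010

    def test_beat_ordering_invariant(self):
        ecg, _ = generate_ecg(EcgModelParams(hr_mean=70), 10.0, seed=3)
        ann = detect_waves(ecg, FS)
        assert ann.n_beats > 5
        for q, r, s, t in zip(ann.q_times, ann.r_times, ann.s_times,
                              ann.t_times):
            assert q < r < s < t

    def test_flat_trace_yields_empty_annotation(self):
        ann = detect_waves(np.zeros(1000), FS)
        assert ann.n_beats == 0

    def test_pluggable_detector(self):
        marker = WaveAnnotation(*[np.array([1.0])] * 4)
        ann = detect_waves(np.sin(np.arange(1000) / 5.0), FS,
                           detector=lambda e, f: marker)
        assert ann is marker


def brute_force_match(ref, rec, window):
    """Exhaustive assignment minimizing total error (oracle for small n)."""
    best = (0, 0.0)
    feasible = [(i, j) for i in range(len(ref)) for j in range(len(rec))
                if abs(ref[i] - rec[j]) <= window]
    for r in range(len(feasible), 0, -1):
        for combo in itertools.combinations(feasible, r):
            ri = [c[0] for c in combo]
            rj = [c[1] for c in combo]
            if len(set(ri)) == r and len(set(rj)) == r:
                cost = sum(abs(ref[i] - rec[j]) for i, j in combo)
                if r > best[0] or (r == best[0] and cost < best[1]):
                    best = (r, cost)
        if best[0] == r:
            break
    return best


class TestLocalizationErrors:
    def annotate(self, times):
        a = np.asarray(times, dtype=float)
        return WaveAnnotation(a, a, a, a)

    def test_identical_annotations(self):
        ann = self.annotate([1.0, 2.0, 3.0])
        errors, misses = localization_errors(ann, ann)
        assert all(e == [0.0, 0.0, 0.0] for e in errors.values())
        assert all(m == 0 for m in misses.values())

    def test_uniform_shift(self):
        ref = self.annotate([1.0, 2.0, 3.0])
        rec = self.annotate([1.02, 2.02, 3.02])
        errors, misses = localization_errors(rec, ref)
        assert np.allclose(errors["r"], 0.02)
        assert misses["r"] == 0

    def test_partial_match_against_brute_force(self):
        ref = np.array([1.0, 2.0, 3.0])
        rec = np.array([1.004, 2.5, 3.01])
        errors, misses = localization_errors(self.annotate(rec),
                                             self.annotate(ref),
                                             match_window=0.15)
        assert np.allclose(sorted(errors["r"]), [0.004, 0.01])
        assert misses["r"] == 1
        n_matched, cost = brute_force_match(ref, rec, 0.15)
        assert n_matched == len(errors["r"])
        assert cost == pytest.approx(sum(errors["r"]))

    def test_greedy_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            ref = np.sort(rng.uniform(0, 10, 5))
            rec = np.sort(ref + rng.normal(0, 0.05, 5))[:4]
            errors, _ = localization_errors(self.annotate(rec),
                                            self.annotate(ref), 0.15)
            n_bf, _ = brute_force_match(ref, rec, 0.15)
            assert len(errors["r"]) == n_bf


class TestSummarize:
    def per_segment(self, n=3):
        return pd.DataFrame({
            "segment": range(n), "subject": ["A"] * n,
            "scenario": ["Sitting-CR-Eu"] * n,
            "pcc": np.linspace(0.8, 0.9, n),
            "rmse": np.linspace(0.1, 0.2, n),
            "mae": np.linspace(0.05, 0.1, n)})

    def test_percentile_convention(self):
        errs = {w: list(np.arange(1, 11) * 0.001) for w in "qrst"}
        rep = summarize(self.per_segment(), errs)
        row = rep.wave_stats.set_index("wave").loc["r"]
        assert row["median"] == pytest.approx(0.0055)
        assert row["p90"] == pytest.approx(0.0091)

    def test_single_segment_aggregates_equal_segment(self):
        df = self.per_segment(1)
        rep = summarize(df, {w: [0.01] for w in "qrst"})
        assert rep.mean_pcc == df["pcc"][0]
        assert rep.mean_rmse == df["rmse"][0]

    def test_cdf_properties(self):
        rep = summarize(self.per_segment(7), {w: [] for w in "qrst"})
        for table in rep.cdf.values():
            frac = table["cum_fraction"].to_numpy()
            assert frac[-1] == 1.0
            assert np.all(np.diff(frac) >= 0)
            assert np.all(np.diff(table["value"].to_numpy()) >= 0)

    def test_per_scenario_grouping(self):
        df = self.per_segment(4)
        df.loc[2:, "scenario"] = "Supine-CSR-Ap"
        rep = summarize(df, {w: [] for w in "qrst"})
        assert set(rep.per_scenario["scenario"]) == {"Sitting-CR-Eu",
                                                     "Supine-CSR-Ap"}

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize(pd.DataFrame(), {})
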