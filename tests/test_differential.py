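"""Thermal-shift vs abundance statistics, distance score, CETSA path."""

import math

import numpy as np
import pandas as pd
import pytest

import tppmelt as tp
from tppmelt.differential import MIN_P, analyze_protein, distance_score
from tppmelt.io import RunConfig


def _single_protein_matrix(spec, noise, seed=1):
    matrix, truths = tp.simulate_tr_experiment(1, spec, noise, seed=seed)
    return matrix, truths[0]


def _pt_frame(rows):
    return pd.DataFrame(rows, columns=["temperature", "log2_ratio", "p",
                                       "n_pairs", "zero_variance"])


class TestPerTemperatureTests:
    def test_identical_arms_null(self, noiseless, homogeneous_spec):
        matrix, _ = _single_protein_matrix(
            homogeneous_spec({"unaffected": 1.0}), noiseless)
        row = matrix.values.iloc[0]
        out = tp.per_temperature_tests(row, matrix.samples)
        np.testing.assert_allclose(out["log2_ratio"], 0.0, atol=1e-12)
        np.testing.assert_allclose(out["p"], 1.0)

    def test_exact_twofold_flagged_degenerate(self, noiseless,
                                              homogeneous_spec):
        matrix, _ = _single_protein_matrix(
            homogeneous_spec({"abundance_up": 1.0}), noiseless)
        row = matrix.values.iloc[0]
        out = tp.per_temperature_tests(row, matrix.samples)
        np.testing.assert_allclose(out["log2_ratio"], 1.0, atol=1e-12)
        assert (out["p"] == MIN_P).all()
        assert out["zero_variance"].all()

    def test_null_pvalues_uniform(self):
        # calibration: with true ratio 0 the paired t-test p-values are
        # uniform (KS test over a pooled null cohort)
        from scipy.stats import kstest
        noise = tp.NoiseModel(cv=0.1, sample_scale_sd=0.0, missing_rate=0.0)
        matrix, _ = tp.simulate_tr_experiment(200, noise=noise, seed=17)
        ps = []
        for pid in matrix.protein_ids:
            out = tp.per_temperature_tests(matrix.values.loc[pid],
                                           matrix.samples)
            ps.extend(out["p"].dropna())
        assert kstest(ps, "uniform").pvalue > 0.01


class TestDeltaTm:
    def test_identical_arms_zero_shift(self, noiseless, homogeneous_spec):
        matrix, _ = _single_protein_matrix(
            homogeneous_spec({"unaffected": 1.0}), noiseless)
        dtm, p, t, n = tp.compute_delta_tm(matrix.values.iloc[0],
                                           matrix.samples)
        assert dtm == pytest.approx(0.0, abs=1e-6)
        assert n == 3

    def test_noiseless_exact_recovery(self, noiseless, homogeneous_spec):
        matrix, truth = _single_protein_matrix(
            homogeneous_spec({"stabilized": 1.0}), noiseless)
        dtm, p, t, n = tp.compute_delta_tm(matrix.values.iloc[0],
                                           matrix.samples)
        assert dtm == pytest.approx(2.0, abs=1e-3)


class TestAbundanceChange:
    def test_stability_does_not_leak_into_abundance(self, noiseless,
                                                    homogeneous_spec):
        matrix, _ = _single_protein_matrix(
            homogeneous_spec({"stabilized": 1.0}), noiseless)
        # the only residual is the sigmoid's (not exactly flat) low-T tail
        lfc, p, t = tp.abundance_change(matrix.values.iloc[0], matrix.samples)
        assert lfc == pytest.approx(0.0, abs=1e-3)

    def test_noiseless_abundance_recovery(self, noiseless, homogeneous_spec):
        matrix, _ = _single_protein_matrix(
            homogeneous_spec({"abundance_up": 1.0}), noiseless)
        lfc, p, t = tp.abundance_change(matrix.values.iloc[0], matrix.samples)
        assert lfc == pytest.approx(1.0, abs=1e-9)


class TestDistanceScore:
    def test_no_significant_temperature_scores_zero(self):
        frame = _pt_frame([(40.0, 1.0, 0.5, 3, False)])
        score, ratio = distance_score(frame, alpha=0.05)
        assert score == 0.0

    def test_single_significant_temperature(self):
        frame = _pt_frame([(40.0, 1.0, 0.01, 3, False)])
        score, ratio = distance_score(frame, alpha=0.05)
        assert score == pytest.approx(1.0)
        assert ratio == pytest.approx(2.0)

    def test_two_significant_temperatures_euclidean(self):
        frame = _pt_frame([(40.0, 1.0, 0.01, 3, False),
                           (50.0, 1.0, 0.01, 3, False),
                           (60.0, 5.0, 0.9, 3, False)])
        score, ratio = distance_score(frame, alpha=0.05)
        assert score == pytest.approx(math.sqrt(2.0))
        assert ratio == pytest.approx(2.0)

    def test_negative_effect_negative_score(self):
        frame = _pt_frame([(40.0, -1.0, 0.01, 3, False)])
        score, _ = distance_score(frame, alpha=0.05)
        assert score == pytest.approx(-1.0)


class TestClassify:
    def test_double_null_is_none(self):
        assert tp.classify_protein(1.0, 0.5, 1.0, 1.0, 0.5, 1.0) == "none"

    def test_dominant_effect_wins(self):
        # stability t-statistic larger -> stabilized primary
        assert tp.classify_protein(2.0, 0.001, 9.0, 1.0, 0.01, 3.0) == "stabilized"
        assert tp.classify_protein(-2.0, 0.001, -9.0, 1.0, 0.5, 1.0) == "destabilized"
        assert tp.classify_protein(0.1, 0.5, 0.5, -1.0, 0.001, -8.0) == "abundance_down"


class TestInvariances:
    def test_scale_invariance_of_results(self):
        matrix, _ = tp.simulate_tr_experiment(
            5, tp.TruthSpec(proportions={"stabilized": 1.0}),
            tp.NoiseModel(cv=0.05, sample_scale_sd=0.0), seed=3)
        config = RunConfig()
        base = [analyze_protein(matrix.values.loc[p], matrix.samples, config)
                for p in matrix.protein_ids]
        scaled_matrix = tp.IntensityMatrix(matrix.values * 7.0, matrix.samples)
        scaled = [analyze_protein(scaled_matrix.values.loc[p],
                                  scaled_matrix.samples, config)
                  for p in scaled_matrix.protein_ids]
        for b, s in zip(base, scaled):
            assert s.delta_tm == pytest.approx(b.delta_tm, abs=1e-4)
            assert s.abundance_log2fc == pytest.approx(b.abundance_log2fc,
                                                       rel=1e-9)
            assert s.distance_score == pytest.approx(b.distance_score,
                                                     rel=1e-9)

    def test_arm_swap_antisymmetry(self):
        matrix, _ = tp.simulate_tr_experiment(
            3, tp.TruthSpec(proportions={"stabilized": 1.0}),
            tp.NoiseModel(cv=0.05, sample_scale_sd=0.0), seed=6)
        config = RunConfig()
        swapped_ann = matrix.samples.copy()
        swapped_ann["treatment"] = swapped_ann["treatment"].map(
            {"compound": "vehicle", "vehicle": "compound"})
        for pid in matrix.protein_ids:
            fwd = analyze_protein(matrix.values.loc[pid], matrix.samples,
                                  config)
            rev = analyze_protein(matrix.values.loc[pid], swapped_ann, config)
            assert rev.delta_tm == pytest.approx(-fwd.delta_tm, abs=1e-4)
            assert rev.abundance_log2fc == pytest.approx(
                -fwd.abundance_log2fc, rel=1e-9)
            assert rev.distance_score == pytest.approx(
                -fwd.distance_score, rel=1e-6)


class TestAnalyzeTr:
    def test_cohort_flags_and_classes(self):
        spec = tp.TruthSpec(
            proportions={"unaffected": 0.5, "abundance_up": 0.5})
        matrix, truths = tp.simulate_tr_experiment(
            30, spec, tp.NoiseModel(cv=0.05, sample_scale_sd=0.0), seed=12)
        results = tp.analyze_tr(matrix)
        classes = {t.protein_id: t.affected_class for t in truths}
        up = results.loc[[p for p, c in classes.items()
                          if c == "abundance_up"]]
        null = results.loc[[p for p, c in classes.items()
                            if c == "unaffected"]]
        assert up["significant"].mean() > 0.8
        assert (up["effect_class"] == "abundance_up").mean() > 0.8
        assert null["significant"].mean() < 0.2


class TestCetsa:
    def _series(self, delta_tm=0.0, scale=None, seed=0):
        rng = np.random.default_rng(seed)
        grid = tp.make_temperature_grid()
        rows = []
        for arm, shift in (("vehicle", 0.0), ("compound", delta_tm)):
            for rep in (1, 2, 3):
                params = tp.MeltingParams(0.0, 1.0, 51.0 + shift, -0.5)
                y = params.predict(np.array(grid))
                y = y * np.exp(rng.normal(0, 0.02, len(grid)))
                factor = scale.get((arm, rep), 1.0) if scale else 1.0
                for t, v in zip(grid, y * factor):
                    rows.append({"treatment": arm, "replicate": rep,
                                 "temperature": t, "intensity": v})
        return pd.DataFrame(rows)

    def test_unit_plateau_normalization_is_identity(self):
        series = self._series()
        result = tp.analyze_cetsa(series)
        assert result.delta_tm == pytest.approx(0.0, abs=0.3)

    def test_invariant_to_rescaling_one_series(self):
        base = tp.analyze_cetsa(self._series(delta_tm=2.0, seed=4))
        scaled = tp.analyze_cetsa(self._series(
            delta_tm=2.0, scale={("compound", 2): 37.5}, seed=4))
        assert scaled.delta_tm == pytest.approx(base.delta_tm, abs=1e-6)
        pd.testing.assert_frame_equal(scaled.per_temperature,
                                      base.per_temperature)

    def test_thermal_shift_recovered(self):
        result = tp.analyze_cetsa(self._series(delta_tm=2.0, seed=4))
        assert result.delta_tm == pytest.approx(2.0, abs=0.5)
        assert result.effect_class == "stabilized"

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="column"):
            tp.analyze_cetsa(pd.DataFrame({"temperature": [1.0]}))
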