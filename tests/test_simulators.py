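import itertools
import json

import numpy as np
import pytest
from scipy import stats

from epimine.simulators import (
    F2_MODELS,
    F2EpistasisModel,
    SimulationConfig,
    TruthRecord,
    TwoLocusOddsModel,
    _hwe_probs,
    f2_expected_ratio,
    odds_table,
    simulate_case_control,
    simulate_f2,
    solve_alpha,
)

GRID_THETAS = (0.2, 0.3, 0.5, 0.7)
GRID_MAFS = (0.05, 0.1, 0.2, 0.5)


class TestOddsTable:
    @pytest.mark.parametrize("alpha,theta", [(0.1, 0.5), (1 / 9, 0.7), (0.03, 0.2)])
    def test_model1_multiplicative(self, alpha, theta):
        tab = odds_table(1, alpha, theta)
        for i, j in itertools.product(range(3), repeat=2):
            assert tab[i, j] == pytest.approx(alpha * (1 + theta) ** (i + j))

    @pytest.mark.parametrize("alpha,theta", [(0.1, 0.5), (0.08, 0.7)])
    def test_model2_threshold_then_multiplicative(self, alpha, theta):
        tab = odds_table(2, alpha, theta)
        for i, j in itertools.product(range(3), repeat=2):
            if i == 0 or j == 0:
                assert tab[i, j] == alpha
            else:
                assert tab[i, j] == pytest.approx(alpha * (1 + theta) ** (i * j))
        assert tab[2, 2] == pytest.approx(alpha * (1 + theta) ** 4)

    @pytest.mark.parametrize("alpha,theta", [(0.1, 0.5), (0.08, 0.7)])
    def test_model3_pure_threshold(self, alpha, theta):
        tab = odds_table(3, alpha, theta)
        for i, j in itertools.product(range(3), repeat=2):
            expected = alpha if (i == 0 or j == 0) else alpha * (1 + theta)
            assert tab[i, j] == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            odds_table(4, 0.1, 0.5)
        with pytest.raises(ValueError):
            odds_table(1, -0.1, 0.5)


class TestSolveAlpha:
    def test_theta_zero_closed_form(self):
        assert solve_alpha(1, 0.0, 0.2, 0.2, 0.1) == pytest.approx(1 / 9)

    def prevalence_of(self, model_id, alpha, theta, maf):
        odds = odds_table(model_id, alpha, theta)
        pen = odds / (1 + odds)
        joint = np.outer(_hwe_probs(maf), _hwe_probs(maf))
        return float((joint * pen).sum())

    @pytest.mark.parametrize("model_id", [1, 2, 3])
    def test_prevalence_equation_across_grid(self, model_id):
        for theta, maf in itertools.product(GRID_THETAS, GRID_MAFS):
            alpha = solve_alpha(model_id, theta, maf, maf, 0.1)
            assert self.prevalence_of(model_id, alpha, theta, maf) == pytest.approx(
                0.1, abs=1e-10
            )

    def test_alpha_decreases_with_effect(self):
        a_small = solve_alpha(1, 0.2, 0.3, 0.3, 0.1)
        a_large = solve_alpha(1, 0.7, 0.3, 0.3, 0.1)
        assert a_large < a_small

    def test_invalid_prevalence(self):
        with pytest.raises(ValueError):
            solve_alpha(1, 0.5, 0.2, 0.2, 1.5)


class TestRetrospectiveSampling:
    def test_case_frequencies_match_analytic_law(self):
        model = TwoLocusOddsModel.from_prevalence(2, 0.7, 0.3, 0.3, 0.1)
        cfg = SimulationConfig(
            model_id=2, theta=0.7, maf_a=0.3, maf_b=0.3,
            n_cases=100_000, n_controls=100, m_null_snps=0, seed=21,
        )
        gm, phen, truth = simulate_case_control(cfg, model)
        ia, ib = truth.causal_indices
        cells = gm.genotypes[phen.case_mask, ia] * 3 + gm.genotypes[phen.case_mask, ib]
        observed = np.bincount(cells, minlength=9)
        joint = np.outer(_hwe_probs(0.3), _hwe_probs(0.3)).ravel()
        pen = model.penetrance.ravel()
        p_case = joint * pen / (joint * pen).sum()
        # chi-square goodness of fit at n = 1e5
        chi2 = ((observed - 100_000 * p_case) ** 2 / (100_000 * p_case)).sum()
        assert stats.chi2.sf(chi2, df=8) > 1e-4

    def test_null_effect_gives_equal_distributions(self):
        model = TwoLocusOddsModel.from_prevalence(1, 0.0, 0.2, 0.2, 0.1)
        cfg = SimulationConfig(
            model_id=1, theta=0.0, maf_a=0.2, maf_b=0.2,
            n_cases=20_000, n_controls=20_000, m_null_snps=0, seed=22,
        )
        gm, phen, truth = simulate_case_control(cfg, model)
        ia, ib = truth.causal_indices
        cells = gm.genotypes[:, ia] * 3 + gm.genotypes[:, ib]
        case_counts = np.bincount(cells[phen.case_mask], minlength=9)
        ctrl_counts = np.bincount(cells[phen.control_mask], minlength=9)
        table = np.vstack([case_counts, ctrl_counts])
        keep = table.sum(0) > 0
        chi2, p, _, _ = stats.chi2_contingency(table[:, keep], correction=False)
        assert p > 1e-3

    def test_prevalence_conservation(self):
        # mixing case/control genotype laws at (p, 1-p) recovers HWE
        model = TwoLocusOddsModel.from_prevalence(3, 0.5, 0.2, 0.5, 0.1)
        joint = np.outer(_hwe_probs(0.2), _hwe_probs(0.5))
        pen = model.penetrance
        p_case = joint * pen / 0.1
        p_ctrl = joint * (1 - pen) / 0.9
        np.testing.assert_allclose(
            0.1 * p_case + 0.9 * p_ctrl, joint, atol=1e-9
        )
        assert p_case.sum() == pytest.approx(1.0, abs=1e-9)

    def test_shapes_and_truth_record(self):
        cfg = SimulationConfig(
            model_id=1, theta=0.5, maf_a=0.1, maf_b=0.1,
            n_cases=50, n_controls=60, m_null_snps=30, seed=23,
        )
        gm, phen, truth = simulate_case_control(cfg)
        assert (gm.n_samples, gm.m_variants) == (110, 32)
        assert phen.n_cases == 50 and phen.n_controls == 60
        ia, ib = truth.causal_indices
        assert gm.variant_ids[ia] == truth.causal_ids[0]
        rt = TruthRecord.from_json(truth.to_json())
        assert rt == truth

    def test_seed_reproducibility(self):
        cfg = SimulationConfig(seed=7, n_cases=30, n_controls=30, m_null_snps=10)
        a = simulate_case_control(cfg)
        b = simulate_case_control(cfg)
        np.testing.assert_array_equal(a[0].genotypes, b[0].genotypes)

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            SimulationConfig(maf_a=0.7)
        with pytest.raises(ValueError):
            SimulationConfig(prevalence=0.0)


class TestF2:
    def test_classical_ratios(self):
        expected = {
            "no_interaction": {"A_B_": 9, "A_bb": 3, "aaB_": 3, "aabb": 1},
            "dominant_epistasis": {"A_": 12, "aaB_": 3, "aabb": 1},
            "recessive_epistasis": {"A_B_": 9, "A_bb": 3, "aa": 4},
            "duplicate_cumulative": {"both": 9, "one": 6, "neither": 1},
            "duplicate_dominant": {"altered": 15, "wild": 1},
            "duplicate_recessive": {"altered": 7, "wild": 9},
            "dominant_recessive_interaction": {"majority": 13, "minority": 3},
        }
        for name, want in expected.items():
            assert f2_expected_ratio(F2_MODELS[name]) == want

    def test_affected_fraction_duplicate_dominant(self):
        gm, phen, truth = simulate_f2("duplicate_dominant", 32_000, 0, seed=31)
        assert phen.n_cases / phen.n_samples == pytest.approx(15 / 16, abs=0.01)

    def test_exhaustive_census(self):
        # all 16 gamete combinations exactly once: affected count equals the
        # ratio numerator
        model = F2_MODELS["duplicate_recessive"]
        gametes = [(a1 + a2, b1 + b2)
                   for a1 in (0, 1) for a2 in (0, 1)
                   for b1 in (0, 1) for b2 in (0, 1)]
        gi = np.array([g[0] for g in gametes])
        gj = np.array([g[1] for g in gametes])
        assert int(model.phenotype(gi, gj).sum()) == 7

    def test_rule_consistency_per_sample(self):
        gm, phen, truth = simulate_f2("dominant_recessive_interaction", 300, 20, seed=33)
        ia, ib = truth.causal_indices
        model = F2_MODELS["dominant_recessive_interaction"]
        np.testing.assert_array_equal(
            phen.labels, model.phenotype(gm.genotypes[:, ia], gm.genotypes[:, ib])
        )

    def test_multiclass_model_rejected_for_case_control(self):
        with pytest.raises(ValueError, match="phenotype classes"):
            simulate_f2("no_interaction", 100, 10, seed=1)

    def test_null_snps_segregate_one_two_one(self):
        gm, phen, truth = simulate_f2("duplicate_dominant", 4000, 5, seed=35)
        null_col = [j for j in range(7) if j not in truth.causal_indices][0]
        counts = np.bincount(gm.genotypes[:, null_col], minlength=3)
        chi2 = ((counts - 4000 * np.array([0.25, 0.5, 0.25])) ** 2
                / (4000 * np.array([0.25, 0.5, 0.25]))).sum()
        assert stats.chi2.sf(chi2, 2) > 1e-4


def test_truth_record_json_round_trip():
    t = TruthRecord((3, 9), ("snp3", "snp9"), "f2_duplicate_dominant",
                    {"n_samples": 180}, 5)
    s = t.to_json()
    assert json.loads(s)["causal_ids"] == ["snp3", "snp9"]
    assert TruthRecord.from_json(s) == t
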