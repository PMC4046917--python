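import itertools

import numpy as np
import pytest

from epimine.assoc_tests import single_marker_tests_all
from epimine.conditional_permutation import (
    ThresholdLookupTable,
    _RegularPairNullEngine,
    _spawn_seeds,
    build_threshold_table,
    call_significant,
    conditional_permutation_null,
    marginal_bin,
    min_contingency_p,
    regular_permutation_null,
)
from epimine.genotype_data import GenotypeMatrix, PhenotypeVector
from epimine.pattern_mining import MinerConfig, mine_patterns
from epimine.simulators import SimulationConfig, simulate_case_control

from conftest import make_matrix, random_dataset

LOOSE = MinerConfig(report_p_threshold=0.3, grow_p_threshold=0.3)


class TestRegularNull:
    def test_seed_determinism(self):
        gm, phen = random_dataset(15, 15, 6, seed=41)
        a = regular_permutation_null(gm, phen, LOOSE, B=3, seed=9)
        b = regular_permutation_null(gm, phen, LOOSE, B=3, seed=9)
        np.testing.assert_array_equal(a.min_p_samples, b.min_p_samples)

    def test_tiny_n_matches_enumeration_oracle(self):
        # n=5 (2 cases, 3 controls): only C(5,2)=10 distinct label
        # arrangements exist; sampled minima must realise exactly the
        # enumerated value set
        rng = np.random.default_rng(0)
        geno = rng.integers(0, 3, size=(5, 3)).astype(np.int8)
        gm = make_matrix(geno)
        phen = PhenotypeVector(np.array([1, 1, 0, 0, 0], dtype=np.int8))
        cfg = MinerConfig(
            report_p_threshold=0.9999, grow_p_threshold=1.0, min_support=0.0
        )
        oracle = set()
        for case_pos in itertools.combinations(range(5), 2):
            labels = np.zeros(5, dtype=np.int8)
            labels[list(case_pos)] = 1
            oracle.add(
                round(min_contingency_p(gm, PhenotypeVector(labels), cfg, 1), 12)
            )
        null = regular_permutation_null(gm, phen, cfg, B=150, seed=3, rare_min_count=1)
        sampled = {round(v, 12) for v in null.min_p_samples}
        assert sampled == oracle

    def test_engine_matches_naive_path(self):
        gm, phen = random_dataset(60, 60, 12, seed=42)
        cfg = MinerConfig(report_p_threshold=0.2)
        eng = _RegularPairNullEngine(gm, phen, cfg)
        rng = np.random.default_rng(5)
        for _ in range(8):
            labels = phen.labels[rng.permutation(phen.n_samples)]
            assert eng.min_p(labels) == pytest.approx(
                min_contingency_p(gm, PhenotypeVector(labels), cfg), abs=1e-14
            )

    def test_critical_value_is_lower_quantile(self):
        null = regular_permutation_null(
            *random_dataset(12, 12, 4, seed=43), LOOSE, B=19, seed=1
        )
        k = int(np.floor(0.05 * 20))  # = 1 -> smallest sample
        assert null.critical_value(0.05) == np.sort(null.min_p_samples)[k - 1]
        assert 0 < null.empirical_p(0.5) <= 1


class TestConditionalNull:
    def test_marginal_table_invariant_in_every_replicate(self):
        gm, phen = random_dataset(40, 40, 8, seed=44)
        j = 3
        observed = single_marker_tests_all(gm, phen)[j]
        B, seed = 12, 6
        # reproduce the permutation stream the null uses
        for s in _spawn_seeds(seed, B):
            rng = np.random.default_rng(s)
            perm = rng.permutation(phen.n_samples)
            gm_b = GenotypeMatrix(gm.genotypes.copy(), gm.variant_ids, gm.alleles)
            gm_b.genotypes[:, j] = gm.genotypes[perm, j]
            phen_b = PhenotypeVector(phen.labels[perm])
            assert single_marker_tests_all(gm_b, phen_b)[j] == pytest.approx(
                observed, rel=1e-12
            )

    def test_monomorphic_conditioning_equals_regular_null(self):
        gm, phen = random_dataset(25, 25, 6, seed=45)
        geno = gm.genotypes.copy()
        geno[:, 2] = 1  # conditioning on a constant column is vacuous
        gm = make_matrix(geno)
        reg = regular_permutation_null(gm, phen, LOOSE, B=10, seed=4)
        cond = conditional_permutation_null(gm, phen, 2, LOOSE, B=10, seed=4)
        np.testing.assert_allclose(cond.min_p_samples, reg.min_p_samples)

    def test_engine_matches_naive_path(self):
        gm, phen = random_dataset(50, 50, 10, seed=46)
        cfg = MinerConfig(report_p_threshold=0.2)
        fast = conditional_permutation_null(gm, phen, 4, cfg, B=6, seed=2)
        # force the naive path by breaking engine applicability via missing
        geno = gm.genotypes.copy()
        gm2 = make_matrix(geno)
        assert _RegularPairNullEngine.applicable(gm2, cfg)
        eng = _RegularPairNullEngine(gm2, phen, cfg)
        naive = np.empty(6)
        for b, s in enumerate(_spawn_seeds(2, 6)):
            rng = np.random.default_rng(s)
            perm = rng.permutation(phen.n_samples)
            gm_b = GenotypeMatrix(gm.genotypes.copy(), gm.variant_ids, gm.alleles)
            gm_b.genotypes[:, 4] = gm.genotypes[perm, 4]
            naive[b] = min_contingency_p(
                gm_b, PhenotypeVector(phen.labels[perm]), cfg
            )
        np.testing.assert_allclose(fast.min_p_samples, naive, atol=1e-14)

    def test_unknown_variant_rejected(self):
        gm, phen = random_dataset(10, 10, 3, seed=47)
        with pytest.raises(KeyError):
            conditional_permutation_null(gm, phen, "nope", LOOSE, B=1, seed=0)

    def test_strong_marginal_conditioning_shifts_null_down(self):
        # planting a strong-marginal variant makes the conditional null's
        # minima stochastically smaller than the regular null's: marginal
        # leakage alone produces extreme contingency tables
        rng = np.random.default_rng(48)
        n = 300
        geno = rng.integers(0, 3, size=(2 * n, 30)).astype(np.int8)
        labels = np.r_[np.ones(n, dtype=np.int8), np.zeros(n, dtype=np.int8)]
        strong = np.where(rng.random(2 * n) < 0.35, labels * 2, rng.integers(0, 3, 2 * n))
        geno[:, 0] = strong
        gm = make_matrix(geno)
        phen = PhenotypeVector(labels)
        cfg = MinerConfig(report_p_threshold=0.05)
        reg = regular_permutation_null(gm, phen, cfg, B=40, seed=5)
        cond = conditional_permutation_null(gm, phen, 0, cfg, B=40, seed=5)
        assert np.median(cond.min_p_samples) < np.median(reg.min_p_samples)


class TestThresholdTable:
    def test_marginal_bins(self):
        assert marginal_bin(0.5) == 0
        assert marginal_bin(2e-3) == 0
        assert marginal_bin(5e-4) == 1
        assert marginal_bin(1e-3) == 1  # bins are (10^-(k+3), 10^-(k+2)]
        assert marginal_bin(5e-5) == 2
        assert marginal_bin(3e-7) == 4

    def test_amd_like_spectrum_instantiates_five_bins(self):
        # marginal-p spectrum shaped like a real GWAS: 62 variants in
        # (1e-4,1e-3], 8 in (1e-5,1e-4], 1 in (1e-6,1e-5], 1 in (1e-7,1e-6],
        # the rest above 1e-3 -> 5 lookup bins
        gm, phen = random_dataset(20, 20, 100, seed=49)
        marg = np.full(100, 0.5)
        marg[:62] = 5e-4
        marg[62:70] = 5e-5
        marg[70] = 5e-6
        marg[71] = 5e-7
        table = build_threshold_table(
            gm, phen, LOOSE, B=2, seed=1, marginal_p=marg
        )
        assert sorted(table.entries) == [0, 1, 2, 3, 4]

    def test_single_bin_lookup(self):
        gm, phen = random_dataset(15, 15, 5, seed=50)
        table = build_threshold_table(
            gm, phen, LOOSE, B=5, seed=2, marginal_p=np.full(5, 0.4)
        )
        assert list(table.entries) == [0]
        crit = table.entries[0]["critical_value"]
        assert table.lookup(0.9) == crit
        # unseen bins fall back to the nearest built one
        assert table.lookup(1e-6) == crit

    def test_null_bin_matches_regular_null_critical(self):
        gm, phen = random_dataset(40, 40, 10, seed=51)
        cfg = MinerConfig(report_p_threshold=0.3)
        table = build_threshold_table(gm, phen, cfg, B=30, seed=3)
        reg = regular_permutation_null(gm, phen, cfg, B=30, seed=12)
        crit_cond = table.entries[0]["critical_value"]
        crit_reg = reg.critical_value(0.05)
        # all-null data: same statistic, same alpha -> agreement within
        # Monte-Carlo error (order of magnitude on the p scale)
        assert 0.05 < crit_cond / crit_reg < 20

    def test_tsv_round_trip(self):
        table = ThresholdLookupTable(0.05, 10, 3)
        table.entries[0] = {
            "conditioning_variant": "v1", "marginal_p": 0.2, "critical_value": 1e-3,
        }
        table.entries[2] = {
            "conditioning_variant": "v7", "marginal_p": 3e-5, "critical_value": 2e-6,
        }
        back = ThresholdLookupTable.from_tsv(table.to_tsv())
        assert back.fwer_alpha == 0.05 and back.B == 10 and back.seed == 3
        assert back.entries.keys() == table.entries.keys()
        assert back.entries[2]["critical_value"] == pytest.approx(2e-6)

    def test_empty_data_rejected(self):
        gm, phen = random_dataset(5, 5, 2, seed=52)
        empty = gm.take_variants(np.array([], dtype=int))
        with pytest.raises(ValueError, match="empty"):
            build_threshold_table(empty, phen, LOOSE, B=1, seed=0)


class TestCallSignificant:
    def _setup(self):
        gm, phen, truth = simulate_case_control(
            SimulationConfig(model_id=2, theta=0.7, maf_a=0.5, maf_b=0.5,
                             n_cases=600, n_controls=600, m_null_snps=28, seed=53)
        )
        cfg = MinerConfig()
        patterns = mine_patterns(gm, phen, cfg)
        marginal = dict(zip(gm.variant_ids, single_marker_tests_all(gm, phen)))
        return gm, phen, truth, cfg, patterns, marginal

    def test_calls_pass_their_bin_threshold(self):
        gm, phen, truth, cfg, patterns, marginal = self._setup()
        table = build_threshold_table(gm, phen, cfg, B=30, seed=4)
        sig = call_significant(patterns, table, marginal, gm, phen)
        for s in sig:
            assert s.contingency.p <= s.critical_value

    def test_above_threshold_excluded_and_dedup(self):
        gm, phen, truth, cfg, patterns, marginal = self._setup()
        # a table whose thresholds are impossible to meet -> nothing called
        table = ThresholdLookupTable(0.05, 1, 0)
        table.entries[0] = {"conditioning_variant": "x", "marginal_p": 1.0,
                            "critical_value": 0.0}
        assert call_significant(patterns, table, marginal, gm, phen) == []
        # permissive table: each variant set reported once, patterns attached
        table.entries[0]["critical_value"] = 1.0
        sig = call_significant(patterns, table, marginal, gm, phen)
        sets = [s.variants for s in sig]
        assert len(sets) == len(set(sets))
        by_set = {s.variants: s for s in sig}
        causal = tuple(
            sorted(truth.causal_ids, key=lambda v: gm.variant_index(v))
        )
        assert causal in by_set
        assert len(by_set[causal].patterns) >= 1

    def test_missing_marginal_p_rejected(self):
        gm, phen, truth, cfg, patterns, marginal = self._setup()
        table = ThresholdLookupTable(0.05, 1, 0)
        table.entries[0] = {"conditioning_variant": "x", "marginal_p": 1.0,
                            "critical_value": 1.0}
        marginal.pop(truth.causal_ids[0], None)
        with pytest.raises(KeyError):
            call_significant(patterns, table, marginal, gm, phen)
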