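"""Replicated simulation experiments: coverage, FDR/power contrasts.

These drive the evaluation harness end to end — simulate, mine, calibrate,
call, score — at configurable scale.  Each experiment derives per-replicate
seeds from a master seed, so results are exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import cycle, product

import numpy as np

from .assoc_tests import pattern_contingency_test, single_marker_tests_all
from .conditional_permutation import (
    build_threshold_table,
    call_significant,
    marginal_bin,
    regular_permutation_null,
    _variant_sets,
)
from .evaluation import (
    EvaluationReport,
    coverage,
    fdr,
    power,
    single_marker_calls,
    single_marker_fwer_threshold,
)
from .pattern_mining import MinerConfig, exhaustive_search, mine_patterns
from .simulators import (
    F2_MODELS,
    SimulationConfig,
    simulate_case_control,
    simulate_f2,
)


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def coverage_experiment(
    n_datasets: int = 40,
    models=(1, 2, 3),
    thetas=(0.3, 0.7),
    mafs=(0.1, 0.5),
    n_cases: int = 1000,
    n_controls: int = 1000,
    m_null_snps: int = 198,
    cfg: MinerConfig | None = None,
    exhaustive_p: float = 1e-4,
    seed: int = 0,
) -> EvaluationReport:
    """Per-dataset coverage of the exhaustive pair search by the miner.

    Cycles through the (model, theta, MAF) grid until ``n_datasets``
    replicates are simulated; coverage compares length-2 mined patterns
    against the exhaustive pair enumeration at ``exhaustive_p``.
    """
    if cfg is None:
        cfg = MinerConfig()
    seeds = _child_seeds(seed, n_datasets)
    covs = []
    for s, (model, theta, maf) in zip(seeds, cycle(product(models, thetas, mafs))):
        gm, phen, _ = simulate_case_control(
            SimulationConfig(
                model_id=model, theta=theta, maf_a=maf, maf_b=maf,
                n_cases=n_cases, n_controls=n_controls,
                m_null_snps=m_null_snps, seed=int(s),
            )
        )
        mined = [p for p in mine_patterns(gm, phen, cfg) if p.length == 2]
        exh = exhaustive_search(gm, phen, length=2, p_threshold=exhaustive_p)
        covs.append(coverage(mined, exh))
    return EvaluationReport(
        coverage_per_dataset=covs,
        n_replicates=n_datasets,
        config={
            "models": list(models), "thetas": list(thetas), "mafs": list(mafs),
            "n_cases": n_cases, "n_controls": n_controls,
            "m_null_snps": m_null_snps, "seed": seed,
        },
    )


@dataclass
class FdrPowerContrast:
    """Regular- vs conditional-calibration calls on the same replicates."""

    fdr_regular: float
    fdr_conditional: float
    power2_regular: float
    power2_conditional: float
    power1_regular: float
    power1_conditional: float
    n_replicates: int
    n_calls_regular: int = 0
    n_calls_conditional: int = 0
    config: dict = field(default_factory=dict)


def fdr_power_experiment(
    n_datasets: int = 50,
    model: int = 2,
    theta: float = 0.5,
    maf: float = 0.2,
    n_cases: int = 500,
    n_controls: int = 500,
    m_null_snps: int = 198,
    B: int = 200,
    fwer_alpha: float = 0.05,
    cfg: MinerConfig | None = None,
    seed: int = 0,
) -> FdrPowerContrast:
    """Head-to-head FDR and power of regular vs conditional calibration.

    Per replicate both procedures score the same mined variant sets: the
    regular procedure against the single family-wise critical value of the
    label-permutation null, the conditional one against the per-bin
    thresholds of the conditional lookup table.
    """
    if cfg is None:
        cfg = MinerConfig()
    seeds = _child_seeds(seed, 3 * n_datasets).reshape(n_datasets, 3)
    calls_reg, calls_cond, truths = [], [], []
    for s_sim, s_tab, s_reg in seeds:
        gm, phen, truth = simulate_case_control(
            SimulationConfig(
                model_id=model, theta=theta, maf_a=maf, maf_b=maf,
                n_cases=n_cases, n_controls=n_controls,
                m_null_snps=m_null_snps, seed=int(s_sim),
            )
        )
        truths.append(truth)
        patterns = mine_patterns(gm, phen, cfg)
        sets = _variant_sets(patterns)
        contingency = {
            vs: pattern_contingency_test(vs, gm, phen) for vs in sets
        }
        marginal = dict(zip(gm.variant_ids, single_marker_tests_all(gm, phen)))

        null_reg = regular_permutation_null(gm, phen, cfg, B=B, seed=int(s_reg))
        crit_reg = null_reg.critical_value(fwer_alpha)
        calls_reg.append([vs for vs, tab in contingency.items() if tab.p <= crit_reg])

        table = build_threshold_table(
            gm, phen, cfg, fwer_alpha=fwer_alpha, B=B, seed=int(s_tab),
            marginal_p=np.array([marginal[v] for v in gm.variant_ids]),
        )
        sig = call_significant(patterns, table, marginal, gm, phen)
        calls_cond.append([s.variants for s in sig])
    return FdrPowerContrast(
        fdr_regular=fdr(calls_reg, truths),
        fdr_conditional=fdr(calls_cond, truths),
        power2_regular=power(calls_reg, truths, 2),
        power2_conditional=power(calls_cond, truths, 2),
        power1_regular=power(calls_reg, truths, 1),
        power1_conditional=power(calls_cond, truths, 1),
        n_replicates=n_datasets,
        n_calls_regular=sum(len(c) for c in calls_reg),
        n_calls_conditional=sum(len(c) for c in calls_cond),
        config={
            "model": model, "theta": theta, "maf": maf, "B": B,
            "n_cases": n_cases, "n_controls": n_controls,
            "m_null_snps": m_null_snps, "fwer_alpha": fwer_alpha, "seed": seed,
        },
    )


@dataclass
class PowerComparison:
    """Miner vs single-marker power over replicates of one design."""

    miner_power2: float
    single_marker_power1: float
    single_marker_power2: float
    n_replicates: int
    config: dict = field(default_factory=dict)


def _causal_pair_call(gm, phen, truth, cfg, B, fwer_alpha, seed) -> bool:
    """Did the conditional-calibration pipeline call the causal pair?

    Level-2 power only depends on the causal set, so only its own
    marginal-p bin of the lookup table is built.
    """
    anchor = min(truth.causal_ids, key=gm.variant_index)
    patterns = mine_patterns(gm, phen, cfg, restrict_to_variant=anchor)
    causal = set(truth.causal_ids)
    pats = [p for p in patterns if set(p.variants) == causal]
    if not pats:
        return False
    vset = pats[0].variants
    marginal = dict(zip(gm.variant_ids, single_marker_tests_all(gm, phen)))
    best = min(marginal[v] for v in vset)
    table = build_threshold_table(
        gm, phen, cfg, fwer_alpha=fwer_alpha, B=B, seed=seed,
        marginal_p=np.array([marginal[v] for v in gm.variant_ids]),
        only_bins={marginal_bin(float(best))},
    )
    tab = pattern_contingency_test(vset, gm, phen)
    return tab.p <= table.lookup(float(best))


def _power_comparison(datasets, cfg, B, B_single, fwer_alpha, seeds, config) -> PowerComparison:
    miner_calls, sm_l1, sm_l2, truths = [], [], [], []
    for (gm, phen, truth), (s_tab, s_sm) in zip(datasets, seeds):
        truths.append(truth)
        miner_calls.append(
            [truth.causal_ids]
            if _causal_pair_call(gm, phen, truth, cfg, B, fwer_alpha, int(s_tab))
            else []
        )
        thr = single_marker_fwer_threshold(
            gm, phen, B=B_single, alpha=fwer_alpha, seed=int(s_sm)
        )
        called = {v for (v,) in single_marker_calls(gm, phen, thr)}
        hits = called & set(truth.causal_ids)
        sm_l1.append(len(hits) >= 1)
        sm_l2.append(len(hits) == 2)
    return PowerComparison(
        miner_power2=power(miner_calls, truths, 2),
        single_marker_power1=float(np.mean(sm_l1)),
        single_marker_power2=float(np.mean(sm_l2)),
        n_replicates=len(truths),
        config=config,
    )


def odds_model_power_experiment(
    n_datasets: int = 25,
    model: int = 3,
    theta: float = 0.7,
    maf: float = 0.2,
    n_cases: int = 500,
    n_controls: int = 500,
    m_null_snps: int = 198,
    B: int = 100,
    B_single: int = 100,
    fwer_alpha: float = 0.05,
    cfg: MinerConfig | None = None,
    seed: int = 0,
) -> PowerComparison:
    """Level-2 power of the miner vs the single-marker comparator under a
    two-locus odds model."""
    if cfg is None:
        cfg = MinerConfig()
    seeds = _child_seeds(seed, 3 * n_datasets).reshape(n_datasets, 3)
    datasets = (
        simulate_case_control(
            SimulationConfig(
                model_id=model, theta=theta, maf_a=maf, maf_b=maf,
                n_cases=n_cases, n_controls=n_controls,
                m_null_snps=m_null_snps, seed=int(s[0]),
            )
        )
        for s in seeds
    )
    return _power_comparison(
        datasets, cfg, B, B_single, fwer_alpha, seeds[:, 1:],
        {
            "model": model, "theta": theta, "maf": maf, "B": B,
            "n_cases": n_cases, "n_controls": n_controls,
            "m_null_snps": m_null_snps, "seed": seed,
        },
    )


def f2_power_experiment(
    model: str = "dominant_recessive_interaction",
    n_datasets: int = 100,
    n_samples: int = 180,
    m_null_snps: int = 998,
    B: int = 25,
    B_single: int = 100,
    fwer_alpha: float = 0.05,
    cfg: MinerConfig | None = None,
    seed: int = 0,
) -> PowerComparison:
    """Miner vs single-marker power on F2 genotypes under a classical
    two-gene epistasis rule (single-marker level 2 = both causal loci
    individually pass the family-wise single-marker threshold)."""
    if cfg is None:
        cfg = MinerConfig()
    if model not in F2_MODELS:
        raise ValueError(f"unknown F2 model {model!r}")
    seeds = _child_seeds(seed, 3 * n_datasets).reshape(n_datasets, 3)
    datasets = (
        simulate_f2(model, n_samples=n_samples, m_null_snps=m_null_snps, seed=int(s[0]))
        for s in seeds
    )
    return _power_comparison(
        datasets, cfg, B, B_single, fwer_alpha, seeds[:, 1:],
        {
            "model": model, "n_samples": n_samples,
            "m_null_snps": m_null_snps, "B": B, "seed": seed,
        },
    )
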