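"""Evaluation metrics: coverage, Level-1/Level-2 power, and FDR.

*Coverage* measures how much of the exhaustive-search result the pruned
miner retains: |mined ∩ exhaustive| / |exhaustive| per dataset.

*Power* is counted over replicate datasets, each with one planted causal
pair: Level 1 = some significant call contains at least one causal
variant; Level 2 = some call contains both.

*FDR* pools significant calls over replicates: a call is a true discovery
only if it contains both causal variants; a set with no causal variant, or
exactly one causal variant padded with nulls, counts as false.  The
per-dataset average of the same ratio is reported alongside the pooled
value.

A single-marker comparator (genotypic test with its own
regular-permutation family-wise threshold) is included for the power
contrasts between marginal and interaction-based detection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .assoc_tests import single_marker_tests_all
from .genotype_data import GenotypeMatrix, PhenotypeVector


def coverage(mined, exhaustive) -> float:
    """|mined ∩ exhaustive| / |exhaustive|; 1.0 when exhaustive is empty.

    Accepts pattern objects (keyed by canonical items) or raw keys.
    """
    mset = {getattr(p, "key", p) for p in mined}
    eset = {getattr(p, "key", p) for p in exhaustive}
    if not eset:
        return 1.0
    return len(mset & eset) / len(eset)


def _is_true_call(call, causal: tuple) -> bool:
    vs = set(call)
    return set(causal) <= vs


def _hits_level(calls, causal: tuple, level: int) -> bool:
    if level == 2:
        return any(_is_true_call(c, causal) for c in calls)
    if level == 1:
        return any(set(c) & set(causal) for c in calls)
    raise ValueError("level must be 1 or 2")


def power(calls_per_replicate, truths, level: int) -> float:
    """Fraction of replicates whose calls detect the causal pair.

    ``calls_per_replicate`` is one list of called variant sets per
    replicate; ``truths`` gives each replicate's causal pair (a TruthRecord
    or a 2-tuple of variant ids).
    """
    if len(calls_per_replicate) != len(truths):
        raise ValueError("one truth record per replicate required")
    if not truths:
        raise ValueError("no replicates")
    hits = 0
    for calls, truth in zip(calls_per_replicate, truths):
        causal = tuple(getattr(truth, "causal_ids", truth))
        hits += _hits_level(calls, causal, level)
    return hits / len(truths)


def fdr(calls_per_replicate, truths, pooled: bool = True) -> float:
    """False discoveries / all discoveries; 0.0 when nothing is called.

    ``pooled=True`` pools calls over replicates; otherwise the mean of the
    per-dataset ratios (datasets without calls excluded from the mean,
    or 0.0 if none has calls).
    """
    if len(calls_per_replicate) != len(truths):
        raise ValueError("one truth record per replicate required")
    per_dataset = []
    false_tot = tot = 0
    for calls, truth in zip(calls_per_replicate, truths):
        causal = tuple(getattr(truth, "causal_ids", truth))
        n_false = sum(not _is_true_call(c, causal) for c in calls)
        false_tot += n_false
        tot += len(calls)
        if calls:
            per_dataset.append(n_false / len(calls))
    if pooled:
        return false_tot / tot if tot else 0.0
    return float(np.mean(per_dataset)) if per_dataset else 0.0


# --------------------------------------------------------------------------
# single-marker comparator


def single_marker_fwer_threshold(
    gm: GenotypeMatrix,
    phen: PhenotypeVector,
    B: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Family-wise per-variant p threshold by regular label permutation.

    The alpha-quantile of the permuted dataset-wise minimum single-marker
    p-value: the classical genome-wide calibration of the marginal test.
    """
    rng = np.random.default_rng(seed)
    mins = np.empty(B)
    for b in range(B):
        perm = rng.permutation(phen.n_samples)
        phen_b = PhenotypeVector(phen.labels[perm])
        mins[b] = single_marker_tests_all(gm, phen_b).min()
    k = max(1, int(np.floor(alpha * (B + 1))))
    return float(np.sort(mins)[min(k, B) - 1])


def single_marker_calls(
    gm: GenotypeMatrix, phen: PhenotypeVector, threshold: float
) -> list:
    """Variants whose genotypic-test p-value passes the threshold, returned
    as singleton variant sets for the power/FDR machinery."""
    pvals = single_marker_tests_all(gm, phen)
    return [(gm.variant_ids[j],) for j in np.flatnonzero(pvals <= threshold)]


@dataclass
class EvaluationReport:
    """Aggregated evaluation of one simulation design."""

    coverage_per_dataset: list = field(default_factory=list)
    power_level1: float | None = None
    power_level2: float | None = None
    fdr_pooled: float | None = None
    fdr_per_dataset_mean: float | None = None
    n_replicates: int = 0
    n_calls_total: int = 0
    config: dict = field(default_factory=dict)

    @property
    def mean_coverage(self) -> float | None:
        if not self.coverage_per_dataset:
            return None
        return float(np.mean(self.coverage_per_dataset))

    def to_json(self) -> str:
        d = {
            "n_replicates": self.n_replicates,
            "n_calls_total": self.n_calls_total,
            "mean_coverage": self.mean_coverage,
            "coverage_per_dataset": self.coverage_per_dataset,
            "power_level1": self.power_level1,
            "power_level2": self.power_level2,
            "fdr_pooled": self.fdr_pooled,
            "fdr_per_dataset_mean": self.fdr_per_dataset_mean,
            "config": self.config,
        }
        return json.dumps(d, indent=1)

    def to_tsv(self) -> str:
        rows = [
            ("n_replicates", self.n_replicates),
            ("n_calls_total", self.n_calls_total),
            ("mean_coverage", self.mean_coverage),
            ("power_level1", self.power_level1),
            ("power_level2", self.power_level2),
            ("fdr_pooled", self.fdr_pooled),
            ("fdr_per_dataset_mean", self.fdr_per_dataset_mean),
        ]
        lines = [f"{k}\t{'' if v is None else v}" for k, v in rows]
        return "\n".join(lines) + "\n"
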