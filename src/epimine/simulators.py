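"""Synthetic case/control data under two-locus interaction models.

Two families of generative models are provided.

**Two-locus odds models.**  Disease odds for the nine
genotype combinations at an interacting pair (A, B) follow one of three
3x3 tables parameterised by a baseline ``alpha`` and an effect ``theta``
(the grid parameter lambda is identified with theta):

* model 1 — multiplicative within and between loci:
  odds = alpha (1+theta)^(i+j), where i, j count disease alleles;
* model 2 — threshold then multiplicative: odds = alpha if i=0 or j=0,
  else alpha (1+theta)^(i*j);
* model 3 — threshold with no further increase: odds = alpha if i=0 or
  j=0, else alpha (1+theta).

``alpha`` is solved so the population prevalence equals a target (default
0.1) under Hardy-Weinberg genotype frequencies at both loci.  Case/control
genotypes at the causal pair are drawn retrospectively:
P(g|case) propto P_HWE(g) pi_g and P(g|control) propto P_HWE(g) (1-pi_g)
with penetrance pi_g = odds_g / (1+odds_g).  Null SNPs are HWE draws with
minor-allele frequencies from a configurable law, identical in both groups.

**F2 epistasis models** (classical breeding ratios).  Two unlinked loci
segregating 1:2:1 in an F2 population give 16 equally likely gamete
combinations; classical two-gene interaction rules partition them into
phenotype classes with integer ratios summing to 16 (e.g. duplicate
dominant 15:1, duplicate recessive 9:7).  The two-class rules double as
case/control phenotypes for mining.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .genotype_data import GenotypeMatrix, PhenotypeVector


def _hwe_probs(freq: float) -> np.ndarray:
    """P(genotype = 0,1,2 copies of the allele) under Hardy-Weinberg."""
    q = freq
    return np.array([(1 - q) ** 2, 2 * q * (1 - q), q * q])


def odds_table(model_id: int, alpha: float, theta: float) -> np.ndarray:
    """3x3 disease-odds table over (aa,Aa,AA) x (bb,Bb,BB).

    Row index i and column index j count copies of the disease alleles A
    and B respectively.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if theta <= -1:
        raise ValueError("theta must exceed -1")
    i = np.arange(3)[:, None]
    j = np.arange(3)[None, :]
    if model_id == 1:
        return alpha * (1.0 + theta) ** (i + j)
    if model_id == 2:
        return np.where((i == 0) | (j == 0), alpha, alpha * (1.0 + theta) ** (i * j))
    if model_id == 3:
        return np.where((i == 0) | (j == 0), alpha, alpha * (1.0 + theta))
    raise ValueError(f"unknown model_id {model_id}; expected 1, 2 or 3")


def _prevalence(model_id, alpha, theta, maf_a, maf_b) -> float:
    odds = odds_table(model_id, alpha, theta)
    pen = odds / (1.0 + odds)
    joint = np.outer(_hwe_probs(maf_a), _hwe_probs(maf_b))
    return float(np.sum(joint * pen))


def solve_alpha(
    model_id: int,
    theta: float,
    maf_a: float,
    maf_b: float,
    prevalence: float,
    tol: float = 1e-12,
) -> float:
    """Baseline odds alpha giving the target population prevalence.

    The population disease probability is strictly increasing in alpha, so
    the root is unique; solved by bracketed root-finding to ~1e-10 residual
    on the prevalence scale.
    """
    if not (0.0 < prevalence < 1.0):
        raise ValueError("prevalence must lie in (0, 1)")
    if theta == 0.0:
        return prevalence / (1.0 - prevalence)

    def f(a: float) -> float:
        return _prevalence(model_id, a, theta, maf_a, maf_b) - prevalence

    lo, hi = 1e-12, 1.0
    while f(hi) < 0:
        hi *= 10.0
        if hi > 1e12:
            raise RuntimeError("no root for alpha in (0, 1e12)")
    alpha = optimize.brentq(f, lo, hi, xtol=tol, rtol=8.9e-16)
    return float(alpha)


@dataclass
class TwoLocusOddsModel:
    """Disease-odds table for an interacting pair, with solved baseline."""

    model_id: int
    alpha: float
    theta: float
    odds: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.odds = odds_table(self.model_id, self.alpha, self.theta)

    @classmethod
    def from_prevalence(
        cls, model_id: int, theta: float, maf_a: float, maf_b: float,
        prevalence: float = 0.1,
    ) -> "TwoLocusOddsModel":
        alpha = solve_alpha(model_id, theta, maf_a, maf_b, prevalence)
        return cls(model_id, alpha, theta)

    @property
    def penetrance(self) -> np.ndarray:
        return self.odds / (1.0 + self.odds)


@dataclass
class SimulationConfig:
    """Design of one retrospective case/control simulation.

    Defaults follow the study design these models are evaluated under:
    prevalence 0.1, theta (lambda) on {0.2, 0.3, 0.5, 0.7}, disease-allele
    frequencies on {0.05, 0.1, 0.2, 0.5}, 1000 cases + 1000 controls, one
    causal pair among null SNPs whose MAFs are uniform on [0.05, 0.5].
    """

    model_id: int = 2
    theta: float = 0.5
    maf_a: float = 0.2
    maf_b: float = 0.2
    prevalence: float = 0.1
    n_cases: int = 1000
    n_controls: int = 1000
    m_null_snps: int = 998
    null_maf_low: float = 0.05
    null_maf_high: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must lie in (0, 1)")
        for maf in (self.maf_a, self.maf_b):
            if not (0.0 < maf <= 0.5):
                raise ValueError("causal MAFs must lie in (0, 0.5]")
        if min(self.n_cases, self.n_controls) <= 0:
            raise ValueError("sample counts must be positive")
        if self.m_null_snps < 0:
            raise ValueError("m_null_snps must be >= 0")


@dataclass
class TruthRecord:
    """Ground truth of one simulated dataset (causal columns + parameters)."""

    causal_indices: tuple
    causal_ids: tuple
    model: str
    params: dict
    seed: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "causal_indices": list(self.causal_indices),
                "causal_ids": list(self.causal_ids),
                "model": self.model,
                "params": self.params,
                "seed": self.seed,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "TruthRecord":
        d = json.loads(text)
        return cls(
            tuple(d["causal_indices"]),
            tuple(d["causal_ids"]),
            d["model"],
            d["params"],
            d["seed"],
        )


def _draw_retrospective_pair(
    model: TwoLocusOddsModel, maf_a: float, maf_b: float,
    n_cases: int, n_controls: int, rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Causal-pair genotype codes for cases then controls (columns ga, gb)."""
    joint = np.outer(_hwe_probs(maf_a), _hwe_probs(maf_b))
    pen = model.penetrance
    p_case = (joint * pen).ravel()
    p_case /= p_case.sum()
    p_ctrl = (joint * (1.0 - pen)).ravel()
    p_ctrl /= p_ctrl.sum()
    cells_case = rng.choice(9, size=n_cases, p=p_case)
    cells_ctrl = rng.choice(9, size=n_controls, p=p_ctrl)
    cells = np.concatenate([cells_case, cells_ctrl])
    return (cells // 3).astype(np.int8), (cells % 3).astype(np.int8)


def simulate_case_control(
    cfg: SimulationConfig, model: TwoLocusOddsModel | None = None
) -> tuple[GenotypeMatrix, PhenotypeVector, TruthRecord]:
    """Retrospective case/control sample with one planted interacting pair.

    Cases come first in sample order.  The two causal columns are placed at
    random positions among the null SNPs; their indices are recorded in the
    truth record.
    """
    if model is None:
        model = TwoLocusOddsModel.from_prevalence(
            cfg.model_id, cfg.theta, cfg.maf_a, cfg.maf_b, cfg.prevalence
        )
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_cases + cfg.n_controls
    m = cfg.m_null_snps + 2
    ga, gb = _draw_retrospective_pair(
        model, cfg.maf_a, cfg.maf_b, cfg.n_cases, cfg.n_controls, rng
    )
    null_mafs = rng.uniform(cfg.null_maf_low, cfg.null_maf_high, size=cfg.m_null_snps)
    geno = np.empty((n, m), dtype=np.int8)
    pos = np.sort(rng.choice(m, size=2, replace=False))
    ia, ib = int(pos[0]), int(pos[1])
    null_cols = [j for j in range(m) if j not in (ia, ib)]
    geno[:, ia] = ga
    geno[:, ib] = gb
    geno[:, null_cols] = rng.binomial(
        2, null_mafs[None, :], size=(n, cfg.m_null_snps)
    ).astype(np.int8)
    vids = np.array([f"snp{j}" for j in range(m)], dtype=object)
    alleles = np.array([("a", "b")] * m, dtype=object).reshape(-1, 2)
    gm = GenotypeMatrix(geno, vids, alleles)
    phen = PhenotypeVector(
        np.concatenate(
            [np.ones(cfg.n_cases, dtype=np.int8), np.zeros(cfg.n_controls, dtype=np.int8)]
        )
    )
    truth = TruthRecord(
        (ia, ib),
        (str(vids[ia]), str(vids[ib])),
        f"two_locus_odds_model_{model.model_id}",
        {
            "theta": cfg.theta,
            "alpha": model.alpha,
            "maf_a": cfg.maf_a,
            "maf_b": cfg.maf_b,
            "prevalence": cfg.prevalence,
            "n_cases": cfg.n_cases,
            "n_controls": cfg.n_controls,
            "m_variants": m,
        },
        cfg.seed,
    )
    return gm, phen, truth


# --------------------------------------------------------------------------
# F2 epistasis models

# Each rule maps a two-locus genotype (i copies of A, j copies of B) to a
# phenotype class label.  F2 weights (1:2:1 per locus) over the 9 classes
# sum to 16; the induced class ratio is the model's classical signature.


def _rule_no_interaction(i: int, j: int) -> str:
    return ("A_" if i > 0 else "aa") + ("B_" if j > 0 else "bb")


def _rule_dominant_epistasis(i: int, j: int) -> str:
    # A_ masks the second locus: 12 : 3 : 1
    if i > 0:
        return "A_"
    return "aaB_" if j > 0 else "aabb"


def _rule_recessive_epistasis(i: int, j: int) -> str:
    # aa masks the second locus: 9 : 3 : 4
    if i == 0:
        return "aa"
    return "A_B_" if j > 0 else "A_bb"


def _rule_duplicate_cumulative(i: int, j: int) -> str:
    # duplicate genes with cumulative effect: 9 : 6 : 1
    dom = (i > 0) + (j > 0)
    return ("both", "one", "neither")[2 - dom]


def _rule_duplicate_dominant(i: int, j: int) -> str:
    # a dominant allele at either locus alters phenotype: 15 : 1
    return "altered" if (i > 0 or j > 0) else "wild"


def _rule_duplicate_recessive(i: int, j: int) -> str:
    # a homozygous mutant at either locus alters phenotype: 9 : 7
    return "altered" if (i == 0 or j == 0) else "wild"


def _rule_dominant_recessive(i: int, j: int) -> str:
    # dominant carrier at locus A or double recessive aabb: 13 : 3
    return "majority" if (i > 0 or j == 0) else "minority"


@dataclass(frozen=True)
class F2EpistasisModel:
    """Classical two-gene epistasis rule over F2 genotype classes."""

    name: str
    rule: callable = field(compare=False)
    affected_class: str

    def phenotype(self, gi: np.ndarray, gj: np.ndarray) -> np.ndarray:
        """Binary phenotype (1 = affected class) from genotype code arrays."""
        lut = np.array(
            [
                [int(self.rule(i, j) == self.affected_class) for j in range(3)]
                for i in range(3)
            ],
            dtype=np.int8,
        )
        return lut[np.asarray(gi), np.asarray(gj)]

    @property
    def n_classes(self) -> int:
        return len(f2_expected_ratio(self))


F2_MODELS: dict[str, F2EpistasisModel] = {
    m.name: m
    for m in [
        F2EpistasisModel("no_interaction", _rule_no_interaction, "A_B_"),
        F2EpistasisModel("dominant_epistasis", _rule_dominant_epistasis, "A_"),
        F2EpistasisModel("recessive_epistasis", _rule_recessive_epistasis, "aa"),
        F2EpistasisModel("duplicate_cumulative", _rule_duplicate_cumulative, "both"),
        F2EpistasisModel("duplicate_dominant", _rule_duplicate_dominant, "altered"),
        F2EpistasisModel("duplicate_recessive", _rule_duplicate_recessive, "altered"),
        F2EpistasisModel("dominant_recessive_interaction", _rule_dominant_recessive, "majority"),
    ]
}


def f2_expected_ratio(model: F2EpistasisModel) -> dict[str, int]:
    """Integer phenotype-class ratio over the 16 two-locus F2 combinations.

    Evaluates the rule on the nine genotype classes with 1:2:1 weights per
    locus (independent loci); the returned counts sum to 16.
    """
    weights = {0: 1, 1: 2, 2: 1}
    out: dict[str, int] = {}
    for i in range(3):
        for j in range(3):
            cls = model.rule(i, j)
            out[cls] = out.get(cls, 0) + weights[i] * weights[j]
    assert sum(out.values()) == 16
    return out


def simulate_f2(
    model: F2EpistasisModel | str,
    n_samples: int = 180,
    m_null_snps: int = 998,
    seed: int = 0,
) -> tuple[GenotypeMatrix, PhenotypeVector, TruthRecord]:
    """F2 population with two causal loci under a two-class epistasis rule.

    All loci (causal and null) segregate 1:2:1 independently, as unlinked
    loci do in an F2 cross; the phenotype is assigned deterministically by
    the model's rule.  Only two-class models can serve as case/control
    phenotypes.
    """
    if isinstance(model, str):
        model = F2_MODELS[model]
    if model.n_classes != 2:
        raise ValueError(
            f"model {model.name!r} has {model.n_classes} phenotype classes; "
            "case/control simulation needs exactly 2"
        )
    rng = np.random.default_rng(seed)
    m = m_null_snps + 2
    geno = rng.binomial(2, 0.5, size=(n_samples, m)).astype(np.int8)
    pos = np.sort(rng.choice(m, size=2, replace=False))
    ia, ib = int(pos[0]), int(pos[1])
    labels = model.phenotype(geno[:, ia], geno[:, ib])
    # mining needs both groups present; resample the rare class in if absent
    tries = 0
    while labels.min() == labels.max():
        geno = rng.binomial(2, 0.5, size=(n_samples, m)).astype(np.int8)
        labels = model.phenotype(geno[:, ia], geno[:, ib])
        tries += 1
        if tries > 1000:
            raise RuntimeError("could not realise both phenotype classes")
    vids = np.array([f"snp{j}" for j in range(m)], dtype=object)
    alleles = np.array([("a", "b")] * m, dtype=object).reshape(-1, 2)
    gm = GenotypeMatrix(geno, vids, alleles)
    phen = PhenotypeVector(labels)
    truth = TruthRecord(
        (ia, ib),
        (str(vids[ia]), str(vids[ib])),
        f"f2_{model.name}",
        {"n_samples": n_samples, "m_variants": m},
        seed,
    )
    return gm, phen, truth
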