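"""Statistical kernels: proportion test, single-marker test, pattern table.

Three tests drive the pipeline:

* the pooled-variance two-sample *proportion test* (Armitage) used as the
  pattern-growth criterion — its squared statistic is chi-square with 1 df
  and identical to the Pearson statistic of the corresponding 2x2 table;
* the single-marker *genotypic* chi-square (genotype x status table, up to
  2 df) that measures a variant's marginal effect;
* the genotype-pattern K x 2 contingency chi-square over all multi-locus
  patterns of a variant set, with patterns rare in both cases and controls
  pooled into a single aggregate row to avoid sparse-table artifacts.

No continuity corrections are applied anywhere: the squared-z / Pearson
equivalence requires the uncorrected statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .genotype_data import MISSING, GenotypeMatrix, PhenotypeVector


@dataclass
class ProportionTestResult:
    """Two-sample proportion test of a pattern's case vs control frequency."""

    k1: int
    n1: int
    k2: int
    n2: int
    p1_hat: float
    p2_hat: float
    pi_hat: float
    z: float
    chi2: float
    p: float


def proportion_test(k1: int, n1: int, k2: int, n2: int) -> ProportionTestResult:
    """Pooled two-proportion z test of k1/n1 vs k2/n2.

    z = (p1 - p2) / sqrt(pi (1 - pi) (1/n1 + 1/n2)) with pi the pooled
    frequency estimate; z^2 ~ chi-square(1) under equal frequencies.  When
    the pooled frequency is degenerate (0 or 1) the variance vanishes along
    with the numerator; by convention z = 0 and p = 1.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes n1, n2 must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("pattern counts must satisfy 0 <= k <= n")
    p1 = k1 / n1
    p2 = k2 / n2
    pi = (k1 + k2) / (n1 + n2)
    if pi <= 0.0 or pi >= 1.0:
        z = 0.0
    else:
        z = (p1 - p2) / np.sqrt(pi * (1.0 - pi) * (1.0 / n1 + 1.0 / n2))
    chi2 = z * z
    p = float(stats.chi2.sf(chi2, df=1)) if chi2 > 0 else 1.0
    return ProportionTestResult(k1, n1, k2, n2, p1, p2, pi, float(z), float(chi2), p)


def proportion_chi2_arrays(k1, n1, k2, n2) -> np.ndarray:
    """Vectorised z^2 of the pooled two-proportion test (degenerate -> 0)."""
    k1 = np.asarray(k1, dtype=np.float64)
    k2 = np.asarray(k2, dtype=np.float64)
    n1 = np.asarray(n1, dtype=np.float64)
    n2 = np.asarray(n2, dtype=np.float64)
    pi = (k1 + k2) / (n1 + n2)
    var = pi * (1.0 - pi) * (1.0 / n1 + 1.0 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (k1 / n1 - k2 / n2) / np.sqrt(var)
    chi2 = np.where(var > 0, z * z, 0.0)
    return chi2


def _pearson(table: np.ndarray) -> tuple[float, int]:
    """Pearson chi-square and df of a table after dropping empty rows/cols."""
    table = np.asarray(table, dtype=np.float64)
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    r, c = table.shape
    if r < 2 or c < 2:
        return 0.0, 0
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    chi2 = float(np.sum((table - expected) ** 2 / expected))
    return chi2, (r - 1) * (c - 1)


def single_marker_test(column: np.ndarray, phen: PhenotypeVector) -> float:
    """Genotypic (up to 2 df) chi-square p-value of one variant's marginal
    association with case/control status.

    Missing genotypes are dropped pairwise; df is the number of observed
    genotype levels minus one.  A monomorphic variant has df 0 and p = 1.
    """
    column = np.asarray(column)
    ok = column != MISSING
    if not ok[phen.case_mask].any() or not ok[phen.control_mask].any():
        raise ValueError("a phenotype group has zero complete observations")
    table = np.zeros((3, 2), dtype=np.int64)
    for grp, mask in enumerate((phen.control_mask, phen.case_mask)):
        counts = np.bincount(column[mask & ok].astype(np.int64), minlength=3)
        table[:, grp] = counts[:3]
    chi2, df = _pearson(table)
    return float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0


def single_marker_tests_all(gm: GenotypeMatrix, phen: PhenotypeVector) -> np.ndarray:
    """Vectorised genotypic-test p-values for every variant of a matrix."""
    geno = gm.genotypes
    n, m = geno.shape
    counts = np.zeros((m, 3, 2), dtype=np.int64)
    for grp, mask in enumerate((phen.control_mask, phen.case_mask)):
        sub = geno[mask]
        # one bincount pass over (variant, level) pairs, missing excluded
        ok = sub != MISSING
        cols = np.broadcast_to(np.arange(m), sub.shape)[ok]
        flat = cols * 3 + sub[ok].astype(np.int64)
        counts[:, :, grp] = np.bincount(flat, minlength=3 * m).reshape(m, 3)
    totals = counts.sum(axis=2)  # (m, 3)
    col_tot = counts.sum(axis=1)  # (m, 2)
    if (col_tot == 0).any():
        raise ValueError("a phenotype group has zero complete observations")
    grand = col_tot.sum(axis=1)  # (m,)
    expected = totals[:, :, None] * col_tot[:, None, :] / grand[:, None, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = (counts - expected) ** 2 / expected
    terms[~np.isfinite(terms)] = 0.0
    chi2 = terms.sum(axis=(1, 2))
    df = (totals > 0).sum(axis=1) - 1
    pvals = np.ones(m)
    nz = df > 0
    pvals[nz] = stats.chi2.sf(chi2[nz], df[nz])
    return pvals


@dataclass
class PatternContingencyTable:
    """K x 2 table of multi-locus genotype patterns by case/control status.

    ``major_rows`` are patterns common enough in at least one group; every
    pattern with both group counts below ``rare_min_count`` is pooled into
    ``rare_row``.  ``degenerate`` flags tables that collapse below 2 rows
    (p fixed at 1).
    """

    variant_set: tuple
    major_rows: list  # [(pattern levels tuple, case count, control count)]
    rare_row: tuple | None  # (case count, control count) or None
    df: int
    chi2: float
    p: float
    degenerate: bool = False
    n_complete_cases: int = 0
    n_complete_controls: int = 0
    rare_min_count: int = 5
    rare_members: list = field(default_factory=list)

    def to_tsv(self) -> str:
        """Audit export: pattern string, case count, control count."""
        lines = ["#pattern\tcases\tcontrols"]
        for levels, a, b in self.major_rows:
            pat = "_".join(f"{v}:{g}" for v, g in zip(self.variant_set, levels))
            lines.append(f"{pat}\t{a}\t{b}")
        if self.rare_row is not None:
            lines.append(f"RARE\t{self.rare_row[0]}\t{self.rare_row[1]}")
        return "\n".join(lines) + "\n"


def pattern_contingency_test(
    variant_set,
    gm: GenotypeMatrix,
    phen: PhenotypeVector,
    rare_min_count: int = 5,
) -> PatternContingencyTable:
    """Pearson chi-square of the genotype-pattern x status table.

    Rows enumerate the multi-locus genotype patterns observed over
    ``variant_set`` among samples complete at every member variant; a
    pattern with case count < ``rare_min_count`` AND control count <
    ``rare_min_count`` is pooled into the single rare row.  df = rows - 1.
    """
    variant_set = tuple(variant_set)
    if len(variant_set) < 1:
        raise ValueError("variant_set must contain at least one variant")
    idx = np.array(
        [
            v if isinstance(v, (int, np.integer)) else gm.variant_index(v)
            for v in variant_set
        ]
    )
    sub = gm.genotypes[:, idx]
    complete = (sub != MISSING).all(axis=1)
    k = len(idx)
    # pattern code = base-3 integer over the variant set
    weights = 3 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    codes = sub[complete].astype(np.int64) @ weights
    status = phen.labels[complete]
    n_codes = 3**k
    counts_case = np.bincount(codes[status == 1], minlength=n_codes)
    counts_ctrl = np.bincount(codes[status == 0], minlength=n_codes)
    observed = np.flatnonzero(counts_case + counts_ctrl)

    def decode(c: int) -> tuple:
        levels = []
        for w in weights:
            levels.append(int(c // w))
            c = c % w
        return tuple(levels)

    major_rows = []
    rare_case = rare_ctrl = 0
    rare_members = []
    for c in observed:
        a, b = int(counts_case[c]), int(counts_ctrl[c])
        if a < rare_min_count and b < rare_min_count:
            rare_case += a
            rare_ctrl += b
            rare_members.append((decode(int(c)), a, b))
        else:
            major_rows.append((decode(int(c)), a, b))
    rare_row = (rare_case, rare_ctrl) if rare_members else None

    rows = [(a, b) for _, a, b in major_rows]
    if rare_row is not None:
        rows.append(rare_row)
    table = np.array(rows, dtype=np.float64).reshape(-1, 2)
    n_cc = int(counts_case.sum())
    n_ct = int(counts_ctrl.sum())
    if table.shape[0] < 2 or n_cc == 0 or n_ct == 0:
        return PatternContingencyTable(
            variant_set, major_rows, rare_row, 0, 0.0, 1.0, True,
            n_cc, n_ct, rare_min_count, rare_members,
        )
    chi2, df = _pearson(table)
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return PatternContingencyTable(
        variant_set, major_rows, rare_row, df, chi2, p, df == 0,
        n_cc, n_ct, rare_min_count, rare_members,
    )
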