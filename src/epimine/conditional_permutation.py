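"""Permutation nulls, marginal-effect binning, and significance calling.

The test statistic for a variant set is the p-value of its genotype-pattern
contingency chi-square.  Because that statistic mixes marginal and
interaction effects, two null schemes are provided:

* **regular permutation** — case/control labels are permuted wholesale and
  the full mine-and-test pipeline is re-run; the dataset-wise minimum
  contingency p is recorded per replicate (family-wise calibration);
* **conditional permutation** — the (phenotype, conditioning-variant)
  pairs are permuted *jointly* against all other columns, so the
  conditioning variant keeps its exact marginal association while every
  interaction is destroyed.  The same whole-process minimum contingency p
  is recorded.  This yields the null distribution of the statistic *given*
  a marginal effect of that strength, separating interaction signal from
  single-variant signal; when the conditioning variant is independent of
  the phenotype the two nulls coincide.

Running a conditional null for every variant is unaffordable, and variants
with similar marginal significance share a null, so variants are binned by
order of magnitude of their single-marker p-value (one extra bin for
p > 1e-3); the most significant variant of each bin is permuted once and
its alpha-quantile becomes the bin's critical value — the
``ThresholdLookupTable`` consulted when calling significant variant sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assoc_tests import (
    PatternContingencyTable,
    pattern_contingency_test,
    proportion_chi2_arrays,
    single_marker_tests_all,
)
from .genotype_data import GenotypeMatrix, PhenotypeVector
from .pattern_mining import GenotypePattern, MinerConfig, mine_patterns


@dataclass
class PermutationNull:
    """Empirical null of the dataset-wise minimum contingency p-value."""

    kind: str  # "regular" | "conditional"
    conditioning_variant: object | None
    B: int
    min_p_samples: np.ndarray
    seed: int

    def critical_value(self, alpha: float = 0.05) -> float:
        """Empirical alpha-quantile of the min-p null (k-th order statistic
        with k = max(1, floor(alpha (B+1))))."""
        k = max(1, int(np.floor(alpha * (self.B + 1))))
        k = min(k, self.B)
        return float(np.sort(self.min_p_samples)[k - 1])

    def empirical_p(self, observed: float) -> float:
        """(r+1)/(B+1) with r the permuted minima at least as extreme."""
        r = int(np.sum(self.min_p_samples <= observed))
        return (r + 1) / (self.B + 1)


def _variant_sets(patterns: list[GenotypePattern]) -> dict[tuple, list[GenotypePattern]]:
    """Group mined patterns by their (multi-variant) variant set."""
    sets: dict[tuple, list[GenotypePattern]] = {}
    for pat in patterns:
        if pat.length < 2:
            continue
        sets.setdefault(pat.variants, []).append(pat)
    return sets


def min_contingency_p(
    gm: GenotypeMatrix,
    phen: PhenotypeVector,
    cfg: MinerConfig,
    rare_min_count: int = 5,
    containing: object | None = None,
) -> float:
    """Mine one dataset and return the smallest contingency-test p-value
    over implicated multi-variant sets (optionally only sets containing one
    variant).  1.0 when nothing is mined."""
    patterns = mine_patterns(gm, phen, cfg, restrict_to_variant=containing)
    best = 1.0
    for vset in _variant_sets(patterns):
        tab = pattern_contingency_test(vset, gm, phen, rare_min_count)
        best = min(best, tab.p)
    return best


class _RegularPairNullEngine:
    """Fast permutation null for the default pair search.

    Under label permutation the genotypes never change, so the sample
    membership of every candidate item — and of every item pair — is
    fixed.  All B replicates are therefore scored at once: the binary
    pair-membership matrix (pairs x samples) multiplied by the permuted
    case-indicator matrix (samples x B) yields every pair's case count in
    every replicate as one chunked BLAS product, and integer lower/upper
    count bounds (precomputed per pooled count from the proportion-test
    cutoffs) flag the rare hits without any per-pair floating-point work.
    Items below the support floor join the candidate set only in
    replicates that happen to make them differential; their few pairs,
    and the conditioning variant's pairs in conditional replicates, are
    counted on the fly.  Only valid for complete (no-missing) matrices
    with max_length == 2 and a non-binding non-differential budget;
    callers must check :func:`applicable`.
    """

    CHUNK_BYTES = 192 * 1024 * 1024

    def __init__(self, gm, phen, cfg: MinerConfig, rare_min_count: int = 5):
        self.gm = gm
        self.cfg = cfg
        self.rare = rare_min_count
        geno = gm.genotypes
        n, m = geno.shape
        self.n = n
        self.n_cases = phen.n_cases
        self.n_controls = phen.n_controls
        from .pattern_mining import _chi2_crit

        self.report_crit = _chi2_crit(cfg.report_p_threshold)
        self.grow_crit = _chi2_crit(cfg.grow_p_threshold)
        self._lo_rep, self._hi_rep = self._count_bounds(self.report_crit)
        self._lo_grow, self._hi_grow = self._count_bounds(self.grow_crit)

        it_j, it_level, it_ktot, rows = [], [], [], []
        for j in range(m):
            counts = np.bincount(geno[:, j].astype(np.int64), minlength=3)
            for level in range(3):
                if counts[level] == 0:
                    continue
                it_j.append(j)
                it_level.append(level)
                it_ktot.append(int(counts[level]))
                rows.append((geno[:, j] == level).astype(np.uint8))
        self.it_j = np.array(it_j)
        self.it_level = np.array(it_level)
        self.it_ktot = np.array(it_ktot)
        self.it_bool = np.array(rows)  # (n_items, n) uint8 0/1
        self.high = (self.it_ktot / n) >= cfg.min_support

        hi = np.flatnonzero(self.high)
        a_idx, b_idx = np.triu_indices(hi.size, k=1)
        pa, pb = hi[a_idx], hi[b_idx]
        keep = self.it_j[pa] != self.it_j[pb]
        pa, pb = pa[keep], pb[keep]
        if pa.size * n > 40 * self.CHUNK_BYTES:
            raise ValueError("candidate pair set too large for the engine")
        self.chunk = max(1, self.CHUNK_BYTES // (4 * n))
        # pooled pattern counts are label-invariant; drop pairs whose pooled
        # count can never reach the reporting cutoff at any case split
        ktot = np.empty(pa.size, dtype=np.int64)
        for lo in range(0, pa.size, self.chunk):
            sl = slice(lo, min(lo + self.chunk, pa.size))
            ktot[sl] = (self.it_bool[pa[sl]] & self.it_bool[pb[sl]]).sum(
                axis=1, dtype=np.int64
            )
        reachable = ~(
            (self._lo_rep[ktot] == -1) & (self._hi_rep[ktot] == n + 1)
        )
        self.pair_a = pa[reachable]
        self.pair_b = pb[reachable]
        self.pair_ktot = ktot[reachable]
        self.n_pairs = self.pair_a.size
        self._scratch_gm = None
        self._code_cache: dict = {}

    def _count_bounds(self, crit):
        """Per pooled count t: case counts k1 <= lo[t] or >= hi[t] reach the
        chi-square cutoff (chi2 is convex in k1 at fixed t)."""
        n = self.n
        lo = np.full(n + 1, -1, dtype=np.int64)
        hi = np.full(n + 1, n + 1, dtype=np.int64)
        for t in range(1, n + 1):
            k1 = np.arange(max(0, t - self.n_controls), min(t, self.n_cases) + 1)
            chi2 = proportion_chi2_arrays(k1, self.n_cases, t - k1, self.n_controls)
            ok = np.flatnonzero(chi2 >= crit)
            if ok.size == 0:
                continue
            gaps = np.flatnonzero(np.diff(ok) > 1)
            if gaps.size:  # leading and trailing runs
                lo[t] = k1[ok[gaps[0]]]
                hi[t] = k1[ok[gaps[0] + 1]]
            elif k1[ok[0]] == k1[0] and k1[ok[-1]] < k1[-1]:
                lo[t] = k1[ok[-1]]
            elif k1[ok[-1]] == k1[-1] and k1[ok[0]] > k1[0]:
                hi[t] = k1[ok[0]]
            else:  # a single run covering the whole range
                lo[t] = k1[-1]
        return lo, hi

    @staticmethod
    def applicable(gm, cfg: MinerConfig) -> bool:
        from .genotype_data import MISSING

        return (
            cfg.max_length == 2
            and cfg.max_nondifferential_items >= 2
            and not bool((gm.genotypes == MISSING).any())
        )

    def _pair_code(self, i, j, v_j=None, v_col=None):
        """Per-sample joint genotype code (0..8) of a variant pair, with the
        pooled 9-cell histogram; cached for label-permutation reuse."""
        if v_j is None or (i != v_j and j != v_j):
            hit = self._code_cache.get((i, j))
            if hit is None:
                code = (
                    self.gm.genotypes[:, i].astype(np.int64) * 3
                    + self.gm.genotypes[:, j]
                )
                hit = (code, np.bincount(code, minlength=9))
                if len(self._code_cache) < 200_000:
                    self._code_cache[(i, j)] = hit
            return hit
        ci = v_col if i == v_j else self.gm.genotypes[:, i]
        cj = v_col if j == v_j else self.gm.genotypes[:, j]
        code = ci.astype(np.int64) * 3 + cj
        return code, np.bincount(code, minlength=9)

    def _pair_contingency_stat(self, code, pooled, case_row):
        """Pattern-table chi-square statistic and df of one variant pair,
        mirroring pattern_contingency_test for complete data."""
        case = np.bincount(code[case_row], minlength=9)
        ctrl = pooled - case
        obs = np.flatnonzero(pooled)
        a = case[obs].astype(np.float64)
        b = ctrl[obs].astype(np.float64)
        rare = (a < self.rare) & (b < self.rare)
        if rare.any():
            a = np.append(a[~rare], a[rare].sum())
            b = np.append(b[~rare], b[rare].sum())
        if a.size < 2:
            return 0.0, 0
        ra = a + b
        ca = np.array([a.sum(), b.sum()])
        if (ca == 0).any():
            return 0.0, 0
        expected = np.outer(ra, ca) / ra.sum()
        chi2 = float((((np.column_stack([a, b])) - expected) ** 2 / expected).sum())
        return chi2, a.size - 1

    def min_p_batch(
        self,
        labels_mat: np.ndarray,
        v_j: int | None = None,
        v_cols: np.ndarray | None = None,
    ) -> np.ndarray:
        """Min contingency p for a batch of permuted replicates.

        ``labels_mat`` is (B, n); for conditional replicates ``v_cols``
        (B, n) holds the conditioning variant's co-permuted genotype
        column per replicate.
        """
        from scipy import stats

        labels_mat = np.asarray(labels_mat, dtype=np.int8)
        B, n = labels_mat.shape
        case_bool = labels_mat == 1
        case_f = np.ascontiguousarray(case_bool.T, dtype=np.float32)

        it_f = self.it_bool.astype(np.float32)
        k1_items = np.rint(it_f @ case_f).astype(np.int64)  # (n_items, B)
        v_items = np.array([], dtype=np.int64)
        if v_j is not None:
            v_items = np.flatnonzero(self.it_j == v_j)
            # the conditioning column is co-permuted: recount its items
            for t in v_items:
                vb = v_cols == self.it_level[t]  # (B, n)
                k1_items[t] = (vb & case_bool).sum(axis=1)
        t_it = self.it_ktot[:, None]
        diff = (k1_items <= self._lo_grow[t_it]) | (k1_items >= self._hi_grow[t_it])

        # candidate hits collected as flat arrays, confirmed in one pass
        h_a, h_b, h_k1, h_t, h_perm = [], [], [], [], []

        def collect(a_arr, b_arr, k1_arr, t_arr, perm_arr):
            h_a.append(np.asarray(a_arr, dtype=np.int64))
            h_b.append(np.asarray(b_arr, dtype=np.int64))
            h_k1.append(np.asarray(k1_arr, dtype=np.int64))
            h_t.append(np.asarray(t_arr, dtype=np.int64))
            h_perm.append(np.asarray(perm_arr, dtype=np.int64))

        if v_j is None:
            skip = None
        else:
            skip = (self.it_j[self.pair_a] == v_j) | (self.it_j[self.pair_b] == v_j)
        for lo in range(0, self.n_pairs, self.chunk):
            sl = slice(lo, min(lo + self.chunk, self.n_pairs))
            keep = slice(None) if skip is None else ~skip[sl]
            pa = self.pair_a[sl][keep]
            pb = self.pair_b[sl][keep]
            if pa.size == 0:
                continue
            M = (self.it_bool[pa] & self.it_bool[pb]).astype(np.float32)
            K1 = (M @ case_f).astype(np.int32)  # exact: integer-valued f32
            t = self.pair_ktot[sl][keep][:, None]
            trig = (K1 <= self._lo_rep[t]) | (K1 >= self._hi_rep[t])
            r, b = np.nonzero(trig)
            if r.size:
                collect(pa[r], pb[r], K1[r, b], t[r, 0], b)

        # pairs of the conditioning variant, re-counted per replicate
        if v_j is not None and v_items.size:
            partners = np.flatnonzero(self.high & (self.it_j != v_j))
            for t_v in v_items:
                if not self.high[t_v]:
                    continue
                for b in range(B):
                    vb = (v_cols[b] == self.it_level[t_v]).astype(np.uint8)
                    joint = self.it_bool[partners] & vb[None, :]
                    tk = joint.sum(axis=1, dtype=np.int64)
                    k1 = (joint & case_bool[b][None, :]).sum(axis=1, dtype=np.int64)
                    trig = (
                        (k1 <= self._lo_rep[tk]) | (k1 >= self._hi_rep[tk])
                    ) & (tk > 0)
                    s = np.flatnonzero(trig)
                    if s.size:
                        collect(
                            np.full(s.size, t_v), partners[s], k1[s], tk[s],
                            np.full(s.size, b),
                        )

        # per-replicate low-frequency differential items join the candidates
        low_diff_any = diff & ~self.high[:, None]
        for b in np.flatnonzero(low_diff_any.any(axis=0)):
            cand_b = np.flatnonzero(self.high | diff[:, b])
            for a in np.flatnonzero(low_diff_any[:, b]):
                keep = cand_b[
                    (self.it_j[cand_b] != self.it_j[a])
                    & (self.high[cand_b] | (cand_b > a))
                ]
                if keep.size == 0:
                    continue
                if v_j is not None and self.it_j[a] == v_j:
                    a_row = (v_cols[b] == self.it_level[a]).astype(np.uint8)
                else:
                    a_row = self.it_bool[a]
                rows = self.it_bool[keep]
                if v_j is not None:
                    rows = rows.copy()
                    for t in v_items:
                        w = np.flatnonzero(keep == t)
                        if w.size:
                            rows[w[0]] = (v_cols[b] == self.it_level[t]).astype(np.uint8)
                joint = rows & a_row[None, :]
                tk = joint.sum(axis=1, dtype=np.int64)
                k1 = (joint & case_bool[b][None, :]).sum(axis=1, dtype=np.int64)
                trig = (
                    (k1 <= self._lo_rep[tk]) | (k1 >= self._hi_rep[tk])
                ) & (tk > 0)
                s = np.flatnonzero(trig)
                if s.size:
                    collect(
                        np.full(s.size, a), keep[s], k1[s], tk[s],
                        np.full(s.size, b),
                    )

        mins = np.ones(B)
        if not h_a:
            return mins
        a = np.concatenate(h_a)
        bb = np.concatenate(h_b)
        k1 = np.concatenate(h_k1)
        t = np.concatenate(h_t)
        perm = np.concatenate(h_perm)
        chi2 = proportion_chi2_arrays(k1, self.n_cases, t - k1, self.n_controls)
        ok = chi2 >= self.report_crit
        ok[ok] = stats.chi2.sf(chi2[ok], 1) < self.cfg.report_p_threshold
        a, bb, perm = a[ok], bb[ok], perm[ok]
        if a.size == 0:
            return mins

        # score the implicated variant sets per replicate
        ja = self.it_j[a]
        jb = self.it_j[bb]
        i_lo = np.minimum(ja, jb)
        i_hi = np.maximum(ja, jb)
        for b in range(B):
            sel = perm == b
            if not sel.any():
                continue
            vsets = set(zip(i_lo[sel].tolist(), i_hi[sel].tolist()))
            chi2s, dfs = [], []
            for i, j in vsets:
                code, pooled = self._pair_code(
                    i, j, v_j, None if v_j is None else v_cols[b]
                )
                c, d = self._pair_contingency_stat(code, pooled, case_bool[b])
                if d > 0:
                    chi2s.append(c)
                    dfs.append(d)
            if chi2s:
                mins[b] = min(
                    1.0, float(np.min(stats.chi2.sf(chi2s, dfs)))
                )
        return mins

    def min_p(self, labels_perm, v_j=None, v_col=None) -> float:
        """Single-replicate convenience wrapper around :meth:`min_p_batch`."""
        v_cols = None if v_col is None else np.asarray(v_col)[None, :]
        return float(
            self.min_p_batch(np.asarray(labels_perm)[None, :], v_j, v_cols)[0]
        )


def _spawn_seeds(seed: int, B: int) -> np.ndarray:
    """Counter-mode child seeds from a master seed (reproducible, <2^31)."""
    rng = np.random.default_rng(seed)
    return rng.integers(0, 2**31 - 1, size=B)


def regular_permutation_null(
    gm: GenotypeMatrix,
    phen: PhenotypeVector,
    cfg: MinerConfig,
    B: int = 1000,
    seed: int = 0,
    rare_min_count: int = 5,
) -> PermutationNull:
    """Null of the min contingency p under wholesale label permutation."""
    if B < 1:
        raise ValueError("B must be >= 1")
    engine = None
    if _RegularPairNullEngine.applicable(gm, cfg):
        try:
            engine = _RegularPairNullEngine(gm, phen, cfg, rare_min_count)
        except ValueError:
            engine = None
    labels_mat = np.empty((B, phen.n_samples), dtype=np.int8)
    for b, s in enumerate(_spawn_seeds(seed, B)):
        rng = np.random.default_rng(s)
        labels_mat[b] = phen.labels[rng.permutation(phen.n_samples)]
    if engine is not None:
        mins = engine.min_p_batch(labels_mat)
    else:
        mins = np.array([
            min_contingency_p(gm, PhenotypeVector(row), cfg, rare_min_count)
            for row in labels_mat
        ])
    return PermutationNull("regular", None, B, mins, seed)


def conditional_permutation_null(
    gm: GenotypeMatrix,
    phen: PhenotypeVector,
    v,
    cfg: MinerConfig,
    B: int = 1000,
    seed: int = 0,
    rare_min_count: int = 5,
    _engine=None,
) -> PermutationNull:
    """Null of the whole-dataset min contingency p under joint permutation
    of the (phenotype, genotype-of-``v``) pairs.

    The (Y, G_v) pairing — hence v's marginal association — is identical in
    every replicate; all other columns become independent of Y.  The
    recorded statistic is the same whole-process minimum as in the regular
    scheme, so the two nulls coincide exactly when v carries no marginal
    effect, and the conditional null absorbs the significance that v's
    marginal effect alone produces.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    j = v if isinstance(v, (int, np.integer)) else int(gm.variant_index(v))
    vid = gm.variant_ids[j]
    engine = _engine
    if engine is None and _RegularPairNullEngine.applicable(gm, cfg):
        try:
            engine = _RegularPairNullEngine(gm, phen, cfg, rare_min_count)
        except ValueError:
            engine = None
    n = phen.n_samples
    labels_mat = np.empty((B, n), dtype=np.int8)
    v_cols = np.empty((B, n), dtype=np.int8)
    for b, s in enumerate(_spawn_seeds(seed, B)):
        rng = np.random.default_rng(s)
        perm = rng.permutation(n)
        labels_mat[b] = phen.labels[perm]
        v_cols[b] = gm.genotypes[perm, j]
    if engine is not None:
        mins = engine.min_p_batch(labels_mat, v_j=j, v_cols=v_cols)
    else:
        # reuse one scratch matrix across replicates; only column j changes
        gm_b = GenotypeMatrix(gm.genotypes.copy(), gm.variant_ids, gm.alleles)
        mins = np.empty(B)
        for b in range(B):
            gm_b.genotypes[:, j] = v_cols[b]
            mins[b] = min_contingency_p(
                gm_b, PhenotypeVector(labels_mat[b]), cfg, rare_min_count
            )
    return PermutationNull("conditional", vid, B, mins, seed)


def marginal_bin(p: float) -> int:
    """Order-of-magnitude bin of a single-marker p-value.

    Bin 0 holds p > 1e-3; bin k >= 1 holds 10^-(k+3) < p <= 10^-(k+2),
    i.e. bin 1 is (1e-4, 1e-3], bin 2 is (1e-5, 1e-4], ...
    """
    if p > 1e-3:
        return 0
    k = 1
    while p <= 10.0 ** (-(k + 3)):
        k += 1
    return k


@dataclass
class ThresholdLookupTable:
    """Marginal-p bins -> conditional-permutation critical values.

    One entry per non-empty bin of the observed marginal-p spectrum; the
    lookup key for a variant set is the bin of its most marginally
    significant member.  Critical values come from the conditional null of
    each bin's most significant variant.
    """

    fwer_alpha: float
    B: int
    seed: int
    entries: dict = field(default_factory=dict)
    # entries[bin] = {"conditioning_variant", "marginal_p", "critical_value"}

    def lookup(self, marginal_p: float) -> float:
        b = marginal_bin(marginal_p)
        if b in self.entries:
            return self.entries[b]["critical_value"]
        # a bin unseen at build time: fall back to the nearest built bin
        # (more significant first, since its threshold is the more stringent)
        built = sorted(self.entries)
        if not built:
            raise ValueError("empty threshold table")
        nearest = min(built, key=lambda x: (abs(x - b), -x))
        return self.entries[nearest]["critical_value"]

    def to_tsv(self) -> str:
        lines = [
            f"# fwer_alpha = {self.fwer_alpha}",
            f"# B = {self.B}",
            f"# seed = {self.seed}",
            "bin\tp_upper\tp_lower\tconditioning_variant\tmarginal_p\tcritical_value",
        ]
        for b in sorted(self.entries):
            e = self.entries[b]
            upper = 1.0 if b == 0 else 10.0 ** (-(b + 2))
            lower = 1e-3 if b == 0 else 10.0 ** (-(b + 3))
            lines.append(
                f"{b}\t{upper:g}\t{lower:g}\t{e['conditioning_variant']}"
                f"\t{e['marginal_p']:.6g}\t{e['critical_value']:.6g}"
            )
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "ThresholdLookupTable":
        meta = {}
        entries = {}
        for line in text.splitlines():
            if line.startswith("#"):
                k, _, v = line[1:].partition("=")
                meta[k.strip()] = v.strip()
                continue
            if line.startswith("bin\t") or not line.strip():
                continue
            b, _up, _lo, var, mp, crit = line.split("\t")
            entries[int(b)] = {
                "conditioning_variant": var,
                "marginal_p": float(mp),
                "critical_value": float(crit),
            }
        return cls(
            float(meta.get("fwer_alpha", 0.05)),
            int(meta.get("B", 0)),
            int(meta.get("seed", 0)),
            entries,
        )


def build_threshold_table(
    gm: GenotypeMatrix,
    phen: PhenotypeVector,
    cfg: MinerConfig,
    fwer_alpha: float = 0.05,
    B: int = 1000,
    seed: int = 0,
    rare_min_count: int = 5,
    marginal_p: np.ndarray | None = None,
    only_bins=None,
) -> ThresholdLookupTable:
    """Pre-compute per-bin critical values by conditional permutation.

    Variants are binned by order of magnitude of their single-marker
    p-value (p > 1e-3 forms one bin); in each non-empty bin the most
    significant variant (ties broken by smallest column index) is the
    conditioning variant, and the ``fwer_alpha``-quantile of its
    conditional min-p null is the bin's critical value.

    ``only_bins`` restricts the build to selected bin indices (the seed
    stream stays aligned with the full build), for workflows that only
    consult known bins — e.g. scoring one variant set of interest.
    """
    if gm.m_variants == 0 or phen.n_samples == 0:
        raise ValueError("empty data")
    if marginal_p is None:
        marginal_p = single_marker_tests_all(gm, phen)
    bins: dict[int, list[int]] = {}
    for j, p in enumerate(marginal_p):
        bins.setdefault(marginal_bin(float(p)), []).append(j)
    table = ThresholdLookupTable(fwer_alpha, B, seed)
    engine = None
    if _RegularPairNullEngine.applicable(gm, cfg):
        try:
            engine = _RegularPairNullEngine(gm, phen, cfg, rare_min_count)
        except ValueError:
            engine = None
    seeds = _spawn_seeds(seed, len(bins))
    for s, b in zip(seeds, sorted(bins)):
        if only_bins is not None and b not in only_bins:
            continue
        members = bins[b]
        rep = min(members, key=lambda j: (marginal_p[j], j))
        null = conditional_permutation_null(
            gm, phen, rep, cfg, B=B, seed=int(s),
            rare_min_count=rare_min_count, _engine=engine,
        )
        table.entries[b] = {
            "conditioning_variant": gm.variant_ids[rep],
            "marginal_p": float(marginal_p[rep]),
            "critical_value": null.critical_value(fwer_alpha),
        }
    return table


@dataclass
class SignificantSet:
    """A variant set passing its bin's conditional critical value."""

    variants: tuple
    contingency: PatternContingencyTable
    critical_value: float
    bin: int
    patterns: list = field(default_factory=list)


def call_significant(
    patterns: list[GenotypePattern],
    table: ThresholdLookupTable,
    marginal_p: dict,
    gm: GenotypeMatrix,
    phen: PhenotypeVector,
    rare_min_count: int = 5,
) -> list[SignificantSet]:
    """Compare each implicated variant set with the pre-computed lookup
    table and return the significant ones with their driving patterns.

    The bin key of a set is its most marginally significant member; a set
    reached by several patterns is reported once with all its patterns.
    """
    out = []
    for vset, pats in sorted(_variant_sets(patterns).items()):
        try:
            best_marg = min(float(marginal_p[v]) for v in vset)
        except KeyError as exc:
            raise KeyError(f"variant {exc.args[0]!r} missing from marginal_p") from None
        tab = pattern_contingency_test(vset, gm, phen, rare_min_count)
        crit = table.lookup(best_marg)
        if tab.p <= crit:
            out.append(
                SignificantSet(vset, tab, crit, marginal_bin(best_marg), pats)
            )
    return out
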