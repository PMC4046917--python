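"""Apriori-style growth of differential genotype patterns.

A *genotype pattern* is an ordered set of (variant, genotype-level) items;
its support is counted separately in cases and controls over the samples
complete (non-missing) at every member variant.  The miner grows patterns
one item at a time:

* round 1 keeps every single item that is *differential* (proportion-test
  p below the growth threshold) plus non-differential items with pooled
  frequency above ``min_support`` — the latter admit interactors that lack
  a marginal effect;
* each later round extends retained patterns by one candidate item with a
  strictly larger variant index (canonical, duplicate-free enumeration),
  discards extensions carrying more than ``max_nondifferential_items``
  items without marginal effect before any counting, and retains a grown
  pattern for further growth only if it is itself differential.

``exhaustive_search`` enumerates every variant combination and observed
genotype-level combination of a fixed length; with all pruning disabled the
miner reproduces it exactly, which serves as the engine's correctness
oracle.
"""

from __future__ import annotations

import os
import pickle
import tempfile
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .assoc_tests import ProportionTestResult, proportion_chi2_arrays, proportion_test
from .genotype_data import MISSING, GenotypeMatrix, PhenotypeVector


@dataclass(frozen=True)
class GenotypePattern:
    """Canonical genotype pattern with case/control support.

    ``items`` pairs variant ids with genotype-level codes (0/1/2 copies of
    the alternate allele), ordered by matrix column so the form is unique.
    """

    items: tuple  # ((variant_id, level), ...)
    support_cases: int
    support_controls: int
    n_cases: int
    n_controls: int
    prop_result: ProportionTestResult = field(compare=False, hash=False)

    @property
    def length(self) -> int:
        return len(self.items)

    @property
    def key(self) -> tuple:
        return self.items

    @property
    def variants(self) -> tuple:
        return tuple(v for v, _ in self.items)

    @property
    def p(self) -> float:
        return self.prop_result.p

    def label(self, gm: GenotypeMatrix | None = None) -> str:
        """Human-readable pattern string, e.g. ``46_AT_609_GG``."""
        parts = []
        for vid, level in self.items:
            if gm is not None:
                parts.append(f"{vid}_{gm.genotype_string(vid, level)}")
            else:
                parts.append(f"{vid}_{level}")
        return "_".join(parts)


@dataclass
class MinerConfig:
    """Tunable knobs of the pattern-growth search.

    ``grow_p_threshold`` is the proportion-test significance below which a
    pattern counts as differential during growth; ``min_support`` is the
    pooled-frequency floor for keeping *non*-differential single items in
    the round-1 candidate set; ``report_p_threshold`` filters the final
    report.  Setting ``grow_p_threshold=1``, ``min_support=0`` and an
    unbounded ``max_nondifferential_items`` disables all pruning, making
    the miner an exhaustive enumerator.
    """

    max_length: int = 2
    grow_p_threshold: float = 0.01
    min_support: float = 0.05
    report_p_threshold: float = 1e-4
    max_nondifferential_items: int = 2
    spill_dir: str | None = None
    max_candidates_in_memory: int = 2_000_000

    def __post_init__(self) -> None:
        if self.max_length < 1:
            raise ValueError("max_length must be >= 1")
        for name in ("grow_p_threshold", "min_support", "report_p_threshold"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    def no_pruning(self) -> "MinerConfig":
        """Copy of this config with every growth filter disabled."""
        return replace(
            self,
            grow_p_threshold=1.0,
            min_support=0.0,
            max_nondifferential_items=self.max_length,
        )


class _CandidateStore:
    """Frontier container that spills to disk past a memory budget.

    Each candidate round can dwarf the genotype matrix itself; when the
    in-memory list exceeds the budget, whole chunks are pickled to a
    temporary file and streamed back on iteration.
    """

    def __init__(self, max_in_memory: int, spill_dir: str | None):
        self._max = max_in_memory
        self._dir = spill_dir
        self._mem: list = []
        self._file = None
        self._n_spilled = 0

    def append(self, item) -> None:
        self._mem.append(item)
        if len(self._mem) >= self._max:
            self._spill()

    def extend(self, items) -> None:
        for it in items:
            self.append(it)

    def _spill(self) -> None:
        if self._file is None:
            fd, path = tempfile.mkstemp(suffix=".cand", dir=self._dir)
            self._file = os.fdopen(fd, "w+b")
            self._path = path
        pickle.dump(self._mem, self._file)
        self._n_spilled += len(self._mem)
        self._mem = []

    def __len__(self) -> int:
        return self._n_spilled + len(self._mem)

    def __iter__(self):
        if self._file is not None:
            self._file.flush()
            self._file.seek(0)
            while True:
                try:
                    chunk = pickle.load(self._file)
                except EOFError:
                    break
                yield from chunk
            self._file.seek(0, os.SEEK_END)
        yield from self._mem

    def close(self) -> None:
        if self._file is not None:
            self._file.close()
            os.unlink(self._path)
            self._file = None


def _group_level_counts(
    geno: np.ndarray, mask: np.ndarray, cols: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant genotype-level counts and complete-sample totals within a
    sample mask, optionally restricted to a column subset.  Returns
    (counts (n_cols, 3), n_complete (n_cols,))."""
    sub = geno[mask] if cols is None else geno[np.ix_(mask, cols)]
    k = sub.shape[1]
    ok = sub != MISSING
    idx = np.broadcast_to(np.arange(k), sub.shape)[ok]
    flat = idx * 3 + sub[ok].astype(np.int64)
    counts = np.bincount(flat, minlength=3 * k).reshape(k, 3)
    return counts, ok.sum(axis=0)


def _chi2_crit(p_threshold: float) -> float:
    if p_threshold >= 1.0:
        return -1.0  # every pattern qualifies, including chi2 == 0
    if p_threshold <= 0.0:
        return np.inf
    return float(stats.chi2.isf(p_threshold, df=1))


def mine_patterns(
    gm: GenotypeMatrix,
    phen: PhenotypeVector,
    cfg: MinerConfig | None = None,
    restrict_to_variant=None,
) -> list[GenotypePattern]:
    """Mine differential genotype patterns by Apriori-style growth.

    Returns every evaluated pattern (length 1 .. ``cfg.max_length``) whose
    proportion-test p-value falls below ``cfg.report_p_threshold``, in
    canonical form.  See the module docstring for the growth rules.

    ``restrict_to_variant`` limits the output to patterns containing one
    variant (by id or column index) — used by the conditional permutation,
    whose statistic only involves sets containing the conditioning variant.
    """
    if cfg is None:
        cfg = MinerConfig()
    geno = gm.genotypes
    if geno.shape[0] != phen.n_samples:
        raise ValueError("genotype matrix and phenotype disagree on sample count")
    case_mask = phen.case_mask
    ctrl_mask = phen.control_mask

    k_case, n1v = _group_level_counts(geno, case_mask)
    k_ctrl, n2v = _group_level_counts(geno, ctrl_mask)
    if (n1v == 0).any() or (n2v == 0).any():
        raise ValueError("some variant has zero complete samples in a group")

    m = geno.shape[1]
    cols = np.repeat(np.arange(m), 3)
    levels = np.tile(np.arange(3), m)
    kc = k_case.ravel()
    kt = k_ctrl.ravel()
    observed = (kc + kt) > 0
    chi2_1 = proportion_chi2_arrays(kc, n1v[cols], kt, n2v[cols])
    p_1 = np.where(chi2_1 > 0, stats.chi2.sf(chi2_1, df=1), 1.0)
    pooled_freq = (kc + kt) / (n1v[cols] + n2v[cols])
    differential = observed & (p_1 <= cfg.grow_p_threshold)
    candidate = observed & (differential | (pooled_freq >= cfg.min_support))

    results: list[GenotypePattern] = []

    def make_pattern(item_idx_levels, k1, n1, k2, n2) -> GenotypePattern:
        res = proportion_test(int(k1), int(n1), int(k2), int(n2))
        items = tuple(
            (gm.variant_ids[j], int(l)) for j, l in item_idx_levels
        )
        return GenotypePattern(items, int(k1), int(k2), int(n1), int(n2), res)

    rj = None
    if restrict_to_variant is not None:
        rj = (
            int(restrict_to_variant)
            if isinstance(restrict_to_variant, (int, np.integer))
            else gm.variant_index(restrict_to_variant)
        )

    report_crit = _chi2_crit(cfg.report_p_threshold)
    for t in np.flatnonzero(observed):
        if rj is not None and cols[t] != rj:
            continue
        if chi2_1[t] >= report_crit and p_1[t] < cfg.report_p_threshold:
            results.append(
                make_pattern(
                    [(cols[t], levels[t])], kc[t], n1v[cols[t]], kt[t], n2v[cols[t]]
                )
            )

    if cfg.max_length == 1:
        return results

    cand_idx = np.flatnonzero(candidate)
    cand_j = cols[cand_idx]
    cand_level = levels[cand_idx]
    cand_isdiff = differential[cand_idx]
    cand_nondiff = (~cand_isdiff).astype(np.int64)

    any_missing = bool((geno == MISSING).any())
    grow_crit = _chi2_crit(cfg.grow_p_threshold)
    n_case_tot = int(case_mask.sum())
    n_ctrl_tot = int(ctrl_mask.sum())
    scan_args = (
        geno, case_mask, ctrl_mask, cand_j, cand_level,
        report_crit, cfg, make_pattern, any_missing,
    )

    if cfg.max_length == 2:
        budget = cfg.max_nondifferential_items
        if rj is not None:
            # only pairs containing the conditioning variant can matter
            anchors = np.flatnonzero(cand_j == rj)
            partner_keep = [
                (cand_j != rj) & (cand_nondiff + cand_nondiff[a] <= budget)
                for a in anchors
            ]
            results.extend(_anchored_scan(*scan_args, anchors, partner_keep))
        elif budget <= 1:
            # every admissible pair holds >= 1 differential item; anchoring
            # on those visits each pair once (diff-diff pairs only from
            # their lower-index member)
            anchors = np.flatnonzero(cand_isdiff)
            partner_keep = [
                (cand_isdiff & (cand_j > cand_j[a]))
                | (
                    (~cand_isdiff) & (cand_j != cand_j[a])
                    if budget == 1
                    else np.zeros(cand_j.size, dtype=bool)
                )
                for a in anchors
            ]
            results.extend(_anchored_scan(*scan_args, anchors, partner_keep))
        else:
            results.extend(
                _candidate_pairs(*scan_args, cand_isdiff)
            )
        return results

    # general growth for max_length >= 3
    # frontier entries: (item index/level list, n_nondifferential)
    frontier = _CandidateStore(cfg.max_candidates_in_memory, cfg.spill_dir)
    for t in cand_idx:
        nondiff = 0 if differential[t] else 1
        if nondiff > cfg.max_nondifferential_items:
            continue
        if rj is not None and cols[t] != rj and cols[t] >= rj:
            continue  # can never grow to contain the conditioning variant
        frontier.append(([(int(cols[t]), int(levels[t]))], nondiff))

    try:
        for _length in range(2, cfg.max_length + 1):
            nxt = _CandidateStore(cfg.max_candidates_in_memory, cfg.spill_dir)
            for parent_items, parent_nondiff in frontier:
                last_j = parent_items[-1][0]
                lo = np.searchsorted(cand_j, last_j, side="right")
                if lo >= cand_j.size:
                    continue
                sel_j = cand_j[lo:]
                sel_level = cand_level[lo:]
                sel_isdiff = cand_isdiff[lo:]
                if parent_nondiff >= cfg.max_nondifferential_items:
                    keep = sel_isdiff
                    sel_j, sel_level, sel_isdiff = (
                        sel_j[keep], sel_level[keep], sel_isdiff[keep],
                    )
                    if sel_j.size == 0:
                        continue
                uniq_cols, inv = np.unique(sel_j, return_inverse=True)

                match = np.ones(geno.shape[0], dtype=bool)
                for j, l in parent_items:
                    match &= geno[:, j] == l

                per_group = []
                for gmask, n_tot in ((case_mask, n_case_tot), (ctrl_mask, n_ctrl_tot)):
                    counts, _ = _group_level_counts(geno, gmask & match, uniq_cols)
                    if any_missing:
                        complete = np.ones(geno.shape[0], dtype=bool)
                        for j, _l in parent_items:
                            complete &= geno[:, j] != MISSING
                        n_complete = (
                            geno[np.ix_(gmask & complete, uniq_cols)] != MISSING
                        ).sum(axis=0)
                    else:
                        n_complete = np.full(uniq_cols.size, n_tot)
                    per_group.append((counts, n_complete))
                (ck, cn), (tk, tn) = per_group
                k1 = ck[inv, sel_level]
                k2 = tk[inv, sel_level]
                n1 = cn[inv]
                n2 = tn[inv]
                ok = (n1 > 0) & (n2 > 0) & ((k1 + k2) > 0)
                chi2 = np.zeros(sel_j.size)
                chi2[ok] = proportion_chi2_arrays(k1[ok], n1[ok], k2[ok], n2[ok])
                grown_diff = ok & (chi2 >= grow_crit)
                maybe_report = ok & (chi2 >= report_crit)
                for t in np.flatnonzero(grown_diff | maybe_report):
                    child_items = parent_items + [(int(sel_j[t]), int(sel_level[t]))]
                    contains = rj is None or any(j == rj for j, _l in child_items)
                    if maybe_report[t] and contains:
                        pat = make_pattern(child_items, k1[t], n1[t], k2[t], n2[t])
                        if pat.p < cfg.report_p_threshold:
                            results.append(pat)
                    reachable = contains or child_items[-1][0] < rj
                    if grown_diff[t] and _length < cfg.max_length and reachable:
                        nxt.append((child_items, parent_nondiff + (0 if sel_isdiff[t] else 1)))
            frontier.close()
            frontier = nxt
            if len(frontier) == 0:
                break
    finally:
        frontier.close()

    return results


def _anchored_scan(
    geno, case_mask, ctrl_mask, cand_j, cand_level,
    report_crit, cfg, make_pattern, any_missing, anchors, partner_keep,
):
    """Length-2 scan anchored on selected candidate items.

    ``anchors`` indexes into the candidate-item arrays; ``partner_keep[a]``
    is the boolean partner mask for anchor ``a``.  The caller chooses the
    masks so each admissible pair is visited exactly once."""
    out = []
    n_case_tot = int(case_mask.sum())
    n_ctrl_tot = int(ctrl_mask.sum())
    for a, keep in zip(anchors, partner_keep):
        jd = int(cand_j[a])
        ld = int(cand_level[a])
        if not keep.any():
            continue
        sel_j = cand_j[keep]
        sel_level = cand_level[keep]
        uniq_cols, inv = np.unique(sel_j, return_inverse=True)
        anchor_match = geno[:, jd] == ld
        per_group = []
        for gmask, n_tot in ((case_mask, n_case_tot), (ctrl_mask, n_ctrl_tot)):
            counts, _ = _group_level_counts(geno, gmask & anchor_match, uniq_cols)
            if any_missing:
                rows_n = gmask & (geno[:, jd] != MISSING)
                n_complete = (geno[np.ix_(rows_n, uniq_cols)] != MISSING).sum(axis=0)
            else:
                n_complete = np.full(uniq_cols.size, n_tot)
            per_group.append((counts, n_complete))
        (ck, cn), (tk, tn) = per_group
        k1 = ck[inv, sel_level]
        k2 = tk[inv, sel_level]
        n1 = cn[inv]
        n2 = tn[inv]
        ok = (n1 > 0) & (n2 > 0) & ((k1 + k2) > 0)
        chi2 = np.zeros(sel_j.size)
        chi2[ok] = proportion_chi2_arrays(k1[ok], n1[ok], k2[ok], n2[ok])
        for s in np.flatnonzero(ok & (chi2 >= report_crit)):
            items = sorted([(jd, ld), (int(sel_j[s]), int(sel_level[s]))])
            pat = make_pattern(items, k1[s], n1[s], k2[s], n2[s])
            if pat.p < cfg.report_p_threshold:
                out.append(pat)
    return out


def _candidate_pairs(
    geno, case_mask, ctrl_mask, cand_j, cand_level,
    report_crit, cfg, make_pattern, any_missing, cand_isdiff,
):
    """Length-2 scan over all admissible pairs of candidate items.

    Used when pairs of two non-differential items are allowed
    (max_nondifferential_items >= 2): a column-blocked joint-genotype
    histogram, like the exhaustive pair scan but restricted to candidate
    variants and admissible level combinations."""
    m = geno.shape[1]
    adm = np.zeros((m, 3), dtype=bool)
    adm[cand_j, cand_level] = True
    ndf = np.zeros((m, 3), dtype=np.int8)
    ndf[cand_j[~cand_isdiff], cand_level[~cand_isdiff]] = 1
    ccols = np.unique(cand_j)
    masks = (case_mask, ctrl_mask)
    out = []
    budget = cfg.max_nondifferential_items
    for a_pos in range(ccols.size - 1):
        i = int(ccols[a_pos])
        partners = ccols[a_pos + 1 :]
        gi = geno[:, i].astype(np.int64)
        Gj = geno[:, partners].astype(np.int64)
        mj = partners.size
        per_group = []
        for gmask in masks:
            gi_g = gi[gmask]
            Gj_g = Gj[gmask]
            valid = (gi_g[:, None] != MISSING) & (Gj_g != MISSING)
            code = np.where(valid, gi_g[:, None] * 3 + Gj_g, 9)
            flat = code + 10 * np.arange(mj)[None, :]
            counts = np.bincount(flat.ravel(), minlength=10 * mj).reshape(mj, 10)
            per_group.append((counts[:, :9], valid.sum(axis=0)))
        (k1, n1), (k2, n2) = per_group
        # admissible level combos (c = li*3+lj): both items candidates and
        # the non-differential budget kept
        li = np.arange(9) // 3
        lj = np.arange(9) % 3
        pair_adm = adm[i][li][None, :] & adm[partners][:, lj]
        pair_ndf = ndf[i][li][None, :] + ndf[partners][:, lj]
        okc = (
            pair_adm
            & (pair_ndf <= budget)
            & ((k1 + k2) > 0)
            & (n1 > 0)[:, None]
            & (n2 > 0)[:, None]
        )
        chi2 = np.zeros((mj, 9))
        chi2[okc] = proportion_chi2_arrays(
            k1[okc], np.broadcast_to(n1[:, None], (mj, 9))[okc],
            k2[okc], np.broadcast_to(n2[:, None], (mj, 9))[okc],
        )
        for r, c in np.argwhere(okc & (chi2 >= report_crit)):
            j = int(partners[r])
            lii, ljj = divmod(int(c), 3)
            pat = make_pattern(
                [(i, lii), (j, ljj)],
                k1[r, c], n1[r], k2[r, c], n2[r],
            )
            if pat.p < cfg.report_p_threshold:
                out.append(pat)
    return out


def exhaustive_search(
    gm: GenotypeMatrix,
    phen: PhenotypeVector,
    length: int = 2,
    p_threshold: float = 1e-4,
    budget: int = 50_000_000,
) -> list[GenotypePattern]:
    """Enumerate every genotype pattern of a fixed length; keep those with
    proportion-test p below ``p_threshold``.

    The reference implementation the miner's coverage is measured against.
    Guarded by ``budget`` on (variant combinations) x (level combinations).
    """
    from math import comb

    m = gm.m_variants
    n_enum = comb(m, length) * 3**length
    if n_enum > budget:
        raise ValueError(
            f"exhaustive enumeration of {n_enum} patterns exceeds the budget "
            f"({budget}); reduce the variant count, length, or raise budget"
        )
    if length == 2:
        return _exhaustive_pairs(gm, phen, p_threshold)
    return _exhaustive_generic(gm, phen, length, p_threshold)


def _finalize_hits(gm, hits) -> list[GenotypePattern]:
    out = []
    for item_idx_levels, k1, n1, k2, n2 in hits:
        res = proportion_test(k1, n1, k2, n2)
        items = tuple((gm.variant_ids[j], int(l)) for j, l in item_idx_levels)
        out.append(GenotypePattern(items, k1, k2, n1, n2, res))
    return out


def _exhaustive_pairs(gm, phen, p_threshold) -> list[GenotypePattern]:
    geno = gm.genotypes
    m = geno.shape[1]
    crit = _chi2_crit(p_threshold)
    masks = (phen.case_mask, phen.control_mask)
    hits = []
    for i in range(m - 1):
        gi = geno[:, i].astype(np.int64)
        Gj = geno[:, i + 1 :].astype(np.int64)
        mj = m - i - 1
        per_group = []
        for gmask in masks:
            gi_g = gi[gmask]
            Gj_g = Gj[gmask]
            valid = (gi_g[:, None] != MISSING) & (Gj_g != MISSING)
            code = np.where(valid, gi_g[:, None] * 3 + Gj_g, 9)
            flat = code + 10 * np.arange(mj)[None, :]
            counts = np.bincount(flat.ravel(), minlength=10 * mj).reshape(mj, 10)
            per_group.append((counts[:, :9], valid.sum(axis=0)))
        (k1, n1), (k2, n2) = per_group
        ok = (n1 > 0) & (n2 > 0)
        pooled = k1 + k2
        chi2 = np.zeros((mj, 9))
        okc = ok[:, None] & (pooled > 0)
        chi2[okc] = proportion_chi2_arrays(
            k1[okc], np.broadcast_to(n1[:, None], (mj, 9))[okc],
            k2[okc], np.broadcast_to(n2[:, None], (mj, 9))[okc],
        )
        sig = okc & (chi2 > crit)
        for r, c in np.argwhere(sig):
            if float(stats.chi2.sf(chi2[r, c], 1)) >= p_threshold:
                continue
            j = i + 1 + int(r)
            li, lj = divmod(int(c), 3)
            hits.append(
                ([(i, li), (j, lj)], int(k1[r, c]), int(n1[r]), int(k2[r, c]), int(n2[r]))
            )
    return _finalize_hits(gm, hits)


def _exhaustive_generic(gm, phen, length, p_threshold) -> list[GenotypePattern]:
    from itertools import combinations, product

    geno = gm.genotypes
    m = geno.shape[1]
    masks = (phen.case_mask, phen.control_mask)
    hits = []
    for combo in combinations(range(m), length):
        sub = geno[:, combo]
        complete = (sub != MISSING).all(axis=1)
        for levels in product(range(3), repeat=length):
            match = complete & (sub == np.array(levels)).all(axis=1)
            k1 = int(np.sum(match & masks[0]))
            k2 = int(np.sum(match & masks[1]))
            n1 = int(np.sum(complete & masks[0]))
            n2 = int(np.sum(complete & masks[1]))
            if k1 + k2 == 0 or n1 == 0 or n2 == 0:
                continue
            res = proportion_test(k1, n1, k2, n2)
            if res.p < p_threshold:
                hits.append((list(zip(combo, levels)), k1, n1, k2, n2))
    return _finalize_hits(gm, hits)


def pattern_report_tsv(
    patterns: list[GenotypePattern],
    gm: GenotypeMatrix,
    cfg: MinerConfig | None = None,
) -> str:
    """TSV report of mined patterns, config echoed in ``#`` header lines."""
    lines = []
    if cfg is not None:
        for k, v in vars(cfg).items():
            lines.append(f"# {k} = {v}")
    lines.append(
        "pattern\tlength\tsupport_cases\tsupport_controls\tn_cases\tn_controls"
        "\tfreq_cases\tfreq_controls\tz\tchi2\tp"
    )
    for pat in sorted(patterns, key=lambda q: q.p):
        r = pat.prop_result
        lines.append(
            f"{pat.label(gm)}\t{pat.length}\t{pat.support_cases}\t{pat.support_controls}"
            f"\t{pat.n_cases}\t{pat.n_controls}\t{r.p1_hat:.6g}\t{r.p2_hat:.6g}"
            f"\t{r.z:.6g}\t{r.chi2:.6g}\t{r.p:.6g}"
        )
    return "\n".join(lines) + "\n"
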