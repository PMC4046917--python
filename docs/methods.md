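# Methods

## Data model

Genotypes are biallelic SNPs coded per cell as 0/1/2 copies of the
variant's alternate allele (the lexicographically later allele symbol), or
missing.  Phenotypes are binary case/control labels.  Supported dialects:
PLINK text ped/map (phenotype column 1=control, 2=case; `0 0` = missing
genotype), a TSV matrix with a sample/status sidecar, and an HDF5 container
(`genotypes` int8 with −1 for missing, `variant_ids`, `alleles`,
`phenotype`) so large panels can stay file-backed.  The only sample-side QC
implemented is the per-variant missingness filter (default: drop variants
with more than 4 missing genotypes).  Samples missing a genotype at any
variant of a pattern are excluded from that pattern's support counting, and
the group sizes n₁/n₂ of the proportion test shrink accordingly; no
imputation is attempted.

## Statistics

**Proportion test (growth criterion).**  For a pattern with k₁/n₁ carriers
in cases and k₂/n₂ in controls, z = (p̂₁−p̂₂)/√(π̂(1−π̂)(1/n₁+1/n₂)) with
π̂ the pooled frequency; z² is referred to χ²(1).  No continuity
correction anywhere — z² is then algebraically identical to the Pearson
chi-square of the corresponding 2×2 table, a property the test suite
asserts to 1e−10.  Degenerate pooled frequencies (π̂ ∈ {0,1}) are defined
as z = 0, p = 1.

**Single-marker (marginal) test.**  Genotypic Pearson chi-square on the
(genotype level × status) table, df = observed levels − 1, missing dropped
pairwise; monomorphic variants get p = 1.  This is both the comparator in
power studies and the quantity that bins variants for the threshold table.

**Pattern contingency test.**  For a variant set, rows are the observed
multi-locus genotype patterns over samples complete at every member
variant; rows with both group counts below `rare_min_count` (default 5,
the classic chi-square validity heuristic; the rarity cutoff is not a
published constant, so it is exposed as a parameter) are pooled into one
rare row.  Pearson chi-square with df = rows − 1; tables that collapse
below two rows are flagged degenerate with p = 1.  On a single variant
with no aggregation this reduces exactly to the single-marker test.

## Pattern mining

Round 1 evaluates every (variant, genotype) item: *differential* items
(proportion-test p ≤ `grow_p_threshold`, default 0.01) are kept, and so
are non-differential items with pooled frequency ≥ `min_support` (default
0.05) — the route by which interactors without marginal effects enter the
search.  Round k ≥ 2 extends each retained pattern by one candidate item
with a strictly larger column index (canonical, duplicate-free), counts
support, and retains the grown pattern for further growth only if it is
itself differential.  A growth budget `max_nondifferential_items` caps how
many items without marginal effect a pattern may contain.  Its default is
2: a pair may consist of two common non-marginal items, which is the
scenario the method exists for (two variants, individually null, jointly
differential) and is required to reproduce the ~0.97 coverage of the
exhaustive pair search on the odds-model grid — with the cap at 1,
measured coverage drops to ~0.80 because exactly those pairs are pruned.
From length 3 on, the differential-only retention rule automatically
discards patterns all of whose sub-patterns are null.  Reported output is
every evaluated pattern with p < `report_p_threshold` (default 1e−4, the
pair-search convention).

Candidate rounds can exceed memory on large panels; the frontier spills to
disk in pickled chunks past a configurable in-memory budget.

`exhaustive_search` enumerates every variant combination of a fixed length
and every observed genotype-level combination, guarded by an enumeration
budget.  With pruning disabled (`MinerConfig.no_pruning()`) the miner's
length-2 output equals it exactly — asserted in the tests, together with
anti-monotone support and column-order invariance.

*Coverage* of the exhaustive set by the default miner, measured here on
40 datasets over the full odds-model grid (1000+1000 samples, 200 SNPs),
averages ≈0.97–0.99 with occasional low-coverage datasets, driven by rare
genotype items that fall below the support floor without being
individually differential.

## Permutation calibration

The test statistic per dataset is the minimum pattern-contingency p over
all variant sets implicated by mined patterns (sets of size ≥ 2).

*Regular permutation* permutes case/control labels wholesale and re-runs
the entire mine-and-test pipeline per replicate; the α-quantile (order
statistic k = ⌊α(B+1)⌋) of the B minima is the family-wise critical value.

*Conditional permutation* jointly permutes the (phenotype, G_v) pairs of a
conditioning variant v against all other columns, so v's marginal
association is bit-identical in every replicate while all interactions are
destroyed; the same whole-process minimum is recorded.  When v is
independent of the phenotype this null coincides with the regular one;
when v has a strong marginal effect the null minima are already extreme,
so the resulting critical value demands significance *beyond* what
marginal leakage alone produces.  Empirical p-values use the (r+1)/(B+1)
correction.

Because variants with similar marginal significance share a null, the
*threshold lookup table* bins variants by order of magnitude of marginal p
(one extra bin for p > 1e−3), conditions on each non-empty bin's most
significant variant (ties broken by the smallest column index), and stores
the α-quantile per bin.  A variant set is called significant when its
contingency p is at or below the critical value of the bin of its most
marginally significant member.  The bin representative follows the
"most significant variant in the class" reading; the alternative
("lower limit of the class") would condition on a hypothetical variant at
the bin edge and is not constructible from observed data.

**Permutation engine.**  For complete (no-missing) matrices and the
default pair search, nulls run on a batched engine: item and item-pair
sample-membership matrices are fixed under label permutation, so all B
replicates are scored at once as a chunked product of the binary
pair-membership matrix with the permuted case-indicator matrix, with
integer lower/upper case-count bounds per pooled count standing in for the
chi-square cutoffs, and pairs whose pooled count can never reach the
reporting cutoff dropped up front.  In conditional replicates only the
conditioning variant's column changes and only its pairs are re-counted.
The engine is bit-equivalent to re-running the miner per replicate
(asserted in tests); with missing data or non-default growth settings the
naive path is used.

## Simulators

**Two-locus odds models.**  Disease odds over the 9 genotype classes of an
interacting pair: model 1, α(1+θ)^(i+j) (multiplicative within and between
loci); model 2, α for i=0 or j=0, else α(1+θ)^(i·j) (threshold then
multiplicative); model 3, α for i=0 or j=0, else α(1+θ) (pure threshold).
The grid parameter λ is identified with θ (the tables are parameterised in
θ and the evaluation grids in λ with no separate definition; the identity
mapping is documented rather than a marginal-effect reparameterisation).
α is solved by bracketed root-finding so that the population prevalence
Σ P_HWE(g)·odds_g/(1+odds_g) equals the target (default 0.1) to 1e−10;
at θ = 0 the closed form α = K/(1−K) applies.  Case/control genotypes at
the causal pair are drawn retrospectively, P(g|case) ∝ P_HWE(g)π_g and
P(g|control) ∝ P_HWE(g)(1−π_g); null SNPs are HWE draws with MAF uniform
on [0.05, 0.5] (a conventional GWAS-panel spectrum; the null-SNP law is
not otherwise specified) identical in both groups.  No linkage
disequilibrium is simulated.  Default design: prevalence 0.1,
λ ∈ {0.2, 0.3, 0.5, 0.7}, causal allele frequency ∈ {0.05, 0.1, 0.2, 0.5},
1000 cases + 1000 controls, one causal pair among null SNPs.

**F2 epistasis models.**  Two unlinked loci segregating 1:2:1 give 16
equally likely gamete combinations; each classical rule maps the 9
genotype classes to phenotype classes, and `f2_expected_ratio` recovers
the textbook ratios by enumeration (duplicate dominant 15:1, duplicate
recessive 9:7, dominant & recessive interaction 13:3, no interaction
9:3:3:1, dominant epistasis 12:3:1, recessive epistasis 9:3:4, duplicate
cumulative 9:6:1).  The dominant-and-recessive rule is fixed by its 13:3
two-class split (majority class = dominant carrier at the first locus or
double recessive); a frequently quoted verbal form of this rule implies
15:1 and is rejected in favour of the tabulated ratio.  The two-class
rules double as case/control phenotypes (deterministic, no environmental
noise); genotypes at all loci, causal and null, are synthetic F2 draws —
real reference genotypes are deliberately out of scope, which removes LD
and frequency structure and makes marginal effects somewhat easier to
detect than on real panels.

## Evaluation harness

Coverage = |mined ∩ exhaustive| / |exhaustive| per dataset (1.0 when the
exhaustive set is empty).  Level-1 / Level-2 power = fraction of replicate
datasets in which some significant call contains at least one / both
causal variants; for the single-marker comparator (per-variant genotypic
test against its own regular-permutation family-wise threshold) level 2
means both causal variants individually pass.  A called set counts as a
true discovery only if it contains both causal variants; sets with no
causal variant, or one causal variant padded with nulls, are false — the
granularity matching level-2 detection.  FDR is pooled over replicates;
the mean of per-dataset ratios is reported alongside.  Experiment drivers
(`epimine.experiments`) reproduce the standard contrasts at desk scale:

* coverage: 40 datasets across the grid (~1–2 min);
* FDR/power, regular vs conditional calibration: 50 model-2 datasets
  (λ=0.5, MAF=0.2, 500+500 samples, 200 SNPs, B=200; ~4 min).  At this
  weak cell the causal pair's expected contingency chi-square is ≈10
  (df 8), so level-2 power is essentially zero in both arms and the
  pooled FDR (false / all calls) degenerates to 1 whenever any chance
  call occurs; the regular-vs-conditional contrast then lives in the
  false-call *counts* (the report records both).  At a cell with real
  power (λ=0.7, MAF=0.5, same sample size) the contrast appears in FDR
  proper — the regular threshold floods on (causal, null) marginal
  leakage while the conditional table rejects it at equal level-2 power —
  and is asserted in the test suite;
* miner vs single-marker power: model-3 grids (500+500, 200 SNPs) and the
  F2 dominant-and-recessive design (180 samples, 1000 SNPs, 100
  replicates, B=25 per conditional null — the critical value is then the
  smallest permuted minimum, the ~1/26 order statistic, slightly
  conservative at α=0.05).

For power-only experiments the lookup table is built only for the causal
set's own marginal bin (`only_bins`), since no other bin can affect
whether that set is called.

## Numerical and degenerate-input conventions

Chi-square thresholds are applied on the statistic scale via
`isf(p, 1)` to avoid per-candidate survival-function calls; exact p-values
are computed for everything reported.  Ties for "most significant variant"
break by smallest column index so outputs are deterministic.  Replicate
seeds derive from a master seed in counter mode (all below 2³¹).  Empty
pattern sets give min-p 1.0; zero-call evaluations report power 0 and FDR
0 by convention (denominators are recorded).

## Limitations

* Patterns are genotype-level; haplotype phase is ignored.
* Simulations carry no LD, no genotyping error and no covariates, so
  passing tests demonstrate correctness of the machinery and the
  direction of the regular-vs-conditional contrast, not performance on
  structured real panels.
* The conditional null conditions on one variant per set (the strongest
  marginal member); joint conditioning on several strong marginals is not
  implemented.
* Logistic-regression epistasis scans and exact (Fisher-type) tests are
  out of scope; the single-marker genotypic test is the only built-in
  comparator.
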