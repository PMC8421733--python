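# Methods

## Problem setting

The package formalizes a cross-species prioritization analysis for
congenital heart disease. A mouse model of outflow-tract (OFT)
malformations supplies two layers of expression evidence: a bulk
differential-expression (DE) table comparing mutant and wildtype OFTs, and
single-cell RNA-seq of the wildtype OFT that assigns genes to the cell
lineages in which they are specifically expressed. Patient cohorts supply
gene-level variant tables. The analysis asks whether the genes hit by
(de novo) variants in patients overlap the dysregulated mouse genes more
than chance would predict, and uses that overlap to rank candidates.

## Statistical model and tail convention

The overlap test treats the two gene lists as fixed-size draws from a
common population of N genes (here: human genes with a mouse homolog).
Under independence the overlap count X is hypergeometric(N, m, k), and the
p-value is an exact upper-tail sum computed from log-gamma terms with
log-sum-exp accumulation. No normal or saddlepoint approximation is used:
the p-values of interest span roughly 1e-5 to 0.4, and the exact sum over
at most min(m, k) terms is cheap.

Two tail conventions exist in the wild: the inclusive tail P(X ≥ q)
("equal or more" overlap) and the exclusive tail P(X > q), which is what
R's `phyper(q, m, n, k, lower.tail=FALSE)` literally returns. The two
differ by one PMF term, which is material in the far tail. Both are
implemented. The package default (`CALIBRATED_TAIL`) is the inclusive
tail: evaluated at the four published test parameterizations — (q=29,
m=270, k=1054, N=16536), (19, 224, 1054, 16536), (83, 112, 592, 1054) and
(10, 270, 475, 16536) — the inclusive tail reproduces all four published
p-values simultaneously (0.004115 vs 0.0042; 0.1245 vs 0.126; 2.718e-5 vs
2.72e-5; 0.2501 vs 0.251) while the exclusive tail reproduces none. The
tail implementations themselves are verified against an exact rational
enumeration oracle for every parameterization with N ≤ 30.

The replication test across two cohorts restricts the population to the
expression-evidence list (step 1 intersects each cohort with that list;
step 2 tests the overlap of the intersections with N equal to the
expression-evidence list size). This conditions on dysregulation: the
question is whether the two cohorts hit the *same* dysregulated genes, not
whether they hit dysregulated genes at all.

The de novo burden test models the cohort-wide de novo count in a gene set
as Poisson with mean 2 · n_trios · Σ per-gene rates (the factor 2 counts
both parental haplotypes) and reports the exact Poisson upper tail, summed
in log space (downward via the complement when the observation is below
the mean, upward term-by-term when above, so tiny tails lose no
precision). The shipped rate tables (uniform 1e-5 per gene, or
length-proportional at 5e-6 per kb) are deliberately simple placeholders
for user-supplied genome-wide rate tables; the test's contract is the
expected-vs-observed Poisson tail, not any particular rate model.

Benjamini–Hochberg adjustment (used for marker p-values and multi-list
reporting) delegates to statsmodels' `fdr_bh`.

## Single-cell specificity calling

Cells carrying at least one read of the genotype-selection marker (a
neomycin-resistance cassette marks heterozygote cells in the emulated
experiment) are removed first; the step is idempotent and warns (rather
than fails) when the marker gene is absent. Normalization is standard
per-cell depth scaling, ln(1 + s·c/total) with s = 1e4; zero counts stay
zero, preserving sparsity.

Marker calling is one-vs-rest per (gene, cluster): a pair is tested only
when max(pct_in, pct_out) ≥ 0.25 (inclusive) and |log-FC| ≥ 0.5, where the
fold change is the natural log of the ratio of within/without means of
expm1(normalized values) with a 1e-9 pseudocount — the convention under
which the 0.5 threshold is interpreted. Two tests are available:
`rank_sum` (Wilcoxon/Mann–Whitney, asymptotic with tie and continuity
correction; the default) and `wald_normal` (difference of means over a
pooled standard error). Both are shipped because the emulated procedure's
description is ambiguous between a rank-based marker test and a Wald test;
on the synthetic data the two agree on every planted marker. All tested
pairs form a single BH family. A gene is "specific" to every cluster where
adjusted p ≤ 0.05 (inclusive) and log-FC > 0; multi-cluster assignment is
allowed.

Lineage exclusion drops a gene only when its lineage set is non-empty and
entirely contained in the excluded lineages (blood, ectoderm): a gene
specific to blood *and* myocardium is kept. Genes with no specific
assignment are kept by default (`keep_unassigned=True`), since absence of
specificity is not evidence of non-contribution. Human gene lists are
lineage-filtered through their mouse homologs — single-cell evidence lives
on the mouse side — keeping a human gene when at least one mouse partner
passes.

Cell-level QC (minimum expressed genes, mitochondrial fraction) is
upstream of this package's inputs: cluster labels are consumed, not
computed, and no clustering or dimensionality reduction is performed.

## List construction conventions

- DE selection: genes with ≤ 5 total reads are excluded (strict), then
  adjusted p ≤ 0.05 (inclusive). Genes whose adjusted p is missing (as
  independent-filtering DE tools report) are never selected.
- FPKM: count / ((length/1000) · (total/1e6)); per-sample library totals
  default to column sums over all supplied genes, configurable because the
  denominator gene set is a modeling choice.
- The highly-expressed control list takes the top N genes by mean wildtype
  FPKM with N matched to the DE list size (one variable held fixed); ties
  at the rank-N boundary break by lexicographic symbol order, a documented
  deterministic rule.
- Homolog projection takes the union of all partners (one-to-many expands
  the list; partnerless genes are dropped and counted in provenance).
  Gene identity is a namespace-tagged symbol; translating between
  identifier systems is the homolog/alias map's job, and comparisons stay
  case-sensitive because silent case-folding hides real identifier errors.
- Variant consequence vocabulary is normalized through a shipped,
  user-extensible alias table (e.g. "frameshift" → loss-of-function);
  unknown tokens are format errors, not silent drops.
- Every filter appends "description: in -> out" to the list's provenance,
  so a finished list carries its full attrition trail; the report renders
  these chains and the tests assert their internal consistency.

## Synthetic data: what it emulates and what it does not

The generator produces every input the pipeline consumes, with planted
truth, under one root seed that fans out to named child streams
(`SeedSequence(seed, spawn_key=(crc32(name),))`), so adding a generator
never perturbs another and re-runs are byte-identical.

- DE table: null p-values Uniform(0,1); true-DEG p-values Beta(a, 1) with
  a = 0.05, an exchangeable stand-in for a well-behaved DE test under
  signal; adjusted p is BH over the whole table. DE testing itself is out
  of scope, so p-values are generated directly rather than from counts.
  About 2% of *null* genes are forced to ≤ 5 total reads to exercise the
  count filter without contaminating the planted truth.
- Single-cell counts: negative binomial (mean 0.3, dispersion 2 — sparse,
  droplet-like), 7 clusters × 50 cells cycling through the seven OFT-study
  lineages, 10 planted markers per cluster whose mean is multiplied by the
  marker fold (default 8) in the home cluster, and a selection-marker gene
  positive in exactly 30% of cells.
- Homolog map: each of 4,000 mouse genes gains a human partner with
  probability 0.85 and a second partner with probability 0.06, matching
  the order of one-to-many multiplicity seen in curated maps.
- Variant cohorts: per patient, Poisson(1) de novo variants plus inherited
  variants tuned to a 50% inherited fraction; variant genes are drawn with
  causal genes (150, half overlapping the true-DEG homologs) upweighted by
  the enrichment factor; 30% of variants are synonymous, the rest split
  60/25/15 missense/LoF/other. The emulated study design gives the two
  TOF cohorts the configured enrichment and leaves the SLV and HLHS
  cohorts null; cohort sizes scale as 419 : 245 : 371 : 829.

The generator does **not** emulate: real library sizes or gene counts
(~24k genes, ~2k cells), correlated gene expression, batch structure,
doublets or ambient RNA, linkage between variants, or sequencing error.
Passing tests therefore demonstrate that the *procedures* are correct and
well-calibrated under a clean generative model, not that any particular
biological conclusion transfers to real data.

## Verified statistical properties

The acceptance suite computes (rather than asserts from memory):

- exactness of both hypergeometric tails against a rational enumeration
  oracle for all parameterizations with N ≤ 30 (tolerance 1e-12);
- reproduction of the four published test values at their printed
  parameters, within one unit in the second significant digit;
- null calibration: across 500 seeded null cohorts the overlap p-values
  are uniform-or-conservative (one-sided Kolmogorov–Smirnov bound on the
  anti-conservative direction, α = 0.01);
- power: the median pipeline p-value falls strictly as the planted
  enrichment factor rises through {1, 2, 4, 8} (100 seeds each, 400
  patients) and is ≤ 0.01 at factor 8;
- marker recovery: ≥ 90% of planted markers recalled with ≤ 5% of null
  genes called specific at the standard thresholds.

Problem sizes (4,000 genes, 350 cells, 400 patients, 100–500 replicates)
were chosen so the full suite runs in about a minute on one core while
keeping the binomial/KS bounds tight enough to be meaningful.

## Known limitations

- The published counts that depend on the original raw data and database
  versions (e.g. the exact sizes of the constructed lists) are not
  reproducible here; the pipeline reproduces the construction *rules* and
  records every size in provenance instead.
- One published comparison (the HLHS overlap) is printed with two
  different p-values and without its group-1 size, so it cannot be
  re-evaluated from printed numbers; it is excluded from the reproduction
  set.
- The population size N = 16,536 ("human genes with a mouse homolog") is a
  dataset-version-dependent constant; the general API derives N from a
  supplied population list and the constant lives only in the
  reproduction preset.
- The burden test ships toy rate tables only; conclusions about real
  cohorts require genome-wide per-gene rate estimates supplied by the
  user.
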