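# Methods

This note documents the models, defaults and numerical choices behind
`lumexome`, and what the synthetic cohorts do and do not establish about
behavior on real data.

## Variant prioritization cascade

The cascade operates on per-sample variant observations whose identity is
the site key *(build, chrom, pos, ref, alt)*; positions are 1-based and
alleles single nucleotides (the scope is nonsynonymous SNVs). Stages are
pure functions, each output a subset of its input, so the cascade is
deterministic and invariant to record order.

**Caller consensus.** The pipeline retains exactly the calls supported by
all three callers. Workflows sometimes rescue discordant calls by manual
inspection; `lumexome` is deliberately strict and instead logs discordant
sites for audit, trading a little sensitivity for reproducibility.

**Germline subtraction.** Removal is keyed on the site, not the
(site, sample) pair, and ignores genotype/zygosity: one control-exome
observation anywhere disqualifies the site everywhere. Mixing genome
builds here is refused outright — there is no silent liftover anywhere in
the package.

**Six-tool pathogenicity filter.** Defaults: SIFT < 0.05 (strict
inequality), PolyPhen-2 ≥ 0.98, MutationTaster ∈ {A, D}, FATHMM = D,
CADD ≥ 20, GERP++ ≥ 2. A missing score fails its tool. The conservative
missing-score rule avoids silently inflating the pathogenic set; it also
guarantees the next stage's precondition that all four quantitative
scores are present.

**Percentile pruning.** For each quantitative tool (SIFT, PolyPhen-2,
CADD, GERP++) the empirical *q*-quantile of the pathogenicity-ordered
scores is computed over *distinct sites* (so sample multiplicity does not
weight the quantile), with linear interpolation (the same convention as
`numpy.quantile` and R's default type 7). A site is retained iff, for
every tool, its score is strictly more pathogenic than or exactly tied
with the boundary. Ties are retained because that rule is deterministic
and permutation-invariant; dropping ties would make survival depend on
row order. Both preset strengths (q = 0.10 and q = 0.20) use the same
all-four-tools consensus retention rule. Pruning is intentionally *not*
idempotent: re-running it recomputes quantiles on the shrunken set and
cuts deeper; the test suite pins this behavior down.

**Quality gate.** A per-record caller quality value is carried through
I/O and an optional minimum-quality gate is available in `run_cascade`,
default off: coverage and call-quality control belong upstream of this
pipeline.

## Expression pipeline

**Low-expression filter.** `base_expression_filter` re-implements the
published `filterByExpr` rule: keep a gene iff its CPM is at least
`min_count / median(library size) × 1e6` in at least *n* samples, where
*n* is the smallest group size (shrunk as `large_n + (n − large_n) ×
min_prop` when it exceeds `large_n`), and the gene's total count is at
least `min_total_count`. Defaults `min_count = 10`,
`min_total_count = 15`, `large_n = 10`, `min_prop = 0.7`. The test suite
cross-checks keep-sets against the reference Bioconductor implementation
(edgeR, via Rscript) and against a loop-based transcription of the rule.

**Group-wise recovery.** The recovery threshold is 3 × the median of
per-gene mean raw counts, computed over *all* genes of the matrix (not
just the filtered-out ones) and over all samples; the unrounded value is
used internally and displayed at two decimals. A filtered-out gene is
recovered when its per-group mean raw count exceeds the threshold in
exactly one or two of the three groups {Luminal, Others, Control}; the
six possible group patterns are reported. Recovery operates on raw
counts, not CPM, because the threshold is defined on the count scale.

**TMM normalization.** Factors follow the trimmed mean of M-values
method: the reference sample is the one whose library-size-scaled upper
quartile is closest to the mean upper quartile; per sample, M-values
(log₂ proportion ratios vs the reference) and A-values are computed over
genes with nonzero counts in both samples; the M-distribution is trimmed
30 % from each tail and the A-distribution 5 % from each tail (ranks with
average tie-handling); the factor is the precision-weighted mean of the
surviving M-values, with weights the inverse binomial variances; factors
are rescaled to unit geometric mean. CPM = count / (library size ×
factor) × 1e6, with library sizes recomputed on the gene set being
normalized (base-filter survivors plus recovered genes). Because the
precision weights depend on absolute counts, rescaling one sample's
counts leaves its CPM column exactly unchanged only in the proportional
two-sample case and to within about 1 % otherwise; the test suite asserts
both statements.

**Differential expression.** Replicating Limma-Voom and DESeq2 is out of
scope; the engine is a documented stand-in that preserves the structural
property downstream steps rely on — a *two-method consensus*. Per gene,
log₂FC = log₂(mean CPM Luminal + 0.5) − log₂(mean CPM Control + 0.5),
and a p-value is computed under two configurations: a two-sided Welch
*t*-test and a two-sided Wilcoxon rank-sum test, both on log₂(CPM + 0.5).
The pseudo-count 0.5 is the common convention for log-CPM. p-values are
BH-adjusted within each configuration (step-up, order-preserving;
delegated to statsmodels and verified against the closed-form formula).
A gene is selected iff it passes the thresholds under *both*
configurations with concordant fold-change sign; sign-discordant
double-significant genes are excluded and logged. Strict defaults:
adjusted *p* < 0.001 and |log₂FC| > 2.5; the relaxed setting
(adjusted *p* < 0.05, no fold-change floor) is used when annotating
variant-bearing genes. Constant genes receive p = 1.

Type-I calibration of the engine is measured on a no-effect synthetic
cohort, where the raw rejection rate at α = 0.05 sits within binomial
99 % bounds of nominal. On cohorts where planted effects make up a large
fraction (≳ 20 %) of the normalized gene set, TMM's trimmed mean cannot
fully absorb the composition shift and null genes acquire a small
systematic log-ratio offset (≈ −0.3 log₂ at 23 % planted, 8-fold
effects); this is a property of global-scaling normalization, not of the
implementation, and is why calibration is assessed under the null.

## Integration

**Driver classification** is bookkeeping, not prediction: each variant
arrives with a prediction flag (polymorphism / passenger / driver) from an
upstream predictor or catalog column, and driver-flagged variants are
looked up in a local catalog on *(gene, aa_change)* — present entries
inherit the catalog status (known / reported), absent ones are labeled
*new*. The function is pure and permutation-invariant; duplicate catalog
keys are rejected.

**Cross-cohort intersection** matches mutation sites exactly, either on
the full site key (requiring a single genome build across both cohorts)
or on rsIDs (the sanctioned path across builds). Gene-level rollups and
multi-mutation gene counts are derived from the common sites. The
operation is symmetric.

**Mutation-linked expression (eQTL-style).** For a mutation site, the
expression of its host gene — log₂(CPM + 0.5) — is compared between
mutated and wildtype samples with a two-sided Wilcoxon rank-sum test,
chosen for robustness at mutated-group sizes as small as six. The exact
null distribution is used when the mutated group has ≤ 10 samples, the
normal approximation (with continuity correction) otherwise; at the
crossover the two differ by < 0.01 in absolute p. The reported effect is
the difference of group means on the log scale. Across the sites of one
scan, p-values are BH-adjusted; with identical expression in all samples
p = 1 by convention.

## Synthetic cohorts

The generator exists so that every stage has a truth table to reconcile
against. A single seed drives everything; each output table draws from a
deterministically derived sub-stream (`(seed, table-index)` seeding), so
adding an output never perturbs the others, and identical configs produce
byte-identical files.

**Variant arm.** Sites are placed on a toy genome (22 autosomes + X,
1-based, globally unique positions). Every site receives one of five
disjoint truth labels — consensus-fail, germline, benign, pathogenic-low,
pathogenic-driver — and its generated evidence is consistent with the
label by construction: consensus-fail sites lack a caller, germline sites
are copied into ≥ 1 control exome, benign sites fail 1–6 of the six
thresholds (and may carry missing scores), pathogenic-low sites pass all
six with moderate scores, and planted drivers pass with extreme scores
drawn from ranges disjoint from the moderate ones, so they sit in the
most-pathogenic tail of every quantitative tool. Germline assignment
prefers non-driver sites and spills into drivers only when
`germline_fraction` forces it (at 1.0, every site is contaminated).

Key defaults mirror the cohort structure the pipeline targets: 33 tumor
samples, 7 control exomes, `germline_fraction = 0.31` (about a third of
raw tumor variants are typically shared with control tissue),
`consensus_fail_fraction = 0.10`, `pathogenic_low_fraction = 0.05` (a few
percent of consensus somatic variants pass a strict six-tool filter).

**Expression arm.** Counts are negative-binomial — the standard bulk
RNA-seq assumption — with mean μ and variance μ(1 + φμ), common
dispersion φ = 0.1 by default. Gene base means are lognormal with median
≈ 2.25 counts and a long upper tail, reproducing the situation where the
median per-gene mean sits near 2–3 counts while expressed genes reach
thousands. Group sizes default to 510 Luminal / 260 Others / 89 Control,
and the six group-restriction patterns default to 159 / 224 / 285 / 22 /
79 / 11 genes. Restricted genes are *bursty*: expressed at
`restricted_burst_mean` (default 300) in just enough samples of their
pattern groups to push the group mean to `restricted_group_mean`
(default 15, comfortably above a threshold of ~7) while staying below the
smallest-group sample-count requirement of the base filter — this is the
mechanism by which a gene can be biologically present in one group yet
removed by `filterByExpr`, which is exactly the case the recovery
protocol exists for. Planted DE genes sit on well-expressed baselines
(lognormal around 40 counts) and multiply the Luminal mean by
2^`effect_log2fc`. `library_size_range` sets per-sample expected totals
for the *baseline* transcriptome; planted effects then shift realized
totals, as composition does in real libraries.

**What the synthetic data does not emulate:** read-level artifacts and
alignment error, caller-specific error profiles, ancestry and population
structure, linkage between sites, gene–gene expression correlation, gene
length and GC effects, per-gene dispersion trends, and batch effects.
Passing tests therefore establish the *logic* of every stage (set
semantics, thresholds, truth reconciliation, statistical calibration
under the stated model), not robustness to those real-data
complications.

**Driver catalog.** A configurable fraction of planted drivers is listed
as known (`catalog_known_fraction`, default 0.2) or reported
(`catalog_reported_fraction`, default 0.6); the remainder is deliberately
absent so the integration layer must label it *new*.

## Problem sizes

The test suite and the acceptance script run at sizes chosen to make
every distributional check statistically meaningful while keeping the
whole suite in the tens of seconds on one CPU: 500–1000-site variant
cohorts, 2000–5000-gene count matrices, 200-instance oracle sweeps,
200-replicate power simulations, and a 476-sample eQTL cohort with 6
mutated carriers.

## Numerical conventions

- Quantiles: linear interpolation everywhere (numpy default, R type 7).
- Missing values: NaN for numeric scores, empty string for categories;
  on disk `"."` (TSV) or an absent INFO key (VCF).
- VCF score fields are String-typed INFO so decimal text round-trips
  exactly (htslib stores Float INFO in single precision); TSV floats are
  written as shortest round-trip reprs and parsed with pandas'
  `float_precision="round_trip"`.
- Multi-allelic VCF rows split into one record per ALT allele.
- One amino-acid change per variant record is assumed (one annotated
  transcript per variant).
- BH adjustment returns values in input order with monotonicity
  enforcement; adjusted ≥ raw elementwise.
- Derived seeds stay below 2³¹.

## Known limitations

- The DE engine is a mean/rank-based stand-in, not an NB GLM; it does not
  model gene-wise dispersion shrinkage or voom-style precision weights,
  and its fold-change estimate is the difference of log group means.
- Driver classification is only as complete as the supplied catalog;
  "new" means "absent from this catalog".
- The pipeline never reconciles coordinates across genome builds; rsID
  matching is the only cross-build path.
- Percentile pruning depends on the composition of the filtered set by
  design, so cohort composition changes move the pruning boundary.
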