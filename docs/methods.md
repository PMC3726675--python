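# Methods

`szprior` implements a multi-domain candidate-gene prioritization and
evaluation pipeline for schizophrenia family studies: genes under linkage
peaks are ranked by combining three independent evidence domains, selected
for genotyping either by that ranking or by the neurodevelopmental
hypothesis, and the resulting per-SNP association signal is evaluated
against SNP-count-matched random gene sets from genome-wide association
study (GWAS) universes and by cross-study meta-analysis. Because the real
inputs (family genotypes, controlled-access GWAS data) cannot be
redistributed, the package ships a first-class synthetic-data generator
that emulates every input with a configurable planted-signal structure.

## Gene ranking model

Each gene *g* receives one p-value per evidence domain:

* **Expression** — a differential-expression p-value (from an external
  brain-expression meta-analysis), corrected for multiple testing.
  Benjamini–Hochberg step-up is the default correction
  (q(i) = min_{j≥i} N·p(j)/j, clipped at 1); a Storey-style variant with a
  fixed-λ π₀ estimate (λ = 0.5, π₀ = #{p > λ}/((1−λ)N)) is available. BH is
  the default because it is deterministic and parameter-free; the Storey
  switch preserves fidelity to correction procedures that estimate the null
  proportion.
* **Network proximity** — the minimum number of protein–protein interaction
  steps from the gene to any of a small set of established susceptibility
  genes, computed by breadth-first search (seeds are distance 0). Genes
  absent from the network or disconnected from every seed are "unreachable"
  and share the worst rank.
* **Literature** — the number of search-term categories (out of five:
  disease states, neurotransmitters, neuronal features, brain development,
  brain structures; 29 terms total) in which an automated literature query
  returns at least one hit.

The network and literature domains are converted to p-values by rank:
p = midrank/N, where tied values receive the mean of the ranks they span.
Midrank/N is the simplest convention that is tie-safe and bounded in
(0, 1]; rank/(N+1) is available as a switch. The combined score is

  S(g) = −log₁₀ p_expr − log₁₀ p_ppi − log₁₀ p_lit,

and genes are ranked by descending S with ties broken lexicographically by
gene id, so the ranking is a deterministic permutation of 1..N. Genes
missing from the expression table are assigned p_expr = 1 (no evidence)
and counted in the log. Domains are weighted equally; weighting is out of
scope.

## Selection and categories

The hypothesis set contains every gene annotated with "nervous system
development" or "brain development" (exact label, case-insensitive). The
rank set is filled greedily in rank order under a tag-SNP array budget:
hypothesis genes consume no budget (their SNPs are already allocated),
other genes are added when their SNP count fits the remaining budget and
skipped otherwise, and the scan ends when no budget-consuming gene ahead
can fit the remaining budget — the point at which the array is full. The
plain "stop at remaining = 0" rule almost never triggers exactly and would
otherwise scan the entire ranking, absorbing every hypothesis gene into
the rank set; the array-full rule keeps the rank cutoff meaningful.
Categories: 1 = hypothesis ∩ rank, 2 = hypothesis only, 3 = rank only;
the three always partition the selected union.

## Association summaries

SNPs map to genes by 0-based half-open interval containment (SNPs carrying
an explicit gene assignment keep it; a SNP inside two overlapping genes
yields one row per gene). Per-category summary rows report gene count, SNP
count, mean and minimum p, and observed versus expected counts below
α ∈ {0.05, 0.005}, with E = n_snps·α displayed rounded half away from zero
to one decimal (full precision retained internally). Union rows (1+2, 1+3,
All) deduplicate SNPs shared by overlapping genes so that per-category
additivity remains testable without double counting. Experiment-wide
correction is Bonferroni (min(1, N·p)) plus BH q-values; the genomic
inflation factor is λ = median(observed χ²₁)/m₁ with m₁ ≈ 0.4549 the 1-df
chi-square median obtained by numerical quantile inversion.

A simplified transmission test is included solely so synthetic PED/MAP
trios can be run end to end: it counts transmissions b and
non-transmissions c of the risk allele from heterozygous parents, uses
(b−c)²/(b+c) against χ²₁ (p = 1 when no parent is informative), and skips
Mendelian-inconsistent trios with a logged count. It is deliberately not a
haplotype-aware pedigree disequilibrium test and is labeled as a stand-in
in its documentation.

## Enrichment against random gene sets

For each category, random gene sets of the same size are drawn uniformly
without replacement from a genome-wide GWAS universe, and four metrics are
computed per draw: total SNP count, minimum p, and counts of SNPs below
0.05 and 0.005. All four decompose over genes, so per-gene statistics are
precomputed once and each draw is a reduction — this is what keeps 10⁵
draws tractable. Empirical significance uses the plus-one rule
p = (r + 1)/n with r the number of draws as or more extreme than observed
("≥" for counts, "≤" for minimum p), bounded below by 1/n and never zero.

Gene size varies enormously, so a SNP-dense observed set biases the raw
comparison. Draws are therefore sorted by total SNP count and filtered to
the top K, with K chosen as the smallest value in
{500, 1000, 2000, 5000, 10000, 20000, 50000} for which the observed count
is two-sided compatible with the retained counts — both tail fractions
(draws ≥ observed, draws ≤ observed) at least 0.025. For tie-free counts
this is equivalent to requiring the ≥-fraction to lie in [0.025, 0.975],
and it remains well defined when draws tie the observed value exactly. If
no K is compatible the unfiltered draws are used and flagged. Filtering is
per category; a joint match across categories is not attempted.

A caveat discovered during calibration: when the simulation universe is
small relative to the set size, the empirical p of a null draw is visibly
conservative for the minimum-p metric, because many draws share the
universe's single most extreme gene (probability ≈ set_size/n_genes of
containing any fixed gene). Calibration checks therefore use universes of
≥ 2000 genes with 40-gene sets, where the tie probability is ~2%; real
genome-wide universes (~20k genes) make it negligible.

## Meta-analysis

Per-SNP study effects (log-odds β, standard error) are pooled with
inverse-variance weights w = 1/se²: β̂ = Σwβ/Σw, se = √(1/Σw), two-sided
normal p. Heterogeneity: Cochran's Q = Σw(β−β̂)² against χ²(k−1)
(asymptotic; no small-k correction), I² = max(0, (Q−(k−1))/Q)·100 with
I² = 0 at Q = 0. SNPs with p_het < 0.05 are removed before reporting;
SNPs present in a single study pass through with missing heterogeneity.
Effect alleles must match exactly across studies — mismatches raise an
error rather than silently flipping signs, since silent flipping is a
classic meta-analysis bug; harmonization is an explicit preprocessing
responsibility.

## Synthetic-data generator

The generator's defaults mirror the emulated study design: 3819
protein-coding genes in 26 autosomal linkage regions (regions emulate
nonparametric-linkage peaks with maximum score ≥ 2.0), ~22.3 tag SNPs per
gene (Poisson, floored at 1; 3725 SNPs / 167 genes), 29 literature search
terms in 5 categories, 3 external GWAS studies, 265 families, and a
neurodevelopment-label fraction of 0.03 (matching the observed 115 of 3819
hypothesis genes; the true genome-wide fraction is not derivable from the
design, so it is a free parameter). Genes are placed non-overlapping
inside regions (minimum length 200 bp; an impossible placement raises an
explicit error), each inside exactly one region. One seeded generator
drives a run, with per-stage substreams derived from fixed stage labels so
stages are independently reproducible; identical configurations give
byte-identical outputs.

Planted signal is controlled by `frac_associated_genes` (default 0: null),
optionally concentrated in the neurodevelopment label
(`associate_neurodev`). Planted genes receive Beta(a, 1) expression
p-values with a = 0.3, a direct edge to a network seed gene with
probability 0.3, and elevated per-category literature hit probability
(0.45 vs 0.10). Planted SNP p-values are drawn from a non-central 1-df
chi-square whose non-centrality is implied by the configured odds ratio
and trio count (transmission probability π = OR/(1+OR), informative
transmissions 2·n_trios·2·maf·(1−maf) at risk-allele frequency 0.3) —
generating p-values directly is orders of magnitude faster than
simulating genotypes per SNP; genotype-level trio simulation (one causal
SNP per planted gene) is retained for end-to-end smoke tests of the
transmission stand-in. The GWAS universe uses a geometric (long-tailed)
per-gene SNP-count distribution so that SNP-count matching is a real
filtering problem, and shares one true effect per planted gene across
studies.

What the generator does **not** emulate: linkage disequilibrium between
SNPs (p-values are independent given gene membership), haplotype phase,
population stratification, genotyping error, or correlated evidence
domains. Passing tests therefore demonstrate the statistical machinery —
calibration, recovery, bias correction — not robustness to those
real-data features.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale, chosen as the package's
own defaults: 120–200 candidate genes, 2000-gene GWAS universes, 2000
simulations per enrichment call (the 100,000-draw setting remains
available for full-scale runs), 200 replicates for null calibration, 50
for signal recovery, 500 for meta-analysis coverage. Coordinates are
0-based half-open everywhere internally; 1-based positions appear only in
PED/MAP and GWAS TSV output. Ranking ties break lexicographically; p = 0
inputs are rejected where a logarithm is required; empirical p-values are
capped at 1; I² is floored at 0 before division-by-Q issues can arise.

## Known limitations

The transmission stand-in ignores missing data and extended pedigrees.
The literature domain consumes a precomputed hit matrix — the query
pipeline itself (and how the 29 terms partition into categories beyond the
category labels) is outside the package. Tag-SNP selection, imputation,
and GWAS sample quality control are out of scope; per-study summary
statistics are consumed as given.
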