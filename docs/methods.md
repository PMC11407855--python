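# Methods

## The gene-level ASE test

The analysis unit is a gene with one or more informative exonic SNPs (sites
heterozygous in all F1s because the parents are homozygous for different
alleles). Per SNP, allelic counts (a, b) are kept when a + b ≥ 10
(`min_total`, the filter below which single-SNP imbalance is essentially
uninformative). With true phase (parent-based SNPs), a is the maternal
count; without it (sibling-inferred SNPs), a is an arbitrary but consistent
reference-like allele and genes are pseudo-phased: at each SNP the larger
count joins the putative major haplotype.

The null model holds each SNP's total fixed and draws one allele's count
from a beta-binomial with mean 0.5·n and intraclass correlation ρ. The
parameterisation is α = μ(1/ρ − 1), β = (1 − μ)(1/ρ − 1); it reduces to the
binomial as ρ → 0 and, at μ = 0.5 and ρ = 0.038, gives α = β ≈ 12.66.
Every simulated replicate is aggregated exactly as the observed data
(summing maternal counts in phased mode; pseudo-phasing per replicate in
unphased mode — this matters, because pseudo-phasing inflates the null MAF
and ignoring it would anti-conserve the test). The p-value is the plain
proportion of replicates with simulated MAF ≥ observed MAF; with n_sims
finite it can be zero, matching the proportion definition; a (k+1)/(n+1)
estimator is available behind `add_one` but off by default.

Numerical choices worth knowing:

* Simulated and observed MAFs share the denominator Σnᵢ, so the comparison
  is done on integer numerators — ties are exact, never float-dependent.
  A tied SNP (a = b) contributes its total/2 to the major haplotype.
* Each gene gets a deterministic substream seeded by (seed, crc32(gene_id)),
  so results are independent of gene order and reproducible bit-for-bit;
  replicates are drawn in batches capped at ~4e6 array elements.
* Defaults are ρ = 0.038 and n_sims = 10⁶; the test-suite and the analysis
  drivers use 10³–10⁵ replicates, which bounds the Monte-Carlo error of any
  p near 0.05 at a few times 1e-3–1e-2.

### Heterogeneity

For genes with ≥ 2 SNPs, Q = Σᵢ nᵢ (fᵢ − f̄)² where fᵢ is the per-SNP
major-haplotype fraction and f̄ the count-weighted mean; p_het is the
proportion of the same null replicates with Q at or above the observed
value. This count-weighted construction is this package's own choice of
heterogeneity statistic — simple, symmetric under global haplotype flips in
phased mode, and referred to a null that needs no extra simulation. It is
not claimed to be numerically identical to other published gene-aggregation
tools. Single-SNP genes have no p_het (absent, not 1).

### Overdispersion

ρ is estimated by bounded 1-D maximum likelihood with μ fixed at 0.5,
searched on [1e-8, 0.95] (xatol 1e-8). The LRT against the nested binomial
uses the boundary mixture 0.5·χ²₀ + 0.5·χ²₁ since ρ = 0 sits on the edge of
the parameter space; when the optimiser lands below the binomial likelihood
the fit is reported as exactly ρ̂ = 0. In practice the estimate should be
computed on counts from genes believed balanced; the driver script fits on
non-cis, non-CNV genes and recovers the generator's ρ to ~1e-3.

### FDR

Benjamini–Hochberg step-up q-values (via statsmodels) across genes within
each cross, separately for p_ase and p_het, at a nominal 5% rate.

## Parentage and QC

Trio calls are classified by gamete enumeration on biallelic dosages:
a trio is an error iff no pair of parental gametes yields the child dosage,
and uninformative if any call is missing (missing-at-random exclusion from
both numerator and denominator). The assigned father minimises the median
per-progeny error rate (mid-mean for even progeny counts); candidates with
zero informative sites are excluded with a warning, and a minimum above
`max_error` (default 0.05, configurable) returns no-match.

Father matching must be restricted to autosomes: male F1s are hemizygous on
X, where a diploid trio model would count every maternally-inherited X
"genotype" that conflicts with the father as an error. The API takes
whatever sites it is given; all drivers and tests pass autosome-subset
matrices.

A caveat the synthetic cohorts make visible: candidates from the true
father's own colony are near-relatives, and in partially inbred colonies
their Mendelian error rates can sit at only a few percent. A missing father
is therefore reliably distinguished from *unrelated* candidates (error
rates ≈ 0.3–0.4), but a colony-mate of a missing father can fall under a
lax threshold. The threshold is configurable and always logged.

Sibling-based informative sites are autosomal sites at which every
non-missing male sibling is heterozygous (≥ 2 calls required by default).
Sites where both parents are heterozygous leak through at rate (1/2)^n_sibs
per site; with six siblings that is ≈ 1.6% of het×het sites, and such sites
enter the unphased analysis with a pool allele fraction that is itself near
0.5 in expectation.

Colony consensus differences count sites whose observed calls are all
homozygous within each colony, for different alleles between colonies;
missing calls are ignored rather than disqualifying a site.

## The synthetic cohort

The generator emulates the statistical structure of the study design, not
its sequences:

* **Sites and genes.** Genes (2 kb, 1 kb apart) fill five chromosome arms
  (2L, 2R, 3L, 3R, X) in equal blocks; candidate exonic SNPs per gene are
  Poisson(8). A fraction `colony_div` = 0.3 of sites is fixed for different
  alleles between colonies; the rest may segregate within a colony
  (susceptible 0.25, resistant 0.45 — the resistant-like colony retains
  more diversity, and cross-specific informative SNPs outnumber consensus
  differences, as in the study design this emulates). Each segregating site
  is guaranteed one heterozygous carrier, so no segregating site can
  masquerade as a fixed colony difference; planted fixed differences are
  therefore exactly recoverable by the consensus scan.
* **Crosses.** Six crosses by default (three per direction); the first two
  lack a sequenced father (their father is generated but excluded from the
  candidate pool), mirroring a study in which two fathers were never
  recovered. Six male siblings per cross are drawn by Mendelian
  segregation, hemizygous on X (paternal gamete replaced by the maternal
  allele). Per-call missingness is 1%.
* **Expression truth.** 20% of genes are cis-regulated with true major
  fraction 0.7; the high allele is a colony allele, so the planted
  maternal/paternal direction flips with cross orientation. Counts at each
  informative SNP are beta-binomial around the pooled expectation with
  ρ_true = 0.038 and Poisson(100) totals, for a pool of ten F1 females
  whose haplotypes are realised individually.
* **CNV confounders.** 10% of genes carry a duplication on one colony
  haplotype; pool carriers (each female inherits it with probability 1/2)
  contribute copy-weighted allele fractions, shifting the pooled fraction
  to ≈ (n + c)/(2n + c) — apparent ASE without cis-regulation. This is why
  observed FDR in the recovery tests is measured against *planted
  imbalance* (cis-regulated or CNV-shifted): the gene-level statistic tests
  imbalance, and separating its mechanism is exactly the job of the
  CNV-vs-ASE Fisher test downstream.
* **Gene ages.** A six-tip ladder species tree with the focal taxon
  innermost; a gene of age class c occupies the clade of the focal
  lineage's c-th ancestor (single gain, no loss). Most genes are ancient
  (45% root class, 15% focal-specific).

What the generator does **not** emulate: read-level artefacts (mapping
bias, duplicates), linkage between SNPs, isoform structure, genotyping
error, and gene-loss histories. Passing recovery tests therefore show the
statistics are correct and calibrated under the declared noise model — not
that real-data artefacts are handled.

## Cross comparison and enrichment

* **Intersections.** UpSet-style exclusive combination counts plus the
  plain all-cross intersection. The permutation null redraws each cross's
  significant set uniformly (without replacement) from the shared
  detectable universe, by default with draw sizes restricted to that
  universe (the full-set mode is available and the mode is recorded in the
  output); p uses the add-one estimator (1 + #{null ≥ obs})/(n_perm + 1),
  which unlike the ASE p-value can never be zero — the asymmetry is
  deliberate, since a reported permutation p of 0 would be unusable
  downstream. Default 100 000 permutations; tests use 10⁴.
* **Fisher tests** report the sample (cross-product) odds ratio ad/bc,
  which matches the published one-decimal values, with the exact two-sided
  p from scipy (verified against full hypergeometric enumeration for all
  tables with total ≤ 40).
* **Wagner ages.** Binary presence/absence characters are reconstructed by
  minimum-change parsimony (Sankoff inside/outside tables); a gene's age is
  the most rootward focal ancestor that is present in *some* minimum-cost
  labelling — ties resolve toward the older origin. Consequence: a gene
  present in everything except the outgroup sister of the root is assigned
  to the root class, since gain-below-root and root-plus-loss are equally
  parsimonious; with the default ladder tree this affects class-1 genes
  (~10% disagreement with planted truth, all of it this ambiguity).
* **Arm ANOVA.** Two-way main-effects ANOVA on raw per-(arm, cross)
  proportions of significant/detectable genes, sums of squares from
  marginal means, residual df (A−1)(C−1); raw rather than transformed
  proportions are used, and the decomposition SS_total = SS_arm + SS_cross
  + SS_resid is exact. Degenerate all-equal grids report F = 0, p = 1.
* **Intervals.** Overlap means intersection length > 0 on half-open
  coordinates; a gene is "in" a swept region at ≥ 1 bp overlap; a predicted
  CRM maps to every gene it overlaps plus the nearest non-overlapping gene
  on each side of the same arm.

## Problem sizes

The shipped tests and the acceptance script run everything at desk scale as
the package's own defaults: cohorts of 150–1000 genes, 1–6 crosses, 10³–10⁵
Monte-Carlo replicates per gene, 10⁴ permutations, 20-seed repetitions for
the qualitative invariants. The full-study configuration (10⁶ replicates,
10⁵ permutations) is the library default and is exercised through the same
code paths.

## Known limitations

* The heterogeneity statistic is a reasonable in-house construction, not a
  reimplementation of any specific published p_het.
* Overdispersion is fitted with μ fixed at 0.5; counts from strongly
  imbalanced genes bias ρ̂ upward, so fit on balanced genes.
* Multi-allelic sites and indels are excluded at input; X-linked analysis
  is supported for female F1 RNA but male-sibling X calls are synthetic
  hemizygous homozygotes and are never used for site inference.
* The permutation null treats genes as exchangeable; real detectability
  varies with SNP density and expression, which the universe restriction
  only partially absorbs.
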