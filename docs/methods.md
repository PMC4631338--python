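# Methods

## Setting and model

The pipeline targets the post-calling stages of a two-strain inbred
comparison: a case strain fixed for a disease phenotype by selective
inbreeding, and a control strain representing the founder background,
genotyped against a common reference. Because both genomes are close to
fully homozygous, case-specific variation is dominated by sites that are
homozygous-variant in the case and homozygous-reference in the control
(group 2 of the five genotype groups), and heterozygous calls are mostly
residual segregation or calling noise. All statistics below assume
diploid, unphased genotypes; phasing is deliberately discarded on input.

### Hard filters

SNV rules (per-sample depth ≥ 10, allele number = 4, base quality ≥ 30,
quality-by-depth ≥ 5, MQ0 ≤ 4, indel-footprint and cluster exclusion) are
conjunctive, so the surviving set is order-independent; the removal report
attributes each record to the first rule it fails, in a fixed documented
order. Three interpretation choices are built in and surfaced to users:

* *Depth* is per-sample total depth, not per-allele depth. A per-allele
  reading of ≥ 10 would exceed the indel rule's site minimum of 8, which
  is not coherent for the stricter variant class.
* *Allele number 4* means all four alleles of the two diploid samples were
  called — i.e. no missing genotype at the site (standard VCF `AN`
  semantics).
* *Indel regions* are the reference footprint of any raw indel padded by
  one base — the minimal reading of "located on indel regions".
* The *cluster rule* removes every member of any 10-bp window containing
  ≥ 3 candidate SNVs (not just the excess members). With sorted positions
  this is equivalent to flagging every run of three consecutive candidates
  spanning ≤ 9 bases; the test suite checks the equivalence against a
  literal sliding-window oracle.

A record with a missing QC field fails (rule `missing_qc`) rather than
silently passing.

### Genotype groups and QC statistics

Genotype codes are normalized (alleles sorted, phase removed) and matched
exactly against the five patterns; a site missing on either side is
unclassifiable, hence not case-specific — a conservative choice, since
specificity cannot be established without the control genotype. Allele
indices above 2 are rejected: the five-group scheme covers at most two
alternate alleles, and multi-allelic records are kept whole precisely so
that the 1/2 genotypes of groups 4 and 5 stay recognizable.

Ti/Tv is counted over the alternate alleles the case strain actually
carries, per allele at multi-allelic sites (transitions A↔G, C↔T).
Homozygosity is the fraction a/a (a ≥ 1) among the strain's variant
sites; that denominator, rather than all high-quality sites, is what
reproduces the published worked percentage from its printed counts.
Percentages are printed to two decimals, rounding half away from zero, and
reproduction tests use a ±0.01 band because the published values mix
truncation with rounding (95.99 printed where the quotient is 95.997).

Truth-panel validation takes known polymorphic and known invariant
positions per strain group: sensitivity is the called fraction of the
former, specificity the call-free fraction of the latter; an empty truth
set yields an undefined statistic (None), never 0.

### Density profiling

Bins are anchored at coordinate 0 per chromosome (the simplest
reproducible grid; the source analysis does not state its origin), default
width 1 Mb, last partial bin kept at true width. Density is variants per
base covered by ≥ 3 reads; a bin with zero covered bases has undefined
density but is retained. SNV–indel correlation is Pearson on per-bin
densities with pairwise deletion of undefined bins (an alternative reading
— correlating binned frequency histograms of density — exists; per-bin
densities were chosen and are noted here for users). Extreme bins take the
⌈fraction·n⌉ highest and lowest defined densities, dropping
gap-overlapping bins from the low tail, with coordinate tie-breaks for
determinism.

### Panel screen and prioritization

The protein-affecting vocabulary maps every annotation class explicitly to
PAV or non-PAV; an unknown class raises instead of defaulting, so
vocabulary drift in inputs cannot silently discard variants. The panel
consistency rule is asymmetric about missing genotypes by design: a
case-consistent strain must be *observed* homozygous for the same
alternate allele (missing ⇒ drop), while a background strain merely must
not be observed homozygous-variant (missing ⇒ keep). "Same alternate
allele" matters at multi-allelic sites: a background strain homozygous for
a *different* alternate is a different mutation and does not disqualify.
Heterozygous focal PAVs are reported on a side list and excluded from
candidates. An empty panel degrades to a warning and passes homozygous
PAVs through, so the pipeline remains runnable without panel data.
Strain-group membership (which strains are case-consistent, which are
background) is configuration, not code — the background set excludes any
strain whose own phenotype would confound the screen.

### Phylogeny

The pairwise distance is Nei's net nucleotide substitution d_A: mean
between-strain allele-difference probability minus the average
within-strain heterozygosity, floored at zero, over the pairwise-complete
sites (pairwise deletion maximizes usable sites in panels with unequal
coverage; complete-site deletion would discard most of a ragged matrix).
UPGMA uses size-weighted arithmetic-mean cluster distances, node heights
at half the merge distance, and lexicographic smallest-member tie-breaks —
implemented directly because deterministic tie-breaking is part of the
contract; the cophenetic heights are cross-checked in the tests against
scipy's average-linkage clustering.

### Enrichment and expression evidence

Partner enrichment is a one-sided Fisher exact test on the 2×2 table of
(partner × prior) membership over a universe excluding the tested gene.
The default universe is every gene incident to a post-threshold edge plus
the prior set; counting genes invisible to the interaction data as
non-partners would only dilute the margin, but a whole-genome universe is
available as an option. The score threshold is strict (> 0.4). The
adjustment method is Benjamini–Hochberg by default — the upstream
analysis names only a generic adjustment; BH is the community norm for
enrichment screens and the method used is recorded in the output, with
Bonferroni/Holm available.

Differential expression is a Welch two-sample t-test (robust to unequal
variances; at the thresholds used the difference from the pooled test is
negligible) with a direction-symmetric fold-change rule, per
tissue × time cell. Fold change is a ratio of linear-scale means; a
config flag switches to 2^(mean difference) for log-scale matrices.
Zero-variance degenerate cells resolve to p = 1 (equal means) or p = 0
(unequal, decided by the fold-change rule alone).

Differential co-expression has no canonical statistic, so the package
defines one explicitly, named `dcz` in outputs: for each gene, the mean
over partner genes of |z_case − z_control| with z the Fisher transform of
the Pearson correlation, with a label-permutation null (seeded, default
1000 permutations, p = (1 + exceedances)/(1 + B)) and Bonferroni
correction over the requested gene set. Two consequences worth knowing:
the statistic dilutes as the gene set grows (one flipped pair contributes
1/(m−1) of the mean), and the permutation p-value's granularity is 1/(B+1),
so Bonferroni-significant calls need B comfortably above the set size
divided by α. Per-time-point calls combine by union — differential at any
time point in a tissue, any tissue overall.

### Evidence tiers

A candidate is high-confidence iff it is a prior gene or its partner set
is enrichment-significant; expression support annotates but never
promotes. This codifies the evidence pattern of the analysis the pipeline
reproduces, where every final high-confidence gene carried flag 1) or 2)
and expression evidence appeared only as corroboration.

## Synthetic data

The generator emulates the study conditions at desk scale: two 10-Mb
chromosomes (so 1-Mb binning yields 20 bins), 24,000 variants at an
indel fraction of 0.12 (the real callsets ran ≈ 0.135), genotype-group
mixture (3.6%, 92.9%, 3.5%, 0, 0), target Ti/Tv 2.10, ≈ 4%
heterozygosity in the case strain, a 17-strain panel (one case-consistent
strain, eleven Wistar-derived background strains, one excluded diabetic
strain, reference and outgroup strains), 240 genes with 24% flagged
olfactory-receptor, a PPI universe of ~1,040 genes with 60+ prior genes,
and expression in three tissues at five time points with five samples per
condition. One global seed drives named substreams
(`SeedSequence(seed, spawn_key=(k,))`), so regenerating one component
never perturbs another, and identical configs produce byte-identical
files.

Specific generator choices:

* `het_fraction` rescales the heterozygous groups (1 and 5) of the
  mixture; 0 forces complete homozygosity.
* Alternate alleles are drawn transition-vs-transversion with probability
  Ti/Tv/(1+Ti/Tv), so the realized ratio converges to the target with
  binomial error.
* QC-rule violations are planted on disjoint record subsets at
  configurable fractions; clusters are planted as explicit triples inside
  a 10-bp window; positions are unique per chromosome by construction.
* The panel evolves binary homozygous states along a clock-like tree by
  per-branch Bernoulli flips with probability equal to branch length. The
  default tree keeps a tight case clade and a *balanced* background clade
  with merge heights spaced well above the binomial noise of the default
  3,000 sites — a deep ladder with small steps would saturate
  identity-by-state and make recovery depend on luck rather than signal.
* Focal protein-affecting sites are injected into the panel with planted
  outcomes: half consistent (case clade homozygous, background reference),
  half sabotaged in the case clade or leaked into one background strain,
  giving the screen true positives and true negatives.
* Planted enrichment fixes the partner composition exactly (9 prior of 15
  partners by default, against a ~7% background prior rate) rather than
  sampling it, so recovery tests measure the test, not generator variance.
* Expression is log-normal (log2 sd 0.25 around gene-level means);
  DE genes shift the case mean by log2(fold change) in one tissue; DC
  genes are generated as bivariate-normal pairs with condition-dependent
  correlation.

### What passing tests do and do not show

The generator produces idealized data: exchangeable samples, independent
sites, no linkage structure, no batch effects, no annotation error, and
planted effects that are exactly the model each stage assumes (log-normal
shifts, bivariate-normal correlation flips, hypergeometric partner
composition). Passing recovery tests therefore demonstrates that the
implementation computes its statistics correctly and that the stages
compose — not that the thresholds have the same operating characteristics
on real sequencing data, where coverage artifacts, mapping bias and
correlated genes will move both error rates. Genome-scale published
counts (millions of specific SNVs, the published density R², the named
candidate genes) depend on the archived reads and arrays and are out of
reach of the synthetic study by design.

Two statistical caveats are documented rather than hidden. Fisher's exact
test is conservative when partner counts are small, so its empirical null
rejection rate sits below the nominal α at the generator's default scale;
the calibration test checks the rate against α in a large-margin regime
(universe 5,000, prior 1,000, partner degree ~100) where table support is
fine-grained, and separately checks non-anti-conservatism at default
scale. The DC power condition (ρ flip 0.9/−0.9 at n = 20 per condition,
small gene set) follows the statistic's stated design point; at the
microarray-like default of 5 samples per condition the permutation test
is underpowered and is expected to flag nothing.

## Numerical and degenerate-input conventions

* Percentages: 2 d.p., round half away from zero (`decimal` arithmetic,
  no binary-float rounding surprises); undefined ratios are None, not 0.
* Correlations are clipped to ±0.999999 before the Fisher transform.
* UPGMA requires finite symmetric input (1e-12 symmetry tolerance) and
  produces ultrametric trees to 1e-9.
* Deterministic orderings everywhere outputs are written: VCF by
  coordinate, edges and candidate tables by sorted keys, JSON with sorted
  keys — reports are byte-identical across reruns with one seed.
* Interval semantics: VCF positions 1-based; genes, features, bins and
  coverage 0-based half-open; a feature ending where a gene starts does
  not overlap it.

## Problem sizes

Default test and acceptance runs use the desk-scale study above
(~24k variants, 3k panel sites, 17 strains, 240 genes, 150 expression
samples); convergence checks use up to 10^5 variants, oracle-equivalence
checks up to 10^4 sites and 10^3 × 10^3 interval pairs, and null
calibrations 200 simulated graphs and a few thousand t-tests — sizes at
which every statistical bound asserted in the tests has comfortable
binomial margins.
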