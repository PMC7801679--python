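# Methods

## Epiallele model

A locus is a run of four adjacent CpG sites whose first-to-fourth distance
fits within a single read (default cap 72 bp, matched to typical RRBS read
lengths). Each read covering all four CpGs is phased into one of 16
patterns, encoded as a 4-bit integer with the 5'-most CpG as the most
significant bit (1 = methylated); code 0 is the fully unmethylated
epiallele, 15 the fully methylated one. A sample's state at a locus is the
count vector over those 16 codes; all downstream metrics are functions of
the derived proportion vector *p*, so they are invariant to sequencing
depth beyond sampling noise.

Reads are taken from bisulfite alignments with Bismark-style `XM` call
strings ('Z'/'z' for methylated/unmethylated CpG-context cytosines; other
context characters are ignored). Reference positions are recovered
CIGAR-aware from the aligned pairs, so indels are handled exactly. Records
that are unmapped, below mapping quality 20, or duplicate-flagged are
skipped (both thresholds configurable; common bisulfite practice, chosen
here as defaults). Overlapping paired-end mates are deduplicated per locus
by read name, so a fragment is counted once. Strands are profiled
independently and never merged: a locus is read-phased on one strand, and
plus- and minus-strand windows are distinct loci. Loci with fewer than 60
fully informative reads are discarded (the default coverage floor; it
trades locus yield against the stability of 16-cell proportion
estimates). Sliding 4-CpG windows overlap with stride 1 and are all kept.

## Metrics

* **PDR** = (reads not showing code 0 or 15) / total. Range [0, 1].
* **Epipolymorphism** = 1 − Σ pᵢ², the Gini–Simpson index of the pattern
  distribution: the probability that two epialleles sampled at random
  differ. Range [0, 15/16 = 0.9375].
* **Shannon entropy** = −Σ pᵢ log₂ pᵢ. The log base is configurable; base
  2 is the default so the 16-pattern space tops out at exactly 4 bits.
* **Delta entropy** ΔS = S(comparison) − S(baseline) with
  S = scale · Σ pᵢ log₂ pᵢ ≤ 0. Since Σ p log₂ p has minimum −4 on the
  16-simplex, the default scale of 36 makes S range over [−144, 0] and ΔS
  over [−144, +144], with ΔS = −144 attained exactly for a clonal baseline
  against a uniform comparison. The scale is exposed as a parameter for
  compatibility with other builds of the extraction stage; 0·log 0 := 0
  throughout. Negative ΔS means the comparison sample is the more
  epiallele-diverse one.

Custom metrics register by name next to the built-ins and are accepted by
the matrix, DEH and network stages unchanged; a metric is any
deterministic function of a profile.

## Cohort matrix and views

The locus × sample matrix keeps loci observed in at least a
`shared_fraction` of samples (default 1.0, the strictest choice).
Multivariate views — PCA, t-SNE, hierarchical clustering — run on the
complete-case row subset; univariate summaries use all available cells.
No imputation is performed anywhere. PCA centers loci by default and
scales only on request; variance-explained fractions are reported over
all components. Hierarchical clustering first keeps the top
`top_sd_fraction` of loci by row standard deviation (default 5%). t-SNE
uses PCA initialization and a mandatory seed so embeddings are
reproducible, and enforces perplexity < (n − 1)/3. MA data fix the
direction convention M = mean(group_b) − mean(group_a), with the group
order given by the caller and echoed in the output.

## DEH testing

A two-stage procedure: loci first pass an effect-size filter
|mean_b − mean_a| > 0.2 that never looks at p-values (independent
filtering), then the surviving loci are tested — Welch's t-test by default
for PDR and Epipolymorphism (the paper-of-record behavior for bounded
proportions; pooled-variance optionally), and a label-permutation test for
Shannon entropy with 1000 permutations by default. The permutation pools
the n₁ + n₂ values, reshuffles, and re-assigns the first n₁ to group a;
the default p-value is two-sided on |mean difference| so that increases
and decreases are treated symmetrically, with `alternative="greater"`
available for the literal one-sided proportion, and an optional
(r+1)/(B+1) smoothed estimator that cannot return zero.
Benjamini–Hochberg adjustment spans the stage-1 survivors only, and
adjustment happens after the effect-size cut — the filter is independent
of the test statistic, which preserves FDR control while raising power.
Zero-variance degenerate cases follow the conventions t = 0, p = 1 (equal
means) and p → 0 (unequal means, flagged).

## Networks and modules

Gene-level networks average each gene's DEH-locus values per sample (≥ 1 bp
overlap between the locus CpG span and any annotated interval; a locus may
hit several genes; BED inputs stay 0-based half-open). Correlation is
Pearson or the biweight midcorrelation with the standard 9·MAD tuning and
hard weight cutoff at |u| = 1; constant rows are excluded with a count.

Module detection follows the weighted co-expression standard: unsigned
soft-threshold adjacency |cor|^β with β = 6, topological-overlap
dissimilarity, average-linkage clustering, a height cut, and a minimum
module size of 30 (consistent with the smallest modules such networks
typically report); smaller clusters and uncut nodes are labelled "grey",
a reserved name no module ever takes. When no cut height is given the
tree is cut inside the largest gap of the merge-height sequence — in the
planted-block regime within-module merges sit far below any
between-module or background merge, so the gap cut isolates exactly the
tight branches, and on structureless data the gap is noise-level and
everything falls below the minimum size (all grey). Modules take names
from a fixed color palette in decreasing size order, ties broken by the
lexicographically smallest member.

A module's PC1 is the first principal component of its z-scored member ×
sample matrix, sign-oriented to correlate non-negatively with the module
mean profile; it summarizes the module's heterogeneity level per sample.
Module–trait association is Pearson r with the exact t-distribution
p-value on n − 2 degrees of freedom. Enrichment is the upper-tail
hypergeometric probability P[X ≥ k] with BH adjustment across all
(module, set) pairs; the default universe is the network's genes
(overridable), and in DEG-annotation mode, when nothing is significant the
modules merely containing DEGs are flagged instead. Node topology is
computed on the |cor| > cutoff subgraph (default 0.2): degree, eigenvector
centrality from the adjacency spectrum (well-defined on disconnected
graphs), betweenness, and Wasserman–Faust closeness normalized per
connected component; isolated nodes score 0 everywhere. "Centrality" here
means eigenvector centrality.

## Synthetic data

`simulate_profiles` uses a hierarchical Dirichlet–multinomial. Each locus
has a population composition π over the 16 patterns: background (null)
loci draw π once from a symmetric Dirichlet(α) shared by both groups —
α is the diversity knob; the default derives from a baseline mean
epipolymorphism of 0.2 through the closed form E[1 − Σp²] = 15α/(16α + 1),
i.e. α = m/(15 − 16m), emulating largely clonal non-malignant tissue.
Planted DEH loci instead use deterministic group compositions: a blend
(1 − t)·e_base + t·uniform with the concordant base pattern drawn per
locus and t root-solved so the chosen metric hits the group target
exactly (baseline 0.2 vs baseline + shift 0.4 by default, 50 of 1000 loci,
8 vs 8 samples). Each sample then draws replicate proportions from
Dirichlet(κ·π) with replicate concentration κ = 300 — separating
population composition from between-replicate variability, which a single
symmetric Dirichlet per sample cannot do because its variance is tied to
its mean — and counts from a multinomial at a Poisson(80) coverage
truncated at the 60× extraction floor (the generator emulates
post-filter tables). The generated data emulate count structure and group
shifts but not sequencing error, incomplete bisulfite conversion,
alignment artifacts, or genomic covariates of heterogeneity, so passing
recovery tests demonstrate the statistical machinery, not robustness to
those real-data features.

`simulate_module_cohort` plants correlated blocks via a latent factor per
module: member value = loading·z(sample) + Gaussian noise (defaults:
two 40-node modules, 120 background nodes, 12 samples, loading 1, noise
sd 0.1), squashed into the metric range by a logistic map that preserves
correlations at moderate loadings; one trait equals a designated module's
factor plus noise (sd 0.1). `simulate_sam` writes reads whose XM strings
realize a profile's counts exactly, on disjoint spans, so extraction is
an exact inverse — used for end-to-end round-trip tests.

All generators are pure functions of their seed, and ground-truth labels
(DEH flags, module partition, latent factors) always accompany the data.

## Numerical choices and limitations

* Proportions serialize at 6 decimals; counts are recovered as
  round(p·total) with drift repaired on the argmax so totals are exact.
* Tree-cut, palette order and tie-breaks are deterministic; permutation
  and t-SNE randomness always flow from an explicit seed.
* Problem sizes in the test suite (1000 loci × 16 samples for DEH
  recovery, 200 loci for SAM round-trips, 200-node module cohorts) are the
  package's reference study conditions for the simulators.
* Two groups only in DEH (no paired designs or covariates); 4-CpG loci
  only; no CHH/CHG contexts; no batch correction; gene sets are supplied
  as GMT files, with no live pathway-database access.
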