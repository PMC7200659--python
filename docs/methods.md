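# Methods

`memsig` implements a signal-detection analysis of whole-genome bisulfite
methylomes for experiments in which a treatment group (here, plants
carrying a heritable epigenetic "memory" state) must be distinguished
from spontaneous epigenomic variation in a control population, and the
induced repatterning must be followed across generations.

## Divergence statistics

Every sample is compared site-by-site against a *reference centroid*: the
element-wise sum of the control group's methylated/unmethylated read
counts, with centroid level q = mC/(mC+uC). Two statistics are kept per
cytosine:

- **TV**, the signed level difference p − q between the individual's
  level p and the centroid level. Its sign defines hyper- (TV > 0) and
  hypomethylation (TV < 0).
- **HD**, the coverage-weighted Hellinger divergence

      HD = 2 w [ (√p − √q)² + (√(1−p) − √(1−q))² ],   w = n₁n₂/(n₁+n₂),

  with n₁ the sample coverage and n₂ the pooled reference coverage. HD is
  zero iff p = q, symmetric in its two (level, coverage) arguments, and
  linear in w, so discrepancies supported by deep coverage outrank
  poorly covered ones.

Levels are maximum-likelihood proportions; no pseudo-count is applied by
default (a Jeffreys-type correction would mostly be masked by the TV
filter below). Sites absent from either the sample or the centroid are
dropped, not imputed.

## DMP calling

1. **Per-individual null model.** The positive HD values of each sample
   are fitted by maximum likelihood to a two-parameter gamma
   distribution (Weibull as an AIC-selected alternative in `auto` mode;
   zeros are excluded because the point mass at identity breaks
   continuous MLE). The critical value is the (1 − α) quantile of the
   fit, α = 0.05 by default.
2. **Potential DMPs.** Sites with |TV| strictly above 0.2 (a 20% level
   difference) *and* HD at or above the individual's critical value.
3. **Youden cutoff.** Candidate thresholds are the sorted unique pDMP HD
   values pooled over samples; a pDMP is classified "treatment" iff
   HD ≥ cutoff, and the cutoff maximizing J = sensitivity +
   specificity − 1 for discriminating treatment-carried from
   control-carried pDMPs is kept (ties break to the smallest cutoff).
4. **Final DMPs.** Treatment pDMPs with HD ≥ cutoff. Control pDMPs
   passing the same rule are retained separately as *spontaneous DMPs* —
   they quantify background epigenomic fluctuation, not treatment
   effect. Boundary conventions: TV filter strict, HD criteria
   inclusive.

**Site-level consensus.** DMP calls are per (site, sample). The package's
site-level output, `consensus_sites`, requires a site to be called in at
least two treatment individuals and, by default, to show no pDMP
evidence in any control individual. Replication separates induced
repatterning from single-individual spontaneous shifts, and the
control-overlap exclusion mirrors the treatment-specific set logic used
at gene level (subtracting control-overlapping calls). Both knobs are
parameters.

Critical values are fitted per individual; a pooled fit across samples is
available for very small designs. The cutoff is estimated once per
contrast with contexts pooled; per-context cutoffs are available by flag
but are not the default because a context with no true signal gives a
degenerate Youden problem.

## Caller benchmark

Four callers are compared at shared thresholds (|level difference| >
0.25, p < 0.05): pooled two-sided Fisher exact per site; a
replicate-level Wald test on proportions whose group variance is
max(empirical across-replicate variance, binomial floor p̄(1−p̄)/Σn)
divided by the replicate count — a moment-estimator approximation to the
dispersion-shrinkage tests of that family, with the floor guaranteeing a
finite z when replicates agree exactly; a root-mean-square
goodness-of-fit statistic on the pooled 2×2 with an add-one Monte-Carlo
null (multinomial draws under independence with observed margins,
p = (1 + #{sim ≥ obs})/(1 + n_mc), n_mc = 1000); and the
signal-detection caller above at benchmark parity.

Scoring follows the validation logic of the study design: at every
called site each sample contributes a feature row (HD, |TV|, log2
coverage, context indicators) labeled by its group; a standardized,
regularized logistic model (an LDA alternative by flag — the choice is
deterministic and auditable) is trained on a stratified 60% split and
scored on the held-out 40%. Accuracy, sensitivity, specificity and
FDR = FP/(TP+FP) are reported with percentile 95% CIs from 999
bootstrap resamples of the test set. Metrics are at the DMP-instance
level; sample-level aggregation by majority vote is available.

## Gene-level (DMG) testing

DMP instances (treatment calls plus control spontaneous calls) are
counted per sample within each gene's extended region — body ±1 kb, the
unit of gene-associated methylation here; a body-only mode exists. A
gene must reach **2.5 DMPs per kb in every treatment sample** to be
tested. The density scope is deliberately the treatment group: requiring
the density of every sample *including controls* would reject precisely
the genes the test exists to find, since controls carry only spontaneous
calls; `each_sample`, `any_sample` and `group_mean` scopes are provided.

Per gene, the GLM family is chosen by the pooled within-group
mean/variance ratio: Poisson when mean/variance ≥ 0.95 (the rate
parameter is configurable and logged; counts at or below equidispersion
gain nothing from an overdispersion parameter), otherwise
negative-binomial with a moment-estimated dispersion (quasi-Poisson by
flag). The group effect is Wald-tested under a log link. A perfectly
separated gene (one group total zero) makes the Wald z unbounded, so it
falls back to the exact conditional two-sample Poisson test (binomial
test of the treatment total given the overall total). log2 fold-change
of group means uses a +0.5 continuity guard on both means when either is
zero. p-values are Benjamini–Hochberg adjusted within each contrast (not
across generations); a DMG requires |log2FC| > 1 and adjusted p < 0.05.

## Heritability and recurrence

The heritable set is the intersection of per-generation DMG lists, with
per-gene recurrence counts over the union. To calibrate how much
recurrence chance alone produces, the null simulation draws the same
number of lists with the same sizes uniformly without replacement from
the gene universe and tallies, for first-list genes, membership across
all lists; the Monte-Carlo fractions converge to the Poisson-binomial
closed form with pⱼ = nⱼ/N (computed exactly by convolution and used as
a cross-check). An observed recurrence histogram (counts by membership
1..L) can be tested against the simulated expectation with Pearson's
chi-squared. At the published scale (universe 27,655; list sizes 6925,
5148, 5603, 7231, 7704, 6050) the null puts ≈8.2% of first-list genes in
≥4 lists, ≈1.1% in ≥5 and ≈4 genes in all six.

TE-proximity enrichment classifies a gene as TE-proximal iff the gap
between its body and the nearest TE-related feature is ≤1 kb (overlap =
gap 0) and Fisher-tests the 2×2 of proximal/distal by in-set/out-of-set.

## Discrimination and expression association

Samples are represented as vectors of mean HD at DMP positions within
2-kb non-overlapping genomic bins (left-closed, 1-based, complete
tiling; empty bins are 0) and clustered with Ward linkage on Euclidean
distances — scipy's update on unsquared distances, i.e. the Ward.D2
variant. A companion matrix sums |TV| per bin over differential sites
for heatmap-style views. PCA (fewest centered/scaled components reaching
90% variance) followed by LDA gives a leave-one-out classification
accuracy, the quantitative proxy for "the groups are separable".

Methylation divergence per gene (MD) is the sum of HD over the extended
gene region (mean by flag), averaged over the chosen samples. Genes with
MD > 0 are split by expression direction (up/down by log2FC sign);
within each stratum Spearman's ρ of MD against |log2FC| is reported, and
a linear-by-linear association test — M² = (N−1)r² on equal-frequency
rank-binned ordinal grids, referred to χ²₁ — tests for monotone trend.

## Synthetic data generator

The generator emulates the study design so every stage is testable with
known truth: a toy genome (default one 50-kb chromosome; 8 genes of
1.5 kb, 6 TEs of which half sit within 1 kb of distinct genes, 3 small
RNA features; all features ≥2.2 kb apart so each gene's extended region
is disjoint from every other gene's body, promoter and induced sites,
keeping gene-level truth labels unambiguous). Cytosine sites are laid
down at 0.06/bp with context probabilities (CG, CHG, CHH) =
(0.25, 0.25, 0.50).

Baseline levels: CG 0.08, with a 0.85 high-methylation component on 30%
of gene-body CG sites (bimodal gene-body methylation); CHG 0.10; CHH
0.05; TE sites elevated to (0.80, 0.50, 0.30). Noise: per-individual
levels are beta-distributed around the site baseline with intra-class
correlation ρ = 0.05 — biological inter-individual variation is the
reason a divergence-based caller is needed at all — binomial read
sampling at negative-binomial coverage (mean 30, size 5), and rare
spontaneous single-individual level shifts (rate 0.002/site/individual,
magnitude ±U(0.2, 0.5)).

Treatment effects follow the repatterning the analysis targets: +0.4 CHH
in promoters (1 kb upstream, strand-aware) and −0.4 CG in bodies of 5
target genes (70% of eligible sites per gene). Sites where clipping to
(0.01, 0.99) would leave less than 0.25 of the intended shift are
ineligible, so every truth site carries a recoverable effect; truth
records the realized (post-clipping) shift. Generation 1 holds wild
type, memory and a nonmemory sibling group sharing a random 30% of the
induced sites; later generations hold wild type and memory, each induced
site surviving independently with probability 0.8 per transition, so
truth sets are nested. Matched expression tables couple each target
gene's log2FC to −2× its mean methylation shift plus N(0, 0.5) noise.

All randomness derives child generators from (seed, operation-name), so
every stage is independently reproducible under one global seed.

What the generator does *not* model: sequence-driven context spacing and
strand symmetry, linkage between neighboring cytosines, read-level
errors or incomplete bisulfite conversion, methylome-wide compositional
shifts, and realistic chromosome-scale annotation. Passing recovery
tests therefore demonstrate that the statistics behave as designed under
the stated noise model, not that real-data error rates are matched.

## Problem sizes and numerical choices

Validation runs use the toy scale throughout: ~3,000 sites and 5 + 5
samples per contrast for site-level checks (20 seeds for null error
control, 10 for recovery), and a ~1.4-Mb, 250-gene genome with 100
target genes (10 seeds) for gene-level recall — sizes chosen so the full
suite exercises every stage end to end in minutes on one CPU. The
recurrence simulation runs 200 replicates at the published scale.
Degenerate inputs are handled explicitly: constant HD vectors refuse to
fit; an empty pDMP group skips the cutoff with a warning rather than
failing the contrast; all-zero genes are excluded before testing;
context classes with no covered sites report as missing, not zero.

## Known limitations

- Symmetric CpG strand merging is not performed (site identity is
  (chrom, pos, strand)); whether the original analysis merged strands is
  not stated, and the comparison convention here is explicit instead.
- The Wald benchmark caller is a deliberate approximation, not a
  reimplementation of any published dispersion-shrinkage test.
- Published real-data quantities (per-generation DMG counts, the
  954-gene heritable set, Spearman ρ ≈ −0.17) depend on the deposited
  sequencing data and are out of desk-scale reach; the package
  reproduces the self-contained quantities (recurrence null, printed
  enrichment arithmetic) and validates everything else by synthetic
  recovery.
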