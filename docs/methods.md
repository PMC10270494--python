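# Methods

`gutliver` analyses genus-level 16S rRNA count tables collected from three
body compartments (feces, blood, liver tissue) of patients in three disease
groups (noncirrhotic NAFLD, compensated cirrhosis, HCC), optionally paired
with liver bulk RNA-seq gene counts. This note records the models, the
defaults and why, the numerical choices, and what the synthetic cohorts do
and do not establish about real data.

## Data model

A `CompartmentTable` holds nonnegative integer counts (samples x taxa),
per-sample metadata (subject, compartment, disease group — both closed
vocabularies, rejected at load time if unknown) and a rank-labelled lineage
per taxon. Counts must be integers; fractional inputs are rejected rather
than rounded, because silent rounding hides upstream unit mistakes (e.g.
feeding in TPM). Samples with zero library size are retained in the table but
excluded from every statistic, with a logged warning: dropping them silently
would hide data errors, while including them would poison proportions.

Taxa with no genus assignment are kept under a reserved
`unclassified:<parent>` label. They participate in library-size normalization
(they are real reads) but can never enter a fecal core signature, which is
defined over classified genera only. This makes the translocation proportion
conservative: unclassified mass inflates the denominator, never the numerator.

## Alpha and beta diversity

Shannon index H = −Σ p_i ln p_i in nats; evenness is Pielou's J = H / ln S
with S the observed richness (J is flagged missing when S ≤ 1). "Species
evenness" has several estimators; Pielou is the standard companion of the
Shannon index and is what this package computes — a deliberate choice, not a
claim about any particular study's estimator.

Beta diversity is Bray-Curtis on relative abundances, without rarefaction:
rarefaction is a stochastic preprocessing step that would complicate the
determinism contract, and users who want it can rarefy upstream. Group
structure is tested with single-factor PERMANOVA: with k groups and n
samples,

    SS_total = Σ_{i<j} d_ij² / n,   SS_within = Σ_g Σ_{i<j∈g} d_ij² / n_g,
    pseudo-F = ((SS_total − SS_within)/(k−1)) / (SS_within/(n−k)),
    R² = 1 − SS_within / SS_total.

The p-value is permutational: p = (1 + #{F_perm ≥ F_obs}) / (1 + P) over P
seeded label permutations (default P = 999; the +1 form cannot produce p = 0
and makes the achievable minimum 1/(P+1)). For n ≤ 8 an exhaustive mode
enumerates every label permutation and reports the exact permutation p; the
test suite checks it against an independent brute-force enumeration and the
sampled mode against scikit-bio's implementation. F-ties under permutation
are resolved with a relative 1e-12 tolerance in favour of counting the tie
(conservative). A constant distance matrix yields a flagged degenerate
result rather than a division by zero. Pairwise (post hoc) PERMANOVA runs on
each group pair's sub-matrix and is Benjamini-Hochberg-adjusted across pairs.

Group contrasts of alpha metrics use the two-sided Mann-Whitney U test:
exact null distribution when both groups have n ≤ 20 and there are no ties,
tie-corrected normal approximation otherwise. Identical constant samples
give p = 1 (degenerate, no evidence).

## The fecal-translocation proportion

For each disease group g, the fecal core signature is the set of classified
genera whose relative abundance is ≥ `tau_abund` (default 0.001, i.e. 0.1%)
in at least a fraction `tau_prev` (default 0.05) of g's fecal samples. Both
comparisons are inclusive ("at least"): with 20 fecal samples, one qualifying
sample (prevalence exactly 0.05) suffices. Prevalence is a fraction, never a
rounded count.

A blood or liver sample's translocation proportion T is the summed relative
abundance of its own group's signature genera in that sample — each sample is
scored against the signature of its own disease group, because the signature
is defined per group; a `pooled_signature` flag scores everyone against one
pooled fecal signature for sensitivity analysis. T ∈ [0, 1], is monotone in
the signature, and depends only on relative abundances (both
property-tested). Group contrasts use Mann-Whitney against a reference group
(NAFLD by default), BH-adjusted within each compartment.

## LDA effect sizes

The differential-abundance screen is a two-stage LefSe-style procedure. It is
a *documented variant*, reproducible from its recorded constants, not a
bug-compatible port of any released LefSe binary:

1. per-million scaling (each sample's proportions × 1e6);
2. rank gate: two-sided rank-sum test per taxon, gate at alpha = 0.05;
3. effect: 30 bootstrap rounds; each draws a 2/3 class-stratified subsample
   (minimum 3 per class, both classes need ≥ 3 samples), fits a two-class
   Fisher discriminant with ridge-regularized pooled covariance
   (ridge 1e-6 on the identity; on a Cholesky failure the ridge escalates
   tenfold up to three times, then the taxa are flagged NaN), and scores each
   taxon as (|w_f · (w·μ_A − w·μ_B)| + |μ_A,f − μ_B,f|) / 2 with w the
   unit-norm discriminant direction;
4. e = sign(mean_A − mean_B) · log10(max(1, mean raw score over rounds)).

Positive e means enrichment in the first-named group of the pair; the
convention is recorded in every result object. The bootstrap stream is
canonicalized over the sorted class pair and sorted sample ids, so swapping
the class order exactly negates e and reordering samples leaves it unchanged.
There is no within-class ("subclass") Wilcoxon stage: the design has no
subclasses. The screen runs per sample type and pairwise group contrast on
family- and genus-aggregated tables; a taxon is reported when |e| ≥ 3.5
(default threshold) in at least one sample type, and the report then carries
that taxon's effect in every sample type.

## Negative-binomial host-microbe association

Liver gene counts are modelled per gene as NB with log link:

    y_i ~ NB(μ_i, α),   log μ_i = β0 + β1 x_i + log s_i,

with Var(y) = μ + α μ². Size factors s_i are median-of-ratios to the
geometric reference over genes positive in all samples (falling back to
library-size ratios, with a warning, if no such gene exists), normalized to
geometric mean 1. Dispersion α is estimated per gene by profile maximum
likelihood over log α bounded in [1e-8, 1e4] (method-of-moments start;
boundary candidates are checked so Poisson-like genes land on the lower
bound); β comes from IRLS at the profiled α. Wald z = β1/SE(β1), two-sided
normal reference. There is deliberately no information sharing across genes:
results are method-variant relative to shrinkage-based packages, which is
the transparent choice for a per-pair association screen. Non-converged fits
are flagged and excluded from the FDR family; genes that are all-zero are
excluded and flagged.

Differential expression uses the same fit with a two-level group indicator
(NAFLD as the reference level by default); log2FC = β1 / ln 2, BH across
genes, DE at q < 0.05. The gene × genus grid regresses each gene on each
genus's liver relative abundance on [0, 1] (unstandardized, so β1 is the
log-mean change from absence to fixation of the genus; a `standardize` flag
is available). Genera must have a nonzero read count — evaluated on counts,
not fractions — in at least 5 shared samples. BH runs jointly over the whole
grid by default (one correction family; `joint_fdr=False` gives per-gene
families), and the pruned view keeps only genes and genera with at least one
association at q < 0.05. Whether to test all genes or only DE genes is left
to the caller (`genes=`); both modes are supported.

## The synthetic cohort generator

The generator emulates the study design the pipeline targets, with ground
truth exposed for every planted quantity:

* **Fecal communities.** A log-normal base abundance profile over `n_genera`
  genera (σ = 1.5); group profiles are the base raised to the power
  1/`diversity_effect` (values < 1 sharpen the profile, lowering Shannon
  diversity and evenness — the advanced-disease phenotype), with explicit
  multiplicative depletions of named genera (default: two genera depleted
  1–1.5 log2 units in cirrhosis/HCC, emulating the loss of short-chain
  fatty-acid producers). Subject compositions are Dirichlet draws around the
  group profile with concentration θ (default 50) and counts are multinomial
  at the fecal depth — i.e. Dirichlet-multinomial, because plain multinomial
  counts are underdispersed and would make type-I-error checks dishonest.
* **Blood/liver communities.** Mixture (1 − π)·background + π·fecal, where
  the background lives on disjoint tissue taxa except for a small shared
  tail (default 2% of background mass spread uniformly over the fecal
  genera). Disjointness makes π identifiable; the shared tail keeps the
  translocation statistic from being trivially equal to π. The realized
  per-sample weight is Beta-jittered around the group π (concentration 150)
  and recorded in the truth table. Default π: NAFLD 0.03, cirrhosis 0.12,
  HCC 0.22 in both compartments — chosen once to reproduce the qualitative
  ordering of translocation burden across disease stages; no quantitative
  field values exist for these fractions.
* **Cohort sizes.** Defaults are 21/27/111 subjects (NAFLD/cirrhosis/HCC),
  the size of the patient cohort this design emulates; tests and examples
  pass smaller, faster configurations explicitly.
* **Transcriptomes.** Per liver sample, gene counts are gamma-Poisson
  (equivalently NB) with log mean β0_g + group effect + β1_g · x, where x is
  the genus relative abundance in that sample's simulated liver profile.
  Planted DE genes get ±2 log2 units in HCC (half also in cirrhosis);
  planted gene–genus pairs get β1 = 5 per unit relative abundance (roughly
  e-fold expression change across a 0.2-wide abundance range — a strong but
  realistic association); all other β1 are exactly zero, giving a clean null
  for FDR checks. Per-gene dispersions are log-normal around 0.1; library
  size factors log-normal (σ = 0.2).

All randomness flows from one integer seed through named substreams, so any
stage's output is bitwise reproducible and insensitive to changes in other
stages' draw counts.

**What passing tests on synthetic cohorts show — and what they do not.** The
generator produces overdispersed compositional counts with realistic
diversity variance, but its taxa are exchangeable labels without phylogeny,
its background is stationary across subjects, and it has no batch effects,
no contamination, no primer or copy-number bias, and no correlation between
translocation and transcriptome beyond the planted effects. Passing tests
therefore establish correctness of the statistics under their own model
assumptions (calibrated nulls, recovery of planted effects, exactness against
oracles) — not robustness to the artefacts of real 16S or RNA-seq data.

## Problem sizes used in validation

The automated checks run at deliberately modest scale, chosen so that the
full suite runs comfortably on a single CPU: 1000 random compositions for
the formula oracles; exhaustive PERMANOVA at n = 6 (720 permutations) plus a
500-replicate null calibration (24 samples, 199 permutations each); a
six-point π grid with 30 subjects per point; 100 planted and 100 matched
null replicates for the LDA screen; NB slope recovery at n = 50 with 20
replicates per slope; and a 10/10/10-subject end-to-end run with 40 genes.
`scripts/acceptance.py` recomputes all of these from scratch at the same
sizes.

## Known limitations

* PERMANOVA is single-factor; covariate adjustment (age, BMI) is out of scope.
* The LDA effect size is a fixed documented variant; numbers are not
  expected to coincide with any specific LefSe release.
* The NB GLM estimates dispersion per gene with no shrinkage, which is noisy
  at very small n; non-convergence is flagged rather than rescued.
* BIOM input is not supported; feature tables are TSV.
* No rarefaction, no phylogenetic (UniFrac-type) diversity, no ordination
  layouts, no plotting.
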