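# Methods

This note documents the statistical models behind `rsomics`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical choices that affect results.

## Differential testing (diffstats)

Per-feature ordinary least squares on M-values (methylation) or log2-CPM
(expression): `y ~ intercept + group + covariates`, where the group term is
an indicator for the first contrast group, so the coefficient is the
covariate-adjusted group difference. Covariates (e.g. estimated B-cell
fractions) enter as additive fixed effects only; no interactions.

Residual variances are shrunk with the standard empirical-Bayes hierarchical
model: feature variances are assumed to follow a scaled inverse-chi-square
prior with `d0` degrees of freedom and scale `s0²`, estimated by the moments
method on `log s²` (mean and variance of `log s²` corrected by digamma /
trigamma terms; the trigamma inverse is solved by Newton iteration). The
moderated statistic uses the posterior variance
`s̃² = (d0·s0² + df·s²)/(d0 + df)` and `df + d0` degrees of freedom. When the
observed spread of `log s²` is no larger than its sampling noise the prior
degrees of freedom are infinite: every feature receives the pooled variance
and the statistic is referred to a normal distribution. Features with zero
residual variance are excluded before moderation (logged), not given
infinite statistics.

P-values are two-sided; FDR control is the Benjamini–Hochberg step-up
`q_(i) = min_{j≥i} m·p_(j)/j`, capped at 1. On null simulations (no group
effect, 2000 features, 10 + 10 samples) the fraction of features with
p < 0.05 stays within [0.035, 0.065], which the acceptance suite checks.

## Methylation LPS classifier (lps)

Selection cascade (fixed order): CLL-vs-DLBCL differential CpGs at
q < 0.01 → removal of CpGs differential between IGHV-unmutated and -mutated
CLL at q < 0.01 (the removal is the intersection with the IGHV-differential
set) → removal of CpGs with |Δβ| ≤ 0.30. Δβ is the difference of group mean
beta-values; the filter uses the absolute value, consistent with symmetric
hypo-/hyper-methylation.

The score is the weighted sum of beta-values with moderated-t weights. Note
the deliberate scale mix: statistics (and hence weights) come from M-values,
while scoring uses beta-values, whose bounded range keeps single extreme
probes from dominating the sum.

Reference-group score distributions use the sample mean and unbiased
(n−1) variance; at least 3 samples per reference group are required and zero
variance is an error. The two-class posterior is computed from log-densities
through a logistic transform, `p_CLL = expit(logφ_CLL − logφ_DLBCL)`, so
well-separated groups saturate to 0/1 without underflow, and
`p_CLL + p_DLBCL = 1` holds exactly by construction. Labels use an inclusive
0.98 threshold on either posterior; everything else is "intermediate" (a
single label; relabelling intermediates as low-score CLL-derived is a
reporting choice this package does not make).

Rescaling all weights by a positive constant rescales the score and the
refitted group Gaussians coherently, leaving posteriors unchanged (asserted
numerically in the tests). Models serialize to versioned JSON so an external
cohort can be scored without retraining.

## RNA-seq preparation (rnaseq)

Features are kept when expressed (non-zero) in at least 2 samples and their
mean count is at least `max(20, mean library size / 5·10⁶)`; with deep
libraries the printed floor of 20 reads is the binding constraint, and the
threshold is exposed as a parameter. Filtering precedes normalization.

TMM scale factors follow the canonical trimmed-mean-of-M-values recipe:
reference sample = upper-quartile of count/library-size closest to the
cohort mean; M/A values computed over features expressed in both sample and
reference; 30% two-sided trim on M and 5% on A (rank-based); factor =
2^(precision-weighted mean of surviving M), with delta-method inverse
variances as weights; factors renormalized to geometric mean 1. The
implementation reproduces Bioconductor edgeR's factors to 1e-6 on a
negative-binomial fixture (frozen in the tests). log2-CPM uses
`log2((count + c)/(effective library + 2c) × 1e6)` with prior count
c = 0.5 — small enough not to distort quantification, large enough to keep
zeros finite.

## Signature derivation (signature)

Gene profiles are median-centered per row and compared with the uncentered
Pearson correlation distance `d = 1 − ⟨x,y⟩/(‖x‖‖y‖)` (range [0, 2]); since
rows are centered only by medians, profile level still contributes, which is
the intended behaviour of this distance. Agglomerative clustering (complete
or average linkage) runs on the full pairwise distance matrix; with distinct
pairwise distances the merge tree is unique and therefore deterministic.
Consensus k-means runs 20 seeded restarts, accumulates a co-assignment
matrix, and cuts its average-linkage tree at k.

The up/down cluster pair is chosen to maximize the absolute cluster-mean
contrast between the CLL-derived and DLBCL-like sample groups — an explicit
rule standing in for a visual dendrogram cut. The signature keeps
protein-coding members supported by the integrome (at least one significant
methylation–expression correlation) and assigns +1/−1 weights.

A synthetic stand-in for the published 215-gene signature ships with the
package (122 up / 93 down, synthetic identifiers); the real gene list sits
behind restricted supplementary data, so the packaged file reproduces only
its shape, letting the LCS machinery run end to end.

## Expression LCS classifier (lcs)

Steps: restrict features to signature genes → sum features per gene →
z-scale each gene (unbiased sd; zero-variance genes dropped, reducing n) →
trim positive outliers at the matrix-wide 99.9th permille → score →
standardize across the cohort. The trim threshold is an order statistic
(no interpolation), which makes trimming idempotent; only the positive tail
is trimmed. The standardized score is referred to the upper tail of a
standard normal ("one-way" test: high scores are RS-like), significance is
strict p < 0.05, and a top-fraction flag (default top 25%, ties broken by
sample order) marks the extreme scores.

Both standardizations are cohort-relative: the score of one sample depends
on the composition of the dataset it is screened in, so single samples
cannot be classified in isolation. This is a property of the method, not an
implementation shortcut.

## Integration (integration)

CpG–transcript pairs come from shared gene identifiers (carrying the array
feature class) and from coordinate overlap within an inclusive 2 kb window
around the TSS (labelled `TSSoverlap2kb`); identifier links win on
duplicates. Transcripts are the unit of computation; per-gene summaries are
roll-ups. Spearman correlations use mid-ranks; p-values use the
t-approximation `t = rho·√((n−2)/(1−rho²))` for n ≥ 10 and exhaustive
permutation below that (the approximation cannot reach p < 0.001 at tiny n).
Constant vectors yield undefined correlations and the association is dropped
with a logged count.

Candidate regions require ≥ 3 same-direction CpGs with |rho| > 1/3 and
p < 0.001 in promoter classes. Enrichment is observed/expected frequency;
association tests are two-sided Fisher exact or Pearson chi-square (no
continuity correction).

A power note: at n = 40 samples the p < 0.001 gate requires an observed
|rho| ≥ 0.50, so for promoters planted at rho = −0.6 the per-promoter
recovery probability is ≈ 0.80 — the recovery rate reported by the
acceptance script hovers at that ceiling by construction, not because of an
implementation defect.

## Synthetic cohorts (simulate)

The generator emulates the statistical architecture the analysis relies on:

- **Methylation.** Baseline CpG M-values from a bimodal mixture
  (N(3, 1) / N(−3, 1), i.e. beta modes near 0.89/0.11). Planted
  CLL-vs-DLBCL CpGs get group means set on the beta scale around 0.5 so the
  target differential (default 0.35) is attainable; effects are applied on
  the M scale and mapped through the logistic, because additive beta effects
  would saturate at the boundaries. The achieved |Δβ| is recorded in the
  ground truth (≈ 0.34 at the 0.35 target with noise sd 0.5). IGHV CpGs
  shift IGHV-unmutated samples of every group (+2 on the M scale). RS
  samples carry a global hypomethylation shift (−0.5 M) on top of their
  subgroup's effect pattern (CLL-like RS share CLL effects, DLBCL-like share
  DLBCL effects).
- **Expression.** Negative-binomial counts (dispersion 0.1, a typical bulk
  RNA-seq value) with log-normal library sizes (default 64 M ± 5%).
  Signature genes (4% of genes, up:down ≈ 122:93) separate the RS
  subpopulations by 1 log2 unit. For planted promoters, the gene's log-mean
  couples to the realized promoter mean M-value; the coupling constant is
  calibrated analytically — Moran's finite-n expectation of the sample
  Spearman coefficient is inverted for the target rho (default −0.6 over the
  RS compartment), and the attenuation from idiosyncratic per-CpG noise is
  undone. Promoter CpGs are tightly co-methylated (own noise sd 0.2 versus
  a shared promoter signal sd of 2.0), reflecting within-island correlation
  of array probes. Realized median Spearman across seeds is −0.60 ± 0.02.
- **Presets.** `small` (2000 CpGs, 500 genes, 60 samples) for fast tests;
  `medium` (20 000 CpGs, 5000 genes, 180 samples: 40 U-CLL, 40 M-CLL,
  60 DLBCL, 30 CLL-like RS, 10 DLBCL-like RS) for recovery experiments —
  sizes chosen so the full acceptance run stays under a minute while keeping
  reference groups at realistic cohort scale.

All randomness flows through the single config seed; equal configs produce
bit-identical bundles (checksummed manifests).

What the generator does **not** emulate — and what passing tests therefore
do not establish about real data: probe-level array artifacts (dye bias,
cross-reactive probes, detection failures), batch structure, cell-type
composition beyond a single optional nuisance covariate, linkage
disequilibrium of CpGs outside the planted promoter blocks, realistic
gene-length/GC effects on counts, isoform complexity (one transcript per
gene), and survival endpoints. Effects are planted with homogeneous sizes,
so recovery rates on synthetic cohorts bound the method's behaviour under
its own assumptions rather than predicting clinical performance.

## Numerical choices and degenerate inputs

- Beta clipping bound `eps = 1e−6` for the M transform; the logistic inverse
  is evaluated in its numerically stable branch on either sign.
- All variances that become denominators are validated > 0; zero-variance
  features/groups are dropped with logged counts or raise errors, never
  propagate NaN silently.
- BH adjustment, posterior logistic, and TMM geometric-mean renormalization
  are exact (no tolerance); tests against independent re-implementations
  assert 1e−9 or tighter.
- Matrix writers emit `%.17g`, so write → read round-trips are bit-exact.
- Tie-breaks: hierarchical clustering is deterministic for distinct
  distances (degenerate ties follow scipy's nearest-neighbor-chain order);
  the LCS top-fraction flag breaks score ties by sample order.

## Known limitations

- The packaged signature is a synthetic stand-in (shape only); applying the
  LCS to real cohorts requires the genuine gene list.
- The cohort-level funnel counts of the original study (e.g. the exact
  number of scoring CpGs) are not reproducible without the restricted
  patient data; synthetic cohorts reproduce structure, not those totals.
- IGHV exclusion removes the intersection of the two differential sets;
  published set sizes suggest the original bookkeeping differed slightly,
  and exact totals are unverifiable without the data.
- The Spearman exact-permutation branch enumerates all n! permutations and
  is only used for 5 ≤ n < 10.
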