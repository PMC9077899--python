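# Methods

## Model and procedure

The pipeline treats a gene expression matrix (GEM; genes × samples,
FPKM on the linear scale) with a categorical condition label per sample
(optionally quantitative covariates) and a directed TF → target
regulatory network as inputs, and produces a condition-specific
co-expression network (csGCN), per-edge regulatory assessments and
triangle motifs.

### Normalization

Raw FPKM values are log2-transformed with **zeros mapping to missing**
— no pseudocount. The downstream analysis ignores log2 values outside
[0, 15], which presumes log2 FPKM without an offset; a pseudocount
would compress exactly the low range where that filter operates.
Quantile normalization replaces each sample's non-missing values by the
mean sorted profile across samples, interpolated at the sample's own
average-tie ranks; columns with different missing counts are aligned on
a common quantile grid. Ties share the average of their ranks'
reference values, so the procedure is deterministic and permuted
columns normalize identically. Missing values propagate as masked and
are never imputed (except inside the classifier, below).

The Kolmogorov–Smirnov screen compares each sample's non-missing value
distribution against the pooled values of all other samples (the
reference is configurable; pooling is the default since a single
reference sample would itself need choosing) and flags samples with
D > 0.15. Flagging is advisory — removal is the caller's decision.

### Per-pair mixture clustering

For each gene pair, samples where both genes are non-missing and both
log2 values lie in [0, 15] are kept. Pairs with < 30 usable samples are
skipped. Full-covariance Gaussian mixtures with k = 1..5 components are
fit (k-means++ initialization, per-pair seed derived deterministically
from the global seed and the two gene indices, so results are
independent of pair enumeration order and sample column order); k is
chosen by minimum BIC and samples are assigned to their maximum-
posterior component. Components with < 30 members are discarded: 30 is
the minimum cluster size at which a Spearman correlation of ~0.5 has
usable power at α = 0.001.

### Edge tests

* **Similarity**: Spearman ρ within the cluster; candidate iff
  |ρ| > 0.5. Zero variance in either gene yields no candidate.
* **Power**: Fisher-z approximation,
  power = Φ(|atanh ρ|·√(n−3) − z₁₋α/₂) with α = 0.001; clusters below
  power 0.8 (20% Type II error) are dropped.
* **Categorical condition association**: two one-sided z-tests of
  proportions with pooled variance and no continuity correction.
  Test 1 compares the fraction of in-cluster samples carrying the label
  against that fraction out-of-cluster; test 2 compares the capture
  rate of labeled samples by the cluster against the capture rate of
  unlabeled samples. The cluster is labeled iff both enrichment
  p-values < 0.001. One-sided testing reflects that only *enrichment*
  marks condition specificity; depletion is not a label.
* **Quantitative covariates**: simple linear regression between the
  cluster-membership indicator and the covariate; labeled iff r² > 0.30
  and slope p < 0.001. r² and the slope p-value are identical in both
  regression orientations, so the unresolvable question of which
  variable is the response has no effect.
* **Differential cluster expression (DCE)**: both genes must shift
  between in-cluster and out-of-cluster samples — Welch's test per gene,
  keep only if both p ≤ 0.001. With exactly two groups Welch's one-way
  ANOVA coincides with Welch's t-test, which is how it is computed.
* **Missingness balance**: within each labeled condition's samples, the
  two genes' per-sample missingness indicators are compared by
  equal-variance Student's t-test; the edge is dropped at p < 0.1.
  Missingness concentrated in one gene in one condition means sample
  removal before correlation biased the condition association. With no
  missing values the test is undefined and the edge is trivially kept.

Retained edges are ranked by |ρ| descending, then r² descending (where
present), then smallest condition-test p ascending; ranking is stable
and removes nothing.

### Regulatory integration

Differential expression between two conditions uses a negative-binomial
Wald GLM (log link, method-of-moments dispersion pooled across groups
and floored at 1e-8) for linear/counts-scale input, or Welch's t-test
on log2 values for normalized input; p-values are Benjamini–Hochberg
adjusted across genes and a gene is a DEG at adjusted p < 0.001. The
NB-Wald route reproduces the operative contract of the standard DE
callers (DEG flag and direction at a given threshold) without
size-factor estimation or dispersion shrinkage.

The TF/TR ratio statistic is computed per sample on the **linear**
scale as (TF + ε)/(TR + ε) with ε = 0.01 (a log-scale ratio would be a
difference and change the test; linear is the default, configurable),
and compared between conditions with the classical equal-variance
Student's t-test at p < 0.001, unadjusted. An edge whose two genes are
DEGs and whose ratio shifts is *doubly significant* and falls in
exactly one of four directional categories (TF up/down × TR up/down);
the categories partition the doubly-significant edges by construction.

Triangle motifs are (TF, edge) incidences: one motif per TF regulating
both endpoints of a condition-subnetwork edge, ordered
lexicographically. A TF in several triangles appears once per edge.
Self-targeting regulatory edges never form triangles.

### Network summaries

Average connectivity is mean degree 2E/N. The mean local clustering
coefficient counts nodes of degree < 2 as contributing 0 (rather than
excluding them), which makes acyclic subnetworks score exactly 0.
Display rounding is half-up to two decimals. Unique nodes/edges of a
condition subnetwork are those appearing in no sibling subnetwork;
edges are unordered pairs.

### Classifier validation

The MLP has three hidden layers of 512, 256 and 128 ReLU units with a
softmax output, trained on a 70% split. The split is **stratified** by
class — a deviation from plain random splitting, adopted because at
small sample counts a random split can lose a class entirely. Missing
expression is imputed to 0 for the classifier only (recorded in the
report). Optimizer settings (Adam, learning rate 1e-3, max 300 epochs)
are fixed in `ClassifierConfig` and logged; results are deterministic
given (seed, data).

## Synthetic data: what it emulates, and what it does not

The generator produces log-normal linear-scale expression (a log2
Gaussian latent, exponentiated) so the normalization path is exercised.
Planted condition-specific pairs draw from a Gaussian copula with
Pearson r = 2·sin(π·ρ_s/6), giving an exact target Spearman ρ_s within
the active condition and independence elsewhere. Planted pairs also
shift their mean by +3 log2 units within the active condition: without
a mean shift the mixture model has nothing to separate on, and the DCE
filter — which demands both genes shift between in- and out-of-cluster
samples — would correctly remove every planted edge. This mirrors real
cohorts, where condition-specific co-expression co-occurs with
condition-specific expression level. Planted-structure genes keep
their shifted means inside the background mean range (4–9 log2 units)
so rank-based quantile normalization retains resolution where the
signal lives; at a realistic gene count the distortion is negligible,
but small fixtures put planted genes in sparse tail ranks otherwise.

Regulatory chain edges generate the target as base + slope·(TF − base)
+ Gaussian noise with per-condition slope. Triangle TFs are
presence-only regulatory edges onto both genes of a planted pair, with
the TF's expression shifted by −1.5 log2 units in the pair's active
condition so TF/TR ratios move between conditions. DEG genes shift by
±2 log2 units between the first two conditions. Missingness is
independent Bernoulli per cell at (gene, condition)-specific rates.

Defaults (20 pairs at ρ = 0.85 with +3 shift, 8 chain + 4 triangle
regulatory structures, 10 DEGs at |log2FC| = 2, base σ = 0.8) describe
strong, cleanly recoverable structure. What passing tests therefore
show is that the *machinery* is correct — thresholds act where they
should, labels attach to the right condition, counts partition. They
do not show that real tumor cohorts yield comparable recovery: real
data has correlated backgrounds, batch structure, heavier tails and
weaker, denser signal than the planted fixtures.

## Problem sizes and numerical choices

The per-pair GMM stage is quadratic in genes, so test and example runs
restrict the pair enumeration to the planted gene block (40 genes ≈ 780
pairs, ~35 s) or cap `max_pairs`; the benchmark fixture is 200 genes ×
3 conditions × 100 samples. GMM fits use `reg_covar` = 1e-6;
non-converged k values are skipped with a warning; an all-k failure
skips the pair. Degenerate cases resolve conservatively: constant
genes produce no correlation candidate, undefined DCE p-values drop the
edge, undefined missingness p-values keep it (no evidence of bias),
conditions absent from a pair's analyzable samples yield unlabeled
results with NaN p-values. Seeds below 2³¹ are derived per pair as
(seed·1000003 + i·131071 + j·8191) mod (2³¹ − 1).

## Known limitations

* No batch-effect correction; inputs are assumed batch-corrected
  upstream.
* The two proportion z-tests are a reconstruction of the intended
  enrichment tests from their description; the exact forms are
  module-local and swappable.
* The NB-Wald DE test is not a DESeq2 replica (no size factors, no
  dispersion shrinkage); calls near the threshold can differ.
* Whether Welch's screen should group by cluster membership or by
  condition label is ambiguous in the original description;
  in-cluster-vs-out is implemented.
* Ratio-test p-values are deliberately unadjusted for multiplicity.
* Triangle counting is per (TF, edge) incidence; per-node-triple
  counting would give different totals on dense regulatory networks.
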