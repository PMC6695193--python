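# Methods

## The model

DNA methylation at a CpG site is measured as a beta value — methylated
signal over total signal — so a gene's methylation across tumors is a
random variable on (0, 1).  The pipeline asks two questions of every
CpG cluster: *is its methylation differentially distributed in tumors
relative to normal tissue*, and *does that methylation predict a
downstream molecular layer*?  Only genes answering yes to both are
called methylation-driven.  The downstream layer is gene expression in
GE mode and protein abundance in PA mode; comparing the two lists
isolates genes whose transcript-level methylation effect is buffered
before the proteome (post-transcriptional, translational or degradation
regulation).

### Step 1 — beta mixture per cluster

Tumor betas of a cluster are modeled as a K-component mixture of
Beta(α_k, β_k) densities.  K is selected forward: starting at K = 1,
a (K+1)-component fit replaces the current model only if it strictly
lowers

    BIC = −2 log L + (3K − 1) log n

(two shapes per component, K − 1 free weights).  Each accepted component
is a *methylation state*: a patient subgroup with a distinct methylation
level.  Samples are assigned to states by maximum posterior, ties going
to the lower-mean state.

EM specifics (the literature leaves them open; these are this package's
choices):

* values are clamped to [1e−3, 1 − 1e−3] before likelihood evaluation;
* the M-step solves the weighted beta maximum-likelihood equations
  ψ(α) − ψ(α+β) = E[log x], ψ(β) − ψ(α+β) = E[log(1−x)] exactly by
  damped Newton iteration on the digamma system, vectorized over
  components and warm-started from the previous EM iterate.  Because the
  M-step is an exact maximizer, the observed-data log-likelihood is
  non-decreasing across iterations (asserted; a numerical decrease
  aborts the candidate);
* convergence at |Δ log L| < 1e−6 or 500 iterations;
* initialization: a deterministic quantile split of the sorted values,
  plus 4 random seed-point restarts.  Restarts use the short-EM
  strategy: every initialization runs at most 50 iterations and only the
  best is continued to convergence — the selected optimum is the same as
  running every restart to convergence at a fraction of the cost;
* shape parameters are bounded in [1e−3, 1e7]; a candidate is rejected
  if any mixing weight falls below 1/n (less than one expected sample);
* a zero-spread cluster returns a degenerate one-state model.

### Step 2 — differential state calling

Each state's DM value (differential methylation) is its component mean
μ_k minus the mean beta of normal samples.  States with ≥ 3 assigned
tumor samples are tested by a two-sided Wilcoxon rank-sum of member
betas against the normal betas (exact enumeration when min(n, m) ≤ 8
and tie-free, otherwise the normal approximation with tie and continuity
correction).  P-values are Benjamini–Hochberg corrected **pooled over
all (cluster, state) tests in the run**; a state is flagged when
q ≤ 0.05 **and** |DM| ≥ 0.10.  The 0.10 floor reflects array platform
sensitivity; the pooling scope is a package choice (per-run), as is
testing state members rather than all tumors.

### Step 3 — functional filter

Downstream values are regressed by OLS on the cluster's raw per-sample
betas over samples matched between the methylation and downstream
matrices (mixture fitting uses all tumor methylation samples; only the
matched subset enters the regression).  A cluster passes when slope < 0
(promoter methylation should silence), R² > 0.05 (strict), and the
regression q-value — BH-pooled over all tested clusters per layer —
is ≤ 0.01.  A gene is a driver when at least one of its clusters has a
flagged state and passes the filter; its direction is the sign pattern
of flagged DM values (hyper / hypo / mixed).

The run also emits the DM matrix (tumor samples × driver clusters):
a sample carries its assigned state's DM value when that state is
flagged, otherwise 0 — normal-like samples thus sit at 0, and the matrix
encodes deviations from normal.

## Preprocessing

* CpG features with **more than** 10% missing entries are removed, then
  missing values are imputed by 15-NN: neighbors are other features
  (the expression-imputation convention; the axis is configurable),
  distance is Euclidean over co-observed samples rescaled to the full
  sample count, and the imputed value is the mean of the k nearest
  features' values in that sample.  Observed cells are never altered;
  imputed betas are clamped to [0, 1].  Note 15-NN only helps where
  features genuinely co-vary (dense probe blocks); on independent
  features it averages noise and a column mean does as well or better.
* Protein samples: per-sample SD across genes (pairwise-complete) is fit
  with a 1-D two-component Gaussian mixture; the higher-mean component is
  degraded material and removed.  If one component wins by BIC, the two
  means are indistinguishable, or the fit collapses onto a single
  occupied component, nothing is removed and a warning is recorded —
  degenerate fits must not discard data.  Samples with **more than** 75%
  missing proteins are dropped.
* Label-free counts are quantile normalized (mean order statistics,
  ties averaged, missing-aware by interpolating each sample's empirical
  quantile function) and log2-transformed with a +1 pseudocount
  (configurable); log infinities can be replaced by 1e−3 of the smallest
  positive value.
* Batch correction is a pluggable hook (matrix in / matrix out plus
  labels).  The shipped reference is per-feature, per-batch
  location/scale standardization that equalizes batch means and
  preserves the grand mean; empirical-Bayes correctors can be plugged in
  unchanged.

## CpG clustering

Probes are clustered per chromosome (clusters map to a single TSS, so
they may not span chromosomes) by complete-linkage hierarchical
clustering on 1 − Pearson r, cut at height 1 − 0.4.  The complete-
linkage cut guarantees min pairwise r ≥ 0.4 inside every cluster, which
implies the average-r criterion; the average is still asserted on every
output.  Constant probes are uncorrelatable (distance 1) and become
singletons with a warning.  A cluster's profile is the per-sample mean
beta of its members; its representative position is the median member
position; it maps to the gene with the nearest TSS (absolute genomic
distance, strand used only to locate the TSS; equidistant ties go to the
lexicographically smallest gene id).  Many clusters may map to one gene;
each cluster maps to exactly one (cis effects only).

## Evaluation

**Consensus clustering** of the DM matrix: for each K in 2..6, 500
bootstrap subsamples of ⌈0.8 n⌉ samples are clustered by k-means
(Euclidean, 10 k-means++ restarts per subsample); consensus(i, j) is the
co-clustered count over the co-sampled count (never co-sampled pairs are
missing and excluded from the scores).  Final labels come from
average-linkage clustering of 1 − consensus cut at K — the label
extraction rule is a package choice.  Stability is summarized by the PAC
score (fraction of off-diagonal consensus entries strictly inside
(0.1, 0.9), the conventional interval; configurable) and by intra/inter
cluster consensus (mean consensus over same-/different-cluster pairs,
0–100 scale).  Lower PAC, higher intra and lower inter indicate a more
stable K.

**Cluster–covariate association**: chi-squared on the contingency table
for categorical covariates, Kruskal–Wallis across clusters for ordinal
or continuous ones; missing values dropped per feature; single-level
features reported untestable; optional BH across features.

**Tumor-marker enrichment**: for every background gene, expression is
Spearman-correlated with an ordinal (stage) or continuous (size)
clinical variable.  Markers need p < 0.05, variance at or above the
median across background genes ("top 50th quantile"), and — when the
gene's methylation direction is known — a sign consistent with it:
hyper-methylated candidates (tumor suppressors) must correlate
negatively with progression, hypo-methylated ones (oncogenes)
positively.  Driver-list enrichment for markers is a two-sided Fisher
exact test (probability-mass rule) on the marker × driver 2×2 table over
the background; a generic Fisher over-representation against GMT gene
sets is provided in place of any external annotation service.

## The synthetic generator

The generator produces cohorts with the exact statistical structure the
pipeline assumes, so every stage is testable without external data.
Defaults define the study conditions: 150 tumors, 30 normals; 10 + 10
hyper/hypo drivers, 20 buffered genes, 60 nulls; normal-like and
aberrant methylation means 0.2 and 0.7 (DM 0.5) with beta concentration
40 (per-state SD ≈ 0.06); aberrant-state weight 0.4; expression
= 8 − 2·β + N(0, 0.5²); protein = −2·β + N(0, 0.5²) for drivers and
slope 0 for buffered and null genes.  Couplings are linear on the beta
scale, matching the pipeline's linear filter.  Each gene's cluster is
expanded into 3 probes = cluster beta + N(0, 0.02²), placed within
100 bp of the gene's TSS on a two-chromosome layout, so probe clustering
and TSS mapping run end to end.  Clinical stage is four ordinal levels
thresholded from a latent score driven by marker-gene expression
(suppressor-like markers oriented negative), tumor size is log-normal
around the same score, and batches are balanced round-robin labels with
centered additive shifts available through the perturbation helper
(missing-completely-at-random masking plus batch offsets, with the truth
retained for error measurement).

What the generator does **not** emulate: realistic 450k probe density
and genomic autocorrelation, non-linear methylation–expression dose
response (a stress-test option exists), mRNA–protein coupling beyond the
shared methylation signal, cellular heterogeneity, and
missing-not-at-random proteomics dropout.  Passing tests therefore
demonstrate correctness of the algorithms under their own assumptions,
not performance on real cohorts.

## Problem sizes in the test suite

The acceptance-style checks use cohorts of 100 genes × 150 tumors,
100-cluster mixture-recovery batches at n = 500, consensus runs with 100
bootstrap subsamples, and exhaustive statistic sweeps (all rank-sum
layouts with min(n, m) ≤ 6; all 2×2 tables with margins ≤ 30).  These
sizes were chosen so the full suite runs comfortably on a single CPU
while keeping every estimate's Monte-Carlo error well below the margins
being asserted.

## Known limitations

* Beta-mixture BIC selection has an inherent false-split rate that grows
  as cohorts shrink (≈ 5% at n = 80, ≈ 0.3% at n = 150 on unimodal
  Beta(5,5) data); the differential q/DM gates and the functional filter
  keep the end-to-end null driver rate ≪ 1%, but state counts from small
  cohorts should be read cautiously.
* The mixture likelihood is unbounded; shape caps and the minimum-weight
  rule suppress degenerate spike components but cannot remove them
  entirely.
* The marker direction rule needs a per-gene methylation direction;
  genes with mixed hyper/hypo flagged states keep marker status on
  p/variance alone.
* Consensus k-means assumes roughly spherical DM clusters; strongly
  elongated methylation subtypes may fragment.
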