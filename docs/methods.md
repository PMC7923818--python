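# Methods

This note documents the models and procedures menmetab implements, the
parameter choices that matter, what the synthetic cohort does and does not
emulate, and the numerical decisions taken where the design was open.

## The synthetic cohort generator

The generator (`synthdata`) produces the conditions under which the whole
pipeline is validated. On the log₂ scale each metabolite intensity is

    x_sj = b_j + e·1{sample s in the subtype marked by metabolite j}
         + ρ·f_{m(j),s} + ε_sj,

exponentiated to the positive raw scale. The pieces:

- **Baseline** b_j ~ N(0, 1) per metabolite — a lognormal abundance
  spread, chosen because small-cohort NMR studies do not publish an
  abundance distribution.
- **Subtype effect** e (`effect_size`, default 1.0 log₂-fold) applied to
  the subtype's signature set: glycine/serine/arginine/creatine/glutamate
  for subtype I, choline/phosphocholine/sphingosine/isoleucine for II-a,
  tryptophan/kynurenine/kynurenic-acid/choline for II-b. Choline sits in
  both II-a and II-b sets: the choline pathway marks the whole second
  cluster.
- **Modules.** Five modules of 12 metabolites share a latent factor
  f_m ~ N(0,1) with loading ρ (`module_loading`, default 0.6); residual
  noise is ε ~ N(0, noise_sd²) with noise_sd = 0.5. The first three
  modules are *anchored* on the signature pathways and their factors are
  mean-shifted by `anchor_activation`·e in the matching group (module 1 in
  subtype I, module 2 in the whole second cluster, module 3 in II-b);
  modules 4–5 are pure co-abundance. Anchoring is what makes module
  eigengenes carry clinical contrasts, exactly as the pathway modules in
  the motivating cohort tracked grade and edema. `anchor_activation`
  defaults to 4.0 — a large but fixed pathway-activation difference chosen
  at design time so the generator's own contract holds under the default
  effect size, loading and noise: the two-cluster structure is recoverable
  (k = 2, ARI ≥ 0.9), the five modules are detectable, and the
  subtype-I module eigengene anti-correlates with edema. Module filler
  members come from the unnamed (numbered) metabolites so that the named
  pathway library stays orthogonal to filler and only planted pathways
  appear enriched.
- **Clinical covariates** are drawn with per-cluster margins mirroring the
  cohort's baseline table (sex 2/15 vs 8/28 male, edema rates 4/15 vs
  18/28, location and Simpson-grade multinomials, age normals 62.3 ± 13.1
  vs 64.4 ± 12.8, tumor volume lognormals moment-matched to 48.3 ± 51.8 vs
  88.6 ± 103.3 cm³). MIB-1 proliferation is lognormal per subtype with
  mean exactly 1.2 / 2.1 / 11.7 % (σ_log = 0.25, giving interquartile
  ranges near the reported 0.3 / 0.7 / 4.3). WHO grade is grade I
  throughout cluster 1 and subtype II-a; subtype II-b carries 12 grade-II
  and 3 grade-III tumors, so the second cluster holds 13 benign and 15
  higher-grade samples. `exact_margins=True` reproduces the categorical
  counts deterministically (for testing the cohort-statistics layer);
  otherwise margins hold in expectation.
- **Survival.** Progression-free survival is exponential with per-cluster
  hazards 0.01 / 0.05 events·month⁻¹ (a 5× ratio; the source cohort
  reports only that the benign cluster progressed later), administratively
  censored at 60 months. Subcluster sizes (13 + 15) and the censoring
  pattern are configuration, not claims.

**What passing tests do not show.** The generator has Gaussian log-scale
noise, exact factor structure, no batch effects, no missing values, and no
NMR artifacts (phasing, baseline roll, water residual). Recovery rates on
it demonstrate algorithmic correctness and calibration, not performance on
real tissue extracts.

## Spectra

The toy spectral stage uses a 2¹⁴-point grid spanning the 16.02 ppm
acquisition sweep centered at 4.691 ppm (the instrument's 64k time-domain
points are unnecessary at this scale). Templates are Lorentzian peak lists
at standard ¹H shift positions with unit total area, so NNLS coefficients
are intensities on the area scale. Alignment takes the maximum-intensity
point within ±0.05 ppm of 1.310 ppm as the lactate apex — argmax without
quadratic interpolation, the simplest contract consistent with setting a
reference peak — and translates the spectrum by whole grid steps (edge
fill 0), so a planted offset is recovered to within one grid step
(~0.001 ppm). The simulator boosts the lactate doublet to at least 2× the
largest other signal, as lactate dominates real tumor extracts (which is
why it serves as the reference); the doublet apex is drawn slightly
asymmetric so peak-picking is unambiguous. Quantification is deterministic
non-negative least squares; Bayesian template fitting is out of scope.

## Normalization

Pseudo-counted quantile normalization adds a pseudocount (default 1.0)
and replaces each sample's sorted intensities with the across-sample mean
of order statistics; ties receive the mean of the reference quantiles they
span, so equal inputs map to equal outputs and a second pass is a no-op.
The reference statistic (mean of order statistics) is the standard
quantile-normalization convention; the pseudocount keeps zeros positive
for the log₂ transform. Feature selection keeps the n = 100 metabolites of
largest unbiased sample variance, ties broken by name for determinism.

## Clustering

Distances are Euclidean on the top-100 log₂-centered matrix (correlation
distance 1 − r is available). PAM runs BUILD + SWAP with best-improvement
exchanges; because SWAP is a local search, eight seeded random restarts
supplement the deterministic BUILD start and the lowest-cost solution is
kept — on instances small enough to enumerate this reaches the exhaustive
optimum, and the result is deterministic given (data, k, seed). The
selected k maximizes the mean silhouette width over k = 2…12, ties going
to the smallest k; samples with negative silhouette are flagged non-core
and excluded from signature extraction. Subtypes inside a cluster are
found by re-running the same selection restricted to that cluster's
samples.

Nearest shrunken centroids standardize class-vs-overall differences by the
pooled within-class SD offset by s₀ = median per-metabolite pooled SD and
by m_k = √(1/n_k − 1/n) (the standard error of x̄_k − x̄, since the overall
mean contains class k). Δ is chosen by stratified k-fold cross-validation
with the one-standard-error rule: the largest Δ whose CV misclassification
is within one binomial SE of the minimum. On strongly separated cohorts
the CV error is zero over a wide Δ range and the rule then returns a very
sparse signature — a deliberate parsimony property: the selected set is a
minimal discriminative signature, not an exhaustive list of differential
metabolites. The per-metabolite linear-model route (slope of a class
indicator, t-test, Benjamini–Hochberg) is the exhaustive counterpart, and
both are reported side by side because the originating analysis used
either interchangeably.

## Network analysis

The network is **signed**: a_ij = ((1 + r_ij)/2)^β. An unsigned |r|^β
variant is available but is not the default, because pathways regulated in
opposite directions between subtypes (here: the glycine/serine module up
in cluster 1, the choline module up in cluster 2) are strongly
anti-correlated, and an unsigned network fuses them into one module — we
measured cross-module TOM dissimilarity (0.65) below the within-module
values of weaker modules (0.9), making the fusion unresolvable at any cut.
β is the smallest power whose connectivity distribution passes the
scale-free criterion (signed R² ≥ 0.8 of the log-density vs log-k fit):
the R² is signed by the slope, since a good fit with *increasing* p(k) is
the signature of an unstructured dense network, and the density is
estimated over equal-count (quantile) bins — equal-width bins on a few
hundred metabolites make the criterion unstable.

Modules come from average-linkage clustering of 1 − TOM with a static cut
at 0.75 replaced by 0.95: within-module TOM dissimilarity at ρ = 0.6 and
noise 0.5 lies around 0.85–0.95 at any useful β, so a 0.75 cut detects
nothing; 0.95 separates modules (which join below it) from background
(≈ 0.99+). A membership reassignment stage follows, as in standard module
detection practice: each metabolite joins the module of its highest
eigengene correlation when that kME ≥ 0.55 (≈ 3.5 null SDs at n = 43),
rescuing members the static cut strands in grey; modules whose eigengenes
correlate above 0.9 are merged. Eigengenes are the first principal
component of the standardized member submatrix, unit variance, oriented to
correlate positively with members on average. Module–trait statistics
report both the Pearson/point-biserial correlation (p from the t transform
at n − 2 df, BH across the full module × trait grid) and a
single-predictor logistic regression for binary traits, because the
originating analysis is ambiguous about which it printed. The
cluster-of-clusters view clusters eigengenes and standardized metabolite
profiles as one object set under correlation distance, where the
metabolite–module distance is exactly 1 − kME.

## Enrichment

The enrichment score is implemented as the observed/expected hit ratio
ES = (k/n)/(K/N) with an upper-tail hypergeometric p — the originating
analysis does not define its "Enrichment Score", so this convention is
declared, and published ES values are not comparison targets. The
quantitative variant uses the mean |Welch t| of set members between the
two clusters against a label-permutation null with +1 smoothing
(p ≥ 1/(n_perm + 1) by construction). The universe is all quantified
metabolites; the built-in library covers the six pathways the named
metabolites span.

## Cohort statistics

The two-sided Fisher p sums, over the hypergeometric support of the
observed margins, every point probability ≤ the observed one × (1 + 1e-7),
computed in log space — the convention that reproduces the published
two-decimal values (0.45, 0.16, 0.64, 1, 0.54). Pearson χ² defaults to no
continuity correction, which reproduces the published edema p = 0.02
(Yates correction does not); the corrected variant sits behind a flag.
The t-test is Welch's from summary statistics (n, mean, SD) — the form a
reader can recompute from a published table row — with Welch–Satterthwaite
df. Wilcoxon rank-sum enumerates the exact rank-sum distribution when
n₁ + n₂ ≤ 12 without ties, else uses the normal approximation with tie and
continuity corrections. Kaplan–Meier is the product-limit estimator with
Greenwood variance; the log-rank test uses the standard
observed-vs-expected decomposition with hypergeometric variance at each
event time. A small set of published rows (spinal location 0.11,
proliferation 0.01, Simpson grade 1 0.74, pathology 0.001) cannot be
reproduced from their printed counts under any of the four tests and are
flagged rather than targeted. The published log-rank p (0.0083), the
module–trait correlations and the enrichment scores depend on the
undeposited patient-level data and are likewise not reproducible; the
pipeline computes each quantity from synthetic cohorts instead.

## Problem sizes

Validation runs use the study dimensions throughout: 43 × 270 cohorts,
k = 2…12, β = 1…20, 20 seeded replicates for recovery rates, 200–1000
permutations for calibration checks, and 2¹⁴-point spectra — sizes at
which the complete test suite and the acceptance script each finish in
well under a minute of compute per stage on one CPU.

## Known limitations

- The static-cut + kME-rescue module detector is a simplification of
  dynamic tree cutting; very unequal module strengths may still require
  adjusting the cut height.
- The shrunken-centroid one-SE rule yields minimal signatures on separable
  cohorts (see above); use the linear-model route when an exhaustive
  differential list is wanted.
- The spectral stage models neither phase/baseline artifacts nor
  multiplet-aware alignment; it is a deterministic desk-scale stand-in.
- Fisher's two-sided convention and the no-continuity χ² are choices among
  several defensible conventions, fixed to match the published reporting.
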