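# menmetab

Metabolomic subtyping of tumor NMR profiles — a tested re-implementation of
the analysis pipeline used to stratify meningiomas by their metabolite
fingerprints: from 1D ¹H spectra (or quantified intensity tables) through
normalization, unsupervised clustering, co-abundance network analysis,
pathway enrichment, and clinical cohort statistics.

The package is aimed at computational biologists who want to run, probe, or
extend this class of small-cohort metabolomics analysis. Because raw
clinical NMR cohorts of this kind are rarely deposited, a first-class
synthetic-cohort generator reproduces the statistical structure the
analysis assumes (43 samples × 270 metabolites, two planted clusters of
15/28 with the second splitting 13 + 15, five correlated metabolite
modules, cluster-linked covariates and progression-free survival), so every
stage is testable end to end.

## What it computes

- **Spectra** — alignment of toy 1D spectra to the L-lactate doublet at
  1.310 ppm (apex within ±0.05 ppm moved onto the nearest grid point) and
  metabolite quantification by non-negative least squares on a Lorentzian
  template library.
- **Normalization** — pseudo-counted quantile normalization (each sample's
  sorted intensities replaced by the mean order statistics), log₂
  transform, per-metabolite median centering, top-variance feature
  selection.
- **Clustering** — Partitioning Around Medoids (BUILD + SWAP with seeded
  restarts) over k = 2…12 on the top-100 matrix; the selected k maximizes
  the mean silhouette width s(i) = (b−a)/max(a,b); samples with s(i) < 0
  are dropped as non-core; subtype signatures by nearest shrunken
  centroids, d_ik = (x̄_ik − x̄_i)/(m_k(s_i + s₀)), soft-thresholded at a
  cross-validated Δ, and by per-metabolite linear models with
  Benjamini–Hochberg correction.
- **Network analysis** — signed soft-threshold adjacency ((1+r)/2)^β with
  β chosen by scale-free topology fit, topological overlap
  TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j)+1−a_ij), average-linkage
  module detection with a kME reassignment stage, module eigengenes (first
  principal component), module membership kME, module–trait correlation and
  logistic statistics, hub extraction, joint cluster-of-clusters ordering,
  GraphML export.
- **Enrichment** — over-representation (hypergeometric upper tail,
  ES = (k/n)/(K/N)) and quantitative permutation enrichment against a
  built-in pathway library.
- **Cohort statistics** — Fisher's exact test (two-sided, by point
  probability), Pearson χ² (no continuity correction by default), Welch's t
  from summary statistics, Wilcoxon rank-sum (exact for small untied
  samples), Kaplan–Meier curves and the log-rank test.

## Worked example

```python
import menmetab as mm

matrix, clinical, truth = mm.simulate_cohort(mm.SimulationConfig(seed=1))
centered = mm.log2_median_center(mm.pq_normalize(matrix))
top = mm.top_variable(centered, 100)

res = mm.select_k(top, k_range=range(2, 13), seed=1)
print(res.k_selected, res.cluster_sizes)
# 2 {0: 15, 1: 28}

d = clinical.data
surv = mm.log_rank(d["pfs_time"], d["pfs_event"], res.labels)
print(round(surv.chi2, 2), f"{surv.p:.2e}")
# 19.53 9.93e-06
```

Silhouette-selected PAM finds the two planted metabolic clusters at their
true sizes (15 benign-leaning, 28 with higher proliferation and edema), and
the log-rank test detects the planted 5× progression hazard between them.
The scripts in `examples/` walk through each capability (simulation,
spectra, clustering, networks, enrichment, survival) and print the numbers
with a line on what they mean; the command-line entry point `menmetab`
exposes the same stages (`menmetab simulate`, `menmetab cluster`,
`menmetab run-all`, …) for shell use.

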