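"""Unsupervised subtyping: PAM, silhouette model selection, and subtype signatures.

The subtyping stage clusters sample metabolite profiles with Partitioning
Around Medoids (k-medoids, BUILD + SWAP) over a range of cluster numbers,
selects the k that maximizes the mean silhouette width, drops samples with
negative silhouette width ("non-core" samples that fit their assigned
cluster worse than the nearest alternative), and extracts the metabolites
that discriminate the clusters by two routes: a nearest-shrunken-centroid
classifier with cross-validated shrinkage, and per-metabolite linear models
with Benjamini-Hochberg correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import MetaboliteMatrix


class DegenerateDataError(ValueError):
    """All samples identical (or otherwise unclusterable) input."""


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def sample_distances(matrix: MetaboliteMatrix, metric: str = "euclidean") -> np.ndarray:
    """Pairwise sample-profile distances.

    metric: 'euclidean' (default) or 'correlation' (1 - Pearson r).
    """
    x = matrix.to_numpy()
    if metric not in ("euclidean", "correlation"):
        raise ValueError(f"unknown metric {metric!r}")
    return squareform(pdist(x, metric=metric))


# ---------------------------------------------------------------------------
# PAM (k-medoids, BUILD + SWAP)
# ---------------------------------------------------------------------------

def pam(
    dist: np.ndarray,
    k: int,
    seed: int = 0,
    max_iter: int = 200,
    n_restarts: int = 8,
) -> tuple[np.ndarray, np.ndarray, float]:
    """k-medoids (PAM: BUILD + SWAP) on a precomputed distance matrix.

    BUILD greedily seeds k medoids (first = the sample minimizing total
    distance, then whichever sample most reduces total cost); SWAP then
    iterates best-improvement medoid/non-medoid exchanges until no single
    swap lowers the total cost.  Because SWAP is a local search, the
    deterministic BUILD start is supplemented with ``n_restarts`` seeded
    random initializations and the lowest-cost solution is kept — on
    small instances this reliably reaches the exhaustive optimum.  Cost =
    sum of distances of samples to their nearest medoid.  The result is
    deterministic for a given (dist, k, seed); remaining tie-breaks are
    by lowest index.

    Returns (labels, medoid_indices, cost).
    """
    n = dist.shape[0]
    if dist.shape != (n, n):
        raise ValueError("dist must be square")
    if not (2 <= k < n):
        raise ValueError(f"k must satisfy 2 <= k < n_samples ({n}), got {k}")

    # BUILD
    medoids = [int(np.argmin(dist.sum(axis=0)))]
    while len(medoids) < k:
        d_near = dist[:, medoids].min(axis=1)
        # gain of adding candidate c: sum of positive reductions
        gains = np.maximum(d_near[None, :] - dist, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))

    rng = np.random.default_rng(seed)
    starts = [sorted(medoids)]
    for _ in range(n_restarts):
        starts.append(sorted(rng.choice(n, size=k, replace=False).tolist()))

    best_meds, best_cost = None, np.inf
    for start in starts:
        meds, cost = _pam_swap(dist, list(start), max_iter)
        if cost < best_cost - 1e-12:
            best_meds, best_cost = meds, cost
    labels = np.argmin(dist[:, best_meds], axis=1)
    return labels, np.asarray(best_meds), best_cost


def _pam_swap(dist: np.ndarray, medoids: list[int],
              max_iter: int) -> tuple[list[int], float]:
    """Best-improvement SWAP until no exchange lowers the cost."""
    n = dist.shape[0]

    def total_cost(meds: Sequence[int]) -> float:
        return float(dist[:, list(meds)].min(axis=1).sum())

    cost = total_cost(medoids)
    for _ in range(max_iter):
        best = (0.0, None, None)
        med_set = set(medoids)
        for mi in range(len(medoids)):
            others = medoids[:mi] + medoids[mi + 1 :]
            d_rest = dist[:, others].min(axis=1) if others else np.full(n, np.inf)
            for h in range(n):
                if h in med_set:
                    continue
                delta = float(np.minimum(d_rest, dist[:, h]).sum()) - cost
                if delta < best[0] - 1e-12:
                    best = (delta, mi, h)
        if best[1] is None:
            break
        medoids[best[1]] = best[2]
        medoids = sorted(medoids)
        new_cost = total_cost(medoids)
        assert new_cost <= cost + 1e-9, "SWAP increased cost"
        cost = new_cost
    return medoids, cost


# ---------------------------------------------------------------------------
# Silhouette widths
# ---------------------------------------------------------------------------

def silhouette_widths(dist: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-sample silhouette width s(i) = (b - a) / max(a, b).

    a(i) = mean distance to the sample's own cluster (excluding itself);
    b(i) = smallest mean distance to any other cluster.  Samples in
    singleton clusters get s(i) = 0 by convention.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    n = len(labels)
    s = np.zeros(n)
    cluster_idx = {c: np.flatnonzero(labels == c) for c in uniq}
    for i in range(n):
        own = cluster_idx[labels[i]]
        if len(own) == 1:
            s[i] = 0.0
            continue
        a = dist[i, own].sum() / (len(own) - 1)
        b = min(dist[i, cluster_idx[c]].mean() for c in uniq if c != labels[i])
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return s


# ---------------------------------------------------------------------------
# Model selection over k
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    """PAM subtyping outcome: chosen k, labels, silhouettes, core samples."""

    k_selected: int
    labels: pd.Series  # sample id -> cluster id (0-based)
    silhouette: pd.Series
    mean_silhouette_by_k: dict[int, float]
    core_mask: pd.Series  # True where s(i) >= 0
    medoid_ids: list[str]

    @property
    def cluster_sizes(self) -> dict[int, int]:
        return self.labels.value_counts().sort_index().to_dict()

    def core_sample_ids(self) -> list[str]:
        return list(self.labels.index[self.core_mask])


def select_k(
    matrix: MetaboliteMatrix,
    k_range: Sequence[int] = range(2, 13),
    seed: int = 0,
    metric: str = "euclidean",
) -> ClusterResult:
    """Run PAM for every k in k_range; keep the k with maximal mean silhouette.

    Ties go to the smallest k (parsimony).  Samples with negative
    silhouette width at the selected k are flagged non-core; downstream
    signature extraction uses core samples only.
    """
    matrix.require_state("log2_centered")
    dist = sample_distances(matrix, metric=metric)
    if np.allclose(dist, 0):
        raise DegenerateDataError("all samples identical: clustering undefined")
    k_range = [int(k) for k in k_range]
    results: dict[int, tuple[np.ndarray, np.ndarray, float]] = {}
    mean_sil: dict[int, float] = {}
    for k in k_range:
        labels, medoids, _ = pam(dist, k, seed=seed)
        results[k] = (labels, medoids, 0.0)
        mean_sil[k] = float(silhouette_widths(dist, labels).mean())
    best_k = max(sorted(mean_sil), key=lambda k: mean_sil[k])
    # max over sorted keys keeps the smallest k on exact ties
    best_k = min(k for k in mean_sil if mean_sil[k] == mean_sil[best_k])
    labels, medoids, _ = results[best_k]
    sil = silhouette_widths(dist, labels)
    ids = matrix.sample_ids
    return ClusterResult(
        k_selected=best_k,
        labels=pd.Series(labels, index=ids, name="cluster"),
        silhouette=pd.Series(sil, index=ids, name="silhouette"),
        mean_silhouette_by_k=mean_sil,
        core_mask=pd.Series(sil >= 0, index=ids, name="core"),
        medoid_ids=[ids[m] for m in medoids],
    )


def subcluster(
    matrix: MetaboliteMatrix,
    result: ClusterResult,
    cluster_id: int,
    k_range: Sequence[int] = range(2, 13),
    seed: int = 0,
    metric: str = "euclidean",
) -> ClusterResult:
    """Re-run silhouette-selected PAM restricted to one cluster's samples.

    Used to split a heterogeneous cluster into subtypes (e.g. the second
    metabolic cluster separating into a choline-driven and a
    tryptophan-driven subgroup).
    """
    members = list(result.labels.index[result.labels == cluster_id])
    if len(members) < 4:
        raise ValueError(f"cluster {cluster_id} too small to subcluster ({len(members)})")
    sub = matrix.with_values(matrix.values.loc[members], matrix.state)
    k_range = [k for k in k_range if k < len(members)]
    return select_k(sub, k_range=k_range, seed=seed, metric=metric)


# ---------------------------------------------------------------------------
# Nearest shrunken centroids (PAMR-style)
# ---------------------------------------------------------------------------

@dataclass
class SignatureModel:
    """Shrunken-centroid discriminator with the CV-chosen threshold."""

    classes: list
    centroids: pd.DataFrame          # class x metabolite shrunken centroids
    d_shrunk: pd.DataFrame           # class x metabolite shrunken differences
    delta: float
    s0: float
    selected: dict[str, list]        # metabolite -> classes with nonzero difference
    cv_error_by_delta: dict[float, float]

    @property
    def signature(self) -> list[str]:
        return sorted(self.selected)


def _nsc_stats(x: np.ndarray, y: np.ndarray, classes: np.ndarray):
    """Class centroids, pooled within-class SD, and t-like scores d_ik."""
    n, p = x.shape
    K = len(classes)
    overall = x.mean(axis=0)
    cent = np.vstack([x[y == c].mean(axis=0) for c in classes])
    nk = np.array([(y == c).sum() for c in classes])
    ss = np.zeros(p)
    for c, ck in zip(classes, cent):
        ss += ((x[y == c] - ck) ** 2).sum(axis=0)
    s = np.sqrt(ss / (n - K))
    s0 = float(np.median(s))
    mk = np.sqrt(1.0 / nk - 1.0 / n)
    d = (cent - overall) / (mk[:, None] * (s + s0)[None, :])
    return overall, cent, s, s0, mk, d


def _nsc_predict(x: np.ndarray, overall, s, s0, mk, d_shrunk, priors) -> np.ndarray:
    """Discriminant-score classification with shrunken centroids."""
    cent_shrunk = overall[None, :] + mk[:, None] * (s + s0)[None, :] * d_shrunk
    scores = np.empty((x.shape[0], d_shrunk.shape[0]))
    for kk in range(d_shrunk.shape[0]):
        scores[:, kk] = (
            ((x - cent_shrunk[kk]) ** 2 / (s + s0) ** 2).sum(axis=1)
            - 2.0 * np.log(priors[kk])
        )
    return np.argmin(scores, axis=1)


def shrunken_centroid_signature(
    matrix: MetaboliteMatrix,
    labels: pd.Series,
    delta_grid: Sequence[float] | None = None,
    cv_folds: int = 10,
    seed: int = 0,
) -> SignatureModel:
    """Nearest-shrunken-centroid subtype signature with cross-validated shrinkage.

    Per-metabolite class-vs-overall differences are standardized by the
    pooled within-class SD (offset by s0 = median pooled SD) and
    soft-thresholded by Delta.  Delta is chosen by k-fold cross-validation
    with the one-standard-error rule: the largest Delta whose CV
    misclassification is within one SE of the minimum, favoring sparser
    signatures.  Metabolites with a nonzero shrunken difference for any
    class form the signature.
    """
    matrix.require_state("log2_centered")
    x = matrix.to_numpy()
    y = np.asarray(labels.loc[matrix.sample_ids])
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    counts = {c: int((y == c).sum()) for c in classes}
    if min(counts.values()) < 2:
        raise ValueError(f"each class needs >= 2 samples, got {counts}")
    overall, cent, s, s0, mk, d = _nsc_stats(x, y, classes)
    if delta_grid is None:
        delta_grid = np.linspace(0.0, float(np.abs(d).max()), 30)
    delta_grid = sorted(float(dd) for dd in delta_grid)

    min_class = min(counts.values())
    folds = cv_folds
    if min_class < cv_folds:
        folds = max(2, min_class)
        warnings.warn(
            f"smallest class has {min_class} samples; reducing CV folds to {folds}",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    # stratified fold assignment
    fold_of = np.empty(len(y), dtype=int)
    for c in classes:
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        fold_of[idx] = np.arange(len(idx)) % folds
    priors = np.array([counts[c] for c in classes], dtype=float) / len(y)

    cv_err: dict[float, float] = {}
    for delta in delta_grid:
        wrong = 0
        for f in range(folds):
            tr, te = fold_of != f, fold_of == f
            ov, _, s_f, s0_f, mk_f, d_f = _nsc_stats(x[tr], y[tr], classes)
            d_shr = np.sign(d_f) * np.maximum(np.abs(d_f) - delta, 0.0)
            pred = _nsc_predict(x[te], ov, s_f, s0_f, mk_f, d_shr, priors)
            wrong += int((classes[pred] != y[te]).sum())
        cv_err[delta] = wrong / len(y)

    errs = np.array([cv_err[dd] for dd in delta_grid])
    best = errs.min()
    se = float(np.sqrt(best * (1 - best) / len(y)))
    chosen = max(dd for dd, e in zip(delta_grid, errs) if e <= best + se)

    d_shrunk = np.sign(d) * np.maximum(np.abs(d) - chosen, 0.0)
    cent_shrunk = overall[None, :] + mk[:, None] * (s + s0)[None, :] * d_shrunk
    names = matrix.metabolite_names
    selected = {
        names[j]: [classes[kk] for kk in range(len(classes)) if d_shrunk[kk, j] != 0]
        for j in range(len(names))
        if np.any(d_shrunk[:, j] != 0)
    }
    return SignatureModel(
        classes=list(classes),
        centroids=pd.DataFrame(cent_shrunk, index=list(classes), columns=names),
        d_shrunk=pd.DataFrame(d_shrunk, index=list(classes), columns=names),
        delta=chosen,
        s0=s0,
        selected=selected,
        cv_error_by_delta=cv_err,
    )


# ---------------------------------------------------------------------------
# GLM signature
# ---------------------------------------------------------------------------

def glm_signature(
    matrix: MetaboliteMatrix,
    labels: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-metabolite linear model of intensity on a class indicator.

    For two classes: estimate = slope of the 0/1 indicator (difference of
    class means on the log2-centered scale), two-sided p from the slope's
    t statistic, Benjamini-Hochberg adjustment across metabolites.  With
    more than two classes each class is tested one-vs-rest and rows are
    stacked.  Zero-variance metabolites get p = 1 and a flag.

    Returns a DataFrame with columns class, metabolite, estimate, p, p_adj,
    significant, zero_variance.
    """
    matrix.require_state("log2_centered")
    y = np.asarray(labels.loc[matrix.sample_ids])
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    contrasts = [classes[1]] if len(classes) == 2 else list(classes)
    x = matrix.to_numpy()
    frames = []
    for c in contrasts:
        ind = (y == c).astype(float)
        est, pvals, zerovar = _indicator_regression(x, ind)
        p_adj = multipletests(pvals, method="fdr_bh")[1]
        frames.append(pd.DataFrame({
            "class": c,
            "metabolite": matrix.metabolite_names,
            "estimate": est,
            "p": pvals,
            "p_adj": p_adj,
            "significant": p_adj <= alpha,
            "zero_variance": zerovar,
        }))
    return pd.concat(frames, ignore_index=True)


def _indicator_regression(x: np.ndarray, ind: np.ndarray):
    """Vectorized OLS of each column of x on a binary indicator."""
    n = len(ind)
    ind_c = ind - ind.mean()
    sxx = float((ind_c**2).sum())
    xc = x - x.mean(axis=0)
    slope = ind_c @ xc / sxx
    resid = xc - np.outer(ind_c, slope)
    sse = (resid**2).sum(axis=0)
    zerovar = xc.std(axis=0) == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sse / (n - 2) / sxx)
        t = np.where(se > 0, slope / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(zerovar, 1.0, p)
    return slope, p, zerovar
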