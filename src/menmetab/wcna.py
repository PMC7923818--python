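"""Weighted correlation network analysis of metabolite co-abundance.

Metabolite profiles are turned into an unsigned weighted network by
raising absolute Pearson correlations to a soft-threshold power beta,
chosen as the smallest power at which the network's connectivity
distribution is approximately scale-free.  Pairwise topological overlap
(shared-neighbor similarity) then drives average-linkage module
detection.  Each module is summarized by its eigengene (first principal
component of the member profiles across samples); module membership
(kME) is the correlation of a metabolite with an eigengene, and
module-trait statistics relate eigengenes to clinical covariates by
correlation and single-predictor logistic models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster, leaves_list
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .containers import ClinicalTable, MetaboliteMatrix

GREY = "grey"  #: label for metabolites not assigned to any module


# ---------------------------------------------------------------------------
# Soft thresholding
# ---------------------------------------------------------------------------

def adjacency_matrix(matrix: MetaboliteMatrix, beta: float,
                     network: str = "signed") -> pd.DataFrame:
    """Soft-thresholded correlation adjacency with zero diagonal.

    ``signed`` (default) uses ((1 + r)/2)^beta, which keeps anti-correlated
    metabolites apart — pathways regulated in opposite directions between
    subtypes would otherwise be fused into one module.  ``unsigned`` uses
    |r|^beta.  Constant metabolites are excluded (their correlation is
    undefined) with a warning.
    """
    if network not in ("signed", "unsigned"):
        raise ValueError(f"unknown network type {network!r}")
    df = matrix.values
    keep = df.std(axis=0, ddof=1) > 0
    if not keep.all():
        dropped = list(df.columns[~keep])
        warnings.warn(f"excluding {len(dropped)} constant metabolites: "
                      f"{dropped[:5]}", stacklevel=2)
        df = df.loc[:, keep]
    corr = np.corrcoef(df.to_numpy(), rowvar=False)
    if network == "signed":
        adj = ((1.0 + corr) / 2.0) ** beta
    else:
        adj = np.abs(corr) ** beta
    np.fill_diagonal(adj, 0.0)
    return pd.DataFrame(adj, index=df.columns, columns=df.columns)


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log10 p(k) vs log10 k fit over connectivity bins.

    Scale-free topology requires p(k) to *decrease* with k, so the R^2 is
    signed by the slope: a good fit with a positive slope (the signature
    of an unstructured dense network) scores negative and is never
    selected.  Bins are equal-count (quantile) with a width correction,
    i.e. the fit is on the estimated log-density; equal-width bins are
    too noisy at a few hundred metabolites.
    """
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    if len(k) < 2 * n_bins:
        return float("nan")
    edges = np.quantile(k, np.linspace(0, 1, n_bins + 1))
    edges[-1] += 1e-12
    log_k, log_p = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        members = k[(k >= lo) & (k < hi)]
        width = hi - lo
        if len(members) == 0 or width <= 0:
            continue
        density = len(members) / (len(k) * width)
        log_k.append(np.log10(members.mean()))
        log_p.append(np.log10(density))
    if len(log_k) < 2:
        return float("nan")
    r = np.corrcoef(log_k, log_p)[0, 1]
    return float(-np.sign(r) * r**2)


def soft_threshold(
    matrix: MetaboliteMatrix,
    beta_grid: Sequence[int] = range(1, 21),
    target_r2: float = 0.8,
    network: str = "signed",
) -> tuple[int, dict[int, float]]:
    """Choose the soft-threshold power by the scale-free topology criterion.

    Returns the smallest beta whose connectivity distribution fits a
    power law with R^2 >= target_r2; if no beta reaches the target, the
    argmax R^2 is returned with a warning.
    """
    if matrix.n_metabolites < 10:
        raise ValueError("need >= 10 metabolites for soft-threshold selection")
    fits: dict[int, float] = {}
    for beta in beta_grid:
        adj = adjacency_matrix(matrix, beta, network=network).to_numpy()
        k = adj.sum(axis=1)
        fits[int(beta)] = scale_free_fit(k)
    for beta in sorted(fits):
        if np.isfinite(fits[beta]) and fits[beta] >= target_r2:
            return beta, fits
    best = max((b for b in fits if np.isfinite(fits[b])), key=lambda b: fits[b])
    warnings.warn(
        f"no beta reached scale-free R^2 >= {target_r2}; using argmax beta={best} "
        f"(R^2={fits[best]:.3f})", stacklevel=2,
    )
    return best, fits


# ---------------------------------------------------------------------------
# Topological overlap
# ---------------------------------------------------------------------------

def topological_overlap(adjacency: np.ndarray | pd.DataFrame) -> pd.DataFrame | np.ndarray:
    """Topological overlap matrix.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) for
    i != j and TOM_ii = 1, where k_i is node connectivity.  High overlap
    means two metabolites share their network neighborhoods, not merely
    correlate with each other.
    """
    is_df = isinstance(adjacency, pd.DataFrame)
    a = adjacency.to_numpy() if is_df else np.asarray(adjacency, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if (a < 0).any() or (a > 1).any():
        raise ValueError("adjacency entries must lie in [0, 1]")
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    if is_df:
        return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)
    return tom


# ---------------------------------------------------------------------------
# Module detection
# ---------------------------------------------------------------------------

def detect_modules(
    tom: pd.DataFrame,
    cut_height: float = 0.95,
    min_size: int = 5,
    merge_cor: float = 0.9,
    matrix: MetaboliteMatrix | None = None,
    kme_rescue: float | None = 0.55,
) -> pd.Series:
    """Average-linkage modules from TOM dissimilarity with a static cut.

    Clusters of 1 - TOM below ``cut_height`` with at least ``min_size``
    members become modules (labelled M1, M2, ... by decreasing size);
    everything else is grey.  If the intensity matrix is supplied, two
    refinements run: a membership (kME) reassignment stage that moves each
    metabolite to the module with its highest eigengene correlation when
    that correlation reaches ``kme_rescue`` (recovering members the static
    cut stranded in grey), and an eigengene merge of module pairs
    correlating above ``merge_cor``, iterated until stable.
    """
    names = list(tom.index)
    dissim = 1.0 - tom.to_numpy()
    np.fill_diagonal(dissim, 0.0)
    dissim = np.clip((dissim + dissim.T) / 2.0, 0.0, None)
    link = average(squareform(dissim, checks=False))
    flat = fcluster(link, t=cut_height, criterion="distance")
    module_of = _label_modules(flat, names, min_size)
    if matrix is not None:
        if kme_rescue is not None:
            module_of = _kme_reassign(module_of, matrix, kme_rescue,
                                      min_size=min_size)
        module_of = _merge_correlated(module_of, matrix, merge_cor)
    if (module_of == GREY).all():
        warnings.warn("no module passed the size filter; all metabolites grey",
                      stacklevel=2)
    return module_of


def _kme_reassign(module_of: pd.Series, matrix: MetaboliteMatrix,
                  threshold: float, min_size: int, max_iter: int = 3) -> pd.Series:
    """Membership-based reassignment: each metabolite joins its best-kME module.

    Metabolites whose maximal kME falls below ``threshold`` go grey;
    modules shrinking under ``min_size`` dissolve.  Iterated a few times
    with recomputed eigengenes, which converges quickly in practice.
    """
    module_of = module_of.copy()
    for _ in range(max_iter):
        mods = [m for m in module_of.unique() if m != GREY]
        if not mods:
            return module_of
        eig = module_eigengene(matrix, module_of)
        kme = compute_kme(matrix, eig)
        best_mod = kme.idxmax(axis=1)
        best_val = kme.max(axis=1)
        new = pd.Series(np.where(best_val >= threshold, best_mod, GREY),
                        index=module_of.index, name="module")
        sizes = new.value_counts()
        for m in [m for m in sizes.index if m != GREY and sizes[m] < min_size]:
            new[new == m] = GREY
        if new.equals(module_of):
            break
        module_of = new
    return module_of


def _label_modules(flat: np.ndarray, names: list[str], min_size: int) -> pd.Series:
    sizes = pd.Series(flat).value_counts()
    keep = [c for c in sizes.index if sizes[c] >= min_size]
    # deterministic labels: decreasing size, ties by first-member position
    keep.sort(key=lambda c: (-sizes[c], int(np.flatnonzero(flat == c)[0])))
    relabel = {c: f"M{i + 1}" for i, c in enumerate(keep)}
    return pd.Series([relabel.get(c, GREY) for c in flat], index=names, name="module")


def _merge_correlated(module_of: pd.Series, matrix: MetaboliteMatrix,
                      merge_cor: float) -> pd.Series:
    module_of = module_of.copy()
    while True:
        mods = [m for m in module_of.unique() if m != GREY]
        if len(mods) < 2:
            return module_of
        eig = module_eigengene(matrix, module_of)
        corr = eig.corr()
        best, best_r = None, merge_cor
        for i, m1 in enumerate(mods):
            for m2 in mods[i + 1:]:
                r = corr.loc[m1, m2]
                if r > best_r:
                    best, best_r = (m1, m2), r
        if best is None:
            return module_of
        module_of[module_of == best[1]] = best[0]


# ---------------------------------------------------------------------------
# Eigengenes and module membership
# ---------------------------------------------------------------------------

def module_eigengene(matrix: MetaboliteMatrix, module_of: pd.Series) -> pd.DataFrame:
    """First-principal-component eigengene per module, unit variance.

    Member profiles are standardized across samples, the leading left
    singular vector over samples is scaled to unit variance, and its sign
    is oriented so the mean correlation with member profiles is positive.
    A singleton module's eigengene is that metabolite's standardized
    profile (flagged with a warning).
    """
    df = matrix.values
    eigs = {}
    for mod in [m for m in pd.unique(module_of) if m != GREY]:
        members = list(module_of.index[module_of == mod])
        sub = df[members].to_numpy()
        z = (sub - sub.mean(axis=0)) / sub.std(axis=0, ddof=1)
        if len(members) == 1:
            warnings.warn(f"module {mod} has a single member; eigengene is its "
                          "standardized profile", stacklevel=2)
            e = z[:, 0]
        else:
            u, sv, _ = np.linalg.svd(z, full_matrices=False)
            e = u[:, 0]
        e = e / e.std(ddof=1)
        mean_cor = np.mean([np.corrcoef(e, z[:, j])[0, 1] for j in range(z.shape[1])])
        if mean_cor < 0:
            e = -e
        eigs[mod] = e
    return pd.DataFrame(eigs, index=df.index)


def compute_kme(matrix: MetaboliteMatrix, eigengene_E: pd.DataFrame) -> pd.DataFrame:
    """Module membership: Pearson correlation of each metabolite with each eigengene.

    Zero-variance metabolite profiles get kME = 0 (flagged).
    """
    x = matrix.to_numpy()
    sd = x.std(axis=0, ddof=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} zero-variance metabolites get kME = 0",
                      stacklevel=2)
    xc = x - x.mean(axis=0)
    x_norm = np.sqrt((xc**2).sum(axis=0))
    out = {}
    for mod in eigengene_E.columns:
        e = eigengene_E[mod].to_numpy()
        ec = e - e.mean()
        e_norm = np.sqrt((ec**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            kme = xc.T @ ec / (x_norm * e_norm)
        out[mod] = np.clip(np.where(flat, 0.0, kme), -1.0, 1.0)
    return pd.DataFrame(out, index=matrix.metabolite_names)


# ---------------------------------------------------------------------------
# Module-trait statistics
# ---------------------------------------------------------------------------

def encode_traits(clinical: ClinicalTable) -> pd.DataFrame:
    """Numeric trait design: binary indicators + continuous covariates.

    WHO grade, edema, sex and location become 0/1 indicators; age, tumor
    size, MIB-1, Simpson grade and KPS stay numeric.
    """
    d = clinical.data
    out = pd.DataFrame(index=d.index)
    if "who_grade" in d:
        for g in ("I", "II", "III"):
            out[f"grade_{g}"] = (d["who_grade"] == g).astype(float)
    if "edema" in d:
        out["edema_high"] = (d["edema"] == "high").astype(float)
    if "sex" in d:
        out["sex_male"] = (d["sex"] == "male").astype(float)
    if "location" in d:
        for loc in sorted(d["location"].dropna().unique()):
            out[f"location_{loc.replace(' ', '_')}"] = (d["location"] == loc).astype(float)
    for cont in ("age", "size_cm3", "mib1", "simpson", "kps_pre", "kps_post"):
        if cont in d:
            out[cont] = d[cont].astype(float)
    return out


def module_trait_stats(
    eigengene_E: pd.DataFrame,
    clinical: ClinicalTable,
) -> pd.DataFrame:
    """Correlate each module eigengene with each clinical trait.

    R is the Pearson correlation (point-biserial for 0/1 traits), p comes
    from the t transform of R at n - 2 degrees of freedom, and BH
    adjustment runs across the whole module x trait grid.  For binary
    traits a single-predictor logistic regression of the trait on the
    eigengene (Newton-Raphson fit, Wald p) is reported alongside.
    """
    traits = encode_traits(clinical).loc[eigengene_E.index]
    rows = []
    n = len(eigengene_E)
    for trait in traits.columns:
        tvals = traits[trait].to_numpy()
        if np.std(tvals) == 0:
            warnings.warn(f"constant trait {trait!r} skipped", stacklevel=2)
            continue
        binary = set(np.unique(tvals)) <= {0.0, 1.0}
        for mod in eigengene_E.columns:
            e = eigengene_E[mod].to_numpy()
            r = float(np.corrcoef(e, tvals)[0, 1])
            tstat = r * np.sqrt((n - 2) / max(1e-300, 1 - r**2))
            p = float(2 * stats.t.sf(abs(tstat), df=n - 2))
            lb, lp = (_logistic_wald(tvals, e) if binary else (np.nan, np.nan))
            rows.append({"module": mod, "trait": trait, "R": r, "p": p,
                         "logistic_beta": lb, "logistic_p": lp})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
        out = out[["module", "trait", "R", "p", "p_adj", "logistic_beta", "logistic_p"]]
    return out


def _logistic_wald(y: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    """Slope and Wald p of logit(P(y=1)) = b0 + b1 x, Newton-Raphson fit."""
    import statsmodels.api as sm

    X = sm.add_constant(x)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(method="newton", disp=0, maxiter=50)
        return float(fit.params[1]), float(fit.pvalues[1])
    except Exception:
        return float("nan"), float("nan")


# ---------------------------------------------------------------------------
# Hubs, joint clustering, export
# ---------------------------------------------------------------------------

def hub_metabolites(
    kme: pd.DataFrame,
    module_of: pd.Series,
    top_n: int = 3,
) -> dict[str, list[str]]:
    """Top-n members of each module ranked by kME to their own module.

    Ties are broken by metabolite name order; if top_n exceeds the module
    size the whole module is returned in kME order.
    """
    hubs: dict[str, list[str]] = {}
    for mod in kme.columns:
        members = [m for m in module_of.index if module_of[m] == mod]
        ranked = sorted(members, key=lambda m: (-kme.loc[m, mod], m))
        hubs[mod] = ranked[:top_n]
    return hubs


def cluster_of_clusters(
    matrix: MetaboliteMatrix,
    eigengene_E: pd.DataFrame,
    height: float = 0.5,
) -> tuple[list[str], pd.Series]:
    """Joint hierarchical clustering of module eigengenes and metabolites.

    Eigengenes and standardized metabolite profiles are placed in one
    object set (columns over samples) and clustered with average linkage
    on correlation distance 1 - r; the distance between a metabolite and
    a module object is therefore exactly 1 - kME.  Returns the dendrogram
    leaf order and flat groups at the requested height.
    """
    x = matrix.values
    z = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1).replace(0, 1)
    joint = pd.concat([eigengene_E.add_prefix("ME:"), z], axis=1)
    corr = np.corrcoef(joint.to_numpy(), rowvar=False)
    dissim = np.clip(1.0 - corr, 0.0, None)
    np.fill_diagonal(dissim, 0.0)
    link = average(squareform((dissim + dissim.T) / 2, checks=False))
    order = [joint.columns[i] for i in leaves_list(link)]
    flat = fcluster(link, t=height, criterion="distance")
    groups = pd.Series(flat, index=joint.columns, name="group")
    return order, groups


def export_network(
    weights: pd.DataFrame,
    module_of: pd.Series,
    threshold: float,
    graphml_path: str | Path | None = None,
    edgelist_path: str | Path | None = None,
    kme: pd.DataFrame | None = None,
):
    """Write intramodular edges with weight >= threshold.

    Produces a networkx graph (returned) and optionally GraphML and an
    edge-list CSV (source, target, weight, module).  Node attributes are
    module and, when available, kME to the node's own module.
    """
    import networkx as nx

    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    g = nx.Graph()
    names = list(weights.index)
    for nm in names:
        mod = module_of.get(nm, GREY)
        attrs = {"module": str(mod)}
        if kme is not None and mod in getattr(kme, "columns", []):
            attrs["kME"] = float(kme.loc[nm, mod])
        g.add_node(nm, **attrs)
    w = weights.to_numpy()
    for i, ni in enumerate(names):
        for j in range(i + 1, len(names)):
            nj = names[j]
            if module_of.get(ni, GREY) == module_of.get(nj, GREY) != GREY:
                if w[i, j] >= threshold:
                    g.add_edge(ni, nj, weight=float(w[i, j]),
                               module=str(module_of[ni]))
    if graphml_path is not None:
        nx.write_graphml(g, str(graphml_path))
    if edgelist_path is not None:
        rows = [{"source": u, "target": v, "weight": d["weight"],
                 "module": d["module"]} for u, v, d in g.edges(data=True)]
        pd.DataFrame(rows, columns=["source", "target", "weight", "module"]).to_csv(
            edgelist_path, index=False)
    return g


@dataclass
class WcnaResult:
    """Bundle of the full network-analysis outputs."""

    beta: int
    scale_free_fit_by_beta: dict[int, float]
    module_of: pd.Series
    eigengene_E: pd.DataFrame
    kme: pd.DataFrame
    trait_stats: pd.DataFrame | None
    hubs: dict[str, list[str]]


def run_wcna(
    matrix: MetaboliteMatrix,
    clinical: ClinicalTable | None = None,
    beta_grid: Sequence[int] = range(1, 21),
    target_r2: float = 0.8,
    cut_height: float = 0.95,
    min_size: int = 5,
    merge_cor: float = 0.9,
    hub_top_n: int = 3,
    network: str = "signed",
) -> WcnaResult:
    """Soft threshold -> TOM -> modules -> eigengenes -> kME -> trait statistics."""
    beta, fits = soft_threshold(matrix, beta_grid=beta_grid, target_r2=target_r2,
                                network=network)
    adj = adjacency_matrix(matrix, beta, network=network)
    tom = topological_overlap(adj)
    module_of = detect_modules(tom, cut_height=cut_height, min_size=min_size,
                               merge_cor=merge_cor, matrix=matrix)
    mods = [m for m in module_of.unique() if m != GREY]
    if not mods:
        return WcnaResult(beta, fits, module_of, pd.DataFrame(index=matrix.sample_ids),
                          pd.DataFrame(index=matrix.metabolite_names), None, {})
    eig = module_eigengene(matrix, module_of)
    kme = compute_kme(matrix, eig)
    traits = None
    if clinical is not None:
        traits = module_trait_stats(eig, clinical.aligned_to(matrix.sample_ids))
    hubs = hub_metabolites(kme, module_of, top_n=hub_top_n)
    return WcnaResult(beta, fits, module_of, eig, kme, traits, hubs)
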