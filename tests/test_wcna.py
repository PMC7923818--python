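"""Weighted correlation network analysis: TOM, modules, eigengenes, traits."""

import numpy as np
import pandas as pd
import pytest

import menmetab as mm
from menmetab.containers import ClinicalTable, MetaboliteMatrix
from menmetab.wcna import GREY, detect_modules, scale_free_fit, topological_overlap

from conftest import random_matrix


# ---------------------------------------------------------------------------
# Adjacency & soft threshold
# ---------------------------------------------------------------------------

def test_adjacency_beta_one_unsigned_equals_abs_correlation():
    m = random_matrix(12, 3, 0)
    adj = mm.adjacency_matrix(m, beta=1, network="unsigned")
    r = np.corrcoef(m.to_numpy(), rowvar=False)
    expected = np.abs(r)
    np.fill_diagonal(expected, 0.0)
    np.testing.assert_allclose(adj.to_numpy(), expected, atol=1e-12)


def test_adjacency_bounds_and_constant_exclusion():
    m = random_matrix(10, 6, 1)
    vals = m.values.copy()
    vals["m0"] = 1.0
    m = MetaboliteMatrix(vals, state="log2_centered")
    with pytest.warns(UserWarning, match="constant"):
        adj = mm.adjacency_matrix(m, beta=6)
    assert "m0" not in adj.columns
    a = adj.to_numpy()
    assert (a >= 0).all() and (a <= 1).all()


def test_soft_threshold_reproducible_and_in_grid(centered_cohort):
    centered, _, _ = centered_cohort
    b1, f1 = mm.soft_threshold(centered)
    b2, f2 = mm.soft_threshold(centered)
    assert b1 == b2 and f1 == f2
    assert b1 in range(1, 21)
    # power must amplify module contrast beyond the identity power
    assert b1 >= 2


def test_scale_free_fit_penalizes_increasing_degree_distribution():
    rng = np.random.default_rng(0)
    decreasing = rng.exponential(1.0, size=500)  # many low-k, few hubs
    assert scale_free_fit(decreasing) > 0
    increasing = 10.0 - rng.exponential(1.0, size=500).clip(max=9.9)
    assert scale_free_fit(increasing) < 0


# ---------------------------------------------------------------------------
# TOM
# ---------------------------------------------------------------------------

def test_tom_hand_computed_triangle():
    a = np.full((3, 3), 0.5)
    np.fill_diagonal(a, 0.0)
    tom = topological_overlap(a)
    # (sum_u a_iu a_uj + a_ij) / (min(k) + 1 - a_ij) = (0.25+0.5)/(1+1-0.5)
    assert tom[0, 1] == pytest.approx(0.5, abs=1e-12)
    assert np.allclose(np.diag(tom), 1.0)


def test_tom_of_empty_adjacency_is_identity():
    tom = topological_overlap(np.zeros((5, 5)))
    np.testing.assert_allclose(tom, np.eye(5), atol=1e-12)


def test_tom_matches_triple_loop_oracle():
    rng = np.random.default_rng(2)
    for _ in range(5):
        a = rng.uniform(0, 1, size=(8, 8))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        tom = topological_overlap(a)
        k = a.sum(axis=1)
        for i in range(8):
            for j in range(8):
                if i == j:
                    assert tom[i, j] == 1.0
                    continue
                shared = sum(a[i, u] * a[u, j] for u in range(8))
                expect = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
                assert tom[i, j] == pytest.approx(expect, abs=1e-12)


def test_tom_rejects_asymmetric_or_out_of_range():
    bad = np.zeros((3, 3))
    bad[0, 1] = 0.5
    with pytest.raises(ValueError, match="symmetric"):
        topological_overlap(bad)
    toobig = np.full((3, 3), 1.5)
    np.fill_diagonal(toobig, 0.0)
    with pytest.raises(ValueError, match="0, 1"):
        topological_overlap(toobig)


# ---------------------------------------------------------------------------
# Module detection
# ---------------------------------------------------------------------------

def block_tom(sizes, within=0.9, names=None):
    n = sum(sizes)
    tom = np.zeros((n, n))
    start = 0
    for s in sizes:
        tom[start:start + s, start:start + s] = within
        start += s
    np.fill_diagonal(tom, 1.0)
    names = names or [f"m{j}" for j in range(n)]
    return pd.DataFrame(tom, index=names, columns=names)


def test_block_diagonal_tom_gives_exact_modules():
    tom = block_tom([6, 6])
    mo = detect_modules(tom, cut_height=0.5, min_size=5, matrix=None)
    assert (mo != GREY).all()
    assert mo.nunique() == 2
    assert mo.iloc[:6].nunique() == 1 and mo.iloc[6:].nunique() == 1


def test_min_size_larger_than_network_gives_all_grey():
    tom = block_tom([4, 4])
    with pytest.warns(UserWarning, match="grey"):
        mo = detect_modules(tom, cut_height=0.5, min_size=20, matrix=None)
    assert (mo == GREY).all()


def test_detected_labels_are_deterministic():
    tom = block_tom([7, 5])
    a = detect_modules(tom, cut_height=0.5, min_size=5, matrix=None)
    b = detect_modules(tom, cut_height=0.5, min_size=5, matrix=None)
    assert a.equals(b)
    assert a.value_counts()["M1"] == 7  # labels ordered by decreasing size


# ---------------------------------------------------------------------------
# Eigengenes and kME
# ---------------------------------------------------------------------------

def module_series(names, label="M1"):
    return pd.Series(label, index=names, name="module")


def test_eigengene_of_identical_profiles_is_standardized_profile():
    rng = np.random.default_rng(4)
    profile = rng.normal(size=10)
    df = pd.DataFrame({f"m{j}": profile for j in range(4)},
                      index=[f"s{i}" for i in range(10)])
    m = MetaboliteMatrix(df, state="log2_centered")
    eig = mm.module_eigengene(m, module_series(df.columns))
    z = (profile - profile.mean()) / profile.std(ddof=1)
    np.testing.assert_allclose(eig["M1"], z, atol=1e-10)


def test_eigengene_two_member_closed_form():
    # two standardized members: first PC direction is (1,1)/sqrt(2) when r>0,
    # so E is proportional to the standardized mean profile
    df = pd.DataFrame({"a": [1.0, 2.0, 6.0], "b": [0.0, 3.0, 4.0]},
                      index=["s0", "s1", "s2"])
    m = MetaboliteMatrix(df, state="log2_centered")
    eig = mm.module_eigengene(m, module_series(df.columns))["M1"].to_numpy()
    za = (df["a"] - df["a"].mean()) / df["a"].std(ddof=1)
    zb = (df["b"] - df["b"].mean()) / df["b"].std(ddof=1)
    mean_prof = (za + zb).to_numpy()
    expected = mean_prof / np.std(mean_prof, ddof=1)
    np.testing.assert_allclose(eig, expected, atol=1e-10)


def test_eigengene_orientation_invariant_to_global_sign_flip():
    m = random_matrix(12, 5, 6)
    mo = module_series(m.metabolite_names)
    e1 = mm.module_eigengene(m, mo)["M1"]
    flipped = MetaboliteMatrix(-m.values, state="log2_centered")
    e2 = mm.module_eigengene(flipped, mo)["M1"]
    # orientation rule: positive mean correlation with members in both cases
    assert np.corrcoef(e1, e2)[0, 1] == pytest.approx(-1.0, abs=1e-10)


def test_eigengene_explains_at_least_any_single_member():
    m = random_matrix(15, 6, 7)
    mo = module_series(m.metabolite_names)
    eig = mm.module_eigengene(m, mo)["M1"].to_numpy()
    z = (m.values - m.values.mean()) / m.values.std(ddof=1)
    zv = z.to_numpy()
    def explained(direction):
        d = direction / np.linalg.norm(direction)
        return float(((zv.T @ d) ** 2).sum())
    e_var = explained(eig)
    for j in range(6):
        assert e_var + 1e-9 >= explained(zv[:, j])


def test_single_member_module_flagged():
    m = random_matrix(8, 1, 0)
    with pytest.warns(UserWarning, match="single member"):
        eig = mm.module_eigengene(m, module_series(m.metabolite_names))
    assert eig.shape == (8, 1)


def test_kme_bounds_rank_one_and_zero_variance():
    rng = np.random.default_rng(9)
    profile = rng.normal(size=12)
    df = pd.DataFrame({"a": profile, "b": 2 * profile, "flat": np.zeros(12)},
                      index=[f"s{i}" for i in range(12)])
    m = MetaboliteMatrix(df, state="log2_centered")
    eig = mm.module_eigengene(m, pd.Series(["M1", "M1", GREY], index=df.columns))
    with pytest.warns(UserWarning, match="zero-variance"):
        kme = mm.compute_kme(m, eig)
    assert abs(kme.loc["a", "M1"]) == pytest.approx(1.0, abs=1e-10)
    assert kme.loc["flat", "M1"] == 0.0
    assert ((kme >= -1) & (kme <= 1)).all().all()


def test_kme_of_independent_metabolite_stays_small(centered_cohort):
    """Metabolites with no planted loading rarely reach |kME| 0.5."""
    centered, _, truth = centered_cohort
    eig = mm.module_eigengene(centered, truth.module_assignment.rename(
        lambda _: _, axis=0).replace("none", GREY))
    free = truth.module_assignment.index[truth.module_assignment == "none"]
    kme = mm.compute_kme(centered, eig)
    frac = (kme.loc[free].abs() < 0.5).to_numpy().mean()
    assert frac >= 0.95


# ---------------------------------------------------------------------------
# Module-trait statistics
# ---------------------------------------------------------------------------

def test_trait_identical_to_eigengene_gives_r_one(centered_cohort):
    centered, clinical, truth = centered_cohort
    eig = mm.module_eigengene(
        centered, truth.module_assignment.replace("none", GREY))
    clin = ClinicalTable(pd.DataFrame(
        {"age": eig["mod1"].to_numpy()}, index=eig.index))
    stats = mm.module_trait_stats(eig, clin)
    row = stats[(stats.module == "mod1") & (stats.trait == "age")].iloc[0]
    assert row.R == pytest.approx(1.0, abs=1e-10)
    assert row.p < 1e-30


def test_constant_trait_skipped_with_warning(centered_cohort):
    centered, _, truth = centered_cohort
    eig = mm.module_eigengene(
        centered, truth.module_assignment.replace("none", GREY))
    clin = ClinicalTable(pd.DataFrame({"age": np.full(len(eig), 50.0)},
                                      index=eig.index))
    with pytest.warns(UserWarning, match="constant trait"):
        stats = mm.module_trait_stats(eig, clin)
    assert len(stats) == 0


def test_permuted_traits_are_calibrated(centered_cohort):
    """BH-significant fraction under label permutation stays near alpha."""
    centered, clinical, truth = centered_cohort
    eig = mm.module_eigengene(
        centered, truth.module_assignment.replace("none", GREY))
    rng = np.random.default_rng(0)
    hits = trials = 0
    for _ in range(200):
        perm = clinical.data.sample(frac=1.0, random_state=rng.integers(2**31))
        perm.index = clinical.data.index
        stats = mm.module_trait_stats(eig, ClinicalTable(perm[["age"]]))
        hits += int((stats["p"] <= 0.05).sum())
        trials += len(stats)
    rate = hits / trials
    se = np.sqrt(0.05 * 0.95 / trials)
    assert rate <= 0.05 + 3 * se


def test_edema_negatively_tracks_subtype_one_module(centered_cohort):
    """The glycine/serine module eigengene anti-correlates with edema."""
    centered, clinical, truth = centered_cohort
    eig = mm.module_eigengene(
        centered, truth.module_assignment.replace("none", GREY))
    stats = mm.module_trait_stats(eig, clinical)
    row = stats[(stats.module == "mod1") & (stats.trait == "edema_high")].iloc[0]
    assert row.R < 0
    assert np.isfinite(row.logistic_beta)


# ---------------------------------------------------------------------------
# Hubs, joint clustering, export
# ---------------------------------------------------------------------------

def test_hub_ranking_and_boundaries():
    rng = np.random.default_rng(11)
    profile = rng.normal(size=20)
    df = pd.DataFrame({
        "strong": profile + rng.normal(0, 0.1, 20),
        "weak": profile + rng.normal(0, 2.0, 20),
        "mid": profile + rng.normal(0, 0.5, 20),
    }, index=[f"s{i}" for i in range(20)])
    m = MetaboliteMatrix(df, state="log2_centered")
    mo = module_series(df.columns)
    eig = mm.module_eigengene(m, mo)
    kme = mm.compute_kme(m, eig)
    hubs = mm.hub_metabolites(kme, mo, top_n=2)
    assert hubs["M1"][0] == "strong"
    full = mm.hub_metabolites(kme, mo, top_n=10)
    assert set(full["M1"]) == {"strong", "weak", "mid"}


def test_cluster_of_clusters_groups_eigengene_with_members():
    rng = np.random.default_rng(12)
    f1, f2 = rng.normal(size=(2, 30))
    df = pd.DataFrame({
        "a1": f1, "a2": f1 * 1.5, "b1": f2, "b2": -f2,
    }, index=[f"s{i}" for i in range(30)])
    m = MetaboliteMatrix(df, state="log2_centered")
    mo = pd.Series(["M1", "M1", "M2", "M2"], index=df.columns)
    eig = mm.module_eigengene(m, mo)
    order, groups = mm.cluster_of_clusters(m, eig, height=0.5)
    assert set(order) == set(groups.index)
    assert groups["ME:M1"] == groups["a1"] == groups["a2"]
    assert groups["ME:M1"] != groups["b1"]
    # determinism
    order2, groups2 = mm.cluster_of_clusters(m, eig, height=0.5)
    assert order == order2 and groups.equals(groups2)


def test_export_network_edge_counts_and_round_trip(tmp_path):
    import networkx as nx
    rng = np.random.default_rng(13)
    names = [f"m{j}" for j in range(9)]
    w = rng.uniform(0.1, 0.9, size=(9, 9))
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0.0)
    weights = pd.DataFrame(w, index=names, columns=names)
    mo = pd.Series(["M1"] * 4 + ["M2"] * 3 + [GREY] * 2, index=names)
    with pytest.raises(ValueError):
        mm.export_network(weights, mo, threshold=1.5)
    g0 = mm.export_network(weights, mo, threshold=0.0)
    assert g0.number_of_edges() == 6 + 3  # C(4,2) + C(3,2)
    gml = tmp_path / "net.graphml"
    g = mm.export_network(weights, mo, threshold=0.3, graphml_path=gml,
                          edgelist_path=tmp_path / "edges.csv")
    back = nx.read_graphml(gml)
    got = {frozenset((u, v)): round(d["weight"], 12)
           for u, v, d in back.edges(data=True)}
    want = {frozenset((u, v)): round(d["weight"], 12)
            for u, v, d in g.edges(data=True)}
    assert got == want


def test_run_wcna_end_to_end_recovers_planted_modules(centered_cohort):
    centered, clinical, truth = centered_cohort
    res = mm.run_wcna(centered, clinical)
    assert res.beta >= 2
    found = [m for m in res.module_of.unique() if m != GREY]
    assert len(found) >= 4
    from conftest import best_match_jaccard
    recovered = sum(
        best_match_jaccard(
            res.module_of,
            set(truth.module_assignment.index[truth.module_assignment == pm]),
        ) >= 0.8
        for pm in [f"mod{i}" for i in range(1, 6)]
    )
    assert recovered >= 4
    assert res.trait_stats is not None and {"R", "p", "p_adj"} <= set(
        res.trait_stats.columns)
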