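"""Cohort statistics: exact 2x2 tests, rank/means tests, survival curves."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.integrate import quad

import menmetab as mm
from menmetab.clinstats import km_survival_at


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("table,expected", [
    ((2, 8, 13, 20), 0.45),   # sex by cluster
    ((2, 10, 13, 18), 0.16),  # convexity
    ((1, 1, 14, 27), 1.00),   # petroclival
    ((0, 3, 15, 25), 0.54),   # Simpson grade 3
    ((1, 4, 14, 24), 0.64),   # location "others"
])
def test_fisher_reproduces_clinical_baseline_table(table, expected):
    res = mm.fisher_exact_2x2(*table)
    assert round(res.p, 2) == expected


def test_fisher_matches_enumeration_oracle_all_small_margins():
    """Every 2x2 with N <= 20: p equals explicit support enumeration."""
    def oracle(a, b, c, d):
        n, r1, c1 = a + b + c + d, a + b, a + c
        lo, hi = max(0, r1 + c1 - n), min(r1, c1)
        def pt(x):
            return (math.comb(r1, x) * math.comb(n - r1, c1 - x)
                    / math.comb(n, c1))
        obs = pt(a)
        return sum(pt(x) for x in range(lo, hi + 1)
                   if pt(x) <= obs * (1 + 1e-7))
    rng = np.random.default_rng(0)
    checked = 0
    for n in range(4, 21):
        for _ in range(6):
            cells = rng.multinomial(n, [0.25] * 4)
            a, b, c, d = (int(x) for x in cells)
            if (a + b) in (0, n) or (a + c) in (0, n):
                continue
            res = mm.fisher_exact_2x2(a, b, c, d)
            assert res.p == pytest.approx(oracle(a, b, c, d), abs=1e-12)
            checked += 1
    assert checked > 50


def test_fisher_agrees_with_scipy():
    rng = np.random.default_rng(1)
    for _ in range(30):
        a, b, c, d = rng.integers(0, 15, size=4)
        if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
            continue
        ours = mm.fisher_exact_2x2(int(a), int(b), int(c), int(d)).p
        ref = stats.fisher_exact([[a, b], [c, d]])[1]
        assert ours == pytest.approx(ref, rel=1e-9)


def test_fisher_degenerate_margin_flagged():
    res = mm.fisher_exact_2x2(0, 0, 5, 7)
    assert res.p == 1.0 and res.degenerate


def test_fisher_rejects_non_integer_counts():
    with pytest.raises(ValueError):
        mm.fisher_exact_2x2(1.5, 2, 3, 4)
    with pytest.raises(ValueError):
        mm.fisher_exact_2x2(-1, 2, 3, 4)


# ---------------------------------------------------------------------------
# Chi-squared
# ---------------------------------------------------------------------------

def test_chi_squared_reproduces_edema_comparison():
    res = mm.chi_squared_2x2(4, 18, 11, 10)
    assert round(res.p, 2) == 0.02
    with_corr = mm.chi_squared_2x2(4, 18, 11, 10, continuity=True)
    assert with_corr.p > res.p


def test_chi_squared_independence_gives_p_one():
    res = mm.chi_squared_2x2(4, 8, 2, 4)  # ad = bc
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p == 1.0


def test_chi_squared_tail_matches_quadrature_oracle():
    """Upper-tail p equals numeric integration of the df-1 density."""
    def density(x):
        return x ** (-0.5) * np.exp(-x / 2) / (np.sqrt(2) * math.gamma(0.5))
    for chi2 in (0.5, 1.0, 3.84, 7.0):
        p_ref = quad(density, chi2, np.inf)[0]
        assert stats.chi2.sf(chi2, df=1) == pytest.approx(p_ref, abs=1e-10)
    res = mm.chi_squared_2x2(4, 18, 11, 10)
    p_ref = quad(density, res.statistic, np.inf)[0]
    assert res.p == pytest.approx(p_ref, abs=1e-10)


def test_chi_squared_zero_margin_raises():
    with pytest.raises(ValueError, match="margin"):
        mm.chi_squared_2x2(0, 0, 3, 4)


# ---------------------------------------------------------------------------
# Welch t / Wilcoxon
# ---------------------------------------------------------------------------

def test_welch_reproduces_age_comparison_from_summaries():
    t, df, p = mm.welch_t_from_summary(15, 62.3, 13.1, 28, 64.4, 12.8)
    assert round(p, 2) == 0.62


def test_welch_equal_summaries_give_p_one():
    t, df, p = mm.welch_t_from_summary(10, 5.0, 1.0, 12, 5.0, 1.0)
    assert t == 0.0 and p == 1.0


def test_welch_matches_raw_data_construction():
    """Summaries of constructed raw samples give the same test as scipy on raw."""
    rng = np.random.default_rng(2)
    x = rng.normal(3, 1.5, size=14)
    y = rng.normal(3.8, 2.0, size=19)
    t_ref, p_ref = stats.ttest_ind(x, y, equal_var=False)
    t, df, p = mm.welch_t_from_summary(len(x), x.mean(), x.std(ddof=1),
                                       len(y), y.mean(), y.std(ddof=1))
    assert t == pytest.approx(t_ref, rel=1e-12)
    assert p == pytest.approx(p_ref, rel=1e-12)


def test_wilcoxon_exact_separated_samples():
    u, p = mm.wilcoxon_rank_sum([1, 2, 3], [10, 11, 12])
    assert p == pytest.approx(2 / math.comb(6, 3))


def test_wilcoxon_identical_samples():
    _, p = mm.wilcoxon_rank_sum([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])
    assert p == 1.0


def test_wilcoxon_branches_agree_at_boundary_sizes():
    rng = np.random.default_rng(3)
    diffs = []
    for _ in range(100):
        x = rng.normal(0, 1, size=6)
        y = rng.normal(0.5, 1, size=6)
        _, p_exact = mm.wilcoxon_rank_sum(x, y)           # 12 samples: exact
        _, p_ref = stats.mannwhitneyu(x, y, alternative="two-sided",
                                      method="asymptotic", use_continuity=True)
        diffs.append(abs(p_exact - p_ref))
    assert np.median(diffs) < 0.02 and max(diffs) < 0.08


def test_wilcoxon_empty_group_raises():
    with pytest.raises(ValueError):
        mm.wilcoxon_rank_sum([], [1.0])


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank
# ---------------------------------------------------------------------------

def test_km_without_censoring_is_empirical_survivor():
    times = [3.0, 1.0, 4.0, 1.0, 5.0]
    curve = mm.kaplan_meier(times, [1] * 5)
    for t in (0.5, 1.0, 3.5, 5.0):
        emp = np.mean([ti > t for ti in times])
        assert km_survival_at(curve, t) == pytest.approx(emp, abs=1e-12)


def test_km_hand_oracle_with_censoring():
    # times 1 (event), 2 (censored), 3 (event)
    curve = mm.kaplan_meier([1.0, 2.0, 3.0], [1, 0, 1])
    assert km_survival_at(curve, 1.0) == pytest.approx(2 / 3)
    assert km_survival_at(curve, 2.9) == pytest.approx(2 / 3)
    assert km_survival_at(curve, 3.0) == pytest.approx(0.0)


def test_km_all_censored_curve_stays_at_one():
    curve = mm.kaplan_meier([1.0, 2.0, 3.0], [0, 0, 0])
    assert curve.empty
    assert km_survival_at(curve, 10.0) == 1.0


def test_km_properties_negative_time_monotone_greenwood():
    with pytest.raises(ValueError):
        mm.kaplan_meier([-1.0], [1])
    rng = np.random.default_rng(4)
    t = rng.exponential(10, size=40)
    e = rng.integers(0, 2, size=40)
    if e.sum() == 0:
        e[0] = 1
    curve = mm.kaplan_meier(t, e)
    s = curve["survival"].to_numpy()
    assert (np.diff(s) <= 1e-12).all()
    assert (curve["greenwood_var"] >= 0).all()


def test_km_matches_lifelines():
    from lifelines import KaplanMeierFitter
    rng = np.random.default_rng(5)
    t = np.round(rng.exponential(10, size=30), 1)
    e = rng.integers(0, 2, size=30)
    if e.sum() == 0:
        e[0] = 1
    curve = mm.kaplan_meier(t, e)
    kmf = KaplanMeierFitter().fit(t, e)
    for ti in curve["time"]:
        assert km_survival_at(curve, ti) == pytest.approx(
            float(kmf.predict(ti)), abs=1e-10)


def test_log_rank_duplicated_groups_give_p_one():
    t = [2.0, 4.0, 6.0, 8.0]
    e = [1, 0, 1, 1]
    res = mm.log_rank(t + t, e + e, ["a"] * 4 + ["b"] * 4)
    assert res.chi2 == pytest.approx(0.0, abs=1e-12)
    assert res.p == 1.0


def test_log_rank_hand_oracle_two_event_times():
    # groups: A times (1, 3), both events; B times (2, 3), event at 2 censored at 3
    times = [1.0, 3.0, 2.0, 3.0]
    events = [1, 1, 1, 0]
    groups = ["A", "A", "B", "B"]
    res = mm.log_rank(times, events, groups)
    # t=1: n=4 (2A/2B) d=1 in A -> E_A += 1/2, V += 2*2*1*3/(16*3) = 1/4
    # t=2: n=3 (1A/2B) d=1 in B -> E_A += 1/3, V += 1*2*1*2/(9*2)  = 2/9
    # t=3: n=2 (1A/1B) d=1 in A -> E_A += 1/2, V += 1*1*1*1/(4*1)  = 1/4
    o_a, e_a, v = 2.0, 0.5 + 1 / 3 + 0.5, 0.25 + 2 / 9 + 0.25
    assert res.observed["A"] == pytest.approx(o_a)
    assert res.expected["A"] == pytest.approx(e_a, abs=1e-12)
    assert res.variance == pytest.approx(v, abs=1e-12)
    assert res.chi2 == pytest.approx((o_a - e_a) ** 2 / v, abs=1e-12)


def test_log_rank_invariant_under_label_swap():
    rng = np.random.default_rng(6)
    t = rng.exponential(10, size=30)
    e = rng.integers(0, 2, size=30)
    g = rng.choice(["x", "y"], size=30)
    if e.sum() == 0:
        e[0] = 1
    a = mm.log_rank(t, e, g)
    b = mm.log_rank(t, e, np.where(g == "x", "y", "x"))
    assert a.chi2 == pytest.approx(b.chi2, abs=1e-12)


def test_log_rank_matches_lifelines():
    from lifelines.statistics import logrank_test
    rng = np.random.default_rng(7)
    t = rng.exponential(10, size=40)
    g = np.repeat(["x", "y"], 20)
    t[20:] *= 0.4
    e = rng.integers(0, 2, size=40)
    if e.sum() == 0:
        e[0] = 1
    ours = mm.log_rank(t, e, g)
    ref = logrank_test(t[:20], t[20:], e[:20], e[20:])
    assert ours.chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
    assert ours.p == pytest.approx(ref.p_value, rel=1e-9)


def test_log_rank_detects_planted_hazard_ratio():
    _, clinical, truth = mm.simulate_cohort(mm.SimulationConfig(seed=11))
    d = clinical.data
    res = mm.log_rank(d["pfs_time"], d["pfs_event"], truth.cluster_labels)
    assert res.p < 0.05


def test_log_rank_validation():
    with pytest.raises(ValueError, match="2 groups"):
        mm.log_rank([1, 2], [1, 1], ["a", "a"])
    with pytest.raises(ValueError, match="events"):
        mm.log_rank([1, 2], [0, 0], ["a", "b"])


# ---------------------------------------------------------------------------
# Cohort table
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def exact_cohort():
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return mm.simulate_cohort(mm.SimulationConfig(seed=0, exact_margins=True))


def test_cohort_table_reproduces_printed_p_values(exact_cohort):
    _, clinical, truth = exact_cohort
    table = mm.cohort_table(clinical, truth.cluster_labels)
    t = table.set_index(["variable", "level"])
    assert t.loc[("simpson", "grade 3"), "p_display"] == "0.54"
    assert t.loc[("location", "others"), "p_display"] == "0.64"
    assert t.loc[("sex", "male"), "p_display"] == "0.45"
    assert t.loc[("edema", "high"), "p_display"] == "0.02"
    assert t.loc[("location", "convexity"), "p_display"] == "0.16"
    assert t.loc[("location", "petroclival"), "p_display"] == "1.00"


def test_cohort_table_requires_two_clusters(exact_cohort):
    _, clinical, truth = exact_cohort
    with pytest.raises(ValueError, match="2 clusters"):
        mm.cohort_table(clinical, pd.Series(1, index=truth.cluster_labels.index))


def test_cohort_table_covers_every_variable_family(exact_cohort):
    _, clinical, truth = exact_cohort
    table = mm.cohort_table(clinical, truth.cluster_labels)
    assert {"fisher", "chi2", "welch_t", "wilcoxon"} <= set(table["test"])
    assert ((table["p"] > 0) & (table["p"] <= 1)).all()
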