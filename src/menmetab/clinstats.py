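"""Cohort statistics: 2x2 tests, rank/means tests, Kaplan-Meier and log-rank.

This layer reproduces a clinical baseline table ("Table-1-style" report)
comparing two metabolic clusters: Fisher's exact test for sparse
categorical rows, Pearson chi-squared for well-filled 2x2 tables, Welch's
t for continuous means, Wilcoxon rank-sum for scores, and a Kaplan-Meier
/ log-rank comparison of progression-free survival.

The two-sided Fisher p is the sum of probabilities of all tables sharing
the observed margins whose point hypergeometric probability does not
exceed the observed table's (with a 1 + 1e-7 relative tolerance for
floating-point equality), evaluated in log space.  The chi-squared test
defaults to no continuity correction.  Both conventions are what standard
clinical reporting software prints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .containers import ClinicalTable


@dataclass
class ContingencyResult:
    table: tuple[int, int, int, int]  # a, b / c, d
    test: str
    statistic: float | None
    p: float
    odds_ratio: float
    degenerate: bool = False


@dataclass
class SurvivalResult:
    """Two-group Kaplan-Meier comparison with the log-rank test."""

    curves: dict  # group -> DataFrame(time, n_at_risk, d_events, survival)
    observed: dict
    expected: dict
    variance: float
    chi2: float
    p: float


# ---------------------------------------------------------------------------
# 2x2 tests
# ---------------------------------------------------------------------------

def _log_hypergeom_pmf(x: int, row1: int, col1: int, n: int) -> float:
    """log P(X = x) for the 2x2 table [x, row1-x / col1-x, ...] with fixed margins."""
    return (
        gammaln(row1 + 1) - gammaln(x + 1) - gammaln(row1 - x + 1)
        + gammaln(n - row1 + 1) - gammaln(col1 - x + 1)
        - gammaln(n - row1 - col1 + x + 1)
        - (gammaln(n + 1) - gammaln(col1 + 1) - gammaln(n - col1 + 1))
    )


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> ContingencyResult:
    """Two-sided Fisher's exact test for a 2x2 table [[a, b], [c, d]].

    Sums, over the hypergeometric support defined by the observed margins,
    the point probabilities no larger than the observed table's
    probability times (1 + 1e-7).  Degenerate margins (an all-zero row or
    column) yield p = 1 with a flag.
    """
    cells = (a, b, c, d)
    if any(v < 0 or int(v) != v for v in cells):
        raise ValueError(f"counts must be non-negative integers, got {cells}")
    a, b, c, d = (int(v) for v in cells)
    n = a + b + c + d
    row1, col1 = a + b, a + c
    odds = _odds_ratio(a, b, c, d)
    if n == 0 or row1 in (0, n) or col1 in (0, n):
        return ContingencyResult((a, b, c, d), "fisher", None, 1.0, odds,
                                 degenerate=True)
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    support = np.arange(lo, hi + 1)
    logp = np.array([_log_hypergeom_pmf(x, row1, col1, n) for x in support])
    log_obs = _log_hypergeom_pmf(a, row1, col1, n)
    keep = logp <= log_obs + np.log1p(1e-7)
    p = float(np.exp(logp[keep]).sum())
    return ContingencyResult((a, b, c, d), "fisher", None, min(p, 1.0), odds)


def _odds_ratio(a, b, c, d) -> float:
    if b * c == 0:
        return float("inf") if a * d > 0 else float("nan")
    return (a * d) / (b * c)


def chi_squared_2x2(a: int, b: int, c: int, d: int,
                    continuity: bool = False) -> ContingencyResult:
    """Pearson chi-squared test for a 2x2 table, df = 1.

    Default is no Yates continuity correction.  A zero margin makes the
    statistic undefined and raises.
    """
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("counts must be non-negative")
    n = a + b + c + d
    if n <= 0:
        raise ValueError("empty table")
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if 0 in (r1, r2, c1, c2):
        raise ValueError("zero margin: chi-squared undefined")
    diff = abs(a * d - b * c)
    if continuity:
        diff = max(0.0, diff - n / 2.0)
    chi2 = n * diff**2 / (r1 * r2 * c1 * c2)
    p = float(stats.chi2.sf(chi2, df=1))
    return ContingencyResult((a, b, c, d), "chi2", float(chi2), p,
                             _odds_ratio(a, b, c, d))


# ---------------------------------------------------------------------------
# Continuous / ordinal comparisons
# ---------------------------------------------------------------------------

def welch_t_from_summary(n1: int, mean1: float, sd1: float,
                         n2: int, mean2: float, sd2: float) -> tuple[float, float, float]:
    """Welch's two-sample t from summary statistics.

    Returns (t, Welch-Satterthwaite df, two-sided p).  This is the test a
    reader can recompute from a published "mean +/- SD" row.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    t = (mean1 - mean2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = float(2 * stats.t.sf(abs(t), df=df))
    return float(t), float(df), p


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration of the rank-sum distribution when n1 + n2 <= 12 and
    there are no ties; otherwise the normal approximation with tie and
    continuity corrections.  Returns (U statistic of the first sample, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = len(x), len(y)
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    w = ranks[:n1].sum()              # rank sum of x
    u = w - n1 * (n1 + 1) / 2.0       # Mann-Whitney U of x
    ties = np.unique(combined, return_counts=True)[1]
    if n1 + n2 <= 12 and (ties == 1).all():
        from itertools import combinations

        total_ranks = np.arange(1, n1 + n2 + 1)
        sums = np.array([sum(cmb) for cmb in combinations(total_ranks, n1)])
        mean_w = n1 * (n1 + n2 + 1) / 2.0
        p = float((np.abs(sums - mean_w) >= abs(w - mean_w) - 1e-9).mean())
        return float(u), min(p, 1.0)
    mu = n1 * n2 / 2.0
    tie_term = ((ties**3 - ties).sum()) / ((n1 + n2) * (n1 + n2 - 1))
    sigma = np.sqrt(n1 * n2 / 12.0 * (n1 + n2 + 1 - tie_term))
    if sigma == 0:
        return float(u), 1.0
    z = (abs(u - mu) - 0.5) / sigma   # continuity correction
    z = max(z, 0.0)
    p = float(2 * stats.norm.sf(z))
    return float(u), min(p, 1.0)


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------

def kaplan_meier(times: Sequence[float], events: Sequence[int]) -> pd.DataFrame:
    """Product-limit survivor curve.

    Returns a DataFrame over distinct event times with columns time,
    n_at_risk, d_events, survival, greenwood_var.  Samples censored at an
    event time are counted at risk for that time.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if (t < 0).any():
        raise ValueError("negative survival time")
    if t.shape != e.shape:
        raise ValueError("times and events must align")
    event_times = np.unique(t[e == 1])
    rows = []
    s = 1.0
    gw = 0.0
    for ti in event_times:
        n_risk = int((t >= ti).sum())
        d = int(((t == ti) & (e == 1)).sum())
        s *= 1.0 - d / n_risk
        if n_risk > d:
            gw += d / (n_risk * (n_risk - d))
        rows.append({"time": ti, "n_at_risk": n_risk, "d_events": d,
                     "survival": s, "greenwood_var": s**2 * gw})
    return pd.DataFrame(rows, columns=["time", "n_at_risk", "d_events",
                                       "survival", "greenwood_var"])


def km_survival_at(curve: pd.DataFrame, t: float) -> float:
    """S(t) read off a Kaplan-Meier curve (right-continuous step function)."""
    past = curve[curve["time"] <= t]
    return 1.0 if past.empty else float(past["survival"].iloc[-1])


def log_rank(times: Sequence[float], events: Sequence[int],
             groups: Sequence) -> SurvivalResult:
    """Two-group log-rank test.

    At each distinct event time t_j with d_j pooled events and n_gj at
    risk per group: E_1j = n_1j d_j / n_j and
    V_j = n_1j n_2j d_j (n_j - d_j) / (n_j^2 (n_j - 1)); the statistic is
    (O_1 - E_1)^2 / sum V_j referred to chi-squared with 1 df.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups)
    labels = np.unique(g)
    if len(labels) != 2:
        raise ValueError(f"log-rank requires exactly 2 groups, got {len(labels)}")
    if e.sum() == 0:
        raise ValueError("no events observed")
    event_times = np.unique(t[e == 1])
    O = {lab: 0.0 for lab in labels}
    E = {lab: 0.0 for lab in labels}
    V = 0.0
    for tj in event_times:
        at_risk = t >= tj
        n_j = int(at_risk.sum())
        d_j = int(((t == tj) & (e == 1)).sum())
        n_1 = int((at_risk & (g == labels[0])).sum())
        n_2 = n_j - n_1
        d_1 = int(((t == tj) & (e == 1) & (g == labels[0])).sum())
        O[labels[0]] += d_1
        O[labels[1]] += d_j - d_1
        E[labels[0]] += n_1 * d_j / n_j
        E[labels[1]] += n_2 * d_j / n_j
        if n_j > 1:
            V += n_1 * n_2 * d_j * (n_j - d_j) / (n_j**2 * (n_j - 1))
    chi2 = 0.0 if V == 0 else (O[labels[0]] - E[labels[0]]) ** 2 / V
    p = float(stats.chi2.sf(chi2, df=1))
    curves = {
        lab: kaplan_meier(t[g == lab], e[g == lab]) for lab in labels
    }
    return SurvivalResult(curves=curves, observed=O, expected=E,
                          variance=V, chi2=float(chi2), p=p)


# ---------------------------------------------------------------------------
# Table-1-style cohort report
# ---------------------------------------------------------------------------

def _two_by_two(flags: pd.Series, in_g1: pd.Series) -> tuple[int, int, int, int]:
    a = int((flags & in_g1).sum())
    b = int((flags & ~in_g1).sum())
    c = int((~flags & in_g1).sum())
    d = int((~flags & ~in_g1).sum())
    return a, b, c, d


def cohort_table(clinical: ClinicalTable, labels: pd.Series) -> pd.DataFrame:
    """Per-variable two-cluster comparison (a Table-1-style report).

    Categorical rows use Fisher's exact test (one level vs rest), except
    2x2 variables whose expected counts are all >= 5, which use Pearson
    chi-squared; age and tumor size use Welch's t on the raw values; KPS
    scores use the Wilcoxon rank-sum test.  p-values are reported at full
    precision with a two-decimal display column.
    """
    d = clinical.data.loc[labels.index]
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"cohort table requires exactly 2 clusters, got {len(groups)}")
    in_g1 = pd.Series(np.asarray(labels) == groups[0], index=labels.index)
    rows: list[dict] = []

    def add(variable, level, test, p, detail=""):
        rows.append({"variable": variable, "level": level, "test": test,
                     "p": p, "p_display": f"{p:.2f}", "detail": detail})

    def categorical(var: str, level_order=None):
        if var not in d:
            warnings.warn(f"variable {var!r} missing; omitted", stacklevel=2)
            return
        levels = level_order or sorted(d[var].dropna().unique())
        for lev in levels:
            flags = d[var] == lev
            a, b, c, dd = _two_by_two(flags, in_g1)
            # chi-squared when all expected counts reach 5, Fisher otherwise
            n = a + b + c + dd
            exp_ok = n > 0 and min(
                (a + b) * (a + c), (a + b) * (b + dd),
                (c + dd) * (a + c), (c + dd) * (b + dd)) / n >= 5
            if exp_ok and len(levels) == 2:
                res = chi_squared_2x2(a, b, c, dd)
            else:
                res = fisher_exact_2x2(a, b, c, dd)
            add(var, str(lev), res.test, res.p, f"{a}/{b} vs {c}/{dd}")
            if len(levels) == 2:
                break  # one row describes a binary variable

    def continuous(var: str):
        if var not in d:
            warnings.warn(f"variable {var!r} missing; omitted", stacklevel=2)
            return
        x = d.loc[in_g1, var].dropna().to_numpy(dtype=float)
        y = d.loc[~in_g1, var].dropna().to_numpy(dtype=float)
        t, df, p = welch_t_from_summary(len(x), x.mean(), x.std(ddof=1),
                                        len(y), y.mean(), y.std(ddof=1))
        add(var, "", "welch_t", p, f"{x.mean():.1f}±{x.std(ddof=1):.1f} vs "
                                   f"{y.mean():.1f}±{y.std(ddof=1):.1f}")

    def rank(var: str):
        if var not in d:
            warnings.warn(f"variable {var!r} missing; omitted", stacklevel=2)
            return
        x = d.loc[in_g1, var].dropna().to_numpy(dtype=float)
        y = d.loc[~in_g1, var].dropna().to_numpy(dtype=float)
        _, p = wilcoxon_rank_sum(x, y)
        add(var, "", "wilcoxon", p)

    categorical("sex", level_order=["male", "female"])
    continuous("age")
    continuous("size_cm3")
    if "edema" in d:
        a, b, c, dd = _two_by_two(d["edema"] == "high", in_g1)
        res = chi_squared_2x2(a, b, c, dd)
        add("edema", "high", res.test, res.p, f"{a}/{b} vs {c}/{dd}")
    categorical("location")
    if "simpson" in d:
        for lev in sorted(d["simpson"].dropna().unique()):
            a, b, c, dd = _two_by_two(d["simpson"] == lev, in_g1)
            res = fisher_exact_2x2(a, b, c, dd)
            add("simpson", f"grade {int(lev)}", res.test, res.p,
                f"{a}/{b} vs {c}/{dd}")
    rank("kps_pre")
    rank("kps_post")
    if "mib1" in d:
        a, b, c, dd = _two_by_two(d["mib1"] < 5.0, in_g1)
        res = fisher_exact_2x2(a, b, c, dd)
        add("mib1", "< 5%", res.test, res.p, f"{a}/{b} vs {c}/{dd}")
    if "who_grade" in d:
        a, b, c, dd = _two_by_two(d["who_grade"] == "I", in_g1)
        res = fisher_exact_2x2(a, b, c, dd)
        add("who_grade", "I vs II+III", res.test, res.p, f"{a}/{b} vs {c}/{dd}")
    return pd.DataFrame(rows, columns=["variable", "level", "test", "p",
                                       "p_display", "detail"])
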