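"""Metabolite-set enrichment against a small built-in pathway library.

Two complementary flavors:

* ORA (over-representation analysis): given a discrete list of selected
  metabolites (a cluster signature, a module), the upper-tail
  hypergeometric probability of observing at least the seen number of
  pathway hits, with an enrichment score ES = (k/n)/(K/N) — the
  observed-over-expected hit ratio.
* QEA (quantitative enrichment analysis): no hard cut; the per-set
  statistic is the mean absolute Welch t of member metabolites between
  two sample groups, referenced to its label-permutation null.

Both report Benjamini-Hochberg adjusted p-values across sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import MetaboliteMatrix

#: compact pathway library over the named metabolites the simulator emits
BUILTIN_SETS: dict[str, list[str]] = {
    "glycine_serine_threonine_metabolism": [
        "glycine", "serine", "threonine", "creatine", "arginine"],
    "glutamate_metabolism": ["glutamate", "glutamine", "aspartate", "alanine"],
    "tryptophan_metabolism": ["tryptophan", "kynurenine", "kynurenic_acid"],
    "choline_glycerophospholipid_metabolism": [
        "choline", "phosphocholine", "myo_inositol"],
    "sphingolipid_metabolism": ["sphingosine", "serine", "choline"],
    "glycolysis": ["glucose", "l_lactic_acid", "citrate", "succinate"],
}


@dataclass
class MetaboliteSetLibrary:
    """Named metabolite sets (pathways)."""

    sets: dict[str, list[str]]

    def __post_init__(self) -> None:
        empty = [k for k, v in self.sets.items() if not v]
        if empty:
            raise ValueError(f"empty sets: {empty}")

    @classmethod
    def builtin(cls) -> "MetaboliteSetLibrary":
        return cls({k: list(v) for k, v in BUILTIN_SETS.items()})

    def restricted_to(self, universe: Iterable[str]) -> "MetaboliteSetLibrary":
        uni = set(universe)
        kept = {k: [m for m in v if m in uni] for k, v in self.sets.items()}
        return MetaboliteSetLibrary({k: v for k, v in kept.items() if v})

    # GMT-style text: name <tab> description <tab> member ...
    def to_gmt(self, path: str | Path) -> None:
        lines = [f"{name}\t-\t" + "\t".join(members)
                 for name, members in self.sets.items()]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_gmt(cls, path: str | Path) -> "MetaboliteSetLibrary":
        sets = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line!r}")
            sets[parts[0]] = parts[2:]
        return cls(sets)


def ora(
    selected: Sequence[str],
    set_library: MetaboliteSetLibrary,
    universe: Sequence[str],
) -> pd.DataFrame:
    """Over-representation analysis by the upper-tail hypergeometric test.

    For each set: k = hits among the n selected metabolites, K = set size
    within the N-metabolite universe, p = P(X >= k) for X hypergeometric,
    ES = (k/n) / (K/N).  BH adjustment across sets.
    """
    if len(selected) == 0:
        raise ValueError("empty selection")
    uni = set(universe)
    sel = set(selected)
    if not sel <= uni:
        raise ValueError(f"selected metabolites outside universe: "
                         f"{sorted(sel - uni)[:5]}")
    N, n = len(uni), len(sel)
    rows = []
    for name, members in set_library.sets.items():
        mem = set(members) & uni
        if not mem:
            continue
        K = len(mem)
        k = len(mem & sel)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        es = (k / n) / (K / N)
        rows.append({"set": name, "k": k, "K": K, "n": n, "N": N,
                     "es": es, "p": min(p, 1.0)})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def qea(
    matrix: MetaboliteMatrix,
    labels: pd.Series,
    set_library: MetaboliteSetLibrary,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Quantitative enrichment by label permutation.

    Per-set statistic: mean |Welch t| of member metabolites between the
    two groups.  p = (1 + #{permutations with statistic >= observed}) /
    (1 + n_perm), so a permutation p is never exactly zero.  BH across
    sets.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is low; permutation p-values will be "
                      "coarse", stacklevel=2)
    y = np.asarray(labels.loc[matrix.sample_ids])
    groups = np.unique(y)
    if len(groups) != 2:
        raise ValueError(f"QEA requires exactly 2 groups, got {len(groups)}")
    x = matrix.to_numpy()
    names = matrix.metabolite_names
    col_of = {m: j for j, m in enumerate(names)}
    mask = y == groups[0]

    def set_stats(group_mask: np.ndarray) -> np.ndarray:
        """|Welch t| per metabolite for one labelling."""
        a, b = x[group_mask], x[~group_mask]
        na, nb = len(a), len(b)
        va, vb = a.var(axis=0, ddof=1) / na, b.var(axis=0, ddof=1) / nb
        with np.errstate(invalid="ignore", divide="ignore"):
            t = (a.mean(axis=0) - b.mean(axis=0)) / np.sqrt(va + vb)
        return np.abs(np.nan_to_num(t))

    obs_t = set_stats(mask)
    rng = np.random.default_rng(seed)
    perm_t = np.empty((n_perm, len(names)))
    n1 = int(mask.sum())
    for i in range(n_perm):
        pm = np.zeros(len(y), dtype=bool)
        pm[rng.choice(len(y), size=n1, replace=False)] = True
        perm_t[i] = set_stats(pm)

    rows = []
    for name, members in set_library.sets.items():
        cols = [col_of[m] for m in members if m in col_of]
        if not cols:
            continue
        obs = float(obs_t[cols].mean())
        null = perm_t[:, cols].mean(axis=1)
        p = (1.0 + float((null >= obs).sum())) / (1.0 + n_perm)
        rows.append({"set": name, "statistic": obs, "n_members": len(cols), "p": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    return out
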