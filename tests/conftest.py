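import warnings

import numpy as np
import pandas as pd
import pytest

import menmetab as mm


@pytest.fixture(autouse=True)
def _quiet():
    # generator / statsmodels convergence chatter is irrelevant to assertions
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture(scope="session")
def default_cohort():
    """One seeded default cohort shared by read-only tests."""
    return mm.simulate_cohort(mm.SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def centered_cohort(default_cohort):
    matrix, clinical, truth = default_cohort
    centered = mm.log2_median_center(mm.pq_normalize(matrix))
    return centered, clinical, truth


def jaccard(a, b) -> float:
    a, b = set(a), set(b)
    return len(a & b) / len(a | b) if (a | b) else 1.0


def best_match_jaccard(found: pd.Series, planted: set[str]) -> float:
    """Best Jaccard of a planted module against any detected module."""
    best = 0.0
    for mod in [m for m in found.unique() if m != "grey"]:
        members = set(found.index[found == mod])
        best = max(best, jaccard(members, planted))
    return best


def random_matrix(n_samples, n_metabolites, seed, state="log2_centered"):
    rng = np.random.default_rng(seed)
    vals = rng.normal(size=(n_samples, n_metabolites))
    df = pd.DataFrame(vals, index=[f"s{i}" for i in range(n_samples)],
                      columns=[f"m{j}" for j in range(n_metabolites)])
    return mm.MetaboliteMatrix(df, state=state)
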