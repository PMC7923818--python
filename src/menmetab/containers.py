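"""Core in-memory containers shared across the pipeline.

The pipeline's central object is a samples x metabolites intensity table
carried through an explicit processing-state machine: ``raw`` intensities
(non-negative, as quantified from spectra) -> ``normalized`` (pseudo-counted
quantile normalization) -> ``log2_centered`` (log2 transform, per-metabolite
median centering).  Forcing every stage to declare which state it accepts
catches silent misuse (e.g. clustering raw intensities) early.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

#: allowed processing states, in pipeline order
STATES = ("raw", "normalized", "log2_centered")


class StateError(ValueError):
    """Raised when an operation receives a matrix in the wrong processing state."""


@dataclass
class MetaboliteMatrix:
    """Samples x metabolites intensity table with a processing-state flag.

    Parameters
    ----------
    values
        DataFrame with sample ids as index and metabolite names as columns.
    state
        One of ``raw``, ``normalized``, ``log2_centered``.
    """

    values: pd.DataFrame
    state: str = "raw"

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}; expected one of {STATES}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate metabolite names: {dups}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("intensity matrix contains non-finite entries")
        if self.state == "raw" and (self.values.to_numpy() < 0).any():
            raise ValueError("raw intensities must be non-negative")

    # -- convenience views ------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def metabolite_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.values.shape[1]

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def require_state(self, *states: str) -> None:
        if self.state not in states:
            raise StateError(
                f"matrix state is {self.state!r}, operation requires {' or '.join(states)}"
            )

    def with_values(self, values: pd.DataFrame, state: str) -> "MetaboliteMatrix":
        """Return a new matrix with replaced values and state (no mutation)."""
        return MetaboliteMatrix(values=values, state=state)


#: clinical covariates the cohort table may carry; order is report order
CLINICAL_COLUMNS = (
    "cluster",
    "subtype",
    "sex",
    "age",
    "size_cm3",
    "edema",
    "location",
    "simpson",
    "kps_pre",
    "kps_post",
    "mib1",
    "who_grade",
    "pfs_time",
    "pfs_event",
)

LOCATIONS = (
    "falx",
    "convexity",
    "frontobasal",
    "sphenoid wing",
    "petroclival",
    "spinal",
    "others",
)


@dataclass
class ClinicalTable:
    """Per-sample clinical covariates including progression-free survival.

    ``data`` is indexed by sample id.  Expected columns (any subset): sex
    ('male'/'female'), age (years), size_cm3, edema ('high'/'low'), location
    (one of the declared sites), simpson (1-4), kps_pre/kps_post (%),
    mib1 (%), who_grade ('I'/'II'/'III'), pfs_time (months),
    pfs_event (0/1), plus optional cluster/subtype labels.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate sample ids in clinical table")
        if "pfs_time" in self.data.columns and (self.data["pfs_time"] < 0).any():
            raise ValueError("pfs_time must be non-negative")
        if "pfs_event" in self.data.columns:
            ev = set(self.data["pfs_event"].dropna().unique())
            if not ev <= {0, 1}:
                raise ValueError(f"pfs_event must be 0/1, got {sorted(ev)}")
        if "location" in self.data.columns:
            bad = set(self.data["location"].dropna().unique()) - set(LOCATIONS)
            if bad:
                raise ValueError(f"unknown locations: {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def aligned_to(self, sample_ids: Sequence[str]) -> "ClinicalTable":
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise KeyError(f"clinical table missing samples: {missing[:5]}")
        return ClinicalTable(self.data.loc[list(sample_ids)])
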