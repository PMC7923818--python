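"""File I/O: intensity tables, clinical tables, truth, and run manifests."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ClinicalTable, MetaboliteMatrix


class ParseError(ValueError):
    pass


def _sniff_delimiter(path: Path) -> str:
    head = path.read_text().splitlines()[0] if path.stat().st_size else ""
    return "\t" if head.count("\t") >= head.count(",") else ","


def read_metabolite_table(path: str | Path, state: str | None = None) -> MetaboliteMatrix:
    """Load a samples x metabolites table (TSV or CSV, delimiter auto-detected).

    First column = sample id, header row = metabolite names.  A sidecar
    ``<path>.state.json`` written by :func:`write_metabolite_table`
    restores the processing-state flag; otherwise the state defaults to
    ``raw`` (or the explicit ``state`` argument).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _sniff_delimiter(path)
    header = path.read_text().splitlines()[0].split(sep)[1:]
    if len(set(header)) != len(header):
        dups = sorted({h for h in header if header.count(h) > 1})
        raise ParseError(f"duplicate metabolite columns in {path}: {dups}")
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:  # surface pandas' line info
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].tolist()
        raise ParseError(f"duplicate sample ids in {path}: {dups}")
    bad = df.columns[~df.apply(lambda c: pd.to_numeric(c, errors="coerce").notna().all())]
    if len(bad):
        raise ParseError(f"non-numeric cells in columns {list(bad)} of {path}")
    if state is None:
        sidecar = path.with_suffix(path.suffix + ".state.json")
        state = (json.loads(sidecar.read_text())["state"] if sidecar.exists()
                 else "raw")
    return MetaboliteMatrix(values=df.astype(float), state=state)


def write_metabolite_table(matrix: MetaboliteMatrix, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    matrix.values.to_csv(path, sep=sep)
    sidecar = path.with_suffix(path.suffix + ".state.json")
    sidecar.write_text(json.dumps({"state": matrix.state}))


def read_clinical_table(path: str | Path) -> ClinicalTable:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sniff_delimiter(path), index_col=0)
    return ClinicalTable(df)


def write_clinical_table(clinical: ClinicalTable, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    clinical.data.to_csv(path, sep=sep)
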