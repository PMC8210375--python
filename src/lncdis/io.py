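"""Readers and writers for TSV matrices, edge lists, the disease DAG and
the run-configuration file.

File conventions
----------------
* Matrices: TSV with a header row of column names and a first column of row
  names. Binary matrices are validated to contain only 0/1.
* Edge lists: two-column TSV of ``(row_name, col_name)`` pairs, optionally a
  third weight/relation column (ignored for associations).
* DAG: three-column TSV of ``(child, parent, relation)`` rows.
* Config: ``key: value`` lines; blank lines and ``#`` comments ignored.
"""

from __future__ import annotations

import ast
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .core import (
    AssociationMatrix,
    BinaryMatrix,
    DiseaseDAG,
    EntityIndex,
    LabeledMatrix,
    RunConfig,
    ValidationError,
)


def _check_unique(names: Sequence[str], what: str, path) -> None:
    seen = set()
    for nm in names:
        if nm in seen:
            raise ValidationError(f"duplicate identifier {nm!r} in {what} of {path}")
        seen.add(nm)


def read_matrix(path, row_kind: str, col_kind: str, binary: bool = False) -> LabeledMatrix:
    """Read a named TSV matrix.

    Entity order on disk is preserved into the indexes (files are
    name-addressed, so any order round-trips identically).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str}, float_precision="round_trip")
    _check_unique(list(df.index.astype(str)), "row names", path)
    _check_unique(list(df.columns.astype(str)), "column names", path)
    try:
        values = df.to_numpy(dtype=float)
    except ValueError:
        for i, row in enumerate(df.itertuples(index=False)):
            for j, v in enumerate(row):
                try:
                    float(v)
                except (TypeError, ValueError):
                    raise ValidationError(
                        f"non-numeric cell {v!r} at row {df.index[i]!r}, "
                        f"column {df.columns[j]!r} of {path}"
                    ) from None
        raise
    rows = EntityIndex(row_kind, df.index.astype(str), keep_order=True)
    cols = EntityIndex(col_kind, df.columns.astype(str), keep_order=True)
    cls = BinaryMatrix if binary else LabeledMatrix
    return cls(rows, cols, values)


def write_matrix(mat, path) -> None:
    """Write a labelled or similarity matrix as a named TSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if hasattr(mat, "row_index"):
        rows, cols = mat.row_index.names, mat.col_index.names
    else:  # SimilarityMatrix
        rows = cols = mat.index.names
    df = pd.DataFrame(mat.values, index=list(rows), columns=list(cols))
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_edge_list(
    path,
    kinds: tuple[str, str],
    row_universe: Sequence[str] | None = None,
    col_universe: Sequence[str] | None = None,
) -> AssociationMatrix:
    """Read a two-column TSV of pairs into a dense 0/1 association matrix.

    Without an explicit universe, the index is the sorted union of observed
    names. With a universe, names outside it are rejected (prevents shape
    drift between matrices built from different files).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        raise ValidationError(f"empty edge list: {path}") from None
    if df.empty:
        raise ValidationError(f"empty edge list: {path}")
    if df.shape[1] < 2:
        raise ValidationError(f"edge list {path} needs at least two columns")
    pairs = list(zip(df[0].astype(str), df[1].astype(str)))
    row_kind, col_kind = kinds
    if row_kind == col_kind:
        for a, b in pairs:
            if a == b:
                raise ValidationError(f"self-pair {a!r} in same-kind edge list {path}")
    if row_universe is None:
        rows = EntityIndex(row_kind, sorted({a for a, _ in pairs}))
    else:
        rows = EntityIndex(row_kind, row_universe, keep_order=True)
    if col_universe is None:
        cols = EntityIndex(col_kind, sorted({b for _, b in pairs}))
    else:
        cols = EntityIndex(col_kind, col_universe, keep_order=True)
    values = np.zeros((len(rows), len(cols)))
    for a, b in pairs:
        if a not in rows:
            raise ValidationError(f"unknown {row_kind} {a!r} not in declared universe")
        if b not in cols:
            raise ValidationError(f"unknown {col_kind} {b!r} not in declared universe")
        values[rows.position(a), cols.position(b)] = 1.0
    return AssociationMatrix(rows, cols, values)


def write_edge_list(mat: AssociationMatrix, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for i, j in np.argwhere(mat.values == 1):
            fh.write(f"{mat.row_index.names[i]}\t{mat.col_index.names[j]}\n")


def read_dag(path, relation_weight: dict[str, float] | None = None) -> DiseaseDAG:
    """Read a (child, parent, relation) TSV into a validated disease DAG."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValidationError(f"DAG file {path} needs (child, parent[, relation]) columns")
    g = nx.DiGraph()
    for row in df.itertuples(index=False):
        child, parent = str(row[0]), str(row[1])
        rel = str(row[2]) if len(row) > 2 and not pd.isna(row[2]) else "is_a"
        g.add_edge(child, parent, relation=rel)
    kwargs = {} if relation_weight is None else {"relation_weight": relation_weight}
    return DiseaseDAG(g, **kwargs)


def write_dag(dag: DiseaseDAG, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for child, parent, data in dag.graph.edges(data=True):
            fh.write(f"{child}\t{parent}\t{data.get('relation', 'is_a')}\n")


def read_config(path) -> RunConfig:
    """Read a ``key: value`` config file into a RunConfig."""
    d = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if ":" not in line:
            raise ValidationError(f"malformed config line {lineno}: {line!r}")
        key, val = (s.strip() for s in line.split(":", 1))
        try:
            d[key] = ast.literal_eval(val)
        except (ValueError, SyntaxError):
            d[key] = val
    return RunConfig.from_dict(d)


def write_config(config: RunConfig, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, val in config.to_dict().items():
            fh.write(f"{key}: {val!r}\n" if isinstance(val, str) else f"{key}: {val}\n")
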