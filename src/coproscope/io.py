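"""Readers/writers for abundance tables and labelled distance matrices.

Abundance tables are plain TSV with a header row and an id column; the
in-memory container is a pandas DataFrame oriented hosts x taxa with
non-negative numeric entries.  Distance matrices are written with the full
symmetric body and round-trip through :class:`skbio.DistanceMatrix`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skbio.stats.distance import DistanceMatrix

__all__ = [
    "read_abundance_table",
    "write_abundance_table",
    "validate_abundance_table",
    "read_distance_matrix",
    "write_distance_matrix",
]


def validate_abundance_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check an in-memory hosts x taxa table: unique ids, numeric, >= 0."""
    if table.index.duplicated().any():
        dupes = sorted(table.index[table.index.duplicated()].unique())
        raise ValueError(f"duplicate host ids: {dupes}")
    if table.columns.duplicated().any():
        dupes = sorted(table.columns[table.columns.duplicated()].unique())
        raise ValueError(f"duplicate taxon ids: {dupes}")
    values = table.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError("abundance table entries must be numeric")
    if (values < 0).any():
        raise ValueError("abundance table contains negative entries")
    return table


def read_abundance_table(path, orientation: str = "hosts") -> pd.DataFrame:
    """Read a TSV count table; normalise orientation to hosts x taxa.

    Parameters
    ----------
    orientation : {"hosts", "taxa"}
        Which entity occupies the rows *in the file*.  ``"taxa"`` inputs are
        transposed on read, so callers always receive hosts-in-rows.
    """
    if orientation not in ("hosts", "taxa"):
        raise ValueError(f"orientation must be 'hosts' or 'taxa', "
                         f"got {orientation!r}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    col_ids = header[1:]
    if len(set(col_ids)) != len(col_ids):
        dupes = sorted({c for c in col_ids if col_ids.count(c) > 1})
        raise ValueError(f"duplicate column ids: {dupes}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.isna().any().any():
        raise ValueError("ragged or missing entries in abundance table")
    if orientation == "taxa":
        df = df.T
    return validate_abundance_table(df)


def write_abundance_table(table: pd.DataFrame, path) -> None:
    validate_abundance_table(table)
    out = table.copy()
    out.index.name = out.index.name or "host"
    out.to_csv(path, sep="\t")


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise ValueError("distance matrix row/column labels disagree")
    return DistanceMatrix(df.to_numpy(dtype=float),
                          ids=[str(i) for i in df.index])


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(path, sep="\t")
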