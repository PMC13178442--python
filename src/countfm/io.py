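"""Count-matrix readers and writers (CSV and MatrixMarket)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .containers import CountMatrix, ValidationError


def _validate_frame(df: pd.DataFrame, path) -> CountMatrix:
    values = df.to_numpy()
    if values.dtype == object or not np.issubdtype(values.dtype, np.number):
        raise ValidationError(f"{path}: non-numeric entries in count matrix")
    bad = ~np.isfinite(values.astype(float)) | (values.astype(float) % 1 != 0) | (values < 0)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValidationError(
            f"{path}: entry at row {df.index[r]!r}, column {df.columns[c]!r} "
            "is not a nonnegative integer"
        )
    row_names = tuple(str(i) for i in df.index) if not isinstance(
        df.index, pd.RangeIndex) else None
    return CountMatrix(values.astype(np.int64), row_names=row_names,
                       col_names=tuple(str(c) for c in df.columns))


def read_counts(path, fmt: str | None = None) -> CountMatrix:
    """Read a count matrix from CSV (dense) or MatrixMarket (sparse).

    The format is inferred from the suffix unless given explicitly.  CSV files
    may carry a leading non-numeric index column, which is preserved as row
    names.
    """
    path = Path(path)
    fmt = fmt or ("mtx" if path.suffix == ".mtx" else "csv")
    if fmt == "mtx":
        mat = spio.mmread(path)
        if sparse.issparse(mat):
            mat = mat.toarray()
        arr = np.asarray(mat)
        if np.any(arr % 1 != 0) or np.any(arr < 0):
            raise ValidationError(f"{path}: non-integer or negative entries")
        return CountMatrix(arr.astype(np.int64))
    if fmt != "csv":
        raise ValidationError(f"unknown format {fmt!r}")
    df = pd.read_csv(path)
    first = df.columns[0]
    if df[first].dtype == object:
        df = df.set_index(first)
    return _validate_frame(df, path)


def write_counts(matrix: CountMatrix, path, fmt: str | None = None) -> None:
    """Write a count matrix; deterministic bytes for a fixed input."""
    if not isinstance(matrix, CountMatrix):
        matrix = CountMatrix(matrix)
    path = Path(path)
    fmt = fmt or ("mtx" if path.suffix == ".mtx" else "csv")
    if fmt == "mtx":
        spio.mmwrite(path, sparse.coo_matrix(matrix.values))
        return
    if fmt != "csv":
        raise ValidationError(f"unknown format {fmt!r}")
    cols = matrix.col_names or tuple(f"c{i}" for i in range(matrix.d))
    df = pd.DataFrame(matrix.values, columns=list(cols))
    if matrix.row_names is not None:
        df.insert(0, "sample", list(matrix.row_names))
    df.to_csv(path, index=False)


def read_covariates(path) -> np.ndarray:
    """Read a covariate table (CSV, one row per sample)."""
    df = pd.read_csv(path)
    first = df.columns[0]
    if df[first].dtype == object:
        df = df.set_index(first)
    return df.to_numpy(dtype=float)
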