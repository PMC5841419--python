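"""Readers and writers for the pipeline's plain-text formats."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, check_labels


def read_expression(
    path: str | Path, classes_path: str | Path | None = None
) -> ExpressionMatrix | pd.DataFrame:
    """Read a genes x samples TSV (first column gene id, header = samples).

    With ``classes_path`` (a 2-column TSV gene/class) the result is an
    :class:`ExpressionMatrix`; without it the raw DataFrame is returned
    (e.g. probe-level matrices that have no gene class yet).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ValueError(f"{path}: empty expression matrix")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()]
        rows = [int(i) + 2 for i in np.flatnonzero(df.index.duplicated())]
        raise ValueError(
            f"{path}: duplicate gene ids {list(dup.unique())[:5]} (rows {rows[:5]})"
        )
    non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        for c in non_numeric:
            bad = df[pd.to_numeric(df[c], errors="coerce").isna()]
            if len(bad):
                raise ValueError(
                    f"{path}: non-numeric value in column {c!r}, gene {bad.index[0]!r}"
                )
        df = df.astype(float)
    if classes_path is None:
        return df
    classes = pd.read_csv(classes_path, sep="\t", index_col=0).iloc[:, 0]
    return ExpressionMatrix(df, classes)


def read_labels(path: str | Path) -> pd.Series:
    """Read a 2-column TSV (sample id, class in {0,1})."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] != 1:
        raise ValueError(f"{path}: labels file must have exactly 2 columns")
    s = df.iloc[:, 0]
    if s.index.has_duplicates:
        raise ValueError(f"{path}: duplicate sample ids")
    if set(s.unique()) - {0, 1}:
        raise ValueError(f"{path}: labels must be 0/1, found {sorted(s.unique())}")
    return s.astype(int)


def read_interactions(path: str | Path) -> pd.DataFrame:
    """Read a 2-column miRNA-target TSV (header optional)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] != 2:
        raise ValueError(f"{path}: interaction table must have 2 columns")
    df.columns = ["mirna", "target"]
    if df.isna().any().any():
        row = int(df[df.isna().any(axis=1)].index[0]) + 2
        raise ValueError(f"{path}: missing field at row {row}")
    return df


def load_matrix_with_labels(
    expression: str | Path, labels: str | Path, classes: str | Path
) -> tuple[ExpressionMatrix, pd.Series]:
    expr = read_expression(expression, classes)
    lab = read_labels(labels)
    lab = check_labels(lab, expr.samples)
    return expr, lab


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False, **meta) -> None:
    """Write a TSV with ``# key: value`` header comments recording parameters."""
    path = Path(path)
    with path.open("w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=index)
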