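"""Shared in-memory containers for expression data."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GENE_CLASSES = ("mRNA", "lncRNA")


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix of log2 expression values.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample.
    gene_class
        Series mapping every gene id in ``values`` to ``"mRNA"`` or
        ``"lncRNA"``.
    """

    values: pd.DataFrame
    gene_class: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dup)[:5]}")
        self.gene_class = self.gene_class.reindex(self.values.index)
        if self.gene_class.isna().any():
            missing = self.gene_class.index[self.gene_class.isna()]
            raise ValueError(f"genes without a class label: {list(missing)[:5]}")
        bad = set(self.gene_class.unique()) - set(GENE_CLASSES)
        if bad:
            raise ValueError(f"unknown gene classes: {sorted(bad)}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def of_class(self, gene_class: str) -> pd.DataFrame:
        """Rows of the requested gene class."""
        if gene_class not in GENE_CLASSES:
            raise ValueError(f"gene_class must be one of {GENE_CLASSES}")
        return self.values.loc[self.gene_class == gene_class]

    def subset(self, genes) -> "ExpressionMatrix":
        genes = pd.Index(genes)
        missing = genes.difference(self.values.index)
        if len(missing):
            raise KeyError(f"genes absent from matrix: {list(missing)[:5]}")
        return ExpressionMatrix(self.values.loc[genes], self.gene_class.loc[genes])


def check_labels(labels: pd.Series, samples: pd.Index) -> pd.Series:
    """Validate a binary sample-label vector against a sample index."""
    labels = labels.astype(int)
    if set(labels.unique()) - {0, 1}:
        raise ValueError("labels must be binary (0/1)")
    if set(labels.index) != set(samples):
        extra = sorted(set(labels.index) - set(samples))
        miss = sorted(set(samples) - set(labels.index))
        raise ValueError(
            f"label/sample mismatch: labels lack {miss[:5]}, matrix lacks {extra[:5]}"
        )
    return labels.reindex(samples)
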