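"""Probe re-annotation by genomic-interval matching.

Assigns array probes (pre-aligned, BED6) to genes (GTF annotation, e.g.
GENCODE lncRNAs) when their intervals overlap on the same chromosome
(and strand, unless relaxed).  Probes hitting zero genes or more than
one gene are dropped -- uniqueness of the mapping is required so that
probe signal is never double-counted.  Probe-level expression is then
collapsed to gene level by averaging the probes of each gene.

All coordinates are handled internally as 0-based half-open; BED is
consumed natively and GTF's 1-based inclusive coordinates are converted
on read.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from intervaltree import IntervalTree

_STRANDS = ("+", "-")


@dataclass(frozen=True)
class ProbeAlignment:
    probe_id: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"probe {self.probe_id}: malformed interval {self.start}>={self.end}"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"probe {self.probe_id}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    chrom: str
    start: int  # 0-based half-open (converted from GTF on read)
    end: int
    strand: str
    biotype: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"gene {self.gene_id}: malformed interval {self.start}>={self.end}"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")


def read_bed6(path: str | Path) -> list[ProbeAlignment]:
    """Probe alignments from a BED6 file (natively 0-based half-open)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 6:
        raise ValueError(f"{path}: BED6 requires 6 columns, found {df.shape[1]}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            ProbeAlignment(
                probe_id=str(row[3]),
                chrom=str(row[0]),
                start=int(row[1]),
                end=int(row[2]),
                strand=str(row[5]),
            )
        )
    return out


def read_gtf_genes(path: str | Path, feature: str = "gene") -> list[GeneAnnotation]:
    """Gene records from a GTF file, converted to 0-based half-open.

    Uses ``gene_id`` and (when present) ``gene_type``/``gene_biotype``
    attributes of ``gene`` feature lines.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    out = []
    for f in db.features_of_type(feature):
        biotype = ""
        for key in ("gene_type", "gene_biotype"):
            if key in f.attributes:
                biotype = f.attributes[key][0]
                break
        out.append(
            GeneAnnotation(
                gene_id=f.attributes["gene_id"][0],
                chrom=f.seqid,
                start=f.start - 1,  # GTF is 1-based inclusive
                end=f.end,
                strand=f.strand,
                biotype=biotype,
            )
        )
    return out


@dataclass
class MatchResult:
    """Unique probe-to-gene mapping with bookkeeping of dropped probes."""

    mapping: dict[str, str]
    n_ambiguous: int
    n_unmatched: int
    ambiguous: tuple[str, ...]
    unmatched: tuple[str, ...]


def match_probes_to_genes(
    probes: list[ProbeAlignment],
    genes: list[GeneAnnotation],
    strand_mode: str = "strict",
    min_overlap: int = 1,
) -> MatchResult:
    """Map each probe to the unique gene it overlaps.

    A probe maps to a gene iff their intervals share >= ``min_overlap``
    bases on the same chromosome (and the same strand when
    ``strand_mode="strict"``).  Probes overlapping zero genes or more
    than one gene are excluded and counted.
    """
    if strand_mode not in ("strict", "ignore"):
        raise ValueError("strand_mode must be 'strict' or 'ignore'")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")

    trees: dict[tuple, IntervalTree] = {}
    for g in genes:
        key = (g.chrom, g.strand) if strand_mode == "strict" else (g.chrom,)
        trees.setdefault(key, IntervalTree())[g.start : g.end] = g

    mapping: dict[str, str] = {}
    ambiguous: list[str] = []
    unmatched: list[str] = []
    for p in probes:
        key = (p.chrom, p.strand) if strand_mode == "strict" else (p.chrom,)
        hits = set()
        for iv in trees.get(key, IntervalTree()).overlap(p.start, p.end):
            ov = min(p.end, iv.end) - max(p.start, iv.begin)
            if ov >= min_overlap:
                hits.add(iv.data.gene_id)
        if len(hits) == 1:
            mapping[p.probe_id] = hits.pop()
        elif not hits:
            unmatched.append(p.probe_id)
        else:
            ambiguous.append(p.probe_id)
    return MatchResult(
        mapping=mapping,
        n_ambiguous=len(ambiguous),
        n_unmatched=len(unmatched),
        ambiguous=tuple(sorted(ambiguous)),
        unmatched=tuple(sorted(unmatched)),
    )


def collapse_probes(
    probe_expr: pd.DataFrame, mapping: dict[str, str]
) -> pd.DataFrame:
    """Collapse a probes x samples matrix to genes by arithmetic mean.

    Every mapped probe must be present in the matrix; each gene's row
    is the per-sample mean of its probes' rows.
    """
    missing = sorted(set(mapping) - set(probe_expr.index))
    if missing:
        raise KeyError(f"mapped probes absent from matrix: {missing[:10]}")
    sub = probe_expr.loc[list(mapping)]
    gene_of = pd.Series(mapping)
    collapsed = sub.groupby(gene_of.reindex(sub.index)).mean()
    collapsed.index.name = probe_expr.index.name or "gene"
    return collapsed
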