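"""Gene-set overrepresentation analysis (ORA) for network mRNA sets.

Upper-tail hypergeometric enrichment of a query gene set against a
user-supplied GMT collection, with an explicit background universe.
Significance is flagged on the raw p-value (default alpha 0.05);
Benjamini-Hochberg q-values are reported for transparency but do not
drive the flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._hypergeom import hypergeom_upper_tail


@dataclass
class GeneSetCollection:
    """Named gene sets clipped to a background universe."""

    sets: dict[str, frozenset[str]] = field(repr=False)
    universe: frozenset[str] = field(repr=False)

    def __post_init__(self) -> None:
        if not self.universe:
            raise ValueError("universe must be non-empty")
        clipped = {}
        for name, genes in self.sets.items():
            g = frozenset(genes) & self.universe
            if not g:
                continue  # set entirely outside the background
            clipped[name] = g
        if not clipped:
            raise ValueError("no gene set overlaps the universe")
        self.sets = clipped


def read_gmt(path: str | Path) -> dict[str, frozenset[str]]:
    """Parse a GMT file (name <tab> description <tab> gene...)."""
    sets: dict[str, frozenset[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"{path}:{lineno}: GMT line needs name, description and >=1 gene"
            )
        name, genes = fields[0], frozenset(g for g in fields[2:] if g)
        if not genes:
            raise ValueError(f"{path}:{lineno}: gene set {name!r} is empty")
        sets[name] = genes
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return sets


@dataclass(frozen=True)
class EnrichmentRow:
    set_name: str
    overlap: int
    set_size: int
    query_size: int
    universe_size: int
    p_value: float


def ora_test(query, gene_set, universe) -> EnrichmentRow:
    """Upper-tail hypergeometric P(X >= overlap) for one gene set."""
    universe = frozenset(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    q = frozenset(query) & universe
    s = frozenset(gene_set) & universe
    if not q:
        warnings.warn("query is empty after clipping to the universe", stacklevel=2)
        return EnrichmentRow("", 0, len(s), 0, len(universe), 1.0)
    overlap = len(q & s)
    p = hypergeom_upper_tail(overlap, len(universe), len(s), len(q))
    return EnrichmentRow("", overlap, len(s), len(q), len(universe), p)


def enrich(
    query, collection: GeneSetCollection, alpha: float = 0.05
) -> pd.DataFrame:
    """ORA of ``query`` against every set in the collection.

    Returns one row per set sorted by ascending p (name breaks ties),
    with a raw-p significance flag at ``alpha`` and BH q-values.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    rows = []
    for name in sorted(collection.sets):
        r = ora_test(query, collection.sets[name], collection.universe)
        rows.append(
            {
                "set_name": name,
                "overlap": r.overlap,
                "set_size": r.set_size,
                "query_size": r.query_size,
                "universe_size": r.universe_size,
                "p_value": r.p_value,
            }
        )
    df = pd.DataFrame(rows)
    df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
    df["significant"] = df["p_value"] < alpha
    return df.sort_values(["p_value", "set_name"], ignore_index=True)
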