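"""Bipartite dysregulated lncRNA-mRNA network construction and degree
analysis: per-class degree summaries, top-degree hub selection with tie
inclusion, and a Wilcoxon rank-sum comparison of lncRNA vs mRNA
degrees."""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats


def build_network(pairs) -> nx.Graph:
    """Merge retained lncRNA-mRNA pairs into a bipartite graph.

    ``pairs`` is an iterable of (lncrna, mrna) tuples or a DataFrame
    with ``lncrna``/``mrna`` columns.  Nodes carry a ``gene_class``
    attribute; duplicate edges collapse.  A gene appearing on both
    sides violates bipartiteness and raises.
    """
    if isinstance(pairs, pd.DataFrame):
        edge_iter = list(zip(pairs["lncrna"], pairs["mrna"]))
    else:
        edge_iter = [(l, m) for l, m in pairs]
    lnc_side = {l for l, _ in edge_iter}
    mrna_side = {m for _, m in edge_iter}
    both = lnc_side & mrna_side
    if both:
        raise ValueError(
            f"nodes appear as both lncRNA and mRNA (not bipartite): {sorted(both)[:5]}"
        )
    g = nx.Graph()
    g.add_nodes_from(sorted(lnc_side), gene_class="lncRNA", bipartite=0)
    g.add_nodes_from(sorted(mrna_side), gene_class="mRNA", bipartite=1)
    g.add_edges_from(edge_iter)
    return g


def _class_nodes(net: nx.Graph, cls: str) -> list[str]:
    return [n for n, d in net.nodes(data=True) if d["gene_class"] == cls]


@dataclass
class DegreeSummary:
    """Per-node degrees plus per-class statistics of a bipartite network."""

    degrees: pd.Series
    class_stats: pd.DataFrame  # index mRNA/lncRNA; columns mean/min/max/n
    skewness: float
    wilcoxon_p: float

    def mean_degree(self, cls: str, ndigits: int | None = 2) -> float:
        v = float(self.class_stats.loc[cls, "mean"])
        return round(v, ndigits) if ndigits is not None else v


def degree_stats(net: nx.Graph) -> DegreeSummary:
    """Degree summary: class means (full precision, 2-dp display),
    right-skewness of the pooled degree distribution (sample skewness),
    and a two-sided Wilcoxon rank-sum p for lncRNA vs mRNA degrees."""
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    deg = pd.Series(dict(net.degree())).sort_index()
    rows = {}
    for cls in ("mRNA", "lncRNA"):
        nodes = _class_nodes(net, cls)
        d = deg.loc[nodes]
        rows[cls] = {
            "mean": float(d.mean()) if len(d) else math.nan,
            "min": int(d.min()) if len(d) else 0,
            "max": int(d.max()) if len(d) else 0,
            "n": len(d),
        }
    lnc_deg = deg.loc[_class_nodes(net, "lncRNA")].to_numpy()
    mrna_deg = deg.loc[_class_nodes(net, "mRNA")].to_numpy()
    if len(lnc_deg) and len(mrna_deg):
        p = wilcoxon_rank_sum(lnc_deg, mrna_deg)
    else:
        p = math.nan
    return DegreeSummary(
        degrees=deg,
        class_stats=pd.DataFrame(rows).T,
        skewness=float(stats.skew(deg.to_numpy(), bias=True)),
        wilcoxon_p=p,
    )


def select_hubs(net: nx.Graph, fraction: float = 0.05) -> list[str]:
    """Nodes in the top ``fraction`` of the degree ranking.

    k = ceil(fraction * node count); every node whose degree ties the
    k-th ranked degree is included.  Output ordered by (degree
    descending, id ascending).
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    ranked = sorted(net.degree(), key=lambda kv: (-kv[1], kv[0]))
    k = math.ceil(fraction * len(ranked))
    cutoff = ranked[k - 1][1]
    return [n for n, d in ranked if d >= cutoff]


def wilcoxon_rank_sum(x, y, method: str = "auto") -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    With ``method="auto"``: exact null enumeration when n_x + n_y <= 20
    and the pooled sample is tie-free; otherwise a normal approximation
    with tie correction and a continuity correction shrunk toward the
    null mean (identical samples therefore give p = 1).  ``"exact"`` /
    ``"asymptotic"`` force one path.
    """
    if method not in ("auto", "exact", "asymptotic"):
        raise ValueError("method must be auto, exact or asymptotic")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    tie_free = len(np.unique(pooled)) == len(pooled)
    use_exact = (
        method == "exact"
        or (method == "auto" and len(pooled) <= 20 and tie_free)
    )
    if use_exact:
        return float(
            stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        )
    n1, n2 = len(x), len(y)
    ranks = stats.rankdata(pooled)
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var == 0:
        return 1.0
    z = max(abs(u - mu) - 0.5, 0.0) / math.sqrt(var)
    return float(min(1.0, 2.0 * stats.norm.sf(z)))


def node_table(net: nx.Graph, hub_fraction: float = 0.05) -> pd.DataFrame:
    """Per-node table (id, class, degree, is_hub) for export."""
    deg = dict(net.degree())
    hubs = set(select_hubs(net, hub_fraction)) if net.number_of_nodes() else set()
    rows = [
        {
            "node": n,
            "gene_class": net.nodes[n]["gene_class"],
            "degree": deg[n],
            "is_hub": n in hubs,
        }
        for n in sorted(net.nodes)
    ]
    return pd.DataFrame(rows)
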