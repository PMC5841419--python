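"""ceRNA module detection on the network incidence matrix.

The bipartite network is encoded as a binary lncRNA x mRNA incidence
matrix; lncRNAs are clustered agglomeratively (city-block distance,
complete linkage -- the classic heatmap-clustering setting), the
dendrogram is cut
into k clusters, and each mRNA is assigned to the lncRNA cluster that
holds the majority of its edges.  Agglomeration uses an explicit
deterministic tie-break: among all minimum-distance cluster pairs the
lexicographically smallest (by sorted leaf indices) is merged first, so
results are reproducible and independent of input order.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist


@dataclass
class IncidenceMatrix:
    """Binary lncRNA (rows) x mRNA (cols) incidence of a bipartite net."""

    values: pd.DataFrame

    @property
    def lncrnas(self) -> pd.Index:
        return self.values.index

    @property
    def mrnas(self) -> pd.Index:
        return self.values.columns


def incidence_matrix(net: nx.Graph) -> IncidenceMatrix:
    """Deterministic (id-ascending) incidence matrix of the network."""
    lncs = sorted(n for n, d in net.nodes(data=True) if d["gene_class"] == "lncRNA")
    mrnas = sorted(n for n, d in net.nodes(data=True) if d["gene_class"] == "mRNA")
    mat = pd.DataFrame(0, index=lncs, columns=mrnas, dtype=int)
    for a, b in net.edges():
        if net.nodes[a]["gene_class"] == "lncRNA":
            mat.loc[a, b] = 1
        else:
            mat.loc[b, a] = 1
    return IncidenceMatrix(mat)


@dataclass
class Dendrogram:
    """Agglomerative merge tree over named leaves.

    ``merges`` lists (left_leaves, right_leaves, height) in merge
    order, each side given as a tuple of sorted leaf indices.
    """

    labels: tuple[str, ...]
    merges: tuple[tuple[tuple[int, ...], tuple[int, ...], float], ...]

    def cut(self, k: int) -> dict[str, int]:
        """Flat clustering with k clusters (replay first n-k merges).

        Cluster ids are 0..k-1 ordered by each cluster's smallest leaf
        index.
        """
        n = len(self.labels)
        if not 1 <= k <= n:
            raise ValueError(f"k must lie in [1, {n}]")
        clusters = [(i,) for i in range(n)]
        for left, right, _ in self.merges[: n - k]:
            clusters.remove(left)
            clusters.remove(right)
            clusters.append(tuple(sorted(left + right)))
        clusters.sort(key=lambda c: c[0])
        out: dict[str, int] = {}
        for cid, members in enumerate(clusters):
            for i in members:
                out[self.labels[i]] = cid
        return out

    def to_newick(self) -> str:
        """Newick string with merge heights as internal branch lengths."""
        n = len(self.labels)
        rep: dict[tuple[int, ...], str] = {(i,): self.labels[i] for i in range(n)}
        node = ""
        for left, right, h in self.merges:
            node = f"({rep.pop(left)},{rep.pop(right)}):{h:g}"
            rep[tuple(sorted(left + right))] = node
        if len(rep) > 1:  # unmerged leaves (k was never forced to 1)
            node = "(" + ",".join(rep.values()) + ")"
        return node + ";"


def hierarchical_cluster(
    matrix, axis: str = "rows", metric: str = "cityblock", linkage: str = "complete"
) -> Dendrogram:
    """Agglomerative clustering of matrix rows or columns.

    Only the city-block metric with complete linkage is supported (the
    module-detection setting); other choices raise.  Complete linkage
    distance between clusters is the maximum pairwise leaf distance,
    computed on the original distance matrix.
    """
    if metric != "cityblock":
        raise ValueError(f"unsupported metric: {metric}")
    if linkage != "complete":
        raise ValueError(f"unsupported linkage: {linkage}")
    if isinstance(matrix, IncidenceMatrix):
        matrix = matrix.values
    if isinstance(matrix, pd.DataFrame):
        labels = tuple(str(x) for x in (matrix.index if axis == "rows" else matrix.columns))
        x = matrix.to_numpy(dtype=float)
    else:
        x = np.asarray(matrix, dtype=float)
        labels = tuple(
            str(i) for i in range(x.shape[0] if axis == "rows" else x.shape[1])
        )
    if axis == "cols":
        x = x.T
    elif axis != "rows":
        raise ValueError("axis must be 'rows' or 'cols'")
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 vectors to cluster")

    dist = cdist(x, x, metric="cityblock")
    clusters: list[tuple[int, ...]] = [(i,) for i in range(n)]
    merges = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                ca, cb = clusters[a], clusters[b]
                d = dist[np.ix_(ca, cb)].max()  # complete linkage
                key = (d, min(ca, cb), max(ca, cb))
                if best is None or key < best:
                    best = key
                    pick = (a, b, d)
        a, b, d = pick
        ca, cb = clusters[a], clusters[b]
        left, right = (ca, cb) if ca < cb else (cb, ca)
        merges.append((left, right, float(d)))
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)]
        clusters.append(tuple(sorted(ca + cb)))
    return Dendrogram(labels=labels, merges=tuple(merges))


@dataclass
class CeRNAModule:
    """One detected module: member lncRNAs, assigned mRNAs, and the
    number of network edges internal to the module."""

    module_id: int
    lncrnas: tuple[str, ...]
    mrnas: tuple[str, ...]
    internal_edges: int


def extract_modules(
    net: nx.Graph, row_dendrogram: Dendrogram, k: int
) -> list[CeRNAModule]:
    """Cut the lncRNA dendrogram into k clusters and attach mRNAs.

    Each mRNA joins the cluster holding the majority of its edges;
    ties go to the cluster of its highest-degree lncRNA partner, then
    to the cluster of the first partner in id order.  Modules may be
    reported with zero mRNAs.
    """
    assignment = row_dendrogram.cut(k)
    deg = dict(net.degree())
    mrnas = sorted(n for n, d in net.nodes(data=True) if d["gene_class"] == "mRNA")
    mrna_cluster: dict[str, int] = {}
    for m in mrnas:
        partners = sorted(net.neighbors(m))
        votes: dict[int, int] = {}
        for p in partners:
            votes[assignment[p]] = votes.get(assignment[p], 0) + 1
        top = max(votes.values())
        tied = {c for c, v in votes.items() if v == top}
        if len(tied) == 1:
            mrna_cluster[m] = tied.pop()
        else:
            # highest-degree partner among tied clusters, then id order
            cands = [p for p in partners if assignment[p] in tied]
            cands.sort(key=lambda p: (-deg[p], p))
            mrna_cluster[m] = assignment[cands[0]]
    out = []
    for cid in range(k):
        lncs = tuple(sorted(l for l, c in assignment.items() if c == cid))
        mods = tuple(sorted(m for m, c in mrna_cluster.items() if c == cid))
        internal = sum(
            1 for l in lncs for m in net.neighbors(l) if mrna_cluster.get(m) == cid
        )
        out.append(
            CeRNAModule(module_id=cid, lncrnas=lncs, mrnas=mods, internal_edges=internal)
        )
    return out


def module_table(modules: list[CeRNAModule]) -> pd.DataFrame:
    rows = []
    for mod in modules:
        for g, cls in [(l, "lncRNA") for l in mod.lncrnas] + [
            (m, "mRNA") for m in mod.mrnas
        ]:
            rows.append({"module": mod.module_id, "gene": g, "gene_class": cls})
    return pd.DataFrame(rows, columns=["module", "gene", "gene_class"])
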