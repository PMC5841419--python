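"""Dysregulated lncRNA-mRNA competing-pair identification.

Two-step screen under the ceRNA hypothesis:

1. *Shared-miRNA significance.*  For each candidate lncRNA-mRNA pair
   the overlap of their miRNA regulator sets, within the universe of
   miRNAs common to both interaction tables ("Total"), is scored with a
   cumulative (upper-tail) hypergeometric test

       p = sum_{i=overlap}^{min(N_mRNA, N_lnc)}
           C(N_mRNA, i) C(Total - N_mRNA, N_lnc - i) / C(Total, N_lnc).

   Pairs with p < hyper_alpha (default 0.05) become candidates.

2. *Positive co-expression.*  The Pearson correlation of each candidate
   pair is computed across samples; the retention threshold is the
   95th percentile of the candidate correlation distribution (a
   data-dependent output, reported alongside the pairs), and pairs with
   PCC strictly above max(threshold, 0) are retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from ._hypergeom import hypergeom_upper_tail
from .containers import ExpressionMatrix

_cached_tail = lru_cache(maxsize=None)(hypergeom_upper_tail)


@dataclass(frozen=True)
class InteractionUniverse:
    """miRNA-target maps restricted to the shared miRNA universe.

    ``universe`` is the intersection of the miRNA sets of the
    miRNA-mRNA and miRNA-lncRNA tables; every per-gene set is clipped
    to it (genes whose clipped set is empty are retained with N = 0).
    """

    mrna_targets: dict[str, frozenset[str]] = field(repr=False)
    lnc_targets: dict[str, frozenset[str]] = field(repr=False)
    universe: frozenset[str] = field(repr=False)

    @property
    def total(self) -> int:
        return len(self.universe)


def _read_table(table: pd.DataFrame, name: str) -> pd.DataFrame:
    if table.shape[1] != 2:
        raise ValueError(f"{name} must have exactly 2 columns (miRNA, target)")
    if table.empty:
        raise ValueError(f"{name} is empty")
    t = table.copy()
    t.columns = ["mirna", "target"]
    return t.drop_duplicates()


def build_universe(
    mirna_mrna: pd.DataFrame, mirna_lncrna: pd.DataFrame
) -> InteractionUniverse:
    """Intersect the two interaction tables into a common miRNA universe."""
    mm = _read_table(mirna_mrna, "miRNA-mRNA table")
    ml = _read_table(mirna_lncrna, "miRNA-lncRNA table")
    universe = frozenset(mm["mirna"]) & frozenset(ml["mirna"])
    if not universe:
        raise ValueError(
            "the miRNA sets of the two tables are disjoint; "
            "the shared-miRNA test is undefined"
        )

    def _sets(t: pd.DataFrame) -> dict[str, frozenset[str]]:
        out: dict[str, frozenset[str]] = {}
        for target, grp in t.groupby("target", sort=True):
            out[str(target)] = frozenset(grp["mirna"]) & universe
        return out

    return InteractionUniverse(
        mrna_targets=_sets(mm), lnc_targets=_sets(ml), universe=universe
    )


def shared_mirna_test(
    mrna_id: str, lncrna_id: str, u: InteractionUniverse
) -> tuple[int, float]:
    """Overlap count and cumulative hypergeometric p for one pair."""
    try:
        m_set = u.mrna_targets[mrna_id]
        l_set = u.lnc_targets[lncrna_id]
    except KeyError as exc:
        raise KeyError(f"gene absent from interaction universe: {exc}") from exc
    overlap = len(m_set & l_set)
    p = _cached_tail(overlap, u.total, len(m_set), len(l_set))
    return overlap, p


def pearson_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation of two equal-length sample vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    xc = x - x.mean()
    yc = y - y.mean()
    return float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))


@dataclass
class PairScreenResult:
    """Outcome of the two-step competing-pair screen.

    ``table`` has one row per candidate pair (lncrna, mrna, overlap,
    hyper_p, pcc, retained); ``pcc_threshold`` is the realized
    percentile threshold (None when there were no candidates).
    """

    table: pd.DataFrame
    pcc_threshold: float | None
    n_candidates: int
    n_retained: int

    @property
    def retained(self) -> pd.DataFrame:
        return self.table[self.table["retained"]]


def _row_correlations(
    expr: ExpressionMatrix, lnc: np.ndarray, mrna: np.ndarray
) -> np.ndarray:
    """PCC for parallel arrays of lncRNA/mRNA ids (vectorized)."""
    genes = pd.Index(np.unique(np.concatenate([lnc, mrna])))
    x = expr.values.loc[genes].to_numpy(dtype=float)
    x = x - x.mean(axis=1, keepdims=True)
    norm = np.sqrt((x**2).sum(axis=1))
    if (norm == 0).any():
        bad = genes[norm == 0]
        raise ValueError(f"constant expression rows: {list(bad)[:5]}")
    x = x / norm[:, None]
    pos = {g: i for i, g in enumerate(genes)}
    li = np.array([pos[g] for g in lnc])
    mi = np.array([pos[g] for g in mrna])
    return np.einsum("ij,ij->i", x[li], x[mi])


def identify_competing_pairs(
    sde_mrnas,
    sde_lncrnas,
    u: InteractionUniverse,
    expr: ExpressionMatrix,
    hyper_alpha: float = 0.05,
    pcc_percentile: float = 95.0,
    pcc_population: str = "candidates",
) -> PairScreenResult:
    """Score all SDE lncRNA x SDE mRNA pairs and retain competing ones.

    ``pcc_population`` selects the distribution whose percentile sets
    the retention threshold: ``"candidates"`` (default) uses the
    step-1 survivors, ``"all"`` uses every SDE lncRNA x mRNA pair.
    Percentiles use linear interpolation between order statistics.
    """
    if not 0 < hyper_alpha < 1:
        raise ValueError("hyper_alpha must lie in (0, 1)")
    if not 0 < pcc_percentile <= 100:
        raise ValueError("pcc_percentile must lie in (0, 100]")
    if pcc_population not in ("candidates", "all"):
        raise ValueError("pcc_population must be 'candidates' or 'all'")
    mrnas = sorted(set(sde_mrnas) & set(u.mrna_targets) & set(expr.genes))
    lncs = sorted(set(sde_lncrnas) & set(u.lnc_targets) & set(expr.genes))
    if not mrnas or not lncs:
        raise ValueError("no SDE genes present in both universe and matrix")

    mirna_order = {m: i for i, m in enumerate(sorted(u.universe))}
    total = u.total

    def _member_matrix(genes, sets):
        mat = np.zeros((len(genes), total), dtype=np.int32)
        for i, g in enumerate(genes):
            idx = [mirna_order[m] for m in sets[g]]
            mat[i, idx] = 1
        return mat

    l_mat = _member_matrix(lncs, u.lnc_targets)
    m_mat = _member_matrix(mrnas, u.mrna_targets)
    overlap = l_mat @ m_mat.T  # n_lnc x n_mrna
    l_sizes = l_mat.sum(axis=1)
    m_sizes = m_mat.sum(axis=1)

    li, mi = np.meshgrid(np.arange(len(lncs)), np.arange(len(mrnas)), indexing="ij")
    li, mi = li.ravel(), mi.ravel()
    pvals = np.array(
        [
            _cached_tail(int(overlap[a, b]), total, int(m_sizes[b]), int(l_sizes[a]))
            for a, b in zip(li, mi)
        ]
    )
    cand = pvals < hyper_alpha
    n_candidates = int(cand.sum())
    if n_candidates == 0:
        warnings.warn("no pair passed the shared-miRNA screen", stacklevel=2)
        empty = pd.DataFrame(
            columns=["lncrna", "mrna", "overlap", "hyper_p", "pcc", "retained"]
        )
        return PairScreenResult(empty, None, 0, 0)

    lnc_arr = np.array(lncs)
    mrna_arr = np.array(mrnas)
    cl, cm = lnc_arr[li[cand]], mrna_arr[mi[cand]]
    pcc = _row_correlations(expr, cl, cm)
    if pcc_population == "candidates":
        population = pcc
    else:
        population = _row_correlations(expr, lnc_arr[li], mrna_arr[mi])
    threshold = float(np.percentile(population, pcc_percentile))
    retained = pcc > max(threshold, 0.0)

    table = pd.DataFrame(
        {
            "lncrna": cl,
            "mrna": cm,
            "overlap": overlap[li[cand], mi[cand]],
            "hyper_p": pvals[cand],
            "pcc": pcc,
            "retained": retained,
        }
    ).sort_values(["lncrna", "mrna"], ignore_index=True)
    return PairScreenResult(table, threshold, n_candidates, int(retained.sum()))


def expected_null_candidate_rate(
    u: InteractionUniverse, alpha: float = 0.05
) -> float:
    """Exact null rate of the step-1 screen given the realized set sizes.

    For independent random sets the probability that a pair's
    cumulative hypergeometric p falls below ``alpha`` equals the tail
    mass at the smallest overlap whose p is below ``alpha`` -- the
    achievable size of the discrete test, which is at most ``alpha``.
    Averaged over all lncRNA x mRNA size combinations of ``u``.
    """
    total = u.total

    @lru_cache(maxsize=None)
    def _rate(n_m: int, n_l: int) -> float:
        for k in range(min(n_m, n_l) + 1):
            p = _cached_tail(k, total, n_m, n_l)
            if p < alpha:
                return p
        return 0.0

    m_sizes = [len(s) for s in u.mrna_targets.values()]
    l_sizes = [len(s) for s in u.lnc_targets.values()]
    acc = 0.0
    for nl in l_sizes:
        for nm in m_sizes:
            acc += _rate(nm, nl)
    return acc / (len(m_sizes) * len(l_sizes))
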