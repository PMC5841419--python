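"""Empirical-Bayes moderated t-test for two-group differential expression.

Per-gene residual variances from a two-group design are shrunk toward a
common prior by modelling s_g^2 | sigma_g^2 ~ sigma_g^2 * chi^2_dg / dg
with a scaled inverse-chi-square prior (d0, s0^2) on sigma_g^2.  The
hyperparameters are estimated by moment matching on log s_g^2 using
digamma/trigamma identities; the moderated statistic

    t_g = mean_diff_g / (s_tilde_g * sqrt(1/n0 + 1/n1)),
    s_tilde_g^2 = (d0 * s0^2 + dg * s_g^2) / (d0 + dg)

is referred to a t distribution on d0 + dg degrees of freedom (standard
normal when d0 is infinite).  d0 = 0 degenerates to the ordinary pooled
two-sample t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, check_labels

_VAR_FLOOR = 1e-12


@dataclass(frozen=True)
class EBayesFit:
    """Hyperparameters of the variance prior.

    d0 : prior degrees of freedom (``np.inf`` when the observed
        variances show no excess dispersion beyond chi-square sampling).
    s0_sq : prior variance.
    dg : residual degrees of freedom per gene (n0 + n1 - 2).
    """

    d0: float
    s0_sq: float
    dg: int

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise ValueError("d0 must be non-negative")
        if self.s0_sq <= 0:
            raise ValueError("s0_sq must be positive")


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def _group_split(expr: ExpressionMatrix, labels: pd.Series):
    labels = check_labels(labels, expr.samples)
    x = expr.values.to_numpy(dtype=float)
    g0 = x[:, (labels == 0).to_numpy()]
    g1 = x[:, (labels == 1).to_numpy()]
    if g0.shape[1] < 2 or g1.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples")
    return g0, g1


def residual_variances(expr: ExpressionMatrix, labels: pd.Series):
    """Pooled per-gene residual variances s_g^2 with dg = n0 + n1 - 2."""
    g0, g1 = _group_split(expr, labels)
    n0, n1 = g0.shape[1], g1.shape[1]
    dg = n0 + n1 - 2
    ss = g0.var(axis=1, ddof=1) * (n0 - 1) + g1.var(axis=1, ddof=1) * (n1 - 1)
    s_g_sq = np.maximum(ss / dg, _VAR_FLOOR)
    return s_g_sq, n0, n1, dg


def fit_ebayes(expr: ExpressionMatrix, labels: pd.Series) -> EBayesFit:
    """Estimate (d0, s0^2) by moment matching on log s_g^2.

    Writes e_g = log s_g^2 - digamma(dg/2) + log(dg/2); under the model
    mean(e) = log s0^2 + digamma(d0/2) - log(d0/2) and the variance of
    e in excess of trigamma(dg/2) estimates trigamma(d0/2).  A
    non-positive excess yields d0 = infinity with s0^2 the
    geometric-mean-based pooled variance exp(mean(e)).
    """
    s_g_sq, _, _, dg = residual_variances(expr, labels)
    z = np.log(s_g_sq)
    e = z - special.digamma(dg / 2.0) + np.log(dg / 2.0)
    e_mean = float(e.mean())
    n_genes = len(e)
    if n_genes < 2:
        raise ValueError("need at least 2 genes to estimate the prior")
    excess = float(
        np.mean((e - e_mean) ** 2) * n_genes / (n_genes - 1)
        - special.polygamma(1, dg / 2.0)
    )
    if excess <= 0:
        # no excess dispersion: geometric-mean pooled variance
        return EBayesFit(d0=np.inf, s0_sq=float(np.exp(z.mean())), dg=dg)
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = float(
        np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    )
    return EBayesFit(d0=d0, s0_sq=s0_sq, dg=dg)


def moderated_t_test(
    expr: ExpressionMatrix, labels: pd.Series, fit: EBayesFit
) -> pd.DataFrame:
    """Per-gene moderated t statistics and two-sided p-values.

    Returns a DataFrame indexed by gene with columns gene_class,
    mean_diff (group1 - group0), s_g_sq, t_mod, df_total, p_value,
    q_value (Benjamini-Hochberg, reported for transparency only) and
    direction (up iff mean_diff > 0).
    """
    s_g_sq, n0, n1, dg = residual_variances(expr, labels)
    if dg != fit.dg:
        raise ValueError("fit was computed on a design with different df")
    g0, g1 = _group_split(expr, labels)
    mean_diff = g1.mean(axis=1) - g0.mean(axis=1)
    if np.isinf(fit.d0):
        s_tilde_sq = np.full_like(s_g_sq, fit.s0_sq)
        df_total = np.inf
    else:
        s_tilde_sq = (fit.d0 * fit.s0_sq + dg * s_g_sq) / (fit.d0 + dg)
        df_total = fit.d0 + dg
    se = np.sqrt(s_tilde_sq * (1.0 / n0 + 1.0 / n1))
    t_mod = mean_diff / se
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    p = np.minimum(p, 1.0)
    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "gene_class": expr.gene_class,
            "mean_diff": mean_diff,
            "s_g_sq": s_g_sq,
            "t_mod": t_mod,
            "df_total": df_total,
            "p_value": p,
            "q_value": q,
            "direction": np.where(mean_diff > 0, "up", "down"),
        },
        index=expr.genes,
    )


def select_sde(
    results: pd.DataFrame, p_threshold: float
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Significantly differentially expressed genes at a raw-p cutoff.

    Returns the filtered table (p_value < threshold, strict) and
    up/down counts.  Selection deliberately uses raw p-values; the BH
    q-values in the table are informational.
    """
    if results.empty:
        raise ValueError("empty result table")
    if not 0.0 < p_threshold < 1.0:
        raise ValueError("p_threshold must lie strictly inside (0, 1)")
    sde = results[results["p_value"] < p_threshold]
    counts = {
        "n_sde": int(len(sde)),
        "n_up": int((sde["direction"] == "up").sum()),
        "n_down": int((sde["direction"] == "down").sum()),
    }
    return sde, counts


def run_de(
    expr: ExpressionMatrix, labels: pd.Series, p_threshold: float = 0.01
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Fit, test and select in one step; returns (table, sde, summary)."""
    fit = fit_ebayes(expr, labels)
    table = moderated_t_test(expr, labels, fit)
    sde, counts = select_sde(table, p_threshold)
    summary = {
        "d0": fit.d0,
        "s0_sq": fit.s0_sq,
        "p_threshold": p_threshold,
        **counts,
    }
    for cls in ("mRNA", "lncRNA"):
        sub = sde[sde["gene_class"] == cls]
        summary[f"n_sde_{cls}"] = int(len(sub))
    return table, sde, summary
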