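"""Scored experiments on synthetic data with known ground truth.

Two experiment families quantify how well the pipeline behaves under
the generator's study conditions:

* :func:`planted_recovery` runs differential expression, the
  competing-pair screen, network construction and module detection on
  one planted dataset and scores pair recovery, the false-pair
  fraction of the retained set, and module-assignment purity against
  the planted blocks.
* :func:`null_calibration` measures type-I behaviour with nothing
  planted: the step-1 pair-discovery rate at alpha (compared with the
  exact achievable size of the discrete hypergeometric test, which is
  at most alpha) and the false-positive rate of the moderated t-test.
"""

from __future__ import annotations

import numpy as np

from .cerna_pairs import (
    build_universe,
    expected_null_candidate_rate,
    identify_competing_pairs,
    shared_mirna_test,
)
from .diffexpr import run_de
from .modules import extract_modules, hierarchical_cluster, incidence_matrix
from .network import build_network
from .synthetic_data import SyntheticConfig, generate_dataset, null_config


def planted_recovery(cfg: SyntheticConfig, de_p: float = 0.01) -> dict:
    """Run the pipeline through modules on one planted dataset.

    Returns recovery (fraction of planted pairs among the network
    edges), false_fraction (non-planted fraction of retained pairs),
    module_purity (fraction of planted nodes in the network whose
    detected module's dominant block matches their own), and stage
    counts.
    """
    if not cfg.n_planted_pairs:
        raise ValueError("config plants nothing; use null_calibration instead")
    mm, ml, truth, expr, labels = generate_dataset(cfg)
    _, sde, _ = run_de(expr, labels, de_p)
    u = build_universe(mm, ml)
    screen = identify_competing_pairs(
        sde[sde["gene_class"] == "mRNA"].index,
        sde[sde["gene_class"] == "lncRNA"].index,
        u,
        expr,
    )
    planted = {(l, m) for l, m, _ in truth.pairs}
    net = build_network(screen.retained)
    edges = {
        (a, b) if net.nodes[a]["gene_class"] == "lncRNA" else (b, a)
        for a, b in net.edges()
    }
    recovery = len(planted & edges) / len(planted)
    false_fraction = len(edges - planted) / len(edges) if edges else 0.0

    module_purity = float("nan")
    n_lnc = sum(1 for _, d in net.nodes(data=True) if d["gene_class"] == "lncRNA")
    k = cfg.n_blocks
    if n_lnc >= k:
        dendro = hierarchical_cluster(incidence_matrix(net), axis="rows")
        mods = extract_modules(net, dendro, k)
        member_of: dict[str, int] = {}
        for mod in mods:
            for g in mod.lncrnas + mod.mrnas:
                member_of[g] = mod.module_id
        dominant: dict[int, int] = {}
        for mod in mods:
            blocks = [
                truth.blocks[g]
                for g in mod.lncrnas + mod.mrnas
                if g in truth.blocks
            ]
            if blocks:
                vals, counts = np.unique(blocks, return_counts=True)
                dominant[mod.module_id] = int(vals[np.argmax(counts)])
        scored = [
            g for g in truth.blocks if g in member_of and member_of[g] in dominant
        ]
        if scored:
            module_purity = float(
                np.mean(
                    [dominant[member_of[g]] == truth.blocks[g] for g in scored]
                )
            )
    return {
        "recovery": recovery,
        "false_fraction": false_fraction,
        "module_purity": module_purity,
        "n_candidates": screen.n_candidates,
        "n_retained": screen.n_retained,
        "pcc_threshold": screen.pcc_threshold,
        "n_nodes": net.number_of_nodes(),
        "n_edges": net.number_of_edges(),
    }


def pair_discovery_rate(u, alpha: float = 0.05) -> float:
    """Fraction of all lncRNA x mRNA pairs whose shared-miRNA p < alpha."""
    hits = 0
    n = 0
    for lnc in u.lnc_targets:
        for mrna in u.mrna_targets:
            _, p = shared_mirna_test(mrna, lnc, u)
            hits += p < alpha
            n += 1
    return hits / n


def null_calibration(
    n_seeds: int = 50, base_seed: int = 0, alpha: float = 0.05, **cfg_overrides
) -> dict:
    """Type-I calibration across seeds under the no-signal generator.

    Reports the Monte-Carlo step-1 discovery rate, its exact analytic
    expectation given the realized set sizes (the achievable size of
    the discrete test), the standard error of the Monte-Carlo
    estimate, and the moderated-t false-positive rate at ``alpha``.
    """
    disc = []
    expected = []
    de_fp = []
    n_pairs_total = 0
    for s in range(n_seeds):
        cfg = null_config(seed=base_seed + s, **cfg_overrides)
        mm, ml, truth, expr, labels = generate_dataset(cfg)
        u = build_universe(mm, ml)
        disc.append(pair_discovery_rate(u, alpha))
        expected.append(expected_null_candidate_rate(u, alpha))
        n_pairs_total += len(u.lnc_targets) * len(u.mrna_targets)
        table, _, _ = run_de(expr, labels, alpha)
        de_fp.append(float((table["p_value"] < alpha).mean()))
    disc_rate = float(np.mean(disc))
    exp_rate = float(np.mean(expected))
    # binomial SE treating every pair test as one draw
    se = float(np.sqrt(exp_rate * (1 - exp_rate) / n_pairs_total))
    return {
        "discovery_rate": disc_rate,
        "expected_rate": exp_rate,
        "se": se,
        "de_fp_rate": float(np.mean(de_fp)),
        "de_fp_se": float(np.std(de_fp, ddof=1) / np.sqrt(n_seeds)),
        "n_seeds": n_seeds,
        "alpha": alpha,
    }
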