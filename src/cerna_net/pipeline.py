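"""End-to-end orchestration of the ceRNA network analysis.

One configuration drives the whole chain

    differential expression -> competing pairs -> network -> modules
    -> enrichment (optional) -> biomarker panel

for either an occurrence-style contrast (default p < 0.01) or a
recurrence-style contrast (p < 0.05, typically with a small imbalanced
group); the two differ only in thresholds and labels.  Every stage
writes its outputs under the output directory and the run manifest
records thresholds, seeds, input checksums and stage summaries.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import yaml

from . import biomarkers as bm
from . import cerna_pairs, diffexpr, enrichment, io, modules, network

log = logging.getLogger("cerna_net")

__version__ = "0.1.0"

_IMBALANCE_WARN = 10  # smallest group size below which LOOCV accuracy
# concentrates near the majority-class rate under the null


@dataclass
class PipelineConfig:
    """Paths, thresholds and seed for one pipeline run."""

    expression: str
    labels: str
    gene_classes: str
    mirna_mrna: str
    mirna_lncrna: str
    out_dir: str
    gmt: str | None = None
    de_p: float = 0.01
    hyper_alpha: float = 0.05
    pcc_percentile: float = 95.0
    pcc_population: str = "candidates"
    hub_fraction: float = 0.05
    module_k: int = 3
    target_k: int = 7
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def validate(self) -> None:
        for name, lo, hi in (
            ("de_p", 0.0, 1.0),
            ("hyper_alpha", 0.0, 1.0),
            ("hub_fraction", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not lo < v <= hi if name == "hub_fraction" else not lo < v < hi:
                raise ValueError(f"{name}={v} outside ({lo}, {hi})")
        if not 0 < self.pcc_percentile <= 100:
            raise ValueError("pcc_percentile outside (0, 100]")
        if self.module_k < 1 or self.target_k < 1:
            raise ValueError("module_k and target_k must be >= 1")
        for name in ("expression", "labels", "gene_classes", "mirna_mrna", "mirna_lncrna"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")
        if self.gmt is not None and not Path(self.gmt).exists():
            raise FileNotFoundError(f"gmt file not found: {self.gmt}")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest.

    A stage failure aborts the run with the stage name; the partial
    manifest written so far is left in the output directory.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": dataclasses.asdict(cfg),
        "inputs": {
            name: _sha256(getattr(cfg, name))
            for name in (
                "expression",
                "labels",
                "gene_classes",
                "mirna_mrna",
                "mirna_lncrna",
            )
        },
        "stages": {},
    }
    manifest_path = out / "manifest.json"

    def _write_manifest() -> None:
        manifest_path.write_text(json.dumps(manifest, indent=1, default=str))

    stage = "load"
    try:
        expr, labels = io.load_matrix_with_labels(
            cfg.expression, cfg.labels, cfg.gene_classes
        )
        n0 = int((labels == 0).sum())
        n1 = int((labels == 1).sum())
        manifest["stages"]["load"] = {
            "n_genes": int(len(expr.genes)),
            "n_samples": int(len(expr.samples)),
            "n_group0": n0,
            "n_group1": n1,
            "imbalance_caveat": min(n0, n1) < _IMBALANCE_WARN,
        }
        if min(n0, n1) < _IMBALANCE_WARN:
            log.warning(
                "smallest group has %d samples; null LOOCV accuracy "
                "concentrates near the majority-class rate %.3f",
                min(n0, n1),
                max(n0, n1) / (n0 + n1),
            )

        stage = "diffexpr"
        de_table, sde, de_summary = diffexpr.run_de(expr, labels, cfg.de_p)
        io.write_tsv(
            de_table.rename_axis("gene"), out / "de_table.tsv", index=True,
            de_p=cfg.de_p,
        )
        manifest["stages"]["diffexpr"] = de_summary
        log.info("diffexpr: %s", de_summary)

        stage = "cerna_pairs"
        mm = io.read_interactions(cfg.mirna_mrna)
        ml = io.read_interactions(cfg.mirna_lncrna)
        universe = cerna_pairs.build_universe(mm, ml)
        sde_m = sde[sde["gene_class"] == "mRNA"].index
        sde_l = sde[sde["gene_class"] == "lncRNA"].index
        screen = cerna_pairs.identify_competing_pairs(
            sde_m,
            sde_l,
            universe,
            expr,
            hyper_alpha=cfg.hyper_alpha,
            pcc_percentile=cfg.pcc_percentile,
            pcc_population=cfg.pcc_population,
        )
        io.write_tsv(
            screen.table, out / "pairs.tsv",
            hyper_alpha=cfg.hyper_alpha, pcc_percentile=cfg.pcc_percentile,
        )
        pair_summary = {
            "total_mirnas": universe.total,
            "n_candidates": screen.n_candidates,
            "n_retained": screen.n_retained,
            "pcc_threshold": screen.pcc_threshold,
        }
        (out / "pairs_summary.json").write_text(json.dumps(pair_summary, indent=1))
        manifest["stages"]["cerna_pairs"] = pair_summary
        log.info("cerna_pairs: %s", pair_summary)

        stage = "network"
        net = network.build_network(screen.retained)
        nodes = network.node_table(net, cfg.hub_fraction) if net.number_of_nodes() else None
        if net.number_of_nodes():
            summary = network.degree_stats(net)
            hubs = network.select_hubs(net, cfg.hub_fraction)
            io.write_tsv(screen.retained[["lncrna", "mrna"]], out / "network_edges.tsv")
            io.write_tsv(nodes, out / "network_nodes.tsv", hub_fraction=cfg.hub_fraction)
            nx.write_graphml(net, out / "network.graphml")
            net_summary = {
                "n_nodes": net.number_of_nodes(),
                "n_edges": net.number_of_edges(),
                "mean_degree_mrna": summary.mean_degree("mRNA"),
                "mean_degree_lncrna": summary.mean_degree("lncRNA"),
                "degree_skewness": summary.skewness,
                "wilcoxon_p": summary.wilcoxon_p,
                "hubs": hubs,
            }
            (out / "degree_summary.json").write_text(
                json.dumps(net_summary, indent=1)
            )
        else:
            net_summary = {"n_nodes": 0, "n_edges": 0}
        manifest["stages"]["network"] = net_summary
        log.info("network: %d nodes / %d edges", net_summary["n_nodes"], net_summary["n_edges"])

        stage = "modules"
        n_lnc = sum(
            1 for _, d in net.nodes(data=True) if d["gene_class"] == "lncRNA"
        )
        if n_lnc >= 2:
            k = min(cfg.module_k, n_lnc)
            inc = modules.incidence_matrix(net)
            dendro = modules.hierarchical_cluster(inc, axis="rows")
            mods = modules.extract_modules(net, dendro, k)
            io.write_tsv(modules.module_table(mods), out / "modules.tsv", k=k)
            (out / "dendrogram.newick").write_text(dendro.to_newick())
            manifest["stages"]["modules"] = {
                "k": k,
                "sizes": [len(m.lncrnas) + len(m.mrnas) for m in mods],
                "internal_edges": [m.internal_edges for m in mods],
            }
        else:
            manifest["stages"]["modules"] = {"skipped": "fewer than 2 network lncRNAs"}

        stage = "enrichment"
        if cfg.gmt is not None:
            sets = enrichment.read_gmt(cfg.gmt)
            background = frozenset(expr.of_class("mRNA").index)
            coll = enrichment.GeneSetCollection(sets, background)
            query = [
                n for n, d in net.nodes(data=True) if d["gene_class"] == "mRNA"
            ]
            table = enrichment.enrich(query, coll, alpha=0.05)
            io.write_tsv(table, out / "enrichment.tsv", gmt=cfg.gmt)
            manifest["stages"]["enrichment"] = {
                "n_sets": len(coll.sets),
                "n_significant": int(table["significant"].sum()),
            }
        else:
            manifest["stages"]["enrichment"] = {"skipped": "no GMT supplied"}

        stage = "biomarkers"
        net_lncs = sorted(
            n for n, d in net.nodes(data=True) if d["gene_class"] == "lncRNA"
        )
        if len(net_lncs) >= 2:
            x = expr.values.loc[net_lncs]
            best, ranked, trace = bm.select_optimal_panel(
                x, labels, cfg.target_k, cfg.seed
            )
            io.write_tsv(ranked, out / "biomarker_ranked.tsv", target_k=cfg.target_k)
            io.write_tsv(
                best.scores.rename("score").rename_axis("sample").reset_index(),
                out / "sample_scores.tsv",
            )
            io.write_tsv(bm.roc_points(best.scores, labels), out / "roc_points.tsv")
            panel = {
                "features": list(best.features),
                "accuracy": best.accuracy,
                "auc": best.auc,
                "confusion": best.confusion,
                "degenerate_folds": best.degenerate_folds,
                "rf_retained": list(trace.retained),
                "n_subsets": len(ranked),
            }
            (out / "best_panel.json").write_text(json.dumps(panel, indent=1))
            manifest["stages"]["biomarkers"] = panel
            log.info("biomarkers: %s acc=%.3f auc=%.3f", best.features, best.accuracy, best.auc)
        else:
            manifest["stages"]["biomarkers"] = {
                "skipped": "fewer than 2 network lncRNAs"
            }
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        _write_manifest()
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    _write_manifest()
    return manifest
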