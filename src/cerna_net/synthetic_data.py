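"""Synthetic ceRNA benchmark data with planted ground truth.

Emulates the inputs of a two-group lncRNA-mRNA competing-endogenous-RNA
study: miRNA-target interaction tables for mRNAs and lncRNAs, and a
log2-scale expression matrix with differential effects.  A configurable
number of lncRNA-mRNA pairs is *planted*: the two genes of a true pair
share exactly ``shared_k`` miRNA regulators by construction and are
co-expressed through a shared latent factor with target correlation
``rho``.  Planted pairs are organised in blocks (one latent factor and
one shared miRNA core per block), which defines ground-truth ceRNA
modules for the clustering stage.

Every downstream stage of the pipeline can therefore be scored against
known truth: pair recovery, false-pair rate, module assignment, and
null calibration when nothing is planted.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    Defaults describe a two-group design of 25 vs 25 samples with a
    200-miRNA universe, miRNA sets of mean size 15, and 36 planted
    pairs in 3 blocks (2 lncRNAs x 6 mRNAs per block) whose members
    share exactly 10 miRNAs and are co-expressed at rho = 0.9 on top
    of a 2 log2-unit differential effect.  Differentially expressed
    gene counts are chosen so that planted pairs make up roughly 5% of
    the candidate pairs surviving the shared-miRNA screen, mirroring
    the top-5% co-expression retention rule they must pass.
    """

    n_mirna: int = 200
    n_mrna: int = 1600
    n_lncrna: int = 40
    per_gene_targets: float = 15.0
    n_planted_pairs: int = 36
    shared_k: int = 10
    n_blocks: int = 3
    lnc_per_block: int = 2
    n_de_mrna: int = 1185
    n_de_lncrna: int = 24
    n_group0: int = 25
    n_group1: int = 25
    effect_size: float = 2.0
    rho: float = 0.9
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_mirna", "n_mrna", "n_lncrna", "n_group0", "n_group1"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")
        if self.per_gene_targets <= 0:
            raise ValueError("per_gene_targets must be positive")
        if self.shared_k > self.n_mirna:
            raise ValueError("shared_k cannot exceed the miRNA universe size")
        if self.shared_k > self.planted_set_size:
            raise ValueError("shared_k cannot exceed the per-gene miRNA set size")
        if self.n_de_mrna > self.n_mrna or self.n_de_lncrna > self.n_lncrna:
            raise ValueError("differential gene counts exceed gene counts")
        if self.n_planted_pairs < 0 or self.shared_k < 0:
            raise ValueError("counts must be non-negative")
        if self.n_planted_pairs:
            if self.n_planted_pairs % self.n_blocks:
                raise ValueError("n_planted_pairs must divide evenly into n_blocks")
            if (self.n_planted_pairs // self.n_blocks) % self.lnc_per_block:
                raise ValueError(
                    "pairs per block must divide evenly by lnc_per_block"
                )
            if self.n_blocks * self.shared_k > self.n_mirna:
                raise ValueError("disjoint miRNA cores exhaust the universe")
            if self.n_planted_lnc > min(self.n_lncrna, self.n_de_lncrna):
                raise ValueError("planted lncRNAs exceed available (DE) lncRNAs")
            if self.n_planted_mrna > min(self.n_mrna, self.n_de_mrna):
                raise ValueError("planted mRNAs exceed available (DE) mRNAs")

    @property
    def planted_set_size(self) -> int:
        """miRNA-set size used for planted genes (rounded mean size)."""
        return int(round(self.per_gene_targets))

    @property
    def n_planted_lnc(self) -> int:
        return self.n_blocks * self.lnc_per_block if self.n_planted_pairs else 0

    @property
    def n_planted_mrna(self) -> int:
        if not self.n_planted_pairs:
            return 0
        return self.n_planted_pairs // self.lnc_per_block

    @property
    def n_samples(self) -> int:
        return self.n_group0 + self.n_group1

    def mirna_ids(self) -> list[str]:
        return [f"miR-{i + 1:04d}" for i in range(self.n_mirna)]

    def mrna_ids(self) -> list[str]:
        return [f"MRNA-{i + 1:05d}" for i in range(self.n_mrna)]

    def lncrna_ids(self) -> list[str]:
        return [f"LNC-{i + 1:04d}" for i in range(self.n_lncrna)]

    def sample_ids(self) -> list[str]:
        return [f"S{i + 1:04d}" for i in range(self.n_samples)]


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth emitted alongside a synthetic dataset.

    ``pairs`` holds (lncRNA, mRNA, shared miRNA ids) for every planted
    pair; ``de_genes`` the signed differential genes as (gene, sign);
    ``blocks`` maps each planted gene to its block index (the planted
    module label).
    """

    pairs: tuple[tuple[str, str, tuple[str, ...]], ...]
    de_genes: tuple[tuple[str, int], ...]
    blocks: dict[str, int]

    def to_json(self) -> str:
        return json.dumps(
            {
                "pairs": [list(p[:2]) + [list(p[2])] for p in self.pairs],
                "de_genes": [list(g) for g in self.de_genes],
                "blocks": self.blocks,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "PlantedTruth":
        d = json.loads(text)
        return cls(
            pairs=tuple((p[0], p[1], tuple(p[2])) for p in d["pairs"]),
            de_genes=tuple((g, int(s)) for g, s in d["de_genes"]),
            blocks={k: int(v) for k, v in d["blocks"].items()},
        )


def _truncated_poisson_sizes(
    rng: np.random.Generator, mean: float, n: int, upper: int
) -> np.ndarray:
    """Per-gene miRNA-set sizes: Poisson(mean) clipped to [1, upper]."""
    return np.clip(rng.poisson(mean, size=n), 1, upper)


def generate_interactions(
    cfg: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, PlantedTruth]:
    """Draw miRNA-mRNA and miRNA-lncRNA interaction tables.

    Planted blocks receive disjoint miRNA "cores" of size ``shared_k``;
    within a block, every lncRNA's and every mRNA's miRNA set contains
    the block core, the remaining miRNAs of a planted mRNA are drawn
    outside the union of its block lncRNAs' sets, so each planted pair
    overlaps in exactly ``shared_k`` miRNAs.  All other genes draw
    uniform random sets of Poisson-distributed size (mean
    ``per_gene_targets``).

    Returns two 2-column tables (miRNA id, target id) and the
    :class:`PlantedTruth`.
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 11])
    mirnas = np.array(cfg.mirna_ids())
    mrnas = cfg.mrna_ids()
    lncs = cfg.lncrna_ids()
    all_idx = np.arange(cfg.n_mirna)
    m_size = cfg.planted_set_size

    sets: dict[str, np.ndarray] = {}
    pairs: list[tuple[str, str, tuple[str, ...]]] = []
    blocks: dict[str, int] = {}
    de: list[tuple[str, int]] = []

    planted_lncs: list[str] = []
    planted_mrnas: list[str] = []
    if cfg.n_planted_pairs:
        lnc_pick = rng.choice(cfg.n_lncrna, size=cfg.n_planted_lnc, replace=False)
        mrna_pick = rng.choice(cfg.n_mrna, size=cfg.n_planted_mrna, replace=False)
        planted_lncs = [lncs[i] for i in lnc_pick]
        planted_mrnas = [mrnas[i] for i in mrna_pick]
        core_pool = rng.permutation(all_idx)
        mrna_per_block = cfg.n_planted_mrna // cfg.n_blocks
        for b in range(cfg.n_blocks):
            core = core_pool[b * cfg.shared_k : (b + 1) * cfg.shared_k]
            b_lncs = planted_lncs[b * cfg.lnc_per_block : (b + 1) * cfg.lnc_per_block]
            b_mrnas = planted_mrnas[b * mrna_per_block : (b + 1) * mrna_per_block]
            sign = int(rng.choice([-1, 1]))
            lnc_union = set(core.tolist())
            for lnc in b_lncs:
                pool = np.setdiff1d(all_idx, core)
                fill = rng.choice(pool, size=m_size - cfg.shared_k, replace=False)
                sets[lnc] = np.concatenate([core, fill])
                lnc_union.update(fill.tolist())
                blocks[lnc] = b
                de.append((lnc, sign))
            pool = np.setdiff1d(all_idx, np.array(sorted(lnc_union)))
            if len(pool) < m_size - cfg.shared_k:
                raise ValueError("miRNA universe too small for disjoint fills")
            core_set = tuple(sorted(mirnas[core].tolist()))
            for mr in b_mrnas:
                fill = rng.choice(pool, size=m_size - cfg.shared_k, replace=False)
                sets[mr] = np.concatenate([core, fill])
                blocks[mr] = b
                de.append((mr, sign))
                for lnc in b_lncs:
                    pairs.append((lnc, mr, core_set))

    # background genes: random sets of Poisson-distributed size
    rest_mrnas = [g for g in mrnas if g not in sets]
    rest_lncs = [g for g in lncs if g not in sets]
    for group in (rest_mrnas, rest_lncs):
        sizes = _truncated_poisson_sizes(
            rng, cfg.per_gene_targets, len(group), cfg.n_mirna
        )
        for g, size in zip(group, sizes):
            sets[g] = rng.choice(all_idx, size=size, replace=False)

    # remaining differential genes drawn outside the planted ones
    n_extra_m = cfg.n_de_mrna - cfg.n_planted_mrna
    n_extra_l = cfg.n_de_lncrna - cfg.n_planted_lnc
    for group, n_extra in ((rest_mrnas, n_extra_m), (rest_lncs, n_extra_l)):
        picked = rng.choice(len(group), size=n_extra, replace=False)
        signs = rng.choice([-1, 1], size=n_extra)
        for i, s in zip(picked, signs):
            de.append((group[i], int(s)))

    def _table(gene_ids: list[str]) -> pd.DataFrame:
        rows = [
            (mirnas[j], g) for g in gene_ids for j in np.sort(sets[g])
        ]
        df = pd.DataFrame(rows, columns=["mirna", "target"])
        return df.drop_duplicates(ignore_index=True)

    truth = PlantedTruth(pairs=tuple(pairs), de_genes=tuple(de), blocks=blocks)
    return _table(mrnas), _table(lncs), truth


def generate_expression(
    cfg: SyntheticConfig, truth: PlantedTruth
) -> tuple[ExpressionMatrix, pd.Series]:
    """Draw the log2 expression matrix implied by a planted truth.

    Differential genes have their group-1 mean shifted by
    ``sign * effect_size``.  Genes of one planted block share a latent
    factor: residual = sqrt(rho) * z_block + sqrt(1 - rho) * eps, so the
    within-group Pearson correlation of a planted pair has expectation
    ``rho`` (the shared differential shift raises the pooled
    correlation further).  Deterministic given the config seed.
    """
    cfg.validate()
    genes = cfg.mrna_ids() + cfg.lncrna_ids()
    gene_pos = {g: i for i, g in enumerate(genes)}
    unknown = [g for g, _ in truth.de_genes if g not in gene_pos]
    unknown += [g for g in truth.blocks if g not in gene_pos]
    if unknown:
        raise ValueError(
            f"truth references genes outside the configured matrix: {unknown[:5]}"
        )

    rng = np.random.default_rng([cfg.seed, 22])
    n = cfg.n_samples
    g_count = len(genes)
    group = np.zeros(n)
    group[cfg.n_group0 :] = 1.0

    base = rng.uniform(6.0, 12.0, size=g_count)
    eps = rng.standard_normal((g_count, n))
    z_block = rng.standard_normal((max(cfg.n_blocks, 1), n))

    effect = np.zeros(g_count)
    for gene, sign in truth.de_genes:
        effect[gene_pos[gene]] = sign * cfg.effect_size

    resid = eps.copy()
    for gene, b in truth.blocks.items():
        i = gene_pos[gene]
        resid[i] = np.sqrt(cfg.rho) * z_block[b] + np.sqrt(1.0 - cfg.rho) * eps[i]

    values = base[:, None] + np.outer(effect, group) + cfg.noise_sd * resid
    samples = cfg.sample_ids()
    df = pd.DataFrame(values, index=genes, columns=samples)
    classes = pd.Series(
        ["mRNA"] * cfg.n_mrna + ["lncRNA"] * cfg.n_lncrna, index=genes
    )
    labels = pd.Series(group.astype(int), index=samples, name="label")
    return ExpressionMatrix(df, classes), labels


def generate_dataset(cfg: SyntheticConfig):
    """Convenience wrapper: interactions + expression in one call."""
    mm, ml, truth = generate_interactions(cfg)
    expr, labels = generate_expression(cfg, truth)
    return mm, ml, truth, expr, labels


def write_dataset(cfg: SyntheticConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write a full synthetic dataset as plain-text files.

    Emits expression.tsv (first column gene id, header = sample ids),
    labels.tsv, gene_classes.tsv, mirna_mrna.tsv, mirna_lncrna.tsv and
    truth.json under ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mm, ml, truth, expr, labels = generate_dataset(cfg)
    paths = {
        "expression": out / "expression.tsv",
        "labels": out / "labels.tsv",
        "gene_classes": out / "gene_classes.tsv",
        "mirna_mrna": out / "mirna_mrna.tsv",
        "mirna_lncrna": out / "mirna_lncrna.tsv",
        "truth": out / "truth.json",
        "config": out / "config.json",
    }
    expr.values.to_csv(paths["expression"], sep="\t", index_label="gene")
    labels.rename_axis("sample").to_csv(paths["labels"], sep="\t", header=["label"])
    expr.gene_class.rename_axis("gene").to_csv(
        paths["gene_classes"], sep="\t", header=["class"]
    )
    mm.to_csv(paths["mirna_mrna"], sep="\t", index=False)
    ml.to_csv(paths["mirna_lncrna"], sep="\t", index=False)
    paths["truth"].write_text(truth.to_json())
    paths["config"].write_text(json.dumps(dataclasses.asdict(cfg), indent=1))
    return paths


def null_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """A no-signal configuration: nothing planted, no differential effect.

    Used for type-I-error calibration of the pair screen and the
    moderated t-test.  Gene counts are kept large enough that every
    miRNA appears in both interaction tables with near certainty, so
    the shared-miRNA universe equals the full miRNA set.
    """
    defaults = dict(
        n_mirna=200,
        n_mrna=200,
        n_lncrna=100,
        per_gene_targets=15.0,
        n_planted_pairs=0,
        n_de_mrna=0,
        n_de_lncrna=0,
        effect_size=0.0,
        seed=seed,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)
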