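"""Synthetic multi-omics cohorts with known planted structure.

Emulates a post-differential-analysis glioma cohort: three molecular subtype
labels with a deliberately underrepresented third class, a chosen number of
subtype-discriminative ("informative") genes whose class-conditional means are
separated by a configurable effect size, a methylation layer coupled to the
mRNA layer at a configurable cross-layer correlation (negative by default:
hypermethylation tracks low expression), and a scale-free protein-interaction
network in which the informative genes can be forced to be hubs. Everything is
driven by one integer seed, so identical configurations produce bit-identical
cohorts and byte-identical exported files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotate import OmicsMatrix

SUBTYPES = ("IDHmut-codel", "IDHmut-non-codel", "IDHwt")


@dataclass
class SimulationConfig:
    """Knobs of the cohort generator; defaults are the study conditions.

    ``effect_size`` is the between-class mean shift in units of the unit
    within-class SD. ``cross_layer_rho`` is the target Pearson correlation
    between a gene's mRNA value and its mapped methylation value (negative =
    epigenetic-silencing direction). ``n_per_class`` mirrors the imbalance of
    the three glioma subtypes (IDH-wildtype rare).
    """

    n_per_class: tuple[int, int, int] = (60, 60, 20)
    n_genes: int = 200
    n_mirnas: int = 40
    n_cpgs: int = 100
    n_informative_genes: int = 20
    effect_size: float = 2.0
    cross_layer_rho: float = -0.5
    ppi_attach_edges: int = 2
    hub_informative: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_per_class) != 3:
            raise ValueError("n_per_class must have length 3")
        counts = (*self.n_per_class, self.n_genes, self.n_mirnas, self.n_cpgs,
                  self.n_informative_genes)
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if self.n_informative_genes > self.n_genes:
            raise ValueError("n_informative_genes must be <= n_genes")
        if not -1.0 <= self.cross_layer_rho <= 1.0:
            raise ValueError("cross_layer_rho must lie in [-1, 1]")
        if self.ppi_attach_edges < 1:
            raise ValueError("ppi_attach_edges must be >= 1")


@dataclass
class SyntheticCohort:
    mrna: OmicsMatrix
    mirna: OmicsMatrix
    meth: OmicsMatrix
    labels: pd.DataFrame  # columns: sample_id, subtype
    truth_genes: list[str]
    ppi_edges: pd.DataFrame  # columns: gene_a, gene_b, combined_score
    mirna_map: pd.DataFrame  # columns: mirna_id, target_gene, report_count
    cpg_map: pd.DataFrame  # columns: probe_id, gene_list
    config: SimulationConfig = field(repr=False, default=None)

    @property
    def y(self) -> np.ndarray:
        return self.labels["subtype"].to_numpy()

    def to_dir(self, path: str) -> dict[str, str]:
        """Export the exact delimited-text formats the pipeline consumes."""
        os.makedirs(path, exist_ok=True)
        files = {}
        for name, layer in (("mrna", self.mrna), ("mirna", self.mirna), ("meth", self.meth)):
            files[name] = os.path.join(path, f"{name}.tsv")
            layer.write_tsv(files[name])
        files["labels"] = os.path.join(path, "labels.tsv")
        self.labels.to_csv(files["labels"], sep="\t", index=False)
        files["ppi"] = os.path.join(path, "ppi_edges.tsv")
        self.ppi_edges.to_csv(files["ppi"], sep="\t", index=False)
        files["mirna_map"] = os.path.join(path, "mirna_map.tsv")
        self.mirna_map.to_csv(files["mirna_map"], sep="\t", index=False)
        files["cpg_map"] = os.path.join(path, "cpg_map.tsv")
        self.cpg_map.to_csv(files["cpg_map"], sep="\t", index=False)
        files["truth"] = os.path.join(path, "truth_genes.tsv")
        pd.DataFrame({"gene": self.truth_genes}).to_csv(files["truth"], sep="\t", index=False)
        return files


def generate_ppi(genes: list[str], attach_edges: int, seed: int) -> pd.DataFrame:
    """Scale-free scored edge table by preferential attachment.

    The seed graph is the first two genes joined by one edge; every further
    gene attaches to ``min(attach_edges, #existing)`` distinct existing genes,
    drawn with probability proportional to current degree. Gene list order is
    therefore the node-addition order: early genes end up as hubs. Edge scores
    are integers uniform on [400, 1000] (the medium-to-high confidence band of
    a 0-1000 interaction score).
    """
    n = len(genes)
    if n < 2:
        raise ValueError("need at least 2 genes to build a PPI network")
    if attach_edges < 1:
        raise ValueError("attach_edges must be >= 1")
    rng = np.random.default_rng(seed)
    deg = np.zeros(n)
    edges: list[tuple[int, int]] = [(0, 1)]
    deg[0] = deg[1] = 1
    for new in range(2, n):
        m = min(attach_edges, new)
        p = deg[:new] / deg[:new].sum()
        targets = rng.choice(new, size=m, replace=False, p=p)
        for t in sorted(targets):
            edges.append((int(t), new))
            deg[t] += 1
            deg[new] += 1
    scores = rng.integers(400, 1001, size=len(edges))
    return pd.DataFrame(
        {
            "gene_a": [genes[a] for a, _ in edges],
            "gene_b": [genes[b] for _, b in edges],
            "combined_score": scores,
        }
    )


def generate_mappings(
    genes: list[str],
    n_mirnas: int,
    n_cpgs: int,
    seed: int,
    priority_genes: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """miRNA-target and CpG-gene annotation tables with known top targets.

    Every miRNA maps to 1-3 candidate genes with report counts whose strict
    maximum is the designated target; ``priority_genes`` (the planted
    informative genes) are used as designated targets first so the miRNA
    channel carries signal. Every fifth CpG probe lists two genes and every
    seventh repeats its first gene, deliberately exercising the merge and
    dedup annotation rules downstream.
    """
    if n_mirnas < 0 or n_cpgs < 0:
        raise ValueError("n_mirnas and n_cpgs must be >= 0")
    rng = np.random.default_rng(seed)
    priority = list(priority_genes or [])

    mir_rows = []
    for i in range(n_mirnas):
        mid = f"hsa-miR-{100 + i}-5p" if i % 2 == 0 else f"hsa-mir-{100 + i}"
        target = priority[i] if i < len(priority) else genes[int(rng.integers(len(genes)))]
        n_extra = int(rng.integers(0, 3))
        decoys = [g for g in rng.choice(genes, size=n_extra + 2, replace=False) if g != target]
        top = int(rng.integers(5, 11))
        mir_rows.append((mid, target, top))
        for d in decoys[:n_extra]:
            mir_rows.append((mid, d, int(rng.integers(1, top))))
    mirna_map = pd.DataFrame(mir_rows, columns=["mirna_id", "target_gene", "report_count"])

    cpg_rows = []
    for i in range(n_cpgs):
        probe = f"cg{i:08d}"
        g1 = priority[i] if i < len(priority) else genes[int(rng.integers(len(genes)))]
        parts = [g1]
        if i % 7 == 3:
            parts.append(g1)  # duplicate on purpose
        if i % 5 == 2:
            g2 = genes[int(rng.integers(len(genes)))]
            if g2 != g1:
                parts.append(g2)
        cpg_rows.append((probe, ";".join(parts)))
    cpg_map = pd.DataFrame(cpg_rows, columns=["probe_id", "gene_list"])
    return mirna_map, cpg_map


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw one synthetic cohort under ``config``; fully seeded.

    Informative genes receive a class-conditional mean shift of
    ``effect_size`` (one subtype shifted per gene, cycling over subtypes so
    each is covered). Methylation beta values are a logistic squash of a
    latent that correlates with the gene's mRNA value at ``cross_layer_rho``;
    miRNAs whose resolved target is informative reuse ``|cross_layer_rho|``.
    All other features are exchangeable unit-variance Gaussian noise.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = int(sum(cfg.n_per_class))
    sample_ids = [f"S{i:04d}" for i in range(n)]
    y = np.repeat(np.array(SUBTYPES, dtype=object), cfg.n_per_class)
    # shuffle sample order so class blocks are not contiguous
    perm = rng.permutation(n)
    y = y[perm]

    genes = [f"GENE{i:04d}" for i in range(1, cfg.n_genes + 1)]
    informative = sorted(
        rng.choice(genes, size=cfg.n_informative_genes, replace=False).tolist()
    )

    # mRNA: unit-SD Gaussian noise + per-gene one-subtype shift
    X = rng.standard_normal((n, cfg.n_genes))
    gene_idx = {g: i for i, g in enumerate(genes)}
    class_masks = [y == s for s in SUBTYPES]
    for k, g in enumerate(informative):
        up = k % 3
        X[class_masks[up], gene_idx[g]] += cfg.effect_size
    mrna = OmicsMatrix(X, sample_ids, genes, "mrna")

    mirna_map, cpg_map = generate_mappings(
        genes, cfg.n_mirnas, cfg.n_cpgs, seed=int(rng.integers(2**31)),
        priority_genes=informative,
    )

    # standardized mRNA per gene drives the coupled layers
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd

    rho = cfg.cross_layer_rho
    meth_vals = np.empty((n, cfg.n_cpgs))
    for j, (probe, gl) in enumerate(zip(cpg_map["probe_id"], cpg_map["gene_list"])):
        g = str(gl).split(";")[0]
        latent = rho * Z[:, gene_idx[g]] + np.sqrt(1 - rho**2) * rng.standard_normal(n)
        meth_vals[:, j] = _sigmoid(latent)
    meth = OmicsMatrix(meth_vals, sample_ids, list(cpg_map["probe_id"]), "meth")

    # resolved (max-count) target of each miRNA drives its coupling
    informative_set = set(informative)
    top_target = (
        mirna_map.sort_values(["report_count", "target_gene"], ascending=[False, True])
        .groupby("mirna_id", sort=False)
        .first()["target_gene"]
        .to_dict()
        if len(mirna_map)
        else {}
    )
    mir_ids = list(dict.fromkeys(mirna_map["mirna_id"])) if len(mirna_map) else []
    mir_vals = np.empty((n, len(mir_ids)))
    r = abs(rho)
    for j, mid in enumerate(mir_ids):
        tgt = top_target.get(mid)
        noise = rng.standard_normal(n)
        if tgt in informative_set:
            mir_vals[:, j] = r * Z[:, gene_idx[tgt]] + np.sqrt(1 - r**2) * noise
        else:
            mir_vals[:, j] = noise
    mirna = OmicsMatrix(mir_vals, sample_ids, mir_ids, "mirna")

    # hubs-first node order plants informative genes at the network core
    if cfg.hub_informative:
        node_order = informative + [g for g in genes if g not in informative_set]
    else:
        node_order = list(genes)
    ppi_edges = generate_ppi(node_order, cfg.ppi_attach_edges, seed=int(rng.integers(2**31)))

    labels = pd.DataFrame({"sample_id": sample_ids, "subtype": y})
    return SyntheticCohort(
        mrna=mrna, mirna=mirna, meth=meth, labels=labels,
        truth_genes=informative, ppi_edges=ppi_edges,
        mirna_map=mirna_map, cpg_map=cpg_map, config=cfg,
    )
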