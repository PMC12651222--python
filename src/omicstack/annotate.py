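"""Gene-centric annotation of multi-omics layers.

Three measurement layers — mRNA expression (gene symbols), miRNA expression
(miRBase-style identifiers), and DNA methylation (Illumina 450k CpG probes) —
are reduced to a single shared gene universe. Each miRNA is assigned its most
frequently reported target gene; each CpG probe carries a (deduplicated) set
of overlapping genes. The result is, per sample and per gene, a three-channel
vector (mrna, meth, mirna); channels with no mapped measurement are zero.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MODALITIES = ("mrna", "mirna", "meth")
#: channel order of every per-gene feature vector
CHANNELS = ("mrna", "meth", "mirna")

_MIRNA_SUFFIX = re.compile(r"(-[35]p|\.\d+)$")


@dataclass
class OmicsMatrix:
    """One omics layer: samples x features with a modality tag."""

    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    modality: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError(
                f"{self.modality}: values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError(f"{self.modality}: duplicate feature ids")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_ids)
        df.insert(0, "sample_id", self.sample_ids)
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, modality: str) -> "OmicsMatrix":
        if df.columns[0] != "sample_id":
            raise ValueError("first column must be 'sample_id'")
        return cls(
            values=df.iloc[:, 1:].to_numpy(dtype=float),
            sample_ids=[str(s) for s in df["sample_id"]],
            feature_ids=[str(c) for c in df.columns[1:]],
            modality=modality,
        )

    @classmethod
    def read_tsv(cls, path, modality: str) -> "OmicsMatrix":
        return cls.from_dataframe(pd.read_csv(path, sep="\t"), modality)

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.10g")


def normalize_mirna_id(mirna_id: str) -> str:
    """Canonical miRNA identifier: lowercase, arm/variant suffixes stripped.

    Trailing ``-3p``/``-5p`` arm tags and ``.<digit>`` variant tags are removed
    repeatedly until a fixed point, so the function is idempotent.
    """
    s = str(mirna_id).strip().lower()
    while True:
        stripped = _MIRNA_SUFFIX.sub("", s)
        if stripped == s:
            break
        s = stripped
    if not s:
        raise ValueError(f"empty miRNA identifier after normalization: {mirna_id!r}")
    return s


def normalize_mirna_ids(ids) -> list[str]:
    return [normalize_mirna_id(i) for i in ids]


def canonical_gene(symbol: str) -> str:
    return str(symbol).strip().upper()


def resolve_mirna_targets(mirna_map: pd.DataFrame) -> dict[str, str]:
    """Assign each miRNA its most frequently reported target gene.

    Report counts for the same (miRNA, gene) pair are summed after identifier
    normalization; ties on the maximal total count break to the
    lexicographically smallest gene symbol so the map is deterministic.
    """
    required = {"mirna_id", "target_gene", "report_count"}
    if not required.issubset(mirna_map.columns):
        raise ValueError(f"miRNA map needs columns {sorted(required)}")
    if len(mirna_map) == 0:
        return {}
    df = mirna_map.copy()
    df["mirna_id"] = [normalize_mirna_id(m) for m in df["mirna_id"]]
    df["target_gene"] = [canonical_gene(g) for g in df["target_gene"]]
    totals = (
        df.groupby(["mirna_id", "target_gene"], sort=True)["report_count"]
        .sum()
        .reset_index()
    )
    out: dict[str, str] = {}
    for mirna, grp in totals.groupby("mirna_id", sort=True):
        best = grp.sort_values(
            ["report_count", "target_gene"], ascending=[False, True]
        ).iloc[0]
        out[mirna] = best["target_gene"]
    return out


def resolve_cpg_genes(cpg_map: pd.DataFrame) -> dict[str, tuple[str, ...]]:
    """Per CpG probe, the deduplicated set of overlapping genes.

    The semicolon-joined gene list is split, trimmed, uppercased and
    deduplicated preserving first-seen order. Probes with an empty list are
    dropped (logged).
    """
    required = {"probe_id", "gene_list"}
    if not required.issubset(cpg_map.columns):
        raise ValueError(f"CpG map needs columns {sorted(required)}")
    out: dict[str, tuple[str, ...]] = {}
    n_dropped = 0
    for probe, raw in zip(cpg_map["probe_id"], cpg_map["gene_list"]):
        genes: list[str] = []
        raw = "" if raw is None or (isinstance(raw, float) and np.isnan(raw)) else str(raw)
        for token in raw.split(";"):
            g = canonical_gene(token)
            if g and g not in genes:
                genes.append(g)
        if genes:
            out[str(probe)] = tuple(genes)
        else:
            n_dropped += 1
    if n_dropped:
        logger.info("resolve_cpg_genes: dropped %d probes with empty gene list", n_dropped)
    return out


@dataclass
class GeneTable:
    """Gene-centric bundle: per sample, per gene, channels (mrna, meth, mirna)."""

    sample_ids: list[str]
    genes: list[str]
    channels: dict[str, np.ndarray] = field(repr=False)  # name -> [n_samples, n_genes]

    def __post_init__(self) -> None:
        for name in CHANNELS:
            if name not in self.channels:
                raise ValueError(f"missing channel {name}")
            shape = self.channels[name].shape
            if shape != (len(self.sample_ids), len(self.genes)):
                raise ValueError(f"channel {name} has shape {shape}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def tensor(self) -> np.ndarray:
        """[n_samples, n_genes, 3] stacked in CHANNELS order."""
        return np.stack([self.channels[c] for c in CHANNELS], axis=2)

    def wide(self) -> tuple[np.ndarray, list[tuple[str, str]]]:
        """Flat feature matrix [n_samples, 3*n_genes] and (gene, channel) column keys."""
        X = np.concatenate([self.channels[c] for c in CHANNELS], axis=1)
        cols = [(g, c) for c in CHANNELS for g in self.genes]
        return X, cols

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for c in CHANNELS:
            df = pd.DataFrame(self.channels[c], columns=self.genes)
            df.insert(0, "sample_id", self.sample_ids)
            long = df.melt(id_vars="sample_id", var_name="gene", value_name=c)
            rows.append(long.set_index(["sample_id", "gene"]))
        return pd.concat(rows, axis=1).reset_index()[
            ["sample_id", "gene", "mrna", "meth", "mirna"]
        ]

    def write_long_tsv(self, path) -> None:
        self.to_long_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")

    def write_wide_tsv(self, path_prefix) -> None:
        for c in CHANNELS:
            df = pd.DataFrame(self.channels[c], columns=self.genes)
            df.insert(0, "sample_id", self.sample_ids)
            df.to_csv(f"{path_prefix}.{c}.tsv", sep="\t", index=False, float_format="%.10g")


def build_gene_table(
    mrna: OmicsMatrix,
    mirna: OmicsMatrix | None,
    meth: OmicsMatrix | None,
    mirna_targets: dict[str, str] | None = None,
    cpg_genes: dict[str, tuple[str, ...]] | None = None,
) -> GeneTable:
    """Fuse the three layers into per-gene (mrna, meth, mirna) channels.

    The gene universe is the union of mRNA gene symbols, CpG-mapped genes and
    resolved miRNA target genes, ordered lexicographically. Missing channels
    are zero-filled; several CpGs (or miRNAs) mapping to one gene are reduced
    by the arithmetic mean.
    """
    mirna_targets = mirna_targets or {}
    cpg_genes = cpg_genes or {}
    sample_ids = list(mrna.sample_ids)
    sample_set = set(sample_ids)

    def _aligned(layer: OmicsMatrix | None, name: str) -> OmicsMatrix | None:
        if layer is None or layer.n_features == 0:
            return None
        if set(layer.sample_ids) != sample_set:
            offending = sorted(set(layer.sample_ids) ^ sample_set)
            raise ValueError(f"sample-ID mismatch in {name} layer: {offending[:10]}")
        order = [layer.sample_ids.index(s) for s in sample_ids]
        return OmicsMatrix(layer.values[order], sample_ids, layer.feature_ids, layer.modality)

    mirna = _aligned(mirna, "miRNA")
    meth = _aligned(meth, "methylation")

    mrna_genes = [canonical_gene(g) for g in mrna.feature_ids]
    universe: set[str] = set(mrna_genes)
    for genes in cpg_genes.values():
        universe.update(genes)
    universe.update(mirna_targets.values())
    genes = sorted(universe)
    gidx = {g: i for i, g in enumerate(genes)}
    n, G = len(sample_ids), len(genes)

    ch = {c: np.zeros((n, G)) for c in CHANNELS}

    for j, g in enumerate(mrna_genes):
        ch["mrna"][:, gidx[g]] = mrna.values[:, j]

    if meth is not None:
        sums = np.zeros((n, G))
        counts = np.zeros(G)
        for j, probe in enumerate(meth.feature_ids):
            for g in cpg_genes.get(str(probe), ()):
                if g in gidx:
                    sums[:, gidx[g]] += meth.values[:, j]
                    counts[gidx[g]] += 1
        nz = counts > 0
        ch["meth"][:, nz] = sums[:, nz] / counts[nz]

    if mirna is not None:
        sums = np.zeros((n, G))
        counts = np.zeros(G)
        for j, mid in enumerate(mirna.feature_ids):
            g = mirna_targets.get(normalize_mirna_id(mid))
            if g is not None and g in gidx:
                sums[:, gidx[g]] += mirna.values[:, j]
                counts[gidx[g]] += 1
        nz = counts > 0
        ch["mirna"][:, nz] = sums[:, nz] / counts[nz]

    return GeneTable(sample_ids=sample_ids, genes=genes, channels=ch)
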