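"""Shared PPI topology and per-patient graphs.

The interaction network (nodes = gene symbols, edges = scored functional
associations) is identical for every patient; only the node-feature matrix —
one row per gene, channels (mrna, meth, mirna) — is patient-specific. Edges
are kept at a combined confidence score of at least 400/1000, symmetric
duplicates are collapsed keeping the maximum score, and the network is
restricted to genes present in the annotated multi-omics dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotate import CHANNELS, GeneTable, canonical_gene

logger = logging.getLogger(__name__)

STRING_API_URL = "https://string-db.org/api/tsv/network"
HUMAN_TAXON = 9606
QUERY_BATCH_SIZE = 100


@dataclass
class PPINetwork:
    """Undirected scored interaction network with a frozen node order."""

    nodes: list[str]
    edges: list[tuple[str, str]]
    scores: np.ndarray
    min_score: int = 400

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=int)
        node_set = set(self.nodes)
        seen = set()
        for (a, b), s in zip(self.edges, self.scores):
            if a == b:
                raise ValueError(f"self-loop on {a}")
            if a not in node_set or b not in node_set:
                raise ValueError(f"edge endpoint outside node list: ({a}, {b})")
            key = frozenset((a, b))
            if key in seen:
                raise ValueError(f"duplicate unordered pair ({a}, {b})")
            seen.add(key)
            if s < self.min_score:
                raise ValueError(f"edge ({a}, {b}) score {s} below {self.min_score}")
        self._index = {g: i for i, g in enumerate(self.nodes)}

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_index(self) -> np.ndarray:
        """[2, n_edges] integer endpoints in node order."""
        if not self.edges:
            return np.zeros((2, 0), dtype=int)
        return np.array(
            [[self._index[a] for a, _ in self.edges], [self._index[b] for _, b in self.edges]]
        )

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        for a, b in self.edges:
            deg[self._index[a]] += 1
            deg[self._index[b]] += 1
        return deg

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_a": [a for a, _ in self.edges],
                "gene_b": [b for _, b in self.edges],
                "combined_score": self.scores,
            }
        )


def string_query_batches(genes: list[str], batch_size: int = QUERY_BATCH_SIZE) -> list[list[str]]:
    """Split a gene query list into API-sized batches (100 genes each)."""
    if not genes:
        raise ValueError("empty gene query list")
    return [genes[i : i + batch_size] for i in range(0, len(genes), batch_size)]


def load_string_edges(source, min_score: int = 400, genes: list[str] | None = None) -> pd.DataFrame:
    """Raw scored edge rows from a local TSV file / DataFrame or the live API.

    File mode (a path or a DataFrame with columns gene_a, gene_b,
    combined_score) is the supported, hermetic route. Network mode queries the
    human (taxon 9606) interaction API in batches of 100 genes and requires
    connectivity; on failure it raises with instructions to use a local edge
    file instead. Rows scoring below ``min_score`` are dropped in both modes;
    malformed rows are skipped and counted.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    elif isinstance(source, str) and source.startswith(("http://", "https://")):
        df = _fetch_string_edges(genes or [], url=source)
    else:
        df = pd.read_csv(source, sep="\t")
    required = {"gene_a", "gene_b", "combined_score"}
    if not required.issubset(df.columns):
        raise ValueError(f"edge table needs columns {sorted(required)}")
    n0 = len(df)
    df = df.dropna(subset=["gene_a", "gene_b", "combined_score"])
    df = df[pd.to_numeric(df["combined_score"], errors="coerce").notna()]
    df["combined_score"] = df["combined_score"].astype(int)
    if len(df) < n0:
        logger.warning("load_string_edges: skipped %d malformed rows", n0 - len(df))
    return df[df["combined_score"] >= min_score].reset_index(drop=True)


def _fetch_string_edges(genes: list[str], url: str = STRING_API_URL) -> pd.DataFrame:
    """Query the interaction API batch-wise; never exercised in tests."""
    import io
    import urllib.parse
    import urllib.request

    frames = []
    for batch in string_query_batches(genes):
        params = urllib.parse.urlencode(
            {"identifiers": "%0d".join(batch), "species": HUMAN_TAXON}
        )
        try:
            with urllib.request.urlopen(f"{url}?{params}", timeout=30) as resp:
                raw = resp.read().decode()
        except Exception as exc:  # pragma: no cover - needs network
            raise RuntimeError(
                "PPI API unreachable; pass a local edge TSV "
                "(columns gene_a, gene_b, combined_score) instead"
            ) from exc
        part = pd.read_csv(io.StringIO(raw), sep="\t")
        part = part.rename(
            columns={"preferredName_A": "gene_a", "preferredName_B": "gene_b", "score": "combined_score"}
        )
        part["combined_score"] = (part["combined_score"] * 1000).round().astype(int)
        frames.append(part[["gene_a", "gene_b", "combined_score"]])
    return pd.concat(frames, ignore_index=True)


def dedupe_and_restrict(
    raw_rows: pd.DataFrame,
    annotated_genes,
    min_score: int = 400,
    include_isolated: bool = False,
) -> PPINetwork:
    """Collapse symmetric duplicates (max score wins), drop self-loops and
    edges touching unannotated genes; node order is frozen lexicographic.

    With ``include_isolated`` the annotated genes without any surviving edge
    are kept as nodes (they only ever see their own signal through the
    self-loops added at model time); by default they are excluded.
    """
    annotated = {canonical_gene(g) for g in annotated_genes}
    best: dict[tuple[str, str], int] = {}
    for a, b, s in zip(raw_rows["gene_a"], raw_rows["gene_b"], raw_rows["combined_score"]):
        a, b = canonical_gene(a), canonical_gene(b)
        if a == b or a not in annotated or b not in annotated:
            continue
        s = int(s)
        if s < min_score:
            continue
        key = (a, b) if a < b else (b, a)
        if s > best.get(key, -1):
            best[key] = s
    pairs = sorted(best)
    nodes = sorted({g for pair in pairs for g in pair})
    if include_isolated:
        nodes = sorted(annotated)
    return PPINetwork(
        nodes=nodes,
        edges=pairs,
        scores=np.array([best[p] for p in pairs], dtype=int),
        min_score=min_score,
    )


@dataclass
class PatientGraph:
    """One patient's view: shared topology + private node features."""

    topology: PPINetwork
    node_features: np.ndarray  # [n_nodes, 3] in CHANNELS order
    sample_id: str
    label: str | None = None


@dataclass
class PatientGraphSet:
    """All patients over one shared topology; features [n_samples, n_nodes, 3]."""

    topology: PPINetwork
    features: np.ndarray
    sample_ids: list[str]
    labels: np.ndarray | None = None
    channel_names: tuple[str, ...] = CHANNELS

    def __len__(self) -> int:
        return len(self.sample_ids)

    def __getitem__(self, i: int) -> PatientGraph:
        lab = None if self.labels is None else self.labels[i]
        return PatientGraph(self.topology, self.features[i], self.sample_ids[i], lab)

    def subset(self, idx) -> "PatientGraphSet":
        idx = np.asarray(idx)
        return PatientGraphSet(
            self.topology,
            self.features[idx],
            [self.sample_ids[i] for i in idx],
            None if self.labels is None else self.labels[idx],
        )


def assemble_patient_graphs(
    network: PPINetwork,
    gene_table: GeneTable,
    labels: pd.DataFrame | None = None,
) -> PatientGraphSet:
    """One graph per sample: network-ordered node rows of (mrna, meth, mirna).

    Genes in the network missing from the gene table get an all-zero feature
    row (logged). If a label table is given, every labeled sample must exist.
    """
    tensor = gene_table.tensor()
    col = {g: j for j, g in enumerate(gene_table.genes)}
    n = gene_table.n_samples
    X = np.zeros((n, network.n_nodes, len(CHANNELS)))
    missing = []
    for i, g in enumerate(network.nodes):
        j = col.get(g)
        if j is None:
            missing.append(g)
        else:
            X[:, i, :] = tensor[:, j, :]
    if missing:
        logger.info("assemble_patient_graphs: %d network genes absent from gene table "
                    "(zero rows): %s", len(missing), missing[:5])
    y = None
    if labels is not None:
        lab = dict(zip(labels["sample_id"], labels["subtype"]))
        absent = [s for s in lab if s not in set(gene_table.sample_ids)]
        if absent:
            raise ValueError(f"labeled samples missing from gene table: {absent[:10]}")
        y = np.array([lab[s] for s in gene_table.sample_ids], dtype=object)
    return PatientGraphSet(network, X, list(gene_table.sample_ids), y)
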