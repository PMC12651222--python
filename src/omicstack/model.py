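"""Model / Results surface of the hybrid classifier.

:class:`HybridStackModel` bundles a gene-centric multi-omics table, a shared
PPI topology and subtype labels with all pipeline settings; :meth:`fit` runs
the repeated, leakage-safe cross-validation of the three models (RF, GAT,
ridge-logistic stack) and returns a :class:`HybridStackResults` carrying the
per-fold metrics, paired model comparisons, the biomarker ranking with its
best-omic annotation, and writers for every report table.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict

import numpy as np
import pandas as pd

from . import __version__
from .annotate import (GeneTable, OmicsMatrix, build_gene_table,
                       resolve_cpg_genes, resolve_mirna_targets)
from .biomarkers import aggregate_importances, annotate_best_omic, combine_and_rank
from .evaluate import (CVPlan, CVResult, PipelineConfig, anova_table, run_cv)
from .ppi import PPINetwork, assemble_patient_graphs, dedupe_and_restrict, load_string_edges

_FLOAT_FMT = "%.6g"


class HybridStackModel:
    """PPI-informed hybrid subtype classifier (GAT + RF + logistic stacking)."""

    def __init__(self, gene_table: GeneTable, network: PPINetwork,
                 labels: np.ndarray, config: PipelineConfig | None = None):
        self.gene_table = gene_table
        self.network = network
        self.labels = np.asarray(labels)
        if len(self.labels) != gene_table.n_samples:
            raise ValueError("one label per sample required")
        self.config = config or PipelineConfig()

    # ------------------------------------------------------------ constructors
    @classmethod
    def from_cohort(cls, cohort, config: PipelineConfig | None = None,
                    min_score: int = 400) -> "HybridStackModel":
        """Build from a :class:`~omicstack.simulate.SyntheticCohort`."""
        gene_table = build_gene_table(
            cohort.mrna, cohort.mirna, cohort.meth,
            resolve_mirna_targets(cohort.mirna_map),
            resolve_cpg_genes(cohort.cpg_map),
        )
        raw = load_string_edges(cohort.ppi_edges, min_score=min_score)
        network = dedupe_and_restrict(raw, gene_table.genes, min_score=min_score)
        graphs = assemble_patient_graphs(network, gene_table, cohort.labels)
        return cls(gene_table, network, graphs.labels, config)

    @classmethod
    def from_files(cls, mrna_path, mirna_path, meth_path, labels_path,
                   ppi_path, mirna_map_path, cpg_map_path,
                   config: PipelineConfig | None = None,
                   min_score: int = 400) -> "HybridStackModel":
        """Build from the delimited-text formats documented in the README."""
        mrna = OmicsMatrix.read_tsv(mrna_path, "mrna")
        mirna = OmicsMatrix.read_tsv(mirna_path, "mirna")
        meth = OmicsMatrix.read_tsv(meth_path, "meth")
        labels = pd.read_csv(labels_path, sep="\t")
        gene_table = build_gene_table(
            mrna, mirna, meth,
            resolve_mirna_targets(pd.read_csv(mirna_map_path, sep="\t")),
            resolve_cpg_genes(pd.read_csv(cpg_map_path, sep="\t")),
        )
        raw = load_string_edges(ppi_path, min_score=min_score)
        network = dedupe_and_restrict(raw, gene_table.genes, min_score=min_score)
        graphs = assemble_patient_graphs(network, gene_table, labels)
        return cls(gene_table, network, graphs.labels, config)

    # -------------------------------------------------------------------- fit
    def fit(self, plan: CVPlan | None = None,
            unsafe_global_standardize: bool = False) -> "HybridStackResults":
        plan = plan or CVPlan(seed=self.config.seed)
        cv = run_cv(self.gene_table, self.network, self.labels, self.config,
                    plan, unsafe_global_standardize=unsafe_global_standardize)
        anova = anova_table(self.gene_table, self.labels)
        return HybridStackResults(self, plan, cv, anova)

    def config_hash(self, plan: CVPlan | None = None) -> str:
        payload = {
            "config": _jsonable(self.config),
            "plan": None if plan is None else asdict(plan),
            "n_samples": self.gene_table.n_samples,
            "n_genes": self.gene_table.n_genes,
            "n_edges": self.network.n_edges,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


class HybridStackResults:
    """Estimates, comparisons and rankings from one cross-validated fit."""

    def __init__(self, model: HybridStackModel, plan: CVPlan, cv: CVResult,
                 anova: pd.DataFrame):
        self.model = model
        self.plan = plan
        self.cv = cv
        self.anova = anova
        self.fold_results = cv.fold_results

    # ------------------------------------------------------------------ views
    def summary(self) -> pd.DataFrame:
        """Mean ± SD of all six metrics per model over the repeat x fold cells."""
        return self.cv.summary()

    def ttest_table(self) -> pd.DataFrame:
        return self.cv.ttest_table()

    def biomarkers(self, weight: float = 0.5) -> pd.DataFrame:
        rf = aggregate_importances(self.cv.rf_importance)
        att = aggregate_importances(self.cv.attention)
        ranking = combine_and_rank(rf, att, weight=weight)
        return annotate_best_omic(ranking, self.anova)

    def anova_report(self, top: int | None = None) -> pd.DataFrame:
        df = self.anova.sort_values("p_value").reset_index(drop=True)
        return df.head(top) if top else df

    def plot_top_biomarkers(self, k: int = 20, weight: float = 0.5, ax=None):
        """Horizontal bar chart of the top-k hybrid scores."""
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        df = self.biomarkers(weight=weight).nsmallest(k, "rank")[::-1]
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 0.3 * k + 1))
        ax.barh(df["gene"], df["combined"], color="#4878a8")
        ax.set_xlabel("hybrid importance score")
        ax.set_title(f"Top {k} candidate biomarkers")
        return ax

    # ---------------------------------------------------------------- exports
    def save_artifacts(self, out_dir: str, weight: float = 0.5) -> dict[str, str]:
        """Write every report table as TSV plus a run manifest; deterministic."""
        os.makedirs(out_dir, exist_ok=True)
        cfg_hash = self.model.config_hash(self.plan)
        files = {}

        def _write(name: str, df: pd.DataFrame) -> None:
            path = os.path.join(out_dir, name)
            with open(path, "w") as fh:
                fh.write(f"# config_hash={cfg_hash}\n")
                df.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)
            files[name] = path

        _write("fold_results.tsv", self.fold_results)
        _write("summary.tsv", self.summary())
        _write("ttests.tsv", self.ttest_table())
        _write("anova.tsv", self.anova_report())
        _write("biomarkers.tsv", self.biomarkers(weight=weight))
        _write("selected_features.tsv", self.cv.selected)
        attention = self.cv.attention.copy()
        attention.insert(0, "fold_index", np.arange(len(attention)))
        _write("attention_scores.tsv", attention)
        _write("audit.tsv", self.cv.audit.to_frame())

        manifest = {
            "config_hash": cfg_hash,
            "package_version": __version__,
            "seed": self.model.config.seed,
            "plan": asdict(self.plan),
            "config": _jsonable(self.model.config),
            "n_samples": self.model.gene_table.n_samples,
            "n_genes": self.model.gene_table.n_genes,
            "n_network_nodes": self.model.network.n_nodes,
            "n_network_edges": self.model.network.n_edges,
        }
        path = os.path.join(out_dir, "manifest.json")
        with open(path, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        files["manifest.json"] = path
        return files


def _jsonable(obj):
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    return obj
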