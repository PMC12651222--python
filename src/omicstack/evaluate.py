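"""Repeated stratified cross-validation of the hybrid classifier.

Every preprocessing statistic — per-feature standardisation, the variance
filter, the ElasticNet support, the SMOTE oversampling — is computed on the
training partition of each fold only; test rows are transformed with the
frozen statistics. A :class:`LeakageAudit` records the sample set behind
every fitted quantity and refuses any fold in which a test row entered a fit.

Metrics per fold and model: accuracy, macro precision/recall/F1, and
one-vs-rest macro ROC-AUC and AUPRC. Model comparisons use a paired t-test
over the repeat x fold cells; per-gene one-way ANOVA against the subtype
labels identifies the most discriminative omic layer per gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import RepeatedStratifiedKFold

from . import rf as rf_mod
from .annotate import CHANNELS, GeneTable
from .enet import ElasticNetParams, select
from .gat import GATClassifier, GATConfig
from .ppi import PPINetwork
from .smote import SmoteParams, interpolate_rows, smote_balance
from .stacking import oof_meta_features, predict_stacked, train_meta
from .utils import minmax_normalize

logger = logging.getLogger(__name__)

#: omic display names keyed by channel (reports use the display form)
OMIC_NAMES = {"mrna": "RNASeq", "meth": "Methylation", "mirna": "miRNA"}
#: accepted aliases for channel subsets
CHANNEL_ALIASES = {
    "rna": "mrna", "mrna": "mrna",
    "meth": "meth", "methylation": "meth",
    "mir": "mirna", "mirna": "mirna",
}

MODELS = ("RF", "GAT", "Stacked")
METRICS = ("accuracy", "precision", "recall", "f1", "roc_auc", "auprc")


class LeakageError(RuntimeError):
    pass


class LeakageAudit:
    """Book-keeping of which samples stood behind every fitted statistic."""

    def __init__(self) -> None:
        self.events: list[tuple[str, str, frozenset]] = []

    def register(self, fold_key: str, stage: str, sample_idx) -> None:
        self.events.append((fold_key, stage, frozenset(int(i) for i in sample_idx)))

    def check_fold(self, fold_key: str, test_idx) -> None:
        test = frozenset(int(i) for i in test_idx)
        for key, stage, fitted in self.events:
            if key != fold_key:
                continue
            overlap = fitted & test
            if overlap:
                raise LeakageError(
                    f"fold {fold_key}: stage {stage!r} was fitted on test rows "
                    f"{sorted(overlap)[:5]}"
                )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(k, s, len(ids)) for k, s, ids in self.events],
            columns=["fold", "stage", "n_fit_samples"],
        )


@dataclass
class CVPlan:
    """Repeated stratified k-fold assignment."""

    n_folds: int = 5
    n_repeats: int = 3
    seed: int = 0

    def folds(self, y: np.ndarray):
        """Yields (repeat, fold, train_idx, test_idx)."""
        y = np.asarray(y)
        rskf = RepeatedStratifiedKFold(
            n_splits=self.n_folds, n_repeats=self.n_repeats, random_state=self.seed
        )
        for i, (tr, te) in enumerate(rskf.split(np.zeros(len(y)), y)):
            yield i // self.n_folds, i % self.n_folds, tr, te


@dataclass
class PipelineConfig:
    """All tunables of one cross-validated run."""

    enet: ElasticNetParams = field(default_factory=ElasticNetParams)
    smote: SmoteParams = field(default_factory=SmoteParams)
    gat: GATConfig = field(default_factory=GATConfig)
    rf_trees: int = 500
    ridge_strength: float = 1.0
    inner_folds: int = 5
    subset: tuple[str, ...] = ("mrna", "meth", "mirna")
    variance_tol: float = 1e-12
    seed: int = 0

    def __post_init__(self) -> None:
        subset = tuple(CHANNEL_ALIASES[s.strip().lower()] for s in self.subset)
        if not subset:
            raise ValueError("channel subset must be non-empty")
        self.subset = tuple(c for c in CHANNELS if c in subset)


@dataclass
class CVResult:
    fold_results: pd.DataFrame
    rf_importance: pd.DataFrame  # folds x genes
    attention: pd.DataFrame  # folds x genes
    selected: pd.DataFrame  # per-fold selected features
    audit: LeakageAudit
    classes: np.ndarray

    def mean_metric(self, model: str, metric: str = "accuracy") -> float:
        df = self.fold_results
        return float(df.loc[df["model"] == model, metric].mean())

    def summary(self) -> pd.DataFrame:
        rows = []
        for model in MODELS:
            df = self.fold_results[self.fold_results["model"] == model]
            row = {"model": model}
            for metric in METRICS:
                row[metric] = f"{df[metric].mean():.3f} ± {df[metric].std(ddof=1):.3f}"
            rows.append(row)
        return pd.DataFrame(rows)

    def ttest_table(self) -> pd.DataFrame:
        """Paired comparisons of the stacked model against each base model."""
        rows = []
        df = self.fold_results.sort_values(["repeat", "fold"])
        for metric in ("roc_auc", "auprc"):
            hybrid = df.loc[df["model"] == "Stacked", metric].to_numpy()
            for base in ("RF", "GAT"):
                other = df.loc[df["model"] == base, metric].to_numpy()
                t, p = paired_ttest(hybrid, other)
                rows.append({"metric": metric, "comparison": f"Stacked vs. {base}",
                             "t_statistic": t, "p_value": p})
        return pd.DataFrame(rows)


class _FoldFit:
    """Frozen preprocessing + both base models for one training partition."""

    def __init__(self, cfg: PipelineConfig, Xw: np.ndarray, col_keys,
                 network: PPINetwork, y: np.ndarray, classes: np.ndarray,
                 train_idx, seed: int, fold_key: str,
                 audit: LeakageAudit | None = None,
                 unsafe_global_standardize: bool = False,
                 n_all: int | None = None):
        self.cfg = cfg
        self.col_keys = col_keys
        self.network = network
        self.classes = classes
        train_idx = np.asarray(train_idx)
        Xtr = Xw[train_idx]
        ytr = y[train_idx]

        if unsafe_global_standardize:
            # deliberate negative control: statistics from the whole dataset
            basis = Xw
            basis_idx = np.arange(len(Xw) if n_all is None else n_all)
        else:
            basis = Xtr
            basis_idx = train_idx
        self.keep = basis.var(axis=0) > cfg.variance_tol
        self.mu = basis[:, self.keep].mean(axis=0)
        self.sd = basis[:, self.keep].std(axis=0)
        self.sd[self.sd == 0] = 1.0
        if audit is not None:
            audit.register(fold_key, "variance_filter+standardize", basis_idx)

        Xtr_s = (Xtr[:, self.keep] - self.mu) / self.sd
        self.sel, self.coefs, self.lambda_star = select(
            Xtr_s, ytr, cfg.enet, seed=seed
        )
        if audit is not None:
            audit.register(fold_key, "elasticnet_select", train_idx)

        X_rf, y_aug, smote_audit = smote_balance(
            Xtr_s[:, self.sel], ytr, SmoteParams(k=cfg.smote.k, seed=seed)
        )
        if audit is not None:
            audit.register(fold_key, "smote", train_idx)
        counts = dict(zip(*np.unique(y_aug, return_counts=True)))
        logger.info("fold %s: %d features selected (lambda*=%.2g), class counts "
                    "post-SMOTE %s", fold_key, len(self.sel), self.lambda_star, counts)

        self.rf = rf_mod.train_forest(X_rf, y_aug, n_trees=cfg.rf_trees, seed=seed)

        # GAT sees the same augmented cohort: the recorded SMOTE interpolations
        # are re-applied to the full standardized row before graph assembly
        synth_full = interpolate_rows(Xtr_s, smote_audit)
        X_full_aug = np.vstack([Xtr_s, synth_full])
        gat_cfg = GATConfig(**{**cfg.gat.__dict__, "seed": seed})
        self.gat = GATClassifier(gat_cfg, network.edge_index(), network.n_nodes)
        self.gat.fit(self._to_tensor(X_full_aug), y_aug)
        self._train_tensor = self._to_tensor(Xtr_s)

        if not np.array_equal(self.rf.classes_, classes) or not np.array_equal(
            self.gat.classes_, classes
        ):
            raise RuntimeError("class order mismatch between arms")

    def _to_tensor(self, X_s: np.ndarray) -> np.ndarray:
        """Standardized selected columns -> node-feature tensor (others zero)."""
        node_pos = {g: i for i, g in enumerate(self.network.nodes)}
        chan_pos = {c: k for k, c in enumerate(CHANNELS)}
        T = np.zeros((X_s.shape[0], self.network.n_nodes, len(CHANNELS)))
        kept_keys = [k for k, keep in zip(self.col_keys, self.keep) if keep]
        for j in self.sel:
            gene, channel = kept_keys[j]
            i = node_pos.get(gene)
            if i is not None:
                T[:, i, chan_pos[channel]] = X_s[:, j]
        return T

    def transform(self, X_rows: np.ndarray) -> np.ndarray:
        return (X_rows[:, self.keep] - self.mu) / self.sd

    def predict_blocks(self, X_rows: np.ndarray):
        X_s = self.transform(X_rows)
        _, rf_probs = rf_mod.predict_vote(self.rf, X_s[:, self.sel])
        gat_probs = self.gat.predict_proba(self._to_tensor(X_s))
        return rf_probs, gat_probs

    def selected_frame(self) -> pd.DataFrame:
        kept_keys = [k for k, keep in zip(self.col_keys, self.keep) if keep]
        rows = []
        for j in self.sel:
            gene, channel = kept_keys[j]
            rows.append({"gene": gene, "channel": channel,
                         "modality": OMIC_NAMES[channel],
                         "coefficient": float(np.abs(self.coefs[j]).max())})
        return pd.DataFrame(rows)

    def gene_importance(self, genes: list[str]) -> np.ndarray:
        """RF impurity importance summed over each gene's selected channels."""
        imp = rf_mod.importance(self.rf)
        kept_keys = [k for k, keep in zip(self.col_keys, self.keep) if keep]
        gidx = {g: i for i, g in enumerate(genes)}
        out = np.zeros(len(genes))
        for v, j in zip(imp, self.sel):
            gene, _ = kept_keys[j]
            out[gidx[gene]] += v
        return out

    def attention_scores(self, genes: list[str]) -> np.ndarray:
        """GAT incoming-attention mass per gene (training graphs), on the
        full gene universe (genes outside the network score 0)."""
        scores = self.gat.node_attention_scores(self._train_tensor)
        gidx = {g: i for i, g in enumerate(genes)}
        out = np.zeros(len(genes))
        for g, s in zip(self.network.nodes, scores):
            out[gidx[g]] = s
        return out


def run_cv(
    gene_table: GeneTable,
    network: PPINetwork,
    y: np.ndarray,
    cfg: PipelineConfig | None = None,
    plan: CVPlan | None = None,
    unsafe_global_standardize: bool = False,
) -> CVResult:
    """Repeated stratified CV of RF, GAT and the stacked hybrid.

    ``unsafe_global_standardize`` injects a whole-dataset standardisation step
    and exists only as a negative control for the leakage audit: the run then
    aborts with :class:`LeakageError`.
    """
    cfg = cfg or PipelineConfig()
    plan = plan or CVPlan(seed=cfg.seed)
    y = np.asarray(y)
    classes = np.unique(y)

    Xw_full, col_keys_full = gene_table.wide()
    use = [k for k, (_, c) in enumerate(col_keys_full) if c in cfg.subset]
    Xw = Xw_full[:, use]
    col_keys = [col_keys_full[k] for k in use]

    audit = LeakageAudit()
    records = []
    rf_imp_rows, att_rows, sel_frames = [], [], []
    for repeat, fold, tr, te in plan.folds(y):
        fold_key = f"r{repeat}f{fold}"
        seed = (cfg.seed * 1000003 + repeat * 10007 + fold * 101) % (2**31)

        fit = _FoldFit(cfg, Xw, col_keys, network, y, classes, tr, seed,
                       fold_key, audit=audit,
                       unsafe_global_standardize=unsafe_global_standardize,
                       n_all=len(y))

        def _inner_fit_predict(inner_tr, inner_te, _tr=tr, _seed=seed,
                               _key=fold_key):
            inner_fit = _FoldFit(cfg, Xw, col_keys, network, y, classes,
                                 _tr[inner_tr], _seed + 1, _key + "-inner",
                                 audit=audit)
            rf_p, gat_p = inner_fit.predict_blocks(Xw[_tr[inner_te]])
            return np.hstack([rf_p, gat_p])

        meta, provenance = oof_meta_features(
            _inner_fit_predict, y[tr], inner_folds=cfg.inner_folds, seed=seed
        )
        audit.register(fold_key, "meta_features", tr)
        meta_model = train_meta(meta, y[tr], ridge_strength=cfg.ridge_strength)
        audit.register(fold_key, "meta_model", tr)

        audit.check_fold(fold_key, te)
        audit.check_fold(fold_key + "-inner", te)

        rf_probs, gat_probs = fit.predict_blocks(Xw[te])
        stack_probs, _ = predict_stacked(meta_model, rf_probs, gat_probs)
        for model, probs in (("RF", rf_probs), ("GAT", gat_probs),
                             ("Stacked", stack_probs)):
            rec = {"model": model, "repeat": repeat, "fold": fold}
            rec.update(compute_metrics(y[te], probs, classes))
            records.append(rec)

        rf_imp_rows.append(fit.gene_importance(gene_table.genes))
        att_rows.append(fit.attention_scores(gene_table.genes))
        sf = fit.selected_frame()
        sf.insert(0, "fold", fold)
        sf.insert(0, "repeat", repeat)
        sel_frames.append(sf)

    fold_results = pd.DataFrame(records)
    return CVResult(
        fold_results=fold_results,
        rf_importance=pd.DataFrame(rf_imp_rows, columns=gene_table.genes),
        attention=pd.DataFrame(att_rows, columns=gene_table.genes),
        selected=pd.concat(sel_frames, ignore_index=True),
        audit=audit,
        classes=classes,
    )


def compute_metrics(y_true: np.ndarray, probs: np.ndarray,
                    classes: np.ndarray) -> dict[str, float]:
    """Accuracy, macro precision/recall/F1 and one-vs-rest macro AUC/AUPRC.

    Classes absent from ``y_true`` (possible in tiny folds) are excluded from
    the AUC macro averages with a warning.
    """
    y_true = np.asarray(y_true)
    probs = np.asarray(probs, dtype=float)
    if len(y_true) != len(probs):
        raise ValueError("length mismatch between labels and probabilities")
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    y_pred = classes[np.argmax(probs, axis=1)]
    out = {
        "accuracy": accuracy_score(y_true, y_pred),
        "precision": precision_score(y_true, y_pred, labels=classes,
                                     average="macro", zero_division=0),
        "recall": recall_score(y_true, y_pred, labels=classes,
                               average="macro", zero_division=0),
        "f1": f1_score(y_true, y_pred, labels=classes, average="macro",
                       zero_division=0),
    }
    aucs, auprcs = [], []
    for k, cls in enumerate(classes):
        pos = (y_true == cls).astype(int)
        if pos.min() == pos.max():
            logger.warning("compute_metrics: class %r absent or exhaustive in "
                           "fold, excluded from AUC macro", cls)
            continue
        aucs.append(roc_auc_score(pos, probs[:, k]))
        auprcs.append(average_precision_score(pos, probs[:, k]))
    out["roc_auc"] = float(np.mean(aucs)) if aucs else np.nan
    out["auprc"] = float(np.mean(auprcs)) if auprcs else np.nan
    return {k: float(v) for k, v in out.items()}


def paired_ttest(metric_a, metric_b):
    """Two-sided paired t-test on fold-wise differences, df = n - 1.

    Degenerate branches: identically zero differences give (0, 1); constant
    non-zero differences give (+-inf, 0).
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need equal-length paired vectors with n >= 2")
    d = a - b
    if np.all(d == 0):
        return 0.0, 1.0
    sd = d.std(ddof=1)
    # constant differences (up to float fuzz) have no within-pair variance
    if sd <= 1e-12 * max(1.0, abs(d.mean())):
        return float(np.sign(d.mean()) * np.inf), 0.0
    t = d.mean() / (sd / np.sqrt(len(d)))
    p = 2 * stats.t.sf(abs(t), df=len(d) - 1)
    return float(t), float(p)


@dataclass
class AnovaResult:
    gene: str
    f_stats: dict[str, float]
    p_values: dict[str, float]
    best_omic: str | None
    lowest_p: float

    @property
    def skipped(self) -> bool:
        return self.best_omic is None


def anova_per_gene(gene: str, channel_values: dict[str, np.ndarray],
                   labels: np.ndarray) -> AnovaResult:
    """One-way ANOVA of each omic channel against the class labels.

    All-zero channels are skipped (the gene has no measurement in that layer);
    the best omic is the one with the smallest p-value.
    """
    labels = np.asarray(labels)
    groups_idx = [np.flatnonzero(labels == c) for c in np.unique(labels)]
    if sum(len(g) > 0 for g in groups_idx) < 2:
        logger.warning("anova_per_gene(%s): fewer than 2 non-empty groups", gene)
        return AnovaResult(gene, {}, {}, None, np.nan)
    f_stats, p_values = {}, {}
    for channel, values in channel_values.items():
        values = np.asarray(values, dtype=float)
        if np.all(values == 0):
            continue
        if np.ptp(values) == 0:
            f, p = 0.0, 1.0
        else:
            f, p = stats.f_oneway(*(values[g] for g in groups_idx))
            if not np.isfinite(f):
                f, p = 0.0, 1.0
        name = OMIC_NAMES.get(channel, channel)
        f_stats[name] = float(f)
        p_values[name] = float(p)
    if not p_values:
        return AnovaResult(gene, {}, {}, None, np.nan)
    best = min(p_values, key=lambda k: (p_values[k], k))
    return AnovaResult(gene, f_stats, p_values, best, p_values[best])


def anova_table(gene_table: GeneTable, labels: np.ndarray) -> pd.DataFrame:
    """Per-gene best-omic ANOVA over the whole cohort (descriptive report)."""
    rows = []
    for j, gene in enumerate(gene_table.genes):
        res = anova_per_gene(
            gene,
            {c: gene_table.channels[c][:, j] for c in CHANNELS},
            labels,
        )
        rows.append({"gene": gene, "best_omic": res.best_omic,
                     "p_value": res.lowest_p})
    return pd.DataFrame(rows)


__all__ = [
    "AnovaResult", "CVPlan", "CVResult", "LeakageAudit", "LeakageError",
    "PipelineConfig", "anova_per_gene", "anova_table", "compute_metrics",
    "minmax_normalize", "paired_ttest", "run_cv",
]
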