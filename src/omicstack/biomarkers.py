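"""Biomarker ranking from RF importance and GAT attention.

Per-fold RF impurity importances and per-fold attention masses are averaged
over all folds and repeats, each component min-max scaled to [0, 1], and
combined as w * rf + (1 - w) * attention (w = 0.5 by default, so the RF-only
and attention-only views are the w = 1 / w = 0 endpoints). Each ranked gene is
annotated with the omic layer that best separates the subtypes (one-way ANOVA,
smallest p-value).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .utils import minmax_normalize


def aggregate_importances(per_fold_scores: pd.DataFrame) -> pd.Series:
    """Mean over folds/repeats, then min-max scaled to [0, 1].

    ``per_fold_scores`` is folds x genes; genes missing from a fold's
    selection are expected to carry 0 already.
    """
    if len(per_fold_scores) == 0:
        raise ValueError("no folds to aggregate")
    means = per_fold_scores.mean(axis=0)
    return pd.Series(minmax_normalize(means.to_numpy()), index=means.index)


def combine_and_rank(rf_scores: pd.Series, attention_scores: pd.Series,
                     weight: float = 0.5) -> pd.DataFrame:
    """Weighted hybrid score, sorted descending; ties break lexicographically."""
    if not 0.0 <= weight <= 1.0:
        raise ValueError("weight must lie in [0, 1]")
    if set(rf_scores.index) != set(attention_scores.index):
        diff = sorted(set(rf_scores.index) ^ set(attention_scores.index))
        raise ValueError(f"gene universes differ: {diff[:10]}")
    genes = sorted(rf_scores.index)
    rf = rf_scores.reindex(genes)
    att = attention_scores.reindex(genes)
    combined = weight * rf + (1.0 - weight) * att
    df = pd.DataFrame(
        {"gene": genes, "rf_importance": rf.to_numpy(),
         "attention_score": att.to_numpy(), "combined": combined.to_numpy()}
    )
    df = df.sort_values(["combined", "gene"], ascending=[False, True],
                        kind="mergesort").reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df


def annotate_best_omic(ranking: pd.DataFrame, anova: pd.DataFrame) -> pd.DataFrame:
    """Attach best_omic and its p-value; genes without ANOVA are flagged."""
    merged = ranking.merge(anova[["gene", "best_omic", "p_value"]],
                           on="gene", how="left")
    merged["anova_missing"] = merged["best_omic"].isna()
    return merged


def precision_at_k(ranking: pd.DataFrame, truth_genes, k: int = 20) -> float:
    """Fraction of the top-k combined ranking that are planted truth genes."""
    truth = set(truth_genes)
    top = ranking.nsmallest(k, "rank")["gene"]
    return float(np.mean([g in truth for g in top]))
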