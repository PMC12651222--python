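"""Ridge-logistic stacking of the RF and GAT class probabilities.

The meta-learner is a multinomial logistic regression with an L2 penalty on
the coefficients (intercepts unpenalised) — the symmetric three-class
extension of the binary sigmoid meta-model. Its six inputs per patient are
the three RF vote fractions and the three GAT softmax probabilities.

To keep the meta-learner honest, its training rows are out-of-fold: the
training fold is split again (stratified), the full base pipeline — scaling,
feature selection, oversampling, both base models — is refit on each inner
complement, and each training row receives predictions only from fits that
never saw it. The fold bookkeeping needed to assert that is returned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold


def oof_meta_features(fit_predict, y: np.ndarray, inner_folds: int = 5,
                      seed: int = 0):
    """Out-of-fold meta matrix [n, 6]: 3 RF probabilities ++ 3 GAT.

    ``fit_predict(train_idx, test_idx)`` must run the complete fold-confined
    base pipeline on ``train_idx`` and return the [len(test_idx), 6] block.
    Returns ``(meta, provenance)`` where ``provenance[i]`` is the set of row
    indices the fit that predicted row ``i`` was trained on.
    """
    y = np.asarray(y)
    n = len(y)
    meta = np.full((n, 6), np.nan)
    provenance: list[frozenset | None] = [None] * n
    skf = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    for tr, te in skf.split(np.zeros(n), y):
        block = fit_predict(tr, te)
        meta[te] = block
        held = frozenset(int(i) for i in tr)
        for i in te:
            provenance[int(i)] = held
    if np.isnan(meta).any():
        raise RuntimeError("some rows received no out-of-fold prediction")
    for i, held in enumerate(provenance):
        if i in held:
            raise RuntimeError(f"leakage: row {i} present in its own meta-feature fit")
    return meta, provenance


@dataclass
class MetaModel:
    estimator: LogisticRegression
    mean: np.ndarray
    scale: np.ndarray
    classes_: np.ndarray
    ridge_strength: float

    def transform(self, M: np.ndarray) -> np.ndarray:
        return (np.asarray(M, dtype=float) - self.mean) / self.scale

    def predict_proba(self, M: np.ndarray) -> np.ndarray:
        return self.estimator.predict_proba(self.transform(M))


def train_meta(meta: np.ndarray, y: np.ndarray, ridge_strength: float = 1.0,
               tol: float = 1e-8, max_iter: int = 5000) -> MetaModel:
    """Multinomial ridge-logistic fit on standardised meta features."""
    meta = np.asarray(meta, dtype=float)
    if not np.all(np.isfinite(meta)):
        raise ValueError("non-finite meta features")
    mean = meta.mean(axis=0)
    scale = meta.std(axis=0)
    scale[scale == 0] = 1.0
    est = LogisticRegression(
        C=1.0 / ridge_strength,  # L2 penalty (default), intercept unpenalised
        solver="lbfgs",
        tol=tol,
        max_iter=max_iter,
    )
    est.fit((meta - mean) / scale, y)
    n_iter = int(np.max(est.n_iter_))
    if n_iter >= max_iter:
        raise RuntimeError(f"meta-model did not converge in {n_iter} iterations")
    return MetaModel(est, mean, scale, est.classes_, ridge_strength)


def predict_stacked(meta_model: MetaModel, rf_probs: np.ndarray,
                    gat_probs: np.ndarray):
    """Final probabilities and labels from base-model probability blocks."""
    rf_probs = np.asarray(rf_probs, dtype=float)
    gat_probs = np.asarray(gat_probs, dtype=float)
    if rf_probs.shape != gat_probs.shape or rf_probs.shape[1] != 3:
        raise ValueError("expected two aligned [n, 3] probability blocks")
    M = np.hstack([rf_probs, gat_probs])
    probs = meta_model.predict_proba(M)
    labels = meta_model.classes_[np.argmax(probs, axis=1)]
    return probs, labels
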