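"""Synthetic minority oversampling (SMOTE).

Every minority class is raised to the majority count by convex interpolation:
a synthetic point is x_new = x_i + delta * (x_j - x_i) with x_i a minority
sample, x_j one of its k nearest minority neighbours (Euclidean), and
delta ~ U(0, 1). Original rows are preserved verbatim and come first in the
output; parent pairs and deltas are recorded for auditability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)


@dataclass
class SmoteParams:
    k: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")


def smote_balance(
    X: np.ndarray,
    y: np.ndarray,
    params: SmoteParams | None = None,
    delta: float | None = None,
):
    """Equalise all class counts to the majority count.

    Returns ``(X_aug, y_aug, audit)`` where ``audit`` has one row per
    synthetic sample with its parent row indices (into the input X) and the
    delta used. ``delta`` forces a fixed interpolation weight (endpoint
    checks); by default each synthetic point draws its own U(0,1).
    Already-balanced input is returned unchanged (empty audit).
    """
    params = params or SmoteParams()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(params.seed)
    classes, counts = np.unique(y, return_counts=True)
    n_max = counts.max()

    new_X: list[np.ndarray] = []
    new_y: list[np.ndarray] = []
    audit_rows = []
    for cls, cnt in zip(classes, counts):
        need = int(n_max - cnt)
        if need == 0:
            continue
        if cnt < 2:
            raise ValueError(
                f"class {cls!r} has {cnt} sample(s); SMOTE needs at least 2 "
                "to form a neighbour pair"
            )
        k_eff = min(params.k, cnt - 1)
        if k_eff < params.k:
            logger.info("smote_balance: class %r has %d samples, k reduced %d -> %d",
                        cls, cnt, params.k, k_eff)
        rows = np.flatnonzero(y == cls)
        Xc = X[rows]
        nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(Xc)
        neigh = nn.kneighbors(Xc, return_distance=False)[:, 1:]  # drop self
        seeds = rng.integers(0, cnt, size=need)
        picks = rng.integers(0, k_eff, size=need)
        deltas = np.full(need, delta, dtype=float) if delta is not None else rng.random(need)
        xi = Xc[seeds]
        xj = Xc[neigh[seeds, picks]]
        synth = xi + deltas[:, None] * (xj - xi)
        new_X.append(synth)
        new_y.append(np.full(need, cls, dtype=y.dtype))
        for s, (i_loc, d) in enumerate(zip(seeds, deltas)):
            audit_rows.append(
                (int(rows[i_loc]), int(rows[neigh[seeds[s], picks[s]]]), float(d))
            )

    audit = pd.DataFrame(audit_rows, columns=["parent_i", "parent_j", "delta"])
    audit.index.name = "synthetic_row"
    if not new_X:
        return X, y, audit
    X_aug = np.vstack([X] + new_X)
    y_aug = np.concatenate([y] + new_y)
    audit.index = np.arange(len(X), len(X_aug))
    return X_aug, y_aug, audit


def interpolate_rows(X: np.ndarray, audit: pd.DataFrame) -> np.ndarray:
    """Re-apply recorded (parent_i, parent_j, delta) triples to another matrix.

    Used to carry the exact same synthetic cohort into a second feature space
    (e.g. the per-gene node-feature channels consumed by the graph model), so
    both classifier arms train on identical augmented samples.
    """
    if len(audit) == 0:
        return np.zeros((0, X.shape[1]))
    xi = X[audit["parent_i"].to_numpy()]
    xj = X[audit["parent_j"].to_numpy()]
    d = audit["delta"].to_numpy()[:, None]
    return xi + d * (xj - xi)
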