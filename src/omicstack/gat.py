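"""Graph attention network over the shared PPI topology.

Every patient is one graph: identical edges, patient-specific node features
(one gene = one node, channels mrna/meth/mirna). A two-layer multi-head GAT
is followed by mean pooling over nodes and an affine softmax classifier:

    h'_i      = W h_i                                  (per head)
    e_ij      = LeakyReLU( a . [h'_i || h'_j] )        (j in N_i, incl. self)
    alpha_ij  = softmax_j( e_ij )
    h_i^(l+1) = sigma( sum_j alpha_ij h'_j )           (sigma = ELU)

with the K heads concatenated after the hidden layer and averaged after the
output layer. Because the topology is shared, the forward and backward passes
are vectorised across patients: edges (with self-loops) are sorted by
destination node and attention softmax / aggregation run as segment
operations over that ordering. Gradients are derived by hand; training is
full-batch Adam with decoupled weight decay, dropout on inputs, hidden
features and attention coefficients, and early stopping on a stratified
validation split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .utils import minmax_normalize


@dataclass
class GATConfig:
    """Architecture and optimisation settings (defaults: 8 heads, 64 hidden
    channels, dropout 0.5, learning rate 1e-3, weight decay 1e-4)."""

    heads: int = 8
    hidden: int = 64
    dropout: float = 0.5
    learning_rate: float = 1e-3
    weight_decay: float = 1e-4
    layers: int = 2
    leaky_slope: float = 0.2
    epochs: int = 200
    patience: int = 20
    val_fraction: float = 0.1
    seed: int = 0
    dtype: str = "float64"

    def __post_init__(self) -> None:
        if self.heads < 1 or self.hidden < 1:
            raise ValueError("heads and hidden must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.layers != 2:
            raise ValueError("this implementation is the canonical 2-layer stack")


class EdgeStructure:
    """Directed edge arrays (both directions + self-loops) sorted by
    destination, with segment boundaries for softmax/aggregation and a second
    (source-sorted) permutation for scatter-by-source in the backward pass."""

    def __init__(self, edge_index: np.ndarray, n_nodes: int):
        und_src, und_dst = np.asarray(edge_index)
        loops = np.arange(n_nodes)
        src = np.concatenate([und_src, und_dst, loops])
        dst = np.concatenate([und_dst, und_src, loops])
        order = np.lexsort((src, dst))
        self.src = src[order]
        self.dst = dst[order]
        self.n_nodes = int(n_nodes)
        self.n_directed = len(self.src)
        # self-loops guarantee every node owns a non-empty dst segment
        self.dst_starts = np.searchsorted(self.dst, np.arange(n_nodes))
        self.perm_src = np.lexsort((self.dst, self.src))
        src_sorted = self.src[self.perm_src]
        self.src_starts = np.searchsorted(src_sorted, np.arange(n_nodes))
        self.self_mask = self.src == self.dst

    def seg_softmax(self, e: np.ndarray, axis: int = -1) -> np.ndarray:
        """Softmax over the incoming edges of each destination node."""
        m = np.maximum.reduceat(e, self.dst_starts, axis=axis)
        ex = np.exp(e - np.take(m, self.dst, axis=axis))
        s = np.add.reduceat(ex, self.dst_starts, axis=axis)
        return ex / np.take(s, self.dst, axis=axis)

    def sum_by_dst(self, x: np.ndarray, axis: int) -> np.ndarray:
        return np.add.reduceat(x, self.dst_starts, axis=axis)

    def sum_by_src(self, x: np.ndarray, axis: int) -> np.ndarray:
        x = np.take(x, self.perm_src, axis=axis)
        return np.add.reduceat(x, self.src_starts, axis=axis)


def elu(z: np.ndarray) -> np.ndarray:
    return np.where(z > 0, z, np.expm1(np.minimum(z, 0.0)))


def _elu_grad(z: np.ndarray) -> np.ndarray:
    return np.where(z > 0, 1.0, np.exp(np.minimum(z, 0.0)))


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[-2], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def init_params(config: GATConfig, n_features: int, n_classes: int,
                rng: np.random.Generator) -> dict[str, np.ndarray]:
    K, H = config.heads, config.hidden
    return {
        "W1": _glorot(rng, (K, n_features, H)),
        "a1": _glorot(rng, (K, 1, 2 * H))[:, 0, :],
        "W2": _glorot(rng, (K, K * H, H)),
        "a2": _glorot(rng, (K, 1, 2 * H))[:, 0, :],
        "Wout": _glorot(rng, (H, n_classes)),
        "bout": np.zeros(n_classes),
    }


def _layer_forward(H, W, a, es: EdgeStructure, slope: float, mode: str,
                   drop: float, rng: np.random.Generator | None):
    """One multi-head attention layer; returns pre-activation Z and a cache.

    Internal layout keeps the edge axis second ([patients, edges, heads, ...])
    so softmax/aggregation are contiguous reduceat calls and the feature
    transforms are plain 2-D matmuls.
    """
    K, Fin, Fh = W.shape
    P, N, _ = H.shape
    Wall = np.ascontiguousarray(W.transpose(1, 0, 2).reshape(Fin, K * Fh))
    Hp = (H.reshape(P * N, Fin) @ Wall).reshape(P, N, K, Fh)
    a_center, a_neigh = a[:, :Fh], a[:, Fh:]
    sd = (Hp * a_center[None, None]).sum(-1)  # [P,N,K]
    ss = (Hp * a_neigh[None, None]).sum(-1)
    logit = sd[:, es.dst] + ss[:, es.src]  # [P,E,K]
    e = np.where(logit > 0, logit, slope * logit)
    alpha = es.seg_softmax(e, axis=1)
    if rng is not None and drop > 0:
        amask = (rng.random(alpha.shape, dtype=alpha.dtype) >= drop).astype(alpha.dtype) / (1.0 - drop)
        alpha_used = alpha * amask
    else:
        amask = None
        alpha_used = alpha
    Hp_src = Hp[:, es.src]  # [P,E,K,Fh]
    agg = es.sum_by_dst(alpha_used[..., None] * Hp_src, axis=1)  # [P,N,K,Fh]
    if mode == "concat":
        Z = agg.reshape(P, N, K * Fh)
    else:
        Z = agg.mean(axis=2)
    cache = dict(H=H, Hp=Hp, Hp_src=Hp_src, logit=logit, alpha=alpha,
                 alpha_used=alpha_used, amask=amask, W=W, Wall=Wall, a=a,
                 mode=mode, slope=slope)
    return Z, alpha, cache


def _layer_backward(dZ, cache, es: EdgeStructure):
    W, a = cache["W"], cache["a"]
    K, Fin, Fh = W.shape
    P, N, _ = cache["H"].shape
    Hp, alpha, alpha_used = cache["Hp"], cache["alpha"], cache["alpha_used"]
    a_center, a_neigh = a[:, :Fh], a[:, Fh:]

    if cache["mode"] == "concat":
        dagg = dZ.reshape(P, N, K, Fh)
    else:
        dagg = np.broadcast_to(dZ[:, :, None] / K, (P, N, K, Fh))
    dmsg = dagg[:, es.dst]  # [P,E,K,Fh]
    dalpha_used = (dmsg * cache["Hp_src"]).sum(-1)  # [P,E,K]
    dHp = es.sum_by_src(alpha_used[..., None] * dmsg, axis=1)  # [P,N,K,Fh]

    dalpha = dalpha_used if cache["amask"] is None else dalpha_used * cache["amask"]
    t = es.sum_by_dst(alpha * dalpha, axis=1)
    de = alpha * (dalpha - t[:, es.dst])
    dlogit = np.where(cache["logit"] > 0, de, cache["slope"] * de)
    dsd = es.sum_by_dst(dlogit, axis=1)  # [P,N,K]
    dss = es.sum_by_src(dlogit, axis=1)
    dHp += dsd[..., None] * a_center[None, None]
    dHp += dss[..., None] * a_neigh[None, None]

    da = np.concatenate(
        [
            (dsd[..., None] * Hp).sum(axis=(0, 1)),
            (dss[..., None] * Hp).sum(axis=(0, 1)),
        ],
        axis=1,
    )
    dHp2 = dHp.reshape(P * N, K * Fh)
    dWall = cache["H"].reshape(P * N, Fin).T @ dHp2  # [Fin, K*Fh]
    dW = np.ascontiguousarray(dWall.reshape(Fin, K, Fh).transpose(1, 0, 2))
    dH = (dHp2 @ cache["Wall"].T).reshape(P, N, Fin)
    return dH, dW, da


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=-1, keepdims=True)


class GATClassifier:
    """Two-layer multi-head GAT with mean-pool readout over a fixed topology."""

    def __init__(self, config: GATConfig, edge_index: np.ndarray, n_nodes: int):
        self.config = config
        self.es = EdgeStructure(edge_index, n_nodes)
        self.params: dict[str, np.ndarray] | None = None
        self.classes_: np.ndarray | None = None
        self.loss_history_: list[float] = []

    # ------------------------------------------------------------------ core
    def _forward(self, X, params, train=False, rng=None, y_idx=None,
                 collect_attention=False):
        cfg = self.config
        drop = cfg.dropout if train else 0.0
        caches: dict = {}
        dt = params["Wout"].dtype
        H0 = np.asarray(X, dtype=dt)
        if train and drop > 0:
            mask0 = (rng.random(H0.shape, dtype=dt) >= drop).astype(dt) / (1.0 - drop)
            H0 = H0 * mask0
        Z1, alpha1, c1 = _layer_forward(H0, params["W1"], params["a1"], self.es,
                                        cfg.leaky_slope, "concat", drop,
                                        rng if train else None)
        H1 = elu(Z1)
        if train and drop > 0:
            mask1 = (rng.random(H1.shape, dtype=dt) >= drop).astype(dt) / (1.0 - drop)
            H1d = H1 * mask1
        else:
            mask1 = None
            H1d = H1
        Z2, alpha2, c2 = _layer_forward(H1d, params["W2"], params["a2"], self.es,
                                        cfg.leaky_slope, "average", drop,
                                        rng if train else None)
        H2 = elu(Z2)
        pooled = H2.mean(axis=1)
        logits = pooled @ params["Wout"] + params["bout"]
        probs = _softmax(logits)
        out = dict(probs=probs, pooled=pooled, logits=logits)
        if collect_attention:
            out["attention"] = [alpha1, alpha2]
        if y_idx is not None:
            p_true = np.clip(probs[np.arange(len(y_idx)), y_idx], 1e-12, None)
            out["loss"] = float(-np.mean(np.log(p_true)))
            caches.update(c1=c1, c2=c2, Z1=Z1, Z2=Z2, mask1=mask1, H1=H1, H2=H2)
            out["caches"] = caches
        return out

    def _backward(self, out, y_idx, params):
        c = out["caches"]
        P = len(y_idx)
        N = self.es.n_nodes
        Y = np.zeros_like(out["probs"])
        Y[np.arange(P), y_idx] = 1.0
        dlogits = (out["probs"] - Y) / P
        grads = {
            "Wout": out["pooled"].T @ dlogits,
            "bout": dlogits.sum(axis=0),
        }
        dpooled = dlogits @ params["Wout"].T
        dH2 = np.broadcast_to(dpooled[:, None, :] / N, c["H2"].shape)
        dZ2 = dH2 * _elu_grad(c["Z2"])
        dH1d, grads["W2"], grads["a2"] = _layer_backward(dZ2, c["c2"], self.es)
        if c["mask1"] is not None:
            dH1d = dH1d * c["mask1"]
        dZ1 = dH1d * _elu_grad(c["Z1"])
        _, grads["W1"], grads["a1"] = _layer_backward(dZ1, c["c1"], self.es)
        return grads

    # -------------------------------------------------------------- training
    def fit(self, X: np.ndarray, y: np.ndarray) -> "GATClassifier":
        cfg = self.config
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 1 or any(
            (y == cls).sum() < 1 for cls in self.classes_
        ):
            raise ValueError("need at least one graph per class")
        y_idx = np.searchsorted(self.classes_, y)
        rng = np.random.default_rng(cfg.seed)
        dt = np.dtype(cfg.dtype)
        self.params = {
            k: v.astype(dt)
            for k, v in init_params(cfg, X.shape[2], len(self.classes_), rng).items()
        }
        X = np.asarray(X, dtype=dt)
        self.loss_history_ = []
        if cfg.epochs == 0:
            return self

        tr_idx, va_idx = _stratified_holdout(y_idx, cfg.val_fraction, rng)
        m = {k: np.zeros_like(v) for k, v in self.params.items()}
        v = {k: np.zeros_like(v_) for k, v_ in self.params.items()}
        b1, b2, eps = 0.9, 0.999, 1e-8
        best_val = np.inf
        best_params = None
        stall = 0
        for epoch in range(1, cfg.epochs + 1):
            out = self._forward(X[tr_idx], self.params, train=True, rng=rng,
                                y_idx=y_idx[tr_idx])
            if not np.isfinite(out["loss"]):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}: {out['loss']}"
                )
            self.loss_history_.append(out["loss"])
            grads = self._backward(out, y_idx[tr_idx], self.params)
            lr = cfg.learning_rate
            for k in self.params:
                m[k] = b1 * m[k] + (1 - b1) * grads[k]
                v[k] = b2 * v[k] + (1 - b2) * grads[k] ** 2
                mhat = m[k] / (1 - b1**epoch)
                vhat = v[k] / (1 - b2**epoch)
                if k != "bout":  # decoupled weight decay, bias exempt
                    self.params[k] = self.params[k] * (1 - lr * cfg.weight_decay)
                self.params[k] = self.params[k] - lr * mhat / (np.sqrt(vhat) + eps)
            if va_idx is not None:
                val = self._forward(X[va_idx], self.params, y_idx=y_idx[va_idx])
                if val["loss"] < best_val - 1e-6:
                    best_val = val["loss"]
                    best_params = {k: p.copy() for k, p in self.params.items()}
                    stall = 0
                else:
                    stall += 1
                    if stall >= cfg.patience:
                        break
        if best_params is not None:
            self.params = best_params
        return self

    # ------------------------------------------------------------- inference
    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self.params is None:
            raise RuntimeError("model is not fitted")
        probs = self._forward(np.asarray(X), self.params)["probs"]
        return probs.astype(float)

    def predict(self, X: np.ndarray) -> np.ndarray:
        probs = self.predict_proba(X)
        return self.classes_[np.argmax(probs, axis=1)]

    def attention(self, X: np.ndarray) -> list[np.ndarray]:
        """Per layer, attention coefficients [n_patients, n_directed, heads]
        over the directed edge arrays of ``self.es`` (evaluation mode)."""
        if self.params is None:
            raise RuntimeError("model is not fitted")
        out = self._forward(np.asarray(X), self.params, collect_attention=True)
        return out["attention"]

    def node_attention_scores(self, X: np.ndarray, exclude_self: bool = True) -> np.ndarray:
        """Per gene, incoming attention mass sum_i alpha_ij averaged over
        patients, layers and heads; min-max scaled to [0, 1]. Self-loop mass
        is excluded by default (it reflects architecture, not biology)."""
        alphas = self.attention(X)
        es = self.es
        per_layer = []
        for alpha in alphas:
            a = alpha.mean(axis=(0, 2))  # [n_directed]
            if exclude_self:
                a = np.where(es.self_mask, 0.0, a)
            per_layer.append(es.sum_by_src(a, axis=0))
        return minmax_normalize(np.mean(per_layer, axis=0))


    # ----------------------------------------------------------- persistence
    def save(self, path: str) -> None:
        """Checkpoint: config, topology and parameters in one .npz file."""
        import json

        if self.params is None:
            raise RuntimeError("model is not fitted")
        np.savez(
            path,
            config=json.dumps(self.config.__dict__),
            classes=self.classes_.astype(str),
            src=self.es.src, dst=self.es.dst, n_nodes=self.es.n_nodes,
            **{f"param_{k}": v for k, v in self.params.items()},
        )

    @classmethod
    def load(cls, path: str) -> "GATClassifier":
        import json

        data = np.load(path, allow_pickle=False)
        config = GATConfig(**json.loads(str(data["config"])))
        n_nodes = int(data["n_nodes"])
        # reconstruct from the stored directed arrays: keep only one
        # direction of each non-loop edge
        src, dst = data["src"], data["dst"]
        keep = src < dst
        model = cls(config, np.stack([src[keep], dst[keep]]), n_nodes)
        model.params = {k[6:]: data[k] for k in data.files
                        if k.startswith("param_")}
        model.classes_ = data["classes"]
        return model

    def attention_frame(self, X: np.ndarray, node_names: list[str] | None = None):
        """Patient-averaged attention as a long table
        (layer, head, gene_i, gene_j, alpha); gene_i attends to gene_j."""
        import pandas as pd

        names = node_names or [str(i) for i in range(self.es.n_nodes)]
        rows = []
        for layer, alpha in enumerate(self.attention(X)):
            mean = alpha.mean(axis=0)  # [n_directed, heads]
            for k in range(mean.shape[1]):
                for e in range(self.es.n_directed):
                    rows.append((layer, k, names[self.es.dst[e]],
                                 names[self.es.src[e]], float(mean[e, k])))
        return pd.DataFrame(rows, columns=["layer", "head", "gene_i",
                                           "gene_j", "alpha"])


def _stratified_holdout(y_idx: np.ndarray, val_fraction: float,
                        rng: np.random.Generator):
    """Stratified validation split; no split if infeasible or fraction 0."""
    if val_fraction <= 0:
        return np.arange(len(y_idx)), None
    tr, va = [], []
    for cls in np.unique(y_idx):
        rows = np.flatnonzero(y_idx == cls)
        rows = rng.permutation(rows)
        n_val = max(1, int(round(val_fraction * len(rows))))
        if len(rows) - n_val < 1:
            return np.arange(len(y_idx)), None
        va.extend(rows[:n_val])
        tr.extend(rows[n_val:])
    return np.sort(np.array(tr)), np.sort(np.array(va))


def train_gat(graphs_X: np.ndarray, labels: np.ndarray, config: GATConfig,
              edge_index: np.ndarray, n_nodes: int):
    """Convenience wrapper: returns (fitted model, training loss history)."""
    model = GATClassifier(config, edge_index, n_nodes)
    model.fit(graphs_X, labels)
    return model, list(model.loss_history_)
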