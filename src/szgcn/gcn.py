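"""The hierarchical GCN classifier: architecture, training, inference.

Three blocks of (graph convolution -> TopK pooling -> readout); the three
readout vectors are summed and fed to a fully connected head
(2h -> h -> 2) with batch normalisation, ReLU and dropout.  Trained by
Adam on softmax cross-entropy with early stopping on an internal
stratified validation split.

Everything is plain NumPy with hand-derived gradients; the selection
step of TopK pooling is discrete, so (as in standard implementations)
gradients flow through the tanh gate and the projection scores of the
retained nodes only.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .graphs import BrainGraphSample
from .nn import normalized_adjacency, pool_size, topk_indices

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "TrainedModel",
    "init_params",
    "forward",
    "forward_trace",
    "predict_proba",
    "predict_label",
    "train",
    "stratified_holdout",
]

N_BLOCKS = 3
BN_EPS = 1e-5
BN_MOMENTUM = 0.1


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``pool_ratio`` must leave at least 20 survivors after the third
    pooling layer (the saliency procedure reads the top 20 nodes there);
    with the default 0.8 a 90-node graph pools 90 -> 72 -> 58 -> 47.
    """

    hidden_dim: int = 64
    pool_ratio: float = 0.8
    n_blocks: int = N_BLOCKS
    dropout: float = 0.5
    n_classes: int = 2
    use_batchnorm: bool = True

    def __post_init__(self) -> None:
        if self.n_blocks != N_BLOCKS:
            raise ValueError("architecture is fixed at 3 blocks")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must lie in [0, 1)")
        if not (0.0 < self.pool_ratio <= 1.0):
            raise ValueError("pool_ratio must lie in (0, 1]")

    def survivor_counts(self, n_nodes: int) -> list[int]:
        counts = []
        n = n_nodes
        for _ in range(self.n_blocks):
            n = pool_size(n, self.pool_ratio)
            counts.append(n)
        return counts

    def check_saliency_floor(self, n_nodes: int, minimum: int = 20) -> None:
        last = self.survivor_counts(n_nodes)[-1]
        if last < minimum:
            raise ValueError(
                f"pool_ratio {self.pool_ratio} leaves only {last} nodes after the "
                f"last pooling layer for N = {n_nodes}; saliency needs >= {minimum}"
            )


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation protocol: Adam, cross-entropy, early stopping."""

    learning_rate: float = 1e-4
    batch_size: int = 30
    max_epochs: int = 1000
    patience: int = 500
    val_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2")
        if not (0.0 < self.val_fraction < 1.0):
            raise ValueError("val_fraction must lie in (0, 1)")
        if self.max_epochs < 1 or self.patience < 0:
            raise ValueError("max_epochs >= 1 and patience >= 0 required")


@dataclass
class TrainedModel:
    """Fitted weights plus the training log and the configs that made them."""

    params: dict[str, np.ndarray]
    bn_stats: dict[str, np.ndarray]
    model_cfg: ModelConfig
    train_cfg: TrainConfig
    log: list[dict]
    best_epoch: int
    n_features: int

    def copy_weights(self) -> tuple[dict, dict]:
        return (
            {k: v.copy() for k, v in self.params.items()},
            {k: v.copy() for k, v in self.bn_stats.items()},
        )


# --------------------------------------------------------------------------
# parameters

def init_params(
    n_features: int, cfg: ModelConfig, rng: np.random.Generator
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Uniform fan-in initialisation; all randomness from ``rng``.

    Projection vectors are initialised non-negative: node activations are
    non-negative after ReLU, so a non-negative projection makes the
    initial pooling scores rank nodes by activation magnitude rather
    than by an arbitrary random direction.  With a sign-symmetric
    initialisation the selection orientation is a coin flip — networks
    that *drop* the most atypical nodes classify just as well as ones
    that retain them, but make selection-frequency saliency point away
    from the informative regions.
    """
    h = cfg.hidden_dim

    def uni(fan_in: int, shape) -> np.ndarray:
        bound = 1.0 / math.sqrt(fan_in)
        return rng.uniform(-bound, bound, size=shape)

    def uni_pos(fan_in: int, shape) -> np.ndarray:
        return rng.uniform(0.0, 1.0 / math.sqrt(fan_in), size=shape)

    params = {
        "W1": uni(n_features, (n_features, h)),
        "W2": uni(h, (h, h)),
        "W3": uni(h, (h, h)),
        "p1": uni_pos(h, (h,)),
        "p2": uni_pos(h, (h,)),
        "p3": uni_pos(h, (h,)),
        "Wf1": uni(2 * h, (2 * h, h)),
        "bf1": np.zeros(h),
        "gamma": np.ones(h),
        "beta": np.zeros(h),
        "Wf2": uni(h, (h, cfg.n_classes)),
        "bf2": np.zeros(cfg.n_classes),
    }
    bn_stats = {"mean": np.zeros(h), "var": np.ones(h)}
    return params, bn_stats


# --------------------------------------------------------------------------
# forward

def _graph_forward(
    params: dict, sample: BrainGraphSample, cfg: ModelConfig, want_cache: bool
):
    """Per-sample pass through the three conv/pool/readout blocks.

    Returns the summed readout vector, the per-block caches (or None) and
    the per-block selections mapped back to original node indices.
    """
    H = sample.features
    A = sample.adjacency
    h = cfg.hidden_dim
    g = np.zeros(2 * h)
    caches = [] if want_cache else None
    orig = np.arange(sample.n_nodes)
    selections = []
    for layer in range(1, N_BLOCKS + 1):
        W = params[f"W{layer}"]
        p = params[f"p{layer}"]
        S = normalized_adjacency(A)
        M = S @ H
        Z = M @ W
        Hc = np.maximum(Z, 0.0)
        norm = np.linalg.norm(p)
        if norm == 0:
            raise ValueError(f"projection vector p{layer} is zero")
        v = p / norm
        y = Hc @ v
        k = pool_size(Hc.shape[0], cfg.pool_ratio)
        idx = topk_indices(y, k)
        t = np.tanh(y)
        Hp = Hc[idx] * t[idx][:, None]
        A_next = A[np.ix_(idx, idx)]
        amax = Hp.argmax(axis=0)
        r = np.concatenate([Hp[amax, np.arange(Hp.shape[1])], Hp.mean(axis=0)])
        g = g + r
        orig = orig[idx]
        selections.append({"indices": orig.copy(), "scores": y[idx].copy()})
        if want_cache:
            caches.append(
                {"S": S, "M": M, "Z": Z, "Hc": Hc, "v": v, "norm": norm,
                 "y": y, "idx": idx, "t": t, "Hp": Hp, "amax": amax}
            )
        H, A = Hp, A_next
    return g, caches, selections


def _graph_backward(params: dict, caches: list[dict], dg: np.ndarray, grads: dict):
    """Backward through the three blocks given the summed-readout gradient."""
    h = dg.size // 2
    d_next: np.ndarray | None = None
    for layer in range(N_BLOCKS, 0, -1):
        c = caches[layer - 1]
        Hp, amax = c["Hp"], c["amax"]
        k = Hp.shape[0]
        dHp = np.tile(dg[h:] / k, (k, 1))
        dHp[amax, np.arange(h)] += dg[:h]
        if d_next is not None:
            dHp = dHp + d_next
        idx, t, Hc, v = c["idx"], c["t"], c["Hc"], c["v"]
        ti = t[idx]
        dHc = np.zeros_like(Hc)
        dHc[idx] = dHp * ti[:, None]
        dy = np.zeros(Hc.shape[0])
        dy[idx] = (dHp * Hc[idx]).sum(axis=1) * (1.0 - ti**2)
        dHc += np.outer(dy, v)
        dv = Hc.T @ dy
        grads[f"p{layer}"] += (dv - v * (v @ dv)) / c["norm"]
        dZ = dHc * (c["Z"] > 0)
        grads[f"W{layer}"] += c["M"].T @ dZ
        d_next = c["S"] @ (dZ @ params[f"W{layer}"].T)
    return d_next  # gradient w.r.t. the input features (unused)


def _head_forward(
    params: dict,
    bn_stats: dict,
    G: np.ndarray,
    cfg: ModelConfig,
    training: bool,
    rng: np.random.Generator | None,
):
    """Fully connected head on a batch of summed readouts (B x 2h)."""
    cache: dict = {}
    Z1 = G @ params["Wf1"] + params["bf1"]
    if cfg.use_batchnorm:
        if training:
            mu = Z1.mean(axis=0)
            var = Z1.var(axis=0)
            bn_stats["mean"] = (1 - BN_MOMENTUM) * bn_stats["mean"] + BN_MOMENTUM * mu
            bn_stats["var"] = (1 - BN_MOMENTUM) * bn_stats["var"] + BN_MOMENTUM * var
        else:
            mu, var = bn_stats["mean"], bn_stats["var"]
        std = np.sqrt(var + BN_EPS)
        Zh = (Z1 - mu) / std
        B1 = params["gamma"] * Zh + params["beta"]
        cache.update(Zh=Zh, std=std)
    else:
        B1 = Z1
    A1 = np.maximum(B1, 0.0)
    if training and cfg.dropout > 0:
        mask = (rng.random(A1.shape) >= cfg.dropout) / (1.0 - cfg.dropout)
    else:
        mask = np.ones_like(A1)
    D1 = A1 * mask
    logits = D1 @ params["Wf2"] + params["bf2"]
    cache.update(G=G, B1=B1, mask=mask, D1=D1)
    return logits, cache


def _head_backward(params: dict, cache: dict, dlogits: np.ndarray, cfg: ModelConfig, grads: dict):
    grads["Wf2"] += cache["D1"].T @ dlogits
    grads["bf2"] += dlogits.sum(axis=0)
    dD1 = dlogits @ params["Wf2"].T
    dA1 = dD1 * cache["mask"]
    dB1 = dA1 * (cache["B1"] > 0)
    if cfg.use_batchnorm:
        Zh, std = cache["Zh"], cache["std"]
        grads["gamma"] += (dB1 * Zh).sum(axis=0)
        grads["beta"] += dB1.sum(axis=0)
        dZh = dB1 * params["gamma"]
        b = dZh.shape[0]
        dZ1 = (dZh - dZh.mean(axis=0) - Zh * (dZh * Zh).mean(axis=0)) / std
        if b == 1:  # batch statistics undefined; treated as frozen
            dZ1 = dZh / std
    else:
        dZ1 = dB1
    grads["Wf1"] += cache["G"].T @ dZ1
    grads["bf1"] += dZ1.sum(axis=0)
    return dZ1 @ params["Wf1"].T  # dG


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _batch_forward(
    params, bn_stats, samples, cfg, training, rng
):
    gs, gcaches = [], []
    for s in samples:
        g, cache, _ = _graph_forward(params, s, cfg, want_cache=training)
        gs.append(g)
        gcaches.append(cache)
    G = np.stack(gs)
    logits, hcache = _head_forward(params, bn_stats, G, cfg, training, rng)
    return logits, gcaches, hcache


def forward(model: TrainedModel, sample: BrainGraphSample) -> np.ndarray:
    """Deterministic inference: class scores (logits) for one graph."""
    logits, _, _ = _batch_forward(
        model.params, model.bn_stats, [sample], model.model_cfg, False, None
    )
    return logits[0]


def forward_trace(model: TrainedModel, sample: BrainGraphSample):
    """Logits plus the per-block node selections (original indices + scores)."""
    g, _, selections = _graph_forward(
        model.params, sample, model.model_cfg, want_cache=False
    )
    logits, _ = _head_forward(
        model.params, model.bn_stats, g[None, :], model.model_cfg, False, None
    )
    return logits[0], selections


def predict_proba(model: TrainedModel, samples: list[BrainGraphSample]) -> np.ndarray:
    """Class-membership probabilities (softmax of the logits), one row each."""
    logits, _, _ = _batch_forward(
        model.params, model.bn_stats, samples, model.model_cfg, False, None
    )
    return _softmax(logits)


def predict_label(model: TrainedModel, samples: list[BrainGraphSample]) -> np.ndarray:
    return predict_proba(model, samples).argmax(axis=1)


# --------------------------------------------------------------------------
# training

def _cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    probs = _softmax(logits)
    b = logits.shape[0]
    loss = -np.log(probs[np.arange(b), labels] + 1e-300).mean()
    dlogits = probs.copy()
    dlogits[np.arange(b), labels] -= 1.0
    return float(loss), dlogits / b


class _Adam:
    def __init__(self, params: dict, lr: float, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for k in params:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def stratified_holdout(
    labels: np.ndarray, fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Split indices into (kept, held-out) preserving class proportions.

    The held-out side receives round(fraction * n_c) per class, at least 1
    when the class has at least 2 members.
    """
    labels = np.asarray(labels)
    keep, hold = [], []
    for cls in np.unique(labels):
        members = np.flatnonzero(labels == cls)
        members = members[rng.permutation(members.size)]
        n_hold = int(round(fraction * members.size))
        if members.size >= 2:
            n_hold = min(max(n_hold, 1), members.size - 1)
        else:
            n_hold = 0
        hold.extend(members[:n_hold])
        keep.extend(members[n_hold:])
    return np.sort(np.array(keep, dtype=int)), np.sort(np.array(hold, dtype=int))


def _dataset_loss(params, bn_stats, samples, labels, cfg) -> float:
    logits, _, _ = _batch_forward(params, bn_stats, samples, cfg, False, None)
    loss, _ = _cross_entropy(logits, labels)
    return loss


def train(
    dataset: list[BrainGraphSample],
    train_ids: list[str] | set[str],
    model_cfg: ModelConfig | None = None,
    train_cfg: TrainConfig | None = None,
) -> TrainedModel:
    """Fit the classifier on the subjects named by ``train_ids``.

    A stratified ``val_fraction`` of the training subjects is held out
    internally to monitor validation loss; training stops at
    ``max_epochs`` or once validation loss has not improved for more than
    ``patience`` epochs, and the best-validation-loss weights are
    returned.  All randomness (init, shuffling, dropout, the validation
    split) flows from ``train_cfg.seed``.
    """
    model_cfg = model_cfg or ModelConfig()
    train_cfg = train_cfg or TrainConfig()
    train_ids = set(train_ids)
    pool = [s for s in dataset if s.subject_id in train_ids]
    if len(pool) != len(train_ids):
        raise ValueError("train_ids not all present in dataset")
    labels = np.array([s.label for s in pool])
    if min((labels == 0).sum(), (labels == 1).sum()) < 2:
        raise ValueError("need at least 2 training subjects per class")

    rng = np.random.default_rng(np.random.SeedSequence([train_cfg.seed, 0x7121]))
    fit_idx, val_idx = stratified_holdout(labels, train_cfg.val_fraction, rng)
    fit_set = [pool[i] for i in fit_idx]
    fit_labels = labels[fit_idx]
    val_set = [pool[i] for i in val_idx]
    val_labels = labels[val_idx]

    params, bn_stats = init_params(pool[0].features.shape[1], model_cfg, rng)
    opt = _Adam(params, train_cfg.learning_rate)

    log: list[dict] = []
    best_loss = np.inf
    best_epoch = -1
    best_weights = ({k: v.copy() for k, v in params.items()},
                    {k: v.copy() for k, v in bn_stats.items()})
    bad_epochs = 0

    n_fit = len(fit_set)
    for epoch in range(train_cfg.max_epochs):
        order = rng.permutation(n_fit)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n_fit, train_cfg.batch_size):
            batch_idx = order[start : start + train_cfg.batch_size]
            if batch_idx.size < 2 and model_cfg.use_batchnorm:
                continue  # batch statistics undefined for a single sample
            batch = [fit_set[i] for i in batch_idx]
            blabels = fit_labels[batch_idx]
            logits, gcaches, hcache = _batch_forward(
                params, bn_stats, batch, model_cfg, True, rng
            )
            loss, dlogits = _cross_entropy(logits, blabels)
            grads = {k: np.zeros_like(v) for k, v in params.items()}
            dG = _head_backward(params, hcache, dlogits, model_cfg, grads)
            for i, cache in enumerate(gcaches):
                _graph_backward(params, cache, dG[i], grads)
            opt.step(params, grads)
            epoch_loss += loss
            n_batches += 1
        val_loss = _dataset_loss(params, bn_stats, val_set, val_labels, model_cfg)
        log.append(
            {"epoch": epoch,
             "train_loss": epoch_loss / max(n_batches, 1),
             "val_loss": val_loss}
        )
        if val_loss < best_loss - 1e-12:
            best_loss = val_loss
            best_epoch = epoch
            best_weights = ({k: v.copy() for k, v in params.items()},
                            {k: v.copy() for k, v in bn_stats.items()})
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs > train_cfg.patience:
                break

    return TrainedModel(
        params=best_weights[0],
        bn_stats=best_weights[1],
        model_cfg=model_cfg,
        train_cfg=train_cfg,
        log=log,
        best_epoch=best_epoch,
        n_features=pool[0].features.shape[1],
    )
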