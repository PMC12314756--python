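"""Cost-sensitive graph convolutional network for node classification.

A transductive L-layer GCN classifies image vertices of the semantic graph:

    H^(0) = X,   H^(l+1) = ReLU(A_hat H^(l) W^(l)),
    logits = H^(L) W_head^T + b,   y_hat = softmax(logits)

where ``A_hat`` is the symmetric degree-normalized adjacency.  Convolution
layers carry no bias; only the 2-class softmax head does.  Every vertex —
training images, test images, and feature vertices — participates in message
passing, but only labeled training image vertices enter the loss.

The class imbalance of screening (positives ~8x rarer) is handled by a
cost-sensitive cross-entropy that multiplies only the positive-class
log-term by a weight w_c:

    L = -(1/T) sum_train [ w_c * y * log p1 + (1-y) * log(1-p1) ].

Note this weights only the positive term, not both classes symmetrically.
Training is full-batch Adam with decoupled L2 weight decay; gradients are
computed analytically (closed-form backprop through the two matrix products
and the ReLU).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

EPS = 1e-12


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


@dataclass
class GCNParams:
    """All trainable parameters of the GCN and its softmax head."""

    conv_weights: list[np.ndarray]  # W^(l): (d_l, d_{l+1})
    head_weight: np.ndarray  # (2, d_L)
    head_bias: np.ndarray  # (2,)
    activation: str = "relu"

    @property
    def n_layers(self) -> int:
        return len(self.conv_weights)

    def copy(self) -> "GCNParams":
        return GCNParams(
            conv_weights=[w.copy() for w in self.conv_weights],
            head_weight=self.head_weight.copy(),
            head_bias=self.head_bias.copy(),
            activation=self.activation,
        )

    def flat(self) -> list[np.ndarray]:
        return [*self.conv_weights, self.head_weight, self.head_bias]


@dataclass
class TrainConfig:
    learning_rate: float = 0.01
    weight_decay: float = 0.001
    w_c: float = 7.0
    epochs: int = 200
    patience: int = 30
    seed: int = 0
    hidden_dims: tuple[int, ...] = (64,)
    n_layers: int = 2

    def validate(self) -> None:
        if self.w_c < 1.0:
            raise ValueError("w_c must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


def init_params(
    in_dim: int, cfg: TrainConfig, rng: np.random.Generator
) -> GCNParams:
    """Fan-in-scaled symmetric-uniform initialization.

    Layer dims: in_dim -> hidden_dims (cycled/truncated to n_layers-1) -> d_L,
    where d_L is the last hidden dim (or in_dim when n_layers == 1 uses the
    first hidden dim as output).
    """
    dims = [in_dim]
    for l in range(cfg.n_layers):
        h = cfg.hidden_dims[min(l, len(cfg.hidden_dims) - 1)]
        dims.append(h)
    conv = []
    for d_in, d_out in zip(dims[:-1], dims[1:]):
        bound = 1.0 / np.sqrt(d_in)
        conv.append(rng.uniform(-bound, bound, size=(d_in, d_out)))
    d_last = dims[-1]
    bound = 1.0 / np.sqrt(d_last)
    head_w = rng.uniform(-bound, bound, size=(2, d_last))
    return GCNParams(conv_weights=conv, head_weight=head_w, head_bias=np.zeros(2))


def gcn_forward(
    X: np.ndarray, A_hat: sp.spmatrix, params: GCNParams, return_cache: bool = False
):
    """Run the stacked convolutions; returns H^(L) (and the backprop cache)."""
    H = np.asarray(X, dtype=float)
    cache = {"H": [H], "Z": []}
    for W in params.conv_weights:
        if H.shape[1] != W.shape[0]:
            raise ValueError(
                f"dimension mismatch: H has {H.shape[1]} columns, W expects {W.shape[0]}"
            )
        Z = A_hat @ (H @ W)
        H = relu(Z)
        cache["Z"].append(Z)
        cache["H"].append(H)
    return (H, cache) if return_cache else H


def _softmax2(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def classify_nodes(H_L: np.ndarray, params: GCNParams) -> tuple[np.ndarray, np.ndarray]:
    """Softmax head: returns (P(class 1), hard labels); ties go to class 0."""
    with np.errstate(invalid="ignore"):
        logits = H_L @ params.head_weight.T + params.head_bias[None, :]
    if not np.isfinite(logits).all():
        raise FloatingPointError("non-finite logits")
    probs = _softmax2(logits)
    p1 = probs[:, 1]
    hard = (p1 > 0.5).astype(np.int8)
    return p1, hard


def detection_loss(yhat: np.ndarray, y: np.ndarray, w_c: float) -> float:
    """Cost-sensitive binary cross-entropy over training vertices.

    ``yhat`` is P(class 1); the positive log-term is scaled by w_c.
    """
    yhat = np.asarray(yhat, dtype=float)
    y = np.asarray(y, dtype=float)
    if yhat.size == 0:
        raise ValueError("empty training set")
    p = np.clip(yhat, EPS, 1.0 - EPS)
    terms = w_c * y * np.log(p) + (1.0 - y) * np.log(1.0 - p)
    return float(-terms.mean())


@dataclass
class _Adam:
    lr: float
    wd: float
    b1: float = 0.9
    b2: float = 0.999
    eps: float = 1e-8
    m: list = field(default_factory=list)
    v: list = field(default_factory=list)
    t: int = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray], decay_mask):
        if not self.m:
            self.m = [np.zeros_like(p) for p in params]
            self.v = [np.zeros_like(p) for p in params]
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if decay_mask[i]:
                p -= self.lr * self.wd * p


def loss_and_grads(
    X: np.ndarray,
    A_hat: sp.spmatrix,
    params: GCNParams,
    train_idx: np.ndarray,
    y_train: np.ndarray,
    w_c: float,
) -> tuple[float, list[np.ndarray]]:
    """Analytic loss and gradients for the full model.

    Backprop: for the softmax + weighted CE, dL/dlogits at a training vertex
    is (w_c if y=1 else 1) * (softmax - onehot(y)) / T; then through the
    head and each convolution (A_hat is symmetric, so its transpose is
    itself).
    """
    H_L, cache = gcn_forward(X, A_hat, params, return_cache=True)
    logits = H_L @ params.head_weight.T + params.head_bias[None, :]
    probs = _softmax2(logits)
    T = train_idx.size
    p1 = np.clip(probs[train_idx, 1], EPS, 1.0 - EPS)
    y = y_train.astype(float)
    loss = float(-np.mean(w_c * y * np.log(p1) + (1 - y) * np.log(1 - p1)))

    G_logits = np.zeros_like(logits)
    w = np.where(y == 1, w_c, 1.0)
    onehot = np.zeros((T, 2))
    onehot[np.arange(T), y_train.astype(int)] = 1.0
    G_logits[train_idx] = w[:, None] * (probs[train_idx] - onehot) / T

    g_head_w = G_logits.T @ H_L
    g_head_b = G_logits.sum(axis=0)
    dH = G_logits @ params.head_weight

    g_conv: list[np.ndarray] = [None] * params.n_layers  # type: ignore[list-item]
    for l in range(params.n_layers - 1, -1, -1):
        Z = cache["Z"][l]
        H_prev = cache["H"][l]
        dZ = dH * (Z > 0)
        S = A_hat @ H_prev
        g_conv[l] = S.T @ dZ
        if l > 0:
            dH = A_hat @ (dZ @ params.conv_weights[l].T)
    return loss, [*g_conv, g_head_w, g_head_b]


def train_detector(
    graph,
    X: np.ndarray,
    train_mask: np.ndarray,
    cfg: TrainConfig | None = None,
    params: GCNParams | None = None,
    A_hat: sp.spmatrix | None = None,
) -> tuple[GCNParams, list[float]]:
    """Fit the GCN on the labeled training image vertices.

    ``train_mask`` is a boolean mask over image vertices; labels are taken
    from ``graph.labels`` (which must be 0/1 on masked vertices).  Returns
    the trained parameters and the per-epoch loss trace.  Early stopping:
    training halts after ``patience`` epochs without improving the best
    training loss, restoring the best parameters.
    """
    from .graph import adjacency

    cfg = cfg or TrainConfig()
    cfg.validate()
    X = np.asarray(X, dtype=float)
    if A_hat is None:
        A_hat = adjacency(graph, self_loops=False).A_hat
    train_idx = np.flatnonzero(np.asarray(train_mask, dtype=bool))
    if train_idx.size == 0:
        raise ValueError("empty training mask")
    y_train = np.asarray(graph.labels)[train_idx]
    if not np.isin(y_train, (0, 1)).all():
        raise ValueError("training vertices must carry 0/1 labels")

    rng = np.random.default_rng(cfg.seed)
    if params is None:
        params = init_params(X.shape[1], cfg, rng)
    flat = params.flat()
    decay_mask = [True] * params.n_layers + [True, False]  # no decay on bias
    opt = _Adam(lr=cfg.learning_rate, wd=cfg.weight_decay)

    trace: list[float] = []
    best_loss = np.inf
    best = params.copy()
    stale = 0
    for _ in range(cfg.epochs):
        loss, grads = loss_and_grads(X, A_hat, params, train_idx, y_train, cfg.w_c)
        if not np.isfinite(loss):
            raise FloatingPointError(
                "training diverged (non-finite loss); lower the learning rate"
            )
        trace.append(loss)
        if loss < best_loss - 1e-9:
            best_loss, best, stale = loss, params.copy(), 0
        else:
            stale += 1
            if stale > cfg.patience:
                break
        opt.step(flat, grads, decay_mask)
    return best, trace


def predict(
    graph, X: np.ndarray, params: GCNParams, A_hat: sp.spmatrix | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """P(class 1) and hard labels for the *image* vertices of the graph."""
    from .graph import adjacency

    if A_hat is None:
        A_hat = adjacency(graph, self_loops=False).A_hat
    H_L = gcn_forward(np.asarray(X, dtype=float), A_hat, params)
    p1, hard = classify_nodes(H_L, params)
    return p1[: graph.n_images], hard[: graph.n_images]
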