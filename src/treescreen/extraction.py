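"""Surrogate automatic feature extraction with a cost-sensitive loss.

The real pipeline fine-tunes an image CNN with 98 parallel binary heads to
code each drawing automatically.  Here each feature gets an independent
logistic scorer on the cohort's latent evidence channel for that feature —
the multi-label losses and the minority-class weighting are identical to the
CNN setting, only the backbone differs.  Any scorer producing per-feature
probabilities can be dropped in.

Losses: the plain multi-label objective is the mean over features of the
per-feature mean binary cross-entropy.  The cost-sensitive variant multiplies
the minority-class term of each feature by a weight w_f >= 1: the presence
term when presence is the minority coding for that feature, the absence term
otherwise (minority direction is estimated on training rows only).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

EPS = 1e-12


@dataclass
class ExtractionLossConfig:
    """Cost-sensitive weighting for the multi-label extraction loss.

    ``minority_is_presence[i]`` is True when z=1 is the minority coding of
    feature i on the training split.
    """

    w_f: float = 4.0
    minority_is_presence: np.ndarray | None = None

    def validate(self, n_features: int | None = None) -> None:
        if self.w_f < 1.0:
            raise ValueError("w_f must be >= 1")
        if n_features is not None and self.minority_is_presence is not None:
            if np.shape(self.minority_is_presence) != (n_features,):
                raise ValueError("minority_is_presence length mismatch")


@dataclass
class ExtractorTrainConfig:
    learning_rate: float = 0.5
    epochs: int = 300
    w_f: float = 4.0
    seed: int = 0


@dataclass
class ExtractorModel:
    """One logistic scorer per catalog feature: sigmoid(w_i * s_ij + b_i)."""

    weights: np.ndarray  # (N,)
    biases: np.ndarray  # (N,)
    cfg: ExtractorTrainConfig = field(default_factory=ExtractorTrainConfig)

    def predict_proba(self, signals: np.ndarray) -> np.ndarray:
        signals = np.asarray(signals, dtype=float)
        return expit(signals * self.weights[None, :] + self.biases[None, :])


def _clip(p: np.ndarray) -> np.ndarray:
    return np.clip(p, EPS, 1.0 - EPS)


def feature_ce_loss(zhat: np.ndarray, z: np.ndarray) -> float:
    """Mean over features of per-feature mean binary cross-entropy."""
    zhat = np.asarray(zhat, dtype=float)
    z = np.asarray(z, dtype=float)
    if zhat.shape != z.shape or zhat.ndim != 2:
        raise ValueError("zhat and z must be equal-shape M x N matrices")
    p = _clip(zhat)
    cell = -(z * np.log(p) + (1.0 - z) * np.log(1.0 - p))
    return float(cell.mean(axis=0).mean())


def minority_direction(z_train: np.ndarray) -> np.ndarray:
    """Per feature, True when presence (z=1) is the minority coding."""
    z_train = np.asarray(z_train)
    return z_train.mean(axis=0) < 0.5


def feature_ce_loss_weighted(
    zhat: np.ndarray, z: np.ndarray, cfg: ExtractionLossConfig
) -> float:
    """Cost-sensitive multi-label cross-entropy.

    The minority-class log-term of each feature (presence term when presence
    is minority, absence term otherwise) is scaled by w_f.  With w_f = 1 this
    reduces exactly to :func:`feature_ce_loss`.
    """
    zhat = np.asarray(zhat, dtype=float)
    z = np.asarray(z, dtype=float)
    if zhat.shape != z.shape or zhat.ndim != 2:
        raise ValueError("zhat and z must be equal-shape M x N matrices")
    cfg.validate(n_features=z.shape[1])
    minority_pres = (
        cfg.minority_is_presence
        if cfg.minority_is_presence is not None
        else minority_direction(z)
    )
    p = _clip(zhat)
    w_pos = np.where(minority_pres, cfg.w_f, 1.0)[None, :]
    w_neg = np.where(minority_pres, 1.0, cfg.w_f)[None, :]
    cell = -(w_pos * z * np.log(p) + w_neg * (1.0 - z) * np.log(1.0 - p))
    return float(cell.mean(axis=0).mean())


def extractor_loss_grads(
    w: np.ndarray,
    b: np.ndarray,
    signals: np.ndarray,
    z: np.ndarray,
    minority_pres: np.ndarray,
    w_f: float,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Cost-sensitive loss of the logistic scorers and its analytic gradient.

    The loss is the overall cell mean of the weighted cross-entropy (the
    same quantity as :func:`feature_ce_loss_weighted` applied to the scorer
    probabilities); gradients are with respect to the per-feature weights
    and biases.
    """
    w_pos = np.where(minority_pres, w_f, 1.0)[None, :]
    w_neg = np.where(minority_pres, 1.0, w_f)[None, :]
    p = _clip(expit(signals * w[None, :] + b[None, :]))
    cell = -(w_pos * z * np.log(p) + w_neg * (1.0 - z) * np.log(1.0 - p))
    loss = float(cell.mean())
    # d/dlogit of the weighted cross-entropy
    g = (w_pos * z * (p - 1.0) + w_neg * (1.0 - z) * p) / cell.size
    gw = (g * signals).sum(axis=0)
    gb = g.sum(axis=0)
    return loss, gw, gb


def train_extractor(
    cohort,
    cfg: ExtractorTrainConfig | None = None,
    train_rows: np.ndarray | None = None,
) -> ExtractorModel:
    """Fit the per-feature logistic scorers by full-batch gradient descent.

    Minimizes the cost-sensitive multi-label loss on ``train_rows`` (all rows
    when omitted); the minority direction of each feature is estimated on the
    same rows.  Deterministic: the objective is convex per feature and
    initialization is zero.
    """
    cfg = cfg or ExtractorTrainConfig()
    s = np.asarray(cohort.signals, dtype=float)
    z = np.asarray(cohort.Z, dtype=float)
    if train_rows is not None:
        s, z = s[train_rows], z[train_rows]
    m, n = z.shape
    minority_pres = minority_direction(z)

    w = np.zeros(n)
    b = np.zeros(n)
    # per-cell mean gradient: rescale the summed gradient by the cell count
    for _ in range(cfg.epochs):
        _, gw, gb = extractor_loss_grads(w, b, s, z, minority_pres, cfg.w_f)
        gw, gb = gw * n, gb * n  # step per feature, not per cell
        if not (np.isfinite(gw).all() and np.isfinite(gb).all()):
            raise FloatingPointError(
                "non-finite extractor gradient; lower the learning rate"
            )
        w -= cfg.learning_rate * gw
        b -= cfg.learning_rate * gb
    return ExtractorModel(weights=w, biases=b, cfg=cfg)


def extract_features(model: ExtractorModel, signals: np.ndarray) -> np.ndarray:
    """Binary feature predictions; ties at p = 0.5 break toward presence."""
    p = model.predict_proba(signals)
    return (p >= 0.5).astype(np.int8)
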