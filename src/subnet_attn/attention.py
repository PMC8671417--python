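"""Entropy-driven attention over subnetwork representations.

Each subnetwork's representation of a sample is a class-probability
distribution; its negative Shannon entropy c_t = sum_k p_tk ln p_tk measures
how certain that subnetwork-level predictor is (0 for a degenerate
distribution, most negative for a uniform one). The certainty vector
C = <c_1..c_T> is mapped through a trainable square matrix W and a softmax,

    H = softmax(W C'),

yielding per-sample attention weights over subnetworks. The master decision
is the attention-weighted average of the subnetwork distributions,
d_k = sum_t h_t p_tk, followed by a softmax f = softmax(d). Attention is
instance-wise: samples with different certainty profiles receive different
weights, and the per-sample attention map is the basis of biomarker ranking.

Training minimises a configurable loss (categorical cross-entropy by
default; squared hinge and mean-absolute-percentage-error are provided)
between f and the one-hot labels, by full-batch AdaGrad on W with inverted
dropout applied to C during training and early stopping on an internal
stratified validation split. The layer is bias-free, matching
H = softmax(W C').
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .data_io import SampleLabels
from .representation import RepresentationTensor

_MAPE_EPS = 1e-7


def certainty(rep: RepresentationTensor) -> np.ndarray:
    """Negative Shannon entropy c_t per sample per subnetwork (0 ln 0 := 0)."""
    p = rep.probs
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
    return terms.sum(axis=2)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


@dataclass
class TrainConfig:
    loss: str = "cross_entropy"  # | "squared_hinge" | "mape"
    learning_rate: float = 0.1
    epochs: int = 500
    dropout: float = 0.5
    val_split: float = 0.1
    patience: int = 20
    seed: int = 0


@dataclass
class AttentionModel:
    W: np.ndarray  # (T, T)
    subnetwork_ids: list[str]
    class_set: list[str]
    config: TrainConfig = field(default_factory=TrainConfig)

    def save(self, path: str) -> None:
        payload = {
            "W": self.W.tolist(),
            "subnetwork_ids": self.subnetwork_ids,
            "class_set": self.class_set,
            "config": asdict(self.config),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path: str) -> "AttentionModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            np.array(payload["W"]),
            payload["subnetwork_ids"],
            payload["class_set"],
            TrainConfig(**payload["config"]),
        )


@dataclass
class PredictionResult:
    sample_ids: list[str]
    class_set: list[str]
    d: np.ndarray  # weighted sums, (n, k)
    f: np.ndarray  # softmax class probabilities, (n, k)

    @property
    def predicted(self) -> list[str]:
        return [self.class_set[i] for i in np.argmax(self.f, axis=1)]


def attention_forward(W: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Per-sample attention H = softmax(W C'); C is (n_samples, T)."""
    if W.shape[1] != C.shape[1]:
        raise ValueError(f"W is {W.shape} but C has {C.shape[1]} subnetworks")
    return _softmax(C @ W.T)


def decide(H: np.ndarray, rep: RepresentationTensor) -> PredictionResult:
    """Master decision: d_k = sum_t h_t p_tk, f = softmax(d)."""
    if H.shape != rep.probs.shape[:2]:
        raise ValueError("attention map shape does not match representation")
    d = np.einsum("nt,ntk->nk", H, rep.probs)
    return PredictionResult(list(rep.sample_ids), list(rep.class_set), d, _softmax(d))


def _loss_grad_d(F: np.ndarray, Y: np.ndarray, loss: str) -> tuple[float, np.ndarray]:
    """Loss value and gradient w.r.t. the pre-softmax decision d (mean over samples)."""
    n, k = F.shape
    if loss == "cross_entropy":
        value = float(-(Y * np.log(np.clip(F, 1e-12, None))).sum() / n)
        dLdd = (F - Y) / n
        return value, dLdd
    if loss == "squared_hinge":
        y_pm = 2.0 * Y - 1.0
        margin = np.maximum(0.0, 1.0 - y_pm * F)
        value = float((margin**2).sum() / (n * k))
        dLdF = -2.0 * margin * y_pm / (n * k)
    elif loss == "mape":
        err = Y - F
        denom = np.maximum(np.abs(Y), _MAPE_EPS)
        value = float((np.abs(err) / denom).sum() / (n * k) * 100.0)
        dLdF = -np.sign(err) / denom / (n * k) * 100.0
    else:
        raise ValueError(f"unknown loss {loss!r}")
    # back through softmax: dL/dd = F * (dL/dF - sum_k F dL/dF)
    inner = (F * dLdF).sum(axis=1, keepdims=True)
    return value, F * (dLdF - inner)


def loss_and_grad(
    W: np.ndarray,
    C: np.ndarray,
    P: np.ndarray,
    Y: np.ndarray,
    loss: str = "cross_entropy",
) -> tuple[float, np.ndarray]:
    """Analytic loss and dLoss/dW for the full attention head.

    C: certainty (n, T); P: representations (n, T, k); Y: one-hot (n, k).
    """
    Z = C @ W.T
    H = _softmax(Z)
    d = np.einsum("nt,ntk->nk", H, P)
    F = _softmax(d)
    value, dLdd = _loss_grad_d(F, Y, loss)
    dLdH = np.einsum("ntk,nk->nt", P, dLdd)
    inner = (H * dLdH).sum(axis=1, keepdims=True)
    dLdZ = H * (dLdH - inner)
    return value, dLdZ.T @ C


def _one_hot(labels: SampleLabels) -> np.ndarray:
    idx = {c: i for i, c in enumerate(labels.class_set)}
    Y = np.zeros((len(labels.labels), len(labels.class_set)))
    for m, l in enumerate(labels.labels):
        Y[m, idx[l]] = 1.0
    return Y


def _stratified_split(
    labels: SampleLabels, fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    train_idx, val_idx = [], []
    labs = np.array(labels.labels)
    for cls in labels.class_set:
        idx = np.flatnonzero(labs == cls)
        if idx.size == 0:
            continue
        idx = rng.permutation(idx)
        n_val = max(1, int(np.floor(fraction * idx.size)))
        if n_val >= idx.size:
            raise ValueError(
                f"validation split leaves no training sample for class {cls!r}"
            )
        val_idx.append(idx[:n_val])
        train_idx.append(idx[n_val:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(val_idx))


def train(
    rep_train: RepresentationTensor,
    labels: SampleLabels,
    config: TrainConfig | None = None,
) -> AttentionModel:
    """Fit W by full-batch AdaGrad with dropout and early stopping.

    Dropout (inverted, rate ``config.dropout``) is applied to the certainty
    vectors during training only. A stratified ``val_split`` fraction is held
    out internally; training stops after ``patience`` epochs without
    improvement of the validation loss and the best-validation W is kept.
    Fully deterministic given ``config.seed``.
    """
    if config is None:
        config = TrainConfig()
    if rep_train.sample_ids != labels.sample_ids:
        raise ValueError("representation and labels must cover the same samples in order")
    if len(set(labels.labels)) < 2:
        raise ValueError("training requires >= 2 classes present")
    if len(labels.sample_ids) < 4:
        raise ValueError("training requires >= 4 samples")
    rng = np.random.default_rng(config.seed)
    C = certainty(rep_train)
    P = rep_train.probs
    Y = _one_hot(labels)
    T = C.shape[1]

    tr, va = _stratified_split(labels, config.val_split, rng)
    C_tr, P_tr, Y_tr = C[tr], P[tr], Y[tr]
    C_va, P_va, Y_va = C[va], P[va], Y[va]

    limit = np.sqrt(6.0 / (T + T))  # Glorot-uniform
    W = rng.uniform(-limit, limit, size=(T, T))
    accum = np.zeros_like(W)
    best_W = W.copy()
    best_val = np.inf
    since_best = 0
    for _ in range(config.epochs):
        if config.dropout > 0:
            mask = (rng.random(C_tr.shape) >= config.dropout) / (1.0 - config.dropout)
            C_in = C_tr * mask
        else:
            C_in = C_tr
        _, grad = loss_and_grad(W, C_in, P_tr, Y_tr, config.loss)
        accum += grad**2
        W = W - config.learning_rate * grad / (np.sqrt(accum) + 1e-8)

        val_loss, _ = loss_and_grad(W, C_va, P_va, Y_va, config.loss)
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_W = W.copy()
            since_best = 0
        else:
            since_best += 1
            if since_best > config.patience:
                break
    return AttentionModel(best_W, list(rep_train.subnetwork_ids), list(labels.class_set), config)


def predict(
    model: AttentionModel, rep: RepresentationTensor
) -> tuple[PredictionResult, np.ndarray]:
    """Inference composition: certainty -> attention -> decision (no dropout)."""
    if rep.subnetwork_ids != model.subnetwork_ids:
        raise ValueError("representation subnetworks do not match the model")
    C = certainty(rep)
    H = attention_forward(model.W, C)
    return decide(H, rep), H
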