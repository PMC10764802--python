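"""Prototype computation, margin contrastive loss, and the training loop.

Each cell type gets one *representative* (prototype): the arithmetic
mean of all its training cells in preprocessed input space.  Training
pulls every cell's embedding toward its own representative and pushes
it at least a margin ``m`` away from every other representative:

    L(c_i, ct_j, y_ij) = y_ij * 1/2 * D(z_i, zr_j)^2
                       + (1 - y_ij) * 1/2 * max(0, m - D(z_i, zr_j))^2

with D the Euclidean distance in embedding space and y_ij = 1 iff
representative j matches cell i's type.  The reported loss is the mean
over all B*T (cell, representative) pairs.

Representatives are fixed in input space and re-embedded with the
current weights at every step; cells and representatives share one
forward pass so batch-norm statistics are common.  Optimization is
Adam; validation loss is monitored every ``validate_every_epochs``
epochs and training stops after ``patience_checks`` checks without
improvement, returning the best-validation parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .core_data import LabelVocabulary
from .encoder import EncoderConfig, EncoderParams, backward, forward, init_encoder

__all__ = [
    "RepresentativeSet",
    "TrainConfig",
    "TrainLog",
    "compute_representatives",
    "contrastive_loss",
    "early_stop_check",
    "train",
]


@dataclass
class RepresentativeSet:
    """Mean input-space profile per cell type, ordered like the vocabulary."""

    matrix: np.ndarray  # (T, d)
    vocab: LabelVocabulary
    counts: np.ndarray  # cells per type, (T,)


@dataclass
class TrainConfig:
    margin: float = 1.0
    batch_size: int = 512
    max_epochs: int = 100
    learning_rate: float = 1e-3
    validate_every_epochs: int = 2
    patience_checks: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.margin <= 0:
            raise ValueError("margin must be positive")
        for name in ("batch_size", "learning_rate", "validate_every_epochs", "patience_checks"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_epochs < 0:
            raise ValueError("max_epochs must be >= 0")


@dataclass
class TrainLog:
    train_loss: list[float] = field(default_factory=list)  # per epoch
    val_loss: list[float] = field(default_factory=list)  # per validation check
    val_epochs: list[int] = field(default_factory=list)
    stopped_epoch: int = 0
    stop_reason: str = "max_epochs"


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense() if sp.issparse(X) else X, dtype=np.float64)


def compute_representatives(X_train, labels, vocab: LabelVocabulary) -> RepresentativeSet:
    """Exact arithmetic mean profile per type, in input space.

    Every vocabulary type must have at least one training cell.
    """
    labels = np.asarray([str(l) for l in labels])
    if len(labels) != X_train.shape[0]:
        raise ValueError("labels and matrix rows differ in length")
    T, d = len(vocab), X_train.shape[1]
    reps = np.zeros((T, d))
    counts = np.zeros(T, dtype=int)
    for j, t in enumerate(vocab.types):
        idx = np.flatnonzero(labels == t)
        if idx.size == 0:
            raise ValueError(f"cell type {t!r} has no training cells")
        counts[j] = idx.size
        sub = X_train[idx]
        reps[j] = np.asarray(sub.mean(axis=0)).ravel()
    return RepresentativeSet(matrix=reps, vocab=vocab, counts=counts)


def _pair_distances(z_cells: np.ndarray, z_reps: np.ndarray) -> np.ndarray:
    diff = z_cells[:, None, :] - z_reps[None, :, :]
    return np.sqrt((diff * diff).sum(axis=2)), diff


def contrastive_loss(
    z_cells: np.ndarray,
    z_reps: np.ndarray,
    type_index: np.ndarray,
    m: float = 1.0,
) -> float:
    """Mean margin contrastive loss over all (cell, representative) pairs."""
    loss, _, _ = contrastive_loss_grad(z_cells, z_reps, type_index, m)
    return loss


def contrastive_loss_grad(
    z_cells: np.ndarray,
    z_reps: np.ndarray,
    type_index: np.ndarray,
    m: float = 1.0,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Loss plus gradients w.r.t. cell and representative embeddings.

    For a cross-type pair sitting exactly at distance 0 the hinge term
    is maximal but has no defined direction; the subgradient 0 is used.
    """
    if m <= 0:
        raise ValueError("margin must be positive")
    z_cells = np.asarray(z_cells, dtype=np.float64)
    z_reps = np.asarray(z_reps, dtype=np.float64)
    if not (np.all(np.isfinite(z_cells)) and np.all(np.isfinite(z_reps))):
        raise ValueError("non-finite embeddings")
    B, T = z_cells.shape[0], z_reps.shape[0]
    type_index = np.asarray(type_index, dtype=int)
    if type_index.shape != (B,) or np.any(type_index < 0) or np.any(type_index >= T):
        raise ValueError("type_index must map each cell to a representative row")

    dist, diff = _pair_distances(z_cells, z_reps)
    same = np.zeros((B, T), dtype=bool)
    same[np.arange(B), type_index] = True

    hinge = np.maximum(0.0, m - dist)
    per_pair = np.where(same, 0.5 * dist**2, 0.5 * hinge**2)
    n_pairs = B * T
    loss = float(per_pair.sum() / n_pairs)

    # same-type pair: d(0.5 D^2)/dz_c = diff, exact even at D = 0.
    # cross-type pair with active hinge: d(0.5 (m-D)^2)/dz_c = -(m-D) * diff/D.
    coeff = np.where(same, 1.0, np.where(dist > 0, -hinge / np.where(dist > 0, dist, 1.0), 0.0))
    pair_grad = coeff[:, :, None] * diff / n_pairs
    d_cells = pair_grad.sum(axis=1)
    d_reps = -pair_grad.sum(axis=0)
    return loss, d_cells, d_reps


def early_stop_check(val_losses, patience: int = 5) -> bool:
    """True iff the last ``patience`` checks all failed to beat the running best.

    A check "improves" only by strictly decreasing the best loss seen
    before it; an improvement resets the counter.
    """
    if len(val_losses) == 0:
        raise ValueError("empty validation-loss sequence")
    best = np.inf
    since_best = 0
    for v in val_losses:
        if v < best:
            best = v
            since_best = 0
        else:
            since_best += 1
    return since_best >= patience


class _Adam:
    def __init__(self, keys, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: None for k in keys}
        self.v = {k: None for k in keys}
        self.t = 0

    def step(self, params: EncoderParams, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            if self.m[k] is None:
                self.m[k] = np.zeros_like(g)
                self.v[k] = np.zeros_like(g)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] = params[k] - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _validation_loss(params, enc_cfg, X_val, val_idx, reps, m) -> float:
    Zv = forward(params, X_val, enc_cfg, mode="eval")[0]
    Zr = forward(params, reps, enc_cfg, mode="eval")[0]
    return contrastive_loss(Zv, Zr, val_idx, m)


def train(
    X_train,
    labels_train,
    X_val,
    labels_val,
    enc_cfg: EncoderConfig,
    train_cfg: TrainConfig,
    vocab: LabelVocabulary | None = None,
) -> tuple[EncoderParams, RepresentativeSet, TrainLog]:
    """Train the encoder with the prototype contrastive objective.

    Returns the parameters from the best validation check (or the final
    parameters if no check ran), the representative set, and a log of
    per-epoch training loss and per-check validation loss.
    """
    if X_val.shape[0] == 0:
        raise ValueError("empty validation set")
    if X_train.shape[1] != X_val.shape[1]:
        raise ValueError("train and validation gene spaces differ")
    labels_train = np.asarray([str(l) for l in labels_train])
    labels_val = np.asarray([str(l) for l in labels_val])
    if vocab is None:
        vocab = LabelVocabulary.from_labels(labels_train)

    reps_set = compute_representatives(X_train, labels_train, vocab)
    reps = reps_set.matrix
    T = len(vocab)
    train_idx = vocab.encode(labels_train)
    val_idx = vocab.encode(labels_val)
    Xtr = _dense(X_train)
    Xva = _dense(X_val)

    params = init_encoder(enc_cfg)
    rng = np.random.default_rng(train_cfg.seed)
    opt = _Adam(EncoderParams.TRAINABLE, lr=train_cfg.learning_rate)
    log = TrainLog()
    best_params = params.copy()
    best_val = np.inf
    n = Xtr.shape[0]
    m = train_cfg.margin

    stop = False
    epoch = 0
    for epoch in range(1, train_cfg.max_epochs + 1):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, train_cfg.batch_size):
            idx = order[start : start + train_cfg.batch_size]
            if idx.size < 2:
                continue  # batch-norm needs >= 2 rows
            Xb = np.vstack([Xtr[idx], reps])
            Z, cache = forward(params, Xb, enc_cfg, mode="train", rng=rng)
            z_cells, z_reps = Z[: idx.size], Z[idx.size :]
            loss, d_cells, d_reps = contrastive_loss_grad(z_cells, z_reps, train_idx[idx], m)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch} "
                    f"(lr={train_cfg.learning_rate}, margin={m})"
                )
            dZ = np.vstack([d_cells, d_reps])
            grads = backward(params, enc_cfg, cache, dZ)
            opt.step(params, grads)
            epoch_losses.append(loss)
        log.train_loss.append(float(np.mean(epoch_losses)) if epoch_losses else np.nan)

        if epoch % train_cfg.validate_every_epochs == 0:
            vloss = _validation_loss(params, enc_cfg, Xva, val_idx, reps, m)
            log.val_loss.append(vloss)
            log.val_epochs.append(epoch)
            if vloss < best_val:
                best_val = vloss
                best_params = params.copy()
            if early_stop_check(log.val_loss, train_cfg.patience_checks):
                stop = True
                break
    log.stopped_epoch = epoch
    log.stop_reason = "early_stop" if stop else "max_epochs"
    if not log.val_loss:  # no check ran (e.g. 0 epochs requested)
        best_params = params
    return best_params, reps_set, log
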