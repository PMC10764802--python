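"""MLP encoder mapping gene-expression profiles to a low-dimensional embedding.

Architecture (three dense layers, two normalized hidden blocks):

    hidden1 = BatchNorm(Dropout(ReLU(Dense(X))))
    hidden2 = BatchNorm(Dropout(ReLU(Dense(hidden1))))
    Z       = Dense(hidden2)

The network is small enough that a self-contained NumPy implementation
(explicit forward caches, analytic backprop in :mod:`sclsc.training`)
is both fast and dependency-free.  Train mode applies dropout and batch
statistics (updating running estimates); eval mode is a deterministic,
row-independent pure function of (params, X) using the running
statistics.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "EncoderConfig",
    "EncoderParams",
    "init_encoder",
    "embed",
    "forward",
    "save_checkpoint",
    "load_checkpoint",
]

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1  # running <- (1-m)*running + m*batch


@dataclass
class EncoderConfig:
    """Layer sizes, dropout rate and init seed for the encoder.

    ``input_dim`` is the number of genes d; ``output_dim`` the embedding
    dimension d' (16 by default — compact enough for fast KNN, wide
    enough to separate dozens of types).  Hidden sizes form a monotone
    bottleneck between the two.
    """

    input_dim: int
    hidden1_dim: int = 256
    hidden2_dim: int = 64
    output_dim: int = 16
    dropout_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("input_dim", "hidden1_dim", "hidden2_dim", "output_dim"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must lie in [0, 1)")


class EncoderParams:
    """Flat dict of named arrays: three dense layers + two batch-norm blocks.

    Dense layer l: ``Wl`` (fan_in x fan_out), ``bl``.  Batch-norm block
    l: affine ``gammal``/``betal`` and running ``rml``/``rvl``.
    """

    TRAINABLE = ("W1", "b1", "gamma1", "beta1", "W2", "b2", "gamma2", "beta2", "W3", "b3")

    def __init__(self, arrays: dict[str, np.ndarray]):
        self.arrays = {k: np.asarray(v, dtype=np.float64) for k, v in arrays.items()}
        for k, v in self.arrays.items():
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite values in parameter {k}")

    def __getitem__(self, key: str) -> np.ndarray:
        return self.arrays[key]

    def __setitem__(self, key: str, value: np.ndarray) -> None:
        self.arrays[key] = value

    def copy(self) -> "EncoderParams":
        return EncoderParams({k: v.copy() for k, v in self.arrays.items()})

    def dims(self) -> tuple[int, int, int, int]:
        return (
            self.arrays["W1"].shape[0],
            self.arrays["W1"].shape[1],
            self.arrays["W2"].shape[1],
            self.arrays["W3"].shape[1],
        )


def init_encoder(cfg: EncoderConfig) -> EncoderParams:
    """Deterministic fan-in-scaled uniform init; identity batch-norm state.

    Weights and biases of layer l are drawn from U(-k, k) with
    k = 1/sqrt(fan_in), the standard symmetric scaling for ReLU MLPs.
    """
    rng = np.random.default_rng(cfg.seed)
    dims = (cfg.input_dim, cfg.hidden1_dim, cfg.hidden2_dim, cfg.output_dim)
    arrays: dict[str, np.ndarray] = {}
    for l, (fan_in, fan_out) in enumerate(zip(dims[:-1], dims[1:]), start=1):
        k = 1.0 / np.sqrt(fan_in)
        arrays[f"W{l}"] = rng.uniform(-k, k, size=(fan_in, fan_out))
        arrays[f"b{l}"] = rng.uniform(-k, k, size=fan_out)
    for l, width in enumerate((cfg.hidden1_dim, cfg.hidden2_dim), start=1):
        arrays[f"gamma{l}"] = np.ones(width)
        arrays[f"beta{l}"] = np.zeros(width)
        arrays[f"rm{l}"] = np.zeros(width)
        arrays[f"rv{l}"] = np.ones(width)
    return EncoderParams(arrays)


def forward(
    params: EncoderParams,
    X: np.ndarray,
    cfg: EncoderConfig,
    mode: str = "eval",
    rng: np.random.Generator | None = None,
    update_running: bool = True,
) -> tuple[np.ndarray, dict]:
    """Forward pass returning (Z, cache); the cache feeds backprop.

    In train mode batch-norm uses batch statistics (batch size >= 2
    required) and dropout masks are drawn from ``rng``; running
    statistics are updated in place when ``update_running``.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != cfg.input_dim:
        raise ValueError(f"expected ({X.shape[0]}, {cfg.input_dim}) input, got {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in encoder input")
    if mode not in ("train", "eval"):
        raise ValueError(f"unknown mode {mode!r}")
    train = mode == "train"
    if train and X.shape[0] < 2:
        raise ValueError("train mode needs batch size >= 2 for batch statistics")
    if train and cfg.dropout_rate > 0 and rng is None:
        raise ValueError("train mode with dropout requires an rng")

    cache: dict = {"X": X, "mode": mode}
    h = X
    for l in (1, 2):
        lin = h @ params[f"W{l}"] + params[f"b{l}"]
        relu = np.maximum(lin, 0.0)
        if train and cfg.dropout_rate > 0:
            keep = 1.0 - cfg.dropout_rate
            mask = (rng.random(relu.shape) < keep) / keep  # inverted dropout
            dropped = relu * mask
        else:
            mask = None
            dropped = relu
        if train:
            mu = dropped.mean(axis=0)
            var = dropped.var(axis=0)
            if update_running:
                params[f"rm{l}"] = (1 - _BN_MOMENTUM) * params[f"rm{l}"] + _BN_MOMENTUM * mu
                params[f"rv{l}"] = (1 - _BN_MOMENTUM) * params[f"rv{l}"] + _BN_MOMENTUM * var
        else:
            mu = params[f"rm{l}"]
            var = params[f"rv{l}"]
        inv_std = 1.0 / np.sqrt(var + _BN_EPS)
        xhat = (dropped - mu) * inv_std
        h_next = params[f"gamma{l}"] * xhat + params[f"beta{l}"]
        cache[l] = {
            "input": h,
            "lin": lin,
            "relu": relu,
            "mask": mask,
            "dropped": dropped,
            "xhat": xhat,
            "inv_std": inv_std,
        }
        h = h_next
    Z = h @ params["W3"] + params["b3"]
    cache["h2"] = h
    return Z, cache


def backward(params: EncoderParams, cfg: EncoderConfig, cache: dict, dZ: np.ndarray) -> dict[str, np.ndarray]:
    """Analytic gradients of a scalar loss w.r.t. all trainable arrays.

    ``dZ`` is dLoss/dZ from the loss; batch-norm backprop uses the
    batch-statistics path in train mode and the constant running-stats
    path in eval mode.
    """
    grads: dict[str, np.ndarray] = {}
    h2 = cache["h2"]
    grads["W3"] = h2.T @ dZ
    grads["b3"] = dZ.sum(axis=0)
    dh = dZ @ params["W3"].T
    train = cache["mode"] == "train"
    for l in (2, 1):
        c = cache[l]
        grads[f"gamma{l}"] = (dh * c["xhat"]).sum(axis=0)
        grads[f"beta{l}"] = dh.sum(axis=0)
        dxhat = dh * params[f"gamma{l}"]
        if train:
            n = dxhat.shape[0]
            # full batch-norm backprop (mean/var depend on the batch)
            ddropped = (
                c["inv_std"]
                / n
                * (n * dxhat - dxhat.sum(axis=0) - c["xhat"] * (dxhat * c["xhat"]).sum(axis=0))
            )
        else:
            ddropped = dxhat * c["inv_std"]
        drelu = ddropped * c["mask"] if c["mask"] is not None else ddropped
        dlin = drelu * (c["lin"] > 0)
        grads[f"W{l}"] = c["input"].T @ dlin
        grads[f"b{l}"] = dlin.sum(axis=0)
        dh = dlin @ params[f"W{l}"].T
    return grads


def embed(params: EncoderParams, X: np.ndarray, cfg: EncoderConfig, mode: str = "eval",
          rng: np.random.Generator | None = None) -> np.ndarray:
    """Embed a batch of profiles; eval mode is deterministic and row-independent."""
    Z, _ = forward(params, X, cfg, mode=mode, rng=rng)
    return Z


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(
    params: EncoderParams,
    cfg: EncoderConfig,
    path,
    gene_ids: list[str] | None = None,
    label_types: list[str] | None = None,
) -> None:
    """Write weights (.npz) plus a JSON sidecar describing the model.

    The sidecar records layer dims, dropout, seed, the ordered HVG gene
    list and the label vocabulary, so a query pipeline can re-index its
    genes to the reference order before embedding.
    """
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **params.arrays)
    sidecar = {
        "config": asdict(cfg),
        "gene_ids": gene_ids,
        "label_types": label_types,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_checkpoint(path) -> tuple[EncoderParams, EncoderConfig, dict]:
    """Load (params, cfg, meta); meta carries gene_ids and label_types."""
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    cfg = EncoderConfig(**sidecar["config"])
    with np.load(path.with_suffix(".npz")) as npz:
        params = EncoderParams({k: npz[k] for k in npz.files})
    if params.dims() != (cfg.input_dim, cfg.hidden1_dim, cfg.hidden2_dim, cfg.output_dim):
        raise ValueError(
            f"checkpoint weight shapes {params.dims()} disagree with config "
            f"({cfg.input_dim}, {cfg.hidden1_dim}, {cfg.hidden2_dim}, {cfg.output_dim})"
        )
    meta = {"gene_ids": sidecar.get("gene_ids"), "label_types": sidecar.get("label_types")}
    return params, cfg, meta
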