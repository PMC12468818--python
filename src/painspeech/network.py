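"""The GRU-Mixer network: stacked bidirectional GRU, temporal mean pooling
("mixing"), dropout, and a linear softmax head.

The network consumes a Log-Mel spectrogram sequence (T x F per clip),
encodes it with L bidirectional GRU layers (inverted dropout between
layers while training), averages the top-layer hidden sequence over time
into a single utterance embedding, applies dropout to the embedding, and
maps it linearly to class logits.  Softmax over the logits gives posterior
probabilities; prediction is the argmax (ties to the lowest class index).

Everything is plain NumPy with hand-derived gradients; see
:mod:`painspeech.gru` for the recurrent primitives.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .gru import (
    GRUCellParams,
    bidirectional_backward,
    init_cell,
    run_layer_bidirectional,
    temporal_mean_pool,
)

__all__ = [
    "ModelConfig",
    "GRUMixerNet",
    "softmax",
    "predict_from_logits",
    "head_logits",
    "weighted_ce_from_logits",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class ModelConfig:
    input_size: int = 64
    hidden_size: int = 64
    num_layers: int = 3
    bidirectional: bool = True
    dropout_p: float = 0.5
    n_classes: int = 2

    def __post_init__(self) -> None:
        if self.hidden_size < 1 or self.num_layers < 1:
            raise ValueError("hidden_size and num_layers must be >= 1")
        if not 0 <= self.dropout_p < 1:
            raise ValueError("dropout_p must be in [0, 1)")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")

    @property
    def layer_width(self) -> int:
        return self.hidden_size * (2 if self.bidirectional else 1)


def softmax(o: np.ndarray) -> np.ndarray:
    o = np.asarray(o, dtype=np.float64)
    if not np.all(np.isfinite(o)):
        raise FloatingPointError("non-finite logits")
    shifted = o - o.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def predict_from_logits(o: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Posterior probabilities and argmax labels (ties -> lowest index)."""
    p = softmax(o)
    return p, np.argmax(p, axis=-1)


def head_logits(
    h_bar: np.ndarray,
    W_c: np.ndarray,
    b_c: np.ndarray,
    training: bool = False,
    dropout_p: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Linear class scores o = W_c h + b_c, with dropout on h while training."""
    h_bar = np.asarray(h_bar, dtype=np.float64)
    if h_bar.shape[-1] != W_c.shape[1]:
        raise ValueError(f"embedding width {h_bar.shape[-1]} != head width {W_c.shape[1]}")
    if training and dropout_p > 0:
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        mask = (rng.random(h_bar.shape) >= dropout_p) / (1.0 - dropout_p)
        h_bar = h_bar * mask
    return h_bar @ W_c.T + b_c


def weighted_ce_from_logits(
    logits: np.ndarray, y: np.ndarray, class_weights: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Class-weighted cross-entropy (mean over the batch) and its gradient.

    Computed from logits via log-sum-exp for stability; semantically the
    loss is -w_y * ln(p_y) per item.
    """
    logits = np.atleast_2d(np.asarray(logits, dtype=np.float64))
    y = np.asarray(y, dtype=np.intp)
    B, K = logits.shape
    w = np.ones(K) if class_weights is None else np.asarray(class_weights, dtype=np.float64)
    shifted = logits - logits.max(axis=1, keepdims=True)
    log_z = np.log(np.exp(shifted).sum(axis=1))
    log_p = shifted - log_z[:, None]
    wy = w[y]
    loss = float(np.mean(-wy * log_p[np.arange(B), y]))
    p = np.exp(log_p)
    dlogits = p * wy[:, None]
    dlogits[np.arange(B), y] -= wy
    return loss, dlogits / B


class GRUMixerNet:
    """Parameter container + forward/backward of the full classifier."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        self.layers: list[tuple[GRUCellParams, GRUCellParams | None]] = []
        in_size = config.input_size
        for _ in range(config.num_layers):
            fwd = init_cell(in_size, config.hidden_size, rng)
            bwd = init_cell(in_size, config.hidden_size, rng) if config.bidirectional else None
            self.layers.append((fwd, bwd))
            in_size = config.layer_width
        s = 1.0 / np.sqrt(config.layer_width)
        self.W_c = rng.uniform(-s, s, size=(config.n_classes, config.layer_width))
        self.b_c = np.zeros(config.n_classes)

    # --- parameter plumbing -------------------------------------------------

    def parameters(self) -> list[np.ndarray]:
        out = []
        for fwd, bwd in self.layers:
            out.extend(fwd.arrays())
            if bwd is not None:
                out.extend(bwd.arrays())
        out.extend([self.W_c, self.b_c])
        return out

    def set_parameters(self, arrays: list[np.ndarray]) -> None:
        current = self.parameters()
        if len(arrays) != len(current):
            raise ValueError("parameter count mismatch")
        for dst, src in zip(current, arrays):
            np.copyto(dst, src)

    # --- forward ------------------------------------------------------------

    def encode(
        self, X: np.ndarray, training: bool = False, rng: np.random.Generator | None = None,
        return_cache: bool = False,
    ):
        """Apply the GRU stack: (B, T, F) or (T, F) -> (B, T, 2H) or (T, 2H)."""
        squeeze = X.ndim == 2
        X = np.atleast_3d(X) if squeeze is False else X[None]
        if X.shape[2] != self.config.input_size:
            raise ValueError(
                f"feature width {X.shape[2]} != model input_size {self.config.input_size}"
            )
        if training and self.config.dropout_p > 0 and rng is None:
            raise ValueError("training-mode encode needs an rng for dropout")
        caches, masks = [], []
        out = X
        for i, (fwd, bwd) in enumerate(self.layers):
            if bwd is not None:
                out, cache = run_layer_bidirectional(out, fwd, bwd, return_cache=True)
            else:
                from .gru import gru_forward
                out, cache = gru_forward(out, fwd)
            caches.append(cache)
            if i < len(self.layers) - 1:
                if training and self.config.dropout_p > 0:
                    mask = (rng.random(out.shape) >= self.config.dropout_p) / (
                        1.0 - self.config.dropout_p
                    )
                    out = out * mask
                    masks.append(mask)
                else:
                    masks.append(None)
        if return_cache:
            return out, {"caches": caches, "masks": masks}
        return out[0] if squeeze else out

    def forward(
        self, X: np.ndarray, training: bool = False, rng: np.random.Generator | None = None,
        return_cache: bool = False,
    ):
        """Full pass: features (B, T, F) -> logits (B, n_classes)."""
        squeeze = X.ndim == 2
        Xb = X[None] if squeeze else X
        Hseq, cache = self.encode(Xb, training=training, rng=rng, return_cache=True)
        h_bar = temporal_mean_pool(Hseq)
        head_mask = None
        h_in = h_bar
        if training and self.config.dropout_p > 0:
            head_mask = (rng.random(h_bar.shape) >= self.config.dropout_p) / (
                1.0 - self.config.dropout_p
            )
            h_in = h_bar * head_mask
        logits = h_in @ self.W_c.T + self.b_c
        if return_cache:
            cache.update({"T": Xb.shape[1], "h_in": h_in, "head_mask": head_mask})
            return logits, cache
        return logits[0] if squeeze else logits

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Deterministic evaluation-mode probabilities and labels."""
        return predict_from_logits(self.forward(X, training=False))

    # --- backward -----------------------------------------------------------

    def backward(self, dlogits: np.ndarray, cache: dict) -> list[np.ndarray]:
        """Gradients for every parameter, aligned with :meth:`parameters`."""
        T = cache["T"]
        dW_c = dlogits.T @ cache["h_in"]
        db_c = dlogits.sum(axis=0)
        dh = dlogits @ self.W_c
        if cache["head_mask"] is not None:
            dh = dh * cache["head_mask"]
        dHseq = np.repeat(dh[:, None, :], T, axis=1) / T
        grads_layers: list[list[np.ndarray]] = []
        dOut = dHseq
        for i in range(len(self.layers) - 1, -1, -1):
            fwd, bwd = self.layers[i]
            if i < len(self.layers) - 1 and cache["masks"][i] is not None:
                dOut = dOut * cache["masks"][i]
            if bwd is not None:
                dOut, gf, gb = bidirectional_backward(dOut, cache["caches"][i], fwd, bwd)
                grads_layers.append(gf.arrays() + gb.arrays())
            else:
                from .gru import gru_backward
                dOut, gf = gru_backward(dOut, cache["caches"][i], fwd)
                grads_layers.append(gf.arrays())
        grads: list[np.ndarray] = []
        for g in reversed(grads_layers):
            grads.extend(g)
        grads.extend([dW_c, db_c])
        return grads


def save_checkpoint(path: str | Path, net: GRUMixerNet, metadata: dict | None = None) -> None:
    """Versioned checkpoint: all tensors plus model config and metadata."""
    path = Path(path)
    arrays = {f"param_{i:03d}": a for i, a in enumerate(net.parameters())}
    header = {
        "version": CHECKPOINT_VERSION,
        "model_config": vars(net.config) if not hasattr(net.config, "__dataclass_fields__")
        else {k: getattr(net.config, k) for k in net.config.__dataclass_fields__},
        "seed": net.seed,
        "metadata": metadata or {},
    }
    np.savez(path, __header__=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> tuple[GRUMixerNet, dict]:
    path = Path(path)
    with np.load(path) as data:
        header = json.loads(bytes(data["__header__"]).decode())
        if header.get("version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {header.get('version')}")
        config = ModelConfig(**header["model_config"])
        net = GRUMixerNet(config, seed=header["seed"])
        arrays = [data[f"param_{i:03d}"] for i in range(len(net.parameters()))]
    net.set_parameters(arrays)
    return net, header["metadata"]
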