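"""Bidirectional GRU encoder with temporal mean pooling — NumPy forward and
analytic backward passes.

A GRU cell updates its hidden state h_t from input x_t via

    z_t = sigmoid(W_z x_t + U_z h_{t-1} + b_z)        (update gate)
    r_t = sigmoid(W_r x_t + U_r h_{t-1} + b_r)        (reset gate)
    hc_t = tanh(W_h x_t + U_h (r_t * h_{t-1}) + b_h)  (candidate state)
    h_t = (1 - z_t) * h_{t-1} + z_t * hc_t

A bidirectional layer runs one cell forward in time and a second cell
backward, concatenating the two hidden sequences per step.  The encoder
stacks L such layers with inverted dropout between them (training mode
only); the utterance embedding is the arithmetic mean of the top layer's
outputs over time.

The backward pass is hand-derived and exact; tests check it against central
finite differences and the forward pass against a scalar-loop evaluation of
the cell equations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GRUCellParams",
    "init_cell",
    "sigmoid",
    "gru_cell_step",
    "gru_forward",
    "gru_backward",
    "run_layer_bidirectional",
    "temporal_mean_pool",
]

_GATES = ("Wz", "Wr", "Wh", "Uz", "Ur", "Uh", "bz", "br", "bh")


@dataclass
class GRUCellParams:
    """Weights of one GRU direction: W* (H x F), U* (H x H), b* (H,)."""

    Wz: np.ndarray
    Wr: np.ndarray
    Wh: np.ndarray
    Uz: np.ndarray
    Ur: np.ndarray
    Uh: np.ndarray
    bz: np.ndarray
    br: np.ndarray
    bh: np.ndarray

    def __post_init__(self) -> None:
        H, F = self.Wz.shape
        for name in _GATES:
            a = getattr(self, name)
            expected = (H, F) if name.startswith("W") else (H, H) if name.startswith("U") else (H,)
            if a.shape != expected:
                raise ValueError(f"{name} has shape {a.shape}, expected {expected}")
            if not np.all(np.isfinite(a)):
                raise ValueError(f"{name} contains non-finite entries")

    @property
    def hidden_size(self) -> int:
        return self.Wz.shape[0]

    @property
    def input_size(self) -> int:
        return self.Wz.shape[1]

    def arrays(self) -> list[np.ndarray]:
        return [getattr(self, name) for name in _GATES]

    def zeros_like(self) -> "GRUCellParams":
        return GRUCellParams(*[np.zeros_like(a) for a in self.arrays()])


def init_cell(input_size: int, hidden_size: int, rng: np.random.Generator) -> GRUCellParams:
    """Uniform initialization in +-1/sqrt(H), the usual recurrent-net scale."""
    s = 1.0 / np.sqrt(hidden_size)
    def u(*shape):
        return rng.uniform(-s, s, size=shape)
    return GRUCellParams(
        Wz=u(hidden_size, input_size), Wr=u(hidden_size, input_size), Wh=u(hidden_size, input_size),
        Uz=u(hidden_size, hidden_size), Ur=u(hidden_size, hidden_size), Uh=u(hidden_size, hidden_size),
        bz=u(hidden_size), br=u(hidden_size), bh=u(hidden_size),
    )


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def gru_cell_step(x_t: np.ndarray, h_prev: np.ndarray, p: GRUCellParams) -> np.ndarray:
    """One cell update for a single time step (vectors or batched rows)."""
    single = np.ndim(x_t) == 1
    x_t = np.atleast_2d(x_t)
    h_prev = np.atleast_2d(h_prev)
    if x_t.shape[1] != p.input_size or h_prev.shape[1] != p.hidden_size:
        raise ValueError(
            f"shape mismatch: x {x_t.shape}, h {h_prev.shape} vs cell "
            f"(F={p.input_size}, H={p.hidden_size})"
        )
    z = sigmoid(x_t @ p.Wz.T + h_prev @ p.Uz.T + p.bz)
    r = sigmoid(x_t @ p.Wr.T + h_prev @ p.Ur.T + p.br)
    hc = np.tanh(x_t @ p.Wh.T + (r * h_prev) @ p.Uh.T + p.bh)
    h = (1.0 - z) * h_prev + z * hc
    return h[0] if single else h


def gru_forward(X: np.ndarray, p: GRUCellParams) -> tuple[np.ndarray, dict]:
    """Run one direction over a batch.  X: (B, T, F) -> H-sequence (B, T, H).

    Returns the hidden sequence and a cache of gate activations for the
    backward pass.
    """
    B, T, F = X.shape
    H = p.hidden_size
    # input projections for all steps at once
    Az = X @ p.Wz.T + p.bz
    Ar = X @ p.Wr.T + p.br
    Ah = X @ p.Wh.T + p.bh
    Z = np.empty((B, T, H)); R = np.empty((B, T, H))
    HC = np.empty((B, T, H)); Hs = np.empty((B, T, H))
    h = np.zeros((B, H))
    for t in range(T):
        z = sigmoid(Az[:, t] + h @ p.Uz.T)
        r = sigmoid(Ar[:, t] + h @ p.Ur.T)
        hc = np.tanh(Ah[:, t] + (r * h) @ p.Uh.T)
        h = (1.0 - z) * h + z * hc
        Z[:, t], R[:, t], HC[:, t], Hs[:, t] = z, r, hc, h
    Hprev = np.concatenate([np.zeros((B, 1, H)), Hs[:, :-1]], axis=1)
    cache = {"X": X, "Z": Z, "R": R, "HC": HC, "Hprev": Hprev}
    return Hs, cache


def gru_backward(dH: np.ndarray, cache: dict, p: GRUCellParams) -> tuple[np.ndarray, GRUCellParams]:
    """Backprop through one direction.

    dH: (B, T, H) gradient w.r.t. the hidden sequence.  Returns (dX, grads)
    where grads mirrors the parameter structure.
    """
    X, Z, R, HC, Hprev = cache["X"], cache["Z"], cache["R"], cache["HC"], cache["Hprev"]
    B, T, H = dH.shape
    dAz = np.empty((B, T, H)); dAr = np.empty((B, T, H)); dAh = np.empty((B, T, H))
    dh = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        dh = dh + dH[:, t]
        z, r, hc, h_prev = Z[:, t], R[:, t], HC[:, t], Hprev[:, t]
        dz = dh * (hc - h_prev)
        daz = dz * z * (1.0 - z)
        dah = dh * z * (1.0 - hc * hc)
        drh = dah @ p.Uh               # grad w.r.t. (r * h_prev)
        dar = drh * h_prev * r * (1.0 - r)
        dAz[:, t], dAr[:, t], dAh[:, t] = daz, dar, dah
        dh = dh * (1.0 - z) + daz @ p.Uz + dar @ p.Ur + drh * r
    flat = lambda A: A.reshape(-1, A.shape[-1])
    RH = R * Hprev
    grads = GRUCellParams(
        Wz=flat(dAz).T @ flat(X), Wr=flat(dAr).T @ flat(X), Wh=flat(dAh).T @ flat(X),
        Uz=flat(dAz).T @ flat(Hprev), Ur=flat(dAr).T @ flat(Hprev), Uh=flat(dAh).T @ flat(RH),
        bz=flat(dAz).sum(0), br=flat(dAr).sum(0), bh=flat(dAh).sum(0),
    )
    dX = dAz @ p.Wz + dAr @ p.Wr + dAh @ p.Wh
    return dX, grads


def run_layer_bidirectional(
    X: np.ndarray, fwd: GRUCellParams, bwd: GRUCellParams, return_cache: bool = False
):
    """One bidirectional layer: (B, T, F) or (T, F) -> (B, T, 2H) or (T, 2H).

    Row t is [forward state at t ; backward state at t], both recursions
    starting from zero initial states.
    """
    squeeze = X.ndim == 2
    if squeeze:
        X = X[None]
    if X.shape[1] < 1:
        raise ValueError("empty sequence")
    Hf, cache_f = gru_forward(X, fwd)
    Hb_rev, cache_b = gru_forward(X[:, ::-1], bwd)
    out = np.concatenate([Hf, Hb_rev[:, ::-1]], axis=2)
    if squeeze:
        out = out[0]
    if return_cache:
        return out, (cache_f, cache_b)
    return out


def bidirectional_backward(
    dOut: np.ndarray, caches: tuple, fwd: GRUCellParams, bwd: GRUCellParams
) -> tuple[np.ndarray, GRUCellParams, GRUCellParams]:
    cache_f, cache_b = caches
    H = fwd.hidden_size
    dXf, gf = gru_backward(np.ascontiguousarray(dOut[:, :, :H]), cache_f, fwd)
    dXb, gb = gru_backward(np.ascontiguousarray(dOut[:, ::-1, H:]), cache_b, bwd)
    return dXf + dXb[:, ::-1], gf, gb


def temporal_mean_pool(Hseq: np.ndarray) -> np.ndarray:
    """Mean over time: (T, D) -> (D,) or (B, T, D) -> (B, D)."""
    Hseq = np.asarray(Hseq, dtype=np.float64)
    axis = Hseq.ndim - 2
    if Hseq.ndim < 2 or Hseq.shape[axis] < 1:
        raise ValueError("temporal_mean_pool needs at least one time step")
    return Hseq.mean(axis=axis)
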