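"""Dynamic attention fusion of the two encoder pathways.

For token representations T (LSTM pathway) and B (transformer pathway) the
gate runs, per position:

    T' = mean(T)              B' = mean(B)          (mean over hidden dim)
    T'' = w_t' T' + b_t'      B'' = w_b' B' + b_b'  (scalar linear maps)
    T''' = tanh(T'')          B''' = tanh(B'')
    [W_T; W_B] = softmax([T'''; B'''])
    V = W_T * T + W_B * B

so each position gets a convex pair of weights (W_T + W_B = 1, both in (0,1))
that decides how much of each pathway enters the fused representation V fed
to the CRF. The per-token mean axis makes the weights vary along the
sequence; ``pooling="sequence"`` pools over the whole sequence instead and
yields one global weight pair (ablation variant).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class FusionParams:
    """Two scalar->scalar linear maps, one per pathway."""

    w_t: float = 0.0
    b_t: float = 0.0
    w_b: float = 0.0
    b_b: float = 0.0

    @classmethod
    def init(cls, rng: np.random.Generator) -> "FusionParams":
        return cls(*(float(x) for x in rng.normal(0.0, 0.1, size=4)))

    def as_array(self) -> np.ndarray:
        return np.array([self.w_t, self.b_t, self.w_b, self.b_b])


@dataclass
class FusionOutput:
    v: np.ndarray  # (..., L, h) fused representation
    weight_t: np.ndarray  # (..., L) in (0,1)
    weight_b: np.ndarray  # (..., L); weight_t + weight_b = 1

    def weights_json(self) -> list[dict]:
        """Per-position weight pairs for inspection/interpretability dumps."""
        wt = np.atleast_1d(self.weight_t)
        wb = np.atleast_1d(self.weight_b)
        return [
            {"position": i, "lstm": float(a), "transformer": float(b)}
            for i, (a, b) in enumerate(zip(wt.ravel(), wb.ravel()))
        ]


@dataclass
class FusionCache:
    """Intermediates kept for the backward pass."""

    t: np.ndarray
    b: np.ndarray
    mask: np.ndarray
    s_t: np.ndarray  # per-position means
    s_b: np.ndarray
    a_t: np.ndarray  # tanh outputs
    a_b: np.ndarray
    w_t: np.ndarray  # softmax weights
    w_b: np.ndarray


def fuse(
    params: FusionParams,
    t: np.ndarray,
    b: np.ndarray,
    mask: np.ndarray | None = None,
    pooling: str = "token",
    return_cache: bool = False,
) -> FusionOutput | tuple[FusionOutput, FusionCache]:
    """Fuse pathway outputs ``t`` and ``b`` (same shape, (..., L, h)).

    Masked positions carry zero rows in V (their weights are reported as the
    softmax of the raw gate values but never contribute to the loss).
    """
    t = np.asarray(t, dtype=float)
    b = np.asarray(b, dtype=float)
    if t.shape != b.shape:
        raise ValueError(f"pathway shapes differ: {t.shape} vs {b.shape}")
    if mask is None:
        mask = np.ones(t.shape[:-1])
    mask = np.asarray(mask, dtype=float)
    if mask.shape != t.shape[:-1]:
        raise ValueError("mask shape does not match token axes")

    if pooling == "token":
        s_t = t.mean(axis=-1)  # (..., L)
        s_b = b.mean(axis=-1)
    elif pooling == "sequence":
        denom = np.maximum(mask.sum(axis=-1, keepdims=True), 1.0)
        s_t = np.broadcast_to(
            (t.mean(axis=-1) * mask).sum(axis=-1, keepdims=True) / denom, mask.shape
        ).copy()
        s_b = np.broadcast_to(
            (b.mean(axis=-1) * mask).sum(axis=-1, keepdims=True) / denom, mask.shape
        ).copy()
    else:
        raise ValueError(f"unknown pooling {pooling!r}")

    a_t = np.tanh(params.w_t * s_t + params.b_t)
    a_b = np.tanh(params.w_b * s_b + params.b_b)
    m = np.maximum(a_t, a_b)
    e_t = np.exp(a_t - m)
    e_b = np.exp(a_b - m)
    z = e_t + e_b
    w_t = e_t / z
    w_b = e_b / z
    v = (w_t[..., None] * t + w_b[..., None] * b) * mask[..., None]
    out = FusionOutput(v, w_t, w_b)
    if not return_cache:
        return out
    return out, FusionCache(t, b, mask, s_t, s_b, a_t, a_b, w_t, w_b)


def fuse_backward(
    params: FusionParams, cache: FusionCache, d_v: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Backward pass of :func:`fuse` with token pooling.

    Returns ``(d_t, d_b, d_params)`` where ``d_params`` is the gradient for
    ``[w_t, b_t, w_b, b_b]``. Gradients flow into BOTH pathway inputs; the
    caller may discard ``d_b`` when the transformer pathway is frozen.
    """
    h = cache.t.shape[-1]
    d_v = d_v * cache.mask[..., None]
    d_t = cache.w_t[..., None] * d_v
    d_b = cache.w_b[..., None] * d_v
    dw_t = np.sum(d_v * cache.t, axis=-1)  # d loss / d weight_t per position
    dw_b = np.sum(d_v * cache.b, axis=-1)
    # softmax over the 2-vector [a_t, a_b]
    da_t = cache.w_t * cache.w_b * (dw_t - dw_b)
    da_b = -da_t
    du_t = da_t * (1.0 - cache.a_t**2)
    du_b = da_b * (1.0 - cache.a_b**2)
    g = np.array(
        [
            float(np.sum(du_t * cache.s_t)),
            float(np.sum(du_t)),
            float(np.sum(du_b * cache.s_b)),
            float(np.sum(du_b)),
        ]
    )
    d_t += (du_t * params.w_t)[..., None] / h
    d_b += (du_b * params.w_b)[..., None] / h
    return d_t, d_b, g
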