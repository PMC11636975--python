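"""Linear-chain conditional random field over per-token emission scores.

The score of a tag path y for a length-L sequence is

    s(y) = start[y_0] + sum_t e[t, y_t] + sum_t A[y_{t-1}, y_t] + stop[y_{L-1}]

where ``e`` is the emission matrix (here an affine projection of the fused
token representations), ``A`` the learned tag-transition matrix and
``start``/``stop`` boundary scores. p(y|x) = exp(s(y)) / Z with the partition
Z summed over all K^L paths; Z is computed exactly by the forward recursion
in log space. Decoding is exact Viterbi; ties prefer the lower tag index at
every backtrack step, which makes decoding deterministic.

Transitions are learned, not hard-constrained: the model is expected to learn
that e.g. O -> I-X is a bad move. An optional BIO constraint mask for
decoding is available for users who want guaranteed-legal output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus import TagSet


def _logsumexp(a: np.ndarray, axis: int | None = None) -> np.ndarray:
    if axis is None:
        m = float(np.max(a))
        return m + float(np.log(np.sum(np.exp(a - m))))
    m = np.max(a, axis=axis, keepdims=True)
    out = m + np.log(np.sum(np.exp(a - m), axis=axis, keepdims=True))
    return np.squeeze(out, axis=axis)


@dataclass
class CrfParams:
    """Emission projection plus transition/boundary scores for K tags."""

    proj: np.ndarray  # (h_model, K)
    proj_bias: np.ndarray  # (K,)
    transitions: np.ndarray  # (K, K); [i, j] scores moving i -> j
    start: np.ndarray  # (K,)
    stop: np.ndarray  # (K,)

    def __post_init__(self) -> None:
        k = self.proj.shape[1]
        if self.transitions.shape != (k, k):
            raise ValueError("transition matrix shape inconsistent with projection")
        if self.start.shape != (k,) or self.stop.shape != (k,):
            raise ValueError("boundary score shapes inconsistent")

    @property
    def n_tags(self) -> int:
        return self.proj.shape[1]

    @classmethod
    def init(cls, h_model: int, n_tags: int, rng: np.random.Generator) -> "CrfParams":
        scale = 1.0 / np.sqrt(h_model)
        return cls(
            proj=rng.normal(0.0, scale, size=(h_model, n_tags)),
            proj_bias=np.zeros(n_tags),
            transitions=rng.normal(0.0, 0.01, size=(n_tags, n_tags)),
            start=np.zeros(n_tags),
            stop=np.zeros(n_tags),
        )


def emissions(params: CrfParams, v: np.ndarray) -> np.ndarray:
    """Affine row-wise map of fused representations (L, h) to scores (L, K)."""
    if v.ndim != 2 or v.shape[1] != params.proj.shape[0]:
        raise ValueError(f"expected (L, {params.proj.shape[0]}) input, got {v.shape}")
    return v @ params.proj + params.proj_bias


def path_score(params: CrfParams, e: np.ndarray, y: np.ndarray) -> float:
    """Score of one tag path under emissions ``e``."""
    y = np.asarray(y, dtype=int)
    if len(y) != e.shape[0]:
        raise ValueError("path length does not match emission rows")
    if np.any(y < 0) or np.any(y >= params.n_tags):
        raise IndexError("tag index out of range")
    s = params.start[y[0]] + e[np.arange(len(y)), y].sum() + params.stop[y[-1]]
    if len(y) > 1:
        s += params.transitions[y[:-1], y[1:]].sum()
    return float(s)


def _forward(params: CrfParams, e: np.ndarray) -> np.ndarray:
    """Log-space forward variables alpha, shape (L, K)."""
    L = e.shape[0]
    alpha = np.empty_like(e)
    alpha[0] = params.start + e[0]
    for t in range(1, L):
        alpha[t] = e[t] + _logsumexp(alpha[t - 1][:, None] + params.transitions, axis=0)
    return alpha


def log_partition(params: CrfParams, e: np.ndarray) -> float:
    """log Z: log-sum-exp of path scores over all K^L paths."""
    if e.shape[0] == 0:
        raise ValueError("empty emission matrix")
    alpha = _forward(params, e)
    return float(_logsumexp(alpha[-1] + params.stop))


def nll(params: CrfParams, e: np.ndarray, y_gold: np.ndarray) -> float:
    """Negative log-likelihood of the gold path; always >= 0."""
    return log_partition(params, e) - path_score(params, e, y_gold)


def viterbi_decode(
    params: CrfParams,
    e: np.ndarray,
    tag_constraints: np.ndarray | None = None,
    start_constraints: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Highest-scoring tag path and its score (exact dynamic program).

    ``tag_constraints`` is an optional (K, K) additive mask (e.g. -inf on
    illegal BIO transitions) applied on top of the learned transitions;
    ``start_constraints`` is the analogous (K,) mask for the first position.
    """
    if e.shape[0] == 0:
        raise ValueError("empty emission matrix")
    A = params.transitions
    if tag_constraints is not None:
        A = A + tag_constraints
    L, K = e.shape
    delta = params.start + e[0]
    if start_constraints is not None:
        delta = delta + start_constraints
    back = np.zeros((L, K), dtype=int)
    for t in range(1, L):
        cand = delta[:, None] + A  # (prev, cur)
        back[t] = np.argmax(cand, axis=0)  # argmax -> lowest index on ties
        delta = cand[back[t], np.arange(K)] + e[t]
    delta = delta + params.stop
    best = int(np.argmax(delta))
    path = np.empty(L, dtype=int)
    path[-1] = best
    for t in range(L - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path, float(delta[best])


def bio_constraint_mask(tagset: TagSet, penalty: float = -1e4) -> np.ndarray:
    """Additive (K, K) mask penalising transitions that break strict BIO."""
    K = len(tagset)
    mask = np.zeros((K, K))
    for j, to_tag in enumerate(tagset.tags):
        if not to_tag.startswith("I-"):
            continue
        t = to_tag[2:]
        for i, from_tag in enumerate(tagset.tags):
            if from_tag not in (f"B-{t}", f"I-{t}"):
                mask[i, j] = penalty
    return mask


def bio_start_mask(tagset: TagSet, penalty: float = -1e4) -> np.ndarray:
    """Additive (K,) mask: a sequence may not open with an I- tag."""
    return np.array(
        [penalty if t.startswith("I-") else 0.0 for t in tagset.tags]
    )


@dataclass
class CrfGradients:
    """d(nll)/d(theta) for one sequence, plus d(nll)/d(emissions)."""

    d_emissions: np.ndarray
    d_transitions: np.ndarray
    d_start: np.ndarray
    d_stop: np.ndarray
    value: float  # the nll itself
    log_z: float = field(default=0.0)


def nll_gradients(params: CrfParams, e: np.ndarray, y_gold: np.ndarray) -> CrfGradients:
    """NLL and its exact gradients via the forward-backward marginals.

    d nll / d e[t,k]          = P(y_t = k | x) - [y_gold_t = k]
    d nll / d A[i,j]          = sum_t P(y_t=i, y_{t+1}=j | x) - gold pair counts
    d nll / d start, stop     = boundary marginals minus gold indicators
    """
    y = np.asarray(y_gold, dtype=int)
    L, K = e.shape
    alpha = _forward(params, e)
    beta = np.empty_like(e)
    beta[-1] = params.stop
    for t in range(L - 2, -1, -1):
        beta[t] = _logsumexp(
            params.transitions + (e[t + 1] + beta[t + 1])[None, :], axis=1
        )
    log_z = float(_logsumexp(alpha[-1] + params.stop))

    unary = np.exp(alpha + beta - log_z)  # (L, K) marginals
    d_e = unary.copy()
    d_e[np.arange(L), y] -= 1.0

    d_a = np.zeros((K, K))
    for t in range(L - 1):
        pair = np.exp(
            alpha[t][:, None]
            + params.transitions
            + (e[t + 1] + beta[t + 1])[None, :]
            - log_z
        )
        d_a += pair
        d_a[y[t], y[t + 1]] -= 1.0

    d_start = unary[0].copy()
    d_start[y[0]] -= 1.0
    d_stop = unary[-1].copy()
    d_stop[y[-1]] -= 1.0

    value = log_z - path_score(params, e, y)
    return CrfGradients(d_e, d_a, d_start, d_stop, value, log_z)
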