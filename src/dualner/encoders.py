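"""The two parallel token-representation pathways.

* LSTM pathway: CBOW character vectors run through a (bi)directional LSTM;
  the concatenated directions are linearly projected to ``h_model`` so the
  output is shape-compatible with the transformer pathway. Gates follow the
  standard formulation

      F_t = sigma(W_f X_t + U_f H_{t-1} + b_f)      (forget)
      I_t = sigma(W_i X_t + U_i H_{t-1} + b_i)      (input)
      O_t = sigma(W_o X_t + U_o H_{t-1} + b_o)      (output)
      C~_t = tanh(W_c X_t + U_c H_{t-1} + b_c)
      C_t = F_t * C_{t-1} + I_t * C~_t,   H_t = O_t * tanh(C_t).

* Transformer pathway: a pluggable encoder. The built-in implementation is a
  small deterministic (seeded) pre-LayerNorm transformer with its own
  character vocabulary, [CLS]/[SEP] markers (stripped from the output) and an
  npz checkpoint format. It is used frozen, as a feature extractor.

Both pathways emit ``length x h_model`` matrices for the same sequence.

Everything is numpy; the LSTM forward keeps the per-step tensors needed for
exact backpropagation through time (see :class:`LstmCache`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .corpus import LabeledSequence


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


# ---------------------------------------------------------------------------
# LSTM pathway
# ---------------------------------------------------------------------------


@dataclass
class LstmParams:
    """One direction's gate parameters, packed [forget, input, output, cell]."""

    w: np.ndarray  # (input_dim, 4*units)
    u: np.ndarray  # (units, 4*units)
    b: np.ndarray  # (4*units,)

    def __post_init__(self) -> None:
        units = self.u.shape[0]
        if self.w.shape[1] != 4 * units or self.u.shape != (units, 4 * units):
            raise ValueError("inconsistent LSTM weight shapes")
        if self.b.shape != (4 * units,):
            raise ValueError("inconsistent LSTM bias shape")

    @property
    def units(self) -> int:
        return self.u.shape[0]

    @property
    def input_dim(self) -> int:
        return self.w.shape[0]

    @classmethod
    def init(
        cls, input_dim: int, units: int, rng: np.random.Generator
    ) -> "LstmParams":
        s_w = 1.0 / np.sqrt(input_dim)
        s_u = 1.0 / np.sqrt(units)
        b = np.zeros(4 * units)
        b[:units] = 1.0  # forget-gate bias 1: remember by default
        return cls(
            w=rng.uniform(-s_w, s_w, size=(input_dim, 4 * units)),
            u=rng.uniform(-s_u, s_u, size=(units, 4 * units)),
            b=b,
        )

    def zeros_like(self) -> "LstmParams":
        return LstmParams(np.zeros_like(self.w), np.zeros_like(self.u), np.zeros_like(self.b))


def lstm_step(
    params: LstmParams, x_t: np.ndarray, h_prev: np.ndarray, c_prev: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM step for a single vector (or a batch of row vectors)."""
    if x_t.shape[-1] != params.input_dim:
        raise ValueError(f"input dim {x_t.shape[-1]} != {params.input_dim}")
    if h_prev.shape[-1] != params.units or c_prev.shape[-1] != params.units:
        raise ValueError("state dims do not match units")
    n = params.units
    z = x_t @ params.w + h_prev @ params.u + params.b
    f = sigmoid(z[..., :n])
    i = sigmoid(z[..., n : 2 * n])
    o = sigmoid(z[..., 2 * n : 3 * n])
    g = np.tanh(z[..., 3 * n :])
    c_t = f * c_prev + i * g
    h_t = o * np.tanh(c_t)
    return h_t, c_t


@dataclass
class LstmCache:
    """Per-step tensors saved by a batched forward pass, for BPTT."""

    x: np.ndarray  # (B, L, input_dim)
    mask: np.ndarray  # (B, L) float 0/1
    h_prev: np.ndarray  # (B, L, units) post-mask h_{t-1}
    c_prev: np.ndarray  # (B, L, units)
    f: np.ndarray
    i: np.ndarray
    o: np.ndarray
    g: np.ndarray
    c_raw: np.ndarray  # pre-mask cell state
    h: np.ndarray  # (B, L, units) post-mask outputs


def lstm_forward(
    params: LstmParams, x: np.ndarray, mask: np.ndarray
) -> tuple[np.ndarray, LstmCache]:
    """Run one direction over a padded batch; padded steps keep zero state.

    ``x`` is (B, L, input_dim); ``mask`` is (B, L) with 1 on real tokens.
    Masking multiplies both h and c by the step mask, which leaves valid
    prefixes untouched (pads trail in the iteration order used here).
    """
    if x.ndim != 3:
        raise ValueError("expected (batch, length, dim) input")
    B, L, _ = x.shape
    n = params.units
    m = mask.astype(float)
    h = np.zeros((B, n))
    c = np.zeros((B, n))
    cache = LstmCache(
        x=x,
        mask=m,
        h_prev=np.zeros((B, L, n)),
        c_prev=np.zeros((B, L, n)),
        f=np.zeros((B, L, n)),
        i=np.zeros((B, L, n)),
        o=np.zeros((B, L, n)),
        g=np.zeros((B, L, n)),
        c_raw=np.zeros((B, L, n)),
        h=np.zeros((B, L, n)),
    )
    for t in range(L):
        cache.h_prev[:, t] = h
        cache.c_prev[:, t] = c
        z = x[:, t] @ params.w + h @ params.u + params.b
        f = sigmoid(z[:, :n])
        i = sigmoid(z[:, n : 2 * n])
        o = sigmoid(z[:, 2 * n : 3 * n])
        g = np.tanh(z[:, 3 * n :])
        c_raw = f * c + i * g
        h_raw = o * np.tanh(c_raw)
        mt = m[:, t][:, None]
        h = h_raw * mt
        c = c_raw * mt
        cache.f[:, t], cache.i[:, t], cache.o[:, t] = f, i, o
        cache.g[:, t], cache.c_raw[:, t], cache.h[:, t] = g, c_raw, h
    return cache.h, cache


def lstm_backward(
    params: LstmParams, cache: LstmCache, d_h_out: np.ndarray
) -> tuple[LstmParams, np.ndarray]:
    """Exact BPTT given d(loss)/d(h outputs); returns (grads, d_x)."""
    B, L, n = cache.h.shape
    grads = params.zeros_like()
    d_x = np.zeros_like(cache.x)
    dh_next = np.zeros((B, n))
    dc_next = np.zeros((B, n))
    for t in range(L - 1, -1, -1):
        mt = cache.mask[:, t][:, None]
        dh_total = d_h_out[:, t] + dh_next
        dh_raw = dh_total * mt
        f, i, o, g = cache.f[:, t], cache.i[:, t], cache.o[:, t], cache.g[:, t]
        tanh_c = np.tanh(cache.c_raw[:, t])
        do = dh_raw * tanh_c
        dc_raw = dc_next * mt + dh_raw * o * (1.0 - tanh_c**2)
        df = dc_raw * cache.c_prev[:, t]
        di = dc_raw * g
        dg = dc_raw * i
        dc_next = dc_raw * f
        dz = np.concatenate(
            [
                df * f * (1.0 - f),
                di * i * (1.0 - i),
                do * o * (1.0 - o),
                dg * (1.0 - g**2),
            ],
            axis=1,
        )
        grads.w += cache.x[:, t].T @ dz
        grads.u += cache.h_prev[:, t].T @ dz
        grads.b += dz.sum(axis=0)
        d_x[:, t] = dz @ params.w.T
        dh_next = dz @ params.u.T
    return grads, d_x


def lstm_encode(
    params: LstmParams,
    embedded: np.ndarray,
    mask: np.ndarray,
    params_bwd: LstmParams | None = None,
) -> np.ndarray:
    """Encode one sequence (L, d) -> (L, units) or (L, 2*units) if bidirectional.

    Convenience single-sequence API (no cache); the training loop uses the
    batched ``lstm_forward`` directly. Padded positions emit zero rows.
    """
    if embedded.ndim != 2 or embedded.shape[0] == 0:
        raise ValueError("expected a non-empty (length, dim) matrix")
    if embedded.shape[0] != len(mask):
        raise ValueError("mask length does not match sequence length")
    x = embedded[None]
    m = np.asarray(mask, dtype=float)[None]
    h_fwd, _ = lstm_forward(params, x, m)
    if params_bwd is None:
        return h_fwd[0]
    h_bwd, _ = lstm_forward(params_bwd, x[:, ::-1], m[:, ::-1])
    return np.concatenate([h_fwd[0], h_bwd[0, ::-1]], axis=1)


# ---------------------------------------------------------------------------
# Transformer pathway
# ---------------------------------------------------------------------------

_SPECIALS = ("[PAD]", "[UNK]", "[CLS]", "[SEP]")


@dataclass
class TransformerConfig:
    hidden: int = 32
    n_layers: int = 2
    n_heads: int = 2
    ffn: int = 64
    max_len: int = 512
    seed: int = 0


class TinyTransformer:
    """Small deterministic transformer encoder over characters.

    One output row per input character; [CLS]/[SEP] are added internally and
    stripped from the output. Weights are drawn once from the seeded rng at
    construction, so two encoders built with the same vocabulary and seed are
    bit-identical. The encoder is used frozen (feature extractor).
    """

    def __init__(self, vocab: dict[str, int], config: TransformerConfig):
        if config.hidden % config.n_heads:
            raise ValueError("hidden must divide evenly into heads")
        self.vocab = vocab
        self.config = config
        rng = np.random.default_rng(config.seed)
        h, f = config.hidden, config.ffn
        s = 0.5 / np.sqrt(h)
        self.tok_emb = rng.normal(0, s, size=(len(vocab), h))
        self.tok_emb[vocab["[PAD]"]] = 0.0
        pos = np.arange(config.max_len)[:, None]
        div = np.exp(-np.log(10000.0) * np.arange(0, h, 2) / h)
        self.pos_emb = np.zeros((config.max_len, h))
        self.pos_emb[:, 0::2] = np.sin(pos * div)
        self.pos_emb[:, 1::2] = np.cos(pos * div[: self.pos_emb[:, 1::2].shape[1]])
        self.layers = []
        for _ in range(config.n_layers):
            self.layers.append(
                {
                    "wq": rng.normal(0, s, (h, h)),
                    "wk": rng.normal(0, s, (h, h)),
                    "wv": rng.normal(0, s, (h, h)),
                    "wo": rng.normal(0, s, (h, h)),
                    "w1": rng.normal(0, s, (h, f)),
                    "b1": np.zeros(f),
                    "w2": rng.normal(0, 0.5 / np.sqrt(f), (f, h)),
                    "b2": np.zeros(h),
                    "ln1_g": np.ones(h),
                    "ln1_b": np.zeros(h),
                    "ln2_g": np.ones(h),
                    "ln2_b": np.zeros(h),
                }
            )

    @classmethod
    def from_charset(
        cls, chars: set[str] | list[str], config: TransformerConfig | None = None
    ) -> "TinyTransformer":
        config = config or TransformerConfig()
        vocab = {t: i for i, t in enumerate(_SPECIALS)}
        for c in sorted(set(chars)):
            vocab[c] = len(vocab)
        return cls(vocab, config)

    @property
    def hidden(self) -> int:
        return self.config.hidden

    @staticmethod
    def _ln(x: np.ndarray, g: np.ndarray, b: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        sd = np.sqrt(x.var(axis=-1, keepdims=True) + 1e-6)
        return (x - mu) / sd * g + b

    def encode_ids(self, chars: list[str]) -> np.ndarray:
        unk = self.vocab["[UNK]"]
        return np.array(
            [self.vocab["[CLS]"]]
            + [self.vocab.get(c, unk) for c in chars]
            + [self.vocab["[SEP]"]],
            dtype=int,
        )

    def encode_batch(self, batch: list[list[str]]) -> tuple[np.ndarray, np.ndarray]:
        """Encode sequences -> ((B, L_max, hidden), (B, L_max) mask).

        L_max is the longest raw sequence; marker rows are already stripped
        and padded rows are zero.
        """
        ids = [self.encode_ids(chars) for chars in batch]
        L = max(len(i) for i in ids)
        id_mat = np.zeros((len(ids), L), dtype=int)
        mask = np.zeros((len(ids), L))
        for b, row in enumerate(ids):
            id_mat[b, : len(row)] = row
            mask[b, : len(row)] = 1.0
        x = self.tok_emb[id_mat] + self.pos_emb[:L][None]
        x *= mask[..., None]
        nh = self.config.n_heads
        dh = self.hidden // nh
        att_bias = (1.0 - mask)[:, None, None, :] * -1e9  # (B,1,1,L)
        for layer in self.layers:
            y = self._ln(x, layer["ln1_g"], layer["ln1_b"])
            q = (y @ layer["wq"]).reshape(len(ids), L, nh, dh).transpose(0, 2, 1, 3)
            k = (y @ layer["wk"]).reshape(len(ids), L, nh, dh).transpose(0, 2, 1, 3)
            v = (y @ layer["wv"]).reshape(len(ids), L, nh, dh).transpose(0, 2, 1, 3)
            scores = q @ k.transpose(0, 1, 3, 2) / np.sqrt(dh) + att_bias
            scores -= scores.max(axis=-1, keepdims=True)
            att = np.exp(scores)
            att /= att.sum(axis=-1, keepdims=True)
            ctx = (att @ v).transpose(0, 2, 1, 3).reshape(len(ids), L, self.hidden)
            x = x + ctx @ layer["wo"]
            y = self._ln(x, layer["ln2_g"], layer["ln2_b"])
            x = x + np.maximum(y @ layer["w1"] + layer["b1"], 0.0) @ layer["w2"] + layer["b2"]
            x *= mask[..., None]
        # strip [CLS]/[SEP]: keep rows 1..len-1 per sequence
        out_len = max(len(row) - 2 for row in ids)
        out = np.zeros((len(ids), out_len, self.hidden))
        out_mask = np.zeros((len(ids), out_len))
        for b, row in enumerate(ids):
            n = len(row) - 2
            out[b, :n] = x[b, 1 : 1 + n]
            out_mask[b, :n] = 1.0
        return out, out_mask

    def encode(self, seq: LabeledSequence | list[str]) -> np.ndarray:
        """One output row per input character (markers stripped)."""
        chars = seq.chars if isinstance(seq, LabeledSequence) else list(seq)
        if not chars:
            return np.zeros((0, self.hidden))
        out, _ = self.encode_batch([chars])
        return out[0]

    # -- checkpointing -----------------------------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "config.json").write_text(
            json.dumps(self.config.__dict__), encoding="utf-8"
        )
        inv = sorted(self.vocab, key=self.vocab.get)
        (directory / "vocab.txt").write_text("\n".join(inv) + "\n", encoding="utf-8")
        arrays = {"tok_emb": self.tok_emb, "pos_emb": self.pos_emb}
        for li, layer in enumerate(self.layers):
            for k, v in layer.items():
                arrays[f"layer{li}_{k}"] = v
        np.savez(directory / "weights.npz", **arrays)

    @classmethod
    def load(cls, directory: str | Path) -> "TinyTransformer":
        directory = Path(directory)
        config = TransformerConfig(
            **json.loads((directory / "config.json").read_text(encoding="utf-8"))
        )
        vocab = {
            t: i
            for i, t in enumerate(
                (directory / "vocab.txt").read_text(encoding="utf-8").splitlines()
            )
        }
        enc = cls(vocab, config)
        with np.load(directory / "weights.npz") as data:
            enc.tok_emb = data["tok_emb"]
            enc.pos_emb = data["pos_emb"]
            for li, layer in enumerate(enc.layers):
                for k in layer:
                    layer[k] = data[f"layer{li}_{k}"]
        return enc
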