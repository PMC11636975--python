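"""End-to-end tagger assembling the two pathways, the fusion gate and the CRF.

Four architecture variants share one implementation:

* ``fused``       — LSTM pathway + frozen transformer pathway, combined by the
                    dynamic attention gate (the full model).
* ``lstm``        — LSTM pathway only (CBOW -> BiLSTM -> projection -> CRF).
* ``transformer`` — frozen transformer features straight into the CRF.
* ``stacked``     — transformer features fed INTO the LSTM (the classic
                    sequential BERT-LSTM-CRF layout), then CRF.

Training is plain numpy: the forward pass caches what exact backpropagation
needs, gradients are assembled by hand (BPTT through the LSTM, analytic
softmax/tanh chain through the fusion gate, forward-backward marginals in the
CRF) and applied with AdamW. The transformer pathway is frozen — it acts as a
fixed feature extractor, so no gradient flows into it by design.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import crf as crf_mod
from .cbow import EmbeddingTable
from .corpus import TagSet
from .crf import CrfParams
from .encoders import LstmParams, TinyTransformer, lstm_backward, lstm_forward
from .fusion import FusionParams, fuse, fuse_backward

VARIANTS = ("fused", "lstm", "transformer", "stacked")


class DivergenceError(RuntimeError):
    """Loss became non-finite during training."""


@dataclass
class BatchResult:
    loss: float
    grads: dict[str, np.ndarray] | None


class Tagger:
    """Character tagger with a dual-pathway encoder and CRF decoder."""

    def __init__(
        self,
        tagset: TagSet,
        table: EmbeddingTable,
        encoder: TinyTransformer | None,
        lstm_units: int = 128,
        h_model: int | None = None,
        variant: str = "fused",
        bidirectional: bool = True,
        seed: int = 0,
    ):
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}")
        if variant in ("fused", "transformer", "stacked") and encoder is None:
            raise ValueError(f"variant {variant!r} needs a transformer encoder")
        self.tagset = tagset
        self.table = table
        self.encoder = encoder
        self.variant = variant
        self.bidirectional = bidirectional
        self.lstm_units = lstm_units
        if h_model is None:
            h_model = encoder.hidden if encoder is not None else lstm_units
        if encoder is not None and encoder.hidden != h_model:
            raise ValueError("h_model must equal the transformer hidden size")
        self.h_model = h_model

        rng = np.random.default_rng(seed)
        lstm_in = encoder.hidden if variant == "stacked" else table.dim
        self.emb = table.vectors.copy()
        self.lstm_f = LstmParams.init(lstm_in, lstm_units, rng)
        self.lstm_b = LstmParams.init(lstm_in, lstm_units, rng) if bidirectional else None
        d_cat = lstm_units * (2 if bidirectional else 1)
        self.proj_w = rng.normal(0.0, 1.0 / np.sqrt(d_cat), size=(d_cat, h_model))
        self.proj_b = np.zeros(h_model)
        self.fusion = np.array(FusionParams.init(rng).as_array())
        self.crf = CrfParams.init(h_model, len(tagset), rng)

    # -- parameter plumbing ------------------------------------------------

    def parameters(self) -> dict[str, np.ndarray]:
        params = {
            "crf_proj": self.crf.proj,
            "crf_bias": self.crf.proj_bias,
            "crf_trans": self.crf.transitions,
            "crf_start": self.crf.start,
            "crf_stop": self.crf.stop,
        }
        if self.variant != "transformer":
            params.update(
                {
                    "lstm_f_w": self.lstm_f.w,
                    "lstm_f_u": self.lstm_f.u,
                    "lstm_f_b": self.lstm_f.b,
                    "proj_w": self.proj_w,
                    "proj_b": self.proj_b,
                }
            )
            if self.lstm_b is not None:
                params.update(
                    {
                        "lstm_b_w": self.lstm_b.w,
                        "lstm_b_u": self.lstm_b.u,
                        "lstm_b_b": self.lstm_b.b,
                    }
                )
            if self.variant != "stacked":
                params["emb"] = self.emb
        if self.variant == "fused":
            params["fusion"] = self.fusion
        return params

    def set_parameters(self, values: dict[str, np.ndarray]) -> None:
        own = self.parameters()
        for name, arr in values.items():
            own[name][...] = arr

    def snapshot(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.parameters().items()}

    def _fusion_params(self) -> FusionParams:
        return FusionParams(*(float(x) for x in self.fusion))

    # -- forward / backward ------------------------------------------------

    def _pad(self, batch: list[list[str]]) -> tuple[np.ndarray, np.ndarray]:
        L = max(len(c) for c in batch)
        ids = np.zeros((len(batch), L), dtype=int)
        mask = np.zeros((len(batch), L))
        for b, chars in enumerate(batch):
            ids[b, : len(chars)] = self.table.indices(chars)
            mask[b, : len(chars)] = 1.0
        return ids, mask

    def forward_backward(
        self,
        batch_chars: list[list[str]],
        batch_tags: list[np.ndarray] | None,
        compute_grads: bool = True,
    ) -> tuple[BatchResult, list[np.ndarray], np.ndarray | None]:
        """One pass over a batch.

        Returns ``(BatchResult, emissions_per_sequence, fusion_weight_t)``.
        With ``batch_tags=None`` only the forward pass runs (prediction).
        """
        if not batch_chars:
            raise ValueError("empty batch")
        if any(len(c) == 0 for c in batch_chars):
            raise ValueError("empty sequence in batch")
        B = len(batch_chars)
        ids, mask = self._pad(batch_chars)
        lengths = [len(c) for c in batch_chars]

        b_enc = None
        if self.variant in ("fused", "transformer", "stacked"):
            b_enc, _ = self.encoder.encode_batch(batch_chars)

        caches: dict[str, object] = {}
        if self.variant != "transformer":
            lstm_in = b_enc if self.variant == "stacked" else self.emb[ids] * mask[..., None]
            h_f, cache_f = lstm_forward(self.lstm_f, lstm_in, mask)
            parts = [h_f]
            caches["f"] = cache_f
            if self.lstm_b is not None:
                h_b_rev, cache_b = lstm_forward(
                    self.lstm_b, lstm_in[:, ::-1], mask[:, ::-1]
                )
                parts.append(h_b_rev[:, ::-1])
                caches["b"] = cache_b
            h_cat = np.concatenate(parts, axis=-1)
            t_mat = (h_cat @ self.proj_w + self.proj_b) * mask[..., None]
        else:
            t_mat = None

        weight_t = None
        if self.variant == "fused":
            f_out, f_cache = fuse(
                self._fusion_params(), t_mat, b_enc, mask, return_cache=True
            )
            v = f_out.v
            weight_t = f_out.weight_t
        elif self.variant == "transformer":
            v = b_enc * mask[..., None]
        else:
            v = t_mat

        e_all = v @ self.crf.proj + self.crf.proj_bias  # (B, L, K)
        e_list = [e_all[b, : lengths[b]] for b in range(B)]

        if batch_tags is None:
            return BatchResult(0.0, None), e_list, weight_t

        loss = 0.0
        d_e_all = np.zeros_like(e_all)
        d_trans = np.zeros_like(self.crf.transitions)
        d_start = np.zeros_like(self.crf.start)
        d_stop = np.zeros_like(self.crf.stop)
        for b in range(B):
            g = crf_mod.nll_gradients(self.crf, e_list[b], batch_tags[b])
            loss += g.value
            if compute_grads:
                d_e_all[b, : lengths[b]] = g.d_emissions
                d_trans += g.d_transitions
                d_start += g.d_start
                d_stop += g.d_stop
        loss /= B
        if not np.isfinite(loss):
            raise DivergenceError("non-finite loss")
        if not compute_grads:
            return BatchResult(loss, None), e_list, weight_t

        d_e_all /= B
        grads: dict[str, np.ndarray] = {
            "crf_proj": np.einsum("blh,blk->hk", v, d_e_all),
            "crf_bias": d_e_all.sum(axis=(0, 1)),
            "crf_trans": d_trans / B,
            "crf_start": d_start / B,
            "crf_stop": d_stop / B,
        }
        d_v = d_e_all @ self.crf.proj.T

        if self.variant == "fused":
            d_t, _d_b, g_fusion = fuse_backward(self._fusion_params(), f_cache, d_v)
            grads["fusion"] = g_fusion
        elif self.variant == "transformer":
            return BatchResult(loss, grads), e_list, weight_t
        else:
            d_t = d_v * mask[..., None]

        grads["proj_w"] = np.einsum("bld,blh->dh", h_cat, d_t)
        grads["proj_b"] = d_t.sum(axis=(0, 1))
        d_hcat = d_t @ self.proj_w.T
        u = self.lstm_units
        g_f, d_x = lstm_backward(self.lstm_f, caches["f"], d_hcat[..., :u])
        grads["lstm_f_w"], grads["lstm_f_u"], grads["lstm_f_b"] = g_f.w, g_f.u, g_f.b
        if self.lstm_b is not None:
            g_b, d_x_rev = lstm_backward(
                self.lstm_b, caches["b"], d_hcat[:, ::-1, u:]
            )
            grads["lstm_b_w"], grads["lstm_b_u"], grads["lstm_b_b"] = (
                g_b.w,
                g_b.u,
                g_b.b,
            )
            d_x = d_x + d_x_rev[:, ::-1]
        if self.variant != "stacked":
            d_emb = np.zeros_like(self.emb)
            flat = mask.astype(bool)
            np.add.at(d_emb, ids[flat], d_x[flat])
            grads["emb"] = d_emb
        return BatchResult(loss, grads), e_list, weight_t

    # -- inference ---------------------------------------------------------

    def predict(
        self, sentences: list[list[str]], constrain_bio: bool = False
    ) -> tuple[list[list[str]], list[np.ndarray] | None]:
        """Viterbi-decode tag sequences; returns (tags, fusion weights)."""
        if not sentences:
            return [], None
        mask_mat = start_mat = None
        if constrain_bio:
            mask_mat = crf_mod.bio_constraint_mask(self.tagset)
            start_mat = crf_mod.bio_start_mask(self.tagset)
        _, e_list, weight_t = self.forward_backward(sentences, None)
        tags = []
        for e in e_list:
            path, _ = crf_mod.viterbi_decode(self.crf, e, mask_mat, start_mat)
            tags.append([self.tagset.tag_of(int(i)) for i in path])
        weights = None
        if weight_t is not None:
            weights = [weight_t[b, : len(s)].copy() for b, s in enumerate(sentences)]
        return tags, weights

    # -- checkpointing -----------------------------------------------------

    def save(self, directory: str | Path, extra_config: dict | None = None) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "variant": self.variant,
            "bidirectional": self.bidirectional,
            "lstm_units": self.lstm_units,
            "h_model": self.h_model,
            "config": extra_config or {},
        }
        (directory / "model.json").write_text(json.dumps(meta), encoding="utf-8")
        (directory / "tagset.json").write_text(self.tagset.to_json(), encoding="utf-8")
        EmbeddingTable(self.table.vocab, self.emb).save_word2vec(
            directory / "embeddings.w2v.txt"
        )
        if self.encoder is not None:
            self.encoder.save(directory / "encoder")
        np.savez(directory / "weights.npz", **self.parameters())

    @classmethod
    def load(cls, directory: str | Path) -> "Tagger":
        directory = Path(directory)
        try:
            meta = json.loads((directory / "model.json").read_text(encoding="utf-8"))
            tagset = TagSet.from_json(
                (directory / "tagset.json").read_text(encoding="utf-8")
            )
            table = EmbeddingTable.load_word2vec(directory / "embeddings.w2v.txt")
            encoder = (
                TinyTransformer.load(directory / "encoder")
                if (directory / "encoder").exists()
                else None
            )
            model = cls(
                tagset,
                table,
                encoder,
                lstm_units=meta["lstm_units"],
                h_model=meta["h_model"],
                variant=meta["variant"],
                bidirectional=meta["bidirectional"],
            )
            with np.load(directory / "weights.npz") as data:
                model.set_parameters({k: data[k] for k in data.files})
        except (OSError, KeyError, ValueError, json.JSONDecodeError) as exc:
            raise CheckpointError(f"cannot load checkpoint at {directory}: {exc}")
        return model


class CheckpointError(RuntimeError):
    """Checkpoint directory is missing pieces or corrupt."""


class AdamW:
    """Decoupled-weight-decay Adam; decay applies to matrices only."""

    def __init__(
        self,
        params: dict[str, np.ndarray],
        learning_rate: float,
        weight_decay: float = 0.01,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.lr = learning_rate
        self.wd = weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for k, p in params.items():
            g = grads[k]
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            update = (self.m[k] / b1c) / (np.sqrt(self.v[k] / b2c) + self.eps)
            if p.ndim >= 2 and self.wd:
                p -= self.lr * self.wd * p
            p -= self.lr * update


class SGD:
    def __init__(self, params: dict[str, np.ndarray], learning_rate: float, **_: object):
        self.lr = learning_rate

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        for k, p in params.items():
            p -= self.lr * grads[k]


class Adam(AdamW):
    def __init__(self, params: dict[str, np.ndarray], learning_rate: float, **kw: object):
        super().__init__(params, learning_rate, weight_decay=0.0)


OPTIMIZERS = {"adamw": AdamW, "adam": Adam, "sgd": SGD}
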