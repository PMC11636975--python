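# dualner

Character-level named-entity recognition for Chinese clinical text, built
around a **dual-pathway encoder with dynamic attention fusion and a
linear-chain CRF decoder** — implemented from first principles in numpy,
fully testable on a CPU in minutes.

## Who this is for

Practitioners and students working on clinical/TCM (traditional Chinese
medicine) text mining who want a transparent, dependency-light reference
implementation of the BERT‖BiLSTM-with-attention-fusion-CRF family of
taggers: every gradient (BPTT through the LSTM, the softmax gate, the CRF
forward–backward) is written out and verified against independent oracles,
rather than hidden inside an autodiff framework.

## The model

A sentence `X = (x_1 … x_n)` of characters is encoded twice:

* **T** — CBOW character vectors → bidirectional LSTM → linear projection;
* **B** — a transformer encoder (pluggable checkpoint; a small seeded
  deterministic encoder is built in), one vector per character.

The **dynamic attention gate** fuses them per position *i*:

```
T′ = mean(T_i)              B′ = mean(B_i)           (mean over hidden dim)
T″ = w_t′·T′ + b_t′         B″ = w_b′·B′ + b_b′
T‴ = tanh(T″)               B‴ = tanh(B″)
[W_T ; W_B] = softmax([T‴ ; B‴])
V_i = W_T·T_i + W_B·B_i
```

so `W_T + W_B = 1` at every position and the weights shift along the
sentence with the usefulness of each pathway. `V` feeds a linear-chain CRF:
path score `s(y) = start_{y_1} + Σ e_{i,y_i} + Σ A_{y_{i-1},y_i} +
stop_{y_n}`, exact partition by the log-space forward recursion, exact
Viterbi decoding, BIO tags, strict entity-level precision/recall/F1 plus
token accuracy.

The package also ships a synthetic-corpus generator whose defaults mirror
the imbalanced type distribution of the public TCM clinical-records
benchmark (10 entity types, 21 BIO tags), including an exact statistical
replica of its printed counts (6,574 sentences; 15,846 entities; 183,900 O
tokens) for pipeline-scale testing.

## Worked example

```python
import dualner as d

types = tuple(d.EntityTypeSpec(n, f, (2, 4)) for n, f in
              [("alpha", 4.0), ("beta", 2.0), ("gamma", 1.0), ("delta", 1.0)])
gen = lambda seed, n: d.generate_corpus(d.GeneratorConfig(
    seed=seed, n_sentences=n, sentence_length=(8, 20), entity_types=types,
    entity_density=0.3, background_alphabet_size=60, lexicon_size=12))

train_c, dev_c = gen(11, 500), gen(12, 100)
res = d.train(d.TrainConfig.tiny_test(seed=1), train_c, dev_c)
print(res.best_report.summary())

seq = dev_c.sequences[0]
out = d.predict(res.model, ["".join(seq.chars)])
print(out[0]["tags"])
print([round(w["lstm"], 3) for w in out[0]["fusion_weights"]][:8])
```

prints (≈15 s on one CPU core):

```
processed 1463 tokens; found: 123 entities; correct: 123.
accuracy: 100.00%; precision: 100.00%; recall: 100.00%; FB1: 100.00
['O', 'O', 'O', 'O', 'B-delta', 'I-delta', 'I-delta', 'I-delta', 'O',
 'B-alpha', 'I-alpha', 'I-alpha', 'O', 'O', 'O']
[0.501, 0.461, 0.479, 0.581, 0.757, 0.754, 0.746, 0.714]
```

All 123 dev entities are recovered exactly (the synthetic task is built to
be learnable: each entity type draws characters from its own lexicon). The
last line shows the per-position gate: inside entities the model leans on
the LSTM pathway (≈0.75) and sits near an even split on background tokens —
the fusion weights are interpretable per character.

The same workflow is available from the shell:

```bash
dualner generate corpus.txt --seed 3 --n-sentences 500
dualner stats corpus.txt
dualner train train.txt dev.txt --checkpoint ckpt/ --encoder-mode tiny \
        --learning-rate 0.01 --seed 7
dualner evaluate ckpt/ test.txt --text-summary
dualner predict ckpt/ -s "咳嗽发热"
dualner ablate train.txt dev.txt --variants lstm,fused --encoder-mode tiny
```

## Layout

```
src/dualner/
  corpus.py      # CoNLL-style BIO IO, tag universe, validation, statistics
  synthetic.py   # synthetic corpus generator + exact benchmark replica
  cbow.py        # CBOW character embeddings (full softmax / negative sampling)
  encoders.py    # BiLSTM pathway (with BPTT) + tiny transformer pathway
  fusion.py      # the dynamic attention gate (forward + backward)
  crf.py         # linear-chain CRF: partition, NLL, gradients, Viterbi
  metrics.py     # strict entity-level P/R/F1, token accuracy
  model.py       # assembly of the four architecture variants, AdamW
  train.py       # training loop, checkpointing, prediction, ablation
  cli.py         # dualner train/evaluate/predict/generate/stats/ablate
docs/methods.md  # modelling assumptions, parameters, limitations
```

See `docs/methods.md` for the modelling details and the design decisions.
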