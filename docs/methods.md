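# Methods

## Problem and model

The package targets character-level named-entity recognition in Chinese
clinical text (the motivating domain is traditional-Chinese-medicine
electronic records with ten entity types such as herbs, prescriptions,
syndromes and diagnoses). Sentences are sequences of characters, labels
follow the BIO scheme, and an entity is a maximal `B-X (I-X)*` run.

The architecture encodes each sentence along two parallel pathways and fuses
them before decoding:

1. **LSTM pathway.** Characters are embedded with CBOW vectors trained on
   the task corpus, passed through a bidirectional LSTM (standard forget /
   input / output gate equations), and the concatenated directions are
   linearly projected to the shared width `h_model`.
2. **Transformer pathway.** A transformer encoder produces one contextual
   vector per character ([CLS]/[SEP] markers are added internally and
   stripped). This pathway is *pluggable*: any checkpoint in the package's
   `config.json + weights.npz + vocab.txt` layout can be loaded; the built-in
   encoder is a small, seeded, deterministic pre-LayerNorm transformer.
3. **Dynamic attention fusion.** Per position, each pathway's vector is
   reduced to a scalar by a mean over the hidden dimension, passed through a
   scalar linear map and `tanh`, and the two resulting gate values are
   softmax-normalised into convex weights `(W_T, W_B)`. The fused
   representation is `V = W_T·T + W_B·B`.
4. **Linear-chain CRF.** An affine projection maps `V` to per-tag emission
   scores; a learned transition matrix plus start/stop vectors define path
   scores. Training minimises the exact negative log-likelihood (partition
   via the log-space forward recursion); decoding is exact Viterbi with
   deterministic lowest-index tie-breaking.

## Design choices where the design was open

- **Mean axis in the gate.** The scalar reduction is per *token* (mean over
  the hidden dimension), so the fusion weights vary along the sequence;
  a sequence-level pooling (`pooling="sequence"`) giving one global weight
  pair is available for ablation.
- **Shared width.** The fusion requires both pathways at the same width; a
  learned linear projection after the (bi)LSTM maps to the transformer's
  hidden size rather than constraining the LSTM units.
- **Separate gate parameters** for the two branches (not shared), matching
  their distinct roles.
- **Frozen transformer pathway.** The transformer acts as a fixed feature
  extractor; gradients flow through the fusion gate, the LSTM pathway, the
  embeddings and the CRF, but not into the transformer weights. With the
  small deterministic encoder used here, fine-tuning a random encoder would
  add cost without scientific content; with a genuinely pretrained
  checkpoint a fine-tuning mode would be the natural extension.
- **Factorised CRF potentials.** The potential is emission + transition, the
  standard linear-chain factorisation; transition-specific emission weights
  (a full bilinear form) are not implemented.
- **No hard BIO constraints during training.** Legal tag order is learned
  through the transition matrix; an optional additive constraint mask (and
  a start-position mask) is available at decode time for guaranteed-legal
  output.
- **CBOW at the character level with a full softmax.** The tagging unit is
  the character, so embeddings are character vectors. Full-batch gradient
  descent on the full-softmax cross-entropy keeps training deterministic
  and (at the default step size, on the small vocabularies used here)
  epoch-wise non-increasing; negative sampling is available for larger
  vocabularies. The out-of-vocabulary vector is the mean of all trained
  vectors; `<PAD>` is pinned to zero.

## Hyperparameters

`TrainConfig` defaults follow the benchmark configuration this package
targets: 30 epochs, learning rate 2e-5, batch size 64, maximum sequence
length 128, 128 LSTM units, AdamW; the CBOW defaults are 10 epochs, vector
size 200, window 5. The 2e-5 rate is a fine-tuning rate for a pretrained
transformer. Training the whole stack from random initialisation — the
`TrainConfig.tiny_test` preset used throughout the tests — instead uses
AdamW at 1e-2 with 32-wide embeddings/LSTM/encoder and batch size 32, the
conventional regime for small networks trained from scratch.

## Synthetic data

The generator emits sentences of CJK-range symbols with multi-character
entities embedded in background text, at least one O token between
entities, per-type relative frequencies mirroring the strongly imbalanced
distribution of the real benchmark (~10x between rarest and commonest
types), and roughly one token in five inside an entity. Each type draws its
characters from a private lexicon disjoint from the background alphabet and
from all other lexicons, so type identity is decidable from characters and
only the B/I boundary structure requires context — a task the architecture
can solve essentially perfectly, which is the point: failures indicate
implementation defects, not task difficulty.

`synthetic_tcm_replica` additionally reproduces the real corpus's *printed
counting structure exactly* (6,574 sentences split 5,259/657/658; 15,846
entities with the published per-type counts; 183,900 O tokens) so that
parsing and statistics pipelines can be exercised at full scale. It is
synthetic text: no conclusion about real clinical language follows from it.

What passing tests on these corpora do **not** show: robustness to
ambiguous or shared vocabulary across entity types, real lexical
statistics, long-range dependencies, annotation noise, or the benefit of
genuine pretraining in the transformer pathway.

## Problem sizes and numerical choices

- End-to-end runs use 500 training / 100 dev sentences, 4 entity types,
  30 epochs; the fused-vs-LSTM-only comparison repeats both fits under 5
  seeds at the same size. At this scale the task saturates (~100% dev F1).
  Noteworthy and reproducible: at much shorter budgets (e.g. 8 epochs on
  150 sentences) the LSTM-only variant converges *faster* than the fused
  model, because the gate first has to learn to discount the untrained
  transformer features — with a pretrained encoder the relation reverses.
- All arithmetic is float64. CRF recursions run in log space; Viterbi ties
  break toward the lower tag index; gradient checks use central differences
  at 1e-6 with a 1e-4 acceptance threshold.
- Exhaustive-enumeration oracles for the CRF cover K ≤ 5, L ≤ 7 (at most
  78,125 paths), where brute force is unambiguous and fast.
- Empty sequences are rejected by the encoders and the CRF; empty *inputs*
  to embedding lookup return 0×d matrices. Sequences longer than `max_len`
  are truncated for training only, never for corpus statistics.
- Batches pad to the longest member; masks propagate through both encoders
  (the LSTM multiplies states by the step mask, which preserves zero state
  through leading pads of the reversed pass), the fusion gate and the CRF
  (per-sequence true lengths).

## Known limitations

- The built-in transformer is not pretrained; headline benchmark scores
  from the literature (entity F1 in the low 80s on the real TCM corpus)
  require a pretrained Chinese BERT-style checkpoint and are out of scope.
- The CRF uses the factorised potential (see above).
- Skip-gram embeddings are not implemented (CBOW only).
- `accuracy` is token-level; entity true negatives are not defined, and the
  `tn` field counts both-O tokens.
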