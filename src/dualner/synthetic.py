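"""Synthetic BIO corpora with the statistical shape of Chinese clinical text.

Sentences are short sequences of CJK-range symbols. Multi-character entities
of configurable types are embedded into background text, with at least one
O token between consecutive entities so gold spans are unambiguous. Each
entity type draws its characters from a private lexicon disjoint from the
background alphabet and from every other type's lexicon, which makes the
tagging task learnable from characters alone: the symbols are synthetic, no
real clinical terminology is involved.

Default frequencies mirror the strongly imbalanced type distribution of the
public TCM clinical-records benchmark (roughly 10x between the rarest and the
commonest types); :func:`synthetic_tcm_replica` goes further and reproduces
that corpus's printed counts exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus import Corpus, LabeledSequence, TagSet, TCM_ENTITY_TYPES

#: Whole-dataset entity counts of the TCM benchmark, per type.
TCM_ENTITY_COUNTS: dict[str, int] = {
    "TCM diagnosis": 336,
    "Western medicine diagnosis": 3082,
    "TCM treatment": 1325,
    "Chinese herbs": 3540,
    "TCM syndrome": 1464,
    "Prescription": 1243,
    "TCM treatment principles": 397,
    "Clinical manifestations": 3812,
    "Western medicine treatment": 562,
    "Other treatments": 85,
}

#: Sentence counts of the benchmark's train/validation/test splits.
TCM_SPLIT_SIZES: dict[str, int] = {"train": 5259, "dev": 657, "test": 658}

#: Number of O-tagged (non-entity) tokens in the whole benchmark.
TCM_O_TOKENS: int = 183_900

_CJK_BASE = 0x4E00  # start of the unified CJK block used for synthetic symbols


class ConfigError(ValueError):
    """The generator configuration is inconsistent or infeasible."""


@dataclass(frozen=True)
class EntityTypeSpec:
    name: str
    frequency: float = 1.0
    length_range: tuple[int, int] = (2, 6)

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if not (1 <= lo <= hi):
            raise ConfigError(f"{self.name}: bad length range {self.length_range}")
        if self.frequency < 0:
            raise ConfigError(f"{self.name}: negative frequency")


def _tcm_like_types() -> tuple[EntityTypeSpec, ...]:
    return tuple(
        EntityTypeSpec(name, frequency=float(TCM_ENTITY_COUNTS[name]))
        for name in TCM_ENTITY_TYPES
    )


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic corpus generator.

    ``entity_density`` is the expected fraction of tokens inside entities;
    the benchmark corpus is roughly four-fifths O tokens, hence the default.
    """

    seed: int = 0
    n_sentences: int = 1000
    sentence_length: tuple[int, int] = (10, 60)
    entity_types: tuple[EntityTypeSpec, ...] = field(default_factory=_tcm_like_types)
    entity_density: float = 0.2
    background_alphabet_size: int = 500
    lexicon_size: int = 30

    def __post_init__(self) -> None:
        lo, hi = self.sentence_length
        if not (1 <= lo <= hi):
            raise ConfigError(f"bad sentence length range {self.sentence_length}")
        if not (0.0 <= self.entity_density < 1.0):
            raise ConfigError("entity_density must lie in [0, 1)")
        if not self.entity_types:
            raise ConfigError("at least one entity type required")
        if sum(t.frequency for t in self.entity_types) <= 0:
            raise ConfigError("entity type frequencies must sum to > 0")
        if self.entity_density > 0:
            shortest = min(t.length_range[0] for t in self.entity_types)
            if shortest > hi:
                raise ConfigError(
                    f"shortest entity ({shortest}) exceeds max sentence length ({hi})"
                )
        if self.background_alphabet_size < 1 or self.lexicon_size < 1:
            raise ConfigError("alphabet sizes must be positive")

    def tagset(self) -> TagSet:
        return TagSet(tuple(t.name for t in self.entity_types))


def _alphabets(config: GeneratorConfig) -> tuple[list[str], dict[str, list[str]]]:
    """Background alphabet plus disjoint per-type lexicons (CJK code points)."""
    cp = _CJK_BASE
    background = [chr(cp + i) for i in range(config.background_alphabet_size)]
    cp += config.background_alphabet_size
    lexicons: dict[str, list[str]] = {}
    for spec in config.entity_types:
        lexicons[spec.name] = [chr(cp + i) for i in range(config.lexicon_size)]
        cp += config.lexicon_size
    return background, lexicons


def _entity_tokens(
    rng: np.random.Generator, spec: EntityTypeSpec, lexicon: list[str], max_len: int
) -> tuple[list[str], list[str]]:
    lo, hi = spec.length_range
    hi = min(hi, max_len)
    length = int(rng.integers(lo, hi + 1))
    chars = [lexicon[i] for i in rng.integers(0, len(lexicon), size=length)]
    tags = [f"B-{spec.name}"] + [f"I-{spec.name}"] * (length - 1)
    return chars, tags


def generate_corpus(config: GeneratorConfig, split_name: str = "train") -> Corpus:
    """Generate a BIO-well-formed corpus; deterministic for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    background, lexicons = _alphabets(config)
    specs = config.entity_types
    freqs = np.array([t.frequency for t in specs], dtype=float)
    freqs /= freqs.sum()
    mean_len = float(np.mean([sum(t.length_range) / 2 for t in specs]))
    d = config.entity_density
    # probability that a generation step opens an entity rather than emitting
    # one background character, chosen so the expected in-entity token
    # fraction equals entity_density
    p_entity = d / (mean_len * (1 - d) + d) if d > 0 else 0.0

    sequences = []
    lo, hi = config.sentence_length
    for _ in range(config.n_sentences):
        target = int(rng.integers(lo, hi + 1))
        chars: list[str] = []
        tags: list[str] = []
        just_closed = False  # force >= 1 O between consecutive entities
        while len(chars) < target:
            room = target - len(chars)
            can_entity = (
                p_entity > 0
                and not just_closed
                and room >= min(t.length_range[0] for t in specs)
            )
            if can_entity and rng.random() < p_entity:
                feasible = [i for i, t in enumerate(specs) if t.length_range[0] <= room]
                w = freqs[feasible] / freqs[feasible].sum()
                k = feasible[int(rng.choice(len(feasible), p=w))]
                ec, et = _entity_tokens(rng, specs[k], lexicons[specs[k].name], room)
                chars.extend(ec)
                tags.extend(et)
                just_closed = True
            else:
                chars.append(background[int(rng.integers(0, len(background)))])
                tags.append("O")
                just_closed = False
        sequences.append(LabeledSequence(chars, tags))
    return Corpus(sequences, split_name=split_name)


def _spread(total: int, n_bins: int) -> list[int]:
    """Split ``total`` into ``n_bins`` integers differing by at most one."""
    base, rem = divmod(total, n_bins)
    return [base + (1 if i < rem else 0) for i in range(n_bins)]


def synthetic_tcm_replica(seed: int = 0) -> dict[str, Corpus]:
    """SYNTHETIC replica of the TCM benchmark's printed shape, exactly.

    Produces train/dev/test corpora with 5,259 + 657 + 658 = 6,574 sentences,
    the published per-type entity counts (15,846 entities in total) and
    exactly 183,900 O-tagged tokens. Entity and background characters are
    synthetic CJK-range symbols; only the counting structure — not the text —
    mirrors the real corpus, so it serves to exercise parsing and statistics
    pipelines at full scale, not to train clinically meaningful models.
    """
    rng = np.random.default_rng(seed)
    config = GeneratorConfig(seed=seed)
    _, lexicons = _alphabets(config)
    background, _ = _alphabets(config)

    # one entry per entity, shuffled so types mix across sentences/splits
    entity_types = np.repeat(
        np.arange(len(TCM_ENTITY_TYPES)),
        [TCM_ENTITY_COUNTS[t] for t in TCM_ENTITY_TYPES],
    )
    rng.shuffle(entity_types)

    n_sentences = sum(TCM_SPLIT_SIZES.values())
    per_sentence = _spread(len(entity_types), n_sentences)
    # every sentence carries n_entities + 1 O gaps (>=1 token each) so spans
    # never touch; the remaining O budget is spread evenly
    base_o = sum(n + 1 for n in per_sentence)
    if base_o > TCM_O_TOKENS:
        raise ConfigError("O-token budget too small for separator gaps")
    extra_o = _spread(TCM_O_TOKENS - base_o, n_sentences)

    sequences: list[LabeledSequence] = []
    cursor = 0
    for i in range(n_sentences):
        n_ent = per_sentence[i]
        ents = entity_types[cursor : cursor + n_ent]
        cursor += n_ent
        gaps = _spread(extra_o[i] + n_ent + 1, n_ent + 1)
        chars: list[str] = []
        tags: list[str] = []
        for j in range(n_ent + 1):
            for _ in range(gaps[j]):
                chars.append(background[int(rng.integers(0, len(background)))])
                tags.append("O")
            if j < n_ent:
                name = TCM_ENTITY_TYPES[int(ents[j])]
                lex = lexicons[name]
                length = int(rng.integers(2, 5))
                chars.extend(lex[k] for k in rng.integers(0, len(lex), size=length))
                tags.append(f"B-{name}")
                tags.extend([f"I-{name}"] * (length - 1))
        sequences.append(LabeledSequence(chars, tags))

    out: dict[str, Corpus] = {}
    start = 0
    for split, size in TCM_SPLIT_SIZES.items():
        out[split] = Corpus(sequences[start : start + size], split_name=split)
        start += size
    return out
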