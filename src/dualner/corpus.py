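"""BIO-annotated corpus reading, writing, validation and statistics.

The on-disk dialect is CoNLL-style two-column text: one character and its tag
per line separated by whitespace, sentences delimited by blank lines. Because
entity type names may themselves contain spaces ("Western medicine diagnosis"),
only the FIRST whitespace run on a line is a separator: field 1 is the
character, the remainder of the line is the tag.

A converter for the PaddlePaddle dialect (text and label sequence on a single
line, fields separated by a control character) is also provided.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

#: The ten entity types of the traditional-Chinese-medicine clinical-record
#: benchmark, in their canonical order. "O" (non-entity) is a tag, not a type.
TCM_ENTITY_TYPES: tuple[str, ...] = (
    "TCM diagnosis",
    "Western medicine diagnosis",
    "TCM treatment",
    "Chinese herbs",
    "TCM syndrome",
    "Prescription",
    "TCM treatment principles",
    "Clinical manifestations",
    "Western medicine treatment",
    "Other treatments",
)

OUTSIDE = "O"


class CorpusError(Exception):
    """Base class for corpus-format problems."""


class ParseError(CorpusError):
    """A line could not be interpreted as `char tag`."""


class TagError(CorpusError):
    """A tag outside the declared tag universe was encountered."""


class EmptyCorpusError(CorpusError):
    """The file contained no sentences."""


@dataclass(frozen=True)
class TagSet:
    """The label universe for a BIO tagging task.

    ``tags`` always starts with ``O`` (index 0) followed by a ``B-``/``I-``
    pair per entity type, in entity-type order, so ``len(tags) ==
    2 * len(entity_types) + 1``.
    """

    entity_types: tuple[str, ...]
    tags: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        if len(set(self.entity_types)) != len(self.entity_types):
            raise ValueError("duplicate entity types")
        tags = [OUTSIDE]
        for t in self.entity_types:
            tags.append(f"B-{t}")
            tags.append(f"I-{t}")
        object.__setattr__(self, "tags", tuple(tags))

    @classmethod
    def default_tcm(cls) -> "TagSet":
        return cls(TCM_ENTITY_TYPES)

    @classmethod
    def from_tags(cls, observed: Iterable[str]) -> "TagSet":
        """Infer a TagSet from observed tags, preserving first-seen type order."""
        types: list[str] = []
        for tag in observed:
            if tag == OUTSIDE:
                continue
            if not (tag.startswith("B-") or tag.startswith("I-")):
                raise TagError(f"tag {tag!r} is not O, B-<type> or I-<type>")
            t = tag[2:]
            if t not in types:
                types.append(t)
        return cls(tuple(types))

    def __len__(self) -> int:
        return len(self.tags)

    def __contains__(self, tag: str) -> bool:
        return tag in self._index

    @property
    def _index(self) -> dict[str, int]:
        # tiny, rebuilt lazily; frozen dataclass keeps it out of __init__
        if not hasattr(self, "_index_cache"):
            object.__setattr__(
                self, "_index_cache", {t: i for i, t in enumerate(self.tags)}
            )
        return self._index_cache  # type: ignore[attr-defined]

    def index_of(self, tag: str) -> int:
        try:
            return self._index[tag]
        except KeyError:
            raise TagError(f"unknown tag {tag!r}") from None

    def tag_of(self, index: int) -> str:
        return self.tags[index]

    def to_json(self) -> str:
        return json.dumps({"entity_types": list(self.entity_types)})

    @classmethod
    def from_json(cls, text: str) -> "TagSet":
        return cls(tuple(json.loads(text)["entity_types"]))


@dataclass
class LabeledSequence:
    """A character sequence with aligned BIO tags."""

    chars: list[str]
    tags: list[str]
    source_line: int = 0

    def __post_init__(self) -> None:
        if len(self.chars) != len(self.tags):
            raise ValueError(
                f"chars/tags length mismatch at line {self.source_line}: "
                f"{len(self.chars)} vs {len(self.tags)}"
            )

    def __len__(self) -> int:
        return len(self.chars)

    @property
    def text(self) -> str:
        return "".join(self.chars)


@dataclass
class Corpus:
    sequences: list[LabeledSequence]
    split_name: str = "train"

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self) -> Iterator[LabeledSequence]:
        return iter(self.sequences)

    def characters(self) -> set[str]:
        return {c for seq in self.sequences for c in seq.chars}


def parse_bio_corpus(
    path: str | Path,
    tagset: TagSet | None = None,
    split_name: str = "train",
) -> Corpus:
    """Parse a two-column CoNLL-style BIO file into a :class:`Corpus`.

    If ``tagset`` is given, every tag is checked against it; otherwise the tag
    universe is inferred by the caller from the parsed corpus as needed.
    """
    path = Path(path)
    sequences: list[LabeledSequence] = []
    chars: list[str] = []
    tags: list[str] = []
    start_line = 1
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                if chars:
                    sequences.append(LabeledSequence(chars, tags, start_line))
                    chars, tags = [], []
                start_line = lineno + 1
                continue
            parts = line.split(None, 1)
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected `char tag`, got {line!r}")
            ch, tag = parts[0], parts[1].strip()
            if tagset is not None and tag not in tagset:
                raise TagError(f"{path}:{lineno}: unknown tag {tag!r}")
            chars.append(ch)
            tags.append(tag)
    if chars:
        sequences.append(LabeledSequence(chars, tags, start_line))
    if not sequences:
        raise EmptyCorpusError(f"{path}: no sentences found")
    return Corpus(sequences, split_name=split_name)


def write_bio_corpus(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus in the two-column dialect `parse_bio_corpus` reads."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for seq in corpus.sequences:
            for ch, tag in zip(seq.chars, seq.tags):
                fh.write(f"{ch} {tag}\n")
            fh.write("\n")


def parse_paddle_corpus(
    path: str | Path,
    separator: str = "\x02",
    field_separator: str = "\t",
    split_name: str = "train",
) -> Corpus:
    """Parse the one-sentence-per-line dialect: `c1<sep>c2...<tab>t1<sep>t2...`."""
    path = Path(path)
    sequences: list[LabeledSequence] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            try:
                text_part, label_part = line.split(field_separator, 1)
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: expected text{field_separator!r}labels"
                ) from None
            chars = text_part.split(separator)
            tags = label_part.split(separator)
            if len(chars) != len(tags):
                raise ParseError(
                    f"{path}:{lineno}: {len(chars)} chars but {len(tags)} tags"
                )
            sequences.append(LabeledSequence(chars, tags, lineno))
    if not sequences:
        raise EmptyCorpusError(f"{path}: no sentences found")
    return Corpus(sequences, split_name=split_name)


def validate_bio(seq: LabeledSequence) -> list[tuple[int, str]]:
    """Report strict-BIO violations: each I-X must follow B-X or I-X.

    Returns ``(index, message)`` pairs; an empty list means well-formed.
    Reports, never raises.
    """
    violations: list[tuple[int, str]] = []
    prev = OUTSIDE
    for i, tag in enumerate(seq.tags):
        if tag.startswith("I-"):
            t = tag[2:]
            if not (prev == f"B-{t}" or prev == f"I-{t}"):
                violations.append(
                    (i, f"I-{t} at position {i} not preceded by B-{t}/I-{t}")
                )
        prev = tag
    return violations


def truncate_corpus(corpus: Corpus, max_len: int) -> Corpus:
    """Clip every sequence to ``max_len`` characters (training-time only;
    evaluation statistics always use the untruncated corpus)."""
    if max_len <= 0:
        raise ValueError("max_len must be positive")
    out = [
        LabeledSequence(s.chars[:max_len], s.tags[:max_len], s.source_line)
        for s in corpus.sequences
    ]
    return Corpus(out, split_name=corpus.split_name)


def corpus_stats(corpus: Corpus, tagset: TagSet) -> dict:
    """Per-type entity counts plus token-level tallies.

    Entity counts follow the same conlleval-style repair used by the
    evaluation metrics: an I-X not preceded by B-X/I-X opens a new X entity,
    so each counted entity corresponds to exactly one span.
    """
    from .metrics import extract_entities  # local import avoids a cycle

    per_type = {t: 0 for t in tagset.entity_types}
    o_tokens = 0
    total_tokens = 0
    entity_tokens = 0
    for seq in corpus.sequences:
        total_tokens += len(seq)
        o_tokens += sum(1 for t in seq.tags if t == OUTSIDE)
        for span in extract_entities(seq.tags):
            if span.type not in per_type:
                raise TagError(f"entity type {span.type!r} not in tag set")
            per_type[span.type] += 1
            entity_tokens += span.end - span.start
    return {
        "split": corpus.split_name,
        "n_sentences": len(corpus),
        "n_tokens": total_tokens,
        "n_o_tokens": o_tokens,
        "n_entity_tokens": entity_tokens,
        "n_entities": sum(per_type.values()),
        "entities_per_type": per_type,
        "n_entity_types": len(tagset.entity_types),
        "n_label_categories": len(tagset.entity_types) + 1,  # counting O
        "n_tags": len(tagset),
    }


def stats_json(stats: dict) -> str:
    return json.dumps(stats, ensure_ascii=False, indent=2)


def merge_corpora(corpora: Sequence[Corpus], split_name: str = "all") -> Corpus:
    seqs = [s for c in corpora for s in c.sequences]
    return Corpus(seqs, split_name=split_name)
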