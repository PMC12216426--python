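"""Parsing of ';'-separated standardized medical code strings and
Bag-of-Terms (BoT) encoding.

EHR diagnosis/operation fields in this setting are not free text: each
value is an ordered list of standardized medical codes joined by ';',
with the first code designated primary.  BoT generalizes one-hot
encoding: each distinct code gets a binary indicator column, and a
record's vector has 1s for every code present.  Entries are binary
because a code cannot appear more than once in a field.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

SEPARATOR = ";"
JOINER = "; "


@dataclass(frozen=True)
class CodeSequence:
    """An ordered, duplicate-free list of normalized codes.

    The first code, when present, is the primary code.
    """

    codes: tuple[str, ...]

    def __post_init__(self) -> None:
        if any(not c for c in self.codes):
            raise ValueError("CodeSequence may not contain empty codes")
        if len(set(self.codes)) != len(self.codes):
            raise ValueError("CodeSequence may not contain duplicates")

    @property
    def primary(self) -> str | None:
        return self.codes[0] if self.codes else None

    def join(self) -> str:
        return JOINER.join(self.codes)

    def __len__(self) -> int:
        return len(self.codes)

    def __iter__(self):
        return iter(self.codes)


@dataclass(frozen=True)
class CodeVocabulary:
    """Lexicographically ordered set of distinct codes with column index."""

    codes: tuple[str, ...]
    index: dict[str, int] = field(compare=False, default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.codes) != sorted(set(self.codes)):
            raise ValueError("vocabulary codes must be sorted and distinct")
        object.__setattr__(self, "index", {c: i for i, c in enumerate(self.codes)})

    def __len__(self) -> int:
        return len(self.codes)

    def __contains__(self, code: str) -> bool:
        return code in self.index


def normalize_code(code: str) -> str:
    return code.strip().lower()


def parse_field(text: str) -> CodeSequence:
    """Parse a raw ';'-separated field into a normalized code sequence.

    Splits on ';', trims whitespace, lowercases, drops empty entries and
    deduplicates keeping the first occurrence (so the primary code keeps
    its position).  Any string is accepted; an all-empty input yields an
    empty sequence.
    """
    seen: dict[str, None] = {}
    for raw in str(text).split(SEPARATOR) if text else []:
        code = normalize_code(raw)
        if code and code not in seen:
            seen[code] = None
    return CodeSequence(tuple(seen))


def build_vocabulary(corpus: Iterable[CodeSequence]) -> CodeVocabulary:
    """Union of all codes in the corpus, sorted lexicographically."""
    corpus = list(corpus)
    if not corpus:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    codes: set[str] = set()
    for seq in corpus:
        codes.update(seq.codes)
    return CodeVocabulary(tuple(sorted(codes)))


def encode_bot(seq: CodeSequence, vocab: CodeVocabulary) -> np.ndarray:
    """Binary indicator vector over the vocabulary.

    Out-of-vocabulary codes are ignored with a logged warning so that a
    vocabulary built on training rows only can still encode held-out rows.
    """
    if len(vocab) == 0:
        raise ValueError("vocabulary is empty")
    vec = np.zeros(len(vocab), dtype=np.float64)
    for code in seq:
        pos = vocab.index.get(code)
        if pos is None:
            logger.warning("code %r not in vocabulary; ignored", code)
        else:
            vec[pos] = 1.0
    return vec


def encode_bot_matrix(
    corpus: Sequence[CodeSequence], vocab: CodeVocabulary
) -> np.ndarray:
    """Stack BoT vectors for a corpus into an n x |vocab| binary matrix."""
    return np.vstack([encode_bot(seq, vocab) for seq in corpus])
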