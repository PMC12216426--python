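"""Embedder contract with offline implementations.

Every embedder maps a list of raw code-string fields to an
:class:`EmbeddingMatrix`.  Dense embedders return unit-L2-norm rows
(cosine geometry); the Bag-of-Terms encoder deliberately does not,
since the L1 norm of a BoT vector (the number of codes) is informative.

Offline kinds:

``bot``
    Bag-of-Terms indicators over the corpus vocabulary.
``hash``
    Each code hashes to a fixed random unit vector; a field embeds as
    the normalized sum over its codes.  Deterministic per (dimension,
    seed), order-free by construction — a documented difference from
    contextual LLM embedders.
``doc2vec``
    Adapter over gensim's Doc2Vec, exposing the dbow/dm variant,
    epochs and dimension hyperparameters; available only when gensim
    is importable.
``external-adapter``
    Hook for user-registered embedding backends (e.g. a sentence
    transformer or a commercial API client); raises
    :class:`CapabilityMissingError` unless one is registered.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .ehr_text import build_vocabulary, encode_bot_matrix, parse_field

logger = logging.getLogger(__name__)


class CapabilityMissingError(RuntimeError):
    """An embedder kind requires an adapter that is not installed."""


#: Default hash-embedding width; mirrors the output dimension of the
#: commercial embedders the hash stub stands in for, and keeps
#: hash-collision noise small relative to code-overlap signal.
DEFAULT_HASH_DIM = 1536


@dataclass
class EmbeddingMatrix:
    """n x d embedding with row identifiers and an honesty flag.

    ``normalized`` must be truthful: spherical clustering refuses input
    whose flag is false, and the flag is property-tested against the
    actual row norms for every registered embedder.
    """

    values: np.ndarray
    row_ids: list
    normalized: bool

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("embedding values must be a 2-D matrix")
        if len(self.row_ids) != self.values.shape[0]:
            raise ValueError("row_ids length must match number of rows")
        if self.normalized:
            norms = np.linalg.norm(self.values, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-9):
                raise ValueError("normalized=True but rows are not unit norm")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def dimension(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class EmbedderSpec:
    """Configuration naming an embedder implementation.

    ``hyperparameters`` is kind-specific, e.g. for doc2vec:
    ``{"variant": "dbow", "epochs": 100, "dimension": 400}``.
    """

    name: str
    kind: str
    dimension: int = 0
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown embedder kind {self.kind!r}")

    def to_config(self) -> dict:
        return {
            "name": self.name,
            "kind": self.kind,
            "dimension": self.dimension,
            "hyperparameters": dict(self.hyperparameters),
        }

    @classmethod
    def from_config(cls, cfg: dict) -> "EmbedderSpec":
        return cls(
            name=cfg["name"],
            kind=cfg["kind"],
            dimension=cfg.get("dimension", 0),
            hyperparameters=dict(cfg.get("hyperparameters", {})),
        )


_ADAPTERS: dict[str, Callable[[Sequence[str], EmbedderSpec], EmbeddingMatrix]] = {}


def register_adapter(
    name: str, fn: Callable[[Sequence[str], EmbedderSpec], EmbeddingMatrix]
) -> None:
    """Register an external embedding backend under ``name``."""
    _ADAPTERS[name] = fn


def l2_normalize(matrix: EmbeddingMatrix) -> EmbeddingMatrix:
    """Scale every row to unit L2 norm.

    Raises on all-zero rows, naming the offending row id, since a zero
    vector has no direction.
    """
    norms = np.linalg.norm(matrix.values, axis=1)
    zero = np.flatnonzero(norms == 0.0)
    if zero.size:
        raise ValueError(
            f"cannot L2-normalize zero rows: ids {[matrix.row_ids[i] for i in zero]}"
        )
    return EmbeddingMatrix(
        values=matrix.values / norms[:, None],
        row_ids=list(matrix.row_ids),
        normalized=True,
    )


def _code_unit_vector(code: str, dimension: int, seed: int) -> np.ndarray:
    digest = hashlib.blake2b(
        code.encode("utf-8"), digest_size=8, key=str(seed).encode()
    ).digest()
    rng = np.random.default_rng(int.from_bytes(digest, "big"))
    v = rng.standard_normal(dimension)
    return v / np.linalg.norm(v)


def hash_embed(
    texts: Sequence[str], dimension: int, seed: int, row_ids: Sequence | None = None
) -> EmbeddingMatrix:
    """Deterministic bag-of-codes hash embedding.

    Each parsed code maps (via a seeded hash) to a fixed random unit
    vector; a field embeds as the L2-normalized sum of its codes'
    vectors.  Fields that parse to nothing embed as a fixed "null" unit
    vector and are flagged with a warning.
    """
    if dimension < 2:
        raise ValueError("hash embedding dimension must be >= 2")
    null_vec = _code_unit_vector("\x00null", dimension, seed)
    rows = np.empty((len(texts), dimension), dtype=np.float64)
    for i, text in enumerate(texts):
        seq = parse_field(text)
        if not len(seq):
            logger.warning("row %d has no codes; using null vector", i)
            rows[i] = null_vec
            continue
        acc = np.zeros(dimension)
        for code in seq:
            acc += _code_unit_vector(code, dimension, seed)
        norm = np.linalg.norm(acc)
        rows[i] = acc / norm if norm > 0 else null_vec
    ids = list(row_ids) if row_ids is not None else list(range(len(texts)))
    return EmbeddingMatrix(values=rows, row_ids=ids, normalized=True)


def _embed_bot(texts: Sequence[str], spec: EmbedderSpec) -> EmbeddingMatrix:
    corpus = [parse_field(t) for t in texts]
    vocab = build_vocabulary(corpus)
    return EmbeddingMatrix(
        values=encode_bot_matrix(corpus, vocab),
        row_ids=list(range(len(texts))),
        normalized=False,
    )


def _embed_hash(texts: Sequence[str], spec: EmbedderSpec) -> EmbeddingMatrix:
    hp = spec.hyperparameters
    return hash_embed(texts, spec.dimension, int(hp.get("seed", 0)))


def _embed_doc2vec(texts: Sequence[str], spec: EmbedderSpec) -> EmbeddingMatrix:
    try:
        from gensim.models.doc2vec import Doc2Vec, TaggedDocument
    except ImportError as exc:  # pragma: no cover - depends on install
        raise CapabilityMissingError(
            "doc2vec embedder requires the optional gensim dependency"
        ) from exc
    hp = spec.hyperparameters
    variant = hp.get("variant", "dbow")
    if variant not in ("dbow", "dm"):
        raise ValueError(f"unknown doc2vec variant {variant!r}")
    docs = [
        TaggedDocument(words=list(parse_field(t)), tags=[i])
        for i, t in enumerate(texts)
    ]
    model = Doc2Vec(  # pragma: no cover
        docs,
        vector_size=int(hp.get("dimension", spec.dimension or 40)),
        epochs=int(hp.get("epochs", 100)),
        dm=0 if variant == "dbow" else 1,
        min_count=1,
        seed=int(hp.get("seed", 0)),
        workers=1,
    )
    values = np.vstack([model.dv[i] for i in range(len(texts))])  # pragma: no cover
    return l2_normalize(  # pragma: no cover
        EmbeddingMatrix(values=values, row_ids=list(range(len(texts))), normalized=False)
    )


def _embed_external(texts: Sequence[str], spec: EmbedderSpec) -> EmbeddingMatrix:
    adapter = _ADAPTERS.get(spec.name)
    if adapter is None:
        raise CapabilityMissingError(
            f"no external adapter registered under {spec.name!r}"
        )
    return adapter(texts, spec)


_KINDS: dict[str, Callable[[Sequence[str], EmbedderSpec], EmbeddingMatrix]] = {
    "bot": _embed_bot,
    "hash": _embed_hash,
    "doc2vec": _embed_doc2vec,
    "external-adapter": _embed_external,
}


def embed(texts: Sequence[str], spec: EmbedderSpec) -> EmbeddingMatrix:
    """Embed a list of raw field strings per the spec's kind."""
    if not len(texts):
        raise ValueError("texts must be non-empty")
    return _KINDS[spec.kind](list(texts), spec)


def concatenate_embeddings(
    a: EmbeddingMatrix, b: EmbeddingMatrix, renormalize: bool = True
) -> EmbeddingMatrix:
    """Concatenate two embeddings row-wise (e.g. diagnosis + operation).

    The concatenation of two unit vectors has norm sqrt(2), so by
    default the result is re-normalized to restore cosine geometry.
    """
    if a.row_ids != b.row_ids:
        raise ValueError("row ids differ between the two embeddings")
    out = EmbeddingMatrix(
        values=np.hstack([a.values, b.values]),
        row_ids=list(a.row_ids),
        normalized=False,
    )
    return l2_normalize(out) if renormalize else out


@dataclass(frozen=True)
class FinetunePair:
    """A matched diagnosis/operation text pair for contrastive tuning."""

    diagnosis_text: str
    operation_text: str
    patient_id: object

    def __post_init__(self) -> None:
        if not self.diagnosis_text or not self.operation_text:
            raise ValueError("finetune pair fields must be non-empty")


def build_finetune_pairs(cohort: pd.DataFrame) -> list[FinetunePair]:
    """One (diagnosis, operation) pair per row with both fields present.

    The pairing task assumes the diagnosis drives the operations
    performed, so matched pairs should embed closer together than
    mix-and-matched ones.  Rows with an empty field are skipped with a
    warning.
    """
    pairs: list[FinetunePair] = []
    for _, row in cohort.iterrows():
        dx = str(row.get("diagnosis", "") or "").strip()
        op = str(row.get("operation", "") or "").strip()
        if not dx or not op:
            logger.warning("row %r missing a text field; skipped", row.get("patient_id"))
            continue
        pairs.append(
            FinetunePair(diagnosis_text=dx, operation_text=op, patient_id=row.get("patient_id"))
        )
    logger.info("built %d finetune pairs", len(pairs))
    return pairs
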