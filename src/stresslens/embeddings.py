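"""Per-token document vectors through a pluggable encoder contract.

Downstream stages (topic fusion, sentiment, tagging) only require that the
encoder be deterministic given its state and produce position-dependent
("dynamic") token vectors. The default :class:`HashingTextEncoder` satisfies
the contract offline: each token vector is the sum of a seeded-hash token
embedding, a sinusoidal position embedding, and a constant per-sentence
segment embedding, so the same token at two positions maps to two different
vectors. Any pretrained transformer encoder exposing the same interface can
be substituted.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .corpus import TokenizedDoc

logger = logging.getLogger(__name__)

DEFAULT_DIM = 64
DEFAULT_MAX_SEQ_LEN = 256


@dataclass(frozen=True)
class EmbeddingSequence:
    """Ordered per-token vectors of one document."""

    post_id: str
    vectors: np.ndarray  # (n_tokens, d)

    def __post_init__(self) -> None:
        if self.vectors.ndim != 2 or self.vectors.shape[0] == 0:
            raise ValueError("vectors must be a non-empty (n, d) array")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("non-finite embedding entries")

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def __len__(self) -> int:
        return self.vectors.shape[0]


@dataclass(frozen=True)
class DocEmbedding:
    post_id: str
    vector: np.ndarray


def _token_vector(token: str, seed: int, dim: int) -> np.ndarray:
    """Seeded-hash embedding: pure integer hashing before float conversion,
    so it is identical across platforms and runs."""
    digest = hashlib.blake2b(
        token.encode("utf-8"), digest_size=8, key=str(seed).encode()
    ).digest()
    rng = np.random.default_rng(int.from_bytes(digest, "little"))
    return rng.standard_normal(dim) / np.sqrt(dim)


def _position_matrix(n: int, dim: int) -> np.ndarray:
    """Sinusoidal position encoding, scaled down so token identity dominates."""
    pos = np.arange(n)[:, None]
    i = np.arange(dim)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / dim)
    mat = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return 0.1 * mat


class HashingTextEncoder(BaseEstimator, TransformerMixin):
    """Deterministic offline token encoder.

    Parameters
    ----------
    dim : embedding dimension (64 by default; 768 matches a pretrained
        transformer backend when one is plugged in instead).
    seed : controls the token-hash key and segment vectors.
    max_seq_len : documents longer than this are truncated with a warning.
    """

    def __init__(self, dim: int = DEFAULT_DIM, seed: int = 0, max_seq_len: int = DEFAULT_MAX_SEQ_LEN):
        self.dim = dim
        self.seed = seed
        self.max_seq_len = max_seq_len

    # The encoder is stateless apart from its parameters; fit is a no-op that
    # marks the estimator fitted for sklearn pipeline compatibility.
    def fit(self, X: Iterable[TokenizedDoc] | None = None, y=None) -> "HashingTextEncoder":
        self.n_features_out_ = self.dim
        self._token_cache: dict[str, np.ndarray] = {}
        return self

    def _tok(self, token: str) -> np.ndarray:
        cache = getattr(self, "_token_cache", None)
        if cache is None:
            self._token_cache = cache = {}
        vec = cache.get(token)
        if vec is None:
            vec = _token_vector(token, self.seed, self.dim)
            cache[token] = vec
        return vec

    def encode(self, doc: TokenizedDoc) -> EmbeddingSequence:
        """Per-token vectors = token hash + sinusoidal position + segment."""
        tokens = doc.tokens
        if len(tokens) > self.max_seq_len:
            logger.warning(
                "doc %s: %d tokens truncated to max_seq_len=%d",
                doc.post_id, len(tokens), self.max_seq_len,
            )
            tokens = tokens[: self.max_seq_len]
        n = len(tokens)
        mat = np.empty((n, self.dim))
        for j, tok in enumerate(tokens):
            mat[j] = self._tok(tok)
        mat += _position_matrix(n, self.dim)
        seg_rng = np.random.default_rng(self.seed + 7919)
        seg = 0.05 * seg_rng.standard_normal((len(doc.sentence_bounds), self.dim))
        for s, (start, end) in enumerate(doc.sentence_bounds):
            mat[start : min(end, n)] += seg[s]
            if start >= n:
                break
        return EmbeddingSequence(post_id=doc.post_id, vectors=mat)

    def transform(self, X: Iterable[TokenizedDoc]) -> list[EmbeddingSequence]:
        if not hasattr(self, "n_features_out_"):
            self.fit()
        return [self.encode(doc) for doc in X]

    def encode_corpus(self, docs: Iterable[TokenizedDoc]) -> dict[str, EmbeddingSequence]:
        return {seq.post_id: seq for seq in self.transform(docs)}


def encode(doc: TokenizedDoc, backend: HashingTextEncoder) -> EmbeddingSequence:
    """Functional wrapper over ``backend.encode``."""
    return backend.encode(doc)


def doc_embedding(seq: EmbeddingSequence) -> DocEmbedding:
    """Document vector: arithmetic mean of the token vectors."""
    if len(seq) == 0:
        raise ValueError("empty embedding sequence")
    return DocEmbedding(post_id=seq.post_id, vector=seq.vectors.mean(axis=0))


def doc_embeddings(seqs: Mapping[str, EmbeddingSequence]) -> dict[str, DocEmbedding]:
    return {pid: doc_embedding(seq) for pid, seq in seqs.items()}
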