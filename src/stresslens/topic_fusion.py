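"""Embedding–topic fusion: the stress-feature extraction core.

The document representation couples two components:

* a latent topic model fit by collapsed Gibbs sampling on token identities
  (priors: symmetric ``alpha = 50/K`` over document–topic weights and
  ``beta = 0.01`` over topic–word distributions), and
* the encoder's dynamic token vectors, from which each topic receives an
  embedding-space vector — the centroid of the token vectors assigned to it.

A document's topic-space vector is the θ-weighted combination of topic
vectors; the *optimal* topic of a document is the one whose vector has
minimum cosine distance (maximum cosine similarity) to the document's mean
embedding, and fusing adds that topic vector to every token vector. Topics
are finally merged into the five stress features (research, employment,
affection, financial, other) either by a configured grouping or by
agglomerative clustering of topic vectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from numba import njit
from sklearn.base import BaseEstimator
from sklearn.cluster import AgglomerativeClustering

from .corpus import TokenizedDoc
from .embeddings import DocEmbedding, EmbeddingSequence

logger = logging.getLogger(__name__)

STRESS_FEATURES = ("research", "employment", "affection", "financial", "other")

#: Reference grouping of 20 topics into the five stress features (the
#: corpus-specific default; new corpora should use auto_group_topics).
DEFAULT_K20_GROUPS: dict[str, frozenset[int]] = {
    "research": frozenset({1, 6, 11, 12}),
    "employment": frozenset({0, 2, 14, 18}),
    "affection": frozenset({3, 7, 8, 9}),
    "financial": frozenset({4, 13, 15, 17}),
    "other": frozenset({5, 10, 16, 19}),
}

DEFAULT_CANDIDATE_KS = (5, 10, 15, 20, 25, 30)


@njit(cache=True)
def _gibbs_sweeps(doc_ids, word_ids, z, n_ik, n_kw, n_k, alpha, beta, n_iter, seed):
    np.random.seed(seed)
    K, V = n_kw.shape
    T = doc_ids.shape[0]
    cum = np.empty(K)
    for _ in range(n_iter):
        for t in range(T):
            d, w, k = doc_ids[t], word_ids[t], z[t]
            n_ik[d, k] -= 1
            n_kw[k, w] -= 1
            n_k[k] -= 1
            total = 0.0
            for kk in range(K):
                total += (n_ik[d, kk] + alpha) * (n_kw[kk, w] + beta) / (n_k[kk] + V * beta)
                cum[kk] = total
            u = np.random.random() * total
            knew = 0
            while cum[knew] < u:
                knew += 1
            z[t] = knew
            n_ik[d, knew] += 1
            n_kw[knew, w] += 1
            n_k[knew] += 1


@njit(cache=True)
def _fold_in_sweeps(doc_ids, word_ids, z, n_ik, phi, alpha, n_iter, seed):
    """Gibbs over held-out docs with the topic–word distributions frozen."""
    np.random.seed(seed)
    K = phi.shape[0]
    T = doc_ids.shape[0]
    cum = np.empty(K)
    for _ in range(n_iter):
        for t in range(T):
            d, w, k = doc_ids[t], word_ids[t], z[t]
            n_ik[d, k] -= 1
            total = 0.0
            for kk in range(K):
                total += (n_ik[d, kk] + alpha) * phi[kk, w]
                cum[kk] = total
            u = np.random.random() * total
            knew = 0
            while cum[knew] < u:
                knew += 1
            z[t] = knew
            n_ik[d, knew] += 1


class GibbsLDA(BaseEstimator):
    """Latent topic model fit by collapsed Gibbs sampling.

    Parameters
    ----------
    n_topics : number of topics K.
    alpha : symmetric document–topic prior; ``None`` means 50/K.
    beta : symmetric topic–word prior (0.01 by default).
    n_iter : Gibbs sweeps over the corpus.
    random_state : seed; the fit is deterministic given it.

    Attributes (after fit)
    ----------------------
    vocab_ : token -> column index.
    topic_word_counts_, doc_topic_counts_ : integer count matrices.
    assignments_ : per-doc arrays of token topic ids.
    phi_, theta_ : smoothed posterior point estimates,
        ``phi[k,w] = (n_kw + beta) / (n_k + V*beta)`` and
        ``theta[i,k] = (n_ik + alpha) / (N_i + K*alpha)``.
    """

    def __init__(
        self,
        n_topics: int = 20,
        alpha: float | None = None,
        beta: float = 0.01,
        n_iter: int = 200,
        random_state: int = 0,
    ):
        self.n_topics = n_topics
        self.alpha = alpha
        self.beta = beta
        self.n_iter = n_iter
        self.random_state = random_state

    @property
    def alpha_(self) -> float:
        return 50.0 / self.n_topics if self.alpha is None else self.alpha

    def fit(self, docs: Sequence[TokenizedDoc], y=None) -> "GibbsLDA":
        K = self.n_topics
        if K < 1:
            raise ValueError("n_topics must be >= 1")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if self.alpha_ <= 0 or self.beta <= 0:
            raise ValueError("priors must be positive")
        if any(len(d) == 0 for d in docs):
            raise ValueError("empty documents must be dropped upstream")
        vocab: dict[str, int] = {}
        for doc in docs:
            for tok in doc.tokens:
                if tok not in vocab:
                    vocab[tok] = len(vocab)
        V = len(vocab)
        total_tokens = sum(len(d) for d in docs)
        if K > total_tokens:
            raise ValueError(f"n_topics={K} exceeds corpus token count {total_tokens}")

        doc_ids = np.empty(total_tokens, dtype=np.int64)
        word_ids = np.empty(total_tokens, dtype=np.int64)
        offsets = [0]
        t = 0
        for i, doc in enumerate(docs):
            for tok in doc.tokens:
                doc_ids[t] = i
                word_ids[t] = vocab[tok]
                t += 1
            offsets.append(t)

        rng = np.random.default_rng(self.random_state)
        z = rng.integers(0, K, size=total_tokens).astype(np.int64)
        n_ik = np.zeros((len(docs), K), dtype=np.int64)
        n_kw = np.zeros((K, V), dtype=np.int64)
        n_k = np.zeros(K, dtype=np.int64)
        np.add.at(n_ik, (doc_ids, z), 1)
        np.add.at(n_kw, (z, word_ids), 1)
        np.add.at(n_k, z, 1)
        _gibbs_sweeps(
            doc_ids, word_ids, z, n_ik, n_kw, n_k,
            float(self.alpha_), float(self.beta), int(self.n_iter),
            int(self.random_state) % (2**31 - 1),
        )

        self.vocab_ = vocab
        self.post_ids_ = [d.post_id for d in docs]
        self.doc_lengths_ = np.diff(offsets)
        self.assignments_ = [z[offsets[i] : offsets[i + 1]].copy() for i in range(len(docs))]
        self.doc_topic_counts_ = n_ik
        self.topic_word_counts_ = n_kw
        self.topic_counts_ = n_k
        return self

    @property
    def phi_(self) -> np.ndarray:
        n_kw = self.topic_word_counts_
        V = n_kw.shape[1]
        return (n_kw + self.beta) / (self.topic_counts_[:, None] + V * self.beta)

    @property
    def theta_(self) -> np.ndarray:
        n_ik = self.doc_topic_counts_
        K = n_ik.shape[1]
        return (n_ik + self.alpha_) / (self.doc_lengths_[:, None] + K * self.alpha_)

    def transform(
        self, docs: Sequence[TokenizedDoc], n_sweeps: int = 25, seed: int | None = None
    ) -> np.ndarray:
        """Fold in unseen docs: θ̂ rows estimated with φ̂ frozen."""
        K = self.n_topics
        phi = self.phi_
        tok_doc: list[int] = []
        tok_word: list[int] = []
        lengths = np.zeros(len(docs), dtype=np.int64)
        oov = 0
        for i, doc in enumerate(docs):
            for tok in doc.tokens:
                w = self.vocab_.get(tok)
                if w is None:
                    oov += 1
                    continue
                tok_doc.append(i)
                tok_word.append(w)
                lengths[i] += 1
        if oov:
            logger.info("transform: %d out-of-vocabulary token(s) excluded", oov)
        doc_ids = np.asarray(tok_doc, dtype=np.int64)
        word_ids = np.asarray(tok_word, dtype=np.int64)
        fold_seed = (self.random_state + 13 if seed is None else seed) % (2**31 - 1)
        rng = np.random.default_rng(fold_seed)
        z = rng.integers(0, K, size=len(doc_ids)).astype(np.int64)
        n_ik = np.zeros((len(docs), K), dtype=np.int64)
        np.add.at(n_ik, (doc_ids, z), 1)
        if len(doc_ids):
            _fold_in_sweeps(doc_ids, word_ids, z, n_ik, phi, float(self.alpha_),
                            int(n_sweeps), fold_seed)
        return (n_ik + self.alpha_) / (lengths[:, None] + K * self.alpha_)


def fit_lda(
    corpus: Sequence[TokenizedDoc],
    K: int,
    alpha: float | None = None,
    beta: float = 0.01,
    iters: int = 200,
    seed: int = 0,
) -> GibbsLDA:
    return GibbsLDA(n_topics=K, alpha=alpha, beta=beta, n_iter=iters, random_state=seed).fit(corpus)


def perplexity_from_matrices(
    theta: np.ndarray, phi: np.ndarray, docs: Sequence[TokenizedDoc], vocab: Mapping[str, int]
) -> float:
    """exp(−mean log Σ_k θ_ik φ_kw) over in-vocabulary tokens."""
    log_lik = 0.0
    n_tokens = 0
    oov = 0
    for i, doc in enumerate(docs):
        for tok in doc.tokens:
            w = vocab.get(tok)
            if w is None:
                oov += 1
                continue
            p = float(theta[i] @ phi[:, w])
            log_lik += np.log(p)
            n_tokens += 1
    if oov:
        logger.info("perplexity: %d out-of-vocabulary token(s) excluded", oov)
    if n_tokens == 0:
        raise ValueError("no in-vocabulary tokens")
    return float(np.exp(-log_lik / n_tokens))


def perplexity(
    model: GibbsLDA,
    corpus: Sequence[TokenizedDoc],
    held_out: bool = True,
    completion: bool = False,
) -> float:
    """Predictive perplexity of ``corpus`` under the fitted model.

    θ̂ rows are re-estimated by folding in (so the same formula serves
    training and held-out documents); lower is better, minimum 1. With
    ``completion=True`` θ̂ is estimated on the even token positions only and
    the perplexity is measured on the odd positions (document completion),
    which penalizes topic counts that merely sub-split true topics.
    """
    if not completion:
        theta = model.transform(corpus) if held_out else model.theta_
        return perplexity_from_matrices(theta, model.phi_, corpus, model.vocab_)
    est_docs: list[TokenizedDoc] = []
    eval_docs: list[TokenizedDoc] = []
    for doc in corpus:
        est = doc.tokens[0::2]
        ev = doc.tokens[1::2]
        est_docs.append(
            TokenizedDoc(post_id=doc.post_id, tokens=est, sentence_bounds=((0, len(est)),))
        )
        if ev:
            eval_docs.append(
                TokenizedDoc(post_id=doc.post_id, tokens=ev, sentence_bounds=((0, len(ev)),))
            )
    theta = model.transform(est_docs)
    keep = [i for i, doc in enumerate(corpus) if len(doc.tokens) > 1]
    return perplexity_from_matrices(theta[keep], model.phi_, eval_docs, model.vocab_)


def select_topic_count(
    corpus: Sequence[TokenizedDoc],
    candidate_Ks: Sequence[int] = DEFAULT_CANDIDATE_KS,
    seeds_per_K: int = 3,
    alpha: float | None = None,
    beta: float = 0.01,
    iters: int = 100,
    seed: int = 0,
    holdout_fraction: float = 0.2,
) -> tuple[int, pd.DataFrame]:
    """Topic-count selection by held-out perplexity with restart variance.

    Each candidate K is fit ``seeds_per_K`` times on an 80/20 document
    split and scored by document-completion perplexity on the held-out
    docs. Candidates whose mean lies within one joint standard error of
    the best mean are treated as statistically tied; among those the
    smallest K wins (the one-standard-error parsimony rule), with the
    across-restart variance breaking any remaining exact tie.
    """
    if not candidate_Ks:
        raise ValueError("candidate_Ks must be non-empty")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(corpus))
    n_hold = max(1, int(round(holdout_fraction * len(corpus))))
    hold = [corpus[i] for i in idx[:n_hold]]
    train = [corpus[i] for i in idx[n_hold:]]
    rows = []
    for K in candidate_Ks:
        perps = []
        for r in range(seeds_per_K):
            model = GibbsLDA(
                n_topics=K, alpha=alpha, beta=beta, n_iter=iters,
                random_state=seed + 1000 * r + K,
            ).fit(train)
            perps.append(perplexity(model, hold, completion=True))
        rows.append(
            {"K": K, "mean_perplexity": float(np.mean(perps)),
             "var_perplexity": float(np.var(perps)),
             "se_perplexity": float(np.std(perps) / np.sqrt(len(perps)))}
        )
    table = pd.DataFrame(rows)
    best = table.loc[table["mean_perplexity"].idxmin()]
    margin = table["se_perplexity"] + best["se_perplexity"]
    tied = table[table["mean_perplexity"] <= best["mean_perplexity"] + margin]
    order = tied.sort_values(["K", "var_perplexity"]).reset_index(drop=True)
    return int(order.loc[0, "K"]), table


# ---------------------------------------------------------------------------
# Topic vectors, cosine selection, fusion


@dataclass(frozen=True)
class TopicVector:
    topic_id: int
    vector: np.ndarray


@dataclass(frozen=True)
class FusedSequence:
    """Token vectors with the selected topic vector added to each."""

    post_id: str
    vectors: np.ndarray
    topic_id: int

    def __len__(self) -> int:
        return self.vectors.shape[0]


def topic_vectors(
    model: GibbsLDA, embeddings: Mapping[str, EmbeddingSequence]
) -> tuple[dict[int, TopicVector], dict[str, np.ndarray]]:
    """Embedding-space topic vectors and per-document topic combinations.

    A topic's vector is the centroid of the token vectors Gibbs assigned to
    it; a document's vector is ``z_i = Σ_k θ̂_ik t_k``. Documents longer
    than the encoder's window contribute only their embedded positions.
    """
    missing = [pid for pid in model.post_ids_ if pid not in embeddings]
    if missing:
        raise ValueError(f"embeddings missing for docs: {missing[:5]}")
    dim = next(iter(embeddings.values())).dim
    K = model.n_topics
    sums = np.zeros((K, dim))
    counts = np.zeros(K, dtype=np.int64)
    for i, pid in enumerate(model.post_ids_):
        vecs = embeddings[pid].vectors
        z = model.assignments_[i]
        n = min(len(z), vecs.shape[0])
        np.add.at(sums, z[:n], vecs[:n])
        np.add.at(counts, z[:n], 1)
    tvecs: dict[int, TopicVector] = {}
    centroid = np.zeros((K, dim))
    for k in range(K):
        if counts[k] == 0:
            logger.warning("topic %d has no assigned tokens; zero vector", k)
        else:
            centroid[k] = sums[k] / counts[k]
        tvecs[k] = TopicVector(topic_id=k, vector=centroid[k])
    theta = model.theta_
    doc_vecs = {pid: theta[i] @ centroid for i, pid in enumerate(model.post_ids_)}
    return tvecs, doc_vecs


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for zero vectors")
    return float(np.dot(a, b) / (na * nb))


def assign_optimal_topic(
    doc_emb: DocEmbedding | np.ndarray, topic_vecs: Mapping[int, TopicVector]
) -> int:
    """Topic with minimum cosine distance (max similarity) to the document
    vector; ties and zero topic vectors resolved toward smaller topic id."""
    vec = doc_emb.vector if isinstance(doc_emb, DocEmbedding) else np.asarray(doc_emb)
    if not topic_vecs:
        raise ValueError("no topic vectors")
    best_k, best_sim = None, -np.inf
    for k in sorted(topic_vecs):
        tv = topic_vecs[k].vector
        if np.linalg.norm(tv) == 0:
            continue
        sim = cosine_similarity(vec, tv)
        if sim > best_sim + 1e-12:
            best_k, best_sim = k, sim
    if best_k is None:
        raise ValueError("all topic vectors are zero")
    return best_k


def fuse(seq: EmbeddingSequence, topic_vec: TopicVector) -> FusedSequence:
    """Add the selected topic vector to every token vector."""
    if seq.vectors.shape[1] != topic_vec.vector.shape[0]:
        raise ValueError("dimension mismatch between embeddings and topic vector")
    return FusedSequence(
        post_id=seq.post_id,
        vectors=seq.vectors + topic_vec.vector[None, :],
        topic_id=topic_vec.topic_id,
    )


def fuse_corpus(
    model: GibbsLDA,
    embeddings: Mapping[str, EmbeddingSequence],
) -> dict[str, FusedSequence]:
    """Full fusion step: doc mean embedding -> optimal topic -> fuse."""
    tvecs, _ = topic_vectors(model, embeddings)
    fused: dict[str, FusedSequence] = {}
    for pid, seq in embeddings.items():
        k = assign_optimal_topic(seq.vectors.mean(axis=0), tvecs)
        fused[pid] = fuse(seq, tvecs[k])
    return fused


# ---------------------------------------------------------------------------
# Topic merging into stress features


@dataclass(frozen=True)
class StressFeatureMap:
    mapping: dict[int, str]  # topic id -> feature label
    top_words: dict[str, tuple[tuple[str, float], ...]]  # ranked (word, prob)

    def feature_of(self, topic_id: int) -> str:
        return self.mapping[topic_id]


def merge_topics(
    model: GibbsLDA,
    groups: Sequence[Iterable[int]],
    labels: Sequence[str] = STRESS_FEATURES,
    top_n: int | None = None,
) -> StressFeatureMap:
    """Merge topic groups into named stress features.

    A feature's word distribution is the mean of its member topics' φ̂ rows,
    re-ranked; ``groups`` must partition [0, K).
    """
    group_sets = [set(g) for g in groups]
    if len(group_sets) != len(labels):
        raise ValueError("groups and labels must align")
    flat = [k for g in group_sets for k in g]
    if sorted(flat) != list(range(model.n_topics)):
        raise ValueError("groups must partition the topic ids")
    inv_vocab = {v: w for w, v in model.vocab_.items()}
    phi = model.phi_
    mapping: dict[int, str] = {}
    top_words: dict[str, tuple[tuple[str, float], ...]] = {}
    for g, label in zip(group_sets, labels):
        for k in g:
            mapping[k] = label
        row = phi[sorted(g)].mean(axis=0)
        order = np.argsort(-row, kind="stable")
        if top_n is not None:
            order = order[:top_n]
        top_words[label] = tuple((inv_vocab[w], float(row[w])) for w in order)
    return StressFeatureMap(mapping=mapping, top_words=top_words)


def auto_group_topics(
    model: GibbsLDA,
    embeddings: Mapping[str, EmbeddingSequence],
    n_groups: int,
) -> list[set[int]]:
    """Reproducible default for the manual "merge similar topics" step:
    agglomerative clustering of topic vectors by cosine similarity."""
    K = model.n_topics
    if not 1 <= n_groups <= K:
        raise ValueError("need 1 <= n_groups <= n_topics")
    if n_groups == K:
        return [{k} for k in range(K)]
    tvecs, _ = topic_vectors(model, embeddings)
    mat = np.stack([tvecs[k].vector for k in range(K)])
    norms = np.linalg.norm(mat, axis=1)
    mat[norms == 0] = 1e-12  # degenerate empty topics cluster together
    if n_groups == 1:
        return [set(range(K))]
    clust = AgglomerativeClustering(n_clusters=n_groups, metric="cosine", linkage="average")
    labels = clust.fit_predict(mat)
    groups: dict[int, set[int]] = {}
    for k, g in enumerate(labels):
        groups.setdefault(int(g), set()).add(k)
    return sorted(groups.values(), key=min)
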