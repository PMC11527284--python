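"""Seeded synthetic corpora with planted ground truth.

Every pipeline stage is exercised against corpora whose generating process
is known: a K-topic mixture with Dirichlet document weights for topic
recovery, a valence-word process for sentiment, lexicon-planted SEX/EDU/ORG
mentions for tagging, and per-category stress-feature mixtures for
profiling. Tokens are abstract strings ("w0017", "univ alpha"); the
pipeline is script-agnostic, so Chinese fixtures are a lexicon swap away.

All generators are pure functions of their config: the same seed yields a
byte-identical corpus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .corpus import BIOTaggedSentence, EntitySpan, Post, TokenizedDoc, bio_from_spans

STRESS_FEATURES = ("research", "employment", "affection", "financial", "other")

DEFAULT_SEX_LEXICON: tuple[tuple[str, ...], ...] = (("male",), ("female",))
DEFAULT_EDU_LEXICON: tuple[tuple[str, ...], ...] = (("master",), ("doctor",), ("phd",))
DEFAULT_ORG_LEXICON: tuple[tuple[str, ...], ...] = (
    ("univ", "alpha"),
    ("univ", "beta"),
    ("univ", "gamma"),
    ("institute", "delta"),
    ("institute", "epsilon", "tech"),
    ("college", "zeta"),
)
#: Institutions treated as world-class in the synthetic tier split.
DEFAULT_WORLD_CLASS = ("univ alpha", "univ beta", "institute epsilon tech")

_DEFAULT_FEATURE_MIXTURES: dict[tuple[str, str], tuple[float, ...]] = {
    ("male", "doctor"): (0.5, 0.2, 0.2, 0.05, 0.05),
    ("female", "doctor"): (0.2, 0.5, 0.1, 0.1, 0.1),
    ("male", "master"): (0.1, 0.1, 0.5, 0.2, 0.1),
    ("female", "master"): (0.05, 0.15, 0.1, 0.5, 0.2),
}


@dataclass
class GeneratorConfig:
    """Knobs of all four generators; defaults are the study conditions the
    recovery experiments assume."""

    seed: int
    # topic corpus
    vocab_size: int = 60
    n_topics: int = 3
    n_docs: int = 300
    tokens_per_doc: tuple[float, float] = (40.0, 0.0)  # (mean, dispersion)
    alpha_true: float = 0.3
    beta_true: float = 0.1
    topic_separation: float = 1.0
    # sentiment corpus
    negative_fraction: float = 0.88
    valence_rate: float = 0.5
    n_valence_words: int = 10
    # ner corpus
    sex_lexicon: tuple[tuple[str, ...], ...] = DEFAULT_SEX_LEXICON
    edu_lexicon: tuple[tuple[str, ...], ...] = DEFAULT_EDU_LEXICON
    org_lexicon: tuple[tuple[str, ...], ...] = DEFAULT_ORG_LEXICON
    plant_probs: Mapping[str, float] = field(
        default_factory=lambda: {"SEX": 0.35, "EDU": 0.35, "ORG": 0.45}
    )
    background_vocab: int = 200
    sentence_len_mean: float = 10.0
    # profile corpus
    facet_mixture: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: {k: 0.25 for k in _DEFAULT_FEATURE_MIXTURES}
    )
    feature_mixtures: Mapping[tuple[str, str], tuple[float, ...]] = field(
        default_factory=lambda: dict(_DEFAULT_FEATURE_MIXTURES)
    )
    words_per_feature: int = 10
    feature_token_rate: float = 0.5

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_topics < 1 or self.vocab_size < self.n_topics:
            raise ValueError("need vocab_size >= n_topics >= 1")
        if self.topic_separation > 0.5 and self.vocab_size < 10 * self.n_topics:
            raise ValueError("separable regime requires vocab_size >= 10 * n_topics")
        for name, p in [
            ("topic_separation", self.topic_separation),
            ("negative_fraction", self.negative_fraction),
            ("valence_rate", self.valence_rate),
            ("feature_token_rate", self.feature_token_rate),
            *[(f"plant_probs[{t}]", q) for t, q in self.plant_probs.items()],
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        for key, mix in self.feature_mixtures.items():
            if abs(sum(mix) - 1.0) > 1e-9:
                raise ValueError(f"feature mixture for {key} does not sum to 1")
        if abs(sum(self.facet_mixture.values()) - 1.0) > 1e-9:
            raise ValueError("facet mixture does not sum to 1")


def _doc_lengths(rng: np.random.Generator, n: int, mean: float, dispersion: float) -> np.ndarray:
    if dispersion <= 0:
        return np.full(n, max(1, int(round(mean))), dtype=int)
    # negative binomial with Var = mean * (1 + dispersion)
    r = mean / dispersion
    p = 1.0 / (1.0 + dispersion)
    return np.maximum(1, rng.negative_binomial(r, p, size=n))


def generate_topic_corpus(
    config: GeneratorConfig,
) -> tuple[list[TokenizedDoc], np.ndarray, np.ndarray, list[np.ndarray]]:
    """Sample docs from the standard topic-mixture generative process.

    Returns (docs, true_theta (M,K), true_phi (K,V), per-doc token topic
    assignments). ``topic_separation`` is the fraction of each topic's mass
    confined to its own disjoint vocabulary block.
    """
    rng = np.random.default_rng(config.seed)
    K, V, M = config.n_topics, config.vocab_size, config.n_docs
    block = V // K
    phi = np.zeros((K, V))
    for k in range(K):
        own = np.zeros(V)
        lo, hi = k * block, (k + 1) * block if k < K - 1 else V
        own[lo:hi] = rng.dirichlet(np.full(hi - lo, config.beta_true * 10))
        spread = rng.dirichlet(np.full(V, config.beta_true * 10))
        phi[k] = config.topic_separation * own + (1 - config.topic_separation) * spread
    theta = rng.dirichlet(np.full(K, config.alpha_true), size=M) if K > 1 else np.ones((M, 1))
    lengths = _doc_lengths(rng, M, *config.tokens_per_doc)
    words = [f"w{v:04d}" for v in range(V)]
    docs: list[TokenizedDoc] = []
    assignments: list[np.ndarray] = []
    for i in range(M):
        z = rng.choice(K, size=lengths[i], p=theta[i])
        w = np.array([rng.choice(V, p=phi[k]) for k in z])
        docs.append(
            TokenizedDoc(
                post_id=f"t{i:05d}",
                tokens=tuple(words[v] for v in w),
                sentence_bounds=((0, int(lengths[i])),),
            )
        )
        assignments.append(z)
    return docs, theta, phi, assignments


def generate_sentiment_corpus(
    config: GeneratorConfig, n_docs: int | None = None, doc_len: int = 20
) -> tuple[list[TokenizedDoc], list[str]]:
    """Valence-word corpus: negative docs over-sample a negative-valence
    block at ``valence_rate`` (positives symmetrically); labels returned."""
    rng = np.random.default_rng(config.seed + 1)
    n = n_docs if n_docs is not None else config.n_docs
    neg_block = [f"negval_{j}" for j in range(config.n_valence_words)]
    pos_block = [f"posval_{j}" for j in range(config.n_valence_words)]
    background = [f"w{v:04d}" for v in range(config.background_vocab)]
    docs: list[TokenizedDoc] = []
    labels: list[str] = []
    is_neg = rng.random(n) < config.negative_fraction
    for i in range(n):
        block = neg_block if is_neg[i] else pos_block
        toks = [
            rng.choice(block) if rng.random() < config.valence_rate else rng.choice(background)
            for _ in range(doc_len)
        ]
        docs.append(
            TokenizedDoc(post_id=f"s{i:05d}", tokens=tuple(toks), sentence_bounds=((0, doc_len),))
        )
        labels.append("negative" if is_neg[i] else "positive")
    return docs, labels


def generate_ner_corpus(
    config: GeneratorConfig,
    n_sentences: int,
    entity_types: Sequence[str] = ("SEX", "EDU", "ORG"),
) -> tuple[list[BIOTaggedSentence], list[list[EntitySpan]]]:
    """Background sentences with entity mentions planted from the lexicons.

    ``entity_types=("ORG",)`` gives the first-stage, ORG-only regime.
    Returns the tagged sentences and the planting log (gold spans per
    sentence, identical to what the BIO labels encode).
    """
    lexicons = {"SEX": config.sex_lexicon, "EDU": config.edu_lexicon, "ORG": config.org_lexicon}
    for t in entity_types:
        if t not in lexicons or not lexicons[t]:
            raise ValueError(f"empty or unknown lexicon for entity type {t!r}")
    rng = np.random.default_rng(config.seed + 2)
    background = [f"bg{v:04d}" for v in range(config.background_vocab)]
    sentences: list[BIOTaggedSentence] = []
    log: list[list[EntitySpan]] = []
    for _ in range(n_sentences):
        toks = [str(rng.choice(background)) for _ in range(3 + rng.poisson(config.sentence_len_mean))]
        spans: list[EntitySpan] = []
        for etype in entity_types:
            if rng.random() >= config.plant_probs.get(etype, 0.0):
                continue
            lex = lexicons[etype]
            mention = lex[rng.integers(len(lex))]
            pos = int(rng.integers(len(toks) + 1))
            toks[pos:pos] = list(mention)
            # shift previously planted spans that sit at/after the insertion
            spans = [
                EntitySpan(
                    start=s.start + len(mention) if s.start >= pos else s.start,
                    end=s.end + len(mention) if s.start >= pos else s.end,
                    entity_type=s.entity_type,
                    surface=s.surface,
                )
                for s in spans
            ]
            spans.append(
                EntitySpan(pos, pos + len(mention), etype, " ".join(mention))
            )
        spans.sort()
        labels = bio_from_spans(spans, len(toks))
        sentences.append(BIOTaggedSentence(tokens=tuple(toks), labels=tuple(labels)))
        log.append(spans)
    return sentences, log


def feature_word_lists(words_per_feature: int = 10) -> dict[str, list[tuple[str, float]]]:
    """Synthetic per-feature top-word lists with geometric pseudo-probabilities."""
    out: dict[str, list[tuple[str, float]]] = {}
    for f in STRESS_FEATURES:
        probs = np.array([0.5**j for j in range(words_per_feature)])
        probs = probs / probs.sum() * 0.2  # arbitrary scale; ranking is what matters
        out[f] = [(f"{f}_w{j}", float(probs[j])) for j in range(words_per_feature)]
    return out


def generate_profile_corpus(
    config: GeneratorConfig, n_docs: int = 2000, doc_len: int = 30
) -> tuple[list[TokenizedDoc], list[dict[str, str]], dict]:
    """Docs with planted (sex, edu, org_tier) facets and per-category
    stress-feature token mixtures.

    Returns (docs, per-doc facets, truth) where truth records the category
    mixtures, category counts and the feature word lists used.
    """
    rng = np.random.default_rng(config.seed + 3)
    categories = list(config.facet_mixture.keys())
    cat_probs = np.array([config.facet_mixture[c] for c in categories])
    words = feature_word_lists(config.words_per_feature)
    background = [f"w{v:04d}" for v in range(config.background_vocab)]
    tiers = ("world_class", "non_top_tier")
    docs: list[TokenizedDoc] = []
    facets: list[dict[str, str]] = []
    counts = {c: 0 for c in categories}
    cat_idx = rng.choice(len(categories), size=n_docs, p=cat_probs)
    for i in range(n_docs):
        sex, edu = categories[cat_idx[i]]
        counts[(sex, edu)] += 1
        mix = np.asarray(config.feature_mixtures[(sex, edu)])
        toks: list[str] = []
        for _ in range(doc_len):
            if rng.random() < config.feature_token_rate:
                f = STRESS_FEATURES[rng.choice(len(STRESS_FEATURES), p=mix)]
                toks.append(words[f][rng.integers(config.words_per_feature)][0])
            else:
                toks.append(str(rng.choice(background)))
        docs.append(
            TokenizedDoc(post_id=f"p{i:05d}", tokens=tuple(toks), sentence_bounds=((0, doc_len),))
        )
        facets.append({"sex": sex, "edu": edu, "org_tier": tiers[int(rng.random() < 0.5)]})
    truth = {
        "category_counts": counts,
        "feature_mixtures": {c: tuple(config.feature_mixtures[c]) for c in categories},
        "feature_words": words,
    }
    return docs, facets, truth


def generate_pipeline_corpus(
    config: GeneratorConfig, n_docs: int = 200, n_ner_train: int = 300
) -> tuple[list[Post], list[str], list[BIOTaggedSentence]]:
    """Smoke-scale corpus exercising every pipeline stage at once.

    Each post is a background sentence with planted entity mentions plus a
    few sentiment-valence tokens matching its label; a separate tagged
    sentence set is returned for training the NER stage. Returns
    (labelled posts, labels, ner training sentences).
    """
    rng = np.random.default_rng(config.seed + 4)
    # plant densely so a useful share of posts carries both SEX and EDU
    from dataclasses import replace

    dense = replace(config, plant_probs={"SEX": 0.6, "EDU": 0.6, "ORG": 0.5})
    sentences, _ = generate_ner_corpus(dense, n_sentences=n_docs)
    neg_block = [f"negval_{j}" for j in range(config.n_valence_words)]
    pos_block = [f"posval_{j}" for j in range(config.n_valence_words)]
    posts: list[Post] = []
    labels: list[str] = []
    for i, sent in enumerate(sentences):
        neg = rng.random() < config.negative_fraction
        block = neg_block if neg else pos_block
        extra = [str(rng.choice(block)) for _ in range(6)]
        label = "negative" if neg else "positive"
        posts.append(
            Post(
                id=f"e{i:05d}",
                text=" ".join(list(sent.tokens) + extra),
                platform="synthetic",
                label_sentiment=label,
            )
        )
        labels.append(label)
    ner_cfg = GeneratorConfig(seed=config.seed + 5)
    ner_train, _ = generate_ner_corpus(ner_cfg, n_sentences=n_ner_train)
    return posts, labels, ner_train


def docs_to_posts(docs: Sequence[TokenizedDoc], labels: Sequence[str] | None = None) -> list[Post]:
    """Serialize synthetic docs as whitespace-joined posts."""
    posts = []
    for i, doc in enumerate(docs):
        posts.append(
            Post(
                id=doc.post_id,
                text=" ".join(doc.tokens),
                platform="synthetic",
                label_sentiment=labels[i] if labels is not None else None,
            )
        )
    return posts
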