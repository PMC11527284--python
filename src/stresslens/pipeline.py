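"""End-to-end orchestration: encode -> topic fusion -> sentiment split ->
stress topic model -> NER -> profile, with seeded determinism and a run
manifest.

A single global seed fans out to per-stage seeds by a stable derivation so
any stage can be rerun in isolation; rerunning the whole pipeline with the
same config and data reproduces every artifact.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, field_validator

from . import corpus as corpus_mod
from .corpus import Post, TokenizedDoc, read_conll, tokenize, write_posts_jsonl
from .embeddings import HashingTextEncoder
from .ner import BiLSTMCRFTagger, LSTMParams, extract_entities
from .profile import ProfileTable, build_profile, facets_from_entities
from .sentiment import SentimentClassifier, SentimentHyper, split_corpus, train_sentiment
from .synthetic import DEFAULT_WORLD_CLASS
from .topic_fusion import (
    DEFAULT_K20_GROUPS,
    STRESS_FEATURES,
    GibbsLDA,
    StressFeatureMap,
    auto_group_topics,
    fuse_corpus,
    merge_topics,
)

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed derivation (keeps seeds below 2**31)."""
    return (global_seed * 1000003 + zlib.crc32(stage.encode())) % (2**31 - 1)


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class EncoderConfig(_Strict):
    dim: int = 64
    max_seq_len: int = 256


class LDAConfig(_Strict):
    n_topics: int = 20
    alpha: float | str | None = None  # None or "50/l" both mean 50/K
    beta: float = 0.01
    iters: int = 200
    groups: list[list[int]] | None = None  # explicit topic -> feature groups

    @field_validator("alpha")
    @classmethod
    def _parse_alpha(cls, v):
        if isinstance(v, str):
            if v.replace(" ", "").lower() in ("50/l", "50/k"):
                return None
            raise ValueError(f"unsupported alpha expression {v!r}")
        return v


class SentimentConfig(_Strict):
    lr: float = 0.1
    epochs: int = 300
    threshold: float = 0.5
    class_weighted: bool = False


class NERConfig(_Strict):
    train_conll: str | None = None
    hidden_dim: int = 200
    lr: float = 2e-5
    epochs: int = 5
    batch_size: int = 64
    dropout: float = 0.5
    max_seq_len: int = 256
    embedding_dim: int = 32
    use_crf: bool = True
    peephole: bool = True


class ProfileConfig(_Strict):
    dims: tuple[str, str] = ("sex", "edu")
    top_n: int = 10
    world_class_lexicon: list[str] = list(DEFAULT_WORLD_CLASS)


class PipelineConfig(_Strict):
    """Stage-keyed parameter tree; unknown keys are rejected."""

    seed: int = 0
    tokenize_mode: Literal["character", "whitespace", "segmenter"] = "whitespace"
    encoder: EncoderConfig = EncoderConfig()
    lda: LDAConfig = LDAConfig()
    sentiment: SentimentConfig = SentimentConfig()
    ner: NERConfig = NERConfig()
    profile: ProfileConfig = ProfileConfig()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Model bundle serialization (JSON metadata + npz arrays)


def save_lda(model: GibbsLDA, prefix: str | Path) -> None:
    prefix = Path(prefix)
    meta = {
        "n_topics": model.n_topics,
        "alpha": model.alpha,
        "beta": model.beta,
        "n_iter": model.n_iter,
        "random_state": model.random_state,
        "vocab": model.vocab_,
        "post_ids": model.post_ids_,
    }
    prefix.with_suffix(".json").write_text(json.dumps(meta), encoding="utf-8")
    np.savez(
        prefix.with_suffix(".npz"),
        doc_topic_counts=model.doc_topic_counts_,
        topic_word_counts=model.topic_word_counts_,
        topic_counts=model.topic_counts_,
        doc_lengths=model.doc_lengths_,
        assignments=np.concatenate(model.assignments_) if model.assignments_ else np.array([]),
        assignment_offsets=np.cumsum([0] + [len(a) for a in model.assignments_]),
    )


def load_lda(prefix: str | Path) -> GibbsLDA:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text(encoding="utf-8"))
    arrays = np.load(prefix.with_suffix(".npz"))
    model = GibbsLDA(
        n_topics=meta["n_topics"], alpha=meta["alpha"], beta=meta["beta"],
        n_iter=meta["n_iter"], random_state=meta["random_state"],
    )
    model.vocab_ = dict(meta["vocab"])
    model.post_ids_ = list(meta["post_ids"])
    model.doc_topic_counts_ = arrays["doc_topic_counts"]
    model.topic_word_counts_ = arrays["topic_word_counts"]
    model.topic_counts_ = arrays["topic_counts"]
    model.doc_lengths_ = arrays["doc_lengths"]
    offs = arrays["assignment_offsets"]
    flat = arrays["assignments"]
    model.assignments_ = [flat[offs[i] : offs[i + 1]] for i in range(len(offs) - 1)]
    return model


def save_tagger(model: BiLSTMCRFTagger, prefix: str | Path) -> None:
    prefix = Path(prefix)
    meta = {k: v for k, v in model.get_params().items()}
    meta["entity_types"] = list(model.entity_types)
    prefix.with_suffix(".json").write_text(json.dumps(meta), encoding="utf-8")
    arrays = {key.replace(".", "__"): arr for key, arr in model._param_items()}
    np.savez(prefix.with_suffix(".npz"), **arrays)


def load_tagger(prefix: str | Path) -> BiLSTMCRFTagger:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text(encoding="utf-8"))
    meta["entity_types"] = tuple(meta["entity_types"])
    model = BiLSTMCRFTagger(**meta)
    from .ner import label_vocabulary

    model.labels_ = label_vocabulary(model.entity_types)
    model.label_to_id_ = {lab: i for i, lab in enumerate(model.labels_)}
    model.encoder_ = HashingTextEncoder(
        dim=model.embedding_dim, seed=model.seed, max_seq_len=model.max_seq_len
    ).fit()
    model._init_state()
    arrays = np.load(prefix.with_suffix(".npz"))
    for key, arr in model._param_items():
        arr[...] = arrays[key.replace(".", "__")]
    return model


def save_sentiment(model: SentimentClassifier, path: str | Path) -> None:
    obj = model.get_params()
    obj["weight"] = model.weight_.tolist()
    obj["bias"] = model.bias_
    Path(path).write_text(json.dumps(obj), encoding="utf-8")


def load_sentiment(path: str | Path) -> SentimentClassifier:
    obj = json.loads(Path(path).read_text(encoding="utf-8"))
    weight = np.asarray(obj.pop("weight"))
    bias = obj.pop("bias")
    model = SentimentClassifier(**obj)
    model.weight_ = weight
    model.bias_ = float(bias)
    model.classes_ = np.array(["positive", "negative"])
    return model


# ---------------------------------------------------------------------------
# Pipeline


def _file_checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(
    config: PipelineConfig, posts: Sequence[Post], outdir: str | Path
) -> dict:
    """Execute all stages in order and write the run directory.

    Artifacts: sentiment split (JSONL), model bundles, the stress-feature
    map (JSON), per-document entities (JSONL), the profile table (CSV +
    JSON) and a manifest with seeds, config hash and output checksums.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "config": config.model_dump(mode="json"),
        "seed": config.seed,
        "stages": {},
        "outputs": {},
    }
    stage = "tokenize"
    try:
        docs: list[TokenizedDoc] = []
        kept_posts: list[Post] = []
        dropped = 0
        for post in posts:
            try:
                docs.append(tokenize(post.text, mode=config.tokenize_mode, post_id=post.id))
                kept_posts.append(post)
            except corpus_mod.EmptyDocumentError:
                dropped += 1
        if not docs:
            raise ValueError("no non-empty documents")
        manifest["stages"][stage] = {"docs": len(docs), "dropped": dropped}

        stage = "encode"
        encoder = HashingTextEncoder(
            dim=config.encoder.dim,
            seed=derive_seed(config.seed, "encoder"),
            max_seq_len=config.encoder.max_seq_len,
        ).fit()
        seqs = encoder.encode_corpus(docs)
        manifest["stages"][stage] = {"dim": config.encoder.dim}

        stage = "topic_fusion"
        lda_seed = derive_seed(config.seed, "lda")
        lda = GibbsLDA(
            n_topics=config.lda.n_topics,
            alpha=config.lda.alpha,
            beta=config.lda.beta,
            n_iter=config.lda.iters,
            random_state=lda_seed,
        ).fit(docs)
        fused = fuse_corpus(lda, seqs)
        manifest["stages"][stage] = {"K": config.lda.n_topics, "seed": lda_seed}

        stage = "sentiment"
        labelled = [
            (fused[p.id], p.label_sentiment) for p in kept_posts if p.label_sentiment
        ]
        if not labelled:
            raise ValueError("no posts carry sentiment labels for training")
        hyper = SentimentHyper(
            lr=config.sentiment.lr,
            epochs=config.sentiment.epochs,
            seed=derive_seed(config.seed, "sentiment"),
            threshold=config.sentiment.threshold,
            class_weighted=config.sentiment.class_weighted,
        )
        sent_model, sent_acc = train_sentiment(labelled, hyper)
        negative, positive = split_corpus(kept_posts, fused, sent_model)
        write_posts_jsonl(negative, outdir / "posts_negative.jsonl")
        write_posts_jsonl(positive, outdir / "posts_positive.jsonl")
        save_sentiment(sent_model, outdir / "sentiment_model.json")
        manifest["stages"][stage] = {
            "negative": len(negative), "positive": len(positive),
            "holdout_accuracy": sent_acc,
        }

        stage = "stress_topics"
        neg_ids = {p.id for p in negative}
        neg_docs = [d for d in docs if d.post_id in neg_ids] or docs
        stress_lda = GibbsLDA(
            n_topics=config.lda.n_topics,
            alpha=config.lda.alpha,
            beta=config.lda.beta,
            n_iter=config.lda.iters,
            random_state=derive_seed(config.seed, "stress_lda"),
        ).fit(neg_docs)
        neg_seqs = {pid: seqs[pid] for pid in (d.post_id for d in neg_docs)}
        if config.lda.groups is not None:
            groups = [set(g) for g in config.lda.groups]
            feature_labels = list(STRESS_FEATURES[: len(groups)])
        elif config.lda.n_topics == 20:
            groups = [set(DEFAULT_K20_GROUPS[f]) for f in STRESS_FEATURES]
            feature_labels = list(STRESS_FEATURES)
        else:
            n_feat = min(len(STRESS_FEATURES), config.lda.n_topics)
            groups = auto_group_topics(stress_lda, neg_seqs, n_feat)
            feature_labels = list(STRESS_FEATURES[:n_feat])
        feature_map = merge_topics(stress_lda, groups, feature_labels)
        save_lda(stress_lda, outdir / "stress_lda")
        (outdir / "feature_map.json").write_text(
            json.dumps(
                {
                    "mapping": {str(k): v for k, v in feature_map.mapping.items()},
                    "top_words": {
                        f: feature_map.top_words[f][: config.profile.top_n]
                        for f in feature_map.top_words
                    },
                },
                ensure_ascii=False, indent=1,
            ),
            encoding="utf-8",
        )
        manifest["stages"][stage] = {"docs": len(neg_docs), "groups": [sorted(g) for g in groups]}

        stage = "ner"
        if config.ner.train_conll is None:
            raise ValueError("ner.train_conll is required to run the NER stage")
        train_sents = read_conll(config.ner.train_conll)
        tagger = BiLSTMCRFTagger(
            hidden_dim=config.ner.hidden_dim,
            lr=config.ner.lr,
            epochs=config.ner.epochs,
            batch_size=config.ner.batch_size,
            dropout=config.ner.dropout,
            use_crf=config.ner.use_crf,
            peephole=config.ner.peephole,
            embedding_dim=config.ner.embedding_dim,
            max_seq_len=config.ner.max_seq_len,
            seed=derive_seed(config.seed, "ner"),
        ).fit(train_sents)
        save_tagger(tagger, outdir / "ner_model")
        entities = extract_entities(tagger, neg_docs)
        with open(outdir / "entities.jsonl", "w", encoding="utf-8") as fh:
            for doc, spans in zip(neg_docs, entities):
                fh.write(
                    json.dumps(
                        {
                            "id": doc.post_id,
                            "entities": [
                                [s.entity_type, s.start, s.end, s.surface] for s in spans
                            ],
                        },
                        ensure_ascii=False,
                    )
                    + "\n"
                )
        manifest["stages"][stage] = {
            "train_sentences": len(train_sents),
            "docs_tagged": len(neg_docs),
            "entities": sum(len(s) for s in entities),
        }

        stage = "profile"
        facets = [
            facets_from_entities(
                doc.post_id, spans,
                world_class_lexicon=config.profile.world_class_lexicon,
            )
            for doc, spans in zip(neg_docs, entities)
        ]
        tokens_by_post = {d.post_id: d.tokens for d in neg_docs}
        table: ProfileTable = build_profile(
            facets, tokens_by_post, feature_map,
            dims=config.profile.dims, top_n=config.profile.top_n,
        )
        frame = table.to_frame()
        frame.to_csv(outdir / "profile.csv", index=False)
        (outdir / "profile.json").write_text(
            frame.to_json(orient="records"), encoding="utf-8"
        )
        manifest["stages"][stage] = {
            "categories": len(table.rows), "excluded_unknown": table.excluded,
        }
    except Exception as exc:
        manifest["failed_stage"] = stage
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1), encoding="utf-8")
        if isinstance(exc, PipelineStageError):
            raise
        raise PipelineStageError(stage, exc) from exc

    for path in sorted(outdir.iterdir()):
        if path.name != "manifest.json" and path.is_file():
            manifest["outputs"][path.name] = _file_checksum(path)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1), encoding="utf-8")
    return manifest
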