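"""Corpus data model and I/O.

Posts are short social-media documents; annotated sentences use the BIO2
scheme over the entity types SEX (gender mention), EDU (degree level) and
ORG (institution name). Readers/writers cover JSONL for posts and the
CoNLL-style two-column TSV for tagged sentences.
"""

from __future__ import annotations

import json
import logging
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

ENTITY_TYPES = ("SEX", "EDU", "ORG")

#: Cohort-identification keys: first-person degree statements and
#: advisor/research-group mentions characteristic of postgraduate authors.
DEFAULT_COHORT_PATTERNS = (
    r"I\s+am\s+(?:a\s+)?(?:master|doctor(?:al)?|Ph\.?D\.?)\s+candidate",
    r"my\s+advisor",
    r"my\s+research\s+group",
)


class EmptyDocumentError(ValueError):
    """Raised when a text is empty after cleaning; callers drop the post."""


@dataclass(frozen=True)
class Post:
    """A raw social-media document."""

    id: str
    text: str
    platform: str = "synthetic"
    timestamp: str | None = None
    label_sentiment: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("post id must be non-empty")
        if not self.text.strip():
            raise EmptyDocumentError(f"post {self.id!r}: empty text")


@dataclass(frozen=True)
class TokenizedDoc:
    """A segmented document: tokens plus half-open sentence bounds."""

    post_id: str
    tokens: tuple[str, ...]
    sentence_bounds: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        n = len(self.tokens)
        if n == 0:
            raise EmptyDocumentError(f"doc {self.post_id!r}: no tokens")
        prev_end = 0
        for start, end in self.sentence_bounds:
            if start != prev_end or end <= start:
                raise ValueError("sentence_bounds must partition [0, n)")
            prev_end = end
        if prev_end != n:
            raise ValueError("sentence_bounds must cover all tokens")

    def __len__(self) -> int:
        return len(self.tokens)

    def sentence_of(self, index: int) -> int:
        """Sentence id containing token ``index``."""
        for s, (start, end) in enumerate(self.sentence_bounds):
            if start <= index < end:
                return s
        raise IndexError(index)


@dataclass(frozen=True)
class BIOTaggedSentence:
    tokens: tuple[str, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.labels):
            raise ValueError("tokens and labels must align")
        validate_bio(self.labels)


@dataclass(frozen=True, order=True)
class EntitySpan:
    """Exact token span [start, end) of one entity mention."""

    start: int
    end: int
    entity_type: str
    surface: str = field(compare=False, default="")

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad span bounds ({self.start}, {self.end})")


_SENT_SPLIT = re.compile(r"(?<=[.!?。！？；;])\s*")


def _split_sentences(text: str) -> list[str]:
    parts = [p for p in _SENT_SPLIT.split(text) if p.strip()]
    return parts or [text]


def tokenize(
    text: str,
    mode: str = "character",
    *,
    post_id: str = "",
    stop_words: Iterable[str] | None = None,
) -> TokenizedDoc:
    """Segment ``text`` into tokens and sentences.

    ``character`` splits into code points (the CJK default), ``whitespace``
    on runs of spaces (synthetic corpora), ``segmenter`` uses jieba if it is
    importable. Stop words are removed only when a list is supplied.
    """
    if not text.strip():
        raise EmptyDocumentError("empty text")
    stop = set(stop_words) if stop_words else None
    tokens: list[str] = []
    bounds: list[tuple[int, int]] = []
    for sent in _split_sentences(text):
        if mode == "whitespace":
            raw = sent.split()
        elif mode == "character":
            raw = [ch for ch in sent if not ch.isspace()]
        elif mode == "segmenter":
            try:
                import jieba  # type: ignore
            except ImportError as exc:  # pragma: no cover - optional dep
                raise RuntimeError(
                    "segmenter mode requires the optional jieba package; "
                    "use mode='character' for CJK text"
                ) from exc
            raw = [t for t in jieba.cut(sent) if t.strip()]
        else:
            raise ValueError(f"unknown tokenize mode {mode!r}")
        if stop:
            raw = [t for t in raw if t not in stop]
        if raw:
            start = len(tokens)
            tokens.extend(raw)
            bounds.append((start, len(tokens)))
    if not tokens:
        raise EmptyDocumentError("empty document after cleaning")
    return TokenizedDoc(post_id=post_id, tokens=tuple(tokens), sentence_bounds=tuple(bounds))


def compile_patterns(patterns: Sequence[str]) -> list[re.Pattern[str]]:
    """Compile cohort regexes eagerly so bad patterns fail at load time."""
    if not patterns:
        raise ValueError("patterns must be non-empty")
    try:
        return [re.compile(p, re.IGNORECASE) for p in patterns]
    except re.error as exc:
        raise ValueError(f"invalid cohort pattern: {exc}") from exc


def match_postgraduate(
    post: Post, patterns: Sequence[str] | Sequence[re.Pattern[str]] | None = None
) -> bool:
    """True iff any cohort pattern matches the post text."""
    if patterns is None:
        patterns = DEFAULT_COHORT_PATTERNS
    compiled = [p if isinstance(p, re.Pattern) else re.compile(p, re.IGNORECASE) for p in patterns]
    if not compiled:
        raise ValueError("patterns must be non-empty")
    return any(p.search(post.text) for p in compiled)


def filter_cohort(posts: Iterable[Post], patterns: Sequence[str] | None = None) -> list[Post]:
    compiled = compile_patterns(list(patterns) if patterns else list(DEFAULT_COHORT_PATTERNS))
    return [p for p in posts if match_postgraduate(p, compiled)]


# ---------------------------------------------------------------------------
# JSONL posts


def read_posts_jsonl(path: str | Path) -> tuple[list[Post], list[tuple[int, str]]]:
    """Read one post per JSON line; returns (posts, bad-line report).

    Malformed lines (bad JSON, missing id/text, duplicate id) are collected
    as (line-number, reason) pairs rather than aborting the read.
    """
    posts: list[Post] = []
    errors: list[tuple[int, str]] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                errors.append((lineno, f"bad json: {exc.msg}"))
                continue
            if not isinstance(obj, dict) or "id" not in obj or "text" not in obj:
                errors.append((lineno, "missing id/text"))
                continue
            if obj["id"] in seen:
                errors.append((lineno, f"duplicate id {obj['id']!r}"))
                continue
            try:
                post = Post(
                    id=str(obj["id"]),
                    text=obj["text"],
                    platform=obj.get("platform", "synthetic"),
                    timestamp=obj.get("timestamp"),
                    label_sentiment=obj.get("label_sentiment"),
                )
            except ValueError as exc:
                errors.append((lineno, str(exc)))
                continue
            seen.add(post.id)
            posts.append(post)
    if errors:
        logger.warning("read_posts_jsonl: %d malformed line(s) in %s", len(errors), path)
    return posts, errors


def write_posts_jsonl(posts: Iterable[Post], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in posts:
            obj: dict[str, object] = {"id": p.id, "text": p.text, "platform": p.platform}
            if p.timestamp is not None:
                obj["timestamp"] = p.timestamp
            if p.label_sentiment is not None:
                obj["label_sentiment"] = p.label_sentiment
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")


# ---------------------------------------------------------------------------
# BIO labels and CoNLL TSV


def validate_bio(labels: Sequence[str]) -> None:
    """Raise ValueError unless ``labels`` is a valid BIO2 sequence."""
    prev = "O"
    for lab in labels:
        if lab == "O":
            prev = lab
            continue
        if len(lab) < 3 or lab[1] != "-" or lab[0] not in "BI":
            raise ValueError(f"malformed BIO label {lab!r}")
        if lab[0] == "I":
            if prev == "O" or prev[2:] != lab[2:]:
                raise ValueError(f"I-label {lab!r} without matching B/I predecessor")
        prev = lab


def repair_bio(labels: Sequence[str]) -> tuple[list[str], int]:
    """Turn illegal I- openings into B- (BIO2 repair); returns repair count."""
    fixed: list[str] = []
    repairs = 0
    prev = "O"
    for lab in labels:
        if lab.startswith("I-") and (prev == "O" or (prev != "O" and prev[2:] != lab[2:])):
            lab = "B-" + lab[2:]
            repairs += 1
        fixed.append(lab)
        prev = lab
    return fixed, repairs


def project_labels(labels: Sequence[str], keep: set[str]) -> list[str]:
    """Map labels whose entity type is outside ``keep`` to O (retention rule)."""
    return [lab if lab != "O" and lab[2:] in keep else "O" for lab in labels]


def read_conll(
    path: str | Path,
    *,
    keep_types: set[str] | None = None,
    strict: bool = False,
) -> list[BIOTaggedSentence]:
    """Read token<TAB>label sentences separated by blank lines.

    ``keep_types`` projects any other entity type to O before validation.
    Illegal I- openings are repaired to B- (logged) unless ``strict``.
    """
    sentences: list[BIOTaggedSentence] = []
    tokens: list[str] = []
    labels: list[str] = []
    total_repairs = 0

    def flush() -> None:
        nonlocal tokens, labels, total_repairs
        if not tokens:
            return
        labs = project_labels(labels, keep_types) if keep_types is not None else list(labels)
        if strict:
            validate_bio(labs)
        else:
            labs, n = repair_bio(labs)
            total_repairs += n
        sentences.append(BIOTaggedSentence(tokens=tuple(tokens), labels=tuple(labs)))
        tokens, labels = [], []

    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                flush()
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'token<TAB>label'")
            tokens.append(parts[0])
            labels.append(parts[1])
    flush()
    if total_repairs:
        logger.warning("read_conll: repaired %d illegal I- opening(s) in %s", total_repairs, path)
    return sentences


def write_conll(sentences: Iterable[BIOTaggedSentence], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sent in sentences:
            for tok, lab in zip(sent.tokens, sent.labels):
                fh.write(f"{tok}\t{lab}\n")
            fh.write("\n")


def spans_from_bio(
    labels: Sequence[str], tokens: Sequence[str] | None = None
) -> list[EntitySpan]:
    """Maximal entity spans of a valid BIO2 sequence, sorted by start."""
    validate_bio(labels)
    spans: list[EntitySpan] = []
    start = None
    etype = ""
    for i, lab in enumerate(labels):
        if lab.startswith("B-"):
            if start is not None:
                spans.append(_mk_span(start, i, etype, tokens))
            start, etype = i, lab[2:]
        elif lab == "O":
            if start is not None:
                spans.append(_mk_span(start, i, etype, tokens))
            start = None
    if start is not None:
        spans.append(_mk_span(start, len(labels), etype, tokens))
    return spans


def _mk_span(start: int, end: int, etype: str, tokens: Sequence[str] | None) -> EntitySpan:
    surface = " ".join(tokens[start:end]) if tokens is not None else ""
    return EntitySpan(start=start, end=end, entity_type=etype, surface=surface)


def bio_from_spans(spans: Sequence[EntitySpan], length: int) -> list[str]:
    """Inverse of :func:`spans_from_bio`; spans must not overlap."""
    labels = ["O"] * length
    for span in sorted(spans):
        if span.end > length:
            raise ValueError(f"span {span} exceeds length {length}")
        if any(labels[i] != "O" for i in range(span.start, span.end)):
            raise ValueError(f"overlapping span {span}")
        labels[span.start] = "B-" + span.entity_type
        for i in range(span.start + 1, span.end):
            labels[i] = "I-" + span.entity_type
    return labels


def normalize_surface(surface: str) -> str:
    """Case-fold and strip a surface form for lexicon lookups."""
    return unicodedata.normalize("NFKC", surface).strip().lower()
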