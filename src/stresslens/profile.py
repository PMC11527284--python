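"""Multi-dimensional stress profiling.

Extracted SEX/EDU/ORG mentions are mapped to user facets (gender, degree
level, institution tier), documents with two known facets are cross-
tabulated into mixed-label categories (e.g. "female doctoral"), and each
category receives a probability distribution over the five stress features,
estimated as normalized hit counts of the features' top words among the
category's tokens.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .corpus import EntitySpan, normalize_surface
from .topic_fusion import STRESS_FEATURES, StressFeatureMap

logger = logging.getLogger(__name__)

UNKNOWN = None

#: Surface -> facet value lexicons; editable, shipped as config in practice.
DEFAULT_SEX_LEXICON = {
    "male": "male", "man": "male", "男": "male",
    "female": "female", "woman": "female", "女": "female",
}
DEFAULT_EDU_LEXICON = {
    "master": "master", "master's": "master", "硕士": "master",
    "doctor": "doctor", "doctoral": "doctor", "phd": "doctor",
    "ph.d.": "doctor", "博士": "doctor",
}


@dataclass(frozen=True)
class UserFacets:
    post_id: str
    sex: str | None = None
    edu: str | None = None
    org_tier: str | None = None

    def get(self, name: str) -> str | None:
        return getattr(self, name)


def classify_org(surface: str, world_class_lexicon: Sequence[str]) -> str | None:
    """Binary institution tier: world_class iff the normalized surface is in
    the lexicon, otherwise non_top_tier; empty surface is unknown."""
    norm = normalize_surface(surface)
    if not norm:
        return UNKNOWN
    lex = {normalize_surface(s) for s in world_class_lexicon}
    return "world_class" if norm in lex else "non_top_tier"


def facets_from_entities(
    post_id: str,
    spans: Sequence[EntitySpan],
    sex_lexicon: Mapping[str, str] | None = None,
    edu_lexicon: Mapping[str, str] | None = None,
    world_class_lexicon: Sequence[str] = (),
) -> UserFacets:
    """Deterministic span -> facet mapping; conflicting evidence for a facet
    (e.g. both male and female surfaces) yields unknown, logged."""
    sex_lexicon = DEFAULT_SEX_LEXICON if sex_lexicon is None else sex_lexicon
    edu_lexicon = DEFAULT_EDU_LEXICON if edu_lexicon is None else edu_lexicon
    sex_lex = {normalize_surface(k): v for k, v in sex_lexicon.items()}
    edu_lex = {normalize_surface(k): v for k, v in edu_lexicon.items()}
    found: dict[str, set[str]] = {"sex": set(), "edu": set(), "org_tier": set()}
    for span in spans:
        surface = normalize_surface(span.surface)
        if span.entity_type == "SEX" and surface in sex_lex:
            found["sex"].add(sex_lex[surface])
        elif span.entity_type == "EDU" and surface in edu_lex:
            found["edu"].add(edu_lex[surface])
        elif span.entity_type == "ORG":
            tier = classify_org(span.surface, world_class_lexicon)
            if tier is not None:
                found["org_tier"].add(tier)
    values: dict[str, str | None] = {}
    for facet, vals in found.items():
        if len(vals) == 1:
            values[facet] = vals.pop()
        else:
            if len(vals) > 1:
                logger.warning("post %s: conflicting %s evidence %s", post_id, facet, sorted(vals))
            values[facet] = UNKNOWN
    return UserFacets(post_id=post_id, **values)


_FACET_VALUES = {
    "sex": ("male", "female"),
    "edu": ("master", "doctor"),
    "org_tier": ("world_class", "non_top_tier"),
}


def crosstab(
    facets: Sequence[UserFacets], dims: tuple[str, str]
) -> tuple[dict[tuple[str, str], list[UserFacets]], int]:
    """Partition docs with both facets known into the 4 mixed-label
    categories; returns (categories, number excluded as unknown)."""
    for d in dims:
        if d not in _FACET_VALUES:
            raise ValueError(f"unknown facet dimension {d!r}")
    categories: dict[tuple[str, str], list[UserFacets]] = {
        (a, b): [] for a in _FACET_VALUES[dims[0]] for b in _FACET_VALUES[dims[1]]
    }
    excluded = 0
    for uf in facets:
        key = (uf.get(dims[0]), uf.get(dims[1]))
        if key[0] is None or key[1] is None:
            excluded += 1
            continue
        categories[key].append(uf)
    if excluded:
        logger.info("crosstab: %d doc(s) excluded with unknown facets", excluded)
    return categories, excluded


@dataclass(frozen=True)
class ProfileRow:
    category: tuple[str, str]
    count: int
    feature_probs: dict[str, float]
    degenerate: bool = False  # no feature-word hits (or empty category)


@dataclass(frozen=True)
class ProfileTable:
    dims: tuple[str, str]
    rows: tuple[ProfileRow, ...] = field(default_factory=tuple)
    excluded: int = 0

    def to_frame(self) -> pd.DataFrame:
        """Tidy (category, feature, count, probability) table."""
        records = []
        for row in self.rows:
            for feat, prob in row.feature_probs.items():
                records.append(
                    {
                        "category": " ".join(row.category),
                        "feature": feat,
                        "count": row.count,
                        "probability": prob,
                        "degenerate": row.degenerate,
                    }
                )
        return pd.DataFrame(records)


def feature_word_probabilities(
    category: tuple[str, str],
    token_lists: Sequence[Sequence[str]],
    feature_map: StressFeatureMap,
    top_n: int = 10,
) -> ProfileRow:
    """Hit-count distribution over the five features for one category.

    hits(f) = occurrences of feature f's top-``top_n`` words among the
    category's tokens; probabilities normalize hits. No hits at all (or an
    empty category) gives a uniform row flagged degenerate.
    """
    features = list(feature_map.top_words.keys()) or list(STRESS_FEATURES)
    word_to_feature: dict[str, str] = {}
    for feat in features:
        for word, _ in feature_map.top_words[feat][:top_n]:
            word_to_feature.setdefault(word, feat)
    hits = {f: 0 for f in features}
    for tokens in token_lists:
        for tok in tokens:
            feat = word_to_feature.get(tok)
            if feat is not None:
                hits[feat] += 1
    total = sum(hits.values())
    if total == 0:
        probs = {f: 1.0 / len(features) for f in features}
        return ProfileRow(category=category, count=len(token_lists),
                          feature_probs=probs, degenerate=True)
    probs = {f: hits[f] / total for f in features}
    return ProfileRow(category=category, count=len(token_lists), feature_probs=probs)


def build_profile(
    facets: Sequence[UserFacets],
    tokens_by_post: Mapping[str, Sequence[str]],
    feature_map: StressFeatureMap,
    dims: tuple[str, str] = ("sex", "edu"),
    top_n: int = 10,
) -> ProfileTable:
    """Crosstab + per-category feature distributions in one call."""
    categories, excluded = crosstab(facets, dims)
    rows = []
    for cat in sorted(categories):
        members = categories[cat]
        token_lists = [tokens_by_post[uf.post_id] for uf in members]
        rows.append(feature_word_probabilities(cat, token_lists, feature_map, top_n))
    return ProfileTable(dims=dims, rows=tuple(rows), excluded=excluded)
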