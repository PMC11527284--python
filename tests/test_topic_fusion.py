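"""Topic model, topic vectors, cosine selection, fusion and merging."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from stresslens.corpus import TokenizedDoc, tokenize
from stresslens.embeddings import DocEmbedding, EmbeddingSequence, HashingTextEncoder
from stresslens.topic_fusion import (
    STRESS_FEATURES,
    GibbsLDA,
    TopicVector,
    assign_optimal_topic,
    auto_group_topics,
    cosine_similarity,
    fuse,
    merge_topics,
    perplexity,
    perplexity_from_matrices,
    select_topic_count,
    topic_vectors,
)


def _doc(post_id: str, tokens: list[str]) -> TokenizedDoc:
    return TokenizedDoc(post_id=post_id, tokens=tuple(tokens), sentence_bounds=((0, len(tokens)),))


@pytest.fixture(scope="module")
def tiny_corpus():
    return [
        _doc("a", ["x", "x", "y"]),
        _doc("b", ["y", "z", "z", "z"]),
        _doc("c", ["x", "z"]),
    ]


class TestGibbsLDA:
    def test_single_topic_degenerate(self, tiny_corpus):
        model = GibbsLDA(n_topics=1, n_iter=5, random_state=0).fit(tiny_corpus)
        assert all((z == 0).all() for z in model.assignments_)
        np.testing.assert_allclose(model.theta_, 1.0)

    def test_count_consistency_invariant(self, planted_topic_corpus):
        docs = planted_topic_corpus[0]
        model = GibbsLDA(n_topics=3, n_iter=20, random_state=2).fit(docs)
        total = sum(len(d) for d in docs)
        assert model.topic_word_counts_.sum() == total
        assert model.doc_topic_counts_.sum() == total
        np.testing.assert_array_equal(
            model.topic_word_counts_.sum(axis=1), model.topic_counts_
        )
        np.testing.assert_array_equal(
            model.doc_topic_counts_.sum(axis=0), model.topic_counts_
        )

    def test_theta_phi_rows_are_distributions(self, tiny_corpus):
        model = GibbsLDA(n_topics=2, n_iter=10, random_state=1).fit(tiny_corpus)
        np.testing.assert_allclose(model.theta_.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(model.phi_.sum(axis=1), 1.0, atol=1e-9)

    def test_alpha_defaults_to_50_over_K(self):
        assert GibbsLDA(n_topics=20).alpha_ == pytest.approx(2.5)
        assert GibbsLDA(n_topics=20, alpha=0.1).alpha_ == pytest.approx(0.1)

    def test_deterministic_given_seed(self, tiny_corpus):
        a = GibbsLDA(n_topics=2, n_iter=15, random_state=5).fit(tiny_corpus)
        b = GibbsLDA(n_topics=2, n_iter=15, random_state=5).fit(tiny_corpus)
        np.testing.assert_array_equal(a.topic_word_counts_, b.topic_word_counts_)

    def test_invalid_inputs(self, tiny_corpus):
        with pytest.raises(ValueError):
            GibbsLDA(n_topics=100, n_iter=1).fit(tiny_corpus)
        with pytest.raises(ValueError):
            GibbsLDA(n_topics=2, n_iter=0).fit(tiny_corpus)

    def test_planted_recovery_top_words(self, planted_topic_corpus):
        """Matched top-10 word overlap on the disjoint-block corpus."""
        docs, _, phi, _ = planted_topic_corpus
        model = GibbsLDA(n_topics=3, n_iter=200, random_state=3).fit(docs)
        inv = {v: w for w, v in model.vocab_.items()}
        true_top = [set(f"w{v:04d}" for v in np.argsort(-phi[k])[:10]) for k in range(3)]
        learned = [set(inv[v] for v in np.argsort(-model.phi_[k])[:10]) for k in range(3)]
        overlap = np.array([[len(a & b) for b in learned] for a in true_top])
        r, c = linear_sum_assignment(-overlap)
        assert overlap[r, c].sum() / 30 >= 0.8


class TestPerplexity:
    def test_uniform_model_gives_vocab_size(self):
        V = 7
        docs = [_doc("a", [f"w{i}" for i in range(V)])]
        vocab = {f"w{i}": i for i in range(V)}
        theta = np.full((1, 3), 1 / 3)
        phi = np.full((3, V), 1 / V)
        assert perplexity_from_matrices(theta, phi, docs, vocab) == pytest.approx(V)

    def test_heavy_smoothing_approaches_vocab_size(self):
        docs = [_doc("a", ["a", "a", "b"])]
        model = GibbsLDA(n_topics=1, beta=1e6, n_iter=2, random_state=0).fit(docs)
        assert perplexity(model, docs) == pytest.approx(2.0, rel=1e-3)

    def test_perplexity_at_least_one(self, planted_topic_corpus):
        docs = planted_topic_corpus[0]
        model = GibbsLDA(n_topics=3, n_iter=30, random_state=0).fit(docs[:100])
        assert perplexity(model, docs[100:150]) >= 1.0

    def test_oov_tokens_excluded(self, tiny_corpus):
        model = GibbsLDA(n_topics=2, n_iter=10, random_state=0).fit(tiny_corpus)
        value = perplexity(model, [_doc("d", ["x", "UNSEEN"])])
        assert np.isfinite(value)


class TestSelectTopicCount:
    def test_single_candidate_returned(self, tiny_corpus):
        best, table = select_topic_count(tiny_corpus, [2], seeds_per_K=1, iters=5)
        assert best == 2 and len(table) == 1

    def test_table_has_finite_stats(self, planted_topic_corpus):
        docs = planted_topic_corpus[0][:100]
        _, table = select_topic_count(docs, [2, 3], seeds_per_K=2, iters=20, seed=1)
        assert table.shape[0] == 2
        assert np.isfinite(table["mean_perplexity"]).all()
        assert np.isfinite(table["var_perplexity"]).all()


class TestTopicVectors:
    def _embeddings(self, model_docs, vectors_by_token):
        out = {}
        for doc in model_docs:
            mat = np.stack([vectors_by_token[t] for t in doc.tokens])
            out[doc.post_id] = EmbeddingSequence(post_id=doc.post_id, vectors=mat)
        return out

    def test_single_topic_centroid_is_corpus_mean(self, tiny_corpus):
        model = GibbsLDA(n_topics=1, n_iter=5, random_state=0).fit(tiny_corpus)
        vecs = {"x": np.array([1.0, 0.0]), "y": np.array([0.0, 1.0]), "z": np.array([1.0, 1.0])}
        embeddings = self._embeddings(tiny_corpus, vecs)
        tvecs, doc_vecs = topic_vectors(model, embeddings)
        all_tokens = [vecs[t] for d in tiny_corpus for t in d.tokens]
        np.testing.assert_allclose(tvecs[0].vector, np.mean(all_tokens, axis=0))
        for v in doc_vecs.values():
            np.testing.assert_allclose(v, tvecs[0].vector)

    def test_disjoint_token_sets_give_their_centroids(self):
        docs = [_doc("a", ["p", "p"]), _doc("b", ["q", "q"])]
        model = GibbsLDA(n_topics=2, n_iter=1, random_state=1).fit(docs)
        # pin the assignments: topic 0 owns all p tokens, topic 1 all q
        model.assignments_ = [np.array([0, 0]), np.array([1, 1])]
        model.doc_topic_counts_ = np.array([[2, 0], [0, 2]])
        vecs = {"p": np.array([1.0, 0.0]), "q": np.array([0.0, 1.0])}
        tvecs, _ = topic_vectors(model, self._embeddings(docs, vecs))
        np.testing.assert_allclose(tvecs[0].vector, [1.0, 0.0])
        np.testing.assert_allclose(tvecs[1].vector, [0.0, 1.0])

    def test_doc_vector_matches_bruteforce_sum(self, planted_topic_corpus):
        docs = planted_topic_corpus[0][:40]
        model = GibbsLDA(n_topics=3, n_iter=30, random_state=4).fit(docs)
        encoder = HashingTextEncoder(dim=8, seed=1).fit()
        embeddings = encoder.encode_corpus(docs)
        tvecs, doc_vecs = topic_vectors(model, embeddings)
        theta = model.theta_
        for i, pid in enumerate(model.post_ids_):
            brute = np.zeros(8)
            for k in range(3):
                brute += theta[i, k] * tvecs[k].vector
            np.testing.assert_allclose(doc_vecs[pid], brute, atol=1e-10)


class TestCosineAndAssignment:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ((1, 0), (0, 1), 0.0),
            ((2, 0), (1, 0), 1.0),
            ((1, 1), (1, 0), 2**-0.5),
        ],
    )
    def test_analytic_values(self, a, b, expected):
        assert cosine_similarity(np.array(a, float), np.array(b, float)) == pytest.approx(
            expected, abs=1e-9
        )

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity(np.zeros(2), np.ones(2))

    def test_exact_match_selected(self):
        tvecs = {0: TopicVector(0, np.array([1.0, 0.0])), 1: TopicVector(1, np.array([0.0, 1.0]))}
        emb = DocEmbedding(post_id="d", vector=np.array([1.0, 0.0]))
        assert assign_optimal_topic(emb, tvecs) == 0

    def test_higher_cosine_wins(self):
        tvecs = {0: TopicVector(0, np.array([1.0, 0.0])), 1: TopicVector(1, np.array([0.0, 1.0]))}
        assert assign_optimal_topic(np.array([0.6, 0.8]), tvecs) == 1

    def test_tie_breaks_to_smaller_id(self):
        v = np.array([1.0, 1.0])
        tvecs = {0: TopicVector(0, v), 1: TopicVector(1, v.copy())}
        assert assign_optimal_topic(np.array([2.0, 2.0]), tvecs) == 0

    def test_invariant_under_positive_rescaling(self):
        rng = np.random.default_rng(2)
        tvecs = {k: TopicVector(k, rng.standard_normal(5)) for k in range(4)}
        d = rng.standard_normal(5)
        base = assign_optimal_topic(d, tvecs)
        scaled = {k: TopicVector(k, 3.7 * tv.vector) for k, tv in tvecs.items()}
        assert assign_optimal_topic(2.2 * d, scaled) == base


class TestFusion:
    def test_zero_topic_vector_is_identity(self):
        seq = EmbeddingSequence(post_id="p", vectors=np.arange(6.0).reshape(3, 2))
        fused = fuse(seq, TopicVector(0, np.zeros(2)))
        np.testing.assert_array_equal(fused.vectors, seq.vectors)

    def test_vector_addition(self):
        seq = EmbeddingSequence(post_id="p", vectors=np.array([[1.0, 2.0]]))
        fused = fuse(seq, TopicVector(1, np.array([3.0, 4.0])))
        np.testing.assert_array_equal(fused.vectors, [[4.0, 6.0]])
        assert fused.topic_id == 1

    def test_subtracting_topic_recovers_input(self):
        rng = np.random.default_rng(3)
        seq = EmbeddingSequence(post_id="p", vectors=rng.standard_normal((5, 4)))
        z = rng.standard_normal(4)
        fused = fuse(seq, TopicVector(2, z))
        np.testing.assert_allclose(fused.vectors - z, seq.vectors, atol=1e-12)

    def test_dimension_mismatch_rejected(self):
        seq = EmbeddingSequence(post_id="p", vectors=np.ones((2, 3)))
        with pytest.raises(ValueError):
            fuse(seq, TopicVector(0, np.ones(4)))


class TestMergeTopics:
    def test_singleton_groups_keep_own_ranking(self, tiny_corpus):
        model = GibbsLDA(n_topics=2, n_iter=20, random_state=1).fit(tiny_corpus)
        fmap = merge_topics(model, [{0}, {1}], ["f0", "f1"])
        inv = {v: w for w, v in model.vocab_.items()}
        for k, label in [(0, "f0"), (1, "f1")]:
            expected = [inv[v] for v in np.argsort(-model.phi_[k], kind="stable")]
            assert [w for w, _ in fmap.top_words[label]] == expected

    def test_probabilities_non_increasing(self, tiny_corpus):
        model = GibbsLDA(n_topics=2, n_iter=20, random_state=1).fit(tiny_corpus)
        fmap = merge_topics(model, [{0, 1}], ["all"])
        probs = [p for _, p in fmap.top_words["all"]]
        assert probs == sorted(probs, reverse=True)

    def test_merging_identical_topics_preserves_ranking(self):
        docs = [_doc(str(i), ["a", "b", "a"]) for i in range(4)]
        model = GibbsLDA(n_topics=2, n_iter=30, random_state=0).fit(docs)
        merged = merge_topics(model, [{0, 1}], ["m"])
        row = model.phi_.mean(axis=0)
        inv = {v: w for w, v in model.vocab_.items()}
        expected = [inv[v] for v in np.argsort(-row, kind="stable")]
        assert [w for w, _ in merged.top_words["m"]] == expected

    def test_split_topic_merge_recovers_true_top_words(self, planted_topic_corpus):
        """Fitting 6 topics on a 3-topic corpus oversplits; merging the two
        halves assigned to one true block recovers its top words."""
        docs, _, phi, _ = planted_topic_corpus
        model = GibbsLDA(n_topics=6, n_iter=150, random_state=5).fit(docs)
        # group learned topics by which true block dominates them
        block = 60 // 3
        inv = {v: w for w, v in model.vocab_.items()}
        groups: dict[int, set[int]] = {0: set(), 1: set(), 2: set()}
        for k in range(6):
            top = np.argsort(-model.phi_[k])[:5]
            votes = [int(inv[v][1:]) // block for v in top]
            groups[max(set(votes), key=votes.count)].add(k)
        nonempty = [g for g in (groups[0], groups[1], groups[2]) if g]
        labels = [f"g{j}" for j in range(len(nonempty))]
        fmap = merge_topics(
            model,
            nonempty + [set(range(6)) - set.union(*nonempty)] if set.union(*nonempty) != set(range(6)) else nonempty,
            labels + (["rest"] if set.union(*nonempty) != set(range(6)) else []),
        )
        # each merged feature's top-10 should overlap the matching true topic
        true_top = [set(f"w{v:04d}" for v in np.argsort(-phi[t])[:10]) for t in range(3)]
        hits = 0
        for label in labels:
            merged_top = {w for w, _ in fmap.top_words[label][:10]}
            hits = max(hits, max(len(merged_top & tt) for tt in true_top))
        assert hits >= 8

    def test_non_partition_rejected(self, tiny_corpus):
        model = GibbsLDA(n_topics=2, n_iter=5, random_state=0).fit(tiny_corpus)
        with pytest.raises(ValueError):
            merge_topics(model, [{0}], ["only"])
        with pytest.raises(ValueError):
            merge_topics(model, [{0, 1}, {1}], ["a", "b"])


class TestAutoGroup:
    def test_n_groups_equals_K_gives_singletons(self, tiny_corpus):
        model = GibbsLDA(n_topics=2, n_iter=10, random_state=0).fit(tiny_corpus)
        enc = HashingTextEncoder(dim=8, seed=0).fit()
        groups = auto_group_topics(model, enc.encode_corpus(tiny_corpus), 2)
        assert groups == [{0}, {1}]

    def test_one_group_contains_all(self, tiny_corpus):
        model = GibbsLDA(n_topics=2, n_iter=10, random_state=0).fit(tiny_corpus)
        enc = HashingTextEncoder(dim=8, seed=0).fit()
        assert auto_group_topics(model, enc.encode_corpus(tiny_corpus), 1) == [{0, 1}]

    def test_planted_clusters_recovered(self):
        """4 topics over 2 well-separated embedding clusters group 2+2."""
        docs = (
            [_doc(f"a{i}", ["p1", "p2"] * 10) for i in range(10)]
            + [_doc(f"b{i}", ["p3", "p4"] * 10) for i in range(10)]
            + [_doc(f"c{i}", ["q1", "q2"] * 10) for i in range(10)]
            + [_doc(f"d{i}", ["q3", "q4"] * 10) for i in range(10)]
        )
        model = GibbsLDA(n_topics=4, n_iter=100, random_state=2).fit(docs)
        base = {
            "p1": [1, 0], "p2": [1, 0.1], "p3": [1, -0.1], "p4": [0.9, 0],
            "q1": [0, 1], "q2": [0.1, 1], "q3": [-0.1, 1], "q4": [0, 0.9],
        }
        embeddings = {
            d.post_id: EmbeddingSequence(
                post_id=d.post_id, vectors=np.array([base[t] for t in d.tokens], float)
            )
            for d in docs
        }
        groups = auto_group_topics(model, embeddings, 2)
        # topics dominated by p-words should separate from q-word topics
        phi = model.phi_
        p_cols = [model.vocab_[w] for w in ("p1", "p2", "p3", "p4") if w in model.vocab_]
        p_topic = {k for k in range(4) if phi[k, p_cols].sum() > 0.5}
        assert p_topic in (set(groups[0]), set(groups[1]))
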