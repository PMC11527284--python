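# Methods

This note documents the models, estimators and numerical choices behind
`stresslens`, what the synthetic generators do and do not emulate, and the
known limitations.

## Corpus model and annotation conventions

Documents are short social-media posts. Token indexing is 0-based with
half-open spans throughout. Entity annotation uses strict BIO2 (every entity
opens with `B-TYPE`); illegal `I-` openings in hand-annotated input are
repaired to `B-` by default (a logged, reversible normalization) with a
strict mode that fails instead. CoNLL reading supports a tag-projection
option that maps any entity type outside a kept set to `O`, the usual way of
reusing public corpora that carry richer tag sets than the task needs.
Character-level tokenization is the default because the target texts are
CJK; whitespace mode serves the synthetic corpora, and a `segmenter` mode
delegates to jieba when that optional package is importable. The cohort
filter compiles its regexes eagerly so configuration errors surface at load
time, not per post.

## Token encoder

Downstream computations need per-token vectors that are (a) deterministic
given a seed and (b) *dynamic* — the same token at different positions or in
different sentences must map to different vectors. The built-in
`HashingTextEncoder` meets the contract offline: each vector is the sum of a
token embedding drawn from a generator keyed by a blake2b hash of the token
(pure integer hashing before any float conversion, hence platform-stable), a
sinusoidal position embedding scaled to 0.1 so token identity dominates, and
a per-sentence segment vector scaled to 0.05. Default dimension is 64 —
large enough for ~hundreds of synthetic types to be near-orthogonal, small
enough to keep the tagger fast; a pretrained transformer encoder (d = 768)
can be substituted wherever an encoder is accepted, since nothing downstream
depends on more than the contract. Documents beyond `max_seq_len` (default
256) are truncated with a warning; posts in this domain are short, so
truncation is preferred over window splitting.

The document embedding is the arithmetic mean of token vectors — exactly
permutation-invariant and linear, both property-tested.

## Topic model and fusion

The topic model is standard LDA fit by collapsed Gibbs sampling over token
identities: per-token conditionals
p(z = k) ∝ (n_ik + α)(n_kw + β)/(n_k + Vβ), with symmetric priors defaulting
to α = 50/K and β = 0.01. Collapsed Gibbs was chosen over variational
inference for implementational transparency: the count matrices admit exact
invariants (row/column sums equal corpus token totals after every sweep)
that the tests assert. The inner sweep is a numba-compiled kernel seeded
explicitly, so fits are deterministic given `random_state`; 200 sweeps
suffice on the planted benchmarks. Point estimates are the usual smoothed
posteriors φ̂_kw = (n_kw + β)/(n_k + Vβ) and θ̂_ik = (n_ik + α)/(N_i + Kα).

Embeddings enter through topic-vector construction, not through the sampler:
LDA is defined on discrete counts, and this split preserves both components'
semantics. Topic k's embedding-space vector t⃗_k is the centroid of the token
vectors Gibbs assigned to k (a topic with no tokens gets a zero vector and a
warning); a document's topic-space vector is the θ̂-weighted combination
z⃗_i = Σ_k θ̂_ik t⃗_k. The *optimal* topic of a document minimizes cosine
distance — equivalently maximizes cosine similarity — between t⃗_k and the
document's mean embedding, with ties and zero topic vectors resolved toward
the smallest topic id. Fusion adds the selected topic vector to every token
vector; it is exactly invertible, which the tests exploit.

### Held-out evaluation and topic-count selection

Perplexity is exp(−mean log Σ_k θ̂_ik φ̂_kw) over in-vocabulary tokens;
out-of-vocabulary tokens are excluded with a logged count. For held-out
documents θ̂ is re-estimated by folding in (Gibbs sweeps with φ̂ frozen).
Whole-document fold-in, however, barely penalizes topic counts that merely
sub-split true topics, because the fold-in sees the very tokens being
scored. Topic-count selection therefore uses **document completion**: θ̂ is
estimated on the even token positions only and perplexity measured on the
odd positions. Each candidate K is fit with several restarts on a seeded
80/20 document split; candidates whose mean perplexity lies within one joint
standard error of the best mean are treated as statistically tied, and among
ties the smallest K wins (the one-standard-error parsimony rule), with
across-restart variance breaking exact ties. On planted 3-topic corpora
this selects K = 3 against candidates {1, 3, 9} across all seed pairs
tried, whereas a pure arg-min (or a variance-first tie-break) intermittently
selects the over-split K = 9.

### Merging topics into stress features

The five stress features — research, employment, affection, financial,
other — are unions of topics. A feature's word distribution is the mean of
its member topics' φ̂ rows, re-ranked. The reference grouping of 20 topics
into the five features ships as a config default for K = 20; for any other
corpus `auto_group_topics` provides a reproducible replacement for what is
otherwise a manual judgement: agglomerative clustering (average linkage,
cosine metric) of the topic vectors, with user-editable labels.

## Sentiment split

The sentiment head is deliberately minimal — a logistic decision over
mean-pooled fused token vectors — because its role in the pipeline is to
exercise the fused representation and stratify the corpus, not to compete on
sentiment benchmarks. It is trained by full-batch Adam (lr 0.1, 300 epochs)
on the logistic loss, deterministic given its seed; inverse-frequency class
weights are available (off by default) for the ~88/12 negative/positive
imbalance this domain exhibits. `split_corpus` partitions posts exactly by
predicted label; the negative side is the stress document set DT consumed by
the stress topic model and the profiler.

## Entity tagger

The recurrence is the peephole LSTM variant — input and forget gates read
c_{t−1}, the output gate reads c_t — implemented exactly as specified, with
full peephole weight matrices; a config switch zeroes and freezes them for
the standard no-peephole cell. Forward and backward hidden states (shared
hidden size H, default 200) are concatenated per position and projected
linearly to per-label emission scores P ∈ R^{N×k}, k = 7 for BIO2 over
SEX/EDU/ORG. The linear-chain CRF uses a (k+2)×(k+2) transition matrix with
explicit START and STOP states; only the structurally meaningful entries
(START→label, label→label, label→STOP) are ever read, so the unused entries
stay at zero with zero gradients. Training minimizes the sequence NLL
(log-partition by the forward algorithm in log space, minus the gold path
score) with Adam; the `use_crf=False` ablation replaces the CRF by
per-position softmax cross-entropy and argmax decoding. Viterbi backtracking
resolves ties toward the smallest label index.

All gradients are hand-derived numpy (no autodiff framework): backprop
through the peephole cell includes the W_co path from the output gate into
dc_t and the W_ci/W_cf paths into dc_{t−1}, and the CRF gradient is
expected-minus-observed sufficient statistics from forward–backward
marginals. Both are verified against central finite differences in the test
suite, and the decoder and partition function against exhaustive path
enumeration on small instances. Dropout (inverted, default 0.5) applies to
the BiLSTM output rows during training. Batches are gradient-accumulation
groups over variable-length sentences — semantically identical to padded
tensors with masking (padded positions would contribute nothing) and much
simpler in numpy. Sentences beyond `max_seq_len` are truncated, and
predictions are padded back with `O` so output length always matches input.

Defaults mirror the reference configuration (hidden 200, lr 2e-5, batch 64,
dropout 0.5, window 256). The 2e-5 rate is a fine-tuning rate; the synthetic
recovery experiments train small nets from random initialization and
therefore pass their own hyperparameters (hidden 50, lr 0.01, 3 epochs,
dropout 0.1, 32-dimensional embeddings) — chosen once for the benchmark, with
forget-gate biases initialized to 1 to keep early memory open.

Two-stage training follows the protocol of pretraining on ORG-only data and
continuing on the full three-type data: `fit(org_only)` then
`fit(full, warm_start=True)`, which preserves parameters and optimizer
state. Evaluation is entity-level exact-span micro precision/recall/F1,
overall and per type, with P = 0 by convention when nothing is predicted;
decoded label sequences are BIO2-repaired before span extraction so emitted
spans are always well-formed.

## Profiling

Facets are derived only from extracted entity spans plus editable lexicons:
gender surfaces, degree surfaces, and a world-class-institution list for the
binary ORG tier (normalized exact match; everything else is non-top-tier,
empty surfaces are unknown). Conflicting evidence for a facet (e.g. both
male and female surfaces in one post) yields *unknown*, logged — never a
silent choice. Cross-tabulation over sex×edu or edu×org_tier partitions the
documents with both facets known into four mixed-label categories and counts
the excluded unknowns explicitly.

"Probability of occurrence of the five feature words" is operationalized as
normalized token-hit counts: hits(f) is the number of tokens in a category
matching feature f's top-n words (n = 10 by default, matching the ten words
a feature's reference listing prints; a word appearing in several features
counts for the first), and the row is hits/Σhits. Categories with no hits
get a uniform row flagged degenerate rather than NaNs. The estimator is
scale-invariant under document duplication, which the tests assert.

## Synthetic data

The generators are pure functions of a seeded config — byte-identical output
per seed — and return their ground truth alongside the corpus:

- **Topic corpus**: the standard LDA generative process (θ ~ Dir(α_true),
  tokens from φ per assignment), with `topic_separation` placing that
  fraction of each topic's mass on its own disjoint vocabulary block.
  Defaults (V = 60, K = 3, 300 docs × 40 tokens, separation 1) are the
  separable regime the recovery benchmarks assume.
- **Sentiment corpus**: negative documents over-sample a negative-valence
  word block at rate 0.5 (positives symmetrically); class balance defaults
  to 88% negative, the imbalance typical of stress-filtered corpora.
- **NER corpus**: background sentences (Poisson lengths, mean 10 + 3) with
  mentions planted from SEX/EDU/ORG lexicons, multi-token institution names
  included, BIO2 labels emitted with the planting log; an ORG-only mode
  emulates first-stage training data.
- **Profile corpus**: each document draws a (sex, edu, org_tier) facet
  combination and its tokens mix feature words per a per-category mixture;
  the truth tables drive exact recovery tests.

What the generators deliberately do **not** emulate: natural-language
syntax, ambiguous or nested entity mentions, out-of-lexicon surface
variation, sarcasm/irony, platform artifacts (hashtags, emoji), or label
noise. Passing recovery tests therefore demonstrate that the estimators are
correct and well-conditioned — that the sampler finds planted topics, the
tagger learns plantable patterns, the profiler inverts known mixtures — not
that the pipeline attains any particular accuracy on real social-media
text, where entity recall and sentiment accuracy will be substantially
lower.

## Benchmark scales and runtime

The recovery experiments run at: 1,000 random CRF instances (N ≤ 6, k ≤ 5)
against exhaustive enumeration; 5 sampler restarts on the 300-document topic
corpus; 1,000 sentiment documents; 2,000/500 train/test sentences for the
tagger at hidden size 50; 2,000 profile documents; 150–200 posts for the
end-to-end determinism check. These sizes were chosen so the whole suite
completes in a few minutes on one CPU while leaving each statistical margin
wide (e.g. mixture recovery tolerance ±0.05 against an observed maximum
error below 0.02).

## Known limitations

- The encoder is a contract implementation, not a language model: fused
  vectors carry lexical identity, position and topic information but no
  learned semantics. Conclusions about real-text accuracy require plugging
  in a pretrained encoder.
- LDA fold-in uses a modest number of Gibbs sweeps (25) for θ̂ on held-out
  documents; very short documents get noisy θ̂, which the completion-based
  selection partially absorbs into its restart variance.
- The tagger trains sentence-by-sentence with gradient accumulation; on very
  large corpora a batched/vectorized implementation (or an autodiff backend)
  would be preferable.
- Embedding sequences are recomputed rather than cached on disk; at the
  scales this package targets the hash encoder is cheap enough that a cache
  is unnecessary.
- Facet extraction is lexicon-bound and single-valued per facet; it does not
  attempt coreference, hedged self-descriptions, or institutions referred to
  by paraphrase ("a top-2 school").
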