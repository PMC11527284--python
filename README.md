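# stresslens

Topic-fused stress-feature extraction and entity-based profiling for
social-media mental-health text.

Mental-health researchers increasingly mine social platforms for signals of
psychological stress in specific populations (here: postgraduate students,
whose posts mention advisors, theses, degrees and institutions). `stresslens`
implements that pipeline end to end as a tested, reusable Python package:

1. **Cohort filtering** — regex-based identification of posts written by the
   target population (first-person degree statements, advisor/research-group
   mentions).
2. **Embedding–topic fusion** — a deterministic token encoder provides
   *dynamic* per-token vectors w⃗_ij (the same token gets different vectors at
   different positions); a latent topic model fit by collapsed Gibbs sampling
   provides document–topic weights θ_i and topic–word distributions φ_k. Each
   topic k receives an embedding-space vector t⃗_k (the centroid of token
   vectors assigned to it), a document's topic vector is z⃗_i = Σ_k θ̂_ik t⃗_k,
   its *optimal* topic maximizes cos(d⃗_i, t⃗_k) against the mean embedding
   d⃗_i = (Σ_j w⃗_ij)/N_i, and fusion adds that topic vector to every token
   vector.
3. **Sentiment split** — a logistic head over mean-pooled fused vectors
   partitions the corpus; the negative half is the *stress document set* DT
   on which stress topics are modelled and merged into five stress features
   (research, employment, affection, financial, other).
4. **Entity tagging** — a from-scratch peephole BiLSTM-CRF (numpy, hand-derived
   gradients) tags SEX/EDU/ORG mentions in BIO2. The CRF scores a label
   sequence as score(y) = Σ_j B[y_j, y_{j+1}] + Σ_j P[j, y_j] with START/STOP
   transitions; training minimizes the negative log-likelihood via the forward
   algorithm and decoding uses Viterbi.
5. **Profiling** — extracted mentions become user facets (gender, degree
   level, institution tier); documents with two known facets are
   cross-tabulated into mixed-label categories and each category gets a
   probability distribution over the five stress features from normalized
   feature-word hit counts.

Real crawled corpora are private and platform-bound, so the package ships
seeded synthetic generators with planted ground truth (topic structure,
sentiment labels, entity spans, facet mixtures) that exercise every stage and
make all recovery claims testable.

## Worked example

```python
from stresslens import (
    GeneratorConfig, GibbsLDA, HashingTextEncoder,
    generate_topic_corpus, select_topic_count, fuse_corpus,
)

docs, true_theta, true_phi, _ = generate_topic_corpus(GeneratorConfig(seed=42))
model = GibbsLDA(n_topics=3, n_iter=200, random_state=0).fit(docs)
print("alpha =", round(model.alpha_, 3), " beta =", model.beta)
best, table = select_topic_count(docs, [1, 3, 9], seeds_per_K=2, iters=100, seed=0)
print(table.to_string(index=False))
print("selected K =", best)
```

prints

```
alpha = 16.667  beta = 0.01
 K  mean_perplexity  var_perplexity  se_perplexity
 1        41.235660        0.000000       0.000000
 3        32.100947        0.000513       0.016018
 9        31.926968        0.141455       0.265946
selected K = 3
```

The symmetric priors default to α = 50/K and β = 0.01. The corpus was
generated from three topics with disjoint vocabulary blocks; K = 1 underfits
badly (perplexity 41.2 against ~32). K = 9 merely sub-splits the true topics:
its mean document-completion perplexity is statistically tied with K = 3
(difference 0.17 against a joint standard error of 0.28) but far less stable
across restarts, and the one-standard-error parsimony rule correctly selects
K = 3 — the number of planted topics.

A full run (encode → topics → sentiment split → NER → profile) on a JSONL
corpus:

```bash
stresslens synth ner --seed 1 --n 300 --out synth/          # NER training data
stresslens run --config config.yaml posts.jsonl rundir/
```

`rundir/` then contains the sentiment split (`posts_negative.jsonl` is the
stress set DT), the fitted model bundles, `feature_map.json` (stress features
with their top words), `entities.jsonl`, `profile.csv` (category × feature
probabilities) and a `manifest.json` with seeds, config hash and output
checksums; reruns with the same config and seed are byte-identical.

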