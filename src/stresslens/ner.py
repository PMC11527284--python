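"""BiLSTM-CRF sequence tagger for SEX/EDU/ORG entity mentions.

The recurrence is the peephole LSTM variant, whose input and forget gates
read the previous memory cell and whose output gate reads the current one:

    i_t = sigma(W_xi x_t + W_hi h_{t-1} + W_ci c_{t-1} + b_i)
    f_t = sigma(W_xf x_t + W_hf h_{t-1} + W_cf c_{t-1} + b_f)
    c_t = f_t * c_{t-1} + i_t * tanh(W_hc h_{t-1} + W_xc x_t + b_c)
    o_t = sigma(W_xo x_t + W_ho h_{t-1} + W_co c_t + b_o)
    h_t = o_t * tanh(c_t)

Forward and backward hidden states are concatenated per position and
projected to per-label emission scores P (N x k). A linear-chain CRF with
transition matrix B of shape (k+2) x (k+2) (k labels plus START and STOP)
scores a label sequence as

    score(y) = sum_j B[y_j, y_{j+1}] + sum_j P[j, y_j]

with the START->y_1 and y_N->STOP transitions included. Training minimizes
the CRF negative log-likelihood (log-partition by the forward algorithm);
decoding uses Viterbi. Everything is plain numpy with hand-derived
gradients; no autodiff framework is involved.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Iterable, Sequence

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .corpus import (
    BIOTaggedSentence,
    EntitySpan,
    TokenizedDoc,
    repair_bio,
    spans_from_bio,
)
from .embeddings import HashingTextEncoder

DEFAULT_ENTITY_TYPES = ("SEX", "EDU", "ORG")


def label_vocabulary(entity_types: Sequence[str] = DEFAULT_ENTITY_TYPES) -> list[str]:
    """BIO2 label set: O first, then B-/I- per type (k = 1 + 2*types)."""
    labels = ["O"]
    for t in entity_types:
        labels += [f"B-{t}", f"I-{t}"]
    return labels


# ---------------------------------------------------------------------------
# Peephole LSTM


@dataclass
class LSTMParams:
    """Gate weights/biases of one LSTM direction."""

    w_xi: np.ndarray
    w_hi: np.ndarray
    w_ci: np.ndarray
    b_i: np.ndarray
    w_xf: np.ndarray
    w_hf: np.ndarray
    w_cf: np.ndarray
    b_f: np.ndarray
    w_xo: np.ndarray
    w_ho: np.ndarray
    w_co: np.ndarray
    b_o: np.ndarray
    w_xc: np.ndarray
    w_hc: np.ndarray
    b_c: np.ndarray

    @property
    def hidden_dim(self) -> int:
        return self.b_i.shape[0]

    def items(self):
        for f in fields(self):
            yield f.name, getattr(self, f.name)


def init_lstm_params(d_in: int, hidden: int, rng: np.random.Generator,
                     peephole: bool = True) -> LSTMParams:
    def glorot(rows: int, cols: int) -> np.ndarray:
        limit = np.sqrt(6.0 / (rows + cols))
        return rng.uniform(-limit, limit, size=(rows, cols))

    z = np.zeros((hidden, hidden))
    return LSTMParams(
        w_xi=glorot(hidden, d_in), w_hi=glorot(hidden, hidden),
        w_ci=glorot(hidden, hidden) * 0.1 if peephole else z.copy(),
        b_i=np.zeros(hidden),
        w_xf=glorot(hidden, d_in), w_hf=glorot(hidden, hidden),
        w_cf=glorot(hidden, hidden) * 0.1 if peephole else z.copy(),
        b_f=np.ones(hidden),  # open forget gate at init
        w_xo=glorot(hidden, d_in), w_ho=glorot(hidden, hidden),
        w_co=glorot(hidden, hidden) * 0.1 if peephole else z.copy(),
        b_o=np.zeros(hidden),
        w_xc=glorot(hidden, d_in), w_hc=glorot(hidden, hidden),
        b_c=np.zeros(hidden),
    )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def lstm_step(
    params: LSTMParams, x_t: np.ndarray, h_prev: np.ndarray, c_prev: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """One peephole-LSTM step; returns (h_t, c_t)."""
    p = params
    i = _sigmoid(p.w_xi @ x_t + p.w_hi @ h_prev + p.w_ci @ c_prev + p.b_i)
    f = _sigmoid(p.w_xf @ x_t + p.w_hf @ h_prev + p.w_cf @ c_prev + p.b_f)
    g = np.tanh(p.w_hc @ h_prev + p.w_xc @ x_t + p.b_c)
    c = f * c_prev + i * g
    o = _sigmoid(p.w_xo @ x_t + p.w_ho @ h_prev + p.w_co @ c + p.b_o)
    h = o * np.tanh(c)
    return h, c


def _lstm_forward(p: LSTMParams, X: np.ndarray) -> tuple[np.ndarray, list[tuple]]:
    """Run the recurrence over a sentence, caching gate values for backprop."""
    n = X.shape[0]
    H = p.hidden_dim
    h = np.zeros(H)
    c = np.zeros(H)
    out = np.empty((n, H))
    caches: list[tuple] = []
    for t in range(n):
        x = X[t]
        i = _sigmoid(p.w_xi @ x + p.w_hi @ h + p.w_ci @ c + p.b_i)
        f = _sigmoid(p.w_xf @ x + p.w_hf @ h + p.w_cf @ c + p.b_f)
        g = np.tanh(p.w_hc @ h + p.w_xc @ x + p.b_c)
        c_new = f * c + i * g
        o = _sigmoid(p.w_xo @ x + p.w_ho @ h + p.w_co @ c_new + p.b_o)
        tc = np.tanh(c_new)
        h_new = o * tc
        caches.append((x, h, c, i, f, g, c_new, o, tc))
        h, c = h_new, c_new
        out[t] = h_new
    return out, caches


def _lstm_backward(
    p: LSTMParams, caches: list[tuple], dH: np.ndarray
) -> dict[str, np.ndarray]:
    """Backpropagate dLoss/dh_t through the cached recurrence.

    Gradients follow the chain rule through each gate, including the
    peephole paths: the output gate reads c_t, so part of dc_t arrives via
    W_co; the input/forget gates read c_{t-1}, contributing to dc_{t-1}.
    """
    grads = {name: np.zeros_like(arr) for name, arr in p.items()}
    H = p.hidden_dim
    dh_next = np.zeros(H)
    dc_next = np.zeros(H)
    for t in range(len(caches) - 1, -1, -1):
        x, h_prev, c_prev, i, f, g, c, o, tc = caches[t]
        dh = dH[t] + dh_next
        do_pre = dh * tc * o * (1.0 - o)
        dc = dc_next + dh * o * (1.0 - tc * tc) + p.w_co.T @ do_pre
        di_pre = dc * g * i * (1.0 - i)
        df_pre = dc * c_prev * f * (1.0 - f)
        dg_pre = dc * i * (1.0 - g * g)
        dc_next = dc * f + p.w_ci.T @ di_pre + p.w_cf.T @ df_pre
        dh_next = (
            p.w_hi.T @ di_pre + p.w_hf.T @ df_pre + p.w_ho.T @ do_pre + p.w_hc.T @ dg_pre
        )
        grads["w_xi"] += np.outer(di_pre, x)
        grads["w_hi"] += np.outer(di_pre, h_prev)
        grads["w_ci"] += np.outer(di_pre, c_prev)
        grads["b_i"] += di_pre
        grads["w_xf"] += np.outer(df_pre, x)
        grads["w_hf"] += np.outer(df_pre, h_prev)
        grads["w_cf"] += np.outer(df_pre, c_prev)
        grads["b_f"] += df_pre
        grads["w_xo"] += np.outer(do_pre, x)
        grads["w_ho"] += np.outer(do_pre, h_prev)
        grads["w_co"] += np.outer(do_pre, c)
        grads["b_o"] += do_pre
        grads["w_xc"] += np.outer(dg_pre, x)
        grads["w_hc"] += np.outer(dg_pre, h_prev)
        grads["b_c"] += dg_pre
    return grads


def bilstm_encode(fwd: LSTMParams, bwd: LSTMParams, X: np.ndarray) -> np.ndarray:
    """Row t = [left-to-right h_t ; right-to-left h_t], shape (N, 2H)."""
    if X.shape[0] == 0:
        raise ValueError("empty sequence")
    if fwd.hidden_dim != bwd.hidden_dim:
        raise ValueError("directions must share the hidden dimension")
    Hf, _ = _lstm_forward(fwd, X)
    Hb, _ = _lstm_forward(bwd, X[::-1])
    return np.concatenate([Hf, Hb[::-1]], axis=1)


# ---------------------------------------------------------------------------
# Linear-chain CRF (array-level; START = k, STOP = k + 1)


@dataclass(frozen=True)
class TagSequence:
    y: tuple[int, ...]
    score: float


def _check_crf(B: np.ndarray, P: np.ndarray) -> int:
    k = P.shape[1]
    if B.shape != (k + 2, k + 2):
        raise ValueError(f"transition matrix must be ({k+2},{k+2}), got {B.shape}")
    return k


def crf_score(B: np.ndarray, P: np.ndarray, y: Sequence[int]) -> float:
    """Path score: START->y_1->...->y_N->STOP transitions plus emissions."""
    k = _check_crf(B, P)
    n = P.shape[0]
    if len(y) != n:
        raise ValueError("label sequence length mismatch")
    if any(not 0 <= lab < k for lab in y):
        raise ValueError("label index out of range")
    start, stop = k, k + 1
    s = B[start, y[0]] + P[0, y[0]]
    for j in range(1, n):
        s += B[y[j - 1], y[j]] + P[j, y[j]]
    s += B[y[n - 1], stop]
    return float(s)


def crf_log_partition(B: np.ndarray, P: np.ndarray) -> float:
    """log sum over all k^N paths of exp(score), by the forward algorithm."""
    k = _check_crf(B, P)
    start, stop = k, k + 1
    log_alpha = B[start, :k] + P[0]
    for j in range(1, P.shape[0]):
        log_alpha = logsumexp(log_alpha[:, None] + B[:k, :k], axis=0) + P[j]
    return float(logsumexp(log_alpha + B[:k, stop]))


def viterbi_decode(B: np.ndarray, P: np.ndarray) -> TagSequence:
    """Highest-scoring label sequence; ties resolve to the smallest label
    index at each backtracking step (argmax returns the first maximum)."""
    k = _check_crf(B, P)
    n = P.shape[0]
    start, stop = k, k + 1
    delta = B[start, :k] + P[0]
    back = np.zeros((n, k), dtype=int)
    for j in range(1, n):
        cand = delta[:, None] + B[:k, :k]
        back[j] = np.argmax(cand, axis=0)
        delta = cand[back[j], np.arange(k)] + P[j]
    final = delta + B[:k, stop]
    last = int(np.argmax(final))
    y = [last]
    for j in range(n - 1, 0, -1):
        y.append(int(back[j, y[-1]]))
    y.reverse()
    return TagSequence(y=tuple(y), score=float(final[last]))


def crf_marginals(B: np.ndarray, P: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Posterior label marginals (N,k) and expected transition counts
    ((k+2),(k+2)), the gradient of the log-partition in (P, B)."""
    k = _check_crf(B, P)
    n = P.shape[0]
    start, stop = k, k + 1
    log_alpha = np.empty((n, k))
    log_alpha[0] = B[start, :k] + P[0]
    for j in range(1, n):
        log_alpha[j] = logsumexp(log_alpha[j - 1][:, None] + B[:k, :k], axis=0) + P[j]
    log_beta = np.empty((n, k))
    log_beta[n - 1] = B[:k, stop]
    for j in range(n - 2, -1, -1):
        log_beta[j] = logsumexp(B[:k, :k] + (P[j + 1] + log_beta[j + 1])[None, :], axis=1)
    log_z = logsumexp(log_alpha[n - 1] + B[:k, stop])
    unary = np.exp(log_alpha + log_beta - log_z)
    expected = np.zeros_like(B)
    expected[start, :k] = np.exp(B[start, :k] + P[0] + log_beta[0] - log_z)
    for j in range(n - 1):
        expected[:k, :k] += np.exp(
            log_alpha[j][:, None] + B[:k, :k] + (P[j + 1] + log_beta[j + 1])[None, :] - log_z
        )
    expected[:k, stop] = np.exp(log_alpha[n - 1] + B[:k, stop] - log_z)
    return unary, expected


def _observed_transitions(y: Sequence[int], k: int) -> np.ndarray:
    obs = np.zeros((k + 2, k + 2))
    start, stop = k, k + 1
    obs[start, y[0]] += 1
    for j in range(1, len(y)):
        obs[y[j - 1], y[j]] += 1
    obs[y[-1], stop] += 1
    return obs


# ---------------------------------------------------------------------------
# Tagger estimator


class BiLSTMCRFTagger(BaseEstimator):
    """Sequence tagger: hash-encoded tokens -> BiLSTM -> CRF (or softmax).

    Defaults mirror the reference configuration (hidden 200, lr 2e-5,
    batch 64, dropout 0.5, window 256); recovery experiments on small
    synthetic corpora typically pass a larger lr and smaller hidden size.
    ``use_crf=False`` replaces the CRF by per-position argmax over softmax
    emissions — the ablation baseline.
    """

    def __init__(
        self,
        hidden_dim: int = 200,
        lr: float = 2e-5,
        epochs: int = 5,
        batch_size: int = 64,
        dropout: float = 0.5,
        peephole: bool = True,
        use_crf: bool = True,
        entity_types: Sequence[str] = DEFAULT_ENTITY_TYPES,
        embedding_dim: int = 32,
        max_seq_len: int = 256,
        seed: int = 0,
    ):
        self.hidden_dim = hidden_dim
        self.lr = lr
        self.epochs = epochs
        self.batch_size = batch_size
        self.dropout = dropout
        self.peephole = peephole
        self.use_crf = use_crf
        self.entity_types = tuple(entity_types)
        self.embedding_dim = embedding_dim
        self.max_seq_len = max_seq_len
        self.seed = seed

    # -- parameter plumbing

    def _init_state(self) -> None:
        rng = np.random.default_rng(self.seed)
        d, H = self.embedding_dim, self.hidden_dim
        k = len(self.labels_)
        self.fwd_ = init_lstm_params(d, H, rng, self.peephole)
        self.bwd_ = init_lstm_params(d, H, rng, self.peephole)
        limit = np.sqrt(6.0 / (2 * H + k))
        self.w_emit_ = rng.uniform(-limit, limit, size=(2 * H, k))
        self.b_emit_ = np.zeros(k)
        self.transitions_ = np.zeros((k + 2, k + 2))
        self._adam_m = {key: np.zeros_like(arr) for key, arr in self._param_items()}
        self._adam_v = {key: np.zeros_like(arr) for key, arr in self._param_items()}
        self._adam_t = 0

    def _param_items(self) -> list[tuple[str, np.ndarray]]:
        items = [(f"fwd.{n}", a) for n, a in self.fwd_.items()]
        items += [(f"bwd.{n}", a) for n, a in self.bwd_.items()]
        items += [("w_emit", self.w_emit_), ("b_emit", self.b_emit_)]
        if self.use_crf:
            items.append(("transitions", self.transitions_))
        return items

    def _adam_step(self, grads: dict[str, np.ndarray]) -> None:
        self._adam_t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        t = self._adam_t
        for key, arr in self._param_items():
            g = grads[key]
            if not self.peephole and key.split(".")[-1] in ("w_ci", "w_cf", "w_co"):
                continue
            m = self._adam_m[key] = b1 * self._adam_m[key] + (1 - b1) * g
            v = self._adam_v[key] = b2 * self._adam_v[key] + (1 - b2) * g * g
            arr -= self.lr * (m / (1 - b1**t)) / (np.sqrt(v / (1 - b2**t)) + eps)

    # -- per-sentence computation

    def _embed(self, tokens: Sequence[str]) -> np.ndarray:
        tokens = tokens[: self.max_seq_len]
        doc = TokenizedDoc(
            post_id="", tokens=tuple(tokens), sentence_bounds=((0, len(tokens)),)
        )
        return self.encoder_.encode(doc).vectors

    def _sentence_loss_grads(
        self, X: np.ndarray, y: Sequence[int], mask: np.ndarray | None
    ) -> tuple[float, dict[str, np.ndarray]]:
        k = len(self.labels_)
        Hf, cf = _lstm_forward(self.fwd_, X)
        Hb, cb = _lstm_forward(self.bwd_, X[::-1])
        Hmat = np.concatenate([Hf, Hb[::-1]], axis=1)
        Hd = Hmat * mask if mask is not None else Hmat
        P = Hd @ self.w_emit_ + self.b_emit_
        if self.use_crf:
            B = self.transitions_
            log_z = crf_log_partition(B, P)
            gold = crf_score(B, P, y)
            loss = log_z - gold
            unary, expected = crf_marginals(B, P)
            dP = unary.copy()
            dP[np.arange(len(y)), list(y)] -= 1.0
            dB = expected - _observed_transitions(y, k)
        else:
            shifted = P - P.max(axis=1, keepdims=True)
            probs = np.exp(shifted)
            probs /= probs.sum(axis=1, keepdims=True)
            loss = -float(np.sum(np.log(probs[np.arange(len(y)), list(y)] + 1e-300)))
            dP = probs.copy()
            dP[np.arange(len(y)), list(y)] -= 1.0
            dB = None
        dw_emit = Hd.T @ dP
        db_emit = dP.sum(axis=0)
        dHd = dP @ self.w_emit_.T
        dH = dHd * mask if mask is not None else dHd
        H = self.hidden_dim
        gf = _lstm_backward(self.fwd_, cf, dH[:, :H])
        gb = _lstm_backward(self.bwd_, cb, dH[::-1, H:])
        grads = {f"fwd.{n}": g for n, g in gf.items()}
        grads.update({f"bwd.{n}": g for n, g in gb.items()})
        grads["w_emit"] = dw_emit
        grads["b_emit"] = db_emit
        if dB is not None:
            grads["transitions"] = dB
        return float(loss), grads

    # -- public API

    def fit(
        self,
        sentences: Sequence[BIOTaggedSentence],
        dev: Sequence[BIOTaggedSentence] | None = None,
        warm_start: bool = False,
    ) -> "BiLSTMCRFTagger":
        """Minimize the mean sentence NLL with Adam.

        ``warm_start=True`` continues from the current parameters — the
        two-stage protocol (ORG-only pretraining, then all three entity
        types) is ``fit(org_only).fit(full, warm_start=True)``.
        """
        self.labels_ = label_vocabulary(self.entity_types)
        self.label_to_id_ = {lab: i for i, lab in enumerate(self.labels_)}
        for sent in sentences:
            for lab in sent.labels:
                if lab not in self.label_to_id_:
                    raise ValueError(f"label {lab!r} outside the configured tag set")
        if not (warm_start and hasattr(self, "fwd_")):
            self.encoder_ = HashingTextEncoder(
                dim=self.embedding_dim, seed=self.seed, max_seq_len=self.max_seq_len
            ).fit()
            self._init_state()
            self.loss_history_ = []
        rng = np.random.default_rng(self.seed + 1)
        data = [
            (self._embed(s.tokens), [self.label_to_id_[l] for l in s.labels[: self.max_seq_len]])
            for s in sentences
        ]
        for _ in range(self.epochs):
            order = rng.permutation(len(data))
            epoch_loss = 0.0
            for lo in range(0, len(order), self.batch_size):
                batch = order[lo : lo + self.batch_size]
                acc: dict[str, np.ndarray] = {}
                for idx in batch:
                    X, y = data[idx]
                    if self.dropout > 0:
                        mask = (
                            rng.random((X.shape[0], 2 * self.hidden_dim)) >= self.dropout
                        ) / (1.0 - self.dropout)
                    else:
                        mask = None
                    loss, grads = self._sentence_loss_grads(X, y, mask)
                    epoch_loss += loss
                    for key, g in grads.items():
                        if key in acc:
                            acc[key] += g
                        else:
                            acc[key] = g
                for key in acc:
                    acc[key] /= len(batch)
                self._adam_step(acc)
            self.loss_history_.append(epoch_loss / len(data))
            if dev is not None:
                report = evaluate_ner(self, dev)
                self.dev_f1_ = report.f1
        return self

    def predict_labels(self, tokens: Sequence[str]) -> tuple[str, ...]:
        X = self._embed(tokens)
        Hmat = bilstm_encode(self.fwd_, self.bwd_, X)
        P = Hmat @ self.w_emit_ + self.b_emit_
        if self.use_crf:
            y = viterbi_decode(self.transitions_, P).y
        else:
            y = tuple(int(i) for i in np.argmax(P, axis=1))
        labs = tuple(self.labels_[i] for i in y)
        # pad truncated tails with O so output length matches the input
        if len(labs) < len(tokens):
            labs = labs + ("O",) * (len(tokens) - len(labs))
        return labs

    def predict(
        self, sentences: Sequence[BIOTaggedSentence] | Sequence[Sequence[str]]
    ) -> list[tuple[str, ...]]:
        out = []
        for sent in sentences:
            tokens = sent.tokens if isinstance(sent, BIOTaggedSentence) else tuple(sent)
            out.append(self.predict_labels(tokens))
        return out


@dataclass(frozen=True)
class NERReport:
    """Entity-level exact-span micro scores, overall and per type."""

    precision: float
    recall: float
    f1: float
    per_type: dict[str, tuple[float, float, float]]
    support: dict[str, int]


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


def evaluate_ner(model: BiLSTMCRFTagger, test: Sequence[BIOTaggedSentence]) -> NERReport:
    """Exact-span micro precision/recall/F1; a predicted span counts only if
    its (type, start, end) all match a gold span."""
    tp: dict[str, int] = {}
    fp: dict[str, int] = {}
    fn: dict[str, int] = {}
    support: dict[str, int] = {}
    for sent, pred_labels in zip(test, model.predict(test)):
        gold = {(s.entity_type, s.start, s.end) for s in spans_from_bio(sent.labels)}
        repaired, _ = repair_bio(pred_labels)
        pred = {(s.entity_type, s.start, s.end) for s in spans_from_bio(repaired)}
        for item in gold:
            support[item[0]] = support.get(item[0], 0) + 1
        for item in pred & gold:
            tp[item[0]] = tp.get(item[0], 0) + 1
        for item in pred - gold:
            fp[item[0]] = fp.get(item[0], 0) + 1
        for item in gold - pred:
            fn[item[0]] = fn.get(item[0], 0) + 1
    types = sorted(set(tp) | set(fp) | set(fn) | set(support))
    per_type = {t: _prf(tp.get(t, 0), fp.get(t, 0), fn.get(t, 0)) for t in types}
    overall = _prf(sum(tp.values()), sum(fp.values()), sum(fn.values()))
    return NERReport(
        precision=overall[0], recall=overall[1], f1=overall[2],
        per_type=per_type, support=support,
    )


def train_ner(
    train: Sequence[BIOTaggedSentence],
    dev: Sequence[BIOTaggedSentence] | None = None,
    **hyper,
) -> BiLSTMCRFTagger:
    """Convenience wrapper: construct and fit a tagger with ``hyper``."""
    return BiLSTMCRFTagger(**hyper).fit(train, dev=dev)


def extract_entities(
    model: BiLSTMCRFTagger, docs: Iterable[TokenizedDoc | Sequence[str]]
) -> list[list[EntitySpan]]:
    """Decode each document and return its entity spans (BIO2-consistent)."""
    out = []
    for doc in docs:
        tokens = doc.tokens if isinstance(doc, TokenizedDoc) else tuple(doc)
        labels, _ = repair_bio(model.predict_labels(tokens))
        out.append(spans_from_bio(labels, tokens))
    return out
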