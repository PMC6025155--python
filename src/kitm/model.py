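"""Labeled LDA trained with zero-order collapsed variational inference.

Topics are identified one-to-one with labels; each document's topic
support is restricted to its own label set, which is the model's defining
constraint and is enforced exactly (zero mass off-support, not epsilon).
Every token carries a variational distribution over its document's
allowed labels, updated from collapsed counts that exclude the token's
own mass (the zero-order update).  All updates are batch/vectorized and
deterministic given the seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class LabeledLdaDataset:
    docs: list[tuple[np.ndarray, frozenset[int]]]
    vocabulary: dict[str, int]
    label_names: dict[int, str]

    @property
    def n_docs(self) -> int:
        return len(self.docs)

    @property
    def n_labels(self) -> int:
        return len(self.label_names)

    @property
    def n_terms(self) -> int:
        return len(self.vocabulary)


def build_dataset(
    docs: Iterable[tuple[str, Sequence[str]]],
    labels: Mapping[str, set[str]] | Sequence[tuple[str, set[str]]],
) -> LabeledLdaDataset:
    """Integer-code a token stream plus per-document label sets.

    Documents lacking tokens or surviving labels are excluded and logged.
    Vocabulary and label ids are assigned in sorted order, so the coding
    is deterministic regardless of input order.
    """
    if not isinstance(labels, Mapping):
        labels = dict(labels)
    docs = list(docs)
    kept: list[tuple[str, Sequence[str], set[str]]] = []
    for doc_id, tokens in docs:
        doc_labels = labels.get(doc_id, set())
        if not tokens or not doc_labels:
            logger.info("dataset: excluding %r (tokens=%d labels=%d)",
                        doc_id, len(tokens), len(doc_labels))
            continue
        kept.append((doc_id, tokens, doc_labels))

    vocab_terms = sorted({t for _id, tokens, _l in kept for t in tokens})
    vocabulary = {t: i for i, t in enumerate(vocab_terms)}
    label_list = sorted({l for _id, _t, doc_labels in kept for l in doc_labels})
    label_ids = {l: i for i, l in enumerate(label_list)}
    coded = [
        (
            np.array([vocabulary[t] for t in tokens], dtype=np.int64),
            frozenset(label_ids[l] for l in doc_labels),
        )
        for _id, tokens, doc_labels in kept
    ]
    return LabeledLdaDataset(
        docs=coded,
        vocabulary=vocabulary,
        label_names={i: l for l, i in label_ids.items()},
    )


@dataclass
class KitmModel:
    topic_word: np.ndarray  # (K, V), rows sum to 1
    doc_topic: np.ndarray  # (D, K), rows sum to 1, zero off-support
    doc_allowed: np.ndarray  # (D, K) bool
    vocabulary: dict[str, int]
    label_names: dict[int, str]
    alpha: float
    beta: float
    n_iterations: int
    seed: int

    @property
    def n_topics(self) -> int:
        return self.topic_word.shape[0]

    def to_json(self) -> str:
        return json.dumps(
            {
                "topic_word": self.topic_word.tolist(),
                "doc_topic": self.doc_topic.tolist(),
                "doc_allowed": self.doc_allowed.astype(int).tolist(),
                "vocabulary": self.vocabulary,
                "label_names": {str(k): v for k, v in self.label_names.items()},
                "alpha": self.alpha,
                "beta": self.beta,
                "n_iterations": self.n_iterations,
                "seed": self.seed,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "KitmModel":
        payload = json.loads(text)
        return cls(
            topic_word=np.array(payload["topic_word"], dtype=float),
            doc_topic=np.array(payload["doc_topic"], dtype=float),
            doc_allowed=np.array(payload["doc_allowed"], dtype=bool),
            vocabulary={k: int(v) for k, v in payload["vocabulary"].items()},
            label_names={int(k): v for k, v in payload["label_names"].items()},
            alpha=payload["alpha"],
            beta=payload["beta"],
            n_iterations=payload["n_iterations"],
            seed=payload["seed"],
        )


@dataclass
class PerplexityResult:
    value: float
    n_tokens: int
    base: float = 2.0
    n_oov_dropped: int = 0


def _flatten(dataset: LabeledLdaDataset):
    token_doc = np.concatenate(
        [np.full(len(w), d, dtype=np.int64) for d, (w, _a) in enumerate(dataset.docs)]
    ) if dataset.docs else np.zeros(0, dtype=np.int64)
    token_word = (
        np.concatenate([w for w, _a in dataset.docs])
        if dataset.docs
        else np.zeros(0, dtype=np.int64)
    )
    allowed = np.zeros((dataset.n_docs, dataset.n_labels), dtype=bool)
    for d, (_w, labs) in enumerate(dataset.docs):
        for k in labs:
            allowed[d, k] = True
    return token_doc, token_word, allowed


def _counts(gamma, token_doc, token_word, D, V):
    K = gamma.shape[1]
    n_wk = np.zeros((V, K))
    np.add.at(n_wk, token_word, gamma)
    n_dk = np.zeros((D, K))
    np.add.at(n_dk, token_doc, gamma)
    n_k = gamma.sum(axis=0)
    return n_wk, n_dk, n_k


def train_cvb0(
    dataset: LabeledLdaDataset,
    alpha: float = 0.1,
    beta: float = 0.01,
    n_iterations: int = 200,
    seed: int = 0,
) -> KitmModel:
    """Train labeled LDA with zero-order collapsed variational updates.

    gamma[i, k] ∝ (N_wk − γ_i + β)/(N_k − γ_i + Vβ) · (N_dk − γ_i + α),
    masked to the document's allowed labels and renormalized; counts are
    the summed variational masses.  ``n_iterations=0`` returns the model
    implied by the random initialization (still valid distributions).
    """
    if dataset.n_docs == 0:
        raise ValueError("empty dataset")
    D, K, V = dataset.n_docs, dataset.n_labels, dataset.n_terms
    token_doc, token_word, allowed = _flatten(dataset)
    rng = np.random.default_rng(seed)
    gamma = rng.random((len(token_word), K)) * allowed[token_doc]
    row_sums = gamma.sum(axis=1, keepdims=True)
    # a doc always has >= 1 allowed label, but guard against all-zero draws
    degenerate = row_sums[:, 0] == 0
    if degenerate.any():
        gamma[degenerate] = allowed[token_doc[degenerate]].astype(float)
        row_sums = gamma.sum(axis=1, keepdims=True)
    gamma /= row_sums

    for _ in range(n_iterations):
        n_wk, n_dk, n_k = _counts(gamma, token_doc, token_word, D, V)
        num = (
            (n_wk[token_word] - gamma + beta)
            / (n_k - gamma + V * beta)
            * (n_dk[token_doc] - gamma + alpha)
        )
        num *= allowed[token_doc]
        gamma = num / num.sum(axis=1, keepdims=True)

    n_wk, n_dk, n_k = _counts(gamma, token_doc, token_word, D, V)
    topic_word = ((n_wk + beta) / (n_k + V * beta)).T
    topic_word /= topic_word.sum(axis=1, keepdims=True)
    doc_topic = (n_dk + alpha) * allowed
    doc_topic /= doc_topic.sum(axis=1, keepdims=True)
    return KitmModel(
        topic_word=topic_word,
        doc_topic=doc_topic,
        doc_allowed=allowed,
        vocabulary=dict(dataset.vocabulary),
        label_names=dict(dataset.label_names),
        alpha=alpha,
        beta=beta,
        n_iterations=n_iterations,
        seed=seed,
    )


def infer_doc(
    model: KitmModel,
    tokens: Sequence[int],
    allowed_labels: Iterable[int],
    n_iterations: int = 50,
) -> np.ndarray:
    """Fold-in inference: CVB0 updates with topic_word frozen.

    Returns a distribution over all K topics with support restricted to
    ``allowed_labels``.  An empty token list yields the uniform
    distribution over the allowed labels.
    """
    K = model.n_topics
    allowed = np.zeros(K, dtype=bool)
    allowed[list(allowed_labels)] = True
    if not allowed.any():
        raise ValueError("allowed_labels must be non-empty")
    if len(tokens) == 0:
        theta = allowed / allowed.sum()
        return theta.astype(float)
    w = np.asarray(tokens, dtype=np.int64)
    phi_w = model.topic_word[:, w].T  # (n, K)
    gamma = phi_w * allowed
    gamma /= gamma.sum(axis=1, keepdims=True)
    for _ in range(n_iterations):
        n_k = gamma.sum(axis=0)
        num = phi_w * (n_k - gamma + model.alpha)
        num *= allowed
        gamma = num / num.sum(axis=1, keepdims=True)
    theta = (gamma.sum(axis=0) + model.alpha) * allowed
    return theta / theta.sum()


def perplexity(
    model: KitmModel,
    heldout: LabeledLdaDataset,
    base: float = 2.0,
    mode: str = "completion",
) -> PerplexityResult:
    """Held-out perplexity  PK = base^(−(1/N) Σ log_base q(x_i)).

    ``mode="completion"`` (default) folds in the first half of each
    held-out document and scores the second half; ``mode="full"`` folds in
    and scores every token (training-set style).  Held-out terms are
    remapped through the model vocabulary; out-of-vocabulary tokens are
    dropped and counted.  The value is base-invariant by construction.
    """
    if base <= 1.0:
        raise ValueError("base must be > 1")
    inv_vocab = {i: t for t, i in heldout.vocabulary.items()}
    model_label_ids = {name: i for i, name in model.label_names.items()}
    total_log = 0.0
    n_scored = 0
    n_oov = 0
    for w_ids, labs in heldout.docs:
        terms = [inv_vocab[i] for i in w_ids]
        mapped = [model.vocabulary[t] for t in terms if t in model.vocabulary]
        n_oov += len(terms) - len(mapped)
        if not mapped:
            continue
        # held-out label ids are remapped through label names
        labs = frozenset(
            model_label_ids[heldout.label_names[lab]]
            for lab in labs
            if heldout.label_names[lab] in model_label_ids
        )
        if not labs:
            continue
        if mode == "completion":
            half = (len(mapped) + 1) // 2
            fold, score = mapped[:half], mapped[half:]
        elif mode == "full":
            fold, score = mapped, mapped
        else:
            raise ValueError(f"unknown perplexity mode {mode!r}")
        if not score:
            continue
        theta = infer_doc(model, fold, labs)
        q = theta @ model.topic_word[:, score]
        total_log += float(np.log(q).sum())
        n_scored += len(score)
    if n_oov:
        logger.info("perplexity: dropped %d out-of-vocabulary tokens", n_oov)
    if n_scored == 0:
        raise ValueError("no scoreable tokens after OOV dropping")
    value = float(np.exp(-total_log / n_scored))
    return PerplexityResult(value=value, n_tokens=n_scored, base=base, n_oov_dropped=n_oov)


def training_perplexity(model: KitmModel, dataset: LabeledLdaDataset, base: float = 2.0) -> float:
    """Perplexity of the training data under the trained doc mixtures."""
    total_log = 0.0
    n = 0
    for d, (w_ids, _labs) in enumerate(dataset.docs):
        q = model.doc_topic[d] @ model.topic_word[:, w_ids]
        total_log += float(np.log(q).sum())
        n += len(w_ids)
    if n == 0:
        raise ValueError("empty dataset")
    return float(np.exp(-total_log / n))


def top_terms(model: KitmModel, k: int) -> list[list[str]]:
    """Per-topic top-k terms by probability, ties broken lexicographically;
    k beyond the vocabulary returns the full ranking."""
    inv_vocab = {i: t for t, i in model.vocabulary.items()}
    result = []
    for row in model.topic_word:
        ranked = sorted(
            range(len(row)), key=lambda i: (-row[i], inv_vocab[i])
        )
        result.append([inv_vocab[i] for i in ranked[:k]])
    return result
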