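"""Synthetic knowledge bases and labeled corpora with known structure.

The generator follows the labeled-LDA generative story: each post draws
its topic mixture over its own labels only, and words come from per-topic
distributions.  A configurable fraction of each topic's word mass sits on
knowledge-base synonyms, so the explicit-knowledge rate of the generated
corpus is controllable.  KB concepts are partitioned into contiguous
per-topic blocks and the IS_A slice is grown as one subtree per block, so
hierarchy neighbors share a topic (as drug-class subtrees do in real
terminologies).

Everything is deterministic given the seed: one ``numpy`` Generator per
call, no hidden global state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .corpus_model import Corpus, Post
from .knowledge_base import (
    Concept,
    ConceptRelation,
    KbConfig,
    KnowledgeBase,
    build_hierarchy,
)

_EXTRA_RELATION_LABELS = ("related_to", "may_treat", "associated_with")
_SEMANTIC_TYPES = ("drug", "condition", "procedure")


@dataclass
class SynthConfig:
    n_concepts: int = 30
    n_relations: int = 15
    hierarchy_depth: int = 3
    n_posts: int = 200
    n_topics: int = 5
    vocab_size: int = 200
    doc_length_mean: int = 50
    concept_term_fraction: float = 0.3
    label_topic_map: dict[str, int] | None = None
    dirichlet_alpha: float = 0.5
    dirichlet_beta: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_concepts",
            "n_posts",
            "n_topics",
            "vocab_size",
            "doc_length_mean",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_relations < 0 or self.hierarchy_depth < 0:
            raise ValueError("n_relations and hierarchy_depth must be >= 0")
        if not 0.0 <= self.concept_term_fraction <= 1.0:
            raise ValueError("concept_term_fraction must be in [0, 1]")
        if self.dirichlet_alpha <= 0 or self.dirichlet_beta <= 0:
            raise ValueError("Dirichlet hyperparameters must be positive")
        if self.label_topic_map is None:
            self.label_topic_map = {
                f"label{k:02d}": k for k in range(self.n_topics)
            }
        if not self.label_topic_map:
            raise ValueError("label_topic_map must not be empty")
        for label, topic in self.label_topic_map.items():
            if not 0 <= topic < self.n_topics:
                raise ValueError(f"label {label!r} maps to invalid topic {topic}")


@dataclass
class TrueParams:
    """Generating parameters, for model-recovery oracles."""

    topic_word: np.ndarray  # (K, V)
    doc_topic: list[np.ndarray]  # per-doc mixture over all K topics
    vocab: list[str]
    label_topic_map: dict[str, int]
    kb_terms: list[str]

    def to_json(self) -> str:
        return json.dumps(
            {
                "topic_word": self.topic_word.tolist(),
                "doc_topic": [d.tolist() for d in self.doc_topic],
                "vocab": self.vocab,
                "label_topic_map": self.label_topic_map,
                "kb_terms": self.kb_terms,
            }
        )


def concept_blocks(n_concepts: int, n_topics: int, chain_len: int = 0) -> list[int]:
    """Topic-block assignment for concepts, by code order.

    Evenly partitions concepts into ``n_topics`` contiguous blocks; the
    first ``chain_len + 1`` concepts are forced into block 0 so the
    depth-realizing IS_A chain stays within one block.
    """
    blocks = [min(i * n_topics // n_concepts, n_topics - 1) for i in range(n_concepts)]
    for i in range(min(chain_len + 1, n_concepts)):
        blocks[i] = 0
    return blocks


def generate_kb(config: SynthConfig) -> KnowledgeBase:
    """Random KB: an acyclic IS_A tree of the stated depth plus random
    non-hierarchical relations.  Deterministic given the seed."""
    if config.n_relations > config.n_concepts**2:
        raise ValueError("n_relations exceeds n_concepts^2: infeasible")
    rng = np.random.default_rng(config.seed)
    n = config.n_concepts
    codes = [f"K{i:04d}" for i in range(n)]
    kb = KnowledgeBase(name="synth", config=KbConfig())
    for i, code in enumerate(codes):
        term = f"kbterm{i:04d}"
        kb.add_concept(
            Concept(
                code=code,
                source="SYNTHVOC",
                preferred_name=term,
                semantic_type=_SEMANTIC_TYPES[i % len(_SEMANTIC_TYPES)],
            )
        )

    # The IS_A slice is a forest of one subtree per topic block, so
    # hierarchy neighborhoods are topic-coherent (as drug-class subtrees
    # are in real terminologies).  The first block carries a chain of
    # exactly max_depth so the stated depth is realized.
    max_depth = min(config.hierarchy_depth, n - 1)
    blocks = concept_blocks(n, config.n_topics, chain_len=max_depth)
    depth_of: dict[str, int] = {}
    block_members: dict[int, list[str]] = {}
    for i, code in enumerate(codes):
        members = block_members.setdefault(blocks[i], [])
        if not members:
            depth_of[code] = 0  # block root
        elif blocks[i] == 0 and depth_of[members[-1]] < max_depth:
            parent = members[-1]  # chain guaranteeing the stated depth
            kb.add_relation(ConceptRelation(code, frozenset({"IS_A"}), parent))
            depth_of[code] = depth_of[parent] + 1
        else:
            candidates = [c for c in members if depth_of[c] < max_depth]
            parent = (
                candidates[int(rng.integers(len(candidates)))]
                if candidates
                else members[0]
            )
            if max_depth > 0:
                kb.add_relation(
                    ConceptRelation(code, frozenset({"IS_A"}), parent)
                )
                depth_of[code] = depth_of[parent] + 1
            else:
                depth_of[code] = 0
        members.append(code)

    existing = {(r.source_code, r.target_code) for r in kb.relations}
    placed = 0
    attempts = 0
    while placed < config.n_relations and attempts < 50 * (config.n_relations + 1):
        attempts += 1
        a, b = rng.integers(n), rng.integers(n)
        if a == b:
            continue
        pair = (codes[int(a)], codes[int(b)])
        if pair in existing:
            continue
        existing.add(pair)
        label = _EXTRA_RELATION_LABELS[int(rng.integers(len(_EXTRA_RELATION_LABELS)))]
        kb.add_relation(ConceptRelation(pair[0], frozenset({label}), pair[1]))
        placed += 1

    kb.validate()
    kb.build_term_index()
    build_hierarchy(kb)
    return kb


def generate_corpus(
    config: SynthConfig, kb: KnowledgeBase
) -> tuple[Corpus, TrueParams]:
    """Generate a labeled corpus over ``kb``'s synonym vocabulary plus
    filler terms.

    Per-topic word distributions put exactly ``concept_term_fraction`` of
    their mass on KB synonyms, concentrated on the topic's own concept
    block; each post samples a topic mixture over its own labels' topics
    and draws tokens accordingly.
    """
    rng = np.random.default_rng(config.seed)
    K = config.n_topics
    label_names = sorted(config.label_topic_map)

    kb_terms = sorted(
        {syn.lower() for c in kb.concepts.values() for syn in c.synonyms if " " not in syn}
    )
    # same block assignment the KB generator used, so topic word mass is
    # aligned with the per-topic IS_A subtrees
    ordered_concepts = sorted(kb.concepts)
    max_depth = min(config.hierarchy_depth, len(ordered_concepts) - 1)
    blocks = concept_blocks(len(ordered_concepts), K, chain_len=max_depth)
    term_block: dict[str, int] = {}
    for idx, code in enumerate(ordered_concepts):
        for syn in kb.concepts[code].synonyms:
            if " " not in syn:
                term_block[syn.lower()] = blocks[idx]

    n_filler = max(0, config.vocab_size - len(kb_terms))
    filler_terms = [f"word{i:04d}" for i in range(n_filler)]
    vocab = kb_terms + filler_terms
    V = len(vocab)
    f = config.concept_term_fraction if kb_terms else 0.0
    if not filler_terms:
        f = 1.0 if kb_terms else 0.0

    topic_word = np.zeros((K, V))
    for k in range(K):
        if kb_terms:
            conc = np.array(
                [
                    config.dirichlet_beta
                    if term_block.get(t, k % K) == k
                    else config.dirichlet_beta * 0.05
                    for t in kb_terms
                ]
            )
            kb_part = rng.dirichlet(conc)
            topic_word[k, : len(kb_terms)] = f * kb_part
        if filler_terms:
            filler_part = rng.dirichlet(
                np.full(len(filler_terms), config.dirichlet_beta)
            )
            topic_word[k, len(kb_terms):] = (1.0 - f) * filler_part
        topic_word[k] /= topic_word[k].sum()

    posts: list[Post] = []
    doc_topics: list[np.ndarray] = []
    n_labels_max = min(2, len(label_names))
    for d in range(config.n_posts):
        n_lab = 1 + int(rng.integers(n_labels_max))
        chosen = sorted(
            rng.choice(len(label_names), size=n_lab, replace=False).tolist()
        )
        labels = [label_names[i] for i in chosen]
        topics = [config.label_topic_map[l] for l in labels]
        theta_local = rng.dirichlet(np.full(len(topics), config.dirichlet_alpha))
        theta = np.zeros(K)
        for t, w in zip(topics, theta_local):
            theta[t] += w
        length = max(1, int(rng.poisson(config.doc_length_mean)))
        zs = rng.choice(K, size=length, p=theta)
        words = [
            vocab[int(rng.choice(V, p=topic_word[z]))] for z in zs
        ]
        posts.append(
            Post(
                id=f"p{d:05d}",
                labels=set(labels),
                caption=f"synthetic post {d}",
                text=" ".join(words),
            )
        )
        doc_topics.append(theta)

    corpus = Corpus(posts=posts, metadata={"generator_seed": str(config.seed)})
    truth = TrueParams(
        topic_word=topic_word,
        doc_topic=doc_topics,
        vocab=vocab,
        label_topic_map=dict(config.label_topic_map),
        kb_terms=kb_terms,
    )
    return corpus, truth
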