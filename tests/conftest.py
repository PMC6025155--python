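from __future__ import annotations

import numpy as np
import pytest

from kitm.concept_encoding import encode_tokens
from kitm.corpus_model import load_example_posts
from kitm.knowledge_base import (
    Concept,
    ConceptRelation,
    KbConfig,
    KnowledgeBase,
    build_hierarchy,
)


def make_kb(
    concepts: dict[str, list[str]],
    relations: list[tuple[str, str, str]],
    name: str = "testkb",
    source: str = "TESTVOC",
    config: KbConfig | None = None,
    semantic_types: dict[str, str] | None = None,
    sources: dict[str, str] | None = None,
) -> KnowledgeBase:
    """Build a KnowledgeBase from {code: [synonyms...]} plus (s, label, t)
    triples; the first synonym is the preferred name."""
    kb = KnowledgeBase(name=name, config=config or KbConfig())
    for code, synonyms in concepts.items():
        kb.add_concept(
            Concept(
                code=code,
                source=(sources or {}).get(code, source),
                preferred_name=synonyms[0],
                synonyms=set(synonyms),
                semantic_type=(semantic_types or {}).get(code, "thing"),
            )
        )
    for s, label, t in relations:
        kb.add_relation(ConceptRelation(s, frozenset({label}), t))
    kb.validate()
    kb.build_term_index()
    return kb


def random_relation_kb(
    seed: int, n_nodes: int, n_extra: int = 10, p_isa: float = 0.7
) -> KnowledgeBase:
    """Random KB whose IS_A slice is an acyclic random tree plus random
    typed extra relations; used by graph-oracle tests."""
    rng = np.random.default_rng(seed)
    codes = [f"N{i:03d}" for i in range(n_nodes)]
    concepts = {code: [f"t{code.lower()}"] for code in codes}
    relations: list[tuple[str, str, str]] = []
    for i in range(1, n_nodes):
        parent = int(rng.integers(i))
        if rng.random() < p_isa:
            relations.append((codes[i], "IS_A", codes[parent]))
    for _ in range(n_extra):
        a, b = int(rng.integers(n_nodes)), int(rng.integers(n_nodes))
        if a != b:
            relations.append((codes[a], "related_to", codes[b]))
    return make_kb(concepts, relations, name=f"rand{seed}")


@pytest.fixture(scope="session")
def toy_kb():
    from importlib import resources

    from kitm.knowledge_base import load_toy_kb

    path = resources.files("kitm.data").joinpath("toy_kb.tsv")
    with resources.as_file(path) as p:
        return load_toy_kb(str(p))


@pytest.fixture(scope="session")
def table2_corpus():
    return load_example_posts()


@pytest.fixture(scope="session")
def chain_kb():
    """A -IS_A-> B -IS_A-> C plus one cross relation."""
    return make_kb(
        {"A": ["alpha"], "B": ["beta"], "C": ["gamma"], "D": ["delta"]},
        [("A", "IS_A", "B"), ("B", "IS_A", "C"), ("A", "may_treat", "D")],
    )


@pytest.fixture(scope="session")
def star_kb():
    """Hub H with three IS_A children."""
    return make_kb(
        {"H": ["hub"], "X": ["exx"], "Y": ["why"], "Z": ["zed"]},
        [("X", "IS_A", "H"), ("Y", "IS_A", "H"), ("Z", "IS_A", "H")],
    )


@pytest.fixture(scope="session")
def separated_dataset():
    """Two labels with disjoint vocabularies: the sharpest possible
    labeled-LDA fixture."""
    from kitm.model import build_dataset

    docs = []
    labels = {}
    vocab_a = ["apple", "avocado", "apricot"]
    vocab_b = ["banana", "blueberry", "bramble"]
    rng = np.random.default_rng(0)
    for i in range(30):
        which = i % 2
        words = list(rng.choice(vocab_a if which == 0 else vocab_b, size=12))
        doc_id = f"d{i:02d}"
        docs.append((doc_id, words))
        labels[doc_id] = {"fruit_a" if which == 0 else "fruit_b"}
    return build_dataset(docs, labels)
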