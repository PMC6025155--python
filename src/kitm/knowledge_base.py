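"""Terminology knowledge base: concepts, typed relations and the IS_A hierarchy.

The knowledge base abstracts a medical terminology compendium (concepts with
codes, synonyms, semantic types; typed inter-concept relations; an acyclic
IS_A hierarchy).  Two on-disk dialects are supported:

* a pipe-delimited RRF dialect following the MRCONSO/MRREL column
  conventions (configurable column indices), and
* a self-contained two-section TSV dialect (``CONCEPTS`` / ``RELATIONS``)
  documented in the README.

Relations are stored directed; graph traversal is undirected by default
(``KbConfig.directed_traversal`` switches it), because RRF sources carry
both directions while hand-written toy files usually carry one.
"""

from __future__ import annotations

import json
import logging
import math
import unicodedata
from collections import deque
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

UNREACHABLE = math.inf
HIERARCHY_LABEL = "IS_A"


class KbError(ValueError):
    """Malformed knowledge-base input."""


class CyclicHierarchyError(KbError):
    """The IS_A relation set contains a cycle."""

    def __init__(self, cycle: list[str]):
        self.cycle = cycle
        super().__init__("cyclic IS_A hierarchy: " + " -> ".join(cycle + cycle[:1]))


def normalize_term(term: str) -> str:
    """Canonical term form: lowercase, punctuation/symbols stripped,
    whitespace collapsed.

    This is the single normal form where free text and knowledge-base
    synonyms meet; the tokenizer lowercases and strips punctuation the
    same way.
    """
    chars = []
    for ch in term.lower():
        cat = unicodedata.category(ch)
        if cat.startswith("P") or cat.startswith("S"):
            chars.append(" ")
        else:
            chars.append(ch)
    return " ".join("".join(chars).split())


@dataclass
class Concept:
    """A coded terminology concept.

    ``attributes`` carries arbitrary key/value concept attributes and
    ``definitions`` free-text definitions; both may be empty.
    """

    code: str
    source: str
    preferred_name: str
    synonyms: set[str] = field(default_factory=set)
    semantic_type: str = ""
    attributes: dict[str, str] = field(default_factory=dict)
    definitions: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.code:
            raise KbError("concept code must be non-empty")
        self.synonyms = set(self.synonyms)
        self.synonyms.add(self.preferred_name)


@dataclass(frozen=True)
class ConceptRelation:
    """A directed, typed relation between two concept codes."""

    source_code: str
    relation_labels: frozenset[str]
    target_code: str

    def __post_init__(self) -> None:
        if not self.relation_labels:
            raise KbError(
                f"relation {self.source_code}->{self.target_code} has no labels"
            )
        object.__setattr__(self, "relation_labels", frozenset(self.relation_labels))


@dataclass
class KbConfig:
    """Column layout and traversal conventions.

    Defaults follow MRCONSO (CUI=0, SAB=11, STR=14) and MRREL
    (CUI1=0, REL=3, CUI2=4).  ``domain_axis`` selects what plays the role
    of a concept's domain: its source vocabulary or its semantic type.
    """

    conso_code_col: int = 0
    conso_source_col: int = 11
    conso_term_col: int = 14
    conso_semtype_col: int | None = None
    rel_source_col: int = 0
    rel_label_col: int = 3
    rel_target_col: int = 4
    hierarchy_label: str = HIERARCHY_LABEL
    directed_traversal: bool = False
    domain_axis: str = "source"  # or "semantic_type"


@dataclass
class KnowledgeBase:
    name: str
    concepts: dict[str, Concept] = field(default_factory=dict)
    relations: list[ConceptRelation] = field(default_factory=list)
    term_index: dict[str, set[str]] = field(default_factory=dict)
    config: KbConfig = field(default_factory=KbConfig)

    # -- construction ---------------------------------------------------

    def add_concept(self, concept: Concept) -> None:
        if concept.code in self.concepts:
            raise KbError(f"duplicate concept code {concept.code!r}")
        self.concepts[concept.code] = concept

    def add_relation(self, relation: ConceptRelation) -> None:
        self.relations.append(relation)

    def build_term_index(self) -> None:
        self.term_index = {}
        for concept in self.concepts.values():
            for syn in concept.synonyms:
                norm = normalize_term(syn)
                if norm:
                    self.term_index.setdefault(norm, set()).add(concept.code)

    def validate(self) -> None:
        dangling = sorted(
            {
                code
                for rel in self.relations
                for code in (rel.source_code, rel.target_code)
                if code not in self.concepts
            }
        )
        if dangling:
            raise KbError(f"dangling relation endpoints: {', '.join(dangling)}")

    # -- queries --------------------------------------------------------

    def domain_of(self, code: str) -> str:
        concept = self.concepts[code]
        if self.config.domain_axis == "semantic_type":
            return concept.semantic_type
        return concept.source

    def lookup(self, term: str) -> set[str]:
        """Codes whose synonyms match ``term`` after normalization."""
        return set(self.term_index.get(normalize_term(term), set()))

    def relation_labels_between(
        self, a: str, b: str, directed: bool | None = None
    ) -> set[str]:
        directed = self.config.directed_traversal if directed is None else directed
        labels: set[str] = set()
        for rel in self.relations:
            if rel.source_code == a and rel.target_code == b:
                labels |= rel.relation_labels
            elif not directed and rel.source_code == b and rel.target_code == a:
                labels |= rel.relation_labels
        return labels

    def adjacency(
        self, scope: str = "all", directed: bool | None = None
    ) -> dict[str, list[tuple[str, str]]]:
        """code -> list of (neighbor, relation label) under ``scope``.

        scope "hierarchy" restricts edges to the configured hierarchy label.
        """
        directed = self.config.directed_traversal if directed is None else directed
        adj: dict[str, list[tuple[str, str]]] = {c: [] for c in self.concepts}
        for rel in self.relations:
            labels = rel.relation_labels
            if scope == "hierarchy":
                if self.config.hierarchy_label not in labels:
                    continue
                labels = frozenset({self.config.hierarchy_label})
            for label in sorted(labels):
                adj[rel.source_code].append((rel.target_code, label))
                if not directed:
                    adj[rel.target_code].append((rel.source_code, label))
        return adj

    # -- canonical serialization ---------------------------------------

    def to_canonical_dict(self) -> dict:
        return {
            "name": self.name,
            "concepts": [
                {
                    "code": c.code,
                    "source": c.source,
                    "preferred_name": c.preferred_name,
                    "synonyms": sorted(c.synonyms),
                    "semantic_type": c.semantic_type,
                    "attributes": dict(sorted(c.attributes.items())),
                    "definitions": list(c.definitions),
                }
                for c in sorted(self.concepts.values(), key=lambda c: c.code)
            ],
            "relations": sorted(
                {
                    (r.source_code, tuple(sorted(r.relation_labels)), r.target_code)
                    for r in self.relations
                }
            ),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_canonical_dict(), sort_keys=True, indent=None)

    @classmethod
    def from_json(cls, text: str, config: KbConfig | None = None) -> "KnowledgeBase":
        payload = json.loads(text)
        kb = cls(name=payload["name"], config=config or KbConfig())
        for rec in payload["concepts"]:
            kb.add_concept(
                Concept(
                    code=rec["code"],
                    source=rec["source"],
                    preferred_name=rec["preferred_name"],
                    synonyms=set(rec["synonyms"]),
                    semantic_type=rec["semantic_type"],
                    attributes=dict(rec["attributes"]),
                    definitions=list(rec["definitions"]),
                )
            )
        for src, labels, tgt in payload["relations"]:
            kb.add_relation(ConceptRelation(src, frozenset(labels), tgt))
        kb.validate()
        kb.build_term_index()
        return kb


@dataclass
class KnowledgeHierarchy:
    """The IS_A slice of a knowledge base, guaranteed acyclic."""

    kb_name: str
    isa_edges: set[tuple[str, str]] = field(default_factory=set)

    def parents(self, code: str) -> set[str]:
        return {p for c, p in self.isa_edges if c == code}

    def children(self, code: str) -> set[str]:
        return {c for c, p in self.isa_edges if p == code}


def _find_cycle(edges: set[tuple[str, str]]) -> list[str] | None:
    """Return one directed cycle in the edge set, or None."""
    adj: dict[str, list[str]] = {}
    for child, parent in edges:
        adj.setdefault(child, []).append(parent)
    WHITE, GRAY, BLACK = 0, 1, 2
    color: dict[str, int] = {}
    stack_path: list[str] = []

    def visit(node: str) -> list[str] | None:
        color[node] = GRAY
        stack_path.append(node)
        for nxt in adj.get(node, ()):
            state = color.get(nxt, WHITE)
            if state == GRAY:
                idx = stack_path.index(nxt)
                return stack_path[idx:]
            if state == WHITE:
                found = visit(nxt)
                if found is not None:
                    return found
        stack_path.pop()
        color[node] = BLACK
        return None

    for node in list(adj):
        if color.get(node, WHITE) == WHITE:
            cycle = visit(node)
            if cycle is not None:
                return cycle
    return None


def build_hierarchy(
    kb: KnowledgeBase, hierarchy_label: str | None = None
) -> KnowledgeHierarchy:
    """Filter the KB's relations down to its hierarchy label and verify
    acyclicity.

    Raises :class:`CyclicHierarchyError` (with one offending cycle) if the
    IS_A edges contain a cycle; layer counting downstream diverges on
    cyclic input, so this is rejected eagerly.
    """
    label = hierarchy_label or kb.config.hierarchy_label
    edges = {
        (rel.source_code, rel.target_code)
        for rel in kb.relations
        if label in rel.relation_labels
    }
    cycle = _find_cycle(edges)
    if cycle is not None:
        raise CyclicHierarchyError(cycle)
    return KnowledgeHierarchy(kb_name=kb.name, isa_edges=edges)


def graph_distance(
    kb: KnowledgeBase,
    from_code: str,
    to_code: str,
    max_hops: int,
    scope: str = "all",
    directed: bool | None = None,
) -> float:
    """Shortest relation-path length between two codes, or ``UNREACHABLE``
    (``math.inf``) if no path of length <= max_hops exists.
    """
    for code in (from_code, to_code):
        if code not in kb.concepts:
            raise KbError(f"unknown concept code {code!r}")
    if from_code == to_code:
        return 0
    adj = kb.adjacency(scope=scope, directed=directed)
    dist = {from_code: 0}
    queue = deque([from_code])
    while queue:
        node = queue.popleft()
        d = dist[node]
        if d >= max_hops:
            continue
        for nbr, _label in adj[node]:
            if nbr not in dist:
                dist[nbr] = d + 1
                if nbr == to_code:
                    return d + 1
                queue.append(nbr)
    return UNREACHABLE


def bfs_layers(
    kb: KnowledgeBase,
    source: str,
    max_depth: int,
    scope: str = "all",
    directed: bool | None = None,
) -> dict[str, int]:
    """Exact shortest distances (<= max_depth) from ``source`` to every
    reachable code, excluding the source itself."""
    if source not in kb.concepts:
        raise KbError(f"unknown concept code {source!r}")
    adj = kb.adjacency(scope=scope, directed=directed)
    dist = {source: 0}
    queue = deque([source])
    while queue:
        node = queue.popleft()
        d = dist[node]
        if d >= max_depth:
            continue
        for nbr, _label in adj[node]:
            if nbr not in dist:
                dist[nbr] = d + 1
                queue.append(nbr)
    dist.pop(source)
    return dist


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _split_rrf_line(line: str, path: str, lineno: int, min_fields: int) -> list[str]:
    fields = line.rstrip("\n").split("|")
    if len(fields) < min_fields:
        raise KbError(
            f"{path}:{lineno}: expected at least {min_fields} pipe-delimited "
            f"fields, got {len(fields)}"
        )
    return fields


def load_rrf_kb(
    conso_path: str, rel_path: str, config: KbConfig | None = None, name: str = "rrf"
) -> KnowledgeBase:
    """Read a pipe-delimited concept file plus relation file.

    Rows sharing a code are merged into one concept (first row supplies the
    preferred name and source; every row's string becomes a synonym).
    Relations are deduplicated; relation endpoints must resolve.
    """
    config = config or KbConfig()
    kb = KnowledgeBase(name=name, config=config)
    conso_min = max(config.conso_code_col, config.conso_source_col,
                    config.conso_term_col,
                    config.conso_semtype_col or 0) + 1
    with open(conso_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = _split_rrf_line(line, str(conso_path), lineno, conso_min)
            code = fields[config.conso_code_col]
            source = fields[config.conso_source_col]
            term = fields[config.conso_term_col]
            semtype = (
                fields[config.conso_semtype_col]
                if config.conso_semtype_col is not None
                else ""
            )
            if code in kb.concepts:
                kb.concepts[code].synonyms.add(term)
            else:
                kb.add_concept(
                    Concept(
                        code=code,
                        source=source,
                        preferred_name=term,
                        semantic_type=semtype,
                    )
                )
    rel_min = max(config.rel_source_col, config.rel_label_col,
                  config.rel_target_col) + 1
    seen: set[tuple[str, str, str]] = set()
    with open(rel_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = _split_rrf_line(line, str(rel_path), lineno, rel_min)
            key = (
                fields[config.rel_source_col],
                fields[config.rel_label_col],
                fields[config.rel_target_col],
            )
            if key in seen:
                continue
            seen.add(key)
            kb.add_relation(
                ConceptRelation(key[0], frozenset({key[1]}), key[2])
            )
    kb.validate()
    kb.build_term_index()
    return kb


_CONCEPT_COLS = ("code", "source", "preferred_name", "synonyms", "semantic_type")


def load_toy_kb(path: str, config: KbConfig | None = None) -> KnowledgeBase:
    """Read the two-section TSV dialect (see README for the grammar).

    Sections are introduced by ``[CONCEPTS]`` and ``[RELATIONS]`` header
    lines; synonyms within a concept row are ``|``-separated.  The IS_A
    slice is validated for acyclicity at load time.
    """
    config = config or KbConfig()
    name = "toy"
    kb = KnowledgeBase(name=name, config=config)
    section = None
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                if line.startswith("#") and "name=" in line:
                    kb.name = line.split("name=", 1)[1].strip()
                continue
            if line.strip() == "[CONCEPTS]":
                section = "concepts"
                continue
            if line.strip() == "[RELATIONS]":
                section = "relations"
                continue
            fields = line.split("\t")
            if section == "concepts":
                if len(fields) != len(_CONCEPT_COLS):
                    raise KbError(
                        f"{path}:{lineno}: expected {len(_CONCEPT_COLS)} "
                        f"tab-delimited fields, got {len(fields)}"
                    )
                code, source, preferred, syns, semtype = fields
                synonyms = {s for s in syns.split("|") if s}
                kb.add_concept(
                    Concept(
                        code=code,
                        source=source,
                        preferred_name=preferred,
                        synonyms=synonyms,
                        semantic_type=semtype,
                    )
                )
            elif section == "relations":
                if len(fields) != 3:
                    raise KbError(
                        f"{path}:{lineno}: expected 3 tab-delimited fields, "
                        f"got {len(fields)}"
                    )
                src, label, tgt = fields
                kb.add_relation(ConceptRelation(src, frozenset({label}), tgt))
            else:
                raise KbError(f"{path}:{lineno}: content before a section header")
    kb.validate()
    kb.build_term_index()
    build_hierarchy(kb)  # raises on cyclic IS_A input
    return kb


def write_toy_kb(kb: KnowledgeBase, path: str) -> None:
    """Serialize a KnowledgeBase in the two-section TSV dialect."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# kitm knowledge base\tname={kb.name}\n")
        fh.write("[CONCEPTS]\n")
        for concept in sorted(kb.concepts.values(), key=lambda c: c.code):
            syns = "|".join(sorted(concept.synonyms))
            fh.write(
                "\t".join(
                    (
                        concept.code,
                        concept.source,
                        concept.preferred_name,
                        syns,
                        concept.semantic_type,
                    )
                )
                + "\n"
            )
        fh.write("[RELATIONS]\n")
        for src, labels, tgt in sorted(
            {
                (r.source_code, tuple(sorted(r.relation_labels)), r.target_code)
                for r in kb.relations
            }
        ):
            for label in labels:
                fh.write(f"{src}\t{label}\t{tgt}\n")
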