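"""Relation-item extraction and latent-knowledge text expansion.

Two kinds of relation candidates are read off an encoded post: descriptive
items (ordered pairs of concept terms co-occurring within an adjacency
window) and semantic items (those pairs that are backed by a KB relation).
Latent discovery then walks the knowledge hierarchy outward from the
explicit concepts, layer by exact shortest-distance layer, and text
expansion appends the discovered concepts' preferred names to the token
stream as a bag-of-words augmentation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

from .concept_encoding import EncodedText
from .knowledge_base import KnowledgeBase, normalize_term

logger = logging.getLogger(__name__)

DESCRIPTIVE = "descriptive"
SEMANTIC = "semantic"
ADJACENT = "adjacent"

# Search space for layer traversal: the hierarchy slice by default (layer
# counting is defined on the KH), all relation types optionally.
SCOPE_HIERARCHY = "hierarchy"
SCOPE_ALL = "all"


@dataclass(frozen=True)
class RelationItem:
    kind: str  # DESCRIPTIVE or SEMANTIC
    source_code: str
    relation_label: str
    target_code: str
    provenance: tuple[str, int, int]  # (post_id, source position, target position)


@dataclass
class LatentRelationSet:
    layer: int
    triples: set[tuple[str, str, str]] = field(default_factory=set)

    @property
    def targets(self) -> set[str]:
        return {t for _s, _r, t in self.triples}


@dataclass
class ExpandedText:
    post_id: str
    explicit_terms: set[str]
    latent_terms: dict[int, set[str]]
    expanded_tokens: list[str]


def extract_relation_items(
    encoded: EncodedText, kb: KnowledgeBase, window: int = 4
) -> list[RelationItem]:
    """Enumerate relation candidates from an encoded post.

    For every ordered pair of concept-bearing terms whose positions are at
    most ``window`` apart (in encoded-term positions, order of appearance
    preserved): one descriptive item per code pair, plus one semantic item
    per KB relation label connecting the pair.
    """
    positions = [
        (idx, term) for idx, term in enumerate(encoded.terms) if term.is_concept
    ]
    items: list[RelationItem] = []
    for a in range(len(positions)):
        for b in range(a + 1, len(positions)):
            pos_a, term_a = positions[a]
            pos_b, term_b = positions[b]
            if pos_b - pos_a > window:
                break
            for code_a in sorted(c.code for c in term_a.codes):
                for code_b in sorted(c.code for c in term_b.codes):
                    provenance = (encoded.post_id, pos_a, pos_b)
                    items.append(
                        RelationItem(
                            DESCRIPTIVE, code_a, ADJACENT, code_b, provenance
                        )
                    )
                    for label in sorted(
                        kb.relation_labels_between(code_a, code_b)
                    ):
                        items.append(
                            RelationItem(
                                SEMANTIC, code_a, label, code_b, provenance
                            )
                        )
    return items


def _seed_codes(rels0: Iterable) -> list[str]:
    """Accept explicit triples (s, r, t) or bare concept codes."""
    seeds = []
    for item in rels0:
        if isinstance(item, str):
            seeds.append(item)
        else:
            seeds.append(item[0])
    return sorted(set(seeds))


def discover_latent(
    rels0: Iterable,
    kb: KnowledgeBase,
    z: int,
    scope: str = SCOPE_HIERARCHY,
    directed: bool | None = None,
) -> LatentRelationSet:
    """Layer-z latent discovery.

    For each explicit source concept s0, find every KB concept t whose
    shortest distance from s0 (over the chosen relation scope) is exactly
    ``z``; emit (s0, r, t) with r the label of the final edge of a
    shortest path — one triple per distinct final-edge label, set
    semantics.  Sources that do not resolve in the KB are skipped and
    logged, mirroring the algorithm's membership guard.
    """
    if z < 1:
        raise ValueError("z must be >= 1")
    adj = kb.adjacency(scope=scope, directed=directed)
    triples: set[tuple[str, str, str]] = set()
    for s0 in _seed_codes(rels0):
        if s0 not in kb.concepts:
            logger.info("latent discovery: skipping unknown source %r", s0)
            continue
        dist = _bfs(adj, s0, z)
        frontier = [t for t, d in dist.items() if d == z]
        for t in frontier:
            labels = {
                label
                for prev, d in dist.items()
                if d == z - 1
                for nbr, label in adj[prev]
                if nbr == t
            }
            for label in labels:
                triples.add((s0, label, t))
    return LatentRelationSet(layer=z, triples=triples)


def _bfs(adj: dict[str, list[tuple[str, str]]], source: str, max_depth: int) -> dict[str, int]:
    from collections import deque

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
    return dist


def expand_text(
    encoded: EncodedText,
    kb: KnowledgeBase,
    m: int,
    scope: str = SCOPE_HIERARCHY,
    directed: bool | None = None,
) -> ExpandedText:
    """Union the explicit terms with the concepts found in layers 1..m.

    Layer sets exclude the post's own explicit codes; each latent
    concept's preferred name is appended once per layer occurrence, in
    deterministic (sorted) order.  m=0 is the identity.
    """
    if m < 0:
        raise ValueError("m must be >= 0")
    explicit = encoded.explicit_codes
    tokens = [t.term for t in encoded.terms]
    latent: dict[int, set[str]] = {}
    for z in range(1, m + 1):
        layer = discover_latent(explicit, kb, z, scope=scope, directed=directed)
        latent[z] = layer.targets - explicit
        for code in sorted(latent[z]):
            tokens.append(normalize_term(kb.concepts[code].preferred_name))
    return ExpandedText(
        post_id=encoded.post_id,
        explicit_terms=explicit,
        latent_terms=latent,
        expanded_tokens=tokens,
    )


# -- serialization helpers --------------------------------------------------


def expanded_to_record(expanded: ExpandedText) -> dict:
    return {
        "id": expanded.post_id,
        "explicit": sorted(expanded.explicit_terms),
        "latent": {str(z): sorted(codes) for z, codes in expanded.latent_terms.items()},
        "tokens": expanded.expanded_tokens,
    }


def expanded_from_record(record: dict) -> ExpandedText:
    return ExpandedText(
        post_id=record["id"],
        explicit_terms=set(record["explicit"]),
        latent_terms={int(z): set(codes) for z, codes in record["latent"].items()},
        expanded_tokens=list(record["tokens"]),
    )
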