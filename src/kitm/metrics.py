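"""Knowledge-rate metrics: EKR, LKR and KCR.

EKR is the fraction of a post's terms that encode to KB concepts; LKR the
relative growth of its concept set after m layers of hierarchy expansion;
KCR the fraction of extracted relation triples corroborated by the KB.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

from .concept_encoding import EncodedText
from .knowledge_base import KnowledgeBase, graph_distance
from .knowledge_expansion import SCOPE_HIERARCHY, discover_latent

logger = logging.getLogger(__name__)

MODE_REACHABLE = "reachable"
MODE_PATH_COUNT = "path_count"


class MetricUndefinedError(ValueError):
    """The metric's denominator is empty for this input."""


@dataclass
class MetricReport:
    post_id: str
    ekr: float
    lkr_by_m: dict[int, float]
    kcr: float
    counts: dict[str, int] = field(default_factory=dict)


def ekr(encoded: EncodedText) -> float:
    """Explicit knowledge rate: concept-bearing term occurrences over raw
    term count (0 by convention for an empty post)."""
    if encoded.n_raw == 0:
        return 0.0
    return encoded.n_concepts / encoded.n_raw


def ekr_unique(encoded: EncodedText) -> float:
    """Variant counting distinct concepts rather than occurrences."""
    if encoded.n_raw == 0:
        return 0.0
    return encoded.n_unique_concepts / encoded.n_raw


def _explicit_codes(encoded) -> set[str]:
    if isinstance(encoded, EncodedText):
        return encoded.explicit_codes
    return set(encoded)


def _walk_count(
    kb: KnowledgeBase, start: str, length: int, scope: str, directed: bool | None
) -> int:
    """Number of walks of exactly ``length`` edges starting at ``start``."""
    adj = kb.adjacency(scope=scope, directed=directed)
    frontier = {start: 1}
    for _step in range(length):
        nxt: dict[str, int] = {}
        for node, count in frontier.items():
            for nbr, _label in adj[node]:
                nxt[nbr] = nxt.get(nbr, 0) + count
        frontier = nxt
    return sum(frontier.values())


def lkr(
    encoded,
    kb: KnowledgeBase,
    m: int,
    mode: str = MODE_REACHABLE,
    scope: str = SCOPE_HIERARCHY,
    directed: bool | None = None,
) -> float:
    """Latent knowledge rate (k_r − k_d) / k_d.

    In the default ``reachable`` mode, k_r counts the distinct concepts
    reachable from the post's explicit concepts within m hierarchy layers,
    explicit concepts included (so k_r >= k_d and LKR is non-decreasing in
    m).  The ``path_count`` mode implements the literal nested-sum
    reading: for each explicit concept occurrence, the number of length-m
    relation walks; it is kept as an explicitly labeled alternative.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    explicit = _explicit_codes(encoded)
    known = {c for c in explicit if c in kb.concepts}
    k_d = len(known)
    if k_d == 0:
        raise MetricUndefinedError("no explicit concepts: LKR undefined (k_d = 0)")
    if mode == MODE_REACHABLE:
        latent: set[str] = set()
        for z in range(1, m + 1):
            layer = discover_latent(known, kb, z, scope=scope, directed=directed)
            latent |= layer.targets - known
        k_r = k_d + len(latent)
    elif mode == MODE_PATH_COUNT:
        occurrences: list[str]
        if isinstance(encoded, EncodedText):
            occurrences = [
                c.code
                for t in encoded.terms
                for c in t.codes
                if c.code in kb.concepts
            ]
        else:
            occurrences = sorted(known)
        k_r = sum(
            _walk_count(kb, code, m, scope=scope, directed=directed)
            for code in occurrences
        )
    else:
        raise ValueError(f"unknown LKR mode {mode!r}")
    return (k_r - k_d) / k_d


def kcr(
    extracted: Iterable[tuple[str, str, str]],
    kb: KnowledgeBase,
    hop_radius: int = 1,
) -> float:
    """Knowledge correlation rate: fraction of extracted triples whose
    endpoints are semantically found in the KB (related within
    ``hop_radius`` over any relation type).

    An empty extraction is vacuously correct (returns 1.0, logged).
    """
    n_s, n = kcr_counts(extracted, kb, hop_radius=hop_radius)
    if n == 0:
        logger.info("KCR on empty extraction: vacuously 1.0")
        return 1.0
    return n_s / n


def kcr_counts(
    extracted: Iterable[tuple[str, str, str]],
    kb: KnowledgeBase,
    hop_radius: int = 1,
) -> tuple[int, int]:
    """(n_s, n): corroborated triple count and total triple count."""
    triples = list(extracted)
    n_s = 0
    for s, _r, t in triples:
        if s not in kb.concepts or t not in kb.concepts:
            continue
        if graph_distance(kb, s, t, max_hops=hop_radius, scope="all") <= hop_radius:
            n_s += 1
    return n_s, len(triples)


def metric_report(
    encoded: EncodedText,
    kb: KnowledgeBase,
    ms: Iterable[int] = (1, 2, 3),
    extracted: Iterable[tuple[str, str, str]] | None = None,
    lkr_mode: str = MODE_REACHABLE,
    scope: str = SCOPE_HIERARCHY,
    kcr_hop_radius: int = 1,
) -> MetricReport:
    """One combined per-post metric row.

    When the post has no explicit concepts, LKR entries are reported as
    NaN rather than raising, so corpus-level reports stay total.
    """
    from math import nan

    lkr_by_m: dict[int, float] = {}
    for m in ms:
        try:
            lkr_by_m[m] = lkr(encoded, kb, m, mode=lkr_mode, scope=scope)
        except MetricUndefinedError:
            lkr_by_m[m] = nan
    if extracted is None:
        from .knowledge_expansion import extract_relation_items, SEMANTIC

        items = extract_relation_items(encoded, kb)
        extracted = [
            (it.source_code, it.relation_label, it.target_code)
            for it in items
            if it.kind == SEMANTIC
        ]
    extracted = list(extracted)
    known = {c for c in encoded.explicit_codes if c in kb.concepts}
    n_s, n = kcr_counts(extracted, kb, hop_radius=kcr_hop_radius)
    return MetricReport(
        post_id=encoded.post_id,
        ekr=ekr(encoded),
        lkr_by_m=lkr_by_m,
        kcr=1.0 if n == 0 else n_s / n,
        counts={
            "n_raw": encoded.n_raw,
            "n_k": encoded.n_concepts,
            "n_unique": encoded.n_unique_concepts,
            "k_d": len(known),
            "n_s": n_s,
            "n": n,
        },
    )
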