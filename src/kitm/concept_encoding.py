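"""Domain discovery and concept encoding of token streams.

Tokens are matched against the knowledge base's synonym index by greedy
longest multi-word match (window of 3 tokens by default).  A matched term
receives the full quadruple for each matching concept — (knowledge source,
code, semantic type, preferred name) — with set semantics: ambiguity is
preserved, never tie-broken.  Matching is plain dictionary lookup; no
external concept-recognition service is involved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

from .knowledge_base import KnowledgeBase, normalize_term

logger = logging.getLogger(__name__)

NOUN, VERB, ADJ, ADV, NUM, OTHER = "NOUN", "VERB", "ADJ", "ADV", "NUM", "OTHER"
TAGSET = frozenset({NOUN, VERB, ADJ, ADV, NUM, OTHER})

NO_DOMAIN = "none"


@dataclass(frozen=True)
class ConceptCode:
    """Quadruple identifying a concept match."""

    kb_name: str
    code: str
    semantic_type: str
    preferred_name: str


@dataclass
class EncodedTerm:
    term: str
    pos: str = NOUN
    domain: str = NO_DOMAIN
    codes: frozenset[ConceptCode] = frozenset()

    @property
    def is_concept(self) -> bool:
        return bool(self.codes)


@dataclass
class EncodedText:
    post_id: str
    terms: list[EncodedTerm]
    n_raw: int
    n_concepts: int
    n_unique_concepts: int

    @property
    def explicit_codes(self) -> set[str]:
        return {c.code for t in self.terms for c in t.codes}


# ---------------------------------------------------------------------------
# Part-of-speech tagging
# ---------------------------------------------------------------------------

# Small closed-class lexicons for the built-in rule tagger.  The tagger
# interface is pluggable (any callable token-list -> tag-list), so a real
# statistical tagger can be swapped in without touching the encoder.

_VERBS = {
    "am", "are", "is", "was", "were", "be", "been", "being",
    "take", "takes", "took", "taking", "taken", "get", "got", "getting",
    "have", "has", "had", "having", "do", "does", "did", "doing",
    "go", "going", "went", "gone", "stop", "stopped", "stopping",
    "start", "started", "try", "tried", "trying", "use", "used", "using",
    "feel", "felt", "feeling", "work", "worked", "working", "help",
    "helped", "helps", "give", "gave", "given", "wish", "wished", "quit",
    "suggest", "suggested", "want", "wanted", "miss", "missed", "hope",
    "resolved", "supposed", "worked", "can", "could", "will", "would",
    "may", "might", "should", "must",
}
_ADVS = {
    "very", "really", "quite", "too", "so", "not", "never", "always",
    "often", "soon", "now", "then", "here", "there", "again", "ago",
    "basically", "well",
}
_ADJS = {
    "good", "bad", "new", "old", "low", "high", "generic", "same",
    "potent", "nonaddictive", "more", "most", "less", "least",
}
_FUNCTION = {
    "the", "a", "an", "and", "or", "but", "if", "of", "to", "in", "on",
    "at", "by", "for", "with", "about", "as", "it", "its", "i", "you",
    "he", "she", "we", "they", "me", "him", "her", "us", "them", "my",
    "your", "his", "our", "their", "this", "that", "these", "those",
    "what", "which", "who", "why", "how", "no", "yes", "than", "because",
}


def rule_tagger(tokens: Sequence[str]) -> list[str]:
    """Deterministic lexicon/suffix tagger over the coarse tagset."""
    tags = []
    for tok in tokens:
        if tok.isdigit():
            tags.append(NUM)
        elif tok in _FUNCTION:
            tags.append(OTHER)
        elif tok in _VERBS:
            tags.append(VERB)
        elif tok in _ADVS or (len(tok) > 3 and tok.endswith("ly")):
            tags.append(ADV)
        elif tok in _ADJS:
            tags.append(ADJ)
        else:
            tags.append(NOUN)
    return tags


Tagger = Callable[[Sequence[str]], list[str]]


def tag_pos(tokens: Sequence[str], tagger: Tagger = rule_tagger) -> list[tuple[str, str]]:
    """Tag each token with a coarse part of speech."""
    tags = tagger(tokens)
    if len(tags) != len(tokens):
        raise ValueError("tagger returned wrong number of tags")
    return list(zip(tokens, tags))


# ---------------------------------------------------------------------------
# Domain discovery
# ---------------------------------------------------------------------------


def discover_domains(
    labels: Iterable[str],
    kb: KnowledgeBase,
    domains: Iterable[str] | None = None,
) -> dict[str, set[str]]:
    """Map each label to the set of KB domains whose concepts carry it as
    a synonym.

    The domain axis (source vocabulary vs semantic type) comes from the KB
    configuration.  ``domains``, when given, restricts the candidate
    domains.  Labels matching nothing map to the empty set.  With
    single-term input the same operation serves per-token domain tagging.
    """
    allowed = {normalize_term(d) for d in domains} if domains is not None else None
    result: dict[str, set[str]] = {}
    for label in labels:
        found: set[str] = set()
        for code in kb.lookup(label):
            domain = kb.domain_of(code)
            if allowed is None or normalize_term(domain) in allowed:
                found.add(domain)
        result[label] = found
    return result


# ---------------------------------------------------------------------------
# Term encoding
# ---------------------------------------------------------------------------


def encode_terms(
    tagged: Sequence[tuple[str, str]],
    kb: KnowledgeBase,
    domain_map: Mapping[str, set[str]] | None = None,
    post_id: str = "",
    max_ngram: int = 3,
) -> EncodedText:
    """Encode a tagged token stream against the KB synonym index.

    Greedy longest match: at each position the longest matching span of up
    to ``max_ngram`` tokens wins; its quadruples cover every matching
    concept.  Unmatched tokens pass through with domain ``"none"`` and no
    codes.  ``n_raw`` counts input tokens, ``n_concepts`` concept-bearing
    encoded terms (occurrences), ``n_unique_concepts`` distinct codes.
    """
    domain_map = domain_map or {}
    terms: list[EncodedTerm] = []
    i = 0
    n = len(tagged)
    while i < n:
        match_codes: set[str] = set()
        match_len = 0
        for span in range(min(max_ngram, n - i), 0, -1):
            surface = " ".join(tok for tok, _pos in tagged[i : i + span])
            codes = kb.lookup(surface)
            if codes:
                match_codes = codes
                match_len = span
                break
        if match_codes:
            surface = " ".join(tok for tok, _pos in tagged[i : i + match_len])
            quadruples = frozenset(
                ConceptCode(
                    kb_name=kb.name,
                    code=code,
                    semantic_type=kb.concepts[code].semantic_type,
                    preferred_name=kb.concepts[code].preferred_name,
                )
                for code in match_codes
            )
            mapped = domain_map.get(normalize_term(surface))
            if mapped:
                domain = sorted(mapped)[0]
            else:
                domain = sorted(kb.domain_of(code) for code in match_codes)[0]
            terms.append(
                EncodedTerm(
                    term=surface,
                    pos=tagged[i][1],
                    domain=domain,
                    codes=quadruples,
                )
            )
            i += match_len
        else:
            tok, pos = tagged[i]
            terms.append(EncodedTerm(term=tok, pos=pos))
            i += 1
    n_concepts = sum(1 for t in terms if t.is_concept)
    unique = {(c.kb_name, c.code) for t in terms for c in t.codes}
    return EncodedText(
        post_id=post_id,
        terms=terms,
        n_raw=n,
        n_concepts=n_concepts,
        n_unique_concepts=len(unique),
    )


def encode_tokens(
    tokens: Sequence[str],
    kb: KnowledgeBase,
    domain_map: Mapping[str, set[str]] | None = None,
    post_id: str = "",
    max_ngram: int = 3,
    tagger: Tagger = rule_tagger,
) -> EncodedText:
    """Convenience: tag then encode a bare token list."""
    return encode_terms(
        tag_pos(tokens, tagger), kb, domain_map, post_id=post_id, max_ngram=max_ngram
    )


# -- serialization helpers (JSONL records for the CLI) ----------------------


def encoded_to_record(encoded: EncodedText) -> dict:
    return {
        "id": encoded.post_id,
        "terms": [
            {
                "term": t.term,
                "pos": t.pos,
                "domain": t.domain,
                "codes": sorted(
                    [c.kb_name, c.code, c.semantic_type, c.preferred_name]
                    for c in t.codes
                ),
            }
            for t in encoded.terms
        ],
        "n_raw": encoded.n_raw,
        "n_concepts": encoded.n_concepts,
        "n_unique_concepts": encoded.n_unique_concepts,
    }


def encoded_from_record(record: dict) -> EncodedText:
    terms = [
        EncodedTerm(
            term=t["term"],
            pos=t["pos"],
            domain=t["domain"],
            codes=frozenset(ConceptCode(*c) for c in t["codes"]),
        )
        for t in record["terms"]
    ]
    return EncodedText(
        post_id=record["id"],
        terms=terms,
        n_raw=record["n_raw"],
        n_concepts=record["n_concepts"],
        n_unique_concepts=record["n_unique_concepts"],
    )
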