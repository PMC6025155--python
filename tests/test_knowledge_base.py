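from __future__ import annotations

import itertools
import math
from importlib import resources

import networkx as nx
import pytest

from kitm.knowledge_base import (
    Concept,
    ConceptRelation,
    CyclicHierarchyError,
    KbConfig,
    KbError,
    KnowledgeBase,
    UNREACHABLE,
    build_hierarchy,
    graph_distance,
    load_rrf_kb,
    load_toy_kb,
    normalize_term,
    write_toy_kb,
)

from conftest import make_kb, random_relation_kb


def _data_path(name: str) -> str:
    return str(resources.files("kitm.data").joinpath(name))


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "raw,expected",
    [
        ("Aspirin", "aspirin"),
        ("  Low   Libido ", "low libido"),
        ("beta-blocker", "beta blocker"),
        ("it's", "it s"),
        ("", ""),
    ],
)
def test_normalize_term(raw, expected):
    assert normalize_term(raw) == expected


# ---------------------------------------------------------------------------
# RRF dialect
# ---------------------------------------------------------------------------


def _write_rrf(tmp_path, conso_rows, rel_rows):
    conso = tmp_path / "conso.rrf"
    rel = tmp_path / "rel.rrf"
    conso.write_text("\n".join(conso_rows) + "\n")
    rel.write_text("\n".join(rel_rows) + "\n" if rel_rows else "")
    return str(conso), str(rel)


def _conso_row(code, source, term):
    fields = [""] * 18
    fields[0], fields[11], fields[14] = code, source, term
    return "|".join(fields)


def _rel_row(c1, rel, c2):
    fields = [""] * 16
    fields[0], fields[3], fields[4] = c1, rel, c2
    return "|".join(fields)


def test_load_rrf_minimal(tmp_path):
    conso, rel = _write_rrf(
        tmp_path,
        [_conso_row("C1", "V", "aspirin"), _conso_row("C2", "V", "headache")],
        [_rel_row("C1", "may_treat", "C2")],
    )
    kb = load_rrf_kb(conso, rel)
    assert len(kb.concepts) == 2
    assert len(kb.relations) == 1
    assert kb.lookup("Aspirin") == {"C1"}


def test_load_rrf_dangling_endpoint(tmp_path):
    conso, rel = _write_rrf(
        tmp_path,
        [_conso_row("C1", "V", "aspirin")],
        [_rel_row("C1", "may_treat", "C9")],
    )
    with pytest.raises(KbError, match="C9"):
        load_rrf_kb(conso, rel)


def test_load_rrf_malformed_line_names_lineno(tmp_path):
    conso, rel = _write_rrf(
        tmp_path,
        [_conso_row("C1", "V", "aspirin"), "C2|only|three"],
        [],
    )
    with pytest.raises(KbError, match=":2"):
        load_rrf_kb(conso, rel)


def test_mini_rrf_fixture_term_index_oracle():
    """term_index size equals an independent set-union count over the raw
    concept file."""
    kb = load_rrf_kb(_data_path("mini_conso.rrf"), _data_path("mini_rel.rrf"))
    assert len(kb.concepts) == 12
    assert len(kb.relations) == 15
    # independent recount: normalized distinct strings straight off the file
    distinct = set()
    with open(_data_path("mini_conso.rrf"), encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                distinct.add(normalize_term(line.split("|")[14]))
    assert len(kb.term_index) == len(distinct)
    # and the index covers every synonym of every concept
    for concept in kb.concepts.values():
        for syn in concept.synonyms:
            assert concept.code in kb.term_index[normalize_term(syn)]


def test_rrf_relation_dedup(tmp_path):
    conso, rel = _write_rrf(
        tmp_path,
        [_conso_row("C1", "V", "a"), _conso_row("C2", "V", "b")],
        [_rel_row("C1", "IS_A", "C2"), _rel_row("C1", "IS_A", "C2")],
    )
    assert len(load_rrf_kb(conso, rel).relations) == 1


# ---------------------------------------------------------------------------
# toy TSV dialect
# ---------------------------------------------------------------------------


def test_load_toy_empty_relations(tmp_path):
    path = tmp_path / "kb.tsv"
    path.write_text(
        "[CONCEPTS]\nA1\tV\talpha\talpha\tthing\n[RELATIONS]\n"
    )
    kb = load_toy_kb(str(path))
    assert kb.relations == []
    assert build_hierarchy(kb).isa_edges == set()


def test_toy_fixture_concept_count_is_line_count(toy_kb):
    with open(_data_path("toy_kb.tsv"), encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    start = lines.index("[CONCEPTS]") + 1
    end = lines.index("[RELATIONS]")
    assert len(toy_kb.concepts) == end - start


def test_toy_cycle_rejected(tmp_path):
    path = tmp_path / "kb.tsv"
    path.write_text(
        "[CONCEPTS]\nA\tV\ta\ta\tt\nB\tV\tb\tb\tt\n"
        "[RELATIONS]\nA\tIS_A\tB\nB\tIS_A\tA\n"
    )
    with pytest.raises(CyclicHierarchyError):
        load_toy_kb(str(path))


def test_toy_duplicate_code(tmp_path):
    path = tmp_path / "kb.tsv"
    path.write_text("[CONCEPTS]\nA\tV\ta\ta\tt\nA\tV\tb\tb\tt\n")
    with pytest.raises(KbError, match="duplicate"):
        load_toy_kb(str(path))


def test_rrf_and_toy_round_trip_equal(tmp_path):
    """The same content loaded via both dialects is equal under canonical
    serialization."""
    kb = load_rrf_kb(_data_path("mini_conso.rrf"), _data_path("mini_rel.rrf"))
    out = tmp_path / "converted.tsv"
    write_toy_kb(kb, str(out))
    kb2 = load_toy_kb(str(out))
    kb2.name = kb.name
    assert kb.to_json() == kb2.to_json()


# ---------------------------------------------------------------------------
# hierarchy
# ---------------------------------------------------------------------------


def test_build_hierarchy_filters_label():
    kb = make_kb(
        {"A": ["a"], "B": ["b"], "C": ["c"]},
        [("A", "IS_A", "B"), ("A", "may_treat", "C")],
    )
    assert build_hierarchy(kb).isa_edges == {("A", "B")}


def test_build_hierarchy_empty():
    kb = make_kb({"A": ["a"], "B": ["b"]}, [("A", "may_treat", "B")])
    assert build_hierarchy(kb).isa_edges == set()


def test_toy_hierarchy_matches_grep_oracle(toy_kb):
    with open(_data_path("toy_kb.tsv"), encoding="utf-8") as fh:
        expected = {
            (f[0], f[2])
            for f in (line.rstrip("\n").split("\t") for line in fh)
            if len(f) == 3 and f[1] == "IS_A"
        }
    assert build_hierarchy(toy_kb).isa_edges == expected


def test_hierarchy_subset_property(toy_kb):
    hierarchy = build_hierarchy(toy_kb)
    rel_pairs = {
        (r.source_code, r.target_code)
        for r in toy_kb.relations
        if "IS_A" in r.relation_labels
    }
    assert hierarchy.isa_edges == rel_pairs
    for child, parent in hierarchy.isa_edges:
        labels = toy_kb.relation_labels_between(child, parent, directed=True)
        assert "IS_A" in labels


def test_cycle_error_reports_cycle():
    kb = make_kb(
        {"A": ["a"], "B": ["b"], "C": ["c"]},
        [("A", "IS_A", "B"), ("B", "IS_A", "C"), ("C", "IS_A", "A")],
    )
    with pytest.raises(CyclicHierarchyError) as err:
        build_hierarchy(kb)
    assert set(err.value.cycle) == {"A", "B", "C"}


# ---------------------------------------------------------------------------
# graph distance
# ---------------------------------------------------------------------------


def test_distance_identity(chain_kb):
    assert graph_distance(chain_kb, "A", "A", 5) == 0


def test_distance_chain(chain_kb):
    assert graph_distance(chain_kb, "A", "C", 2) == 2


def test_distance_unreachable_beyond_max_hops(chain_kb):
    assert graph_distance(chain_kb, "A", "C", 1) == UNREACHABLE
    assert math.isinf(graph_distance(chain_kb, "A", "C", 1))


def test_distance_unknown_code(chain_kb):
    with pytest.raises(KbError, match="unknown"):
        graph_distance(chain_kb, "A", "Q", 3)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_distance_all_pairs_floyd_warshall_oracle(seed):
    kb = random_relation_kb(seed, 20, n_extra=15)
    graph = nx.Graph()
    graph.add_nodes_from(kb.concepts)
    for rel in kb.relations:
        graph.add_edge(rel.source_code, rel.target_code)
    oracle = dict(nx.all_pairs_shortest_path_length(graph))
    for a, b in itertools.product(kb.concepts, repeat=2):
        expected = oracle.get(a, {}).get(b, UNREACHABLE)
        if expected is not UNREACHABLE and expected > 6:
            expected = UNREACHABLE
        assert graph_distance(kb, a, b, max_hops=6) == expected


def test_distance_symmetry_and_triangle_inequality(toy_kb):
    codes = sorted(toy_kb.concepts)
    dist = {
        (a, b): graph_distance(toy_kb, a, b, max_hops=len(codes))
        for a in codes
        for b in codes
    }
    for a in codes:
        for b in codes:
            assert dist[a, b] == dist[b, a]
            for c in codes:
                assert dist[a, c] <= dist[a, b] + dist[b, c]


def test_directed_traversal_switch():
    kb = make_kb(
        {"A": ["a"], "B": ["b"]},
        [("A", "IS_A", "B")],
        config=KbConfig(directed_traversal=True),
    )
    assert graph_distance(kb, "A", "B", 3) == 1
    assert graph_distance(kb, "B", "A", 3) == UNREACHABLE
    assert graph_distance(kb, "B", "A", 3, directed=False) == 1


# ---------------------------------------------------------------------------
# invariants
# ---------------------------------------------------------------------------


def test_relation_requires_labels():
    with pytest.raises(KbError):
        ConceptRelation("A", frozenset(), "B")


def test_concept_preferred_name_in_synonyms():
    concept = Concept(code="C", source="V", preferred_name="name", synonyms={"other"})
    assert "name" in concept.synonyms


def test_kb_json_round_trip(toy_kb):
    clone = KnowledgeBase.from_json(toy_kb.to_json())
    assert clone.to_json() == toy_kb.to_json()
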