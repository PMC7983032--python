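"""Interaction merging, consensus, dataset views and exports."""

import itertools

import pytest

from crosstalk_kb.identifiers import (IdService, IdentifierSpace,
                                      MappingTable, ReferenceSet)
from crosstalk_kb.model import ConfigError, Entity, Evidence
from crosstalk_kb.network import (Interaction, NetworkDB, consensus,
                                  coverage_stats, dataset_view, export_tsv,
                                  merge_interactions)
from crosstalk_kb.resources import RawRecord


def _interaction(evidence_specs):
    i = Interaction(Entity("protein", "A"), Entity("protein", "B"),
                    "post_translational")
    for n, (direction, sign) in enumerate(evidence_specs):
        i.add_evidence(Evidence(f"r{n}", frozenset(), "omnipath",
                                direction, sign))
    return i


def test_consensus_single_directed_stimulation():
    c = consensus(_interaction([("a_to_b", "stimulation")]))
    assert (c.directed, c.direction, c.sign) == (True, "a_to_b",
                                                 "stimulation")
    assert not c.contradictory_direction and not c.contradictory_sign


def test_consensus_sign_tie_sets_flag_and_unsets_sign():
    c = consensus(_interaction([("a_to_b", "stimulation"),
                                ("a_to_b", "inhibition")]))
    assert c.sign is None and c.contradictory_sign


def test_consensus_majority_with_flag():
    c = consensus(_interaction([("a_to_b", "stimulation"),
                                ("a_to_b", "stimulation"),
                                ("a_to_b", "inhibition")]))
    assert c.sign == "stimulation" and c.contradictory_sign


def _brute_force_consensus(specs):
    """Independent statement of the documented rule, by direct counting."""
    dirs = [d for d, _ in specs if d in ("a_to_b", "b_to_a")]
    signs = [s for _, s in specs if s in ("stimulation", "inhibition")]
    n_ab, n_ba = dirs.count("a_to_b"), dirs.count("b_to_a")
    n_st, n_in = signs.count("stimulation"), signs.count("inhibition")
    return (
        bool(dirs),
        None if n_ab == n_ba else ("a_to_b" if n_ab > n_ba else "b_to_a"),
        None if n_st == n_in else (
            "stimulation" if n_st > n_in else "inhibition"),
        n_ab > 0 and n_ba > 0,
        n_st > 0 and n_in > 0,
    )


def test_consensus_exhaustive_small_multisets():
    """All direction/sign evidence multisets of size <= 4 agree with the
    brute-force majority rule.  Consensus never asserts a value that zero
    evidences assert."""
    options = list(itertools.product(("a_to_b", "b_to_a", "undirected"),
                                     ("stimulation", "inhibition",
                                      "unknown")))
    for size in (1, 2, 3, 4):
        for combo in itertools.combinations_with_replacement(options, size):
            c = consensus(_interaction(combo))
            assert (c.directed, c.direction, c.sign,
                    c.contradictory_direction, c.contradictory_sign) \
                == _brute_force_consensus(combo)
            if c.direction:
                assert c.direction in [d for d, _ in combo]
            if c.sign:
                assert c.sign in [s for _, s in combo]


def _tiny_service():
    service = IdService()
    service.register_reference("protein", ReferenceSet(
        IdentifierSpace("uniprot"), frozenset({"P1", "P2", "P3"})))
    service.register_table(MappingTable.from_pairs(
        "genesymbol", "uniprot", [("GA", "P1"), ("GB", "P2"), ("GC", "P3")],
        case_insensitive=True))
    return service


def _rec(resource, source, target, sign="+", directed="1"):
    return RawRecord(resource, {"source": source, "target": target,
                                "sign": sign, "is_directed": directed,
                                "references": "1111"}, 1)


def test_merge_same_edge_two_resources_one_interaction():
    db = merge_interactions([_rec("r1", "GA", "GB"), _rec("r2", "GA", "GB")],
                            _tiny_service(),
                            {"r1": "omnipath", "r2": "omnipath"})
    assert len(db) == 1
    i = next(iter(db))
    assert i.resources() == {"r1", "r2"}


def test_merge_empty_input():
    assert len(merge_interactions([], _tiny_service(), {})) == 0


def test_merge_reciprocal_claims_one_interaction_two_directions():
    db = merge_interactions([_rec("r1", "GA", "GB"), _rec("r2", "GB", "GA")],
                            _tiny_service(),
                            {"r1": "omnipath", "r2": "omnipath"})
    assert len(db) == 1
    assert next(iter(db)).directions_asserted() == {"a_to_b", "b_to_a"}


def test_merge_drops_and_counts_unmappable():
    db = merge_interactions([_rec("r1", "GA", "NOPE")], _tiny_service(),
                            {"r1": "omnipath"})
    assert len(db) == 0
    assert db.dropped[("r1", "unmappable_endpoint")] == 1


def test_merge_keeps_self_loops():
    db = merge_interactions([_rec("r1", "GA", "GA")], _tiny_service(),
                            {"r1": "omnipath"})
    assert len(db) == 1


def test_built_network_size_and_views_match_manifest(kb, manifest):
    per_tag = manifest["network"]["per_tag_unique"]
    assert len(kb.network) == manifest["network"]["total_unique"]
    for tag, expected in per_tag.items():
        assert len(dataset_view(kb.network, {tag})) == expected, tag
    # union of all nine tags is the identity view
    assert len(dataset_view(kb.network, set(per_tag))) == len(kb.network)


def test_contradictory_sign_edges_match_manifest(kb, manifest):
    expected = {tuple(p) for p in
                manifest["network"]["contradiction_sign_edges"]}
    got = {tuple(sorted((i.a.id, i.b.id))) for i in kb.network
           if consensus(i).contradictory_sign}
    assert got == expected


def test_dorothea_confidence_filter(kb):
    view_a = dataset_view(kb.network, {"dorothea"}, min_confidence="A")
    for i in view_a:
        assert {e.confidence for e in i.evidences.values()} == {"A"}
    sizes = [len(dataset_view(kb.network, {"dorothea"}, min_confidence=c))
             for c in "ABCD"]
    assert sizes == sorted(sizes)  # views grow with relaxed confidence
    with pytest.raises(ConfigError):
        dataset_view(kb.network, {"nonsense"})


def test_coverage_stats_set_arithmetic(kb):
    nodes = {e.id for e in kb.network.nodes()}
    some = set(list(nodes)[:5])
    stats = coverage_stats(kb.network, {
        "inside": some,
        "outside": {"NOT_A_NODE_1", "NOT_A_NODE_2"},
        "half": some | {"NOT_A_NODE_3"}})
    assert stats["inside"] == (1.0, 5)
    assert stats["outside"] == (0.0, 0)
    assert stats["half"] == (5 / 6, 5)


def test_evidence_conservation(kb, fixture_dir):
    """Every surviving input record's resource/references appear on exactly
    one interaction (evidences are never duplicated across interactions)."""
    seen = {}
    for i in kb.network:
        for ev in i.evidences.values():
            key = (id(ev),)
            assert key not in seen
            seen[key] = i.key()
    total_evidence_rows = sum(len(i.evidences) for i in kb.network)
    assert total_evidence_rows >= len(kb.network)


def test_merge_idempotence(kb):
    merged = kb.network.merge_with(kb.network)
    assert export_tsv(merged) == export_tsv(kb.network)
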