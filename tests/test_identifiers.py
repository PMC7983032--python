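"""Label normalization and identifier translation."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crosstalk_kb.identifiers import (IdService, IdentifierSpace,
                                      MappingTable, ReferenceSet, map_id,
                                      normalize_label)
from crosstalk_kb.model import ConfigError, Entity


@pytest.mark.parametrize("raw,expected", [
    ("IL-6", "IL6"),
    ("TNFα", "TNFA"),
    ("ifn-γ", "IFNG"),
    ("NF–κB", "NFKB"),        # en-dash run + kappa
    ("EGFR", "EGFR"),
])
def test_normalize_label_examples(raw, expected):
    assert normalize_label(raw) == expected


@settings(deadline=None, derandomize=True, max_examples=200)
@given(st.text(min_size=1, max_size=30))
def test_normalize_label_idempotent(raw):
    once = normalize_label(raw)
    if once:  # dash-only inputs normalize to the empty string
        assert normalize_label(once) == once


def test_normalize_rejects_empty():
    with pytest.raises(ValueError):
        normalize_label("")


@pytest.fixture()
def reference():
    space = IdentifierSpace("uniprot")
    sec2sym = MappingTable.from_pairs(
        "uniprot", "genesymbol", [("Q0TEST1", "GENEA")])
    sym2uni = MappingTable.from_pairs(
        "genesymbol", "uniprot",
        [("GENEA", "P0TEST1"), ("GENEA", "P0TEST2"), ("GENEB", "P0TEST3")],
        case_insensitive=True)
    ref = ReferenceSet(space,
                       frozenset({"P0TEST1", "P0TEST2", "P0TEST3"}),
                       secondary_to_symbol=sec2sym,
                       symbol_to_primary=sym2uni)
    return ref, sym2uni


def test_map_id_identity_for_primary(reference):
    ref, _ = reference
    assert map_id("P0TEST1", "uniprot", ref, []) == {"P0TEST1"}


def test_map_id_empty_when_unreachable(reference):
    ref, _ = reference
    assert map_id("GENEA", "genesymbol", ref, []) == frozenset()


def test_map_id_secondary_bridge_keeps_all_candidates(reference):
    """A deprecated accession resolves via its primary symbol to *all*
    primary accessions that symbol maps to."""
    ref, _ = reference
    hits = map_id("Q0TEST1", "uniprot", ref, [])
    assert hits == {"P0TEST1", "P0TEST2"}


def test_map_id_symbol_table_and_case(reference):
    ref, sym2uni = reference
    assert map_id("geneb", "genesymbol", ref, [sym2uni]) == {"P0TEST3"}
    # accession space stays case sensitive
    assert map_id("p0test1", "uniprot", ref, []) == frozenset()


def _service(reference):
    ref, sym2uni = reference
    service = IdService()
    service.register_reference("protein", ref)
    service.register_table(sym2uni)
    return service


def test_unknown_space_is_a_configuration_error(reference):
    service = _service(reference)
    with pytest.raises(ConfigError):
        service.map_id("X", "ensembl", "protein")


def test_unmapped_counted_not_raised(reference):
    service = _service(reference)
    assert service.map_id("NOSUCH", "genesymbol", "protein") == frozenset()
    assert service.unmapped[("genesymbol", "NOSUCH")] == 1


def test_translate_entity_complex_rules(reference):
    service = _service(reference)
    # one member untranslatable -> whole complex untranslatable
    bad = Entity("complex", "COMPLEX:NOPE_P0TEST3")
    assert service.translate_entity(bad) == frozenset()
    # ambiguous member expands by cartesian product; oracle: both variants
    amb = Entity("complex", "COMPLEX:Q0TEST1_P0TEST3")
    got = {e.id for e in service.translate_entity(amb)}
    assert got == {"COMPLEX:P0TEST1_P0TEST3", "COMPLEX:P0TEST2_P0TEST3"}
    # protein with primary id translates to itself
    me = Entity("protein", "P0TEST1")
    assert service.translate_entity(me) == {me}


def test_map_id_matches_reachability_oracle():
    """|map_id(v)| equals the number of reference ids reachable within two
    hops of the fixture mapping graph (brute-force enumeration)."""
    rng = random.Random(11)
    primaries = [f"P{i:03d}" for i in range(30)]
    symbols = [f"S{i:03d}" for i in range(20)]
    secondaries = [f"Q{i:03d}" for i in range(10)]
    sym_pairs = [(rng.choice(symbols), rng.choice(primaries))
                 for _ in range(40)]
    sec_pairs = [(rng.choice(secondaries), rng.choice(symbols))
                 for _ in range(15)]
    ref = ReferenceSet(
        IdentifierSpace("uniprot"), frozenset(primaries),
        secondary_to_symbol=MappingTable.from_pairs(
            "uniprot", "genesymbol", sec_pairs),
        symbol_to_primary=MappingTable.from_pairs(
            "genesymbol", "uniprot", sym_pairs, case_insensitive=True))
    sym_table = MappingTable.from_pairs("genesymbol", "uniprot", sym_pairs,
                                        case_insensitive=True)

    def reachable(value, space):
        if space == "uniprot":
            if value in primaries:
                return {value}
            hops = {s for q, s in sec_pairs if q == value}
            return {p for s, p in sym_pairs if s in hops}
        return {p for s, p in sym_pairs if s == value}

    for value in symbols:
        assert map_id(value, "genesymbol", ref, [sym_table]) \
            == reachable(value, "genesymbol")
    for value in secondaries + primaries:
        assert map_id(value, "uniprot", ref, []) == reachable(value,
                                                              "uniprot")


def test_map_id_output_subset_of_primaries(kb):
    primaries = kb.id_service.references["protein"].primary_ids
    for table in kb.id_service.tables:
        for value in list(table.pairs)[:50]:
            hits = kb.id_service.map_id(value, table.from_space, "protein")
            assert hits <= primaries
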