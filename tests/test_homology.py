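"""Homology translation of proteins, networks and PTM sites."""

import itertools

from crosstalk_kb.enzyme_ptm import SequenceSet
from crosstalk_kb.homology import (HomologyTable, HomologyTranslator,
                                   PTMSiteHomology, load_site_homology,
                                   load_translator, translate_network,
                                   translate_ptms)
from crosstalk_kb.identifiers import MappingTable


def _toy_translator():
    u2r = MappingTable.from_pairs("uniprot", "refseq",
                                  [("P0H1", "RS1"), ("P0H2", "RS2")])
    r2u = MappingTable.from_pairs("refseq", "uniprot",
                                  [("RS9", "P0M1"), ("RS8", "P0M2"),
                                   ("RS7", "P0M3")])
    table = HomologyTable([("g1", 9606, "RS1"), ("g1", 10090, "RS9"),
                           ("g2", 9606, "RS2"), ("g2", 10090, "RS8"),
                           ("g2", 10090, "RS7")])
    return HomologyTranslator(9606, 10090, u2r, r2u, table)


def test_three_step_chain():
    tr = _toy_translator()
    assert tr.translate_protein("P0H1") == {"P0M1"}


def test_no_refseq_mapping_is_empty():
    assert _toy_translator().translate_protein("P0HX") == frozenset()


def test_group_with_two_targets_returns_both():
    assert _toy_translator().translate_protein("P0H2") == {"P0M2", "P0M3"}


def test_expansion_cap_logged():
    pairs = [(f"RS{i}", f"P0M{i}") for i in range(10, 20)]
    tr = HomologyTranslator(
        9606, 10090,
        MappingTable.from_pairs("uniprot", "refseq", [("P0H1", "RS1")]),
        MappingTable.from_pairs("refseq", "uniprot", pairs),
        HomologyTable([("g", 9606, "RS1")]
                      + [("g", 10090, rs) for rs, _ in pairs]),
        max_targets=4)
    assert len(tr.translate_protein("P0H1")) == 4
    assert tr.overflow["P0H1"] == 1


def test_translated_edges_match_path_enumeration_oracle(kb, fixture_dir):
    """Each translated edge set equals the brute-force enumeration of
    three-step paths per endpoint."""
    base, _ = fixture_dir
    tr = load_translator(base)
    translated, coverage = translate_network(kb.network, tr)
    assert 0.0 <= coverage <= 1.0

    u2r, r2u, hom = tr.uniprot_to_refseq, tr.refseq_to_uniprot, tr.homology

    def enumerate_targets(acc):
        out = set()
        for group, taxid, refseq in hom.rows:
            if taxid != 9606 or refseq not in u2r.lookup(acc):
                continue
            for group2, taxid2, refseq2 in hom.rows:
                if group2 == group and taxid2 == 10090:
                    out |= r2u.lookup(refseq2)
        return out

    expected = set()
    for i in kb.network:
        if i.a.kind != "protein" or i.b.kind != "protein":
            continue
        for ta, tb in itertools.product(enumerate_targets(i.a.id),
                                        enumerate_targets(i.b.id)):
            expected.add(frozenset((ta, tb)) if ta != tb
                         else frozenset((ta,)))
    got = {frozenset((i.a.id, i.b.id)) for i in translated}
    assert got == expected


def test_translation_coverage_matches_manifest(kb, fixture_dir):
    base, manifest = fixture_dir
    translated, coverage = translate_network(kb.network, load_translator(
        base))
    assert len(translated) == manifest["homology"]["network_survivors"]
    assert abs(coverage - manifest["homology"]["coverage"]) < 1e-12


def test_human_to_human_identity(kb):
    accs = sorted({e.id for e in kb.network.nodes() if e.kind == "protein"})
    tr = HomologyTranslator(
        9606, 9606,
        MappingTable.from_pairs("uniprot", "refseq",
                                [(a, "R" + a) for a in accs]),
        MappingTable.from_pairs("refseq", "uniprot",
                                [("R" + a, a) for a in accs]),
        HomologyTable([("g" + a, 9606, "R" + a) for a in accs]))
    translated, coverage = translate_network(kb.network, tr)
    protein_only = {k for k in kb.network.interactions
                    if k[0].kind == "protein" and k[1].kind == "protein"}
    assert set(translated.interactions) == protein_only
    for key in protein_only:
        assert translated.interactions[key].evidences.keys() \
            == kb.network.interactions[key].evidences.keys()


def test_translated_ptm_survivors_match_manifest(kb, fixture_dir):
    base, manifest = fixture_dir
    mouse = SequenceSet.from_fasta(base / "homology" /
                                   "mouse_sequences.fasta")
    translated = translate_ptms(kb.enzsub, load_translator(base),
                                load_site_homology(base), mouse)
    assert len(translated) == manifest["homology"]["ptm_survivors"]
    # residue re-validation: no surviving record mismatches its target
    from crosstalk_kb.enzyme_ptm import validate_residue
    for rec in translated:
        ok, _ = validate_residue(rec.substrate.id, rec.residue_letter,
                                 rec.position, mouse)
        assert ok


def test_site_without_homology_row_dropped():
    tr = _toy_translator()
    site = PTMSiteHomology([("P0H2", 5, 10090, "P0M2", 5)])
    assert site.lookup("P0H2", 6, 10090) == set()
    assert site.lookup("P0H2", 5, 10090) == {("P0M2", 5)}


def test_empty_db_translates_empty(kb, fixture_dir):
    from crosstalk_kb.network import NetworkDB
    translated, coverage = translate_network(NetworkDB(),
                                             _toy_translator())
    assert len(translated) == 0 and coverage == 0.0
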