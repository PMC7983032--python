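"""Homology translation of proteins, interactions and PTM sites.

Orthology groups are given in a HomoloGene-style table keyed by RefSeq
protein identifiers, so translating a protein accession takes three steps:
accession -> RefSeq, RefSeq -> homologous RefSeq (same group, target
organism), homologous RefSeq -> target accession.  All paths are followed and
the union of endpoints returned.

Networks translate edge-wise (an interaction survives iff both endpoints
translate; evidence carried over unchanged).  PTM sites additionally need a
site-homology table mapping (accession, position) to the target organism's
(accession, position); translated residues are re-validated against the
target organism's isoform sequences and mismatches discarded.  Sites without
a homology row are dropped rather than carried over at the same numeric
position — alignment-based transfer is out of scope.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace

from .enzyme_ptm import EnzSubDB, PTMRecord, SequenceSet, validate_residue
from .identifiers import MappingTable
from .model import Entity
from .network import Interaction, NetworkDB


@dataclass
class HomologyTable:
    """Rows of (group id, organism taxid, RefSeq protein id)."""

    rows: list[tuple[str, int, str]]
    _by_refseq: dict[tuple[str, int], set[str]] = field(default_factory=dict)
    _by_group: dict[tuple[str, int], set[str]] = field(default_factory=dict)

    def __post_init__(self):
        for group, taxid, refseq in self.rows:
            self._by_refseq.setdefault((refseq, taxid), set()).add(group)
            self._by_group.setdefault((group, taxid), set()).add(refseq)

    @classmethod
    def from_records(cls, records) -> "HomologyTable":
        return cls([(r.fields["group"], int(r.fields["taxid"]),
                     r.fields["refseq"]) for r in records])

    def homologous_refseq(self, refseq: str, source_org: int,
                          target_org: int) -> set[str]:
        out: set[str] = set()
        for group in self._by_refseq.get((refseq, source_org), set()):
            out |= self._by_group.get((group, target_org), set())
        return out


@dataclass
class PTMSiteHomology:
    """Rows of (source accession, source position, target organism,
    target accession, target position)."""

    rows: list[tuple[str, int, int, str, int]]
    _index: dict[tuple[str, int, int], set[tuple[str, int]]] = \
        field(default_factory=dict)

    def __post_init__(self):
        for acc, pos, org, tacc, tpos in self.rows:
            if pos < 1 or tpos < 1:
                raise ValueError("positions must be >= 1")
            self._index.setdefault((acc, pos, org), set()).add((tacc, tpos))

    @classmethod
    def from_records(cls, records) -> "PTMSiteHomology":
        return cls([(r.fields["source_acc"], int(r.fields["source_pos"]),
                     int(r.fields["target_org"]), r.fields["target_acc"],
                     int(r.fields["target_pos"])) for r in records])

    def lookup(self, acc: str, pos: int, target_org: int
               ) -> set[tuple[str, int]]:
        return self._index.get((acc, pos, target_org), set())


@dataclass
class HomologyTranslator:
    """Bundles the tables needed for the three-step protein translation."""

    source_org: int
    target_org: int
    uniprot_to_refseq: MappingTable          # source organism
    refseq_to_uniprot: MappingTable          # target organism
    homology: HomologyTable
    max_targets: int = 4                     # many-to-many expansion cap
    overflow: Counter = field(default_factory=Counter)

    def translate_protein(self, accession: str) -> frozenset[str]:
        """Union over all accession -> RefSeq -> homolog -> accession paths;
        empty when any step has no mapping."""
        out: set[str] = set()
        for refseq in self.uniprot_to_refseq.lookup(accession):
            for homolog in self.homology.homologous_refseq(
                    refseq, self.source_org, self.target_org):
                out |= self.refseq_to_uniprot.lookup(homolog)
        if len(out) > self.max_targets:
            self.overflow[accession] += 1
            out = set(sorted(out)[: self.max_targets])
        return frozenset(out)


def load_translator(base, source_org: int = 9606,
                    target_org: int = 10090) -> HomologyTranslator:
    """Wire a translator from a knowledge-base directory's ``homology/``
    subdirectory (mapping tables + orthology group table)."""
    from pathlib import Path

    from .resources import ResourceDescriptor, parse_table
    hom_dir = Path(base) / "homology"
    table_path = hom_dir / "homologene.tsv"
    groups = HomologyTable.from_records(parse_table(
        table_path,
        ResourceDescriptor("homologene", str(table_path), "homology_table",
                           {"group": "group", "taxid": "taxid",
                            "refseq": "refseq"})))
    return HomologyTranslator(
        source_org, target_org,
        MappingTable.from_tsv(
            hom_dir / f"uniprot2refseq_{source_org}.tsv", "uniprot",
            "refseq"),
        MappingTable.from_tsv(
            hom_dir / f"refseq2uniprot_{target_org}.tsv", "refseq",
            "uniprot"),
        groups)


def load_site_homology(base) -> PTMSiteHomology:
    from pathlib import Path

    from .resources import ResourceDescriptor, parse_table
    path = Path(base) / "homology" / "ptm_site_homology.tsv"
    fields = {"source_acc": "source_acc", "source_pos": "source_pos",
              "target_org": "target_org", "target_acc": "target_acc",
              "target_pos": "target_pos"}
    return PTMSiteHomology.from_records(parse_table(
        path, ResourceDescriptor("ptm_site_homology", str(path),
                                 "site_homology_table", fields)))


def translate_network(db: NetworkDB, translator: HomologyTranslator
                      ) -> tuple[NetworkDB, float]:
    """Translate all protein-protein interactions to the target organism.

    Returns (translated database, coverage), coverage being the fraction of
    original interactions surviving.  Non-protein endpoints do not translate;
    many-to-many mappings expand to all endpoint combinations with evidence
    carried over unchanged.
    """
    out = NetworkDB()
    survivors = 0
    for i in db:
        if i.a.kind != "protein" or i.b.kind != "protein":
            out.dropped[("homology", "non_protein_endpoint")] += 1
            continue
        targets_a = translator.translate_protein(i.a.id)
        targets_b = translator.translate_protein(i.b.id)
        if not targets_a or not targets_b:
            out.dropped[("homology", "untranslatable_endpoint")] += 1
            continue
        survivors += 1
        for ta in sorted(targets_a):
            for tb in sorted(targets_b):
                for ev in i.evidences.values():
                    # evidence direction is relative to (a, b); re-add with
                    # source/target expressed explicitly so canonicalization
                    # in the target space stays consistent.
                    if ev.direction == "b_to_a":
                        out.add(Entity("protein", tb), Entity("protein", ta),
                                i.interaction_type,
                                replace(ev, direction="a_to_b"))
                    else:
                        out.add(Entity("protein", ta), Entity("protein", tb),
                                i.interaction_type, ev)
    coverage = survivors / len(db) if len(db) else 0.0
    return out, coverage


def translate_ptms(db: EnzSubDB, translator: HomologyTranslator,
                   site_homology: PTMSiteHomology,
                   target_seqs: SequenceSet) -> EnzSubDB:
    """Translate enzyme-PTM records to the target organism.

    The enzyme translates through the three-step protein path; the substrate
    site goes through the site-homology table; the residue letter is then
    re-validated against the target isoform sequences.
    """
    out = EnzSubDB()
    for rec in db:
        enzymes = translator.translate_protein(rec.enzyme.id)
        if not enzymes:
            out.dropped[("homology", "enzyme_untranslatable")] += 1
            continue
        sites = site_homology.lookup(rec.substrate.id, rec.position,
                                     translator.target_org)
        if not sites:
            out.dropped[("homology", "no_site_homology")] += 1
            continue
        for target_acc, target_pos in sorted(sites):
            ok, detail = validate_residue(target_acc, rec.residue_letter,
                                          target_pos, target_seqs)
            if not ok:
                out.rejected[detail] += 1
                continue
            for enzyme in sorted(enzymes):
                new = PTMRecord(Entity("protein", enzyme),
                                Entity("protein", target_acc),
                                rec.residue_letter, target_pos,
                                rec.modification, detail)
                for ev in rec.evidences.values():
                    out.add(new, ev)
    return out
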