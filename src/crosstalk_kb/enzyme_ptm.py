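"""Enzyme-PTM relationships with residue validation against isoform sequences.

An enzyme-PTM record states that an enzyme writes (or erases) a
post-translational modification at a specific residue of a substrate, e.g.
"kinase X phosphorylates serine 15 of protein Y".  Records from different
resources are merged on the five-field key (enzyme, substrate, residue,
position, modification).  Before merging, each claimed residue is checked
against the substrate's isoform sequences: a record is kept only if some
isoform actually carries the claimed amino acid at the claimed (1-based)
position; the matching isoform numbers are recorded.  Records without
literature references are kept (high-throughput / predicted sites).
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field

from Bio import SeqIO

from .model import Entity, Evidence
from .resources import RawRecord

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class SequenceSet:
    """Isoform sequences per accession; index 0 is the canonical isoform."""

    isoforms: dict[str, list[str]] = field(default_factory=dict)

    @classmethod
    def from_fasta(cls, path) -> "SequenceSet":
        """Read a multi-isoform FASTA; ``>ACC-2`` style headers accepted."""
        collected: dict[str, dict[int, str]] = {}
        for seq_record in SeqIO.parse(str(path), "fasta"):
            acc, _, iso = seq_record.id.partition("-")
            number = int(iso) if iso else 1
            collected.setdefault(acc, {})[number] = str(
                seq_record.seq).upper()
        return cls({acc: [seq for _, seq in sorted(by_iso.items())]
                    for acc, by_iso in collected.items()})

    def get(self, accession: str) -> list[str]:
        return self.isoforms.get(accession, [])


@dataclass(frozen=True, order=True)
class PTMKey:
    enzyme: str
    substrate: str
    residue_letter: str
    position: int
    modification: str


@dataclass
class PTMRecord:
    enzyme: Entity
    substrate: Entity
    residue_letter: str
    position: int
    modification: str
    isoforms: tuple[int, ...] = ()   # isoform numbers where the residue matches
    evidences: dict[tuple, Evidence] = field(default_factory=dict)

    def key(self) -> PTMKey:
        return PTMKey(self.enzyme.id, self.substrate.id, self.residue_letter,
                      self.position, self.modification)

    def add_evidence(self, ev: Evidence) -> None:
        k = ev.key()
        self.evidences[k] = self.evidences[k].merged_with(ev) \
            if k in self.evidences else ev


def validate_residue(substrate: str, residue_letter: str, position: int,
                     seqs: SequenceSet):
    """Check a claimed residue against all isoform sequences.

    Returns ``(True, isoform_numbers)`` when some isoform carries
    ``residue_letter`` at the 1-based ``position``; otherwise
    ``(False, reason)`` with reason in {"no_sequence", "residue_mismatch"}.
    """
    sequences = seqs.get(substrate)
    if not sequences:
        return False, "no_sequence"
    matches = tuple(n for n, seq in enumerate(sequences, start=1)
                    if position <= len(seq)
                    and seq[position - 1] == residue_letter)
    if matches:
        return True, matches
    return False, "residue_mismatch"


class EnzSubDB:
    """Merged enzyme-PTM store keyed by the five-field site key."""

    def __init__(self):
        self.records: dict[PTMKey, PTMRecord] = {}
        self.rejected: Counter = Counter()   # reason -> count
        self.dropped: Counter = Counter()    # (resource, reason) -> count

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records.values())

    def add(self, rec: PTMRecord, ev: Evidence) -> None:
        key = rec.key()
        if key not in self.records:
            self.records[key] = rec
        self.records[key].add_evidence(ev)

    def modification_histogram(self) -> Counter:
        return Counter(r.modification for r in self)


def merge_ptms(records: list[RawRecord], id_service, seqs: SequenceSet,
               id_space_of: dict[str, str] | None = None,
               dataset: str = "omnipath") -> EnzSubDB:
    """Translate, validate and merge raw enzyme-substrate rows.

    Ambiguous identifier mappings expand to all enzyme/substrate
    combinations; each expanded substrate is validated independently.
    """
    db = EnzSubDB()
    id_space_of = id_space_of or {}
    for rec in records:
        space = id_space_of.get(rec.resource, "uniprot")
        enzymes = id_service.map_id(rec.fields["enzyme"], space, "protein")
        substrates = id_service.map_id(rec.fields["substrate"], space,
                                       "protein")
        if not enzymes or not substrates:
            db.dropped[(rec.resource, "unmappable")] += 1
            continue
        letter = rec.fields["residue_type"].upper()
        try:
            position = int(rec.fields["residue_offset"])
        except ValueError:
            db.dropped[(rec.resource, "bad_position")] += 1
            continue
        if letter not in STANDARD_AA or position < 1:
            db.dropped[(rec.resource, "bad_residue")] += 1
            continue
        refs = frozenset(r for r in rec.fields.get(
            "references", "").split(";") if r)
        ev = Evidence(rec.resource, refs, dataset, "a_to_b", "unknown")
        for substrate in sorted(substrates):
            ok, detail = validate_residue(substrate, letter, position, seqs)
            if not ok:
                db.rejected[detail] += 1
                continue
            for enzyme in sorted(enzymes):
                record = PTMRecord(Entity("protein", enzyme),
                                   Entity("protein", substrate), letter,
                                   position, rec.fields["modification"],
                                   detail)
                db.add(record, ev)
    return db


def classify_target(rec: PTMRecord, complex_db) -> str:
    """Classify a PTM by its target: the enzyme itself, a protein sharing a
    complex with the enzyme, or an independent protein."""
    if rec.enzyme.id == rec.substrate.id:
        return "self"
    if complex_db.share_complex(rec.enzyme.id, rec.substrate.id):
        return "within_complex"
    return "independent"


EXPORT_COLUMNS = ("enzyme", "substrate", "residue_type", "residue_offset",
                  "modification", "isoforms", "sources", "references")


def export_tsv(db: EnzSubDB) -> str:
    buf = io.StringIO()
    buf.write("\t".join(EXPORT_COLUMNS) + "\n")
    for key in sorted(db.records):
        r = db.records[key]
        refs = set().union(*(e.references for e in r.evidences.values()))
        row = (r.enzyme.id, r.substrate.id, r.residue_letter,
               str(r.position), r.modification,
               ";".join(str(n) for n in r.isoforms),
               ";".join(sorted({e.resource for e in r.evidences.values()})),
               ";".join(sorted(refs)))
        buf.write("\t".join(row) + "\n")
    return buf.getvalue()
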