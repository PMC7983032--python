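"""Non-redundant protein-complex database keyed by unique component sets.

A complex is defined by its unique combination of members, regardless of how
the original resource processed the underlying data.  The canonical identity
is the component accessions sorted alphabetically, joined by underscores and
prefixed with ``COMPLEX:`` — a homomultimer therefore collapses to a single
accession.  Records sharing an identity are merged; synonyms, PDB ids and
evidences are unioned, and stoichiometry is preserved when the contributing
records agree (or only one asserts it) and flagged when they conflict.
"""

from __future__ import annotations

import io
import itertools
from collections import Counter
from dataclasses import dataclass, field

from .model import COMPLEX_PREFIX, Entity, Evidence
from .resources import RawRecord


def complex_identity(components) -> str:
    """Canonical identity string of a component collection."""
    unique = sorted(set(components))
    if not unique:
        raise ValueError("complex needs at least one component")
    return COMPLEX_PREFIX + "_".join(unique)


@dataclass
class ComplexRecord:
    components: dict[str, int | None]      # accession -> copy number (or None)
    identity: str
    synonyms: set[str] = field(default_factory=set)
    pdb_ids: set[str] = field(default_factory=set)
    evidences: dict[tuple, Evidence] = field(default_factory=dict)
    stoichiometry_conflict: bool = False
    stoichiometry_variants: list[dict[str, int]] = field(default_factory=list)

    @property
    def is_homomultimer(self) -> bool:
        return len(self.components) == 1

    @property
    def has_stoichiometry(self) -> bool:
        return not self.stoichiometry_conflict and any(
            n is not None for n in self.components.values())

    def entity(self) -> Entity:
        return Entity("complex", self.identity)

    def add_evidence(self, ev: Evidence) -> None:
        k = ev.key()
        self.evidences[k] = self.evidences[k].merged_with(ev) \
            if k in self.evidences else ev


class ComplexDB:
    def __init__(self):
        self.records: dict[str, ComplexRecord] = {}
        self.dropped: Counter = Counter()
        self._member_index: dict[str, set[str]] | None = None

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records.values())

    def _index(self) -> dict[str, set[str]]:
        if self._member_index is None:
            self._member_index = {}
            for identity, rec in self.records.items():
                for acc in rec.components:
                    self._member_index.setdefault(acc, set()).add(identity)
        return self._member_index

    def share_complex(self, acc_a: str, acc_b: str) -> bool:
        """True when some complex contains both proteins."""
        idx = self._index()
        return bool(idx.get(acc_a, set()) & idx.get(acc_b, set()))

    def summary(self) -> dict[str, float]:
        n = len(self) or 1
        return {
            "n_complexes": len(self),
            "homomultimer_fraction":
                sum(r.is_homomultimer for r in self) / n,
            "le4_unique_components_fraction":
                sum(len(r.components) <= 4 for r in self) / n,
            "with_stoichiometry_fraction":
                sum(r.has_stoichiometry for r in self) / n,
        }


def _merge_stoichiometry(target: ComplexRecord,
                         stoich: dict[str, int] | None) -> None:
    """Agree-or-single-assertion policy; disagreement keeps every variant and
    raises the conflict flag while counts revert to unknown."""
    if stoich is None:
        return
    if stoich not in target.stoichiometry_variants:
        target.stoichiometry_variants.append(stoich)
    if len(target.stoichiometry_variants) == 1:
        if not target.stoichiometry_conflict:
            target.components = dict(stoich)
    else:
        target.stoichiometry_conflict = True
        target.components = {acc: None for acc in target.components}


def merge_complexes(records: list[RawRecord], id_service,
                    id_space_of: dict[str, str] | None = None,
                    dataset: str = "omnipath") -> ComplexDB:
    """Translate component identifiers and merge on identical component sets.

    Raw rows carry ``components`` as a ``;``-separated accession list with an
    optional parallel ``stoichiometry`` count list, plus optional ``name``,
    ``pdb`` and ``references`` fields.  Components failing translation drop
    the whole record (counted); ambiguous components expand the complex by
    cartesian product, mirroring entity translation.
    """
    db = ComplexDB()
    id_space_of = id_space_of or {}
    for rec in records:
        space = id_space_of.get(rec.resource, "uniprot")
        raw_components = [c for c in rec.fields["components"].split(";") if c]
        counts_raw = [c for c in rec.fields.get(
            "stoichiometry", "").split(";") if c]
        counts = None
        if counts_raw and len(counts_raw) == len(raw_components):
            counts = [int(c) for c in counts_raw]
        translated: list[list[str]] = []
        ok = True
        for component in raw_components:
            hits = id_service.map_id(component, space, "protein")
            if not hits:
                ok = False
                break
            translated.append(sorted(hits))
        if not ok or not translated:
            db.dropped[(rec.resource, "unmappable_component")] += 1
            continue
        refs = frozenset(r for r in rec.fields.get(
            "references", "").split(";") if r)
        ev = Evidence(rec.resource, refs, dataset)
        for combo in itertools.product(*translated):
            identity = complex_identity(combo)
            stoich = None
            if counts is not None:
                stoich = {}
                for acc, n in zip(combo, counts):
                    stoich[acc] = stoich.get(acc, 0) + n
            if identity not in db.records:
                components = {acc: None for acc in sorted(set(combo))}
                db.records[identity] = ComplexRecord(components, identity)
            target = db.records[identity]
            if rec.fields.get("name"):
                target.synonyms.add(rec.fields["name"])
            target.pdb_ids.update(
                p for p in rec.fields.get("pdb", "").split(";") if p)
            target.add_evidence(ev)
            _merge_stoichiometry(target, stoich)
    db._member_index = None
    return db


EXPORT_COLUMNS = ("identity", "components", "stoichiometry_conflict",
                  "synonyms", "pdb_ids", "sources", "references")


def export_tsv(db: ComplexDB) -> str:
    buf = io.StringIO()
    buf.write("\t".join(EXPORT_COLUMNS) + "\n")
    for identity in sorted(db.records):
        r = db.records[identity]
        comps = "_".join(
            acc if r.components[acc] is None else f"{acc}:{r.components[acc]}"
            for acc in sorted(r.components))
        refs = set().union(*(e.references for e in r.evidences.values())) \
            if r.evidences else set()
        row = (identity, comps, str(int(r.stoichiometry_conflict)),
               ";".join(sorted(r.synonyms)), ";".join(sorted(r.pdb_ids)),
               ";".join(sorted({e.resource for e in r.evidences.values()})),
               ";".join(sorted(refs)))
        buf.write("\t".join(row) + "\n")
    return buf.getvalue()
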