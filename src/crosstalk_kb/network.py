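"""Merged molecular-interaction network with per-evidence provenance.

Pairwise connections from many resources are translated into reference
identifiers and merged into one typed network.  An interaction is keyed by its
canonically ordered endpoint pair and interaction type; all per-resource
claims survive as :class:`~crosstalk_kb.model.Evidence` objects carrying
literature references, direction and effect sign.  Direction/sign consensus is
computed on demand by a majority rule with explicit contradiction flags — the
raw evidences are always preserved so users can apply their own policy.

Datasets (activity-flow core, kinase-substrate extensions, ligand-receptor
collections, graded TF regulons, miRNA interactions, ...) are views over the
same merged store, selected by evidence tags.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field, replace

from .model import (CONFIDENCE_ORDER, DATASET_ENDPOINT_KINDS,
                    DATASET_INTERACTION_TYPE, DATASET_TAGS, ConfigError,
                    Entity, Evidence)
from .resources import RawRecord

_FLIP = {"a_to_b": "b_to_a", "b_to_a": "a_to_b", "undirected": "undirected"}

_SIGN_CODES = {"+": "stimulation", "-": "inhibition", "": "unknown",
               "0": "unknown", "stimulation": "stimulation",
               "inhibition": "inhibition", "unknown": "unknown"}


@dataclass
class Interaction:
    """A typed source/target pair with all supporting evidences.

    Endpoints are stored in canonical (lexicographic) order; direction is
    encoded on the evidences relative to (a, b), so reciprocal claims A->B and
    B->A live on one interaction as both-direction evidences.
    """

    a: Entity
    b: Entity
    interaction_type: str
    evidences: dict[tuple, Evidence] = field(default_factory=dict)

    def key(self) -> tuple:
        return (self.a, self.b, self.interaction_type)

    def add_evidence(self, ev: Evidence) -> None:
        k = ev.key()
        self.evidences[k] = self.evidences[k].merged_with(ev) \
            if k in self.evidences else ev

    def resources(self) -> set[str]:
        return {e.resource for e in self.evidences.values()}

    def references(self) -> set[str]:
        return set().union(*(e.references for e in self.evidences.values())) \
            if self.evidences else set()

    def datasets(self) -> set[str]:
        return {e.dataset for e in self.evidences.values()}

    def directions_asserted(self) -> set[str]:
        """Directions claimed by at least one evidence (excl. undirected)."""
        return {e.direction for e in self.evidences.values()
                if e.direction != "undirected"}


@dataclass(frozen=True)
class Consensus:
    directed: bool
    direction: str | None
    sign: str | None
    contradictory_direction: bool
    contradictory_sign: bool


def consensus(interaction: Interaction) -> Consensus:
    """Majority-with-flags consensus over an interaction's evidences.

    Directed if any evidence asserts a direction.  Direction and sign are each
    decided by strict majority over the evidences that assert one; opposing
    assertions raise the corresponding contradiction flag, and a tie leaves
    the consensus unset.  Undirected / unknown-sign evidences abstain.
    """
    evs = list(interaction.evidences.values())
    if not evs:
        raise ValueError("interaction without evidence")
    n_ab = sum(1 for e in evs if e.direction == "a_to_b")
    n_ba = sum(1 for e in evs if e.direction == "b_to_a")
    directed = (n_ab + n_ba) > 0
    contra_dir = n_ab > 0 and n_ba > 0
    direction = None
    if n_ab != n_ba:
        direction = "a_to_b" if n_ab > n_ba else "b_to_a"
    n_stim = sum(1 for e in evs if e.sign == "stimulation")
    n_inh = sum(1 for e in evs if e.sign == "inhibition")
    contra_sign = n_stim > 0 and n_inh > 0
    sign = None
    if n_stim != n_inh:
        sign = "stimulation" if n_stim > n_inh else "inhibition"
    return Consensus(directed, direction, sign, contra_dir, contra_sign)


class NetworkDB:
    """The merged interaction store."""

    def __init__(self):
        self.interactions: dict[tuple, Interaction] = {}
        self.dropped: Counter = Counter()

    def __len__(self):
        return len(self.interactions)

    def __iter__(self):
        return iter(self.interactions.values())

    def add(self, source: Entity, target: Entity, interaction_type: str,
            ev: Evidence) -> None:
        """Insert one claim, canonicalizing endpoint order.

        ``ev.direction`` of ``a_to_b`` is interpreted as source->target and
        re-expressed relative to the stored (a, b) order.
        """
        if (target, source) < (source, target):
            a, b = target, source
            direction = _FLIP[ev.direction]
        else:
            a, b = source, target
            direction = ev.direction
        ev = replace(ev, direction=direction)
        key = (a, b, interaction_type)
        if key not in self.interactions:
            self.interactions[key] = Interaction(a, b, interaction_type)
        self.interactions[key].add_evidence(ev)

    def nodes(self) -> set[Entity]:
        out = set()
        for i in self:
            out.update((i.a, i.b))
        return out

    def merge_with(self, other: "NetworkDB") -> "NetworkDB":
        """Union of two stores; evidences dedup by key, references union."""
        merged = NetworkDB()
        for db in (self, other):
            for i in db:
                for ev in i.evidences.values():
                    key = i.key()
                    if key not in merged.interactions:
                        merged.interactions[key] = Interaction(
                            i.a, i.b, i.interaction_type)
                    merged.interactions[key].add_evidence(ev)
        merged.dropped = self.dropped + other.dropped
        return merged

    def directed_edges(self) -> set[tuple[Entity, Entity]]:
        """(source, target) pairs asserted by at least one evidence."""
        out = set()
        for i in self:
            for d in i.directions_asserted():
                out.add((i.a, i.b) if d == "a_to_b" else (i.b, i.a))
        return out


def merge_interactions(records: list[RawRecord], id_service,
                       dataset_of: dict[str, str],
                       id_space_of: dict[str, str] | None = None) -> NetworkDB:
    """Build the network database from parsed interaction rows.

    ``dataset_of`` maps resource name -> dataset tag (declarative, from the
    registry).  Endpoints are translated to reference identifiers; rows with
    any unmappable endpoint are dropped and counted, ambiguous mappings expand
    to all endpoint combinations.  Self-loops are kept.
    """
    db = NetworkDB()
    id_space_of = id_space_of or {}
    for rec in records:
        tag = dataset_of.get(rec.resource)
        if tag not in DATASET_TAGS:
            raise ConfigError(
                f"resource {rec.resource!r} has no valid dataset tag: {tag!r}")
        src_kind, tgt_kind = DATASET_ENDPOINT_KINDS[tag]
        space = id_space_of.get(rec.resource, "genesymbol")
        sources = id_service.map_id(rec.fields["source"], _space_for(
            space, src_kind), src_kind)
        targets = id_service.map_id(rec.fields["target"], _space_for(
            space, tgt_kind), tgt_kind)
        if not sources or not targets:
            db.dropped[(rec.resource, "unmappable_endpoint")] += 1
            continue
        directed = rec.fields.get("is_directed", "1") not in ("0", "", "no")
        sign = _SIGN_CODES.get(rec.fields.get("sign", ""), "unknown")
        refs = frozenset(r for r in rec.fields.get(
            "references", "").split(";") if r)
        conf = rec.fields.get("confidence") or None
        if tag == "dorothea" and conf not in tuple(CONFIDENCE_ORDER):
            db.dropped[(rec.resource, "bad_confidence")] += 1
            continue
        ev = Evidence(rec.resource, refs, tag,
                      "a_to_b" if directed else "undirected", sign, conf)
        itype = DATASET_INTERACTION_TYPE[tag]
        for s in sorted(sources):
            for t in sorted(targets):
                db.add(Entity(src_kind, s), Entity(tgt_kind, t), itype, ev)
    return db


def _space_for(space: str, kind: str) -> str:
    # miRNA / lncRNA ids come in their own (already primary) namespaces.
    if kind == "mirna":
        return "mirbase_mature"
    if kind == "lncrna":
        return "lncrna"
    return space


def dataset_view(db: NetworkDB, tags, min_confidence: str | None = None
                 ) -> NetworkDB:
    """Restrict to evidences in the given dataset tags.

    Graded TF-regulon evidences are additionally filtered to
    confidence <= ``min_confidence`` in the order A<B<C<D.  Interactions left
    without evidence disappear from the view.
    """
    tags = set(tags)
    unknown = tags - set(DATASET_TAGS)
    if unknown:
        raise ConfigError(f"unknown dataset tag(s): {sorted(unknown)}")
    view = NetworkDB()
    for i in db:
        kept = [e for e in i.evidences.values() if e.dataset in tags]
        if min_confidence is not None:
            cutoff = CONFIDENCE_ORDER.index(min_confidence)
            kept = [e for e in kept
                    if e.dataset != "dorothea"
                    or (e.confidence is not None
                        and CONFIDENCE_ORDER.index(e.confidence) <= cutoff)]
        if kept:
            ni = Interaction(i.a, i.b, i.interaction_type)
            for e in kept:
                ni.add_evidence(e)
            view.interactions[ni.key()] = ni
    return view


def coverage_stats(db: NetworkDB, protein_sets: dict[str, set[str]]
                   ) -> dict[str, tuple[float, int]]:
    """Fraction of each named protein set present as a network node."""
    node_ids = {e.id for e in db.nodes()}
    out = {}
    for name, members in protein_sets.items():
        covered = len(set(members) & node_ids)
        out[name] = (covered / len(members) if members else 0.0, covered)
    return out


EXPORT_COLUMNS = ("source", "target", "source_kind", "target_kind", "type",
                  "is_directed", "consensus_direction", "consensus_sign",
                  "contradictory_direction", "contradictory_sign", "sources",
                  "datasets", "references", "n_evidences")


def export_tsv(db: NetworkDB) -> str:
    """Deterministic tab-separated export (sorted rows and cells)."""
    buf = io.StringIO()
    buf.write("\t".join(EXPORT_COLUMNS) + "\n")
    for key in sorted(db.interactions,
                      key=lambda k: (k[2], k[0].id, k[1].id)):
        i = db.interactions[key]
        c = consensus(i)
        cons_dir = ""
        if c.direction == "a_to_b":
            cons_dir = f"{i.a.id}->{i.b.id}"
        elif c.direction == "b_to_a":
            cons_dir = f"{i.b.id}->{i.a.id}"
        row = (i.a.id, i.b.id, i.a.kind, i.b.kind, i.interaction_type,
               str(int(c.directed)), cons_dir, c.sign or "",
               str(int(c.contradictory_direction)),
               str(int(c.contradictory_sign)),
               ";".join(sorted(i.resources())),
               ";".join(sorted(i.datasets())),
               ";".join(sorted(i.references())),
               str(len(i.evidences)))
        buf.write("\t".join(row) + "\n")
    return buf.getvalue()


def export_sif(db: NetworkDB) -> str:
    """Three-column SIF export over directed consensus edges."""
    lines = []
    for i in db:
        c = consensus(i)
        rel = {"stimulation": "stimulates", "inhibition": "inhibits",
               None: "interacts"}[c.sign]
        if c.direction == "b_to_a":
            lines.append(f"{i.b.id}\t{rel}\t{i.a.id}")
        else:
            lines.append(f"{i.a.id}\t{rel}\t{i.b.id}")
    return "\n".join(sorted(lines)) + ("\n" if lines else "")
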