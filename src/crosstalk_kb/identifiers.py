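"""Identifier normalization and translation to reference identifier spaces.

Resource files label molecules inconsistently: gene symbols with extra dashes
("IL-6"), Greek glyphs ("TNFα"), deprecated accessions, and identifiers from
foreign namespaces.  This module normalizes labels, and translates foreign
identifiers into the reference space of each entity kind (proteins: UniProt
accessions, miRNAs: miRBase mature accessions), *keeping every candidate* when
a foreign identifier is ambiguous — downstream merges expand over all of them
rather than silently picking one.

Deprecated/secondary protein accessions are recovered through a two-hop
bridge: secondary accession -> primary gene symbol -> primary accession(s).
"""

from __future__ import annotations

import itertools
import logging
import re
from collections import Counter
from dataclasses import dataclass, field

from .model import COMPLEX_PREFIX, ConfigError, Entity

log = logging.getLogger(__name__)

#: Default Greek-glyph substitutions applied by :func:`normalize_label`.
#: Both lowercase and capital glyphs map to single Latin letters, following
#: common gene-symbol usage (TNFα == TNFA, IFNγ == IFNG).
DEFAULT_GREEK = {
    "α": "A", "Α": "A",
    "β": "B", "Β": "B",
    "γ": "G", "Γ": "G",
    "δ": "D", "Δ": "D",
    "ε": "E", "Ε": "E",
    "ζ": "Z", "Ζ": "Z",
    "η": "H", "Η": "H",
    "θ": "T", "Θ": "T",
    "κ": "K", "Κ": "K",
    "λ": "L", "Λ": "L",
    "μ": "M", "Μ": "M",
    "σ": "S", "Σ": "S",
    "ω": "O", "Ω": "O",
}

_DASH_RUN = re.compile(r"[-‐‑‒–—]+")


def normalize_label(raw: str, greek: dict[str, str] | None = None,
                    strip_dashes: bool = True) -> str:
    """Canonicalize a molecule label.

    Upper-cases, replaces configured Greek glyphs with Latin spellings and
    removes runs of hyphens/en-dashes.  Unknown glyphs pass through.  The
    operation is idempotent.
    """
    if not raw:
        raise ValueError("label must be non-empty")
    table = DEFAULT_GREEK if greek is None else greek
    # upper-case first: some glyphs (e.g. the micro sign) only become Greek
    # capitals on upper-casing, and substitution must still catch them.
    out = raw.upper()
    out = "".join(table.get(ch, ch) for ch in out)
    if strip_dashes:
        out = _DASH_RUN.sub("", out)
    return out


@dataclass(frozen=True)
class IdentifierSpace:
    """A namespace of identifiers for one organism."""

    name: str
    organism: int = 9606

    def __post_init__(self):
        if not self.name:
            raise ConfigError("identifier space needs a non-empty name")


def _space_name(space) -> str:
    return space.name if isinstance(space, IdentifierSpace) else str(space)


@dataclass
class MappingTable:
    """Many-to-many (foreign id -> reference id) lookup.

    ``case_insensitive`` keys are stored normalized (used for gene symbols);
    accession spaces stay case-sensitive.
    """

    from_space: str
    to_space: str
    pairs: dict[str, frozenset[str]] = field(default_factory=dict)
    case_insensitive: bool = False

    def _key(self, value: str) -> str:
        return normalize_label(value) if self.case_insensitive else value

    @classmethod
    def from_pairs(cls, from_space, to_space, pairs,
                   case_insensitive: bool = False) -> "MappingTable":
        table = cls(_space_name(from_space), _space_name(to_space),
                    {}, case_insensitive)
        acc: dict[str, set[str]] = {}
        for foreign, ref in pairs:
            acc.setdefault(table._key(foreign), set()).add(ref)
        table.pairs = {k: frozenset(v) for k, v in acc.items()}
        return table

    @classmethod
    def from_tsv(cls, path, from_space, to_space,
                 case_insensitive: bool = False) -> "MappingTable":
        """Read a 2-column tab-separated file with header ``foreign\\treference``."""
        pairs = []
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
            if "\t" not in header:
                raise ConfigError(f"not a 2-column mapping table: {path}")
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                foreign, ref = line.split("\t")[:2]
                pairs.append((foreign, ref))
        return cls.from_pairs(from_space, to_space, pairs, case_insensitive)

    def lookup(self, value: str) -> frozenset[str]:
        return self.pairs.get(self._key(value), frozenset())


@dataclass
class ReferenceSet:
    """The set of primary identifiers of one space, plus the
    secondary-accession bridge tables (secondary -> symbol -> primary)."""

    space: IdentifierSpace
    primary_ids: frozenset[str]
    secondary_to_symbol: MappingTable | None = None
    symbol_to_primary: MappingTable | None = None

    @classmethod
    def from_file(cls, path, space, **bridges) -> "ReferenceSet":
        with open(path, encoding="utf-8") as fh:
            ids = frozenset(line.strip() for line in fh
                            if line.strip() and not line.startswith("#"))
        if not isinstance(space, IdentifierSpace):
            space = IdentifierSpace(str(space))
        return cls(space, ids, **bridges)


def map_id(value: str, from_space, ref: ReferenceSet,
           tables: list[MappingTable]) -> frozenset[str]:
    """All reference identifiers reachable from ``value``.

    Direct tables from ``from_space`` to the reference space are applied
    first; if the value lives in the reference space itself, the primary
    identity short-circuit and the deprecated-accession two-hop bridge are
    tried.  Multi-hop chains beyond the bridge are deliberately not followed.
    Returns the empty set when unmappable; never picks one of several
    candidates.
    """
    fs = _space_name(from_space)
    ref_name = ref.space.name
    if fs == ref_name and value in ref.primary_ids:
        return frozenset({value})
    out: set[str] = set()
    for table in tables:
        if table.from_space == fs and table.to_space == ref_name:
            out |= table.lookup(value)
    if not out and fs == ref_name and ref.secondary_to_symbol is not None \
            and ref.symbol_to_primary is not None:
        for symbol in ref.secondary_to_symbol.lookup(value):
            out |= ref.symbol_to_primary.lookup(symbol)
    return frozenset(out & ref.primary_ids)


class IdService:
    """Registry of reference sets and mapping tables per entity kind.

    Unmapped identifiers are counted (``unmapped``), never raised: a batch
    build must not abort because one resource labels a molecule obscurely.
    """

    def __init__(self):
        self.references: dict[str, ReferenceSet] = {}
        self.tables: list[MappingTable] = []
        self._spaces: set[str] = set()
        self.unmapped: Counter = Counter()

    def register_reference(self, kind: str, ref: ReferenceSet) -> None:
        self.references[kind] = ref
        self._spaces.add(ref.space.name)

    def register_table(self, table: MappingTable) -> None:
        self.tables.append(table)
        self._spaces.update((table.from_space, table.to_space))

    def map_id(self, value: str, from_space, kind: str = "protein"
               ) -> frozenset[str]:
        fs = _space_name(from_space)
        if fs not in self._spaces:
            raise ConfigError(f"unknown identifier space: {fs!r}")
        if kind not in self.references:
            raise ConfigError(f"no reference space registered for {kind!r}")
        hits = map_id(value, fs, self.references[kind], self.tables)
        if not hits:
            self.unmapped[(fs, value)] += 1
        return hits

    def translate_entity(self, entity: Entity, from_space="uniprot"
                         ) -> frozenset[Entity]:
        """Translate an entity; complexes translate component-wise.

        A complex survives only if *every* component translates; ambiguous
        components expand the complex by cartesian product.
        """
        if entity.is_complex:
            per_component = []
            for acc in entity.components():
                hits = self.map_id(acc, from_space, "protein")
                if not hits:
                    return frozenset()
                per_component.append(sorted(hits))
            out = set()
            for combo in itertools.product(*per_component):
                ident = COMPLEX_PREFIX + "_".join(sorted(set(combo)))
                out.add(Entity("complex", ident))
            return frozenset(out)
        hits = self.map_id(entity.id, from_space, entity.kind)
        return frozenset(Entity(entity.kind, h) for h in hits)
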