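"""Core domain types shared by all database segments.

An *entity* is any molecule (or complex of molecules) that can appear as an
endpoint of an interaction or carry an annotation.  Each entity kind has one
reference identifier space (proteins: UniProt accessions; miRNAs: miRBase
mature accessions); complexes are identified by a canonical ``COMPLEX:`` string
listing their unique components.

*Evidence* objects attach provenance (resource of origin, literature
references, dataset membership) to every merged record, so the integrated
databases stay fully traceable to their sources.
"""

from __future__ import annotations

from dataclasses import dataclass, field

COMPLEX_PREFIX = "COMPLEX:"

ENTITY_KINDS = ("protein", "mirna", "lncrna", "complex")

#: The nine network dataset tags.
DATASET_TAGS = (
    "omnipath",
    "pathwayextra",
    "kinaseextra",
    "ligrecextra",
    "dorothea",
    "tf_target",
    "post_transcriptional",
    "tf_mirna",
    "lncrna_mrna",
)

#: TF-target confidence grades, best first (grade E is never imported).
CONFIDENCE_ORDER = "ABCD"

#: Interaction type implied by each dataset tag.
DATASET_INTERACTION_TYPE = {
    "omnipath": "post_translational",
    "pathwayextra": "post_translational",
    "kinaseextra": "post_translational",
    "ligrecextra": "post_translational",
    "dorothea": "transcriptional",
    "tf_target": "transcriptional",
    "post_transcriptional": "post_transcriptional",
    "tf_mirna": "mirna_transcriptional",
    "lncrna_mrna": "lncrna_post_transcriptional",
}

#: Default entity kinds of (source, target) per dataset tag.
DATASET_ENDPOINT_KINDS = {
    "omnipath": ("protein", "protein"),
    "pathwayextra": ("protein", "protein"),
    "kinaseextra": ("protein", "protein"),
    "ligrecextra": ("protein", "protein"),
    "dorothea": ("protein", "protein"),
    "tf_target": ("protein", "protein"),
    "post_transcriptional": ("mirna", "protein"),
    "tf_mirna": ("protein", "mirna"),
    "lncrna_mrna": ("lncrna", "protein"),
}

DIRECTIONS = ("a_to_b", "b_to_a", "undirected")
SIGNS = ("stimulation", "inhibition", "unknown")


@dataclass(frozen=True, order=True)
class Entity:
    """A molecule with one reference identifier.

    ``kind`` is one of :data:`ENTITY_KINDS`; complexes carry their canonical
    ``COMPLEX:`` identity string as ``id``.
    """

    kind: str
    id: str

    @property
    def is_complex(self) -> bool:
        return self.kind == "complex"

    def components(self) -> tuple[str, ...]:
        """Unique components of a complex entity (empty for non-complexes)."""
        if not self.is_complex:
            return ()
        return tuple(self.id[len(COMPLEX_PREFIX):].split("_"))


@dataclass(frozen=True)
class Evidence:
    """One resource's claim about a record.

    ``direction`` and ``sign`` are expressed relative to the canonically
    ordered endpoints of the interaction the evidence is attached to.
    ``confidence`` is only used by graded TF-target regulon evidences.
    """

    resource: str
    references: frozenset[str] = frozenset()
    dataset: str = "omnipath"
    direction: str = "undirected"
    sign: str = "unknown"
    confidence: str | None = None

    def key(self) -> tuple:
        """Deduplication key: at most one evidence per (resource, dataset,
        direction, sign, confidence) — references are unioned on merge."""
        return (self.resource, self.dataset, self.direction, self.sign,
                self.confidence)

    def merged_with(self, other: "Evidence") -> "Evidence":
        assert self.key() == other.key()
        return Evidence(self.resource, self.references | other.references,
                        self.dataset, self.direction, self.sign,
                        self.confidence)


class ConfigError(ValueError):
    """Raised on invalid configuration (unknown space, dataset tag, ...)."""


class FormatError(ValueError):
    """Raised on malformed resource files or expressions."""
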