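"""Intercellular-communication role categories.

Proteins (and complexes) play roles in communication between cells: they
transmit signals (ligands, ECM components, secreted enzymes), receive them
(receptors, adhesion proteins, transporters), or sit in locations enabling
either (secreted, plasma-membrane transmembrane/peripheral).  Categories are
*functional* or *locational*, *generic* or *specific*, and each carries
transmitter/receiver and location flags inherited by every member row.

Membership comes from three kinds of contributors: explicit per-resource role
tables, Boolean expressions over Gene Ontology annotations, and *composite*
categories formed as the union of all contributors minus a curated exclusion
list (standing in for manual curation of wrong source annotations).  A
complex belongs to a category if and only if all its members belong to it.
"""

from __future__ import annotations

from dataclasses import dataclass

import yaml

from .model import ConfigError, FormatError

# ---------------------------------------------------------------- GO algebra

TERM, AND, OR, NOT = "term", "and", "or", "not"


def parse_go_expression(text: str):
    """Parse an s-expression like ``(and GO:0005102 (not GO:0004888))``.

    Leaves are GO identifiers; operators are ``and``, ``or``, ``not``.
    """
    tokens = text.replace("(", " ( ").replace(")", " ) ").split()
    pos = 0

    def read():
        nonlocal pos
        if pos >= len(tokens):
            raise FormatError(f"unbalanced expression: {text!r}")
        token = tokens[pos]
        pos += 1
        if token == "(":
            if pos >= len(tokens):
                raise FormatError(f"unbalanced expression: {text!r}")
            op = tokens[pos].lower()
            pos += 1
            children = []
            while pos < len(tokens) and tokens[pos] != ")":
                children.append(read())
            if pos >= len(tokens):
                raise FormatError(f"unbalanced expression: {text!r}")
            pos += 1
            if op == NOT:
                if len(children) != 1:
                    raise FormatError("'not' takes exactly one operand")
                return (NOT, children[0])
            if op in (AND, OR):
                return (op, children)
            raise FormatError(f"unknown operator: {op!r}")
        if token == ")":
            raise FormatError(f"unbalanced expression: {text!r}")
        return (TERM, token)

    expr = read()
    if pos != len(tokens):
        raise FormatError(f"trailing tokens in expression: {text!r}")
    return expr


def evaluate_go_expression(expr, terms: set[str]) -> bool:
    """Standard Boolean semantics over an entity's GO term set."""
    op = expr[0]
    if op == TERM:
        return expr[1] in terms
    if op == NOT:
        return not evaluate_go_expression(expr[1], terms)
    if op == AND:
        return all(evaluate_go_expression(c, terms) for c in expr[1])
    if op == OR:
        return any(evaluate_go_expression(c, terms) for c in expr[1])
    raise FormatError(f"unknown operator: {op!r}")


def load_gaf(records) -> dict[str, set[str]]:
    """Entity -> GO term set from GAF-style raw records (fields
    ``entity`` and ``go_id``)."""
    out: dict[str, set[str]] = {}
    for rec in records:
        out.setdefault(rec.fields["entity"], set()).add(rec.fields["go_id"])
    return out


# ---------------------------------------------------------------- categories

@dataclass(frozen=True)
class IntercellCategory:
    name: str
    database: str                    # resource name, "go", or "composite"
    aspect: str = "functional"       # functional | locational
    scope: str = "generic"           # generic | specific
    parent: str | None = None
    transmitter: bool = False
    receiver: bool = False
    secreted: bool = False
    plasma_membrane_transmembrane: bool = False
    plasma_membrane_peripheral: bool = False

    FLAGS = ("transmitter", "receiver", "secreted",
             "plasma_membrane_transmembrane", "plasma_membrane_peripheral")


def load_category_definitions(path) -> tuple[list[dict], dict]:
    """Read the category taxonomy YAML.

    Each entry: ``name``, ``aspect``, ``scope``, optional ``parent``, Boolean
    flags, and an optional ``go_expression`` string defining a GO-based
    contributor.  Returns (definitions, options).
    """
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return data.get("categories", []), data.get("options", {})


class IntercellDB:
    """Materialized categories and their members.

    ``members_by`` maps (category name, database) -> member id set; flags are
    carried on the :class:`IntercellCategory` and inherited by every member
    row of the export.
    """

    def __init__(self):
        self.categories: dict[tuple[str, str], IntercellCategory] = {}
        self.members_by: dict[tuple[str, str], set[str]] = {}

    def add(self, category: IntercellCategory, members: set[str]) -> None:
        key = (category.name, category.database)
        self.categories[key] = category
        self.members_by[key] = set(members)

    def members(self, name: str, database: str = "composite") -> set[str]:
        return set(self.members_by.get((name, database), set()))

    def composite_categories(self, aspect: str | None = None,
                             transmitter: bool | None = None,
                             receiver: bool | None = None
                             ) -> list[IntercellCategory]:
        out = []
        for (name, database), cat in sorted(self.categories.items()):
            if database != "composite":
                continue
            if aspect is not None and cat.aspect != aspect:
                continue
            if transmitter is not None and cat.transmitter != transmitter:
                continue
            if receiver is not None and cat.receiver != receiver:
                continue
            out.append(cat)
        return out

    def membrane_bound(self) -> set[str]:
        """Members of composite locational categories flagged as
        plasma-membrane transmembrane or peripheral."""
        out: set[str] = set()
        for cat in self.composite_categories(aspect="locational"):
            if cat.plasma_membrane_transmembrane \
                    or cat.plasma_membrane_peripheral:
                out |= self.members(cat.name)
        return out

    def export_tsv(self) -> str:
        header = ("category", "parent", "database", "scope", "aspect",
                  "entity") + IntercellCategory.FLAGS
        lines = ["\t".join(header)]
        for (name, database) in sorted(self.categories):
            cat = self.categories[(name, database)]
            for entity in sorted(self.members_by[(name, database)]):
                row = (name, cat.parent or "", database, cat.scope,
                       cat.aspect, entity) + tuple(
                    str(int(getattr(cat, flag)))
                    for flag in IntercellCategory.FLAGS)
                lines.append("\t".join(row))
        return "\n".join(lines) + "\n"


def build_categories(role_records, definitions: list[dict],
                     go_annotations: dict[str, set[str]] | None = None,
                     exclusions: dict[str, set[str]] | None = None,
                     id_service=None,
                     id_space_of: dict[str, str] | None = None) -> IntercellDB:
    """Materialize per-resource, GO-derived and composite categories.

    ``role_records`` are raw rows with fields ``category`` and ``entity``
    from per-resource role tables.  Composite membership is the union of all
    contributors of the same category name minus the exclusion set; every
    member row carries its category's flag attributes.
    """
    go_annotations = go_annotations or {}
    exclusions = exclusions or {}
    id_space_of = id_space_of or {}
    defs = {d["name"]: d for d in definitions}

    per_db: dict[tuple[str, str], set[str]] = {}
    for rec in role_records:
        name = rec.fields["category"]
        if name not in defs:
            raise ConfigError(f"role table references undefined category "
                              f"{name!r} ({rec.resource})")
        entity = rec.fields["entity"]
        if id_service is not None:
            space = id_space_of.get(rec.resource, "uniprot")
            hits = id_service.map_id(entity, space, "protein")
            members = set(hits)
        else:
            members = {entity}
        per_db.setdefault((name, rec.resource), set()).update(members)

    db = IntercellDB()

    def category_for(d: dict, database: str) -> IntercellCategory:
        return IntercellCategory(
            name=d["name"], database=database,
            aspect=d.get("aspect", "functional"),
            scope=d.get("scope", "generic"),
            parent=d.get("parent"),
            transmitter=bool(d.get("transmitter", False)),
            receiver=bool(d.get("receiver", False)),
            secreted=bool(d.get("secreted", False)),
            plasma_membrane_transmembrane=bool(
                d.get("plasma_membrane_transmembrane", False)),
            plasma_membrane_peripheral=bool(
                d.get("plasma_membrane_peripheral", False)),
        )

    for (name, database), members in sorted(per_db.items()):
        db.add(category_for(defs[name], database), members)

    for name, d in defs.items():
        if d.get("go_expression"):
            expr = parse_go_expression(d["go_expression"])
            members = {entity for entity, terms in go_annotations.items()
                       if evaluate_go_expression(expr, terms)}
            db.add(category_for(d, "go"), members)

    for name, d in defs.items():
        union: set[str] = set()
        for (cname, database), members in per_db.items():
            if cname == name:
                union |= members
        union |= db.members(name, "go")
        union -= exclusions.get(name, set())
        db.add(category_for(d, "composite"), union)

    return db


def load_exclusions(path) -> dict[str, set[str]]:
    """Versioned exclusion list: tab-separated ``category\\tentity`` rows."""
    out: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            category, entity = line.split("\t")[:2]
            out.setdefault(category, set()).add(entity)
    return out


def infer_complex_roles(db: IntercellDB, complex_db) -> dict[str, set[str]]:
    """Complex memberships per composite category: a complex belongs iff all
    its members belong.  The returned identities are also appended to the
    composite member sets so complexes participate in downstream joins."""
    inferred: dict[str, set[str]] = {}
    for cat in db.composite_categories():
        members = db.members(cat.name)
        hits = {rec.identity for rec in complex_db
                if all(acc in members for acc in rec.components)}
        inferred[cat.name] = hits
        db.members_by[(cat.name, "composite")] |= hits
    return inferred
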