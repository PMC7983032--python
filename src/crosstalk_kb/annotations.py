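"""Uniform long-format annotation store with complex-annotation inference.

Annotation resources are heterogeneous: some merely list proteins belonging
to a category, others attach multi-attribute records (pathway, effect,
disease, ...).  All of them are stored in one long table with columns
(entity, resource, record_id, label, value): the ``record_id`` binds together
the attributes of one original source record, so a per-resource wide table
can be reconstituted losslessly.

Complexes inherit annotations from their members: a complex receives a record
exactly when every component carries a record agreeing on all labels
considered relevant for that resource, and the inferred record carries those
shared values.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import pandas as pd

from .model import Entity
from .resources import RawRecord

COLUMNS = ("entity", "resource", "record_id", "label", "value")


class AnnotationDB:
    """Long-format store; ``table`` is a pandas DataFrame with
    :data:`COLUMNS`."""

    def __init__(self, table: pd.DataFrame | None = None):
        self.table = table if table is not None else pd.DataFrame(
            columns=list(COLUMNS))

    def __len__(self):
        return len(self.table)

    def resources(self) -> list[str]:
        return sorted(self.table["resource"].unique())

    def extend(self, rows: list[dict]) -> None:
        if rows:
            self.table = pd.concat(
                [self.table, pd.DataFrame(rows, columns=list(COLUMNS))],
                ignore_index=True)

    def entities_with(self, resource: str, label: str, value: str
                      ) -> set[str]:
        t = self.table
        hit = t[(t["resource"] == resource) & (t["label"] == label)
                & (t["value"] == value)]
        return set(hit["entity"])

    def export_tsv(self) -> str:
        out = self.table.sort_values(list(COLUMNS)).reset_index(drop=True)
        return out.to_csv(sep="\t", index=False)


def to_long(records: list[RawRecord], schema_labels: dict[str, str] | None,
            resource: str, membership_label: str = "in_resource",
            start_ids: dict[str, int] | None = None) -> list[dict]:
    """Explode raw annotation rows into long-format rows.

    ``schema_labels`` maps semantic field names (beyond ``entity``) to
    attribute labels; when empty the resource is membership-only and each
    record yields a single ``(membership_label, "true")`` row.  ``record_id``
    values are dense from 0 within each (entity, resource) group and assigned
    in canonical (sorted-content) order, so the long table does not depend on
    the row order of the source file.
    """
    per_entity: dict[str, list[list[tuple[str, str]]]] = {}
    for rec in records:
        entity = rec.fields["entity"]
        attrs = [(label, rec.fields.get(fieldname, "").strip())
                 for fieldname, label in (schema_labels or {}).items()]
        attrs = [(label, value) for label, value in attrs if value != ""]
        if not attrs:
            attrs = [(membership_label, "true")]
        per_entity.setdefault(entity, []).append(sorted(attrs))
    rows: list[dict] = []
    start_ids = start_ids or {}
    for entity in sorted(per_entity):
        base = start_ids.get(entity, 0)
        for offset, attrs in enumerate(sorted(per_entity[entity])):
            for label, value in attrs:
                rows.append({"entity": entity, "resource": resource,
                             "record_id": base + offset, "label": label,
                             "value": value})
    return rows


def reconstitute(db: AnnotationDB, resource: str) -> pd.DataFrame:
    """Rebuild the conventional wide data frame of one resource.

    One row per (entity, record_id), one column per label.  Raises KeyError
    for resources absent from the store; an empty (but known) resource yields
    an empty frame with the declared columns.
    """
    t = db.table[db.table["resource"] == resource]
    if t.empty:
        if resource not in set(db.table["resource"]):
            raise KeyError(f"no annotations from resource {resource!r}")
        return pd.DataFrame(columns=["entity", "record_id"])
    wide = t.pivot_table(index=["entity", "record_id"], columns="label",
                         values="value", aggfunc="first")
    wide = wide.reset_index()
    wide.columns.name = None
    return wide.sort_values(["entity", "record_id"]).reset_index(drop=True)


def _value_tuples(t: pd.DataFrame, labels: tuple[str, ...]
                  ) -> dict[str, set[tuple]]:
    """Per entity: set of value tuples over ``labels``, one per record."""
    out: dict[str, set[tuple]] = {}
    for (entity, _rid), group in t.groupby(["entity", "record_id"]):
        values = dict(zip(group["label"], group["value"]))
        out.setdefault(entity, set()).add(
            tuple(values.get(label) for label in labels))
    return out


def infer_complex_annotations(db: AnnotationDB, complex_db,
                              relevant_labels: dict[str, list[str]] | None
                              = None) -> list[dict]:
    """Annotation records inferred for complexes from member agreement.

    For each resource, the labels considered relevant default to all labels
    the resource uses.  A complex is annotated with a value combination iff
    every component has a record carrying exactly those values on the
    relevant labels.
    """
    relevant_labels = relevant_labels or {}
    rows: list[dict] = []
    for resource in db.resources():
        t = db.table[db.table["resource"] == resource]
        labels = tuple(sorted(relevant_labels.get(
            resource, sorted(t["label"].unique()))))
        per_entity = _value_tuples(t, labels)
        for identity in sorted(complex_db.records):
            members = list(complex_db.records[identity].components)
            member_sets = [per_entity.get(m) for m in members]
            if any(s is None for s in member_sets):
                continue
            shared = set.intersection(*member_sets)
            for rid, combo in enumerate(sorted(
                    shared, key=lambda c: tuple(v or "" for v in c))):
                for label, value in zip(labels, combo):
                    if value is not None:
                        rows.append({"entity": identity, "resource": resource,
                                     "record_id": rid, "label": label,
                                     "value": value})
    return rows
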