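"""Long-format annotation store, reconstitution and complex inference."""

import random

import pandas as pd
import pytest

from crosstalk_kb.annotations import (AnnotationDB, infer_complex_annotations,
                                      reconstitute, to_long)
from crosstalk_kb.complexes import ComplexDB, ComplexRecord
from crosstalk_kb.resources import RawRecord


def _rec(entity, **attrs):
    fields = {"entity": entity}
    fields.update(attrs)
    return RawRecord("res", fields, 1)


def test_to_long_multi_attribute_record():
    labels = {f"a{i}": f"a{i}" for i in range(7)}
    rows = to_long([_rec("P1", **{f"a{i}": f"v{i}" for i in range(7)})],
                   labels, "res")
    assert len(rows) == 7
    assert {r["record_id"] for r in rows} == {0}  # one record binds them


def test_to_long_membership_only():
    rows = to_long([_rec("P1")], {}, "res")
    assert rows == [{"entity": "P1", "resource": "res", "record_id": 0,
                     "label": "in_resource", "value": "true"}]


def test_to_long_record_ids_dense_per_entity():
    rows = to_long([_rec("P1", a="x"), _rec("P1", a="y"), _rec("P2", a="z")],
                   {"a": "a"}, "res")
    ids = [(r["entity"], r["record_id"]) for r in rows]
    assert ids == [("P1", 0), ("P1", 1), ("P2", 0)]


def test_round_trip_random_tables():
    rng = random.Random(5)
    labels = ["a", "b", "c"]
    db = AnnotationDB()
    rows = []
    for entity in [f"P{i}" for i in range(10)]:
        for rid in range(rng.randint(1, 3)):
            for label in labels:
                rows.append({"entity": entity, "resource": "res",
                             "record_id": rid, "label": label,
                             "value": f"v{rng.randint(0, 4)}"})
    db.extend(rows)
    wide = reconstitute(db, "res")
    back = []
    for row in wide.itertuples(index=False):
        for label in labels:
            back.append({"entity": row.entity, "resource": "res",
                         "record_id": row.record_id, "label": label,
                         "value": getattr(row, label)})
    key = lambda r: (r["entity"], r["record_id"], r["label"])
    assert sorted(back, key=key) == sorted(rows, key=key)


def test_reconstitute_missing_resource_and_empty(kb):
    with pytest.raises(KeyError):
        reconstitute(kb.annotations, "no_such_resource")
    wide = reconstitute(kb.annotations, "pathdb")
    assert {"entity", "record_id", "pathway", "effect"} <= set(wide.columns)


def _complex_db(sets):
    db = ComplexDB()
    for members in sets:
        identity = "COMPLEX:" + "_".join(sorted(set(members)))
        db.records[identity] = ComplexRecord(
            {m: None for m in sorted(set(members))}, identity)
    return db


def test_inference_agreement_and_disagreement():
    db = AnnotationDB()
    db.extend([
        {"entity": "P1", "resource": "res", "record_id": 0,
         "label": "pathway", "value": "WNT"},
        {"entity": "P2", "resource": "res", "record_id": 0,
         "label": "pathway", "value": "WNT"},
        {"entity": "P3", "resource": "res", "record_id": 0,
         "label": "pathway", "value": "NOTCH"},
    ])
    complexes = _complex_db([["P1", "P2"], ["P1", "P3"], ["P1", "P9"]])
    rows = infer_complex_annotations(db, complexes)
    assert rows == [{"entity": "COMPLEX:P1_P2", "resource": "res",
                     "record_id": 0, "label": "pathway", "value": "WNT"}]


def test_inference_monotone_in_conflict_removal():
    """Removing a member's conflicting record only adds inferred complex
    annotations, never removes unrelated ones."""
    base = [
        {"entity": "P1", "resource": "res", "record_id": 0,
         "label": "pathway", "value": "WNT"},
        {"entity": "P2", "resource": "res", "record_id": 0,
         "label": "pathway", "value": "WNT"},
        {"entity": "P3", "resource": "res", "record_id": 0,
         "label": "pathway", "value": "WNT"},
        {"entity": "P3", "resource": "res", "record_id": 1,
         "label": "pathway", "value": "NOTCH"},
    ]
    complexes = _complex_db([["P1", "P2"], ["P2", "P3"]])
    with_conflict = AnnotationDB()
    with_conflict.extend(base)
    without = AnnotationDB()
    without.extend(base[:3])

    def inferred_set(db):
        return {(r["entity"], r["label"], r["value"])
                for r in infer_complex_annotations(db, complexes)}

    assert inferred_set(with_conflict) <= inferred_set(without)


def test_built_rows_and_inference_match_manifest(kb, manifest):
    expected = manifest["annotations"]
    counts = kb.annotations.table.groupby("resource").size().to_dict()
    assert counts == expected["per_resource_rows"]
    # manifest's brute-force inference over planted truth
    got = {}
    for row in kb.inferred_complex_annotations:
        key = (row["resource"], row["entity"], row["record_id"])
        got.setdefault(key, {})[row["label"]] = row["value"]
    expected_pairs = {
        (resource, identity, tuple(sorted(attrs.items())))
        for resource, inferred in expected["inferred_complex"].items()
        for identity, attrs in inferred}
    got_pairs = {(resource, entity, tuple(sorted(attrs.items())))
                 for (resource, entity, _rid), attrs in got.items()}
    assert got_pairs == expected_pairs


def test_inference_soundness_post_hoc(kb):
    """Every inferred complex record's values are provably held by every
    member."""
    table = kb.annotations.table
    for row in kb.inferred_complex_annotations:
        members = row["entity"].removeprefix("COMPLEX:").split("_")
        for member in members:
            hit = table[(table["resource"] == row["resource"])
                        & (table["entity"] == member)
                        & (table["label"] == row["label"])
                        & (table["value"] == row["value"])]
            assert len(hit) > 0, row
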