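"""One-call orchestration: registry + config files -> the five databases.

``build_knowledgebase`` reads a fixture/resource directory laid out as the
registry expects (see :mod:`crosstalk_kb.fixtures`), wires up the identifier
service, and builds the network, enzyme-PTM, complex, annotation and
intercellular-role databases in dependency order, including complex-role and
complex-annotation inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from . import annotations as ann
from . import complexes as cpx
from . import enzyme_ptm as ptm
from . import intercell as ic
from . import network as nw
from .identifiers import (IdentifierSpace, IdService, MappingTable,
                          ReferenceSet)
from .resources import ResourceDescriptor, load_registry, load_resource


@dataclass
class KnowledgeBase:
    registry: list[ResourceDescriptor]
    id_service: IdService
    sequences: ptm.SequenceSet
    network: nw.NetworkDB
    enzsub: ptm.EnzSubDB
    complexes: cpx.ComplexDB
    annotations: ann.AnnotationDB
    intercell: ic.IntercellDB
    inferred_complex_annotations: list[dict] = field(default_factory=list)
    inferred_complex_roles: dict[str, set[str]] = field(default_factory=dict)


def build_id_service(base: Path) -> IdService:
    mapping = base / "mapping"
    service = IdService()
    sec2sym = MappingTable.from_tsv(mapping / "secondary2symbol.tsv",
                                    "uniprot", "genesymbol")
    sym2uni = MappingTable.from_tsv(mapping / "symbol2uniprot.tsv",
                                    "genesymbol", "uniprot",
                                    case_insensitive=True)
    service.register_reference("protein", ReferenceSet.from_file(
        mapping / "uniprot_primary.txt", IdentifierSpace("uniprot"),
        secondary_to_symbol=sec2sym, symbol_to_primary=sym2uni))
    service.register_reference("mirna", ReferenceSet.from_file(
        mapping / "mirbase_primary.txt",
        IdentifierSpace("mirbase_mature")))
    service.register_reference("lncrna", ReferenceSet.from_file(
        mapping / "lncrna_primary.txt", IdentifierSpace("lncrna")))
    service.register_table(sym2uni)
    return service


def build_knowledgebase(base, cache_dir=None) -> KnowledgeBase:
    base = Path(base)
    registry = load_registry(base / "registry.yaml")
    by_format: dict[str, list[ResourceDescriptor]] = {}
    for desc in registry:
        by_format.setdefault(desc.format, []).append(desc)

    id_service = build_id_service(base)
    sequences = ptm.SequenceSet.from_fasta(base / "sequences.fasta")

    interaction_records = []
    dataset_of, id_space_of = {}, {}
    for desc in by_format.get("interaction_table", []):
        interaction_records += load_resource(desc, cache_dir)
        dataset_of[desc.name] = desc.dataset
        id_space_of[desc.name] = desc.id_space
    network = nw.merge_interactions(interaction_records, id_service,
                                    dataset_of, id_space_of)

    enzsub_records = []
    for desc in by_format.get("enzsub_table", []):
        enzsub_records += load_resource(desc, cache_dir)
        id_space_of[desc.name] = desc.id_space
    enzsub = ptm.merge_ptms(enzsub_records, id_service, sequences,
                            id_space_of)

    complex_records = []
    for desc in by_format.get("complex_table", []):
        complex_records += load_resource(desc, cache_dir)
        id_space_of[desc.name] = desc.id_space
    complexes = cpx.merge_complexes(complex_records, id_service, id_space_of)

    annotations = ann.AnnotationDB()
    role_records = []
    for desc in by_format.get("annotation_table", []):
        records = load_resource(desc, cache_dir)
        if desc.options.get("role_table"):
            role_records += records
            continue
        labels = {f: f for f in desc.schema.values() if f != "entity"}
        annotations.extend(ann.to_long(records, labels, desc.name))

    go_annotations: dict[str, set[str]] = {}
    for desc in by_format.get("go_gaf", []):
        go_annotations = ic.load_gaf(load_resource(desc, cache_dir))

    definitions, _options = ic.load_category_definitions(
        base / "categories.yaml")
    exclusions_path = base / "exclusions.tsv"
    exclusions = ic.load_exclusions(exclusions_path) \
        if exclusions_path.exists() else {}
    intercell = ic.build_categories(role_records, definitions,
                                    go_annotations, exclusions)

    inferred_roles = ic.infer_complex_roles(intercell, complexes)
    inferred_records = ann.infer_complex_annotations(annotations, complexes)

    return KnowledgeBase(registry, id_service, sequences, network, enzsub,
                         complexes, annotations, intercell,
                         inferred_records, inferred_roles)


def export_all(kb: KnowledgeBase, out_dir) -> dict[str, Path]:
    """Write the deterministic tabular exports of all five databases."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, text in (
            ("interactions.tsv", nw.export_tsv(kb.network)),
            ("network.sif", nw.export_sif(kb.network)),
            ("enzsub.tsv", ptm.export_tsv(kb.enzsub)),
            ("complexes.tsv", cpx.export_tsv(kb.complexes)),
            ("annotations.tsv", kb.annotations.export_tsv()),
            ("intercell.tsv", kb.intercell.export_tsv())):
        path = out / name
        path.write_text(text, encoding="utf-8")
        paths[name] = path
    return paths


def genes_of_map(kb: KnowledgeBase) -> dict[str, tuple[str, ...]]:
    """Protein accession -> gene symbol(s), for expression bridging."""
    table = next(t for t in kb.id_service.tables
                 if t.from_space == "genesymbol" and t.to_space == "uniprot")
    out: dict[str, list[str]] = {}
    for symbol, accessions in table.pairs.items():
        for acc in accessions:
            out.setdefault(acc, []).append(symbol)
    return {acc: tuple(sorted(symbols)) for acc, symbols in out.items()}
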