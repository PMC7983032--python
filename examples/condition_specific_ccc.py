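"""Condition-specific cell-cell communication and downstream signaling.

Given cell-type average expression under two conditions (healthy vs disease),
a transmitter->receiver edge is *active* when both endpoints are expressed in
their respective cell types (a gene counts as expressed when its log2 value
exceeds the cell type's mean-minus-2-sd threshold over nonzero genes), and
*condition-specific* when active in exactly one condition.  Downstream
effects in the receiving cell are mapped as the two-step neighborhood of the
condition-specific receptors, restricted to expressed genes, followed by
pathway over-representation.
"""

import tempfile
from pathlib import Path

from crosstalk_kb import build_knowledgebase, generate_knowledgebase
from crosstalk_kb.build import genes_of_map
from crosstalk_kb.comm import (ExpressionData, UC_PROFILE,
                               build_intercell_network,
                               condition_specific_edges, downstream_network,
                               enrich)

with tempfile.TemporaryDirectory() as tmp:
    base = Path(tmp) / "kb"
    generate_knowledgebase(seed=7, out_dir=base)
    kb = build_knowledgebase(base)

    edges = build_intercell_network(kb.network, kb.intercell, UC_PROFILE)
    expr = ExpressionData.from_tsv(base / "expression.tsv")
    genes_of = genes_of_map(kb)
    result = condition_specific_edges(edges, expr, "myofibroblast", "treg",
                                      ("healthy", "uc"), genes_of)
    for condition in ("healthy", "uc"):
        print(f"{condition}: {len(result.active[condition])} active, "
              f"{len(result.specific[condition])} condition-specific")
    print("disease-specific ligand-receptor pairs:",
          sorted(result.specific["uc"]))

    allowed = {acc for acc, genes in genes_of.items()
               if any(g in expr.expressed("uc", "treg") for g in genes)}
    seeds = {receptor for _, receptor in result.specific["uc"]} & allowed
    nodes, induced = downstream_network(kb.network, seeds, allowed, k=2)
    print(f"\ndownstream network (2 steps from {len(seeds)} receptors): "
          f"{len(nodes)} proteins, {len(induced)} edges")

    table = kb.annotations.table
    pathdb = table[(table["resource"] == "pathdb")
                   & (table["label"] == "pathway")
                   & (~table["entity"].str.startswith("COMPLEX:"))]
    gene_sets = {v: set(g["entity"]) for v, g in pathdb.groupby("value")}
    universe = set(kb.id_service.references["protein"].primary_ids)
    print("\npathway over-representation of the downstream proteins:")
    print(enrich(nodes & universe, gene_sets, universe).to_string(
        index=False))
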