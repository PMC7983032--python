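# crosstalk-kb

Molecular knowledge of signaling is scattered across dozens of resources
with incompatible formats, identifier conventions and levels of curation.
Analyses of cell–cell communication — who talks to whom in a tissue, through
which ligand–receptor pairs, and with what downstream consequences — need
that knowledge unified: interactions with direction and effect sign,
enzyme–PTM relationships with verified residues, protein complexes, and
annotations of who transmits and who receives intercellular signals.

`crosstalk-kb` is an integration engine for this problem.  It builds five
interlinked databases from declarative resource registries:

* **network** — typed molecular interactions (protein–protein,
  TF–target, miRNA–mRNA, TF–miRNA, lncRNA–mRNA) merged across resources with
  every per-resource claim preserved as evidence (resource, PubMed
  references, dataset tag, direction, sign).  Direction/sign consensus is a
  majority vote with explicit contradiction flags; dataset views slice the
  store by evidence tags, including confidence-graded TF regulons (A–D).
* **enzyme–PTM** — enzyme → substrate-residue modification records, merged on
  the (enzyme, substrate, residue, position, modification) key and validated
  against isoform sequences: a claimed residue must actually occur at the
  claimed position in some isoform.
* **complexes** — deduplicated by unique component set
  (`COMPLEX:` + members sorted alphabetically, underscore-joined), with
  stoichiometry preserved when the sources agree.
* **annotations** — heterogeneous per-protein attributes in one long format
  `(entity, resource, record_id, label, value)`, losslessly reconstitutable
  into per-resource wide tables; complexes inherit annotations when all
  members agree.
* **intercell** — transmitter/receiver role categories (functional and
  locational), sourced from role tables, Boolean expressions over Gene
  Ontology terms, and composite unions with curated exclusion lists.  A
  complex belongs to a category iff all its members do.

On top of the databases sit the analyses:

* **transmitter → receiver network**: a join of directed interactions with
  role annotations, with a strict profile (no indirect-regulator categories,
  membrane-bound receivers only) for direct cell–cell contact;
* **condition-specific communication**: with cell-type average expression
  under two conditions, an edge is active when both endpoints are expressed
  (log2 value above the cell type's mean − 2·sd threshold over nonzero
  genes, strict), condition-specific when active in exactly one condition;
  downstream effects are the k-step neighborhood of the specific receptors
  restricted to expressed genes, scored by hypergeometric
  over-representation with Benjamini–Hochberg correction;
* **ligand–target regulatory potential**: personalized PageRank from each
  ligand over the union of the ligand–receptor and signaling graphs,
  multiplied by the weighted adjacency of the gene regulatory network:
  `potential(ℓ, g) = Σ_tf  PPR_ℓ(tf) · w(tf → g)`.

Homology translation to other organisms runs accession → RefSeq →
orthologous RefSeq → accession, with PTM sites additionally mapped through a
site-homology table and re-validated against target sequences.

Everything runs on synthetic knowledge bases generated by
`crosstalk_kb.fixtures`: every input format is emulated with planted ground
truth, and the generator's manifest predicts every database summary exactly.

## Worked example

```sh
python examples/build_knowledgebase.py
```

```
interactions :   90 (manifest: 90)
enzyme-PTM   :   18 (manifest: 18; rejected residues: {'residue_mismatch': 6, 'no_sequence': 2})
complexes    :   12 (manifest: 12)
annotations  :   55 long-format rows
intercell    : 11 composite categories
```

The 90 merged interactions equal the generator's planted unique
(endpoint-pair, type) keys — overlapping resources collapse into single
interactions with multiple evidences.  Of 26 enzyme–PTM rows, 6 are rejected
because the claimed residue matches no isoform sequence and 2 because the
substrate has no sequence; the 18 survivors merge to the planted unique
sites.  `examples/condition_specific_ccc.py` continues the pipeline:

```
healthy: 4 active, 2 condition-specific
uc: 6 active, 4 condition-specific
disease-specific ligand-receptor pairs: [('P0T0010', 'P0T0008'), ...]
downstream network (2 steps from 4 receptors): 8 proteins, 6 edges
```

i.e. four ligand–receptor connections between myofibroblasts and regulatory
T cells are only possible in the disease condition, and the two-step
downstream network in the T cells maps their intracellular consequences.
The other examples cover consensus/views, the transmitter–receiver join,
regulatory potential and homology translation.

A thin CLI wraps the same calls: `crosstalk-kb fixtures|build|cache|
translate|ccc` (see `--help`).

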