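# Methods

## Scope and data model

The engine integrates four kinds of source material — molecular
interactions, enzyme–PTM relationships, protein complexes, and per-molecule
annotations — into five databases (the fifth, intercellular communication
roles, is derived from annotation-type sources).  Every merged record keeps
its full provenance as *evidence* objects: resource name, literature
references (possibly empty), dataset tag, and the direction/sign the
resource asserted.  Nothing is discarded at merge time except records that
fail identifier translation or residue validation, and those are counted,
never raised — a batch build must not abort because one resource labels a
molecule obscurely.

Entities are proteins, miRNAs, lncRNAs or complexes, each with one
reference identifier space (UniProt accessions for proteins, miRBase mature
accessions for miRNAs).  Complexes are identified by their unique component
set: accessions sorted alphabetically, underscore-joined, prefixed
`COMPLEX:`; a homomultimer collapses to a single accession.

## Identifier handling

Labels are normalized before lookup: upper-cased, configured Greek glyphs
replaced by Latin letters, hyphen/en-dash runs removed.  Upper-casing runs
first because some glyphs (the micro sign) only become Greek capitals under
case mapping.  The substitution table ships as editable configuration; the
default maps each Greek letter to its conventional single Latin letter
(α→A, κ→K, …).  Normalization is idempotent (property-tested).

Foreign identifiers translate through registered mapping tables into the
reference space.  Ambiguity is preserved: if a symbol maps to several
accessions, all are returned and downstream merges expand over all endpoint
combinations; complexes translate component-wise by cartesian product and
survive only if every component translates.  Deprecated accessions use a
two-hop bridge (secondary accession → primary symbol → primary accessions).
General multi-hop chains are capped at these two hops to avoid spurious
transitive identifications.  Symbol matching is case-insensitive; accession
matching is case-sensitive.

## Network merging and consensus

Interactions are keyed by canonically ordered endpoints and interaction
type; direction is encoded on evidences relative to the stored order, so
reciprocal claims A→B and B→A form one interaction with both-direction
evidences.  Evidences deduplicate on (resource, dataset, direction, sign,
confidence) with reference union, which makes merging idempotent and
order-independent; exports sort rows and cells, so identical inputs in any
record order produce byte-identical exports.

Consensus is deliberately conservative: an interaction is directed if any
evidence asserts a direction; direction and sign are each decided by strict
majority over the evidences that assert one; the presence of opposing
assertions raises a contradiction flag even when a majority exists, and a
tie leaves the consensus unset.  The raw evidences always remain available,
so users can substitute their own policy.  Nine dataset tags partition the
evidence space (activity-flow core, pathway/kinase/ligand-receptor
extensions, graded TF regulons, literature TF–target, miRNA–mRNA, TF–miRNA,
lncRNA–mRNA); regulon evidences carry confidence grades A–D and views filter
by grade in that order (the lowest grade, E, is never imported).

## Residue validation

Positions are 1-based with residue 1 the initiator methionine, following
the UniProt convention.  A claimed site is accepted iff some isoform carries
the claimed amino acid at the claimed position; matching isoform numbers are
recorded, and positions are taken as given per matching isoform (no
renumbering across isoforms).  Substrates without sequences are rejected
with a distinct reason rather than passed through — the conservative
default.  Records without literature references are kept, since
high-throughput and predicted sites legitimately lack them.

## Complexes and annotations

Stoichiometry merging follows an agree-or-single-assertion rule: counts are
kept when all asserting sources agree or only one asserts them; a
disagreement flags the record, reverts counts to unknown and preserves every
variant.  Complex records with non-protein or untranslatable members are
dropped with a counter.

Annotations live in one long table `(entity, resource, record_id, label,
value)`; `record_id` binds the attributes of one source record and is
assigned in canonical sorted-content order, dense from zero per entity, so
the table is independent of source row order.  Per-resource wide tables
reconstitute losslessly (round-trip property-tested).  Complex annotation
inference: for each resource, a complex receives a value combination over
the resource's *relevant* labels (all labels by default, configurable) iff
every component has a record with exactly those values; agreement is exact
text equality after whitespace trimming.

## Intercellular roles

Categories carry aspect (functional/locational), scope (generic/specific),
transmitter/receiver flags and three location flags; member rows inherit
their category's flags.  Membership contributors are per-resource role
tables, Boolean s-expressions over GO annotations (`(and GO:… (not
GO:…))`), and composite categories: union of same-name contributors minus a
versioned exclusion list, which stands in for manual curation of wrong
source annotations.  GO ancestor closure is off by default (expressions are
evaluated against direct annotation sets) and can be enabled by
pre-expanding the annotation input.  Complex roles follow the iff-rule: a
complex belongs to a category exactly when all members do.

## Homology translation

Protein translation is the three-step path accession → RefSeq → orthologous
RefSeq (same group, target organism) → target accession, union over all
paths.  Many-to-many expansion is capped (default 4 targets per source,
logged on overflow).  An interaction survives iff both endpoints translate;
evidence is carried unchanged.  PTM sites require a site-homology row —
sites without one are dropped rather than carried at the same numeric
position, since alignment-based transfer is out of scope — and the residue
is re-validated against the target organism's sequences.

## Communication analyses

**Expressed genes.**  The threshold base set is the cell type's nonzero
genes (the natural reading of "expressed genes" that avoids circularity);
the threshold is mean − 2·sd with the sample standard deviation (ddof = 1),
and the inequality is strict, so a zero-variance profile yields an empty
expressed set.  Both choices are configurable at the call site.

**Transmitter → receiver join.**  One edge per (interaction, asserted
direction, transmitter category, receiver category).  Any evidence-asserted
direction qualifies (not only the consensus) — contradictory knowledge
should surface in the join rather than vanish.  The strict contact profile
excludes the indirect-regulator categories (ECM proteins, ECM regulators,
ligand/receptor regulators, matrix adhesion regulators) and requires
receivers annotated transmembrane or peripheral at the plasma membrane.

**Condition specificity.**  An edge is active in a condition iff its
transmitter gene is expressed in the transmitter cell type and its receiver
gene in the receiver cell type; condition-specific means active in exactly
one of the two conditions; counts are over unique protein pairs per cell
pair.  A complex endpoint is expressed iff all components are (consistent
with the all-members role rule).  Genes mapping to several proteins activate
all of them.

**Downstream networks.**  Breadth-first expansion along directed edges,
default two steps, restricted to the expressed-gene set of the receiving
cell; the returned subnetwork is induced on the reached nodes, so it is
monotone in the step count.

**Enrichment.**  One-sided hypergeometric over-representation
(`scipy.stats.hypergeom`) against a configurable universe, gene sets
intersected with the universe, Benjamini–Hochberg step-up across all tested
sets (`statsmodels`).

**Regulatory potential.**  Personalized PageRank by power iteration:
damping 0.85, restart distribution a point mass on the ligand, dangling
mass returned to the restart vector, L1 tolerance 1e−10, iteration cap
10⁴ (non-convergence raises with diagnostics; each vector sums to one by
construction).  Union-graph edge weights default to 1 when the source
provides none.  The ligand × node score matrix is multiplied by the
regulatory network's weighted adjacency, making the potential linear in
regulatory edge weights and exactly zero for genes with no incoming
regulatory edge.  The three input graphs are composed as: ligand–receptor =
the dedicated ligand–receptor dataset plus PPIs from ligand-annotated
sources to receptor-annotated targets; signaling = activity-flow core plus
kinase and pathway extensions; regulatory = graded regulons at confidence
≤ C plus the literature TF–target dataset.

## Synthetic knowledge base

The generator emulates the study conditions at desk scale: three
overlapping PPI resources (with planted sign contradictions, an autocrine
self-loop, dirty labels and unmappable symbols), dedicated
kinase/pathway/ligand–receptor resources, a graded regulon resource and
literature TF–target, miRNA/TF–miRNA/lncRNA resources, two enzyme–PTM
resources with planted invalid residues against an emitted isoform FASTA,
two complex resources with duplicate complexes and one stoichiometry
conflict, membership-only and multi-attribute annotation resources, role
tables with an exclusion-listed wrong annotation, GO annotations with a
decoy entity exercising negation, mapping/homology/site-homology tables, a
cell-type × condition expression matrix and a differential-expression table
with boundary rows at both thresholds.

Generation is manifest-first: truth is sampled, files are rendered from it,
and the manifest predicts every database summary, so test oracles never
re-implement the system under test.  Default sizes (60 proteins, 90 unique
interactions across the nine datasets, 18 valid + 6 invalid + 2
sequence-less PTM sites, 12 complexes, 70% homology coverage, uniform
log2 expression in (6, 10) for expressed genes) keep a full
generate-build-analyze cycle under 50 ms while exercising every merge path.
Expression values are drawn far above the mean − 2·sd threshold, so the
expressed set equals the planted nonzero set by construction; condition
specificity is planted by zeroing one endpoint gene per selected pair in
exactly one condition, and the manifest's expected sets are computed from
the planted truth with independent nested loops, so induced side effects of
gene-level planting are part of the ground truth.

What the fixtures do *not* emulate: realistic expression distributions,
dropout noise, correlated annotations, real ontology structure, or the
scale of production resources.  Passing tests therefore demonstrate the
correctness of merging, validation, inference and the analysis algorithms —
not the biological fidelity of any particular public resource snapshot.

## Known limitations

* Consensus is per-interaction majority; no weighting by resource quality
  or reference count.
* GO expressions are evaluated against direct annotations; ontology-aware
  closure must be provided by the caller.
* Homology transfer is strictly table-driven; no alignment fallback for
  sites without a homology row.
* The cache is content-addressed by locator digest, not by remote version;
  a changed remote file behind the same locator requires a cache clear.
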