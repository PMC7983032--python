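"""Transmitter-receiver networks and cell-cell communication analyses.

Three computations build on the integrated databases:

* the *intercellular network*: a join of directed interactions with
  transmitter-role sources and receiver-role targets (ligand-receptor being
  the paradigmatic case), with an optional filter profile that discards
  indirect regulator categories and demands membrane-bound receivers;
* *condition-specific communication*: given per-condition, per-cell-type
  expression profiles, an edge is active when both endpoints are expressed in
  their respective cell types, and condition-specific when active in exactly
  one of two conditions; downstream effects are mapped by a depth-limited
  walk over the signaling network restricted to expressed genes, followed by
  over-representation analysis;
* *ligand-target regulatory potential*: personalized PageRank from each
  ligand over the union of the ligand-receptor and signaling networks,
  multiplied by the weighted adjacency of the gene regulatory network.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intercell import IntercellDB
from .model import ConfigError, Entity
from .network import NetworkDB, dataset_view

# ------------------------------------------------------- intercell network

#: Indirect-regulator categories discarded by the ulcerative-colitis profile.
UC_EXCLUDED_CATEGORIES = frozenset({
    "ecm", "ecm_regulator", "ligand_regulator", "receptor_regulator",
    "matrix_adhesion_regulator",
})


@dataclass(frozen=True)
class FilterProfile:
    excluded_categories: frozenset[str] = frozenset()
    require_membrane_receiver: bool = False


#: The direct cell-cell contact profile used in the colitis case study.
UC_PROFILE = FilterProfile(UC_EXCLUDED_CATEGORIES, True)


@dataclass(frozen=True)
class CommEdge:
    """One transmitter -> receiver connection backed by a network edge."""

    transmitter: Entity
    transmitter_category: str
    receiver: Entity
    receiver_category: str
    interaction_key: tuple

    def pair(self) -> tuple[str, str]:
        return (self.transmitter.id, self.receiver.id)


def build_intercell_network(net: NetworkDB, roles: IntercellDB,
                            filter_profile: FilterProfile | None = None
                            ) -> list[CommEdge]:
    """Join directed interactions with transmitter/receiver category members.

    An edge qualifies when some evidence asserts the transmitter->receiver
    direction; one CommEdge is produced per (interaction, direction,
    transmitter category, receiver category) combination.  Under a filter
    profile, edges touching excluded categories are discarded and receivers
    must be membrane-bound (transmembrane or peripheral).
    """
    profile = filter_profile or FilterProfile()
    tx_cats = [c for c in roles.composite_categories(
        aspect="functional", transmitter=True)
        if c.name not in profile.excluded_categories]
    rx_cats = [c for c in roles.composite_categories(
        aspect="functional", receiver=True)
        if c.name not in profile.excluded_categories]
    tx_members = {c.name: roles.members(c.name) for c in tx_cats}
    rx_members = {c.name: roles.members(c.name) for c in rx_cats}
    membrane = roles.membrane_bound() \
        if profile.require_membrane_receiver else None

    edges: list[CommEdge] = []
    for i in net:
        for direction in sorted(i.directions_asserted()):
            source, target = (i.a, i.b) if direction == "a_to_b" \
                else (i.b, i.a)
            if membrane is not None and target.id not in membrane:
                continue
            for tc in tx_cats:
                if source.id not in tx_members[tc.name]:
                    continue
                for rc in rx_cats:
                    if target.id not in rx_members[rc.name]:
                        continue
                    edges.append(CommEdge(source, tc.name, target, rc.name,
                                          i.key()))
    return edges


# ------------------------------------------------------------- expression

@dataclass
class ExpressionData:
    """Cell-type average log2 expression per condition.

    ``values[(condition, cell_type)]`` maps gene -> non-negative log2 mean
    expression.  The tabular input is a wide matrix: rows are genes, columns
    are ``<condition>|<cell_type>``.
    """

    values: dict[tuple[str, str], dict[str, float]]
    _expressed_cache: dict[tuple[str, str], frozenset[str]] = \
        field(default_factory=dict)

    @classmethod
    def from_tsv(cls, path) -> "ExpressionData":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        values: dict[tuple[str, str], dict[str, float]] = {}
        for column in frame.columns:
            condition, _, cell_type = column.partition("|")
            values[(condition, cell_type)] = frame[column].to_dict()
        return cls(values)

    def profile(self, condition: str, cell_type: str) -> dict[str, float]:
        try:
            return self.values[(condition, cell_type)]
        except KeyError:
            raise ConfigError(
                f"no expression profile for ({condition!r}, {cell_type!r})")

    def expressed(self, condition: str, cell_type: str) -> frozenset[str]:
        key = (condition, cell_type)
        if key not in self._expressed_cache:
            self._expressed_cache[key] = frozenset(
                expressed_genes(self.profile(condition, cell_type)))
        return self._expressed_cache[key]


def expressed_genes(profile: dict[str, float]) -> set[str]:
    """Genes expressed in a cell type.

    Base set S: genes with expression > 0.  Threshold t = mean(S) - 2*sd(S)
    (sample sd, ddof=1); genes strictly above t are expressed.  With fewer
    than two nonzero genes the sd is undefined and the nonzero set is
    returned; in the degenerate zero-variance case the strict inequality
    leaves the set empty.
    """
    nonzero = {g: v for g, v in profile.items() if v > 0}
    if len(nonzero) < 2:
        return set(nonzero)
    arr = np.array(list(nonzero.values()), dtype=float)
    threshold = arr.mean() - 2.0 * arr.std(ddof=1)
    return {g for g, v in nonzero.items() if v > threshold}


# --------------------------------------------- condition-specific edges

def _entity_expressed(entity: Entity, expressed: frozenset[str],
                      genes_of: dict[str, tuple[str, ...]]) -> bool:
    """An entity is expressed iff its gene is; complexes require *all*
    components expressed (consistent with the all-members role rule)."""
    if entity.is_complex:
        return all(any(g in expressed for g in genes_of.get(acc, (acc,)))
                   for acc in entity.components())
    return any(g in expressed for g in genes_of.get(entity.id, (entity.id,)))


@dataclass
class ConditionSpecificResult:
    active: dict[str, set[tuple[str, str]]]      # condition -> protein pairs
    specific: dict[str, set[tuple[str, str]]]
    edges: dict[str, list[CommEdge]]             # condition-specific edges


def condition_specific_edges(edges: list[CommEdge], expr: ExpressionData,
                             tx_cell: str, rx_cell: str,
                             conditions: tuple[str, str],
                             genes_of: dict[str, tuple[str, ...]]
                             ) -> ConditionSpecificResult:
    """Split communication edges by the condition they are active in.

    An edge is active in a condition iff its transmitter is expressed in the
    transmitter cell type and its receiver in the receiver cell type, both
    under that condition.  Condition-specific edges are active in exactly one
    of the two conditions.  Pair sets are over unique protein pairs.
    """
    active: dict[str, set[tuple[str, str]]] = {c: set() for c in conditions}
    by_condition: dict[str, list[CommEdge]] = {c: [] for c in conditions}
    edge_active: dict[str, set[int]] = {c: set() for c in conditions}
    for condition in conditions:
        tx_expressed = expr.expressed(condition, tx_cell)
        rx_expressed = expr.expressed(condition, rx_cell)
        for n, edge in enumerate(edges):
            if _entity_expressed(edge.transmitter, tx_expressed, genes_of) \
                    and _entity_expressed(edge.receiver, rx_expressed,
                                          genes_of):
                active[condition].add(edge.pair())
                edge_active[condition].add(n)
    this, other = conditions
    specific = {
        this: active[this] - active[other],
        other: active[other] - active[this],
    }
    for condition, opposite in ((this, other), (other, this)):
        for n in sorted(edge_active[condition]):
            if edges[n].pair() in specific[condition]:
                by_condition[condition].append(edges[n])
    return ConditionSpecificResult(active, specific, by_condition)


def ccc_counts(edges: list[CommEdge], expr: ExpressionData,
               cell_types: list[str], conditions: tuple[str, str],
               genes_of: dict[str, tuple[str, ...]]) -> pd.DataFrame:
    """Unique active protein-pair counts per (transmitter cell, receiver
    cell, condition)."""
    rows = []
    for tx_cell in cell_types:
        for rx_cell in cell_types:
            result = condition_specific_edges(edges, expr, tx_cell, rx_cell,
                                              conditions, genes_of)
            for condition in conditions:
                rows.append({"tx_cell": tx_cell, "rx_cell": rx_cell,
                             "condition": condition,
                             "n_pairs": len(result.active[condition])})
    return pd.DataFrame(rows)


# ------------------------------------------------------ downstream network

def downstream_network(net: NetworkDB, seeds: set[str], allowed: set[str],
                       k: int = 2) -> tuple[set[str], set[tuple[str, str]]]:
    """Breadth-first expansion of the directed network from receptor seeds.

    Walks ``k`` steps along directed edges, visiting only nodes in
    ``allowed`` (genes expressed in the receiving cell type), and returns the
    induced subnetwork (reached nodes and all directed edges among them).
    """
    adjacency: dict[str, set[str]] = {}
    directed = set()
    for source, target in net.directed_edges():
        adjacency.setdefault(source.id, set()).add(target.id)
        directed.add((source.id, target.id))
    reached = set(s for s in seeds if s in allowed)
    frontier = deque((s, 0) for s in sorted(reached))
    depth_of = {s: 0 for s in reached}
    while frontier:
        node, depth = frontier.popleft()
        if depth >= k:
            continue
        for neighbor in sorted(adjacency.get(node, ())):
            if neighbor in allowed and neighbor not in depth_of:
                depth_of[neighbor] = depth + 1
                reached.add(neighbor)
                frontier.append((neighbor, depth + 1))
    induced = {(s, t) for s, t in directed if s in reached and t in reached}
    return reached, induced


# ------------------------------------------------------------- enrichment

def enrich(genes: set[str], gene_sets: dict[str, set[str]],
           universe: set[str]) -> pd.DataFrame:
    """One-sided hypergeometric over-representation with BH correction.

    Gene sets are intersected with the universe; the p-value for a set of
    size K is P[overlap >= observed] when drawing |genes| items from the
    universe without replacement.
    """
    if not universe:
        raise ConfigError("enrichment needs a non-empty universe")
    if not set(genes) <= set(universe):
        raise ConfigError("query genes must be a subset of the universe")
    M, n = len(universe), len(genes)
    rows = []
    for name in sorted(gene_sets):
        members = set(gene_sets[name]) & set(universe)
        K = len(members)
        overlap = len(members & set(genes))
        p = float(stats.hypergeom.sf(overlap - 1, M, K, n))
        rows.append({"set": name, "set_size": K, "overlap": overlap,
                     "p": min(p, 1.0)})
    frame = pd.DataFrame(rows)
    if len(frame):
        frame["q"] = multipletests(frame["p"], method="fdr_bh")[1]
    else:
        frame["q"] = []
    return frame


# -------------------------------------------------------- ligand selection

def select_overexpressed_ligands(de: pd.DataFrame, roles: IntercellDB,
                                 id_service=None,
                                 adj_p: float = 0.1, log2fc: float = 1.0,
                                 gene_space: str = "genesymbol") -> set[str]:
    """Over-expressed ligands from a differential-expression table.

    ``de`` has columns (gene, log2fc, padj).  Both thresholds are strict
    (padj < 0.1 and log2fc > 1 by default); a passing gene is selected iff it
    maps to a protein in the composite ligand category.  Returns gene labels.
    """
    ligands = roles.members("ligand")
    selected: set[str] = set()
    for row in de.itertuples(index=False):
        if not (row.padj < adj_p and row.log2fc > log2fc):
            continue
        if id_service is not None:
            proteins = id_service.map_id(row.gene, gene_space, "protein")
        else:
            proteins = {row.gene}
        if proteins & ligands:
            selected.add(row.gene)
    return selected


# --------------------------------------------------- case-study networks

def assemble_case_networks(net: NetworkDB, roles: IntercellDB,
                           dorothea_max_conf: str = "C"):
    """The three graphs of the ligand-target prioritization workflow.

    * ligand-receptor graph: the dedicated ligand-receptor dataset plus any
      PPI whose source is a ligand and target a receptor;
    * signaling graph: the literature-curated activity-flow core plus the
      kinase-substrate and pathway extensions;
    * gene regulatory graph: graded TF regulons at confidence <= the cutoff
      plus the literature-curated TF-target dataset (edge weight 1.0 when
      the resource provides none).

    Graphs are returned as edge dicts {(source id, target id): weight}.
    """
    ligands = roles.members("ligand")
    receptors = roles.members("receptor")

    ligrec: dict[tuple[str, str], float] = {}
    for source, target in dataset_view(net, {"ligrecextra"}).directed_edges():
        ligrec[(source.id, target.id)] = 1.0
    ppi = dataset_view(net, {"omnipath", "pathwayextra", "kinaseextra",
                             "ligrecextra"})
    for source, target in ppi.directed_edges():
        if source.id in ligands and target.id in receptors:
            ligrec[(source.id, target.id)] = 1.0

    signaling = {(s.id, t.id): 1.0 for s, t in dataset_view(
        net, {"omnipath", "kinaseextra", "pathwayextra"}).directed_edges()}

    grn: dict[tuple[str, str], float] = {}
    tf_view = dataset_view(net, {"dorothea", "tf_target"},
                           min_confidence=dorothea_max_conf)
    for source, target in tf_view.directed_edges():
        grn[(source.id, target.id)] = 1.0
    return ligrec, signaling, grn


# ------------------------------------------------- regulatory potential

@dataclass
class RegulatoryPotential:
    """Ligand x target score matrix plus the underlying PageRank vectors."""

    scores: pd.DataFrame          # index: ligand, columns: target genes
    pagerank: pd.DataFrame        # index: ligand, columns: union-graph nodes
    damping: float


def personalized_pagerank(edges: dict[tuple[str, str], float],
                          nodes: list[str], seed: str,
                          damping: float = 0.85, tol: float = 1e-10,
                          max_iter: int = 10_000) -> np.ndarray:
    """Random walk with restart to a single seed node, by power iteration.

    The walk follows out-edges with probability proportional to edge weight;
    dangling mass and the restart probability (1 - damping) return to the
    seed.  The returned vector sums to one.
    """
    index = {node: n for n, node in enumerate(nodes)}
    size = len(nodes)
    # column-stochastic transition matrix
    matrix = np.zeros((size, size))
    out_weight = np.zeros(size)
    for (source, target), weight in edges.items():
        out_weight[index[source]] += weight
    for (source, target), weight in edges.items():
        matrix[index[target], index[source]] = weight / out_weight[
            index[source]]
    dangling = out_weight == 0
    restart = np.zeros(size)
    restart[index[seed]] = 1.0
    x = restart.copy()
    for _ in range(max_iter):
        dangling_mass = x[dangling].sum()
        new = damping * (matrix @ x + dangling_mass * restart) \
            + (1.0 - damping) * restart
        if np.abs(new - x).sum() < tol:
            return new
        x = new
    raise ArithmeticError(
        f"personalized PageRank did not converge within {max_iter} "
        f"iterations (residual {np.abs(new - x).sum():.2e}, seed {seed})")


def ligand_target_potential(union_edges: dict[tuple[str, str], float],
                            grn_edges: dict[tuple[str, str], float],
                            ligands: list[str], damping: float = 0.85,
                            tol: float = 1e-10,
                            max_iter: int = 10_000) -> RegulatoryPotential:
    """Ligand-target regulatory potential.

    For each ligand, a personalized PageRank over the union of the
    ligand-receptor and signaling graphs scores every node's proximity to
    the ligand; the ligand x node matrix is then multiplied by the weighted
    adjacency of the gene regulatory network, so a target's potential is the
    PageRank-weighted sum of its incoming regulator edges.  Targets with no
    incoming regulatory edge score exactly zero.
    """
    nodes = sorted({n for edge in union_edges for n in edge} | set(ligands))
    missing = [l for l in ligands if l not in nodes]
    if missing:
        raise ConfigError(f"ligands absent from the union graph: {missing}")
    pagerank = np.vstack([
        personalized_pagerank(union_edges, nodes, ligand, damping, tol,
                              max_iter)
        for ligand in ligands]) if ligands else np.zeros((0, len(nodes)))

    targets = sorted({t for _, t in grn_edges})
    node_index = {node: n for n, node in enumerate(nodes)}
    target_index = {t: n for n, t in enumerate(targets)}
    adjacency = np.zeros((len(nodes), len(targets)))
    for (regulator, target), weight in grn_edges.items():
        if regulator in node_index:
            adjacency[node_index[regulator], target_index[target]] = weight
    scores = pagerank @ adjacency
    return RegulatoryPotential(
        pd.DataFrame(scores, index=list(ligands), columns=targets),
        pd.DataFrame(pagerank, index=list(ligands), columns=nodes),
        damping)
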