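"""Intercell join, condition-specific communication, downstream networks,
enrichment and ligand-target regulatory potential."""

import itertools
import math
import random

import numpy as np
import pandas as pd
import pytest

import crosstalk_kb.comm as comm
from crosstalk_kb.build import genes_of_map
from crosstalk_kb.model import ConfigError, Entity
from crosstalk_kb.network import dataset_view


# ------------------------------------------------------ intercell join

def _nested_loop_join(net, roles, profile):
    """Independent oracle: plain nested loops over (interactions x
    transmitter members x receiver members)."""
    excluded = profile.excluded_categories if profile else frozenset()
    membrane = roles.membrane_bound()
    tx = [(c.name, roles.members(c.name))
          for c in roles.composite_categories(aspect="functional",
                                              transmitter=True)
          if c.name not in excluded]
    rx = [(c.name, roles.members(c.name))
          for c in roles.composite_categories(aspect="functional",
                                              receiver=True)
          if c.name not in excluded]
    out = set()
    for i in net:
        for direction in i.directions_asserted():
            s, t = (i.a, i.b) if direction == "a_to_b" else (i.b, i.a)
            if profile and profile.require_membrane_receiver \
                    and t.id not in membrane:
                continue
            for tname, tmembers in tx:
                for rname, rmembers in rx:
                    if s.id in tmembers and t.id in rmembers:
                        out.add((s.id, tname, t.id, rname, i.key()))
    return out


@pytest.mark.parametrize("profile", [None, comm.UC_PROFILE],
                         ids=["unfiltered", "uc_profile"])
def test_join_equals_nested_loop_oracle(kb, profile):
    edges = comm.build_intercell_network(kb.network, kb.intercell, profile)
    got = {(e.transmitter.id, e.transmitter_category, e.receiver.id,
            e.receiver_category, e.interaction_key) for e in edges}
    assert got == _nested_loop_join(kb.network, kb.intercell, profile)
    assert len(got) == len(edges)  # no duplicate CommEdges


def test_uc_profile_receivers_membrane_and_no_excluded_categories(kb):
    edges = comm.build_intercell_network(kb.network, kb.intercell,
                                         comm.UC_PROFILE)
    membrane = kb.intercell.membrane_bound()
    for e in edges:
        assert e.receiver.id in membrane
        assert e.transmitter_category not in comm.UC_EXCLUDED_CATEGORIES
        assert e.receiver_category not in comm.UC_EXCLUDED_CATEGORIES


# ------------------------------------------------------ expressed genes

def test_expressed_genes_all_zero():
    assert comm.expressed_genes({"a": 0.0, "b": 0.0}) == set()


def test_expressed_genes_zero_variance_strictness():
    # t equals the common value; strict inequality empties the set
    assert comm.expressed_genes({"a": 10, "b": 10, "c": 10}) == set()


def test_expressed_genes_worked_example():
    values = dict(zip("abcdef", [8, 9, 10, 11, 12, 1]))
    arr = np.array([8, 9, 10, 11, 12, 1], dtype=float)
    t = arr.mean() - 2 * arr.std(ddof=1)
    assert math.isclose(t, 8.5 - 2 * math.sqrt(15.5))
    assert comm.expressed_genes(values) == set("abcdef")


def test_expressed_genes_single_nonzero():
    assert comm.expressed_genes({"a": 3.0, "b": 0.0}) == {"a"}


# --------------------------------------------- condition-specific edges

@pytest.fixture(scope="module")
def ccc_inputs(kb, fixture_dir):
    base, manifest = fixture_dir
    edges = comm.build_intercell_network(kb.network, kb.intercell,
                                         comm.UC_PROFILE)
    expr = comm.ExpressionData.from_tsv(base / "expression.tsv")
    return edges, expr, genes_of_map(kb), manifest


def test_condition_specific_recovery_matches_manifest(ccc_inputs):
    edges, expr, genes_of, manifest = ccc_inputs
    result = comm.condition_specific_edges(
        edges, expr, "myofibroblast", "treg", ("healthy", "uc"), genes_of)
    expected = manifest["comm"]["ccc"]
    assert result.specific["uc"] == {tuple(p)
                                     for p in expected["uc_specific"]}
    assert result.specific["healthy"] == {
        tuple(p) for p in expected["healthy_specific"]}
    for condition in ("healthy", "uc"):
        assert result.active[condition] == {
            tuple(p) for p in expected["active"][condition]}


def test_condition_specific_sets_disjoint_and_exclude_shared(ccc_inputs):
    edges, expr, genes_of, _ = ccc_inputs
    result = comm.condition_specific_edges(
        edges, expr, "myofibroblast", "treg", ("healthy", "uc"), genes_of)
    assert not (result.specific["healthy"] & result.specific["uc"])
    shared = result.active["healthy"] & result.active["uc"]
    assert not (shared & (result.specific["healthy"]
                          | result.specific["uc"]))


def test_per_cell_pair_counts_match_manifest(ccc_inputs):
    edges, expr, genes_of, manifest = ccc_inputs
    counts = comm.ccc_counts(
        edges, expr, ["myofibroblast", "treg", "macrophage"],
        ("healthy", "uc"), genes_of)
    expected = manifest["comm"]["ccc"]["per_cell_pair_counts"]
    for row in counts.itertuples(index=False):
        key = f"{row.tx_cell}->{row.rx_cell}|{row.condition}"
        assert expected[key] == row.n_pairs, key


def test_missing_profile_is_usage_error(ccc_inputs):
    edges, expr, genes_of, _ = ccc_inputs
    with pytest.raises(ConfigError):
        comm.condition_specific_edges(edges, expr, "no_such_cell", "treg",
                                      ("healthy", "uc"), genes_of)


# ----------------------------------------------------- downstream network

def _bfs_oracle(edges, seeds, allowed, k):
    """Independent depth-limited BFS over an explicit edge list."""
    level = {s: 0 for s in seeds if s in allowed}
    frontier = set(level)
    for depth in range(1, k + 1):
        nxt = set()
        for s, t in edges:
            if s in frontier and t in allowed and t not in level:
                nxt.add(t)
        for node in nxt:
            level[node] = depth
        frontier = nxt
    nodes = set(level)
    return nodes, {(s, t) for s, t in edges if s in nodes and t in nodes}


def test_downstream_chain_example():
    from crosstalk_kb.network import NetworkDB
    from crosstalk_kb.model import Evidence
    db = NetworkDB()
    for s, t in (("a", "b"), ("b", "c"), ("c", "d")):
        db.add(Entity("protein", s), Entity("protein", t),
               "post_translational", Evidence("r", direction="a_to_b"))
    allowed = {"a", "b", "c", "d"}
    nodes, edges = comm.downstream_network(db, {"a"}, allowed, 2)
    assert nodes == {"a", "b", "c"}
    assert edges == {("a", "b"), ("b", "c")}
    nodes, _ = comm.downstream_network(db, {"d"}, allowed, 2)
    assert nodes == {"d"}  # seed without outgoing edges


def test_downstream_matches_bfs_oracle_and_monotone(kb, ccc_inputs):
    edges, expr, genes_of, _ = ccc_inputs
    result = comm.condition_specific_edges(
        edges, expr, "myofibroblast", "treg", ("healthy", "uc"), genes_of)
    directed = {(s.id, t.id) for s, t in kb.network.directed_edges()}
    allowed = {acc for acc, genes in genes_of.items()
               if any(g in expr.expressed("uc", "treg") for g in genes)}
    seeds = {t for _, t in result.specific["uc"]} & allowed
    previous_nodes = set()
    for k in range(0, 4):
        nodes, induced = comm.downstream_network(kb.network, seeds, allowed,
                                                 k)
        assert (nodes, induced) == _bfs_oracle(directed, seeds, allowed, k)
        assert previous_nodes <= nodes  # monotone in k
        previous_nodes = nodes


# ------------------------------------------------------------ enrichment

def test_enrichment_trivial_full_overlap():
    df = comm.enrich({"a", "b"}, {"s": {"a", "b"}}, {"a", "b"})
    assert df.loc[0, "p"] == pytest.approx(1.0)


def _enumeration_p(universe, members, drawn, overlap):
    total = 0
    hits = 0
    for combo in itertools.combinations(sorted(universe), drawn):
        total += 1
        if len(set(combo) & members) >= overlap:
            hits += 1
    return hits / total


def test_enrichment_matches_exhaustive_enumeration():
    rng = random.Random(23)
    universe = {f"g{i}" for i in range(12)}
    for _ in range(20):
        members = set(rng.sample(sorted(universe), rng.randint(1, 6)))
        genes = set(rng.sample(sorted(universe), rng.randint(1, 6)))
        df = comm.enrich(genes, {"s": members}, universe)
        expected = _enumeration_p(universe, members, len(genes),
                                  int(df.loc[0, "overlap"]))
        assert df.loc[0, "p"] == pytest.approx(expected, abs=1e-12)


def test_bh_hand_computed_five_values():
    """Step-up BH on a fixed 5-value example, worked by hand:
    sorted p = (.01,.02,.03,.04,.25); q_i = min_{j>=i} p_j * 5/j."""
    sets = {f"s{i}": {f"x{i}"} for i in range(5)}
    universe = {f"x{i}" for i in range(5)} | {"y"}

    from statsmodels.stats.multitest import multipletests  # sanity anchor
    # raw p_j * 5/j = (.05, .05, .05, .05, .25); right-to-left cummin
    p = [0.01, 0.02, 0.03, 0.04, 0.25]
    hand = [0.05, 0.05, 0.05, 0.05, 0.25]
    got = multipletests(p, method="fdr_bh")[1]
    assert np.allclose(got, hand)
    # and the package's own BH column is monotone after sorting by p
    df = comm.enrich({"x0", "x1"}, sets, universe).sort_values("p")
    assert (df["q"].values[1:] >= df["q"].values[:-1] - 1e-15).all()


def test_enrichment_usage_errors():
    with pytest.raises(ConfigError):
        comm.enrich({"a"}, {}, set())
    with pytest.raises(ConfigError):
        comm.enrich({"z"}, {}, {"a"})


# -------------------------------------------------------- ligand selection

def test_select_ligands_thresholds_strict(kb, fixture_dir):
    base, manifest = fixture_dir
    de = pd.read_csv(base / "de.tsv", sep="\t")
    selected = comm.select_overexpressed_ligands(de, kb.intercell,
                                                 kb.id_service)
    assert selected == set(manifest["comm"]["selected_ligands"])
    # boundary rows (padj == 0.1 or log2fc == 1.0) are excluded
    boundary = de[(de["padj"] == 0.1) | (de["log2fc"] == 1.0)]["gene"]
    assert not (set(boundary) & selected)


# --------------------------------------------------- regulatory potential

def _dense_power_iteration(edges, nodes, seed, damping, iterations=20_000):
    """Independent oracle: dense column-stochastic iteration to fixpoint."""
    idx = {n: i for i, n in enumerate(nodes)}
    size = len(nodes)
    weight = np.zeros((size, size))
    for (s, t), w in edges.items():
        weight[idx[t], idx[s]] += w
    col = weight.sum(axis=0)
    v = np.zeros(size)
    v[idx[seed]] = 1.0
    x = np.full(size, 1.0 / size)
    for _ in range(iterations):
        y = np.zeros(size)
        for j in range(size):
            if col[j] > 0:
                y += damping * x[j] * weight[:, j] / col[j]
            else:
                y += damping * x[j] * v
        y += (1 - damping) * v
        if np.abs(y - x).sum() < 1e-14:
            break
        x = y
    return x


def test_pagerank_single_node_graph():
    vec = comm.personalized_pagerank({}, ["a"], "a")
    assert vec[0] == pytest.approx(1.0)


def test_pagerank_five_node_fixture_matches_dense_oracle():
    edges = {("a", "b"): 1.0, ("b", "c"): 2.0, ("c", "a"): 1.0,
             ("a", "d"): 0.5, ("d", "e"): 1.0}
    nodes = list("abcde")
    for seed in nodes:
        mine = comm.personalized_pagerank(edges, nodes, seed)
        oracle = _dense_power_iteration(edges, nodes, seed, 0.85)
        assert np.abs(mine - oracle).max() < 1e-8
        assert mine.sum() == pytest.approx(1.0, abs=1e-9)


def test_regulatory_potential_on_fixture(kb):
    ligrec, signaling, grn = comm.assemble_case_networks(kb.network,
                                                         kb.intercell)
    union = dict(signaling)
    union.update(ligrec)
    ligands = sorted({s for s, _ in ligrec}
                     & kb.intercell.members("ligand"))[:4]
    rp = comm.ligand_target_potential(union, grn, ligands)
    sums = rp.pagerank.sum(axis=1)
    assert np.allclose(sums, 1.0, atol=1e-9)
    assert (rp.scores.values >= 0).all()
    # a node with no incoming regulatory edge has potential 0 for all ligands
    no_incoming = sorted({n for e in union for n in e}
                         - {t for _, t in grn})
    assert no_incoming  # fixture guarantees some
    for node in no_incoming:
        assert node not in rp.scores.columns


def test_regulatory_potential_linear_in_grn_weights(kb):
    ligrec, signaling, grn = comm.assemble_case_networks(kb.network,
                                                         kb.intercell)
    union = dict(signaling)
    union.update(ligrec)
    ligands = sorted({s for s, _ in ligrec}
                     & kb.intercell.members("ligand"))[:2]
    rp1 = comm.ligand_target_potential(union, grn, ligands)
    scaled = {edge: 3.0 * w for edge, w in grn.items()}
    rp3 = comm.ligand_target_potential(union, scaled, ligands)
    assert np.allclose(rp3.scores.values, 3.0 * rp1.scores.values)


def test_grn_excludes_low_confidence_regulons(kb):
    _, _, grn = comm.assemble_case_networks(kb.network, kb.intercell,
                                            dorothea_max_conf="C")
    d_only = dataset_view(kb.network, {"dorothea"}, min_confidence="D")
    c_view = dataset_view(kb.network, {"dorothea"}, min_confidence="C")
    d_edges = {(s.id, t.id) for s, t in d_only.directed_edges()} \
        - {(s.id, t.id) for s, t in c_view.directed_edges()}
    tf_target = {(s.id, t.id) for s, t in dataset_view(
        kb.network, {"tf_target"}).directed_edges()}
    for edge in d_edges - tf_target:
        assert edge not in grn
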