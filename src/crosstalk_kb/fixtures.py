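"""Seeded generator of a complete synthetic knowledge base.

Real builds of this kind of resource integrate >100 live databases; tests
and examples instead run on a synthetic knowledge base that emulates every
input format (interaction tables, enzyme-substrate tables, complex lists,
annotation tables, role tables, GO annotations, mapping and homology tables,
isoform FASTA, expression matrices, differential-expression tables) with
*planted ground truth*.

Generation is manifest-first: the truth (unique interaction keys per dataset,
contradiction edges, valid/invalid PTM sites, complex identities, role
memberships, expression states, ...) is sampled first, the resource files are
rendered from it second, and the manifest is written alongside.  The manifest
therefore predicts every database summary exactly and serves as the oracle
for build and analysis tests without re-implementing the system under test.

All identifiers live in a reserved fake namespace (``P0Tnnnn`` accessions,
``GENEnnn`` symbols) to avoid collision with real data.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

import yaml

AA20 = "ACDEFGHIKLMNPQRSTVWY"

CELL_TYPES = ["myofibroblast", "treg", "macrophage"]
CONDITIONS = ("healthy", "uc")

MODIFICATIONS = ("phosphorylation", "dephosphorylation", "acetylation",
                 "proteolytic cleavage")
MOD_WEIGHTS = (0.7, 0.1, 0.1, 0.1)

MOUSE_TAXID = 10090
HUMAN_TAXID = 9606


@dataclass
class FixtureSizes:
    """Problem sizes of the synthetic knowledge base.

    Defaults are small enough for sub-second builds while exercising every
    merge path: overlapping resources, contradictions, ambiguity, invalid
    residues, duplicate complexes, excluded role members.
    """

    n_proteins: int = 60
    n_mirnas: int = 3
    n_lncrnas: int = 2
    n_omnipath: int = 30
    n_kinaseextra: int = 8
    n_pathwayextra: int = 8
    n_ligrecextra: int = 12
    n_dorothea: int = 12
    n_tf_target: int = 8
    n_post_transcriptional: int = 6
    n_tf_mirna: int = 3
    n_lncrna_mrna: int = 3
    n_contradictions: int = 3
    n_ptm_valid: int = 18
    n_ptm_invalid: int = 6
    n_ptm_no_sequence: int = 2
    n_complexes: int = 12
    n_member_annotations: int = 15
    homology_fraction: float = 0.7
    site_homology_fraction: float = 0.75
    site_mismatch_fraction: float = 0.3
    n_uc_specific: int = 5
    n_healthy_specific: int = 3


# --------------------------------------------------------------- helpers

def _acc(i: int) -> str:
    return f"P0T{i:04d}"


def _sym(i: int) -> str:
    return f"GENE{i:03d}"


def _write(path: Path, text: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(text, encoding="utf-8")


def _tsv(header: list[str], rows: list[list[str]]) -> str:
    lines = ["\t".join(header)]
    lines += ["\t".join(str(c) for c in row) for row in rows]
    return "\n".join(lines) + "\n"


def _sample_pairs(rng: random.Random, sources, targets, n: int,
                  used: set[frozenset], allow_self: bool = False
                  ) -> list[tuple[str, str]]:
    """Directed pairs whose unordered key is globally unique."""
    out = []
    guard = 0
    while len(out) < n:
        guard += 1
        if guard > 100_000:
            raise RuntimeError("cannot sample enough unique pairs")
        s = rng.choice(sources)
        t = rng.choice(targets)
        if s == t and not allow_self:
            continue
        key = frozenset((s, t))
        if key in used:
            continue
        used.add(key)
        out.append((s, t))
    return out


# ---------------------------------------------------------------- truth

@dataclass
class Truth:
    """In-memory planted ground truth, sampled before any file is written."""

    accs: list[str] = field(default_factory=list)
    sym_of: dict[str, str] = field(default_factory=dict)
    mirnas: list[str] = field(default_factory=list)
    lncrnas: list[str] = field(default_factory=list)
    roles: dict[str, set[str]] = field(default_factory=dict)
    role_tables: dict[str, list[tuple[str, str]]] = field(
        default_factory=dict)  # resource -> (category, entity)
    go_terms: dict[str, set[str]] = field(default_factory=dict)
    exclusions: dict[str, set[str]] = field(default_factory=dict)
    composite: dict[str, set[str]] = field(default_factory=dict)
    membrane: set[str] = field(default_factory=set)
    pools: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    signs: dict[tuple[str, str], str] = field(default_factory=dict)
    contradictions: list[tuple[str, str]] = field(default_factory=list)
    sequences: dict[str, list[str]] = field(default_factory=dict)
    ptm_valid: list[tuple] = field(default_factory=list)   # 5-field keys
    ptm_invalid: list[tuple] = field(default_factory=list)
    complex_sets: list[list[str]] = field(default_factory=list)
    complex_stoich: dict[int, dict[str, int]] = field(default_factory=dict)
    annotation_records: dict[str, dict[str, list[dict]]] = field(
        default_factory=dict)  # resource -> entity -> records
    translatable: set[str] = field(default_factory=set)
    mouse_acc: dict[str, str] = field(default_factory=dict)
    mouse_seq: dict[str, str] = field(default_factory=dict)
    site_rows: list[tuple] = field(default_factory=list)
    expressed: dict[tuple[str, str], set[str]] = field(default_factory=dict)
    expr_values: dict[tuple[str, str], dict[str, float]] = field(
        default_factory=dict)
    de_rows: list[tuple[str, float, float]] = field(default_factory=list)


# ------------------------------------------------------------ generation

def generate_knowledgebase(seed: int, out_dir,
                           sizes: FixtureSizes | None = None) -> dict:
    """Write a complete synthetic knowledge base and return its manifest.

    Deterministic given (seed, sizes): the same call produces byte-identical
    files.  The manifest (also written to ``manifest.yaml``) predicts every
    database summary of a build over the generated files.
    """
    sizes = sizes or FixtureSizes()
    rng = random.Random(seed)
    out = Path(out_dir)
    truth = Truth()

    _plant_entities(rng, sizes, truth)
    _plant_roles(rng, sizes, truth)
    _plant_interactions(rng, sizes, truth)
    _plant_sequences_and_ptms(rng, sizes, truth)
    _plant_complexes(rng, sizes, truth)
    _plant_annotations(rng, sizes, truth)
    _plant_homology(rng, sizes, truth)
    generate_expression(rng, CELL_TYPES, CONDITIONS, truth, sizes)
    _plant_de_table(rng, sizes, truth)

    _render_files(out, truth, sizes)
    manifest = _build_manifest(seed, truth, sizes)
    _write(out / "manifest.yaml",
           yaml.safe_dump(manifest, sort_keys=True))
    return manifest


def _plant_entities(rng, sizes, truth: Truth) -> None:
    truth.accs = [_acc(i) for i in range(1, sizes.n_proteins + 1)]
    truth.sym_of = {_acc(i): _sym(i) for i in range(1, sizes.n_proteins + 1)}
    # a protein with an accession and symbol but no sequence record
    truth.sym_of["P0TMISS"] = "GENEMISS"
    truth.mirnas = [f"hsa-miR-T{i}-5p" for i in range(1, sizes.n_mirnas + 1)]
    truth.lncrnas = [f"LNCT{i}" for i in range(1, sizes.n_lncrnas + 1)]


def _plant_roles(rng, sizes, truth: Truth) -> None:
    shuffled = rng.sample(truth.accs, len(truth.accs))
    roles = {
        "ligand": set(shuffled[0:10]),
        "receptor": set(shuffled[10:20]),
        "ecm": set(shuffled[20:23]),
        "adhesion": set(shuffled[23:27]),
        "transporter": set(shuffled[27:30]),
        "secreted_enzyme": set(shuffled[30:33]),
        "junction": set(shuffled[33:36]),
        "ecm_regulator": set(shuffled[36:38]),
    }
    truth.roles = roles
    wrong_ligand = shuffled[38]
    decoy = shuffled[39]
    truth.exclusions = {"ligand": {wrong_ligand}}
    ligands = sorted(roles["ligand"])
    receptors = sorted(roles["receptor"])
    no_mem_receptor = receptors[-1]

    truth.roles["secreted"] = roles["ligand"] | roles["ecm"] \
        | roles["secreted_enzyme"]
    truth.roles["plasma_membrane_transmembrane"] = \
        (roles["receptor"] - {no_mem_receptor}) | roles["transporter"] \
        | roles["junction"]
    truth.roles["plasma_membrane_peripheral"] = set(roles["adhesion"])
    truth.membrane = truth.roles["plasma_membrane_transmembrane"] \
        | truth.roles["plasma_membrane_peripheral"]

    truth.go_terms = {}
    for acc in roles["ligand"] | {decoy}:
        truth.go_terms.setdefault(acc, set()).add("GO:0000001")
    for acc in roles["receptor"] | {decoy}:
        truth.go_terms.setdefault(acc, set()).add("GO:0000002")

    truth.role_tables = {
        "roles_a": sorted(
            [("ligand", a) for a in ligands[0:7]]
            + [("receptor", a) for a in receptors[0:7]]
            + [("ecm", a) for a in sorted(roles["ecm"])]
            + [("adhesion", a) for a in sorted(roles["adhesion"])]),
        "roles_b": sorted(
            [("ligand", a) for a in ligands[4:10] + [wrong_ligand]]
            + [("receptor", a) for a in receptors[5:10]]
            + [("transporter", a) for a in sorted(roles["transporter"])]
            + [("secreted_enzyme", a)
               for a in sorted(roles["secreted_enzyme"])]
            + [("junction", a) for a in sorted(roles["junction"])]
            + [("ecm_regulator", a)
               for a in sorted(roles["ecm_regulator"])]),
        "loc_db": sorted(
            [("secreted", a) for a in sorted(truth.roles["secreted"])]
            + [("plasma_membrane_transmembrane", a) for a in
               sorted(truth.roles["plasma_membrane_transmembrane"])]
            + [("plasma_membrane_peripheral", a) for a in
               sorted(truth.roles["plasma_membrane_peripheral"])]),
    }

    # composite = union of role tables and GO contributors minus exclusions;
    # GO expressions reproduce the ligand/receptor sets (decoy carries both
    # terms, so the and-not expressions reject it).
    go_ligand = {a for a, t in truth.go_terms.items()
                 if "GO:0000001" in t and "GO:0000002" not in t}
    go_receptor = {a for a, t in truth.go_terms.items()
                   if "GO:0000002" in t and "GO:0000001" not in t}
    per_name: dict[str, set[str]] = {}
    for table in truth.role_tables.values():
        for category, entity in table:
            per_name.setdefault(category, set()).add(entity)
    per_name["ligand"] = per_name.get("ligand", set()) | go_ligand
    per_name["receptor"] = per_name.get("receptor", set()) | go_receptor
    truth.composite = {
        name: members - truth.exclusions.get(name, set())
        for name, members in per_name.items()}


def _plant_interactions(rng, sizes, truth: Truth) -> None:
    used: set[frozenset] = set()
    ligands = sorted(truth.roles["ligand"])
    receptors = sorted(truth.roles["receptor"])
    no_mem_receptor = receptors[-1]

    ligrec = [(ligands[0], no_mem_receptor)]
    used.add(frozenset(ligrec[0]))
    ligrec += _sample_pairs(rng, ligands, receptors,
                            sizes.n_ligrecextra - 1, used)
    omnipath = _sample_pairs(rng, truth.accs, truth.accs,
                             sizes.n_omnipath - 1, used)
    self_node = rng.choice(truth.accs)
    omnipath.append((self_node, self_node))  # autocrine self-loop
    used.add(frozenset((self_node,)))
    kinase = _sample_pairs(rng, truth.accs, truth.accs,
                           sizes.n_kinaseextra, used)
    pathway = _sample_pairs(rng, truth.accs, truth.accs,
                            sizes.n_pathwayextra, used)

    used_tx: set[frozenset] = set()
    tfs = rng.sample(truth.accs, 4)
    dorothea = _sample_pairs(rng, tfs, truth.accs, sizes.n_dorothea, used_tx)
    tf_target = _sample_pairs(rng, tfs, truth.accs, sizes.n_tf_target,
                              used_tx)
    mirna = _sample_pairs(rng, truth.mirnas, truth.accs,
                          sizes.n_post_transcriptional, set())
    tf_mirna = _sample_pairs(rng, tfs, truth.mirnas, sizes.n_tf_mirna, set())
    lncrna = _sample_pairs(rng, truth.lncrnas, truth.accs,
                           sizes.n_lncrna_mrna, set())

    truth.pools = {
        "omnipath": omnipath, "kinaseextra": kinase,
        "pathwayextra": pathway, "ligrecextra": ligrec,
        "dorothea": dorothea, "tf_target": tf_target,
        "post_transcriptional": mirna, "tf_mirna": tf_mirna,
        "lncrna_mrna": lncrna,
    }
    for pool in truth.pools.values():
        for pair in pool:
            truth.signs[pair] = rng.choice(("+", "-"))
    truth.contradictions = [tuple(sorted(p))
                            for p in omnipath[10:10 + sizes.n_contradictions]]


def _plant_sequences_and_ptms(rng, sizes, truth: Truth) -> None:
    for acc in truth.accs:
        seq = "".join(rng.choice(AA20)
                      for _ in range(rng.randint(40, 60)))
        truth.sequences[acc] = [seq]
    for acc in truth.accs[:10]:
        seq = list(truth.sequences[acc][0])
        for pos in rng.sample(range(len(seq)), 5):
            seq[pos] = rng.choice([a for a in AA20 if a != seq[pos]])
        truth.sequences[acc].append("".join(seq))

    enzymes = rng.sample(truth.accs, 4)
    keys: set[tuple] = set()
    # two sites valid only on the alternative isoform
    iso2_only = 0
    while len(keys) < sizes.n_ptm_valid:
        enzyme = rng.choice(enzymes)
        if iso2_only < 2:
            substrate = rng.choice(truth.accs[:10])
            iso1, iso2 = truth.sequences[substrate]
            diff = [n for n in range(min(len(iso1), len(iso2)))
                    if iso1[n] != iso2[n]]
            pos = rng.choice(diff) + 1
            letter = iso2[pos - 1]
        else:
            substrate = rng.choice(truth.accs)
            pos = rng.randint(1, len(truth.sequences[substrate][0]))
            letter = truth.sequences[substrate][0][pos - 1]
        modification = rng.choices(MODIFICATIONS, MOD_WEIGHTS)[0]
        key = (enzyme, substrate, letter, pos, modification)
        if key in keys:
            continue
        keys.add(key)
        iso2_only += 1 if iso2_only < 2 else 0
        truth.ptm_valid.append(key)

    for _ in range(sizes.n_ptm_invalid):
        enzyme = rng.choice(enzymes)
        substrate = rng.choice(truth.accs)
        pos = rng.randint(1, len(truth.sequences[substrate][0]))
        present = {seq[pos - 1] for seq in truth.sequences[substrate]
                   if pos <= len(seq)}
        letter = rng.choice([a for a in AA20 if a not in present])
        modification = rng.choices(MODIFICATIONS, MOD_WEIGHTS)[0]
        truth.ptm_invalid.append(
            (enzyme, substrate, letter, pos, modification))


def _plant_complexes(rng, sizes, truth: Truth) -> None:
    seen: set[frozenset] = set()
    homomer_accs = rng.sample(truth.accs, 2)
    for acc in homomer_accs:
        truth.complex_sets.append([acc])
        seen.add(frozenset((acc,)))
    while len(truth.complex_sets) < sizes.n_complexes:
        members = sorted(rng.sample(truth.accs, rng.randint(2, 5)))
        if frozenset(members) in seen:
            continue
        seen.add(frozenset(members))
        truth.complex_sets.append(members)
    for idx in (0, 1, 2, 3, 4, 5, 6):
        truth.complex_stoich[idx] = {
            acc: (2 if len(truth.complex_sets[idx]) == 1
                  else rng.randint(1, 3))
            for acc in truth.complex_sets[idx]}


def _plant_annotations(rng, sizes, truth: Truth) -> None:
    member_entities = rng.sample(truth.accs, sizes.n_member_annotations)
    truth.annotation_records["memberdb"] = {
        acc: [{"in_resource": "true"}] for acc in member_entities}

    pathdb: dict[str, list[dict]] = {}
    agree = set(truth.complex_sets[2]) | set(truth.complex_sets[3])
    for acc in sorted(agree):
        pathdb[acc] = [{"pathway": "WNT", "effect": "activation"}]
    disagree = [a for a in truth.complex_sets[4] if a not in agree]
    for n, acc in enumerate(sorted(disagree)):
        pathdb.setdefault(acc, []).append(
            {"pathway": "NOTCH" if n % 2 else "TGF", "effect": "activation"})
    blocked = agree | set(disagree)
    candidates = [a for a in truth.accs if a not in blocked]
    for acc in rng.sample(candidates, 8):
        pathdb.setdefault(acc, []).append(
            {"pathway": rng.choice(("NOTCH", "TGF", "MAPK")),
             "effect": rng.choice(("activation", "repression"))})
    truth.annotation_records["pathdb"] = pathdb


def _plant_homology(rng, sizes, truth: Truth) -> None:
    n = int(round(sizes.homology_fraction * len(truth.accs)))
    translatable = sorted(rng.sample(truth.accs, n))
    truth.translatable = set(translatable)
    for acc in translatable:
        i = int(acc[3:])
        truth.mouse_acc[acc] = f"M0T{i:04d}"
        truth.mouse_seq[truth.mouse_acc[acc]] = truth.sequences[acc][0]

    mismatch_sites = []
    for key in truth.ptm_valid:
        _, substrate, letter, pos, _ = key
        if substrate not in truth.translatable:
            continue
        if rng.random() >= sizes.site_homology_fraction:
            continue
        target_acc = truth.mouse_acc[substrate]
        truth.site_rows.append(
            (substrate, pos, MOUSE_TAXID, target_acc, pos))
        if rng.random() < sizes.site_mismatch_fraction:
            mismatch_sites.append((target_acc, pos, letter))
    for target_acc, pos, letter in mismatch_sites:
        seq = list(truth.mouse_seq[target_acc])
        seq[pos - 1] = rng.choice([a for a in AA20 if a != letter])
        truth.mouse_seq[target_acc] = "".join(seq)


def generate_expression(rng, cell_types, conditions, truth: Truth,
                        sizes: FixtureSizes) -> None:
    """Plant per-cell-type, per-condition expression states.

    Log2 values for expressed genes are drawn uniformly from (6, 10), far
    above the mean-minus-2-sd threshold of any profile, so the expressed set
    equals the nonzero set by construction; condition specificity is planted
    by zeroing one endpoint gene of selected ligand-receptor pairs in exactly
    one condition.  Raises when a planted pair references an absent gene.
    """
    symbols = sorted(truth.sym_of.values())
    noise = [f"NOISE{i:02d}" for i in range(1, 11)]
    expressed: dict[tuple[str, str], set[str]] = {
        (cond, cell): set(symbols) for cond in conditions
        for cell in cell_types}
    for cond in conditions:
        for cell in cell_types:
            for gene in noise:
                if rng.random() < 0.7:
                    expressed[(cond, cell)].add(gene)

    ligrec = truth.pools["ligrecextra"]
    comm_ok = [(l, r) for l, r in ligrec
               if r in truth.membrane
               and l in truth.composite["ligand"]
               and r in truth.composite["receptor"]]
    planted = rng.sample(comm_ok, min(len(comm_ok),
                                      sizes.n_uc_specific
                                      + sizes.n_healthy_specific))
    for n, (ligand, receptor) in enumerate(planted):
        for gene in (truth.sym_of[ligand], truth.sym_of[receptor]):
            if gene not in symbols:
                raise ValueError(f"planted gene absent from matrix: {gene}")
        absent_cond = "healthy" if n < sizes.n_uc_specific else "uc"
        if n % 2 == 0:
            expressed[(absent_cond, "myofibroblast")].discard(
                truth.sym_of[ligand])
        else:
            expressed[(absent_cond, "treg")].discard(
                truth.sym_of[receptor])

    truth.expressed = expressed
    all_genes = sorted(set(symbols) | set(noise))
    for cond in conditions:
        for cell in cell_types:
            values = {}
            for gene in all_genes:
                values[gene] = round(rng.uniform(6.0, 10.0), 3) \
                    if gene in expressed[(cond, cell)] else 0.0
            truth.expr_values[(cond, cell)] = values


def _plant_de_table(rng, sizes, truth: Truth) -> None:
    ligand_syms = sorted(truth.sym_of[a] for a in truth.composite["ligand"])
    wrong = sorted(truth.exclusions["ligand"])[0]
    rows: list[tuple[str, float, float]] = []
    for sym in ligand_syms[:5]:     # pass both strict thresholds
        rows.append((sym, round(rng.uniform(1.2, 3.0), 3),
                     round(rng.uniform(0.001, 0.09), 4)))
    rows.append((ligand_syms[5], 0.5, 0.01))        # fold-change too small
    rows.append((ligand_syms[6], 2.0, 0.5))         # not significant
    rows.append((ligand_syms[7], 1.0, 0.01))        # boundary: strict fail
    rows.append((truth.sym_of[wrong], 2.5, 0.01))   # excluded from composite
    non_ligands = sorted(set(truth.accs) - truth.composite["ligand"]
                         - truth.exclusions["ligand"])
    for acc in rng.sample(non_ligands, 4):          # pass but not ligands
        rows.append((truth.sym_of[acc], round(rng.uniform(1.2, 3.0), 3),
                     round(rng.uniform(0.001, 0.09), 4)))
    truth.de_rows = sorted(rows)


# ------------------------------------------------------------- rendering

def _dirty(symbol: str) -> str:
    """A non-standard label form the normalizer must repair."""
    return (symbol[:4] + "-" + symbol[4:]).lower()


def _refs(rng) -> str:
    return ";".join(str(rng.randint(10_000_000, 39_999_999))
                    for _ in range(rng.randint(1, 3)))


def _interaction_rows(rng, pairs, truth, directed=True, signed=True,
                      with_refs=True, confidences=None, sym_endpoints=True,
                      flip_signs_for=(), dirty_rows=()):
    rows = []
    for n, (s, t) in enumerate(pairs):
        sign = truth.signs[(s, t)] if signed else ""
        if tuple(sorted((s, t))) in flip_signs_for:
            sign = "-" if sign == "+" else "+"
        label_s = truth.sym_of.get(s, s)
        label_t = truth.sym_of.get(t, t)
        if n in dirty_rows:
            label_s = _dirty(label_s)
        rows.append([label_s if sym_endpoints else s,
                     label_t if sym_endpoints else t,
                     "1" if directed else "0", sign,
                     _refs(rng) if with_refs else "",
                     confidences[n] if confidences else ""])
    return rows


def _render_files(out: Path, truth: Truth, sizes: FixtureSizes) -> None:
    rng = random.Random(0xF1C5)  # presentation-only randomness
    res = out / "resources"
    header = ["source", "target", "is_directed", "sign", "references",
              "confidence"]

    omnipath = truth.pools["omnipath"]
    rows_a = _interaction_rows(rng, omnipath[:20], truth, dirty_rows=(1,))
    rows_a.append(["NOSYM1", _sym(1), "1", "+", "", ""])       # unmappable
    rows_a.append([_sym(2), "NOSYM2", "1", "-", "", ""])       # unmappable
    text_a = _tsv(header, rows_a)
    text_a += "MALFORMED\tROW\n"                               # skipped
    _write(res / "ppi_a.tsv", text_a)

    contradiction_keys = set(truth.contradictions)
    _write(res / "ppi_b.tsv", _tsv(header, _interaction_rows(
        rng, omnipath[10:28], truth, flip_signs_for=contradiction_keys)))
    _write(res / "ppi_c.tsv", _tsv(header, _interaction_rows(
        rng, omnipath[0:5] + omnipath[28:30], truth, directed=False,
        signed=False, with_refs=False)))

    _write(res / "kinase_db.tsv", _tsv(header, _interaction_rows(
        rng, truth.pools["kinaseextra"], truth, with_refs=False)))
    _write(res / "pathway_db.tsv", _tsv(header, _interaction_rows(
        rng, truth.pools["pathwayextra"], truth, with_refs=False)))
    _write(res / "ligrec_db.tsv", _tsv(header, _interaction_rows(
        rng, truth.pools["ligrecextra"], truth)))

    n_dor = len(truth.pools["dorothea"])
    confidences = ["A", "B", "C", "D"] + [
        rng.choice("ABCD") for _ in range(n_dor - 4)]
    truth_conf = dict(zip(truth.pools["dorothea"], confidences))
    truth.pools["dorothea_conf"] = truth_conf  # type: ignore[assignment]
    _write(res / "dorothea_db.tsv", _tsv(header, _interaction_rows(
        rng, truth.pools["dorothea"], truth, confidences=confidences)))
    _write(res / "tftarget_db.tsv", _tsv(header, _interaction_rows(
        rng, truth.pools["tf_target"], truth)))
    _write(res / "mirna_db.tsv", _tsv(header, _interaction_rows(
        rng, truth.pools["post_transcriptional"], truth)))
    _write(res / "tfmirna_db.tsv", _tsv(header, _interaction_rows(
        rng, truth.pools["tf_mirna"], truth)))
    _write(res / "lncrna_db.tsv", _tsv(header, _interaction_rows(
        rng, truth.pools["lncrna_mrna"], truth)))

    # enzyme-PTM resources (accession identifiers, overlapping coverage)
    es_header = ["enzyme", "substrate", "residue", "position",
                 "modification", "references"]
    valid, invalid = truth.ptm_valid, truth.ptm_invalid
    nosub = [(rng.choice(truth.accs), "P0TMISS", "S", 5, "phosphorylation")
             for _ in range(sizes.n_ptm_no_sequence)]

    def es_rows(keys, with_refs=True):
        return [[e, s, l, str(p), m, _refs(rng) if with_refs else ""]
                for e, s, l, p, m in keys]

    _write(res / "enzsub_a.tsv", _tsv(es_header, es_rows(
        valid[:12] + invalid[:3] + nosub[:1])))
    _write(res / "enzsub_b.tsv", _tsv(es_header, es_rows(
        valid[7:] + invalid[3:] + nosub[1:], with_refs=False)))

    # complexes
    cx_header = ["components", "stoichiometry", "name", "pdb", "references"]

    def cx_row(idx, stoich_from=None, conflict=False):
        members = truth.complex_sets[idx]
        unique = sorted(set(members))
        stoich = ""
        if stoich_from is not None:
            counts = dict(stoich_from)
            if conflict:
                first = unique[0]
                counts[first] = counts[first] + 1
            stoich = ";".join(str(counts[a]) for a in unique)
        return [";".join(unique), stoich, f"CPX{idx:02d}",
                f"{1000 + idx}", _refs(rng)]

    rows = [cx_row(i, truth.complex_stoich.get(i) if i <= 5 else None)
            for i in range(0, 9)]
    _write(res / "complex_a.tsv", _tsv(cx_header, rows))
    rows = []
    for i in range(4, 12):
        if i == 5:
            rows.append(cx_row(i, truth.complex_stoich[i], conflict=True))
        elif i in (4, 6):
            rows.append(cx_row(i, truth.complex_stoich[i]))
        else:
            rows.append(cx_row(i))
    _write(res / "complex_b.tsv", _tsv(cx_header, rows))

    # annotations
    _write(res / "memberdb.tsv", _tsv(["entity"], [
        [acc] for acc in sorted(truth.annotation_records["memberdb"])]))
    rows = []
    for acc in sorted(truth.annotation_records["pathdb"]):
        for record in truth.annotation_records["pathdb"][acc]:
            rows.append([acc, record["pathway"], record["effect"]])
    _write(res / "pathdb.tsv", _tsv(["entity", "pathway", "effect"], rows))

    # role tables + GO annotations + taxonomy + exclusions
    for resource, table in truth.role_tables.items():
        _write(res / f"{resource}.tsv", _tsv(["category", "entity"],
                                             [[c, e] for c, e in table]))
    gaf_rows = [["FIXDB", acc, truth.sym_of[acc], "", term, "FIX:0001",
                 "IEA", "", "F", "", "", "protein", f"taxon:{HUMAN_TAXID}"]
                for acc in sorted(truth.go_terms)
                for term in sorted(truth.go_terms[acc])]
    _write(res / "go_annotations.gaf", _tsv(
        ["db", "entity", "symbol", "qualifier", "go_id", "reference",
         "evidence", "with", "aspect", "name", "synonym", "type", "taxon"],
        gaf_rows))
    _write(out / "categories.yaml", yaml.safe_dump(
        {"categories": _category_definitions()}, sort_keys=False))
    _write(out / "exclusions.tsv", "".join(
        f"{category}\t{entity}\n"
        for category in sorted(truth.exclusions)
        for entity in sorted(truth.exclusions[category])))

    # identifier mapping
    mapping = out / "mapping"
    _write(mapping / "uniprot_primary.txt",
           "\n".join(sorted(truth.accs + ["P0TMISS"])) + "\n")
    _write(mapping / "mirbase_primary.txt",
           "\n".join(sorted(truth.mirnas)) + "\n")
    _write(mapping / "lncrna_primary.txt",
           "\n".join(sorted(truth.lncrnas)) + "\n")
    _write(mapping / "symbol2uniprot.tsv", "foreign\treference\n" + "".join(
        f"{sym}\t{acc}\n" for acc, sym in sorted(truth.sym_of.items())))
    # deprecated accessions bridged via the primary symbol
    _write(mapping / "secondary2symbol.tsv", "foreign\treference\n"
           + f"Q0T0001\t{truth.sym_of[_acc(1)]}\n"
           + f"Q0T0002\t{truth.sym_of[_acc(2)]}\n")

    # sequences
    fasta = []
    for acc in sorted(truth.sequences):
        for n, seq in enumerate(truth.sequences[acc], start=1):
            name = acc if n == 1 else f"{acc}-{n}"
            fasta.append(f">{name}\n{seq}")
    _write(out / "sequences.fasta", "\n".join(fasta) + "\n")

    # homology
    hom = out / "homology"
    rows = []
    u2r, r2u = [], []
    for acc in sorted(truth.translatable):
        i = int(acc[3:])
        group, rsh, rsm = f"HG{i:04d}", f"RSH{i:04d}", f"RSM{i:04d}"
        rows += [[group, str(HUMAN_TAXID), rsh],
                 [group, str(MOUSE_TAXID), rsm]]
        u2r.append(f"{acc}\t{rsh}\n")
        r2u.append(f"{rsm}\t{truth.mouse_acc[acc]}\n")
    _write(hom / "homologene.tsv", _tsv(["group", "taxid", "refseq"], rows))
    _write(hom / "uniprot2refseq_9606.tsv",
           "foreign\treference\n" + "".join(u2r))
    _write(hom / "refseq2uniprot_10090.tsv",
           "foreign\treference\n" + "".join(r2u))
    _write(hom / "ptm_site_homology.tsv", _tsv(
        ["source_acc", "source_pos", "target_org", "target_acc",
         "target_pos"],
        [[a, str(p), str(o), ta, str(tp)]
         for a, p, o, ta, tp in sorted(truth.site_rows)]))
    _write(hom / "mouse_sequences.fasta", "\n".join(
        f">{acc}\n{seq}" for acc, seq in sorted(truth.mouse_seq.items()))
        + "\n")

    # expression matrix and differential expression
    columns = [f"{cond}|{cell}" for cond in CONDITIONS
               for cell in CELL_TYPES]
    genes = sorted(truth.expr_values[(CONDITIONS[0], CELL_TYPES[0])])
    lines = ["gene\t" + "\t".join(columns)]
    for gene in genes:
        cells = [f"{truth.expr_values[(cond, cell)][gene]:g}"
                 for cond in CONDITIONS for cell in CELL_TYPES]
        lines.append(gene + "\t" + "\t".join(cells))
    _write(out / "expression.tsv", "\n".join(lines) + "\n")
    _write(out / "de.tsv", _tsv(["gene", "log2fc", "padj"], [
        [g, f"{fc:g}", f"{p:g}"] for g, fc, p in truth.de_rows]))

    _write(out / "registry.yaml", yaml.safe_dump(
        _registry_entries(), sort_keys=False))


def _category_definitions() -> list[dict]:
    def cat(name, **kw):
        d = {"name": name, "aspect": "functional", "scope": "generic"}
        d.update(kw)
        return d
    return [
        cat("ligand", transmitter=True, secreted=True,
            go_expression="(and GO:0000001 (not GO:0000002))"),
        cat("receptor", receiver=True, plasma_membrane_transmembrane=True,
            go_expression="(and GO:0000002 (not GO:0000001))"),
        cat("ecm", transmitter=True, secreted=True),
        cat("ecm_regulator", transmitter=True),
        cat("adhesion", transmitter=True, receiver=True),
        cat("transporter", receiver=True,
            plasma_membrane_transmembrane=True),
        cat("secreted_enzyme", transmitter=True, secreted=True),
        cat("junction", transmitter=True, receiver=True),
        cat("secreted", aspect="locational", secreted=True),
        cat("plasma_membrane_transmembrane", aspect="locational",
            plasma_membrane_transmembrane=True),
        cat("plasma_membrane_peripheral", aspect="locational",
            plasma_membrane_peripheral=True),
    ]


def _registry_entries() -> list[dict]:
    ia_schema = {"source": "source", "target": "target",
                 "is_directed": "is_directed", "sign": "sign",
                 "references": "references", "confidence": "confidence"}

    def interaction(name, dataset, literature=True):
        return {"name": name, "locator": f"resources/{name}.tsv",
                "format": "interaction_table", "schema": ia_schema,
                "dataset": dataset, "id_space": "genesymbol",
                "literature_curated": literature}

    es_schema = {"enzyme": "enzyme", "substrate": "substrate",
                 "residue": "residue_type", "position": "residue_offset",
                 "modification": "modification", "references": "references"}
    cx_schema = {"components": "components",
                 "stoichiometry": "stoichiometry", "name": "name",
                 "pdb": "pdb", "references": "references"}
    return [
        interaction("ppi_a", "omnipath"),
        interaction("ppi_b", "omnipath", literature=False),
        interaction("ppi_c", "omnipath"),
        interaction("kinase_db", "kinaseextra", literature=False),
        interaction("pathway_db", "pathwayextra", literature=False),
        interaction("ligrec_db", "ligrecextra"),
        interaction("dorothea_db", "dorothea", literature=False),
        interaction("tftarget_db", "tf_target"),
        interaction("mirna_db", "post_transcriptional"),
        interaction("tfmirna_db", "tf_mirna"),
        interaction("lncrna_db", "lncrna_mrna"),
        {"name": "enzsub_a", "locator": "resources/enzsub_a.tsv",
         "format": "enzsub_table", "schema": es_schema,
         "literature_curated": True},
        {"name": "enzsub_b", "locator": "resources/enzsub_b.tsv",
         "format": "enzsub_table", "schema": es_schema},
        {"name": "complex_a", "locator": "resources/complex_a.tsv",
         "format": "complex_table", "schema": cx_schema},
        {"name": "complex_b", "locator": "resources/complex_b.tsv",
         "format": "complex_table", "schema": cx_schema,
         "secondary_of": ["complex_a"]},
        {"name": "memberdb", "locator": "resources/memberdb.tsv",
         "format": "annotation_table", "schema": {"entity": "entity"}},
        {"name": "pathdb", "locator": "resources/pathdb.tsv",
         "format": "annotation_table",
         "schema": {"entity": "entity", "pathway": "pathway",
                    "effect": "effect"}},
        {"name": "roles_a", "locator": "resources/roles_a.tsv",
         "format": "annotation_table",
         "schema": {"category": "category", "entity": "entity"},
         "options": {"role_table": True}},
        {"name": "roles_b", "locator": "resources/roles_b.tsv",
         "format": "annotation_table",
         "schema": {"category": "category", "entity": "entity"},
         "options": {"role_table": True}},
        {"name": "loc_db", "locator": "resources/loc_db.tsv",
         "format": "annotation_table",
         "schema": {"category": "category", "entity": "entity"},
         "options": {"role_table": True}},
        {"name": "go_annotations",
         "locator": "resources/go_annotations.gaf", "format": "go_gaf",
         "schema": {"entity": "entity", "go_id": "go_id"}},
    ]


# -------------------------------------------------------------- manifest

def _expected_comm_pairs(truth: Truth, uc_profile: bool
                         ) -> set[tuple[str, str]]:
    """Nested-loop join over the planted truth (independent of the package's
    join implementation)."""
    excluded = {"ecm", "ecm_regulator", "ligand_regulator",
                "receptor_regulator", "matrix_adhesion_regulator"} \
        if uc_profile else set()
    tx_cats = {"ligand", "ecm", "ecm_regulator", "adhesion",
               "secreted_enzyme", "junction"} - excluded
    rx_cats = {"receptor", "adhesion", "transporter", "junction"} - excluded
    directed = []
    for tag in ("omnipath", "kinaseextra", "pathwayextra", "ligrecextra",
                "dorothea", "tf_target"):
        pool = truth.pools[tag]
        if tag == "omnipath":
            pool = pool[:28]     # final two pairs only appear undirected
        directed += pool
    pairs = set()
    for source, target in directed:
        if uc_profile and target not in truth.membrane:
            continue
        if any(source in truth.composite.get(c, set()) for c in tx_cats) \
                and any(target in truth.composite.get(c, set())
                        for c in rx_cats):
            pairs.add((source, target))
    return pairs


def _expected_ccc(truth: Truth) -> dict:
    comm = _expected_comm_pairs(truth, uc_profile=True)
    active = {}
    for cond in CONDITIONS:
        tx_expr = truth.expressed[(cond, "myofibroblast")]
        rx_expr = truth.expressed[(cond, "treg")]
        active[cond] = {
            (s, t) for s, t in comm
            if truth.sym_of[s] in tx_expr and truth.sym_of[t] in rx_expr}
    counts = {}
    for tx_cell in CELL_TYPES:
        for rx_cell in CELL_TYPES:
            for cond in CONDITIONS:
                tx_expr = truth.expressed[(cond, tx_cell)]
                rx_expr = truth.expressed[(cond, rx_cell)]
                n = sum(1 for s, t in comm
                        if truth.sym_of[s] in tx_expr
                        and truth.sym_of[t] in rx_expr)
                counts[f"{tx_cell}->{rx_cell}|{cond}"] = n
    healthy, uc = CONDITIONS
    return {
        "active": {c: sorted(map(list, active[c])) for c in CONDITIONS},
        "uc_specific": sorted(map(list, active[uc] - active[healthy])),
        "healthy_specific": sorted(map(list, active[healthy] - active[uc])),
        "per_cell_pair_counts": counts,
    }


def _expected_homology(truth: Truth, sizes: FixtureSizes) -> dict:
    protein_tags = ("omnipath", "kinaseextra", "pathwayextra", "ligrecextra",
                    "dorothea", "tf_target")
    total = sum(len(truth.pools[tag]) for tag in truth.pools
                if tag != "dorothea_conf")
    survivors = sum(
        1 for tag in protein_tags for s, t in truth.pools[tag]
        if s in truth.translatable and t in truth.translatable)
    site_index = {(a, p): (ta, tp)
                  for a, p, _o, ta, tp in truth.site_rows}
    ptm_survivors = set()
    for enzyme, substrate, letter, pos, modification in truth.ptm_valid:
        if enzyme not in truth.translatable:
            continue
        site = site_index.get((substrate, pos))
        if site is None:
            continue
        target_acc, target_pos = site
        seq = truth.mouse_seq[target_acc]
        if target_pos <= len(seq) and seq[target_pos - 1] == letter:
            ptm_survivors.add((truth.mouse_acc[enzyme], target_acc, letter,
                               target_pos, modification))
    return {
        "network_total": total,
        "network_survivors": survivors,
        "coverage": survivors / total,
        "ptm_survivors": len(ptm_survivors),
    }


def _expected_inferred_annotations(truth: Truth) -> dict:
    """Brute-force all-members-agree inference over the planted truth."""
    out: dict[str, list] = {}
    for resource, per_entity in truth.annotation_records.items():
        labels = sorted({label for records in per_entity.values()
                         for record in records for label in record})
        inferred = []
        for members in truth.complex_sets:
            unique = sorted(set(members))
            if not all(m in per_entity for m in unique):
                continue
            tuples = [
                {tuple(record.get(l) for l in labels)
                 for record in per_entity[m]} for m in unique]
            shared = set.intersection(*tuples)
            identity = "COMPLEX:" + "_".join(unique)
            for combo in sorted(shared,
                                key=lambda c: tuple(v or "" for v in c)):
                inferred.append([identity,
                                 {l: v for l, v in zip(labels, combo)
                                  if v is not None}])
        out[resource] = inferred
    return out


def _build_manifest(seed: int, truth: Truth, sizes: FixtureSizes) -> dict:
    per_tag = {tag: len(pool) for tag, pool in truth.pools.items()
               if tag != "dorothea_conf"}
    unique_ptm = sorted(set(truth.ptm_valid))
    modtype = {}
    for key in unique_ptm:
        modtype[key[4]] = modtype.get(key[4], 0) + 1
    complex_ids = ["COMPLEX:" + "_".join(sorted(set(m)))
                   for m in truth.complex_sets]
    conflict_id = complex_ids[5]
    with_stoich = sorted(complex_ids[i] for i in truth.complex_stoich
                         if i != 5)
    uc_comm = _expected_comm_pairs(truth, uc_profile=True)
    all_comm = _expected_comm_pairs(truth, uc_profile=False)
    return {
        "seed": seed,
        "network": {
            "per_tag_unique": per_tag,
            "total_unique": sum(per_tag.values()),
            "contradiction_sign_edges": sorted(map(list,
                                                   truth.contradictions)),
            "dropped_unmappable": 2,
            "parse_skipped": 1,
        },
        "enzsub": {
            "unique_valid": len(unique_ptm),
            "invalid_records": sizes.n_ptm_invalid,
            "no_sequence_records": sizes.n_ptm_no_sequence,
            "modification_histogram": modtype,
        },
        "complexes": {
            "identities": sorted(complex_ids),
            "n_identities": len(complex_ids),
            "raw_records": 17,
            "homomultimers": sum(
                1 for m in truth.complex_sets if len(set(m)) == 1),
            "le4_unique_components": sum(
                1 for m in truth.complex_sets if len(set(m)) <= 4),
            "with_stoichiometry": with_stoich,
            "stoichiometry_conflicts": [conflict_id],
        },
        "annotations": {
            "per_resource_rows": {
                "memberdb": sizes.n_member_annotations,
                "pathdb": sum(
                    2 * len(records) for records in
                    truth.annotation_records["pathdb"].values()),
            },
            "inferred_complex": _expected_inferred_annotations(truth),
        },
        "intercell": {
            "composite": {name: sorted(members) for name, members in
                          truth.composite.items()},
            "complex_members": {
                name: sorted(
                    "COMPLEX:" + "_".join(sorted(set(m)))
                    for m in truth.complex_sets
                    if all(acc in members for acc in set(m)))
                for name, members in truth.composite.items()},
            "exclusions": {name: sorted(members) for name, members in
                           truth.exclusions.items()},
        },
        "homology": _expected_homology(truth, sizes),
        "comm": {
            "transmitter_receiver_pairs": len(all_comm),
            "uc_profile_pairs": len(uc_comm),
            "ccc": _expected_ccc(truth),
            "selected_ligands": sorted(
                g for g, fc, p in truth.de_rows
                if p < 0.1 and fc > 1.0
                and g in {truth.sym_of[a]
                          for a in truth.composite["ligand"]}),
        },
    }
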