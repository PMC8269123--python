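"""Synthetic inputs for every pipeline stage.

The real training substrate (a curated signed human interactome and a
drug-condition truth table) is proprietary, so each consumer module gets a
generator that emulates its input statistically and records the planted
ground truth alongside: a sparse signed background network with a planted
signed mechanism from a "drug target" to disease effectors, a truth table
that is exactly satisfiable when every planted edge carries weight 1 and
every background edge weight 0, fingerprint libraries with planted analogs,
bioactivity tables with planted consensus targets, docking-pose tables with
planted positives, and a hand-curated miniature thrombocytopenia fixture
(MPL -> JAK/STAT -> TGFB1 / IFNG / PPARG / FOXP3) for qualitative
mechanism-path checks.  Every generator is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .disease import (DiseaseDefinition, DrugDefinition, Motive, TruthEntry,
                      TruthTable)
from .errors import ValidationError
from .network import Interaction, Interactome, ProteinNode
from .offtarget import BioactivityRecord, Fingerprint, tanimoto
from .docking import DockingPose, PocketSpec

_SEED_MOD = 2**31 - 1


# ---------------------------------------------------------------------------
# network generation


@dataclass
class NetworkGenSpec:
    """Statistical profile of the background interactome."""

    n_nodes: int = 200
    mean_degree: float = 4.0
    sign_fractions: tuple = (0.45, 0.25, 0.30)  # activating, inhibiting, unknown
    topology: str = "scale_free"
    seed: int = 0

    def __post_init__(self):
        if self.n_nodes < 4:
            raise ValidationError("n_nodes must be >= 4")
        if abs(sum(self.sign_fractions) - 1.0) > 1e-9:
            raise ValidationError("sign fractions must sum to 1")
        if self.topology not in ("scale_free", "erdos_renyi"):
            raise ValidationError(f"unknown topology {self.topology!r}")


def generate_network(spec: NetworkGenSpec) -> Interactome:
    """Connected signed background network, reproducible from the seed.

    Background edges are undirected (physical/functional contacts work both
    ways for signal flow); signs are drawn from the configured fractions.
    Only the largest connected component is retained.
    """
    rng = np.random.default_rng(spec.seed)
    nx_seed = int(rng.integers(_SEED_MOD))
    if spec.topology == "scale_free":
        m = max(1, int(round(spec.mean_degree / 2)))
        if m >= spec.n_nodes:
            raise ValidationError("mean_degree infeasible for n_nodes")
        g = nx.barabasi_albert_graph(spec.n_nodes, m, seed=nx_seed)
    else:
        n_edges = int(round(spec.n_nodes * spec.mean_degree / 2))
        if n_edges > spec.n_nodes * (spec.n_nodes - 1) // 2:
            raise ValidationError("mean_degree infeasible for n_nodes")
        g = nx.gnm_random_graph(spec.n_nodes, n_edges, seed=nx_seed)
    largest = max(nx.connected_components(g), key=len)
    g = g.subgraph(largest)

    width = len(str(spec.n_nodes))
    name = {i: f"P{i:0{width}d}" for i in g.nodes}
    signs = np.array([1, -1, 0])
    net = Interactome()
    for i in sorted(g.nodes):
        net.add_node(ProteinNode(name[i]))
    for u, v in sorted(g.edges):
        sign = int(rng.choice(signs, p=spec.sign_fractions))
        net.add_edge(Interaction(name[u], name[v], sign=sign,
                                 relation="physical", directed=False))
    return net


# ---------------------------------------------------------------------------
# mechanism planting


@dataclass
class PlantedMechanism:
    """Ground-truth signed paths from the focal drug target to effectors."""

    source: str
    effector_paths: tuple  # of (node tuple starting at source, sign tuple)
    planted_weight: float = 1.0

    def __post_init__(self):
        for nodes, signs in self.effector_paths:
            if nodes[0] != self.source:
                raise ValidationError("planted path must start at the source")
            if len(set(nodes)) != len(nodes):
                raise ValidationError("planted path must be simple")
            if len(signs) != len(nodes) - 1:
                raise ValidationError("one sign per edge required")
        interiors = [set(nodes[1:]) for nodes, _ in self.effector_paths]
        for i, a in enumerate(interiors):
            for b in interiors[i + 1:]:
                if a & b:
                    raise ValidationError(
                        "planted paths must be node-disjoint after the source")

    def net_signs(self) -> dict:
        return {nodes[-1]: int(np.prod(signs))
                for nodes, signs in self.effector_paths}


def plant_mechanism(net: Interactome, mech: PlantedMechanism) -> dict:
    """Insert the mechanism's directed signed edges; returns ground truth.

    Missing nodes are created; an already-present edge is overwritten with
    the planted sign (idempotent on repeat).  The record lists planted edge
    keys, per-effector paths and net signs.
    """
    planted_keys = []
    for nodes, signs in mech.effector_paths:
        for (u, v), s in zip(zip(nodes, nodes[1:]), signs):
            edge = Interaction(u, v, sign=int(s), relation="functional",
                               directed=True)
            net.add_edge(edge, replace=True)
            planted_keys.append(edge.key)
    return {
        "source": mech.source,
        "paths": [{"nodes": list(nodes), "signs": [int(s) for s in signs],
                   "net_sign": int(np.prod(signs))}
                  for nodes, signs in mech.effector_paths],
        "planted_edges": planted_keys,
        "planted_weight": mech.planted_weight,
    }


def default_mechanism(prefix: str = "") -> PlantedMechanism:
    """Two disjoint signed paths used by the planted benchmark.

    One three-edge all-activating path and one two-edge path ending in an
    inhibitory arc, mirroring the shapes of typical receptor -> kinase ->
    transcription-factor -> effector cascades.
    """
    p = prefix
    return PlantedMechanism(
        source=f"{p}TGT",
        effector_paths=(
            ((f"{p}TGT", f"{p}K1", f"{p}TF1", f"{p}EFF_A"), (1, 1, 1)),
            ((f"{p}TGT", f"{p}K2", f"{p}EFF_B"), (1, -1)),
        ))


# ---------------------------------------------------------------------------
# truth-table generation


@dataclass
class TruthGenSpec:
    """Shape of the synthetic training signal."""

    n_background_drugs: int = 11
    n_entries: int = 20
    n_pathways: int = 6
    label_noise: float = 0.0
    n_anchor_edges: int = 1
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.label_noise < 0.5:
            raise ValidationError("label_noise must be in [0, 0.5)")
        if self.n_entries < 1:
            raise ValidationError("n_entries must be >= 1")


def generate_truth_table(net: Interactome, mech_record: dict,
                         spec: TruthGenSpec):
    """Build drugs, conditions and a truth table around a planted mechanism.

    The focal drug agonizes the mechanism source and is an *indication*
    for the focal disease, whose effectors are the planted path endpoints
    with pathological direction opposite to each path's net sign (so the
    planted mechanism satisfies the entry).  Background physiology is a
    pool of shared planted *pathways*: each pathway runs from a hub node
    through short signed chains of fresh nodes to two effector nodes whose
    pathological direction opposes the chain's net sign.  Each background
    drug targets the hubs of the pathways it has entries for; the entry's
    relation follows from the drug's mode (agonism of a curative pathway
    is an indication, antagonism an adverse effect).  Pathways are reused
    by several drugs, which is what lets held-out entries generalize
    under cross-validation.  Weight 1 on every planted edge and 0 elsewhere
    satisfies the whole table exactly, at any network size.  Every fresh
    node is anchored to the background by random undirected edges, so
    under random weights background signal interferes at the effectors
    and high accuracy requires actual training.  Label noise flips the
    relation of a fixed fraction of entries (recorded in the ground
    truth).

    Mutates ``net`` by planting the background chains.  Returns
    (drugs, conditions, truth_table, ground_truth).
    """
    rng = np.random.default_rng(spec.seed)
    mech_nodes = {n for p in mech_record["paths"] for n in p["nodes"]}
    pool = sorted(set(net.nodes) - mech_nodes)

    motives = tuple(
        Motive(f"mechanism_{i}", ((p["nodes"][-1], -p["net_sign"]),))
        for i, p in enumerate(mech_record["paths"]))
    disease = DiseaseDefinition("focal_disease", motives)
    focal_drug = DrugDefinition("drug_focal", ((mech_record["source"], 1),))
    drugs = [focal_drug]
    conditions = [disease]
    entries = [TruthEntry(focal_drug, disease, "indication")]

    background_edges = []

    def plant_edge(u, v, sign):
        edge = Interaction(u, v, sign=sign, relation="functional",
                           directed=True)
        net.add_edge(edge, replace=True)
        background_edges.append(edge.key)

    def anchor(node):
        for _ in range(spec.n_anchor_edges):
            other = pool[int(rng.integers(len(pool)))]
            net.add_edge(Interaction(node, other,
                                     sign=int(rng.choice([-1, 1])),
                                     relation="physical", directed=False))

    # shared pathways: hub -> chains of fresh nodes -> two effectors
    pathway_conditions = []
    for p in range(spec.n_pathways):
        hub = f"H{p:02d}"
        anchor(hub)
        effs = []
        for e in range(2):
            length = int(rng.integers(1, 3))
            chain = ([hub]
                     + [f"C{p:02d}_{e}{h}" for h in range(length - 1)]
                     + [f"C{p:02d}_E{e}"])
            signs = [int(s) for s in rng.choice([-1, 1], size=length)]
            for (u, v), s in zip(zip(chain, chain[1:]), signs):
                plant_edge(u, v, s)
            for fresh in chain[1:]:
                anchor(fresh)
            # hub activation moves the effector against its pathological
            # direction: the pathway is curative by construction
            effs.append((chain[-1], -int(np.prod(signs))))
        cond = DiseaseDefinition(f"cond_{p:02d}",
                                 (Motive(f"cond_{p:02d}_m", tuple(effs)),))
        pathway_conditions.append((hub, cond))
        conditions.append(cond)

    # background drugs act on pathway hubs; relation follows the mode
    n_background = spec.n_entries - 1
    drug_modes, drug_pathways = {}, {}
    for j in range(n_background):
        dname = f"drug_bg{j % spec.n_background_drugs:02d}"
        if dname not in drug_modes:
            drug_modes[dname] = int(rng.choice([-1, 1]))
            drug_pathways[dname] = []
        for k in range(spec.n_pathways):
            p = (j + k) % spec.n_pathways
            if p not in drug_pathways[dname]:
                drug_pathways[dname].append(p)
                break
        else:
            raise ValidationError(
                "not enough pathways for unique drug-condition pairs")
    for dname in sorted(drug_modes):
        mode = drug_modes[dname]
        targets = tuple((pathway_conditions[p][0], mode)
                        for p in drug_pathways[dname])
        drug = DrugDefinition(dname, targets)
        drugs.append(drug)
        relation = "indication" if mode == 1 else "adverse_effect"
        for p in drug_pathways[dname]:
            entries.append(TruthEntry(drug, pathway_conditions[p][1],
                                      relation))

    n_flip = int(round(spec.label_noise * len(entries)))
    flip_idx = sorted(rng.choice(len(entries), size=n_flip, replace=False)) \
        if n_flip else []
    flipped = []
    for i in flip_idx:
        e = entries[i]
        other = ("adverse_effect" if e.relation == "indication"
                 else "indication")
        entries[i] = TruthEntry(e.drug, e.condition, other)
        flipped.append((e.drug.name, e.condition.name))

    ground_truth = {
        "focal_entry": (focal_drug.name, disease.name),
        "background_planted_edges": background_edges,
        "flipped_entries": flipped,
        "n_entries": len(entries),
        "relation_counts": TruthTable(list(entries)).relation_counts(),
    }
    return drugs, conditions, TruthTable(entries), ground_truth


# ---------------------------------------------------------------------------
# full planted benchmark


@dataclass
class PlantedBenchmark:
    network: Interactome
    mechanism: PlantedMechanism
    drugs: list
    conditions: list
    disease: DiseaseDefinition
    focal_drug: DrugDefinition
    truth_table: TruthTable
    ground_truth: dict = field(default_factory=dict)


def planted_benchmark(seed: int = 0, n_nodes: int = 200,
                      mean_degree: float = 4.0, n_entries: int = 20,
                      n_background_drugs: int = 11,
                      label_noise: float = 0.0,
                      n_anchor_edges: int = 1) -> PlantedBenchmark:
    """The default end-to-end training benchmark.

    A scale-free signed background network, the default two-path mechanism
    planted on fresh nodes, each planted node anchored to the background by
    ``n_anchor_edges`` random undirected edges (so alternative, longer
    routes to the effectors exist and path recovery is not trivial), and a
    truth table whose planted solution reaches accuracy 1.
    """
    rng = np.random.default_rng(seed)
    net = generate_network(NetworkGenSpec(
        n_nodes=n_nodes, mean_degree=mean_degree, seed=int(rng.integers(_SEED_MOD))))
    mech = default_mechanism()
    mech_record = plant_mechanism(net, mech)

    background = sorted(set(net.nodes) - {n for nodes, _ in
                                          mech.effector_paths for n in nodes})
    for nodes, _ in mech.effector_paths:
        for nid in nodes:
            anchors = rng.choice(len(background), size=n_anchor_edges,
                                 replace=False)
            for a in anchors:
                net.add_edge(Interaction(nid, background[a],
                                         sign=int(rng.choice([-1, 1])),
                                         relation="physical", directed=False))

    drugs, conditions, table, gt = generate_truth_table(
        net, mech_record,
        TruthGenSpec(n_background_drugs=n_background_drugs,
                     n_entries=n_entries, label_noise=label_noise,
                     seed=int(rng.integers(_SEED_MOD))))
    gt["mechanism"] = mech_record
    return PlantedBenchmark(network=net, mechanism=mech, drugs=drugs,
                            conditions=conditions, disease=conditions[0],
                            focal_drug=drugs[0], truth_table=table,
                            ground_truth=gt)


def oracle_assignment(net: Interactome, ground_truth: dict):
    """The planted weight assignment: planted edges 1, everything else 0.

    Unknown-sign edges resolve to +1 (they carry no weight, so the choice
    is immaterial for propagation).
    """
    planted = set(map(tuple, ground_truth["mechanism"]["planted_edges"])) | \
        set(map(tuple, ground_truth["background_planted_edges"]))
    from .propagation import WeightAssignment
    weights = {k: (1.0 if k in planted else 0.0) for k in net.edges}
    resolved = {k: 1 for k, e in net.edges.items() if e.sign == 0}
    return WeightAssignment(weights, resolved)


# ---------------------------------------------------------------------------
# compound screen generation


def generate_compound_screen(n_decoys: int = 99, n_analogs: int = 1,
                             n_consensus_targets: int = 3,
                             n_sources: int = 3, seed: int = 0,
                             n_bits: int = 1024, n_on_bits: int = 200,
                             max_tries: int = 200):
    """Fingerprint library plus bioactivity table with planted consensus.

    Analogs mutate fewer than 10% of the query's on-bits, guaranteeing
    Tanimoto similarity > 0.8 (verified post hoc); decoys are random draws
    verified dissimilar (< 0.5).  Each planted consensus target has active
    records for an analog in all sources; near-miss proteins (active in
    n_sources - 1 databases) and decoy-linked records exercise the filter.

    Returns (query, library, records, ground_truth).
    """
    rng = np.random.default_rng(seed)
    query_bits = frozenset(int(b) for b in
                           rng.choice(n_bits, size=n_on_bits, replace=False))
    query = Fingerprint("QUERY", query_bits, n_bits)

    library, analog_ids = [], []
    n_mut = max(1, int(0.09 * n_on_bits))
    for i in range(n_analogs):
        for _ in range(max_tries):
            drop = rng.choice(sorted(query_bits), size=n_mut, replace=False)
            off_pool = sorted(set(range(n_bits)) - query_bits)
            gain = rng.choice(off_pool, size=n_mut, replace=False)
            bits = (query_bits - set(int(x) for x in drop)) | \
                set(int(x) for x in gain)
            fp = Fingerprint(f"ANALOG{i:02d}", frozenset(bits), n_bits)
            if tanimoto(query, fp) > 0.8:
                break
        else:
            raise ValidationError("could not construct a valid analog")
        library.append(fp)
        analog_ids.append(fp.compound_id)

    for i in range(n_decoys):
        for _ in range(max_tries):
            bits = frozenset(int(b) for b in
                             rng.choice(n_bits, size=n_on_bits, replace=False))
            fp = Fingerprint(f"DECOY{i:03d}", bits, n_bits)
            if tanimoto(query, fp) < 0.5:
                break
        else:
            raise ValidationError("could not construct a valid decoy")
        library.append(fp)

    sources = [f"db{i + 1}" for i in range(n_sources)]
    targets = [f"TGT_P{i + 1}" for i in range(n_consensus_targets)]
    records = []
    for t in targets:
        for aid in analog_ids[:1]:
            for s in sources:
                records.append(BioactivityRecord(aid, t, s, True, "human"))
    if analog_ids:
        # near-misses: one source short of consensus / non-human / inactive
        for s in sources[:-1]:
            records.append(BioactivityRecord(analog_ids[0], "NEAR_P1", s,
                                             True, "human"))
        for s in sources:
            records.append(BioactivityRecord(analog_ids[0], "MOUSE_P1", s,
                                             True, "mouse"))
            records.append(BioactivityRecord(analog_ids[0], "INACT_P1", s,
                                             False, "human"))
    if n_decoys:
        for s in sources:
            records.append(BioactivityRecord("DECOY000", "DECOY_P1", s, True,
                                             "human"))

    ground_truth = {"analogs": analog_ids, "consensus_targets": targets,
                    "sources": sources}
    return query, library, records, ground_truth


# ---------------------------------------------------------------------------
# docking pose generation


def generate_pose_table(n_poses: int = 100, frac_positive: float = 0.25,
                        seed: int = 0,
                        positive_energy=(-10.0, -6.2),
                        positive_distance=(0.5, 4.5),
                        negative_energy=(-5.8, -2.0),
                        negative_distance=(5.2, 12.0)):
    """Pose table with planted positives and threshold-violating negatives.

    Positives draw energy and distance strictly inside the acceptance
    region (< -6 kcal/mol, < 5 A); each negative violates at least one
    threshold (energy only, distance only, or both).  Poses are dealt
    round-robin over three candidates x two pockets so every candidate
    receives positives whenever frac_positive > 0.1.

    Returns (poses, pockets, ground_truth).
    """
    if not 0 <= frac_positive <= 1:
        raise ValidationError("frac_positive must be in [0, 1]")
    rng = np.random.default_rng(seed)
    candidates = ["CAND_A", "CAND_B", "CAND_C"]
    pockets = []
    for c, cand in enumerate(candidates):
        for p in range(2):
            residues = tuple(range(10 + 30 * p, 25 + 30 * p))
            pockets.append(PocketSpec(cand, f"Q{c:05d}", f"{c + 1}ABC", "A",
                                      residues, pocket_type=f"site{p + 1}"))

    n_pos = int(round(frac_positive * n_poses))
    poses, positive_ids = [], []
    for i in range(n_poses):
        pocket = pockets[i % len(pockets)]
        ligand = f"pose{i:03d}"
        if i < n_pos:
            e = float(rng.uniform(*positive_energy))
            d = float(rng.uniform(*positive_distance))
            positive_ids.append(ligand)
        else:
            kind = rng.choice(["energy", "distance", "both"])
            e = float(rng.uniform(*negative_energy)
                      if kind in ("energy", "both")
                      else rng.uniform(*positive_energy))
            d = float(rng.uniform(*negative_distance)
                      if kind in ("distance", "both")
                      else rng.uniform(*positive_distance))
        poses.append(DockingPose(ligand, pocket.label, e, d))

    ground_truth = {"positives": positive_ids, "n_positive": n_pos,
                    "candidates": candidates}
    return poses, pockets, ground_truth


# ---------------------------------------------------------------------------
# miniature ITP fixture (hand-curated, not random)

# Directed signed edges of the curated mini network: receptor -> Janus
# kinases -> STAT factors -> effectors, with PTPN1-mediated inhibition of
# interferon-gamma signaling.
_MINI_ITP_EDGES = [
    ("MPL", "JAK2", 1), ("MPL", "TYK2", 1),
    ("JAK2", "STAT3", 1), ("TYK2", "STAT3", 1),
    ("STAT3", "TGFB1", 1),
    ("JAK2", "PTPN1", 1), ("STAT3", "PTPN1", 1),
    ("PTPN1", "IFNG", -1), ("STAT3", "IFNG", -1),
    ("JAK2", "STAT1", 1), ("TYK2", "STAT1", 1),
    ("JAK2", "STAT5", 1), ("TYK2", "STAT5", 1),
    ("STAT1", "PPARG", 1),
    ("STAT1", "FOXP3", 1), ("STAT5", "FOXP3", 1),
]

# Pathological directions encode the disease narrative of the fixture:
# interferon-gamma signaling overactive; TGF-beta, PPAR-gamma and
# regulatory-T-cell FOXP3 deficient.  A fixture-authoring choice, not a
# clinical claim.
_MINI_ITP_EFFECTORS = {
    "TGFB1": ("tgfb_production", -1),
    "IFNG": ("ifng_signaling", 1),
    "PPARG": ("pparg_expression", -1),
    "FOXP3": ("treg_differentiation", -1),
}


def make_mini_itp_fixture():
    """Curated miniature thrombocytopenia network and molecular definitions.

    Returns (interactome, disease, drug, truth_table): the MPL agonist
    drug is an indication for the four-effector disease, satisfiable by
    the drawn pathway signs.
    """
    net = Interactome()
    for u, v, s in _MINI_ITP_EDGES:
        net.add_edge(Interaction(u, v, sign=s, relation="functional",
                                 directed=True))
    motives = tuple(Motive(mname, ((eff, d),))
                    for eff, (mname, d) in _MINI_ITP_EFFECTORS.items())
    disease = DiseaseDefinition("mini_itp", motives)
    drug = DrugDefinition("eltrombopag", (("MPL", 1),))
    table = TruthTable([TruthEntry(drug, disease, "indication")])
    return net, disease, drug, table


# ---------------------------------------------------------------------------
# miniature PDB fixture


def write_mini_pdb(path, n_residues: int = 3, chain: str = "A") -> dict:
    """Author a tiny synthetic PDB file with known heavy-atom coordinates.

    Each residue r (1-based) is a glycine-like triad N/CA/C at x = 10*r
    plus one hydrogen (which extraction must ignore); residue 1 carries an
    altloc pair for its CA with occupancies 0.3/0.7 (the 0.7 conformer at
    the canonical position must win).  Returns the expected heavy-atom
    coordinates per residue for use as a test oracle.
    """
    lines, expected = [], {}
    serial = 1

    def atom_line(serial, name, altloc, resseq, x, y, z, occ, element):
        return (f"ATOM  {serial:5d} {name:<4s}{altloc}GLY {chain}{resseq:4d}"
                f"    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}  0.00          "
                f"{element:>2s}")

    for r in range(1, n_residues + 1):
        base = 10.0 * r
        coords = [("N", base, 0.0, 0.0), ("CA", base + 1.0, 1.0, 0.0),
                  ("C", base + 2.0, 0.0, 1.0)]
        expected[r] = [(x, y, z) for _, x, y, z in coords]
        for name, x, y, z in coords:
            if r == 1 and name == "CA":
                lines.append(atom_line(serial, "CA", "B", r, x + 5, y, z,
                                       0.30, "C"))
                serial += 1
                lines.append(atom_line(serial, "CA", "A", r, x, y, z, 0.70,
                                       "C"))
            else:
                lines.append(atom_line(serial, name, " ", r, x, y, z, 1.00,
                                       name[0]))
            serial += 1
        lines.append(atom_line(serial, "H", " ", r, base, -1.0, 0.0, 1.00,
                               "H"))
        serial += 1
    lines.append("END")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
    return expected
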