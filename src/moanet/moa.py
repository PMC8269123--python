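"""Mechanism-of-action extraction from a trained solution ensemble.

A single solution says little; the mechanism is what the population of
valid solutions agrees on.  For each solution we propagate the drug
stimulus and measure per-arc signal flow |w * s_source| at the fixed point,
normalize by the solution's maximum flow, and average across solutions.
The resulting edge-usage values in [0, 1] act as traversal probabilities:
a candidate mechanism path is scored by the product of its edge usages and
the k best simple paths from drug target to each disease effector are
reported together with their net regulatory sign (product of edge signs:
+1 net activation of the effector, -1 net inhibition).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .disease import DiseaseDefinition, DrugDefinition, key_proteins
from .errors import ValidationError
from .network import Interactome
from .propagation import CompiledNetwork, PropagationConfig
from .training import SolutionEnsemble, ensemble_mean_accuracy

_TIE_TOL = 1e-12


@dataclass
class EdgeUsage:
    """Ensemble-mean normalized signal flow per arc, plus consensus signs.

    ``usage`` maps directed arcs (source, target) to [0, 1]; ``arc_sign``
    gives the ensemble-majority resolved sign of each arc.
    """

    usage: dict      # (source, target) -> float in [0, 1]
    arc_sign: dict   # (source, target) -> {-1, +1}


@dataclass(frozen=True)
class MoAPath:
    nodes: tuple
    edge_signs: tuple
    score: float

    def __post_init__(self):
        if len(set(self.nodes)) != len(self.nodes):
            raise ValidationError("MoA path must be simple")
        if self.score <= 0:
            raise ValidationError("MoA path score must be > 0")

    @property
    def net_sign(self) -> int:
        return path_sign(self)


def path_sign(path: MoAPath) -> int:
    """Product of edge signs: +1 net activation, -1 net inhibition."""
    prod = 1
    for s in path.edge_signs:
        if s not in (-1, 1):
            raise ValidationError(
                "unresolved sign on path; resolve signs per solution before "
                "aggregating")
        prod *= s
    return prod


def edge_usage(ensemble: SolutionEnsemble, net: Interactome,
               drug: DrugDefinition,
               config: PropagationConfig | None = None) -> EdgeUsage:
    """Mean per-solution max-normalized arc flow under the drug stimulus.

    Per-solution normalization puts solutions on a common scale so a
    single high-gain solution cannot dominate the ensemble mean.  Arcs
    carrying zero flow in every solution get usage 0.
    """
    if not ensemble.solutions:
        raise ValidationError("empty ensemble")
    config = config or PropagationConfig()
    cn = CompiledNetwork(net)
    clamp_idx, clamp_vals = cn.drug_clamp(drug)

    n_arcs = len(cn.arc_src)
    total = np.zeros(n_arcs)
    sign_votes = np.zeros(n_arcs)
    for sol in ensemble.solutions:
        w, sign = cn.weight_arrays(sol.wa)
        s, _, _ = cn.propagate_arrays(w, sign, clamp_idx, clamp_vals, config)
        flow = np.abs(w[cn.arc_edge] * s[cn.arc_src])
        peak = flow.max() if n_arcs else 0.0
        if peak > 0:
            total += flow / peak
        sign_votes += sign[cn.arc_edge]

    mean_flow = total / len(ensemble.solutions)
    usage, arc_sign = {}, {}
    for a in range(n_arcs):
        u, v = cn.node_ids[cn.arc_src[a]], cn.node_ids[cn.arc_dst[a]]
        usage[(u, v)] = float(mean_flow[a])
        arc_sign[(u, v)] = 1 if sign_votes[a] >= 0 else -1
    return EdgeUsage(usage=usage, arc_sign=arc_sign)


def top_paths(net: Interactome, usage: EdgeUsage, source: str, sink: str,
              k: int = 5, max_len: int = 6) -> list[MoAPath]:
    """k best simple directed paths by product of edge usages.

    Equivalent to k-shortest-path search under additive -log(usage)
    weights (Yen's algorithm); zero-usage arcs are excluded, path length is
    capped at ``max_len`` edges, and ties are broken lexicographically by
    node sequence.  An unreachable sink yields an empty list.
    """
    if source == sink:
        raise ValidationError("source and sink must differ")
    if k < 1:
        raise ValidationError("k must be >= 1")
    g = nx.DiGraph()
    g.add_nodes_from(net.nodes)
    for (u, v), val in usage.usage.items():
        if val > 0:
            g.add_edge(u, v, nlog=-math.log(val), usage=val,
                       sign=usage.arc_sign[(u, v)])
    if source not in g or sink not in g or not nx.has_path(g, source, sink):
        return []

    candidates = []
    kth_weight = math.inf
    for i, nodes in enumerate(nx.shortest_simple_paths(g, source, sink,
                                                       weight="nlog")):
        weight = sum(g[u][v]["nlog"] for u, v in zip(nodes, nodes[1:]))
        if len(candidates) >= k and weight > kth_weight + _TIE_TOL:
            break
        if i > 10000:   # tie-exhaustion guard on pathological graphs
            break
        if len(nodes) - 1 > max_len:
            continue
        score = math.exp(-weight)
        signs = tuple(g[u][v]["sign"] for u, v in zip(nodes, nodes[1:]))
        candidates.append(MoAPath(tuple(nodes), signs, score))
        if len(candidates) >= k:
            kth_weight = sorted(-math.log(c.score) for c in candidates)[k - 1]
    candidates.sort(key=lambda p: (-p.score, p.nodes))
    return candidates[:k]


def moa_report(ensemble: SolutionEnsemble, net: Interactome,
               drug: DrugDefinition, disease: DiseaseDefinition,
               k: int = 5, max_len: int = 6,
               config: PropagationConfig | None = None) -> dict:
    """Machine-readable mechanism report: top paths per disease effector.

    Every key protein of the disease appears, either with its ranked paths
    from each drug target or with an explicit unreachable marker.  The
    ensemble accuracy summary rides along so a report is self-describing.
    """
    usage = edge_usage(ensemble, net, drug, config)
    effectors = key_proteins(disease)
    report = {
        "drug": drug.name,
        "disease": disease.name,
        "ensemble": {
            "n_solutions": len(ensemble),
            "mean_accuracy": ensemble_mean_accuracy(ensemble),
            "validity_threshold": ensemble.validity_threshold,
        },
        "effectors": {},
    }
    for eff, direction in effectors.items():
        paths = []
        for target, _mode in drug.targets:
            if eff == target:
                continue
            paths.extend(top_paths(net, usage, target, eff, k=k,
                                   max_len=max_len))
        paths.sort(key=lambda p: (-p.score, p.nodes))
        report["effectors"][eff] = {
            "pathological_direction": direction,
            "reachable": bool(paths),
            "paths": [{
                "nodes": list(p.nodes),
                "edge_signs": list(p.edge_signs),
                "score": p.score,
                "net_sign": p.net_sign,
            } for p in paths[:k]],
        }
    return report


def write_moa_report(report: dict, json_path=None, tsv_path=None) -> None:
    """Persist a report as JSON and/or a flat ranked-path TSV."""
    if json_path:
        with open(json_path, "w") as fh:
            json.dump(report, fh, indent=2)
    if tsv_path:
        rows = []
        for eff, block in report["effectors"].items():
            if not block["paths"]:
                rows.append((eff, 0, "UNREACHABLE", float("nan"), 0))
            for rank, p in enumerate(block["paths"], start=1):
                rows.append((eff, rank, "->".join(p["nodes"]), p["score"],
                             p["net_sign"]))
        pd.DataFrame(rows, columns=["effector", "rank", "path", "score",
                                    "net_sign"]).to_csv(
            tsv_path, sep="\t", index=False)


def report_contains_path(report: dict, nodes, net_sign: int | None = None) -> bool:
    """True if the report lists the exact node sequence (optionally signed)."""
    nodes = list(nodes)
    for block in report["effectors"].values():
        for p in block["paths"]:
            if p["nodes"] == nodes and (net_sign is None
                                        or p["net_sign"] == net_sign):
                return True
    return False
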