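"""Signed, weighted signal propagation and truth-table compliance scoring.

The model clamps the drug's targets at their action mode (+1 agonist, -1
antagonist) and lets the perturbation spread over the interactome through a
saturating update,

    s_v  <-  tanh( sum over incoming arcs u->v of  w_uv * sign_uv * s_u ),

applied synchronously until the largest per-node change falls below a
tolerance.  tanh keeps every activation in [-1, 1], respects regulatory
signs (it is odd), and attenuates long paths when weights are below 1, so
fixed-point iteration converges for any weight assignment in [0, 1].

Compliance: effector activations are discretized at a readout threshold
tau; an indication entry is satisfied when effectors move, in majority,
against their pathological direction, an adverse-effect entry when they
move with it.  Accuracy of a weight assignment is the fraction of
truth-table entries satisfied.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

try:
    from numba import njit
except ImportError:   # pragma: no cover - numba is an optional accelerator
    njit = None

if njit is not None:

    @njit(cache=True)
    def _iterate_clamped(arc_src, arc_dst, vals, clamp_idx, clamp_vals, n,
                         max_iterations, tolerance):
        s = np.zeros(n)
        for i in range(clamp_idx.size):
            s[clamp_idx[i]] = clamp_vals[i]
        clamped = np.zeros(n, dtype=np.bool_)
        for i in range(clamp_idx.size):
            clamped[clamp_idx[i]] = True
        acc = np.zeros(n)
        for it in range(max_iterations):
            acc[:] = 0.0
            for a in range(arc_src.size):
                acc[arc_dst[a]] += vals[a] * s[arc_src[a]]
            delta = 0.0
            for v in range(n):
                if clamped[v]:
                    continue
                nv = math.tanh(acc[v])
                dv = abs(nv - s[v])
                if dv > delta:
                    delta = dv
                s[v] = nv
            if delta < tolerance:
                return s, it + 1, True
        return s, max_iterations, False
    @njit(cache=True)
    def _iterate_clamped_batch(arc_src, arc_dst, vals, clamped, clamp_vals,
                               n, k, max_iterations, tolerance):
        """Propagate k stimuli at once; column j is one drug's clamp."""
        s = np.zeros((n, k))
        for v in range(n):
            for j in range(k):
                if clamped[v, j]:
                    s[v, j] = clamp_vals[v, j]
        acc = np.zeros((n, k))
        for it in range(max_iterations):
            acc[:, :] = 0.0
            for a in range(arc_src.size):
                sa, da, va = arc_src[a], arc_dst[a], vals[a]
                for j in range(k):
                    acc[da, j] += va * s[sa, j]
            delta = 0.0
            for v in range(n):
                for j in range(k):
                    if clamped[v, j]:
                        continue
                    nv = math.tanh(acc[v, j])
                    dv = abs(nv - s[v, j])
                    if dv > delta:
                        delta = dv
                    s[v, j] = nv
            if delta < tolerance:
                return s, it + 1, True
        return s, max_iterations, False
else:
    _iterate_clamped = None
    _iterate_clamped_batch = None

from .disease import DrugDefinition, TruthEntry, key_proteins
from .errors import InputError, ValidationError
from .network import Interactome


@dataclass
class PropagationConfig:
    """Hyperparameters of the fixed-point iteration and the readout."""

    max_iterations: int = 50
    tolerance: float = 1e-6
    readout_threshold: float = 0.05

    def __post_init__(self):
        if self.max_iterations < 1:
            raise ValidationError("max_iterations must be >= 1")
        if self.tolerance <= 0:
            raise ValidationError("tolerance must be > 0")
        if not 0 < self.readout_threshold < 1:
            raise ValidationError("readout_threshold must be in (0, 1)")


@dataclass
class WeightAssignment:
    """Edge-keyed weights in [0, 1] plus resolved signs for sign-0 edges."""

    weights: dict       # edge key -> w in [0, 1]
    resolved_signs: dict  # edge key -> {-1, +1}

    def validate(self, net: Interactome) -> None:
        for key, e in net.edges.items():
            if key not in self.weights:
                raise ValidationError(f"edge {key} has no weight")
            w = self.weights[key]
            if not 0 <= w <= 1:
                raise ValidationError(f"weight {w} for {key} outside [0, 1]")
            s = self.resolved_signs.get(key, e.sign)
            if s not in (-1, 1):
                raise ValidationError(f"edge {key} has unresolved sign")

    def effective_sign(self, net: Interactome, key) -> int:
        base = net.edges[key].sign
        return base if base != 0 else self.resolved_signs[key]


@dataclass
class PropagationState:
    activations: dict   # node id -> s in [-1, 1]
    iterations_run: int
    converged: bool


class CompiledNetwork:
    """Array-level view of an interactome for fast repeated propagation.

    Precomputes node/edge indexing and the arc list (undirected edges
    expanded to two arcs sharing one weight slot) so the trainer can score
    thousands of weight vectors without touching Python dicts.
    """

    def __init__(self, net: Interactome):
        self.net = net
        self.node_ids = sorted(net.nodes)
        self.node_index = {n: i for i, n in enumerate(self.node_ids)}
        self.edge_keys = sorted(net.edges)
        self.edge_index = {k: i for i, k in enumerate(self.edge_keys)}
        self.base_signs = np.array(
            [net.edges[k].sign for k in self.edge_keys], dtype=np.int8)
        self.unknown_mask = self.base_signs == 0

        arc_src, arc_dst, arc_edge = [], [], []
        for k in self.edge_keys:
            e = net.edges[k]
            arc_src.append(self.node_index[e.source])
            arc_dst.append(self.node_index[e.target])
            arc_edge.append(self.edge_index[k])
            if not e.directed:
                arc_src.append(self.node_index[e.target])
                arc_dst.append(self.node_index[e.source])
                arc_edge.append(self.edge_index[k])
        self.arc_src = np.array(arc_src, dtype=np.intp)
        self.arc_dst = np.array(arc_dst, dtype=np.intp)
        self.arc_edge = np.array(arc_edge, dtype=np.intp)
        self.n = len(self.node_ids)

    # -- weight handling ---------------------------------------------------

    def weight_arrays(self, wa: WeightAssignment):
        """(w, sign) edge-indexed arrays; unresolved signs must be filled."""
        w = np.array([wa.weights[k] for k in self.edge_keys], dtype=float)
        sign = self.base_signs.astype(float)
        for i, k in enumerate(self.edge_keys):
            if self.unknown_mask[i]:
                sign[i] = wa.resolved_signs[k]
        return w, sign

    def assignment_from_arrays(self, w, sign) -> WeightAssignment:
        weights = {k: float(w[i]) for i, k in enumerate(self.edge_keys)}
        resolved = {k: int(sign[i]) for i, k in enumerate(self.edge_keys)
                    if self.unknown_mask[i]}
        return WeightAssignment(weights, resolved)

    def operator(self, w, sign) -> sp.csr_matrix:
        vals = (w * sign)[self.arc_edge]
        return sp.csr_matrix((vals, (self.arc_dst, self.arc_src)),
                             shape=(self.n, self.n))

    def drug_clamp(self, drug: DrugDefinition):
        idx, vals = [], []
        for nid, mode in drug.targets:
            if nid not in self.node_index:
                raise InputError(
                    f"drug target {nid!r} absent from interactome")
            idx.append(self.node_index[nid])
            vals.append(float(mode))
        return np.array(idx, dtype=np.intp), np.array(vals)

    def propagate_arrays(self, w, sign, clamp_idx, clamp_vals,
                         config: PropagationConfig):
        """Run the clamped fixed-point iteration; returns (s, iters, conv)."""
        if _iterate_clamped is not None:
            vals = (w * sign)[self.arc_edge]
            return _iterate_clamped(self.arc_src, self.arc_dst, vals,
                                    clamp_idx, clamp_vals, self.n,
                                    config.max_iterations, config.tolerance)
        A = self.operator(w, sign)
        s = np.zeros(self.n)
        s[clamp_idx] = clamp_vals
        for it in range(1, config.max_iterations + 1):
            s_new = np.tanh(A @ s)
            s_new[clamp_idx] = clamp_vals
            delta = np.max(np.abs(s_new - s)) if self.n else 0.0
            s = s_new
            if delta < config.tolerance:
                return s, it, True
        return s, config.max_iterations, False

    def propagate_batch(self, w, sign, clamped, clamp_vals,
                        config: PropagationConfig):
        """Propagate several clamp columns at once; returns (n, k) states.

        ``clamped`` and ``clamp_vals`` are (n, k) arrays, one column per
        stimulus (drug).  Faster than per-drug calls inside the trainer's
        inner loop; numerically identical to column-by-column propagation.
        """
        k = clamped.shape[1]
        if _iterate_clamped_batch is not None:
            vals = (w * sign)[self.arc_edge]
            s, _, _ = _iterate_clamped_batch(
                self.arc_src, self.arc_dst, vals, clamped, clamp_vals,
                self.n, k, config.max_iterations, config.tolerance)
            return s
        out = np.zeros((self.n, k))
        for j in range(k):
            idx = np.flatnonzero(clamped[:, j])
            s, _, _ = self.propagate_arrays(w, sign, idx,
                                            clamp_vals[idx, j], config)
            out[:, j] = s
        return out


# ---------------------------------------------------------------------------
# public operations


def propagate(net: Interactome, wa: WeightAssignment, drug: DrugDefinition,
              config: PropagationConfig | None = None,
              compiled: CompiledNetwork | None = None) -> PropagationState:
    """Propagate the drug stimulus to a converged activation state.

    Targets are clamped to their mode at every iteration; all other nodes
    start at 0.  Non-convergence within ``max_iterations`` is not an error:
    the final state is returned with ``converged=False``.
    """
    config = config or PropagationConfig()
    cn = compiled or CompiledNetwork(net)
    wa.validate(net)
    w, sign = cn.weight_arrays(wa)
    clamp_idx, clamp_vals = cn.drug_clamp(drug)
    s, iters, conv = cn.propagate_arrays(w, sign, clamp_idx, clamp_vals, config)
    return PropagationState(
        activations={nid: float(s[i]) for i, nid in enumerate(cn.node_ids)},
        iterations_run=iters, converged=conv)


def effector_readout(state: PropagationState, effectors, tau: float) -> dict:
    """Discretize effector activations: sign(s) if |s| >= tau else 0.

    The boundary |s| == tau counts as a call.
    """
    out = {}
    for item in effectors:
        nid = item[0] if isinstance(item, tuple) else item
        s = state.activations[nid]
        out[nid] = int(np.sign(s)) if abs(s) >= tau else 0
    return out


def _effector_directions(entry: TruthEntry) -> dict:
    return key_proteins(entry.condition)


def score_entry(state: PropagationState, entry: TruthEntry,
                tau: float = 0.05) -> bool:
    """Majority-rule compliance of one truth-table entry.

    indication:     satisfied iff sum over effectors of (-direction * readout) > 0
    adverse_effect: satisfied iff sum of (+direction * readout) > 0

    Direction-0 (conflict-flagged) effectors are skipped; a tie (sum 0)
    fails.  Raises when no scorable effector remains.
    """
    directions = _effector_directions(entry)
    scorable = {nid: d for nid, d in directions.items() if d != 0}
    if not scorable:
        raise ValidationError(
            f"entry ({entry.drug.name}, {entry.condition.name}) has no "
            "scorable effectors")
    readout = effector_readout(state, scorable.keys(), tau)
    orient = -1 if entry.relation == "indication" else 1
    total = sum(orient * d * readout[nid] for nid, d in scorable.items())
    return total > 0


def accuracy(wa: WeightAssignment, net: Interactome, truth_table,
             config: PropagationConfig | None = None,
             compiled: CompiledNetwork | None = None) -> float:
    """Fraction of truth-table entries satisfied by one weight assignment.

    Propagation is run once per distinct drug and reused across entries.
    Deterministic given its inputs.
    """
    if not len(truth_table.entries):
        raise ValidationError("truth table is empty")
    config = config or PropagationConfig()
    cn = compiled or CompiledNetwork(net)
    wa.validate(net)
    w, sign = cn.weight_arrays(wa)

    states: dict[str, PropagationState] = {}
    n_ok = 0
    for entry in truth_table.entries:
        if entry.drug.name not in states:
            clamp_idx, clamp_vals = cn.drug_clamp(entry.drug)
            s, iters, conv = cn.propagate_arrays(w, sign, clamp_idx,
                                                 clamp_vals, config)
            states[entry.drug.name] = PropagationState(
                {nid: float(s[i]) for i, nid in enumerate(cn.node_ids)},
                iters, conv)
        if score_entry(states[entry.drug.name], entry,
                       config.readout_threshold):
            n_ok += 1
    return n_ok / len(truth_table.entries)


# ---------------------------------------------------------------------------
# serialization


def write_weight_assignment(path, net: Interactome, wa: WeightAssignment) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["source", "target", "relation", "weight", "resolved_sign"])
        for key in sorted(net.edges):
            e = net.edges[key]
            rs = wa.resolved_signs.get(key, e.sign)
            w.writerow([e.source, e.target, e.relation,
                        repr(wa.weights[key]), rs])


def write_propagation_state(path, state: PropagationState) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["node", "activation"])
        for nid in sorted(state.activations):
            w.writerow([nid, repr(state.activations[nid])])


def read_weight_assignment(path, net: Interactome) -> WeightAssignment:
    weights, resolved = {}, {}
    with open(path, encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            key = (row["source"], row["target"], row["relation"])
            if key not in net.edges:
                raise ValidationError(f"unknown edge {key} in weight file")
            weights[key] = float(row["weight"])
            if net.edges[key].sign == 0:
                resolved[key] = int(row["resolved_sign"])
    wa = WeightAssignment(weights, resolved)
    wa.validate(net)
    return wa
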