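"""Signed, typed protein-interaction graphs.

The interactome is the substrate of every downstream step: signal
propagation, mechanism-path extraction and connectivity checks.  Nodes are
proteins identified by an accession-like string; edges carry a regulatory
sign (+1 activating, -1 inhibiting, 0 unknown), a relation type (physical /
transcriptional / functional) and a directedness flag.  Undirected edges are
stored once with lexicographically ordered endpoints and expanded to two
arcs only at propagation time.
"""

from __future__ import annotations

import csv
import logging
import math
from collections import deque
from dataclasses import dataclass, field

import networkx as nx

from .errors import InputError, ValidationError

logger = logging.getLogger(__name__)

RELATIONS = ("physical", "transcriptional", "functional")

#: Default mapping of SIF interaction labels to (sign, relation).
DEFAULT_SIF_MAP = {
    "activates": (1, "functional"),
    "inhibits": (-1, "functional"),
}
DEFAULT_SIF_FALLBACK = (0, "functional")


@dataclass(frozen=True)
class ProteinNode:
    """A network vertex: unique id, display name, free-form annotations."""

    id: str
    name: str = ""
    annotations: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if not self.id:
            raise ValidationError("node id must be non-empty")


@dataclass(frozen=True)
class Interaction:
    """One signed edge; undirected edges keep endpoints in sorted order."""

    source: str
    target: str
    sign: int = 0
    relation: str = "functional"
    directed: bool = True

    def __post_init__(self):
        if self.sign not in (-1, 0, 1):
            raise ValidationError(f"sign must be -1, 0 or +1, got {self.sign}")
        if self.relation not in RELATIONS:
            raise ValidationError(f"unknown relation {self.relation!r}")
        if not self.directed and self.source > self.target:
            lo, hi = self.target, self.source
            object.__setattr__(self, "source", lo)
            object.__setattr__(self, "target", hi)

    @property
    def key(self) -> tuple:
        return (self.source, self.target, self.relation)


class Interactome:
    """A set of protein nodes plus signed interactions between them.

    Invariants enforced on construction: unique node ids, unique
    (source, target, relation) triples, no self-loops, resolvable endpoints.
    """

    def __init__(self, nodes=(), edges=()):
        self.nodes: dict[str, ProteinNode] = {}
        self.edges: dict[tuple, Interaction] = {}
        for n in nodes:
            self.add_node(n)
        for e in edges:
            self.add_edge(e)

    def add_node(self, node: ProteinNode) -> None:
        if node.id in self.nodes:
            return
        self.nodes[node.id] = node

    def add_edge(self, edge: Interaction, *, replace: bool = False) -> None:
        if edge.source == edge.target:
            logger.warning("dropping self-loop on %s", edge.source)
            return
        canon = edge if edge.directed else Interaction(
            *sorted((edge.source, edge.target)), sign=edge.sign,
            relation=edge.relation, directed=False)
        if canon.key in self.edges and not replace:
            if self.edges[canon.key] == canon:
                return
            raise ValidationError(f"duplicate edge triple {canon.key}")
        for nid in (canon.source, canon.target):
            if nid not in self.nodes:
                self.nodes[nid] = ProteinNode(nid, nid)
        self.edges[canon.key] = canon

    def has_edge(self, source: str, target: str) -> bool:
        return self.arc_sign(source, target) is not None

    def arc_sign(self, source: str, target: str):
        """Sign of the arc source->target, or None if absent.

        Checks directed edges in the stated orientation and undirected
        edges in either orientation.
        """
        for e in self.edges.values():
            if e.directed and (e.source, e.target) == (source, target):
                return e.sign
            if not e.directed and {e.source, e.target} == {source, target}:
                return e.sign
        return None

    def __len__(self):
        return len(self.nodes)

    def __repr__(self):
        return f"Interactome({len(self.nodes)} nodes, {len(self.edges)} edges)"

    # -- conversions -------------------------------------------------------

    def to_networkx(self, *, respect_direction: bool = True) -> nx.DiGraph:
        """Arc-level view: undirected edges become two antiparallel arcs."""
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for e in self.edges.values():
            g.add_edge(e.source, e.target, sign=e.sign, relation=e.relation)
            if not e.directed or not respect_direction:
                g.add_edge(e.target, e.source, sign=e.sign, relation=e.relation)
        return g

    def arcs(self):
        """Yield (source, target, sign, edge_key) with undirected expansion."""
        for e in self.edges.values():
            yield e.source, e.target, e.sign, e.key
            if not e.directed:
                yield e.target, e.source, e.sign, e.key


# ---------------------------------------------------------------------------
# readers / writers


def _parse_bool(tok: str) -> bool:
    return tok.strip().lower() in ("1", "true", "yes", "directed")


def read_edge_list(path, dialect: str = "tsv", sif_map=None,
                   sif_fallback=DEFAULT_SIF_FALLBACK) -> Interactome:
    """Read an interactome from a TSV edge list or a SIF file.

    The TSV dialect expects a header ``source  target  sign  relation
    directed``.  SIF lines are whitespace-separated ``source label target``;
    labels map to (sign, relation) through ``sif_map`` (default:
    activates/inhibits), anything else falling back to sign 0.
    Unparseable rows raise with their line number.
    """
    try:
        fh = open(path, encoding="utf-8")
    except OSError as exc:
        raise InputError(f"cannot open edge list {path}: {exc}") from exc
    net = Interactome()
    sif_map = DEFAULT_SIF_MAP if sif_map is None else sif_map
    with fh:
        if dialect == "tsv":
            reader = csv.DictReader(fh, delimiter="\t")
            required = {"source", "target", "sign", "relation", "directed"}
            if reader.fieldnames is None or not required <= set(reader.fieldnames):
                raise ValidationError(
                    f"TSV edge list must have columns {sorted(required)}")
            for lineno, row in enumerate(reader, start=2):
                try:
                    edge = Interaction(
                        row["source"].strip(), row["target"].strip(),
                        sign=int(row["sign"]), relation=row["relation"].strip(),
                        directed=_parse_bool(row["directed"]))
                except (ValueError, ValidationError) as exc:
                    raise ValidationError(f"line {lineno}: {exc}") from exc
                net.add_edge(edge)
        elif dialect == "sif":
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                toks = line.split()
                if len(toks) < 3:
                    raise ValidationError(
                        f"line {lineno}: SIF rows need >= 3 columns")
                src, label = toks[0], toks[1]
                sign, relation = sif_map.get(label, sif_fallback)
                for tgt in toks[2:]:
                    net.add_edge(Interaction(src, tgt, sign=sign,
                                             relation=relation, directed=True))
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
    return net


def write_edge_list(path, net: Interactome, dialect: str = "tsv") -> None:
    """Write the edge list back out (TSV round-trips bit-identically)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if dialect == "tsv":
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["source", "target", "sign", "relation", "directed"])
            for key in sorted(net.edges):
                e = net.edges[key]
                w.writerow([e.source, e.target, e.sign, e.relation,
                            str(e.directed).lower()])
        elif dialect == "sif":
            inv = {v: k for k, v in DEFAULT_SIF_MAP.items()}
            for key in sorted(net.edges):
                e = net.edges[key]
                label = inv.get((e.sign, e.relation), e.relation)
                fh.write(f"{e.source} {label} {e.target}\n")
        else:
            raise ValueError(f"unknown dialect {dialect!r}")


def read_node_table(path, net: Interactome) -> None:
    """Attach display names / annotations from a node TSV (id, name, ...)."""
    with open(path, encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "id" not in reader.fieldnames:
            raise ValidationError("node table needs an 'id' column")
        for row in reader:
            nid = row["id"].strip()
            extra = {k: v for k, v in row.items() if k not in ("id", "name")}
            net.nodes[nid] = ProteinNode(nid, row.get("name", nid) or nid, extra)


# ---------------------------------------------------------------------------
# neighborhood extraction and connectivity


def extract_interactome(network: Interactome, seeds, radius: int = 1) -> Interactome:
    """Induced subgraph on all nodes within ``radius`` hops of any seed.

    Hop distance ignores edge direction (a neighborhood delimits biological
    context, not signal flow).  Seeds are always retained, so the output has
    at least ``len(seeds)`` nodes.  ``radius=0`` returns the induced
    subgraph on the seeds alone.
    """
    seeds = set(seeds)
    missing = seeds - set(network.nodes)
    if missing:
        raise InputError(f"unknown seed ids: {sorted(missing)}")
    if radius < 0:
        raise ValueError("radius must be >= 0")

    adj: dict[str, set] = {n: set() for n in network.nodes}
    for e in network.edges.values():
        adj[e.source].add(e.target)
        adj[e.target].add(e.source)

    keep = set(seeds)
    frontier = set(seeds)
    hops = 0
    while hops < radius:   # radius may be math.inf: loop ends when frontier empties
        frontier = {m for n in frontier for m in adj[n]} - keep
        if not frontier:
            break
        keep |= frontier
        hops += 1

    sub = Interactome()
    for nid in keep:
        sub.add_node(network.nodes[nid])
    for e in network.edges.values():
        if e.source in keep and e.target in keep:
            sub.add_edge(e)
    return sub


@dataclass
class ConnectivityReport:
    """Per-sink reachability from a source set, ignoring edge signs."""

    sources: frozenset
    reachable: dict          # sink id -> bool
    distance: dict           # sink id -> int hops or math.inf

    @property
    def all_reachable(self) -> bool:
        return all(self.reachable.values())


def check_connectivity(net: Interactome, sources, sinks) -> ConnectivityReport:
    """BFS reachability from any source to each sink, respecting direction.

    Signs are ignored; directed edges are traversed only forwards while
    undirected edges are traversed both ways.
    """
    sources, sinks = set(sources), set(sinks)
    if not sources or not sinks:
        raise InputError("sources and sinks must both be non-empty")
    unknown = (sources | sinks) - set(net.nodes)
    if unknown:
        raise InputError(f"unknown node ids: {sorted(unknown)}")

    succ: dict[str, set] = {n: set() for n in net.nodes}
    for u, v, _, _ in net.arcs():
        succ[u].add(v)

    dist = {s: 0 for s in sources}
    queue = deque(sources)
    while queue:
        u = queue.popleft()
        for v in succ[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)

    return ConnectivityReport(
        sources=frozenset(sources),
        reachable={t: t in dist for t in sorted(sinks)},
        distance={t: dist.get(t, math.inf) for t in sorted(sinks)},
    )
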