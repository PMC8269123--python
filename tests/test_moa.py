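"""Edge-usage aggregation and mechanism-path extraction."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from moanet.disease import DrugDefinition
from moanet.errors import ValidationError
from moanet.moa import (EdgeUsage, MoAPath, edge_usage, moa_report,
                        path_sign, report_contains_path, top_paths,
                        write_moa_report)
from moanet.network import Interaction, Interactome
from moanet.propagation import WeightAssignment
from moanet.training import ModelSolution, SolutionEnsemble


def solution(net, weights, signs=None):
    wa = WeightAssignment(
        {k: weights.get(k, 0.0) for k in net.edges},
        signs or {k: 1 for k, e in net.edges.items() if e.sign == 0})
    return ModelSolution(wa=wa, train_accuracy=1.0, seed=0,
                         anneal_iterations=1)


def ensemble(net, *weight_maps):
    return SolutionEnsemble([solution(net, w) for w in weight_maps],
                            validity_threshold=0.9,
                            target_size=len(weight_maps))


class TestEdgeUsage:
    def test_single_edge_self_normalizes_to_one(self):
        net = Interactome()
        net.add_edge(Interaction("MPL", "A", sign=1, directed=True))
        drug = DrugDefinition("d", (("MPL", 1),))
        key = ("MPL", "A", "functional")
        usage = edge_usage(ensemble(net, {key: 1.0}), net, drug)
        assert usage.usage[("MPL", "A")] == pytest.approx(1.0)

    def test_zero_weight_edge_has_zero_usage(self):
        net = Interactome()
        net.add_edge(Interaction("MPL", "A", sign=1, directed=True))
        net.add_edge(Interaction("A", "B", sign=1, directed=True))
        drug = DrugDefinition("d", (("MPL", 1),))
        usage = edge_usage(ensemble(net, {("MPL", "A", "functional"): 1.0}),
                           net, drug)
        assert usage.usage[("A", "B")] == 0.0

    def test_mean_across_two_solutions(self):
        net = Interactome()
        net.add_edge(Interaction("MPL", "A", sign=1, directed=True))
        net.add_edge(Interaction("MPL", "B", sign=1, directed=True))
        drug = DrugDefinition("d", (("MPL", 1),))
        k1, k2 = ("MPL", "A", "functional"), ("MPL", "B", "functional")
        # solution 1: flows (1.0, 0.5) -> normalized (1.0, 0.5)
        # solution 2: flows (1.0, 1.0) -> normalized (1.0, 1.0)
        usage = edge_usage(ensemble(net, {k1: 1.0, k2: 0.5},
                                    {k1: 1.0, k2: 1.0}), net, drug)
        assert usage.usage[("MPL", "B")] == pytest.approx(0.75)
        assert usage.usage[("MPL", "A")] == pytest.approx(1.0)

    def test_empty_ensemble_rejected(self):
        net = Interactome()
        net.add_edge(Interaction("MPL", "A", sign=1, directed=True))
        with pytest.raises(ValidationError):
            edge_usage(SolutionEnsemble([]), net,
                       DrugDefinition("d", (("MPL", 1),)))


def diamond_usage():
    net = Interactome()
    for u, v in [("MPL", "JAK2"), ("MPL", "TYK2"), ("JAK2", "STAT3"),
                 ("TYK2", "STAT3"), ("STAT3", "TGFB1")]:
        net.add_edge(Interaction(u, v, sign=1, directed=True))
    vals = {("MPL", "JAK2"): 0.9, ("JAK2", "STAT3"): 0.9,
            ("MPL", "TYK2"): 0.8, ("TYK2", "STAT3"): 0.7,
            ("STAT3", "TGFB1"): 0.9}
    usage = EdgeUsage(usage=vals, arc_sign={a: 1 for a in vals})
    return net, usage


class TestTopPaths:
    def test_diamond_best_product(self):
        net, usage = diamond_usage()
        paths = top_paths(net, usage, "MPL", "TGFB1", k=2)
        assert paths[0].nodes == ("MPL", "JAK2", "STAT3", "TGFB1")
        assert paths[0].score == pytest.approx(0.9 * 0.9 * 0.9)
        assert paths[1].score == pytest.approx(0.8 * 0.7 * 0.9)

    def test_k_exhausts_available_paths(self):
        net, usage = diamond_usage()
        paths = top_paths(net, usage, "MPL", "TGFB1", k=10)
        assert len(paths) == 2

    def test_unreachable_sink_empty(self):
        net, usage = diamond_usage()
        assert top_paths(net, usage, "TGFB1", "MPL", k=1) == []

    def test_max_len_filters(self):
        net, usage = diamond_usage()
        assert top_paths(net, usage, "MPL", "TGFB1", k=5, max_len=2) == []

    def test_zero_usage_edges_excluded(self):
        net, usage = diamond_usage()
        usage.usage[("JAK2", "STAT3")] = 0.0
        paths = top_paths(net, usage, "MPL", "TGFB1", k=2)
        assert [p.nodes for p in paths] == [("MPL", "TYK2", "STAT3", "TGFB1")]

    def test_lexicographic_tie_break(self):
        net = Interactome()
        for mid in ("A", "B"):
            net.add_edge(Interaction("S", mid, sign=1, directed=True))
            net.add_edge(Interaction(mid, "T", sign=1, directed=True))
        vals = {("S", "A"): 0.5, ("A", "T"): 0.5,
                ("S", "B"): 0.5, ("B", "T"): 0.5}
        usage = EdgeUsage(vals, {a: 1 for a in vals})
        paths = top_paths(net, usage, "S", "T", k=2)
        assert [p.nodes for p in paths] == [("S", "A", "T"), ("S", "B", "T")]

    def test_matches_exhaustive_enumeration_on_small_graphs(self):
        """Yen-style search equals brute force on all digraphs <= 8 nodes."""
        rng = np.random.default_rng(4)
        for trial in range(25):
            n = int(rng.integers(4, 9))
            net = Interactome()
            g = nx.DiGraph()
            names = [f"N{i}" for i in range(n)]
            from moanet.network import ProteinNode
            for nm in names:
                net.add_node(ProteinNode(nm))
                g.add_node(nm)
            vals = {}
            for i, j in itertools.permutations(range(n), 2):
                if rng.random() < 0.35:
                    u, v = names[i], names[j]
                    net.add_edge(Interaction(u, v, sign=1, directed=True))
                    vals[(u, v)] = float(rng.uniform(0.05, 1.0))
                    g.add_edge(u, v)
            usage = EdgeUsage(vals, {a: 1 for a in vals})
            src, snk = names[0], names[-1]
            got = top_paths(net, usage, src, snk, k=4, max_len=6)
            brute = []
            if src in g and snk in g:
                for nodes in nx.all_simple_paths(g, src, snk, cutoff=6):
                    score = math.prod(vals[(a, b)]
                                      for a, b in zip(nodes, nodes[1:]))
                    brute.append((tuple(nodes), score))
            brute.sort(key=lambda t: (-t[1], t[0]))
            expect = brute[:4]
            assert [(p.nodes) for p in got] == [t[0] for t in expect]
            for p, (_, s) in zip(got, expect):
                assert p.score == pytest.approx(s, rel=1e-9)

    def test_extension_cannot_increase_score(self):
        net, usage = diamond_usage()
        p3 = top_paths(net, usage, "MPL", "STAT3", k=1)[0]
        p4 = top_paths(net, usage, "MPL", "TGFB1", k=1)[0]
        assert p4.score <= p3.score


class TestPathSign:
    @pytest.mark.parametrize("signs,expected", [
        ((1, 1), 1), ((1, -1), -1), ((-1, -1), 1), ((1, 1, -1), -1),
    ])
    def test_product(self, signs, expected):
        nodes = tuple(f"N{i}" for i in range(len(signs) + 1))
        assert path_sign(MoAPath(nodes, signs, 0.5)) == expected

    def test_unresolved_sign_rejected(self):
        with pytest.raises(ValidationError, match="unresolved"):
            path_sign(MoAPath(("A", "B"), (0,), 0.5))

    def test_non_simple_path_rejected(self):
        with pytest.raises(ValidationError, match="simple"):
            MoAPath(("A", "B", "A"), (1, 1), 0.5)


class TestMoAReport:
    def test_unreachable_effector_marked(self, tmp_path):
        net = Interactome()
        net.add_edge(Interaction("MPL", "A", sign=1, directed=True))
        net.add_edge(Interaction("X", "E2", sign=1, directed=True))
        from moanet.disease import DiseaseDefinition, Motive
        disease = DiseaseDefinition("d", (Motive("m", (("A", -1),
                                                       ("E2", 1))),))
        drug = DrugDefinition("drug", (("MPL", 1),))
        key = ("MPL", "A", "functional")
        ens = ensemble(net, {key: 1.0})
        report = moa_report(ens, net, drug, disease)
        assert report["effectors"]["A"]["reachable"]
        assert not report["effectors"]["E2"]["reachable"]
        write_moa_report(report, json_path=tmp_path / "r.json",
                         tsv_path=tmp_path / "r.tsv")
        text = (tmp_path / "r.tsv").read_text()
        assert "UNREACHABLE" in text

    def test_report_contains_path_helper(self):
        report = {"effectors": {"E": {"paths": [
            {"nodes": ["MPL", "A"], "net_sign": -1, "score": 1.0,
             "edge_signs": [-1]}]}}}
        assert report_contains_path(report, ["MPL", "A"], -1)
        assert not report_contains_path(report, ["MPL", "A"], 1)
        assert not report_contains_path(report, ["MPL", "B"])
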