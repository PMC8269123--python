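"""Propagation dynamics, readout discretization, compliance scoring."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from moanet.disease import (DiseaseDefinition, DrugDefinition, Motive,
                            TruthEntry, TruthTable)
from moanet.errors import InputError, ValidationError
from moanet.network import Interaction, Interactome
from moanet.propagation import (PropagationConfig, PropagationState,
                                WeightAssignment, accuracy,
                                effector_readout, propagate, score_entry)
from moanet.synthetic import (NetworkGenSpec, generate_network,
                              oracle_assignment, planted_benchmark)


def unit_weights(net, sign_fill=1):
    return WeightAssignment({k: 1.0 for k in net.edges},
                            {k: sign_fill for k, e in net.edges.items()
                             if e.sign == 0})


def drug(target="MPL", mode=1):
    return DrugDefinition("d", ((target, mode),))


class TestPropagate:
    def test_single_activating_edge_reaches_tanh_one(self):
        net = Interactome()
        net.add_edge(Interaction("MPL", "X", sign=1, directed=True))
        state = propagate(net, unit_weights(net), drug())
        assert state.converged
        assert state.activations["MPL"] == 1.0
        assert state.activations["X"] == pytest.approx(math.tanh(1.0),
                                                       abs=1e-6)

    def test_sign_flip_through_inhibitory_arc(self, chain_net):
        state = propagate(chain_net, unit_weights(chain_net), drug())
        assert state.activations["A"] == pytest.approx(math.tanh(1.0), 1e-6)
        assert state.activations["B"] == pytest.approx(
            math.tanh(-math.tanh(1.0)), abs=1e-6)

    def test_zero_weights_give_zero_activations(self, chain_net):
        wa = WeightAssignment({k: 0.0 for k in chain_net.edges}, {})
        state = propagate(chain_net, wa, drug())
        assert state.activations["A"] == 0.0 == state.activations["B"]

    def test_missing_target_named(self, chain_net):
        with pytest.raises(InputError, match="GHOST"):
            propagate(chain_net, unit_weights(chain_net), drug("GHOST"))

    def test_antagonist_clamps_negative(self, chain_net):
        state = propagate(chain_net, unit_weights(chain_net),
                          drug(mode=-1))
        assert state.activations["MPL"] == -1.0

    def test_deterministic(self, chain_net):
        wa = unit_weights(chain_net)
        s1 = propagate(chain_net, wa, drug())
        s2 = propagate(chain_net, wa, drug())
        assert s1.activations == s2.activations

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 10**6))
    def test_activations_bounded(self, seed):
        """tanh dynamics keep every node inside [-1, 1] for any weights."""
        rng = np.random.default_rng(seed)
        net = generate_network(NetworkGenSpec(
            n_nodes=int(rng.integers(5, 40)), seed=seed))
        wa = WeightAssignment(
            {k: float(rng.uniform()) for k in net.edges},
            {k: int(rng.choice([-1, 1])) for k, e in net.edges.items()
             if e.sign == 0})
        target = sorted(net.nodes)[0]
        state = propagate(net, wa, drug(target))
        assert all(-1.0 <= v <= 1.0 for v in state.activations.values())

    def test_sign_equivariance(self):
        """Negating the stimulus negates every activation (odd update)."""
        net = generate_network(NetworkGenSpec(n_nodes=30, seed=2))
        rng = np.random.default_rng(0)
        wa = WeightAssignment(
            {k: float(rng.uniform()) for k in net.edges},
            {k: int(rng.choice([-1, 1])) for k, e in net.edges.items()
             if e.sign == 0})
        target = sorted(net.nodes)[0]
        plus = propagate(net, wa, drug(target, 1))
        minus = propagate(net, wa, drug(target, -1))
        for n in net.nodes:
            assert plus.activations[n] == pytest.approx(
                -minus.activations[n], abs=1e-9)

    def test_monotone_attenuation_along_chain(self):
        net = Interactome()
        names = [f"N{i}" for i in range(11)]
        for u, v in zip(names, names[1:]):
            net.add_edge(Interaction(u, v, sign=1, directed=True))
        wa = WeightAssignment({k: 0.8 for k in net.edges}, {})
        state = propagate(net, wa, drug(names[0]))
        mags = [abs(state.activations[n]) for n in names]
        assert all(a >= b for a, b in zip(mags, mags[1:]))

    def test_nonconvergence_flagged_not_raised(self):
        net = Interactome()
        net.add_edge(Interaction("MPL", "X", sign=1, directed=True))
        cfg = PropagationConfig(max_iterations=1, tolerance=1e-12)
        state = propagate(net, unit_weights(net), drug(), cfg)
        assert not state.converged
        assert state.iterations_run == 1


class TestReadout:
    @pytest.mark.parametrize("s,expected", [
        (0.30, 1), (0.01, 0), (-0.05, -1), (0.05, 1), (-0.3, -1), (0.0, 0),
    ])
    def test_threshold_rule(self, s, expected):
        state = PropagationState({"E": s}, 1, True)
        assert effector_readout(state, {"E"}, tau=0.05)["E"] == expected


def entry(relation, effectors):
    d = drug()
    cond = DiseaseDefinition("c", (Motive("m", tuple(effectors)),))
    return TruthEntry(d, cond, relation)


class TestScoreEntry:
    def test_indication_counter_pathological_movement(self):
        state = PropagationState({"A": -1.0, "B": 1.0}, 1, True)
        assert score_entry(state, entry("indication", [("A", 1), ("B", -1)]))

    def test_null_signal_fails(self):
        state = PropagationState({"A": 0.0, "B": 0.0}, 1, True)
        assert not score_entry(state, entry("indication",
                                            [("A", 1), ("B", -1)]))

    def test_adverse_effect_with_pathological_movement(self):
        state = PropagationState({"A": 1.0}, 1, True)
        assert score_entry(state, entry("adverse_effect", [("A", 1)]))

    def test_tie_fails(self):
        # one effector moves against, one with its pathological direction
        state = PropagationState({"A": -1.0, "B": 1.0}, 1, True)
        assert not score_entry(state, entry("indication",
                                            [("A", 1), ("B", 1)]))

    def test_conflict_effectors_skipped(self):
        d = drug()
        cond = DiseaseDefinition("c", (Motive("m1", (("A", 1), ("B", -1))),
                                       Motive("m2", (("A", -1),))))
        state = PropagationState({"A": 1.0, "B": 1.0}, 1, True)
        # A conflicts (skipped); B readout +1 against direction -1 satisfies
        assert score_entry(state, TruthEntry(d, cond, "indication"))

    def test_all_conflicting_raises(self):
        d = drug()
        cond = DiseaseDefinition("c", (Motive("m1", (("A", 1),)),
                                       Motive("m2", (("A", -1),))))
        state = PropagationState({"A": 1.0}, 1, True)
        with pytest.raises(ValidationError, match="scorable"):
            score_entry(state, TruthEntry(d, cond, "indication"))


class TestAccuracy:
    def test_fraction_of_satisfied_entries(self, mini_itp):
        net, disease, d, table = mini_itp
        wa = unit_weights(net)
        assert accuracy(wa, net, table) == 1.0

    def test_oracle_weights_reach_one_on_planted_benchmark(self):
        b = planted_benchmark(seed=3, n_nodes=60)
        wa = oracle_assignment(b.network, b.ground_truth)
        assert accuracy(wa, b.network, b.truth_table) == 1.0

    def test_zero_weights_score_zero(self, mini_itp):
        net, disease, d, table = mini_itp
        wa = WeightAssignment({k: 0.0 for k in net.edges}, {})
        assert accuracy(wa, net, table) == 0.0

    def test_empty_table_rejected(self, mini_itp):
        net, *_ = mini_itp
        with pytest.raises(ValidationError):
            accuracy(unit_weights(net), net, TruthTable([]))
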