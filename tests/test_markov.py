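"""Markov scheme construction, SDE coefficient matrices, stationary laws."""

import json

import numpy as np
import pytest

from bvrpop.markov import (
    ChannelStateVector,
    SchemeDefinitionError,
    build_scheme,
    evaluate_matrices,
    hh_gate_scheme,
    scheme_from_json,
    scheme_to_json,
    steady_state_distribution,
    tensor_product_scheme,
)
from conftest import make_two_state


def chain_definition(n_states=4):
    """C3 -> C2 -> C1 -> O chain with reverse transitions."""
    states = [f"C{n_states - 1 - k}" for k in range(n_states - 1)] + ["O"]
    transitions = []
    for a, b in zip(states[:-1], states[1:]):
        transitions.append({"from": a, "to": b, "rate": "0.5"})
        transitions.append({"from": b, "to": a, "rate": "0.5"})
    return {"name": "chain", "states": states, "transitions": transitions,
            "open_states": ["O"]}


class TestBuildScheme:
    def test_minimal_two_state(self, two_state):
        assert two_state.states == ("C", "O")
        assert two_state.n_transitions == 2
        assert two_state.open_states == frozenset({"O"})

    def test_unknown_state_rejected(self):
        with pytest.raises(SchemeDefinitionError, match="unknown state"):
            build_scheme({
                "name": "bad", "states": ["C", "O"],
                "transitions": [{"from": "C", "to": "Z", "rate": "1.0"}],
                "open_states": ["O"],
            })

    def test_no_open_state_rejected(self):
        with pytest.raises(SchemeDefinitionError, match="open state"):
            build_scheme({
                "name": "bad", "states": ["C", "O"],
                "transitions": [{"from": "C", "to": "O", "rate": "1.0"},
                                {"from": "O", "to": "C", "rate": "1.0"}],
                "open_states": [],
            })

    def test_chain_connectivity_matches_networkx(self):
        """BFS reachability agrees with an independent graph oracle."""
        import networkx as nx

        scheme = build_scheme(chain_definition())
        assert scheme.n_transitions == 6
        g = nx.DiGraph()
        for t in scheme.transitions:
            g.add_edge(t.from_state, t.to_state)
        assert nx.is_strongly_connected(g)

    def test_disconnected_scheme_rejected(self):
        with pytest.raises(SchemeDefinitionError, match="not connected"):
            build_scheme({
                "name": "split", "states": ["A", "B", "C", "O"],
                "transitions": [{"from": "A", "to": "B", "rate": "1"},
                                {"from": "B", "to": "A", "rate": "1"},
                                {"from": "C", "to": "O", "rate": "1"},
                                {"from": "O", "to": "C", "rate": "1"}],
                "open_states": ["O"],
            })

    def test_negative_rate_rejected(self):
        with pytest.raises(SchemeDefinitionError, match="negative"):
            build_scheme({
                "name": "neg", "states": ["C", "O"],
                "transitions": [{"from": "C", "to": "O", "rate": "V"},
                                {"from": "O", "to": "C", "rate": "1"}],
                "open_states": ["O"],
            })


class TestEvaluateMatrices:
    def test_hand_constructed_two_state(self, two_state):
        x = ChannelStateVector(np.array([0.5, 0.5]), "two_state")
        A, E, d = evaluate_matrices(two_state, x, V=0.0)
        assert np.allclose(A, [[-1.0, 1.0], [1.0, -1.0]])
        assert np.allclose(E, [[-1.0, 1.0], [1.0, -1.0]])
        assert np.allclose(d, [0.5, 0.5])

    @pytest.mark.parametrize("definition", [chain_definition(3), chain_definition(5)])
    def test_generator_columns_sum_to_zero(self, definition):
        scheme = build_scheme(definition)
        for V in np.linspace(-120, 80, 9):
            A, _, _ = evaluate_matrices(
                scheme, np.full(scheme.n_states, 1 / scheme.n_states), V)
            assert np.allclose(A.sum(axis=0), 0.0, atol=1e-12)

    def test_drift_form_equivalence(self, rng):
        """A x = E d on random simplex points (drift consistency)."""
        scheme = build_scheme(chain_definition(4))
        for _ in range(100):
            x = rng.dirichlet(np.ones(scheme.n_states))
            V = rng.uniform(-100, 60)
            A, E, d = evaluate_matrices(scheme, x, V)
            assert np.allclose(A @ x, E @ d, atol=1e-12)

    def test_zero_intensity_when_source_empty(self):
        scheme = make_two_state(0.0, 1.0)
        _, _, d = evaluate_matrices(scheme, np.array([1.0, 0.0]), V=0.0)
        # alpha = 0 (floored at 1e-10) and the open state is empty
        assert np.all(d <= 1e-9)

    def test_dimension_mismatch_rejected(self, two_state):
        with pytest.raises(ValueError, match="shape"):
            evaluate_matrices(two_state, np.array([1.0, 0.0, 0.0]), 0.0)


class TestSteadyState:
    def test_symmetric_two_state(self, two_state):
        x = steady_state_distribution(two_state, V=0.0)
        assert np.allclose(x.values, [0.5, 0.5], atol=1e-12)

    def test_open_fraction_alpha_over_alpha_plus_beta(self):
        scheme = make_two_state(3.0, 1.0)
        x = steady_state_distribution(scheme, V=0.0)
        assert np.isclose(scheme.open_fraction(x.values), 0.75, atol=1e-10)

    def test_uniform_on_symmetric_chain(self):
        scheme = build_scheme(chain_definition(3))
        x = steady_state_distribution(scheme, V=0.0)
        assert np.allclose(x.values, 1.0 / 3.0, atol=1e-10)

    def test_matches_gillespie_occupancy(self):
        """Stationary law agrees with a long discrete-channel simulation."""
        from bvrpop.sde import VoltageProtocol, simulate_channel_ssa

        scheme = make_two_state(2.0, 1.0)
        target = steady_state_distribution(scheme, 0.0).values
        traj = simulate_channel_ssa(
            scheme, VoltageProtocol.constant(0.0, 5000.0), N=10_000, seed=7)
        empirical = traj.states.mean(axis=0)
        assert np.all(np.abs(empirical - target) / target < 0.02)


class TestTensorAndJson:
    def test_tensor_product_states_and_open(self):
        a = hh_gate_scheme("a", "1.0", "2.0")
        b = hh_gate_scheme("b", "0.5", "0.25")
        t = tensor_product_scheme("ab", a, b)
        assert t.n_states == 4
        assert t.n_transitions == 8
        assert len(t.open_states) == 1

    def test_tensor_size_cap(self):
        g = hh_gate_scheme("g", "1.0", "1.0")
        big = g
        with pytest.raises(SchemeDefinitionError, match="cap"):
            for _ in range(7):  # 2^7 = 128 > 64
                big = tensor_product_scheme("big", big, g)

    def test_json_round_trip_preserves_rates(self, two_state):
        doc = scheme_to_json(two_state)
        back = scheme_from_json(doc)
        assert back.states == two_state.states
        assert back.open_states == two_state.open_states
        for V in (-80.0, 0.0, 40.0):
            assert np.allclose(back.rates(V), two_state.rates(V))
        # serialization is lossless: dumping again gives the same document
        assert json.loads(scheme_to_json(back)) == json.loads(doc)

    def test_cell_schemes_are_valid_and_serializable(self):
        from bvrpop.cell import cell_schemes

        for name, scheme in cell_schemes().items():
            x = steady_state_distribution(scheme, -87.0)
            assert np.isclose(x.values.sum(), 1.0)
            back = scheme_from_json(scheme_to_json(scheme))
            for V in (-90.0, -20.0, 30.0):
                assert np.allclose(back.rates(V), scheme.rates(V))
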