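"""Ordinal symbolization, network construction, parameter heuristics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import statescape as ss
from statescape.opn import (
    EmbeddingParams,
    _degree_variance,
    build_opn,
    opn_counts,
    ordinal_symbols,
    select_dim,
    select_dim_mode,
    select_tau,
)


class TestOrdinalSymbols:
    def test_by_definition(self):
        sym = ordinal_symbols([1, 3, 2, 4], EmbeddingParams(3, 1))
        assert sym.symbols == [(0, 2, 1), (1, 0, 2)]

    def test_monotone_series_single_symbol(self):
        sym = ordinal_symbols(np.arange(20.0), EmbeddingParams(4, 2))
        assert set(sym.symbols) == {(0, 1, 2, 3)}

    def test_ties_break_toward_earlier_position(self):
        sym = ordinal_symbols([2, 2, 1], EmbeddingParams(3, 1))
        assert sym.symbols == [(2, 0, 1)]

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            ordinal_symbols([1, 2, 3], EmbeddingParams(3, 2))

    @given(
        data=st.lists(st.floats(-100, 100, allow_nan=False), min_size=12, max_size=60),
        d=st.integers(2, 4),
        tau=st.integers(1, 3),
    )
    def test_window_count_and_symbol_validity(self, data, d, tau):
        if len(data) <= (d - 1) * tau:
            return
        sym = ordinal_symbols(np.array(data), EmbeddingParams(d, tau))
        assert sym.n_windows == len(data) - (d - 1) * tau
        assert all(sorted(s) == list(range(d)) for s in sym.symbols)


class TestBuildOPN:
    def test_two_symbol_alternation(self):
        sym = ordinal_symbols([1, 2, 1, 2, 1], EmbeddingParams(2, 1))
        net = build_opn(sym)
        # symbols: (0,1),(1,0),(0,1),(1,0)
        a, b = (0, 1), (1, 0)
        assert net.node_weights == {a: 2, b: 2}
        assert net.edge_counts == {(a, b): 2, (b, a): 1}

    def test_identical_symbols_single_self_loop(self):
        sym = ordinal_symbols(np.arange(10.0), EmbeddingParams(3, 1))
        net = build_opn(sym)
        assert net.n_nodes == 1
        node = net.nodes[0]
        assert net.node_weights[node] == 8
        assert net.edge_counts == {(node, node): 7}

    def test_periodic_input_gives_directed_cycle(self):
        # period-4 pattern whose four sliding windows have distinct symbols
        x = np.tile([0.0, 2.0, 1.0, 3.0], 20)
        net = build_opn(ordinal_symbols(x, EmbeddingParams(3, 1)))
        assert net.n_nodes == 4
        _, w = net.out_distributions()
        assert np.all((w > 0).sum(axis=1) == 1)

    def test_conservation_of_weights_and_edge_counts(self, rng):
        x = rng.standard_normal(500)
        sym = ordinal_symbols(x, EmbeddingParams(4, 2))
        net = build_opn(sym)
        assert sum(net.node_weights.values()) == sym.n_windows
        assert sum(net.edge_counts.values()) == sym.n_windows - 1

    def test_node_count_bounds(self, rng):
        x = rng.standard_normal(300)
        sym = ordinal_symbols(x, EmbeddingParams(5, 1))
        net = build_opn(sym)
        assert net.n_nodes <= min(sym.n_windows, 120)

    def test_determinism_of_construction(self, rng):
        x = rng.standard_normal(400)
        n1 = build_opn(ordinal_symbols(x, EmbeddingParams(5, 3)))
        n2 = build_opn(ordinal_symbols(x, EmbeddingParams(5, 3)))
        assert n1.node_weights == n2.node_weights and n1.edge_counts == n2.edge_counts


class TestOpnCounts:
    def test_examples(self):
        cyc = ss.OrdinalPartitionNetwork.from_edges({(i, (i + 1) % 4): 1 for i in range(4)})
        assert opn_counts(cyc) == {"n_nodes": 4, "n_edges": 4}
        loop = ss.OrdinalPartitionNetwork.from_edges({("a", "a"): 5})
        assert opn_counts(loop) == {"n_nodes": 1, "n_edges": 1}
        path = ss.OrdinalPartitionNetwork.from_edges(
            [(("A"), ("B")), (("B"), ("C")), (("C"), ("A")), (("A"), ("C"))]
        )
        assert opn_counts(path) == {"n_nodes": 3, "n_edges": 4}


class TestSelectTau:
    def test_sine_quarter_period(self):
        assert select_tau(ss.gen_sine(10, 1000, 1000)) == 25

    def test_white_noise_first_lag(self):
        assert select_tau(ss.gen_ar1(0.0, 1.0, 10**4, seed=0)) == 1

    def test_no_crossing_returns_cap_with_warning(self):
        x = np.exp(-np.arange(200) / 1e6) + np.linspace(0, 1, 200)  # strongly trending
        with pytest.warns(UserWarning, match="cap"):
            tau = select_tau(x, max_tau=10)
        assert tau == 10

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            select_tau(np.ones(100))


class TestSelectDim:
    def test_matches_exhaustive_recomputation_on_sine(self):
        x = ss.gen_sine(5, 250, 1500)
        tau = select_tau(x)
        cands = (3, 4, 5, 6, 7, 8)
        chosen = select_dim(x, tau, cands)
        variances = {
            d: _degree_variance(build_opn(ordinal_symbols(x, EmbeddingParams(d, tau))))
            for d in cands
        }
        assert chosen == max(variances, key=lambda d: (variances[d], -d))

    def test_path_graph_dimension_never_beats_structured_one(self):
        x = np.tile([0.0, 3.0, 1.0, 4.0, 2.0], 30)
        # d=2 gives a tiny repeating network; a huge d makes every window
        # unique (path graph, near-zero degree variance)
        assert select_dim(x, tau=1, candidates=(2, 20)) == 2

    def test_mode_aggregation(self):
        assert select_dim_mode([5, 5, 4]) == 5
        assert select_dim_mode([4, 5]) == 4  # tie -> smallest

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError, match="candidates"):
            select_dim(np.arange(100.0), 1, ())
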