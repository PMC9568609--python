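"""TAISM graph stage: intercept, reachability, loops, skeleton, TS/WS."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, strategies as st

import dematel_taism as dt
from dematel_taism.factors import FactorSystem
from dematel_taism.matrices import TotalInfluenceMatrix

from reference_nssi import REF_ADJACENCY, REF_TS, REF_WS_UNITS


def _system(n):
    return FactorSystem(tuple(f"F{i}" for i in range(n)))


def _random_adjacency(seed, n_max=8):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, n_max + 1))
    A = (rng.random((n, n)) < 0.3).astype(np.int8)
    np.fill_diagonal(A, 0)
    return dt.AdjacencyMatrix(_system(n), A)


class TestThreshold:
    def test_constant_matrix(self):
        T = TotalInfluenceMatrix(_system(3), np.full((3, 3), 0.5))
        thr = dt.compute_threshold(T)
        assert thr.mean == pytest.approx(0.5)
        assert thr.sd == pytest.approx(0.0)
        assert thr.lam == pytest.approx(0.5)

    def test_two_by_two_hand_computation(self):
        T = TotalInfluenceMatrix(_system(2), np.array([[0.0, 0.1], [0.0, 0.0]]))
        thr = dt.compute_threshold(T)
        assert thr.mean == pytest.approx(0.025)
        assert thr.sd == pytest.approx(np.sqrt(0.001875))
        assert thr.lam == pytest.approx(0.025 + np.sqrt(0.001875))

    def test_population_not_sample_divisor(self):
        values = np.array([[0.0, 0.1], [0.2, 0.0]])
        thr = dt.compute_threshold(TotalInfluenceMatrix(_system(2), values))
        assert thr.sd == pytest.approx(float(np.std(values)))  # divisor n^2


class TestBinarize:
    def test_fixture_matches_published_adjacency(self, nssi_report):
        expected = np.array([[int(c) for c in row] for row in REF_ADJACENCY])
        assert np.array_equal(nssi_report.A.values, expected)

    def test_strict_comparison_row_spot_check(self, nssi_report):
        system = nssi_report.system
        row = nssi_report.A.values[system.index("A2")]
        assert row[system.index("B4")] == 1 and row[system.index("Y")] == 1
        assert row.sum() == 2
        assert nssi_report.A.values[system.index("B2"), system.index("B6")] == 0

    def test_lambda_above_maximum_kills_all_edges(self, nssi_report):
        A = dt.binarize(nssi_report.T, nssi_report.T.values.max() + 1)
        assert not A.values.any()

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_raising_lambda_never_adds_edges(self, seed):
        rng = np.random.default_rng(seed)
        T = TotalInfluenceMatrix(_system(5), rng.random((5, 5)) * 0.2)
        thr = dt.compute_threshold(T)
        low = dt.binarize(T, thr.mean)
        high = dt.binarize(T, thr.lam)
        assert np.all(high.values <= low.values)


class TestReachability:
    def test_empty_adjacency_gives_identity(self):
        rs = dt.compute_reachability(dt.AdjacencyMatrix(_system(4), np.zeros((4, 4))))
        assert np.array_equal(rs.R, np.eye(4, dtype=bool))
        assert all(len(c) == 1 for c in rs.components)

    def test_fixture_loops(self, nssi_report):
        assert nssi_report.reachability.loops == (("B2", "B3"), ("B7", "B8", "B9"))

    def test_reachability_is_reflexive_transitive_idempotent(self, nssi_report):
        R = nssi_report.reachability.R
        assert np.all(np.diag(R))
        assert np.array_equal(R, R | (R @ R))

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_floyd_warshall_closure(self, seed):
        """Boolean-power reachability equals an independent O(n^3) closure."""
        A = _random_adjacency(seed)
        rs = dt.compute_reachability(A)
        n = A.system.n
        expected = A.values.astype(bool) | np.eye(n, dtype=bool)
        for k in range(n):
            expected = expected | (expected[:, k][:, None] & expected[k, :][None, :])
        assert np.array_equal(rs.R, expected)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_components_match_networkx_scc_oracle(self, seed):
        A = _random_adjacency(seed)
        rs = dt.compute_reachability(A)
        G = nx.from_numpy_array(A.values, create_using=nx.DiGraph)
        expected = {frozenset(c) for c in nx.strongly_connected_components(G)}
        idx = {c: i for i, c in enumerate(A.system.codes)}
        ours = {frozenset(idx[c] for c in comp) for comp in rs.components}
        assert ours == expected

    def test_condensed_relation_is_partial_order(self, nssi_report):
        Rc = nssi_report.reachability.R_condensed
        off = ~np.eye(Rc.shape[0], dtype=bool)
        assert not (Rc & Rc.T & off).any()


class TestSkeleton:
    def test_chain_with_shortcut_drops_transitive_edge(self):
        system = _system(3)
        A = dt.AdjacencyMatrix(system, np.array([[0, 1, 1], [0, 0, 1], [0, 0, 0]]))
        sk = dt.compute_skeleton(dt.compute_reachability(A))
        assert sk.S_general[0, 1] and sk.S_general[1, 2]
        assert not sk.S_general[0, 2]

    def test_fixture_skeleton_support_matches_published_values(self, nssi_report):
        system = nssi_report.system
        support = {
            (system.codes[i], system.codes[j])
            for i in range(13) for j in range(13)
            if nssi_report.skeleton.S_general[i, j]
        }
        assert support == set(REF_TS)

    def test_fixture_exercise_factor_keeps_single_out_edge(self, nssi_report):
        system = nssi_report.system
        row = nssi_report.skeleton.S_general[system.index("A3")]
        assert row.sum() == 1 and row[system.index("A2")]

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_reduction_closure_round_trip(self, seed):
        """Boolean closure of (S_condensed + I) recovers R_condensed."""
        A = _random_adjacency(seed)
        rs = dt.compute_reachability(A)
        sk = dt.compute_skeleton(rs)
        m = rs.R_condensed.shape[0]
        closure = sk.S_condensed | np.eye(m, dtype=bool)
        for k in range(m):
            closure = closure | (closure[:, k][:, None] & closure[k, :][None, :])
        assert np.array_equal(closure, rs.R_condensed)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_general_skeleton_acyclic_outside_loops(self, seed):
        A = _random_adjacency(seed)
        rs = dt.compute_reachability(A)
        sk = dt.compute_skeleton(rs)
        in_loop = {c for loop in rs.loops for c in loop}
        G = nx.DiGraph()
        codes = A.system.codes
        for i in range(A.system.n):
            for j in range(A.system.n):
                if sk.S_general[i, j] and not (codes[i] in in_loop and codes[j] in in_loop
                                               and rs.component_index[codes[i]]
                                               == rs.component_index[codes[j]]):
                    G.add_edge(codes[i], codes[j])
        assert nx.is_directed_acyclic_graph(G)


class TestValuedSkeleton:
    def test_fixture_TS_values_match_published_four_decimals(self, nssi_report):
        system = nssi_report.system
        TS = nssi_report.valued.TS
        for (a, b), expected in REF_TS.items():
            assert round(TS[system.index(a), system.index(b)], 4) == pytest.approx(
                expected, abs=1.5e-4), (a, b)
        # zero exactly off the skeleton support
        assert (TS != 0).sum() == len(REF_TS)

    def test_fixture_WS_unit_marking_is_loop_clique(self, nssi_report):
        system = nssi_report.system
        WS = nssi_report.valued.WS
        units = {
            (system.codes[i], system.codes[j])
            for i in range(13) for j in range(13)
            if WS[i, j] == 1.0
        }
        assert units == REF_WS_UNITS
        # WS differs from TS only inside loops
        diff = np.argwhere(WS != nssi_report.valued.TS)
        loop_idx = {system.index(c) for loop in nssi_report.reachability.loops for c in loop}
        assert all(i in loop_idx and j in loop_idx for i, j in diff)

    def test_loop_free_system_has_WS_equal_TS(self):
        system = _system(3)
        A = dt.AdjacencyMatrix(system, np.array([[0, 1, 0], [0, 0, 1], [0, 0, 0]]))
        rs = dt.compute_reachability(A)
        sk = dt.compute_skeleton(rs)
        T = TotalInfluenceMatrix(system, np.full((3, 3), 0.2))
        vs = dt.build_valued_skeleton(T, sk, rs)
        assert np.array_equal(vs.TS, vs.WS)
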