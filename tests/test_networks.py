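import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tmadissect import networks

from conftest import make_cells


def residual_partial_correlation(C, i, j):
    """Oracle: correlation between variables i and j after linearly
    regressing out all other variables (computed from the covariance
    algebra of the Schur complement)."""
    C = np.asarray(C, dtype=float)
    others = [k for k in range(len(C)) if k not in (i, j)]
    if not others:
        return C[i, j]
    A = C[np.ix_([i, j], [i, j])]
    B = C[np.ix_([i, j], others)]
    D = C[np.ix_(others, others)]
    S = A - B @ np.linalg.inv(D) @ B.T  # residual covariance of (i, j)
    return S[0, 1] / np.sqrt(S[0, 0] * S[1, 1])


def random_correlation(n, rng):
    A = rng.normal(size=(n, n + 3))
    S = A @ A.T
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)


class TestShrinkage:
    def test_pd_input_is_untouched(self):
        C = np.array([[1.0, 0.3], [0.3, 1.0]])
        M, delta = networks.shrink_to_pd(C)
        assert delta == 0.0
        np.testing.assert_array_equal(M, C)

    def test_identity_fixed_point(self):
        M, delta = networks.shrink_to_pd(np.eye(4))
        np.testing.assert_array_equal(M, np.eye(4))
        assert delta == 0.0

    def test_rank_deficient_gets_smallest_qualifying_delta(self):
        # duplicated marker -> singular matrix
        C = np.ones((3, 3))
        M, delta = networks.shrink_to_pd(C)
        assert delta > 0
        assert np.linalg.eigvalsh(M).min() >= 1e-6
        smaller = (1 - (delta - 0.01)) * C + (delta - 0.01) * np.eye(3)
        assert np.linalg.eigvalsh(smaller).min() < 1e-6


class TestPartialCorrelations:
    def test_two_variable_case_equals_marginal(self):
        C = pd.DataFrame([[1.0, 0.5], [0.5, 1.0]], index=["a", "b"], columns=["a", "b"])
        rho = networks.partial_correlations(C)
        assert rho.loc["a", "b"] == pytest.approx(0.5)

    def test_equicorrelated_three_variables(self):
        C = np.full((3, 3), 0.5)
        np.fill_diagonal(C, 1.0)
        rho = networks.partial_correlations(C)
        assert rho.iloc[0, 1] == pytest.approx((0.5 - 0.25) / (1 - 0.25))

    def test_identity_gives_zero_partials(self):
        rho = networks.partial_correlations(np.eye(4)).to_numpy()
        assert np.allclose(rho - np.eye(4), 0.0)

    def test_matches_residual_regression_oracle(self):
        rng = np.random.default_rng(12)
        for n in (3, 4, 5):
            for _ in range(20):
                C = random_correlation(n, rng)
                rho = networks.partial_correlations(C).to_numpy()
                for i, j in itertools.combinations(range(n), 2):
                    assert rho[i, j] == pytest.approx(
                        residual_partial_correlation(C, i, j), abs=1e-10
                    )

    def test_non_pd_input_rejected(self):
        C = np.ones((3, 3))
        with pytest.raises(ValueError, match="positive definite"):
            networks.partial_correlations(C)


class TestGroupDistributionsAndJsd:
    def test_identical_distributions_zero(self):
        p = np.full(10, 0.1)
        assert networks.jsd(p, p) == 0.0

    def test_disjoint_supports_one_bit(self):
        p = np.array([0.5, 0.5, 0.0, 0.0])
        q = np.array([0.0, 0.0, 0.5, 0.5])
        assert networks.jsd(p, q) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        assert networks.jsd([0.5, 0.5], [1.0, 0.0]) == pytest.approx(0.311278, abs=1e-6)

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            networks.jsd([0.5, 0.6], [0.5, 0.5])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 10), min_size=2, max_size=30),
           st.lists(st.floats(0.01, 10), min_size=2, max_size=30))
    def test_properties(self, a, b):
        n = min(len(a), len(b))
        p = np.asarray(a[:n]) / np.sum(a[:n])
        q = np.asarray(b[:n]) / np.sum(b[:n])
        d1 = networks.jsd(p, q)
        assert 0.0 <= d1 <= 1.0 + 1e-12
        assert d1 == pytest.approx(networks.jsd(q, p))
        assert networks.jsd(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_group_histograms(self):
        rng = np.random.default_rng(1)
        values = rng.uniform(-1, 1, 8000)
        groups = np.array([1] * 4000 + [0] * 4000)
        p1, p0, edges = networks.group_distributions(values, groups, n_bins=40)
        assert p1.sum() == pytest.approx(1.0)
        assert len(edges) == 41
        assert np.abs(p1 - 0.025).max() < 0.01

    def test_single_bin_degenerate(self):
        values = np.full(20, 0.33)
        groups = np.array([1] * 10 + [0] * 10)
        p1, p0, edges = networks.group_distributions(values, groups)
        assert p1.max() == pytest.approx(1.0)
        np.testing.assert_allclose(p1, p0)

    def test_empty_group_names_it(self):
        with pytest.raises(ValueError, match="recurrent"):
            networks.group_distributions([0.1, 0.2], [0, 0])


class TestDistanceMatrixAndNetwork:
    def make_partials(self, rng, n_markers=4, n_per_group=10, planted=None):
        markers = [f"m{i}" for i in range(n_markers)]
        partials, outcomes = {}, {}
        for g in (0, 1):
            for k in range(n_per_group):
                C = np.eye(n_markers)
                iu = np.triu_indices(n_markers, 1)
                C[iu] = np.clip(rng.normal(0, 0.1, len(iu[0])), -0.9, 0.9)
                C = C + C.T - np.diag(np.diag(C))
                np.fill_diagonal(C, 1.0)
                if planted and g == 1:
                    i, j = planted
                    C[i, j] = C[j, i] = np.clip(rng.normal(0.6, 0.05), -0.9, 0.9)
                M, _ = networks.shrink_to_pd(C)
                pid = f"g{g}k{k}"
                partials[pid] = networks.partial_correlations(
                    pd.DataFrame(M, index=markers, columns=markers)
                )
                outcomes[pid] = g
        return partials, pd.Series(outcomes)

    def test_unique_entry_count(self):
        partials, outcomes = self.make_partials(np.random.default_rng(0))
        D = networks.distance_matrix(partials, outcomes)
        iu = np.triu_indices(4, 1)
        assert len(D.to_numpy()[iu]) == 6
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0.0)

    def test_identical_groups_near_zero(self):
        rng = np.random.default_rng(3)
        partials, outcomes = self.make_partials(rng)
        # duplicate one group's matrices into the other: groups identical
        g1 = [p for p in partials if outcomes[p] == 1]
        g0 = [p for p in partials if outcomes[p] == 0]
        for a, b in zip(g0, g1):
            partials[b] = partials[a]
        D = networks.distance_matrix(partials, outcomes)
        assert D.to_numpy().max() == pytest.approx(0.0, abs=1e-9)

    def test_planted_pair_is_matrix_maximum(self):
        rng = np.random.default_rng(4)
        partials, outcomes = self.make_partials(rng, n_markers=5, n_per_group=25, planted=(1, 3))
        D = networks.distance_matrix(partials, outcomes)
        M = D.to_numpy()
        iu = np.triu_indices(5, 1)
        assert M[1, 3] == M[iu].max()

    def test_threshold_counting(self):
        rng = np.random.default_rng(5)
        n = 15  # 105 pairs
        D = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        vals = rng.permutation(np.linspace(0.01, 0.9, len(iu[0])))
        D[iu] = vals
        D = D + D.T
        names = [f"m{i}" for i in range(n)]
        net = networks.threshold_network(pd.DataFrame(D, index=names, columns=names), 99.0)
        assert len(net.edges) == 1
        u, v, w = net.edges[0]
        assert w == pytest.approx(vals.max())
        assert len(net.nodes) == n  # isolated nodes retained

    def test_percentile_zero_keeps_everything_above_min(self):
        D = pd.DataFrame(
            [[0, 0.1, 0.2], [0.1, 0, 0.3], [0.2, 0.3, 0]],
            index=list("abc"), columns=list("abc"),
        )
        net = networks.threshold_network(D, 0.0)
        assert len(net.edges) == 2  # strictly above the minimum weight 0.1

    def test_all_equal_weights_no_edges(self):
        D = pd.DataFrame(
            [[0, 0.4, 0.4], [0.4, 0, 0.4], [0.4, 0.4, 0]],
            index=list("abc"), columns=list("abc"),
        )
        net = networks.threshold_network(D, 99.0)
        assert len(net.edges) == 0


class TestBuildFromCells:
    def test_correlation_matrix_from_patient_table(self):
        rng = np.random.default_rng(8)
        z = rng.normal(size=60)
        mA = 5 + z + rng.normal(0, 0.3, 60)
        mB = 5 + z + rng.normal(0, 0.3, 60)
        mC = rng.uniform(2, 8, 60)
        table = make_cells(n=60, panel=("mA", "mB", "mC"), mA=mA, mB=mB, mC=mC)
        C, delta = networks.build_correlation_matrix(table, ["mA", "mB", "mC"], percentile=20)
        assert np.allclose(np.diag(C), 1.0 - delta + delta)
        assert C.loc["mA", "mB"] > abs(C.loc["mA", "mC"])
        rho = networks.partial_correlations(C)
        assert rho.loc["mA", "mB"] > 0

    def test_requires_two_markers(self):
        table = make_cells(n=10, panel=("mA",))
        with pytest.raises(ValueError):
            networks.build_correlation_matrix(table, ["mA"])


class TestExport:
    def test_round_trip(self, tmp_path):
        g_nodes = ["a", "b", "c"]
        D = pd.DataFrame(
            [[0, 0.9, 0.1], [0.9, 0, 0.2], [0.1, 0.2, 0]], index=g_nodes, columns=g_nodes
        )
        net = networks.threshold_network(D, 50.0)
        paths = networks.export_network(net, tmp_path / "net")
        back = networks.read_network(paths["graphml"])
        assert set(back.nodes) == set(net.nodes)
        assert sorted((u, v) for u, v, _ in back.edges) == sorted(
            (u, v) for u, v, _ in net.edges
        )
        for (u, v, w), (u2, v2, w2) in zip(sorted(net.edges), sorted(back.edges)):
            assert w == pytest.approx(w2)
        edges_text = paths["edges"].read_text().splitlines()
        assert edges_text[0] == "node_i\tnode_j\tweight"

    def test_empty_graph_valid_files(self, tmp_path):
        D = pd.DataFrame([[0, 0.5], [0.5, 0]], index=["a", "b"], columns=["a", "b"])
        net = networks.threshold_network(D, 99.0)
        assert len(net.edges) == 0
        paths = networks.export_network(net, tmp_path / "empty")
        back = networks.read_network(paths["graphml"])
        assert set(back.nodes) == {"a", "b"}
        assert len(back.edges) == 0
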