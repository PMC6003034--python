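"""Shrinkage precision estimation, partial correlations and orientation."""

import numpy as np
import pytest

from arganet.correlation import DataMatrix
from arganet.exceptions import ConfigurationError, ValidationError
from arganet.network import (
    PartialCorrelationNetwork,
    b_matrix,
    build_network,
    estimate_precision,
    node_order_scores,
    orient_edges,
    partial_correlation_matrix,
    select_edges,
    shrinkage_intensity,
    standardize,
)
from arganet.synthetic import chain_spec, fork_spec, simulate_sem


def residual_partial_correlation(X, i, j):
    """Oracle: correlation of OLS residuals after regressing out the rest."""
    n, p = X.shape
    rest = [k for k in range(p) if k not in (i, j)]
    Z = np.column_stack([np.ones(n)] + [X[:, k] for k in rest])
    ri = X[:, i] - Z @ np.linalg.lstsq(Z, X[:, i], rcond=None)[0]
    rj = X[:, j] - Z @ np.linalg.lstsq(Z, X[:, j], rcond=None)[0]
    return float(ri @ rj / np.sqrt((ri @ ri) * (rj @ rj)))


def random_matrix(rng, n=20, p=5):
    return DataMatrix(rng.normal(size=(n, p)), tuple(f"v{k}" for k in range(p)))


class TestStandardize:
    def test_simple_column(self):
        Z = standardize(DataMatrix(np.array([[1.0], [2.0], [3.0]]), ("x",)))
        assert np.allclose(Z.values[:, 0], [-1, 0, 1])

    def test_idempotence(self, rng):
        Z1 = standardize(random_matrix(rng))
        Z2 = standardize(Z1)
        assert np.allclose(Z1.values, Z2.values)

    def test_constant_column_named_in_error(self, rng):
        X = random_matrix(rng, p=3)
        V = X.values.copy()
        V[:, 1] = 4.2
        with pytest.raises(ValidationError, match="v1"):
            standardize(DataMatrix(V, X.columns))


class TestPrecision:
    def test_full_shrinkage_gives_identity(self, rng):
        Z = standardize(random_matrix(rng))
        pe = estimate_precision(Z, shrinkage=1.0)
        assert np.allclose(pe.omega, np.eye(Z.p), atol=1e-12)

    def test_two_variable_closed_form(self, rng):
        Z = standardize(random_matrix(rng, n=40, p=2))
        pe = estimate_precision(Z, shrinkage=0.0)
        r = pe.sigma[0, 1]
        expected = np.array([[1, -r], [-r, 1]]) / (1 - r * r)
        assert np.allclose(pe.omega, expected, atol=1e-10)

    def test_spd_under_auto_shrinkage_when_singular(self, rng):
        # n < p: sample covariance is singular but the shrunk one is SPD
        Z = standardize(random_matrix(rng, n=7, p=10))
        pe = estimate_precision(Z)
        assert 0 < pe.shrinkage <= 1
        assert np.all(np.linalg.eigvalsh(pe.sigma_shrunk) > 0)
        assert np.all(np.isfinite(pe.omega))
        assert np.allclose(pe.omega @ pe.sigma_shrunk, np.eye(10), atol=1e-8)

    def test_shrinkage_intensity_in_unit_interval(self, rng):
        for n, p in [(5, 8), (30, 4), (100, 10)]:
            lam = shrinkage_intensity(standardize(random_matrix(rng, n=n, p=p)))
            assert 0.0 <= lam <= 1.0

    def test_shrinkage_vanishes_with_sample_size(self):
        # with genuinely correlated variables the analytic intensity decays
        # as the correlations become precisely estimated
        lams = []
        for n in (10, 100, 5000):
            r = np.random.default_rng(5)
            X = r.normal(size=(n, 4))
            X[:, 1] += X[:, 0]
            lams.append(shrinkage_intensity(standardize(DataMatrix(X, tuple("abcd")))))
        assert lams[0] > lams[1] > lams[2]
        assert lams[2] < 0.01

    def test_out_of_range_shrinkage(self, rng):
        Z = standardize(random_matrix(rng))
        with pytest.raises(ConfigurationError):
            estimate_precision(Z, shrinkage=1.5)


class TestPartialCorrelation:
    def test_diagonal_precision_gives_zero(self):
        from arganet.network import PrecisionEstimate

        omega = np.diag([2.0, 3.0, 4.0])
        pe = PrecisionEstimate(
            sigma=np.eye(3), sigma_shrunk=np.eye(3), omega=omega,
            sigma_diag=np.ones(3), shrinkage=0.0, n=10, p=3,
        )
        rho = partial_correlation_matrix(pe)
        assert np.allclose(rho - np.eye(3), 0.0)

    def test_two_variables_equal_marginal(self, rng):
        Z = standardize(random_matrix(rng, n=50, p=2))
        pe = estimate_precision(Z, shrinkage=0.0)
        rho = partial_correlation_matrix(pe)
        assert rho[0, 1] == pytest.approx(pe.sigma[0, 1], abs=1e-12)

    @pytest.mark.parametrize("p", [3, 4])
    def test_matches_residual_regression_oracle(self, rng, p):
        """Unshrunk partial correlations equal residual-based ones exactly."""
        X = rng.normal(size=(60, p))
        X[:, -1] += 0.8 * X[:, 0]  # induce structure
        Z = standardize(DataMatrix(X, tuple(f"v{k}" for k in range(p))))
        pe = estimate_precision(Z, shrinkage=0.0)
        rho = partial_correlation_matrix(pe)
        for i in range(p):
            for j in range(i + 1, p):
                oracle = residual_partial_correlation(Z.values, i, j)
                assert rho[i, j] == pytest.approx(oracle, abs=1e-10)

    def test_shrinkage_drives_pcorr_to_zero(self, rng):
        """The strongest partial correlation decays monotonically as the
        covariance shrinks toward the identity, and all of them vanish in
        the full-shrinkage limit.  (Individual near-zero pairs may wiggle
        through sign changes, so the guarantee is on the maximum.)"""
        Z = standardize(random_matrix(rng, n=15, p=5))
        iu = np.triu_indices(5, 1)
        maxes = []
        for lam in [0.05, 0.2, 0.4, 0.6, 0.8, 0.99]:
            rho = partial_correlation_matrix(estimate_precision(Z, shrinkage=lam))
            maxes.append(np.abs(rho[iu]).max())
        assert all(b <= a + 1e-12 for a, b in zip(maxes, maxes[1:]))
        assert maxes[-1] < 0.05  # lambda -> 1 kills all partial correlations


class TestEdgeSelection:
    def test_tau_zero_complete_graph(self, rng):
        rho = partial_correlation_matrix(
            estimate_precision(standardize(random_matrix(rng, p=5)))
        )
        assert len(select_edges(rho, tau=0.0)) == 10

    def test_tau_one_empty(self, rng):
        rho = partial_correlation_matrix(
            estimate_precision(standardize(random_matrix(rng, p=5)))
        )
        assert select_edges(rho, tau=1.0) == []

    def test_enumeration_oracle(self):
        rho = np.eye(4)
        pairs = {(0, 1): 0.55, (1, 2): -0.40, (2, 3): 0.10}
        for (i, j), v in pairs.items():
            rho[i, j] = rho[j, i] = v
        edges = select_edges(rho, tau=0.3)
        assert [(i, j) for i, j, _ in edges] == [(0, 1), (1, 2)]

    def test_tau_out_of_range(self):
        with pytest.raises(ConfigurationError):
            select_edges(np.eye(2), tau=1.5)


class TestOrientation:
    def test_b_reciprocity_is_exact(self, rng):
        g = rng.uniform(0.1, 2.0, size=6)
        B = b_matrix(g)
        assert np.allclose(B * B.T, 1.0, atol=1e-12)

    def test_orientation_follows_score_order(self):
        g = np.array([1.0, 0.5])
        net = orient_edges([(0, 1, 0.8)], g, ("a", "b"))
        assert net.directed_arcs == [("a", "b", 0.8, 2.0)]

    def test_tie_stays_undirected(self):
        g = np.array([0.7, 0.7])
        net = orient_edges([(0, 1, 0.8)], g, ("a", "b"))
        assert net.directed_arcs == []
        assert net.undirected_edges == [("a", "b", 0.8)]

    def test_distinct_scores_fully_direct_and_acyclic(self, rng):
        p = 7
        g = rng.permutation(np.linspace(0.2, 1.4, p))
        edges = [(i, j, 0.5) for i in range(p) for j in range(i + 1, p)]
        net = orient_edges(edges, g, tuple(f"n{k}" for k in range(p)))
        assert len(net.directed_arcs) == len(edges)
        assert net.is_acyclic

    def test_acyclic_on_random_builds(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 40))
            p = int(rng.integers(3, 8))
            res = build_network(random_matrix(rng, n=n, p=p), tau=float(rng.uniform(0, 0.5)))
            assert res.network.is_acyclic

    def test_chain_root_arc_points_away_from_root(self):
        """For x0 -> x1 -> x2, the root has the largest standardized partial
        variance, so its edge orients x0 -> x1 in nearly every replicate.
        (The downstream edge orients x2 -> x1: the middle node of a chain is
        the best-explained one, a known behaviour of this heuristic.)"""
        hits = trials = 0
        for seed in range(100):
            X = simulate_sem(chain_spec(3, beta=1.0, n=500, seed=seed))
            res = build_network(X, tau=0.2)
            arcs = {(u, v) for u, v, *_ in res.network.directed_arcs}
            if ("x0", "x1") in arcs or ("x1", "x0") in arcs:
                trials += 1
                hits += ("x0", "x1") in arcs
        assert trials >= 90
        assert hits / trials >= 0.9


class TestModelAPI:
    def test_study_table_builds_ten_node_dag(self, study_matrix):
        res = PartialCorrelationNetwork(study_matrix).fit()
        assert len(res.network.nodes) == 10
        assert res.network.is_acyclic
        assert 0 < res.shrinkage <= 1

    def test_duplicate_column_dominates_pcorr(self, rng):
        X = rng.normal(size=(50, 4))
        X[:, 3] = X[:, 0]
        res = build_network(DataMatrix(X, ("a", "b", "c", "a2")))
        pc = np.abs(res.pcorr.copy())
        np.fill_diagonal(pc, 0)
        i, j = np.unravel_index(np.argmax(pc), pc.shape)
        assert {res.columns[i], res.columns[j]} == {"a", "a2"}

    def test_independent_columns_near_empty_network(self):
        spec = chain_spec(6, beta=0.0, n=500, seed=11)
        res = build_network(simulate_sem(spec), tau=0.3)
        assert len(res.arcs) + len(res.undirected) <= 1

    def test_from_dataframe_and_summary(self, study_matrix):
        df = study_matrix.to_dataframe()
        res = PartialCorrelationNetwork.from_dataframe(df).fit()
        text = res.summary()
        assert "Shrinkage lambda" in text and "Acyclic:             True" in text

    def test_unstandardized_reading_agrees_after_standardization(self, rng):
        """The literal raw-scale B test equals the standardized one when the
        input is already standardized."""
        Z = standardize(random_matrix(rng, n=30, p=4))
        a = PartialCorrelationNetwork(Z).fit(shrinkage=0.1, tau=0.0)
        b = PartialCorrelationNetwork(Z).fit(shrinkage=0.1, tau=0.0,
                                             standardize_data=False)
        arcs_a = {(u, v) for u, v, *_ in a.network.directed_arcs}
        arcs_b = {(u, v) for u, v, *_ in b.network.directed_arcs}
        assert arcs_a == arcs_b

    def test_skeleton_recovery_on_sems(self):
        """Chain and fork skeletons are recovered at tau=0.2, beta=0.8, n=500."""
        recovered = total = 0
        for seed in range(30):
            for spec in (chain_spec(4, 0.8, 500, seed), fork_spec(3, 0.8, 500, seed + 1000)):
                truth = {
                    tuple(sorted((p, c)))
                    for c, ps in spec.parents.items()
                    for p in ps
                }
                res = build_network(simulate_sem(spec), tau=0.2)
                found = {
                    tuple(sorted((u, v)))
                    for u, v, *_ in res.network.directed_arcs
                } | {tuple(sorted((u, v))) for u, v, _ in res.network.undirected_edges}
                recovered += len(truth & found)
                total += len(truth)
        assert recovered / total >= 0.8

    def test_node_order_scores_match_precision_diag(self, rng):
        Z = standardize(random_matrix(rng, n=25, p=5))
        pe = estimate_precision(Z, shrinkage=0.2)
        g = node_order_scores(pe)
        assert np.allclose(g, np.diag(pe.sigma_shrunk) / np.diag(pe.omega))
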