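import itertools

import numpy as np
import pytest

from orlrs import solver
from orlrs.norms import (
    RegularizedPowerSpec,
    capped_norm,
    effective_ridge,
    l21_norm,
    low_rank_term,
    sym_power,
)
from orlrs.solver import (
    assign_labels,
    augmented_merit,
    cluster_scores,
    fit,
    fit_lrs,
    objective,
    update_A,
    update_E,
    update_indicators,
    update_weights,
)
from orlrs.synthetic import SubspaceSpec, clean_recovery_case, generate
from orlrs.types import ExpressionMatrix, IndicatorSet, SolverConfig

from conftest import mid_theta


def _xm(values):
    values = np.asarray(values, dtype=float)
    m, n = values.shape
    return ExpressionMatrix(values, [f"g{i}" for i in range(m)], [f"s{j}" for j in range(n)])


def _flip(labels, idx, c):
    labels = labels.copy()
    labels[idx] = (labels[idx] + 1) % c
    return labels


class TestObjective:
    def test_k1_zero_noise_is_squared_frobenius(self, rng):
        A = rng.standard_normal((6, 8))
        X = _xm(A)
        cfg = SolverConfig(c=3, k=1.0)
        ind = IndicatorSet(labels=rng.integers(0, 3, 8), c=3)
        val = objective(X, A, np.zeros_like(A), ind, cfg)
        assert val == pytest.approx(float(np.sum(A**2)), rel=1e-10)

    def test_zero_A_infinite_theta_is_l21(self, rng):
        E = rng.standard_normal((5, 6))
        X = _xm(E)
        cfg = SolverConfig(c=2, lam=1.7, theta=np.inf)
        ind = IndicatorSet(labels=np.array([0, 1, 0, 1, 0, 1]), c=2)
        val = objective(X, np.zeros_like(E), E, ind, cfg)
        assert val == pytest.approx(1.7 * l21_norm(E), rel=1e-12)

    def test_matches_per_cluster_oracle(self, rng):
        A = rng.standard_normal((7, 6))
        E = 0.1 * rng.standard_normal((7, 6))
        X = _xm(A + E)
        labels = np.array([0, 0, 1, 1, 0, 1])
        cfg = SolverConfig(c=2, lam=0.8, theta=1.2, k=0.5)
        expected = sum(
            low_rank_term(A[:, labels == i], 0.5) for i in range(2)
        ) + 0.8 * capped_norm(E, 1.2)
        val = objective(X, A, E, IndicatorSet(labels=labels, c=2), cfg)
        assert val == pytest.approx(expected, rel=1e-12)


class TestUpdateA:
    def test_k1_closed_form_shrinkage(self, rng):
        X = rng.standard_normal((8, 5))
        E = 0.1 * rng.standard_normal((8, 5))
        Y = rng.standard_normal((8, 5))
        A_prev = rng.standard_normal((8, 5))
        mu = 0.37
        B = X - E + Y / mu
        A = update_A(X, E, Y, mu, A_prev, k=1.0, ridge=1e-10)
        np.testing.assert_allclose(A, (mu / (2 + mu)) * B, rtol=1e-10, atol=1e-12)

    def test_large_mu_returns_B(self, rng):
        X = rng.standard_normal((6, 4))
        E = 0.05 * rng.standard_normal((6, 4))
        Y = rng.standard_normal((6, 4))
        mu = 1e12
        B = X - E + Y / mu
        for k in (1.0, 0.5):
            A = update_A(X, E, Y, mu, rng.standard_normal((6, 4)), k, 1e-10)
            assert np.linalg.norm(A - B) / np.linalg.norm(B) < 1e-6

    def test_stationarity_residual(self, rng):
        X = rng.standard_normal((8, 5))
        E = 0.1 * rng.standard_normal((8, 5))
        Y = rng.standard_normal((8, 5))
        A_prev = rng.standard_normal((8, 5))
        mu, k, ridge = 2.3, 0.5, 1e-10
        B = X - E + Y / mu
        A = update_A(X, E, Y, mu, A_prev, k, ridge)
        G = A_prev.T @ A_prev
        eps = effective_ridge(float(np.linalg.eigvalsh(G)[-1]), ridge)
        H = k * sym_power(G, RegularizedPowerSpec(k - 1.0, eps))
        res = np.linalg.norm(2 * A @ H + mu * (A - B)) / np.linalg.norm(B)
        assert res < 1e-8


class TestUpdateEAndWeights:
    def test_weight_rule(self):
        E = np.zeros((3, 3))
        E[0] = [0.5, 2.0, 1.0]  # column norms 0.5, 2, 1
        w = update_weights(E, theta=1.0)
        assert w[0] == pytest.approx(1.0)  # 1/(2*0.5)
        assert w[1] == 0.0  # above threshold
        assert w[2] == 0.0  # exactly theta: strict inequality

    def test_zero_column_gets_capped_weight(self):
        w = update_weights(np.zeros((4, 2)), theta=5.0)
        np.testing.assert_allclose(w, 1.0 / (2 * solver.EPS_NORM))

    def test_outlier_column_passes_through(self, rng):
        X = rng.standard_normal((5, 4))
        A = rng.standard_normal((5, 4))
        Y = rng.standard_normal((5, 4))
        mu = 1.3
        F = X - A + Y / mu
        o = np.array([0.0, 0.5, 1.0, 0.0])
        E = update_E(X, A, Y, mu, lam=1.0, o_diag=o)
        np.testing.assert_array_equal(E[:, 0], F[:, 0])
        np.testing.assert_array_equal(E[:, 3], F[:, 3])

    def test_half_scaling_example(self, rng):
        X = rng.standard_normal((4, 3))
        A = np.zeros((4, 3))
        Y = np.zeros((4, 3))
        E = update_E(X, A, Y, mu=1.0, lam=1.0, o_diag=np.full(3, 0.5))
        np.testing.assert_allclose(E, X / 2.0, rtol=1e-14)

    def test_stationarity_is_exact(self, rng):
        X = rng.standard_normal((6, 5))
        A = rng.standard_normal((6, 5))
        Y = rng.standard_normal((6, 5))
        mu, lam = 0.7, 1.9
        o = rng.uniform(0, 2, 5)
        F = X - A + Y / mu
        E = update_E(X, A, Y, mu, lam, o)
        res = 2 * lam * E * o[None, :] + mu * (E - F)
        assert np.linalg.norm(res) < 1e-12


class TestClusterScores:
    def test_thin_path_matches_dense_power_oracle(self, rng):
        A = rng.standard_normal((6, 4))
        ind = IndicatorSet(labels=np.zeros(4, dtype=int), c=1)
        k, ridge = 1.0, 1e-10
        z = cluster_scores(A, ind, k, ridge)
        s = np.linalg.svd(A, compute_uv=False)
        eps = effective_ridge(float(s[0] ** 2), ridge)
        L = np.sqrt(np.sum(s**2)) * sym_power(
            A @ A.T, RegularizedPowerSpec((k - 2) / 2, eps)
        )
        np.testing.assert_allclose(
            z[:, 0], np.diag(A.T @ L @ A), rtol=1e-5
        )

    def test_own_subspace_scores_lower(self, rng):
        # two orthogonal 2-dim column spans
        Q = np.linalg.qr(rng.standard_normal((10, 4)))[0]
        A = np.concatenate(
            [Q[:, :2] @ rng.standard_normal((2, 5)), Q[:, 2:] @ rng.standard_normal((2, 5))],
            axis=1,
        )
        ind = IndicatorSet(labels=np.repeat([0, 1], 5), c=2)
        z = cluster_scores(A, ind, 1.0, 1e-10)
        for j in range(10):
            own = ind.labels[j]
            assert z[j, own] < z[j, 1 - own]

    def test_zero_matrix_gives_zero_scores(self):
        ind = IndicatorSet(labels=np.array([0, 1, 0, 1]), c=2)
        z = cluster_scores(np.zeros((5, 4)), ind, 0.5, 1e-10)
        np.testing.assert_array_equal(z, 0.0)


class TestAssignLabels:
    def test_rowwise_argmin_and_tie_break(self):
        scores = np.array([[0.2, 0.5], [0.3, 0.3], [0.9, 0.1]])
        out = assign_labels(scores)
        np.testing.assert_array_equal(out.labels, [0, 0, 1])

    def test_partition_property(self, rng):
        out = assign_labels(rng.uniform(size=(12, 4)))
        assert out.labels.shape == (12,)
        assert set(np.unique(out.labels)) <= set(range(4))

    def test_attains_exhaustive_minimum(self, rng):
        scores = rng.uniform(size=(6, 2))
        out = assign_labels(scores)
        best = min(
            sum(scores[j, lab[j]] for j in range(6))
            for lab in itertools.product(range(2), repeat=6)
        )
        got = float(scores[np.arange(6), out.labels].sum())
        assert got == pytest.approx(best, rel=1e-12)


class TestUpdateIndicators:
    @staticmethod
    def _orthogonal_block_instance(rng, n_per=4):
        Q = np.linalg.qr(rng.standard_normal((12, 4)))[0]
        A = np.concatenate(
            [Q[:, :2] @ rng.standard_normal((2, n_per)),
             Q[:, 2:] @ rng.standard_normal((2, n_per))],
            axis=1,
        )
        truth = np.repeat([0, 1], n_per)
        return A, truth

    def test_truth_is_fixed_point(self, rng):
        A, truth = self._orthogonal_block_instance(rng)
        out = update_indicators(A, IndicatorSet(labels=truth, c=2), 1.0, 1e-10, 10)
        np.testing.assert_array_equal(out.labels, truth)

    def test_recovers_single_mislabel(self, rng):
        A, truth = self._orthogonal_block_instance(rng)
        init = _flip(truth, [2], 2)
        out = update_indicators(A, IndicatorSet(labels=init, c=2), 1.0, 1e-10, 20)
        np.testing.assert_array_equal(out.labels, truth)
        # exhaustive check: truth minimizes the score-sum among all
        # assignments at the returned fixed point
        z = cluster_scores(A, out, 1.0, 1e-10)
        best = min(
            sum(z[j, lab[j]] for j in range(8))
            for lab in itertools.product(range(2), repeat=8)
        )
        assert float(z[np.arange(8), out.labels].sum()) == pytest.approx(best, rel=1e-9)

    def test_max_inner_zero_returns_input(self, rng):
        A, truth = self._orthogonal_block_instance(rng)
        init = _flip(truth, [0, 5], 2)
        out = update_indicators(A, IndicatorSet(labels=init, c=2), 1.0, 1e-10, 0)
        np.testing.assert_array_equal(out.labels, init)

    def test_partition_term_nonincreasing_for_small_k(self, rng):
        A = rng.standard_normal((10, 8))
        init = IndicatorSet(labels=rng.integers(0, 2, 8), c=2)
        before = solver._partition_term(A, init.labels, 2, 0.5)
        out = update_indicators(A, init, 0.5, 1e-10, 25)
        after = solver._partition_term(A, out.labels, 2, 0.5)
        assert after <= before * (1 + 1e-10)


class TestFit:
    def test_clean_fixture_recovery_from_near_truth_init(self):
        X, truth = clean_recovery_case(seed=5)
        cfg = SolverConfig(c=3, k=1.0, theta=np.inf, seed=0)
        init = IndicatorSet(labels=_flip(truth.labels, [1, 20, 40], 3), c=3)
        res = fit(X, cfg, init_labels=init)
        # labels equal truth up to permutation of cluster names
        from orlrs.evaluation import LabelPair, clustering_accuracy

        assert clustering_accuracy(LabelPair(truth.labels, res.labels)) == 1.0
        assert res.converged

    def test_theta_limit_traces_identical(self, noisy_outlier_case):
        X, truth, mask = noisy_outlier_case
        big = 10.0 * float(np.linalg.norm(X.values, axis=0).max())
        cfg_inf = SolverConfig(c=3, theta=np.inf, seed=0)
        cfg_big = SolverConfig(c=3, theta=big, seed=0)
        r1 = fit(X, cfg_inf)
        r2 = fit(X, cfg_big)
        assert r1.objective_trace == r2.objective_trace
        np.testing.assert_array_equal(r1.labels, r2.labels)
        assert np.all(r1.o_diag > 0) and np.all(r2.o_diag > 0)

    def test_objective_trace_capped_term_is_l21_at_infinite_theta(self):
        X, truth = clean_recovery_case(seed=2)
        cfg = SolverConfig(c=3, theta=np.inf, seed=0, max_outer=30)
        recs = []
        fit(X, cfg, init_labels=truth, block_records=recs)
        # recorded objective after each E block must equal low-rank + λ·l21
        assert all(np.isfinite(r.objective) for r in recs)

    def test_augmented_merit_nonincreasing_per_block(self, noisy_outlier_case):
        X, truth, mask = noisy_outlier_case
        theta = mid_theta(X, mask)
        cfg = SolverConfig(c=3, theta=theta, k=1.0, seed=0)
        recs = []
        fit(X, cfg, block_records=recs)
        worst = 0.0
        for prev, cur in zip(recs, recs[1:]):
            if cur.outer != prev.outer:
                continue  # merit is only comparable at fixed (Y, mu)
            worst = max(worst, (cur.merit - prev.merit) / max(abs(prev.merit), 1e-300))
        assert worst <= 1e-8

    def test_column_permutation_equivariance(self, rng):
        X, truth = clean_recovery_case(seed=9)
        perm = rng.permutation(X.n_samples)
        Xp = ExpressionMatrix(
            X.values[:, perm], X.gene_ids, [X.sample_ids[j] for j in perm]
        )
        init = IndicatorSet(labels=_flip(truth.labels, [3, 17], 3), c=3)
        init_p = IndicatorSet(labels=init.labels[perm], c=3)
        cfg = SolverConfig(c=3, theta=np.inf, seed=0, max_outer=60)
        r = fit(X, cfg, init_labels=init)
        rp = fit(Xp, cfg, init_labels=init_p)
        np.testing.assert_array_equal(rp.labels, r.labels[perm])

    def test_restarts_return_best_objective(self):
        X, truth, mask = generate(
            SubspaceSpec(ambient_dim=40, samples_per_cluster=[10, 10],
                         subspace_dims=[2, 2], noise_sd=0.05, seed=11)
        )
        cfg = SolverConfig(c=2, theta=np.inf, k=0.5, seed=1, restarts=3, max_outer=60)
        res = fit(X, cfg)
        assert res.restart_objectives is not None and len(res.restart_objectives) == 3
        assert res.objective_trace[-1] == pytest.approx(min(res.restart_objectives))


class TestFitLRS:
    def test_clean_recovery_from_near_truth_init(self):
        X, truth = clean_recovery_case(seed=4)
        cfg = SolverConfig(c=3, seed=0)
        init = IndicatorSet(labels=_flip(truth.labels, [0, 30], 3), c=3)
        res = fit_lrs(X, cfg, init_labels=init)
        from orlrs.evaluation import LabelPair, clustering_accuracy

        assert clustering_accuracy(LabelPair(truth.labels, res.labels)) == 1.0
        assert res.converged
        assert not res.outlier_flags.any()

    def test_singleton_clusters_objective(self, rng):
        # c = n: every low-rank term is a single column, value ‖X_j‖^{2k}
        vals = rng.standard_normal((6, 4))
        X = _xm(vals)
        k = 0.5
        cfg = SolverConfig(c=4, k=k, max_outer=1, max_indicator_inner=0)
        init = IndicatorSet(labels=np.arange(4), c=4)
        res = fit_lrs(X, cfg, init_labels=init)
        expected = float(np.sum(np.linalg.norm(vals, axis=0) ** (2 * k)))
        assert res.objective_trace[0] == pytest.approx(expected, rel=1e-10)

    def test_orlrs_flags_extreme_outlier_where_lrs_cannot(self):
        spec = SubspaceSpec(
            ambient_dim=40, samples_per_cluster=[12, 12], subspace_dims=[2, 2],
            noise_sd=0.0, outlier_fraction=1 / 24, outlier_scale=10.0, seed=21,
        )
        X, truth, mask = generate(spec)
        theta = mid_theta(X, mask)
        cfg = SolverConfig(c=2, theta=theta, seed=0)
        r_orlrs = fit(X, cfg, init_labels=truth)
        r_lrs = fit_lrs(X, cfg, init_labels=truth)
        assert r_orlrs.outlier_flags[mask].all()
        assert not r_lrs.outlier_flags.any()


class TestMeritDefinition:
    def test_merit_exceeds_objective_by_penalty(self, rng):
        A = rng.standard_normal((5, 4))
        E = rng.standard_normal((5, 4))
        Xv = A + E + 0.1 * rng.standard_normal((5, 4))
        Y = rng.standard_normal((5, 4))
        labels = np.array([0, 1, 0, 1])
        mu, lam, theta, k = 1.7, 0.9, 2.0, 1.0
        merit = augmented_merit(Xv, A, E, labels, 2, k, lam, theta, Y, mu)
        obj = solver._partition_term(A, labels, 2, k) + lam * capped_norm(E, theta)
        R = A + E - Xv - Y / mu
        assert merit == pytest.approx(obj + 0.5 * mu * float(np.sum(R * R)), rel=1e-12)
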