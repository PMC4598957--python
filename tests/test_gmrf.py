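import numpy as np
import pytest

from alpgraze.gmrf import (
    build_rw1_precision,
    build_rw2d_precision,
    constrained_marginal_variances,
    prior_sd_upper_limit,
    sample_constrained,
    scale_precision,
)


class TestRW1:
    def test_n3_matrix_exact(self):
        Q = build_rw1_precision(3).Q.toarray()
        assert np.array_equal(Q, np.array([[1, -1, 0], [-1, 2, -1], [0, -1, 1]], dtype=float))

    @pytest.mark.parametrize("n", [2, 5, 11])
    def test_structure_properties(self, n):
        s = build_rw1_precision(n)
        Q = s.Q.toarray()
        assert np.allclose(Q, Q.T)
        assert np.allclose(Q.sum(axis=1), 0.0)
        assert np.linalg.matrix_rank(Q) == n - 1
        assert s.rank_deficiency == 1

    @pytest.mark.parametrize("n", [4, 7])
    def test_equals_pairwise_difference_penalty(self, n):
        # brute force: sum over adjacent pairs of (e_i - e_j)(e_i - e_j)^T
        Q = build_rw1_precision(n).Q.toarray()
        brute = np.zeros((n, n))
        for i in range(n - 1):
            d = np.zeros(n)
            d[i], d[i + 1] = 1.0, -1.0
            brute += np.outer(d, d)
        assert np.allclose(Q, brute)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            build_rw1_precision(1)


class TestRW2D:
    def test_interior_13_point_stencil(self):
        s = build_rw2d_precision(np.ones((6, 6), bool))
        row = s.Q.toarray()[3 * 6 + 3].reshape(6, 6)
        assert row[3, 3] == 20.0
        assert all(row[i, j] == -8.0 for i, j in [(2, 3), (4, 3), (3, 2), (3, 4)])
        assert all(row[i, j] == 2.0 for i, j in [(2, 2), (2, 4), (4, 2), (4, 4)])
        assert all(row[i, j] == 1.0 for i, j in [(1, 3), (5, 3), (3, 1), (3, 5)])

    def test_annihilates_planes(self):
        mask = np.ones((7, 5), bool)
        s = build_rw2d_precision(mask)
        rows, cols = np.nonzero(mask)
        for v in [np.ones(mask.sum()), cols.astype(float), rows.astype(float)]:
            assert np.allclose(s.Q @ v, 0.0, atol=1e-12)
        assert s.rank_deficiency == 3

    def test_positive_semidefinite(self):
        s = build_rw2d_precision(np.ones((6, 6), bool))
        ev = np.linalg.eigvalsh(s.Q.toarray())
        assert ev.min() >= -1e-9

    def test_disconnected_mask_rejected(self):
        mask = np.ones((8, 8), bool)
        mask[:, 4] = False
        with pytest.raises(ValueError, match="disconnected"):
            build_rw2d_precision(mask)

    def test_small_extent_rejected(self):
        with pytest.raises(ValueError):
            build_rw2d_precision(np.ones((3, 8), bool))


class TestScaling:
    def test_geometric_mean_marginal_variance_is_one(self):
        for s in (build_rw1_precision(20), build_rw2d_precision(np.ones((8, 8), bool))):
            sc = scale_precision(s)
            var = constrained_marginal_variances(sc)
            assert np.exp(np.mean(np.log(var))) == pytest.approx(1.0, abs=1e-6)

    def test_rw1_factor_matches_dense_pinv_oracle(self):
        n = 5
        s = build_rw1_precision(n)
        sc = scale_precision(s)
        # oracle: marginal variances of the constrained generalised inverse
        # via dense pseudo-inverse and explicit sum-to-zero projection
        Q = s.Q.toarray()
        Sig = np.linalg.pinv(Q)
        A = np.ones((1, n))
        SA = Sig @ A.T
        Sig_c = Sig - SA @ np.linalg.solve(A @ SA, SA.T)
        gmean = np.exp(np.mean(np.log(np.diag(Sig_c))))
        assert sc.scaling == pytest.approx(gmean, rel=1e-6)

    def test_scaling_idempotent(self):
        s = scale_precision(build_rw1_precision(12))
        s2 = scale_precision(s)
        assert s2.scaling / s.scaling == pytest.approx(1.0, abs=1e-6)

    def test_constrained_sample_respects_constraints(self):
        s = scale_precision(build_rw2d_precision(np.ones((6, 6), bool)))
        rng = np.random.default_rng(0)
        x = sample_constrained(s, tau=2.0, rng=rng)
        assert np.allclose(s.constraints @ x, 0.0, atol=1e-8)


class TestPriorUpperLimit:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (1.0, 1.00e-05, 0.1),
            (1.0, 0.00025, 0.5),
            (1.0, 0.001, 1.0),
            (1.0, 0.0255, 5.0),
            (5.0, 0.185, 0.5),
            (12.0, 1.01, 0.5),
            (20.0, 2.24, 0.5),
        ],
    )
    def test_prior_grid_values(self, a, b, expected):
        assert prior_sd_upper_limit(a, b) == pytest.approx(expected, rel=0.02)

    def test_shape_one_closed_form(self):
        b = 3.7e-4
        closed = np.sqrt(b / (-np.log(1 - 0.001)))
        assert prior_sd_upper_limit(1.0, b) == pytest.approx(closed, rel=1e-9)

    def test_general_shape_matches_quantile_root(self):
        from scipy.stats import gamma

        a, b = 2.7, 0.8
        U = prior_sd_upper_limit(a, b)
        # P(tau < U^-2) should equal the tail probability
        assert gamma.cdf(U**-2, a, scale=1 / b) == pytest.approx(0.001, rel=1e-9)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            prior_sd_upper_limit(0.0, 1.0)
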