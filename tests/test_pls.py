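"""PLS-correlation engine: SVD, scores, permutation, bootstrap, seed PLS."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scnpls.exceptions import DataError, NumericalError
from scnpls.pls import (
    PLSCorrelation,
    bootstrap_stability,
    cross_block,
    derive_scn,
    fit_pls,
    latent_correlation,
)

from conftest import make_gm


def eig_oracle(C):
    """Independent decomposition: right/left saliences and singular values
    from the eigendecomposition of C'C (C the q x p cross-block)."""
    evals, V = np.linalg.eigh(C.T @ C)
    order = np.argsort(evals)[::-1][: min(C.shape)]
    s = np.sqrt(np.clip(evals[order], 0.0, None))
    V = V[:, order]
    return V, s


def assert_matches_oracle(res, C, atol=1e-8):
    """Singular values always; salience vectors only for LVs that are
    nonzero and well separated (vectors of degenerate or zero singular
    values are arbitrary up to rotation)."""
    V, s = eig_oracle(C)
    np.testing.assert_allclose(res.singular_values, s, atol=atol)
    padded = np.r_[np.inf, s, -np.inf]
    for l in range(len(s)):
        if s[l] < 1e-6 * max(1.0, s[0]):
            continue
        if min(padded[l] - s[l], s[l] - padded[l + 2]) < 1e-6:
            continue
        got, want = res.left_saliences[:, l], V[:, l]
        sign = np.sign(got @ want) or 1.0
        np.testing.assert_allclose(sign * got, want, atol=atol)


class TestCrossBlock:
    def test_standardized_blocks_give_correlations(self, rng):
        X = rng.standard_normal((30, 4))
        Y = rng.standard_normal((30, 3))
        R = cross_block(X, Y, scaling="correlation")
        expect = np.array(
            [[np.corrcoef(Y[:, i], X[:, j])[0, 1] for j in range(4)]
             for i in range(3)]
        )
        np.testing.assert_allclose(R, expect, atol=1e-12)

    def test_single_seed_column_is_covariance_vector(self, rng):
        X = rng.standard_normal((20, 5))
        y = rng.standard_normal(20)
        R = cross_block(X, y, scaling="covariance")
        assert R.shape == (1, 5)
        expect = [np.cov(y, X[:, j])[0, 1] for j in range(5)]
        np.testing.assert_allclose(R[0], expect, atol=1e-12)

    def test_constant_column_under_correlation_raises(self, rng):
        X = rng.standard_normal((10, 3))
        Y = np.c_[rng.standard_normal(10), np.ones(10)]
        with pytest.raises(DataError, match="1"):
            cross_block(X, Y, scaling="correlation")


class TestFit:
    def test_diagonal_cross_block_variance_explained(self):
        # blocks built so the cross-block is diag(2, 1)
        n = 40
        t = np.arange(n, dtype=float)
        a = (t - t.mean()) / t.std(ddof=1)
        b = np.cos(np.linspace(0, 7 * np.pi, n))
        b = (b - b.mean()) / b.std(ddof=1)
        # orthogonalize b against a
        b -= (a @ b) / (a @ a) * a
        b /= b.std(ddof=1)
        X = np.c_[2 * a, b]
        Y = np.c_[a, b]
        res = fit_pls(X, Y, scaling="covariance")
        np.testing.assert_allclose(res.singular_values, [2.0, 1.0], atol=1e-8)
        np.testing.assert_allclose(res.variance_explained, [0.8, 0.2], atol=1e-8)

    def test_identical_single_columns_correlate_perfectly(self, rng):
        x = rng.standard_normal(25)
        res = fit_pls(x, x)
        r, _ = latent_correlation(res, 0)
        assert r == pytest.approx(1.0)

    def test_rank1_recovery(self, rng):
        u = rng.standard_normal(6)
        u /= np.linalg.norm(u)
        v = rng.standard_normal(10)
        v /= np.linalg.norm(v)
        C = 3.0 * np.outer(u, v)
        # build blocks with this exact cross-block via shared latent
        z = rng.standard_normal(200)
        z = (z - z.mean()) / z.std(ddof=1)
        X = 3.0 * np.outer(z, v)
        Y = np.outer(z, u)
        res = fit_pls(X, Y)
        assert res.singular_values[1] == pytest.approx(0.0, abs=1e-10)
        for got, want in ((res.left_saliences[:, 0], v),
                          (res.right_saliences[:, 0], u)):
            sign = np.sign(got @ want)
            np.testing.assert_allclose(sign * got, want, atol=1e-8)

    def test_matches_eigendecomposition_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(5, 31))
            p = int(rng.integers(2, 13))
            q = int(rng.integers(1, 7))
            X = rng.standard_normal((n, p))
            Y = rng.standard_normal((n, q))
            assert_matches_oracle(fit_pls(X, Y), cross_block(X, Y))

    def test_salience_columns_unit_norm_and_ve_sums_to_one(self, rng):
        X = rng.standard_normal((25, 8))
        Y = rng.standard_normal((25, 4))
        res = fit_pls(X, Y)
        np.testing.assert_allclose(
            np.linalg.norm(res.left_saliences, axis=0), 1.0, atol=1e-12
        )
        assert abs(res.variance_explained.sum() - 1.0) < 1e-12
        assert np.all(np.diff(res.singular_values) <= 1e-12)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(-50, 50), st.floats(-50, 50))
    def test_column_shift_invariance(self, seed, cx, cy):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((15, 4))
        Y = rng.standard_normal((15, 3))
        base = fit_pls(X, Y)
        Xs = X.copy()
        Xs[:, 0] += cx
        Ys = Y.copy()
        Ys[:, 1] += cy
        shifted = fit_pls(Xs, Ys)
        np.testing.assert_allclose(
            shifted.singular_values, base.singular_values, atol=1e-10
        )
        np.testing.assert_allclose(
            shifted.left_saliences, base.left_saliences, atol=1e-10
        )


class TestPermutation:
    def test_add_one_lower_bound_with_dominant_signal(self, rng):
        z = rng.standard_normal(60)
        X = np.outer(z, rng.standard_normal(5)) + 0.01 * rng.standard_normal((60, 5))
        Y = z[:, None] + 0.01 * rng.standard_normal((60, 1))
        res = fit_pls(X, Y, n_perm=499, rng_seed=0)
        assert res.perm_p[0] == pytest.approx(1.0 / 500.0)

    def test_p_bounds(self, rng):
        X = rng.standard_normal((20, 4))
        Y = rng.standard_normal((20, 2))
        res = fit_pls(X, Y, n_perm=100, rng_seed=1)
        assert np.all(res.perm_p >= 1.0 / 101.0)
        assert np.all(res.perm_p <= 1.0)

    def test_too_few_permutations_rejected(self, rng):
        with pytest.raises(DataError):
            fit_pls(rng.standard_normal((20, 3)),
                    rng.standard_normal((20, 2)), n_perm=50)

    def test_null_p_roughly_uniform(self, rng):
        # moderate Monte-Carlo: independent blocks, p1 should not concentrate
        hits = 0
        sims = 40
        for i in range(sims):
            r = np.random.default_rng(1000 + i)
            X = r.standard_normal((40, 20))
            Y = r.standard_normal((40, 5))
            res = fit_pls(X, Y, n_perm=100, rng_seed=i)
            hits += res.perm_p[0] <= 0.05
        # binomial(40, 0.05): observing more than 7 rejections is <1e-4
        assert hits <= 7


class TestBootstrap:
    def test_planted_signal_has_larger_bsr(self, rng):
        z = rng.standard_normal(60)
        X = np.c_[
            np.outer(z, np.ones(10)) + 0.5 * rng.standard_normal((60, 10)),
            rng.standard_normal((60, 90)),
        ]
        y = z + 0.3 * rng.standard_normal(60)
        res = bootstrap_stability(X, y[:, None], n_boot=100, rng_seed=0)
        bsr = np.abs(res.left_bootstrap_ratios[:, 0])
        assert bsr[:10].mean() > bsr[10:].mean()

    def test_degenerate_se_gives_inf_sentinel(self):
        # two perfectly collinear columns: every resample reproduces the
        # same right salience exactly
        n = 20
        z = np.linspace(-1, 1, n)
        X = z[:, None]
        Y = z[:, None]
        res = bootstrap_stability(X, Y, n_boot=100, rng_seed=0)
        assert np.isinf(res.right_bootstrap_ratios).all()
        assert res.n_infinite_bsr >= 1

    def test_loading_ci_collapses_for_identical_feature(self, rng):
        z = rng.standard_normal(40)
        X = z[:, None]  # single feature == opposite-block score direction
        Y = z[:, None]
        res = bootstrap_stability(X, Y, n_boot=100, rng_seed=0)
        lo, hi = res.left_loading_ci[0, 0]
        assert lo == pytest.approx(1.0) and hi == pytest.approx(1.0)

    def test_procrustes_alignment_runs(self, rng):
        X = rng.standard_normal((30, 6))
        Y = rng.standard_normal((30, 4))
        res = fit_pls(X, Y, n_boot=100, rng_seed=0, align="procrustes")
        assert res.left_bootstrap_ratios.shape == (6, 4)


class TestDeterminism:
    def test_identical_results_under_same_seed(self, rng):
        X = rng.standard_normal((30, 10))
        Y = rng.standard_normal((30, 3))
        a = fit_pls(X, Y, n_perm=100, n_boot=100, rng_seed=99)
        b = fit_pls(X, Y, n_perm=100, n_boot=100, rng_seed=99)
        for f in ("singular_values", "left_saliences", "perm_p",
                  "left_bootstrap_ratios", "left_loading_ci"):
            assert np.array_equal(getattr(a, f), getattr(b, f)), f


class TestLatentCorrelation:
    def test_undefined_for_zero_variance(self):
        z = np.linspace(0, 1, 30)
        res = fit_pls(z[:, None], z[:, None])
        res.left_scores[:, 0] = 0.0
        with pytest.raises(NumericalError):
            latent_correlation(res, 0)

    def test_short_scores_rejected(self):
        with pytest.raises(DataError):
            fit_pls(np.ones((2, 1)), np.ones((2, 1)))

    def test_independent_blocks_small_r_at_large_n(self):
        small = 0
        for i in range(10):
            r = np.random.default_rng(i)
            x = r.standard_normal(1000)
            y = r.standard_normal(1000)
            res = fit_pls(x[:, None], y[:, None])
            rr, _ = latent_correlation(res, 0)
            small += abs(rr) < 0.1
        assert small >= 9


class TestSeedPLS:
    def test_single_seed_salience_is_normalized_covariance(self, rng):
        vols = 0.5 + 0.05 * rng.standard_normal((30, 8, 8, 8))
        gm = make_gm(np.clip(vols, 0, 1), threshold=0.0)
        y = gm.data[:, 13].copy()
        res = derive_scn(gm, y[:, None])
        cov = np.array([np.cov(y, gm.data[:, j])[0, 1]
                        for j in range(gm.n_voxels)])
        expect = cov / np.linalg.norm(cov)
        sign = np.sign(res.left_saliences[:, 0] @ expect)
        np.testing.assert_allclose(sign * res.left_saliences[:, 0], expect,
                                   atol=1e-10)
        # the voxel identical to the seed attains the max salience magnitude
        assert np.argmax(np.abs(res.left_saliences[:, 0])) == 13

    def test_duplicated_seed_columns_rank_deficient(self, rng):
        vols = 0.5 + 0.05 * rng.standard_normal((25, 6, 6, 6))
        gm = make_gm(np.clip(vols, 0, 1), threshold=0.0)
        y = gm.data[:, 3]
        res = derive_scn(gm, np.c_[y, y])
        assert res.singular_values[1] == pytest.approx(0.0, abs=1e-10)

    def test_rejects_wide_seed_block(self, rng):
        vols = 0.5 + 0.05 * rng.standard_normal((10, 4, 4, 4))
        gm = make_gm(np.clip(vols, 0, 1), threshold=0.0)
        with pytest.raises(DataError):
            derive_scn(gm, rng.standard_normal((10, 3)))
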