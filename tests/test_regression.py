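"""Unit tests for the conjugate piecewise linear regression core."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nhdbn.regression import (
    DegenerateInputError,
    ExpressionMatrix,
    NoiseHyper,
    PriorMoments,
    RegressionTask,
    SegmentData,
    Segmentation,
    build_regression_task,
    cov_matrix_C,
    delta_squared,
    log_det_C,
    log_marginal_likelihood,
    posterior_mean_weights,
    sample_sigma2,
    sample_weights,
    segmentize,
)

from conftest import random_segments


class TestBuildRegressionTask:
    def test_yeast_sized_matrix(self):
        # 16 + 21 merged measurements: 37 columns give T = 36 observations
        g = np.random.default_rng(0)
        data = ExpressionMatrix(
            values=g.standard_normal((5, 37)),
            node_names=tuple("abcde"),
        )
        task = build_regression_task(data, 0)
        assert task.n_obs == 36
        assert task.n_candidates == 4

    def test_lag_alignment(self, small_matrix):
        task = build_regression_task(small_matrix, 1)
        np.testing.assert_array_equal(task.response, small_matrix.values[1, 1:])
        np.testing.assert_array_equal(
            task.covariates[:, 0], small_matrix.values[0, :-1]
        )
        np.testing.assert_array_equal(
            task.covariates[:, 1], small_matrix.values[2, :-1]
        )
        assert task.covariate_names == ("A", "C", "D")

    def test_boundary_masks_one_lag_pair(self):
        g = np.random.default_rng(0)
        data = ExpressionMatrix(
            values=g.standard_normal((3, 10)),
            node_names=("a", "b", "c"),
            series_boundaries=(5,),
        )
        task = build_regression_task(data, 0)
        assert task.n_obs == 9
        assert task.valid_mask.sum() == 8
        assert not task.valid_mask[4]

    def test_constant_signal(self):
        data = ExpressionMatrix(
            values=np.array([[2.0] * 6, [3.0] * 6]), node_names=("a", "b")
        )
        task = build_regression_task(data, 0)
        assert np.ptp(task.response) == 0.0
        assert np.ptp(task.covariates) == 0.0

    def test_bad_inputs(self):
        with pytest.raises(ValueError, match="non-finite"):
            ExpressionMatrix(
                values=np.array([[1.0, np.nan, 2.0]]), node_names=("a",)
            )
        g = np.random.default_rng(0)
        data = ExpressionMatrix(
            values=g.standard_normal((2, 3)),
            node_names=("a", "b"),
            series_boundaries=(1, 2),
        )
        with pytest.raises(DegenerateInputError):
            build_regression_task(data, 0)
        with pytest.raises(IndexError):
            build_regression_task(data, 5)


class TestSegmentize:
    def _task(self, T, n=2, seed=0):
        g = np.random.default_rng(seed)
        return RegressionTask(
            target_index=0,
            response=g.standard_normal(T),
            covariates=g.standard_normal((T, n)),
            valid_mask=np.ones(T, dtype=bool),
            covariate_names=tuple(f"X{j}" for j in range(n)),
        )

    def test_four_equal_segments(self):
        segs = segmentize(self._task(40), Segmentation((10, 20, 30)), (0,))
        assert len(segs) == 4
        assert all(s.n_obs == 10 for s in segs)

    def test_no_changepoints_single_segment(self):
        segs = segmentize(self._task(12), Segmentation(()), ())
        assert len(segs) == 1 and segs[0].n_obs == 12
        assert segs[0].X.shape == (12, 1)

    def test_small_exhaustive(self):
        segs = segmentize(self._task(6), Segmentation((2, 4)), (1,))
        assert [s.n_obs for s in segs] == [2, 2, 2]
        assert all(s.X.shape == (2, 2) for s in segs)

    def test_segments_partition_observations(self):
        task = self._task(17)
        segs = segmentize(task, Segmentation((5, 11)), (0, 1))
        ys = np.concatenate([s.y for s in segs])
        np.testing.assert_array_equal(np.sort(ys), np.sort(task.response))

    def test_min_seg_len_violation(self):
        with pytest.raises(DegenerateInputError, match="min_seg_len"):
            segmentize(self._task(10), Segmentation((1,)), ())
        # allowed when relaxed
        segs = segmentize(self._task(10), Segmentation((1,)), (), min_seg_len=1)
        assert segs[0].n_obs == 1


class TestCovMatrix:
    def test_zero_prior_variance_gives_identity(self):
        seg = SegmentData(y=np.zeros(3), X=np.ones((3, 1)))
        C = cov_matrix_C(seg, PriorMoments(mu=np.zeros(1), Sigma=np.zeros((1, 1))))
        np.testing.assert_array_equal(C, np.eye(3))

    def test_scalar_cases(self):
        seg = SegmentData(y=np.zeros(1), X=np.array([[1.0]]))
        C = cov_matrix_C(seg, PriorMoments(mu=np.zeros(1), Sigma=np.eye(1)))
        assert C == pytest.approx(np.array([[2.0]]))
        seg2 = SegmentData(y=np.zeros(1), X=np.array([[1.0, 2.0]]))
        C2 = cov_matrix_C(seg2, PriorMoments(mu=np.zeros(2), Sigma=np.eye(2)))
        assert C2 == pytest.approx(np.array([[6.0]]))

    def test_dimension_mismatch(self):
        seg = SegmentData(y=np.zeros(2), X=np.ones((2, 1)))
        with pytest.raises(ValueError):
            cov_matrix_C(seg, PriorMoments(mu=np.zeros(2), Sigma=np.eye(2)))


class TestDeltaSquared:
    def test_zero_residual(self, rng):
        X = np.column_stack([np.ones(4), rng.standard_normal(4)])
        mu = np.array([0.3, -1.2])
        seg = SegmentData(y=X @ mu, X=X)
        mom = PriorMoments(mu=mu, Sigma=np.eye(2))
        assert delta_squared([seg], [mom]) == pytest.approx(0.0, abs=1e-12)

    def test_scalar_value(self):
        seg = SegmentData(y=np.array([1.0]), X=np.array([[1.0]]))
        mom = PriorMoments(mu=np.zeros(1), Sigma=np.eye(1))
        assert delta_squared([seg], [mom]) == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_dense_inverse_oracle(self, seed):
        g = np.random.default_rng(seed)
        segments, moments = random_segments(g, H=3, T_h=5, k=2, coupled_mu=True)
        brute = sum(
            (s.y - s.X @ m.mu)
            @ np.linalg.inv(cov_matrix_C(s, m))
            @ (s.y - s.X @ m.mu)
            for s, m in zip(segments, moments)
        )
        assert delta_squared(segments, moments) == pytest.approx(brute, rel=1e-10)

    @given(perm_seed=st.integers(0, 10_000))
    def test_invariant_under_observation_reordering(self, perm_seed):
        g = np.random.default_rng(99)
        segments, moments = random_segments(g, H=2, T_h=6, k=1, coupled_mu=True)
        p = np.random.default_rng(perm_seed).permutation(6)
        shuffled = [SegmentData(y=s.y[p], X=s.X[p]) for s in segments]
        assert delta_squared(shuffled, moments) == pytest.approx(
            delta_squared(segments, moments), rel=1e-10
        )


class TestLogMarginal:
    @pytest.mark.parametrize("seed", [3, 4])
    def test_det_lemma_matches_dense_determinant(self, seed):
        g = np.random.default_rng(seed)
        segments, moments = random_segments(g, H=2, T_h=7, k=2)
        for s, m in zip(segments, moments):
            direct = np.linalg.slogdet(cov_matrix_C(s, m))[1]
            assert log_det_C(s, m) == pytest.approx(direct, rel=1e-10)

    def test_segment_order_invariance(self, rng):
        segments, moments = random_segments(rng, H=3, T_h=4, k=1, coupled_mu=True)
        noise = NoiseHyper()
        a = log_marginal_likelihood(segments, moments, noise)
        b = log_marginal_likelihood(segments[::-1], moments[::-1], noise)
        assert a == pytest.approx(b, rel=1e-12)

    def test_vanishing_prior_variance_limit(self, rng):
        # Sigma -> 0: weights pinned at mu, sigma2 still marginalised
        from scipy.special import gammaln

        segments, moments = random_segments(rng, H=2, T_h=5, k=1, coupled_mu=True)
        noise = NoiseHyper(0.01, 0.02)
        tiny = [
            PriorMoments(mu=m.mu, Sigma=1e-14 * np.eye(m.mu.size)) for m in moments
        ]
        got = log_marginal_likelihood(segments, tiny, noise)
        T = sum(s.n_obs for s in segments)
        rss = sum(float((s.y - s.X @ m.mu) @ (s.y - s.X @ m.mu))
                  for s, m in zip(segments, moments))
        a, b = noise.alpha_sigma, noise.beta_sigma
        closed = (
            gammaln(T / 2 + a) - gammaln(a) - T / 2 * np.log(np.pi)
            + a * np.log(2 * b) - (T / 2 + a) * np.log(2 * b + rss)
        )
        assert got == pytest.approx(closed, rel=1e-6)

    def test_rejects_bad_hyperparameters(self):
        with pytest.raises(ValueError):
            NoiseHyper(-1.0, 1.0)


class TestSamplers:
    def test_sigma2_moments(self, rng):
        g = np.random.default_rng(5)
        segments, moments = random_segments(g, H=2, T_h=20, k=1)
        noise = NoiseHyper(0.005, 0.005)
        T = sum(s.n_obs for s in segments)
        shape = noise.alpha_sigma + T / 2  # = 20.005 for T = 40
        assert shape == pytest.approx(20.005)
        rate = noise.beta_sigma + delta_squared(segments, moments) / 2
        draws = np.array(
            [1.0 / sample_sigma2(segments, moments, noise, rng) for _ in range(20_000)]
        )
        se = np.sqrt(shape) / rate / np.sqrt(draws.size)
        assert abs(draws.mean() - shape / rate) < 3 * se

    def test_weight_limits(self, rng):
        X = np.column_stack([np.ones(6), rng.standard_normal(6)])
        y = rng.standard_normal(6)
        seg = SegmentData(y=y, X=X)
        mu = np.array([1.5, -0.5])
        prior_dom = PriorMoments(mu=mu, Sigma=1e-12 * np.eye(2))
        np.testing.assert_allclose(
            posterior_mean_weights(seg, prior_dom), mu, atol=1e-6
        )
        flat = PriorMoments(mu=np.zeros(2), Sigma=1e12 * np.eye(2))
        lstsq = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(
            posterior_mean_weights(seg, flat), lstsq, atol=1e-6
        )

    def test_scalar_conjugate_case(self, rng):
        seg = SegmentData(y=np.array([1.0]), X=np.array([[1.0]]))
        mom = PriorMoments(mu=np.zeros(1), Sigma=np.eye(1))
        draws = np.array(
            [sample_weights(seg, 1.0, mom, rng)[0] for _ in range(20_000)]
        )
        assert draws.mean() == pytest.approx(0.5, abs=3 * np.sqrt(0.5 / draws.size))
        assert draws.var() == pytest.approx(0.5, rel=0.05)

    def test_posterior_mean_matches_sampler(self, rng):
        g = np.random.default_rng(6)
        segments, moments = random_segments(g, H=1, T_h=8, k=1, coupled_mu=True)
        seg, mom = segments[0], moments[0]
        mean = posterior_mean_weights(seg, mom)
        draws = np.array(
            [sample_weights(seg, 0.7, mom, rng) for _ in range(20_000)]
        )
        se = draws.std(axis=0, ddof=1) / np.sqrt(draws.shape[0])
        assert np.all(np.abs(draws.mean(axis=0) - mean) < 4 * se)
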