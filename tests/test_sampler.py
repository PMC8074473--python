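"""Unit tests for the reversible-jump sampler and its jit kernels."""

import math

import numpy as np
import pytest

import nhdbn
from nhdbn import _kernels
from nhdbn.models import CouplingHyper, CouplingState, prior_moments
from nhdbn.regression import (
    NoiseHyper,
    RegressionTask,
    Segmentation,
    log_marginal_likelihood,
    segmentize,
)
from nhdbn.sampler import ChainConfig, TargetSampler, fixed_changepoints, run_chain


def make_task(T=24, n=3, seed=0):
    g = np.random.default_rng(seed)
    return RegressionTask(
        target_index=0,
        response=g.standard_normal(T),
        covariates=g.standard_normal((T, n)),
        valid_mask=np.ones(T, dtype=bool),
        covariate_names=tuple(f"X{j}" for j in range(n)),
        target_name="Y",
    )


class _ScriptedRng:
    """Returns a scripted sequence for integers(); random() stays real."""

    def __init__(self, ints):
        self.ints = list(ints)
        self._g = np.random.default_rng(0)

    def integers(self, *_args, **_kw):
        return self.ints.pop(0)

    def random(self, *a, **k):
        return self._g.random(*a, **k)


class TestKernelAgainstReference:
    """The jit fast path must agree with the numpy reference exactly."""

    @pytest.mark.parametrize("variant,state", [
        ("M1", CouplingState(lambda_u=0.7)),
        ("M2", CouplingState(lambda_u=0.7, lambda_c=2.3)),
        ("M3", CouplingState(lambda_u=0.7, lambda_c=2.3, delta=(1, 0))),
        ("M4", CouplingState(lambda_u=0.7, lambda_seg=(0.4, 5.0))),
    ])
    @pytest.mark.parametrize("parents", [(), (1,), (0, 2)])
    def test_log_marginal_agreement(self, variant, state, parents):
        task = make_task(T=21, seed=8)
        seg = Segmentation((7, 14))
        segs = segmentize(task, seg, parents)
        ref = log_marginal_likelihood(
            segs, prior_moments(variant, state, segs), NoiseHyper()
        )
        sampler = TargetSampler(
            task, variant, config=ChainConfig(iterations=10, fixed_changepoints=seg)
        )
        sampler.set_state(
            parents=parents,
            lambda_u=state.lambda_u,
            lambda_c=state.lambda_c,
            delta=state.delta,
            lambda_seg=state.lambda_seg,
        )
        assert sampler.log_marginal == pytest.approx(ref, rel=1e-11, abs=1e-9)

    def test_delta_update_probability_matches_reference(self):
        from nhdbn.models import log_delta_prior, sample_delta

        task = make_task(T=16, seed=3)
        seg = Segmentation((8,))
        segs = segmentize(task, seg, (0,))
        hyper = CouplingHyper()
        lp = {}
        for d in (0, 1):
            s = CouplingState(lambda_u=0.9, lambda_c=1.4, delta=(d,))
            lp[d] = log_marginal_likelihood(
                segs, prior_moments("M3", s, segs), hyper.noise
            ) + log_delta_prior((d,), hyper.a, hyper.b)
        exact_p1 = 1.0 / (1.0 + np.exp(lp[0] - lp[1]))

        sampler = TargetSampler(
            task, "M3", hyper, ChainConfig(iterations=10, fixed_changepoints=seg)
        )
        sampler.set_state(parents=(0,), lambda_u=0.9, lambda_c=1.4, delta=(0,))
        couple = np.zeros(2, dtype=np.int8)
        hits = 0
        n = 4000
        g = np.random.default_rng(11)
        for _ in range(n):
            couple[1] = 0
            _kernels.update_deltas(
                sampler.yv, sampler._cur_design, sampler._cur_starts,
                sampler._cur_ends, couple, 0.9, 1.4, hyper.a, hyper.b,
                hyper.noise.alpha_sigma, hyper.noise.beta_sigma, g.random(1),
            )
            hits += int(couple[1])
        se = math.sqrt(exact_p1 * (1 - exact_p1) / n)
        assert hits / n == pytest.approx(exact_p1, abs=4 * max(se, 1e-3))


class TestHastingsRatios:
    def test_addition_ratio(self):
        task = make_task(T=24, n=10, seed=1)
        sampler = TargetSampler(task, "M1", config=ChainConfig(iterations=10))
        sampler.set_state(parents=(4,))
        new, log_hr = sampler._parent_proposal(_ScriptedRng([0, 0]))
        assert len(new) == 2
        assert log_hr == pytest.approx(math.log((10 - 1) / 2))  # = log 4.5

    def test_exchange_ratio_is_one(self):
        task = make_task(T=24, n=10, seed=1)
        sampler = TargetSampler(task, "M1", config=ChainConfig(iterations=10))
        sampler.set_state(parents=(4,))
        new, log_hr = sampler._parent_proposal(_ScriptedRng([2, 0, 0]))
        assert len(new) == 1 and new != (4,)
        assert log_hr == 0.0

    def test_unavailable_moves_rejected(self):
        task = make_task(T=24, n=2, seed=1)
        sampler = TargetSampler(task, "M1", config=ChainConfig(iterations=10))
        # removal from the empty set
        assert sampler._parent_proposal(_ScriptedRng([1])) is None
        # death with no changepoint
        assert sampler.changepoint_move(_ScriptedRng([1])) is False
        # fan-in violation always rejected
        sampler3 = TargetSampler(
            make_task(T=24, n=6), "M1",
            CouplingHyper(fan_in=3), ChainConfig(iterations=10),
        )
        sampler3.set_state(parents=(0, 1, 2))
        before = sampler3.parents
        assert sampler3.parent_move(_ScriptedRng([0, 0])) is False
        assert sampler3.parents == before

    def test_parent_detailed_balance_negation(self):
        task = make_task(T=24, n=5, seed=2)
        sampler = TargetSampler(task, "M2", config=ChainConfig(iterations=10))
        sampler.set_state(parents=(1,), changepoints=(12,),
                          lambda_u=0.6, lambda_c=1.7)
        hr_add = math.log((5 - 1) / 2)
        fwd, _ = sampler.parent_log_accept((1, 3), hr_add)
        sampler.set_state(parents=(1, 3))
        hr_rem = math.log(2 / (5 - 1))
        rev, _ = sampler.parent_log_accept((1,), hr_rem)
        assert fwd == pytest.approx(-rev, rel=1e-10)

    def test_changepoint_detailed_balance_negation(self):
        T = 40  # 41 time points yield 40 regression observations
        task = make_task(T=T, n=3, seed=4)
        sampler = TargetSampler(task, "M2", config=ChainConfig(iterations=10))
        sampler.set_state(parents=(0,), changepoints=(10, 20, 30),
                          lambda_u=0.6, lambda_c=1.7)
        hr_birth = math.log((T - 1 - 3) / 4)  # = log 9 at T=41, |tau|=3
        assert hr_birth == pytest.approx(math.log(9))
        fwd = sampler.changepoint_log_accept((5, 10, 20, 30), hr_birth)
        sampler.set_state(changepoints=(5, 10, 20, 30))
        hr_death = math.log(4 / (T - 1 - 3))
        rev = sampler.changepoint_log_accept((10, 20, 30), hr_death)
        assert fwd == pytest.approx(-rev, rel=1e-10)


class TestChainDriver:
    def test_retained_sample_arithmetic(self):
        task = make_task()
        res = run_chain(task, "M1", config=ChainConfig(iterations=100), seed=0)
        assert len(res.samples) == 5
        assert ChainConfig(iterations=100_000).n_retained == 5000

    def test_same_seed_bit_identical(self):
        task = make_task(T=20, n=2, seed=5)
        cfg = ChainConfig(iterations=400)
        a = run_chain(task, "M3", config=cfg, seed=99)
        b = run_chain(task, "M3", config=cfg, seed=99)
        assert a.samples == b.samples
        c = run_chain(task, "M3", config=cfg, seed=100)
        assert a.samples != c.samples

    def test_m1_sweep_touches_only_lambda_u(self, rng):
        task = make_task()
        sampler = TargetSampler(
            task, "M1",
            config=ChainConfig(iterations=10, fixed_changepoints=Segmentation((12,))),
        )
        lam_c0, delta0 = sampler.lam_c, sampler.delta.copy()
        lam_u0 = sampler.lam_u
        sampler.gibbs_sweep(rng)
        assert sampler.lam_u != lam_u0
        assert sampler.lam_c == lam_c0
        np.testing.assert_array_equal(sampler.delta, delta0)

    def test_m3_single_segment_has_no_deltas(self, rng):
        task = make_task()
        sampler = TargetSampler(
            task, "M3",
            config=ChainConfig(iterations=10, fixed_changepoints=Segmentation(())),
        )
        sampler.gibbs_sweep(rng)
        assert sampler.delta.size == 0

    def test_sample_structural_validity(self):
        ds = nhdbn.generate_study2(m=4, seed=0)
        task = nhdbn.build_regression_task(ds.data, 2)
        res = run_chain(task, "M3", config=ChainConfig(iterations=600), seed=3)
        for s in res.samples:
            assert len(s.parents) <= 3
            assert all(0 <= p < 4 for p in s.parents)
            assert list(s.changepoints) == sorted(set(s.changepoints))
            assert all(1 <= c < task.n_obs for c in s.changepoints)
            assert s.lambda_u > 0 and s.lambda_c > 0
            assert len(s.delta) == len(s.changepoints)
            assert np.isfinite(s.log_marginal)


class TestCouplingRecovery:
    """With tau fixed, M3 must infer coupling from coefficient (dis)agreement."""

    def _two_segment_task(self, flip, seed=0):
        g = np.random.default_rng(seed)
        T, n = 24, 2
        w = np.array([0.4, 0.9, -0.3])
        X = g.standard_normal((T, n))
        y = np.empty(T)
        for t in range(T):
            wt = -w if (flip and t >= T // 2) else w
            y[t] = wt[0] + X[t] @ wt[1:] + 0.05 * g.standard_normal()
        return RegressionTask(
            target_index=0, response=y, covariates=X,
            valid_mask=np.ones(T, dtype=bool),
            covariate_names=("X1", "X2"), target_name="Y",
        )

    @pytest.mark.parametrize("flip,expect_coupled", [(False, True), (True, False)])
    def test_delta_posterior_direction(self, flip, expect_coupled):
        task = self._two_segment_task(flip)
        cfg = ChainConfig(iterations=3000, fixed_changepoints=Segmentation((12,)))
        res = run_chain(task, "M3", config=cfg, seed=7)
        p_coupled = np.mean([s.delta[0] for s in res.samples])
        assert (p_coupled > 0.5) == expect_coupled


class TestFixedChangepoints:
    def test_single_boundary(self):
        assert fixed_changepoints(1, 35, 15).changepoints == (15,)

    def test_midpoint_of_longest_segment(self):
        assert fixed_changepoints(2, 35, 15).changepoints == (15, 25)

    def test_k_changepoints_give_k_plus_1_segments(self):
        for K in range(1, 6):
            seg = fixed_changepoints(K, 36, 16)
            assert seg.n_segments == K + 1

    def test_infeasible(self):
        with pytest.raises(ValueError):
            fixed_changepoints(10, 8, 4)
        with pytest.raises(ValueError):
            fixed_changepoints(1, 10, 12)
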