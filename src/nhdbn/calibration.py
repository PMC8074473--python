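"""Simulation-based calibration of the sampler (Geweke-style).

The successive-conditional simulator alternates (i) drawing a fresh
response vector from the model given the current state (pi, tau, theta)
and (ii) applying one full MCMC transition targeting the posterior given
that response.  If the transition kernel is correct, the marginal
distribution of the state stays exactly at the prior, so long-run
averages of prior-known quantities (E[1/lambda_u], E[1/lambda_c], E|pi|,
E[H], ...) must match their prior expectations up to Monte Carlo error.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from .models import CouplingHyper
from .regression import RegressionTask
from .sampler import ChainConfig, TargetSampler


def make_fixed_design_task(T: int, n: int, rng: np.random.Generator) -> RegressionTask:
    """A regression task with a fixed standard-normal covariate design."""
    return RegressionTask(
        target_index=0,
        response=np.zeros(T),
        covariates=rng.standard_normal((T, n)),
        valid_mask=np.ones(T, dtype=bool),
        covariate_names=tuple(f"X{j + 1}" for j in range(n)),
        target_name="Y",
    )


def _allowed_parent_sets(n: int, fan_in: int):
    sets = []
    for k in range(min(fan_in, n) + 1):
        sets.extend(combinations(range(n), k))
    return sets


def prior_sample_state(sampler: TargetSampler, rng: np.random.Generator) -> None:
    """Draw (pi, tau, theta) from the model prior and inject it."""
    hyp = sampler.hyper
    sets = _allowed_parent_sets(sampler.n, hyp.fan_in)
    parents = sets[int(rng.integers(len(sets)))]
    # geometric inter-changepoint distances == iid Bernoulli(p) positions
    cps = tuple(
        t for t in range(1, sampler.T) if rng.random() < hyp.p_cp
    )
    H = len(cps) + 1
    lam_u = 1.0 / rng.gamma(hyp.alpha_u, 1.0 / hyp.beta_u)
    lam_c = 1.0 / rng.gamma(hyp.alpha_c, 1.0 / hyp.beta_c)
    delta = None
    lam_seg = None
    if sampler.variant == "M3":
        p = rng.beta(hyp.a, hyp.b)
        delta = (rng.random(H - 1) < p).astype(np.int8)
    if sampler.variant == "M4":
        lam_seg = 1.0 / rng.gamma(hyp.alpha_c, 1.0 / hyp.beta_c, size=H - 1)
    sampler.set_state(
        parents=parents,
        changepoints=cps,
        lambda_u=lam_u,
        lambda_c=lam_c,
        delta=delta,
        lambda_seg=lam_seg,
    )


def draw_response(sampler: TargetSampler, rng: np.random.Generator) -> np.ndarray:
    """Draw y | (pi, tau, theta) and install it in the sampler.

    Segments are generated in time order because the coupled priors feed
    the posterior expectation of segment h-1 (given its freshly generated
    data) forward as segment h's prior mean.
    """
    hyp = sampler.hyper
    lam, couple = sampler._lam_couple()
    X = sampler._design(sampler.parents)
    starts, ends = sampler._bounds(sampler.cps)
    k1 = X.shape[1]
    sigma2 = 1.0 / rng.gamma(
        hyp.noise.alpha_sigma, 1.0 / hyp.noise.beta_sigma
    )
    y = np.empty(sampler.yv.shape[0])
    wt_prev = np.zeros(k1)
    for h in range(starts.shape[0]):
        s, e = starts[h], ends[h]
        Xh = X[s:e]
        mu = couple[h] * wt_prev
        w = mu + np.sqrt(sigma2 * lam[h]) * rng.standard_normal(k1)
        y[s:e] = Xh @ w + np.sqrt(sigma2) * rng.standard_normal(e - s)
        A = np.eye(k1) / lam[h] + Xh.T @ Xh
        wt_prev = np.linalg.solve(A, mu / lam[h] + Xh.T @ y[s:e])
    full = np.empty(sampler.T)
    full[np.flatnonzero(sampler.task.valid_mask)] = y
    sampler.set_response(full)
    return full


def successive_conditional(
    variant: str,
    n_sweeps: int,
    T: int = 8,
    n: int = 2,
    hyper: CouplingHyper | None = None,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Run the successive-conditional simulator and return state traces.

    Returns traces of 1/lambda_u, 1/lambda_c, the parent-set size and the
    segment count, one entry per sweep.
    """
    rng = np.random.default_rng(seed)
    hyper = hyper or CouplingHyper()
    task = make_fixed_design_task(T, n, rng)
    sampler = TargetSampler(
        task, variant, hyper, ChainConfig(iterations=10, min_seg_len=1)
    )
    prior_sample_state(sampler, rng)
    traces = {k: np.empty(n_sweeps) for k in ("inv_lambda_u", "inv_lambda_c", "n_parents", "n_segments")}
    for i in range(n_sweeps):
        draw_response(sampler, rng)
        sampler.step(rng)
        traces["inv_lambda_u"][i] = 1.0 / sampler.lam_u
        traces["inv_lambda_c"][i] = 1.0 / sampler.lam_c
        traces["n_parents"][i] = len(sampler.parents)
        traces["n_segments"][i] = sampler.n_segments
    return traces


def batch_means_se(trace: np.ndarray, n_batches: int = 50) -> float:
    """Autocorrelation-robust standard error of a trace mean."""
    m = len(trace) // n_batches
    if m < 2:
        raise ValueError("trace too short for batch means")
    batches = trace[: m * n_batches].reshape(n_batches, m).mean(axis=1)
    return float(batches.std(ddof=1) / np.sqrt(n_batches))
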