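"""The four prior instantiations of the piecewise linear regression model.

Variant overview (all share the generic likelihood from
:mod:`nhdbn.regression`):

* ``M1`` (uncoupled) — every segment gets the vague prior
  ``w_h ~ N(0, sigma2 * lambda_u I)``; segments are learned independently.
* ``M2`` (fully coupled) — segment 1 is uncoupled; for h > 1 the posterior
  expectation ``w~_{h-1}`` of the previous segment is recycled as prior
  mean, ``w_h ~ N(w~_{h-1}, sigma2 * lambda_c I)``.
* ``M3`` (partially segment-wise coupled) — a binary indicator ``delta_h``
  per segment h > 1 selects between the uncoupled prior (delta_h = 0) and
  the coupled prior (delta_h = 1); the indicators are inferred from the
  data with collapsed Gibbs steps.  delta_1 == 0 is a fixed constant.
* ``M4`` (generalised coupled) — like M2 but with a segment-specific
  coupling strength lambda_h per segment h > 1.

``lambda_u`` acts as a signal-to-noise ratio parameter and ``lambda_c``
(resp. ``lambda_h``) as coupling strength; all have inverse-Gamma priors.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from math import comb, lgamma
from typing import Literal, Sequence

import numpy as np

from .regression import (
    NoiseHyper,
    PriorMoments,
    SegmentData,
    log_marginal_likelihood,
    posterior_mean_weights,
)

Variant = Literal["M1", "M2", "M3", "M4"]
VARIANTS: tuple[str, ...] = ("M1", "M2", "M3", "M4")


@dataclass(frozen=True)
class CouplingHyper:
    """Hyperparameters shared by all model variants.

    Defaults follow the standard uninformative settings used throughout
    the NH-DBN literature: 1/lambda_u ~ Gamma(2, 0.2),
    1/lambda_c ~ Gamma(3, 3), noise 1/sigma2 ~ Gamma(0.005, 0.005), a flat
    Beta(1, 1) hyperprior on the coupling probability p, a geometric prior
    on changepoint distances with hyperparameter ``p_cp``, and a fan-in
    restriction of 3 parents per node.
    """

    alpha_u: float = 2.0
    beta_u: float = 0.2
    alpha_c: float = 3.0
    beta_c: float = 3.0
    a: float = 1.0
    b: float = 1.0
    p_cp: float = 0.05
    fan_in: int = 3
    noise: NoiseHyper = NoiseHyper()

    def __post_init__(self):
        for name in ("alpha_u", "beta_u", "alpha_c", "beta_c", "a", "b"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 < self.p_cp < 1.0):
            raise ValueError("p_cp must lie in (0, 1)")
        if self.fan_in < 0:
            raise ValueError("fan_in must be non-negative")


@dataclass(frozen=True)
class CouplingState:
    """Variance/coupling parameters of one model variant for H segments.

    ``lambda_seg`` (M4) and ``delta`` (M3) are indexed by segment
    h = 2..H, i.e. they have length H-1; delta_1 == 0 is implicit.
    """

    lambda_u: float
    lambda_c: float | None = None
    lambda_seg: tuple[float, ...] | None = None
    delta: tuple[int, ...] | None = None

    def __post_init__(self):
        if self.lambda_u <= 0:
            raise ValueError("lambda_u must be positive")
        if self.lambda_c is not None and self.lambda_c <= 0:
            raise ValueError("lambda_c must be positive")
        if self.lambda_seg is not None:
            lam = tuple(float(v) for v in self.lambda_seg)
            if any(v <= 0 for v in lam):
                raise ValueError("all lambda_h must be positive")
            object.__setattr__(self, "lambda_seg", lam)
        if self.delta is not None:
            d = tuple(int(v) for v in self.delta)
            if any(v not in (0, 1) for v in d):
                raise ValueError("delta entries must be 0/1")
            object.__setattr__(self, "delta", d)


def _check_state(variant: Variant, state: CouplingState, H: int) -> None:
    if variant in ("M2", "M3") and state.lambda_c is None:
        raise ValueError(f"{variant} requires lambda_c")
    if variant == "M3":
        if state.delta is None or len(state.delta) != H - 1:
            raise ValueError("M3 requires a delta vector of length H-1")
    if variant == "M4":
        if state.lambda_seg is None or len(state.lambda_seg) != H - 1:
            raise ValueError("M4 requires lambda_seg of length H-1")


def segment_variances(variant: Variant, state: CouplingState, H: int) -> np.ndarray:
    """Prior variance factor lambda of each segment h = 1..H."""
    _check_state(variant, state, H)
    if variant == "M1":
        return np.full(H, state.lambda_u)
    if variant == "M2":
        lam = np.full(H, state.lambda_c)
        lam[0] = state.lambda_u
        return lam
    if variant == "M3":
        lam = np.empty(H)
        lam[0] = state.lambda_u
        for h in range(1, H):
            lam[h] = state.lambda_c if state.delta[h - 1] else state.lambda_u
        return lam
    return np.concatenate([[state.lambda_u], np.asarray(state.lambda_seg)])


def coupling_pattern(variant: Variant, state: CouplingState, H: int) -> np.ndarray:
    """Indicator per segment: is its prior mean the previous posterior mean?"""
    _check_state(variant, state, H)
    c = np.zeros(H, dtype=np.int8)
    if variant in ("M2", "M4"):
        c[1:] = 1
    elif variant == "M3":
        c[1:] = np.asarray(state.delta, dtype=np.int8)
    return c


def prior_moments(
    variant: Variant,
    state: CouplingState,
    segments: Sequence[SegmentData],
) -> list[PriorMoments]:
    """Per-segment prior moments, with the forward w~ recursion.

    The posterior-mean chain is computed sequentially: segment h's prior
    mean is ``couple_h * w~_{h-1}`` where ``w~_{h-1}`` is the posterior
    expectation of segment h-1's coefficients under its own prior moments
    (treated as a fixed hyperparameter when fed forward), with
    ``w~_0 := 0``.
    """
    H = len(segments)
    lam = segment_variances(variant, state, H)
    couple = coupling_pattern(variant, state, H)
    k1 = segments[0].X.shape[1]
    out: list[PriorMoments] = []
    wt_prev = np.zeros(k1)
    for h in range(H):
        mu = couple[h] * wt_prev
        mom = PriorMoments(mu=mu, Sigma=lam[h] * np.eye(k1))
        out.append(mom)
        wt_prev = posterior_mean_weights(segments[h], mom)
    return out


def sample_lambdas(
    variant: Variant,
    state: CouplingState,
    weights: Sequence[np.ndarray],
    moments: Sequence[PriorMoments],
    sigma2: float,
    hyper: CouplingHyper,
    rng: np.random.Generator,
) -> CouplingState:
    """Gibbs update of the variance/coupling parameters given drawn weights.

    The full conditionals are Gamma distributions for the precisions; the
    quadratic terms are ``||w_h - mu_h||^2`` with ``mu_h`` the current
    prior mean of segment h (zero for uncoupled segments, w~_{h-1} for
    coupled ones).
    """
    H = len(weights)
    _check_state(variant, state, H)
    couple = coupling_pattern(variant, state, H)
    k1 = weights[0].shape[0]
    d = np.array(
        [float((w - m.mu) @ (w - m.mu)) for w, m in zip(weights, moments, strict=True)]
    )

    def draw_inv(shape: float, rate: float) -> float:
        return float(1.0 / rng.gamma(shape, 1.0 / rate))

    if variant == "M1":
        lam_u = draw_inv(
            hyper.alpha_u + H * k1 / 2.0, hyper.beta_u + 0.5 / sigma2 * d.sum()
        )
        return replace(state, lambda_u=lam_u)
    if variant == "M2":
        lam_u = draw_inv(hyper.alpha_u + k1 / 2.0, hyper.beta_u + 0.5 / sigma2 * d[0])
        lam_c = draw_inv(
            hyper.alpha_c + (H - 1) * k1 / 2.0,
            hyper.beta_c + 0.5 / sigma2 * d[1:].sum(),
        )
        return replace(state, lambda_u=lam_u, lambda_c=lam_c)
    if variant == "M3":
        unc = couple == 0
        H_u = int(unc.sum())
        H_c = H - H_u
        lam_u = draw_inv(
            hyper.alpha_u + H_u * k1 / 2.0, hyper.beta_u + 0.5 / sigma2 * d[unc].sum()
        )
        # with no coupled segment the conditional reduces to the prior
        lam_c = draw_inv(
            hyper.alpha_c + H_c * k1 / 2.0, hyper.beta_c + 0.5 / sigma2 * d[~unc].sum()
        )
        return replace(state, lambda_u=lam_u, lambda_c=lam_c)
    lam_u = draw_inv(hyper.alpha_u + k1 / 2.0, hyper.beta_u + 0.5 / sigma2 * d[0])
    lam_seg = tuple(
        draw_inv(hyper.alpha_c + k1 / 2.0, hyper.beta_c + 0.5 / sigma2 * d[h])
        for h in range(1, H)
    )
    return replace(state, lambda_u=lam_u, lambda_seg=lam_seg)


def log_delta_prior(delta: Sequence[int], a: float, b: float) -> float:
    """Marginal prior of the coupling indicators with p integrated out.

    p({delta_h}) = B(a + sum delta, b + sum(1 - delta)) / B(a, b) for the
    H-1 exchangeable Bernoulli(p) indicators with p ~ Beta(a, b).
    """
    delta = np.asarray(delta, dtype=int)
    s = int(delta.sum())
    f = delta.size - s
    return (
        lgamma(a + b)
        - lgamma(a)
        - lgamma(b)
        + lgamma(a + s)
        + lgamma(b + f)
        - lgamma(a + b + delta.size)
    )


def sample_delta(
    k: int,
    state: CouplingState,
    segments: Sequence[SegmentData],
    hyper: CouplingHyper,
    rng: np.random.Generator,
) -> CouplingState:
    """Collapsed Gibbs update of one coupling indicator delta_k (k = 2..H).

    The weights, sigma2 and the Bernoulli parameter p are integrated out:
    the two candidate values are scored by the closed-form marginal
    likelihood (with the w~ chain recomputed downstream of k, since
    delta_k feeds into w~_k, w~_{k+1}, ...) times the marginal indicator
    prior.
    """
    H = len(segments)
    _check_state("M3", state, H)
    if not (2 <= k <= H):
        raise ValueError("delta index k must be in 2..H")
    logp = np.empty(2)
    for cand in (0, 1):
        delta = list(state.delta)
        delta[k - 2] = cand
        cand_state = replace(state, delta=tuple(delta))
        moms = prior_moments("M3", cand_state, segments)
        logp[cand] = log_marginal_likelihood(
            list(segments), moms, hyper.noise
        ) + log_delta_prior(delta, hyper.a, hyper.b)
    p1 = 1.0 / (1.0 + np.exp(logp[0] - logp[1]))
    delta = list(state.delta)
    delta[k - 2] = int(rng.random() < p1)
    return replace(state, delta=tuple(delta))


def log_changepoint_prior(tau: Sequence[int], T: int, p_cp: float) -> float:
    """Geometric inter-changepoint distance prior.

    p(tau) = p^(H-1) * (1-p)^((T-1)-(H-1)); equivalently every candidate
    position 1..T-1 carries an independent Bernoulli(p) changepoint.
    """
    K = len(tau)
    return K * np.log(p_cp) + ((T - 1) - K) * np.log1p(-p_cp)


def log_parent_prior(parents: Sequence[int], n: int, fan_in: int) -> float:
    """Uniform prior over parent sets obeying the fan-in restriction."""
    k = len(parents)
    if k > fan_in:
        return -np.inf
    n_allowed = sum(comb(n, j) for j in range(min(fan_in, n) + 1))
    return -np.log(n_allowed)
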