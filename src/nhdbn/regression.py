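"""Conjugate Bayesian piecewise linear regression.

This module implements the generic building block shared by all four
network models: a lag-1 linear regression for one target node whose
observations are divided into disjoint time segments.  Within segment
``h`` the response is Gaussian,

    y_h | (w_h, sigma2)  ~  N(X_h w_h, sigma2 * I),

the coefficient vector has a conjugate Gaussian prior
``w_h ~ N(mu_h, sigma2 * Sigma_h)``, and the shared noise variance has an
inverse-Gamma prior ``1/sigma2 ~ Gamma(alpha_sigma, beta_sigma)``.  With
this fully conjugate structure the marginal likelihood (w's and sigma2
integrated out) is available in closed form, and sigma2 and the w's have
standard full conditional distributions.

All likelihood computations are carried out in the log domain.  The
T_h x T_h covariance matrix ``C_h = I + X_h Sigma_h X_h^T`` is never
factorised directly; the matrix determinant lemma and the Woodbury
identity reduce everything to the (k+1) x (k+1) inner matrix
``Sigma_h^{-1} + X_h^T X_h`` (the number of covariates k is at most the
fan-in, typically 3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import gammaln


class DegenerateInputError(ValueError):
    """Raised when an input leaves no usable observations or segments."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """A gene-expression time series: N nodes observed at T+1 time points.

    Parameters
    ----------
    values
        Real matrix of shape (N, T+1); rows are nodes, columns are
        equidistant time points.
    node_names
        N unique identifiers.
    series_boundaries
        0-based column indices at which an independent experiment starts
        (used when several separately measured series are concatenated
        into one matrix).  A lag-1 observation pair that straddles a
        boundary is physically meaningless and is masked out.
    """

    values: np.ndarray
    node_names: tuple[str, ...]
    series_boundaries: tuple[int, ...] = ()

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("expression values must be a 2-d matrix")
        if not np.all(np.isfinite(values)):
            raise ValueError("expression matrix contains missing/non-finite values")
        if values.shape[1] < 3:
            raise ValueError("need at least 3 time points (T+1 >= 3)")
        if len(self.node_names) != values.shape[0]:
            raise ValueError("node_names length does not match number of rows")
        if len(set(self.node_names)) != len(self.node_names):
            raise ValueError("duplicate node names")
        bounds = tuple(self.series_boundaries)
        if list(bounds) != sorted(set(bounds)):
            raise ValueError("series boundaries must be strictly increasing")
        if bounds and (bounds[0] < 1 or bounds[-1] >= values.shape[1]):
            raise ValueError("series boundaries out of column range")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "node_names", tuple(self.node_names))
        object.__setattr__(self, "series_boundaries", bounds)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class RegressionTask:
    """One target node's lagged regression problem.

    ``response[t]`` is the target value at raw time point t+1 and row t of
    ``covariates`` holds the values of all n = N-1 non-target nodes at raw
    time point t (1-based observation index is t+1).  ``valid_mask[t]`` is
    False when the (t, t+1) pair crosses a series boundary.
    """

    target_index: int
    response: np.ndarray
    covariates: np.ndarray
    valid_mask: np.ndarray
    covariate_names: tuple[str, ...]
    target_name: str = ""

    @property
    def n_obs(self) -> int:
        return self.response.shape[0]

    @property
    def n_candidates(self) -> int:
        return self.covariates.shape[1]


@dataclass(frozen=True)
class Segmentation:
    """A sorted set of changepoints tau, each in [1, T).

    Observation t (1-based, t = 1..T) belongs to segment h when
    ``tau_{h-1} < t <= tau_h`` with the pseudo changepoints tau_0 := 0 and
    tau_H := T, so every observation is covered and ``changepoint at t``
    means t is the last observation of its segment.
    """

    changepoints: tuple[int, ...] = ()

    def __post_init__(self):
        cps = tuple(int(c) for c in self.changepoints)
        if list(cps) != sorted(set(cps)):
            raise ValueError("changepoints must be strictly increasing")
        if cps and cps[0] < 1:
            raise ValueError("changepoints must be >= 1")
        object.__setattr__(self, "changepoints", cps)

    @property
    def n_segments(self) -> int:
        return len(self.changepoints) + 1

    def segment_of(self, t: int) -> int:
        """1-based segment index of 1-based observation t."""
        return int(np.searchsorted(np.asarray(self.changepoints), t, side="left")) + 1


@dataclass(frozen=True)
class SegmentData:
    """Response vector and design matrix (first column all ones) of one segment."""

    y: np.ndarray
    X: np.ndarray

    def __post_init__(self):
        if self.y.shape[0] != self.X.shape[0]:
            raise ValueError("response/design row mismatch")
        if self.X.shape[0] and not np.allclose(self.X[:, 0], 1.0):
            raise ValueError("first design column must be the intercept (all ones)")

    @property
    def n_obs(self) -> int:
        return self.y.shape[0]


@dataclass(frozen=True)
class PriorMoments:
    """Gaussian prior moments (mu_h, Sigma_h) of one segment's coefficients."""

    mu: np.ndarray
    Sigma: np.ndarray


@dataclass(frozen=True)
class NoiseHyper:
    """Inverse-Gamma hyperparameters of the noise variance, 1/sigma2 ~ Gamma(a, b)."""

    alpha_sigma: float = 0.005
    beta_sigma: float = 0.005

    def __post_init__(self):
        if self.alpha_sigma <= 0 or self.beta_sigma <= 0:
            raise ValueError("noise hyperparameters must be positive")


def build_regression_task(data: ExpressionMatrix, target: int) -> RegressionTask:
    """Turn an expression matrix into the lag-1 regression problem of one node.

    T+1 time points yield T observations: the response is the target at
    times 2..T+1 and the covariates are all other nodes at times 1..T.
    Observation pairs straddling a declared series boundary are masked.
    """
    N, Tp1 = data.values.shape
    if not (0 <= target < N):
        raise IndexError(f"target index {target} out of range for N={N}")
    T = Tp1 - 1
    others = [i for i in range(N) if i != target]
    response = data.values[target, 1:].copy()
    covariates = data.values[others, :-1].T.copy()
    valid = np.ones(T, dtype=bool)
    for b in data.series_boundaries:
        # boundary at 0-based column b: the pair (b-1, b) crosses it
        valid[b - 1] = False
    if not valid.any():
        raise DegenerateInputError("all observations masked by series boundaries")
    return RegressionTask(
        target_index=target,
        response=response,
        covariates=covariates,
        valid_mask=valid,
        covariate_names=tuple(data.node_names[i] for i in others),
        target_name=data.node_names[target],
    )


def segmentize(
    task: RegressionTask,
    seg: Segmentation,
    parents: tuple[int, ...] | list[int],
    min_seg_len: int = 2,
) -> list[SegmentData]:
    """Split the valid observations into per-segment (y_h, X_h) blocks.

    ``parents`` are 0-based covariate column indices; each design matrix is
    ``[1 | covariate columns of parents]``.  Raises when any segment holds
    fewer than ``min_seg_len`` valid observations.
    """
    T = task.n_obs
    parents = tuple(int(p) for p in parents)
    if seg.changepoints and seg.changepoints[-1] >= T:
        raise ValueError("changepoint at or beyond T")
    bounds = (0,) + seg.changepoints + (T,)
    out = []
    for h in range(seg.n_segments):
        lo, hi = bounds[h], bounds[h + 1]
        rows = np.flatnonzero(task.valid_mask[lo:hi]) + lo
        if rows.size < min_seg_len:
            raise DegenerateInputError(
                f"segment {h + 1} has {rows.size} valid observations "
                f"(min_seg_len={min_seg_len})"
            )
        X = np.column_stack(
            [np.ones(rows.size)] + [task.covariates[rows, p] for p in parents]
        )
        out.append(SegmentData(y=task.response[rows], X=X))
    return out


def cov_matrix_C(seg: SegmentData, moments: PriorMoments) -> np.ndarray:
    """Marginal covariance factor C_h = I + X_h Sigma_h X_h^T (T_h x T_h)."""
    X = seg.X
    if moments.Sigma.shape[0] != X.shape[1]:
        raise ValueError("Sigma dimension does not match design columns")
    return np.eye(X.shape[0]) + X @ moments.Sigma @ X.T


def _inner_factor(seg: SegmentData, moments: PriorMoments):
    """Cholesky pieces for the Woodbury form of C_h^{-1} and det(C_h).

    Returns (cho(A), cho(Sigma)) with A = Sigma^{-1} + X^T X.
    """
    sig_cho = cho_factor(moments.Sigma, lower=True, check_finite=False)
    k1 = moments.Sigma.shape[0]
    A = cho_solve(sig_cho, np.eye(k1), check_finite=False) + seg.X.T @ seg.X
    return cho_factor(A, lower=True, check_finite=False), sig_cho


def delta_squared(segments: list[SegmentData], moments: list[PriorMoments]) -> float:
    """Total weighted residual sum Delta^2 = sum_h r_h^T C_h^{-1} r_h.

    Computed via the Woodbury identity,
    ``r^T C^{-1} r = r^T r - u^T A^{-1} u`` with ``u = X^T r`` and
    ``A = Sigma^{-1} + X^T X``, using Cholesky factorisations only.
    """
    total = 0.0
    for seg, mom in zip(segments, moments, strict=True):
        r = seg.y - seg.X @ mom.mu
        u = seg.X.T @ r
        A_cho, _ = _inner_factor(seg, mom)
        total += float(r @ r - u @ cho_solve(A_cho, u, check_finite=False))
    return max(total, 0.0)


def log_det_C(seg: SegmentData, moments: PriorMoments) -> float:
    """log det(I + X Sigma X^T) via det(Sigma) * det(Sigma^{-1} + X^T X)."""
    A_cho, sig_cho = _inner_factor(seg, moments)
    return 2.0 * (
        np.log(np.diag(A_cho[0])).sum() + np.log(np.diag(sig_cho[0])).sum()
    )


def log_marginal_likelihood(
    segments: list[SegmentData],
    moments: list[PriorMoments],
    noise: NoiseHyper,
) -> float:
    """Closed-form log marginal likelihood with all w_h and sigma2 integrated out.

    log p(y | theta) = lgam(T/2 + a) - lgam(a) - (T/2) log pi + a log(2b)
                       - 1/2 sum_h log det C_h - (T/2 + a) log(2b + Delta^2)
    """
    a, b = noise.alpha_sigma, noise.beta_sigma
    T = sum(s.n_obs for s in segments)
    if T == 0:
        raise DegenerateInputError("no observations")
    logdet = sum(log_det_C(s, m) for s, m in zip(segments, moments, strict=True))
    d2 = delta_squared(segments, moments)
    return float(
        gammaln(T / 2.0 + a)
        - gammaln(a)
        - (T / 2.0) * np.log(np.pi)
        + a * np.log(2.0 * b)
        - 0.5 * logdet
        - (T / 2.0 + a) * np.log(2.0 * b + d2)
    )


def sample_sigma2(
    segments: list[SegmentData],
    moments: list[PriorMoments],
    noise: NoiseHyper,
    rng: np.random.Generator,
) -> float:
    """Collapsed draw of sigma2 (w's integrated out).

    1/sigma2 ~ Gamma(alpha_sigma + T/2, beta_sigma + Delta^2/2).
    """
    T = sum(s.n_obs for s in segments)
    d2 = delta_squared(segments, moments)
    shape = noise.alpha_sigma + T / 2.0
    rate = noise.beta_sigma + d2 / 2.0
    return float(1.0 / rng.gamma(shape, 1.0 / rate))


def posterior_mean_weights(seg: SegmentData, moments: PriorMoments) -> np.ndarray:
    """Posterior expectation of a segment's coefficient vector,

    w~ = [Sigma^{-1} + X^T X]^{-1} (Sigma^{-1} mu + X^T y).
    """
    A_cho, sig_cho = _inner_factor(seg, moments)
    rhs = cho_solve(sig_cho, moments.mu, check_finite=False) + seg.X.T @ seg.y
    return cho_solve(A_cho, rhs, check_finite=False)


def sample_weights(
    seg: SegmentData,
    sigma2: float,
    moments: PriorMoments,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw w_h from its Gaussian full conditional given sigma2."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    A_cho, sig_cho = _inner_factor(seg, moments)
    rhs = cho_solve(sig_cho, moments.mu, check_finite=False) + seg.X.T @ seg.y
    mean = cho_solve(A_cho, rhs, check_finite=False)
    # A = L L^T  =>  cov = sigma2 A^{-1}; draw mean + sqrt(sigma2) L^{-T} z
    L = np.tril(A_cho[0])
    z = rng.standard_normal(mean.shape[0])
    from scipy.linalg import solve_triangular

    return mean + np.sqrt(sigma2) * solve_triangular(
        L.T, z, lower=False, check_finite=False
    )
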