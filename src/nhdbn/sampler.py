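"""Per-target reversible-jump MCMC sampler.

One :class:`TargetSampler` explores the joint posterior of a single
node's parent set pi, changepoint set tau and variance/coupling
parameters theta.  Each iteration performs, in order,

1. a Gibbs sweep over theta (collapsed sigma2 draw, weight draws, lambda
   updates and — for the partially coupled model — collapsed coupling
   indicator updates),
2. one Metropolis-Hastings move on the parent set (addition / removal /
   exchange), and
3. one Metropolis-Hastings move on the changepoint set (birth / death /
   re-allocation), skipped when the segmentation is user-fixed.

The move type is drawn uniformly from the three types; if the drawn type
is unavailable in the current state (death with no changepoint, addition
at the fan-in bound, ...) the iteration counts as a rejection, which
keeps the textbook Hastings ratios valid without boundary bookkeeping.
For the trans-dimensional variants, segments that stay identical keep
their parameters; parameters of newly created segments are re-proposed
(fair coin flips for coupling indicators, prior draws for segment-wise
coupling strengths).
"""

from __future__ import annotations

import math
from bisect import bisect_left
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .models import (
    CouplingHyper,
    CouplingState,
    Variant,
    log_changepoint_prior,
    log_parent_prior,
)
from .regression import RegressionTask, Segmentation

_MOVE_NAMES = ("parent", "changepoint")


@dataclass(frozen=True)
class ChainConfig:
    """Run-length and bookkeeping settings of one RJMCMC chain."""

    iterations: int = 100_000
    burn_in_fraction: float = 0.5
    thinning: int = 10
    min_seg_len: int = 2
    fixed_changepoints: Segmentation | None = None

    def __post_init__(self):
        if self.iterations < self.thinning:
            raise ValueError("iterations must be >= thinning")
        if not (0.0 <= self.burn_in_fraction < 1.0):
            raise ValueError("burn_in_fraction must be in [0, 1)")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")

    @property
    def burn_in(self) -> int:
        return int(self.iterations * self.burn_in_fraction)

    @property
    def n_retained(self) -> int:
        return (self.iterations - self.burn_in) // self.thinning


@dataclass(frozen=True)
class PosteriorSample:
    """One retained draw of (pi, tau, theta) with its log marginal."""

    parents: tuple[int, ...]
    changepoints: tuple[int, ...]
    lambda_u: float
    lambda_c: float | None
    lambda_seg: tuple[float, ...] | None
    delta: tuple[int, ...] | None
    log_marginal: float


@dataclass
class ChainResult:
    samples: list[PosteriorSample]
    acceptance: dict
    target_name: str = ""


def fixed_changepoints(K: int, T: int, first_boundary: int) -> Segmentation:
    """Deterministic placement of K fixed changepoints.

    The first changepoint sits at ``first_boundary``; each further one is
    placed at the midpoint of the currently longest segment (leftmost on
    ties) until K changepoints are set.  K changepoints yield H = K + 1
    segments.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if not (1 <= first_boundary < T):
        raise ValueError("first boundary must lie in [1, T)")
    cps = [int(first_boundary)]
    while len(cps) < K:
        bounds = [0] + cps + [T]
        lengths = [bounds[i + 1] - bounds[i] for i in range(len(bounds) - 1)]
        j = int(np.argmax(lengths))
        if lengths[j] < 2:
            raise ValueError(f"cannot place {K} changepoints in T={T} observations")
        mid = bounds[j] + lengths[j] // 2
        cps.append(mid)
        cps.sort()
    return Segmentation(tuple(cps))


class TargetSampler:
    """RJMCMC chain for one target node.

    The heavy numerics run through the jit-compiled kernels in
    :mod:`nhdbn._kernels`; all randomness is drawn from the single
    generator handed to the step methods, so runs are reproducible from
    the seed alone.
    """

    def __init__(
        self,
        task: RegressionTask,
        variant: Variant,
        hyper: CouplingHyper | None = None,
        config: ChainConfig | None = None,
    ):
        self.task = task
        self.variant = variant
        self.hyper = hyper or CouplingHyper()
        self.config = config or ChainConfig()
        idx = np.flatnonzero(task.valid_mask)
        self.tv = idx + 1  # 1-based observation indices of valid rows
        self.yv = np.ascontiguousarray(task.response[idx])
        self.Xall = np.column_stack(
            [np.ones(idx.size), task.covariates[idx]]
        )  # column 0 = intercept, column j+1 = covariate j
        self.n = task.n_candidates
        self.T = task.n_obs
        self.fixed_tau = self.config.fixed_changepoints is not None

        # deterministic initial state: empty parent set, fixed or empty
        # segmentation, lambdas at their prior harmonic means, uncoupled.
        self.parents: tuple[int, ...] = ()
        if self.fixed_tau:
            self.cps = tuple(self.config.fixed_changepoints.changepoints)
            self._check_seg_lengths(self.cps, raise_on_violation=True)
        else:
            self.cps = ()
        h = self.hyper
        self.lam_u = h.beta_u / h.alpha_u
        self.lam_c = h.beta_c / h.alpha_c
        H = len(self.cps) + 1
        self.delta = np.zeros(H - 1, dtype=np.int8)
        self.lam_seg = np.full(H - 1, self.lam_c)
        self.accept_count = {m: 0 for m in _MOVE_NAMES}
        self.attempt_count = {m: 0 for m in _MOVE_NAMES}
        self._refresh_cache()

    # ------------------------------------------------------------------
    # state plumbing

    @property
    def n_segments(self) -> int:
        return len(self.cps) + 1

    def coupling_state(self) -> CouplingState:
        v = self.variant
        return CouplingState(
            lambda_u=self.lam_u,
            lambda_c=self.lam_c if v in ("M2", "M3") else None,
            lambda_seg=tuple(self.lam_seg) if v == "M4" else None,
            delta=tuple(int(d) for d in self.delta) if v == "M3" else None,
        )

    def set_state(
        self,
        parents: tuple[int, ...] | None = None,
        changepoints: tuple[int, ...] | None = None,
        lambda_u: float | None = None,
        lambda_c: float | None = None,
        lambda_seg=None,
        delta=None,
    ) -> None:
        """Inject a state (used by tests and by the Geweke harness)."""
        if parents is not None:
            self.parents = tuple(sorted(int(p) for p in parents))
        if changepoints is not None:
            self.cps = tuple(sorted(int(c) for c in changepoints))
        H = self.n_segments
        if lambda_u is not None:
            self.lam_u = float(lambda_u)
        if lambda_c is not None:
            self.lam_c = float(lambda_c)
        if delta is not None:
            self.delta = np.asarray(delta, dtype=np.int8).copy()
        if lambda_seg is not None:
            self.lam_seg = np.asarray(lambda_seg, dtype=float).copy()
        if len(self.delta) != H - 1:
            self.delta = np.zeros(H - 1, dtype=np.int8)
        if len(self.lam_seg) != H - 1:
            self.lam_seg = np.full(H - 1, self.lam_c)
        self._refresh_cache()

    def set_response(self, response: np.ndarray) -> None:
        """Replace the response vector (full length T; masked rows dropped).

        Used by simulation-based calibration, where data are redrawn from
        the model between transitions.
        """
        response = np.asarray(response, dtype=float)
        if response.shape[0] != self.T:
            raise ValueError("response length mismatch")
        self.yv = np.ascontiguousarray(response[np.flatnonzero(self.task.valid_mask)])
        self._refresh_cache()

    def _lam_couple(self, cps=None, delta=None, lam_seg=None, lam_u=None, lam_c=None):
        """Per-segment (lam, couple) arrays for the current variant."""
        cps = self.cps if cps is None else cps
        H = len(cps) + 1
        lam_u = self.lam_u if lam_u is None else lam_u
        lam_c = self.lam_c if lam_c is None else lam_c
        couple = np.zeros(H, dtype=np.int8)
        lam = np.full(H, lam_u)
        if self.variant == "M2":
            couple[1:] = 1
            lam[1:] = lam_c
        elif self.variant == "M3":
            d = self.delta if delta is None else delta
            couple[1:] = d
            lam[1:] = np.where(np.asarray(d) == 1, lam_c, lam_u)
        elif self.variant == "M4":
            ls = self.lam_seg if lam_seg is None else lam_seg
            couple[1:] = 1
            lam[1:] = ls
        return lam, couple

    def _bounds(self, cps):
        b = np.searchsorted(self.tv, np.asarray(cps, dtype=np.int64), side="right")
        starts = np.concatenate(([0], b))
        ends = np.concatenate((b, [self.tv.size]))
        return starts, ends

    def _seg_counts(self, cps):
        starts, ends = self._bounds(cps)
        return ends - starts

    def _check_seg_lengths(self, cps, raise_on_violation=False) -> bool:
        ok = bool((self._seg_counts(cps) >= self.config.min_seg_len).all())
        if not ok and raise_on_violation:
            raise ValueError("segmentation violates min_seg_len")
        return ok

    def _design(self, parents):
        cols = [0] + [p + 1 for p in parents]
        return np.ascontiguousarray(self.Xall[:, cols])

    def _suite(self, design, starts, ends, lam, couple):
        return _kernels.suite(
            self.yv,
            design,
            starts,
            ends,
            lam,
            couple,
            self.hyper.noise.alpha_sigma,
            self.hyper.noise.beta_sigma,
        )

    def _eval(self, parents, cps, lam, couple):
        starts, ends = self._bounds(cps)
        return self._suite(self._design(parents), starts, ends, lam, couple)

    def _refresh_cache(self):
        """Rebuild all per-state caches (design, bounds, lam/couple, suite)."""
        self._cur_design = self._design(self.parents)
        self._cur_starts, self._cur_ends = self._bounds(self.cps)
        self._lam, self._couple = self._lam_couple()
        self.log_marginal, self._delta2, self._wtilde, self._chols = self._suite(
            self._cur_design, self._cur_starts, self._cur_ends, self._lam, self._couple
        )

    # ------------------------------------------------------------------
    # Gibbs sweep over theta

    def gibbs_sweep(self, rng: np.random.Generator) -> None:
        """Resample sigma2, weights, lambdas and (M3) coupling indicators.

        sigma2 and the weights are auxiliary: they are needed only to
        update the lambdas and are discarded afterwards.
        """
        h = self.hyper
        H = self.n_segments
        k1 = len(self.parents) + 1
        Tv = self.yv.size
        couple = self._couple

        # (1) collapsed sigma2 draw
        shape = h.noise.alpha_sigma + 0.5 * Tv
        rate = h.noise.beta_sigma + 0.5 * self._delta2
        sigma2 = 1.0 / rng.gamma(shape, 1.0 / rate)

        # (2) weight draws from their Gaussian full conditionals
        Z = rng.standard_normal((H, k1))
        W = _kernels.draw_weights(self._chols, self._wtilde, Z, math.sqrt(sigma2))

        # (3) lambda updates; prior means mu_h = couple_h * w~_{h-1}
        mus = np.zeros((H, k1))
        mus[1:] = couple[1:, None] * self._wtilde[:-1]
        d = ((W - mus) ** 2).sum(axis=1)

        def draw_inv(shape, rate):
            return 1.0 / rng.gamma(shape, 1.0 / rate)

        if self.variant == "M1":
            self.lam_u = draw_inv(
                h.alpha_u + H * k1 / 2.0, h.beta_u + 0.5 / sigma2 * d.sum()
            )
        elif self.variant == "M2":
            self.lam_u = draw_inv(h.alpha_u + k1 / 2.0, h.beta_u + 0.5 / sigma2 * d[0])
            self.lam_c = draw_inv(
                h.alpha_c + (H - 1) * k1 / 2.0, h.beta_c + 0.5 / sigma2 * d[1:].sum()
            )
        elif self.variant == "M3":
            unc = couple == 0
            self.lam_u = draw_inv(
                h.alpha_u + int(unc.sum()) * k1 / 2.0,
                h.beta_u + 0.5 / sigma2 * d[unc].sum(),
            )
            self.lam_c = draw_inv(
                h.alpha_c + int((~unc).sum()) * k1 / 2.0,
                h.beta_c + 0.5 / sigma2 * d[~unc].sum(),
            )
        else:  # M4
            self.lam_u = draw_inv(h.alpha_u + k1 / 2.0, h.beta_u + 0.5 / sigma2 * d[0])
            for j in range(1, H):
                self.lam_seg[j - 1] = draw_inv(
                    h.alpha_c + k1 / 2.0, h.beta_c + 0.5 / sigma2 * d[j]
                )

        # (4) collapsed coupling-indicator sweep (M3 only)
        if self.variant == "M3" and H > 1:
            couple = np.zeros(H, dtype=np.int8)
            couple[1:] = self.delta
            out = _kernels.update_deltas(
                self.yv,
                self._cur_design,
                self._cur_starts,
                self._cur_ends,
                couple,
                self.lam_u,
                self.lam_c,
                h.a,
                h.b,
                h.noise.alpha_sigma,
                h.noise.beta_sigma,
                rng.random(H - 1),
            )
            self.delta = couple[1:].copy()
            self._couple = couple
            self._lam = np.where(couple == 1, self.lam_c, self.lam_u)
            self.log_marginal, self._delta2, self._wtilde, self._chols = out
        else:
            # lambdas changed: refresh the variance factors and the cache
            self._lam, self._couple = self._lam_couple()
            self.log_marginal, self._delta2, self._wtilde, self._chols = self._suite(
                self._cur_design,
                self._cur_starts,
                self._cur_ends,
                self._lam,
                self._couple,
            )

    # ------------------------------------------------------------------
    # parent-set move

    def _parent_proposal(self, rng):
        """Propose a parent set differing by one addition/removal/exchange.

        Returns (new_parents, log_hastings) or None when the drawn move
        type is unavailable (auto-rejection).
        """
        pi = self.parents
        free = [j for j in range(self.n) if j not in pi]
        move = int(rng.integers(3))
        if move == 0:  # addition
            if not free:
                return None
            j = free[int(rng.integers(len(free)))]
            new = tuple(sorted(pi + (j,)))
            return new, math.log((self.n - len(pi)) / len(new))
        if move == 1:  # removal
            if not pi:
                return None
            i = pi[int(rng.integers(len(pi)))]
            new = tuple(p for p in pi if p != i)
            return new, math.log(len(pi) / (self.n - len(new)))
        if not pi or not free:  # exchange
            return None
        i = pi[int(rng.integers(len(pi)))]
        j = free[int(rng.integers(len(free)))]
        return tuple(sorted([p for p in pi if p != i] + [j])), 0.0

    def parent_log_accept(self, new_parents, log_hastings=0.0):
        """Log acceptance ratio (before min) for a parent-set proposal.

        The parent-set prior is uniform over fan-in-respecting sets, so
        the prior ratio is 1 between two allowed sets and 0 when the
        proposal exceeds the fan-in.
        """
        prior = log_parent_prior(
            new_parents, self.n, self.hyper.fan_in
        ) - log_parent_prior(self.parents, self.n, self.hyper.fan_in)
        if prior == -np.inf:
            return -np.inf, None
        design = self._design(new_parents)
        logml, d2, wt, ch = self._suite(
            design, self._cur_starts, self._cur_ends, self._lam, self._couple
        )
        return (
            logml - self.log_marginal + prior + log_hastings,
            (logml, d2, wt, ch, design),
        )

    def parent_move(self, rng: np.random.Generator) -> bool:
        self.attempt_count["parent"] += 1
        prop = self._parent_proposal(rng)
        if prop is None:
            return False
        new_parents, log_hr = prop
        if len(new_parents) > self.hyper.fan_in:
            return False  # zero prior: always rejected
        design = self._design(new_parents)
        logml, d2, wt, ch = self._suite(
            design, self._cur_starts, self._cur_ends, self._lam, self._couple
        )
        if math.log(rng.random()) < logml - self.log_marginal + log_hr:
            self.parents = new_parents
            self._cur_design = design
            self.log_marginal, self._delta2, self._wtilde, self._chols = (
                logml,
                d2,
                wt,
                ch,
            )
            self.accept_count["parent"] += 1
            return True
        return False

    # ------------------------------------------------------------------
    # changepoint move

    def changepoint_log_accept(self, new_cps, log_hr):
        """Log acceptance ratio (before min) for a tau proposal with theta kept.

        Covers the M1/M2 case where the changepoint move carries no
        segment-specific parameters; exposed so that detailed-balance
        algebra can be checked on fixed state pairs.
        """
        lam, couple = self._lam_couple(cps=new_cps)
        starts, ends = self._bounds(new_cps)
        logml, *_ = self._suite(self._cur_design, starts, ends, lam, couple)
        return (
            logml
            - self.log_marginal
            + log_changepoint_prior(new_cps, self.T, self.hyper.p_cp)
            - log_changepoint_prior(self.cps, self.T, self.hyper.p_cp)
            + log_hr
        )

    def changepoint_move(self, rng: np.random.Generator) -> bool:
        if self.fixed_tau:
            return False
        self.attempt_count["changepoint"] += 1
        T = self.T
        cps = self.cps
        K = len(cps)
        move = int(rng.integers(3))

        if move == 0:  # birth
            free = [t for t in range(1, T) if t not in cps]
            if not free:
                return False
            pos = free[int(rng.integers(len(free)))]
            new_cps = tuple(sorted(cps + (pos,)))
            if not self._check_seg_lengths(new_cps):
                return False
            j = bisect_left(new_cps, pos)  # 0-based index of the split segment
            log_hr = math.log((T - 1 - K) / (K + 1))
            return self._transdim_accept(rng, new_cps, log_hr, birth_at=j)

        if move == 1:  # death
            if K == 0:
                return False
            i = int(rng.integers(K))
            new_cps = cps[:i] + cps[i + 1 :]
            log_hr = math.log(K / (T - 1 - (K - 1)))
            return self._transdim_accept(rng, new_cps, log_hr, death_at=i)

        # re-allocation
        if K == 0:
            return False
        i = int(rng.integers(K))
        lo = cps[i - 1] if i > 0 else 0
        hi = cps[i + 1] if i + 1 < K else T
        candidates = range(lo + 1, hi)
        if len(candidates) <= 1:
            return False
        pos = candidates[int(rng.integers(len(candidates)))]
        if pos == cps[i]:  # identical segmentation: identity move
            self.accept_count["changepoint"] += 1
            return True
        new_cps = tuple(sorted(cps[:i] + cps[i + 1 :] + (pos,)))
        if not self._check_seg_lengths(new_cps):
            return False
        return self._transdim_accept(rng, new_cps, 0.0, realloc_at=i)

    def _transdim_accept(
        self, rng, new_cps, log_hr, birth_at=None, death_at=None, realloc_at=None
    ) -> bool:
        """Shared acceptance logic of birth/death/re-allocation.

        Handles the variant-specific re-proposal of parameters for newly
        created segments: M3 flips fair coins for their coupling
        indicators (the coin-count asymmetry of birth/death contributes
        the factor c_tau = 2 resp. 1/2), M4 draws fresh coupling strengths
        from their prior (proposal and prior terms cancel), M1/M2 carry
        no segment-specific parameters.
        """
        T = self.T
        hyp = self.hyper
        log_acc = log_changepoint_prior(
            new_cps, T, hyp.p_cp
        ) - log_changepoint_prior(self.cps, T, hyp.p_cp)
        log_acc += log_hr

        new_delta = self.delta
        new_lam_seg = self.lam_seg
        if self.variant == "M3":
            new_delta, flips_f, flips_r = self._remap_delta(
                rng, birth_at, death_at, realloc_at
            )
            log_acc += (flips_f - flips_r) * math.log(2.0)
            log_acc += _kernels._log_delta_prior(
                np.concatenate(([0], new_delta)).astype(np.int8), hyp.a, hyp.b
            ) - _kernels._log_delta_prior(
                np.concatenate(([0], self.delta)).astype(np.int8), hyp.a, hyp.b
            )
        elif self.variant == "M4":
            new_lam_seg = self._remap_lam_seg(rng, birth_at, death_at, realloc_at)

        lam, couple = self._lam_couple(
            cps=new_cps, delta=new_delta, lam_seg=new_lam_seg
        )
        starts, ends = self._bounds(new_cps)
        logml, d2, wt, ch = self._suite(self._cur_design, starts, ends, lam, couple)
        log_acc += logml - self.log_marginal
        if math.log(rng.random()) < log_acc:
            self.cps = new_cps
            self.delta = new_delta
            self.lam_seg = new_lam_seg
            self._cur_starts, self._cur_ends = starts, ends
            self._lam, self._couple = lam, couple
            self.log_marginal, self._delta2, self._wtilde, self._chols = (
                logml,
                d2,
                wt,
                ch,
            )
            self.accept_count["changepoint"] += 1
            return True
        return False

    def _remap_delta(self, rng, birth_at, death_at, realloc_at):
        """Coupling indicators for the proposed segmentation.

        Segments that stay identical keep their indicator; every newly
        created segment (both children of a birth split, the merged
        segment of a death, both segments adjacent to a re-allocated
        changepoint) gets a fair coin flip — except segment 1, whose
        indicator is the fixed constant 0.  Returns the new delta vector
        together with the forward and reverse flip counts.
        """
        old = list(self.delta)  # entry i <-> segment i+1 (0-based segments)
        if birth_at is not None:
            j = birth_at
            new = old[: max(j - 1, 0)] + [0, 0] + old[j:]
            if j == 0:
                new = new[1:]
            flips_f = 0
            for seg in (j, j + 1):
                if seg >= 1:
                    new[seg - 1] = int(rng.random() < 0.5)
                    flips_f += 1
            flips_r = 1 if j >= 1 else 0  # reverse death re-flips the merged segment
            return np.asarray(new, dtype=np.int8), flips_f, flips_r
        if death_at is not None:
            j = death_at  # merged segment index (0-based)
            new = old[: max(j - 1, 0)] + ([0] if j >= 1 else []) + old[j + 1 :]
            flips_f = 0
            if j >= 1:
                new[j - 1] = int(rng.random() < 0.5)
                flips_f = 1
            flips_r = 2 if j >= 1 else 1  # reverse birth flips both children
            return np.asarray(new, dtype=np.int8), flips_f, flips_r
        i = realloc_at  # segments i and i+1 are re-formed
        new = list(old)
        flips = 0
        for seg in (i, i + 1):
            if seg >= 1:
                new[seg - 1] = int(rng.random() < 0.5)
                flips += 1
        return np.asarray(new, dtype=np.int8), flips, flips

    def _remap_lam_seg(self, rng, birth_at, death_at, realloc_at):
        """Segment-wise coupling strengths (M4) for the proposal.

        New segments draw 1/lambda_h ~ Gamma(alpha_c, beta_c); unchanged
        segments keep their value.
        """
        hyp = self.hyper

        def prior_draw():
            return 1.0 / rng.gamma(hyp.alpha_c, 1.0 / hyp.beta_c)

        old = list(self.lam_seg)
        if birth_at is not None:
            j = birth_at
            new = old[: max(j - 1, 0)] + [0.0, 0.0] + old[j:]
            if j == 0:
                new = new[1:]
            for seg in (j, j + 1):
                if seg >= 1:
                    new[seg - 1] = prior_draw()
            return np.asarray(new)
        if death_at is not None:
            j = death_at
            new = old[: max(j - 1, 0)] + ([0.0] if j >= 1 else []) + old[j + 1 :]
            if j >= 1:
                new[j - 1] = prior_draw()
            return np.asarray(new)
        i = realloc_at
        new = list(old)
        for seg in (i, i + 1):
            if seg >= 1:
                new[seg - 1] = prior_draw()
        return np.asarray(new)

    # ------------------------------------------------------------------
    # chain driver

    def step(self, rng: np.random.Generator) -> None:
        self.gibbs_sweep(rng)
        self.parent_move(rng)
        self.changepoint_move(rng)

    def sample(self) -> PosteriorSample:
        v = self.variant
        return PosteriorSample(
            parents=self.parents,
            changepoints=self.cps,
            lambda_u=float(self.lam_u),
            lambda_c=float(self.lam_c) if v in ("M2", "M3") else None,
            lambda_seg=tuple(float(x) for x in self.lam_seg) if v == "M4" else None,
            delta=tuple(int(d) for d in self.delta) if v == "M3" else None,
            log_marginal=float(self.log_marginal),
        )

    def run(self, rng: np.random.Generator) -> list[PosteriorSample]:
        cfg = self.config
        burn = cfg.burn_in
        out: list[PosteriorSample] = []
        for it in range(1, cfg.iterations + 1):
            self.step(rng)
            if it > burn and (it - burn) % cfg.thinning == 0:
                out.append(self.sample())
        return out


def run_chain(
    task: RegressionTask,
    variant: Variant,
    hyper: CouplingHyper | None = None,
    config: ChainConfig | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> ChainResult:
    """Run one full RJMCMC chain for a target node.

    Fully reproducible: two runs with the same seed produce identical
    sample lists.
    """
    sampler = TargetSampler(task, variant, hyper, config)
    rng = np.random.default_rng(seed)
    samples = sampler.run(rng)
    acc = {
        m: (
            sampler.accept_count[m] / sampler.attempt_count[m]
            if sampler.attempt_count[m]
            else float("nan")
        )
        for m in _MOVE_NAMES
    }
    return ChainResult(samples=samples, acceptance=acc, target_name=task.target_name)
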