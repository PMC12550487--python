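"""No-U-Turn sampler with dual-averaging step-size adaptation.

Gradient-based MCMC for the smooth, fully differentiable posteriors
this package produces.  Three ingredients:

* **Multinomial NUTS trajectories**: each iteration doubles a leapfrog
  trajectory until it starts to turn back on itself, then samples a
  point from it with Boltzmann weights.  Dynamic trajectory lengths are
  what make the hierarchical-scale directions (the "funnel" between a
  family's scale and its non-centred offsets) mix at acceptable cost.
* **Dense mass matrix** (regularised sample covariance of warmup
  draws): the additive effect decompositions are identified through
  sums, leaving long correlated ridges a diagonal metric cannot absorb.
  Dimensions stay in the hundreds, so the O(d^2) leapfrog cost is
  negligible; a diagonal metric kicks in automatically above
  ``dense_mass_max_dim``.
* **Stan-style warmup**: step-size-only head and tail phases around
  expanding covariance-estimation windows, with Nesterov dual averaging
  of the step size toward a target acceptance statistic.

The interface is a single function, :func:`sample`; chains are run
independently by the caller.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Tuple

import numpy as np

__all__ = ["sample", "HMCStats"]

LogpGrad = Callable[[np.ndarray], Tuple[float, np.ndarray]]

_DH_MAX = 1000.0  # energy error treated as divergence


@dataclass
class HMCStats:
    """Per-chain sampler diagnostics."""

    step_size: float
    mean_accept: float
    divergences: int
    n_leapfrog_total: int
    max_treedepth_hits: int = 0


class _Mass:
    """Metric: momenta p ~ N(0, C^{-1}) with C the position covariance.

    Velocity is ``C @ p``; kinetic energy ``p' C p / 2``.  ``cov`` is a
    vector (diagonal metric) or a full matrix.
    """

    def __init__(self, cov: np.ndarray, frozen: Optional[np.ndarray] = None):
        cov = np.array(cov)
        self.frozen = frozen
        if frozen is not None and frozen.any():
            # frozen coordinates: no coupling, unit diagonal (kept
            # positive-definite), zero momentum -> they never move
            if cov.ndim == 2:
                cov[frozen, :] = 0.0
                cov[:, frozen] = 0.0
                cov[frozen, frozen] = 1.0
            else:
                cov[frozen] = 1.0
        self.cov = cov
        self.dense = cov.ndim == 2
        if self.dense:
            self._chol = np.linalg.cholesky(cov)  # C = L L'
        else:
            self._sqrt = np.sqrt(cov)

    def sample_momentum(self, rng: np.random.Generator, dim: int) -> np.ndarray:
        z = rng.standard_normal(dim)
        if self.dense:
            p = np.linalg.solve(self._chol.T, z)  # p = L^{-T} z
        else:
            p = z / self._sqrt
        if self.frozen is not None:
            p[self.frozen] = 0.0
        return p

    def velocity(self, p: np.ndarray) -> np.ndarray:
        return self.cov @ p if self.dense else self.cov * p

    def kinetic(self, p: np.ndarray, v: Optional[np.ndarray] = None) -> float:
        with np.errstate(over="ignore", invalid="ignore"):
            k = 0.5 * float(p @ (self.velocity(p) if v is None else v))
        return k if np.isfinite(k) else np.inf


class _Welford:
    """Streaming mean/(co)variance for mass-matrix estimation."""

    def __init__(self, dim: int, dense: bool):
        self.n = 0
        self.dense = dense
        self.mean = np.zeros(dim)
        self.m2 = np.zeros((dim, dim)) if dense else np.zeros(dim)

    def push(self, x: np.ndarray) -> None:
        self.n += 1
        d = x - self.mean
        self.mean += d / self.n
        d2 = x - self.mean
        self.m2 += np.outer(d, d2) if self.dense else d * d2

    def covariance(self) -> np.ndarray:
        if self.n < 5:
            dim = self.mean.size
            return np.eye(dim) if self.dense else np.ones(dim)
        cov = self.m2 / (self.n - 1)
        w = self.n / (self.n + 5.0)  # Stan-style shrinkage
        if self.dense:
            return w * cov + 1e-3 * (1 - w) * np.eye(self.mean.size)
        return w * cov + 1e-3 * (1 - w)


class _DualAveraging:
    """Nesterov dual averaging of log step size (Stan's schedule)."""

    def __init__(self, eps0: float, target: float,
                 gamma: float = 0.05, t0: float = 10.0, kappa: float = 0.75):
        self.target = target
        self.gamma, self.t0, self.kappa = gamma, t0, kappa
        self.restart(eps0)

    def restart(self, eps: float) -> None:
        self.mu = math.log(10.0 * eps)
        self.log_eps = math.log(eps)
        self.log_eps_bar = math.log(eps)
        self.h_bar = 0.0
        self.count = 0

    def update(self, accept_stat: float) -> float:
        self.count += 1
        m = self.count
        eta = 1.0 / (m + self.t0)
        self.h_bar = (1 - eta) * self.h_bar + eta * (self.target - accept_stat)
        self.log_eps = self.mu - math.sqrt(m) / self.gamma * self.h_bar
        w = m ** (-self.kappa)
        self.log_eps_bar = w * self.log_eps + (1 - w) * self.log_eps_bar
        return math.exp(self.log_eps)

    @property
    def adapted(self) -> float:
        return math.exp(self.log_eps_bar)


class _State:
    """One phase-space point with cached density, gradient, velocity."""

    __slots__ = ("x", "p", "lp", "grad", "v")

    def __init__(self, x, p, lp, grad, v):
        self.x, self.p, self.lp, self.grad, self.v = x, p, lp, grad, v


class _Tree:
    """A NUTS subtree: ends, multinomial proposal, bookkeeping."""

    __slots__ = ("minus", "plus", "prop", "log_w", "sum_accept", "n_steps",
                 "turning", "diverged")

    def __init__(self, minus, plus, prop, log_w, sum_accept, n_steps,
                 turning, diverged):
        self.minus, self.plus, self.prop = minus, plus, prop
        self.log_w, self.sum_accept = log_w, sum_accept
        self.n_steps = n_steps
        self.turning, self.diverged = turning, diverged


def _logaddexp(a: float, b: float) -> float:
    if a == -math.inf:
        return b
    if b == -math.inf:
        return a
    m = a if a > b else b
    return m + math.log(math.exp(a - m) + math.exp(b - m))


def _leapfrog(logp_grad: LogpGrad, s: _State, eps: float, mass: _Mass
              ) -> Optional[_State]:
    p = s.p + 0.5 * eps * s.grad
    x = s.x + eps * mass.velocity(p)
    lp, grad = logp_grad(x)
    if not np.isfinite(lp):
        return None
    p = p + 0.5 * eps * grad
    return _State(x, p, lp, grad, mass.velocity(p))


def _uturn(minus: _State, plus: _State) -> bool:
    dx = plus.x - minus.x
    return float(dx @ minus.v) < 0.0 or float(dx @ plus.v) < 0.0


def _build_tree(logp_grad, s: _State, depth: int, direction: int, eps: float,
                mass: _Mass, h0: float, rng: np.random.Generator) -> _Tree:
    if depth == 0:
        nxt = _leapfrog(logp_grad, s, direction * eps, mass)
        if nxt is None:
            return _Tree(s, s, s, -np.inf, 0.0, 1, False, True)
        h = -nxt.lp + mass.kinetic(nxt.p, nxt.v)
        dh = h - h0
        if not math.isfinite(dh) or dh > _DH_MAX:
            return _Tree(nxt, nxt, nxt, -np.inf, 0.0, 1, False, True)
        return _Tree(nxt, nxt, nxt, -dh, math.exp(-dh) if dh > 0 else 1.0, 1,
                     False, False)

    first = _build_tree(logp_grad, s, depth - 1, direction, eps, mass, h0, rng)
    if first.turning or first.diverged:
        return first
    edge = first.plus if direction == 1 else first.minus
    second = _build_tree(logp_grad, edge, depth - 1, direction, eps, mass,
                         h0, rng)
    n_steps = first.n_steps + second.n_steps
    sum_accept = first.sum_accept + second.sum_accept
    if second.turning or second.diverged:
        return _Tree(first.minus, first.plus, first.prop, first.log_w,
                     sum_accept, n_steps, second.turning, second.diverged)
    log_w = _logaddexp(first.log_w, second.log_w)
    # multinomial sampling between the two halves
    prop = first.prop
    if math.log(rng.uniform()) < second.log_w - log_w:
        prop = second.prop
    minus = first.minus if direction == 1 else second.minus
    plus = second.plus if direction == 1 else first.plus
    return _Tree(minus, plus, prop, log_w, sum_accept, n_steps,
                 _uturn(minus, plus), False)


def _nuts_step(logp_grad, x, lp, grad, eps, mass, rng, max_depth):
    """One NUTS transition; returns (x, lp, grad, accept_stat, diverged,
    depth_hit, n_leapfrog)."""
    dim = x.size
    p0 = mass.sample_momentum(rng, dim)
    h0 = -lp + mass.kinetic(p0)
    here = _State(x, p0, lp, grad, mass.velocity(p0))
    tree = _Tree(here, here, here, 0.0, 0.0, 0, False, False)
    diverged = False
    depth = 0
    n_leapfrog = 0
    while depth < max_depth:
        direction = 1 if rng.uniform() < 0.5 else -1
        edge = tree.plus if direction == 1 else tree.minus
        sub = _build_tree(logp_grad, edge, depth, direction, eps, mass, h0, rng)
        n_leapfrog += sub.n_steps
        if sub.diverged:
            diverged = True
        if sub.diverged or sub.turning:
            break
        # progressive sampling biased toward the new subtree
        if math.log(rng.uniform()) < sub.log_w - tree.log_w:
            tree.prop = sub.prop
        tree.log_w = _logaddexp(tree.log_w, sub.log_w)
        tree.sum_accept += sub.sum_accept
        tree.n_steps += sub.n_steps
        if direction == 1:
            tree.plus = sub.plus
        else:
            tree.minus = sub.minus
        depth += 1
        if _uturn(tree.minus, tree.plus):
            break
    # average Metropolis statistic over every leapfrog step taken,
    # including a rejected final subtree (informs step-size adaptation)
    accept_stat = (tree.sum_accept + (sub.sum_accept if (sub.diverged or
                   sub.turning) else 0.0)) / max(n_leapfrog, 1)
    prop = tree.prop
    return (prop.x, prop.lp, prop.grad, accept_stat, diverged,
            depth >= max_depth, n_leapfrog)


def slice_sample_1d(logf: Callable[[float], float], x0: float,
                    rng: np.random.Generator, width: float = 1.0,
                    max_steps: int = 50) -> float:
    """One univariate slice-sampling update (stepping out + shrinkage)."""
    f0 = logf(x0)
    y = f0 - rng.exponential()
    lo = x0 - width * rng.uniform()
    hi = lo + width
    for _ in range(max_steps):
        if logf(lo) <= y:
            break
        lo -= width
    for _ in range(max_steps):
        if logf(hi) <= y:
            break
        hi += width
    for _ in range(100):
        x1 = rng.uniform(lo, hi)
        if logf(x1) > y:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1
    return x0


def _find_initial_step(logp_grad: LogpGrad, x: np.ndarray, mass: _Mass,
                       rng: np.random.Generator) -> float:
    """Double/halve until one leapfrog step has acceptance near 1/2."""
    lp0, g0 = logp_grad(x)
    p = mass.sample_momentum(rng, x.size)
    h0 = -lp0 + mass.kinetic(p)
    s = _State(x, p, lp0, g0, mass.velocity(p))

    def delta_h(eps: float) -> float:
        nxt = _leapfrog(logp_grad, s, eps, mass)
        if nxt is None:
            return np.inf
        return (-nxt.lp + mass.kinetic(nxt.p)) - h0

    eps = 1.0
    dh = delta_h(eps)
    direction = 1 if dh < math.log(2.0) else -1
    for _ in range(60):
        eps_new = eps * (2.0 if direction == 1 else 0.5)
        dh = delta_h(eps_new)
        if direction == 1 and not (dh < math.log(2.0)):
            break
        if direction == -1 and not (dh > math.log(2.0)):
            eps = eps_new
            break
        eps = eps_new
    return eps


def sample(
    logp_grad: LogpGrad,
    x0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    *,
    target_accept: float = 0.85,
    max_depth: int = 9,
    dense_mass: Optional[bool] = None,
    dense_mass_max_dim: int = 600,
    interleave: Optional[Callable[[np.ndarray, np.random.Generator],
                                  np.ndarray]] = None,
    frozen: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, HMCStats]:
    """Run one NUTS chain.

    Parameters
    ----------
    logp_grad : callable
        Returns ``(log density, gradient)`` at a point; ``-inf`` marks
        the boundary of the representable region.
    x0 : ndarray
        Initial position.
    n_warmup, n_draws : int
        Adaptation iterations (discarded) and retained draws.
    rng : numpy Generator
        Sole source of randomness; fixes the chain bit-for-bit.
    target_accept : float
        Dual-averaging target for the mean Metropolis statistic.
    max_depth : int
        Trajectory doubling limit (at most ``2^max_depth`` leapfrog
        steps per iteration).
    interleave : callable, optional
        Extra posterior-preserving transition composed after every NUTS
        step (e.g. interweaved Gibbs updates of hierarchical scales);
        receives and returns a position vector.
    frozen : boolean ndarray, optional
        Coordinates held fixed during NUTS steps (blocked-Gibbs: they
        must be updated by ``interleave`` instead).  Freezing the
        hierarchical locations/scales removes the funnel curvature from
        the trajectories.
    """
    x = np.array(x0, dtype=float)
    dim = x.size
    if dense_mass is None:
        dense_mass = dim <= dense_mass_max_dim
    if frozen is not None and frozen.any():
        inner = logp_grad

        def logp_grad(q, _inner=inner, _frozen=frozen):
            lp, g = _inner(q)
            if g is not None:
                g = g.copy()
                g[_frozen] = 0.0
            return lp, g
    mass = _Mass(np.eye(dim) if dense_mass else np.ones(dim), frozen)

    eps = _find_initial_step(logp_grad, x, mass, rng)
    da = _DualAveraging(eps, target_accept)

    head = min(75, max(10, int(0.15 * n_warmup)))
    tail = min(100, max(10, int(0.10 * n_warmup)))
    window_end = []
    w = 25
    pos = head
    while pos + w < n_warmup - tail:
        pos += w
        window_end.append(pos)
        w *= 2
    window_end.append(n_warmup - tail)

    welford = _Welford(dim, dense_mass)
    lp, grad = logp_grad(x)
    draws = np.empty((n_draws, dim))
    accept_sum = 0.0
    divergences = 0
    depth_hits = 0
    n_leapfrog_total = 0
    win_i = 0

    for it in range(n_warmup + n_draws):
        warming = it < n_warmup
        x, lp, grad, accept_stat, diverged, depth_hit, n_lf = _nuts_step(
            logp_grad, x, lp, grad, eps, mass, rng, max_depth)
        n_leapfrog_total += n_lf
        if interleave is not None:
            x = interleave(x, rng)
            lp, grad = logp_grad(x)

        if warming:
            eps = da.update(accept_stat)
            if head <= it < n_warmup - tail:
                welford.push(x)
                if win_i < len(window_end) and it + 1 == window_end[win_i]:
                    mass = _Mass(welford.covariance(), frozen)
                    welford = _Welford(dim, dense_mass)
                    win_i += 1
                    da.restart(max(da.adapted, 1e-10))
            if it + 1 == n_warmup:
                eps = da.adapted
        else:
            accept_sum += accept_stat
            divergences += int(diverged)
            depth_hits += int(depth_hit)
            draws[it - n_warmup] = x

    stats = HMCStats(
        step_size=eps,
        mean_accept=accept_sum / max(n_draws, 1),
        divergences=divergences,
        n_leapfrog_total=n_leapfrog_total,
        max_treedepth_hits=depth_hits,
    )
    return draws, stats
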