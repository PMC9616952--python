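"""No-U-Turn sampler with dual-averaging step size and diagonal mass adaptation.

A self-contained implementation of dynamic Hamiltonian Monte Carlo for
differentiable log posteriors: multiplicative slice variant of the
no-u-turn criterion, divergence detection, Nesterov dual averaging toward a
target acceptance statistic, and windowed estimation of a diagonal inverse
mass matrix during warmup. The caller supplies ``logp_and_grad(x) ->
(float, ndarray)`` on the unconstrained scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["sample_nuts", "NUTSStats"]

_DIVERGENCE_THRESHOLD = 1000.0  # drop in joint log density treated as divergent


@dataclass
class NUTSStats:
    step_size: float
    inv_mass: np.ndarray
    divergences: int = 0
    accept_stat: list = field(default_factory=list)
    tree_depth: list = field(default_factory=list)
    n_grad_evals: int = 0


class _System:
    """Bundles the target, metric and counters for one chain."""

    def __init__(self, logp_and_grad, inv_mass):
        self._f = logp_and_grad
        self.inv_mass = inv_mass
        self.sqrt_mass = 1.0 / np.sqrt(inv_mass)
        self.n_evals = 0

    def set_inv_mass(self, inv_mass):
        self.inv_mass = inv_mass
        self.sqrt_mass = 1.0 / np.sqrt(inv_mass)

    def logp_grad(self, q):
        self.n_evals += 1
        return self._f(q)

    def kinetic(self, p):
        return 0.5 * float(np.dot(p * p, self.inv_mass))

    def draw_momentum(self, rng, dim):
        return rng.standard_normal(dim) * self.sqrt_mass

    def leapfrog(self, q, p, grad, eps):
        p = p + 0.5 * eps * grad
        q = q + eps * (self.inv_mass * p)
        logp, grad = self.logp_grad(q)
        p = p + 0.5 * eps * grad
        return q, p, logp, grad


def _find_reasonable_epsilon(system, q, logp, grad, rng):
    eps = 1.0
    p = system.draw_momentum(rng, q.size)
    h0 = logp - system.kinetic(p)
    q1, p1, logp1, _ = system.leapfrog(q, p, grad, eps)
    h1 = logp1 - system.kinetic(p1)
    if not np.isfinite(h1):
        h1 = -np.inf
    direction = 1.0 if (h1 - h0) > math.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0**direction
        q1, p1, logp1, _ = system.leapfrog(q, p, grad, eps)
        h1 = logp1 - system.kinetic(p1)
        if not np.isfinite(h1):
            h1 = -np.inf
        if direction * (h1 - h0) < direction * math.log(0.5):
            break
    return max(eps, 1e-8)


class _DualAveraging:
    def __init__(self, eps0, target, gamma=0.05, t0=10.0, kappa=0.75):
        self.mu = math.log(10.0 * eps0)
        self.target = target
        self.gamma, self.t0, self.kappa = gamma, t0, kappa
        self.log_eps = math.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.count = 0

    def update(self, accept_stat):
        self.count += 1
        m = self.count
        eta = 1.0 / (m + self.t0)
        self.h_bar = (1 - eta) * self.h_bar + eta * (self.target - accept_stat)
        self.log_eps = self.mu - math.sqrt(m) / self.gamma * self.h_bar
        w = m ** (-self.kappa)
        self.log_eps_bar = w * self.log_eps + (1 - w) * self.log_eps_bar
        return math.exp(self.log_eps)

    def restart(self, eps0):
        self.mu = math.log(10.0 * eps0)
        self.log_eps = math.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.count = 0

    @property
    def averaged(self):
        return math.exp(self.log_eps_bar)


class _Welford:
    def __init__(self, dim):
        self.n = 0
        self.mean = np.zeros(dim)
        self.m2 = np.zeros(dim)

    def push(self, x):
        self.n += 1
        d = x - self.mean
        self.mean += d / self.n
        self.m2 += d * (x - self.mean)

    def regularized_variance(self):
        # shrink toward unit scale as Stan does, so short windows stay sane
        if self.n < 3:
            return None
        var = self.m2 / (self.n - 1)
        w = self.n / (self.n + 5.0)
        return w * var + 1e-3 * (1 - w) * np.ones_like(var)


def _uturn(system, q_minus, q_plus, p_minus, p_plus):
    dq = q_plus - q_minus
    return (
        np.dot(dq, system.inv_mass * p_minus) < 0
        or np.dot(dq, system.inv_mass * p_plus) < 0
    )


def _build_tree(system, rng, q, p, grad, log_u, direction, depth, eps, h0):
    """Recursively double the trajectory; returns the subtree summary."""
    if depth == 0:
        q1, p1, logp1, grad1 = system.leapfrog(q, p, grad, direction * eps)
        h1 = logp1 - system.kinetic(p1)
        if not np.isfinite(h1):
            h1 = -np.inf
        n1 = 1 if log_u <= h1 else 0
        diverged = log_u - _DIVERGENCE_THRESHOLD >= h1
        alpha = min(1.0, math.exp(min(0.0, h1 - h0)))
        return dict(
            q_minus=q1, p_minus=p1, grad_minus=grad1,
            q_plus=q1, p_plus=p1, grad_plus=grad1,
            q_prop=q1, logp_prop=logp1, grad_prop=grad1,
            n=n1, cont=not diverged, diverged=diverged,
            alpha=alpha, n_alpha=1,
        )
    t1 = _build_tree(system, rng, q, p, grad, log_u, direction, depth - 1, eps, h0)
    if not t1["cont"]:
        return t1
    if direction == 1:
        t2 = _build_tree(
            system, rng, t1["q_plus"], t1["p_plus"], t1["grad_plus"],
            log_u, direction, depth - 1, eps, h0,
        )
        t1["q_plus"], t1["p_plus"], t1["grad_plus"] = t2["q_plus"], t2["p_plus"], t2["grad_plus"]
    else:
        t2 = _build_tree(
            system, rng, t1["q_minus"], t1["p_minus"], t1["grad_minus"],
            log_u, direction, depth - 1, eps, h0,
        )
        t1["q_minus"], t1["p_minus"], t1["grad_minus"] = t2["q_minus"], t2["p_minus"], t2["grad_minus"]
    n_tot = t1["n"] + t2["n"]
    if n_tot > 0 and rng.random() < t2["n"] / n_tot:
        t1["q_prop"], t1["logp_prop"], t1["grad_prop"] = t2["q_prop"], t2["logp_prop"], t2["grad_prop"]
    t1["n"] = n_tot
    t1["alpha"] += t2["alpha"]
    t1["n_alpha"] += t2["n_alpha"]
    t1["diverged"] = t1["diverged"] or t2["diverged"]
    t1["cont"] = (
        t2["cont"]
        and not _uturn(system, t1["q_minus"], t1["q_plus"], t1["p_minus"], t1["p_plus"])
    )
    return t1


def _nuts_transition(system, rng, q, logp, grad, eps, max_treedepth):
    p0 = system.draw_momentum(rng, q.size)
    h0 = logp - system.kinetic(p0)
    log_u = h0 - rng.exponential()
    state = dict(
        q_minus=q, p_minus=p0, grad_minus=grad,
        q_plus=q, p_plus=p0, grad_plus=grad,
    )
    q_new, logp_new, grad_new = q, logp, grad
    n = 1
    depth = 0
    diverged = False
    alpha_sum, n_alpha = 0.0, 0
    while depth < max_treedepth:
        direction = 1 if rng.random() < 0.5 else -1
        if direction == 1:
            t = _build_tree(
                system, rng, state["q_plus"], state["p_plus"], state["grad_plus"],
                log_u, 1, depth, eps, h0,
            )
            state["q_plus"], state["p_plus"], state["grad_plus"] = t["q_plus"], t["p_plus"], t["grad_plus"]
        else:
            t = _build_tree(
                system, rng, state["q_minus"], state["p_minus"], state["grad_minus"],
                log_u, -1, depth, eps, h0,
            )
            state["q_minus"], state["p_minus"], state["grad_minus"] = t["q_minus"], t["p_minus"], t["grad_minus"]
        alpha_sum += t["alpha"]
        n_alpha += t["n_alpha"]
        diverged = diverged or t["diverged"]
        if t["cont"] and t["n"] > 0 and rng.random() < min(1.0, t["n"] / n):
            q_new, logp_new, grad_new = t["q_prop"], t["logp_prop"], t["grad_prop"]
        n += t["n"]
        depth += 1
        if not t["cont"] or _uturn(
            system, state["q_minus"], state["q_plus"], state["p_minus"], state["p_plus"]
        ):
            break
    accept_stat = alpha_sum / max(n_alpha, 1)
    return q_new, logp_new, grad_new, accept_stat, depth, diverged


def _warmup_windows(n_warmup):
    """(start, end) index pairs of mass-adaptation windows, Stan-style."""
    init_buffer = max(min(75, n_warmup // 5), 1)
    term_buffer = max(min(50, n_warmup // 10), 1)
    windows = []
    start = init_buffer
    size = 25
    while start < n_warmup - term_buffer:
        end = min(start + size, n_warmup - term_buffer)
        # absorb a trailing sliver into the final window
        if (n_warmup - term_buffer) - end < size:
            end = n_warmup - term_buffer
        windows.append((start, end))
        start = end
        size *= 2
    return windows


def sample_nuts(
    logp_and_grad,
    x0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    target_accept: float = 0.95,
    max_treedepth: int = 10,
    adapt_mass: bool = True,
):
    """Run one NUTS chain; returns ``(draws, NUTSStats)``.

    ``draws`` has shape ``(n_draws, dim)`` and contains only post-warmup
    states. Fully deterministic given ``rng``'s state.
    """
    q = np.array(x0, dtype=float)
    dim = q.size
    system = _System(logp_and_grad, np.ones(dim))
    logp, grad = system.logp_grad(q)
    if not np.isfinite(logp):
        raise ValueError("initial point has non-finite log posterior")

    eps = _find_reasonable_epsilon(system, q, logp, grad, rng)
    da = _DualAveraging(eps, target_accept)
    windows = _warmup_windows(n_warmup) if adapt_mass else []
    welford = _Welford(dim)
    window_idx = 0

    stats = NUTSStats(step_size=eps, inv_mass=system.inv_mass.copy())
    draws = np.empty((n_draws, dim))

    for it in range(n_warmup + n_draws):
        q, logp, grad, accept_stat, depth, diverged = _nuts_transition(
            system, rng, q, logp, grad, eps, max_treedepth
        )
        if it < n_warmup:
            eps = da.update(accept_stat)
            if window_idx < len(windows):
                w_start, w_end = windows[window_idx]
                if w_start <= it < w_end:
                    welford.push(q)
                if it == w_end - 1:
                    var = welford.regularized_variance()
                    if var is not None:
                        system.set_inv_mass(var)
                    welford = _Welford(dim)
                    window_idx += 1
                    eps = _find_reasonable_epsilon(system, q, logp, grad, rng)
                    da.restart(eps)
            if it == n_warmup - 1:
                eps = da.averaged
                stats.step_size = eps
                stats.inv_mass = system.inv_mass.copy()
        else:
            draws[it - n_warmup] = q
            stats.accept_stat.append(accept_stat)
            stats.tree_depth.append(depth)
            if diverged:
                stats.divergences += 1
    stats.n_grad_evals = system.n_evals
    return draws, stats
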