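"""Adaptive Hamiltonian Monte Carlo with dual-averaging step-size and
diagonal mass-matrix adaptation.

A compact, dependency-free HMC used by :mod:`harmalloc.hierarchical`.
Warmup follows the usual windowed schedule: an initial step-size-only
phase, a sequence of doubling covariance-estimation windows updating the
diagonal inverse mass, and a final step-size-only phase.  Trajectory
lengths are jittered to avoid resonance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

LogpGrad = Callable[[np.ndarray], tuple[float, np.ndarray]]

DIVERGENCE_ENERGY = 1000.0

#: hard bound on unconstrained coordinates; proposals beyond it are
#: rejected.  All supported models put negligible prior mass out there,
#: and without the bound a wild warmup trajectory can strand a chain so
#: far out that the adapted mass matrix freezes the coordinate.
POSITION_BOUND = 50.0


@dataclass
class ChainStats:
    step_size: float
    inv_mass: np.ndarray
    accept_rate: float
    divergences: int
    energies: np.ndarray


def _leapfrog(logp_grad: LogpGrad, x, p, grad, eps, inv_mass, n_steps):
    x, p, grad = x.copy(), p.copy(), grad
    for _ in range(n_steps):
        p = p + 0.5 * eps * grad
        x = x + eps * inv_mass * p
        if np.any(np.abs(x) > POSITION_BOUND):
            return x, p, -np.inf, grad
        lp, grad = logp_grad(x)
        if not np.isfinite(lp):
            return x, p, lp, grad
        p = p + 0.5 * eps * grad
    return x, p, lp, grad


def _find_initial_step(logp_grad, x0, inv_mass, rng) -> float:
    """Heuristic: double/halve until the one-step acceptance crosses 0.5."""
    eps = 0.1
    lp0, grad0 = logp_grad(x0)
    p0 = rng.standard_normal(x0.size) / np.sqrt(inv_mass)
    h0 = lp0 - 0.5 * np.sum(inv_mass * p0 * p0)
    x, p, lp, _ = _leapfrog(logp_grad, x0, p0, grad0, eps, inv_mass, 1)
    h = lp - 0.5 * np.sum(inv_mass * p * p) if np.isfinite(lp) else -np.inf
    direction = 1.0 if (h - h0) > np.log(0.5) else -1.0
    for _ in range(50):
        eps = eps * (2.0 ** direction)
        x, p, lp, _ = _leapfrog(logp_grad, x0, p0, grad0, eps, inv_mass, 1)
        h = lp - 0.5 * np.sum(inv_mass * p * p) if np.isfinite(lp) else -np.inf
        crossed = (h - h0) > np.log(0.5)
        if (direction > 0 and not crossed) or (direction < 0 and crossed):
            break
    return float(eps)


def _warmup_windows(n_warmup: int) -> list[tuple[int, int, bool]]:
    """(start, end, adapt_mass) windows covering [0, n_warmup)."""
    init = max(5, int(0.15 * n_warmup))
    term = max(5, int(0.10 * n_warmup))
    windows = [(0, init, False)]
    start, size = init, max(10, int(0.0625 * n_warmup))
    while start < n_warmup - term:
        end = min(start + size, n_warmup - term)
        # absorb a remainder too small to estimate a variance from
        if (n_warmup - term - end) < size:
            end = n_warmup - term
        windows.append((start, end, True))
        start, size = end, size * 2
    windows.append((n_warmup - term, n_warmup, False))
    return windows


def sample_chain(
    logp_grad: LogpGrad,
    x0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    target_accept: float = 0.8,
    max_leapfrog: int = 128,
    traj_length: float = 6.0,
) -> tuple[np.ndarray, ChainStats]:
    """Run one HMC chain; returns (draws[n_draws, dim], stats)."""
    dim = x0.size
    x = np.asarray(x0, float).copy()
    inv_mass = np.ones(dim)
    lp, grad = logp_grad(x)
    if not np.isfinite(lp):
        raise FloatingPointError("non-finite log density at the initial point")

    eps = _find_initial_step(logp_grad, x, inv_mass, rng)
    # floor below which adaptation may not drive the step size; guards
    # against collapse when a chain wanders into a funnel neck
    eps_floor = 0.1 * eps
    # dual averaging state (Hoffman & Gelman defaults)
    mu_da, log_eps_bar, h_bar = np.log(10.0 * eps), 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    da_count = 0

    divergences = 0
    accepts: list[float] = []
    draws = np.empty((n_draws, dim))
    energies = np.empty(n_draws)
    windows = _warmup_windows(n_warmup)
    window_buf: list[np.ndarray] = []

    def one_step(eps_use):
        nonlocal x, lp, grad, divergences
        p0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        h0 = lp - 0.5 * np.sum(inv_mass * p0 * p0)
        n_max = max(1, min(max_leapfrog, int(np.ceil(traj_length / eps_use))))
        n_lo = max(1, int(0.5 * n_max))
        n_steps = int(rng.integers(n_lo, n_max + 1))
        x_new, p_new, lp_new, grad_new = _leapfrog(
            logp_grad, x, p0, grad, eps_use, inv_mass, n_steps
        )
        if np.isfinite(lp_new):
            h_new = lp_new - 0.5 * np.sum(inv_mass * p_new * p_new)
            delta = h_new - h0
        else:
            delta = -np.inf
        if delta < -DIVERGENCE_ENERGY:
            divergences += 1
        a_prob = min(1.0, np.exp(min(0.0, delta))) if np.isfinite(delta) else 0.0
        if rng.random() < a_prob:
            x, lp, grad = x_new, lp_new, grad_new
        return a_prob, lp

    it = 0
    for (w_start, w_end, adapt_mass) in windows:
        window_buf = []
        for it in range(w_start, w_end):
            a_prob, _ = one_step(eps)
            # dual averaging update
            da_count += 1
            frac = 1.0 / (da_count + t0)
            h_bar = (1 - frac) * h_bar + frac * (target_accept - a_prob)
            log_eps = mu_da - np.sqrt(da_count) / gamma * h_bar
            w = da_count ** (-kappa)
            log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
            eps = max(float(np.exp(log_eps)), eps_floor)
            if adapt_mass:
                window_buf.append(x.copy())
        if adapt_mass and len(window_buf) >= 10:
            arr = np.asarray(window_buf)
            n = arr.shape[0]
            var = arr.var(axis=0, ddof=1)
            inv_mass = (n / (n + 5.0)) * var + 1e-3 * (5.0 / (n + 5.0))
            # restart step-size adaptation around the current value;
            # the floor only ratchets up so a chain that wanders into a
            # funnel neck cannot drag it down with it
            eps = _find_initial_step(logp_grad, x, inv_mass, rng)
            eps_floor = max(eps_floor, 0.1 * eps)
            mu_da, log_eps_bar, h_bar, da_count = np.log(10.0 * eps), 0.0, 0.0, 0

    eps = max(float(np.exp(log_eps_bar)), eps_floor) if n_warmup > 0 else eps
    divergences = 0  # count only post-warmup divergences
    for i in range(n_draws):
        a_prob, lp_cur = one_step(eps)
        accepts.append(a_prob)
        draws[i] = x
        energies[i] = lp_cur
    stats = ChainStats(
        step_size=eps,
        inv_mass=inv_mass,
        accept_rate=float(np.mean(accepts)) if accepts else float("nan"),
        divergences=divergences,
        energies=energies,
    )
    return draws, stats
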