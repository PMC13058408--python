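"""Hamiltonian Monte Carlo for the outcome models.

A fixed-length leapfrog HMC sampler with a diagonal mass matrix taken from
a Laplace approximation at the posterior mode and per-chain step sizes
tuned by dual averaging during burn-in toward a target acceptance
probability (0.8 by default, matching the analysis settings). All chains
run as one vectorised batch, so a fit costs a few hundred batched
gradient evaluations regardless of the chain count.

The log-posterior callable must accept positions of shape (chains, dim)
and return (logp (chains,), grad (chains, dim)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["run_hmc", "HmcResult"]


@dataclass
class HmcResult:
    draws: np.ndarray          # (chains, kept_iterations, dim)
    accept_rate: np.ndarray    # (chains,)
    step_size: np.ndarray      # (chains,)
    n_divergent: int


def _leapfrog(logp_and_grad, x, p, eps, inv_mass, n_steps):
    logp, grad = logp_and_grad(x)
    p = p + 0.5 * eps[:, None] * grad
    for step in range(n_steps):
        x = x + eps[:, None] * (inv_mass * p)
        logp, grad = logp_and_grad(x)
        if step < n_steps - 1:
            p = p + eps[:, None] * grad
    p = p + 0.5 * eps[:, None] * grad
    return x, p, logp


def run_hmc(logp_and_grad, x0: np.ndarray, n_iterations: int, burn_in: int,
            rng: np.random.Generator, inv_mass: np.ndarray | None = None,
            target_accept: float = 0.8,
            leapfrog_range: tuple[int, int] = (5, 10)) -> HmcResult:
    """Sample ``n_iterations`` per chain, discarding the first ``burn_in``.

    ``x0`` has shape (chains, dim); ``inv_mass`` is the diagonal inverse
    mass (posterior variance estimate per coordinate), shaped (dim,) or
    (chains, dim). The leapfrog length is jittered uniformly over
    ``leapfrog_range`` to avoid resonance.
    """
    x = np.array(x0, dtype=float)
    n_chains, dim = x.shape
    if inv_mass is None:
        inv_mass = np.ones(dim)
    inv_mass = np.broadcast_to(np.atleast_2d(inv_mass), (n_chains, dim))
    sqrt_mass = np.sqrt(1.0 / inv_mass)

    eps = np.full(n_chains, 0.25)
    # dual-averaging state (Hoffman & Gelman constants)
    mu_da = np.log(10.0 * eps)
    log_eps_bar = np.zeros(n_chains)
    h_bar = np.zeros(n_chains)
    gamma, t0, kappa = 0.05, 10.0, 0.75

    logp_cur, _ = logp_and_grad(x)
    if not np.all(np.isfinite(logp_cur)):
        raise FloatingPointError("non-finite log posterior at the initial point")

    kept = n_iterations - burn_in
    draws = np.empty((n_chains, kept, dim))
    n_accept = np.zeros(n_chains)
    n_divergent = 0

    for it in range(n_iterations):
        p0 = rng.standard_normal((n_chains, dim)) * sqrt_mass
        n_steps = int(rng.integers(leapfrog_range[0], leapfrog_range[1] + 1))
        x_new, p_new, logp_new = _leapfrog(logp_and_grad, x, p0, eps,
                                           inv_mass, n_steps)
        ke0 = 0.5 * np.sum(p0 ** 2 * inv_mass, axis=1)
        ke1 = 0.5 * np.sum(p_new ** 2 * inv_mass, axis=1)
        log_ratio = (logp_new - ke1) - (logp_cur - ke0)
        log_ratio = np.where(np.isfinite(log_ratio), log_ratio, -np.inf)
        n_divergent += int(np.sum(log_ratio < -1000))
        accept_prob = np.exp(np.minimum(0.0, log_ratio))
        accepted = rng.random(n_chains) < accept_prob
        x = np.where(accepted[:, None], x_new, x)
        logp_cur = np.where(accepted, logp_new, logp_cur)

        if it < burn_in:
            t = it + 1
            h_bar = (1 - 1 / (t + t0)) * h_bar + (
                (target_accept - accept_prob) / (t + t0))
            log_eps = mu_da - np.sqrt(t) / gamma * h_bar
            w = t ** (-kappa)
            log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
            eps = np.exp(log_eps)
            if it == burn_in - 1:
                eps = np.exp(log_eps_bar)
        else:
            draws[:, it - burn_in, :] = x
            n_accept += accepted

    return HmcResult(draws=draws, accept_rate=n_accept / max(kept, 1),
                     step_size=eps, n_divergent=n_divergent)
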