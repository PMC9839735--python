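"""A compact Hamiltonian Monte Carlo sampler with warmup adaptation.

Implements the standard recipe: leapfrog integration with a jittered number
of steps, dual-averaging step-size adaptation toward a target acceptance
rate, and windowed diagonal mass-matrix estimation during warmup.  A
transition whose energy error exceeds ``DIVERGENCE_THRESHOLD`` is flagged as
divergent and rejected, mirroring the usual validity check for hierarchical
posteriors.

The sampler takes an arbitrary ``logp_grad(x) -> (logp, grad)`` callable, so
it is reusable for any differentiable unconstrained-space density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["sample_chain", "sample", "ChainResult", "DIVERGENCE_THRESHOLD"]

DIVERGENCE_THRESHOLD = 1000.0


@dataclass
class ChainResult:
    draws: np.ndarray        # (n_draws, dim)
    divergences: int         # post-warmup divergent transitions
    accept_rate: float
    step_size: float
    mass_diag: np.ndarray
    logp: np.ndarray         # (n_draws,)


def _leapfrog(logp_grad, x, p, eps, n_steps, inv_mass):
    logp, grad = logp_grad(x)
    for _ in range(n_steps):
        p = p + 0.5 * eps * grad
        x = x + eps * (inv_mass * p)
        logp, grad = logp_grad(x)
        if not np.isfinite(logp):
            return x, p, -np.inf, grad
        p = p + 0.5 * eps * grad
    return x, p, logp, grad


def _initial_step_size(logp_grad, x0, rng, inv_mass):
    """Stan-style heuristic: double/halve until acceptance crosses 0.5."""
    eps = 1.0
    logp0, _ = logp_grad(x0)
    p0 = rng.normal(size=x0.shape) / np.sqrt(inv_mass)
    h0 = logp0 - 0.5 * np.sum(inv_mass * p0**2)
    _, p1, logp1, _ = _leapfrog(logp_grad, x0, p0, eps, 1, inv_mass)
    h1 = logp1 - 0.5 * np.sum(inv_mass * p1**2)
    delta = h1 - h0
    direction = 1 if delta > np.log(0.8) else -1
    for _ in range(50):
        eps *= 2.0**direction
        _, p1, logp1, _ = _leapfrog(logp_grad, x0, p0, eps, 1, inv_mass)
        h1 = logp1 - 0.5 * np.sum(inv_mass * p1**2)
        delta = h1 - h0 if np.isfinite(logp1) else -np.inf
        if direction == 1 and delta <= np.log(0.8):
            break
        if direction == -1 and delta >= np.log(0.8):
            break
    return max(eps, 1e-8)


def sample_chain(logp_grad, x0, n_warmup: int, n_draws: int, rng,
                 target_accept: float = 0.95, max_leapfrog: int = 32) -> ChainResult:
    """Run one HMC chain; returns post-warmup draws and diagnostics."""
    x = np.asarray(x0, dtype=float).copy()
    dim = x.size
    mass = np.ones(dim)           # momentum variances
    inv_mass = 1.0 / mass

    eps = _initial_step_size(logp_grad, x, rng, inv_mass)
    # dual averaging state
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75

    # warmup schedule: step-size-only head/tail around mass-estimation windows
    head = max(int(0.15 * n_warmup), 1)
    tail_start = max(int(0.9 * n_warmup), head + 1)
    window_ends = []
    if n_warmup >= 100:
        mid = head + (tail_start - head) // 3
        window_ends = [mid, tail_start]
    elif n_warmup >= 40:
        window_ends = [tail_start]
    window_buf: list[np.ndarray] = []

    logp, _ = logp_grad(x)
    draws = np.empty((n_draws, dim))
    logps = np.empty(n_draws)
    divergences = 0
    n_accept = 0
    adapt_count = 0

    total = n_warmup + n_draws
    for it in range(total):
        warm = it < n_warmup
        p0 = rng.normal(size=dim) * np.sqrt(mass)
        h0 = logp - 0.5 * np.sum(inv_mass * p0**2)
        n_steps = int(rng.integers(1, max_leapfrog + 1))
        x1, p1, logp1, _ = _leapfrog(logp_grad, x, p0, eps, n_steps, inv_mass)
        h1 = logp1 - 0.5 * np.sum(inv_mass * p1**2) if np.isfinite(logp1) else -np.inf
        delta = h1 - h0
        divergent = (not np.isfinite(delta)) or (-delta > DIVERGENCE_THRESHOLD)
        alpha = 0.0 if not np.isfinite(delta) else min(1.0, float(np.exp(min(delta, 0.0))))
        if (not divergent) and rng.random() < alpha:
            x, logp = x1, logp1
            if not warm:
                n_accept += 1
        if warm:
            # dual averaging toward target acceptance
            adapt_count += 1
            frac = 1.0 / (adapt_count + t0)
            h_bar = (1 - frac) * h_bar + frac * (target_accept - alpha)
            log_eps = mu - np.sqrt(adapt_count) / gamma * h_bar
            w = adapt_count ** (-kappa)
            log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
            eps = float(np.exp(log_eps))
            if window_ends and it >= head:
                window_buf.append(x.copy())
                if it + 1 == window_ends[0]:
                    buf = np.asarray(window_buf)
                    n = len(buf)
                    if n > 4:
                        var = buf.var(axis=0)
                        # regularized toward unit scale, as in Stan
                        var = (n / (n + 5.0)) * var + (5.0 / (n + 5.0)) * 1e-3
                        mass = 1.0 / np.maximum(var, 1e-10)
                        inv_mass = var
                        eps = _initial_step_size(logp_grad, x, rng, inv_mass)
                        mu = np.log(10.0 * eps)
                        h_bar, log_eps_bar, adapt_count = 0.0, 0.0, 0
                    window_buf = []
                    window_ends.pop(0)
            if it + 1 == n_warmup:
                eps = float(np.exp(log_eps_bar)) if adapt_count else eps
        else:
            if divergent:
                divergences += 1
            draws[it - n_warmup] = x
            logps[it - n_warmup] = logp

    return ChainResult(
        draws=draws,
        divergences=divergences,
        accept_rate=n_accept / max(n_draws, 1),
        step_size=eps,
        mass_diag=mass,
        logp=logps,
    )


def sample(logp_grad, x0_fn, n_chains: int, n_warmup: int, n_draws: int,
           seed: int, target_accept: float = 0.95, max_leapfrog: int = 32):
    """Run ``n_chains`` sequential chains with independent sub-seeds.

    ``x0_fn(rng)`` draws an overdispersed initial point per chain.  Returns
    ``(draws, results)`` where draws has shape (n_chains, n_draws, dim).
    """
    seqs = np.random.SeedSequence(seed).spawn(n_chains)
    results = []
    all_draws = None
    for c, sub in enumerate(seqs):
        rng = np.random.default_rng(sub)
        x0 = np.asarray(x0_fn(rng), dtype=float)
        res = sample_chain(logp_grad, x0, n_warmup, n_draws, rng,
                           target_accept=target_accept, max_leapfrog=max_leapfrog)
        if all_draws is None:
            all_draws = np.empty((n_chains, n_draws, x0.size))
        all_draws[c] = res.draws
        results.append(res)
    return all_draws, results
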