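"""Adaptive Hamiltonian Monte Carlo on a differentiable log posterior.

A self-contained gradient-based MCMC kernel: leapfrog integration with a
diagonal mass matrix, dual-averaging step-size adaptation toward a target
acceptance rate, windowed estimation of the mass matrix from warmup draws,
and jittered trajectory lengths to avoid resonance. The interface is a
single function taking ``logp_and_grad(theta) -> (float, ndarray)``.

Correctness is defined by the package's oracle tests (grid posteriors,
known-truth recovery), not by equivalence to any particular sampler.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SamplerConfig", "ChainResult", "run_chain", "sample"]


@dataclass
class SamplerConfig:
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    target_accept: float = 0.8
    max_leapfrog: int = 48
    trajectory_length: float = 1.2
    #: energy error above which a trajectory is declared divergent
    divergence_threshold: float = 1000.0
    init_jitter: float = 0.5


@dataclass
class ChainResult:
    draws: np.ndarray  # (n_draws, ndim)
    accept_rate: float
    divergences: int
    step_size: float
    logp: np.ndarray = field(default=None)  # (n_draws,)


def _leapfrog(logp_and_grad, q, p, grad, eps, inv_mass, n_steps):
    """Integrate Hamilton's equations; returns (q, p, logp, grad)."""
    p = p + 0.5 * eps * grad
    for i in range(n_steps):
        q = q + eps * inv_mass * p
        logp, grad = logp_and_grad(q)
        if not np.isfinite(logp):
            return q, p, -np.inf, grad
        if i < n_steps - 1:
            p = p + eps * grad
    p = p + 0.5 * eps * grad
    return q, p, logp, grad


def _find_initial_step(logp_and_grad, q, logp, grad, inv_mass, rng):
    """Double/halve the step size until the one-step acceptance crosses 0.5."""
    eps = 0.1
    p = rng.standard_normal(q.size) / np.sqrt(inv_mass)
    h0 = logp - 0.5 * np.sum(p * p * inv_mass)
    _, p1, logp1, _ = _leapfrog(logp_and_grad, q, p, grad, eps, inv_mass, 1)
    h1 = logp1 - 0.5 * np.sum(p1 * p1 * inv_mass) if np.isfinite(logp1) else -np.inf
    direction = 1.0 if (h1 - h0) > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0 ** direction
        _, p1, logp1, _ = _leapfrog(logp_and_grad, q, p, grad, eps, inv_mass, 1)
        h1 = logp1 - 0.5 * np.sum(p1 * p1 * inv_mass) if np.isfinite(logp1) else -np.inf
        if direction * (h1 - h0) < direction * np.log(0.5):
            break
    return min(eps, 1.0)


def run_chain(logp_and_grad, init: np.ndarray, config: SamplerConfig,
              rng: np.random.Generator) -> ChainResult:
    """Run one HMC chain: ``config.warmup`` adaptation steps, then draws."""
    q = np.array(init, dtype=float)
    ndim = q.size
    logp, grad = logp_and_grad(q)
    if not np.isfinite(logp):
        raise ValueError("log posterior is not finite at the initial point")

    inv_mass = np.ones(ndim)
    eps = _find_initial_step(logp_and_grad, q, logp, grad, inv_mass, rng)

    # dual averaging (Nesterov-style) toward target acceptance
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75

    warmup, draws = config.warmup, config.draws
    # mass-matrix re-estimation points within warmup
    mass_updates = {int(warmup * 0.4), int(warmup * 0.7)} if warmup >= 20 else set()
    welford_n = 0
    welford_mean = np.zeros(ndim)
    welford_m2 = np.zeros(ndim)

    out = np.empty((draws, ndim))
    out_logp = np.empty(draws)
    n_accept = 0
    n_div = 0
    da_iter = 0

    total = warmup + draws
    for it in range(total):
        adapting = it < warmup
        p0 = rng.standard_normal(ndim) / np.sqrt(inv_mass)
        h0 = logp - 0.5 * np.sum(p0 * p0 * inv_mass)
        n_base = max(1, min(config.max_leapfrog, int(np.ceil(config.trajectory_length / eps))))
        n_steps = int(rng.integers(max(1, int(0.8 * n_base)), n_base + 1))
        q1, p1, logp1, grad1 = _leapfrog(logp_and_grad, q, p0, grad, eps, inv_mass, n_steps)
        if np.isfinite(logp1):
            h1 = logp1 - 0.5 * np.sum(p1 * p1 * inv_mass)
            delta = h1 - h0
        else:
            delta = -np.inf
        divergent = (not np.isfinite(delta)) or (-delta > config.divergence_threshold)
        accept_prob = 0.0 if divergent else min(1.0, float(np.exp(min(0.0, delta))))
        if (not divergent) and rng.random() < accept_prob:
            q, logp, grad = q1, logp1, grad1
            if not adapting:
                n_accept += 1
        if divergent and not adapting:
            n_div += 1

        if adapting:
            da_iter += 1
            h_bar = (1 - 1 / (da_iter + t0)) * h_bar + (config.target_accept - accept_prob) / (da_iter + t0)
            log_eps = mu - np.sqrt(da_iter) / gamma * h_bar
            w = da_iter ** (-kappa)
            log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
            eps = float(np.exp(log_eps))

            welford_n += 1
            delta_w = q - welford_mean
            welford_mean += delta_w / welford_n
            welford_m2 += delta_w * (q - welford_mean)
            if it in mass_updates and welford_n > 10:
                var = welford_m2 / (welford_n - 1)
                # shrink toward unit variance, Stan-style regularization
                n = welford_n
                inv_mass = (n / (n + 5.0)) * var + (5.0 / (n + 5.0)) * 1e-3
                inv_mass = np.maximum(inv_mass, 1e-8)
                welford_n = 0
                welford_mean[:] = 0.0
                welford_m2[:] = 0.0
                eps = _find_initial_step(logp_and_grad, q, logp, grad, inv_mass, rng)
                mu = np.log(10.0 * eps)
                log_eps_bar, h_bar, da_iter = 0.0, 0.0, 0
        else:
            out[it - warmup] = q
            out_logp[it - warmup] = logp

        if it == warmup - 1:
            eps = float(np.exp(log_eps_bar)) if warmup > 0 else eps

    return ChainResult(
        draws=out,
        accept_rate=n_accept / max(1, draws),
        divergences=n_div,
        step_size=eps,
        logp=out_logp,
    )


def sample(logp_and_grad, ndim: int, config: SamplerConfig, seed: int,
           init: np.ndarray | None = None) -> tuple[np.ndarray, list[ChainResult]]:
    """Run ``config.chains`` independent chains.

    Chain c uses ``default_rng([seed, c])``; results are deterministic given
    the seed and config. Returns (draws array of shape
    (chains, draws, ndim), per-chain results).
    """
    if init is None:
        init = np.zeros(ndim)
    all_draws = np.empty((config.chains, config.draws, ndim))
    results = []
    for c in range(config.chains):
        rng = np.random.default_rng([int(seed) % (2**31), c])
        start = init + config.init_jitter * rng.standard_normal(ndim)
        res = run_chain(logp_and_grad, start, config, rng)
        all_draws[c] = res.draws
        results.append(res)
    return all_draws, results
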