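"""No-U-Turn sampler with dual-averaging step-size and diagonal mass adaptation.

A compact, dependency-free NUTS implementation used by every model in this
package.  Models supply ``logp_and_grad(theta) -> (float, ndarray)`` for the
joint log-density of an unconstrained parameter vector; the sampler returns
per-chain draws plus the sample statistics arviz expects (energy, divergences,
tree depth, acceptance).

Algorithmic choices (standard practice):

* multinomial sampling over the trajectory with biased progressive
  favouring of the newer subtree;
* generalized U-turn check on subtree endpoints in the metric induced by the
  diagonal mass matrix;
* divergence declared when the Hamiltonian error exceeds 1000;
* warmup split Stan-style into a fast step-size window, doubling
  covariance-estimation windows (each followed by a mass-matrix update and a
  dual-averaging restart), and a final fast window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = ["SamplerConfig", "NUTSResult", "sample_nuts"]

LogpGrad = Callable[[np.ndarray], tuple[float, np.ndarray]]

_DIVERGENCE_THRESHOLD = 1000.0


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC settings shared by all models.

    Defaults follow common practice for moderate hierarchical models:
    4 chains x (1000 warmup + 1000 kept draws), target acceptance 0.9,
    R-hat convergence gate 1.01.
    """

    chains: int = 4
    draws: int = 1000
    warmup: int = 1000
    target_accept: float = 0.9
    max_treedepth: int = 10
    rhat_threshold: float = 1.01

    def __post_init__(self) -> None:
        if self.chains < 1 or self.draws < 1 or self.warmup < 10:
            raise ValueError("chains >= 1, draws >= 1, warmup >= 10 required")
        if not 0 < self.target_accept < 1:
            raise ValueError("target_accept must be in (0, 1)")


@dataclass
class NUTSResult:
    """Raw sampler output: draws of shape (chains, draws, ndim) plus stats."""

    draws: np.ndarray
    accept_rate: np.ndarray      # (chains, draws)
    tree_depth: np.ndarray       # (chains, draws)
    diverging: np.ndarray        # (chains, draws) bool
    energy: np.ndarray           # (chains, draws)
    step_size: np.ndarray        # (chains,)
    n_divergent: int = 0

    def __post_init__(self) -> None:
        self.n_divergent = int(self.diverging.sum())


class _Leaf:
    __slots__ = ("q", "p", "grad", "logw", "H")

    def __init__(self, q, p, grad, logw, H):
        self.q, self.p, self.grad, self.logw, self.H = q, p, grad, logw, H


def _leapfrog(logp_grad: LogpGrad, q, p, grad, eps, inv_mass):
    p = p + 0.5 * eps * grad
    q = q + eps * inv_mass * p
    logp, grad = logp_grad(q)
    p = p + 0.5 * eps * grad
    return q, p, logp, grad


def _kinetic(p, inv_mass) -> float:
    return 0.5 * float(np.dot(p, inv_mass * p))


def _uturn(q_minus, q_plus, p_minus, p_plus, inv_mass) -> bool:
    dq = q_plus - q_minus
    return (
        float(np.dot(dq, inv_mass * p_minus)) < 0
        or float(np.dot(dq, inv_mass * p_plus)) < 0
    )


class _Tree:
    """A balanced subtree of the NUTS trajectory (multinomial weights)."""

    __slots__ = (
        "q_minus", "p_minus", "grad_minus", "q_plus", "p_plus", "grad_plus",
        "proposal", "logw", "sum_accept", "n_leapfrog", "turning", "diverging",
    )

    def __init__(self, leaf: _Leaf, accept_stat: float, diverging: bool):
        self.q_minus = self.q_plus = leaf.q
        self.p_minus = self.p_plus = leaf.p
        self.grad_minus = self.grad_plus = leaf.grad
        self.proposal = leaf
        self.logw = leaf.logw
        self.sum_accept = accept_stat
        self.n_leapfrog = 1
        self.turning = False
        self.diverging = diverging


def _build_tree(logp_grad, leaf_q, leaf_p, leaf_grad, depth, direction,
                eps, H0, inv_mass, rng) -> _Tree | None:
    """Build a subtree of 2**depth leapfrog steps starting beyond the given
    edge state.  Returns None when the very first step diverges."""
    if depth == 0:
        q, p, logp, grad = _leapfrog(
            logp_grad, leaf_q, leaf_p, leaf_grad, direction * eps, inv_mass
        )
        H = -logp + _kinetic(p, inv_mass)
        if not math.isfinite(H):
            H = math.inf
        dH = H - H0
        diverging = dH > _DIVERGENCE_THRESHOLD
        logw = -dH if math.isfinite(dH) else -math.inf
        accept = min(1.0, math.exp(min(0.0, -dH))) if math.isfinite(dH) else 0.0
        return _Tree(_Leaf(q, p, grad, logw, H), accept, diverging)

    first = _build_tree(
        logp_grad, leaf_q, leaf_p, leaf_grad, depth - 1, direction,
        eps, H0, inv_mass, rng,
    )
    if first.turning or first.diverging:
        return first
    if direction > 0:
        edge_q, edge_p, edge_g = first.q_plus, first.p_plus, first.grad_plus
    else:
        edge_q, edge_p, edge_g = first.q_minus, first.p_minus, first.grad_minus
    second = _build_tree(
        logp_grad, edge_q, edge_p, edge_g, depth - 1, direction,
        eps, H0, inv_mass, rng,
    )
    # merge second into first
    first.sum_accept += second.sum_accept
    first.n_leapfrog += second.n_leapfrog
    if second.diverging:
        first.diverging = True
        return first
    total = np.logaddexp(first.logw, second.logw)
    if math.isfinite(second.logw) and math.log(rng.random()) < second.logw - total:
        first.proposal = second.proposal
    first.logw = total
    if direction > 0:
        first.q_plus, first.p_plus, first.grad_plus = (
            second.q_plus, second.p_plus, second.grad_plus)
    else:
        first.q_minus, first.p_minus, first.grad_minus = (
            second.q_minus, second.p_minus, second.grad_minus)
    first.turning = second.turning or _uturn(
        first.q_minus, first.q_plus, first.p_minus, first.p_plus, inv_mass
    )
    return first


def _nuts_step(logp_grad, q, logp, grad, eps, inv_mass, max_treedepth, rng):
    """One NUTS transition.  Returns (q, logp, grad, stats dict)."""
    mass = 1.0 / inv_mass
    p0 = rng.standard_normal(q.shape) * np.sqrt(mass)
    H0 = -logp + _kinetic(p0, inv_mass)

    q_minus = q_plus = q
    p_minus = p_plus = p0
    grad_minus = grad_plus = grad
    proposal = _Leaf(q, p0, grad, 0.0, H0)
    logw = 0.0
    sum_accept = 0.0
    n_leapfrog = 0
    depth = 0
    diverging = False

    while depth < max_treedepth:
        direction = 1 if rng.random() < 0.5 else -1
        if direction > 0:
            subtree = _build_tree(
                logp_grad, q_plus, p_plus, grad_plus, depth, 1,
                eps, H0, inv_mass, rng,
            )
        else:
            subtree = _build_tree(
                logp_grad, q_minus, p_minus, grad_minus, depth, -1,
                eps, H0, inv_mass, rng,
            )
        sum_accept += subtree.sum_accept
        n_leapfrog += subtree.n_leapfrog
        if subtree.diverging:
            diverging = True
            break
        if subtree.turning:
            break
        # biased progressive sampling: favour the new subtree
        if math.isfinite(subtree.logw):
            if subtree.logw >= logw or math.log(rng.random()) < subtree.logw - logw:
                proposal = subtree.proposal
        logw = np.logaddexp(logw, subtree.logw)
        if direction > 0:
            q_plus, p_plus, grad_plus = (
                subtree.q_plus, subtree.p_plus, subtree.grad_plus)
        else:
            q_minus, p_minus, grad_minus = (
                subtree.q_minus, subtree.p_minus, subtree.grad_minus)
        depth += 1
        if _uturn(q_minus, q_plus, p_minus, p_plus, inv_mass):
            break

    q_new = proposal.q
    if proposal.logw != 0.0 or proposal.H != H0:
        logp_new, grad_new = logp_grad(q_new)
    else:  # proposal is the initial point
        logp_new, grad_new = logp, grad
    stats = {
        "accept": sum_accept / max(n_leapfrog, 1),
        "depth": depth,
        "diverging": diverging,
        "energy": proposal.H,
    }
    return q_new, logp_new, grad_new, stats


def _find_initial_step_size(logp_grad, q, logp, grad, inv_mass, rng) -> float:
    """Heuristic: double/halve eps until the one-step acceptance crosses 0.5."""
    eps = 1.0
    mass = 1.0 / inv_mass
    p = rng.standard_normal(q.shape) * np.sqrt(mass)
    H0 = -logp + _kinetic(p, inv_mass)

    def delta_h(eps):
        q1, p1, logp1, _ = _leapfrog(logp_grad, q, p, grad, eps, inv_mass)
        H1 = -logp1 + _kinetic(p1, inv_mass)
        return H1 - H0 if math.isfinite(H1) else math.inf

    dh = delta_h(eps)
    direction = 1 if dh < math.log(2.0) else -1
    for _ in range(100):
        eps *= 2.0 ** direction
        dh = delta_h(eps)
        if (direction == 1 and dh >= math.log(2.0)) or (
            direction == -1 and dh <= math.log(2.0)
        ):
            break
        if eps < 1e-10 or eps > 1e7:
            break
    return max(eps, 1e-10)


def _warmup_schedule(warmup: int) -> list[tuple[int, int, bool]]:
    """(start, end, is_mass_window) segments of the warmup phase."""
    init_buf = max(int(0.15 * warmup), 10)
    term_buf = max(int(0.10 * warmup), 10)
    middle = warmup - init_buf - term_buf
    if middle < 20:
        return [(0, warmup, False)]
    segments = [(0, init_buf, False)]
    start = init_buf
    size = max(middle // 8, 10)
    while start < init_buf + middle:
        end = min(start + size, init_buf + middle)
        # absorb a too-small tail into the last window
        if (init_buf + middle) - end < 10:
            end = init_buf + middle
        segments.append((start, end, True))
        start = end
        size *= 2
    segments.append((init_buf + middle, warmup, False))
    return segments


def _run_chain(logp_grad, q0, config: SamplerConfig, rng):
    ndim = q0.size
    inv_mass = np.ones(ndim)
    logp, grad = logp_grad(q0)
    if not math.isfinite(logp):
        raise ValueError("initial point has non-finite log-density")
    q = q0.copy()

    eps = _find_initial_step_size(logp_grad, q, logp, grad, inv_mass, rng)

    # dual averaging state
    mu = math.log(10.0 * eps)
    log_eps_bar, h_bar, da_count = 0.0, 0.0, 0
    gamma, t0, kappa = 0.05, 10.0, 0.75

    def da_update(accept_prob):
        nonlocal eps, log_eps_bar, h_bar, da_count
        da_count += 1
        eta = 1.0 / (da_count + t0)
        h_bar = (1 - eta) * h_bar + eta * (config.target_accept - accept_prob)
        log_eps = mu - math.sqrt(da_count) / gamma * h_bar
        w = da_count ** (-kappa)
        log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
        eps = math.exp(log_eps)

    # ----- warmup -----
    for start, end, is_mass in _warmup_schedule(config.warmup):
        if is_mass:
            window = np.empty((end - start, ndim))
        for i in range(start, end):
            q, logp, grad, st = _nuts_step(
                logp_grad, q, logp, grad, eps, inv_mass,
                config.max_treedepth, rng,
            )
            da_update(st["accept"])
            if is_mass:
                window[i - start] = q
        if is_mass and end - start >= 10:
            n = end - start
            var = np.var(window, axis=0, ddof=1)
            # Stan-style shrinkage toward unit metric
            inv_mass = (n / (n + 5.0)) * var + (5.0 / (n + 5.0)) * 1e-3
            inv_mass = np.clip(inv_mass, 1e-10, 1e10)
            # restart step-size adaptation around the current eps
            eps = _find_initial_step_size(logp_grad, q, logp, grad, inv_mass, rng)
            mu = math.log(10.0 * eps)
            log_eps_bar, h_bar, da_count = 0.0, 0.0, 0
    eps = math.exp(log_eps_bar) if da_count > 0 else eps

    # ----- sampling -----
    draws = np.empty((config.draws, ndim))
    accept = np.empty(config.draws)
    depth = np.empty(config.draws, dtype=int)
    diverging = np.zeros(config.draws, dtype=bool)
    energy = np.empty(config.draws)
    for i in range(config.draws):
        q, logp, grad, st = _nuts_step(
            logp_grad, q, logp, grad, eps, inv_mass,
            config.max_treedepth, rng,
        )
        draws[i] = q
        accept[i] = st["accept"]
        depth[i] = st["depth"]
        diverging[i] = st["diverging"]
        energy[i] = st["energy"]
    return draws, accept, depth, diverging, energy, eps


def sample_nuts(
    logp_grad: LogpGrad,
    ndim: int,
    *,
    config: SamplerConfig | None = None,
    seed: int,
    initial: np.ndarray | None = None,
    jitter: float = 1.0,
) -> NUTSResult:
    """Run NUTS chains and return raw draws.

    Parameters
    ----------
    logp_grad : callable
        Joint log-density and gradient of the unconstrained parameters.
    ndim : int
        Dimension of the parameter vector.
    seed : int
        Seed for all randomness (chain seeds are spawned from it).
    initial : ndarray, optional
        Starting point; chains jitter around it (or around 0).
    """
    config = config or SamplerConfig()
    rng = np.random.default_rng(seed)
    base = np.zeros(ndim) if initial is None else np.asarray(initial, float)

    all_draws, all_acc, all_dep, all_div, all_en, eps_out = [], [], [], [], [], []
    for _c in range(config.chains):
        chain_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
        for attempt in range(10):
            q0 = base + jitter * (0.5 ** attempt) * chain_rng.standard_normal(ndim)
            lp, _ = logp_grad(q0)
            if math.isfinite(lp):
                break
        else:
            raise ValueError("could not find a finite starting point")
        d, a, dp, dv, en, eps = _run_chain(logp_grad, q0, config, chain_rng)
        all_draws.append(d)
        all_acc.append(a)
        all_dep.append(dp)
        all_div.append(dv)
        all_en.append(en)
        eps_out.append(eps)

    return NUTSResult(
        draws=np.stack(all_draws),
        accept_rate=np.stack(all_acc),
        tree_depth=np.stack(all_dep),
        diverging=np.stack(all_div),
        energy=np.stack(all_en),
        step_size=np.asarray(eps_out),
    )
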