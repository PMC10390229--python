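"""No-U-Turn sampler with dual-averaging step size and diagonal mass adaptation.

A self-contained gradient-based MCMC backend for densities exposing
``logp_grad(z) -> (float, ndarray)`` on an unconstrained parameter vector.
The implementation follows the slice-sampling tree-doubling scheme of the
original no-U-turn algorithm, with a Stan-style windowed warmup: an initial
step-size phase, expanding diagonal-mass estimation windows, and a terminal
step-size phase.  Post-warmup draws are retained with optional thinning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["NutsConfig", "NutsResult", "nuts_sample"]

_MAX_ENERGY_ERROR = 1000.0  # divergence threshold on the Hamiltonian error


@dataclass(frozen=True)
class NutsConfig:
    iterations: int = 1000      # total per chain, warmup included
    warmup: int = 500
    thin: int = 2
    target_accept: float = 0.8
    max_depth: int = 10
    init_buffer: int = 75       # step-size-only phase at the start of warmup
    term_buffer: int = 50       # step-size-only phase at the end of warmup
    base_window: int = 25


@dataclass
class NutsResult:
    draws: np.ndarray           # (n_retained, dim), unconstrained scale
    logp: np.ndarray            # (n_retained,)
    accept_stat: np.ndarray     # mean Metropolis acceptance per iteration
    divergences: int
    step_size: float
    inv_mass: np.ndarray
    tree_depths: np.ndarray = field(repr=False, default=None)


class _Tree:
    """State bundle for one NUTS trajectory."""

    __slots__ = ("zm", "pm", "gm", "zp", "pp", "gp", "zprop", "lprop", "n", "s",
                 "alpha", "n_alpha", "diverged")


def _kinetic(p: np.ndarray, inv_mass: np.ndarray) -> float:
    return 0.5 * float(p @ (inv_mass * p))


def _leapfrog(logp_grad, z, p, g, eps, inv_mass):
    p = p + 0.5 * eps * g
    z = z + eps * inv_mass * p
    lp, g = logp_grad(z)
    p = p + 0.5 * eps * g
    return z, p, g, lp


def _find_initial_step_size(logp_grad, z, rng, inv_mass) -> float:
    """Double/halve until the one-step acceptance crosses 0.5."""
    eps = 1.0
    lp0, g0 = logp_grad(z)
    p0 = rng.standard_normal(z.size) / np.sqrt(inv_mass)
    h0 = lp0 - _kinetic(p0, inv_mass)

    def joint(eps):
        try:
            _, p1, _, lp1 = _leapfrog(logp_grad, z, p0, g0, eps, inv_mass)
        except FloatingPointError:
            return -np.inf
        h1 = lp1 - _kinetic(p1, inv_mass)
        return h1 - h0 if np.isfinite(h1) else -np.inf

    direction = 1 if joint(eps) > np.log(0.5) else -1
    for _ in range(100):
        if direction == 1 and joint(eps) <= np.log(0.5):
            break
        if direction == -1 and joint(eps) > np.log(0.5):
            break
        eps *= 2.0**direction
    return eps


def _build_tree(logp_grad, z, p, g, log_u, v, depth, eps, h0, inv_mass, rng) -> _Tree:
    t = _Tree()
    if depth == 0:
        z1, p1, g1, lp1 = _leapfrog(logp_grad, z, p, g, v * eps, inv_mass)
        h1 = lp1 - _kinetic(p1, inv_mass)
        if not np.isfinite(h1):
            h1 = -np.inf
        t.zm = t.zp = t.zprop = z1
        t.pm = t.pp = p1
        t.gm = t.gp = g1
        t.lprop = lp1
        t.n = int(log_u <= h1)
        t.diverged = log_u - _MAX_ENERGY_ERROR >= h1
        t.s = int(not t.diverged)
        t.alpha = min(1.0, np.exp(min(0.0, h1 - h0)))
        t.n_alpha = 1
        return t
    left = _build_tree(logp_grad, z, p, g, log_u, v, depth - 1, eps, h0, inv_mass, rng)
    t.zm, t.pm, t.gm = left.zm, left.pm, left.gm
    t.zp, t.pp, t.gp = left.zp, left.pp, left.gp
    t.zprop, t.lprop = left.zprop, left.lprop
    t.n, t.s = left.n, left.s
    t.alpha, t.n_alpha = left.alpha, left.n_alpha
    t.diverged = left.diverged
    if left.s == 1:
        if v == -1:
            right = _build_tree(logp_grad, left.zm, left.pm, left.gm, log_u, v,
                                depth - 1, eps, h0, inv_mass, rng)
            t.zm, t.pm, t.gm = right.zm, right.pm, right.gm
        else:
            right = _build_tree(logp_grad, left.zp, left.pp, left.gp, log_u, v,
                                depth - 1, eps, h0, inv_mass, rng)
            t.zp, t.pp, t.gp = right.zp, right.pp, right.gp
        total = left.n + right.n
        if total > 0 and rng.random() < right.n / total:
            t.zprop, t.lprop = right.zprop, right.lprop
        t.alpha = left.alpha + right.alpha
        t.n_alpha = left.n_alpha + right.n_alpha
        t.n = total
        t.diverged = left.diverged or right.diverged
        dz = t.zp - t.zm
        no_uturn = (dz @ (inv_mass * t.pm) >= 0) and (dz @ (inv_mass * t.pp) >= 0)
        t.s = int(right.s == 1 and no_uturn and not t.diverged)
    return t


@dataclass
class _DualAveraging:
    """Nesterov dual averaging of log step size toward a target acceptance."""

    mu: float
    gamma: float = 0.05
    t0: float = 10.0
    kappa: float = 0.75
    count: int = 0
    h_bar: float = 0.0
    log_eps_bar: float = 0.0

    def update(self, accept_prob: float, target: float) -> float:
        self.count += 1
        frac = 1.0 / (self.count + self.t0)
        self.h_bar = (1 - frac) * self.h_bar + frac * (target - accept_prob)
        log_eps = self.mu - np.sqrt(self.count) / self.gamma * self.h_bar
        w = self.count ** (-self.kappa)
        self.log_eps_bar = w * log_eps + (1 - w) * self.log_eps_bar
        return float(np.exp(log_eps))


def _mass_windows(cfg: NutsConfig) -> list[tuple[int, int]]:
    """Expanding [start, end) windows for diagonal mass estimation."""
    start = cfg.init_buffer
    end_all = cfg.warmup - cfg.term_buffer
    if end_all - start < cfg.base_window:
        if cfg.warmup >= 20:  # degenerate short warmup: one middle window
            return [(cfg.warmup // 3, (5 * cfg.warmup) // 6)]
        return []
    windows = []
    size = cfg.base_window
    while start + size < end_all:
        if start + 3 * size >= end_all:  # absorb the remainder into the last window
            size = end_all - start
        windows.append((start, start + size))
        start += size
        size *= 2
    if not windows or windows[-1][1] < end_all:
        windows.append((start, end_all))
    return windows


def nuts_sample(
    logp_grad,
    z0: np.ndarray,
    rng: np.random.Generator,
    config: NutsConfig = NutsConfig(),
) -> NutsResult:
    """Run one NUTS chain; returns retained post-warmup draws (thinned)."""
    cfg = config
    dim = z0.size
    inv_mass = np.ones(dim)
    z = np.asarray(z0, dtype=float).copy()
    lp, g = logp_grad(z)
    if not np.isfinite(lp):
        raise ValueError("initial point has non-finite log density")

    eps = _find_initial_step_size(logp_grad, z, rng, inv_mass)
    da = _DualAveraging(mu=np.log(10.0 * eps))
    windows = _mass_windows(cfg)
    window_i = 0
    window_buf: list[np.ndarray] = []

    n_keep = (cfg.iterations - cfg.warmup + cfg.thin - 1) // cfg.thin
    draws = np.empty((n_keep, dim))
    lps = np.empty(n_keep)
    accept = np.empty(cfg.iterations)
    depths = np.empty(cfg.iterations, dtype=int)
    kept = 0
    divergences = 0

    for it in range(cfg.iterations):
        p0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        h0 = lp - _kinetic(p0, inv_mass)
        log_u = h0 + np.log(rng.random())
        zm = zp = z
        pm = pp = p0
        gm = gp_ = g
        n = 1
        s = 1
        depth = 0
        alpha_stat, n_alpha = 0.0, 1
        while s == 1 and depth < cfg.max_depth:
            v = 1 if rng.random() < 0.5 else -1
            if v == -1:
                tr = _build_tree(logp_grad, zm, pm, gm, log_u, v, depth, eps, h0,
                                 inv_mass, rng)
                zm, pm, gm = tr.zm, tr.pm, tr.gm
            else:
                tr = _build_tree(logp_grad, zp, pp, gp_, log_u, v, depth, eps, h0,
                                 inv_mass, rng)
                zp, pp, gp_ = tr.zp, tr.pp, tr.gp
            if tr.s == 1 and rng.random() < min(1.0, tr.n / n):
                z, lp = tr.zprop, tr.lprop
            n += tr.n
            alpha_stat, n_alpha = tr.alpha, tr.n_alpha
            dz = zp - zm
            no_uturn = (dz @ (inv_mass * pm) >= 0) and (dz @ (inv_mass * pp) >= 0)
            s = int(tr.s == 1 and no_uturn)
            depth += 1
            if it >= cfg.warmup and tr.diverged:
                divergences += 1
        _, g = logp_grad(z)  # refresh gradient at the accepted point
        accept[it] = alpha_stat / max(n_alpha, 1)
        depths[it] = depth

        if it < cfg.warmup:
            eps = da.update(accept[it], cfg.target_accept)
            if window_i < len(windows):
                w_start, w_end = windows[window_i]
                if w_start <= it < w_end:
                    window_buf.append(z.copy())
                if it == w_end - 1 and len(window_buf) >= 10:
                    m = np.asarray(window_buf)
                    nw = m.shape[0]
                    var = m.var(axis=0, ddof=1)
                    inv_mass = (nw / (nw + 5.0)) * var + 1e-3 * (5.0 / (nw + 5.0))
                    window_buf = []
                    window_i += 1
                    eps = _find_initial_step_size(logp_grad, z, rng, inv_mass)
                    da = _DualAveraging(mu=np.log(10.0 * eps))
            if it == cfg.warmup - 1:
                eps = float(np.exp(da.log_eps_bar))
        else:
            if (it - cfg.warmup) % cfg.thin == 0:
                draws[kept] = z
                lps[kept] = lp
                kept += 1

    return NutsResult(
        draws=draws[:kept],
        logp=lps[:kept],
        accept_stat=accept,
        divergences=divergences,
        step_size=eps,
        inv_mass=inv_mass,
        tree_depths=depths,
    )
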