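"""Rate-network and ring-model dynamics on BTSP-learned connectivity.

The full network integrates

    τ dr_i/dt = −r_i + φ( (1/κN) Σ_j w̄_ij r_j S_j + I₀ ) S_i,

with w̄_ij = W₀ + W_max (w_ij − μ_w) the centred, rescaled learned weights,
S the activity mask of the environment being recalled, and φ an expansive
transfer function (zero below threshold, quadratic at low input, sublinear
above).  Restricted to the manifold of spatial modulations of a single
environment this reduces to a ring model with connectivity
W₀ + W₁ cos Δθ (+ quenched noise), whose uniform state loses stability to
a bump at the Turing point W₁ = 2/φ₀′.

Memory recall is probed by seeding a bump in the ordering of a past
environment; an environment counts as retrieved when the steady state is a
bump in that ordering and in no other.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize

from .plasticity import EnvironmentSequence

__all__ = [
    "RateNetConfig",
    "RingConfig",
    "BumpReadout",
    "transfer_phi",
    "transfer_phi_prime",
    "uniform_rate",
    "build_effective_weights",
    "simulate_rate_network",
    "bump_amplitude",
    "shuffle_null_amplitude",
    "seed_and_measure",
    "simulate_ring",
    "draw_ring_noise",
    "ring_turing_point",
    "ring_saddle_node",
    "retrieve",
    "bump_threshold",
    "capacity_by_bisection",
    "capacity_sweep",
]

_RATE_CAP = 1e6


def transfer_phi(x):
    """φ(x): 0 for x<0, x² for 0≤x≤1, 2√(x−3/4) for x>1 (C¹ everywhere)."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    mid = (x >= 0.0) & (x <= 1.0)
    out[mid] = x[mid] ** 2
    hi = x > 1.0
    out[hi] = 2.0 * np.sqrt(x[hi] - 0.75)
    return out


def transfer_phi_prime(x):
    """dφ/dx, continuous at both branch points."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    mid = (x >= 0.0) & (x <= 1.0)
    out[mid] = 2.0 * x[mid]
    hi = x > 1.0
    out[hi] = 1.0 / np.sqrt(x[hi] - 0.75)
    return out


def uniform_rate(W0: float, I0: float) -> tuple[float, float]:
    """Stable uniform fixed point r₀ = φ(W₀ r₀ + I₀) and the slope φ₀′ there."""

    def gap(r):
        return float(transfer_phi(W0 * r + I0)) - r

    hi = 1.0
    while gap(hi) > 0.0 and hi < 1e9:
        hi *= 2.0
    r0 = float(optimize.brentq(gap, 0.0, hi)) if gap(0.0) > 0.0 else 0.0
    phi0p = float(transfer_phi_prime(W0 * r0 + I0))
    if W0 >= 1.0 / phi0p:
        raise ValueError("uniform instability: W0 >= 1/phi0'")
    return r0, phi0p


@dataclass(frozen=True)
class RateNetConfig:
    kappa: float
    W_max: float
    W0: float
    I0: float = 0.9
    tau: float = 1.0
    dt: float = 0.05
    t_end: float = 200.0
    conv_tol: float = 1e-6
    seed_eps_small: float = 0.05  # × r₀
    seed_eps_large: float = 2.0  # × r₀

    def __post_init__(self) -> None:
        if self.tau <= 0 or self.dt <= 0 or self.t_end <= 0:
            raise ValueError("tau, dt and t_end must be positive")
        if self.dt >= self.tau / 5.0:
            raise ValueError("dt must be below tau/5 for stable integration")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")


def build_effective_weights(
    W: np.ndarray, mu_w: float, W_max: float, W0: float
) -> np.ndarray:
    """w̄ = W₀ + W_max (w − μ_w); the 1/(κN) input normalization is applied
    by the integrator."""
    return W0 + W_max * (np.asarray(W, dtype=float) - mu_w)


@dataclass
class SimResult:
    rates: np.ndarray
    converged: bool
    t: float


def _integrate(drive_fn, r, tau, dt, t_end, conv_tol):
    """Explicit Euler with early exit on ‖dr/dt‖∞ < conv_tol·max(r)."""
    n_steps = int(np.ceil(t_end / dt))
    converged = False
    t = 0.0
    for k in range(n_steps):
        delta = (dt / tau) * (-r + drive_fn(r))
        r += delta
        t += dt
        if np.max(r) > _RATE_CAP:
            raise FloatingPointError("runaway excitation: rates exceeded cap")
        if k % 20 == 19:
            scale = max(float(np.max(r)), 1e-12)
            if float(np.max(np.abs(delta))) / dt < conv_tol * scale:
                converged = True
                break
    return r, converged, t


def simulate_rate_network(
    wbar: np.ndarray,
    active: np.ndarray,
    init_rates: np.ndarray,
    config: RateNetConfig,
    n_positions: int,
) -> SimResult:
    """Integrate the full rate network in one environment.

    ``n_positions`` is the N of the 1/(κN) input normalization (number of
    encoded positions, not the cell count MN).  Inactive cells are pinned
    to zero — the transfer term is gated by the mask — so only the active
    subnetwork is integrated.
    """
    init_rates = np.asarray(init_rates, dtype=float)
    if (init_rates < 0).any():
        raise ValueError("initial rates must be nonnegative")
    mn = wbar.shape[0]
    if wbar.shape != (mn, mn) or active.shape != (mn,):
        raise ValueError("shape mismatch between weights and activity mask")
    idx = np.flatnonzero(active)
    sub = np.ascontiguousarray(wbar[np.ix_(idx, idx)]) / (config.kappa * n_positions)
    r = init_rates[idx].copy()

    def drive(rr):
        return transfer_phi(sub @ rr + config.I0)

    r, converged, t = _integrate(
        drive, r, config.tau, config.dt, config.t_end, config.conv_tol
    )
    full = np.zeros(mn)
    full[idx] = r
    return SimResult(rates=full, converged=converged, t=t)


def bump_amplitude(
    rates: np.ndarray, phases: np.ndarray, active=None, n_slots: int | None = None
) -> float:
    """First-Fourier-mode modulus 2|⟨r̄ e^{iθ}⟩| of the rate profile.

    With ``n_slots`` the (active) cells are first averaged per phase slot —
    the population readout used for bump measurement; empty slots are
    dropped from the circular mean.  Without it the mean runs directly over
    cells (identical when every slot is equally occupied).
    """
    rates = np.asarray(rates, dtype=float)
    phases = np.asarray(phases, dtype=float)
    if active is not None:
        rates = rates[active]
        phases = phases[active]
    if n_slots is None:
        return 2.0 * float(np.abs(np.mean(rates * np.exp(1j * phases))))
    slots = np.rint(phases * n_slots / (2.0 * np.pi)).astype(int) % n_slots
    counts = np.bincount(slots, minlength=n_slots)
    have = counts > 0
    prof = np.bincount(slots, weights=rates, minlength=n_slots)[have] / counts[have]
    theta = 2.0 * np.pi * np.arange(n_slots)[have] / n_slots
    return 2.0 * float(np.abs(np.mean(prof * np.exp(1j * theta))))


def shuffle_null_amplitude(
    rates: np.ndarray,
    phases: np.ndarray,
    rng: np.random.Generator,
    active=None,
    n_shuffles: int = 8,
    n_slots: int | None = None,
) -> float:
    """Mean first-mode amplitude after randomly permuting the phase labels:
    the incoherent (finite-size) amplitude floor."""
    rates = np.asarray(rates, dtype=float)
    phases = np.asarray(phases, dtype=float)
    if active is not None:
        rates = rates[active]
        phases = phases[active]
    amps = [
        bump_amplitude(rates, rng.permutation(phases), n_slots=n_slots)
        for _ in range(n_shuffles)
    ]
    return float(np.mean(amps))


@dataclass(frozen=True)
class BumpReadout:
    """Steady-state bump amplitudes of one recall simulation, measured in
    several environment orderings."""

    amplitudes: dict
    uniform_rate: float
    null_amplitude: float
    converged: bool
    env: int


def seed_and_measure(
    wbar: np.ndarray,
    seq: EnvironmentSequence,
    env: int,
    amplitude_init: str,
    config: RateNetConfig,
    rng: np.random.Generator,
    orderings=None,
) -> BumpReadout:
    """Seed a bump in the ordering of ``env``, relax, and measure the bump
    amplitude under every requested ordering (default: all stored)."""
    if not 0 <= env < seq.n:
        raise ValueError(f"environment {env} outside learned history (n={seq.n})")
    if amplitude_init not in ("small", "large"):
        raise ValueError("amplitude_init must be 'small' or 'large'")
    eps = config.seed_eps_small if amplitude_init == "small" else config.seed_eps_large
    r0, _ = uniform_rate(config.W0 * seq.s * seq.M / config.kappa, config.I0)
    phases = seq.phase_angles(env)
    init = np.clip(r0 * (1.0 + eps * np.cos(phases)), 0.0, None)
    active = seq.active[env]
    init = init * active
    res = simulate_rate_network(wbar, active, init, config, n_positions=seq.N)
    if orderings is None:
        orderings = range(seq.n)
    amps = {
        k: bump_amplitude(res.rates, seq.phase_angles(k), active=active, n_slots=seq.N)
        for k in orderings
    }
    null = shuffle_null_amplitude(res.rates, phases, rng, active=active, n_slots=seq.N)
    return BumpReadout(
        amplitudes=amps,
        uniform_rate=r0,
        null_amplitude=null,
        converged=res.converged,
        env=env,
    )


# ---------------------------------------------------------------------------
# Ring model


@dataclass(frozen=True)
class RingConfig:
    """N-discretized neural field on the circle with connectivity
    W₀ + W₁ cos Δθ plus an optional quenched noise term."""

    N: int
    W0: float
    W1: float
    I0: float = 0.9
    tau: float = 1.0
    dt: float = 0.05
    t_end: float = 200.0
    conv_tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.N < 16:
            raise ValueError("N must be at least 16 for the continuum approximation")
        if self.dt >= self.tau / 5.0:
            raise ValueError("dt must be below tau/5")


def draw_ring_noise(
    config: RingConfig,
    rng: np.random.Generator,
    std: float | np.ndarray = 0.0,
    kind: str = "pairwise",
) -> np.ndarray | None:
    """One quenched-noise realization for the ring connectivity.

    ``std`` is a scalar or an N-profile of standard deviations √V(Δθ).
    ``kind='pairwise'`` draws an independent z per ordered pair (matching
    the full network); ``'circulant'`` draws a single profile z(Δθ) shared
    by all rows, the form assumed by the Fourier-mode theory.
    """
    N = config.N
    std = np.asarray(std, dtype=float)
    if np.all(std == 0.0):
        return None
    if kind == "circulant":
        profile = std * rng.standard_normal(N)  # indexed by Δθ slot
        offsets = np.mod(np.arange(N)[:, None] - np.arange(N)[None, :], N)
        return profile[offsets]
    if kind in ("pairwise", "symmetric"):
        z = rng.standard_normal((N, N))
        if kind == "symmetric":
            # learned matrices are asymptotically symmetric for even kernels
            # (w_ij and w_ji see identical updates), so the matched noise is too
            iu = np.triu_indices(N, 1)
            z[(iu[1], iu[0])] = z[iu]
        if std.ndim == 0:
            return std * z
        offsets = np.mod(np.arange(N)[:, None] - np.arange(N)[None, :], N)
        return std[offsets] * z
    raise ValueError(f"unknown noise kind {kind!r}")


@dataclass
class RingResult:
    profile: np.ndarray
    amplitude: float
    uniform_rate: float
    converged: bool


def simulate_ring(
    config: RingConfig,
    noise: np.ndarray | None = None,
    init_profile: np.ndarray | None = None,
    seed_eps: float = 0.05,
    seed_phase: float = 0.0,
) -> RingResult:
    """Relax the ring model; default initial condition is the uniform state
    plus a cosine seed of relative amplitude ``seed_eps``."""
    N = config.N
    theta = 2.0 * np.pi * np.arange(N) / N
    K = config.W0 + config.W1 * np.cos(theta[:, None] - theta[None, :])
    if noise is not None:
        K = K + noise
    K = K / N  # (1/2π)∫ dθ′ → (1/N)Σ
    r0, _ = uniform_rate(config.W0, config.I0)
    if init_profile is None:
        init_profile = np.clip(
            r0 * (1.0 + seed_eps * np.cos(theta - seed_phase)), 0.0, None
        )
    r = np.asarray(init_profile, dtype=float).copy()

    def drive(rr):
        return transfer_phi(K @ rr + config.I0)

    r, converged, _ = _integrate(
        drive, r, config.tau, config.dt, config.t_end, config.conv_tol
    )
    return RingResult(
        profile=r,
        amplitude=bump_amplitude(r, theta),
        uniform_rate=r0,
        converged=converged,
    )


def _bisect_boundary(classify, lo: float, hi: float, tol: float) -> float:
    """Bisection on a monotone bool classifier; lo must be False, hi True."""
    if classify(lo):
        return lo
    if not classify(hi):
        return hi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if classify(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def ring_turing_point(
    config: RingConfig,
    w1_lo: float,
    w1_hi: float,
    noise: np.ndarray | None = None,
    seed_eps: float = 0.01,
    bump_criterion: float = 0.25,
    tol: float = 1e-3,
    classifier: str = "amplitude",
) -> float:
    """Onset of bump formation from a small seed, located by bisection in W₁.

    ``classifier='amplitude'``: a bump is present when the final first-mode
    amplitude exceeds ``bump_criterion``·r₀ — the operational notion used
    for noisy rings, where the uniform state is never exact.
    ``classifier='growth'``: supercritical when the seed's amplitude has
    grown by more than a factor of three — an unbiased probe of the linear
    instability of the uniform state (zero-noise rings).
    """
    r0, _ = uniform_rate(config.W0, config.I0)

    def classify(w1):
        res = simulate_ring(replace(config, W1=w1), noise=noise, seed_eps=seed_eps)
        if classifier == "growth":
            return res.amplitude > 3.0 * seed_eps * r0
        if classifier == "amplitude":
            return res.amplitude > bump_criterion * r0
        raise ValueError(f"unknown classifier {classifier!r}")

    return _bisect_boundary(classify, w1_lo, w1_hi, tol)


def ring_saddle_node(
    config: RingConfig,
    w1_lo: float,
    w1_hi: float,
    noise: np.ndarray | None = None,
    seed_eps: float = 2.0,
    bump_criterion: float = 0.25,
    tol: float = 1e-3,
) -> float:
    """Loss of the large-amplitude bump branch, by bisection with a large
    seed: below the saddle-node even a fully formed bump collapses."""
    r0, _ = uniform_rate(config.W0, config.I0)
    thr = bump_criterion * r0

    def classify(w1):
        res = simulate_ring(replace(config, W1=w1), noise=noise, seed_eps=seed_eps)
        return res.amplitude > thr

    return _bisect_boundary(classify, w1_lo, w1_hi, tol)


# ---------------------------------------------------------------------------
# Retrieval and capacity


def retrieve(
    wbar: np.ndarray,
    seq: EnvironmentSequence,
    eta: int,
    config: RateNetConfig,
    rng: np.random.Generator,
    threshold_factor: float = 5.0,
    min_rel_amplitude: float = 0.1,
) -> tuple[bool, BumpReadout]:
    """Large-seed recall of the environment of age ``eta``.

    Retrieved ⇔ the steady state is a bump in the seeded ordering and in no
    other stored ordering (the single-environment criterion).  "Bump" means
    amplitude above threshold_factor × the shuffle null and above
    min_rel_amplitude × r₀ (an absolute floor so that a numerically uniform
    state never counts)."""
    env = seq.env_for_age(eta)
    readout = seed_and_measure(wbar, seq, env, "large", config, rng)
    thr = bump_threshold(readout, threshold_factor, min_rel_amplitude)
    amp = readout.amplitudes[env]
    others = [a for k, a in readout.amplitudes.items() if k != env]
    ok = amp > thr and all(a <= thr for a in others)
    return ok, readout


def bump_threshold(
    readout: BumpReadout,
    threshold_factor: float = 5.0,
    min_rel_amplitude: float = 0.1,
) -> float:
    """Amplitude above which a measured ordering counts as a bump."""
    return max(
        threshold_factor * readout.null_amplitude,
        min_rel_amplitude * readout.uniform_rate,
    )


def capacity_by_bisection(
    wbar: np.ndarray,
    seq: EnvironmentSequence,
    config: RateNetConfig,
    rng: np.random.Generator,
    eta_hi: int | None = None,
    threshold_factor: float = 5.0,
) -> int:
    """Retrieval capacity as the retrievable/non-retrievable boundary age.

    Retrievability is monotone in age up to boundary noise, so the count of
    retrievable ages is estimated as the boundary located by integer
    bisection (far cheaper than testing every age)."""
    if eta_hi is None:
        eta_hi = seq.n - 1
    ok0, _ = retrieve(wbar, seq, 0, config, rng, threshold_factor)
    if not ok0:
        return 0
    ok_hi, _ = retrieve(wbar, seq, eta_hi, config, rng, threshold_factor)
    if ok_hi:
        return eta_hi + 1
    lo, hi = 0, eta_hi  # lo retrievable, hi not
    while hi - lo > 1:
        mid = (lo + hi) // 2
        ok, _ = retrieve(wbar, seq, mid, config, rng, threshold_factor)
        if ok:
            lo = mid
        else:
            hi = mid
    return lo + 1


def capacity_sweep(
    learned,
    eta_list,
    config: RateNetConfig,
    rng: np.random.Generator,
    threshold_factor: float = 5.0,
):
    """Bifurcation-diagram data over replicate learned systems.

    ``learned`` is a sequence of (wbar, seq) pairs.  For each age in
    ``eta_list`` and each replicate, seeds a small and a large bump and
    records amplitudes, the shuffle-null, and the retrieval flag.
    """
    import pandas as pd

    rows = []
    for rep, (wbar, seq) in enumerate(learned):
        for eta in eta_list:
            env = seq.env_for_age(eta)
            small = seed_and_measure(
                wbar, seq, env, "small", config, rng, orderings=[env]
            )
            ok, big = retrieve(wbar, seq, eta, config, rng, threshold_factor)
            thr = bump_threshold(big, threshold_factor)
            rows.append(
                {
                    "rep": rep,
                    "eta": eta,
                    "amp_small": small.amplitudes[env],
                    "amp_large": big.amplitudes[env],
                    "null": big.null_amplitude,
                    "n_supra": sum(a > thr for a in big.amplitudes.values()),
                    "retrievable": ok,
                }
            )
    return pd.DataFrame(rows)
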