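"""The 1D BTSP map: feedforward induction, recurrent learning, trace stats.

The map collapses one plasticity "event" (a lap with a plateau potential,
or the exploration of one environment) into a single update of bounded
synaptic weights:

    w ← clip(w + P (1 − w) f_P(Δθ) − D w f_D(Δθ), 0, 1),

where f_P, f_D are spatial plasticity kernels in phase units and Δθ is the
phase difference between presynaptic place field and plateau onset
(feedforward) or between the two cells' place fields (recurrent).

Recurrent learning runs over a sequence of environments.  Each environment
globally remaps the place-field phases (an independent permutation of the
M·N cells over N phase slots) and activates each cell independently with
probability s; only synapses between co-active cells are updated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kernels import CosineKernel, PhaseKernel, cosine_kernel
from . import biophys as bp

__all__ = [
    "MapParams",
    "EnvironmentSequence",
    "OrderedStats",
    "feedforward_induction",
    "generate_environment_sequence",
    "recurrent_learn",
    "empirical_trace_stats",
    "block_average",
    "map_vs_biophys",
    "iterate_scalar_synapse",
]


@dataclass(frozen=True)
class MapParams:
    """Learning rates and kernel pair of the 1D map."""

    P: float
    D: float
    f_p: PhaseKernel
    f_d: PhaseKernel

    def __post_init__(self) -> None:
        if self.P < 0 or self.D < 0:
            raise ValueError("learning rates P and D must be nonnegative")

    @classmethod
    def cosine(cls, P: float, D: float) -> "MapParams":
        """Symmetric cosine rule f_P = 1+cos θ, f_D = 1−cos θ."""
        return cls(P=P, D=D, f_p=cosine_kernel("plus"), f_d=cosine_kernel("minus"))

    @property
    def is_cosine(self) -> bool:
        return isinstance(self.f_p, CosineKernel) and isinstance(self.f_d, CosineKernel)


def map_update(w, dtheta, params: MapParams):
    """One application of the map at phase offsets ``dtheta``; returns w'."""
    fp = params.f_p(dtheta)
    fd = params.f_d(dtheta)
    return np.clip(w + params.P * (1.0 - w) * fp - params.D * w * fd, 0.0, 1.0)


def feedforward_induction(w, theta_bar: float, params: MapParams, theta=None):
    """Weight profile after one plateau at phase ``theta_bar``.

    ``w`` lives on the uniform grid θ_i = 2π i / len(w) unless ``theta`` is
    given explicitly.
    """
    if not np.isfinite(theta_bar):
        raise ValueError("theta_bar must be finite")
    w = np.asarray(w, dtype=float)
    if theta is None:
        theta = 2.0 * np.pi * np.arange(w.shape[-1]) / w.shape[-1]
    return map_update(w, theta - theta_bar, params)


class EnvironmentSequence:
    """A sequence of globally remapped, sparsely active environments.

    Per environment k: ``slots[k, i]`` is the phase slot (0..N−1) of cell i
    (each slot hosts exactly M cells) and ``active[k, i]`` is a
    Bernoulli(s) mask.  Each environment draws from its own RNG sub-stream,
    so extending the sequence never reshuffles earlier environments.
    """

    def __init__(self, N: int, M: int, s: float, n: int, seed: int):
        if N < 1 or M < 1 or n < 1:
            raise ValueError("N, M and n must all be at least 1")
        if not 0.0 < s <= 1.0:
            raise ValueError(f"sparseness s must lie in (0, 1], got {s}")
        self.N, self.M, self.s, self.n, self.seed = N, M, float(s), n, seed
        base = np.arange(N).repeat(M)
        slots = np.empty((n, N * M), dtype=np.int32)
        active = np.empty((n, N * M), dtype=bool)
        for k, ss in enumerate(np.random.SeedSequence(seed).spawn(n)):
            rng = np.random.default_rng(ss)
            slots[k] = rng.permutation(base)
            active[k] = rng.random(N * M) < s
        self.slots = slots
        self.active = active

    @property
    def n_cells(self) -> int:
        return self.N * self.M

    def phase_angles(self, env: int) -> np.ndarray:
        """Place-field phases θ_i^env in [0, 2π)."""
        return 2.0 * np.pi * self.slots[env] / self.N

    def env_for_age(self, eta: int) -> int:
        """Environment index of age ``eta`` (0 = most recent)."""
        env = self.n - 1 - eta
        if not 0 <= env < self.n:
            raise ValueError(f"age {eta} outside the stored sequence (n={self.n})")
        return env


def generate_environment_sequence(
    N: int, M: int, s: float, n: int, seed: int
) -> EnvironmentSequence:
    return EnvironmentSequence(N=N, M=M, s=s, n=n, seed=seed)


def _kernel_tables(params: MapParams, N: int) -> tuple[np.ndarray, np.ndarray]:
    """f_P, f_D evaluated on the N discrete phase differences 2πk/N."""
    return params.f_p.on_grid(N), params.f_d.on_grid(N)


def recurrent_learn(
    W0: np.ndarray,
    seq: EnvironmentSequence,
    params: MapParams,
    snapshots=(),
) -> tuple[np.ndarray, dict]:
    """Evolve the recurrent weight matrix through all environments in order.

    Updates are applied in place on a copy of ``W0``, restricted to pairs of
    co-active cells; self-connections are never updated.  Returns the final
    matrix and a dict of requested per-environment snapshots (copies).
    """
    W = np.array(W0, dtype=float)
    mn = seq.n_cells
    if W.shape != (mn, mn):
        raise ValueError(f"W0 must be {(mn, mn)}, got {W.shape}")
    fp_tab, fd_tab = _kernel_tables(params, seq.N)
    P, D = params.P, params.D
    wanted = set(snapshots)
    snaps: dict[int, np.ndarray] = {}
    for k in range(seq.n):
        idx = np.flatnonzero(seq.active[k])
        if idx.size:
            sl = seq.slots[k, idx]
            d = np.mod(sl[:, None] - sl[None, :], seq.N)
            sub = W[np.ix_(idx, idx)]
            new = np.clip(
                sub + P * (1.0 - sub) * fp_tab[d] - D * sub * fd_tab[d], 0.0, 1.0
            )
            np.fill_diagonal(new, np.diag(sub))  # self-connections untouched
            W[np.ix_(idx, idx)] = new
        if k in wanted:
            snaps[k] = W.copy()
    return W, snaps


@dataclass(frozen=True)
class OrderedStats:
    """Weight statistics ordered by phase difference in one environment."""

    delta_theta: np.ndarray  # N phase-difference bins, in [0, 2π)
    mean_profile: np.ndarray
    var_profile: np.ndarray
    lo95: np.ndarray
    hi95: np.ndarray
    counts: np.ndarray
    amplitude: float  # 2⟨cos Δθ · w⟩, the first cosine coefficient
    sine_amplitude: float
    mean_weight: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "delta_theta": self.delta_theta,
                "mean": self.mean_profile,
                "var": self.var_profile,
                "lo95": self.lo95,
                "hi95": self.hi95,
                "count": self.counts,
            }
        )


def _active_pairs(seq: EnvironmentSequence, env: int):
    """Index and slot arrays of cells active in ``env``."""
    idx = np.flatnonzero(seq.active[env])
    return idx, seq.slots[env, idx]


def empirical_trace_stats(
    W: np.ndarray, seq: EnvironmentSequence, eta: int
) -> OrderedStats:
    """Memory-trace estimators for the environment of age ``eta``.

    Pairs of cells active in that environment (self-connections excluded)
    are binned by their discrete phase difference; the trace amplitude is
    the first cosine Fourier coefficient 2⟨cos Δθ·w⟩ over those pairs.
    """
    env = seq.env_for_age(eta)
    idx, sl = _active_pairs(seq, env)
    if idx.size < 2:
        raise ValueError("fewer than two active cells in the requested environment")
    d = np.mod(sl[:, None] - sl[None, :], seq.N)
    sub = W[np.ix_(idx, idx)]
    off = ~np.eye(idx.size, dtype=bool)
    dflat = d[off]
    wflat = sub[off]

    N = seq.N
    counts = np.bincount(dflat, minlength=N)
    sums = np.bincount(dflat, weights=wflat, minlength=N)
    sq = np.bincount(dflat, weights=wflat * wflat, minlength=N)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = sums / counts
        var = sq / counts - mean * mean
    var = np.maximum(var, 0.0)
    # First cosine coefficient by least squares on the binned profile.
    # Equivalent to the discrete Fourier coefficient 2⟨cos Δθ·w⟩ when every
    # bin is populated, and unbiased when some are not (at M=1 the Δθ=0 bin
    # holds only the excluded self-connections).
    have = counts > 0
    bin_theta = 2.0 * np.pi * np.arange(N) / N
    X = np.column_stack(
        [np.ones(have.sum()), np.cos(bin_theta[have]), np.sin(bin_theta[have])]
    )
    coef, *_ = np.linalg.lstsq(X, mean[have], rcond=None)
    amplitude = float(coef[1])
    sine_amplitude = float(coef[2])
    order = np.argsort(dflat, kind="stable")
    lo = np.full(N, np.nan)
    hi = np.full(N, np.nan)
    start = 0
    wsorted = wflat[order]
    for k in range(N):
        stop = start + counts[k]
        if counts[k] > 0:
            lo[k], hi[k] = np.percentile(wsorted[start:stop], [2.5, 97.5])
        start = stop
    return OrderedStats(
        delta_theta=2.0 * np.pi * np.arange(N) / N,
        mean_profile=mean,
        var_profile=var,
        lo95=lo,
        hi95=hi,
        counts=counts,
        amplitude=amplitude,
        sine_amplitude=sine_amplitude,
        mean_weight=float(wflat.mean()),
    )


def block_average(W: np.ndarray, seq: EnvironmentSequence, env: int):
    """Slot-level connectivity: average weight between active populations.

    Entry (b, a) averages w_ij over active presynaptic cells j in slot a and
    active postsynaptic cells i in slot b of ``env`` (self-connections
    excluded).  Slots with no active cell are flagged in ``missing`` and
    left NaN, never zero-filled.

    Returns ``(block, missing)`` with ``block`` of shape (N, N).
    """
    if not 0 <= env < seq.n:
        raise ValueError(f"environment {env} outside sequence of length {seq.n}")
    idx, sl = _active_pairs(seq, env)
    N = seq.N
    missing = np.array([not np.any(sl == a) for a in range(N)])
    block = np.full((N, N), np.nan)
    sub = np.array(W[np.ix_(idx, idx)], dtype=float)
    np.fill_diagonal(sub, np.nan)
    members = [np.flatnonzero(sl == a) for a in range(N)]
    for b in range(N):
        if missing[b]:
            continue
        rows = sub[members[b]]
        for a in range(N):
            if missing[a]:
                continue
            vals = rows[:, members[a]]
            if np.isnan(vals).all():
                continue
            block[b, a] = np.nanmean(vals)
    return block, missing


def map_vs_biophys(
    protocol: "bp.LapProtocol",
    biophys_params: "bp.BiophysParams",
    map_params: MapParams,
    lap: int = 0,
    w_grid=None,
) -> tuple[pd.DataFrame, float]:
    """Paired per-lap weight changes of the 1D map and the biophysical model.

    Both models are evaluated on the grid of presynaptic positions × initial
    weights for the given lap; returns the tidy table and the Pearson
    correlation of the two Δw columns (NaN when either column is constant,
    e.g. for a lap without a plateau).
    """
    if w_grid is None:
        w_grid = np.linspace(0.0, 1.0, 5)
    w_grid = np.asarray(w_grid, dtype=float)
    positions = protocol.input_positions()
    theta = 2.0 * np.pi * positions / protocol.track_length
    x_pp = protocol.plateau_positions[lap]
    dq_plus, dq_minus = bp.lap_overlap_integrals(protocol, biophys_params, lap)
    rows = []
    for w0 in w_grid:
        wvec = np.full(positions.size, w0)
        dw_bio = (1.0 - wvec) * biophys_params.k_plus * dq_plus \
            - wvec * biophys_params.k_minus * dq_minus
        dw_bio = np.clip(wvec + dw_bio, 0.0, 1.0) - wvec
        if x_pp is None:
            dw_map = np.zeros_like(wvec)
        else:
            theta_bar = 2.0 * np.pi * x_pp / protocol.track_length
            dw_map = map_update(wvec, theta - theta_bar, map_params) - wvec
        for pos, a, b in zip(positions, dw_map, dw_bio):
            rows.append((pos, w0, a, b))
    table = pd.DataFrame(rows, columns=["position", "w_init", "dw_map", "dw_biophys"])
    if table["dw_map"].std() == 0.0 or table["dw_biophys"].std() == 0.0:
        r = float("nan")
    else:
        r = float(np.corrcoef(table["dw_map"], table["dw_biophys"])[0, 1])
    return table, r


def iterate_scalar_synapse(
    params: MapParams,
    s: float,
    n_steps: int,
    rng: np.random.Generator,
    w0: float = 0.5,
) -> np.ndarray:
    """Monte-Carlo twin of the theory: one synapse iterated over random
    environments (uniform Δθ, Bernoulli(s)² gating).  Returns the weight
    trajectory of length n_steps+1 — the long-run marginal is the
    steady-state weight distribution."""
    w = np.empty(n_steps + 1)
    w[0] = w0
    cur = w0
    for k in range(n_steps):
        if rng.random() < s * s:
            cur = float(map_update(cur, rng.uniform(0.0, 2.0 * np.pi), params))
        w[k + 1] = cur
    return w
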