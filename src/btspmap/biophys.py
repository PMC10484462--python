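"""Reference biophysical BTSP model (eligibility trace × instructive signal).

A CA1 cell receives N Gaussian-tuned CA3 inputs while a virtual animal runs
laps at constant velocity.  Presynaptic activity drives a synapse-specific
eligibility trace (ET); a dendritic plateau potential (PP) drives a global
instructive signal (IS).  Both are first-order low-pass filters, rescaled
to unit peak within each lap so that their product lies in [0, 1], the
anchoring domain of the normalized sigmoid gains q± that convert overlap
into potentiation and depression.  The per-lap weight change is

    Δw_i = (1 − w_i) k⁺ ΔQ⁺_i − w_i k⁻ ΔQ⁻_i,   ΔQ± = ∫ q±(ET_i·IS) dt,

with weights clipped to [0, 1].  This model is the ground truth against
which the 1D spatial map is validated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BiophysParams",
    "LapProtocol",
    "normalized_sigmoid",
    "input_rates_and_plateau",
    "lap_plasticity",
    "run_protocol",
]

_SQRT2 = np.sqrt(2.0)


@dataclass(frozen=True)
class BiophysParams:
    tau_et: float  # eligibility-trace time constant, s
    tau_is: float  # instructive-signal time constant, s
    alpha_plus: float
    beta_plus: float
    alpha_minus: float
    beta_minus: float
    k_plus: float
    k_minus: float
    r_max: float = 1.0
    field_sigma: float = 90.0 / (3.0 * _SQRT2)  # place-field width, cm
    plateau_duration: float = 0.3  # s

    def __post_init__(self) -> None:
        for name in ("tau_et", "tau_is", "beta_plus", "beta_minus", "k_plus",
                     "k_minus", "r_max", "field_sigma", "plateau_duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class LapProtocol:
    """Virtual-track protocol: one entry of ``plateau_positions`` per lap
    (position in cm, or None for a lap without a plateau)."""

    track_length: float
    velocity: float
    n_inputs: int
    plateau_positions: tuple = ()
    dt: float = 0.01

    def __post_init__(self) -> None:
        if self.track_length <= 0 or self.velocity <= 0:
            raise ValueError("track_length and velocity must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_inputs < 1:
            raise ValueError("n_inputs must be at least 1")
        object.__setattr__(
            self, "plateau_positions", tuple(self.plateau_positions)
        )
        for x in self.plateau_positions:
            if x is not None and not 0.0 <= x < self.track_length:
                raise ValueError("plateau positions must lie in [0, L)")

    @property
    def n_laps(self) -> int:
        return len(self.plateau_positions)

    @property
    def lap_duration(self) -> float:
        return self.track_length / self.velocity

    def input_positions(self) -> np.ndarray:
        """Peak firing positions y_i, uniformly spaced on [0, L)."""
        return self.track_length * np.arange(self.n_inputs) / self.n_inputs


def normalized_sigmoid(x, alpha: float, beta: float):
    """Logistic gain rescaled so s(0) = 0 and s(1) = 1."""
    def raw(u):
        return 1.0 / (1.0 + np.exp(-beta * (np.asarray(u, dtype=float) - alpha)))

    s0, s1 = raw(0.0), raw(1.0)
    return (raw(x) - s0) / (s1 - s0)


def input_rates_and_plateau(protocol: LapProtocol, params: BiophysParams, lap: int):
    """Time series of input rates R_i(t) and the plateau indicator P(t).

    Returns ``(t, rates, plateau)`` with ``rates`` of shape
    ``(n_steps, n_inputs)``.  Distances on the circular track are taken
    through the shorter arc.
    """
    if not 0 <= lap < protocol.n_laps:
        raise ValueError(f"lap {lap} outside protocol with {protocol.n_laps} laps")
    if params.field_sigma / protocol.velocity < 3.0 * protocol.dt:
        raise ValueError("dt does not resolve the narrowest place field")
    t = np.arange(0.0, protocol.lap_duration, protocol.dt)
    x = np.mod(protocol.velocity * t, protocol.track_length)
    y = protocol.input_positions()
    d = np.abs(x[:, None] - y[None, :])
    d = np.minimum(d, protocol.track_length - d)
    rates = params.r_max * np.exp(-0.5 * (d / params.field_sigma) ** 2)
    plateau = np.zeros_like(t)
    x_pp = protocol.plateau_positions[lap]
    if x_pp is not None:
        t_pp = x_pp / protocol.velocity
        plateau[(t >= t_pp) & (t < t_pp + params.plateau_duration)] = 1.0
    return t, rates, plateau


def _lowpass(drive: np.ndarray, tau: float, dt: float) -> np.ndarray:
    """Explicit-Euler first-order filter of ``drive`` along axis 0."""
    out = np.zeros_like(drive)
    decay = 1.0 - dt / tau
    state = np.zeros(drive.shape[1:] if drive.ndim > 1 else ())
    for k in range(drive.shape[0]):
        state = state * decay + (dt / tau) * drive[k]
        out[k] = state
    return out


def lap_plasticity(
    w: np.ndarray, protocol: LapProtocol, params: BiophysParams, lap: int
) -> np.ndarray:
    """Per-lap weight change Δw for every input synapse.

    ET and IS are low-pass filters of R_i/R_max and P(t), each rescaled to
    unit peak over the lap; Δw is clipped so that w + Δw stays in [0, 1].
    """
    w = np.asarray(w, dtype=float)
    if w.shape != (protocol.n_inputs,):
        raise ValueError("weight vector length must equal n_inputs")
    if (w < 0).any() or (w > 1).any():
        raise ValueError("weights must lie in [0, 1]")
    dq_plus, dq_minus = lap_overlap_integrals(protocol, params, lap)
    dw = (1.0 - w) * params.k_plus * dq_plus - w * params.k_minus * dq_minus
    return np.clip(w + dw, 0.0, 1.0) - w


def lap_overlap_integrals(protocol: LapProtocol, params: BiophysParams, lap: int):
    """ΔQ⁺_i and ΔQ⁻_i for one lap (weight-independent part of the rule)."""
    _, rates, plateau = input_rates_and_plateau(protocol, params, lap)
    if plateau.max() == 0.0:
        z = np.zeros(protocol.n_inputs)
        return z, z.copy()
    et = _lowpass(rates / params.r_max, params.tau_et, protocol.dt)
    inst = _lowpass(plateau, params.tau_is, protocol.dt)
    et = et / et.max(axis=0, keepdims=True)
    inst = inst / inst.max()
    overlap = et * inst[:, None]
    q_plus = normalized_sigmoid(overlap, params.alpha_plus, params.beta_plus)
    q_minus = normalized_sigmoid(overlap, params.alpha_minus, params.beta_minus)
    return q_plus.sum(axis=0) * protocol.dt, q_minus.sum(axis=0) * protocol.dt


def run_protocol(
    protocol: LapProtocol, params: BiophysParams, w0: np.ndarray
) -> np.ndarray:
    """Apply lap_plasticity sequentially; returns (n_laps+1, N) history
    starting with w0."""
    w = np.asarray(w0, dtype=float).copy()
    history = [w.copy()]
    for lap in range(protocol.n_laps):
        w += lap_plasticity(w, protocol, params, lap)
        history.append(w.copy())
    return np.array(history)
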