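"""Reference parameter sets for the standard virtual-track experiment
(187 cm circular track, 25 cm/s, 100 tuned inputs) and the skew-t kernel
fits of the biophysical plasticity processes at that velocity."""

from __future__ import annotations

from .biophys import BiophysParams, LapProtocol
from .kernels import SkewTParams, build_phase_kernel
from .plasticity import MapParams

__all__ = [
    "reference_biophys_params",
    "reference_map_params",
    "reference_protocol",
]

TRACK_LENGTH = 187.0  # cm
VELOCITY = 25.0  # cm/s
N_INPUTS = 100


def reference_biophys_params() -> BiophysParams:
    """Eligibility/instructive-signal model constants fitted to CA1
    plateau-induction experiments (time constants in seconds)."""
    return BiophysParams(
        tau_et=1.6641,
        tau_is=0.737,
        alpha_plus=0.415,
        beta_plus=3.609,
        alpha_minus=0.026,
        beta_minus=13.815,
        k_plus=0.9,
        k_minus=0.275,
    )


def reference_map_params(
    v: float = VELOCITY, L: float = TRACK_LENGTH, wrap_tol: float = 1e-8
) -> MapParams:
    """1D-map learning rates and wrapped skew-t kernels fitted to the
    biophysical model at velocity ``v`` on a track of length ``L``."""
    f_p = build_phase_kernel(
        SkewTParams(loc=0.685, scale=1.65, skew=-1.61, dof=3.5),
        v=v, L=L, wrap_tol=wrap_tol,
    )
    f_d = build_phase_kernel(
        SkewTParams(loc=1.75, scale=3.65, skew=-5.35, dof=5.0),
        v=v, L=L, wrap_tol=wrap_tol,
    )
    return MapParams(P=2.365, D=2.57, f_p=f_p, f_d=f_d)


def reference_protocol(plateau_positions=(93.5,), dt: float = 0.01) -> LapProtocol:
    return LapProtocol(
        track_length=TRACK_LENGTH,
        velocity=VELOCITY,
        n_inputs=N_INPUTS,
        plateau_positions=plateau_positions,
        dt=dt,
    )
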