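"""Closed-form statistics of the BTSP-learned weight matrix.

After many environments the bounded-weight map reaches a statistical
steady state.  Ordering the matrix by the phases of an environment of age
η (0 = most recent) reveals a memory trace: a mean profile
μ_w + a_η cos Δθ whose amplitude decays geometrically with age
(the palimpsest property), superposed with quenched variability
V_η(Δθ) = A_η + B_η cos Δθ + C_η cos²Δθ from interference with all other
stored environments.  The signal-to-noise ratio of the trace defines a
structural memory capacity; projecting the variability onto spatial
Fourier modes quantifies how it shifts the Turing bifurcation of the
associated ring attractor model.

The amplitude is available for arbitrary kernels; the variance recursion
follows the cosine rule f_P = 1 + cos θ, f_D = 1 − cos θ, for which it is
exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .kernels import KernelMoments, kernel_moments
from .plasticity import MapParams

__all__ = [
    "TraceStats",
    "CapacityEstimate",
    "NoiseFourierStats",
    "TuringResult",
    "steady_state_moments",
    "memory_trace",
    "trace_amplitude_general",
    "snr_curve",
    "snr_capacity",
    "quenched_fourier_stats",
    "sample_noise_profiles",
    "fourier_coefficients",
    "turing_thresholds",
]


def _cosine_f_moments(P: float, D: float, s: float) -> tuple[float, float]:
    """⟨F⟩ and ⟨F²⟩ for the cosine rule with Bernoulli(s) activity gating."""
    mean_f = 1.0 - s * s * (P + D)
    second_f = 1.0 + s * s * (3 * P * P + 3 * D * D + 2 * P * D - 4 * P - 4 * D) / 2.0
    return mean_f, second_f


def steady_state_moments(
    params: MapParams, moments: KernelMoments | None = None, s: float = 1.0
) -> tuple[float, float]:
    """Steady-state mean and variance of the weight matrix.

    Sparseness only slows convergence — a synapse is updated with
    probability s² per environment — so the steady-state values themselves
    do not depend on s.
    """
    if moments is None:
        moments = kernel_moments(params.f_p, params.f_d)
    P, D = params.P, params.D
    denom = P * moments.mean_p + D * moments.mean_d
    if denom <= 0:
        raise ValueError("P⟨f_P⟩ + D⟨f_D⟩ must be positive")
    mu = P * moments.mean_p / denom
    second_f = moments.second_f(P, D)
    if second_f >= 1.0:
        raise ValueError("no stochastic steady state: ⟨F²⟩ >= 1 (map not contracting)")
    second_w = (P * P * moments.second_p + 2.0 * P * mu * moments.cross_pf(P, D)) / (
        1.0 - second_f
    )
    return mu, second_w - mu * mu


def _geom_diff(x: float, y: float, eta) -> np.ndarray:
    """(x^η − y^η)/(x − y) with the confluent limit η x^(η−1)."""
    eta = np.asarray(eta, dtype=float)
    if abs(x - y) < 1e-12:
        return eta * x ** (eta - 1.0)
    return (x ** eta - y ** eta) / (x - y)


def _gsum(x: float, eta) -> np.ndarray:
    """(1 − x^η)/(1 − x), the geometric partial sum."""
    eta = np.asarray(eta, dtype=float)
    if abs(1.0 - x) < 1e-12:
        return eta
    return (1.0 - x ** eta) / (1.0 - x)


@dataclass(frozen=True)
class TraceStats:
    """Trace amplitude and variance-profile coefficients per age."""

    eta: np.ndarray
    a: np.ndarray
    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    mu_w: float
    sigma2_w: float
    mean_f: float
    second_f: float

    def variance_profile(self, delta_theta, i: int = 0) -> np.ndarray:
        """V_η(Δθ) for the i-th stored age."""
        c = np.cos(delta_theta)
        return self.A[i] + self.B[i] * c + self.C[i] * c * c

    def mean_variance(self) -> np.ndarray:
        """⟨V_η⟩ over the circle: A_η + C_η/2."""
        return self.A + self.C / 2.0


def memory_trace(
    eta, P: float, D: float, s: float = 1.0, params: MapParams | None = None
) -> TraceStats:
    """Mean amplitude a_η and variance coefficients (A_η, B_η, C_η) for the
    cosine plasticity rule with sparseness s ∈ (0, 1].

    a_η = (2PD/(P+D)) (1 − s²(P+D))^η ; the variance coefficients follow the
    steady-state recursion with ⟨F⟩ = 1 − s²(P+D) and
    ⟨F²⟩ = 1 + s²(3P² + 3D² + 2PD − 4P − 4D)/2.

    The variance recursion is specific to the cosine kernel pair; for other
    kernels only the amplitude is available (see
    :func:`trace_amplitude_general`), and passing a non-cosine ``params``
    raises ``NotImplementedError``.
    """
    if params is not None and not params.is_cosine:
        raise NotImplementedError(
            "variance recursion is implemented for cosine kernels only; "
            "use trace_amplitude_general for the amplitude of other kernels"
        )
    if not 0.0 < s <= 1.0:
        raise ValueError("s must lie in (0, 1]")
    eta = np.atleast_1d(np.asarray(eta, dtype=float))
    params = MapParams.cosine(P, D)
    mu, sigma2 = steady_state_moments(params)
    w2 = sigma2 + mu * mu
    fm, f2 = _cosine_f_moments(P, D, s)
    if f2 >= 1.0:
        raise ValueError("no stochastic steady state: ⟨F²⟩ >= 1")

    a0 = 2.0 * P * D / (P + D)
    a = a0 * fm ** eta

    one = 1.0 - P - D  # ⟨F⟩ within the fully active trace environment
    A0 = P * P + 2.0 * P * one * mu + one * one * w2 - mu * mu
    B0 = 2.0 * (P - D) / (P + D) * (
        P * P + P * (1.0 - 2.0 * P - 2.0 * D) * mu - (P + D) * one * w2
    )
    C0 = ((P - D) / (P + D)) ** 2 * (
        P * P - 2.0 * P * (P + D) * mu + (P + D) ** 2 * w2
    )

    e = 1.0 - 1.5 * P - 0.5 * D
    s2, s4 = s * s, s ** 4
    f2_pow = f2 ** eta
    fm_pow = fm ** eta
    fm_pow2 = fm ** (2.0 * eta)

    if abs(fm - f2) < 1e-12:
        # limit of [g(fm) − g(f2)]/(fm − f2) with g(x) = (1 − x^η)/(1 − x)
        nested = (
            -eta * fm ** (eta - 1.0) * (1.0 - fm) + (1.0 - fm ** eta)
        ) / (1.0 - fm) ** 2
    else:
        nested = (_gsum(fm, eta) - _gsum(f2, eta)) / (fm - f2)

    A = (
        A0 * f2_pow
        + mu * mu * (f2_pow - 1.0)
        + 1.5 * P * P * s2 * _gsum(f2, eta)
        + 2.0 * P * P * s4 * e * nested
        + 2.0 * mu * P * s2 * e * _geom_diff(fm, f2, eta)
    )
    B = (
        B0 * f2_pow
        + 2.0 * a0 * mu * (f2_pow - fm_pow2)
        + 2.0 * a0 * P * s2
        * (e * _geom_diff(fm, f2, eta) - (fm_pow - fm_pow2) / (1.0 - fm))
    )
    C = C0 * f2_pow + a0 * a0 * (f2_pow - fm_pow2)
    return TraceStats(
        eta=eta, a=a, A=A, B=B, C=C,
        mu_w=mu, sigma2_w=sigma2, mean_f=fm, second_f=f2,
    )


def trace_amplitude_general(
    eta, params: MapParams, s: float = 1.0, moments: KernelMoments | None = None
) -> np.ndarray:
    """Trace amplitude for arbitrary even kernels:
    a_η = 2(P⟨cos·f_P⟩ + μ_w⟨cos·F⟩)⟨F⟩^η with ⟨cos·F⟩ = −P⟨cos·f_P⟩ − D⟨cos·f_D⟩.
    """
    if moments is None:
        moments = kernel_moments(params.f_p, params.f_d)
    P, D = params.P, params.D
    mu, _ = steady_state_moments(params, moments)
    cos_f = -P * moments.cos_p - D * moments.cos_d
    a0 = 2.0 * (P * moments.cos_p + mu * cos_f)
    # sparsity gates each update with probability s²
    mean_f = 1.0 - s * s * (P * moments.mean_p + D * moments.mean_d)
    return a0 * mean_f ** np.asarray(eta, dtype=float)


def snr_curve(eta, P: float, D: float, s: float, M: float) -> np.ndarray:
    """SNR_η = √(sM)·a_η / √(A_η + C_η/2) (spatially flat noise component)."""
    ts = memory_trace(eta, P, D, s)
    return np.sqrt(s * M) * ts.a / np.sqrt(ts.mean_variance())


@dataclass(frozen=True)
class CapacityEstimate:
    """Structural capacity from the SNR threshold crossing (P = D)."""

    eta_max: int  # floor of the exact real crossing
    eta_max_real: float
    eta_max_closed: float  # closed-form crossing
    eta_max_asymptotic: float  # large-sM, small-s² simplification
    T: float
    s: float
    M: float
    P: float


def snr_capacity(s: float, M: float, P: float, T: float = 1.0) -> CapacityEstimate:
    """Capacity η_max for the symmetric rule P = D.

    The exact crossing solves SNR_η = T on the continuous-η SNR; the closed
    form is −ln(8P(1−P)T²(sM + T²/2)) / (2 ln(1 − 2s²P)); the asymptotic
    form is ln(8P(1−P)sM)/(4s²P).
    """
    if T <= 0:
        raise ValueError("threshold T must be positive")
    if not 0.0 < s <= 1.0 or M < 1:
        raise ValueError("need s in (0,1] and M >= 1")
    sM = s * M

    def g(eta):
        return float(snr_curve(eta, P, P, s, M)[0]) - T

    if g(0.0) <= 0.0:
        eta_real = 0.0
    else:
        hi = 1.0
        while g(hi) > 0.0 and hi < 1e9:
            hi *= 2.0
        eta_real = float(optimize.brentq(g, 0.0, hi))
    closed = -np.log(8.0 * P * (1.0 - P) * T * T * (sM + T * T / 2.0)) / (
        2.0 * np.log(1.0 - 2.0 * s * s * P)
    )
    asym = np.log(sM * 8.0 * P * (1.0 - P)) / (4.0 * s * s * P)
    return CapacityEstimate(
        eta_max=int(np.floor(eta_real)),
        eta_max_real=eta_real,
        eta_max_closed=float(closed),
        eta_max_asymptotic=float(asym),
        T=T, s=s, M=M, P=P,
    )


@dataclass(frozen=True)
class NoiseFourierStats:
    """Statistics of the spatial Fourier modes of a quenched noise profile
    ΔW(θ) = √V(θ)·z(θ) sampled on N grid points, with
    ΔW(θ) = 2Σ α_j cos jθ + 2Σ β_j sin jθ."""

    var_alpha1: float
    var_beta1: float
    var_higher: float
    cov_lag1: float
    cov_lag2: float
    r_mean: float  # ⟨R⟩ = E[2√(α₁² + β₁²)], the expected first-mode modulation
    N: int


def _expected_first_mode_modulus(var_a: float, var_b: float) -> float:
    """E[2√(X²+Y²)] for independent zero-mean Gaussians X, Y.

    In polar form the radius is Rayleigh (mean √(π/2)) and the angular
    average of the anisotropic scale is a smooth 1D integral.
    """
    phi = np.linspace(0.0, 2.0 * np.pi, 4096, endpoint=False)
    angular = np.mean(np.sqrt(var_a * np.cos(phi) ** 2 + var_b * np.sin(phi) ** 2))
    return 2.0 * np.sqrt(np.pi / 2.0) * angular


def quenched_fourier_stats(A: float, B: float, C: float, N: int) -> NoiseFourierStats:
    """Mode statistics of quenched noise with variance profile
    V(θ) = A + B cos θ + C cos²θ."""
    if N < 3:
        raise ValueError("N must be at least 3")
    theta = 2.0 * np.pi * np.arange(max(N, 64)) / max(N, 64)
    v = A + B * np.cos(theta) + C * np.cos(theta) ** 2
    if (v < -1e-12).any():
        raise ValueError("variance profile V(θ) is negative somewhere on the grid")
    var_a1 = (A + 0.75 * C) / (2.0 * N)
    var_b1 = (A + 0.25 * C) / (2.0 * N)
    return NoiseFourierStats(
        var_alpha1=var_a1,
        var_beta1=var_b1,
        var_higher=(A + 0.5 * C) / (2.0 * N),
        cov_lag1=B / (4.0 * N),
        cov_lag2=C / (8.0 * N),
        r_mean=_expected_first_mode_modulus(var_a1, var_b1),
        N=N,
    )


def sample_noise_profiles(
    A: float, B: float, C: float, N: int, n_samples: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw quenched profiles ΔW(θ_k) = √V(θ_k) z_k, z white unit Gaussian."""
    theta = 2.0 * np.pi * np.arange(N) / N
    v = A + B * np.cos(theta) + C * np.cos(theta) ** 2
    if (v < -1e-12).any():
        raise ValueError("variance profile V(θ) is negative somewhere on the grid")
    return np.sqrt(np.maximum(v, 0.0)) * rng.standard_normal((n_samples, N))


def fourier_coefficients(profiles: np.ndarray, n_modes: int):
    """α_j, β_j of sampled profiles: α_j = (1/N)Σ_k ΔW(θ_k) cos(jθ_k)."""
    profiles = np.atleast_2d(profiles)
    N = profiles.shape[1]
    theta = 2.0 * np.pi * np.arange(N) / N
    js = np.arange(1, n_modes + 1)
    cos = np.cos(js[:, None] * theta[None, :])
    sin = np.sin(js[:, None] * theta[None, :])
    alphas = profiles @ cos.T / N
    betas = profiles @ sin.T / N
    return alphas, betas


@dataclass(frozen=True)
class TuringResult:
    """Turing-threshold capacities of the ring-model hierarchy."""

    w1_cr_clean: float  # 2/φ₀′
    w1_cr_noisy: float  # 2/φ₀′ − ⟨R⟩ at the crossing age
    eta_cr_clean: int
    eta_cr_noisy: int
    eta_cr_closed: float  # leading-order closed form
    r_mean_at_crossing: float


def _w1_of_age(eta, P, D, s, M, kappa, W_max) -> float:
    a = float(memory_trace(eta, P, D, s).a[0])
    return W_max * (s * M / kappa) * a


def turing_thresholds(
    phi_slope: float,
    P: float,
    D: float,
    s: float,
    M: float,
    kappa: float,
    W_max: float,
    N: int,
    W0: float | None = None,
) -> TuringResult:
    """Oldest environment whose ring model sits at the Turing bifurcation.

    The spatially modulated connectivity of age η is
    W₁^η = W_max (sM/κ) a_η; the clean threshold is 2/φ₀′.  Quenched
    variability — connectivity noise of scale W_max (sM/κ) √V_η on the ring
    projection, which empirically matches the slot-level disorder of
    learned matrices (weight variance plus binomial slot occupancy) — puts
    power ⟨R⟩ into the first spatial mode and lowers the threshold to
    2/φ₀′ − ⟨R⟩.
    """
    if phi_slope <= 0:
        raise ValueError("phi_slope must be positive")
    if W0 is not None and W0 >= 1.0 / phi_slope:
        raise ValueError("uniform instability: W0 >= 1/phi_slope")
    w1_clean = 2.0 / phi_slope
    noise_scale = W_max * s * M / kappa  # multiplies √V_η

    def r_mean(eta):
        ts = memory_trace(eta, P, D, s)
        stats = quenched_fourier_stats(
            float(ts.A[0]) * noise_scale ** 2,
            float(ts.B[0]) * noise_scale ** 2,
            float(ts.C[0]) * noise_scale ** 2,
            N,
        )
        return stats.r_mean

    def clean_gap(eta):
        return _w1_of_age(eta, P, D, s, M, kappa, W_max) - w1_clean

    def noisy_gap(eta):
        return _w1_of_age(eta, P, D, s, M, kappa, W_max) - (w1_clean - r_mean(eta))

    def crossing(gap):
        if gap(0.0) <= 0.0:
            return 0.0
        hi = 1.0
        while gap(hi) > 0.0 and hi < 1e9:
            hi *= 2.0
        if gap(hi) > 0.0:
            # ⟨R⟩ alone exceeds the threshold: modulation persists at any age
            return hi
        return float(optimize.brentq(gap, 0.0, hi))

    eta_clean = crossing(clean_gap)
    eta_noisy = crossing(noisy_gap)
    r_at = r_mean(eta_noisy)
    closed = (1.0 / (s * s * (P + D))) * np.log(
        (s * M / kappa) * W_max * phi_slope * P * D / (P + D)
    )
    return TuringResult(
        w1_cr_clean=w1_clean,
        w1_cr_noisy=w1_clean - r_at,
        eta_cr_clean=int(np.floor(eta_clean)),
        eta_cr_noisy=int(np.floor(eta_noisy)),
        eta_cr_closed=float(closed),
        r_mean_at_crossing=r_at,
    )
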