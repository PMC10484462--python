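"""Spatial plasticity kernels on the circle.

BTSP potentiation and depression are described by temporal kernels centred
on the plateau-potential onset.  For an animal running at constant velocity
``v`` on a circular track of length ``L``, a temporal kernel ``f̄(t)``
becomes a spatial kernel ``f̄((x − x_PP)/v)`` which must be wrapped around
the track (teleportation makes the track a circle).  In phase units
``θ = 2π x / L`` this yields a periodic plasticity function ``f(θ)``.

Two families are provided:

* wrapped skew-t kernels — the shape that fits the biophysical model; and
* the analytically convenient cosine kernels ``f_P = 1 + cos θ``,
  ``f_D = 1 − cos θ`` used throughout the recurrent-network theory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate
from scipy import stats

__all__ = [
    "SkewTParams",
    "PhaseKernel",
    "CosineKernel",
    "WrappedSkewTKernel",
    "KernelMoments",
    "skew_t_pdf",
    "build_phase_kernel",
    "cosine_kernel",
    "kernel_moments",
    "grid_kernel_moments",
]

_MAX_WRAPS = 10_000


@dataclass(frozen=True)
class SkewTParams:
    """Location/scale/skewness/dof of a skew-t temporal kernel (seconds)."""

    loc: float
    scale: float
    skew: float
    dof: float

    def __post_init__(self) -> None:
        if not np.isfinite([self.loc, self.scale, self.skew, self.dof]).all():
            raise ValueError("skew-t parameters must be finite")
        if self.scale <= 0:
            raise ValueError(f"scale must be positive, got {self.scale}")
        if self.dof <= 0:
            raise ValueError(f"dof must be positive, got {self.dof}")


def skew_t_pdf(t, params: SkewTParams):
    """Skew-t probability density (Azzalini form).

    ``2/σ · t_ν(z) · T_{ν+1}(λ z √((ν+1)/(ν+z²)))`` with ``z = (t−μ)/σ``,
    where ``t_ν`` and ``T_{ν+1}`` are the pdf and cdf of the standardised
    Student t distribution.  Integrates to one over the real line.
    """
    t = np.asarray(t, dtype=float)
    if not np.isfinite(t).all():
        raise ValueError("evaluation points must be finite")
    z = (t - params.loc) / params.scale
    nu = params.dof
    arg = params.skew * z * np.sqrt((nu + 1.0) / (nu + z * z))
    return 2.0 / params.scale * stats.t.pdf(z, nu) * stats.t.cdf(arg, nu + 1.0)


def _tail_interval(params: SkewTParams, tol: float) -> tuple[float, float]:
    """Interval [lo, hi] outside which the skew-t mass is below ``tol``."""
    # The skew-t tail is bounded by twice the symmetric-t tail, so the
    # symmetric quantile at tol/4 on each side is a safe enclosure.
    q = stats.t.ppf(tol / 4.0, params.dof)
    lo = params.loc + params.scale * q
    hi = params.loc - params.scale * q
    return lo, hi


class PhaseKernel:
    """A nonnegative 2π-periodic plasticity function f(θ)."""

    def __call__(self, theta):  # pragma: no cover - abstract
        raise NotImplementedError

    def on_grid(self, n: int) -> np.ndarray:
        """Evaluate on the uniform grid θ_i = 2π i / n."""
        return self(2.0 * np.pi * np.arange(n) / n)

    def fwhm(self, n: int = 8192) -> float:
        """Full width at half maximum, in phase units."""
        theta = 2.0 * np.pi * np.arange(n) / n
        f = self(theta)
        peak = np.argmax(f)
        half = f[peak] / 2.0
        # rotate so the peak sits mid-array, then scan outwards
        f = np.roll(f, n // 2 - peak)
        above = f >= half
        idx = np.flatnonzero(above)
        return (idx[-1] - idx[0] + 1) * 2.0 * np.pi / n

    def to_frame(self, n: int = 1024):
        """Two-column table (theta, f) for export."""
        import pandas as pd

        theta = 2.0 * np.pi * np.arange(n) / n
        return pd.DataFrame({"theta": theta, "f": self(theta)})


@dataclass(frozen=True)
class CosineKernel(PhaseKernel):
    """f(θ) = 1 ± cos θ, the symmetric rule used in the recurrent theory."""

    sign: int = 1

    def __post_init__(self) -> None:
        if self.sign not in (-1, 1):
            raise ValueError("sign must be +1 or -1")

    def __call__(self, theta):
        return 1.0 + self.sign * np.cos(theta)


def cosine_kernel(sign) -> CosineKernel:
    """Cosine kernel by sign: 'plus'/+1 → 1+cos θ, 'minus'/−1 → 1−cos θ."""
    mapping = {"plus": 1, "minus": -1, 1: 1, -1: -1}
    try:
        return CosineKernel(mapping[sign])
    except KeyError:
        raise ValueError(f"unknown cosine kernel sign {sign!r}") from None


@dataclass(frozen=True)
class WrappedSkewTKernel(PhaseKernel):
    """Skew-t temporal kernel wrapped onto a circular track.

    f(θ) = Σ_i f̄((x̂ − x_PP + i L)/v) with x̂ = θ L / (2π).  The wrap sum is
    truncated once the temporal tail mass left outside the covered span is
    below ``wrap_tol``.

    ``normalization='density'`` keeps f in the temporal-pdf units (s⁻¹), so
    the learning rates P, D of the 1D map set the plasticity amplitude on
    the same scale as the paper's fitted values; ``'unit_peak'`` rescales
    the maximum to one.
    """

    params: SkewTParams
    velocity: float
    track_length: float
    x_pp: float = 0.0
    wrap_tol: float = 1e-8
    normalization: str = "density"
    _scale: float = field(default=0.0, init=False, repr=False, compare=False)
    _n_wraps: int = field(default=0, init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.velocity <= 0 or self.track_length <= 0:
            raise ValueError("velocity and track_length must be positive")
        if not 0.0 <= self.x_pp < self.track_length:
            raise ValueError("x_pp must lie in [0, track_length)")
        if self.wrap_tol <= 0:
            raise ValueError("wrap_tol must be positive")
        if self.normalization not in ("density", "unit_peak"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        lap_time = self.track_length / self.velocity
        lo, hi = _tail_interval(self.params, self.wrap_tol)
        n_wraps = int(np.ceil(max(abs(lo), abs(hi)) / lap_time)) + 1
        if n_wraps > _MAX_WRAPS:
            raise ValueError(
                f"wrap sum needs {n_wraps} terms, above the cap {_MAX_WRAPS}; "
                "increase wrap_tol or the ratio track_length/velocity"
            )
        object.__setattr__(self, "_n_wraps", n_wraps)
        scale = 1.0
        if self.normalization == "unit_peak":
            raw = self._raw(2.0 * np.pi * np.arange(4096) / 4096)
            scale = 1.0 / raw.max()
        object.__setattr__(self, "_scale", scale)

    def _raw(self, theta) -> np.ndarray:
        theta = np.mod(np.asarray(theta, dtype=float), 2.0 * np.pi)
        x_hat = theta * self.track_length / (2.0 * np.pi)
        total = np.zeros_like(x_hat)
        L, v = self.track_length, self.velocity
        for i in range(-self._n_wraps, self._n_wraps + 1):
            total += skew_t_pdf((x_hat - self.x_pp + i * L) / v, self.params)
        return total

    def __call__(self, theta):
        return self._scale * self._raw(theta)


def build_phase_kernel(
    params: SkewTParams,
    v: float,
    L: float,
    x_pp: float = 0.0,
    wrap_tol: float = 1e-8,
    normalization: str = "density",
) -> WrappedSkewTKernel:
    """Wrap the temporal skew-t kernel onto a track of length ``L`` (cm)
    traversed at velocity ``v`` (cm/s), plateau onset at ``x_pp`` (cm)."""
    return WrappedSkewTKernel(
        params=params,
        velocity=v,
        track_length=L,
        x_pp=x_pp,
        wrap_tol=wrap_tol,
        normalization=normalization,
    )


@dataclass(frozen=True)
class KernelMoments:
    """Uniform circular averages of a potentiation/depression kernel pair."""

    mean_p: float
    mean_d: float
    second_p: float
    second_d: float
    cross: float
    cos_p: float
    cos_d: float

    def mean_f(self, P: float, D: float) -> float:
        """⟨F⟩ with F = 1 − P f_P − D f_D."""
        return 1.0 - P * self.mean_p - D * self.mean_d

    def second_f(self, P: float, D: float) -> float:
        """⟨F²⟩."""
        return (
            1.0
            - 2.0 * (P * self.mean_p + D * self.mean_d)
            + P * P * self.second_p
            + D * D * self.second_d
            + 2.0 * P * D * self.cross
        )

    def cross_pf(self, P: float, D: float) -> float:
        """⟨f_P F⟩."""
        return self.mean_p - P * self.second_p - D * self.cross


def kernel_moments(f_p: PhaseKernel, f_d: PhaseKernel, n_grid: int = 8192) -> KernelMoments:
    """Circular moments ⟨f⟩, ⟨f²⟩, ⟨f_P f_D⟩, ⟨cos θ·f⟩ of a kernel pair.

    Cosine kernels use closed forms; anything else uses the trapezoid rule
    on a uniform periodic grid, which is spectrally accurate for smooth
    periodic integrands.
    """
    if isinstance(f_p, CosineKernel) and isinstance(f_d, CosineKernel):
        sp, sd = f_p.sign, f_d.sign
        return KernelMoments(
            mean_p=1.0,
            mean_d=1.0,
            second_p=1.5,
            second_d=1.5,
            cross=1.0 + 0.5 * sp * sd,
            cos_p=0.5 * sp,
            cos_d=0.5 * sd,
        )
    if n_grid < 64:
        raise ValueError("n_grid too coarse for the requested tolerance")
    theta = 2.0 * np.pi * np.arange(n_grid) / n_grid
    fp = np.asarray(f_p(theta), dtype=float)
    fd = np.asarray(f_d(theta), dtype=float)
    c = np.cos(theta)
    return KernelMoments(
        mean_p=float(fp.mean()),
        mean_d=float(fd.mean()),
        second_p=float((fp * fp).mean()),
        second_d=float((fd * fd).mean()),
        cross=float((fp * fd).mean()),
        cos_p=float((c * fp).mean()),
        cos_d=float((c * fd).mean()),
    )


def grid_kernel_moments(
    f_p: PhaseKernel, f_d: PhaseKernel, N: int, exclude_zero: bool = False
) -> KernelMoments:
    """Kernel moments over the N discrete phase offsets 2πd/N.

    With ``exclude_zero`` the d = 0 offset is dropped — the support actually
    sampled by distinct cells in a single-cell-per-slot (M = 1) network,
    where two different cells never share a phase slot.  The O(1/N)
    difference from the continuum moments is the exact finite-size
    correction to the steady-state weight statistics.
    """
    if N < 3:
        raise ValueError("N must be at least 3")
    d = np.arange(1 if exclude_zero else 0, N)
    theta = 2.0 * np.pi * d / N
    fp = np.asarray(f_p(theta), dtype=float)
    fd = np.asarray(f_d(theta), dtype=float)
    c = np.cos(theta)
    return KernelMoments(
        mean_p=float(fp.mean()),
        mean_d=float(fd.mean()),
        second_p=float((fp * fp).mean()),
        second_d=float((fd * fd).mean()),
        cross=float((fp * fd).mean()),
        cos_p=float((c * fp).mean()),
        cos_d=float((c * fd).mean()),
    )


def skew_t_total_mass(params: SkewTParams) -> float:
    """Quadrature check that the skew-t pdf integrates to one."""
    val, _ = integrate.quad(
        lambda t: skew_t_pdf(t, params), -np.inf, np.inf, limit=200
    )
    return float(val)
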