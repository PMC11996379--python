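"""Fluorescence-decay model: multi-exponential donor and buffer terms, FRET
quenching averaged over Gaussian donor-acceptor distance distributions (one or
two acceptors), and reconvolution with a measured instrument response function.

All times are nanoseconds, all distances angstroms.  Model intensities are
normalized so the donor term equals 1 at t = 0 before amplitude scaling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import fftconvolve
from scipy.special import ndtr

from .exceptions import ConfigurationError, DegenerateDataError
from .tcspc import DecayHistogram, ModelCurve

__all__ = [
    "DonorModel",
    "BufferModel",
    "GaussianComponent",
    "DistanceDistribution",
    "FretDecayParameters",
    "gaussian_density",
    "fret_efficiency",
    "donor_intensity",
    "buffer_intensity",
    "fret_intensity_single",
    "fret_intensity_two_acceptor",
    "reconvolve",
]

# Distance quadrature: fixed grid, trapezoidal rule, density renormalized on
# the grid.  The lower bound truncates the (formally unbounded) Gaussians;
# the upper bound grows adaptively for far-acceptor edge cases.
R_QUAD_LO = 2.0
R_QUAD_HI = 150.0
R_QUAD_STEP = 0.1
#: maximum tolerated truncated density mass
TRUNCATION_TOL = 1e-3

_FRACTION_ATOL = 1e-12


@dataclass(frozen=True)
class DonorModel:
    """Intrinsic donor fluorescence: 1-2 exponential components.

    ``components`` is a sequence of ``(alpha, tau_ns)`` pairs with amplitudes
    summing to 1.
    """

    components: tuple[tuple[float, float], ...]

    def __post_init__(self):
        comps = tuple((float(a), float(tau)) for a, tau in self.components)
        object.__setattr__(self, "components", comps)
        if not 1 <= len(comps) <= 2:
            raise ValueError("donor model takes 1-2 exponential components")
        if any(tau <= 0 for _, tau in comps):
            raise ValueError("donor lifetimes must be positive")
        if any(a < 0 for a, _ in comps):
            raise ValueError("donor amplitudes must be non-negative")
        if abs(sum(a for a, _ in comps) - 1.0) > _FRACTION_ATOL:
            raise ValueError("donor amplitude fractions must sum to 1")

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([a for a, _ in self.components])

    @property
    def lifetimes(self) -> np.ndarray:
        return np.array([tau for _, tau in self.components])


@dataclass(frozen=True)
class BufferModel:
    """Buffer-only fluorescence: 1-4 exponentials with count-scale amplitudes."""

    components: tuple[tuple[float, float], ...]

    def __post_init__(self):
        comps = tuple((float(a), float(tau)) for a, tau in self.components)
        object.__setattr__(self, "components", comps)
        if not 1 <= len(comps) <= 4:
            raise ValueError("buffer model takes 1-4 exponential components")
        if any(tau <= 0 for _, tau in comps):
            raise ValueError("buffer lifetimes must be positive")
        if any(a < 0 for a, _ in comps):
            raise ValueError("buffer amplitudes must be non-negative")

    def scaled(self, factor: float) -> "BufferModel":
        return BufferModel(tuple((a * factor, tau) for a, tau in self.components))


@dataclass(frozen=True)
class GaussianComponent:
    """One Gaussian of a donor-acceptor distance distribution."""

    f_A: float
    r_bar: float
    sigma: float

    def __post_init__(self):
        if self.r_bar <= 0:
            raise ValueError("r_bar must be positive")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.f_A < 0:
            raise ValueError("f_A must be non-negative")


@dataclass(frozen=True)
class DistanceDistribution:
    """Sum of up to two Gaussians over donor-acceptor distance."""

    components: tuple[GaussianComponent, ...]

    def __post_init__(self):
        comps = tuple(self.components)
        object.__setattr__(self, "components", comps)
        if not 1 <= len(comps) <= 2:
            raise ValueError("distance distribution takes 1-2 Gaussian components")
        if abs(sum(c.f_A for c in comps) - 1.0) > _FRACTION_ATOL:
            raise ValueError("Gaussian fractions must sum to 1")

    @classmethod
    def single(cls, r_bar: float, sigma: float) -> "DistanceDistribution":
        return cls((GaussianComponent(1.0, r_bar, sigma),))

    @classmethod
    def two_state(
        cls, f_active: float, resting: tuple[float, float], active: tuple[float, float]
    ) -> "DistanceDistribution":
        """Resting/active mixture with ``f_active`` weight on the active Gaussian."""
        if f_active <= 0.0:
            return cls.single(*resting)
        if f_active >= 1.0:
            return cls.single(*active)
        return cls(
            (
                GaussianComponent(1.0 - f_active, *resting),
                GaussianComponent(f_active, *active),
            )
        )

    def truncated_mass(self, lo: float = R_QUAD_LO, hi: float = R_QUAD_HI) -> float:
        """Analytic density mass lying outside [lo, hi]."""
        inside = 0.0
        for c in self.components:
            z_lo = (lo - c.r_bar) / c.sigma
            z_hi = (hi - c.r_bar) / c.sigma
            inside += c.f_A * (ndtr(z_hi) - ndtr(z_lo))
        return 1.0 - inside

    def quadrature(self) -> tuple[np.ndarray, np.ndarray]:
        """Distance nodes and normalized point masses for FRET averaging.

        Nodes lie on the fixed global grid (step ``R_QUAD_STEP`` from
        ``R_QUAD_LO``) restricted to the density support; trapezoid weights,
        renormalized so the masses sum to 1.
        """
        hi = max(R_QUAD_HI, max(c.r_bar + 10 * c.sigma for c in self.components))
        if self.truncated_mass(R_QUAD_LO, hi) > TRUNCATION_TOL:
            raise ConfigurationError(
                "distance quadrature grid truncates > 0.1% of the density mass"
            )
        lo_s = min(c.r_bar - 10 * c.sigma for c in self.components)
        hi_s = max(c.r_bar + 10 * c.sigma for c in self.components)
        i0 = max(0, int(math.floor((lo_s - R_QUAD_LO) / R_QUAD_STEP)) - 1)
        i1 = int(math.ceil((min(hi_s, hi) - R_QUAD_LO) / R_QUAD_STEP)) + 1
        n_hi = int(round((hi - R_QUAD_LO) / R_QUAD_STEP))
        i1 = min(i1, n_hi)
        if i1 - i0 < 4:
            i0 = max(0, i0 - 2)
            i1 = min(n_hi, i1 + 2)
        r = R_QUAD_LO + R_QUAD_STEP * np.arange(i0, i1 + 1)
        w = np.full(r.size, R_QUAD_STEP)
        w[0] = w[-1] = R_QUAD_STEP / 2.0
        q = gaussian_density(self, r) * w
        total = q.sum()
        if total <= 0:
            raise ConfigurationError("distance density vanishes on the quadrature grid")
        return r, q / total

    def density_curve(self) -> tuple[np.ndarray, np.ndarray]:
        """(r, density) on the default export grid (unnormalized analytic density)."""
        r = np.arange(R_QUAD_LO, R_QUAD_HI + R_QUAD_STEP / 2, R_QUAD_STEP)
        return r, gaussian_density(self, r)


def gaussian_density(dist: DistanceDistribution, r) -> np.ndarray:
    """Evaluate the (untruncated) mixture density at distance(s) ``r``."""
    r = np.asarray(r, dtype=float)
    out = np.zeros_like(r)
    for c in dist.components:
        z = (r - c.r_bar) / c.sigma
        out += c.f_A / (c.sigma * math.sqrt(2 * math.pi)) * np.exp(-0.5 * z * z)
    return out


def fret_efficiency(r, R0: float):
    """Forster transfer efficiency E = 1 / (1 + (r/R0)^6)."""
    r = np.asarray(r, dtype=float)
    if R0 <= 0:
        raise ValueError("R0 must be positive")
    if np.any(r <= 0):
        raise ValueError("distance must be positive")
    out = 1.0 / (1.0 + (r / R0) ** 6)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class FretDecayParameters:
    """Full parameter set of one decay fit.

    Covers the 15-parameter vector (donor-only fraction, donor biexponential,
    Forster radius, two-Gaussian intrasubunit distance distribution, IRF
    shift, buffer scale, amplitude, backgrounds) plus an optional second,
    intersubunit acceptor distribution whose active-state fraction is linked
    to that of the first distribution.
    """

    f_D: float
    donor: DonorModel
    R0: float
    rho1: DistanceDistribution
    rho2: Optional[DistanceDistribution] = None
    shift_irf: float = 0.0
    f_B: float = 0.0
    A0: float = 1.0
    bkgr_dec: float = 0.0
    bkgr_irf: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.f_D <= 1.0:
            raise ValueError("f_D must lie in [0, 1]")
        if self.R0 <= 0:
            raise ValueError("R0 must be positive")
        if self.A0 < 0:
            raise ValueError("A0 must be non-negative")
        if self.bkgr_dec < 0 or self.bkgr_irf < 0:
            raise ValueError("background terms must be non-negative")
        if self.f_B < 0:
            raise ValueError("f_B must be non-negative")
        if self.rho2 is not None:
            if len(self.rho1.components) == 2 and len(self.rho2.components) == 2:
                f1 = self.rho1.components[1].f_A
                f2 = self.rho2.components[1].f_A
                if abs(f1 - f2) > 1e-9:
                    raise ValueError(
                        "two-acceptor model requires equal active-state fractions "
                        f"in rho1 and rho2 (got {f1} vs {f2})"
                    )


def donor_intensity(donor: DonorModel, t) -> np.ndarray:
    """Normalized donor-only intensity: sum of alpha_i * exp(-t / tau_i)."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    for a, tau in donor.components:
        out += a * np.exp(-t / tau)
    return out


def buffer_intensity(buffer: BufferModel, t) -> np.ndarray:
    """Buffer intensity on the counts scale: sum of alpha_i * exp(-t / tau_i)."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    for a, tau in buffer.components:
        out += a * np.exp(-t / tau)
    return out


def _fret_average(t: np.ndarray, rate_scale: np.ndarray, q: np.ndarray, tau: float) -> np.ndarray:
    # mean over the distance distribution of exp(-(t/tau) * rate_scale(r))
    return np.exp(np.outer(t, -rate_scale / tau)) @ q


def fret_intensity_single(p: FretDecayParameters, t_grid) -> np.ndarray:
    """Normalized donor intensity quenched by one Gaussian-distributed acceptor.

    ``f_D * donor(t) + (1 - f_D) * <exp(-t/tau_i - (t/tau_i)(R0/r)^6)>_rho1``
    averaged per donor component; equals 1 at t = 0.
    """
    if p.rho2 is not None:
        raise ValueError("parameters carry rho2; use fret_intensity_two_acceptor")
    t = np.asarray(t_grid, dtype=float)
    out = p.f_D * donor_intensity(p.donor, t)
    if p.f_D < 1.0:
        r, q = p.rho1.quadrature()
        u = 1.0 + (p.R0 / r) ** 6
        acc = np.zeros_like(t)
        for a, tau in p.donor.components:
            acc += a * _fret_average(t, u, q, tau)
        out = out + (1.0 - p.f_D) * acc
    return out


def fret_intensity_two_acceptor(p: FretDecayParameters, t_grid) -> np.ndarray:
    """Normalized donor intensity quenched by two independent acceptors.

    The double integral over (r1, r2) factorizes into a product of single
    integrals because the two distance distributions are independent; each
    donor lifetime component carries its own pair of transfer terms.
    """
    if p.rho2 is None:
        raise ValueError("parameters carry no rho2; use fret_intensity_single")
    t = np.asarray(t_grid, dtype=float)
    out = p.f_D * donor_intensity(p.donor, t)
    if p.f_D < 1.0:
        r1, q1 = p.rho1.quadrature()
        r2, q2 = p.rho2.quadrature()
        u1 = 1.0 + (p.R0 / r1) ** 6
        v2 = (p.R0 / r2) ** 6
        acc = np.zeros_like(t)
        for a, tau in p.donor.components:
            acc += a * _fret_average(t, u1, q1, tau) * _fret_average(t, v2, q2, tau)
        out = out + (1.0 - p.f_D) * acc
    return out


def fret_intensity(p: FretDecayParameters, t_grid) -> np.ndarray:
    """Dispatch to the single- or two-acceptor intensity based on rho2."""
    if p.f_D >= 1.0:
        return donor_intensity(p.donor, np.asarray(t_grid, dtype=float))
    if p.rho2 is None:
        return fret_intensity_single(p, t_grid)
    return fret_intensity_two_acceptor(p, t_grid)


def prepare_irf(p: FretDecayParameters, irf: DecayHistogram) -> np.ndarray:
    """Background-subtract, clip at zero, and sub-bin shift the measured IRF."""
    t = irf.time
    vals = np.clip(irf.counts.astype(float) - p.bkgr_irf, 0.0, None)
    if vals.sum() <= 0:
        raise DegenerateDataError("IRF has no counts after background subtraction")
    if p.shift_irf != 0.0:
        vals = np.interp(t - p.shift_irf, t, vals, left=0.0, right=0.0)
        if vals.sum() <= 0:
            raise DegenerateDataError("IRF shifted entirely out of the data window")
    return vals


def reconvolve(
    p: FretDecayParameters,
    donor_part,
    buffer: Optional[BufferModel],
    irf: DecayHistogram,
) -> ModelCurve:
    """Convolve the (shifted, background-subtracted) IRF with the decay model.

    ``donor_part`` is the amplitude-scaled sample intensity (A0 applied by the
    caller); the buffer term ``f_B * I_B`` is added before convolving, and the
    constant decay background is added after.  Linear discrete convolution,
    truncated to the data window.
    """
    t = irf.time
    kernel = prepare_irf(p, irf)
    signal = np.asarray(donor_part, dtype=float)
    if signal.shape != t.shape:
        raise ValueError("donor_part must be on the IRF time grid")
    if buffer is not None and p.f_B > 0:
        signal = signal + p.f_B * buffer_intensity(buffer, t)
    conv = fftconvolve(kernel, signal)[: t.size]
    conv = np.clip(conv, 0.0, None)  # fft round-off can go epsilon-negative
    return ModelCurve(time=t, values=conv + p.bkgr_dec)


def expected_decay(
    p: FretDecayParameters, buffer: Optional[BufferModel], irf: DecayHistogram
) -> ModelCurve:
    """Full forward model: amplitude-scaled FRET intensity reconvolved with the IRF."""
    ida = fret_intensity(p, irf.time)
    return reconvolve(p, p.A0 * ida, buffer, irf)
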