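"""Two-state energetics and ligand dose-response with depletion.

State fractions from decay fits convert to conformational free energies by
the Boltzmann relation; titrations of the active-state fraction against total
ligand are fit with the quadratic (ligand-depletion) binding isotherm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

from .exceptions import ConvergenceError, UnidentifiableError

__all__ = [
    "R_GAS_KCAL",
    "StateFraction",
    "EnergyRecord",
    "TitrationSeries",
    "DoseResponseFitResult",
    "delta_g",
    "delta_delta_g",
    "dose_response",
    "fit_dose_response",
]

#: gas constant in kcal / (mol K)
R_GAS_KCAL = 1.9872e-3
DEFAULT_TEMPERATURE_K = 298.0


@dataclass(frozen=True)
class StateFraction:
    """Fraction of molecules in the active state under one condition."""

    f_A2: float
    condition: str = ""
    temperature_K: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self):
        if not 0.0 < self.f_A2 < 1.0:
            raise ValueError(
                "f_A2 must lie strictly in (0, 1) for energy conversion; "
                "boundary fractions from fixed single-state fits should be "
                "reported as bounds, not converted"
            )
        if self.temperature_K <= 0:
            raise ValueError("temperature must be positive")


@dataclass(frozen=True)
class EnergyRecord:
    """Free-energy change (kcal/mol) of the resting-to-active transition."""

    delta_g: float
    condition: str = ""
    temperature_K: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self):
        if not math.isfinite(self.delta_g):
            raise ValueError("delta_g must be finite")


def delta_g(f: "StateFraction | float", temperature_K: Optional[float] = None) -> EnergyRecord:
    """Boltzmann free energy of the transition: -R T ln(f / (1 - f)).

    Active-state fraction above one half gives a negative (favorable) energy.
    """
    if not isinstance(f, StateFraction):
        f = StateFraction(float(f), temperature_K=temperature_K or DEFAULT_TEMPERATURE_K)
    T = temperature_K if temperature_K is not None else f.temperature_K
    dg = -R_GAS_KCAL * T * math.log(f.f_A2 / (1.0 - f.f_A2))
    return EnergyRecord(delta_g=dg, condition=f.condition, temperature_K=T)


def delta_delta_g(g_ligand: EnergyRecord, g_apo: EnergyRecord) -> float:
    """Ligand-induced energy change: liganded minus apo, same temperature."""
    if abs(g_ligand.temperature_K - g_apo.temperature_K) > 1e-9:
        raise ValueError("delta_delta_g requires both energies at the same temperature")
    return g_ligand.delta_g - g_apo.delta_g


@dataclass(frozen=True)
class TitrationSeries:
    """Active-state fraction versus total ligand concentration (micromolar)."""

    points: tuple[tuple[float, float], ...]
    protein_total: Optional[float] = None

    def __post_init__(self):
        pts = tuple((float(L), float(f)) for L, f in self.points)
        object.__setattr__(self, "points", pts)
        ligs = [L for L, _ in pts]
        if any(L < 0 for L in ligs):
            raise ValueError("ligand concentrations must be non-negative")
        if len(set(ligs)) != len(ligs):
            raise ValueError("duplicate ligand concentrations in titration")
        if self.protein_total is not None and self.protein_total <= 0:
            raise ValueError("protein_total must be positive")

    @property
    def ligand(self) -> np.ndarray:
        return np.array([L for L, _ in self.points])

    @property
    def response(self) -> np.ndarray:
        return np.array([f for _, f in self.points])


@dataclass(frozen=True)
class DoseResponseFitResult:
    """Quadratic-isotherm fit: dissociation constant, protein, plateau fractions."""

    K_D: float
    protein_total: float
    A: float
    B: float

    def __post_init__(self):
        if self.K_D <= 0:
            raise ValueError("K_D must be positive")
        if self.protein_total <= 0:
            raise ValueError("protein_total must be positive")
        if not (-1e-9 <= self.B <= self.A + 1e-9 and self.A <= 1.0 + 1e-9):
            raise ValueError("plateau fractions must satisfy 0 <= B <= A <= 1")


def _quadratic_isotherm(L, P: float, K: float, A: float, B: float):
    L = np.asarray(L, dtype=float)
    s = L + P + K
    disc = np.clip(s * s - 4.0 * P * L, 0.0, None)
    bound = (s - np.sqrt(disc)) / (2.0 * P)
    return (A - B) * bound + B


def dose_response(L_total, fit: DoseResponseFitResult):
    """Fractional response at total ligand ``L_total`` under ligand depletion."""
    out = _quadratic_isotherm(L_total, fit.protein_total, fit.K_D, fit.A, fit.B)
    return float(out) if np.ndim(out) == 0 else out


def fit_dose_response(
    series: TitrationSeries, fix_protein: bool = False
) -> DoseResponseFitResult:
    """Least-squares fit of the depletion isotherm to a titration.

    Free parameters: K_D, A, B, and the total protein concentration unless
    ``fix_protein`` is set (then ``series.protein_total`` is required).
    """
    L = series.ligand
    f = series.response
    if L.size < 4:
        raise ValueError("dose-response fitting needs at least 4 titration points")
    if f.max() - f.min() < 1e-4:
        raise UnidentifiableError("flat response: K_D cannot be determined")
    if fix_protein and series.protein_total is None:
        raise ValueError("fix_protein requires series.protein_total")

    L_pos = L[L > 0]
    K0 = float(np.median(L_pos)) if L_pos.size else 1.0
    P0 = series.protein_total if series.protein_total else K0
    A0 = float(f.max())
    B0 = float(f.min())

    def residuals(x):
        if fix_protein:
            K, A, B = x
            P = series.protein_total
        else:
            K, P, A, B = x
        return _quadratic_isotherm(L, P, K, A, B) - f

    lo_frac, hi_frac = -0.5, 1.5  # loose: noise can push plateaus past [0, 1]
    if fix_protein:
        x0 = [K0, A0, B0]
        lb = [1e-9, lo_frac, lo_frac]
        ub = [1e9, hi_frac, hi_frac]
    else:
        x0 = [K0, P0, A0, B0]
        lb = [1e-9, 1e-9, lo_frac, lo_frac]
        ub = [1e9, 1e9, hi_frac, hi_frac]

    best = None
    for K_start in (K0, K0 / 10.0, K0 * 10.0, K0 / 100.0):
        start = list(x0)
        start[0] = K_start
        res = least_squares(
            residuals, start, bounds=(lb, ub), method="trf",
            xtol=1e-15, ftol=1e-15, gtol=1e-15,
        )
        if best is None or res.cost < best.cost:
            best = res
        if best.cost < 1e-20:
            break
    if best is None or not best.success and best.cost > 1e-6:
        raise ConvergenceError("dose-response fit did not converge", best=best)
    if fix_protein:
        K, A, B = best.x
        P = series.protein_total
    else:
        K, P, A, B = best.x
    A = min(max(A, 0.0), 1.0)
    B = min(max(B, 0.0), min(A, 1.0))
    return DoseResponseFitResult(K_D=float(K), protein_total=float(P), A=float(A), B=float(B))
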