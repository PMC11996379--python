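"""Chi-square fitting of the reconvolution decay model to measured histograms.

One generic engine handles buffer fits, donor-only fits, single-decay FRET
fits, global multi-decay fits with parameter sharing, the two-acceptor
(intersubunit) protocol, and chi-square profiles/surfaces for parameter
identifiability.

Parameter names follow the decay model: ``f_D, tau_D1, alpha_D1, tau_D2, R0,
r1, sigma1, f_A2, r2, sigma2, shift_irf, f_B, A0, bkgr_dec, bkgr_irf``; the
two-acceptor model adds the fixed intersubunit distribution parameters
``r1_inter, sigma1_inter, r2_inter, sigma2_inter`` (its state fraction is
always linked to ``f_A2``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .exceptions import ConvergenceError, DegenerateDataError, SpecError
from .model import (
    BufferModel,
    DistanceDistribution,
    DonorModel,
    FretDecayParameters,
    buffer_intensity,
    fret_intensity,
    reconvolve,
)
from .tcspc import AcquisitionPair, DecayHistogram, ModelCurve

__all__ = [
    "PARAM_NAMES",
    "INTER_PARAM_NAMES",
    "ParameterSpec",
    "FitSpec",
    "FitResult",
    "chi2",
    "fit",
    "fit_buffer",
    "fit_donor_only",
    "fit_fret_single",
    "fit_fret_global",
    "fit_fret_two_acceptor",
    "make_fret_spec",
    "chi2_profile",
    "chi2_surface",
]

PARAM_NAMES = (
    "f_D", "tau_D1", "alpha_D1", "tau_D2", "R0",
    "r1", "sigma1", "f_A2", "r2", "sigma2",
    "shift_irf", "f_B", "A0", "bkgr_dec", "bkgr_irf",
)
INTER_PARAM_NAMES = ("r1_inter", "sigma1_inter", "r2_inter", "sigma2_inter")

_FRACTIONS = {"f_D", "alpha_D1", "f_A2"}

DEFAULT_BOUNDS = {
    "f_D": (0.0, 1.0),
    "tau_D1": (0.01, 200.0),
    "alpha_D1": (0.0, 1.0),
    "tau_D2": (0.01, 200.0),
    "R0": (5.0, 120.0),
    "r1": (5.0, 120.0),
    "sigma1": (0.05, 30.0),
    "f_A2": (0.0, 1.0),
    "r2": (5.0, 120.0),
    "sigma2": (0.05, 30.0),
    "shift_irf": (-3.0, 3.0),
    "f_B": (0.0, 1e6),
    "A0": (0.0, np.inf),
    "bkgr_dec": (0.0, np.inf),
    "bkgr_irf": (0.0, np.inf),
    "r1_inter": (5.0, 120.0),
    "sigma1_inter": (0.05, 30.0),
    "r2_inter": (5.0, 120.0),
    "sigma2_inter": (0.05, 30.0),
}

_SCALES = {
    "f_D": 0.1, "tau_D1": 5.0, "alpha_D1": 0.1, "tau_D2": 2.0, "R0": 10.0,
    "r1": 10.0, "sigma1": 1.0, "f_A2": 0.1, "r2": 10.0, "sigma2": 1.0,
    "shift_irf": 0.05, "f_B": 0.1, "bkgr_dec": 1.0, "bkgr_irf": 1.0,
    "r1_inter": 10.0, "sigma1_inter": 1.0, "r2_inter": 10.0, "sigma2_inter": 1.0,
}


@dataclass
class ParameterSpec:
    """Status of one model parameter within one decay of a fit.

    ``status`` is ``fixed``, ``free``, or ``shared``; shared parameters join
    the group ``group`` (defaulting to the parameter name) across decays.
    """

    name: str
    status: str = "fixed"
    value: float = 0.0
    bounds: Optional[tuple[float, float]] = None
    group: Optional[str] = None

    def __post_init__(self):
        if self.name not in PARAM_NAMES + INTER_PARAM_NAMES:
            raise SpecError(f"unknown parameter name {self.name!r}")
        if self.status not in ("fixed", "free", "shared"):
            raise SpecError(f"status must be fixed/free/shared, got {self.status!r}")
        if self.bounds is None:
            self.bounds = DEFAULT_BOUNDS[self.name]
        if self.name in _FRACTIONS:
            lo, hi = self.bounds
            if lo < 0.0 or hi > 1.0:
                raise SpecError(f"{self.name} bounds must lie within [0, 1]")
        if self.status != "fixed":
            lo, hi = self.bounds
            if not (np.isfinite(lo) and (np.isfinite(hi) or self.name in ("A0", "bkgr_dec"))):
                raise SpecError(f"free parameter {self.name} needs finite bounds")
        if self.group is None and self.status == "shared":
            self.group = self.name


@dataclass
class FitSpec:
    """Which decays are fitted and how each parameter is handled per decay."""

    pairs: list[AcquisitionPair]
    params: list[dict[str, ParameterSpec]]
    buffers: list[Optional[BufferModel]]
    two_acceptor: bool = False
    weighting: str = "poisson"
    window: str = "auto"

    def __post_init__(self):
        n = len(self.pairs)
        if n == 0:
            raise SpecError("FitSpec needs at least one decay")
        if len(self.params) != n or len(self.buffers) != n:
            raise SpecError("params and buffers must match the number of decays")
        names = PARAM_NAMES + (INTER_PARAM_NAMES if self.two_acceptor else ())
        groups: dict[str, int] = {}
        for table in self.params:
            missing = set(names) - set(table)
            if missing:
                raise SpecError(f"parameter table missing entries: {sorted(missing)}")
            for name in names:
                ps = table[name]
                if ps.name != name:
                    raise SpecError(f"table key {name!r} holds spec for {ps.name!r}")
                if ps.status == "shared":
                    groups[ps.group] = groups.get(ps.group, 0) + 1
            if self.two_acceptor:
                for name in INTER_PARAM_NAMES:
                    if table[name].status != "fixed":
                        raise SpecError(
                            "intersubunit distribution parameters must be fixed "
                            "(protocol: rho2 shape comes from the intersubunit fit)"
                        )
        if n > 1:
            bad = [g for g, k in groups.items() if k < 2]
            if bad:
                raise SpecError(f"shared groups present in fewer than 2 decays: {bad}")
        elif groups:
            raise SpecError("shared parameters require >= 2 decays")
        if self.weighting not in ("poisson", "as-printed"):
            raise SpecError(f"unknown weighting rule {self.weighting!r}")


@dataclass
class FitResult:
    """Estimates, goodness of fit, and bookkeeping for one (possibly global) fit."""

    estimates: list[dict[str, float]]
    chi2: float
    reduced_chi2: float
    n_free: int
    n_points: int
    residuals: list[np.ndarray]
    success: bool
    message: str
    spec: FitSpec = field(repr=False)
    windows: list[slice] = field(repr=False)

    def estimate(self, name: str, decay: int = 0) -> float:
        return self.estimates[decay][name]


def _sigma(observed: np.ndarray, weighting: str) -> np.ndarray:
    floor = np.maximum(observed.astype(float), 1.0)
    if weighting == "poisson":
        return np.sqrt(floor)
    if weighting == "as-printed":
        return floor
    raise SpecError(f"unknown weighting rule {weighting!r}")


def fit_window(hist: DecayHistogram) -> slice:
    """Bins from the first clear rise above the pre-pulse background to the end."""
    counts = hist.counts
    k = max(8, counts.size // 64)
    base = float(np.median(counts[:k]))
    thr = base + 5.0 * math.sqrt(base + 1.0)
    above = counts > thr
    if not above.any():
        return slice(0, counts.size)
    return slice(int(np.argmax(above)), counts.size)


def chi2(
    observed: DecayHistogram,
    model: ModelCurve,
    weighting: str = "poisson",
    window: Optional[slice] = None,
) -> tuple[float, np.ndarray]:
    """Weighted chi-square and signed weighted residuals over the fit window."""
    if observed.counts.sum() == 0:
        raise DegenerateDataError("observed trace has zero total counts")
    if observed.time.shape != model.time.shape or not np.allclose(
        observed.time, model.time, rtol=0, atol=1e-9 * observed.dt
    ):
        raise SpecError("observed and model must share the time grid")
    w = window if window is not None else slice(0, observed.counts.size)
    obs = observed.counts[w].astype(float)
    mod = model.values[w]
    res = (obs - mod) / _sigma(obs, weighting)
    return float(np.dot(res, res)), res


# ---------------------------------------------------------------------------
# generic engine

def _build_params(values: dict[str, float], two_acceptor: bool) -> FretDecayParameters:
    a1 = min(max(values["alpha_D1"], 0.0), 1.0)
    comps = ((a1, values["tau_D1"]), (1.0 - a1, values["tau_D2"]))
    comps = tuple((a, tau) for a, tau in comps if a > 0.0)
    donor = DonorModel(comps)
    fa2 = min(max(values["f_A2"], 0.0), 1.0)
    rho1 = DistanceDistribution.two_state(
        fa2, (values["r1"], values["sigma1"]), (values["r2"], values["sigma2"])
    )
    rho2 = None
    if two_acceptor:
        rho2 = DistanceDistribution.two_state(
            fa2,
            (values["r1_inter"], values["sigma1_inter"]),
            (values["r2_inter"], values["sigma2_inter"]),
        )
    return FretDecayParameters(
        f_D=min(max(values["f_D"], 0.0), 1.0),
        donor=donor,
        R0=values["R0"],
        rho1=rho1,
        rho2=rho2,
        shift_irf=values["shift_irf"],
        f_B=values["f_B"],
        A0=max(values["A0"], 0.0),
        bkgr_dec=max(values["bkgr_dec"], 0.0),
        bkgr_irf=max(values["bkgr_irf"], 0.0),
    )


def predict_decay(spec: FitSpec, values: dict[str, float], decay: int) -> ModelCurve:
    """Forward model for one decay of the spec under the given parameter values."""
    p = _build_params(values, spec.two_acceptor)
    pair = spec.pairs[decay]
    ida = fret_intensity(p, pair.time)
    return reconvolve(p, p.A0 * ida, spec.buffers[decay], pair.irf)


class _Packing:
    """Maps between the free-parameter vector and per-decay value dicts."""

    def __init__(self, spec: FitSpec):
        self.spec = spec
        names = PARAM_NAMES + (INTER_PARAM_NAMES if spec.two_acceptor else ())
        self.names = names
        self.slot_of: list[dict[str, int]] = [dict() for _ in spec.params]
        self.x0: list[float] = []
        self.lb: list[float] = []
        self.ub: list[float] = []
        self.slot_names: list[str] = []
        shared: dict[str, int] = {}
        for d, table in enumerate(spec.params):
            for name in names:
                ps = table[name]
                if ps.status == "fixed":
                    continue
                if ps.status == "shared":
                    if ps.group in shared:
                        self.slot_of[d][name] = shared[ps.group]
                        continue
                    shared[ps.group] = len(self.x0)
                slot = len(self.x0)
                self.slot_of[d][name] = slot
                lo, hi = ps.bounds
                self.x0.append(min(max(ps.value, lo), hi))
                self.lb.append(lo)
                self.ub.append(hi)
                self.slot_names.append(name)
        self.n_free = len(self.x0)

    def unpack(self, x: np.ndarray) -> list[dict[str, float]]:
        out = []
        for d, table in enumerate(self.spec.params):
            vals = {name: table[name].value for name in self.names}
            for name, slot in self.slot_of[d].items():
                vals[name] = float(x[slot])
            out.append(vals)
        return out

    def scales(self) -> np.ndarray:
        sc = []
        for i, name in enumerate(self.slot_names):
            base = _SCALES.get(name, 1.0)
            if name == "A0":
                base = max(abs(self.x0[i]), 1e-12)
            sc.append(max(base, 1e-12))
        return np.array(sc)


def _auto_starts(spec: FitSpec, packing: _Packing) -> None:
    """Fill data-driven starting values for A0 and bkgr_dec when still at 0."""
    for d, table in enumerate(spec.params):
        win = fit_window(spec.pairs[d].sample) if spec.window == "auto" else slice(None)
        obs = spec.pairs[d].sample.counts
        ps_b = table["bkgr_dec"]
        if ps_b.status != "fixed" and ps_b.value == 0.0:
            k = max(8, obs.size // 64)
            ps_b.value = float(np.median(obs[:k])) + 0.1
        ps_a = table["A0"]
        if ps_a.status != "fixed" and ps_a.value == 0.0:
            vals = {name: table[name].value for name in packing.names}
            vals["A0"] = 1.0
            curve = predict_decay(spec, vals, d).values
            denom = float(curve[win].sum() - vals["bkgr_dec"] * curve[win].size)
            num = float(obs[win].sum() - vals["bkgr_dec"] * curve[win].size)
            ps_a.value = max(num / denom if denom > 0 else 1.0, 1e-12)


def _swap_state_labels(result: "FitResult") -> None:
    """Relabel so component 1 is the longer-distance (resting) Gaussian.

    Applied only when both distances and the state fraction were estimated;
    the model is invariant under the swap.
    """
    spec = result.spec
    if spec.two_acceptor:
        # swapping would also flip the fixed rho2 mixture via the linked
        # fraction, changing the model; leave labels as fitted
        return
    tables = spec.params

    def adjustable(name):
        return all(t[name].status != "fixed" for t in tables)

    if not (adjustable("r1") and adjustable("r2") and adjustable("f_A2")):
        return
    r1 = result.estimates[0]["r1"]
    r2 = result.estimates[0]["r2"]
    if r1 >= r2:
        return
    for est in result.estimates:
        est["r1"], est["r2"] = est["r2"], est["r1"]
        est["sigma1"], est["sigma2"] = est["sigma2"], est["sigma1"]
        est["f_A2"] = 1.0 - est["f_A2"]


def fit(
    spec: FitSpec,
    n_starts: int = 5,
    seed: int = 0,
    early_stop_redchi: float = 1.5,
    max_nfev: Optional[int] = None,
    canonical_labels: bool = True,
) -> FitResult:
    """Minimize the joint weighted chi-square over all decays of ``spec``.

    Multistart: the nominal start first, then up to ``n_starts - 1`` seeded
    perturbations; stops early once the reduced chi-square falls below
    ``early_stop_redchi``.  With zero free parameters this just evaluates
    the chi-square.
    """
    packing = _Packing(spec)
    _auto_starts(spec, packing)
    packing = _Packing(spec)  # re-pack with auto starting values in place

    windows = [
        fit_window(p.sample) if spec.window == "auto" else slice(0, p.sample.counts.size)
        for p in spec.pairs
    ]
    obs = [p.sample.counts[w].astype(float) for p, w in zip(spec.pairs, windows)]
    sigmas = [_sigma(o, spec.weighting) for o in obs]
    n_points = sum(o.size for o in obs)
    for p in spec.pairs:
        if p.sample.counts.sum() == 0:
            raise DegenerateDataError("sample trace has zero total counts")

    from .exceptions import ConfigurationError

    def residuals(x):
        vals = packing.unpack(x)
        out = []
        try:
            for d in range(len(spec.pairs)):
                curve = predict_decay(spec, vals[d], d).values[windows[d]]
                out.append((obs[d] - curve) / sigmas[d])
        except ConfigurationError:
            # infeasible trial point (e.g. sigma so wide the quadrature
            # truncates); huge cost makes the optimizer reject the step
            return np.full(n_points, 1e8)
        return np.concatenate(out)

    def finish(x, success, message, jac=None):
        vals = packing.unpack(x)
        res_list = []
        total = 0.0
        for d in range(len(spec.pairs)):
            curve = predict_decay(spec, vals[d], d).values[windows[d]]
            r = (obs[d] - curve) / sigmas[d]
            res_list.append(r)
            total += float(np.dot(r, r))
        dof = max(n_points - packing.n_free, 1)
        result = FitResult(
            estimates=vals,
            chi2=total,
            reduced_chi2=total / dof,
            n_free=packing.n_free,
            n_points=n_points,
            residuals=res_list,
            success=success,
            message=message,
            spec=spec,
            windows=windows,
        )
        if jac is not None and packing.n_free > 0:
            sv = np.linalg.svd(jac, compute_uv=False)
            if sv[0] <= 0 or sv[-1] / sv[0] < 1e-12:
                warnings.warn(
                    "near-singular Jacobian at optimum: some parameters may be "
                    "unidentifiable", RuntimeWarning, stacklevel=2,
                )
        if canonical_labels:
            _swap_state_labels(result)
        return result

    if packing.n_free == 0:
        return finish(np.array([]), True, "no free parameters: chi-square evaluation only")

    x0 = np.array(packing.x0)
    lb = np.array(packing.lb)
    ub = np.array(packing.ub)
    rng = np.random.default_rng(seed)
    best = None
    last_exc = None
    for attempt in range(max(1, n_starts)):
        if attempt == 0:
            start = x0
        else:
            width = np.where(np.isfinite(ub), ub - lb, 10.0 * packing.scales())
            start = np.clip(
                x0 + rng.normal(0.0, 0.15, size=x0.size) * width, lb, ub
            )
            start = np.where(np.isfinite(start), start, x0)
        try:
            res = least_squares(
                residuals, start, bounds=(lb, ub), method="trf",
                x_scale=packing.scales(), xtol=1e-10, ftol=1e-10, gtol=1e-10,
                max_nfev=max_nfev,
            )
        except Exception as exc:  # noqa: BLE001 - one bad start must not kill the multistart
            last_exc = exc
            continue
        if best is None or res.cost < best.cost:
            best = res
        dof = max(n_points - packing.n_free, 1)
        if best is not None and 2.0 * best.cost / dof < early_stop_redchi:
            break
    if best is None:
        raise ConvergenceError(f"all optimization starts failed: {last_exc}")
    success = best.status > 0
    if not success:
        raise ConvergenceError(
            f"fit did not converge: {best.message}",
            best=finish(best.x, False, best.message),
        )
    return finish(best.x, success, best.message, jac=best.jac)


# ---------------------------------------------------------------------------
# parameter-table builders and protocol wrappers

def _fixed_table(**values) -> dict[str, ParameterSpec]:
    table = {}
    for name in PARAM_NAMES + INTER_PARAM_NAMES:
        table[name] = ParameterSpec(name, "fixed", values.get(name, 0.0))
    # benign defaults so _build_params always yields a valid model
    defaults = {
        "tau_D1": 15.0, "alpha_D1": 1.0, "tau_D2": 3.0, "R0": 43.5,
        "r1": 50.0, "sigma1": 3.0, "r2": 30.0, "sigma2": 3.0,
        "r1_inter": 54.0, "sigma1_inter": 3.0, "r2_inter": 58.0, "sigma2_inter": 5.0,
        "A0": 1.0,
    }
    for name, val in defaults.items():
        if name not in values:
            table[name].value = val
    return table


def make_fret_spec(
    pairs: Sequence[AcquisitionPair],
    donor: DonorModel,
    buffers: Sequence[Optional[BufferModel]],
    R0: float,
    two_acceptor: bool = False,
    inter: Optional[DistanceDistribution] = None,
    shared: Sequence[str] = (),
    overrides: "Optional[Sequence[dict[str, ParameterSpec]] | dict[str, ParameterSpec]]" = None,
    weighting: str = "poisson",
) -> FitSpec:
    """FitSpec following the standard FRET-fit protocol.

    Fixed: donor biexponential (from the donor-only fit), ``R0``, ``f_B``
    (acquisition-time ratio), ``bkgr_irf`` (0).  Free: ``f_D``, the distance
    distribution (``r1, sigma1, f_A2, r2, sigma2``), ``shift_irf``, ``A0``,
    ``bkgr_dec``.  ``shared`` lists names constrained across decays; per-decay
    ``overrides`` replace individual entries (e.g. fixing ``f_A2`` to 0 or 1
    for single-state fits).  For the two-acceptor protocol pass ``inter``, the
    fixed intersubunit distribution; its state fraction is linked to ``f_A2``.
    """
    pairs = list(pairs)
    buffers = list(buffers)
    if len(buffers) != len(pairs):
        raise SpecError("one buffer model per decay required (None allowed)")
    if two_acceptor and inter is None:
        raise SpecError("two-acceptor protocol requires the intersubunit distribution")
    if isinstance(overrides, dict):
        overrides = [overrides] * len(pairs)
    if overrides is not None and len(overrides) != len(pairs):
        raise SpecError("overrides must be per-decay or a single shared dict")

    alpha1, tau1 = donor.components[0]
    tau2 = donor.components[1][1] if len(donor.components) == 2 else tau1

    tables = []
    for d, pair in enumerate(pairs):
        table = _fixed_table(
            tau_D1=tau1, alpha_D1=alpha1, tau_D2=tau2, R0=R0,
            f_B=pair.f_B_default if buffers[d] is not None else 0.0,
            bkgr_irf=0.0,
        )
        for name, start in (
            ("f_D", 0.1), ("r1", 48.0), ("sigma1", 3.0), ("f_A2", 0.5),
            ("r2", 30.0), ("sigma2", 3.0), ("shift_irf", 0.0),
            ("A0", 0.0), ("bkgr_dec", 0.0),
        ):
            status = "shared" if name in shared else "free"
            table[name] = ParameterSpec(name, status, start)
        if two_acceptor:
            comps = inter.components
            c1 = comps[0]
            c2 = comps[1] if len(comps) == 2 else comps[0]
            table["r1_inter"] = ParameterSpec("r1_inter", "fixed", c1.r_bar)
            table["sigma1_inter"] = ParameterSpec("sigma1_inter", "fixed", c1.sigma)
            table["r2_inter"] = ParameterSpec("r2_inter", "fixed", c2.r_bar)
            table["sigma2_inter"] = ParameterSpec("sigma2_inter", "fixed", c2.sigma)
        if overrides is not None:
            for name, ps in overrides[d].items():
                if ps.name != name:
                    raise SpecError(f"override key {name!r} holds spec for {ps.name!r}")
                table[name] = replace(ps)
        # a single-state fit leaves the absent Gaussian inert: pin it so the
        # Jacobian stays full-rank
        fa2 = table["f_A2"]
        if fa2.status == "fixed":
            inert = ("r2", "sigma2") if fa2.value <= 0.0 else (
                ("r1", "sigma1") if fa2.value >= 1.0 else ()
            )
            for name in inert:
                if table[name].status != "fixed":
                    table[name] = ParameterSpec(name, "fixed", table[name].value)
        tables.append(table)
    return FitSpec(
        pairs=pairs, params=tables, buffers=buffers,
        two_acceptor=two_acceptor, weighting=weighting,
    )


def fit_donor_only(
    pair: AcquisitionPair,
    buffer: Optional[BufferModel] = None,
    n_starts: int = 3,
    seed: int = 0,
    weighting: str = "poisson",
) -> tuple[DonorModel, FitResult]:
    """Biexponential reconvolution fit of a donor-only decay (f_D fixed at 1).

    Free parameters: the donor lifetimes and amplitude split, IRF shift,
    amplitude, and decay background.  Returns the fitted donor model (longer
    lifetime first) for fixing in subsequent FRET fits.
    """
    table = _fixed_table(
        f_D=1.0, f_B=pair.f_B_default if buffer is not None else 0.0, bkgr_irf=0.0
    )
    table["tau_D1"] = ParameterSpec("tau_D1", "free", 15.0, (1.0, 100.0))
    table["alpha_D1"] = ParameterSpec("alpha_D1", "free", 0.8)
    table["tau_D2"] = ParameterSpec("tau_D2", "free", 3.0, (0.01, 100.0))
    table["shift_irf"] = ParameterSpec("shift_irf", "free", 0.0)
    table["A0"] = ParameterSpec("A0", "free", 0.0)
    table["bkgr_dec"] = ParameterSpec("bkgr_dec", "free", 0.0)
    spec = FitSpec(pairs=[pair], params=[table], buffers=[buffer], weighting=weighting)
    result = fit(spec, n_starts=n_starts, seed=seed)
    est = result.estimates[0]
    if est["tau_D1"] < est["tau_D2"]:  # canonical: component 1 is the long lifetime
        est["tau_D1"], est["tau_D2"] = est["tau_D2"], est["tau_D1"]
        est["alpha_D1"] = 1.0 - est["alpha_D1"]
    a1 = est["alpha_D1"]
    if a1 >= 1.0 - 1e-9:
        donor = DonorModel(((1.0, est["tau_D1"]),))
    else:
        donor = DonorModel(((a1, est["tau_D1"]), (1.0 - a1, est["tau_D2"])))
    return donor, result


def fit_buffer(
    buffer_hist: DecayHistogram,
    irf: DecayHistogram,
    n_components: int = 1,
    n_starts: int = 3,
    seed: int = 0,
    weighting: str = "poisson",
) -> tuple[BufferModel, FitResult]:
    """Multi-exponential reconvolution fit of the buffer-only decay.

    The returned BufferModel (amplitudes on the counts scale) is held fixed
    when fitting sample decays.
    """
    if not 1 <= n_components <= 4:
        raise SpecError("buffer model supports 1-4 exponential components")
    if buffer_hist.counts.sum() < 100:
        raise DegenerateDataError("buffer trace has fewer than 100 total counts")
    t = buffer_hist.time
    win = fit_window(buffer_hist)
    obs = buffer_hist.counts[win].astype(float)
    sig = _sigma(obs, weighting)
    irf_counts = irf.counts.astype(float)
    window_ns = float(t[-1] - t[0])
    taus0 = np.geomspace(max(4 * buffer_hist.dt, 0.05), window_ns / 4.0, n_components)
    peak = float(obs.max())
    amp0 = max(peak / max(irf_counts.sum(), 1.0), 1e-12)
    k = max(8, buffer_hist.counts.size // 64)
    bkgr0 = float(np.median(buffer_hist.counts[:k]))

    from scipy.signal import fftconvolve

    def model(x):
        amps = x[:n_components]
        taus = x[n_components:2 * n_components]
        shift, bkgr = x[-2], x[-1]
        vals = np.clip(irf_counts, 0.0, None)
        if shift != 0.0:
            vals = np.interp(t - shift, t, vals, left=0.0, right=0.0)
        ib = np.zeros_like(t)
        for a, tau in zip(amps, taus):
            ib += a * np.exp(-t / tau)
        return fftconvolve(vals, ib)[: t.size][win] + bkgr

    def residuals(x):
        return (obs - model(x)) / sig

    x0 = np.concatenate([np.full(n_components, amp0 / n_components), taus0, [0.0, bkgr0]])
    lb = np.concatenate([np.zeros(n_components), np.full(n_components, 0.01), [-3.0, 0.0]])
    ub = np.concatenate(
        [np.full(n_components, np.inf), np.full(n_components, 200.0), [3.0, np.inf]]
    )
    rng = np.random.default_rng(seed)
    best = None
    for attempt in range(max(1, n_starts)):
        start = x0 if attempt == 0 else np.clip(
            x0 * np.exp(rng.normal(0, 0.5, x0.size)), lb, ub
        )
        start[-2] = 0.0
        res = least_squares(residuals, start, bounds=(lb, ub), method="trf",
                            xtol=1e-10, ftol=1e-10)
        if best is None or res.cost < best.cost:
            best = res
        if 2 * best.cost / max(obs.size - x0.size, 1) < 1.5:
            break
    if best is None or best.status <= 0:
        raise ConvergenceError("buffer fit did not converge", best=best)
    amps = best.x[:n_components]
    taus = best.x[n_components:2 * n_components]
    order = np.argsort(-taus)
    bmodel = BufferModel(tuple((float(amps[i]), float(taus[i])) for i in order))
    r = residuals(best.x)
    dof = max(obs.size - best.x.size, 1)
    est = {f"alpha_B{i+1}": float(amps[j]) for i, j in enumerate(order)}
    est.update({f"tau_B{i+1}": float(taus[j]) for i, j in enumerate(order)})
    est.update({"shift_irf": float(best.x[-2]), "bkgr_dec": float(best.x[-1])})
    result = FitResult(
        estimates=[est], chi2=float(np.dot(r, r)), reduced_chi2=float(np.dot(r, r)) / dof,
        n_free=int(best.x.size), n_points=int(obs.size), residuals=[r],
        success=True, message=best.message,
        spec=None, windows=[win],  # type: ignore[arg-type] - buffer fits have no FitSpec
    )
    return bmodel, result


def fit_fret_single(
    pair: AcquisitionPair, spec: FitSpec, n_starts: int = 5, seed: int = 0
) -> FitResult:
    """Single-decay FRET fit; ``spec`` must reference exactly this pair."""
    if len(spec.pairs) != 1 or spec.pairs[0] is not pair:
        raise SpecError("spec must reference exactly the given pair")
    return fit(spec, n_starts=n_starts, seed=seed)


def fit_fret_global(spec: FitSpec, n_starts: int = 5, seed: int = 0) -> FitResult:
    """Joint fit over >= 2 decays with shared-parameter constraints."""
    if len(spec.pairs) < 2:
        raise SpecError("global fit requires at least 2 decays")
    return fit(spec, n_starts=n_starts, seed=seed)


def fit_fret_two_acceptor(
    pair: AcquisitionPair,
    inter: DistanceDistribution,
    spec: Optional[FitSpec] = None,
    donor: Optional[DonorModel] = None,
    buffer: Optional[BufferModel] = None,
    R0: float = 43.5,
    n_starts: int = 5,
    seed: int = 0,
) -> FitResult:
    """Two-acceptor fit with the intersubunit distribution shape held fixed.

    Either pass a prepared two-acceptor ``spec`` or the donor/buffer models
    and ``R0`` from which the protocol spec is built.
    """
    if spec is None:
        if donor is None:
            raise SpecError("either spec or donor model must be given")
        spec = make_fret_spec(
            [pair], donor, [buffer], R0, two_acceptor=True, inter=inter
        )
    if not spec.two_acceptor:
        raise SpecError("spec is not a two-acceptor specification")
    return fit(spec, n_starts=n_starts, seed=seed)


# ---------------------------------------------------------------------------
# identifiability

def _respec_with(result: FitResult, fixed: dict[tuple[int, str], float]) -> FitSpec:
    """Clone the spec with starts at the fitted optimum and some entries fixed."""
    spec = result.spec
    tables = []
    for d, table in enumerate(spec.params):
        new = {}
        for name, ps in table.items():
            val = result.estimates[d].get(name, ps.value)
            new[name] = ParameterSpec(name, ps.status, val, ps.bounds, ps.group)
        tables.append(new)
    for (d, name), val in fixed.items():
        ps = spec.params[d][name]
        if ps.status == "shared":
            # fix every member of the group to keep the constraint
            for dd, table in enumerate(spec.params):
                if table[name].status == "shared" and table[name].group == ps.group:
                    tables[dd][name] = ParameterSpec(name, "fixed", val, ps.bounds)
        else:
            tables[d][name] = ParameterSpec(name, "fixed", val, ps.bounds)
    return FitSpec(
        pairs=spec.pairs, params=tables, buffers=spec.buffers,
        two_acceptor=spec.two_acceptor, weighting=spec.weighting, window=spec.window,
    )


def _check_param_free(result: FitResult, param: str, decay: int) -> None:
    ps = result.spec.params[decay][param]
    if ps.status == "fixed":
        raise SpecError(f"parameter {param!r} is fixed in the fit; cannot profile it")


def chi2_profile(
    result: FitResult,
    param: str,
    grid: Sequence[float],
    decay: int = 0,
    n_starts: int = 1,
    seed: int = 0,
) -> np.ndarray:
    """Profiled reduced chi-square along ``grid`` for one parameter.

    At each grid value the parameter is fixed and all remaining free
    parameters are re-optimized (true profiling).  Reduced values use the
    original fit's degrees of freedom so the profile minimum matches
    ``result.reduced_chi2``.
    """
    _check_param_free(result, param, decay)
    grid = np.asarray(grid, dtype=float)
    fitted = result.estimates[decay][param]
    if fitted < grid.min() - 1e-12 or fitted > grid.max() + 1e-12:
        warnings.warn(
            f"profile grid for {param!r} excludes the fitted optimum {fitted:.4g}",
            RuntimeWarning, stacklevel=2,
        )
    dof = max(result.n_points - result.n_free, 1)
    out = np.empty(grid.size)
    for i, g in enumerate(grid):
        sub = _respec_with(result, {(decay, param): float(g)})
        r = fit(sub, n_starts=n_starts, seed=seed, early_stop_redchi=0.0,
                canonical_labels=False)
        out[i] = r.chi2 / dof
    return out


def chi2_surface(
    result: FitResult,
    param_x: str,
    param_y: str,
    grid_x: Sequence[float],
    grid_y: Sequence[float],
    decay: int = 0,
    n_starts: int = 1,
    seed: int = 0,
) -> np.ndarray:
    """2-D profiled reduced chi-square surface, shape (len(grid_y), len(grid_x))."""
    _check_param_free(result, param_x, decay)
    _check_param_free(result, param_y, decay)
    grid_x = np.asarray(grid_x, dtype=float)
    grid_y = np.asarray(grid_y, dtype=float)
    dof = max(result.n_points - result.n_free, 1)
    out = np.empty((grid_y.size, grid_x.size))
    for j, gy in enumerate(grid_y):
        for i, gx in enumerate(grid_x):
            sub = _respec_with(
                result, {(decay, param_x): float(gx), (decay, param_y): float(gy)}
            )
            r = fit(sub, n_starts=n_starts, seed=seed, early_stop_redchi=0.0,
                    canonical_labels=False)
            out[j, i] = r.chi2 / dof
    return out
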