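"""Synthetic TCSPC fixtures with the statistical structure the analysis assumes.

The forward model is exactly the reconvolution decay model (Gaussian IRF,
multi-exponential donor quenched by Gaussian-distributed acceptors, buffer
fluorescence, uniform background) followed by independent per-bin Poisson
sampling.  Scenario builders parameterize the fixtures from the study's
published fitted values so every pipeline stage can be exercised against a
known ground truth.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .energetics import DoseResponseFitResult, dose_response
from .exceptions import ConfigurationError, TdfretError
from .model import (
    BufferModel,
    DistanceDistribution,
    DonorModel,
    FretDecayParameters,
    buffer_intensity,
    fret_intensity,
    reconvolve,
)
from .tcspc import AcquisitionPair, DecayHistogram

__all__ = [
    "SimulationConfig",
    "FixtureSet",
    "simulate_irf",
    "simulate_decay",
    "simulate_single",
    "make_study_fixture",
    "SCENARIOS",
    "DONOR_MODEL",
    "FORSTER_RADIUS_ACD_RU",
]

_COUNT_OVERFLOW = 2**31

# ---------------------------------------------------------------------------
# study-derived fixture truth (published fitted parameters used as ground truth)

#: donor biexponential: 87% of a 17.6 ns lifetime, 13% of 4.73 ns
DONOR_MODEL = DonorModel(((0.87, 17.6), (0.13, 4.73)))
#: Forster radius of the Acd / Ru-complex pair (angstrom)
FORSTER_RADIUS_ACD_RU = 43.5

#: heterotetramer C-terminal construct, intrasubunit acceptor (r_bar, sigma)
HETERO_RESTING = (41.7, 2.3)
HETERO_ACTIVE = (28.8, 2.1)
HETERO_FRACTIONS = {"apo": 0.08, "sat": 0.96}
#: heterotetramer dose-response (micromolar; saturating/zero-ligand plateaus)
HETERO_DOSE = DoseResponseFitResult(K_D=0.22, protein_total=1.2, A=0.96, B=0.08)
TITRATION_UM = (0.0, 0.5, 1.0, 2.0, 320.0)

#: intersubunit-only heterotetramer (donor and acceptors on different subunits)
INTER_RESTING = (54.1, 3.0)
INTER_ACTIVE = (58.0, 5.0)
#: state fractions fixed (not fitted) in the intersubunit protocol
INTER_FRACTIONS = {"apo": 0.2, "sat": 0.8}

#: homotetramer C-terminal construct, intrasubunit distribution
HOMO_RESTING = (41.6, 3.6)
HOMO_ACTIVE = (29.1, 4.1)
HOMO_FRACTIONS = {"apo": 0.25, "sat": 0.94}

#: full-length construct, intrasubunit distribution
FULL_RESTING = (39.8, 4.1)
FULL_ACTIVE = (31.0, 2.7)
#: cross-construct global-fit state fractions
FULL_FRACTIONS = {"apo": 0.41, "sat": 0.99}

SCENARIOS = (
    "donor_only",
    "cterm_hetero_titration",
    "intersubunit",
    "cterm_homo",
    "full_length",
)


def intersubunit_distribution(f_active: float) -> DistanceDistribution:
    """Fixed-shape intersubunit distance distribution at the given fraction."""
    return DistanceDistribution.two_state(f_active, INTER_RESTING, INTER_ACTIVE)


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to generate one matched sample/buffer/IRF triple."""

    truth: FretDecayParameters
    buffer: Optional[BufferModel] = None
    time_window: float = 50.0
    n_bins: int = 1024
    irf_center: float = 2.0
    irf_fwhm: float = 0.5
    total_counts: float = 1e7
    irf_counts: float = 1e6
    buffer_counts: Optional[float] = None  # default: 1% of total_counts
    sample_acquisition_s: float = 300.0
    seed: int = 0
    label: str = ""

    def __post_init__(self):
        if self.n_bins < 64:
            raise ValueError("n_bins must be >= 64")
        if self.total_counts <= 0 or self.irf_counts <= 0:
            raise ValueError("count budgets must be positive")
        if self.irf_fwhm <= 0:
            raise ValueError("irf_fwhm must be positive")
        if self.time_window <= 0:
            raise ValueError("time_window must be positive")

    @property
    def dt(self) -> float:
        return self.time_window / self.n_bins

    @property
    def time(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.dt


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def _poisson(rng: np.random.Generator, expected: np.ndarray) -> np.ndarray:
    if np.any(expected >= _COUNT_OVERFLOW):
        raise TdfretError("expected counts exceed the per-bin overflow guard (2^31)")
    return rng.poisson(expected)


def simulate_irf(cfg: SimulationConfig) -> DecayHistogram:
    """Poisson-sampled Gaussian excitation pulse (scatter measurement)."""
    if cfg.irf_fwhm < 2 * cfg.dt:
        warnings.warn(
            "IRF FWHM below two bin widths: pulse is under-resolved",
            RuntimeWarning, stacklevel=2,
        )
    t = cfg.time
    sigma = cfg.irf_fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    z = (t - cfg.irf_center) / sigma
    expected = np.exp(-0.5 * z * z)
    total = expected.sum()
    if total <= 0:
        raise ConfigurationError("IRF pulse lies outside the time window")
    expected *= cfg.irf_counts / total
    counts = _poisson(_rng(cfg, 0), expected)
    return DecayHistogram(
        time=t, counts=counts, role="irf",
        acquisition_time=cfg.sample_acquisition_s, label=cfg.label,
    )


def simulate_decay(
    cfg: SimulationConfig, irf: DecayHistogram
) -> tuple[AcquisitionPair, FretDecayParameters, Optional[BufferModel]]:
    """Simulate a matched sample/buffer/IRF triple from the configured truth.

    The amplitude ``A0`` is rescaled so the expected sample signal (before
    buffer and background) totals ``cfg.total_counts``; buffer amplitudes are
    rescaled so the buffer-only trace totals ``cfg.buffer_counts``.  Returns
    the pair plus the effective (rescaled) truth for recovery checks.
    """
    t = irf.time
    if t.size != cfg.n_bins or abs(t[1] - t[0] - cfg.dt) > 1e-9 * cfg.dt:
        raise ConfigurationError("IRF grid does not match the simulation config")
    p = cfg.truth

    # amplitude calibration against the unit-amplitude convolved signal
    ida = fret_intensity(p, t)
    base = reconvolve(replace(p, f_B=0.0, bkgr_dec=0.0), ida, None, irf).values
    base_total = base.sum()
    if p.A0 == 0.0:
        A0_eff = 0.0  # explicit background/buffer-only truth: no signal term
    else:
        if base_total <= 0:
            raise ConfigurationError("model signal vanishes on the simulation grid")
        A0_eff = cfg.total_counts / base_total

    buffer_eff = None
    buffer_expected = None
    if cfg.buffer is not None:
        raw = reconvolve(
            replace(p, f_B=1.0, bkgr_dec=0.0), np.zeros_like(t), cfg.buffer, irf
        ).values
        target = cfg.buffer_counts if cfg.buffer_counts is not None else 0.01 * cfg.total_counts
        scale = target / raw.sum() if raw.sum() > 0 else 0.0
        buffer_eff = cfg.buffer.scaled(scale)
        buffer_expected = raw * scale + p.bkgr_dec

    truth_eff = replace(p, A0=A0_eff)
    sample_expected = reconvolve(truth_eff, A0_eff * ida, buffer_eff, irf).values
    sample_counts = _poisson(_rng(cfg, 1), sample_expected)

    f_B = truth_eff.f_B
    buffer_acq = cfg.sample_acquisition_s / f_B if f_B > 0 else cfg.sample_acquisition_s
    if buffer_expected is None:
        buffer_expected = np.full_like(t, max(p.bkgr_dec, 0.1))
    buffer_counts = _poisson(_rng(cfg, 2), buffer_expected)

    pair = AcquisitionPair(
        sample=DecayHistogram(
            t, sample_counts, role="sample",
            acquisition_time=cfg.sample_acquisition_s, label=cfg.label,
        ),
        buffer=DecayHistogram(
            t, buffer_counts, role="buffer",
            acquisition_time=buffer_acq, label=cfg.label,
        ),
        irf=irf,
    )
    return pair, truth_eff, buffer_eff


def simulate_single(
    rho1: DistanceDistribution,
    rho2: Optional[DistanceDistribution] = None,
    f_D: float = 0.05,
    seed: int = 0,
    n_bins: int = 1024,
    time_window: float = 50.0,
    total_counts: float = 1e7,
    with_buffer: bool = True,
    donor: DonorModel = DONOR_MODEL,
    R0: float = FORSTER_RADIUS_ACD_RU,
    label: str = "",
) -> tuple[AcquisitionPair, FretDecayParameters, Optional[BufferModel]]:
    """One matched triple from a study-like truth with the given distribution(s)."""
    truth = FretDecayParameters(
        f_D=f_D, donor=donor, R0=R0, rho1=rho1, rho2=rho2,
        f_B=0.5, A0=1.0, bkgr_dec=5.0,
    )
    cfg = SimulationConfig(
        truth=truth,
        buffer=_DEFAULT_BUFFER if with_buffer else None,
        n_bins=n_bins, time_window=time_window,
        total_counts=total_counts, seed=seed, label=label,
    )
    irf = simulate_irf(cfg)
    return simulate_decay(cfg, irf)


@dataclass(frozen=True)
class FixtureSet:
    """A scenario's simulated decays with their generating ground truth."""

    scenario: str
    pairs: tuple[AcquisitionPair, ...]
    truths: tuple[FretDecayParameters, ...]
    buffers: tuple[Optional[BufferModel], ...]
    labels: tuple[str, ...]
    donor: DonorModel
    R0: float
    two_acceptor: bool
    f_A2: tuple[float, ...]
    configs: tuple[SimulationConfig, ...] = field(repr=False, default=())

    def __iter__(self):
        return iter(self.pairs)

    def __len__(self):
        return len(self.pairs)


def _default_truth(
    rho1: DistanceDistribution,
    rho2: Optional[DistanceDistribution] = None,
    f_D: float = 0.05,
) -> FretDecayParameters:
    return FretDecayParameters(
        f_D=f_D,
        donor=DONOR_MODEL,
        R0=FORSTER_RADIUS_ACD_RU,
        rho1=rho1,
        rho2=rho2,
        shift_irf=0.0,
        f_B=0.5,
        A0=1.0,
        bkgr_dec=5.0,
        bkgr_irf=0.0,
    )


_DEFAULT_BUFFER = BufferModel(((1.0, 2.0),))


def make_study_fixture(
    scenario: str,
    seed: int = 0,
    n_bins: int = 1024,
    time_window: float = 50.0,
    total_counts: float = 1e7,
    irf_counts: float = 1e6,
    with_buffer: bool = True,
) -> FixtureSet:
    """Simulated decays for one study-like scenario.

    Scenarios: ``donor_only`` (one donor-only pair), ``cterm_hetero_titration``
    (five single-acceptor decays at 0/0.5/1/2/320 uM ligand, fractions from
    the published dose-response curve), ``intersubunit`` (apo and saturating
    decays of the intersubunit-only construct), ``cterm_homo`` and
    ``full_length`` (two-acceptor decays with the intersubunit distribution
    linked to the intrasubunit fraction).
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")

    conditions: list[tuple[str, float]] = []  # (label, f_A2)
    two_acceptor = False
    if scenario == "donor_only":
        conditions = [("donor_only", 0.0)]
    elif scenario == "cterm_hetero_titration":
        conditions = [
            (f"cAMP_{L:g}uM", dose_response(L, HETERO_DOSE)) for L in TITRATION_UM
        ]
    elif scenario == "intersubunit":
        conditions = [("apo", INTER_FRACTIONS["apo"]), ("cAMP_320uM", INTER_FRACTIONS["sat"])]
    elif scenario == "cterm_homo":
        two_acceptor = True
        conditions = [("apo", HOMO_FRACTIONS["apo"]), ("cAMP_320uM", HOMO_FRACTIONS["sat"])]
    elif scenario == "full_length":
        two_acceptor = True
        conditions = [("apo", FULL_FRACTIONS["apo"]), ("cAMP_320uM", FULL_FRACTIONS["sat"])]

    pairs, truths, buffers, labels, fa2s, cfgs = [], [], [], [], [], []
    base_cfg = SimulationConfig(
        truth=_default_truth(DistanceDistribution.single(50.0, 3.0)),
        n_bins=n_bins, time_window=time_window,
        total_counts=total_counts, irf_counts=irf_counts, seed=seed,
    )
    irf = simulate_irf(base_cfg)
    for i, (label, f_active) in enumerate(conditions):
        if scenario == "donor_only":
            truth = replace(
                _default_truth(DistanceDistribution.single(50.0, 3.0)), f_D=1.0
            )
        elif scenario == "cterm_hetero_titration":
            rho1 = DistanceDistribution.two_state(f_active, HETERO_RESTING, HETERO_ACTIVE)
            truth = _default_truth(rho1)
        elif scenario == "intersubunit":
            rho1 = DistanceDistribution.two_state(f_active, INTER_RESTING, INTER_ACTIVE)
            truth = _default_truth(rho1)
        else:
            resting, active = (
                (HOMO_RESTING, HOMO_ACTIVE) if scenario == "cterm_homo"
                else (FULL_RESTING, FULL_ACTIVE)
            )
            rho1 = DistanceDistribution.two_state(f_active, resting, active)
            truth = _default_truth(rho1, rho2=intersubunit_distribution(f_active))
        cfg = replace(
            base_cfg, truth=truth, buffer=_DEFAULT_BUFFER if with_buffer else None,
            seed=seed + 1000 * i + 1, label=label,
        )
        pair, truth_eff, buffer_eff = simulate_decay(cfg, irf)
        pairs.append(pair)
        truths.append(truth_eff)
        buffers.append(buffer_eff)
        labels.append(label)
        fa2s.append(f_active)
        cfgs.append(cfg)
    return FixtureSet(
        scenario=scenario,
        pairs=tuple(pairs),
        truths=tuple(truths),
        buffers=tuple(buffers),
        labels=tuple(labels),
        donor=DONOR_MODEL,
        R0=FORSTER_RADIUS_ACD_RU,
        two_acceptor=two_acceptor,
        f_A2=tuple(fa2s),
        configs=tuple(cfgs),
    )
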