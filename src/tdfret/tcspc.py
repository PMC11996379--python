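"""Domain types for TCSPC decay records and plain-text histogram I/O.

A decay record is a photon-count histogram on a uniform grid of time-bin
centers (nanoseconds).  Files are two-column delimited text (tab or comma,
auto-detected) with optional ``#``-prefixed ``key=value`` header lines
carrying metadata (``acquisition_time_s``, ``label``, ``role``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .exceptions import FormatError, GridError

__all__ = [
    "DecayHistogram",
    "ModelCurve",
    "AcquisitionPair",
    "read_histogram",
    "write_histogram",
]

log = logging.getLogger(__name__)

ROLES = ("sample", "buffer", "irf")

#: relative tolerance on bin-spacing uniformity
GRID_RTOL = 1e-9
#: minimum number of bins in a usable histogram
MIN_BINS = 16


def _check_grid(time: np.ndarray) -> float:
    """Validate a strictly increasing uniform grid; return the bin width."""
    if time.ndim != 1 or time.size < MIN_BINS:
        raise GridError(f"time grid must be 1-D with >= {MIN_BINS} bins, got shape {time.shape}")
    diffs = np.diff(time)
    if np.any(diffs <= 0):
        raise GridError("time grid must be strictly increasing")
    dt = float(np.mean(diffs))
    if np.max(np.abs(diffs - dt)) > max(GRID_RTOL * dt, 64 * np.finfo(float).eps * abs(time[-1])):
        raise GridError("time grid spacing is not uniform")
    return dt


@dataclass(frozen=True)
class DecayHistogram:
    """A measured or simulated photon-count trace.

    Parameters
    ----------
    time
        Bin centers in nanoseconds; strictly increasing, uniform spacing.
    counts
        Non-negative integer photon counts, one per bin.
    role
        One of ``sample``, ``buffer``, ``irf``.
    acquisition_time
        Acquisition duration in seconds (used for buffer scaling).
    label
        Free-text condition tag (construct, ligand concentration, ...).
    """

    time: np.ndarray
    counts: np.ndarray
    role: str = "sample"
    acquisition_time: float = 1.0
    label: str = ""

    def __post_init__(self):
        time = np.asarray(self.time, dtype=float)
        counts = np.asarray(self.counts)
        object.__setattr__(self, "time", time)
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        _check_grid(time)
        if counts.shape != time.shape:
            raise FormatError("time and counts must have the same length")
        carr = np.asarray(counts, dtype=float)
        if not np.all(np.isfinite(carr)):
            raise FormatError("counts must be finite")
        if np.any(carr < 0):
            raise FormatError("counts must be non-negative")
        if np.any(carr != np.floor(carr)):
            raise FormatError("counts must be integer-valued (use ModelCurve for model output)")
        object.__setattr__(self, "counts", carr.astype(np.int64))
        if self.acquisition_time <= 0:
            raise ValueError("acquisition_time must be positive")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def total_counts(self) -> int:
        return int(self.counts.sum())

    def with_role(self, role: str) -> "DecayHistogram":
        return replace(self, role=role)

    def same_grid(self, other: "DecayHistogram") -> bool:
        return self.time.shape == other.time.shape and np.allclose(
            self.time, other.time, rtol=0, atol=GRID_RTOL * self.dt
        )


@dataclass(frozen=True)
class ModelCurve:
    """Real-valued model estimate of a decay on the same grid contract."""

    time: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        time = np.asarray(self.time, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "values", values)
        _check_grid(time)
        if values.shape != time.shape:
            raise FormatError("time and values must have the same length")
        if not np.all(np.isfinite(values)):
            raise FormatError("model values must be finite")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])


@dataclass(frozen=True)
class AcquisitionPair:
    """Matched sample / buffer-only / IRF measurements on one time grid."""

    sample: DecayHistogram
    buffer: DecayHistogram
    irf: DecayHistogram

    def __post_init__(self):
        for name, h, role in (
            ("sample", self.sample, "sample"),
            ("buffer", self.buffer, "buffer"),
            ("irf", self.irf, "irf"),
        ):
            if h.role != role:
                raise ValueError(f"{name} histogram has role {h.role!r}, expected {role!r}")
        if not (self.sample.same_grid(self.buffer) and self.sample.same_grid(self.irf)):
            raise GridError("sample, buffer and irf must share an identical time grid")

    @property
    def f_B_default(self) -> float:
        """Buffer scale: sample acquisition time over buffer acquisition time."""
        return self.sample.acquisition_time / self.buffer.acquisition_time

    @property
    def time(self) -> np.ndarray:
        return self.sample.time


def read_histogram(path, role: str = "sample") -> DecayHistogram:
    """Read a two-column delimited-text histogram.

    Header lines start with ``#`` and may carry ``key=value`` metadata.
    Missing ``acquisition_time_s`` defaults to 1 s with a logged warning.
    """
    meta: dict[str, str] = {}
    rows: list[tuple[float, float]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    meta[key.strip()] = value.strip()
                continue
            for sep in ("\t", ",", None):
                parts = line.split(sep)
                if len(parts) == 2:
                    break
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected two columns, got {line!r}")
            try:
                rows.append((float(parts[0]), float(parts[1])))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric entry in {line!r}") from exc
    if not rows:
        raise FormatError(f"{path}: no data rows")
    arr = np.array(rows, dtype=float)
    if "acquisition_time_s" in meta:
        acq = float(meta["acquisition_time_s"])
    else:
        log.warning("%s: no acquisition_time_s metadata; defaulting to 1 s", path)
        acq = 1.0
    return DecayHistogram(
        time=arr[:, 0],
        counts=arr[:, 1],
        role=meta.get("role", role),
        acquisition_time=acq,
        label=meta.get("label", ""),
    )


def write_histogram(h: DecayHistogram, path) -> str:
    """Write ``h`` as two-column tab-delimited text; round-trips bit-exactly."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# role={h.role}\n")
        fh.write(f"# acquisition_time_s={h.acquisition_time:.17g}\n")
        if h.label:
            fh.write(f"# label={h.label}\n")
        for t, c in zip(h.time, h.counts):
            fh.write(f"{t:.17g}\t{int(c)}\n")
    return str(path)
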