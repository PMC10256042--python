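"""R–R interval cleaning and uniform resampling.

Heartbeat interval series (tachograms) carry occasional physiologically
implausible beats — premature complexes, missed detections — that must be
removed before spectral analysis.  Beats outside a plausibility range are
replaced by the average of their valid neighbours, and the irregularly
sampled tachogram is then resampled on a uniform grid at the mean heart
rate so that autoregressive spectral estimation applies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
from scipy.interpolate import CubicSpline, interp1d

__all__ = [
    "RRSeries",
    "UniformSeries",
    "QualityError",
    "filter_rr_range",
    "resample_uniform",
    "hr_trend",
    "read_rr_csv",
    "write_rr_csv",
]

#: Default plausibility range for an R–R interval (ms); beats outside it
#: correspond to instantaneous heart rates above ~220 or below 40 bpm.
RR_LO_MS = 273.0
RR_HI_MS = 1500.0


class QualityError(ValueError):
    """Recording unusable: too large a fraction of beats is out of range."""


@dataclass(frozen=True)
class RRSeries:
    """Ordered heartbeat intervals with their onset times.

    ``t_ms[i]`` is the onset time of interval ``rr_ms[i]``; the first
    interval starts at ``t_ms[0]`` (conventionally 0) and the series covers
    ``t_ms[0] .. t_ms[-1] + rr_ms[-1]`` milliseconds.
    """

    rr_ms: np.ndarray
    t_ms: np.ndarray
    schedule: "object | None" = field(default=None, compare=False)

    def __post_init__(self) -> None:
        rr = np.asarray(self.rr_ms, dtype=float)
        t = np.asarray(self.t_ms, dtype=float)
        object.__setattr__(self, "rr_ms", rr)
        object.__setattr__(self, "t_ms", t)
        if rr.ndim != 1 or t.ndim != 1 or rr.size != t.size:
            raise ValueError("rr_ms and t_ms must be 1-D arrays of equal length")
        if rr.size < 2:
            raise ValueError("an RR series needs at least 2 beats")
        if np.any(rr <= 0):
            raise ValueError("rr_ms must be strictly positive")
        if np.any(np.diff(t) <= 0):
            raise ValueError("t_ms must be strictly increasing")

    def __len__(self) -> int:
        return int(self.rr_ms.size)

    @property
    def duration_ms(self) -> float:
        """Total time spanned by the intervals."""
        return float(self.t_ms[-1] + self.rr_ms[-1] - self.t_ms[0])

    @classmethod
    def from_intervals(cls, rr_ms, t0_ms: float = 0.0, schedule=None) -> "RRSeries":
        """Build a series from bare intervals, reconstructing onset times
        cumulatively from ``t0_ms``."""
        rr = np.asarray(rr_ms, dtype=float)
        t = t0_ms + np.concatenate([[0.0], np.cumsum(rr[:-1])])
        return cls(rr_ms=rr, t_ms=t, schedule=schedule)


@dataclass(frozen=True)
class UniformSeries:
    """Evenly resampled tachogram: ``values_ms[k]`` at ``t0_ms + k/fs_hz``."""

    values_ms: np.ndarray
    fs_hz: float
    t0_ms: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "values_ms", np.asarray(self.values_ms, dtype=float))
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")

    def __len__(self) -> int:
        return int(self.values_ms.size)

    @property
    def t_s(self) -> np.ndarray:
        """Sample times in seconds."""
        return (self.t0_ms + np.arange(len(self)) / self.fs_hz * 1000.0) / 1000.0


def filter_rr_range(
    rr: RRSeries,
    lo_ms: float = RR_LO_MS,
    hi_ms: float = RR_HI_MS,
    max_bad_fraction: float = 0.5,
) -> tuple[RRSeries, int]:
    """Replace out-of-range intervals by the mean of their valid neighbours.

    Each interval outside ``[lo_ms, hi_ms]`` is replaced by the average of
    the nearest in-range interval before it and after it; an edge beat with
    only one valid neighbour copies that neighbour.  Onset times are rebuilt
    cumulatively from the replaced intervals, so the corrected series has a
    consistent timeline.

    Returns the cleaned series and the number of replaced beats.

    Raises
    ------
    QualityError
        If more than ``max_bad_fraction`` of beats are out of range.
    ValueError
        If no beat at all is in range (nothing to interpolate from), or the
        series is shorter than 3 beats while containing an interior artifact.
    """
    x = rr.rr_ms.copy()
    bad = (x < lo_ms) | (x > hi_ms)
    n_bad = int(bad.sum())
    if n_bad == 0:
        return rr, 0
    if n_bad > max_bad_fraction * x.size:
        raise QualityError(
            f"{n_bad}/{x.size} beats outside [{lo_ms}, {hi_ms}] ms "
            f"(> {max_bad_fraction:.0%}); recording unusable"
        )
    good_idx = np.flatnonzero(~bad)
    if good_idx.size == 0:
        raise ValueError("no in-range beats to interpolate from")

    for i in np.flatnonzero(bad):
        left = good_idx[good_idx < i]
        right = good_idx[good_idx > i]
        if left.size and right.size:
            x[i] = 0.5 * (x[left[-1]] + x[right[0]])
        elif left.size:
            x[i] = x[left[-1]]
        else:
            x[i] = x[right[0]]

    t = rr.t_ms[0] + np.concatenate([[0.0], np.cumsum(x[:-1])])
    return RRSeries(rr_ms=x, t_ms=t, schedule=rr.schedule), n_bad


def resample_uniform(
    rr: RRSeries,
    method: Literal["cubic", "linear"] = "cubic",
    min_duration_s: float = 30.0,
) -> UniformSeries:
    """Resample the tachogram at the mean heart rate.

    The sampling frequency is ``1 / mean(rr)`` (in Hz), i.e. one sample per
    mean beat.  The tachogram ``(t_i, rr_i)`` is interpolated on the uniform
    grid starting at the first beat onset; the number of samples is
    ``floor(duration * fs)``.  Cubic-spline interpolation is the default
    (standard HRV practice); ``linear`` is exact for piecewise-linear tests.
    """
    duration_s = rr.duration_ms / 1000.0
    if duration_s < min_duration_s:
        raise ValueError(
            f"recording of {duration_s:.1f} s is shorter than the "
            f"{min_duration_s:.0f}-s minimum for one spectral window"
        )
    mean_rr_s = float(np.mean(rr.rr_ms)) / 1000.0
    fs = 1.0 / mean_rr_s
    n = int(np.floor(duration_s * fs))
    grid_ms = rr.t_ms[0] + np.arange(n) / fs * 1000.0
    # hold edge values outside the observed beat times
    grid_clipped = np.clip(grid_ms, rr.t_ms[0], rr.t_ms[-1])
    if method == "cubic" and len(rr) >= 4:
        f = CubicSpline(rr.t_ms, rr.rr_ms)
        values = f(grid_clipped)
    else:
        f = interp1d(rr.t_ms, rr.rr_ms, kind="linear")
        values = f(grid_clipped)
    return UniformSeries(values_ms=np.asarray(values), fs_hz=fs, t0_ms=float(rr.t_ms[0]))


def hr_trend(rr: RRSeries) -> np.ndarray:
    """Per-beat heart rate in beats/min: ``60000 / rr_ms``."""
    return 60000.0 / rr.rr_ms


def read_rr_csv(path: str | Path) -> RRSeries:
    """Read an RR series from CSV with header ``t_ms,rr_ms``, or from a bare
    list of interval values (one ms value per line, onsets reconstructed
    cumulatively)."""
    path = Path(path)
    first = path.read_text().lstrip().splitlines()[0]
    if "," in first:
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return RRSeries(rr_ms=data[:, 1], t_ms=data[:, 0])
    rr = np.loadtxt(path, ndmin=1)
    return RRSeries.from_intervals(rr)


def write_rr_csv(rr: RRSeries, path: str | Path) -> None:
    """Write the series as ``t_ms,rr_ms`` CSV."""
    arr = np.column_stack([rr.t_ms, rr.rr_ms])
    np.savetxt(path, arr, delimiter=",", header="t_ms,rr_ms", comments="", fmt="%.6f")
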