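"""Couch-space positioning errors and accuracy statistics.

Axis mapping between image displacements and couch axes: the frontal
image's x axis corresponds to the couch lateral direction, the lateral
image's x axis to the vertical direction, and both images' y axes to the
longitudinal direction.  The positioning error at pattern position *i*
against a couch movement ``m_i`` is

    E_lat,i  = m_lat,i  - (dx_F,ref - dx_F,i)
    E_vert,i = m_vert,i - (dx_L,ref - dx_L,i)
    E_long,i = m_long,i - ((dy_F,ref - dy_F,i) + (dy_L,ref - dy_L,i)) / 2

with the reference displacements taken from the registration at the origin
couch position and all pixel displacements converted to mm through the
shared pixel spacing.  The per-position RMSE pools the three axis errors;
pattern aggregates use population standard deviations (divisor n).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .types import Displacement, ReferenceDisplacement

__all__ = [
    "CouchShift",
    "PositioningError",
    "couch_error",
    "rmse_of_axes",
    "aggregate_pattern",
    "PatternSummary",
    "correlate_with_reference",
    "screen_threshold",
    "ScreenResult",
]


@dataclass(frozen=True)
class CouchShift:
    """Signed couch displacement (mm) along the three couch axes."""

    lat_mm: float
    vert_mm: float
    long_mm: float
    label: str = ""

    def __post_init__(self) -> None:
        for v in (self.lat_mm, self.vert_mm, self.long_mm):
            if not math.isfinite(v):
                raise ValueError("couch shifts must be finite")


@dataclass(frozen=True)
class PositioningError:
    """Per-axis positioning errors (mm) and their pooled RMSE."""

    e_lat_mm: float
    e_vert_mm: float
    e_long_mm: float
    rmse_mm: float
    label: str = ""

    def __post_init__(self) -> None:
        expect = rmse_of_axes(self.e_lat_mm, self.e_vert_mm, self.e_long_mm)
        if abs(expect - self.rmse_mm) > 1e-12:
            raise ValueError("rmse_mm inconsistent with the per-axis errors")

    @classmethod
    def from_axes(cls, e_lat: float, e_vert: float, e_long: float, label: str = "") -> "PositioningError":
        return cls(e_lat, e_vert, e_long, rmse_of_axes(e_lat, e_vert, e_long), label)


def rmse_of_axes(e_lat_mm: float, e_vert_mm: float, e_long_mm: float) -> float:
    """Root of the mean of the three squared axis errors."""
    return math.sqrt((e_lat_mm**2 + e_vert_mm**2 + e_long_mm**2) / 3.0)


def couch_error(
    ref: ReferenceDisplacement,
    meas: ReferenceDisplacement,
    couch: CouchShift,
    pixel_spacing_mm: float,
) -> PositioningError:
    """Positioning error of one measured pattern position.

    ``ref`` is the frontal/lateral registration at the origin couch
    position, ``meas`` the registration at the displaced position, and
    ``couch`` the movement actually applied.  Displacements are converted
    from pixels to mm with the single shared spacing.
    """
    if pixel_spacing_mm <= 0:
        raise ValueError("pixel_spacing_mm must be > 0")
    sp = pixel_spacing_mm
    e_lat = couch.lat_mm - (ref.frontal.dx_px - meas.frontal.dx_px) * sp
    e_vert = couch.vert_mm - (ref.lateral.dx_px - meas.lateral.dx_px) * sp
    e_long = couch.long_mm - 0.5 * (
        (ref.frontal.dy_px - meas.frontal.dy_px) + (ref.lateral.dy_px - meas.lateral.dy_px)
    ) * sp
    return PositioningError.from_axes(e_lat, e_vert, e_long, label=couch.label)


@dataclass(frozen=True)
class PatternSummary:
    """Aggregate accuracy over a movement pattern (means and population SDs)."""

    n: int
    mean_lat_mm: float
    sd_lat_mm: float
    mean_vert_mm: float
    sd_vert_mm: float
    mean_long_mm: float
    sd_long_mm: float
    mean_rmse_mm: float
    sd_rmse_mm: float


def aggregate_pattern(errors: Sequence[PositioningError]) -> PatternSummary:
    """Per-axis mean +/- SD and RMSE mean +/- SD over a list of positions.

    Standard deviations are population SDs (divisor n), matching the
    convention of the published aggregate.
    """
    if len(errors) == 0:
        raise ValueError("cannot aggregate an empty error list")
    lat = np.array([e.e_lat_mm for e in errors])
    vert = np.array([e.e_vert_mm for e in errors])
    long_ = np.array([e.e_long_mm for e in errors])
    rmse = np.array([e.rmse_mm for e in errors])
    return PatternSummary(
        n=len(errors),
        mean_lat_mm=float(lat.mean()),
        sd_lat_mm=float(lat.std()),
        mean_vert_mm=float(vert.mean()),
        sd_vert_mm=float(vert.std()),
        mean_long_mm=float(long_.mean()),
        sd_long_mm=float(long_.std()),
        mean_rmse_mm=float(rmse.mean()),
        sd_rmse_mm=float(rmse.std()),
    )


def correlate_with_reference(calc: Sequence[float], ref: Sequence[float]) -> float:
    """Pearson correlation between calculated and reference components."""
    calc = np.asarray(calc, dtype=np.float64)
    ref = np.asarray(ref, dtype=np.float64)
    if calc.shape != ref.shape or calc.ndim != 1:
        raise ValueError("inputs must be equal-length 1D sequences")
    if calc.size < 3:
        raise ValueError("need at least 3 points for a correlation")
    if calc.std() == 0 or ref.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(stats.pearsonr(calc, ref).statistic)


@dataclass(frozen=True)
class ScreenResult:
    """Counts of positions passing/failing a per-direction error limit."""

    n: int
    limit_mm: float
    n_rmse_pass: int
    n_rmse_fail: int
    n_axis_fail_lat: int
    n_axis_fail_vert: int
    n_axis_fail_long: int

    @property
    def pass_fraction(self) -> float:
        return self.n_rmse_pass / self.n


def screen_threshold(errors: Sequence[PositioningError], limit_mm: float = 2.0) -> ScreenResult:
    """Screen positions against the clinical re-setup limit (default 2 mm).

    A position fails on an axis when the absolute axis error exceeds the
    limit; the RMSE count uses the pooled per-position RMSE.
    """
    if len(errors) == 0:
        raise ValueError("cannot screen an empty error list")
    rmse_fail = sum(1 for e in errors if e.rmse_mm > limit_mm)
    return ScreenResult(
        n=len(errors),
        limit_mm=limit_mm,
        n_rmse_pass=len(errors) - rmse_fail,
        n_rmse_fail=rmse_fail,
        n_axis_fail_lat=sum(1 for e in errors if abs(e.e_lat_mm) > limit_mm),
        n_axis_fail_vert=sum(1 for e in errors if abs(e.e_vert_mm) > limit_mm),
        n_axis_fail_long=sum(1 for e in errors if abs(e.e_long_mm) > limit_mm),
    )
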