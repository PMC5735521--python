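"""AP-VS curves versus heart rate: gradients, regression, PQ comparison.

The shape of the AP-VS curve under the M10/M20 recipes is counter-intuitive
because cycle length is hyperbolic in heart rate while the tabulated VAI
maximum falls in 10-bpm steps.  This module samples the curves on a heart
rate grid, differentiates them, fits ordinary least-squares regression lines
(with Pearson R^2) and compares a curve against a heart-rate-dependent PQ
duration reference.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .device_core import Method, VaiMaxTable, ap_vs_for_method, round_half_up

__all__ = [
    "ApVsCurve",
    "RegressionResult",
    "PqReference",
    "ReferenceComparison",
    "build_curve",
    "curve_gradient",
    "fit_regression",
    "pq_reference_curve",
    "compare_to_reference",
    "default_pq_reference",
    "observer_regressions",
]


@dataclass(frozen=True)
class ApVsCurve:
    """Sampled (heart rate, AP-VS) series with its generating method/grid."""

    method: Method
    hr: np.ndarray  # bpm, strictly increasing
    ap_vs: np.ndarray  # ms, unrounded
    grid: tuple[float, float, float]  # (hr_min, hr_max, step)

    def __post_init__(self) -> None:
        hr = np.asarray(self.hr, dtype=float)
        vals = np.asarray(self.ap_vs, dtype=float)
        object.__setattr__(self, "hr", hr)
        object.__setattr__(self, "ap_vs", vals)
        if hr.size != vals.size or hr.size == 0:
            raise ValueError("hr and ap_vs must be equal-length, non-empty")
        if np.any(np.diff(hr) <= 0):
            raise ValueError("hr must be strictly increasing")
        if np.any(vals <= 0):
            raise ValueError("all AP-VS values must be positive")

    @property
    def n(self) -> int:
        return int(self.hr.size)

    def rounded(self) -> np.ndarray:
        """Integer-ms view of the samples (presentation/device resolution)."""
        return np.array([round_half_up(v) for v in self.ap_vs])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"hr_bpm": self.hr, "ap_vs_ms": self.ap_vs})


def build_curve(
    method: Method | str,
    hr_min: float,
    hr_max: float,
    step: float,
    table: VaiMaxTable | None = None,
) -> ApVsCurve:
    """Sample the AP-VS curve of recipe M10/M20 on a uniform heart-rate grid.

    The grid is ``hr_min, hr_min + step, ...`` up to and including ``hr_max``
    when it lies on the grid.  A recipe that is unprogrammable at any grid
    point (e.g. M20 above 210 bpm) raises an error naming that rate.
    """
    method = Method.coerce(method)
    if step <= 0:
        raise ValueError("step must be positive")
    if hr_min > hr_max:
        raise ValueError("hr_min must not exceed hr_max")
    n = int(np.floor((hr_max - hr_min) / step + 1e-9)) + 1
    grid = hr_min + step * np.arange(n)
    values = []
    for hr in grid:
        try:
            values.append(ap_vs_for_method(hr, method, table))
        except ValueError as exc:
            raise ValueError(f"{method.value} undefined at {hr:g} bpm: {exc}") from exc
    return ApVsCurve(method, grid, np.array(values), (hr_min, hr_max, step))


def curve_gradient(curve: ApVsCurve, resolution: str = "device") -> np.ndarray:
    """Forward finite-difference gradient of the curve, in ms/bpm.

    Returns an ``(n-1, 2)`` array of ``(hr, gradient)`` pairs, the gradient
    between grid points ``k`` and ``k+1`` being attached to the left point.

    ``resolution='device'`` (default) differentiates the integer-ms view of
    the curve — the granularity at which intervals are programmed and
    reported — while ``'exact'`` uses the unrounded samples.  The distinction
    matters: at exact resolution the M20 curve has a +0.04 ms/bpm ripple
    between 170 and 180 bpm that vanishes at 1-ms resolution.
    """
    if curve.n < 2:
        raise ValueError("gradient needs at least two samples")
    if resolution == "device":
        y = curve.rounded().astype(float)
    elif resolution == "exact":
        y = curve.ap_vs
    else:
        raise ValueError("resolution must be 'device' or 'exact'")
    grads = np.diff(y) / np.diff(curve.hr)
    return np.column_stack([curve.hr[:-1], grads])


@dataclass(frozen=True)
class RegressionResult:
    """OLS line through an AP-VS curve, with Pearson R^2."""

    slope: float  # ms/bpm
    intercept: float  # ms
    r_squared: float
    n: int
    hr_range: tuple[float, float]

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("regression needs n >= 2")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("R^2 must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "slope_ms_per_bpm": self.slope,
            "intercept_ms": self.intercept,
            "r_squared": self.r_squared,
            "n": self.n,
            "hr_range_bpm": list(self.hr_range),
        }


def fit_regression(curve: ApVsCurve) -> RegressionResult:
    """Ordinary least squares of AP-VS on heart rate.

    R^2 is the squared Pearson correlation between the samples and the
    fitted line, which for simple OLS equals the squared correlation of the
    raw variables.
    """
    if curve.n < 2:
        raise ValueError("regression needs at least two samples")
    if np.ptp(curve.hr) == 0:
        raise ValueError("degenerate curve: all heart rates identical")
    fit = stats.linregress(curve.hr, curve.ap_vs)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n=curve.n,
        hr_range=(float(curve.hr[0]), float(curve.hr[-1])),
    )


@dataclass(frozen=True)
class PqReference:
    """Piecewise-linear heart-rate-dependent PQ duration reference.

    ``anchors`` are (hr, pq) pairs with hr strictly increasing and pq
    non-increasing; ``offset`` is a constant added to every interpolated
    value (the +0/+10/+20 ms comparison bands).
    """

    anchors: tuple[tuple[float, float], ...]
    offset: float = 0.0

    def __post_init__(self) -> None:
        if len(self.anchors) < 2:
            raise ValueError("need at least two anchors")
        hrs = [h for h, _ in self.anchors]
        pqs = [p for _, p in self.anchors]
        if hrs != sorted(hrs) or len(set(hrs)) != len(hrs):
            raise ValueError("anchor heart rates must be strictly increasing")
        if any(b > a for a, b in zip(pqs, pqs[1:])):
            raise ValueError("PQ must be non-increasing with heart rate")

    @property
    def hr_span(self) -> tuple[float, float]:
        return (self.anchors[0][0], self.anchors[-1][0])

    def with_offset(self, offset: float) -> "PqReference":
        return PqReference(self.anchors, offset)


#: Synthetic stand-in for literature PQ-duration data (not patient-derived):
#: monotone decreasing from ~160 ms at 100 bpm to ~100 ms at 220 bpm.
_SYNTHETIC_PQ_ANCHORS = (
    (60.0, 170.0),
    (100.0, 160.0),
    (140.0, 142.0),
    (180.0, 122.0),
    (220.0, 100.0),
    (260.0, 92.0),
)


def default_pq_reference(offset: float = 0.0) -> PqReference:
    """Synthetic PQ-duration reference shipped as a configurable stand-in."""
    return PqReference(_SYNTHETIC_PQ_ANCHORS, offset)


def pq_reference_curve(ref: PqReference, hr_grid: Sequence[float]) -> np.ndarray:
    """Interpolated reference values (pq + offset) on a heart-rate grid."""
    grid = np.asarray(hr_grid, dtype=float)
    lo, hi = ref.hr_span
    if grid.size == 0:
        raise ValueError("empty heart-rate grid")
    if grid.min() < lo or grid.max() > hi:
        raise ValueError(
            f"grid [{grid.min():g}, {grid.max():g}] bpm outside the anchor "
            f"span [{lo:g}, {hi:g}] bpm"
        )
    xs = np.array([h for h, _ in ref.anchors])
    ys = np.array([p for _, p in ref.anchors])
    vals = np.interp(grid, xs, ys) + ref.offset
    return np.column_stack([grid, vals])


@dataclass(frozen=True)
class ReferenceComparison:
    """Signed residuals of an AP-VS curve against a PQ reference."""

    table: pd.DataFrame = field(repr=False)  # hr_bpm, ap_vs_ms, reference_ms, residual_ms
    mean_abs_residual: float = 0.0


def compare_to_reference(curve: ApVsCurve, ref: PqReference) -> ReferenceComparison:
    """Residuals curve - (pq + offset) on the overlap of the two hr ranges."""
    lo, hi = ref.hr_span
    mask = (curve.hr >= lo) & (curve.hr <= hi)
    if not mask.any():
        raise ValueError("curve and reference heart-rate ranges do not overlap")
    hr = curve.hr[mask]
    vals = curve.ap_vs[mask]
    refvals = pq_reference_curve(ref, hr)[:, 1]
    resid = vals - refvals
    table = pd.DataFrame(
        {
            "hr_bpm": hr,
            "ap_vs_ms": vals,
            "reference_ms": refvals,
            "residual_ms": resid,
        }
    )
    return ReferenceComparison(table, float(np.abs(resid).mean()))


def observer_regressions() -> pd.DataFrame:
    """Read-only fixture: regression characteristics of the calculated curves
    and of six experienced observers' estimated curves (documentation only;
    the raw estimates behind the observer rows are not available)."""
    ref = resources.files("avtpace.data").joinpath("observer_regressions.csv")
    with ref.open("r", newline="") as fh:
        return pd.read_csv(fh)
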