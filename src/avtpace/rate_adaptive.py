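"""Rate-adaptive ideal AP-VS relation and its smooth closed form.

The hemodynamically ideal AP-VS interval mimics the AV node: long at slow
rates, short at fast rates, changing at about -0.4 ms/bpm in between.  Two
equivalent descriptions are provided:

* :func:`piecewise_ideal` — the piecewise-linear idealisation: a 130 ms
  plateau below 122.5 bpm, a 95 ms floor above 210 bpm, and a -0.4 ms/bpm
  linear segment between the two.
* :func:`ideal_ap_vs` — a smooth closed form built from a sum of
  log-magnitude terms of two even-order Butterworth low-pass responses with
  pole quality factors :func:`butterworth_q`; it rounds the corners of the
  piecewise relation while keeping the same plateaus and mid-slope, which
  makes it directly implementable in device firmware.

Both work in normalised units x = HR/100 bpm, y = AP-VS/100 ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .threshold_policy import Classification, SafetyBand, classify

__all__ = [
    "IdealApVsParams",
    "AdaptiveSettings",
    "SensingWindow",
    "Recommendation",
    "butterworth_q",
    "ideal_ap_vs",
    "piecewise_ideal",
    "sensing_window",
    "recommend_interval",
    "DEFAULT_PARAMS",
]


def butterworth_q(n: int) -> np.ndarray:
    """Pole quality factors of an order-``n`` Butterworth low-pass.

    Q_i = 1 / (2 sin phi_i) with phi_i = pi (2i - 1) / (2n), i = 1..n/2;
    returned strictly decreasing.  ``n`` must be even and positive.
    """
    if n <= 0 or n % 2:
        raise ValueError(f"order must be a positive even integer, got {n}")
    i = np.arange(1, n // 2 + 1)
    phi = math.pi / (2 * n) * (2 * i - 1)
    return 1.0 / (2.0 * np.sin(phi))


@dataclass(frozen=True)
class IdealApVsParams:
    """Parameters of the smooth ideal AP-VS relation (normalised units).

    x1, x2   corner rates / 100 bpm (plateau ends at 100*x1 bpm, floor
             begins at 100*x2 bpm)
    m        mid-region slope magnitude; 0.4 means -0.4 ms/bpm
    c        low-rate plateau / 100 ms (AP-VS maximum)
    n        Butterworth order controlling corner sharpness (even)
    """

    x1: float = 1.225
    x2: float = 2.1
    m: float = 0.4
    c: float = 1.3
    n: int = 8

    def __post_init__(self) -> None:
        if self.x1 >= self.x2:
            raise ValueError("x1 must be below x2")
        if self.n <= 0 or self.n % 2:
            raise ValueError("n must be a positive even integer")
        if self.m <= 0:
            raise ValueError("slope m must be positive")
        if self.floor_ms <= 0:
            raise ValueError("derived minimum c - m*(x2 - x1) must be positive")

    @property
    def plateau_ms(self) -> float:
        """Low-rate AP-VS plateau, 100*c ms."""
        return 100.0 * self.c

    @property
    def floor_ms(self) -> float:
        """High-rate AP-VS asymptote, 100*(c - m*(x2 - x1)) ms."""
        return 100.0 * (self.c - self.m * (self.x2 - self.x1))

    @property
    def hr_low(self) -> float:
        """Rate (bpm) at which the plateau ends, 100*x1."""
        return 100.0 * self.x1

    @property
    def hr_high(self) -> float:
        """Rate (bpm) at which the floor is reached, 100*x2."""
        return 100.0 * self.x2


DEFAULT_PARAMS = IdealApVsParams()


def _log_magnitude_sum(x: np.ndarray, corner: float, q: np.ndarray) -> np.ndarray:
    # sum_i ln[(1 - e^{2(x - corner)})^2 + e^{2(x - corner)} / Q_i^2]
    e = np.exp(2.0 * (x - corner))
    return np.log((1.0 - e[..., None]) ** 2 + e[..., None] / q**2).sum(axis=-1)


def ideal_ap_vs(hr, params: IdealApVsParams = DEFAULT_PARAMS):
    """Smooth ideal AP-VS interval (ms, unrounded) at heart rate ``hr`` (bpm).

    Evaluates, with x = hr/100 and Q_i the Butterworth quality factors,

        y(x) = (m / 2n) * sum_i { ln[(1 - e^{2(x-x2)})^2 + e^{2(x-x2)}/Q_i^2]
                                 - ln[(1 - e^{2(x-x1)})^2 + e^{2(x-x1)}/Q_i^2] } + c

    and returns 100*y.  Accepts a scalar or array; natural logarithm and
    radians throughout.  The constant ``c`` enters once, outside the sum.
    """
    x = np.asarray(hr, dtype=float)
    if np.any(x <= 0):
        raise ValueError("heart rate must be positive")
    scalar = x.ndim == 0
    x = np.atleast_1d(x) / 100.0
    q = butterworth_q(params.n)
    y = (
        0.5
        * params.m
        / params.n
        * (_log_magnitude_sum(x, params.x2, q) - _log_magnitude_sum(x, params.x1, q))
        + params.c
    )
    out = 100.0 * y
    return float(out[0]) if scalar else out


def piecewise_ideal(hr, params: IdealApVsParams = DEFAULT_PARAMS):
    """Piecewise-linear ideal AP-VS: plateau, -m ms/bpm ramp, floor."""
    x = np.asarray(hr, dtype=float)
    if np.any(x <= 0):
        raise ValueError("heart rate must be positive")
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    out = np.where(
        x <= params.hr_low,
        params.plateau_ms,
        np.where(
            x >= params.hr_high,
            params.floor_ms,
            params.plateau_ms - params.m * (x - params.hr_low),
        ),
    )
    return float(out[0]) if scalar else out


@dataclass(frozen=True)
class AdaptiveSettings:
    """Device settings for the rate-adaptive mode.

    The effective PAVRP must leave a sensing window of at least
    ``min_sensing_window`` below the smallest ideal interval, i.e.
    pavrp + min_sensing_window <= floor of the ideal curve.
    """

    pavrp: float = 90.0
    min_sensing_window: float = 5.0
    band: SafetyBand = field(default_factory=SafetyBand)
    params: IdealApVsParams = DEFAULT_PARAMS

    def __post_init__(self) -> None:
        if self.pavrp < 0 or self.min_sensing_window < 0:
            raise ValueError("pavrp and min_sensing_window must be non-negative")
        if self.pavrp + self.min_sensing_window > self.params.floor_ms + 1e-9:
            raise ValueError(
                f"PAVRP {self.pavrp} ms + window {self.min_sensing_window} ms "
                f"exceeds the minimum ideal AP-VS {self.params.floor_ms:g} ms"
            )


@dataclass(frozen=True)
class SensingWindow:
    """Time left for ventricular sensing after the refractory period."""

    window_ms: float
    adequate: bool


def sensing_window(
    hr: float, settings: AdaptiveSettings = AdaptiveSettings(),
    params: IdealApVsParams | None = None,
) -> SensingWindow:
    """Ideal AP-VS minus the effective PAVRP; flagged when below minimum."""
    p = params or settings.params
    w = ideal_ap_vs(hr, p) - settings.pavrp
    return SensingWindow(float(w), bool(w >= settings.min_sensing_window))


@dataclass(frozen=True)
class Recommendation:
    ap_vs: float  # ms
    warnings: tuple[str, ...]


def recommend_interval(
    hr: float,
    mode: str = "formula",
    settings: AdaptiveSettings = AdaptiveSettings(),
    offset: float = 0.0,
    manual_value: float | None = None,
) -> Recommendation:
    """AP-VS recommendation with safety warnings, never hard failures.

    ``mode`` is ``'formula'`` (smooth curve), ``'piecewise'`` or ``'manual'``
    (requires ``manual_value``); ``offset`` is a clinician-chosen additive
    fine-tuning term applied after the curve value.  Warnings flag values
    outside the safety band and inadequate sensing windows.
    """
    mode = mode.lower()
    if mode == "formula":
        value = ideal_ap_vs(hr, settings.params)
    elif mode == "piecewise":
        value = piecewise_ideal(hr, settings.params)
    elif mode == "manual":
        if manual_value is None:
            raise ValueError("manual mode requires manual_value")
        value = float(manual_value)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    value = value + offset
    warnings = []
    cls = classify(value, settings.band) if value > 0 else Classification.TOO_SHORT
    if cls is not Classification.SAFE:
        warnings.append(
            f"{cls.value}: {value:.1f} ms outside safe band "
            f"[{settings.band.min_ap_vs:g}, {settings.band.max_ap_vs:g}] ms"
        )
    window = value - settings.pavrp
    if window < settings.min_sensing_window:
        warnings.append(
            f"SENSING_WINDOW: {window:.1f} ms < {settings.min_sensing_window:g} ms "
            f"after PAVRP {settings.pavrp:g} ms"
        )
    return Recommendation(float(value), tuple(warnings))
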