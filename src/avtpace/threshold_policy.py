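"""Safety-band classification and intervention-threshold analysis.

A junctional rate drifts while the VAI stays frozen at the value chosen for
the original rate; the AP-VS interval then shortens as the rate climbs and
lengthens as it falls.  This module classifies intervals against the safe
band (80-165 ms by default) and computes how far the rate may drift, in the
clinically used 5-bpm-up / 10-bpm-down increments, before the interval
leaves the band.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .device_core import (
    InfeasibleTimingError,
    Method,
    MethodUnavailableError,
    VaiMaxTable,
    ap_vs,
    ap_vs_for_method,
    method_mtr,
    round_half_up,
    vai_max,
)

__all__ = [
    "SafetyBand",
    "Classification",
    "ExcursionReport",
    "classify",
    "ap_vs_after_drift",
    "tolerated_excursion",
    "excursion_table",
]


@dataclass(frozen=True)
class SafetyBand:
    """Inclusive AP-VS safety band in ms.

    Intervals strictly below ``min_ap_vs`` risk atrial contraction against
    closed AV valves; intervals strictly above ``max_ap_vs`` risk
    pacemaker-induced tachycardia.  The endpoints themselves are safe.
    """

    min_ap_vs: float = 80.0
    max_ap_vs: float = 165.0

    def __post_init__(self) -> None:
        if not (0 < self.min_ap_vs < self.max_ap_vs):
            raise ValueError(
                f"need 0 < min < max, got [{self.min_ap_vs}, {self.max_ap_vs}]"
            )


class Classification(str, enum.Enum):
    TOO_SHORT = "TOO_SHORT"
    SAFE = "SAFE"
    TOO_LONG = "TOO_LONG"


def classify(ap_vs_ms: float, band: SafetyBand = SafetyBand()) -> Classification:
    """Classify an AP-VS interval against the safety band (endpoints safe)."""
    if ap_vs_ms <= 0:
        raise ValueError(f"AP-VS must be positive, got {ap_vs_ms} ms")
    if ap_vs_ms < band.min_ap_vs:
        return Classification.TOO_SHORT
    if ap_vs_ms > band.max_ap_vs:
        return Classification.TOO_LONG
    return Classification.SAFE


def ap_vs_after_drift(
    hr0: float,
    delta: float,
    method: Method | str,
    table: VaiMaxTable | None = None,
) -> float:
    """AP-VS at rate ``hr0 + delta`` with the VAI frozen at the hr0 setting."""
    vai = vai_max(method_mtr(hr0, method), table)
    return ap_vs(hr0 + delta, vai)


@dataclass(frozen=True)
class ExcursionReport:
    """How far the rate may drift from hr0 before the band is violated.

    Tolerances are quantised at the scan steps; the limiting intervals are
    the AP-VS values reached at the largest tolerated drift in each
    direction.  ``baseline_safe`` is False when hr0 itself already violates
    the band, in which case both tolerances are zero.
    """

    hr0: float
    method: Method
    vai_fixed: float
    tolerated_increase: float  # bpm
    tolerated_decrease: float  # bpm
    limiting_interval_up: float  # ms, at hr0 + tolerated_increase
    limiting_interval_down: float  # ms, at hr0 - tolerated_decrease
    baseline_safe: bool = True

    def to_dict(self) -> dict:
        return {
            "hr0_bpm": self.hr0,
            "method": self.method.value,
            "vai_fixed_ms": self.vai_fixed,
            "tolerated_increase_bpm": self.tolerated_increase,
            "tolerated_decrease_bpm": self.tolerated_decrease,
            "limiting_interval_up_ms": self.limiting_interval_up,
            "limiting_interval_down_ms": self.limiting_interval_down,
            "baseline_safe": self.baseline_safe,
        }


def tolerated_excursion(
    hr0: float,
    method: Method | str,
    band: SafetyBand = SafetyBand(),
    step_up: float = 5.0,
    step_down: float = 10.0,
    table: VaiMaxTable | None = None,
    max_steps: int = 200,
) -> ExcursionReport:
    """Largest tolerated rate excursion in each direction with a frozen VAI.

    Scans drifts ``+step_up, +2*step_up, ...`` until the interval leaves the
    band (or becomes infeasible), and ``-step_down, -2*step_down, ...``
    until it leaves the band (or the rate would become non-positive); the
    tolerated excursion is the last scanned drift with every intermediate
    multiple still safe.
    """
    method = Method.coerce(method)
    if step_up <= 0 or step_down <= 0:
        raise ValueError("steps must be positive")
    vai = float(vai_max(method_mtr(hr0, method), table))
    baseline = ap_vs(hr0, vai)
    if classify(baseline, band) is not Classification.SAFE:
        return ExcursionReport(
            hr0, method, vai, 0.0, 0.0, baseline, baseline, baseline_safe=False
        )

    def scan(step: float, sign: int) -> tuple[float, float]:
        tolerated, limiting = 0.0, baseline
        for k in range(1, max_steps + 1):
            delta = sign * k * step
            if hr0 + delta <= 0:
                break
            try:
                val = ap_vs(hr0 + delta, vai)
            except InfeasibleTimingError:
                break
            if classify(val, band) is not Classification.SAFE:
                break
            tolerated, limiting = k * step, val
        return tolerated, limiting

    up, lim_up = scan(step_up, +1)
    down, lim_down = scan(step_down, -1)
    return ExcursionReport(hr0, method, vai, up, down, lim_up, lim_down)


def excursion_table(
    hr0_list: Sequence[float],
    deltas: Sequence[float] = (0, 5, 10, -10, -20),
    methods: Iterable[Method | str] = (Method.M10, Method.M20),
    table: VaiMaxTable | None = None,
) -> pd.DataFrame:
    """AP-VS (integer ms) per (hr0, drift, method) with a frozen VAI.

    Cells where the recipe cannot be programmed at hr0 (e.g. M20 at
    220 bpm), or where the frozen VAI no longer fits the drifted cycle, are
    left missing and flagged in the ``note`` column rather than raising.
    """
    methods = [Method.coerce(m) for m in methods]
    rows = []
    for hr0 in hr0_list:
        for delta in deltas:
            for m in methods:
                row = {
                    "hr0_bpm": hr0,
                    "delta_bpm": delta,
                    "method": m.value,
                    "ap_vs_ms": pd.NA,
                    "note": "",
                }
                try:
                    row["ap_vs_ms"] = round_half_up(
                        ap_vs_after_drift(hr0, delta, m, table)
                    )
                except MethodUnavailableError:
                    row["note"] = "method unavailable"
                except (InfeasibleTimingError, ValueError):
                    row["note"] = "infeasible timing"
                rows.append(row)
    return pd.DataFrame(rows)
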