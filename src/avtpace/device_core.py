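"""Timing model of the inversely connected external dual-chamber pacemaker.

In AVT pacing (atrial pacing triggered by ventricular sensing) the pacing
wires of a commercial external dual-chamber pacemaker are connected
inversely: the device senses the junctional R wave on its atrial channel and
delivers the atrial stimulus through its ventricular output.  The programmed
AV-delay therefore acts as an effective *ventriculoatrial interval* (VAI),
and the clinically relevant interval between atrial pacing and the next
sensed ventricular event is

    AP-VS = cycle length - VAI,        cycle length = 60000 / HR.

The device does not expose the VAI directly; its maximum allowed duration is
capped by the programmed maximum tracking rate (MTR) through a fixed lookup
table (:class:`VaiMaxTable`).  The two conventional operating recipes, M10
and M20, set the MTR 10 or 20 bpm above the junctional rate and program the
VAI to that maximum.
"""

from __future__ import annotations

import csv
import enum
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

__all__ = [
    "MS_PER_MINUTE",
    "Method",
    "VaiMaxTable",
    "DeviceSettings",
    "InfeasibleTimingError",
    "MethodUnavailableError",
    "cycle_length",
    "vai_max",
    "ap_vs",
    "method_mtr",
    "ap_vs_for_method",
    "round_half_up",
    "default_table",
]

#: Single bpm <-> ms conversion constant used throughout the package.
MS_PER_MINUTE = 60000.0

#: MTR programming range of the modelled external pacemaker, in bpm.
MTR_DEVICE_MIN = 80
MTR_DEVICE_MAX = 230


class InfeasibleTimingError(ValueError):
    """The requested VAI does not fit into the tachycardia cycle length."""


class MethodUnavailableError(ValueError):
    """The M10/M20 recipe cannot be programmed at this junctional rate."""


class Method(str, enum.Enum):
    """Operating recipe for choosing the effective VAI."""

    M10 = "M10"  # MTR = HR + 10, VAI at its maximum allowed duration
    M20 = "M20"  # MTR = HR + 20, VAI at its maximum allowed duration
    MANUAL = "MANUAL"
    ADAPTIVE = "ADAPTIVE"

    @classmethod
    def coerce(cls, value: "Method | str") -> "Method":
        if isinstance(value, Method):
            return value
        return cls(str(value).upper())

    @property
    def mtr_offset(self) -> int:
        if self is Method.M10:
            return 10
        if self is Method.M20:
            return 20
        raise ValueError(f"{self.value} has no MTR offset")


def round_half_up(x: float) -> int:
    """Round to integer ms with ties away from zero-half (clinical tables)."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class VaiMaxTable:
    """MTR -> maximum effective ventriculoatrial interval lookup.

    The table is ordered by ascending MTR; ``vai_max`` is non-increasing in
    MTR.  For an MTR between two rows the lookup rounds *up* to the next
    tabulated MTR, returning the shorter (conservative) maximum so that a
    programmed VAI never exceeds a tabulated limit.
    """

    entries: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if len(self.entries) < 2:
            raise ValueError("table needs at least two rows")
        mtrs = [m for m, _ in self.entries]
        vais = [v for _, v in self.entries]
        if mtrs != sorted(mtrs) or len(set(mtrs)) != len(mtrs):
            raise ValueError("MTR column must be strictly increasing")
        if any(b > a for a, b in zip(vais, vais[1:])):
            raise ValueError("vai_max must be non-increasing with MTR")
        if any(v <= 0 for v in vais):
            raise ValueError("vai_max values must be positive")

    @property
    def mtr_min(self) -> int:
        return self.entries[0][0]

    @property
    def mtr_max(self) -> int:
        return self.entries[-1][0]

    def lookup(self, mtr: float) -> int:
        if not (self.mtr_min <= mtr <= self.mtr_max):
            raise ValueError(
                f"MTR {mtr} bpm outside table range "
                f"[{self.mtr_min}, {self.mtr_max}] bpm"
            )
        for row_mtr, row_vai in self.entries:
            if mtr <= row_mtr:
                return row_vai
        raise AssertionError("unreachable")  # guarded by the range check

    @classmethod
    def from_csv(cls, path_or_file) -> "VaiMaxTable":
        if hasattr(path_or_file, "read"):
            rows = list(csv.DictReader(path_or_file))
        else:
            with open(path_or_file, newline="") as fh:
                rows = list(csv.DictReader(fh))
        try:
            entries = tuple(
                sorted((int(r["mtr_bpm"]), int(r["vai_max_ms"])) for r in rows)
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(
                "VAI table CSV needs integer columns mtr_bpm, vai_max_ms"
            ) from exc
        return cls(entries)


_DEFAULT_TABLE: VaiMaxTable | None = None


def default_table() -> VaiMaxTable:
    """The 15-row lookup table shipped with the package (90-230 bpm)."""
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        ref = resources.files("avtpace.data").joinpath("vai_max_table.csv")
        with ref.open("r", newline="") as fh:
            _DEFAULT_TABLE = VaiMaxTable.from_csv(fh)
    return _DEFAULT_TABLE


def cycle_length(hr: float) -> float:
    """Cycle length in ms for a heart rate in bpm (60000 / HR, unrounded)."""
    if hr <= 0:
        raise ValueError(f"heart rate must be positive, got {hr} bpm")
    return MS_PER_MINUTE / hr


def vai_max(mtr: float, table: VaiMaxTable | None = None) -> int:
    """Maximum effective VAI (ms) allowed at a given MTR (bpm)."""
    return (table or default_table()).lookup(mtr)


def ap_vs(hr: float, vai: float) -> float:
    """AP-VS interval: cycle length minus the effective VAI, unrounded ms.

    Raises :class:`InfeasibleTimingError` if the VAI fills (or exceeds) the
    whole cycle, in which case the atrial stimulus could not precede the next
    ventricular event.
    """
    cl = cycle_length(hr)
    if vai < 0:
        raise ValueError(f"VAI must be non-negative, got {vai} ms")
    if vai >= cl:
        raise InfeasibleTimingError(
            f"VAI {vai} ms does not fit into the {cl:.1f} ms cycle at {hr} bpm"
        )
    return cl - vai


def method_mtr(hr: float, method: Method | str) -> float:
    """MTR programmed by recipe M10/M20 at junctional rate ``hr``."""
    if hr <= 0:
        raise ValueError(f"heart rate must be positive, got {hr} bpm")
    method = Method.coerce(method)
    mtr = hr + method.mtr_offset
    if mtr > MTR_DEVICE_MAX:
        raise MethodUnavailableError(
            f"{method.value} needs MTR {mtr:g} bpm but the device maximum is "
            f"{MTR_DEVICE_MAX} bpm (junctional rate {hr:g} bpm too high)"
        )
    table_min = default_table().mtr_min
    if mtr < table_min:
        raise MethodUnavailableError(
            f"{method.value} MTR {mtr:g} bpm is below the tabulated range "
            f"(>= {table_min} bpm)"
        )
    return mtr


def ap_vs_for_method(
    hr: float, method: Method | str, table: VaiMaxTable | None = None
) -> float:
    """AP-VS interval when the VAI sits at its maximum for recipe M10/M20."""
    mtr = method_mtr(hr, method)
    return ap_vs(hr, vai_max(mtr, table))


@dataclass(frozen=True)
class DeviceSettings:
    """The knobs a clinician programs on the external pacemaker.

    ``pavrp`` is the effective post-atrial ventricular refractory period: on
    the physical device it is the PVARP, which acts post-atrially because of
    the inverse wire connection.  Default 100 ms for the conventional
    configuration; the rate-adaptive proposal uses 90 ms.
    """

    mtr: float
    vai: float
    pavrp: float = 100.0
    method: Method = Method.MANUAL
    table: VaiMaxTable = field(default_factory=default_table)

    def __post_init__(self) -> None:
        if not (MTR_DEVICE_MIN <= self.mtr <= MTR_DEVICE_MAX):
            raise ValueError(
                f"MTR {self.mtr} bpm outside the device range "
                f"[{MTR_DEVICE_MIN}, {MTR_DEVICE_MAX}] bpm"
            )
        if self.vai <= 0:
            raise ValueError(f"VAI must be positive, got {self.vai} ms")
        if self.pavrp <= 0:
            raise ValueError(f"PAVRP must be positive, got {self.pavrp} ms")
        m = Method.coerce(self.method)
        object.__setattr__(self, "method", m)
        if m in (Method.M10, Method.M20):
            limit = self.table.lookup(self.mtr)
            if self.vai > limit:
                raise ValueError(
                    f"VAI {self.vai} ms exceeds the maximum {limit} ms "
                    f"allowed at MTR {self.mtr} bpm"
                )
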