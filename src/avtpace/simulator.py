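"""Beat-by-beat simulation of AVT pacing over a junctional rate trace.

The junctional focus is modelled as a pure rate source: ventricular events
occur at the instantaneous cycle length, with rate changes taking effect at
the next ventricular event.  Each beat, the atrial stimulus is scheduled
either a fixed VAI after the sensed R wave (M10/M20 policies, VAI frozen at
the value chosen for the starting rate) or so that the AP-VS interval equals
the rate-adaptive ideal (ADAPTIVE policy).  Every beat's interval is
classified against the safety band; with ``readjust='on_violation'`` a
fixed-VAI policy re-derives its VAI from the current rate at each unsafe
beat, mirroring a clinician reprogramming the device.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .device_core import (
    Method,
    MethodUnavailableError,
    VaiMaxTable,
    cycle_length,
    method_mtr,
    vai_max,
)
from .rate_adaptive import DEFAULT_PARAMS, IdealApVsParams, ideal_ap_vs
from .threshold_policy import Classification, SafetyBand, classify

__all__ = [
    "RateTrace",
    "BeatLog",
    "SimulationSummary",
    "generate_trace",
    "simulate",
    "summarise",
]

HR_MIN, HR_MAX = 60.0, 260.0

BEAT_COLUMNS = [
    "beat_index",
    "vs_time_ms",
    "ap_time_ms",
    "ap_vs_ms",
    "vai_ms",
    "classification",
    "event",
]


@dataclass(frozen=True)
class RateTrace:
    """Junctional rate as a right-continuous step function of time."""

    time_ms: np.ndarray
    hr_bpm: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time_ms, dtype=float)
        hr = np.asarray(self.hr_bpm, dtype=float)
        object.__setattr__(self, "time_ms", t)
        object.__setattr__(self, "hr_bpm", hr)
        if t.size == 0 or t.size != hr.size:
            raise ValueError("trace needs equal-length, non-empty columns")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any((hr < HR_MIN) | (hr > HR_MAX)):
            raise ValueError(f"rates must lie in [{HR_MIN:g}, {HR_MAX:g}] bpm")

    @property
    def duration_ms(self) -> float:
        return float(self.time_ms[-1] - self.time_ms[0])

    def rate_at(self, t: float) -> float:
        """Rate in effect at time t (last sample at or before t)."""
        idx = int(np.searchsorted(self.time_ms, t, side="right")) - 1
        return float(self.hr_bpm[max(idx, 0)])

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            fh.write(f"# avtpace {__version__} rate trace\n")
            pd.DataFrame({"time_ms": self.time_ms, "hr_bpm": self.hr_bpm}).to_csv(
                fh, index=False
            )

    @classmethod
    def from_csv(cls, path) -> "RateTrace":
        df = pd.read_csv(path, comment="#")
        return cls(df["time_ms"].to_numpy(), df["hr_bpm"].to_numpy())


def generate_trace(
    duration_ms: float,
    profile: str = "constant",
    seed: int | None = None,
    dt_ms: float = 500.0,
    hr: float = 200.0,
    hr_end: float | None = None,
    noise_sd: float = 6.0,
) -> RateTrace:
    """Seeded synthetic junctional-rate trace.

    Profiles: ``constant`` (rate ``hr`` throughout), ``ramp`` (linear from
    ``hr`` to ``hr_end``) and ``plateau_noise`` (rate ``hr`` plus white
    Gaussian jitter of SD ``noise_sd`` bpm, emulating the spontaneous rate
    wander of the arrhythmia).  Rates are clipped to [60, 260] bpm and the
    trace is reproducible for a fixed seed.
    """
    if duration_ms <= 0:
        raise ValueError("duration must be positive")
    if dt_ms <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(0.0, duration_ms + dt_ms / 2, dt_ms)
    if profile == "constant":
        rates = np.full(t.size, hr)
    elif profile == "ramp":
        if hr_end is None:
            raise ValueError("ramp profile requires hr_end")
        rates = np.linspace(hr, hr_end, t.size)
    elif profile == "plateau_noise":
        rng = np.random.default_rng(seed)
        rates = hr + rng.normal(0.0, noise_sd, t.size)
    else:
        raise ValueError(f"unknown profile {profile!r}")
    return RateTrace(t, np.clip(rates, HR_MIN, HR_MAX))


@dataclass(frozen=True)
class BeatLog:
    """Per-beat simulator output (one row per ventricular interval)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in BEAT_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"beat log missing columns {missing}")

    def __len__(self) -> int:
        return len(self.frame)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            fh.write(f"# avtpace {__version__} beat log\n")
            self.frame.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "BeatLog":
        return cls(pd.read_csv(path, comment="#"))


def simulate(
    trace: RateTrace,
    policy: Method | str,
    band: SafetyBand = SafetyBand(),
    readjust: str = "never",
    params: IdealApVsParams = DEFAULT_PARAMS,
    table: VaiMaxTable | None = None,
) -> BeatLog:
    """Run the beat-by-beat AVT simulation over a rate trace.

    ``policy`` is ``M10``/``M20`` (fixed VAI) or ``ADAPTIVE``; ``readjust``
    is ``'never'`` or ``'on_violation'`` (fixed policies only).  A fixed
    policy must be programmable at the starting rate; if a mid-run
    readjustment is impossible (e.g. M20 above 210 bpm) the beat is logged
    with an ``UNAVAILABLE`` event and left unpaced, and the simulation
    continues with the previous VAI thereafter.
    """
    policy = Method.coerce(policy)
    if readjust not in ("never", "on_violation"):
        raise ValueError("readjust must be 'never' or 'on_violation'")
    adaptive = policy is Method.ADAPTIVE
    t0 = float(trace.time_ms[0])
    end = float(trace.time_ms[-1])
    vai: float | None = None
    if not adaptive:
        vai = float(vai_max(method_mtr(trace.rate_at(t0), policy), table))

    rows = []
    t = t0
    k = 0
    unpaced_next = False
    while True:
        hr_now = trace.rate_at(t)
        cl = cycle_length(hr_now)
        t_next = t + cl
        if k > 0 and t_next > end:
            break
        event = "none"
        if adaptive:
            interval = float(ideal_ap_vs(hr_now, params))
            vai_eff = cl - interval
        else:
            vai_eff = vai
            interval = cl - vai
        if unpaced_next or interval <= 0:
            # no atrial stimulus this beat (readjustment unavailable or the
            # frozen VAI no longer fits the cycle)
            rows.append(
                [k, t_next, np.nan, np.nan, vai_eff, "", "UNAVAILABLE"]
            )
            unpaced_next = False
            t = t_next
            k += 1
            continue
        cls = classify(interval, band)
        if (
            not adaptive
            and readjust == "on_violation"
            and cls is not Classification.SAFE
        ):
            try:
                vai = float(vai_max(method_mtr(hr_now, policy), table))
                event = "READJUST"
            except MethodUnavailableError:
                unpaced_next = True
                event = "UNAVAILABLE"
        rows.append([k, t_next, t_next - interval, interval, vai_eff, cls.value, event])
        t = t_next
        k += 1

    frame = pd.DataFrame(rows, columns=BEAT_COLUMNS)
    return BeatLog(frame)


@dataclass(frozen=True)
class SimulationSummary:
    beats: int
    pct_safe: float
    readjust_count: int
    unavailable_count: int
    min_ap_vs: float
    max_ap_vs: float

    def to_dict(self) -> dict:
        return {
            "beats": self.beats,
            "pct_safe": self.pct_safe,
            "readjust_count": self.readjust_count,
            "unavailable_count": self.unavailable_count,
            "min_ap_vs_ms": self.min_ap_vs,
            "max_ap_vs_ms": self.max_ap_vs,
        }


def summarise(log: BeatLog) -> SimulationSummary:
    """Aggregate a beat log: counts, % safe beats, interval extremes."""
    if len(log) == 0:
        raise ValueError("empty beat log")
    f = log.frame
    paced = f[f["classification"].astype(str).isin([c.value for c in Classification])]
    n_safe = int((paced["classification"] == Classification.SAFE.value).sum())
    return SimulationSummary(
        beats=len(f),
        pct_safe=100.0 * n_safe / len(f),
        readjust_count=int((f["event"] == "READJUST").sum()),
        unavailable_count=int((f["event"] == "UNAVAILABLE").sum()),
        min_ap_vs=float(paced["ap_vs_ms"].min()) if len(paced) else float("nan"),
        max_ap_vs=float(paced["ap_vs_ms"].max()) if len(paced) else float("nan"),
    )
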