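"""YAML run configuration: all defaults live in code, config only overrides.

Schema (all keys optional)::

    table: path/to/vai_table.csv          # override the built-in MTR table
    band: {min_ap_vs: 80, max_ap_vs: 165}
    adaptive: {pavrp: 90, min_sensing_window: 5}
    params: {x1: 1.225, x2: 2.1, m: 0.4, c: 1.3, n: 8}
    regression_grid: {hr_min: 130, hr_max: 220, step: 10}
    output_dir: .
    seed: 0
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .device_core import VaiMaxTable, default_table
from .rate_adaptive import AdaptiveSettings, IdealApVsParams
from .threshold_policy import SafetyBand

__all__ = ["RunConfig", "parse_config"]


class ConfigError(ValueError):
    """Configuration file violates the schema; the message names the field."""


@dataclass(frozen=True)
class RunConfig:
    table: VaiMaxTable = field(default_factory=default_table)
    band: SafetyBand = field(default_factory=SafetyBand)
    adaptive: AdaptiveSettings = field(default_factory=AdaptiveSettings)
    params: IdealApVsParams = field(default_factory=IdealApVsParams)
    regression_grid: tuple[float, float, float] = (130.0, 220.0, 10.0)
    output_dir: Path = Path(".")
    seed: int = 0


_KNOWN_KEYS = {
    "table",
    "band",
    "adaptive",
    "params",
    "regression_grid",
    "output_dir",
    "seed",
}


def _sub(raw: dict, key: str, allowed: set[str]) -> dict:
    block = raw.get(key) or {}
    if not isinstance(block, dict):
        raise ConfigError(f"{key}: expected a mapping")
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"{key}: unknown field(s) {sorted(unknown)}")
    return block


def parse_config(path) -> RunConfig:
    """Parse and validate a YAML config file, filling defaults."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ConfigError("top level must be a mapping")
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"unknown top-level field(s) {sorted(unknown)}")

    if "table" in raw and raw["table"]:
        try:
            table = VaiMaxTable.from_csv(raw["table"])
        except (OSError, ValueError) as exc:
            raise ConfigError(f"table: {exc}") from exc
    else:
        table = default_table()

    try:
        band = SafetyBand(**_sub(raw, "band", {"min_ap_vs", "max_ap_vs"}))
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"band: {exc}") from exc

    try:
        params = IdealApVsParams(**_sub(raw, "params", {"x1", "x2", "m", "c", "n"}))
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"params: {exc}") from exc

    try:
        adaptive = AdaptiveSettings(
            band=band,
            params=params,
            **_sub(raw, "adaptive", {"pavrp", "min_sensing_window"}),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"adaptive: {exc}") from exc

    grid_block = _sub(raw, "regression_grid", {"hr_min", "hr_max", "step"})
    defaults = RunConfig()
    grid = (
        float(grid_block.get("hr_min", defaults.regression_grid[0])),
        float(grid_block.get("hr_max", defaults.regression_grid[1])),
        float(grid_block.get("step", defaults.regression_grid[2])),
    )
    if grid[0] >= grid[1] or grid[2] <= 0:
        raise ConfigError("regression_grid: need hr_min < hr_max and step > 0")

    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        raise ConfigError("seed: must be an integer")

    return RunConfig(
        table=table,
        band=band,
        adaptive=adaptive,
        params=params,
        regression_grid=grid,
        output_dir=Path(raw.get("output_dir", ".")),
        seed=seed,
    )
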