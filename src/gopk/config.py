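"""Structured run configuration for the command-line pipeline.

A single YAML (or JSON) file drives every stage.  All sections are
optional; omitted values fall back to the reported population estimates.
Unknown keys anywhere in the file are rejected, so typos fail loudly.

Example::

    seed: 1
    cell: {R_p: 279.0, k_d: 0.34}
    systemic: {k: 0.01919, V: 6.2}
    blasts: {N_0: 2.47e12, alpha: 0.104}
    schedule:
      - {day: 1, dose: 6.0}
      - {day: 8, dose: 3.0}
    horizon_hours: 672
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import yaml

from .model import DEFAULT_HORIZON_HOURS
from .params import (
    BlastDynamics,
    CellKineticParams,
    CLINICAL_BLASTS,
    CLINICAL_MEAN_PARAMS,
    CLINICAL_SYSTEMIC,
    DoseSchedule,
    SystemicParams,
)

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    """Raised when a run-configuration file is malformed."""


def _merge_dataclass(default, overrides: Optional[dict], section: str):
    if overrides is None:
        return default
    if not isinstance(overrides, dict):
        raise ConfigError(f"section {section!r} must be a mapping")
    valid = {f.name for f in dataclasses.fields(default)}
    unknown = set(overrides) - valid
    if unknown:
        raise ConfigError(
            f"unknown keys in section {section!r}: {sorted(unknown)}"
        )
    return dataclasses.replace(default, **{k: float(v) for k, v in overrides.items()})


def _parse_schedule(raw, section: str = "schedule") -> DoseSchedule:
    if raw is None:
        return DoseSchedule.single(9.0)
    if not isinstance(raw, list) or not raw:
        raise ConfigError(f"section {section!r} must be a non-empty list")
    events = []
    for item in raw:
        if not isinstance(item, dict):
            raise ConfigError(f"{section!r} entries must be mappings")
        unknown = set(item) - {"day", "start_hour", "dose", "duration"}
        if unknown:
            raise ConfigError(f"unknown keys in {section!r} entry: {sorted(unknown)}")
        if "dose" not in item:
            raise ConfigError(f"{section!r} entries need a 'dose' (mg/m²)")
        if ("day" in item) == ("start_hour" in item):
            raise ConfigError(
                f"{section!r} entries need exactly one of 'day' or 'start_hour'"
            )
        start = (
            24.0 * (float(item["day"]) - 1.0)
            if "day" in item
            else float(item["start_hour"])
        )
        events.append((start, float(item["dose"]), float(item.get("duration", 2.0))))
    try:
        return DoseSchedule(events=tuple(events))
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration shared by all CLI commands."""

    cell: CellKineticParams = CLINICAL_MEAN_PARAMS
    systemic: SystemicParams = CLINICAL_SYSTEMIC
    blasts: BlastDynamics = CLINICAL_BLASTS
    schedule: DoseSchedule = DoseSchedule.single(9.0)
    horizon_hours: float = DEFAULT_HORIZON_HOURS
    rtol: float = 1e-8
    seed: int = 0
    sweep_factors: int = 25
    cohort_n: int = 100

    _TOP_KEYS = (
        "cell",
        "systemic",
        "blasts",
        "schedule",
        "horizon_hours",
        "rtol",
        "seed",
        "sweep_factors",
        "cohort_n",
    )

    @classmethod
    def from_mapping(cls, raw: Optional[dict]) -> "RunConfig":
        raw = raw or {}
        if not isinstance(raw, dict):
            raise ConfigError("configuration root must be a mapping")
        unknown = set(raw) - set(cls._TOP_KEYS)
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        try:
            return cls(
                cell=_merge_dataclass(CLINICAL_MEAN_PARAMS, raw.get("cell"), "cell"),
                systemic=_merge_dataclass(
                    CLINICAL_SYSTEMIC, raw.get("systemic"), "systemic"
                ),
                blasts=_merge_dataclass(CLINICAL_BLASTS, raw.get("blasts"), "blasts"),
                schedule=_parse_schedule(raw.get("schedule")),
                horizon_hours=float(raw.get("horizon_hours", DEFAULT_HORIZON_HOURS)),
                rtol=float(raw.get("rtol", 1e-8)),
                seed=int(raw.get("seed", 0)),
                sweep_factors=int(raw.get("sweep_factors", 25)),
                cohort_n=int(raw.get("cohort_n", 100)),
            )
        except (TypeError, ValueError) as exc:
            if isinstance(exc, ConfigError):
                raise
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            raw = json.loads(text)
        else:
            raw = yaml.safe_load(text)
        return cls.from_mapping(raw)
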