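"""Readers/writers and run configuration shared by the CLI pipeline.

Every output embeds a short hash of the resolved run configuration and the
per-parameter provenance of the chemical inputs, so any number in a results
directory is traceable to the inputs that produced it.  Numeric output uses
6 significant digits.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .physiology import DosingSchedule

__all__ = ["RunConfig", "config_hash", "write_timeseries_csv", "write_json", "sig6"]

FLOAT_FORMAT = "%.6g"


def sig6(x: float) -> float:
    """Round to the 6 significant digits used in all file output."""
    return float(f"{x:.6g}")


def config_hash(payload: Any) -> str:
    """Short stable hash of a JSON-serializable configuration."""
    canon = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


@dataclass
class RunConfig:
    """Resolved configuration for one pipeline invocation."""

    chemicals: str
    assays: str | None = None
    exposures: str | None = None
    physiology: str = "human_70kg"
    schedule: str = "oral:1mg/kg@1h x24"
    fabs: float = 1.0
    ka: float | None = None  # None -> schedule default
    duration: float | None = None
    group: str | None = None
    outdir: str = "results"
    ead_stat: str = "median"

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config key(s) {sorted(unknown)} in {path}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def hash(self) -> str:
        return config_hash(self.to_dict())


def _schedule_dict(schedule: DosingSchedule) -> dict:
    return {
        "route": schedule.route,
        "dose_per_admin_mg_per_kg": schedule.dose_per_admin,
        "interval_h": schedule.interval,
        "n_doses": schedule.n_doses,
        "fabs": schedule.fabs,
        "ka_per_h": schedule.ka,
    }


def write_timeseries_csv(result, path) -> None:
    """Write the dense time-series to CSV with the documented fixed layout
    (``time_h,plasma_ven_uM,...,a_feces_umol``) at 6 significant digits."""
    result.to_frame().to_csv(path, index=False, float_format=FLOAT_FORMAT)


def _round_floats(obj):
    if isinstance(obj, float):
        return sig6(obj)
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    if isinstance(obj, DosingSchedule):
        return _round_floats(_schedule_dict(obj))
    return obj


def write_json(payload: dict, path) -> None:
    Path(path).write_text(json.dumps(_round_floats(payload), indent=2, default=str) + "\n")
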