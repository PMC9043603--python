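"""Species physiology and dosing schedules.

Volumes are litres, flows are *plasma* flows in L/h, masses in grams.  The
flow-balance invariant (cardiac output = hepatic artery + gut + kidney +
rest inflows; the liver drains the hepatic artery plus the gut outflow) is
validated on construction, so an inconsistent physiology never reaches the
solver.
"""

from __future__ import annotations

import copy
import dataclasses
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "TissueSpec",
    "Physiology",
    "DosingSchedule",
    "default_human",
    "load_physiology",
    "parse_schedule",
    "DEFAULT_KA_PER_H",
]

#: Default first-order gut absorption rate, 1/h (convention of the
#: generalized model family this package follows).
DEFAULT_KA_PER_H = 2.18

MODEL_TISSUES = ("gut", "liver", "kidney", "rest")


@dataclass(frozen=True)
class TissueSpec:
    volume_L: float
    flow_L_per_h: float


@dataclass
class Physiology:
    """Whole-body physiology for the lumped-compartment PBPK model.

    ``tissues['liver'].flow_L_per_h`` is the hepatic-artery plasma flow; the
    total liver perfusion is hepatic artery + gut (portal) outflow.
    """

    species: str = "human"
    bw: float = 70.0  # kg
    tissues: dict[str, TissueSpec] = field(default_factory=dict)
    v_ven: float = 2.25  # venous plasma, L
    v_art: float = 0.75  # arterial plasma, L
    q_cardiac: float = 191.0  # total plasma flow, L/h
    gfr: float = 6.7  # glomerular filtration, L/h
    hepatocellularity: float = 110.0  # 10^6 cells / g liver
    liver_mass: float = 1820.0  # g

    def __post_init__(self) -> None:
        self.validate()

    @property
    def q_hepatic_artery(self) -> float:
        return self.tissues["liver"].flow_L_per_h

    @property
    def q_liver_total(self) -> float:
        """Total liver perfusion: hepatic artery + portal (gut) outflow."""
        return self.q_hepatic_artery + self.tissues["gut"].flow_L_per_h

    def validate(self) -> None:
        missing = [t for t in MODEL_TISSUES if t not in self.tissues]
        if missing:
            raise ValueError(f"physiology missing tissue block(s) {missing}")
        for name, spec in self.tissues.items():
            if spec.volume_L <= 0 or spec.flow_L_per_h <= 0:
                raise ValueError(f"tissue {name!r}: volume and flow must be > 0")
        for label in ("bw", "v_ven", "v_art", "q_cardiac", "hepatocellularity", "liver_mass"):
            if getattr(self, label) <= 0:
                raise ValueError(f"{label} must be > 0")
        if self.gfr < 0:
            raise ValueError("gfr must be >= 0")
        arterial_supply = self.q_hepatic_artery + sum(
            self.tissues[t].flow_L_per_h for t in ("gut", "kidney", "rest")
        )
        if not np.isclose(arterial_supply, self.q_cardiac, rtol=1e-6):
            raise ValueError(
                "flow balance violated: hepatic artery + gut + kidney + rest = "
                f"{arterial_supply} L/h but q_cardiac = {self.q_cardiac} L/h"
            )

    def copy(self) -> "Physiology":
        return copy.deepcopy(self)

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "body_weight_kg": self.bw,
            "tissues": {
                name: {"volume_L": spec.volume_L, "flow_L_per_h": spec.flow_L_per_h}
                for name, spec in self.tissues.items()
            },
            "venous_plasma_volume_L": self.v_ven,
            "arterial_plasma_volume_L": self.v_art,
            "cardiac_plasma_flow_L_per_h": self.q_cardiac,
            "gfr_L_per_h": self.gfr,
            "hepatocellularity_1e6_per_g": self.hepatocellularity,
            "liver_mass_g": self.liver_mass,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Physiology":
        tissues = {
            name: TissueSpec(block["volume_L"], block["flow_L_per_h"])
            for name, block in d["tissues"].items()
        }
        return cls(
            species=d.get("species", "human"),
            bw=d["body_weight_kg"],
            tissues=tissues,
            v_ven=d["venous_plasma_volume_L"],
            v_art=d["arterial_plasma_volume_L"],
            q_cardiac=d["cardiac_plasma_flow_L_per_h"],
            gfr=d["gfr_L_per_h"],
            hepatocellularity=d["hepatocellularity_1e6_per_g"],
            liver_mass=d["liver_mass_g"],
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def default_human() -> Physiology:
    """The shipped reference-human (70 kg) physiology."""
    text = resources.files("revdosim.data").joinpath("human_70kg.yaml").read_text()
    return Physiology.from_dict(yaml.safe_load(text))


def load_physiology(spec: str | Path) -> Physiology:
    """Load a physiology by shipped id (``human_70kg``) or YAML file path."""
    if str(spec) == "human_70kg":
        return default_human()
    path = Path(spec)
    if not path.exists():
        raise FileNotFoundError(f"physiology {spec!r}: not a shipped id or readable file")
    return Physiology.from_dict(yaml.safe_load(path.read_text()))


@dataclass(frozen=True)
class DosingSchedule:
    """A repeated-bolus dosing schedule.

    ``fabs`` is the oral fraction absorbed; the default of 1 is the
    conservative 100%-absorption screening convention.  ``ka`` is the
    first-order gut-lumen absorption rate in 1/h.
    """

    route: str  # "oral" | "iv"
    dose_per_admin: float  # mg/kg
    interval: float  # h
    n_doses: int
    fabs: float = 1.0
    ka: float = DEFAULT_KA_PER_H

    def __post_init__(self) -> None:
        if self.route not in ("oral", "iv"):
            raise ValueError(f"route must be 'oral' or 'iv', got {self.route!r}")
        if self.interval <= 0:
            raise ValueError("interval must be > 0")
        if self.n_doses < 1:
            raise ValueError("n_doses must be >= 1")
        if self.dose_per_admin < 0:
            raise ValueError("dose_per_admin must be >= 0")
        if not 0.0 < self.fabs <= 1.0:
            raise ValueError("fabs must be in (0, 1]")
        if self.ka <= 0:
            raise ValueError("ka must be > 0")

    @property
    def dose_times(self) -> np.ndarray:
        """Administration times in hours, starting at t = 0."""
        return np.arange(self.n_doses) * self.interval

    @property
    def total_daily_dose(self) -> float:
        """mg/kg administered per 24 h if the schedule is sustained."""
        return self.dose_per_admin * 24.0 / self.interval

    def with_dose(self, dose_per_admin: float) -> "DosingSchedule":
        return dataclasses.replace(self, dose_per_admin=dose_per_admin)


_SCHEDULE_RE = re.compile(
    r"^\s*(?P<route>oral|iv)\s*:\s*(?P<dose>[0-9.eE+-]+)\s*mg/kg\s*"
    r"@\s*(?P<interval>[0-9.eE+-]+)\s*h\s*(?:x\s*(?P<n>\d+))?\s*$"
)


def parse_schedule(text: str, fabs: float = 1.0, ka: float = DEFAULT_KA_PER_H) -> DosingSchedule:
    """Parse the schedule mini-grammar ``route:DOSEmg/kg@INTERVALh xN``.

    Example: ``oral:1mg/kg@1h x24`` is an hourly 1 mg/kg oral bolus given
    24 times.  ``xN`` defaults to 1.
    """
    m = _SCHEDULE_RE.match(text)
    if m is None:
        raise ValueError(
            f"cannot parse schedule {text!r}; expected e.g. 'oral:1mg/kg@1h x24'"
        )
    return DosingSchedule(
        route=m["route"],
        dose_per_admin=float(m["dose"]),
        interval=float(m["interval"]),
        n_doses=int(m["n"] or 1),
        fabs=fabs,
        ka=ka,
    )
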