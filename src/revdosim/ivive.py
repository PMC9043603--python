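"""Reverse dosimetry: Cmax-based EADs and margin-of-exposure screening.

The equivalent administered dose (EAD) maps an in vitro bioactivity
concentration (AC50, µM) to the external dose whose predicted venous-plasma
Cmax reaches it.  Because every process in the PK model is first order,
Cmax scales linearly with dose, so a single unit-dose simulation
(1 mg/kg per administration, under the user's schedule) suffices:

    EAD [mg/kg/day] = AC50 / Cmax(1 mg/kg per administration)

The dosing schedule used is recorded with every result because the
unit-dose Cmax — and hence every EAD — depends on dosing frequency.
The margin of exposure (MoE) divides an EAD summary statistic (median by
default) by an expected daily exposure; small MoEs flag priority chemicals.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chem import ChemicalProfile
from .pbpk import build_model, cmax, simulate
from .physiology import DosingSchedule, Physiology

__all__ = [
    "AssayRecord",
    "EADResult",
    "MoEResult",
    "read_assay_table",
    "read_exposure_table",
    "unit_dose_cmax",
    "compute_ead",
    "summarize_eads",
    "margin_of_exposure",
    "rank_chemicals",
]

#: Accepted AC50 units and their conversion factors to µM.
AC50_UNIT_TO_UM = {"uM": 1.0, "nM": 1e-3, "M": 1e6}


@dataclass(frozen=True)
class AssayRecord:
    """One curated HTS assay result for one chemical (AC50 in µM)."""

    casrn: str
    assay_id: str
    group: str
    ac50: float
    active: bool = True

    def __post_init__(self) -> None:
        if self.active and not self.ac50 > 0:
            raise ValueError(
                f"{self.casrn}/{self.assay_id}: active record requires ac50 > 0"
            )


@dataclass
class EADResult:
    """Per-assay EADs and their summary for one chemical under one schedule."""

    casrn: str
    schedule: DosingSchedule
    cmax_unit: float  # µM at 1 mg/kg per administration
    per_assay: list[tuple[str, float, float]]  # (assay_id, ac50 µM, ead mg/kg/day)
    summary: dict[str, float] = field(default_factory=dict)

    @property
    def median_ead(self) -> float:
        return self.summary["median"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.per_assay, columns=["assay_id", "ac50_uM", "ead_mg_per_kg_day"])


@dataclass(frozen=True)
class MoEResult:
    """Margin of exposure for one chemical: EAD statistic / daily exposure."""

    casrn: str
    ead_stat: str  # label of the EAD summary statistic used
    ead: float  # mg/kg/day
    exposure: float  # mg/kg/day
    moe: float  # dimensionless


def read_assay_table(path, group: str | None = None) -> list[AssayRecord]:
    """Read the assay CSV (``casrn,assay_id,group,ac50,ac50_units,active``),
    normalizing AC50s to µM and optionally filtering to one annotation group."""
    df = pd.read_csv(path)
    records: list[AssayRecord] = []
    for row in df.itertuples(index=False):
        units = getattr(row, "ac50_units", "uM")
        if units not in AC50_UNIT_TO_UM:
            raise ValueError(f"unknown AC50 unit {units!r} (expected one of {list(AC50_UNIT_TO_UM)})")
        if group is not None and row.group != group:
            continue
        records.append(
            AssayRecord(
                casrn=str(row.casrn),
                assay_id=str(row.assay_id),
                group=str(row.group),
                ac50=float(row.ac50) * AC50_UNIT_TO_UM[units],
                active=bool(row.active),
            )
        )
    return records


def read_exposure_table(path) -> dict[str, float]:
    """Read the exposure CSV (``casrn,exposure_mg_per_kg_day[,percentile_label]``)."""
    df = pd.read_csv(path)
    return {str(r.casrn): float(r.exposure_mg_per_kg_day) for r in df.itertuples(index=False)}


def unit_dose_cmax(
    profile: ChemicalProfile,
    physiology: Physiology,
    schedule: DosingSchedule,
    duration: float | None = None,
) -> float:
    """Venous-plasma Cmax (µM) over the full window for the user's schedule
    run at 1 mg/kg per administration."""
    unit_schedule = schedule.with_dose(1.0)
    result = simulate(build_model(profile, physiology, unit_schedule), duration=duration)
    value, _ = cmax(result, "plasma_ven", window="full")
    return value


def compute_ead(ac50: float, cmax_unit: float) -> float:
    """EAD in mg/kg/day: AC50 divided by the unit-dose Cmax."""
    if not ac50 > 0:
        raise ValueError(f"ac50 must be > 0, got {ac50}")
    if not cmax_unit > 0:
        raise ValueError(f"cmax_unit must be > 0, got {cmax_unit}")
    return ac50 / cmax_unit * 1.0


def summarize_eads(
    records: Iterable[AssayRecord],
    cmax_unit: float,
    schedule: DosingSchedule | None = None,
    casrn: str | None = None,
) -> EADResult | None:
    """Per-assay EADs and summary statistics for one chemical's assay set.

    Inactive records are excluded.  The median uses the midpoint-of-two
    convention for even counts; quartiles are linearly interpolated.
    Returns ``None`` (a distinct no-data signal, not an error) when no
    active record remains.
    """
    active = [r for r in records if r.active]
    if not active:
        return None
    if casrn is None:
        casrn = active[0].casrn
    per_assay = [(r.assay_id, r.ac50, compute_ead(r.ac50, cmax_unit)) for r in active]
    eads = np.array([e for _, _, e in per_assay])
    summary = {
        "n": float(len(eads)),
        "median": float(np.median(eads)),
        "q1": float(np.percentile(eads, 25)),
        "q3": float(np.percentile(eads, 75)),
        "min": float(eads.min()),
        "max": float(eads.max()),
    }
    if schedule is None:
        schedule = DosingSchedule(route="oral", dose_per_admin=1.0, interval=1.0, n_doses=24)
    return EADResult(
        casrn=casrn, schedule=schedule, cmax_unit=cmax_unit,
        per_assay=per_assay, summary=summary,
    )


def margin_of_exposure(ead: float, exposure: float) -> float:
    """Margin of exposure: EAD (mg/kg/day) over expected exposure (mg/kg/day)."""
    if not exposure > 0:
        raise ValueError(f"exposure must be > 0, got {exposure}")
    return ead / exposure


def rank_chemicals(moe_results: Sequence[MoEResult]) -> list[MoEResult]:
    """Stable ascending sort by MoE: the smallest margins (highest screening
    priority) come first; ties preserve input order."""
    if not moe_results:
        raise ValueError("no MoE results to rank")
    return sorted(moe_results, key=lambda r: r.moe)
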