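"""Chemical parameter model: provenance resolution, ionization, clearance
scaling, and tissue:plasma partition coefficients.

A :class:`ChemicalProfile` holds the chemical-specific physicochemical and
ADME quantities a generalized PBPK model needs (molecular weight, logP,
dissociation constants, plasma fraction unbound, intrinsic hepatic
clearance), each tagged with its provenance (``measured``, ``predicted`` or
``default``).  The resolution policy mirrors common screening practice:
prefer experimentally measured values where available and fall back to
in-silico (QSAR) predictions otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "TissueComposition",
    "ChemicalProfile",
    "ParameterResolutionError",
    "resolve_parameters",
    "read_chemical_table",
    "scale_intrinsic_clearance",
    "neutral_fraction",
    "total_neutral_fraction",
    "calc_partition_coefficients",
    "DEFAULT_TISSUE_COMPOSITIONS",
    "PLASMA_COMPOSITION",
]

#: Preference order used when several sources report the same parameter.
DEFAULT_SOURCE_POLICY: tuple[str, ...] = ("measured", "predicted", "default")

#: Parameters that must be present (from any source) for a usable profile.
REQUIRED_PARAMETERS: tuple[str, ...] = ("mw", "fub", "clint")

#: Documented fallbacks applied when neither a measured nor a predicted
#: candidate exists.  Only the blood:plasma ratio has a model-level default;
#: the oral fraction absorbed lives on the dosing schedule (default 1,
#: the conservative 100%-absorption convention).
PARAMETER_DEFAULTS: Mapping[str, float] = {"rb2p": 1.0}


class ParameterResolutionError(ValueError):
    """A chemical is missing a required parameter from every source."""


@dataclass(frozen=True)
class TissueComposition:
    """Bulk composition of a tissue as volume fractions.

    ``f_water`` + ``f_neutral_lipid`` + ``f_phospholipid`` must not exceed 1;
    the remainder is treated as partition-inert solids.
    """

    f_water: float
    f_neutral_lipid: float
    f_phospholipid: float

    def __post_init__(self) -> None:
        for name in ("f_water", "f_neutral_lipid", "f_phospholipid"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        total = self.f_water + self.f_neutral_lipid + self.f_phospholipid
        if total > 1.0 + 1e-9:
            raise ValueError(f"composition fractions sum to {total} > 1")


#: Reference-human tissue compositions (volume fractions of water, neutral
#: lipid and phospholipid) for the lumped compartments of the model.
DEFAULT_TISSUE_COMPOSITIONS: Mapping[str, TissueComposition] = {
    "gut": TissueComposition(0.718, 0.0487, 0.0163),
    "liver": TissueComposition(0.745, 0.0348, 0.0252),
    "kidney": TissueComposition(0.783, 0.0207, 0.0162),
    # rest-of-body lumps muscle, skin, bone and adipose; the adipose share
    # raises its neutral-lipid fraction well above the lean-tissue values
    "rest": TissueComposition(0.700, 0.0600, 0.0070),
}

PLASMA_COMPOSITION = TissueComposition(0.945, 0.0023, 0.0013)


@dataclass
class ChemicalProfile:
    """Resolved, model-ready chemical parameters with provenance.

    Parameters
    ----------
    mw : molecular weight, g/mol.
    logp : log10 octanol-water partition coefficient. ``None`` is allowed
        only when every model tissue has a direct ``kp_overrides`` entry.
    pka : sequence of ``(value, kind)`` with kind ``"acid"`` or ``"base"``;
        empty for neutral chemicals.
    fub : fraction unbound in plasma, in (0, 1].
    clint : intrinsic hepatic clearance, µL/min per 10^6 hepatocytes.
    rb2p : blood:plasma concentration ratio (stored; the model reports
        venous plasma and defaults this ratio to 1).
    kp_overrides : direct tissue:plasma partition coefficients that take
        precedence over the volume-fraction calculation.
    provenance : parameter name -> {"measured", "predicted", "default"}.
    """

    name: str
    casrn: str
    mw: float
    fub: float
    clint: float
    logp: float | None = None
    pka: Sequence[tuple[float, str]] = ()
    rb2p: float = 1.0
    kp_overrides: dict[str, float] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.mw <= 0:
            raise ValueError(f"{self.casrn}: mw must be > 0, got {self.mw}")
        if not 0.0 < self.fub <= 1.0:
            raise ValueError(f"{self.casrn}: fub must be in (0, 1], got {self.fub}")
        if self.clint < 0:
            raise ValueError(f"{self.casrn}: clint must be >= 0, got {self.clint}")
        if self.rb2p <= 0:
            raise ValueError(f"{self.casrn}: rb2p must be > 0, got {self.rb2p}")
        for tissue, kp in self.kp_overrides.items():
            if kp <= 0:
                raise ValueError(f"{self.casrn}: kp override for {tissue} must be > 0")
        for value, kind in self.pka:
            if kind not in ("acid", "base"):
                raise ValueError(f"{self.casrn}: unknown pKa kind {kind!r}")
            float(value)


def resolve_parameters(
    raw_records: pd.DataFrame | Iterable[Mapping] | ChemicalProfile,
    policy: Sequence[str] = DEFAULT_SOURCE_POLICY,
) -> ChemicalProfile:
    """Resolve per-parameter candidate values into a :class:`ChemicalProfile`.

    ``raw_records`` holds one row per (parameter, source) candidate with
    columns ``casrn, name, parameter, value, source`` (``units`` is carried
    but not interpreted here; the canonical units are documented on the
    profile fields).  For each parameter the first source present in
    ``policy`` order wins; parameters absent from every source fall back to
    :data:`PARAMETER_DEFAULTS` where one exists.

    Resolution is idempotent: passing an already-resolved
    :class:`ChemicalProfile` returns it unchanged.
    """
    if isinstance(raw_records, ChemicalProfile):
        return raw_records
    df = pd.DataFrame(raw_records)
    if df.empty:
        raise ParameterResolutionError("no parameter records supplied")
    required_cols = {"parameter", "value", "source"}
    missing_cols = required_cols - set(df.columns)
    if missing_cols:
        raise ParameterResolutionError(f"parameter table missing columns {sorted(missing_cols)}")

    casrn = str(df["casrn"].iloc[0]) if "casrn" in df.columns else ""
    name = str(df["name"].iloc[0]) if "name" in df.columns else casrn

    chosen: dict[str, float] = {}
    provenance: dict[str, str] = {}
    pka: list[tuple[float, str]] = []
    kp_overrides: dict[str, float] = {}

    for parameter, group in df.groupby("parameter", sort=False):
        sources = dict(zip(group["source"], group["value"]))
        unknown = set(sources) - set(policy)
        if unknown:
            raise ParameterResolutionError(
                f"{casrn}: unknown source(s) {sorted(unknown)} for parameter {parameter!r}"
            )
        for source in policy:
            if source in sources:
                value = float(sources[source])
                break
        else:  # pragma: no cover - groupby yields non-empty groups
            continue
        parameter = str(parameter)
        if parameter.startswith("kp_"):
            kp_overrides[parameter[3:]] = value
            provenance[parameter] = source
        elif parameter in ("pka_acid", "pka_base"):
            pka.append((value, parameter.removeprefix("pka_")))
            provenance[parameter] = source
        else:
            chosen[parameter] = value
            provenance[parameter] = source

    for parameter, default in PARAMETER_DEFAULTS.items():
        if parameter not in chosen:
            chosen[parameter] = default
            provenance[parameter] = "default"

    missing = [p for p in REQUIRED_PARAMETERS if p not in chosen]
    if missing:
        raise ParameterResolutionError(
            f"chemical {name or casrn!r} ({casrn}): no candidate of any source for "
            f"required parameter(s) {missing}"
        )

    return ChemicalProfile(
        name=name,
        casrn=casrn,
        mw=chosen["mw"],
        fub=chosen["fub"],
        clint=chosen["clint"],
        logp=chosen.get("logp"),
        pka=tuple(pka),
        rb2p=chosen["rb2p"],
        kp_overrides=kp_overrides,
        provenance=provenance,
    )


def read_chemical_table(path) -> dict[str, ChemicalProfile]:
    """Read the chemical parameter CSV (one row per chemical/parameter/source)
    and resolve every chemical, keyed by CASRN."""
    df = pd.read_csv(path)
    profiles: dict[str, ChemicalProfile] = {}
    for casrn, group in df.groupby("casrn", sort=False):
        profiles[str(casrn)] = resolve_parameters(group)
    return profiles


def scale_intrinsic_clearance(
    clint: float, hepatocellularity: float, liver_mass: float
) -> float:
    """Scale per-cell intrinsic clearance to the whole liver.

    ``clint`` in µL/min per 10^6 hepatocytes, ``hepatocellularity`` in
    10^6 cells per gram liver, ``liver_mass`` in grams; returns L/h.
    """
    for label, v in (("clint", clint), ("hepatocellularity", hepatocellularity),
                     ("liver_mass", liver_mass)):
        if v < 0:
            raise ValueError(f"{label} must be >= 0, got {v}")
    return clint * hepatocellularity * liver_mass * 60.0 * 1e-6


def neutral_fraction(pka: float, kind: str, ph: float) -> float:
    """Henderson-Hasselbalch neutral fraction of a monoprotic group at ``ph``."""
    if kind == "acid":
        return 1.0 / (1.0 + 10.0 ** (ph - pka))
    if kind == "base":
        return 1.0 / (1.0 + 10.0 ** (pka - ph))
    raise ValueError(f"unknown ionization kind {kind!r} (expected 'acid' or 'base')")


def total_neutral_fraction(pka: Sequence[tuple[float, str]], ph: float) -> float:
    """Neutral fraction of a (possibly multiprotic) chemical: the product of
    per-group neutral fractions; 1 for chemicals without ionizable groups."""
    f = 1.0
    for value, kind in pka:
        f *= neutral_fraction(value, kind, ph)
    return f


def calc_partition_coefficients(
    profile: ChemicalProfile,
    compositions: Mapping[str, TissueComposition] | None = None,
    plasma: TissueComposition = PLASMA_COMPOSITION,
    ph: float = 7.4,
    tissues: Sequence[str] | None = None,
) -> dict[str, float]:
    """Tissue:plasma partition coefficients from tissue composition.

    Uses a Poulin-Theil-style volume-fraction model on the effective
    (ionization-corrected) octanol-water partition coefficient
    ``P = 10**logp * f_neutral(pH 7.4)``::

        Kp_t = [P*(f_nl_t + 0.3 f_pl_t) + (f_w_t + 0.7 f_pl_t)]
             / [P*(f_nl_p + 0.3 f_pl_p) + (f_w_p + 0.7 f_pl_p)]

    The unbound-fraction tissue/plasma ratio is taken as 1 (documented
    simplification).  Any tissue present in ``profile.kp_overrides`` uses the
    override verbatim, so externally derived coefficients always win.
    """
    if compositions is None:
        compositions = DEFAULT_TISSUE_COMPOSITIONS
    if tissues is None:
        tissues = tuple(compositions)

    needs_formula = [t for t in tissues if t not in profile.kp_overrides]
    missing = [t for t in needs_formula if t not in compositions]
    if missing:
        raise ValueError(f"no tissue composition for model tissue(s) {missing}")
    if needs_formula and profile.logp is None:
        raise ValueError(
            f"{profile.casrn}: logp required to compute Kp for {needs_formula} "
            "(no direct override supplied)"
        )

    kps: dict[str, float] = {}
    if needs_formula:
        p_eff = 10.0 ** profile.logp * total_neutral_fraction(profile.pka, ph)
        denom = (
            p_eff * (plasma.f_neutral_lipid + 0.3 * plasma.f_phospholipid)
            + plasma.f_water + 0.7 * plasma.f_phospholipid
        )
        for tissue in needs_formula:
            c = compositions[tissue]
            numer = (
                p_eff * (c.f_neutral_lipid + 0.3 * c.f_phospholipid)
                + c.f_water + 0.7 * c.f_phospholipid
            )
            kps[tissue] = numer / denom
    for tissue in tissues:
        if tissue in profile.kp_overrides:
            kps[tissue] = profile.kp_overrides[tissue]
    if any(not math.isfinite(kp) or kp <= 0 for kp in kps.values()):
        raise ValueError(f"{profile.casrn}: non-positive partition coefficient in {kps}")
    return {t: kps[t] for t in tissues}
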