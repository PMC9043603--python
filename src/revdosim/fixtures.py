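"""Synthetic chemicals, assay tables and exposure tables.

Two archetype chemicals emulate the qualitative contrast the toolkit is
built to expose.  They are documented constants — **not** the real
case-study chemicals, whose measured/QSAR parameter values are not
distributed with this package:

* ``DTAC-like`` — a slowly cleared, highly partitioning chemical (low
  intrinsic clearance, lipophilic logP giving rest/gut/kidney Kp well above
  10, low plasma fraction unbound).  Its liver Kp is overridden below 1 to
  emulate the plasma sequestration that strong plasma-protein binding
  produces in httk-style partitioning, so venous plasma concentrations
  exceed liver concentrations and repeated hourly dosing accumulates.
* ``CNPA-like`` — a rapidly cleared chemical (intrinsic clearance far above
  hepatic plasma flow, Kp near 1 in the splanchnic tissues, an
  extracellular-restricted rest-of-body Kp).  First-pass extraction keeps
  systemic exposure low, the liver — fed directly from the gut — carries the
  highest concentrations, and hourly dosing shows essentially no
  accumulation.

Both archetypes share a synthetic assay table whose AC50 medians are
similar, so their EAD medians differ only through pharmacokinetics — the
core screening message this package demonstrates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .chem import ChemicalProfile

__all__ = [
    "dtac_like_profile",
    "cnpa_like_profile",
    "make_archetypes",
    "random_profiles",
    "synthetic_assays",
    "archetype_exposures",
    "profiles_to_table",
]

ASSAY_GROUP = "KCC8: Receptor-Mediated Effects"


def dtac_like_profile() -> ChemicalProfile:
    """Slowly cleared, high-partitioning archetype (synthetic surrogate)."""
    return ChemicalProfile(
        name="DTAC-like",
        casrn="FIX-0001",
        mw=263.89,
        logp=4.0,
        fub=0.01,
        clint=0.5,
        kp_overrides={"liver": 0.4},
        provenance={k: "default" for k in ("mw", "logp", "fub", "clint", "rb2p", "kp_liver")},
    )


def cnpa_like_profile() -> ChemicalProfile:
    """Rapidly cleared, low-partitioning archetype (synthetic surrogate)."""
    return ChemicalProfile(
        name="CNPA-like",
        casrn="FIX-0002",
        mw=169.61,
        logp=0.5,
        fub=1.0,
        clint=300.0,
        kp_overrides={"liver": 1.5, "rest": 0.10},
        provenance={k: "default" for k in ("mw", "logp", "fub", "clint", "rb2p",
                                           "kp_liver", "kp_rest")},
    )


#: Gut absorption rate (1/h) per archetype.  Absorption speed is a chemical
#: property: the small, polar, rapidly dissolving archetype absorbs much
#: faster than the surfactant-like one, which keeps the shipped default.
ARCHETYPE_KA = {"FIX-0001": 2.18, "FIX-0002": 6.0}


def archetype_schedule(
    profile: ChemicalProfile,
    dose_per_admin: float = 1.0,
    interval: float = 1.0,
    n_doses: int = 24,
) -> "DosingSchedule":
    """Hourly-bolus schedule carrying the archetype's absorption rate."""
    from .physiology import DEFAULT_KA_PER_H, DosingSchedule

    ka = ARCHETYPE_KA.get(profile.casrn, DEFAULT_KA_PER_H)
    return DosingSchedule("oral", dose_per_admin, interval, n_doses, ka=ka)


def make_archetypes(seed: int = 7) -> tuple[list[ChemicalProfile], pd.DataFrame, pd.DataFrame]:
    """The two archetype profiles, a shared-group assay table with similar
    AC50 medians for both, and an exposure table.

    Returns ``(profiles, assay_table, exposure_table)``; reproducible for a
    given ``seed``.
    """
    profiles = [dtac_like_profile(), cnpa_like_profile()]
    frames = []
    for profile, gm, sub_seed in zip(profiles, (20.0, 24.0), (seed, seed + 1)):
        frames.append(
            synthetic_assays([profile], per_chem=20, gm=gm, gsd=2.0, seed=sub_seed)
        )
    assays = pd.concat(frames, ignore_index=True)
    return profiles, assays, archetype_exposures()


def archetype_exposures() -> pd.DataFrame:
    """Daily exposure estimates for the archetypes (95th-percentile style
    screening values, mg/kg/day)."""
    return pd.DataFrame(
        {
            "casrn": ["FIX-0001", "FIX-0002"],
            "exposure_mg_per_kg_day": [0.106, 7.19e-4],
            "percentile_label": ["p95", "p95"],
        }
    )


#: Log-uniform sampling ranges for plausible screening-library chemicals.
RANDOM_RANGES = {
    "mw": (150.0, 500.0),  # g/mol
    "logp": (-1.0, 5.0),  # uniform, not log-uniform
    "fub": (0.005, 1.0),
    "clint": (0.1, 300.0),  # µL/min/10^6 cells
}


def random_profiles(n: int, seed: int) -> list[ChemicalProfile]:
    """``n`` reproducible random chemical profiles within documented ranges."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    profiles = []
    for i in range(n):
        lo, hi = RANDOM_RANGES["mw"]
        mw = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        logp = float(rng.uniform(*RANDOM_RANGES["logp"]))
        lo, hi = RANDOM_RANGES["fub"]
        fub = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        lo, hi = RANDOM_RANGES["clint"]
        clint = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        pka = ()
        kind = rng.choice(["none", "acid", "base"])
        if kind != "none":
            pka = ((float(rng.uniform(2.0, 11.0)), str(kind)),)
        profiles.append(
            ChemicalProfile(
                name=f"RND-{i:04d}",
                casrn=f"RND-{seed}-{i:04d}",
                mw=mw, logp=logp, fub=fub, clint=clint, pka=pka,
                provenance={k: "predicted" for k in ("mw", "logp", "fub", "clint")},
            )
        )
    return profiles


def synthetic_assays(
    profiles: list[ChemicalProfile],
    per_chem: int = 20,
    gm: float = 20.0,
    gsd: float = 2.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic curated-HTS-style assay table.

    AC50s are log-normal with geometric mean ``gm`` (µM) and geometric
    standard deviation ``gsd``; roughly 10% of records are flagged inactive.
    Reproducible for a given ``seed``.
    """
    if per_chem < 1:
        raise ValueError("per_chem must be >= 1")
    if not gm > 0:
        raise ValueError("gm must be > 0")
    if gsd < 1:
        raise ValueError("gsd must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for profile in profiles:
        ac50 = gm * np.exp(rng.standard_normal(per_chem) * np.log(gsd))
        active = rng.uniform(size=per_chem) >= 0.10
        for j in range(per_chem):
            rows.append(
                {
                    "casrn": profile.casrn,
                    "assay_id": f"ASSAY-{j:03d}",
                    "group": ASSAY_GROUP,
                    "ac50": float(ac50[j]),
                    "ac50_units": "uM",
                    "active": bool(active[j]),
                }
            )
    return pd.DataFrame(rows)


def profiles_to_table(profiles: list[ChemicalProfile]) -> pd.DataFrame:
    """Serialize profiles to the chemical-parameter CSV layout (one row per
    chemical/parameter/source)."""
    rows = []
    units = {"mw": "g/mol", "logp": "", "fub": "", "clint": "uL/min/1e6cells",
             "rb2p": ""}
    for p in profiles:
        entries: list[tuple[str, float]] = [
            ("mw", p.mw), ("fub", p.fub), ("clint", p.clint), ("rb2p", p.rb2p),
        ]
        if p.logp is not None:
            entries.append(("logp", p.logp))
        for value, kind in p.pka:
            entries.append((f"pka_{kind}", value))
        for tissue, kp in p.kp_overrides.items():
            entries.append((f"kp_{tissue}", kp))
        for parameter, value in entries:
            rows.append(
                {
                    "casrn": p.casrn,
                    "name": p.name,
                    "parameter": parameter,
                    "value": value,
                    "units": units.get(parameter, ""),
                    "source": p.provenance.get(parameter, "default"),
                }
            )
    return pd.DataFrame(rows)
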