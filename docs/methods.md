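# Methods

## Scope and model structure

`revdosim` implements a generalized, flow-limited physiologically based
pharmacokinetic (PBPK) model for screening-level forward dosimetry, and a
Cmax-based reverse-dosimetry (IVIVE) layer that converts in vitro AC50
bioactivity concentrations into equivalent administered doses (EADs) and
margin-of-exposure (MoE) metrics.  It is built for breadth across chemicals
rather than chemical-specific precision: every chemical is described by a
small physicochemical/ADME parameter set, and every PK process is first
order.

The body is lumped into six reported compartments — gut, liver, kidney,
rest-of-body, venous plasma and arterial plasma — plus a gut-lumen depot
and three cumulative elimination ledgers (hepatic metabolism, urine,
feces).  The lung is lumped into the arterial leg.  This is the smallest
structure that reproduces the two behaviours the tool exists to expose:
oral first-pass hepatic extraction (the liver receives the portal outflow
of the gut before the systemic circulation does) and multi-dose
accumulation.  The tissue map is configuration-extensible in principle,
but the shipped model is the six-compartment human.

State variables are chemical amounts in µmol.  With `C_x = A_x / V_x` and
tissue venous-equilibrium concentration `C_t / Kp_t`:

```
dA_gutlumen/dt = -ka * A_gutlumen
dA_gut/dt      = fabs*ka*A_gutlumen + Q_gut*(C_art - C_gut/Kp_gut)
dA_liver/dt    = Q_ha*C_art + Q_gut*C_gut/Kp_gut
                 - (Q_ha+Q_gut)*C_liver/Kp_liver - CLint_whole*fub*C_liver/Kp_liver
dA_kidney/dt   = Q_kid*(C_art - C_kid/Kp_kid) - GFR*fub*C_kid/Kp_kid
dA_rest/dt     = Q_rest*(C_art - C_rest/Kp_rest)
dA_ven/dt      = (Q_ha+Q_gut)*C_liver/Kp_liver + Q_kid*C_kid/Kp_kid
                 + Q_rest*C_rest/Kp_rest - Q_card*C_ven
dA_art/dt      = Q_card*C_ven - Q_card*C_art
```

The non-absorbed oral fraction `(1-fabs)` of each lumen transfer goes to
the feces ledger; hepatic metabolism and glomerular filtration feed the
metabolized and urine ledgers.  Because the ledgers are states, mass
balance (amounts + ledgers = cumulative administered dose) is a property
of the solution, and the simulator asserts it to 0.1% at every output
time; in practice it holds to ~1e-13 relative.

Assumptions worth stating plainly: perfusion-limited (flow-limited) tissue
uptake with instantaneous venous equilibration; linear (non-saturable)
metabolism — the well-stirred liver acting on the unbound
venous-equivalent concentration `fub * C_liver / Kp_liver`; renal
elimination by filtration only (`GFR * fub`, no secretion or
reabsorption); no enterohepatic recirculation; oral and IV routes only.

## Chemical parameters and provenance

Each chemical needs molecular weight (g/mol), logP, optional pKa values
(acid/base), fraction unbound in plasma `fub`, and intrinsic hepatic
clearance `CLint` (µL/min per 10^6 hepatocytes).  The parameter CSV holds
one row per (chemical, parameter, source); resolution prefers `measured`
over `predicted` over `default`, records the provenance of every value,
and rejects a chemical that lacks `mw`, `fub` or `clint` from any source.
Only the blood:plasma ratio (`rb2p`, default 1) and the oral fraction
absorbed (`fabs`, default 1 — the conservative 100%-absorption screening
convention, carried on the dosing schedule) have defaults.  Henry's-law
constants and other inhalation-relevant descriptors are accepted by the
schema but play no role in the oral-route model.

`CLint` is scaled to the whole liver as
`CLint_whole [L/h] = CLint * hepatocellularity * liver_mass * 60e-6`
(defaults 110e6 cells/g and 1820 g for the shipped human).

## Partition coefficients

Tissue:plasma partition coefficients come from a Poulin–Theil-style
volume-fraction model on the effective lipophilicity
`P = 10^logP * f_neutral(pH 7.4)`:

```
Kp_t = [P*(f_nl_t + 0.3 f_pl_t) + (f_w_t + 0.7 f_pl_t)]
     / [P*(f_nl_p + 0.3 f_pl_p) + (f_w_p + 0.7 f_pl_p)]
```

with water/neutral-lipid/phospholipid volume fractions per tissue.
Design choices, made where several defensible options exist:

* The tissue/plasma unbound-fraction ratio is set to 1.  This is a
  deliberate simplification; it biases Kp high for strongly
  protein-bound chemicals.  Direct `kp_<tissue>` overrides in the input
  table therefore always win verbatim, so users can inject coefficients
  from any external method (including ones that model plasma binding).
* Ionization is handled by multiplying P by the Henderson–Hasselbalch
  neutral fraction at pH 7.4 (product over groups for multiprotic
  chemicals) — an effective-logD correction, the simplest defensible one.
* The rest-of-body composition includes the adipose share of the lump
  (neutral lipid fraction 0.06), so lipophilic chemicals reach rest Kp
  values above 10 as they should when fat is part of the lump.

## Numerics

Between dose events the system is linear and can be stiff (clearance rate
constants can exceed distribution ones by orders of magnitude), so
integration uses an adaptive stiff-capable solver (LSODA) with the
constant Jacobian supplied, rtol 1e-8 and atol 1e-10 µmol.  Dosing is
event-driven: the integration is segmented at administration times and
the bolus is added to the gut lumen (oral) or venous plasma (IV) as an
exact state jump; `1 mg/kg` converts to `bw/mw * 1000` µmol.  The output
grid is uniform with at least 20 points per dosing interval and includes
every event time; the sample at an event time is the post-dose state.
These tolerances are tight enough that the dose-linearity and
mass-balance test assertions measure model error, not solver error.
Solver noise of order atol can produce concentrations a hair below zero;
they are clipped at zero on output.

Cmax reporting uses venous plasma ("plasma" in all outputs), the full
simulation window by default, and breaks ties toward the earliest time.
AUC is the trapezoidal integral on the output grid with interpolated
endpoints.

## Reverse dosimetry

Because every process is first order, concentrations scale linearly with
dose, and one simulation at 1 mg/kg per administration under the user's
schedule yields `Cmax_unit`; then `EAD = AC50 / Cmax_unit` in mg/kg/day.
The published case-study numbers this package checks itself against fix
the same normalization: the printed median AC50 / median EAD pair implies
a unit-dose divisor of 1.4815 µM, consistent with the reported
sub-1.5 µM hourly-schedule plasma Cmax.  (The companion statement that
the faster-cleared chemical's Cmax is "under 0.1 µM" sits slightly below
its back-calculated divisor of ~0.108 µM; the implementation follows the
printed EAD arithmetic and this discrepancy is noted, not resolved.)
The dosing schedule is recorded in every EAD result because EADs depend
on dosing frequency; EADs are per mg/kg *per administration* normalized
by the 1 mg/kg unit run, reported as mg/kg/day for the daily schedules
the tool targets.

Summary statistics over an assay set exclude inactive records, use the
midpoint-of-two median convention for even counts and linear-interpolated
quartiles.  An assay set with no active records yields a distinct
"no data" signal (`None`), not an error.  MoE divides a selectable EAD
statistic (median by default, logged) by a daily exposure estimate;
ranking sorts ascending by MoE with stable ties, so the smallest margins
— the screening priorities — come first.

## Synthetic data

The fixture generators make every stage testable without downloads.  The
two archetypes are documented constants chosen to exhibit the qualitative
contrast the tool is designed to reveal; they are **not** the real
case-study chemicals, whose parameter values are not redistributed here.

* **DTAC-like** (mw 263.89, logP 4.0, fub 0.01, CLint 0.5): negligible
  clearance and strong partitioning (rest/gut Kp ≈ 19–22) drive multi-dose
  accumulation (hourly-dosing plasma Cmax ≈ 5.9× the first-dose peak).
  Its liver Kp is overridden to 0.4: a composition-only Kp formula with
  unit unbound-fraction ratio cannot represent the plasma sequestration
  that fub = 0.01 produces, and a flow-limited model with liver Kp > 1
  can never show plasma concentrations above liver concentrations.  The
  override emulates the binding-dominated tissue:plasma ratio the
  archetype needs; this is exactly the injection path real users take for
  externally derived coefficients.
* **CNPA-like** (mw 169.61, logP 0.5, fub 1.0, CLint 300): intrinsic
  clearance far above liver plasma flow gives ~99% first-pass extraction,
  so the liver — fed directly from the gut — carries the highest
  concentrations.  Its rest Kp is overridden to 0.10
  (extracellular-restricted distribution) and its absorption rate set to
  6 h⁻¹ (rapid dissolution of a small polar molecule); together these
  give a distribution volume and terminal half-life short enough that
  hourly dosing accumulates < 5%.  At physiologic volumes with Kp ≈ 1
  everywhere and the default absorption rate of 2.18 h⁻¹, no parameter
  choice can meet that bound (the absorption rate itself limits the
  terminal phase), which is why absorption speed is treated as the
  chemical property it is.

The shared assay table draws 20 log-normal AC50s per archetype
(geometric means 20 and 24 µM, GSD 2.0, ~10% inactive, fixed default
seed), giving similar bioactivity medians (within 1.5×) while the EAD
medians differ > 20× — the pharmacokinetics-driven divergence that
motivates IVIVE.  What passing these fixture tests shows is that the
*model* produces the first-pass, accumulation and EAD-divergence
behaviours; it does not validate any real chemical's parameters, and the
synthetic assay table has none of the assay-family correlation structure,
censoring at tested-concentration bounds, or curve-fit uncertainty of
real curated HTS data.

Problem sizes used throughout the test and acceptance runs — 24-dose
hourly schedules on a ~500-point grid, 6–8 randomized chemicals for the
mass-balance property, 20 assays per chemical — are the package's chosen
demonstration scale; each simulation takes tens of milliseconds.

## Known limitations

* Screening-grade generalized model: no saturable metabolism, transporters,
  enterohepatic recirculation, or inhalation/dermal routes.
* Kp formula ignores plasma-protein binding asymmetry (see above); use
  overrides for strongly bound chemicals.
* Human-only shipped physiology (editable YAML; the schema supports other
  species but no other parameter sets are distributed).
* No population variability or uncertainty propagation; single
  deterministic parameter sets only.
* Whether reported "plasma" should be venous, arterial or whole blood is a
  modelling convention; this package reports venous plasma and defaults
  rb2p to 1 so blood and plasma coincide unless overridden.
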