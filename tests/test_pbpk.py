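"""PBPK core: model assembly, event-driven integration, closed-form oracles,
mass balance and first-order (dose-linearity) properties."""

import numpy as np
import pytest

from revdosim.chem import ChemicalProfile
from revdosim.fixtures import archetype_schedule, random_profiles
from revdosim.pbpk import STATE_NAMES, auc, build_model, cmax, simulate
from revdosim.physiology import DosingSchedule, Physiology, TissueSpec

UNIT_KP = {t: 1.0 for t in ("gut", "liver", "kidney", "rest")}


def _profile(**kw):
    base = dict(name="t", casrn="TEST-1", mw=200.0, fub=0.5, clint=10.0, logp=1.0)
    base.update(kw)
    return ChemicalProfile(**base)


def _scaled_flows(phys: Physiology, factor: float) -> Physiology:
    return Physiology(
        species=phys.species,
        bw=phys.bw,
        tissues={
            t: TissueSpec(s.volume_L, s.flow_L_per_h * factor)
            for t, s in phys.tissues.items()
        },
        v_ven=phys.v_ven,
        v_art=phys.v_art,
        q_cardiac=phys.q_cardiac * factor,
        gfr=phys.gfr,
        hepatocellularity=phys.hepatocellularity,
        liver_mass=phys.liver_mass,
    )


class TestBuildModel:
    def test_oral_events_target_gut_lumen(self, human):
        model = build_model(_profile(), human, DosingSchedule("oral", 1.0, 1.0, 3))
        assert all(idx == STATE_NAMES.index("gutlumen") for _, idx, _ in model.events)

    def test_iv_events_target_venous_plasma(self, human):
        model = build_model(_profile(), human, DosingSchedule("iv", 1.0, 1.0, 3))
        assert all(idx == STATE_NAMES.index("ven") for _, idx, _ in model.events)

    def test_dose_amount_unit_conversion(self, human):
        # 1 mg/kg in a 70 kg human at 263.89 g/mol
        model = build_model(
            _profile(mw=263.89), human, DosingSchedule("oral", 1.0, 1.0, 1)
        )
        assert model.events[0][2] == pytest.approx(265.26, abs=0.01)

    def test_missing_kp_rejected(self, human):
        with pytest.raises(ValueError, match="kidney"):
            build_model(
                _profile(), human, DosingSchedule("oral", 1.0, 1.0, 1),
                kps={"gut": 1.0, "liver": 1.0, "rest": 1.0},
            )


class TestSimulate:
    def test_zero_dose_gives_identically_zero_series(self, human):
        model = build_model(_profile(), human, DosingSchedule("oral", 0.0, 1.0, 3))
        result = simulate(model, duration=5.0)
        for series in result.conc.values():
            assert np.all(series == 0.0)

    def test_concentrations_nonnegative(self, dtac_hourly_result):
        for series in dtac_hourly_result.conc.values():
            assert np.all(series >= 0.0)

    def test_grid_contains_event_times_and_is_dense(self, dtac_hourly_result):
        t = dtac_hourly_result.time
        for event in range(24):
            assert np.any(np.isclose(t, float(event)))
        assert len(t) >= 24 * 20

    def test_duration_before_last_dose_rejected(self, human):
        model = build_model(_profile(), human, DosingSchedule("oral", 1.0, 1.0, 10))
        with pytest.raises(ValueError, match="duration"):
            simulate(model, duration=5.0)

    def test_elimination_free_iv_conserves_and_equilibrates(self, human):
        """With no clearance, total amount is constant and every tissue
        reaches the common venous-equilibrium level D / sum(V_j * Kp_j)."""
        phys = human.copy()
        phys.gfr = 0.0
        kps = {"gut": 3.0, "liver": 5.0, "kidney": 2.0, "rest": 4.0}
        profile = _profile(clint=0.0, kp_overrides=kps)
        model = build_model(profile, phys, DosingSchedule("iv", 1.0, 1.0, 1))
        result = simulate(model, duration=50.0)

        total = result.amounts.sum(axis=1)
        assert np.allclose(total[result.time > 0], total[-1], rtol=1e-9)

        dose = 1.0 * phys.bw / profile.mw * 1000.0
        v_kp = (
            sum(phys.tissues[t].volume_L * kps[t] for t in kps)
            + phys.v_ven + phys.v_art
        )
        expected = dose / v_kp
        full_kps = dict(kps, plasma_ven=1.0, plasma_art=1.0)
        for comp, series in result.conc.items():
            assert series[-1] / full_kps[comp] == pytest.approx(expected, rel=1e-6)

    def test_bateman_limit_one_compartment(self, human):
        """Perfusion made non-limiting (flows x1e6) with unit Kp collapses the
        body to one well-mixed volume; the plasma curve must match the
        Bateman solution within 1% at every output time."""
        fast = _scaled_flows(human, 1e6)
        profile = _profile(clint=10.0, fub=0.5, kp_overrides=dict(UNIT_KP))
        sched = DosingSchedule("oral", 1.0, 1.0, 1, fabs=0.8, ka=2.18)
        result = simulate(build_model(profile, fast, sched), duration=6.0)

        v_tot = sum(s.volume_L for s in human.tissues.values()) + human.v_ven + human.v_art
        cl_whole = profile.clint * human.hepatocellularity * human.liver_mass * 60e-6
        ke = (cl_whole + human.gfr) * profile.fub / v_tot
        dose = 1.0 * human.bw / profile.mw * 1000.0
        ka = sched.ka
        t = result.time
        bateman = sched.fabs * dose * ka / (v_tot * (ka - ke)) * (
            np.exp(-ke * t) - np.exp(-ka * t)
        )
        sim = result.conc["plasma_ven"]
        mask = t > 0
        assert np.allclose(sim[mask], bateman[mask], rtol=0.01)

    def test_mass_balance_on_random_parameter_sets(self, human):
        """Amount in compartments + elimination ledgers equals cumulative
        administered amount within 0.1% at every output time."""
        for i, profile in enumerate(random_profiles(6, seed=20260921)):
            route = "oral" if i % 2 == 0 else "iv"
            sched = DosingSchedule(route, 1.0, 2.0, 3, fabs=0.9 if route == "oral" else 1.0)
            result = simulate(build_model(profile, human, sched), duration=8.0)
            assert result.mass_balance_rel_error().max() < 1e-3

    def test_dose_linearity(self, human, dtac_like):
        """All processes are first order: scaling the dose by lambda scales
        every concentration series by lambda."""
        lam = 3.7
        sched = archetype_schedule(dtac_like, n_doses=6)
        base = simulate(build_model(dtac_like, human, sched))
        scaled = simulate(build_model(dtac_like, human, sched.with_dose(lam)))
        for comp in base.conc:
            assert np.allclose(scaled.conc[comp], lam * base.conc[comp], rtol=1e-6, atol=1e-12)
        assert cmax(scaled)[0] == pytest.approx(lam * cmax(base)[0], rel=1e-6)

    def test_increasing_clint_decreases_plasma_auc(self, human):
        kps = dict(UNIT_KP)
        aucs = []
        for clint in (1.0, 10.0, 100.0):
            profile = _profile(clint=clint, kp_overrides=kps)
            result = simulate(
                build_model(profile, human, DosingSchedule("oral", 1.0, 1.0, 1)),
                duration=24.0,
            )
            aucs.append(auc(result, "plasma_ven"))
        assert aucs[0] > aucs[1] > aucs[2]

    def test_less_frequent_dosing_does_not_raise_cmax(self, human, dtac_like):
        values = []
        for interval in (1.0, 2.0, 4.0):
            sched = DosingSchedule("oral", 1.0, interval, 6)
            result = simulate(build_model(dtac_like, human, sched))
            values.append(cmax(result)[0])
        assert values[0] >= values[1] >= values[2]


class TestFirstPassContrast:
    def test_high_clearance_chemical_peaks_in_liver(self, cnpa_hourly_result):
        """Oral dosing with high intrinsic clearance: the liver, fed directly
        from the gut, carries higher concentrations than venous plasma."""
        assert cmax(cnpa_hourly_result, "liver")[0] > cmax(cnpa_hourly_result, "plasma_ven")[0]

    def test_slowly_cleared_chemical_peaks_in_plasma(self, dtac_hourly_result):
        assert cmax(dtac_hourly_result, "plasma_ven")[0] > cmax(dtac_hourly_result, "liver")[0]

    def test_slowly_cleared_chemical_accumulates(self, dtac_hourly_result):
        r = dtac_hourly_result
        first = r.conc["plasma_ven"][r.time <= 1.0].max()
        last = cmax(r, "plasma_ven", window="last_interval")[0]
        assert last > 1.5 * first


class TestCmaxAuc:
    def test_monotone_decaying_iv_curve_has_tmax_zero(self, human):
        profile = _profile(clint=50.0, kp_overrides=dict(UNIT_KP))
        result = simulate(
            build_model(profile, human, DosingSchedule("iv", 1.0, 1.0, 1)), duration=12.0
        )
        _, tmax = cmax(result, "plasma_ven")
        assert tmax < 0.2  # initial mixing transient only

    def test_constant_series_ties_break_to_window_start(self, human):
        model = build_model(_profile(), human, DosingSchedule("oral", 0.0, 1.0, 2))
        result = simulate(model, duration=4.0)
        value, tmax = cmax(result, "plasma_ven")
        assert value == 0.0 and tmax == 0.0

    def test_full_window_cmax_in_final_interval_when_accumulating(self, dtac_hourly_result):
        _, tmax = cmax(dtac_hourly_result, "plasma_ven", window="full")
        assert tmax >= 23.0

    def test_unknown_compartment_rejected(self, dtac_hourly_result):
        with pytest.raises(KeyError):
            cmax(dtac_hourly_result, "brain")

    def test_auc_of_zero_series_is_zero(self, human):
        model = build_model(_profile(), human, DosingSchedule("oral", 0.0, 1.0, 1))
        assert auc(simulate(model, duration=2.0), "plasma_ven") == 0.0

    def test_auc_rectangle_rule_on_constant_series(self, human):
        result = simulate(
            build_model(_profile(), human, DosingSchedule("oral", 0.0, 1.0, 1)),
            duration=2.0,
        )
        result.conc["plasma_ven"] = np.full_like(result.time, 3.0)
        assert auc(result, "plasma_ven", 0.25, 1.75) == pytest.approx(3.0 * 1.5)

    def test_auc_window_outside_range_rejected(self, dtac_hourly_result):
        with pytest.raises(ValueError):
            auc(dtac_hourly_result, "plasma_ven", 0.0, 48.0)

    def test_bateman_total_auc_closed_form(self, human):
        fast = _scaled_flows(human, 1e6)
        profile = _profile(clint=10.0, fub=0.5, kp_overrides=dict(UNIT_KP))
        sched = DosingSchedule("oral", 1.0, 1.0, 1, fabs=0.8)
        result = simulate(build_model(profile, fast, sched), duration=60.0)
        v_tot = sum(s.volume_L for s in human.tissues.values()) + human.v_ven + human.v_art
        cl_whole = profile.clint * human.hepatocellularity * human.liver_mass * 60e-6
        ke = (cl_whole + human.gfr) * profile.fub / v_tot
        dose = 1.0 * human.bw / profile.mw * 1000.0
        expected = sched.fabs * dose / (v_tot * ke)
        assert auc(result, "plasma_ven") == pytest.approx(expected, rel=0.01)
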