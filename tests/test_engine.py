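"""PBPK engine: closed-form oracles, conservation, linearity, depot input."""

import numpy as np
import pytest

from lapbpk import DoseEvent, GridSpec, load_drug, simulate_profile, simulate_states
from lapbpk.drugs import _from_dict, depot_release_rates
from lapbpk.engine import (N_STATES, STATE_INDEX, PBPKModel, build_model,
                           cumulative_depot_release, depot_release_input,
                           mass_balance_error)
from lapbpk.trial import RegimenSchedule, build_regimen
from tests.conftest import make_individual


def synthetic_drug(**over):
    """A neutral test compound with unit binding and simple kinetics."""
    raw = {
        "name": "synthetic-neutral",
        "molecular_weight": 300.0, "log_p": 0.0, "pka": [],
        "fu_plasma": 1.0, "blood_to_plasma_ratio": 1.0,
        "protein_binding_partner": "albumin",
        "elimination_pathways": {"CYP3A4": 1.0},
        "intrinsic_clearance_reference": 2.0,
        "oral_absorption": {"ka": 0.5, "fa": 1.0, "lag": 0.0},
        "reference": {"hematocrit": 0.45, "albumin_g_per_l": 46.0,
                      "gfr_ml_per_min": 115.0, "liver_volume_l": 1.80},
        "depot": {"release_model": "single_first_order",
                  "k_release_fast": 2.0, "k_release_slow": 2.0,
                  "fast_fraction": 1.0, "bioavailable_fraction": 1.0,
                  "flow_sensitivity": 0.0, "release_cv": 0.0,
                  "reference_muscle_flow": 66.3},
    }
    depot_over = over.pop("depot", None)
    raw.update(over)
    if depot_over:
        raw["depot"].update(depot_over)
    return _from_dict(raw)


def schedule(events, horizon, interval=24.0, ident="test"):
    return RegimenSchedule(id=ident, events=tuple(events), horizon_h=horizon,
                           dosing_interval_h=interval)


def unit_kp():
    from lapbpk.population import ORGANS
    return {o: 1.0 for o in ORGANS}


def dosed_before(events, times):
    return np.array([sum(e.amount for e in events if e.time < t - 1e-9)
                     for t in times])


@pytest.fixture(scope="module")
def ref():
    return make_individual()


class TestConservationAndLinearity:
    def test_total_amount_conserved_without_elimination(self, ref):
        """Kp = 1 everywhere, no elimination: dose stays in the system."""
        drug = synthetic_drug()
        model = build_model(drug, ref, kp_override=unit_kp(), clint_override=0.0)
        events = [DoseEvent(0.0, "intramuscular", 600.0)]
        times = np.arange(0.0, 48.1, 0.5)
        states = simulate_states(model, events, times)
        totals = states.sum(axis=1)
        assert np.all(np.abs(totals[1:] - 600.0) / 600.0 < 1e-8)
        assert np.all(states >= -1e-12)

    def test_mass_balance_with_elimination_full_regimen(self, ref, cab):
        """Dose in = system + eliminated, to 1e-6 relative, at every time."""
        sched = build_regimen("cabotegravir", "Q4W", horizon_weeks=24)
        profile, states = simulate_profile(ref, cab, sched, return_states=True)
        dosed = dosed_before(sched.events, profile.times)
        err = mass_balance_error(states[1:], dosed[1:])
        assert err.max() < 1e-6
        assert np.all(states >= 0.0)

    def test_dose_linearity(self, ref, cab):
        sched1 = build_regimen("cabotegravir", "Q4W", horizon_weeks=16)
        doubled = schedule([DoseEvent(e.time, e.route, 2 * e.amount)
                            for e in sched1.events], sched1.horizon_h)
        p1 = simulate_profile(ref, cab, sched1)
        p2 = simulate_profile(ref, cab, doubled)
        mask = p1.plasma_concentration > 1e-9
        ratio = p2.plasma_concentration[mask] / p1.plasma_concentration[mask]
        assert np.all(np.abs(ratio - 2.0) < 2e-6)

    def test_superposition_of_overlapping_doses(self, ref, cab):
        e1 = [DoseEvent(0.0, "intramuscular", 600.0)]
        e2 = [DoseEvent(336.0, "intramuscular", 400.0)]
        horizon = 8 * 168.0
        pa = simulate_profile(ref, cab, schedule(e1, horizon))
        pb = simulate_profile(ref, cab, schedule(e2, horizon))
        pab = simulate_profile(ref, cab, schedule(e1 + e2, horizon))
        total = pa.plasma_concentration + pb.plasma_concentration
        mask = total > 1e-9
        assert np.allclose(pab.plasma_concentration[mask], total[mask], rtol=1e-6)


class TestClosedFormOracles:
    def test_one_compartment_bateman_oracle(self, ref):
        """A hand-built one-compartment system with first-order input matches
        the Bateman closed form to near machine precision."""
        v, cl, ka, dose = 40.0, 3.0, 0.25, 100.0
        m = np.zeros((N_STATES, N_STATES))
        ven, dep = STATE_INDEX["venous_blood"], STATE_INDEX["depot_fast"]
        elim = STATE_INDEX["eliminated_hepatic"]
        m[dep, dep] = -ka
        m[ven, dep] = ka
        m[ven, ven] = -cl / v
        m[elim, ven] = cl / v
        model = PBPKModel(matrix=m, venous_index=ven, venous_volume=v,
                          blood_to_plasma=1.0, kp={}, fu=1.0, k_fast=ka,
                          k_slow=ka, bioavailable_fraction=1.0,
                          fast_fraction=1.0, depot_to="venous")
        times = np.arange(0.0, 96.1, 1.0)
        states = simulate_states(model, [DoseEvent(0.0, "intramuscular", dose)],
                                 times)
        k = cl / v
        t = times[1:]
        analytic = dose / v * ka / (ka - k) * (np.exp(-k * t) - np.exp(-ka * t))
        simulated = states[1:, ven] / v
        assert np.allclose(simulated, analytic, rtol=1e-9)

    def test_whole_body_reduces_to_one_compartment(self, ref):
        """With negligible tissue partitioning the whole-body model collapses
        to one well-mixed blood compartment within 0.5% of the closed form."""
        drug = synthetic_drug(intrinsic_clearance_reference=1.0)
        kp = {o: 1e-3 for o in unit_kp()}
        model = build_model(drug, ref, kp_override=kp)
        phys = ref.physiology
        v_eff = (phys.organ_volumes["arterial_blood"]
                 + phys.organ_volumes["venous_blood"]
                 + sum(phys.organ_volumes[o] * 1e-3 for o in kp))
        q_h = phys.organ_blood_flows["liver"]
        clint = drug.intrinsic_clearance_reference * \
            phys.organ_volumes["liver"] / 1.80
        cl = q_h * clint / (q_h + clint)          # well-stirred, fu = BP = 1
        k, ka, dose = cl / v_eff, 2.0, 100.0
        times = np.arange(0.0, 16.1, 0.25)
        states = simulate_states(model, [DoseEvent(0.0, "intramuscular", dose)],
                                 times)
        sel = times >= 3.0   # past the brief distribution/input transient
        t = times[sel]
        analytic = dose / v_eff * ka / (ka - k) * (np.exp(-k * t) - np.exp(-ka * t))
        simulated = states[sel][:, STATE_INDEX["venous_blood"]] / \
            phys.organ_volumes["venous_blood"]
        # amplitude and slope agree within 0.5%
        assert np.all(np.abs(simulated / analytic - 1.0) < 0.005)

    def test_two_compartment_biexponential_oracle(self):
        """Central + peripheral system matches the analytic biexponential."""
        v1, v2, q, cl, dose = 10.0, 50.0, 5.0, 2.0, 100.0
        k10, k12, k21 = cl / v1, q / v1, q / v2
        m = np.zeros((N_STATES, N_STATES))
        ven, per = STATE_INDEX["venous_blood"], STATE_INDEX["muscle"]
        elim = STATE_INDEX["eliminated_hepatic"]
        m[ven, ven] = -(k10 + k12)
        m[per, ven] = k12
        m[ven, per] = k21
        m[per, per] = -k21
        m[elim, ven] = k10
        model = PBPKModel(matrix=m, venous_index=ven, venous_volume=v1,
                          blood_to_plasma=1.0, kp={}, fu=1.0, k_fast=1.0,
                          k_slow=1.0, bioavailable_fraction=1.0,
                          fast_fraction=1.0, depot_to="venous")
        # bolus: a very fast depot emptied before the first comparison point
        times = np.arange(0.0, 240.1, 1.0)
        states = np.zeros((len(times), N_STATES))
        init = np.zeros(N_STATES)
        init[ven] = dose
        from scipy.linalg import expm
        for i, t in enumerate(times):
            states[i] = expm(m * t) @ init if t > 0 else init
        beta_sum = k10 + k12 + k21
        disc = np.sqrt(beta_sum ** 2 - 4 * k10 * k21)
        alpha, beta = (beta_sum + disc) / 2, (beta_sum - disc) / 2
        t = times
        a = dose / v1 * (alpha - k21) / (alpha - beta)
        b = dose / v1 * (k21 - beta) / (alpha - beta)
        analytic = a * np.exp(-alpha * t) + b * np.exp(-beta * t)
        simulated = states[:, ven] / v1
        assert np.allclose(simulated, analytic, rtol=1e-8)


class TestDepotInput:
    def test_cumulative_release_reaches_bioavailable_dose(self):
        depot = synthetic_drug(depot={"k_release_fast": 1e-3,
                                      "k_release_slow": 1e-3}).depot
        events = [DoseEvent(0.0, "intramuscular", 600.0)]
        released = cumulative_depot_release(depot, events, 5e4)
        assert released == pytest.approx(600.0, rel=1e-6)

    def test_causality_zero_before_dose(self):
        depot = synthetic_drug().depot
        events = [DoseEvent(100.0, "intramuscular", 600.0)]
        times = np.array([0.0, 50.0, 99.9, 100.0, 101.0])
        rate = depot_release_input(depot, events, times)
        assert np.all(rate[:3] == 0.0)
        assert rate[3] > 0.0

    def test_dual_release_superposes_two_phases(self):
        depot = synthetic_drug(depot={"release_model": "dual_first_order",
                                      "fast_fraction": 0.3,
                                      "k_release_fast": 1e-2,
                                      "k_release_slow": 1e-4}).depot
        events = [DoseEvent(0.0, "intramuscular", 100.0)]
        t = np.array([0.0, 10.0, 100.0])
        rate = depot_release_input(depot, events, t)
        expected = (100 * (0.3 * 1e-2 * np.exp(-1e-2 * t)
                           + 0.7 * 1e-4 * np.exp(-1e-4 * t)))
        assert np.allclose(rate, expected)

    def test_oral_event_rejected(self):
        depot = synthetic_drug().depot
        with pytest.raises(ValueError):
            depot_release_input(depot, [DoseEvent(0.0, "oral", 30.0)],
                                np.array([1.0]))

    def test_flip_flop_terminal_slope_equals_release_rate(self, ref, cab):
        """When release is much slower than elimination, the plasma tail
        decays at the release rate (fitted within 5%)."""
        events = [DoseEvent(0.0, "intramuscular", 600.0)]
        horizon = 24 * 168.0
        prof = simulate_profile(ref, cab, schedule(events, horizon),
                                grid=GridSpec(lead_in_end=0.0, step=6.0))
        mask = (prof.times >= 10 * 168.0) & (prof.times <= 20 * 168.0)
        slope = -np.polyfit(prof.times[mask],
                            np.log(prof.plasma_concentration[mask]), 1)[0]
        k_release, _ = depot_release_rates(cab, ref)
        assert slope == pytest.approx(k_release, rel=0.05)


class TestSimulateProfile:
    def test_zero_dose_gives_zero_profile(self, ref, cab):
        events = [DoseEvent(0.0, "intramuscular", 0.0)]
        prof = simulate_profile(ref, cab, schedule(events, 336.0))
        assert np.all(prof.plasma_concentration == 0.0)

    def test_grid_insensitivity_of_week96_trough(self, ref, cab):
        sched = build_regimen("cabotegravir", "Q4W")
        t96 = 96 * 168.0 - 1.0
        fine = simulate_profile(ref, cab, sched, grid=GridSpec(step=6.0),
                                extra_times=[t96])
        coarse = simulate_profile(ref, cab, sched, grid=GridSpec(step=24.0),
                                  extra_times=[t96])
        assert coarse.at(t96) == pytest.approx(fine.at(t96), rel=0.02)

    def test_bdf_cross_checks_matrix_exponential(self, ref, cab):
        """The adaptive stiff integrator reproduces the exact propagator."""
        events = [DoseEvent(24.0 * d, "oral", 30.0) for d in range(7)]
        events.append(DoseEvent(168.0, "intramuscular", 600.0))
        sched = schedule(events, 3 * 168.0)
        a = simulate_profile(ref, cab, sched, method="expm")
        b = simulate_profile(ref, cab, sched, method="bdf")
        scale = a.plasma_concentration.max()
        mask = a.plasma_concentration > 0.01 * scale
        rel = np.abs(b.plasma_concentration[mask] / a.plasma_concentration[mask] - 1)
        assert rel.max() < 1e-4

    def test_non_finite_parameter_rejected(self, ref):
        drug = synthetic_drug(oral_absorption={"ka": float("inf"), "fa": 1.0,
                                               "lag": 0.0})
        with pytest.raises(ValueError):
            build_model(drug, ref)

    def test_elimination_pathway_bookkeeping(self, ref, cab):
        """Integrated hepatic/renal elimination split matches the configured
        pathway fractions within 2% in the linear regime."""
        events = [DoseEvent(0.0, "oral", 30.0)]
        prof, states = simulate_profile(ref, cab, schedule(events, 3000.0),
                                        grid=GridSpec(lead_in_end=0, step=12.0),
                                        return_states=True)
        hep = states[-1, STATE_INDEX["eliminated_hepatic"]]
        ren = states[-1, STATE_INDEX["eliminated_renal"]]
        frac_hep = hep / (hep + ren)
        assert frac_hep == pytest.approx(
            cab.elimination_pathways["UGT1A1"], rel=0.02)
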