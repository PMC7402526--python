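"""Trajectory integration and normalized dose-response simulation."""

import math

import numpy as np
import pytest

from hemodecon import (
    CELL_TYPES,
    DOSE_GRID_NM,
    DrugEffectParameters,
    integrate,
    simulate_control_kinetics,
    simulate_dose_response,
)

from conftest import empty_state, zeroed_system

GRID = np.linspace(0.0, 6.0, 13)


class TestIntegrate:
    def test_zero_rates_constant_trajectory(self):
        sys = zeroed_system()
        traj = integrate(sys, None, 0.0, empty_state(HSC=1000.0, B=50.0), GRID)
        assert np.allclose(traj.states, traj.states[0])

    def test_single_compartment_exponential(self):
        # HSC with rho = 1: pure exponential at rate kappa
        sys = zeroed_system(kappa_HSC=0.9, rho_HSC=1.0)
        traj = integrate(sys, None, 0.0, empty_state(HSC=100.0), GRID)
        expected = 100.0 * np.exp(0.9 * GRID)
        got = traj.table["HSC"].values
        assert np.allclose(got, expected, rtol=1e-6)

    def test_terminal_decay_and_mass_conservation(self):
        sys = zeroed_system(delta=0.5)
        traj = integrate(sys, None, 0.0, empty_state(Mono=1000.0), GRID)
        live = traj.table["Mono"].values
        dead = traj.table["totalDeadCells"].values
        assert np.allclose(live, 1000.0 * np.exp(-0.5 * GRID), rtol=1e-6)
        assert np.allclose(dead, 1000.0 - live, rtol=1e-6)

    def test_two_compartment_closed_form(self):
        # HSC -> MPP with inert MPP: analytic influx accumulation
        rho, kappa = 0.8, 1.1
        sys = zeroed_system(kappa_HSC=kappa, rho_HSC=rho)
        a = (2 * rho - 1) * kappa         # HSC net self rate
        b = 2 * (1 - rho) * kappa          # outflow rate into MPP
        traj = integrate(sys, None, 0.0, empty_state(HSC=200.0), GRID)
        hsc = 200.0 * np.exp(a * GRID)
        mpp = 200.0 * b / a * (np.exp(a * GRID) - 1.0)
        assert np.allclose(traj.table["HSC"].values, hsc, rtol=1e-6)
        assert np.allclose(traj.table["MPP"].values, mpp, rtol=1e-6)

    def test_expm_agrees_with_adaptive_integrator(self, ref_sys, ref_init):
        t = np.array([0.0, 2.0, 4.0, 6.0])
        a = integrate(ref_sys, None, 0.0, ref_init, t, method="expm")
        b = integrate(ref_sys, None, 0.0, ref_init, t, method="LSODA",
                      rtol=1e-10, atol=1e-8)
        assert np.allclose(a.states[-1], b.states[-1], rtol=1e-6)

    def test_tolerance_robustness(self, ref_sys, ref_init):
        t = np.array([0.0, 6.0])
        a = integrate(ref_sys, None, 0.0, ref_init, t, method="BDF", rtol=1e-8)
        b = integrate(ref_sys, None, 0.0, ref_init, t, method="BDF", rtol=5e-9)
        rel = np.abs(a.states[-1] - b.states[-1]) / (np.abs(a.states[-1]) + 1.0)
        assert rel.max() < 1e-4

    def test_total_viable_is_live_sum(self, ref_sys, ref_init):
        traj = simulate_control_kinetics(ref_sys, ref_init)
        tab = traj.table
        assert np.allclose(tab["totalViableCells"].values,
                           tab[list(CELL_TYPES)].sum(axis=1).values)

    def test_dead_pool_nondecreasing(self, ref_sys, ref_init):
        traj = integrate(ref_sys, None, 0.0, ref_init, GRID)
        dead = traj.table["totalDeadCells"].values
        assert (np.diff(dead) >= -1e-9).all()

    def test_nonincreasing_time_grid_rejected(self, ref_sys, ref_init):
        with pytest.raises(ValueError):
            integrate(ref_sys, None, 0.0, ref_init, [0.0, 2.0, 2.0])


class TestControlKinetics:
    def test_day0_only_echoes_initial(self, ref_sys, ref_init):
        traj = simulate_control_kinetics(ref_sys, ref_init, days=[0.0])
        assert traj.state_at(0.0).counts == pytest.approx(ref_init.counts)

    def test_sampling_is_restriction_of_full_trajectory(self, ref_sys, ref_init):
        full = simulate_control_kinetics(
            ref_sys, ref_init, days=np.arange(0.0, 6.5, 0.5))
        sampled = simulate_control_kinetics(
            ref_sys, ref_init, days=[0.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        for day in (2.0, 4.0, 6.0):
            assert np.allclose(sampled.state_at(day).to_vector(),
                               full.state_at(day).to_vector(), rtol=1e-9)

    def test_daily_doubling_toy(self):
        # rho = 1, kappa = ln 2, C0 = 100 -> 100 * 2^6 = 6400 at day 6
        sys = zeroed_system(kappa_HSC=math.log(2.0), rho_HSC=1.0)
        traj = simulate_control_kinetics(sys, empty_state(HSC=100.0))
        assert traj.state_at(6.0).counts["HSC"] == pytest.approx(6400.0, rel=1e-9)


class TestDoseResponse:
    def test_inert_drug_all_ones(self, ref_sys, ref_init, inert_drug):
        sim = simulate_dose_response(
            ref_sys, inert_drug, (0.0,) + DOSE_GRID_NM, ref_init)
        assert np.allclose(sim.normalized.values, 1.0)

    def test_dose_zero_row_is_one(self, ref_sys, ref_init):
        from hemodecon import reference_drug
        sim = simulate_dose_response(
            ref_sys, reference_drug("docetaxel"), (0.0,) + DOSE_GRID_NM, ref_init)
        assert np.allclose(sim.normalized.loc[0.0].values, 1.0)

    def test_live_readouts_monotone_nonincreasing_in_dose(self, ref_sys, ref_init):
        from hemodecon import reference_drug
        sim = simulate_dose_response(
            ref_sys, reference_drug("paclitaxel"), DOSE_GRID_NM, ref_init)
        live = sim.normalized[list(CELL_TYPES)].values
        assert (np.diff(live, axis=0) <= 1e-9).all()

    def test_dead_readout_flat_without_killing_and_delta(self, ref_init):
        # all Emax_T <= 1 and delta = 0: dead accrual is dose-independent
        sys = zeroed_system(kappa_HSC=0.8, rho_HSC=0.9)
        drug = DrugEffectParameters.inert()
        drug.emax_total["HSC"] = 0.9
        drug.log_ec50["HSC"] = math.log(10.0)
        sim = simulate_dose_response(sys, drug, (0.0,) + DOSE_GRID_NM,
                                     empty_state(HSC=1000.0))
        assert np.allclose(sim.normalized["totalDeadCells"].values, 1.0)

    def test_dead_readout_monotone_with_killing(self, ref_init):
        sys = zeroed_system(kappa_HSC=0.8, rho_HSC=0.9)
        drug = DrugEffectParameters.inert()
        drug.emax_total["HSC"] = 2.0
        drug.log_ec50["HSC"] = math.log(10.0)
        sim = simulate_dose_response(sys, drug, (0.0,) + DOSE_GRID_NM,
                                     empty_state(HSC=1000.0, Mono=100.0),
                                     )
        dead = sim.normalized["totalDeadCells"].values
        assert (np.diff(dead) >= -1e-9).all()

    def test_two_compartment_ratio_matches_closed_form(self):
        # HSC -> MPP toy under pure anti-proliferation: treated/vehicle
        # ratio of HSC is exp(-emax*occ*(2 rho - 1 + 2(1-rho)) kappa t)...
        # computed against the exact scalar exponential
        rho, kappa, emax, ec50 = 1.0, 0.6, 0.5, 20.0
        sys = zeroed_system(kappa_HSC=kappa, rho_HSC=rho)
        drug = DrugEffectParameters.inert()
        drug.emax_total["HSC"] = emax
        drug.log_ec50["HSC"] = math.log(ec50)
        dose = 20.0
        sim = simulate_dose_response(sys, drug, [0.0, dose],
                                     empty_state(HSC=100.0))
        occ = dose / (dose + ec50)
        k_eff = kappa * (1.0 - emax * occ)
        expected = math.exp(k_eff * 6.0) / math.exp(kappa * 6.0)
        assert sim.normalized.loc[dose, "HSC"] == pytest.approx(
            expected, rel=1e-6)

    def test_negative_dose_rejected(self, ref_sys, ref_init, inert_drug):
        with pytest.raises(ValueError):
            simulate_dose_response(ref_sys, inert_drug, [-1.0], ref_init)
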