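"""Lineage topology, parameter accounting, drug-effect algebra, and the ODE
right-hand side."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemodecon import (
    CELL_TYPES,
    RENEWING_TYPES,
    REPORTED_SPECIES,
    TERMINAL_TYPES,
    DrugEffectParameters,
    SystemParameters,
    build_reference_topology,
    decompose_emax,
    effective_division_rate,
    evaluate_rhs,
    hill_occupancy,
    killing_flux,
)
from hemodecon.model import cell_type_table

from conftest import empty_state, zeroed_system


class TestTopology:
    def test_tree_structure(self):
        topo = build_reference_topology()
        # a tree over the 13 cell types rooted at HSC: 12 edges
        assert len(topo.edges) == 12
        assert len(topo.branch_points) == 2
        assert set(topo.branch_points) == {"MPP", "GMP"}
        assert len(topo.branch_points["MPP"]) == 4
        assert len(topo.branch_points["GMP"]) == 2
        assert topo.reachable_from("HSC") == set(CELL_TYPES)

    def test_cell_type_roles(self):
        table = cell_type_table()
        assert len(table) == 13
        assert {ct for ct, v in table.items() if v.is_terminal} == {
            "ErythII", "MK", "Mono", "Neut", "B"}
        assert {ct for ct, v in table.items() if v.has_renewal} == {
            "HSC", "MPP", "GMP", "GranP", "Gran", "MonoP", "ErythI"}
        assert not table["LymP"].has_renewal

    def test_free_parameter_accounting(self, ref_sys):
        assert SystemParameters.N_FREE == 27
        assert (len(ref_sys.kappa) + len(ref_sys.rho) + len(ref_sys.beta)
                + 1) == 27
        assert DrugEffectParameters.N_FREE == 26
        d = DrugEffectParameters.inert()
        assert len(d.emax_total) + len(d.log_ec50) == 26
        assert len(REPORTED_SPECIES) == 15


class TestDrugAlgebra:
    @pytest.mark.parametrize("conc,ec50,expected", [
        (0.0, 10.0, 0.0),
        (10.0, 10.0, 0.5),
        (30.0, 10.0, 0.75),
    ])
    def test_hill_occupancy(self, conc, ec50, expected):
        assert hill_occupancy(conc, ec50) == pytest.approx(expected)

    def test_hill_domain_errors(self):
        with pytest.raises(ValueError):
            hill_occupancy(-1.0, 10.0)
        with pytest.raises(ValueError):
            hill_occupancy(1.0, 0.0)

    @pytest.mark.parametrize("total,ap,ck", [
        (2.014, 1.0, 1.014),   # strong cell killing
        (0.0, 0.0, 0.0),       # no effect
        (0.489, 0.489, 0.0),   # pure anti-proliferation
        (1.0, 1.0, 0.0),       # exactly at the killing threshold
    ])
    def test_decompose_emax(self, total, ap, ck):
        got_ap, got_ck = decompose_emax(total)
        assert got_ap == pytest.approx(ap)
        assert got_ck == pytest.approx(ck)

    def test_decompose_rejects_negative(self):
        with pytest.raises(ValueError):
            decompose_emax(-0.1)

    @given(total=st.floats(0.0, 3.0))
    @settings(max_examples=50, derandomize=True)
    def test_decomposition_sums_to_total_above_one(self, total):
        ap, ck = decompose_emax(total)
        assert 0.0 <= ap <= 1.0 and ck >= 0.0
        if total >= 1.0:
            assert ap + ck == pytest.approx(total)

    def test_effective_division_rate(self):
        assert effective_division_rate(1.3, 0.0, 100.0, 10.0) == 1.3
        assert effective_division_rate(1.0, 0.5, 10.0, 10.0) == pytest.approx(0.75)
        # full anti-proliferation at saturating dose blocks division
        assert effective_division_rate(2.0, 1.0, 1e12, 10.0) == pytest.approx(
            0.0, abs=1e-9)

    def test_killing_flux_zero_below_threshold(self):
        for emax in (0.0, 0.5, 1.0):
            assert killing_flux(emax, 1e6, 10.0, 1000.0) == 0.0
        assert killing_flux(2.0, 100.0, 10.0, 0.0) == 0.0

    def test_killing_flux_saturating_limit(self):
        # Emax_T = 2.014 -> Emax_CK = 1.014; at saturating dose the flux is
        # Emax_CK * count
        assert killing_flux(2.014, 1e12, 10.0, 1000.0) == pytest.approx(
            1014.0, rel=1e-9)


class TestRhs:
    def test_all_rates_zero_gives_zero_derivative(self):
        sys = zeroed_system()
        state = empty_state(HSC=1000.0, Mono=500.0)
        d = evaluate_rhs(state, sys)
        assert all(v == 0.0 for v in d.counts.values())
        assert d.total_dead == 0.0

    def test_renewal_differentiation_balance(self):
        # rho = 0.5: renewal exactly offsets differentiation loss
        sys = zeroed_system(kappa_GMP=1.5)
        state = empty_state(GMP=1000.0)
        d = evaluate_rhs(state, sys)
        assert d.counts["GMP"] == pytest.approx(0.0)
        # outflow 2*(1-rho)*kappa*[C] split by beta
        assert d.counts["GranP"] == pytest.approx(0.5 * 1.5 * 1000.0)
        assert d.counts["MonoP"] == pytest.approx(0.5 * 1.5 * 1000.0)

    def test_pure_renewal_exponential_growth(self):
        sys = zeroed_system(kappa_HSC=math.log(2.0), rho_HSC=1.0)
        state = empty_state(HSC=100.0)
        d = evaluate_rhs(state, sys)
        assert d.counts["HSC"] == pytest.approx(math.log(2.0) * 100.0)

    def test_branch_outflow_equals_child_influx(self, ref_sys):
        state = empty_state(MPP=1000.0)
        d = evaluate_rhs(state, ref_sys)
        rho, kappa = ref_sys.rho["MPP"], ref_sys.kappa["MPP"]
        outflow = 2.0 * (1.0 - rho) * kappa * 1000.0
        influx = sum(d.counts[c] for c in ("GMP", "ErythI", "MK", "LymP"))
        assert influx == pytest.approx(outflow)

    def test_lymp_converts_without_doubling(self):
        sys = zeroed_system()
        sys.kappa["LymP"] = 0.5
        state = empty_state(LymP=1000.0)
        d = evaluate_rhs(state, sys)
        assert d.counts["LymP"] == pytest.approx(-500.0)
        assert d.counts["B"] == pytest.approx(500.0)

    def test_lymp_doubling_config_switch(self):
        sys = zeroed_system()
        sys.kappa["LymP"] = 0.5
        sys.lymp_doubling = True
        d = evaluate_rhs(empty_state(LymP=1000.0), sys)
        assert d.counts["B"] == pytest.approx(1000.0)

    def test_terminal_death_feeds_dead_pool(self):
        sys = zeroed_system(delta=0.4)
        state = empty_state(Mono=1000.0)
        d = evaluate_rhs(state, sys)
        assert d.counts["Mono"] == pytest.approx(-400.0)
        assert d.total_dead == pytest.approx(400.0)

    def test_drug_killing_removes_into_dead_pool(self):
        sys = zeroed_system()
        drug = DrugEffectParameters.inert()
        drug.emax_total["Mono"] = 2.0  # Emax_CK = 1
        drug.log_ec50["Mono"] = math.log(10.0)
        state = empty_state(Mono=1000.0)
        state.drug_conc = 10.0  # half occupancy
        d = evaluate_rhs(state, sys, drug)
        assert d.counts["Mono"] == pytest.approx(-500.0)
        assert d.total_dead == pytest.approx(500.0)

    def test_mass_balance_with_no_proliferation(self, ref_sys):
        # with all kappa = 0 total live + dead is conserved
        sys = ref_sys.copy()
        sys.kappa = {ct: 0.0 for ct in CELL_TYPES}
        state = empty_state(**{ct: 100.0 for ct in CELL_TYPES})
        d = evaluate_rhs(state, sys)
        live = sum(d.counts.values()) + d.quiescent_neutrophils
        assert live + d.total_dead == pytest.approx(0.0, abs=1e-9)

    def test_invalid_state_rejected(self, ref_sys):
        state = empty_state(HSC=-1.0)
        with pytest.raises(ValueError):
            evaluate_rhs(state, ref_sys)

    def test_invalid_parameters_rejected(self, ref_sys):
        bad = ref_sys.copy()
        bad.rho["HSC"] = 0.4  # below the HSC renewal floor
        with pytest.raises(ValueError, match="rho_HSC"):
            evaluate_rhs(empty_state(HSC=10.0), bad)

    def test_rhs_matches_finite_difference_of_closed_form(self):
        # 1-compartment: C(t) = C0 * exp((2 rho - 1) kappa t)
        sys = zeroed_system(kappa_HSC=0.7, rho_HSC=0.9)
        a = (2 * 0.9 - 1) * 0.7
        state = empty_state(HSC=500.0)
        d = evaluate_rhs(state, sys)
        h = 1e-6
        fd = 500.0 * (math.exp(a * h) - 1.0) / h
        assert d.counts["HSC"] == pytest.approx(fd, rel=1e-5)
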