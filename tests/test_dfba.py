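"""Flux LPs, the C1-C4 transformations, and the dFBA stepping loop."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from diauxie import CoreParameters, make_batch, make_variant, simulate
from diauxie.core import SolverSettings
from diauxie.dfba import (assemble_system, base_stoichiometric_matrix,
                          saturation, simulate_dfba, solve_flux_lp,
                          structured_fluxes, variant_C2_rules)


class TestSaturation:
    def test_half_saturation(self):
        assert saturation(1.0, 1.0, 1.0) == pytest.approx(0.5)

    def test_zero_substrate(self):
        assert saturation(0.0, 1.0, 1.0) == 0.0

    def test_asymptote(self):
        assert saturation(1e12, 2.0, 1.0) == pytest.approx(2.0, rel=1e-9)


class TestAssembly:
    def test_base_matrix_rows(self):
        p = CoreParameters()
        sys = assemble_system({"s1": 1.0, "s2": 1.0, "e1": 1.0, "e2": 1.0}, p)
        expect = np.array([[0.5, -1, 0, 0, 0],
                           [0, 0, 0.5, -1, 0],
                           [0, 1, 0, 1, -1]])
        assert np.allclose(sys.Nprime, expect)
        assert sys.x_labels == ("E1", "r_d1", "E2", "r_d2", "r_b")

    def test_recovers_pure_stoichiometry(self):
        p = CoreParameters()
        sys = assemble_system({"s1": 0.7, "s2": 0.3, "e1": 1.0, "e2": 1.0}, p)
        N = base_stoichiometric_matrix()
        h1 = saturation(0.7, 1.0, 1.0)
        h2 = saturation(0.3, 1.0, 1.0)
        recovered = sys.Nprime.copy()
        recovered[:, 0] /= h1
        recovered[:, 2] /= h2
        assert np.allclose(recovered, N)

    def test_objective_selects_biomass_flux(self):
        p = CoreParameters()
        sys = assemble_system({"s1": 1.0, "s2": 1.0, "e1": 1.0, "e2": 1.0}, p)
        x = np.array([1.0, 0.5, 1.0, 0.5, 1.0])
        assert sys.c @ x == pytest.approx(1.0)   # c^T x = r_b


class TestSolveFluxLP:
    def test_equalities_determine_solution(self):
        # h(S1)=0.5, h(S2)=0.25, E fixed at 1 -> r_d1=.5, r_d2=.25, r_b=.75
        p = CoreParameters()
        sys = assemble_system({"s1": 1.0, "s2": 1.0 / 3.0,
                               "e1": 1.0, "e2": 1.0}, p)
        sol = solve_flux_lp(sys)
        assert sol.status == "optimal"
        assert np.allclose(sol.x, [1.0, 0.5, 1.0, 0.25, 0.75], atol=1e-8)
        assert np.max(np.abs(sys.Nprime @ sol.x)) <= 1e-9

    def test_inconsistent_bounds_infeasible(self):
        p = CoreParameters()
        sys = assemble_system({"s1": 1.0, "s2": 1.0, "e1": 1.0, "e2": 1.0}, p)
        sys.lb[4], sys.ub[4] = 1.0, 0.5
        assert solve_flux_lp(sys).status == "infeasible"

    def test_cap_below_forced_biomass_infeasible(self):
        p = CoreParameters()
        sys = assemble_system({"s1": 1.0, "s2": 1.0 / 3.0,
                               "e1": 1.0, "e2": 1.0}, p)
        sys.H = np.array([[0.0, 0, 0, 0, 1.0]])
        sys.h = np.array([0.3])          # equalities force r_b = 0.75
        assert solve_flux_lp(sys).status == "infeasible"

    def test_no_uptake_means_no_growth(self):
        p = CoreParameters()
        sys = assemble_system({"s1": 0.0, "s2": 0.0, "e1": 1.0, "e2": 1.0}, p)
        sol = solve_flux_lp(sys)
        assert sol.objective == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize("variant", ["base", "C1", "C2", "C3", "C4"])
def test_closed_form_matches_linprog(variant):
    """The analytic flux solutions agree with the general LP solver."""
    rng = np.random.default_rng(42)
    spec = make_variant(variant) if variant != "base" else \
        make_variant("base_dfba")
    vp = spec.variant_params
    p = spec.core
    for _ in range(15):
        state = {"s1": rng.uniform(0, 2), "s2": rng.uniform(0, 2),
                 "e1": rng.uniform(0.01, 1), "e2": rng.uniform(0.01, 1)}
        fx = structured_fluxes(spec.structure, state["s1"], state["s2"],
                               state["e1"], state["e2"], p, vp)
        sys = assemble_system(state, p, spec.structure, vp)
        sol = solve_flux_lp(sys)
        assert sol.status == "optimal"
        lp_rb = sol.x[3] + sol.x[4] if variant == "C1" else sol.x[4]
        assert fx["mu"] == pytest.approx(lp_rb, abs=1e-7)


def test_added_inequalities_never_increase_biomass():
    p = CoreParameters()
    state = dict(s1=1.0, s2=0.8, e1=0.5, e2=0.5)
    base = structured_fluxes("base", state["s1"], state["s2"],
                             state["e1"], state["e2"], p, {})["mu"]
    for A_max in (0.01, 0.1, 0.5, 2.0, 100.0):
        mu = structured_fluxes("C3", state["s1"], state["s2"], state["e1"],
                               state["e2"], p,
                               dict(a1=1.0, a2=2.0, A_max=A_max))["mu"]
        assert mu <= base + 1e-12
    for slack in (0.0, 0.01, 1.0, 1e6):
        mu = structured_fluxes("C4", state["s1"], state["s2"], state["e1"],
                               state["e2"], p,
                               dict(cost1=1.0, cost2=2.0, slack=slack))["mu"]
        assert mu <= base + 1e-12


class TestVariantRules:
    def test_c2_rule(self):
        assert not variant_C2_rules(1.0)          # S1 available -> E2 off
        assert variant_C2_rules(0.0)
        assert not variant_C2_rules(0.01, 0.01, 1.0)   # tie -> repression

    def test_c2_blocks_s2_uptake_in_phase1(self):
        fx = structured_fluxes("C2", 1.0, 1.0, 0.5, 0.5, CoreParameters(),
                               dict(s1_threshold=0.01))
        assert fx["r_s2"] == 0.0
        assert fx["r_s1"] > 0

    def test_c3_corner_allocation(self):
        # equal saturation, cheaper membrane cost wins the whole budget
        fx = structured_fluxes("C3", 1e12, 1e12, 5.0, 5.0, CoreParameters(),
                               dict(a1=1.0, a2=2.0, A_max=1.0))
        assert fx["e1_eff"] == pytest.approx(1.0)
        assert fx["e2_eff"] == pytest.approx(0.0)

    def test_c3_nonbinding_reduces_to_base(self):
        p = CoreParameters()
        fx = structured_fluxes("C3", 1.0, 0.5, 0.3, 0.4, p,
                               dict(a1=1.0, a2=2.0, A_max=1e9))
        base = structured_fluxes("base", 1.0, 0.5, 0.3, 0.4, p, {})
        assert fx["mu"] == pytest.approx(base["mu"])

    def test_c4_nonbinding_limits(self):
        p = CoreParameters()
        loose = structured_fluxes("C4", 1.0, 1.0, 0.5, 0.5, p,
                                  dict(cost1=1.0, cost2=2.0, slack=1e9))
        assert loose["r_e1"] == pytest.approx(p.k1)
        assert loose["r_e2"] == pytest.approx(p.k2)
        free = structured_fluxes("C4", 1.0, 1.0, 0.5, 0.5, p,
                                 dict(cost1=1e-12, cost2=1e-12, slack=0.0))
        assert free["r_e1"] == pytest.approx(p.k1)

    def test_c4_tight_slack_prefers_cheap_enzyme(self):
        fx = structured_fluxes("C4", 1e-9, 1e-9, 0.01, 0.01, CoreParameters(),
                               dict(cost1=1.0, cost2=10.0, slack=0.5))
        assert fx["r_e1"] == pytest.approx(0.5)   # budget all on cheap enzyme
        assert fx["r_e2"] == 0.0

    def test_c1_inefficient_cap_zero_blocks_phase2(self):
        fx = structured_fluxes("C1", 0.0, 1.0, 0.5, 0.5, CoreParameters(),
                               dict(cap_frac=0.0))
        assert fx["mu"] == 0.0


class TestC1Phases:
    def test_s2_produced_then_consumed_and_mass_closes(self):
        spec = make_variant("C1")
        scen = make_batch(S2_0=0.0, t_end=60)
        traj = simulate(spec, scen)
        s2 = traj.states["s2"]
        assert s2.max() > 0.05                       # excretion in phase 1
        assert s2[-1] < 1e-3 * s2.max()              # consumed in phase 2
        # phase-1 excretion equals what is available at the start of phase 2
        i_peak = int(np.argmax(s2))
        produced = s2[i_peak]
        consumed = s2[i_peak] - s2[-1]
        assert consumed == pytest.approx(produced, rel=1e-2)


def test_dfba_cross_oracle_against_qss_kinetics():
    """Base dFBA equals the QSS-reduced kinetic model (independent solve)."""
    spec = make_variant("base_dfba")
    traj = simulate_dfba(spec, make_batch(t_end=25),
                         SolverSettings(n_out=501))

    def qss_rhs(t, y):
        s1, s2, b, e1, e2 = y
        r1 = max(e1, 0) * max(s1, 0) / (1 + max(s1, 0))
        r2 = max(e2, 0) * max(s2, 0) / (1 + max(s2, 0))
        mu = r1 + r2
        return [-r1 * b, -r2 * b, mu * b, 1 - mu * e1, 1 - mu * e2]

    sol = solve_ivp(qss_rhs, (0, 25), [1.0, 1.0, 0.01, 0.01, 0.01],
                    method="LSODA", rtol=1e-11, atol=1e-13, t_eval=traj.t)
    for i, key in enumerate(("s1", "s2", "b", "e1", "e2")):
        scale = np.max(np.abs(sol.y[i]))
        err = np.max(np.abs(traj.states[key] - sol.y[i])) / scale
        assert err < 1e-4, key


def test_both_substrates_zero_keeps_biomass_constant():
    traj = simulate_dfba(make_variant("base_dfba"),
                         make_batch(S1_0=0.0, S2_0=0.0, t_end=5))
    assert np.allclose(traj.states["b"], 0.01)
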