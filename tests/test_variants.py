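"""Regulation hooks, variant construction, R5 bistability and hysteresis."""

import numpy as np
import pytest
from hypothesis import given, settings as hsettings, strategies as st

from diauxie import (ConfigurationError, activation_factor, diauxic_index,
                     induction_factor, inhibition_factor, make_batch,
                     make_variant, r5_enzyme_switch, simulate,
                     steady_state_branches)
from diauxie.core import SolverSettings
from diauxie.variants import ENSEMBLE, list_variants


class TestFactors:
    def test_induction_examples(self):
        assert induction_factor(1.0, 1.0) == pytest.approx(0.5)
        assert induction_factor(0.0, 1.0) == 0.0

    def test_inhibition_examples(self):
        assert inhibition_factor(0.0, 1.0) == 1.0
        assert inhibition_factor(1.0, 1.0) == pytest.approx(0.5)
        assert inhibition_factor(1e12, 1.0) == pytest.approx(0.0, abs=1e-9)

    def test_activation_examples(self):
        assert activation_factor(0.0, 1.0, 2.0) == 0.0
        assert activation_factor(1.0, 1.0, 2.0) == pytest.approx(0.5)

    def test_r5_switch(self):
        f1, f2 = r5_enzyme_switch(0.3, 0.3)
        assert f1 == pytest.approx(0.5) and f2 == pytest.approx(0.5)
        hi = r5_enzyme_switch(100.0, 0.3)
        assert hi[0] > 0.999 and hi[1] < 1e-3
        lo = r5_enzyme_switch(0.0, 0.3)
        assert lo[1] == pytest.approx(1.0)

    @hsettings(derandomize=True, max_examples=50)
    @given(x=st.floats(0, 1e6), k=st.floats(1e-6, 1e6),
           n=st.floats(1.0, 4.0))
    def test_factors_bounded_and_monotone(self, x, k, n):
        f = induction_factor(x, k, n)
        g = inhibition_factor(x, k, n)
        assert 0.0 <= f < 1.0 + 1e-12
        assert 0.0 < g <= 1.0
        assert induction_factor(x + 1.0, k, n) >= f - 1e-12


class TestMakeVariant:
    def test_catalogue_covers_ensemble(self):
        recs = {r["id"] for r in list_variants()}
        assert recs == set(ENSEMBLE)
        assert len(ENSEMBLE) == 19

    def test_n1_differs_from_base_only_in_synthesis_rates(self):
        n1 = make_variant("N1")
        base = make_variant("base")
        diff = {k for k in base.core.__dict__
                if getattr(n1.core, k) != getattr(base.core, k)}
        assert diff == {"k1"} or diff == {"k1", "k2"}
        assert n1.hooks.f1 is not None          # induction installed

    def test_r1_has_single_free_parameter(self):
        assert make_variant("R1").free_params == ("K_I",)

    def test_foreign_asymmetry_rejected(self):
        with pytest.raises(ConfigurationError):
            make_variant("R1", {"k1": 2.0})
        with pytest.raises(ConfigurationError):
            make_variant("N1", {"k_s1": 3.0})

    def test_own_asymmetry_allowed(self):
        spec = make_variant("N4", {"k_s1": 3.0, "k_s2": 0.5})
        assert spec.core.k_s1 == 3.0

    def test_unknown_variant(self):
        with pytest.raises(ConfigurationError):
            make_variant("Z9")

    def test_base_shows_no_diauxie(self):
        traj = simulate(make_variant("base"), make_batch(t_end=40))
        assert diauxic_index(traj).d < 0.05


class TestR5:
    def test_branches_match_bisection_oracle(self):
        spec = make_variant("R5")
        vp = spec.variant_params
        bc = steady_state_branches(spec, (0.02, 0.8), 40)
        eps, K = vp["eps"], vp["K_A"]

        def g(m, phi):
            return phi * (eps + (1 - eps) * m ** 2 / (K ** 2 + m ** 2)) - m

        for phi, branch in zip(bc.flux_grid, bc.branches):
            # oracle: dense sign-change scan + bisection
            grid = np.linspace(0.0, 3.0, 30001)
            vals = g(grid, phi)
            oracle = []
            for a, b in zip(grid[:-1], grid[1:]):
                if g(a, phi) * g(b, phi) < 0:
                    lo, hi = a, b
                    for _ in range(80):
                        mid = 0.5 * (lo + hi)
                        if g(lo, phi) * g(mid, phi) <= 0:
                            hi = mid
                        else:
                            lo = mid
                    oracle.append(0.5 * (lo + hi))
            roots = [m for m, _ in branch]
            interior = [r for r in roots if r > 1e-12]
            assert len(interior) == len(oracle)
            for r, o in zip(sorted(interior), sorted(oracle)):
                assert r == pytest.approx(o, abs=1e-8)

    def test_fold_interval_has_three_roots_outer_stable(self):
        spec = make_variant("R5")
        bc = steady_state_branches(spec, (0.02, 0.8), 200)
        counts = bc.n_roots()
        assert (counts == 3).any() and (counts == 1).any()
        for branch in bc.branches:
            if len(branch) == 3:
                stable = [s for _, s in branch]
                assert stable == [True, False, True]

    def test_hysteresis_substrate_pulse_does_not_restore(self):
        # after the batch drops to the low-M branch, even a large fresh
        # dose of S1 cannot re-engage the E1 branch (the inducer pool is
        # gated off by the low product activation), whereas a direct M
        # disturbance immediately flips the enzyme-synthesis switch
        spec = make_variant("R5")
        theta = spec.variant_params["theta"]
        st = SolverSettings(rtol=1e-8, atol=1e-10, n_out=2401)

        scen = make_batch(t_end=60)
        scen.pulses = [(40.0, {"s1": 5.0})]
        arm_s1 = simulate(spec, scen, st)
        win = (arm_s1.t > 41.0) & (arm_s1.t < 56.0)
        assert np.all(arm_s1.states["m"][win] < theta)
        assert np.all(arm_s1.rates["f1"][win] < 0.1)

        scen2 = make_batch(t_end=60)
        scen2.pulses = [(40.0, {"s1": 5.0, "m": 2.0})]
        arm_m = simulate(spec, scen2, st)
        early = (arm_m.t > 40.2) & (arm_m.t < 41.5)
        assert np.all(arm_m.states["m"][early] > theta)
        assert np.all(arm_m.rates["f1"][early] > 0.9)
        # E1 synthesis resumes only in the M-disturbed arm
        i0, i1 = np.searchsorted(arm_m.t, [40.2, 42.0])
        assert arm_m.states["e1"][i1] > arm_m.states["e1"][i0] + 0.3
        j0, j1 = np.searchsorted(arm_s1.t, [40.2, 42.0])
        assert arm_s1.states["e1"][j1] < arm_s1.states["e1"][j0] + 0.05


class TestMechanisms:
    def test_n1_dilutes_nonpreferred_enzyme(self):
        # calibrated asymmetry: synthesis of E2 far below its dilution
        traj = simulate(make_variant("N1", {"k1": 2.0, "k2": 0.02}),
                        make_batch(t_end=40))
        phase1 = traj.states["s1"] > 0.1
        e2 = traj.states["e2"][phase1]
        e1 = traj.states["e1"][phase1]
        assert e2[len(e2) // 2] < e2[0]          # E2 washes out
        assert e1[-1] > e1[0]                    # E1 accumulates

    def test_r1_r2_do_not_need_induction(self):
        for vid, strong in (("R1", {"K_I": 0.01}), ("R2", {"K_I": 0.01})):
            spec = make_variant(vid, dict(strong, induction=False))
            traj = simulate(spec, make_batch(t_end=120))
            assert diauxic_index(traj).d > 0.8, vid

    def test_r3_r4_need_induction(self):
        for vid in ("R3", "R4"):
            spec = make_variant(vid, {"induction": False})
            traj = simulate(spec, make_batch(t_end=120))
            assert diauxic_index(traj).d < 0.2, vid
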