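"""Cellular layer: priming cascade, killing law, antigen cycle,
trafficking and algebraic regulatory populations."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icbsim.immune import (
    N_IMMUNE,
    STATE_INDEX,
    TRAFFIC_SLICE,
    TRAFFIC_STATES,
    AntigenCycleParameters,
    CellState,
    KillingParameters,
    PrimingParameters,
    TraffickingParameters,
    TumorGeometry,
    antigen_cycle_rhs,
    cells_to_diameter,
    diameter_to_cells,
    killing_rate,
    priming_probability,
    priming_rhs,
    proliferation_fold,
    regulatory_populations,
    trafficking_matrix,
    trafficking_rhs,
)


@pytest.fixture
def prim():
    return PrimingParameters()


class TestPrimingProbability:
    def test_no_mapc_no_priming(self, prim):
        assert priming_probability(prim, 0.0, 1e8) == 0.0

    def test_saturates_with_long_window(self, prim):
        p = replace(prim, t_max=1e9)
        assert priming_probability(p, 1e5, 1e8) == pytest.approx(1.0)

    def test_matches_direct_formula(self, prim):
        mapc, t_tot = 3.7e4, 2.1e8
        x = (4.0 * math.pi * prim.d_t * prim.diff_t * mapc * t_tot
             * prim.phi_nt * prim.antigen_strength
             / (prim.t_clonality * prim.s_nt_mapc) * prim.t_max)
        assert priming_probability(prim, mapc, t_tot) == pytest.approx(
            1.0 - math.exp(-x), abs=1e-12)

    def test_monotonicities(self, prim):
        # small mAPC counts keep the encounter probability off saturation
        base = priming_probability(prim, 100.0, 2e8)
        assert priming_probability(prim, 200.0, 2e8) > base
        stronger = replace(prim, antigen_strength=1.0)
        assert priming_probability(stronger, 100.0, 2e8) > base
        more_clones = replace(prim, t_clonality=130.0)
        assert priming_probability(more_clones, 100.0, 2e8) < base

    def test_zero_clonality_rejected(self, prim):
        with pytest.raises(ValueError):
            replace(prim, t_clonality=0.0)


class TestPrimingRhs:
    def test_no_mapc_no_fluxes(self, prim):
        state = CellState()
        state["NT"] = prim.naive_pool_target  # homeostasis quiescent
        d = priming_rhs(state, prim)
        assert np.allclose(d, 0.0)

    def test_cell_conservation_without_proliferation_and_output(self, prim):
        p = replace(prim, n_tdln=1.0)
        state = CellState()
        state["NT"] = 5e4
        state["NT1"] = 2e3
        state["NT2"] = 1e3
        state["PRO1"] = 500.0
        state["PRO2"] = 300.0
        state["PRO3"] = 100.0
        state["mAPC_ln"] = 1e5
        d = priming_rhs(state, p, proliferate=False, homeostasis=False)
        cells = ["NT", "NT1", "NT2", "PRO1", "PRO2", "PRO3", "E_blood"]
        total = sum(d[STATE_INDEX[n]] for n in cells)
        assert total == pytest.approx(0.0, abs=1e-9 * 5e4)

    def test_fold_expansion_matches_exponential_growth(self, prim):
        """Three divisions/day over five days: 2^15, the solution of
        dN/dt = ln2 * 3 * N."""
        want = math.exp(math.log(2.0) * 3.0 * 5.0)
        assert proliferation_fold(prim, 1.0) == pytest.approx(want, rel=0.05)

    def test_ctla4_blockade_never_reduces_output(self, prim):
        state = CellState()
        state["NT"] = 1e5
        state["NT1"] = 1e3
        state["NT2"] = 1e3
        state["PRO3"] = 100.0
        state["mAPC_ln"] = 1e5
        outs = [
            priming_rhs(state, prim, ctla4_inhibition=i)[STATE_INDEX["E_blood"]]
            for i in (0.9, 0.5, 0.1, 0.0)
        ]
        assert all(a <= b + 1e-12 for a, b in zip(outs, outs[1:]))

    def test_ln_tregs_suppress_costimulation(self, prim):
        state = CellState()
        state["NT"] = 1e5
        state["mAPC_ln"] = 1e5
        lo = priming_rhs(state, prim, treg_ln_frac=0.05)[STATE_INDEX["NT1"]]
        hi = priming_rhs(state, prim, treg_ln_frac=0.35)[STATE_INDEX["NT1"]]
        assert hi < lo


class TestKillingRate:
    def test_no_effectors_no_killing(self):
        assert killing_rate(0.0, 1e6, KillingParameters()) == 0.0

    def test_no_targets_no_division_by_zero(self):
        assert killing_rate(1e5, 0.0, KillingParameters()) == 0.0

    def test_forced_half_saturation(self):
        k = KillingParameters(d=2.0, lam=1.0, s=1.0)
        # E = T makes (E/T)^lam = 1, so rate = d*T/2
        assert killing_rate(5e5, 5e5, k) == pytest.approx(2.0 * 5e5 / 2.0)

    @given(
        st.floats(min_value=1.0, max_value=1e9),
        st.floats(min_value=1.0, max_value=1e9),
        st.floats(min_value=0.01, max_value=5.0),
        st.floats(min_value=0.1, max_value=3.0),
        st.floats(min_value=0.01, max_value=10.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_direct_formula(self, e, t, d, lam, s):
        k = KillingParameters(d=d, lam=lam, s=s)
        ratio = (e / t) ** lam
        assert killing_rate(e, t, k) == pytest.approx(
            d * ratio / (s + ratio) * t, rel=1e-12)

    def test_saturates_at_maximal_rate(self):
        k = KillingParameters(d=1.0, lam=1.2, s=0.05)
        assert killing_rate(1e12, 1e3, k) == pytest.approx(1e3, rel=1e-3)


class TestAntigenCycle:
    def test_killing_fifty_cells_releases_five_thousand_antigens(self):
        state = CellState()  # zero cancer cells: no natural turnover
        d = antigen_cycle_rhs(state, 100.0, 200.0, AntigenCycleParameters(),
                              kill_flux=50.0)
        assert d[STATE_INDEX["TAA_t"]] == pytest.approx(5000.0)

    def test_no_death_no_release(self):
        state = CellState()
        d = antigen_cycle_rhs(state, 100.0, 200.0, AntigenCycleParameters())
        assert d[STATE_INDEX["TAA_t"]] == 0.0

    def test_taa_mass_balance_identity(self):
        rng = np.random.default_rng(8)
        a = AntigenCycleParameters()
        for _ in range(10):
            state = CellState(rng.uniform(0, 1e6, N_IMMUNE))
            kill = rng.uniform(0, 1e4)
            d = antigen_cycle_rhs(state, a.antigen_per_cell, 200.0, a,
                                  kill_flux=kill)
            release = a.antigen_per_cell * (a.cancer_turnover * state["C"] + kill)
            uptake = a.k_uptake * state["APC_t"] * state["TAA_t"]
            drain = a.k_taa_drain * state["TAA_t"]
            deg = a.k_taa_degrade * state["TAA_t"]
            assert d[STATE_INDEX["TAA_t"]] == pytest.approx(
                release - uptake - drain - deg, rel=1e-12)

    def test_each_tdln_receives_equal_share(self):
        state = CellState()
        state["mAPC_t"] = 3.2e5
        a = AntigenCycleParameters()
        d32 = antigen_cycle_rhs(state, 100.0, 200.0, a, n_tdln=32.0)
        d16 = antigen_cycle_rhs(state, 100.0, 200.0, a, n_tdln=16.0)
        assert d32[STATE_INDEX["mAPC_ln"]] * 2 == pytest.approx(
            d16[STATE_INDEX["mAPC_ln"]])


class TestTrafficking:
    def test_zero_effectors_zero_derivatives(self):
        d = trafficking_rhs(CellState(), TraffickingParameters())
        assert np.allclose(d, 0.0)

    def test_conservation_without_elimination(self):
        rng = np.random.default_rng(11)
        t = TraffickingParameters()
        for _ in range(5):
            state = CellState(rng.uniform(0, 1e6, N_IMMUNE))
            d = trafficking_rhs(state, t, eliminate=False)
            assert d[TRAFFIC_SLICE].sum() == pytest.approx(0.0, abs=1e-6)

    def test_steady_state_matches_linear_solve(self):
        """Constant influx into blood: the stationary distribution solves
        A x = -b."""
        t = TraffickingParameters()
        a = trafficking_matrix(t, chemokine_factor=200.0, tumor_diameter_mm=40.0)
        b = np.zeros(len(TRAFFIC_STATES))
        b[0] = 1e5  # cells/day into blood
        x_direct = np.linalg.solve(a, -b)

        from scipy.integrate import solve_ivp

        sol = solve_ivp(lambda _, x: a @ x + b, (0.0, 2000.0),
                        np.zeros_like(b), rtol=1e-10, atol=1e-4)
        assert np.allclose(sol.y[:, -1], x_direct, rtol=1e-5)

    def test_chemokine_scales_tumor_arrest(self):
        t = TraffickingParameters()
        lo = trafficking_matrix(t, 50.0, 40.0)
        hi = trafficking_matrix(t, 500.0, 40.0)
        i_b = list(TRAFFIC_STATES).index("E_tumor_bound")
        i_a = list(TRAFFIC_STATES).index("E_tumor_arrest")
        assert hi[i_a, i_b] == pytest.approx(10 * lo[i_a, i_b])

    def test_tumor_interstitium_is_absorbing(self):
        t = TraffickingParameters()
        a = trafficking_matrix(t, 200.0, 40.0, eliminate=False)
        i_ti = list(TRAFFIC_STATES).index("E_tumor_int")
        col = a[:, i_ti].copy()
        col[i_ti] = 0.0
        assert np.allclose(col, 0.0)  # no exit path back to circulation


class TestRegulatoryPopulations:
    def test_zero_cancer_cells(self):
        _, treg_t, mdsc = regulatory_populations(CellState(), 0.2, 0.001)
        assert treg_t == 0.0 and mdsc == 0.0

    def test_mdsc_is_three_times_tregs(self):
        state = CellState()
        state["C"] = 1e5
        _, treg_t, mdsc = regulatory_populations(state, 0.2, 0.001,
                                                 mdsc_multiplier=3.0)
        assert treg_t == pytest.approx(100.0)
        assert mdsc == pytest.approx(300.0)

    def test_ln_tregs_fraction_of_t_cells(self):
        treg_ln, _, _ = regulatory_populations(CellState(), 0.2, 0.0,
                                               t_total_ln=1e6)
        assert treg_ln == pytest.approx(2e5)


class TestTumorGeometry:
    def test_roundtrip_identity(self):
        g = TumorGeometry()
        d0 = 47.5
        assert cells_to_diameter(diameter_to_cells(d0, g), g) == pytest.approx(
            d0, rel=1e-10)

    def test_cubic_scaling(self):
        g = TumorGeometry()
        assert diameter_to_cells(80.0, g) == pytest.approx(
            8.0 * diameter_to_cells(40.0, g), rel=1e-12)

    @pytest.mark.parametrize("d", [15.0, 80.0])
    def test_trial_range_admissible(self, d):
        g = TumorGeometry()
        assert diameter_to_cells(d, g) > 0

    def test_nonpositive_input_rejected(self):
        with pytest.raises(ValueError):
            diameter_to_cells(0.0, TumorGeometry())
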