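"""Assembled system: initialization, event handling, determinism,
tolerance stability, and fast-kernel consistency."""

import numpy as np
import pytest

from icbsim import ModelParams, PatientParameters, SolverSettings, simulate
from icbsim import regimens
from icbsim.engine import AssembledModel, initialize
from icbsim.immune import N_IMMUNE, diameter_to_cells


@pytest.fixture(scope="module")
def params():
    return ModelParams(patient=PatientParameters())


class TestFastKernel:
    def test_matches_readable_rhs(self, params):
        """The compiled kernel and the composed module functions are the
        same equations."""
        model = AssembledModel(params, drugs=["antiPD1", "antiCTLA4"])
        rates = {"antiPD1": 120.0, "antiCTLA4": 40.0}
        fast = model.make_rhs(rates)
        rng = np.random.default_rng(0)
        scale = np.array([1e5] * 8 + [1e6] * 16 + [2e9, 1e5, 1e5, 1e8]
                         + [50.0] * 10)
        for _ in range(20):
            y = rng.uniform(0, 1, model.n_states) * scale
            a = fast(0.0, y)
            b = model.rhs(0.0, y, rates)
            assert np.allclose(a, b, rtol=1e-12, atol=1e-9)


class TestInitialize:
    def test_reaches_start_diameter(self, params):
        model, y = initialize(params)
        c_start = diameter_to_cells(params.patient.tumor_diameter_start,
                                    params.geometry)
        assert y[model.i_c] == pytest.approx(c_start, rel=1e-3)

    def test_immune_state_drift_is_slow_at_handoff(self, params):
        """The returned state is quasi-steady: no immune species is on a
        fast transient (relative drift well below its turnover scale; the
        residual few %/day reflects tracking of the still-growing tumor)."""
        model, y = initialize(params)
        d = model.rhs(0.0, y, None)
        for i in range(N_IMMUNE):
            if i == model.i_c or y[i] < 1.0:
                continue
            assert abs(d[i]) / y[i] < 0.2

    def test_impossible_growth_raises_with_parameter_name(self):
        from dataclasses import replace

        from icbsim.engine import InitializationError

        p = ModelParams(patient=PatientParameters())
        p.growth = replace(p.growth, growth_rate=1e-7)
        with pytest.raises(InitializationError, match="growth_rate"):
            initialize(p, pre_therapy_cap_days=200.0)


class TestSimulate:
    def test_pre_therapy_growth_monotone(self, params):
        res = simulate(params, regimens.no_therapy(), horizon=120.0)
        assert np.all(np.diff(res.diameter_mm) > -1e-9)

    def test_zero_dose_equals_no_therapy(self, params):
        from icbsim.pbpk import expand_schedule

        zero = expand_schedule("antiPD1", 0.0, 14.0, 4)
        a = simulate(params, zero, horizon=90.0)
        b = simulate(params, regimens.no_therapy(), horizon=90.0)
        assert np.allclose(a.diameter_mm, b.diameter_mm, rtol=1e-6)

    def test_determinism(self, params):
        reg = regimens.anti_pd1(3.0, n_doses=4)
        a = simulate(params, reg, horizon=60.0)
        b = simulate(params, reg, horizon=60.0)
        assert np.array_equal(a.states, b.states)

    def test_tolerance_refinement_stability(self, params):
        """Halving both tolerances moves the final diameter by < 0.1%."""
        reg = regimens.anti_pd1(3.0, n_doses=4)
        base = simulate(params, reg, horizon=60.0,
                        settings=SolverSettings())
        tight = simulate(params, reg, horizon=60.0,
                         settings=SolverSettings(abs_tol=0.5e-9, rel_tol=0.5e-8))
        rel = abs(tight.diameter_mm[-1] - base.diameter_mm[-1]) / base.diameter_mm[-1]
        assert rel < 1e-3

    def test_infusion_mass_balance(self, params):
        """Administered mass = drug in the system + cumulative elimination
        (linear PK)."""
        from icbsim.pbpk import expand_schedule

        reg = expand_schedule("antiPD1", 3.0, 14.0, 1)
        res = simulate(params, reg, horizon=4.0, grid_step=0.005)
        pkp = params.pk["antiPD1"]
        off = res.state_names.index("pk_antiPD1_central")
        amounts = res.states[:, off:off + 5].sum(axis=1)
        conc = res.states[:, off] / pkp.v_central
        eliminated = np.trapezoid(pkp.clearance * conc, res.time)
        dose_mass = 3.0 * params.patient.body_weight
        assert amounts[-1] + eliminated == pytest.approx(dose_mass, rel=1e-3)

    def test_horizon_and_grid(self, params):
        res = simulate(params, regimens.no_therapy(), horizon=30.0)
        assert res.time[0] == 0.0 and res.time[-1] == pytest.approx(30.0)
        assert np.all(np.diff(res.time) > 0)

    def test_invalid_horizon(self, params):
        with pytest.raises(ValueError):
            simulate(params, regimens.no_therapy(), horizon=-1.0)


class TestCheckpointCoupling:
    def test_anti_pd1_lifts_subtype_inhibition(self, params):
        """With anti-PD-1 in the tumor, the average killing inhibition
        across the subtype lattice drops."""
        model = AssembledModel(params, drugs=["antiPD1"])
        ro_free = model.killing_ro({"antiPD1": 0.0})
        ro_blocked = model.killing_ro({"antiPD1": 1e-7})
        fa_free = model.subtype_fa(ro_free)
        fa_blocked = model.subtype_fa(ro_blocked)
        assert float(model.weights @ fa_blocked) < float(model.weights @ fa_free)
        # PD-1:PD-L2 is blocked by anti-PD-1 (axis index 1)
        assert ro_blocked[1] < ro_free[1]

    def test_anti_pdl1_spares_pdl2_axis(self, params):
        model = AssembledModel(params, drugs=["antiPDL1"])
        ro_free = model.killing_ro({"antiPDL1": 0.0})
        ro_blocked = model.killing_ro({"antiPDL1": 1e-7})
        assert ro_blocked[1] == pytest.approx(ro_free[1])   # PD1-PDL2 untouched
        assert ro_blocked[0] < ro_free[0]                   # PD1-PDL1 blocked
        assert ro_blocked[2] < ro_free[2]                   # CD80-PDL1 blocked

    def test_priming_fa_halved_at_baseline_and_reduced_by_drug(self, params):
        model = AssembledModel(params, drugs=["antiCTLA4"])
        assert model.priming_fa({"antiCTLA4": 0.0}) == pytest.approx(0.5, abs=1e-12)
        assert model.priming_fa({"antiCTLA4": 5e-8}) < 0.4
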