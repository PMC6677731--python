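"""Molecular layer: equilibrium binding, competition, signal integration,
and the tumor subtype lattice."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from icbsim.checkpoints import (
    AVOGADRO,
    AntibodyBindingSpec,
    CheckpointAxis,
    SignalIntegrationParams,
    build_subtype_lattice,
    competitive_occupancy,
    integrate_signals,
    receptor_occupancy,
)

V_SYN = 1e-15


def two_species_oracle(r_tot, l_tot, kd, v):
    """Bisection on the conservation equation (r0-c)(l0-c) = kd*c."""
    r0, l0 = r_tot / (AVOGADRO * v), l_tot / (AVOGADRO * v)

    def f(c):
        return (r0 - c) * (l0 - c) - kd * c

    c = brentq(f, 0.0, min(r0, l0), xtol=1e-30, rtol=1e-15)
    return c / r0


class TestReceptorOccupancy:
    def test_no_ligand_means_no_binding(self):
        assert receptor_occupancy(1e4, 0.0, 1e-6, V_SYN) == 0.0

    def test_saturation_with_excess_ligand(self):
        kd = 1e-9
        # ligand concentration 1000x kd, ligand >> receptor
        ligand = 1000 * kd * AVOGADRO * V_SYN
        ro = receptor_occupancy(10.0, ligand, kd, V_SYN)
        assert ro == pytest.approx(1.0, abs=1e-2)

    def test_matches_bisection_oracle_near_kd(self):
        # concentrations comparable to kd: the regime where naive formulas fail
        kd = 1e4 / (AVOGADRO * V_SYN)
        got = receptor_occupancy(1e4, 1e4, kd, V_SYN)
        want = two_species_oracle(1e4, 1e4, kd, V_SYN)
        assert got == pytest.approx(want, rel=1e-10)

    @pytest.mark.parametrize("r,l", [(1e3, 1e4), (5e4, 2e3), (7.5e3, 7.5e3)])
    def test_oracle_agreement_across_regimes(self, r, l):
        for kd in (1e-8, 1e-6, 1e-4):
            assert receptor_occupancy(r, l, kd, V_SYN) == pytest.approx(
                two_species_oracle(r, l, kd, V_SYN), rel=1e-10
            )

    def test_invalid_parameters_raise(self):
        with pytest.raises(ValueError):
            receptor_occupancy(1e3, 1e3, 0.0, V_SYN)
        with pytest.raises(ValueError):
            receptor_occupancy(1e3, 1e3, 1e-6, -1.0)

    def test_bounded_by_ligand_availability(self):
        r, l = 1e4, 3e3
        ro = receptor_occupancy(r, l, 1e-9, V_SYN)
        assert 0.0 <= ro <= l / r


def three_species_oracle(axis, a, kd_ab):
    """Root-find the receptor-ligand-antibody equilibrium (antibody bath).

    Unknown: free receptor fr.  Bound complex c = fr*l0/(kd+fr); receptor
    conservation fr*(1 + a/kd_ab) + c = r0.
    """
    r0 = axis.receptor_density / (AVOGADRO * axis.synapse_volume)
    l0 = axis.ligand_density / (AVOGADRO * axis.synapse_volume)
    kd = axis.kd

    def f(fr):
        c = fr * l0 / (kd + fr)
        return fr * (1.0 + a / kd_ab) + c - r0

    fr = brentq(f, 0.0, r0, xtol=1e-30, rtol=1e-15)
    return (fr * l0 / (kd + fr)) / r0


@pytest.fixture
def pd1_axis():
    return CheckpointAxis("PD1-PDL1", 3e3, 8e3, 8.2e-6, V_SYN)


@pytest.fixture
def anti_pd1():
    return AntibodyBindingSpec(drug="antiPD1", kd_ab=3e-9)


class TestCompetitiveOccupancy:
    def test_zero_antibody_equals_drug_free(self, pd1_axis, anti_pd1):
        free = pd1_axis.drug_free_occupancy()
        assert competitive_occupancy(pd1_axis, 0.0, anti_pd1) == pytest.approx(free)

    def test_continuity_at_vanishing_concentration(self, pd1_axis, anti_pd1):
        free = pd1_axis.drug_free_occupancy()
        assert competitive_occupancy(pd1_axis, 1e-15, anti_pd1) == pytest.approx(
            free, rel=1e-5
        )

    def test_complete_blockade_limit(self, pd1_axis, anti_pd1):
        assert competitive_occupancy(pd1_axis, 1e-2, anti_pd1) < 1e-3

    def test_pdl2_axis_immune_to_anti_pdl1(self):
        # anti-PD-L1 cannot prevent the PD-1:PD-L2 interaction
        axis = CheckpointAxis("PD1-PDL2", 3e3, 2e3, 2.3e-6, V_SYN)
        spec = AntibodyBindingSpec(drug="antiPDL1", kd_ab=1e-9)
        free = axis.drug_free_occupancy()
        for conc in (1e-9, 1e-7, 1e-5):
            assert competitive_occupancy(axis, conc, spec) == pytest.approx(free)

    @given(st.floats(min_value=0.0, max_value=1e-5))
    @settings(max_examples=40, deadline=None)
    def test_monotone_nonincreasing_in_concentration(self, conc):
        axis = CheckpointAxis("PD1-PDL1", 3e3, 8e3, 8.2e-6, V_SYN)
        spec = AntibodyBindingSpec(drug="antiPD1", kd_ab=3e-9)
        lo = competitive_occupancy(axis, conc, spec)
        hi = competitive_occupancy(axis, conc * 0.5, spec)
        assert lo <= hi + 1e-12

    @pytest.mark.parametrize("conc", [1e-10, 3e-9, 5e-8, 1e-6])
    def test_matches_three_species_root_oracle(self, pd1_axis, anti_pd1, conc):
        got = competitive_occupancy(pd1_axis, conc, anti_pd1)
        want = three_species_oracle(pd1_axis, conc, anti_pd1.kd_ab)
        assert got == pytest.approx(want, rel=1e-10)

    def test_unknown_pairing_rejected(self):
        with pytest.raises(ValueError):
            AntibodyBindingSpec(drug="antiTIM3", kd_ab=1e-9)


def _axis(ro, ro_max):
    return CheckpointAxis("PD1-PDL1", 1e3, 1e3, 1e-6, V_SYN, ro=ro, ro_max=ro_max)


class TestIntegrateSignals:
    def test_no_signal(self):
        params = SignalIntegrationParams(m=2.0, axes=[_axis(0.0, 0.8), _axis(0.0, 0.3)])
        assert integrate_signals(params) == 0.0

    @pytest.mark.parametrize("m", [1.5, 2.0, 4.0])
    def test_single_axis_at_maximum_gives_half(self, m):
        params = SignalIntegrationParams(m=m, axes=[_axis(0.7, 0.7)])
        assert integrate_signals(params) == pytest.approx(0.5, abs=1e-12)

    def test_two_axis_hand_evaluation(self):
        # w = (0.8, 0.2); S = 0.8*(0.4/0.8) + 0.2*(0.1/0.2) = 0.5
        params = SignalIntegrationParams(
            m=2.0, axes=[_axis(0.4, 0.8), _axis(0.1, 0.2)]
        )
        want = 0.5**2 / (1.0 + 0.5**2)
        assert integrate_signals(params) == pytest.approx(want, abs=1e-12)

    def test_all_ro_max_zero_warns_and_returns_zero(self):
        params = SignalIntegrationParams(m=2.0, axes=[_axis(0.0, 0.0)])
        with pytest.warns(UserWarning):
            assert integrate_signals(params) == 0.0

    def test_hill_coefficient_must_exceed_one(self):
        with pytest.raises(ValueError):
            SignalIntegrationParams(m=1.0)

    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=0.0, max_value=1.0),
                st.floats(min_value=1e-6, max_value=1.0),
            ),
            min_size=1,
            max_size=5,
        ),
        st.floats(min_value=1.01, max_value=6.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_bounded_and_monotone(self, pairs, m):
        axes = [_axis(frac * romax, romax) for frac, romax in pairs]
        fa = integrate_signals(SignalIntegrationParams(m=m, axes=axes))
        assert 0.0 <= fa <= 0.5 + 1e-12
        # raising any single occupancy never decreases the combined effect
        bumped = [a for a in axes]
        bumped[0] = _axis(min(bumped[0].ro_max, bumped[0].ro + 0.1 * bumped[0].ro_max),
                          bumped[0].ro_max)
        fa2 = integrate_signals(SignalIntegrationParams(m=m, axes=bumped))
        assert fa2 >= fa - 1e-12


class TestSubtypeLattice:
    def test_four_checkpoints_give_sixteen_subtypes(self):
        lat = build_subtype_lattice(
            {"PD1": 0.3, "PDL1": 0.6, "PDL2": 0.25, "CD80": 0.1}
        )
        assert lat.n_subtypes == 16
        assert np.count_nonzero(lat.weights) == 16

    def test_two_half_expressed_checkpoints(self):
        lat = build_subtype_lattice({"A": 0.5, "B": 0.5})
        assert np.allclose(lat.weights, [0.25, 0.25, 0.25, 0.25])

    def test_fully_expressed_checkpoint_is_degenerate(self):
        lat = build_subtype_lattice({"A": 1.0})
        assert lat.weights[0] == 0.0 and lat.weights[1] == 1.0

    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            build_subtype_lattice({"A": 1.5})

    def test_mask_semantics(self):
        lat = build_subtype_lattice({"A": 0.6, "B": 0.3})
        # mask 0b01 expresses A only; weight = 0.6 * (1-0.3)
        assert lat.weights[0b01] == pytest.approx(0.6 * 0.7)
        assert lat.expresses(0b01, "A") and not lat.expresses(0b01, "B")

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=6))
    @settings(max_examples=60, deadline=None)
    def test_weights_are_a_probability_distribution(self, fracs):
        lat = build_subtype_lattice({f"c{i}": f for i, f in enumerate(fracs)})
        assert np.all(lat.weights >= 0.0)
        assert lat.weights.sum() == pytest.approx(1.0, abs=1e-12)
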