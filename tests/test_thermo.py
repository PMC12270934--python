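"""Unit and property tests of the freezing-equilibrium model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icecurve import (
    DEFAULT_CONSTANTS,
    SoluteSpec,
    SolutionComposition,
    equilibrium_solute_mole_fraction,
    fit_dissociation_degree,
    freezing_point_colligative,
    hydration_number_from_point,
    ice_content,
    melting_point,
    serum_concentration,
    unfrozen_water_pct,
)
from tests._reference import NACL_FREEZING_POINTS

C = DEFAULT_CONSTANTS


def brute_force_ice_pct(mw_solute: float, conc_pct: float, h: float, t_c: float) -> float:
    """Independent step-by-step oracle: tabulate x_s, free serum water moles
    and bound water moles separately, then assemble the ice percentage."""
    m_solute = conc_pct
    m_water = 100.0 - conc_pct
    x_s = 1.0 - math.exp(C.a - C.b / (t_c + 273.15))
    n_water = m_water / C.molar_mass_water
    n_solute = m_solute / mw_solute
    free_serum_moles = ((1.0 - x_s) / x_s) * n_solute
    bound_moles = n_solute * h
    return 100.0 * C.molar_mass_water * (n_water - free_serum_moles - bound_moles) / (
        m_water + m_solute
    )


class TestFreezingPoint:
    def test_glucose_premix(self, registry):
        comp = SolutionComposition.single(registry.get("glucose"), 11.5)
        assert freezing_point_colligative(comp) == pytest.approx(-1.34, abs=5e-3)

    def test_pure_water_is_zero(self):
        assert freezing_point_colligative(SolutionComposition([])) == 0.0

    def test_ideal_nacl(self, registry):
        # i = 2: 1.86 · 2 · (3/58.4) / 0.097 kg = 1.97 K of depression
        comp = SolutionComposition.single(registry.get("nacl"), 3.0)
        assert freezing_point_colligative(comp) == pytest.approx(-1.97, abs=5e-3)

    def test_additive_over_solutes(self, registry):
        g, s = registry.get("glucose"), registry.get("sucrose")
        mixed = SolutionComposition([(g, 10.0), (s, 10.0)])
        # same water mass in the single-solute references so molalities match
        only_g = -1.86 * (10.0 / 180.0) / 0.080
        only_s = -1.86 * (10.0 / 342.0) / 0.080
        assert freezing_point_colligative(mixed) == pytest.approx(only_g + only_s)

    def test_waterless_composition_rejected(self, registry):
        with pytest.raises(ValueError):
            SolutionComposition.single(registry.get("glucose"), 100.0)


class TestEquilibriumMoleFraction:
    def test_vanishes_where_exponent_cancels(self):
        t_zero = C.b / C.a - 273.15  # = 0 °C for the exact a
        assert equilibrium_solute_mole_fraction(t_zero) == pytest.approx(0.0, abs=1e-12)

    def test_value_at_minus_18(self):
        expected = 1.0 - math.exp(C.a - C.b / 255.15)
        assert equilibrium_solute_mole_fraction(-18.0) == pytest.approx(expected)
        assert equilibrium_solute_mole_fraction(-18.0) == pytest.approx(0.1705, abs=2e-3)

    def test_monotone_in_cold(self):
        assert (
            equilibrium_solute_mole_fraction(-18.0)
            > equilibrium_solute_mole_fraction(-8.0)
            > 0.0
        )

    def test_nonphysical_temperature(self):
        with pytest.raises(ValueError):
            equilibrium_solute_mole_fraction(-300.0)


class TestIceContent:
    def test_glucose_15_example(self, glucose15):
        pt = ice_content(glucose15, 10.5, -18.0)
        assert pt.valid
        assert pt.ice_content_pct == pytest.approx(61.9, abs=0.1)

    def test_all_water_bound_gives_zero_invalid(self, glucose15):
        h_all = glucose15.water_moles / glucose15.total_solute_moles
        pt = ice_content(glucose15, h_all * 1.01, -18.0)
        assert pt.ice_content_pct == 0.0 and not pt.valid

    def test_monotone_in_temperature(self, glucose15):
        cold = ice_content(glucose15, 7.0, -18.0)
        warm = ice_content(glucose15, 7.0, -8.0)
        assert cold.valid and warm.valid
        assert cold.ice_content_pct > warm.ice_content_pct

    def test_monotone_in_concentration_and_h(self, registry):
        g = registry.get("glucose")
        lo = ice_content(SolutionComposition.single(g, 10.0), 5.0, -12.0)
        hi = ice_content(SolutionComposition.single(g, 25.0), 5.0, -12.0)
        assert lo.ice_content_pct > hi.ice_content_pct
        comp = SolutionComposition.single(g, 15.0)
        assert (
            ice_content(comp, 2.0, -12.0).ice_content_pct
            > ice_content(comp, 9.0, -12.0).ice_content_pct
        )

    @given(
        conc=st.floats(5.0, 35.0),
        h=st.floats(0.0, 12.0),
        t=st.floats(-30.0, -5.0),
        mw=st.floats(46.5, 800.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_oracle(self, conc, h, t, mw):
        spec = SoluteSpec("x", mw)
        comp = SolutionComposition.single(spec, conc)
        expected = brute_force_ice_pct(mw, conc, h, t)
        pt = ice_content(comp, h, t)
        assert pt.ice_content_pct == pytest.approx(max(expected, 0.0), abs=1e-9)

    def test_mass_conservation(self, glucose15):
        pt = ice_content(glucose15, 7.0, -15.0)
        ufw = unfrozen_water_pct(glucose15, pt.ice_content_pct)
        water_pct = 100.0 * glucose15.water_mass / glucose15.basis_mass
        assert pt.ice_content_pct + ufw == pytest.approx(water_pct, abs=1e-12)


class TestSerumConcentration:
    def test_sucrose_freeze_concentration(self, registry):
        comp = SolutionComposition.single(registry.get("sucrose"), 15.0)
        assert serum_concentration(comp, 70.0)["sucrose"] == pytest.approx(50.0)

    def test_identity_at_zero_ice(self, glucose15):
        assert serum_concentration(glucose15, 0.0)["glucose"] == pytest.approx(15.0)

    def test_monotone_in_ice(self, glucose15):
        assert (
            serum_concentration(glucose15, 60.0)["glucose"]
            > serum_concentration(glucose15, 30.0)["glucose"]
            > 15.0
        )

    def test_overfrozen_errors(self, glucose15):
        with pytest.raises(ValueError):
            serum_concentration(glucose15, 90.0)  # only 85 % water available


class TestUnfrozenWater:
    def test_difference_of_moisture_and_ice(self, registry):
        comp = SolutionComposition.single(registry.get("glucose"), 11.5)
        assert unfrozen_water_pct(comp, 73.0) == pytest.approx(15.5)

    def test_zero_ice_returns_moisture(self, glucose15):
        assert unfrozen_water_pct(glucose15, 0.0) == pytest.approx(85.0)

    def test_inconsistent_inputs_error(self, glucose15):
        with pytest.raises(ValueError):
            unfrozen_water_pct(glucose15, 90.0)


class TestMeltingPoint:
    def test_agrees_with_colligative_for_dilute_h0(self, registry):
        comp = SolutionComposition.single(registry.get("glucose"), 11.5)
        mp = melting_point(comp, 0.0)
        colligative = freezing_point_colligative(comp)
        assert abs(mp - colligative) / abs(colligative) < 0.05

    def test_h_lowers_melting_point(self, glucose15):
        mps = [melting_point(glucose15, h) for h in (0.0, 5.0, 10.0)]
        assert mps[0] > mps[1] > mps[2]

    def test_pure_water(self):
        assert melting_point(SolutionComposition([]), 0.0) == 0.0

    def test_all_water_bound_errors(self, glucose15):
        h_all = glucose15.water_moles / glucose15.total_solute_moles
        with pytest.raises(ValueError):
            melting_point(glucose15, h_all * 1.5)

    def test_melting_point_zeroes_the_ice_curve(self, glucose15):
        mp = melting_point(glucose15, 7.0)
        pt = ice_content(glucose15, 7.0, mp - 1e-4)
        assert pt.ice_content_pct < 0.05


class TestHydrationInversion:
    def test_round_trip_exact(self, glucose15):
        pt = ice_content(glucose15, 7.0, -18.0)
        assert hydration_number_from_point(glucose15, -18.0, pt.ice_content_pct) == pytest.approx(
            7.0, abs=1e-9
        )

    def test_h0_prediction_inverts_to_zero(self, glucose15):
        pt = ice_content(glucose15, 0.0, -18.0)
        assert hydration_number_from_point(glucose15, -18.0, pt.ice_content_pct) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_glucose_example(self, glucose15):
        h = hydration_number_from_point(glucose15, -18.0, 61.9)
        assert h == pytest.approx(10.5, abs=0.05)

    def test_negative_h_warns_not_clamps(self, glucose15):
        too_much_ice = 84.0  # more ice than the h=0 model allows
        with pytest.warns(UserWarning, match="negative hydration"):
            h = hydration_number_from_point(glucose15, -18.0, too_much_ice)
        assert h < 0

    def test_above_equilibrium_limit_errors(self, glucose15):
        with pytest.raises(ValueError):
            hydration_number_from_point(glucose15, 1.0, 10.0)

    @given(
        conc=st.floats(5.0, 30.0),
        h=st.floats(0.0, 10.0),
        t=st.floats(-35.0, -6.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_inversion_property(self, registry, conc, h, t):
        comp = SolutionComposition.single(registry.get("sucrose"), conc)
        pt = ice_content(comp, h, t)
        if not pt.valid:
            return
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # h within rounding of 0 may warn
            h_back = hydration_number_from_point(comp, t, pt.ice_content_pct)
        assert h_back == pytest.approx(h, abs=1e-9)


class TestDissociationDegree:
    def test_nacl_effective_i(self, registry):
        i = fit_dissociation_degree(registry.get("nacl"), NACL_FREEZING_POINTS)
        assert i == pytest.approx(1.57, abs=0.02)

    def test_exact_recovery(self, registry):
        spec = registry.get("nacl")
        obs = []
        for conc in (2.0, 4.0, 6.0):
            molality = conc / spec.molecular_weight / ((100.0 - conc) / 1000.0)
            obs.append((conc, -1.86 * 2.0 * molality))
        assert fit_dissociation_degree(spec, obs) == pytest.approx(2.0, abs=1e-9)

    def test_single_observation_is_exact_ratio(self, registry):
        spec = registry.get("nacl")
        molality = 3.0 / spec.molecular_weight / 0.097
        i = fit_dissociation_degree(spec, [(3.0, -1.54)])
        assert i == pytest.approx(1.54 / (1.86 * molality), abs=1e-12)

    def test_no_observations_error(self, registry):
        with pytest.raises(ValueError):
            fit_dissociation_degree(registry.get("nacl"), [])
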