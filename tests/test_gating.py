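"""Two-state gating energetics: energy differences, Po curves, sensitivities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from piezomech import (
    FLAT,
    CompartmentSpec,
    GatingScenario,
    MembraneSpec,
    calibrate_delta_gdp,
    cap_from_radius,
    gating_curve,
    gating_energy,
    open_probability,
    tension_sensitivity,
)


@pytest.fixture(scope="module")
def flat_open_scenario():
    """Closed dome R=10.2 nm opening to an exactly flat state, Kb=20 kBT."""
    return GatingScenario(
        closed=cap_from_radius(10.2, 390.0),
        open=FLAT,
        membrane=MembraneSpec(20.0, 0.1),
    )


class TestOpenProbability:
    def test_symmetry_and_fixed_points(self):
        assert open_probability(0.0) == 0.5
        assert open_probability(np.log(9.0)) == pytest.approx(0.1)
        assert open_probability(-np.log(9.0)) == pytest.approx(0.9)

    @given(dg=st.floats(-30, 30))
    @settings(max_examples=100, derandomize=True)
    def test_boltzmann_inversion_identity(self, dg):
        # ln(Po/(1-Po)) = -dG.  Recovering dG from a float64 Po is limited by
        # the representation of min(Po, 1-Po): error ~ eps * e^{|dG|}
        po = open_probability(dg)
        tol = 1e-10 + 4e-16 * np.exp(abs(dg))
        assert np.log(po) - np.log1p(-po) == pytest.approx(-dg, abs=tol)

    def test_numerically_stable_at_extreme_energies(self):
        assert open_probability(1000.0) == 0.0
        assert open_probability(-1000.0) == 1.0
        assert 0 < open_probability(700.0) < 1e-300 or open_probability(700.0) == 0.0


class TestGatingEnergy:
    def test_flat_open_state_membrane_terms(self, flat_open_scenario):
        en = gating_energy(flat_open_scenario, 0.1)
        # open state exactly flat: all its membrane terms vanish, so the
        # differences are minus the closed-state dome terms
        assert en.open.dome_bending == 0.0 and en.open.footprint == 0.0
        assert en.delta_dome_bending == pytest.approx(-149.9, abs=0.1)
        assert en.delta_dome_tension == pytest.approx(-11.63, abs=0.01)
        assert en.delta_footprint < 0
        assert en.delta_total == pytest.approx(
            en.delta_gdp + en.delta_dome_bending + en.delta_dome_tension + en.delta_footprint
        )

    def test_identical_states_no_gating(self):
        cap = cap_from_radius(10.2, 390.0)
        sc = GatingScenario(closed=cap, open=cap, membrane=MembraneSpec(20.0, 0.1), delta_gdp=3.0)
        en = gating_energy(sc, 0.1)
        assert en.delta_dome_bending == 0.0
        assert en.delta_dome_tension == 0.0
        assert en.delta_footprint == pytest.approx(0.0, abs=1e-8)
        assert en.delta_total == pytest.approx(3.0)

    def test_inverted_radii_rejected(self):
        with pytest.raises(ValueError, match="Rc <= Ro"):
            GatingScenario(
                closed=cap_from_radius(11.2, 390.0),
                open=cap_from_radius(10.2, 390.0),
                membrane=MembraneSpec(20.0, 0.1),
            )

    def test_zero_tension_footprint_of_no_consequence(self, flat_open_scenario):
        # at gamma = 0 both the dome tension work and the footprint term vanish
        en = gating_energy(flat_open_scenario, 0.0)
        assert en.delta_dome_tension == 0.0
        assert en.delta_footprint == 0.0
        assert en.delta_total == pytest.approx(en.delta_gdp + en.delta_dome_bending)


class TestTensionSensitivity:
    def test_dome_part_is_constant_excess_area(self, flat_open_scenario):
        s1 = tension_sensitivity(flat_open_scenario, 0.05, include_footprint=False)
        s2 = tension_sensitivity(flat_open_scenario, 0.2, include_footprint=False)
        assert s1["dG_dgamma"] == pytest.approx(-116.34, abs=0.01)
        assert s2["dG_dgamma"] == pytest.approx(s1["dG_dgamma"])

    def test_envelope_vs_finite_difference(self, flat_open_scenario):
        env = tension_sensitivity(flat_open_scenario, 0.05, method="envelope")
        fd = tension_sensitivity(flat_open_scenario, 0.05, method="fd", step=1e-3)
        assert fd["dG_dgamma"] == pytest.approx(env["dG_dgamma"], rel=0.01)

    def test_magnitude_diverges_toward_zero_tension(self, flat_open_scenario):
        gammas = np.geomspace(1e-3, 1e-1, 5)
        sens = [
            abs(tension_sensitivity(flat_open_scenario, g)["dG_dgamma"]) for g in gammas
        ]
        assert all(a > b for a, b in zip(sens, sens[1:]))

    def test_identical_states_zero_sensitivity(self):
        cap = cap_from_radius(10.2, 390.0)
        sc = GatingScenario(closed=cap, open=cap, membrane=MembraneSpec(20.0, 0.1))
        s = tension_sensitivity(sc, 0.05)
        assert s["dG_dgamma"] == pytest.approx(0.0, abs=1e-6)


class TestCalibration:
    def test_midpoint_condition(self, flat_open_scenario):
        dgdp = calibrate_delta_gdp(flat_open_scenario, 0.05)
        sc = flat_open_scenario.with_delta_gdp(dgdp)
        po = open_probability(gating_energy(sc, 0.05).delta_total)
        assert po == pytest.approx(0.5, abs=1e-6)

    def test_calibrated_offset_positive_and_monotone(self, flat_open_scenario):
        # membrane terms favor the open state, so the closed state must be
        # protein-stabilized; a higher midpoint tension needs a larger offset
        d1 = calibrate_delta_gdp(flat_open_scenario, 0.03)
        d2 = calibrate_delta_gdp(flat_open_scenario, 0.1)
        assert d1 > 0 and d2 > d1

    def test_invalid_midpoint(self, flat_open_scenario):
        with pytest.raises(ValueError):
            calibrate_delta_gdp(flat_open_scenario, 0.0)


@pytest.fixture(scope="module")
def calibrated_curve(flat_open_scenario):
    """Activation curve for the flat-open scenario, midpoint pinned at 0.05."""
    sc = flat_open_scenario.with_delta_gdp(calibrate_delta_gdp(flat_open_scenario, 0.05))
    grid = np.geomspace(0.005, 0.3, 15)
    return gating_curve(sc, grid)


class TestGatingCurves:
    def test_po_monotone_nondecreasing(self, calibrated_curve):
        assert np.all(np.diff(calibrated_curve.open_probability) >= -1e-12)
        assert np.all((calibrated_curve.open_probability >= 0)
                      & (calibrated_curve.open_probability <= 1))

    def test_dG_decreasing_in_tension(self, calibrated_curve):
        assert np.all(calibrated_curve.dG_dgamma <= 0)
        assert np.all(np.diff(calibrated_curve.delta_total) <= 1e-9)

    def test_footprint_shifts_activation_to_lower_tension(self, calibrated_curve):
        # with the footprint included, Po reaches every level at smaller
        # tension than dome-only at the same protein offset
        cv = calibrated_curve
        assert cv.dome_only is not None
        assert np.all(cv.open_probability >= cv.dome_only.open_probability - 1e-12)
        g_half = np.interp(0.5, cv.open_probability, cv.tensions)
        g_half_dome = np.interp(0.5, cv.dome_only.open_probability, cv.tensions)
        assert g_half < g_half_dome

    def test_footprint_steepens_activation(self, calibrated_curve):
        cv = calibrated_curve
        assert cv.dPo_dgamma.max() > cv.dome_only.dPo_dgamma.max()
        assert np.all(cv.dPo_dgamma >= 0)

    def test_footprint_term_comparable_to_dome_term(self):
        # for all three conformational-pair geometries there is a tension
        # range where |dGM| is at least as large as |dGDgamma|
        pairs = [
            (10.2, None),  # flat open state
            (10.2, 11.2),
            (20.0, None),
        ]
        gammas = np.geomspace(0.005, 0.3, 8)
        for rc, ro in pairs:
            sc = GatingScenario(
                closed=cap_from_radius(rc, 390.0),
                open=FLAT if ro is None else cap_from_radius(ro, 390.0),
                membrane=MembraneSpec(20.0, 0.1),
            )
            cv = gating_curve(sc, gammas, include_dome_only=False)
            ratio = np.abs(cv.delta_footprint) / np.abs(cv.delta_dome_tension)
            assert np.any(ratio >= 1.0)

    def test_bending_modulus_modulates_gating(self):
        # the activation midpoint depends on Kb through dGDb + dGM
        closed = cap_from_radius(10.2, 390.0)
        mids = []
        for kb in (10.0, 20.0, 40.0):
            sc = GatingScenario(
                closed=closed, open=FLAT, membrane=MembraneSpec(kb, 0.1),
                delta_gdp=270.0,
            )
            cv = gating_curve(sc, np.geomspace(0.01, 1.5, 10), include_dome_only=False)
            mids.append(np.interp(0.0, -cv.delta_total, cv.tensions))
        assert len({round(m, 4) for m in mids}) == 3

    def test_compartment_scenario_runs(self):
        sc = GatingScenario(
            closed=cap_from_radius(10.2, 390.0),
            open=FLAT,
            membrane=MembraneSpec(20.0, 0.1),
            compartment=CompartmentSpec.finite(5.0),
        )
        cv = gating_curve(sc, np.array([0.01, 0.05]), include_dome_only=False)
        # the clamped compartment raises the closed-state footprint energy,
        # favoring the open state relative to the infinite membrane
        sc_inf = GatingScenario(
            closed=sc.closed, open=FLAT, membrane=sc.membrane
        )
        cv_inf = gating_curve(sc_inf, np.array([0.01, 0.05]), include_dome_only=False)
        assert np.all(cv.delta_footprint <= cv_inf.delta_footprint + 1e-9)

    def test_bad_grid_rejected(self, flat_open_scenario):
        with pytest.raises(ValueError):
            gating_curve(flat_open_scenario, [])
        with pytest.raises(ValueError):
            gating_curve(flat_open_scenario, [0.1, 0.05])
        with pytest.raises(ValueError):
            gating_curve(flat_open_scenario, [-0.1, 0.05])
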