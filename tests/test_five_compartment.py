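"""Reference-model construction, scenarios and full steady-state tables.

The expected values below are the published steady states of this
classic five-compartment circulation in its normal state and two
perturbations; each cell is checked within one unit of its last
printed digit.
"""

import pytest

from steadycirc import (
    apply_scenario,
    build_reference_model,
    conservation_coefficients,
    derived_hemodynamics,
    get_parameter,
    reduced_mu_lambda,
    solve_general,
    steady_state,
    Scenario,
)

# variable -> {scenario: printed value}; tolerance = 1 unit in the last digit
EXPECTED = {
    "mu": {"normal": "0.326", "case1": "0.536", "case2": "0.372"},
    "lambda": {"normal": "0.0838", "case1": "0.138", "case2": "0.0838"},
    "Z": {"normal": "0.370", "case1": "0.523", "case2": "0.404"},
    "Q": {"normal": "5", "case1": "7.1", "case2": "5.5"},
    "P_R": {"normal": "0", "case1": "0.70", "case2": "-3.8"},
    "P_lungs": {"normal": "10", "case1": "14", "case2": "7"},
    "P_L": {"normal": "4", "case1": "5.9", "case2": "0.4"},
    "P_viscera": {"normal": "8", "case1": "5.5", "case2": "4.9"},
    "P_periphery": {"normal": "4", "case1": "9.6", "case2": "0.5"},
    "PA": {"normal": "100", "case1": "116", "case2": "105"},
    "PPA": {"normal": "13", "case1": "19", "case2": "10"},
    "V_right_atrium": {"normal": "0.15", "case1": "0.16", "case2": "0.15"},
    "V_lungs": {"normal": "0.50", "case1": "0.56", "case2": "0.52"},
    "V_left_atrium": {"normal": "0.20", "case1": "0.22", "case2": "0.20"},
    "V_viscera": {"normal": "2.94", "case1": "2.62", "case2": "3.06"},
    "V_periphery": {"normal": "0.76", "case1": "0.98", "case2": "0.62"},
    "TPR": {"normal": "20", "case1": "16", "case2": "20"},
    "f4": {"normal": "0.50", "case1": "0.21", "case2": "0.50"},
    "f5": {"normal": "0.50", "case1": "0.79", "case2": "0.50"},
}


# The published case-1 CVP cell (0.70) is internally inconsistent with the
# published Q = 7.1 (inverting the right cardiac curve at 7.1 gives 0.73;
# full-precision solving gives 0.715), so that single cell gets a wider band.
TOLERANCE_OVERRIDES = {("P_R", "case1"): 0.02}


def last_digit_tolerance(printed: str) -> float:
    """One unit in the last printed digit (ignoring sign)."""
    if "." in printed:
        return 10.0 ** -(len(printed.split(".")[1]))
    return 1.0


def cell_tolerance(variable: str, scenario: str, printed: str) -> float:
    return TOLERANCE_OVERRIDES.get(
        (variable, scenario), last_digit_tolerance(printed)
    )


def model_value(model, state, variable):
    if variable in ("mu", "lambda"):
        rf = reduced_mu_lambda(model)
        return rf.mu if variable == "mu" else rf.lam
    if variable in ("Z", "Q", "P_R", "P_L"):
        return getattr(state, variable)
    if variable in ("PA", "PPA", "TPR", "f4", "f5"):
        return getattr(derived_hemodynamics(model, state), variable)
    if variable.startswith("P_"):
        return state.pressures[variable[2:]]
    if variable.startswith("V_"):
        return state.volumes[variable[2:]]
    raise KeyError(variable)


class TestReferenceModel:
    def test_structure(self, reference_model):
        m = reference_model
        assert len(m.compartments) == 5
        assert sum(c.circuit == "right_atrium" for c in m.compartments) == 1
        assert sum(c.circuit == "left_atrium" for c in m.compartments) == 1
        assert m.BV == pytest.approx(5.000)
        assert m.balanced

    def test_stressed_volume(self, reference_model):
        # 5.000 - 0.452 - (0.102+0.290+0.102+1.380+0.600)
        assert reference_model.delta_BV == pytest.approx(2.074, abs=1e-12)

    def test_bundled_config_equals_builder(self, reference_model):
        from steadycirc import reference_config_path
        from steadycirc.io import read_model

        assert read_model(reference_config_path()) == reference_model


class TestScenarios:
    def test_case1_overrides(self, reference_model):
        m = apply_scenario(reference_model, "case1")
        assert get_parameter(m, "RA_viscera") == 73.6
        assert get_parameter(m, "RA_periphery") == 19.2
        # everything else untouched
        assert get_parameter(m, "RV_viscera") == 3.2
        assert get_parameter(m, "P_e") == -4.0
        assert m.BV == reference_model.BV

    def test_case2_overrides(self, reference_model):
        m = apply_scenario(reference_model, "case2")
        assert get_parameter(m, "P_e") == -8.0
        assert get_parameter(m, "P_a") == -8.0
        assert m.right_heart.P_ext == -8.0
        assert m.compartment("periphery").P_ext == 0.0  # not in any cavity
        assert get_parameter(m, "RA_viscera") == 36.8

    def test_base_model_is_unmodified(self, reference_model):
        before = reference_model
        apply_scenario(reference_model, "case1")
        assert reference_model == before

    def test_empty_override_is_identity(self, reference_model):
        assert (
            apply_scenario(reference_model, Scenario("noop", {}))
            == reference_model
        )

    def test_unknown_scenario_rejected(self, reference_model):
        with pytest.raises(KeyError):
            apply_scenario(reference_model, "case99")
        with pytest.raises(KeyError):
            apply_scenario(reference_model, Scenario("bad", {"bogus": 1.0}))


class TestSteadyStateTables:
    @pytest.mark.parametrize("variable", sorted(EXPECTED))
    def test_all_printed_cells_reproduced(
        self, variable, scenario_models, scenario_states
    ):
        """Every steady-state table cell, in all three scenarios, within
        one unit of its last printed digit."""
        for scenario, printed in EXPECTED[variable].items():
            value = model_value(
                scenario_models[scenario], scenario_states[scenario], variable
            )
            tol = cell_tolerance(variable, scenario, printed)
            assert value == pytest.approx(float(printed), abs=tol), (
                f"{variable} in {scenario}: got {value}, printed {printed}"
            )

    def test_case1_headline_deltas(self, scenario_models, scenario_states):
        """Resistance redistribution: cardiac output up ~42%, and nearly
        80% of the flow through the periphery."""
        q0 = scenario_states["normal"].Q
        q1 = scenario_states["case1"].Q
        assert 100.0 * (q1 - q0) / q0 == pytest.approx(42.0, abs=1.0)
        dh = derived_hemodynamics(scenario_models["case1"], scenario_states["case1"])
        assert dh.f5 == pytest.approx(0.79, abs=0.01)
        assert dh.PA == pytest.approx(116.0, abs=1.0)

    def test_derived_hemodynamics_symmetric_branches(self, reference_model):
        st = steady_state(reference_model)
        dh = derived_hemodynamics(reference_model, st)
        # equal branch totals (40 = 40) split flow exactly in half
        assert dh.f4 == 0.5
        assert dh.f4 + dh.f5 == pytest.approx(1.0, abs=1e-15)
        assert 1.0 / dh.TPR == pytest.approx(1.0 / 40.0 + 1.0 / 40.0)


class TestTopologyIndependence:
    def test_merged_systemic_bed_same_output(self, reference_model):
        """A structurally different model with matched reduced parameters
        (CS, CP, CR, D) has the same cardiac output: the solution depends
        only on the reduced form, not the arrangement of compartments."""
        from steadycirc import CirculationModel, Compartment

        base = reference_model
        rf = conservation_coefficients(base)
        visc = base.compartment("viscera")
        peri = base.compartment("periphery")
        C_m = visc.C + peri.C
        # choose RV so C_m * RV matches the systemic share of CR, and
        # P_ext so the compliance-weighted external pressure matches D
        cr_systemic = rf.CR - base.compartment("lungs").C * 1.2
        RV_m = cr_systemic / C_m
        P_ext_m = (visc.C * visc.P_ext + peri.C * peri.P_ext) / C_m
        merged = Compartment(
            "body", "systemic", C=C_m, V0n=visc.V0n + peri.V0n,
            P_ext=P_ext_m, RA=20.0 - RV_m, RV=RV_m,
        )
        comps = tuple(
            c for c in base.compartments if c.id not in ("viscera", "periphery")
        ) + (merged,)
        model4 = CirculationModel(
            right_heart=base.right_heart, left_heart=base.left_heart,
            compartments=comps, pulmonary_topology="lungs",
            systemic_topology="body", BV=base.BV, V0=base.V0,
        )
        rf4 = conservation_coefficients(model4)
        assert rf4.CS == pytest.approx(rf.CS, abs=1e-14)
        assert rf4.CR == pytest.approx(rf.CR, abs=1e-14)
        assert rf4.D == pytest.approx(rf.D, abs=1e-14)
        assert solve_general(model4) == pytest.approx(
            solve_general(base), rel=1e-9
        )
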