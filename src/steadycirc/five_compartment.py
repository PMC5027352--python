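"""The bundled five-compartment reference circulation.

A classic minimal closed-loop layout: right atrium -> lungs -> left
atrium -> (viscera parallel periphery) -> back to the right atrium,
with the heart, lungs and both atria inside the chest (shared
intrathoracic pressure ``P_e``) and the viscera inside the abdomen
(abdominal pressure ``P_a``).  External pressure on the peripheral bed
is ignored (fixed at 0).  Both heart sides share the same maximum
output K, so the balanced single-equation form applies.

Two standard perturbation scenarios accompany the normal state:

* ``case1`` — redistribution of systemic resistance: visceral arterial
  resistance doubled (36.8 -> 73.6) and peripheral arterial resistance
  halved (38.4 -> 19.2).  Only the conservation plane moves; cardiac
  output rises sharply and most flow shifts to the periphery.
* ``case2`` — chest and abdominal pressures lowered from -4 to
  -8 mmHg (the acute central shift studied in early spaceflight
  physiology): central venous pressure falls by nearly 4 mmHg while
  cardiac output and arterial pressure rise only modestly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Union

from .errors import ModelError
from .model import (
    CardiacCurve,
    CirculationModel,
    Compartment,
    PressureGroup,
    SteadyState,
)
from .network import derive_g_coefficients, equivalent_resistance, parallel
from .parameters import parameter_names, set_parameter

__all__ = [
    "Scenario",
    "SCENARIOS",
    "DerivedHemodynamics",
    "build_reference_model",
    "apply_scenario",
    "derived_hemodynamics",
    "reference_config_path",
]


@dataclass(frozen=True)
class Scenario:
    """A named set of parameter overrides applied to a base model."""

    name: str
    overrides: Mapping[str, float]


SCENARIOS = {
    "normal": Scenario("normal", {}),
    "case1": Scenario("case1", {"RA_viscera": 73.6, "RA_periphery": 19.2}),
    "case2": Scenario("case2", {"P_e": -8.0, "P_a": -8.0}),
}


def build_reference_model() -> CirculationModel:
    """The five-compartment reference model at its normal parameter values.

    Blood volume 5.000 L (0.452 L non-capacitive), chest pressure
    -4 mmHg, abdominal pressure -4 mmHg, balanced hearts with
    K = 13.5 L/min.
    """
    Pe, Pa = -4.0, -4.0
    return CirculationModel(
        right_heart=CardiacCurve(K=13.5, alpha=55.2, beta=0.870, P_ext=Pe),
        left_heart=CardiacCurve(K=13.5, alpha=23.1, beta=0.326, P_ext=Pe),
        compartments=(
            Compartment("right_atrium", "right_atrium", C=0.012, V0n=0.102, P_ext=Pe),
            Compartment("lungs", "pulmonary", C=0.015, V0n=0.290, P_ext=Pe, RA=0.6, RV=1.2),
            Compartment("left_atrium", "left_atrium", C=0.012, V0n=0.102, P_ext=Pe),
            Compartment("viscera", "systemic", C=0.130, V0n=1.380, P_ext=Pa, RA=36.8, RV=3.2),
            Compartment("periphery", "systemic", C=0.040, V0n=0.600, P_ext=0.0, RA=38.4, RV=1.6),
        ),
        pulmonary_topology="lungs",
        systemic_topology=parallel("viscera", "periphery"),
        BV=5.000,
        V0=0.452,
        pressure_groups=(
            PressureGroup("P_e", ("right_atrium", "lungs", "left_atrium"), include_heart=True),
            PressureGroup("P_a", ("viscera",), include_heart=False),
        ),
    )


def apply_scenario(
    model: CirculationModel, scenario: Union[str, Scenario]
) -> CirculationModel:
    """Return a new model with the scenario's overrides applied.

    The base model is never modified.  Override names must exist on the
    base model; unknown scenario names raise ``KeyError`` listing the
    available ones.
    """
    if isinstance(scenario, str):
        try:
            scenario = SCENARIOS[scenario]
        except KeyError:
            raise KeyError(
                f"unknown scenario {scenario!r}; available: "
                f"{', '.join(sorted(SCENARIOS))}"
            ) from None
    known = set(parameter_names(model))
    unknown = set(scenario.overrides) - known
    if unknown:
        raise KeyError(
            f"scenario {scenario.name!r} overrides unknown parameter(s) "
            f"{sorted(unknown)}"
        )
    out = model
    for name, value in scenario.overrides.items():
        out = set_parameter(out, name, value)
    return out


@dataclass(frozen=True)
class DerivedHemodynamics:
    """Derived quantities of a solved state.

    TPR is the equivalent resistance of the (parallel) systemic beds;
    f4/f5 the visceral and peripheral flow fractions; PA the systemic
    arterial pressure reconstructed upstream of the beds
    (``P_R + TPR*Q``); PPA the pulmonary arterial pressure
    (``P_L + R_pulmonary * Q``).
    """

    TPR: float
    f4: float
    f5: float
    PA: float
    PPA: float
    flow_fractions: Mapping[str, float]


def derived_hemodynamics(
    model: CirculationModel, state: SteadyState
) -> DerivedHemodynamics:
    """Compute TPR, flow fractions and arterial pressures from a solved state."""
    sysnet = model.systemic_network()
    tpr = equivalent_resistance(sysnet)
    fractions = dict(derive_g_coefficients(sysnet).fractions)
    if "viscera" in fractions and "periphery" in fractions:
        f4, f5 = fractions["viscera"], fractions["periphery"]
    elif len(fractions) == 1:
        f4, f5 = 1.0, 0.0
    else:
        raise ModelError(
            "flow-fraction split requires 'viscera'/'periphery' compartments "
            "(or a single systemic bed)"
        )
    r_pulmonary = equivalent_resistance(model.pulmonary_network())
    return DerivedHemodynamics(
        TPR=tpr,
        f4=f4,
        f5=f5,
        PA=state.P_R + tpr * state.Q,
        PPA=state.P_L + r_pulmonary * state.Q,
        flow_fractions=fractions,
    )


def reference_config_path():
    """Path to the bundled YAML config equivalent to
    :func:`build_reference_model` (for CLI use and round-trip checks)."""
    from importlib.resources import files

    return files("steadycirc.data") / "five_compartment.yaml"
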