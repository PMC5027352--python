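"""Exact and finite-difference parameter sensitivities.

In the balanced special case the steady state satisfies

    Q = gamma + omega * log((K - Q) / Q),   gamma = K*mu, omega = K*lam,

so differentiating implicitly with respect to any parameter p gives

    dQ/dp = [ dgamma/dp + ((Q - gamma)/omega) * domega/dp
              + omega/(K - Q) * dK/dp ]
            / [ 1 + K*omega / (Q*(K - Q)) ].

The (Q - gamma)/omega factor is just log((K - Q)/Q) evaluated at the
operating point; the dK/dp term is nonzero only when the parameter is
the maximum cardiac output itself, which appears in the equation
outside gamma and omega.

``analytic`` mode evaluates this formula with dgamma/dp and domega/dp
obtained in closed form for shared-external-pressure parameters
(pressure groups: dgamma/dp = [sum of member compliances - (CS+CP) if
the heart is included]/CR, domega/dp = 0) and by central differences of
the *reduced parameters* — cheap arithmetic, no re-solving — otherwise.
``finite_difference`` mode re-solves the full model at p +/- h and
differences Q directly; it works for unbalanced models too and serves
as the independent cross-check.

The customary dimensionless sensitivity (elasticity) is
d(log v)/d(log p) = (dv/dp) * p / v, computed with signed values (a
negative parameter like intrathoracic pressure can yield a positive
elasticity); it is undefined (NaN) at p = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

from .errors import SpecialCaseError
from .five_compartment import derived_hemodynamics
from .model import CirculationModel, evaluate_state
from .parameters import get_parameter, parameter_names, set_parameter
from .solvers import reduced_mu_lambda, solve_general

__all__ = [
    "SensitivityResult",
    "gamma_omega",
    "dQ_dp",
    "derived_variable_sensitivity",
    "variable_value",
]

_K_NAMES = ("K", "K_R", "K_L")


@dataclass(frozen=True)
class SensitivityResult:
    """Sensitivity of cardiac output to one parameter."""

    parameter: str
    dQ_dp: float  #: (L/min) per parameter unit
    log_sensitivity: float  #: elasticity dlogQ/dlogp; NaN when p == 0
    mode: str
    derived: Optional[Dict[str, Tuple[float, float]]] = None


def gamma_omega(model: CirculationModel) -> Tuple[float, float]:
    """The flow-scaled reduced pair (gamma, omega) = (K*mu, K*lam).

    Balanced special case only; propagates
    :class:`~steadycirc.errors.SpecialCaseError` otherwise.
    """
    rf = reduced_mu_lambda(model)
    return rf.gamma, rf.omega


def _fd_step(p: float) -> float:
    # central-difference step balancing truncation against roundoff for
    # parameter magnitudes of order 0.01 .. 100
    return 1e-6 * max(1.0, abs(p))


def _check_parameter(model: CirculationModel, parameter: str) -> float:
    if parameter not in parameter_names(model):
        raise KeyError(
            f"unknown parameter {parameter!r}; available: "
            f"{', '.join(parameter_names(model))}"
        )
    return get_parameter(model, parameter)


def dQ_dp(
    model: CirculationModel,
    parameter: str,
    mode: str = "analytic",
    step: Optional[float] = None,
) -> SensitivityResult:
    """Sensitivity of cardiac output Q to a named parameter.

    Parameters
    ----------
    mode : {"analytic", "finite_difference"}
        ``analytic`` uses the implicit-derivative formula (balanced
        models only); ``finite_difference`` re-solves the model at
        p +/- h.  The two agree to ~1e-6 relative for the reference
        model's parameters.
    step : float, optional
        Override the central-difference step h.
    """
    p = _check_parameter(model, parameter)
    h = step if step is not None else _fd_step(p)
    if mode == "finite_difference":
        Qp = solve_general(set_parameter(model, parameter, p + h))
        Qm = solve_general(set_parameter(model, parameter, p - h))
        d = (Qp - Qm) / (2.0 * h)
        Q = solve_general(model)
    elif mode == "analytic":
        if not model.balanced:
            raise SpecialCaseError(
                "analytic sensitivities presume the balanced reduced form; "
                "use mode='finite_difference' for unbalanced models"
            )
        rf = reduced_mu_lambda(model)
        K = model.right_heart.K
        Q = solve_general(model)
        dgamma, domega = _reduced_derivatives(model, parameter, p, h, rf)
        dK = 1.0 if parameter in _K_NAMES else 0.0
        numer = (
            dgamma
            + ((Q - rf.gamma) / rf.omega) * domega
            + rf.omega / (K - Q) * dK
        )
        denom = 1.0 + K * rf.omega / (Q * (K - Q))
        d = numer / denom
    else:
        raise ValueError(f"unknown mode {mode!r}")
    log_s = d * p / Q if p != 0.0 and Q != 0.0 else math.nan
    return SensitivityResult(parameter=parameter, dQ_dp=d, log_sensitivity=log_s, mode=mode)


def _reduced_derivatives(model, parameter, p, h, rf):
    """(dgamma/dp, domega/dp): closed form for pressure groups, central
    differences of the reduced parameters otherwise."""
    group = next((g for g in model.pressure_groups if g.name == parameter), None)
    if group is not None:
        c_sum = sum(model.compartment(cid).C for cid in group.compartments)
        if group.include_heart:
            c_sum -= rf.CS + rf.CP
        return c_sum / rf.CR, 0.0
    rp = reduced_mu_lambda(set_parameter(model, parameter, p + h))
    rm = reduced_mu_lambda(set_parameter(model, parameter, p - h))
    return (
        (rp.gamma - rm.gamma) / (2.0 * h),
        (rp.omega - rm.omega) / (2.0 * h),
    )


# --------------------------------------------------------------------------
# Sensitivities of derived variables


def variable_value(model: CirculationModel, Q: float, variable: str) -> float:
    """Evaluate a named model variable at cardiac output ``Q``.

    Recognized names: ``Q``, ``Z``, ``P_R``, ``P_L``, ``PA``, ``PPA``,
    ``TPR``, ``P_<compartment>`` and ``V_<compartment>``.  Everything
    downstream of Q (atrial pressures, compartmental state, derived
    pressures) is recomputed from the model, so the value responds to
    parameter changes at fixed Q as well as to Q itself.
    """
    if variable == "Q":
        return Q
    P_R = model.right_heart.inverse(Q)
    P_L = model.left_heart.inverse(Q)
    if variable == "P_R":
        return P_R
    if variable == "P_L":
        return P_L
    state = evaluate_state(model, Q, P_R, P_L)
    if variable == "Z":
        return state.Z
    if variable in ("PA", "PPA", "TPR"):
        dh = derived_hemodynamics(model, state)
        return getattr(dh, variable)
    if variable.startswith("P_") and variable[2:] in state.pressures:
        return state.pressures[variable[2:]]
    if variable.startswith("V_") and variable[2:] in state.volumes:
        return state.volumes[variable[2:]]
    raise KeyError(f"unknown variable {variable!r}")


def derived_variable_sensitivity(
    model: CirculationModel,
    variable: str,
    parameter: str,
    mode: str = "analytic",
    step: Optional[float] = None,
) -> Tuple[float, float]:
    """(derivative, elasticity) of a derived variable w.r.t. a parameter.

    ``analytic`` mode chains the analytic dQ/dp through the variable's
    defining relation: dv/dp = (dv/dQ) * dQ/dp + (dv/dp at fixed Q),
    with the two partials evaluated by central differences of cheap
    arithmetic (no re-solving).  ``finite_difference`` mode re-solves
    the full model at p +/- h.  For ``variable="Q"`` both reduce to
    :func:`dQ_dp` exactly.
    """
    p = _check_parameter(model, parameter)
    h = step if step is not None else _fd_step(p)
    Q = solve_general(model)
    v = variable_value(model, Q, variable)
    if mode == "finite_difference":
        mp = set_parameter(model, parameter, p + h)
        mm = set_parameter(model, parameter, p - h)
        d = (
            variable_value(mp, solve_general(mp), variable)
            - variable_value(mm, solve_general(mm), variable)
        ) / (2.0 * h)
    elif mode == "analytic":
        dQ = dQ_dp(model, parameter, mode="analytic", step=step).dQ_dp
        hq = 1e-6 * max(1.0, abs(Q))
        dv_dQ = (
            variable_value(model, Q + hq, variable)
            - variable_value(model, Q - hq, variable)
        ) / (2.0 * hq)
        dv_dp_fixedQ = (
            variable_value(set_parameter(model, parameter, p + h), Q, variable)
            - variable_value(set_parameter(model, parameter, p - h), Q, variable)
        ) / (2.0 * h)
        d = dv_dQ * dQ + dv_dp_fixedQ
    else:
        raise ValueError(f"unknown mode {mode!r}")
    log_s = d * p / v if p != 0.0 and v != 0.0 else math.nan
    return d, log_s
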