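"""Domain types for steady-state, closed-circulation compartmental models.

A model in this class couples two Starling-type cardiac function curves
(right and left heart) to N vascular compartments with linear
compliance, arranged in series-parallel resistance circuits for the
pulmonary and systemic beds, inside a closed loop holding a fixed total
blood volume.

In steady state the flow out of both sides of the heart equals the
cardiac output Q, and each compartmental pressure is affine in Q and
the downstream atrial pressure (``P_n = P_atrium + G_n * Q``, see
:mod:`steadycirc.network`).  Conservation of blood volume then confines
the operating point to the *conservation plane*

    CS * P_R + CP * P_L + CR * Q = D

whose coefficients are pure arithmetic over the model fields
(:func:`conservation_coefficients`).  Eliminating the atrial pressures
through the cardiac curves collapses the whole model — regardless of
compartment count or arrangement — to one nonlinear equation for Q,
solved in :mod:`steadycirc.solvers`.

Units: pressure mmHg (relative to atmospheric), volume L, flow L/min,
compliance L/mmHg, resistance mmHg/(L/min).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, Optional, Tuple

import numpy as np

from .errors import DomainError, InvalidModelError
from .network import (
    GCoefficients,
    Node,
    ResistanceNetwork,
    _coerce,
    leaf_ids,
)

__all__ = [
    "CIRCUITS",
    "CardiacCurve",
    "Compartment",
    "PressureGroup",
    "CirculationModel",
    "ReducedForm",
    "SteadyState",
    "starling_flow",
    "inverse_starling",
    "conservation_coefficients",
    "compartment_state",
    "evaluate_state",
    "conservation_residual",
]

#: Valid compartment circuit tags.  The right atrium belongs to the
#: systemic circulation (it collects systemic venous return); the left
#: atrium to the pulmonary circulation.
CIRCUITS = ("right_atrium", "pulmonary", "left_atrium", "systemic")

_ATRIAL = ("right_atrium", "left_atrium")


# --------------------------------------------------------------------------
# Cardiac function curve


@dataclass(frozen=True)
class CardiacCurve:
    """One heart side's Starling-type cardiac function curve.

    Ventricular output as a function of atrial pressure P:

        F(P) = K / (1 + alpha * exp(-beta * (P - P_ext)))

    a sigmoid rising from 0 to the maximum output ``K`` as atrial
    filling pressure rises above the external (pericardial /
    intrathoracic) pressure ``P_ext``.  At ``P == P_ext`` the output is
    exactly ``K / (1 + alpha)``.

    Parameters
    ----------
    K : float
        Maximum ventricular output, L/min.
    alpha : float
        Dimensionless shape parameter (> 0); sets the output fraction
        at zero transmural filling pressure.
    beta : float
        Steepness, /mmHg (> 0).
    P_ext : float
        External pressure on the atrium, mmHg.
    """

    K: float
    alpha: float
    beta: float
    P_ext: float = 0.0

    def __post_init__(self) -> None:
        if not (self.K > 0 and self.alpha > 0 and self.beta > 0):
            raise InvalidModelError(
                f"cardiac curve requires K, alpha, beta > 0; got "
                f"K={self.K}, alpha={self.alpha}, beta={self.beta}"
            )

    def flow(self, P):
        """Ventricular output at atrial pressure ``P`` (scalar or array).

        Evaluated in log space so that very negative transmural
        pressures yield a tiny positive flow instead of overflowing.
        """
        x = self.beta * (np.asarray(P, dtype=float) - self.P_ext)
        # 1 + alpha*exp(-x) == exp(logaddexp(0, log(alpha) - x))
        out = self.K * np.exp(-np.logaddexp(0.0, math.log(self.alpha) - x))
        return float(out) if out.ndim == 0 else out

    def inverse(self, Q: float) -> float:
        """Atrial pressure producing output ``Q``; exact inverse of
        :meth:`flow`.

        Raises
        ------
        DomainError
            If ``Q`` is outside the open interval (0, K).
        """
        if not 0.0 < Q < self.K:
            raise DomainError(
                f"cardiac curve is invertible only for 0 < Q < K={self.K}; got {Q}"
            )
        return self.P_ext + math.log(self.alpha * Q / (self.K - Q)) / self.beta


def starling_flow(curve: CardiacCurve, P_atrial):
    """Functional alias for :meth:`CardiacCurve.flow`."""
    return curve.flow(P_atrial)


def inverse_starling(curve: CardiacCurve, Q: float) -> float:
    """Functional alias for :meth:`CardiacCurve.inverse`."""
    return curve.inverse(Q)


# --------------------------------------------------------------------------
# Compartments and the assembled model


@dataclass(frozen=True)
class Compartment:
    """A vascular bed with linear compliance.

    Volume relates to pressure by ``V = V0n + C * (P - P_ext)`` where
    ``C`` is the compliance, ``V0n`` the unstressed volume and
    ``P_ext`` any external pressure on the bed.  Non-atrial
    compartments additionally carry an arterial (inflow) resistance
    ``RA`` and a venous (outflow) resistance ``RV``; the capacitive
    node sits between them.
    """

    id: str
    circuit: str
    C: float
    V0n: float
    P_ext: float = 0.0
    RA: Optional[float] = None
    RV: Optional[float] = None

    def __post_init__(self) -> None:
        if self.circuit not in CIRCUITS:
            raise InvalidModelError(
                f"compartment {self.id!r}: circuit must be one of {CIRCUITS}"
            )
        if self.C < 0 or self.V0n < 0:
            raise InvalidModelError(
                f"compartment {self.id!r}: C and V0n must be non-negative"
            )
        if self.is_atrium:
            if self.RA is not None or self.RV is not None:
                raise InvalidModelError(
                    f"atrial compartment {self.id!r} must not carry resistances"
                )
        else:
            if self.RA is None or self.RV is None:
                raise InvalidModelError(
                    f"compartment {self.id!r}: non-atrial compartments need RA and RV"
                )
            if self.RA < 0 or self.RV < 0:
                raise InvalidModelError(
                    f"compartment {self.id!r}: resistances must be non-negative"
                )

    @property
    def is_atrium(self) -> bool:
        return self.circuit in _ATRIAL


@dataclass(frozen=True)
class PressureGroup:
    """A named external-pressure parameter shared by several compartments.

    Cavities like the chest or abdomen impose one pressure on every
    structure they enclose.  A group maps a parameter name (e.g.
    ``"P_e"`` for intrathoracic pressure) to the compartments sharing
    that external pressure; ``include_heart`` extends it to both
    cardiac curves' ``P_ext`` (the heart sits in the chest).
    """

    name: str
    compartments: Tuple[str, ...]
    include_heart: bool = False


@dataclass(frozen=True)
class CirculationModel:
    """Closed-loop steady-state circulation model.

    Parameters
    ----------
    right_heart, left_heart : CardiacCurve
    compartments : tuple of Compartment
        Exactly one ``right_atrium`` (listed first, by convention) and
        one ``left_atrium``; the rest tagged ``pulmonary`` or
        ``systemic``.
    pulmonary_topology, systemic_topology : topology node
        Series-parallel arrangement of the circuit's non-atrial
        compartments (see :mod:`steadycirc.network`).
    BV : float
        Total blood volume, L.
    V0 : float
        Blood volume in non-capacitive regions, L.
    pressure_groups : tuple of PressureGroup
        Named shared external pressures (optional; used by scenario
        overrides and sensitivity analysis).
    """

    right_heart: CardiacCurve
    left_heart: CardiacCurve
    compartments: Tuple[Compartment, ...]
    pulmonary_topology: Node
    systemic_topology: Node
    BV: float
    V0: float
    pressure_groups: Tuple[PressureGroup, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "pulmonary_topology", _coerce(self.pulmonary_topology))
        object.__setattr__(self, "systemic_topology", _coerce(self.systemic_topology))
        ids = [c.id for c in self.compartments]
        if len(ids) != len(set(ids)):
            raise InvalidModelError("compartment ids must be unique")
        n_ra = sum(c.circuit == "right_atrium" for c in self.compartments)
        n_la = sum(c.circuit == "left_atrium" for c in self.compartments)
        if n_ra != 1 or n_la != 1:
            raise InvalidModelError(
                "model needs exactly one right atrium and one left atrium"
            )
        if self.compartments[0].circuit != "right_atrium":
            raise InvalidModelError("the right atrium must be listed first")
        if not (self.BV > self.V0 >= 0):
            raise InvalidModelError("require BV > V0 >= 0")
        # closed circulation: both circuits nonempty
        for circuit, topo in (
            ("pulmonary", self.pulmonary_topology),
            ("systemic", self.systemic_topology),
        ):
            want = sorted(c.id for c in self.compartments if c.circuit == circuit)
            have = sorted(leaf_ids(topo))
            if not want:
                raise InvalidModelError(f"{circuit} circuit has no compartments")
            if want != have:
                raise InvalidModelError(
                    f"{circuit} topology leaves {have} do not match "
                    f"compartments {want}"
                )
        known = set(ids)
        for g in self.pressure_groups:
            unknown = set(g.compartments) - known
            if unknown:
                raise InvalidModelError(
                    f"pressure group {g.name!r} references unknown "
                    f"compartment(s) {sorted(unknown)}"
                )
        if self.delta_BV <= 0:
            warnings.warn(
                f"stressed blood volume dBV = {self.delta_BV:.4g} L is not "
                "positive; the model still has a mathematical solution but "
                "the operating point may be unphysiological",
                stacklevel=2,
            )

    # -- structural accessors ------------------------------------------------

    @property
    def right_atrium(self) -> Compartment:
        return self.compartments[0]

    @property
    def left_atrium(self) -> Compartment:
        return next(c for c in self.compartments if c.circuit == "left_atrium")

    def compartment(self, cid: str) -> Compartment:
        for c in self.compartments:
            if c.id == cid:
                return c
        raise KeyError(cid)

    @property
    def delta_BV(self) -> float:
        """Stressed blood volume: BV - V0 - sum of unstressed volumes, L."""
        return self.BV - self.V0 - sum(c.V0n for c in self.compartments)

    @property
    def balanced(self) -> bool:
        """True when both heart sides share K and external pressure, the
        special case reducing the model to Z = mu + lambda*log((1-Z)/Z)."""
        r, l = self.right_heart, self.left_heart
        return (
            math.isclose(r.K, l.K, rel_tol=1e-12, abs_tol=0.0)
            and math.isclose(r.P_ext, l.P_ext, rel_tol=0.0, abs_tol=1e-12)
        )

    def pulmonary_network(self) -> ResistanceNetwork:
        return ResistanceNetwork.from_compartments(
            self.pulmonary_topology,
            (c for c in self.compartments if c.circuit == "pulmonary"),
        )

    def systemic_network(self) -> ResistanceNetwork:
        return ResistanceNetwork.from_compartments(
            self.systemic_topology,
            (c for c in self.compartments if c.circuit == "systemic"),
        )

    def g_coefficients(self) -> GCoefficients:
        """Pressure-transfer coefficients for every compartment.

        Atria get G = 0 (their pressures are the atrial pressures
        themselves); fractions merge both circuits (each carries the
        full cardiac output at its root).
        """
        pul = self.pulmonary_network().g_coefficients()
        sys_ = self.systemic_network().g_coefficients()
        G: Dict[str, float] = {}
        fractions: Dict[str, float] = {}
        for c in self.compartments:
            if c.is_atrium:
                G[c.id] = 0.0
                fractions[c.id] = 1.0
            else:
                src = pul if c.circuit == "pulmonary" else sys_
                G[c.id] = src.G[c.id]
                fractions[c.id] = src.fractions[c.id]
        return GCoefficients(
            G=G, fractions=fractions, groups=pul.groups + sys_.groups
        )

    def replace_compartment(self, cid: str, **changes) -> "CirculationModel":
        """Return a copy of the model with one compartment's fields changed."""
        self.compartment(cid)  # raise KeyError early
        comps = tuple(
            replace(c, **changes) if c.id == cid else c for c in self.compartments
        )
        return replace(self, compartments=comps)


# --------------------------------------------------------------------------
# Reduced form and steady state containers


@dataclass(frozen=True)
class ReducedForm:
    """Scalars collapsing the model to one equation.

    ``CS`` (total systemic compliance, incl. the right atrium), ``CP``
    (total pulmonary compliance, incl. the left atrium), ``CR``
    (compliance-resistance coupling, L/(L/min)) and ``D`` (conservation
    constant, L) define the conservation plane
    ``CS*P_R + CP*P_L + CR*Q = D``.  In the balanced special case the
    dimensionless pair (``mu``, ``lam``) — and the flow-scaled pair
    ``gamma = K*mu``, ``omega = K*lam`` — fully determine the scaled
    cardiac output Z = Q/K.
    """

    CS: float
    CP: float
    CR: float
    D: float
    mu: Optional[float] = None
    lam: Optional[float] = None
    gamma: Optional[float] = None
    omega: Optional[float] = None


@dataclass(frozen=True)
class SteadyState:
    """The solved operating point of a circulation model."""

    Q: float  #: cardiac output, L/min
    Z: float  #: Q / K (K = min of the two maximum outputs), dimensionless
    P_R: float  #: right atrial pressure == central venous pressure, mmHg
    P_L: float  #: left atrial pressure, mmHg
    pressures: Mapping[str, float]  #: compartmental pressures, mmHg
    volumes: Mapping[str, float]  #: compartmental volumes, L
    residual_volume: float  #: V0 + sum(V_n) - BV, L
    flow_mismatch_right: float  #: F_R(P_R) - Q, L/min
    flow_mismatch_left: float  #: F_L(P_L) - Q, L/min


# --------------------------------------------------------------------------
# Conservation-plane arithmetic


def conservation_coefficients(model: CirculationModel) -> ReducedForm:
    """Coefficients of the conservation plane CS*P_R + CP*P_L + CR*Q = D.

    CS sums the compliances of the systemic side (right atrium plus
    systemic beds), CP those of the pulmonary side (lungs plus left
    atrium), CR couples compliance to the resistive pressure build-up
    (sum of C_n * G_n over non-atrial compartments), and
    D = dBV + sum(C_n * P_ext,n).  Pure arithmetic; no solving.
    """
    CS = sum(c.C for c in model.compartments if c.circuit in ("right_atrium", "systemic"))
    CP = sum(c.C for c in model.compartments if c.circuit in ("pulmonary", "left_atrium"))
    G = model.g_coefficients().G
    CR = sum(c.C * G[c.id] for c in model.compartments if not c.is_atrium)
    D = model.delta_BV + sum(c.C * c.P_ext for c in model.compartments)
    if CS <= 0 or CP <= 0 or CR <= 0:
        raise InvalidModelError(
            f"reduced coefficients must be positive (CS={CS}, CP={CP}, CR={CR})"
        )
    return ReducedForm(CS=CS, CP=CP, CR=CR, D=D)


def compartment_state(
    model: CirculationModel, Q: float, P_R: float, P_L: float
) -> Tuple[Dict[str, float], Dict[str, float]]:
    """Compartmental pressures and volumes at a given operating point.

    ``P_n = P_atrium + G_n * Q`` (atria use their own pressures), and
    ``V_n = V0n + C_n * (P_n - P_ext,n)``.
    """
    G = model.g_coefficients().G
    pressures: Dict[str, float] = {}
    volumes: Dict[str, float] = {}
    for c in model.compartments:
        if c.circuit == "right_atrium":
            P = P_R
        elif c.circuit == "left_atrium":
            P = P_L
        elif c.circuit == "pulmonary":
            P = P_L + G[c.id] * Q
        else:
            P = P_R + G[c.id] * Q
        pressures[c.id] = P
        volumes[c.id] = c.V0n + c.C * (P - c.P_ext)
    return pressures, volumes


def evaluate_state(
    model: CirculationModel, Q: float, P_R: float, P_L: float
) -> SteadyState:
    """Populate a full :class:`SteadyState` at (Q, P_R, P_L) without solving.

    Useful both for packaging a solved point and for probing residuals
    at perturbed points (the conservation residual is affine in the
    operating point with coefficients CS, CP, CR).
    """
    pressures, volumes = compartment_state(model, Q, P_R, P_L)
    K = min(model.right_heart.K, model.left_heart.K)
    return SteadyState(
        Q=Q,
        Z=Q / K,
        P_R=P_R,
        P_L=P_L,
        pressures=pressures,
        volumes=volumes,
        residual_volume=model.V0 + sum(volumes.values()) - model.BV,
        flow_mismatch_right=model.right_heart.flow(P_R) - Q,
        flow_mismatch_left=model.left_heart.flow(P_L) - Q,
    )


def conservation_residual(model: CirculationModel, state: SteadyState) -> float:
    """Blood-volume conservation residual V0 + sum(V_n) - BV, in L.

    Zero (to solver tolerance) at a valid steady state.
    """
    return model.V0 + sum(state.volumes.values()) - model.BV
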