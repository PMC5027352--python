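"""Solution strategies for the steady-state circulation equations.

Three equivalent routes to the operating point:

1. **Single nonlinear equation** — eliminate both atrial pressures
   through the (invertible) cardiac curves and substitute into the
   conservation plane, leaving one scalar equation for Q
   (:func:`solve_general`).  In the balanced special case
   (K_R == K_L == K, equal heart external pressures) this becomes the
   two-parameter dimensionless form

       Z = mu + lam * log((1 - Z) / Z),     Z = Q / K

   solved by :func:`solve_z`, with (mu, lam) from
   :func:`reduced_mu_lambda`.

2. **2-D composite-flow-curve intersection** — eliminate only P_L,
   producing a straight line Q = A - B * P_R (the "venous return"-like
   composite flow curve, :func:`composite_flow_line`) whose
   intersection with the right-heart Starling curve is the solution
   (:func:`solve_2d`).

3. **3-D surface sampling** — sample the two Starling sheets and the
   conservation plane over a (P_R, P_L) grid (:func:`surface_grids`);
   their mutual intersection is the same operating point.

A Lagrange-inversion series in powers of ``lam``
(:func:`lagrange_series`) gives an explicit, rapidly convergent
approximation to Z for small ``lam``; its terms are generated by exact
symbolic differentiation, never transcribed coefficients.

All roots are found by bracketed Brent refinement; the scalar residuals
are monotone in their unknown, so the root is unique in the
physiological bracket.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Tuple

import numpy as np
from scipy.optimize import brentq

from .errors import DomainError, NoSolutionError, SpecialCaseError
from .model import (
    CirculationModel,
    ReducedForm,
    SteadyState,
    conservation_coefficients,
    evaluate_state,
)

__all__ = [
    "CompositeFlowLine",
    "SeriesSolution",
    "SurfaceGrids",
    "reduced_mu_lambda",
    "solve_z",
    "solve_general",
    "composite_flow_line",
    "solve_2d",
    "surface_grids",
    "lagrange_series",
    "steady_state",
]

#: Convergence targets for the scalar root solves (on the Z or Q scale).
_XTOL = 1e-13
_RTOL = 4 * np.finfo(float).eps


# --------------------------------------------------------------------------
# Balanced special case: the dimensionless single equation


def reduced_mu_lambda(model: CirculationModel) -> ReducedForm:
    """Reduced form with the dimensionless (mu, lam) pair filled in.

    Requires the balanced special case K_R == K_L and equal heart
    external pressures; otherwise raises
    :class:`~steadycirc.errors.SpecialCaseError` (use
    :func:`solve_general`, which needs no symmetry).

        lam = (CS/beta_R + CP/beta_L) / (K * CR)
        mu  = [D - (CS+CP)*P_e - (CS/beta_R)*log(alpha_R)
                 - (CP/beta_L)*log(alpha_L)] / (K * CR)

    Also fills the flow-scaled pair gamma = K*mu, omega = K*lam used by
    the sensitivity calculus.  Natural logarithms throughout.
    """
    if not model.balanced:
        raise SpecialCaseError(
            "reduced (mu, lambda) form needs K_R == K_L and equal heart "
            "external pressures; this model is unbalanced — use solve_general"
        )
    rf = conservation_coefficients(model)
    r, l = model.right_heart, model.left_heart
    K = r.K
    Pe = r.P_ext
    denom = K * rf.CR
    lam = (rf.CS / r.beta + rf.CP / l.beta) / denom
    mu = (
        rf.D
        - (rf.CS + rf.CP) * Pe
        - (rf.CS / r.beta) * math.log(r.alpha)
        - (rf.CP / l.beta) * math.log(l.alpha)
    ) / denom
    return ReducedForm(
        CS=rf.CS, CP=rf.CP, CR=rf.CR, D=rf.D,
        mu=mu, lam=lam, gamma=K * mu, omega=K * lam,
    )


def _z_residual(Z: float, mu: float, lam: float) -> float:
    return Z - mu - lam * math.log((1.0 - Z) / Z)


def solve_z(mu: float, lam: float) -> float:
    """Unique root in (0, 1) of ``Z - mu - lam*log((1-Z)/Z) = 0``.

    The left side is strictly increasing and the right side strictly
    decreasing in Z, so at most one root exists; for ``lam > 0`` the
    residual spans (-inf, +inf) and a root always exists (possibly
    exponentially close to an endpoint).  ``lam == 0`` degenerates to
    ``Z = mu`` and requires ``0 < mu < 1``.
    """
    if lam < 0:
        raise DomainError(f"lam must be non-negative; got {lam}")
    if lam == 0.0:
        if not 0.0 < mu < 1.0:
            raise NoSolutionError(
                f"with lam = 0 the solution Z = mu = {mu} lies outside (0, 1)"
            )
        return mu
    lo, hi = 1e-12, 1.0 - 1e-12
    # move a bracket end inward when the root is exponentially close to it
    if _z_residual(lo, mu, lam) > 0.0:
        lo = math.exp(-min(700.0, (abs(mu) + 2.0) / lam))
    if _z_residual(hi, mu, lam) < 0.0:
        hi = 1.0 - math.exp(-min(700.0, (abs(mu - 1.0) + 2.0) / lam))
    flo, fhi = _z_residual(lo, mu, lam), _z_residual(hi, mu, lam)
    if flo > 0.0 or fhi < 0.0:
        raise NoSolutionError(
            f"no sign change for Z in [{lo:g}, {hi:g}]: "
            f"residuals ({flo:g}, {fhi:g})"
        )
    return brentq(_z_residual, lo, hi, args=(mu, lam), xtol=_XTOL, rtol=_RTOL)


# --------------------------------------------------------------------------
# General single equation (no heart symmetry required)


def _general_residual(Q: float, model: CirculationModel, rf: ReducedForm) -> float:
    """Residual of the general one-equation form, log-space evaluated.

    CR*Q - D + CS*P_ext,R + CP*P_ext,L
        - (CS/beta_R)*log((K_R - Q)/(alpha_R * Q))
        - (CP/beta_L)*log((K_L - Q)/(alpha_L * Q))

    Strictly increasing in Q on (0, min(K_R, K_L)); -inf / +inf limits
    at the bracket ends.
    """
    r, l = model.right_heart, model.left_heart
    return (
        rf.CR * Q
        - rf.D
        + rf.CS * r.P_ext
        + rf.CP * l.P_ext
        - (rf.CS / r.beta) * (math.log(r.K - Q) - math.log(r.alpha * Q))
        - (rf.CP / l.beta) * (math.log(l.K - Q) - math.log(l.alpha * Q))
    )


def solve_general(model: CirculationModel) -> float:
    """Cardiac output Q from the general single nonlinear equation.

    Works for unbalanced hearts (K_R != K_L, unequal external
    pressures).  For balanced models it agrees with
    ``K * solve_z(mu, lam)`` to roundoff.
    """
    rf = conservation_coefficients(model)
    Kmin = min(model.right_heart.K, model.left_heart.K)
    eps = 1e-9 * Kmin
    lo, hi = eps, Kmin - eps
    flo = _general_residual(lo, model, rf)
    fhi = _general_residual(hi, model, rf)
    # shrink toward the open endpoints if the root hides in the tails
    shrink = 0
    while flo > 0.0 and lo > 1e-280 * Kmin and shrink < 40:
        lo *= 1e-6
        flo = _general_residual(lo, model, rf)
        shrink += 1
    shrink = 0
    while fhi < 0.0 and (Kmin - hi) > 1e-280 * Kmin and shrink < 40:
        hi = Kmin - (Kmin - hi) * 1e-6
        fhi = _general_residual(hi, model, rf)
        shrink += 1
    if flo > 0.0 or fhi < 0.0:
        raise NoSolutionError(
            f"no steady state in (0, {Kmin}): residual at bracket "
            f"[{lo:g}, {hi:g}] is ({flo:g}, {fhi:g})"
        )
    return brentq(
        _general_residual, lo, hi, args=(model, rf),
        xtol=_XTOL * Kmin, rtol=_RTOL,
    )


# --------------------------------------------------------------------------
# 2-D analysis: composite flow curve


@dataclass(frozen=True)
class CompositeFlowLine:
    """The line Q = A - B * P_R obtained by eliminating P_L.

    Plays the role of a venous-return curve: its intersection with the
    right-heart Starling curve in the (P_R, Q) plane is the steady
    state.  B > 0 for physiological parameter sets.
    """

    A: float  #: intercept, L/min
    B: float  #: slope, (L/min)/mmHg

    def q_at(self, P_R):
        """Composite flow at right atrial pressure ``P_R`` (scalar or array)."""
        out = self.A - self.B * np.asarray(P_R, dtype=float)
        return float(out) if out.ndim == 0 else out


def composite_flow_line(model: CirculationModel) -> CompositeFlowLine:
    """Coefficients (A, B) of the composite flow curve.

    Eliminating P_L between the two cardiac curves (which yields a line
    exactly when K_R == K_L; unequal alphas, betas and external
    pressures are fine) and substituting into the conservation plane
    gives Q as a *linear* function of P_R.  For unbalanced maximum
    outputs the exact composite curve is nonlinear — use
    :func:`solve_2d`, which performs the exact elimination.
    """
    rf = conservation_coefficients(model)
    r, l = model.right_heart, model.left_heart
    ratio = r.beta / l.beta
    A = (
        rf.D
        - rf.CP * (l.P_ext - ratio * r.P_ext + math.log(l.alpha / r.alpha) / l.beta)
    ) / rf.CR
    B = (rf.CS + rf.CP * ratio) / rf.CR
    return CompositeFlowLine(A=A, B=B)


def solve_2d(
    model: CirculationModel, line: Optional[CompositeFlowLine] = None
) -> Tuple[float, float]:
    """Intersection (P_R, Q) of the right Starling curve with the
    composite flow curve in the (P_R, Q) plane.

    By default the elimination of P_L is exact: along the right curve
    Q = F_R(P_R), the left atrial pressure is F_L^{-1}(Q), and the
    conservation plane supplies the residual

        h(P_R) = CS*P_R + CP*F_L^{-1}(F_R(P_R)) + CR*F_R(P_R) - D

    which is strictly increasing, so the intersection is unique.  When
    K_R == K_L this curve *is* the straight composite flow line, and
    the result agrees with :func:`solve_general` to roundoff.

    Passing an explicit ``line`` intersects the right curve with that
    line instead (useful for graphical constructions); a horizontal
    line (B == 0) degenerates to inverting the right curve at Q = A.
    """
    right, left = model.right_heart, model.left_heart
    if line is not None:
        if line.B == 0.0:
            return right.inverse(line.A), line.A

        def g(P: float) -> float:
            return right.flow(P) - line.q_at(P)

        lo = hi = right.P_ext
        w = 1.0
        for _ in range(120):
            if g(lo) < 0.0:
                break
            lo -= w
            w *= 2.0
        w = 1.0
        for _ in range(120):
            if g(hi) > 0.0:
                break
            hi += w
            w *= 2.0
        if not (g(lo) < 0.0 < g(hi)):
            raise NoSolutionError(
                f"composite line does not intersect the right cardiac curve "
                f"in [{lo:g}, {hi:g}]"
            )
        P_R = brentq(g, lo, hi, xtol=_XTOL, rtol=_RTOL)
        return P_R, line.q_at(P_R)

    rf = conservation_coefficients(model)
    Kmin = min(right.K, left.K)

    def h(P: float) -> float:
        Q = min(right.flow(P), Kmin * (1.0 - 1e-15))
        return rf.CS * P + rf.CP * left.inverse(Q) + rf.CR * Q - rf.D

    # upper bracket: right-curve pressure delivering (almost) Kmin
    hi = right.inverse(Kmin * (1.0 - 1e-12))
    lo = min(right.P_ext, hi - 1.0)
    w = 1.0
    for _ in range(200):
        if h(lo) < 0.0:
            break
        lo -= w
        w *= 2.0
    if not (h(lo) < 0.0 <= h(hi)):
        raise NoSolutionError(
            f"composite curve does not intersect the right cardiac curve "
            f"in [{lo:g}, {hi:g}]"
        )
    P_R = brentq(h, lo, hi, xtol=_XTOL, rtol=_RTOL)
    return P_R, right.flow(P_R)


# --------------------------------------------------------------------------
# 3-D analysis: sampled surfaces


@dataclass(frozen=True)
class SurfaceGrids:
    """Sampled Q surfaces over a (P_R, P_L) grid.

    ``q_right`` and ``q_left`` are the two Starling sheets (constant
    along the other atrium's axis); ``q_plane`` is the conservation
    plane Q = (D - CS*P_R - CP*P_L)/CR.  Arrays are indexed
    ``[i_PR, i_PL]``.  The mutual intersection of the three surfaces is
    the model's steady state.
    """

    P_R: np.ndarray
    P_L: np.ndarray
    q_right: np.ndarray
    q_left: np.ndarray
    q_plane: np.ndarray

    def to_frame(self):
        """Long-format table (P_R, P_L, Q_right, Q_left, Q_plane) for export."""
        import pandas as pd

        PR, PL = np.meshgrid(self.P_R, self.P_L, indexing="ij")
        return pd.DataFrame(
            {
                "P_R": PR.ravel(),
                "P_L": PL.ravel(),
                "Q_right": self.q_right.ravel(),
                "Q_left": self.q_left.ravel(),
                "Q_plane": self.q_plane.ravel(),
            }
        )


def surface_grids(
    model: CirculationModel,
    PR_range: Tuple[float, float],
    PL_range: Tuple[float, float],
    n_points: int = 50,
) -> SurfaceGrids:
    """Sample the two Starling sheets and the conservation plane.

    ``n_points`` grid nodes per axis (>= 2); ranges are (min, max) with
    min < max.
    """
    if n_points < 2:
        raise DomainError(f"n_points must be >= 2; got {n_points}")
    for name, (lo, hi) in (("PR_range", PR_range), ("PL_range", PL_range)):
        if not hi > lo:
            raise DomainError(f"{name} is empty: ({lo}, {hi})")
    rf = conservation_coefficients(model)
    P_R = np.linspace(PR_range[0], PR_range[1], n_points)
    P_L = np.linspace(PL_range[0], PL_range[1], n_points)
    q_right = np.broadcast_to(
        model.right_heart.flow(P_R)[:, None], (n_points, n_points)
    ).copy()
    q_left = np.broadcast_to(
        model.left_heart.flow(P_L)[None, :], (n_points, n_points)
    ).copy()
    q_plane = (rf.D - rf.CS * P_R[:, None] - rf.CP * P_L[None, :]) / rf.CR
    return SurfaceGrids(P_R=P_R, P_L=P_L, q_right=q_right, q_left=q_left, q_plane=q_plane)


# --------------------------------------------------------------------------
# Lagrange-inversion series


@dataclass(frozen=True)
class SeriesSolution:
    """Truncated Lagrange-inversion series for Z.

    ``terms[n]`` is the coefficient of lam**n (dimensionless), so
    ``value = sum(terms[n] * lam**n)``.  ``terms[0] == mu`` exactly.
    """

    order: int
    terms: Tuple[float, ...]
    value: float


@lru_cache(maxsize=None)
def _series_term_functions(order: int):
    """Callables for the lam**n coefficients, n = 1..order.

    The n-th coefficient is (1/n!) d^{n-1}/dmu^{n-1} [log((1-mu)/mu)]^n,
    generated symbolically so no typeset expansion is ever transcribed.
    """
    import sympy as sp

    m = sp.Symbol("m", positive=True)
    L = sp.log((1 - m) / m)
    funcs = []
    for n in range(1, order + 1):
        expr = sp.diff(L**n, m, n - 1) / sp.factorial(n)
        funcs.append(sp.lambdify(m, expr, modules="math"))
    return tuple(funcs)


def lagrange_series(mu: float, lam: float, order: int = 3) -> SeriesSolution:
    """Series solution Z = mu + sum_{n>=1} c_n(mu) * lam**n.

    Converges rapidly for small ``lam`` (the physiological regime);
    ``order`` 3 retains the terms usually written out explicitly.
    ``mu`` must lie in (0, 1) for the logarithms to exist.  At
    ``mu == 0.5`` every correction term vanishes and Z = 0.5 exactly.
    """
    if not 0.0 < mu < 1.0:
        raise DomainError(f"series requires 0 < mu < 1; got {mu}")
    if order < 0:
        raise DomainError(f"order must be >= 0; got {order}")
    terms = [mu]
    for f in _series_term_functions(order) if order else ():
        terms.append(float(f(mu)))
    value = math.fsum(t * lam**n for n, t in enumerate(terms))
    return SeriesSolution(order=order, terms=tuple(terms), value=value)


# --------------------------------------------------------------------------
# Full steady state


def steady_state(model: CirculationModel) -> SteadyState:
    """Solve the model and populate the complete operating point.

    Q from :func:`solve_general`; atrial pressures by inverting each
    cardiac curve at Q; compartmental pressures/volumes from the
    pressure-transfer coefficients; residual diagnostics included.
    """
    Q = solve_general(model)
    P_R = model.right_heart.inverse(Q)
    P_L = model.left_heart.inverse(Q)
    return evaluate_state(model, Q, P_R, P_L)
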