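# Methods

## Model and assumptions

`steadycirc` implements the steady-state theory of closed-loop
compartmental circulations. The assumptions defining the model class
are strict and deliberate:

- **Steady state** — no time dependence; flow out of each heart side
  equals the cardiac output `Q`, and so does the total flow through
  each circuit.
- **Closed circulation** — total blood volume `BV` is constant. A
  fixed amount `V0` resides in non-capacitive regions; the rest fills
  the compartments.
- **Nonpulsatile flow, linear resistive transport** — flow between
  compartments is proportional to the pressure difference across the
  connecting resistance.
- **Linear compliances** — `V_n = V0n + C_n (P_n − P_ext,n)` in every
  compartment.
- **Starling-type cardiac function curves** —
  `F(P) = K / (1 + α exp(−β (P − P_ext)))` for each side; smooth,
  strictly increasing, bounded in `(0, K)`, hence invertible.
- **No venous collapse** near the right heart, no baroreflexes, no
  nonlinear compliances. These are modeling limits, not options.

All pressures are stored relative to atmospheric. Units are fixed by
convention and not checked by a unit system: pressure mmHg, volume L,
flow L/min, compliance L/mmHg, resistance mmHg/(L/min).

## Network reduction

Each circuit must be a series-parallel tree whose leaves are the
circuit's non-atrial compartments; each leaf's capacitive node sits
between its arterial resistance RA and venous resistance RV. This
placement is forced by the convention that a compartment's pressure
exceeds the downstream atrial pressure by the resistive drops on the
venous side of its node:

    P_n = P_atrium + G_n · Q.

`G_n` is computed by one recursive pass carrying the subtree's flow
fraction `f` and the shared downstream drop per unit cardiac output
`g0`: a leaf contributes `G = g0 + RV·f`; a series node adds
`f · R_eq(downstream siblings)` to each child's offset (children are
ordered arterial → venous); a parallel node splits the fraction by
equivalent-resistance ratios `f_b = f · R_group / R_branch`. Atria
carry no resistances (any inter-atrial drop is absorbed into adjacent
compartments) and have `G = 0`.

Arbitrary resistor graphs (bridges, meshes) are rejected with an
unsupported-topology error rather than approximated: for them the
branch-fraction decomposition is not well defined, and the class of
models this package targets never needs it. The test suite checks the
reduction against an independent dense nodal-analysis solve of the
full resistor network on randomized trees (agreement to 1e−10).

A parallel branch with zero total resistance is an invalid model (the
split degenerates); a lone zero resistance in a single branch is fine
and simply contributes nothing to `G`.

## Conservation plane and the single equation

Volume conservation, written at the operating point, is a plane in
`(P_R, P_L, Q)`:

    CS·P_R + CP·P_L + CR·Q = D

with `CS` the total systemic-side compliance (right atrium included),
`CP` the pulmonary-side total (left atrium included),
`CR = Σ C_n G_n` over non-atrial compartments, and
`D = ΔBV + Σ C_n P_ext,n`, where `ΔBV = BV − V0 − Σ V0n` is the
stressed volume. `ΔBV ≤ 0` is allowed with a warning — the equation
still has a root, but the operating point is unlikely to be
physiological.

Substituting the inverted cardiac curves for `P_R` and `P_L` yields a
scalar residual in `Q`, strictly increasing on `(0, min(K_R, K_L))`
with infinite limits at both ends, so the steady state exists and is
unique. In the balanced special case (`K_R = K_L = K`, equal heart
external pressures) the equation reduces to the dimensionless form
`Z = μ + λ log((1−Z)/Z)` with `Z = Q/K`; `μ` aggregates volumes and
external pressures, `λ` the compliance/steepness coupling. Natural
logarithms are used throughout — this is required for consistency with
the exponential in the cardiac curve.

## Numerical choices

- **Root refinement**: `scipy.optimize.brentq` on a bracketing
  interval, `xtol = 1e−13` (scaled by K for the Q equation), machine
  `rtol`. If the residual does not change sign at the nominal bracket
  `(ε, K−ε)`, `ε = 1e−9·K`, the endpoint is walked geometrically
  toward the open boundary (the root can sit exponentially close to 0
  or K when `μ` is far outside `(0,1)`); a genuine failure raises a
  no-solution error carrying both endpoint residuals.
- **Overflow safety**: the cardiac curve is evaluated in log space
  (`K·exp(−logaddexp(0, log α − x))`), so very negative transmural
  pressures give tiny positive flows instead of overflowing; the
  general residual likewise sums logarithms instead of exponentiating.
- **The 2-D construction**: eliminating `P_L` between the two cardiac
  curves gives a straight composite flow line `Q = A − B·P_R` exactly
  when `K_R = K_L` (unequal α, β, `P_ext` are fine). `solve_2d`
  therefore intersects the right Starling curve with the *exact*
  composite curve — `h(P_R) = CS·P_R + CP·F_L⁻¹(F_R(P_R)) +
  CR·F_R(P_R) − D`, strictly increasing — which coincides with the
  line in the balanced case and remains exact for unbalanced hearts.
  The linear coefficients stay available via `composite_flow_line`.
- **Finite-difference steps**: central differences with
  `h = 1e−6·max(1, |p|)`, balancing truncation against roundoff for
  the parameter magnitudes this model uses (0.01–100).

## Lagrange-inversion series

The series `Z = μ + Σ (λⁿ/n!) dⁿ⁻¹/dμⁿ⁻¹ [log((1−μ)/μ)]ⁿ` is
evaluated with coefficients generated by sympy symbolic
differentiation at call time (cached per order) — no typeset expansion
is transcribed, which protects against grouping ambiguities in printed
forms. Default truncation order is 3.

The series is asymptotic in the small parameter; empirically the
effective expansion parameter is `λ/(μ(1−μ))`. Truncation error
decreases monotonically through order 4 when that ratio stays below
roughly 0.4 — e.g. all `λ ≤ 0.05` for `μ ∈ [0.2, 0.8]`, and the
reference model's `λ = 0.084` for `μ ∈ [0.35, 0.65]` — and the
property tests assert exactly that region. Near `μ = 0.5` every
correction term vanishes and the series is exact at order 0.

## Sensitivity calculus

In the balanced case the steady state satisfies
`Q = γ + ω log((K−Q)/Q)` with `γ = Kμ`, `ω = Kλ`. Implicit
differentiation with respect to a parameter `p` gives

    dQ/dp = [dγ/dp + ((Q−γ)/ω)·dω/dp + ω/(K−Q)·dK/dp]
            / [1 + K·ω/(Q(K−Q))].

The `dK/dp` term matters only when the parameter *is* the maximum
output, which appears in the equation outside `γ` and `ω`; omitting it
(as a term-by-term differentiation of the γ/ω form alone would) breaks
the K-sensitivity. For shared external-pressure parameters (pressure
groups such as intrathoracic `P_e`) `dγ/dp` has the closed form
`[Σ_group C_n − (CS+CP)·1_heart]/CR` and `dω/dp = 0`; for every other
parameter `(dγ/dp, dω/dp)` are central differences of the reduced
parameters — cheap arithmetic with no re-solving. `finite_difference`
mode re-solves the full model at `p ± h` and is the only mode offered
for unbalanced models (the formula above presumes the balanced form).
The two modes agree to better than 1e−6 relative on every parameter of
the reference model; the tests require 1e−4.

Derived-variable sensitivities chain the analytic `dQ/dp` through the
variable's defining relation: `dv/dp = (∂v/∂Q)·dQ/dp + ∂v/∂p|_Q`,
with the two partials taken by central differences of the closed-form
state evaluation at fixed `Q` (again no re-solving). For arterial
pressure versus chest pressure this reproduces the explicit chain rule
`dPA/dP_e = 1 + [TPR + K/(β_R Q(K−Q))]·dQ/dP_e`.

Elasticities `dlog v/dlog p = (dv/dp)·p/v` use signed values — a
negative parameter like `P_e = −4` legitimately yields a positive
elasticity — and are reported as NaN at `p = 0`.

Two sensitivity facts about the reference model are worth flagging
because they are counterintuitive and are asserted in the tests: the
arterial resistance of a lone in-series circuit (lungs) has *zero*
effect on steady-state output (it enters neither `CR` nor `D`), and
raising the visceral arterial resistance *increases* output (flow
shifts to the peripheral branch, whose venous resistance is lower, so
`CR` falls). The second effect is precisely why the case-1
redistribution raises cardiac output by ~41%.

## Reference model and scenarios

The bundled five-compartment model (right atrium, lungs, left atrium,
viscera ∥ periphery) carries 25 parameters: volumes (BV 5.000 L, V0
0.452 L, five unstressed volumes), five compliances, six resistances,
chest and abdominal pressures (−4 mmHg each), and five cardiac-curve
constants (balanced K = 13.5 L/min). The periphery's external
pressure is fixed at zero — it sits in neither cavity — so the
lowered-pressure scenario (`case2`, chest and abdomen to −8 mmHg)
deliberately leaves it untouched, and `V0` is held constant in every
scenario. `case1` sets the visceral arterial resistance to 73.6 and
the peripheral to 19.2 mmHg/(L/min), exactly twice and half the
normal table values.

Scenario overrides go through the same named-parameter layer as the
CLI `--set` flag and the sensitivity calculus, so any single-parameter
perturbation study can be scripted the same way.

Reported tables mirror the mixed precision of the published steady
states (integers for the large pressures, one or two decimals
elsewhere); stored values keep full double precision. One published
cell is internally inconsistent at its own precision — the case-1
central venous pressure prints 0.70 mmHg, while inverting the right
cardiac curve even at the *printed* output of 7.1 L/min gives 0.73,
and full-precision solving gives 0.715 — so the cell-by-cell table
test carries a documented 0.02 mmHg band for that single entry.

## Determinism and problem sizes

Nothing in the package draws random numbers: solves are bracketed
deterministic refinements, and regenerating a report from the same
config and version is byte-identical (provenance deliberately records
no timestamp). Randomness appears only in the test suite's generators
(seeded numpy `default_rng`, derandomized hypothesis profiles): 100
random closed-loop models for cross-solver agreement, 30 random
series-parallel trees against the dense nodal oracle, grids of
(μ, λ) for root bracketing and series properties. These sizes keep
the whole suite under a few seconds while exercising every branch of
the reduction and solver logic.

The steady-state identity between abdominal and intrathoracic pressure
(`P_a = P_e`) that holds physiologically is *not* enforced: the two
are independent parameters (and independent pressure groups), which is
what makes `∂Q/∂P_e` at fixed `P_a` well defined.

## Known limitations

- Only series-parallel vascular topologies; no bridges or meshes.
- No dynamics: transients, pulsatility, venous collapse, baroreflex
  and autoregulation are out of scope by construction.
- The sigmoid cardiac-curve family is fixed; other monotone forms
  would slot into the same framework (only invertibility is used by
  the 2-D and 1-D reductions) but are not implemented.
- Analytic sensitivities require the balanced special case; unbalanced
  models fall back to finite differences.
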