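# steadycirc

Steady-state, closed-circulation compartmental hemodynamics: reduce any
N-compartment cardiovascular model with Starling-type cardiac function
curves to a single nonlinear equation for cardiac output, solve it three
equivalent ways, and differentiate it exactly with respect to any
parameter.

## The model class

A circulation is a closed loop: two heart sides pumping along
Starling-type function curves

$$F(P) = \frac{K}{1 + \alpha\,e^{-\beta (P - P^e)}}$$

(maximum output $K$, shape $\alpha$, steepness $\beta$, external
pericardial/intrathoracic pressure $P^e$), feeding pulmonary and
systemic circuits of vascular compartments with linear compliance
$V_n = V_n^0 + C_n (P_n - P_n^e)$ and series-parallel arterial/venous
resistances.

In steady state both sides pump the same cardiac output $Q$, and every
compartmental pressure is affine in $Q$ and its downstream atrial
pressure: $P_n = P_{\text{atrium}} + G_n Q$, with pressure-transfer
coefficients $G_n$ obtained by exact series-parallel reduction.
Because total blood volume is fixed, the operating point
$(P_R, P_L, Q)$ is confined to the **conservation plane**

$$C_S P_R + C_P P_L + C_R Q = D,$$

whose four coefficients are plain sums over the model's compliances,
resistances and volumes.  Eliminating the atrial pressures through the
(invertible) cardiac curves collapses everything — regardless of how
many compartments the model has or how they are arranged — to one
scalar equation.  When both heart sides share $K$ and $P^e$ it takes
the two-parameter dimensionless form

$$Z = \mu + \lambda \log\frac{1-Z}{Z}, \qquad Z = Q/K,$$

with a unique root in $(0,1)$.  The package solves this (and the
general unbalanced form) by bracketed Brent refinement, offers the 2-D
composite-flow-curve and 3-D surface constructions as numeric exports,
evaluates the Lagrange-inversion series $Z(\mu,\lambda)$ by symbolic
differentiation, and computes exact parameter sensitivities
$\partial Q/\partial p$ and elasticities
$\partial \log Q/\partial \log p$ by implicit differentiation —
cross-checked against full re-solves.

A fully parameterized five-compartment reference circulation (right
atrium, lungs, left atrium, viscera ∥ periphery, with chest and
abdominal pressure cavities) ships with the package, along with its two
classic perturbations: redistribution of systemic arterial resistance
(`case1`) and lowered intrathoracic/abdominal pressure (`case2`).

## Who this is for

Physiologists and modelers who want a transparent, fully inspectable
steady-state circulation — for teaching the cardiac-output/venous-return
construction, for probing parameter sensitivity hypotheses (e.g. how
central venous pressure responds to intrathoracic pressure), or as an
analytically tractable baseline next to large dynamic models.

## Worked example

```python
from steadycirc import (build_reference_model, apply_scenario,
                        reduced_mu_lambda, steady_state,
                        derived_hemodynamics, dQ_dp)

model = build_reference_model()
rf = reduced_mu_lambda(model)
print(f"mu = {rf.mu:.3f}, lambda = {rf.lam:.4f}")   # mu = 0.326, lambda = 0.0838

state = steady_state(model)
print(f"Q = {state.Q:.2f} L/min at CVP = {state.P_R:.2f} mmHg")
# Q = 5.00 L/min at CVP = 0.00 mmHg

case1 = apply_scenario(model, "case1")   # double RA_viscera, halve RA_periphery
s1 = steady_state(case1)
dh = derived_hemodynamics(case1, s1)
print(f"case1: Q = {s1.Q:.2f}, PA = {dh.PA:.0f} mmHg, periphery fraction {dh.f5:.2f}")
# case1: Q = 7.06, PA = 116 mmHg, periphery fraction 0.79

r = dQ_dp(model, "P_e")                  # intrathoracic pressure sensitivity
print(f"dQ/dP_e = {r.dQ_dp:.3f} (L/min)/mmHg, elasticity {r.log_sensitivity:.3f}")
# dQ/dP_e = -0.485 (L/min)/mmHg, elasticity 0.388
```

The normal state sits at a cardiac output of 5 L/min with central
venous pressure ≈ 0 mmHg; redistributing systemic resistance raises
output ~41% and routes ~79% of flow through the periphery without
touching the heart; and each mmHg fall in chest pressure recruits about
half a liter per minute of output.

Short narrative scripts, one per capability, live in `examples/`
(steady states, sensitivities, graphical constructions, the series
solution, and a custom six-compartment model).  A thin CLI wraps the
same functions:

```sh
steadycirc solve --scenario case2          # full steady-state table
steadycirc sensitivity -p P_e -p BV        # dQ/dp and elasticities
steadycirc surfaces -o grid.tsv            # 2-D/3-D graphical exports
steadycirc validate my_model.yaml          # config linting
```

Custom models are plain YAML (`steadycirc validate` checks them); see
`src/steadycirc/data/five_compartment.yaml` for the schema.

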