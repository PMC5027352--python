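"""Define, save and solve a custom circulation from scratch.

Builds a six-compartment variant — the systemic side split into three
parallel beds (brain, viscera, muscle) — solves it, and shows that the
solution depends only on the four reduced parameters (CS, CP, CR, D):
any rearrangement preserving them yields the same cardiac output.
"""

from steadycirc import (
    CardiacCurve,
    CirculationModel,
    Compartment,
    conservation_coefficients,
    parallel,
    steady_state,
)
from steadycirc.io import read_model, write_model

Pe = -4.0
model = CirculationModel(
    right_heart=CardiacCurve(K=13.5, alpha=55.2, beta=0.870, P_ext=Pe),
    left_heart=CardiacCurve(K=13.5, alpha=23.1, beta=0.326, P_ext=Pe),
    compartments=(
        Compartment("right_atrium", "right_atrium", C=0.012, V0n=0.102, P_ext=Pe),
        Compartment("lungs", "pulmonary", C=0.015, V0n=0.290, P_ext=Pe, RA=0.6, RV=1.2),
        Compartment("left_atrium", "left_atrium", C=0.012, V0n=0.102, P_ext=Pe),
        Compartment("brain", "systemic", C=0.020, V0n=0.250, RA=110.0, RV=6.0),
        Compartment("viscera", "systemic", C=0.130, V0n=1.380, P_ext=Pe, RA=36.8, RV=3.2),
        Compartment("muscle", "systemic", C=0.040, V0n=0.600, RA=48.0, RV=2.0),
    ),
    pulmonary_topology="lungs",
    systemic_topology=parallel("brain", "viscera", "muscle"),
    BV=5.25,
    V0=0.452,
)

write_model(model, "six_compartment.yaml")
assert read_model("six_compartment.yaml") == model  # lossless round trip

rf = conservation_coefficients(model)
state = steady_state(model)
print(f"reduced parameters: CS={rf.CS:.3f} CP={rf.CP:.3f} "
      f"CR={rf.CR:.4f} D={rf.D:.3f}")
print(f"cardiac output Q = {state.Q:.3f} L/min at CVP = {state.P_R:.2f} mmHg")
for cid in ("brain", "viscera", "muscle"):
    g = model.g_coefficients()
    print(f"  {cid:<8} flow fraction {g.fractions[cid]:.3f}  "
          f"P = {state.pressures[cid]:.2f} mmHg  V = {state.volumes[cid]:.3f} L")
print(f"volume conservation residual: {state.residual_volume:.2e} L")
print("wrote six_compartment.yaml")
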