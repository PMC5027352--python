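"""Numeric backing for the 2-D and 3-D graphical constructions.

Exports (1) the composite flow line — the model's "venous return"
curve — together with the right-heart Starling curve, whose
intersection is the operating point, and (2) the three surfaces over
the (P_R, P_L) plane whose mutual intersection is the same point.
Tables are written as TSV for plotting with any external tool.
"""

import numpy as np

from steadycirc import (
    build_reference_model,
    composite_flow_line,
    solve_2d,
    steady_state,
    surface_grids,
)

model = build_reference_model()

# --- 2-D: composite flow line vs right cardiac curve ---------------------
line = composite_flow_line(model)
P_R, Q = solve_2d(model)
print(f"composite flow line: Q = {line.A:.3f} - {line.B:.3f} * P_R")
print(f"intersection with right Starling curve: P_R = {P_R:.3f} mmHg, "
      f"Q = {Q:.3f} L/min")

ps = np.linspace(-6.0, 6.0, 25)
with open("composite_line.tsv", "w") as fh:
    fh.write("P_R\tQ_line\tQ_starling\n")
    for p in ps:
        fh.write(f"{p}\t{line.q_at(p)}\t{model.right_heart.flow(p)}\n")

# --- 3-D: two Starling sheets and the conservation plane -----------------
grids = surface_grids(model, (-6.0, 6.0), (-2.0, 10.0), n_points=49)
grids.to_frame().to_csv("surfaces.tsv", sep="\t", index=False)

state = steady_state(model)
print(f"steady state (mutual surface intersection): "
      f"(P_R, P_L, Q) = ({state.P_R:.3f}, {state.P_L:.3f}, {state.Q:.3f})")
print("wrote composite_line.tsv (25 samples) and surfaces.tsv (49x49 grid)")
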