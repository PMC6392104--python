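"""Fixed points of the Tbet positive-feedback loop.

The isolated Tbet equation (no antigen) is bistable under the shipped
parameter set: concentrations below the unstable point decay to 0
(memory-precursor fate), concentrations above it converge to the high
stable state (short-lived effector fate).
"""

import numpy as np

from cd8sim import MolecularParams, check_bistability, step_molecular, tbet_fixed_points
from cd8sim.molecular import EnvironmentInputs
from cd8sim.params import TB

params = MolecularParams()
print("bistability condition satisfied:", check_bistability(params))
for root, stable in tbet_fixed_points(params, with_stability=True):
    print(f"  steady state {root:8.2f} mol/L  ({'stable' if stable else 'unstable'})")

# trajectories from either side of the unstable point
tb_u = tbet_fixed_points(params)[1]
for start in (0.8 * tb_u, 1.2 * tb_u):
    y = np.zeros(6)
    y[TB] = start
    for _ in range(400):
        y = step_molecular(y, EnvironmentInputs(), params, dt=1.0)
    print(f"  Tb(0) = {start:6.2f}  ->  Tb(400 h) = {y[TB]:8.2f} mol/L")

print(
    "\nCells whose Tbet falls below the unstable point are captured by the\n"
    "low basin (future memory); above it they commit to the effector state."
)
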