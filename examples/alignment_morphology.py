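"""Cell alignment and the strain field around the clamps after four days.

Runs the reference construct to day 4 and reports, per region, the axial
alignment order parameter of the cells (1/3 = random, 1 = perfectly
longitudinal) and the mean principal-strain magnitude of the accumulated
deformation.  Away from the clamped ends the cells align with the long axis
— the direction of relative tension in a tethered contracting gel — while
elements at the clamped faces see a locally distorted field and the corner
regions deviate from the axis.
"""

import numpy as np

from constructsim import SimulationConfig, order_parameter, principal_guidance, run
from constructsim.coupling import DAY

config = SimulationConfig(seed=1, duration=4 * DAY, snapshot_days=(0.0, 4.0))
state = run(config)

pop = state.population
x = pop.positions[:, 0]
Lx = state.mesh.extents[0]
regions = {
    "near clamps (outer sixths)": (x < Lx / 6) | (x > 5 * Lx / 6),
    "mid-construct (middle third)": (x > Lx / 3) & (x < 2 * Lx / 3),
    "whole population": np.ones(pop.n_agents, bool),
}
print("alignment order parameter at day 4 (isotropic baseline 1/3):")
for name, mask in regions.items():
    print(f"  {name:30s} {order_parameter(pop.orientations[mask]):.3f}")

strain = state.last_strain
dirs, _ = principal_guidance(strain)
deviation = np.degrees(np.arccos(np.clip(np.abs(dirs[:, 0]), 0, 1)))
nx, ny, _ = state.mesh.shape
eid = np.arange(state.mesh.n_elements)
ex, ey = eid % nx, (eid // nx) % ny
corner = ((ex < 2) | (ex >= nx - 2)) & ((ey < 2) | (ey >= ny - 2))
mid = (ex >= nx // 3) & (ex < 2 * nx // 3)
mag = strain.max_abs
print("\naccumulated strain field at day 4:")
print(f"  clamp-corner elements: |strain| {mag[corner].mean():.2e}, "
      f"direction off-axis by {deviation[corner].mean():.0f} deg")
print(f"  mid-length elements:   |strain| {mag[mid].mean():.2e}, "
      f"direction off-axis by {deviation[mid].mean():.0f} deg")
print(
    "\nAt the minute strains of the nominal parameters the clamped faces "
    "concentrate (rather than shield) strain in their corner elements; "
    "the guidance directions there are set by the clamp constraint, not by "
    "the construct's long axis."
)
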