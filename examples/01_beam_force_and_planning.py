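"""Light-sheet force model and acquisition planning.

Evaluates the radiation-pressure force the default 120 mW light sheet
exerts on a 1.9-um melamine-resin bead in water, the lateral extent of
that force, and the acquisition/sensitivity arithmetic of a volumetric
BM-mode scan.
"""

import numpy as np

from pfoce.beam import (
    DEFAULT_BEAM,
    DEFAULT_PLAN,
    acquisition_times,
    bead_volume_fraction,
    displacement_sensitivity,
    force_profile_from_model,
    glmt_force,
    max_measurable_modulus,
)
from pfoce.mechanics import MELAMINE_RESIN, MediumSpec

water = MediumSpec(refractive_index=1.33, density=1000.0)

force = glmt_force(DEFAULT_BEAM, MELAMINE_RESIN, water)[2]
print(f"peak axial force at the focus: {force * 1e12:.2f} pN")

grid_x = np.linspace(-80e-6, 80e-6, 801)
fmap = force_profile_from_model(DEFAULT_BEAM, MELAMINE_RESIN, water,
                                grid_x, np.array([0.0]))
row = fmap.force[0]
above = grid_x[row >= row.max() / 2]
print(f"lateral force FWHM: {(above.max() - above.min()) * 1e6:.1f} um")

sens = displacement_sensitivity(DEFAULT_PLAN)
print(f"shot-noise displacement sensitivity: {sens * 1e12:.1f} pm "
      f"({DEFAULT_PLAN.n_frames} frames at {DEFAULT_PLAN.snr_db:.0f} dB)")

g_max = max_measurable_modulus(force, MELAMINE_RESIN.radius, 76e-12)
print(f"max measurable G' at 76 pm experimental sensitivity: {g_max:.0f} Pa")

per, n_pos, total, total_wait = acquisition_times(DEFAULT_PLAN)
print(f"scan: {per:.1f} s x {n_pos} slow positions = {total / 60:.1f} min "
      f"({total_wait / 60:.1f} min with stage-settling waits)")

phi = bead_volume_fraction(MELAMINE_RESIN.diameter, 20e-6)
print(f"bead volume fraction at 20 um edge spacing: {phi:.2e} (< 1e-4 for live cells)")

# The force scale (~3 pN) and its 80-um lateral extent determine which beads
# a single sheet position can interrogate; the sensitivity and the force
# together bound the stiffest medium whose response is still resolvable.
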