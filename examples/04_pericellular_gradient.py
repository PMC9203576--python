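"""Pericellular stiffness gradient: segmentation, profiling, power-law fit.

Builds a synthetic scene of beads around an ellipsoidal cell whose matrix
stiffens toward the cell surface as G'(r) ~ r^-0.19, segments the cell by
temporal speckle contrast, bins G' against the distance to the cell, and
fits the decay exponent with its 95% confidence interval.
"""

import numpy as np

from pfoce.analysis import (
    distance_profile,
    distance_to_cell,
    fit_power_law,
    speckle_segment_cell,
)
from pfoce.synthetic import gen_pericellular_scene

scene = gen_pericellular_scene(
    beta=-0.19, g_background=100.0, n_beads=200,
    with_speckle_movie=True, seed=2,
)
mask = speckle_segment_cell(scene["movie"])
truth_mask = scene["cell_mask"]
dice = 2 * (mask & truth_mask).sum() / (mask.sum() + truth_mask.sum())
print(f"cell segmentation Dice vs truth: {dice:.3f}")

r = distance_to_cell(scene["positions"], mask, scene["pixel_sizes"])
prof = distance_profile(scene["g_prime"], scene["loss_ratio"], r, normalise=True)
print("distance profile (normalised to the >=30 um background):")
for rc, g, n in zip(prof.r * 1e6, prof.g_prime_mean, prof.n):
    if np.isfinite(g) and rc < 36:
        print(f"  r = {rc:4.1f} um: G'/G'_bg = {g:.2f} (n = {n})")

sel = (r > 0) & (r <= 30e-6)
beta, ci = fit_power_law(r[sel], scene["g_prime"][sel])
print(f"fitted decay exponent: {beta:+.3f} +/- {ci:.3f} (95% CI); truth -0.19")

# A negative exponent with a CI excluding zero quantifies cell-mediated
# stiffening concentrated within ~30 um of the cell surface.
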