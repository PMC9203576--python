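# pfoce — light-sheet photonic-force optical coherence elastography

`pfoce` is a Python toolkit for quantitative 3-D micromechanical imaging of
soft biological media with light-sheet radiation pressure and phase-sensitive
optical coherence tomography (OCT). Micrometre probe beads embedded in a
hydrogel or extracellular matrix are driven by a harmonically modulated
light sheet (~pN forces); their sub-nanometre oscillations, detected through
OCT phase, encode the local complex shear modulus *G\** = *G′* + i*G″*. The
package is aimed at researchers building or analysing such systems: it
provides the forward optics, the force calibration, the reconstruction
pipeline from raw complex BM-mode stacks to per-bead moduli, and the
downstream pericellular/matrix analyses — plus physics-based synthetic-data
generators with ground truth for every stage.

## The model

A bead of radius *a* and mass *m* driven by a harmonic force of amplitude
*F*<sub>rad</sub> responds with displacement amplitude *A*<sub>mech</sub> and
phase shift *φ*<sub>mech</sub> relative to the drive. The force balance gives
an effective modulus

    G̃_eff = (F_rad + m ω² A_mech e^{iφ_mech}) / (6π a A_mech e^{iφ_mech})

and the oscillating-sphere model of a rigid sphere in a viscoelastic
continuum relates it to the local modulus through the complex shear
wavenumber *k\** = ω√(ρ/G\*):

    G̃_eff = G* [1 − i k* a − (k* a)²/9]

which `pfoce` inverts by fixed-point iteration (the correction is tiny at
20 Hz and micrometre radii, so the map is strongly contractive). The drive
force comes either from a generalized Lorenz–Mie (GLMT) simulation of the
light sheet — Mie partial waves weighted by localized beam-shape
coefficients for the elliptical Gaussian focus — or from an OCT-based
calibration that tracks beads settling through a fluid of known viscosity
and solves m z̈ = F(z) − 6πηa ż + buoyancy for the depth-resolved force.

The reconstruction pipeline (`pfoce.pipeline`) demodulates each voxel's
temporal phase at the exact modulation frequency, registers common-mode
phase drift, segments bead and medium-scatter voxels by OCT magnitude SNR,
fits and subtracts the photothermal (heating-induced) optical-path
modulation as a separable complex surface, clusters voxels into beads, and
converts each bead's response plus interpolated force into *G′*, *G″*, and
the loss ratio *R* = *G″*/*G′*.

## Worked example

`examples/03_modulus_reconstruction.py` generates a synthetic BM-mode
volume for beads in a medium with *G\** = 200 + 60i Pa — with speckle
background, a photothermal phase background five times the mechanical
signal, common-mode drift, and shot-noise phase jitter at the 28 dB
operating point — and runs the full reconstruction:

```
generated 16 slow-axis stacks, 12 beads, G* = (200+60j) Pa
reconstructed 12 beads
median G'  =  193.7 Pa (truth 200.0)
median G'' =   49.3 Pa (truth 60.0)
median loss ratio R = 0.267 (truth 0.300)
```

The median storage modulus is recovered to ~3% despite the 5× photothermal
background — the central correctness property of the compensation scheme.
The other examples cover beam/force planning (`01`), trajectory-based force
calibration (`02`), pericellular stiffness-gradient analysis (`04`), and
fibre-shell metrics with deformation tracking (`05`); each prints the
numbers it computes and what they mean.

A thin CLI wraps the same workflows
(`pfoce plan | simulate | measure-force | reconstruct | analyze-collagen |
analyze-cell | analyze-timelapse`).

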