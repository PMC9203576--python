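# Methods

This note documents the physical models, numerical choices, and synthetic
study conditions behind `pfoce`, in the order data flows through the
package.

## Oscillating-sphere viscoelastic response (`pfoce.mechanics`)

A rigid sphere of radius *a* oscillating harmonically in an unbounded
viscoelastic continuum of density ρ experiences a reaction proportional to
an effective modulus

G̃_eff = G\* [1 − i k\* a − (k\* a)²/9],  k\* = ω √(ρ / G\*).

The shear wavenumber uses the principal square root (Re k\* ≥ 0) under an
e^{+iωt} time convention; this branch makes shear waves decay away from the
sphere and reproduces Stokes drag F = 6πηa·v in the purely viscous limit
G\* = iωη (verified by test). At the operating point (20 Hz, a ≈ 1 µm,
ρ ≈ 1000 kg/m³, G′ ≥ 10 Pa) |k\*a| ≲ 10⁻³, so the bracket is within 0.1%
of unity; it is retained and inverted anyway for generality.

**Inversion.** G\* is recovered from G̃_eff by fixed-point iteration
G_{n+1} = G̃_eff / (1 − i k_n a − (k_n a)²/9), starting at G̃_eff, declared
converged at relative change < 10⁻¹² (default). Because |k\*a| ≪ 1 the map
is strongly contractive and converges in a handful of iterations; a damped
Newton root finder on (Re G, Im G) serves as an independent oracle in the
tests (agreement 10⁻⁸ relative over G′ ∈ [10, 2000] Pa, G″ ∈ [1, 500] Pa).
The medium density entering k\* defaults to 1000 kg/m³ (aqueous hydrogels)
and is configurable; in this regime the recovered moduli are insensitive to
it at the per-mil level.

**Bead dynamics in fluid.** The 1-D axial equation of motion
m z̈ = F(z) − 6πηa ż + g(4/3)πa³(ρ_b − ρ_f) is integrated with LSODA
(rtol 10⁻⁸): the momentum relaxation time m/(6πηa) ≈ 0.2 µs makes the
system stiff relative to second-scale trajectories. Default bead materials:
melamine resin (1.9 µm, 1510 kg/m³, n = 1.68 at 789 nm) and polystyrene
(1.7 µm, 1050 kg/m³, n = 1.58); all configurable.

## Light-sheet optics and radiation force (`pfoce.mie`, `pfoce.beam`)

The pump beam is an elliptical Gaussian with focal intensity FWHMs of
80 µm (long axis, x) × 1.4 µm (short axis, y), 120 mW total power, each
axis diverging with its own Rayleigh range in the medium; the transverse
plane integral equals the beam power at every depth (tested by quadrature).

The radiation force on a Mie-regime bead uses the on-axis GLMT
pressure cross-section with partial-wave coefficients a_n, b_n
(Bohren–Huffman Riccati–Bessel form, Wiscombe truncation; validated against
the classical m = 1.5, x = 10 benchmark and the Rayleigh limit) and
beam-shape coefficients g_n from the localized approximation: partial wave
n samples the transverse field on a ring of radius (n + ½)/k, whose average
over an elliptical Gaussian has the closed form e^{−A} I₀(B). The series
reduces exactly to C_ext − ⟨cosθ⟩C_sca for g_n = 1 (tested to 10⁻¹⁰). The
force is F_z = (n_med/c)·I_axis·C_pr with the local on-axis intensity; at
depth the short-axis spot size entering g_n widens accordingly. Transverse
gradient forces and aberrations are not modelled; the localized
approximation for a strongly astigmatic focus carries an estimated ±20%
band on absolute force. At the default operating point the model gives
3.19 pN peak force, and the lateral force FWHM equals the intensity FWHM
(80 µm) because the cross-section varies only with depth.

**Sensitivity arithmetic.** The shot-noise displacement sensitivity is
δz = λ₀/(4πn√(2N·SNR)): the single-quadrature standard deviation of the
N-frame complex mean of per-frame optical-path noise with phase jitter
1/√SNR. The amplitude estimator (factor-2 convention) has quadrature noise
2δz; both relations are verified Monte-Carlo against the demodulator. The
maximum measurable storage modulus uses a response-amplitude floor of 4×
the displacement sensitivity: G′_max = F/(6πa·4·δz_exp). The factor 4 is
the unique constant consistent with both printed endpoints of the
instrument's stated measurable range (550 Pa at 76 pm, ~1160 Pa at 36 pm);
it is exposed as a parameter.

**Bead density planning.** The mean edge-to-edge nearest-neighbour spacing
s maps to number density through the Poisson relation
r̄ = 0.554·n^{−1/3} with r̄ = s + d, giving volume fraction n·(π/6)d³
(validated against direct Poisson placement with a periodic KD-tree).

## Force calibration from trajectories (`pfoce.force_measurement`)

Beads settling through 10% w/w glycerol–water (η = 1.31 mPa·s,
ρ = 1021 kg/m³, n = 1.3469 at room temperature — configurable) trace
streaks in space–time images. The local streak slope is the
maximum-variance projection angle of the Radon transform within sliding
windows (default 32 frames × 24 depth px, 50% overlap, 0.25° grid, with
parabolic sub-grid peak refinement); slope × (dz/dt) is the axial velocity.
Window depth placement uses a background-subtracted intensity centroid.

Two estimator refinements matter in practice and are documented here
because they are not obvious: (i) the max-variance angle is biased toward
shallow angles when the streak displacement within the window is comparable
to the point-spread width, so each coarse estimate is refined on a window
long enough for ~48 px of displacement (capped at 128 frames) with a fine
0.05° grid around the coarse angle; (ii) a long window measures the *mean*
velocity over its span, so the second-order curvature term T²/24·v̈
(estimated by a Savitzky–Golay second derivative) is subtracted before
smoothing. With both, constant-velocity recovery is quantization-limited
and the end-to-end force round trip is accurate to ~2–3% pointwise.

Velocity is smoothed with a Savitzky–Golay filter (order 2, default window
11 samples); acceleration is the filter's analytic derivative. The force
follows pointwise from the equation of motion (gravity/buoyancy included by
default for the settling geometry — ~0.02 pN for melamine beads) and is
binned onto a regular depth grid with quality weights derived from the
Radon peak contrast (windows below a contrast threshold of 0.6 are
discarded; pure-noise windows score ≲0.5, real streaks ≳0.8). Per-segment
depth profiles assemble into the 2-D force map F(x, z).

## Reconstruction pipeline (`pfoce.pipeline`)

**Demodulation.** Per voxel, the temporal phase is unwrapped (1-D in time),
converted to displacement via λ₀/(4πn_med), and least-squares fit to
A·cos(2πf_mod·t + φ) plus a constant at the *exact* modulation frequency —
the modulation is deliberately not commensurate with the acquisition
window, so a DFT bin would leak. Phases are reported relative to the drive
waveform. The additive-noise floor is estimated as the median over voxels
of half the mean squared temporal first difference: first-differencing
cancels static speckle and is insensitive both to slow common-mode drift
and to the (slow) modulation itself. The per-voxel magnitude SNR and
predicted amplitude-noise maps derive from this floor.

**Registration.** The common-mode phase of each frame is the argument of
the complex mean of S(t)·conj(S̄) over a static reference region (S̄ the
temporal-mean field). Conjugating against the reference aligns the random
speckle phases so contributions add coherently; a plain complex mean of
speckle has a Rayleigh-small resultant and injects angle noise. A uniform
drift is removed exactly up to one global constant. Shallow depth rows are
a good reference: static, and above the cumulative photothermal signal.

**Segmentation.** Bead cores are connected blobs with magnitude SNR ≥
26 dB (a 2 dB guard below the nominal 28 dB bead operating SNR, so beads
at the operating point are not lost to threshold ties) and plausible size
(4–400 voxels per plane). Exclusions, recorded with reason codes: blobs
touching a 3-voxel edge margin; pairs whose dilations (radius 2 bead
diameters) overlap — only plausible-size blobs participate, so an
above-threshold noise speck cannot disqualify a real bead. Photothermal
reference voxels have SNR in (6, 26) dB and lie outside all dilated bead
regions. All thresholds are parameters of `ReconstructionConfig`.

**Photothermal reconstruction.** The heating-induced optical-path
modulation is modelled as separable: PT(x, z) = I(x)·f(z), with I(x) the
known light-sheet long-axis intensity and f(z) a complex depth profile
estimated per depth row as the SNR-weighted complex mean of phasor/I(x)
over PT voxels (pooled across slow positions — the sheet is stationary).
|f| is constrained monotone non-decreasing in depth by isotonic regression
(the optical path accumulates along the beam); the phase is circularly
smoothed. An optional coverslip anchor rescales |f| to the direct
measurement at stated rows. The mechanical response is the complex
difference total − PT at bead voxels.

**Clustering and per-bead response.** Accepted bead voxels across slow
positions form a (slow, depth, fast) volume clustered by 26-connected
components (≥ 5 voxels). Centroids are OCT-magnitude-weighted means. The
per-bead response is the componentwise (Re, Im) median of the complex
voxel phasors: the magnitude of a noisy phasor is Rice-distributed, so a
median of *amplitudes* is biased upward near the noise floor, which would
systematically depress G′ for stiff (small-amplitude) beads; the complex
median is unbiased under symmetric noise. The amplitude-median +
circular-phase-median variant remains available (`method`), and the
circular median (minimiser of summed angular distance, ties toward the
circular mean) is part of the public API. Beads whose per-voxel amplitude
noise exceeds half the recovered amplitude are flagged "poor sinusoid
fit" — evaluated on the assembled 3-D bead rather than per 2-D plane so a
single noisy plane cannot split a bead into two clusters.

**Modulus mapping.** The force at each centroid is bilinearly interpolated
from the 2-D force map (the stationary beam axis defaults to the fast-axis
FOV centre); beads outside the map support are flagged and left without
moduli. G\* follows from the force balance and the oscillating-sphere
inversion; R = G″/G′.

## Analyses (`pfoce.analysis`)

- **Cell segmentation** by temporal speckle contrast (per-voxel temporal
  std of magnitude over its mean): dynamic intracellular scatter
  decorrelates, static matrix does not. Threshold defaults to the 99th
  percentile of observed contrast (a static calibration region is
  preferable when available); morphological closing, largest component.
- **Distance profiling**: Euclidean distance transform of the cell-mask
  complement (anisotropic sampling) at bead centroids; 3-µm bins; per-bin
  mean with Student-t 95% CIs; optional normalisation by the mean over the
  background region (≥ 30 µm), which maps the background to 1 by
  construction.
- **Stiffness-gradient exponent**: degree-1 least squares of log G′ on
  log r restricted to r ≤ 30 µm. The log–log space is the only reading
  that yields a dimensionless decay exponent; the CI comes from the slope
  standard error and the t distribution. With lognormal multiplicative
  scatter this is an exactly specified linear model, so CI coverage is
  nominal (verified at ~95% over 500 synthetic scenes).
- **Deformation statistics**: per-step bead displacements minus the mean
  over beads (the bulk sample shift), accumulated from the second time
  point — any common translation cancels exactly. The scalar deformation
  S is the Euclidean norm signed by the dataset-level major axis: the
  argmax of the direction-cosine magnitudes averaged over all beads and
  time points (zero-norm entries skipped). Grouping thresholds default to
  the 67th percentile of |S| at the final time (roughly terciles);
  configurable.
- **Shell metrics**: beads are removed by magnitude segmentation plus mask
  dilation; voxels within 3 µm of the bead circumference contribute the
  0.95 intensity quantile (fibre-thickness surrogate), the mean intensity
  (content surrogate), and the fibre volume fraction = voxels ≥ 14 dB SNR
  over voxels ≥ 6 dB (noise floor). The printed threshold pair is
  internally ordered this way because a fraction needs a denominator at
  or below its numerator's threshold; the all-shell-voxel denominator is
  available by setting the noise floor to −∞. Fibre connectivity counts
  are user-supplied (manual, blinded counting; not automated here).
- **Correlations**: Spearman rank correlation; for n ≤ 9 the two-sided
  p-value is the exact permutation probability (vectorised enumeration) —
  the t approximation is off by >0.01 at such n; larger samples use the
  tie-corrected approximation. The linear best-fit line is display-only.
- **Distribution width** σ_FWHM: Gaussian KDE (Silverman bandwidth), width
  at half the mode by linear interpolation, then deconvolved for kernel
  broadening (the KDE is the sample distribution convolved with the
  kernel, so the squared width overestimates by the squared bandwidth).
- **Group tests**: two-sided Welch t (means) and Levene (variances), with
  Pearson r added for paired samples.
- **Confocal enhancement**: zero below the 80th percentile, normalise to
  the maximum, gamma 0.4.

## Synthetic data and study conditions (`pfoce.synthetic`)

The generators emulate the measurement physics rather than re-using the
reconstruction code paths: bead responses come from the forward force
balance + oscillating-sphere relation; stacks contain static Rayleigh
speckle, 3×3×3-voxel bead reflectors at 28 dB, background at 16 dB,
separable photothermal modulation (lateral sheet intensity × linear
cumulative depth profile by default; a quadratic variant exercises model
mismatch), optional common-mode random-walk drift, and per-voxel per-frame
phase jitter of 1/√SNR — the shot-noise convention under which the
sensitivity formula is exact, which the demodulator reproduces within 5%.
Bead centres are rejection-sampled at ≥ 16 px (12 µm) separation, the
typical bead spacing in these preparations. What the generators do *not*
emulate: depth-dependent OCT roll-off, speckle decorrelation of the matrix,
aberrated beam profiles, non-separable photothermal fields, and bead
polydispersity — so passing recovery tests demonstrate correctness of the
reconstruction chain under the stated noise model, not robustness to every
instrument non-ideality.

Problem sizes in the test suite are scaled to bench-top runs: recovery
studies use 64×64-voxel frames, 36 slow positions, 2048 frames (4.8 s at
425 Hz — enough that the per-voxel amplitude noise sits well below the
stiffest group's response), 50 beads per modulus group at
G′ ∈ {50, 200, 500} Pa with a photothermal background 5× the mechanical
amplitude; force-calibration round trips use 5 lateral segments × 3 beads
with the axial force extent of 34 µm (σ) matching the instrument's
measured 80 µm FWHM. The acceptance script's quantities are fully
deterministic (Mie series + quadrature) and take seconds.

## Known limitations

- The localized-approximation GLMT is accurate to tens of percent for a
  strongly astigmatic focus; absolute forces inherit that band (the
  calibration path exists precisely to avoid relying on it).
- Faxén wall corrections, Basset history forces, nonlinear rheology and
  poroelastic two-phase behaviour are out of scope.
- The photothermal model is separable and monotone in depth; strongly
  non-separable heating (e.g. absorbing inclusions) would bias the
  compensation.
- The Radon velocimeter's accuracy degrades for streak displacements below
  the point-spread width even with adaptive windows; very slow beads
  (< ~15 µm/s at the default rendering) should be excluded via the quality
  weights.
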