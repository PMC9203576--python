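"""Light-sheet beam model, radiation force, and acquisition planning.

The pump beam is a weakly focused light sheet: an elliptical Gaussian focus
with a long axis (lateral, x) of ~80 um FWHM and a short axis (y) of ~1.4 um
FWHM, harmonically power-modulated at ~20 Hz.  Each axis diverges
independently with its own Rayleigh range, so the transverse plane integral
of intensity equals the beam power at every depth.

Radiation force on a Mie-regime bead is computed from the generalized
Lorenz-Mie pressure cross-section (:mod:`pfoce.mie`) scaled by the local
on-axis intensity; the localized approximation ties the partial-wave weights
to the local short-axis spot size.  Because the beam-shape coefficients are
approximate, absolute forces carry an estimated ~20% model band.

Also here: shot-noise displacement-sensitivity arithmetic, the maximum
measurable modulus implied by a force and a displacement noise floor,
acquisition-time bookkeeping, and the bead volume-fraction estimate from a
mean nearest-neighbour spacing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import mie
from .mechanics import BeadSpec, MediumSpec

__all__ = [
    "LightSheetBeam",
    "AcquisitionPlan",
    "ForceProfile2D",
    "DEFAULT_BEAM",
    "DEFAULT_PLAN",
    "lightsheet_intensity",
    "glmt_force",
    "force_profile_from_model",
    "displacement_sensitivity",
    "max_measurable_modulus",
    "acquisition_times",
    "bead_volume_fraction",
]

C_LIGHT = 299792458.0
FWHM_TO_WAIST = 1.0 / np.sqrt(2.0 * np.log(2.0))  # w = FWHM / sqrt(2 ln 2)


@dataclass(frozen=True)
class LightSheetBeam:
    """Elliptical-Gaussian pump beam.

    ``fwhm_long``/``fwhm_short`` are intensity FWHMs of the focal spot along
    the long (x) and short (y) axes; power is the total beam power delivered
    to the sample; modulation_frequency is the harmonic power-modulation
    frequency driving the bead oscillation.
    """

    wavelength: float = 789e-9
    power: float = 0.120
    fwhm_long: float = 80e-6
    fwhm_short: float = 1.4e-6
    modulation_frequency: float = 20.0

    def __post_init__(self) -> None:
        for name in ("wavelength", "power", "fwhm_long", "fwhm_short", "modulation_frequency"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.fwhm_long <= self.fwhm_short:
            raise ValueError("fwhm_long must exceed fwhm_short")

    @property
    def waist_long(self) -> float:
        """1/e^2-intensity waist radius along the long axis (m)."""
        return self.fwhm_long * FWHM_TO_WAIST

    @property
    def waist_short(self) -> float:
        return self.fwhm_short * FWHM_TO_WAIST

    def rayleigh_range(self, waist: float, medium_index: float) -> float:
        return np.pi * waist**2 * medium_index / self.wavelength

    def spot_sizes(self, z, medium_index: float):
        """Waist radii (w_long(z), w_short(z)) at depth z from the focus."""
        zx = self.rayleigh_range(self.waist_long, medium_index)
        zy = self.rayleigh_range(self.waist_short, medium_index)
        z = np.asarray(z, dtype=float)
        wx = self.waist_long * np.sqrt(1.0 + (z / zx) ** 2)
        wy = self.waist_short * np.sqrt(1.0 + (z / zy) ** 2)
        return wx, wy

    @property
    def omega(self) -> float:
        return 2.0 * np.pi * self.modulation_frequency


@dataclass(frozen=True)
class AcquisitionPlan:
    """BM-mode acquisition parameters and the OCT detection operating point."""

    frame_rate: float = 425.0
    n_frames: int = 6400
    fast_range: float = 90e-6
    pixel_size: float = 0.75e-6
    slow_range: float = 350e-6
    slow_step: float = 0.75e-6
    wait_time: float = 6.0
    oct_wavelength: float = 1300e-9
    medium_index: float = 1.34
    snr_db: float = 28.0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.pixel_size <= 0 or self.frame_rate <= 0:
            raise ValueError("pixel_size and frame_rate must be positive")
        if self.slow_range > 0 and not (0 < self.slow_step <= self.slow_range):
            raise ValueError("slow_step must lie in (0, slow_range]")


@dataclass
class ForceProfile2D:
    """Radiation-pressure force magnitude on a regular (x, z) grid.

    ``grid_x`` runs along the light-sheet long axis, ``grid_z`` along depth;
    both strictly increasing.  ``force`` is non-negative with shape
    ``(len(grid_z), len(grid_x))``; missing cells are NaN.
    """

    grid_x: np.ndarray
    grid_z: np.ndarray
    force: np.ndarray
    provenance: str = "simulated"

    def __post_init__(self) -> None:
        self.grid_x = np.asarray(self.grid_x, dtype=float)
        self.grid_z = np.asarray(self.grid_z, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        for g, name in ((self.grid_x, "grid_x"), (self.grid_z, "grid_z")):
            if g.ndim != 1 or (len(g) > 1 and np.any(np.diff(g) <= 0)):
                raise ValueError(f"{name} must be 1-D strictly increasing")
        if self.force.shape != (len(self.grid_z), len(self.grid_x)):
            raise ValueError("force must have shape (n_z, n_x)")
        if np.any(self.force[np.isfinite(self.force)] < 0):
            raise ValueError("force values must be non-negative")

    def interpolate(self, x: float, z: float) -> float:
        """Bilinear interpolation; NaN outside the grid support."""
        from scipy.interpolate import RegularGridInterpolator

        interp = RegularGridInterpolator(
            (self.grid_z, self.grid_x), self.force, bounds_error=False, fill_value=np.nan
        )
        return float(interp((z, x)))


DEFAULT_BEAM = LightSheetBeam()
DEFAULT_PLAN = AcquisitionPlan()


def lightsheet_intensity(beam: LightSheetBeam, x, y, z, medium_index: float = 1.33):
    """Intensity (W/m^2) of the diverging elliptical-Gaussian sheet.

    ``z`` is depth relative to the focal plane.  The plane integral over
    (x, y) equals the beam power at every z.
    """
    wx, wy = beam.spot_sizes(z, medium_index)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    peak = 2.0 * beam.power / (np.pi * wx * wy)
    return peak * np.exp(-2.0 * x**2 / wx**2 - 2.0 * y**2 / wy**2)


def glmt_force(
    beam: LightSheetBeam,
    bead: BeadSpec,
    medium: MediumSpec,
    position=(0.0, 0.0, 0.0),
) -> np.ndarray:
    """Radiation force vector (N) on a bead at ``position`` = (x, y, z).

    The axial (z, propagation) component dominates for a weakly focused
    sheet and is computed as ``(n_med/c) * I(x, y, z) * C_pr`` with the GLMT
    on-axis pressure cross-section evaluated with localized beam-shape
    coefficients at the local short-axis spot size.  Transverse gradient
    forces are not modelled (returned as 0); the force is linear in power.
    """
    x, y, z = position
    n_med = medium.refractive_index
    k = 2.0 * np.pi * n_med / beam.wavelength
    size_param = k * bead.radius
    m_rel = bead.refractive_index / n_med
    wx, wy = beam.spot_sizes(z, n_med)
    c_pr = mie.pressure_cross_section(m_rel, size_param, k, w_short=float(wy), w_long=float(wx))
    intensity = lightsheet_intensity(beam, x, y, z, n_med)
    f_axial = n_med / C_LIGHT * intensity * c_pr
    return np.array([0.0, 0.0, float(f_axial)])


def force_profile_from_model(
    beam: LightSheetBeam,
    bead: BeadSpec,
    medium: MediumSpec,
    grid_x: np.ndarray,
    grid_z: np.ndarray,
) -> ForceProfile2D:
    """Sample the axial GLMT force on an (x, z) grid at y = 0.

    The pressure cross-section depends on depth only (through the local spot
    size), so each depth row is one cross-section evaluation scaled by the
    lateral intensity profile.
    """
    grid_x = np.asarray(grid_x, dtype=float)
    grid_z = np.asarray(grid_z, dtype=float)
    n_med = medium.refractive_index
    force = np.empty((len(grid_z), len(grid_x)))
    for i, z in enumerate(grid_z):
        on_axis = glmt_force(beam, bead, medium, (0.0, 0.0, z))[2]
        wx, _ = beam.spot_sizes(z, n_med)
        force[i] = on_axis * np.exp(-2.0 * grid_x**2 / wx**2)
    return ForceProfile2D(grid_x=grid_x, grid_z=grid_z, force=force, provenance="simulated")


def displacement_sensitivity(plan: AcquisitionPlan) -> float:
    """Shot-noise-limited displacement sensitivity (m) of the demodulated response.

    delta_z = lambda0 / (4 pi n sqrt(2 N SNR)), the single-quadrature
    standard deviation of the N-frame complex mean of the per-frame phase
    noise, converted to optical path length.  The amplitude-estimator
    quadrature noise is twice this value (the estimator carries a factor 2).
    """
    if plan.n_frames < 2:
        raise ValueError("need at least 2 frames")
    snr_lin = 10.0 ** (plan.snr_db / 10.0)
    return plan.oct_wavelength / (
        4.0 * np.pi * plan.medium_index * np.sqrt(2.0 * plan.n_frames * snr_lin)
    )


def max_measurable_modulus(
    force_peak: float, radius: float, sensitivity: float, snr_factor: float = 4.0
) -> float:
    """Largest storage modulus resolvable at a given displacement noise floor.

    G'_max = F / (6 pi a * snr_factor * sensitivity): the modulus at which the
    response amplitude falls to ``snr_factor`` times the displacement noise.
    """
    if min(force_peak, radius, sensitivity, snr_factor) <= 0:
        raise ValueError("all inputs must be positive")
    return force_peak / (6.0 * np.pi * radius * snr_factor * sensitivity)


def acquisition_times(plan: AcquisitionPlan):
    """Per-position and total acquisition times.

    Returns ``(per_position, n_positions, total_without_wait, total_with_wait)``
    in seconds (counts for n_positions).  The number of slow-axis positions is
    ``ceil(slow_range / slow_step)`` (1 when slow_range = 0).
    """
    per_position = plan.n_frames / plan.frame_rate
    if plan.slow_range == 0:
        n_positions = 1
    else:
        if plan.slow_step == 0:
            raise ValueError("slow_step must be positive when slow_range > 0")
        n_positions = int(np.ceil(plan.slow_range / plan.slow_step))
    total = per_position * n_positions
    total_wait = (per_position + plan.wait_time) * n_positions
    return per_position, n_positions, total, total_wait


def bead_volume_fraction(diameter: float, mean_edge_spacing: float) -> float:
    """Bead volume fraction implied by a mean edge-to-edge nearest-neighbour spacing.

    For a Poisson point process of density n, the mean centre-to-centre
    nearest-neighbour distance is ``r = 0.554 n^(-1/3)``; with
    ``r = spacing + diameter`` this yields n and the volume fraction
    ``phi = n (pi/6) d^3``.
    """
    if mean_edge_spacing <= 0:
        raise ValueError("spacing must be positive")
    r_center = mean_edge_spacing + diameter
    density = (0.554 / r_center) ** 3
    return density * np.pi / 6.0 * diameter**3
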