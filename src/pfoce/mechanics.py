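"""Viscoelastic response physics for an oscillating probe bead.

A micrometre-scale sphere embedded in a viscoelastic medium and driven by a
harmonic external force responds with an amplitude and phase lag that encode
the local complex shear modulus ``G* = G' + iG''``.  Oestreicher's model of a
sphere oscillating in a viscoelastic continuum relates the apparent
(effective) modulus sensed by the bead to the true local modulus through the
complex shear wave number ``k* = omega * sqrt(rho / G*)``:

    G_eff = G* [1 - i k* a - (k* a)^2 / 9]

At the ~20 Hz modulation frequencies and micrometre bead radii used in
photonic-force elastography, ``|k* a| << 1`` so the correction is tiny, but
it is retained (and invertible) for generality.

The sign conventions assume an ``exp(+i omega t)`` time dependence, under
which a purely viscous medium ``G* = i omega eta`` reproduces Stokes drag
``F = 6 pi eta a v`` with the velocity in quadrature to the displacement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "BeadSpec",
    "MediumSpec",
    "ComplexResponse",
    "oestreicher_geff",
    "invert_geff",
    "modulus_from_response",
    "integrate_bead_eom",
    "MELAMINE_RESIN",
    "POLYSTYRENE",
]

G_STANDARD = 9.80665  # m/s^2


@dataclass(frozen=True)
class BeadSpec:
    """Probe bead: geometry, density and optical index.

    Parameters
    ----------
    diameter : float
        Bead diameter in metres.
    density : float
        Mass density in kg/m^3.
    refractive_index : float
        Refractive index at the pump wavelength.
    material : str
        Free-form label.
    """

    diameter: float
    density: float
    refractive_index: float
    material: str = ""

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("bead diameter must be positive")
        if self.density <= 0:
            raise ValueError("bead density must be positive")
        if self.refractive_index < 1:
            raise ValueError("bead refractive index must be >= 1")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def mass(self) -> float:
        """Bead mass m = (4/3) pi a^3 rho."""
        return 4.0 / 3.0 * np.pi * self.radius**3 * self.density


@dataclass(frozen=True)
class MediumSpec:
    """Embedding medium: optical index, density, and rheology.

    ``viscosity`` applies to fluid media (force calibration in glycerol-water);
    ``complex_shear_modulus`` to viscoelastic media (hydrogels, ECM).
    """

    refractive_index: float
    density: float
    viscosity: float = 0.0
    complex_shear_modulus: complex | None = None

    def __post_init__(self) -> None:
        if self.refractive_index < 1:
            raise ValueError("medium refractive index must be >= 1")
        if self.density <= 0:
            raise ValueError("medium density must be positive")
        if self.viscosity < 0:
            raise ValueError("viscosity must be non-negative")
        if self.complex_shear_modulus is not None and self.complex_shear_modulus.real < 0:
            raise ValueError("storage modulus G' must be non-negative")


@dataclass(frozen=True)
class ComplexResponse:
    """Harmonic displacement response of a bead: amplitude, phase, frequency.

    The phase shift is referenced to the drive waveform; a negative phase is a
    lag.  Phase is stored wrapped to (-pi, pi].
    """

    amplitude: float
    phase_shift: float
    angular_frequency: float

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if not (-np.pi < self.phase_shift <= np.pi):
            raise ValueError("phase_shift must lie in (-pi, pi]")

    @property
    def phasor(self) -> complex:
        return self.amplitude * np.exp(1j * self.phase_shift)


# Default bead materials (densities and pump-wavelength indices configurable
# through BeadSpec).
MELAMINE_RESIN = BeadSpec(
    diameter=1.9e-6, density=1510.0, refractive_index=1.68, material="melamine resin"
)
POLYSTYRENE = BeadSpec(
    diameter=1.7e-6, density=1050.0, refractive_index=1.58, material="polystyrene"
)


def shear_wavenumber(g_star: complex, omega: float, rho: float) -> complex:
    """Complex shear wave number k* = omega sqrt(rho / G*), principal root.

    The principal square root (Re k* >= 0) fixes the branch so that shear
    waves decay away from the bead under the exp(+i omega t) convention.
    """
    if g_star == 0:
        raise ValueError("k* undefined for G* = 0")
    return omega * np.sqrt(rho / g_star + 0j)


def oestreicher_geff(g_star: complex, omega: float, radius: float, rho: float) -> complex:
    """Effective modulus sensed by an oscillating sphere of given radius.

    Implements G_eff = G* (1 - i k* a - (k* a)^2 / 9) with
    k* = omega sqrt(rho/G*) (principal root).  In the zero-density or
    point-sphere limit G_eff -> G*.

    Parameters
    ----------
    g_star : complex
        Local complex shear modulus G' + iG'' in Pa.
    omega : float
        Angular modulation frequency in rad/s.
    radius : float
        Bead radius in metres.
    rho : float
        Medium mass density in kg/m^3 (0 disables inertial corrections).
    """
    if g_star == 0:
        raise ValueError("G* = 0: effective modulus undefined (k* diverges)")
    if omega <= 0:
        raise ValueError("omega must be positive")
    if radius <= 0:
        raise ValueError("radius must be positive")
    if rho < 0:
        raise ValueError("rho must be non-negative")
    ka = shear_wavenumber(g_star, omega, rho) * radius
    return g_star * (1.0 - 1j * ka - ka**2 / 9.0)


def invert_geff(
    g_eff: complex,
    omega: float,
    radius: float,
    rho: float,
    tol: float = 1e-12,
    max_iter: int = 200,
) -> complex:
    """Invert the oscillating-sphere relation to recover G* from G_eff.

    Uses fixed-point iteration ``G_{n+1} = G_eff / (1 - i k_n a - (k_n a)^2/9)``
    starting from ``G_0 = G_eff``.  Because ``|k* a| << 1`` in the operating
    regime the map is strongly contractive and converges in a few iterations.

    Raises
    ------
    RuntimeError
        If the relative change has not fallen below ``tol`` within
        ``max_iter`` iterations; the message carries the last iterate and
        residual.
    """
    if g_eff == 0:
        raise ValueError("G_eff = 0 cannot be inverted")
    if tol <= 0:
        raise ValueError("tol must be positive")
    if rho == 0:
        return g_eff  # relation degenerates to the identity
    g = g_eff
    for _ in range(max_iter):
        ka = shear_wavenumber(g, omega, rho) * radius
        g_new = g_eff / (1.0 - 1j * ka - ka**2 / 9.0)
        if abs(g_new - g) <= tol * abs(g_new):
            return g_new
        g = g_new
    residual = abs(oestreicher_geff(g, omega, radius, rho) - g_eff)
    raise RuntimeError(
        f"modulus inversion did not converge within {max_iter} iterations; "
        f"last iterate {g}, residual |G_eff(G) - G_eff| = {residual:.3e} Pa"
    )


def effective_modulus_from_response(
    force: float, response: ComplexResponse, bead: BeadSpec
) -> complex:
    """Apparent modulus from the force balance on a harmonically driven sphere.

    G_eff = (F + m omega^2 A e^{i phi}) / (6 pi a A e^{i phi}),
    with m and a the bead mass and radius.
    """
    if response.amplitude <= 0:
        raise ValueError("no detectable mechanical response (zero amplitude)")
    if force <= 0:
        raise ValueError("force must be positive")
    d = response.phasor
    m = bead.mass
    omega = response.angular_frequency
    return (force + m * omega**2 * d) / (6.0 * np.pi * bead.radius * d)


def modulus_from_response(
    force: float,
    response: ComplexResponse,
    bead: BeadSpec,
    medium_rho: float = 1000.0,
    tol: float = 1e-12,
) -> complex:
    """Local complex shear modulus G* from a bead's harmonic response.

    Two steps: the force balance yields the apparent modulus G_eff
    (:func:`effective_modulus_from_response`), which is then inverted through
    the oscillating-sphere relation (:func:`invert_geff`) to remove the
    medium-inertia correction.  ``medium_rho`` defaults to 1000 kg/m^3
    (aqueous hydrogels).
    """
    g_eff = effective_modulus_from_response(force, response, bead)
    return invert_geff(g_eff, response.angular_frequency, bead.radius, medium_rho, tol=tol)


def integrate_bead_eom(
    force_profile,
    bead: BeadSpec,
    fluid: MediumSpec,
    z0: float,
    duration: float,
    dt: float,
    gravity: bool = False,
    v0: float = 0.0,
):
    """Integrate the 1-D axial equation of motion of a bead in viscous fluid.

        m z'' = F(z) - 6 pi eta a z' + g (4/3) pi a^3 (rho_bead - rho_fluid)

    The gravity/buoyancy term follows the convention that the optical force
    and +z point downward into the sample, so a bead denser than the fluid
    sediments toward +z.  The momentum relaxation time
    ``tau = m / (6 pi eta a)`` is sub-microsecond for micrometre beads, making
    the system stiff; an implicit (LSODA) integrator is used and output is
    sampled on a regular grid of spacing ``dt``.

    Parameters
    ----------
    force_profile : callable
        ``F(z)`` in newtons; must return finite values.
    z0, v0 : float
        Initial position (m) and velocity (m/s).
    duration, dt : float
        Total time and output sampling step in seconds.

    Returns
    -------
    t, z, v : ndarray
        Sampled times, positions and velocities.
    """
    if fluid.viscosity <= 0:
        raise ValueError("fluid viscosity must be positive")
    m = bead.mass
    a = bead.radius
    drag = 6.0 * np.pi * fluid.viscosity * a
    f_grav = (
        G_STANDARD * (4.0 / 3.0) * np.pi * a**3 * (bead.density - fluid.density)
        if gravity
        else 0.0
    )

    def rhs(_t, y):
        f = force_profile(y[0])
        if not np.isfinite(f):
            raise ValueError(f"non-finite force at z = {y[0]:.3e} m")
        return [y[1], (f - drag * y[1] + f_grav) / m]

    t_eval = np.arange(0.0, duration + 0.5 * dt, dt)
    sol = solve_ivp(
        rhs,
        (0.0, t_eval[-1]),
        [z0, v0],
        method="LSODA",
        t_eval=t_eval,
        rtol=1e-8,
        atol=1e-15,
        max_step=duration,
    )
    if not sol.success:
        raise RuntimeError(f"equation-of-motion integration failed: {sol.message}")
    return sol.t, sol.y[0], sol.y[1]
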