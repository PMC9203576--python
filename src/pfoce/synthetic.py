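"""Forward generators for every input the pipeline consumes, with ground truth.

Real acquisitions of this kind cannot be bundled with a software package, so
each consumer of measured data has a physics-based generator here:

* :func:`gen_bm_stacks` -- complex BM-mode stacks over a slow-axis scan:
  static Rayleigh-speckle background, bright bead reflectors whose
  interferometric phase oscillates with the mechanical response predicted
  from a ground-truth G* through the oscillating-sphere model, a separable
  depth-cumulative photothermal phase modulation, shot-noise-limited phase
  noise ``sigma_phi = 1/sqrt(SNR)`` per voxel and frame, and optional
  common-mode phase drift.
* :func:`gen_trajectory_movie` -- space-time streak images of a bead moving
  through viscous fluid under a known force profile, for force-calibration
  round trips.
* :func:`gen_pericellular_scene` -- bead records around an ellipsoidal
  dynamic-speckle cell with a power-law stiffness gradient
  ``G'(r) = G_bg (r / 30 um)^beta`` inside the pericellular region.
* :func:`gen_fibre_volume` -- random-cylinder fibre phantoms with planted
  per-bead shell-metric truth.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import mechanics
from .beam import AcquisitionPlan, ForceProfile2D, LightSheetBeam, lightsheet_intensity
from .force_measurement import TrajectoryImage
from .mechanics import BeadSpec, MediumSpec, oestreicher_geff
from .pipeline import BMStack

__all__ = [
    "SceneTruth",
    "gen_bm_stacks",
    "gen_noise_stack",
    "gen_trajectory_movie",
    "gen_pericellular_scene",
    "gen_fibre_volume",
    "bead_response_phasor",
]


@dataclass
class SceneTruth:
    """Ground truth for a synthetic BM-mode volume.

    ``positions`` are bead centroids (x fast, y slow, z depth) in metres;
    ``g_star`` the per-bead complex shear moduli; ``response`` the per-bead
    displacement phasors implied by the force profile and moduli;
    ``force`` the per-bead drive-force amplitudes.
    """

    positions: np.ndarray
    g_star: np.ndarray
    response: np.ndarray
    force: np.ndarray
    pt_amplitude: float
    pt_phase: float
    bead_snr_db: float
    background_snr_db: float
    seed: int
    extras: dict = field(default_factory=dict)


def bead_response_phasor(
    force: float,
    g_star: complex,
    bead: BeadSpec,
    omega: float,
    medium_rho: float = 1000.0,
) -> complex:
    """Displacement phasor D of a bead driven harmonically in a viscoelastic medium.

    Forward composition of the force balance and the oscillating-sphere
    relation: ``D = F / (6 pi a G_eff - m omega^2)`` with
    ``G_eff = G*(1 - i k* a - (k* a)^2/9)``.
    """
    g_eff = oestreicher_geff(g_star, omega, bead.radius, medium_rho)
    return force / (6.0 * np.pi * bead.radius * g_eff - bead.mass * omega**2)


def _bead_layout(
    rng: np.random.Generator,
    n_beads: int,
    n_slow: int,
    n_z: int,
    n_x: int,
    margin: int,
    min_sep: int,
    slow_span: int,
):
    """Random non-overlapping bead voxel centres (slow, z, x) with margins."""
    half = slow_span // 2
    chosen: list[tuple[int, int, int]] = []
    attempts = 0
    while len(chosen) < n_beads and attempts < 50000:
        attempts += 1
        iy = int(rng.integers(half, n_slow - half))
        iz = int(rng.integers(margin, n_z - margin))
        ix = int(rng.integers(margin, n_x - margin))
        if all(
            abs(iz - z0) >= min_sep or abs(ix - x0) >= min_sep or abs(iy - y0) > slow_span
            for (y0, z0, x0) in chosen
        ):
            chosen.append((iy, iz, ix))
    if len(chosen) < n_beads:
        raise RuntimeError("could not place beads with the requested separation")
    return chosen


def gen_bm_stacks(
    g_star,
    plan: AcquisitionPlan,
    beam: LightSheetBeam,
    bead: BeadSpec,
    force_map: ForceProfile2D,
    n_beads: int = 25,
    n_z: int = 64,
    n_x: int = 64,
    n_slow: int = 12,
    n_frames: int | None = None,
    bead_snr_db: float = 28.0,
    background_snr_db: float = 16.0,
    pt_relative_amplitude: float = 0.0,
    pt_phase: float = -1.0,
    pt_depth_profile: str = "linear",
    drive_phase: float = 0.3,
    drift_rms: float = 0.0,
    bead_span: int = 3,
    medium_rho: float = 1000.0,
    seed: int = 0,
):
    """Generate BM-mode stacks over a slow scan with known per-bead truth.

    ``g_star`` is a scalar or per-bead array of complex shear moduli.  Beads
    occupy ``bead_span``^3 voxel cubes; their drive force comes from the
    supplied force map at the bead (x, z).  The photothermal modulation is
    separable -- light-sheet lateral intensity times a depth profile
    ("linear" cumulative by default, "quadratic" for model-mismatch
    studies) -- with amplitude ``pt_relative_amplitude`` times the median
    mechanical amplitude.  Noise enters as per-voxel, per-frame phase jitter
    of standard deviation ``1/sqrt(SNR_voxel)`` (the shot-noise-limited
    convention of the displacement-sensitivity formula), with the voxel SNR
    set by its magnitude against a unit noise floor; ``drift_rms`` adds a
    common-mode random-walk phase per frame.

    Returns ``(stacks, truth)`` where stacks is a list of :class:`BMStack`.
    """
    rng = np.random.default_rng(seed)
    n_frames = n_frames or plan.n_frames
    omega = beam.omega
    g_star = np.broadcast_to(np.asarray(g_star, dtype=complex), (n_beads,)).copy()

    margin = 6
    min_sep = 16  # 12 um centre spacing at 0.75-um pixels, the typical bead spacing
    centres = _bead_layout(rng, n_beads, n_slow, n_z, n_x, margin, min_sep, bead_span)
    positions = np.array(
        [
            [ix * plan.pixel_size, iy * plan.slow_step, iz * plan.pixel_size]
            for (iy, iz, ix) in centres
        ]
    )
    # the pump-beam axis sits at the FOV centre in x and the focus at z = 0;
    # the force map is expressed in that beam frame
    x_axis = (n_x - 1) / 2.0 * plan.pixel_size
    forces = np.array(
        [force_map.interpolate(p[0] - x_axis, p[2]) for p in positions]
    )
    if np.any(~np.isfinite(forces)):
        raise ValueError("a bead fell outside the force-map support")
    response = np.array(
        [
            bead_response_phasor(f, g, bead, omega, medium_rho)
            for f, g in zip(forces, g_star)
        ]
    )
    if n_beads:
        max_amp = np.abs(response).max()
        opl_margin = plan.oct_wavelength / (4.0 * plan.medium_index) / 2.0  # lambda/4 wrap
        if max_amp > opl_margin:
            warnings.warn(
                f"bead amplitude {max_amp:.3e} m exceeds the lambda/4 unwrapping margin"
            )

    x_coords = np.arange(n_x) * plan.pixel_size
    x_rel = x_coords - x_coords.mean()
    lateral = lightsheet_intensity(beam, x_rel, 0.0, 0.0, plan.medium_index)
    lateral = lateral / lateral.max()
    z_frac = (np.arange(n_z) + 0.5) / n_z
    depth_profile = z_frac if pt_depth_profile == "linear" else z_frac**2
    pt_amp = pt_relative_amplitude * np.median(np.abs(response)) if n_beads else 0.0
    pt_map = pt_amp * depth_profile[:, None] * lateral[None, :]

    k_opl = 4.0 * np.pi * plan.medium_index / plan.oct_wavelength
    t = np.arange(n_frames) / plan.frame_rate
    wt = omega * t + drive_phase
    cos_t, sin_t = np.cos(wt), np.sin(wt)

    bg_amp = np.sqrt(10.0 ** (background_snr_db / 10.0))
    bead_amp = np.sqrt(10.0 ** (bead_snr_db / 10.0))
    half = bead_span // 2

    stacks: list[BMStack] = []
    for iy in range(n_slow):
        # static scene for this slow position
        mag = bg_amp * np.sqrt(rng.exponential(size=(n_z, n_x)))  # Rayleigh speckle
        static_phase = rng.uniform(-np.pi, np.pi, size=(n_z, n_x))
        # displacement phasor maps: d(t) = C cos(wt+theta_d) - S sin(wt+theta_d)
        c_map = pt_map * np.cos(pt_phase)
        s_map = pt_map * np.sin(pt_phase)
        c_map = c_map.copy()
        for b, (by, bz, bx) in enumerate(centres):
            if abs(iy - by) > half:
                continue
            sl_z = slice(bz - half, bz + half + 1)
            sl_x = slice(bx - half, bx + half + 1)
            mag[sl_z, sl_x] = bead_amp
            d = response[b]
            c_map[sl_z, sl_x] += np.abs(d) * np.cos(np.angle(d))
            s_map[sl_z, sl_x] += np.abs(d) * np.sin(np.angle(d))
        disp = (
            cos_t[:, None, None].astype(np.float32) * c_map[None].astype(np.float32)
            - sin_t[:, None, None].astype(np.float32) * s_map[None].astype(np.float32)
        )
        phase = static_phase[None].astype(np.float32) + np.float32(k_opl) * disp
        if drift_rms > 0:
            drift = np.cumsum(rng.normal(0.0, drift_rms, size=n_frames)).astype(np.float32)
            phase = phase + drift[:, None, None]
        # shot-noise-limited phase jitter: sigma_phi = 1/sqrt(SNR) per voxel,
        # with SNR = magnitude^2 against a unit noise floor
        sigma_phi = (1.0 / mag).astype(np.float32)
        phase = phase + rng.standard_normal(
            (n_frames, n_z, n_x), dtype=np.float32
        ) * sigma_phi[None]
        field = (mag[None].astype(np.float32) * np.exp(1j * phase)).astype(np.complex64)
        stacks.append(
            BMStack(
                field=field,
                frame_rate=plan.frame_rate,
                f_mod=beam.modulation_frequency,
                pixel_z=plan.pixel_size,
                pixel_x=plan.pixel_size,
                oct_wavelength=plan.oct_wavelength,
                medium_index=plan.medium_index,
                drive_phase=drive_phase,
                slow_position=iy * plan.slow_step,
            )
        )
    truth = SceneTruth(
        positions=positions,
        g_star=g_star,
        response=response,
        force=forces,
        pt_amplitude=pt_amp,
        pt_phase=pt_phase,
        bead_snr_db=bead_snr_db,
        background_snr_db=background_snr_db,
        seed=seed,
        extras={"lateral_shape": lateral, "centres": centres,
                "depth_profile": pt_depth_profile},
    )
    return stacks, truth


def gen_noise_stack(
    plan: AcquisitionPlan,
    f_mod: float = 20.0,
    n_z: int = 40,
    n_x: int = 50,
    n_frames: int = 1024,
    snr_db: float = 28.0,
    drive_phase: float = 0.0,
    seed: int = 0,
) -> BMStack:
    """Noise-only BM stack: constant magnitude, pure phase jitter 1/sqrt(SNR).

    Every voxel has identical magnitude at the stated SNR and no signal, so
    the demodulated phasors sample the displacement noise floor directly --
    the fixture behind shot-noise sensitivity checks.
    """
    rng = np.random.default_rng(seed)
    snr_lin = 10.0 ** (snr_db / 10.0)
    mag = np.sqrt(snr_lin)
    phase = rng.standard_normal((n_frames, n_z, n_x)) / np.sqrt(snr_lin)
    field = (mag * np.exp(1j * phase)).astype(np.complex64)
    return BMStack(
        field=field,
        frame_rate=plan.frame_rate,
        f_mod=f_mod,
        pixel_z=plan.pixel_size,
        pixel_x=plan.pixel_size,
        oct_wavelength=plan.oct_wavelength,
        medium_index=plan.medium_index,
        drive_phase=drive_phase,
        slow_position=0.0,
    )


def gen_trajectory_movie(
    force_profile,
    bead: BeadSpec,
    fluid: MediumSpec,
    z0: float,
    duration: float,
    frame_rate: float = 425.0,
    dz: float = 0.4e-6,
    n_z: int = 256,
    psf_fwhm: float = 2.5e-6,
    noise_snr_db: float = 20.0,
    gravity: bool = True,
    x_position: float = 0.0,
    segment_index: int = 0,
    seed: int = 0,
):
    """Render the space-time streak of one bead settling through viscous fluid.

    The trajectory comes from :func:`pfoce.mechanics.integrate_bead_eom`
    under ``force_profile`` (callable F(z)); the streak is a Gaussian axial
    point-spread of the given FWHM plus additive Gaussian intensity noise at
    ``noise_snr_db`` below the streak peak.  If the bead exits the rendered
    depth window the movie is truncated (flagged in the returned truth).

    Returns ``(TrajectoryImage, truth)`` with truth holding the sampled
    (t, z, v) and a ``truncated`` flag.
    """
    rng = np.random.default_rng(seed)
    dt = 1.0 / frame_rate
    t, z, v = mechanics.integrate_bead_eom(
        force_profile, bead, fluid, z0=z0, duration=duration, dt=dt, gravity=gravity
    )
    z_max = (n_z - 1) * dz
    inside = (z >= 0) & (z <= z_max)
    truncated = not inside.all()
    if truncated:
        last = int(np.argmin(inside)) if not inside[0] else int(np.argmax(~inside))
        t, z, v = t[:last], z[:last], v[:last]
        if len(t) < 8:
            raise ValueError("bead exits the rendered window almost immediately")
    sigma = psf_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    grid = np.arange(n_z) * dz
    img = np.exp(-0.5 * ((grid[None, :] - z[:, None]) / sigma) ** 2)
    noise_rms = 10.0 ** (-noise_snr_db / 20.0)
    img = img + rng.normal(0.0, noise_rms, size=img.shape)
    img = np.clip(img, 0.0, None)
    traj = TrajectoryImage(
        data=img, dt=dt, dz=dz, x_position=x_position, segment_index=segment_index
    )
    return traj, {"t": t, "z": z, "v": v, "truncated": truncated}


def gen_pericellular_scene(
    beta: float = -0.19,
    g_background: float = 100.0,
    n_beads: int = 150,
    loss_ratio_background: float = 0.25,
    scatter_cv: float = 0.15,
    fov: tuple[float, float, float] = (80e-6, 120e-6, 80e-6),
    cell_semiaxes: tuple[float, float, float] = (8e-6, 25e-6, 8e-6),
    pericellular_extent: float = 30e-6,
    pixel: float = 1.5e-6,
    with_speckle_movie: bool = False,
    n_frames: int = 16,
    seed: int = 0,
):
    """Bead records around an ellipsoidal cell with a power-law stiffness gradient.

    Truth: ``G'(r) = G_bg (r / extent)^beta`` for ``r <= extent`` and
    ``G_bg`` beyond, with lognormal multiplicative scatter of coefficient of
    variation ``scatter_cv`` (the paired loss ratio gets a mild opposing
    trend).  Bead positions are uniform outside the cell; distances are
    measured from the cell surface on the voxel grid, consistently with the
    analysis pipeline.  With ``with_speckle_movie`` a magnitude movie
    (t, x, y, z voxels) with frame-decorrelating speckle inside the cell and
    static speckle outside is returned for segmentation tests.

    Returns a dict with bead positions, distances ``r``, sampled ``g_prime``
    and ``loss_ratio``, the cell mask and pixel sizes, truth parameters, and
    optionally the movie.
    """
    if n_beads < 10:
        raise ValueError("need at least 10 beads")
    rng = np.random.default_rng(seed)
    shape = tuple(int(round(f / pixel)) for f in fov)
    centre = np.array([(s - 1) / 2.0 * pixel for s in shape])
    grids = np.meshgrid(*[np.arange(s) * pixel for s in shape], indexing="ij")
    ell = sum(
        ((g - c) / ax) ** 2 for g, c, ax in zip(grids, centre, cell_semiaxes)
    )
    cell_mask = ell <= 1.0

    from scipy import ndimage

    dist = ndimage.distance_transform_edt(~cell_mask, sampling=(pixel,) * 3)
    positions = []
    while len(positions) < n_beads:
        p = rng.uniform(0.0, 1.0, size=3) * (np.array(shape) - 1) * pixel
        idx = tuple(np.round(p / pixel).astype(int))
        if not cell_mask[idx]:
            positions.append(p)
    positions = np.array(positions)
    idx = np.round(positions / pixel).astype(int)
    r = dist[tuple(idx.T)]

    rel = np.clip(r / pericellular_extent, None, 1.0)
    rel = np.maximum(rel, pixel / pericellular_extent)  # guard r = 0 at the surface
    g_true = g_background * rel**beta
    sigma_ln = np.sqrt(np.log(1.0 + scatter_cv**2))
    g_prime = g_true * rng.lognormal(-sigma_ln**2 / 2.0, sigma_ln, size=n_beads)
    lr_true = loss_ratio_background * rel ** (-0.3 * beta)
    loss_ratio = lr_true * rng.lognormal(-sigma_ln**2 / 2.0, sigma_ln, size=n_beads)

    out = {
        "positions": positions,
        "r": r,
        "g_prime": g_prime,
        "loss_ratio": loss_ratio,
        "cell_mask": cell_mask,
        "pixel_sizes": np.array([pixel] * 3),
        "beta": beta,
        "g_background": g_background,
        "extent": pericellular_extent,
        "seed": seed,
    }
    if with_speckle_movie:
        static = np.sqrt(rng.exponential(size=shape))
        frames = np.empty((n_frames,) + shape)
        for i in range(n_frames):
            dynamic = np.sqrt(rng.exponential(size=shape))
            frames[i] = np.where(cell_mask, dynamic, static)
        out["movie"] = frames
    return out


def gen_fibre_volume(
    n_fibres: int = 40,
    shape: tuple[int, int, int] = (48, 48, 48),
    pixel: float = 1.0e-6,
    radius_range: tuple[float, float] = (0.8e-6, 2.4e-6),
    background_level: float = 1.0,
    fibre_gain: float = 40.0,
    n_beads: int = 20,
    bead_radius: float = 0.95e-6,
    link_moduli: bool = False,
    seed: int = 0,
):
    """Random-cylinder fibre phantom with planted per-bead shell truths.

    Fibres are straight cylinders of random orientation and radius drawn
    from ``radius_range``; voxel intensity is the background level plus
    ``fibre_gain`` scaled by the fibre radius (thicker fibres scatter more).
    Beads are planted at random positions with a minimum separation.  With
    ``link_moduli`` a per-bead storage modulus is derived monotonically from
    the local fibre occupancy (plus mild noise) so rank-correlation
    behaviour can be exercised against a planted association.

    Returns a dict with the intensity volume, noise power (background^2),
    bead centroids, and when requested the linked ``g_prime`` array.
    """
    rng = np.random.default_rng(seed)
    grids = np.meshgrid(*[np.arange(s) * pixel for s in shape], indexing="ij")
    pts = np.stack([g.ravel() for g in grids], axis=1)
    extent = np.array(shape) * pixel
    vol = np.full(shape, background_level, dtype=float)
    for _ in range(n_fibres):
        p0 = rng.uniform(0.0, 1.0, 3) * extent
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        radius = rng.uniform(*radius_range)
        rel = pts - p0
        along = rel @ direction
        perp2 = np.einsum("ij,ij->i", rel, rel) - along**2
        hit = perp2 <= radius**2
        gain = fibre_gain * radius / radius_range[1]
        vol.ravel()[hit] = np.maximum(vol.ravel()[hit], background_level + gain)
    centroids = []
    min_sep = 4.0 * bead_radius
    attempts = 0
    while len(centroids) < n_beads and attempts < 20000:
        attempts += 1
        p = rng.uniform(0.1, 0.9, 3) * extent
        if all(np.linalg.norm(p - q) >= min_sep for q in centroids):
            centroids.append(p)
    centroids = np.array(centroids)
    out = {
        "volume": vol,
        "noise_power": background_level**2,
        "centroids": centroids,
        "pixel_sizes": np.array([pixel] * 3),
        "seed": seed,
    }
    if link_moduli:
        occ = []
        for c in centroids:
            d2 = sum((g - ci) ** 2 for g, ci in zip(grids, c))
            shell = (d2 <= (bead_radius + 3e-6) ** 2) & (d2 > bead_radius**2)
            occ.append((vol[shell] > background_level).mean() if shell.any() else 0.0)
        occ = np.array(occ)
        g_prime = 50.0 + 400.0 * occ
        g_prime = g_prime * rng.lognormal(0.0, 0.05, size=len(occ))
        out["occupancy"] = occ
        out["g_prime"] = g_prime
    return out
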