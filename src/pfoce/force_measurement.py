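"""Radiation-pressure force calibration from bead trajectories in viscous fluid.

A bead released in a fluid of known viscosity accelerates under the optical
force until drag balances it; its depth-versus-time streak in a space-time
(kymograph) image therefore encodes the depth-resolved force.  The local
streak slope is extracted automatically with the Radon transform: within a
sliding window, the projection angle that maximises the variance of the
sinogram column is the angle at which rays align with the streak, and the
corresponding slope gives the instantaneous axial velocity.  Acceleration
follows from a Savitzky-Golay derivative of the velocity, and the 1-D
equation of motion is solved pointwise for the force:

    F(z(t)) = m a(t) + 6 pi eta a_bead v(t) - g (4/3) pi a_bead^3 (rho_b - rho_f)

Per-lateral-segment depth profiles are assembled into the 2-D force map
F(x, z) used by the elastography reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter
from skimage.transform import radon

from .beam import ForceProfile2D
from .mechanics import BeadSpec, G_STANDARD, MediumSpec

__all__ = [
    "TrajectoryImage",
    "Kinematics",
    "extract_kinematics",
    "recover_force_profile",
    "assemble_force_map",
    "GLYCEROL_WATER_10PCT",
]

# 10% w/w glycerol-water at room temperature: the standard calibration fluid.
GLYCEROL_WATER_10PCT = MediumSpec(
    refractive_index=1.3469, density=1021.0, viscosity=1.31e-3
)


@dataclass
class TrajectoryImage:
    """Space-time (time x depth) intensity image of one bead in viscous fluid."""

    data: np.ndarray  # (n_t, n_z), non-negative intensity
    dt: float  # frame interval, s
    dz: float  # depth pixel, m
    x_position: float = 0.0  # lateral segment position, m
    segment_index: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("trajectory image must be 2-D (time, depth)")
        if self.dt <= 0 or self.dz <= 0:
            raise ValueError("dt and dz must be positive")
        if np.any(self.data < 0):
            raise ValueError("intensity must be non-negative")


@dataclass
class Kinematics:
    """Sampled bead kinematics with per-sample confidence in [0, 1]."""

    t: np.ndarray
    z: np.ndarray
    v: np.ndarray
    accel: np.ndarray
    quality: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        arrays = [np.asarray(a, dtype=float) for a in (self.t, self.z, self.v, self.accel)]
        self.t, self.z, self.v, self.accel = arrays
        if self.quality is None:
            self.quality = np.ones_like(self.t)
        self.quality = np.asarray(self.quality, dtype=float)
        lengths = {len(a) for a in (self.t, self.z, self.v, self.accel, self.quality)}
        if len(lengths) != 1:
            raise ValueError("kinematics arrays must have equal length")
        used = self.quality > 0
        for a in (self.v, self.accel):
            if np.any(~np.isfinite(a[used])):
                raise ValueError("non-finite kinematics at quality > 0 samples")


def _window_slope(window: np.ndarray, angles_deg: np.ndarray):
    """Streak slope (pixels per frame) in a (time, depth) window via Radon.

    Returns (slope, quality); quality is the peak contrast of the
    variance-versus-angle curve, 0 when no streak stands out.
    """
    img = window - window.mean()
    if not np.any(img):
        return 0.0, 0.0
    sino = radon(img, theta=angles_deg, circle=False)
    var = sino.var(axis=0)
    i = int(np.argmax(var))
    med = np.median(var)
    spread = np.median(np.abs(var - med))
    contrast = (var[i] - med) / (med + 3.0 * spread + 1e-300)
    quality = float(np.clip(contrast / (1.0 + contrast), 0.0, 1.0))
    # parabolic sub-grid refinement of the peak angle
    theta = angles_deg[i]
    if 0 < i < len(angles_deg) - 1:
        y0, y1, y2 = var[i - 1], var[i], var[i + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom < 0:
            theta = theta + 0.5 * (y0 - y2) / denom * (angles_deg[i + 1] - angles_deg[i])
    return float(np.tan(np.deg2rad(theta))), quality


def extract_kinematics(
    img: TrajectoryImage,
    window: tuple[int, int] = (32, 24),
    angle_step: float = 0.25,
    angle_max: float = 85.0,
    overlap: float = 0.5,
    min_quality: float = 0.6,
    smooth_window: int = 11,
    smooth_order: int = 2,
    min_displacement: float = 48.0,
    max_refine_frames: int = 128,
    refine: bool = True,
) -> Kinematics:
    """Depth-resolved bead velocity and acceleration from a space-time image.

    Velocity comes from the Radon streak slope in sliding windows of
    ``window = (n_t, n_z)`` pixels (``overlap`` fractional overlap in time);
    the window is centred in depth on the intensity centroid of its time
    span.  The max-variance angle loses accuracy when the streak moves less
    than a few point-spread widths within the window, so each coarse
    estimate is refined on a window long enough for a displacement of
    ``min_displacement`` pixels (capped at ``max_refine_frames`` frames)
    with a fine angle grid around the coarse angle.  Position z(t) is the
    per-window centroid; acceleration is the analytic derivative of a
    Savitzky-Golay fit to v(t).  Windows whose Radon peak contrast falls
    below ``min_quality`` get quality 0.
    """
    n_t, n_z = window
    data = img.data
    if n_t > data.shape[0] or n_z > data.shape[1]:
        raise ValueError("window does not fit inside the image")
    angles = np.arange(-angle_max, angle_max + angle_step / 2.0, angle_step)
    step = max(1, int(round(n_t * (1.0 - overlap))))
    starts = np.arange(0, data.shape[0] - n_t + 1, step)

    t_c = np.empty(len(starts))
    z_c = np.empty(len(starts))
    v = np.empty(len(starts))
    quality = np.empty(len(starts))
    t_window = np.empty(len(starts))
    z_pix = np.arange(data.shape[1])
    smooth_kernel = np.ones(5) / 5.0
    for j, s in enumerate(starts):
        block = data[s : s + n_t]
        profile = block.sum(axis=0)
        # suppress the integrated background before locating the streak
        profile = np.clip(profile - np.median(profile), 0.0, None)
        smoothed = np.convolve(profile, smooth_kernel, mode="same")
        peak = int(np.argmax(smoothed))
        lo_c = max(0, peak - n_z // 2)
        hi_c = min(data.shape[1], peak + n_z // 2 + 1)
        local = profile[lo_c:hi_c]
        total = local.sum()
        centroid = (
            local @ z_pix[lo_c:hi_c] / total if total > 0 else (data.shape[1] - 1) / 2.0
        )
        lo = int(np.clip(round(centroid - n_z / 2.0), 0, data.shape[1] - n_z))
        slope_px, q = _window_slope(block[:, lo : lo + n_z], angles)

        # adaptive refinement: stretch the window in time until the streak
        # displacement is resolvable, then search a fine angle grid
        n_ref = n_t
        if refine and q >= min_quality:
            if abs(slope_px) * n_t < min_displacement:
                n_ref = int(
                    min(
                        max_refine_frames,
                        np.ceil(min_displacement / max(abs(slope_px), 0.05)),
                    )
                )
                n_ref = max(n_ref, n_t)
            centre_t = s + (n_t - 1) / 2.0
            r_lo = int(np.clip(round(centre_t - n_ref / 2.0), 0, data.shape[0] - n_ref))
            rblock = data[r_lo : r_lo + n_ref]
            span = int(np.ceil(abs(slope_px) * n_ref)) + n_z
            zc_ref = centroid + slope_px * (r_lo + (n_ref - 1) / 2.0 - centre_t)
            z_lo = int(np.clip(round(zc_ref - span / 2.0), 0, max(1, data.shape[1] - span)))
            theta0 = np.rad2deg(np.arctan(slope_px))
            fine = np.arange(theta0 - 2.0, theta0 + 2.0 + 0.025, 0.05)
            # quality keeps the coarse-grid contrast: the fine grid spans only
            # the peak neighbourhood, so its own contrast is uninformative
            slope_ref, _ = _window_slope(rblock[:, z_lo : z_lo + span], fine)
            if np.isfinite(slope_ref):
                slope_px = slope_ref

        t_c[j] = (s + (n_t - 1) / 2.0) * img.dt
        z_c[j] = centroid * img.dz
        v[j] = slope_px * img.dz / img.dt
        t_window[j] = n_ref * img.dt if q >= min_quality else n_t * img.dt
        quality[j] = q if q >= min_quality else 0.0

    good = quality > 0
    v = np.where(good, v, 0.0)
    accel = np.zeros_like(v)
    n_good = int(good.sum())
    if n_good >= 3:
        win = min(smooth_window, n_good if n_good % 2 == 1 else n_good - 1)
        if win > smooth_order:
            dt_s = float(np.median(np.diff(t_c)))
            vg = v[good]
            # the window slope is the mean velocity over its span; remove the
            # second-order (curvature) term T^2/24 * v'' before smoothing
            if n_good > win:
                v_dd = savgol_filter(
                    vg, win, max(smooth_order, 2), deriv=2, delta=dt_s, mode="interp"
                )
                vg = vg - t_window[good] ** 2 / 24.0 * v_dd
            v[good] = savgol_filter(vg, win, smooth_order, mode="interp")
            accel[good] = savgol_filter(
                vg, win, smooth_order, deriv=1, delta=dt_s, mode="interp"
            )
    return Kinematics(t=t_c, z=z_c, v=v, accel=accel, quality=quality)


def recover_force_profile(
    kin: Kinematics,
    bead: BeadSpec,
    fluid: MediumSpec,
    gravity: bool = True,
    z_grid: np.ndarray | None = None,
):
    """Depth-resolved force F(z) from bead kinematics by the equation of motion.

    Gravity/buoyancy is included by default (the calibration geometry has the
    bead settling through glycerol-water).  Samples are resampled onto a
    regular depth grid with quality-weighted averaging; empty grid cells are
    NaN.

    Returns
    -------
    z_grid, force : ndarray
        Regular depth grid (m) and the quality-weighted mean force (N).
    """
    if fluid.viscosity <= 0:
        raise ValueError("fluid viscosity must be positive")
    used = kin.quality > 0
    if not np.any(used):
        raise ValueError("trajectory unusable: all samples have zero quality")
    a = bead.radius
    drag = 6.0 * np.pi * fluid.viscosity * a
    f_grav = (
        G_STANDARD * 4.0 / 3.0 * np.pi * a**3 * (bead.density - fluid.density)
        if gravity
        else 0.0
    )
    f_samples = bead.mass * kin.accel[used] + drag * kin.v[used] - f_grav
    z_samples = kin.z[used]
    w = kin.quality[used]

    if z_grid is None:
        span = z_samples.max() - z_samples.min()
        dz = span / 32 if span > 0 else 1.0
        z_grid = np.arange(z_samples.min(), z_samples.max() + dz / 2, dz) if span > 0 else np.array(
            [z_samples.min()]
        )
    z_grid = np.asarray(z_grid, dtype=float)
    force = np.full(len(z_grid), np.nan)
    if len(z_grid) == 1:
        force[0] = np.average(f_samples, weights=w)
        return z_grid, force
    edges = np.concatenate(
        ([z_grid[0] - (z_grid[1] - z_grid[0]) / 2], (z_grid[1:] + z_grid[:-1]) / 2,
         [z_grid[-1] + (z_grid[-1] - z_grid[-2]) / 2])
    )
    idx = np.digitize(z_samples, edges) - 1
    for i in range(len(z_grid)):
        sel = idx == i
        if np.any(sel):
            force[i] = np.average(f_samples[sel], weights=w[sel])
    return z_grid, force


def assemble_force_map(
    profiles: list[tuple[float, np.ndarray, np.ndarray]],
    smooth_lateral: bool = False,
) -> ForceProfile2D:
    """Stack per-segment depth profiles (x, z_grid, F(z)) into F(x, z).

    All profiles must share the same depth grid.  Cells without data stay
    NaN; optional 3-point lateral smoothing fills no gaps and only averages
    measured neighbours.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    order = np.argsort([p[0] for p in profiles])
    xs = np.array([profiles[i][0] for i in order])
    z_ref = np.asarray(profiles[order[0]][1], dtype=float)
    cols = []
    for i in order:
        _, z_i, f_i = profiles[i]
        if len(z_i) != len(z_ref) or not np.allclose(z_i, z_ref):
            raise ValueError("inconsistent depth grids across lateral segments")
        cols.append(np.asarray(f_i, dtype=float))
    force = np.column_stack(cols)  # (n_z, n_x)
    if smooth_lateral and force.shape[1] >= 3:
        sm = force.copy()
        for j in range(1, force.shape[1] - 1):
            trio = force[:, j - 1 : j + 2]
            with np.errstate(invalid="ignore"):
                sm[:, j] = np.nanmean(trio, axis=1)
        force = sm
    # clip tiny negative excursions from noise; the map is a force magnitude
    force = np.where(np.isfinite(force), np.clip(force, 0.0, None), np.nan)
    if len(xs) == 1:
        grid_x = xs
    else:
        grid_x = xs
    return ForceProfile2D(grid_x=grid_x, grid_z=z_ref, force=force, provenance="measured")
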