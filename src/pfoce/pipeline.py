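"""Phase-sensitive elastography reconstruction: BM-mode stacks to bead moduli.

The pipeline consumes complex BM-mode OCT stacks (one per slow-axis
position) and produces one record per probe bead with its local complex
shear modulus.  The stages mirror the physical measurement:

1. (optional) per-frame phase registration against a static reference region
   to remove common-mode interferometric drift;
2. demodulation: each voxel's temporal phase is unwrapped, converted to
   optical path length, and least-squares fit at the exact modulation
   frequency (which is deliberately not a DFT bin) to a phasor
   ``A exp(i phi)`` referenced to the drive waveform;
3. segmentation of voxels into bead cores and medium-scatter (photothermal
   reference) regions by OCT magnitude SNR, with exclusion bookkeeping;
4. photothermal (PT) reconstruction: the spurious optical-path modulation
   from light-sheet heating is fitted as a separable complex surface --
   lateral shape following the sheet's long-axis intensity, depth shape
   monotone non-decreasing (heating accumulates along the beam path);
5. complex subtraction of the PT phasor from bead voxels, clustering of
   voxels into beads, per-bead median response;
6. conversion of force + response to G* through the oscillating-sphere
   model (:mod:`pfoce.mechanics`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .beam import ForceProfile2D
from .mechanics import BeadSpec, ComplexResponse, modulus_from_response

__all__ = [
    "BMStack",
    "PhasorField",
    "SegmentationMasks",
    "PTField",
    "BeadRecord",
    "ReconstructionConfig",
    "demodulate",
    "register_phase",
    "segment",
    "reconstruct_pt",
    "isolate_mech",
    "cluster_beads",
    "map_modulus",
    "reconstruct_volume",
    "circular_median",
]


@dataclass
class BMStack:
    """Complex BM-mode OCT field at one slow-axis position.

    ``field`` has axes (time, depth, fast); acquisition metadata rides along.
    ``drive_phase`` is the phase of the force drive waveform at t = 0.
    """

    field: np.ndarray
    frame_rate: float
    f_mod: float
    pixel_z: float
    pixel_x: float
    oct_wavelength: float
    medium_index: float
    drive_phase: float = 0.0
    slow_position: float = 0.0

    def __post_init__(self) -> None:
        self.field = np.asarray(self.field)
        if self.field.ndim != 3:
            raise ValueError("field must be 3-D (time, depth, fast)")
        if self.field.shape[0] < 2:
            raise ValueError("need at least 2 frames")
        if not self.f_mod < self.frame_rate / 2.0:
            raise ValueError("modulation frequency must be below Nyquist")

    @property
    def n_frames(self) -> int:
        return self.field.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    @property
    def opl_per_radian(self) -> float:
        """Displacement per radian of interferometric phase, lambda0/(4 pi n)."""
        return self.oct_wavelength / (4.0 * np.pi * self.medium_index)


@dataclass
class PhasorField:
    """Per-voxel modulation-frequency response over (depth, fast).

    ``amplitude`` is the displacement amplitude in metres, ``phase_shift``
    the phase w.r.t. the drive waveform in (-pi, pi].  ``mean_magnitude`` is
    the time-averaged OCT magnitude, ``snr_db`` its power SNR against the
    estimated additive-noise floor, and ``noise_amplitude`` the predicted
    demodulation amplitude-noise per voxel (used for fit-quality checks).
    """

    amplitude: np.ndarray
    phase_shift: np.ndarray
    mean_magnitude: np.ndarray
    snr_db: np.ndarray
    noise_amplitude: np.ndarray | None = None

    @property
    def phasor(self) -> np.ndarray:
        return self.amplitude * np.exp(1j * self.phase_shift)


@dataclass
class SegmentationMasks:
    """Mutually exclusive voxel assignments for one stack."""

    bead_voxels: np.ndarray  # bool, accepted bead cores
    pt_voxels: np.ndarray  # bool, medium-scatter PT reference
    excluded: np.ndarray  # bool, removed from analysis
    reasons: dict[str, np.ndarray] = field(default_factory=dict)
    bead_labels: np.ndarray | None = None  # int labels of accepted beads


@dataclass
class PTField:
    """Reconstructed photothermal response surface over (depth, fast)."""

    amplitude: np.ndarray
    phase_shift: np.ndarray

    @property
    def phasor(self) -> np.ndarray:
        return self.amplitude * np.exp(1j * self.phase_shift)


@dataclass
class BeadRecord:
    """One probe bead: position, mechanical response, force, and moduli."""

    bead_id: int
    xc: float
    yc: float
    zc: float
    a_mech: float
    phi_mech: float
    n_voxels: int
    force: float = np.nan
    g_prime: float = np.nan
    g_double_prime: float = np.nan
    loss_ratio: float = np.nan
    qc_flags: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class ReconstructionConfig:
    """Thresholds and rules for segmentation and clustering.

    ``bead_snr_db`` sits a 2 dB guard band below the nominal 28 dB operating
    SNR so that beads at the operating point are retained under noise.  The
    PT window selects medium scatter above the noise floor but below bead
    brightness.  ``exclusion_dilation_diameters`` is the adjacent-bead
    exclusion radius in bead diameters; ``edge_margin`` is in voxels.
    ``fit_residual_max`` excludes beads whose demodulation noise exceeds
    that fraction of the fitted amplitude.
    """

    bead_snr_db: float = 26.0
    pt_snr_window: tuple[float, float] = (6.0, 26.0)
    edge_margin: int = 3
    exclusion_dilation_diameters: float = 2.0
    fit_residual_max: float = 0.5
    min_bead_voxels: int = 4
    max_bead_voxels: int = 400
    min_pt_voxels: int = 50
    min_cluster_voxels: int = 5


def register_phase(stack: BMStack, reference_mask: np.ndarray) -> BMStack:
    """Remove per-frame common-mode phase measured over static reference voxels.

    The common-mode phase of frame t is the argument of the complex mean of
    ``S(t) * conj(S_ref)`` over the reference mask, where ``S_ref`` is the
    temporal-mean field; conjugating against the reference aligns the random
    speckle phases so that the voxel contributions add coherently (bright
    voxels dominating), and every voxel of the frame is then rotated by the
    negative of that angle.  A spatially uniform phase drift is removed
    exactly (up to one global constant) while differential (bead or PT)
    modulation is untouched.
    """
    reference_mask = np.asarray(reference_mask, dtype=bool)
    if reference_mask.shape != stack.field.shape[1:]:
        raise ValueError("reference mask must match the (depth, fast) frame shape")
    if not reference_mask.any():
        raise ValueError("reference mask is empty")
    ref_voxels = stack.field[:, reference_mask]
    ref_field = ref_voxels.mean(axis=0)
    corr = (ref_voxels * np.conj(ref_field)[None, :]).mean(axis=1)
    if np.any(np.abs(corr) == 0):
        raise ValueError("reference region has zero complex mean in some frame")
    rot = np.exp(-1j * np.angle(corr))
    out = BMStack(
        field=stack.field * rot[:, None, None],
        frame_rate=stack.frame_rate,
        f_mod=stack.f_mod,
        pixel_z=stack.pixel_z,
        pixel_x=stack.pixel_x,
        oct_wavelength=stack.oct_wavelength,
        medium_index=stack.medium_index,
        drive_phase=stack.drive_phase,
        slow_position=stack.slow_position,
    )
    return out


def demodulate(stack: BMStack, noise_power: float | None = None) -> PhasorField:
    """Per-voxel displacement phasor at the modulation frequency.

    The temporal phase of each voxel is unwrapped, converted to displacement
    ``d(t) = phase * lambda0 / (4 pi n)``, and fit by linear least squares to
    ``A cos(2 pi f_mod t + phi)`` at the exact modulation frequency plus a
    constant offset.  NaN frames are excluded from the fit.  The reported
    phase is relative to the drive waveform.

    ``noise_power`` (complex-noise variance per voxel) is estimated when not
    supplied as the median over voxels of half the mean squared temporal
    first-difference of the field -- first-differencing cancels the static
    speckle and is insensitive to slow common-mode drift and to the (slow
    relative to the frame rate) modulation itself.  It feeds the per-voxel
    SNR and predicted amplitude-noise maps.
    """
    t = stack.times
    if t[-1] * stack.f_mod < 2.0:
        raise ValueError("need at least 2 modulation cycles for demodulation")
    n_t, n_z, n_x = stack.field.shape
    f = stack.field.reshape(n_t, -1)
    finite = np.all(np.isfinite(f), axis=0)
    phase = np.unwrap(np.angle(f), axis=0)
    d = phase * stack.opl_per_radian

    omega_t = 2.0 * np.pi * stack.f_mod * t
    basis = np.column_stack([np.cos(omega_t), np.sin(omega_t), np.ones_like(t)])
    coeff = np.full((3, f.shape[1]), np.nan)
    if finite.all():
        coeff = np.linalg.pinv(basis) @ d
    else:
        coeff[:, finite] = np.linalg.pinv(basis) @ d[:, finite]
        bad = ~finite & np.any(np.isfinite(f), axis=0)
        for j in np.flatnonzero(bad):
            ok = np.isfinite(f[:, j])
            dj = np.unwrap(np.angle(f[ok, j])) * stack.opl_per_radian
            coeff[:, j], *_ = np.linalg.lstsq(basis[ok], dj, rcond=None)
    # d(t) = A cos(wt + phi) = (A cos phi) cos - (A sin phi) sin
    amp = np.hypot(coeff[0], coeff[1])
    phi = np.arctan2(-coeff[1], coeff[0]) - stack.drive_phase
    phi = np.angle(np.exp(1j * phi))

    mag = np.abs(f)
    mean_mag = mag.mean(axis=0)
    if noise_power is None:
        diff = np.diff(f, axis=0)
        noise_power = float(np.median(0.5 * np.mean(np.abs(diff) ** 2, axis=0)))
    noise_power = max(noise_power, 1e-300)
    with np.errstate(divide="ignore"):
        snr_db = 10.0 * np.log10(np.maximum(mean_mag**2 / noise_power, 1e-300))
    snr_lin = np.maximum(mean_mag**2 / noise_power, 1e-12)
    # amplitude-estimator quadrature noise: 2x the single-quadrature
    # complex-mean noise at this voxel's SNR
    noise_amp = 2.0 * stack.opl_per_radian / np.sqrt(2.0 * n_t * snr_lin)
    return PhasorField(
        amplitude=amp.reshape(n_z, n_x),
        phase_shift=phi.reshape(n_z, n_x),
        mean_magnitude=mean_mag.reshape(n_z, n_x),
        snr_db=snr_db.reshape(n_z, n_x),
        noise_amplitude=noise_amp.reshape(n_z, n_x),
    )


def _bead_radius_pixels(bead: BeadSpec, pixel: float, diameters: float) -> int:
    return max(1, int(round(diameters * bead.diameter / pixel)))


def segment(
    stack: BMStack,
    phasors: PhasorField,
    bead: BeadSpec,
    config: ReconstructionConfig = ReconstructionConfig(),
) -> SegmentationMasks:
    """Assign voxels to bead cores or the PT reference region.

    Bead cores are connected blobs of voxels at or above ``bead_snr_db`` of
    plausible bead size.  Blobs are excluded (with reason codes) when they
    touch the edge margin or overlap another bead's exclusion dilation.
    Sinusoid-fit quality is judged later on the assembled 3-D bead (see
    :func:`cluster_beads`) so that a single noisy plane cannot split a bead.
    PT voxels have magnitude SNR inside the PT window and sit outside the
    dilated bead regions.
    """
    lo, hi = config.pt_snr_window
    if not lo < hi:
        raise ValueError("PT SNR window must be ordered (lo < hi)")
    snr = phasors.snr_db
    shape = snr.shape
    core = snr >= config.bead_snr_db
    labels, n_blobs = ndimage.label(core)
    excluded = np.zeros(shape, dtype=bool)
    reasons: dict[str, np.ndarray] = {
        "edge proximity": np.zeros(shape, dtype=bool),
        "adjacent-bead overlap": np.zeros(shape, dtype=bool),
        "implausible size": np.zeros(shape, dtype=bool),
    }
    r_dil = _bead_radius_pixels(bead, min(stack.pixel_z, stack.pixel_x),
                                config.exclusion_dilation_diameters)
    struct = ndimage.generate_binary_structure(2, 2)
    dilations = {}
    ok = {}
    m = config.edge_margin
    for lbl in range(1, n_blobs + 1):
        blob = labels == lbl
        ok[lbl] = True
        n_vox = int(blob.sum())
        if not (config.min_bead_voxels <= n_vox <= config.max_bead_voxels):
            reasons["implausible size"] |= blob
            ok[lbl] = False
            continue  # specks and merged slabs do not count as neighbours
        idx_z, idx_x = np.nonzero(blob)
        if m > 0 and (
            idx_z.min() < m or idx_x.min() < m
            or idx_z.max() >= shape[0] - m or idx_x.max() >= shape[1] - m
        ):
            reasons["edge proximity"] |= blob
            ok[lbl] = False
        dilations[lbl] = ndimage.binary_dilation(blob, structure=struct, iterations=r_dil)
    for lbl in list(dilations):
        others = np.zeros(shape, dtype=bool)
        for other, dil in dilations.items():
            if other != lbl:
                others |= dil
        if np.any(dilations[lbl] & others):
            reasons["adjacent-bead overlap"] |= labels == lbl
            ok[lbl] = False
    accepted = np.zeros(shape, dtype=bool)
    final_labels = np.zeros(shape, dtype=np.int32)
    for lbl, good in ok.items():
        if good:
            accepted |= labels == lbl
            final_labels[labels == lbl] = lbl
    for mask in reasons.values():
        excluded |= mask
    excluded &= ~accepted

    all_dilated = np.zeros(shape, dtype=bool)
    for dil in dilations.values():
        all_dilated |= dil
    pt = (snr >= lo) & (snr < hi) & ~all_dilated & ~core
    return SegmentationMasks(
        bead_voxels=accepted,
        pt_voxels=pt,
        excluded=excluded,
        reasons=reasons,
        bead_labels=final_labels,
    )


def reconstruct_pt(
    phasors: PhasorField | list[PhasorField],
    masks: SegmentationMasks | list[SegmentationMasks],
    coverslip_rows: tuple[int, int] | None = None,
    lateral_shape: np.ndarray | None = None,
    min_pt_voxels: int = 50,
    phase_smooth: int = 5,
) -> PTField:
    """Fit the 2-D photothermal response surface from medium-scatter voxels.

    Model: ``PT(x, z) = I(x) * f(z)`` where ``I(x)`` is the (known)
    light-sheet long-axis intensity shape, normalised to peak 1, and ``f(z)``
    is a complex depth profile whose magnitude is constrained monotone
    non-decreasing (heating-induced optical path accumulates with depth).
    ``f`` is estimated per depth row as the SNR-weighted complex mean of
    ``phasor / I(x)`` over PT voxels (pooled across stacks when lists are
    given), isotonic-regressed in magnitude, and circularly smoothed in
    phase.  When ``coverslip_rows`` is given the magnitude is rescaled to
    match the direct measurement over those rows.
    """
    phasor_list = phasors if isinstance(phasors, list) else [phasors]
    mask_list = masks if isinstance(masks, list) else [masks]
    if len(phasor_list) != len(mask_list):
        raise ValueError("phasors and masks lists must align")
    n_z, n_x = phasor_list[0].amplitude.shape
    if lateral_shape is None:
        lateral = np.ones(n_x)
    else:
        lateral = np.asarray(lateral_shape, dtype=float)
        if lateral.shape != (n_x,) or np.any(lateral <= 0):
            raise ValueError("lateral_shape must be positive with length n_x")
        lateral = lateral / lateral.max()

    total_pt = sum(int(m.pt_voxels.sum()) for m in mask_list)
    if total_pt < min_pt_voxels:
        raise ValueError(
            f"insufficient PT reference voxels: {total_pt} < {min_pt_voxels}"
        )
    num = np.zeros(n_z, dtype=complex)
    den = np.zeros(n_z)
    for ph, mk in zip(phasor_list, mask_list):
        w = np.where(mk.pt_voxels, 10.0 ** (ph.snr_db / 10.0), 0.0)
        scaled = ph.phasor / lateral[None, :]
        num += (w * scaled).sum(axis=1)
        den += w.sum(axis=1)
    have = den > 0
    prof = np.zeros(n_z, dtype=complex)
    prof[have] = num[have] / den[have]
    if not have.all():
        idx = np.arange(n_z)
        prof = np.interp(idx, idx[have], prof.real[have]) + 1j * np.interp(
            idx, idx[have], prof.imag[have]
        )

    mag = np.abs(prof)
    # monotone non-decreasing magnitude: pool-adjacent-violators on the
    # weighted per-row magnitudes
    from sklearn.isotonic import IsotonicRegression

    weights = np.where(have, den, den[have].min() if have.any() else 1.0)
    mag_iso = IsotonicRegression(increasing=True).fit_transform(
        np.arange(n_z), mag, sample_weight=weights
    )
    if phase_smooth > 1:
        kernel = np.ones(min(phase_smooth, n_z)) / min(phase_smooth, n_z)
        unit = np.where(mag > 0, prof / np.maximum(mag, 1e-300), 0.0 + 0.0j)
        sm = np.convolve(unit, kernel, mode="same")
        phase = np.angle(np.where(np.abs(sm) > 0, sm, unit + (np.abs(unit) == 0)))
    else:
        phase = np.angle(prof)
    if coverslip_rows is not None:
        lo, hi = coverslip_rows
        direct = np.average(mag[lo:hi], weights=np.maximum(weights[lo:hi], 1e-300))
        fitted = np.mean(mag_iso[lo:hi])
        if fitted > 0:
            mag_iso = mag_iso * direct / fitted
    amplitude = mag_iso[:, None] * lateral[None, :]
    phase_2d = np.broadcast_to(phase[:, None], (n_z, n_x)).copy()
    return PTField(amplitude=amplitude, phase_shift=phase_2d)


def isolate_mech(phasors: PhasorField, pt: PTField) -> PhasorField:
    """Complex subtraction of the PT phasor from the total response.

    ``A_mech e^{i phi_mech} = A_tot e^{i phi_tot} - A_PT e^{i phi_PT}``
    evaluated voxel-wise; magnitude/SNR maps are carried through unchanged.
    """
    mech = phasors.phasor - pt.phasor
    return PhasorField(
        amplitude=np.abs(mech),
        phase_shift=np.angle(mech),
        mean_magnitude=phasors.mean_magnitude,
        snr_db=phasors.snr_db,
        noise_amplitude=phasors.noise_amplitude,
    )


def circular_median(angles: np.ndarray) -> float:
    """Circular median: the sample angle minimising summed angular distance.

    Ties are broken toward the circular mean.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("empty angle set")
    if angles.size == 1:
        return float(angles[0])
    diff = np.abs(np.angle(np.exp(1j * (angles[:, None] - angles[None, :]))))
    cost = diff.sum(axis=1)
    best = np.flatnonzero(np.isclose(cost, cost.min()))
    if len(best) == 1:
        return float(angles[best[0]])
    mean = np.angle(np.mean(np.exp(1j * angles)))
    dist = np.abs(np.angle(np.exp(1j * (angles[best] - mean))))
    return float(angles[best[np.argmin(dist)]])


def cluster_beads(
    mech_list: list[PhasorField],
    mask_list: list[SegmentationMasks],
    pixel_z: float,
    pixel_x: float,
    slow_positions: np.ndarray,
    min_cluster_voxels: int = 5,
    fit_residual_max: float = 0.5,
    method: str = "complex-median",
) -> list[BeadRecord]:
    """Cluster bead voxels across the slow axis into per-bead records.

    Voxels flagged as bead cores in each stack are stacked into a
    (slow, depth, fast) volume and grouped by 3-D connected components
    (26-connectivity).  Each component's centroid is the OCT-magnitude-
    weighted mean position.  The per-bead median response is, by default,
    the component-wise (real, imaginary) median of the complex voxel
    phasors: unlike a median of amplitudes it is not biased upward when
    voxels approach the amplitude noise floor (the magnitude of a noisy
    phasor is Rice-distributed).  ``method="amplitude-phase"`` instead takes
    the median of voxel amplitudes with the circular median of phases.
    Beads whose per-voxel demodulation noise exceeds ``fit_residual_max``
    times the recovered amplitude are flagged "poor sinusoid fit".
    """
    if len(mech_list) != len(mask_list) or not mech_list:
        raise ValueError("mech phasors and masks must align and be non-empty")
    slow_positions = np.asarray(slow_positions, dtype=float)
    vol_mask = np.stack([m.bead_voxels for m in mask_list])
    if not vol_mask.any():
        return []
    vol_amp = np.stack([p.amplitude for p in mech_list])
    vol_phase = np.stack([p.phase_shift for p in mech_list])
    vol_mag = np.stack([p.mean_magnitude for p in mech_list])
    vol_noise = (
        np.stack([p.noise_amplitude for p in mech_list])
        if all(p.noise_amplitude is not None for p in mech_list)
        else None
    )
    labels, n = ndimage.label(vol_mask, structure=np.ones((3, 3, 3), dtype=bool))
    records: list[BeadRecord] = []
    bead_id = 0
    for lbl in range(1, n + 1):
        sel = labels == lbl
        n_vox = int(sel.sum())
        if n_vox < min_cluster_voxels:
            continue
        iy, iz, ix = np.nonzero(sel)
        w = vol_mag[sel]
        w = w / w.sum()
        yc = float(np.sum(w * slow_positions[iy]))
        zc = float(np.sum(w * iz)) * pixel_z
        xc = float(np.sum(w * ix)) * pixel_x
        if method == "complex-median":
            phasors = vol_amp[sel] * np.exp(1j * vol_phase[sel])
            med = np.median(phasors.real) + 1j * np.median(phasors.imag)
            amp = float(np.abs(med))
            phase = float(np.angle(med))
        elif method == "amplitude-phase":
            amp = float(np.median(vol_amp[sel]))
            phase = circular_median(vol_phase[sel])
        else:
            raise ValueError(f"unknown clustering method '{method}'")
        flags = []
        if vol_noise is not None:
            noise = float(np.median(vol_noise[sel]))
            if amp <= 0 or noise / amp > fit_residual_max:
                flags.append("poor sinusoid fit")
        bead_id += 1
        records.append(
            BeadRecord(
                bead_id=bead_id, xc=xc, yc=yc, zc=zc,
                a_mech=amp, phi_mech=phase, n_voxels=n_vox, qc_flags=flags,
            )
        )
    return records


def map_modulus(
    records: list[BeadRecord],
    force_map: ForceProfile2D,
    bead: BeadSpec,
    medium_rho: float,
    omega: float,
    beam_axis_x: float = 0.0,
) -> list[BeadRecord]:
    """Attach the interpolated force and the recovered moduli to each record.

    The force at the bead centroid is bilinearly interpolated from the 2-D
    force map; beads outside the map support are flagged and left without
    moduli.  ``beam_axis_x`` locates the (stationary) pump-beam axis in the
    records' absolute fast-axis frame when the force map is expressed
    relative to the beam.  ``G* = G' + iG''`` comes from the force balance
    plus the oscillating-sphere inversion; the loss ratio is ``R = G''/G'``.
    """
    from scipy.interpolate import RegularGridInterpolator

    interp = RegularGridInterpolator(
        (force_map.grid_z, force_map.grid_x), force_map.force,
        bounds_error=False, fill_value=np.nan,
    )
    out = []
    for rec in records:
        f = float(interp((rec.zc, rec.xc - beam_axis_x)))
        if not np.isfinite(f) or f <= 0:
            rec.qc_flags.append("outside-force-map")
            out.append(rec)
            continue
        rec.force = f
        if rec.a_mech <= 0:
            rec.qc_flags.append("no-mechanical-response")
            out.append(rec)
            continue
        response = ComplexResponse(
            amplitude=rec.a_mech, phase_shift=rec.phi_mech, angular_frequency=omega
        )
        g_star = modulus_from_response(f, response, bead, medium_rho)
        rec.g_prime = float(g_star.real)
        rec.g_double_prime = float(g_star.imag)
        rec.loss_ratio = (
            float(g_star.imag / g_star.real) if g_star.real > 0 else np.nan
        )
        out.append(rec)
    return out


def reconstruct_volume(
    stacks: list[BMStack],
    force_map: ForceProfile2D,
    bead: BeadSpec,
    medium_rho: float = 1000.0,
    config: ReconstructionConfig = ReconstructionConfig(),
    lateral_shape: np.ndarray | None = None,
    register_reference: np.ndarray | None = None,
    coverslip_rows: tuple[int, int] | None = None,
    beam_axis_x: float | None = None,
    pt_compensation: bool = True,
) -> list[BeadRecord]:
    """Run reconstruction stages 2-6 over a volume of BM-mode stacks.

    ``register_reference`` (a (depth, fast) boolean mask) enables per-stack
    phase registration; ``lateral_shape`` is the light-sheet long-axis
    intensity sampled on the fast-axis pixel grid, used by the PT fit.
    ``beam_axis_x`` defaults to the fast-axis FOV centre (the stationary
    pump beam is aligned to the centre of the scan).
    """
    if not stacks:
        raise ValueError("no stacks given")
    phasor_list: list[PhasorField] = []
    mask_list: list[SegmentationMasks] = []
    for stack in stacks:
        if register_reference is not None:
            stack = register_phase(stack, register_reference)
        ph = demodulate(stack)
        mk = segment(stack, ph, bead, config)
        phasor_list.append(ph)
        mask_list.append(mk)
    if pt_compensation:
        pt = reconstruct_pt(
            phasor_list, mask_list, coverslip_rows=coverslip_rows,
            lateral_shape=lateral_shape, min_pt_voxels=config.min_pt_voxels,
        )
        mech_list = [isolate_mech(ph, pt) for ph in phasor_list]
    else:
        mech_list = phasor_list
    records = cluster_beads(
        mech_list, mask_list, stacks[0].pixel_z, stacks[0].pixel_x,
        np.array([s.slow_position for s in stacks]),
        min_cluster_voxels=config.min_cluster_voxels,
        fit_residual_max=config.fit_residual_max,
    )
    omega = 2.0 * np.pi * stacks[0].f_mod
    if beam_axis_x is None:
        beam_axis_x = (stacks[0].field.shape[2] - 1) / 2.0 * stacks[0].pixel_x
    return map_modulus(records, force_map, bead, medium_rho, omega,
                       beam_axis_x=beam_axis_x)
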