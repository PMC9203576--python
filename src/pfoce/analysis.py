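"""Downstream analyses: matrix microarchitecture, pericellular gradients,
matrix deformation tracking, and distribution statistics.

These operations act on per-bead modulus records and OCT volumes:

* temporal speckle-contrast segmentation of the (dynamic) cell body against
  a static fibrous background;
* distance-to-cell profiling of G' and loss ratio R with 3-um bins, t-based
  confidence intervals, background normalisation, and a log-log power-law
  fit of the pericellular stiffness gradient;
* cumulative bead displacement with bulk-shift cancellation and the signed
  scalar deformation S used to group beads by local matrix remodelling;
* per-bead collagen shell metrics (intensity quantiles, fibre volume
  fraction) within a 3-um shell around each bead, and their rank
  correlations with the mechanical read-outs;
* distribution FWHM summaries and the standard two-sample tests (Welch,
  Levene) plus Pearson trends.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

__all__ = [
    "ShellMetrics",
    "DistanceProfile",
    "speckle_segment_cell",
    "distance_to_cell",
    "distance_profile",
    "fit_power_law",
    "cumulative_displacement",
    "signed_displacement",
    "group_by_deformation",
    "shell_metrics",
    "correlate_metrics",
    "distribution_fwhm",
    "group_tests",
    "confocal_postprocess",
]


@dataclass
class ShellMetrics:
    """Per-bead microarchitecture metrics from the 3-um shell around the bead."""

    bead_id: int
    q95_intensity: float
    mean_intensity: float
    fibre_volume_fraction: float
    connectivity: int | None = None
    n_shell_voxels: int = 0
    flags: list[str] = field(default_factory=list)


@dataclass
class DistanceProfile:
    """Binned distance-to-cell profile of G' and loss ratio R.

    ``ci`` entries are 95% half-widths from the Student t distribution,
    defined only for bins with n >= 2 (NaN otherwise).  When normalised, the
    reference is the mean over the background region (r >= cutoff).
    """

    r: np.ndarray
    g_prime_mean: np.ndarray
    g_prime_ci: np.ndarray
    loss_ratio_mean: np.ndarray
    loss_ratio_ci: np.ndarray
    n: np.ndarray
    normalised: bool = False
    background_cutoff: float = 30e-6


def speckle_segment_cell(
    magnitude,
    contrast_threshold: float | None = None,
    closing_radius: int = 2,
    threshold_percentile: float = 99.0,
):
    """Segment the cell body by temporal speckle contrast.

    ``magnitude`` is an OCT magnitude array with the time axis first:
    (t, z, x) for one stack or (t, slow, z, x) for a volume.  Per voxel, the
    temporal standard deviation normalised by the temporal mean is the
    speckle contrast: dynamic (intracellular) scatter decorrelates between
    frames while the fibrous background stays static.  Voxels above the
    threshold are morphologically closed and the largest connected component
    is returned as the cell mask.

    When no explicit threshold is given it is set at ``threshold_percentile``
    of the observed contrast (a static calibration region is the better
    source when available).
    """
    mag = np.asarray(magnitude, dtype=float)
    if mag.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    mean = mag.mean(axis=0)
    contrast = mag.std(axis=0) / np.maximum(mean, 1e-300)
    if contrast_threshold is None:
        contrast_threshold = float(np.percentile(contrast, threshold_percentile))
    mask = contrast > contrast_threshold
    if not mask.any():
        warnings.warn("no voxel above speckle-contrast threshold; empty cell mask")
        return mask
    if mask.all():
        warnings.warn("all voxels dynamic; degenerate cell mask covers everything")
        return mask
    if closing_radius > 0:
        struct = ndimage.generate_binary_structure(mask.ndim, 1)
        mask = ndimage.binary_closing(mask, structure=struct, iterations=closing_radius)
    labels, n = ndimage.label(mask)
    if n == 0:
        warnings.warn("speckle mask vanished after morphology; empty cell mask")
        return np.zeros_like(mask)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def distance_to_cell(centroids: np.ndarray, cell_mask: np.ndarray, pixel_sizes) -> np.ndarray:
    """Shortest distance (m) from each bead centroid to the cell surface.

    The Euclidean distance transform of the mask complement (with anisotropic
    voxel sampling) is evaluated at the centroid voxel; beads inside the mask
    get 0.  ``centroids`` is (n, ndim) in metres, ordered like the mask axes;
    ``pixel_sizes`` the voxel pitch per axis in metres.
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if not cell_mask.any():
        raise ValueError("empty cell mask")
    pixel_sizes = np.asarray(pixel_sizes, dtype=float)
    dist = ndimage.distance_transform_edt(~cell_mask, sampling=pixel_sizes)
    centroids = np.atleast_2d(np.asarray(centroids, dtype=float))
    idx = np.round(centroids / pixel_sizes[None, :]).astype(int)
    idx = np.clip(idx, 0, np.array(cell_mask.shape) - 1)
    return dist[tuple(idx.T)]


def distance_profile(
    g_prime: np.ndarray,
    loss_ratio: np.ndarray,
    r: np.ndarray,
    bin_width: float = 3e-6,
    background_cutoff: float = 30e-6,
    normalise: bool = False,
) -> DistanceProfile:
    """Bin per-bead G' and R by distance to the cell (3-um bins).

    Per bin: mean and 95% confidence half-width of the mean from the Student
    t distribution.  With ``normalise`` the means are divided by the mean
    over beads at ``r >= background_cutoff`` (per quantity), mapping the
    background to 1.
    """
    g_prime = np.asarray(g_prime, dtype=float)
    loss_ratio = np.asarray(loss_ratio, dtype=float)
    r = np.asarray(r, dtype=float)
    if len(r) == 0:
        raise ValueError("need at least one bead")
    n_bins = int(np.ceil((r.max() + 1e-12) / bin_width)) or 1
    centers = (np.arange(n_bins) + 0.5) * bin_width
    idx = np.minimum((r / bin_width).astype(int), n_bins - 1)

    def summarise(vals):
        mean = np.full(n_bins, np.nan)
        ci = np.full(n_bins, np.nan)
        count = np.zeros(n_bins, dtype=int)
        for b in range(n_bins):
            sel = (idx == b) & np.isfinite(vals)
            count[b] = sel.sum()
            if count[b] == 0:
                continue
            mean[b] = vals[sel].mean()
            if count[b] >= 2:
                s = vals[sel].std(ddof=1)
                ci[b] = stats.t.ppf(0.975, count[b] - 1) * s / np.sqrt(count[b])
                if count[b] >= 2 and s == 0:
                    ci[b] = 0.0
        return mean, ci, count

    gp_mean, gp_ci, n_g = summarise(g_prime)
    lr_mean, lr_ci, _ = summarise(loss_ratio)
    if normalise:
        bg = r >= background_cutoff
        if not bg.any():
            raise ValueError("no background beads beyond the cutoff to normalise by")
        gp_ref = np.nanmean(g_prime[bg])
        lr_ref = np.nanmean(loss_ratio[bg])
        gp_mean, gp_ci = gp_mean / gp_ref, gp_ci / gp_ref
        lr_mean, lr_ci = lr_mean / lr_ref, lr_ci / lr_ref
    return DistanceProfile(
        r=centers, g_prime_mean=gp_mean, g_prime_ci=gp_ci,
        loss_ratio_mean=lr_mean, loss_ratio_ci=lr_ci, n=n_g,
        normalised=normalise, background_cutoff=background_cutoff,
    )


def fit_power_law(r: np.ndarray, g_prime: np.ndarray, r_max: float = 30e-6):
    """Decay exponent of the pericellular stiffness gradient, G' ~ r^beta.

    Degree-1 least squares of log G' against log r restricted to
    ``r <= r_max``; the 95% CI of the exponent comes from the slope standard
    error and the t distribution.  Returns ``(beta, ci_half_width)``.
    """
    r = np.asarray(r, dtype=float)
    g_prime = np.asarray(g_prime, dtype=float)
    sel = (r <= r_max) & np.isfinite(g_prime) & np.isfinite(r)
    if sel.sum() < 3:
        raise ValueError("need at least 3 points with r <= r_max")
    if np.any(r[sel] <= 0) or np.any(g_prime[sel] <= 0):
        raise ValueError("power-law fit requires positive r and G'")
    res = stats.linregress(np.log(r[sel]), np.log(g_prime[sel]))
    n = int(sel.sum())
    half = stats.t.ppf(0.975, n - 2) * res.stderr if n > 2 else np.nan
    return float(res.slope), float(half)


def cumulative_displacement(positions: np.ndarray) -> np.ndarray:
    """Cumulative per-bead displacement after bulk-shift correction.

    ``positions`` is (n_times, n_beads, 3) bead centroids in metres.  The
    per-step displacement of each bead, minus the mean per-step displacement
    over all beads (the bulk sample shift), is summed from the second time
    point on.  Output has the same shape with the first time point all zero.
    Steps with non-finite coordinates for a bead drop that bead from the
    bulk estimate for that step and propagate NaN for the bead itself.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 3 or pos.shape[2] != 3:
        raise ValueError("positions must be (n_times, n_beads, 3)")
    n_t, n_beads, _ = pos.shape
    if n_t < 2:
        raise ValueError("need at least 2 time points")
    if n_beads == 1:
        warnings.warn("single bead: bulk shift equals its own motion; zeros returned")
        return np.zeros_like(pos)
    steps = np.diff(pos, axis=0)  # (n_t-1, n_beads, 3)
    finite = np.all(np.isfinite(steps), axis=2)
    if not finite.all():
        warnings.warn("beads missing at some time steps; dropped from bulk estimate")
    bulk = np.empty((n_t - 1, 3))
    for i in range(n_t - 1):
        ok = finite[i]
        bulk[i] = steps[i, ok].mean(axis=0) if ok.any() else 0.0
    corrected = steps - bulk[:, None, :]
    out = np.zeros_like(pos)
    out[1:] = np.cumsum(corrected, axis=0)
    return out


def signed_displacement(delta: np.ndarray):
    """Signed scalar deformation S from cumulative displacement vectors.

    The dataset-level major axis is the argmax of the direction-cosine
    magnitudes ``(|dx|, |dy|, |dz|)/||dr||`` averaged over all beads and
    time points (zero-norm entries skipped).  Then
    ``S = sgn(delta_major) * ||delta||`` per bead and time.  Returns
    ``(S, major_axis)`` with S shaped (n_times, n_beads).
    """
    delta = np.asarray(delta, dtype=float)
    if delta.ndim != 3 or delta.shape[2] != 3:
        raise ValueError("delta must be (n_times, n_beads, 3)")
    norms = np.linalg.norm(delta, axis=2)
    nonzero = norms > 0
    if not nonzero.any():
        return np.zeros(delta.shape[:2]), 0
    cosines = np.abs(delta[nonzero]) / norms[nonzero][:, None]
    major = int(np.argmax(cosines.mean(axis=0)))
    s = np.sign(delta[:, :, major]) * norms
    return s, major


def group_by_deformation(s_final: np.ndarray, s_hi: float | None = None):
    """Label beads as high-negative / low / high-positive matrix deformation.

    ``s_hi`` is the magnitude threshold; by default the 67th percentile of
    |S| at the final time point (roughly the upper tercile).  Returns an
    array of labels from {"high-negative", "low", "high-positive"}.
    """
    s_final = np.asarray(s_final, dtype=float)
    if not np.all(np.isfinite(s_final)):
        raise ValueError("S must be finite")
    if s_hi is None:
        s_hi = float(np.percentile(np.abs(s_final), 67.0))
    labels = np.where(
        s_final >= s_hi, "high-positive", np.where(s_final <= -s_hi, "high-negative", "low")
    )
    if s_hi == 0:
        # degenerate all-zero case: everything is low
        labels = np.where(s_final > 0, "high-positive",
                          np.where(s_final < 0, "high-negative", "low"))
    return labels


def shell_metrics(
    intensity: np.ndarray,
    bead_centroids: np.ndarray,
    bead_radius: float,
    pixel_sizes,
    noise_power: float,
    shell: float = 3e-6,
    snr_noise_db: float = 6.0,
    snr_fibre_db: float = 14.0,
    removal_dilation: int = 1,
) -> list[ShellMetrics]:
    """Microarchitecture metrics in a 3-um shell around each bead.

    The beads themselves are first removed from the intensity volume by
    magnitude segmentation (voxels within the bead radius, dilated by
    ``removal_dilation``).  For each bead the remaining voxels within
    ``shell`` of the bead circumference contribute: the 0.95 intensity
    quantile (fibre-thickness surrogate), the mean intensity (content
    surrogate), and the fibre volume fraction -- voxels at or above the
    fibre SNR threshold divided by voxels at or above the noise floor.
    SNR is ``10 log10(I^2 / noise_power)`` for amplitude volumes.
    """
    if shell <= 0:
        raise ValueError("shell thickness must be positive")
    vol = np.asarray(intensity, dtype=float)
    pixel_sizes = np.asarray(pixel_sizes, dtype=float)
    centroids = np.atleast_2d(np.asarray(bead_centroids, dtype=float))
    coords = np.meshgrid(
        *[np.arange(s) * p for s, p in zip(vol.shape, pixel_sizes)], indexing="ij"
    )
    bead_mask = np.zeros(vol.shape, dtype=bool)
    for c in centroids:
        d2 = sum((g - ci) ** 2 for g, ci in zip(coords, c))
        bead_mask |= d2 <= bead_radius**2
    if removal_dilation > 0:
        bead_mask = ndimage.binary_dilation(
            bead_mask, ndimage.generate_binary_structure(vol.ndim, 1),
            iterations=removal_dilation,
        )
    with np.errstate(divide="ignore"):
        snr_db = 10.0 * np.log10(np.maximum(vol**2 / noise_power, 1e-300))
    out: list[ShellMetrics] = []
    for i, c in enumerate(centroids):
        d2 = sum((g - ci) ** 2 for g, ci in zip(coords, c))
        in_shell = (d2 <= (bead_radius + shell) ** 2) & ~bead_mask
        n_shell = int(in_shell.sum())
        if n_shell == 0:
            out.append(
                ShellMetrics(bead_id=i, q95_intensity=np.nan, mean_intensity=np.nan,
                             fibre_volume_fraction=np.nan, n_shell_voxels=0,
                             flags=["empty shell"])
            )
            continue
        vals = vol[in_shell]
        above_noise = snr_db[in_shell] >= snr_noise_db
        above_fibre = snr_db[in_shell] >= snr_fibre_db
        frac = above_fibre.sum() / above_noise.sum() if above_noise.any() else 0.0
        out.append(
            ShellMetrics(
                bead_id=i,
                q95_intensity=float(np.quantile(vals, 0.95)),
                mean_intensity=float(vals.mean()),
                fibre_volume_fraction=float(frac),
                n_shell_voxels=n_shell,
            )
        )
    return out


def correlate_metrics(metric: np.ndarray, response: np.ndarray):
    """Spearman rank correlation between a per-bead metric and G' or R.

    Returns ``(rho, p_two_tailed)``; a linear best-fit line may be drawn for
    display but the statistic reported is always the rank correlation.
    For n <= 9 the p-value is the exact permutation probability (the t
    approximation is noticeably off at such n); larger samples use the
    tie-corrected t approximation.  Constant inputs make rho undefined
    (ValueError).
    """
    metric = np.asarray(metric, dtype=float)
    response = np.asarray(response, dtype=float)
    ok = np.isfinite(metric) & np.isfinite(response)
    n = int(ok.sum())
    if n < 4:
        raise ValueError("need at least 4 paired observations")
    if np.ptp(metric[ok]) == 0 or np.ptp(response[ok]) == 0:
        raise ValueError("constant input: rank correlation undefined")
    rho, p = stats.spearmanr(metric[ok], response[ok])
    if n <= 9:
        from itertools import permutations

        rx = stats.rankdata(metric[ok])
        ry = stats.rankdata(response[ok])
        perms = np.array(list(permutations(ry)))
        rx_c = rx - rx.mean()
        p_c = perms - perms.mean(axis=1, keepdims=True)
        denom = np.sqrt((rx_c**2).sum() * (p_c**2).sum(axis=1))
        rhos = p_c @ rx_c / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    return float(rho), float(p)


def distribution_fwhm(samples: np.ndarray, n_grid: int = 2048) -> float:
    """FWHM of a Gaussian-KDE fit to the sample distribution.

    Silverman-bandwidth kernel density estimate; the width is measured at
    half the KDE mode by linear interpolation of the crossings, then
    corrected for the kernel broadening (the KDE of a distribution is its
    convolution with the kernel, so the squared half-width overestimates by
    the squared kernel bandwidth).  Degenerate (zero-variance) input
    returns 0.
    """
    samples = np.asarray(samples, dtype=float)
    samples = samples[np.isfinite(samples)]
    if len(samples) < 10:
        raise ValueError("need at least 10 samples")
    if np.ptp(samples) == 0:
        return 0.0
    kde = stats.gaussian_kde(samples, bw_method="silverman")
    pad = 4.0 * samples.std() * kde.factor + np.ptp(samples) * 0.1
    grid = np.linspace(samples.min() - pad, samples.max() + pad, n_grid)
    dens = kde(grid)
    peak = int(np.argmax(dens))
    half = dens[peak] / 2.0

    def crossing(idx_range, reverse):
        seq = idx_range[::-1] if reverse else idx_range
        for j in seq:
            if dens[j] < half:
                j0, j1 = (j, j + 1) if reverse else (j - 1, j)
                frac = (half - dens[j0]) / (dens[j1] - dens[j0])
                return grid[j0] + frac * (grid[j1] - grid[j0])
        return grid[0] if reverse else grid[-1]

    left = crossing(range(0, peak), reverse=True)
    right = crossing(range(peak + 1, n_grid), reverse=False)
    width = float(right - left)
    bandwidth = kde.factor * samples.std(ddof=1)
    factor = 2.0 * np.sqrt(2.0 * np.log(2.0))
    corrected_sq = (width / factor) ** 2 - bandwidth**2
    return factor * np.sqrt(corrected_sq) if corrected_sq > 0 else width


def group_tests(a: np.ndarray, b: np.ndarray):
    """Two-sample comparison: Welch t (means) and Levene (variances).

    Returns a dict with the two-sided statistics, p-values, and the effect
    direction of the mean difference; adds Pearson r when the samples are
    paired (equal length).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need n >= 2 in each group")
    t_stat, t_p = stats.ttest_ind(a, b, equal_var=False)
    lev_stat, lev_p = stats.levene(a, b)
    out = {
        "welch_t": float(t_stat),
        "welch_p": float(t_p),
        "levene_w": float(lev_stat),
        "levene_p": float(lev_p),
        "mean_difference": float(a.mean() - b.mean()),
    }
    if len(a) == len(b):
        r, p = stats.pearsonr(a, b)
        out["pearson_r"] = float(r)
        out["pearson_p"] = float(p)
    return out


def confocal_postprocess(image: np.ndarray, percentile: float = 80.0, gamma: float = 0.4):
    """Threshold-and-gamma enhancement of a confocal reflectance image.

    Pixels below the given percentile of the image are zeroed; the retained
    values are normalised to the image maximum and raised to ``gamma``.
    A constant image thresholds to all zero (warned).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or np.any(img < 0):
        raise ValueError("image must be 2-D and non-negative")
    thr = np.percentile(img, percentile)
    if np.ptp(img) == 0:
        warnings.warn("constant image: threshold equals the value; all-zero output")
        return np.zeros_like(img)
    out = np.where(img >= thr, img, 0.0)
    peak = out.max()
    if peak > 0:
        out = (out / peak) ** gamma * (out > 0)
    return out
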