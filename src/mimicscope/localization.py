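"""Single-molecule detection, Gaussian fitting, drift correction, filtering.

Works on the spatial-channel stack.  Candidate emitters are local maxima
of a matched-filtered (PSF-smoothed) frame above a robust
median + k·MAD threshold, screened by a window-sum significance test and
then refined by least-squares fitting of a pixel-integrated symmetric 2D
Gaussian.  Localization precision follows the Thompson-style photon/
background formula.  Drift is estimated by cross-correlating super-
resolved images of temporal bins; the density filter keeps localizations
with enough spatial neighbors across all frames.

Localization tables are pandas DataFrames with columns
``frame, x_nm, y_nm, sigma_nm, photons, background, uncertainty_nm``
(frame is 1-based; coordinates are continuous nm with the origin at the
top-left pixel center, x right, y down).  ``io`` converts these to and
from THUNDERSTORM-compatible CSV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from scipy.interpolate import CubicSpline
from scipy.spatial import cKDTree
from scipy.special import erf
from skimage.feature import peak_local_max
from skimage.registration import phase_cross_correlation

__all__ = [
    "LOC_COLUMNS",
    "detect_and_fit",
    "drift_correct",
    "density_filter",
    "colocalization_fraction",
    "thompson_precision",
]

LOC_COLUMNS = ["frame", "x_nm", "y_nm", "sigma_nm", "photons", "background", "uncertainty_nm"]


def thompson_precision(
    sigma_nm: float, photons: float, background_var: float, pixel_nm: float
) -> float:
    """Lateral localization precision (nm) from PSF width, photon count and
    per-pixel background variance: (16/9)·σ_a²/N + 8π σ_a⁴ b²/(a² N²) with
    σ_a² = σ² + a²/12.  The 16/9 factor on the shot-noise term is the
    correction for unweighted least-squares Gaussian fitting (which this
    module uses); a maximum-likelihood fitter would approach σ_a²/N.
    """
    sa2 = sigma_nm**2 + pixel_nm**2 / 12.0
    var = (16.0 / 9.0) * sa2 / photons \
        + 8.0 * np.pi * sa2**2 * background_var / (pixel_nm**2 * photons**2)
    return float(np.sqrt(var))


def _integ_gauss(centers: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    s = sigma * np.sqrt(2.0)
    return 0.5 * (erf((centers + 0.5 - mu) / s) - erf((centers - 0.5 - mu) / s))


def _fit_window(win: np.ndarray, x0: float, y0: float, sigma0: float):
    """Least-squares pixel-integrated 2D Gaussian fit on a square window.

    Parameters: x, y (px, window coords), sigma (px), N (photons), b (offset).
    Returns None on non-convergence or unphysical parameters.
    """
    h, w = win.shape
    xs = np.arange(w, dtype=float)
    ys = np.arange(h, dtype=float)
    b0 = float(np.percentile(win, 20))
    n0 = max(float(win.sum() - b0 * win.size), 10.0)

    def resid(p):
        x, y, s, n, b = p
        model = n * np.outer(_integ_gauss(ys, y, s), _integ_gauss(xs, x, s)) + b
        return (model - win).ravel()

    try:
        res = optimize.least_squares(
            resid,
            x0=[x0, y0, sigma0, n0, b0],
            bounds=([-1, -1, 0.3, 1.0, -np.inf], [w, h, 10.0, np.inf, np.inf]),
            max_nfev=200,
        )
    except Exception:
        return None
    if not res.success:
        return None
    x, y, s, n, b = res.x
    if not (0 <= x <= w - 1 and 0 <= y <= h - 1) or n <= 0:
        return None
    return x, y, s, n, b


def detect_and_fit(
    frame_stack: np.ndarray,
    pixel_size_nm: float,
    threshold_k: float = 3.0,
    fit_window: int = 7,
    psf_sigma_guess_nm: float = 130.0,
    min_photons: float = 50.0,
    screen_significance: float = 5.0,
) -> pd.DataFrame:
    """Detect and fit emitters in every frame of a 2D image stack.

    Candidates are local maxima of the PSF-matched smoothed frame above
    median + threshold_k·1.4826·MAD.  A cheap screen — background-
    subtracted window sum above ``screen_significance`` Poisson sigmas —
    rejects noise candidates before the Gaussian fit.  Non-converged or
    sub-``min_photons`` fits are dropped.
    """
    stack = np.asarray(frame_stack, dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    half = fit_window // 2
    sigma_px = psf_sigma_guess_nm / pixel_size_nm
    records = []
    for t, frame in enumerate(stack, start=1):
        smooth = ndimage.gaussian_filter(frame, sigma_px)
        med = np.median(smooth)
        mad = np.median(np.abs(smooth - med))
        thr = med + threshold_k * 1.4826 * mad
        peaks = peak_local_max(
            smooth, min_distance=max(int(sigma_px), 1) + 1,
            threshold_abs=thr, exclude_border=half,
        )
        if len(peaks) == 0:
            continue
        bg_med = np.median(frame)
        for r, c in peaks:
            win = frame[r - half : r + half + 1, c - half : c + half + 1]
            # Poisson significance of the window sum over flat background
            excess = win.sum() - bg_med * win.size
            noise = np.sqrt(max(bg_med, 0.5) * win.size)
            if excess < screen_significance * noise:
                continue
            fit = _fit_window(win, float(half), float(half), sigma_px)
            if fit is None:
                continue
            x, y, s, n, b = fit
            if n < min_photons:
                continue
            records.append(
                (
                    t,
                    (c - half + x) * pixel_size_nm,
                    (r - half + y) * pixel_size_nm,
                    s * pixel_size_nm,
                    n,
                    b,
                    thompson_precision(s * pixel_size_nm, n, max(b, 0.0), pixel_size_nm),
                )
            )
    return pd.DataFrame(records, columns=LOC_COLUMNS)


# ---------------------------------------------------------------------------
# drift correction


def _render_histogram(x, y, bin_nm, shape):
    img, _, _ = np.histogram2d(
        y, x, bins=shape, range=[[0, shape[0] * bin_nm], [0, shape[1] * bin_nm]]
    )
    return img


def drift_correct(
    locs: pd.DataFrame,
    n_bins: int = 10,
    render_bin_nm: float = 20.0,
    upsample: int = 100,
    min_locs_per_bin: int = 20,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-correlation drift correction.

    Frames are split into ``n_bins`` equal temporal bins; each bin is
    rendered as a 2D histogram image and registered against the first bin
    by subpixel phase cross-correlation.  Per-frame drift is interpolated
    (cubic for ≥4 bins, linear otherwise, constant beyond the outermost
    bin centers) and subtracted, so the first bin defines zero drift and
    within-frame relative positions are preserved exactly.

    Returns (corrected locs, drift trace with columns frame, dx_nm, dy_nm).
    """
    locs = locs.copy()
    frames = locs["frame"].to_numpy()
    f_min, f_max = int(frames.min()), int(frames.max())
    all_frames = np.arange(f_min, f_max + 1)
    zero = pd.DataFrame({"frame": all_frames, "dx_nm": 0.0, "dy_nm": 0.0})
    if n_bins < 2:
        warnings.warn("drift_correct: fewer than 2 temporal bins; identity correction")
        return locs, zero
    edges = np.linspace(f_min, f_max + 1, n_bins + 1)
    which = np.clip(np.searchsorted(edges, frames, side="right") - 1, 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)
    if (counts < min_locs_per_bin).any():
        warnings.warn("drift_correct: insufficient localizations per bin; identity correction")
        return locs, zero

    span_x = locs["x_nm"].max() + 3 * render_bin_nm
    span_y = locs["y_nm"].max() + 3 * render_bin_nm
    shape = (int(np.ceil(span_y / render_bin_nm)), int(np.ceil(span_x / render_bin_nm)))
    ref = None
    centers = 0.5 * (edges[:-1] + edges[1:])
    shifts = np.zeros((n_bins, 2))
    for i in range(n_bins):
        sel = which == i
        img = _render_histogram(
            locs.loc[sel, "x_nm"].to_numpy(), locs.loc[sel, "y_nm"].to_numpy(),
            render_bin_nm, shape,
        )
        if ref is None:
            ref = img
            continue
        shift, _, _ = phase_cross_correlation(ref, img, upsample_factor=upsample)
        shifts[i] = -shift[::-1] * render_bin_nm  # (row, col) -> drift (dx, dy)

    if n_bins >= 4:
        fx = CubicSpline(centers, shifts[:, 0])
        fy = CubicSpline(centers, shifts[:, 1])
    else:
        fx = lambda f: np.interp(f, centers, shifts[:, 0])
        fy = lambda f: np.interp(f, centers, shifts[:, 1])
    fq = np.clip(all_frames, centers[0], centers[-1])
    trace = pd.DataFrame({"frame": all_frames, "dx_nm": fx(fq), "dy_nm": fy(fq)})
    per_loc = np.clip(frames, centers[0], centers[-1])
    locs["x_nm"] = locs["x_nm"] - fx(per_loc)
    locs["y_nm"] = locs["y_nm"] - fy(per_loc)
    return locs, trace


def density_filter(
    locs: pd.DataFrame, radius_nm: float = 100.0, min_neighbors: int = 3
) -> pd.DataFrame:
    """Keep localizations with ≥ min_neighbors others within radius (all frames)."""
    if radius_nm <= 0:
        raise ValueError("radius must be positive")
    if locs.empty:
        return locs.copy()
    xy = locs[["x_nm", "y_nm"]].to_numpy()
    tree = cKDTree(xy)
    counts = tree.query_ball_point(xy, r=radius_nm, return_length=True) - 1
    return locs[counts >= min_neighbors].copy()


def colocalization_fraction(
    core_spots_nm: np.ndarray, cluster_centroids_nm: np.ndarray, radius_nm: float = 250.0
) -> float:
    """Fraction of core-channel spots with a cluster centroid within radius."""
    core = np.atleast_2d(np.asarray(core_spots_nm, float))
    if core.size == 0:
        raise ValueError("no core spots provided")
    cents = np.atleast_2d(np.asarray(cluster_centroids_nm, float))
    if cents.size == 0:
        return 0.0
    d, _ = cKDTree(cents).query(core)
    return float(np.mean(d <= radius_nm))
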