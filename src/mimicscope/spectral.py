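"""Dispersion calibration, spectrum extraction and per-event peak fitting.

The grating projects each emitter twice: the zeroth order gives the
position, the first order a dispersed footprint whose distance from the
position encodes the emission wavelength.  Calibration maps that
spatial-to-spectral pixel distance to wavelength with a low-order
polynomial fitted through reference lamp lines (the argon lamp lines at
435, 586 and 763 nm in the real rig).  For each localization the spectrum
is read out of a transverse band of the background-subtracted spectral
frame, converted to wavelength, and fitted with a 1D Gaussian to obtain
the peak wavelength and its standard error; the intensity-weighted
centroid is reported alongside.

Quality control follows the published filter literally: a spectrum
survives iff its peak uncertainty is ≤ 40 nm AND its spectral photon
count is ≥ 300 (values exactly at the boundary are kept).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "DispersionCalibration",
    "SpectralFit",
    "ARGON_LINES_NM",
    "calibrate_dispersion",
    "extract_spectrum",
    "fit_peak",
    "qc_filter",
    "fits_to_frame",
    "QC_MAX_UNCERTAINTY_NM",
    "QC_MIN_PHOTONS",
]

#: Calibration-lamp lines used on the real rig (nm).
ARGON_LINES_NM = (435.0, 586.0, 763.0)

QC_MAX_UNCERTAINTY_NM = 40.0
QC_MIN_PHOTONS = 300.0

WORKING_RANGE_NM = (550.0, 700.0)


@dataclass(frozen=True)
class DispersionCalibration:
    """Polynomial map from spatial-to-spectral pixel distance to wavelength.

    ``coefficients`` are in ascending power order (numpy.polynomial
    convention).  The map must be strictly monotone over the working
    wavelength range.
    """

    coefficients: np.ndarray
    order: int
    residuals_nm: np.ndarray
    domain_px: tuple[float, float]  # monotone pixel-distance domain

    def wavelength(self, distance_px):
        return np.polynomial.polynomial.polyval(np.asarray(distance_px, float), self.coefficients)

    def distance(self, wavelength_nm):
        """Inverse map (nm -> px) by root bracketing on the monotone domain."""
        lam = np.atleast_1d(np.asarray(wavelength_nm, float))
        lo, hi = self.domain_px
        out = np.empty_like(lam)
        for i, l in enumerate(lam):
            out[i] = optimize.brentq(
                lambda d: self.wavelength(d) - l, lo, hi, xtol=1e-12, rtol=1e-15
            )
        return out if np.ndim(wavelength_nm) else float(out[0])


def calibrate_dispersion(
    lines: list[tuple[float, float]],
    order: int = 2,
    working_range_nm: tuple[float, float] = WORKING_RANGE_NM,
) -> DispersionCalibration:
    """Least-squares polynomial fit of (pixel distance, wavelength) pairs.

    With exactly order+1 lines the fit interpolates (zero residuals).
    Raises if the pixel distances are degenerate or the fitted map is not
    strictly monotone over the working range.
    """
    pts = np.asarray(lines, float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("lines must be (pixel_distance, wavelength) pairs")
    d, lam = pts[:, 0], pts[:, 1]
    if len(np.unique(d)) < order + 1:
        raise ValueError("degenerate calibration: need order+1 distinct pixel distances")
    if len(d) < order + 1:
        raise ValueError(f"need at least {order + 1} lines for order {order}")
    coeffs = np.polynomial.polynomial.polyfit(d, lam, order)
    fitted = np.polynomial.polynomial.polyval(d, coeffs)
    residuals = lam - fitted
    # monotonicity over the pixel span covering the working range
    span = d.max() - d.min()
    grid = np.linspace(d.min() - 0.5 * span, d.max() + 0.5 * span, 4001)
    vals = np.polynomial.polynomial.polyval(grid, coeffs)
    lo, hi = working_range_nm
    inside = (vals >= lo - 10) & (vals <= hi + 10)
    if inside.sum() < 2:
        raise ValueError("calibration does not cover the working wavelength range")
    dv = np.diff(vals[inside])
    if not (np.all(dv > 0) or np.all(dv < 0)):
        raise ValueError("dispersion map is not monotone over the working range")
    dom = grid[inside]
    domain = (float(dom.min()) - 1.0, float(dom.max()) + 1.0)
    return DispersionCalibration(coeffs, order, residuals, domain)


@dataclass
class SpectralFit:
    """Per-localization spectrum and its fit results."""

    loc_id: int
    frame: int
    x_nm: float
    y_nm: float
    wavelength_nm: np.ndarray = field(repr=False)
    intensity: np.ndarray = field(repr=False)
    photons_spectral: float = np.nan
    peak_wavelength_nm: float = np.nan
    peak_uncertainty_nm: float = np.nan
    sigma_nm: float = np.nan
    centroid_wavelength_nm: float = np.nan
    passed_qc: bool = False
    qc_reason: str = ""
    fitted: bool = False


def extract_spectrum(
    loc,
    spectral_frame: np.ndarray,
    cal: DispersionCalibration,
    pixel_size_nm: float,
    window_px: int = 5,
    working_range_nm: tuple[float, float] = WORKING_RANGE_NM,
    loc_id: int = -1,
    background_rows: np.ndarray | None = None,
    background_method: str = "mean",
) -> SpectralFit:
    """Read one localization's emission spectrum out of a spectral frame.

    A ``window_px``-row band centred on the localization row is summed
    transversely; the per-column background, estimated over emitter-free
    rows (all rows outside the band plus a 2-px guard unless
    ``background_rows`` is given), is subtracted per contributing row.
    The default estimator is the column mean, which is unbiased for
    Poisson background (the column median of low-count Poisson data is
    biased low by ~0.1 count); ``background_method="median"`` is the
    robust alternative for fields crowded with concurrent emitters.
    Columns are converted to wavelength through the calibration, keeping
    the working range.  ``photons_spectral`` is the net sum over that
    support.
    """
    frame = np.asarray(spectral_frame, float)
    H, W = frame.shape
    def _get(obj, key):
        try:
            return getattr(obj, key)
        except AttributeError:
            return obj[key]

    x_px = _get(loc, "x_nm") / pixel_size_nm
    y_px = _get(loc, "y_nm") / pixel_size_nm
    frame_no = int(_get(loc, "frame"))
    r0 = int(round(y_px))
    halfw = window_px // 2
    rows = np.arange(r0 - halfw, r0 + halfw + 1)
    fit = SpectralFit(loc_id, frame_no, float(x_px * pixel_size_nm),
                      float(y_px * pixel_size_nm), np.empty(0), np.empty(0))
    if rows[0] < 0 or rows[-1] >= H:
        fit.qc_reason = "band outside chip"
        return fit
    if background_rows is None:
        guard = 2
        mask = np.ones(H, bool)
        mask[max(rows[0] - guard, 0) : rows[-1] + guard + 1] = False
        background_rows = np.nonzero(mask)[0]
    if len(background_rows):
        reducer = np.mean if background_method == "mean" else np.median
        bg_col = reducer(frame[background_rows, :], axis=0)
    else:
        bg_col = np.zeros(W)
    band = frame[rows, :].sum(axis=0) - window_px * bg_col

    cols = np.arange(W, dtype=float)
    lam = cal.wavelength(cols - x_px)
    lo, hi = working_range_nm
    sel = (lam >= lo) & (lam <= hi)
    if sel.sum() < 4:
        fit.qc_reason = "spectrum support outside chip"
        return fit
    order = np.argsort(lam[sel])
    fit.wavelength_nm = lam[sel][order]
    fit.intensity = band[sel][order]
    fit.photons_spectral = float(fit.intensity.sum())
    return fit


def _gauss(lam, a, mu, sig):
    return a * np.exp(-0.5 * ((lam - mu) / sig) ** 2)


def fit_peak(sf: SpectralFit) -> SpectralFit:
    """Gaussian peak fit of an extracted spectrum.

    Sets peak wavelength, its standard error (from the fit covariance),
    the fitted spectral width, and the intensity-weighted centroid.
    Non-convergence marks the fit failed (and QC-rejected) with a reason.
    """
    if sf.wavelength_nm.size < 4:
        sf.qc_reason = sf.qc_reason or "empty spectrum"
        return sf
    lam, inten = sf.wavelength_nm, sf.intensity
    pos = np.clip(inten, 0, None)
    if pos.sum() <= 0:
        sf.qc_reason = "no positive intensity"
        return sf
    sf.centroid_wavelength_nm = float((lam * pos).sum() / pos.sum())
    a0 = float(inten.max())
    mu0 = float(lam[np.argmax(inten)])
    try:
        popt, pcov = optimize.curve_fit(
            _gauss, lam, inten,
            p0=[a0, mu0, 20.0],
            bounds=([0, lam.min() - 50, 1.0], [np.inf, lam.max() + 50, 300.0]),
            maxfev=2000,
        )
    except (RuntimeError, ValueError):
        sf.qc_reason = "peak fit did not converge"
        return sf
    perr = np.sqrt(np.diag(pcov))
    if not np.isfinite(perr[1]):
        sf.qc_reason = "singular fit covariance"
        return sf
    sf.peak_wavelength_nm = float(popt[1])
    sf.sigma_nm = float(popt[2])
    sf.peak_uncertainty_nm = float(perr[1])
    sf.fitted = True
    return sf


def qc_filter(
    fits: pd.DataFrame,
    max_uncertainty_nm: float = QC_MAX_UNCERTAINTY_NM,
    min_photons: float = QC_MIN_PHOTONS,
    use_width: bool = False,
) -> pd.DataFrame:
    """Set ``passed_qc`` on a spectral-fit table, never mutating wavelengths.

    Literal boundary reading: uncertainty strictly greater than 40 nm is
    rejected, photon counts strictly below 300 are rejected; equality
    survives.  ``use_width=True`` applies the uncertainty rule to the
    fitted spectral width instead of the center standard error.
    """
    out = fits.copy()
    unc = out["sigma_nm"] if use_width else out["unc_nm"]
    ok = (
        out["fitted"].astype(bool)
        & (unc <= max_uncertainty_nm)
        & (out["photons_spectral"] >= min_photons)
    )
    out["passed_qc"] = ok.to_numpy()
    return out


def fits_to_frame(fits: list[SpectralFit]) -> pd.DataFrame:
    """Tabulate SpectralFit objects (CSV-ready columns)."""
    return pd.DataFrame(
        {
            "loc_id": [f.loc_id for f in fits],
            "frame": [f.frame for f in fits],
            "x_nm": [f.x_nm for f in fits],
            "y_nm": [f.y_nm for f in fits],
            "peak_nm": [f.peak_wavelength_nm for f in fits],
            "centroid_nm": [f.centroid_wavelength_nm for f in fits],
            "sigma_nm": [f.sigma_nm for f in fits],
            "unc_nm": [f.peak_uncertainty_nm for f in fits],
            "photons_spectral": [f.photons_spectral for f in fits],
            "fitted": [f.fitted for f in fits],
            "passed_qc": [f.passed_qc for f in fits],
            "qc_reason": [f.qc_reason for f in fits],
        }
    )
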