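"""End-to-end sPAINT analysis: stacks in, summarized particle clusters out.

Order of operations mirrors the acquisition geometry: spectra must be
extracted against the *camera* coordinates of each localization (the
dispersed footprint lives on the raw chip), so extraction happens before
drift correction; the drift-corrected coordinates are then used for
density filtering and clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import localization as loc
from . import particles as part
from . import spectral as spec

__all__ = ["SPaintParams", "SPaintResult", "analyze_spaint"]


@dataclass
class SPaintParams:
    pixel_size_nm: float = 90.0
    exposure_ms: float = 50.0
    threshold_k: float = 3.0
    fit_window_px: int = 7
    psf_sigma_guess_nm: float = 130.0
    drift_bins: int = 0  # 0 disables drift correction
    density_radius_nm: float = 100.0
    density_min_neighbors: int = 3
    spectral_window_px: int = 5
    bandwidth_nm: float = 100.0
    max_gap_frames: int = 0
    min_events: int = 5


@dataclass
class SPaintResult:
    locs: pd.DataFrame
    fits: pd.DataFrame
    clusters: list = field(default_factory=list)
    drift: pd.DataFrame | None = None

    @property
    def validated_clusters(self):
        return [c for c in self.clusters if c.validated]


def analyze_spaint(
    spatial_stack: np.ndarray,
    spectral_stack: np.ndarray,
    cal: spec.DispersionCalibration,
    params: SPaintParams = SPaintParams(),
) -> SPaintResult:
    """Run localization → spectral fitting → QC → clustering → summaries."""
    locs = loc.detect_and_fit(
        spatial_stack,
        params.pixel_size_nm,
        threshold_k=params.threshold_k,
        fit_window=params.fit_window_px,
        psf_sigma_guess_nm=params.psf_sigma_guess_nm,
    )
    if locs.empty:
        return SPaintResult(locs, spec.fits_to_frame([]))

    fits = []
    for i, row in enumerate(locs.itertuples(index=False)):
        sf = spec.extract_spectrum(
            row,
            spectral_stack[int(row.frame) - 1],
            cal,
            params.pixel_size_nm,
            window_px=params.spectral_window_px,
            loc_id=i,
        )
        fits.append(spec.fit_peak(sf))
    fit_df = spec.fits_to_frame(fits)
    fit_df["photons"] = locs["photons"].to_numpy()

    drift = None
    if params.drift_bins >= 2:
        corrected, drift = loc.drift_correct(locs, n_bins=params.drift_bins)
        fit_df["x_nm"] = corrected["x_nm"].to_numpy()
        fit_df["y_nm"] = corrected["y_nm"].to_numpy()
        locs = corrected

    fit_df = spec.qc_filter(fit_df)
    passed = fit_df[fit_df["passed_qc"]].copy()
    if not passed.empty:
        kept = loc.density_filter(
            passed, params.density_radius_nm, params.density_min_neighbors
        )
    else:
        kept = passed

    clusters = part.mean_shift_cluster(kept, params.bandwidth_nm)
    for c in clusters:
        part.summarize_cluster(
            c, params.exposure_ms, params.max_gap_frames, params.min_events
        )
    return SPaintResult(locs, fit_df, clusters, drift)
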