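"""Dispersion calibration, spectrum extraction, peak fitting, QC filter."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mimicscope import spectral as spec
from mimicscope import synthetic as syn


class TestCalibration:
    def test_three_lines_quadratic_interpolates_exactly(self):
        # distances chosen as an arbitrary monotone map hitting the lamp lines
        lines = [(10.0, 435.0), (60.0, 586.0), (130.0, 763.0)]
        cal = spec.calibrate_dispersion(lines, order=2, working_range_nm=(435, 763))
        np.testing.assert_allclose(cal.residuals_nm, 0.0, atol=1e-9)

    def test_affine_recovery_machine_precision(self):
        slope_nm_px, intercept = 1.7, 480.0
        d = np.array([40.0, 70.0, 100.0, 130.0])
        cal = spec.calibrate_dispersion(list(zip(d, intercept + slope_nm_px * d)), order=1)
        np.testing.assert_allclose(cal.coefficients, [intercept, slope_nm_px], rtol=1e-12)

    def test_duplicate_distances_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            spec.calibrate_dispersion([(10.0, 435.0), (10.0, 586.0), (60.0, 763.0)], order=2)

    def test_non_monotone_rejected(self):
        with pytest.raises(ValueError, match="monotone"):
            spec.calibrate_dispersion(
                [(0.0, 550.0), (40.0, 700.0), (80.0, 620.0)], order=2
            )

    def test_roundtrip_identity(self, affine_cal):
        lam = np.linspace(550.0, 700.0, 31)
        back = affine_cal.wavelength(affine_cal.distance(lam))
        np.testing.assert_allclose(back, lam, atol=1e-9)


def one_event_movie(wavelength=620.0, photons=1500.0, noise=False, bg=0.0, seed=7):
    cfg = syn.SimulationConfig(
        fov_px=(48, 48), n_frames=1, noise=noise, background_per_px=bg,
        photons_mean=photons, seed=seed,
    )
    ev = pd.DataFrame(
        [{"frame": 1, "particle_id": 0, "event_id": 0,
          "x_nm": 20 * 90.0, "y_nm": 24 * 90.0, "wavelength_nm": wavelength}]
    )
    return syn.render_movie(ev, cfg), cfg


class TestExtraction:
    def test_known_wavelength_peaks_at_truth(self, affine_cal):
        mv, cfg = one_event_movie(wavelength=620.0)
        sf = spec.extract_spectrum(
            {"frame": 1, "x_nm": 1800.0, "y_nm": 2160.0}, mv.spectral[0],
            affine_cal, cfg.pixel_size_nm,
        )
        lam_max = sf.wavelength_nm[np.argmax(sf.intensity)]
        assert lam_max == pytest.approx(620.0, abs=cfg.dispersion[1] / 2 + 1e-9)

    def test_background_only_nets_to_zero(self, affine_cal, rng):
        """Pure Poisson background must subtract away: the mean net photon sum
        over many extractions stays below one count."""
        sums = []
        for _ in range(2000):
            frame = rng.poisson(2.0, size=(40, 120)).astype(float)
            sf = spec.extract_spectrum(
                {"frame": 1, "x_nm": 10 * 90.0, "y_nm": 20 * 90.0}, frame,
                affine_cal, 90.0,
            )
            sums.append(sf.photons_spectral)
        assert abs(np.mean(sums)) < 1.0

    def test_photon_split_fractions_honored(self, affine_cal):
        mv, cfg = one_event_movie()
        locs_row = {"frame": 1, "x_nm": 1800.0, "y_nm": 2160.0}
        sf = spec.extract_spectrum(locs_row, mv.spectral[0], affine_cal, 90.0)
        spatial_photons = mv.spatial[0].sum()
        # transverse 5-px window truncates ~8% of the footprint
        assert sf.photons_spectral / spatial_photons == pytest.approx(0.32 / 0.41, rel=0.10)

    def test_band_outside_chip_flagged(self, affine_cal):
        mv, cfg = one_event_movie()
        sf = spec.extract_spectrum(
            {"frame": 1, "x_nm": 1800.0, "y_nm": 30.0}, mv.spectral[0],
            affine_cal, 90.0,
        )
        assert sf.qc_reason == "band outside chip"
        assert not spec.fit_peak(sf).fitted


class TestPeakFit:
    def gaussian_spectrum(self, mu=620.0, sigma=19.0, amp=100.0):
        lam = np.arange(550.0, 700.0, 2.0)
        return spec.SpectralFit(
            0, 1, 0.0, 0.0, lam, amp * np.exp(-0.5 * ((lam - mu) / sigma) ** 2)
        )

    def test_noiseless_gaussian_exact(self):
        sf = spec.fit_peak(self.gaussian_spectrum())
        assert sf.fitted
        assert sf.peak_wavelength_nm == pytest.approx(620.0, abs=0.1)
        assert sf.centroid_wavelength_nm == pytest.approx(sf.peak_wavelength_nm, abs=0.5)

    def test_skewed_spectrum_centroid_oracle(self):
        lam = np.arange(550.0, 700.0, 2.0)
        inten = (100 * np.exp(-0.5 * ((lam - 600) / 12) ** 2)
                 + 40 * np.exp(-0.5 * ((lam - 650) / 15) ** 2))
        sf = spec.fit_peak(spec.SpectralFit(0, 1, 0.0, 0.0, lam, inten))
        expected_centroid = (lam * inten).sum() / inten.sum()
        assert sf.centroid_wavelength_nm == pytest.approx(expected_centroid, rel=1e-12)
        assert sf.centroid_wavelength_nm != pytest.approx(sf.peak_wavelength_nm, abs=1.0)
        assert lam.min() <= sf.peak_wavelength_nm <= lam.max()

    def test_bias_and_uncertainty_scale_with_photons(self, rng):
        """Peak recovery must be unbiased (<1 nm) and its reported SE must
        shrink roughly as 1/√photons."""
        levels = [300, 1200, 4800]
        biases, ses = [], []
        for photons in levels:
            peaks, uncs = [], []
            for _ in range(300):
                lam = np.arange(550.0, 700.0, 2.0)
                shape = np.exp(-0.5 * ((lam - 620) / 19.0) ** 2)
                expected = photons * shape / shape.sum()
                inten = rng.poisson(expected).astype(float)
                sf = spec.fit_peak(spec.SpectralFit(0, 1, 0.0, 0.0, lam, inten))
                if sf.fitted:
                    peaks.append(sf.peak_wavelength_nm)
                    uncs.append(sf.peak_uncertainty_nm)
            biases.append(abs(np.mean(peaks) - 620.0))
            ses.append(np.median(uncs))
            # reported SE consistent with observed scatter (factor 2)
            assert np.median(uncs) == pytest.approx(np.std(peaks), rel=1.0)
        assert all(b < 1.0 for b in biases)
        assert ses[0] / ses[2] == pytest.approx(4.0, rel=0.5)


class TestQcFilter:
    def frame_with(self, unc, photons):
        return pd.DataFrame(
            {
                "peak_nm": [612.0], "centroid_nm": [613.0], "sigma_nm": [19.0],
                "unc_nm": [unc], "photons_spectral": [photons], "fitted": [True],
            }
        )

    @pytest.mark.parametrize(
        "unc,photons,expected",
        [
            (40.0, 1000.0, True),   # boundary uncertainty survives
            (40.0 + 1e-9, 1000.0, False),
            (45.0, 1000.0, False),
            (10.0, 300.0, True),    # boundary photon count survives
            (10.0, 299.0, False),
            (10.0, 10_000.0, True),
        ],
    )
    def test_boundary_literalism(self, unc, photons, expected):
        out = spec.qc_filter(self.frame_with(unc, photons))
        assert bool(out["passed_qc"].iloc[0]) is expected

    @given(
        unc=st.lists(st.floats(0.0, 80.0), min_size=1, max_size=20),
        photons=st.lists(st.floats(0.0, 2000.0), min_size=20, max_size=20),
    )
    def test_never_mutates_wavelengths(self, unc, photons):
        df = pd.DataFrame(
            {
                "peak_nm": np.linspace(560, 690, len(unc)),
                "centroid_nm": np.linspace(560, 690, len(unc)),
                "sigma_nm": 19.0,
                "unc_nm": unc,
                "photons_spectral": photons[: len(unc)],
                "fitted": True,
            }
        )
        out = spec.qc_filter(df)
        np.testing.assert_array_equal(out["peak_nm"], df["peak_nm"])
        assert out["passed_qc"].sum() <= len(df)
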