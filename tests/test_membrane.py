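"""Membrane observables: APL, thickness, compressibility, diffusivity."""

import numpy as np
import pytest

from mimicscope import membrane as mem
from mimicscope import synthetic as syn
from mimicscope.constants import BOLTZMANN
from mimicscope.membrane import HeadTrajectory


def rigid_trajectory(L=14.5, n_leaf=500, T=50, z=2.0):
    times = np.arange(T) * 10.0
    box = np.full((T, 2), L)
    n = 2 * n_leaf
    rng = np.random.default_rng(0)
    xy = rng.uniform(0, L, size=(T, n, 2))
    leaflet = np.where(np.arange(n) < n_leaf, 1, -1)
    zc = np.repeat(leaflet[None, :] * z, T, axis=0).astype(float)
    pos = np.concatenate([xy, zc[:, :, None]], axis=2)
    return HeadTrajectory(times, box, pos, leaflet, n_leaf)


class TestApl:
    def test_constant_box_exact_value(self):
        traj = rigid_trajectory()
        apl = mem.apl_series(traj)
        np.testing.assert_allclose(apl.apl_nm2, 14.5 * 14.5 / 500)
        assert apl.mean == pytest.approx(0.4205, abs=1e-4)

    def test_doubling_leaflet_count_halves_apl(self):
        t1 = rigid_trajectory(n_leaf=250)
        t2 = rigid_trajectory(n_leaf=500)
        assert mem.apl_series(t1).mean == pytest.approx(2 * mem.apl_series(t2).mean)

    def test_fluctuating_box_mean_recovered(self):
        traj = syn.simulate_trajectory(
            n_heads=100, apl_mean_nm2=0.42, apl_sd_nm2=0.004, n_steps=4000, seed=5
        )
        apl = mem.apl_series(traj)
        # AR(1) samples are correlated (corr time 100 frames): the effective
        # sample size is n/(2·τ), so allow 3 effective standard errors
        eff_se = 0.004 * np.sqrt(2 * 100 / 4000)
        assert abs(apl.mean - 0.42) < 3 * eff_se

    def test_stderr_shrinks_with_length(self):
        errs = []
        for steps in (1000, 4000, 16000):
            traj = syn.simulate_trajectory(
                n_heads=50, apl_sd_nm2=0.004, n_steps=steps, seed=8
            )
            errs.append(mem.apl_series(traj).stderr)
        assert errs[0] > errs[1] > errs[2]
        assert errs[0] / errs[2] == pytest.approx(4.0, rel=0.5)


class TestThickness:
    def test_clean_leaflets(self):
        traj = rigid_trajectory(z=2.0)
        assert mem.bilayer_thickness(traj) == pytest.approx(4.0, abs=0.05)

    def test_translation_invariance(self):
        traj = rigid_trajectory(z=2.0)
        shifted = HeadTrajectory(
            traj.times_ns, traj.box_nm,
            traj.positions_nm + np.array([0.0, 0.0, 7.3]),
            traj.leaflet, traj.n_per_leaflet,
        )
        assert mem.bilayer_thickness(shifted) == pytest.approx(
            mem.bilayer_thickness(traj), abs=1e-9
        )

    def test_smeared_leaflets_within_two_percent(self):
        traj = syn.simulate_trajectory(
            n_heads=500, d_hh_nm=4.0, z_noise_nm=0.3, n_steps=200, seed=4
        )
        assert mem.bilayer_thickness(traj) == pytest.approx(4.0, rel=0.02)

    def test_unimodal_density_rejected(self):
        traj = rigid_trajectory(z=0.0)
        with pytest.raises(ValueError, match="unresolved"):
            mem.bilayer_thickness(traj)


class TestCompressibility:
    def series(self, mean, sd, n=100):
        return mem.AplSeries(np.arange(n) * 10.0, np.full(n, mean), mean, 0.0, sd)

    def test_literal_formula_oracle(self):
        k = mem.compressibility(self.series(0.6, 0.006), 310.0)
        assert k == pytest.approx(BOLTZMANN * 310.0 * 100.0, rel=1e-12)
        assert k == pytest.approx(4.28e-19, rel=0.01)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            mem.compressibility(self.series(0.6, 0.0), 310.0)

    def test_scale_invariance_of_literal_mode(self):
        k1 = mem.compressibility(self.series(0.6, 0.006), 310.0)
        k2 = mem.compressibility(self.series(1.2, 0.012), 310.0)
        assert k1 == pytest.approx(k2, rel=1e-12)

    def test_variance_mode_conventional_units(self):
        k = mem.compressibility(self.series(0.42, 0.004), 310.0, mode="variance",
                                n_per_leaflet=250)
        expected = BOLTZMANN * 310.0 * 0.42 / (250 * 0.004**2) * 1e21
        assert k == pytest.approx(expected, rel=1e-12)


class TestDiffusivity:
    def test_msd_matches_brute_force_oracle(self, rng):
        xy = rng.normal(size=(100, 12, 2)).cumsum(axis=0)
        msd = mem.mean_square_displacement(xy)
        T = xy.shape[0]
        brute = np.array(
            [np.mean([((xy[k + m] - xy[k]) ** 2).sum(-1) for k in range(T - m)])
             for m in range(T)]
        )
        np.testing.assert_allclose(msd, brute, atol=1e-9)

    def test_wrapped_equals_unwrapped(self, rng):
        T, N, L = 500, 10, 25.0
        steps = rng.normal(0, 0.4, size=(T - 1, N, 2))
        true = np.concatenate([rng.uniform(0, L, (1, N, 2)), steps]).cumsum(axis=0)
        box = np.full((T, 2), L)
        z = np.zeros((T, N, 1))
        t_u = HeadTrajectory(np.arange(T) * 1.0, box, np.concatenate([true, z], 2),
                             np.ones(N), N)
        t_w = HeadTrajectory(np.arange(T) * 1.0, box,
                             np.concatenate([np.mod(true, L), z], 2), np.ones(N), N)
        m_u = mem.mean_square_displacement(t_u.positions_nm[:, :, :2])
        m_w = mem.mean_square_displacement(mem.unwrap_trajectory(t_w))
        np.testing.assert_allclose(m_u, m_w, atol=1e-9)

    def test_immobile_heads_zero(self):
        traj = syn.simulate_trajectory(n_heads=20, d_true_um2_s=0.0, n_steps=200, seed=1)
        fit = mem.lateral_diffusivity(traj)
        assert fit.d_um2_s == pytest.approx(0.0, abs=1e-9)

    def test_ballistic_motion_flagged(self):
        T, N = 400, 10
        t = np.arange(T) * 1.0
        v = np.linspace(0.5, 1.5, N)
        x = np.outer(t, v)
        pos = np.stack([x, np.zeros_like(x), np.zeros_like(x)], axis=2)
        big = np.full((T, 2), 1e9)
        traj = HeadTrajectory(t, big, pos, np.ones(N), N)
        fit = mem.lateral_diffusivity(traj)
        assert fit.poor_linear_fit

    def test_formulation_ordering_recovered(self):
        """Three synthetic systems with D1 > D3 > D2 must keep their order."""
        estimates = {}
        for label, d in {"f1": 6.0, "f2": 2.0, "f3": 4.0}.items():
            traj = syn.simulate_trajectory(
                n_heads=200, d_true_um2_s=d, n_steps=2000, seed=13
            )
            estimates[label] = mem.lateral_diffusivity(
                traj, fit_window_fraction=(0.01, 0.2)
            ).d_um2_s
        assert estimates["f1"] > estimates["f3"] > estimates["f2"]

    def test_window_outside_span_rejected(self):
        traj = syn.simulate_trajectory(n_heads=10, n_steps=20, seed=2)
        with pytest.raises(ValueError):
            mem.lateral_diffusivity(traj, fit_window_fraction=(0.9, 0.95))


class TestCsvRoundTrip:
    def test_trajectory_roundtrip(self, tmp_path):
        traj = syn.simulate_trajectory(n_heads=10, n_steps=20, seed=3)
        path = tmp_path / "traj.csv"
        mem.write_trajectory_csv(traj, path)
        back = mem.read_trajectory_csv(str(path))
        np.testing.assert_allclose(back.positions_nm, traj.positions_nm, atol=1e-9)
        np.testing.assert_allclose(back.box_nm, traj.box_nm, atol=1e-9)
        assert back.n_per_leaflet == traj.n_per_leaflet
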