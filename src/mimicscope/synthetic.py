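"""Ground-truthed synthetic data for every downstream stage.

Emulates the raw inputs of a spectrally resolved Nile Red PAINT experiment
on lipid-coated nanocapsules, plus the auxiliary data the package analyses:

* transient dye binding as a per-frame two-state (dark/bright) Markov
  chain per particle — a binding event is one bright run with a fixed
  position on the particle and a fixed emission peak wavelength drawn from
  the particle's polarity distribution;
* paired spatial/spectral camera stacks: the spatial channel renders a
  pixel-integrated 2D Gaussian PSF (zeroth grating order), the spectral
  channel a dispersed footprint whose position along the dispersion axis
  encodes the emission wavelength (first order), both with Poisson photon
  and background noise;
* TEM-like capsule size distributions (truncated-normal samples, 5-nm
  bins);
* 2D Brownian lipid head-group trajectories with Gaussian box-area
  fluctuations, for the membrane estimators.

Every generator takes an explicit seed and is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import erf

from .membrane import NM2_PER_NS_TO_UM2_PER_S, HeadTrajectory

__all__ = [
    "GroundTruthParticle",
    "SimulationConfig",
    "SimulatedMovie",
    "simulate_blinking",
    "render_movie",
    "simulate_particle_field",
    "simulate_movie",
    "simulate_size_distribution",
    "draw_truncated_diameters",
    "simulate_trajectory",
]

NILE_RED_RANGE_NM = (550.0, 700.0)


@dataclass(frozen=True)
class GroundTruthParticle:
    """One simulated particle with known polarity and kinetics."""

    id: int
    center_nm: tuple[float, float]
    diameter_nm: float
    coated: bool
    peak_wavelength_mean_nm: float
    peak_wavelength_sd_nm: float
    on_rate: float  # dark -> bright probability per frame
    off_rate: float  # bright -> dark probability per frame

    def __post_init__(self) -> None:
        lo, hi = NILE_RED_RANGE_NM
        if not (lo <= self.peak_wavelength_mean_nm <= hi):
            raise ValueError("peak wavelength outside the Nile Red emission range")
        for r in (self.on_rate, self.off_rate):
            if not (0 < r <= 1):
                raise ValueError("rates must lie in (0, 1]")


@dataclass
class SimulationConfig:
    """Imaging-rig and acquisition parameters for the simulator.

    The defaults mirror the spectral rig: 90 nm pixels, 50 ms exposure,
    41%/32% grating split between the zeroth (spatial) and first
    (spectral) order, and an affine dispersion λ = b + s·Δpx mapping the
    spatial-to-spectral pixel distance to wavelength.
    """

    fov_px: tuple[int, int] = (64, 64)  # rows (y), cols (x)
    pixel_size_nm: float = 90.0
    n_frames: int = 1000
    exposure_ms: float = 50.0
    psf_sigma_nm: float = 130.0
    photons_mean: float = 1500.0  # total emitted per bright frame
    zeroth_fraction: float = 0.41
    first_fraction: float = 0.32
    background_per_px: float = 2.0  # counts/px/frame
    spectral_fwhm_nm: float = 45.0
    dispersion: tuple[float, float] = (500.0, 2.0)  # λ = b + s·Δpx
    spectral_width_px: int | None = None  # default: fov cols + dispersion extent
    noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pixel_size_nm", "n_frames", "exposure_ms", "psf_sigma_nm",
                     "photons_mean", "spectral_fwhm_nm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if self.spectral_width_px is None:
            b, s = self.dispersion
            extent = (NILE_RED_RANGE_NM[1] - b) / s
            self.spectral_width_px = int(self.fov_px[1] + math.ceil(extent) + 16)

    @property
    def psf_sigma_px(self) -> float:
        return self.psf_sigma_nm / self.pixel_size_nm

    def wavelength_to_distance_px(self, wavelength_nm: float) -> float:
        b, s = self.dispersion
        return (wavelength_nm - b) / s


@dataclass
class SimulatedMovie:
    spatial: np.ndarray  # (T, H, W) float32 counts
    spectral: np.ndarray  # (T, H, Ws) float32 counts
    truth: pd.DataFrame  # one row per rendered event-frame
    particles: list[GroundTruthParticle]
    config: SimulationConfig
    n_dropped: int = 0


# ---------------------------------------------------------------------------
# blinking kinetics


def simulate_blinking(
    particles: list[GroundTruthParticle],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-frame bright events from a two-state Markov chain per particle.

    Chains start dark; a dark→bright transition opens a binding event whose
    bright stretch has geometric length (mean 1/off_rate frames).  Each
    event carries a fixed position — uniform on the particle's projected
    disc — and a fixed peak wavelength ~ Normal(mean, sd) clipped to the
    Nile Red emission range.  Uncoated particles never bind dye.

    Returns a frame-level table: frame (1-based), particle_id, event_id,
    x_nm, y_nm, wavelength_nm.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    rows: list[tuple] = []
    event_id = 0
    lo, hi = NILE_RED_RANGE_NM
    for p in particles:
        if not p.coated:
            continue
        # state chain: dark->bright w.p. on_rate, bright persists w.p. 1-off_rate,
        # so bright runs are geometric with mean 1/off_rate frames
        u = rng.random(config.n_frames)
        bright = False
        start = 0
        runs: list[tuple[int, int]] = []
        for t in range(config.n_frames):
            if bright:
                if u[t] < p.off_rate:
                    runs.append((start, t - 1))
                    bright = False
            else:
                if u[t] < p.on_rate:
                    bright = True
                    start = t
        if bright:
            runs.append((start, config.n_frames - 1))
        for first, last in runs:
            r = p.diameter_nm / 2.0 * np.sqrt(rng.random())
            phi = rng.uniform(0, 2 * np.pi)
            x = p.center_nm[0] + r * np.cos(phi)
            y = p.center_nm[1] + r * np.sin(phi)
            lam = float(np.clip(
                rng.normal(p.peak_wavelength_mean_nm, p.peak_wavelength_sd_nm), lo, hi
            ))
            for f in range(first, last + 1):
                rows.append((f + 1, p.id, event_id, x, y, lam))
            event_id += 1
    return pd.DataFrame(
        rows, columns=["frame", "particle_id", "event_id", "x_nm", "y_nm", "wavelength_nm"]
    )


# ---------------------------------------------------------------------------
# rendering


def _integrated_gaussian_1d(centers: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    """Fraction of a unit Gaussian falling into unit pixels at ``centers``."""
    s = sigma * np.sqrt(2.0)
    return 0.5 * (erf((centers + 0.5 - mu) / s) - erf((centers - 0.5 - mu) / s))


def render_movie(
    events: pd.DataFrame,
    config: SimulationConfig,
    particles: list[GroundTruthParticle] | None = None,
    rng: np.random.Generator | None = None,
) -> SimulatedMovie:
    """Render paired spatial + spectral stacks from a bright-event table.

    Spatial channel: pixel-integrated 2D Gaussian PSF at the event
    position with ``photons·zeroth_fraction`` photons.  Spectral channel:
    a footprint at pixel distance ``(λ − b)/s`` from the event's spatial
    column, Gaussian along the dispersion axis (FWHM set by
    ``spectral_fwhm_nm`` mapped through the dispersion) and PSF-sized
    transversely, with ``photons·first_fraction`` photons.  With
    ``noise=True`` every pixel is Poisson-drawn (photon noise + uniform
    background); otherwise expected counts are returned.  Events whose
    footprint centre falls off the spectral chip are dropped and counted.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    H, W = config.fov_px
    Ws = config.spectral_width_px
    T = config.n_frames
    spatial = np.zeros((T, H, W), dtype=np.float32)
    spectral = np.zeros((T, H, Ws), dtype=np.float32)
    sig_px = config.psf_sigma_px
    b, s = config.dispersion
    sig_spec_px = config.spectral_fwhm_nm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / s

    truth_rows = []
    n_dropped = 0
    half = 4  # render out to ±4σ
    wsp = int(np.ceil(half * sig_px)) + 1
    wspec = int(np.ceil(half * sig_spec_px)) + 1

    for row in events.itertuples(index=False):
        t = int(row.frame) - 1
        x_px = row.x_nm / config.pixel_size_nm
        y_px = row.y_nm / config.pixel_size_nm
        photons = config.photons_mean if not config.noise else float(rng.poisson(config.photons_mean))
        x_spec = x_px + config.wavelength_to_distance_px(row.wavelength_nm)
        if not (0 <= x_spec < Ws):
            n_dropped += 1
            truth_rows.append((row.frame, row.particle_id, row.event_id, row.x_nm,
                               row.y_nm, row.wavelength_nm, photons, True))
            continue

        # spatial PSF
        c0, r0 = int(round(x_px)), int(round(y_px))
        cols = np.arange(max(c0 - wsp, 0), min(c0 + wsp + 1, W))
        rows_ = np.arange(max(r0 - wsp, 0), min(r0 + wsp + 1, H))
        if len(cols) and len(rows_):
            gx = _integrated_gaussian_1d(cols, x_px, sig_px)
            gy = _integrated_gaussian_1d(rows_, y_px, sig_px)
            spatial[t, rows_[0]:rows_[-1] + 1, cols[0]:cols[-1] + 1] += (
                photons * config.zeroth_fraction * np.outer(gy, gx)
            ).astype(np.float32)

        # spectral footprint
        c1 = int(round(x_spec))
        cols = np.arange(max(c1 - wspec, 0), min(c1 + wspec + 1, Ws))
        rows_ = np.arange(max(r0 - wsp, 0), min(r0 + wsp + 1, H))
        if len(cols) and len(rows_):
            gx = _integrated_gaussian_1d(cols, x_spec, sig_spec_px)
            gy = _integrated_gaussian_1d(rows_, y_px, sig_px)
            spectral[t, rows_[0]:rows_[-1] + 1, cols[0]:cols[-1] + 1] += (
                photons * config.first_fraction * np.outer(gy, gx)
            ).astype(np.float32)

        truth_rows.append((row.frame, row.particle_id, row.event_id, row.x_nm,
                           row.y_nm, row.wavelength_nm, photons, False))

    if config.noise:
        for t in range(T):
            spatial[t] = rng.poisson(spatial[t] + config.background_per_px)
            spectral[t] = rng.poisson(spectral[t] + config.background_per_px)
    else:
        spatial += config.background_per_px
        spectral += config.background_per_px

    truth = pd.DataFrame(
        truth_rows,
        columns=["frame", "particle_id", "event_id", "x_nm", "y_nm",
                 "wavelength_nm", "photons", "dropped"],
    )
    return SimulatedMovie(spatial, spectral, truth, particles or [], config, n_dropped)


def simulate_particle_field(
    n_particles: int,
    config: SimulationConfig,
    wavelength_means_nm: tuple[float, ...] = (612.0,),
    wavelength_inter_sd_nm: float = 3.0,
    wavelength_intra_sd_nm: float = 5.0,
    diameter_mean_nm: float = 80.0,
    diameter_sd_nm: float = 12.0,
    on_rate: float = 0.05,
    off_rate: float = 0.5,
    coated_fraction: float = 1.0,
    row_spacing_px: float = 10.0,
    x_range_px: tuple[float, float] = (15.0, 55.0),
    rng: np.random.Generator | None = None,
) -> list[GroundTruthParticle]:
    """Lay out particles one per row band (so spectral footprints never share
    rows) and draw per-particle polarity means from the listed
    sub-population means, cycling through them.
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    px = config.pixel_size_nm
    parts = []
    for i in range(n_particles):
        y_px = row_spacing_px * (i + 0.5) + rng.uniform(-1.5, 1.5)
        if y_px >= config.fov_px[0] - 2:
            raise ValueError("FOV too small for the requested particle count")
        x_px = rng.uniform(*x_range_px)
        mean = wavelength_means_nm[i % len(wavelength_means_nm)]
        lam = float(np.clip(rng.normal(mean, wavelength_inter_sd_nm), *NILE_RED_RANGE_NM))
        d = float(np.clip(rng.normal(diameter_mean_nm, diameter_sd_nm), 40.0, 160.0))
        parts.append(
            GroundTruthParticle(
                id=i,
                center_nm=(x_px * px, y_px * px),
                diameter_nm=d,
                coated=bool(rng.random() < coated_fraction),
                peak_wavelength_mean_nm=lam,
                peak_wavelength_sd_nm=wavelength_intra_sd_nm,
                on_rate=on_rate,
                off_rate=off_rate,
            )
        )
    return parts


def simulate_movie(
    particles: list[GroundTruthParticle], config: SimulationConfig
) -> SimulatedMovie:
    """Blinking + rendering with a single seeded generator."""
    rng = np.random.default_rng(config.seed)
    events = simulate_blinking(particles, config, rng)
    return render_movie(events, config, particles, rng)


# ---------------------------------------------------------------------------
# size distribution


def draw_truncated_diameters(
    mean: float, sd: float, n: int, seed: int, lower: float = 45.0, upper: float = 125.0
) -> np.ndarray:
    a, b = (lower - mean) / sd, (upper - mean) / sd
    return stats.truncnorm(a, b, loc=mean, scale=sd).rvs(
        n, random_state=np.random.default_rng(seed)
    )


def simulate_size_distribution(mean: float, sd: float, n: int, seed: int):
    """TEM-like diameter histogram: truncated-normal samples on [45, 125] nm
    binned at 5 nm.  Returns (SizeDistribution, samples)."""
    from .budget import SizeDistribution

    if n < 1:
        raise ValueError("n must be >= 1")
    if sd <= 0:  # degenerate: all mass in the bin containing the mean
        samples = np.full(n, mean)
    else:
        samples = draw_truncated_diameters(mean, sd, n, seed)
    return SizeDistribution.from_samples(samples), samples


# ---------------------------------------------------------------------------
# bilayer trajectories


def simulate_trajectory(
    n_heads: int = 1000,
    d_true_um2_s: float = 5.0,
    apl_mean_nm2: float = 0.42,
    apl_sd_nm2: float = 0.004,
    d_hh_nm: float = 4.0,
    n_steps: int = 2000,
    dt_ns: float = 10.0,
    seed: int = 0,
    z_noise_nm: float = 0.1,
    temperature_K: float = 310.0,
    apl_corr_frames: float = 100.0,
) -> HeadTrajectory:
    """2D Brownian head-group motion in a fluctuating periodic box.

    Per-axis step variance is 2·D·dt; the box side follows
    L(t) = sqrt(n_per_leaflet·APL(t)) where APL(t) is a stationary AR(1)
    process with mean ``apl_mean_nm2``, sd ``apl_sd_nm2`` and correlation
    time ``apl_corr_frames`` frames — barostat-regulated box areas relax
    smoothly rather than jumping frame to frame, and smooth box motion is
    what keeps minimum-image unwrapping consistent.  apl_sd 0 gives a
    rigid box, under which the compressibility estimator must refuse to
    divide by zero.  Heads sit at z = ±d_hh/2 plus Gaussian noise, half
    per leaflet.
    """
    rng = np.random.default_rng(seed)
    n_leaf = n_heads // 2
    if n_leaf < 1:
        raise ValueError("need at least 2 heads")
    times = np.arange(n_steps) * dt_ns
    apl = np.full(n_steps, float(apl_mean_nm2))
    if apl_sd_nm2 > 0:
        a = np.exp(-1.0 / max(apl_corr_frames, 1.0))
        innov = np.sqrt(1.0 - a * a)
        e = rng.standard_normal(n_steps)
        z_ar = np.empty(n_steps)
        z_ar[0] = e[0]
        for t in range(1, n_steps):
            z_ar[t] = a * z_ar[t - 1] + innov * e[t]
        apl += apl_sd_nm2 * z_ar
    L = np.sqrt(np.maximum(apl, 1e-6) * n_leaf)
    box = np.stack([L, L], axis=1)

    d_nm2_ns = d_true_um2_s / NM2_PER_NS_TO_UM2_PER_S
    sigma_step = np.sqrt(2.0 * d_nm2_ns * dt_ns)
    xy = np.empty((n_steps, n_heads, 2))
    xy[0] = rng.uniform(0, L[0], size=(n_heads, 2))
    if sigma_step > 0:
        steps = rng.normal(0.0, sigma_step, size=(n_steps - 1, n_heads, 2))
    else:
        steps = np.zeros((n_steps - 1, n_heads, 2))
    np.cumsum(steps, axis=0, out=xy[1:])
    xy[1:] += xy[0]
    xy = np.mod(xy, box[:, None, :])

    leaflet = np.where(np.arange(n_heads) < n_leaf, 1, -1)
    z = np.broadcast_to(leaflet[None, :] * (d_hh_nm / 2.0), (n_steps, n_heads)).astype(float)
    if z_noise_nm > 0:
        z = z + z_noise_nm * rng.standard_normal((n_steps, n_heads))
    pos = np.concatenate([xy, z[:, :, None]], axis=2)
    return HeadTrajectory(times, box, pos, leaflet, n_leaf, temperature_K)
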