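# Methods

## Coating-stoichiometry budget

**Model.** A capsule of outer diameter *d*, wall thickness *t* and density ρ
is a perfect hollow sphere: `m_NC = (4/3)π[(d/2)³ − (d/2 − t)³]·ρ` (nm³
converted to cm³). Its single-bilayer coat is a two-leaflet area model: the
inner leaflet tiles a sphere of radius *d*/2, the outer one of radius
*d*/2 + *t_b* (geometric bilayer thickness *t_b*, default 4.0 nm — a typical
fluid bilayer), each molecule occupying an effective area *a_eff*. Molecule
count `N = 4π(r_in² + r_out²)/a_eff`; coat mass `N·⟨M⟩/N_A` with the
mole-fraction-weighted molar mass `⟨M⟩ = Σxᵢ·Mᵢ`, `xᵢ ∝ (mass fractionᵢ)/Mᵢ`.
The per-diameter capsule:lipid ratio is evaluated on the 45–125 nm grid in
5 nm steps and averaged with the frequency weights of a size distribution
(`Σ ratio(d)·freq(d)/100`).

**Defaults and why.** Wall 3.68 nm, density 1.87 g/cm³ and the truncated
normal size model (mean 79.4 nm, sd 11.6 nm, support [45, 125], 5 nm bins)
are the TEM/literature values for the target capsules. *a_eff* = 0.72 nm²
uniformly across species is the default; it reproduces the published design
window ([1.4, 2.6]) for the per-diameter ratios of the six mimic
formulations. A per-species mode (mole-fraction-weighted catalog areas,
cholesterol ≈ 0.40 nm², phospholipids 0.55–0.72 nm²) is available; it
yields a smaller effective area (condensed-packing picture) and accordingly
higher lipid masses — both conventions are legitimate, the uniform one is
the package's calibrated default. Molar masses are supplier-catalog values
for the named commercial products (e.g. cholesterol 386.65, 16:0 SM 703.03,
DSPE-PEG(2000) amine 2790.5, DOPC 786.11 g/mol); they are chemistry, not
fit parameters. For deterministic weighting the truncated-normal frequencies
come from CDF differences, not sampling; the sampling version lives in the
synthetic module and agrees within sampling error.

**Limits.** The area model ignores PEG-corona geometry, curvature-dependent
packing asymmetry between leaflets and any thermodynamics of coating
success; it budgets area only.

## Synthetic data generator

The generator emulates a spectrally resolved Nile Red PAINT acquisition on
immobilized particles plus the auxiliary inputs of the other stages. What it
reproduces: frame-quantized two-state blinking (dark→bright with per-frame
probability `on_rate`; bright runs geometric with mean `1/off_rate` frames);
one binding event = one bright run with a fixed position (uniform on the
particle's projected disc) and a fixed emission peak wavelength
`~N(particle mean, intra-particle sd)` clipped to the 550–700 nm Nile Red
band — the molecule's environment does not change during one binding;
pixel-integrated Gaussian PSF (σ default 130 nm ≈ λ/2NA for a 1.49 NA
objective at ~590 nm); a grating splitting 41% of photons into the zeroth
(spatial) and 32% into the first (spectral) order; an affine dispersion
λ = b + s·Δpx (default 500 nm + 2 nm/px); a Gaussian spectral footprint of
45 nm FWHM (the Gaussian matches the downstream fitting model; real Nile Red
spectra are broader and asymmetric); Poisson photon and background noise;
90 nm pixels and 50 ms exposure. What it does not reproduce: EMCCD gain
statistics, chromatic/astigmatic aberrations, particle motion, spectral
overlap of simultaneous emitters in one camera row, and the asymmetric dye
lineshape. Passing tests therefore demonstrate correctness of the
*estimators* under a faithful geometric/photon model, not robustness to
every instrument artifact.

Bilayer trajectories are 2D Brownian walks (per-axis step variance 2·D·dt)
wrapped in a periodic box whose area follows a stationary AR(1) process
(mean `apl_mean·n_leaflet`, sd `apl_sd·n_leaflet`, correlation time 100
frames). The AR(1) choice is physical — barostat-coupled box areas relax
smoothly — and practical: white per-frame box jumps make minimum-image
unwrapping inconsistent and visibly bias recovered diffusivities. Heads sit
at z = ±D_HH/2 with Gaussian smear (default 0.1 nm).

All generators consume a single seeded `numpy` Generator and are
bit-reproducible.

## Localization

Candidates are local maxima of the PSF-matched-filtered frame above
median + k·1.4826·MAD (k = 3 default); a window-sum Poisson significance
screen (5σ default) rejects noise candidates cheaply before the
least-squares fit of a pixel-integrated symmetric 2D Gaussian
(7×7 px window; parameters x, y, σ, N, offset; non-converged, edge or
sub-50-photon fits dropped). Precision is the least-squares variant of the
Thompson-style formula, `var = (16/9)σ_a²/N + 8πσ_a⁴b²/(a²N²)` with
σ_a² = σ² + a²/12 — the 16/9 factor is the known penalty of unweighted LS
fitting relative to the MLE bound and matches the empirical error of this
fitter on synthetic movies.

Drift correction renders 10 temporal bins (default) as 20 nm histogram
images, registers each against the first by subpixel phase
cross-correlation, interpolates per-frame drift (cubic for ≥4 bins, constant
beyond the outer bin centers) and subtracts it; the first bin defines zero
drift and within-frame relative geometry is preserved exactly. The density
filter keeps localizations with ≥3 neighbors within 100 nm (defaults;
unstated in the original workflows, config-exposed). Colocalization is the
fraction of diffraction-limited core spots with a cluster centroid within a
radius (default 250 nm ≈ core PSF width).

## Spectral analysis

Dispersion calibration fits a polynomial (default order 2, through e.g. the
435/586/763 nm lamp lines; exactly order+1 points ⇒ interpolation with zero
residuals) and refuses non-monotone maps over the 550–700 nm working range;
the inverse map is solved by root bracketing to 1e-12. Spectrum extraction
sums a 5-px transverse band at the localization row, subtracts a per-column
background estimated over emitter-free rows, and converts columns to
wavelength relative to the localization position. The background estimator
default is the column **mean**: the column median of low-count Poisson data
is biased low by ~0.1 count/px, which inflates net spectral photons by tens
of counts per spectrum; the median remains available for fields crowded
with concurrent emitters. Peak fitting is a 1D Gaussian (amplitude, center,
width); the reported uncertainty is the center's standard error from the
fit covariance (the fitted width is exposed for width-based filtering as an
alternative reading of "uncertainty"). The centroid is the
positive-intensity-weighted mean. QC is literal: reject iff uncertainty
> 40 nm or spectral photons < 300; equality survives. Note the 5-px band
truncates ~8% of the transverse footprint, so measured spectral/spatial
photon ratios sit slightly below the nominal grating split.

## Particles and populations

Clustering is flat-kernel mean shift on (x, y): seeds are occupied
bandwidth-sized grid cells, each climbing to the mean of points within one
bandwidth until convergence (tolerance 1e-4·bandwidth); modes closer than
bandwidth/2 merge (higher support wins) and every localization joins its
nearest mode, so clusters partition the input. Bandwidth default 100 nm
(≈ particle radius + localization precision). Bright/dark linking groups
consecutive frames (gap tolerance default 0; 1 tolerates single-frame
blinking dropouts): a k-frame run is k·exposure of bright time, inter-run
gaps are dark times. Cluster size is `2√2 ×` RMS member-to-centroid
distance — unbiased for a uniformly sampled disc (RMS radius of a disc of
radius R is R/√2); aspect ratio is √(λ₁/λ₂) of the position covariance.
A cluster is "validated" with ≥5 events (config-exposed; degenerate
single-member clusters report sd 0 and are flagged).

Population comparison pools peak wavelengths of validated clusters (per
localization, or one mean per cluster) into 2-nm histograms on [550, 700]
normalized to unit integral; similarity is the zero-lag Pearson correlation
of matched-bin densities with the conventional 0.9 threshold. Peak (not
centroid) wavelength is the default observable. Heterogeneity splits into
inter-particle (sd of cluster means) and intra-particle (within-cluster
sds, summarized by their median) components.

## Membrane observables

APL is sampled every 10 ns (default) as `Lx·Ly/n_leaflet`; the standard
error treats samples as independent, so for strongly autocorrelated box
processes it understates the true uncertainty (the synthetic tests account
for this explicitly). D_HH is the distance between the two most prominent
peaks of the pooled head z-density (0.1 nm bins), each peak refined by the
local mean of head positions within ±3.5 bins — exact for delta-like
leaflets, unbiased for symmetric smearing. K_A defaults to the literal
fluctuation relation `k_B·T·⟨APL⟩/σ_APL`, which carries energy units (the
ratio ⟨APL⟩/σ_APL is dimensionless); the conventional variance-based
estimator `k_B·T·⟨APL⟩/(n_leaflet·σ_APL²)` in mN/m is an explicit mode.
Faithful-first, correct-optional: the literal form is reported for
comparability, the variance form for physical interpretation. Zero APL
variance (rigid box) is a refused division, not a silent infinity.

Diffusivity: lateral positions are unwrapped by per-step minimum image with
the current box, the ensemble MSD uses all time origins (FFT
autocorrelation algorithm, verified exactly against the brute-force double
loop), and D = slope/(2d), d = 2, from a weighted linear fit over a lag
window. The default window is 8–72.5% of the span, mirroring production-run
practice of skipping the short-time sub-diffusive regime; the default
weights are 1/τ² because the MSD estimate is strongly heteroscedastic
(variance ~ τ², ever fewer independent origins), with plain OLS available.
On the pure-Brownian synthetic bed there is no caging regime, so the
validation suite fits 1–20% of the span where the estimator is sharpest;
this is a window choice, not a different estimator. An R² below 0.995 flags
non-diffusive (e.g. ballistic) input. No finite-size correction is applied
to D; values are comparative, not absolute.

## Problem sizes in the test suite

The shipped suite runs at desk scale: the end-to-end sPAINT check uses 50
particles (two polarity sub-populations 60 nm apart), 1500 frames on a
512×96 px chip, one particle per 10-px row band so dispersed footprints
never share camera rows; trajectory recovery uses 500 heads × 10⁴ steps;
variance-component recovery uses 200 clusters × 100 events. These sizes
give comfortable statistical margins for every tolerance asserted while
keeping the full suite in a few minutes on one CPU.
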