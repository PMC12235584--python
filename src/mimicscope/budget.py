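"""Coating-stoichiometry budget for lipid-bilayer-coated nanocapsules.

How much lipid does a batch of hollow organosilica nanocapsules (NCs) need
for every capsule to receive exactly one bilayer?  The budget compares two
masses per capsule:

* the capsule itself, modeled as a perfect hollow silica sphere:
  ``m_NC = (4/3)·π·(r_o³ − (r_o − t)³)·ρ``;
* the bilayer coat, modeled with a two-leaflet area model: the inner
  leaflet tiles a sphere of the capsule radius, the outer leaflet a sphere
  one bilayer thickness larger, and each molecule occupies an effective
  area ``a_eff``; mass follows from the mole-fraction-weighted molar mass.

The per-diameter NC:lipid mass ratio is then averaged over the measured
capsule size distribution (frequency-weighted) to give the single
mass ratio used when mixing capsules and lipid films.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .constants import AVOGADRO, FAMILIES, LIPID_CATALOG, NM3_TO_CM3

__all__ = [
    "LipidSpecies",
    "Formulation",
    "NCGeometry",
    "SizeDistribution",
    "RatioCurve",
    "FormulationError",
    "available_formulations",
    "load_formulation",
    "validate_formulation",
    "nc_shell_mass",
    "effective_area",
    "bilayer_molecule_count",
    "bilayer_mass",
    "ratio_curve",
    "weighted_ratio",
    "truncated_normal_distribution",
    "budget_report",
    "DEFAULT_DIAMETERS_NM",
    "DEFAULT_AREA_NM2",
    "DEFAULT_BILAYER_THICKNESS_NM",
]

#: Diameter grid for ratio curves (nm).
DEFAULT_DIAMETERS_NM = np.arange(45.0, 130.0, 5.0)

#: Default uniform effective per-molecule area in a leaflet (nm^2).
DEFAULT_AREA_NM2 = 0.72

#: Default geometric bilayer thickness separating the two leaflets (nm).
DEFAULT_BILAYER_THICKNESS_NM = 4.0

MASS_FRACTION_TOL = 0.2  # formulation table rows sum to 100 within this


class FormulationError(ValueError):
    """A formulation violates its mass-balance or catalog invariants."""


@dataclass(frozen=True)
class LipidSpecies:
    """One lipid species of a formulation.

    mass_fraction is the percent of total formulation mass; molar_mass in
    g/mol; ref_area the per-molecule leaflet area in nm^2 (used only in
    the per-species area mode).
    """

    name: str
    family: str
    mass_fraction: float
    molar_mass: float
    ref_area: float

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise FormulationError(
                f"unknown lipid family {self.family!r} for species {self.name!r}"
            )
        if self.mass_fraction < 0:
            raise FormulationError(f"negative mass fraction for {self.name!r}")
        if self.molar_mass <= 0 or self.ref_area <= 0:
            raise FormulationError(f"non-positive constants for {self.name!r}")


@dataclass(frozen=True)
class Formulation:
    """An ordered list of lipid species with mass percentages."""

    label: str
    species: tuple[LipidSpecies, ...]

    @property
    def mass_fractions(self) -> np.ndarray:
        return np.array([s.mass_fraction for s in self.species])

    @property
    def molar_masses(self) -> np.ndarray:
        return np.array([s.molar_mass for s in self.species])

    def mole_fractions(self) -> np.ndarray:
        """Mole fractions x_i ∝ mass_fraction_i / molar_mass_i, normalized to 1."""
        w = self.mass_fractions / self.molar_masses
        return w / w.sum()

    def mean_molar_mass(self) -> float:
        """Mole-fraction-weighted mean molar mass, g/mol."""
        return float(self.mole_fractions() @ self.molar_masses)


@dataclass(frozen=True)
class NCGeometry:
    """Hollow-sphere nanocapsule geometry.

    Defaults are the TEM estimates for the target capsules: mean outer
    diameter 79.4 nm, wall 3.68 nm, and a sol-gel silica density of
    1.87 g/cm^3.
    """

    outer_diameter: float = 79.4  # nm
    wall_thickness: float = 3.68  # nm
    density: float = 1.87  # g/cm^3

    def __post_init__(self) -> None:
        if not (0 < 2 * self.wall_thickness <= self.outer_diameter):
            raise ValueError(
                "wall thickness must satisfy 0 < 2t <= outer diameter "
                f"(got t={self.wall_thickness}, d={self.outer_diameter})"
            )
        if self.density <= 0:
            raise ValueError("density must be positive")


@dataclass(frozen=True)
class SizeDistribution:
    """Binned capsule diameter distribution (uniform bins, percent frequencies)."""

    bin_edges: np.ndarray  # nm, len n+1
    frequency: np.ndarray  # percent per bin, len n

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        freq = np.asarray(self.frequency, dtype=float)
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "frequency", freq)
        widths = np.diff(edges)
        if len(freq) != len(widths):
            raise ValueError("frequency length must be len(bin_edges) - 1")
        if not np.allclose(widths, widths[0]):
            raise ValueError("bin width must be constant")
        if abs(freq.sum() - 100.0) > 0.01:
            raise ValueError(f"frequencies sum to {freq.sum():.4f}, expected 100")
        if (freq < 0).any():
            raise ValueError("negative frequency")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @classmethod
    def from_samples(
        cls,
        diameters_nm: np.ndarray,
        lower: float = 45.0,
        upper: float = 125.0,
        bin_width: float = 5.0,
    ) -> "SizeDistribution":
        edges = np.arange(lower, upper + bin_width / 2, bin_width)
        counts, _ = np.histogram(diameters_nm, bins=edges)
        if counts.sum() == 0:
            raise ValueError("no diameters fall inside the binning range")
        return cls(edges, 100.0 * counts / counts.sum())


@dataclass(frozen=True)
class RatioCurve:
    """Per-diameter NC:lipid mass ratio for one formulation."""

    diameters: np.ndarray  # nm, strictly increasing
    ratio: np.ndarray  # dimensionless
    formulation_label: str
    nc_mass_g: np.ndarray = field(default=None)  # type: ignore[assignment]
    lipid_mass_g: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        d = np.asarray(self.diameters, dtype=float)
        r = np.asarray(self.ratio, dtype=float)
        object.__setattr__(self, "diameters", d)
        object.__setattr__(self, "ratio", r)
        if not np.all(np.diff(d) > 0):
            raise ValueError("diameters must be strictly increasing")
        if (r <= 0).any():
            raise ValueError("ratios must be positive")


# ---------------------------------------------------------------------------
# formulation catalog


def _load_yaml() -> dict:
    with resources.files("mimicscope.data").joinpath("formulations.yaml").open() as fh:
        return yaml.safe_load(fh)


def available_formulations() -> list[str]:
    """Keys accepted by :func:`load_formulation`."""
    return sorted(_load_yaml()["formulations"])


def load_formulation(key: str) -> Formulation:
    """Load a packaged formulation (e.g. ``"ce-mimic-3"``) and validate it."""
    table = _load_yaml()["formulations"]
    if key not in table:
        raise KeyError(f"unknown formulation {key!r}; have {sorted(table)}")
    entry = table[key]
    species = []
    for name, fraction in entry["species"].items():
        cat = LIPID_CATALOG[str(name)]
        species.append(
            LipidSpecies(
                name=str(name),
                family=cat["family"],
                mass_fraction=float(fraction),
                molar_mass=cat["molar_mass"],
                ref_area=cat["ref_area"],
            )
        )
    return validate_formulation(Formulation(entry["label"], tuple(species)))


def validate_formulation(f: Formulation) -> Formulation:
    """Check mass balance (sum to 100 within 0.2) and positive constants."""
    if not f.species:
        raise FormulationError("formulation has no species")
    total = float(f.mass_fractions.sum())
    if abs(total - 100.0) > MASS_FRACTION_TOL:
        raise FormulationError(
            f"mass fractions sum to {total:g}, expected 100 ± {MASS_FRACTION_TOL}"
        )
    return f


# ---------------------------------------------------------------------------
# masses and ratios


def nc_shell_mass(g: NCGeometry) -> float:
    """Mass of one hollow capsule in grams.

    Shell volume (4/3)π(r_o³ − (r_o − t)³) in nm³ converted to cm³ and
    multiplied by the silica density.
    """
    r_o = g.outer_diameter / 2.0
    r_i = r_o - g.wall_thickness
    volume_nm3 = (4.0 / 3.0) * np.pi * (r_o**3 - r_i**3)
    return float(volume_nm3 * NM3_TO_CM3 * g.density)


def effective_area(f: Formulation, area_mode: str = "uniform", a_eff: float = DEFAULT_AREA_NM2) -> float:
    """Effective per-molecule leaflet area (nm^2).

    ``uniform`` uses a single area for every species (default 0.72 nm^2,
    calibrated so the per-diameter ratios fall in the published design
    window); ``per_species`` uses the mole-fraction-weighted catalog areas.
    """
    if area_mode == "uniform":
        if a_eff <= 0:
            raise ValueError("a_eff must be positive")
        return float(a_eff)
    if area_mode == "per_species":
        areas = np.array([s.ref_area for s in f.species])
        return float(f.mole_fractions() @ areas)
    raise ValueError(f"unknown area_mode {area_mode!r}")


def bilayer_molecule_count(
    d_nc: float,
    f: Formulation,
    t_bilayer: float = DEFAULT_BILAYER_THICKNESS_NM,
    area_mode: str = "uniform",
    a_eff: float = DEFAULT_AREA_NM2,
) -> float:
    """Molecules in a single bilayer coat (both leaflets) of a d_nc-nm capsule.

    N = [4π r_in² + 4π r_out²] / a_eff with r_in = d/2, r_out = d/2 + t.
    """
    if d_nc <= 0:
        raise ValueError("capsule diameter must be positive")
    if t_bilayer < 0:
        raise ValueError("bilayer thickness must be non-negative")
    r_in = d_nc / 2.0
    r_out = r_in + t_bilayer
    area = 4.0 * np.pi * (r_in**2 + r_out**2)
    return float(area / effective_area(f, area_mode, a_eff))


def bilayer_mass(
    d_nc: float,
    f: Formulation,
    t_bilayer: float = DEFAULT_BILAYER_THICKNESS_NM,
    area_mode: str = "uniform",
    a_eff: float = DEFAULT_AREA_NM2,
) -> float:
    """Mass in grams of a single bilayer coat of formulation ``f``."""
    n = bilayer_molecule_count(d_nc, f, t_bilayer, area_mode, a_eff)
    return n * f.mean_molar_mass() / AVOGADRO


def ratio_curve(
    f: Formulation,
    geom_template: NCGeometry = NCGeometry(),
    diameters: np.ndarray | None = None,
    t_bilayer: float = DEFAULT_BILAYER_THICKNESS_NM,
    area_mode: str = "uniform",
    a_eff: float = DEFAULT_AREA_NM2,
) -> RatioCurve:
    """NC:lipid mass ratio per diameter; wall thickness and density held fixed."""
    validate_formulation(f)
    d = DEFAULT_DIAMETERS_NM.copy() if diameters is None else np.asarray(diameters, float)
    nc = np.array([nc_shell_mass(replace(geom_template, outer_diameter=di)) for di in d])
    lip = np.array([bilayer_mass(di, f, t_bilayer, area_mode, a_eff) for di in d])
    return RatioCurve(d, nc / lip, f.label, nc_mass_g=nc, lipid_mass_g=lip)


def weighted_ratio(curve: RatioCurve, dist: SizeDistribution) -> float:
    """Frequency-weighted mass ratio: Σ_d ratio(d)·freq(d)/100.

    Bin-center ratios are taken from the curve (linear interpolation on the
    5-nm grid); bins outside the curve's diameter range are an error.
    """
    centers = dist.bin_centers
    occupied = dist.frequency > 0
    if centers[occupied].min() < curve.diameters[0] or centers[occupied].max() > curve.diameters[-1]:
        raise ValueError("size distribution extends beyond the ratio curve's diameter range")
    r = np.interp(centers, curve.diameters, curve.ratio)
    return float(r @ dist.frequency / 100.0)


def truncated_normal_distribution(
    mean: float = 79.4,
    sd: float = 11.6,
    lower: float = 45.0,
    upper: float = 125.0,
    bin_width: float = 5.0,
) -> SizeDistribution:
    """Deterministic truncated-normal size model, binned like a TEM histogram."""
    a, b = (lower - mean) / sd, (upper - mean) / sd
    tn = stats.truncnorm(a, b, loc=mean, scale=sd)
    edges = np.arange(lower, upper + bin_width / 2, bin_width)
    freq = np.diff(tn.cdf(edges))
    return SizeDistribution(edges, 100.0 * freq / freq.sum())


def budget_report(
    f: Formulation,
    geom_template: NCGeometry = NCGeometry(),
    dist: SizeDistribution | None = None,
    **kwargs,
) -> tuple[pd.DataFrame, float]:
    """Per-diameter budget table plus the frequency-weighted ratio."""
    curve = ratio_curve(f, geom_template, **kwargs)
    if dist is None:
        dist = truncated_normal_distribution()
    wr = weighted_ratio(curve, dist)
    table = pd.DataFrame(
        {
            "diameter_nm": curve.diameters,
            "nc_mass_g": curve.nc_mass_g,
            "lipid_mass_g": curve.lipid_mass_g,
            "ratio": curve.ratio,
        }
    )
    return table, wr
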