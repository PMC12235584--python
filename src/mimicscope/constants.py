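"""Physical constants and the lipid-species catalog.

Molar masses are supplier-catalog values for the commercial products used
to assemble the mimic formulations (Avanti Polar Lipids / Sigma-Aldrich
listings; sodium-salt masses where the product is sold as such).
``ref_area`` is a literature-typical per-molecule area in a fluid leaflet,
used only in the optional per-species area mode of the coating budget.
"""

from __future__ import annotations

#: Avogadro constant, 1/mol.
AVOGADRO = 6.02214076e23

#: Boltzmann constant, J/K.
BOLTZMANN = 1.380649e-23

#: Volume conversion: nm^3 -> cm^3.
NM3_TO_CM3 = 1e-21

#: Recognized lipid head-group families.
FAMILIES = frozenset({"Chol", "SM", "PE", "PC", "PS", "PA"})

#: Per-species constants: family, molar mass (g/mol), reference area (nm^2).
LIPID_CATALOG: dict[str, dict] = {
    "cholesterol": {"family": "Chol", "molar_mass": 386.65, "ref_area": 0.40},
    "16:0 SM": {"family": "SM", "molar_mass": 703.03, "ref_area": 0.55},
    "DSPE-PEG(2000) amine": {"family": "PE", "molar_mass": 2790.5, "ref_area": 0.60},
    "18:2 PE": {"family": "PE", "molar_mass": 738.0, "ref_area": 0.65},
    "DOPC": {"family": "PC", "molar_mass": 786.11, "ref_area": 0.72},
    "16:0 PS": {"family": "PS", "molar_mass": 757.95, "ref_area": 0.60},
    "18:1 PA": {"family": "PA", "molar_mass": 722.94, "ref_area": 0.65},
}
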