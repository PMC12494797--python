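"""Reference tables: residue compositions, volumes, masses; atomic parameters.

Electron counts are for the in-chain residue (amino acid minus one water).
Residue volumes are standard crystallographic mean volumes (Å³); average
residue masses are the usual average isotopic values (Da). These feed the
coarse-grained excess scattering length
``b_eff = electrons − ρ_solvent · V_residue`` with ρ_solvent = 0.334 e/Å³.
"""

from __future__ import annotations

import numpy as np

#: electron density of bulk water at 20 °C, e/Å³
SOLVENT_EDENS = 0.334

#: σ = K · V^{1/3} makes a Gaussian bead's second moment match a uniform
#: sphere of volume V: 3σ² = (3/5)R² with R = (3V/4π)^{1/3}
GAUSS_WIDTH_K = (1.0 / 5.0) ** 0.5 * (3.0 / (4.0 * np.pi)) ** (1.0 / 3.0)

# residue: (electrons, volume Å³, average mass Da)
RESIDUE_TABLE: dict[str, tuple[int, float, float]] = {
    "GLY": (30, 63.8, 57.0519),
    "ALA": (38, 90.1, 71.0788),
    "SER": (46, 94.2, 87.0782),
    "PRO": (52, 123.1, 97.1167),
    "VAL": (54, 139.1, 99.1326),
    "THR": (54, 120.0, 101.1051),
    "CYS": (54, 113.2, 103.1388),
    "LEU": (62, 164.6, 113.1594),
    "ILE": (62, 164.9, 113.1594),
    "ASN": (60, 127.5, 114.1038),
    "ASP": (60, 117.1, 115.0886),
    "GLN": (68, 149.4, 128.1307),
    "LYS": (70, 170.0, 128.1741),
    "GLU": (68, 140.8, 129.1155),
    "MET": (70, 167.7, 131.1926),
    "HIS": (72, 159.3, 137.1411),
    "PHE": (78, 193.5, 147.1766),
    "ARG": (84, 192.8, 156.1875),
    "TYR": (86, 197.1, 163.1760),
    "TRP": (98, 231.7, 186.2132),
}

#: fallback for non-standard residues: table averages
AVERAGE_RESIDUE = tuple(
    float(np.mean([v[i] for v in RESIDUE_TABLE.values()])) for i in range(3)
)

WATER_MASS = 18.0153  # Da, added once per chain terminus pair

ONE_TO_THREE = {
    "G": "GLY", "A": "ALA", "S": "SER", "P": "PRO", "V": "VAL",
    "T": "THR", "C": "CYS", "L": "LEU", "I": "ILE", "N": "ASN",
    "D": "ASP", "Q": "GLN", "K": "LYS", "E": "GLU", "M": "MET",
    "H": "HIS", "F": "PHE", "R": "ARG", "Y": "TYR", "W": "TRP",
}

ATOM_ELECTRONS = {"H": 1, "C": 6, "N": 7, "O": 8, "P": 15, "S": 16}

#: per-atom displaced solvent volumes (Å³), standard excluded-volume set
ATOM_VOLUMES = {"H": 5.15, "C": 16.44, "N": 2.49, "O": 9.13, "P": 5.73, "S": 19.86}

#: van der Waals radii (Å) for solvent-accessible surface area
VDW_RADII = {"H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "P": 1.80, "S": 1.80}
DEFAULT_VDW_RADIUS = 1.70

#: electron density of water times one water volume — used for hydration beads
WATER_EDENS = SOLVENT_EDENS
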