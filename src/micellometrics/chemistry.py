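"""Chemical reference data for the coarse peptoid micelle model.

The in-memory representation is one bead per heavy group: every peptoid
residue contributes a backbone bead (the N-CH2-C=O unit) plus side-chain
beads, the carboxylate of COE is resolved into an explicit carbon and two
oxygens (its distances define salt bridges and coordination shells), water
is a rigid three-site molecule and sodium a single ion.  Masses are the
group formula masses in amu; each bead carries the element whose nucleus
dominates its neutron scattering contrast.

All tables here are plain dicts so callers can pass overrides.
"""

from __future__ import annotations

# residue name vocabulary: N-decyl (DEC), N-methoxyethyl (MOE),
# N-(2-carboxyethyl) (COE) peptoid residues, water, sodium
RESIDUE_NAMES = ("DEC", "MOE", "COE", "WAT", "NA")

# aliases seen in common file dialects, mapped onto the canonical vocabulary
RESIDUE_ALIASES = {
    "SOL": "WAT", "HOH": "WAT", "TIP3": "WAT", "WAT": "WAT",
    "NA+": "NA", "SOD": "NA", "NA": "NA",
    "DEC": "DEC", "MOE": "MOE", "COE": "COE",
}

ATOM_ROLES = (
    "backbone", "sidechain",
    "carboxylate_carbon", "carboxylate_oxygen",
    "water_oxygen", "water_hydrogen", "sodium",
)

# group formula masses, amu
_M_H, _M_C, _M_N, _M_O, _M_NA = 1.008, 12.011, 14.007, 15.999, 22.990
MASS_BACKBONE = 2 * _M_C + 2 * _M_H + _M_N + _M_O          # -N-CH2-C(=O)-
MASS_DECYL = 10 * _M_C + 21 * _M_H                         # C10H21
MASS_METHOXYETHYL = 3 * _M_C + 7 * _M_H + _M_O             # CH2CH2OCH3
MASS_ETHYL_LINKER = 2 * _M_C + 4 * _M_H                    # CH2CH2
MASS_WATER_O = _M_O
MASS_WATER_H = _M_H
MASS_SODIUM = _M_NA
MASS_WATER = _M_O + 2 * _M_H

# bead layout per residue: (atom name, element, role, mass)
BEAD_LAYOUT = {
    "DEC": (
        ("BB", "C", "backbone", MASS_BACKBONE),
        ("SC", "C", "sidechain", MASS_DECYL),
    ),
    "MOE": (
        ("BB", "C", "backbone", MASS_BACKBONE),
        ("SC", "C", "sidechain", MASS_METHOXYETHYL),
    ),
    "COE": (
        ("BB", "C", "backbone", MASS_BACKBONE),
        ("SC", "C", "sidechain", MASS_ETHYL_LINKER),
        ("CG", "C", "carboxylate_carbon", _M_C),
        ("OD1", "O", "carboxylate_oxygen", _M_O),
        ("OD2", "O", "carboxylate_oxygen", _M_O),
    ),
    "WAT": (
        ("OW", "O", "water_oxygen", MASS_WATER_O),
        ("HW1", "H", "water_hydrogen", MASS_WATER_H),
        ("HW2", "H", "water_hydrogen", MASS_WATER_H),
    ),
    "NA": (
        ("NA", "Na", "sodium", MASS_SODIUM),
    ),
}

# (residue, atom name) -> (element, role, mass); the user-overridable
# inference table applied on file read
ROLE_TABLE = {
    (res, name): (elem, role, mass)
    for res, beads in BEAD_LAYOUT.items()
    for name, elem, role, mass in beads
}

# Bondi van der Waals radii, nm
VDW_RADII_NM = {
    "H": 0.120,
    "C": 0.170,
    "N": 0.155,
    "O": 0.152,
    "Na": 0.227,
    "S": 0.180,
    "P": 0.180,
    "Cl": 0.175,
}

# coherent neutron scattering lengths, fm (Sears, Neutron News 3 (1992) 26)
COHERENT_B_FM = {
    "H": -3.7390,
    "D": 6.671,
    "C": 6.6460,
    "N": 9.360,
    "O": 5.803,
    "Na": 3.630,
    "Cl": 9.5770,
    "S": 2.847,
}

# liquid water at 300 K
WATER_NUMBER_DENSITY_NM3 = 33.37   # molecules / nm^3
WATER_MASS_DENSITY_G_CM3 = 0.997
AMU_PER_NM3_PER_G_CM3 = 602.214    # 1 g/cm^3 in amu/nm^3

# rigid water geometry (TIP3P-like)
WATER_OH_NM = 0.09572
WATER_HOH_DEG = 104.52


def canonical_residue(token: str) -> str:
    """Map a file residue token onto the canonical vocabulary.

    Raises ``KeyError`` with the offending token if it is unknown.
    """
    key = token.strip().upper()
    if key not in RESIDUE_ALIASES:
        raise KeyError(token)
    return RESIDUE_ALIASES[key]


def water_box_edge(n_waters: int, peptoid_wt_percent: float = 0.0) -> float:
    """Cubic box edge (nm) holding ``n_waters`` water molecules at liquid
    density, inflated for a peptoid weight fraction assumed near unit density.

    Mirrors how the simulated systems were sized: the water count fixes the
    solution volume at ~1 g/cm^3.
    """
    v_water = n_waters * MASS_WATER / (
        WATER_MASS_DENSITY_G_CM3 * AMU_PER_NM3_PER_G_CM3)
    v_total = v_water / max(1.0 - peptoid_wt_percent / 100.0, 1e-9)
    return v_total ** (1.0 / 3.0)
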