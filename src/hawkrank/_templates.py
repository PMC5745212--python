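"""Residue topology and force-field templates for the 20 standard amino acids.

Each template lists the residue's atoms as ``(name, element, lj_class,
charge)`` plus the intra-residue bond list.  The bond lists are the packaged
residue-topology table used for chemical-environment typing (ring membership,
bonded-oxygen counts, attached-hydrogen identity); typing is therefore
deterministic and conformation independent.

Lennard-Jones classes carry Amber-style (rmin/2, epsilon) values.  Charges
are ff14SB-style point charges; at load time each residue's charges are
renormalized exactly onto its formal charge (residual folded into CB, or CA
when no CB exists), so per-residue charge sums are exact.
"""

from __future__ import annotations

# lj_class -> (rmin_half [A], epsilon [kcal/mol])
LJ_CLASSES: dict[str, tuple[float, float]] = {
    "CT": (1.9080, 0.1094),   # sp3 carbon
    "C": (1.9080, 0.0860),    # carbonyl / carboxylate carbon
    "CA": (1.9080, 0.0860),   # aromatic carbon
    "C2": (1.9080, 0.0860),   # other sp2 carbon (ring CC/CW/CR..., guanidinium)
    "N": (1.8240, 0.1700),    # amide / guanidinium nitrogen
    "NA": (1.8240, 0.1700),   # aromatic ring nitrogen
    "N3": (1.8240, 0.1700),   # sp3 ammonium nitrogen
    "O": (1.6612, 0.2100),    # carbonyl oxygen
    "O2": (1.6612, 0.2100),   # carboxylate oxygen
    "OH": (1.7210, 0.2104),   # hydroxyl oxygen
    "S": (2.0000, 0.2500),    # thioether sulfur
    "SH": (2.0000, 0.2500),   # thiol sulfur
    "H": (0.6000, 0.0157),    # H on N
    "HO": (0.3000, 0.0000),   # H on hydroxyl O (zero well depth)
    "HS": (0.6000, 0.0157),   # H on S
    "HC": (1.4870, 0.0157),   # H on aliphatic C
    "H1": (1.3870, 0.0157),   # H on C with one electron-withdrawing neighbour
    "HP": (1.1000, 0.0157),   # H on C next to charged N
    "HA": (1.4590, 0.0150),   # H on aromatic C
    "H4": (1.4090, 0.0150),   # aromatic H, one electronegative neighbour
    "H5": (1.3590, 0.0150),   # aromatic H, two electronegative neighbours
}

# Shared backbone block (all residues except GLY and PRO).
_BB_ATOMS = [
    ("N", "N", "N", -0.4157),
    ("H", "H", "H", 0.2719),
    ("CA", "C", "CT", 0.0337),
    ("HA", "H", "H1", 0.0823),
    ("C", "C", "C", 0.5973),
    ("O", "O", "O", -0.5679),
]
_BB_BONDS = [("N", "H"), ("N", "CA"), ("CA", "HA"), ("CA", "C"), ("C", "O")]


def _res(side_atoms, side_bonds, formal_charge=0, link="CB"):
    atoms = list(_BB_ATOMS) + list(side_atoms)
    bonds = list(_BB_BONDS) + list(side_bonds)
    if link is not None:
        bonds.append(("CA", link))
    return {"atoms": atoms, "bonds": bonds, "formal_charge": formal_charge}


def _h3(stem, cls, q, parent):
    """Three equivalent hydrogens HX1..HX3 on one parent atom."""
    atoms = [(f"{stem}{k}", "H", cls, q) for k in (1, 2, 3)]
    bonds = [(parent, f"{stem}{k}") for k in (1, 2, 3)]
    return atoms, bonds


_HB1, _BB1 = _h3("HB", "HC", 0.0603, "CB")

RESIDUE_TEMPLATES: dict[str, dict] = {
    "ALA": _res(
        [("CB", "C", "CT", -0.1825)] + _HB1,
        _BB1,
    ),
    "ARG": _res(
        [
            ("CB", "C", "CT", -0.0301), ("HB2", "H", "HC", 0.0285), ("HB3", "H", "HC", 0.0285),
            ("CG", "C", "CT", 0.0390), ("HG2", "H", "HC", 0.0285), ("HG3", "H", "HC", 0.0285),
            ("CD", "C", "CT", 0.0486), ("HD2", "H", "H1", 0.0687), ("HD3", "H", "H1", 0.0687),
            ("NE", "N", "N", -0.5295), ("HE", "H", "H", 0.3456),
            ("CZ", "C", "C2", 0.8076),
            ("NH1", "N", "N", -0.8627), ("HH11", "H", "H", 0.4478), ("HH12", "H", "H", 0.4478),
            ("NH2", "N", "N", -0.8627), ("HH21", "H", "H", 0.4478), ("HH22", "H", "H", 0.4478),
        ],
        [
            ("CB", "HB2"), ("CB", "HB3"), ("CB", "CG"),
            ("CG", "HG2"), ("CG", "HG3"), ("CG", "CD"),
            ("CD", "HD2"), ("CD", "HD3"), ("CD", "NE"),
            ("NE", "HE"), ("NE", "CZ"),
            ("CZ", "NH1"), ("NH1", "HH11"), ("NH1", "HH12"),
            ("CZ", "NH2"), ("NH2", "HH21"), ("NH2", "HH22"),
        ],
        formal_charge=1,
    ),
    "ASN": _res(
        [
            ("CB", "C", "CT", -0.2041), ("HB2", "H", "HC", 0.0797), ("HB3", "H", "HC", 0.0797),
            ("CG", "C", "C", 0.7130), ("OD1", "O", "O", -0.5931),
            ("ND2", "N", "N", -0.9191), ("HD21", "H", "H", 0.4196), ("HD22", "H", "H", 0.4196),
        ],
        [
            ("CB", "HB2"), ("CB", "HB3"), ("CB", "CG"),
            ("CG", "OD1"), ("CG", "ND2"), ("ND2", "HD21"), ("ND2", "HD22"),
        ],
    ),
    "ASP": _res(
        [
            ("CB", "C", "CT", -0.0303), ("HB2", "H", "HC", -0.0122), ("HB3", "H", "HC", -0.0122),
            ("CG", "C", "C", 0.7994), ("OD1", "O", "O2", -0.8014), ("OD2", "O", "O2", -0.8014),
        ],
        [("CB", "HB2"), ("CB", "HB3"), ("CB", "CG"), ("CG", "OD1"), ("CG", "OD2")],
        formal_charge=-1,
    ),
    "CYS": _res(
        [
            ("CB", "C", "CT", -0.1231), ("HB2", "H", "H1", 0.1112), ("HB3", "H", "H1", 0.1112),
            ("SG", "S", "SH", -0.3119), ("HG", "H", "HS", 0.1933),
        ],
        [("CB", "HB2"), ("CB", "HB3"), ("CB", "SG"), ("SG", "HG")],
    ),
    "GLN": _res(
        [
            ("CB", "C", "CT", -0.0036), ("HB2", "H", "HC", 0.0171), ("HB3", "H", "HC", 0.0171),
            ("CG", "C", "CT", -0.0645), ("HG2", "H", "HC", 0.0352), ("HG3", "H", "HC", 0.0352),
            ("CD", "C", "C", 0.6951), ("OE1", "O", "O", -0.6086),
            ("NE2", "N", "N", -0.9407), ("HE21", "H", "H", 0.4251), ("HE22", "H", "H", 0.4251),
        ],
        [
            ("CB", "HB2"), ("CB", "HB3"), ("CB", "CG"),
            ("CG", "HG2"), ("CG", "HG3"), ("CG", "CD"),
            ("CD", "OE1"), ("CD", "NE2"), ("NE2", "HE21"), ("NE2", "HE22"),
        ],
    ),
    "GLU": _res(
        [
            ("CB", "C", "CT", 0.0560), ("HB2", "H", "HC", -0.0173), ("HB3", "H", "HC", -0.0173),
            ("CG", "C", "CT", 0.0136), ("HG2", "H", "HC", -0.0425), ("HG3", "H", "HC", -0.0425),
            ("CD", "C", "C", 0.8054), ("OE1", "O", "O2", -0.8188), ("OE2", "O", "O2", -0.8188),
        ],
        [
            ("CB", "HB2"), ("CB", "HB3"), ("CB", "CG"),
            ("CG", "HG2"), ("CG", "HG3"), ("CG", "CD"),
            ("CD", "OE1"), ("CD", "OE2"),
        ],
        formal_charge=-1,
    ),
    "GLY": {
        "atoms": [
            ("N", "N", "N", -0.4157), ("H", "H", "H", 0.2719),
            ("CA", "C", "CT", -0.0252), ("HA2", "H", "H1", 0.0698), ("HA3", "H", "H1", 0.0698),
            ("C", "C", "C", 0.5973), ("O", "O", "O", -0.5679),
        ],
        "bonds": [
            ("N", "H"), ("N", "CA"), ("CA", "HA2"), ("CA", "HA3"),
            ("CA", "C"), ("C", "O"),
        ],
        "formal_charge": 0,
    },
    # Neutral His modeled as the NE2-protonated (epsilon) tautomer.
    "HIS": _res(
        [
            ("CB", "C", "CT", -0.1012), ("HB2", "H", "HC", 0.0367), ("HB3", "H", "HC", 0.0367),
            ("CG", "C", "C2", 0.1868),
            ("ND1", "N", "NA", -0.5432),
            ("CE1", "C", "C2", 0.1635), ("HE1", "H", "H5", 0.1435),
            ("NE2", "N", "NA", -0.2795), ("HE2", "H", "H", 0.3339),
            ("CD2", "C", "C2", -0.2207), ("HD2", "H", "H4", 0.1862),
        ],
        [
            ("CB", "HB2"), ("CB", "HB3"), ("CB", "CG"),
            ("CG", "ND1"), ("ND1", "CE1"), ("CE1", "HE1"), ("CE1", "NE2"),
            ("NE2", "HE2"), ("NE2", "CD2"), ("CD2", "HD2"), ("CD2", "CG"),
        ],
    ),
    "ILE": _res(
        [
            ("CB", "C", "CT", 0.1303), ("HB", "H", "HC", 0.0187),
            ("CG2", "C", "CT", -0.3204),
            ("HG21", "H", "HC", 0.0882), ("HG22", "H", "HC", 0.0882), ("HG23", "H", "HC", 0.0882),
            ("CG1", "C", "CT", -0.0430), ("HG12", "H", "HC", 0.0236), ("HG13", "H", "HC", 0.0236),
            ("CD1", "C", "CT", -0.0660),
            ("HD11", "H", "HC", 0.0186), ("HD12", "H", "HC", 0.0186), ("HD13", "H", "HC", 0.0186),
        ],
        [
            ("CB", "HB"), ("CB", "CG2"), ("CB", "CG1"),
            ("CG2", "HG21"), ("CG2", "HG22"), ("CG2", "HG23"),
            ("CG1", "HG12"), ("CG1", "HG13"), ("CG1", "CD1"),
            ("CD1", "HD11"), ("CD1", "HD12"), ("CD1", "HD13"),
        ],
    ),
    "LEU": _res(
        [
            ("CB", "C", "CT", -0.1102), ("HB2", "H", "HC", 0.0457), ("HB3", "H", "HC", 0.0457),
            ("CG", "C", "CT", 0.3531), ("HG", "H", "HC", -0.0361),
            ("CD1", "C", "CT", -0.4121),
            ("HD11", "H", "HC", 0.1000), ("HD12", "H", "HC", 0.1000), ("HD13", "H", "HC", 0.1000),
            ("CD2", "C", "CT", -0.4121),
            ("HD21", "H", "HC", 0.1000), ("HD22", "H", "HC", 0.1000), ("HD23", "H", "HC", 0.1000),
        ],
        [
            ("CB", "HB2"), ("CB", "HB3"), ("CB", "CG"),
            ("CG", "HG"), ("CG", "CD1"), ("CG", "CD2"),
            ("CD1", "HD11"), ("CD1", "HD12"), ("CD1", "HD13"),
            ("CD2", "HD21"), ("CD2", "HD22"), ("CD2", "HD23"),
        ],
    ),
    "LYS": _res(
        [
            ("CB", "C", "CT", -0.0094), ("HB2", "H", "HC", 0.0362), ("HB3", "H", "HC", 0.0362),
            ("CG", "C", "CT", 0.0187), ("HG2", "H", "HC", 0.0103), ("HG3", "H", "HC", 0.0103),
            ("CD", "C", "CT", -0.0479), ("HD2", "H", "HC", 0.0621), ("HD3", "H", "HC", 0.0621),
            ("CE", "C", "CT", -0.0143), ("HE2", "H", "HP", 0.1135), ("HE3", "H", "HP", 0.1135),
            ("NZ", "N", "N3", -0.3854),
            ("HZ1", "H", "H", 0.3400), ("HZ2", "H", "H", 0.3400), ("HZ3", "H", "H", 0.3400),
        ],
        [
            ("CB", "HB2"), ("CB", "HB3"), ("CB", "CG"),
            ("CG", "HG2"), ("CG", "HG3"), ("CG", "CD"),
            ("CD", "HD2"), ("CD", "HD3"), ("CD", "CE"),
            ("CE", "HE2"), ("CE", "HE3"), ("CE", "NZ"),
            ("NZ", "HZ1"), ("NZ", "HZ2"), ("NZ", "HZ3"),
        ],
        formal_charge=1,
    ),
    "MET": _res(
        [
            ("CB", "C", "CT", 0.0342), ("HB2", "H", "HC", 0.0241), ("HB3", "H", "HC", 0.0241),
            ("CG", "C", "CT", 0.0018), ("HG2", "H", "H1", 0.0440), ("HG3", "H", "H1", 0.0440),
            ("SD", "S", "S", -0.2737),
            ("CE", "C", "CT", -0.0536),
            ("HE1", "H", "H1", 0.0684), ("HE2", "H", "H1", 0.0684), ("HE3", "H", "H1", 0.0684),
        ],
        [
            ("CB", "HB2"), ("CB", "HB3"), ("CB", "CG"),
            ("CG", "HG2"), ("CG", "HG3"), ("CG", "SD"), ("SD", "CE"),
            ("CE", "HE1"), ("CE", "HE2"), ("CE", "HE3"),
        ],
    ),
    "PHE": _res(
        [
            ("CB", "C", "CT", -0.0343), ("HB2", "H", "HC", 0.0295), ("HB3", "H", "HC", 0.0295),
            ("CG", "C", "CA", 0.0118),
            ("CD1", "C", "CA", -0.1256), ("HD1", "H", "HA", 0.1330),
            ("CE1", "C", "CA", -0.1704), ("HE1", "H", "HA", 0.1430),
            ("CZ", "C", "CA", -0.1072), ("HZ", "H", "HA", 0.1297),
            ("CE2", "C", "CA", -0.1704), ("HE2", "H", "HA", 0.1430),
            ("CD2", "C", "CA", -0.1256), ("HD2", "H", "HA", 0.1330),
        ],
        [
            ("CB", "HB2"), ("CB", "HB3"), ("CB", "CG"),
            ("CG", "CD1"), ("CD1", "HD1"), ("CD1", "CE1"), ("CE1", "HE1"),
            ("CE1", "CZ"), ("CZ", "HZ"), ("CZ", "CE2"), ("CE2", "HE2"),
            ("CE2", "CD2"), ("CD2", "HD2"), ("CD2", "CG"),
        ],
    ),
    "PRO": {
        "atoms": [
            ("N", "N", "N", -0.2548),
            ("CD", "C", "CT", 0.0192), ("HD2", "H", "H1", 0.0391), ("HD3", "H", "H1", 0.0391),
            ("CG", "C", "CT", 0.0189), ("HG2", "H", "HC", 0.0213), ("HG3", "H", "HC", 0.0213),
            ("CB", "C", "CT", -0.0070), ("HB2", "H", "HC", 0.0253), ("HB3", "H", "HC", 0.0253),
            ("CA", "C", "CT", -0.0266), ("HA", "H", "H1", 0.0641),
            ("C", "C", "C", 0.5896), ("O", "O", "O", -0.5748),
        ],
        "bonds": [
            ("N", "CA"), ("N", "CD"),
            ("CD", "HD2"), ("CD", "HD3"), ("CD", "CG"),
            ("CG", "HG2"), ("CG", "HG3"), ("CG", "CB"),
            ("CB", "HB2"), ("CB", "HB3"), ("CB", "CA"),
            ("CA", "HA"), ("CA", "C"), ("C", "O"),
        ],
        "formal_charge": 0,
    },
    "SER": _res(
        [
            ("CB", "C", "CT", 0.2117), ("HB2", "H", "H1", 0.0352), ("HB3", "H", "H1", 0.0352),
            ("OG", "O", "OH", -0.6546), ("HG", "H", "HO", 0.4275),
        ],
        [("CB", "HB2"), ("CB", "HB3"), ("CB", "OG"), ("OG", "HG")],
    ),
    "THR": _res(
        [
            ("CB", "C", "CT", 0.3654), ("HB", "H", "H1", 0.0043),
            ("CG2", "C", "CT", -0.2438),
            ("HG21", "H", "HC", 0.0642), ("HG22", "H", "HC", 0.0642), ("HG23", "H", "HC", 0.0642),
            ("OG1", "O", "OH", -0.6761), ("HG1", "H", "HO", 0.4102),
        ],
        [
            ("CB", "HB"), ("CB", "CG2"), ("CB", "OG1"),
            ("CG2", "HG21"), ("CG2", "HG22"), ("CG2", "HG23"),
            ("OG1", "HG1"),
        ],
    ),
    "TRP": _res(
        [
            ("CB", "C", "CT", -0.0050), ("HB2", "H", "HC", 0.0339), ("HB3", "H", "HC", 0.0339),
            ("CG", "C", "C2", -0.1415),
            ("CD1", "C", "C2", -0.1638), ("HD1", "H", "H4", 0.2062),
            ("NE1", "N", "NA", -0.3418), ("HE1", "H", "H", 0.3412),
            ("CE2", "C", "C2", 0.1380),
            ("CD2", "C", "C2", 0.1243),
            ("CE3", "C", "CA", -0.2387), ("HE3", "H", "HA", 0.1700),
            ("CZ3", "C", "CA", -0.1972), ("HZ3", "H", "HA", 0.1447),
            ("CH2", "C", "CA", -0.1134), ("HH2", "H", "HA", 0.1417),
            ("CZ2", "C", "CA", -0.2601), ("HZ2", "H", "HA", 0.1572),
        ],
        [
            ("CB", "HB2"), ("CB", "HB3"), ("CB", "CG"),
            ("CG", "CD1"), ("CD1", "HD1"), ("CD1", "NE1"),
            ("NE1", "HE1"), ("NE1", "CE2"), ("CE2", "CD2"), ("CD2", "CG"),
            ("CE2", "CZ2"), ("CZ2", "HZ2"), ("CZ2", "CH2"), ("CH2", "HH2"),
            ("CH2", "CZ3"), ("CZ3", "HZ3"), ("CZ3", "CE3"), ("CE3", "HE3"),
            ("CE3", "CD2"),
        ],
    ),
    "TYR": _res(
        [
            ("CB", "C", "CT", -0.0152), ("HB2", "H", "HC", 0.0295), ("HB3", "H", "HC", 0.0295),
            ("CG", "C", "CA", -0.0011),
            ("CD1", "C", "CA", -0.1906), ("HD1", "H", "HA", 0.1699),
            ("CE1", "C", "CA", -0.2341), ("HE1", "H", "HA", 0.1656),
            ("CZ", "C", "CA", 0.3226),
            ("OH", "O", "OH", -0.5579), ("HH", "H", "HO", 0.3992),
            ("CE2", "C", "CA", -0.2341), ("HE2", "H", "HA", 0.1656),
            ("CD2", "C", "CA", -0.1906), ("HD2", "H", "HA", 0.1699),
        ],
        [
            ("CB", "HB2"), ("CB", "HB3"), ("CB", "CG"),
            ("CG", "CD1"), ("CD1", "HD1"), ("CD1", "CE1"), ("CE1", "HE1"),
            ("CE1", "CZ"), ("CZ", "OH"), ("OH", "HH"),
            ("CZ", "CE2"), ("CE2", "HE2"), ("CE2", "CD2"), ("CD2", "HD2"),
            ("CD2", "CG"),
        ],
    ),
    "VAL": _res(
        [
            ("CB", "C", "CT", 0.2985), ("HB", "H", "HC", -0.0297),
            ("CG1", "C", "CT", -0.3192),
            ("HG11", "H", "HC", 0.0791), ("HG12", "H", "HC", 0.0791), ("HG13", "H", "HC", 0.0791),
            ("CG2", "C", "CT", -0.3192),
            ("HG21", "H", "HC", 0.0791), ("HG22", "H", "HC", 0.0791), ("HG23", "H", "HC", 0.0791),
        ],
        [
            ("CB", "HB"), ("CB", "CG1"), ("CB", "CG2"),
            ("CG1", "HG11"), ("CG1", "HG12"), ("CG1", "HG13"),
            ("CG2", "HG21"), ("CG2", "HG22"), ("CG2", "HG23"),
        ],
    ),
}

# Neutral-His naming aliases accepted on input.
RESIDUE_ALIASES = {"HIE": "HIS", "HID": "HIS"}

STANDARD_RESIDUES = frozenset(RESIDUE_TEMPLATES)

# Terminal decorations applied on top of the internal template.
# N-terminus: backbone amide H replaced by an ammonium H1/H2/H3 triplet
# (PRO keeps two: H2/H3); C-terminus: OXT added, carbonyl O becomes part of
# a carboxylate.  Charges of terminal residues are renormalized to
# formal_charge + 1 (N-term) or formal_charge - 1 (C-term).
NTERM_H_CHARGE = 0.22
CTERM_OXT_CHARGE = -0.80
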