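"""Reference tables: van der Waals radii, maximal residue ASA, residue chemistry.

The radii follow the protein set of Chothia (1976) as used by NACCESS
(carbonyl carbon 1.76 Å, other carbons 1.87 Å, nitrogen 1.65 Å, oxygen
1.40 Å, sulfur 1.85 Å).  Maximal per-residue ASA values are the
Gly-X-Gly theoretical values of Tien et al. (2013), used to normalise
absolute ASA into relative ASA.
"""

from __future__ import annotations

# --- van der Waals radii (Å), NACCESS-like --------------------------------

VDW_BY_ELEMENT: dict[str, float] = {
    "C": 1.87,
    "N": 1.65,
    "O": 1.40,
    "S": 1.85,
    "P": 1.80,
    "H": 1.00,
    "SE": 1.90,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}

# carbonyl / carboxyl carbons are smaller in the Chothia set
CARBONYL_CARBON_NAMES = {"C", "CG", "CD", "CZ"}
CARBONYL_CARBON_RESIDUES = {
    "C": None,  # backbone carbonyl C, all residues
    "CG": {"ASP", "ASN"},
    "CD": {"GLU", "GLN"},
    "CZ": {"ARG"},
}
VDW_CARBONYL_C = 1.76


def vdw_radius(atom_name: str, element: str, residue_name: str) -> float | None:
    """Radius for one heavy atom, or None when the element is unknown."""
    el = element.upper()
    if el == "C":
        restr = CARBONYL_CARBON_RESIDUES.get(atom_name.upper())
        if atom_name.upper() == "C" or (restr and residue_name.upper() in restr):
            return VDW_CARBONYL_C
        return VDW_BY_ELEMENT["C"]
    return VDW_BY_ELEMENT.get(el)


# --- maximal ASA in Gly-X-Gly (Å², Tien et al. 2013 theoretical) ----------

MAX_ASA_GXG: dict[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

# --- polarity alphabet (configurable at call sites) ------------------------

POLAR_RESIDUES: frozenset[str] = frozenset({
    "ARG", "LYS", "HIS", "ASP", "GLU", "ASN", "GLN",
    "SER", "THR", "TYR", "TRP", "CYS",
})
APOLAR_RESIDUES: frozenset[str] = frozenset({
    "ALA", "GLY", "ILE", "LEU", "MET", "PHE", "PRO", "VAL",
})

# --- hydrogen-bond donor / acceptor heavy atoms ----------------------------
# Backbone N donates, backbone O accepts (for every residue; PRO's N cannot
# donate).  Side-chain entries list heavy atoms that can act as donor (D)
# or acceptor (A); hydroxyls and histidine nitrogens are both.

HBOND_DONORS: dict[str, frozenset[str]] = {
    "ARG": frozenset({"NE", "NH1", "NH2"}),
    "ASN": frozenset({"ND2"}),
    "CYS": frozenset({"SG"}),
    "GLN": frozenset({"NE2"}),
    "HIS": frozenset({"ND1", "NE2"}),
    "LYS": frozenset({"NZ"}),
    "SER": frozenset({"OG"}),
    "THR": frozenset({"OG1"}),
    "TRP": frozenset({"NE1"}),
    "TYR": frozenset({"OH"}),
}

HBOND_ACCEPTORS: dict[str, frozenset[str]] = {
    "ASN": frozenset({"OD1"}),
    "ASP": frozenset({"OD1", "OD2"}),
    "GLN": frozenset({"OE1"}),
    "GLU": frozenset({"OE1", "OE2"}),
    "HIS": frozenset({"ND1", "NE2"}),
    "MET": frozenset({"SD"}),
    "SER": frozenset({"OG"}),
    "THR": frozenset({"OG1"}),
    "TYR": frozenset({"OH"}),
}

BACKBONE_DONOR = "N"
BACKBONE_ACCEPTOR = "O"

WATER_RESNAMES: frozenset[str] = frozenset({"HOH", "WAT", "SOL", "TIP3", "TIP"})

STANDARD_RESIDUES: frozenset[str] = frozenset(MAX_ASA_GXG)


def is_hbond_donor(residue_name: str, atom_name: str) -> bool:
    res, atom = residue_name.upper(), atom_name.upper()
    if atom == BACKBONE_DONOR and res != "PRO":
        return True
    return atom in HBOND_DONORS.get(res, frozenset())


def is_hbond_acceptor(residue_name: str, atom_name: str) -> bool:
    res, atom = residue_name.upper(), atom_name.upper()
    if atom in (BACKBONE_ACCEPTOR, "OXT"):
        return True
    return atom in HBOND_ACCEPTORS.get(res, frozenset())
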