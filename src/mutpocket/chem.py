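"""Chemical reference data: amino-acid codes, van der Waals radii, residue volumes.

All tables cover the 20 standard proteinogenic amino acids by their
three-letter codes (upper case). Radii are Bondi-type values in Angstrom;
residue volumes are Zamyatnin (1972) mean residue volumes in cubic Angstrom.
"""

from __future__ import annotations

# The 20 standard amino acids, three-letter codes.
STANDARD_AA: frozenset[str] = frozenset(
    {
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
        "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    }
)

# Backbone heavy-atom names; everything else heavy in a residue is side chain
# (CB included, terminal OXT excluded from both the backbone set and the
# side chain).
BACKBONE_ATOMS: frozenset[str] = frozenset({"N", "CA", "C", "O"})
NON_SIDECHAIN_ATOMS: frozenset[str] = BACKBONE_ATOMS | {"OXT"}

# van der Waals radii (Angstrom) used for the occupancy model of the protein
# body. Elements not listed fall back to DEFAULT_VDW_RADIUS.
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "SE": 1.90,
}
DEFAULT_VDW_RADIUS: float = 1.70

# Zamyatnin (1972) amino-acid residue volumes, cubic Angstrom.
ZAMYATNIN_VOLUMES: dict[str, float] = {
    "ALA": 88.6,
    "ARG": 173.4,
    "ASN": 114.1,
    "ASP": 111.1,
    "CYS": 108.5,
    "GLN": 143.8,
    "GLU": 138.4,
    "GLY": 60.1,
    "HIS": 153.2,
    "ILE": 166.7,
    "LEU": 166.7,
    "LYS": 168.6,
    "MET": 162.9,
    "PHE": 189.9,
    "PRO": 112.7,
    "SER": 89.0,
    "THR": 116.1,
    "TRP": 227.8,
    "TYR": 193.6,
    "VAL": 140.0,
}

# Canonical heavy-atom counts per residue (backbone N, CA, C, O included;
# no OXT, no hydrogens). Used for sanity checks on parsed structures.
HEAVY_ATOM_COUNTS: dict[str, int] = {
    "GLY": 4, "ALA": 5, "SER": 6, "CYS": 6, "VAL": 7, "THR": 7, "PRO": 7,
    "LEU": 8, "ILE": 8, "ASN": 8, "ASP": 8, "MET": 8, "GLN": 9, "GLU": 9,
    "LYS": 9, "HIS": 10, "ARG": 11, "PHE": 11, "TYR": 12, "TRP": 14,
}


def vdw_radius(element: str, radii: dict[str, float] | None = None) -> float:
    """Van der Waals radius for an element symbol (case-insensitive)."""
    table = VDW_RADII if radii is None else radii
    return table.get(element.upper(), DEFAULT_VDW_RADIUS)


def normalize_aa(code: str) -> str:
    """Validate and upper-case a three-letter amino-acid code."""
    aa = code.strip().upper()
    if aa not in STANDARD_AA:
        raise ValueError(f"unknown amino-acid code {code!r}")
    return aa
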