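"""Static chemical reference data.

Element tables (Bondi van der Waals radii, standard atomic weights),
amino-acid code translation, backbone/side-chain membership, and the
donor/acceptor/charge capability tables used by the interaction
detectors and the triage capability rule.
"""

from __future__ import annotations

# Bondi van der Waals radii, Angstrom.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
}

DEFAULT_VDW_RADIUS = 1.70  # fallback when an element is missing from the table

# Standard atomic weights, g/mol.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "F": 18.998,
    "CL": 35.45,
    "BR": 79.904,
    "I": 126.904,
    "SE": 78.971,
}

DEFAULT_ATOMIC_MASS = 12.011

AA3_TO_AA1: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

AA1_TO_AA3: dict[str, str] = {v: k for k, v in AA3_TO_AA1.items()}

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

# Residues with apolar side chains, used for hydrophobic-cluster detection.
HYDROPHOBIC_AA1 = frozenset("AVLIMFWPY")

# Side-chain N/O atoms able to donate a hydrogen bond, per residue type.
SIDECHAIN_DONORS: dict[str, frozenset[str]] = {
    "SER": frozenset({"OG"}),
    "THR": frozenset({"OG1"}),
    "TYR": frozenset({"OH"}),
    "ASN": frozenset({"ND2"}),
    "GLN": frozenset({"NE2"}),
    "LYS": frozenset({"NZ"}),
    "ARG": frozenset({"NE", "NH1", "NH2"}),
    "HIS": frozenset({"ND1", "NE2"}),
    "TRP": frozenset({"NE1"}),
}

# Side-chain N/O atoms able to accept a hydrogen bond.
SIDECHAIN_ACCEPTORS: dict[str, frozenset[str]] = {
    "SER": frozenset({"OG"}),
    "THR": frozenset({"OG1"}),
    "TYR": frozenset({"OH"}),
    "ASN": frozenset({"OD1"}),
    "GLN": frozenset({"OE1"}),
    "ASP": frozenset({"OD1", "OD2"}),
    "GLU": frozenset({"OE1", "OE2"}),
    "HIS": frozenset({"ND1", "NE2"}),
}

# Side-chain atoms carrying formal positive charge at neutral pH (His
# included: it can form salt bridges when protonated).
BASIC_ATOMS: dict[str, frozenset[str]] = {
    "LYS": frozenset({"NZ"}),
    "ARG": frozenset({"NE", "NH1", "NH2"}),
    "HIS": frozenset({"ND1", "NE2"}),
}

# Side-chain carboxylate oxygens.
ACIDIC_ATOMS: dict[str, frozenset[str]] = {
    "ASP": frozenset({"OD1", "OD2"}),
    "GLU": frozenset({"OE1", "OE2"}),
}

# Residue-level capabilities (one-letter), for the triage capability rule:
# can the substituted side chain in principle sustain a given interaction?
AA_SIDECHAIN_DONOR = frozenset("STYNQKRHWC")
AA_SIDECHAIN_ACCEPTOR = frozenset("STYNQDEH")
AA_POSITIVE = frozenset("KRH")
AA_NEGATIVE = frozenset("DE")


def element_radius(element: str, fallback: float | None = None) -> float:
    """Bondi vdW radius in Angstrom; ``fallback`` (or the package default)
    when the element is not tabulated."""
    r = VDW_RADII.get(element.upper())
    if r is None:
        return DEFAULT_VDW_RADIUS if fallback is None else fallback
    return r


def element_mass(element: str) -> float:
    return ATOMIC_MASSES.get(element.upper(), DEFAULT_ATOMIC_MASS)
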