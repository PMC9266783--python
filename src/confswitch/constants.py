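"""Amino-acid tables shared across modules."""

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
STANDARD_AA3 = frozenset(THREE_TO_ONE)
STANDARD_AA1 = frozenset(THREE_TO_ONE.values())

# Side-chain heavy-atom counts (CB and beyond).
SIDE_CHAIN_HEAVY = {
    "G": 0, "A": 1, "S": 2, "C": 2, "T": 3, "V": 3, "P": 3,
    "D": 4, "N": 4, "I": 4, "L": 4, "M": 4, "E": 5, "Q": 5,
    "K": 5, "H": 6, "F": 7, "R": 7, "Y": 8, "W": 10,
}

# "Small" side chains eligible for trp substitution (<= 3 heavy atoms,
# proline excluded because its backbone ring cannot be swapped cleanly).
SMALL_AA = frozenset("GASCVT")
# One-time widening of the small set (<= 4 heavy atoms).
SMALL_AA_WIDE = SMALL_AA | frozenset("NDIL")

# Residues counted as hydrophobic when locating the membrane belt.
HYDROPHOBIC_AA3 = frozenset(
    {"ALA", "CYS", "PHE", "ILE", "LEU", "MET", "VAL", "TRP", "TYR"}
)

# Per-element van der Waals radii (Å) for the clash term.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}

BACKBONE_ATOMS = ("N", "CA", "C", "O")
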