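"""Shared residue-level reference data.

Three-letter/one-letter residue codes, a synonym table for common
modified residues, heavy-atom van der Waals radii (Chothia-style values
used for solvent-accessibility calculations), and the side-chain
hydrogen-bond donor/acceptor dictionary for the 20 standard residues.
"""

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}
STANDARD_AA = "ARNDCQEGHILKMFPSTWYV"

# MODRES-style synonyms: modified residue -> standard parent (one-letter).
RESIDUE_SYNONYMS = {
    "MSE": "M",  # selenomethionine
    "SEC": "C",  # selenocysteine mapped to Cys for sequence purposes
    "PYL": "K",
    "SEP": "S",  # phosphoserine
    "TPO": "T",  # phosphothreonine
    "PTR": "Y",  # phosphotyrosine
    "CSO": "C",
    "HYP": "P",
    "MLY": "K",
    "KCX": "K",
}

# Heavy-atom radii (Angstrom), Chothia-style grouping by element.
VDW_RADII = {
    "C": 1.87,
    "N": 1.65,
    "O": 1.40,
    "S": 1.85,
    "SE": 1.90,
    "P": 1.90,
}

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

# Side-chain hydrogen-bond capable atoms per residue type.
# Ser/Thr/Tyr hydroxyls and His ring nitrogens are ambivalent
# (donor and acceptor); Cys SG likewise.  Met SD accepts only.
SIDECHAIN_DONORS = {
    "R": {"NE", "NH1", "NH2"},
    "N": {"ND2"},
    "Q": {"NE2"},
    "H": {"ND1", "NE2"},
    "K": {"NZ"},
    "S": {"OG"},
    "T": {"OG1"},
    "W": {"NE1"},
    "Y": {"OH"},
    "C": {"SG"},
}
SIDECHAIN_ACCEPTORS = {
    "D": {"OD1", "OD2"},
    "E": {"OE1", "OE2"},
    "N": {"OD1"},
    "Q": {"OE1"},
    "H": {"ND1", "NE2"},
    "S": {"OG"},
    "T": {"OG1"},
    "Y": {"OH"},
    "C": {"SG"},
    "M": {"SD"},
}

SULPHUR_ATOMS = {"SG", "SD", "SE"}


def element_of(atom_name: str) -> str:
    """Infer the element from a PDB heavy-atom name ('OG1' -> 'O')."""
    name = atom_name.strip()
    if name.upper().startswith("SE"):
        return "SE"
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {atom_name!r}")
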