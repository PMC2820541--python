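"""Internal-coordinate peptide construction.

Builds polypeptide heavy-atom models from backbone torsions and
single-rotamer side-chain templates. Geometry is idealized (fixed bond
lengths and angles, trans peptide bonds); the goal is correct topology,
chirality and rough packing, not energy-minimized realism.
"""

from __future__ import annotations

import math

import numpy as np

from varstruct.constants import AA1_TO_3

# Backbone ideal internal coordinates (Angstrom, degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
OMEGA = 180.0


def dihedral(p0, p1, p2, p3) -> float:
    """Torsion angle p0-p1-p2-p3 in degrees, range (-180, 180]."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1 /= np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = float(np.dot(v, w))
    y = float(np.dot(np.cross(b1, v), w))
    ang = math.degrees(math.atan2(y, x))
    return 180.0 if ang == -180.0 else ang


def place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """NeRF placement: position X with |cX|=bond, angle(b,c,X)=angle,
    dihedral(a,b,c,X)=torsion (degrees)."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    ang = math.radians(angle)
    tor = math.radians(torsion)
    d = np.array([
        -bond * math.cos(ang),
        bond * math.sin(ang) * math.cos(tor),
        bond * math.sin(ang) * math.sin(tor),
    ])
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    rot = np.column_stack([bc, m, n])
    return c + rot @ d


# Side-chain templates: atom -> (ref1, ref2, ref3, bond, angle, torsion).
# refs name previously placed atoms of the same residue; torsions encode a
# single common rotamer per residue type.  CB is placed for every non-Gly
# residue with the L-configuration improper (C, N, CA) frame.
_CB = ("C", "N", "CA", 1.530, 110.5, -122.6)  # L-configuration improper

SIDECHAIN_TEMPLATES: dict[str, list[tuple]] = {
    "G": [],
    "A": [("CB", *_CB)],
    "S": [("CB", *_CB), ("OG", "N", "CA", "CB", 1.417, 110.8, -65.0)],
    "C": [("CB", *_CB), ("SG", "N", "CA", "CB", 1.808, 114.4, -65.0)],
    "T": [("CB", *_CB),
          ("OG1", "N", "CA", "CB", 1.433, 109.6, -60.0),
          ("CG2", "N", "CA", "CB", 1.521, 110.5, 60.0)],
    "V": [("CB", *_CB),
          ("CG1", "N", "CA", "CB", 1.521, 110.5, 175.0),
          ("CG2", "N", "CA", "CB", 1.521, 110.5, -65.0)],
    "L": [("CB", *_CB),
          ("CG", "N", "CA", "CB", 1.530, 116.3, -65.0),
          ("CD1", "CA", "CB", "CG", 1.521, 110.7, 175.0),
          ("CD2", "CA", "CB", "CG", 1.521, 110.7, -65.0)],
    "I": [("CB", *_CB),
          ("CG1", "N", "CA", "CB", 1.530, 110.4, -65.0),
          ("CG2", "N", "CA", "CB", 1.521, 110.5, 175.0),
          ("CD1", "CA", "CB", "CG1", 1.513, 113.9, 170.0)],
    "M": [("CB", *_CB),
          ("CG", "N", "CA", "CB", 1.530, 114.1, -65.0),
          ("SD", "CA", "CB", "CG", 1.803, 112.7, 180.0),
          ("CE", "CB", "CG", "SD", 1.791, 100.9, -70.0)],
    "F": [("CB", *_CB),
          ("CG", "N", "CA", "CB", 1.530, 113.8, -65.0),
          ("CD1", "CA", "CB", "CG", 1.391, 120.8, 80.0),
          ("CD2", "CA", "CB", "CG", 1.391, 120.8, -100.0),
          ("CE1", "CB", "CG", "CD1", 1.393, 121.0, 180.0),
          ("CE2", "CB", "CG", "CD2", 1.393, 121.0, 180.0),
          ("CZ", "CG", "CD1", "CE1", 1.390, 120.0, 0.0)],
    "Y": [("CB", *_CB),
          ("CG", "N", "CA", "CB", 1.530, 113.8, -65.0),
          ("CD1", "CA", "CB", "CG", 1.391, 120.8, 80.0),
          ("CD2", "CA", "CB", "CG", 1.391, 120.8, -100.0),
          ("CE1", "CB", "CG", "CD1", 1.393, 121.0, 180.0),
          ("CE2", "CB", "CG", "CD2", 1.393, 121.0, 180.0),
          ("CZ", "CG", "CD1", "CE1", 1.390, 120.0, 0.0),
          ("OH", "CD1", "CE1", "CZ", 1.380, 120.0, 180.0)],
    "W": [("CB", *_CB),
          ("CG", "N", "CA", "CB", 1.498, 113.6, -65.0),
          ("CD1", "CA", "CB", "CG", 1.365, 126.9, 90.0),
          ("CD2", "CA", "CB", "CG", 1.433, 126.7, -90.0),
          ("NE1", "CB", "CG", "CD1", 1.374, 110.2, 180.0),
          ("CE2", "CB", "CG", "CD2", 1.409, 107.2, 180.0),
          ("CE3", "CB", "CG", "CD2", 1.398, 133.9, 0.0),
          ("CZ2", "CG", "CD2", "CE2", 1.398, 122.4, 180.0),
          ("CZ3", "CG", "CD2", "CE3", 1.382, 118.6, 180.0),
          ("CH2", "CD2", "CE3", "CZ3", 1.400, 121.1, 0.0)],
    "D": [("CB", *_CB),
          ("CG", "N", "CA", "CB", 1.516, 113.0, -70.0),
          ("OD1", "CA", "CB", "CG", 1.249, 117.2, -15.0),
          ("OD2", "CA", "CB", "CG", 1.249, 117.2, 165.0)],
    "N": [("CB", *_CB),
          ("CG", "N", "CA", "CB", 1.516, 113.0, -70.0),
          ("OD1", "CA", "CB", "CG", 1.231, 120.8, -60.0),
          ("ND2", "CA", "CB", "CG", 1.328, 116.4, 120.0)],
    "E": [("CB", *_CB),
          ("CG", "N", "CA", "CB", 1.530, 114.1, -65.0),
          ("CD", "CA", "CB", "CG", 1.516, 112.6, 180.0),
          ("OE1", "CB", "CG", "CD", 1.249, 117.2, -10.0),
          ("OE2", "CB", "CG", "CD", 1.249, 117.2, 170.0)],
    "Q": [("CB", *_CB),
          ("CG", "N", "CA", "CB", 1.530, 114.1, -65.0),
          ("CD", "CA", "CB", "CG", 1.516, 112.6, 180.0),
          ("OE1", "CB", "CG", "CD", 1.231, 120.8, -10.0),
          ("NE2", "CB", "CG", "CD", 1.328, 116.4, 170.0)],
    "K": [("CB", *_CB),
          ("CG", "N", "CA", "CB", 1.530, 114.1, -65.0),
          ("CD", "CA", "CB", "CG", 1.520, 111.3, 180.0),
          ("CE", "CB", "CG", "CD", 1.520, 111.3, 180.0),
          ("NZ", "CG", "CD", "CE", 1.489, 111.9, 180.0)],
    "R": [("CB", *_CB),
          ("CG", "N", "CA", "CB", 1.530, 114.1, -65.0),
          ("CD", "CA", "CB", "CG", 1.520, 111.3, 180.0),
          ("NE", "CB", "CG", "CD", 1.461, 112.0, 180.0),
          ("CZ", "CG", "CD", "NE", 1.329, 124.2, 180.0),
          ("NH1", "CD", "NE", "CZ", 1.326, 120.0, 0.0),
          ("NH2", "CD", "NE", "CZ", 1.326, 120.0, 180.0)],
    "H": [("CB", *_CB),
          ("CG", "N", "CA", "CB", 1.497, 113.8, -65.0),
          ("ND1", "CA", "CB", "CG", 1.378, 122.7, -75.0),
          ("CD2", "CA", "CB", "CG", 1.354, 131.0, 105.0),
          ("CE1", "CB", "CG", "ND1", 1.321, 109.3, 180.0),
          ("NE2", "CB", "CG", "CD2", 1.374, 107.2, 180.0)],
    "P": [("CB", *_CB),
          ("CG", "N", "CA", "CB", 1.492, 104.5, 25.0),
          ("CD", "CA", "CB", "CG", 1.503, 106.1, -35.0)],
}


def build_peptide(sequence: str, phipsi: list[tuple[float, float]],
                  origin=(0.0, 0.0, 0.0)) -> list[dict]:
    """Build an all-heavy-atom peptide from per-residue (phi, psi).

    phi of the first residue is ignored (undefined); psi of the last residue
    only orients its carbonyl oxygen. Returns one dict per residue:
    {"aa", "name3", "atoms": {name: ndarray(3)}}.
    """
    n = len(sequence)
    if n != len(phipsi):
        raise ValueError("sequence and torsion list lengths differ")
    for aa in sequence:
        if aa not in SIDECHAIN_TEMPLATES:
            raise ValueError(f"unknown residue {aa!r}")
    residues: list[dict] = []
    origin = np.asarray(origin, dtype=float)
    # first residue backbone in a canonical local frame
    N = origin + np.array([0.0, 0.0, 0.0])
    CA = origin + np.array([BOND_N_CA, 0.0, 0.0])
    ang = math.radians(ANGLE_N_CA_C)
    C = CA + BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    atoms = {"N": N, "CA": CA, "C": C}
    residues.append({"aa": sequence[0], "name3": AA1_TO_3[sequence[0]], "atoms": atoms})
    for i in range(1, n):
        prev = residues[-1]["atoms"]
        psi_prev = phipsi[i - 1][1]
        Nn = place_atom(prev["N"], prev["CA"], prev["C"],
                        BOND_C_N, ANGLE_CA_C_N, psi_prev)
        CAn = place_atom(prev["CA"], prev["C"], Nn,
                         BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        Cn = place_atom(prev["C"], Nn, CAn,
                        BOND_CA_C, ANGLE_N_CA_C, phipsi[i][0])
        # carbonyl O of the previous residue, anti to the new amide N
        prev["O"] = place_atom(Nn, prev["CA"], prev["C"],
                               BOND_C_O, ANGLE_CA_C_O, 180.0)
        residues.append({"aa": sequence[i], "name3": AA1_TO_3[sequence[i]],
                         "atoms": {"N": Nn, "CA": CAn, "C": Cn}})
    # last residue's O oriented by its own psi
    last = residues[-1]["atoms"]
    last["O"] = place_atom(last["N"], last["CA"], last["C"],
                           BOND_C_O, ANGLE_CA_C_O, phipsi[-1][1] + 180.0)
    for res in residues:
        for entry in SIDECHAIN_TEMPLATES[res["aa"]]:
            name, r1, r2, r3, bond, angle, torsion = entry
            res["atoms"][name] = place_atom(
                res["atoms"][r1], res["atoms"][r2], res["atoms"][r3],
                bond, angle, torsion)
    return residues
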