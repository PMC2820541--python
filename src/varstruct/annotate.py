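"""Per-residue structural environment annotation.

A residue's local structural environment combines three features:

* secondary-structure class from backbone torsions — alpha-helix (H),
  beta-strand (E), coil (C), or positive-phi (P, a strained conformation
  mostly tolerated by Gly/Asn/Asp);
* side-chain solvent burial — relative side-chain accessibility below the
  7.0% cutoff marks a residue inaccessible;
* side-chain hydrogen bonding — three independent flags for bonds from the
  side chain to a main-chain amide (NH), to a main-chain carbonyl (CO),
  and to another side chain (SC).

4 x 2 x 8 = 64 distinct environment classes, encoded bijectively in an
integer 0-63.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from varstruct.constants import (
    SIDECHAIN_ACCEPTORS,
    SIDECHAIN_DONORS,
    SULPHUR_ATOMS,
)
from varstruct.geometry import dihedral
from varstruct.pdbio import Residue
from varstruct.sasa import relative_sidechain_accessibility, structure_sasa

log = logging.getLogger(__name__)

SS_CLASSES = "HECP"


@dataclass
class AnnotationConfig:
    """Thresholds for environment annotation.

    acc_cutoff_pct: relative side-chain accessibility separating accessible
        (>= cutoff) from inaccessible residues, in percent.
    hb_dist / hb_dist_sulphur: donor-acceptor distance cutoffs (Angstrom);
        the sulphur cutoff applies when either atom is a sulphur/selenium.
    peptide_bond_max: C(i)-N(i+1) distance above which a chain break is
        declared and flanking torsions are undefined.
    helix/strand windows and minimum run lengths define the torsion-region
    secondary-structure rules; positive phi always wins (class P).
    """

    acc_cutoff_pct: float = 7.0
    hb_dist: float = 3.5
    hb_dist_sulphur: float = 4.0
    probe_radius: float = 1.4
    sphere_points: int = 960
    peptide_bond_max: float = 2.5
    helix_phi: tuple = (-100.0, -30.0)
    helix_psi: tuple = (-80.0, -5.0)
    helix_min_run: int = 4
    strand_phi: tuple = (-180.0, -45.0)
    strand_psi: tuple = (45.0, 180.0)
    strand_min_run: int = 3
    accessible_at_cutoff: bool = True   # value == cutoff counts as accessible
    require_hb_chemistry: bool = True   # donor/acceptor role compatibility

    def __post_init__(self):
        for name in ("acc_cutoff_pct", "hb_dist", "hb_dist_sulphur",
                     "probe_radius", "peptide_bond_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.hb_dist_sulphur < self.hb_dist:
            raise ValueError("sulphur cutoff must be >= standard cutoff")


@dataclass
class StructuralEnvironment:
    """The (ss, burial, H-bond) feature tuple and its 0-63 code."""

    ss: str
    accessible: bool
    hb_nh: bool
    hb_co: bool
    hb_sc: bool
    code: int = field(init=False)

    def __post_init__(self):
        self.code = classify_environment(self.ss, self.accessible,
                                         self.hb_nh, self.hb_co, self.hb_sc)


def classify_environment(ss: str, accessible: bool, hb_nh: bool,
                         hb_co: bool, hb_sc: bool) -> int:
    """Bijective environment code: ss index * 16 + burial bit * 8 + HB bits."""
    if ss not in SS_CLASSES:
        raise ValueError(f"unknown secondary-structure class {ss!r}")
    return (SS_CLASSES.index(ss) * 16 + int(bool(accessible)) * 8
            + int(bool(hb_nh)) * 4 + int(bool(hb_co)) * 2 + int(bool(hb_sc)))


def env_decode(code: int) -> tuple[str, bool, bool, bool, bool]:
    """Inverse of :func:`classify_environment`."""
    if not 0 <= code <= 63:
        raise ValueError("environment code out of range")
    ss = SS_CLASSES[code // 16]
    rem = code % 16
    return (ss, bool(rem & 8), bool(rem & 4), bool(rem & 2), bool(rem & 1))


def backbone_torsions(residues: list[Residue],
                      config: AnnotationConfig | None = None):
    """Per-residue (phi, psi) in degrees; None at termini and chain breaks."""
    config = config or AnnotationConfig()
    n = len(residues)
    bonded = []  # bonded[i]: residue i peptide-bonded to residue i+1
    for i in range(n - 1):
        a, b = residues[i], residues[i + 1]
        ok = ("C" in a.atoms and "N" in b.atoms and
              np.linalg.norm(a.atoms["C"] - b.atoms["N"])
              <= config.peptide_bond_max)
        bonded.append(ok)
    out = []
    for i, res in enumerate(residues):
        phi = psi = None
        have_bb = all(a in res.atoms for a in ("N", "CA", "C"))
        if have_bb and i > 0 and bonded[i - 1]:
            prev = residues[i - 1]
            if "C" in prev.atoms:
                phi = dihedral(prev.atoms["C"], res.atoms["N"],
                               res.atoms["CA"], res.atoms["C"])
        if have_bb and i < n - 1 and bonded[i]:
            nxt = residues[i + 1]
            if "N" in nxt.atoms:
                psi = dihedral(res.atoms["N"], res.atoms["CA"],
                               res.atoms["C"], nxt.atoms["N"])
        out.append((phi, psi))
    return out


def _in_window(value, window) -> bool:
    lo, hi = window
    return value is not None and lo < value <= hi


def assign_secondary_structure(torsions, config: AnnotationConfig | None = None
                               ) -> list[str]:
    """Secondary-structure class per residue from (phi, psi) lists.

    P wins whenever phi > 0; helix/strand require torsion-window membership
    in runs of at least the configured length; everything else is coil,
    including residues with undefined phi and psi.
    """
    config = config or AnnotationConfig()
    n = len(torsions)
    ss = ["C"] * n
    helix = [(_in_window(phi, config.helix_phi)
              and _in_window(psi, config.helix_psi)) for phi, psi in torsions]
    strand = [(_in_window(phi, config.strand_phi)
               and _in_window(psi, config.strand_psi)) for phi, psi in torsions]

    def mark_runs(member, label, min_run):
        i = 0
        while i < n:
            if member[i]:
                j = i
                while j < n and member[j]:
                    j += 1
                if j - i >= min_run:
                    for k in range(i, j):
                        ss[k] = label
                i = j
            else:
                i += 1

    mark_runs(strand, "E", config.strand_min_run)
    mark_runs(helix, "H", config.helix_min_run)
    for i, (phi, _psi) in enumerate(torsions):
        if phi is not None and phi > 0:
            ss[i] = "P"
    return ss


def sidechain_hbonds(residues_by_chain: dict,
                     config: AnnotationConfig | None = None) -> dict:
    """Per-residue (hb_nh, hb_co, hb_sc) flags over all chains jointly.

    A hydrogen bond is a donor-acceptor heavy-atom pair within the distance
    cutoff (sulphur-involving pairs use the longer cutoff); no angle term
    and no explicit hydrogens, and same-residue pairs are excluded while
    sequence neighbours are allowed. With ``require_hb_chemistry`` the pair
    must consist of one donor and one acceptor; without it any two
    hydrogen-bond-capable atoms within the cutoff count.
    """
    config = config or AnnotationConfig()
    entries = []  # (residue key, atom name, xyz, kind flags, residue id)
    for cid, residues in residues_by_chain.items():
        for res in residues:
            donors = SIDECHAIN_DONORS.get(res.aa, set())
            acceptors = SIDECHAIN_ACCEPTORS.get(res.aa, set())
            for name, xyz in res.atoms.items():
                is_bb_n = name == "N" and res.aa != "P"
                is_bb_o = name in ("O", "OXT")
                sc_d = name in donors
                sc_a = name in acceptors
                if not (is_bb_n or is_bb_o or sc_d or sc_a):
                    continue
                entries.append({
                    "res": res.key, "atom": name, "xyz": xyz,
                    "bb_donor": is_bb_n, "bb_acceptor": is_bb_o,
                    "sc_donor": sc_d, "sc_acceptor": sc_a,
                    "sulphur": name in SULPHUR_ATOMS,
                })
    flags = {res.key: {"hb_nh": False, "hb_co": False, "hb_sc": False}
             for residues in residues_by_chain.values() for res in residues}
    if not entries:
        return flags
    xyz = np.array([e["xyz"] for e in entries])
    diff = xyz[:, None, :] - xyz[None, :, :]
    dist = np.sqrt((diff ** 2).sum(-1))
    m = len(entries)
    for i in range(m):
        ei = entries[i]
        if not (ei["sc_donor"] or ei["sc_acceptor"]):
            continue
        for j in range(m):
            if i == j:
                continue
            ej = entries[j]
            if ei["res"] == ej["res"]:
                continue
            cutoff = (config.hb_dist_sulphur
                      if ei["sulphur"] or ej["sulphur"] else config.hb_dist)
            # <= cutoff, with a tolerance for float representation of ties
            if dist[i, j] > cutoff + 1e-9:
                continue
            chem = config.require_hb_chemistry
            # side chain (i) -> main-chain amide of j
            if ej["bb_donor"] and (ei["sc_acceptor"] or not chem):
                flags[ei["res"]]["hb_nh"] = True
            # side chain (i) -> main-chain carbonyl of j
            if ej["bb_acceptor"] and (ei["sc_donor"] or not chem):
                flags[ei["res"]]["hb_co"] = True
            # side chain - side chain
            if ej["sc_donor"] or ej["sc_acceptor"]:
                compatible = ((ei["sc_donor"] and ej["sc_acceptor"])
                              or (ei["sc_acceptor"] and ej["sc_donor"]))
                if compatible or not chem:
                    flags[ei["res"]]["hb_sc"] = True
    return flags


def annotate_structure(residues_by_chain: dict,
                       config: AnnotationConfig | None = None) -> dict:
    """Full per-residue environment annotation for a structure.

    Returns {(chain, resnumber): record} with phi/psi, ss, rel_acc,
    accessible, H-bond flags, the environment object and code. Residues
    whose accessibility is undefined (no side-chain atoms) get env=None and
    are excluded from environment-stratified statistics downstream.
    """
    config = config or AnnotationConfig()
    atom_areas = structure_sasa(residues_by_chain, config.probe_radius,
                                config.sphere_points)
    hb = sidechain_hbonds(residues_by_chain, config)
    out: dict = {}
    for cid, residues in residues_by_chain.items():
        torsions = backbone_torsions(residues, config)
        ss = assign_secondary_structure(torsions, config)
        for res, (phi, psi), s in zip(residues, torsions, ss):
            rel = relative_sidechain_accessibility(
                res, atom_areas, config.probe_radius, config.sphere_points)
            if rel is None:
                accessible = None
                env = None
                log.info("residue %s %s: accessibility undefined; excluded "
                         "from environment statistics", cid, res.number)
            else:
                if config.accessible_at_cutoff:
                    accessible = rel >= config.acc_cutoff_pct
                else:
                    accessible = rel > config.acc_cutoff_pct
                env = StructuralEnvironment(s, accessible, **hb[res.key])
            out[res.key] = {
                "chain": cid, "number": res.number, "aa": res.aa,
                "phi": phi, "psi": psi, "ss": s, "rel_acc": rel,
                "accessible": accessible, **hb[res.key],
                "env": env, "env_code": env.code if env else None,
            }
    return out


def annotation_table(annotation: dict):
    """Annotation dict -> tidy pandas DataFrame (one row per residue)."""
    import pandas as pd

    rows = []
    for (chain, number), rec in annotation.items():
        row = {k: v for k, v in rec.items() if k != "env"}
        rows.append(row)
    return pd.DataFrame(rows)
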