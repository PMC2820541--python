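"""Solvent-accessible surface area and relative side-chain accessibility.

SASA uses the Shrake-Rupley method: each atom's solvent-exposed sphere
(vdW radius + probe) is sampled with a deterministic golden-spiral point
set and points are counted as accessible when outside every neighbour's
expanded sphere. Relative side-chain accessibility normalizes a residue's
side-chain area by the area of the same residue type in an ideal extended
Gly-X-Gly tripeptide computed with identical parameters, so the 0-100%
scale is self-consistent by construction.
"""

from __future__ import annotations

import logging
import math
from functools import lru_cache

import numpy as np

from varstruct.constants import BACKBONE_ATOMS, VDW_RADII, element_of

log = logging.getLogger(__name__)


@lru_cache(maxsize=8)
def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (golden spiral)."""
    i = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def atom_radius(atom_name: str, strict: bool = False) -> float | None:
    """vdW radius for a heavy atom name; None (or raise) when unknown."""
    try:
        elem = element_of(atom_name)
    except ValueError:
        elem = None
    radius = VDW_RADII.get(elem) if elem else None
    if radius is None and strict:
        raise ValueError(f"no radius for atom {atom_name!r}")
    return radius


def shrake_rupley(coords: np.ndarray, radii: np.ndarray,
                  probe_radius: float = 1.4, n_points: int = 960) -> np.ndarray:
    """Per-atom solvent-accessible surface areas (A^2)."""
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = len(coords)
    if n == 0:
        return np.zeros(0)
    pts = sphere_points(n_points)
    expanded = radii + probe_radius
    areas = np.zeros(n)
    # neighbour lists via a single pairwise distance matrix
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff ** 2).sum(-1))
    for i in range(n):
        cutoff = expanded[i] + expanded
        nbr = np.where((dist[i] < cutoff) & (np.arange(n) != i))[0]
        surface = coords[i] + expanded[i] * pts
        if len(nbr):
            d2 = ((surface[:, None, :] - coords[nbr][None, :, :]) ** 2).sum(-1)
            buried = (d2 < (expanded[nbr] ** 2)[None, :]).any(axis=1)
            n_acc = int((~buried).sum())
        else:
            n_acc = n_points
        areas[i] = 4.0 * math.pi * expanded[i] ** 2 * n_acc / n_points
    return areas


def structure_sasa(residues_by_chain: dict, probe_radius: float = 1.4,
                   n_points: int = 960, unknown_atom: str = "skip") -> dict:
    """Per-atom SASA for a whole structure.

    Returns {(chain, resnumber): {atom_name: area}}. Atoms without a known
    radius are skipped (logged) or fatal depending on ``unknown_atom``.
    """
    coords, radii, owners = [], [], []
    for cid, residues in residues_by_chain.items():
        for res in residues:
            for name, xyz in res.atoms.items():
                r = atom_radius(name, strict=(unknown_atom == "fatal"))
                if r is None:
                    log.info("no radius for atom %s in %s %s; skipped",
                             name, cid, res.number)
                    continue
                coords.append(xyz)
                radii.append(r)
                owners.append((res.key, name))
    areas = shrake_rupley(np.array(coords), np.array(radii),
                          probe_radius, n_points)
    out: dict = {}
    for (key, name), area in zip(owners, areas):
        out.setdefault(key, {})[name] = float(area)
    return out


def sidechain_atoms(res) -> list[str]:
    """Side-chain heavy atoms of a residue; Gly's 'side chain' is its CA."""
    side = [a for a in res.atoms if a not in BACKBONE_ATOMS]
    if not side and res.aa == "G" and "CA" in res.atoms:
        side = ["CA"]
    return side


@lru_cache(maxsize=None)
def _gxg_reference_area(aa: str, probe_radius: float, n_points: int,
                        phi: float, psi: float) -> float:
    """Side-chain SASA of residue type ``aa`` in an extended G-X-G tripeptide."""
    from varstruct.geometry import build_peptide
    from varstruct.pdbio import Residue
    from varstruct.constants import AA1_TO_3

    built = build_peptide("G" + aa + "G", [(phi, psi)] * 3)
    residues = [Residue("A", str(i + 1), r["aa"], AA1_TO_3[r["aa"]], r["atoms"])
                for i, r in enumerate(built)]
    areas = structure_sasa({"A": residues}, probe_radius, n_points)
    centre = residues[1]
    per_atom = areas[centre.key]
    return sum(per_atom.get(a, 0.0) for a in sidechain_atoms(centre))


def relative_sidechain_accessibility(res, atom_areas: dict,
                                     probe_radius: float = 1.4,
                                     n_points: int = 960,
                                     ref_phi: float = -139.0,
                                     ref_psi: float = 135.0) -> float | None:
    """Side-chain SASA as % of the Gly-X-Gly extended reference.

    Returns None when the residue has no resolved side-chain atoms with
    computed areas (such residues are excluded from accessibility-stratified
    statistics).
    """
    side = sidechain_atoms(res)
    per_atom = atom_areas.get(res.key, {})
    present = [a for a in side if a in per_atom]
    if not present:
        return None
    area = sum(per_atom[a] for a in present)
    ref = _gxg_reference_area(res.aa, probe_radius, n_points, ref_phi, ref_psi)
    if ref <= 0:
        return None
    return 100.0 * area / ref
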