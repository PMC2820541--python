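"""PDB reading/writing and SEQATM extraction.

Reading goes through gemmi (ATOM/HETATM/SEQRES, alternate locations,
insertion codes); writing is a minimal fixed-width emitter sufficient for
the idealized structures this package generates (ATOM + SEQRES + TER).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from varstruct.constants import AA3_TO_1, AA1_TO_3, RESIDUE_SYNONYMS, element_of

log = logging.getLogger(__name__)


@dataclass
class Residue:
    """One polymer residue: identity plus named heavy-atom coordinates."""

    chain: str
    number: str          # author residue number + insertion code
    aa: str              # one-letter code (synonyms already mapped)
    name3: str
    atoms: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def key(self) -> tuple[str, str]:
        return (self.chain, self.number)

    def coord(self, atom: str) -> np.ndarray:
        return self.atoms[atom]


def _one_letter(name3: str) -> str | None:
    if name3 in AA3_TO_1:
        return AA3_TO_1[name3]
    return RESIDUE_SYNONYMS.get(name3)


def read_structure_residues(path, chains=None, keep_nonstandard=True):
    """Parse a PDB file into per-chain residue lists.

    Alternate locations are resolved to the highest-occupancy conformer;
    hydrogens are dropped; modified residues are mapped to their standard
    parent via the synonym table (unmapped residue types are skipped with a
    log notice). Returns ``(residues_by_chain, seqres_by_chain)`` where
    seqres is a one-letter string (empty when the file has no SEQRES).
    """
    st = gemmi.read_structure(str(Path(path)))
    st.remove_hydrogens()
    seqres_by_chain: dict[str, str] = {}
    for ent in st.entities:
        if not ent.full_sequence:
            continue
        letters = "".join(_one_letter(m) or "X" for m in ent.full_sequence)
        if ent.name:
            seqres_by_chain.setdefault(ent.name, letters)
    residues_by_chain: dict[str, list[Residue]] = {}
    model = st[0]
    for chain in model:
        if chains is not None and chain.name not in chains:
            continue
        out: list[Residue] = []
        for res in chain:
            one = _one_letter(res.name)
            if one is None:
                if res.name not in ("HOH", "WAT"):
                    log.info("skipping non-residue %s %s%s", res.name,
                             chain.name, res.seqid.num)
                continue
            if not keep_nonstandard and res.name not in AA3_TO_1:
                continue
            best: dict[str, tuple[float, np.ndarray]] = {}
            for atom in res:
                occ = atom.occ
                prev = best.get(atom.name)
                if prev is None or occ > prev[0]:
                    best[atom.name] = (occ, np.array([atom.pos.x, atom.pos.y,
                                                      atom.pos.z]))
            number = f"{res.seqid.num}{res.seqid.icode}".strip()
            out.append(Residue(chain.name, number, one, res.name,
                               {k: v[1] for k, v in best.items()}))
        if out:
            residues_by_chain[chain.name] = out
    if not residues_by_chain:
        raise ValueError(f"{path}: no polymer residues parsed")
    seqres = {c: seqres_by_chain.get(c, "") for c in residues_by_chain}
    return residues_by_chain, seqres


def extract_seqatm(residues: list[Residue]) -> str:
    """One-letter sequence of residues that have coordinates, in chain order."""
    if not residues:
        raise ValueError("empty chain: no residues with coordinates")
    return "".join(r.aa for r in residues)


def write_pdb(chains: dict[str, list[Residue]], path, seqres=None) -> None:
    """Write chains to a PDB file with SEQRES and ATOM records.

    ``seqres`` optionally maps chain id -> one-letter sequence; when absent
    the coordinate sequence is used.
    """
    lines = []
    for cid, residues in chains.items():
        seq = (seqres or {}).get(cid) or "".join(r.aa for r in residues)
        three = [AA1_TO_3[a] for a in seq]
        for i in range(0, len(three), 13):
            chunk = three[i:i + 13]
            lines.append(f"SEQRES {i // 13 + 1:>3} {cid:1} {len(three):>4}  "
                         + " ".join(f"{t:>3}" for t in chunk))
    serial = 1
    for cid, residues in chains.items():
        for res in residues:
            for name, xyz in res.atoms.items():
                elem = element_of(name)
                aname = f" {name:<3}" if len(name) < 4 else name
                lines.append(
                    f"ATOM  {serial:>5} {aname:<4}{res.name3:>4} {cid:1}"
                    f"{int(res.number):>4}    "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {elem:>2}")
                serial += 1
        lines.append(f"TER   {serial:>5}      {residues[-1].name3:>3} {cid:1}"
                     f"{int(residues[-1].number):>4}")
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
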