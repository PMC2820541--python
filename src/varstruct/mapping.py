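"""Double-map: anchoring sequence positions onto structure residues.

Two global pairwise alignments are composed through the SEQRES record:
first the coordinate-derived sequence (SEQATM) against SEQRES, then SEQRES
against the external database sequence (SP). A sequence position maps to a
structure residue only if it is aligned (non-gap) in both alignments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

from varstruct.pdbio import Residue
from varstruct.variants import VariantSet

log = logging.getLogger(__name__)


@dataclass
class ResidueMap:
    """Composed sequence-position -> structure-residue mapping.

    pairs hold (1-based SP position, index into the SEQATM residue list);
    both coordinates are strictly increasing (no crossings) and each side
    maps at most once.
    """

    accession: str
    structure_id: str
    chain: str
    pairs: list[tuple[int, int]] = field(default_factory=list)
    identity_seqres_sp: float = 0.0
    identity_seqatm_seqres: float = 0.0
    accepted: bool = True

    def __post_init__(self):
        for (p0, r0), (p1, r1) in zip(self.pairs, self.pairs[1:]):
            if p1 <= p0 or r1 <= r0:
                raise ValueError("mapping pairs must be strictly increasing")

    def position_to_residue(self) -> dict[int, int]:
        return dict(self.pairs)


def _global_aligner(blosum: bool) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if blosum:
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11.0
        aligner.extend_gap_score = -1.0
    else:
        # SEQATM and SEQRES derive from one molecule: forbid mismatches
        aligner.match_score = 1.0
        aligner.mismatch_score = -100.0
        aligner.open_gap_score = -1.0
        aligner.extend_gap_score = -0.5
    return aligner


def _aligned_pairs(seq_a: str, seq_b: str, blosum: bool):
    """0-based aligned index pairs (a_i, b_i) of a global alignment."""
    alignment = _global_aligner(blosum).align(seq_a, seq_b)[0]
    pairs = []
    for (a_start, a_end), (b_start, b_end) in zip(*alignment.aligned):
        for k in range(a_end - a_start):
            pairs.append((a_start + k, b_start + k))
    return pairs


def double_map(sp_seq: str, seqres_seq: str, seqatm_residues: list[Residue],
               accession: str = "", structure_id: str = "", chain: str = "",
               min_identity: float = 0.90) -> ResidueMap:
    """Compose SEQATM<->SEQRES and SEQRES<->SP alignments through SEQRES.

    The composed SP<->SEQATM identity (matches over aligned columns) must
    reach ``min_identity``, otherwise the mapping is rejected
    (``accepted=False``) and should not be used for anchoring.
    """
    if not sp_seq or not seqres_seq or not seqatm_residues:
        raise ValueError("double_map requires three non-empty sequences")
    seqatm = "".join(r.aa for r in seqatm_residues)
    atm_res = _aligned_pairs(seqatm, seqres_seq, blosum=False)
    res_sp = _aligned_pairs(seqres_seq, sp_seq, blosum=True)
    atm_matches = sum(seqatm[i] == seqres_seq[j] for i, j in atm_res)
    ident_atm = atm_matches / len(atm_res) if atm_res else 0.0
    sp_matches = sum(seqres_seq[i] == sp_seq[j] for i, j in res_sp)
    ident_sp = sp_matches / len(res_sp) if res_sp else 0.0
    seqres_to_sp = dict(res_sp)
    pairs = []
    composed_matches = 0
    for atm_i, seqres_i in atm_res:
        sp_i = seqres_to_sp.get(seqres_i)
        if sp_i is None:
            continue
        pairs.append((sp_i + 1, atm_i))
        if sp_seq[sp_i] == seqatm[atm_i]:
            composed_matches += 1
    composed_identity = composed_matches / len(pairs) if pairs else 0.0
    accepted = composed_identity >= min_identity
    if not accepted:
        log.warning("mapping %s -> %s:%s rejected: composed identity %.1f%% "
                    "below %.1f%%", accession, structure_id, chain,
                    100 * composed_identity, 100 * min_identity)
    return ResidueMap(accession, structure_id, chain, pairs,
                      identity_seqres_sp=ident_sp,
                      identity_seqatm_seqres=ident_atm,
                      accepted=accepted)


def map_variants(variants: VariantSet, residue_map: ResidueMap,
                 seqatm_residues: list[Residue]):
    """Anchor variants onto structure residues.

    A variant is anchored when its position is mapped and its wild-type
    amino acid equals the structure residue's type (coordinate-drift guard).
    Returns (anchored, counters) where anchored is a list of
    (VariantRecord, Residue) and counters reports unmapped/mismatch drops.
    """
    if not residue_map.accepted:
        raise ValueError("residue map was rejected; cannot anchor variants")
    pos2res = residue_map.position_to_residue()
    anchored = []
    counters = {"anchored": 0, "unmapped": 0, "wt_mismatch": 0}
    for rec in variants:
        idx = pos2res.get(rec.position)
        if idx is None:
            counters["unmapped"] += 1
            continue
        res = seqatm_residues[idx]
        if res.aa != rec.wt_aa:
            counters["wt_mismatch"] += 1
            continue
        anchored.append((rec, res))
        counters["anchored"] += 1
    if counters["wt_mismatch"]:
        log.info("%s: %d variants dropped by wild-type mismatch",
                 variants.dataset, counters["wt_mismatch"])
    return anchored, counters
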