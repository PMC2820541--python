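"""Functional-site annotation and variant occupancy of functional residues.

Eight UniProt-style feature categories (ACT_SITE, BINDING, CA_BIND,
DISULFID, DNA_BIND, LIPID, METAL, NP_BIND) plus structure-derived
protein-protein-interface residues (PPI). The occupancy statistic is the
percentage of a category's functional residues carrying at least one
variant of a dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

log = logging.getLogger(__name__)

FEATURE_CATEGORIES = ("ACT_SITE", "BINDING", "CA_BIND", "DISULFID",
                      "DNA_BIND", "LIPID", "METAL", "NP_BIND", "PPI")


@dataclass(frozen=True)
class FunctionalFeature:
    """One functional annotation: a residue range of a category."""

    accession: str
    category: str
    start: int
    end: int

    def __post_init__(self):
        if self.category not in FEATURE_CATEGORIES:
            raise ValueError(f"unknown feature category {self.category!r}")
        if not 1 <= self.start <= self.end:
            raise ValueError("feature range must satisfy 1 <= start <= end")

    def residues(self) -> set[int]:
        """Residue positions covered by the feature.

        DISULFID features name the two bonded partner residues (start and
        end), not the intervening range; all other categories expand to
        every residue in the inclusive range.
        """
        if self.category == "DISULFID":
            return {self.start, self.end}
        return set(range(self.start, self.end + 1))


def parse_features(path) -> list[FunctionalFeature]:
    """Parse a feature TSV (accession, category, start, end).

    Rows with an unknown category or an invalid range are rejected and
    logged; a header line is permitted.
    """
    path = Path(path)
    features = []
    rejected = 0
    for ln in path.read_text(encoding="utf-8").splitlines():
        if not ln.strip():
            continue
        parts = ln.split("\t")
        if parts[0].strip().lower() == "accession":
            continue
        try:
            feat = FunctionalFeature(parts[0].strip(), parts[1].strip(),
                                     int(parts[2]), int(parts[3]))
        except (ValueError, IndexError) as exc:
            rejected += 1
            log.warning("%s: rejected feature row %r (%s)", path.name, ln, exc)
            continue
        features.append(feat)
    if rejected:
        log.info("%s: rejected %d feature rows", path.name, rejected)
    return features


def write_features(features, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("accession\tcategory\tstart\tend\n")
        for f in features:
            fh.write(f"{f.accession}\t{f.category}\t{f.start}\t{f.end}\n")


def interface_residues(residues_by_chain: dict, cutoff: float = 5.0,
                       accession_of_chain: dict | None = None
                       ) -> list[FunctionalFeature]:
    """Contact-based protein-protein-interface residues.

    A residue is at an interface when any of its heavy atoms lies within
    ``cutoff`` Angstrom of a heavy atom of a residue in another chain.
    Positions are reported as the residue's 1-based index within its chain;
    ``accession_of_chain`` optionally renames chains to sequence accessions.
    Returns single-residue PPI features (empty for single-chain input or a
    non-positive cutoff).
    """
    chains = list(residues_by_chain)
    if len(chains) < 2 or cutoff <= 0:
        return []
    coords = {}
    for cid in chains:
        per_res = []
        for res in residues_by_chain[cid]:
            per_res.append(np.array(list(res.atoms.values())))
        coords[cid] = per_res
    features = []
    for cid in chains:
        other = np.vstack([atoms for oc in chains if oc != cid
                           for atoms in coords[oc]])
        acc = (accession_of_chain or {}).get(cid, cid)
        for idx, atoms in enumerate(coords[cid], start=1):
            d2 = ((atoms[:, None, :] - other[None, :, :]) ** 2).sum(-1)
            if (d2 <= cutoff * cutoff).any():
                features.append(FunctionalFeature(acc, "PPI", idx, idx))
    return features


def functional_occupancy(features, variant_sets):
    """Table-style occupancy: % of functional residues with >= 1 variant.

    For category c and dataset d the statistic is
    100 * |{(accession, residue) of c with a variant of d}| / |{(accession,
    residue) of c}| with residues deduplicated across overlapping features.
    Categories without functional residues report NaN (not available).
    Returns a pandas DataFrame (categories x datasets) plus an 'n_residues'
    column with the denominators.
    """
    import pandas as pd

    residues_by_cat: dict[str, set] = {c: set() for c in FEATURE_CATEGORIES}
    for feat in features:
        for pos in feat.residues():
            residues_by_cat[feat.category].add((feat.accession, pos))
    variant_positions = {vset.dataset: {(r.accession, r.position) for r in vset}
                         for vset in variant_sets}
    rows = {}
    for cat in FEATURE_CATEGORIES:
        residues = residues_by_cat[cat]
        row = {"n_residues": len(residues)}
        for dataset, positions in variant_positions.items():
            if not residues:
                row[dataset] = float("nan")
            else:
                hit = sum(1 for r in residues if r in positions)
                row[dataset] = 100.0 * hit / len(residues)
        rows[cat] = row
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "category"
    return frame
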