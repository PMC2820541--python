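"""Alignment-column conservation by Shannon entropy.

Entropy is computed over the 20 standard amino-acid frequencies at a
column (natural log by default, so the range is [0, ln 20]). A column is
skipped when the family has fewer than three sequences or when gaps occupy
more than half of the sequences at that position; gap characters are
excluded from the frequencies themselves.
"""

from __future__ import annotations

import logging
import math

from varstruct.constants import STANDARD_AA

log = logging.getLogger(__name__)

GAP_CHARS = set("-.")

SKIP_TOO_FEW = "too_few_sequences"
SKIP_GAP_FRACTION = "gap_fraction"


def column_entropy(column, min_sequences: int = 3, max_gap_fraction: float = 0.5,
                   base: float = math.e):
    """Entropy of one alignment column, or a skip reason.

    Returns ``(entropy, None)`` or ``(None, reason)`` with reason in
    {'too_few_sequences', 'gap_fraction'}. The gap fraction is taken over
    all sequences; frequencies are over non-gap standard residues only
    (other letters are excluded with a log notice).
    """
    column = list(column)
    n = len(column)
    if n < min_sequences:
        return None, SKIP_TOO_FEW
    gaps = sum(1 for ch in column if ch in GAP_CHARS)
    if gaps / n > max_gap_fraction:
        return None, SKIP_GAP_FRACTION
    counts: dict[str, int] = {}
    for ch in column:
        if ch in GAP_CHARS:
            continue
        ch = ch.upper()
        if ch not in STANDARD_AA:
            log.info("non-standard letter %r excluded from entropy", ch)
            continue
        counts[ch] = counts.get(ch, 0) + 1
    total = sum(counts.values())
    if total == 0:
        return None, SKIP_GAP_FRACTION
    entropy = 0.0
    for c in counts.values():
        p = c / total
        entropy -= p * math.log(p)
    if base != math.e:
        entropy /= math.log(base)
    return entropy, None


def alignment_entropy_profile(sequences, alignment_id: str = "",
                              min_sequences: int = 3,
                              max_gap_fraction: float = 0.5,
                              base: float = math.e):
    """Per-column entropy profile of an alignment (pandas DataFrame).

    ``sequences`` is a list of equal-length aligned strings. Columns of the
    result: column (1-based), n_nongap, entropy, skip_reason.
    """
    import pandas as pd

    if not sequences:
        raise ValueError("empty alignment")
    length = len(sequences[0])
    if any(len(s) != length for s in sequences):
        raise ValueError("aligned sequences have unequal lengths")
    rows = []
    for j in range(length):
        col = [s[j] for s in sequences]
        value, reason = column_entropy(col, min_sequences, max_gap_fraction, base)
        rows.append({"alignment": alignment_id, "column": j + 1,
                     "n_nongap": sum(1 for ch in col if ch not in GAP_CHARS),
                     "entropy": value, "skip_reason": reason})
    return pd.DataFrame(rows)


def positions_to_columns(reference_row: str) -> dict[int, int]:
    """Map 1-based ungapped positions of the reference row to 1-based columns."""
    mapping = {}
    pos = 0
    for j, ch in enumerate(reference_row, start=1):
        if ch not in GAP_CHARS:
            pos += 1
            mapping[pos] = j
    return mapping


def variant_entropy(variant_sets, profiles: dict, reference_rows: dict,
                    accessibility: dict | None = None):
    """Per-variant entropy records stratified by dataset and accessibility.

    profiles: accession -> entropy-profile DataFrame; reference_rows:
    accession -> the aligned row whose ungapped coordinates are the
    variant coordinates; accessibility (optional): variant key -> bool.
    Variants at skipped columns or without an alignment are omitted and
    counted. Returns (DataFrame, counters).
    """
    import pandas as pd

    rows = []
    counters = {"scored": 0, "no_alignment": 0, "skipped_column": 0}
    colmaps = {acc: positions_to_columns(row)
               for acc, row in reference_rows.items()}
    for vset in variant_sets:
        for rec in vset:
            profile = profiles.get(rec.accession)
            colmap = colmaps.get(rec.accession)
            col = colmap.get(rec.position) if colmap else None
            if profile is None or col is None:
                counters["no_alignment"] += 1
                continue
            entry = profile[profile["column"] == col].iloc[0]
            if entry["skip_reason"] is not None or entry["entropy"] is None:
                counters["skipped_column"] += 1
                continue
            acc_flag = (accessibility or {}).get(rec.key)
            if acc_flag is None:
                stratum = "unstratified"
            else:
                stratum = "accessible" if acc_flag else "inaccessible"
            rows.append({"dataset": rec.dataset, "accession": rec.accession,
                         "position": rec.position, "stratum": stratum,
                         "entropy": float(entry["entropy"])})
            counters["scored"] += 1
    return pd.DataFrame(rows), counters
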