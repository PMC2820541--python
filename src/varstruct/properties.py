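"""Physicochemical 6-class amino-acid typing and property substitution matrices.

The 20 standard amino acids partition into six classes: aliphatic (ALI),
aromatic (ARO), polar non-charged (NON), positively charged (POS),
negatively charged (NEG) and neutral (NEU). Counting variants by the class
of their wild-type and variant residue gives a 6x6 matrix whose
row-normalized form shows where each class tends to go.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

PROPERTY_CLASSES = {
    "ALI": set("AILVM"),
    "ARO": set("FWY"),
    "NON": set("CNQST"),
    "POS": set("RHK"),
    "NEG": set("DE"),
    "NEU": set("GP"),
}
CLASS_ORDER = ("ALI", "ARO", "NON", "POS", "NEG", "NEU")

_AA_TO_CLASS = {aa: label for label, members in PROPERTY_CLASSES.items()
                for aa in members}


def classify_aa(aa: str) -> str:
    """Class label of one standard amino acid."""
    try:
        return _AA_TO_CLASS[aa.upper()]
    except KeyError:
        raise ValueError(f"non-standard amino acid {aa!r}") from None


@dataclass
class PropertyMatrix:
    """6x6 substitution counts (row = wild-type class) with row-normalized probs."""

    dataset: str
    counts: np.ndarray = field(
        default_factory=lambda: np.zeros((6, 6), dtype=int))

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (6, 6) or (self.counts < 0).any():
            raise ValueError("counts must be a non-negative 6x6 matrix")

    @property
    def probs(self) -> np.ndarray:
        """Row-normalized probabilities; zero rows stay at zero (flagged)."""
        totals = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            probs = np.where(totals > 0, self.counts / np.maximum(totals, 1), 0.0)
        return probs

    @property
    def zero_rows(self) -> list[str]:
        return [CLASS_ORDER[i] for i in range(6) if self.counts[i].sum() == 0]

    @property
    def n_variants(self) -> int:
        return int(self.counts.sum())

    def to_frame(self, normalized: bool = True):
        import pandas as pd

        data = self.probs if normalized else self.counts
        return pd.DataFrame(data, index=CLASS_ORDER, columns=CLASS_ORDER)


def build_matrix(variants, dataset: str | None = None) -> PropertyMatrix:
    """Accumulate a property matrix from variant records (wt -> var classes)."""
    records = list(variants)
    label = dataset or (records[0].dataset if records else "")
    counts = np.zeros((6, 6), dtype=int)
    for rec in records:
        i = CLASS_ORDER.index(classify_aa(rec.wt_aa))
        j = CLASS_ORDER.index(classify_aa(rec.var_aa))
        counts[i, j] += 1
    return PropertyMatrix(label, counts)


def matrix_distance(a: PropertyMatrix, b: PropertyMatrix,
                    metric: str = "frobenius") -> float:
    """Distance between two row-normalized property matrices.

    'frobenius' (default) is the Frobenius norm of the difference;
    'jensen-shannon' averages per-row Jensen-Shannon distances. Rows with
    zero counts in either matrix are excluded pairwise.
    """
    pa, pb = a.probs, b.probs
    valid = np.array([a.counts[i].sum() > 0 and b.counts[i].sum() > 0
                      for i in range(6)])
    if not valid.any():
        raise ValueError("no jointly defined rows")
    if metric == "frobenius":
        diff = pa[valid] - pb[valid]
        return float(np.sqrt((diff ** 2).sum()))
    if metric == "jensen-shannon":
        from scipy.spatial.distance import jensenshannon

        vals = [jensenshannon(pa[i], pb[i], base=2.0)
                for i in range(6) if valid[i]]
        return float(np.mean(vals))
    raise ValueError(f"unknown metric {metric!r}")
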