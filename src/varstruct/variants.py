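"""Variant-table parsing, Mendelian-disease filtering and overlap accounting.

Variant tables follow a humsavar-like tab-separated layout with one
substitution per row: accession, 1-based sequence position, wild-type and
variant amino acid (one-letter), a class label, a free-text annotation
(disease name or variant id) and an optional MIM disease number.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from varstruct.constants import STANDARD_AA

log = logging.getLogger(__name__)

DATASET_LABELS = ("SVD", "SVP", "SAP", "CSM")

#: disease-name tokens that flag a cancer-related annotation
CANCER_TOKENS = (
    "cancer", "tumor", "neoplasia", "leukaemia", "lymphoma",
    "melanoma", "carcinoma", "blastoma", "cytoma",
)


@dataclass(frozen=True)
class VariantRecord:
    """One single amino-acid substitution in protein-sequence coordinates."""

    accession: str
    position: int
    wt_aa: str
    var_aa: str
    dataset: str
    annotation: str = ""
    mim: Optional[int] = None

    def __post_init__(self):
        if self.wt_aa == self.var_aa:
            raise ValueError("wild-type and variant amino acid are identical")
        if self.wt_aa not in STANDARD_AA or self.var_aa not in STANDARD_AA:
            raise ValueError(f"non-standard amino acid in {self.wt_aa}->{self.var_aa}")
        if self.position < 1:
            raise ValueError("position must be >= 1")

    @property
    def key(self) -> tuple:
        """Identity tuple: (accession, position, wt, var)."""
        return (self.accession, self.position, self.wt_aa, self.var_aa)


@dataclass
class VariantSet:
    """A labelled collection of distinct variant records."""

    dataset: str
    records: list[VariantRecord] = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        unique = []
        for rec in self.records:
            if rec.dataset != self.dataset:
                raise ValueError(
                    f"record labelled {rec.dataset} in {self.dataset} set")
            if rec.key not in seen:
                seen.add(rec.key)
                unique.append(rec)
        self.records = unique

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def keys(self) -> set:
        return {rec.key for rec in self.records}


COLUMNS = ("accession", "position", "wt_aa", "var_aa", "type", "annotation", "mim")


def parse_variant_table(path, dataset_label: str) -> VariantSet:
    """Parse a tab-separated variant table into a :class:`VariantSet`.

    The first line may be a header naming the columns (any order); headerless
    files are read in the canonical column order. Malformed rows (bad amino
    acids, wt == var, non-numeric position) are skipped and counted in a log
    message. Duplicate (accession, position, wt, var) rows collapse to one
    record.

    Raises ``FileNotFoundError`` for a missing file and ``ValueError`` when
    no row parses.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[VariantRecord] = []
    skipped = 0
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty variant table")
    first = lines[0].split("\t")
    if "accession" in [c.strip().lower() for c in first]:
        header = [c.strip().lower() for c in first]
        order = {name: header.index(name) for name in header}
        body = lines[1:]
    else:
        order = {name: i for i, name in enumerate(COLUMNS)}
        body = lines
    for line in body:
        fields = line.split("\t")

        def get(col, default=""):
            idx = order.get(col)
            if idx is None or idx >= len(fields):
                return default
            return fields[idx].strip()

        try:
            mim_text = get("mim")
            rec = VariantRecord(
                accession=get("accession"),
                position=int(get("position")),
                wt_aa=get("wt_aa").upper(),
                var_aa=get("var_aa").upper(),
                dataset=dataset_label,
                annotation=get("annotation"),
                mim=int(mim_text) if mim_text else None,
            )
            if not rec.accession:
                raise ValueError("empty accession")
        except (ValueError, KeyError) as exc:
            skipped += 1
            log.warning("%s: skipped row %r (%s)", path.name, line, exc)
            continue
        records.append(rec)
    if skipped:
        log.info("%s: skipped %d malformed rows", path.name, skipped)
    if not records:
        raise ValueError(f"{path}: no parseable variant rows "
                         f"({skipped} malformed rows skipped)")
    return VariantSet(dataset_label, records)


def write_variant_table(vset: VariantSet, path) -> None:
    """Serialize a variant set to canonical TSV (fixed column order)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(COLUMNS) + "\n")
        for rec in vset:
            fh.write("\t".join([
                rec.accession, str(rec.position), rec.wt_aa, rec.var_aa,
                rec.dataset, rec.annotation,
                "" if rec.mim is None else str(rec.mim),
            ]) + "\n")


def filter_mendelian(vset: VariantSet, tokens: Iterable[str] = CANCER_TOKENS,
                     match_tumour_spelling: bool = True) -> VariantSet:
    """Restrict a disease set to Mendelian-disease variants.

    Keeps only records that carry a MIM number and whose annotation contains
    none of the cancer-name tokens (case-insensitive substring match).
    ``match_tumour_spelling`` additionally matches the 'tumour' spelling
    whenever 'tumor' is among the tokens.
    """
    toks = [t.lower() for t in tokens]
    if match_tumour_spelling and "tumor" in toks and "tumour" not in toks:
        toks.append("tumour")
    kept = []
    for rec in vset:
        if rec.mim is None:
            continue
        text = rec.annotation.lower()
        if any(tok in text for tok in toks):
            continue
        kept.append(rec)
    return VariantSet(vset.dataset, kept)


def overlap_stats(a: VariantSet, b: VariantSet) -> dict:
    """Shared-variant accounting between two sets.

    Returns the shared count and the share as a percentage of each set
    (rounded to the nearest integer, the precision used in reports); an
    empty set yields ``None`` for its percentage.
    """
    shared = len(a.keys() & b.keys())
    pct_a = round(100.0 * shared / len(a)) if len(a) else None
    pct_b = round(100.0 * shared / len(b)) if len(b) else None
    return {"shared": shared, "pct_of_a": pct_a, "pct_of_b": pct_b,
            "n_a": len(a), "n_b": len(b)}
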