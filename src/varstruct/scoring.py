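"""Substitution scoring: BLOSUM62 and environment-specific tables (ESSTs).

An ESST holds one 20x20 log-odds table per structural environment, so the
score of a substitution depends on where in the structure it happens.
:func:`estimate_esst` provides a deliberately simple estimator (raw
substitution counts with a unit pseudocount turned into half-bit log-odds
against the pooled background); it is not equivalent to the smoothed,
weighted procedures used to build production ESSTs, but it produces tables
with the same shape, units and environment specificity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from varstruct.constants import STANDARD_AA

log = logging.getLogger(__name__)

#: canonical row/column order for ESST tables
ESST_ALPHABET = STANDARD_AA


@dataclass
class SubstitutionTable:
    """A square substitution matrix over a residue alphabet (row = wild type)."""

    name: str
    alphabet: str
    scores: np.ndarray

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        n = len(self.alphabet)
        if self.scores.shape != (n, n):
            raise ValueError("scores must be square over the alphabet")
        self._index = {aa: i for i, aa in enumerate(self.alphabet)}

    def score(self, wt_aa: str, var_aa: str) -> float:
        for aa in (wt_aa, var_aa):
            if aa not in self._index:
                raise KeyError(f"letter {aa!r} not in table {self.name}")
        return float(self.scores[self._index[wt_aa], self._index[var_aa]])

    @property
    def is_symmetric(self) -> bool:
        return bool(np.allclose(self.scores, self.scores.T))


def lookup_score(table: SubstitutionTable, wt_aa: str, var_aa: str) -> float:
    """Score of substituting wt_aa by var_aa (row = wild type)."""
    return table.score(wt_aa, var_aa)


def parse_matrix_text(text: str, name: str = "matrix") -> SubstitutionTable:
    """Parse an NCBI-layout matrix: '#' comments, column header, labelled rows."""
    lines = [ln for ln in text.splitlines()
             if ln.strip() and not ln.lstrip().startswith("#")]
    header = lines[0].split()
    n = len(header)
    scores = np.zeros((n, n))
    row_labels = []
    for ln in lines[1:]:
        parts = ln.split()
        row_labels.append(parts[0])
        scores[len(row_labels) - 1, :] = [float(x) for x in parts[1:n + 1]]
    if row_labels != header:
        raise ValueError("matrix row labels do not match column header")
    return SubstitutionTable(name, "".join(header), scores)


def load_blosum62() -> SubstitutionTable:
    """The shipped BLOSUM62 matrix (half-bit log-odds, NCBI layout)."""
    text = resources.files("varstruct.data").joinpath("blosum62.txt").read_text()
    return parse_matrix_text(text, name="BLOSUM62")


@dataclass
class ESST:
    """One substitution table per declared structural environment."""

    name: str
    tables: dict[int, SubstitutionTable] = field(default_factory=dict)
    pooled_envs: set = field(default_factory=set)  # filled from pooled estimate

    def environments(self) -> list[int]:
        return sorted(self.tables)


def esst_lookup(esst: ESST, env_code: int, wt_aa: str, var_aa: str) -> float:
    """Score for (wt -> var) in the table of the given environment."""
    if env_code not in esst.tables:
        raise KeyError(f"environment {env_code} not declared in ESST {esst.name}")
    return esst.tables[env_code].score(wt_aa, var_aa)


def write_esst(esst: ESST, path) -> None:
    """Serialize: '>ENV <code>' headers, 20x20 matrices in ARNDCQEGHILKMFPSTWYV order."""
    with open(path, "w", encoding="utf-8") as fh:
        for code in esst.environments():
            table = esst.tables[code]
            if table.alphabet != ESST_ALPHABET:
                raise ValueError("ESST tables must use the canonical alphabet")
            fh.write(f">ENV {code}\n")
            for row in table.scores:
                fh.write(" ".join(f"{v:g}" for v in row) + "\n")


def read_esst(path, name: str | None = None) -> ESST:
    """Parse the ESST text format written by :func:`write_esst` (bit-exact)."""
    path = Path(path)
    esst = ESST(name or path.stem)
    code = None
    rows: list[list[float]] = []

    def flush():
        if code is None:
            return
        if len(rows) != 20:
            raise ValueError(f"ENV {code}: expected 20 rows, got {len(rows)}")
        esst.tables[code] = SubstitutionTable(
            f"ENV{code}", ESST_ALPHABET, np.array(rows))

    for ln in path.read_text(encoding="utf-8").splitlines():
        ln = ln.strip()
        if not ln:
            continue
        if ln.startswith(">ENV"):
            flush()
            code = int(ln.split()[1])
            rows = []
        else:
            rows.append([float(x) for x in ln.split()])
    flush()
    if not esst.tables:
        raise ValueError(f"{path}: no environment tables found")
    return esst


def estimate_esst(annotated_columns, name: str = "estimated",
                  environments=None, pseudocount: float = 1.0) -> ESST:
    """Estimate an ESST from environment-annotated alignment columns.

    ``annotated_columns`` is an iterable of (env_code, column) where column
    is the string of residues observed at one alignment position (gaps and
    non-standard letters ignored). For each environment, ordered residue
    pairs within a column are counted as substitutions a->b; with a unit
    pseudocount, score(e, a, b) = round(2 * log2(P(b | a, e) / f(b))) where
    f is the residue background over all columns. Environments declared but
    never observed are filled from the pooled (environment-free) estimate
    and recorded in ``pooled_envs``.
    """
    idx = {aa: i for i, aa in enumerate(ESST_ALPHABET)}
    counts: dict[int, np.ndarray] = {}
    pooled = np.zeros((20, 20))
    background = np.zeros(20)
    n_cols = 0
    for env_code, column in annotated_columns:
        residues = [aa for aa in column if aa in idx]
        if not residues:
            continue
        n_cols += 1
        for aa in residues:
            background[idx[aa]] += 1
        mat = counts.setdefault(int(env_code), np.zeros((20, 20)))
        # ordered pairs over distinct sequence slots (identical letters in
        # different sequences still count as a->a "substitutions")
        for i, a in enumerate(residues):
            for j, b in enumerate(residues):
                if i != j:
                    mat[idx[a], idx[b]] += 1
                    pooled[idx[a], idx[b]] += 1
    if n_cols == 0:
        raise ValueError("no usable alignment columns")
    freq = background / background.sum()
    # guard zero-frequency letters: they never appear as targets either
    freq[freq == 0] = 1.0 / background.sum()

    def to_scores(mat: np.ndarray) -> np.ndarray:
        cond = mat + pseudocount
        cond = cond / cond.sum(axis=1, keepdims=True)
        return np.round(2.0 * np.log2(cond / freq[None, :]))

    esst = ESST(name)
    declared = sorted(environments) if environments is not None else sorted(counts)
    pooled_scores = to_scores(pooled)
    for code in declared:
        if code in counts:
            esst.tables[code] = SubstitutionTable(
                f"ENV{code}", ESST_ALPHABET, to_scores(counts[code]))
        else:
            esst.tables[code] = SubstitutionTable(
                f"ENV{code}", ESST_ALPHABET, pooled_scores.copy())
            esst.pooled_envs.add(code)
            log.info("environment %d has no columns; pooled estimate used", code)
    return esst


def score_variant_sets(variant_sets, blosum: SubstitutionTable,
                       esst: ESST | None = None, environments: dict | None = None):
    """Long-format per-variant score records.

    ``environments`` maps a variant identity key to its
    :class:`~varstruct.annotate.StructuralEnvironment` (or None); variants
    without an environment get BLOSUM62 scores only. Returns a pandas
    DataFrame with one row per variant carrying dataset, environment
    features and scores.
    """
    import pandas as pd

    rows = []
    for vset in variant_sets:
        for rec in vset:
            env = (environments or {}).get(rec.key)
            row = {
                "dataset": rec.dataset, "accession": rec.accession,
                "position": rec.position, "wt_aa": rec.wt_aa,
                "var_aa": rec.var_aa,
                "blosum62": lookup_score(blosum, rec.wt_aa, rec.var_aa),
                "ss": None, "accessible": None, "hb_nh": None,
                "hb_co": None, "hb_sc": None, "env_code": None, "esst": None,
            }
            if env is not None:
                row.update(ss=env.ss, accessible=env.accessible,
                           hb_nh=env.hb_nh, hb_co=env.hb_co, hb_sc=env.hb_sc,
                           env_code=env.code)
                if esst is not None:
                    row["esst"] = esst_lookup(esst, env.code, rec.wt_aa,
                                              rec.var_aa)
            rows.append(row)
    return pd.DataFrame(rows)


def negative_fraction(scores, column: str = "blosum62", by=("dataset",)):
    """Per-stratum fraction of variants with a negative substitution score.

    Empty strata are simply absent from the output (they carry no rows).
    """
    import pandas as pd

    df = scores.dropna(subset=[column])
    grouped = df.groupby(list(by))[column]
    out = grouped.apply(lambda s: float((s < 0).mean()))
    out.name = f"negative_fraction_{column}"
    return out
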