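"""Occurrence tables, enrichment, rank-sum tests and representative selection.

The occurrence table reports, per variant dataset and for a background
residue set, the percentage of residues/variants falling in each structural
category (burial, the three H-bond flags, the four secondary-structure
classes). Enrichment compares an observed percentage against the background
expectation. Distribution comparisons use the two-sided Wilcoxon rank-sum
test. Representative-domain selection reproduces the classic
redundancy-filtering recipe: resolution filter, family length filter,
greedy identity clustering, best resolution per cluster.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

log = logging.getLogger(__name__)

OCCURRENCE_ROWS = ("inaccessible", "hb_nh", "hb_co", "hb_sc", "H", "E", "P", "C")


def _category_fractions(envs) -> dict[str, float]:
    envs = [e for e in envs if e is not None]
    n = len(envs)
    if n == 0:
        return {}
    out = {
        "inaccessible": 100.0 * sum(not e.accessible for e in envs) / n,
        "hb_nh": 100.0 * sum(e.hb_nh for e in envs) / n,
        "hb_co": 100.0 * sum(e.hb_co for e in envs) / n,
        "hb_sc": 100.0 * sum(e.hb_sc for e in envs) / n,
    }
    for ss in "HEPC":
        out[ss] = 100.0 * sum(e.ss == ss for e in envs) / n
    out["n"] = n
    return out


def occurrence_table(envs_by_dataset: dict, background_envs):
    """Occurrence (%) of variants by structural environment, with background.

    ``envs_by_dataset`` maps dataset label -> list of StructuralEnvironment
    (one per anchored variant; None entries are dropped); background_envs is
    the residue-level background. Datasets with zero annotated variants are
    omitted with a log notice. Returns a pandas DataFrame whose rows are the
    structural categories plus an 'n' row of denominators; the four
    secondary-structure rows of every column sum to 100 up to rounding.
    """
    import pandas as pd

    columns = {}
    for dataset, envs in envs_by_dataset.items():
        fractions = _category_fractions(envs)
        if not fractions:
            log.warning("dataset %s has no annotated variants; omitted", dataset)
            continue
        columns[dataset] = fractions
    background = _category_fractions(background_envs)
    if background:
        columns["background"] = background
    frame = pd.DataFrame(columns).reindex(list(OCCURRENCE_ROWS) + ["n"])
    frame.index.name = "category"
    return frame


def enrichment(observed_pct: float, background_pct: float) -> dict:
    """Relative enrichment of an observed percentage over the background.

    raw = 100 * (observed/background - 1); display rounds toward zero to an
    integer (42.25 vs 31.21 -> +35). Zero background is undefined.
    """
    if background_pct <= 0:
        raise ValueError("background percentage must be > 0")
    raw = 100.0 * (observed_pct / background_pct - 1.0)
    return {"raw": raw, "display": math.trunc(raw)}


def wilcoxon_rank_sum(x, y, alternative: str = "two-sided",
                      exact_max_n: int = 20):
    """Two-sided (by default) Wilcoxon rank-sum test.

    Returns (W, p) where W is the rank-sum of ``x`` with midranks for ties.
    The p-value is exact (enumeration-equivalent) when the pooled sample has
    at most ``exact_max_n`` observations and no ties, and otherwise uses the
    normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    w = float(ranks[:len(x)].sum())
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= exact_max_n and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method,
                           use_continuity=True)
    return w, float(res.pvalue)


@dataclass(frozen=True)
class DomainRecord:
    """A structural domain: family membership, resolution, sequence, method."""

    family: str
    domain_id: str
    resolution: float | None  # None for NMR entries
    sequence: str
    method: str = "xray"  # 'xray' (diffraction) or 'nmr'

    def __post_init__(self):
        if self.method != "nmr" and (self.resolution is None
                                     or self.resolution <= 0):
            raise ValueError("diffraction entries need a positive resolution")


def sequence_identity(a: str, b: str) -> float:
    """Global-alignment identity: matches / alignment length."""
    from varstruct.mapping import _global_aligner

    alignment = _global_aligner(blosum=True).align(a, b)[0]
    matches = 0
    for (a0, a1), (b0, b1) in zip(*alignment.aligned):
        matches += sum(a[a0 + k] == b[b0 + k] for k in range(a1 - a0))
    return matches / alignment.length


def select_representatives(domains, max_resolution: float = 2.5,
                           identity_threshold: float = 0.80,
                           length_tolerance: float = 0.30):
    """Representative domains per family.

    Per family: NMR entries and resolution worse than ``max_resolution`` are
    dropped; domains with sequence length outside (1 +/- tolerance) times the
    family mean length (after the resolution filter) are dropped; remaining
    domains are greedily clustered longest-first at >= identity_threshold;
    the best-resolution member represents each cluster.
    """
    by_family: dict[str, list[DomainRecord]] = {}
    for dom in domains:
        by_family.setdefault(dom.family, []).append(dom)
    representatives = []
    for family in sorted(by_family):
        members = [d for d in by_family[family]
                   if d.method != "nmr" and d.resolution is not None
                   and d.resolution <= max_resolution]
        if not members:
            continue
        mean_len = float(np.mean([len(d.sequence) for d in members]))
        members = [d for d in members
                   if (1 - length_tolerance) * mean_len <= len(d.sequence)
                   <= (1 + length_tolerance) * mean_len]
        if not members:
            continue
        # deterministic greedy clustering: longest first, ties by id
        members.sort(key=lambda d: (-len(d.sequence), d.domain_id))
        clusters: list[list[DomainRecord]] = []
        for dom in members:
            for cluster in clusters:
                if sequence_identity(dom.sequence,
                                     cluster[0].sequence) >= identity_threshold:
                    cluster.append(dom)
                    break
            else:
                clusters.append([dom])
        for cluster in clusters:
            best = min(cluster, key=lambda d: (d.resolution, d.domain_id))
            representatives.append(best)
    return representatives
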