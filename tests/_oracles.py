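"""Independent reference implementations used as test oracles.

These deliberately use different algorithms (Monte-Carlo surface sampling,
brute-force enumeration, all-pairs scans) from the package code they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def sasa_monte_carlo(coords, radii, probe: float = 1.4,
                     n_samples: int = 40000, seed: int = 0) -> np.ndarray:
    """Per-atom SASA by uniform random sampling on each expanded sphere."""
    rng = np.random.default_rng(seed)
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float) + probe
    areas = np.zeros(len(coords))
    for i in range(len(coords)):
        # uniform points on the unit sphere via normalized Gaussians
        pts = rng.normal(size=(n_samples, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        surface = coords[i] + radii[i] * pts
        exposed = np.ones(n_samples, dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            d2 = ((surface - coords[j]) ** 2).sum(axis=1)
            exposed &= d2 >= radii[j] ** 2
        areas[i] = 4 * math.pi * radii[i] ** 2 * exposed.mean()
    return areas


def ranksum_exact_pvalue(x, y) -> float:
    """Two-sided rank-sum p-value by full enumeration (no ties allowed)."""
    x = list(x)
    y = list(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "enumeration oracle needs no ties"
    nx = len(x)
    ranks = {v: r for r, v in enumerate(pooled, start=1)}
    w_obs = sum(ranks[v] for v in x)
    mean_w = nx * (len(pooled) + 1) / 2
    count = 0
    total = 0
    for combo in itertools.combinations(range(1, len(pooled) + 1), nx):
        w = sum(combo)
        total += 1
        if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-9:
            count += 1
    return count / total


def median_by_sort(values) -> float:
    """Median via explicit sorting (independent of numpy/pandas)."""
    values = sorted(values)
    n = len(values)
    mid = n // 2
    if n % 2:
        return float(values[mid])
    return (values[mid - 1] + values[mid]) / 2.0


def interface_pairs_bruteforce(residues_by_chain, cutoff):
    """All residues with any cross-chain heavy-atom pair within cutoff."""
    flagged = set()
    chains = list(residues_by_chain)
    for a in chains:
        for b in chains:
            if a == b:
                continue
            for ra in residues_by_chain[a]:
                for rb in residues_by_chain[b]:
                    for xa in ra.atoms.values():
                        for xb in rb.atoms.values():
                            if np.linalg.norm(xa - xb) <= cutoff:
                                flagged.add((a, ra.number))
    return flagged
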