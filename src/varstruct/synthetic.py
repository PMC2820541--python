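"""Synthetic fixtures: ideal structures, biased variant sets, alignments.

Everything here is a pure function of (configuration, seed). The generators
emulate the *shape* of real inputs — PDB structures with known secondary
structure and burial composition, variant tables with controlled
environment enrichment, family alignments with controlled per-column
conservation — not their biophysical realism: side chains take one
canonical rotamer, helices are geometrically ideal, and no clash relief is
attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from varstruct.constants import AA1_TO_3, STANDARD_AA
from varstruct.geometry import build_peptide
from varstruct.pdbio import Residue
from varstruct.variants import VariantRecord, VariantSet

SEGMENT_TORSIONS = {
    "helix": (-57.0, -47.0),
    "strand": (-139.0, 135.0),
    "pos-phi": (60.0, 45.0),
}
# coil torsions are sampled from this box, disjoint from the helix, strand
# and positive-phi windows so construction labels are unambiguous
COIL_PHI = (-180.0, -110.0)
COIL_PSI = (-30.0, 40.0)


@dataclass
class Segment:
    kind: str       # helix | strand | pos-phi | coil
    sequence: str


@dataclass
class ChainRecipe:
    chain: str
    segments: list[Segment]
    origin: tuple = (0.0, 0.0, 0.0)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic end-to-end demo.

    Odds ratios control how strongly each variant class prefers buried
    (rho_acc), hydrogen-bonded (rho_hb) and functional (rho_fun) residues;
    values above 1 enrich, below 1 deplete. Defaults give the disease-like
    class a strong burial/H-bond preference, the cancer-like class an
    intermediate one, and the polymorphism-like classes depletion plus
    avoidance of functional sites. Conservation concentrations set the
    Dirichlet weight on the reference residue for buried vs exposed
    alignment columns (larger = more conserved).
    """

    seed: int = 0
    n_variants: dict = field(default_factory=lambda: {
        "SVD": 400, "SVP": 400, "SAP": 400, "CSM": 400})
    rho_acc: dict = field(default_factory=lambda: {
        "SVD": 3.0, "SVP": 0.5, "SAP": 0.5, "CSM": 1.5})
    rho_hb: dict = field(default_factory=lambda: {
        "SVD": 2.0, "SVP": 0.8, "SAP": 0.8, "CSM": 1.5})
    rho_fun: dict = field(default_factory=lambda: {
        "SVD": 1.0, "SVP": 0.3, "SAP": 0.3, "CSM": 1.0})
    # substitution-severity kernel: P(var | wt) ~ exp(beta * BLOSUM62),
    # positive beta favours conservative changes, negative beta drastic ones
    score_bias: dict = field(default_factory=lambda: {
        "SVD": -0.5, "SVP": 0.5, "SAP": 0.5, "CSM": -0.25})
    n_alignment_seqs: int = 12
    conc_conserved: float = 25.0   # Dirichlet weight at the reference letter
    conc_variable: float = 0.8
    gap_column_fraction: float = 0.05
    gap_fraction: float = 0.6      # gaps per gap column (skipped downstream)

    def __post_init__(self):
        for mapping in (self.rho_acc, self.rho_hb, self.rho_fun):
            if any(v <= 0 for v in mapping.values()):
                raise ValueError("odds ratios must be > 0")


def build_ideal_structure(recipe: list[ChainRecipe], seed: int = 0
                          ) -> dict[str, list[Residue]]:
    """Build chains of ideal-geometry segments; coil torsions use the seed."""
    rng = np.random.default_rng(seed)
    chains: dict[str, list[Residue]] = {}
    for chain_recipe in recipe:
        sequence = ""
        phipsi: list[tuple[float, float]] = []
        for seg in chain_recipe.segments:
            if seg.kind == "coil":
                for _ in seg.sequence:
                    phipsi.append((rng.uniform(*COIL_PHI),
                                   rng.uniform(*COIL_PSI)))
            elif seg.kind in SEGMENT_TORSIONS:
                phipsi.extend([SEGMENT_TORSIONS[seg.kind]] * len(seg.sequence))
            else:
                raise ValueError(f"unknown segment kind {seg.kind!r}")
            sequence += seg.sequence
        built = build_peptide(sequence, phipsi, origin=chain_recipe.origin)
        chains[chain_recipe.chain] = [
            Residue(chain_recipe.chain, str(i + 1), r["aa"], AA1_TO_3[r["aa"]],
                    r["atoms"])
            for i, r in enumerate(built)
        ]
    return chains


def helix_axis_frame(length: int = 16, aa: str = "A"):
    """Unit axis of an ideal poly-aa helix plus two perpendicular unit vectors."""
    built = build_peptide(aa * length, [SEGMENT_TORSIONS["helix"]] * length)
    ca0 = built[1]["atoms"]["CA"]
    ca1 = built[-2]["atoms"]["CA"]
    u = ca1 - ca0
    u /= np.linalg.norm(u)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, u)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    v = np.cross(u, ref)
    v /= np.linalg.norm(v)
    w = np.cross(u, v)
    return u, v, w


def bundle_recipe(n_side: int = 3, length: int = 16, spacing: float = 9.5,
                  sequence: str | None = None) -> list[ChainRecipe]:
    """An n_side x n_side grid of parallel ideal helices (separate chains).

    With the default 3x3 grid the central helix is shielded on all sides,
    giving the structure a solvent-inaccessible core and inter-chain
    contacts for interface detection.
    """
    seq = sequence or ("LAVILAMSLAVILAMS" * (length // 16 + 1))[:length]
    _u, v, w = helix_axis_frame(length)
    chains = []
    ids = "ABCDEFGHIJKLMNO"
    k = 0
    half = (n_side - 1) / 2.0
    for i in range(n_side):
        for j in range(n_side):
            offset = (i - half) * spacing * v + (j - half) * spacing * w
            chains.append(ChainRecipe(ids[k], [Segment("helix", seq)],
                                      origin=tuple(offset)))
            k += 1
    return chains


def mixed_chain_recipe(chain: str = "A") -> list[ChainRecipe]:
    """One chain exercising all four secondary-structure classes."""
    return [ChainRecipe(chain, [
        Segment("helix", "ADKLSEQVRAML"),
        Segment("coil", "TSGN"),
        Segment("strand", "TVKIEFCW"),
        Segment("coil", "GPHD"),
        Segment("pos-phi", "GNDG"),
        Segment("coil", "QRYS"),
        Segment("helix", "EKALHDWMIVRE"),
    ])]


def _any_hbond(record: dict) -> bool:
    return record["hb_nh"] or record["hb_co"] or record["hb_sc"]


def simulate_variants(annotation: dict, config: SimulationConfig,
                      accession_of_chain: dict,
                      functional_positions: set | None = None,
                      datasets=None, rng=None, distinct: bool = True
                      ) -> dict[str, VariantSet]:
    """Draw variant sets with controlled environment enrichment.

    Residue selection probability is proportional to the product of the
    class odds: rho_acc when the residue is buried, rho_hb when it carries
    any side-chain H-bond flag, rho_fun when (accession, position) is a
    functional residue. The variant amino acid is uniform over the 19
    alternatives. Residues with undefined accessibility are excluded.

    With ``distinct=True`` (default) each dataset is a :class:`VariantSet`
    of distinct records (rejection-sampled); with ``distinct=False`` the
    draws are independent with replacement and returned as plain record
    lists, the natural sampling model for occurrence-recovery experiments
    whose target size exceeds the distinct-variant pool.
    """
    rng = rng or np.random.default_rng(config.seed)
    functional_positions = functional_positions or set()
    from varstruct.scoring import load_blosum62

    blosum = load_blosum62()
    pool = []
    for (chain, number), rec in sorted(annotation.items(),
                                       key=lambda kv: (kv[1]["chain"],
                                                       int(kv[1]["number"]))):
        if rec["accessible"] is None or rec["chain"] not in accession_of_chain:
            continue
        pool.append((accession_of_chain[rec["chain"]], int(rec["number"]), rec))
    if not pool:
        raise ValueError("no annotated residues to sample from")
    out = {}
    for dataset in (datasets or sorted(config.n_variants)):
        weights = []
        for acc, pos, rec in pool:
            w = 1.0
            if not rec["accessible"]:
                w *= config.rho_acc[dataset]
            if _any_hbond(rec):
                w *= config.rho_hb[dataset]
            if (acc, pos) in functional_positions:
                w *= config.rho_fun[dataset]
            weights.append(w)
        weights = np.asarray(weights)
        if weights.sum() <= 0:
            raise ValueError("all sampling weights are zero")
        weights = weights / weights.sum()
        target = config.n_variants[dataset]

        beta = config.score_bias.get(dataset, 0.0) if config.score_bias else 0.0

        def draw(counter: int) -> VariantRecord:
            idx = int(rng.choice(len(pool), p=weights))
            acc, pos, rec = pool[idx]
            wt = rec["aa"]
            alternatives = [aa for aa in STANDARD_AA if aa != wt]
            if beta:
                kernel = np.array([np.exp(beta * blosum.score(wt, aa))
                                   for aa in alternatives])
                kernel /= kernel.sum()
                var = alternatives[int(rng.choice(19, p=kernel))]
            else:
                var = alternatives[int(rng.integers(19))]
            return VariantRecord(acc, pos, wt, var, dataset,
                                 annotation=f"synthetic:{dataset}",
                                 mim=600000 + counter
                                 if dataset == "SVD" else None)

        if distinct:
            chosen: dict[tuple, VariantRecord] = {}
            attempts = 0
            max_attempts = max(1000, target * 100)
            while len(chosen) < target and attempts < max_attempts:
                attempts += 1
                record = draw(len(chosen))
                chosen.setdefault(record.key, record)
            if len(chosen) < target:
                raise ValueError(
                    f"could not draw {target} distinct variants for {dataset}")
            out[dataset] = VariantSet(dataset, list(chosen.values()))
        else:
            out[dataset] = [draw(i) for i in range(target)]
    return out


def simulate_alignment(n_seqs: int, column_classes, concentrations: dict,
                       seed: int = 0, gap_fractions: dict | None = None
                       ) -> list[str]:
    """Columns drawn from Dirichlet-multinomial processes.

    ``column_classes`` lists one class label per column; ``concentrations``
    maps label -> symmetric Dirichlet concentration over the 20 residues (a
    scalar) or a length-20 vector. ``gap_fractions`` optionally maps a label
    to the fraction of sequences gapped at such columns.
    """
    if n_seqs < 3:
        raise ValueError("alignments need at least 3 sequences")
    rng = np.random.default_rng(seed)
    gap_fractions = gap_fractions or {}
    columns = []
    for label in column_classes:
        alpha = concentrations[label]
        alpha = (np.full(20, float(alpha)) if np.isscalar(alpha)
                 else np.asarray(alpha, dtype=float))
        p = rng.dirichlet(alpha)
        letters = [STANDARD_AA[i] for i in rng.choice(20, size=n_seqs, p=p)]
        gap_frac = gap_fractions.get(label, 0.0)
        if gap_frac > 0:
            n_gap = int(round(gap_frac * n_seqs))
            for i in rng.choice(n_seqs, size=n_gap, replace=False):
                letters[i] = "-"
        columns.append(letters)
    return ["".join(col[i] for col in columns) for i in range(n_seqs)]


def simulate_family_alignment(ref_seq: str, conserved_positions: set,
                              config: SimulationConfig, seed: int = 0
                              ) -> list[str]:
    """A family alignment whose first row is the (ungapped) reference.

    Conserved positions put Dirichlet weight ``conc_conserved`` on the
    reference letter, variable positions ``conc_variable``; a random subset
    of columns is gapped in non-reference rows at ``gap_fraction`` so the
    downstream gap rule has work to do.
    """
    rng = np.random.default_rng(seed)
    n = config.n_alignment_seqs
    idx = {aa: i for i, aa in enumerate(STANDARD_AA)}
    rows = [list(ref_seq)] + [[""] * len(ref_seq) for _ in range(n - 1)]
    for j, aa in enumerate(ref_seq):
        conc = (config.conc_conserved if (j + 1) in conserved_positions
                else config.conc_variable)
        alpha = np.full(20, 0.05)
        alpha[idx[aa]] += conc
        p = rng.dirichlet(alpha)
        for i in range(1, n):
            rows[i][j] = STANDARD_AA[int(rng.choice(20, p=p))]
    n_gap_cols = int(round(config.gap_column_fraction * len(ref_seq)))
    if n_gap_cols:
        gap_cols = rng.choice(len(ref_seq), size=n_gap_cols, replace=False)
        n_gapped = int(round(config.gap_fraction * n))
        for j in gap_cols:
            for i in rng.choice(np.arange(1, n), size=min(n_gapped, n - 1),
                                replace=False):
                rows[i][j] = "-"
    return ["".join(r) for r in rows]


def config_to_dict(config: SimulationConfig) -> dict:
    return asdict(config)


def write_demo_workspace(root, config: SimulationConfig | None = None) -> dict:
    """Materialize a complete synthetic workspace for the pipeline.

    Generates two structures (a mixed-secondary-structure chain and a 3x3
    helix bundle), per-chain database sequences, variant tables for the four
    classes with the configured environment biases (plus a few decoy
    disease rows that the Mendelian filter must remove), functional
    features, family alignments whose conserved columns follow burial, and
    the plain-text pipeline configuration. Returns a summary dict.
    """
    from pathlib import Path

    from varstruct.annotate import AnnotationConfig, annotate_structure
    from varstruct.functional import FunctionalFeature, write_features
    from varstruct.pdbio import write_pdb
    from varstruct.variants import write_variant_table

    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    root = Path(root)
    for sub in ("structures", "variants", "alignments"):
        (root / sub).mkdir(parents=True, exist_ok=True)

    structures = {
        "SYN1": build_ideal_structure(mixed_chain_recipe(),
                                      seed=int(rng.integers(2 ** 31))),
        "SYN2": build_ideal_structure(bundle_recipe(),
                                      seed=int(rng.integers(2 ** 31))),
    }
    ann_config = AnnotationConfig()
    chain_rows = []
    merged_annotation = {}
    accession_of = {}
    sequences = {}
    for sid, chains in structures.items():
        write_pdb(chains, root / "structures" / f"{sid}.pdb")
        annotation = annotate_structure(chains, ann_config)
        for (chain, number), rec in annotation.items():
            acc = f"{sid}{chain}"
            rec = dict(rec)
            rec["chain"] = acc
            merged_annotation[(acc, number)] = rec
            accession_of[acc] = acc
        for chain, residues in chains.items():
            acc = f"{sid}{chain}"
            chain_rows.append((acc, sid, chain))
            sequences[acc] = "".join(r.aa for r in residues)

    with open(root / "chains.tsv", "w", encoding="utf-8") as fh:
        fh.write("accession\tstructure\tchain\n")
        for acc, sid, chain in chain_rows:
            fh.write(f"{acc}\t{sid}\t{chain}\n")
    with open(root / "sequences.fasta", "w", encoding="utf-8") as fh:
        for acc in sorted(sequences):
            fh.write(f">{acc}\n{sequences[acc]}\n")

    # functional features: a handful of sites per accession
    features = []
    for acc in sorted(sequences):
        seq = sequences[acc]
        n = len(seq)
        positions = rng.choice(np.arange(1, n + 1), size=min(6, n),
                               replace=False)
        positions = [int(p) for p in positions]
        features.append(FunctionalFeature(acc, "ACT_SITE", positions[0],
                                          positions[0]))
        features.append(FunctionalFeature(acc, "METAL", positions[1],
                                          positions[1]))
        start = min(positions[2], max(1, n - 4))
        features.append(FunctionalFeature(acc, "NP_BIND", start,
                                          min(n, start + 4)))
        a, b = sorted((positions[3], positions[4]))
        if a < b:
            features.append(FunctionalFeature(acc, "DISULFID", a, b))
    write_features(features, root / "features.tsv")
    functional_positions = {(f.accession, pos)
                            for f in features for pos in f.residues()}

    variant_sets = simulate_variants(merged_annotation, config, accession_of,
                                     functional_positions, rng=rng)
    for label, vset in variant_sets.items():
        path = root / "variants" / f"{label}.tsv"
        write_variant_table(vset, path)
        if label == "SVD":
            # decoys the Mendelian filter must drop: cancer token / no MIM
            acc = chain_rows[0][0]
            keys = vset.keys()
            decoys = []
            for pos, annotation, mim in (
                    (1, "synthetic breast carcinoma", "600999"),
                    (2, "synthetic unassigned disease", "")):
                wt = sequences[acc][pos - 1]
                var = next(aa for aa in STANDARD_AA if aa != wt
                           and (acc, pos, wt, aa) not in keys)
                decoys.append(f"{acc}\t{pos}\t{wt}\t{var}\tSVD\t"
                              f"{annotation}\t{mim}\n")
            with open(path, "a", encoding="utf-8") as fh:
                fh.writelines(decoys)

    # family alignments: conserved columns follow burial
    for acc in sorted(sequences):
        conserved = {int(number)
                     for (a, number), rec in merged_annotation.items()
                     if a == acc and rec["accessible"] is False}
        rows = simulate_family_alignment(sequences[acc], conserved, config,
                                         seed=int(rng.integers(2 ** 31)))
        with open(root / "alignments" / f"{acc}.fasta", "w",
                  encoding="utf-8") as fh:
            for i, row in enumerate(rows):
                name = acc if i == 0 else f"{acc}_hom{i}"
                fh.write(f">{name}\n{row}\n")

    (root / "config.txt").write_text(
        "# varstruct pipeline configuration (KEY = VALUE)\n"
        f"seed = {config.seed}\n"
        "acc_cutoff_pct = 7.0\n"
        "hb_dist = 3.5\n"
        "hb_dist_sulphur = 4.0\n"
        "peptide_bond_max = 2.5\n"
        "ppi_cutoff = 5.0\n"
        "identity_threshold = 0.80\n"
        "length_tolerance = 0.30\n"
        "max_gap_fraction = 0.5\n"
        "min_sequences = 3\n",
        encoding="utf-8")
    return {
        "structures": sorted(structures),
        "accessions": sorted(sequences),
        "n_variants": {label: len(vset)
                       for label, vset in variant_sets.items()},
        "n_features": len(features),
    }
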