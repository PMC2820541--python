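"""End-to-end orchestration over a workspace directory.

A workspace contains (or `simulate` generates) structures, variant tables,
sequences, alignments and a feature table:

    workspace/
      structures/<id>.pdb
      variants/{SVD,SVP,SAP,CSM}.tsv
      sequences.fasta            # database (SP) sequence per accession
      alignments/<accession>.fasta
      features.tsv
      chains.tsv                 # accession <TAB> structure id <TAB> chain

Outputs are plain TSV tables under workspace/output plus a JSON run
manifest (config snapshot, input digests, seed, output inventory). Reruns
on identical inputs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

import varstruct
from varstruct.annotate import AnnotationConfig, annotate_structure, annotation_table
from varstruct.conservation import (
    alignment_entropy_profile,
    positions_to_columns,
    variant_entropy,
)
from varstruct.functional import (
    functional_occupancy,
    interface_residues,
    parse_features,
    write_features,
)
from varstruct.mapping import double_map, map_variants
from varstruct.pdbio import read_structure_residues
from varstruct.properties import CLASS_ORDER, build_matrix, matrix_distance
from varstruct.scoring import (
    estimate_esst,
    load_blosum62,
    negative_fraction,
    score_variant_sets,
    write_esst,
)
from varstruct.stats import enrichment, occurrence_table, wilcoxon_rank_sum
from varstruct.variants import filter_mendelian, parse_variant_table

log = logging.getLogger("varstruct.pipeline")

DATASETS = ("SVD", "SVP", "SAP", "CSM")
FLOAT_FORMAT = "%.6g"


def read_config_file(path) -> dict:
    """Parse the plain KEY = VALUE pipeline configuration file."""
    values: dict = {}
    for ln in Path(path).read_text(encoding="utf-8").splitlines():
        ln = ln.split("#", 1)[0].strip()
        if not ln:
            continue
        key, _, raw = ln.partition("=")
        raw = raw.strip()
        try:
            value = json.loads(raw)
        except json.JSONDecodeError:
            value = raw
        values[key.strip()] = value
    return values


def annotation_config_from(values: dict) -> AnnotationConfig:
    fields = AnnotationConfig.__dataclass_fields__
    kwargs = {k: v for k, v in values.items() if k in fields}
    return AnnotationConfig(**kwargs)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_tsv(frame: pd.DataFrame, path: Path, index=True) -> None:
    frame.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index=index)


class Workspace:
    """File layout helper for a pipeline run."""

    def __init__(self, root):
        self.root = Path(root)
        self.structures = self.root / "structures"
        self.variants = self.root / "variants"
        self.alignments = self.root / "alignments"
        self.output = self.root / "output"

    def structure_files(self):
        return sorted(self.structures.glob("*.pdb"))

    def variant_files(self):
        return {p.stem: p for p in sorted(self.variants.glob("*.tsv"))}

    def alignment_files(self):
        return {p.stem: p for p in sorted(self.alignments.glob("*.fasta"))}

    def chain_table(self) -> list[tuple[str, str, str]]:
        rows = []
        for ln in (self.root / "chains.tsv").read_text().splitlines():
            if not ln.strip() or ln.startswith("accession"):
                continue
            acc, sid, chain = ln.split("\t")
            rows.append((acc, sid, chain))
        return rows


def run_pipeline(workspace, config: dict | None = None,
                 min_identity: float = 0.90) -> dict:
    """Run every stage on a workspace; returns the manifest dict."""
    ws = Workspace(workspace)
    config = dict(config or {})
    ann_config = annotation_config_from(config)
    ws.output.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package_version": varstruct.__version__,
        "config": {**asdict(ann_config),
                   **{k: v for k, v in config.items()
                      if k not in AnnotationConfig.__dataclass_fields__}},
        "inputs": {}, "outputs": [], "counters": {},
    }

    # --- load inputs ------------------------------------------------------
    sp_seqs = {rec.id: str(rec.seq)
               for rec in SeqIO.parse(ws.root / "sequences.fasta", "fasta")}
    structures = {}
    for path in ws.structure_files():
        residues, seqres = read_structure_residues(path)
        structures[path.stem] = (residues, seqres)
        manifest["inputs"][str(path.relative_to(ws.root))] = _digest(path)

    variant_sets = {}
    for label, path in ws.variant_files().items():
        vset = parse_variant_table(path, label)
        if label == "SVD":
            before = len(vset)
            vset = filter_mendelian(vset)
            manifest["counters"]["svd_filtered_out"] = before - len(vset)
        variant_sets[label] = vset
        manifest["inputs"][str(path.relative_to(ws.root))] = _digest(path)

    # --- stage: annotate --------------------------------------------------
    annotations = {}
    for sid, (residues, _seqres) in sorted(structures.items()):
        ann = annotate_structure(residues, ann_config)
        annotations[sid] = ann
        table = annotation_table(ann).sort_values(["chain", "number"],
                                                  key=_sort_key)
        _write_tsv(table, ws.output / f"annotation_{sid}.tsv", index=False)
        manifest["outputs"].append(f"annotation_{sid}.tsv")
    log.info("annotated %d structures", len(annotations))

    # --- stage: map -------------------------------------------------------
    env_by_key = {}           # variant key -> StructuralEnvironment
    acc_flag_by_key = {}      # variant key -> accessible bool
    envs_by_dataset = {d: [] for d in variant_sets}
    accession_of_chain = {}
    mapped_counters = {d: {"anchored": 0, "unmapped": 0, "wt_mismatch": 0}
                       for d in variant_sets}
    for acc, sid, chain in ws.chain_table():
        if sid not in structures or acc not in sp_seqs:
            log.warning("chain table entry %s/%s:%s has no inputs; skipped",
                        acc, sid, chain)
            continue
        residues_by_chain, seqres = structures[sid]
        if chain not in residues_by_chain:
            continue
        accession_of_chain[(sid, chain)] = acc
        residues = residues_by_chain[chain]
        rmap = double_map(sp_seqs[acc], seqres[chain] or
                          "".join(r.aa for r in residues), residues,
                          accession=acc, structure_id=sid, chain=chain,
                          min_identity=min_identity)
        if not rmap.accepted:
            continue
        ann = annotations[sid]
        for label, vset in variant_sets.items():
            sub = [r for r in vset if r.accession == acc]
            from varstruct.variants import VariantSet
            anchored, counters = map_variants(VariantSet(label, sub), rmap,
                                              residues)
            for k in counters:
                mapped_counters[label][k] += counters[k]
            for rec, res in anchored:
                env = ann[res.key]["env"]
                if env is None:
                    continue
                env_by_key[rec.key] = env
                acc_flag_by_key[rec.key] = env.accessible
                envs_by_dataset[label].append(env)
    manifest["counters"]["mapping"] = mapped_counters

    # --- stage: occurrence ------------------------------------------------
    background_envs = [rec["env"]
                       for sid in sorted(annotations)
                       for rec in annotations[sid].values()]
    occurrence = occurrence_table(envs_by_dataset, background_envs)
    _write_tsv(occurrence, ws.output / "occurrence.tsv")
    manifest["outputs"].append("occurrence.tsv")
    enrich_rows = []
    for cat in occurrence.index:
        if cat == "n":
            continue
        bg = occurrence.loc[cat, "background"]
        for dataset in variant_sets:
            if dataset not in occurrence.columns or not bg > 0:
                continue
            e = enrichment(occurrence.loc[cat, dataset], bg)
            enrich_rows.append({"category": cat, "dataset": dataset,
                                "observed_pct": occurrence.loc[cat, dataset],
                                "background_pct": bg,
                                "enrichment_raw": e["raw"],
                                "enrichment_display": e["display"]})
    _write_tsv(pd.DataFrame(enrich_rows), ws.output / "enrichment.tsv",
               index=False)
    manifest["outputs"].append("enrichment.tsv")

    # --- stage: ESST estimation + scoring ---------------------------------
    alignment_rows = {}
    for acc, path in ws.alignment_files().items():
        seqs = [str(r.seq) for r in SeqIO.parse(path, "fasta")]
        if seqs:
            alignment_rows[acc] = seqs
            manifest["inputs"][str(path.relative_to(ws.root))] = _digest(path)
    annotated_columns = []
    chain_of_acc = {acc: (sid, chain) for acc, sid, chain in ws.chain_table()}
    for acc in sorted(alignment_rows):
        if acc not in chain_of_acc:
            continue
        sid, chain = chain_of_acc[acc]
        if sid not in annotations:
            continue
        ann = annotations[sid]
        residues = structures[sid][0].get(chain, [])
        colmap = positions_to_columns(alignment_rows[acc][0])
        col_env = {col: ann[res.key]["env_code"]
                   for pos, col in colmap.items()
                   if pos - 1 < len(residues)
                   for res in [residues[pos - 1]]}
        for col, code in col_env.items():
            if code is None:
                continue
            column = "".join(row[col - 1] for row in alignment_rows[acc])
            annotated_columns.append((code, column))
    blosum = load_blosum62()
    esst = None
    if annotated_columns:
        esst = estimate_esst(annotated_columns, name="estimated",
                             environments=range(64))
        write_esst(esst, ws.output / "esst.txt")
        manifest["outputs"].append("esst.txt")
    scores = score_variant_sets(variant_sets.values(), blosum, esst,
                                env_by_key)
    scores = scores.sort_values(["dataset", "accession", "position",
                                 "var_aa"]).reset_index(drop=True)
    _write_tsv(scores, ws.output / "scores.tsv", index=False)
    manifest["outputs"].append("scores.tsv")
    neg = negative_fraction(scores, "blosum62").reset_index()
    _write_tsv(neg, ws.output / "negative_fractions.tsv", index=False)
    manifest["outputs"].append("negative_fractions.tsv")

    # --- stage: rank-sum comparisons ---------------------------------------
    stat_rows = []
    labels = sorted(variant_sets)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            xa = scores.loc[scores.dataset == a, "blosum62"].dropna()
            xb = scores.loc[scores.dataset == b, "blosum62"].dropna()
            if len(xa) and len(xb):
                w, p = wilcoxon_rank_sum(xa, xb)
                stat_rows.append({"comparison": f"{a}-vs-{b}",
                                  "stratum": "all", "statistic": w,
                                  "p_value": p, "n_x": len(xa), "n_y": len(xb)})
    for label in labels:
        sub = scores[(scores.dataset == label) & scores.esst.notna()]
        core = sub.loc[sub.accessible == False, "esst"]  # noqa: E712
        surf = sub.loc[sub.accessible == True, "esst"]   # noqa: E712
        if len(core) and len(surf):
            w, p = wilcoxon_rank_sum(core, surf)
            stat_rows.append({"comparison": f"{label}: core-vs-surface",
                              "stratum": "esst", "statistic": w, "p_value": p,
                              "n_x": len(core), "n_y": len(surf)})
    _write_tsv(pd.DataFrame(stat_rows), ws.output / "wilcoxon.tsv", index=False)
    manifest["outputs"].append("wilcoxon.tsv")

    # --- stage: property matrices -----------------------------------------
    matrices = {label: build_matrix(vset) for label, vset in
                sorted(variant_sets.items())}
    prop_frames = []
    for label, matrix in matrices.items():
        frame = matrix.to_frame()
        frame.insert(0, "dataset", label)
        prop_frames.append(frame.reset_index(names="wt_class"))
    _write_tsv(pd.concat(prop_frames, ignore_index=True),
               ws.output / "property_matrices.tsv", index=False)
    manifest["outputs"].append("property_matrices.tsv")
    dist_rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            dist_rows.append({"a": a, "b": b,
                              "frobenius": matrix_distance(matrices[a],
                                                           matrices[b])})
    _write_tsv(pd.DataFrame(dist_rows), ws.output / "property_distances.tsv",
               index=False)
    manifest["outputs"].append("property_distances.tsv")

    # --- stage: entropy -----------------------------------------------------
    if alignment_rows:
        profiles = {}
        for acc, rows in sorted(alignment_rows.items()):
            profiles[acc] = alignment_entropy_profile(rows, alignment_id=acc)
        profile_table = pd.concat(profiles.values(), ignore_index=True)
        _write_tsv(profile_table, ws.output / "entropy_profiles.tsv",
                   index=False)
        manifest["outputs"].append("entropy_profiles.tsv")
        references = {acc: rows[0] for acc, rows in alignment_rows.items()}
        ent, counters = variant_entropy(variant_sets.values(), profiles,
                                        references, acc_flag_by_key)
        ent = ent.sort_values(["dataset", "accession",
                               "position"]).reset_index(drop=True)
        _write_tsv(ent, ws.output / "entropy_variants.tsv", index=False)
        manifest["outputs"].append("entropy_variants.tsv")
        manifest["counters"]["entropy"] = counters
    else:
        log.warning("no alignments in workspace; entropy stage skipped")

    # --- stage: functional ---------------------------------------------------
    features_path = ws.root / "features.tsv"
    features = parse_features(features_path) if features_path.exists() else []
    ppi = []
    for sid, (residues_by_chain, _seqres) in sorted(structures.items()):
        names = {chain: accession_of_chain.get((sid, chain), f"{sid}:{chain}")
                 for chain in residues_by_chain}
        ppi.extend(interface_residues(residues_by_chain,
                                      cutoff=float(config.get("ppi_cutoff", 5.0)),
                                      accession_of_chain=names))
    all_features = features + ppi
    if all_features:
        write_features(ppi, ws.output / "ppi_features.tsv")
        manifest["outputs"].append("ppi_features.tsv")
        occupancy = functional_occupancy(all_features, variant_sets.values())
        _write_tsv(occupancy, ws.output / "functional_occupancy.tsv")
        manifest["outputs"].append("functional_occupancy.tsv")

    manifest_path = ws.output / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True,
                                        default=str) + "\n", encoding="utf-8")
    return manifest


def _sort_key(col: pd.Series) -> pd.Series:
    try:
        return col.astype(int)
    except (ValueError, TypeError):
        return col
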