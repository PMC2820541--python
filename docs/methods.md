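# Methods

This note documents the models, conventions and design choices behind
`varstruct`, the parameters that matter, and what the synthetic-data
generator does and does not emulate.

## Structural environment annotation

**Backbone torsions.** φ(i) is the dihedral C(i−1)–N(i)–CA(i)–C(i), ψ(i)
is N(i)–CA(i)–C(i)–N(i+1), both in degrees in (−180, 180]. Torsions are
undefined at chain termini and across chain breaks; a break is declared
when the C(i)–N(i+1) distance exceeds `peptide_bond_max` (default 2.5 Å).

**Secondary structure** is assigned from torsions alone, which keeps the
rule fully reproducible:

- **P** (positive φ): φ > 0, always wins. This conformation is strained for
  most L-amino acids and is typically tolerated by Gly, Asn and Asp.
- **H** (α-helix): φ ∈ (−100°, −30°) and ψ ∈ (−80°, −5°) in runs of ≥ 4.
- **E** (β-strand): φ ∈ (−180°, −45°) and ψ ∈ (45°, 180°] in runs of ≥ 3.
- **C** (coil): everything else, including residues with undefined torsions.

All windows and run lengths are fields of `AnnotationConfig`. Hydrogen-bond
patterns are deliberately not used (no DSSP-style energy term): the
assignment must be computable from coordinates alone and invertible on the
generator's ideal segments.

**Solvent accessibility.** Per-atom SASA uses the Shrake–Rupley method
with a deterministic golden-spiral point set (default 960 points), probe
radius 1.4 Å and Chothia-style heavy-atom radii grouped by element
(C 1.87, N 1.65, O 1.40, S 1.85, Se/P 1.90 Å). Relative side-chain
accessibility of a residue is its summed side-chain atom SASA as a
percentage of the same residue type's side-chain SASA in an ideal extended
Gly-X-Gly tripeptide (φ = −139°, ψ = 135°) computed with identical
parameters — a self-consistent reference rather than a published table, so
the X-in-GXG value is exactly 100 % by construction. Glycine's "side chain"
is its CA (the NACCESS convention). A residue is **inaccessible** when the
value is below 7.0 %; a value exactly at the cutoff counts as accessible
(`accessible_at_cutoff`). Residues with no resolved side-chain atoms have
undefined accessibility and are excluded from environment-stratified
statistics (they are logged and counted).

**Side-chain hydrogen bonds.** A bond is a donor/acceptor heavy-atom pair
within 3.5 Å (4.0 Å when either atom is sulphur or selenium); no angle
term and no explicit hydrogens. Ties at the cutoff count as bonded (a 1e-9
float tolerance). Same-residue pairs are excluded; sequence neighbours are
allowed. Three per-residue flags are derived — side chain to main-chain
amide (the backbone N must be the donor, so the side-chain partner must be
an acceptor; Pro N is excluded), side chain to main-chain carbonyl, and
side chain to side chain — and multiple bonds of one type still set one
flag. The donor/acceptor dictionary treats Ser/Thr/Tyr hydroxyls, His ring
nitrogens and Cys SG as ambivalent; Met SD accepts only. Donor/acceptor
chemistry checking can be disabled (`require_hb_chemistry=False`), in which
case any two hydrogen-bond-capable atoms within the cutoff count.

**Environment code.** (ss, accessible, hb_nh, hb_co, hb_sc) is encoded as
`ss_index*16 + accessible*8 + hb_nh*4 + hb_co*2 + hb_sc` with ss order
HECP — a bijection onto 0–63.

## Sequence-to-structure mapping

The double-map composes two global pairwise alignments through the SEQRES
record: SEQATM (one letter per residue with coordinates, modified residues
mapped to parents via a synonym table) against SEQRES with mismatches
effectively forbidden (match +1, mismatch −100), and SEQRES against the
database sequence with BLOSUM62, gap open 11 / extend 1 (the classic
protein-alignment parameterization; the aligner itself is
`Bio.Align.PairwiseAligner`). A database position maps to a structure
residue only when aligned non-gap in both alignments; the mapping is
monotone and one-to-one by construction. Mappings whose composed identity
over aligned columns is below `min_identity` (default 0.90, a configuration
default rather than an externally fixed truth) are rejected. Anchoring a
variant additionally requires the wild-type amino acid to equal the
structure residue's type; mismatches are dropped and counted, which guards
the environment statistics against coordinate drift.

## Substitution scoring

BLOSUM62 ships as an NCBI-layout text file and is parsed bit-exactly
(row = wild type, column = variant; the matrix is symmetric and checked
entry-by-entry against an independent copy in the tests). ESSTs hold one
20×20 table per declared environment in a plain text format (`>ENV <code>`
header followed by a whitespace-separated matrix in ARNDCQEGHILKMFPSTWYV
order); tables may be asymmetric.

`estimate_esst` is a deliberately **simplified** estimator, not a
re-implementation of the production ESST build (no sequence weighting, no
smoothing across environments): within each environment it counts ordered
residue pairs in alignment columns labelled with that environment, adds a
unit pseudocount, and scores
`round(2·log2(P(b|a,e)/f(b)))` — half-bit log-odds against the pooled
residue background over all columns. Environments with no observed columns
are filled from the pooled, environment-free estimate and flagged
(`ESST.pooled_envs`). The estimator recovers the qualitative structure the
pipeline needs (positive diagonals for conserved environments, lower
off-diagonal scores in more conserved environments) and is exercised as
such in the tests.

## Conservation

Column entropy is Shannon entropy over the 20 standard amino-acid
frequencies, natural log by default (range [0, ln 20 ≈ 3.00] nats; the base
is configurable since only orderings and distribution comparisons are
used). Columns are skipped when the family has fewer than 3 sequences or
when gaps occupy **strictly more than** 50 % of sequences; the gap fraction
is taken over all sequences while gaps (and non-standard letters, logged)
are excluded from the frequencies. Variant-level records are stratified by
dataset and by the accessibility of the mapped residue.

## Occurrence, enrichment and testing

The occurrence table reports, per dataset and for a background residue
set, the percentage of entries in each structural category. The four
secondary-structure rows of a column partition (sum to 100 up to
rounding); the three hydrogen-bond rows and the burial row are independent
flags. Denominators (the `n` row) are reported alongside, and only
variants with a defined annotation enter them. Enrichment is
100·(observed/background − 1); the display value rounds **toward zero** to
an integer while the raw value is always emitted alongside.

The Wilcoxon rank-sum test is two-sided with midranks for ties; the
p-value is exact when the pooled sample has ≤ 20 observations and no ties,
otherwise a normal approximation with tie and continuity corrections
(scipy's Mann–Whitney machinery underneath; an enumeration oracle checks
the exact branch in the tests). No multiple-testing correction is applied —
the report carries raw p-values with sample sizes.

Representative-domain selection per family: drop NMR entries and
resolution worse than 2.5 Å; drop domains whose sequence length falls
outside (1 ± 0.3) × the family mean (mean taken after the resolution
filter); greedily cluster longest-first at ≥ 80 % global-alignment identity
(matches / alignment length); keep the best-resolution member per cluster.
The greedy clusterer is a deterministic stand-in for a general-purpose
redundancy tool and is documented as such.

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of (configuration, seed).

**Structures** are built from internal coordinates (N–CA 1.458, CA–C 1.525,
C–N 1.329 Å, ω = 180°) with one canonical rotamer per residue type; helix
segments use φ/ψ = −57°/−47°, strands −139°/135°, positive-φ +60°/+45°,
and coil torsions are sampled from a box (φ ∈ (−180°, −110°),
ψ ∈ (−30°, 40°)) disjoint from the three labelled windows so construction
labels are unambiguous. No clash relief or packing optimization is done —
the structures are topologically and geometrically plausible, not
physically realistic. The demo set pairs a mixed-segment single chain with
a 3×3 grid of parallel helices (spacing 9.5 Å) whose central chains are
genuinely buried and whose chain contacts exercise interface detection.

**Variants** are drawn residue-by-residue with selection odds multiplied by
ρ_acc when buried, ρ_hb when any H-bond flag is set and ρ_fun at
functional residues. Defaults (the demo's study conditions, chosen once):
disease-like SVD ρ_acc = 3, ρ_hb = 2; cancer-like CSM 1.5/1.5;
polymorphism-like SVP/SAP 0.5/0.8 with functional avoidance ρ_fun = 0.3.
The variant amino acid follows a substitution-severity kernel
P(var|wt) ∝ exp(β·BLOSUM62(wt,var)) with β = −0.5 (SVD), −0.25 (CSM),
+0.5 (SVP/SAP), so disease-like sets prefer drastic changes and
polymorphism-like sets conservative ones. Distinct-record sets are
rejection-sampled; recovery experiments whose target exceeds the distinct
pool use independent draws with replacement (`distinct=False`), the
sampling model under which the binomial recovery interval is exact.

**Alignments** draw each column from a Dirichlet–multinomial; the family
generator puts Dirichlet weight 25 (conserved, used at buried positions)
or 0.8 (variable) on the reference letter, and gaps 60 % of the
non-reference rows in a random 5 % of columns so the gap-skip rule fires.

Passing tests on these fixtures demonstrate that the machinery measures
what it claims (construction labels are recovered, injected odds ratios
are estimated within binomial error, conserved placement lowers measured
entropy). They do **not** demonstrate anything about real proteomes: real
structures have correlated environments, real variant ascertainment is
biased in ways no odds ratio captures, and real alignments have
phylogenetic correlation that Dirichlet columns lack.

## Numerical and interface choices

- SASA point sets are deterministic; doubling the density changes totals by
  well under 1 % on small clusters, and areas are rotation/translation
  invariant to sampling tolerance.
- All pipeline outputs are TSV with `%.6g` floats and sorted, deterministic
  row order; reruns on identical inputs are byte-identical, and the run
  manifest records the configuration, input digests and output inventory.
- The pipeline configuration is a single plain KEY = VALUE text file in
  which each threshold (7.0 % accessibility, 3.5/4.0 Å, 2.5 Å peptide bond,
  80 % identity, ±0.3 length tolerance, 50 % gap rule, 3-sequence minimum)
  appears exactly once.
- Demo problem sizes (two structures, 192 residues, 400 variants per class,
  12-sequence alignments) keep the full default demo far under five minutes
  on one CPU while leaving every statistic well-populated; recovery
  property tests use 5000 draws where binomial precision matters.
- Known limitations: torsion-only secondary structure differs from
  hydrogen-bond-based assignments near segment edges; the simplified ESST
  estimator is not comparable in absolute value to published ESSTs; the
  interface detector is a plain heavy-atom contact criterion (5.0 Å) with
  no interaction typing; representative selection uses greedy clustering,
  which can split clusters a global method would merge.
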