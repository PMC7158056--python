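# Methods

`olesuite` re-creates, at desk scale and on synthetic data, the
computational chain behind a comparative survey of bacterial olefin
biosynthesis: find *oleABCD* gene clusters in genomes, relate the OleA
condensing enzymes to each other in a sequence similarity network, map
cluster presence onto a species phylogeny, quantify GC/MS olefin and
fatty-acid profiles, and model how the olefin product spectrum follows
from precursor supply and OleA substrate specificity. This note records
the models, the defaults and their reasons, the numerical choices, and
what the synthetic benchmarks do and do not establish.

## Motif screen

OleA candidates are proteins matching the compact PROSITE-style pattern
`EPxx[AS]x(14,18)DxxNACL`: literals, `x` wildcards, `[..]` choice sets,
`{..}` exclusion sets (supported for pattern-language completeness), and
repeat suffixes binding to the preceding element. Scanning reports every
start position that admits a match and, per start, the *shortest*
admissible span (lazy gap). This is deterministic and sufficient because
downstream stages only consume "has at least one hit". Ambiguity codes
(B, Z, X) in input sequences satisfy wildcards only — a conservative
choice that can only lose borderline candidates, never invent them.
Coordinates are 0-based half-open internally and 1-based inclusive in
TSV/CLI output. Anchors (`<`, `>`) and PSSM scanning are out of scope.

## Local alignment and E-values

Homology checks use an affine-gap Smith–Waterman over BLOSUM62 with gap
costs open 11, extend 1; a gap of length *k* costs `11 + k` (the
convention under which BLAST's "11/1" defaults are usually quoted — the
convention matters only for consistency, and the brute-force oracle in
the test suite shares it). The traceback is made unique by fixing the
end cell to the earliest best-scoring cell in row-major order and
breaking step ties diagonal > up > left. Percent identity divides
identities by the full alignment length *including gap columns*; some
convention must be fixed for the 75% node collapse to be deterministic,
and this is the most conservative one. Significance is the
Karlin–Altschul expectation `E = K·m·n·exp(−λS)` on the raw score with
the published gapped BLOSUM62(11,1) constants λ = 0.267, K = 0.041.
Raw-score E-values are monotone-equivalent to bit-score ones for
thresholding, which is all the pipeline does with them (`E ≤ 1e-5`).
The DP kernel is numba-jitted; scores are exact integers. Degenerate
case: when no cell scores above zero the hit has score 0, empty spans
and 0% identity.

## Cluster detection

A genome is screened in two steps. (1) Motif scan of every annotated
protein yields *oleA* candidates. (2) Each candidate is verified by
aligning two queries — OleBC (the fused dehydrogenase/lactone-synthetase
gene as in *M. luteus*) and OleD — against every *other* gene on the
same contig whose span intersects the candidate's gene span extended by
±5000 bp. Both queries must hit at `E ≤ 1e-5`; the best-E hit per query
is recorded with the boundary-to-boundary distance (0 if spans overlap).
Design choices that the window rule leaves open were fixed as: the
window anchors on the gene span (the most permissive deterministic
reading of "± 5000 bp"), hits to the *oleA* gene itself never count as
OleBCD evidence, neighbors on other contigs never qualify, and with
several candidates each is verified independently with the genome-level
call their OR. GenBank and GFF3+FASTA loaders convert 1-based inclusive
coordinates to the internal half-open convention; supplied translations
are used verbatim, otherwise CDSs are translated with the bacterial
code (table 11), minus strand from the reverse complement. Compound
(`join`) locations and pseudogenes are out of scope.

## Sequence similarity network

All n(n−1)/2 pairs are aligned; members linked by chains of pairwise
identity strictly above 75% collapse into one node (single-linkage
connected components — order-independent and reproducible, unlike greedy
centroid schemes; "higher than 75%" is read strictly). The node
representative is the longest member, ties by smallest id. Distinct
nodes are joined when any member pair aligns at `E < 1e-5`; the edge
stores the best member-pair score. Edges between nodes with different
phylum labels are reported as lateral-transfer candidates. For larger
inputs an optional 4-mer pre-filter skips alignments for pairs sharing
almost no 4-mers (shared fraction < 0.02 of the smaller 4-mer set); the
test suite checks on hundreds of pairs spanning 0–100% identity that no
pair at ≥ 70% alignment identity comes anywhere near the cut, so the
collapse graph is unaffected.

## Phylogenetic presence mapping

Presence/absence is attached to tree leaves from a species table;
species missing from the tree are reported, not fatal, and leaves
missing from the table are `unknown`. Genus-level ubiquity is the share
of genera whose presence fraction is exactly 0 or 1. "Presence
clusters" — the visual statistic of contiguous positive arcs on a
circular tree — are operationalized as maximal runs of present leaves in
a canonical ladderized leaf order (children sorted by subtree size, ties
by smallest leaf name), with runs separated by at most `gap_tolerance`
non-present leaves merging. The count is deterministic, invariant under
label renaming, and non-increasing in the tolerance; the tolerance is
exposed rather than guessed because the visual criterion it replaces has
no single canonical value.

## GC/MS quantification

Amounts are `area_analyte / area_IS × amount_IS / volume / OD600`, in
µg per mL culture per OD unit. Response factors default to 1 for every
analyte (areas compared directly, per the underlying protocol) and are
configurable. Internal-standard defaults follow the extraction recipes:
olefins, 4 mL hexane × 10 µg/mL triacontane = 40 µg (10 mL culture);
FAMEs, 0.5 mL × 100 µg/mL eicosanoic acid = 50 µg (2.5 mL culture).
Quantification is invariant to rescaling all areas jointly. An olefin
carries one branch state per chain end (iso, anteiso, or straight),
giving six unordered end-pair classes: isoiso, isoai, aiai, isosc, aisc,
scsc. OD normalization is linear division by the measured OD600; peak
identities are taken from the table labels (deconvolution and
retention-index work is upstream of this package).

## Condensation model

OleA joins two fatty-acyl chains head to head; after β-keto reduction
(OleD), lactonization (OleC) and decarboxylation (OleB) the olefin has
`n_i + n_j − 1` carbons and inherits one branch state per end. The model
treats the two substrate draws as independent with probability
`π_s ∝ w_s f_s` (specificity weight × pool abundance), so the unordered
pair {i, j} has probability `π_i π_j (2 − [i=j])` and pairs landing on
the same (chain length, isomer class) cell sum. This is the minimal
quantitative form of the claim that the olefin profile is set jointly by
the precursor pool and OleA substrate specificity; it ignores enzyme
kinetics and absolute flux deliberately — only the product
*distribution* is modelled, as no expression or activity data constrain
more. Weights are identified only up to scale; the anchor `Σ w_s f_s = 1`
over the reference pool fixes it. Weights are per (chain length,
branch) class, not per molecule; unsaturated and cyclic fatty-acid
species are excluded from the pool by default because the olefin tables
resolve only branch classes.

Fitting maximizes the multinomial likelihood of observed category counts
by EM over the latent substrate pair, from a uniform start: the E-step
splits each category count over its contributing pairs in proportion to
current pair probabilities; the M-step sets π proportional to expected
draw counts. The likelihood is non-decreasing by construction (asserted
per step in tests); iteration stops when `max|Δπ| < 1e-10` (default cap
5000 iterations — typical fits take tens). Observed categories
unreachable from the pool are an error, or reported and dropped with
`allow_slack`. The swap experiment predicts profiles under host and
donor weights on the *same* host pool and summarizes the shift (total
variation, modal-chain shift, per-class share deltas) — the
computational analogue of exchanging the *oleA* gene while the host's
fatty-acid supply stays fixed.

The shipped study conditions (`scenarios.py`) encode a
*Micrococcus-luteus*-like host (anteiso-dominated C13–C17 pool, no
straight chains, OleA preferring anteiso-C15 → modal product C29 aiai)
and a *Kocuria*-like donor (shorter, iso/straight-rich pool, OleA
preferring iso-C13 → C23–C25 products). With donor weights fitted to a
sampled donor profile (1e5 molecules) and applied to the host pool, the
modal product moves from C29 to C25, iso-branched classes gain ~0.87
share, and the scsc share is exactly 0 — pool-limited, since the host
pool has no straight-chain species.

## Synthetic data

Each generator is a pure function of (seed, parameters) with one
explicit NumPy `default_rng` stream and byte-identical re-runs; every
dataset carries a JSON truth record sufficient to compute the expected
output of the consuming stage.

* **Genome sets** plant a motif-bearing *oleA* with OleBC/OleD homologs
  (5% point mutations of the queries) within ±5000 bp, written as
  GenBank, GFF3 and FASTA. Decoy classes: motif destroyed by one
  forbidden residue at the D anchor; homologs moved 5500 bp away;
  OleD neighbor replaced by a residue-scrambled copy (same composition,
  E ≫ 1e-5 — confirmed empirically in the tests); homologs on a second
  contig. Background proteins are uniform over the 20 residues, so the
  expected number of chance motif hits is computable in closed form
  (≈ 4 × 10⁻¹⁰ per residue) and is asserted below 10⁻⁴ per generated
  dataset — small enough that the zero-noise benchmark is effectively
  deterministic.
* **Families** plant blocks with controlled identities: block members
  carry pairwise-disjoint substitution sets against a block ancestor
  (so within-block identity is exact by construction, and re-measured
  with the internal aligner to ±2 points; substitutions avoid the
  termini so local alignments span fully); block ancestors diverge from
  a common root to a between-block identity target, or are independent
  when the target is 0.
* **Trees** join random genus-monophyletic subtrees; exactly k genus
  blocks are made fully positive, chosen from the realized ladderized
  genus order so positive blocks are separated (needs 2k−1 ≤ n_genera),
  giving planted cluster count k and genus ubiquity 1.
* **Peak tables** draw multinomial molecule counts from the model's
  predicted distribution; areas are counts × response factor ×
  unit-mean lognormal noise with the requested coefficient of variation;
  the internal-standard row is appended with its known amount.

What the generators do *not* emulate: real codon usage or GC content,
sequence-composition biases, gene-density variation, chromatographic
peak shapes, co-eluting analytes, or phylogenetic signal in protein
divergence. Passing the planted benchmarks therefore demonstrates
correctness of the decision rules and estimators under their own
assumptions, not detection performance on real genomes or instruments.

## Problem sizes and determinism

The shipped analyses use 30 positive + 40 decoy genomes (~8–15 kb, 3–7
genes each), families of 8–14 sequences of length 150, trees of 16
genera / ~72 species, and 10⁵-molecule peak tables (10⁶ for the
sampling-error check); parameter recovery uses 20 seeded replicates of a
12-species pool. These sizes give exact or tightly-concentrated
statistics while every stage runs in seconds. All randomness flows
through explicit seeds; reruns are bit-reproducible.

## Known limitations

* E-values use fixed gapped constants on raw scores; they are threshold
  devices, not calibrated significance estimates for short sequences.
* The EFI-style collapse convention the SSN emulates is not published in
  detail; single-linkage at strict >75% is one defensible reading, and
  absolute node counts on external data will depend on it.
* The presence-cluster statistic depends on the canonical leaf order;
  counts on other ladderizations can differ for the same tree.
* The condensation model assumes independent substrate draws and class
  (not molecule) level weights; diene/polyene products and double-bond
  positions are out of scope.
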