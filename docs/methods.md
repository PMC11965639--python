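# Methods

This note documents the models and procedures `recip` implements, the
defaults and why they were chosen, what the synthetic data generator does and
does not emulate, and the numerical conventions used throughout.

## Coordinates and genome annotation

All intervals are 0-based half-open on the forward strand internally.
GenBank and GFF3 coordinates (1-based inclusive) are converted on input and
output, so a printed feature `101..400` becomes `[100, 400)` and interval
arithmetic (length, overlap) needs no ±1 bookkeeping. Overlap between a
coding sequence and a BGC region is `max(starts) < min(ends)` on the same
contig; a region ending exactly where a CDS begins does not overlap it.

CDS records carry the functional identifiers the reverse mapping needs: EC
numbers (four dot-separated fields, `-` allowed per field, e.g. `6.3.2.-`)
and COG identifiers (e.g. `COG1020`). GenBank parsing uses Biopython; GFF3
parsing uses gffutils, with translations taken from a companion protein
FASTA keyed by locus tag, or translated from the nucleotide sequence when
only that is available.

The packaged BRA006 region table stores the printed cells verbatim. Two
cells of one row carry obvious typographic slips (a truncated end coordinate
and a stray comma in a similarity cell); the loader substitutes a cleaned
numeric reading for that row and flags it `editorial`, keeping the verbatim
text alongside. Dual similarity cells like `92%/88%` are ordered
Illumina/MinION. Region lengths are always computed from coordinates, never
taken from prose.

## Cluster comparison

Query-cluster proteins are aligned against reference-cluster proteins with
Smith–Waterman local alignment under BLOSUM62, gap open 11 / extend 1 (the
conventional protein-BLAST scoring; a gap of length k costs 11 + k). Percent
identity is identical columns over alignment columns, the `pident` analogue.
Because co-optimal tracebacks exist, identity is computed on the
lexicographically ordered sequence pair, making score, identity and length
symmetric in argument order and deterministic across platforms.

Each query keeps its single highest-scoring hit. Raw alignment score stands
in for e-value ranking: with a single reference cluster there is no database
size to correct for, and for fixed scoring the highest-scoring pair is the
lowest-e-value pair. Ties break by higher identity, then lexicographic
reference locus tag. Hits scoring below 40 matrix units are suppressed
before selection — short spurious segment matches between unrelated proteins
rarely exceed this floor. The identity filter keeps hits *strictly above*
70 % by default.

Cluster-level similarity is the percent of reference genes receiving a
retained hit, rounded to the nearest integer — the convention behind
"most-similar known cluster" percentages in cluster-prediction reports.

Orientation is classified from Kendall's τ between query and reference gene
ordinals over the retained hits: colinear for τ ≥ 0.5, inverted for
τ ≤ −0.5, rearranged otherwise (and whenever fewer than three pairs matched,
with τ reported as 0). The ±0.5 thresholds sit far from both a complete
inversion (τ = −1) and perfect colinearity (τ = +1), so indels and local
shuffles do not flip the call.

## Molecular networking

The modified cosine weights peaks by the square root of intensity and admits
a fragment pair when the m/z values agree within 0.02 Da either directly or
after shifting one spectrum by the precursor mass difference. Candidate
pairs are accepted greedily by descending weight product, each peak used at
most once; the score is the accepted product sum over the product of vector
norms, clamped to [0, 1]. On spectra whose candidate pairs are unambiguous
(peak spacing above twice the tolerance) the greedy acceptance equals the
exhaustive matching optimum, which is how the tests validate it; an
independent reference implementation (matchms) is cross-checked in the test
suite, never used in the pipeline.

Edges are kept when cosine ≥ 0.7, at least 6 peak pairs matched, and the
edge ranks within the strongest 10 edges of both endpoints — the customary
feature-based molecular-networking defaults, all configurable. Nodes without
any surviving edge are excluded: the network counts only features with at
least one connection.

## Sequential annotation and composition

Three annotation sources are merged with strict precedence: spectral-library
matches (tier 1) first, network-propagated candidates (tier 2) only onto
nodes still empty, single-spectrum in-silico candidates (tier 3) onto the
remainder. Within a tier the highest score wins; exact score ties break by
lexicographic name so the merge is order-independent. Tier-2/3 candidate
tables are *inputs* — the propagation and structure-prediction tools that
produce them are out of scope; the package enforces only the sequential
semantics. Tier counts plus the unannotated remainder always equal the node
count.

Structure keys are normalized to uppercase InChIKeys when 27-character
key-shaped, else kept as raw SMILES text; the chemical-taxonomy lookup
(kingdom / superclass / class) is keyed on the normalized form, with missing
keys pooled under "None". Composition percentages are over annotated nodes,
rounded to one decimal.

Isomer candidates are node pairs whose precursor m/z agree within 20 ppm but
whose retention times differ by at least 1.0 min, restricted by default to
network neighbors (similar fragmentation). The 20 ppm tolerance is
deliberately loose relative to library-match mass errors of a few ppm —
feature-level m/z values are noisier than curated matches; the 1.0 min floor
operationalizes "very different retention time" on a typical 40-min
reversed-phase gradient.

## Reciprocal mapping

Compound names are compared after Unicode NFKD decomposition, casefolding
and removal of all non-alphanumerics, so `Cinerubin B` and `cinerubin-B`
match. Structure-key matching uses the first (skeleton) InChIKey block,
which ignores stereo/charge layers. Predicted compounds are grouped by
chemical class; "None" is not counted among the distinct classes.

EC matching is field-wise with `-` on *either* side matching anything —
genome annotations and pathway records both use partial ECs, so the wildcard
must be symmetric. A CDS matches a pathway enzyme if any of its EC numbers
matches or its COG equals the enzyme's; `matched_by` records which key(s)
fired so either convention can be audited downstream. Region ranking by
overlap count breaks ties lexicographically by region id for determinism.

Scaffold sharing in the neighborhood report is a caller-supplied flag per
structure key, not computed substructure chemistry: whether two candidate
structures share, say, an indole-like nucleus is a judgement the core stays
agnostic about, keeping the dependency surface small. A cheminformatics
adapter can populate the flags.

## Synthetic data

The generator emits a complete toy study whose planted facts mirror the
study design the package models: a pathway of **16** enzymes whose CDSs are
scattered over two contigs with **11** of them consecutive inside one
predicted BGC region (and one more inside a decoy region, so the ranking is
non-trivial); a molecular network of **90** connected nodes in **9**
components; annotation tiers of **(20, 50, 10)** nodes with 10 left
unannotated; a hub node with **7** neighbors of which **6** share its
scaffold, annotated as the pathway's anchoring metabolite by a
spectral-library match (score 0.97, mass error 2.47 ppm); **2** isomer
pairs; and a reference/query cluster pair at a configurable identity target
(default 80 %), optionally inverted, with gene-level indels.

Pathway enzymes are a deliberate mix of matching conventions: ten match by
EC only (one of them through a wildcard EC in the database), three by COG
only, three by both. Background CDSs draw ECs and COGs from disjoint ranges
so no accidental matches occur.

Protein sequences are uniform over the 20 amino acids — adequate for testing
alignment machinery, though real proteins have biased composition and local
structure an aligner can exploit. Spectra are constructed per network
component from a shared 10-peak fragment set with per-member intensities in
a 2× band, which bounds every within-component modified cosine above
2√2/3 ≈ 0.94; fragment windows of different components are disjoint.
Component sizes never exceed 11, so the mutual top-10 edge filter cannot
split a component and the realized network provably equals the planted
topology. Default component count is 9 to respect that bound at 90 nodes.
Precursor m/z values are spaced ≥ 2 Da apart except planted isomer pairs
(Δm/z ≤ 2 mDa, Δrt ≥ 1.5 min), so isomer detection recovers exactly the
planted pairs.

Cluster mutation applies per-gene point substitutions at rate
(100 − target)/100, always to a different residue; for genes of ≥ 200
residues the realized identity concentrates within ~2.5 points of the target
(binomial), which is why recovery tests use a ±3-point band. Inversion
reverses gene order and strand; indels alternate deleting a gene and
inserting an unrelated one.

Every artifact type has its own random stream sub-seeded from the scenario
seed and an artifact tag, so adding a new output never perturbs existing
ones and a fixed seed reproduces byte-identical files (GenBank records carry
a pinned date).

What the generator does **not** emulate: chimeric/fragmented assemblies,
annotation errors, isotope patterns, chromatographic peak shape, spectral
noise peaks, shared fragments between unrelated compounds, or realistic
taxonomy depth. Passing tests therefore demonstrate that the pipeline's
logic recovers planted structure through the full file-format round trip —
not that the thresholds are optimal for any particular instrument or
organism.

## Pipeline and problem sizes

The orchestrated run loads each input once, builds the network from a
precomputed edge list when quant+edge tables are given (falling back to
all-pairs modified cosine over an MGF), and emits a JSON report that
validates against the pydantic-generated schema shipped with the package.
Reports are byte-deterministic for fixed inputs. Stage boundaries are logged
with record counts so the records surviving each stated filter are
auditable.

Tests and the acceptance script run entirely on synthetic scenarios at the
default sizes above (60 CDSs, 90 spectra, 8-gene clusters, 20-seed sweeps
for the reverse chain, 10 planted inversions), sizes at which every planted
recovery is exact and the whole suite completes in well under a minute of
compute per sweep.

## Known limitations

- Alignment score ranking reproduces best-hit *selection*, not BLAST
  e-values; absolute similarity percentages against real reference clusters
  depend on search parameters the package does not model (word size,
  composition adjustment).
- The greedy peak pairing can in principle differ from the optimal matching
  on adversarial spectra with chained candidate conflicts; on real spectra
  the difference is negligible and on the validated toy set it is zero.
- Pathway lookup matches exact structure keys or normalized names; it does
  not resolve synonyms or salt/charge variants beyond the InChIKey skeleton.
- The census treats a region detected by both techniques as one region per
  technique; it does not attempt cross-technique region identity mapping
  beyond the packaged table's own labels.
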