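# Methods

This note documents the models, statistics and design choices behind
`mimicscan`, in the spirit of the methods documentation of packages such as
msprime or statsmodels: what is computed, under which assumptions, which
knobs matter, and what the synthetic benchmarks do and do not show.

## Local alignment and significance

All pairwise alignment in the package — the epitope-vs-proteome scan, the
homology exclusion of predicted peptides, both autoreactivity rounds, and
cluster-to-antigen mapping — goes through one internal Smith–Waterman
engine rather than external BLASTp/LALIGN calls. The engine implements the
Gotoh affine-gap recursion over BLOSUM62 with gap open 11 and gap extend 1
(a gap of length g costs 11 + g), numba-accelerated with an identical
pure-Python fallback. Conventions:

- Coordinates are 1-based inclusive (BLAST convention).
- Percent identity = 100 · identical columns / alignment columns (gap
  columns included in the denominator); query cover = 100 · aligned query
  span / query length. These match BLAST report semantics.
- Ambiguous residues (B, Z, X, U, O, J) are mapped to X on input and score
  0 against everything; BLOSUM62 has no U/O rows and epitope catalogs are
  canonical, so this only affects degenerate inputs.
- Traceback is deterministic: match column preferred over a gap in the
  subject over a gap in the query; among equal-score local optima the
  alignment with the smallest (subject start, query start) is reported.
- Suboptimal alignments (used where a screen wants more than the single
  best alignment per pair) are produced by iteratively masking the subject
  interval of each reported alignment and re-aligning. This mirrors the
  optimal-plus-suboptimal behaviour of classical local aligners without a
  full Waterman–Eggert declumping implementation; alignments crossing a
  masked region are suppressed outright.

Significance is the Karlin–Altschul expectation E = K·m·n·exp(−λS) with the
standard gapped-BLOSUM62 constants λ = 0.267 and K = 0.041, m the query
length and n the searched database size (total residues of the protein
collection for proteome scans; the antigen length for autoreactivity
round 2). No finite-size edge correction or composition adjustment is
applied. **Absolute e-values therefore differ from what BLAST or LALIGN
would print for the same pair**; the thresholds in the configuration
(E < 1 for the mimicry filter, E < 10⁻³ for autoreactivity confirmation)
are interpreted against this package's statistic. At the package's default
scales the statistic is comfortably discriminative: a perfect 15-mer match
against a 10⁵-residue proteome scores ≈ 75–90, giving E ≈ 10⁻⁵–10⁻⁷, while
the best random 15-mer hit hovers near E ≈ 1.

The engine is verified two independent ways: exhaustive brute-force
enumeration of every local alignment (all start pairs, all gap placements,
affine costs) on >10⁴ small sequence pairs, and score agreement with
Biopython's separately developed `PairwiseAligner` on random peptide-scale
pairs.

## The composite mimicry filter

A scan hit is kept iff identity ≥ 80 %, query cover ≥ 80 %, gap count = 0,
and E < 1 (identity/cover boundaries inclusive, e-value strict). For a
full-cover ungapped 15-mer alignment this admits exactly 0–3 mismatches,
which the test suite verifies by enumerating mutated 15-mers at every
divergence d = 0..15.

**Known limitation — terminal trimming.** The 3-mismatch budget is a
statement about *full-cover* alignments. The optimal local alignment of a
15-mer carrying ≥ 2 mutations clustered at its ends trims those ends (any
score-maximizing aligner, including BLAST's X-drop extension, does the
same), and the surviving 12–13 columns can meet both the 80 % identity and
80 % cover thresholds — e.g. mutations at positions {1, 15} leave a
13-column alignment at 84.6 % identity and 86.7 % cover. Consequently, on
synthetic studies where mutation positions are drawn uniformly, a minority
of mimics planted at d = 4 (≈ 15 % per plant) are still detected, and the
idealized expectation "no d ≥ 4 mimic passes" does not hold exactly; at the
default study seed the measured d = 4 detection rate is 0.4 (2 of 5
plants, both with terminal mutation clusters). These detections are not
false positives of the implementation: a d = 4 plant with two terminal
mutations *is* a 13-residue mimic at 84.6 % identity, and the filter admits
it by design.

## Epitope catalog curation

Deduplication treats two records as identical when their sanitized
sequences match exactly, ignoring modification text — catalogs repeat the
same peptide once per post-translational-modification variant. The first
occurrence is the retained representative (stable, order-preserving, and
idempotent). Records without a source-antigen assignment are excluded with
a logged id. Antigen re-assignment (e.g. folding collagen precursor entries
into the single collagen antigen) is data, not code: a two-column mapping
table shipped or supplied by the user, so other catalogs can carry other
re-assignments.

The real curated RA catalog (an IEDB export) is not redistributable, so the
package ships `synthetic_iedb_catalog`, a generator that reproduces the
export's bookkeeping structure on synthetic sequences: 234 raw rows, 28
PTM-duplicate rows, 206 unique sequences, one antigen-less epitope
(id 28), a 20-epitope collagen re-assignment list, 42 epitopes on
Antigen 1, and 37 distinct antigens after re-assignment. Tests that assert
these counts validate the curation *logic* on an exactly structured
stand-in, not the provenance of any real export.

## MHC binding prediction

Trained MHC-binding predictors (the NetMHC/consensus family behind IEDB
tools) cannot be re-derived from published thresholds and are deliberately
not bundled. Scoring goes through the `BindingScorer` interface —
deterministic, total over its supported alleles — so a real predictor can
be plugged in unchanged. The shipped baseline is a per-allele
position-specific scoring matrix over a 9-mer binding core: class I 9-mers
are scored directly; class II 15-mers take the maximum over the seven
sliding core offsets. Baseline matrices are drawn from a seeded standard
normal per (position, residue), optionally with a planted high-affinity
motif (+5 per matching core position by default) so that rank-recovery
behaviour is testable: a peptide containing the motif attains the best rank
in its protein.

Percentile ranks are computed **within protein**: in each (protein, allele)
group of N peptides, a peptide of competition rank r (ties share the
smaller rank) gets percentile 100·r/N, and `best_rank` is the minimum over
panel alleles after exclusions — a peptide is selected into a tier if *any*
disease-relevant allele ranks it there. Web predictors rank against a large
global background pool instead; that pool is not available offline, so
printed rank values from such tools (e.g. "0.02 %") are qualitative anchors
only, and tiers below 100/N cannot be populated on short proteins (the
top-0.5 % tier needs ≥ 200 peptides, i.e. proteins of ≈ 1,000 residues at
step 5). Tier selection is monotone by construction: the top-a % set is
contained in the top-b % set whenever a ≤ b.

The allele panels default to the standard 26-allele class II and 27-allele
class I (A & B) reference panels used by IEDB's prediction front-ends; the
three class II specificities without established RA association
(DRB5\*01:01, DQA1\*01:01/DQB1\*05:01, DQA1\*04:01/DQB1\*04:02) are excluded
from rank aggregation by default. Population-coverage figures attached to
these panels are configuration metadata, not computed quantities.

## Reconciliation of hits and predictions

Experimental epitopes vary in length while predictions are fixed-length, so
exact coordinate matches cannot be expected. A hit and a prediction on the
same protein are a *full* match when either interval contains the other
with at most `overhang_max_aa` residues of total overhead (default 3,
interpreted as a total budget across both ends — the stricter of the two
possible readings, flagged here for users who expect per-side); intervals
that merely intersect are *partial*; disjoint intervals do not match. Each
hit is labeled by its best class over all in-tier predictions, and
per-organism counts of recovered/partial/unrecovered hits always sum to the
organism's hit count.

## Autoreactivity screen

Candidates are the top-0.5 % predicted peptides per protein, minus any
peptide whose optimal alignment to an experimental epitope passes the
composite mimicry filter (those would merely re-discover the screen's own
inputs; "substantial homology" is operationalised as that same filter).
Round 1 aligns each candidate against every antigen and keeps *all*
antigens attaining the maximal score. Round 2 re-aligns against each winner
and confirms at E < 10⁻³ with m = peptide length, n = antigen length;
peptides shorter than 10 residues cannot be assessed and are reported
`too_short`. When several winners confirm, all are evaluated and the
lowest-e-value antigen (ties by id) is recorded as `confirmed_antigen`.
Both rounds use the single internal scoring scheme; classical two-tool
pipelines used different default parameterisations per round, so only the
confirm/reject decisions — not e-value magnitudes — should be compared
across implementations.

On synthetic ground truth the screen is sharp: for 15-mers excised from a
random antigen panel (8 antigens, 300–500 residues) and mutated at d ≤ 2,
100 of 100 seeded replicates confirm, and every confirmation names the true
source antigen — a random 400-residue antigen essentially never reaches the
≈ 66-score needed for E < 10⁻³ by chance.

## Clustering and sequence logos

Pairwise identity between two peptides is the maximum over ungapped
relative offsets of 100·matches/overlap, requiring mutual overlap of at
least half the shorter peptide; epitopes are short and near-fixed-length,
so gapless comparison is used throughout (gapped cluster alignment is not
supported). Cluster-break proceeds: build the graph of pairs meeting the
identity threshold (default 70 %), take connected components, elect as
representative the member to which most members meet the threshold
*directly* (ties: highest mean identity, then lexicographic), break out
members failing the direct test and re-cluster them recursively. The
result is a partition in which every member meets the threshold against
its cluster's representative, deterministic under input permutation. The
IEDB cluster-break tool's internals are unpublished; this is a documented
approximation, so exact cluster counts from that tool are not comparison
surfaces. Clusters below the minimum size (default 5) are dropped before
logo generation.

Logos use a uniform 1/20 background: per aligned column j,
IC_j = log₂20 + Σₐ pₐ·log₂pₐ (0·log 0 := 0), with residue contributions
pₐ·IC_j stacked to IC_j. IC is clipped to [0, log₂20]; a fully conserved
column reaches log₂20 ≈ 4.32 bits, a uniform column 0. Matrices are written
as TSV; a minimal matplotlib stacked-bar rendering is provided for
inspection rather than publication-grade typography.

## Synthetic studies

`generate_study` composes four seeded generators (antigen panel, epitope
excision, background proteome with organism annotations, mimic planting)
via spawned seed sequences, so every artifact is byte-identical given
(parameters, seed). Defaults: 37 antigens of 200–700 residues, two 15-mer
epitopes excised per antigen, 300 background proteins of 280–400 residues
(≈ 10⁵ residues total, a deliberate desk-scale stand-in for the terabyte
scale of real sequence databases) over 30 organisms with categorical
group/host/literature annotations, and five mimics planted at each
divergence d = 0..4 — straddling the filter's 3-mismatch boundary from
both sides. Mutation positions are uniform over the peptide, substitutions
uniform over the 19 alternative residues (never back to the original):
exact identity control matters more here than substitution-model realism.
Plants never overlap one another.

What the synthetic benchmarks show: the scan's sensitivity/specificity at
the filter boundary, end-to-end bookkeeping conservation, autoreactivity
attribution accuracy, and determinism. What they do not show: behaviour on
real proteomes (compositional bias, low-complexity regions, homologous
protein families creating correlated hits), real binding-affinity
landscapes (the baseline scorer is a toy), or database-scale e-value
calibration. Background amino-acid frequencies default to uniform; a
Robinson–Robinson-style composition is available
(`mimicscan.synthetic.ROBINSON_AA`).

## Numerical and degenerate-input conventions

- Alignment of any empty sequence is an argument error; scanning an empty
  proteome is an error, while an empty epitope list yields an empty result.
- Proteins shorter than the peptide length yield no predicted peptides.
- E-value computation requires positive lengths and non-negative scores.
- All ranking, clustering and tie-breaks are deterministic (documented
  orderings; no reliance on hash or insertion order).
- Organism names round-trip through FASTA via the NCBI defline convention
  `>accession description [organism]`.
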