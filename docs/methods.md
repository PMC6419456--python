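# Methods

## Model and procedure

`tadfamily` treats a TAD as an ordered chain of genomic bins. The pipeline
assumes the standard polymer-physics picture of chromatin contact data:
contact frequency between two loci falls off as a power of their genomic
separation, `E[c(s)] ∝ s^α` with α < 0, and higher contact implies closer
spatial proximity.

**Contact rescaling.** The wish-distance law `d = (1/c)^(1/3)` is sensitive
to the overall contact scale (for c ≫ 10 all distances collapse toward a
small constant), so each TAD's observed contacts are first mapped affinely
onto `[1, 30]`, using the min/max over observed entries only. Missing
entries (NA tokens, unlisted sparse pairs) stay missing; observed zeros are
data. The diagonal is always treated as missing: a bin's self-distance is 0
by definition, not something to derive from its self-contact. A constant
matrix is rejected rather than silently filled — it carries no distance
information.

**Embedding.** The wish distances are embedded in 3D with weighted SMACOF
stress majorization, minimizing `σ(X) = Σ_{i<j} w_ij (‖x_i−x_j‖ − d_ij)²`
with `w_ij = 0` on missing pairs and 1 otherwise. The Guttman transform uses
the pseudoinverse of `V = diag(W·1) − W`, which handles arbitrary zero-weight
patterns; a disconnected observation graph is rejected up front. The first
start is deterministic classical (Torgerson) scaling — exact on noiseless
Euclidean input, which is what makes geometry-recovery checks sharp — the
remaining `n_init − 1` starts are seeded Gaussian; lowest final stress wins.
Defaults: `n_init = 4`, `max_iter = 300`, relative stress tolerance 1e-10.
An in-package SMACOF (rather than scikit-learn's) is used because per-pair
weights are part of the contract; scikit-learn's `smacof` serves as an
independent cross-check on complete matrices in the test suite.

**t-SNE alternative.** A 3-component t-SNE on the precomputed wish
distances is run once per (perplexity, learning-rate) combination (defaults
{5, 10, 30, 50} × {10, 100, 200, 1000}); each candidate is rigidly
superposed onto the MDS reference (rotation + translation + optional
reflection, no scaling) and the minimum-RMSD candidate is selected, with the
full per-candidate RMSD table returned. MDS structures are the default for
all downstream similarity.

**Structure statistics.** The *exponent parameter* is the unweighted
least-squares slope of `log P(s)` on `log s`, where `P(s)` is the mean
observed contact at bin separation `s` (separations with `P(s) ≤ 0` or no
observations are dropped; at least 3 usable separations required). It is
fitted on the original, pre-rescale contacts. The *radius of gyration* is
the root-mean-square bead distance to the centroid of the embedded
structure. Across a cohort the two should be negatively correlated — slow
decay ⇒ compact structure — and the package reports Pearson and Spearman
coefficients of that association as a reconstruction-consistency check.

**TM-score.** Structural similarity of two bead chains is the TM-score
normalized by the smaller length `L_min`:
`max (1/L_min) Σ_i 1/(1 + (d_i/d0)²)` over sequence-order-preserving
correspondences and rigid transforms, where the superposition of a
correspondence is the Kabsch fit of exactly its matched pairs and
`d0(L) = max(0.5, 1.24·(L−15)^(1/3) − 1.8)`. Two conventions make a
protein-calibrated score meaningful on chromatin beads of arbitrary units:
each structure is pre-scaled so its mean consecutive-bead distance is 3.8
(the Cα virtual bond length), and reflections are allowed, because an
embedding's chirality is arbitrary. The search seeds gapless alignments at
diagonal offsets and short cross-fragments (plus, for short chains, random
monotone 5-subsets), then alternates Kabsch superposition with a
dynamic-programming re-matching; the DP proposes, for every feasible size k,
the best k-pair monotone matching under the current superposition, each
proposal is scored by its own Kabsch fit, and iteration stops at a fixed
point (cap 20). On 10-bead toys the search attains the brute-force optimum
over all order-preserving correspondences (verified in the tests); for
*unrelated* chains it can undershoot the exhaustive optimum by a few
hundredths — a regime where the score is noise-level anyway. Symmetry
`tm(a,b) = tm(b,a)` is enforced by canonicalizing the operand order.

**Fold enrichment and functional similarity.** For TAD t and state s,
`F_s = (bp of s in t / |t|) / (bp of s genome-wide / G)`. States absent
genome-wide get `F_s = 0`; bases of t not covered by any segmentation
record count in the denominator but carry no state; arithmetic is in base
pairs, not tool-specific bins. Functional similarity is `|Pearson r|`
between raw fold-enrichment vectors (log2 is used only for display and
scoring); a constant vector has similarity 0 by convention. Cluster-level
enrichment pools members by summing overlap bases and lengths before the
ratio.

**Clustering and families.** Spectral clustering runs on the precomputed
affinity (normalized-Laplacian embedding into k dimensions, seeded k-means,
`n_init = 10`). Raw labels are arbitrary, so clusters are relabelled
1..k by decreasing size (ties by first occurrence) — the only reproducible
contract. Default k grids follow the analysis design: functional
{10, 20, 30}, structural {2, 3, 5, 10}. Families are the non-empty
intersections of the two clusterings, ordered by size; they partition the
TAD set by construction. The family score is the fraction of states with
`F_s > 1` computed on the family's own pooled members (the plausible
alternative — scoring the parent functional cluster — is one line of code
away but intersections are what families are). Overlap enrichment between
cluster pairs is `scale · count / (size_functional · size_structural)`
(scale 1000), displayed at one decimal with full precision kept internally.

**Average heatmaps.** Every family member is brought to 30×30: members of
exactly 30 bins contribute their chromosome submatrix; smaller members are
extended symmetrically into flanking bins (odd remainder downstream),
clipped at chromosome bounds with asymmetric completion; larger members
have their bins split into 30 near-equal contiguous groups and
block-averaged, excluding missing entries. The family heatmap is the
masked elementwise mean over members, reported as `log2(mean + 1)` — the
pseudocount fixes the zero-handling that a bare "log2 scale" leaves open.

**acrossCells.** TAD pairs from two cell types match only on exactly equal
(chrom, start, end). Their chromatin-state correlation is the *signed*
Pearson r (unlike the |r| used for clustering — a pair can be functionally
anti-correlated, and the sign is information here); their structural measure
is the TM-score of the two reconstructions.

**Annotation.** A feature belongs to a TAD on ≥ 1 bp overlap (strand
ignored); a feature spanning several TADs belongs to all. lncRNA records
from different catalogs merge into one alias group on same-chromosome,
same-strand ≥ 1 bp overlap, closed transitively; strand must match because
overlapping transcripts on opposite strands are distinct lncRNAs. Alias
groups count once per TAD. Inputs must share one genome build.

## Synthetic cohorts: what they emulate, and what they do not

`gen_cohort` produces per-TAD contact matrices with
`E[c_ij] = |i−j|^α` (|i−j| floored at 1, diagonal masked), multiplicative
log-normal noise mean-corrected so the expectation is exact
(`c = E[c]·exp(σZ − σ²/2)`, σ = `noise_sd`), a chromatin-state segmentation
drawn tile-by-tile from per-TAD state profiles against a uniform background,
and round-robin planted classes: the structural class (decay exponent)
cycles fastest and the functional class cycles over the pair grid, so the
two labelings are balanced and independent and every (struct, state) pair
occurs.

Defaults are chosen as a controlled study at desk scale: 30 TADs of 25 bins
(1.25 Mb at 50 kb resolution), exponents {−0.5, −1.0, −1.5} spanning compact
to extended chromatin, three state profiles (active / repressed / quiescent
mixed with a uniform floor) over a 25-label state model, 200 bp segmentation
tiles, noise σ = 0.1. Bin count is fixed *by design*: the per-TAD [1, 30]
rescale makes local bead geometry depend on chain length, so varying TAD
size would plant a second, unintended structural factor that confounds the
decay classes (empirically, same-exponent chains of 20 vs 40 beads score TM
≈ 0.15 — cross-class level). Pass a wider `bins_range` to study the length
effect deliberately.

Noise sensitivity is worth stating precisely: wish distances derived from a
power law are not exactly 3D-embeddable, so the MDS optimum is
ill-conditioned — a few percent of multiplicative contact noise displaces
the optimal embedding by an order of magnitude more (relative to structure
diameter), and TM-score contrast between adjacent decay classes collapses.
Empirically, three-way planted structural recovery is exact at noise
σ ≤ 0.02 and unreliable by σ = 0.05; two-class recovery between the extreme
exponents survives longer. The functional (chromatin-state) side is far more
robust and recovers its planted classes exactly at all tested noise levels.

The generator does not emulate: KR-normalization artifacts, translocations,
sequence-dependent contact structure, domain-boundary errors from TAD
callers, single-cell sparsity, or segmentation posterior uncertainty.
Passing tests therefore demonstrate correctness of the computational
chain and recoverability of planted signal under idealized power-law data —
not performance on real Hi-C, where structural classes are broader and
confounded with TAD length and coverage.

## Numerical choices and degenerate inputs

- Observed symmetry tolerance for matrices read from text: 1e-9 (tiny
  asymmetries from decimal truncation are averaged before validation).
- Constant contact matrix → `DegenerateInputError`; all-missing →
  `EmptyInputError`; disconnected observation graph → `ConnectivityError`;
  fewer than 3 usable separations for the exponent →
  `InsufficientDataError`; zero-variance vectors in the consistency
  correlations → `UndefinedCorrelationError`. acrossCells keeps a pair with
  an undefined correlation, reporting NaN with a warning.
- k-means can leave a spectral cluster empty on degenerate affinities;
  labels are then compacted with a warning rather than failing the run.
- Pipeline seeds: a single global seed fans out per stage as
  `(seed · 1000003 + crc32(stage)) mod 2³¹`, so any stage can be re-run in
  isolation with identical randomness; re-running an identical config
  reproduces outputs byte-for-byte.
- Known limitation: the TM search is a heuristic; away from the regimes
  checked against brute force (related chains, ≤ 10 beads exhaustive) its
  score is a lower bound on the exhaustive optimum.

## Problem sizes

The shipped tests and examples run cohorts of 9–30 TADs of 25 bins with
3 structural × 3 functional classes — large enough for every stage
(reconstruction, both similarity matrices, clustering, families, heatmaps)
to be exercised end-to-end with planted-truth recovery, and small enough
that the whole suite runs in minutes on one core. All generators scale to
larger cohorts linearly in TAD count and quadratically in pair count.
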