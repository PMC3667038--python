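# Methods

## Disorder calls and boundary semantics

A residue is called disordered from a score track according to the track's
declared orientation — orientation is always an explicit argument, because
the two predictor conventions in common use point in opposite directions.
For high-is-disordered tracks (IUPred-style, scores in [0, 1]) the call is
`score >= threshold` with default threshold 0.5: the threshold value itself
counts as disordered. For low-is-disordered tracks (unfoldability indices)
the call is `score < threshold` with default threshold 0.0: strictly
negative values are unfolded, zero is ordered. The two conventions
deliberately disagree on the exact boundary value, which is why the
orientation-flip symmetry (negating scores and flipping orientation
preserves calls) holds only off the boundary.

A protein is "mostly disordered" (class D) when its disordered ratio is
at least 0.5; the boundary ratio 0.5 is class D because the ordered class
is defined by *less than* 0.5.

## The baseline charge–hydropathy predictor

The built-in predictor computes the unfoldability index
`a·⟨H⟩ − |⟨R⟩| − b` with a = 2.785 and b = 1.151, where ⟨H⟩ is the mean
Kyte–Doolittle hydropathy rescaled to [0, 1] via (KD + 4.5)/9 and ⟨R⟩ the
mean net side-chain charge, over a centered window (default 51 residues,
odd by construction; configurable). Termini use the truncated window.
Positive values mean foldable, negative unfolded, so the output is a
low-is-disordered track. Unknown residue X is imputed neutrally
(hydropathy 0 on the KD scale, charge 0). The predictor is a deliberately
simple sequence-only stand-in for sophisticated per-residue predictors: it
recovers coarse block structure (composition-driven), not their numeric
profiles, and the package's analyses are designed to ingest external
tracks as the primary route.

## Segmentation and long disordered regions

Maximal runs of disordered calls are extracted first. For LDR detection,
adjacent runs separated by an ordered gap of at most `max_gap` residues
(default 3) are chained; chaining is transitive, so three short runs joined
by two tolerable gaps form one chain even when no pair alone would qualify.
A chain qualifies as an LDR when it contains at least `min_ldr_length`
(default 30) disordered residues. Counting *disordered residues* rather
than the whole chained span is the default because the two published
phrasings of the rule differ on this point and the residue-count reading is
the stricter and more explicit one; `ldr_length_mode="span_length"` is
available for sensitivity analysis. The reported span runs from the first
to the last disordered residue of the chain. The "longest consecutive
disordered segment" metric uses raw runs without gap merging — the merge
rule exists only for LDR detection — and this choice is surfaced in the
API so users can tell the two metrics apart.

## Domain partition and family averaging

Each protein is partitioned into E2-binding intervals, transmembrane
intervals, and the remainder (the complement; other domains and
substrate-recognition domains stay inside the remainder). The three classes
are pairwise disjoint and cover the chain exactly, so region-wise residue
counts always recompose the whole-protein count — this conservation is
asserted in tests. An empty region class yields a missing value, never 0,
so proteins without an annotated E2-binding domain drop out of the
E2-column average instead of biasing it.

Family summaries average per-protein percentages without weighting
(pooled residue counts would let long proteins dominate); the remainder
excess is tested one-tailed (alternative: remainder more disordered than
E2-binding domains), treating the two per-protein value lists as
independent samples. A paired alternative is out of scope.

## Linkers

A linker is the non-empty gap between two *consecutive* (position-sorted)
annotations, one E2-binding and one substrate-recognition, in either order.
Consecutiveness encodes the "not interrupted by any other domain or
transmembrane region" rule exactly: if anything is annotated between the
pair, they are not consecutive. Abutting domains (zero-length gap) yield no
linker; an E2-binding domain flanked by substrate-recognition domains on
both sides yields two linkers. Substrate-recognition status is taken from
the annotation category column — deciding *which* domain names count as
substrate-recognition is editorial curation, supplied by the user (an
editable default name set ships in `linker_finder.DEFAULT_SRD_NAMES`).
Per-linker disorder is the mean *raw* score over the interval, because the
quantity of interest is the average disorder tendency rather than a
thresholded fraction; a call-fraction column is emitted alongside. Cohort
lengths are binned [1,50], (50,200], (200,∞).

## Connectivity classes

Degree k counts distinct partners after merging all edge sources as a union
of partner sets (an interaction reported by two sources counts once), with
partners outside the analysed set still contributing — database degrees
count all partners, not only cohort members. Classes: hub k ≥ 25, ICP
4 ≤ k ≤ 24, non-hub k ≤ 3; the thresholds are validated to partition the
non-negative integers. The hub-vs-non-hub disorder comparison is one-tailed
(alternative: hubs more disordered).

## Mann-Whitney U implementation

U is computed from midranked rank sums (U = R₁ − n₁(n₁+1)/2, equal to the
pair count #{x > y} + ½#{x = y}). With max(n₁, n₂) ≤ 8 (configurable) the
p-value is exact: all C(n₁+n₂, n₁) group labelings are enumerated
(vectorised over cached combination index arrays; U values are
half-integers so the tail comparisons are exact in floating point). Above
the cutoff, a normal approximation is used with tie-corrected variance
σ² = n₁n₂/12 · (n+1 − Σ(t³−t)/(n(n−1))) and a 0.5 continuity correction;
when all values are tied the variance is zero and p = 1. Two-sided
p-values are twice the smaller one-sided p, capped at 1 (the same
convention as scipy); in exact mode this equals the tail-mass definition
P(|U−μ| ≥ |U_obs−μ|) because the permutation distribution of U is
symmetric. Consequences of the doubling convention: the one-sided normal
approximation has a maximum error of 0.0055 against the exact distribution
at n₁ = n₂ = 8 (computed by full enumeration), and the two-sided value
carries up to twice that. The exact cutoff of 8 keeps the largest
enumeration at C(16, 8) = 12,870 labelings, milliseconds per call.

Percentage histograms use left-closed right-open bins with the final bin
closed at 100, so counts always sum to n. Pearson correlation raises on
constant input rather than returning NaN silently.

## Redundancy filtering

Identity between two sequences is the number of identical aligned positions
in an optimal Needleman–Wunsch global alignment (match +1, mismatch 0,
linear gap −1), divided by the shorter sequence's length — the
short-sequence normalisation used by CD-HIT-style tools. Among co-optimal
alignments the first reported one is used; at the identity thresholds of
interest this does not change cluster membership in practice. Clustering is
greedy in "best annotated" priority order (user rank, then reviewed flag,
then longer sequence, then lexicographic id — an explicit, deterministic
chain for an inherently editorial criterion): each sequence joins the first
cluster whose representative it matches at or above the threshold
(default 0.85), else founds a new cluster. Representatives are therefore
always the highest-priority members. No k-mer prescreening is implemented;
all-pairs alignment is adequate at the hundreds-of-sequences scale this
package targets. Exact replication of CD-HIT's cluster boundaries is not
claimed (word size and coverage options differ).

## Synthetic cohorts: what they emulate and what they do not

Each synthetic protein is a block architecture — disordered N-tail, ordered
E2-binding domain (45–65 residues, annotated RING), disordered linker,
ordered substrate-recognition domain, disordered C-tail — with the
disordered blocks sized to the whole-protein disorder target
(default 20%, the level typical of single-subunit E3 cohorts) and lengths
drawn from N(500, 100²) truncated at 200. Scores are Gaussian around block
means 0.15 (ordered) / 0.85 (disordered) with sd 0.12, smoothed by a
9-residue moving average (post-smoothing sd ≈ 0.04, so spurious threshold
crossings are rare) and clipped to [0, 1]. Within a block, each residue's
base mean is flipped with a small probability (ordered blocks 2%,
disordered 98%), adding local texture. Sequences are drawn from
disorder-promoting (E, K, S, P, G, Q, A, R, D) or order-promoting
(I, L, V, F, W, Y, M, …) residue pools per block, so the baseline
predictor recovers the architecture qualitatively.

Networks either pin degrees exactly — each protein is wired to its
requested number of distinct external stub partners, which matches how
database degrees count all partners and makes any degree realisable — or
draw degrees from a Zipf distribution (default exponent 2.5) for
heavy-tailed cohorts. Effect injection raises a group's disorder content by
a chosen number of percentage points by flipping randomly chosen ordered
residues above the threshold, per protein, so the group's unweighted mean
rises by the requested delta up to rounding.

What passing tests on these cohorts show: the pipeline's arithmetic,
segmentation, partitioning, linker logic and statistics are correct, and
the designed contrasts (ordered E2 domains vs disordered remainder; hubs
vs non-hubs) are detected with the expected power. What they do not show:
anything about real predictor score profiles (the generator's scores are
block-Gaussian, not physics), real domain-boundary uncertainty, isoform
handling, or real interactome structure beyond the degree distribution.

## Problem sizes and determinism

The test and verification workloads are sized for quick desk runs: 10,000
random call strings (length ≤ 300) for the LDR oracle comparison, 1,000
enumeration draws for the exact Mann-Whitney check, a 200-protein cohort
for parameter recovery, and 100 seeded runs each for the hub-contrast and
clustering checks; the whole verification completes in well under a
minute. Every stochastic component takes an explicit seed
(numpy `default_rng`); the pipeline itself is deterministic given inputs,
and two runs with the same config produce byte-identical report bundles.

## Known limitations

* One canonical sequence per identifier; isoforms are not handled.
* The linker analysis trusts the annotation categories; it does not
  detect domains from sequence.
* The distribution comparison against a reference proteome is a
  two-sample Mann-Whitney on per-protein contents — an interpretation
  choice, since such comparisons are often reported without naming a test.
* No multiple-testing correction is applied (none is used in the analysis
  style this package reproduces).
* The baseline predictor is composition-driven and should not be used as a
  substitute for modern per-residue predictors in real analyses.
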