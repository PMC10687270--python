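# Methods notes

## The filtering model

A synteny block is a pair of 0-based half-open intervals — one on the target
(reference) genome, one on the query — plus an orientation flag. Query
coordinates are always stored on the plus strand, as PSL reports them; an
inverted alignment differs only in the flag. The filter consumes all blocks of
one (target genome, query genome) pair and applies four steps in a fixed
order:

1. **Embedded removal.** A block is dropped when another block of the same
   (target chromosome, query chromosome) pair contains it. Containment is
   judged on *both* axes simultaneously by default: removing on a single axis
   would also delete genuine duplicated homologies whose other-axis placement
   differs. An `either`-axis mode is exposed for comparison; in that mode a
   block is removed whenever any other block contains it on at least one axis
   (with canonical-order tie-breaking for mutual containment). Exact
   duplicates always collapse to a single copy, keeping the canonically first.
2. **Isolated-short removal.** A block with target-axis length < 1 Mbp
   (`short_length`) is dropped iff its nearest same-pair neighbour is
   strictly further than 3 Mbp away (`isolation_distance`) on the target
   axis. Gap = base pairs strictly between intervals; touching or overlapping
   is gap 0. This removes isolated noise while keeping short, clustered
   blocks that jointly witness a real homology.
3. **Adjacency merging.** Two blocks of the same pair *and orientation* whose
   gap is < 1 Mbp (`merge_gap`) on the target axis **and** on the query axis
   are replaced by their coordinate hull, repeated to a fixpoint. Hulls only
   grow and other blocks are untouched, so gaps never increase: the set of
   mergeable pairs is monotone and the fixpoint is unique regardless of merge
   order (the implementation and the brute-force test oracle exploit this by
   merging in different orders). Requiring the gap on both axes prevents
   hulls that silently bridge large query-side jumps; restricting to equal
   orientation keeps the flag meaningful on the hull.
4. **Retention.** Only blocks with target-axis length strictly > 1 Mbp
   (`min_length`) are kept — "longer than" is strict. The 5 Mbp *display
   view* (`display_threshold`, inclusive ≥, "at least") is a view applied
   when building figures and association strings, not a pipeline stage; no
   re-merging happens after it.

All length and distance decisions use the target axis (the PSL reference
frame); the query-axis length is reported but never thresholded. Threshold
strictness follows the wording of the procedure exactly: short is `< 1 Mbp`,
isolated is `> 3 Mbp`, merge is `< 1 Mbp`, retained is `> 1 Mbp`, display is
`≥ 5 Mbp`. Which axis the original pipeline used for isolation and
containment is not documented anywhere we know of; both choices here are
explicit parameters rather than silent guesses.

## Association analysis

Filtered blocks on one query chromosome, ordered by query start, read off a
sequence of target-chromosome labels; collapsing consecutive repeats yields
the association string (`7/6/11/6`). Each adjacent unequal label pair is a
syntenic association; repeats of the same pair on one query chromosome
collapse into a single association carrying all adjacency witnesses, while
occurrences on different query chromosomes are kept separate (multiplicity
matters: the same pair arising three vs four times in two genomes is a real
signal). Associations are, by default, read from the 5 Mbp display view, the
scale at which painted karyotype maps are drawn; the 1 Mbp set can be used
instead.

Cross-species matching compares the reference footprints of equal label
pairs: for each label, the hull of its witness target intervals in species A
must overlap that of species B by at least `min_reciprocal_overlap`
(default 0.5) of the *smaller* footprint. Published comparative analyses
assert such correspondences without a numeric criterion; here the threshold
is an explicit parameter. Matching is greedy, best-minimum-overlap first,
one-to-one. A label pair with at least one correspondence is flagged
putatively ancestral (parsimony: present in both descendants); pairs seen in
one species only are lineage-specific, and pairs present in both species
whose footprints never overlap are reported separately.

Autosomal fragment counts use the query genome definition's autosome flags —
never chromosome-name matching — and the same strict/inclusive threshold
semantics as the filter.

## The simulator and what it does (not) emulate

The simulator evolves an ancestral karyotype along two lineages through
inversions, fissions, fusions and reciprocal translocations. Chromosomes are
ordered lists of ancestral segments with strand; breakpoints are drawn
uniformly, at least `min_segment` (default 100 kbp) from chromosome ends and
existing breakpoints, so no degenerate slivers arise. Inversions reverse the
covered segment list and flip strands (parity is cumulative); fusions may
attach a flipped partner; bookkeeping is exact, so the homology blocks
between the two descendants follow by intersecting the two segmentations on
ancestor coordinates. Truth blocks tile both genomes exactly, and their
orientation is the product of the two local strands.

Because breakpoints are uniform, an event draw can occasionally produce truth
blocks that the filter itself would legitimately merge (e.g. two
same-orientation neighbours flanking a sub-megabase inverted segment touch
within the merge gap on both axes). Such configurations make exact
truth-versus-filtered comparison ill-posed, so by default the simulator
redraws event placements (seeds derived deterministically from the scenario
seed) until the truth set restricted to blocks above the retention length is
a fixpoint of the full filter — a *filter-stable* scenario. This is a
property of the generated study conditions, not of the filter under test;
the redraw count is recorded in the output.

The noise model reproduces three artifact classes of raw alignment-derived
blocks, each constructed to be exactly removable:

* **fragmentation** — each truth block is split (Poisson, default 0.05
  splits/Mbp) into sub-blocks separated by gaps drawn strictly below the
  merge gap on both axes, so merging restores the original span to the base
  pair;
* **embedded duplicates** (default 10) — copies fully nested inside a raw
  fragment on both axes, removed by the containment stage;
* **isolated spurious blocks** (default 10) — blocks shorter than the short
  length (at least 50 kbp, mirroring the minimum block size of upstream
  synteny extraction) placed strictly further than the isolation distance
  from every same-pair block already present, including each other, removed
  by the isolation stage. Placements that cannot satisfy the constraints on
  small genomes are skipped with a warning.

Under these constraints, filter(noise(truth)) provably equals the truth
blocks above the retention length, which is what the recovery tests and the
acceptance script assert (precision = recall = 1, zero boundary deviation).
The simulator emulates block-level karyotype structure only: no sequence,
no repeats, no alignment error inside blocks, no assembly chimerism, and
uncalibrated event rates. Passing recovery tests therefore show that the
filter inverts exactly the artifact classes it was designed for — not that
real alignments contain only those artifacts.

`simulate_two_species` chains the same machinery: shared events build an
intermediate ancestor whose derived associations both species inherit (the
planted "ancestral" signal), then each species accumulates its own events;
the unchanged root genome serves as the common reference frame, mirroring
reference-painted comparative maps.

## Visualization

SVG is generated directly as text with two-decimal coordinates, so identical
inputs yield byte-identical files (golden-file testable). Colours are a pure
function of the target chromosome label: a fixed 20-colour categorical
palette cycled over the natural-sorted labels of the block set. Two-track
plots draw same-orientation blocks on the upper track and inverted blocks on
the lower; karyotype maps draw two colour columns per query chromosome (one
per target species), black centromere dots where annotated, and a 50 Mb
scale bar, with blocks below the display threshold and within-block
inversions not shown. Heterochromatin-gap annotations seen on cytogenetic
idiograms are out of scope; the genome definition format is the natural
extension point should such data be available.

## Problem sizes and numerics

All coordinates are integers in bp; no floating point enters any filtering
decision, so results are platform-independent. Oracle-equivalence tests run
500 random block sets of up to 200 blocks against quadratic brute-force
references; recovery tests run 20 scenarios with 3–10 chromosomes (40–200
Mbp) and up to 15 events per lineage; the acceptance script uses an
11-chromosome reference (60–200 Mbp, plus an X exercising the autosome
flags), 4 shared fusions + 3 shared inversions, and 6 species-specific
events per lineage — sizes chosen so the whole analysis reruns in seconds
while leaving every threshold regime (sub-short, clustered, mergeable,
display-scale) populated.

Degenerate inputs: empty block sets pass through every stage; a single-label
association string yields no associations; genomes without centromere
annotations render without dots; an association-footprint overlap against a
zero-length footprint is defined as 0.
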