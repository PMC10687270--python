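# syntenymap

Post-processing and comparative analysis of pairwise synteny blocks for
chromosome-level genome comparisons.

Whole-genome alignment tools such as halSynteny emit *raw* synteny blocks —
pairs of intervals (one on a target/reference genome, one on a query genome,
with a relative orientation) descended from a single ancestral segment. Raw
output is noisy at the scale cytogeneticists care about: small rearrangements,
repeat matches and assembly artifacts produce embedded duplicates, fragmented
runs of sub-megabase pieces, and isolated spurious hits. This package
implements the block-level cleanup and the downstream comparative-karyotype
analysis used to reconcile such data with chromosome painting maps:

1. **Filtering** — raw blocks pass through three stages plus a retention rule:
   * blocks completely embedded in a longer block of the same
     (target chromosome, query chromosome) pair are removed;
   * "short" blocks (length *L* < 1 Mbp) lying **further than 3 Mbp** from every
     other block of the same chromosome pair are removed — isolated noise goes,
     short but clustered blocks stay;
   * adjacent blocks of the same pair and orientation with a gap **< 1 Mbp**
     (on both axes) are merged into their coordinate hull, to a fixpoint;
   * only blocks **longer than 1 Mbp** are retained. A separate inclusive
     **≥ 5 Mbp** display view feeds the karyotype figures.
2. **Association analysis** — reading the target-chromosome labels of filtered
   blocks along each query chromosome (consecutive repeats collapsed) gives an
   *association string* such as `8/4/8`: adjacency of two different reference
   chromosomes (a *syntenic association*, `4/8`) marks a fusion, and a repeated
   flanking label marks an inversion inside the fusion product. Associations
   found in two species, with reciprocally overlapping footprints on the shared
   reference, are flagged putatively ancestral by parsimony.
3. **Fragment counts** — the number of autosomal syntenic fragments at the
   1 Mbp (strict) and 5 Mbp (inclusive) cutoffs, the scale-dependent summary
   statistic of karyotype conservation.
4. **Visualization** — two-track SVG plots (same-orientation blocks above the
   chromosome line, inverted below) and painted karyotype ideograms with two
   colour columns per chromosome, centromere dots and a 50 Mb scale bar.
5. **Simulation** — a karyotype-evolution simulator (inversions, fissions,
   fusions, reciprocal translocations, with exact homology bookkeeping) plus a
   noise model reproducing the three artifact classes above, so the whole
   pipeline is testable end to end without any external alignment.

Coordinates are 0-based half-open on both axes (native PSL); query coordinates
are always plus-strand with inversion kept as a separate orientation flag.

## Worked example

```python
import syntenymap as sm

MB = 1_000_000
ancestor = sm.GenomeDef("REF", (
    sm.ChromosomeDef("1", 180 * MB),
    sm.ChromosomeDef("2", 140 * MB),
    sm.ChromosomeDef("3", 110 * MB),
))
# one shared fusion + inversion builds the common ancestor of two species
res = sm.simulate_two_species(
    ancestor,
    shared=sm.EventCounts(fusions=1, inversions=1),
    events_1=sm.EventCounts(inversions=2),
    events_2=sm.EventCounts(inversions=1, fissions=1),
    seed=7,
)
raw1 = sm.add_noise(res.truth_1, sm.NoiseParams(seed=1))
f1 = sm.run_filter(raw1)
print(len(raw1), "->", len(f1))                    # 49 -> 9
rep = sm.evaluate_recovery(f1, res.truth_1, min_truth_length=MB)
print(rep.precision, rep.recall, rep.max_boundary_deviation)   # 1.0 1.0 0

d1 = sm.display_view(f1)
print(sm.build_association_string(d1, "S12"))      # 3/2
```

Filtering collapses 49 noisy raw blocks back to the 9 exact homology
segments (precision = recall = 1.0, boundaries recovered to the base pair).
The association string `3/2` on species-1 chromosome `S12` is the fused
product of reference chromosomes 2 and 3 — and because the fusion predates
the split, matching it against species 2 on reference coordinates flags it
ancestral:

```python
a1 = sm.genome_associations(d1, res.genome_1)
a2 = sm.genome_associations(sm.display_view(sm.run_filter(
    sm.add_noise(res.truth_2, sm.NoiseParams(seed=2)))), res.genome_2)
matches = sm.match_across_species(a1, a2)
print(sm.infer_ancestral(a1, a2, matches).ancestral_labels)    # ('2/3',)
```

The same operations are available from a CLI
(`syntenymap filter|associate|ancestral|count|simulate|render`), e.g.:

```sh
syntenymap filter --in raw.psl --out filtered.psl
syntenymap count --in filtered.psl --genome genome.yaml --threshold 1000000
syntenymap render --mode two-track --in filtered.psl --genome genome.yaml --out map.svg
```

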