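"""Association strings, cross-species synteny matching and fragment counts.

Reading the target-chromosome labels of filtered blocks along each query
chromosome (in query order, consecutive repeats collapsed) yields an
association string such as ``8/4/8`` — the classic notation of comparative
chromosome painting, where adjacency of segments homologous to two
different reference chromosomes (a syntenic association, e.g. ``4/8``)
marks a fusion, and a repeated flanking label marks an inversion inside the
fusion product. Associations found in two descendant species, with
overlapping footprints on the shared reference genome, are flagged
putatively ancestral by parsimony.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .model import (
    BlockSet,
    GenomeDef,
    GenomeMismatchError,
    Orientation,
    SyntenyBlock,
    UnknownChromosomeError,
    block_length,
    natural_key,
)


@dataclass(frozen=True)
class LabelRun:
    """A maximal run of consecutive same-target-chromosome blocks on one query chromosome."""

    label: str
    blocks: tuple[SyntenyBlock, ...]

    @property
    def target_span(self) -> tuple[int, int]:
        return (
            min(b.target_start for b in self.blocks),
            max(b.target_end for b in self.blocks),
        )

    @property
    def query_span(self) -> tuple[int, int]:
        return (
            min(b.query_start for b in self.blocks),
            max(b.query_end for b in self.blocks),
        )


@dataclass(frozen=True)
class AssociationString:
    """Ordered, repeat-collapsed target-chromosome labels along a query chromosome."""

    query_chrom: str
    runs: tuple[LabelRun, ...]

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(r.label for r in self.runs)

    def __str__(self) -> str:
        return "/".join(self.labels)


@dataclass(frozen=True)
class SyntenyAssociation:
    """Adjacency of two different reference-chromosome labels on one query chromosome.

    ``witnesses`` holds each adjacent run pair realising the association on
    this query chromosome (an ``i/j/i`` string yields one association with
    two witnesses); ``footprints`` maps each label to the hull of its
    witness runs' target intervals on the shared reference.
    """

    target_genome: str
    query_chrom: str
    pair: frozenset[str]
    witnesses: tuple[tuple[LabelRun, LabelRun], ...]

    @property
    def footprints(self) -> dict[str, tuple[int, int]]:
        spans: dict[str, tuple[int, int]] = {}
        for left, right in self.witnesses:
            for run in (left, right):
                lo, hi = run.target_span
                if run.label in spans:
                    plo, phi = spans[run.label]
                    spans[run.label] = (min(plo, lo), max(phi, hi))
                else:
                    spans[run.label] = (lo, hi)
        return spans

    @property
    def pair_label(self) -> str:
        return format_pair(self.pair)


def format_pair(pair: frozenset[str]) -> str:
    return "/".join(sorted(pair, key=natural_key))


@dataclass(frozen=True)
class Correspondence:
    """A matched association pair across two query species on the shared reference."""

    a: SyntenyAssociation
    b: SyntenyAssociation
    overlap_fractions: dict[str, float]


def build_association_string(
    bs: BlockSet, query_chrom: str, genome: Optional[GenomeDef] = None
) -> AssociationString:
    """Association string of one query chromosome from a filtered BlockSet.

    Blocks are ordered by query_start; consecutive identical target labels
    collapse into one run. When a genome definition is supplied the
    chromosome must exist in it.
    """
    if genome is not None and query_chrom not in genome:
        raise UnknownChromosomeError(
            f"chromosome {query_chrom!r} not in genome {genome.name!r}"
        )
    blocks = sorted(
        bs.on_query_chrom(query_chrom), key=lambda b: (b.query_start, b.query_end)
    )
    runs: list[LabelRun] = []
    current: list[SyntenyBlock] = []
    for b in blocks:
        if current and b.target_chrom == current[-1].target_chrom:
            current.append(b)
        else:
            if current:
                runs.append(LabelRun(current[-1].target_chrom, tuple(current)))
            current = [b]
    if current:
        runs.append(LabelRun(current[-1].target_chrom, tuple(current)))
    return AssociationString(query_chrom=query_chrom, runs=tuple(runs))


def extract_associations(
    s: AssociationString, target_genome: str = "target"
) -> tuple[SyntenyAssociation, ...]:
    """Associations of one query chromosome: one per distinct adjacent label pair.

    Repeats of the same pair on the same query chromosome collapse into a
    single association carrying all adjacency witnesses; multiplicity across
    query chromosomes is preserved by the caller keeping per-chromosome
    results separate.
    """
    by_pair: dict[frozenset[str], list[tuple[LabelRun, LabelRun]]] = {}
    order: list[frozenset[str]] = []
    for left, right in zip(s.runs, s.runs[1:]):
        pair = frozenset((left.label, right.label))
        if pair not in by_pair:
            by_pair[pair] = []
            order.append(pair)
        by_pair[pair].append((left, right))
    return tuple(
        SyntenyAssociation(
            target_genome=target_genome,
            query_chrom=s.query_chrom,
            pair=pair,
            witnesses=tuple(by_pair[pair]),
        )
        for pair in order
    )


def genome_associations(
    bs: BlockSet, genome: Optional[GenomeDef] = None
) -> tuple[SyntenyAssociation, ...]:
    """All associations of a BlockSet, per query chromosome, multiplicity kept."""
    chroms = genome.chromosome_ids if genome is not None else bs.query_chroms()
    out: list[SyntenyAssociation] = []
    for chrom in chroms:
        if not bs.on_query_chrom(chrom):
            continue
        s = build_association_string(bs, chrom, genome)
        out.extend(extract_associations(s, target_genome=bs.target_genome))
    return tuple(out)


def _overlap_fraction(a: tuple[int, int], b: tuple[int, int]) -> float:
    ov = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    smaller = min(a[1] - a[0], b[1] - b[0])
    return ov / smaller if smaller > 0 else 0.0


def match_across_species(
    assoc_a: Sequence[SyntenyAssociation],
    assoc_b: Sequence[SyntenyAssociation],
    min_reciprocal_overlap: float = 0.5,
) -> tuple[Correspondence, ...]:
    """Match equal-label-pair associations across two query species.

    Two associations of the same label pair correspond when, for each label,
    their reference-coordinate footprints overlap by at least
    ``min_reciprocal_overlap`` of the smaller footprint. Matching is greedy
    best-overlap-first and one-to-one.
    """
    genomes_a = {a.target_genome for a in assoc_a}
    genomes_b = {b.target_genome for b in assoc_b}
    if genomes_a and genomes_b and genomes_a != genomes_b:
        raise GenomeMismatchError(
            f"associations reference different target genomes: "
            f"{sorted(genomes_a)} vs {sorted(genomes_b)}"
        )
    candidates: list[tuple[float, tuple, int, int, dict[str, float]]] = []
    for i, a in enumerate(assoc_a):
        for j, b in enumerate(assoc_b):
            if a.pair != b.pair:
                continue
            fa, fb = a.footprints, b.footprints
            fracs = {lab: _overlap_fraction(fa[lab], fb[lab]) for lab in a.pair}
            if all(f >= min_reciprocal_overlap for f in fracs.values()):
                score = min(fracs.values())
                tie = (a.query_chrom, b.query_chrom)
                candidates.append((score, tie, i, j, fracs))
    candidates.sort(key=lambda c: (-c[0], c[1], c[2], c[3]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    matches: list[Correspondence] = []
    for score, _tie, i, j, fracs in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matches.append(Correspondence(a=assoc_a[i], b=assoc_b[j], overlap_fractions=fracs))
    return tuple(matches)


@dataclass(frozen=True)
class AncestralReport:
    """Label pairs split by cross-species support."""

    ancestral: frozenset[frozenset[str]]
    only_a: frozenset[frozenset[str]]
    only_b: frozenset[frozenset[str]]
    shared_unmatched: frozenset[frozenset[str]]

    @property
    def ancestral_labels(self) -> tuple[str, ...]:
        return tuple(sorted((format_pair(p) for p in self.ancestral), key=natural_key))


def infer_ancestral(
    assoc_a: Sequence[SyntenyAssociation],
    assoc_b: Sequence[SyntenyAssociation],
    matches: Sequence[Correspondence],
) -> AncestralReport:
    """Flag label pairs with at least one cross-species correspondence as putatively ancestral.

    Pairs seen in only one species are reported as lineage-specific; pairs
    present in both but with non-overlapping reference footprints are
    reported separately as shared-but-unmatched.
    """
    pairs_a = {a.pair for a in assoc_a}
    pairs_b = {b.pair for b in assoc_b}
    ancestral = frozenset(m.a.pair for m in matches)
    return AncestralReport(
        ancestral=ancestral,
        only_a=frozenset(pairs_a - pairs_b),
        only_b=frozenset(pairs_b - pairs_a),
        shared_unmatched=frozenset((pairs_a & pairs_b) - ancestral),
    )


def count_autosomal_fragments(
    bs: BlockSet, genome: GenomeDef, threshold: int, inclusive: bool = False
) -> int:
    """Number of blocks on autosomal query chromosomes passing the length rule.

    Length is measured on the target axis; the 1 Mbp cutoff is strict
    (``inclusive=False``), the 5 Mbp cutoff inclusive. Sex chromosomes are
    excluded via the genome definition's autosome flags, never by name.
    """
    n = 0
    for b in bs:
        chrom = genome[b.query_chrom]  # raises UnknownChromosomeError if absent
        if not chrom.is_autosome:
            continue
        length = block_length(b, "target")
        if (length >= threshold) if inclusive else (length > threshold):
            n += 1
    return n


def fragment_count_table(
    bs: BlockSet, genome: GenomeDef, threshold: int, inclusive: bool = False
) -> pd.DataFrame:
    """Per-query-chromosome block counts at a threshold (autosomes flagged)."""
    rows = []
    for chrom in genome.chromosomes:
        blocks = bs.on_query_chrom(chrom.id)
        if inclusive:
            n = sum(block_length(b, "target") >= threshold for b in blocks)
        else:
            n = sum(block_length(b, "target") > threshold for b in blocks)
        rows.append(
            {"query_chrom": chrom.id, "is_autosome": chrom.is_autosome, "n_blocks": n}
        )
    return pd.DataFrame(rows, columns=["query_chrom", "is_autosome", "n_blocks"])


def association_table(bs: BlockSet, genome: Optional[GenomeDef] = None) -> pd.DataFrame:
    """Per-query-chromosome association strings as a table (TSV-ready)."""
    chroms = genome.chromosome_ids if genome is not None else bs.query_chroms()
    rows = []
    for chrom in chroms:
        if not bs.on_query_chrom(chrom):
            continue
        s = build_association_string(bs, chrom, genome)
        rows.append(
            {
                "query_chrom": chrom,
                "association": str(s),
                "n_runs": len(s.runs),
                "n_blocks": len(bs.on_query_chrom(chrom)),
            }
        )
    return pd.DataFrame(rows, columns=["query_chrom", "association", "n_runs", "n_blocks"])
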