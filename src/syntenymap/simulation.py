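"""Karyotype-evolution simulator with exact homology bookkeeping.

An ancestral genome evolves along two lineages through inversions,
fissions, fusions and reciprocal translocations. Each descendant
chromosome is represented as an ordered list of ancestral segments with
strand, so the exact homologous blocks between the two descendants (the
truth set) follow by intersecting the two segmentations on ancestor
coordinates. A noise model then degrades the truth set into raw
halSynteny-like output: sub-merge-gap fragmentation, fully nested
duplicate blocks, and isolated spurious short blocks — the three artifact
classes the filter pipeline is designed to remove.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np

from .filtering import apply_min_length, run_filter
from .model import (
    BlockSet,
    ChromosomeDef,
    FilterParams,
    GenomeDef,
    Orientation,
    SyntenyBlock,
    SyntenyError,
    block_length,
)


class InfeasibleEventError(SyntenyError):
    """A rearrangement event cannot be applied; the message names its index."""


class Segment(NamedTuple):
    """A piece of an ancestral chromosome inside a descendant chromosome."""

    anc_chrom: str
    start: int
    end: int
    strand: int  # +1 forward, -1 reversed

    @property
    def length(self) -> int:
        return self.end - self.start


# a lineage genome: list of chromosomes, each an ordered list of segments
Lineage = list[list[Segment]]


@dataclass(frozen=True)
class EventCounts:
    """How many events of each type a lineage experiences."""

    inversions: int = 0
    fissions: int = 0
    fusions: int = 0
    translocations: int = 0

    def __post_init__(self) -> None:
        for name in ("inversions", "fissions", "fusions", "translocations"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def total(self) -> int:
        return self.inversions + self.fissions + self.fusions + self.translocations


@dataclass(frozen=True)
class EventRecord:
    """One applied rearrangement: lineage tag, running index, type, breakpoints."""

    lineage: str
    index: int
    kind: str
    chrom_indices: tuple[int, ...]
    positions: tuple[int, ...]


@dataclass(frozen=True)
class EvolutionScenario:
    """Simulation conditions: ancestor, per-lineage event counts, seed.

    Lineage A is by convention the reference-like genome (zero or few
    events) so that associations such as i/j on lineage-B chromosomes arise
    from fusions in lineage B, mirroring reference-painted comparative maps.
    ``min_segment`` keeps every segment produced by a breakpoint at least
    that long (default 100 kbp). With ``require_filter_stable`` the event
    placements are redrawn until the truth set is a fixpoint of the filter
    pipeline restricted to blocks above the retention length, so that
    recovery comparisons are exact.
    """

    ancestor: GenomeDef
    events_a: EventCounts = field(default_factory=EventCounts)
    events_b: EventCounts = field(default_factory=EventCounts)
    min_segment: int = 100_000
    seed: int = 0
    name_a: str = "A"
    name_b: str = "B"
    require_filter_stable: bool = True
    filter_params: Optional[FilterParams] = None


@dataclass(frozen=True)
class TruthSet:
    """Exact homologous blocks between two descendants plus the event log."""

    blocks: BlockSet
    events: tuple[EventRecord, ...]
    target_genome_def: GenomeDef
    query_genome_def: GenomeDef
    seed: int
    attempts: int = 1


@dataclass(frozen=True)
class SimulationResult:
    genome_a: GenomeDef
    genome_b: GenomeDef
    truth: TruthSet


def _chrom_length(chrom: list[Segment]) -> int:
    return sum(s.length for s in chrom)


def _boundaries(chrom: list[Segment]) -> list[int]:
    """Interior segment boundaries in descendant coordinates."""
    out = []
    pos = 0
    for seg in chrom[:-1]:
        pos += seg.length
        out.append(pos)
    return out


def _split_at(chrom: list[Segment], pos: int) -> tuple[list[Segment], list[Segment]]:
    """Split a chromosome at descendant coordinate pos (0 < pos < length)."""
    left: list[Segment] = []
    right: list[Segment] = []
    cursor = 0
    for seg in chrom:
        if cursor + seg.length <= pos:
            left.append(seg)
        elif cursor >= pos:
            right.append(seg)
        else:
            d = pos - cursor  # offset into this segment
            if seg.strand == 1:
                left.append(Segment(seg.anc_chrom, seg.start, seg.start + d, 1))
                right.append(Segment(seg.anc_chrom, seg.start + d, seg.end, 1))
            else:
                left.append(Segment(seg.anc_chrom, seg.end - d, seg.end, -1))
                right.append(Segment(seg.anc_chrom, seg.start, seg.end - d, -1))
        cursor += seg.length
    return left, right


def _flip(segments: Sequence[Segment]) -> list[Segment]:
    return [Segment(s.anc_chrom, s.start, s.end, -s.strand) for s in reversed(segments)]


def _coalesce(chrom: list[Segment]) -> list[Segment]:
    """Merge ancestor-contiguous same-strand neighbours back into one segment."""
    out: list[Segment] = []
    for seg in chrom:
        if out:
            prev = out[-1]
            if prev.anc_chrom == seg.anc_chrom and prev.strand == seg.strand:
                if seg.strand == 1 and prev.end == seg.start:
                    out[-1] = Segment(prev.anc_chrom, prev.start, seg.end, 1)
                    continue
                if seg.strand == -1 and prev.start == seg.end:
                    out[-1] = Segment(prev.anc_chrom, seg.start, prev.end, -1)
                    continue
        out.append(seg)
    return out


def _draw_breakpoint(
    rng: np.random.Generator,
    chrom: list[Segment],
    min_segment: int,
    avoid: Sequence[int] = (),
) -> Optional[int]:
    """Uniform breakpoint at least min_segment from ends, existing boundaries and `avoid`."""
    length = _chrom_length(chrom)
    if length < 2 * min_segment:
        return None
    keep_away = list(_boundaries(chrom)) + list(avoid)
    for _ in range(100):
        pos = int(rng.integers(min_segment, length - min_segment + 1))
        if all(abs(pos - b) >= min_segment for b in keep_away):
            return pos
    return None


def _pick_chrom(
    rng: np.random.Generator, state: Lineage, eligible: list[int]
) -> int:
    lengths = np.array([_chrom_length(state[i]) for i in eligible], dtype=float)
    return eligible[int(rng.choice(len(eligible), p=lengths / lengths.sum()))]


def apply_events(
    state: Lineage,
    counts: EventCounts,
    rng: np.random.Generator,
    min_segment: int,
    lineage: str,
    start_index: int = 0,
) -> list[EventRecord]:
    """Apply a shuffled sequence of rearrangements in place; return the event log."""
    kinds = (
        ["inversion"] * counts.inversions
        + ["fission"] * counts.fissions
        + ["fusion"] * counts.fusions
        + ["translocation"] * counts.translocations
    )
    order = rng.permutation(len(kinds))
    kinds = [kinds[i] for i in order]
    log: list[EventRecord] = []
    for offset, kind in enumerate(kinds):
        index = start_index + offset
        if kind == "inversion":
            eligible = [
                i for i, c in enumerate(state) if _chrom_length(c) >= 3 * min_segment
            ]
            if not eligible:
                raise InfeasibleEventError(
                    f"{lineage} event {index} (inversion): no chromosome long enough"
                )
            ci = _pick_chrom(rng, state, eligible)
            p1 = _draw_breakpoint(rng, state[ci], min_segment)
            p2 = (
                None
                if p1 is None
                else _draw_breakpoint(rng, state[ci], min_segment, avoid=[p1])
            )
            if p1 is None or p2 is None:
                raise InfeasibleEventError(
                    f"{lineage} event {index} (inversion): breakpoints unsatisfiable"
                )
            lo, hi = sorted((p1, p2))
            left, rest = _split_at(state[ci], lo)
            mid, right = _split_at(rest, hi - lo)
            state[ci] = _coalesce(left + _flip(mid) + right)
            log.append(EventRecord(lineage, index, kind, (ci,), (lo, hi)))
        elif kind == "fission":
            eligible = [
                i for i, c in enumerate(state) if _chrom_length(c) >= 2 * min_segment
            ]
            if not eligible:
                raise InfeasibleEventError(
                    f"{lineage} event {index} (fission): no chromosome long enough"
                )
            ci = _pick_chrom(rng, state, eligible)
            pos = _draw_breakpoint(rng, state[ci], min_segment)
            if pos is None:
                raise InfeasibleEventError(
                    f"{lineage} event {index} (fission): breakpoint unsatisfiable"
                )
            left, right = _split_at(state[ci], pos)
            state[ci] = left
            state.append(right)
            log.append(EventRecord(lineage, index, kind, (ci, len(state) - 1), (pos,)))
        elif kind == "fusion":
            if len(state) < 2:
                raise InfeasibleEventError(
                    f"{lineage} event {index} (fusion): fewer than two chromosomes"
                )
            i, j = (int(x) for x in rng.choice(len(state), size=2, replace=False))
            other = state[j] if rng.integers(2) == 0 else _flip(state[j])
            state[i] = _coalesce(state[i] + other)
            del state[j]
            log.append(EventRecord(lineage, index, kind, (i, j), ()))
        else:  # reciprocal translocation
            eligible = [
                i for i, c in enumerate(state) if _chrom_length(c) >= 2 * min_segment
            ]
            if len(eligible) < 2:
                raise InfeasibleEventError(
                    f"{lineage} event {index} (translocation): needs two long chromosomes"
                )
            i = _pick_chrom(rng, state, eligible)
            j = _pick_chrom(rng, state, [e for e in eligible if e != i])
            pi = _draw_breakpoint(rng, state[i], min_segment)
            pj = _draw_breakpoint(rng, state[j], min_segment)
            if pi is None or pj is None:
                raise InfeasibleEventError(
                    f"{lineage} event {index} (translocation): breakpoints unsatisfiable"
                )
            li, ri = _split_at(state[i], pi)
            lj, rj = _split_at(state[j], pj)
            state[i] = _coalesce(li + rj)
            state[j] = _coalesce(lj + ri)
            log.append(EventRecord(lineage, index, kind, (i, j), (pi, pj)))
    return log


def _identity_lineage(ancestor: GenomeDef) -> Lineage:
    return [[Segment(c.id, 0, c.length, 1)] for c in ancestor.chromosomes]


def _lineage_genome(state: Lineage, name: str, ancestor: GenomeDef) -> GenomeDef:
    chroms = []
    for i, segs in enumerate(state):
        autosome = all(ancestor[s.anc_chrom].is_autosome for s in segs)
        chroms.append(
            ChromosomeDef(
                id=f"{name}{i + 1}",
                length=_chrom_length(segs),
                centromere=None,
                is_autosome=autosome,
            )
        )
    return GenomeDef(name=name, chromosomes=tuple(chroms))


class _Placed(NamedTuple):
    chrom: str
    desc_start: int
    desc_end: int
    anc_start: int
    anc_end: int
    strand: int


def _placements(state: Lineage, genome: GenomeDef) -> dict[str, list[_Placed]]:
    """Per-ancestral-chromosome placement of every segment in descendant coordinates."""
    by_anc: dict[str, list[_Placed]] = {}
    for chrom_def, segs in zip(genome.chromosomes, state):
        pos = 0
        for seg in segs:
            by_anc.setdefault(seg.anc_chrom, []).append(
                _Placed(chrom_def.id, pos, pos + seg.length, seg.start, seg.end, seg.strand)
            )
            pos += seg.length
    return by_anc


def truth_blocks(
    state_a: Lineage,
    genome_a: GenomeDef,
    state_b: Lineage,
    genome_b: GenomeDef,
) -> BlockSet:
    """Exact homology blocks between two lineages by ancestor-coordinate intersection."""
    pa = _placements(state_a, genome_a)
    pb = _placements(state_b, genome_b)
    blocks: list[SyntenyBlock] = []
    for anc_chrom, a_list in pa.items():
        for a in a_list:
            for b in pb.get(anc_chrom, []):
                lo = max(a.anc_start, b.anc_start)
                hi = min(a.anc_end, b.anc_end)
                if lo >= hi:
                    continue
                if a.strand == 1:
                    ta = a.desc_start + (lo - a.anc_start)
                    te = a.desc_start + (hi - a.anc_start)
                else:
                    ta = a.desc_start + (a.anc_end - hi)
                    te = a.desc_start + (a.anc_end - lo)
                if b.strand == 1:
                    qa = b.desc_start + (lo - b.anc_start)
                    qe = b.desc_start + (hi - b.anc_start)
                else:
                    qa = b.desc_start + (b.anc_end - hi)
                    qe = b.desc_start + (b.anc_end - lo)
                blocks.append(
                    SyntenyBlock(
                        target_chrom=a.chrom,
                        target_start=ta,
                        target_end=te,
                        query_chrom=b.chrom,
                        query_start=qa,
                        query_end=qe,
                        orientation=Orientation.SAME
                        if a.strand == b.strand
                        else Orientation.INVERTED,
                    )
                )
    return BlockSet(
        target_genome=genome_a.name, query_genome=genome_b.name, blocks=tuple(blocks)
    )


def _is_filter_stable(blocks: BlockSet, params: FilterParams) -> bool:
    expected = apply_min_length(blocks, params.min_length, inclusive=False)
    return run_filter(blocks, params) == expected


def _derived_seed(seed: int, attempt: int) -> int:
    return (seed * 1_000_003 + attempt * 7_919) % (2**31 - 1)


def simulate(scenario: EvolutionScenario, max_attempts: int = 50) -> SimulationResult:
    """Evolve the ancestor along lineages A and B; return genomes and truth set.

    Deterministic under a fixed seed. When ``require_filter_stable`` is set,
    event placements are redrawn (with seeds derived from the scenario seed)
    until the truth blocks above the retention length are a fixpoint of the
    filter pipeline.
    """
    params = scenario.filter_params or FilterParams()
    last_error: Optional[Exception] = None
    for attempt in range(max_attempts):
        rng = np.random.default_rng(_derived_seed(scenario.seed, attempt))
        state_a = _identity_lineage(scenario.ancestor)
        state_b = _identity_lineage(scenario.ancestor)
        try:
            log_a = apply_events(
                state_a, scenario.events_a, rng, scenario.min_segment, "A"
            )
            log_b = apply_events(
                state_b, scenario.events_b, rng, scenario.min_segment, "B"
            )
        except InfeasibleEventError as exc:
            if scenario.require_filter_stable:
                last_error = exc
                continue  # a different draw may be feasible
            raise
        genome_a = _lineage_genome(state_a, scenario.name_a, scenario.ancestor)
        genome_b = _lineage_genome(state_b, scenario.name_b, scenario.ancestor)
        blocks = truth_blocks(state_a, genome_a, state_b, genome_b)
        if scenario.require_filter_stable and not _is_filter_stable(blocks, params):
            continue
        truth = TruthSet(
            blocks=blocks,
            events=tuple(log_a + log_b),
            target_genome_def=genome_a,
            query_genome_def=genome_b,
            seed=scenario.seed,
            attempts=attempt + 1,
        )
        return SimulationResult(genome_a=genome_a, genome_b=genome_b, truth=truth)
    if last_error is not None:
        raise last_error
    raise SyntenyError(
        f"no filter-stable event placement found in {max_attempts} attempts "
        f"(seed {scenario.seed})"
    )


@dataclass(frozen=True)
class NoiseParams:
    """halSynteny-like degradation of a truth set.

    ``fragmentation_rate`` is the expected number of splits per Mbp of
    target-axis block length; each split removes a gap drawn strictly below
    the merge gap, so merging recovers the original span exactly. Embedded
    duplicates are fully nested inside raw fragments. Spurious blocks are
    shorter than the short-block length and placed strictly further than the
    isolation distance from every same-pair block, so the filter removes
    them all. ``min_block`` mirrors the minimum block size of the upstream
    synteny extraction (50 kbp).
    """

    fragmentation_rate: float = 0.05
    n_embedded: int = 10
    n_spurious: int = 10
    min_block: int = 50_000
    short_length: int = 1_000_000
    isolation_distance: int = 3_000_000
    merge_gap: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fragmentation_rate < 0:
            raise ValueError("fragmentation_rate must be >= 0")
        if not 0 < self.min_block < self.short_length:
            raise ValueError("min_block must lie in (0, short_length)")
        if self.merge_gap < 2:
            raise ValueError("merge_gap must be >= 2 to leave room for gaps")


def _map_offsets(b: SyntenyBlock, lo: int, hi: int) -> tuple[int, int, int, int]:
    """Map target-axis offsets [lo, hi) of a block to coordinates on both axes."""
    ts, te = b.target_start + lo, b.target_start + hi
    if b.orientation is Orientation.SAME:
        qs, qe = b.query_start + lo, b.query_start + hi
    else:
        qs, qe = b.query_end - hi, b.query_end - lo
    return ts, te, qs, qe


def add_noise(truth: TruthSet, noise: NoiseParams) -> BlockSet:
    """Degrade a truth set into a raw, noisy BlockSet (deterministic under seed)."""
    rng = np.random.default_rng(noise.seed)
    raw: list[SyntenyBlock] = []
    margin = noise.min_block

    # 1. fragmentation: split blocks, gaps strictly below the merge gap
    for b in truth.blocks:
        length = block_length(b, "target")
        n_splits = int(rng.poisson(noise.fragmentation_rate * length / 1e6))
        cuts: list[int] = []
        if n_splits > 0 and length >= 2 * (margin + noise.merge_gap):
            proposals = sorted(
                int(x)
                for x in rng.integers(
                    margin + noise.merge_gap,
                    length - margin - noise.merge_gap + 1,
                    size=n_splits,
                )
            )
            prev = 0
            for c in proposals:
                if c - prev >= margin + noise.merge_gap:
                    cuts.append(c)
                    prev = c
        if not cuts:
            raw.append(b)
            continue
        gaps = [int(rng.integers(1, noise.merge_gap)) for _ in cuts]
        prev = 0
        pieces: list[tuple[int, int]] = []
        for c, g in zip(cuts, gaps):
            pieces.append((prev, c))
            prev = c + g
        pieces.append((prev, length))
        for lo, hi in pieces:
            ts, te, qs, qe = _map_offsets(b, lo, hi)
            raw.append(
                SyntenyBlock(b.target_chrom, ts, te, b.query_chrom, qs, qe, b.orientation)
            )

    # 2. fully nested duplicate blocks inside raw fragments
    hosts = [b for b in raw if block_length(b, "target") >= 4 * margin]
    skipped_embedded = 0
    for _ in range(noise.n_embedded):
        if not hosts:
            skipped_embedded += 1
            continue
        host = hosts[int(rng.integers(len(hosts)))]
        hlen = block_length(host, "target")
        dup_len = int(rng.integers(margin, min(hlen - 2, noise.short_length - 1) + 1))
        lo = int(rng.integers(1, hlen - dup_len))
        ts, te, qs, qe = _map_offsets(host, lo, lo + dup_len)
        orient = (
            Orientation.SAME if rng.integers(2) == 0 else Orientation.INVERTED
        )
        raw.append(
            SyntenyBlock(host.target_chrom, ts, te, host.query_chrom, qs, qe, orient)
        )

    # 3. isolated spurious short blocks, strictly further than the isolation
    #    distance from every same-pair block already present
    skipped_spurious = 0
    tg, qg = truth.target_genome_def, truth.query_genome_def
    for _ in range(noise.n_spurious):
        placed = False
        for _try in range(200):
            t_chrom = tg.chromosomes[int(rng.integers(len(tg.chromosomes)))]
            q_chrom = qg.chromosomes[int(rng.integers(len(qg.chromosomes)))]
            sp_len = int(rng.integers(noise.min_block, noise.short_length))
            if t_chrom.length <= sp_len or q_chrom.length <= sp_len:
                continue
            t_pos = int(rng.integers(0, t_chrom.length - sp_len + 1))
            same_pair = [
                b
                for b in raw
                if b.target_chrom == t_chrom.id and b.query_chrom == q_chrom.id
            ]
            if any(
                max(0, max(b.target_start - (t_pos + sp_len), t_pos - b.target_end))
                <= noise.isolation_distance
                for b in same_pair
            ):
                continue
            q_pos = int(rng.integers(0, q_chrom.length - sp_len + 1))
            orient = Orientation.SAME if rng.integers(2) == 0 else Orientation.INVERTED
            raw.append(
                SyntenyBlock(
                    t_chrom.id, t_pos, t_pos + sp_len, q_chrom.id, q_pos, q_pos + sp_len, orient
                )
            )
            placed = True
            break
        if not placed:
            skipped_spurious += 1
    if skipped_embedded or skipped_spurious:
        warnings.warn(
            f"noise constraints unsatisfiable for {skipped_embedded} embedded and "
            f"{skipped_spurious} spurious blocks; skipped",
            stacklevel=2,
        )
    return BlockSet(
        target_genome=truth.blocks.target_genome,
        query_genome=truth.blocks.query_genome,
        blocks=tuple(raw),
    )


@dataclass(frozen=True)
class RecoveryReport:
    """Precision/recall of a filtered set against truth, with boundary deviations."""

    n_filtered: int
    n_truth: int
    n_matched: int
    precision: float
    recall: float
    max_boundary_deviation: int
    mean_boundary_deviation: float


def evaluate_recovery(
    filtered: BlockSet,
    truth: TruthSet | BlockSet,
    slack: int = 0,
    min_truth_length: int = 0,
) -> RecoveryReport:
    """Match filtered blocks to truth blocks and report precision and recall.

    A filtered block matches a truth block when both share (target
    chromosome, query chromosome, orientation) and all four boundaries agree
    within ``slack`` on both axes. Truth blocks with target length
    <= ``min_truth_length`` are excluded from the comparison.
    """
    truth_bs = truth.blocks if isinstance(truth, TruthSet) else truth
    truth_list = [
        b for b in truth_bs if block_length(b, "target") > min_truth_length
    ]
    unmatched = list(range(len(truth_list)))
    deviations: list[int] = []
    n_matched = 0
    for f in filtered:
        best: Optional[tuple[int, int]] = None  # (deviation, truth index)
        for pos, ti in enumerate(unmatched):
            t = truth_list[ti]
            if (
                t.target_chrom != f.target_chrom
                or t.query_chrom != f.query_chrom
                or t.orientation != f.orientation
            ):
                continue
            dev = max(
                abs(t.target_start - f.target_start),
                abs(t.target_end - f.target_end),
                abs(t.query_start - f.query_start),
                abs(t.query_end - f.query_end),
            )
            if dev <= slack and (best is None or dev < best[0]):
                best = (dev, pos)
        if best is not None:
            deviations.append(best[0])
            unmatched.pop(best[1])
            n_matched += 1
    n_filtered, n_truth = len(filtered), len(truth_list)
    return RecoveryReport(
        n_filtered=n_filtered,
        n_truth=n_truth,
        n_matched=n_matched,
        precision=n_matched / n_filtered if n_filtered else 1.0,
        recall=n_matched / n_truth if n_truth else 1.0,
        max_boundary_deviation=max(deviations) if deviations else 0,
        mean_boundary_deviation=float(np.mean(deviations)) if deviations else 0.0,
    )


@dataclass(frozen=True)
class TwoSpeciesResult:
    """Two descendant species mapped onto the same (unchanged) reference genome."""

    reference: GenomeDef
    genome_1: GenomeDef
    genome_2: GenomeDef
    truth_1: TruthSet
    truth_2: TruthSet
    shared_events: tuple[EventRecord, ...]


def simulate_two_species(
    reference: GenomeDef,
    shared: EventCounts,
    events_1: EventCounts,
    events_2: EventCounts,
    seed: int = 0,
    min_segment: int = 100_000,
    name_1: str = "S1",
    name_2: str = "S2",
    require_filter_stable: bool = True,
    filter_params: Optional[FilterParams] = None,
    max_attempts: int = 50,
) -> TwoSpeciesResult:
    """Evolve a common intermediate ancestor, then two species from it.

    The reference genome stays unchanged (the human-like frame); shared
    events build the intermediate ancestor whose derived associations are
    then inherited by both species — the signal the ancestral-synteny
    analysis is meant to recover.
    """
    params = filter_params or FilterParams()
    last_error: Optional[Exception] = None
    for attempt in range(max_attempts):
        rng = np.random.default_rng(_derived_seed(seed, attempt))
        ref_state = _identity_lineage(reference)
        intermediate = _identity_lineage(reference)
        try:
            shared_log = apply_events(intermediate, shared, rng, min_segment, "shared")
            state_1 = [list(c) for c in intermediate]
            state_2 = [list(c) for c in intermediate]
            log_1 = apply_events(
                state_1, events_1, rng, min_segment, name_1, start_index=shared.total
            )
            log_2 = apply_events(
                state_2, events_2, rng, min_segment, name_2, start_index=shared.total
            )
        except InfeasibleEventError as exc:
            if require_filter_stable:
                last_error = exc
                continue
            raise
        genome_1 = _lineage_genome(state_1, name_1, reference)
        genome_2 = _lineage_genome(state_2, name_2, reference)
        blocks_1 = truth_blocks(ref_state, reference, state_1, genome_1)
        blocks_2 = truth_blocks(ref_state, reference, state_2, genome_2)
        if require_filter_stable and not (
            _is_filter_stable(blocks_1, params) and _is_filter_stable(blocks_2, params)
        ):
            continue
        return TwoSpeciesResult(
            reference=reference,
            genome_1=genome_1,
            genome_2=genome_2,
            truth_1=TruthSet(
                blocks=blocks_1,
                events=tuple(shared_log + log_1),
                target_genome_def=reference,
                query_genome_def=genome_1,
                seed=seed,
                attempts=attempt + 1,
            ),
            truth_2=TruthSet(
                blocks=blocks_2,
                events=tuple(shared_log + log_2),
                target_genome_def=reference,
                query_genome_def=genome_2,
                seed=seed,
                attempts=attempt + 1,
            ),
            shared_events=tuple(shared_log),
        )
    if last_error is not None:
        raise last_error
    raise SyntenyError(
        f"no filter-stable event placement found in {max_attempts} attempts (seed {seed})"
    )
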