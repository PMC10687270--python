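"""Three-stage filtering of raw synteny blocks plus final length thresholding.

The pipeline mirrors the post-processing applied to raw halSynteny output
before comparison with chromosome painting data:

1. drop shorter blocks completely embedded in longer ones;
2. drop "short" (< 1 Mbp) blocks lying further than 3 Mbp from any other
   block of the same (target chromosome, query chromosome) pair — removing
   isolated noise while keeping short but clustered blocks;
3. merge adjacent (< 1 Mbp apart) blocks of the same chromosome pair and
   orientation;
4. retain only blocks longer than 1 Mbp.

Threshold strictness follows the published wording exactly: short is
L < 1 Mbp, isolated is gap > 3 Mbp, merging needs gap < 1 Mbp, retained
blocks are > 1 Mbp, and the 5 Mbp display view is inclusive (>= 5 Mbp).

All length and gap decisions are made on the target axis (the reference
frame of the PSL); merging additionally requires the gap condition on the
query axis so that hulls never bridge large query-side jumps. Embedded-block
containment is judged on both axes by default, with an either-axis mode
available.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from typing import Iterable

import numpy as np
from intervaltree import IntervalTree

from .model import BlockSet, FilterParams, Orientation, SyntenyBlock, block_length

logger = logging.getLogger(__name__)

_AXIS_MODES = {"both", "either"}


def _group_by_pair(
    blocks: Iterable[SyntenyBlock],
) -> dict[tuple[str, str], list[SyntenyBlock]]:
    groups: dict[tuple[str, str], list[SyntenyBlock]] = defaultdict(list)
    for b in blocks:
        groups[(b.target_chrom, b.query_chrom)].append(b)
    return groups


def _contains(a: SyntenyBlock, b: SyntenyBlock, axis_mode: str) -> bool:
    """Does a's footprint contain b's, per the configured axis mode?"""
    on_target = a.target_start <= b.target_start and b.target_end <= a.target_end
    on_query = a.query_start <= b.query_start and b.query_end <= a.query_end
    if axis_mode == "both":
        return on_target and on_query
    return on_target or on_query


def remove_embedded(bs: BlockSet, axis_mode: str = "both") -> BlockSet:
    """Drop blocks completely embedded in another block of the same pair.

    Exact duplicates (identical coordinate + orientation tuples) collapse to
    a single copy. Where two distinct blocks contain each other (identical
    footprints, differing orientation), the canonically first one is kept.
    """
    if axis_mode not in _AXIS_MODES:
        raise ValueError(f"axis_mode must be one of {_AXIS_MODES}, got {axis_mode!r}")
    kept: list[SyntenyBlock] = []
    for group in _group_by_pair(bs.blocks).values():
        group = sorted(group, key=lambda b: b.sort_key)
        # collapse exact duplicates first (keep first in canonical order)
        deduped: list[SyntenyBlock] = []
        seen: set[tuple] = set()
        for b in group:
            if b.sort_key in seen:
                continue
            seen.add(b.sort_key)
            deduped.append(b)
        if axis_mode == "both":
            # containment on both axes implies target-axis overlap, so an
            # interval tree on the target axis finds every candidate container
            tree = IntervalTree()
            for idx, b in enumerate(deduped):
                tree.addi(b.target_start, b.target_end, idx)
            candidates = [
                [(iv.data, deduped[iv.data]) for iv in tree.overlap(b.target_start, b.target_end)]
                for b in deduped
            ]
        else:
            all_pairs = list(enumerate(deduped))
            candidates = [all_pairs for _ in deduped]
        for rank, b in enumerate(deduped):
            removed = False
            for idx, a in candidates[rank]:
                if idx == rank or not _contains(a, b, axis_mode):
                    continue
                # mutual containment resolves in favour of the canonically first
                if _contains(b, a, axis_mode) and rank < idx:
                    continue
                removed = True
                break
            if not removed:
                kept.append(b)
    return bs.with_blocks(kept)


def remove_isolated_short(bs: BlockSet, params: FilterParams | None = None) -> BlockSet:
    """Drop short blocks with no same-pair neighbour within the isolation distance.

    A block with target-axis length < ``short_length`` is removed iff every
    other block of the same (target chromosome, query chromosome) pair lies
    strictly further than ``isolation_distance`` away on the target axis
    (gap measured between interval ends; overlap or touching counts as 0).
    """
    params = params or FilterParams()
    kept: list[SyntenyBlock] = []
    for group in _group_by_pair(bs.blocks).values():
        starts = np.array([b.target_start for b in group], dtype=np.int64)
        ends = np.array([b.target_end for b in group], dtype=np.int64)
        lengths = ends - starts
        for i, b in enumerate(group):
            if lengths[i] >= params.short_length:
                kept.append(b)
                continue
            gaps = np.maximum(0, np.maximum(starts - ends[i], starts[i] - ends))
            gaps[i] = np.iinfo(np.int64).max  # ignore self
            if len(group) > 1 and gaps.min() <= params.isolation_distance:
                kept.append(b)
    return bs.with_blocks(kept)


def _hull(a: SyntenyBlock, b: SyntenyBlock) -> SyntenyBlock:
    return SyntenyBlock(
        target_chrom=a.target_chrom,
        target_start=min(a.target_start, b.target_start),
        target_end=max(a.target_end, b.target_end),
        query_chrom=a.query_chrom,
        query_start=min(a.query_start, b.query_start),
        query_end=max(a.query_end, b.query_end),
        orientation=a.orientation,
    )


def merge_adjacent(bs: BlockSet, params: FilterParams | None = None) -> BlockSet:
    """Merge same-pair, same-orientation blocks closer than the merge gap.

    Two blocks merge when their gap is < ``merge_gap`` on the target axis
    AND on the query axis; they are replaced by their coordinate hull on
    both axes, repeatedly until a fixpoint. The fixpoint is unique: hulls
    only grow, so gaps never increase and merge opportunities never vanish.
    """
    params = params or FilterParams()
    gap = params.merge_gap
    out: list[SyntenyBlock] = []
    groups: dict[tuple, list[SyntenyBlock]] = defaultdict(list)
    for b in bs.blocks:
        groups[(b.target_chrom, b.query_chrom, b.orientation)].append(b)
    for group in groups.values():
        work = sorted(group, key=lambda b: b.sort_key)
        changed = True
        while changed:
            changed = False
            for i in range(len(work)):
                for j in range(i + 1, len(work)):
                    a, b = work[i], work[j]
                    t_gap = max(0, max(a.target_start - b.target_end, b.target_start - a.target_end))
                    q_gap = max(0, max(a.query_start - b.query_end, b.query_start - a.query_end))
                    if t_gap < gap and q_gap < gap:
                        merged = _hull(a, b)
                        work = [w for k, w in enumerate(work) if k not in (i, j)]
                        work.append(merged)
                        work.sort(key=lambda b: b.sort_key)
                        changed = True
                        break
                if changed:
                    break
        out.extend(work)
    return bs.with_blocks(out)


def apply_min_length(
    bs: BlockSet, threshold: int, inclusive: bool = False
) -> BlockSet:
    """Keep blocks passing a target-axis length threshold.

    The 1 Mbp retention rule is strict ("longer than": ``inclusive=False``);
    the 5 Mbp display rule is inclusive ("at least": ``inclusive=True``).
    """
    if inclusive:
        keep = [b for b in bs if block_length(b, "target") >= threshold]
    else:
        keep = [b for b in bs if block_length(b, "target") > threshold]
    return bs.with_blocks(keep)


def display_view(bs: BlockSet, params: FilterParams | None = None) -> BlockSet:
    """The inclusive >= 5 Mbp view used for karyotype maps (a view, not a stage)."""
    params = params or FilterParams()
    return apply_min_length(bs, params.display_threshold, inclusive=True)


def run_filter(
    bs: BlockSet,
    params: FilterParams | None = None,
    axis_mode: str = "both",
) -> BlockSet:
    """Run the full pipeline: embedded -> isolated-short -> merge -> retention.

    Per-stage block counts are logged at INFO level.
    """
    params = params or FilterParams()
    logger.info("raw: %d blocks", len(bs))
    s1 = remove_embedded(bs, axis_mode=axis_mode)
    logger.info("after embedded removal: %d blocks", len(s1))
    s2 = remove_isolated_short(s1, params)
    logger.info("after isolated-short removal: %d blocks", len(s2))
    s3 = merge_adjacent(s2, params)
    logger.info("after adjacency merge: %d blocks", len(s3))
    s4 = apply_min_length(s3, params.min_length, inclusive=False)
    logger.info("after min-length retention: %d blocks", len(s4))
    return s4
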