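"""Independent quadratic brute-force oracles for the filter stages.

These are deliberately naive, literal transcriptions of the stage
definitions (O(n^2) predicate scans and an explicit merge fixpoint loop)
against which the package's sweep/vectorized implementations are checked.
"""

from __future__ import annotations

from syntenymap.model import BlockSet, FilterParams, SyntenyBlock


def _same_pair(a: SyntenyBlock, b: SyntenyBlock) -> bool:
    return a.target_chrom == b.target_chrom and a.query_chrom == b.query_chrom


def _contains_both(a: SyntenyBlock, b: SyntenyBlock) -> bool:
    return (
        a.target_start <= b.target_start
        and b.target_end <= a.target_end
        and a.query_start <= b.query_start
        and b.query_end <= a.query_end
    )


def oracle_remove_embedded(bs: BlockSet) -> BlockSet:
    """A block is dropped iff some other same-pair block contains it on both
    axes; in mutual-containment ties (duplicates, identical footprints) only
    the canonically first survives."""
    blocks = sorted(bs.blocks, key=lambda b: b.sort_key)
    out = []
    for i, b in enumerate(blocks):
        drop = False
        for j, a in enumerate(blocks):
            if i == j or not _same_pair(a, b) or not _contains_both(a, b):
                continue
            if _contains_both(b, a) and j > i:
                continue  # mutual: the earlier block wins
            drop = True
            break
        if not drop:
            out.append(b)
    return bs.with_blocks(out)


def _t_gap(a: SyntenyBlock, b: SyntenyBlock) -> int:
    return max(0, max(a.target_start - b.target_end, b.target_start - a.target_end))


def _q_gap(a: SyntenyBlock, b: SyntenyBlock) -> int:
    return max(0, max(a.query_start - b.query_end, b.query_start - a.query_end))


def oracle_remove_isolated_short(bs: BlockSet, params: FilterParams) -> BlockSet:
    """Nearest-neighbour scan: drop short blocks whose closest same-pair
    neighbour (target axis) is strictly further than the isolation distance."""
    blocks = list(bs.blocks)
    out = []
    for b in blocks:
        if b.target_end - b.target_start >= params.short_length:
            out.append(b)
            continue
        neighbours = [a for a in blocks if a is not b and _same_pair(a, b)]
        if neighbours and min(_t_gap(a, b) for a in neighbours) <= params.isolation_distance:
            out.append(b)
    return bs.with_blocks(out)


def oracle_merge_adjacent(bs: BlockSet, params: FilterParams) -> BlockSet:
    """Explicit fixpoint: repeatedly merge the canonically first qualifying
    pair (same pair + orientation, gap < merge_gap on both axes) into its hull."""
    work = sorted(bs.blocks, key=lambda b: b.sort_key)
    while True:
        found = None
        for i in range(len(work)):
            for j in range(i + 1, len(work)):
                a, b = work[i], work[j]
                if (
                    _same_pair(a, b)
                    and a.orientation == b.orientation
                    and _t_gap(a, b) < params.merge_gap
                    and _q_gap(a, b) < params.merge_gap
                ):
                    found = (i, j)
                    break
            if found:
                break
        if not found:
            return bs.with_blocks(work)
        i, j = found
        a, b = work[i], work[j]
        hull = SyntenyBlock(
            a.target_chrom,
            min(a.target_start, b.target_start),
            max(a.target_end, b.target_end),
            a.query_chrom,
            min(a.query_start, b.query_start),
            max(a.query_end, b.query_end),
            a.orientation,
        )
        work = [w for k, w in enumerate(work) if k not in (i, j)] + [hull]
        work.sort(key=lambda b: b.sort_key)


def oracle_apply_min_length(bs: BlockSet, threshold: int, inclusive: bool = False) -> BlockSet:
    if inclusive:
        return bs.with_blocks(
            [b for b in bs.blocks if b.target_end - b.target_start >= threshold]
        )
    return bs.with_blocks(
        [b for b in bs.blocks if b.target_end - b.target_start > threshold]
    )
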