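"""Domain types shared by all pipeline stages.

Coordinates are 0-based half-open on both axes, the native PSL convention.
Query coordinates are always stored on the plus strand; an inversion is a
separate orientation flag, mirroring how PSL reports qStart/qEnd for '-'
strand records.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Iterator, Optional, Sequence


class SyntenyError(Exception):
    """Base class for all errors raised by this package."""


class IncomparableBlocksError(SyntenyError):
    """Two blocks do not share a chromosome on the requested axis."""


class UnknownChromosomeError(SyntenyError):
    """A chromosome label is absent from the relevant genome definition."""


class GenomeMismatchError(SyntenyError):
    """Two inputs that must share a genome name do not."""


class Orientation(str, Enum):
    """Relative strand of the query interval with respect to the target."""

    SAME = "same"
    INVERTED = "inverted"

    @classmethod
    def from_strand(cls, strand: str) -> "Orientation":
        if strand == "+":
            return cls.SAME
        if strand == "-":
            return cls.INVERTED
        raise ValueError(f"unrecognised strand {strand!r}")

    @property
    def strand(self) -> str:
        return "+" if self is Orientation.SAME else "-"


@dataclass(frozen=True)
class ChromosomeDef:
    """One chromosome: label, length in bp, optional centromere, autosome flag."""

    id: str
    length: int
    centromere: Optional[int] = None
    is_autosome: bool = True

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"chromosome {self.id!r}: length must be > 0")
        if self.centromere is not None and not (0 <= self.centromere <= self.length):
            raise ValueError(
                f"chromosome {self.id!r}: centromere {self.centromere} outside [0, {self.length}]"
            )


@dataclass(frozen=True)
class GenomeDef:
    """Chromosome inventory of one genome (a short species tag plus chromosomes)."""

    name: str
    chromosomes: tuple[ChromosomeDef, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosomes", tuple(self.chromosomes))
        ids = [c.id for c in self.chromosomes]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"genome {self.name!r}: duplicate chromosome ids {dup}")

    def __getitem__(self, chrom_id: str) -> ChromosomeDef:
        for c in self.chromosomes:
            if c.id == chrom_id:
                return c
        raise UnknownChromosomeError(
            f"chromosome {chrom_id!r} not in genome {self.name!r}"
        )

    def __contains__(self, chrom_id: str) -> bool:
        return any(c.id == chrom_id for c in self.chromosomes)

    @property
    def chromosome_ids(self) -> tuple[str, ...]:
        return tuple(c.id for c in self.chromosomes)


@dataclass(frozen=True, order=False)
class SyntenyBlock:
    """One homologous segment: a target interval paired with a query interval.

    Both intervals are 0-based half-open; the query interval is plus-strand
    regardless of orientation.
    """

    target_chrom: str
    target_start: int
    target_end: int
    query_chrom: str
    query_start: int
    query_end: int
    orientation: Orientation = Orientation.SAME

    def __post_init__(self) -> None:
        if not self.target_start < self.target_end:
            raise ValueError(
                f"empty/negative target interval {self.target_start}..{self.target_end}"
            )
        if not self.query_start < self.query_end:
            raise ValueError(
                f"empty/negative query interval {self.query_start}..{self.query_end}"
            )

    @property
    def sort_key(self) -> tuple:
        return (
            self.target_chrom,
            self.target_start,
            self.target_end,
            self.query_chrom,
            self.query_start,
            self.query_end,
            self.orientation.value,
        )

    def validate_against(
        self, target_genome: GenomeDef, query_genome: GenomeDef
    ) -> None:
        """Check intervals fall within the chromosome bounds of attached genomes."""
        t = target_genome[self.target_chrom]
        q = query_genome[self.query_chrom]
        if self.target_end > t.length:
            raise ValueError(
                f"target interval end {self.target_end} exceeds {t.id} length {t.length}"
            )
        if self.query_end > q.length:
            raise ValueError(
                f"query interval end {self.query_end} exceeds {q.id} length {q.length}"
            )


def block_length(block: SyntenyBlock, axis: str = "target") -> int:
    """Length of the block on one axis (bp covered, end - start)."""
    if axis == "target":
        return block.target_end - block.target_start
    if axis == "query":
        return block.query_end - block.query_start
    raise ValueError(f"axis must be 'target' or 'query', got {axis!r}")


def _interval(block: SyntenyBlock, axis: str) -> tuple[str, int, int]:
    if axis == "target":
        return block.target_chrom, block.target_start, block.target_end
    if axis == "query":
        return block.query_chrom, block.query_start, block.query_end
    raise ValueError(f"axis must be 'target' or 'query', got {axis!r}")


def gap_distance(a: SyntenyBlock, b: SyntenyBlock, axis: str = "target") -> int:
    """Base pairs strictly between two blocks on one axis; 0 if they overlap or touch.

    Raises IncomparableBlocksError when the blocks sit on different
    chromosomes on that axis.
    """
    ca, sa, ea = _interval(a, axis)
    cb, sb, eb = _interval(b, axis)
    if ca != cb:
        raise IncomparableBlocksError(
            f"blocks on different {axis} chromosomes: {ca!r} vs {cb!r}"
        )
    return max(0, max(sa - eb, sb - ea))


@dataclass(frozen=True)
class BlockSet:
    """All synteny blocks for one (target genome, query genome) pair.

    Blocks are held in canonical order: ascending
    (target_chrom, target_start, target_end, query_chrom, query_start, ...).
    """

    target_genome: str
    query_genome: str
    blocks: tuple[SyntenyBlock, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "blocks", tuple(sorted(self.blocks, key=lambda b: b.sort_key))
        )

    def __len__(self) -> int:
        return len(self.blocks)

    def __iter__(self) -> Iterator[SyntenyBlock]:
        return iter(self.blocks)

    def with_blocks(self, blocks: Iterable[SyntenyBlock]) -> "BlockSet":
        return replace(self, blocks=tuple(blocks))

    def on_query_chrom(self, chrom: str) -> tuple[SyntenyBlock, ...]:
        return tuple(b for b in self.blocks if b.query_chrom == chrom)

    def query_chroms(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for b in self.blocks:
            seen.setdefault(b.query_chrom, None)
        return tuple(sorted(seen, key=natural_key))

    def target_chroms(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for b in self.blocks:
            seen.setdefault(b.target_chrom, None)
        return tuple(sorted(seen, key=natural_key))


@dataclass(frozen=True)
class FilterParams:
    """Thresholds of the three-stage filter plus the display cutoff.

    Defaults follow the published procedure: short blocks are < 1 Mbp,
    isolation means further than 3 Mbp from any same-pair neighbour, merging
    joins same-pair blocks closer than 1 Mbp, retention keeps blocks longer
    than 1 Mbp, and the display view keeps blocks of at least 5 Mbp.
    """

    short_length: int = 1_000_000
    isolation_distance: int = 3_000_000
    merge_gap: int = 1_000_000
    min_length: int = 1_000_000
    display_threshold: int = 5_000_000

    def __post_init__(self) -> None:
        for name in (
            "short_length",
            "isolation_distance",
            "merge_gap",
            "min_length",
            "display_threshold",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def natural_key(label: str) -> tuple:
    """Sort key that orders embedded integers numerically (chr2 before chr10)."""
    parts: list[tuple[int, object]] = []
    num = ""
    for ch in label:
        if ch.isdigit():
            num += ch
        else:
            if num:
                parts.append((0, int(num)))
                num = ""
            parts.append((1, ch))
    if num:
        parts.append((0, int(num)))
    return tuple(parts)
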