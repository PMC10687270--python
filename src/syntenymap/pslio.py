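"""PSL, BED and homology-table I/O for synteny block sets.

PSL here is the UCSC 21-column tab-separated format as emitted by
halSynteny: coordinates 0-based half-open, query coordinates on the plus
strand with a separate strand column. Per-record sub-alignment structure
(blockCount/blockSizes/qStarts/tStarts) is collapsed to a single span on
read — the pipeline operates on block spans only — and written back in the
single-block degenerate encoding.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .model import BlockSet, GenomeDef, Orientation, SyntenyBlock, block_length

PSL_COLUMNS = 21


class PslParseError(Exception):
    """A malformed PSL line; the message names the 1-based line number."""


def _is_header(fields: list[str], line: str) -> bool:
    if not line.strip():
        return True
    if line.startswith(("psLayout", "----", "#")):
        return True
    # the classic 2-line column header starts with the word "match"
    return fields[0] in {"match", "matches"} and not fields[0].isdigit()


def read_psl(
    path: Union[str, Path],
    target_genome: str = "target",
    query_genome: str = "query",
) -> BlockSet:
    """Read one PSL file into a canonical BlockSet.

    Strand '+' maps to orientation ``same``, '-' to ``inverted``.
    Coordinates are taken from tStart/tEnd/qStart/qEnd unchanged.
    """
    blocks: list[SyntenyBlock] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.rstrip("\n").split("\t")
            if _is_header(fields, line):
                continue
            if len(fields) != PSL_COLUMNS:
                raise PslParseError(
                    f"{path} line {lineno}: expected {PSL_COLUMNS} columns, got {len(fields)}"
                )
            strand = fields[8]
            if strand not in {"+", "-"}:
                raise PslParseError(
                    f"{path} line {lineno}: unrecognised strand {strand!r}"
                )
            try:
                q_start, q_end = int(fields[11]), int(fields[12])
                t_start, t_end = int(fields[15]), int(fields[16])
            except ValueError as exc:
                raise PslParseError(
                    f"{path} line {lineno}: non-numeric coordinate ({exc})"
                ) from None
            if t_start >= t_end or q_start >= q_end:
                raise PslParseError(
                    f"{path} line {lineno}: start >= end "
                    f"(t {t_start}..{t_end}, q {q_start}..{q_end})"
                )
            blocks.append(
                SyntenyBlock(
                    target_chrom=fields[13],
                    target_start=t_start,
                    target_end=t_end,
                    query_chrom=fields[9],
                    query_start=q_start,
                    query_end=q_end,
                    orientation=Orientation.from_strand(strand),
                )
            )
    return BlockSet(target_genome=target_genome, query_genome=query_genome, blocks=tuple(blocks))


def _chrom_sizes(bs: BlockSet, genome: Optional[GenomeDef], axis: str) -> dict[str, int]:
    """Chromosome sizes for the PSL size columns.

    Without a genome definition the size falls back to the maximum end
    coordinate seen for that chromosome (deterministic, round-trip safe:
    the parser never uses the size columns).
    """
    sizes: dict[str, int] = {}
    for b in bs:
        chrom = b.target_chrom if axis == "target" else b.query_chrom
        end = b.target_end if axis == "target" else b.query_end
        sizes[chrom] = max(sizes.get(chrom, 0), end)
    if genome is not None:
        for chrom in sizes:
            if chrom in genome:
                sizes[chrom] = genome[chrom].length
    return sizes


def write_psl(
    bs: BlockSet,
    path: Union[str, Path],
    target_genome_def: Optional[GenomeDef] = None,
    query_genome_def: Optional[GenomeDef] = None,
) -> None:
    """Write a BlockSet as 21-column PSL in canonical order.

    Alignment-detail columns are filled with the single-block degenerate
    encoding: one block spanning the whole interval, matches = target span
    length, qStarts in reverse-complement coordinates for '-' records per
    the PSL convention.
    """
    t_sizes = _chrom_sizes(bs, target_genome_def, "target")
    q_sizes = _chrom_sizes(bs, query_genome_def, "query")
    with open(path, "w") as fh:
        for b in bs:
            t_len = b.target_end - b.target_start
            q_size = q_sizes[b.query_chrom]
            strand = b.orientation.strand
            q_block_start = (
                b.query_start if strand == "+" else q_size - b.query_end
            )
            fields = [
                t_len,  # matches
                0,  # misMatches
                0,  # repMatches
                0,  # nCount
                0,  # qNumInsert
                0,  # qBaseInsert
                0,  # tNumInsert
                0,  # tBaseInsert
                strand,
                b.query_chrom,
                q_size,
                b.query_start,
                b.query_end,
                b.target_chrom,
                t_sizes[b.target_chrom],
                b.target_start,
                b.target_end,
                1,  # blockCount
                f"{t_len},",
                f"{q_block_start},",
                f"{b.target_start},",
            ]
            fh.write("\t".join(str(f) for f in fields) + "\n")


def homology_table(bs: BlockSet) -> pd.DataFrame:
    """Canonically sorted table of block coordinates and sizes on both axes."""
    rows = [
        {
            "target_chrom": b.target_chrom,
            "target_start": b.target_start,
            "target_end": b.target_end,
            "target_size": block_length(b, "target"),
            "query_chrom": b.query_chrom,
            "query_start": b.query_start,
            "query_end": b.query_end,
            "query_size": block_length(b, "query"),
            "orientation": b.orientation.value,
        }
        for b in bs
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "target_chrom",
            "target_start",
            "target_end",
            "target_size",
            "query_chrom",
            "query_start",
            "query_end",
            "query_size",
            "orientation",
        ],
    )


def write_homology_table(bs: BlockSet, path: Union[str, Path]) -> None:
    """Write the per-block coordinate/size table as TSV."""
    homology_table(bs).to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_bed(bs: BlockSet, path: Union[str, Path]) -> None:
    """BED4 on the target axis; the name field carries the query descriptor."""
    with open(path, "w") as fh:
        for b in bs:
            name = (
                f"{b.query_chrom}:{b.query_start}-{b.query_end}"
                f"({b.orientation.strand})"
            )
            fh.write(
                f"{b.target_chrom}\t{b.target_start}\t{b.target_end}\t{name}\n"
            )
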