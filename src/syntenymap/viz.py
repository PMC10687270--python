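"""SVG rendering of synteny comparisons.

Two figure styles:

* two-track plots — one horizontal bar per query chromosome, blocks in the
  same orientation as the reference drawn on the upper track, inverted
  blocks on the lower track;
* painted karyotype maps — vertical per-chromosome ideograms with two
  side-by-side colour columns (one per target species), centromere dots and
  a 50 Mb scale bar; only blocks of at least the display threshold are
  drawn, and inversions within blocks are not shown.

SVG is written as plain text with fixed-precision coordinates, so renders
of identical inputs are byte-identical and diffable (golden-file testable).
Colours are a pure function of the target chromosome label: a fixed
categorical palette cycled over the natural-sorted labels of the block set.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional, Sequence, Union
from xml.sax.saxutils import escape, quoteattr

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
from .filtering import apply_min_length

# 20-colour categorical palette (hex), cycled in natural label order
PALETTE = (
    "#1f77b4", "#aec7e8", "#ff7f0e", "#ffbb78", "#2ca02c",
    "#98df8a", "#d62728", "#ff9896", "#9467bd", "#c5b0d5",
    "#8c564b", "#c49c94", "#e377c2", "#f7b6d2", "#7f7f7f",
    "#c7c7c7", "#bcbd22", "#dbdb8d", "#17becf", "#9edae5",
)

SCALE_BAR_BP = 50_000_000


def color_map(labels: Iterable[str]) -> dict[str, str]:
    """Deterministic label -> colour assignment (natural sort, palette cycled)."""
    ordered = sorted(set(labels), key=natural_key)
    return {lab: PALETTE[i % len(PALETTE)] for i, lab in enumerate(ordered)}


def _fmt(x: float) -> str:
    return f"{x:.2f}".rstrip("0").rstrip(".")


class _Svg:
    """Minimal deterministic SVG document builder."""

    def __init__(self, width: float, height: float) -> None:
        self.width = width
        self.height = height
        self.parts: list[str] = []

    def elem(self, tag: str, text: Optional[str] = None, **attrs: object) -> None:
        rendered = " ".join(
            f"{k.replace('_', '-')}={quoteattr(_fmt(v) if isinstance(v, float) else str(v))}"
            for k, v in attrs.items()
        )
        if text is None:
            self.parts.append(f"<{tag} {rendered}/>")
        else:
            self.parts.append(f"<{tag} {rendered}>{escape(text)}</{tag}>")

    def rect(self, x: float, y: float, w: float, h: float, fill: str, **attrs: object) -> None:
        self.elem("rect", x=float(x), y=float(y), width=float(w), height=float(h), fill=fill, **attrs)

    def write(self, path: Union[str, Path]) -> None:
        body = "\n".join(self.parts)
        doc = (
            f'<svg xmlns="http://www.w3.org/2000/svg" '
            f'width={quoteattr(_fmt(self.width))} height={quoteattr(_fmt(self.height))} '
            f'viewBox={quoteattr(f"0 0 {_fmt(self.width)} {_fmt(self.height)}")}>\n'
            f"{body}\n</svg>\n"
        )
        Path(path).write_text(doc)


def render_two_track(
    bs: BlockSet,
    genome: GenomeDef,
    out_path: Union[str, Path],
    threshold: int = 5_000_000,
    inclusive: bool = True,
    width: float = 1000.0,
) -> None:
    """Two-track orientation plot: one horizontal bar per query chromosome.

    Same-orientation blocks go on the upper track, inverted blocks on the
    lower. ``genome`` is the query genome definition; every query chromosome
    in the block set must exist in it. The threshold is applied with the
    display semantics by default (inclusive >= 5 Mbp) or strictly
    (``inclusive=False``) for the 1 Mbp retention view.
    """
    if width <= 0:
        raise ValueError("rendering area must have positive width")
    for b in bs:
        if b.query_chrom not in genome:
            raise UnknownChromosomeError(
                f"query chromosome {b.query_chrom!r} not in genome {genome.name!r}"
            )
    shown = apply_min_length(bs, threshold, inclusive=inclusive)
    colors = color_map(b.target_chrom for b in bs)
    chroms = genome.chromosomes
    margin, label_w = 20.0, 60.0
    track_h, row_gap = 14.0, 16.0
    row_h = 2 * track_h + row_gap
    max_len = max((c.length for c in chroms), default=1)
    px_per_bp = (width - label_w - 2 * margin) / max_len
    height = margin * 2 + row_h * len(chroms) + 30.0
    svg = _Svg(width, height)
    svg.elem(
        "text",
        text=f"{bs.target_genome} blocks on {bs.query_genome} chromosomes",
        x=float(margin),
        y=14.0,
        font_size="12",
        font_family="sans-serif",
        **{"class": "title"},
    )
    for row, chrom in enumerate(chroms):
        y0 = margin + 20.0 + row * row_h
        x0 = margin + label_w
        svg.elem(
            "text",
            text=chrom.id,
            x=float(margin),
            y=y0 + track_h + 4.0,
            font_size="11",
            font_family="sans-serif",
            **{"class": "chrom-label"},
        )
        # backbone between the two tracks
        svg.rect(
            x0,
            y0 + track_h - 0.5,
            chrom.length * px_per_bp,
            1.0,
            "#333333",
            **{"class": "chrom"},
        )
        for b in shown.on_query_chrom(chrom.id):
            bx = x0 + b.query_start * px_per_bp
            bw = max(block_length(b, "query") * px_per_bp, 0.5)
            upper = b.orientation is Orientation.SAME
            by = y0 if upper else y0 + track_h + 1.0
            svg.rect(
                bx,
                by,
                bw,
                track_h - 2.0,
                colors[b.target_chrom],
                stroke="#222222",
                stroke_width="0.3",
                **{
                    "class": "block",
                    "data-target": b.target_chrom,
                    "data-track": "upper" if upper else "lower",
                },
            )
    _scale_bar(svg, margin + label_w, height - 18.0, px_per_bp)
    svg.write(out_path)


def _scale_bar(svg: _Svg, x: float, y: float, px_per_bp: float) -> None:
    bar_px = SCALE_BAR_BP * px_per_bp
    svg.rect(x, y, bar_px, 3.0, "#000000", **{"class": "scale-bar"})
    svg.elem(
        "text",
        text="50 Mb",
        x=x + bar_px + 6.0,
        y=y + 4.0,
        font_size="10",
        font_family="sans-serif",
        **{"class": "scale-label"},
    )


def render_karyotype_map(
    bs_x: BlockSet,
    bs_y: BlockSet,
    genome: GenomeDef,
    out_path: Union[str, Path],
    threshold: int = 5_000_000,
    height: float = 420.0,
) -> None:
    """Painted karyotype: vertical ideograms with two colour columns per chromosome.

    ``bs_x`` and ``bs_y`` are two block sets sharing the same query genome
    (e.g. homologies of two different target species on one karyotype).
    Only blocks of at least ``threshold`` (inclusive) are painted; block
    orientation is not depicted. Centromeres, where annotated in the genome
    definition, are drawn as black dots beside each ideogram.
    """
    if bs_x.query_genome != bs_y.query_genome:
        raise GenomeMismatchError(
            f"block sets map different query genomes: "
            f"{bs_x.query_genome!r} vs {bs_y.query_genome!r}"
        )
    if genome.name != bs_x.query_genome:
        raise GenomeMismatchError(
            f"genome {genome.name!r} does not match query genome {bs_x.query_genome!r}"
        )
    shown_x = apply_min_length(bs_x, threshold, inclusive=True)
    shown_y = apply_min_length(bs_y, threshold, inclusive=True)
    colors_x = color_map(b.target_chrom for b in bs_x)
    colors_y = color_map(b.target_chrom for b in bs_y)
    chroms = genome.chromosomes
    margin, top = 20.0, 40.0
    col_w, col_gap, slot_gap = 12.0, 3.0, 26.0
    slot_w = 2 * col_w + col_gap + slot_gap
    max_len = max((c.length for c in chroms), default=1)
    px_per_bp = (height - top - 60.0) / max_len
    width = margin * 2 + slot_w * len(chroms)
    svg = _Svg(width, height)
    svg.elem(
        "text",
        text=(
            f"{genome.name} karyotype painted by "
            f"{bs_x.target_genome} (left) and {bs_y.target_genome} (right)"
        ),
        x=float(margin),
        y=16.0,
        font_size="12",
        font_family="sans-serif",
        **{"class": "title"},
    )
    for i, chrom in enumerate(chroms):
        x0 = margin + i * slot_w
        for col, (shown, colors, tag) in enumerate(
            ((shown_x, colors_x, bs_x.target_genome), (shown_y, colors_y, bs_y.target_genome))
        ):
            cx = x0 + col * (col_w + col_gap)
            svg.rect(
                cx,
                top,
                col_w,
                chrom.length * px_per_bp,
                "#f2f2f2",
                stroke="#555555",
                stroke_width="0.4",
                **{"class": "ideogram", "data-chrom": chrom.id, "data-species": tag},
            )
            for b in shown.on_query_chrom(chrom.id):
                svg.rect(
                    cx,
                    top + b.query_start * px_per_bp,
                    col_w,
                    block_length(b, "query") * px_per_bp,
                    colors[b.target_chrom],
                    **{"class": "block", "data-target": b.target_chrom, "data-species": tag},
                )
        if chrom.centromere is not None:
            svg.elem(
                "circle",
                cx=x0 + col_w + col_gap / 2,
                cy=top + chrom.centromere * px_per_bp,
                r=3.0,
                fill="#000000",
                **{"class": "centromere", "data-chrom": chrom.id},
            )
        svg.elem(
            "text",
            text=chrom.id,
            x=x0,
            y=top + chrom.length * px_per_bp + 14.0,
            font_size="10",
            font_family="sans-serif",
            **{"class": "chrom-label"},
        )
    _scale_bar(svg, margin, height - 20.0, px_per_bp)
    svg.write(out_path)
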