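"""Rendering: to-scale neighbourhood diagrams, legend TSV, flag-annotated trees.

All outputs are deterministic: no timestamps, fixed float formatting, stable
ordering.  SVG is assembled as text (single root element, shared style
tokens), so re-rendering the same model is byte-identical.

Style semantics follow the figure conventions: conserved groups are filled
with their group colour, non-conserved genes are unfilled with a grey border,
pseudogenes are grey-filled with a blue border, and non-coding genes use a
hatch pattern.  Truncated contig sides render nothing beyond the last real
gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from skbio import TreeNode

from .clustering import (
    QUERY_COLOUR,
    STYLE_CONSERVED,
    STYLE_NONCODING,
    STYLE_NONCONSERVED,
    STYLE_PSEUDOGENE,
    STYLE_QUERY,
    GroupAssignment,
    Node,
)
from .genome_store import GeneRecord
from .neighbourhood import Neighbourhood

__all__ = [
    "GeneGlyph",
    "RowLayout",
    "LegendRow",
    "RenderModel",
    "RenderError",
    "layout_row",
    "build_render_model",
    "render_diagram",
    "write_description",
    "annotate_tree",
]

# Fixed style resolution (fill, stroke) per token; conserved fill comes from
# the palette at layout time.
_STYLE_FILLS = {
    STYLE_QUERY: (QUERY_COLOUR, "#333333"),
    STYLE_NONCONSERVED: ("none", "#999999"),
    STYLE_PSEUDOGENE: ("#bfbfbf", "#1f77b4"),
    STYLE_NONCODING: ("url(#hatch)", "#777777"),
}

_ROW_H = 48.0
_ARROW_H = 16.0
_MARGIN = 18.0
_LABEL_W = 120.0


class RenderError(Exception):
    pass


@dataclass(frozen=True)
class GeneGlyph:
    slot: int
    record: GeneRecord
    style: str
    fill: str
    stroke: str
    label: str  # group number as text, or ""
    x0: float  # px relative to the query start (may be negative)
    x1: float
    points_right: bool


@dataclass(frozen=True)
class RowLayout:
    query_id: str
    assembly_id: str
    contig_id: str
    neighbourhood: Neighbourhood
    glyphs: tuple[GeneGlyph, ...]


@dataclass(frozen=True)
class LegendRow:
    group_id: int
    colour: str
    product: str
    member_protein_ids: tuple[str, ...]
    neighbourhood_count: int


@dataclass
class RenderModel:
    rows: list[RowLayout]
    legend_rows: list[LegendRow]
    scale: float  # bp per pixel
    tree: TreeNode | None = None
    assignments: dict[Node, GroupAssignment] = field(default_factory=dict)


def _resolve_style(
    rec: GeneRecord, assignment: GroupAssignment | None, colours: Mapping[int, str]
) -> tuple[str, str, str, str]:
    """Return (style token, fill, stroke, label) for one gene slot."""
    if rec.kind == "pseudogene":
        fill, stroke = _STYLE_FILLS[STYLE_PSEUDOGENE]
        return STYLE_PSEUDOGENE, fill, stroke, ""
    if rec.kind == "noncoding":
        fill, stroke = _STYLE_FILLS[STYLE_NONCODING]
        return STYLE_NONCODING, fill, stroke, ""
    if assignment is None or assignment.group_id is None:
        fill, stroke = _STYLE_FILLS[STYLE_NONCONSERVED]
        return STYLE_NONCONSERVED, fill, stroke, ""
    label = str(assignment.group_id)
    if assignment.query_family:
        fill, stroke = _STYLE_FILLS[STYLE_QUERY]
        return STYLE_QUERY, fill, stroke, label
    return STYLE_CONSERVED, colours[assignment.group_id], "#333333", label


def layout_row(
    nb: Neighbourhood,
    nb_index: int,
    assignments: Mapping[Node, GroupAssignment],
    colours: Mapping[int, str],
    scale: float,
) -> RowLayout:
    """Compute glyph geometry for one neighbourhood at ``scale`` bp/px.

    Rows are anchored at the query start (x = 0) so that queries align into a
    vertical column across rows; widths and gaps are proportional to base
    pairs within float quantization.
    """
    if scale <= 0:
        raise RenderError(f"scale must be positive, got {scale}")
    origin = nb.query.start
    glyphs: list[GeneGlyph] = []
    for slot, rec in nb.slots():
        if rec.length_bp <= 0:
            raise RenderError(f"zero-length gene at slot {slot}")
        style, fill, stroke, label = _resolve_style(
            rec, assignments.get((nb_index, slot)), colours
        )
        glyphs.append(
            GeneGlyph(
                slot=slot,
                record=rec,
                style=style,
                fill=fill,
                stroke=stroke,
                label=label,
                x0=(rec.start - origin) / scale,
                x1=(rec.end + 1 - origin) / scale,
                points_right=rec.strand == "+",
            )
        )
    assembly_id, contig_id = nb.origin
    return RowLayout(
        query_id=nb.query.protein_id or (nb.query.locus_tag or "?"),
        assembly_id=assembly_id,
        contig_id=contig_id,
        neighbourhood=nb,
        glyphs=tuple(glyphs),
    )


def build_render_model(
    neighbourhoods: Sequence[Neighbourhood],
    assignments: Mapping[Node, GroupAssignment],
    colours: Mapping[int, str],
    scale: float = 16.0,
    tree: TreeNode | None = None,
) -> RenderModel:
    rows = [
        layout_row(nb, i, assignments, colours, scale)
        for i, nb in enumerate(neighbourhoods)
    ]

    # Legend: one row per numbered group, ordered by group number.
    by_group: dict[int, list[tuple[Node, GeneRecord]]] = {}
    rec_of: dict[Node, GeneRecord] = {}
    for i, nb in enumerate(neighbourhoods):
        for slot, rec in nb.slots():
            rec_of[(i, slot)] = rec
    for node, a in assignments.items():
        if a.group_id is not None and node in rec_of:
            by_group.setdefault(a.group_id, []).append((node, rec_of[node]))
    legend: list[LegendRow] = []
    for gid in sorted(by_group):
        members = sorted(by_group[gid], key=lambda t: t[0])
        products = [r.product for _, r in members if r.product]
        any_assignment = assignments[members[0][0]]
        colour = QUERY_COLOUR if any_assignment.query_family else colours[gid]
        legend.append(
            LegendRow(
                group_id=gid,
                colour=colour,
                product=products[0] if products else "",
                member_protein_ids=tuple(
                    sorted({r.protein_id for _, r in members if r.protein_id})
                ),
                neighbourhood_count=any_assignment.neighbourhood_count,
            )
        )
    return RenderModel(
        rows=rows,
        legend_rows=legend,
        scale=scale,
        tree=tree,
        assignments=dict(assignments),
    )


def _fmt(v: float) -> str:
    return f"{v:.2f}"


def _arrow_points(
    x0: float, x1: float, y_mid: float, points_right: bool
) -> str:
    """Seven-point arrow polygon; head shrinks for short genes."""
    h = _ARROW_H / 2.0
    head = min(10.0, 0.45 * (x1 - x0))
    if points_right:
        bx = x1 - head
        pts = [
            (x0, y_mid - h),
            (bx, y_mid - h),
            (bx, y_mid - h - 3),
            (x1, y_mid),
            (bx, y_mid + h + 3),
            (bx, y_mid + h),
            (x0, y_mid + h),
        ]
    else:
        bx = x0 + head
        pts = [
            (x1, y_mid - h),
            (bx, y_mid - h),
            (bx, y_mid - h - 3),
            (x0, y_mid),
            (bx, y_mid + h + 3),
            (bx, y_mid + h),
            (x1, y_mid + h),
        ]
    return " ".join(f"{_fmt(x)},{_fmt(y)}" for x, y in pts)


_HATCH_DEF = (
    '<defs><pattern id="hatch" width="5" height="5" '
    'patternTransform="rotate(45)" patternUnits="userSpaceOnUse">'
    '<line x1="0" y1="0" x2="0" y2="5" stroke="#777777" stroke-width="1.2"/>'
    "</pattern></defs>"
)


def render_diagram(model: RenderModel) -> str:
    """The to-scale neighbourhood diagram as an SVG document (text)."""
    if not model.rows:
        raise RenderError("empty render model")
    max_left = max((-min((g.x0 for g in r.glyphs), default=0.0)) for r in model.rows)
    max_right = max((max((g.x1 for g in r.glyphs), default=0.0)) for r in model.rows)
    x_query = _MARGIN + _LABEL_W + max_left
    width = x_query + max_right + _MARGIN
    height = _MARGIN * 2 + _ROW_H * len(model.rows)

    parts = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{_fmt(width)}" '
        f'height="{_fmt(height)}" viewBox="0 0 {_fmt(width)} {_fmt(height)}">',
        _HATCH_DEF,
    ]
    for ri, row in enumerate(model.rows):
        y_mid = _MARGIN + _ROW_H * ri + _ROW_H / 2.0
        parts.append(
            f'<text x="{_fmt(_MARGIN)}" y="{_fmt(y_mid + 4)}" '
            f'font-family="monospace" font-size="11">{row.query_id}</text>'
        )
        for g in row.glyphs:
            pts = _arrow_points(x_query + g.x0, x_query + g.x1, y_mid, g.points_right)
            parts.append(
                f'<polygon points="{pts}" fill="{g.fill}" stroke="{g.stroke}" '
                f'stroke-width="1.2" data-style="{g.style}" data-slot="{g.slot}"/>'
            )
            if g.label:
                xc = x_query + (g.x0 + g.x1) / 2.0
                parts.append(
                    f'<text x="{_fmt(xc)}" y="{_fmt(y_mid - _ARROW_H / 2.0 - 5)}" '
                    f'font-family="sans-serif" font-size="10" '
                    f'text-anchor="middle" data-group="{g.label}">{g.label}</text>'
                )
    parts.append("</svg>")
    return "\n".join(parts) + "\n"


_DESCRIPTION_HEADER = (
    "#query_id\tassembly_id\tcontig\tslot\tprotein_id\tgroup\tcolour\t"
    "product\tstrand\tstart\tend\tflipped"
)


def write_description(model: RenderModel) -> str:
    """The legend TSV: one row per (query, slot), '#'-prefixed header.

    The ``group`` column holds the group number for numbered genes, ``NC``
    for non-conserved coding genes, ``PSEUDO`` for pseudogenes and ``RNA``
    for non-coding genes.  Coordinates are as drawn; ``flipped`` marks
    mirrored (reverse-strand query) neighbourhoods.
    """
    lines = [_DESCRIPTION_HEADER]
    for row in model.rows:
        nb = row.neighbourhood
        for g in row.glyphs:
            rec = g.record
            if g.style in (STYLE_QUERY, STYLE_CONSERVED):
                group = g.label
                colour = g.fill
            elif g.style == STYLE_PSEUDOGENE:
                group, colour = "PSEUDO", STYLE_PSEUDOGENE
            elif g.style == STYLE_NONCODING:
                group, colour = "RNA", STYLE_NONCODING
            else:
                group, colour = "NC", STYLE_NONCONSERVED
            lines.append(
                "\t".join(
                    [
                        row.query_id,
                        row.assembly_id,
                        row.contig_id,
                        str(g.slot),
                        rec.protein_id or "-",
                        group,
                        colour,
                        rec.product,
                        rec.strand,
                        str(rec.start),
                        str(rec.end),
                        "yes" if nb.flipped else "no",
                    ]
                )
            )
    return "\n".join(lines) + "\n"


def _tree_layout(tree: TreeNode) -> tuple[dict, dict, float]:
    """Assign y per node (tips evenly spaced) and x from branch lengths."""
    ys: dict[int, float] = {}
    xs: dict[int, float] = {}
    tips = list(tree.tips())
    for i, tip in enumerate(tips):
        ys[id(tip)] = float(i)
    for node in tree.postorder():
        if not node.is_tip():
            children = node.children
            ys[id(node)] = sum(ys[id(c)] for c in children) / len(children)
    xs[id(tree)] = 0.0
    max_x = 0.0
    for node in tree.preorder():
        if node is tree:
            continue
        length = node.length if node.length else 0.0
        xs[id(node)] = xs[id(node.parent)] + max(length, 1e-9)
        max_x = max(max_x, xs[id(node)])
    return xs, ys, max_x if max_x > 0 else 1.0


def annotate_tree(tree: TreeNode, model: RenderModel) -> str:
    """Tree SVG with a strip of triangular pennant flags per leaf.

    Leaf names must equal the model's query identifiers; flags reuse the
    diagram's colour and number coding, and flag columns are aligned by slot
    so the query flags form a vertical column.
    """
    leaf_names = [t.name for t in tree.tips()]
    rows_by_query = {row.query_id: row for row in model.rows}
    missing = sorted(set(rows_by_query) - set(leaf_names))
    extra = sorted(set(leaf_names) - set(rows_by_query))
    if missing or extra:
        raise RenderError(
            f"tree/query mismatch: queries missing from tree {missing}, "
            f"tree leaves without queries {extra}"
        )

    xs, ys, max_x = _tree_layout(tree)
    tree_w = 160.0
    row_h = 40.0
    flag_w, flag_h, flag_pitch = 12.0, 10.0, 18.0
    max_up = max(len(r.neighbourhood.upstream) for r in model.rows)
    max_down = max(len(r.neighbourhood.downstream) for r in model.rows)
    strip_x = _MARGIN + tree_w + _LABEL_W + 10.0
    width = strip_x + (max_up + max_down + 1) * flag_pitch + _MARGIN
    height = _MARGIN * 2 + row_h * len(leaf_names)

    def px(node: TreeNode) -> float:
        return _MARGIN + tree_w * xs[id(node)] / max_x

    def py(node: TreeNode) -> float:
        return _MARGIN + row_h * ys[id(node)] + row_h / 2.0

    parts = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{_fmt(width)}" '
        f'height="{_fmt(height)}" viewBox="0 0 {_fmt(width)} {_fmt(height)}">',
    ]
    for node in tree.preorder():
        if node is tree:
            continue
        x0, x1, y = px(node.parent), px(node), py(node)
        yp = py(node.parent)
        parts.append(
            f'<path d="M {_fmt(x0)} {_fmt(yp)} V {_fmt(y)} H {_fmt(x1)}" '
            f'fill="none" stroke="#444444" stroke-width="1.2"/>'
        )
    for tip in tree.tips():
        y = py(tip)
        parts.append(
            f'<text x="{_fmt(_MARGIN + tree_w + 6)}" y="{_fmt(y + 3)}" '
            f'font-family="monospace" font-size="10">{tip.name}</text>'
        )
        row = rows_by_query[tip.name]
        for g in row.glyphs:
            fx = strip_x + (g.slot + max_up) * flag_pitch
            pole_top = y - flag_h - 4.0
            parts.append(
                f'<line x1="{_fmt(fx)}" y1="{_fmt(y + 6)}" x2="{_fmt(fx)}" '
                f'y2="{_fmt(pole_top)}" stroke="#555555" stroke-width="1"/>'
            )
            tri = (
                f"{_fmt(fx)},{_fmt(pole_top)} "
                f"{_fmt(fx + flag_w)},{_fmt(pole_top + flag_h / 2.0)} "
                f"{_fmt(fx)},{_fmt(pole_top + flag_h)}"
            )
            parts.append(
                f'<polygon points="{tri}" fill="{g.fill}" stroke="{g.stroke}" '
                f'stroke-width="1" data-style="{g.style}" data-slot="{g.slot}"/>'
            )
            if g.label:
                parts.append(
                    f'<text x="{_fmt(fx + 2)}" y="{_fmt(y + 14)}" '
                    f'font-family="sans-serif" font-size="7" '
                    f'data-group="{g.label}">{g.label}</text>'
                )
    parts.append("</svg>")
    return "\n".join(parts) + "\n"
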