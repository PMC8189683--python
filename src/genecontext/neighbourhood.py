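"""Flanking-gene extraction: query gene plus up to n neighbours per side.

Flanks are counted by gene index in the per-contig sorted order, not by
base-pair distance; pseudogenes and non-coding genes occupy slots.  A query on
the reverse strand has its whole neighbourhood mirrored (coordinates
reflected, strands inverted, sides swapped) so that queries always point
right in downstream rendering.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator

from .genome_store import Assembly, GeneRecord

__all__ = ["Neighbourhood", "NeighbourhoodError", "extract_neighbourhood"]


class NeighbourhoodError(Exception):
    pass


@dataclass(frozen=True)
class Neighbourhood:
    """A query gene with up to ``n`` flanking genes on each side.

    ``upstream``/``downstream`` are nearest-first and refer to the drawn
    orientation (query pointing right): upstream genes are drawn to the left.
    If ``flipped`` is true the coordinates have been reflected so that the
    original reverse-strand query now reads ``+``.
    """

    query: GeneRecord
    upstream: tuple[GeneRecord, ...]
    downstream: tuple[GeneRecord, ...]
    flipped: bool
    truncated_left: bool
    truncated_right: bool
    origin: tuple[str, str]  # (assembly_id, contig_id)

    def slots(self) -> Iterator[tuple[int, GeneRecord]]:
        """Yield (slot, record) in drawn left-to-right order.

        Upstream slots are negative (-1 nearest the query), the query is
        slot 0, downstream slots are positive.
        """
        for i in range(len(self.upstream) - 1, -1, -1):
            yield -(i + 1), self.upstream[i]
        yield 0, self.query
        for i, rec in enumerate(self.downstream):
            yield i + 1, rec

    @property
    def n_genes(self) -> int:
        return 1 + len(self.upstream) + len(self.downstream)


def _reflect(rec: GeneRecord, axis: int) -> GeneRecord:
    """Mirror a record through ``axis`` (reflected coord = axis + 1 - coord)."""
    return replace(
        rec,
        start=axis + 1 - rec.end,
        end=axis + 1 - rec.start,
        strand="-" if rec.strand == "+" else "+",
    )


def extract_neighbourhood(
    assembly: Assembly, query: GeneRecord, n: int
) -> Neighbourhood:
    """Extract the query plus the ``n`` nearest genes on each side.

    Fewer than ``n`` genes toward a contig end sets the corresponding
    truncation flag.  Features wholly containing the query are excluded from
    the flanks (annotation artifacts would otherwise be double-drawn).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    feats = assembly.features.get(query.contig_id)
    if not feats:
        raise NeighbourhoodError(
            f"contig {query.contig_id} not in assembly {assembly.assembly_id}"
        )
    try:
        qi = feats.index(query)
    except ValueError:
        raise NeighbourhoodError(
            f"query {query.protein_id or query.locus_tag} not found in "
            f"assembly {assembly.assembly_id}"
        )

    def eligible(rec: GeneRecord) -> bool:
        return not (rec.start <= query.start and rec.end >= query.end)

    before = [f for f in feats[:qi] if eligible(f)]
    after = [f for f in feats[qi + 1 :] if eligible(f)]
    left = before[-n:][::-1]  # nearest-first, genomic left
    right = after[:n]  # nearest-first, genomic right
    trunc_low = len(before) < n
    trunc_high = len(after) < n

    if query.strand == "+":
        return Neighbourhood(
            query=query,
            upstream=tuple(left),
            downstream=tuple(right),
            flipped=False,
            truncated_left=trunc_low,
            truncated_right=trunc_high,
            origin=(assembly.assembly_id, query.contig_id),
        )

    # Reverse-strand query: mirror everything so the query points right.
    contig_len = assembly.contigs.get(query.contig_id)
    axis = contig_len if contig_len is not None else max(f.end for f in feats)
    return Neighbourhood(
        query=_reflect(query, axis),
        upstream=tuple(_reflect(r, axis) for r in right),
        downstream=tuple(_reflect(r, axis) for r in left),
        flipped=True,
        truncated_left=trunc_high,
        truncated_right=trunc_low,
        origin=(assembly.assembly_id, query.contig_id),
    )
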