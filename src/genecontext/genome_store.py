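"""Local assembly store: GFF3 + protein FASTA parsing behind a provider contract.

Assemblies are parsed from RefSeq-dialect GFF3 (CDS rows carry ``protein_id``
in column 9) plus an amino-acid FASTA keyed by protein accession.  The module
exposes query-list parsing, assembly loading (plain or gzip) and query
location across one or more loaded assemblies.
"""

from __future__ import annotations

import gzip
import io
import logging
from bisect import bisect_left
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "GeneRecord",
    "Assembly",
    "QueryItem",
    "GenomeStoreError",
    "QueryListError",
    "GFFParseError",
    "QueryNotFoundError",
    "AmbiguousQueryError",
    "parse_query_list",
    "load_assembly",
    "load_assembly_files",
    "locate_query",
]

# Feature types treated as non-coding genes (occupy a neighbourhood slot,
# never clustered).
_NONCODING_TYPES = frozenset(
    {
        "tRNA",
        "rRNA",
        "ncRNA",
        "tmRNA",
        "misc_RNA",
        "antisense_RNA",
        "SRP_RNA",
        "RNase_P_RNA",
        "riboswitch",
    }
)

_VALID_STRANDS = frozenset({"+", "-"})


class GenomeStoreError(Exception):
    """Base error for this module."""


class QueryListError(GenomeStoreError):
    """Malformed, duplicate or empty query list."""


class GFFParseError(GenomeStoreError):
    """Unparseable GFF3 content; message carries the 1-based line number."""


class QueryNotFoundError(GenomeStoreError):
    """Protein accession absent from the searched assemblies."""


class AmbiguousQueryError(GenomeStoreError):
    """Protein accession present in more than one assembly with no target given."""


@dataclass(frozen=True)
class GeneRecord:
    """One annotated feature: coding gene, pseudogene or non-coding gene.

    Coordinates are GFF3-style 1-based inclusive base pairs; ``start <= end``
    always, regardless of strand.
    """

    contig_id: str
    start: int
    end: int
    strand: str
    kind: str  # "coding" | "pseudogene" | "noncoding"
    protein_id: str | None = None
    locus_tag: str | None = None
    product: str = ""

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.kind == "coding" and not self.protein_id:
            raise ValueError("coding record requires a protein_id")
        if self.kind in ("pseudogene", "noncoding") and self.protein_id:
            raise ValueError(f"{self.kind} record must not carry a protein_id")
        if self.kind not in ("coding", "pseudogene", "noncoding"):
            raise ValueError(f"unknown kind {self.kind!r}")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class QueryItem:
    protein_id: str
    assembly_id: str | None = None


@dataclass
class Assembly:
    """A parsed assembly: contigs, per-contig sorted features, protein sequences."""

    assembly_id: str
    contigs: dict[str, int | None] = field(default_factory=dict)
    features: dict[str, list[GeneRecord]] = field(default_factory=dict)
    proteins: dict[str, str] = field(default_factory=dict)
    missing_proteins: set[str] = field(default_factory=set)
    warnings: list[str] = field(default_factory=list)

    def contig_features(self, contig_id: str) -> list[GeneRecord]:
        return self.features[contig_id]

    def iter_features(self) -> Iterable[GeneRecord]:
        for contig in self.features.values():
            yield from contig

    def find_by_protein(self, protein_id: str) -> GeneRecord | None:
        for rec in self.iter_features():
            if rec.protein_id == protein_id:
                return rec
        return None

    def protein_sequence(self, protein_id: str) -> str | None:
        return self.proteins.get(protein_id)

    def find_at(self, contig_id: str, start: int) -> GeneRecord | None:
        """Binary search the sorted feature list for a record starting at ``start``."""
        feats = self.features.get(contig_id, [])
        i = bisect_left(feats, start, key=lambda r: r.start)
        while i < len(feats) and feats[i].start == start:
            return feats[i]
        return None


def parse_query_list(text: str) -> list[QueryItem]:
    """Parse the query-list format: one protein accession per line, optionally
    followed by an assembly identifier.  Blank lines and ``#`` comments are
    skipped; order is preserved; duplicates are rejected.
    """
    items: list[QueryItem] = []
    seen: set[tuple[str, str | None]] = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) > 2:
            raise QueryListError(
                f"line {lineno}: expected 'protein_id' or 'protein_id<TAB>assembly_id', "
                f"got {len(fields)} fields"
            )
        item = QueryItem(fields[0], fields[1] if len(fields) == 2 else None)
        key = (item.protein_id, item.assembly_id)
        if key in seen:
            raise QueryListError(f"line {lineno}: duplicate query {item.protein_id}")
        seen.add(key)
        items.append(item)
    if not items:
        raise QueryListError("no queries")
    return items


def _parse_attributes(col9: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in col9.rstrip(";").split(";"):
        if not chunk:
            continue
        key, _, value = chunk.partition("=")
        attrs[key.strip()] = value.strip()
    return attrs


def _classify(ftype: str, attrs: dict[str, str], pseudo_parents: set[str]) -> str | None:
    """Return record kind for a raw GFF feature, or None if not a gene-like row."""
    if ftype == "pseudogene":
        return "pseudogene"
    if ftype == "CDS":
        if attrs.get("pseudo", "").lower() == "true":
            return "pseudogene"
        parent = attrs.get("Parent")
        if parent is not None and parent in pseudo_parents:
            return "pseudogene"
        return "coding"
    if ftype in _NONCODING_TYPES:
        return "noncoding"
    return None


def load_assembly(gff_source: str, faa_source: str, assembly_id: str) -> Assembly:
    """Build an :class:`Assembly` from GFF3 text and protein-FASTA text.

    RefSeq conventions honoured:

    * CDS rows with ``pseudo=true``, rows of type ``pseudogene``, and CDS
      children of genes with ``gene_biotype=pseudogene`` become pseudogene
      records (no protein).
    * RNA feature types become non-coding records.
    * Multi-segment CDS rows sharing a ``protein_id`` on one contig merge into
      a single record spanning ``min(start)..max(end)``.

    A CDS whose protein is absent from the FASTA is kept but flagged in
    :attr:`Assembly.missing_proteins` (warning, not fatal).
    """
    proteins: dict[str, str] = {}
    for rec in SeqIO.parse(io.StringIO(faa_source), "fasta"):
        proteins[rec.id] = str(rec.seq).upper()

    assembly = Assembly(assembly_id=assembly_id, proteins=proteins)

    # First pass: validate syntax, note contig lengths and pseudogene parents.
    rows: list[tuple[int, list[str]]] = []
    pseudo_parents: set[str] = set()
    for lineno, raw in enumerate(gff_source.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("##sequence-region"):
            parts = line.split()
            if len(parts) >= 4:
                try:
                    assembly.contigs[parts[1]] = int(parts[3])
                except ValueError:
                    raise GFFParseError(f"line {lineno}: bad sequence-region length")
            continue
        if line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise GFFParseError(
                f"line {lineno}: expected 9 tab-separated columns, got {len(cols)}"
            )
        try:
            int(cols[3]), int(cols[4])
        except ValueError:
            raise GFFParseError(f"line {lineno}: non-integer coordinates")
        if cols[6] not in ("+", "-", ".", "?"):
            raise GFFParseError(f"line {lineno}: bad strand {cols[6]!r}")
        rows.append((lineno, cols))
        if cols[2] in ("gene", "pseudogene"):
            attrs = _parse_attributes(cols[8])
            if (
                cols[2] == "pseudogene"
                or attrs.get("gene_biotype") == "pseudogene"
                or attrs.get("pseudo", "").lower() == "true"
            ):
                ident = attrs.get("ID")
                if ident:
                    pseudo_parents.add(ident)

    # Second pass: build records, merging multi-segment CDS by protein_id.
    cds_segments: dict[tuple[str, str], list[tuple[int, int, str, dict[str, str]]]] = {}
    records: list[GeneRecord] = []
    pseudo_spans: set[tuple[str, int, int]] = set()
    for lineno, cols in rows:
        contig, _, ftype, s, e, _, strand, _, col9 = cols
        attrs = _parse_attributes(col9)
        kind = _classify(ftype, attrs, pseudo_parents)
        if kind is None:
            continue
        start, end = int(s), int(e)
        if end < start:
            raise GFFParseError(f"line {lineno}: end < start")
        strand = strand if strand in _VALID_STRANDS else "+"
        if kind == "coding":
            protein_id = attrs.get("protein_id")
            if not protein_id:
                # CDS without accession: treat as pseudogene-like unannotated ORF
                kind = "pseudogene"
            else:
                cds_segments.setdefault((contig, protein_id), []).append(
                    (start, end, strand, attrs)
                )
                continue
        if kind == "pseudogene":
            key = (contig, start, end)
            if key in pseudo_spans:
                continue  # pseudogene row + its own CDS child: keep one
            pseudo_spans.add(key)
        records.append(
            GeneRecord(
                contig_id=contig,
                start=start,
                end=end,
                strand=strand,
                kind=kind,
                locus_tag=attrs.get("locus_tag"),
                product=attrs.get("product", ""),
            )
        )

    for (contig, protein_id), segments in cds_segments.items():
        start = min(s for s, _, _, _ in segments)
        end = max(e for _, e, _, _ in segments)
        _, _, strand, attrs = segments[0]
        records.append(
            GeneRecord(
                contig_id=contig,
                start=start,
                end=end,
                strand=strand,
                kind="coding",
                protein_id=protein_id,
                locus_tag=attrs.get("locus_tag"),
                product=attrs.get("product", ""),
            )
        )
        if protein_id not in proteins:
            assembly.missing_proteins.add(protein_id)
            msg = f"{assembly_id}: protein {protein_id} absent from FASTA"
            assembly.warnings.append(msg)
            logger.warning(msg)

    for rec in records:
        assembly.features.setdefault(rec.contig_id, []).append(rec)
        assembly.contigs.setdefault(rec.contig_id, None)
    for contig, feats in assembly.features.items():
        feats.sort(key=lambda r: (r.start, r.end))
        length = assembly.contigs.get(contig)
        if length is not None:
            for rec in feats:
                if rec.end > length:
                    raise GFFParseError(
                        f"feature {rec.protein_id or rec.locus_tag or rec.start} "
                        f"exceeds contig {contig} length {length}"
                    )
    return assembly


def _open_text(path: str | Path) -> str:
    path = Path(path)
    data = path.read_bytes()
    if data[:2] == b"\x1f\x8b":
        data = gzip.decompress(data)
    return data.decode("utf-8")


def load_assembly_files(
    gff_path: str | Path, faa_path: str | Path, assembly_id: str
) -> Assembly:
    """Load an assembly from files; ``.gz``-compressed inputs are accepted."""
    return load_assembly(_open_text(gff_path), _open_text(faa_path), assembly_id)


def locate_query(
    provider: Assembly | Sequence[Assembly] | Mapping[str, Assembly],
    item: QueryItem,
) -> tuple[Assembly, GeneRecord]:
    """Find the gene record for a query accession.

    With ``item.assembly_id`` set, only that assembly is searched.  Otherwise
    all assemblies are searched; a unique hit is required — matches in two or
    more assemblies raise :class:`AmbiguousQueryError` naming the candidates.
    """
    if isinstance(provider, Assembly):
        assemblies = [provider]
    elif isinstance(provider, Mapping):
        assemblies = list(provider.values())
    else:
        assemblies = list(provider)

    if item.assembly_id is not None:
        pool = [a for a in assemblies if a.assembly_id == item.assembly_id]
        if not pool:
            raise QueryNotFoundError(
                f"assembly {item.assembly_id} not loaded (query {item.protein_id})"
            )
    else:
        pool = assemblies

    hits: list[tuple[Assembly, GeneRecord]] = []
    for assembly in pool:
        rec = assembly.find_by_protein(item.protein_id)
        if rec is not None:
            hits.append((assembly, rec))
    if not hits:
        raise QueryNotFoundError(f"protein {item.protein_id} not found")
    if len(hits) > 1:
        names = ", ".join(a.assembly_id for a, _ in hits)
        raise AmbiguousQueryError(
            f"protein {item.protein_id} found in multiple assemblies ({names}); "
            "add an assembly identifier to the query line"
        )
    return hits[0]
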