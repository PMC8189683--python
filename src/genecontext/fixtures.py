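"""Deterministic synthetic assemblies for offline testing.

The generator emits RefSeq-dialect GFF3 + protein FASTA per assembly, a query
list and a ground-truth table.  It plants homologous protein families across
assemblies by mutating a common ancestor; each member is derived at
``(1 + identity) / 2`` identity to the ancestor so that the *pairwise*
identity between any two members concentrates around the requested
``identity`` fraction.  Substitutions only (no indels), so identity
arithmetic is exact per member.

Pseudogenes are emitted through both RefSeq encodings (CDS with
``pseudo=true``, and a ``gene_biotype=pseudogene`` gene with a CDS child) so
both detection paths get exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "PlantedFamily",
    "FixtureSpec",
    "TruthRow",
    "TruthTable",
    "Fixture",
    "PackingError",
    "generate",
    "write_fixture",
]

_AA = "ARNDCQEGHILKMFPSTWYV"

#: family id used for the planted query family
QUERY_FAMILY = "FAM_Q"


class PackingError(ValueError):
    """More planted members than neighbourhood slots (or too few genes)."""


@dataclass(frozen=True)
class PlantedFamily:
    family_id: str
    members_per_assembly: int = 1
    identity: float = 0.9  # target pairwise identity among members

    def __post_init__(self) -> None:
        if not 0.3 <= self.identity <= 1.0:
            raise ValueError("identity fraction must be in [0.3, 1.0]")
        if self.members_per_assembly < 1:
            raise ValueError("members_per_assembly must be >= 1")


@dataclass(frozen=True)
class FixtureSpec:
    n_assemblies: int = 3
    genes_per_contig: int = 9
    contigs_per_assembly: int = 1
    planted_families: tuple[PlantedFamily, ...] = ()
    pseudogene_rate: float = 0.0
    noncoding_rate: float = 0.0
    edge_query: bool = False
    flank_window: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_assemblies < 1 or self.contigs_per_assembly < 1:
            raise ValueError("need >= 1 assembly and >= 1 contig")
        if self.genes_per_contig < 2:
            raise PackingError("genes_per_contig must be >= 2")
        for rate in (self.pseudogene_rate, self.noncoding_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.pseudogene_rate + self.noncoding_rate > 1.0:
            raise ValueError("pseudogene_rate + noncoding_rate must be <= 1")
        if self.flank_window < 1:
            raise ValueError("flank_window must be >= 1")


@dataclass(frozen=True)
class TruthRow:
    assembly_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    kind: str
    protein_id: str | None
    family_id: str | None  # None for unplanted filler
    is_query: bool


@dataclass
class TruthTable:
    rows: list[TruthRow] = field(default_factory=list)

    def family_of(self, protein_id: str) -> str | None:
        for row in self.rows:
            if row.protein_id == protein_id:
                return row.family_id
        raise KeyError(protein_id)

    def to_tsv(self) -> str:
        header = (
            "#assembly_id\tcontig_id\tstart\tend\tstrand\tkind\t"
            "protein_id\tfamily_id\tis_query"
        )
        lines = [header]
        for r in self.rows:
            lines.append(
                "\t".join(
                    [
                        r.assembly_id,
                        r.contig_id,
                        str(r.start),
                        str(r.end),
                        r.strand,
                        r.kind,
                        r.protein_id or "-",
                        r.family_id or "-",
                        "yes" if r.is_query else "no",
                    ]
                )
            )
        return "\n".join(lines) + "\n"


@dataclass
class Fixture:
    spec: FixtureSpec
    assemblies: list[tuple[str, str, str]]  # (assembly_id, gff_text, faa_text)
    query_list: str
    truth: TruthTable


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(_AA[i] for i in rng.integers(0, len(_AA), size=length))


def _mutate(rng: np.random.Generator, seq: str, identity: float) -> str:
    """Substitute positions so the result has exactly the given identity."""
    length = len(seq)
    n_mut = round((1.0 - identity) * length)
    if n_mut == 0:
        return seq
    positions = rng.choice(length, size=n_mut, replace=False)
    chars = list(seq)
    for pos in positions:
        choices = [a for a in _AA if a != chars[pos]]
        chars[pos] = choices[rng.integers(0, len(choices))]
    return "".join(chars)


def _window_slots(qi: int, n_genes: int, window: int) -> list[int]:
    return [
        j
        for j in range(max(0, qi - window), min(n_genes, qi + window + 1))
        if j != qi
    ]


def generate(spec: FixtureSpec) -> Fixture:
    """Generate the fixture deterministically from ``spec`` (same spec+seed
    gives byte-identical files)."""
    rng = np.random.default_rng(spec.seed)

    qi = 1 if spec.edge_query else spec.genes_per_contig // 2
    slots = _window_slots(qi, spec.genes_per_contig, spec.flank_window)
    demand = sum(f.members_per_assembly for f in spec.planted_families)
    if demand > len(slots):
        raise PackingError(
            f"infeasible packing: {demand} planted members but only "
            f"{len(slots)} neighbourhood slots"
        )

    # Family ancestors (shared across assemblies).  Member-to-ancestor
    # identity (1+t)/2 puts member-to-member identity near t.
    ancestors: dict[str, str] = {
        QUERY_FAMILY: _random_protein(rng, int(rng.integers(110, 160)))
    }
    member_identity: dict[str, float] = {QUERY_FAMILY: 0.95}
    for fam in spec.planted_families:
        ancestors[fam.family_id] = _random_protein(rng, int(rng.integers(100, 160)))
        member_identity[fam.family_id] = (1.0 + fam.identity) / 2.0

    assemblies: list[tuple[str, str, str]] = []
    truth = TruthTable()
    query_lines: list[str] = []

    for a in range(spec.n_assemblies):
        assembly_id = f"GCF_{spec.seed % 100000:05d}{a:02d}.1"
        pid_counter = 0
        gff_lines = ["##gff-version 3"]
        body_lines: list[str] = []
        faa_lines: list[str] = []
        pseudo_gene_counter = 0

        def next_pid() -> str:
            nonlocal pid_counter
            pid_counter += 1
            return f"WP_A{a:02d}{pid_counter:04d}.1"

        # Plan contig 1: query + planted members inside the flank window.
        placement: dict[int, str] = {}  # gene index -> family_id
        order = [int(x) for x in rng.permutation(len(slots))]
        cursor = 0
        for fam in spec.planted_families:
            for _ in range(fam.members_per_assembly):
                placement[slots[order[cursor]]] = fam.family_id
                cursor += 1

        for c in range(spec.contigs_per_assembly):
            contig_id = f"ctg{c + 1}"
            n_genes = (
                spec.genes_per_contig
                if c == 0
                else max(2, spec.genes_per_contig // 2)
            )
            pos = 100
            for j in range(n_genes):
                strand = "+" if rng.random() < 0.5 else "-"
                is_query = c == 0 and j == qi
                family: str | None = None
                if is_query:
                    family = QUERY_FAMILY
                elif c == 0 and j in placement:
                    family = placement[j]

                if family is not None:
                    seq = _mutate(rng, ancestors[family], member_identity[family])
                    kind = "coding"
                else:
                    u = rng.random()
                    if u < spec.pseudogene_rate:
                        kind = "pseudogene"
                    elif u < spec.pseudogene_rate + spec.noncoding_rate:
                        kind = "noncoding"
                    else:
                        kind = "coding"
                        seq = _random_protein(rng, int(rng.integers(80, 160)))

                if kind == "coding":
                    pid = next_pid()
                    bp_len = 3 * (len(seq) + 1)
                    start, end = pos, pos + bp_len - 1
                    body_lines.append(
                        "\t".join(
                            [
                                contig_id,
                                "fixture",
                                "CDS",
                                str(start),
                                str(end),
                                ".",
                                strand,
                                "0",
                                f"ID=cds-{pid};protein_id={pid};"
                                f"product=protein {family or 'filler'} {pid}",
                            ]
                        )
                    )
                    faa_lines.append(f">{pid}\n{seq}")
                elif kind == "pseudogene":
                    pid = None
                    bp_len = int(rng.integers(200, 500))
                    start, end = pos, pos + bp_len - 1
                    pseudo_gene_counter += 1
                    if pseudo_gene_counter % 2 == 1:
                        body_lines.append(
                            "\t".join(
                                [
                                    contig_id,
                                    "fixture",
                                    "CDS",
                                    str(start),
                                    str(end),
                                    ".",
                                    strand,
                                    "0",
                                    f"ID=cds-ps{pseudo_gene_counter};pseudo=true;"
                                    "product=degraded ORF",
                                ]
                            )
                        )
                    else:
                        gid = f"gene-ps{pseudo_gene_counter}"
                        body_lines.append(
                            "\t".join(
                                [
                                    contig_id,
                                    "fixture",
                                    "gene",
                                    str(start),
                                    str(end),
                                    ".",
                                    strand,
                                    ".",
                                    f"ID={gid};gene_biotype=pseudogene",
                                ]
                            )
                        )
                        body_lines.append(
                            "\t".join(
                                [
                                    contig_id,
                                    "fixture",
                                    "CDS",
                                    str(start),
                                    str(end),
                                    ".",
                                    strand,
                                    "0",
                                    f"ID=cds-ps{pseudo_gene_counter};Parent={gid};"
                                    "product=degraded ORF",
                                ]
                            )
                        )
                else:  # noncoding
                    pid = None
                    bp_len = int(rng.integers(80, 300))
                    start, end = pos, pos + bp_len - 1
                    body_lines.append(
                        "\t".join(
                            [
                                contig_id,
                                "fixture",
                                "tRNA",
                                str(start),
                                str(end),
                                ".",
                                strand,
                                ".",
                                f"ID=rna-{c}-{j};product=tRNA-Xxx",
                            ]
                        )
                    )

                truth.rows.append(
                    TruthRow(
                        assembly_id=assembly_id,
                        contig_id=contig_id,
                        start=start,
                        end=end,
                        strand=strand,
                        kind=kind,
                        protein_id=pid if kind == "coding" else None,
                        family_id=family,
                        is_query=is_query,
                    )
                )
                if is_query:
                    query_lines.append(f"{pid}\t{assembly_id}")
                pos = end + 1 + int(rng.integers(30, 150))

            contig_len = pos + 400
            gff_lines.append(f"##sequence-region {contig_id} 1 {contig_len}")

        gff_text = "\n".join(gff_lines + body_lines) + "\n"
        faa_text = "\n".join(faa_lines) + "\n"
        assemblies.append((assembly_id, gff_text, faa_text))

    return Fixture(
        spec=spec,
        assemblies=assemblies,
        query_list="\n".join(query_lines) + "\n",
        truth=truth,
    )


def write_fixture(fixture: Fixture, outdir: str | Path) -> dict[str, Path]:
    """Write GFF/FASTA per assembly, the query list and the truth TSV.

    Returns a map of logical names to paths (``queries``, ``truth`` and
    ``<assembly_id>.gff`` / ``<assembly_id>.faa``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for assembly_id, gff_text, faa_text in fixture.assemblies:
        gff = outdir / f"{assembly_id}.gff"
        faa = outdir / f"{assembly_id}.faa"
        gff.write_text(gff_text)
        faa.write_text(faa_text)
        paths[f"{assembly_id}.gff"] = gff
        paths[f"{assembly_id}.faa"] = faa
    paths["queries"] = outdir / "queries.txt"
    paths["queries"].write_text(fixture.query_list)
    paths["truth"] = outdir / "truth.tsv"
    paths["truth"].write_text(fixture.truth.to_tsv())
    return paths
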