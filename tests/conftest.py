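from __future__ import annotations

import pytest

import genecontext as gc
from genecontext.fixtures import FixtureSpec, PlantedFamily, generate

MINIMAL_GFF = """##gff-version 3
##sequence-region c1 1 5000
c1\tsrc\tCDS\t100\t400\t.\t+\t0\tID=cds1;protein_id=WP_1;product=alpha
"""

MINIMAL_FAA = ">WP_1\nMKTAYIAKQR\n"


def make_gff(rows: list[str], contig: str = "c1", length: int = 100000) -> str:
    head = ["##gff-version 3", f"##sequence-region {contig} 1 {length}"]
    return "\n".join(head + rows) + "\n"


def cds_row(
    start: int,
    end: int,
    pid: str,
    strand: str = "+",
    contig: str = "c1",
    product: str = "p",
    extra: str = "",
) -> str:
    attrs = f"ID=cds-{pid}-{start};protein_id={pid};product={product}{extra}"
    return f"{contig}\tsrc\tCDS\t{start}\t{end}\t.\t{strand}\t0\t{attrs}"


def analyse_fixture(fixture, n_flank=4, cutoff=1e-6, seed=0, backend="builtin"):
    """Run the in-memory analysis stages on a generated fixture."""
    assemblies = [
        gc.load_assembly(gff, faa, aid) for aid, gff, faa in fixture.assemblies
    ]
    items = gc.parse_query_list(fixture.query_list)
    neighbourhoods = []
    for item in items:
        assembly, record = gc.locate_query(assemblies, item)
        neighbourhoods.append(gc.extract_neighbourhood(assembly, record, n_flank))
    proteins = {}
    for assembly in assemblies:
        proteins.update(assembly.proteins)
    params = gc.SearchParams(evalue_cutoff=cutoff, backend=backend)
    graph = gc.build_hit_graph(neighbourhoods, params, proteins)
    components = gc.cluster_components(graph)
    assignments = gc.assign_groups(components, neighbourhoods)
    colours = gc.assign_colours(assignments, seed)
    return {
        "assemblies": assemblies,
        "items": items,
        "neighbourhoods": neighbourhoods,
        "proteins": proteins,
        "graph": graph,
        "components": components,
        "assignments": assignments,
        "colours": colours,
    }


def partition_by_protein(components, neighbourhoods):
    """Recovered partition as a set of frozensets of protein ids."""
    rec_of = {}
    for i, nb in enumerate(neighbourhoods):
        for slot, rec in nb.slots():
            rec_of[(i, slot)] = rec
    out = set()
    for comp in components:
        out.add(frozenset(rec_of[node].protein_id for node in comp))
    return out


def truth_partition(fixture, neighbourhoods):
    """Expected partition over proteins present in the neighbourhoods."""
    family = {
        r.protein_id: r.family_id for r in fixture.truth.rows if r.protein_id
    }
    in_run = set()
    for nb in neighbourhoods:
        for _, rec in nb.slots():
            if rec.kind == "coding":
                in_run.add(rec.protein_id)
    groups: dict = {}
    singletons = set()
    for pid in in_run:
        fam = family[pid]
        if fam is None:
            singletons.add(frozenset([pid]))
        else:
            groups.setdefault(fam, set()).add(pid)
    return {frozenset(g) for g in groups.values()} | singletons


@pytest.fixture
def small_fixture():
    spec = FixtureSpec(
        n_assemblies=3,
        genes_per_contig=9,
        planted_families=(
            PlantedFamily("FAM_1", 1, 0.8),
            PlantedFamily("FAM_2", 1, 0.7),
        ),
        pseudogene_rate=0.1,
        noncoding_rate=0.1,
        seed=5,
    )
    return generate(spec)


@pytest.fixture
def small_analysis(small_fixture):
    return analyse_fixture(small_fixture)
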