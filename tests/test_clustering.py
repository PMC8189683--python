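import random

import pytest

from conftest import analyse_fixture, partition_by_protein, truth_partition
from genecontext.clustering import (
    QUERY_COLOUR,
    HitGraph,
    SearchParams,
    assign_colours,
    assign_groups,
    build_hit_graph,
    cluster_components,
)
from genecontext.fixtures import FixtureSpec, PlantedFamily, generate
from genecontext.genome_store import GeneRecord
from genecontext.neighbourhood import Neighbourhood
from oracles import components_oracle

AA = "ARNDCQEGHILKMFPSTWYV"


def _record(contig, start, pid, kind="coding", strand="+", length=300):
    return GeneRecord(
        contig_id=contig,
        start=start,
        end=start + length - 1,
        strand=strand,
        kind=kind,
        protein_id=pid if kind == "coding" else None,
    )


def make_neighbourhood(idx, slot_kinds, assembly="GCF_X"):
    """Build a neighbourhood whose slots are n//2 upstream, query, rest
    downstream; returns (Neighbourhood, {slot: protein_id})."""
    n_up = len(slot_kinds) // 2
    pids = {}
    upstream, downstream = [], []
    pos = 1000
    query = _record(f"c{idx}", pos, f"Q{idx}")
    pids[0] = f"Q{idx}"
    for i, kind in enumerate(slot_kinds):
        pos += 400
        if i < n_up:
            slot = -(i + 1)
        else:
            slot = i - n_up + 1
        pid = f"P{idx}_{slot}" if kind == "coding" else None
        rec = _record(f"c{idx}", pos, pid, kind=kind)
        if slot < 0:
            upstream.append(rec)
        else:
            downstream.append(rec)
        if pid:
            pids[slot] = pid
    return (
        Neighbourhood(
            query=query,
            upstream=tuple(upstream),
            downstream=tuple(downstream),
            flipped=False,
            truncated_left=False,
            truncated_right=False,
            origin=(assembly, f"c{idx}"),
        ),
        pids,
    )


def _random_seq(rng, k=80):
    return "".join(rng.choices(AA, k=k))


class TestBuildHitGraph:
    def test_identical_proteins_in_two_neighbourhoods_linked(self):
        rng = random.Random(0)
        shared = _random_seq(rng)
        nb0, pids0 = make_neighbourhood(0, ["coding", "coding"])
        nb1, pids1 = make_neighbourhood(1, ["coding", "coding"])
        proteins = {
            pids0[0]: _random_seq(rng),
            pids1[0]: _random_seq(rng),
            pids0[-1]: shared,
            pids1[-1]: shared,
            pids0[1]: _random_seq(rng),
            pids1[1]: _random_seq(rng),
        }
        graph = build_hit_graph(
            [nb0, nb1], SearchParams(evalue_cutoff=1e-3), proteins
        )
        assert ((0, -1), (1, -1)) in graph.edges
        assert len(graph.nodes) == 6

    @pytest.mark.parametrize("seed", range(20))
    def test_shuffled_residues_give_no_edges(self, seed):
        """Empirical null: shuffles of one sequence are unrelated at 1e-6."""
        rng = random.Random(seed)
        base = list(_random_seq(rng, 90))
        nbs, proteins = [], {}
        for i in range(3):
            shuffled = base[:]
            rng.shuffle(shuffled)
            nb, pids = make_neighbourhood(i, [])
            nbs.append(nb)
            proteins[pids[0]] = "".join(shuffled)
        graph = build_hit_graph(nbs, SearchParams(evalue_cutoff=1e-6), proteins)
        assert len(graph.edges) == 0

    def test_tighter_cutoff_is_subset(self, small_fixture):
        loose = analyse_fixture(small_fixture, cutoff=1e-3)
        tight = analyse_fixture(small_fixture, cutoff=1e-10)
        assert tight["graph"].edge_set() <= loose["graph"].edge_set()

    def test_no_self_edges_and_cutoff_respected(self, small_analysis):
        graph = small_analysis["graph"]
        for (a, b), (evalue, _) in graph.edges.items():
            assert a != b
            assert evalue <= 1e-6

    def test_no_coding_proteins_is_error(self):
        nb, _ = make_neighbourhood(0, ["pseudogene"])
        with pytest.raises(ValueError):
            build_hit_graph([nb], SearchParams(), {})


class TestClusterComponents:
    def test_transitive_linkage(self):
        graph = HitGraph(nodes={(0, 0), (1, 0), (2, 0), (3, 0)})
        graph.add_edge((0, 0), (1, 0), 1e-9, 50)
        graph.add_edge((1, 0), (2, 0), 1e-9, 50)
        comps = cluster_components(graph)
        assert {frozenset(c) for c in comps} == {
            frozenset({(0, 0), (1, 0), (2, 0)}),
            frozenset({(3, 0)}),
        }

    def test_empty_edge_set_gives_singletons(self):
        nodes = {(i, 0) for i in range(5)}
        comps = cluster_components(HitGraph(nodes=set(nodes)))
        assert all(len(c) == 1 for c in comps)
        assert len(comps) == 5

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_union_find_oracle(self, seed):
        rng = random.Random(seed)
        for _ in range(20):
            n = rng.randint(2, 40)
            nodes = [(i, rng.randint(-4, 4)) for i in range(n)]
            graph = HitGraph(nodes=set(nodes))
            edges = []
            for _ in range(rng.randint(0, 2 * n)):
                a, b = rng.sample(nodes, 2)
                graph.add_edge(a, b, 1e-8, 40)
                edges.append((a, b))
            got = {frozenset(c) for c in cluster_components(graph)}
            assert got == components_oracle(set(nodes), edges)


class TestAssignGroups:
    def _with_components(self, comps, n_neighbourhoods=6):
        nbs = [make_neighbourhood(i, [])[0] for i in range(n_neighbourhoods)]
        return assign_groups(comps, nbs)

    def test_wider_spread_gets_smaller_number(self):
        # family in 5 neighbourhoods (flank slots) vs family in 3
        big = {(i, 1) for i in range(5)}
        small = {(i, -1) for i in range(3)}
        queries = {(i, 0) for i in range(6)}
        assignments = self._with_components([queries, big, small])
        assert assignments[(0, 0)].group_id == 1  # query family spans 6
        assert assignments[(0, 1)].group_id == 2
        assert assignments[(0, -1)].group_id == 3

    def test_twice_in_one_neighbourhood_not_conserved(self):
        comp = {(0, 1), (0, 2)}  # same neighbourhood, two slots
        queries = {(0, 0)}
        assignments = self._with_components([comp, queries], n_neighbourhoods=1)
        a = assignments[(0, 1)]
        assert not a.conserved
        assert a.group_id is None
        assert a.neighbourhood_count == 1

    def test_query_family_always_numbered(self):
        queries = {(0, 0)}
        assignments = self._with_components([queries], n_neighbourhoods=1)
        a = assignments[(0, 0)]
        assert a.group_id is not None
        assert a.query_family

    def test_group_ids_consecutive_from_one(self, small_analysis):
        ids = sorted(
            {
                a.group_id
                for a in small_analysis["assignments"].values()
                if a.group_id is not None
            }
        )
        assert ids == list(range(1, len(ids) + 1))

    def test_conservation_dichotomy(self, small_analysis):
        for a in small_analysis["assignments"].values():
            if a.conserved:
                assert a.group_id is not None
                assert a.neighbourhood_count >= 2
            elif a.group_id is not None:
                assert a.query_family  # only query families bypass the rule

    @pytest.mark.parametrize("seed", range(10))
    def test_numbering_invariant_to_edge_order(self, seed, small_analysis):
        graph = small_analysis["graph"]
        nbs = small_analysis["neighbourhoods"]
        edges = list(graph.edges.items())
        random.Random(seed).shuffle(edges)
        shuffled = HitGraph(nodes=set(graph.nodes))
        for (a, b), (ev, bits) in edges:
            shuffled.add_edge(a, b, ev, bits)
        reference = {
            n: a.group_id for n, a in small_analysis["assignments"].items()
        }
        redo = assign_groups(cluster_components(shuffled), nbs)
        assert {n: a.group_id for n, a in redo.items()} == reference


class TestAssignColours:
    def test_deterministic(self, small_analysis):
        c1 = assign_colours(small_analysis["assignments"], seed=7)
        c2 = assign_colours(small_analysis["assignments"], seed=7)
        assert c1 == c2

    def test_seed_changes_phase_only(self, small_analysis):
        c1 = assign_colours(small_analysis["assignments"], seed=1)
        c2 = assign_colours(small_analysis["assignments"], seed=2)
        assert set(c1) == set(c2)  # same group ids

    def test_injective_and_avoids_reserved(self):
        nbs = [make_neighbourhood(i, [])[0] for i in range(26)]
        comps = [{(i, 0) for i in range(26)}]  # query family
        for g in range(24):
            comps.append({(2 * g % 26, g + 1), ((2 * g + 1) % 26, g + 1)})
        assignments = assign_groups(comps, nbs)
        colours = assign_colours(assignments, seed=3)
        palette = [c for gid, c in colours.items() if c != QUERY_COLOUR]
        assert len(set(palette)) == len(palette) == 24
        assert QUERY_COLOUR not in palette

    def test_hue_spacing(self):
        """Generated hues are spaced >= 360/(G+1) degrees for G <= 24."""
        import colorsys

        nbs = [make_neighbourhood(i, [])[0] for i in range(26)]
        for n_groups in (2, 5, 12, 24):
            comps = [{(i, 0) for i in range(26)}]
            for g in range(n_groups):
                comps.append({(2 * g % 26, g + 1), ((2 * g + 1) % 26, g + 1)})
            assignments = assign_groups(comps, nbs)
            colours = assign_colours(assignments, seed=11)
            hues = sorted(
                colorsys.rgb_to_hsv(
                    int(c[1:3], 16) / 255,
                    int(c[3:5], 16) / 255,
                    int(c[5:7], 16) / 255,
                )[0]
                * 360.0
                for c in colours.values()
                if c != QUERY_COLOUR
            )
            gaps = [b - a for a, b in zip(hues, hues[1:])]
            gaps.append(360.0 - hues[-1] + hues[0])
            assert min(gaps) >= 360.0 / (n_groups + 1) - 2.0  # hex rounding slack


class TestPlantedFamilyRecovery:
    @pytest.mark.parametrize("seed", [2, 11, 29])
    def test_partition_recovered(self, seed):
        spec = FixtureSpec(
            n_assemblies=5,
            genes_per_contig=11,
            planted_families=tuple(
                PlantedFamily(f"FAM_{k}", 1, 0.65 + 0.05 * k) for k in range(4)
            ),
            flank_window=4,
            seed=seed,
        )
        fixture = generate(spec)
        res = analyse_fixture(fixture, n_flank=4, cutoff=1e-6)
        got = partition_by_protein(res["components"], res["neighbourhoods"])
        assert got == truth_partition(fixture, res["neighbourhoods"])

    def test_group_count_monotone_in_cutoff(self, small_fixture):
        counts = []
        for cutoff in (1e-3, 1e-6, 1e-20):
            res = analyse_fixture(small_fixture, cutoff=cutoff)
            counts.append(
                len(
                    {
                        a.group_id
                        for a in res["assignments"].values()
                        if a.conserved
                    }
                )
            )
        assert counts[0] >= counts[1] >= counts[2]
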