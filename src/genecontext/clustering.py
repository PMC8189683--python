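"""Homology clustering of neighbourhood-encoded proteins.

All coding proteins from every neighbourhood (queries included) are compared
all-vs-all; pairs at or below the E-value cut-off become edges of an
undirected hit graph, whose connected components (single linkage) are the
homologous groups.  Groups present in two or more distinct neighbourhoods are
"conserved" and receive consecutive group numbers; the group containing the
query proteins is always numbered and styled specially.

Two search backends exist: ``builtin`` (the local pairwise scorer; the
iteration count is ignored with a warning) and ``external_profile``, which
shells out to an installed ``jackhmmer`` and uses its per-pair E-values.
"""

from __future__ import annotations

import logging
import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .neighbourhood import Neighbourhood
from .pairwise import builtin_pairwise

logger = logging.getLogger(__name__)

__all__ = [
    "Node",
    "HitGraph",
    "GroupAssignment",
    "SearchParams",
    "BackendUnavailableError",
    "build_hit_graph",
    "cluster_components",
    "assign_groups",
    "assign_colours",
    "QUERY_COLOUR",
    "STYLE_QUERY",
    "STYLE_CONSERVED",
    "STYLE_NONCONSERVED",
    "STYLE_PSEUDOGENE",
    "STYLE_NONCODING",
]

#: A coding gene slot: (neighbourhood index, slot; slot<0 upstream, 0 query).
Node = tuple[int, int]

# Reserved style tokens (rendering classes from the figure semantics).
STYLE_QUERY = "query"
STYLE_CONSERVED = "conserved"
STYLE_NONCONSERVED = "nonconserved"
STYLE_PSEUDOGENE = "pseudogene"
STYLE_NONCODING = "noncoding"

#: Reserved fill for the query family; never produced by the palette.
QUERY_COLOUR = "#d62728"
_RESERVED_COLOURS = frozenset({QUERY_COLOUR, "#999999", "#bfbfbf", "#1f77b4"})


class BackendUnavailableError(RuntimeError):
    pass


@dataclass(frozen=True)
class SearchParams:
    evalue_cutoff: float = 1e-3
    iterations: int = 3
    backend: str = "builtin"  # "builtin" | "external_profile"

    def __post_init__(self) -> None:
        if self.evalue_cutoff <= 0:
            raise ValueError("evalue_cutoff must be > 0")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.backend not in ("builtin", "external_profile"):
            raise ValueError(f"unknown backend {self.backend!r}")


@dataclass
class HitGraph:
    """Undirected significant-similarity graph over coding gene slots."""

    nodes: set[Node] = field(default_factory=set)
    # canonical key: tuple(sorted((a, b))) -> (evalue, bitscore)
    edges: dict[tuple[Node, Node], tuple[float, float]] = field(default_factory=dict)

    def add_edge(self, a: Node, b: Node, evalue: float, bitscore: float) -> None:
        if a == b:
            raise ValueError("self-edges are not allowed")
        key = (a, b) if a <= b else (b, a)
        prev = self.edges.get(key)
        if prev is None or evalue < prev[0]:
            self.edges[key] = (evalue, bitscore)

    def edge_set(self) -> set[tuple[Node, Node]]:
        return set(self.edges)


@dataclass(frozen=True)
class GroupAssignment:
    group_id: int | None
    colour: str
    conserved: bool
    member_count: int
    neighbourhood_count: int
    query_family: bool = False


def _coding_nodes(
    neighbourhoods: Sequence[Neighbourhood],
    proteins: Mapping[str, str],
) -> dict[Node, str]:
    """Map each coding slot to its sequence; slots with missing sequences are
    skipped with a warning."""
    out: dict[Node, str] = {}
    for i, nb in enumerate(neighbourhoods):
        for slot, rec in nb.slots():
            if rec.kind != "coding":
                continue
            seq = proteins.get(rec.protein_id or "")
            if not seq:
                logger.warning(
                    "no sequence for %s (neighbourhood %d slot %d); excluded "
                    "from clustering",
                    rec.protein_id,
                    i,
                    slot,
                )
                continue
            out[(i, slot)] = seq
    return out


def _jackhmmer_pair_evalues(
    sequences: Mapping[str, str], params: SearchParams
) -> dict[tuple[str, str], float]:
    """Run jackhmmer all-vs-all on unique sequences; return per-pair E-values
    keyed by sorted (seq_key_a, seq_key_b)."""
    exe = shutil.which("jackhmmer")
    if exe is None:
        raise BackendUnavailableError(
            "external_profile backend requires jackhmmer on PATH; "
            "use backend=builtin instead"
        )
    evalues: dict[tuple[str, str], float] = {}
    with tempfile.TemporaryDirectory(prefix="genecontext-jh-") as tmp:
        faa = Path(tmp) / "seqs.faa"
        tbl = Path(tmp) / "hits.tbl"
        with faa.open("w") as fh:
            for key, seq in sequences.items():
                fh.write(f">{key}\n{seq}\n")
        cmd = [
            exe,
            "-N",
            str(params.iterations),
            "--tblout",
            str(tbl),
            "--noali",
            "-E",
            str(params.evalue_cutoff),
            "--incE",
            str(params.evalue_cutoff),
            str(faa),
            str(faa),
        ]
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0:
            raise BackendUnavailableError(
                f"jackhmmer failed (exit {proc.returncode}): {proc.stderr[-500:]}"
            )
        for line in tbl.read_text().splitlines():
            if line.startswith("#") or not line.strip():
                continue
            cols = line.split()
            target, query, evalue = cols[0], cols[2], float(cols[4])
            key = (query, target) if query <= target else (target, query)
            if key not in evalues or evalue < evalues[key]:
                evalues[key] = evalue
    return evalues


def build_hit_graph(
    neighbourhoods: Sequence[Neighbourhood],
    params: SearchParams,
    proteins: Mapping[str, str],
) -> HitGraph:
    """All-vs-all similarity search over every coding protein in the run.

    Identical sequences are deduplicated before alignment; edges keep the
    more significant of the two query/target directions.
    """
    node_seq = _coding_nodes(neighbourhoods, proteins)
    if not node_seq:
        raise ValueError("no coding proteins with sequences in the neighbourhoods")

    graph = HitGraph(nodes=set(node_seq))
    unique: dict[str, list[Node]] = {}
    for node in sorted(node_seq):
        unique.setdefault(node_seq[node], []).append(node)
    seqs = list(unique)
    db_size = sum(len(node_seq[n]) for n in node_seq)

    if params.backend == "external_profile":
        keys = {s: f"u{i}" for i, s in enumerate(seqs)}
        pair_ev = _jackhmmer_pair_evalues(
            {keys[s]: s for s in seqs}, params
        )

        def significance(sa: str, sb: str) -> tuple[float, float] | None:
            ka, kb = keys[sa], keys[sb]
            key = (ka, kb) if ka <= kb else (kb, ka)
            ev = pair_ev.get(key)
            if ev is None:
                return None
            bits = -math.log2(max(ev, 1e-300))  # tbl has no symmetric bitscore
            return ev, bits

    else:
        if params.iterations != 1:
            logger.warning(
                "builtin backend is non-iterative; ignoring iterations=%d",
                params.iterations,
            )

        def significance(sa: str, sb: str) -> tuple[float, float] | None:
            bits, ev = builtin_pairwise(sa, sb, db_size)
            if len(sb) < len(sa):
                # bitscore is symmetric; take the more significant direction
                ev = ev * len(sb) / len(sa)
            return ev, bits

    for i, sa in enumerate(seqs):
        for sb in seqs[i:]:
            if sa == sb and len(unique[sa]) < 2:
                continue
            sig = significance(sa, sb)
            if sig is None or sig[0] > params.evalue_cutoff:
                continue
            ev, bits = sig
            members_a, members_b = unique[sa], unique[sb]
            for na in members_a:
                for nb in members_b:
                    if na != nb:
                        graph.add_edge(na, nb, ev, bits)
    return graph


def cluster_components(graph: HitGraph) -> list[set[Node]]:
    """Single-linkage clustering: connected components of the hit graph.

    Isolated nodes form singleton components.  Output order is deterministic
    (components sorted by their smallest node).
    """
    g = nx.Graph()
    g.add_nodes_from(graph.nodes)
    g.add_edges_from(graph.edges)
    components = [set(c) for c in nx.connected_components(g)]
    components.sort(key=lambda c: min(c))
    return components


def assign_groups(
    components: Iterable[set[Node]],
    neighbourhoods: Sequence[Neighbourhood],
) -> dict[Node, GroupAssignment]:
    """Number the components and mark conservation.

    Components spanning >= 2 distinct neighbourhoods are conserved and get
    group numbers, ordered by descending neighbourhood count, then descending
    member count, then by sorted member accessions (content-based, so the
    numbering is invariant to query input order).  The component(s)
    containing query proteins (slot 0) are always numbered, conserved or not,
    so the query family can be styled and referenced in the legend.
    """
    rec_of = {}
    for i, nb in enumerate(neighbourhoods):
        for slot, rec in nb.slots():
            rec_of[(i, slot)] = rec

    comps = [frozenset(c) for c in components]
    stats = []
    for comp in comps:
        nbh_count = len({i for i, _ in comp})
        member_count = len(comp)
        pids = sorted(
            rec_of[n].protein_id
            for n in comp
            if n in rec_of and rec_of[n].protein_id
        )
        # content key; fall back to first occurrence for synthetic graphs
        content = ",".join(pids) if pids else f"￿{min(comp)}"
        has_query = any(slot == 0 for _, slot in comp)
        stats.append((comp, nbh_count, member_count, content, has_query))

    numbered = [s for s in stats if s[1] >= 2 or s[4]]
    numbered.sort(key=lambda s: (-s[1], -s[2], s[3]))

    assignments: dict[Node, GroupAssignment] = {}
    for gid, (comp, nbh_count, member_count, _, has_query) in enumerate(
        numbered, start=1
    ):
        for node in comp:
            assignments[node] = GroupAssignment(
                group_id=gid,
                colour=QUERY_COLOUR if has_query else "",
                conserved=nbh_count >= 2,
                member_count=member_count,
                neighbourhood_count=nbh_count,
                query_family=has_query,
            )
    for comp, nbh_count, member_count, _, has_query in stats:
        if nbh_count >= 2 or has_query:
            continue
        for node in comp:
            assignments[node] = GroupAssignment(
                group_id=None,
                colour="",
                conserved=False,
                member_count=member_count,
                neighbourhood_count=nbh_count,
            )
    return assignments


def _hsv_hex(hue_deg: float, saturation: float, value: float) -> str:
    import colorsys

    r, g, b = colorsys.hsv_to_rgb((hue_deg % 360.0) / 360.0, saturation, value)
    return "#{:02x}{:02x}{:02x}".format(round(r * 255), round(g * 255), round(b * 255))


def assign_colours(
    assignments: Mapping[Node, GroupAssignment], seed: int
) -> dict[int, str]:
    """Deterministic palette: evenly spaced hues by group number.

    The seed perturbs only the hue phase; the query family keeps its reserved
    colour and does not consume a palette slot.
    """
    query_groups = {
        a.group_id for a in assignments.values() if a.query_family and a.group_id
    }
    palette_groups = sorted(
        {
            a.group_id
            for a in assignments.values()
            if a.group_id is not None and a.group_id not in query_groups
        }
    )
    colours: dict[int, str] = {gid: QUERY_COLOUR for gid in query_groups}
    n = len(palette_groups)
    if n == 0:
        return colours
    phase = (seed * 137.50776405003785) % 360.0
    for idx, gid in enumerate(palette_groups):
        hue = (phase + idx * 360.0 / n) % 360.0
        token = _hsv_hex(hue, 0.62, 0.88)
        if token in _RESERVED_COLOURS or token in colours.values():
            token = _hsv_hex(hue, 0.62, 0.84)
        colours[gid] = token
    return colours
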