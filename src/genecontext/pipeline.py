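"""End-to-end orchestration: parse -> load -> locate -> extract -> cluster ->
assign -> render, with per-query failure isolation and atomic output writes.

Outputs land in the configured directory as ``diagram.svg``,
``description.tsv``, ``report.json`` and (when a tree is requested)
``tree.nwk`` + ``tree.svg``.  Files are written to a temporary sibling
directory first and moved into place on success, so a failing run never
leaves partial outputs behind.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

from . import clustering, rendering, tree as treemod
from .genome_store import (
    AmbiguousQueryError,
    QueryNotFoundError,
    load_assembly_files,
    locate_query,
    parse_query_list,
)
from .neighbourhood import extract_neighbourhood

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "PipelineError", "run"]

_PKG_LOGGER = "genecontext"


class PipelineError(Exception):
    pass


@dataclass(frozen=True)
class RunConfig:
    query_file: str
    assemblies: tuple[tuple[str, str, str], ...]  # (gff path, faa path, id)
    outdir: str
    n_flank: int = 4
    evalue_cutoff: float = 1e-3
    iterations: int = 3
    backend: str = "builtin"
    seed: int = 0
    tree: str = "off"  # "off" | "build" | path to a Newick file
    scale: float = 16.0

    def __post_init__(self) -> None:
        if self.n_flank < 1:
            raise ValueError("n_flank must be >= 1")
        if self.evalue_cutoff <= 0:
            raise ValueError("evalue_cutoff must be > 0")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass
class QueryStatus:
    protein_id: str
    assembly_id: str | None
    status: str  # "ok" | "missing" | "ambiguous"
    detail: str = ""


@dataclass
class RunReport:
    ok: bool
    queries: list[QueryStatus] = field(default_factory=list)
    groups: list[dict] = field(default_factory=list)
    params: dict = field(default_factory=dict)
    seed: int = 0
    outputs: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        payload = dataclasses.asdict(self)
        return json.dumps(payload, indent=2, sort_keys=True) + "\n"


class _ListHandler(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record: logging.LogRecord) -> None:
        self.messages.append(record.getMessage())


def run(config: RunConfig) -> RunReport:
    """Execute the full workflow; see module docstring for the stage order.

    Per-query failures (missing or ambiguous accessions) are recorded in the
    report and skipped.  ``report.ok`` is false iff zero queries succeeded.
    """
    handler = _ListHandler()
    pkg_logger = logging.getLogger(_PKG_LOGGER)
    pkg_logger.addHandler(handler)
    try:
        return _run(config, handler)
    finally:
        pkg_logger.removeHandler(handler)


def _run(config: RunConfig, handler: _ListHandler) -> RunReport:
    query_path = Path(config.query_file)
    if not query_path.is_file():
        raise PipelineError(f"query file not readable: {query_path}")
    for gff, faa, _ in config.assemblies:
        for path in (gff, faa):
            if not Path(path).is_file():
                raise PipelineError(f"assembly input not readable: {path}")
    if config.tree not in ("off", "build") and not Path(config.tree).is_file():
        raise PipelineError(f"tree file not readable: {config.tree}")

    queries = parse_query_list(query_path.read_text())
    assemblies = [
        load_assembly_files(gff, faa, assembly_id)
        for gff, faa, assembly_id in config.assemblies
    ]

    report = RunReport(
        ok=False,
        seed=config.seed,
        params={
            "n_flank": config.n_flank,
            "evalue_cutoff": config.evalue_cutoff,
            "iterations": config.iterations,
            "backend": config.backend,
            "tree": config.tree,
            "scale": config.scale,
        },
    )

    neighbourhoods = []
    nb_queries = []  # QueryItem per successful neighbourhood
    for item in queries:
        try:
            assembly, record = locate_query(assemblies, item)
        except QueryNotFoundError as exc:
            logger.warning("query %s: %s", item.protein_id, exc)
            report.queries.append(
                QueryStatus(item.protein_id, item.assembly_id, "missing", str(exc))
            )
            continue
        except AmbiguousQueryError as exc:
            logger.warning("query %s: %s", item.protein_id, exc)
            report.queries.append(
                QueryStatus(item.protein_id, item.assembly_id, "ambiguous", str(exc))
            )
            continue
        neighbourhoods.append(extract_neighbourhood(assembly, record, config.n_flank))
        nb_queries.append((item, assembly))
        report.queries.append(QueryStatus(item.protein_id, item.assembly_id, "ok"))

    if not neighbourhoods:
        report.warnings = list(handler.messages)
        _write_outputs(config, {"report.json": report.to_json()}, report)
        return report

    proteins: dict[str, str] = {}
    for assembly in assemblies:
        proteins.update(assembly.proteins)

    params = clustering.SearchParams(
        evalue_cutoff=config.evalue_cutoff,
        iterations=config.iterations,
        backend="external_profile" if config.backend == "external" else config.backend,
    )
    graph = clustering.build_hit_graph(neighbourhoods, params, proteins)
    components = clustering.cluster_components(graph)
    assignments = clustering.assign_groups(components, neighbourhoods)
    colours = clustering.assign_colours(assignments, config.seed)

    tree_obj = None
    if config.tree == "build":
        seqs = {
            item.protein_id: proteins[item.protein_id]
            for item, _ in nb_queries
            if item.protein_id in proteins
        }
        if len(seqs) < 2:
            logger.warning("fewer than 2 query sequences; skipping tree output")
        else:
            tree_obj = treemod.build_guide_tree(seqs)
    elif config.tree != "off":
        tree_obj = treemod.parse_newick(Path(config.tree).read_text())

    model = rendering.build_render_model(
        neighbourhoods, assignments, colours, scale=config.scale, tree=tree_obj
    )

    outputs = {
        "diagram.svg": rendering.render_diagram(model),
        "description.tsv": rendering.write_description(model),
    }
    if tree_obj is not None:
        outputs["tree.nwk"] = treemod.tree_to_newick(tree_obj)
        outputs["tree.svg"] = rendering.annotate_tree(tree_obj, model)

    report.ok = True
    report.groups = [
        {
            "group_id": row.group_id,
            "colour": row.colour,
            "product": row.product,
            "members": list(row.member_protein_ids),
            "neighbourhood_count": row.neighbourhood_count,
        }
        for row in model.legend_rows
    ]
    report.warnings = list(handler.messages)
    outputs["report.json"] = report.to_json()
    _write_outputs(config, outputs, report)
    # re-serialize with final output paths recorded
    (Path(config.outdir) / "report.json").write_text(report.to_json())
    return report


def _write_outputs(
    config: RunConfig, outputs: dict[str, str], report: RunReport
) -> None:
    """Write all artifacts to a temp dir, then move atomically into outdir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with tempfile.TemporaryDirectory(dir=outdir.parent, prefix=".gc-tmp-") as tmp:
        staged: list[tuple[Path, Path]] = []
        for name, text in outputs.items():
            src = Path(tmp) / name
            src.write_text(text)
            staged.append((src, outdir / name))
        for src, dst in staged:
            os.replace(src, dst)
            report.outputs[dst.name] = str(dst)
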