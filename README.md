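# genecontext

Gene-neighbourhood conservation analysis for locally stored annotated
genomes. Given a list of query protein accessions, `genecontext`:

1. locates each query in its assembly (RefSeq-dialect GFF3 + protein FASTA,
   optionally gzip-compressed),
2. extracts the query gene plus up to *n* flanking genes per side (counted by
   gene index; pseudogenes and non-coding genes occupy slots; contig-edge
   truncation is flagged; reverse-strand queries are mirrored so queries
   always point right),
3. clusters all neighbourhood-encoded proteins (queries included) into
   homologous groups: all-vs-all local alignment (BLOSUM62, affine gaps 11/1,
   Karlin–Altschul bit scores and E-values), significance filtering at a
   user E-value cut-off, single-linkage connected components,
4. renders the result as a to-scale SVG diagram of gene arrows, a legend TSV
   (`description.tsv`), and optionally a phylogenetic tree annotated with
   colour/number-coded pennant flags (Newick + SVG).

Rendering semantics: conserved groups are filled with a stable per-group
colour and numbered; genes not conserved in the dataset are unfilled with a
grey border; pseudogenes are grey with a blue border; non-coding genes are
hatched; truncated contig sides draw nothing beyond the last real gene.

Two similarity backends are available: `builtin` (self-contained pairwise
aligner, default) and `external` (shells out to `jackhmmer` for iterative
profile search; the `--iterations` knob applies only there). All outputs are
deterministic for a fixed config + seed.

## CLI

```sh
genecontext \
  --queries queries.txt \
  --assembly genome1.gff,genome1.faa,GCF_000001.1 \
  --assembly genome2.gff.gz,genome2.faa.gz,GCF_000002.1 \
  --flank 4 --evalue 1e-3 --backend builtin \
  --tree build --seed 0 --outdir out/
```

The query list holds one protein accession per line, optionally followed by
an assembly identifier (tab-separated) to target a particular genome; `#`
comments and blank lines are ignored. A YAML config can replace flags
(`--config run.yaml`; flags override). `--tree` accepts `off`, `build`
(neighbour-joining guide tree from query sequences, midpoint-rooted) or a
path to a user Newick file, which takes precedence.

Outputs in `--outdir`: `diagram.svg`, `description.tsv`, `report.json`, and
with a tree `tree.nwk` + `tree.svg`. Per-query failures (missing or
ambiguous accessions) are recorded in `report.json` and skipped; the exit
status is non-zero only when no query succeeds.

## Python API

```python
import genecontext as gc

asm = gc.load_assembly_files("genome.gff", "genome.faa", "GCF_000001.1")
assembly, record = gc.locate_query([asm], gc.QueryItem("WP_000001.1"))
nb = gc.extract_neighbourhood(assembly, record, n=4)
graph = gc.build_hit_graph([nb], gc.SearchParams(evalue_cutoff=1e-3), asm.proteins)
groups = gc.assign_groups(gc.cluster_components(graph), [nb])
```

`genecontext.fixtures` generates deterministic synthetic assemblies with
planted homologous families, pseudogenes, non-coding genes and contig-edge
queries, plus a ground-truth table — every pipeline stage is testable
offline.

## Tests and acceptance

```sh
python -m pytest tests/            # unit + property + acceptance tests
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script re-runs each acceptance criterion from scratch
(planted-family recovery on 25 fixtures, oracle equivalence for clustering
and alignment, rendering semantics, byte-level determinism, cut-off
monotonicity, neighbour-joining sanity) and prints a pass/fail summary; the
JSON output is an empty target object because all criteria are
property-based rather than numeric.
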