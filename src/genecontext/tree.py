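"""Guide-tree construction and Newick handling for query proteins.

Distances are 1 - fractional identity from the local pairwise aligner; the
tree is neighbour joining (scikit-bio) with negative branch lengths clamped
to zero, midpoint-rooted.  Leaf IDs are fed to NJ in lexicographic order so
the result is independent of query input order.
"""

from __future__ import annotations

import io
import logging
from typing import Mapping

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .pairwise import fractional_identity

logger = logging.getLogger(__name__)

__all__ = ["GuideTreeError", "build_guide_tree", "tree_to_newick", "parse_newick"]


class GuideTreeError(Exception):
    pass


def build_guide_tree(query_sequences: Mapping[str, str]) -> TreeNode:
    """Neighbour-joining tree over the query proteins, midpoint-rooted.

    Raises :class:`GuideTreeError` for fewer than two sequences (run with the
    tree output disabled instead).
    """
    if len(query_sequences) < 2:
        raise GuideTreeError(
            "need >= 2 query sequences to build a tree; rerun with tree output off"
        )
    ids = sorted(query_sequences)
    n = len(ids)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - fractional_identity(query_sequences[ids[i]], query_sequences[ids[j]])
            dm[i, j] = dm[j, i] = max(d, 0.0)
    if n == 2:
        half = dm[0, 1] / 2.0
        tree = TreeNode.read(io.StringIO(f"({ids[0]}:{half},{ids[1]}:{half});"))
        return tree
    tree = nj(DistanceMatrix(dm, ids), neg_as_zero=True)
    if any(
        node.length is not None and node.length < 0 for node in tree.traverse()
    ):  # pragma: no cover - neg_as_zero already clamps
        logger.warning("negative NJ branch lengths clamped to 0")
    rooted = tree.root_at_midpoint()
    for node in rooted.traverse():
        if node.length is not None and node.length < 0:
            logger.warning("negative branch length %.4g clamped to 0", node.length)
            node.length = 0.0
    return rooted


def tree_to_newick(tree: TreeNode) -> str:
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue()


def parse_newick(text: str) -> TreeNode:
    try:
        # keep underscores verbatim: accessions are not Newick word breaks
        return TreeNode.read(io.StringIO(text), convert_underscores=False)
    except Exception as exc:  # skbio raises several parse error types
        raise GuideTreeError(f"could not parse Newick tree: {exc}") from exc
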