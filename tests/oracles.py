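"""Independent reference implementations used only to check the package.

These deliberately avoid the package's own code paths: the alignment oracle
is a plain three-matrix DP over Biopython's shipped BLOSUM62 (cross-checking
the package's hard-coded matrix data), and the component oracle is a
hand-written union-find.
"""

from __future__ import annotations

from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")


def sw_affine_oracle(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> float:
    """Exhaustive Smith-Waterman DP with affine gaps (cost 11 + k)."""
    neg = float("-inf")
    n, m = len(a), len(b)
    h = [[0.0] * (m + 1) for _ in range(n + 1)]
    e = [[neg] * (m + 1) for _ in range(n + 1)]
    f = [[neg] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e[i][j] = max(e[i][j - 1] - gap_extend, h[i][j - 1] - gap_open - gap_extend)
            f[i][j] = max(f[i - 1][j] - gap_extend, h[i - 1][j] - gap_open - gap_extend)
            h[i][j] = max(
                0.0, h[i - 1][j - 1] + _B62[a[i - 1]][b[j - 1]], e[i][j], f[i][j]
            )
            best = max(best, h[i][j])
    return best


class UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def components_oracle(nodes, edges):
    """Partition via union-find; returns a set of frozensets."""
    uf = UnionFind(nodes)
    for a, b in edges:
        uf.union(a, b)
    groups: dict = {}
    for node in nodes:
        groups.setdefault(uf.find(node), set()).add(node)
    return {frozenset(g) for g in groups.values()}
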