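"""Built-in pairwise protein scorer: local alignment, bit scores, E-values.

This is the self-contained fallback backend for similarity search.  Raw
scores come from Smith-Waterman local alignment (Biopython's C aligner) under
BLOSUM62 with affine gaps (open 11, extend 1, BLAST convention: a gap of
length k costs 11 + k).  Raw scores are converted to bit scores with fixed
Karlin-Altschul parameters and to E-values with query-length x
database-residues scaling:

    bits   = (lambda * S - ln K) / ln 2
    evalue = len(seq_a) * db_size * 2 ** (-bits)

The (lambda, K) constants are the published gapped BLOSUM62/11/1 values used
by BLAST; they are fixed here so scores are reproducible across platforms.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

__all__ = [
    "builtin_pairwise",
    "local_alignment_score",
    "fractional_identity",
    "AlignmentInputError",
    "KA_LAMBDA",
    "KA_K",
    "GAP_OPEN",
    "GAP_EXTEND",
]

# Gapped Karlin-Altschul parameters for BLOSUM62, gap open 11 / extend 1.
KA_LAMBDA = 0.267
KA_K = 0.041
GAP_OPEN = 11
GAP_EXTEND = 1

_STANDARD_AA = "ARNDCQEGHILKMFPSTWYV"
# Ambiguity / non-standard codes scored 0 against everything (mismatch-neutral).
_AMBIGUOUS_AA = "BJZXUO*"
_ALPHABET = _STANDARD_AA + _AMBIGUOUS_AA

_BLOSUM62_TEXT = """\
    A  R  N  D  C  Q  E  G  H  I  L  K  M  F  P  S  T  W  Y  V
A  4 -1 -2 -2  0 -1 -1  0 -2 -1 -1 -1 -1 -2 -1  1  0 -3 -2  0
R -1  5  0 -2 -3  1  0 -2  0 -3 -2  2 -1 -3 -2 -1 -1 -3 -2 -3
N -2  0  6  1 -3  0  0  0  1 -3 -3  0 -2 -3 -2  1  0 -4 -2 -3
D -2 -2  1  6 -3  0  2 -1 -1 -3 -4 -1 -3 -3 -1  0 -1 -4 -3 -3
C  0 -3 -3 -3  9 -3 -4 -3 -3 -1 -1 -3 -1 -2 -3 -1 -1 -2 -2 -1
Q -1  1  0  0 -3  5  2 -2  0 -3 -2  1  0 -3 -1  0 -1 -2 -1 -2
E -1  0  0  2 -4  2  5 -2  0 -3 -3  1 -2 -3 -1  0 -1 -3 -2 -2
G  0 -2  0 -1 -3 -2 -2  6 -2 -4 -4 -2 -3 -3 -2  0 -2 -2 -3 -3
H -2  0  1 -1 -3  0  0 -2  8 -3 -3 -1 -2 -1 -2 -1 -2 -2  2 -3
I -1 -3 -3 -3 -1 -3 -3 -4 -3  4  2 -3  1  0 -3 -2 -1 -3 -1  3
L -1 -2 -3 -4 -1 -2 -3 -4 -3  2  4 -2  2  0 -3 -2 -1 -2 -1  1
K -1  2  0 -1 -3  1  1 -2 -1 -3 -2  5 -1 -3 -1  0 -1 -3 -2 -2
M -1 -1 -2 -3 -1  0 -2 -3 -2  1  2 -1  5  0 -2 -1 -1 -1 -1  1
F -2 -3 -3 -3 -2 -3 -3 -3 -1  0  0 -3  0  6 -4 -2 -2  1  3 -1
P -1 -2 -2 -1 -3 -1 -1 -2 -2 -3 -3 -1 -2 -4  7 -1 -1 -4 -3 -2
S  1 -1  1  0 -1  0  0  0 -1 -2 -2  0 -1 -2 -1  4  1 -3 -2 -2
T  0 -1  0 -1 -1 -1 -1 -2 -2 -1 -1 -1 -1 -2 -1  1  5 -2 -2  0
W -3 -3 -4 -4 -2 -2 -3 -2 -2 -3 -2 -3 -1  1 -4 -3 -2 11  2 -3
Y -2 -2 -2 -3 -2 -1 -2 -3  2 -1 -1 -2 -1  3 -3 -2 -2  2  7 -1
V  0 -3 -3 -3 -1 -2 -2 -3 -3  3  1 -2  1 -1 -2 -2  0 -3 -1  4
"""


class AlignmentInputError(ValueError):
    """Empty sequence or a symbol outside the amino-acid alphabet."""


def blosum62() -> dict[tuple[str, str], int]:
    """The substitution scores as a plain dict (ambiguity codes score 0)."""
    lines = _BLOSUM62_TEXT.strip().splitlines()
    header = lines[0].split()
    scores: dict[tuple[str, str], int] = {}
    for line in lines[1:]:
        parts = line.split()
        row = parts[0]
        for col, val in zip(header, parts[1:]):
            scores[(row, col)] = int(val)
    for a in _ALPHABET:
        for b in _AMBIGUOUS_AA:
            scores[(a, b)] = 0
            scores[(b, a)] = 0
    return scores


@lru_cache(maxsize=1)
def _aligner() -> PairwiseAligner:
    matrix = substitution_matrices.Array(alphabet=_ALPHABET, dims=2, dtype=np.float64)
    for (a, b), score in blosum62().items():
        matrix[a, b] = score
    aligner = PairwiseAligner(
        mode="local",
        substitution_matrix=matrix,
        # Biopython charges open_gap_score for the first gap residue; BLAST's
        # 11/1 scheme costs 11 + k for a k-long gap, hence -12 here.
        open_gap_score=-(GAP_OPEN + GAP_EXTEND),
        extend_gap_score=-GAP_EXTEND,
    )
    return aligner


def _validate(seq: str, label: str) -> str:
    if not seq:
        raise AlignmentInputError(f"{label} is empty")
    seq = seq.upper()
    for ch in seq:
        if ch not in _ALPHABET:
            raise AlignmentInputError(
                f"{label} contains non-amino-acid symbol {ch!r}"
            )
    return seq


def local_alignment_score(seq_a: str, seq_b: str) -> float:
    """Raw Smith-Waterman score (BLOSUM62, affine 11/1). Symmetric."""
    seq_a = _validate(seq_a, "seq_a")
    seq_b = _validate(seq_b, "seq_b")
    return float(_aligner().score(seq_a, seq_b))


def builtin_pairwise(seq_a: str, seq_b: str, db_size: int) -> tuple[float, float]:
    """Score a pair of protein sequences; returns ``(bitscore, evalue)``.

    ``db_size`` is the total residue count of the search space; the E-value
    scales with ``len(seq_a) * db_size``.
    """
    if db_size < 1:
        raise ValueError(f"db_size must be positive, got {db_size}")
    raw = local_alignment_score(seq_a, seq_b)
    bits = (KA_LAMBDA * raw - math.log(KA_K)) / math.log(2.0)
    evalue = len(seq_a) * db_size * math.pow(2.0, -bits)
    return bits, evalue


def fractional_identity(seq_a: str, seq_b: str) -> float:
    """Identities in the best local alignment over the longer sequence length.

    Used as the similarity basis for guide-tree distances (d = 1 - identity).
    """
    seq_a = _validate(seq_a, "seq_a")
    seq_b = _validate(seq_b, "seq_b")
    alignment = _aligner().align(seq_a, seq_b)[0]
    identities = alignment.counts().identities
    return identities / max(len(seq_a), len(seq_b))
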