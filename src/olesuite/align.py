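"""Pairwise local protein alignment with percent identity and E-values.

Smith–Waterman with affine gaps (a gap of length k costs
``gap_open + k * gap_extend``, the BLAST convention for "11/1") over
BLOSUM62, plus Karlin–Altschul E-values ``E = K * m * n * exp(-lambda * S)``
on the raw score. The pipeline only consumes the E <= 1e-5 threshold
decision, for which the raw-score form is monotone-equivalent to bit
scores. Percent identity uses the full alignment length including gap
columns as denominator, so the 75% node-collapse rule is deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

try:  # DP kernel is jitted when numba is importable; semantics identical either way
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*a, **k):
        def deco(f):
            return f
        return deco(*a) if a and callable(a[0]) else deco


_BLOSUM_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
_CHAR_TO_IDX = {c: i for i, c in enumerate(_BLOSUM_ALPHABET)}

# Published gapped Karlin-Altschul parameters for BLOSUM62 with gap costs 11/1.
BLOSUM62_GAPPED_LAMBDA = 0.267
BLOSUM62_GAPPED_K = 0.041


@lru_cache(maxsize=None)
def _blosum_matrix(name: str) -> np.ndarray:
    mat = substitution_matrices.load(name)
    if str(mat.alphabet) != _BLOSUM_ALPHABET:
        raise ValueError(f"unexpected alphabet for matrix {name}")
    return np.asarray(mat, dtype=np.int32)


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix, affine gap costs and E-value constants."""

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = BLOSUM62_GAPPED_LAMBDA
    K: float = BLOSUM62_GAPPED_K

    def __post_init__(self):
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("Karlin-Altschul parameters must be positive")

    @property
    def substitution_scores(self) -> np.ndarray:
        return _blosum_matrix(self.matrix_name)

    def score(self, a: str, b: str) -> int:
        m = self.substitution_scores
        return int(m[_CHAR_TO_IDX[a], _CHAR_TO_IDX[b]])


@dataclass(frozen=True)
class AlignmentHit:
    score: int
    aligned_length: int
    identities: int
    evalue: float
    query_span: tuple[int, int]
    subject_span: tuple[int, int]

    @property
    def percent_identity(self) -> float:
        if self.aligned_length == 0:
            return 0.0
        return 100.0 * self.identities / self.aligned_length


def encode_protein(seq: str) -> np.ndarray:
    """Map residues to BLOSUM62 row indices; unknown characters become 'X'."""
    x = _CHAR_TO_IDX["X"]
    return np.fromiter(
        (_CHAR_TO_IDX.get(c, x) for c in seq.upper()), dtype=np.int32, count=len(seq)
    )


@njit(cache=False)
def _sw_fill(a, b, sub, gap_open, gap_extend):  # pragma: no cover - exercised via wrapper
    m, n = a.shape[0], b.shape[0]
    NEG = -10**9
    H = np.zeros((m + 1, n + 1), dtype=np.int64)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int64)  # gap in query (left moves)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int64)  # gap in subject (up moves)
    first_gap = gap_open + gap_extend
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e = H[i, j - 1] - first_gap
            if E[i, j - 1] - gap_extend > e:
                e = E[i, j - 1] - gap_extend
            E[i, j] = e
            f = H[i - 1, j] - first_gap
            if F[i - 1, j] - gap_extend > f:
                f = F[i - 1, j] - gap_extend
            F[i, j] = f
            h = H[i - 1, j - 1] + sub[a[i - 1], b[j - 1]]
            if f > h:
                h = f
            if e > h:
                h = e
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:  # strict: earliest best cell in row-major order wins
                best = h
                bi = i
                bj = j
    return H, E, F, best, bi, bj


def local_align(a: str, b: str, scheme: ScoringScheme | None = None) -> AlignmentHit:
    """Optimal affine-gap local alignment of two protein sequences.

    One optimal traceback is reported: the end cell is the earliest
    best-scoring cell in row-major order, and at each step ties break
    diagonal > up (gap in subject) > left (gap in query).
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    scheme = scheme or ScoringScheme()
    ea, eb = encode_protein(a), encode_protein(b)
    sub = scheme.substitution_scores
    H, E, F, best, bi, bj = _sw_fill(ea, eb, sub, scheme.gap_open, scheme.gap_extend)
    best = int(best)
    if best == 0:
        return AlignmentHit(0, 0, 0, estimate_evalue(0, len(a), len(b), scheme), (0, 0), (0, 0))

    i, j = int(bi), int(bj)
    end_q, end_s = i, j
    aligned = 0
    idents = 0
    state = "H"
    first_gap = scheme.gap_open + scheme.gap_extend
    while True:
        if state == "H":
            if H[i, j] == 0:
                break
            diag = H[i - 1, j - 1] + sub[ea[i - 1], eb[j - 1]]
            if H[i, j] == diag:
                aligned += 1
                if ea[i - 1] == eb[j - 1]:
                    idents += 1
                i -= 1
                j -= 1
            elif H[i, j] == F[i, j]:
                state = "F"
            else:
                state = "E"
        elif state == "F":  # gap in subject: consume query residue
            aligned += 1
            if F[i, j] == H[i - 1, j] - first_gap:
                state = "H"
            i -= 1
        else:  # gap in query: consume subject residue
            aligned += 1
            if E[i, j] == H[i, j - 1] - first_gap:
                state = "H"
            j -= 1
    return AlignmentHit(
        score=best,
        aligned_length=aligned,
        identities=idents,
        evalue=estimate_evalue(best, len(a), len(b), scheme),
        query_span=(i, end_q),
        subject_span=(j, end_s),
    )


def estimate_evalue(score: int, m: int, n: int, scheme: ScoringScheme | None = None) -> float:
    """Karlin-Altschul expected hit count: E = K * m * n * exp(-lambda * score)."""
    if m < 1 or n < 1:
        raise ValueError("sequence lengths must be >= 1")
    scheme = scheme or ScoringScheme()
    return scheme.K * m * n * math.exp(-scheme.lam * score)
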