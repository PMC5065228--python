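"""Pairwise global alignment statistics and cholesterol-motif scanning.

The aligner is a Gotoh affine-gap global aligner with a fixed, documented
tie-breaking order during traceback (diagonal, then up, then left), so the
reported alignment — and therefore the identity/similarity percentages —
are fully deterministic.  Defaults are the classic ClustalW protein
settings: BLOSUM62, gap open 10, gap extend 0.5.  A gap of length L costs
``gap_open + (L - 1) * gap_extend``.

Percent identity is computed over columns where both sequences have a
residue; percent similarity additionally counts pairs with a positive
substitution score.  This denominator choice is deliberate and documented —
alternative conventions (shorter-sequence length, full alignment length)
are exposed by :func:`identity_similarity_all_denominators` so sensitivity
can be reported.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

from Bio.Align import substitution_matrices

from .errors import ValidationError

__all__ = [
    "AlignmentResult",
    "MotifHit",
    "align_global",
    "identity_similarity",
    "identity_similarity_all_denominators",
    "scan_crac",
    "default_matrix",
]

_AMINO = set("ACDEFGHIKLMNPQRSTVWYX")

GAP_OPEN_DEFAULT = 10.0
GAP_EXTEND_DEFAULT = 0.5


@functools.lru_cache(maxsize=4)
def default_matrix(name: str = "BLOSUM62"):
    return substitution_matrices.load(name)


@dataclass
class AlignmentResult:
    """A pairwise global alignment with summary statistics."""

    aligned_a: str
    aligned_b: str
    score: float
    identity_pct: float
    similarity_pct: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValidationError("gapped strings must have equal length")
        if not (0.0 <= self.identity_pct <= self.similarity_pct <= 100.0):
            raise ValidationError(
                "require 0 <= identity_pct <= similarity_pct <= 100, got "
                f"{self.identity_pct} / {self.similarity_pct}"
            )

    @property
    def seq_a(self) -> str:
        return self.aligned_a.replace("-", "")

    @property
    def seq_b(self) -> str:
        return self.aligned_b.replace("-", "")


@dataclass
class MotifHit:
    """One CRAC motif occurrence, 1-based inclusive coordinates."""

    start: int
    end: int
    tyrosine_pos: int
    pattern_id: str = "CRAC"

    def __post_init__(self) -> None:
        if not (self.start <= self.tyrosine_pos <= self.end):
            raise ValidationError("tyrosine position must lie within the hit span")


def _validate_sequence(seq: str, label: str) -> str:
    if not seq:
        raise ValidationError(f"sequence {label} is empty")
    seq = seq.upper()
    for i, c in enumerate(seq):
        if c not in _AMINO:
            raise ValidationError(
                f"sequence {label}: illegal character {c!r} at position {i + 1}"
            )
    return seq


def _score_of(matrix, a: str, b: str) -> float:
    try:
        return float(matrix[a, b])
    except KeyError:
        return float(matrix[b, a])


def align_global(
    seq_a: str,
    seq_b: str,
    substitution_table=None,
    gap_open: float = GAP_OPEN_DEFAULT,
    gap_extend: float = GAP_EXTEND_DEFAULT,
) -> AlignmentResult:
    """Optimal affine-gap global alignment (Gotoh), deterministic traceback.

    Tie-breaking prefers diagonal, then up (gap in ``seq_b``), then left
    (gap in ``seq_a``), applied both to state selection within a cell and to
    the choice of the final state.
    """
    a = _validate_sequence(seq_a, "a")
    b = _validate_sequence(seq_b, "b")
    matrix = substitution_table if substitution_table is not None else default_matrix()
    if gap_open < 0 or gap_extend < 0:
        raise ValidationError("gap penalties must be non-negative")

    n, m = len(a), len(b)
    NEG = float("-inf")
    # Full DP matrices: M = residue-residue, X = gap in b (up), Y = gap in a
    # (left).  Sizes here (<= ~700 aa) make the O(nm) memory acceptable.
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = -gap_open - (j - 1) * gap_extend

    for i in range(1, n + 1):
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        ai = a[i - 1]
        row_scores = [_score_of(matrix, ai, bj) for bj in b]
        for j in range(1, m + 1):
            d = Mp[j - 1]
            if Xp[j - 1] > d:
                d = Xp[j - 1]
            if Yp[j - 1] > d:
                d = Yp[j - 1]
            if d > NEG:
                Mi[j] = d + row_scores[j - 1]
            Xi[j] = max(Mp[j] - gap_open, Xp[j] - gap_extend, Yp[j] - gap_open)
            Yi[j] = max(Mi[j - 1] - gap_open, Yi[j - 1] - gap_extend, Xi[j - 1] - gap_open)

    # Final state, preference M > X > Y on ties.
    end_scores = (M[n][m], X[n][m], Y[n][m])
    score = max(end_scores)
    state = end_scores.index(score)  # 0=M, 1=X, 2=Y

    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    EPS = 1e-9
    while i > 0 or j > 0:
        if state == 0:  # M: consumed a[i-1], b[j-1]
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            target = M[i][j] - _score_of(matrix, a[i - 1], b[j - 1])
            i, j = i - 1, j - 1
            if abs(M[i][j] - target) < EPS:
                state = 0
            elif abs(X[i][j] - target) < EPS:
                state = 1
            else:
                state = 2
        elif state == 1:  # X: consumed a[i-1], gap in b
            out_a.append(a[i - 1])
            out_b.append("-")
            val = X[i][j]
            i -= 1
            if i == 0 and j == 0:
                break
            if abs(M[i][j] - gap_open - val) < EPS:
                state = 0
            elif abs(X[i][j] - gap_extend - val) < EPS:
                state = 1
            else:
                state = 2
        else:  # Y: consumed b[j-1], gap in a
            out_a.append("-")
            out_b.append(b[j - 1])
            val = Y[i][j]
            j -= 1
            if i == 0 and j == 0:
                break
            if abs(M[i][j] - gap_open - val) < EPS:
                state = 0
            elif abs(Y[i][j] - gap_extend - val) < EPS:
                state = 2
            else:
                state = 1

    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))
    identity, similarity = identity_similarity(aligned_a, aligned_b, matrix)
    return AlignmentResult(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=score,
        identity_pct=identity,
        similarity_pct=similarity,
    )


def _column_counts(aligned_a: str, aligned_b: str, matrix) -> tuple[int, int, int]:
    """(non-gap columns, identical pairs, positive-score pairs)."""
    if len(aligned_a) != len(aligned_b):
        raise ValidationError("gapped strings must have equal length")
    cols = ident = simil = 0
    for ca, cb in zip(aligned_a, aligned_b):
        if ca == "-" or cb == "-":
            continue
        cols += 1
        if ca == cb:
            ident += 1
            simil += 1
        elif _score_of(matrix, ca, cb) > 0:
            simil += 1
    return cols, ident, simil


def identity_similarity(
    alignment, aligned_b: str | None = None, matrix=None
) -> tuple[float, float]:
    """Percent identity and similarity over columns where both are residues.

    Accepts either an :class:`AlignmentResult` or two gapped strings.
    """
    if isinstance(alignment, AlignmentResult):
        aligned_a, aligned_b = alignment.aligned_a, alignment.aligned_b
    else:
        aligned_a = alignment
        if aligned_b is None:
            raise ValidationError("need two gapped strings or an AlignmentResult")
    matrix = matrix if matrix is not None else default_matrix()
    cols, ident, simil = _column_counts(aligned_a, aligned_b, matrix)
    if cols == 0:
        raise ValidationError("alignment has zero columns with residues on both sides")
    return 100.0 * ident / cols, 100.0 * simil / cols


def identity_similarity_all_denominators(
    aligned_a: str, aligned_b: str, matrix=None
) -> dict[str, tuple[float, float]]:
    """Identity/similarity under the three common denominator conventions.

    Keys: ``both_residues`` (this package's default), ``shorter_sequence``
    (ClustalW's pairwise-score convention), ``alignment_length``.
    """
    matrix = matrix if matrix is not None else default_matrix()
    cols, ident, simil = _column_counts(aligned_a, aligned_b, matrix)
    len_a = len(aligned_a.replace("-", ""))
    len_b = len(aligned_b.replace("-", ""))
    shorter = min(len_a, len_b)
    full = len(aligned_a)
    out = {}
    for key, denom in (
        ("both_residues", cols),
        ("shorter_sequence", shorter),
        ("alignment_length", full),
    ):
        if denom == 0:
            raise ValidationError("zero-length denominator")
        out[key] = (100.0 * ident / denom, 100.0 * simil / denom)
    return out


def scan_crac(sequence: str) -> list[MotifHit]:
    """All CRAC motif hits: (L/V)-X(1..5)-Y-X(1..5)-(R/K), N→C.

    Overlapping occurrences are allowed; exactly one hit is reported per
    distinct central tyrosine, using the shortest match for that tyrosine
    (ties broken toward the shorter N-terminal arm, then the shorter
    C-terminal arm).  Positions are 1-based inclusive.
    """
    seq = sequence.upper()
    hits: list[MotifHit] = []
    for i, c in enumerate(seq):
        if c != "Y":
            continue
        best: tuple[int, int, int] | None = None  # (span, dl, dr)
        for dl in range(2, 7):
            l = i - dl
            if l < 0 or seq[l] not in "LV":
                continue
            for dr in range(2, 7):
                r = i + dr
                if r >= len(seq) or seq[r] not in "RK":
                    continue
                cand = (dl + dr, dl, dr)
                if best is None or cand < best:
                    best = cand
        if best is not None:
            _, dl, dr = best
            hits.append(
                MotifHit(start=i - dl + 1, end=i + dr + 1, tyrosine_pos=i + 1)
            )
    return hits
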