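"""Pairwise protein alignment and reciprocal-best-hit ortholog pairing.

A self-contained Gotoh dynamic-programming aligner (affine gaps; a gap of
length k costs ``gap_open + (k-1)*gap_extend``) replaces the external
BLAST step at desk scale.  Traceback ties resolve diagonal, then up, then
left, so output is deterministic.  BLOSUM62 (via Biopython's bundled
matrices) is the default scoring.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

from Bio.Align import substitution_matrices

from .seqio import SeqRecord

NEG_INF = float("-inf")


@lru_cache(maxsize=None)
def load_matrix(name: str = "BLOSUM62"):
    return substitution_matrices.load(name)


@dataclass(frozen=True)
class AlignmentResult:
    query_id: str
    target_id: str
    score: float
    aligned_query: str
    aligned_target: str
    identity_fraction: float


@dataclass(frozen=True)
class RbhPair:
    id_a: str
    id_b: str
    score_ab: float
    score_ba: float


def _identity(aq: str, at: str) -> float:
    cols = [(x, y) for x, y in zip(aq, at) if not (x == "-" and y == "-")]
    if not cols:
        return 0.0
    return sum(1 for x, y in cols if x == y and x != "-") / len(cols)


# state codes: 0 = match/mismatch, 1 = gap in target (up), 2 = gap in query (left)


def _gotoh(
    a: str,
    b: str,
    matrix,
    gap_open: float,
    gap_extend: float,
    local: bool,
) -> tuple[float, str, str]:
    n, m = len(a), len(b)
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    pM = [[0] * (m + 1) for _ in range(n + 1)]
    pX = [[0] * (m + 1) for _ in range(n + 1)]
    pY = [[0] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    if not local:
        for i in range(1, n + 1):
            X[i][0] = -(gap_open + (i - 1) * gap_extend)
            pX[i][0] = 1
        for j in range(1, m + 1):
            Y[0][j] = -(gap_open + (j - 1) * gap_extend)
            pY[0][j] = 2
    else:
        for i in range(1, n + 1):
            M[i][0] = 0.0
        for j in range(1, m + 1):
            M[0][j] = 0.0

    best = (0.0, 0, 0) if local else None
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = matrix[ai, b[j - 1]]
            # M: predecessors at (i-1, j-1); tie order M, X, Y
            cands = (M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            k = max(range(3), key=lambda t: (cands[t], -t))
            val = cands[k] + s
            if local and val < 0:
                val, k = 0.0, 0
                M[i][j] = 0.0
            M[i][j] = val
            pM[i][j] = k
            # X: gap in b, consume a[i-1]; from (i-1, j)
            cx = (
                M[i - 1][j] - gap_open,
                X[i - 1][j] - gap_extend,
                Y[i - 1][j] - gap_open,
            )
            k = max(range(3), key=lambda t: (cx[t], -t))
            X[i][j] = cx[k]
            pX[i][j] = k
            # Y: gap in a, consume b[j-1]; from (i, j-1)
            cy = (
                M[i][j - 1] - gap_open,
                X[i][j - 1] - gap_open,
                Y[i][j - 1] - gap_extend,
            )
            k = max(range(3), key=lambda t: (cy[t], -t))
            Y[i][j] = cy[k]
            pY[i][j] = k
            if local and M[i][j] > best[0]:
                best = (M[i][j], i, j)

    if local:
        score, i, j = best
        state = 0
        if score <= 0:
            return 0.0, "", ""
    else:
        finals = (M[n][m], X[n][m], Y[n][m])
        state = max(range(3), key=lambda t: (finals[t], -t))
        score, i, j = finals[state], n, m

    aq, at = [], []
    while True:
        if not local and i == 0 and j == 0:
            break
        if local and state == 0 and M[i][j] == 0:
            break
        if state == 0:
            prev = pM[i][j]
            aq.append(a[i - 1])
            at.append(b[j - 1])
            i, j = i - 1, j - 1
            state = prev
        elif state == 1:
            prev = pX[i][j]
            aq.append(a[i - 1])
            at.append("-")
            i -= 1
            state = prev
        else:
            prev = pY[i][j]
            aq.append("-")
            at.append(b[j - 1])
            j -= 1
            state = prev
        if not local and i == 0 and j == 0:
            break
        if local and state == 0 and M[i][j] == 0:
            break
    return score, "".join(reversed(aq)), "".join(reversed(at))


def _align(
    a: SeqRecord,
    b: SeqRecord,
    matrix=None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    local: bool = True,
) -> AlignmentResult:
    if not a.residues or not b.residues:
        raise ValueError("cannot align empty sequence")
    if not (gap_open >= gap_extend >= 0):
        raise ValueError("require gap_open >= gap_extend >= 0")
    mat = matrix if matrix is not None else load_matrix()
    score, aq, at = _gotoh(a.residues, b.residues, mat, gap_open, gap_extend, local)
    return AlignmentResult(
        query_id=a.id,
        target_id=b.id,
        score=score,
        aligned_query=aq,
        aligned_target=at,
        identity_fraction=_identity(aq, at),
    )


def local_align(a: SeqRecord, b: SeqRecord, matrix=None,
                gap_open: float = 11.0, gap_extend: float = 1.0) -> AlignmentResult:
    """Optimal Smith-Waterman local alignment with affine gaps."""
    return _align(a, b, matrix, gap_open, gap_extend, local=True)


def global_align(a: SeqRecord, b: SeqRecord, matrix=None,
                 gap_open: float = 11.0, gap_extend: float = 1.0) -> AlignmentResult:
    """Needleman-Wunsch global alignment with the same scoring scheme."""
    return _align(a, b, matrix, gap_open, gap_extend, local=False)


def percent_identity(a: SeqRecord, b: SeqRecord, mode: str = "global",
                     matrix=None, gap_open: float = 11.0,
                     gap_extend: float = 1.0) -> float:
    """Identity fraction over the aligned columns of the chosen mode.

    Arguments are ordered canonically before aligning so that tied-score
    alternative alignments cannot make the result asymmetric.
    """
    if mode not in ("local", "global"):
        raise ValueError(f"unknown mode {mode!r}")
    if (b.residues, b.id) < (a.residues, a.id):
        a, b = b, a
    fn = local_align if mode == "local" else global_align
    return fn(a, b, matrix, gap_open, gap_extend).identity_fraction


def reciprocal_best_hits(
    set_a: Sequence[SeqRecord],
    set_b: Sequence[SeqRecord],
    matrix=None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> tuple[list[RbhPair], list[tuple[str, tuple[str, ...]]]]:
    """Pair sequences that are each other's unique best local-alignment hit.

    Returns (pairs, ambiguous) where ``ambiguous`` lists ids whose best
    score was tied across several candidates (no pair is emitted for
    those, by design).
    """
    if not set_a or not set_b:
        raise ValueError("both sets must be non-empty")
    for s in (set_a, set_b):
        ids = [r.id for r in s]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate ids within a set")
    mat = matrix if matrix is not None else load_matrix()
    scores: dict[tuple[str, str], float] = {}
    for a in set_a:
        for b in set_b:
            scores[(a.id, b.id)] = _gotoh(
                a.residues, b.residues, mat, gap_open, gap_extend, True
            )[0]

    def strict_best(candidates: list[str], fixed: str, forward: bool):
        get = (lambda c: scores[(fixed, c)]) if forward else (lambda c: scores[(c, fixed)])
        top = max(get(c) for c in candidates)
        winners = tuple(c for c in candidates if get(c) == top)
        return (winners[0], top) if len(winners) == 1 else (None, top, winners)

    ids_a = [r.id for r in set_a]
    ids_b = [r.id for r in set_b]
    pairs: list[RbhPair] = []
    ambiguous: list[tuple[str, tuple[str, ...]]] = []
    best_for_b: dict[str, Optional[str]] = {}
    for bid in ids_b:
        res = strict_best(ids_a, bid, forward=False)
        best_for_b[bid] = res[0]
        if res[0] is None:
            ambiguous.append((bid, res[2]))
    for aid in ids_a:
        res = strict_best(ids_b, aid, forward=True)
        if res[0] is None:
            ambiguous.append((aid, res[2]))
            continue
        bid = res[0]
        if best_for_b[bid] == aid:
            pairs.append(
                RbhPair(
                    id_a=aid,
                    id_b=bid,
                    score_ab=scores[(aid, bid)],
                    score_ba=scores[(aid, bid)],
                )
            )
    return pairs, ambiguous
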