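"""Independent reference implementations used only to check the package.

These deliberately take different routes from the library code: regex for
motif scanning, Biopython's PairwiseAligner for alignment scores, and a
from-scratch enumeration for NG86 site/difference counting.
"""

from __future__ import annotations

import re
from itertools import permutations

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
BASES = "ACGT"


def regex_pattern_offsets(pattern_text: str, seq: str) -> list[int]:
    """Motif scan via regex with an overlap-permitting lookahead."""
    out = []
    i = 0
    rx = ""
    while i < len(pattern_text):
        c = pattern_text[i]
        if c == "(":
            j = pattern_text.index(")", i)
            rx += "[" + pattern_text[i + 1 : j].replace("/", "") + "]"
            i = j + 1
        elif c == "x":
            rx += "[" + AMINO_ACIDS + "]"
            i += 1
        else:
            rx += c
            i += 1
    return [m.start() for m in re.finditer(f"(?=({rx}))", seq)]


def brute_pswm_scores(scores_by_pos: list[dict], seq: str) -> list[tuple[int, float]]:
    """Window-by-window PSWM scoring with plain dict lookups."""
    w = len(scores_by_pos)
    out = []
    for off in range(len(seq) - w + 1):
        window = seq[off : off + w]
        if any(c not in AMINO_ACIDS for c in window):
            continue
        out.append((off, sum(scores_by_pos[j][c] for j, c in enumerate(window))))
    return out


def biopython_local_score(a: str, b: str, gap_open: float = 11.0,
                          gap_extend: float = 1.0) -> float:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "local"
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return float(aligner.score(a, b))


def biopython_global_score(a: str, b: str, gap_open: float = 11.0,
                           gap_extend: float = 1.0) -> float:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "global"
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return float(aligner.score(a, b))


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def ng86_sites_oracle(codon: str) -> float:
    """Synonymous sites by direct enumeration (stops out of denominators)."""
    ref = _aa(codon)
    assert ref != "*"
    s = 0.0
    for pos in range(3):
        muts = [
            codon[:pos] + b + codon[pos + 1 :]
            for b in BASES
            if b != codon[pos]
        ]
        nonstop = [m for m in muts if _aa(m) != "*"]
        if nonstop:
            s += sum(1 for m in nonstop if _aa(m) == ref) / len(nonstop)
    return s


def ng86_diffs_oracle(c1: str, c2: str):
    """Pathway-averaged (sd, nd); None if every ordering crosses a stop."""
    pos = [i for i in range(3) if c1[i] != c2[i]]
    if not pos:
        return 0.0, 0.0
    results = []
    for order in permutations(pos):
        cur, sd, nd, ok = c1, 0, 0, True
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1 :]
            if _aa(nxt) == "*":
                ok = False
                break
            if _aa(nxt) == _aa(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            results.append((sd, nd))
    if not results:
        return None
    n = len(results)
    return sum(r[0] for r in results) / n, sum(r[1] for r in results) / n
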