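"""Degenerate alpha-repeat patterns and position-specific weight matrices.

Two detection routes are provided: exact degenerate-pattern matching for
the printed consensus motifs, and log-odds PSWM scanning for divergent
motif instances that fall below strict-pattern stringency.  A paired
alpha1/alpha2 search with a spacing constraint models the two-block
architecture of the exchanger transport domains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, TextIO, Union

import numpy as np

from .seqio import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
UNIFORM_BACKGROUND = np.full(20, 0.05)


class PatternError(ValueError):
    pass


@dataclass(frozen=True)
class MotifPattern:
    """A degenerate motif: one allowed-residue set per position."""

    positions: tuple[frozenset, ...]
    label: str
    source_text: str

    def __post_init__(self) -> None:
        if not self.positions:
            raise PatternError("pattern must have >= 1 position")
        for i, s in enumerate(self.positions):
            if not s:
                raise PatternError(f"empty residue set at position {i}")

    def __len__(self) -> int:
        return len(self.positions)

    def matches(self, window: str) -> bool:
        return len(window) == len(self.positions) and all(
            c in s for c, s in zip(window, self.positions)
        )


@dataclass(frozen=True)
class MotifHit:
    seq_id: str
    offset: int  # 0-based
    matched: str
    pattern_label: str

    @property
    def end(self) -> int:
        return self.offset + len(self.matched)


def parse_pattern(text: str, label: str = "") -> MotifPattern:
    """Parse a printed motif string such as ``"GTS(I/V/L)PD"`` or ``"(G/S)(N/D)SxGD"``.

    Single letters are fixed positions, ``(A/B/...)`` is an alternation and
    lower-case ``x`` is a full wildcard.
    """
    positions: list[frozenset] = []
    i = 0
    full = frozenset(AMINO_ACIDS)
    while i < len(text):
        c = text[i]
        if c == "(":
            close = text.find(")", i)
            if close == -1:
                raise PatternError(f"unbalanced parenthesis at column {i + 1}")
            body = text[i + 1 : close]
            alts = [a.strip().upper() for a in body.split("/")]
            if not body or any(len(a) != 1 for a in alts):
                raise PatternError(f"bad alternation {body!r} at column {i + 1}")
            for a in alts:
                if a not in AA_INDEX:
                    raise PatternError(f"illegal residue {a!r} at column {i + 1}")
            positions.append(frozenset(alts))
            i = close + 1
        elif c == "x":
            positions.append(full)
            i += 1
        elif c.upper() in AA_INDEX and c.isupper():
            positions.append(frozenset(c))
            i += 1
        else:
            raise PatternError(f"illegal character {c!r} at column {i + 1}")
    return MotifPattern(tuple(positions), label or text, text)


def scan_pattern(seq: SeqRecord, pattern: MotifPattern) -> list[MotifHit]:
    """All (possibly overlapping) pattern occurrences, sorted by offset."""
    w = len(pattern)
    s = seq.residues
    hits = []
    for off in range(len(s) - w + 1):
        window = s[off : off + w]
        if pattern.matches(window):
            hits.append(MotifHit(seq.id, off, window, pattern.label))
    return hits


@dataclass(frozen=True)
class PSWM:
    """Log2-odds position-specific weight matrix over the 20 amino acids."""

    scores: np.ndarray  # width x 20
    background: np.ndarray
    pseudocount: float
    label: str

    @property
    def width(self) -> int:
        return self.scores.shape[0]

    @property
    def max_score(self) -> float:
        """Best attainable window score (sum of per-column maxima)."""
        return float(self.scores.max(axis=1).sum())

    def score_window(self, window: str) -> float:
        return float(sum(self.scores[j, AA_INDEX[c]] for j, c in enumerate(window)))


@dataclass(frozen=True)
class PswmHit:
    seq_id: str
    offset: int
    window: str
    score: float
    relative_score: float


def build_pswm(
    instances: Sequence[str],
    pseudocount: float = 0.5,
    background: Optional[np.ndarray] = None,
    label: str = "pswm",
) -> PSWM:
    """Build a log2-odds PSWM from equal-length ungapped motif instances.

    score[j][a] = log2(((count_j(a) + pc) / (N + 20*pc)) / background[a]).
    With pseudocount 0 zero-count cells become -inf (permitted, flagged by
    the caller via ``np.isneginf``).
    """
    if not instances:
        raise PatternError("need >= 1 instance")
    width = len(instances[0])
    if any(len(s) != width for s in instances):
        raise PatternError(f"instances differ in length (expected {width})")
    if pseudocount < 0:
        raise PatternError("pseudocount must be >= 0")
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(background, float)
    if bg.shape != (20,) or np.any(bg <= 0) or not np.isclose(bg.sum(), 1.0):
        raise PatternError("background must be 20 positive frequencies summing to 1")
    counts = np.zeros((width, 20))
    for inst in instances:
        for j, c in enumerate(inst.upper()):
            if c not in AA_INDEX:
                raise PatternError(f"illegal residue {c!r} in instance {inst!r}")
            counts[j, AA_INDEX[c]] += 1
    n = len(instances)
    with np.errstate(divide="ignore"):
        freqs = (counts + pseudocount) / (n + 20 * pseudocount)
        scores = np.log2(freqs / bg)
    return PSWM(scores=scores, background=bg, pseudocount=pseudocount, label=label)


def scan_pswm(
    seq: SeqRecord, pswm: PSWM, min_relative_score: float = 0.8
) -> list[PswmHit]:
    """Score every window; keep those at or above the relative-score cutoff.

    Hits are sorted by descending score, then ascending offset.
    """
    s = seq.residues
    w = pswm.width
    maxs = pswm.max_score
    hits = []
    for off in range(len(s) - w + 1):
        window = s[off : off + w]
        if any(c not in AA_INDEX for c in window):
            continue
        score = pswm.score_window(window)
        rel = score / maxs if maxs > 0 else float("-inf")
        if rel >= min_relative_score:
            hits.append(PswmHit(seq.id, off, window, score, rel))
    hits.sort(key=lambda h: (-h.score, h.offset))
    return hits


@dataclass(frozen=True)
class PairReport:
    """Result of the paired alpha1 -> alpha2 search on one protein."""

    alpha1_hit: Optional[object] = None  # MotifHit or PswmHit
    alpha2_hit: Optional[object] = None
    paired: bool = False
    divergent: bool = False


Motif = Union[MotifPattern, PSWM]


def _collect_hits(
    seq: SeqRecord,
    motif: Union[Motif, Sequence[Motif]],
    min_relative_score: float,
) -> list:
    motifs = motif if isinstance(motif, (list, tuple)) else [motif]
    hits: list = []
    for m in motifs:
        if isinstance(m, PSWM):
            hits.extend(scan_pswm(seq, m, min_relative_score))
        else:
            hits.extend(scan_pattern(seq, m))
    hits.sort(key=lambda h: h.offset)
    return hits


def _hit_len(hit) -> int:
    return len(hit.matched if isinstance(hit, MotifHit) else hit.window)


def find_alpha_repeat_pair(
    seq: SeqRecord,
    alpha1: Union[Motif, Sequence[Motif]],
    alpha2: Union[Motif, Sequence[Motif]],
    min_gap: int = 50,
    max_gap: int = 1000,
    min_relative_score: float = 0.8,
) -> PairReport:
    """Search for an alpha1 hit followed by an alpha2 hit at loop distance.

    ``paired`` is true when some alpha1 hit precedes some alpha2 hit with a
    separation (alpha2 offset minus alpha1 end) within [min_gap, max_gap].
    ``divergent`` is true when exactly one of the two repeats is present.
    """
    if min_gap > max_gap:
        raise ValueError("min_gap must be <= max_gap")
    h1 = _collect_hits(seq, alpha1, min_relative_score)
    h2 = _collect_hits(seq, alpha2, min_relative_score)
    best: Optional[tuple] = None
    for a in h1:
        a_end = a.offset + _hit_len(a)
        for b in h2:
            gap = b.offset - a_end
            if min_gap <= gap <= max_gap:
                key = (
                    -(getattr(a, "score", 0.0) + getattr(b, "score", 0.0)),
                    a.offset,
                    b.offset,
                )
                if best is None or key < best[0]:
                    best = (key, a, b)
    if best is not None:
        return PairReport(alpha1_hit=best[1], alpha2_hit=best[2], paired=True)
    found1, found2 = bool(h1), bool(h2)
    return PairReport(
        alpha1_hit=h1[0] if h1 else None,
        alpha2_hit=h2[0] if h2 else None,
        paired=False,
        divergent=found1 != found2,
    )


def _lib(label: str, *texts: str) -> list[MotifPattern]:
    return [parse_pattern(t, f"{label}:{t}") for t in texts]


#: printed consensus motifs per subtype; both the degenerate and the
#: observed-consensus variants are included so either spelling matches.
MOTIF_LIBRARY = {
    "NCX": {
        "alpha1": _lib("NCX_alpha1", "G(S/G)SAPE"),
        "alpha2": _lib("NCX_alpha2", "GTS(I/V/L)PD"),
    },
    "CCX": {
        "alpha1": _lib("CCX_alpha1", "GNG(A/S)PD"),
        "alpha2": _lib("CCX_alpha2", "(G/S)(N/D)SxGD", "(A/S)N(S/C)(V/I)GD"),
    },
}


def write_pswm(pswm: PSWM, handle: TextIO) -> None:
    """Serialise as a plain-text matrix (one row per position, 20 columns)."""
    handle.write(f"# PSWM {pswm.label}\n")
    handle.write(f"# pseudocount {pswm.pseudocount}\n")
    handle.write("# background " + " ".join(f"{b:.6g}" for b in pswm.background) + "\n")
    handle.write("pos\t" + "\t".join(AMINO_ACIDS) + "\n")
    for j in range(pswm.width):
        row = "\t".join(f"{pswm.scores[j, k]:.6f}" for k in range(20))
        handle.write(f"{j + 1}\t{row}\n")


def read_pswm(handle: TextIO) -> PSWM:
    label, pseudocount, background = "pswm", 0.5, UNIFORM_BACKGROUND
    rows = []
    for line in handle:
        line = line.rstrip("\n")
        if line.startswith("# PSWM"):
            label = line.split(None, 2)[2]
        elif line.startswith("# pseudocount"):
            pseudocount = float(line.split()[2])
        elif line.startswith("# background"):
            background = np.array([float(x) for x in line.split()[2:]])
        elif line.startswith("pos\t") or not line:
            continue
        else:
            rows.append([float(x) for x in line.split("\t")[1:]])
    return PSWM(
        scores=np.array(rows),
        background=background,
        pseudocount=pseudocount,
        label=label,
    )
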