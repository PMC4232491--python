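"""Nucleotide diversity and counting-based dN/dS.

Diversity (pi) is the proportion of differing sites among sites that are
unambiguous in both rows, computed pairwise and over DnaSP-style sliding
windows in alignment coordinates (gaps occupy coordinates but never enter
the numerator or denominator).

Selection is estimated with the Nei-Gojobori (1986) counting method:
fractional synonymous/nonsynonymous site assignment by single-nucleotide
mutation enumeration (mutations to stop codons excluded from a position's
denominator), pathway-averaged difference counting for multi-substitution
codons (orderings passing through stop codons discarded), and the
Jukes-Cantor correction d = -(3/4) ln(1 - (4/3) p).  The "global" value
pools site and difference counts over all unordered row pairs before
forming proportions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations, permutations
from typing import Optional, Sequence

import numpy as np

from .codonaln import CodonAlignment, CodonError, translate_codon

BASES = "ACGT"
VALID = frozenset(BASES)


# ---------------------------------------------------------------------------
# nucleotide diversity


def pairwise_pi(a: str, b: str) -> tuple[Optional[float], int]:
    """Proportion of differing sites over sites valid (A/C/G/T) in both rows.

    Returns (pi, valid_sites); pi is None when no site is valid.
    """
    if len(a) != len(b):
        raise ValueError(f"row lengths differ: {len(a)} vs {len(b)}")
    a, b = a.upper(), b.upper()
    valid = diffs = 0
    for x, y in zip(a, b):
        if x in VALID and y in VALID:
            valid += 1
            if x != y:
                diffs += 1
    if valid == 0:
        return None, 0
    return diffs / valid, valid


@dataclass(frozen=True)
class WindowDiversity:
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    midpoint: float
    pi: Optional[float]
    valid_sites: int


def sliding_window_pi(
    rows: Sequence[str], window: int = 100, step: int = 25
) -> list[WindowDiversity]:
    """Sliding-window pi over an alignment of two or more equal-length rows.

    Windows start at 0, step, 2*step, ... while start + window fits; the
    trailing partial window is dropped.  For more than two rows the window
    pi is the mean over all row pairs with defined pi; ``valid_sites`` is
    summed over pairs.
    """
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    if len(rows) < 2:
        raise ValueError("need >= 2 rows")
    length = len(rows[0])
    if any(len(r) != length for r in rows):
        raise ValueError("rows differ in length")
    if length < window:
        warnings.warn(f"alignment length {length} shorter than window {window}")
        return []
    out = []
    for start in range(0, length - window + 1, step):
        end = start + window
        pis, total_valid = [], 0
        for i, j in combinations(range(len(rows)), 2):
            pi, valid = pairwise_pi(rows[i][start:end], rows[j][start:end])
            total_valid += valid
            if pi is not None:
                pis.append(pi)
        out.append(
            WindowDiversity(
                start=start,
                end=end,
                midpoint=(start + end) / 2,
                pi=float(np.mean(pis)) if pis else None,
                valid_sites=total_valid,
            )
        )
    return out


@dataclass(frozen=True)
class DiversitySummary:
    gene_label: str
    mean_pi: float
    window_variance: float
    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float
    whisker_low: float
    whisker_high: float
    n_windows: int


def summarize_diversity(
    windows: Sequence[WindowDiversity], gene_label: str = ""
) -> DiversitySummary:
    """Box-plot statistics over the defined window pi values.

    Quartiles use linear interpolation; variance is the sample (n-1)
    estimator, 0 by convention for a single window; whisker ends are the
    extreme values within 1.5 x IQR of the quartiles.
    """
    values = np.array([w.pi for w in windows if w.pi is not None], float)
    if values.size == 0:
        raise ValueError("no window has a defined pi")
    q1, med, q3 = np.percentile(values, [25, 50, 75], method="linear")
    iqr = q3 - q1
    lo_bound, hi_bound = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo_bound) & (values <= hi_bound)]
    return DiversitySummary(
        gene_label=gene_label,
        mean_pi=float(values.mean()),
        window_variance=float(values.var(ddof=1)) if values.size > 1 else 0.0,
        minimum=float(values.min()),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        maximum=float(values.max()),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        n_windows=int(values.size),
    )


# ---------------------------------------------------------------------------
# NG86 counting


@lru_cache(maxsize=None)
def codon_syn_sites(codon: str, genetic_code: int = 1) -> float:
    """Fractional synonymous-site count for one sense codon.

    At each position the fraction of single-nucleotide changes that are
    synonymous is computed over the changes that do not create a stop
    codon; the three positional fractions sum to the codon's synonymous
    sites (nonsynonymous sites are 3 minus that).
    """
    aa = translate_codon(codon, genetic_code)
    if aa == "*":
        raise CodonError(f"stop codon {codon} has no site decomposition")
    total = 0.0
    for pos in range(3):
        syn = nonstop = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            mut_aa = translate_codon(mut, genetic_code)
            if mut_aa == "*":
                continue
            nonstop += 1
            if mut_aa == aa:
                syn += 1
        if nonstop:
            total += syn / nonstop
    return total


@lru_cache(maxsize=None)
def codon_path_differences(
    c1: str, c2: str, genetic_code: int = 1
) -> Optional[tuple[float, float]]:
    """Pathway-averaged (synonymous, nonsynonymous) differences between codons.

    All orderings of the differing positions are enumerated; orderings
    passing through a stop codon are discarded.  Returns None when every
    ordering is blocked by a stop.
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    sd_total = nd_total = 0.0
    n_paths = 0
    for order in permutations(diff_pos):
        cur = c1
        sd = nd = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if translate_codon(nxt, genetic_code) == "*":
                ok = False
                break
            if translate_codon(cur, genetic_code) == translate_codon(nxt, genetic_code):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            sd_total += sd
            nd_total += nd
            n_paths += 1
    if n_paths == 0:
        return None
    return sd_total / n_paths, nd_total / n_paths


def jc69(p: float) -> Optional[float]:
    """Jukes-Cantor distance; None when p >= 3/4 (correction undefined)."""
    if p >= 0.75:
        return None
    d = -0.75 * math.log(1.0 - (4.0 / 3.0) * p)
    return 0.0 if d == 0 else d


@dataclass
class DnDsResult:
    N: float
    S: float
    Nd: float
    Sd: float
    pN: Optional[float]
    pS: Optional[float]
    dN: Optional[float]
    dS: Optional[float]
    omega: Optional[float]
    compared_codons: int
    skipped_codons: int = 0
    flags: list[str] = field(default_factory=list)


def _finalize(N, S, Nd, Sd, compared, skipped) -> DnDsResult:
    flags = []
    pN = Nd / N if N > 0 else None
    pS = Sd / S if S > 0 else None
    dN = jc69(pN) if pN is not None else None
    dS = jc69(pS) if pS is not None else None
    if pN is not None and dN is None:
        flags.append("dN undefined (pN >= 3/4)")
    if pS is not None and dS is None:
        flags.append("dS undefined (pS >= 3/4)")
    omega = None
    if dN is not None and dS is not None and dS > 0:
        omega = dN / dS
    else:
        flags.append("omega undefined (dS = 0 or correction failed)")
    if skipped:
        flags.append(f"{skipped} codon pair(s) skipped")
    return DnDsResult(
        N=N, S=S, Nd=Nd, Sd=Sd, pN=pN, pS=pS, dN=dN, dS=dS,
        omega=omega, compared_codons=compared, skipped_codons=skipped,
        flags=flags,
    )


def _pair_counts(a: str, b: str, genetic_code: int) -> tuple[float, float, float, float, int, int]:
    if len(a) != len(b):
        raise ValueError("rows differ in length")
    if len(a) % 3:
        raise ValueError("row length not divisible by 3")
    a, b = a.upper(), b.upper()
    N = S = Nd = Sd = 0.0
    compared = skipped = 0
    for k in range(0, len(a), 3):
        ca, cb = a[k : k + 3], b[k : k + 3]
        if any(c not in VALID for c in ca) or any(c not in VALID for c in cb):
            continue  # gap or ambiguity in either row: site skipped pairwise
        if translate_codon(ca, genetic_code) == "*" or translate_codon(cb, genetic_code) == "*":
            raise CodonError(f"stop codon in compared pair at codon {k // 3 + 1}")
        diffs = codon_path_differences(ca, cb, genetic_code)
        if diffs is None:
            warnings.warn(f"codon pair {ca}/{cb} skipped: all pathways hit stops")
            skipped += 1
            continue
        sa, sb = codon_syn_sites(ca, genetic_code), codon_syn_sites(cb, genetic_code)
        S += (sa + sb) / 2
        N += 3 - (sa + sb) / 2
        Sd += diffs[0]
        Nd += diffs[1]
        compared += 1
    return N, S, Nd, Sd, compared, skipped


def ng86_pair(a: str, b: str, genetic_code: int = 1) -> DnDsResult:
    """NG86 dN/dS between two equal-length gapped codon rows."""
    N, S, Nd, Sd, compared, skipped = _pair_counts(a, b, genetic_code)
    return _finalize(N, S, Nd, Sd, compared, skipped)


def global_dnds(
    caln: CodonAlignment, genetic_code: int = 1
) -> tuple[DnDsResult, list[tuple[str, str, DnDsResult]]]:
    """Pooled NG86 over all unordered row pairs of a codon alignment.

    Site and difference counts are summed over pairs, then proportions,
    corrected rates and omega are computed from the pooled counts.  The
    per-pair table is returned alongside.
    """
    rows = caln.records
    if len(rows) < 2:
        raise ValueError("need >= 2 rows")
    tN = tS = tNd = tSd = 0.0
    tc = tsk = 0
    per_pair = []
    for i, j in combinations(range(len(rows)), 2):
        N, S, Nd, Sd, compared, skipped = _pair_counts(
            rows[i].residues, rows[j].residues, genetic_code
        )
        per_pair.append((rows[i].id, rows[j].id, _finalize(N, S, Nd, Sd, compared, skipped)))
        tN += N
        tS += S
        tNd += Nd
        tSd += Sd
        tc += compared
        tsk += skipped
    return _finalize(tN, tS, tNd, tSd, tc, tsk), per_pair
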