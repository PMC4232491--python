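"""In-silico PCR and tandem gene-model bridging.

Primer binding is exact-match by default; amplicons are every compatible
(plus-strand forward site, minus-strand reverse site) combination within
the product-size ceiling.  Bridging asks whether one transcript's mapped
exons overlap two adjacent gene models, the evidence used to merge split
gene predictions.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Optional, Sequence, TextIO, Union

from .seqio import SeqIoError, SeqRecord

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Primer:
    name: str
    sequence: str
    allow_iupac: bool = False

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ValueError(f"empty primer {self.name!r}")
        allowed = set(IUPAC) if self.allow_iupac else set("ACGT")
        bad = set(seq) - allowed
        if bad:
            raise ValueError(f"illegal bases {sorted(bad)} in primer {self.name!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AmpliconPrediction:
    template_id: str
    forward_start: int  # 0-based
    reverse_end: int  # 0-based exclusive
    product_sequence: str

    @property
    def length(self) -> int:
        return self.reverse_end - self.forward_start


def _mismatches(window: str, primer: str) -> int:
    return sum(
        1 for w, p in zip(window, primer) if w not in IUPAC.get(p, p)
    )


def find_primer_sites(
    template: SeqRecord, primer: Primer, max_mismatches: int = 0
) -> tuple[list[int], list[int]]:
    """Plus-strand primer sites and minus-strand (reverse-complement) sites.

    Offsets are 0-based starts of the matching window on the template.
    """
    seq = template.residues.upper()
    p = primer.sequence
    rc = reverse_complement(p)
    w = len(p)
    plus, minus = [], []
    for off in range(len(seq) - w + 1):
        window = seq[off : off + w]
        if _mismatches(window, p) <= max_mismatches:
            plus.append(off)
        if _mismatches(window, rc) <= max_mismatches:
            minus.append(off)
    return plus, minus


def predict_amplicon(
    template: SeqRecord,
    forward: Primer,
    reverse: Primer,
    max_product: int = 10_000,
    max_mismatches: int = 0,
) -> list[AmpliconPrediction]:
    """All forward/reverse site combinations yielding a product, sorted by length.

    Product length spans both primer footprints (forward start to the end
    of the reverse primer's reverse-complement match).
    """
    plus, _ = find_primer_sites(template, forward, max_mismatches)
    _, minus = find_primer_sites(template, reverse, max_mismatches)
    seq = template.residues.upper()
    out = []
    for f in plus:
        for r in minus:
            end = r + len(reverse)
            length = end - f
            if f < end and length <= max_product:
                out.append(
                    AmpliconPrediction(
                        template_id=template.id,
                        forward_start=f,
                        reverse_end=end,
                        product_sequence=seq[f:end],
                    )
                )
    out.sort(key=lambda a: (a.length, a.forward_start))
    return out


@dataclass(frozen=True)
class GeneModel:
    id: str
    contig_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]  # 0-based half-open, sorted

    def __post_init__(self) -> None:
        ex = tuple(sorted(tuple(e) for e in self.exons))
        object.__setattr__(self, "exons", ex)
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping exons in {self.id}")
        for s, e in ex:
            if not 0 <= s < e:
                raise ValueError(f"bad exon interval ({s}, {e}) in {self.id}")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass(frozen=True)
class BridgeReport:
    cdna_id: str
    model_a_id: str
    model_b_id: str
    bridges: bool
    covered_a: int
    covered_b: int
    merged_model: Optional[GeneModel]


def _overlap(intervals: Sequence[tuple[int, int]], span: tuple[int, int]) -> int:
    lo, hi = span
    return sum(max(0, min(e, hi) - max(s, lo)) for s, e in intervals)


def _merge_intervals(intervals: Sequence[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


def bridge_check(
    cdna_id: str,
    cdna_exons: Sequence[tuple[int, int]],
    model_a: GeneModel,
    model_b: GeneModel,
) -> BridgeReport:
    """Test whether a mapped cDNA spans two adjacent gene models.

    ``bridges`` is true iff the cDNA exons overlap both model spans; when
    they do, a merged model is proposed covering the union of both models
    and the cDNA exon structure.
    """
    if model_a.contig_id != model_b.contig_id:
        raise ValueError(
            f"models on different contigs: {model_a.contig_id} vs {model_b.contig_id}"
        )
    sa, sb = model_a.span, model_b.span
    if max(sa[0], sb[0]) < min(sa[1], sb[1]):
        raise ValueError(f"models {model_a.id} and {model_b.id} overlap")
    cov_a = _overlap(cdna_exons, sa)
    cov_b = _overlap(cdna_exons, sb)
    bridges = cov_a > 0 and cov_b > 0
    merged = None
    if bridges:
        merged = GeneModel(
            id=f"{model_a.id}+{model_b.id}",
            contig_id=model_a.contig_id,
            strand=model_a.strand,
            exons=_merge_intervals(
                list(cdna_exons) + list(model_a.exons) + list(model_b.exons)
            ),
        )
    return BridgeReport(
        cdna_id=cdna_id,
        model_a_id=model_a.id,
        model_b_id=model_b.id,
        bridges=bridges,
        covered_a=cov_a,
        covered_b=cov_b,
        merged_model=merged,
    )


def read_gene_models(source: Union[str, TextIO]) -> list[GeneModel]:
    """Read gene models from GFF3 (exon features) or 4-column TSV.

    TSV columns: id, contig, start (1-based), end (inclusive).  GFF3 exon
    rows are grouped by their Parent (or ID) attribute.
    """
    handle = io.StringIO(source) if isinstance(source, str) else source
    exons: dict[str, list] = {}
    contigs: dict[str, str] = {}
    strands: dict[str, str] = {}
    for lineno, line in enumerate(handle, 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) >= 9:  # GFF3
            contig, _, ftype, start, end, _, strand, _, attrs = fields[:9]
            if ftype.lower() not in ("exon", "cds"):
                continue
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            gid = attr.get("Parent") or attr.get("ID")
            if gid is None:
                raise SeqIoError(f"line {lineno}: exon without Parent/ID")
        elif len(fields) == 4:
            gid, contig, start, end = fields
            strand = "+"
        else:
            raise SeqIoError(f"line {lineno}: expected GFF3 or 4-column TSV")
        try:
            s, e = int(start), int(end)
        except ValueError:
            raise SeqIoError(f"line {lineno}: non-integer coordinates") from None
        if s > e:
            raise SeqIoError(f"line {lineno}: start > end")
        exons.setdefault(gid, []).append((s - 1, e))
        contigs[gid] = contig
        strands[gid] = strand
    return [
        GeneModel(id=gid, contig_id=contigs[gid], strand=strands[gid], exons=tuple(ex))
        for gid, ex in exons.items()
    ]
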