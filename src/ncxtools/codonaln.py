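"""Codon-aware back-translation of protein alignments (the PAL2NAL step).

Each aligned protein row is replaced codon-by-codon with its coding
sequence; protein gap columns become ``---``.  Validation is strict:
length and translation mismatches are fatal, a terminal stop codon on the
CDS is trimmed with a warning, and internal stops are always errors
(split gene models hinge on stop codons, so they must never pass
silently).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, TextIO

from Bio.Data import CodonTable

from .seqio import Alignment, SeqRecord

STOP = "*"
GAP_CODON = "---"


class CodonError(ValueError):
    pass


def _table(genetic_code: int):
    return CodonTable.unambiguous_dna_by_id[genetic_code]


def translate_codon(codon: str, genetic_code: int = 1) -> str:
    """Single-codon translation; returns '*' for stop codons."""
    table = _table(genetic_code)
    if codon in table.stop_codons:
        return STOP
    try:
        return table.forward_table[codon]
    except KeyError:
        raise CodonError(f"cannot translate codon {codon!r}") from None


def translate(cds: SeqRecord, genetic_code: int = 1,
              allow_internal_stop: bool = False) -> SeqRecord:
    """Translate a CDS; terminal stop is dropped, internal stops are fatal."""
    seq = cds.residues
    if len(seq) % 3 != 0:
        raise CodonError(f"CDS length {len(seq)} of {cds.id} not divisible by 3")
    aas = []
    n_codons = len(seq) // 3
    for k in range(n_codons):
        aa = translate_codon(seq[3 * k : 3 * k + 3], genetic_code)
        if aa == STOP:
            if k == n_codons - 1:
                break
            if not allow_internal_stop:
                raise CodonError(f"internal stop codon at codon {k + 1} of {cds.id}")
        aas.append(aa)
    return SeqRecord(id=cds.id, residues="".join(aas), description=cds.description)


@dataclass
class CodonAlignment:
    """Gap-consistent nucleotide rows, three columns per protein column."""

    records: list[SeqRecord]
    source_protein_alignment: Alignment

    @property
    def codon_columns(self) -> int:
        return len(self.records[0].residues) // 3

    def to_alignment(self) -> Alignment:
        return Alignment(list(self.records))

    def row_codons(self, idx: int) -> list[str]:
        s = self.records[idx].residues
        return [s[i : i + 3] for i in range(0, len(s), 3)]


def back_translate(
    protein_aln: Alignment,
    cds_map: Mapping[str, SeqRecord],
    genetic_code: int = 1,
    allow_ambiguity: bool = False,
) -> CodonAlignment:
    """Thread each CDS onto its aligned protein row."""
    rows = []
    for prot in protein_aln.records:
        if prot.id not in cds_map:
            raise CodonError(f"no CDS provided for {prot.id}")
        cds = cds_map[prot.id].residues
        ungapped = prot.residues.replace("-", "")
        if len(cds) == 3 * (len(ungapped) + 1):
            tail = cds[-3:]
            if translate_codon(tail, genetic_code) == STOP:
                warnings.warn(f"terminal stop codon trimmed from CDS of {prot.id}")
                cds = cds[:-3]
        if len(cds) != 3 * len(ungapped):
            raise CodonError(
                f"CDS/protein length mismatch for {prot.id}: "
                f"{len(cds)} nt vs {len(ungapped)} aa"
            )
        if not allow_ambiguity:
            bad = set(cds) - set("ACGT")
            if bad:
                raise CodonError(
                    f"ambiguous nucleotides {sorted(bad)} in CDS of {prot.id} "
                    "(use allow_ambiguity to accept)"
                )
        out = []
        k = 0
        for pos, aa in enumerate(prot.residues):
            if aa == "-":
                out.append(GAP_CODON)
                continue
            codon = cds[3 * k : 3 * k + 3]
            if all(c in "ACGT" for c in codon):
                trans = translate_codon(codon, genetic_code)
                if trans != aa:
                    res_index = k + 1
                    raise CodonError(
                        f"translation mismatch for {prot.id} at residue "
                        f"{res_index}: codon {codon} -> {trans}, protein has {aa}"
                    )
            out.append(codon)
            k += 1
        rows.append(SeqRecord(id=prot.id, residues="".join(out),
                              description=prot.description))
    return CodonAlignment(records=rows, source_protein_alignment=protein_aln)


def write_phylip(caln: CodonAlignment, handle: TextIO) -> None:
    """Relaxed sequential PHYLIP for downstream tree tools."""
    n = len(caln.records)
    length = len(caln.records[0].residues)
    handle.write(f" {n} {length}\n")
    for rec in caln.records:
        handle.write(f"{rec.id}  {rec.residues}\n")
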