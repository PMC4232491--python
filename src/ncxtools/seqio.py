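"""Sequence, alignment and domain-table I/O.

FASTA parsing is delegated to Biopython; this module adds the validation
layer (alphabet checks, duplicate-id detection, terminal-stop policy) and
the gap-column stripping used to normalise alignments before downstream
statistics.  Coordinates are 0-based half-open internally; file formats
(FASTA headers aside) emit 1-based inclusive coordinates.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional, TextIO, Union

import yaml
from Bio import SeqIO as _BioSeqIO

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
NUCLEOTIDE_ALPHABET = frozenset("ACGTUNRYSWKMBDHV")
GAP = "-"

#: roles a domain signature can play in subtype classification
ROLE_K_DEP = "K_DEP"
ROLE_EXCHANGER = "EXCHANGER"
ROLE_CALX_BETA = "CALX_BETA"

DEFAULT_ROLE_ALIASES = {
    "IPR004481": ROLE_K_DEP,
    "Na_Ca_ex": ROLE_EXCHANGER,
    "PF01699": ROLE_EXCHANGER,
    "IPR004837": ROLE_EXCHANGER,
    "CalX_Beta": ROLE_CALX_BETA,
    "Calx-beta": ROLE_CALX_BETA,
    "PF03160": ROLE_CALX_BETA,
    "IPR003644": ROLE_CALX_BETA,
}


class SeqIoError(ValueError):
    """Raised on malformed sequence or table input."""


@dataclass(frozen=True)
class SeqRecord:
    """A named, validated sequence (no gap characters)."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise SeqIoError(f"invalid sequence id: {self.id!r}")
        if not self.residues:
            raise SeqIoError(f"empty sequence for id {self.id!r}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Alignment:
    """Equal-length gapped rows; at least two of them."""

    records: list[SeqRecord]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise SeqIoError("alignment needs >= 2 rows")
        lengths = {len(r.residues) for r in self.records}
        if len(lengths) != 1:
            raise SeqIoError(f"alignment rows differ in length: {sorted(lengths)}")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise SeqIoError("duplicate row ids in alignment")

    @property
    def length(self) -> int:
        return len(self.records[0].residues)

    def __len__(self) -> int:
        return len(self.records)

    def row(self, seq_id: str) -> SeqRecord:
        for r in self.records:
            if r.id == seq_id:
                return r
        raise KeyError(seq_id)


@dataclass(frozen=True)
class DomainAnnotation:
    """One signature interval on a protein (1-based inclusive coordinates)."""

    protein_id: str
    signature: str
    start: int
    end: int
    interpro: str = ""
    role: Optional[str] = None

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise SeqIoError(
                f"bad domain interval {self.start}..{self.end} on {self.protein_id}"
            )


class StripResult(NamedTuple):
    alignment: Optional[Alignment]
    retained_columns: list[int]
    empty: bool


def _validate_residues(seq_id: str, residues: str, alphabet: str) -> str:
    allowed = PROTEIN_ALPHABET if alphabet == "protein" else NUCLEOTIDE_ALPHABET
    residues = residues.upper()
    if alphabet == "protein":
        if residues.endswith("*"):
            warnings.warn(f"terminal stop stripped from {seq_id}")
            residues = residues[:-1]
        if "*" in residues:
            pos = residues.index("*")
            raise SeqIoError(f"internal stop '*' in {seq_id} at position {pos + 1}")
    if not residues:
        raise SeqIoError(f"empty sequence for id {seq_id!r}")
    for i, c in enumerate(residues):
        if c not in allowed:
            raise SeqIoError(
                f"illegal {alphabet} residue {c!r} in {seq_id} at position {i + 1}"
            )
    return residues


def read_fasta(
    source: Union[str, TextIO],
    alphabet: str = "protein",
    allow_gaps: bool = False,
) -> list[SeqRecord]:
    """Parse FASTA text into validated :class:`SeqRecord` objects.

    ``alphabet`` is ``protein`` or ``nucleotide``.  Gap characters are
    rejected unless ``allow_gaps`` (used when reading alignments).
    """
    if alphabet not in ("protein", "nucleotide"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    handle = io.StringIO(source) if isinstance(source, str) else source
    out: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in _BioSeqIO.parse(handle, "fasta"):
        if rec.id in seen:
            raise SeqIoError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        residues = str(rec.seq)
        if allow_gaps:
            core = residues.replace(GAP, "")
            core = _validate_residues(rec.id, core, alphabet)
            # revalidate keeps gap layout; rebuild with upper-case + stop policy
            residues = residues.upper()
            if alphabet == "protein" and residues.rstrip(GAP).endswith("*"):
                idx = residues.rstrip(GAP).rindex("*")
                residues = residues[:idx] + residues[idx + 1 :]
        else:
            if GAP in residues:
                raise SeqIoError(f"gap character in ungapped context for {rec.id!r}")
            residues = _validate_residues(rec.id, residues, alphabet)
        desc = rec.description[len(rec.id) :].strip() if rec.description else ""
        out.append(SeqRecord(id=rec.id, residues=residues, description=desc))
    return out


def read_alignment(source: Union[str, TextIO], alphabet: str = "protein") -> Alignment:
    return Alignment(read_fasta(source, alphabet=alphabet, allow_gaps=True))


def write_fasta(records: Iterable[SeqRecord], handle: TextIO, width: int = 60) -> None:
    for rec in records:
        header = rec.id if not rec.description else f"{rec.id} {rec.description}"
        handle.write(f">{header}\n")
        for i in range(0, len(rec.residues), width):
            handle.write(rec.residues[i : i + width] + "\n")


def strip_gap_columns(aln: Alignment, max_gap_frac: float = 0.0) -> StripResult:
    """Drop alignment columns whose gap fraction exceeds ``max_gap_frac``.

    The default (0) removes every column containing at least one gap.
    Returns the stripped alignment, the retained original column indices
    (0-based), and an ``empty`` flag when no column survives (a warning
    condition, not an error).
    """
    n = len(aln.records)
    retained = []
    for j in range(aln.length):
        gaps = sum(1 for r in aln.records if r.residues[j] == GAP)
        if gaps / n <= max_gap_frac:
            retained.append(j)
    if not retained:
        warnings.warn("gap stripping removed every column")
        return StripResult(None, [], True)
    rows = [
        SeqRecord(
            id=r.id,
            residues="".join(r.residues[j] for j in retained),
            description=r.description,
        )
        for r in aln.records
    ]
    return StripResult(Alignment(rows), retained, False)


# InterProScan TSV layout (1-based column numbers)
DEFAULT_DOMAIN_COLUMNS = {
    "protein_id": 1,
    "signature": 5,
    "start": 7,
    "end": 8,
    "interpro": 12,
}


def read_domain_table(
    source: Union[str, TextIO],
    columns: Optional[dict] = None,
    role_aliases: Optional[dict] = None,
) -> list[DomainAnnotation]:
    """Read an InterProScan-style TSV into domain annotations.

    Rows whose signature (or InterPro accession) maps to a known role are
    tagged with it; unrecognised signatures are kept with ``role=None``.
    """
    cols = dict(DEFAULT_DOMAIN_COLUMNS, **(columns or {}))
    aliases = DEFAULT_ROLE_ALIASES if role_aliases is None else role_aliases
    handle = io.StringIO(source) if isinstance(source, str) else source
    out: list[DomainAnnotation] = []
    for lineno, line in enumerate(handle, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")

        def get(name: str) -> str:
            idx = cols[name] - 1
            return fields[idx] if idx < len(fields) else ""

        try:
            start = int(get("start"))
            end = int(get("end"))
        except ValueError as exc:
            raise SeqIoError(f"line {lineno}: non-integer coordinate ({exc})") from None
        if start > end:
            raise SeqIoError(f"line {lineno}: start {start} > end {end}")
        signature = get("signature")
        interpro = get("interpro")
        role = aliases.get(signature) or aliases.get(interpro)
        out.append(
            DomainAnnotation(
                protein_id=get("protein_id"),
                signature=signature,
                start=start,
                end=end,
                interpro=interpro,
                role=role,
            )
        )
    return out


def load_role_aliases(source: Union[str, TextIO]) -> dict:
    """Load a signature→role alias table from YAML (mapping accession: role)."""
    data = yaml.safe_load(source if isinstance(source, str) else source.read())
    if not isinstance(data, dict):
        raise SeqIoError("alias config must be a mapping")
    valid = {ROLE_K_DEP, ROLE_EXCHANGER, ROLE_CALX_BETA}
    for key, role in data.items():
        if role not in valid:
            raise SeqIoError(f"unknown role {role!r} for signature {key!r}")
    return dict(data)
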