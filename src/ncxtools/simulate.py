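"""Synthetic data generators for every pipeline stage.

All generators are pure functions of their spec (seed included), so any
stochastic test is reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .codonaln import translate_codon
from .motifs import AMINO_ACIDS
from .seqio import DEFAULT_ROLE_ALIASES, DomainAnnotation, SeqRecord

BASES = "ACGT"

#: planted alpha1/alpha2 repeats per subtype; NCKX shares the NCX-type
#: repeats (its alpha2 already ends in the potassium-dependence aspartate)
#: and is additionally tagged with a synthetic K_DEP domain annotation.
SUBTYPE_MOTIFS = {
    "NCX": ("GSSAPE", "GTSIPD"),
    "NCKX": ("GSSAPE", "GTSIPD"),
    "CCX": ("GNGAPD", "SNSIGD"),
}

SENSE_CODONS = tuple(
    a + b + c
    for a in BASES
    for b in BASES
    for c in BASES
    if translate_codon(a + b + c) != "*"
)


@dataclass(frozen=True)
class SimSpec:
    seed: int
    subtype: str
    length: int = 600
    alpha1_pos: Optional[int] = None
    alpha2_pos: Optional[int] = None
    noise_rate: float = 0.0
    corrupt_motifs: bool = False
    min_gap: int = 50
    max_gap: int = 1000

    def __post_init__(self) -> None:
        if self.subtype not in SUBTYPE_MOTIFS:
            raise ValueError(f"unknown subtype {self.subtype!r}")
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ValueError("noise_rate must be in [0, 1]")


@dataclass(frozen=True)
class SimulatedProtein:
    record: SeqRecord
    label: str
    alpha1_pos: int
    alpha2_pos: int
    annotations: tuple[DomainAnnotation, ...] = ()


def _default_positions(spec: SimSpec, m1: str, m2: str) -> tuple[int, int]:
    a1 = spec.alpha1_pos if spec.alpha1_pos is not None else max(10, spec.length // 6)
    if spec.alpha2_pos is not None:
        a2 = spec.alpha2_pos
    else:
        gap = min(spec.max_gap, max(spec.min_gap, spec.length // 2))
        a2 = a1 + len(m1) + gap
        if a2 + len(m2) > spec.length:
            a2 = spec.length - len(m2) - 1
    return a1, a2


def simulate_exchanger_protein(spec: SimSpec, seq_id: Optional[str] = None) -> SimulatedProtein:
    """Generate one exchanger-like protein with planted alpha repeats.

    Background residues are uniform; noise mutates positions outside the
    planted motifs (inside them only with ``corrupt_motifs``).
    """
    m1, m2 = SUBTYPE_MOTIFS[spec.subtype]
    a1, a2 = _default_positions(spec, m1, m2)
    if a1 + len(m1) > a2:
        raise ValueError("planted motifs overlap")
    gap = a2 - (a1 + len(m1))
    if not (spec.min_gap <= gap <= spec.max_gap):
        raise ValueError(
            f"motif spacing {gap} outside [{spec.min_gap}, {spec.max_gap}]"
        )
    if a2 + len(m2) > spec.length:
        raise ValueError("alpha2 motif does not fit in sequence")
    rng = np.random.default_rng(spec.seed)
    residues = list(rng.choice(list(AMINO_ACIDS), size=spec.length))
    residues[a1 : a1 + len(m1)] = list(m1)
    residues[a2 : a2 + len(m2)] = list(m2)
    protected = set(range(a1, a1 + len(m1))) | set(range(a2, a2 + len(m2)))
    if spec.noise_rate > 0:
        hit = rng.random(spec.length) < spec.noise_rate
        for i in np.flatnonzero(hit):
            if int(i) in protected and not spec.corrupt_motifs:
                continue
            residues[i] = rng.choice(list(AMINO_ACIDS))
    sid = seq_id or f"sim_{spec.subtype}_{spec.seed}"
    rec = SeqRecord(id=sid, residues="".join(residues),
                    description=f"simulated {spec.subtype} exchanger")
    annotations: tuple[DomainAnnotation, ...] = ()
    if spec.subtype == "NCKX":
        annotations = (
            DomainAnnotation(
                protein_id=sid,
                signature="IPR004481",
                start=a2 + 1,
                end=a2 + len(m2),
                role=DEFAULT_ROLE_ALIASES["IPR004481"],
            ),
        )
    return SimulatedProtein(
        record=rec, label=spec.subtype, alpha1_pos=a1, alpha2_pos=a2,
        annotations=annotations,
    )


def simulate_batch(
    n_per_subtype: int,
    seed: int,
    length: int = 600,
    noise_rate: float = 0.0,
) -> tuple[list[SeqRecord], list[DomainAnnotation], dict[str, str]]:
    """A balanced batch across the three subtypes with ground-truth labels."""
    records, annotations, truth = [], [], {}
    counter = 0
    for subtype in ("NCX", "NCKX", "CCX"):
        for k in range(n_per_subtype):
            spec = SimSpec(
                seed=seed * 1_000_003 + counter,
                subtype=subtype,
                length=length,
                noise_rate=noise_rate,
            )
            sim = simulate_exchanger_protein(spec, seq_id=f"sim{counter:04d}_{subtype}")
            records.append(sim.record)
            annotations.extend(sim.annotations)
            truth[sim.record.id] = subtype
            counter += 1
    return records, annotations, truth


@dataclass(frozen=True)
class OrthoSimSpec:
    seed: int
    length: int  # bases (nucleotide mode) or codons (codon modes)
    per_site_rate: float
    mode: str = "nucleotide"  # nucleotide | codon_synonymous_only | codon_free

    def __post_init__(self) -> None:
        if not 0.0 <= self.per_site_rate < 0.75:
            raise ValueError("per_site_rate must be in [0, 0.75)")
        if self.mode not in ("nucleotide", "codon_synonymous_only", "codon_free"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class SimulatedPair:
    ancestor: SeqRecord
    descendant: SeqRecord
    realized_divergence: float


def _mutate_base(base: str, rng) -> str:
    return rng.choice([b for b in BASES if b != base])


def simulate_ortholog_pair(spec: OrthoSimSpec) -> SimulatedPair:
    """Ancestor/descendant nucleotide pair under a Jukes-Cantor kernel.

    Each site mutates independently with ``per_site_rate`` to one of the
    three other bases (uniformly).  Codon modes draw the ancestor from
    sense codons and reject mutations that create stop codons; the
    synonymous-only mode additionally rejects amino-acid-changing
    mutations, so NG86 on the output has dN = 0 exactly.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.mode == "nucleotide":
        anc = "".join(rng.choice(list(BASES), size=spec.length))
        desc = list(anc)
        hit = rng.random(spec.length) < spec.per_site_rate
        for i in np.flatnonzero(hit):
            desc[i] = _mutate_base(desc[i], rng)
        desc = "".join(desc)
    else:
        from .evolstats import codon_path_differences

        codons = list(rng.choice(SENSE_CODONS, size=spec.length))
        anc = "".join(codons)
        out = []
        for codon in codons:
            cur = codon
            for pos in range(3):
                if rng.random() >= spec.per_site_rate:
                    continue
                cand = _mutate_base(cur[pos], rng)
                nxt = cur[:pos] + cand + cur[pos + 1 :]
                if translate_codon(nxt) == "*":
                    continue
                if spec.mode == "codon_synonymous_only":
                    # require not just a synonymous step but a codon whose
                    # every NG86 pathway back to the ancestor is synonymous,
                    # so pathway-averaged counting yields dN = 0 exactly
                    diffs = codon_path_differences(codon, nxt)
                    if diffs is None or diffs[1] != 0:
                        continue
                cur = nxt
            out.append(cur)
        desc = "".join(out)
    diffs = sum(1 for x, y in zip(anc, desc) if x != y)
    return SimulatedPair(
        ancestor=SeqRecord(id=f"anc_{spec.seed}", residues=anc),
        descendant=SeqRecord(id=f"desc_{spec.seed}", residues=desc),
        realized_divergence=diffs / len(anc),
    )
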