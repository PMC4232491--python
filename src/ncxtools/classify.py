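"""Rule-based NCX / NCKX / CCX subtype classification.

Evidence is gathered from two independent sources: role-mapped domain
annotations (potassium-dependent exchanger signature, exchanger domain,
CalX-beta domain) and paired alpha-repeat motif hits.  Classification is
a fixed-order decision list; the first rule that fires wins and is
recorded in the rationale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from . import motifs
from .seqio import (
    ROLE_CALX_BETA,
    ROLE_EXCHANGER,
    ROLE_K_DEP,
    DomainAnnotation,
    SeqRecord,
)

LABEL_NCX = "NCX"
LABEL_NCKX = "NCKX"
LABEL_CCX = "CCX"
LABEL_UNCLASSIFIED = "UNCLASSIFIED"


@dataclass
class SubtypeEvidence:
    protein_id: str
    has_k_dep_domain: bool = False
    exchanger_domain_count: int = 0
    calx_beta_count: int = 0
    ncx_pair: motifs.PairReport = field(default_factory=motifs.PairReport)
    ccx_pair: motifs.PairReport = field(default_factory=motifs.PairReport)
    divergent: bool = False
    has_domain_annotations: bool = False
    warnings: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class SubtypeCall:
    protein_id: str
    label: str
    divergent_candidate: bool
    rationale: tuple[str, ...]


def collect_evidence(
    seq: SeqRecord,
    domains: Sequence[DomainAnnotation] = (),
    library: Optional[dict] = None,
    min_gap: int = 50,
    max_gap: int = 1000,
    min_relative_score: float = 0.8,
) -> SubtypeEvidence:
    """Derive classification evidence for one protein.

    Domain annotations must refer to ``seq.id``; intervals beyond the
    sequence end are kept but recorded as warnings.
    """
    lib = library or motifs.MOTIF_LIBRARY
    ev = SubtypeEvidence(protein_id=seq.id)
    for dom in domains:
        if dom.protein_id != seq.id:
            continue
        ev.has_domain_annotations = True
        if dom.end > len(seq):
            ev.warnings.append(
                f"domain {dom.signature} interval {dom.start}..{dom.end} "
                f"exceeds sequence length {len(seq)}"
            )
        if dom.role == ROLE_K_DEP:
            ev.has_k_dep_domain = True
        elif dom.role == ROLE_EXCHANGER:
            ev.exchanger_domain_count += 1
        elif dom.role == ROLE_CALX_BETA:
            ev.calx_beta_count += 1
    ev.ncx_pair = motifs.find_alpha_repeat_pair(
        seq, lib["NCX"]["alpha1"], lib["NCX"]["alpha2"],
        min_gap, max_gap, min_relative_score,
    )
    ev.ccx_pair = motifs.find_alpha_repeat_pair(
        seq, lib["CCX"]["alpha1"], lib["CCX"]["alpha2"],
        min_gap, max_gap, min_relative_score,
    )
    ev.divergent = not (ev.ncx_pair.paired or ev.ccx_pair.paired) and (
        ev.ncx_pair.divergent or ev.ccx_pair.divergent
    )
    return ev


def classify_protein(ev: SubtypeEvidence, min_calx: int = 2) -> SubtypeCall:
    """Fixed-precedence decision list.

    1. potassium-dependent exchanger domain -> NCKX
    2. exchanger evidence (domain or paired NCX motifs) + >= ``min_calx``
       CalX-beta domains -> NCX
    2b. no domain annotations at all but paired NCX motifs -> NCX
        (motif-only mode; lower confidence, noted in the rationale)
    3. exchanger evidence (domain or paired CCX motifs) + zero CalX-beta
       domains -> CCX
    4. otherwise UNCLASSIFIED
    """
    rationale: list[str] = []
    label = LABEL_UNCLASSIFIED
    if ev.has_k_dep_domain:
        label = LABEL_NCKX
        rationale.append("rule1: K_DEP domain present")
    elif (
        ev.exchanger_domain_count >= 1 or ev.ncx_pair.paired
    ) and ev.calx_beta_count >= min_calx:
        label = LABEL_NCX
        rationale.append(
            f"rule2: exchanger evidence (domains={ev.exchanger_domain_count}, "
            f"ncx_pair={ev.ncx_pair.paired}) with {ev.calx_beta_count} CalX-beta"
        )
    elif not ev.has_domain_annotations and ev.ncx_pair.paired:
        label = LABEL_NCX
        rationale.append("rule2b: motif-only mode, paired NCX alpha repeats (lower confidence)")
    elif (
        ev.exchanger_domain_count >= 1 or ev.ccx_pair.paired
    ) and ev.calx_beta_count == 0:
        label = LABEL_CCX
        rationale.append(
            f"rule3: exchanger evidence (domains={ev.exchanger_domain_count}, "
            f"ccx_pair={ev.ccx_pair.paired}) with no CalX-beta"
        )
    else:
        rationale.append("rule4: no rule matched")
    if ev.divergent:
        rationale.append("divergent: exactly one alpha repeat detected")
    for w in ev.warnings:
        rationale.append(f"warning: {w}")
    return SubtypeCall(
        protein_id=ev.protein_id,
        label=label,
        divergent_candidate=ev.divergent,
        rationale=tuple(rationale),
    )


def classify_batch(
    seqs: Sequence[SeqRecord],
    domains: Sequence[DomainAnnotation] = (),
    min_calx: int = 2,
    **evidence_kwargs,
) -> list[SubtypeCall]:
    """Classify each sequence independently, preserving input order."""
    seq_ids = {s.id for s in seqs}
    by_protein: dict[str, list[DomainAnnotation]] = {}
    for dom in domains:
        by_protein.setdefault(dom.protein_id, []).append(dom)
    orphans = sorted(set(by_protein) - seq_ids)
    if orphans:
        import warnings as _w

        _w.warn(f"domain annotations for unknown proteins: {', '.join(orphans)}")
    calls = []
    for seq in seqs:
        ev = collect_evidence(seq, by_protein.get(seq.id, ()), **evidence_kwargs)
        calls.append(classify_protein(ev, min_calx=min_calx))
    return calls


def summarize_calls(calls: Sequence[SubtypeCall]) -> dict:
    counts = {LABEL_NCX: 0, LABEL_NCKX: 0, LABEL_CCX: 0, LABEL_UNCLASSIFIED: 0}
    for c in calls:
        counts[c.label] += 1
    return counts
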