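"""Open-reading-frame detection and cluster-level pseudogenization calls.

A duplicated transcript that has lost ORF integrity — a premature stop,
a frame-disrupting deletion, or a missing start — is evidence of
pseudogenization. A paralog cluster where at least one (but not all)
member is disrupted is called PARTIAL: the classic signature of a
duplication followed by decay of one copy.

Scans are forward-strand only: assembled transcripts are oriented mRNA.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from .io_formats import Alignment

__all__ = [
    "OrfAssessment",
    "DisruptionReason",
    "PseudogenizationStatus",
    "find_orfs",
    "longest_orf",
    "assess_orf_in_cluster",
    "cluster_pseudogenization",
]

STOP_CODONS = {"TAA", "TAG", "TGA"}
START_CODON = "ATG"


class DisruptionReason(str, Enum):
    NONE = "none"
    PREMATURE_STOP = "premature_stop"
    FRAMESHIFT_GAP = "frameshift_gap"
    NO_START = "no_start"


class PseudogenizationStatus(str, Enum):
    NONE = "NONE"
    PARTIAL = "PARTIAL"
    ALL = "ALL"


@dataclass(frozen=True)
class OrfAssessment:
    """Per-member ORF integrity verdict within a trimmed cluster alignment."""

    transcript_id: str
    orf_interval: tuple[int, int] | None
    intact: bool
    reason: DisruptionReason

    def __post_init__(self) -> None:
        if self.intact and self.reason is not DisruptionReason.NONE:
            raise ValueError("intact assessment must carry reason 'none'")


def find_orfs(seq: str, min_codons: int = 30) -> list[tuple[int, int]]:
    """All forward-strand ATG->stop spans (stop included) of >= min_codons codons.

    Every ATG opens its own ORF, closed by the next in-frame stop; ORFs
    running off the end of the sequence (no stop) are not reported.
    Returned as 0-based half-open intervals sorted by start.
    """
    seq = seq.upper().replace("U", "T")
    n = len(seq)
    orfs: list[tuple[int, int]] = []
    for frame in range(3):
        # index of the next in-frame stop at or after each codon position
        starts: list[int] = []
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if codon == START_CODON:
                starts.append(pos)
            elif codon in STOP_CODONS:
                end = pos + 3
                for s in starts:
                    if end - s >= min_codons * 3:
                        orfs.append((s, end))
                starts = []
    orfs.sort()
    return orfs


def longest_orf(seq: str, min_codons: int = 1) -> tuple[int, int] | None:
    """Longest ORF interval, ties broken by leftmost start."""
    orfs = find_orfs(seq, min_codons=min_codons)
    if not orfs:
        return None
    return max(orfs, key=lambda iv: (iv[1] - iv[0], -iv[0]))


def _reference_codon_columns(ref_row: str) -> list[tuple[int, int, int]]:
    """Column indices of each reference codon (triplets of ungapped ref columns)."""
    cols = [i for i, c in enumerate(ref_row) if c != "-"]
    if len(cols) % 3 != 0:
        raise ValueError("reference row length (ungapped) not a multiple of 3")
    return [tuple(cols[i : i + 3]) for i in range(0, len(cols), 3)]


def assess_orf_in_cluster(
    trimmed_aln: Alignment,
    member_id: str,
    reference_id: str,
    premature_stop_frac: float = 0.9,
    start_window_codons: int = 10,
) -> OrfAssessment:
    """Assess one member's ORF integrity in a CDS-trimmed alignment.

    The member is read in the reference's frame along the alignment.
    Disruptions, earliest first along the reading frame:

    * ``frameshift_gap`` — a gap run in the member whose length is not a
      multiple of three, ending before ``premature_stop_frac`` of the
      reference codons (in-frame indels are tolerated);
    * ``premature_stop`` — a fully-aligned in-frame stop codon before
      that same boundary (the reference's own terminal stop is beyond it);
    * ``no_start`` — no ATG codon aligned within the first
      ``start_window_codons`` reference codons.

    Earliest-event precedence matters: a frameshift makes every
    downstream reference-frame "stop" spurious, so the frameshift is
    reported, not the stops it manufactures.
    """
    ref_row = trimmed_aln.row(reference_id)
    member_row = trimmed_aln.row(member_id)

    ref_codons = _reference_codon_columns(ref_row)
    n_codons = len(ref_codons)
    ref_seq = ref_row.replace("-", "")
    if not ref_seq.startswith(START_CODON) or ref_seq[-3:] not in STOP_CODONS:
        raise ValueError(f"reference {reference_id!r} is not an ATG..stop span")
    boundary = premature_stop_frac * n_codons  # disruptions strictly before this codon index

    # start check: an aligned ATG within the start window
    has_start = any(
        "".join(member_row[c] for c in ref_codons[i]) == START_CODON
        for i in range(min(start_window_codons, n_codons))
    )

    # walk columns in order, tracking member gap runs and in-frame codons
    gap_run = 0
    gap_run_start_codon = 0
    ref_seen = 0  # ungapped reference positions consumed
    disruption: tuple[float, DisruptionReason] | None = None
    for col in range(trimmed_aln.n_columns):
        codon_idx = ref_seen / 3
        if member_row[col] == "-":
            if gap_run == 0:
                gap_run_start_codon = codon_idx
            gap_run += 1
        else:
            if gap_run and gap_run % 3 != 0 and gap_run_start_codon < boundary:
                disruption = (gap_run_start_codon, DisruptionReason.FRAMESHIFT_GAP)
                break
            gap_run = 0
        if ref_row[col] != "-":
            ref_seen += 1
            if ref_seen % 3 == 0:
                i = ref_seen // 3 - 1
                codon = "".join(member_row[c] for c in ref_codons[i])
                if i < boundary and codon in STOP_CODONS:
                    disruption = (i, DisruptionReason.PREMATURE_STOP)
                    break
    if disruption is None and gap_run and gap_run % 3 != 0 and gap_run_start_codon < boundary:
        disruption = (gap_run_start_codon, DisruptionReason.FRAMESHIFT_GAP)

    if disruption is not None:
        reason = disruption[1]
    elif not has_start:
        reason = DisruptionReason.NO_START
    else:
        reason = DisruptionReason.NONE

    member_seq = member_row.replace("-", "")
    interval = longest_orf(member_seq, min_codons=1)
    return OrfAssessment(
        transcript_id=member_id,
        orf_interval=interval,
        intact=reason is DisruptionReason.NONE,
        reason=reason,
    )


def cluster_pseudogenization(assessments: Sequence[OrfAssessment]) -> PseudogenizationStatus:
    """Roll member assessments up to a cluster call.

    PARTIAL — at least one but not all members disrupted (a
    pseudogenization event leaving >=1 protein-coding copy); NONE — all
    intact; ALL — every member disrupted.
    """
    if len(assessments) < 2:
        raise ValueError("need at least two member assessments")
    n_intact = sum(a.intact for a in assessments)
    if n_intact == len(assessments):
        return PseudogenizationStatus.NONE
    if n_intact == 0:
        return PseudogenizationStatus.ALL
    return PseudogenizationStatus.PARTIAL
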