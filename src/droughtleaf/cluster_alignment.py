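"""Cluster admissibility checks and CDS trimming on paralog alignments.

Before a paralog cluster goes to tree building, two sanity gates apply
to the query (guayule) rows of its multiple sequence alignment:

* the queries must actually overlap each other in the alignment
  (non-overlapping gene fragments carry no evidence of duplication), and
* their pairwise identity must reach a threshold (default 50%) over the
  mutually ungapped columns — below that, the transcripts do not share a
  recent evolutionary past.

``trim_to_cds`` then removes UTR columns so every row spans the
reference's ATG..stop coding region, the form expected by the ORF
integrity checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from itertools import combinations
from typing import Sequence

from .io_formats import Alignment
from .orf_integrity import find_orfs

__all__ = [
    "AdmissibilityVerdict",
    "ClusterAdmissibility",
    "pairwise_identity",
    "assess_cluster",
    "trim_to_cds",
    "MIN_OVERLAP_COLUMNS",
]

MIN_OVERLAP_COLUMNS = 30  # identity over fewer mutually ungapped columns is noise


class AdmissibilityVerdict(str, Enum):
    ADMISSIBLE = "ADMISSIBLE"
    LOW_IDENTITY = "LOW_IDENTITY"
    NO_OVERLAP = "NO_OVERLAP"


@dataclass(frozen=True)
class ClusterAdmissibility:
    verdict: AdmissibilityVerdict
    min_identity: float | None  # None when some pair had no usable overlap
    min_overlap_columns: int


def pairwise_identity(aln: Alignment, a: str, b: str) -> tuple[float | None, int]:
    """Identity between two rows over their mutually ungapped columns.

    Returns (identity fraction, number of mutually ungapped columns);
    identity is None when the overlap is zero (undefined).
    """
    row_a = aln.row(a)
    row_b = aln.row(b)
    matches = 0
    overlap = 0
    for ca, cb in zip(row_a, row_b):
        if ca != "-" and cb != "-":
            overlap += 1
            if ca == cb:
                matches += 1
    if overlap == 0:
        return None, 0
    return matches / overlap, overlap


def assess_cluster(
    aln: Alignment,
    query_ids: Sequence[str],
    min_identity: float = 0.5,
    min_overlap: int = MIN_OVERLAP_COLUMNS,
) -> ClusterAdmissibility:
    """Gate a paralog cluster on query-row overlap and identity.

    NO_OVERLAP (some query pair shares < ``min_overlap`` mutually
    ungapped columns) takes precedence over LOW_IDENTITY (some pair
    below ``min_identity``).
    """
    if len(query_ids) < 2:
        raise ValueError("need at least two query rows to assess a cluster")
    identities: list[float] = []
    min_cols: int | None = None
    no_overlap = False
    for a, b in combinations(query_ids, 2):
        ident, cols = pairwise_identity(aln, a, b)
        min_cols = cols if min_cols is None else min(min_cols, cols)
        if ident is None or cols < min_overlap:
            no_overlap = True
        else:
            identities.append(ident)
    min_ident = min(identities) if identities else None
    if no_overlap:
        return ClusterAdmissibility(AdmissibilityVerdict.NO_OVERLAP, min_ident, min_cols or 0)
    if min_ident is not None and min_ident < min_identity:
        return ClusterAdmissibility(AdmissibilityVerdict.LOW_IDENTITY, min_ident, min_cols or 0)
    return ClusterAdmissibility(AdmissibilityVerdict.ADMISSIBLE, min_ident, min_cols or 0)


def trim_to_cds(aln: Alignment, reference_id: str) -> Alignment:
    """Trim alignment columns to the reference row's ATG..stop span.

    The reference's longest forward-frame ORF defines the coding span;
    columns outside it (UTRs) are removed for every row. Idempotent.
    Raises if the reference has no ATG..stop ORF.
    """
    ref_row = aln.row(reference_id)
    ref_seq = ref_row.replace("-", "")
    orfs = find_orfs(ref_seq, min_codons=2)
    if not orfs:
        raise ValueError(f"reference {reference_id!r} has no ATG..stop span")
    start, end = max(orfs, key=lambda iv: (iv[1] - iv[0], -iv[0]))
    ungapped_to_col = [i for i, c in enumerate(ref_row) if c != "-"]
    col_start = ungapped_to_col[start]
    col_end = ungapped_to_col[end - 1] + 1
    return aln.take_columns(range(col_start, col_end))
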