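"""Plant-style miRNA target-site scoring and binding-site conservation.

The expectation score is the standard plant target-prediction penalty:
the miRNA is aligned antiparallel to the candidate site and each miRNA
position contributes 0 for a Watson-Crick pair, 0.5 for a G:U wobble and
1.0 for a mismatch, with penalties doubled inside the seed region
(miRNA positions 2-13 counted from the miRNA 5' end). An expectation of
0 therefore means perfect complementarity over the whole site — the
signature of a miRNA sponge / target mimic.

Scoring is ungapped (no target bulges); ``score_duplex`` is the single
pluggable point if a bulge-aware scorer is ever wanted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import Alignment, SequenceRecord

__all__ = [
    "MiRnaSite",
    "score_duplex",
    "scan_targets",
    "site_conservation",
    "sponge_report",
    "SEED_START",
    "SEED_END",
]

SEED_START = 2   # miRNA position (1-based, 5'->3') where the seed begins
SEED_END = 13    # last seed position (inclusive)
SEED_MULTIPLIER = 2.0
WOBBLE_PENALTY = 0.5
MISMATCH_PENALTY = 1.0

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "T"), ("T", "G")}  # G:U evaluated on the DNA alphabet


@dataclass(frozen=True)
class MiRnaSite:
    """A candidate miRNA binding site on a target transcript."""

    mirna_id: str
    target_id: str
    start: int
    end: int  # half-open; end - start == len(miRNA)
    expectation: float
    annotations: tuple[str, ...]  # per miRNA position: "WC", "GU" or "MM"
    overlaps_previous: bool = False
    conservation_fraction: float | None = None
    conserved: bool | None = None


def _normalise(seq: str) -> str:
    return seq.upper().replace("U", "T")


def score_duplex(mirna_5to3: str, site_seq: str) -> tuple[float, tuple[str, ...]]:
    """Expectation penalty of a miRNA against an equal-length target site.

    The miRNA binds antiparallel: miRNA position 1 (5' end) pairs with
    the site's 3'-most nucleotide. Returns (expectation, per-position
    annotations ordered by miRNA position).
    """
    mirna = _normalise(mirna_5to3)
    site = _normalise(site_seq)
    if len(mirna) != len(site):
        raise ValueError(f"length mismatch: miRNA {len(mirna)} vs site {len(site)}")
    total = 0.0
    notes: list[str] = []
    L = len(mirna)
    for i in range(1, L + 1):  # miRNA position, 1-based from 5'
        m = mirna[i - 1]
        t = site[L - i]  # antiparallel pairing partner
        if (m, t) in _WC:
            penalty, tag = 0.0, "WC"
        elif (m, t) in _WOBBLE:
            penalty, tag = WOBBLE_PENALTY, "GU"
        else:
            penalty, tag = MISMATCH_PENALTY, "MM"
        if SEED_START <= i <= SEED_END:
            penalty *= SEED_MULTIPLIER
        total += penalty
        notes.append(tag)
    return total, tuple(notes)


def scan_targets(
    mirna_id: str,
    mirna_5to3: str,
    transcript: SequenceRecord,
    cutoff: float = 5.0,
) -> list[MiRnaSite]:
    """Slide the miRNA over a transcript and report sites at or below cutoff.

    Sites are sorted by ascending expectation, then leftmost position;
    a site overlapping a better-ranked one is flagged but still reported.
    """
    mirna = _normalise(mirna_5to3)
    seq = transcript.residues
    L = len(mirna)
    if len(seq) < L:
        raise ValueError(f"transcript {transcript.id!r} shorter than the miRNA")
    raw: list[tuple[float, int, tuple[str, ...]]] = []
    for start in range(len(seq) - L + 1):
        expectation, notes = score_duplex(mirna, seq[start : start + L])
        if expectation <= cutoff:
            raw.append((expectation, start, notes))
    raw.sort(key=lambda r: (r[0], r[1]))
    sites: list[MiRnaSite] = []
    taken: list[tuple[int, int]] = []
    for expectation, start, notes in raw:
        overlap = any(start < e and s < start + L for s, e in taken)
        sites.append(
            MiRnaSite(
                mirna_id=mirna_id,
                target_id=transcript.id,
                start=start,
                end=start + L,
                expectation=expectation,
                annotations=notes,
                overlaps_previous=overlap,
            )
        )
        taken.append((start, start + L))
    return sites


def site_conservation(
    homolog_aln: Alignment,
    focal_id: str,
    site: MiRnaSite,
    min_fraction: float = 1.0,
) -> tuple[float, bool]:
    """Fraction of a site's alignment columns identical across all rows.

    The site's interval on the (ungapped) focal row is mapped through the
    focal row's gap structure to alignment columns; a gap in any row at a
    site column counts as non-identical there. Conserved iff the fraction
    is >= ``min_fraction`` (default: complete conservation).
    """
    focal_row = homolog_aln.row(focal_id)
    ungapped_to_col: list[int] = [i for i, c in enumerate(focal_row) if c != "-"]
    if site.end > len(ungapped_to_col):
        raise ValueError(
            f"site [{site.start}, {site.end}) extends past the ungapped focal row "
            f"({len(ungapped_to_col)} nt)"
        )
    columns = ungapped_to_col[site.start : site.end]
    n_identical = 0
    for col in columns:
        chars = {r.residues[col] for r in homolog_aln.records}
        if len(chars) == 1 and "-" not in chars:
            n_identical += 1
    fraction = n_identical / len(columns)
    return fraction, fraction >= min_fraction


def sponge_report(
    survivors: Sequence[SequenceRecord],
    mirna_library: Mapping[str, str],
    homolog_alignments: Mapping[str, Alignment],
    cutoff: float = 5.0,
    min_fraction: float = 1.0,
) -> pd.DataFrame:
    """Candidate miRNA sponges: one row per conserved site.

    ``homolog_alignments`` maps a survivor id to the MSA of that lncRNA
    with its cross-species homologs (the survivor must be a row). A
    survivor without an alignment cannot show conservation and yields no
    rows. The result is invariant to miRNA library order.
    """
    rows = []
    for rec in survivors:
        aln = homolog_alignments.get(rec.id)
        if aln is None:
            continue
        for mirna_id in sorted(mirna_library):
            mirna_seq = mirna_library[mirna_id]
            if len(rec.residues) < len(mirna_seq):
                continue
            for site in scan_targets(mirna_id, mirna_seq, rec, cutoff=cutoff):
                fraction, conserved = site_conservation(aln, rec.id, site, min_fraction=min_fraction)
                if conserved:
                    rows.append(
                        {
                            "lncrna_id": rec.id,
                            "mirna_id": mirna_id,
                            "start": site.start,
                            "end": site.end,
                            "expectation": site.expectation,
                            "conservation_fraction": fraction,
                        }
                    )
    df = pd.DataFrame(rows, columns=["lncrna_id", "mirna_id", "start", "end", "expectation", "conservation_fraction"])
    return df.sort_values(["lncrna_id", "mirna_id", "start"], kind="mergesort").reset_index(drop=True)
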