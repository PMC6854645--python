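"""The lncRNA identification filter cascade with per-transcript trails.

Candidate transcripts pass four filters in a fixed order; each
transcript is stamped with the first stage that removed it, or survives
with a cross-species conservation class:

1. ``protein_similarity`` — any hit against known proteins (default
   e <= 1e-3) disqualifies;
2. ``te_housekeeping`` — any hit against transposable-element / rRNA /
   spliceosomal-RNA libraries (default e <= 1e-10) disqualifies;
3. ``length_coding`` — must be >= 200 nt with a longest ORF of at most
   100 codons (an ORF-length stand-in for a coding-potential score);
4. ``genome_overlap`` — the best sunflower-genome hit (e <= 1e-20) must
   not intersect an annotated protein-coding feature: such transcripts
   are likely fragments of incompletely assembled coding genes.

Survivors are classified by where sequence homologs are found
(species_only / sunflower / sunflower_lettuce) and flagged when the
best-hit locus is itself annotated as a lncRNA.

All e-value comparisons are inclusive; overlap means any shared base in
half-open coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

from .io_formats import FeatureInterval, HitTable, SequenceRecord
from .orf_integrity import longest_orf

__all__ = [
    "RemovalStage",
    "ConservationClass",
    "FilterTrail",
    "filter_protein_similarity",
    "filter_te_housekeeping",
    "filter_length_coding",
    "filter_genome_overlap",
    "classify_conservation",
    "run_cascade",
    "CODING_FEATURE_KINDS",
]

CODING_FEATURE_KINDS = {"gene", "mRNA", "CDS"}


class RemovalStage(str, Enum):
    PROTEIN_SIMILARITY = "protein_similarity"
    TE_HOUSEKEEPING = "te_housekeeping"
    LENGTH_CODING = "length_coding"
    GENOME_OVERLAP = "genome_overlap"
    SURVIVOR = "survivor"


class ConservationClass(str, Enum):
    SPECIES_ONLY = "species_only"
    SUNFLOWER = "sunflower"
    SUNFLOWER_LETTUCE = "sunflower_lettuce"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class FilterTrail:
    transcript_id: str
    removed_at: RemovalStage
    conservation: ConservationClass | None = None
    annotated_lncrna_sunflower: bool = False
    annotated_lncrna_lettuce: bool = False

    def __post_init__(self) -> None:
        if (self.removed_at is RemovalStage.SURVIVOR) != (self.conservation is not None):
            raise ValueError("conservation set iff the transcript survived")


def _ids_with_hits(ids: Iterable[str], hits: HitTable, evalue_max: float) -> set[str]:
    df = hits.rows
    if df.empty:
        return set()
    hit_ids = set(df.loc[df["evalue"] <= evalue_max, "query_id"])
    return {i for i in ids if i in hit_ids}


def filter_protein_similarity(
    ids: Iterable[str], protein_hits: HitTable, evalue_max: float = 1e-3
) -> tuple[set[str], set[str]]:
    """(retained, removed): ids with any protein hit at e <= cutoff are removed."""
    ids = set(ids)
    removed = _ids_with_hits(ids, protein_hits, evalue_max)
    return ids - removed, removed


def filter_te_housekeeping(
    ids: Iterable[str], decoy_hits: HitTable, evalue_max: float = 1e-10
) -> tuple[set[str], set[str]]:
    """(retained, removed): ids hitting TE/rRNA/snRNA libraries are removed."""
    ids = set(ids)
    removed = _ids_with_hits(ids, decoy_hits, evalue_max)
    return ids - removed, removed


def filter_length_coding(
    records: Sequence[SequenceRecord],
    min_len: int = 200,
    max_orf_codons: int = 100,
) -> tuple[set[str], set[str]]:
    """(retained, removed): keep >= min_len nt with longest ORF <= max codons."""
    retained: set[str] = set()
    removed: set[str] = set()
    for rec in records:
        orf = longest_orf(rec.residues, min_codons=1)
        orf_codons = 0 if orf is None else (orf[1] - orf[0]) // 3
        if len(rec.residues) >= min_len and orf_codons <= max_orf_codons:
            retained.add(rec.id)
        else:
            removed.add(rec.id)
    return retained, removed


def best_hit(hits: HitTable, query_id: str, evalue_max: float) -> pd.Series | None:
    """Best hit for a query: lowest e-value at or below the cutoff, ties
    broken by largest coverage, then first subject sequence id."""
    df = hits.for_query(query_id)
    df = df[df["evalue"] <= evalue_max]
    if df.empty:
        return None
    df = df.sort_values(
        ["evalue", "coverage", "subject_seq_id"],
        ascending=[True, False, True],
        kind="mergesort",
    )
    return df.iloc[0]


def _hit_interval(row: pd.Series) -> FeatureInterval:
    return FeatureInterval(
        seq_id=str(row["subject_seq_id"]),
        start=int(row["subject_start"]),
        end=int(row["subject_end"]),
        kind="hit",
    )


def filter_genome_overlap(
    ids: Iterable[str],
    genome_hits: HitTable,
    annotation: Sequence[FeatureInterval],
    evalue_max: float = 1e-20,
) -> tuple[set[str], set[str]]:
    """(retained, removed): remove ids whose best genome hit intersects an
    annotated coding feature (gene/mRNA/CDS). Ids with no hit are retained."""
    coding = [f for f in annotation if f.kind in CODING_FEATURE_KINDS]
    retained: set[str] = set()
    removed: set[str] = set()
    for i in sorted(set(ids)):
        row = best_hit(genome_hits, i, evalue_max)
        if row is None:
            retained.add(i)
            continue
        iv = _hit_interval(row)
        if any(iv.overlaps(f) for f in coding):
            removed.add(i)
        else:
            retained.add(i)
    return retained, removed


def classify_conservation(
    transcript_id: str,
    sunflower_hits: HitTable,
    lettuce_hits: HitTable,
    evalue_max: float = 1e-20,
    sunflower_lnc_annotation: Sequence[FeatureInterval] = (),
    lettuce_lnc_annotation: Sequence[FeatureInterval] = (),
) -> tuple[ConservationClass, bool, bool]:
    """Conservation class of a surviving lncRNA plus annotated-lncRNA flags.

    sunflower_lettuce when homologs exist in both genomes at the
    threshold; sunflower when only there; species_only otherwise. A
    lettuce-only hit falls outside the nested phylogenetic expectation
    and is classed species_only. The annotated flags report whether the
    best-hit locus intersects a provided lncRNA annotation.
    """
    sun = best_hit(sunflower_hits, transcript_id, evalue_max)
    let = best_hit(lettuce_hits, transcript_id, evalue_max)
    if sun is not None and let is not None:
        cls = ConservationClass.SUNFLOWER_LETTUCE
    elif sun is not None:
        cls = ConservationClass.SUNFLOWER
    else:
        if let is not None:
            import warnings

            warnings.warn(
                f"{transcript_id}: lettuce hit without a sunflower hit; "
                "outside the nested conservation model",
                stacklevel=2,
            )
        cls = ConservationClass.SPECIES_ONLY
    annotated_sun = sun is not None and any(
        _hit_interval(sun).overlaps(f) for f in sunflower_lnc_annotation
    )
    annotated_let = let is not None and any(
        _hit_interval(let).overlaps(f) for f in lettuce_lnc_annotation
    )
    return cls, annotated_sun, annotated_let


def run_cascade(
    records: Sequence[SequenceRecord],
    protein_hits: HitTable,
    decoy_hits: HitTable,
    sunflower_hits: HitTable,
    lettuce_hits: HitTable,
    annotation: Sequence[FeatureInterval],
    sunflower_lnc_annotation: Sequence[FeatureInterval] = (),
    lettuce_lnc_annotation: Sequence[FeatureInterval] = (),
    evalue_protein: float = 1e-3,
    evalue_decoy: float = 1e-10,
    evalue_genome: float = 1e-20,
    min_len: int = 200,
    max_orf_codons: int = 100,
) -> dict[str, FilterTrail]:
    """Apply the four filters in order and classify the survivors."""
    by_id = {r.id: r for r in records}
    trails: dict[str, FilterTrail] = {}

    ids = set(by_id)
    ids, removed = filter_protein_similarity(ids, protein_hits, evalue_protein)
    for i in removed:
        trails[i] = FilterTrail(i, RemovalStage.PROTEIN_SIMILARITY)

    ids, removed = filter_te_housekeeping(ids, decoy_hits, evalue_decoy)
    for i in removed:
        trails[i] = FilterTrail(i, RemovalStage.TE_HOUSEKEEPING)

    ids, removed = filter_length_coding(
        [by_id[i] for i in sorted(ids)], min_len=min_len, max_orf_codons=max_orf_codons
    )
    for i in removed:
        trails[i] = FilterTrail(i, RemovalStage.LENGTH_CODING)

    ids, removed = filter_genome_overlap(ids, sunflower_hits, annotation, evalue_genome)
    for i in removed:
        trails[i] = FilterTrail(i, RemovalStage.GENOME_OVERLAP)

    for i in sorted(ids):
        cls, ann_sun, ann_let = classify_conservation(
            i,
            sunflower_hits,
            lettuce_hits,
            evalue_max=evalue_genome,
            sunflower_lnc_annotation=sunflower_lnc_annotation,
            lettuce_lnc_annotation=lettuce_lnc_annotation,
        )
        trails[i] = FilterTrail(
            i,
            RemovalStage.SURVIVOR,
            conservation=cls,
            annotated_lncrna_sunflower=ann_sun,
            annotated_lncrna_lettuce=ann_let,
        )
    return trails
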