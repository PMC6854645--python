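"""Two-stage redundancy collapse of a de novo transcriptome.

De novo assemblies routinely carry the same underlying transcript
multiple times: exact duplicates, contained fragments, and near-copies
that differ only by a mis-assembled read at one end. The collapse runs
in two stages:

1. ``collapse_identical`` — merge byte-identical sequences and (by
   default) sequences identical to a full-length substring of a longer
   one, i.e. 100%-identity clustering with shorter-sequence coverage.
2. ``collapse_trimmed`` — for each transcript, form two variants by
   removing ``trim_len`` (default 150) nucleotides from the 5' or the 3'
   end; if a variant of length > ``trim_len`` occurs as an exact
   substring of another transcript (or vice versa), the two transcripts
   are merged. This catches copies whose only difference is one
   misplaced read's worth of sequence at an end.

Within every merged block the longest sequence is retained (ties:
lexicographically smallest id). Merges chain through a union-find, so a
single pass yields stable blocks and the pipeline is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io_formats import SequenceRecord

__all__ = [
    "CollapseReport",
    "collapse_identical",
    "collapse_trimmed",
    "collapse_pipeline",
    "DEFAULT_TRIM_LEN",
]

DEFAULT_TRIM_LEN = 150


@dataclass
class CollapseReport:
    """Which ids were merged into which retained id, and at which stage."""

    partition: dict[str, set[str]]  # retained id -> collapsed ids (never contains itself)
    stage: dict[str, str]  # collapsed id -> {"identical", "trim_containment"}
    n_before: int
    n_after: int

    @property
    def n_collapsed(self) -> int:
        return sum(len(v) for v in self.partition.values())

    def merged(self, other: "CollapseReport") -> "CollapseReport":
        """Compose this report with a later stage's report."""
        partition = {k: set(v) for k, v in self.partition.items()}
        stage = dict(self.stage)
        for retained, block in other.partition.items():
            members = set(block)
            # ids retained after stage 1 may be re-collapsed later; carry their blocks along
            absorbed: set[str] = set()
            for m in list(members) + [retained]:
                if m in partition and m != retained:
                    absorbed |= partition.pop(m)
            target = partition.setdefault(retained, set())
            target |= members | absorbed
            for m in members:
                stage.setdefault(m, other.stage[m])
        return CollapseReport(
            partition=partition,
            stage=stage,
            n_before=self.n_before,
            n_after=other.n_after,
        )


class _UnionFind:
    def __init__(self, items: Iterable[str]) -> None:
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb

    def blocks(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for x in self.parent:
            out.setdefault(self.find(x), set()).add(x)
        return out


def _canonical_order(records: Sequence[SequenceRecord]) -> list[SequenceRecord]:
    """Descending length, then lexicographic id — the processing order."""
    return sorted(records, key=lambda r: (-len(r.residues), r.id))


def _check_unique_ids(records: Sequence[SequenceRecord]) -> None:
    seen: set[str] = set()
    for r in records:
        if r.id in seen:
            raise ValueError(f"duplicate id {r.id!r}")
        seen.add(r.id)


def _finish(
    records: Sequence[SequenceRecord],
    uf: _UnionFind,
    stage_name: str,
) -> tuple[list[SequenceRecord], CollapseReport]:
    by_id = {r.id: r for r in records}
    partition: dict[str, set[str]] = {}
    stage: dict[str, str] = {}
    retained_records: list[SequenceRecord] = []
    for block in uf.blocks().values():
        retained = min(block, key=lambda i: (-len(by_id[i].residues), i))
        retained_records.append(by_id[retained])
        rest = block - {retained}
        if rest:
            partition[retained] = rest
            for m in rest:
                stage[m] = stage_name
    retained_records = _canonical_order(retained_records)
    return retained_records, CollapseReport(
        partition=partition, stage=stage, n_before=len(records), n_after=len(retained_records)
    )


def collapse_identical(
    records: Sequence[SequenceRecord],
    containment: bool = True,
) -> tuple[list[SequenceRecord], CollapseReport]:
    """Stage 1: merge 100%-identity redundancy.

    With ``containment=True`` (default, mirroring 100%-identity
    clustering with shorter-sequence coverage) a sequence identical to a
    full-length substring of a longer one is merged into it; with
    ``containment=False`` only byte-identical sequences merge.
    """
    _check_unique_ids(records)
    ordered = _canonical_order(records)
    uf = _UnionFind(r.id for r in ordered)

    by_seq: dict[str, str] = {}
    for r in ordered:
        if r.residues in by_seq:
            uf.union(r.id, by_seq[r.residues])
        else:
            by_seq[r.residues] = r.id

    if containment:
        for i, shorter in enumerate(ordered):
            for longer in ordered[:i]:
                if len(longer.residues) > len(shorter.residues) and shorter.residues in longer.residues:
                    uf.union(shorter.id, longer.id)
                    break
    return _finish(ordered, uf, "identical")


def collapse_trimmed(
    records: Sequence[SequenceRecord],
    trim_len: int = DEFAULT_TRIM_LEN,
) -> tuple[list[SequenceRecord], CollapseReport]:
    """Stage 2: merge transcripts identical after one-end trimming.

    For each transcript T, form T minus its first ``trim_len`` nt and T
    minus its last ``trim_len`` nt; variants of length <= ``trim_len``
    are skipped. If a variant is an exact substring of another
    transcript S, or S is an exact substring of the variant (100%
    identity with 100% coverage of one of the two), T and S merge.
    Single pass in descending-length order; chains resolve via union-find.
    """
    _check_unique_ids(records)
    ordered = _canonical_order(records)
    uf = _UnionFind(r.id for r in ordered)
    for t in ordered:
        variants = []
        if len(t.residues) - trim_len > trim_len:
            variants.append(t.residues[trim_len:])
            variants.append(t.residues[:-trim_len])
        for v in variants:
            for s in ordered:
                if s.id == t.id:
                    continue
                if len(v) <= len(s.residues):
                    if v in s.residues:
                        uf.union(t.id, s.id)
                else:
                    if s.residues in v:
                        uf.union(t.id, s.id)
    return _finish(ordered, uf, "trim_containment")


def collapse_pipeline(
    records: Sequence[SequenceRecord],
    trim_len: int = DEFAULT_TRIM_LEN,
    containment: bool = True,
) -> tuple[list[SequenceRecord], CollapseReport]:
    """Stage 1 followed by stage 2; the concatenated report covers both."""
    if not records:
        return [], CollapseReport(partition={}, stage={}, n_before=0, n_after=0)
    stage1_records, report1 = collapse_identical(records, containment=containment)
    stage2_records, report2 = collapse_trimmed(stage1_records, trim_len=trim_len)
    return stage2_records, report1.merged(report2)
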