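"""Readers and writers for the standard formats the pipeline touches.

Conventions fixed here and relied on everywhere downstream:

* all genomic/transcript coordinates are 0-based half-open internally;
  conversion to and from 1-based inclusive (GFF3) happens only at the
  I/O boundary;
* nucleotide sequences are uppercased on read and U is converted to T,
  so the pipeline works on a single DNA alphabet;
* bootstrap supports live on internal tree nodes as values in [0, 100];
  a node without a support annotation carries ``None`` (absent evidence
  is never coerced to zero).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "Alignment",
    "TreeNode",
    "GeneTree",
    "FeatureInterval",
    "CountTable",
    "HitTable",
    "read_fasta",
    "write_fasta",
    "read_newick",
    "write_newick",
    "read_annotation",
    "write_gff3",
    "read_count_table",
    "write_count_table",
    "read_hit_table",
    "write_hit_table",
]

_FASTA_WIDTH = 80

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """An identified nucleotide sequence.

    ``id`` is a whitespace-free token; ``residues`` is non-empty,
    uppercase DNA (U is normalised to T on construction).
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"sequence id must be a whitespace-free token: {self.id!r}")
        if not self.residues:
            raise ValueError(f"empty sequence for id {self.id!r}")
        normalised = self.residues.upper().replace("U", "T")
        object.__setattr__(self, "residues", normalised)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Alignment:
    """A multiple sequence alignment: >=2 rows of equal length.

    Rows may contain ``-`` gap characters; ungapping a row recovers the
    source sequence.
    """

    records: tuple[SequenceRecord, ...]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise ValueError("an alignment needs at least two rows")
        lengths = {len(r.residues) for r in self.records}
        if len(lengths) != 1:
            raise ValueError(f"alignment rows have unequal lengths: {sorted(lengths)}")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate row ids in alignment")

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.records)

    @property
    def n_columns(self) -> int:
        return len(self.records[0].residues)

    def row(self, row_id: str) -> str:
        for r in self.records:
            if r.id == row_id:
                return r.residues
        raise KeyError(f"no alignment row with id {row_id!r}")

    def ungapped(self, row_id: str) -> str:
        return self.row(row_id).replace("-", "")

    def take_columns(self, columns: Sequence[int]) -> "Alignment":
        cols = list(columns)
        new = tuple(
            replace(r, residues="".join(r.residues[c] for c in cols)) for r in self.records
        )
        return Alignment(new)


@dataclass
class TreeNode:
    """Node of a rooted gene tree.

    Tips carry ``tip_id`` and ``species``; internal nodes may carry a
    bootstrap ``support`` in [0, 100] (``None`` = not annotated).
    """

    children: list["TreeNode"] = field(default_factory=list)
    tip_id: str | None = None
    species: str | None = None
    support: float | None = None
    length: float | None = None

    @property
    def is_tip(self) -> bool:
        return not self.children

    def tips(self) -> Iterator["TreeNode"]:
        if self.is_tip:
            yield self
        else:
            for c in self.children:
                yield from c.tips()

    def walk(self) -> Iterator["TreeNode"]:
        yield self
        for c in self.children:
            yield from c.walk()

    def tip_ids(self) -> frozenset[str]:
        return frozenset(t.tip_id for t in self.tips())


@dataclass
class GeneTree:
    """A rooted gene tree with species-labelled tips.

    ``unrooted_source`` flags trees parsed from a basal polytomy
    (typically an unrooted newick) that still need outgroup rooting.
    """

    root: TreeNode
    unrooted_source: bool = False

    def __post_init__(self) -> None:
        ids = [t.tip_id for t in self.root.tips()]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate tip ids in tree")
        for node in self.root.walk():
            if node.support is not None and not (0 <= node.support <= 100):
                raise ValueError(f"support {node.support} outside [0, 100]")

    @property
    def tip_ids(self) -> frozenset[str]:
        return self.root.tip_ids()

    def tips(self) -> list[TreeNode]:
        return list(self.root.tips())

    def species_of(self, tip_id: str) -> str:
        for t in self.root.tips():
            if t.tip_id == tip_id:
                return t.species
        raise KeyError(f"no tip named {tip_id!r}")


@dataclass(frozen=True)
class FeatureInterval:
    """A stranded feature on a sequence, 0-based half-open."""

    seq_id: str
    start: int
    end: int
    strand: str = "."
    kind: str = "region"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval [{self.start}, {self.end}) on {self.seq_id}")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"bad strand {self.strand!r}")

    def overlaps(self, other: "FeatureInterval") -> bool:
        return self.seq_id == other.seq_id and self.start < other.end and other.start < self.end


@dataclass
class CountTable:
    """Transcripts x samples raw counts with a two-condition design.

    ``counts``: DataFrame indexed by transcript id, columns = sample ids,
    non-negative integers. ``condition`` maps each sample to "control" or
    "deficit". ``lengths`` maps each transcript to its effective length
    in nucleotides (> 0).
    """

    counts: pd.DataFrame
    condition: Mapping[str, str]
    lengths: Mapping[str, float]

    CONTROL = "control"
    DEFICIT = "deficit"

    def __post_init__(self) -> None:
        if (np.asarray(self.counts) < 0).any():
            raise ValueError("negative counts")
        missing = set(self.counts.columns) - set(self.condition)
        if missing:
            raise ValueError(f"samples without a condition label: {sorted(missing)}")
        labels = {self.condition[s] for s in self.counts.columns}
        if labels != {self.CONTROL, self.DEFICIT}:
            raise ValueError(f"need both conditions represented, got {sorted(labels)}")
        missing_len = set(self.counts.index) - set(self.lengths)
        if missing_len:
            raise ValueError(f"transcripts without a length: {sorted(missing_len)[:5]}")
        for t in self.counts.index:
            if self.lengths[t] <= 0:
                raise ValueError(f"non-positive length for {t}")

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.counts.columns if self.condition[s] == condition]

    @property
    def length_vector(self) -> pd.Series:
        return pd.Series({t: float(self.lengths[t]) for t in self.counts.index})


_HIT_COLUMNS = [
    "query_id",
    "subject_id",
    "identity",
    "coverage",
    "evalue",
    "subject_seq_id",
    "subject_start",
    "subject_end",
]


@dataclass
class HitTable:
    """Tabular similarity-search hits (query vs subject).

    Columns: query_id, subject_id, identity (percent, [0, 100]),
    coverage (fraction of query, [0, 1]), evalue (>= 0), subject_seq_id,
    subject_start/subject_end (0-based half-open on the subject sequence).
    """

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.rows
        missing = [c for c in _HIT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"hit table missing columns {missing}")
        if len(df):
            if ((df["identity"] < 0) | (df["identity"] > 100)).any():
                raise ValueError("identity outside [0, 100]")
            if ((df["coverage"] < 0) | (df["coverage"] > 1)).any():
                raise ValueError("coverage outside [0, 1]")
            if (df["evalue"] < 0).any():
                raise ValueError("negative e-value")

    @classmethod
    def empty(cls) -> "HitTable":
        return cls(pd.DataFrame(columns=_HIT_COLUMNS))

    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "HitTable":
        return cls(pd.DataFrame(list(records), columns=_HIT_COLUMNS))

    def for_query(self, query_id: str) -> pd.DataFrame:
        return self.rows[self.rows["query_id"] == query_id]

    def query_ids(self) -> set[str]:
        return set(self.rows["query_id"])


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path_or_handle) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords.

    Residues are uppercased and U->T normalised. Duplicate ids raise;
    an empty file returns an empty list with a warning.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(path_or_handle, "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        records.append(SequenceRecord(id=rec.id, residues=str(rec.seq), description=desc))
    if not records:
        warnings.warn(f"no sequences read from {path_or_handle}", stacklevel=2)
    return records


def write_fasta(records: Iterable[SequenceRecord], path_or_handle) -> None:
    """Write FASTA wrapped at 80 columns (round-trip stable)."""

    def _write(handle) -> None:
        for rec in records:
            header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            handle.write(header + "\n")
            for i in range(0, len(rec.residues), _FASTA_WIDTH):
                handle.write(rec.residues[i : i + _FASTA_WIDTH] + "\n")

    if hasattr(path_or_handle, "write"):
        _write(path_or_handle)
    else:
        with open(path_or_handle, "w") as fh:
            _write(fh)


def read_alignment(path_or_handle) -> Alignment:
    """Read an aligned FASTA (rows may contain '-')."""
    raw: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(path_or_handle, "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        raw.append(SequenceRecord(id=rec.id, residues=str(rec.seq)))
    return Alignment(tuple(raw))


# ---------------------------------------------------------------------------
# Newick


def _species_for_tip(tip_id: str, species_map: Mapping[str, str]) -> str | None:
    if tip_id in species_map:
        return species_map[tip_id]
    # longest-prefix rule
    best = None
    for key, sp in species_map.items():
        if tip_id.startswith(key) and (best is None or len(key) > len(best[0])):
            best = (key, sp)
    return best[1] if best else None


def _convert(dnode: dendropy.Node) -> TreeNode:
    node = TreeNode(length=dnode.edge.length)
    if dnode.is_leaf():
        node.tip_id = dnode.taxon.label if dnode.taxon else (dnode.label or "")
    else:
        label = dnode.label
        if label is not None:
            try:
                node.support = float(label)
            except ValueError:
                pass
        node.children = [_convert(c) for c in dnode.child_nodes()]
    return node


def read_newick(path_or_string, species_map: Mapping[str, str]) -> GeneTree:
    """Parse a newick tree; internal numeric labels become bootstrap supports.

    Every tip must resolve to a species through ``species_map`` (exact id
    match, else the longest map key that prefixes the tip id). A tree whose
    root is a polytomy is flagged ``unrooted_source`` for later rooting.
    """
    if isinstance(path_or_string, (str, Path)) and not str(path_or_string).lstrip().startswith("("):
        text = Path(path_or_string).read_text()
    else:
        text = str(path_or_string)
    dtree = dendropy.Tree.get(
        data=text,
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    root = _convert(dtree.seed_node)
    unmapped = []
    for tip in root.tips():
        sp = _species_for_tip(tip.tip_id, species_map)
        if sp is None:
            unmapped.append(tip.tip_id)
        tip.species = sp
    if unmapped:
        raise ValueError(f"tips absent from species map: {sorted(unmapped)}")
    return GeneTree(root=root, unrooted_source=len(root.children) > 2)


def _to_newick(node: TreeNode, with_lengths: bool = True) -> str:
    if node.is_tip:
        s = node.tip_id
    else:
        inner = ",".join(_to_newick(c, with_lengths) for c in node.children)
        label = "" if node.support is None else format(node.support, "g")
        s = f"({inner}){label}"
    if with_lengths and node.length is not None:
        s += f":{node.length:g}"
    return s


def write_newick(tree: GeneTree, path=None, with_lengths: bool = True) -> str:
    """Serialise to newick; returns the string (and writes if path given)."""
    text = _to_newick(tree.root, with_lengths) + ";"
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


# ---------------------------------------------------------------------------
# Annotations (GFF3 / BED)


def read_annotation(path_or_handle, dialect: str) -> list[FeatureInterval]:
    """Read GFF3 (1-based inclusive) or BED (0-based half-open) intervals.

    All output intervals are 0-based half-open. Rows that are invalid
    after conversion are dropped with a warning.
    """
    if dialect not in {"gff3", "bed"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    if hasattr(path_or_handle, "read"):
        text = path_or_handle.read()
    else:
        text = Path(path_or_handle).read_text()
    out: list[FeatureInterval] = []
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#") or (dialect == "bed" and line.startswith(("track", "browser"))):
            continue
        fields = line.split("\t")
        try:
            if dialect == "gff3":
                seq_id, _source, kind, start, end = fields[0], fields[1], fields[2], int(fields[3]), int(fields[4])
                strand = fields[6] if len(fields) > 6 and fields[6] in "+-" else "."
                start0, end0 = start - 1, end
            else:
                seq_id, start0, end0 = fields[0], int(fields[1]), int(fields[2])
                kind = fields[3] if len(fields) > 3 else "region"
                strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "."
            out.append(FeatureInterval(seq_id=seq_id, start=start0, end=end0, strand=strand, kind=kind))
        except (ValueError, IndexError) as exc:
            warnings.warn(f"dropping malformed {dialect} row {lineno}: {exc}", stacklevel=2)
    return out


def write_gff3(features: Iterable[FeatureInterval], path_or_handle) -> None:
    """Write intervals back out as GFF3 (converting to 1-based inclusive)."""
    lines = ["##gff-version 3"]
    for f in features:
        lines.append(
            "\t".join(
                [f.seq_id, "droughtleaf", f.kind, str(f.start + 1), str(f.end), ".", f.strand, ".", "."]
            )
        )
    text = "\n".join(lines) + "\n"
    if hasattr(path_or_handle, "write"):
        path_or_handle.write(text)
    else:
        Path(path_or_handle).write_text(text)


# ---------------------------------------------------------------------------
# Count tables and hit tables (TSV)


def read_count_table(counts_path, design_path, lengths_path) -> CountTable:
    """Read counts (TSV: first column transcript id, header = sample ids),
    a design TSV (sample, condition) and a lengths TSV (transcript, length)."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    design = pd.read_csv(design_path, sep="\t", index_col=0)
    lengths = pd.read_csv(lengths_path, sep="\t", index_col=0)
    return CountTable(
        counts=counts.astype(int),
        condition=design.iloc[:, 0].to_dict(),
        lengths=lengths.iloc[:, 0].to_dict(),
    )


def write_count_table(table: CountTable, counts_path, design_path, lengths_path) -> None:
    table.counts.to_csv(counts_path, sep="\t", index_label="transcript_id")
    pd.Series({s: table.condition[s] for s in table.counts.columns}, name="condition").to_csv(
        design_path, sep="\t", index_label="sample_id"
    )
    table.length_vector.rename("length").to_csv(lengths_path, sep="\t", index_label="transcript_id")


def read_hit_table(path) -> HitTable:
    df = pd.read_csv(path, sep="\t")
    return HitTable(df)


def write_hit_table(table: HitTable, path) -> None:
    table.rows.to_csv(path, sep="\t", index=False)
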