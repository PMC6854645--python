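"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator is a pure function of its :class:`SimulationParams`
(including the mandatory seed), and returns both the data and a
:class:`TruthBundle` recording what was planted:

* ``gen_redundant_transcriptome`` — a transcript set with planted exact
  duplicates and contained fragments, with the intended collapse
  partition;
* ``gen_count_experiment`` — a two-condition (control vs water-deficit)
  negative-binomial count matrix, three biological replicates per
  condition by default, with planted log2 fold changes and library
  sizes varying threefold across samples so an unnormalised test cannot
  pass silently;
* ``gen_gene_family`` — a gene family evolved down the fixed species
  tree (Arabidopsis,(Lactuca,(Helianthus,Parthenium))) with the
  duplication planted either before the guayule/sunflower split
  ("asteraceae") or on the guayule terminal branch ("lineage"), with
  optional planted ORF disruptions;
* ``gen_lncrna_panel`` — a lncRNA discovery panel with planted decoys
  (protein-coding fragments, TE/rRNA), genome-overlap traps, and
  optionally conserved miRNA binding sites.

The substitution process is per-site uniform with rejection of internal
stop codons inside coding spans — downstream stages test topology and
ORF logic, not substitution-model realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Literal, Mapping

import numpy as np
import pandas as pd

from .io_formats import (
    Alignment,
    CountTable,
    FeatureInterval,
    GeneTree,
    HitTable,
    SequenceRecord,
    read_newick,
    revcomp,
)
from .orf_integrity import STOP_CODONS, longest_orf

__all__ = [
    "SimulationParams",
    "TruthBundle",
    "FamilyTruth",
    "LncTruth",
    "GeneFamily",
    "LncRnaPanel",
    "gen_redundant_transcriptome",
    "gen_count_experiment",
    "gen_gene_family",
    "gen_lncrna_panel",
    "check_truth_consistency",
    "SPECIES_MAP",
    "MIR166",
]

_ALPHABET = np.array(list("ACGT"))

SPECIES_MAP = {
    "at": "Arabidopsis",
    "ls": "Lactuca",
    "ha": "Helianthus",
    "pa": "Parthenium",
}

#: miR166 mature sequence (DNA alphabet), the sponge analysis' flagship miRNA
MIR166 = "TCGGACCAGGCTTCATTCCCC"


@dataclass(frozen=True)
class SimulationParams:
    """Knobs for all generators. ``seed`` is mandatory; all counts and
    rates default to the study-like conditions described in the docs."""

    seed: int
    # redundant transcriptome
    n_base: int = 100
    dup_fraction: float = 0.2
    fragment_fraction: float = 0.2
    base_len_range: tuple[int, int] = (300, 3000)
    trim_len: int = 150
    # count experiment
    n_transcripts: int = 2000
    n_reps: int = 3
    n_de: int = 100
    lfc_mean: float = 2.0
    lfc_sd: float = 0.5
    nb_dispersion: float = 0.1
    libsize_range: tuple[float, float] = (1 / 3, 3.0)
    # gene family
    substitution_rate: float = 0.03
    cds_codons: int = 200
    utr_len: int = 30
    # lncRNA panel
    n_lnc: int = 20
    n_te: int = 10
    n_coding: int = 10
    n_overlap: int = 10
    n_sites: int = 8
    n_conserved_sunflower: int = 4
    n_conserved_both: int = 2
    n_annotated: int = 2
    n_site_disrupted: int = 2
    homolog_substitutions: int = 5
    lnc_len_range: tuple[int, int] = (300, 800)
    mirna_id: str = "miR166"
    mirna_seq: str = MIR166

    def __post_init__(self) -> None:
        for name in ("dup_fraction", "fragment_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.n_de > self.n_transcripts:
            raise ValueError("n_de cannot exceed n_transcripts")
        if not (19 <= len(self.mirna_seq) <= 24):
            raise ValueError("miRNA must be 19-24 nt")


@dataclass(frozen=True)
class FamilyTruth:
    event: str  # "asteraceae" or "lineage"
    pseudogenized: frozenset[str]
    true_tree_newick: str
    cds_span: tuple[int, int]  # ungapped coordinates, identical for all members


@dataclass(frozen=True)
class LncTruth:
    class_label: str  # "lncrna", "te_decoy", "coding_decoy", "overlap_decoy"
    site: tuple[int, int] | None = None
    conserved: bool = False
    conservation_class: str = "species_only"  # "species_only"/"sunflower"/"sunflower_lettuce"
    annotated_sunflower: bool = False
    annotated_lettuce: bool = False


@dataclass
class TruthBundle:
    """Ground truth for one generated dataset; every emitted id appears
    in exactly one entry."""

    redundancy: dict[str, set[str]] | None = None
    de_lfc: dict[str, float] | None = None
    family: FamilyTruth | None = None
    lncrna: dict[str, LncTruth] | None = None

    def all_ids(self) -> set[str]:
        ids: set[str] = set()
        if self.redundancy is not None:
            for base, derived in self.redundancy.items():
                ids.add(base)
                ids |= derived
        if self.de_lfc is not None:
            ids |= set(self.de_lfc)
        if self.lncrna is not None:
            ids |= set(self.lncrna)
        return ids


def check_truth_consistency(bundle: TruthBundle, emitted_ids: Iterable[str]) -> None:
    """Assert every emitted id is covered by exactly one truth entry."""
    emitted = set(emitted_ids)
    covered = bundle.all_ids()
    if bundle.redundancy is not None:
        seen: set[str] = set()
        for base, derived in bundle.redundancy.items():
            block = {base} | derived
            if block & seen:
                raise AssertionError(f"ids in multiple truth clusters: {sorted(block & seen)}")
            seen |= block
    missing = emitted - covered
    extra = covered - emitted
    if missing or extra:
        raise AssertionError(f"truth mismatch; missing={sorted(missing)[:5]} extra={sorted(extra)[:5]}")


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_ALPHABET, size=length))


# ---------------------------------------------------------------------------
# Redundant transcriptome


def gen_redundant_transcriptome(params: SimulationParams) -> tuple[list[SequenceRecord], TruthBundle]:
    """Base transcripts plus planted exact duplicates and contained fragments.

    Fragments are either a base minus at most ``trim_len`` nucleotides
    from one end, or an internal substring of length > ``trim_len``;
    both are recoverable by the collapse pipeline, and the truth records
    the intended partition (base id -> derived ids).
    """
    if params.n_base < 1:
        raise ValueError("n_base must be >= 1")
    rng = np.random.default_rng(params.seed)
    lo, hi = params.base_len_range
    bases: list[SequenceRecord] = []
    for i in range(params.n_base):
        length = int(rng.integers(lo, hi + 1))
        bases.append(SequenceRecord(id=f"base{i:04d}", residues=_random_dna(rng, length)))

    n_dup = round(params.n_base * params.dup_fraction)
    n_frag = round(params.n_base * params.fragment_fraction)
    dup_sources = rng.choice(params.n_base, size=n_dup, replace=False) if n_dup else np.array([], int)
    frag_sources = rng.choice(params.n_base, size=n_frag, replace=False) if n_frag else np.array([], int)

    partition: dict[str, set[str]] = {b.id: set() for b in bases}
    derived: list[SequenceRecord] = []

    for j, src in enumerate(dup_sources):
        rid = f"dup{j:04d}"
        derived.append(SequenceRecord(id=rid, residues=bases[src].residues))
        partition[bases[src].id].add(rid)

    min_frag = params.trim_len + 1
    for j, src in enumerate(frag_sources):
        seq = bases[src].residues
        L = len(seq)
        for _attempt in range(100):
            if rng.random() < 0.5:
                # end-trim fragment: remove 1..trim_len nt from one end
                k = int(rng.integers(1, params.trim_len + 1))
                frag = seq[k:] if rng.random() < 0.5 else seq[:-k]
            else:
                # internal substring, strictly inside, length >= trim_len + 1
                if L < min_frag + 2:
                    continue
                flen = int(rng.integers(min_frag, L - 1))
                start = int(rng.integers(1, L - flen))
                frag = seq[start : start + flen]
            if len(frag) >= min_frag:
                break
        else:  # pragma: no cover - lengths >= 300 always admit a fragment
            raise RuntimeError("could not draw a collapsible fragment")
        rid = f"frag{j:04d}"
        derived.append(SequenceRecord(id=rid, residues=frag))
        partition[bases[src].id].add(rid)

    records = bases + derived
    return records, TruthBundle(redundancy=partition)


# ---------------------------------------------------------------------------
# Count experiment


def gen_count_experiment(params: SimulationParams) -> tuple[CountTable, TruthBundle]:
    """Two-condition NB count matrix with planted differential expression.

    Baseline means are log-uniform on [1, 1e4]; sample library-size
    factors are log-uniform on ``libsize_range``; planted DE transcripts
    shift the deficit-condition mean by the planted log2 fold change
    (random sign, magnitude ~ N(lfc_mean, lfc_sd) truncated at 0.5).
    """
    rng = np.random.default_rng(params.seed)
    n, reps = params.n_transcripts, params.n_reps
    ids = [f"t{i:05d}" for i in range(n)]
    base_mean = np.exp(rng.uniform(np.log(1.0), np.log(1e4), size=n))
    lengths = rng.integers(300, 3001, size=n)

    lfc = np.zeros(n)
    if params.n_de:
        de_idx = rng.choice(n, size=params.n_de, replace=False)
        signs = rng.choice([-1.0, 1.0], size=params.n_de)
        mags = np.maximum(rng.normal(params.lfc_mean, params.lfc_sd, size=params.n_de), 0.5)
        lfc[de_idx] = signs * mags

    samples = [f"control_{r+1}" for r in range(reps)] + [f"deficit_{r+1}" for r in range(reps)]
    condition = {s: ("control" if s.startswith("control") else "deficit") for s in samples}
    lo, hi = params.libsize_range
    libsize = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(samples)))

    disp = params.nb_dispersion
    counts = np.empty((n, len(samples)), dtype=np.int64)
    for j, s in enumerate(samples):
        mu = base_mean * libsize[j]
        if condition[s] == "deficit":
            mu = mu * np.exp2(lfc)
        nb_n = 1.0 / disp
        p = nb_n / (nb_n + mu)
        counts[:, j] = rng.negative_binomial(nb_n, p)

    table = CountTable(
        counts=pd.DataFrame(counts, index=ids, columns=samples),
        condition=condition,
        lengths=dict(zip(ids, lengths.astype(float))),
    )
    truth = TruthBundle(de_lfc={ids[i]: float(lfc[i]) for i in range(n)})
    return table, truth


# ---------------------------------------------------------------------------
# Gene families


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + (n_codons - 2) non-stop codons + stop."""
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = _random_dna(rng, 3)
        if c not in STOP_CODONS:
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def _random_utr(rng: np.random.Generator, length: int) -> str:
    """UTR without any ATG (so the reference's longest ORF is the CDS)."""
    while True:
        u = _random_dna(rng, length)
        if "ATG" not in u:
            return u


def _evolve(
    seq: str,
    rng: np.random.Generator,
    rate: float,
    cds_span: tuple[int, int],
) -> str:
    """Per-site uniform substitution; mutations creating an internal stop
    in the CDS frame, touching the start/stop codons, or creating an ATG
    in the 5' UTR, are rejected (redrawn elsewhere)."""
    chars = list(seq)
    cds_start, cds_end = cds_span
    n_mut = rng.binomial(len(chars), rate)
    positions = rng.choice(len(chars), size=n_mut, replace=False) if n_mut else []
    for pos in positions:
        pos = int(pos)
        if cds_start <= pos < cds_start + 3 or cds_end - 3 <= pos < cds_end:
            continue  # protect start and terminal stop
        old = chars[pos]
        choices = [b for b in "ACGT" if b != old]
        rng.shuffle(choices)
        for new in choices:
            chars[pos] = new
            if cds_start <= pos < cds_end:
                codon_start = cds_start + ((pos - cds_start) // 3) * 3
                codon = "".join(chars[codon_start : codon_start + 3])
                if codon in STOP_CODONS:
                    chars[pos] = old
                    continue
            elif pos < cds_start:
                window = "".join(chars[max(0, pos - 2) : min(cds_start, pos + 3)])
                if "ATG" in window:
                    chars[pos] = old
                    continue
            break
        else:
            chars[pos] = old
    return "".join(chars)


@dataclass
class GeneFamily:
    """One simulated paralog family ready for the downstream stages."""

    sequences: list[SequenceRecord]  # unaligned (gaps removed)
    alignment: Alignment  # columnwise true alignment (indel-free except planted deletion)
    tree: GeneTree  # true gene tree, supports all 100
    truth: TruthBundle
    species_map: Mapping[str, str] = field(default_factory=lambda: dict(SPECIES_MAP))

    @property
    def query_tips(self) -> list[str]:
        return [r.id for r in self.sequences if r.id.startswith("pa")]


def gen_gene_family(
    event_type: Literal["asteraceae", "lineage"],
    params: SimulationParams,
    pseudogenize: Literal[None, "premature_stop", "frameshift"] = None,
) -> GeneFamily:
    """Evolve a coding gene family with a planted duplication event.

    ``asteraceae`` plants the duplication before the guayule/sunflower
    split: two sunflower and two guayule copies, each guayule copy
    sister to a sunflower copy. ``lineage`` plants it on the guayule
    terminal branch: the two guayule copies are mutual sisters.
    ``pseudogenize`` optionally disrupts the first guayule copy with a
    premature stop codon or a 1-nt deletion.
    """
    if event_type not in ("asteraceae", "lineage"):
        raise ValueError(f"unknown event type {event_type!r}")
    rng = np.random.default_rng(params.seed)
    utr = params.utr_len
    cds_len = params.cds_codons * 3
    cds_span = (utr, utr + cds_len)
    root_seq = _random_utr(rng, utr) + _random_cds(rng, params.cds_codons) + _random_dna(rng, utr)
    rate = params.substitution_rate

    def ev(seq: str) -> str:
        return _evolve(seq, rng, rate, cds_span)

    at = ev(root_seq)
    ast = ev(root_seq)
    ls = ev(ast)
    hp = ev(ast)
    seqs: dict[str, str] = {"at1": at, "ls1": ls}
    if event_type == "asteraceae":
        copy_a = ev(hp)
        copy_b = ev(hp)
        seqs["ha1"] = ev(copy_a)
        seqs["pa1"] = ev(copy_a)
        seqs["ha2"] = ev(copy_b)
        seqs["pa2"] = ev(copy_b)
        newick = "(at1,(ls1,((ha1,pa1)100,(ha2,pa2)100)100)100)100;"
    else:
        seqs["ha1"] = ev(hp)
        par = ev(hp)
        seqs["pa1"] = ev(par)
        seqs["pa2"] = ev(par)
        newick = "(at1,(ls1,(ha1,(pa1,pa2)100)100)100)100;"

    pseudogenized: set[str] = set()
    rows: dict[str, str] = dict(seqs)
    if pseudogenize is not None:
        victim = "pa1"
        pseudogenized.add(victim)
        # plant the lesion in the middle of the CDS, inside the 90% window
        codon_idx = params.cds_codons // 2
        pos = utr + codon_idx * 3
        s = rows[victim]
        if pseudogenize == "premature_stop":
            rows[victim] = s[:pos] + "TAA" + s[pos + 3 :]
        elif pseudogenize == "frameshift":
            rows[victim] = s[:pos] + "-" + s[pos + 1 :]
        else:
            raise ValueError(f"unknown pseudogenization mode {pseudogenize!r}")

    order = ["at1", "ls1"] + sorted(k for k in rows if k not in ("at1", "ls1"))
    alignment = Alignment(tuple(SequenceRecord(id=k, residues=rows[k]) for k in order))
    sequences = [SequenceRecord(id=k, residues=rows[k].replace("-", "")) for k in order]
    tree = read_newick(newick, SPECIES_MAP)
    truth = TruthBundle(
        family=FamilyTruth(
            event=event_type,
            pseudogenized=frozenset(pseudogenized),
            true_tree_newick=newick,
            cds_span=cds_span,
        )
    )
    return GeneFamily(sequences=sequences, alignment=alignment, tree=tree, truth=truth)


# ---------------------------------------------------------------------------
# lncRNA panel


@dataclass
class LncRnaPanel:
    """Everything the lncRNA cascade and sponge analysis consume."""

    guayule: list[SequenceRecord]
    sunflower: list[SequenceRecord]
    lettuce: list[SequenceRecord]
    protein_hits: HitTable
    decoy_hits: HitTable
    sunflower_hits: HitTable
    lettuce_hits: HitTable
    sunflower_annotation: list[FeatureInterval]  # protein-coding genes
    sunflower_lnc_annotation: list[FeatureInterval]
    lettuce_lnc_annotation: list[FeatureInterval]
    truth: TruthBundle
    mirna_id: str = "miR166"
    mirna_seq: str = MIR166

    def homolog_alignment(self, guayule_id: str) -> Alignment | None:
        """MSA of a guayule lncRNA with its (equal-length) homologs."""
        rows = [r for r in self.guayule if r.id == guayule_id]
        rows += [r for r in self.sunflower if r.id == f"ha_{guayule_id}"]
        rows += [r for r in self.lettuce if r.id == f"ls_{guayule_id}"]
        if len(rows) < 2:
            return None
        return Alignment(tuple(rows))


def _lnc_like(rng: np.random.Generator, params: SimulationParams, max_orf_codons: int = 100) -> str:
    lo, hi = params.lnc_len_range
    for _ in range(200):
        seq = _random_dna(rng, int(rng.integers(max(lo, 200), hi + 1)))
        orf = longest_orf(seq, min_codons=1)
        if orf is None or (orf[1] - orf[0]) // 3 <= max_orf_codons:
            return seq
    raise RuntimeError("could not draw a lncRNA-like sequence")  # pragma: no cover


def _mutate_positions(seq: str, rng: np.random.Generator, positions: Iterable[int]) -> str:
    chars = list(seq)
    for pos in positions:
        chars[pos] = rng.choice([b for b in "ACGT" if b != chars[pos]])
    return "".join(chars)


def gen_lncrna_panel(params: SimulationParams) -> LncRnaPanel:
    """The four planted classes plus homologs, hit tables and annotations.

    Classes (with truth labels): true lncRNAs, TE/rRNA decoys,
    protein-coding decoys, and lncRNA-like transcripts whose sunflower
    best hit overlaps an annotated protein-coding gene. A subset of true
    lncRNAs carries a planted perfect reverse-complement miRNA site,
    replicated exactly in the sunflower/lettuce homologs when conserved.
    """
    rng = np.random.default_rng(params.seed)
    mirna = params.mirna_seq.upper().replace("U", "T")
    site_seq = revcomp(mirna)
    L = len(mirna)

    if params.n_sites > params.n_lnc:
        raise ValueError("n_sites cannot exceed n_lnc")
    n_cons = params.n_conserved_sunflower + params.n_conserved_both
    if n_cons > params.n_lnc:
        raise ValueError("conserved count cannot exceed n_lnc")

    truth: dict[str, LncTruth] = {}
    guayule: list[SequenceRecord] = []
    sunflower: list[SequenceRecord] = []
    lettuce: list[SequenceRecord] = []
    protein_rows: list[tuple] = []
    decoy_rows: list[tuple] = []
    sun_rows: list[tuple] = []
    let_rows: list[tuple] = []
    gene_annot: list[FeatureInterval] = []
    sun_lnc_annot: list[FeatureInterval] = []
    let_lnc_annot: list[FeatureInterval] = []

    # --- true lncRNAs -----------------------------------------------------
    # conservation classes assigned to the first ids: sunflower+lettuce
    # first, then sunflower-only, then species-only; planted sites go to
    # the first n_sites ids so that conserved and site-bearing overlap.
    sun_cursor = 0  # running coordinate on the virtual sunflower chromosome
    let_cursor = 0
    GAP = 1000  # spacing between loci keeps best-hit intervals disjoint

    for i in range(params.n_lnc):
        gid = f"lnc{i:03d}"
        seq = _lnc_like(rng, params)
        has_site = i < params.n_sites
        site: tuple[int, int] | None = None
        if has_site:
            start = int(rng.integers(50, len(seq) - L - 50))
            seq = seq[:start] + site_seq + seq[start + L :]
            orf = longest_orf(seq, min_codons=1)
            if orf is not None and (orf[1] - orf[0]) // 3 > 100:  # pragma: no cover
                seq = _lnc_like(rng, params)
                start = int(rng.integers(50, len(seq) - L - 50))
                seq = seq[:start] + site_seq + seq[start + L :]
            site = (start, start + L)

        if i < params.n_conserved_both:
            cons_class = "sunflower_lettuce"
        elif i < n_cons:
            cons_class = "sunflower"
        else:
            cons_class = "species_only"
        # the last n_site_disrupted homolog-bearing, site-bearing lncRNAs get
        # a substitution inside the site in the sunflower homolog: a planted
        # NON-conserved site (homolog present, conservation broken)
        disrupt_site = (
            has_site
            and cons_class != "species_only"
            and i >= n_cons - params.n_site_disrupted
        )
        conserved_site = has_site and cons_class != "species_only" and not disrupt_site

        guayule.append(SequenceRecord(id=gid, residues=seq))

        if cons_class != "species_only":
            protected = set(range(site[0], site[1])) if site else set()
            free = [p for p in range(len(seq)) if p not in protected]
            homolog = _mutate_positions(
                seq, rng, rng.choice(free, size=min(params.homolog_substitutions, len(free)), replace=False)
            )
            if disrupt_site:
                homolog = _mutate_positions(homolog, rng, [int(rng.integers(site[0], site[1]))])
            sunflower.append(SequenceRecord(id=f"ha_{gid}", residues=homolog))
            locus = (sun_cursor, sun_cursor + len(seq))
            sun_cursor = locus[1] + GAP
            sun_rows.append((gid, f"ha_{gid}", 98.0, 1.0, 1e-30, "Hann_chr1", locus[0], locus[1]))
            if i < params.n_annotated:
                sun_lnc_annot.append(
                    FeatureInterval("Hann_chr1", locus[0], locus[1], "+", "lnc_RNA")
                )
            if cons_class == "sunflower_lettuce":
                free2 = [p for p in range(len(seq)) if p not in protected]
                homolog2 = _mutate_positions(
                    seq, rng, rng.choice(free2, size=min(params.homolog_substitutions, len(free2)), replace=False)
                )
                lettuce.append(SequenceRecord(id=f"ls_{gid}", residues=homolog2))
                llocus = (let_cursor, let_cursor + len(seq))
                let_cursor = llocus[1] + GAP
                let_rows.append((gid, f"ls_{gid}", 97.0, 1.0, 1e-28, "Lsat_chr1", llocus[0], llocus[1]))
                if i < min(params.n_annotated, 1):
                    let_lnc_annot.append(
                        FeatureInterval("Lsat_chr1", llocus[0], llocus[1], "+", "lnc_RNA")
                    )

        truth[gid] = LncTruth(
            class_label="lncrna",
            site=site,
            conserved=conserved_site,
            conservation_class=cons_class,
            annotated_sunflower=cons_class != "species_only" and i < params.n_annotated,
            annotated_lettuce=cons_class == "sunflower_lettuce" and i < min(params.n_annotated, 1),
        )

    # --- TE / housekeeping decoys ----------------------------------------
    for i in range(params.n_te):
        gid = f"te{i:03d}"
        seq = _random_dna(rng, int(rng.integers(250, 700)))
        guayule.append(SequenceRecord(id=gid, residues=seq))
        decoy_rows.append((gid, f"TE_family_{i % 3}", 95.0, 0.9, 1e-30, f"TE_family_{i % 3}", 0, len(seq)))
        truth[gid] = LncTruth(class_label="te_decoy")

    # --- protein-coding decoys --------------------------------------------
    for i in range(params.n_coding):
        gid = f"cod{i:03d}"
        seq = _random_dna(rng, int(rng.integers(250, 700)))
        guayule.append(SequenceRecord(id=gid, residues=seq))
        protein_rows.append((gid, f"AT_protein_{i}", 80.0, 0.8, 1e-10, f"AT_protein_{i}", 0, len(seq) // 3))
        truth[gid] = LncTruth(class_label="coding_decoy")

    # --- genome-overlap decoys --------------------------------------------
    for i in range(params.n_overlap):
        gid = f"ovl{i:03d}"
        seq = _lnc_like(rng, params)
        guayule.append(SequenceRecord(id=gid, residues=seq))
        locus = (sun_cursor, sun_cursor + len(seq))
        sun_cursor = locus[1] + GAP
        sun_rows.append((gid, f"ha_gene_{i}", 90.0, 0.9, 1e-25, "Hann_chr1", locus[0], locus[1]))
        # an annotated protein-coding gene straddling the hit interval
        gene_annot.append(FeatureInterval("Hann_chr1", max(0, locus[0] - 50), locus[1] + 50, "+", "gene"))
        truth[gid] = LncTruth(class_label="overlap_decoy")

    panel = LncRnaPanel(
        guayule=guayule,
        sunflower=sunflower,
        lettuce=lettuce,
        protein_hits=HitTable.from_records(protein_rows),
        decoy_hits=HitTable.from_records(decoy_rows),
        sunflower_hits=HitTable.from_records(sun_rows),
        lettuce_hits=HitTable.from_records(let_rows),
        sunflower_annotation=gene_annot,
        sunflower_lnc_annotation=sun_lnc_annot,
        lettuce_lnc_annotation=let_lnc_annot,
        truth=TruthBundle(lncrna=truth),
        mirna_id=params.mirna_id,
        mirna_seq=mirna,
    )
    return panel
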