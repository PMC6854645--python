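"""End-to-end orchestration and parameter handling.

``AnalysisParams`` gathers every threshold the pipeline uses, with
defaults matching the study conditions the package emulates (0.5 TPM
expression floor, adjusted-p 0.01, 150-nt end trim, 50% cluster
identity, bootstrap 70, the three e-value tiers, 200-nt/100-codon
lncRNA rule, expectation cutoff 5). Parameters are serialised verbatim
into every results directory so a run can be reproduced from its
outputs alone.

``run_all`` executes the demo pipeline on a fully synthetic bundle:
collapse -> differential expression -> per-family admissibility /
duplication timing / ORF integrity -> lncRNA cascade -> sponge scan.
Given a seed it is deterministic down to the byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Iterable

import yaml

from . import __version__
from .cluster_alignment import assess_cluster, trim_to_cds
from .duplication_timing import classify_duplication, root_on_outgroup
from .expression_stats import DEStatus, nb_de_test
from .io_formats import write_fasta, write_gff3, write_hit_table
from .lncrna_discovery import RemovalStage, run_cascade
from .mirna_motif import sponge_report
from .orf_integrity import assess_orf_in_cluster, cluster_pseudogenization
from .synthetic_data import (
    SimulationParams,
    gen_count_experiment,
    gen_gene_family,
    gen_lncrna_panel,
    gen_redundant_transcriptome,
)
from .transcript_collapse import collapse_pipeline

__all__ = ["AnalysisParams", "run_all"]


@dataclass(frozen=True)
class AnalysisParams:
    seed: int = 0
    tpm_min: float = 0.5
    alpha: float = 0.01
    trim_len: int = 150
    identity_min: float = 0.5
    support_min: float = 70.0
    evalue_protein: float = 1e-3
    evalue_decoy: float = 1e-10
    evalue_genome: float = 1e-20
    lnc_min_len: int = 200
    orf_max_codons: int = 100
    mirna_cutoff: float = 5.0
    premature_stop_frac: float = 0.9

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.tpm_min < 0:
            raise ValueError("tpm_min must be non-negative")
        if not (0 <= self.identity_min <= 1):
            raise ValueError("identity_min must lie in [0, 1]")
        if not (0 <= self.support_min <= 100):
            raise ValueError("support_min must lie in [0, 100]")
        for name in ("evalue_protein", "evalue_decoy", "evalue_genome"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.premature_stop_frac <= 1):
            raise ValueError("premature_stop_frac must lie in (0, 1]")
        if self.trim_len <= 0 or self.lnc_min_len <= 0 or self.orf_max_codons <= 0:
            raise ValueError("length parameters must be positive")
        if self.mirna_cutoff < 0:
            raise ValueError("mirna_cutoff must be non-negative")

    def params_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def to_yaml(self, path: Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "AnalysisParams":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    @classmethod
    def from_config(cls, config_path=None, **overrides) -> "AnalysisParams":
        """Config file first, CLI-style overrides on top."""
        base = cls.from_yaml(config_path) if config_path else cls()
        clean = {k: v for k, v in overrides.items() if v is not None}
        return replace(base, **clean) if clean else base


def _header(params: AnalysisParams) -> str:
    return (
        f"# droughtleaf v{__version__} | seed={params.seed} "
        f"| params_hash={params.params_hash()}\n"
    )


def _write_tsv(path: Path, params: AnalysisParams, header_cols: list[str], rows: Iterable[Iterable]) -> None:
    with open(path, "w") as fh:
        fh.write(_header(params))
        fh.write("\t".join(header_cols) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def run_all(params: AnalysisParams, out_dir) -> dict:
    """Run the full demo pipeline on synthetic inputs; returns the log.

    Every stage consumes synthetic data with known truth, generated from
    ``params.seed``. Outputs (TSVs with a version/seed/params-hash
    header, FASTA, params.yaml, log.json) land in ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params.to_yaml(out / "params.yaml")
    sim = SimulationParams(seed=params.seed)
    log: dict = {"version": __version__, "seed": params.seed, "params_hash": params.params_hash(), "stages": {}}

    # --- stage 1: redundancy collapse -------------------------------------
    records, red_truth = gen_redundant_transcriptome(sim)
    collapsed, report = collapse_pipeline(records, trim_len=params.trim_len)
    write_fasta(collapsed, out / "collapsed.fasta")
    rows = [
        (retained, member, report.stage[member])
        for retained in sorted(report.partition)
        for member in sorted(report.partition[retained])
    ]
    _write_tsv(out / "collapse_report.tsv", params, ["retained_id", "collapsed_id", "stage"], rows)
    log["stages"]["collapse"] = {"in": report.n_before, "out": report.n_after}

    # --- stage 2: differential expression ---------------------------------
    table, de_truth = gen_count_experiment(sim)
    de_results = nb_de_test(table, alpha=params.alpha, tpm_min=params.tpm_min)
    _write_tsv(
        out / "de_results.tsv",
        params,
        ["transcript_id", "base_mean", "log2fc", "se", "pvalue", "padj", "status"],
        [
            (
                r.transcript_id,
                f"{r.base_mean:.4f}",
                "NA" if r.log2_fold_change is None else f"{r.log2_fold_change:.4f}",
                "NA" if r.se is None else f"{r.se:.4f}",
                "NA" if r.pvalue is None else f"{r.pvalue:.3e}",
                "NA" if r.padj is None else f"{r.padj:.3e}",
                r.status.value,
            )
            for r in de_results
        ],
    )
    n_up = sum(r.status is DEStatus.UP for r in de_results)
    n_down = sum(r.status is DEStatus.DOWN for r in de_results)
    log["stages"]["de"] = {"in": len(de_results), "up": n_up, "down": n_down}

    # --- stage 3: per-family duplication timing + ORF integrity -----------
    family_rows = []
    for k, event in enumerate(["asteraceae", "lineage"]):
        for pseudo in (None, "premature_stop"):
            fam = gen_gene_family(event, replace(sim, seed=sim.seed + k * 2 + (pseudo is not None)), pseudogenize=pseudo)
            adm = assess_cluster(fam.alignment, fam.query_tips, min_identity=params.identity_min)
            trimmed = trim_to_cds(fam.alignment, "at1")
            assessments = [
                assess_orf_in_cluster(trimmed, q, "at1", premature_stop_frac=params.premature_stop_frac)
                for q in fam.query_tips
            ]
            pseudo_call = cluster_pseudogenization(assessments)
            rooted = root_on_outgroup(fam.tree)
            call = classify_duplication(rooted, fam.query_tips, support_min=params.support_min)
            family_rows.append(
                (
                    f"{event}{'_pseudo' if pseudo else ''}",
                    adm.verdict.value,
                    call.cluster_class.value,
                    pseudo_call.value,
                    fam.truth.family.event,
                    ";".join(sorted(fam.truth.family.pseudogenized)) or "none",
                )
            )
    _write_tsv(
        out / "duplication_calls.tsv",
        params,
        ["cluster_id", "admissibility", "timing_call", "pseudogenization", "true_event", "true_pseudogenized"],
        family_rows,
    )
    log["stages"]["families"] = {"n": len(family_rows)}

    # --- stage 4: lncRNA cascade + sponges ---------------------------------
    panel = gen_lncrna_panel(sim)
    write_fasta(panel.guayule, out / "lncrna_candidates.fasta")
    write_gff3(panel.sunflower_annotation, out / "sunflower_genes.gff3")
    write_hit_table(panel.sunflower_hits, out / "sunflower_hits.tsv")
    trails = run_cascade(
        panel.guayule,
        panel.protein_hits,
        panel.decoy_hits,
        panel.sunflower_hits,
        panel.lettuce_hits,
        panel.sunflower_annotation,
        panel.sunflower_lnc_annotation,
        panel.lettuce_lnc_annotation,
        evalue_protein=params.evalue_protein,
        evalue_decoy=params.evalue_decoy,
        evalue_genome=params.evalue_genome,
        min_len=params.lnc_min_len,
        max_orf_codons=params.orf_max_codons,
    )
    _write_tsv(
        out / "lncrna_trails.tsv",
        params,
        ["transcript_id", "removed_at", "conservation", "annotated_sunflower", "annotated_lettuce"],
        [
            (
                t.transcript_id,
                t.removed_at.value,
                t.conservation.value if t.conservation else "NA",
                t.annotated_lncrna_sunflower,
                t.annotated_lncrna_lettuce,
            )
            for t in sorted(trails.values(), key=lambda x: x.transcript_id)
        ],
    )
    survivors_ids = sorted(t.transcript_id for t in trails.values() if t.removed_at is RemovalStage.SURVIVOR)
    survivors = [r for r in panel.guayule if r.id in survivors_ids]
    alignments = {
        r.id: aln for r in survivors if (aln := panel.homolog_alignment(r.id)) is not None
    }
    sponges = sponge_report(
        survivors,
        {panel.mirna_id: panel.mirna_seq},
        alignments,
        cutoff=params.mirna_cutoff,
    )
    _write_tsv(
        out / "sponges.tsv",
        params,
        list(sponges.columns),
        [tuple(row) for row in sponges.itertuples(index=False)],
    )
    log["stages"]["lncrna"] = {
        "in": len(panel.guayule),
        "survivors": len(survivors_ids),
        "conserved_sponges": int(sponges["lncrna_id"].nunique()) if len(sponges) else 0,
    }

    (out / "log.json").write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    return log
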