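import numpy as np
import pytest

from droughtleaf.io_formats import write_fasta
from droughtleaf.orf_integrity import STOP_CODONS, find_orfs
from droughtleaf.synthetic_data import (
    SimulationParams,
    check_truth_consistency,
    gen_count_experiment,
    gen_gene_family,
    gen_lncrna_panel,
    gen_redundant_transcriptome,
)


class TestParams:
    def test_fraction_bounds_enforced(self):
        with pytest.raises(ValueError):
            SimulationParams(seed=1, dup_fraction=1.5)

    def test_dispersion_must_be_positive(self):
        with pytest.raises(ValueError):
            SimulationParams(seed=1, nb_dispersion=0)

    def test_nde_bounded_by_transcripts(self):
        with pytest.raises(ValueError):
            SimulationParams(seed=1, n_transcripts=10, n_de=11)


class TestRedundantTranscriptome:
    def test_single_base_full_duplication(self):
        recs, truth = gen_redundant_transcriptome(
            SimulationParams(seed=1, n_base=1, dup_fraction=1.0, fragment_fraction=0.0)
        )
        assert len(recs) == 2
        assert len(truth.redundancy) == 1

    def test_counts_by_construction(self):
        recs, truth = gen_redundant_transcriptome(SimulationParams(seed=7))
        assert len(recs) == 140  # 100 bases + 20 dups + 20 fragments
        assert len(truth.redundancy) == 100

    def test_determinism(self, tmp_path):
        p = SimulationParams(seed=7)
        r1, _ = gen_redundant_transcriptome(p)
        r2, _ = gen_redundant_transcriptome(p)
        f1, f2 = tmp_path / "a.fa", tmp_path / "b.fa"
        write_fasta(r1, f1)
        write_fasta(r2, f2)
        assert f1.read_bytes() == f2.read_bytes()

    def test_truth_covers_every_id(self):
        recs, truth = gen_redundant_transcriptome(SimulationParams(seed=9))
        check_truth_consistency(truth, [r.id for r in recs])

    def test_fragments_are_long_enough_to_collapse(self):
        recs, _ = gen_redundant_transcriptome(SimulationParams(seed=5, n_base=50))
        for r in recs:
            if r.id.startswith("frag"):
                assert len(r.residues) >= 151


class TestCountExperiment:
    def test_null_table_has_no_planted_lfc(self):
        _, truth = gen_count_experiment(SimulationParams(seed=2, n_transcripts=100, n_de=0))
        assert all(v == 0 for v in truth.de_lfc.values())

    def test_determinism(self):
        p = SimulationParams(seed=4, n_transcripts=100)
        t1, _ = gen_count_experiment(p)
        t2, _ = gen_count_experiment(p)
        assert t1.counts.equals(t2.counts)

    def test_planted_ratio_converges_at_many_replicates(self):
        # law of large numbers: mean ratio deficit/control -> 2^lfc
        p = SimulationParams(
            seed=8, n_transcripts=50, n_de=50, n_reps=200, lfc_mean=2.0, lfc_sd=0.0
        )
        table, truth = gen_count_experiment(p)
        control = table.samples_of("control")
        deficit = table.samples_of("deficit")
        ratios = []
        for t, lfc in truth.de_lfc.items():
            mc = table.counts.loc[t, control].mean()
            md = table.counts.loc[t, deficit].mean()
            if lfc > 0 and mc > 20:
                ratios.append(md / mc)
        assert np.median(ratios) == pytest.approx(4.0, rel=0.15)

    def test_both_conditions_present(self):
        table, _ = gen_count_experiment(SimulationParams(seed=3, n_transcripts=50, n_de=5))
        assert len(table.samples_of("control")) == 3
        assert len(table.samples_of("deficit")) == 3


class TestGeneFamily:
    def test_unknown_event_rejected(self):
        with pytest.raises(ValueError):
            gen_gene_family("neither", SimulationParams(seed=1))

    @pytest.mark.parametrize("event", ["asteraceae", "lineage"])
    def test_intact_members_translate_cleanly(self, event):
        fam = gen_gene_family(event, SimulationParams(seed=17))
        start, end = fam.truth.family.cds_span
        for rec in fam.sequences:
            cds = rec.residues[start:end]
            assert cds.startswith("ATG") and cds[-3:] in STOP_CODONS
            internal = [cds[i : i + 3] for i in range(3, len(cds) - 3, 3)]
            assert not any(c in STOP_CODONS for c in internal)

    def test_asteraceae_copy_counts(self):
        fam = gen_gene_family("asteraceae", SimulationParams(seed=23))
        ids = {r.id for r in fam.sequences}
        assert ids == {"at1", "ls1", "ha1", "ha2", "pa1", "pa2"}

    def test_lineage_copy_counts(self):
        fam = gen_gene_family("lineage", SimulationParams(seed=23))
        ids = {r.id for r in fam.sequences}
        assert ids == {"at1", "ls1", "ha1", "pa1", "pa2"}

    def test_pseudogenized_copy_has_single_internal_stop(self):
        fam = gen_gene_family("asteraceae", SimulationParams(seed=23), pseudogenize="premature_stop")
        start, end = fam.truth.family.cds_span
        disrupted = 0
        for rec in fam.sequences:
            if rec.id.startswith("pa"):
                cds = rec.residues[start:end]
                internal = [cds[i : i + 3] for i in range(3, len(cds) - 3, 3)]
                if any(c in STOP_CODONS for c in internal):
                    disrupted += 1
        assert disrupted == 1

    def test_true_tree_supports_are_100(self):
        fam = gen_gene_family("lineage", SimulationParams(seed=2))
        sup = {n.support for n in fam.tree.root.walk() if not n.is_tip} - {None}
        assert sup == {100.0}


class TestLncRnaPanel:
    def test_class_counts_match_request(self):
        p = SimulationParams(seed=61)
        panel = gen_lncrna_panel(p)
        by_class = {}
        for t in panel.truth.lncrna.values():
            by_class[t.class_label] = by_class.get(t.class_label, 0) + 1
        assert by_class == {
            "lncrna": p.n_lnc,
            "te_decoy": p.n_te,
            "coding_decoy": p.n_coding,
            "overlap_decoy": p.n_overlap,
        }

    def test_conserved_sites_identical_across_homologs(self):
        panel = gen_lncrna_panel(SimulationParams(seed=67))
        for gid, t in panel.truth.lncrna.items():
            if not t.conserved:
                continue
            g = next(r for r in panel.guayule if r.id == gid).residues
            s, e = t.site
            for pool in (panel.sunflower, panel.lettuce):
                for hom in pool:
                    if hom.id.endswith(gid):
                        assert hom.residues[s:e] == g[s:e]

    def test_nonconserved_sites_differ_in_homolog(self):
        panel = gen_lncrna_panel(SimulationParams(seed=67))
        broken = [
            (i, t) for i, t in panel.truth.lncrna.items()
            if t.site and not t.conserved and t.conservation_class != "species_only"
        ]
        assert broken
        for gid, t in broken:
            g = next(r for r in panel.guayule if r.id == gid).residues
            hom = next(r for r in panel.sunflower if r.id == f"ha_{gid}")
            s, e = t.site
            assert hom.residues[s:e] != g[s:e]

    def test_determinism(self):
        p = SimulationParams(seed=71)
        p1 = gen_lncrna_panel(p)
        p2 = gen_lncrna_panel(p)
        assert [r.residues for r in p1.guayule] == [r.residues for r in p2.guayule]
        assert p1.sunflower_hits.rows.equals(p2.sunflower_hits.rows)

    def test_true_lncrnas_satisfy_length_and_orf_rules(self):
        panel = gen_lncrna_panel(SimulationParams(seed=73))
        for r in panel.guayule:
            if panel.truth.lncrna[r.id].class_label == "lncrna":
                assert len(r.residues) >= 200
                orfs = find_orfs(r.residues, min_codons=1)
                assert all((e - s) // 3 <= 100 for s, e in orfs)
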