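import pytest

from droughtleaf.io_formats import FeatureInterval, HitTable, SequenceRecord
from droughtleaf.lncrna_discovery import (
    ConservationClass,
    RemovalStage,
    classify_conservation,
    filter_genome_overlap,
    filter_length_coding,
    filter_protein_similarity,
    filter_te_housekeeping,
    run_cascade,
)
from droughtleaf.synthetic_data import SimulationParams, gen_lncrna_panel


def _hits(*rows):
    return HitTable.from_records(rows)


class TestSimilarityFilters:
    def test_hit_below_cutoff_removes(self):
        hits = _hits(("a", "p1", 90, 0.9, 1e-5, "p1", 0, 10))
        retained, removed = filter_protein_similarity({"a", "b"}, hits)
        assert removed == {"a"} and retained == {"b"}

    def test_boundary_evalue_inclusive(self):
        hits = _hits(("a", "p1", 90, 0.9, 1e-3, "p1", 0, 10))
        _, removed = filter_protein_similarity({"a"}, hits, evalue_max=1e-3)
        assert removed == {"a"}

    def test_weak_hit_retained(self):
        hits = _hits(("a", "p1", 90, 0.9, 1e-2, "p1", 0, 10))
        retained, removed = filter_protein_similarity({"a"}, hits)
        assert retained == {"a"} and removed == set()

    def test_te_decoys_all_removed(self):
        panel = gen_lncrna_panel(SimulationParams(seed=41))
        ids = {r.id for r in panel.guayule}
        _, removed = filter_te_housekeeping(ids, panel.decoy_hits)
        te_ids = {i for i, t in panel.truth.lncrna.items() if t.class_label == "te_decoy"}
        assert removed == te_ids


class TestLengthCoding:
    def test_short_transcript_removed(self, rng):
        from conftest import random_dna

        rec = SequenceRecord(id="s", residues=random_dna(rng, 150))
        retained, removed = filter_length_coding([rec])
        assert removed == {"s"}

    def test_long_orf_removed(self):
        seq = "C" * 100 + "ATG" + "AAA" * 120 + "TAA" + "C" * 100
        rec = SequenceRecord(id="c", residues=seq)
        _, removed = filter_length_coding([rec])
        assert removed == {"c"}

    def test_true_lncrnas_retained(self):
        panel = gen_lncrna_panel(SimulationParams(seed=43))
        lnc = [r for r in panel.guayule if panel.truth.lncrna[r.id].class_label == "lncrna"]
        retained, removed = filter_length_coding(lnc)
        assert removed == set()


class TestGenomeOverlap:
    ANN = [FeatureInterval("chr1", 100, 200, "+", "gene")]

    def test_hit_inside_gene_removed(self):
        hits = _hits(("a", "s", 90, 0.9, 1e-30, "chr1", 150, 180))
        retained, removed = filter_genome_overlap({"a"}, hits, self.ANN)
        assert removed == {"a"}

    def test_adjacent_hit_retained_half_open(self):
        hits = _hits(("a", "s", 90, 0.9, 1e-30, "chr1", 200, 230))
        retained, removed = filter_genome_overlap({"a"}, hits, self.ANN)
        assert retained == {"a"}

    def test_no_hit_retained(self):
        retained, removed = filter_genome_overlap({"a"}, HitTable.empty(), self.ANN)
        assert retained == {"a"}

    def test_best_hit_selection_prefers_lowest_evalue(self):
        hits = _hits(
            ("a", "s1", 90, 0.9, 1e-30, "chr1", 500, 530),   # best, outside gene
            ("a", "s2", 90, 0.9, 1e-25, "chr1", 150, 180),   # worse, inside gene
        )
        retained, _ = filter_genome_overlap({"a"}, hits, self.ANN)
        assert retained == {"a"}


class TestConservation:
    def test_both_genomes(self):
        sun = _hits(("a", "s", 90, 0.9, 1e-30, "chr1", 0, 50))
        let = _hits(("a", "s", 90, 0.9, 1e-30, "chrL", 0, 50))
        cls, _, _ = classify_conservation("a", sun, let)
        assert cls is ConservationClass.SUNFLOWER_LETTUCE

    def test_sunflower_only(self):
        sun = _hits(("a", "s", 90, 0.9, 1e-30, "chr1", 0, 50))
        cls, _, _ = classify_conservation("a", sun, HitTable.empty())
        assert cls is ConservationClass.SUNFLOWER

    def test_lettuce_only_is_species_only_with_warning(self):
        let = _hits(("a", "s", 90, 0.9, 1e-30, "chrL", 0, 50))
        with pytest.warns(UserWarning, match="nested"):
            cls, _, _ = classify_conservation("a", HitTable.empty(), let)
        assert cls is ConservationClass.SPECIES_ONLY

    def test_annotated_lncrna_flag(self):
        sun = _hits(("a", "s", 90, 0.9, 1e-30, "chr1", 0, 50))
        ann = [FeatureInterval("chr1", 10, 40, "+", "lnc_RNA")]
        _, flag, _ = classify_conservation("a", sun, HitTable.empty(), sunflower_lnc_annotation=ann)
        assert flag


def _run(panel, **kw):
    return run_cascade(
        panel.guayule,
        panel.protein_hits,
        panel.decoy_hits,
        panel.sunflower_hits,
        panel.lettuce_hits,
        panel.sunflower_annotation,
        panel.sunflower_lnc_annotation,
        panel.lettuce_lnc_annotation,
        **kw,
    )


class TestCascade:
    @pytest.mark.parametrize("seed", [41, 42, 43])
    def test_survivors_equal_truth_lncrna_set(self, seed):
        panel = gen_lncrna_panel(SimulationParams(seed=seed))
        trails = _run(panel)
        survivors = {t.transcript_id for t in trails.values() if t.removed_at is RemovalStage.SURVIVOR}
        truth = {i for i, t in panel.truth.lncrna.items() if t.class_label == "lncrna"}
        assert survivors == truth
        for i in survivors:
            assert trails[i].conservation.value == panel.truth.lncrna[i].conservation_class

    def test_stage_count_conservation(self):
        panel = gen_lncrna_panel(SimulationParams(seed=47))
        trails = _run(panel)
        assert len(trails) == len(panel.guayule)
        by_stage = {}
        for t in trails.values():
            by_stage[t.removed_at] = by_stage.get(t.removed_at, 0) + 1
        assert sum(by_stage.values()) == len(panel.guayule)
        tr = panel.truth.lncrna
        assert by_stage[RemovalStage.PROTEIN_SIMILARITY] == sum(
            t.class_label == "coding_decoy" for t in tr.values()
        )
        assert by_stage[RemovalStage.TE_HOUSEKEEPING] == sum(
            t.class_label == "te_decoy" for t in tr.values()
        )
        assert by_stage[RemovalStage.GENOME_OVERLAP] == sum(
            t.class_label == "overlap_decoy" for t in tr.values()
        )

    def test_order_stability(self, rng):
        panel = gen_lncrna_panel(SimulationParams(seed=53))
        shuffled = list(panel.guayule)
        rng.shuffle(shuffled)
        t1 = _run(panel)
        panel.guayule[:] = shuffled
        t2 = _run(panel)
        assert t1 == t2

    def test_threshold_monotonicity(self):
        panel = gen_lncrna_panel(SimulationParams(seed=59))
        base = _run(panel)
        n_base = sum(t.removed_at is RemovalStage.SURVIVOR for t in base.values())
        looser = _run(panel, evalue_decoy=1e-40)  # stricter removal evidence needed
        n_looser = sum(t.removed_at is RemovalStage.SURVIVOR for t in looser.values())
        tighter = _run(panel, evalue_decoy=1.0)
        n_tighter = sum(t.removed_at is RemovalStage.SURVIVOR for t in tighter.values())
        assert n_tighter <= n_base <= n_looser
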