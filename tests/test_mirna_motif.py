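import numpy as np
import pytest

from _oracles import duplex_penalty_oracle, window_scan_oracle
from conftest import random_dna
from droughtleaf.io_formats import Alignment, SequenceRecord, revcomp
from droughtleaf.mirna_motif import (
    scan_targets,
    score_duplex,
    site_conservation,
    sponge_report,
)
from droughtleaf.synthetic_data import MIR166, SimulationParams, gen_lncrna_panel


def _site_with(mirna, mirna_pos, new_base):
    """Perfect site with the target base paired to miRNA position mirna_pos replaced."""
    site = list(revcomp(mirna))
    idx = len(mirna) - mirna_pos  # antiparallel partner of miRNA position (1-based)
    site[idx] = new_base
    return "".join(site)


class TestScoreDuplex:
    def test_perfect_complement_scores_zero(self):
        e, notes = score_duplex(MIR166, revcomp(MIR166))
        assert e == 0.0 and set(notes) == {"WC"}

    def test_mismatch_outside_seed_costs_one(self):
        # miRNA position 15 pairs A; put C there (A:C is a mismatch)
        mirna = "A" * 21
        site = _site_with(mirna, 15, "C")
        e, notes = score_duplex(mirna, site)
        assert e == 1.0 and notes[14] == "MM"

    def test_wobble_in_seed_costs_one(self):
        mirna = "G" + "A" * 20  # ...no: build G at position 3
        mirna = "AAG" + "A" * 18
        site = _site_with(mirna, 3, "T")  # G:T wobble at seed position 3
        e, notes = score_duplex(mirna, site)
        assert e == 1.0 and notes[2] == "GU"

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            score_duplex("ACGT", "ACG")

    def test_u_and_t_equivalent(self):
        e_u, _ = score_duplex(MIR166.replace("T", "U"), revcomp(MIR166))
        assert e_u == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_random_duplexes_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = random_dna(rng, 21)
        s = random_dna(rng, 21)
        assert score_duplex(m, s)[0] == duplex_penalty_oracle(m, s)

    def test_monotone_in_planted_mismatches(self, rng):
        m = random_dna(rng, 21)
        site = list(revcomp(m))
        prev = 0.0
        # corrupt positions outside the seed one at a time
        for pos in [0, 13, 15, 17, 19]:
            site[pos] = {"A": "C", "C": "A", "G": "A", "T": "C"}[site[pos]]
            e, _ = score_duplex(m, "".join(site))
            assert e >= prev
            prev = e


class TestScanTargets:
    def test_planted_site_found_at_interval(self):
        panel = gen_lncrna_panel(SimulationParams(seed=19))
        for gid, truth in panel.truth.lncrna.items():
            if truth.site is None:
                continue
            rec = next(r for r in panel.guayule if r.id == gid)
            sites = scan_targets(panel.mirna_id, panel.mirna_seq, rec, cutoff=0.0)
            assert [(s.start, s.end) for s in sites] == [truth.site]
            assert sites[0].expectation == 0.0

    def test_random_sequence_has_no_perfect_site(self, rng):
        rec = SequenceRecord(id="r", residues=random_dna(rng, 1000))
        assert scan_targets("m", random_dna(rng, 21), rec, cutoff=0.0) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_all_windows_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mirna = random_dna(rng, 21)
        rec = SequenceRecord(id="r", residues=random_dna(rng, 300))
        got = {(s.start, s.expectation) for s in scan_targets("m", mirna, rec, cutoff=18.0)}
        assert got == set(window_scan_oracle(mirna, rec.residues, 18.0))

    def test_position_shift_with_flank(self, rng):
        mirna = random_dna(rng, 21)
        core = random_dna(rng, 200)
        flank = random_dna(rng, 57)
        base = scan_targets("m", mirna, SequenceRecord(id="a", residues=core), cutoff=15.0)
        shifted = scan_targets("m", mirna, SequenceRecord(id="b", residues=flank + core), cutoff=15.0)
        base_k = [(s.start, s.expectation) for s in base]
        # windows fully inside the core must reappear shifted by the flank length
        shifted_k = [(s.start - 57, s.expectation) for s in shifted if s.start >= 57]
        assert set(base_k) <= set(shifted_k)

    def test_sorted_by_expectation_then_position(self, rng):
        mirna = random_dna(rng, 21)
        rec = SequenceRecord(id="r", residues=random_dna(rng, 500))
        sites = scan_targets("m", mirna, rec, cutoff=20.0)
        keys = [(s.expectation, s.start) for s in sites]
        assert keys == sorted(keys)


class TestSiteConservation:
    def _aln(self, *rows):
        return Alignment(tuple(SequenceRecord(id=f"r{i}", residues=s) for i, s in enumerate(rows)))

    def test_identical_homologs_fully_conserved(self, rng):
        seq = random_dna(rng, 100)
        site = type("S", (), {"start": 10, "end": 31})
        frac, ok = site_conservation(self._aln(seq, seq, seq), "r0", site)
        assert frac == 1.0 and ok

    def test_one_substitution_breaks_default_threshold(self, rng):
        seq = random_dna(rng, 100)
        other = seq[:15] + ("A" if seq[15] != "A" else "C") + seq[16:]
        site = type("S", (), {"start": 10, "end": 31})
        frac, ok = site_conservation(self._aln(seq, other), "r0", site)
        assert frac == pytest.approx(20 / 21) and not ok

    def test_substitutions_outside_site_ignored(self, rng):
        seq = random_dna(rng, 100)
        other = ("A" if seq[0] != "A" else "C") + seq[1:]
        site = type("S", (), {"start": 10, "end": 31})
        frac, ok = site_conservation(self._aln(seq, other), "r0", site)
        assert frac == 1.0 and ok

    def test_gap_counts_as_non_identical(self, rng):
        seq = random_dna(rng, 100)
        gapped = seq[:20] + "-" + seq[21:]
        site = type("S", (), {"start": 10, "end": 31})
        frac, ok = site_conservation(self._aln(seq, gapped), "r0", site)
        assert frac < 1.0 and not ok

    def test_site_past_row_end_errors(self, rng):
        seq = random_dna(rng, 30)
        site = type("S", (), {"start": 20, "end": 41})
        with pytest.raises(ValueError):
            site_conservation(self._aln(seq, seq), "r0", site)


class TestSpongeReport:
    def test_synthetic_panel_recovers_exactly_the_conserved_sites(self):
        panel = gen_lncrna_panel(SimulationParams(seed=29))
        truth = panel.truth.lncrna
        survivors = [r for r in panel.guayule if truth[r.id].class_label == "lncrna"]
        alns = {r.id: a for r in survivors if (a := panel.homolog_alignment(r.id)) is not None}
        report = sponge_report(survivors, {panel.mirna_id: panel.mirna_seq}, alns)
        assert set(report["lncrna_id"]) == {i for i, t in truth.items() if t.conserved}
        for _, row in report.iterrows():
            assert (row["start"], row["end"]) == truth[row["lncrna_id"]].site
            assert row["expectation"] == 0.0

    def test_empty_library_empty_report(self):
        panel = gen_lncrna_panel(SimulationParams(seed=29))
        report = sponge_report(panel.guayule[:3], {}, {})
        assert report.empty

    def test_invariant_to_library_order(self, rng):
        panel = gen_lncrna_panel(SimulationParams(seed=31))
        truth = panel.truth.lncrna
        survivors = [r for r in panel.guayule if truth[r.id].class_label == "lncrna"]
        alns = {r.id: a for r in survivors if (a := panel.homolog_alignment(r.id)) is not None}
        lib1 = {"a_mir": panel.mirna_seq, "b_mir": random_dna(rng, 21)}
        lib2 = dict(reversed(list(lib1.items())))
        r1 = sponge_report(survivors, lib1, alns)
        r2 = sponge_report(survivors, lib2, alns)
        assert r1.equals(r2)
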