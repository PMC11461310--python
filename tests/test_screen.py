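"""Homology screening: aligner properties, two-step labels, COI and 16S calls."""

import numpy as np
import pytest

from conftest import mutate_subs, random_dna_str
from oracles import sw_local

from endomine.align import local_align, reverse_complement
from endomine.io import FastaRecord
from endomine.screen import (PanelEntry, ReferencePanel, ScreenParams, classify_coi,
                             score_hit, screen_transcripts_for_16S, two_step_classify)


class TestScoreHit:
    def test_self_alignment(self, rng):
        q = random_dna_str(100, rng)
        hits = score_hit(q, q)
        assert hits[0].identity == 100.0
        assert hits[0].score == 200  # 100 matches x +2
        assert hits[0].query_span == (1, 100)
        assert hits[0].subject_span == (1, 100)

    def test_planted_block_found_and_scored_like_full_dp(self, rng):
        for _ in range(10):
            block = random_dna_str(50, rng)
            query = random_dna_str(500, rng) + block + random_dna_str(450, rng)
            subject = random_dna_str(300, rng) + block + random_dna_str(650, rng)
            hits = local_align(query, subject)
            oracle_score = sw_local(query, subject)[0]
            assert hits, "planted block not found"
            assert hits[0].score == oracle_score
            # the planted block must sit inside the reported span
            assert hits[0].q_start <= 500 and hits[0].q_end >= 550

    def test_gapless_identity_arithmetic(self, rng):
        # one mismatch over a 382-column gapless alignment
        ref = random_dna_str(382, rng)
        query = mutate_subs(ref, 1, rng)
        hits = score_hit(query, ref)
        assert hits[0].aligned_length == 382
        assert round(hits[0].identity, 3) == round(100 * 381 / 382, 3) == 99.738

    def test_symmetry_of_top_score(self, rng):
        for _ in range(5):
            a = random_dna_str(400, rng)
            b = random_dna_str(150, rng) + mutate_subs(a, 8, rng)[:250] + random_dna_str(100, rng)
            fwd = local_align(a, b)
            rev = local_align(b, a)
            assert bool(fwd) == bool(rev)
            if fwd:
                assert fwd[0].score == rev[0].score

    def test_monotonicity_under_substitutions(self, rng):
        subject = random_dna_str(1000, rng)
        for _ in range(100):
            n1 = int(rng.integers(0, 20))
            n2 = n1 + int(rng.integers(1, 20))
            q1 = mutate_subs(subject, n1, rng)
            q2 = mutate_subs(q1, 0, rng) if n2 == n1 else mutate_subs(subject, n2, rng)
            h1 = local_align(q1, subject)
            h2 = local_align(q2, subject)
            i1 = h1[0].identity if h1 else 0.0
            i2 = h2[0].identity if h2 else 0.0
            assert i2 <= i1 + 1e-9

    def test_reverse_strand_hit_reported_forward(self, rng):
        block = random_dna_str(80, rng)
        query = random_dna_str(200, rng) + block + random_dna_str(200, rng)
        subject = random_dna_str(100, rng) + reverse_complement(block) + random_dna_str(100, rng)
        hits = local_align(query, subject)
        assert hits[0].strand == "-"
        assert 100 <= hits[0].s_start and hits[0].s_end <= 180 + 1

    def test_n_never_matches(self):
        with pytest.raises(ValueError):
            local_align("", "ACGT")
        hits = local_align("N" * 100, "N" * 100)
        assert hits == []

    def test_seed_longer_than_sequence(self):
        with pytest.raises(ValueError):
            local_align("ACGTACGT", "ACGTACGT", k=15)


class TestTwoStep:
    @pytest.fixture()
    def panels(self, rng):
        ppn = random_dna_str(3000, rng)
        other = random_dna_str(3000, rng)
        host = random_dna_str(3000, rng)
        sym = ReferencePanel([PanelEntry("ppn1", "PPN_symbiont", ppn),
                              PanelEntry("oth1", "other_symbiont", other)])
        broad = ReferencePanel([PanelEntry("ppn1", "PPN_symbiont", ppn),
                                PanelEntry("oth1", "other_symbiont", other),
                                PanelEntry("host1", "host", host)])
        return ppn, other, host, sym, broad

    def test_identical_contig_labeled_ppn(self, panels):
        ppn, *_ , sym, broad = panels
        labels = two_step_classify([FastaRecord("q", ppn)], sym, broad)
        assert labels[0].label == "PPN_symbiont"
        assert labels[0].retained

    def test_closer_match_wins(self, panels, rng):
        ppn, other, host, sym, broad = panels
        near_other = mutate_subs(other, 60, rng)  # 2% from other, unrelated to PPN
        labels = two_step_classify([FastaRecord("q", near_other)], sym, broad)
        assert labels[0].label == "other_symbiont"

    def test_random_contig_unclassified(self, panels, rng):
        *_, sym, broad = panels
        labels = two_step_classify([FastaRecord("q", random_dna_str(1000, rng))],
                                   sym, broad)
        assert labels[0].label == "unclassified"
        assert labels[0].best_hit is None

    def test_host_contig_labeled_host(self, panels, rng):
        *_, host, sym, broad = panels[2], panels[3], panels[4]
        host = panels[2]
        labels = two_step_classify([FastaRecord("q", mutate_subs(host, 30, rng))],
                                   panels[3], panels[4])
        assert labels[0].label == "host"
        assert not labels[0].retained

    def test_label_stable_under_panel_order(self, panels, rng):
        ppn, other, host, sym, broad = panels
        query = FastaRecord("q", mutate_subs(ppn, 30, rng))
        shuffled = ReferencePanel(list(reversed(broad.entries)))
        a = two_step_classify([query], sym, broad)[0]
        b = two_step_classify([query], sym, shuffled)[0]
        assert (a.label, a.best_hit.subject_id) == (b.label, b.best_hit.subject_id)

    def test_empty_inputs_rejected(self, panels):
        *_, sym, broad = panels
        with pytest.raises(ValueError):
            two_step_classify([], sym, broad)
        with pytest.raises(ValueError):
            two_step_classify([FastaRecord("q", "ACGT" * 100)], sym,
                              ReferencePanel([sym.entries[0]]))


class TestCoi:
    def _panel(self, rng):
        schachtii = random_dna_str(382, rng)
        medicaginis = mutate_subs(schachtii, 60, rng)
        return schachtii, medicaginis, ReferencePanel([
            PanelEntry("coi_hs", "coi", schachtii, species="H_schachtii"),
            PanelEntry("coi_hm", "coi", medicaginis, species="H_medicaginis")])

    def test_two_divergent_copies_reported_separately(self, rng):
        schachtii, medicaginis, panel = self._panel(rng)
        copy1 = mutate_subs(schachtii, 1, rng)       # 381/382 identity
        copy2 = mutate_subs(schachtii, 36, rng)      # 346/382 identity
        assembly = [FastaRecord("scf", random_dna_str(800, rng) + copy1 +
                                random_dna_str(900, rng) + copy2 +
                                random_dna_str(700, rng))]
        calls = classify_coi(assembly, panel)
        assert len(calls) == 2
        idents = sorted(round(c.identity, 3) for c in calls)
        assert idents == [90.576, 99.738]
        best = {round(c.identity, 3): c.species for c in calls}
        assert best[99.738] == "H_schachtii"

    def test_assembly_without_coi_empty(self, rng):
        _, _, panel = self._panel(rng)
        assert classify_coi([FastaRecord("scf", random_dna_str(2000, rng))], panel) == []

    def test_empty_panel_rejected(self, rng):
        with pytest.raises(ValueError):
            classify_coi([FastaRecord("scf", "ACGT" * 100)], ReferencePanel([]))


class Test16S:
    def test_exact_slice_reported(self, rng):
        ref = random_dna_str(1500, rng)
        t = FastaRecord("t1", random_dna_str(200, rng) + ref[400:900] + random_dna_str(150, rng))
        hits = screen_transcripts_for_16S([t], ref, min_identity=95.0, min_len=200)
        assert len(hits) == 1 and hits[0].identity == 100.0

    def test_unrelated_transcript_not_reported(self, rng):
        ref = random_dna_str(1500, rng)
        t = FastaRecord("t1", random_dna_str(600, rng))
        assert screen_transcripts_for_16S([t], ref) == []

    def test_divergent_transcript_identity(self, rng):
        ref = random_dna_str(1500, rng)
        t = FastaRecord("t1", mutate_subs(ref[:1000], 20, rng))
        hits = screen_transcripts_for_16S([t], ref, min_identity=90.0, min_len=500)
        assert len(hits) == 1
        assert abs(hits[0].identity - 98.0) < 0.5
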