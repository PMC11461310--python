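"""Genome features: GC, skew, coding density, pseudogene indicators, summary."""

import numpy as np
import pytest

from conftest import random_dna_str
from oracles import interval_union_length

from endomine.align import reverse_complement
from endomine.features import (call_pseudogene_indicators, coding_density,
                               gc_content, gc_skew_profile, gc_vs_length_table,
                               summarize_features)
from endomine.io import FastaRecord, GeneModel
from endomine.simulate import make_annotated_genome


class TestGcContent:
    @pytest.mark.parametrize("seq,expected", [
        ("GGCC", 100.0), ("GGNN", 100.0), ("AATT", 0.0), ("ACGT", 50.0),
        ("ACGTNNNN", 50.0)])
    def test_values(self, seq, expected):
        assert gc_content(seq) == expected

    def test_strand_invariant(self, rng):
        seq = random_dna_str(2_000, rng, gc=0.37)
        assert gc_content(seq) == pytest.approx(gc_content(reverse_complement(seq)))

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            gc_content("")
        with pytest.raises(ValueError):
            gc_content("NNNN")


class TestGcSkew:
    def test_all_g_window(self):
        prof = gc_skew_profile("G" * 100, window=100, step=10)
        assert prof[0][1] == 1.0

    def test_balanced_window(self):
        prof = gc_skew_profile("GC" * 50, window=100, step=10)
        assert prof[0][1] == 0.0

    def test_small_window_arithmetic(self):
        prof = gc_skew_profile("GGGC", window=4, step=1)
        assert prof[0][1] == pytest.approx(0.5)

    def test_window_without_gc_flagged(self):
        prof = gc_skew_profile("ATAT" * 5, window=10, step=5)
        assert all(p[2] for p in prof) and all(p[1] == 0.0 for p in prof)

    def test_bad_step(self):
        with pytest.raises(ValueError):
            gc_skew_profile("ACGT" * 10, window=8, step=0)


class TestCodingDensity:
    def mk(self, *ivals):
        return [GeneModel(f"g{i}", "c", a, b, "+", "CDS")
                for i, (a, b) in enumerate(ivals)]

    def test_no_cds(self):
        assert coding_density([], 1000) == 0.0

    def test_overlap_counted_once(self):
        assert coding_density(self.mk((1, 100), (51, 150)), 1000) == 15.0

    def test_full_tiling(self):
        assert coding_density(self.mk((1, 500), (501, 1000)), 1000) == 100.0

    def test_matches_union_oracle(self, rng):
        for _ in range(20):
            ivals = []
            for _ in range(int(rng.integers(1, 15))):
                a = int(rng.integers(1, 900))
                ivals.append((a, a + int(rng.integers(1, 80))))
            genes = self.mk(*ivals)
            want = 100.0 * interval_union_length(ivals) / 1000
            assert coding_density(genes, 1000) == pytest.approx(want)

    def test_permutation_and_split_invariance(self, rng):
        genes = self.mk((10, 200), (150, 400), (500, 700))
        shuffled = list(reversed(genes))
        split = self.mk((10, 100), (101, 200), (150, 400), (500, 600), (601, 700))
        d = coding_density(genes, 1000)
        assert coding_density(shuffled, 1000) == d
        assert coding_density(split, 1000) == d

    def test_bounds_checked(self):
        with pytest.raises(ValueError):
            coding_density(self.mk((1, 100)), 0)
        with pytest.raises(ValueError):
            coding_density(self.mk((900, 1100)), 1000)


def _lesion(genome, gene, kind, rng):
    """Introduce one lesion of the requested kind into a CDS."""
    cds = genome[gene.start - 1:gene.end]
    n_codons = len(cds) // 3
    if kind == "frameshift":
        k = int(rng.integers(10, n_codons - 10)) * 3 + 1
        cds = cds[:k] + "A" + cds[k:]
    elif kind == "internal_stop":
        k = int(rng.integers(10, n_codons - 10)) * 3
        cds = cds[:k] + "TAG" + cds[k + 3:]
    elif kind == "missing_stop":
        cds = cds[:-3] + "CAA"
    elif kind == "missing_start":
        cds = "ATT" + cds[3:]
    return genome[:gene.start - 1] + cds + genome[gene.end:]


class TestPseudogeneIndicators:
    @pytest.fixture()
    def annotated(self):
        genome, genes = make_annotated_genome(n_cds=5, seed=17)
        refs = [FastaRecord(g.gene_id, g.translation)
                for g in genes if g.feature_class == "CDS"]
        return genome, genes, refs

    def test_intact_genome_has_no_calls(self, annotated):
        genome, genes, refs = annotated
        calls, counts, missing = call_pseudogene_indicators(genome, refs)
        assert calls == [] and missing == []
        assert all(v == 0 for v in counts.values())

    @pytest.mark.parametrize("kind", ["frameshift", "internal_stop",
                                      "missing_stop", "missing_start"])
    def test_each_lesion_yields_exactly_its_indicator(self, annotated, kind):
        genome, genes, refs = annotated
        rng = np.random.default_rng(5)
        for trial in range(5):
            gene = genes[int(rng.integers(0, 5))]
            mutated = _lesion(genome, gene, kind, rng)
            calls, counts, _ = call_pseudogene_indicators(mutated, refs)
            assert len(calls) == 1
            assert calls[0].reference_protein_id == gene.gene_id
            assert calls[0].indicators == {kind}

    def test_reverse_strand_gene_found(self, annotated):
        genome, genes, refs = annotated
        calls, _, missing = call_pseudogene_indicators(
            reverse_complement(genome), refs)
        assert calls == [] and missing == []

    def test_absent_reference_is_missing_not_pseudogene(self, annotated, rng):
        genome, genes, refs = annotated
        refs = refs + [FastaRecord("absent", "".join(
            "ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(0, 20, 150)))]
        calls, _, missing = call_pseudogene_indicators(genome, refs)
        assert missing == ["absent"]
        assert calls == []

    def test_empty_reference_rejected(self, annotated):
        genome, *_ = annotated
        with pytest.raises(ValueError):
            call_pseudogene_indicators(genome, [])


class TestSummarize:
    def test_toy_counts(self, rng):
        seq = random_dna_str(3_000, rng)
        genes = [
            GeneModel("t1", "c1", 1, 76, "+", "tRNA", product="tRNA-Gly"),
            GeneModel("t2", "c1", 100, 175, "+", "tRNA", product="tRNA-Ala"),
            GeneModel("r1", "c1", 200, 1700, "+", "rRNA", product="16S ribosomal RNA"),
            GeneModel("c1g", "c1", 1800, 2099, "+", "CDS", product="ankyrin repeat protein"),
            GeneModel("c2g", "c1", 2101, 2400, "+", "CDS", product="IS5 transposase"),
            GeneModel("c3g", "c1", 2402, 2701, "+", "CDS", product="hypothetical protein"),
        ]
        s = summarize_features([FastaRecord("c1", seq)], genes)
        assert (s.n_tRNA, s.n_rRNA) == (2, 1)
        assert (s.n_ankyrin, s.n_transposase, s.n_phage) == (1, 1, 0)
        assert (s.n_proteins_hypothetical, s.n_proteins_known) == (1, 2)
        assert s.coding_density_percent == pytest.approx(100 * 900 / 3000)

    def test_empty_annotation(self, rng):
        s = summarize_features([FastaRecord("c1", random_dna_str(500, rng))], [])
        assert s.coding_density_percent == 0.0
        assert s.n_tRNA == s.n_rRNA == s.n_proteins_known == 0

    def test_generator_truth_recovered(self):
        genome, genes = make_annotated_genome(n_cds=6, n_trna=3, n_rrna=2, seed=9)
        s = summarize_features([FastaRecord("chr1", genome)], genes)
        assert s.n_tRNA == 3 and s.n_rRNA == 2
        assert s.n_proteins_known + s.n_proteins_hypothetical == 6
        assert s.genome_length == len(genome)
        assert s.gc_percent == pytest.approx(gc_content(genome))

    def test_contig_mismatch_rejected(self, rng):
        genes = [GeneModel("x", "nope", 1, 30, "+", "CDS")]
        with pytest.raises(ValueError):
            summarize_features([FastaRecord("c1", random_dna_str(100, rng))], genes)


class TestGcVsLength:
    def test_single_genome_row(self, rng):
        seq = random_dna_str(1_000, rng, gc=0.4)
        table, rho = gc_vs_length_table([("g", [FastaRecord("c", seq)])])
        assert table.iloc[0]["length"] == 1_000
        assert table.iloc[0]["gc_percent"] == pytest.approx(gc_content(seq))
        assert rho is None

    def test_two_point_trend(self, rng):
        small = random_dna_str(10_000, rng, gc=0.32)
        large = random_dna_str(15_000, rng, gc=0.35)
        _, rho = gc_vs_length_table([("s", [FastaRecord("c", small)]),
                                     ("l", [FastaRecord("c", large)])])
        assert rho == 1.0

    def test_rank_correlation_matches_manual_ranks(self, rng):
        genomes = []
        for i in range(8):
            n = 2_000 + 500 * i
            genomes.append((f"g{i}", [FastaRecord("c", random_dna_str(
                n, rng, gc=0.3 + 0.02 * ((i * 3) % 7)))]))
        table, rho = gc_vs_length_table(genomes)
        lengths = table["length"].to_numpy()
        gcs = table["gc_percent"].to_numpy()
        rl = np.argsort(np.argsort(lengths)).astype(float)
        rg = np.argsort(np.argsort(gcs)).astype(float)
        manual = np.corrcoef(rl, rg)[0, 1]
        assert rho == pytest.approx(manual, abs=1e-9)
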