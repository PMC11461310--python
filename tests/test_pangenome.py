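"""Ortholog clustering, Venn counting, and hypergeometric enrichment."""

from fractions import Fraction

import numpy as np
import pytest

from oracles import bbh_clusters, hypergeom_tail, sw_local

from endomine.pangenome import (EnrichmentRow, Proteome, ProteinEntry,
                                all_vs_all_similarity, cluster_orthologs,
                                core_and_venn, fisher_enrichment)

AA = "ACDEFGHIKLMNPQRSTVWY"


def rprot(n, rng):
    return "".join(AA[i] for i in rng.integers(0, 20, n))


def mut(seq, d, rng):
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < d:
            out[i] = AA[rng.integers(0, 20)]
    return "".join(out)


def toy_proteomes(rng, n_genomes=3, n_shared=4, divergence=0.05, n_unique=1):
    family = [rprot(int(rng.integers(80, 160)), rng) for _ in range(n_shared)]
    proteomes = []
    for g in range(n_genomes):
        prots = [ProteinEntry(f"p{g}_{i}", mut(family[i], divergence, rng))
                 for i in range(n_shared)]
        prots += [ProteinEntry(f"p{g}_u{j}", rprot(100, rng))
                  for j in range(n_unique)]
        proteomes.append(Proteome(f"G{g}", prots))
    return proteomes


class TestAllVsAll:
    def test_identical_proteins_full_edge(self, rng):
        p = rprot(120, rng)
        edges = all_vs_all_similarity([Proteome("A", [ProteinEntry("a", p)]),
                                       Proteome("B", [ProteinEntry("b", p)])])
        assert len(edges) == 1
        assert edges[0].identity == 100.0 and edges[0].coverage == 100.0

    def test_unrelated_proteins_no_edge(self, rng):
        edges = all_vs_all_similarity(
            [Proteome("A", [ProteinEntry("a", rprot(100, rng))]),
             Proteome("B", [ProteinEntry("b", rprot(100, rng))])])
        assert edges == []

    def test_edge_set_matches_full_dp_oracle(self, rng):
        proteomes = toy_proteomes(rng, n_genomes=2, n_shared=6, n_unique=4)
        edges = all_vs_all_similarity(proteomes, min_identity=70.0, min_coverage=75.0)
        got = {(e.a, e.b) for e in edges}
        want = set()
        for pa in proteomes[0].proteins:
            for pb in proteomes[1].proteins:
                score, matches, mm, gaps, qs, ss = sw_local(pa.sequence, pb.sequence)
                cols = matches + mm + gaps
                if score < 30 or cols == 0:
                    continue
                ident = 100.0 * matches / cols
                cov = min(100.0 * (qs[1] - qs[0]) / len(pa.sequence),
                          100.0 * (ss[1] - ss[0]) / len(pb.sequence))
                if ident >= 70.0 and cov >= 75.0:
                    want.add((("G0", pa.protein_id), ("G1", pb.protein_id)))
        assert got == want

    def test_input_validation(self, rng):
        one = Proteome("A", [ProteinEntry("a", rprot(50, rng))])
        with pytest.raises(ValueError):
            all_vs_all_similarity([one])
        with pytest.raises(ValueError):
            all_vs_all_similarity([one, Proteome("B", [])])


class TestClustering:
    def test_single_family_three_genomes(self, rng):
        p = rprot(130, rng)
        proteomes = [Proteome(f"G{i}", [ProteinEntry(f"p{i}", p)]) for i in range(3)]
        edges = all_vs_all_similarity(proteomes)
        cs = cluster_orthologs(edges, proteomes)
        assert len(cs.clusters) == 1
        assert len(cs.clusters[0][1]) == 3

    def test_disjoint_proteomes_all_singletons(self, rng):
        proteomes = [Proteome(f"G{i}", [ProteinEntry(f"p{i}_{j}", rprot(90, rng))
                                        for j in range(3)]) for i in range(2)]
        cs = cluster_orthologs([], proteomes)
        assert len(cs.clusters) == 6
        assert all(len(m) == 1 for _, m in cs.clusters)

    def test_matches_independent_bbh_oracle(self, rng):
        for trial in range(3):
            proteomes = toy_proteomes(rng, n_genomes=4, n_shared=5,
                                      divergence=0.08, n_unique=2)
            edges = all_vs_all_similarity(proteomes)
            cs = cluster_orthologs(edges, proteomes)
            got = {frozenset(m) for _, m in cs.clusters}
            assert got == bbh_clusters(edges, proteomes)

    def test_partition_and_no_same_genome_mixing(self, rng):
        proteomes = toy_proteomes(rng, n_genomes=3, n_shared=4, n_unique=2)
        edges = all_vs_all_similarity(proteomes)
        cs = cluster_orthologs(edges, proteomes)
        seen = [p for _, m in cs.clusters for p in m]
        assert len(seen) == len(set(seen)) == sum(len(p.proteins) for p in proteomes)
        for _, members in cs.clusters:
            genomes = [g for g, _ in members]
            assert len(genomes) == len(set(genomes))


class TestVenn:
    def _singleton_cluster_set(self, genome_sets):
        from endomine.pangenome import OrthologClusterSet
        genomes = sorted({g for s in genome_sets for g in s})
        clusters = [(f"c{i}", [(g, f"c{i}_{g}") for g in sorted(s)])
                    for i, s in enumerate(genome_sets)]
        return OrthologClusterSet(clusters, genomes)

    def test_identical_proteomes_all_core(self, rng):
        p = rprot(120, rng)
        proteomes = [Proteome(f"G{i}", [ProteinEntry(f"p{i}", p)]) for i in range(4)]
        cs = cluster_orthologs(all_vs_all_similarity(proteomes), proteomes)
        core, venns = core_and_venn(cs)
        assert core == len(cs.clusters) == 1
        assert all(v.unique_a == v.unique_b == 0 for v in venns)

    def test_set_arithmetic_example(self):
        # clusters g1..g5 for group A and g3..g7 for group B, singleton genes
        sets = [{f"g{i}"} for i in range(1, 8)]
        cs = self._singleton_cluster_set(sets)
        core, venns = core_and_venn(cs, {"A": [f"g{i}" for i in range(1, 6)],
                                         "B": [f"g{i}" for i in range(3, 8)]})
        v = venns[0]
        assert (v.shared, v.unique_a, v.unique_b) == (3, 2, 2)

    def test_empty_intersection(self):
        sets = [{"g1"}, {"g2"}]
        cs = self._singleton_cluster_set(sets)
        _, venns = core_and_venn(cs, {"A": ["g1"], "B": ["g2"]})
        assert venns[0].shared == 0

    def test_region_counts_conserve_totals(self, rng):
        proteomes = toy_proteomes(rng, n_genomes=2, n_shared=5, n_unique=3)
        cs = cluster_orthologs(all_vs_all_similarity(proteomes), proteomes)
        _, venns = core_and_venn(cs, {"A": ["G0"], "B": ["G1"]})
        v = venns[0]
        touching = sum(1 for _, m in cs.clusters
                       if any(g in ("G0", "G1") for g, _ in m))
        assert v.total == touching

    def test_unknown_genome_rejected(self):
        cs = self._singleton_cluster_set([{"g1"}])
        with pytest.raises(ValueError):
            core_and_venn(cs, {"A": ["nope"]})


class TestEnrichment:
    def test_expected_column_is_exact_definition(self):
        # annotated 16 with |study|/|universe| = 0.05 gives expected 0.80
        universe = [f"g{i}" for i in range(320)]
        study = universe[:16]
        gene2go = {g: {"GO:0042802"} for g in universe[:16]}
        rows = fisher_enrichment(study, universe, gene2go)
        assert rows[0].annotated == 16
        assert rows[0].expected == pytest.approx(16 * 16 / 320)
        assert rows[0].expected == pytest.approx(0.80)

    def test_study_equals_universe(self):
        universe = [f"g{i}" for i in range(30)]
        gene2go = {g: {"GO:1"} for g in universe[:12]}
        rows = fisher_enrichment(universe, universe, gene2go)
        assert rows[0].significant == rows[0].annotated == 12
        assert rows[0].p_value == pytest.approx(1.0)

    def test_exact_tail_toy(self):
        universe = [f"g{i}" for i in range(20)]
        study = universe[:10]
        gene2go = {g: {"GO:X"} for g in universe[:5]}
        rows = fisher_enrichment(study, universe, gene2go)
        want = Fraction(3003, 184756)
        assert rows[0].p_value == pytest.approx(float(want), abs=1e-12)
        assert float(want) == pytest.approx(0.01625, abs=5e-5)

    def test_matches_exact_tail_over_random_configs(self, rng):
        for _ in range(20):
            N = int(rng.integers(10, 60))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            universe = [f"g{i}" for i in range(N)]
            annotated = list(rng.choice(universe, size=K, replace=False))
            study = list(rng.choice(universe, size=n, replace=False))
            gene2go = {g: {"GO:T"} for g in annotated}
            rows = fisher_enrichment(study, universe, gene2go)
            k = len(set(annotated) & set(study))
            assert rows[0].significant == k
            assert rows[0].p_value == pytest.approx(
                float(hypergeom_tail(N, K, n, k)), abs=1e-10)

    def test_rows_sorted_by_p(self, rng):
        g2g = {}
        universe = [f"g{i}" for i in range(100)]
        for t in range(5):
            for g in rng.choice(universe, size=20, replace=False):
                g2g.setdefault(g, set()).add(f"GO:{t}")
        rows = fisher_enrichment(universe[:20], universe, g2g)
        assert [r.p_value for r in rows] == sorted(r.p_value for r in rows)

    def test_validation(self):
        with pytest.raises(ValueError):
            fisher_enrichment([], ["g1"], {})
        with pytest.raises(ValueError):
            fisher_enrichment(["g9"], ["g1"], {})
        with pytest.raises(ValueError):
            EnrichmentRow("GO:1", "t", 5, 6, 1.0, 0.5)
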