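"""Simplified pangenome analysis and GO-term enrichment.

Cross-genome protein pairs are scored with the same seeded local aligner
used for nucleotide screening (5-mer peptide seeds); pairs clearing
identity and mutual-coverage thresholds become candidate ortholog edges,
bidirectional-best edges per genome pair are kept, and connected
components form the ortholog clusters (components holding two proteins of
one genome are split by dropping their weakest edge until one-per-genome).
Core / shared / unique cluster counts summarize the pangenome, and
enrichment of GO terms in a study set against a gene universe is scored
with the upper-tail hypergeometric (classic Fisher) test, reporting the
conventional Annotated / Significant / Expected / p-value columns.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
from scipy import stats

from endomine.align import local_align


@dataclass
class ProteinEntry:
    protein_id: str
    sequence: str
    product: str = ""


@dataclass
class Proteome:
    genome_id: str
    proteins: list[ProteinEntry]

    def __post_init__(self):
        ids = [p.protein_id for p in self.proteins]
        if len(set(ids)) != len(ids):
            raise ValueError(f"{self.genome_id}: duplicate protein ids")


@dataclass(frozen=True)
class SimilarityEdge:
    a: tuple[str, str]  # (genome_id, protein_id)
    b: tuple[str, str]
    identity: float
    coverage: float
    score: int


@dataclass
class OrthologClusterSet:
    clusters: list[tuple[str, list[tuple[str, str]]]]
    genome_ids: list[str]

    def presence_absence(self):
        """Roary-style gene_presence_absence table (clusters x genomes)."""
        import pandas as pd

        rows = []
        for cid, members in self.clusters:
            row = {"cluster": cid}
            for gid in self.genome_ids:
                row[gid] = ";".join(p for g, p in members if g == gid)
            rows.append(row)
        return pd.DataFrame(rows).set_index("cluster")


@dataclass
class VennCounts:
    set_labels: tuple[str, str]
    shared: int
    unique_a: int
    unique_b: int

    @property
    def total(self) -> int:
        return self.shared + self.unique_a + self.unique_b


@dataclass
class EnrichmentRow:
    go_id: str
    term: str
    annotated: int
    significant: int
    expected: float
    p_value: float

    def __post_init__(self):
        if self.significant > self.annotated:
            raise ValueError("significant cannot exceed annotated")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


# ---------------------------------------------------------------------------
# all-vs-all similarity and clustering


def all_vs_all_similarity(proteomes: Sequence[Proteome], *, min_identity: float = 70.0,
                          min_coverage: float = 75.0, k: int = 5,
                          min_score: int = 30) -> list[SimilarityEdge]:
    """Cross-genome protein pairs passing identity and mutual coverage.

    Coverage is the aligned span as a percentage of each protein's length;
    both proteins must clear ``min_coverage``.
    """
    if len(proteomes) < 2:
        raise ValueError("need at least two proteomes")
    for pr in proteomes:
        if not pr.proteins:
            raise ValueError(f"empty proteome: {pr.genome_id}")
    edges: list[SimilarityEdge] = []
    for pa, pb in itertools.combinations(proteomes, 2):
        for prot_a in pa.proteins:
            for prot_b in pb.proteins:
                if min(len(prot_a.sequence), len(prot_b.sequence)) < k:
                    continue
                hits = local_align(prot_a.sequence, prot_b.sequence, k=k,
                                   min_score=min_score, protein=True)
                if not hits:
                    continue
                h = hits[0]
                cov_a = 100.0 * (h.q_end - h.q_start) / len(prot_a.sequence)
                cov_b = 100.0 * (h.s_end - h.s_start) / len(prot_b.sequence)
                cov = min(cov_a, cov_b)
                if h.identity >= min_identity and cov >= min_coverage:
                    edges.append(SimilarityEdge(
                        (pa.genome_id, prot_a.protein_id),
                        (pb.genome_id, prot_b.protein_id),
                        h.identity, cov, h.score))
    return edges


def _bidirectional_best(edges: Sequence[SimilarityEdge]) -> list[SimilarityEdge]:
    best: dict[tuple, SimilarityEdge] = {}
    for e in edges:
        for src, dst in ((e.a, e.b), (e.b, e.a)):
            key = (src, dst[0])  # best partner of src in dst's genome
            cur = best.get(key)
            if cur is None or _edge_rank(e) > _edge_rank(cur):
                best[key] = e
    kept = []
    for e in set(best.values()):
        if best.get((e.a, e.b[0])) is e and best.get((e.b, e.a[0])) is e:
            kept.append(e)
    return kept


def _edge_rank(e: SimilarityEdge):
    return (e.score, e.identity, e.coverage,
            # deterministic tie-break on member ids
            tuple(sorted([e.a, e.b])))


def cluster_orthologs(edges: Sequence[SimilarityEdge], proteomes: Sequence[Proteome]) \
        -> OrthologClusterSet:
    """Connected components of the bidirectional-best-hit graph.

    A component holding two proteins of one genome is split by dropping its
    weakest edge until every genome appears at most once per component (or
    no cross-genome edges remain).  Every protein belongs to exactly one
    cluster; proteins without surviving edges are singletons.
    """
    bbh = _bidirectional_best(edges)
    graph = nx.Graph()
    for pr in proteomes:
        for p in pr.proteins:
            graph.add_node((pr.genome_id, p.protein_id))
    for e in bbh:
        graph.add_edge(e.a, e.b, rank=_edge_rank(e))
    clusters: list[list[tuple[str, str]]] = []
    for comp in nx.connected_components(graph):
        clusters.extend(_split_component(graph.subgraph(comp).copy()))
    clusters.sort(key=lambda m: m[0])
    named = [(f"cluster_{i:05d}", members) for i, members in enumerate(clusters)]
    return OrthologClusterSet(named, [p.genome_id for p in proteomes])


def _split_component(sub: nx.Graph) -> list[list[tuple[str, str]]]:
    while True:
        genomes = [g for g, _ in sub.nodes]
        if len(genomes) == len(set(genomes)) or sub.number_of_edges() == 0:
            break
        weakest = min(sub.edges(data="rank"), key=lambda t: t[2])
        sub.remove_edge(weakest[0], weakest[1])
        parts = list(nx.connected_components(sub))
        if len(parts) > 1:
            out = []
            for part in parts:
                out.extend(_split_component(sub.subgraph(part).copy()))
            return out
    return [sorted(sub.nodes)]


# ---------------------------------------------------------------------------
# core genome and Venn regions


def core_and_venn(clusters: OrthologClusterSet,
                  genome_groups: Mapping[str, Sequence[str]] | None = None):
    """Core cluster count plus pairwise Venn counts between genome groups.

    ``genome_groups`` maps labels to genome id lists (default: each genome
    its own group).  A cluster is core when every genome of the set has a
    member.  For each label pair, shared/unique counts are over clusters
    restricted to the union of the two groups.
    """
    known = set(clusters.genome_ids)
    if genome_groups is None:
        genome_groups = {g: [g] for g in clusters.genome_ids}
    for label, gids in genome_groups.items():
        unknown = set(gids) - known
        if unknown:
            raise ValueError(f"group {label} names unknown genomes: {unknown}")
    member_sets = [frozenset(g for g, _ in members) for _, members in clusters.clusters]
    core = sum(1 for s in member_sets if s >= known)
    venns = []
    for la, lb in itertools.combinations(sorted(genome_groups), 2):
        ga, gb = set(genome_groups[la]), set(genome_groups[lb])
        shared = unique_a = unique_b = 0
        for s in member_sets:
            in_a, in_b = bool(s & ga), bool(s & gb)
            if in_a and in_b:
                shared += 1
            elif in_a:
                unique_a += 1
            elif in_b:
                unique_b += 1
        venns.append(VennCounts((la, lb), shared, unique_a, unique_b))
    return core, venns


# ---------------------------------------------------------------------------
# GO enrichment


def fisher_enrichment(study: Sequence[str], universe: Sequence[str],
                      gene2go: Mapping[str, set[str]],
                      term_names: Mapping[str, str] | None = None) -> list[EnrichmentRow]:
    """Classic one-sided Fisher / hypergeometric enrichment per GO term.

    For a term annotating ``annotated`` of ``N`` universe genes, with
    ``significant`` of the ``n`` study genes carrying it:
    ``expected = annotated * n / N`` and
    ``p = P(X >= significant)`` for X ~ Hypergeom(N, annotated, n).
    Rows are sorted by p-value; no multiple-testing correction is applied.
    """
    study_set, universe_set = set(study), set(universe)
    if not study_set or not universe_set:
        raise ValueError("study and universe must be non-empty")
    if not study_set <= universe_set:
        raise ValueError("study set must be a subset of the universe")
    term_genes: dict[str, set[str]] = {}
    dropped = 0
    for gene, terms in gene2go.items():
        if gene not in universe_set:
            dropped += 1
            continue
        for t in terms:
            term_genes.setdefault(t, set()).add(gene)
    fisher_enrichment.last_dropped = dropped  # type: ignore[attr-defined]
    n_univ, n_study = len(universe_set), len(study_set)
    rows = []
    for term in sorted(term_genes):
        genes = term_genes[term]
        annotated = len(genes)
        significant = len(genes & study_set)
        expected = annotated * n_study / n_univ
        p = float(stats.hypergeom.sf(significant - 1, n_univ, annotated, n_study))
        rows.append(EnrichmentRow(term, (term_names or {}).get(term, term),
                                  annotated, significant, expected, min(1.0, p)))
    rows.sort(key=lambda r: (r.p_value, r.go_id))
    return rows


def write_enrichment_tsv(rows: Sequence[EnrichmentRow], path) -> None:
    with open(path, "w") as fh:
        fh.write("GO.ID\tTerm\tAnnotated\tSignificant\tExpected\tp-value\n")
        for r in rows:
            fh.write(f"{r.go_id}\t{r.term}\t{r.annotated}\t{r.significant}\t"
                     f"{r.expected:.2f}\t{r.p_value:.4g}\n")
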