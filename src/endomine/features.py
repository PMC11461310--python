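"""Comparative genome features and pseudogene indicators.

Covers the standard comparison table for a newly closed endosymbiont
genome: GC content and GC-skew profile, coding density, tRNA/rRNA counts,
keyword-based ankyrin / transposase / phage gene counts, the GC-versus-
length trend across genomes, and reference-based pseudogene indicators
(frameshift, internal stop, missing start, missing stop) against an intact
relative's proteome.

Pseudogene calling works on translated comparison: each reference protein
is located in the query genome by exact peptide seeds in all six reading
frames, seed hits are clustered by strand and nucleotide diagonal, and the
cluster structure itself carries the diagnosis — a diagonal shift that is
not a multiple of three is a frameshift, a stop codon interrupting an
otherwise consistent cluster is an internal stop, and the codons at the
mapped start/end positions are checked against bacterial start and stop
codon sets (translation table 11).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio.Seq import Seq
from scipy import stats

from endomine.align import reverse_complement
from endomine.io import FastaRecord, GeneModel

START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")
INDICATORS = ("frameshift", "missing_start", "missing_stop", "internal_stop")

ANKYRIN_KEYWORDS = ("ankyrin",)
TRANSPOSASE_KEYWORDS = ("transposase",)
PHAGE_KEYWORDS = ("phage", "prophage")


# ---------------------------------------------------------------------------
# sequence-level features


def gc_content(sequence: str) -> float:
    """100*(G+C)/(A+C+G+T); ambiguous bases excluded from both counts."""
    if not sequence:
        raise ValueError("empty sequence")
    s = sequence.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    if gc + at == 0:
        raise ValueError("sequence has no unambiguous bases")
    return 100.0 * gc / (gc + at)


def gc_skew_profile(sequence: str, window: int = 10_000, step: int = 1_000):
    """Sliding-window (G-C)/(G+C); windows without G or C report 0 flagged.

    Returns a list of ``(midpoint, skew, degenerate)`` tuples; midpoints are
    1-based window centers.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    s = sequence.upper()
    if window > len(s):
        raise ValueError("window larger than sequence")
    g = np.frombuffer(s.encode("ascii"), np.uint8) == ord("G")
    c = np.frombuffer(s.encode("ascii"), np.uint8) == ord("C")
    gcum = np.concatenate(([0], np.cumsum(g)))
    ccum = np.concatenate(([0], np.cumsum(c)))
    out = []
    for a in range(0, len(s) - window + 1, step):
        b = a + window
        ng = int(gcum[b] - gcum[a])
        nc = int(ccum[b] - ccum[a])
        if ng + nc == 0:
            out.append((a + window // 2 + 1, 0.0, True))
        else:
            out.append((a + window // 2 + 1, (ng - nc) / (ng + nc), False))
    return out


def coding_density(genes: Sequence[GeneModel], genome_length: int) -> float:
    """100 * |union of CDS intervals| / genome_length, strands pooled."""
    if genome_length <= 0:
        raise ValueError("genome_length must be > 0")
    ivals = sorted((g.start, g.end) for g in genes if g.feature_class == "CDS")
    for a, b in ivals:
        if a < 1 or b > genome_length:
            raise ValueError(f"CDS ({a},{b}) outside genome bounds")
    covered = 0
    cur = None
    for a, b in ivals:
        if cur is None:
            cur = [a, b]
        elif a <= cur[1] + 1:
            cur[1] = max(cur[1], b)
        else:
            covered += cur[1] - cur[0] + 1
            cur = [a, b]
    if cur is not None:
        covered += cur[1] - cur[0] + 1
    return 100.0 * covered / genome_length


# ---------------------------------------------------------------------------
# pseudogene indicators


@dataclass
class PseudogeneCall:
    reference_protein_id: str
    query_locus: tuple[int, int]  # 1-based inclusive, forward genome coords
    strand: str
    indicators: set[str]

    def __post_init__(self):
        if not self.indicators:
            raise ValueError("a pseudogene call needs at least one indicator")
        unknown = self.indicators - set(INDICATORS)
        if unknown:
            raise ValueError(f"unknown indicators: {unknown}")


def _frame_translations(genome: str):
    """Yield (strand, frame, peptide) for all six frames."""
    for strand, seq in (("+", genome), ("-", reverse_complement(genome))):
        for f in range(3):
            sub = seq[f:]
            sub = sub[: len(sub) - len(sub) % 3]
            if sub:
                yield strand, f, str(Seq(sub).translate(table=11))


def _locate_protein(genome: str, protein: str, pk: int, min_seeds: int):
    """Seed a reference protein into the genome's six frames.

    Returns ``(strand, segments)`` where segments are diagonal clusters
    ``(diag_nt, r_min, r_max)`` in coordinates of the chosen strand
    (forward genome, or reverse-complemented genome for '-'), sorted by
    reference offset; or None when too few seeds match anywhere.
    """
    if len(protein) < pk:
        return None
    seeds: dict[str, list[int]] = {}
    for r in range(len(protein) - pk + 1):
        seeds.setdefault(protein[r:r + pk], []).append(r)
    by_strand: dict[str, dict[int, list[int]]] = {"+": {}, "-": {}}
    for strand, frame, pep in _frame_translations(genome):
        for p in range(len(pep) - pk + 1):
            for r in seeds.get(pep[p:p + pk], ()):
                g = frame + 3 * p          # nt position of the seed codon
                diag = g - 3 * r           # nt position where ref start maps
                by_strand[strand].setdefault(diag, []).append(r)
    best_strand = max("+-", key=lambda st: sum(len(v) for v in by_strand[st].values()))
    hits = by_strand[best_strand]
    total = sum(len(v) for v in hits.values())
    if total < min_seeds:
        return None
    segments = [(diag, min(rs), max(rs)) for diag, rs in hits.items()]
    segments.sort(key=lambda s: s[1])
    return best_strand, segments


def _codon(seq: str, pos: int) -> str | None:
    if pos < 0 or pos + 3 > len(seq):
        return None
    return seq[pos:pos + 3]


def call_pseudogene_indicators(query_genome: str, reference_proteins: Sequence[FastaRecord],
                               *, peptide_seed: int = 8, min_seeds: int = 3,
                               query_genes: Sequence[GeneModel] | None = None):
    """Classify each reference protein's best query locus for gene lesions.

    Returns ``(calls, indicator_counts, missing)``: pseudogene calls (only
    loci with at least one indicator), per-indicator totals, and reference
    proteins with no detectable locus (absence is not pseudogenization).

    Frameshift: seed clusters on one strand whose nucleotide diagonals
    differ by a non-multiple of three.  Internal stop: an in-frame stop
    interrupting a cluster's span.  Missing start / stop: the codon at the
    mapped reference start / end is not a valid bacterial start / stop;
    these two are only judged when the locus is frame-consistent, since a
    frameshift already destroys the downstream frame.
    """
    if not reference_proteins:
        raise ValueError("reference proteome is empty")
    calls: list[PseudogeneCall] = []
    counts = {ind: 0 for ind in INDICATORS}
    missing: list[str] = []
    n = len(query_genome)
    rc = reverse_complement(query_genome)
    for ref in reference_proteins:
        prot = ref.sequence.upper().rstrip("*")
        located = _locate_protein(query_genome, prot, peptide_seed, min_seeds)
        if located is None:
            missing.append(ref.id)
            continue
        strand, segments = located
        work = query_genome if strand == "+" else rc
        indicators: set[str] = set()
        # frameshift: diagonal change not divisible by 3 between consecutive segments
        frameshift = any((b[0] - a[0]) % 3 != 0
                         for a, b in zip(segments, segments[1:]))
        if frameshift:
            indicators.add("frameshift")
        # internal stop: per segment, translate its covered span in its own frame
        for diag, r_min, r_max in segments:
            lo = max(0, diag + 3 * r_min)
            hi = min(len(work), diag + 3 * (r_max + peptide_seed))
            span = work[lo:lo + ((hi - lo) // 3) * 3]
            if span and "*" in str(Seq(span).translate(table=11)):
                indicators.add("internal_stop")
        if not frameshift:
            diag = segments[0][0]
            start_codon = _codon(work, diag)
            if start_codon is not None and start_codon not in START_CODONS and prot[0] == "M":
                indicators.add("missing_start")
            stop_codon = _codon(work, diag + 3 * len(prot))
            if stop_codon is not None and stop_codon not in STOP_CODONS:
                indicators.add("missing_stop")
        lo_nt = segments[0][0]
        hi_nt = segments[-1][0] + 3 * (len(prot) + 1)
        lo_nt, hi_nt = max(0, lo_nt), min(n, hi_nt)
        if strand == "-":
            locus = (n - hi_nt + 1, n - lo_nt)
        else:
            locus = (lo_nt + 1, hi_nt)
        if indicators:
            calls.append(PseudogeneCall(ref.id, locus, strand, indicators))
            for ind in indicators:
                counts[ind] += 1
    return calls, counts, missing


# ---------------------------------------------------------------------------
# feature summary


@dataclass
class FeatureSummary:
    genome_id: str
    genome_length: int
    gc_percent: float
    n_proteins_known: int = 0
    n_proteins_hypothetical: int = 0
    n_tRNA: int = 0
    n_rRNA: int = 0
    n_pseudogenes: int = 0
    pseudogene_indicator_counts: dict = field(default_factory=dict)
    n_ankyrin: int = 0
    n_transposase: int = 0
    n_phage: int = 0
    coding_density_percent: float = 0.0

    def rows(self) -> list[tuple[str, object]]:
        """Feature table rows in conventional comparison order."""
        out = [("Genome size (bp)", self.genome_length),
               ("%GC", round(self.gc_percent, 2)),
               ("Proteins (known function)", self.n_proteins_known),
               ("Proteins (hypothetical)", self.n_proteins_hypothetical),
               ("tRNA genes", self.n_tRNA),
               ("rRNA genes", self.n_rRNA),
               ("Pseudogenes", self.n_pseudogenes)]
        for ind in INDICATORS:
            out.append((f"Pseudogene indicator: {ind}",
                        self.pseudogene_indicator_counts.get(ind, 0)))
        out += [("Ankyrin genes", self.n_ankyrin),
                ("Transposases", self.n_transposase),
                ("Phage-related genes", self.n_phage),
                ("Coding density %", round(self.coding_density_percent, 2))]
        return out

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"feature\t{self.genome_id}\n")
            for name, value in self.rows():
                fh.write(f"{name}\t{value}\n")


def _product_has(product: str, keywords: Iterable[str]) -> bool:
    p = product.lower()
    return any(k in p for k in keywords)


def summarize_features(genome: Sequence[FastaRecord], genes: Sequence[GeneModel],
                       reference_proteins: Sequence[FastaRecord] | None = None,
                       genome_id: str | None = None,
                       ankyrin_keywords: Iterable[str] = ANKYRIN_KEYWORDS,
                       transposase_keywords: Iterable[str] = TRANSPOSASE_KEYWORDS,
                       phage_keywords: Iterable[str] = PHAGE_KEYWORDS) -> FeatureSummary:
    """Count annotated features and compute the sequence-level statistics."""
    if not genome:
        raise ValueError("empty genome")
    contigs = {r.id for r in genome}
    bad = [g.gene_id for g in genes if g.contig_id not in contigs]
    if bad:
        raise ValueError(f"annotation refers to unknown contigs: {bad[:3]}")
    full = "".join(r.sequence for r in genome)
    summary = FeatureSummary(
        genome_id=genome_id or genome[0].id,
        genome_length=len(full),
        gc_percent=gc_content(full))
    cds = [g for g in genes if g.feature_class == "CDS"]
    summary.n_tRNA = sum(g.feature_class == "tRNA" for g in genes)
    summary.n_rRNA = sum(g.feature_class == "rRNA" for g in genes)
    summary.n_proteins_hypothetical = sum(
        g.product.strip().lower() == "hypothetical protein" for g in cds)
    summary.n_proteins_known = len(cds) - summary.n_proteins_hypothetical
    summary.n_ankyrin = sum(_product_has(g.product, ankyrin_keywords) for g in cds)
    summary.n_transposase = sum(_product_has(g.product, transposase_keywords) for g in cds)
    summary.n_phage = sum(_product_has(g.product, phage_keywords) for g in cds)
    if len(genome) == 1:
        summary.coding_density_percent = coding_density(genes, len(full)) if cds else 0.0
    else:
        covered = sum(coding_density([g for g in genes if g.contig_id == r.id],
                                     len(r.sequence)) / 100.0 * len(r.sequence)
                      for r in genome)
        summary.coding_density_percent = 100.0 * covered / len(full)
    if reference_proteins:
        calls, counts, _ = call_pseudogene_indicators(full, reference_proteins)
        summary.n_pseudogenes = len(calls)
        summary.pseudogene_indicator_counts = counts
    return summary


def gc_vs_length_table(genomes: Sequence[tuple[str, Sequence[FastaRecord]]]):
    """Per-genome (id, length, GC%) table plus the rank correlation of
    length with GC across genomes (None with fewer than 3 rows)."""
    if not genomes:
        raise ValueError("need at least one genome")
    import pandas as pd

    rows = []
    for gid, records in genomes:
        seq = "".join(r.sequence for r in records)
        rows.append({"genome_id": gid, "length": len(seq),
                     "gc_percent": gc_content(seq)})
    table = pd.DataFrame(rows)
    rho = None
    if len(rows) == 2:
        rho = 1.0 if (rows[0]["length"] - rows[1]["length"]) * (
            rows[0]["gc_percent"] - rows[1]["gc_percent"]) > 0 else -1.0
    elif len(rows) > 2:
        rho = float(stats.spearmanr(table["length"], table["gc_percent"]).statistic)
    return table, rho
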