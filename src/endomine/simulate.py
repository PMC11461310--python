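"""Synthetic study generator.

Every input the mining pipeline consumes can be generated here with full
ground truth: a host scaffold carrying an embedded symbiont-derived span
flanked by N-gap junctions and host flanks, long reads with a controlled
host/symbiont coverage differential, labeled reference panels, annotated
genomes, and gene->GO universes with a planted enriched term.

The default :class:`SimulationConfig` reproduces, at 1/100 scale, the
anatomy of the real discovery: a circular symbiont genome whose final
``overlap_length`` bases are withheld when the genome is linearized into
the scaffold, so that re-assembly across the junction gaps recreates a
terminal overlap and closes the circle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np

from endomine.io import AlignmentRecord, FastaRecord
from endomine.screen import PanelEntry, ReferencePanel

BASES = np.frombuffer(b"ACGT", dtype="S1")
READ_MIN_LENGTH = 500


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study.

    Defaults mirror the discovered scaffold anatomy at 1/100 scale:
    a 10,780 bp circular symbiont inserted minus its final 262 bp,
    100 bp N-gaps at both junctions, 1,600/2,500 bp host flanks, and a
    strong host-over-symbiont coverage differential (60X vs 12X).
    """

    seed: int = 0
    symbiont_length: int = 10_780
    symbiont_gc: float = 0.33
    overlap_length: int = 262
    flank_lengths: tuple[int, int] = (1_600, 2_500)
    gap_lengths: tuple[int, int] = (100, 100)
    host_depth: float = 60.0
    symbiont_depth: float = 12.0
    read_length_mean: int = 1_500
    read_error_rate: float = 0.0
    panel_divergence: float = 0.02
    host_gc: float = 0.42

    def __post_init__(self):
        if self.symbiont_length <= 0:
            raise ValueError("symbiont_length must be > 0")
        if not 0.0 <= self.symbiont_gc <= 1.0:
            raise ValueError("symbiont_gc must be in [0, 1]")
        if not 0 <= self.overlap_length < self.symbiont_length:
            raise ValueError("overlap_length must satisfy 0 <= overlap < symbiont_length")
        if any(f <= 0 for f in self.flank_lengths):
            raise ValueError("flank lengths must be > 0")
        if any(g < 0 for g in self.gap_lengths):
            raise ValueError("gap lengths must be >= 0")
        if self.host_depth < 0 or self.symbiont_depth < 0:
            raise ValueError("depths must be >= 0")
        if self.read_length_mean <= 0:
            raise ValueError("read_length_mean must be > 0")
        if not 0.0 <= self.read_error_rate <= 1.0:
            raise ValueError("read_error_rate must be in [0, 1]")
        if not 0.0 <= self.panel_divergence <= 1.0:
            raise ValueError("panel_divergence must be in [0, 1]")


@dataclass
class TruthSet:
    """Ground truth of one simulated scaffold.

    ``symbiont_span`` is 1-based inclusive on the scaffold and covers the
    embedded (overlap-withheld) symbiont text; appending the withheld
    overlap to it reconstructs ``symbiont_circular_sequence`` exactly.
    """

    symbiont_circular_sequence: str
    scaffold: str
    symbiont_span: tuple[int, int]
    gap_intervals: list[tuple[int, int]]
    withheld_overlap: str
    read_origins: dict[str, str] = field(default_factory=dict)
    region_depths: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "TruthSet":
        d = json.loads(text)
        d["symbiont_span"] = tuple(d["symbiont_span"])
        d["gap_intervals"] = [tuple(g) for g in d["gap_intervals"]]
        return cls(**d)


# ---------------------------------------------------------------------------
# sequence generators


def random_dna(length: int, gc: float, rng: np.random.Generator) -> str:
    """I.i.d. bases with P(G)=P(C)=gc/2 and P(A)=P(T)=(1-gc)/2."""
    if length <= 0:
        raise ValueError("length must be > 0")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return BASES[idx].tobytes().decode("ascii")


def make_symbiont_genome(length: int, gc: float, seed: int) -> str:
    """A random circular genome (circular by convention; returned linearized)."""
    return random_dna(length, gc, np.random.default_rng(seed))


def mutate_sequence(seq: str, sub_rate: float, rng: np.random.Generator,
                    indel_rate: float = 0.0) -> str:
    """Apply i.i.d. substitutions (and optionally 1-base indels) to ``seq``."""
    arr = np.frombuffer(seq.encode("ascii"), dtype="S1").copy()
    n = len(arr)
    if sub_rate > 0:
        hit = np.where(rng.random(n) < sub_rate)[0]
        for i in hit:
            choices = [b for b in b"ACGT" if bytes([b]) != arr[i]]
            arr[i] = bytes([choices[rng.integers(len(choices))]])
    out = arr.tobytes().decode("ascii")
    if indel_rate > 0:
        chars = []
        for c in out:
            r = rng.random()
            if r < indel_rate / 2:
                continue  # deletion
            chars.append(c)
            if indel_rate / 2 <= r < indel_rate:
                chars.append("ACGT"[rng.integers(4)])  # insertion
        out = "".join(chars)
    return out


def make_host_scaffold(config: SimulationConfig) -> tuple[str, TruthSet]:
    """Build the scaffold: host flank + N-gap + symbiont(minus overlap) + N-gap + host flank."""
    rng = np.random.default_rng(config.seed)
    circle = random_dna(config.symbiont_length, config.symbiont_gc, rng)
    up, down = config.flank_lengths
    g1, g2 = config.gap_lengths
    up_seq = random_dna(up, config.host_gc, rng)
    down_seq = random_dna(down, config.host_gc, rng)
    embedded = circle[: config.symbiont_length - config.overlap_length] \
        if config.overlap_length else circle
    withheld = circle[config.symbiont_length - config.overlap_length:] \
        if config.overlap_length else ""
    scaffold = up_seq + "N" * g1 + embedded + "N" * g2 + down_seq
    span_start = up + g1 + 1
    span_end = up + g1 + len(embedded)
    gaps = []
    if g1:
        gaps.append((up + 1, up + g1))
    if g2:
        gaps.append((span_end + 1, span_end + g2))
    return scaffold, TruthSet(
        symbiont_circular_sequence=circle,
        scaffold=scaffold,
        symbiont_span=(span_start, span_end),
        gap_intervals=gaps,
        withheld_overlap=withheld,
    )


# ---------------------------------------------------------------------------
# long reads


@dataclass
class ReadTemplate:
    """A template to draw reads from, with optional scaffold placement.

    ``circular`` templates wrap; their reads are reported against
    ``ref_name`` only over the embedded prefix of length ``embedded_length``
    starting at 0-based scaffold offset ``ref_offset`` (the rest soft-clips),
    which is how a mapper would place reads from a resident circular genome
    onto the scaffold that embeds it linearly.
    """

    name: str
    sequence: str
    depth: float
    circular: bool = False
    ref_name: str | None = None
    ref_offset: int = 0
    embedded_length: int | None = None


def _draw_read_length(rng: np.random.Generator, mean: int, limit: int) -> int:
    excess = max(1, mean - READ_MIN_LENGTH)
    rl = READ_MIN_LENGTH + int(rng.geometric(1.0 / excess)) - 1
    return min(rl, limit)


def simulate_long_reads(templates: Sequence[ReadTemplate], config: SimulationConfig,
                        seed: int | None = None):
    """Draw reads to the target depth of every template.

    Returns ``(reads, sam_records, origins)`` where origins maps read id to
    template name.  Reads are drawn until total bases reach depth x length;
    substitution errors are applied at ``config.read_error_rate`` (alignment
    records keep all-M CIGARs, so the records stay truthful placements).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    reads: list[FastaRecord] = []
    sam: list[AlignmentRecord] = []
    origins: dict[str, str] = {}
    for t in templates:
        n = len(t.sequence)
        if n == 0:
            raise ValueError(f"empty template: {t.name}")
        if t.depth < 0:
            raise ValueError("depth must be >= 0")
        target = t.depth * n
        total = 0
        i = 0
        doubled = t.sequence + t.sequence if t.circular else t.sequence
        while total < target:
            rl = _draw_read_length(rng, config.read_length_mean, n)
            if t.circular:
                start = int(rng.integers(0, n))
            else:
                start = int(rng.integers(0, n - rl + 1))
            seq = doubled[start:start + rl]
            if config.read_error_rate > 0:
                seq = mutate_sequence(seq, config.read_error_rate, rng)
            rid = f"{t.name}_read{i}"
            reads.append(FastaRecord(rid, seq))
            origins[rid] = t.name
            if t.ref_name is not None:
                rec = _place_read(rid, seq, start, rl, t)
                if rec is not None:
                    sam.append(rec)
            total += rl
            i += 1
    return reads, sam, origins


def _place_read(rid: str, seq: str, start: int, rl: int, t: ReadTemplate):
    if not t.circular:
        return AlignmentRecord(rid, 0, t.ref_name, t.ref_offset + start + 1,
                               [(rl, "M")], seq)
    emb = t.embedded_length if t.embedded_length is not None else len(t.sequence)
    n = len(t.sequence)
    if start < emb:
        alen = min(rl, emb - start)
        cigar = [(alen, "M")]
        if rl > alen:
            cigar.append((rl - alen, "S"))
        return AlignmentRecord(rid, 0, t.ref_name, t.ref_offset + start + 1, cigar, seq)
    # read starts inside the withheld terminal region: it wraps and lands at
    # the start of the embedded span with a leading soft clip
    clip = n - start
    alen = min(rl - clip, emb)
    if alen <= 0:
        return None
    cigar = [(clip, "S"), (alen, "M")]
    tail = rl - clip - alen
    if tail > 0:
        cigar.append((tail, "S"))
    return AlignmentRecord(rid, 0, t.ref_name, t.ref_offset + 1, cigar, seq)


# ---------------------------------------------------------------------------
# reference panels


def make_reference_panels(n_per_group: int, groups: Sequence[str], panel_divergence: float,
                          seed: int, length: int = 10_000,
                          ancestors: dict[str, str] | None = None,
                          species: dict[str, str] | None = None) -> ReferencePanel:
    """Labeled panel: each group's members derive from a group ancestor by
    substitutions at ``panel_divergence``."""
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    if not groups:
        raise ValueError("empty group list")
    rng = np.random.default_rng(seed)
    entries: list[PanelEntry] = []
    for group in groups:
        if ancestors and group in ancestors:
            ancestor = ancestors[group]
        else:
            ancestor = random_dna(length, 0.4, rng)
        for i in range(n_per_group):
            seq = mutate_sequence(ancestor, panel_divergence, rng) if panel_divergence else ancestor
            sp = (species or {}).get(group, "")
            entries.append(PanelEntry(f"{group}_{i}", group, seq, sp))
    return ReferencePanel(entries)


# ---------------------------------------------------------------------------
# GO universes


def make_go_universe(n_genes: int, n_terms: int, planted_term: int | str,
                     planted_odds: float, seed: int, *,
                     study_fraction: float = 0.1,
                     prevalence_range: tuple[float, float] = (0.05, 0.30)):
    """Gene->GO universe with one term planted at elevated odds in the study set.

    Every term t annotates genes independently with a per-term prevalence
    p_t ~ Uniform(prevalence_range); the planted term annotates study-set
    genes with probability min(1, planted_odds * p_t) instead.  With
    ``planted_odds=1`` no term is enriched by construction.

    Returns ``(gene2go, study, universe)``.
    """
    if planted_odds < 1:
        raise ValueError("planted_odds must be >= 1")
    if n_genes < 1 or n_terms < 1:
        raise ValueError("need at least one gene and one term")
    terms = [f"GO:{i:07d}" for i in range(n_terms)]
    if isinstance(planted_term, int):
        if not 0 <= planted_term < n_terms:
            raise ValueError("planted_term must be among the generated terms")
        planted_term = terms[planted_term]
    if planted_term not in terms:
        raise ValueError("planted_term must be among the generated terms")
    rng = np.random.default_rng(seed)
    universe = [f"gene{i:05d}" for i in range(n_genes)]
    n_study = max(1, int(round(study_fraction * n_genes)))
    if n_study > n_genes:
        raise ValueError("study set larger than universe")
    study = sorted(rng.choice(universe, size=n_study, replace=False).tolist())
    study_set = set(study)
    lo, hi = prevalence_range
    gene2go: dict[str, set[str]] = {g: set() for g in universe}
    in_study = np.array([g in study_set for g in universe])
    for term in terms:
        p = float(rng.uniform(lo, hi)) if n_terms > 1 else 1.0
        p_study = min(1.0, planted_odds * p) if term == planted_term else p
        thresh = np.where(in_study, p_study, p)
        for gi in np.flatnonzero(rng.random(n_genes) < thresh):
            gene2go[universe[gi]].add(term)
    return gene2go, study, universe


# ---------------------------------------------------------------------------
# annotated genomes (for feature summaries and pseudogene batteries)

STOPS = ("TAA", "TAG", "TGA")
_NONSTOP_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                   if a + b + c not in STOPS]


def random_orf(n_codons: int, rng: np.random.Generator) -> str:
    """ATG + random non-stop codons + TAA."""
    body = "".join(_NONSTOP_CODONS[rng.integers(len(_NONSTOP_CODONS))]
                   for _ in range(n_codons - 2))
    return "ATG" + body + "TAA"


def make_annotated_genome(n_cds: int = 8, n_trna: int = 2, n_rrna: int = 1,
                          seed: int = 0, products: Sequence[str] | None = None,
                          spacer: int = 120, cds_codons: tuple[int, int] = (80, 200)):
    """A genome of real ORFs with spacers, plus its annotation.

    Returns ``(sequence, genes)`` where genes are :class:`endomine.io.GeneModel`
    rows (CDS carry their translation).
    """
    from Bio.Seq import Seq
    from endomine.io import GeneModel

    rng = np.random.default_rng(seed)
    parts: list[str] = []
    genes = []
    pos = 0
    default_products = ["hypothetical protein"] * max(0, n_cds - 3) + [
        "ankyrin repeat protein", "IS5 family transposase", "phage tail protein"]
    prods = list(products) if products is not None else default_products[:n_cds]
    while len(prods) < n_cds:
        prods.append("hypothetical protein")
    contig = "chr1"
    for i in range(n_cds):
        gap = random_dna(spacer, 0.35, rng)
        parts.append(gap)
        pos += spacer
        orf = random_orf(int(rng.integers(*cds_codons)), rng)
        parts.append(orf)
        genes.append(GeneModel(
            gene_id=f"cds{i:03d}", contig_id=contig, start=pos + 1,
            end=pos + len(orf), strand="+", feature_class="CDS",
            product=prods[i],
            translation=str(Seq(orf).translate(table=11)).rstrip("*")))
        pos += len(orf)
    for i in range(n_trna):
        gap = random_dna(spacer, 0.35, rng)
        parts.append(gap)
        pos += spacer
        t = random_dna(76, 0.5, rng)
        parts.append(t)
        genes.append(GeneModel(f"trna{i:03d}", contig, pos + 1, pos + 76, "+",
                               "tRNA", product=f"tRNA-Ala"))
        pos += 76
    for i in range(n_rrna):
        gap = random_dna(spacer, 0.35, rng)
        parts.append(gap)
        pos += spacer
        r = random_dna(1500, 0.5, rng)
        parts.append(r)
        genes.append(GeneModel(f"rrna{i:03d}", contig, pos + 1, pos + 1500, "+",
                               "rRNA", product="16S ribosomal RNA"))
        pos += 1500
    parts.append(random_dna(spacer, 0.35, rng))
    return "".join(parts), genes


# ---------------------------------------------------------------------------
# the bundled study


@dataclass
class Dataset:
    """Everything one synthetic mining run needs, with truth attached."""

    config: SimulationConfig
    scaffold_id: str
    scaffold: str
    truth: TruthSet
    reads: list[FastaRecord]
    alignments: list[AlignmentRecord]
    symbiont_panel: ReferencePanel
    broad_panel: ReferencePanel


def make_dataset(config: SimulationConfig, scaffold_id: str = "scaffold_1",
                 n_panel: int = 3) -> Dataset:
    """Generate the full synthetic study for one scaffold.

    Host reads come from the two flanks at ``host_depth``; symbiont reads
    come from the *circular* genome at ``symbiont_depth`` (so some wrap the
    withheld terminal overlap — the raw material for gap filling and
    circularization).  Panels: a symbiont panel derived from the true circle
    (group ``PPN_symbiont``), and a broad panel adding an unrelated symbiont
    group and a host group derived from the flanks.
    """
    scaffold, truth = make_host_scaffold(config)
    up, down = config.flank_lengths
    g1, g2 = config.gap_lengths
    emb = config.symbiont_length - config.overlap_length
    span_offset = up + g1  # 0-based offset of the embedded span
    templates = [
        ReadTemplate("host_up", scaffold[:up], config.host_depth,
                     ref_name=scaffold_id, ref_offset=0),
        ReadTemplate("symbiont", truth.symbiont_circular_sequence,
                     config.symbiont_depth, circular=True,
                     ref_name=scaffold_id, ref_offset=span_offset,
                     embedded_length=emb),
        ReadTemplate("host_down", scaffold[len(scaffold) - down:],
                     config.host_depth, ref_name=scaffold_id,
                     ref_offset=len(scaffold) - down),
    ]
    reads, sam, origins = simulate_long_reads(templates, config, seed=config.seed + 1)
    truth.read_origins = origins
    truth.region_depths = {"host_up": config.host_depth,
                           "symbiont": config.symbiont_depth,
                           "host_down": config.host_depth}
    rng = np.random.default_rng(config.seed + 2)
    host_ancestor = scaffold[:up] + scaffold[len(scaffold) - down:]
    symbiont_panel = make_reference_panels(
        n_panel, ["PPN_symbiont"], config.panel_divergence, config.seed + 3,
        ancestors={"PPN_symbiont": truth.symbiont_circular_sequence})
    other_ancestor = random_dna(config.symbiont_length, 0.35, rng)
    broad_panel = make_reference_panels(
        n_panel, ["PPN_symbiont", "other_symbiont", "host"],
        config.panel_divergence, config.seed + 4,
        ancestors={"PPN_symbiont": truth.symbiont_circular_sequence,
                   "other_symbiont": other_ancestor,
                   "host": host_ancestor})
    return Dataset(config, scaffold_id, scaffold, truth, reads, sam,
                   symbiont_panel, broad_panel)
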