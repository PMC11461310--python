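"""End-to-end mining pipeline: screen -> anatomy -> coverage -> circularize -> features.

``run_mine`` chains the stages over an assembly: windows of each scaffold
are classified against the symbiont and broad panels, window labels and
N-gaps are merged into a scaffold anatomy, read pileup feeds the
endosymbiont-vs-HGT origin test, junction-spanning reads fill the gap and
close the circle, and the circular genome is summarized.  A run is a pure
function of its config (including the seed): identical config produces an
identical report.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from endomine import io as eio
from endomine.anatomy import ScaffoldAnnotation, delineate_regions, find_n_gaps
from endomine.circularize import (CircularGenome, canonical_rotation, circularize,
                                  detect_terminal_overlap, gap_fill)
from endomine.coverage import OriginCall, origin_test, pileup_depth, write_region_summary
from endomine.features import FeatureSummary, summarize_features
from endomine.screen import ReferencePanel, ScreenParams, windowed_two_step


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class AnatomyParams:
    min_gap_run: int = 10
    snap_distance: int | None = None  # default: one screening window


@dataclass
class CoverageParams:
    low_ratio: float = 0.5
    high_ratio: float = 2.0


@dataclass
class CircularizeParams:
    anchor_len: int = 200
    min_spanning_reads: int = 3
    min_overlap: int = 50
    min_identity: float = 95.0
    junction_window: int = 5_000  # how far from the terminus reads are collected
    anchor: str | None = None     # optional rotation anchor sequence


@dataclass
class PipelineConfig:
    assembly: str
    alignments: str
    symbiont_panel: str
    broad_panel: str
    reads: str | None = None
    annotation: str | None = None
    reference_proteins: str | None = None
    outdir: str = "endomine_out"
    seed: int = 0
    screen: ScreenParams = field(default_factory=ScreenParams)
    anatomy: AnatomyParams = field(default_factory=AnatomyParams)
    coverage: CoverageParams = field(default_factory=CoverageParams)
    circularize: CircularizeParams = field(default_factory=CircularizeParams)

    _BLOCKS = {"screen": ScreenParams, "anatomy": AnatomyParams,
               "coverage": CoverageParams, "circularize": CircularizeParams}

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        top_fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - top_fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for key, value in raw.items():
            if key in cls._BLOCKS:
                block_cls = cls._BLOCKS[key]
                block_fields = {f.name for f in dataclasses.fields(block_cls)}
                bad = set(value) - block_fields
                if bad:
                    raise ValueError(f"unknown keys in '{key}' block: {sorted(bad)}")
                kwargs[key] = block_cls(**value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


@dataclass
class MiningReport:
    """Machine-readable result of one mining run; JSON round-trips losslessly."""

    status: str  # symbiont_found | no_symbiont
    parameters: dict
    scaffold_annotations: dict  # scaffold_id -> annotation dict
    origin: dict | None = None
    circular_genome: dict | None = None
    features: dict | None = None
    version: str = ""

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "MiningReport":
        return cls(**json.loads(text))


def _annotation_dict(ann: ScaffoldAnnotation) -> dict:
    return json.loads(ann.to_json())


def _jsonable(obj) -> dict:
    """Normalize a dataclass dict to JSON-native types (tuples -> lists)."""
    return json.loads(json.dumps(asdict(obj)))


def run_mine(config: PipelineConfig) -> MiningReport:
    """Run the full chain and write all artifacts under ``config.outdir``."""
    from endomine import __version__

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # ---- inputs -----------------------------------------------------------
    try:
        assembly = eio.read_fasta(config.assembly)
        if not assembly:
            raise ValueError("assembly contains no sequences")
        symbiont_panel = ReferencePanel.from_fasta(eio.read_fasta(config.symbiont_panel))
        broad_panel = ReferencePanel.from_fasta(eio.read_fasta(config.broad_panel))
    except Exception as exc:
        raise StageError("screen", str(exc)) from exc
    alignments = eio.read_alignments(config.alignments)
    reads = eio.read_fasta(config.reads) if config.reads else []

    # ---- screen + anatomy -------------------------------------------------
    annotations: dict[str, ScaffoldAnnotation] = {}
    for rec in assembly:
        try:
            labels = windowed_two_step(rec.id, rec.sequence, symbiont_panel,
                                       broad_panel, config.screen)
        except Exception as exc:
            raise StageError("screen", f"{rec.id}: {exc}") from exc
        try:
            gaps = find_n_gaps(rec.sequence, config.anatomy.min_gap_run)
            snap = config.anatomy.snap_distance
            ann = delineate_regions(rec.id, len(rec.sequence), labels, gaps,
                                    window_size=min(config.screen.window_size,
                                                    len(rec.sequence)),
                                    snap_distance=snap)
        except Exception as exc:
            raise StageError("anatomy", f"{rec.id}: {exc}") from exc
        annotations[rec.id] = ann
        ann.write_bed(outdir / f"{rec.id}.segments.bed")
        ann.write_tsv(outdir / f"{rec.id}.segments.tsv")

    report = MiningReport(
        status="no_symbiont",
        parameters={"seed": config.seed,
                    "screen": asdict(config.screen),
                    "anatomy": asdict(config.anatomy),
                    "coverage": asdict(config.coverage),
                    "circularize": asdict(config.circularize)},
        scaffold_annotations={sid: _annotation_dict(a) for sid, a in annotations.items()},
        version=__version__)

    best = max((a for a in annotations.values() if a.symbiont_span),
               key=lambda a: a.symbiont_span[1] - a.symbiont_span[0], default=None)
    if best is None:
        (outdir / "report.json").write_text(report.to_json())
        return report
    report.status = "symbiont_found"
    scaffold = next(r for r in assembly if r.id == best.scaffold_id)

    # ---- coverage ---------------------------------------------------------
    try:
        profile = pileup_depth(alignments, best.scaffold_id, best.scaffold_length)
        call = origin_test(best, profile, config.coverage.low_ratio,
                           config.coverage.high_ratio)
    except Exception as exc:
        raise StageError("coverage", str(exc)) from exc
    write_region_summary(profile, best, outdir / "region_coverage.tsv")
    report.origin = _jsonable(call)

    # ---- circularize ------------------------------------------------------
    try:
        genome = _close_circle(scaffold.sequence, best, reads, config.circularize)
    except Exception as exc:
        raise StageError("circularize", str(exc)) from exc
    report.circular_genome = {
        "length": len(genome.sequence), "is_circular": genome.is_circular,
        "merged_overlap": genome.merged_overlap,
        "rotation_offset": genome.rotation_offset}
    eio.write_fasta([eio.FastaRecord(
        "symbiont_genome", genome.sequence,
        f"circular={'true' if genome.is_circular else 'false'} "
        f"merged_overlap={genome.merged_overlap} rotation_offset={genome.rotation_offset}")],
        outdir / "symbiont_genome.fasta")

    # ---- features ---------------------------------------------------------
    try:
        genes = eio.read_gff3(config.annotation) if config.annotation else []
        refs = eio.read_fasta(config.reference_proteins) if config.reference_proteins else None
        summary = summarize_features(
            [eio.FastaRecord("symbiont_genome", genome.sequence)],
            [g for g in genes if g.contig_id == "symbiont_genome"],
            reference_proteins=refs)
    except Exception as exc:
        raise StageError("features", str(exc)) from exc
    summary.write_tsv(outdir / "features.tsv")
    report.features = _jsonable(summary)

    (outdir / "report.json").write_text(report.to_json())
    return report


def _close_circle(scaffold: str, ann: ScaffoldAnnotation, reads, params: CircularizeParams) \
        -> CircularGenome:
    """Gap-fill the downstream junction, detect the terminal overlap, merge."""
    s, e = ann.symbiont_span
    region = scaffold[s - 1:e]
    junction_reads = [r.sequence for r in reads]
    genome = CircularGenome(region, False, 0)
    extension = None
    if junction_reads:
        extension = gap_fill(region, junction_reads, junction="downstream",
                             anchor_len=params.anchor_len,
                             min_spanning_reads=params.min_spanning_reads)
    extended = region + extension.sequence if extension else region
    if len(extended) > 2 * params.min_overlap:
        overlap = detect_terminal_overlap(extended, params.min_overlap,
                                          params.min_identity)
        if overlap is not None:
            genome = circularize(extended, overlap)
            genome = canonical_rotation(genome, params.anchor)
    return genome
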