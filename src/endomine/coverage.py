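"""Per-base fold coverage and the coverage-differential origin test.

A genuinely resident endosymbiont and its host are sequenced from different
numbers of genome copies per cell, so their assemblies attract read depths
that can differ by orders of magnitude.  A true horizontal transfer into the
host chromosome, by contrast, travels with the host and shows host-like
depth.  The origin test therefore compares mean depth over the symbiont span
to the mean of the two host flank means and combines the ratio with the
presence of junction N-gaps:

* ratio far from 1 (outside ``[low_ratio, high_ratio]``) *and* gap-flanked
  junctions -> ENDOSYMBIONT (the apparent integration is an assembly artifact);
* host-like ratio with seamless (gap-free) junctions -> HGT_CANDIDATE;
* anything else -> AMBIGUOUS.

The discordance direction (symbiont above or below host depth) is recorded
in the evidence notes, not judged: free symbiont DNA can be enriched or
depleted relative to host tissue depending on extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from endomine.anatomy import ScaffoldAnnotation
from endomine.io import AlignmentRecord


@dataclass
class DepthProfile:
    """Per-base depth over [1, scaffold_length]."""

    scaffold_id: str
    depth: np.ndarray  # int32, length = scaffold_length

    def __post_init__(self):
        self.depth = np.asarray(self.depth, dtype=np.int32)
        if (self.depth < 0).any():
            raise ValueError("depth values must be >= 0")

    @property
    def scaffold_length(self) -> int:
        return len(self.depth)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for i, d in enumerate(self.depth, 1):
                fh.write(f"{self.scaffold_id}\t{i}\t{int(d)}\n")


@dataclass
class OriginCall:
    verdict: str  # ENDOSYMBIONT | HGT_CANDIDATE | AMBIGUOUS
    coverage_ratio: float
    gap_flanked: bool
    evidence_notes: list[str] = field(default_factory=list)
    symbiont_mean: float = 0.0
    flank_means: tuple[float, float] = (0.0, 0.0)


def pileup_depth(alignments: list[AlignmentRecord], scaffold_id: str,
                 scaffold_length: int) -> DepthProfile:
    """Depth = number of records whose CIGAR consumes a base with M/=/X.

    D and N consume reference without adding depth; I/S/H consume none.
    Unmapped, secondary and supplementary records are skipped.
    """
    diff = np.zeros(scaffold_length + 1, dtype=np.int32)
    for rec in alignments:
        if rec.reference_name != scaffold_id:
            continue
        if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
            continue
        pos = rec.position - 1  # 0-based reference cursor
        for n, op in rec.cigar:
            if op in "M=X":
                if pos + n > scaffold_length:
                    raise ValueError(
                        f"{rec.query_name}: alignment runs past scaffold end "
                        f"({pos + n} > {scaffold_length})")
                diff[pos] += 1
                diff[pos + n] -= 1
                pos += n
            elif op in "DN":
                pos += n
            # I, S, H, P: no reference consumption
    return DepthProfile(scaffold_id, np.cumsum(diff[:-1]))


def region_mean_coverage(profile: DepthProfile, interval: tuple[int, int]) -> float:
    """Arithmetic mean depth over a 1-based inclusive interval."""
    a, b = interval
    if a < 1 or b > profile.scaffold_length or a > b:
        raise ValueError(f"interval ({a},{b}) empty or out of bounds")
    return float(profile.depth[a - 1:b].mean())


def coverage_ratio(symbiont_mean: float, flank_means: tuple[float, float]) -> float:
    """R = symbiont mean depth / unweighted mean of the flank means."""
    denom = (flank_means[0] + flank_means[1]) / 2.0
    if denom == 0:
        return float("inf") if symbiont_mean > 0 else 0.0
    return symbiont_mean / denom


def verdict_from_ratio(ratio: float, gap_flanked: bool,
                       low_ratio: float = 0.5, high_ratio: float = 2.0) -> str:
    extreme = ratio <= low_ratio or ratio >= high_ratio
    if extreme and gap_flanked:
        return "ENDOSYMBIONT"
    if not extreme and not gap_flanked:
        return "HGT_CANDIDATE"
    return "AMBIGUOUS"


def origin_test(annotation: ScaffoldAnnotation, profile: DepthProfile,
                low_ratio: float = 0.5, high_ratio: float = 2.0) -> OriginCall:
    """Coverage-differential verdict for the annotated symbiont span."""
    if annotation.symbiont_span is None:
        raise ValueError("annotation has no symbiont span")
    up_len, down_len = annotation.flank_lengths
    notes: list[str] = []
    flank_means = []
    if up_len > 0:
        flank_means.append(region_mean_coverage(profile, (1, up_len)))
    if down_len > 0:
        flank_means.append(region_mean_coverage(
            profile, (annotation.scaffold_length - down_len + 1, annotation.scaffold_length)))
    if not flank_means:
        raise ValueError("annotation has no host flank")
    if len(flank_means) == 1:
        flank_means = flank_means * 2
        notes.append("single flank; its mean used for both sides")
    sym_mean = region_mean_coverage(profile, annotation.symbiont_span)
    if flank_means[0] == 0 and flank_means[1] == 0:
        notes.append("zero flank coverage; ratio undefined")
        return OriginCall("AMBIGUOUS", float("inf") if sym_mean else 0.0,
                          annotation.gap_flanked, notes, sym_mean,
                          (flank_means[0], flank_means[1]))
    ratio = coverage_ratio(sym_mean, (flank_means[0], flank_means[1]))
    notes.append("symbiont depth below host flanks" if ratio < 1.0
                 else "symbiont depth above host flanks")
    verdict = verdict_from_ratio(ratio, annotation.gap_flanked, low_ratio, high_ratio)
    return OriginCall(verdict, ratio, annotation.gap_flanked, notes,
                      sym_mean, (flank_means[0], flank_means[1]))


def write_region_summary(profile: DepthProfile, annotation: ScaffoldAnnotation, path) -> None:
    with open(path, "w") as fh:
        fh.write("scaffold\tstart\tend\tlabel\tmean_depth\n")
        for seg in annotation.segments:
            m = region_mean_coverage(profile, (seg.start, seg.end))
            fh.write(f"{annotation.scaffold_id}\t{seg.start}\t{seg.end}\t{seg.label}\t{m:.2f}\n")
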