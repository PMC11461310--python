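"""Scaffold anatomy: from window labels and N-gaps to an ordered segmentation.

A scaffold harboring an embedded symbiont shows a characteristic anatomy:
a long symbiont-matching span flanked by runs of uncalled bases (N-gaps)
at the junctions, with host-matching flanks outside.  This module merges
per-window homology labels into maximal segments, lets N-gap intervals
override window labels, snaps the symbiont span to the junction gap edges
(window labels cannot resolve the boundary below window granularity, the
gap edge can), and promotes the largest symbiont segment to the reported
span.

Coordinates are 0-based half-open internally and 1-based inclusive in all
reported structures and files, so published scaffold positions compare
directly.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from endomine.io import write_bed

_CODE = {"unclassified": 0, "host": 1, "symbiont": 2, "gap": 3}
_LABEL = {v: k for k, v in _CODE.items()}
# screening emits panel-group labels; both symbiont groups paint as symbiont
_ALIASES = {"PPN_symbiont": "symbiont", "other_symbiont": "symbiont"}


@dataclass
class Segment:
    start: int  # 1-based inclusive
    end: int
    label: str

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("segment start > end")
        if self.label not in _CODE:
            raise ValueError(f"unknown segment label: {self.label}")

    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class ScaffoldAnnotation:
    scaffold_id: str
    scaffold_length: int
    segments: list[Segment]
    symbiont_span: tuple[int, int] | None
    flank_lengths: tuple[int, int]

    @property
    def gap_flanked(self) -> bool:
        """True when gap segments directly abut both ends of the symbiont span."""
        if self.symbiont_span is None:
            return False
        s, e = self.symbiont_span
        up = any(seg.label == "gap" and seg.end == s - 1 for seg in self.segments)
        down = any(seg.label == "gap" and seg.start == e + 1 for seg in self.segments)
        return up and down

    def to_json(self) -> str:
        return json.dumps({
            "scaffold_id": self.scaffold_id,
            "scaffold_length": self.scaffold_length,
            "segments": [asdict(s) for s in self.segments],
            "symbiont_span": list(self.symbiont_span) if self.symbiont_span else None,
            "flank_lengths": list(self.flank_lengths),
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ScaffoldAnnotation":
        d = json.loads(text)
        return cls(d["scaffold_id"], d["scaffold_length"],
                   [Segment(**s) for s in d["segments"]],
                   tuple(d["symbiont_span"]) if d["symbiont_span"] else None,
                   tuple(d["flank_lengths"]))

    def write_bed(self, path) -> None:
        write_bed([(self.scaffold_id, s.start, s.end, s.label) for s in self.segments], path)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("scaffold\tstart\tend\tlabel\n")
            for s in self.segments:
                fh.write(f"{self.scaffold_id}\t{s.start}\t{s.end}\t{s.label}\n")


def find_n_gaps(sequence: str, min_run: int) -> list[tuple[int, int]]:
    """Maximal runs of N of length >= min_run, as 1-based inclusive intervals."""
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    return [(m.start() + 1, m.end())
            for m in re.finditer(f"N{{{min_run},}}", sequence.upper())]


def _runs(code: np.ndarray) -> list[Segment]:
    edges = np.flatnonzero(np.diff(code)) + 1
    starts = np.concatenate(([0], edges))
    ends = np.concatenate((edges, [len(code)]))
    return [Segment(int(a) + 1, int(b), _LABEL[int(code[a])])
            for a, b in zip(starts, ends)]


def delineate_regions(scaffold_id: str, scaffold_length: int,
                      window_labels: Sequence[tuple[tuple[int, int], str]],
                      gaps: Sequence[tuple[int, int]],
                      window_size: int = 10_000,
                      snap_distance: int | None = None) -> ScaffoldAnnotation:
    """Merge window labels and gaps into a tiling segmentation.

    Rules, in order: window labels paint bases with symbiont > host >
    unclassified priority on overlap; gap intervals override; unclassified
    runs shorter than two windows between two same-label segments inherit
    that label; the largest symbiont stretch (gaps internal to it count as
    contiguity, not interruption) becomes ``symbiont_span``, with its outer
    boundaries snapped to an abutting junction-gap edge within
    ``snap_distance`` (default: one window).
    """
    if snap_distance is None:
        snap_distance = window_size
    code = np.zeros(scaffold_length, dtype=np.int8)
    for (a, b), label in window_labels:
        if a < 1 or b > scaffold_length or a > b:
            raise ValueError(f"window ({a},{b}) outside scaffold bounds")
        c = _CODE[_ALIASES.get(label, label)]
        if c == _CODE["gap"]:
            code[a - 1:b] = c
        else:
            np.maximum(code[a - 1:b], c, out=code[a - 1:b])
    for (a, b) in gaps:
        if a < 1 or b > scaffold_length or a > b:
            raise ValueError(f"gap ({a},{b}) outside scaffold bounds")
        code[a - 1:b] = _CODE["gap"]

    # short unclassified runs between identical labels inherit that label
    segs = _runs(code)
    for i, seg in enumerate(segs):
        if seg.label != "unclassified" or seg.length() >= 2 * window_size:
            continue
        left = segs[i - 1].label if i > 0 else None
        right = segs[i + 1].label if i + 1 < len(segs) else None
        if left is not None and left == right and left in ("host", "symbiont"):
            code[seg.start - 1:seg.end] = _CODE[left]

    span = _largest_symbiont_stretch(code)
    if span is not None:
        span = _snap_to_gaps(code, span, gaps, snap_distance)
    segments = _runs(code)

    flanks = (0, 0)
    if span is not None:
        s, e = span
        up_gap = next((g for g in gaps if g[1] == s - 1), None)
        down_gap = next((g for g in gaps if g[0] == e + 1), None)
        up_edge = up_gap[0] - 1 if up_gap else s - 1
        down_edge = down_gap[1] if down_gap else e
        flanks = (up_edge, scaffold_length - down_edge)
    return ScaffoldAnnotation(scaffold_id, scaffold_length, segments, span, flanks)


def _largest_symbiont_stretch(code: np.ndarray) -> tuple[int, int] | None:
    """Largest symbiont stretch, where internal gap runs do not break contiguity."""
    segs = _runs(code)
    best = None
    i = 0
    while i < len(segs):
        if segs[i].label != "symbiont":
            i += 1
            continue
        j = i
        # extend over symbiont and *internal* gap segments
        while j + 1 < len(segs) and segs[j + 1].label in ("symbiont", "gap"):
            if segs[j + 1].label == "gap" and not (
                    j + 2 < len(segs) and segs[j + 2].label == "symbiont"):
                break
            j += 1
        stretch = (segs[i].start, segs[j].end)
        length = stretch[1] - stretch[0] + 1
        if best is None or length > best[1] - best[0] + 1:
            best = stretch
        i = j + 1
    return best


def _snap_to_gaps(code: np.ndarray, span: tuple[int, int],
                  gaps: Sequence[tuple[int, int]], snap: int) -> tuple[int, int]:
    s, e = span
    up = _nearest_gap_edge(gaps, s, snap, upstream=True)
    if up is not None and up <= e:
        if up < s:
            code[up - 1:s - 1] = _CODE["symbiont"]
        elif up > s:
            outer = _CODE["host"] if _neighbor_is(code, s - 2, -1, _CODE["host"]) else _CODE["unclassified"]
            code[s - 1:up - 1][code[s - 1:up - 1] == _CODE["symbiont"]] = outer
        s = up
    down = _nearest_gap_edge(gaps, e, snap, upstream=False)
    if down is not None and down >= s:
        if down > e:
            code[e:down] = _CODE["symbiont"]
        elif down < e:
            outer = _CODE["host"] if _neighbor_is(code, e, +1, _CODE["host"]) else _CODE["unclassified"]
            code[down:e][code[down:e] == _CODE["symbiont"]] = outer
        e = down
    return (s, e)


def _nearest_gap_edge(gaps, boundary: int, snap: int, upstream: bool) -> int | None:
    """Inner edge (facing the symbiont) of the gap nearest a span boundary."""
    best = None
    for (a, b) in gaps:
        edge = b + 1 if upstream else a - 1
        dist = abs(edge - boundary)
        if dist <= snap and (best is None or dist < best[0]):
            best = (dist, edge)
    return best[1] if best else None


def _neighbor_is(code: np.ndarray, idx0: int, step: int, want: int) -> bool:
    """Whether the first non-symbiont, non-gap base from idx0 (walking by
    ``step``) carries code ``want``."""
    j = idx0
    while 0 <= j < len(code) and code[j] in (_CODE["symbiont"], _CODE["gap"]):
        j += step
    return 0 <= j < len(code) and code[j] == want
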