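"""Closing the circle: gap filling, terminal-overlap detection, rotation.

A circular bacterial genome embedded linearly in a host scaffold loses the
sequence that spans its artificial endpoints.  Long reads that cross a
junction recover it: reads anchored at the region terminus are stacked and
a column-wise majority vote extends the sequence past the terminus.  When
the extension runs past the (circular) origin it duplicates the start of
the region, producing a terminal overlap; trimming one copy of the overlap
closes the circle.  Rotation is then canonicalized so that any two
assemblies of the same circle compare as equal strings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from endomine.align import local_align, reverse_complement


@dataclass
class ExtensionConsensus:
    sequence: str
    supporting_reads: int
    junction: str  # upstream | downstream

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("empty extension consensus")
        if self.junction not in ("upstream", "downstream"):
            raise ValueError("junction must be upstream or downstream")


@dataclass
class OverlapMatch:
    length: int
    identity: float
    end_offset: int    # 0-based start of the matching suffix
    start_offset: int  # 0-based start of the matching prefix (always 0)
    low_complexity: bool = False


@dataclass
class CircularGenome:
    sequence: str
    is_circular: bool
    merged_overlap: int
    rotation_offset: int = 0

    def __len__(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------
# gap filling


def _anchor_offset(read: str, anchor: str, k: int, min_identity: float):
    """Locate ``anchor`` in ``read`` by exact k-mer seeding on a single diagonal.

    Returns the 0-based read offset where the anchor starts (may be negative
    if the read begins inside the anchor), or None.  Verification is gapless
    identity over the overlapping portion.
    """
    index: dict[str, list[int]] = {}
    for i in range(len(anchor) - k + 1):
        index.setdefault(anchor[i:i + k], []).append(i)
    votes: dict[int, int] = {}
    for j in range(len(read) - k + 1):
        for i in index.get(read[j:j + k], ()):
            d = j - i  # read offset of anchor start implied by this seed
            votes[d] = votes.get(d, 0) + 1
    if not votes:
        return None
    d = max(votes, key=lambda key: (votes[key], -abs(key)))
    a_lo = max(0, -d)
    a_hi = min(len(anchor), len(read) - d)
    if a_hi - a_lo < k:
        return None
    matches = sum(anchor[i] == read[d + i] for i in range(a_lo, a_hi))
    if 100.0 * matches / (a_hi - a_lo) < min_identity:
        return None
    return d


def gap_fill(region_sequence: str, junction_reads: list[str], *,
             junction: str = "downstream", anchor_len: int = 200,
             anchor_seed: int = 21, min_spanning_reads: int = 3,
             min_anchor_identity: float = 90.0) -> ExtensionConsensus | None:
    """Majority-vote consensus extension past a region terminus.

    Reads are anchored to the terminal ``anchor_len`` bases of the region by
    exact ``anchor_seed``-mers (checked on both strands) and their portions
    extending beyond the terminus are stacked; each consensus column needs
    ``min_spanning_reads`` coverage, and the extension stops at the last
    column still supported.  Returns None (a distinct no-fill signal) when
    fewer than ``min_spanning_reads`` reads anchor.
    """
    if junction == "downstream":
        anchor = region_sequence[-anchor_len:]
    else:
        anchor = reverse_complement(region_sequence[:anchor_len])
    suffixes: list[str] = []
    for read in junction_reads:
        for oriented in (read, reverse_complement(read)):
            d = _anchor_offset(oriented, anchor, anchor_seed, min_anchor_identity)
            if d is None:
                continue
            tail = oriented[d + len(anchor):]
            if tail:
                suffixes.append(tail)
            break
    if len(suffixes) < min_spanning_reads:
        return None
    max_len = max(len(s) for s in suffixes)
    consensus: list[str] = []
    for col in range(max_len):
        column = [s[col] for s in suffixes if len(s) > col]
        if len(column) < min_spanning_reads:
            break
        values, counts = np.unique(column, return_counts=True)
        # deterministic tie-break: highest count, then alphabetical
        best = values[np.lexsort((values, -counts))][0]
        consensus.append(str(best))
    if not consensus:
        return None
    ext = "".join(consensus)
    if junction == "upstream":
        ext = reverse_complement(ext)
    return ExtensionConsensus(ext, len(suffixes), junction)


# ---------------------------------------------------------------------------
# terminal overlap and circularization


def detect_terminal_overlap(sequence: str, min_overlap: int = 50,
                            min_identity: float = 95.0,
                            max_overlap: int | None = None) -> OverlapMatch | None:
    """Longest gapless suffix-prefix match with identity >= min_identity.

    Terminal repeats arising from re-assembling one circular molecule differ
    only by sequencing error, so no gaps are allowed.  A degenerate
    (single-letter) sequence trivially matches at the maximal length; the
    result is returned with ``low_complexity=True``.
    """
    n = len(sequence)
    if n <= 2 * min_overlap:
        raise ValueError("sequence must be longer than twice min_overlap")
    limit = max_overlap if max_overlap is not None else n // 2
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    best = None
    for L in range(limit, min_overlap - 1, -1):
        matches = int((arr[:L] == arr[n - L:]).sum())
        if 100.0 * matches / L >= min_identity:
            best = OverlapMatch(L, 100.0 * matches / L, n - L, 0)
            break
    if best is not None and len(set(sequence[:best.length])) == 1:
        best.low_complexity = True
    return best


def circularize(linear: str, overlap: OverlapMatch) -> CircularGenome:
    """Trim one copy of the terminal overlap and declare the molecule circular."""
    if overlap is None:
        raise ValueError("no overlap detected; cannot circularize")
    if overlap.length <= 0:
        raise ValueError("overlap length must be > 0")
    if overlap.length >= len(linear):
        raise ValueError("overlap length must be smaller than the sequence")
    return CircularGenome(linear[:len(linear) - overlap.length], True, overlap.length)


def _least_rotation_index(s: str) -> int:
    """Booth's algorithm: index of the lexicographically least rotation."""
    doubled = s + s
    f = [-1] * len(doubled)
    k = 0
    for j in range(1, len(doubled)):
        sj = doubled[j]
        i = f[j - k - 1]
        while i != -1 and sj != doubled[k + i + 1]:
            if sj < doubled[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != doubled[k + i + 1]:
            if sj < doubled[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return k


def canonical_rotation(genome: CircularGenome, anchor: str | None = None,
                       min_score: int = 50) -> CircularGenome:
    """Rotate a circular genome to a defined start.

    Without an anchor, the start is the lexicographically least rotation.
    With an anchor sequence, the rotation starts at its best local-alignment
    hit (falling back to the least rotation, with the offset recorded, if the
    anchor does not align above ``min_score``).
    """
    if not genome.is_circular:
        raise ValueError("genome must be circular")
    seq = genome.sequence
    offset = None
    if anchor is not None:
        doubled = seq + seq[:max(0, len(anchor) - 1)]
        try:
            hits = local_align(anchor, doubled, min_score=min_score)
        except ValueError:
            hits = []
        plus = [h for h in hits if h.strand == "+"]
        if plus:
            offset = plus[0].s_start % len(seq)
    if offset is None:
        offset = _least_rotation_index(seq)
    rotated = seq[offset:] + seq[:offset]
    total = (genome.rotation_offset + offset) % len(seq)
    return CircularGenome(rotated, True, genome.merged_overlap, total)


def is_rotation(a: str, b: str) -> bool:
    """Exact circular-string equality."""
    return len(a) == len(b) and b in a + a
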