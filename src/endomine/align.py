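"""Seeded local alignment.

The screening stages score contigs and windows against reference panels with
a seed-and-extend local aligner: exact k-mer seeds shared between query and
subject are clustered by diagonal, and each cluster is resolved by an affine
Smith-Waterman (Gotoh) pass over a rectangle around the cluster.  The scoring
scheme is fixed to the classic nucleotide-search defaults: match +2,
mismatch -3, and a gap of length L costs 5 + 2*(L-1).

``N`` never matches anything: it scores as a mismatch and is excluded from
seeds.  Both strands are searched for DNA; hits are reported in forward
coordinates of both sequences with a strand flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

MATCH = 2
MISMATCH = -3
GAP_OPEN = 5   # cost of the first gapped base
GAP_EXTEND = 2  # cost of each further gapped base

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class LocalAlignment:
    """A gapped local alignment hit.

    Spans are 0-based half-open in the forward orientation of each sequence.
    ``identity`` is percent matches over aligned columns (gap columns count).
    """

    score: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str
    matches: int
    mismatches: int
    gap_columns: int
    aligned_length: int

    @property
    def identity(self) -> float:
        return 100.0 * self.matches / self.aligned_length if self.aligned_length else 0.0


@njit(cache=True)
def _gotoh_local(q, s, match, mismatch, gap_open, gap_ext, ncode):
    """Affine-gap local DP over the full (len(q)+1) x (len(s)+1) rectangle.

    Returns (score, q_start, q_end, s_start, s_end, matches, mismatches,
    gap_columns); spans half-open.  Traceback pointers are packed per cell:
    bits 0-1 H-source (0 stop, 1 diag, 2 from E, 3 from F), bit 2 E extends,
    bit 3 F extends.
    """
    m, n = len(q), len(s)
    NEG = -(10 ** 9)
    h_prev = np.zeros(n + 1, np.int32)
    h_cur = np.zeros(n + 1, np.int32)
    f_row = np.full(n + 1, NEG, np.int32)
    tb = np.zeros((m + 1, n + 1), np.uint8)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        e = NEG
        h_cur[0] = 0
        qc = q[i - 1]
        for j in range(1, n + 1):
            ptr = np.uint8(0)
            # E: gap consuming subject (horizontal)
            e_open = h_cur[j - 1] - gap_open
            e_ext = e - gap_ext
            if e_ext > e_open:
                e = e_ext
                ptr |= 4
            else:
                e = e_open
            # F: gap consuming query (vertical)
            f_open = h_prev[j] - gap_open
            f_ext = f_row[j] - gap_ext
            if f_ext > f_open:
                f_row[j] = f_ext
                ptr |= 8
            else:
                f_row[j] = f_open
            sc = qc
            if sc == s[j - 1] and sc != ncode:
                diag = h_prev[j - 1] + match
            else:
                diag = h_prev[j - 1] + mismatch
            h = 0
            src = 0
            if diag > h:
                h = diag
                src = 1
            if e > h:
                h = e
                src = 2
            if f_row[j] > h:
                h = f_row[j]
                src = 3
            h_cur[j] = h
            tb[i, j] = ptr | np.uint8(src)
            if h > best:
                best = h
                bi = i
                bj = j
        tmp = h_prev
        h_prev = h_cur
        h_cur = tmp
    # traceback
    i, j = bi, bj
    matches = 0
    mismatches = 0
    gapcols = 0
    state = 0  # 0 = H, 1 = E, 2 = F
    while i > 0 and j > 0:
        cell = tb[i, j]
        if state == 0:
            src = cell & 3
            if src == 0:
                break
            if src == 1:
                if q[i - 1] == s[j - 1] and q[i - 1] != ncode:
                    matches += 1
                else:
                    mismatches += 1
                i -= 1
                j -= 1
            elif src == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            gapcols += 1
            ext = cell & 4
            j -= 1
            if not ext:
                state = 0
        else:
            gapcols += 1
            ext = cell & 8
            i -= 1
            if not ext:
                state = 0
    return best, i, bi, j, bj, matches, mismatches, gapcols


def _kmer_positions(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(i)
    return index


def _seed_matches(query: str, subject_index: dict[str, list[int]], k: int):
    out = []
    for i in range(len(query) - k + 1):
        kmer = query[i:i + k]
        if "N" in kmer:
            continue
        for j in subject_index.get(kmer, ()):
            out.append((j - i, i, j))
    return out


def _cluster_seeds(matches, diag_merge: int, pos_merge: int):
    """Group (diag, qpos, spos) seed matches into candidate regions."""
    matches.sort()
    clusters = []
    group: list[tuple[int, int, int]] = []
    for mtuple in matches:
        if group and mtuple[0] - group[-1][0] > diag_merge:
            clusters.extend(_split_by_qpos(group, pos_merge))
            group = []
        group.append(mtuple)
    if group:
        clusters.extend(_split_by_qpos(group, pos_merge))
    return clusters


def _split_by_qpos(group, pos_merge: int):
    group = sorted(group, key=lambda t: t[1])
    out = []
    cur = [group[0]]
    for t in group[1:]:
        if t[1] - cur[-1][1] > pos_merge:
            out.append(cur)
            cur = []
        cur.append(t)
    out.append(cur)
    return out


def _ascii(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


_SMALL_FULL_CELLS = 2_250_000  # below this, align the whole rectangle
_MAX_RECT_CELLS = 40_000_000


def _align_one_strand(query: str, subject: str, k: int, min_score: int,
                      pad: int, ncode: int, max_clusters: int):
    n_q, n_s = len(query), len(subject)
    if n_q < k or n_s < k:
        raise ValueError(f"seed length k={k} exceeds a sequence length")
    index = _kmer_positions(subject, k)
    seeds = _seed_matches(query, index, k)
    if not seeds:
        return []
    hits = []
    if n_q * n_s <= _SMALL_FULL_CELLS:
        rects = [(0, n_q, 0, n_s)]
    else:
        clusters = _cluster_seeds(seeds, diag_merge=60, pos_merge=600)
        clusters.sort(key=len, reverse=True)
        rects = []
        for cl in clusters[:max_clusters]:
            q_lo = max(0, min(t[1] for t in cl) - pad)
            q_hi = min(n_q, max(t[1] for t in cl) + k + pad)
            s_lo = max(0, min(t[2] for t in cl) - pad)
            s_hi = min(n_s, max(t[2] for t in cl) + k + pad)
            # keep rectangles bounded; long clusters are chunked along the query
            span_cells = (q_hi - q_lo) * (s_hi - s_lo)
            if span_cells > _MAX_RECT_CELLS:
                step = max(1, _MAX_RECT_CELLS // max(1, s_hi - s_lo))
                for qa in range(q_lo, q_hi, step):
                    rects.append((qa, min(q_hi, qa + step + pad), s_lo, s_hi))
            else:
                rects.append((q_lo, q_hi, s_lo, s_hi))
    for q_lo, q_hi, s_lo, s_hi in rects:
        res = _gotoh_local(_ascii(query[q_lo:q_hi]), _ascii(subject[s_lo:s_hi]),
                           MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND, np.uint8(ncode))
        score, qs, qe, ss, se, mat, mis, gaps = res
        if score < min_score or qe == qs:
            continue
        hits.append(LocalAlignment(
            score=int(score), q_start=q_lo + qs, q_end=q_lo + qe,
            s_start=s_lo + ss, s_end=s_lo + se, strand="+",
            matches=int(mat), mismatches=int(mis), gap_columns=int(gaps),
            aligned_length=int(mat + mis + gaps)))
    return hits


def _dedupe(hits: list[LocalAlignment]) -> list[LocalAlignment]:
    hits.sort(key=lambda h: (-h.score, -h.identity))
    kept: list[LocalAlignment] = []
    for h in hits:
        redundant = False
        for g in kept:
            if h.strand == g.strand:
                ov = min(h.q_end, g.q_end) - max(h.q_start, g.q_start)
                if ov > 0.5 * (h.q_end - h.q_start):
                    redundant = True
                    break
        if not redundant:
            kept.append(h)
    return kept


def local_align(query: str, subject: str, *, k: int = 15, min_score: int = 50,
                both_strands: bool = True, pad: int = 200,
                max_clusters: int = 25, protein: bool = False) -> list[LocalAlignment]:
    """All local alignments of ``query`` against ``subject`` above ``min_score``.

    Returns hits sorted by descending score.  For DNA the reverse strand of
    the subject is searched too; minus-strand hits carry the subject span in
    forward subject coordinates.  ``protein=True`` disables strand search and
    N-masking (every residue is an ordinary symbol).
    """
    if not query or not subject:
        raise ValueError("empty sequence")
    ncode = 0 if protein else ord("N")
    hits = _align_one_strand(query, subject, k, min_score, pad, ncode, max_clusters)
    if both_strands and not protein:
        rc = reverse_complement(subject)
        for h in _align_one_strand(query, rc, k, min_score, pad, ncode, max_clusters):
            n_s = len(subject)
            h.s_start, h.s_end = n_s - h.s_end, n_s - h.s_start
            h.strand = "-"
            hits.append(h)
    return _dedupe(hits)


def best_score(query: str, subject: str, **kw) -> int:
    """Top local-alignment score, or 0 when no hit clears ``min_score``."""
    hits = local_align(query, subject, **kw)
    return hits[0].score if hits else 0
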