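"""Independent reference implementations used only to check the package.

Each oracle recomputes a quantity by direct, exhaustive means: full-matrix
local alignment DP over every cell (no seeding, value-based traceback),
per-record interval increments for pileup, a scan over all suffix-prefix
lengths, the minimum over all string rotations, and exact rational
hypergeometric tail sums.  None of them share code with the package.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
from numba import njit

NEG = -(10 ** 9)


@njit(cache=True)
def _sw_fill(q, s, match, mismatch, gap_open, gap_ext):
    m, n = len(q), len(s)
    H = np.zeros((m + 1, n + 1), np.int32)
    E = np.full((m + 1, n + 1), NEG, np.int32)
    F = np.full((m + 1, n + 1), NEG, np.int32)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i, j] = max(H[i, j - 1] - gap_open, E[i, j - 1] - gap_ext)
            F[i, j] = max(H[i - 1, j] - gap_open, F[i - 1, j] - gap_ext)
            sub = match if (q[i - 1] == s[j - 1] and q[i - 1] != 78) else mismatch
            H[i, j] = max(0, H[i - 1, j - 1] + sub, E[i, j], F[i, j])
    return H, E, F


def sw_local(q: str, s: str, match: int = 2, mismatch: int = -3,
             gap_open: int = 5, gap_ext: int = 2):
    """Full Smith-Waterman-Gotoh: (score, matches, mismatches, gap_columns,
    q_span, s_span) of the single best local alignment.

    Traceback re-derives each move by comparing stored H/E/F values.
    """
    qa = np.frombuffer(q.encode(), np.uint8)
    sa = np.frombuffer(s.encode(), np.uint8)
    H, E, F = _sw_fill(qa, sa, match, mismatch, gap_open, gap_ext)
    score = int(H.max())
    if score == 0:
        return 0, 0, 0, 0, (0, 0), (0, 0)
    i, j = np.unravel_index(int(H.argmax()), H.shape)
    bi, bj = int(i), int(j)
    i, j = bi, bj
    matches = mismatches = gaps = 0
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            if H[i, j] == 0:
                break
            sub = match if (qa[i - 1] == sa[j - 1] and qa[i - 1] != 78) else mismatch
            if H[i, j] == H[i - 1, j - 1] + sub:
                if qa[i - 1] == sa[j - 1] and qa[i - 1] != 78:
                    matches += 1
                else:
                    mismatches += 1
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            gaps += 1
            if E[i, j] == E[i, j - 1] - gap_ext:
                j -= 1
            else:
                j -= 1
                state = "H"
        else:
            gaps += 1
            if F[i, j] == F[i - 1, j] - gap_ext:
                i -= 1
            else:
                i -= 1
                state = "H"
    return score, matches, mismatches, gaps, (i, bi), (j, bj)


def naive_pileup(records, scaffold_id: str, length: int) -> np.ndarray:
    """Per-base increments, one record at a time."""
    depth = np.zeros(length, dtype=int)
    for rec in records:
        if rec.reference_name != scaffold_id or rec.is_unmapped:
            continue
        if rec.is_secondary or rec.is_supplementary:
            continue
        pos = rec.position - 1
        for n, op in rec.cigar:
            if op in ("M", "=", "X"):
                for p in range(pos, pos + n):
                    depth[p] += 1
                pos += n
            elif op in ("D", "N"):
                pos += n
    return depth


def brute_suffix_prefix(seq: str, min_overlap: int, min_identity: float,
                        max_overlap: int | None = None):
    """Longest L with identity(prefix_L, suffix_L) >= min_identity, by scan."""
    n = len(seq)
    limit = max_overlap if max_overlap is not None else n // 2
    for L in range(limit, min_overlap - 1, -1):
        same = sum(a == b for a, b in zip(seq[:L], seq[n - L:]))
        if 100.0 * same / L >= min_identity:
            return L, 100.0 * same / L
    return None


def brute_min_rotation(s: str) -> str:
    return min(s[i:] + s[:i] for i in range(len(s)))


def hypergeom_tail(N: int, K: int, n: int, k: int) -> Fraction:
    """Exact P(X >= k) for X ~ Hypergeom(N, K, n)."""
    total = Fraction(0)
    for i in range(k, min(K, n) + 1):
        total += Fraction(comb(K, i) * comb(N - K, n - i), comb(N, n))
    return total


def interval_union_length(intervals) -> int:
    points = sorted(intervals)
    total = 0
    cur = None
    for a, b in points:
        if cur is None or a > cur[1] + 1:
            if cur:
                total += cur[1] - cur[0] + 1
            cur = [a, b]
        else:
            cur[1] = max(cur[1], b)
    if cur:
        total += cur[1] - cur[0] + 1
    return total


def bbh_clusters(edges, proteomes):
    """Independent BBH clustering: explicit best-hit scans, DFS components,
    weakest-edge splitting without graph libraries.

    Returns a set of frozensets of (genome_id, protein_id).
    """
    def rank(e):
        return (e.score, e.identity, e.coverage, tuple(sorted([e.a, e.b])))

    best: dict[tuple, object] = {}
    for e in edges:
        for src, dst in ((e.a, e.b), (e.b, e.a)):
            key = (src, dst[0])
            if key not in best or rank(e) > rank(best[key]):
                best[key] = e
    bbh = []
    for e in {id(v): v for v in best.values()}.values():
        if best.get((e.a, e.b[0])) is e and best.get((e.b, e.a[0])) is e:
            bbh.append(e)

    nodes = [(p.genome_id, pr.protein_id) for p in proteomes for pr in p.proteins]

    def components(edge_list):
        adj: dict = {v: [] for v in nodes}
        for e in edge_list:
            adj[e.a].append((e.b, e))
            adj[e.b].append((e.a, e))
        seen = set()
        comps = []
        for v in nodes:
            if v in seen:
                continue
            stack, comp, comp_edges = [v], set(), []
            while stack:
                u = stack.pop()
                if u in seen:
                    continue
                seen.add(u)
                comp.add(u)
                for w, e in adj[u]:
                    comp_edges.append(e)
                    if w not in seen:
                        stack.append(w)
            comps.append((comp, comp_edges))
        return comps

    def split(comp, comp_edges):
        genomes = [g for g, _ in comp]
        if len(genomes) == len(set(genomes)) or not comp_edges:
            return [frozenset(comp)]
        weakest = min(set(comp_edges), key=rank)
        remaining = [e for e in set(comp_edges) if e is not weakest]
        out = []
        local_nodes = sorted(comp)
        sub = [(c, es) for c, es in _components_of(local_nodes, remaining)]
        for c, es in sub:
            out.extend(split(c, es))
        return out

    def _components_of(local_nodes, edge_list):
        adj: dict = {v: [] for v in local_nodes}
        for e in edge_list:
            adj[e.a].append((e.b, e))
            adj[e.b].append((e.a, e))
        seen = set()
        for v in local_nodes:
            if v in seen:
                continue
            stack, comp, comp_edges = [v], set(), []
            while stack:
                u = stack.pop()
                if u in seen:
                    continue
                seen.add(u)
                comp.add(u)
                for w, e in adj[u]:
                    comp_edges.append(e)
                    if w not in seen:
                        stack.append(w)
            yield comp, comp_edges

    result = []
    for comp, comp_edges in components(bbh):
        result.extend(split(comp, comp_edges))
    return set(result)
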