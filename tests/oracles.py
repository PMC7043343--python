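"""Independent brute-force oracles used only by the test suite.

These deliberately re-derive results from first principles (full
dynamic-programming matrices, per-base counting arrays, exhaustive
enumeration) without calling the code paths they check.
"""

from __future__ import annotations

import math
from functools import lru_cache

NEG = -(10**9)


def sw_oracle(
    q: str,
    s: str,
    match: int = 2,
    mismatch: int = -3,
    gap_open: int = 5,
    gap_extend: int = 2,
    max_paths: int = 500,
):
    """Full (unbanded) affine-gap Smith-Waterman with traceback enumeration.

    A gap of length k costs gap_open + k*gap_extend. N never matches.
    Returns (best_score, stats) where stats is the set of
    (matches, aln_columns, q_span, s_span) over all optimal tracebacks
    (capped at max_paths), or (0, set()) when no positive local alignment
    exists.
    """
    n, m = len(q), len(s)
    first_gap = gap_open + gap_extend

    def sub(i: int, j: int) -> int:
        a, b = q[i - 1], s[j - 1]
        return match if (a == b and a != "N") else mismatch

    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]  # q base against gap
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]  # s base against gap
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            prev = max(0, M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1])
            M[i][j] = prev + sub(i, j)
            Ix[i][j] = max(M[i - 1][j] - first_gap, Ix[i - 1][j] - gap_extend)
            Iy[i][j] = max(M[i][j - 1] - first_gap, Iy[i][j - 1] - gap_extend)
            best = max(best, M[i][j])
    if best <= 0:
        return 0, set()

    budget = [max_paths]

    @lru_cache(maxsize=None)
    def rec(i: int, j: int, state: str) -> frozenset:
        """Paths ending with the column at (i, j, state):
        (q_start, s_start, matches, columns), 1-based starts."""
        out = set()
        if budget[0] <= 0:
            return frozenset()
        if state == "M":
            col_match = 1 if (q[i - 1] == s[j - 1] and q[i - 1] != "N") else 0
            prev = M[i][j] - sub(i, j)
            if prev == 0:
                out.add((i, j, col_match, 1))
            for st, val in (("M", M[i - 1][j - 1]), ("Ix", Ix[i - 1][j - 1]), ("Iy", Iy[i - 1][j - 1])):
                if val == prev and val > 0:
                    for qs, ss, mt, c in rec(i - 1, j - 1, st):
                        out.add((qs, ss, mt + col_match, c + 1))
        elif state == "Ix":
            if M[i - 1][j] - first_gap == Ix[i][j]:
                for qs, ss, mt, c in rec(i - 1, j, "M"):
                    out.add((qs, ss, mt, c + 1))
            if Ix[i - 1][j] - gap_extend == Ix[i][j]:
                for qs, ss, mt, c in rec(i - 1, j, "Ix"):
                    out.add((qs, ss, mt, c + 1))
        else:
            if M[i][j - 1] - first_gap == Iy[i][j]:
                for qs, ss, mt, c in rec(i, j - 1, "M"):
                    out.add((qs, ss, mt, c + 1))
            if Iy[i][j - 1] - gap_extend == Iy[i][j]:
                for qs, ss, mt, c in rec(i, j - 1, "Iy"):
                    out.add((qs, ss, mt, c + 1))
        budget[0] -= len(out)
        return frozenset(out)

    stats = set()
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if M[i][j] == best:
                for qs, ss, mt, c in rec(i, j, "M"):
                    stats.add((mt, c, i - qs + 1, j - ss + 1))
    return best, stats


def greedy_cluster_oracle(records, pair_hits, id_threshold, cov_threshold):
    """Straight-line greedy clustering over a precomputed all-pairs hit matrix.

    ``records`` is a list of (seq_id, sequence); ``pair_hits`` maps
    (member_id, rep_id) to (pct_identity, query_coverage) with the member
    as alignment query. Returns representative_id -> sorted member list.
    """
    order = sorted(records, key=lambda r: (-len(r[1]), r[0]))
    reps: list[str] = []
    members: dict[str, list[str]] = {}
    for seq_id, _ in order:
        best_rep, best_key = None, None
        for rep in reps:
            hit = pair_hits.get((seq_id, rep))
            if hit is None:
                continue
            pid, cov = hit
            if pid >= 100 * id_threshold and cov >= 100 * cov_threshold:
                if best_key is None or (pid, cov) > best_key:
                    best_key, best_rep = (pid, cov), rep
        if best_rep is None:
            reps.append(seq_id)
            members[seq_id] = [seq_id]
        else:
            members[best_rep].append(seq_id)
    return {rep: sorted(ms) for rep, ms in members.items()}


def clean_read_oracle(seq: str, quals: list[int]):
    """Reference read-cleaning: trim Q<=2 tails, require a 60-base non-N run."""
    start = 0
    end = len(seq)
    while start < end and quals[start] <= 2:
        start += 1
    while end > start and quals[end - 1] <= 2:
        end -= 1
    trimmed = seq[start:end]
    best = cur = 0
    for ch in trimmed:
        cur = cur + 1 if ch != "N" else 0
        best = max(best, cur)
    return (trimmed, quals[start:end]) if best >= 60 else None

def hypergeom_tail_oracle(high_novel, total_novel, high_public, total_public):
    """P(X >= high_novel) by exhaustive enumeration of the hypergeometric pmf."""
    population = total_novel + total_public
    successes = high_novel + high_public
    draws = total_novel
    total = math.comb(population, draws)
    acc = 0
    for k in range(high_novel, min(successes, draws) + 1):
        if draws - k > population - successes:
            continue
        acc += math.comb(successes, k) * math.comb(population - successes, draws - k)
    return acc / total


def coverage_oracle(alignments, genome_lengths):
    """Per-base counting-array breadth/depth.

    ``alignments`` is an iterable of (genome_id, start, aligned_length)
    with start 0-based; returns genome_id -> (breadth, mean_depth, n_reads).
    """
    import numpy as np

    depth = {g: np.zeros(length, dtype=int) for g, length in genome_lengths.items()}
    n_reads = {g: 0 for g in genome_lengths}
    for gid, start, length in alignments:
        depth[gid][start : start + length] += 1
        n_reads[gid] += 1
    return {
        g: (float((d > 0).mean()), float(d.mean()), n_reads[g]) for g, d in depth.items()
    }
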