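"""Independent reference implementations used only as test oracles.

Each function here recomputes a quantity by a route deliberately
different from the library's: exhaustive dynamic programming and path
enumeration for alignment scores, a dense Euler-angle grid for optimal
superposition, and window enumeration for operon calls.
"""

from __future__ import annotations

import math
from typing import List, Sequence, Tuple

import numpy as np

NEG_INF = float("-inf")


def gotoh_score(
    seq_a: str, seq_b: str, sub, gap_open: float, gap_extend: float
) -> float:
    """Affine-gap global alignment optimum by the three-matrix recursion.

    A gap of length L costs gap_open + (L - 1) * gap_extend; terminal
    gaps are penalized like internal ones.
    """
    n, m = len(seq_a), len(seq_b)
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # column ends in a match
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # ends in gap in seq_b
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # ends in gap in seq_a
    M[0][0] = 0.0
    for i in range(n + 1):
        for j in range(m + 1):
            if i > 0:
                X[i][j] = max(
                    M[i - 1][j] + gap_open,
                    X[i - 1][j] + gap_extend,
                    Y[i - 1][j] + gap_open,
                )
            if j > 0:
                Y[i][j] = max(
                    M[i][j - 1] + gap_open,
                    Y[i][j - 1] + gap_extend,
                    X[i][j - 1] + gap_open,
                )
            if i > 0 and j > 0:
                s = sub[seq_a[i - 1], seq_b[j - 1]]
                M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
    return max(M[n][m], X[n][m], Y[n][m])


def enumerate_alignment_score(
    seq_a: str, seq_b: str, sub, gap_open: float, gap_extend: float
) -> float:
    """Optimum over an explicit enumeration of every global alignment.

    Exponential; only for very short sequences.  Scores each alignment
    string pair directly with the affine gap rule.
    """

    best = [NEG_INF]

    def score_alignment(cols: List[Tuple[str, str]]) -> float:
        total = 0.0
        prev_gap = None  # 'a' or 'b' when the previous column was a gap
        for ca, cb in cols:
            if ca == "-":
                total += gap_extend if prev_gap == "a" else gap_open
                prev_gap = "a"
            elif cb == "-":
                total += gap_extend if prev_gap == "b" else gap_open
                prev_gap = "b"
            else:
                total += sub[ca, cb]
                prev_gap = None
        return total

    def rec(i: int, j: int, cols: List[Tuple[str, str]]) -> None:
        if i == len(seq_a) and j == len(seq_b):
            s = score_alignment(cols)
            if s > best[0]:
                best[0] = s
            return
        if i < len(seq_a) and j < len(seq_b):
            rec(i + 1, j + 1, cols + [(seq_a[i], seq_b[j])])
        if i < len(seq_a):
            rec(i + 1, j, cols + [(seq_a[i], "-")])
        if j < len(seq_b):
            rec(i, j + 1, cols + [("-", seq_b[j])])

    rec(0, 0, [])
    return best[0]


def _euler_rotations(step_deg: float, centers=None, half_width_deg: float = None):
    """Z-Y-Z Euler rotation matrices on a grid (optionally local)."""
    if centers is None:
        a_grid = np.arange(0.0, 360.0, step_deg)
        b_grid = np.arange(0.0, 180.0 + 1e-9, step_deg)
        c_grid = np.arange(0.0, 360.0, step_deg)
    else:
        a0, b0, c0 = centers
        hw = half_width_deg
        a_grid = np.arange(a0 - hw, a0 + hw + 1e-9, step_deg)
        b_grid = np.arange(b0 - hw, b0 + hw + 1e-9, step_deg)
        c_grid = np.arange(c0 - hw, c0 + hw + 1e-9, step_deg)
    for a in a_grid:
        ca, sa = math.cos(math.radians(a)), math.sin(math.radians(a))
        Rz1 = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1]])
        for b in b_grid:
            cb, sb = math.cos(math.radians(b)), math.sin(math.radians(b))
            Ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
            for c in c_grid:
                cc, sc = math.cos(math.radians(c)), math.sin(math.radians(c))
                Rz2 = np.array([[cc, -sc, 0], [sc, cc, 0], [0, 0, 1]])
                yield (a, b, c), Rz1 @ Ry @ Rz2


def rotation_grid_min_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Minimum RMSD over rotations on a coarse-to-1° Euler grid.

    For each rotation the optimal translation (centroid match) is
    applied analytically.
    """
    a = coords_a - coords_a.mean(axis=0)
    b = coords_b - coords_b.mean(axis=0)

    def rmsd_for(R):
        d = a @ R.T - b
        return math.sqrt(float(np.mean(np.sum(d * d, axis=1))))

    best = (float("inf"), None)
    for angles, R in _euler_rotations(6.0):
        r = rmsd_for(R)
        if r < best[0]:
            best = (r, angles)
    for _, R in _euler_rotations(1.0, centers=best[1], half_width_deg=6.0):
        r = rmsd_for(R)
        if r < best[0]:
            best = (r, best[1])
    return best[0]


def brute_force_operons(genes, criteria) -> List[Tuple[str, ...]]:
    """Operon calls by enumerating all contiguous same-strand windows.

    A window is a valid run when every member shares the strand and all
    successive intergenic gaps are within the cutoff; calls are the
    maximal valid runs that also pass the gene-count and span criteria.
    """
    n = len(genes)

    def gap(i: int) -> int:
        return max(0, genes[i + 1].start - genes[i].end - 1)

    def valid_run(i: int, j: int) -> bool:
        if any(genes[k].strand != genes[i].strand for k in range(i, j + 1)):
            return False
        return all(gap(k) <= criteria.max_intergenic for k in range(i, j))

    calls = []
    for i in range(n):
        for j in range(i + criteria.min_genes - 1, n):
            if not valid_run(i, j):
                continue
            # maximal among valid runs
            if i > 0 and valid_run(i - 1, j):
                continue
            if j < n - 1 and valid_run(i, j + 1):
                continue
            span_start = genes[i].start
            span_end = max(g.end for g in genes[i : j + 1])
            if span_end - span_start + 1 > criteria.min_operon_length:
                calls.append(tuple(g.gene_id for g in genes[i : j + 1]))
    return calls
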