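"""Independent brute-force reference implementations used as oracles.

Everything here is written in the most literal way possible — explicit
double loops over matrix entries, per-point run membership, an
inside/outside state machine per reference point, triple enumeration —
so that it shares no code path with the package implementations it
checks.
"""

from __future__ import annotations

import math

import numpy as np


def brute_mi_2d_hist(x: np.ndarray, y: np.ndarray,
                     edges: np.ndarray) -> float:
    """Plug-in MI from an explicitly accumulated 2-D histogram (nats)."""
    nb = len(edges) - 1
    joint = np.zeros((nb, nb))
    for xi, yi in zip(x, y):
        i = min(np.searchsorted(edges, xi, side="right") - 1, nb - 1)
        j = min(np.searchsorted(edges, yi, side="right") - 1, nb - 1)
        joint[max(i, 0), max(j, 0)] += 1
    n = joint.sum()
    p = joint / n
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mi = 0.0
    for i in range(nb):
        for j in range(nb):
            if p[i, j] > 0:
                mi += p[i, j] * math.log(p[i, j] / (px[i] * py[j]))
    return mi


def brute_discrete_mi(a: np.ndarray, b: np.ndarray) -> float:
    """Plug-in MI of two discrete label vectors by direct summation."""
    n = len(a)
    avals = sorted(set(a.tolist()))
    bvals = sorted(set(b.tolist()))
    mi = 0.0
    for av in avals:
        for bv in bvals:
            pab = sum(1 for x, y in zip(a, b) if x == av and y == bv) / n
            if pab > 0:
                pa = sum(1 for x in a if x == av) / n
                pb = sum(1 for y in b if y == bv) / n
                mi += pab * math.log(pab / (pa * pb))
    return mi


def brute_recurrence_matrix(points: np.ndarray, eps: float) -> np.ndarray:
    """O(N^2) double-loop Euclidean thresholding."""
    n = len(points)
    R = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(n):
            d = math.sqrt(float(np.sum((points[i] - points[j]) ** 2)))
            R[i, j] = d <= eps
    return R


def brute_diagonal_counts(R: np.ndarray, exclude_loi: bool) -> dict[int, int]:
    """Run lengths along every diagonal, walked cell by cell."""
    n = R.shape[0]
    counts: dict[int, int] = {}
    for k in range(-(n - 1), n):
        if k == 0 and exclude_loi:
            continue
        run = 0
        cells = [(i, i + k) for i in range(n) if 0 <= i + k < n]
        for (i, j) in cells:
            if R[i, j]:
                run += 1
            elif run:
                counts[run] = counts.get(run, 0) + 1
                run = 0
        if run:
            counts[run] = counts.get(run, 0) + 1
    return counts


def brute_vertical_counts(R: np.ndarray) -> dict[int, int]:
    """Run lengths down every column, walked cell by cell."""
    n = R.shape[0]
    counts: dict[int, int] = {}
    for j in range(n):
        run = 0
        for i in range(n):
            if R[i, j]:
                run += 1
            elif run:
                counts[run] = counts.get(run, 0) + 1
                run = 0
        if run:
            counts[run] = counts.get(run, 0) + 1
    return counts


def brute_det(R: np.ndarray, l_min: int) -> float:
    """DET by per-point run-membership classification (LOI excluded)."""
    n = R.shape[0]
    on_long_line = 0
    total = 0
    for i in range(n):
        for j in range(n):
            if i == j or not R[i, j]:
                continue
            total += 1
            # walk the diagonal through (i, j) to get its run length
            a, b = i, j
            while a > 0 and b > 0 and R[a - 1, b - 1]:
                a -= 1
                b -= 1
            length = 0
            while a < n and b < n and R[a, b]:
                length += 1
                a += 1
                b += 1
            if length >= l_min:
                on_long_line += 1
    return on_long_line / total if total else 0.0


def brute_recurrence_times(inside: np.ndarray) -> tuple[list[int], list[int]]:
    """Entry-event state machine, run separately per reference point."""
    t1_times: list[int] = []
    t2_times: list[int] = []
    n = inside.shape[0]
    for i in range(n):
        members = [j for j in range(n) if inside[i, j]]
        for a, b in zip(members, members[1:]):
            t1_times.append(b - a)
        was_inside = False
        entries = []
        for j in range(n):
            if inside[i, j] and not was_inside:
                entries.append(j)
            was_inside = inside[i, j]
        for a, b in zip(entries, entries[1:]):
            t2_times.append(b - a)
    return t1_times, t2_times


def brute_transitivity(A: np.ndarray) -> float:
    """Closed/connected triple enumeration over all ordered triples."""
    n = A.shape[0]
    closed = 0
    connected = 0
    for i in range(n):
        for j in range(n):
            for k in range(n):
                if j != k and A[i, j] and A[i, k]:
                    connected += 1
                    if A[j, k]:
                        closed += 1
    return closed / connected if connected else 0.0


def brute_cao_e(series: np.ndarray, tau: int, m: int) -> tuple[float, float]:
    """Cao's E(m) and E*(m) by exhaustive nearest-neighbor search."""
    n = len(series)
    n_pts = n - m * tau
    pts = [series[i:i + (m - 1) * tau + 1:tau] for i in range(n_pts)]
    ratios = []
    gaps = []
    for i in range(n_pts):
        best = None
        best_d = math.inf
        for j in range(n_pts):
            if j == i:
                continue
            d = max(abs(a - b) for a, b in zip(pts[i], pts[j]))
            if d < best_d:
                best_d = d
                best = j
        if best_d == 0:
            continue
        gap = abs(series[i + m * tau] - series[best + m * tau])
        ratios.append(max(best_d, gap) / best_d)
        gaps.append(gap)
    return float(np.mean(ratios)), float(np.mean(gaps))


def brute_mrmr_step(codes: list[np.ndarray], y: np.ndarray,
                    selected: list[int], remaining: list[int],
                    beta: float | None) -> int:
    """Exhaustive evaluation of the greedy criterion at one step."""
    best_j = None
    best_score = -math.inf
    for j in remaining:
        rel = brute_discrete_mi(codes[j], y)
        if selected:
            b = (1.0 / len(selected)) if beta is None else beta
            red = b * sum(brute_discrete_mi(codes[j], codes[s])
                          for s in selected)
        else:
            red = 0.0
        score = rel - red
        if score > best_score:
            best_score = score
            best_j = j
    return best_j
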