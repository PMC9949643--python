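"""Independent brute-force reference implementations used by the tests.

Deliberately naive: direct double loops over point pairs and per-diagonal
run scans, sharing no code with the package's vectorised implementation.
"""

from __future__ import annotations

import math


def brute_recurrence_matrix(points, radius):
    """points: list of coordinate tuples; returns list-of-lists 0/1."""
    n = len(points)
    mat = [[0] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            dist = math.sqrt(
                sum((points[i][k] - points[j][k]) ** 2 for k in range(len(points[i])))
            )
            if dist <= radius:
                mat[i][j] = 1
    return mat


def brute_diagonal_lengths(mat, theiler=1):
    """Maximal diagonal runs at offsets |k| >= max(1, theiler), both halves."""
    n = len(mat)
    lengths = []
    for off in range(max(1, theiler), n):
        for cells in (
            [mat[i][i + off] for i in range(n - off)],
            [mat[i + off][i] for i in range(n - off)],
        ):
            run = 0
            for value in cells + [0]:
                if value:
                    run += 1
                elif run:
                    lengths.append(run)
                    run = 0
    return lengths


def brute_metrics(points, radius=1.0, lmin=2, theiler=1):
    """(rec, det, maxl) for a point series; det None when no off-LOI
    recurrences exist."""
    mat = brute_recurrence_matrix(points, radius)
    n = len(mat)
    rec = 100.0 * sum(sum(row) for row in mat) / (n * n)
    lengths = brute_diagonal_lengths(mat, theiler)
    total = sum(lengths)
    det = None if total == 0 else 100.0 * sum(l for l in lengths if l >= lmin) / total
    maxl = max(lengths) if lengths else 0
    return rec, det, maxl


def brute_lap_count(psi_unwrapped):
    """Count upward 2*pi-threshold crossings of the forward excursion."""
    base = psi_unwrapped[0]
    laps = 0
    while True:
        threshold = base + 2.0 * math.pi * (laps + 1)
        if any(v >= threshold - 1e-9 for v in psi_unwrapped):
            laps += 1
        else:
            return laps
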