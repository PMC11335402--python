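"""Independent brute-force oracles used to validate package algorithms.

These deliberately use naive O(n^2)/O(n^3) formulations with no shared code
paths with the package implementation.
"""

from __future__ import annotations

import numpy as np


def _orient(p, q, r) -> float:
    return (q[0] - p[0]) * (r[1] - p[1]) - (q[1] - p[1]) * (r[0] - p[0])


def _on_segment(p, q, r) -> bool:
    """r collinear with pq: does r lie within the segment's bounding box?"""
    return (
        min(p[0], q[0]) - 1e-12 <= r[0] <= max(p[0], q[0]) + 1e-12
        and min(p[1], q[1]) - 1e-12 <= r[1] <= max(p[1], q[1]) + 1e-12
    )


def segments_intersect(p1, p2, p3, p4) -> bool:
    """Classic orientation-based segment intersection test, including
    collinear-overlap cases."""
    d1 = _orient(p3, p4, p1)
    d2 = _orient(p3, p4, p2)
    d3 = _orient(p1, p2, p3)
    d4 = _orient(p1, p2, p4)
    if ((d1 > 0 and d2 < 0) or (d1 < 0 and d2 > 0)) and (
        (d3 > 0 and d4 < 0) or (d3 < 0 and d4 > 0)
    ):
        return True
    if abs(d1) < 1e-12 and _on_segment(p3, p4, p1):
        return True
    if abs(d2) < 1e-12 and _on_segment(p3, p4, p2):
        return True
    if abs(d3) < 1e-12 and _on_segment(p1, p2, p3):
        return True
    if abs(d4) < 1e-12 and _on_segment(p1, p2, p4):
        return True
    return False


def brute_self_intersecting(points: np.ndarray) -> bool:
    """All-pairs test over non-adjacent edges of the closed polygon."""
    n = len(points)
    edges = [(points[i], points[(i + 1) % n]) for i in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if j == i + 1 or (i == 0 and j == n - 1):
                continue  # adjacent edges share an endpoint
            if segments_intersect(*edges[i], *edges[j]):
                return True
    return False


def brute_pareto_front(oriented: np.ndarray) -> np.ndarray:
    """Weak-dominance front of all-maximize points, by explicit loops."""
    n, k = oriented.shape
    on_front = np.ones(n, dtype=bool)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            ge = all(oriented[j, c] >= oriented[i, c] for c in range(k))
            gt = any(oriented[j, c] > oriented[i, c] for c in range(k))
            if ge and gt:
                on_front[i] = False
                break
    return on_front


def brute_goldberg(oriented: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Iterative peeling with the brute front; returns (front_index, rank)."""
    n = len(oriented)
    front_index = np.zeros(n, dtype=int)
    remaining = list(range(n))
    j = 0
    while remaining:
        j += 1
        sub = oriented[remaining]
        mask = brute_pareto_front(sub)
        taken = [remaining[i] for i in range(len(remaining)) if mask[i]]
        for t in taken:
            front_index[t] = j
        remaining = [r for r in remaining if front_index[r] == 0]
    K = j
    if K == 1:
        rank = np.ones(n)
    else:
        rank = (K - front_index) / (K - 1)
    return front_index, rank


def triangle_exact_inertia(p1, p2, p3, mass: float, axis) -> float:
    """Exact polar second moment of a uniform triangle about axis,
    via the closed-form integral over the triangle (for quantifying the
    centroid-lumping approximation)."""
    a = np.asarray(p1) - np.asarray(axis)
    b = np.asarray(p2) - np.asarray(axis)
    c = np.asarray(p3) - np.asarray(axis)
    # second moment of area about the axis point for a triangle:
    # integral (x^2+y^2) dA = A/6 * (|a|^2+|b|^2+|c|^2 + a.b + b.c + c.a)
    s = (
        a @ a + b @ b + c @ c + a @ b + b @ c + c @ a
    )
    return mass * s / 6.0


def ellipse_efa_first_harmonic(a: float, b: float, n_dense: int = 200_000) -> np.ndarray:
    """First-harmonic EFA coefficient matrix [[a1, b1], [c1, d1]] of an
    axis-aligned ellipse traversed by arc length, by dense trapezoidal
    quadrature of the Fourier integrals (independent of the package's
    piecewise-linear closed forms)."""
    theta = np.linspace(0.0, 2 * np.pi, n_dense + 1)
    x, y = a * np.cos(theta), b * np.sin(theta)
    ds = np.hypot(np.diff(x), np.diff(y))
    t = np.concatenate([[0.0], np.cumsum(ds)])
    T = t[-1]
    w = 2 * np.pi * t / T
    def coef(f, g):
        return 2.0 / T * np.trapezoid(f * g, t)
    return np.array(
        [
            [coef(x, np.cos(w)), coef(x, np.sin(w))],
            [coef(y, np.cos(w)), coef(y, np.sin(w))],
        ]
    )
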