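"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the library code paths they check: DBSCAN by
explicit density-reachability BFS over the full distance matrix, and the
concordance index by direct enumeration of all ordered pairs.
"""

from __future__ import annotations

import numpy as np


def brute_force_dbscan(points: np.ndarray, eps: float, min_pts: int) -> np.ndarray:
    """O(n^2) DBSCAN by definition.

    Core point: >= min_pts points (itself included) within eps.  Clusters
    grow by breadth-first search over core points; border points join the
    first cluster that reaches them; the rest are noise (-1).
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n == 0:
        return np.empty(0, dtype=int)
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    neighbours = d <= eps
    core = neighbours.sum(axis=1) >= min_pts
    labels = np.full(n, -1, dtype=int)
    cluster = 0
    for i in range(n):
        if not core[i] or labels[i] != -1:
            continue
        # BFS over density-reachable points starting from core point i
        labels[i] = cluster
        queue = [i]
        while queue:
            j = queue.pop()
            if not core[j]:
                continue
            for k in np.flatnonzero(neighbours[j]):
                if labels[k] == -1:
                    labels[k] = cluster
                    if core[k]:
                        queue.append(k)
        cluster += 1
    return labels


def labels_equivalent(a: np.ndarray, b: np.ndarray) -> bool:
    """Cluster labellings equal up to renumbering (noise must match exactly)."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        return False
    if not np.array_equal(a == -1, b == -1):
        return False
    mapping: dict[int, int] = {}
    seen: set[int] = set()
    for la, lb in zip(a, b):
        if la == -1:
            continue
        if la in mapping:
            if mapping[la] != lb:
                return False
        else:
            if lb in seen:
                return False
            mapping[la] = lb
            seen.add(lb)
    return True


def brute_force_cindex(risk, times, events) -> float:
    """Harrell's C by explicit enumeration of every ordered pair."""
    risk = np.asarray(risk, float)
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    n = len(risk)
    num = 0.0
    den = 0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if times[i] < times[j] and events[i] == 1:
                comparable = True
            elif times[i] == times[j] and events[i] == 1 and events[j] == 0:
                comparable = True
            else:
                comparable = False
            if not comparable:
                continue
            den += 1
            if risk[i] > risk[j]:
                num += 1.0
            elif risk[i] == risk[j]:
                num += 0.5
    if den == 0:
        raise ZeroDivisionError("no comparable pairs")
    return num / den
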