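"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately written from first principles, without
reusing any code path from the package under test.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def partitions_into_k(items: list, k: int):
    """Yield every set partition of ``items`` into exactly k nonempty blocks."""
    if k == 1:
        yield [list(items)]
        return
    if len(items) == k:
        yield [[x] for x in items]
        return
    if len(items) < k:
        return
    first, rest = items[0], items[1:]
    # first joins an existing block of a (k)-partition of the rest
    for part in partitions_into_k(rest, k):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
    # first is its own block alongside a (k-1)-partition of the rest
    for part in partitions_into_k(rest, k - 1):
        yield [[first]] + part


def exhaustive_kmeans_sse(X: np.ndarray, k: int) -> float:
    """Global optimum of the k-means objective by enumerating all partitions."""
    X = np.asarray(X, dtype=float)
    best = np.inf
    for part in partitions_into_k(list(range(len(X))), k):
        sse = 0.0
        for block in part:
            pts = X[block]
            sse += float(((pts - pts.mean(axis=0)) ** 2).sum())
        best = min(best, sse)
    return best


def brute_force_mean_silhouette(X: np.ndarray, labels: np.ndarray) -> float:
    """Silhouette mean straight from the definition, point by point."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n = len(X)
    s_values = []
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            s_values.append(0.0)  # singleton cluster convention
            continue
        a = np.mean([np.linalg.norm(X[i] - X[j]) for j in own])
        b = np.inf
        for c in set(labels.tolist()) - {labels[i]}:
            members = [j for j in range(n) if labels[j] == c]
            b = min(b, np.mean([np.linalg.norm(X[i] - X[j]) for j in members]))
        s_values.append((b - a) / max(a, b))
    return float(np.mean(s_values))


def g_statistic(counts: np.ndarray) -> float:
    """Contingency G-statistic 2 * sum O * ln(O / E), 0 ln 0 = 0."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / total
    mask = counts > 0
    return float(2.0 * np.sum(counts[mask] * np.log(counts[mask] / expected[mask])))
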