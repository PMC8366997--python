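"""Independent brute-force reference implementations.

Deliberately naive (explicit loops, enumeration, closed forms) so they
share no code path with the package; used to pin down the numerical
operations on small instances.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def cosine_brute(x: np.ndarray) -> np.ndarray:
    n = x.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            num = sum(a * b for a, b in zip(x[i], x[j]))
            da = math.sqrt(sum(a * a for a in x[i]))
            db = math.sqrt(sum(b * b for b in x[j]))
            out[i, j] = num / (da * db) if da > 0 and db > 0 else 0.0
    return out


def pcc_brute(x: np.ndarray) -> np.ndarray:
    centered = np.array([[v - row.mean() for v in row] for row in x])
    return cosine_brute(centered)


def density_brute(sim: np.ndarray, cutoff: float) -> tuple[int, int, float]:
    """(edges, connected nodes, density over connected nodes)."""
    n = sim.shape[0]
    edges = [(i, j) for i in range(n) for j in range(i + 1, n) if sim[i, j] > cutoff]
    nodes = {v for e in edges for v in e}
    m = len(nodes)
    dens = len(edges) / (m * (m - 1) / 2) if m >= 2 else float("nan")
    return len(edges), m, dens


def topk_threshold_brute(abs_vals: list[float], fraction: float) -> float:
    """Sort-and-cut |PCC| threshold for the top-fraction edge rule."""
    vals = sorted(abs_vals, reverse=True)
    k = max(1, math.ceil(fraction * len(vals)))
    return vals[k - 1]


def window_features_brute(
    t: np.ndarray, v: np.ndarray, window: float
) -> tuple[float, float]:
    """Exhaustive ordered-pair scan for max increase / decrease in window."""
    inc, dec = [], []
    for i in range(len(t)):
        for j in range(len(t)):
            if t[j] > t[i] and t[j] - t[i] <= window:
                inc.append(v[j] - v[i])
                dec.append(v[i] - v[j])
    if not inc:
        return float("nan"), float("nan")
    return max(max(inc), 0.0), max(max(dec), 0.0)


def km_brute(times: np.ndarray, events: np.ndarray) -> list[tuple[float, float]]:
    """Product-limit estimate at each distinct event time."""
    order = np.argsort(times, kind="stable")
    times, events = np.asarray(times)[order], np.asarray(events)[order]
    s = 1.0
    out = []
    for t in sorted(set(times[events.astype(bool)])):
        at_risk = int(np.sum(times >= t))
        d = int(np.sum((times == t) & (events.astype(bool))))
        s *= 1.0 - d / at_risk
        out.append((float(t), s))
    return out


def nelson_aalen_brute(times: np.ndarray, events: np.ndarray) -> list[tuple[float, float]]:
    """Step-sum cumulative hazard at each distinct event time."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    h = 0.0
    out = []
    for t in sorted(set(times[events])):
        at_risk = int(np.sum(times >= t))
        d = int(np.sum((times == t) & events))
        h += d / at_risk
        out.append((float(t), h))
    return out


def bh_brute(pvals: list[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values by the textbook recursion."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, pvals[i] * m / rank_from_top)
        adj[i] = val
        prev = val
    return adj


def _contingency(a: list[int], b: list[int]) -> np.ndarray:
    la, lb = sorted(set(a)), sorted(set(b))
    table = np.zeros((len(la), len(lb)), dtype=int)
    for x, y in zip(a, b):
        table[la.index(x), lb.index(y)] += 1
    return table


def ari_brute(a: list[int], b: list[int]) -> float:
    """Adjusted Rand index from the contingency-table formula."""
    table = _contingency(a, b)
    n = len(a)
    sum_ij = sum(math.comb(int(nij), 2) for nij in table.ravel())
    sum_a = sum(math.comb(int(ni), 2) for ni in table.sum(axis=1))
    sum_b = sum(math.comb(int(nj), 2) for nj in table.sum(axis=0))
    total = math.comb(n, 2)
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0
    return (sum_ij - expected) / (max_index - expected)


def ami_brute(a: list[int], b: list[int]) -> float:
    """Adjusted mutual information (arithmetic normalizer) from scratch,
    including the exact hypergeometric expected mutual information."""
    table = _contingency(a, b)
    n = len(a)
    ai = table.sum(axis=1)
    bj = table.sum(axis=0)
    mi = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            nij = table[i, j]
            if nij > 0:
                mi += (nij / n) * math.log(n * nij / (ai[i] * bj[j]))
    h_a = -sum((x / n) * math.log(x / n) for x in ai if x > 0)
    h_b = -sum((x / n) * math.log(x / n) for x in bj if x > 0)
    emi = 0.0
    for i in range(len(ai)):
        for j in range(len(bj)):
            lo = max(1, ai[i] + bj[j] - n)
            hi = min(ai[i], bj[j])
            for nij in range(lo, hi + 1):
                term = (nij / n) * math.log(n * nij / (ai[i] * bj[j]))
                log_prob = (
                    math.lgamma(ai[i] + 1)
                    - math.lgamma(nij + 1)
                    - math.lgamma(ai[i] - nij + 1)
                    + math.lgamma(n - ai[i] + 1)
                    - math.lgamma(bj[j] - nij + 1)
                    - math.lgamma(n - ai[i] - bj[j] + nij + 1)
                    - math.lgamma(n + 1)
                    + math.lgamma(bj[j] + 1)
                    + math.lgamma(n - bj[j] + 1)
                )
                emi += term * math.exp(log_prob)
    denom = (h_a + h_b) / 2 - emi
    if abs(denom) < 1e-15:
        return 1.0
    return (mi - emi) / denom


def set_partitions(items: list[int]):
    """All set partitions of a list (restricted growth strings)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def partition_to_labels(partition: list[list[int]], n: int) -> list[int]:
    labels = [0] * n
    for k, block in enumerate(partition):
        for idx in block:
            labels[idx] = k
    return labels


def betweenness_brute(edges: list[tuple[int, int]], nodes: list[int]) -> dict[int, float]:
    """Normalized betweenness by exhaustive enumeration of all simple
    paths between every node pair (feasible for n <= 9)."""
    adj: dict[int, set[int]] = {v: set() for v in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)

    def all_paths(s: int, t: int) -> list[list[int]]:
        paths = []

        def dfs(node: int, seen: list[int]) -> None:
            if node == t:
                paths.append(list(seen))
                return
            for nb in adj[node]:
                if nb not in seen:
                    dfs(nb, seen + [nb])

        dfs(s, [s])
        return paths

    score = {v: 0.0 for v in nodes}
    for s, t in combinations(nodes, 2):
        paths = all_paths(s, t)
        if not paths:
            continue
        shortest = min(len(p) for p in paths)
        sp = [p for p in paths if len(p) == shortest]
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in sp if v in p)
            score[v] += through / len(sp)
    n = len(nodes)
    norm = (n - 1) * (n - 2) / 2 if n > 2 else 1.0
    return {v: s / norm for v, s in score.items()}


def sse_brute(x: np.ndarray, labels: list[int]) -> float:
    """Within-cluster sum of squared distances to cluster means."""
    total = 0.0
    for k in set(labels):
        pts = x[[i for i, l in enumerate(labels) if l == k]]
        c = pts.mean(axis=0)
        total += float(((pts - c) ** 2).sum())
    return total


def best_two_partition_sse(x: np.ndarray) -> float:
    """Global optimum SSE over all 2-partitions (exhaustive)."""
    n = len(x)
    best = float("inf")
    for mask in range(1, 2 ** (n - 1)):
        labels = [(mask >> i) & 1 for i in range(n)]
        if len(set(labels)) < 2:
            continue
        best = min(best, sse_brute(x, labels))
    return best


def wilson_interval_brute(k: int, n: int, z: float = 1.959963984540054) -> tuple[float, float]:
    p = k / n
    denom = 1 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return center - half, center + half
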