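"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: triple loops,
vectorized grid search over the partial likelihood, and hand agglomeration,
so that agreement with the library is a genuine dual-route check.
"""

from __future__ import annotations

import numpy as np


def brute_force_tom(a: np.ndarray) -> np.ndarray:
    """Triple-loop topological overlap from an adjacency matrix."""
    n = a.shape[0]
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = 0.0
            for u in range(n):
                if u != i and u != j:
                    l += a[i, u] * a[u, j]
            tom[i, j] = (l + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return tom


def brute_force_soft_adjacency(x: np.ndarray, power: int) -> np.ndarray:
    """Elementwise |Pearson correlation|^power via an explicit double loop."""
    n = x.shape[0]
    a = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            xi, xj = x[i], x[j]
            num = ((xi - xi.mean()) * (xj - xj.mean())).sum()
            den = np.sqrt(((xi - xi.mean()) ** 2).sum() * ((xj - xj.mean()) ** 2).sum())
            a[i, j] = abs(num / den) ** power
    return a


def grid_cox_beta(
    x: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    lo: float = -5.0,
    hi: float = 5.0,
    step: float = 1e-4,
) -> float:
    """Grid-search maximizer of the Breslow log partial likelihood (1-d).

    Vectorized over the grid but formula-level independent of the package's
    Newton solver.
    """
    order = np.argsort(time, kind="stable")
    xs, ts, ev = x[order], time[order], event[order]
    grid = np.arange(lo, hi + step, step)
    E = np.exp(grid[:, None] * xs[None, :])
    S0 = np.cumsum(E[:, ::-1], axis=1)[:, ::-1]
    first = np.searchsorted(ts, ts, side="left")
    evi = np.where(ev == 1)[0]
    ll = (grid[:, None] * xs[evi][None, :]).sum(axis=1) - np.log(S0[:, first[evi]]).sum(axis=1)
    return float(grid[np.argmax(ll)])


def upgma_heights(d: np.ndarray) -> list[float]:
    """Naive average-linkage agglomeration; returns sorted merge heights."""
    clusters: list[list[int]] = [[i] for i in range(d.shape[0])]
    heights: list[float] = []
    while len(clusters) > 1:
        best = (np.inf, 0, 1)
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                avg = float(np.mean([d[a, b] for a in clusters[i] for b in clusters[j]]))
                if avg < best[0]:
                    best = (avg, i, j)
        h, i, j = best
        heights.append(h)
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return sorted(heights)


def logrank_by_hand(time, event, group):
    """Observed/expected/variance tabulation at each distinct event time."""
    O = E = V = 0.0
    for t in sorted(set(time[event == 1])):
        risk = time >= t
        n = risk.sum()
        n1 = (risk & (group == 1)).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (group == 1)).sum()
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V if V > 0 else 0.0
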