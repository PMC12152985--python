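"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by the most transparent route possible
(exact fractions, O(V^2) scans) and share no code with the implementation.
"""

import itertools
from fractions import Fraction
from functools import lru_cache
from math import factorial, prod

import numpy as np

from hmisaccess.grid import RasterGrid


def fisher_oracle(table) -> float:
    """Exact-fraction Fisher p-value by enumerating fixed-margin tables."""
    t = np.asarray(table, dtype=int)
    probs = _margin_distribution(
        tuple(int(v) for v in t.sum(axis=1)), tuple(int(v) for v in t.sum(axis=0))
    )
    p_obs = _table_prob(tuple(int(v) for v in t.ravel()),
                        tuple(int(v) for v in t.sum(axis=1)),
                        tuple(int(v) for v in t.sum(axis=0)))
    return float(sum(p for p in probs if p <= p_obs))


def _table_prob(cells, r_sums, c_sums) -> Fraction:
    n = sum(r_sums)
    const = Fraction(
        prod(factorial(v) for v in r_sums) * prod(factorial(v) for v in c_sums),
        factorial(n),
    )
    return const / prod(factorial(v) for v in cells)


@lru_cache(maxsize=100_000)
def _margin_distribution(r_sums: tuple, c_sums: tuple) -> tuple:
    """All table probabilities for fixed margins (cached per margin class)."""
    r, c = len(r_sums), len(c_sums)
    probs = []
    ranges = [range(min(r_sums[i], c_sums[j]) + 1) for i in range(r - 1) for j in range(c - 1)]
    for combo in itertools.product(*ranges):
        m = np.zeros((r, c), dtype=int)
        for k, (i, j) in enumerate(itertools.product(range(r - 1), range(c - 1))):
            m[i, j] = combo[k]
        m[: r - 1, c - 1] = np.array(r_sums[: r - 1]) - m[: r - 1, : c - 1].sum(axis=1)
        m[r - 1, :] = np.array(c_sums) - m[: r - 1, :].sum(axis=0)
        if (m < 0).any():
            continue
        probs.append(_table_prob(tuple(int(v) for v in m.ravel()), r_sums, c_sums))
    return tuple(probs)


def naive_dijkstra(friction: RasterGrid, source_cells) -> np.ndarray:
    """O(V^2) multi-source shortest path over the 8-connected cell grid;
    step time = step distance x mean of the two cells' per-metre costs.
    Returns minutes."""
    cost = friction.data
    n_rows, n_cols = cost.shape
    dist = np.full((n_rows, n_cols), np.inf)
    for r, c in source_cells:
        dist[r, c] = 0.0
    visited = np.zeros((n_rows, n_cols), dtype=bool)
    visited[~np.isfinite(cost)] = True
    while True:
        d = np.where(visited, np.inf, dist)
        idx = np.argmin(d)
        if not np.isfinite(d.flat[idx]):
            break
        r, c = divmod(idx, n_cols)
        visited[r, c] = True
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if not (0 <= rr < n_rows and 0 <= cc < n_cols):
                    continue
                if not np.isfinite(cost[rr, cc]):
                    continue
                step = friction.cell_size * (np.sqrt(2.0) if dr and dc else 1.0)
                nd = dist[r, c] + step * (cost[r, c] + cost[rr, cc]) / 2.0
                if nd < dist[rr, cc]:
                    dist[rr, cc] = nd
    return dist / 60.0
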