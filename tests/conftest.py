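"""Shared fixtures and independent oracle helpers.

The oracles here deliberately avoid the code paths they check: component
counts come from a hand-rolled union-find over an explicit threshold sweep,
shortest paths from a triple-loop Floyd-Warshall, slopes from the textbook
closed-form OLS expression, and partitions from exhaustive enumeration.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from kbinet.io import SUVTable
from kbinet.networks import WeightedNetwork


class UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra

    def n_components(self) -> int:
        return len({self.find(i) for i in range(len(self.parent))})


def components_at_threshold(weights: np.ndarray, lam: float) -> int:
    """Component count of the graph admitting edges of weight <= lam."""
    n = weights.shape[0]
    uf = UnionFind(n)
    for i in range(n):
        for j in range(i + 1, n):
            if weights[i, j] <= lam:
                uf.union(i, j)
    return uf.n_components()


def floyd_warshall(weights: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """All-pairs shortest path lengths by the classic triple loop."""
    n = weights.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and mask[i, j]:
                d[i, j] = weights[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def ols_slope(x, y) -> float:
    """Closed-form OLS slope Sum (x-xbar)(y-ybar) / Sum (x-xbar)^2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2))


def set_partitions(items: list):
    """Every partition of a list into non-empty blocks (Bell-number many)."""
    if len(items) == 1:
        yield [items]
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def random_complete_network(rng: np.random.Generator, n: int) -> WeightedNetwork:
    w = rng.uniform(0.0, 2.0, size=(n, n))
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    return WeightedNetwork(weights=w, roi_labels=[f"R{i}" for i in range(n)])


def random_suv_table(rng: np.random.Generator, k: int, n: int, group: str = "g") -> SUVTable:
    return SUVTable(
        values=rng.uniform(1.0, 9.0, size=(k, n)),
        subject_ids=[f"s{i}" for i in range(k)],
        roi_labels=[f"R{j}" for j in range(n)],
        group=group,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240531)
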