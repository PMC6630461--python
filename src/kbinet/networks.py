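"""Group-wise weighted network construction from ROI uptake tables.

The connectivity between two regions is a correlation *distance*: for
regions *i* and *j* with across-subject uptake vectors ``SUV_i``, ``SUV_j``,

    w_ij = 1 - corr(SUV_i, SUV_j)

so perfectly coupled regions sit at distance 0 and anti-coupled regions at
distance 2.  Pearson correlation is the default; Spearman and Kendall are
drop-in rank-based alternatives.  Each edge also carries the two-sided
p-value of the test of zero correlation, which feeds the Bonferroni edge
filter applied before classical graph indices (path length, diameter,
modularity).  Persistence-based indices deliberately use the unfiltered
distance matrix: the filtration itself sweeps every threshold, so no single
significance cut-off has to be chosen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
from scipy import stats

if TYPE_CHECKING:  # pragma: no cover
    from .io import SUVTable

__all__ = [
    "WeightedNetwork",
    "EdgePValues",
    "correlation_distance",
    "bonferroni_filter",
]

_CLIP_TOL = 1e-12  # numerical noise allowed outside [0, 2] before erroring


@dataclass
class WeightedNetwork:
    """Symmetric ROI x ROI matrix of edge weights.

    ``mask`` marks which edges are present; ``None`` means the complete
    graph (every off-diagonal pair).  Edge filtering removes edges by
    clearing mask entries — the stored weights are never altered.
    """

    weights: np.ndarray
    roi_labels: list[str]
    mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"weights must be square, got shape {w.shape}")
        if len(self.roi_labels) != w.shape[0]:
            raise ValueError("roi_labels length does not match weights")
        if len(set(self.roi_labels)) != len(self.roi_labels):
            raise ValueError("roi_labels must be unique")
        if not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite")
        if not np.allclose(w, w.T, atol=1e-8, rtol=0.0):
            raise ValueError("weights must be symmetric (tolerance 1e-8)")
        w = (w + w.T) / 2.0
        np.fill_diagonal(w, 0.0)
        self.weights = w
        if self.mask is not None:
            m = np.asarray(self.mask, dtype=bool)
            if m.shape != w.shape:
                raise ValueError("mask shape does not match weights")
            m = m & m.T
            np.fill_diagonal(m, False)
            self.mask = m

    @property
    def n_roi(self) -> int:
        return self.weights.shape[0]

    def edge_mask(self) -> np.ndarray:
        """Boolean matrix of present edges (complete graph if no mask)."""
        if self.mask is not None:
            return self.mask
        m = np.ones_like(self.weights, dtype=bool)
        np.fill_diagonal(m, False)
        return m

    def is_complete(self) -> bool:
        return self.mask is None or bool(np.all(self.edge_mask() == ~np.eye(self.n_roi, dtype=bool)))


@dataclass
class EdgePValues:
    """Two-sided p-values of the zero-correlation test per ROI pair."""

    pvals: np.ndarray
    alpha: float = 0.05
    m_tests: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.pvals, dtype=float)
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValueError("pvals must be a square matrix")
        off = p[~np.eye(p.shape[0], dtype=bool)]
        if off.size and (np.nanmin(off) < 0 or np.nanmax(off) > 1):
            raise ValueError("p-values must lie in [0, 1]")
        self.pvals = p
        n = p.shape[0]
        expected = n * (n - 1) // 2
        if self.m_tests == 0:
            self.m_tests = expected
        elif self.m_tests != expected:
            raise ValueError(f"m_tests must equal N(N-1)/2 = {expected}")


def _pearson_matrix(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    k = values.shape[0]
    r = np.corrcoef(values, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    # two-sided test of r = 0 with K-2 degrees of freedom
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((k - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df=k - 2)
    p[np.isnan(p)] = 0.0  # |r| == 1 -> t = inf -> p = 0
    return r, p


def _kendall_matrix(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = values.shape[1]
    r = np.eye(n)
    p = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            res = stats.kendalltau(values[:, i], values[:, j])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    return r, p


def correlation_distance(
    suv: "SUVTable",
    method: str = "pearson",
) -> tuple[WeightedNetwork, EdgePValues]:
    """Build the group-wise distance network w = 1 - corr from an uptake table.

    Parameters
    ----------
    suv
        Subject x ROI table; correlations are taken across subjects,
        so at least 3 subjects are required.
    method
        ``"pearson"`` (default), ``"spearman"`` or ``"kendall"``.

    Returns
    -------
    (WeightedNetwork, EdgePValues)
        The complete distance network and the matching matrix of
        two-sided p-values for the zero-correlation test.
    """
    values = np.asarray(suv.values, dtype=float)
    k, n = values.shape
    if k < 3:
        raise ValueError(f"need at least 3 subjects for correlation, got {k}")
    sd = values.std(axis=0, ddof=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        labels = [suv.roi_labels[i] for i in dead]
        raise ValueError(f"zero-variance ROI(s): {labels}")

    if method == "pearson":
        r, p = _pearson_matrix(values)
    elif method == "spearman":
        res = stats.spearmanr(values)
        r = np.clip(np.atleast_2d(res.statistic), -1.0, 1.0)
        p = np.atleast_2d(res.pvalue)
    elif method == "kendall":
        r, p = _kendall_matrix(values)
    else:
        raise ValueError(f"unknown correlation method: {method!r}")

    w = 1.0 - r
    if w.min() < -_CLIP_TOL or w.max() > 2.0 + _CLIP_TOL:
        raise ValueError("correlation distance outside [0, 2] beyond tolerance")
    w = np.clip(w, 0.0, 2.0)
    np.fill_diagonal(w, 0.0)
    np.fill_diagonal(p, 1.0)
    p = (p + p.T) / 2.0

    net = WeightedNetwork(
        weights=w,
        roi_labels=list(suv.roi_labels),
        meta={"distance": method, "group": suv.group, "n_subjects": k},
    )
    return net, EdgePValues(pvals=p)


def bonferroni_filter(
    network: WeightedNetwork,
    pvals: EdgePValues,
    alpha: float = 0.05,
) -> WeightedNetwork:
    """Keep only edges whose p-value clears the Bonferroni threshold.

    An edge survives iff ``p_ij < alpha / m_tests`` (strict), where
    ``m_tests = N(N-1)/2`` is the number of unique ROI pairs.  Removed
    edges become absent from the graph rather than zero-length; retained
    weights are unchanged.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if pvals.pvals.shape != network.weights.shape:
        raise ValueError("pvals shape does not match network")
    threshold = alpha / pvals.m_tests
    keep = (pvals.pvals < threshold) & network.edge_mask()
    meta = dict(network.meta)
    meta.update({"filter": "bonferroni", "alpha": alpha, "threshold": threshold})
    return WeightedNetwork(
        weights=network.weights.copy(),
        roi_labels=list(network.roi_labels),
        mask=keep,
        meta=meta,
    )
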