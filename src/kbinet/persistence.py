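"""Zeroth persistent homology of weighted networks and the KBI index.

A weighted distance network induces a *graph filtration*: the nested family
of binary graphs obtained by admitting every edge of weight <= lam as lam
grows from 0.  Its zeroth persistent homology tracks connected components;
the lam values at which components merge are exactly the merge heights of
single-linkage agglomeration, i.e. the edge weights of a minimum spanning
tree.  For a connected N-node network the maximal filtration is

    lam_0 = 0 <= lam_1 <= ... <= lam_{m-1},        m = N.

Three univariate indices summarize the filtration:

* BNP — |OLS slope| of the Betti number plot beta_0(lam), the classical
  persistent-homology readout;
* SIP — |OLS slope| of the *integrated persistent feature* (IPF) plot

      IPF(lam_i) = (m - i) / (m (m - 1)) * sum_{k=i+1}^{m-1} lam_k

  for i <= m - 2 and IPF(lam_{m-1}) = 0, which couples the remaining
  component count with the remaining aggregation cost; both slopes measure
  how fast the network integrates into one component;
* KBI — a kernel similarity between a network's IPF plot X = {x_i} and a
  control-derived template T = {t_i} (points paired by lam-sorted index):

      KBI(X) = (1/N) * sum_i arctan(C lam_i(X)^p) arctan(C lam_i(T)^p)
                              exp(-||x_i - t_i||^2 / (2 sigma^2))

  the persistence-weighted Gaussian kernel: long-lived (large-lam) features
  get weight near pi/2, noisy short-lived ones near 0.  Defaults: p = 5,
  sigma = the median over plots of the within-plot median pairwise point
  distance, C = (median over plots of the within-plot median positive
  lam)^(-p).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform

from .networks import WeightedNetwork

__all__ = [
    "Filtration",
    "BettiCurve",
    "IPFPlot",
    "KernelParams",
    "graph_filtration",
    "betti_curve",
    "betti_at",
    "bnp_index",
    "ipf",
    "sip",
    "kernel_params",
    "kbi",
    "template_from_controls",
]


@dataclass
class Filtration:
    """Ordered critical values lam_0 = 0 <= lam_1 <= ... <= lam_{m-1}."""

    lam: np.ndarray

    def __post_init__(self) -> None:
        lam = np.asarray(self.lam, dtype=float)
        if lam.ndim != 1 or lam.size < 2:
            raise ValueError("filtration needs at least 2 values")
        if lam[0] != 0.0:
            raise ValueError("filtration must start at lam_0 = 0")
        if np.any(np.diff(lam) < 0):
            raise ValueError("filtration values must be non-decreasing")
        if not np.all(np.isfinite(lam)):
            raise ValueError("filtration values must be finite")
        self.lam = lam

    @property
    def m(self) -> int:
        return self.lam.size


@dataclass
class BettiCurve:
    """Step function beta_0(lam): (lam, component count) at each distinct lam."""

    points: np.ndarray  # (d, 2): lam, beta_0

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be (d, 2)")
        if np.any(np.diff(pts[:, 1]) > 0):
            raise ValueError("beta_0 must be non-increasing in lam")
        self.points = pts


@dataclass
class IPFPlot:
    """Point set x_i = (lam_i, IPF(lam_i)), i = 0..m-1."""

    points: np.ndarray  # (m, 2)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be (m, 2)")
        if np.any(pts[:, 1] < -1e-15):
            raise ValueError("IPF values must be non-negative")
        self.points = pts

    @property
    def lam(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def values(self) -> np.ndarray:
        return self.points[:, 1]


@dataclass
class KernelParams:
    """Weighting parameters of the KBI kernel: exponent p, bandwidth sigma, scale C."""

    p: int = 5
    sigma: float = 1.0
    c_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.p < 1 or int(self.p) != self.p:
            raise ValueError("p must be a positive integer")
        if not (self.sigma > 0):
            raise ValueError("sigma must be positive")
        if not (self.c_weight > 0):
            raise ValueError("c_weight must be positive")
        self.p = int(self.p)


def graph_filtration(network: WeightedNetwork) -> Filtration:
    """Critical values of the distance filtration of a complete weighted network.

    The N-1 component-merge heights equal the single-linkage dendrogram
    heights (equivalently, sorted minimum-spanning-tree edge weights);
    lam_0 = 0 is prepended.  Ties are kept as repeated values.
    """
    if network.n_roi < 2:
        raise ValueError("need at least 2 nodes")
    if not network.is_complete():
        raise ValueError(
            "graph filtration requires the unfiltered complete distance network"
        )
    condensed = squareform(network.weights, checks=False)
    merge_heights = linkage(condensed, method="single")[:, 2]
    lam = np.concatenate([[0.0], np.sort(merge_heights)])
    return Filtration(lam=lam)


def betti_at(filt: Filtration, lam: float | np.ndarray) -> np.ndarray:
    """beta_0 evaluated at arbitrary lam (right-continuous step convention)."""
    lam = np.asarray(lam, dtype=float)
    merges = filt.lam[1:]
    return filt.m - np.searchsorted(merges, lam, side="right")


def betti_curve(filt: Filtration) -> BettiCurve:
    """Betti number plot sampled at the distinct critical values.

    beta_0(lam) = m - i on [lam_i, lam_{i+1}); repeated critical values
    collapse into a single multi-drop step.
    """
    distinct = np.unique(filt.lam)
    beta = betti_at(filt, distinct)
    return BettiCurve(points=np.column_stack([distinct, beta]))


def _abs_ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0.0:
        raise ValueError("slope undefined: all lam values identical")
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    return abs(sxy / sxx)


def bnp_index(curve: BettiCurve) -> float:
    """|OLS slope| of the Betti number plot over its sampled points."""
    return _abs_ols_slope(curve.points[:, 0], curve.points[:, 1])


def ipf(filt: Filtration) -> IPFPlot:
    """Integrated persistent feature plot of a filtration.

    IPF(lam_i) multiplies the fraction-style component count (m - i) with
    the cost sum of the merges still to come, normalized by m(m-1); the
    last value is 0 by definition.
    """
    lam = filt.lam
    m = filt.m
    # tail_i = sum_{k=i+1}^{m-1} lam_k
    tail = np.concatenate([np.cumsum(lam[::-1])[::-1][1:], [0.0]])
    scale = (m - np.arange(m)) / (m * (m - 1))
    values = scale * tail
    values[-1] = 0.0
    return IPFPlot(points=np.column_stack([lam, values]))


def sip(plot: IPFPlot) -> float:
    """|OLS slope| of the IPF plot: the network integration rate."""
    return _abs_ols_slope(plot.lam, plot.values)


def _positive_points(plot: IPFPlot) -> np.ndarray:
    return plot.points[plot.points[:, 0] > 0.0]


def kernel_params(plots: Iterable[IPFPlot], p: int = 5) -> KernelParams:
    """Data-driven kernel parameters from the plots entering an analysis.

    sigma is the median over plots of the within-plot median Euclidean
    distance between point pairs; C is the median over plots of the
    within-plot median lam, raised to -p.  The lam_0 = 0 point is excluded
    from both medians so that C stays finite and the medians describe the
    informative part of each plot.
    """
    plots = list(plots)
    if not plots:
        raise ValueError("need at least one IPF plot")
    dist_medians = []
    lam_medians = []
    for plot in plots:
        pts = _positive_points(plot)
        if pts.shape[0] < 2:
            raise ValueError("each plot needs at least 2 points with lam > 0")
        dist_medians.append(float(np.median(pdist(pts))))
        lam_medians.append(float(np.median(pts[:, 0])))
    sigma = float(np.median(dist_medians))
    if sigma == 0.0:
        raise ValueError("sigma is zero: plot points coincide in every plot")
    lam_med = float(np.median(lam_medians))
    return KernelParams(p=p, sigma=sigma, c_weight=lam_med ** (-p))


def kbi(X: IPFPlot, T: IPFPlot, params: KernelParams) -> float:
    """Kernel-based IPF index of plot X against template T.

    Points are paired by lam-sorted index (both plots derive from the same
    atlas, so cardinalities match).  Each pair contributes an arctan
    persistence weight for both plots times a Gaussian factor in the point
    distance; the result lies in [0, (pi/2)^2].
    """
    px = np.asarray(X.points, dtype=float)
    pt = np.asarray(T.points, dtype=float)
    if px.shape != pt.shape:
        raise ValueError(
            f"point counts differ: {px.shape[0]} vs {pt.shape[0]}"
        )
    if not (np.all(np.isfinite(px)) and np.all(np.isfinite(pt))):
        raise ValueError("non-finite plot points")
    px = px[np.argsort(px[:, 0], kind="stable")]
    pt = pt[np.argsort(pt[:, 0], kind="stable")]
    c, p, sigma = params.c_weight, params.p, params.sigma
    wx = np.arctan(c * px[:, 0] ** p)
    wt = np.arctan(c * pt[:, 0] ** p)
    sq_dist = np.sum((px - pt) ** 2, axis=1)
    gauss = np.exp(-sq_dist / (2.0 * sigma**2))
    return float(np.mean(wx * wt * gauss))


def template_from_controls(nc_suv, method: str = "pearson") -> IPFPlot:
    """IPF template from the control group's average metabolic network."""
    from .networks import correlation_distance

    net, _ = correlation_distance(nc_suv, method=method)
    return ipf(graph_filtration(net))
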