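"""Ripley's K/L statistics on rectangular windows with isotropic edge correction.

The univariate estimator is

    K_hat(r) = |A| / (n (n-1)) * sum_i sum_{j != i} w_ij 1(d_ij <= r)

where w_ij is the isotropic edge-correction weight: the reciprocal of the
fraction of the circle centered on point i with radius d_ij that lies inside
the window.  The bivariate form K12 counts type-2 neighbors of type-1 points
with |A| / (n1 n2) normalization.  Curves are reported on the L scale,
L(r) - r with L = sqrt(K / pi), which is identically zero under complete
spatial randomness: positive values indicate clumping, negative values
regularity.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist

from forestspat.errors import GridMismatchError, InsufficientPointsError
from forestspat.stem_map import Window

__all__ = [
    "PointPattern", "RGrid", "SummaryCurve", "pairwise_distances",
    "isotropic_edge_weight", "ripley_K", "ripley_K12", "L_transform",
    "ripley_L",
]


@dataclass
class PointPattern:
    """Bare point locations (optionally labeled) inside a window.

    Labels support the bivariate statistics; by convention label 1 is the
    large-diameter subpopulation and label 2 the small-diameter one, but any
    two values work.
    """

    window: Window
    points: np.ndarray
    labels: Optional[np.ndarray] = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != len(self.points):
                raise ValueError("labels must match points in length")
        inside = self.window.contains(self.points[:, 0], self.points[:, 1])
        if not np.all(inside):
            raise ValueError(
                f"{int((~inside).sum())} point(s) outside the window")

    @property
    def n(self) -> int:
        return len(self.points)

    def of_label(self, label) -> np.ndarray:
        if self.labels is None:
            raise ValueError("pattern has no labels")
        return self.points[self.labels == label]


@dataclass(frozen=True)
class RGrid:
    """Uniform grid of evaluation distances r_k = k * r_max / n_steps."""

    r_max: float
    n_steps: int = 512

    def __post_init__(self):
        if self.r_max <= 0 or self.n_steps < 1:
            raise ValueError("r_max must be positive and n_steps >= 1")

    @property
    def r(self) -> np.ndarray:
        return np.linspace(0.0, self.r_max, self.n_steps + 1)

    @property
    def dr(self) -> float:
        return self.r_max / self.n_steps

    def prefix(self, r_max: float) -> "RGrid":
        """The [0, r_max] prefix of this grid (same spacing)."""
        k = int(np.floor(r_max / self.dr + 1e-9))
        if k < 1:
            raise ValueError("prefix too short for this grid")
        return RGrid(r_max=k * self.dr, n_steps=k)


@dataclass
class SummaryCurve:
    """A discretized summary statistic (one value per grid distance)."""

    grid: RGrid
    values: np.ndarray
    estimator: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.grid.n_steps + 1:
            raise GridMismatchError("values do not match the r-grid length")

    def to_csv(self, path) -> None:
        header = json.dumps({"estimator": self.estimator, **self.meta})
        with open(path, "w") as fh:
            fh.write(f"# {header}\n")
            fh.write("r,value\n")
            for r, v in zip(self.grid.r, self.values):
                fh.write(f"{r:.10g},{v:.10g}\n")


def pairwise_distances(pattern: PointPattern) -> np.ndarray:
    """Full symmetric Euclidean distance matrix; warns on duplicate points."""
    if pattern.n < 2:
        raise InsufficientPointsError("need at least 2 points")
    d = cdist(pattern.points, pattern.points)
    off = d[~np.eye(pattern.n, dtype=bool)]
    if np.any(off == 0):
        warnings.warn("pattern contains duplicate points", stacklevel=2)
    return d


def isotropic_edge_weight(center, d, window: Window):
    """Isotropic (Ripley) edge-correction weight, >= 1.

    The weight is 1/f where f is the fraction of the circumference of the
    circle of radius ``d`` centered at ``center`` lying inside the window,
    computed from the analytic circle-rectangle arc geometry.  Exact for
    d <= min(width, height) / 2; beyond that a numeric arc integration is
    used and the weight is capped at 4.

    ``center`` is (x, y) or an (n, 2) array; ``d`` broadcasts against it.
    """
    c = np.asarray(center, dtype=float)
    scalar = c.ndim == 1 and np.ndim(d) == 0
    c = c.reshape(-1, 2)
    d_arr = np.broadcast_to(np.asarray(d, dtype=float), (c.shape[0],)).copy()
    if np.any(d_arr <= 0):
        raise ValueError("d must be positive")
    w = _edge_weights(c[:, 0], c[:, 1], d_arr, window)
    return float(w[0]) if scalar else w


def _edge_weights(x, y, d, window: Window) -> np.ndarray:
    """Vectorized edge-correction weights (arrays of equal shape)."""
    W, H = window.width, window.height
    analytic_ok = d <= min(W, H) / 2.0 + 1e-12
    out = np.empty_like(np.asarray(d, dtype=float))
    if np.any(analytic_ok):
        out[analytic_ok] = _analytic_weight(
            np.asarray(x)[analytic_ok], np.asarray(y)[analytic_ok],
            np.asarray(d)[analytic_ok], W, H)
    if np.any(~analytic_ok):
        warnings.warn("edge-correction distance beyond analytic validity; "
                      "using numeric arc integration with weight capped at 4",
                      stacklevel=3)
        out[~analytic_ok] = _numeric_weight(
            np.asarray(x)[~analytic_ok], np.asarray(y)[~analytic_ok],
            np.asarray(d)[~analytic_ok], W, H)
    return out


def _analytic_weight(x, y, d, W, H) -> np.ndarray:
    # Distances to the four sides.
    eL, eR, eB, eT = x, W - x, y, H - y
    with np.errstate(invalid="ignore"):
        aL = np.arccos(np.minimum(eL / d, 1.0))
        aR = np.arccos(np.minimum(eR / d, 1.0))
        aB = np.arccos(np.minimum(eB / d, 1.0))
        aT = np.arccos(np.minimum(eT / d, 1.0))
    # Exterior arc per side, minus double-counted corner overlaps.
    outside = 2.0 * (aL + aR + aB + aT)
    for a, b in ((aL, aB), (aL, aT), (aR, aB), (aR, aT)):
        outside -= np.maximum(0.0, a + b - 0.5 * np.pi)
    frac = 1.0 - outside / (2.0 * np.pi)
    frac = np.maximum(frac, 0.25)   # weight cap 4
    return 1.0 / frac


def _numeric_weight(x, y, d, W, H, n_seg: int = 1024) -> np.ndarray:
    theta = (np.arange(n_seg) + 0.5) * (2.0 * np.pi / n_seg)
    ct, st = np.cos(theta), np.sin(theta)
    px = x[:, None] + d[:, None] * ct[None, :]
    py = y[:, None] + d[:, None] * st[None, :]
    inside = ((px >= 0) & (px <= W) & (py >= 0) & (py <= H)).mean(axis=1)
    frac = np.maximum(inside, 0.25)
    return 1.0 / frac


def _weighted_k_values(centers: np.ndarray, neighbors: np.ndarray,
                       grid: RGrid, window: Window, self_pairs: bool,
                       chunk: int = 256):
    """Sum of edge weights over pairs with d <= r_k, per grid distance.

    ``self_pairs=True`` marks the univariate case where ``centers`` is
    ``neighbors`` and the diagonal must be excluded.
    """
    r = grid.r
    sums = np.zeros_like(r)
    n_dup = 0
    for lo in range(0, len(centers), chunk):
        blk = centers[lo:lo + chunk]
        d = cdist(blk, neighbors)
        if self_pairs:
            rows = np.arange(lo, lo + len(blk))
            d[np.arange(len(blk)), rows] = np.inf
        mask = d <= grid.r_max
        zero = mask & (d == 0)
        n_dup += int(zero.sum())
        if np.any(mask):
            di = d[mask]
            xi = np.broadcast_to(blk[:, 0:1], d.shape)[mask]
            yi = np.broadcast_to(blk[:, 1:2], d.shape)[mask]
            w = np.ones_like(di)
            pos = di > 0
            w[pos] = _edge_weights(xi[pos], yi[pos], di[pos], window)
            order = np.argsort(di, kind="stable")
            di_s = di[order]
            cw = np.concatenate([[0.0], np.cumsum(w[order])])
            sums += cw[np.searchsorted(di_s, r, side="right")]
    if n_dup:
        warnings.warn(f"{n_dup} zero-distance pair(s) in the pattern",
                      stacklevel=3)
    return sums


def ripley_K(pattern: PointPattern, grid: RGrid) -> SummaryCurve:
    """Univariate Ripley K with isotropic edge correction (K scale, m^2)."""
    if pattern.n < 2:
        raise InsufficientPointsError("Ripley K needs at least 2 points")
    half_min = min(pattern.window.width, pattern.window.height) / 2.0
    if grid.r_max > half_min + 1e-9:
        raise ValueError(
            f"r_max {grid.r_max:g} exceeds half the shorter window side "
            f"({half_min:g} m), outside the analytic correction's validity")
    sums = _weighted_k_values(pattern.points, pattern.points, grid,
                              pattern.window, self_pairs=True)
    factor = pattern.window.area / (pattern.n * (pattern.n - 1))
    return SummaryCurve(grid=grid, values=factor * sums,
                        estimator="ripley_K_isotropic",
                        meta={"n": pattern.n,
                              "window": [pattern.window.width,
                                         pattern.window.height]})


def ripley_K12(pattern: PointPattern, grid: RGrid,
               label1=1, label2=2) -> SummaryCurve:
    """Bivariate Ripley K12 (type-2 neighbors of type-1 points), K scale."""
    p1 = pattern.of_label(label1)
    p2 = pattern.of_label(label2)
    if len(p1) < 1 or len(p2) < 1:
        raise InsufficientPointsError("both types need at least 1 point")
    half_min = min(pattern.window.width, pattern.window.height) / 2.0
    if grid.r_max > half_min + 1e-9:
        raise ValueError("r_max exceeds half the shorter window side")
    sums = _weighted_k_values(p1, p2, grid, pattern.window, self_pairs=False)
    factor = pattern.window.area / (len(p1) * len(p2))
    return SummaryCurve(grid=grid, values=factor * sums,
                        estimator="ripley_K12_isotropic",
                        meta={"n1": int(len(p1)), "n2": int(len(p2)),
                              "window": [pattern.window.width,
                                         pattern.window.height]})


def L_transform(curve: SummaryCurve) -> SummaryCurve:
    """L(r) - r with L = sqrt(K / pi); zero exactly where K = pi r^2."""
    k = curve.values
    if np.any(k < -1e-12):
        raise ValueError("K values must be non-negative")
    values = np.sqrt(np.maximum(k, 0.0) / np.pi) - curve.grid.r
    return SummaryCurve(grid=curve.grid, values=values,
                        estimator=curve.estimator.replace("K", "L") + "_minus_r",
                        meta=dict(curve.meta))


def ripley_L(pattern: PointPattern, grid: RGrid) -> SummaryCurve:
    """Convenience: univariate L(r) - r."""
    return L_transform(ripley_K(pattern, grid))


def ripley_L12(pattern: PointPattern, grid: RGrid,
               label1=1, label2=2) -> SummaryCurve:
    """Convenience: bivariate L12(r) - r."""
    return L_transform(ripley_K12(pattern, grid, label1, label2))
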