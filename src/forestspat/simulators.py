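"""Point-process simulators spanning the uniform -> random -> clustered gradient.

Three families, each returning an exact point count:

* simple sequential inhibition (SSI): uniform proposals accepted only if at
  least the inhibition radius away from every accepted point — increasingly
  uniform patterns at radii 10, 15, 20 m;
* complete spatial randomness, either by resampling fresh uniform points or
  by jittering a reference pattern within a disc (reflected at the window
  boundary);
* the Matérn cluster process — Poisson parents on the window dilated by the
  cluster radius, Poisson(mu) offspring uniform in a disc around each
  parent — thinned uniformly at random to the target count, increasingly
  aggregated at cluster radii 20, 15, 10 m.

The seven canonical experiment levels are ssi-20, ssi-15, ssi-10, random,
matern-20, matern-15 and matern-10 (in gradient order).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist

from forestspat.errors import PackingFailureError, SimulatorError
from forestspat.spatial import PointPattern
from forestspat.stem_map import Window

__all__ = ["PatternSpec", "SEVEN_LEVELS", "simulate_ssi",
           "simulate_matern_fixed_n", "simulate_randomized",
           "simulate_level"]

#: cluster-center intensity (parents per m^2 of the dilated window)
DEFAULT_KAPPA = 0.00055
#: mean offspring per cluster
DEFAULT_MU = 5.0


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class PatternSpec:
    """One level of the pattern gradient."""

    family: str                     # 'ssi' | 'csr' | 'jitter' | 'matern'
    radius: Optional[float] = None  # inhibition / cluster / jitter radius (m)
    kappa: float = DEFAULT_KAPPA
    mu: float = DEFAULT_MU


#: the canonical seven levels, ordered from strong inhibition to clustering
SEVEN_LEVELS: dict[str, PatternSpec] = {
    "ssi-20": PatternSpec("ssi", 20.0),
    "ssi-15": PatternSpec("ssi", 15.0),
    "ssi-10": PatternSpec("ssi", 10.0),
    "random": PatternSpec("csr"),
    "matern-20": PatternSpec("matern", 20.0),
    "matern-15": PatternSpec("matern", 15.0),
    "matern-10": PatternSpec("matern", 10.0),
}


def simulate_ssi(n: int, window: Window, inhibition_radius: float,
                 seed=None, max_attempts: int = 2_000_000) -> PointPattern:
    """Simple sequential inhibition with a hard minimum spacing.

    Points are placed one at a time from uniform proposals; a proposal
    within ``inhibition_radius`` of any accepted point is rejected.
    ``max_attempts`` consecutive rejections abort with a
    :class:`PackingFailureError` reporting how many points were placed.

    The default budget is sized for packings near the random-sequential-
    adsorption jamming limit (e.g. 451 points at 20 m spacing in the
    800 x 320 m window, where the last few points each need ~10^5
    proposals); genuinely infeasible requests still abort within seconds.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = _rng(seed)
    W, H = window.width, window.height
    pts = np.empty((n, 2))
    placed = 0
    r2 = inhibition_radius ** 2
    misses = 0
    while placed < n:
        # propose in batches to amortize RNG cost
        batch = rng.random((32, 2)) * (W, H)
        for p in batch:
            if placed >= n:
                break
            if placed == 0 or r2 == 0 or np.min(
                    ((pts[:placed] - p) ** 2).sum(axis=1)) >= r2:
                pts[placed] = p
                placed += 1
                misses = 0
            else:
                misses += 1
                if misses >= max_attempts:
                    raise PackingFailureError(
                        f"SSI packing failed: {placed} of {n} points placed "
                        f"at radius {inhibition_radius} m",
                        points_placed=placed)
    return PointPattern(window=window, points=pts[:n])


def simulate_matern_fixed_n(n: int, window: Window, cluster_radius: float,
                            kappa: float = DEFAULT_KAPPA,
                            mu: float = DEFAULT_MU, seed=None,
                            max_retries: int = 1000) -> PointPattern:
    """Matérn cluster process thinned uniformly to exactly ``n`` points.

    Parents are Poisson(kappa) on the window dilated by the cluster radius
    (the standard edge-effect guard; parents are never emitted); each parent
    receives Poisson(mu) offspring uniform in its disc; offspring outside
    the window are discarded.  If fewer than ``n`` survive, the whole
    realization is regenerated (partial top-ups would bias the process), up
    to ``max_retries`` times.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed)
    W, H = window.width, window.height
    R = cluster_radius
    area_dil = (W + 2 * R) * (H + 2 * R)
    for _ in range(max_retries):
        n_parents = rng.poisson(kappa * area_dil)
        if n_parents == 0:
            continue
        parents = rng.random((n_parents, 2)) * (W + 2 * R, H + 2 * R) - R
        n_off = rng.poisson(mu, size=n_parents)
        total = int(n_off.sum())
        if total == 0:
            continue
        centers = np.repeat(parents, n_off, axis=0)
        # uniform in the disc of radius R
        rho = R * np.sqrt(rng.random(total))
        theta = rng.random(total) * 2 * np.pi
        off = centers + np.column_stack([rho * np.cos(theta),
                                         rho * np.sin(theta)])
        inside = ((off[:, 0] >= 0) & (off[:, 0] <= W)
                  & (off[:, 1] >= 0) & (off[:, 1] <= H))
        off = off[inside]
        if len(off) >= n:
            keep = rng.choice(len(off), size=n, replace=False)
            return PointPattern(window=window, points=off[keep])
    raise SimulatorError(
        f"Matérn simulation failed to reach {n} points in "
        f"{max_retries} tries (kappa={kappa}, mu={mu}, R={cluster_radius})")


def simulate_randomized(reference: PointPattern, mode: str = "resample_csr",
                        jitter_radius: Optional[float] = None,
                        seed=None) -> PointPattern:
    """Spatially random re-placement of a reference pattern.

    ``resample_csr`` draws fresh uniform points at the reference count
    (the default 'random' level); ``jitter`` displaces each reference point
    uniformly within a disc of ``jitter_radius``, reflecting displacements
    at the window boundary so they stay local.
    """
    if reference.n == 0:
        raise ValueError("reference pattern is empty")
    rng = _rng(seed)
    W, H = reference.window.width, reference.window.height
    if mode == "resample_csr":
        pts = rng.random((reference.n, 2)) * (W, H)
    elif mode == "jitter":
        if jitter_radius is None:
            raise ValueError("jitter mode requires jitter_radius")
        rho = jitter_radius * np.sqrt(rng.random(reference.n))
        theta = rng.random(reference.n) * 2 * np.pi
        pts = reference.points + np.column_stack([rho * np.cos(theta),
                                                  rho * np.sin(theta)])
        pts[:, 0] = _reflect(pts[:, 0], W)
        pts[:, 1] = _reflect(pts[:, 1], H)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return PointPattern(window=reference.window, points=pts)


def _reflect(coord: np.ndarray, extent: float) -> np.ndarray:
    """Fold coordinates into [0, extent] by repeated boundary reflection."""
    folded = np.mod(coord, 2 * extent)
    return np.where(folded > extent, 2 * extent - folded, folded)


def simulate_level(level: str, n: int, window: Window, seed=None,
                   reference: Optional[PointPattern] = None) -> PointPattern:
    """Simulate one named gradient level at an exact count."""
    if level not in SEVEN_LEVELS:
        raise KeyError(f"unknown level {level!r}; "
                       f"choose from {list(SEVEN_LEVELS)}")
    spec = SEVEN_LEVELS[level]
    rng = _rng(seed)
    if spec.family == "ssi":
        return simulate_ssi(n, window, spec.radius, seed=rng)
    if spec.family == "csr":
        if reference is not None:
            return simulate_randomized(reference, "resample_csr", seed=rng)
        pts = rng.random((n, 2)) * (window.width, window.height)
        return PointPattern(window=window, points=pts)
    return simulate_matern_fixed_n(n, window, spec.radius, kappa=spec.kappa,
                                   mu=spec.mu, seed=rng)


def nearest_neighbor_distances(pattern: PointPattern) -> np.ndarray:
    """Distance from each point to its nearest neighbor."""
    d = cdist(pattern.points, pattern.points)
    np.fill_diagonal(d, np.inf)
    return d.min(axis=1)
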