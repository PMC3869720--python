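"""Loosmore–Ford Monte Carlo goodness-of-fit testing.

The deviation measure for curve i within the joint set {empirical union
simulations} is the integrated squared deviation from the leave-one-out
mean,

    u_i = sum_k ( H_i(r_k) - Hbar_{-i}(r_k) )^2 * dr,

and the Monte Carlo p-value is rank-based,

    p = (1 + #{ simulated u >= observed u }) / (n_sim + 1),

so the smallest attainable p with 999 simulations is 0.001.  Ties count
toward rejection (the conservative convention).  Tests are evaluated on the
[0, r_max] prefix of the summary-curve grid, r_max = 9 m by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from forestspat.errors import GridMismatchError
from forestspat.null_models import make_envelope
from forestspat.simulators import simulate_ssi
from forestspat.spatial import PointPattern, RGrid, SummaryCurve
from forestspat.stem_map import Window

__all__ = ["GofResult", "TestBattery", "u_statistic", "u_statistics",
           "gof_test", "bonferroni_threshold", "power_vs_hardcore"]

#: spacing of the default summary grid (80 m / 512 steps), reused for testing
DEFAULT_DR = 80.0 / 512


def u_statistics(curves: np.ndarray, dr: float) -> np.ndarray:
    """Leave-one-out integrated squared deviations for a stack of curves.

    ``curves`` has one row per curve (row 0 conventionally the empirical
    one); each row is compared with the pointwise mean of all other rows.
    """
    curves = np.asarray(curves, dtype=float)
    m = curves.shape[0]
    if m < 3:
        raise ValueError("need at least 3 curves (1 evaluated + 2 references)")
    total = curves.sum(axis=0)
    loo_mean = (total[None, :] - curves) / (m - 1)
    dev = curves - loo_mean
    return (dev ** 2).sum(axis=1) * dr


def u_statistic(curve: SummaryCurve, references: Sequence[SummaryCurve],
                r_max: Optional[float] = None) -> float:
    """u for one curve against its reference set (shared grid required)."""
    if len(references) < 2:
        raise ValueError("need at least 2 reference curves")
    for ref in references:
        if ref.grid != curve.grid:
            raise GridMismatchError("curves evaluated on different grids")
    values = np.vstack([curve.values] + [ref.values for ref in references])
    if r_max is not None:
        keep = curve.grid.r <= r_max + 1e-9
        values = values[:, keep]
    return float(u_statistics(values, curve.grid.dr)[0])


@dataclass
class GofResult:
    """Outcome of one Loosmore–Ford test."""

    u_observed: float
    u_simulated: np.ndarray
    p_value: float
    r_max: float
    n_sim: int
    null: str
    seed: Optional[int]

    def to_json(self) -> str:
        return json.dumps({
            "u_observed": self.u_observed,
            "p_value": self.p_value,
            "r_max": self.r_max,
            "n_sim": self.n_sim,
            "null": self.null,
            "seed": self.seed,
        }, indent=1)


def gof_test(pattern: PointPattern, statistic: str = "L", null: str = "csr",
             n_sim: int = 999, r_max: float = 9.0, seed=None,
             grid: Optional[RGrid] = None, moved_label=1,
             label1=1, label2=2) -> GofResult:
    """Loosmore–Ford test of a pattern against a null model over [0, r_max].

    Builds the Monte Carlo envelope, computes u for the empirical curve and
    for every simulated curve (each against the leave-one-out mean of the
    joint set), and returns the rank-based p-value.
    """
    if grid is None:
        n_steps = max(2, int(round(r_max / DEFAULT_DR)))
        grid = RGrid(r_max=r_max, n_steps=n_steps)
    env = make_envelope(pattern, statistic, null, n_sim, grid, seed=seed,
                        moved_label=moved_label, label1=label1, label2=label2)
    curves = np.vstack([env.empirical.values, env.simulated])
    u = u_statistics(curves, grid.dr)
    u_obs, u_sim = u[0], u[1:]
    p = (1.0 + np.count_nonzero(u_sim >= u_obs)) / (n_sim + 1.0)
    seed_int = None if isinstance(seed, np.random.Generator) else seed
    return GofResult(u_observed=float(u_obs), u_simulated=u_sim,
                     p_value=float(p), r_max=grid.r_max, n_sim=n_sim,
                     null=null, seed=seed_int)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test threshold alpha / m controlling the family-wise error rate."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


@dataclass
class TestBattery:
    """A family of named GOF tests under Bonferroni control."""

    results: list          # of (name, GofResult)
    alpha: float = 0.05

    @property
    def threshold(self) -> float:
        return bonferroni_threshold(self.alpha, len(self.results))

    def to_frame(self) -> pd.DataFrame:
        thr = self.threshold
        rows = []
        for name, res in self.results:
            rows.append({
                "test": name, "u_observed": res.u_observed,
                "p_value": res.p_value, "n_sim": res.n_sim,
                "r_max": res.r_max, "null": res.null,
                "threshold": thr, "significant": res.p_value <= thr,
            })
        return pd.DataFrame(rows)


def power_vs_hardcore(n: int, window: Window, hardcore_radius: float,
                      n_experiments: int = 100, n_sim: int = 99,
                      r_max: float = 9.0, alpha: float = 0.05,
                      seed=None) -> float:
    """Monte Carlo power of the CSR test against a hard-core alternative.

    Simulates ``n_experiments`` simple-sequential-inhibition patterns of
    ``n`` points with the given minimum spacing, runs the Loosmore–Ford
    test of each against CSR, and returns the fraction rejected at
    ``alpha``.  With radius 0 the null is true and the power estimates the
    test's size.
    """
    streams = np.random.SeedSequence(seed).spawn(n_experiments)
    rejected = 0
    for ss in streams:
        rng = np.random.default_rng(ss)
        if hardcore_radius > 0:
            pat = simulate_ssi(n, window, hardcore_radius, seed=rng)
        else:
            from forestspat.null_models import simulate_csr
            pat = simulate_csr(n, window, rng)
        res = gof_test(pat, "L", "csr", n_sim=n_sim, r_max=r_max, seed=rng)
        if res.p_value <= alpha:
            rejected += 1
    return rejected / n_experiments
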