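"""Null-model replicates and Monte Carlo envelopes.

Two nulls are provided:

* complete spatial randomness (CSR) for univariate patterns — the analyzed
  subpopulation is resimulated as a binomial (fixed-n uniform) process at
  its observed count; and
* population independence for bivariate patterns — the relative intratype
  configurations are held fixed while one subpopulation is translated by a
  random toroidal shift.  Shifting only one type by a single vector is
  distributionally equivalent to shifting both, since only the relative
  displacement enters the cross statistic, and it preserves both intratype
  configurations exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from forestspat.errors import InsufficientPointsError
from forestspat.spatial import (PointPattern, RGrid, SummaryCurve,
                                ripley_K, ripley_K12, L_transform)
from forestspat.stem_map import Window

__all__ = ["EnvelopeSet", "simulate_csr", "toroidal_shift", "make_envelope"]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_csr(n: int, window: Window, seed=None) -> PointPattern:
    """n points i.i.d. uniform on the window (binomial process)."""
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = _rng(seed)
    pts = rng.random((n, 2)) * np.array([window.width, window.height])
    return PointPattern(window=window, points=pts)


def toroidal_shift(pattern: PointPattern, shift, moved_label=1
                   ) -> PointPattern:
    """Translate one labeled subpopulation modulo the window dimensions.

    Intratype toroidal pairwise distances are preserved exactly; the other
    type is unchanged.
    """
    if pattern.labels is None:
        raise ValueError("toroidal_shift needs a labeled pattern")
    dx, dy = float(shift[0]), float(shift[1])
    W, H = pattern.window.width, pattern.window.height
    pts = pattern.points.copy()
    move = pattern.labels == moved_label
    pts[move, 0] = np.mod(pts[move, 0] + dx, W)
    pts[move, 1] = np.mod(pts[move, 1] + dy, H)
    return PointPattern(window=pattern.window, points=pts,
                        labels=pattern.labels.copy())


@dataclass
class EnvelopeSet:
    """An empirical summary curve plus its Monte Carlo simulation band."""

    empirical: SummaryCurve
    simulated: np.ndarray          # (n_sim, n_r)
    null: str
    seed: Optional[int]

    def __post_init__(self):
        self.simulated = np.atleast_2d(np.asarray(self.simulated, float))
        if self.simulated.shape[1] != len(self.empirical.values):
            raise ValueError("simulated curves do not match the grid")

    @property
    def n_sim(self) -> int:
        return self.simulated.shape[0]

    @property
    def lo(self) -> np.ndarray:
        return self.simulated.min(axis=0)

    @property
    def hi(self) -> np.ndarray:
        return self.simulated.max(axis=0)

    @property
    def mean(self) -> np.ndarray:
        return self.simulated.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "r": self.empirical.grid.r,
            "empirical": self.empirical.values,
            "sim_min": self.lo,
            "sim_mean": self.mean,
            "sim_max": self.hi,
        })

    def to_csv(self, path) -> None:
        header = json.dumps({"null": self.null, "n_sim": self.n_sim,
                             "seed": self.seed,
                             "estimator": self.empirical.estimator,
                             **self.empirical.meta})
        with open(path, "w") as fh:
            fh.write(f"# {header}\n")
            self.to_frame().to_csv(fh, index=False)


def make_envelope(pattern: PointPattern, statistic: str, null: str,
                  n_sim: int, grid: RGrid, seed=None,
                  moved_label=1, label1=1, label2=2) -> EnvelopeSet:
    """Empirical curve plus ``n_sim`` null-model curves.

    ``statistic`` is ``'L'`` (univariate L(r) - r, CSR null) or ``'L12'``
    (bivariate, independence null).  The CSR null resimulates the pattern at
    its observed count; the independence null redraws one uniform toroidal
    shift vector per replicate and moves the ``moved_label`` subpopulation
    (by convention the large-diameter trees).

    One RNG stream is spawned per replicate from ``seed`` so results do not
    depend on evaluation order.
    """
    valid = {("L", "csr"), ("L12", "independence")}
    if (statistic, null) not in valid:
        raise ValueError(
            f"unsupported statistic/null combination: {statistic!r}/{null!r}")
    seed_int = None if isinstance(seed, np.random.Generator) else seed
    if isinstance(seed, np.random.Generator):
        streams = [np.random.default_rng(s)
                   for s in seed.bit_generator.seed_seq.spawn(n_sim)] \
            if hasattr(seed.bit_generator, "seed_seq") else \
            [np.random.default_rng(seed.integers(2 ** 63))
             for _ in range(n_sim)]
    else:
        streams = [np.random.default_rng(s)
                   for s in np.random.SeedSequence(seed).spawn(n_sim)]

    if statistic == "L":
        empirical = L_transform(ripley_K(pattern, grid))
        n = pattern.n
        sims = np.empty((n_sim, grid.n_steps + 1))
        for k, rng in enumerate(streams):
            rep = simulate_csr(n, pattern.window, rng)
            sims[k] = L_transform(ripley_K(rep, grid)).values
    else:
        if pattern.labels is None:
            raise ValueError("bivariate envelope needs a labeled pattern")
        empirical = L_transform(ripley_K12(pattern, grid, label1, label2))
        sims = np.empty((n_sim, grid.n_steps + 1))
        W, H = pattern.window.width, pattern.window.height
        for k, rng in enumerate(streams):
            shift = (rng.random() * W, rng.random() * H)
            rep = toroidal_shift(pattern, shift, moved_label=moved_label)
            sims[k] = L_transform(ripley_K12(rep, grid, label1,
                                             label2)).values
    return EnvelopeSet(empirical=empirical, simulated=sims, null=null,
                       seed=seed_int)
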