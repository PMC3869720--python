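#!/usr/bin/env python
"""The large-tree permutation experiment.

Replaces the large-diameter tree coordinates with realizations of seven
point processes spanning strong inhibition (ssi-20) through randomness to
strong clustering (matern-10), holding the small trees fixed, and
summarizes quadrat basal-area heterogeneity as CV and skewness at grains
of 100 / 400 / 1600 / 6400 m^2 (50 realizations per level, paired
common-random-numbers design).

Expected findings: CV and skewness rise along the inhibition->clustering
gradient (strongest differentiation at 400 m^2) and fall with increasing
quadrat size within every level.
"""

from pathlib import Path

import numpy as np

from forestspat import (default_forest_spec, empirical_departure, generate,
                        run_experiment)

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)
SEED = 42
LEVEL_ORDER = ["ssi-20", "ssi-15", "ssi-10", "random",
               "matern-20", "matern-15", "matern-10"]


def main():
    smap = generate(default_forest_spec(0.1), seed=SEED)
    table = run_experiment(smap, n_real=50, seed=0)
    table.to_csv(OUT / "heterogeneity.csv", index=False)

    means = (table[~table["is_empirical"]]
             .groupby(["level", "grain_m2"])[["cv", "skewness"]]
             .mean().reset_index())
    means.to_csv(OUT / "heterogeneity_means.csv", index=False)
    print("mean CV by level (rows) and grain in m2 (columns):")
    print(means.pivot(index="level", columns="grain_m2", values="cv")
          .reindex(LEVEL_ORDER).round(3).to_string())
    at400 = means[means["grain_m2"] == 400.0].set_index("level") \
        .reindex(LEVEL_ORDER)
    print("\nCV strictly increasing along the gradient at 400 m2:",
          bool(np.all(np.diff(at400['cv']) > 0)))

    dep = empirical_departure(table)
    dep.to_csv(OUT / "departure.csv", index=False)
    print("\nempirical map vs the CSR level (percentile ranks):")
    print(dep.round(2).to_string(index=False))


if __name__ == "__main__":
    main()
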