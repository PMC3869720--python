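#!/usr/bin/env python
"""Gradient vs homogeneous large-tree placement ("virtual aggregation").

Generates matched full-scale plot pairs differing only in the first-order
intensity of the large trees (exponential west-to-east tilt vs
homogeneous), and asks whether the empirical quadrat-basal-area skewness
at the coarsest grain (6400 m^2) exceeds the 90th percentile of its
CSR-permutation distribution.  A gradient plot should be flagged; its
homogeneous twin should not — heterogeneity beyond what second-order
structure explains is the signature of a density gradient.
"""

from pathlib import Path

import pandas as pd

from forestspat import (default_forest_spec, empirical_departure,
                        generate_pair, run_experiment)

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)
N_SEEDS = 10


def main():
    spec = default_forest_spec(1.0)
    rows = []
    for s in range(N_SEEDS):
        grad_map, homo_map = generate_pair(spec, seed=1000 + s)
        for kind, smap in (("gradient", grad_map),
                           ("homogeneous", homo_map)):
            table = run_experiment(smap, levels=["random"], n_real=199,
                                   grains=[6400.0], seed=s)
            dep = empirical_departure(table).iloc[0]
            rows.append({"seed": s, "map": kind,
                         "skewness_percentile": dep["skewness_percentile"],
                         "cv_percentile": dep["cv_percentile"]})
    frame = pd.DataFrame(rows)
    frame.to_csv(OUT / "gradient_contrast.csv", index=False)
    wide = frame.pivot(index="seed", columns="map",
                       values="skewness_percentile")
    print("skewness percentile at grain 6400 m2 (vs CSR permutations):")
    print(wide.round(1).to_string())
    hits = ((wide["gradient"] > 90) & (wide["homogeneous"] <= 90)).mean()
    print(f"\ngradient flagged (>90) while homogeneous twin is not: "
          f"{100 * hits:.0f}% of {N_SEEDS} seeds")


if __name__ == "__main__":
    main()
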