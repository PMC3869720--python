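# forestspat

Spatial point-pattern analysis and basal-area heterogeneity experiments
for fully mapped forest plots.

## The problem

In late-successional forests a small elite of large-diameter trees
(dbh ≥ 100 cm) holds a third or more of the basal area. Two questions
follow for anyone working with stem-mapped plots:

1. **Pattern.** Are the large trees aggregated, random, or overdispersed —
   and do they interact with the small-tree layer — once edge effects and
   multiple testing are handled honestly?
2. **Consequence.** How much of the quadrat-scale heterogeneity of basal
   area is driven purely by *where* the large trees stand?

`forestspat` implements the full chain for a rectangular plot (the
default window is 800 m × 320 m = 25.6 ha): census summarization of
mapped stems, Ripley's K/L statistics, Monte Carlo null models and
goodness-of-fit tests, point-process simulators, a large-tree permutation
experiment, and a synthetic stem-map generator so that the entire
pipeline is testable without access to a real census.

## The statistics

For a pattern of *n* stems in a window *A*, the univariate estimator is

    K̂(r) = |A| / (n(n−1)) · Σᵢ Σ_{j≠i} w(xᵢ, d_ij) · 1(d_ij ≤ r)

with the isotropic edge correction *w* — the reciprocal fraction of the
circle through the neighbor that lies inside the rectangle, computed from
the analytic arc geometry (weight 1 in the interior, exactly 2 on an
edge, exactly 4 at a corner). Curves are reported as L̂(r) − r with
L = √(K/π), zero under complete spatial randomness (CSR): positive means
clumping, negative regularity. The bivariate L̂₁₂(r) − r counts type-2
neighbors of type-1 points.

Inference is Monte Carlo throughout: CSR envelopes for univariate
patterns, random toroidal shifts of one subpopulation (intratype
configurations held fixed) for the independence null, and the
Loosmore–Ford statistic

    uᵢ = Σ_k ( Hᵢ(r_k) − H̄₋ᵢ(r_k) )² Δr,   p = (1 + #{u_sim ≥ u_obs}) / (n_sim + 1)

over 0 ≤ r ≤ 9 m, with Bonferroni control across the test battery
(α = 0.05, m = 12 → threshold 0.004).

The permutation experiment redraws the large-tree coordinates from seven
point processes — simple sequential inhibition at 10/15/20 m spacing,
CSR, and Matérn clusters (κ = 0.00055 parents/m², μ = 5) at cluster radii
20/15/10 m thinned to the observed count — while the small trees stay
put, and reduces quadrat basal area to CV and skewness at grains of
100/400/1600/6400 m².

## Worked example

```python
import forestspat as fs

smap = fs.generate(fs.default_forest_spec(0.1), seed=42)   # ~3,100 stems
large, small = fs.split_by_diameter(smap)                  # threshold 100 cm

pat = fs.PointPattern(smap.window, small.points())
res = fs.gof_test(pat, "L", "csr", n_sim=199, r_max=9.0, seed=1)
print(len(small), res.p_value)

table = fs.run_experiment(smap, n_real=50, seed=0)
means = (table[~table.is_empirical]
         .groupby(["level", "grain_m2"])["cv"].mean())
print(means.loc[:, 400.0].round(3))
```

prints (exactly, for these seeds):

```
1887 0.005
level
matern-10    1.996
matern-15    1.963
matern-20    1.946
random       1.918
ssi-10       1.902
ssi-15       1.889
ssi-20       1.876
```

The small-tree layer rejects CSR at the p-floor (the generator plants
Matérn clustering), and mean quadrat-CV at the 400 m² grain rises
monotonically along the inhibition → random → clustered gradient: moving
only the largest ~1.5% of stems changes plot-scale structural
heterogeneity.

The numbered scripts under `analysis/` run the same steps as narrative
drivers (census → synthetic map → univariate → bivariate → heterogeneity
experiment → gradient contrast) and write their tables under `results/`.
A `forestspat` CLI (`synth`, `census`, `spatial`, `heterogeneity`, `all`)
exposes the pipeline for shell use.

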