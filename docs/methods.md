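# Methods

This note documents the models, estimators, defaults and design choices
behind `forestspat`, and what the synthetic-data tests do and do not show
about real censuses.

## Data model

A stem map is one record per tagged woody stem in a rectangular window
(origin at the southwest corner, x east, y north, meters). Live stems are
admitted at dbh ≥ 1 cm (measured at 1.37 m); snags at dbh ≥ 10 cm and
height ≥ 1.8 m. Multi-stemmed genets (vine maple, Pacific yew) appear as
one record per stem, not per genet — this is the tagging convention of
large forest-dynamics plots and is itself one source of small-scale
aggregation. Large-diameter means dbh ≥ 100 cm, inclusive, and all
threshold columns (≥1 / ≥10 / ≥100 cm) are inclusive. Basal area is
π(dbh/200)² m². Shrub-patch cover is stored as per-species areas only;
polygon geometry is out of scope.

Census reporting conventions: densities to 0.1 stems/ha with values below
0.05 rendered as trace `t`; basal areas to 0.01 m²/ha; proportions as the
≥100 cm share of the ≥1 cm quantity (≥10 cm for snags). Quadrat
assignment uses half-open `[a, a + side)` intervals (a stem on an
interior boundary belongs to the quadrat to its north/east) with the far
window edge clamped into the last quadrat, which makes quadrat sums
conserve totals exactly at every grain.

## Ripley statistics and edge correction

The estimators are the classical |A|/(n(n−1)) (univariate) and
|A|/(n₁n₂) (bivariate) forms. The isotropic edge weight at center *c*
and distance *d* is 1/f where f is the in-window fraction of the circle's
circumference, computed analytically: exterior arcs of 2·arccos(eᵢ/d)
per side at distance eᵢ < d, minus the corner overlaps
max(0, arccos(a/d) + arccos(b/d) − π/2). The formula is exact for
d ≤ min(width, height)/2, which the estimators enforce as `r_max`
validity (a quarter of the short plot dimension, 80 m for the default
window, is the intended working range); beyond it a 1024-segment numeric
arc integration takes over with the weight capped at 4. During a session
the analytic weights were checked against an independent implementation
of the same correction to machine precision; the in-repo oracle is a
brute-force O(n²·n_steps) recomputation.

The r-grid defaults to 512 steps — curves are smooth at negligible cost —
and the exploratory statistic is L̂(r) − r (not L̂ alone), so CSR sits at
zero and envelopes straddle it. Duplicate points are legal but warned
about; zero-distance pairs carry weight 1 and count at every r > 0.

## Null models and the goodness-of-fit test

* CSR null: the analyzed subpopulation is resimulated as a fixed-n
  binomial process at its observed count.
* Independence null: one uniform toroidal shift vector per replicate,
  applied to the large-diameter subpopulation only. Only the relative
  displacement of the two types enters L₁₂, so a single relative shift is
  distributionally equivalent to shifting both types, and it preserves
  both intratype configurations exactly.

The Loosmore–Ford deviation uses the leave-one-out mean: each curve in
the joint set {empirical ∪ simulations} is compared with the pointwise
mean of all the others, summed over the grid with Δr weighting. The
p-value is the conservative rank form (ties count toward rejection);
its floor is 1/(n_sim + 1) — 0.001 at the conventional 999 replicates.
Tests run on the [0, 9] m prefix of the curve grid; 9 m is the
neighborhood radius at which tree-to-tree interaction is plausibly
expressed in conifer forests. Calibration is verified two ways: the
type-I error over 500 replicate experiments stays inside the binomial
99% interval around α = 0.05, and the null p-values are discrete-uniform
by a Kolmogorov–Smirnov check.

Replicate RNG streams are spawned per replicate from the top-level seed
(`SeedSequence.spawn`), so results are independent of evaluation order,
and a single CLI seed fans out to named substreams per analysis so that
enabling one analysis never perturbs another's numbers.

## Simulators

* **SSI** (simple sequential inhibition): uniform proposals, hard
  rejection within the inhibition radius. The consecutive-rejection
  budget defaults to 2·10⁶ because the canonical experiment level —
  451 points at 20 m spacing in 800 × 320 m — sits essentially at the
  random-sequential-adsorption jamming limit (≈446 points for this
  geometry before edge relief): the last few points each need on the
  order of 10⁵ proposals. Genuinely infeasible packings still abort in
  seconds, reporting how many points were placed.
* **Matérn cluster, fixed n**: Poisson(κ) parents on the window dilated
  by the cluster radius (parents are never emitted), Poisson(μ) offspring
  uniform in the disc, out-of-window offspring discarded, then uniform
  thinning to exactly n. A shortfall regenerates the whole realization —
  partial top-ups would distort the cluster-size distribution. κ is
  interpreted per m² of the *dilated* window; with κ = 0.00055 and μ = 5
  the expected pre-thinning count in the default window is ≈767, so
  thinning to 451 (or to a desk-scale count) is the typical path.
* **Randomization**: fresh CSR resampling at the reference count is the
  default "random" level; a jitter mode (uniform displacement in a disc,
  reflected at the boundary so displacements stay local) is retained for
  fidelity experiments but its radius has no canonical value, and an
  unbounded-displacement reference behaves like full CSR anyway.

## The permutation experiment

`run_experiment` holds the small trees fixed, redraws large-tree
coordinates per level (diameters ride along, so the marginal diameter
distribution and the total basal area are invariant by construction), and
reduces the combined quadrat basal areas to CV (sample SD over mean) and
skewness (moment ratio g₁ = m₃/m₂^{3/2}, n-denominator moments, the
default of the common statistical environments; a bias-corrected variant
sits behind a flag).

**Paired design.** By default, realization k of every level shares one
RNG substream: the SSI levels and the CSR level replay the same uniform
proposal stream at different radii (CSR is SSI with radius 0), and the
three Matérn levels share one parent/offspring/priority draw in which the
cluster radius only scales the unit-disc offsets — parents drawn on the
largest dilation are restricted per-radius (a Poisson process restricted
to a subwindow is again Poisson) and thinning keeps the n smallest shared
priorities. Each level's marginal distribution is exactly the process
above; only the coupling between levels changes. The motivation is
effect size: at desk scale (~46 large trees) adjacent SSI levels differ
in mean CV by well under one standard error of 20 independent
realizations, so an unpaired design cannot resolve the gradient ordering
that the paired design recovers reliably. `paired=False` restores
independent per-(level, realization) streams.

`empirical_departure` ranks the unpermuted map's CV and skewness within
the CSR level's realization distribution (mean rank for ties, percent
scale). A rank above the 90th percentile is treated as elevated — a
deliberately moderate one-sided flag, because at the coarsest grain only
40 quadrats exist and a 97.5% flag has little power against realistic
intensity gradients.

## The synthetic forest

The generator emulates a 25.6-ha old-growth Douglas-fir / western-hemlock
plot. Species abundances, large-diameter proportions and basal areas
follow the embedded reference census (30,973 live stems, 451 large, 62.18
m²/ha). Diameter models: truncated normal (mean 102.1, sd 22) for
P. menziesii, calibrated so ≈54% of its stems exceed 100 cm and its basal
area matches the census row; shifted exponentials for T. plicata
(rate 0.01467 → ≈23% large), A. amabilis, T. brevifolia, A. circinatum
and the pooled minor species; and a two-component "rotated sigmoid"
(exponential body, scale 20, plus a 0.3% bump at N(120, 25)) for
T. heterophylla, giving ≈0.9% large. All models truncate below at 1 cm.

Spatial models: small stems are Matérn-clustered per species (radii 8–20
m, chosen so the multi-stem shrubs cluster tightest and the pioneer
conifer loosest); large trees are CSR by default. The optional gradient
places large trees with x-density ∝ exp(rate·x/W), default rate 4 (an
e⁴ ≈ 55-fold west-to-east intensity ratio). The exponential form is
deliberate: a *linear* tilt widens the quadrat-intensity distribution
symmetrically and therefore raises CV but not skewness; a convex tilt
makes the intensity distribution right-skewed, which is the mechanism by
which a density gradient keeps quadrat-BA skewness elevated at coarse
grains ("virtual aggregation" when read through second-order statistics).
`generate_pair` builds gradient/homogeneous twins from identical
substreams, so the small-tree layers are bit-identical and the contrast
is pure first-order intensity.

Snags are an independently thinned live-like population (fraction
1966/30973, exponential dbh above 10 cm); their spatial structure is not
modeled because they enter no spatial analysis. The desk-scale default is
10% of the full stem count with all proportions preserved, so the
complete pipeline runs in tens of seconds.

`reference_stem_map` is different in kind: a deterministic fixture whose
per-species diameter groups are solved from the census table so that the
census summary reproduces the table's printed arithmetic exactly. Its
stored basal areas are working values chosen inside each printed value's
two-decimal rounding window such that rows *and* totals round correctly
(the naive printed rows do not sum to the printed totals). Its
coordinates are uniform: it anchors arithmetic, not spatial structure.

## Problem sizes used in tests and the acceptance script

Estimator calibration uses 500 CSR patterns of n = 200 in 100 × 100 m;
GOF calibration 500 experiments at n_sim = 99; the heterogeneity
orderings a 10%-scale map with 20 realizations per level; the gradient
contrast full-scale map pairs with 199 CSR permutations per map; and
parameter recovery 20 desk-scale maps at n_sim = 199. These sizes give
each stochastic check a comfortable margin over its Monte Carlo noise
while the whole suite stays in the minutes range.

## What passing tests show — and what they do not

The synthetic maps share the reference census's first-order structure and
plant known spatial structure, so the tests demonstrate *recovery*: the
pipeline detects the aggregation it planted, does not reject planted CSR,
orders the pattern gradient correctly, and flags planted intensity
gradients. They do not validate the generator as a model of any real
forest: real censuses have topographic covariates, interspecific
interactions, snag spatial structure, and diameter-pattern correlations
the generator omits. Quantities that depend on those features (e.g. the
exact quadrat-CV values of a real plot) are reported by the analysis
scripts but have no synthetic ground truth. At desk scale the quadrat
CVs are systematically higher than a full census would give (fewer stems
per quadrat at the same window), which is why the experiment's
conclusions are framed as orderings, not levels.

## Known limitations

* Rectangular windows only; no inhomogeneous K, pair-correlation
  function, or anisotropy.
* The independence null offers toroidal shifts only (no random labeling
  or antecedent-condition nulls); no inhomogeneous Poisson null, although
  the gradient generator would make one easy to add.
* Bonferroni only for multiplicity (no FDR).
* No biomass/carbon allometry — basal area is a measured quantity and is
  used deliberately.
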