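# Methods

`memsel` benchmarks two standard routes to selecting spatial predictors for
multispecies presence/absence data — transformation-based redundancy
analysis with forward selection (RDA/FW) and multispecies binomial GLMs
with summed-AIC selection (GLM/AIC) — on communities simulated with known
spatial structure. This note records the models, the defaults and why they
were chosen, the numerical decisions, and what the synthetic data do and do
not emulate.

## Spatial eigenvector bases

**MEM.** From site coordinates we build a binary connectivity matrix `B`
(minimum spanning tree or Delaunay triangulation over Euclidean distances)
and a weight matrix `A`, and double-centre their Hadamard product
`W = B ∘ A`: with `H = I − 11'/n`, the eigenvectors of `H W H` with
eigenvalues above `1e-9 · max|λ|` form the basis. Positive eigenvalues
correspond to positively autocorrelated patterns (eigenvalue rank order
matches Moran's I rank order); negative-eigenvalue vectors are discarded.

The distance-to-weight transform is `f(d) = 1 − d/d_max` by default
(`d_max` = largest distance among connected pairs), with `1/d` and raw `d`
selectable. A similarity-type weight is required for the positive-eigenvalue
= positive-autocorrelation convention to hold; no row standardisation is
applied so `W` stays symmetric and the eigenproblem real. Ties (equal MST
edge lengths, equal eigenvalues) break lexicographically, and each
eigenvector's sign is fixed so its first non-zero loading is positive —
two runs on identical input are bit-identical. Retained count is at most
n−1 (centring removes one dimension). Coordinates are assumed planar;
project geographic coordinates upstream.

**AEM.** For directional (river) processes, a directed tree from a single
virtual upstream origin defines a sites × edges incidence matrix `E`
(`E[i,k] = 1` when edge k lies on the origin→site path). Left singular
vectors of the column-centred `E` are retained when their singular value is
positive *and* their Moran's I on the symmetrised site connectivity exceeds
the exchangeable-null expectation −1/(n−1). The virtual origin sits
upstream of all tributary heads — the standard construction when no gauge
defines a physical source.

## Simulating communities

A baseline community `Y0` (real or synthetic) is regressed on the full
design `X = [1, V]` (V the eigenvectors) by independent per-species
logistic regressions, giving a coefficient matrix `C` ((m+1) × p). All m·p
estimated spatial slopes are pooled into an empirical distribution. Each
scenario fixes an index set `K` of eigenvectors; the scenario matrix `C*`
keeps the estimated intercepts, fills rows in `K` with i.i.d. draws (with
replacement) from the pool, and zeroes everything else. The 14 scenarios
cross the number of non-zero variables (0, ⌊m/6⌋, ⌊m/3⌋, ⌊m/2⌋, ⌊3m/4⌋, m)
with their placement (broadest scales, finest scales, or half/half). For
the published 16-, 30- and 12-vector tables the printed index sets are
reproduced verbatim — including three 30-vector cells whose sizes
contradict their nominal level (`table="printed"`, the default); a
size-consistent variant is available (`table="consistent"`). For other m
the generic rule is first |K| indices (broad), last |K| (fine), or first
⌈|K|/2⌉ plus last ⌊|K|/2⌋ (mixed).

Binary data arise from `Ŷ = X C*` under two absence mechanisms:

* **SPM** (true absences): presence ~ Bernoulli(expit(ŷ));
* **SAM** (sampling absences): `λ = exp(ŷ)` is an expected abundance and
  detection ~ Bernoulli(1 − e^{−λ}), i.e. a Poisson draw of at least one
  individual.

The two probability maps are implemented separately; they are never equal.
Sites and species are conditionally independent given the design;
interspecific interactions are out of scope.

## Selection methods

**RDA/FW.** The community is Ochiai-transformed (each row divided by the
square root of its species count — the presence/absence analogue of the
Hellinger transformation; empty sites stay as zero rows and are logged).
RDA statistics on column-centred data: joint `R² = SS_fit/SS_total`,
Ezekiel's `adjR² = 1 − (1−R²)(n−1)/(n−k−1)`, pseudo-F. The global test
permutes whole response rows; sequential candidate tests permute residuals
of the reduced model (standard constrained-ordination practice). Forward
selection under the double stopping criterion: proceed only if the global
test is significant at α; each step ranks remaining candidates by the
adjusted R² of the augmented model (ties to the lowest index) and stops
when the best candidate is non-significant or would push adjusted R² above
the global model's. Defaults α = 0.05, 999 permutations (the toolchain
defaults); p = (1 + #{F* ≥ F}) / (1 + nperm), with an exhaustive-enumeration
mode for small n. For species-rich data the centred response is replaced by
its principal-coordinate scores `U·S` (same site-by-site cross-product, at
most n columns) — an exact reduction that keeps permutation loops cheap.

A structural consequence worth knowing: when exactly *one* variable
carries all the signal and species are few, the single-variable model's
adjusted R² is statistically tied with the global model's (both estimate
the same population R²), and the second stopping criterion then blocks
acceptance in a sizeable fraction of runs — vegan's `ordiR2step` behaves
identically on the same data, so this is a property of the criterion, not
of this implementation. With many species and strong effects (the regime
of the simulation grid) the global bound sits reliably above the first
step and recovery is near-certain.

**GLM/AIC.** Each species gets a logistic regression on intercept +
candidate subset; the selection score is AIC summed over species with
(|subset|+1) parameters each (no small-sample correction). Greedy forward
search: evaluate every remaining candidate, add the one that lowers the
summed AIC the most, stop when no candidate improves it by more than 1e-8
(exact ties go to the lower index). The fit summary is the pooled D-value,
`D = 1 − Σ resid. deviance / Σ null deviance` (the per-species pooled
reading of the deviance-based coefficient of determination).

**Separation.** With many rare species and m+1 parameters on a few dozen
sites, complete or quasi-complete separation is routine. IRLS fits cap the
linear predictor at |η| ≤ 30, floor the working weights at 1e-4 (keeping
the working response on the capped scale rather than letting coefficients
diverge), start from the intercept-only solution and halve any step that
increases a species' deviance — so every fit is finite, flagged, and never
worse than the null model. Convergence is a deviance change below 1e-8,
with at most 100 iterations. All-absent and all-present species are kept
(capped fits) so p is constant across methods and scenarios. Two equivalent
engines exist (a numba per-species kernel, default, and a batched numpy
fallback); they agree to ~1e-14 and are cross-checked against statsmodels
in the tests.

## Scoring and the grid

A selection is scored against the generating set K per variable: accuracy
= fraction of the m inclusion/exclusion decisions that are correct, false
inclusions = selected variables with zero true coefficient, false
exclusions = unselected variables with non-zero true coefficient, so
`m·accuracy + FI + FE = m` exactly. The grid crosses datasets × 14
scenarios × {SPM, SAM} × replicates; `C` is estimated once per dataset and
cached, `C*` is redrawn per replicate. Every replicate owns an RNG
substream keyed `SeedSequence(seed, spawn_key=(dataset, scenario,
mechanism, replicate))`, and within a replicate the draw order is fixed
(C* resampling, community simulation, then permutation tests), so runs are
bit-reproducible and independent of execution order. Cell dispersion is
reported both as sd and se across replicates. Failing replicates are
logged and recorded with NaN scores without aborting the grid.

## Synthetic baselines

The three survey datasets the scenario tables were designed around are
represented by synthetic stand-ins with the same dimensions and
connectivity types: 42 sites × 110 species (MST), 94 × 588 (Delaunay), 30
× 47 (river network, AEM). Layouts are uniform on a square window, or a
random binary-branching river tree with exponential edge lengths flowing
from a single origin. Species intercepts are Normal(−2, 1.5) on the logit
scale — median prevalence ≈ 0.12, reproducing the many-rare-species profile
of real community tables; spatial slopes are Normal(0, 2) on a random half
of the eigenvectors. These choices are fixed defaults, not fitted to any
target.

What the stand-ins do *not* emulate: the actual survey geometries. Retained
eigenvector counts depend on the point pattern, so the stand-ins' counts
differ from the published 16/30/12 (uniform layouts give ~19/36/12–15).
Likewise the empirical slope pool inherits heavy separation inflation from
fitting m+1 parameters to 30–94 binary sites — with the consequence that a
few huge coefficients can saturate species' probabilities and leave later
true variables with no deviance to explain, deflating GLM/AIC accuracy in
the all-variables scenarios relative to what the original surveys' pools
produced. Passing grid tests therefore demonstrate the machinery and the
qualitative method ranking (GLM/AIC errs by excluding, RDA/FW by
including; GLM/AIC more accurate overall), not the exact published rates.

## Problem sizes of the standard runs

The full published grid (3 datasets × 14 scenarios × 2 mechanisms × 1,000
replicates) is a cluster-scale computation. The package's standard
reproduction (`scripts/acceptance.py`) uses the full 14 × 2 grid with 60
replicates per cell for the river dataset, 6 for the marine dataset, and 1
for the grassland dataset with species richness scaled to 200 — sizes
chosen so a complete run takes minutes on one core while keeping
Monte-Carlo error on the river summary rates near one percentage point.
The test suite uses further-reduced replicates of the same design.

## Known limitations

* Baseline stand-ins, not the deposited survey data; geometry-dependent
  values are reproduced qualitatively only.
* Printed 30-vector scenario cells are kept verbatim even where their
  sizes contradict the nominal level (switchable).
* The AEM origin and tributary topology are generated, not reconstructed
  from a mapped river.
* No negative-eigenvalue analysis, no GLMMs with spatial random effects,
  no AIC-like selection for RDA (known to perform poorly), no
  interaction terms.
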