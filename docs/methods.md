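# Methods

## Problem setting

Given an n × m matrix of marker dosages (0/1/2 diploid, 0–4 tetraploid, or
continuous reduced features) and a length-n quantitative phenotype, the
package searches for the pair (XGBoost hyperparameters, marker subset) that
maximizes the mean cross-validated coefficient of determination R² of the
resulting regressor. Hyperparameter tuning and marker selection interact —
a subset that is optimal for one learning rate or tree depth need not be
optimal for another — which is why both live in a single search particle
and are optimized together by one metaheuristic.

## The optimizer

The core is a sparrow search algorithm (SSA): a population of N position
vectors in a box [lb, ub], re-partitioned every generation by fitness rank
into three behavioural roles.

* **Discoverers** (the ⌈PD·N⌉ fittest). One alarm draw R ~ U[0,1] and one
  α ~ U(0,1] per generation. If R < ST (alert threshold, default 0.8) each
  discoverer contracts multiplicatively, X ← X·exp(−i/(α·M)) with i its
  1-based fitness rank and M the iteration budget; otherwise each takes an
  additive step X ← X + Q with a scalar Q ~ N(0,1) per sparrow broadcast
  over dimensions (Q times the all-ones row). The boundary case R = ST is
  assigned to the additive branch.
* **Followers** (the rest). A follower with global rank i > N/2 is
  "starving" and relocates to Q·exp((X_worst − X)/i²), with X_worst the
  position of the current generation's worst particle. The others move to
  X_P + mean(|X − X_P|·A), where X_P is the best discoverer position after
  the discoverer move and A a random ±1 row: for sign rows the
  pseudo-inverse product Aᵀ(AAᵀ)⁻¹ collapses exactly to Aᵀ/d, so the
  original matrix expression reduces to this scalar mean broadcast over
  dimensions (an identity the tests verify exhaustively).
* **Vigilantes** (⌈SD·N⌉ sampled uniformly without replacement). A sparrow
  whose fitness differs from the global best f_g jumps to
  X_best + β·|X − X_best|·s with a scalar step control β ~ N(0,1) and a
  per-dimension Lévy step s; one at the global best drifts as
  X_best + k·(X − X_best)/(|f_i − f_w| + ε), k ~ U[−1,1], ε = 1e−8, f_w the
  current worst fitness.

All positions are repaired by hard clipping to [lb, ub] after every move.
Fitness sorts are stable with ties broken by particle index, so runs are
bit-reproducible given a seed.

### The five strategy improvements

1. **Logistic-chaos initialization.** Each element of the initial N × Dim
   matrix is a logistic-map stream c ← μc(1−c) with μ = 4 (fully chaotic
   regime): a uniform seed in (0.01, 0.99), nudged off the map's absorbing
   points {0.25, 0.5, 0.75}, followed by 10 burn-in iterations so the
   samples approach the invariant arcsine density (bimodal toward the
   interval ends — broader initial coverage of the box than plain uniform
   draws). Positions are the affine image lb + (ub−lb)·C.
2. **Adaptive role proportions.** PD interpolates linearly from 0.7 at
   t = 0 to 0.3 at t = M−1; SD from 0.1 to 0.3. Early iterations favour
   global exploration by discoverers; late iterations favour local
   refinement and perturbation. Linear interpolation is the simplest
   monotone schedule with the required direction; the endpoints are
   configuration, not constants.
3. **Lévy flights.** Vigilante steps use the Mantegna construction
   s = u/|v|^(1/β), u ~ N(0, σ_u²), v ~ N(0, 1), with σ_u the standard
   Γ-function scale (σ_u ≈ 0.696575 at the default stability index
   β = 1.5) — mostly short moves with occasional long jumps, which is what
   lets a vigilante escape a local optimum. A numerically zero v is
   resampled.
4. **Elite archive.** The ⌊N·elite_rate⌋ (default 10%) best individuals of
   each generation are archived, merged with the next evaluated generation,
   and the merged set truncated back to N. The population's best fitness
   can therefore never regress between generations.
5. **Early stopping.** A counter increments whenever the best-so-far
   fitness fails to *strictly* improve and resets on improvement; the run
   stops once it reaches the patience (default ⌊M/2⌋).

Integer-constrained dimensions (tree depth, child weight, the group
integers) remain continuous inside all of the above and are rounded half
away from zero only when the objective is evaluated or a particle decoded;
this preserves the continuous search dynamics while the model only ever
sees feasible integer values.

## Grouped binary marker encoding

m markers are cut into ⌈m/step⌉ consecutive groups (default step 10; a
remainder group holds m mod step markers when non-zero). Each group is
represented by one integer in [low_g, high_g] with high_g = 2^len_g − 1;
the integer's binary expansion, zero-padded to the group length with the
most significant bit first, maps onto the group's markers in column order.
low_g = 0 everywhere except the last group, whose minimum of 1 forces a
non-empty overall selection. When step divides m exactly there is no
remainder group and the minimum-of-1 constraint attaches to the (full-size)
last group — a zero-length group would be meaningless. The encoding is a
bijection between the integer box and the admissible masks, which the test
suite checks by exhaustive enumeration on small groupings and randomized
round-trips on the 25/10 worked example. `step` is capped at 62 so group
bounds stay exact in 64-bit integer arithmetic; larger genomes get more
groups, never bigger ones.

## Fitness

A particle decodes into (eta, max_depth, min_child_weight, subsample,
colsample_bytree) plus a marker mask. Fitness is the mean validation R² of
an `xgboost.XGBRegressor` (squared-error objective, 100 boosting rounds,
`tree_method="hist"`, single thread, fixed seed) over a shuffled k-fold
split (default k = 5) generated once per run, so every particle is scored
against the same partitions and fitnesses are comparable. Everything
outside the five tuned parameters is pinned so that fitness is a pure
function of the decoded particle; evaluations are memoized on the decoded
key (positions that round identically share one model fit). Alongside R²
each fold reports the Pearson correlation and its two-sided p-value from
t = r·√((n−2)/(1−r²)) on n−2 degrees of freedom (p = 0 by convention at
|r| = 1; a constant prediction vector gets r = 0, p = 1, since no linear
association is measurable); a fold whose held-out phenotypes are constant
is excluded with a warning. Per-run summaries add the 95% t-interval
mean ± t_{0.975, k−1}·sd/√k over the fold R² values.

Because the subset search and the reported CV score share the same folds,
the final mean R² is an *optimistically biased* estimate of generalization
(no outer validation loop); nested CV is deliberately out of scope and the
number kept comparable with the standard usage of this method family.

## Synthetic data generator

`simulate_dataset` emulates a crop genotype–phenotype panel: per marker an
allele frequency p_j ~ U(0.05, 0.5), dosages Binomial(ploidy, p_j) with
ploidy 2 (codes 0–2) or 4 (codes 0–4); a chosen number of causal markers
with effects β ~ N(0, 1); phenotype y = Σ x_j β_j + ε with the noise
variance set from the *realized* genetic variance so var(g)/var(y) equals
the requested heritability in-sample (effects are resampled in the
measure-zero case of zero realized genetic variance). Markers are
independent — no linkage disequilibrium, population structure, dominance or
epistasis — and effects are Gaussian, so passing recovery tests shows the
machinery finds additive signal at a given signal-to-noise ratio, not that
it handles LD-confounded or structured real panels. Default conditions
n = 200 samples, m = 200 markers, 10 causal, h² = 0.8: a deliberately small
panel with a strong polygenic-but-sparse signal, sized so that a full
optimization run completes in minutes on one core while remaining hard
enough that random marker subsets score clearly worse than enriched ones.

## Numerical and design choices

* Maximization convention throughout; no sign flipping at call sites.
* Rounding is half-away-from-zero (6.5 → 7), not banker's rounding.
* Alarm value R and α are drawn once per generation; Q per sparrow; the
  vigilante Lévy factor is drawn per dimension.
* Out-of-bounds repair by clipping (not reflection or resampling).
* Stagnation means no strict improvement (tolerance 0).
* Hyperparameter boxes default to eta [0.01, 0.3], max_depth [3, 10],
  min_child_weight [1, 10], subsample and colsample_bytree [0.5, 1] —
  standard effective ranges for boosted trees, fully overridable.
* The objective aborting raises an error tagged with the iteration and
  particle index; partial pipeline outputs are removed on failure.

## Problem sizes used in the shipped checks

The analytic benchmarks run the optimizer at N = 30, M = 100 (5-dim sphere)
and N = 20, M = 50 (1-dim shifted quadratic). The marker-recovery check
runs five replicate optimizations at N = 20, M = 30, k = 3 on the default
simulated panel (seeds 0–4) and tests causal-marker enrichment of the final
masks against random selection with a pooled one-sided binomial test; these
sizes are the package's own desk-scale reference conditions.

## Known limitations

Quantitative traits only; no genotype imputation (missing cells are load
errors); no LD-aware grouping — groups are positional, so correlated
markers land in groups arbitrarily; single-objective (accuracy only, no
explicit sparsity pressure beyond what CV accuracy induces); the reported
CV R² carries the selection optimism noted above.
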