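# msxfgp

Genomic prediction for quantitative traits by **jointly** tuning XGBoost
hyperparameters and selecting SNP markers with a multi-strategy improved
sparrow search algorithm (MSSA).

## Who this is for

Breeders and quantitative geneticists doing genomic selection: predicting a
quantitative trait (yield, tuber weight, soluble solids, ...) of candidate
individuals from genome-wide marker dosages so selection can happen before
phenotyping. Marker matrices routinely have far more markers than samples,
so a boosted-tree predictor needs both careful hyperparameter tuning and a
good marker subset — and tuning on all markers (or selecting markers with
untuned models) loses accuracy. This package searches both at once.

## The method

A candidate solution ("search particle") concatenates

* five XGBoost regressor hyperparameters — `eta`, `max_depth`,
  `min_child_weight`, `subsample`, `colsample_bytree` — each bounded in a
  user-set box, and
* one bounded integer per **marker group**: the markers are cut into groups
  of `step` (default 10), and each group's integer, written as a zero-padded
  binary string (MSB first), gives the inclusion flags of its markers. For
  25 markers at step 10 the group lengths are [10, 10, 5], the integer boxes
  [0, 1023], [0, 1023], [1, 31] (the last group's minimum of 1 guarantees a
  non-empty selection), and the vector [3, 5, 2] selects columns
  9, 10, 18, 20, 24.

The fitness of a particle is the mean validation **R²** of an XGBoost model
over a k-fold cross-validation split fixed once per run,

R² = 1 − Σ(y − ŷ)² / Σ(y − ȳ)²,

reported together with the Pearson correlation r = Cov(y, ŷ)/(σ_y σ_ŷ),
per-fold two-sided correlation p-values (t transform on n−2 df) and a 95%
t-interval over the fold R² values.

The maximizer is a sparrow search algorithm — discoverers, followers and
vigilantes re-assigned by fitness rank each generation — improved with five
strategies: logistic-chaos population initialization, a linear schedule
shrinking the discoverer fraction (0.7→0.3) and growing the vigilante
fraction (0.1→0.3), Mantegna Lévy-flight steps in the vigilante move, an
elite archive merged into every generation, and early stopping after
`patience` stagnant iterations (default half the iteration budget). Integer
dimensions stay continuous inside the dynamics and are rounded only at
evaluation/decoding. See `docs/methods.md` for the full model description.

## Worked example

```bash
# a synthetic dataset: 200 samples x 200 diploid markers, 10 causal, h2 = 0.8
msxfgp simulate --out-geno geno.csv --out-pheno pheno.csv \
    --n-samples 200 --n-markers 200 --n-causal 10 --h2 0.8 --seed 0

# scaled-down optimization (defaults are --pop-size 50 --iters 50 --cv 5)
msxfgp run --geno geno.csv --pheno pheno.csv --out results \
    --pop-size 20 --iters 30 --cv 3 --seed 0
```

The run above prints

```
mean R2 0.5893  mean cor 0.7950  selected 94 markers  outputs in results
```

meaning the best particle found reaches a mean held-out R² of 0.589 (the
model explains ~59% of phenotypic variance out of fold — strong for a trait
with h² = 0.8 scored by 3-fold CV), its predictions correlate 0.79 with the
held-out phenotypes, and 94 of 200 markers were kept. `results/` then holds:

* `r2_history.csv` — best fitness, discoverer/vigilante proportions and
  stagnation counter per iteration;
* `optimized_params.json` — the five tuned hyperparameters, group integers,
  selected marker ids, per-fold R²/correlation/p-values and the 95%
  R² confidence interval;
* `selected_genotype.csv` — the genotype matrix restricted to the selected
  markers (train your production model on this);
* `run.log` — config echo and per-iteration progress.

`msxfgp evaluate --geno ... --pheno ... --params results/optimized_params.json`
re-scores a saved parameter/mask pair on any aligned dataset.

The same pipeline is available as a library:

```python
from msxfgp import RunConfig, run
result = run(RunConfig("geno.csv", "pheno.csv", "results",
                       population_size=20, max_iterations=30, folds=3, seed=0))
print(result.evaluation.mean_r2, result.mask.n_selected)
```

## Scope

Quantitative (numeric) traits only; genotypes as integer dosage codes
(0/1/2 diploid, 0–4 tetraploid) or continuous PCA-reduced features, in CSV
with a header row and sample ids in the first column. Missing genotypes are
rejected, not imputed, and phenotype transformations (log10,
standardization) are the caller's responsibility.
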