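"""Search-particle design and the cross-validated genomic-prediction fitness.

A search particle concatenates five XGBoost hyperparameters — eta
(learning rate), max_depth, min_child_weight, subsample, colsample_bytree —
with one bounded integer per marker group (see :mod:`msxfgp.codec`).
Decoding a particle yields the hyperparameter set and a marker-selection
mask; the fitness is the mean validation R² of an XGBoost regressor over a
k-fold split that is fixed once per run, so every particle is scored
against the same partitions.

All model fitting is pinned single-threaded with fixed seeds: a particle's
fitness is a pure function of its decoded value, which both makes optimizer
trajectories reproducible and lets results be memoized on the decoded key.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn import metrics as _sk_metrics
from sklearn.model_selection import KFold
from xgboost import XGBRegressor

from .codec import FeatureGrouping, SelectionMask, decode_selection
from .data import GenoPhenoDataset
from .mssa import SearchSpace, round_half_away

__all__ = [
    "HyperparameterBounds",
    "ParticleDecoding",
    "EvalResult",
    "r2_score",
    "pearson_cor",
    "fold_p_value",
    "r2_confidence_interval",
    "build_search_space",
    "decode_particle",
    "make_fold_assignment",
    "cv_fitness",
    "GPFitness",
]

logger = logging.getLogger(__name__)

_PARAM_NAMES = ("eta", "max_depth", "min_child_weight", "subsample", "colsample_bytree")
_INTEGER_PARAMS = frozenset({"max_depth", "min_child_weight"})


@dataclass(frozen=True)
class HyperparameterBounds:
    """Box constraints for the five tuned XGBoost parameters.

    Defaults cover the standard effective ranges for boosted trees; all
    overridable.
    """

    eta: tuple[float, float] = (0.01, 0.3)
    max_depth: tuple[float, float] = (3, 10)
    min_child_weight: tuple[float, float] = (1, 10)
    subsample: tuple[float, float] = (0.5, 1.0)
    colsample_bytree: tuple[float, float] = (0.5, 1.0)

    def __post_init__(self) -> None:
        for name in _PARAM_NAMES:
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name}: lower bound must be < upper bound")
        if self.eta[0] <= 0:
            raise ValueError("eta bounds must be positive")
        for name in ("subsample", "colsample_bytree"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi > 1:
                raise ValueError(f"{name} bounds must lie in (0, 1]")
        for name in ("max_depth", "min_child_weight"):
            if getattr(self, name)[0] < 1:
                raise ValueError(f"{name} lower bound must be >= 1")


@dataclass(frozen=True)
class ParticleDecoding:
    """A particle decoded into named hyperparameters and a marker mask."""

    hyperparameters: dict[str, float | int]
    group_values: tuple[int, ...]
    mask: SelectionMask

    def cache_key(self) -> tuple:
        return (
            tuple(self.hyperparameters[k] for k in _PARAM_NAMES),
            self.group_values,
        )


@dataclass
class EvalResult:
    """Per-fold and aggregate cross-validation scores of one decoding."""

    per_fold_r2: np.ndarray
    per_fold_cor: np.ndarray
    per_fold_p: np.ndarray

    @property
    def mean_r2(self) -> float:
        return float(np.mean(self.per_fold_r2))

    @property
    def mean_cor(self) -> float:
        return float(np.mean(self.per_fold_cor))


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def r2_score(y_true, y_pred) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot.

    At most 1; negative whenever the predictions fit worse than the mean of
    the observations.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise ValueError("inputs must be equal-length vectors of size >= 2")
    if np.ptp(y_true) == 0:
        raise ValueError("R^2 undefined for constant observations")
    return float(_sk_metrics.r2_score(y_true, y_pred))


def pearson_cor(y_true, y_pred) -> float:
    """Pearson correlation Cov(y, yhat) / (sigma_y * sigma_yhat)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise ValueError("inputs must be equal-length vectors of size >= 2")
    if np.ptp(y_true) == 0 or np.ptp(y_pred) == 0:
        raise ValueError("Pearson correlation undefined for constant input")
    return float(stats.pearsonr(y_true, y_pred).statistic)


def fold_p_value(cor: float, n: int) -> float:
    """Two-sided p-value of the zero-correlation null via the t transform.

    Uses ``t = cor * sqrt((n - 2) / (1 - cor^2))`` on ``n - 2`` degrees of
    freedom; a perfect correlation returns 0 by convention.
    """
    if n < 3:
        raise ValueError("need at least 3 observations")
    if abs(cor) >= 1.0:
        return 0.0
    t = cor * math.sqrt((n - 2) / (1.0 - cor * cor))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def r2_confidence_interval(
    per_run_r2, level: float = 0.95
) -> tuple[float, float, float]:
    """t-distribution confidence interval ``mean ± t_{a/2, n-1} * sd / sqrt(n)``.

    Returns ``(low, high, mean)``; the mean always lies inside the interval.
    """
    values = np.asarray(per_run_r2, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values for a confidence interval")
    n = values.size
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    half = float(stats.t.ppf((1.0 + level) / 2.0, df=n - 1)) * sd / math.sqrt(n)
    return mean - half, mean + half, mean


# ---------------------------------------------------------------------------
# particle design
# ---------------------------------------------------------------------------


def build_search_space(
    bounds: HyperparameterBounds, grouping: FeatureGrouping
) -> SearchSpace:
    """Concatenate the hyperparameter box with the per-group integer box.

    Dimensions 0-4 are eta, max_depth, min_child_weight, subsample and
    colsample_bytree (the two tree-structure parameters integer-masked);
    the remaining dimensions are the group integers, all integer-masked,
    bounded by their minimum/maximum selection values.
    """
    lb = [getattr(bounds, p)[0] for p in _PARAM_NAMES]
    ub = [getattr(bounds, p)[1] for p in _PARAM_NAMES]
    mask = [p in _INTEGER_PARAMS for p in _PARAM_NAMES]
    lb += list(grouping.min_select)
    ub += list(grouping.max_select)
    mask += [True] * grouping.n_groups
    return SearchSpace(
        lower_bounds=np.array(lb, dtype=float),
        upper_bounds=np.array(ub, dtype=float),
        integer_mask=np.array(mask, dtype=bool),
    )


def decode_particle(
    position, bounds: HyperparameterBounds, grouping: FeatureGrouping
) -> ParticleDecoding:
    """Decode a raw position vector into hyperparameters and a marker mask."""
    position = np.asarray(position, dtype=float)
    if position.size != 5 + grouping.n_groups:
        raise ValueError(
            f"position length {position.size} != 5 + {grouping.n_groups} groups"
        )
    params: dict[str, float | int] = {}
    for j, name in enumerate(_PARAM_NAMES):
        lo, hi = getattr(bounds, name)
        value = float(np.clip(position[j], lo, hi))
        if name in _INTEGER_PARAMS:
            params[name] = int(np.clip(round_half_away(value), math.ceil(lo), math.floor(hi)))
        else:
            params[name] = value
    group_values = []
    for g in range(grouping.n_groups):
        raw = round_half_away(position[5 + g])
        group_values.append(
            int(np.clip(raw, grouping.min_select[g], grouping.max_select[g]))
        )
    mask = decode_selection(group_values, grouping)
    return ParticleDecoding(
        hyperparameters=params, group_values=tuple(group_values), mask=mask
    )


# ---------------------------------------------------------------------------
# cross-validated fitness
# ---------------------------------------------------------------------------


def make_fold_assignment(n_samples: int, folds: int, seed: int) -> np.ndarray:
    """Shuffled k-fold labels (0..folds-1) per sample, fixed for a whole run."""
    if folds < 2:
        raise ValueError("need at least 2 folds")
    if n_samples < folds:
        raise ValueError("more folds than samples")
    assignment = np.empty(n_samples, dtype=int)
    splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
    for f, (_, val_idx) in enumerate(splitter.split(np.zeros((n_samples, 1)))):
        assignment[val_idx] = f
    return assignment


def cv_fitness(
    decoding: ParticleDecoding,
    dataset: GenoPhenoDataset,
    fold_assignment: np.ndarray,
    n_estimators: int = 100,
    model_seed: int = 0,
) -> EvalResult:
    """Score one decoding by k-fold cross-validation.

    For every fold an XGBoost regressor (squared-error objective, fixed
    boosting rounds, single thread) is fit on the training partition
    restricted to the selected markers and scored on the held-out partition
    with R², the Pearson correlation and its two-sided p-value.  A fold
    whose held-out phenotypes are constant is excluded with a warning; a
    constant prediction vector scores cor = 0, p = 1 (no measurable linear
    association) while its R² remains defined.
    """
    fold_assignment = np.asarray(fold_assignment)
    x_sel = dataset.genotypes[:, decoding.mask.flags]
    y = dataset.phenotypes
    r2s, cors, ps = [], [], []
    for f in np.unique(fold_assignment):
        train = fold_assignment != f
        val = ~train
        y_val = y[val]
        if np.ptp(y_val) == 0:
            logger.warning("fold %s has constant held-out phenotypes; excluded", f)
            continue
        model = XGBRegressor(
            objective="reg:squarederror",
            n_estimators=n_estimators,
            learning_rate=decoding.hyperparameters["eta"],
            max_depth=decoding.hyperparameters["max_depth"],
            min_child_weight=decoding.hyperparameters["min_child_weight"],
            subsample=decoding.hyperparameters["subsample"],
            colsample_bytree=decoding.hyperparameters["colsample_bytree"],
            random_state=model_seed,
            n_jobs=1,
            tree_method="hist",
            verbosity=0,
        )
        model.fit(x_sel[train], y[train])
        pred = model.predict(x_sel[val])
        r2s.append(r2_score(y_val, pred))
        if np.ptp(pred) == 0:
            cors.append(0.0)
            ps.append(1.0)
        else:
            cor = pearson_cor(y_val, pred)
            cors.append(cor)
            ps.append(fold_p_value(cor, y_val.size))
    if not r2s:
        raise ValueError("every fold was degenerate; cannot score the particle")
    return EvalResult(
        per_fold_r2=np.asarray(r2s),
        per_fold_cor=np.asarray(cors),
        per_fold_p=np.asarray(ps),
    )


class GPFitness:
    """Callable fitness bound to a dataset: position -> mean validation R².

    Holds the fold assignment fixed at construction so all particles are
    comparable, and memoizes evaluations on the decoded particle key (two
    positions that round and decode identically share one model fit).
    """

    def __init__(
        self,
        dataset: GenoPhenoDataset,
        grouping: FeatureGrouping,
        bounds: HyperparameterBounds | None = None,
        folds: int = 5,
        n_estimators: int = 100,
        model_seed: int = 0,
        fold_seed: int = 0,
    ) -> None:
        self.dataset = dataset
        self.grouping = grouping
        self.bounds = bounds if bounds is not None else HyperparameterBounds()
        self.n_estimators = n_estimators
        self.model_seed = model_seed
        self.fold_assignment = make_fold_assignment(dataset.n_samples, folds, fold_seed)
        self.search_space = build_search_space(self.bounds, grouping)
        self._cache: dict[tuple, EvalResult] = {}

    def decode(self, position) -> ParticleDecoding:
        return decode_particle(position, self.bounds, self.grouping)

    def evaluate(self, position) -> EvalResult:
        decoding = self.decode(position)
        key = decoding.cache_key()
        if key not in self._cache:
            self._cache[key] = cv_fitness(
                decoding,
                self.dataset,
                self.fold_assignment,
                n_estimators=self.n_estimators,
                model_seed=self.model_seed,
            )
        return self._cache[key]

    def __call__(self, position) -> float:
        return self.evaluate(position).mean_r2
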