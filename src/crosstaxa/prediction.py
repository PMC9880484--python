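"""Random-forest cross-prediction engine.

Each univariate target is regressed on a multivariate predictor table with
repeated random 80/20 holdouts (Monte Carlo cross-validation): per repeat a
random forest is fit on the training plots and its predictions on the test
plots are correlated (Pearson) with the observed values. Two summary
statistics describe a (predictor, target) pair:

* accuracy of prediction — mean Pearson r over the valid repeats;
* significance frequency — fraction of repeats whose correlation has
  two-sided p < alpha (default 0.05).

A repeat whose test split has constant observations or constant predictions
has no defined correlation; it is recorded as missing, excluded from the
mean, and counted as non-significant.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

from ._seeds import stable_seed
from .targets import TargetVariable

logger = logging.getLogger(__name__)

PREDICTOR_GROUPS = ("bacteria", "fungi", "plants", "environment")


class ConstantInputError(ValueError):
    """A correlation input has zero variance; the result is undefined."""


@dataclass(frozen=True)
class ForestParams:
    """Random-forest hyperparameters.

    Defaults follow the regression conventions of the classic
    implementation: 500 trees, feature subset of ceil(p/3) at each split,
    unlimited depth, bootstrap resampling.
    """

    n_trees: int = 500
    max_features: str | int | float = "third"
    max_depth: int | None = None

    def resolve_max_features(self, n_features: int) -> int | float:
        if self.max_features == "third":
            return max(1, math.ceil(n_features / 3))
        return self.max_features


@dataclass
class CVResult:
    """Per-repeat correlations and the two summary statistics."""

    r_values: list[float | None]
    p_values: list[float | None]
    alpha: float
    n_plots: int

    @property
    def n_repeats(self) -> int:
        return len(self.r_values)

    @property
    def n_valid_repeats(self) -> int:
        return sum(r is not None for r in self.r_values)

    @property
    def accuracy_of_prediction(self) -> float:
        valid = [r for r in self.r_values if r is not None]
        return float(np.mean(valid)) if valid else float("nan")

    @property
    def significance_frequency(self) -> float:
        hits = sum(
            1
            for p in self.p_values
            if p is not None and p < self.alpha
        )
        return hits / self.n_repeats


def pearson_with_p(pred, obs) -> tuple[float, float]:
    """Pearson r between predicted and observed values, with the two-sided
    p-value from t = r * sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom."""
    x = np.asarray(pred, dtype=float)
    y = np.asarray(obs, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-d and equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("correlation undefined for a constant vector")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
    return r, p


def repeated_holdout(
    X: pd.DataFrame,
    y: pd.Series,
    repeats: int = 10,
    train_frac: float = 0.8,
    forest_params: ForestParams = ForestParams(),
    alpha: float = 0.05,
    seed: int = 0,
    seed_tokens: tuple = (),
    strict_folds: bool = False,
) -> CVResult:
    """Monte Carlo cross-validation of one (predictor, target) pair.

    ``X`` and ``y`` must already be aligned on the same plots. Each repeat
    draws an independent uniform random train/test split (train size =
    round(train_frac * n)); split and forest seeds are derived from
    ``seed`` plus ``seed_tokens`` plus the repeat index, so results do not
    depend on execution order. With ``strict_folds`` the repeats instead use
    the ``repeats`` disjoint test folds of a single shuffled partition
    (classic k-fold), offered for comparison.
    """
    if not X.index.equals(y.index):
        raise ValueError("X and y must be aligned on the same plots")
    n = len(y)
    if n < 10:
        raise ValueError(f"need at least 10 plots, got {n}")
    n_train = int(round(train_frac * n))
    n_train = min(max(n_train, 1), n - 3)
    xmat = X.to_numpy(dtype=float)
    yvec = y.to_numpy(dtype=float)
    fold_splits: list[tuple[np.ndarray, np.ndarray]] | None = None
    if strict_folds:
        if repeats > n // 3:
            raise ValueError("too many folds for the number of plots")
        fold_rng = np.random.default_rng(stable_seed(seed, *seed_tokens, "folds"))
        order = fold_rng.permutation(n)
        fold_splits = [
            (np.setdiff1d(order, test), test)
            for test in np.array_split(order, repeats)
        ]
    r_values: list[float | None] = []
    p_values: list[float | None] = []
    for rep in range(repeats):
        rep_seed = stable_seed(seed, *seed_tokens, "rep", rep)
        if fold_splits is not None:
            train, test = fold_splits[rep]
        else:
            rng = np.random.default_rng(rep_seed)
            perm = rng.permutation(n)
            train, test = perm[:n_train], perm[n_train:]
        forest = RandomForestRegressor(
            n_estimators=forest_params.n_trees,
            max_features=forest_params.resolve_max_features(xmat.shape[1]),
            max_depth=forest_params.max_depth,
            random_state=rep_seed % (2**31),
            n_jobs=1,
        )
        forest.fit(xmat[train], yvec[train])
        pred = forest.predict(xmat[test])
        try:
            r, p = pearson_with_p(pred, yvec[test])
        except ConstantInputError:
            logger.debug("repeat %d: undefined correlation (constant vector)", rep)
            r_values.append(None)
            p_values.append(None)
            continue
        r_values.append(r)
        p_values.append(p)
    return CVResult(r_values=r_values, p_values=p_values, alpha=alpha, n_plots=n)


@dataclass
class PredictorSet:
    """A named explanatory table; never predicts its own group's targets."""

    group: str
    table: object  # CommunityTable or EnvironmentTable

    def __post_init__(self) -> None:
        if self.group not in PREDICTOR_GROUPS:
            raise ValueError(f"unknown predictor group {self.group!r}")

    def frame(self) -> pd.DataFrame:
        return self.table.data


@dataclass
class PredictionSettings:
    repeats: int = 10
    train_frac: float = 0.8
    forest: ForestParams = field(default_factory=ForestParams)
    alpha: float = 0.05
    seed: int = 0
    strict_folds: bool = False


def run_model_matrix(
    predictor_sets: list[PredictorSet],
    targets: list[TargetVariable],
    settings: PredictionSettings = PredictionSettings(),
) -> pd.DataFrame:
    """Run every (predictor set, target) model across groups.

    Skips same-group pairs; with the full four predictor sets and 20 targets
    (7 plant, 5 bacteria, 5 fungi, 3 environment) this yields 60 models.
    Plots are intersected per pair (environment plots with missing values
    are dropped) and the per-pair n is reported.
    """
    rows = []
    for pset in predictor_sets:
        for target in targets:
            if target.group not in PREDICTOR_GROUPS:
                raise ValueError(
                    f"target {target.name!r} has unknown group {target.group!r}"
                )
            if target.group == pset.group:
                continue
            x, y = _align_pair(pset, target)
            result = repeated_holdout(
                x,
                y,
                repeats=settings.repeats,
                train_frac=settings.train_frac,
                forest_params=settings.forest,
                alpha=settings.alpha,
                seed=settings.seed,
                seed_tokens=(pset.group, target.name),
                strict_folds=settings.strict_folds,
            )
            rows.append(
                {
                    "predictor_group": pset.group,
                    "target": target.name,
                    "target_group": target.group,
                    "n_plots": result.n_plots,
                    "accuracy": result.accuracy_of_prediction,
                    "significance_frequency": result.significance_frequency,
                    "n_valid_repeats": result.n_valid_repeats,
                }
            )
    return pd.DataFrame(rows)


def _align_pair(pset: PredictorSet, target: TargetVariable
                ) -> tuple[pd.DataFrame, pd.Series]:
    from .io import EnvironmentTable

    xframe = pset.frame()
    if isinstance(pset.table, EnvironmentTable):
        keep = pset.table.complete_plots()
        xframe = xframe.loc[keep]
    y = target.values.dropna()
    shared = sorted(set(xframe.index) & set(y.index))
    if len(shared) < 10:
        raise ValueError(
            f"{pset.group} -> {target.name}: only {len(shared)} shared plots"
        )
    return xframe.loc[shared], y.loc[shared]
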