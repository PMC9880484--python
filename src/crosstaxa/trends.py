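"""Moving-frame analysis along the successional gradient.

A frame is a contiguous window of plots (default 45) in successional order,
identified by its median plot; sliding the window one plot at a time over
135 plots yields 91 frames with identifiers 23 through 113. The
cross-validated prediction statistics are recomputed within each frame, the
accuracy-versus-frame series is fit with a linear or quadratic trend (the
form with the higher adjusted r² wins), and predictor groups are compared
on their frame-wise accuracies by one-way ANOVA with Tukey's HSD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .prediction import ForestParams, repeated_holdout

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Frame:
    """A contiguous run of plots; identifier = median member plot."""

    members: tuple[int, ...]
    identifier: int


def enumerate_frames(
    n_plots: int, window: int = 45, even_rule: str | None = None
) -> list[Frame]:
    """All contiguous windows of ``window`` plots, stepped by one plot.

    Plots are numbered 1..n_plots in successional order. An odd window has a
    unique median identifier; an even window requires ``even_rule="lower"``
    (lower median).
    """
    if window < 1 or window > n_plots:
        raise ValueError(f"window {window} must be in 1..{n_plots}")
    if window % 2 == 0 and even_rule != "lower":
        raise ValueError('even window needs even_rule="lower"')
    frames = []
    for start in range(1, n_plots - window + 2):
        members = tuple(range(start, start + window))
        identifier = members[(window - 1) // 2]
        frames.append(Frame(members=members, identifier=identifier))
    return frames


@dataclass
class FrameSeries:
    """Per-frame prediction statistics for one (predictor, target) pair."""

    predictor_group: str
    target: str
    table: pd.DataFrame  # index frame identifier; accuracy, significance_frequency,
                         # n_frame, n_valid_repeats


def framewise_prediction(
    X: pd.DataFrame,
    y: pd.Series,
    frames: list[Frame],
    repeats: int = 10,
    train_frac: float = 0.8,
    forest_params: ForestParams = ForestParams(),
    alpha: float = 0.05,
    seed: int = 0,
    predictor_group: str = "",
    target: str = "",
    min_frame_plots: int = 10,
    strict_folds: bool = False,
) -> FrameSeries:
    """Repeat the holdout procedure within every moving frame.

    Frame members missing from the aligned pair are dropped, shrinking that
    frame (train/test sizes scale as round(train_frac * n)); a frame with
    fewer than ``min_frame_plots`` usable plots is skipped with a warning.
    At the default window of 45 complete plots each repeat trains on 36 and
    tests on 9.
    """
    shared = sorted(set(X.index) & set(y.dropna().index))
    x = X.loc[shared]
    yv = y.loc[shared]
    rows = []
    for frame in frames:
        plots = [p for p in frame.members if p in x.index]
        if len(plots) < min_frame_plots:
            logger.warning(
                "frame %d skipped: only %d usable plots", frame.identifier, len(plots)
            )
            continue
        result = repeated_holdout(
            x.loc[plots],
            yv.loc[plots],
            repeats=repeats,
            train_frac=train_frac,
            forest_params=forest_params,
            alpha=alpha,
            seed=seed,
            seed_tokens=(predictor_group, target, "frame", frame.identifier),
            strict_folds=strict_folds,
        )
        rows.append(
            {
                "frame_id": frame.identifier,
                "n_frame": len(plots),
                "accuracy": result.accuracy_of_prediction,
                "significance_frequency": result.significance_frequency,
                "n_valid_repeats": result.n_valid_repeats,
            }
        )
    table = pd.DataFrame(rows).set_index("frame_id") if rows else pd.DataFrame()
    return FrameSeries(predictor_group=predictor_group, target=target, table=table)


@dataclass
class TrendFit:
    """Chosen trend of accuracy along the frame identifiers."""

    form: str | None            # "linear" | "quadratic" | None (no fit)
    coefficients: tuple[float, ...]
    adjusted_r2: float
    p_value: float
    significant: bool


def _ols_fit(x: np.ndarray, y: np.ndarray, quadratic: bool):
    cols = [np.ones_like(x), x]
    if quadratic:
        cols.append(x**2)
    design = np.column_stack(cols)
    model = sm.OLS(y, design).fit()
    p = float(model.f_pvalue) if np.isfinite(model.f_pvalue) else 0.0
    # an exact fit has zero residual variance; statsmodels reports nan
    if np.isnan(model.f_pvalue) and model.rsquared > 1 - 1e-12:
        p = 0.0
    return model, p


def fit_trend(series: FrameSeries, alpha: float = 0.05,
              min_frames: int = 10) -> TrendFit:
    """Fit linear and quadratic OLS of accuracy on frame identifier and keep
    the form with the higher adjusted r²; significance is the overall-F test."""
    table = series.table.dropna(subset=["accuracy"]) if len(series.table) else series.table
    if len(table) < min_frames:
        return TrendFit(form=None, coefficients=(), adjusted_r2=float("nan"),
                        p_value=float("nan"), significant=False)
    x = table.index.to_numpy(dtype=float)
    y = table["accuracy"].to_numpy(dtype=float)
    lin, lin_p = _ols_fit(x, y, quadratic=False)
    quad, quad_p = _ols_fit(x, y, quadratic=True)
    if quad.rsquared_adj > lin.rsquared_adj:
        model, p, form = quad, quad_p, "quadratic"
    else:
        model, p, form = lin, lin_p, "linear"
    return TrendFit(
        form=form,
        coefficients=tuple(float(c) for c in model.params),
        adjusted_r2=float(model.rsquared_adj),
        p_value=p,
        significant=p < alpha,
    )


def tukey_compare(groups: dict[str, np.ndarray], alpha: float = 0.05
                  ) -> pd.DataFrame:
    """One-way ANOVA followed by Tukey's HSD across groups of frame-wise
    accuracies.

    Groups with fewer than two observations are excluded with a warning.
    Note the frame series overlap heavily, so observations within a group
    are not independent; the comparison follows the frame-wise protocol
    as-is and should be read accordingly.

    Returns one row per pair: mean difference, confidence interval, adjusted
    p-value, significance flag, plus the overall ANOVA F and p as metadata
    attributes ``anova_F`` and ``anova_p``.
    """
    usable = {}
    for name, values in groups.items():
        v = np.asarray(values, dtype=float)
        v = v[np.isfinite(v)]
        if len(v) < 2:
            logger.warning("group %r excluded: fewer than 2 observations", name)
            continue
        usable[name] = v
    if len(usable) < 2:
        raise ValueError("Tukey comparison needs at least 2 usable groups")
    f_stat, f_p = stats.f_oneway(*usable.values())
    values = np.concatenate(list(usable.values()))
    labels = np.concatenate([[name] * len(v) for name, v in usable.items()])
    res = pairwise_tukeyhsd(values, labels, alpha=alpha)
    names = list(res.groupsunique)
    pairs = [(names[i], names[j]) for i in range(len(names))
             for j in range(i + 1, len(names))]
    out = pd.DataFrame(
        {
            "group_a": [a for a, _ in pairs],
            "group_b": [b for _, b in pairs],
            "mean_diff": np.asarray(res.meandiffs, dtype=float),
            "ci_lower": np.asarray(res.confint[:, 0], dtype=float),
            "ci_upper": np.asarray(res.confint[:, 1], dtype=float),
            "p_adjusted": np.asarray(res.pvalues, dtype=float),
            "significant": np.asarray(res.reject, dtype=bool),
        }
    )
    out.attrs["anova_F"] = float(f_stat)
    out.attrs["anova_p"] = float(f_p)
    return out
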