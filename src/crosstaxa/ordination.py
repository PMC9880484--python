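"""Ordination: summarize a community table by its first two principal
components, which serve as the univariate composition targets."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CommunityTable
from .metrics import css_normalize


class DegenerateOrdinationError(ValueError):
    """The table has no variance to ordinate."""


@dataclass
class PcSummary:
    """First two PC scores per plot and their variance fractions."""

    scores_pc1: pd.Series
    scores_pc2: pd.Series
    varfrac_pc1: float
    varfrac_pc2: float


def pca_first_two(
    table: CommunityTable, transform: str = "none", css_quantile: float = 0.5
) -> PcSummary:
    """Column-centered (unscaled) PCA; returns the first two axes.

    ``transform`` applies a pre-transformation: "none", "css" (cumulative
    sum scaling, the default route for microbial count tables), or
    "hellinger" (square root of relative abundance). The sign of each axis
    is fixed so that its largest-magnitude loading is positive, making the
    output deterministic across linear-algebra backends.
    """
    if table.n_plots < 3:
        raise ValueError("PCA needs at least 3 plots")
    if transform == "css":
        table = css_normalize(table, quantile=css_quantile)
    elif transform == "hellinger":
        mat = table.data.to_numpy(dtype=float)
        totals = mat.sum(axis=1, keepdims=True)
        totals[totals == 0] = 1.0
        table = CommunityTable(
            pd.DataFrame(np.sqrt(mat / totals), index=table.plot_ids,
                         columns=table.feature_ids)
        )
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")

    x = table.data.to_numpy(dtype=float)
    x = x - x.mean(axis=0, keepdims=True)
    if not (x.var(axis=0) > 0).sum() >= 2:
        raise DegenerateOrdinationError(
            "PCA needs at least 2 features with nonzero variance"
        )
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    eigvals = s**2 / (x.shape[0] - 1)
    total_var = eigvals.sum()
    scores = u * s
    # deterministic sign: largest-|loading| entry of each axis positive
    for k in (0, 1):
        loading = vt[k]
        j = int(np.argmax(np.abs(loading)))
        if loading[j] < 0:
            vt[k] = -loading
            scores[:, k] = -scores[:, k]
    idx = table.data.index
    return PcSummary(
        scores_pc1=pd.Series(scores[:, 0], index=idx, name="pc1"),
        scores_pc2=pd.Series(scores[:, 1], index=idx, name="pc2"),
        varfrac_pc1=float(eigvals[0] / total_var),
        varfrac_pc2=float(eigvals[1] / total_var) if len(eigvals) > 1 else 0.0,
    )
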