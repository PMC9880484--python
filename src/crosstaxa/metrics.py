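"""Community-level derived quantities.

Shannon diversity (natural log), rarefied Shannon via repeated subsampling
without replacement, cumulative sum scaling (CSS) normalization of count
tables, Faith's phylogenetic diversity, functional dispersion (FDis) on
Gower distances over mixed traits, community-weighted means, and categorical
trait composition.
"""

from __future__ import annotations

import warnings

import dendropy
import numpy as np
import pandas as pd

from ._seeds import child_rng
from .io import CommunityTable, TraitTable

class UndefinedMetricError(ValueError):
    """The metric is undefined for this input (e.g. all-zero abundances)."""


def shannon(abundances) -> float:
    """Shannon diversity H = -sum p_k ln p_k over positive entries (nats)."""
    a = np.asarray(abundances, dtype=float)
    if (a < 0).any():
        raise ValueError("abundances must be nonnegative")
    total = a.sum()
    if total <= 0:
        raise UndefinedMetricError("Shannon diversity undefined for all-zero vector")
    p = a[a > 0] / total
    return float(-(p * np.log(p)).sum())


def rarefied_shannon(counts, depth: int, repeats: int = 999, seed: int = 0) -> float:
    """Mean Shannon over repeated subsamples of ``depth`` reads.

    Subsampling is without replacement (multivariate hypergeometric), the
    convention for rarefaction of sequence counts.
    """
    c = np.asarray(counts)
    if not np.issubdtype(c.dtype, np.integer):
        cf = np.asarray(counts, dtype=float)
        if not np.allclose(cf, np.round(cf)):
            raise ValueError("rarefaction requires integer counts")
        c = np.round(cf).astype(np.int64)
    if (c < 0).any():
        raise ValueError("counts must be nonnegative")
    total = int(c.sum())
    if depth > total:
        raise ValueError(f"rarefaction depth {depth} exceeds total reads {total}")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    rng = child_rng(seed, "rarefy")
    values = np.empty(repeats)
    for r in range(repeats):
        sub = rng.multivariate_hypergeometric(c, depth)
        values[r] = shannon(sub)
    return float(values.mean())


def css_scaling_factors(table: CommunityTable, quantile: float = 0.5) -> pd.Series:
    """Per-plot CSS scaling factor: sum of counts up to the count quantile.

    The quantile is taken over each sample's positive counts; the factor is
    the cumulative sum of all counts less than or equal to that quantile.
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must lie in (0, 1)")
    mat = table.data.to_numpy(dtype=float)
    factors = np.zeros(mat.shape[0])
    for i in range(mat.shape[0]):
        row = mat[i]
        pos = row[row > 0]
        if pos.size == 0:
            continue
        q = np.quantile(pos, quantile)
        factors[i] = row[row <= q].sum()
    return pd.Series(factors, index=table.plot_ids, name="css_factor")


def css_adaptive_quantile(
    table: CommunityTable,
    grid: np.ndarray | None = None,
    threshold: float = 0.1,
) -> float:
    """Data-driven CSS quantile by a relative-difference instability rule.

    For each candidate quantile the per-sample positive-count quantiles are
    compared to their across-sample median; the chosen quantile is the
    smallest one at which the median absolute deviation starts growing by
    more than ``threshold`` relative to the previous candidate, i.e. where
    the scaling statistic becomes unstable. Falls back to 0.5 when the
    instability criterion never triggers.
    """
    if grid is None:
        grid = np.arange(0.05, 1.0, 0.05)
    mat = table.data.to_numpy(dtype=float)
    rows = [row[row > 0] for row in mat]
    rows = [r for r in rows if r.size]
    if not rows:
        raise UndefinedMetricError("adaptive quantile undefined: all samples empty")
    sample_q = np.array([[np.quantile(r, q) for q in grid] for r in rows])
    ref = np.median(sample_q, axis=0)
    dev = np.median(np.abs(sample_q - ref[None, :]), axis=0)
    for k in range(1, len(grid)):
        prev = max(dev[k - 1], 1e-12)
        if (dev[k] - dev[k - 1]) / prev > threshold:
            return float(grid[k - 1]) if grid[k - 1] > 0 else 0.5
    return 0.5


def css_normalize(table: CommunityTable, quantile: float = 0.5) -> CommunityTable:
    """Cumulative sum scaling normalization of a count table.

    Each sample is divided by its scaling factor (cumulative count sum up to
    the sample's ``quantile``-th count quantile) and rescaled by the median
    factor over samples, correcting for uneven sequencing depth. All-zero
    samples pass through as zeros with a warning.
    """
    factors = css_scaling_factors(table, quantile).to_numpy()
    nonzero = factors > 0
    if not nonzero.any():
        raise UndefinedMetricError("CSS undefined: every sample is empty")
    if not nonzero.all():
        warnings.warn(
            "CSS: all-zero sample(s) pass through unscaled", stacklevel=2
        )
    reference = float(np.median(factors[nonzero]))
    scale = np.ones_like(factors)
    scale[nonzero] = reference / factors[nonzero]
    df = table.data.mul(scale, axis=0)
    return CommunityTable(df)


def faith_pd(
    tree: dendropy.Tree, presence: set[str] | list[str], include_root: bool = True
) -> float:
    """Faith's phylogenetic diversity of a set of present species.

    Sum of branch lengths of the minimal subtree spanning the present tips;
    with ``include_root`` (default) the subtree is anchored at the tree root,
    so a single species contributes its root-to-tip path length.
    """
    present = set(presence)
    if not present:
        raise UndefinedMetricError("PD undefined for an empty species set")
    tips = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    unknown = sorted(present - tips.keys())
    if unknown:
        raise ValueError(f"species not in tree: {unknown}")
    edges: dict[int, float] = {}
    for label in present:
        node = tips[label]
        while node.parent_node is not None:
            if id(node) in edges:
                break
            edges[id(node)] = node.edge.length or 0.0
            node = node.parent_node
    total = sum(edges.values())
    if not include_root:
        # remove edges above the MRCA: the deepest node shared by every
        # present tip's root path
        paths = []
        for label in present:
            node, path = tips[label], []
            while node is not None:
                path.append(id(node))
                node = node.parent_node
            paths.append(path[::-1])  # root -> tip
        depth = 0
        while all(len(p) > depth for p in paths) and len(
            {p[depth] for p in paths}
        ) == 1:
            depth += 1
        mrca_path = paths[0][1:depth]  # edges below root down to the MRCA
        node_by_id = {}
        for label in present:
            node = tips[label]
            while node is not None:
                node_by_id[id(node)] = node
                node = node.parent_node
        for nid in mrca_path:
            total -= node_by_id[nid].edge.length or 0.0
    return float(total)


def gower_distance(traits: TraitTable) -> pd.DataFrame:
    """Gower dissimilarity on mixed traits, equal weights.

    Continuous traits are range-normalized over the supplied species set;
    categorical traits contribute a 0/1 mismatch. Traits with zero range are
    skipped (no information).
    """
    df = traits.data
    n = len(df)
    parts = []
    for col in traits.continuous_columns:
        x = df[col].to_numpy(dtype=float)
        rng_ = np.nanmax(x) - np.nanmin(x)
        if rng_ == 0:
            continue
        parts.append(np.abs(x[:, None] - x[None, :]) / rng_)
    for col in traits.categorical_columns:
        x = df[col].to_numpy()
        parts.append((x[:, None] != x[None, :]).astype(float))
    if not parts:
        return pd.DataFrame(np.zeros((n, n)), index=df.index, columns=df.index)
    d = np.mean(parts, axis=0)
    return pd.DataFrame(d, index=df.index, columns=df.index)


def _pcoa_coordinates(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal-coordinate embedding; returns (real-axis, imaginary-axis)
    coordinate matrices corresponding to positive and negative eigenvalues."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = 1e-10 * max(1.0, np.abs(vals).max())
    pos = vals > tol
    neg = vals < -tol
    x_pos = vecs[:, pos] * np.sqrt(vals[pos])
    x_neg = vecs[:, neg] * np.sqrt(-vals[neg])
    return x_pos, x_neg


def functional_dispersion(
    traits: TraitTable,
    abundances: pd.Series,
    correction: str = "sqrt",
) -> float:
    """Functional dispersion (FDis): abundance-weighted mean distance of
    species to the abundance-weighted centroid in Gower trait space.

    ``correction`` handles non-Euclidean Gower dissimilarities before the
    principal-coordinate embedding: "sqrt" (elementwise square root,
    default), "cailliez" (additive constant), or "none". Species absent from
    the trait table are dropped; the index is 0 when a single species (or a
    set of trait-identical species) is present.
    """
    ab = abundances[abundances > 0]
    covered = [s for s in ab.index if s in traits.data.index]
    if not covered:
        raise UndefinedMetricError("no trait-covered species with positive abundance")
    if len(covered) == 1:
        return 0.0
    sub = TraitTable(traits.data.loc[covered])
    w = ab.loc[covered].to_numpy(dtype=float)
    w = w / w.sum()
    d = gower_distance(sub).to_numpy()
    if correction == "sqrt":
        d = np.sqrt(d)
    elif correction == "cailliez":
        d = _cailliez(d)
    elif correction != "none":
        raise ValueError(f"unknown correction {correction!r}")
    if np.allclose(d, 0):
        return 0.0
    x_pos, x_neg = _pcoa_coordinates(d)
    c_pos = w @ x_pos
    c_neg = w @ x_neg
    z = ((x_pos - c_pos) ** 2).sum(axis=1) - ((x_neg - c_neg) ** 2).sum(axis=1)
    dist = np.sqrt(np.maximum(z, 0.0))
    return float((w * dist).sum())


def _cailliez(d: np.ndarray) -> np.ndarray:
    """Cailliez additive correction making a dissimilarity Euclidean."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    d1 = -0.5 * j @ (d**2) @ j
    d2 = -0.5 * j @ d @ j
    upper = np.block([[np.zeros((n, n)), 2.0 * d1], [-np.eye(n), -4.0 * d2]])
    c = float(np.max(np.real(np.linalg.eigvals(upper))))
    if c <= 0:
        return d
    out = d + c
    np.fill_diagonal(out, 0.0)
    return out


def cwm(traits: TraitTable, abundances: pd.Series) -> pd.Series:
    """Community-weighted means of the continuous traits."""
    ab = abundances[abundances > 0]
    covered = [s for s in ab.index if s in traits.data.index]
    if not covered:
        raise UndefinedMetricError("no trait-covered species with positive abundance")
    w = ab.loc[covered].to_numpy(dtype=float)
    w = w / w.sum()
    cols = traits.continuous_columns
    values = traits.data.loc[covered, cols].to_numpy(dtype=float)
    return pd.Series(w @ values, index=cols)


def categorical_composition(
    plant_cover: CommunityTable, traits: TraitTable
) -> CommunityTable:
    """Plot-by-(trait, level) table: summed cover of species in each level.

    One column per category of each categorical trait; with nine traits
    whose level counts sum to 39, the table has 39 columns.
    """
    cover = plant_cover.data
    covered = [s for s in cover.columns if s in traits.data.index]
    if not covered:
        raise UndefinedMetricError("no species shared between cover and trait tables")
    blocks = []
    for col in traits.categorical_columns:
        levels = sorted(traits.data[col].dropna().unique())
        for level in levels:
            members = [s for s in covered if traits.data.at[s, col] == level]
            total = (cover[members].sum(axis=1) if members
                     else pd.Series(0.0, index=cover.index))
            blocks.append(total.rename(f"{col}={level}"))
    return CommunityTable(pd.concat(blocks, axis=1))
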