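"""Tabular and tree I/O with validation, and plot alignment across tables.

All tables are stored as TSV (UTF-8, tab-separated, "." decimal) with an
integer plot index as the first column. Plot identifiers are integers whose
numeric order is the successional order — tables are kept sorted by that
index, never lexically, so plot 113 follows plot 23.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PLOT_COLUMN = "plot"
ENV_COLUMNS = ("plot_age", "temperature", "pH")


class FormatError(ValueError):
    """A file or in-memory table violates the format contract."""


class AlignmentError(ValueError):
    """Tables share no plots."""


def _check_ids(ids: pd.Index, what: str) -> None:
    if ids.duplicated().any():
        dups = ids[ids.duplicated()].unique().tolist()
        raise FormatError(f"duplicate {what} identifiers: {dups}")


@dataclass
class CommunityTable:
    """Plot-by-feature abundance matrix (counts or cover).

    Rows are plots in successional order (integer index), columns are
    species/OTU/function identifiers. Values are nonnegative reals.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.ndim != 2 or df.shape[1] == 0:
            raise FormatError("community table needs at least one feature column")
        _check_ids(df.index, "plot")
        _check_ids(df.columns, "feature")
        values = df.to_numpy(dtype=float, copy=False)
        if not np.isfinite(values).all():
            raise FormatError("community table contains non-finite values")
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise FormatError(
                f"negative abundance {values[i, j]!r} at plot "
                f"{df.index[i]!r}, feature {df.columns[j]!r}"
            )
        self.data = (
            df.sort_index().rename_axis(PLOT_COLUMN).rename_axis(None, axis=1)
        )

    @property
    def plot_ids(self) -> list[int]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_plots(self) -> int:
        return self.data.shape[0]

    def restrict(self, plots: list[int]) -> "CommunityTable":
        return CommunityTable(self.data.loc[sorted(plots)])

    def write(self, path: str | Path) -> None:
        write_table(self.data, path)


@dataclass
class EnvironmentTable:
    """Plot-by-factor table: plot_age (years), temperature (°C), pH.

    Missing cells are permitted (NaN) and cause the plot to be dropped by
    :func:`align_plots`, with a logged warning.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in ENV_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"environment table lacks columns: {missing}")
        _check_ids(df.index, "plot")
        ph = df["pH"].to_numpy(dtype=float)
        ok = np.isfinite(ph)
        if ((ph[ok] <= 0) | (ph[ok] >= 14)).any():
            raise FormatError("pH values outside (0, 14)")
        self.data = (
            df.sort_index().rename_axis(PLOT_COLUMN).rename_axis(None, axis=1)
        )

    @property
    def plot_ids(self) -> list[int]:
        return list(self.data.index)

    @property
    def n_plots(self) -> int:
        return self.data.shape[0]

    def complete_plots(self) -> list[int]:
        """Plots with no missing factor value."""
        mask = self.data[list(ENV_COLUMNS)].notna().all(axis=1)
        return list(self.data.index[mask])

    def restrict(self, plots: list[int]) -> "EnvironmentTable":
        return EnvironmentTable(self.data.loc[sorted(plots)])

    def write(self, path: str | Path) -> None:
        write_table(self.data, path)


@dataclass
class TraitTable:
    """Species-by-trait table mixing categorical and continuous traits.

    Column type is inferred from dtype: non-numeric columns are categorical
    (finite level set), numeric columns are continuous.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_ids(self.data.index, "species")
        self.data = self.data.rename_axis("species").rename_axis(None, axis=1)

    @property
    def species_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def categorical_columns(self) -> list[str]:
        return [
            c
            for c in self.data.columns
            if not pd.api.types.is_numeric_dtype(self.data[c])
        ]

    @property
    def continuous_columns(self) -> list[str]:
        return [
            c for c in self.data.columns if pd.api.types.is_numeric_dtype(self.data[c])
        ]

    def write(self, path: str | Path, id_column: str = "species") -> None:
        self.data.rename_axis(id_column).to_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.rename_axis(PLOT_COLUMN).to_csv(path, sep="\t")


def _read_frame(path: str | Path, delimiter: str, id_column: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep=delimiter, index_col=0)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise FormatError(f"{path}: {exc}") from exc
    df.index.name = id_column
    return df


def read_community(path: str | Path, delimiter: str = "\t") -> CommunityTable:
    """Read a plot-by-feature table; first column is the integer plot index."""
    df = _read_frame(path, delimiter, PLOT_COLUMN)
    try:
        df.index = df.index.astype(int)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: plot identifiers must be integers") from exc
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise FormatError(
                f"{path}: non-numeric abundance {bad.iloc[0]!r} at plot "
                f"{bad.index[0]!r}, feature {col!r}"
            )
    if df.isna().any().any():
        raise FormatError(f"{path}: missing cells are not permitted (use 0)")
    return CommunityTable(df)


def read_environment(path: str | Path, delimiter: str = "\t") -> EnvironmentTable:
    df = _read_frame(path, delimiter, PLOT_COLUMN)
    df.index = df.index.astype(int)
    return EnvironmentTable(df.astype(float))


def read_traits(path: str | Path, delimiter: str = "\t") -> TraitTable:
    df = _read_frame(path, delimiter, "species")
    return TraitTable(df)


def align_plots(tables: list) -> list:
    """Restrict tables to their shared plots, in successional order.

    Environment tables contribute only plots with complete factor values;
    dropped plots are logged. Idempotent: aligning aligned tables is a no-op.
    """
    if len(tables) < 2:
        raise ValueError("align_plots needs at least two tables")
    shared: set[int] | None = None
    for t in tables:
        plots = set(t.complete_plots() if isinstance(t, EnvironmentTable) else t.plot_ids)
        shared = plots if shared is None else shared & plots
    assert shared is not None
    if not shared:
        raise AlignmentError("tables share no plots")
    keep = sorted(shared)
    for t in tables:
        dropped = sorted(set(t.plot_ids) - shared)
        if dropped:
            logger.warning("align_plots dropped %d plot(s): %s", len(dropped), dropped)
    return [t.restrict(keep) for t in tables]


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a rooted Newick tree with branch lengths."""
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick")
    except Exception as exc:
        raise FormatError(f"{path}: malformed Newick ({exc})") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise FormatError(f"{path}: duplicate tip labels")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise FormatError(f"{path}: negative branch length {edge.length}")
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)
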