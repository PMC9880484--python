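"""Derivation of the univariate target variables.

Twenty targets in four groups:

* plants (7): composition PC1/PC2 of the cover table, functional-composition
  PC1/PC2 (categorical trait composition merged with community-weighted
  means of the measured continuous traits), Shannon diversity, Faith's
  phylogenetic diversity, functional dispersion (FDis);
* bacteria (5): composition PC1/PC2 (CSS-normalized OTU table),
  functional-composition PC1/PC2 (CSS-normalized pathway table), rarefied
  Shannon diversity;
* fungi (5): as bacteria, with a guild-like functional table;
* environment (3): plot age, seasonal soil temperature, soil pH.

Microbial Shannon uses counts rarefied to the minimum per-plot read total
(mean over repeated subsamples, default 999); plot-level rarefaction seeds
are derived from the base seed and the plot id, so results are independent
of iteration order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import pandas as pd

from ._seeds import stable_seed
from .io import CommunityTable, EnvironmentTable, TraitTable
from .metrics import (
    categorical_composition,
    css_adaptive_quantile,
    cwm,
    faith_pd,
    functional_dispersion,
    rarefied_shannon,
    shannon,
)
from .ordination import pca_first_two

GROUP_OF_TARGET = {
    "plant_pc1": "plants", "plant_pc2": "plants",
    "plant_fn_pc1": "plants", "plant_fn_pc2": "plants",
    "plant_shannon": "plants", "plant_pd": "plants", "plant_fdis": "plants",
    "bact_pc1": "bacteria", "bact_pc2": "bacteria",
    "bact_fn_pc1": "bacteria", "bact_fn_pc2": "bacteria",
    "bact_shannon": "bacteria",
    "fungi_pc1": "fungi", "fungi_pc2": "fungi",
    "fungi_fn_pc1": "fungi", "fungi_fn_pc2": "fungi",
    "fungi_shannon": "fungi",
    "plot_age": "environment", "temperature": "environment", "pH": "environment",
}


@dataclass
class TargetVariable:
    """One named univariate target over plots, with its group label."""

    name: str
    group: str
    values: pd.Series


@dataclass
class TargetSet:
    """All derived targets plus ordination variance fractions."""

    table: pd.DataFrame                      # plots x targets
    groups: dict[str, str]                   # target name -> group label
    variance_fractions: dict[str, tuple[float, float]] = field(default_factory=dict)

    def variable(self, name: str) -> TargetVariable:
        return TargetVariable(name, self.groups[name], self.table[name])

    def by_group(self, group: str) -> list[TargetVariable]:
        return [self.variable(n) for n, g in self.groups.items() if g == group]


def _microbial_targets(
    prefix: str,
    otu_table: CommunityTable,
    fn_table: CommunityTable,
    rarefaction_repeats: int,
    seed: int,
    css_quantile: float | str,
) -> tuple[dict[str, pd.Series], dict[str, tuple[float, float]]]:
    def _resolve(table: CommunityTable) -> float:
        if css_quantile == "adaptive":
            return css_adaptive_quantile(table)
        return float(css_quantile)

    comp = pca_first_two(otu_table, transform="css",
                         css_quantile=_resolve(otu_table))
    fn = pca_first_two(fn_table, transform="css",
                       css_quantile=_resolve(fn_table))
    counts = otu_table.data.to_numpy()
    depth = int(counts.sum(axis=1).min())
    div = pd.Series(
        [
            rarefied_shannon(
                counts[i],
                depth,
                repeats=rarefaction_repeats,
                seed=stable_seed(seed, "rarefy", prefix, otu_table.plot_ids[i]),
            )
            for i in range(otu_table.n_plots)
        ],
        index=otu_table.data.index,
    )
    cols = {
        f"{prefix}_pc1": comp.scores_pc1,
        f"{prefix}_pc2": comp.scores_pc2,
        f"{prefix}_fn_pc1": fn.scores_pc1,
        f"{prefix}_fn_pc2": fn.scores_pc2,
        f"{prefix}_shannon": div,
    }
    fracs = {
        f"{prefix}_composition": (comp.varfrac_pc1, comp.varfrac_pc2),
        f"{prefix}_functional": (fn.varfrac_pc1, fn.varfrac_pc2),
    }
    return cols, fracs


def plant_functional_table(
    plants: CommunityTable, traits: TraitTable
) -> CommunityTable:
    """Categorical trait composition merged with per-plot CWM columns."""
    cat = categorical_composition(plants, traits)
    cwm_rows = {}
    for plot in plants.plot_ids:
        ab = plants.data.loc[plot]
        cwm_rows[plot] = cwm(traits, ab) if (ab > 0).any() else None
    cont_cols = TraitTable(traits.data).continuous_columns
    cwm_df = pd.DataFrame(
        {p: (v if v is not None else pd.Series(0.0, index=cont_cols))
         for p, v in cwm_rows.items()}
    ).T
    cwm_df.columns = [f"cwm_{c}" for c in cwm_df.columns]
    merged = pd.concat([cat.data, cwm_df.loc[cat.data.index]], axis=1)
    return CommunityTable(merged)


def build_targets(
    env: EnvironmentTable,
    plants: CommunityTable,
    bacteria: CommunityTable,
    fungi: CommunityTable,
    traits: TraitTable,
    tree: dendropy.Tree,
    bacteria_functions: CommunityTable,
    fungi_functions: CommunityTable,
    rarefaction_repeats: int = 999,
    css_quantile: float | str = 0.5,
    fdis_correction: str = "sqrt",
    include_root: bool = True,
    seed: int = 0,
) -> TargetSet:
    """Derive the 20 univariate targets on the plots shared by all tables."""
    from .io import align_plots

    env, plants, bacteria, fungi, bact_fn, fungi_fn = align_plots(
        [env, plants, bacteria, fungi, bacteria_functions, fungi_functions]
    )
    cols: dict[str, pd.Series] = {}
    fracs: dict[str, tuple[float, float]] = {}

    comp = pca_first_two(plants, transform="none")
    cols["plant_pc1"], cols["plant_pc2"] = comp.scores_pc1, comp.scores_pc2
    fracs["plant_composition"] = (comp.varfrac_pc1, comp.varfrac_pc2)

    fn_table = plant_functional_table(plants, traits)
    fn = pca_first_two(fn_table, transform="none")
    cols["plant_fn_pc1"], cols["plant_fn_pc2"] = fn.scores_pc1, fn.scores_pc2
    fracs["plant_functional"] = (fn.varfrac_pc1, fn.varfrac_pc2)

    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    sh, pd_, fd = {}, {}, {}
    for plot in plants.plot_ids:
        ab = plants.data.loc[plot]
        present = set(ab.index[ab > 0])
        sh[plot] = shannon(ab) if present else 0.0
        pd_[plot] = (
            faith_pd(tree, present & tips, include_root=include_root)
            if present & tips else 0.0
        )
        fd[plot] = (
            functional_dispersion(traits, ab, correction=fdis_correction)
            if present & set(traits.data.index) else 0.0
        )
    cols["plant_shannon"] = pd.Series(sh)
    cols["plant_pd"] = pd.Series(pd_)
    cols["plant_fdis"] = pd.Series(fd)

    bcols, bfracs = _microbial_targets(
        "bact", bacteria, bact_fn, rarefaction_repeats, seed, css_quantile
    )
    fcols, ffracs = _microbial_targets(
        "fungi", fungi, fungi_fn, rarefaction_repeats, seed, css_quantile
    )
    cols.update(bcols)
    fracs.update(bfracs)
    cols.update(fcols)
    fracs.update(ffracs)

    cols["plot_age"] = env.data["plot_age"]
    cols["temperature"] = env.data["temperature"]
    cols["pH"] = env.data["pH"]

    table = pd.DataFrame(cols)[list(GROUP_OF_TARGET)]
    table.index.name = "plot"
    return TargetSet(table=table, groups=dict(GROUP_OF_TARGET),
                     variance_fractions=fracs)
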