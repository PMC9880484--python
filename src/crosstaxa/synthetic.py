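"""Gradient-structured multi-taxon community simulator.

Emulates the processed data of a glacier-forefield chronosequence: 135 plots
ordered by successional age, bacterial and fungal OTU count tables with
uneven sequencing depth, a plant percent-cover table, a mixed trait table
with a plant phylogeny, and environmental factors (plot age, seasonal mean
soil temperature, soil pH) that change monotonically along the gradient.

Each taxon responds to a latent gradient g in [0, 1] (plot index rescaled)
through a Gaussian niche, exp(-(g - mu)^2 / (2 w^2)) with optimum mu uniform
on the gradient and shared breadth w, which produces species turnover along
succession. Microbial taxa can additionally be coupled to plants: the
expected abundance of a microbe is multiplied by
(1 + coupling * z), floored at 0, where z is the standardized local cover of
a few randomly assigned plant "partner" species. The coupling dial therefore
creates plant-microbe association beyond what the shared gradient induces;
at coupling = 0 the microbial tables are conditionally independent of the
plant table given the gradient.

Counts are drawn from a negative binomial around depth-scaled relative
abundances, with per-plot sequencing depth log-normal; the plant table is
nonnegative cover instead of counts.
"""

from __future__ import annotations

import random as _pyrandom
from dataclasses import dataclass, replace

import dendropy
import numpy as np
import pandas as pd

from ._seeds import child_rng
from .io import CommunityTable, EnvironmentTable, TraitTable

MICROBIAL_GROUPS = ("bacteria", "fungi")
GROUPS = ("bacteria", "fungi", "plants")

# Deglaciation-history breakpoints: fraction of the transect -> plot age in
# years. Piecewise-linear interpolation between eight dated positions gives
# the uneven (non-linear) age-versus-position relationship typical of a
# retreating-glacier chronosequence.
_AGE_BREAK_FRACTIONS = np.array([0.0, 0.12, 0.27, 0.42, 0.57, 0.72, 0.87, 1.0])
_AGE_BREAK_YEARS = np.array([2.0, 9.0, 19.0, 34.0, 57.0, 88.0, 128.0, 170.0])


class ScenarioError(ValueError):
    """Scenario parameters violate their constraints."""


@dataclass(frozen=True)
class GradientScenario:
    """Parameters of one synthetic chronosequence.

    Defaults mirror the study design being emulated: 135 plots, 4986
    bacterial and 5701 fungal OTUs, 99 plant species.
    """

    n_plots: int = 135
    n_bact: int = 4986
    n_fungi: int = 5701
    n_plant: int = 99
    coupling: float = 1.0          # strength of plant -> microbe dependence
    niche_width: float = 0.15      # Gaussian niche breadth on the 0-1 gradient
    depth_logmean: float = 9.2     # log reads/plot; exp(9.2) ~ 10k
    depth_logsd: float = 0.5       # gives roughly 5k-50k reads/plot
    env_noise_sd: float = 0.15
    nb_size: float = 5.0           # negative-binomial dispersion (size)
    n_partners: int = 3            # plant partner species per coupled microbe
    plant_cover_noise_sd: float = 0.4   # lognormal sd of cover noise
    # missing-data emulation: randomly dropped plots per table (default off)
    n_missing_bacteria: int = 0
    n_missing_fungi: int = 0
    n_missing_plants: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_plots < 2:
            raise ScenarioError("n_plots must be at least 2")
        if min(self.n_bact, self.n_fungi, self.n_plant) < 1:
            raise ScenarioError("feature counts must be positive")
        if self.coupling < 0:
            raise ScenarioError("coupling must be >= 0")
        if self.niche_width <= 0:
            raise ScenarioError("niche_width must be > 0")
        if self.env_noise_sd < 0:
            raise ScenarioError("env_noise_sd must be >= 0")
        worst = max(self.n_missing_bacteria, self.n_missing_fungi,
                    self.n_missing_plants)
        if worst < 0 or self.n_plots - worst < 2:
            raise ScenarioError("n_missing leaves fewer than 2 plots")

    def with_(self, **kwargs) -> "GradientScenario":
        return replace(self, **kwargs)


def latent_gradient(n_plots: int) -> np.ndarray:
    """Plot index rescaled to [0, 1]; the successional axis."""
    return np.linspace(0.0, 1.0, n_plots)


def generate_environment(scenario: GradientScenario) -> EnvironmentTable:
    """Plot age, seasonal soil temperature and soil pH along the gradient.

    Age increases strictly with plot index (piecewise-linear over the
    deglaciation breakpoints); temperature increases and pH decreases
    monotonically with age, each plus Gaussian noise of sd ``env_noise_sd``.
    """
    g = latent_gradient(scenario.n_plots)
    rng = child_rng(scenario.seed, "environment")
    age = np.interp(g, _AGE_BREAK_FRACTIONS, _AGE_BREAK_YEARS)
    rel = age / _AGE_BREAK_YEARS[-1]
    temperature = 3.5 + 4.5 * rel**0.8 + rng.normal(0.0, scenario.env_noise_sd, len(g))
    ph = 8.3 - 2.0 * rel + rng.normal(0.0, scenario.env_noise_sd, len(g))
    ph = np.clip(ph, 0.1, 13.9)
    plots = np.arange(1, scenario.n_plots + 1)
    df = pd.DataFrame(
        {"plot_age": age, "temperature": temperature, "pH": ph}, index=plots
    )
    return EnvironmentTable(df)


def _feature_names(group: str, n: int) -> list[str]:
    prefix = {"bacteria": "bOTU", "fungi": "fOTU", "plants": "sp"}[group]
    width = len(str(n))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def expected_abundances(
    scenario: GradientScenario,
    group: str,
    plant_table: CommunityTable | None = None,
    niche_width: float | None = None,
) -> np.ndarray:
    """Deterministic expected abundance matrix (plots x taxa), before noise.

    Gaussian niche response to the latent gradient times a lognormal
    per-taxon carrying capacity; for microbial groups with coupling > 0,
    further multiplied by max(0, 1 + coupling * z) where z is the mean
    standardized cover of the taxon's plant partner species.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    n_taxa = {"bacteria": scenario.n_bact, "fungi": scenario.n_fungi,
              "plants": scenario.n_plant}[group]
    w = scenario.niche_width if niche_width is None else niche_width
    if w <= 0:
        raise ScenarioError("niche_width must be > 0")
    g = latent_gradient(scenario.n_plots)
    rng = child_rng(scenario.seed, "niche", group)
    mu = rng.uniform(0.0, 1.0, n_taxa)
    base = rng.lognormal(0.0, 1.0, n_taxa)
    expected = base * np.exp(-((g[:, None] - mu[None, :]) ** 2) / (2.0 * w * w))

    if group in MICROBIAL_GROUPS and scenario.coupling > 0:
        if plant_table is None:
            raise ScenarioError(
                f"coupling={scenario.coupling} > 0 requires a plant table to "
                f"generate {group}"
            )
        cover = plant_table.data.to_numpy(dtype=float)
        sd = cover.std(axis=0)
        sd[sd == 0] = 1.0
        z_cover = (cover - cover.mean(axis=0)) / sd  # plots x plant species
        prng = child_rng(scenario.seed, "partners", group)
        partners = prng.integers(0, cover.shape[1],
                                 size=(n_taxa, scenario.n_partners))
        z = z_cover[:, partners].mean(axis=2)  # plots x taxa
        expected = expected * np.maximum(0.0, 1.0 + scenario.coupling * z)
    return expected


def generate_taxa(
    env: EnvironmentTable,
    scenario: GradientScenario,
    group: str,
    plant_table: CommunityTable | None = None,
    niche_width: float | None = None,
) -> CommunityTable:
    """Generate one group's community table on the plots of ``env``.

    Microbial groups return integer OTU counts drawn negative-binomially
    around depth-scaled relative expected abundances, with per-plot depth
    LogNormal(depth_logmean, depth_logsd). Plants return nonnegative real
    cover (expected abundance times lognormal noise, small values zeroed to
    produce realistic absences).
    """
    if env.n_plots != scenario.n_plots:
        raise ScenarioError(
            f"environment has {env.n_plots} plots but scenario expects "
            f"{scenario.n_plots}"
        )
    expected = expected_abundances(scenario, group, plant_table, niche_width)
    rng = child_rng(scenario.seed, "draw", group)
    n_plots, n_taxa = expected.shape
    if group == "plants":
        noise = rng.lognormal(0.0, scenario.plant_cover_noise_sd, expected.shape)
        cover = 5.0 * expected * noise
        cover[cover < 0.05] = 0.0
        values = cover
    else:
        depth = rng.lognormal(scenario.depth_logmean, scenario.depth_logsd, n_plots)
        totals = expected.sum(axis=1)
        totals[totals == 0] = 1.0
        mean = depth[:, None] * expected / totals[:, None]
        size = scenario.nb_size
        p = size / (size + mean)
        values = rng.negative_binomial(size, p).astype(float)
    df = pd.DataFrame(values, index=env.plot_ids,
                      columns=_feature_names(group, n_taxa))
    return CommunityTable(df)


# Nine BiolFlor-style categorical traits; level counts sum to 39.
_CATEGORICAL_TRAITS: dict[str, int] = {
    "reproduction": 4,
    "diaspore_type": 6,
    "leaf_persistence": 3,
    "life_form": 5,
    "life_span": 3,
    "pollen_vector": 4,
    "strategy_type": 6,
    "type_of_reproduction": 3,
    "dispersal_of_diaspores": 5,
}
_CONTINUOUS_TRAITS = ("plant_height_m", "leaf_area_mm2", "leaf_weight_mg",
                      "sla_mm2_per_mg")


def generate_plant_traits_and_tree(
    plant_table: CommunityTable,
    n_categorical: int = 9,
    n_continuous: int = 4,
    seed: int = 0,
) -> tuple[TraitTable, dendropy.Tree]:
    """Mixed trait table plus a pure-birth (Yule) phylogeny for the plants.

    With the default nine categorical traits the level counts sum to 39, so
    the categorical trait-composition table downstream has 39 columns.
    Continuous traits are log-normal. Tree tip labels equal the plant
    species names exactly, with positive branch lengths.
    """
    species = plant_table.feature_ids
    if not species:
        raise ValueError("plant table has no species")
    rng = child_rng(seed, "traits")
    columns: dict[str, object] = {}
    if n_categorical == len(_CATEGORICAL_TRAITS):
        cat_spec = list(_CATEGORICAL_TRAITS.items())
    else:
        cat_spec = [(f"cat_trait_{i + 1}", int(rng.integers(2, 7)))
                    for i in range(n_categorical)]
    for name, n_levels in cat_spec:
        levels = [f"{name}_L{j + 1}" for j in range(n_levels)]
        draw = rng.integers(0, n_levels, len(species))
        # guarantee every level occurs so the composition table has the
        # full column complement
        for j in range(min(n_levels, len(species))):
            draw[j] = j
        columns[name] = [levels[k] for k in draw]
    cont_names = (_CONTINUOUS_TRAITS if n_continuous == len(_CONTINUOUS_TRAITS)
                  else tuple(f"cont_trait_{i + 1}" for i in range(n_continuous)))
    for name in cont_names:
        columns[name] = rng.lognormal(0.0, 0.6, len(species))
    traits = TraitTable(pd.DataFrame(columns, index=pd.Index(species, name="species")))

    pyrng = _pyrandom.Random(int(child_rng(seed, "tree").integers(2**31)))
    from dendropy.model import birthdeath

    tree = birthdeath.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=len(species), rng=pyrng
    )
    tips = list(tree.leaf_node_iter())
    order = list(range(len(tips)))
    pyrng.shuffle(order)
    namespace = dendropy.TaxonNamespace()
    for tip, k in zip(tips, order):
        tip.taxon = namespace.new_taxon(label=species[k])
    tree.taxon_namespace = namespace
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length <= 0:
            edge.length = 1e-6
    tree.seed_node.edge.length = None  # no branch above the root
    return traits, tree


def generate_functional_tables(
    otu_table: CommunityTable, n_functions: int, seed: int = 0
) -> CommunityTable:
    """Aggregate OTUs into functional categories (pathway/guild emulation).

    Each OTU is assigned to exactly one function by a seed-keyed hash of its
    name, so the assignment — and hence the function table — is invariant to
    OTU column order. Column sums of the function table conserve the per-plot
    totals of the OTU table.
    """
    if n_functions < 1:
        raise ValueError("n_functions must be >= 1")
    if len(otu_table.feature_ids) < n_functions:
        raise ValueError("fewer OTUs than requested functions")
    from ._seeds import stable_seed

    width = len(str(n_functions))
    names = [f"fn{i + 1:0{width}d}" for i in range(n_functions)]
    assign = {
        otu: stable_seed(seed, "function", otu) % n_functions
        for otu in otu_table.feature_ids
    }
    values = np.zeros((otu_table.n_plots, n_functions))
    mat = otu_table.data.to_numpy(dtype=float)
    for j, otu in enumerate(otu_table.feature_ids):
        values[:, assign[otu]] += mat[:, j]
    df = pd.DataFrame(values, index=otu_table.plot_ids, columns=names)
    return CommunityTable(df)


def generate_dataset(scenario: GradientScenario) -> dict:
    """Generate the full linked dataset for one scenario.

    Returns environment, the three community tables, traits + tree, and
    microbial functional tables (bacteria: pathway-like, fungi: guild-like).
    """
    env = generate_environment(scenario)
    plants = generate_taxa(env, scenario, "plants")
    bacteria = generate_taxa(env, scenario, "bacteria", plant_table=plants)
    fungi = generate_taxa(env, scenario, "fungi", plant_table=plants)
    traits, tree = generate_plant_traits_and_tree(plants, seed=scenario.seed)
    for attr, key in (("n_missing_bacteria", "bacteria"),
                      ("n_missing_fungi", "fungi"),
                      ("n_missing_plants", "plants")):
        n_drop = getattr(scenario, attr)
        if n_drop:
            rng = child_rng(scenario.seed, "missing", key)
            table = {"bacteria": bacteria, "fungi": fungi, "plants": plants}[key]
            drop = set(rng.choice(table.plot_ids, n_drop, replace=False).tolist())
            kept = [p for p in table.plot_ids if p not in drop]
            restricted = table.restrict(kept)
            if key == "bacteria":
                bacteria = restricted
            elif key == "fungi":
                fungi = restricted
            else:
                plants = restricted
    n_bact_fn = max(1, min(200, scenario.n_bact // 5))
    n_fungi_fn = max(1, min(60, scenario.n_fungi // 5))
    bact_fn = generate_functional_tables(bacteria, n_bact_fn, seed=scenario.seed)
    fungi_fn = generate_functional_tables(fungi, n_fungi_fn, seed=scenario.seed)
    return {
        "environment": env,
        "plants": plants,
        "bacteria": bacteria,
        "fungi": fungi,
        "traits": traits,
        "tree": tree,
        "bacteria_functions": bact_fn,
        "fungi_functions": fungi_fn,
    }
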