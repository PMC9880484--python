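"""End-to-end orchestration: simulate → targets → predict → frames →
trends → report, with a JSON run manifest for provenance."""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .config import RunConfig, dump_config
from .io import (
    EnvironmentTable,
    read_community,
    read_environment,
    read_newick,
    read_traits,
    write_newick,
)
from .metrics import css_normalize
from .prediction import (
    ForestParams,
    PredictionSettings,
    PredictorSet,
    run_model_matrix,
)
from .synthetic import GradientScenario, generate_dataset
from .targets import TargetSet, build_targets
from .trends import FrameSeries, enumerate_frames, fit_trend, framewise_prediction, tukey_compare

logger = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _scenario_from_config(config: RunConfig) -> GradientScenario:
    return GradientScenario(seed=config.seed, **config.scenario.model_dump())


def load_or_simulate(config: RunConfig, outdir: Path) -> dict:
    """Load tables named in the config; simulate all others from the scenario."""
    paths = config.data
    if all(
        getattr(paths, k) is None
        for k in ("environment", "plants", "bacteria", "fungi")
    ):
        data = generate_dataset(_scenario_from_config(config))
        datadir = outdir / "data"
        datadir.mkdir(parents=True, exist_ok=True)
        for key in ("environment", "plants", "bacteria", "fungi",
                    "bacteria_functions", "fungi_functions"):
            data[key].write(datadir / f"{key}.tsv")
        data["traits"].write(datadir / "traits.tsv")
        write_newick(data["tree"], datadir / "tree.nwk")
        return data
    required = ("environment", "plants", "bacteria", "fungi", "traits", "tree",
                "bacteria_functions", "fungi_functions")
    missing = [k for k in required if getattr(paths, k) is None]
    if missing:
        raise ValueError(f"config data section missing path(s): {missing}")
    return {
        "environment": read_environment(paths.environment),
        "plants": read_community(paths.plants),
        "bacteria": read_community(paths.bacteria),
        "fungi": read_community(paths.fungi),
        "traits": read_traits(paths.traits),
        "tree": read_newick(paths.tree),
        "bacteria_functions": read_community(paths.bacteria_functions),
        "fungi_functions": read_community(paths.fungi_functions),
    }


def derive_targets(data: dict, config: RunConfig) -> TargetSet:
    m = config.metrics
    return build_targets(
        env=data["environment"],
        plants=data["plants"],
        bacteria=data["bacteria"],
        fungi=data["fungi"],
        traits=data["traits"],
        tree=data["tree"],
        bacteria_functions=data["bacteria_functions"],
        fungi_functions=data["fungi_functions"],
        rarefaction_repeats=m.rarefaction_repeats,
        css_quantile=m.css_quantile,
        fdis_correction=m.fdis_correction,
        include_root=m.pd_include_root,
        seed=config.seed,
    )


def predictor_sets(data: dict, config: RunConfig) -> list[PredictorSet]:
    """Explanatory tables: CSS-normalized microbial counts, raw plant cover,
    environmental factors."""
    from .metrics import css_adaptive_quantile

    def _q(table):
        q = config.metrics.css_quantile
        return css_adaptive_quantile(table) if q == "adaptive" else float(q)

    return [
        PredictorSet("bacteria",
                     css_normalize(data["bacteria"], _q(data["bacteria"]))),
        PredictorSet("fungi", css_normalize(data["fungi"], _q(data["fungi"]))),
        PredictorSet("plants", data["plants"]),
        PredictorSet("environment", data["environment"]),
    ]


def _settings(config: RunConfig) -> PredictionSettings:
    p = config.prediction
    return PredictionSettings(
        repeats=p.repeats,
        train_frac=p.train_frac,
        forest=ForestParams(n_trees=p.n_trees),
        alpha=p.alpha,
        seed=config.seed,
        strict_folds=p.strict_folds,
    )


def run_global_predictions(data: dict, targets: TargetSet,
                           config: RunConfig) -> pd.DataFrame:
    sets = predictor_sets(data, config)
    variables = [targets.variable(name) for name in targets.groups]
    return run_model_matrix(sets, variables, _settings(config))


def run_frame_predictions(data: dict, targets: TargetSet,
                          config: RunConfig) -> pd.DataFrame:
    """Frame-wise statistics for every cross-group (predictor, target) pair."""
    n_plots = config.scenario.n_plots
    frames = enumerate_frames(n_plots, config.frames.window,
                              config.frames.even_rule)
    sets = predictor_sets(data, config)
    p = config.prediction
    rows = []
    for pset in sets:
        xframe = pset.frame()
        if isinstance(pset.table, EnvironmentTable):
            xframe = xframe.loc[pset.table.complete_plots()]
        for name, group in targets.groups.items():
            if group == pset.group:
                continue
            series = framewise_prediction(
                xframe,
                targets.table[name],
                frames,
                repeats=p.repeats,
                train_frac=p.train_frac,
                forest_params=ForestParams(n_trees=p.n_trees),
                alpha=p.alpha,
                seed=config.seed,
                predictor_group=pset.group,
                target=name,
                min_frame_plots=config.frames.min_frame_plots,
                strict_folds=p.strict_folds,
            )
            t = series.table.reset_index()
            t.insert(0, "target", name)
            t.insert(0, "predictor_group", pset.group)
            rows.append(t)
    return pd.concat(rows, ignore_index=True)


def run_trends(frame_table: pd.DataFrame, alpha: float = 0.05
               ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Trend fits per (predictor, target) pair and both Tukey comparisons."""
    fits = []
    for (pgroup, target), sub in frame_table.groupby(["predictor_group", "target"]):
        series = FrameSeries(pgroup, target, sub.set_index("frame_id"))
        fit = fit_trend(series, alpha=alpha)
        fits.append(
            {
                "predictor_group": pgroup,
                "target": target,
                "form": fit.form,
                "coefficients": json.dumps(list(fit.coefficients)),
                "adjusted_r2": fit.adjusted_r2,
                "p_value": fit.p_value,
                "significant": fit.significant,
            }
        )
    fits_df = pd.DataFrame(fits)

    by_target = []
    for target, sub in frame_table.groupby("target"):
        groups = {
            g: s["accuracy"].to_numpy()
            for g, s in sub.groupby("predictor_group")
        }
        if len(groups) < 2:
            continue
        table = tukey_compare(groups, alpha=alpha)
        table.insert(0, "target", target)
        by_target.append(table)
    by_pred = []
    for pgroup, sub in frame_table.groupby("predictor_group"):
        groups = {t: s["accuracy"].to_numpy() for t, s in sub.groupby("target")}
        if len(groups) < 2:
            continue
        table = tukey_compare(groups, alpha=alpha)
        table.insert(0, "predictor_group", pgroup)
        by_pred.append(table)
    return (
        fits_df,
        pd.concat(by_target, ignore_index=True) if by_target else pd.DataFrame(),
        pd.concat(by_pred, ignore_index=True) if by_pred else pd.DataFrame(),
    )


def write_report(frame_table: pd.DataFrame, fits: pd.DataFrame,
                 outdir: Path) -> list[Path]:
    """Accuracy-versus-frame curves per predictor group, with fitted trends;
    points shaded by significance frequency."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    for pgroup, sub in frame_table.groupby("predictor_group"):
        targets_ = sorted(sub["target"].unique())
        ncols = 3
        nrows = -(-len(targets_) // ncols)
        fig, axes = plt.subplots(nrows, ncols, figsize=(4 * ncols, 2.6 * nrows),
                                 squeeze=False)
        for ax, target in zip(axes.ravel(), targets_):
            s = sub[sub["target"] == target]
            ax.scatter(s["frame_id"], s["accuracy"],
                       c=s["significance_frequency"], cmap="Greys",
                       vmin=0, vmax=1, edgecolors="k", linewidths=0.3, s=18)
            row = fits[(fits["predictor_group"] == pgroup)
                       & (fits["target"] == target)]
            if len(row) and row.iloc[0]["significant"]:
                coeffs = json.loads(row.iloc[0]["coefficients"])
                xx = s["frame_id"].to_numpy(dtype=float)
                yy = sum(c * xx**k for k, c in enumerate(coeffs))
                order = xx.argsort()
                ax.plot(xx[order], yy[order], color="tab:red", lw=1.2)
            ax.set_title(f"{pgroup} → {target}", fontsize=9)
            ax.set_xlabel("frame (median plot)", fontsize=8)
            ax.set_ylabel("accuracy (r)", fontsize=8)
        for ax in axes.ravel()[len(targets_):]:
            ax.axis("off")
        fig.tight_layout()
        path = outdir / f"frames_{pgroup}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written


def run_pipeline(config: RunConfig, output_dir: str | Path | None = None) -> dict:
    """Run every stage and write results plus a provenance manifest.

    Returns the manifest dictionary. Re-running with the same config and
    seed reproduces bit-identical result tables.
    """
    outdir = Path(output_dir if output_dir is not None else config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    started = datetime.now(timezone.utc).isoformat()

    data = load_or_simulate(config, outdir)
    targets = derive_targets(data, config)
    targets.table.to_csv(outdir / "targets.tsv", sep="\t")
    (outdir / "variance_fractions.json").write_text(
        json.dumps(targets.variance_fractions, indent=2)
    )

    global_table = run_global_predictions(data, targets, config)
    global_table.to_csv(outdir / "global_predictions.tsv", sep="\t", index=False)

    frame_table = run_frame_predictions(data, targets, config)
    frame_table.to_csv(outdir / "frame_predictions.tsv", sep="\t", index=False)

    fits, tukey_target, tukey_pred = run_trends(frame_table,
                                                alpha=config.prediction.alpha)
    fits.to_csv(outdir / "trend_fits.tsv", sep="\t", index=False)
    tukey_target.to_csv(outdir / "tukey_by_target.tsv", sep="\t", index=False)
    tukey_pred.to_csv(outdir / "tukey_by_predictor.tsv", sep="\t", index=False)

    write_report(frame_table, fits, outdir)

    result_files = sorted(
        p for p in outdir.rglob("*")
        if p.is_file() and p.suffix in {".tsv", ".json", ".nwk"}
        and p.name != "manifest.json"
    )
    manifest = {
        "crosstaxa_version": __version__,
        "python": platform.python_version(),
        "started": started,
        "finished": datetime.now(timezone.utc).isoformat(),
        "seed": config.seed,
        "config": dump_config(config),
        "outputs": {str(p.relative_to(outdir)): _sha256(p) for p in result_files},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
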