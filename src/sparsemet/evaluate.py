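"""Cross-validation of sparse-testing designs: predictive ability and MSE.

Runs the full experiment grid — replicates x allocation designs x models
x traits — fitting each model on the observed cells of a design and
scoring the testing cells within each environment by Pearson predictive
ability and mean squared error.  Metrics are computed within environment
and averaged over environments and replicates, matching how sparse-
testing results are reported.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .designs import build_design, classify_cv, partition_nol
from .markers import GRM
from .models import CellFrame, SamplerConfig, build_kernels, fit_model

__all__ = ["pearson", "mse", "run_experiment", "aggregate", "plot_metrics"]


def pearson(pred, obs) -> float:
    """Pearson product-moment correlation between predictions and observations."""
    pred = np.asarray(pred, float)
    obs = np.asarray(obs, float)
    if pred.shape != obs.shape:
        raise ValueError("prediction and observation lengths differ")
    if len(pred) < 3:
        raise ValueError("need at least three pairs")
    if np.ptp(pred) == 0 or np.ptp(obs) == 0:
        raise ValueError("correlation undefined for constant input")
    return float(stats.pearsonr(pred, obs).statistic)


def mse(pred, obs) -> float:
    """Mean of squared deviations between predicted and observed values."""
    pred = np.asarray(pred, float)
    obs = np.asarray(obs, float)
    if pred.shape != obs.shape:
        raise ValueError("prediction and observation lengths differ")
    return float(np.mean((pred - obs) ** 2))


def run_experiment(
    blups: pd.DataFrame,
    grm: GRM,
    grid: list[tuple[int, int, int]],
    models: tuple[str, ...] = ("M1", "M2", "M3"),
    n_replicates: int = 10,
    seed: int | None = None,
    sampler: SamplerConfig | None = None,
    traits: list[str] | None = None,
) -> pd.DataFrame:
    """Run the sparse-testing experiment grid.

    ``blups`` is the long adjusted-phenotype table (env, genotype, trait,
    value) covering every cell; ``grid`` lists (trs_size, n_nol, n_ol)
    designs.  Each replicate redraws the base partition and every
    design's NOL/OL assignment.  Returns one row per (trait, model,
    design, environment, replicate) with predictive ability and MSE over
    that environment's testing set; fits whose correlation is undefined
    (constant predictions) or that fail outright are recorded with NaN
    metrics and a note, and the run continues.
    """
    envs = sorted(blups["env"].unique())
    genotypes = sorted(blups["genotype"].unique())
    if traits is None:
        traits = sorted(blups["trait"].unique())
    sampler = sampler or SamplerConfig()
    master = np.random.SeedSequence(seed)
    rep_seeds = master.spawn(n_replicates)

    records = []
    for rep in range(n_replicates):
        streams = rep_seeds[rep].spawn(len(grid) * (len(models) + 1) + 1)
        part_seed = int(streams[0].generate_state(1)[0] % (2**31))
        partition = partition_nol(genotypes, len(envs), seed=part_seed)
        stream_i = 1
        for trs_size, n_nol, n_ol in grid:
            # one design per (replicate, grid entry): every model sees the
            # same allocation, so model contrasts are paired
            design_seed = int(streams[stream_i].generate_state(1)[0] % (2**31))
            stream_i += 1
            design = build_design(
                partition, trs_size, n_ol, seed=design_seed, environment_ids=envs
            )
            observed_cells = {
                (g, env) for env in envs for g in design.observed_set(env)
            }
            for model in models:
                fit_seed = int(streams[stream_i].generate_state(1)[0] % (2**31))
                stream_i += 1
                for trait in traits:
                    cfg = SamplerConfig(
                        n_iter=sampler.n_iter,
                        burn_in=sampler.burn_in,
                        thin=sampler.thin,
                        df0=sampler.df0,
                        r2=sampler.r2,
                        seed=fit_seed,
                        fixed_components=sampler.fixed_components,
                    )
                    base = {
                        "trait": trait,
                        "model": model,
                        "trs_size": trs_size,
                        "design": design.label,
                        "cv": classify_cv(design),
                        "replicate": rep + 1,
                    }
                    try:
                        cells = CellFrame.from_blups(blups, trait, observed_cells)
                        kernels = build_kernels(
                            cells, grm if model in ("M2", "M3") else None, model
                        )
                        fit = fit_model(cells, kernels, cfg)
                    except Exception as exc:  # keep the grid running
                        for env in envs:
                            records.append(
                                {**base, "env": env, "r": np.nan, "mse": np.nan,
                                 "n_test": len(design.testing_sets[env]),
                                 "note": f"fit failed: {exc}"}
                            )
                        continue
                    cell_index = {
                        (g, e): i
                        for i, (g, e) in enumerate(
                            zip(cells.genotypes, cells.environments)
                        )
                    }
                    for env in envs:
                        test = sorted(design.testing_sets[env])
                        idx = [cell_index[(g, env)] for g in test]
                        pred = fit.predictions[idx]
                        obs = cells.y[idx]
                        row = {**base, "env": env, "n_test": len(test), "note": ""}
                        try:
                            row["r"] = pearson(pred, obs)
                        except ValueError as exc:
                            row["r"] = np.nan
                            row["note"] = f"correlation undefined: {exc}"
                        row["mse"] = mse(pred, obs)
                        records.append(row)
    table = pd.DataFrame.from_records(records)
    return table


def aggregate(eval_table: pd.DataFrame) -> pd.DataFrame:
    """Mean predictive ability and MSE per (trait, model, trs_size, design).

    Averages first over environments within replicate, then over
    replicates — the arithmetic mean either way, but reported alongside
    the replicate count actually used.
    """
    g = (
        eval_table.groupby(["trait", "model", "trs_size", "design", "replicate"])[
            ["r", "mse"]
        ]
        .mean()
        .reset_index()
    )
    out = (
        g.groupby(["trait", "model", "trs_size", "design"])[["r", "mse"]]
        .mean()
        .reset_index()
    )
    out["n_replicates"] = (
        g.groupby(["trait", "model", "trs_size", "design"]).size().values
    )
    return out


def plot_metrics(eval_table: pd.DataFrame, trait: str, metric: str = "r", ax=None):
    """Mean metric versus number of OL genotypes, one line per model and TRS.

    Mirrors the standard sparse-testing summary figure: the x-axis walks
    the allocation designs from all-NOL to all-OL.
    """
    import matplotlib.pyplot as plt

    agg = aggregate(eval_table)
    agg = agg[agg["trait"] == trait].copy()
    agg["n_ol"] = agg["design"].str.split("/").str[1].astype(int)
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    for (model, trs), sub in agg.groupby(["model", "trs_size"]):
        sub = sub.sort_values("n_ol")
        ax.plot(sub["n_ol"], sub[metric], marker="o", label=f"{model}, TRS {trs}")
    ax.set_xlabel("overlapping genotypes per environment")
    ax.set_ylabel({"r": "predictive ability", "mse": "MSE"}.get(metric, metric))
    ax.set_title(trait)
    ax.legend(fontsize=8)
    return ax
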