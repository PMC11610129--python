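"""Inference campaigns: cross-validated ensembles, uncertainty, sparse models.

A *task* fits one model architecture to one joint dataset: an optional
hyperparameter grid search (fold 1) followed by one fit per
cross-validation fold, each with its own rotating train/validation/test
split and, by default, training targets resampled from their measurement
error distributions.  A 3-point grid plus 10-fold cross-validation thus
yields a collection of 13 fitted models.

Coefficient uncertainty is quantified across the cross-validation models by
a Monte-Carlo approach: point estimate = mean, 95% interval = mean +/-
1.96 sd (normal approximation; with ~10 models percentile intervals would
be degenerate).  For mechanistic thermodynamic fits, model units are
dimensionless free energies in RT, converted to kcal/mol via dG = theta*R*T.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design_io import JointDataset
from .model_fit import (
    FitResult,
    GPModel,
    ModelError,
    SplitAssignment,
    TrainConfig,
    assemble_model,
    assign_cv_splits,
    grid_search,
    resample_training_fitness,
    train,
)
from .transformations import (
    DEFAULT_TEMPERATURE_K,
    GAS_CONSTANT_KCAL,
    TransformationRegistry,
)


@dataclass(frozen=True)
class ThermoConstants:
    """Gas constant (kcal/K/mol) and temperature (K) for energy conversion."""

    R: float = GAS_CONSTANT_KCAL
    T: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self):
        if self.T <= 0:
            raise ValueError("temperature must be positive (Kelvin)")


def to_free_energy(theta, constants: ThermoConstants = ThermoConstants()):
    """Convert a model-unit (RT-scaled) coefficient to kcal/mol: dG = theta*R*T."""
    return np.asarray(theta, dtype=float) * constants.R * constants.T


@dataclass
class TaskCollection:
    """Fitted models from one inference task (grid search + k-fold CV)."""

    dataset: JointDataset
    splits: SplitAssignment
    grid_fits: list[FitResult]
    cv_fits: list[FitResult]
    best_config: TrainConfig
    grid_results: pd.DataFrame | None = None
    seed: int | None = None

    @property
    def n_models(self) -> int:
        return len(self.grid_fits) + len(self.cv_fits)

    @property
    def cv_models(self) -> list[GPModel]:
        return [f.model for f in self.cv_fits]

    def coefficient_table(self) -> pd.DataFrame:
        """Per-model coefficient values, long format (trait, name, order, fold)."""
        frames = []
        for fit in self.cv_fits:
            df = fit.model.coefficient_frame()
            df["fold"] = fit.fold
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def run_task(
    dataset: JointDataset,
    *,
    max_interaction_order: int = 1,
    ensemble: bool = False,
    features: Mapping[str, Sequence] | Sequence | None = None,
    downsample_interactions: int | float | None = None,
    k_folds: int = 10,
    validation_factor: int = 2,
    holdout_orders: Sequence[int] | None = None,
    grids: Mapping[str, Sequence] | None = None,
    config: TrainConfig | None = None,
    registry: TransformationRegistry | None = None,
    sos_architecture: Sequence[int] = (20,),
    sos_outputlinear: bool = False,
    seed: int = 0,
) -> TaskCollection:
    """Run one full inference task.

    Seeds for the split assignment, per-fold model initialization,
    mini-batch orders and training resampling are all derived from ``seed``,
    so a task is exactly reproducible.
    """
    config = config or TrainConfig()
    root = np.random.SeedSequence(seed)
    split_seed, grid_seed, fold_root, resample_root, init_root = root.spawn(5)
    splits = assign_cv_splits(
        dataset,
        k_folds=k_folds,
        validation_factor=validation_factor,
        holdout_orders=holdout_orders,
        seed=split_seed,
    )
    init_seeds = init_root.spawn(k_folds + 1)

    def make_model(which: int = 0):
        return assemble_model(
            dataset,
            max_interaction_order=max_interaction_order,
            ensemble=ensemble,
            features=features,
            downsample_interactions=downsample_interactions,
            registry=registry,
            sos_architecture=sos_architecture,
            sos_outputlinear=sos_outputlinear,
            seed=init_seeds[which],
        )

    grid_fits: list[FitResult] = []
    grid_results = None
    if grids:
        config, grid_results, grid_fits = grid_search(
            lambda: make_model(0), splits, config, grids, seed=grid_seed
        )

    fold_seeds = fold_root.spawn(k_folds)
    resample_seeds = resample_root.spawn(k_folds)
    y = dataset.fitness
    sigma = dataset.sigma
    cv_fits = []
    for fold in range(1, k_folds + 1):
        model = make_model(fold)
        y_override = None
        if config.training_resample:
            labels = splits.labels(fold)
            y_override = resample_training_fitness(
                y, sigma, labels == "train", seed=resample_seeds[fold - 1]
            )
        fit = train(
            model,
            splits,
            config,
            fold=fold,
            seed=fold_seeds[fold - 1],
            y_override=y_override,
        )
        fit.model.gauge_fix()
        cv_fits.append(fit)
    return TaskCollection(
        dataset=dataset,
        splits=splits,
        grid_fits=grid_fits,
        cv_fits=cv_fits,
        best_config=config,
        grid_results=grid_results,
        seed=seed,
    )


# -- Monte-Carlo confidence intervals -----------------------------------------


def monte_carlo_intervals(
    collection: TaskCollection,
    level: float = 0.95,
    constants: ThermoConstants = ThermoConstants(),
) -> pd.DataFrame:
    """Per-coefficient estimates with Monte-Carlo confidence intervals.

    Variability across the cross-validation models (independent splits and
    noise-resampled training targets) yields, per coefficient, a point
    estimate (mean), a normal-approximation interval (mean +/- z sd) on the
    model-unit scale, and the kcal/mol conversion of the point estimate.
    """
    models = collection.cv_models
    if len(models) < 2:
        raise ModelError("need at least two models to estimate variability")
    z = float(stats.norm.ppf(0.5 + level / 2))
    long = collection.coefficient_table()
    grouped = long.groupby(["trait", "name", "order"], sort=False)["value"]
    out = grouped.agg(["mean", "std", "count"]).reset_index()
    out = out.rename(columns={"mean": "theta_mean", "std": "theta_sd", "count": "n_models"})
    out["ci95_lower"] = out["theta_mean"] - z * out["theta_sd"]
    out["ci95_upper"] = out["theta_mean"] + z * out["theta_sd"]
    out["ddG_kcal_mol"] = to_free_energy(out["theta_mean"].to_numpy(), constants)
    out = out.sort_values(["trait", "order", "name"], kind="stable").reset_index(drop=True)
    return out


def write_coefficient_tables(
    estimates: pd.DataFrame, out_dir: str | Path
) -> list[Path]:
    """One TSV per trait: name, order, trait, theta_mean, ddG_kcal_mol, CI, n."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    cols = [
        "name",
        "order",
        "trait",
        "theta_mean",
        "ddG_kcal_mol",
        "ci95_lower",
        "ci95_upper",
        "n_models",
    ]
    for trait, sub in estimates.groupby("trait", sort=False):
        path = out_dir / f"coefficients_{trait}.tsv"
        sub[cols].to_csv(path, sep="\t", index=False)
        paths.append(path)
    return paths


# -- sparse two-stage workflow ------------------------------------------------


@dataclass
class SparseWorkflowResult:
    stage1: FitResult
    stage2: FitResult
    ranking: pd.DataFrame  # stage-1 coefficients ranked by |value|
    selected: list  # feature tuples passed to stage 2
    best_l1: float


def sparse_workflow(
    dataset: JointDataset,
    max_order: int = 6,
    l1_grid: Sequence[float] = (0.1, 0.01, 0.001),
    top_k: int = 100,
    config: TrainConfig | None = None,
    seed: int = 0,
) -> SparseWorkflowResult:
    """Two-stage sparse background-averaged epistasis inference.

    Stage 1: embed the library in the ensemble basis up to ``max_order``,
    fit a linear (no global epistasis) model with an L1 penalty chosen from
    ``l1_grid`` by validation loss, and rank coefficients by magnitude
    (ties: lower order first, then name).  Stage 2: refit using only the
    ``top_k`` largest-magnitude coefficients, without L1 regularization.
    Both stages fit fold 1 of the cross-validation split.
    """
    if len(dataset.design.rows) != 1:
        raise ModelError("sparse workflow expects a single-phenotype dataset")
    if dataset.design.rows[0].transformation != "Linear":
        raise ModelError("sparse workflow requires the Linear (identity) transformation")
    config = config or TrainConfig()
    root = np.random.SeedSequence(seed)
    split_seed, grid_seed, fit_seed, init_seed = root.spawn(4)
    splits = assign_cv_splits(dataset, seed=split_seed)

    def make_model(features=None):
        return assemble_model(
            dataset,
            max_interaction_order=max_order,
            ensemble=True,
            features=features,
            seed=init_seed,
        )

    # choose the L1 penalty on the grid (fold 1, short fits)
    l1_values = list(l1_grid)
    if len(l1_values) > 1:
        best_config, _, _ = grid_search(
            make_model,
            splits,
            config,
            {"l1_regularization_factor": l1_values},
            seed=grid_seed,
        )
        best_l1 = best_config.l1_regularization_factor
    else:
        best_l1 = float(l1_values[0])
        best_config = replace(config, l1_regularization_factor=best_l1)

    stage1 = train(make_model(), splits, best_config, fold=1, seed=fit_seed)
    stage1.model.gauge_fix()
    coefs = stage1.model.coefficient_frame()
    nonzero = coefs[coefs["order"] > 0].copy()
    nonzero["magnitude"] = nonzero["value"].abs()
    ranking = nonzero.sort_values(
        ["magnitude", "order", "name"], ascending=[False, True, True], kind="stable"
    ).reset_index(drop=True)
    if top_k > len(ranking):
        raise ModelError(
            f"top_k={top_k} exceeds the {len(ranking)} available coefficients"
        )
    trait = stage1.model.trait_names[0]
    feature_by_name = {
        ":".join(s.name for s in f): f for f in stage1.model.trait_features[trait]
    }
    selected = [feature_by_name[n] for n in ranking["name"].head(top_k)]

    stage2_config = replace(best_config, l1_regularization_factor=0.0)
    stage2 = train(
        make_model(features=selected), splits, stage2_config, fold=1, seed=fit_seed
    )
    stage2.model.gauge_fix()
    return SparseWorkflowResult(
        stage1=stage1,
        stage2=stage2,
        ranking=ranking,
        selected=selected,
        best_l1=best_l1,
    )
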