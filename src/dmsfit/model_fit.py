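"""Model assembly, losses, cross-validation splits and training.

The genotype-phenotype model is the composition F = h(g(f(x))):

* ``f`` -- per-trait additive maps: phi_t = X theta_f[t], where X is a
  feature matrix (one-hot or ensemble basis) and theta_f includes the
  order-0 wild-type term;
* ``g`` -- a global-epistasis transformation per observed phenotype
  (possibly with trainable parameters theta_g);
* ``h`` -- a per-phenotype affine calibration (scale, shift) = theta_h
  mapping the molecular phenotype to assay units.

Training minimizes an empirical-noise-aware loss (sigma-weighted L1 by
default, or a Gaussian negative log-likelihood) by mini-batch Adam with an
exponential learning-rate scheduler triggered on validation-loss plateaus
and early stopping once the wild-type terms of all traits have stabilized.
Gradients are computed by reverse-mode differentiation through the affine
calibration and the transformation's ``backward``.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design_io import JointDataset, VariantTable
from .encode import (
    FeatureMatrix,
    PositionAlleles,
    encode_ensemble,
    encode_onehot,
    ensemble_terms,
    observed_onehot_features,
    position_structure,
)
from .transformations import DEFAULT_REGISTRY, Transformation, TransformationRegistry


class ModelError(ValueError):
    pass


class TrainingDivergedError(RuntimeError):
    def __init__(self, epoch: int):
        super().__init__(f"non-finite loss at epoch {epoch}")
        self.epoch = epoch


# -- configuration ------------------------------------------------------------


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters (defaults follow the published tool)."""

    batch_size: int = 1024
    learn_rate: float = 0.05
    l1_regularization_factor: float = 0.0
    l2_regularization_factor: float = 1e-6
    num_epochs: int = 1000
    num_epochs_grid: int = 100
    scheduler_gamma: float = 0.98
    early_stopping: bool = True
    loss_function_name: str = "WeightedL1"  # or "GaussianNLL"
    training_resample: bool = True

    def __post_init__(self):
        if self.batch_size < 1 or self.learn_rate <= 0:
            raise ModelError("batch_size and learn_rate must be positive")
        if self.l1_regularization_factor < 0 or self.l2_regularization_factor < 0:
            raise ModelError("regularization factors must be non-negative")
        if self.loss_function_name not in ("WeightedL1", "GaussianNLL"):
            raise ModelError(
                "loss_function_name must be 'WeightedL1' or 'GaussianNLL'"
            )


# -- loss functions -----------------------------------------------------------


def _regularization(theta_f: np.ndarray, l1: float, l2: float) -> float:
    theta_f = np.asarray(theta_f, dtype=float)
    return l1 * np.abs(theta_f).sum() + l2 * np.square(theta_f).sum()


def loss_gaussian_nll(y, y_hat, sigma, theta_f=(), l1=0.0, l2=0.0) -> float:
    """Gaussian negative log-likelihood with empirical noise.

    1/(2N) sum (y-y_hat)^2 / sigma^2 + l1*||theta_f||_1 + l2*||theta_f||_2^2
    + c, with c = 1/(2N) sum log(2 pi sigma^2) independent of parameters.
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    n = y.size
    data = np.sum(np.square(y - y_hat) / np.square(sigma)) / (2 * n)
    c = np.sum(np.log(2 * np.pi * np.square(sigma))) / (2 * n)
    return float(data + c + _regularization(theta_f, l1, l2))


def loss_weighted_l1(y, y_hat, sigma, theta_f=(), l1=0.0, l2=0.0) -> float:
    """Sigma-weighted mean absolute error plus regularization (default loss)."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    data = np.mean(np.abs(y - y_hat) / sigma)
    return float(data + _regularization(theta_f, l1, l2))


def _dloss_dyhat(name: str, y, y_hat, sigma) -> np.ndarray:
    """Gradient of the data term w.r.t. predictions, averaged over the batch."""
    n = y.size
    if name == "GaussianNLL":
        return -(y - y_hat) / (np.square(sigma) * n)
    return -np.sign(y - y_hat) / (sigma * n)


# -- cross-validation splits --------------------------------------------------

TRAIN, VALIDATION, TEST = "train", "validation", "test"


@dataclass
class SplitAssignment:
    """K-fold partition with rotating test/validation blocks.

    One random permutation of eligible observations is cut into ``k_folds``
    blocks; for fold j the test set is block j and the validation set the
    next ``validation_factor`` blocks (cyclically).  Observations excluded
    by ``holdout_orders`` -- and every wild type -- are always training.
    """

    k_folds: int
    validation_factor: int
    blocks: list[np.ndarray]  # observation indices per block
    always_train: np.ndarray
    n_obs: int

    def labels(self, fold: int) -> np.ndarray:
        """Per-observation split labels for fold ``fold`` (1-based)."""
        if not 1 <= fold <= self.k_folds:
            raise ModelError(f"fold must be in 1..{self.k_folds}")
        lab = np.full(self.n_obs, TRAIN, dtype=object)
        j = fold - 1
        lab[self.blocks[j]] = TEST
        for v in range(1, self.validation_factor + 1):
            lab[self.blocks[(j + v) % self.k_folds]] = VALIDATION
        lab[self.always_train] = TRAIN
        return lab


def assign_cv_splits(
    dataset: JointDataset,
    k_folds: int = 10,
    validation_factor: int = 2,
    holdout_orders: Sequence[int] | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> SplitAssignment:
    """Random k-fold split assignment, deterministic given ``seed``."""
    if k_folds < 2:
        raise ModelError("k_folds must be >= 2")
    if validation_factor < 1 or validation_factor + 1 >= k_folds:
        raise ModelError(
            "validation_factor must satisfy (validation_factor + 1)/k_folds < 1"
        )
    orders = dataset.mutation_order
    eligible = orders > 0
    if holdout_orders is not None:
        allowed = set(int(o) for o in holdout_orders)
        eligible &= np.array([o in allowed for o in orders])
    idx = np.flatnonzero(eligible)
    if len(idx) < k_folds:
        raise ModelError(
            "too few eligible observations for the requested number of folds "
            "(holdout_orders may be too restrictive)"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(idx)
    blocks = np.array_split(perm, k_folds)
    always_train = np.flatnonzero(~eligible)
    return SplitAssignment(
        k_folds=k_folds,
        validation_factor=validation_factor,
        blocks=[np.asarray(b) for b in blocks],
        always_train=always_train,
        n_obs=dataset.n_obs,
    )


def resample_training_fitness(
    y: np.ndarray,
    sigma: np.ndarray,
    train_mask: np.ndarray,
    seed: int | np.random.SeedSequence = 0,
) -> np.ndarray:
    """Replace training targets by one draw from Normal(y, sigma^2) each.

    Validation and test targets are untouched.  This propagates the
    measurement-error distribution into the ensemble of fitted models.
    """
    rng = np.random.default_rng(seed)
    out = np.array(y, dtype=float)
    out[train_mask] = rng.normal(y[train_mask], sigma[train_mask])
    return out


# -- model --------------------------------------------------------------------


@dataclass
class GPModel:
    """Assembled genotype-phenotype model with its parameters and features.

    theta_f: trait -> coefficient vector (index 0 = wild-type term);
    theta_g: per design row, dict of transformation parameter arrays;
    theta_h: (n_rows, 2) array of (scale, shift).
    """

    dataset: JointDataset
    trait_names: list[str]
    trait_features: dict  # trait -> list of feature tuples (shared columns)
    trait_coeff_names: dict  # trait -> list[str] incl. intercept
    X: list  # per row: dict trait -> (n_k, p_t) matrix
    transformations: list[Transformation]
    theta_f: dict = field(default_factory=dict)
    theta_g: list = field(default_factory=list)
    theta_h: np.ndarray | None = None
    basis: str = "onehot"

    def init_parameters(self, rng: np.random.Generator) -> None:
        self.theta_f = {
            t: np.zeros(len(self.trait_coeff_names[t])) for t in self.trait_names
        }
        self.theta_g = [
            tr.init_params(len(row.traits), rng)
            for tr, row in zip(self.transformations, self.dataset.design.rows)
        ]
        self.theta_h = np.zeros((len(self.dataset.design.rows), 2))
        for k, (tr, table) in enumerate(zip(self.transformations, self.dataset.tables)):
            y = table.fitness
            if tr.bounded01:
                self.theta_h[k] = (float(np.ptp(y)) or 1.0, float(y.min()))
            else:
                self.theta_h[k] = (1.0, 0.0)

    def copy_parameters(self) -> tuple:
        return (
            {t: v.copy() for t, v in self.theta_f.items()},
            [{k: v.copy() for k, v in g.items()} for g in self.theta_g],
            self.theta_h.copy(),
        )

    # -- forward pass ---------------------------------------------------------

    def traits_of_row(self, k: int) -> tuple[str, ...]:
        return self.dataset.design.rows[k].traits

    def phi(self, k: int, idx: np.ndarray | None = None) -> np.ndarray:
        """Additive trait values for row k, shape (n, n_traits_of_row)."""
        cols = []
        for t in self.traits_of_row(k):
            X = self.X[k][t]
            if idx is not None:
                X = X[idx]
            cols.append(X @ self.theta_f[t])
        return np.stack(cols, axis=1)

    def predict_row(self, k: int, idx: np.ndarray | None = None) -> np.ndarray:
        phi = self.phi(k, idx)
        p = self.transformations[k].forward(phi, self.theta_g[k])
        scale, shift = self.theta_h[k]
        return scale * p + shift

    def predict_all(self) -> np.ndarray:
        """Predictions for every observation, in global observation order."""
        return np.concatenate(
            [self.predict_row(k) for k in range(len(self.dataset.tables))]
        )

    def gauge_fix(self) -> None:
        """Remove the affine gauge of identity-transformation phenotypes.

        For a design row using the Linear transformation, only the product
        scale * theta (plus shift on the intercept) is identifiable.  When
        such a row's trait feeds no other phenotype, fold the affine
        calibration into the trait coefficients and reset (scale, shift) to
        (1, 0).  Predictions are exactly unchanged; coefficient values
        become gauge-invariant and hence comparable across refits.
        """
        design = self.dataset.design
        for k, row in enumerate(design.rows):
            if self.transformations[k].name != "Linear":
                continue
            t = row.traits[0]
            used_elsewhere = any(
                t in r.traits for j, r in enumerate(design.rows) if j != k
            )
            if used_elsewhere:
                continue
            scale, shift = self.theta_h[k]
            self.theta_f[t] *= scale
            self.theta_f[t][0] += shift
            self.theta_h[k] = (1.0, 0.0)
        # learned global epistasis: the trait sign is a gauge mode -- orient
        # unidimensional SumOfSigmoids fits so the phenotype increases with
        # the trait (negating the trait and mirroring the sub-network input
        # weights leaves predictions exactly unchanged)
        for k, row in enumerate(design.rows):
            tr = self.transformations[k]
            if tr.name != "SumOfSigmoids" or len(row.traits) != 1:
                continue
            t = row.traits[0]
            exclusive = all(
                t not in r.traits for j, r in enumerate(design.rows) if j != k
            )
            if not exclusive:
                continue
            phi = self.phi(k)[:, 0]
            if np.std(phi) == 0:
                continue
            y_hat = self.predict_row(k)
            slope = np.polyfit(phi, y_hat, 1)[0]
            if slope < 0:
                self.theta_f[t] *= -1.0
                self.theta_g[k]["W0"] *= -1.0

    def coefficient_frame(self) -> pd.DataFrame:
        """Tidy per-trait coefficient table (model units)."""
        recs = []
        for t in self.trait_names:
            names = self.trait_coeff_names[t]
            orders = [0] + [len(f) for f in self.trait_features[t]]
            for name, order, value in zip(names, orders, self.theta_f[t]):
                recs.append(
                    {"trait": t, "name": name, "order": order, "value": float(value)}
                )
        return pd.DataFrame(recs)


def predict(model: GPModel, phenotype: int | str, idx: np.ndarray | None = None):
    """Predicted assay-unit phenotype for one design row.

    ``phenotype`` is a row index or phenotype name.  Predictions are made for
    the requested phenotype's observations (optionally a subset ``idx``).
    """
    if isinstance(phenotype, str):
        names = [r.phenotype for r in model.dataset.design.rows]
        if phenotype not in names:
            raise ModelError(f"unknown phenotype {phenotype!r}; have {names}")
        phenotype = names.index(phenotype)
    if not 0 <= phenotype < len(model.dataset.design.rows):
        raise ModelError(f"phenotype index {phenotype} out of range")
    return model.predict_row(phenotype, idx)


def assemble_model(
    dataset: JointDataset,
    max_interaction_order: int = 1,
    ensemble: bool = False,
    features: Mapping[str, Sequence[tuple]] | Sequence[tuple] | None = None,
    downsample_interactions: int | float | None = None,
    registry: TransformationRegistry | None = None,
    sos_architecture: Sequence[int] = (20,),
    sos_outputlinear: bool = False,
    seed: int | np.random.SeedSequence = 0,
) -> GPModel:
    """Build the network from a joint dataset.

    For each trait, the coefficient set is the union of features enumerated
    from every table whose design row uses that trait, so traits shared
    across phenotypes (e.g. a folding energy entering both an abundance and
    a binding assay) are fitted against shared columns.  ``features`` may be
    a mapping trait -> explicit feature list, or a single list applied to
    every trait.
    """
    registry = registry or DEFAULT_REGISTRY
    design = dataset.design
    design.validate_transformations(registry)
    trait_names = design.trait_names

    seed_seq = (
        seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    )
    ds_seed, init_seed = seed_seq.spawn(2)

    trait_features: dict[str, list] = {}
    trait_positions: dict[str, list[PositionAlleles]] = {}
    for t in trait_names:
        rows = dataset.tables_for_trait(t)
        if ensemble:
            # union allele structure over member tables
            merged: dict[int, PositionAlleles] = {}
            for k in rows:
                for p in position_structure(dataset.tables[k]):
                    if p.pos in merged:
                        muts = tuple(sorted(set(merged[p.pos].mutants) | set(p.mutants)))
                        merged[p.pos] = PositionAlleles(p.pos, p.wt, muts)
                    else:
                        merged[p.pos] = p
            positions = [merged[pos] for pos in sorted(merged)]
            trait_positions[t] = positions
            feats = ensemble_terms(positions, max_interaction_order)
        else:
            union: dict = {}
            for k in rows:
                for f in observed_onehot_features(
                    dataset.tables[k], max_interaction_order
                ):
                    union[f] = None
            feats = sorted(union, key=lambda f: (len(f), ":".join(s.name for s in f)))
        if features is not None:
            explicit = features[t] if isinstance(features, Mapping) else features
            feats = [tuple(sorted(f)) for f in explicit]
        elif downsample_interactions is not None:
            n_avail = len(feats)
            if (
                isinstance(downsample_interactions, float)
                and downsample_interactions <= 1.0
            ):
                target = int(round(downsample_interactions * n_avail))
            else:
                target = int(downsample_interactions)
            if target > n_avail:
                raise ModelError("cannot downsample to more coefficients than exist")
            rng = np.random.default_rng(ds_seed)
            keep = np.sort(rng.choice(n_avail, size=target, replace=False))
            feats = [feats[i] for i in keep]
        trait_features[t] = feats

    from .encode import INTERCEPT_NAME, _interaction_name

    trait_coeff_names = {
        t: [INTERCEPT_NAME] + [_interaction_name(f) for f in trait_features[t]]
        for t in trait_names
    }

    X: list[dict[str, np.ndarray]] = []
    for k, (row, table) in enumerate(zip(design.rows, dataset.tables)):
        mats = {}
        for t in row.traits:
            if ensemble:
                fm = encode_ensemble(
                    table,
                    max_interaction_order,
                    positions=trait_positions[t],
                    features=trait_features[t],
                )
            else:
                fm = encode_onehot(
                    table,
                    max_interaction_order,
                    features=trait_features[t],
                    allow_unknown=True,
                )
            mats[t] = fm.values
        X.append(mats)

    transformations = [
        registry.create(
            row.transformation,
            len(row.traits),
            sos_architecture=sos_architecture,
            sos_outputlinear=sos_outputlinear,
        )
        for row in design.rows
    ]

    model = GPModel(
        dataset=dataset,
        trait_names=trait_names,
        trait_features=trait_features,
        trait_coeff_names=trait_coeff_names,
        X=X,
        transformations=transformations,
        basis="ensemble" if ensemble else "onehot",
    )
    model.init_parameters(np.random.default_rng(init_seed))
    return model


# -- Adam ---------------------------------------------------------------------


class _Adam:
    """Minimal Adam optimizer over a list of named numpy arrays."""

    def __init__(self, arrays: dict, beta1=0.9, beta2=0.999, eps=1e-8):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in arrays.items()}
        self.v = {k: np.zeros_like(v) for k, v in arrays.items()}
        self.t = 0

    def step(self, arrays: dict, grads: dict, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1**self.t
        bc2 = 1 - b2**self.t
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * np.square(g)
            arrays[k] -= lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)


# -- training -----------------------------------------------------------------


@dataclass
class FitResult:
    model: GPModel
    trace: pd.DataFrame
    config: TrainConfig
    fold: int
    stopped_early: bool
    final_train_loss: float
    final_val_loss: float


def _theta_f_concat(model: GPModel) -> np.ndarray:
    return np.concatenate([model.theta_f[t] for t in model.trait_names])


def _full_loss(model, y, sigma, mask, config) -> float:
    """Loss over the masked observations at current parameters."""
    y_hat = model.predict_all()
    theta = _theta_f_concat(model)
    fn = loss_gaussian_nll if config.loss_function_name == "GaussianNLL" else loss_weighted_l1
    return fn(
        y[mask],
        y_hat[mask],
        sigma[mask],
        theta,
        config.l1_regularization_factor,
        config.l2_regularization_factor,
    )


def train(
    model: GPModel,
    splits: SplitAssignment,
    config: TrainConfig,
    fold: int = 1,
    seed: int | np.random.SeedSequence = 0,
    y_override: np.ndarray | None = None,
    num_epochs: int | None = None,
) -> FitResult:
    """Fit the model in place by mini-batch Adam.

    ``y_override`` substitutes the (possibly noise-resampled) training
    targets; validation/test losses always use the original measurements.
    Gradients are computed on training observations only.
    """
    dataset = model.dataset
    y_true = dataset.fitness
    sigma = dataset.sigma
    labels = splits.labels(fold)
    train_mask = labels == TRAIN
    val_mask = labels == VALIDATION
    y_fit = np.array(y_true, dtype=float)
    if y_override is not None:
        y_fit[train_mask] = y_override[train_mask]

    # global observation index -> (row k, local index)
    row_of = dataset.obs_phenotype
    local_of = dataset.obs_local
    train_idx = np.flatnonzero(train_mask)
    if len(train_idx) == 0:
        raise ModelError("empty training set")

    # flat parameter dictionary for the optimizer
    params: dict = {}
    for t in model.trait_names:
        params[("f", t)] = model.theta_f[t]
    for k, g in enumerate(model.theta_g):
        for name, arr in g.items():
            params[("g", k, name)] = arr
    params[("h",)] = model.theta_h

    opt = _Adam(params)
    lr = config.learn_rate
    n_total = num_epochs if num_epochs is not None else config.num_epochs
    rng = np.random.default_rng(seed)
    gauss = config.loss_function_name == "GaussianNLL"
    l1 = config.l1_regularization_factor
    l2 = config.l2_regularization_factor

    trace_rows = []
    val_losses: list[float] = []
    wt_history: list[np.ndarray] = []
    stopped_early = False

    for epoch in range(1, n_total + 1):
        order = rng.permutation(train_idx)
        for start in range(0, len(order), config.batch_size):
            batch = order[start : start + config.batch_size]
            nb = len(batch)
            grads = {k: np.zeros_like(v) for k, v in params.items()}
            for k in np.unique(row_of[batch]):
                sel = batch[row_of[batch] == k]
                loc = local_of[sel]
                phi = model.phi(k, loc)
                tr = model.transformations[k]
                p = tr.forward(phi, model.theta_g[k])
                scale, shift = model.theta_h[k]
                y_hat = scale * p + shift
                yb, sb = y_fit[sel], sigma[sel]
                if gauss:
                    dyhat = -(yb - y_hat) / (np.square(sb) * nb)
                else:
                    dyhat = -np.sign(yb - y_hat) / (sb * nb)
                grads[("h",)][k, 0] += np.dot(dyhat, p)
                grads[("h",)][k, 1] += dyhat.sum()
                dp = dyhat * scale
                dphi, dg = tr.backward(phi, model.theta_g[k], dp)
                for name, arr in dg.items():
                    grads[("g", k, name)] += arr
                for j, t in enumerate(model.traits_of_row(k)):
                    Xb = model.X[k][t][loc]
                    grads[("f", t)] += Xb.T @ dphi[:, j]
            # regularization of theta_f (intercept exempt from L1, kept in L2)
            for t in model.trait_names:
                th = params[("f", t)]
                g = grads[("f", t)]
                if l1 > 0:
                    s = np.sign(th)
                    s[0] = 0.0
                    g += l1 * s
                if l2 > 0:
                    g += 2 * l2 * th
            opt.step(params, grads, lr)

        train_loss = _full_loss(model, y_fit, sigma, train_mask, config)
        val_loss = _full_loss(model, y_true, sigma, val_mask, config)
        if not (np.isfinite(train_loss) and np.isfinite(val_loss)):
            raise TrainingDivergedError(epoch)
        val_losses.append(val_loss)
        wt = np.array([model.theta_f[t][0] for t in model.trait_names])
        wt_history.append(wt)
        trace_rows.append(
            {
                "epoch": epoch,
                "fold": fold,
                "train_loss": train_loss,
                "val_loss": val_loss,
                "lr": lr,
                **{
                    f"wt_{t}": wt[i] for i, t in enumerate(model.trait_names)
                },
            }
        )

        # exponential lr decay when validation loss has plateaued:
        # mean over the last ten epochs vs the preceding ten
        if epoch >= 20:
            recent = np.mean(val_losses[-10:])
            previous = np.mean(val_losses[-20:-10])
            if recent >= previous:
                lr *= config.scheduler_gamma
        # early stop when every trait's WT term has stabilized
        if config.early_stopping and epoch >= 20:
            recent_wt = np.stack(wt_history[-10:])
            if np.all(recent_wt.std(axis=0) <= 1e-3):
                stopped_early = True
                break

    trace = pd.DataFrame(trace_rows)
    return FitResult(
        model=model,
        trace=trace,
        config=config,
        fold=fold,
        stopped_early=stopped_early,
        final_train_loss=trace_rows[-1]["train_loss"],
        final_val_loss=trace_rows[-1]["val_loss"],
    )


# -- hyperparameter grid search ----------------------------------------------

GRID_KEYS = (
    "batch_size",
    "learn_rate",
    "l1_regularization_factor",
    "l2_regularization_factor",
)


def grid_search(
    make_model,
    splits: SplitAssignment,
    base_config: TrainConfig,
    grids: Mapping[str, Sequence],
    seed: int | np.random.SeedSequence = 0,
    fold: int = 1,
):
    """Pick the hyperparameter combination with the smallest validation loss
    after ``num_epochs_grid`` epochs (fold 1 by default; ties to the first
    listed; diverging configurations are excluded with a warning).

    ``make_model`` is a zero-argument factory returning a freshly
    initialized model.  Returns (best_config, results_frame, fits).
    """
    unknown = set(grids) - set(GRID_KEYS)
    if unknown:
        raise ModelError(f"unknown grid key(s): {sorted(unknown)}; allowed {GRID_KEYS}")
    if not grids or any(len(v) == 0 for v in grids.values()):
        raise ModelError("grids must be non-empty")
    seed_seq = (
        seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    )
    keys = list(grids)
    records = []
    fits = []
    best = None
    for combo in itertools.product(*[grids[k] for k in keys]):
        cfg = replace(
            base_config, **dict(zip(keys, combo)), early_stopping=False
        )
        model = make_model()
        child = np.random.SeedSequence(
            entropy=seed_seq.entropy, spawn_key=(*seed_seq.spawn_key, hash(combo) % 2**31)
        )
        try:
            fit = train(
                model,
                splits,
                cfg,
                fold=fold,
                seed=child,
                num_epochs=cfg.num_epochs_grid,
            )
        except TrainingDivergedError as err:
            warnings.warn(
                f"grid point {dict(zip(keys, combo))} diverged ({err}); excluded"
            )
            records.append(
                {**dict(zip(keys, combo)), "val_loss": np.nan, "diverged": True}
            )
            continue
        records.append(
            {**dict(zip(keys, combo)), "val_loss": fit.final_val_loss, "diverged": False}
        )
        fits.append(fit)
        if best is None or fit.final_val_loss < best[1]:
            best = (cfg, fit.final_val_loss)
    if best is None:
        raise ModelError("every grid configuration diverged")
    best_config = replace(best[0], early_stopping=base_config.early_stopping)
    return best_config, pd.DataFrame(records), fits
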