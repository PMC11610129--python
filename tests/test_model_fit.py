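import math

import numpy as np
import pandas as pd
import pytest

from dmsfit.design_io import DesignRow, JointDataset, ModelDesign, variant_table_from_frame
from dmsfit.model_fit import (
    ModelError,
    TrainConfig,
    TrainingDivergedError,
    assemble_model,
    assign_cv_splits,
    grid_search,
    loss_gaussian_nll,
    loss_weighted_l1,
    predict,
    resample_training_fitness,
    train,
)
from dmsfit.synthetic_data import SCENARIOS
from tests.conftest import linear_joint_dataset


class TestLosses:
    def test_gaussian_nll_zero_residual(self):
        assert loss_gaussian_nll([1.0], [1.0], [1.0]) == pytest.approx(
            0.5 * math.log(2 * math.pi)
        )

    def test_gaussian_nll_unit_residual(self):
        assert loss_gaussian_nll([1.0], [0.0], [1.0]) == pytest.approx(
            0.5 + 0.5 * math.log(2 * math.pi)
        )

    def test_gaussian_nll_sigma_scaling(self):
        base = loss_gaussian_nll([1.0], [0.0], [1.0]) - 0.5 * math.log(2 * math.pi)
        halved = loss_gaussian_nll([1.0], [0.0], [0.5]) - 0.5 * math.log(
            2 * math.pi * 0.25
        )
        assert halved == pytest.approx(4 * base)

    def test_gaussian_nll_equals_half_mse_plus_constant(self):
        # with sigma = 1 and no regularization: NLL = MSE/2 + log(2 pi)/2
        rng = np.random.default_rng(0)
        y = rng.normal(size=50)
        y_hat = rng.normal(size=50)
        expected = 0.5 * np.mean((y - y_hat) ** 2) + 0.5 * math.log(2 * math.pi)
        assert loss_gaussian_nll(y, y_hat, np.ones(50)) == pytest.approx(expected)

    def test_weighted_l1_direct(self):
        assert loss_weighted_l1([1.0, 0.0], [0.0, 1.0], [1.0, 2.0]) == pytest.approx(0.75)

    def test_l1_penalty(self):
        assert loss_weighted_l1([0.0], [0.0], [1.0], theta_f=[3.0, -4.0], l1=1.0) == 7.0

    def test_l2_penalty(self):
        assert loss_weighted_l1([0.0], [0.0], [1.0], theta_f=[3.0, -4.0], l2=1.0) == 25.0


class TestSplits:
    def make_dataset(self, n_positions=10, sample=1001):
        from dmsfit.synthetic_data import LibraryDesign, generate_library

        lib = LibraryDesign.biallelic(n_positions)
        seqs = generate_library(lib, seed=0, sample=sample)
        table = variant_table_from_frame(
            pd.DataFrame({"aa_seq": seqs, "fitness": 0.0, "sigma": 1.0}),
            wild_type=lib.wild_type,
        )
        design = ModelDesign([DesignRow("p", ("T",), "Linear", "p.tsv")])
        return JointDataset(design=design, tables=[table])

    def test_default_fractions(self):
        # ~30% held out: 10% test, 20% validation
        ds = self.make_dataset()
        splits = assign_cv_splits(ds, seed=3)
        labels = splits.labels(1)
        n = ds.n_obs
        assert abs(np.sum(labels == "test") - n / 10) <= 1
        assert abs(np.sum(labels == "validation") - 2 * n / 10) <= 2
        assert abs(np.sum(labels == "train") - 7 * n / 10) <= 3

    def test_labels_partition_and_rotate(self):
        ds = self.make_dataset()
        splits = assign_cv_splits(ds, seed=3)
        test_sets = []
        for fold in range(1, 11):
            labels = splits.labels(fold)
            assert set(labels) == {"train", "validation", "test"}
            test_sets.append(frozenset(np.flatnonzero(labels == "test")))
        # rotating test blocks are disjoint and cover all eligible variants
        assert len(set(test_sets)) == 10
        union = set().union(*test_sets)
        assert len(union) == sum(len(s) for s in test_sets)

    def test_wild_type_always_trains(self):
        ds = self.make_dataset()
        splits = assign_cv_splits(ds, seed=5)
        wt = int(np.flatnonzero(ds.mutation_order == 0)[0])
        for fold in range(1, 11):
            assert splits.labels(fold)[wt] == "train"

    def test_holdout_orders_restricts_heldout(self):
        ds = self.make_dataset()
        splits = assign_cv_splits(ds, holdout_orders={2}, seed=7)
        labels = splits.labels(1)
        orders = ds.mutation_order
        held = (labels == "test") | (labels == "validation")
        assert np.all(orders[held] == 2)
        assert np.all(labels[orders == 1] == "train")

    def test_seed_reproducible(self):
        ds = self.make_dataset()
        a = assign_cv_splits(ds, seed=11).labels(1)
        b = assign_cv_splits(ds, seed=11).labels(1)
        c = assign_cv_splits(ds, seed=12).labels(1)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_invalid_validation_factor_rejected(self):
        ds = self.make_dataset()
        with pytest.raises(ModelError):
            assign_cv_splits(ds, k_folds=2, validation_factor=1)

    def test_too_restrictive_holdout_rejected(self):
        ds = self.make_dataset()
        with pytest.raises(ModelError):
            assign_cv_splits(ds, holdout_orders={25})


class TestResample:
    def test_draws_have_requested_spread(self):
        y = np.array([1.0, -2.0])
        sigma = np.array([0.5, 2.0])
        mask = np.array([True, True])
        draws = np.stack(
            [
                resample_training_fitness(y, sigma, mask, seed=s)
                for s in range(10_000)
            ]
        )
        assert np.allclose(draws.mean(axis=0), y, atol=0.05)
        assert np.allclose(draws.std(axis=0), sigma, rtol=0.05)

    def test_untouched_outside_mask(self):
        y = np.array([1.0, -2.0])
        sigma = np.array([0.5, 2.0])
        out = resample_training_fitness(y, sigma, np.array([True, False]), seed=0)
        assert out[1] == -2.0
        assert out[0] != 1.0

    def test_tiny_sigma_is_identity_in_practice(self):
        y = np.array([1.0])
        out = resample_training_fitness(y, np.array([1e-6]), np.array([True]), seed=1)
        assert out[0] == pytest.approx(1.0, abs=1e-4)


class TestPredict:
    def test_wild_type_two_state_closed_form(self, linear_dataset):
        ds, _, _ = linear_dataset
        design = ModelDesign(
            [DesignRow("assay", ("Trait",), "TwoStateFractionFolded", "assay.tsv")]
        )
        ds2 = JointDataset(design=design, tables=ds.tables)
        model = assemble_model(ds2, seed=0)
        g0, a, b = -1.2, 2.0, 0.25
        model.theta_f["Trait"][:] = 0.0
        model.theta_f["Trait"][0] = g0
        model.theta_h[0] = (a, b)
        wt = ds2.tables[0].wild_type_index
        y_hat = predict(model, "assay")
        assert y_hat[wt] == pytest.approx(a / (1 + math.exp(g0)) + b)

    def test_identity_returns_additive_trait(self, linear_dataset):
        ds, _, _ = linear_dataset
        model = assemble_model(ds, seed=0)
        rng = np.random.default_rng(2)
        model.theta_f["Trait"][:] = rng.normal(size=model.theta_f["Trait"].shape)
        model.theta_h[0] = (1.0, 0.0)
        phi = model.X[0]["Trait"] @ model.theta_f["Trait"]
        assert np.allclose(predict(model, 0), phi)

    def test_unknown_phenotype_rejected(self, linear_dataset):
        ds, _, _ = linear_dataset
        model = assemble_model(ds, seed=0)
        with pytest.raises(ModelError):
            predict(model, "nope")


class TestTrain:
    def test_recovers_least_squares_on_noiseless_linear_data(self, linear_dataset):
        ds, _, _ = linear_dataset
        splits = assign_cv_splits(ds, seed=1)
        model = assemble_model(ds, seed=2)
        cfg = TrainConfig(
            batch_size=16,
            loss_function_name="GaussianNLL",
            l2_regularization_factor=0.0,
            early_stopping=False,
            training_resample=False,
            num_epochs=1500,
        )
        train(model, splits, cfg, fold=1, seed=3)
        model.gauge_fix()
        mask = splits.labels(1) == "train"
        X = model.X[0]["Trait"]
        w = np.linalg.lstsq(X[mask], ds.fitness[mask], rcond=None)[0]
        assert np.abs(model.theta_f["Trait"] - w).max() < 1e-3

    def test_constant_fitness_shrinks_effects(self):
        from dmsfit.synthetic_data import LibraryDesign, generate_library

        lib = LibraryDesign.biallelic(5)
        seqs = generate_library(lib)
        table = variant_table_from_frame(
            pd.DataFrame({"aa_seq": seqs, "fitness": 0.7, "sigma": 0.1}),
            wild_type=lib.wild_type,
        )
        design = ModelDesign([DesignRow("p", ("T",), "Linear", "p.tsv")])
        ds = JointDataset(design=design, tables=[table])
        splits = assign_cv_splits(ds, seed=1)
        model = assemble_model(ds, seed=2)
        cfg = TrainConfig(
            batch_size=8,
            l2_regularization_factor=1e-3,
            early_stopping=False,
            training_resample=False,
            num_epochs=300,
        )
        train(model, splits, cfg, fold=1, seed=3)
        model.gauge_fix()
        assert np.abs(model.theta_f["T"][1:]).max() < 1e-2
        assert model.theta_f["T"][0] == pytest.approx(0.7, abs=1e-2)

    def test_two_state_parameter_recovery_single_fit(self):
        sc = SCENARIOS["two_state"](seed=5)
        splits = assign_cv_splits(sc.dataset, seed=1)
        model = assemble_model(sc.dataset, seed=2)
        fit = train(model, splits, sc.train_config, fold=1, seed=3)
        truth = sc.truth.trait_coefs["Folding"]
        names = model.trait_coeff_names["Folding"]
        t = np.array([truth[n] for n in names[1:]])
        e = model.theta_f["Folding"][1:]
        r = np.corrcoef(t, e)[0, 1]
        assert r > 0.99

    def test_trace_records_losses_and_wt_terms(self, linear_dataset):
        ds, _, _ = linear_dataset
        splits = assign_cv_splits(ds, seed=1)
        model = assemble_model(ds, seed=2)
        cfg = TrainConfig(
            early_stopping=False, training_resample=False, num_epochs=25
        )
        fit = train(model, splits, cfg, fold=1, seed=3)
        assert list(fit.trace.columns[:5]) == [
            "epoch",
            "fold",
            "train_loss",
            "val_loss",
            "lr",
        ]
        assert "wt_Trait" in fit.trace.columns
        assert len(fit.trace) == 25

    def test_divergence_raises_with_epoch(self, linear_dataset):
        ds, _, _ = linear_dataset
        splits = assign_cv_splits(ds, seed=1)
        model = assemble_model(ds, seed=2)
        cfg = TrainConfig(
            learn_rate=1e200,
            loss_function_name="GaussianNLL",
            early_stopping=False,
            training_resample=False,
            num_epochs=20,
        )
        with pytest.raises(TrainingDivergedError):
            train(model, splits, cfg, fold=1, seed=3)

    def test_deterministic_given_seed(self, linear_dataset):
        ds, _, _ = linear_dataset
        splits = assign_cv_splits(ds, seed=1)
        cfg = TrainConfig(early_stopping=False, training_resample=False, num_epochs=30)
        results = []
        for _ in range(2):
            model = assemble_model(ds, seed=2)
            train(model, splits, cfg, fold=1, seed=9)
            results.append(model.theta_f["Trait"].copy())
        assert np.array_equal(results[0], results[1])


class TestGridSearch:
    def make(self):
        ds, _, _ = linear_joint_dataset(n_positions=5)
        splits = assign_cv_splits(ds, seed=1)
        cfg = TrainConfig(
            num_epochs_grid=10, early_stopping=False, training_resample=False
        )
        return ds, splits, cfg

    def test_single_point_grid_returns_it(self):
        ds, splits, cfg = self.make()
        best, results, fits = grid_search(
            lambda: assemble_model(ds, seed=2),
            splits,
            cfg,
            {"learn_rate": [0.01]},
            seed=3,
        )
        assert best.learn_rate == 0.01
        assert len(results) == 1 and len(fits) == 1

    def test_l1_grid_runs_three_fits(self):
        ds, splits, cfg = self.make()
        best, results, fits = grid_search(
            lambda: assemble_model(ds, seed=2),
            splits,
            cfg,
            {"l1_regularization_factor": [0.1, 0.01, 0.001]},
            seed=3,
        )
        assert len(fits) == 3
        assert best.l1_regularization_factor in (0.1, 0.01, 0.001)
        assert best.l1_regularization_factor == results.loc[
            results["val_loss"].idxmin(), "l1_regularization_factor"
        ]

    def test_diverging_point_excluded_with_warning(self):
        ds, splits, cfg = self.make()
        cfg = TrainConfig(
            num_epochs_grid=10,
            loss_function_name="GaussianNLL",
            early_stopping=False,
            training_resample=False,
        )
        with pytest.warns(UserWarning, match="diverged"):
            best, results, fits = grid_search(
                lambda: assemble_model(ds, seed=2),
                splits,
                cfg,
                {"learn_rate": [1e200, 0.05]},
                seed=3,
            )
        assert best.learn_rate == 0.05
        assert results["diverged"].tolist() == [True, False]
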