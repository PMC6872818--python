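import numpy as np
import pytest
from scipy.special import expit

import importlib

trainmod = importlib.import_module("capsoqspr.train")

from capsoqspr import data as dataio
from capsoqspr.errors import ConfigurationError, ContractError, DataValidationError
from capsoqspr.metrics import rmsep
from capsoqspr.network import NetworkArchitecture, parameter_count, predict_batch
from capsoqspr.swarm import SwarmConfig
from capsoqspr.synthetic import GeneratorConfig, generate
from capsoqspr.train import (
    ArchSearchResult,
    TrainedModel,
    TrainingConfig,
    gradient_refine,
    make_batch_objective,
    mse_gradient,
    random_search_baseline,
    search_architecture,
    train,
    train_from_table,
    training_objective,
)

SMALL_ARCH = NetworkArchitecture((8, 3, 3, 1))


def small_dataset(n=40, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.uniform(0, 1, size=(n, 8))
    y = 0.3 + 0.4 * X[:, 0] - 0.2 * X[:, 1] ** 2
    return X, y


class TestTrainingObjective:
    def test_perfect_fit_is_zero(self):
        arch = NetworkArchitecture((2, 2, 1))
        params = np.zeros(9)
        X = np.zeros((3, 2))
        assert training_objective(params, arch, X, np.zeros(3)) == 0.0

    def test_constant_zero_network_unit_targets(self):
        arch = NetworkArchitecture((2, 2, 1))
        params = np.zeros(9)
        params[6:8] = 0.0  # output weights
        # zero weights and biases with a linear output predict exactly 0
        assert training_objective(params, arch, np.ones((2, 2)), np.ones(2)) == 1.0

    def test_equals_squared_rmsep(self):
        X, y = small_dataset()
        rng = np.random.default_rng(1)
        params = rng.normal(size=parameter_count(SMALL_ARCH))
        preds = predict_batch(SMALL_ARCH, params, X)
        obj = training_objective(params, SMALL_ARCH, X, y)
        assert obj == pytest.approx(rmsep(y, preds) ** 2, rel=1e-12)

    def test_empty_dataset_rejected(self):
        with pytest.raises(DataValidationError):
            training_objective(np.zeros(9), NetworkArchitecture((2, 2, 1)), np.empty((0, 2)), np.empty(0))

    def test_batch_objective_agrees_per_particle(self):
        X, y = small_dataset()
        rng = np.random.default_rng(2)
        P = rng.normal(size=(12, parameter_count(SMALL_ARCH)))
        batch = make_batch_objective(SMALL_ARCH, X, y)(P)
        loop = np.array([training_objective(p, SMALL_ARCH, X, y) for p in P])
        np.testing.assert_allclose(batch, loop, rtol=1e-12)


def tiny_config(seed=0, iters=30, refine=False):
    return TrainingConfig(
        swarm=SwarmConfig(num_particles=10, max_iterations=iters, rng_seed=seed),
        arch=SMALL_ARCH,
        gradient_refinement=refine,
        refine_epochs=100,
    )


class TestTrain:
    def test_zero_iterations_returns_best_initial_particle(self):
        X, y = small_dataset()
        cfg = tiny_config(iters=0)
        model = train((X, y), None, cfg)
        # reproduce the initial population by hand from the rng protocol
        rng = np.random.default_rng(cfg.swarm.rng_seed)
        pop = rng.uniform(-10, 10, size=(10, parameter_count(SMALL_ARCH)))
        vals = [training_objective(p, SMALL_ARCH, X, y) for p in pop]
        np.testing.assert_array_equal(model.best_params, pop[int(np.argmin(vals))])

    def test_identical_seeds_identical_parameters(self):
        X, y = small_dataset()
        a = train((X, y), None, tiny_config(seed=5))
        b = train((X, y), None, tiny_config(seed=5))
        np.testing.assert_array_equal(a.best_params, b.best_params)

    def test_trace_non_increasing(self):
        X, y = small_dataset()
        model = train((X, y), None, tiny_config())
        assert np.all(np.diff(model.training_trace) <= 0)

    def test_dimension_mismatch_rejected_before_optimization(self):
        X = np.zeros((5, 4))
        with pytest.raises(ContractError):
            train((X, np.zeros(5)), None, tiny_config())

    def test_validation_checkpoints_recorded(self):
        X, y = small_dataset()
        Xv, yv = small_dataset(12, seed=3)
        cfg = tiny_config(iters=25)
        cfg.checkpoint_every = 10
        model = train((X, y), (Xv, yv), cfg)
        assert len(model.checkpoints) == 2
        for _, train_mse, val_mse in model.checkpoints:
            assert train_mse >= 0 and val_mse >= 0

    def test_budget_accounting(self):
        X, y = small_dataset()
        model = train((X, y), None, tiny_config(iters=30))
        assert model.n_evaluations == 10 * 31


class TestGradientRefine:
    def test_zero_epochs_identity(self):
        X, y = small_dataset()
        model = train((X, y), None, tiny_config())
        out = gradient_refine(model, X, y, epochs=0)
        assert out is model

    def test_gradient_matches_hand_derivation_single_unit(self):
        # architecture 1-1-1, one data point: closed-form chain rule
        arch = NetworkArchitecture((1, 1, 1))
        w0, b0, w1, b1 = 0.8, -0.1, 1.3, 0.2
        x, y = 0.6, 1.0
        h = expit(w0 * x + b0)
        pred = w1 * h + b1
        e = 2.0 * (pred - y)
        expected = np.array([e * w1 * h * (1 - h) * x, e * w1 * h * (1 - h), e * h, e])
        grad = mse_gradient(
            np.array([w0, b0, w1, b1]), arch, np.array([[x]]), np.array([y])
        )
        np.testing.assert_allclose(grad, expected, rtol=1e-12)

    def test_plain_gd_step_applied(self):
        arch = NetworkArchitecture((1, 1, 1))
        params = np.array([0.8, -0.1, 1.3, 0.2])
        X, y = np.array([[0.6]]), np.array([1.0])
        model = TrainedModel(arch=arch, best_params=params, training_trace=np.empty(0))
        lr = 1e-3
        out = gradient_refine(model, X, y, learning_rate=lr, epochs=1, method="gd")
        stepped = params - lr * mse_gradient(params, arch, X, y)
        np.testing.assert_allclose(out.best_params, stepped, rtol=1e-12)

    def test_zero_mse_leaves_parameters_unchanged(self):
        arch = NetworkArchitecture((2, 2, 1))
        params = np.zeros(9)
        X, y = np.ones((3, 2)), np.zeros(3)
        model = TrainedModel(arch=arch, best_params=params.copy(), training_trace=np.empty(0))
        out = gradient_refine(model, X, y, epochs=5, method="gd")
        np.testing.assert_array_equal(out.best_params, params)

    def test_refinement_never_degrades_training_mse(self):
        X, y = small_dataset()
        model = train((X, y), None, tiny_config())
        before = training_objective(model.best_params, SMALL_ARCH, X, y)
        for method in ("gd", "rprop"):
            out = gradient_refine(model, X, y, epochs=50, method=method)
            after = training_objective(out.best_params, SMALL_ARCH, X, y)
            assert after <= before + 1e-15

    def test_rprop_makes_substantial_progress(self):
        X, y = small_dataset()
        model = train((X, y), None, tiny_config())
        out = gradient_refine(model, X, y, epochs=300, method="rprop")
        assert out.final_train_mse < 0.25 * model.final_train_mse

    def test_unknown_method_rejected(self):
        X, y = small_dataset()
        model = train((X, y), None, tiny_config())
        with pytest.raises(ConfigurationError):
            gradient_refine(model, X, y, epochs=1, method="adam")


class TestSearchArchitecture:
    def test_single_candidate_selected(self):
        X, y = small_dataset()
        Xv, yv = small_dataset(10, seed=4)
        res = search_architecture((X, y), (Xv, yv), tiny_config(iters=10), node_candidates=[3], hidden_layers=2)
        assert res.selected_nodes == 3
        assert len(res.records) == 1

    def test_selection_minimizes_validation_mse(self):
        X, y = small_dataset()
        Xv, yv = small_dataset(10, seed=4)
        res = search_architecture(
            (X, y), (Xv, yv), tiny_config(iters=15), node_candidates=[2, 3, 4], hidden_layers=2
        )
        frame = res.to_frame()
        best = frame.loc[frame["validation_mse"].idxmin(), "nodes"]
        assert res.selected_nodes == best

    def test_tie_breaks_toward_fewer_nodes(self, monkeypatch):
        def fake_train(train_set, validation_set, cfg):
            return TrainedModel(
                arch=cfg.arch,
                best_params=np.zeros(parameter_count(cfg.arch)),
                training_trace=np.empty(0),
                final_train_mse=0.5,
            )

        monkeypatch.setattr(trainmod, "train", fake_train)
        monkeypatch.setattr(
            trainmod, "training_objective", lambda p, a, X, y: 0.5
        )
        X, y = small_dataset()
        res = search_architecture((X, y), (X, y), tiny_config(), node_candidates=[5, 3, 7])
        assert res.selected_nodes == 3

    def test_candidate_failure_recorded_not_fatal(self, monkeypatch):
        real_train = trainmod.train

        def flaky_train(train_set, validation_set, cfg):
            if cfg.arch.layer_sizes[1] == 2:
                raise RuntimeError("boom")
            return real_train(train_set, validation_set, cfg)

        monkeypatch.setattr(trainmod, "train", flaky_train)
        X, y = small_dataset()
        Xv, yv = small_dataset(10, seed=4)
        res = search_architecture(
            (X, y), (Xv, yv), tiny_config(iters=5), node_candidates=[2, 3], hidden_layers=2
        )
        failed = [r for r in res.records if r["error"] is not None]
        assert len(failed) == 1 and failed[0]["nodes"] == 2
        assert res.selected_nodes == 3

    def test_empty_candidates_rejected(self):
        X, y = small_dataset()
        with pytest.raises(ConfigurationError):
            search_architecture((X, y), (X, y), tiny_config(), node_candidates=[])


class TestRandomBaseline:
    def test_deterministic(self):
        X, y = small_dataset()
        a = random_search_baseline((X, y), SMALL_ARCH, 500, rng_seed=1)
        b = random_search_baseline((X, y), SMALL_ARCH, 500, rng_seed=1)
        np.testing.assert_array_equal(a[0], b[0])
        assert a[1] == b[1]

    def test_best_value_consistent_with_parameters(self):
        X, y = small_dataset()
        params, value = random_search_baseline((X, y), SMALL_ARCH, 300, rng_seed=2)
        assert training_objective(params, SMALL_ARCH, X, y) == pytest.approx(value, rel=1e-12)


class TestModelPersistence:
    def test_save_load_round_trip_bit_exact(self, tmp_path):
        table = generate(GeneratorConfig(n_molecules=40, rng_seed=3))
        cfg = tiny_config(iters=10)
        model = train_from_table(table, cfg)
        path = tmp_path / "model.json"
        model.save(path)
        back = TrainedModel.load(path)
        np.testing.assert_array_equal(back.best_params, model.best_params)
        assert back.arch == model.arch
        assert back.normalization == model.normalization

    def test_loaded_model_predicts_identically(self, tmp_path):
        table = generate(GeneratorConfig(n_molecules=40, rng_seed=3))
        model = train_from_table(table, tiny_config(iters=10))
        path = tmp_path / "model.json"
        model.save(path)
        back = TrainedModel.load(path)
        np.testing.assert_array_equal(back.predict_table(table), model.predict_table(table))

    def test_foreign_json_rejected(self, tmp_path):
        path = tmp_path / "not_model.json"
        path.write_text('{"hello": 1}')
        with pytest.raises(DataValidationError):
            TrainedModel.load(path)

    def test_predict_without_normalization_rejected(self):
        model = TrainedModel(
            arch=SMALL_ARCH,
            best_params=np.zeros(parameter_count(SMALL_ARCH)),
            training_trace=np.empty(0),
        )
        table = generate(GeneratorConfig(n_molecules=5, rng_seed=0))
        with pytest.raises(ConfigurationError):
            model.predict_table(table)
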