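"""Physics-informed loss, accuracy metric, training, sweep and fine-tuning."""

import numpy as np
import pytest

from spinepinn.dataset import TrainingDataset, split_and_normalize
from spinepinn.network import (
    NetConfig,
    PAPER_ARCHITECTURES,
    TrainedNet,
    TrainingDivergedError,
    accuracy,
    architecture_sweep,
    constraint_residuals,
    fine_tune,
    pinn_loss,
    pinn_loss_terms,
    train,
)


def _consistent_sample(E=2.0, nu=0.25, rho=1.0):
    k = E / (3 * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    return np.array([E, E, nu, nu, k, k, mu, mu, rho, rho])


class TestPinnLoss:
    def test_zero_at_consistent_perfect_prediction(self):
        y = _consistent_sample()[None, :]
        assert pinn_loss(y, y, lambda1=1.0, lambda2=1.0) == 0.0

    def test_lambda_zero_reduces_to_mse(self):
        rng = np.random.default_rng(0)
        pred = rng.normal(1.0, 0.2, size=(8, 10))
        target = rng.normal(1.0, 0.2, size=(8, 10))
        manual = np.mean(np.sum((pred - target) ** 2, axis=1))
        assert pinn_loss(pred, target, 0.0, 0.0) == pytest.approx(manual, rel=1e-15)

    def test_crafted_sample_against_manual_arithmetic(self):
        # E = 2, nu = 0.25 -> k = 4/3; bone bulk prediction off by +0.1,
        # everything else exact, lambda1 = 1, lambda2 = 0:
        #   data term:    0.1^2            = 0.01
        #   bulk penalty: |0.1| / 2 groups = 0.05
        target = _consistent_sample()[None, :]
        pred = target.copy()
        pred[0, 4] += 0.1
        terms = pinn_loss_terms(pred, target, lambda1=1.0, lambda2=0.0)
        assert terms["mse"] == pytest.approx(0.01, rel=1e-12)
        assert terms["pen_k"] == pytest.approx(0.05, rel=1e-12)
        assert terms["pen_mu"] == 0.0
        assert terms["total"] == pytest.approx(0.06, rel=1e-12)

    def test_decomposition_identity(self):
        rng = np.random.default_rng(1)
        pred = rng.normal(1.0, 0.3, size=(16, 10))
        target = rng.normal(1.0, 0.3, size=(16, 10))
        t = pinn_loss_terms(pred, target, 0.4, 0.7)
        assert t["total"] == t["mse"] + 0.4 * t["pen_k"] + 0.7 * t["pen_mu"]

    def test_nu_beyond_half_clamped_not_raised(self):
        pred = _consistent_sample()[None, :].copy()
        pred[0, 3] = 0.62  # disc Poisson beyond the incompressible limit
        t = pinn_loss_terms(pred, _consistent_sample()[None, :], 1.0, 1.0)
        assert np.isfinite(t["total"]) and t["n_nu_clamped"] == 1


class TestAccuracy:
    def test_perfect_prediction(self):
        y = np.full((5, 10), 3.0)
        assert accuracy(y, y) == 100.0

    def test_uniform_ten_percent_error(self):
        y = np.full((5, 10), 3.0)
        assert accuracy(1.1 * y, y) == pytest.approx(90.0, abs=1e-9)

    def test_matches_naive_loop(self):
        rng = np.random.default_rng(2)
        pred = rng.normal(5.0, 1.0, size=(7, 10))
        target = rng.normal(5.0, 1.0, size=(7, 10))
        total = 0.0
        for i in range(7):
            for j in range(10):
                total += max(0.0, 1.0 - abs(pred[i, j] - target[i, j]) / abs(target[i, j]))
        assert accuracy(pred, target) == pytest.approx(100 * total / 70, rel=1e-12)


def _tiny_dataset(dataset406, n=10):
    ds = TrainingDataset(X=dataset406.X[:n].copy(), Y=dataset406.Y[:n].copy())
    ds = split_and_normalize(ds, fractions=(0.8, 0.1, 0.1), seed=0)
    return ds


class TestTrain:
    def test_overfits_tiny_dataset(self, dataset406):
        ds = _tiny_dataset(dataset406)
        net = train(ds, NetConfig(hidden_layers=(64, 32), epochs=3000, patience=3000,
                                  learning_rate=3e-3, lambda1=0.0, lambda2=0.0, seed=0))
        assert net.accuracies["train"] > 99.0

    def test_deterministic_given_seed(self, dataset406):
        ds = _tiny_dataset(dataset406, n=40)
        cfg = NetConfig(hidden_layers=(16,), epochs=200, seed=3)
        a = train(ds, cfg)
        b = train(ds, cfg)
        X = ds.X[:5]
        assert np.array_equal(a.predict(X), b.predict(X))

    def test_divergence_aborts_with_diagnostics(self, dataset406):
        ds = _tiny_dataset(dataset406, n=40)
        with pytest.raises(TrainingDivergedError):
            train(ds, NetConfig(hidden_layers=(16,), epochs=80, learning_rate=1e100, seed=0))

    def test_requires_split_dataset(self, dataset406):
        raw = TrainingDataset(X=dataset406.X, Y=dataset406.Y)
        with pytest.raises(ValueError):
            train(raw, NetConfig())

    def test_checkpoint_roundtrip_bit_exact(self, tmp_path, trained_net, dataset406):
        p = tmp_path / "net.json"
        trained_net.save(p)
        back = TrainedNet.load(p)
        X = dataset406.X[:20]
        assert np.array_equal(back.predict(X), trained_net.predict(X))
        assert back.config == trained_net.config


class TestArchitectureSweep:
    def test_eleven_reference_architectures(self):
        assert len(PAPER_ARCHITECTURES) == 11
        assert PAPER_ARCHITECTURES[9] == (64, 32, 16)

    def test_single_case_equals_direct_training(self, dataset406):
        cfg = NetConfig(hidden_layers=(16,), epochs=300, seed=1)
        table = architecture_sweep(dataset406, cases=[cfg])
        net = train(dataset406, cfg)
        assert len(table) == 1
        assert table.loc[0, "train_accuracy"] == net.accuracies["train"]
        assert table.loc[0, "test_accuracy"] == net.accuracies["test"]

    def test_rows_independent_of_sweep_order(self, dataset406):
        cases = [
            NetConfig(hidden_layers=h, epochs=200, seed=2) for h in ((16,), (16, 8), (32,))
        ]
        fwd = architecture_sweep(dataset406, cases=cases)
        rev = architecture_sweep(dataset406, cases=cases[::-1])
        for col in ("train_accuracy", "val_accuracy", "test_accuracy"):
            assert sorted(fwd[col]) == sorted(rev[col])

    def test_failures_recorded_not_raised(self, dataset406):
        cases = [
            NetConfig(hidden_layers=(16,), epochs=60, learning_rate=1e100, seed=0),
            NetConfig(hidden_layers=(16,), epochs=60, seed=0),
        ]
        table = architecture_sweep(dataset406, cases=cases)
        assert table.loc[0, "error"] is not None
        assert table.loc[1, "error"] is None


class TestFineTune:
    def test_zero_learning_rate_is_identity(self, trained_net, calib672):
        tuned = fine_tune(trained_net, calib672, learning_rate=0.0, epochs=20)
        before = tuned.meta["accuracy_before"]
        for split in ("train", "val", "test"):
            assert tuned.accuracies[split] == pytest.approx(before[split], abs=1e-9)

    def test_schema_mismatch_rejected(self, trained_net, calib672):
        import dataclasses

        wrong = dataclasses.replace(
            calib672, feature_names=tuple(f"x{i}" for i in range(16))
        )
        with pytest.raises(ValueError):
            fine_tune(trained_net, wrong)

    def test_roundtrip_after_finetune(self, tmp_path, tuned_net, calib672):
        p = tmp_path / "tuned.json"
        tuned_net.save(p)
        back = TrainedNet.load(p)
        X = calib672.X[:10]
        assert np.array_equal(back.predict(X), tuned_net.predict(X))


class TestPhysicsPenaltySingleSeed:
    def test_penalty_reduces_constraint_residuals(self, dataset406):
        # single-seed version of the multi-seed ablation in the acceptance suite
        res = {}
        for lam in (0.1, 0.0):
            net = train(dataset406, NetConfig(epochs=3000, seed=0, lambda1=lam, lambda2=lam))
            X, _ = dataset406.split_arrays("train")
            r = constraint_residuals(net.predict(X))
            res[lam] = np.mean([r["k_bone"].mean(), r["k_disc"].mean()])
        assert res[0.1] <= res[0.0]
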