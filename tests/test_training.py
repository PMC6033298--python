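import numpy as np
import pytest

from histostep.nn import SmallCNN, cross_entropy_losses, softmax
from histostep.training import (
    ModelHandle,
    Stage,
    StageData,
    StageSchedule,
    mean_loss,
    run_stage,
    run_stepwise,
    swap_head,
)


def toy_dataset(n_per_class=12, n_classes=2, size=16, seed=0):
    """Brightness-separable patches: class i has mean intensity ~ (i+1)/(k+1)."""
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for cls in range(n_classes):
        level = (cls + 1) / (n_classes + 1)
        for _ in range(n_per_class):
            xs.append(np.clip(rng.normal(level, 0.05, (size, size, 3)), 0, 1))
            ys.append(cls)
    x = np.array(xs, dtype=np.float32)
    y = np.array(ys)
    order = rng.permutation(len(y))
    return x[order], y[order]


def make_stage(name="high", n_classes=2, epochs=5, seed=0, lr=0.05, data_seed=0):
    x, y = toy_dataset(n_classes=n_classes, seed=data_seed)
    xv, yv = toy_dataset(n_per_class=6, n_classes=n_classes, seed=data_seed + 1)
    return Stage(
        name=name,
        n_classes=n_classes,
        data=StageData(x, y, xv, yv),
        epochs=epochs,
        learning_rate=lr,
        batch_size=8,
        seed=seed,
    )


class TestMeanLoss:
    def test_all_zero(self):
        assert mean_loss([0.0, 0.0, 0.0]) == 0.0

    def test_simple_mean(self):
        assert mean_loss([0.5, 1.5]) == 1.0

    def test_matches_naive_sum_oracle(self):
        rng = np.random.default_rng(0)
        losses = rng.uniform(0, 5, 100)
        naive = 0.0
        for v in losses:
            naive += v
        naive /= len(losses)
        assert mean_loss(losses) == pytest.approx(naive, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mean_loss([])

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            mean_loss([0.5, -0.1])


class TestSmallCNN:
    def test_gradient_check(self):
        """Finite-difference check of the analytic backward pass (float64)."""
        rng = np.random.default_rng(0)
        net = SmallCNN(n_classes=2, seed=1)
        for key in net.params:
            net.params[key] = net.params[key].astype(np.float64)
        x = rng.uniform(0, 1, (2, 16, 16, 3))
        y = np.array([0, 1])

        def loss_fn():
            probs = softmax(net.forward(x))
            return float(cross_entropy_losses(probs, y).mean())

        cache = {}
        probs = softmax(net.forward(x, cache))
        dlogits = probs.copy()
        dlogits[np.arange(2), y] -= 1.0
        grads = net.backward(cache, dlogits / 2)

        eps = 1e-6
        for key in ("head_w", "conv0_w", "conv0_b", "conv1_w", "conv2_b"):
            param = net.params[key]
            idx = tuple(0 for _ in param.shape)
            orig = param[idx]
            param[idx] = orig + eps
            hi = loss_fn()
            param[idx] = orig - eps
            lo = loss_fn()
            param[idx] = orig
            numeric = (hi - lo) / (2 * eps)
            assert grads[key][idx] == pytest.approx(numeric, rel=1e-4, abs=1e-8)

    def test_forward_shapes(self):
        net = SmallCNN(n_classes=3, seed=0)
        out = net.forward(np.zeros((4, 32, 32, 3), dtype=np.float32))
        assert out.shape == (4, 3)


class TestSwapHead:
    def test_backbone_preserved_and_head_resized(self):
        model = ModelHandle.initialize(n_classes=3, seed=0)
        before = model.network.backbone_checksum()
        swapped = swap_head(model, 2, seed=1)
        assert swapped.n_classes == 2
        assert swapped.network.params["head_w"].shape[0] == 2
        assert swapped.network.backbone_checksum() == before

    def test_same_count_swap_not_noop(self):
        model = ModelHandle.initialize(n_classes=2, seed=0)
        swapped = swap_head(model, 2, seed=99)
        assert not np.array_equal(
            swapped.network.params["head_w"], model.network.params["head_w"]
        )

    def test_swap_determinism(self):
        model = ModelHandle.initialize(n_classes=3, seed=0)
        a = swap_head(model, 2, seed=5)
        b = swap_head(model, 2, seed=5)
        np.testing.assert_array_equal(
            a.network.params["head_w"], b.network.params["head_w"]
        )

    def test_small_class_count_rejected(self):
        model = ModelHandle.initialize(n_classes=2, seed=0)
        with pytest.raises(ValueError):
            swap_head(model, 1, seed=0)


class TestRunStage:
    def test_zero_epochs_unchanged(self):
        model = ModelHandle.initialize(n_classes=2, seed=0)
        before = {k: v.copy() for k, v in model.network.params.items()}
        out, log = run_stage(model, make_stage(epochs=0))
        for k in before:
            np.testing.assert_array_equal(out.network.params[k], before[k])
        assert log.epochs == []

    def test_loss_decreases_on_separable_toy(self):
        model = ModelHandle.initialize(n_classes=2, seed=0)
        _, log = run_stage(model, make_stage(epochs=20))
        assert log.epochs[-1].train_loss < log.epochs[0].train_loss

    def test_determinism(self):
        logs = []
        for _ in range(2):
            model = ModelHandle.initialize(n_classes=2, seed=3)
            _, log = run_stage(model, make_stage(epochs=4, seed=11))
            logs.append([e.train_loss for e in log.epochs])
        assert logs[0] == logs[1]

    def test_empty_dataset_rejected(self):
        model = ModelHandle.initialize(n_classes=2, seed=0)
        empty = Stage(
            name="high",
            n_classes=2,
            data=StageData(
                np.zeros((0, 16, 16, 3)), np.zeros(0, dtype=int),
                np.zeros((0, 16, 16, 3)), np.zeros(0, dtype=int),
            ),
            epochs=1,
        )
        with pytest.raises(ValueError):
            run_stage(model, empty)

    def test_selects_validation_best(self):
        model = ModelHandle.initialize(n_classes=2, seed=0)
        out, log = run_stage(model, make_stage(epochs=6))
        best_epoch = log.selected["high"]
        best = max(
            log.epochs, key=lambda e: (e.val_metric, -e.val_loss)
        )
        assert log.epochs[best_epoch].val_metric == best.val_metric


class TestRunStepwise:
    def test_single_stage_matches_run_stage(self):
        stage = make_stage(epochs=3, seed=2)
        schedule = StageSchedule(init_seed=1, stages=[stage])
        model_a, log_a = run_stepwise(schedule)
        model_b, log_b = run_stage(ModelHandle.initialize(2, seed=1), stage)
        np.testing.assert_array_equal(
            model_a.network.params["head_w"], model_b.network.params["head_w"]
        )
        assert [e.train_loss for e in log_a.epochs] == [e.train_loss for e in log_b.epochs]

    def test_two_stage_with_head_swap(self):
        medium = make_stage(name="medium", n_classes=3, epochs=2, data_seed=5)
        high = make_stage(name="high", n_classes=2, epochs=2, data_seed=6)
        schedule = StageSchedule(init_seed=0, stages=[medium, high])
        model, log = run_stepwise(schedule)
        assert model.n_classes == 2
        assert log.stage_boundaries == ["medium", "high"]
        assert log.head_swaps == [(3, 2)]

    def test_schedule_length_validation(self):
        with pytest.raises(ValueError):
            StageSchedule(init_seed=0, stages=[])
        with pytest.raises(ValueError):
            StageSchedule(init_seed=0, stages=[make_stage()] * 3)
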