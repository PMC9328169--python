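"""Composite loss, gradients, model construction, training mechanics."""

import numpy as np
import pytest

from qrstangle.core_geometry import DegenerateVectorError
from qrstangle.model_loss import (
    ArrayDataset,
    ModelConfig,
    TrainConfig,
    angle_loss,
    angles_between,
    build_model,
    composite_loss,
    composite_loss_and_grad,
    euclid_loss,
    load_model,
    predict_angle,
    save_model,
    train,
)

LEADS4 = ("I", "II", "aVF", "V2")


class TestEuclidLoss:
    def test_same_direction_different_magnitude_is_zero(self):
        assert euclid_loss(np.array([2.0, 0, 0]), np.array([5.0, 0, 0])) == pytest.approx(0.0)

    def test_antiparallel_unit_vectors_give_two(self):
        assert euclid_loss(np.array([1.0, 0, 0]), np.array([-1.0, 0, 0])) == pytest.approx(2.0)

    def test_orthogonal_gives_sqrt_two(self):
        assert euclid_loss(np.array([1.0, 0, 0]), np.array([0, 1.0, 0])) == pytest.approx(
            np.sqrt(2.0), abs=1e-4
        )

    def test_range_and_symmetry(self, rng):
        for _ in range(200):
            u, v = rng.normal(size=3), rng.normal(size=3)
            d = euclid_loss(u, v)
            assert 0.0 <= d <= 2.0
            assert euclid_loss(v, u) == pytest.approx(d)
            assert euclid_loss(3.7 * u, v) == pytest.approx(d, abs=1e-9)

    def test_zero_vector_degenerate(self):
        with pytest.raises(DegenerateVectorError):
            euclid_loss(np.zeros(3), np.ones(3))

    def test_batch_mean(self, rng):
        u = rng.normal(size=(5, 3))
        v = rng.normal(size=(5, 3))
        per = [euclid_loss(u[i], v[i]) for i in range(5)]
        assert euclid_loss(u, v) == pytest.approx(np.mean(per))


class TestAngleLoss:
    def test_identical_angles_zero(self):
        assert angle_loss(np.array([0.5, 1.2]), np.array([0.5, 1.2])) == 0.0

    def test_maximal_case(self):
        assert angle_loss(np.array([np.pi]), np.array([0.0])) == pytest.approx(np.pi)

    def test_batch_mean_absolute(self):
        assert angle_loss(np.array([0.5, 1.0]), np.array([0.7, 1.0])) == pytest.approx(0.1)


class TestCompositeLoss:
    def test_perfect_directions_zero_for_any_weights(self, rng):
        u_qrs = rng.normal(size=(4, 3))
        u_t = rng.normal(size=(4, 3))
        alpha = np.degrees(angles_between(u_qrs, u_t))
        for w1, w2 in [(0.8, 0.2), (1.0, 0.0), (0.5, 1.5)]:
            loss = composite_loss(u_qrs, u_t, alpha, 2.5 * u_qrs, 0.3 * u_t, w1, w2)
            assert loss == pytest.approx(0.0, abs=1e-9)

    def test_rotated_qrs_hand_computation(self):
        """u_T perfect, u_QRS off by 90 degrees: w1*sqrt(2) + w2*(pi/2)."""
        u_qrs = np.array([[1.0, 0, 0]])
        u_t = np.array([[0, 0, 1.0]])
        alpha = np.array([90.0])
        u_qrs_hat = np.array([[0, 1.0, 0]])  # 90 deg off; angle to u_t_hat stays 90
        loss = composite_loss(u_qrs, u_t, alpha, u_qrs_hat, u_t, 0.8, 0.2)
        assert loss == pytest.approx(0.8 * np.sqrt(2.0), abs=1e-9)
        # flipping the QRS prediction to -u_t makes the predicted angle 180
        # degrees: Ld = sqrt(2) still, and the angle term errs by pi/2
        loss2 = composite_loss(u_qrs, u_t, alpha, np.array([[0, 0, -1.0]]), u_t, 0.8, 0.2)
        assert loss2 == pytest.approx(0.8 * np.sqrt(2.0) + 0.2 * np.pi / 2, abs=1e-9)
        # antiparallel QRS prediction: Ld hits its printed extreme of 2 while
        # the predicted angle (90 degrees to u_t) happens to match the target
        loss3 = composite_loss(u_qrs, u_t, alpha, -u_qrs, u_t, 0.8, 0.2)
        assert loss3 == pytest.approx(0.8 * 2.0, abs=1e-9)

    def test_nonnegative(self, rng):
        for _ in range(100):
            uq, ut = rng.normal(size=(2, 3)), rng.normal(size=(2, 3))
            pq, pt = rng.normal(size=(2, 3)), rng.normal(size=(2, 3))
            alpha = np.degrees(angles_between(uq, ut))
            assert composite_loss(uq, ut, alpha, pq, pt, 0.8, 0.2) >= 0.0

    def test_gradient_matches_finite_differences(self, rng):
        """Analytic gradients within 1e-4 relative error of central differences."""
        uq, ut = rng.normal(size=(3, 3)), rng.normal(size=(3, 3))
        pq, pt = rng.normal(size=(3, 3)), rng.normal(size=(3, 3))
        alpha = rng.uniform(10, 170, 3)
        _, gq, gt = composite_loss_and_grad(uq, ut, alpha, pq, pt, 0.8, 0.2)
        eps = 1e-6
        for arr, grad in ((pq, gq), (pt, gt)):
            for i in range(3):
                for j in range(3):
                    arr[i, j] += eps
                    lp = composite_loss(uq, ut, alpha, pq, pt, 0.8, 0.2)
                    arr[i, j] -= 2 * eps
                    lm = composite_loss(uq, ut, alpha, pq, pt, 0.8, 0.2)
                    arr[i, j] += eps
                    numeric = (lp - lm) / (2 * eps)
                    assert abs(numeric - grad[i, j]) <= 1e-4 * max(abs(numeric), 1.0)


class TestModelConstruction:
    def test_emits_six_outputs(self, rng):
        model = build_model(ModelConfig(depth=3, initial_kernels=16, leads=LEADS4))
        out = model.forward(rng.normal(size=(2, 550, 4)), rng.random((2, 2)))
        assert out.shape == (2, 6)

    def test_zero_input_finite_output(self):
        model = build_model(ModelConfig(depth=2, initial_kernels=8, leads=("X", "Y", "Z")))
        out = model.forward(np.zeros((1, 550, 3)), np.zeros((1, 2)))
        assert np.all(np.isfinite(out))

    def test_parameter_count_deterministic(self):
        cfg = ModelConfig(depth=4, initial_kernels=8, leads=("X", "Y", "Z"))
        n1 = build_model(cfg, seed=0).n_parameters
        n2 = build_model(cfg, seed=99).n_parameters
        assert n1 == n2

    def test_depth_scales_parameters(self):
        small = build_model(ModelConfig(depth=2, initial_kernels=16, leads=LEADS4))
        large = build_model(ModelConfig(depth=5, initial_kernels=16, leads=LEADS4))
        assert large.n_parameters > small.n_parameters

    def test_too_few_kernels_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(depth=3, initial_kernels=2, leads=LEADS4)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(w1=0.0, w2=0.0)


class TestPredictAngle:
    def test_composition_with_spatial_angle(self, rng):
        model = build_model(ModelConfig(depth=2, initial_kernels=8, leads=LEADS4), seed=3)
        x = rng.normal(size=(3, 550, 4))
        meta = rng.random((3, 2))
        pairs = predict_angle(model, x, meta)
        out = model.forward(x, meta)
        for pair, row in zip(pairs, out):
            expected = np.degrees(angles_between(row[:3], row[3:]))[0]
            assert pair.alpha_hat == pytest.approx(expected)

    def test_batch_equals_per_record(self, rng):
        model = build_model(ModelConfig(depth=3, initial_kernels=8, leads=LEADS4), seed=3)
        x = rng.normal(size=(4, 550, 4))
        meta = rng.random((4, 2))
        batch = predict_angle(model, x, meta)
        single = [predict_angle(model, x[i : i + 1], meta[i : i + 1])[0] for i in range(4)]
        for b, s in zip(batch, single):
            assert b.alpha_hat == pytest.approx(s.alpha_hat, abs=1e-9)


class TestTraining:
    def test_lr_schedule_halves_every_twenty_epochs(self):
        tc = TrainConfig()
        assert tc.learning_rate(1) == pytest.approx(0.001)
        assert tc.learning_rate(20) == pytest.approx(0.001)
        assert tc.learning_rate(21) == pytest.approx(0.0005)
        assert tc.learning_rate(41) == pytest.approx(0.00025)

    def _toy_dataset(self, rng, n):
        """Inputs whose lead amplitudes encode the target directions."""
        uq = rng.normal(size=(n, 3))
        uq /= np.linalg.norm(uq, axis=1, keepdims=True)
        ut = rng.normal(size=(n, 3))
        ut /= np.linalg.norm(ut, axis=1, keepdims=True)
        x = np.zeros((n, 550, 4))
        pulse = np.exp(-((np.arange(30) - 15) ** 2) / 18.0)
        for i in range(n):
            for lead in range(3):
                x[i, 60:90, lead] = uq[i, lead] * pulse
                x[i, 200:230, lead] = ut[i, lead] * pulse
        alpha = np.degrees(angles_between(uq, ut))
        return ArrayDataset(x, rng.random((n, 2)), uq, ut, alpha)

    def test_loss_decreases_on_learnable_task(self):
        local = np.random.default_rng(7)
        tr = self._toy_dataset(local, 200)
        va = self._toy_dataset(local, 50)
        model = build_model(ModelConfig(depth=2, initial_kernels=8, leads=LEADS4), seed=0)
        hist = train(model, tr, va, TrainConfig(epochs=10, seed=0))
        assert hist["val_loss"].iloc[-1] < hist["val_loss"].iloc[0]
        assert list(hist["epoch"]) == list(range(1, 11))

    def test_degenerate_weighting_allowed(self, rng):
        tr = self._toy_dataset(rng, 32)
        model = build_model(
            ModelConfig(depth=2, initial_kernels=8, leads=LEADS4, w1=1.0, w2=0.0), seed=0
        )
        hist = train(model, tr, tr, TrainConfig(epochs=2, seed=0))
        assert np.isfinite(hist["train_loss"]).all()

    def test_empty_dataset_rejected(self, rng):
        ds = self._toy_dataset(rng, 4)
        empty = ArrayDataset(
            ds.x[:0], ds.meta[:0], ds.u_qrs[:0], ds.u_t[:0], ds.alpha_deg[:0]
        )
        model = build_model(ModelConfig(depth=2, initial_kernels=8, leads=LEADS4))
        with pytest.raises(ValueError):
            train(model, empty, ds, TrainConfig(epochs=1))


class TestCheckpoint:
    def test_save_load_round_trip(self, rng, tmp_path):
        model = build_model(ModelConfig(depth=3, initial_kernels=8, leads=LEADS4), seed=5)
        x = rng.normal(size=(2, 550, 4))
        meta = rng.random((2, 2))
        before = model.forward(x, meta)
        save_model(model, tmp_path / "ckpt")
        restored = load_model(tmp_path / "ckpt")
        after = restored.forward(x, meta)
        np.testing.assert_allclose(after, before, atol=1e-12)
        assert restored.config == model.config
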