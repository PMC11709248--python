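import numpy as np
import pytest

import ligandblob as lb
from ligandblob.errors import DegenerateBlobError, ValidationError
from ligandblob.models import (
    ModelConfig,
    TrainConfig,
    build_model,
    build_epoch_indices,
    evaluate_accuracy,
    predict_ligand,
    train_model,
)
from ligandblob.models.autodiff import Tensor
from ligandblob.point_sampling import PointCloud
from ligandblob.synthetic_data import _random_rotation

SMALL_MINK = dict(channels=(8, 16, 32), netvlad_clusters=4)


def random_cloud(rng, n=60, scale=3.0):
    pts = rng.normal(size=(n, 3)) * scale
    dens = rng.random(n) + 0.5
    return PointCloud(points=np.column_stack([pts, dens]))


class TestAutodiff:
    def test_gradients_match_finite_differences(self, rng):
        """Spot-check the autodiff core against central finite differences."""
        from ligandblob.models.autodiff import Parameter

        w = Parameter(rng.normal(size=(4, 3)))
        x = Tensor(rng.normal(size=(5, 4)))
        seg = np.array([0, 0, 1, 1, 2])

        def loss_value(wdata):
            wt = Parameter(wdata)
            y = (x @ wt).relu().segment_max(seg, 3)
            return (y.sum() * 2.0 + (x @ wt).sigmoid().mean()), wt

        base, wt = loss_value(w.data)
        base.backward()
        eps = 1e-6
        for idx in [(0, 0), (2, 1), (3, 2)]:
            wp = w.data.copy()
            wp[idx] += eps
            up, _ = loss_value(wp)
            wm = w.data.copy()
            wm[idx] -= eps
            dn, _ = loss_value(wm)
            num = (float(up.data) - float(dn.data)) / (2 * eps)
            assert num == pytest.approx(wt.grad[idx], abs=1e-5)


class TestForwardContract:
    @pytest.mark.parametrize("arch", ["riconvpp", "minkloc"])
    def test_softmax_normalization(self, rng, arch):
        model = build_model(ModelConfig(architecture=arch, n_classes=7, seed=0, **(SMALL_MINK if arch == "minkloc" else {})))
        res = predict_ligand(model, random_cloud(rng))
        assert res.class_scores.shape == (7,)
        assert res.class_scores.sum() == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("arch", ["riconvpp", "minkloc"])
    def test_zero_initialized_head_gives_uniform_scores(self, rng, arch):
        model = build_model(ModelConfig(architecture=arch, n_classes=5, seed=0, **(SMALL_MINK if arch == "minkloc" else {})))
        res = predict_ligand(model, random_cloud(rng))
        np.testing.assert_allclose(res.class_scores, 0.2, atol=1e-12)
        np.testing.assert_array_equal(res.ranked_labels, np.arange(5))

    @pytest.mark.parametrize("arch", ["riconvpp", "minkloc"])
    def test_inference_deterministic(self, rng, arch):
        model = _nontrivial_model(arch, rng)
        cloud = random_cloud(rng)
        a = predict_ligand(model, cloud).class_scores
        b = predict_ligand(model, cloud).class_scores
        np.testing.assert_array_equal(a, b)

    def test_ranking_is_descending_with_id_tiebreak(self, rng):
        model = _nontrivial_model("riconvpp", rng)
        res = predict_ligand(model, random_cloud(rng))
        s = res.class_scores[res.ranked_labels]
        assert np.all(np.diff(s) <= 1e-15)

    def test_empty_cloud_is_degenerate(self):
        model = build_model(ModelConfig(architecture="riconvpp", n_classes=3))
        with pytest.raises(DegenerateBlobError):
            predict_ligand(model, PointCloud(points=np.empty((0, 4))))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValidationError):
            ModelConfig(architecture="pointnet")
        with pytest.raises(ValidationError):
            ModelConfig(n_classes=1)


def _nontrivial_model(arch, rng, n_classes=5):
    model = build_model(ModelConfig(architecture=arch, n_classes=n_classes, seed=1, **(SMALL_MINK if arch == "minkloc" else {})))
    head = model.fc2 if arch == "riconvpp" else model.head
    head.w.data = rng.normal(0, 0.5, size=head.w.data.shape)
    return model


class TestInvariances:
    def test_riconv_rotation_invariance(self, rng):
        """Score drift under 20 random rotations of 10 random clouds < 1e-3."""
        model = _nontrivial_model("riconvpp", rng)
        drift = 0.0
        for _ in range(10):
            cloud = random_cloud(rng)
            base = predict_ligand(model, cloud).class_scores
            for _ in range(20):
                rot = _random_rotation(rng)
                rotated = PointCloud(
                    points=np.column_stack([cloud.coords @ rot.T, cloud.densities])
                )
                drift = max(
                    drift, np.abs(predict_ligand(model, rotated).class_scores - base).max()
                )
        assert drift < 1e-3

    @pytest.mark.parametrize("arch", ["riconvpp", "minkloc"])
    def test_permutation_invariance(self, rng, arch):
        model = _nontrivial_model(arch, rng)
        cloud = random_cloud(rng)
        base = predict_ligand(model, cloud).class_scores
        for _ in range(5):
            perm = rng.permutation(len(cloud))
            shuffled = PointCloud(points=cloud.points[perm])
            assert np.abs(predict_ligand(model, shuffled).class_scores - base).max() < 1e-5

    def test_minkloc_translation_invariance(self, rng):
        """Integer-quantum translations leave minkloc scores unchanged."""
        model = _nontrivial_model("minkloc", rng)
        q = model.cfg.quantization_size
        grid_pts = (rng.integers(0, 15, size=(70, 3)) + 0.5) * q
        grid_pts = np.unique(grid_pts, axis=0)
        dens = rng.random(len(grid_pts)) + 0.5
        cloud = PointCloud(points=np.column_stack([grid_pts, dens]))
        base = predict_ligand(model, cloud).class_scores
        for mult in ([1, 0, 0], [2, -3, 5], [-7, 4, 1]):
            moved = PointCloud(
                points=np.column_stack([grid_pts + np.asarray(mult) * q, dens])
            )
            assert np.abs(predict_ligand(model, moved).class_scores - base).max() < 1e-4


class TestTraining:
    def test_single_class_dataset_rejected(self, rng):
        ds = [(random_cloud(rng), 0) for _ in range(4)]
        model = build_model(ModelConfig(architecture="riconvpp", n_classes=2))
        with pytest.raises(ValidationError):
            train_model(model, ds, TrainConfig(epochs=1))

    def test_loss_decreases_over_first_epochs(self, shape_dataset_small):
        model = build_model(ModelConfig(architecture="riconvpp", n_classes=5, seed=0))
        _, history = train_model(
            model,
            shape_dataset_small,
            TrainConfig(learning_rate=1e-2, epochs=5, seed=0),
        )
        losses = [h["loss"] for h in history]
        assert losses[-1] < losses[0]

    def test_oversampling_balances_class_exposure(self, rng):
        """10:1 imbalance, oversampling: per-epoch exposure equal within 5%."""
        labels = np.array([0] * 200 + [1] * 20)
        idx = build_epoch_indices(labels, "oversample", rng)
        exposure = np.bincount(labels[idx])
        assert abs(exposure[0] - exposure[1]) / exposure.max() <= 0.05

    def test_undersampling_caps_majority(self, rng):
        labels = np.array([0] * 200 + [1] * 20)
        idx = build_epoch_indices(labels, "undersample", rng)
        exposure = np.bincount(labels[idx])
        assert exposure[0] == exposure[1] == 20

    def test_training_deterministic_given_seed(self, rng):
        ds = lb.make_shape_dataset(n_classes=2, n_per_class=6, seed=3)
        results = []
        for _ in range(2):
            model = build_model(ModelConfig(architecture="riconvpp", n_classes=2, seed=5))
            _, hist = train_model(model, ds, TrainConfig(epochs=2, seed=9))
            results.append([h["loss"] for h in hist])
        assert results[0] == results[1]

    def test_capacity_overfits_memorizable_clouds(self):
        """The sparse-voxel model reaches 100% training accuracy on 50
        memorizable clouds well within 200 epochs."""
        ds = lb.make_shape_dataset(n_classes=5, n_per_class=10, seed=21)
        model = build_model(
            ModelConfig(architecture="minkloc", n_classes=5, seed=0, quantization_size=0.4, **SMALL_MINK)
        )
        clouds = [c for c, _ in ds]
        labels = [l for _, l in ds]
        total = 0
        for _ in range(20):  # chunks of 10 epochs, 200 max
            model, _ = train_model(
                model,
                ds,
                TrainConfig(learning_rate=5e-3, epochs=10, seed=0, val_fraction=0.0),
            )
            total += 10
            if evaluate_accuracy(model, clouds, labels) == 1.0:
                break
        assert total <= 200
        assert evaluate_accuracy(model, clouds, labels) == 1.0

    def test_rotation_invariance_survives_training(self, rng):
        ds = lb.make_shape_dataset(n_classes=2, n_per_class=8, seed=13)
        model = build_model(ModelConfig(architecture="riconvpp", n_classes=2, seed=2))
        model, _ = train_model(model, ds, TrainConfig(epochs=2, seed=2))
        cloud = random_cloud(rng)
        base = predict_ligand(model, cloud).class_scores
        for _ in range(5):
            rot = _random_rotation(rng)
            rotated = PointCloud(points=np.column_stack([cloud.coords @ rot.T, cloud.densities]))
            assert np.abs(predict_ligand(model, rotated).class_scores - base).max() < 1e-3
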