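import numpy as np
import pytest

from hsipix.cnn import (
    Cnn2DSpec, Cnn3DSpec, TrainConfig, TrainedNetwork, build, predict_map,
    train,
)
from hsipix.patches import PatchSet


def _conv_out(n, f, s):
    return (n - f) // s + 1


def _patchset(rng, n=300, k=9, d=4, n_classes=3, separation=3.0):
    """Classes separated by channel means; trivially learnable."""
    labels = rng.integers(1, n_classes + 1, size=n)
    patches = rng.normal(size=(n, k, k, d)).astype(np.float32)
    for c in range(1, n_classes + 1):
        patches[labels == c, :, :, (c - 1) % d] += separation
    return PatchSet(patches=patches, centers=np.zeros((n, 2), int),
                    labels=labels.astype(np.int32), k=k, d=d)


class TestShapeArithmetic:
    def test_2d_reference_spec(self):
        spec = Cnn2DSpec(k=17, d=10, n_classes=4)
        rep = {r["layer"]: r for r in spec.shape_report()}
        assert rep["conv"]["shape"] == (7, 7, 20)
        assert rep["maxpool"]["shape"] == (3, 3, 20)
        assert rep["dropout"]["shape"] == (180,)
        assert rep["conv"]["params"] == 5 * 5 * 10 * 20 + 20  # 5020

    def test_3d_reference_spec(self):
        spec = Cnn3DSpec(k=7, n_bands=101, n_classes=4)
        rep = {r["layer"]: r for r in spec.shape_report()}
        assert rep["conv3d"]["shape"] == (5, 5, 92, 10)
        assert rep["batchnorm"]["params"] == 20

    def test_collapsing_layer_rejected_at_build(self):
        with pytest.raises(ValueError, match="conv"):
            build(Cnn2DSpec(k=3, d=2, n_classes=2, filter_size=5))
        with pytest.raises(ValueError, match="conv3d"):
            build(Cnn3DSpec(k=7, n_bands=8, n_classes=2, filter_spectral=10))

    def test_random_specs_match_floor_formula(self, rng):
        for _ in range(60):
            k = int(rng.integers(5, 25))
            f = int(rng.integers(2, min(k, 8)))
            s = int(rng.integers(1, 4))
            spec = Cnn2DSpec(k=k, d=3, n_classes=2, filter_size=f, stride=s,
                             pool_size=2, pool_stride=2)
            oh = _conv_out(k, f, s)
            if oh < 2:
                with pytest.raises(ValueError):
                    spec.shape_report()
                continue
            rep = {r["layer"]: r for r in spec.shape_report()}
            assert rep["conv"]["shape"][0] == oh
            assert rep["maxpool"]["shape"][0] == _conv_out(oh, 2, 2)


class TestTraining:
    def test_softmax_rows_sum_to_one(self, rng):
        ps = _patchset(rng, n=64)
        net = build(Cnn2DSpec(k=9, d=4, n_classes=3), seed=1)
        probs = net.predict_proba_patches(ps.patches)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_separable_patches_learned_quickly(self, rng):
        ps = _patchset(rng, n=400)
        net = build(Cnn2DSpec(k=9, d=4, n_classes=3), seed=2)
        cfg = TrainConfig(epochs=30, batch_size=128, seed=2)
        net = train(net, ps, cfg)
        acc = (net.predict_patches(ps.patches) == ps.labels).mean()
        assert acc >= 0.99

    def test_history_rises_then_flattens(self, rng):
        ps = _patchset(rng, n=400)
        net = build(Cnn2DSpec(k=9, d=4, n_classes=3), seed=3)
        net = train(net, ps, TrainConfig(epochs=24, batch_size=128, seed=3))
        accs = np.array(net.history["train_acc"])
        q = len(accs) // 4
        assert accs[-q:].mean() >= accs[:q].mean()

    def test_constant_zero_inputs_loss_stays_at_ln_c(self, rng):
        n, C = 200, 4
        ps = PatchSet(patches=np.zeros((n, 5, 5, 2), np.float32),
                      centers=np.zeros((n, 2), int),
                      labels=(np.arange(n) % C + 1).astype(np.int32), k=5, d=2)
        net = build(Cnn2DSpec(k=5, d=2, n_classes=C, filter_size=3, stride=1),
                    seed=0)
        net = train(net, ps, TrainConfig(epochs=10, batch_size=64, seed=0))
        losses = np.array(net.history["train_loss"])
        assert np.all(np.abs(losses - np.log(C)) < 0.01 * np.log(C) + 0.02)

    def test_training_deterministic_given_seed(self, rng):
        ps = _patchset(rng, n=200)
        outs = []
        for _ in range(2):
            net = build(Cnn2DSpec(k=9, d=4, n_classes=3), seed=11)
            net = train(net, ps, TrainConfig(epochs=5, batch_size=64, seed=11))
            outs.append({k: v.copy() for k, v in net.net.params().items()})
        for key in outs[0]:
            np.testing.assert_array_equal(outs[0][key], outs[1][key])

    def test_3d_network_trains_on_separable_patches(self, rng):
        labels = rng.integers(1, 3, size=240)
        patches = rng.normal(size=(240, 5, 5, 20)).astype(np.float32) * 0.3
        patches[labels == 1, :, :, :8] += 1.5
        patches[labels == 2, :, :, 12:] += 1.5
        ps = PatchSet(patches=patches, centers=np.zeros((240, 2), int),
                      labels=labels.astype(np.int32), k=5, d=20)
        spec = Cnn3DSpec(k=5, n_bands=20, n_classes=2, filter_spectral=5,
                         dropout=0.2)
        net = train(build(spec, seed=4), ps,
                    TrainConfig(epochs=30, batch_size=64, seed=4))
        acc = (net.predict_patches(ps.patches) == ps.labels).mean()
        assert acc >= 0.95

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_divergence_aborts_with_lr_hint(self, rng):
        ps = _patchset(rng, n=100, separation=50.0)
        net = build(Cnn2DSpec(k=9, d=4, n_classes=3), seed=5)
        with pytest.raises(RuntimeError, match="learning rate"):
            train(net, ps, TrainConfig(learning_rate=1e4, epochs=5,
                                       batch_size=64, seed=5))

    def test_background_labels_rejected(self, rng):
        ps = _patchset(rng, n=50)
        ps.labels[0] = 0
        net = build(Cnn2DSpec(k=9, d=4, n_classes=3), seed=0)
        with pytest.raises(ValueError, match="1..C"):
            train(net, ps, TrainConfig(epochs=1, seed=0))


class TestPredictMap:
    @pytest.fixture
    def trained(self, rng):
        ps = _patchset(rng, n=300, k=5, d=3, n_classes=2)
        net = build(Cnn2DSpec(k=5, d=3, n_classes=2, filter_size=3, stride=1),
                    seed=6)
        return train(net, ps, TrainConfig(epochs=15, batch_size=128, seed=6))

    def test_map_contract(self, trained, rng):
        stack = rng.normal(size=(12, 13, 3)).astype(np.float32)
        stack[:, :, 0] += 3.0   # everything looks like class 1
        mask = rng.random((12, 13)) > 0.3
        label, probs = predict_map(trained, stack, mask)
        assert np.all(label.labels[~mask] == 0)
        assert np.all(label.labels[mask] >= 1)
        np.testing.assert_allclose(probs[mask].sum(axis=1), 1.0, atol=1e-6)
        assert np.all(probs[~mask] == 0)

    def test_inference_deterministic(self, trained, rng):
        stack = rng.normal(size=(10, 10, 3)).astype(np.float32)
        mask = np.ones((10, 10), bool)
        l1, p1 = predict_map(trained, stack, mask)
        l2, p2 = predict_map(trained, stack, mask)
        np.testing.assert_array_equal(l1.labels, l2.labels)
        np.testing.assert_array_equal(p1, p2)

    def test_depth_mismatch_rejected(self, trained, rng):
        with pytest.raises(ValueError, match="depth"):
            predict_map(trained, rng.random((8, 8, 5)), np.ones((8, 8), bool))


class TestSerialization:
    def test_2d_roundtrip_identical_predictions(self, rng, tmp_path):
        ps = _patchset(rng, n=200)
        net = build(Cnn2DSpec(k=9, d=4, n_classes=3), seed=9)
        net = train(net, ps, TrainConfig(epochs=5, batch_size=64, seed=9))
        net.save(tmp_path / "net.npz")
        back = TrainedNetwork.load(tmp_path / "net.npz")
        np.testing.assert_array_equal(net.predict_patches(ps.patches),
                                      back.predict_patches(ps.patches))
        np.testing.assert_allclose(net.predict_proba_patches(ps.patches),
                                   back.predict_proba_patches(ps.patches),
                                   atol=0)

    def test_3d_roundtrip_preserves_bn_state(self, rng, tmp_path):
        labels = rng.integers(1, 3, size=120).astype(np.int32)
        patches = rng.normal(size=(120, 5, 5, 16)).astype(np.float32)
        patches[labels == 1, :, :, :6] += 1.0
        ps = PatchSet(patches=patches, centers=np.zeros((120, 2), int),
                      labels=labels, k=5, d=16)
        spec = Cnn3DSpec(k=5, n_bands=16, n_classes=2, filter_spectral=4)
        net = train(build(spec, seed=10), ps,
                    TrainConfig(epochs=4, batch_size=64, seed=10))
        net.save(tmp_path / "net3d.npz")
        back = TrainedNetwork.load(tmp_path / "net3d.npz")
        np.testing.assert_array_equal(back.net.run_mean, net.net.run_mean)
        np.testing.assert_allclose(net.predict_proba_patches(ps.patches),
                                   back.predict_proba_patches(ps.patches),
                                   atol=0)
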