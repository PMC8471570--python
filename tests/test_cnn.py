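"""Network construction, gradients, scaling, and training behavior."""

import numpy as np
import pytest
from scipy import ndimage

from scaffoldnet import (CNNConfig, ScaffoldPropertyCNN, build_model,
                         fit_scaler)
from scaffoldnet.errors import DegenerateScaleError, ShapeError
from scaffoldnet.nn import Adam, Conv3D, MaxPool3D, Network, mse_loss


def tiny_config(seed=0):
    return CNNConfig(input_shape=(8, 8, 4), conv_filters=(2, 3),
                     pools=((2, 2, 2), (2, 2, 1)), dense_units=(4, 3),
                     dropout_rate=0.0, seed=seed)


class TestArchitecture:
    def test_bottleneck_shapes(self):
        net = build_model(CNNConfig())
        spatial = [s[:3] for s in net.layer_shapes if len(s) == 4]
        # conv blocks: 32x32x20 -> 16x16x10 -> 8x8x5 -> 4x4x5
        assert (32, 32, 20) in spatial
        assert (16, 16, 10) in spatial
        assert (8, 8, 5) in spatial
        assert (4, 4, 5) in spatial
        assert net.layer_shapes[-1] == (3,)

    def test_forward_outputs_three_properties(self, rng):
        net = build_model(CNNConfig())
        x = rng.integers(0, 2, (1, 32, 32, 20)).astype(np.float32)
        assert net.forward(x).shape == (1, 3)

    def test_same_seed_same_initial_parameters(self):
        a, b = build_model(CNNConfig(seed=5)), build_model(CNNConfig(seed=5))
        for pa, pb in zip(a.parameters(), b.parameters()):
            assert np.array_equal(pa[0], pb[0])

    def test_indivisible_pooling_chain_rejected_at_build(self):
        with pytest.raises(ShapeError):
            build_model(CNNConfig(input_shape=(30, 30, 20)))

    def test_mismatched_input_shape_rejected(self, rng):
        net = build_model(CNNConfig())
        x = rng.integers(0, 2, (2, 16, 16, 20)).astype(np.float32)
        with pytest.raises(ShapeError):
            net.forward(x)

    def test_output_head_must_have_three_units(self):
        with pytest.raises(ValueError):
            CNNConfig(dense_units=(32, 64, 2))


class TestLayerOracles:
    def test_conv3d_matches_scipy_correlate(self, rng):
        """Same-padded convolution equals scipy's correlate per channel."""
        conv = Conv3D(2, 3, kernel=3, rng=np.random.default_rng(0))
        x = rng.normal(size=(2, 5, 6, 4, 2)).astype(np.float32)
        out = conv.forward(x)
        w = conv.w[0]
        for n in (0, 1):
            for f in (0, 2):
                expected = sum(
                    ndimage.correlate(x[n, :, :, :, c].astype(float),
                                      w[:, :, :, c, f].astype(float),
                                      mode="constant")
                    for c in (0, 1)) + conv.b[0][f]
                assert np.allclose(out[n, :, :, :, f], expected, atol=1e-4)

    def test_maxpool_matches_blockwise_max(self, rng):
        pool = MaxPool3D((2, 2, 1))
        x = rng.normal(size=(1, 4, 4, 3, 2)).astype(np.float32)
        out = pool.forward(x)
        for i in range(2):
            for j in range(2):
                for k in range(3):
                    block = x[0, 2 * i:2 * i + 2, 2 * j:2 * j + 2, k, :]
                    assert np.allclose(out[0, i, j, k], block.max(axis=(0, 1)))

    def test_gradients_match_finite_differences(self, rng):
        """End-to-end parameter gradients vs central differences."""
        net = Network(tiny_config(seed=3))
        x = rng.normal(0.5, 0.5, size=(3, 8, 8, 4)).astype(np.float32)
        y = rng.normal(0.5, 0.2, size=(3, 3)).astype(np.float32)

        def loss():
            return mse_loss(net.forward(x, training=False), y)[0]

        _, grad = mse_loss(net.forward(x, training=False), y)
        net.backward(grad)
        eps = 2e-3
        checked = 0
        for p in net.parameters():
            flat_v, flat_g = p[0].ravel(), p[1].ravel()
            for idx in rng.choice(flat_v.size, size=min(4, flat_v.size),
                                  replace=False):
                orig = flat_v[idx]
                flat_v[idx] = orig + eps
                hi = loss()
                flat_v[idx] = orig - eps
                lo = loss()
                flat_v[idx] = orig
                fd = (hi - lo) / (2 * eps)
                if abs(fd) > 1e-3 or abs(flat_g[idx]) > 1e-3:
                    assert flat_g[idx] == pytest.approx(fd, rel=0.05, abs=1e-3)
                    checked += 1
        assert checked > 10


class TestScaler:
    def test_maps_range_to_unit_interval(self):
        s = fit_scaler(np.array([[0.0, 0, 0], [50, 50, 50], [100, 100, 100]]))
        assert np.allclose(s.apply([[0, 50, 100]]), [[0, 0.5, 1.0]])

    def test_round_trip_identity(self, rng):
        y = rng.uniform(0, 100, (10, 3))
        s = fit_scaler(y)
        assert np.allclose(s.invert(s.apply(y)), y)

    def test_constant_column_rejected(self):
        y = np.array([[1.0, 5.0, 7.0], [2.0, 5.0, 9.0]])
        with pytest.raises(DegenerateScaleError):
            fit_scaler(y)


class TestTraining:
    @staticmethod
    def _dataset(n=20, seed=0, shape=(8, 8, 4)):
        rng = np.random.default_rng(seed)
        grids = rng.integers(0, 2, (n, *shape)).astype(np.uint8)
        labels = np.column_stack([
            100.0 * (1 - grids.reshape(n, -1).mean(axis=1)),
            rng.uniform(5, 90, n), rng.uniform(0, 40, n)])
        return grids, labels

    def test_split_is_70_30_for_20_untransformed(self):
        grids, labels = self._dataset(20)
        model = ScaffoldPropertyCNN(grids, labels, config=tiny_config())
        res = model.fit(epochs=1, seed=0)
        assert res.n_train == 14 and res.n_val == 6

    def test_same_seeds_identical_history(self):
        grids, labels = self._dataset(12)
        kw = dict(epochs=3, seed=4, split_seed=9)
        a = ScaffoldPropertyCNN(grids, labels, config=tiny_config()).fit(**kw)
        b = ScaffoldPropertyCNN(grids, labels, config=tiny_config()).fit(**kw)
        assert a.history.equals(b.history)

    def test_empty_validation_split_rejected(self):
        grids, labels = self._dataset(6)
        model = ScaffoldPropertyCNN(grids, labels, config=tiny_config())
        with pytest.raises(ValueError):
            model.fit(epochs=1, n_val=6)

    def test_memorizes_small_dataset(self):
        """With enough epochs the net drives train MSE toward zero on a
        handful of records (capacity sanity check) and predictions land
        near the labels."""
        grids, labels = self._dataset(5, seed=3)
        config = CNNConfig(input_shape=(8, 8, 4), conv_filters=(4, 8),
                           pools=((2, 2, 2), (2, 2, 1)), dense_units=(16, 3),
                           dropout_rate=0.0, seed=1)
        model = ScaffoldPropertyCNN(grids, labels, config=config)
        res = model.fit(epochs=300, batch_size=5, seed=1, n_val=0,
                        checkpoint="last")
        assert res.train_mse_scaled() < 0.01
        preds = res.predict(grids)
        assert np.abs(preds - labels).max() <= 8.0

    def test_prediction_order_and_shape(self, rng):
        grids, labels = self._dataset(8)
        model = ScaffoldPropertyCNN(grids, labels, config=tiny_config())
        res = model.fit(epochs=2, seed=0)
        batch = res.predict(grids)
        assert batch.shape == (8, 3)
        one = res.predict(grids[2])
        assert np.allclose(one, batch[2], atol=1e-5)
        assert (batch >= 0).all() and (batch <= 100).all()

    def test_leakage_free_split_holds_out_whole_sources(self):
        """With leakage_free=True no source lattice straddles the
        train/validation boundary."""
        from scaffoldnet import PropertyVector, build_strategy

        rng = np.random.default_rng(1)
        base = [(rng.integers(0, 2, (8, 8, 4)).astype(np.uint8),
                 PropertyVector(20.0 + 7 * i, 50.0 - 3 * i, 5.0 + i), f"s{i}")
                for i in range(5)]
        ds = build_strategy(base, 2, seed=0)
        from scaffoldnet.model import ScaffoldPropertyCNN as M
        model = M.from_dataset(ds, config=tiny_config())
        res = model.fit(epochs=1, seed=0, leakage_free=True)
        src = np.array([p.split("|")[0] for p in model.provenances])
        assert not (set(src[res.train_idx]) & set(src[res.val_idx]))
        assert res.n_val > 0 and res.n_train > 0

    def test_summary_mentions_key_facts(self):
        grids, labels = self._dataset(10)
        res = ScaffoldPropertyCNN(grids, labels, config=tiny_config()).fit(
            epochs=2, seed=0)
        text = res.summary()
        assert "train" in text and "MSE" in text and "porosity" in text
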