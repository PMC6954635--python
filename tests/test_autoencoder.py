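"""Multimodal autoencoder: contracts, gradients, training behaviour."""

import numpy as np
import pytest

from comascope.autoencoder import AutoencoderConfig, MultimodalAutoencoder


@pytest.fixture(scope="module")
def tiny_model():
    cfg = AutoencoderConfig.desk(embedding_dim=4, conv_filters=(2, 3, 3), seed=5, batch_size=4, epochs=2)
    return MultimodalAutoencoder(cfg, eeg_shape=(3, 9, 7), egt_shape=(8, 8))


@pytest.fixture(scope="module")
def small_data():
    rng = np.random.default_rng(0)
    eeg = rng.standard_normal((24, 15, 129, 50))
    egt = np.abs(rng.standard_normal((24, 64, 64))) * 1e-3
    return eeg, egt


class TestContracts:
    def test_embedding_length_is_32_by_default(self, small_data):
        eeg, egt = small_data
        model = MultimodalAutoencoder(AutoencoderConfig.desk(seed=1))
        z = model.encode(eeg[:3], egt[:3])
        assert z.shape == (3, 32)
        assert np.all(np.isfinite(z))

    def test_reconstruction_shapes_match_inputs(self, small_data):
        eeg, egt = small_data
        model = MultimodalAutoencoder(AutoencoderConfig.desk(seed=1))
        re, rg = model.reconstruct(eeg[:2], egt[:2])
        assert re.shape == (2, 15, 129, 50)
        assert rg.shape == (2, 64, 64)

    def test_seeded_init_is_reproducible(self):
        a = MultimodalAutoencoder(AutoencoderConfig.desk(seed=9), eeg_shape=(15, 129, 50))
        b = MultimodalAutoencoder(AutoencoderConfig.desk(seed=9), eeg_shape=(15, 129, 50))
        assert a.parameter_checksum() == b.parameter_checksum()
        c = MultimodalAutoencoder(AutoencoderConfig.desk(seed=10), eeg_shape=(15, 129, 50))
        assert a.parameter_checksum() != c.parameter_checksum()

    def test_encode_order_preserving_and_deterministic(self, small_data):
        eeg, egt = small_data
        model = MultimodalAutoencoder(AutoencoderConfig.desk(seed=2))
        z = model.encode(eeg[:6], egt[:6])
        # identical inputs give identical embeddings
        z_dup = model.encode(eeg[[0, 0]], egt[[0, 0]])
        np.testing.assert_array_equal(z_dup[0], z_dup[1])
        # repeated calls are bit-identical; batch size only moves the
        # result within float32 summation-order tolerance
        np.testing.assert_array_equal(z, model.encode(eeg[:6], egt[:6]))
        np.testing.assert_allclose(z[0], model.encode(eeg[:1], egt[:1])[0], atol=1e-5)

    def test_batched_equals_per_item(self, small_data):
        eeg, egt = small_data
        model = MultimodalAutoencoder(AutoencoderConfig.desk(seed=3))
        z_batch = model.encode(eeg, egt)
        z_single = np.vstack([model.encode(eeg[i : i + 1], egt[i : i + 1]) for i in range(len(eeg))])
        np.testing.assert_allclose(z_batch, z_single, atol=1e-5)

    def test_shape_mismatch_rejected(self, small_data):
        eeg, egt = small_data
        model = MultimodalAutoencoder(AutoencoderConfig.desk(seed=1))
        with pytest.raises(ValueError, match="incompatible"):
            model.encode(eeg[:, :, :64, :], egt)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            AutoencoderConfig(embedding_dim=0)
        with pytest.raises(ValueError):
            AutoencoderConfig(validation_fraction=1.5)
        with pytest.raises(ValueError):
            AutoencoderConfig(egt_loss_weight=-1.0)


class TestGradients:
    def test_backprop_matches_finite_differences(self, tiny_model):
        """Analytic gradients of the weighted two-head MSE agree with
        central finite differences (float64, biases moved off the ReLU
        kink where the derivative is undefined)."""
        cfg = AutoencoderConfig.desk(
            embedding_dim=4, conv_filters=(2, 3, 3), seed=5, batch_size=4, epochs=2, dtype="float64"
        )
        m = MultimodalAutoencoder(cfg, eeg_shape=(3, 9, 7), egt_shape=(8, 8))
        rng = np.random.default_rng(0)
        for layer in m._layers:
            for p in layer.parameters():
                if p.ndim == 1:
                    p += rng.standard_normal(p.shape) * 0.05
        x = rng.standard_normal((2, 3, 9, 7))
        g = rng.standard_normal((2, 8, 8))

        def loss():
            _, re, rg = m._forward(x, g)
            return m._losses(x, g, re, rg)[0]

        _, re, rg = m._forward(x, g)
        m._backward(
            2.0 * cfg.eeg_loss_weight * (re - x) / re.size,
            2.0 * cfg.egt_loss_weight * (rg - g[:, None]) / rg.size,
        )
        rs = np.random.default_rng(3)
        checked = 0
        for layer in m._layers:
            for p, grad in zip(layer.parameters(), layer.gradients()):
                for _ in range(5):
                    idx = tuple(rs.integers(0, s) for s in p.shape)
                    orig = p[idx]
                    eps = 1e-6
                    p[idx] = orig + eps
                    lp = loss()
                    p[idx] = orig - eps
                    lm = loss()
                    p[idx] = orig
                    fd = (lp - lm) / (2 * eps)
                    assert abs(fd - grad[idx]) <= 1e-4 * max(1.0, abs(fd)) + 1e-7
                    checked += 1
        assert checked >= 100


class TestTraining:
    def test_loss_is_weighted_sum_of_components(self, small_data):
        eeg, egt = small_data
        model = MultimodalAutoencoder(AutoencoderConfig.desk(seed=4))
        out = model.evaluate(eeg[:8], egt[:8])
        assert out["loss"] == pytest.approx(
            1.0 * out["eeg_mse"] + 100.0 * out["egt_mse"], abs=1e-5
        )

    def test_training_reduces_loss(self, small_data):
        eeg, egt = small_data
        model = MultimodalAutoencoder(AutoencoderConfig.desk(seed=5, epochs=8))
        history = model.fit(eeg, egt)
        rec = history.records
        assert rec["train_loss"].iloc[-1] < rec["train_loss"].iloc[0]
        assert rec["val_loss"].iloc[-1] < rec["val_loss"].iloc[0]

    def test_same_seed_same_final_loss(self, small_data):
        eeg, egt = small_data

        def run():
            m = MultimodalAutoencoder(AutoencoderConfig.desk(seed=6, epochs=3))
            return m.fit(eeg, egt).final["train_loss"]

        assert run() == pytest.approx(run(), rel=1e-9)

    def test_empty_dataset_rejected(self):
        model = MultimodalAutoencoder(AutoencoderConfig.desk(seed=1))
        with pytest.raises(ValueError, match="empty"):
            model.fit(np.empty((0, 15, 129, 50)), np.empty((0, 64, 64)))

    def test_trained_model_beats_untrained_on_validation(self, small_data):
        """Reconstruction property: training helps both output heads."""
        eeg, egt = small_data
        untrained = MultimodalAutoencoder(AutoencoderConfig.desk(seed=7))
        before = untrained.evaluate(eeg[20:], egt[20:])
        trained = MultimodalAutoencoder(AutoencoderConfig.desk(seed=7, epochs=10))
        trained.fit(eeg[:20], egt[:20])
        after = trained.evaluate(eeg[20:], egt[20:])
        assert after["eeg_mse"] < before["eeg_mse"]
        assert after["egt_mse"] < before["egt_mse"]
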