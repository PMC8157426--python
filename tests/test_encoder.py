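import numpy as np
import pytest
from scipy.stats import ortho_group

from contraclust import (
    AugmentConfig,
    EncoderConfig,
    TrainConfig,
    ValidationError,
    build_encoder,
    count_parameters,
    nt_xent_loss,
    preprocess,
    train,
)
from contraclust.encoder import ContrastiveEmbedding, cosine_lr

from oracles import brute_nt_xent


class TestEncoderConstruction:
    def test_forward_shape_default_architecture(self):
        model = build_encoder(EncoderConfig(500, [200, 40, 60]), seed=0)
        out = model.forward(np.random.default_rng(0).normal(size=(10, 500)))
        assert out.shape == (10, 60)

    def test_single_affine_layer(self):
        model = build_encoder(
            EncoderConfig(2, [3], norm_after_hidden=False), seed=0
        )
        assert model.forward(np.zeros((4, 2))).shape == (4, 3)
        assert len(model.layers) == 1

    def test_same_seed_same_initial_outputs(self):
        x = np.random.default_rng(1).normal(size=(6, 30))
        a = build_encoder(EncoderConfig(30, [10, 5]), seed=42).forward(x)
        b = build_encoder(EncoderConfig(30, [10, 5]), seed=42).forward(x)
        np.testing.assert_array_equal(a, b)

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValidationError):
            EncoderConfig(10, [5, 1])
        with pytest.raises(ValidationError):
            EncoderConfig(10, [2] * 9)


class TestParameterCount:
    def test_reference_architecture_footprint(self):
        """500 -> [200, 40, 60] with normalised hidden layers: 111,180 weights.

        Decomposition: 100,200 + 400 + 8,040 + 80 + 2,460.
        """
        cfg = EncoderConfig(500, [200, 40, 60], norm_after_hidden=True)
        assert count_parameters(cfg) == 111_180
        assert 500 * 200 + 200 == 100_200
        assert 2 * 200 == 400
        assert 200 * 40 + 40 == 8_040
        assert 2 * 40 == 80
        assert 40 * 60 + 60 == 2_460
        assert 100_200 + 400 + 8_040 + 80 + 2_460 == 111_180

    def test_counts_match_instantiated_model(self):
        for cfg in (
            EncoderConfig(2, [3], norm_after_hidden=False),
            EncoderConfig(500, [200, 40, 60], norm_after_hidden=False),
            EncoderConfig(500, [200, 40, 60], norm_after_hidden=True),
            EncoderConfig(77, [30, 11], norm_after_hidden=True),
        ):
            assert count_parameters(cfg) == build_encoder(cfg, 0).n_params()

    def test_small_cases(self):
        assert count_parameters(EncoderConfig(2, [3], norm_after_hidden=False)) == 9
        assert (
            count_parameters(EncoderConfig(500, [200, 40, 60], norm_after_hidden=False))
            == 110_700
        )


class TestNTXentLoss:
    def test_single_pair_has_zero_loss(self):
        z = np.random.default_rng(0).normal(size=(2, 7))
        assert nt_xent_loss(z, 0.5) == pytest.approx(0.0, abs=1e-12)

    def test_four_identical_rows_give_ln3(self):
        for tau in (0.1, 0.5, 1.0):
            z = np.tile(np.array([1.0, 2.0, -1.0]), (4, 1))
            assert nt_xent_loss(z, tau) == pytest.approx(np.log(3.0), abs=1e-12)

    def test_orthogonal_pairs_closed_form(self):
        # pairs (e1, e1), (e2, e2): loss = ln(1 + 2 e^{-1/tau})
        z = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.0, 1.0]])
        tau = 0.5
        expected = np.log(1.0 + 2.0 * np.exp(-1.0 / tau))
        assert nt_xent_loss(z, tau) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("tau", [0.1, 0.5, 1.0])
    def test_agrees_with_brute_force(self, tau):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n_pairs = int(rng.integers(2, 9))
            z = rng.normal(size=(2 * n_pairs, int(rng.integers(2, 6))))
            assert nt_xent_loss(z, tau) == pytest.approx(
                brute_nt_xent(z, tau), abs=1e-6
            )

    def test_rotation_invariance(self):
        rng = np.random.default_rng(12)
        z = rng.normal(size=(8, 5))
        rot = ortho_group.rvs(5, random_state=3)
        assert nt_xent_loss(z @ rot, 0.5) == pytest.approx(
            nt_xent_loss(z, 0.5), abs=1e-10
        )

    def test_row_rescaling_invariance(self):
        rng = np.random.default_rng(13)
        z = rng.normal(size=(6, 4))
        scaled = z.copy()
        scaled[2] *= 17.0
        assert nt_xent_loss(scaled, 0.5) == pytest.approx(
            nt_xent_loss(z, 0.5), abs=1e-10
        )

    def test_zero_row_rejected(self):
        z = np.array([[1.0, 0.0], [0.0, 0.0]])
        with pytest.raises(ValidationError):
            nt_xent_loss(z, 0.5)

    def test_small_temperature_is_stable(self):
        rng = np.random.default_rng(14)
        z = rng.normal(size=(8, 4))
        assert np.isfinite(nt_xent_loss(z, 0.01))


class TestCosineSchedule:
    def test_endpoints(self):
        assert cosine_lr(0.4, 0, 30) == pytest.approx(0.4)
        assert cosine_lr(0.4, 30, 30) == pytest.approx(0.0, abs=1e-15)
        assert cosine_lr(0.4, 15, 30) == pytest.approx(0.2)


class TestTraining:
    def test_history_length_and_embedding_shape(self, tiny_dataset):
        pm = preprocess(tiny_dataset.counts, None)
        emb, history = train(
            pm, tcfg=TrainConfig(epochs=5, batch_size=60, seed=0)
        )
        assert len(history) == 5
        assert emb.z.shape == (pm.n_cells, 60)

    def test_loss_decreases_on_structured_data(self, tiny_dataset):
        pm = preprocess(tiny_dataset.counts)
        deltas = []
        for seed in range(3):
            _, history = train(
                pm, tcfg=TrainConfig(epochs=10, batch_size=60, seed=seed)
            )
            deltas.append(history[-1] - history[0])
        assert np.mean(deltas) < 0

    def test_full_determinism_under_seed(self, tiny_dataset):
        pm = preprocess(tiny_dataset.counts)
        tcfg = TrainConfig(epochs=3, batch_size=60, seed=9)
        emb1, h1 = train(pm, tcfg=tcfg)
        emb2, h2 = train(pm, tcfg=tcfg)
        np.testing.assert_array_equal(emb1.z, emb2.z)
        assert h1 == h2

    def test_estimator_api(self, tiny_dataset):
        pm = preprocess(tiny_dataset.counts)
        est = ContrastiveEmbedding(epochs=3, batch_size=60, random_state=0)
        z = est.fit_transform(pm)
        assert z.shape == (pm.n_cells, 60)
        assert len(est.loss_history_) == 3
        # transform in eval mode reproduces the stored embedding
        np.testing.assert_allclose(est.transform(pm), z)
        params = est.get_params()
        assert params["mask_ratio"] == 0.9
        est.set_params(epochs=2)
        assert est.epochs == 2

    def test_too_few_cells_rejected(self):
        from contraclust.encoder import _as_preprocessed

        pm = _as_preprocessed(np.ones((3, 10)))
        with pytest.raises(ValidationError):
            train(pm)
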