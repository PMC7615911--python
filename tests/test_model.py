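"""Model contracts: condition embedding, posterior encoding,
reparameterisation, temporal rollout, decoding and the sequence loss."""

import logging

import numpy as np
import pytest
from scipy.integrate import quad

from cardio4d.model import (COND_VEC_DIM, EncoderPosterior, ModelConfig,
                            SequenceVAE, encode_condition_vector, kl_gaussian,
                            sequence_loss)
from cardio4d.phantom import AnatomySequence, ConditionSet


def _cond(**kw):
    base = dict(age_years=45.0, sex="female", weight=70.0, height=170.0,
                sbp=120.0)
    base.update(kw)
    return ConditionSet(**base)


class TestConditionEncoding:
    def test_vector_layout(self):
        v = encode_condition_vector(_cond())
        assert v.shape == (COND_VEC_DIM,) == (12,)
        assert v[:7].sum() == 1.0 and v[7:9].sum() == 1.0
        assert np.all((0 <= v) & (v <= 1))

    def test_out_of_range_clamped_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING, logger="cardio4d.model"):
            v = encode_condition_vector(_cond(weight=200.0))
        assert v[9] == 1.0
        assert any("clamped" in r.message for r in caplog.records)

    def test_embedding_deterministic_and_sized(self, tiny_model):
        c = _cond()
        z1 = tiny_model.embed_conditions(c)
        z2 = tiny_model.embed_conditions(c)
        np.testing.assert_array_equal(z1, z2)
        assert z1.shape == (tiny_model.config.latent_dim,)

    def test_default_latent_dimension_is_32(self):
        assert ModelConfig().latent_dim == 32
        assert ModelConfig().joint_dim == 64


class TestEncode:
    def test_posterior_shapes_and_determinism(self, tiny_model, tiny_cohort):
        seq, c = tiny_cohort[0]
        z_c = tiny_model.embed_conditions(c)
        p1 = tiny_model.encode(seq.labels[0], z_c)
        p2 = tiny_model.encode(seq.labels[0], z_c)
        L = tiny_model.config.latent_dim
        assert p1.mean.shape == p1.log_var.shape == (L,)
        np.testing.assert_array_equal(p1.mean, p2.mean)

    def test_all_background_input_finite(self, tiny_model):
        x0 = np.zeros(tiny_model.config.grid_shape, np.uint8)
        z_c = tiny_model.embed_conditions(_cond())
        p = tiny_model.encode(x0, z_c)
        assert np.all(np.isfinite(p.mean)) and np.all(np.isfinite(p.log_var))

    def test_wrong_grid_rejected(self, tiny_model):
        z_c = tiny_model.embed_conditions(_cond())
        with pytest.raises(ValueError):
            tiny_model.encode(np.zeros((8, 8, 8), np.uint8), z_c)

    def test_indivisible_grid_rejected_at_build(self):
        with pytest.raises(ValueError):
            ModelConfig(grid_shape=(24, 24, 12))


class TestReparameterize:
    P = EncoderPosterior(mean=np.array([1.0, -2.0]), log_var=np.array([0.0, np.log(4.0)]))

    def test_zero_noise_returns_mean(self):
        np.testing.assert_allclose(
            SequenceVAE.reparameterize(self.P, np.zeros(2)), self.P.mean)

    def test_unit_variance_adds_noise(self):
        e = np.array([0.5, -0.5])
        z = SequenceVAE.reparameterize(
            EncoderPosterior(mean=np.zeros(2), log_var=np.zeros(2)), e)
        np.testing.assert_allclose(z, e)

    def test_monte_carlo_mean_and_scale(self):
        rng = np.random.default_rng(0)
        zs = np.array([SequenceVAE.reparameterize(self.P, rng.standard_normal(2))
                       for _ in range(10_000)])
        np.testing.assert_allclose(zs.mean(axis=0), self.P.mean, atol=0.08)
        np.testing.assert_allclose(zs.std(axis=0), [1.0, 2.0], rtol=0.05)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            SequenceVAE.reparameterize(self.P, np.zeros(3))


class TestTemporalRollout:
    def test_first_element_is_input_and_t1(self, tiny_model):
        z0c = np.arange(tiny_model.config.joint_dim, dtype=np.float32) * 0.01
        out = tiny_model.temporal_rollout(z0c, 1)
        assert out.shape == (1, tiny_model.config.joint_dim)
        np.testing.assert_array_equal(out[0], z0c)
        with pytest.raises(ValueError):
            tiny_model.temporal_rollout(z0c, 0)

    def test_prefix_consistency(self, tiny_model):
        z0c = np.linspace(-1, 1, tiny_model.config.joint_dim).astype(np.float32)
        long = tiny_model.temporal_rollout(z0c, 10)
        short = tiny_model.temporal_rollout(z0c, 5)
        np.testing.assert_array_equal(long[:5], short)

    def test_parameter_count_independent_of_sequence_length(self):
        a = SequenceVAE(ModelConfig(grid_shape=(16, 16, 16), n_frames=5,
                                    latent_dim=8, encoder_channels=(2, 4, 8, 16),
                                    seed=1))
        b = SequenceVAE(ModelConfig(grid_shape=(16, 16, 16), n_frames=20,
                                    latent_dim=8, encoder_channels=(2, 4, 8, 16),
                                    seed=1))
        assert a.n_parameters() == b.n_parameters()
        assert (sum(p.data.size for p in a.parameter_groups()["temporal"])
                == sum(p.data.size for p in b.parameter_groups()["temporal"]))


class TestDecode:
    def test_probabilities_normalised(self, tiny_model):
        z = np.zeros(tiny_model.config.joint_dim, np.float32)
        probs = tiny_model.decode_frame(z)
        assert probs.shape == (4, *tiny_model.config.grid_shape)
        assert np.all(probs >= 0)
        np.testing.assert_allclose(probs.sum(axis=0), 1.0, atol=1e-5)

    def test_argmax_labels_valid(self, tiny_model):
        rng = np.random.default_rng(3)
        zs = rng.standard_normal((3, tiny_model.config.joint_dim)).astype(np.float32)
        labels = tiny_model.decode_labels(zs)
        assert labels.shape == (3, *tiny_model.config.grid_shape)
        assert set(np.unique(labels)) <= {0, 1, 2, 3}


class TestKLGaussian:
    def test_prior_equals_posterior(self):
        p = EncoderPosterior(mean=np.zeros(4), log_var=np.zeros(4))
        assert kl_gaussian(p) == 0.0

    def test_closed_form_unit_case(self):
        p = EncoderPosterior(mean=np.array([1.0]), log_var=np.array([0.0]))
        assert kl_gaussian(p) == pytest.approx(0.5)

    def test_matches_numerical_integration(self):
        mu, lv = 0.7, np.log(0.6)
        p = EncoderPosterior(mean=np.array([mu]), log_var=np.array([lv]))
        s = np.sqrt(np.exp(lv))

        def integrand(x):
            q = np.exp(-(x - mu) ** 2 / (2 * s ** 2)) / (s * np.sqrt(2 * np.pi))
            pr = np.exp(-x ** 2 / 2) / np.sqrt(2 * np.pi)
            return q * np.log(q / pr) if q > 0 else 0.0

        quad_kl, _ = quad(integrand, -12, 12)
        assert kl_gaussian(p) == pytest.approx(quad_kl, abs=1e-3)


class TestSequenceLoss:
    def _uniform_probs(self, shape):
        return np.full((4, *shape), 0.25)

    def test_hand_computed_uniform_toy(self):
        # 2 voxels, 2 frames, uniform probabilities: 2 * ln 4
        labels = np.array([[[[1, 2]]], [[[0, 3]]]], np.uint8)  # (2,1,1,2)
        seq = AnatomySequence(labels=labels, spacing=(1, 1, 1))
        probs = np.stack([self._uniform_probs((1, 1, 2))] * 2)
        p = EncoderPosterior(mean=np.zeros(2), log_var=np.zeros(2))
        assert sequence_loss(seq, probs, p, beta=0.001) == pytest.approx(
            2 * np.log(4.0))

    def test_perfect_fit_limit_is_zero(self):
        labels = np.array([[[[1, 2]]], [[[0, 3]]]], np.uint8)
        seq = AnatomySequence(labels=labels, spacing=(1, 1, 1))
        probs = np.zeros((2, 4, 1, 1, 2))
        for t in range(2):
            for v in range(2):
                probs[t, labels[t, 0, 0, v], 0, 0, v] = 1.0
        p = EncoderPosterior(mean=np.zeros(2), log_var=np.zeros(2))
        assert sequence_loss(seq, probs, p, beta=0.001) == 0.0

    def test_beta_zero_is_pure_reconstruction(self):
        labels = np.zeros((2, 1, 1, 2), np.uint8)
        seq = AnatomySequence(labels=labels, spacing=(1, 1, 1))
        probs = np.stack([self._uniform_probs((1, 1, 2))] * 2)
        p = EncoderPosterior(mean=np.ones(2), log_var=np.zeros(2))
        assert sequence_loss(seq, probs, p, beta=0.0) == pytest.approx(
            2 * np.log(4.0))
        assert sequence_loss(seq, probs, p, beta=1.0) == pytest.approx(
            2 * np.log(4.0) + 1.0)

    def test_frame_mismatch_rejected(self):
        labels = np.zeros((3, 1, 1, 2), np.uint8)
        seq = AnatomySequence(labels=labels, spacing=(1, 1, 1))
        probs = np.stack([self._uniform_probs((1, 1, 2))] * 2)
        p = EncoderPosterior(mean=np.zeros(2), log_var=np.zeros(2))
        with pytest.raises(ValueError):
            sequence_loss(seq, probs, p, beta=0.0)


class TestTrainingGraph:
    def test_gradients_finite_and_nonzero_for_every_group(self, tiny_model,
                                                          tiny_cohort):
        from cardio4d.model import encode_condition_vector as ecv
        labels = np.stack([s.labels for s, _ in tiny_cohort[:2]])
        cvecs = np.stack([ecv(c) for _, c in tiny_cohort[:2]])
        eps = np.random.default_rng(0).standard_normal(
            (2, tiny_model.config.latent_dim)).astype(np.float32)
        loss, _ = tiny_model.training_loss(labels, cvecs, eps)
        for p in tiny_model.parameters():
            p.grad = None
        loss.backward()
        for name, group in tiny_model.parameter_groups().items():
            norms = [np.abs(p.grad).sum() if p.grad is not None else 0.0
                     for p in group]
            assert np.all(np.isfinite(norms)), name
            assert sum(norms) > 0, f"group {name} received no gradient"

    def test_seeded_initialisation_reproducible(self, tiny_config):
        a = SequenceVAE(tiny_config)
        b = SequenceVAE(tiny_config)
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_posterior_collapses_as_beta_grows(self, tiny_cohort, tiny_config):
        """Larger beta pushes the posterior toward the prior: after a few
        identical optimisation steps the KL term is ordered by beta."""
        import dataclasses
        from cardio4d.model import encode_condition_vector as ecv
        from cardio4d.nn import Adam
        labels = np.stack([s.labels for s, _ in tiny_cohort[:4]])
        cvecs = np.stack([ecv(c) for _, c in tiny_cohort[:4]])
        kls = []
        for beta in (0.001, 0.1, 10.0):
            cfg = dataclasses.replace(tiny_config, beta=beta)
            model = SequenceVAE(cfg)
            opt = Adam(model.parameters(), lr=cfg.lr)
            rng = np.random.default_rng(5)
            diag = {}
            for _ in range(8):
                eps = rng.standard_normal((4, cfg.latent_dim)).astype(np.float32)
                loss, diag = model.training_loss(labels, cvecs, eps)
                opt.zero_grad()
                loss.backward()
                opt.step()
            kls.append(diag["kl"])
        assert kls[0] > kls[1] > kls[2]
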