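"""fwBCE loss algebra, backprop gradients, architecture, and training behavior."""

import numpy as np
import pytest

from claimwatch.autoencoder import (
    Autoencoder,
    AutoencoderArchitecture,
    LossConfig,
    ModelConfigError,
    TrainingConfig,
    bce_loss,
    build_autoencoder,
    fwbce_loss,
    load_checkpoint,
    loss_and_gradients,
    per_cpt_scores,
    reconstruct,
    save_checkpoint,
    train_autoencoder,
)
from claimwatch.feature_encoding import build_encoder_spec, encode_corpus
from conftest import make_claim, make_corpus, random_binary_batch, random_prob_batch

TINY_ARCH = AutoencoderArchitecture(
    input_dim=12, encoder_widths=(10, 8, 6), bottleneck_dim=4, decoder_widths=(6, 8, 10)
)


def reference_bce(y, p, n):
    """Independent evaluation of the printed BCE formula (sum over features,
    mean over the batch)."""
    y, p = np.atleast_2d(y), np.atleast_2d(p)
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).sum() / n)


class TestLossValues:
    def test_bce_hand_value(self):
        # y=[1,0], p=[0.5,0.5], N=1 -> 2 * (-log 0.5)
        assert bce_loss([[1, 0]], [[0.5, 0.5]]) == pytest.approx(1.3862943611, abs=1e-9)

    def test_fwbce_hand_value_w_half(self):
        # -(log 0.5 + 0.5 log 0.5)
        loss = fwbce_loss([[1, 0]], [[0.5, 0.5]], LossConfig(w=0.5))
        assert loss == pytest.approx(1.0397207708, abs=1e-9)

    def test_fwbce_hand_value_three_dims(self):
        # -(log 0.9 + 0.5 log 0.9 + 0.5 log 0.8)
        loss = fwbce_loss([[1, 0, 0]], [[0.9, 0.1, 0.2]], LossConfig(w=0.5))
        assert loss == pytest.approx(0.2696134, abs=1e-6)

    def test_perfect_reconstruction_loss_vanishes_as_clip_shrinks(self):
        losses = [
            fwbce_loss([[1.0]], [[1.0 - eps]], LossConfig(w=0.5, probability_clip=eps / 2))
            for eps in (1e-3, 1e-6, 1e-9)
        ]
        assert losses == sorted(losses, reverse=True)
        assert losses[-1] < 1e-8

    def test_normalization_divides_by_batch_size_only(self):
        # doubling the feature length doubles the loss; doubling the batch
        # with identical rows leaves it unchanged
        y, p = [[1, 0]], [[0.8, 0.3]]
        y2, p2 = [[1, 0, 1, 0]], [[0.8, 0.3, 0.8, 0.3]]
        assert fwbce_loss(y2, p2) == pytest.approx(2 * fwbce_loss(y, p))
        assert fwbce_loss([y[0], y[0]], [p[0], p[0]]) == pytest.approx(fwbce_loss(y, p))


class TestLossProperties:
    def test_w_one_equals_bce_reference_on_random_batches(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            y = random_binary_batch(rng, 4, 9)
            p = random_prob_batch(rng, 4, 9)
            ref = reference_bce(y, p, 4)
            got = fwbce_loss(y, p, LossConfig(w=1.0))
            assert got == pytest.approx(ref, rel=1e-12)

    def test_monotone_nondecreasing_in_w(self):
        rng = np.random.default_rng(1)
        y = random_binary_batch(rng, 6, 15)
        p = random_prob_batch(rng, 6, 15)
        losses = [fwbce_loss(y, p, LossConfig(w=w)) for w in (0.01, 0.1, 0.5, 0.9, 1.0)]
        assert losses == sorted(losses)

    def test_nonnegative(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            y = random_binary_batch(rng, 3, 7)
            p = random_prob_batch(rng, 3, 7)
            assert fwbce_loss(y, p, LossConfig(w=0.3)) >= 0.0

    def test_w_out_of_range_rejected(self):
        for w in (0.0, -0.1, 1.5):
            with pytest.raises(ModelConfigError):
                LossConfig(w=w)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ModelConfigError):
            fwbce_loss([[1, 0]], [[0.5]])


class TestGradients:
    def test_backprop_matches_central_finite_differences(self):
        """Analytic fwBCE gradients agree with finite differences to 1e-5."""
        model = build_autoencoder(TINY_ARCH, seed=3)
        rng = np.random.default_rng(4)
        # jitter biases off zero so no ReLU preactivation sits exactly on the
        # kink, where a central difference straddles the nondifferentiability
        for b in model.biases:
            b += rng.normal(0.0, 0.1, size=b.shape)
        X = random_binary_batch(rng, 5, 12)
        cfg = LossConfig(w=0.3)
        _, grad_w, grad_b = loss_and_gradients(model, X, cfg)

        h = 1e-6
        check_rng = np.random.default_rng(5)
        for k in range(model.n_layers):
            flat = model.weights[k].ravel()
            for idx in check_rng.choice(flat.size, size=min(8, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + h
                up = fwbce_loss(X, model.forward(X), cfg)
                flat[idx] = orig - h
                down = fwbce_loss(X, model.forward(X), cfg)
                flat[idx] = orig
                numeric = (up - down) / (2 * h)
                analytic = grad_w[k].ravel()[idx]
                assert analytic == pytest.approx(numeric, rel=1e-5, abs=1e-7)
            bias = model.biases[k]
            idx = int(check_rng.integers(bias.size))
            orig = bias[idx]
            bias[idx] = orig + h
            up = fwbce_loss(X, model.forward(X), cfg)
            bias[idx] = orig - h
            down = fwbce_loss(X, model.forward(X), cfg)
            bias[idx] = orig
            assert grad_b[k][idx] == pytest.approx((up - down) / (2 * h), rel=1e-5, abs=1e-7)


class TestArchitecture:
    def test_layer_stack_shapes(self):
        model = build_autoencoder(TINY_ARCH, seed=0)
        shapes = [w.shape for w in model.weights]
        assert shapes == [
            (12, 10), (10, 8), (8, 6), (6, 4), (4, 6), (6, 8), (8, 10), (10, 12),
        ]
        assert model.n_layers == 8  # seven hidden layers + output

    def test_default_taper_reproduces_reference_geometry(self):
        arch = AutoencoderArchitecture.for_input_dim(4835)
        assert arch.encoder_widths == (2048, 1024, 512)
        assert arch.bottleneck_dim == 128
        assert arch.decoder_widths == (512, 1024, 2048)

    def test_only_input_and_output_widths_change_with_feature_length(self):
        a = AutoencoderArchitecture(input_dim=4835)
        b = AutoencoderArchitecture(input_dim=6769)
        assert a.encoder_widths == b.encoder_widths
        assert a.bottleneck_dim == b.bottleneck_dim == 128
        assert (a.input_dim, b.input_dim) == (4835, 6769)

    def test_non_mirrored_decoder_rejected(self):
        with pytest.raises(ModelConfigError, match="mirror"):
            AutoencoderArchitecture(
                input_dim=12, encoder_widths=(10, 8, 6), bottleneck_dim=4,
                decoder_widths=(8, 6, 10),
            )

    def test_bottleneck_must_be_narrowest(self):
        with pytest.raises(ModelConfigError, match="bottleneck"):
            AutoencoderArchitecture(
                input_dim=12, encoder_widths=(10, 8, 6), bottleneck_dim=6,
                decoder_widths=(6, 8, 10),
            )

    def test_same_seed_gives_identical_initialization(self):
        m1 = build_autoencoder(TINY_ARCH, seed=9)
        m2 = build_autoencoder(TINY_ARCH, seed=9)
        m3 = build_autoencoder(TINY_ARCH, seed=10)
        assert all(np.array_equal(a, b) for a, b in zip(m1.weights, m2.weights))
        assert any(not np.array_equal(a, b) for a, b in zip(m1.weights, m3.weights))


class TestTraining:
    def test_single_repeated_claim_is_memorized(self):
        rng = np.random.default_rng(6)
        vec = np.zeros(12)
        vec[[1, 4, 9]] = 1.0
        X = np.tile(vec, (64, 1))
        model = build_autoencoder(TINY_ARCH, seed=7)
        train_autoencoder(
            model, X, LossConfig(w=0.1),
            TrainingConfig(batch_size=16, epochs=60, validation_fraction=0.0, seed=8),
        )
        probs = reconstruct(model, vec)
        assert (probs[0, [1, 4, 9]] > 0.5).all()

    def test_never_active_dimension_reconstructs_near_zero(self, small_world, small_corpus):
        """Dimensions all-zero during training keep near-zero probabilities —
        the mechanism behind out-of-sample outlier detection."""
        spec = build_encoder_spec(small_corpus, min_claims=2,
                                  reserved_cpts=small_world.reserved_cpts)
        enc = encode_corpus(small_corpus, spec)
        X = enc.matrix()
        reserved_dims = [spec.cpt_index[c] for c in small_world.reserved_cpts]
        assert X[:, reserved_dims].sum() == 0
        arch = AutoencoderArchitecture.for_input_dim(spec.feature_length)
        model = build_autoencoder(arch, seed=11)
        train_autoencoder(
            model, X, LossConfig(w=0.05),
            TrainingConfig(batch_size=64, epochs=40, seed=12),
        )
        probs = reconstruct(model, X[:100])
        assert probs[:, reserved_dims].mean() < 0.1

    def test_validation_checkpoint_has_best_loss(self, small_corpus):
        spec = build_encoder_spec(small_corpus, min_claims=2)
        X = encode_corpus(small_corpus, spec).matrix()
        model = build_autoencoder(
            AutoencoderArchitecture.for_input_dim(spec.feature_length), seed=13
        )
        history = train_autoencoder(
            model, X, LossConfig(w=0.05),
            TrainingConfig(batch_size=64, epochs=8, seed=14),
        )
        assert history.best_val_loss == min(history.val_loss)
        assert history.val_loss[history.best_epoch] == history.best_val_loss

    def test_training_is_seeded_and_reproducible(self, small_corpus):
        spec = build_encoder_spec(small_corpus, min_claims=2)
        X = encode_corpus(small_corpus, spec).matrix()
        arch = AutoencoderArchitecture.for_input_dim(spec.feature_length)
        losses = []
        for _ in range(2):
            model = build_autoencoder(arch, seed=15)
            h = train_autoencoder(model, X, LossConfig(w=0.05),
                                  TrainingConfig(batch_size=64, epochs=3, seed=16))
            losses.append(h.train_loss)
        assert losses[0] == losses[1]


@pytest.fixture(scope="module")
def tiny_model():
    return build_autoencoder(TINY_ARCH, seed=20)


class TestReconstructAndScores:

    def test_zero_vector_gives_finite_probabilities(self, tiny_model):
        probs = reconstruct(tiny_model, np.zeros(12))
        assert probs.shape == (1, 12)
        assert ((probs > 0) & (probs < 1)).all()

    def test_batch_shape_contract(self, tiny_model):
        rng = np.random.default_rng(21)
        probs = reconstruct(tiny_model, random_binary_batch(rng, 7, 12))
        assert probs.shape == (7, 12)

    def test_dimension_mismatch_rejected(self, tiny_model):
        with pytest.raises(ModelConfigError):
            reconstruct(tiny_model, np.zeros(13))

    def test_per_cpt_scores_select_active_dimensions(self, small_corpus):
        spec = build_encoder_spec(small_corpus, min_claims=1)
        enc = encode_corpus(small_corpus, spec)
        row = np.linspace(0.01, 0.99, spec.feature_length)
        claim = enc.claims[0]
        scores = per_cpt_scores(row, claim, spec)
        assert set(scores) == set(claim.active_cpt_codes(spec))
        for code, p in scores.items():
            assert p == pytest.approx(row[spec.cpt_index[code]])


class TestCheckpoint:
    def test_round_trip_preserves_parameters_and_outputs(self, tmp_path):
        model = build_autoencoder(TINY_ARCH, seed=30)
        save_checkpoint(model, tmp_path / "model.npz", LossConfig(w=0.05))
        back = load_checkpoint(tmp_path / "model.npz")
        assert back.architecture == model.architecture
        rng = np.random.default_rng(31)
        X = random_binary_batch(rng, 4, 12)
        assert np.array_equal(model.forward(X), back.forward(X))
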