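"""Network substrate: activations, losses, arch DSL, SGD training loop."""

import math

import numpy as np
import pytest

from cellcodes.network import (
    LayerSpec,
    NetworkSpec,
    TrainConfig,
    TrainedModel,
    TrainingDivergedError,
    activation,
    arch_string,
    cross_entropy_loss,
    forward,
    init_params,
    loss_and_grads,
    mse_loss,
    parse_arch,
    softmax,
    train,
)


class TestActivations:
    @pytest.mark.parametrize(
        "kind,x,expected",
        [
            ("relu", -2.0, 0.0),
            ("relu", 3.0, 3.0),
            ("sigmoid", 0.0, 0.5),
            ("logsigmoid", 0.0, math.log(0.5)),
            ("tanh", 0.0, 0.0),
            ("softplus", 0.0, math.log(2.0)),
        ],
    )
    def test_pointwise_formulas(self, kind, x, expected):
        assert activation(kind, np.array(x)) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "x,lam,expected", [(0.7, 0.5, 0.2), (0.3, 0.5, 0.0), (-0.8, 0.5, -0.3)]
    )
    def test_softshrink_piecewise(self, x, lam, expected):
        assert activation("softshrink", np.array(x), lam=lam) == pytest.approx(expected)

    def test_softmax_symmetry_and_sum(self):
        np.testing.assert_allclose(softmax(np.array([1.0, 1.0, 1.0])), np.ones(3) / 3)
        out = softmax(np.random.default_rng(0).normal(size=(7, 5)) * 100)
        np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-12)
        assert (out >= 0).all()

    def test_large_inputs_stay_finite(self):
        x = np.array([-500.0, 0.0, 500.0])
        for kind in ("sigmoid", "logsigmoid", "softplus", "softmax"):
            assert np.isfinite(activation(kind, x)).all()

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            activation("swish", np.zeros(3))


class TestLosses:
    @pytest.mark.parametrize(
        "pred,target,expected",
        [([1, 2], [1, 2], 0.0), ([0, 2], [0, 0], 2.0), ([1], [0], 1.0)],
    )
    def test_mse(self, pred, target, expected):
        assert mse_loss(np.array(pred, float), np.array(target, float)) == expected

    def test_mse_length_mismatch(self):
        with pytest.raises(ValueError):
            mse_loss(np.zeros(2), np.zeros(3))

    @pytest.mark.parametrize(
        "logits,c,expected",
        [
            ([0.0, 0.0, 0.0], 1, math.log(3.0)),
            ([10.0, 0.0], 0, math.log(1 + math.exp(-10))),
            ([0.0, 0.0], 0, math.log(2.0)),
        ],
    )
    def test_cross_entropy_closed_form(self, logits, c, expected):
        assert cross_entropy_loss(np.array(logits), c) == pytest.approx(
            expected, abs=1e-12
        )

    def test_cross_entropy_stable_and_nonnegative(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            logits = rng.uniform(-500, 500, size=6)
            v = cross_entropy_loss(logits, int(rng.integers(6)))
            assert np.isfinite(v) and v >= 0

    def test_cross_entropy_index_checked(self):
        with pytest.raises(IndexError):
            cross_entropy_loss(np.zeros(3), 3)


class TestParseArch:
    def test_fig_caption_example(self):
        layers = parse_arch("L300, G, L30", 1000)
        assert [l.kind for l in layers] == ["linear", "logsigmoid", "linear"]
        assert (layers[0].in_size, layers[0].out_size) == (1000, 300)
        assert (layers[2].in_size, layers[2].out_size) == (300, 30)

    def test_single_linear(self):
        (l,) = parse_arch("L30", 1000)
        assert (l.in_size, l.out_size) == (1000, 30)

    def test_leading_activation(self):
        layers = parse_arch("G, L30", 1000)
        assert layers[0].kind == "logsigmoid"
        assert (layers[1].in_size, layers[1].out_size) == (1000, 30)

    def test_softshrink_token_carries_lambda(self):
        layers = parse_arch("L10, SH0.25, L5", 20)
        assert layers[1].kind == "softshrink" and layers[1].lam == 0.25

    def test_round_trip_through_arch_string(self):
        text = "L300, G, L100, SM, SH0.5, L30"
        assert arch_string(parse_arch(text, 1000)) == text

    @pytest.mark.parametrize("bad", ["LX", "Q", "L30, Z10", "L-5", ""])
    def test_malformed_tokens_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_arch(bad, 100)


class TestNetworkSpec:
    def test_symmetric_decoder_mirrors_sizes(self):
        spec = NetworkSpec.symmetric(parse_arch("L300, G, L30", 1000))
        assert spec.code_size == 30
        dec = spec.decoder
        assert [l.kind for l in dec] == ["linear", "logsigmoid", "linear"]
        assert (dec[0].in_size, dec[0].out_size) == (30, 300)
        assert (dec[2].in_size, dec[2].out_size) == (300, 1000)

    def test_code_size_consistency_enforced(self):
        enc = parse_arch("L10", 20)
        dec = parse_arch("L20", 11)  # wrong input width
        with pytest.raises(ValueError, match="decoder input"):
            NetworkSpec(encoder=enc, decoder=dec, code_size=10)

    def test_classifier_must_end_with_softmax(self):
        enc = parse_arch("L10", 20)
        with pytest.raises(ValueError, match="softmax"):
            NetworkSpec.symmetric(enc, classifier=parse_arch("L4", 10))


class TestGradients:
    def _numeric_check(self, spec, x, label=None):
        rng = np.random.default_rng(0)
        enc = init_params(spec.encoder, rng)
        dec = init_params(spec.decoder, rng)
        cls = init_params(spec.classifier, rng) if spec.classifier else None
        _, ge, gd, gc = loss_and_grads(spec, enc, dec, cls, x, label=label)
        eps = 1e-6

        def check(params, grads):
            worst = 0.0
            for p, g in zip(params, grads):
                if p is None:
                    continue
                for arr, garr in zip(p, g):
                    flat = arr.ravel()
                    gflat = np.asarray(garr).ravel()
                    for i in range(flat.size):
                        old = flat[i]
                        flat[i] = old + eps
                        lp, *_ = loss_and_grads(spec, enc, dec, cls, x, label=label)
                        flat[i] = old - eps
                        lm, *_ = loss_and_grads(spec, enc, dec, cls, x, label=label)
                        flat[i] = old
                        num = (lp - lm) / (2 * eps)
                        denom = max(1e-8, abs(num) + abs(gflat[i]))
                        worst = max(worst, abs(num - gflat[i]) / denom)
            return worst

        assert check(enc, ge) < 1e-4
        assert check(dec, gd) < 1e-4
        if cls is not None:
            assert check(cls, gc) < 1e-4

    def test_autoencoder_gradients_5_4_5(self):
        """Finite differences match analytic gradients on a 5-4-5 net."""
        spec = NetworkSpec.symmetric(parse_arch("L4, G, L4", 5))
        self._numeric_check(spec, np.random.default_rng(7).normal(size=5))

    def test_classifier_autoencoder_gradients(self):
        spec = NetworkSpec.symmetric(
            parse_arch("L4", 5),
            classifier=(
                LayerSpec("linear", in_size=4, out_size=3),
                LayerSpec("softmax"),
            ),
        )
        self._numeric_check(spec, np.random.default_rng(8).normal(size=5), label=2)

    def test_gradients_through_each_activation(self):
        for act in ("R", "S", "T", "SP", "SH0.3", "SM"):
            spec = NetworkSpec.symmetric(parse_arch(f"L4, {act}, L3", 5))
            x = np.random.default_rng(9).normal(size=5)
            self._numeric_check(spec, x)


class TestTraining:
    def test_zero_epochs_rejected(self):
        with pytest.raises(ValueError, match="epochs"):
            TrainConfig(epochs=0)

    def test_rank1_data_learned_to_near_zero_mse(self):
        """A 1-code linear autoencoder represents rank-1 data exactly; SGD
        should find it (PCA-1 floor is ~0)."""
        rng = np.random.default_rng(5)
        u = rng.normal(size=6)
        X = np.outer(rng.uniform(1, 2, size=30), u)
        spec = NetworkSpec.symmetric(parse_arch("L1", 6))
        model = train(
            spec,
            X,
            cfg=TrainConfig(learning_rate=0.05, epochs=150, iterations_per_epoch=1, seed=0),
        )
        assert model.training_log[-1]["train_mse"] < 1e-3

    def test_same_seed_identical_log(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(12, 8))
        spec = NetworkSpec.symmetric(parse_arch("L3", 8))
        cfg = TrainConfig(learning_rate=0.01, epochs=4, iterations_per_epoch=2, seed=42)
        log1 = train(spec, X, cfg=cfg).training_log
        log2 = train(spec, X, cfg=cfg).training_log
        assert log1 == log2

    def test_training_loss_decreases_on_toy_problem(self):
        rng = np.random.default_rng(7)
        X = np.outer(rng.uniform(1, 2, size=25), rng.normal(size=5))
        spec = NetworkSpec.symmetric(parse_arch("L1", 5))
        log = train(
            spec,
            X,
            cfg=TrainConfig(learning_rate=0.03, epochs=40, iterations_per_epoch=1, seed=1),
        ).training_log
        losses = [e["train_mse"] for e in log]
        assert losses[-1] < losses[0]
        # non-increasing within tolerance epoch to epoch (per-sample SGD
        # fluctuates a little around the descent trend)
        assert all(b <= a * 1.10 + 1e-9 for a, b in zip(losses, losses[1:]))

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_divergence_reported_with_epoch(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(10, 6)) * 100
        spec = NetworkSpec.symmetric(parse_arch("L2", 6))
        with pytest.raises(TrainingDivergedError, match="epoch"):
            train(spec, X, cfg=TrainConfig(learning_rate=5.0, epochs=3))

    def test_labels_required_iff_classifier(self):
        X = np.zeros((4, 5))
        plain = NetworkSpec.symmetric(parse_arch("L2", 5))
        with pytest.raises(ValueError, match="no classifier"):
            train(plain, X, labels=np.zeros(4, int), cfg=TrainConfig(epochs=1))
        withcls = NetworkSpec.symmetric(
            parse_arch("L2", 5),
            classifier=(
                LayerSpec("linear", in_size=2, out_size=2),
                LayerSpec("softmax"),
            ),
        )
        with pytest.raises(ValueError, match="labels are required"):
            train(withcls, X, cfg=TrainConfig(epochs=1))

    def test_denoising_targets_stay_clean(self):
        """With input noise on, the model trained on constant data should
        map noisy inputs near the clean constant target."""
        X = np.full((20, 4), 0.5)
        spec = NetworkSpec.symmetric(parse_arch("L2", 4))
        model = train(
            spec,
            X,
            cfg=TrainConfig(
                learning_rate=0.1, epochs=30, iterations_per_epoch=2,
                input_noise_sd=0.1, seed=3,
            ),
        )
        out = model.decode_array(model.encode_array(np.full(4, 0.5)))
        np.testing.assert_allclose(out, 0.5, atol=0.05)

    def test_centering_round_trip(self):
        rng = np.random.default_rng(9)
        X = rng.normal(8.0, 1.0, size=(15, 6))
        spec = NetworkSpec.symmetric(parse_arch("L3", 6))
        model = train(
            spec, X, cfg=TrainConfig(learning_rate=0.05, epochs=10), center=True
        )
        np.testing.assert_allclose(model.input_offset, X.mean(axis=0))
        # decode(encode) output lives on the original (uncentered) scale
        rec = model.decode_array(model.encode_array(X))
        assert abs(rec.mean() - X.mean()) < 1.0

    def test_save_load_round_trip(self, tmp_path):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(10, 6))
        spec = NetworkSpec.symmetric(parse_arch("L4, G, L2", 6))
        model = train(
            spec, X, cfg=TrainConfig(learning_rate=0.01, epochs=2), center=True
        )
        path = tmp_path / "model.npz"
        model.save(path)
        back = TrainedModel.load(path)
        np.testing.assert_allclose(
            back.encode_array(X), model.encode_array(X), atol=1e-12
        )
        assert back.training_log == model.training_log
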