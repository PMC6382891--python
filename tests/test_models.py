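"""Architectures, encode/decode/classify and the Model/Results API."""

import numpy as np
import pytest

import cellcodes as cc
from cellcodes.models import (
    CICAutoencoder,
    CICMatrix,
    ClassifierAutoencoder,
    candidate_architectures,
    classifier_autoencoder,
    classify,
    decode,
    encode,
    selected_architecture,
)
from cellcodes.network import LayerSpec, NetworkSpec, TrainedModel, init_params, parse_arch


class TestSelectedArchitecture:
    def test_reference_scale_sizes(self):
        spec = selected_architecture(20184, 30)
        enc = spec.encoder
        assert (enc[0].in_size, enc[0].out_size) == (20184, 2000)
        assert enc[1].kind == "logsigmoid"
        assert (enc[2].in_size, enc[2].out_size) == (2000, 30)
        dec = spec.decoder
        assert (dec[0].in_size, dec[0].out_size) == (30, 2000)
        assert (dec[2].in_size, dec[2].out_size) == (2000, 20184)

    def test_hidden_override(self):
        spec = selected_architecture(1000, 30, hidden=300)
        assert spec.encoder[0].out_size == 300

    def test_proportional_hidden_default(self):
        assert selected_architecture(2000, 30).encoder[0].out_size == 200

    def test_code_not_smaller_than_hidden_rejected(self):
        with pytest.raises(ValueError, match="hidden"):
            selected_architecture(20184, code_size=2000, hidden=2000)


class TestCandidateRoster:
    def test_ten_candidates(self):
        roster = candidate_architectures(1000)
        assert len(roster) == 10

    def test_all_bottlenecks_are_30(self):
        for spec in candidate_architectures(1000).values():
            assert spec.code_size == 30

    def test_decoders_mirror_encoders(self):
        for spec in candidate_architectures(1000).values():
            enc_lin = [l for l in spec.encoder if l.kind == "linear"]
            dec_lin = [l for l in spec.decoder if l.kind == "linear"]
            assert [(l.out_size, l.in_size) for l in enc_lin] == [
                (l.in_size, l.out_size) for l in reversed(dec_lin)
            ]

    def test_includes_named_fig_architectures(self):
        from cellcodes.network import arch_string

        texts = {
            arch_string(s.encoder) for s in candidate_architectures(1000).values()
        }
        assert "L300, G, L30" in texts
        assert "L300, SM, L30" in texts
        assert "L300, G, L100, L30" in texts


class TestClassifierArchitecture:
    def test_minimal_classifier_branch(self):
        spec = classifier_autoencoder(1000, 30, 16, hidden_classifier=None)
        assert [l.kind for l in spec.classifier] == ["linear", "softmax"]
        assert spec.classifier[0].out_size == 16

    def test_hidden_classifier_branch_chains(self):
        spec = classifier_autoencoder(1000, 30, 16, hidden_classifier=20)
        kinds = [l.kind for l in spec.classifier]
        assert kinds == ["linear", "logsigmoid", "linear", "softmax"]
        assert spec.classifier[0].out_size == 20
        assert spec.classifier[2].in_size == 20
        assert spec.classifier[2].out_size == 16

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="n_classes"):
            classifier_autoencoder(1000, 30, 1)


def _random_model(spec, seed=0):
    rng = np.random.default_rng(seed)
    return TrainedModel(
        spec=spec,
        encoder_params=init_params(spec.encoder, rng),
        decoder_params=init_params(spec.decoder, rng),
        classifier_params=(
            init_params(spec.classifier, rng) if spec.classifier else None
        ),
    )


class TestEncodeDecode:
    def _matrix(self, rng, genes=50, samples=7):
        return cc.ExpressionMatrix(
            rng.normal(8, 1, size=(genes, samples)),
            [f"g{i}" for i in range(genes)],
            [f"s{j}" for j in range(samples)],
        )

    def test_codes_shape_and_determinism(self, rng):
        spec = selected_architecture(50, 5, hidden=20)
        model = _random_model(spec)
        m = self._matrix(rng)
        cic = encode(model, m)
        assert cic.codes.shape == (7, 5)
        cic2 = encode(model, m)
        np.testing.assert_array_equal(cic.codes, cic2.codes)

    def test_identical_samples_identical_codes(self, rng):
        spec = selected_architecture(50, 5, hidden=20)
        model = _random_model(spec)
        col = rng.normal(8, 1, size=(50, 1))
        m = cc.ExpressionMatrix(np.tile(col, (1, 3)), [f"g{i}" for i in range(50)], list("abc"))
        cic = encode(model, m)
        assert np.ptp(cic.codes, axis=0).max() == pytest.approx(0.0)

    def test_gene_count_mismatch_rejected(self, rng):
        spec = selected_architecture(50, 5, hidden=20)
        model = _random_model(spec)
        with pytest.raises(ValueError, match="genes"):
            encode(model, self._matrix(rng, genes=49))

    def test_zero_weight_decoder_outputs_bias(self):
        spec = selected_architecture(50, 5, hidden=20)
        model = _random_model(spec)
        for i, p in enumerate(model.decoder_params):
            if p is not None:
                model.decoder_params[i] = (np.zeros_like(p[0]), p[1])
        out1 = model.decode_array(np.zeros(5))
        out2 = model.decode_array(np.ones(5) * 7)
        np.testing.assert_allclose(out1, out2)

    def test_wrong_code_width_rejected(self):
        spec = selected_architecture(50, 30, hidden=40)
        model = _random_model(spec)
        with pytest.raises(ValueError, match="code width"):
            model.decode_array(np.zeros(29))

    def test_classify_requires_branch(self, rng):
        spec = selected_architecture(50, 5, hidden=20)
        with pytest.raises(ValueError, match="classifier"):
            classify(_random_model(spec), self._matrix(rng))

    def test_classify_probabilities_sum_to_one(self, rng):
        spec = classifier_autoencoder(50, 5, n_classes=4, hidden=20)
        model = _random_model(spec)
        probs, pred = classify(model, self._matrix(rng))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert set(pred) <= set(probs.columns)


class TestModelResultsAPI:
    @pytest.fixture(scope="class")
    def fitted(self, tmp_path_factory):
        design = cc.SyntheticDesign(
            n_genes=120, n_types=3, samples_per_type=10, n_modules=5,
            n_conditions_per_type=5, noise_sd=0.1, seed=2,
        )
        m, ann, _ = cc.generate(design)
        model = CICAutoencoder(m, arch="selected", code_size=5, hidden=24)
        res = model.fit(learning_rate=0.3, epochs=8, iterations_per_epoch=2, seed=0)
        return m, res

    def test_training_log_length_matches_epochs(self, fitted):
        _, res = fitted
        assert len(res.training_log) == 8

    def test_reconstruct_shapes_and_purity(self, fitted):
        m, res = fitted
        rep = res.reconstruct(m)
        assert rep.shape == m.shape
        rep2 = res.reconstruct(m)
        np.testing.assert_array_equal(rep.values, rep2.values)

    def test_mse_improves_over_training(self, fitted):
        _, res = fitted
        log = res.training_log
        assert log["train_mse"].iloc[-1] < log["train_mse"].iloc[0]

    def test_summary_mentions_architecture(self, fitted):
        _, res = fitted
        text = res.summary()
        assert "L24, G, L5" in text
        assert "Final train MSE" in text

    def test_save_reload_same_codes(self, fitted, tmp_path):
        m, res = fitted
        path = tmp_path / "m.npz"
        res.save(path)
        back = TrainedModel.load(path)
        np.testing.assert_allclose(
            encode(back, m).codes, res.encode(m).codes, atol=1e-12
        )


class TestLinearBottleneckFloor:
    def test_identity_activation_ae_vs_pca(self):
        """A linear (identity-activation) autoencoder can never beat the
        rank-k PCA floor and should approach it after training."""
        design = cc.SyntheticDesign(
            n_genes=100, n_types=3, samples_per_type=12, n_modules=4,
            n_conditions_per_type=4, noise_sd=0.1, seed=3,
        )
        m, _, _ = cc.generate(design)
        model = CICAutoencoder(m, arch="L4", code_size=4)
        res = model.fit(learning_rate=0.5, decay=0.002, epochs=30,
                        iterations_per_epoch=3, seed=1)
        mse = res.mse(m)
        X = m.values.T
        Xc = X - X.mean(axis=0)
        sv = np.linalg.svd(Xc, compute_uv=False)
        floor = (sv[4:] ** 2).sum() / Xc.size
        assert mse >= floor - 1e-10
        assert mse <= 1.5 * floor
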