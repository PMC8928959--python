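import numpy as np
import pytest

from deeplse.model import (DeepLSE, ModelConfig, build_model, combined_loss,
                           load_checkpoint, train)


class TestBuildModel:
    @pytest.mark.parametrize(
        "N, hidden",
        [(1, (10, 5, 2)), (5, (50, 25, 10)), (10, (100, 50, 20))],
    )
    def test_width_law(self, N, hidden):
        spec = build_model(ModelConfig(N=N, k=6, LV=6))
        assert spec.encoder_widths == (2800, *hidden, 6)
        assert spec.decoder_widths == (6, *reversed(hidden), 2800)
        assert spec.classifier_widths == (6, 10, 10, 2)

    def test_decoder_is_exact_mirror(self):
        spec = build_model(ModelConfig(N=3, k=2, LV=4))
        assert spec.decoder_widths == tuple(reversed(spec.encoder_widths))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(N=0)
        with pytest.raises(ValueError):
            ModelConfig(LV=0)
        with pytest.raises(ValueError):
            ModelConfig(lam=1.5)
        with pytest.raises(ValueError):
            ModelConfig(patience=200, max_epochs=100)


class TestCombinedLoss:
    def test_equal_losses_are_fixed_point(self):
        assert combined_loss(1.0, 1.0, 0.99) == pytest.approx(1.0)

    def test_mixing_weight_arithmetic(self):
        assert combined_loss(0.0, 2.0, 0.99) == pytest.approx(0.02)

    def test_boundary_lambda_one_returns_decoder_loss(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            x, y = rng.random(2)
            assert combined_loss(x, y, 1.0) == pytest.approx(x)

    def test_lambda_out_of_range_errors(self):
        with pytest.raises(ValueError):
            combined_loss(1.0, 1.0, 1.01)


class TestParameterCount:
    def test_spec_count_matches_instantiated_network(self, small_results):
        assert small_results.spec.parameter_count() == small_results.n_parameters()


class TestTraining:
    def test_single_class_labels_error(self):
        X = np.random.default_rng(0).random((10, 800))
        with pytest.raises(ValueError, match="both classes"):
            DeepLSE(X, np.ones(10, dtype=int), ModelConfig(N=1, k=1, LV=2))

    def test_nonfinite_features_error(self):
        X = np.random.default_rng(0).random((10, 800))
        X[0, 0] = np.nan
        y = np.array([0, 1] * 5)
        with pytest.raises(ValueError, match="non-finite"):
            DeepLSE(X, y, ModelConfig(N=1, k=1, LV=2))

    def test_width_mismatch_error(self):
        X = np.random.default_rng(0).random((10, 400))
        y = np.array([0, 1] * 5)
        with pytest.raises(ValueError, match="feature matrix"):
            DeepLSE(X, y, ModelConfig(N=1, k=1, LV=2))  # expects 800

    def test_best_epoch_no_worse_than_first(self, small_results):
        h = small_results.history
        assert h.loc[small_results.best_epoch, "val_combined_loss"] <= h.loc[0, "val_combined_loss"]

    def test_history_bounded_by_max_epochs(self, small_results):
        assert len(small_results.history) <= small_results.config.max_epochs

    def test_recovers_planted_signal(self, small_results, small_features):
        _, _, X_te, y_te = small_features
        rep = small_results.evaluate(X_te, y_te)
        assert rep.balanced_accuracy >= 0.85

    def test_seed_determinism(self, small_features):
        X_tr, y_tr, X_te, _ = small_features
        cfg = ModelConfig(N=1, k=1, LV=2, seed=3, max_epochs=15, patience=5)
        r1 = train(X_tr, y_tr, cfg)
        r2 = train(X_tr, y_tr, cfg)
        assert r1.history.equals(r2.history)
        np.testing.assert_array_equal(r1.predict(X_te)[0], r2.predict(X_te)[0])

    def test_lambda_one_freezes_classifier(self, small_features):
        # pure-autoencoder limit: no gradient reaches the classifier head
        X_tr, y_tr, _, _ = small_features
        cfg = ModelConfig(N=1, k=1, LV=2, seed=5, lam=1.0, max_epochs=5, patience=5)
        model = DeepLSE(X_tr, y_tr, cfg)
        res = model.fit()
        rng = np.random.default_rng(cfg.seed)
        from deeplse import _nn
        fresh = _nn.JointNet(res.spec.encoder_widths, res.spec.decoder_widths,
                             res.spec.classifier_widths, cfg.dropout_rate, rng)
        for trained_layer, fresh_layer in zip(res._net.classifier.layers, fresh.classifier.layers):
            for name in ("W", "b", "gamma", "beta"):
                if name in trained_layer.params:
                    np.testing.assert_array_equal(
                        trained_layer.params[name], fresh_layer.params[name]
                    )

    def test_lambda_zero_freezes_decoder(self, small_features):
        X_tr, y_tr, _, _ = small_features
        cfg = ModelConfig(N=1, k=1, LV=2, seed=5, lam=0.0, max_epochs=5, patience=5)
        res = DeepLSE(X_tr, y_tr, cfg).fit()
        rng = np.random.default_rng(cfg.seed)
        from deeplse import _nn
        fresh = _nn.JointNet(res.spec.encoder_widths, res.spec.decoder_widths,
                             res.spec.classifier_widths, cfg.dropout_rate, rng)
        for trained_layer, fresh_layer in zip(res._net.decoder.layers, fresh.decoder.layers):
            for name in ("W", "b"):
                if name in trained_layer.params:
                    np.testing.assert_array_equal(
                        trained_layer.params[name], fresh_layer.params[name]
                    )


class TestInference:
    def test_latent_shape_and_range(self, small_results, small_features):
        _, _, X_te, _ = small_features
        Z = small_results.encode_latent(X_te)
        assert Z.shape == (X_te.shape[0], small_results.config.LV)
        assert Z.min() >= 0.0 and Z.max() <= 1.0

    def test_inference_is_deterministic(self, small_results, small_features):
        _, _, X_te, _ = small_features
        np.testing.assert_array_equal(
            small_results.encode_latent(X_te), small_results.encode_latent(X_te)
        )
        np.testing.assert_array_equal(
            small_results.predict_proba(X_te), small_results.predict_proba(X_te)
        )

    def test_probabilities_sum_to_one(self, small_results, small_features):
        _, _, X_te, _ = small_features
        proba, labels = small_results.predict(X_te)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-12)
        assert set(np.unique(labels)) <= {0, 1}

    def test_zeroed_head_gives_half_half_and_negative_tie(self, small_results, small_features):
        _, _, X_te, _ = small_features
        import copy
        res = copy.deepcopy(small_results)
        head = res._net.classifier.layers[-1]
        head.params["W"][...] = 0.0
        head.params["b"][...] = 0.0
        proba, labels = res.predict(X_te[:5])
        np.testing.assert_allclose(proba, 0.5, atol=1e-12)
        assert (labels == 0).all()  # ties resolve to the majority (negative) class

    def test_reconstruction_identity_and_range(self, small_results, small_features):
        _, _, X_te, _ = small_features
        decoded, residual = small_results.reconstruct(X_te)
        assert decoded.shape == X_te.shape
        np.testing.assert_allclose(decoded + residual, X_te, atol=1e-12)
        assert decoded.min() > 0.0 and decoded.max() < 1.0  # sigmoid output

    def test_width_mismatch_at_inference(self, small_results):
        with pytest.raises(ValueError, match="feature matrix"):
            small_results.encode_latent(np.zeros((3, 17)))


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, small_results, small_features, tmp_path):
        _, _, X_te, _ = small_features
        path = tmp_path / "model.npz"
        small_results.save(path)
        loaded = load_checkpoint(path)
        assert loaded.config == small_results.config
        np.testing.assert_allclose(
            loaded.predict_proba(X_te), small_results.predict_proba(X_te), atol=1e-12
        )
        np.testing.assert_allclose(
            loaded.encode_latent(X_te), small_results.encode_latent(X_te), atol=1e-12
        )


class TestSummary:
    def test_summary_reports_architecture(self, small_results):
        text = small_results.summary()
        assert "encoder widths" in text
        assert str(small_results.spec.input_dim) in text
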