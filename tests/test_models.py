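import numpy as np
import pytest

from aabench import nn
from aabench.encodings import build_blosum62, build_one_hot, build_vhse8, load_matrix, save_matrix
from aabench.models import (
    CNNLSTMModelConfig,
    EmbeddingSpec,
    LSTMModelConfig,
    ModelConfigError,
    SiamesePPIConfig,
    build_cnn_lstm_model,
    build_embedding_layer,
    build_lstm_model,
    build_siamese_ppi_model,
    extract_embedding,
    train_model,
)
from aabench.prep import prepare_peptide_dataset
from aabench.synthetic import generate_peptide_dataset


def small_hla(n=160, seed=3, noise=0.05):
    ds = prepare_peptide_dataset(generate_peptide_dataset(n, noise_sd=noise, seed=seed))
    cut = int(0.8 * n)
    return ((ds.inputs[:cut], ds.targets[:cut]), (ds.inputs[cut:], ds.targets[cut:]))


class TestEmbeddingSpec:
    def test_frozen_one_hot_passthrough(self):
        layer = build_embedding_layer(EmbeddingSpec("frozen", "one_hot"))
        np.testing.assert_array_equal(layer.W.value, build_one_hot().values)
        assert not layer.W.trainable

    def test_learned_init_range(self):
        layer = build_embedding_layer(EmbeddingSpec("learned", dim=4, seed=1))
        assert layer.W.trainable
        assert layer.W.value.shape == (21, 4)
        assert np.all(np.abs(layer.W.value) <= 0.05)

    def test_lookup_semantics(self):
        layer = build_embedding_layer(EmbeddingSpec("frozen", "vhse8"))
        out = layer.forward(np.array([[0, 1, 20]]), training=False)
        np.testing.assert_array_equal(out[0], build_vhse8().values[[0, 1, 20]])

    def test_frozen_without_source_rejected(self):
        with pytest.raises(ModelConfigError):
            EmbeddingSpec("frozen").resolve()

    def test_learned_without_dim_rejected(self):
        with pytest.raises(ModelConfigError):
            EmbeddingSpec("learned").resolve()

    def test_unknown_mode_rejected(self):
        with pytest.raises(ModelConfigError):
            EmbeddingSpec("semi-frozen", "one_hot").resolve()


class TestLSTMModel:
    def test_predictions_in_unit_interval(self, rng):
        model = build_lstm_model(EmbeddingSpec("frozen", "one_hot"), seed=0)
        X = rng.integers(0, 21, size=(8, 26))
        p = model.predict(X)
        assert p.shape == (8,)
        assert np.all((p > 0) & (p < 1))

    def test_recurrent_width_is_12(self):
        model = build_lstm_model(EmbeddingSpec("frozen", "one_hot"), seed=0)
        lstm = model.net.layers[1]
        assert isinstance(lstm, nn.LSTM) and lstm.units == 12

    def test_identical_seeds_identical_params(self):
        a = build_lstm_model(EmbeddingSpec("learned", dim=4, seed=5), seed=5)
        b = build_lstm_model(EmbeddingSpec("learned", dim=4, seed=5), seed=5)
        for pa, pb in zip(a.params(), b.params()):
            assert pa.value.tobytes() == pb.value.tobytes()


class TestCNNLSTMModel:
    def test_default_conv_geometry(self):
        cfg = CNNLSTMModelConfig()
        assert cfg.conv_filters == 36 and cfg.kernel_size == 9 and cfg.stride == 1

    def test_kernel_longer_than_input_rejected(self):
        with pytest.raises(ModelConfigError):
            CNNLSTMModelConfig(input_length=8, kernel_size=9)

    def test_predictions_in_unit_interval(self, rng):
        model = build_cnn_lstm_model(EmbeddingSpec("learned", dim=4, seed=0), seed=0)
        p = model.predict(rng.integers(0, 21, size=(6, 26)))
        assert np.all((p > 0) & (p < 1))


class TestSiameseModel:
    def _tiny_cfg(self, combiner="concat"):
        return SiamesePPIConfig(conv_filters=(4, 6), conv_kernels=(5, 3), pool_width=2,
                                hidden_units=8, combiner=combiner, input_length=40,
                                batch_size=8, epochs=2)

    def test_four_conv_modules_by_default(self):
        model = build_siamese_ppi_model(EmbeddingSpec("learned", dim=4, seed=0), seed=0)
        convs = [l for l in model.branch.layers if isinstance(l, nn.Conv1D)]
        assert len(convs) == 4
        pools = [l for l in model.branch.layers
                 if isinstance(l, (nn.AvgPool, nn.GlobalAvgPool))]
        assert isinstance(pools[-1], nn.GlobalAvgPool)

    def test_branch_weight_sharing(self, rng):
        model = build_siamese_ppi_model(EmbeddingSpec("learned", dim=4, seed=0),
                                        self._tiny_cfg(), seed=0)
        x = rng.integers(0, 21, size=(3, 40))
        model.forward_logits(x, x, training=False)
        np.testing.assert_array_equal(model._za, model._zb)

    def test_symmetric_combiner_swap_invariant(self, rng):
        model = build_siamese_ppi_model(EmbeddingSpec("learned", dim=4, seed=0),
                                        self._tiny_cfg("symmetric"), seed=0)
        xa = rng.integers(0, 21, size=(5, 40))
        xb = rng.integers(0, 21, size=(5, 40))
        np.testing.assert_array_equal(model.predict(xa, xb), model.predict(xb, xa))

    def test_predictions_in_unit_interval(self, rng):
        model = build_siamese_ppi_model(EmbeddingSpec("frozen", "vhse8"),
                                        self._tiny_cfg(), seed=1)
        p = model.predict(rng.integers(0, 21, size=(4, 40)),
                          rng.integers(0, 21, size=(4, 40)))
        assert np.all((p > 0) & (p < 1))

    def test_mismatched_conv_lists_rejected(self):
        with pytest.raises(ModelConfigError):
            SiamesePPIConfig(conv_filters=(4, 6), conv_kernels=(5,))


class TestTraining:
    def test_history_length_equals_epochs(self):
        train, val = small_hla()
        model = build_lstm_model(EmbeddingSpec("frozen", "one_hot"),
                                 LSTMModelConfig(batch_size=64), seed=0)
        history = train_model(model, train, val, epochs=3, seed=0)
        assert len(history) == 3
        assert all(np.isfinite(history.val_metric))
        assert history.metric_name == "auc"

    def test_frozen_blosum_unchanged_by_training(self):
        train, val = small_hla()
        model = build_lstm_model(EmbeddingSpec("frozen", "blosum62"),
                                 LSTMModelConfig(batch_size=64), seed=0)
        before = model.embedding.W.value.tobytes()
        train_model(model, train, val, epochs=5, seed=0)
        assert model.embedding.W.value.tobytes() == before
        np.testing.assert_array_equal(model.embedding.W.value, build_blosum62().values)

    def test_learned_embedding_changes(self):
        train, val = small_hla()
        model = build_lstm_model(EmbeddingSpec("learned", dim=4, seed=0),
                                 LSTMModelConfig(batch_size=64), seed=0)
        before = model.embedding.W.value.copy()
        train_model(model, train, val, epochs=5, seed=0)
        assert np.any(model.embedding.W.value != before)

    def test_seeded_end_to_end_determinism(self):
        train, val = small_hla()
        histories = []
        for _ in range(2):
            model = build_lstm_model(EmbeddingSpec("learned", dim=4, seed=7),
                                     LSTMModelConfig(batch_size=64), seed=7)
            histories.append(train_model(model, train, val, epochs=3, seed=7))
        assert histories[0].train_loss == histories[1].train_loss
        assert histories[0].val_metric == histories[1].val_metric

    def test_shape_mismatch_reported_before_training(self):
        train, val = small_hla()
        model = build_lstm_model(EmbeddingSpec("frozen", "one_hot"),
                                 LSTMModelConfig(input_length=30), seed=0)
        with pytest.raises(ModelConfigError, match=r"\(n, 30\)"):
            train_model(model, train, val, epochs=1, seed=0)

    def test_history_frame_tidy(self):
        train, val = small_hla()
        model = build_lstm_model(EmbeddingSpec("frozen", "one_hot"),
                                 LSTMModelConfig(batch_size=64), seed=0)
        frame = train_model(model, train, val, epochs=2, seed=0).to_frame()
        assert list(frame.columns) == ["epoch", "split", "metric", "value"]
        assert len(frame) == 2 * 3

    def test_capacity_noiseless_auc_above_090(self):
        # the synthetic generator must carry learnable signal: 3-seed
        # majority reaches val AUC > 0.9 on noiseless data (n scaled to
        # 2000 as stated, epoch cap 300 with early stop once exceeded)
        
        from aabench.prep import BINDER_THRESHOLD

        wins = 0
        for seed in (0, 1, 2):
            ds = prepare_peptide_dataset(
                generate_peptide_dataset(2000, noise_sd=0.0, seed=100 + seed))
            cut = 1600
            train = (ds.inputs[:cut], ds.targets[:cut])
            val = (ds.inputs[cut:], ds.targets[cut:])
            model = build_lstm_model(EmbeddingSpec("frozen", "one_hot"), seed=seed)
            history = train_model(model, train, val, epochs=300, seed=seed,
                                  stop_threshold=0.905)
            if history.best_val_metric > 0.9:
                wins += 1
        assert wins >= 2


class TestExtractEmbedding:
    def test_untrained_learned_equals_init(self):
        model = build_lstm_model(EmbeddingSpec("learned", dim=4, seed=3), seed=3)
        from aabench.encodings import init_learned

        np.testing.assert_array_equal(extract_embedding(model).values,
                                      init_learned(4, seed=3).values)

    def test_frozen_vhse_after_training(self):
        train, val = small_hla(n=80)
        model = build_lstm_model(EmbeddingSpec("frozen", "vhse8"),
                                 LSTMModelConfig(batch_size=32), seed=0)
        train_model(model, train, val, epochs=2, seed=0)
        np.testing.assert_array_equal(extract_embedding(model).values,
                                      build_vhse8().values)

    def test_roundtrips_through_serialization(self, tmp_path):
        model = build_lstm_model(EmbeddingSpec("learned", dim=5, seed=2), seed=2)
        emb = extract_embedding(model)
        save_matrix(emb, tmp_path / "emb.tsv")
        back = load_matrix(tmp_path / "emb.tsv")
        assert np.max(np.abs(back.values - emb.values)) <= 1e-12
        assert back.scheme == "learned"

    def test_model_without_embedding_rejected(self):
        class Bare:
            pass

        with pytest.raises(ModelConfigError):
            extract_embedding(Bare())
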