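import numpy as np
import pytest

from rnamodnet.network import (LAYER_NAMES, Network, NetworkConfig,
                               build_network, encode_windows, train,
                               tune_hyperparameters)
from rnamodnet.synthetic import default_spec, generate

TINY = dict(conv_filters=8, lstm_units=4, fc_units=8, dropout=0.0, seed=0)


class TestArchitecture:
    def test_stage_arithmetic(self):
        c = NetworkConfig()
        assert c.conv_len == 41 - 10 + 1 == 32
        assert c.pooled_len == 32 // 3 == 10

    def test_kernel_too_large(self):
        with pytest.raises(ValueError):
            NetworkConfig(seq_len=8, kernel_size=10)

    def test_attention_weights_sum_to_one(self):
        net = build_network(NetworkConfig(**TINY))
        X = np.random.default_rng(1).random((7, 41, 4)).astype(np.float32)
        _, cache = net.forward(X)
        np.testing.assert_allclose(cache["alpha"].sum(axis=1), 1.0, atol=1e-6)

    def test_attention_output_in_convex_hull(self):
        net = build_network(NetworkConfig(**TINY))
        X = np.random.default_rng(2).random((5, 41, 4)).astype(np.float32)
        _, cache = net.forward(X)
        H, A = cache["Hcat"], cache["A"]
        assert (A >= H.min(axis=1) - 1e-6).all()
        assert (A <= H.max(axis=1) + 1e-6).all()

    def test_scores_in_unit_interval_and_deterministic(self):
        net = build_network(NetworkConfig(**TINY))
        w = ["ACGU" * 10 + "A"] * 3
        s1, s2 = net.predict(w), net.predict(w)
        assert ((s1 > 0) & (s1 < 1)).all()
        np.testing.assert_array_equal(s1, s2)
        assert s1[0] == s1[1] == s1[2]  # identical inputs, identical scores

    def test_wrong_length_rejected(self):
        net = build_network(NetworkConfig(**TINY))
        with pytest.raises(ValueError):
            net.predict(["ACGU"])


class TestTraining:
    def test_single_class_errors(self):
        net = build_network(NetworkConfig(**TINY, max_epochs=1))
        w = ["ACGU" * 10 + "A"] * 8
        with pytest.raises(ValueError):
            train(net, w, w, train_labels=[1] * 8, val_labels=[1] * 8)

    def test_patience_stops_and_logs_every_epoch(self):
        # zero learning rate: the validation metric never improves after
        # epoch 0, so training must stop after exactly `patience` more epochs
        cfg = NetworkConfig(**TINY, learning_rate=0.0, patience=3,
                            max_epochs=30)
        windows, _ = generate(default_spec(n_pos=20, n_neg=20, seed=1))
        net = train(build_network(cfg), windows, windows)
        assert len(net.training_log) == 4  # epoch 0 + 3 patience epochs
        assert net.best_epoch == 0
        assert [e["epoch"] for e in net.training_log] == [0, 1, 2, 3]

    def test_separable_fixture_learns(self, small_trained, small_split):
        from sklearn.metrics import roc_auc_score

        _, te = small_split
        scores = small_trained.predict(te)
        labels = [w.label for w in te]
        assert roc_auc_score(labels, scores) >= 0.95
        pos = scores[np.array(labels) == 1]
        neg = scores[np.array(labels) == 0]
        assert pos.mean() > neg.mean()

    def test_training_reproducible(self):
        windows, _ = generate(default_spec(n_pos=30, n_neg=30, seed=2))
        cfg = NetworkConfig(**TINY, max_epochs=2)
        a = train(build_network(cfg), windows, windows).predict(windows[:5])
        b = train(build_network(cfg), windows, windows).predict(windows[:5])
        np.testing.assert_allclose(a, b, atol=1e-6)

    def test_label_shuffle_destroys_signal(self, small_split, small_config):
        from dataclasses import replace

        from sklearn.metrics import roc_auc_score

        tr, te = small_split
        rng = np.random.default_rng(0)
        shuffled = rng.permutation([w.label for w in tr])
        cfg = replace(small_config, max_epochs=3)
        net = train(build_network(cfg), tr, te,
                    train_labels=shuffled, val_labels=[w.label for w in te])
        auc = roc_auc_score([w.label for w in te], net.predict(te))
        # 100-window test set: chance-level AUC has sd ~0.06, and fitting
        # noise labels can drift further; band sized for the reduced fixture
        assert abs(auc - 0.5) <= 0.2

    def test_motif_ablation_drops_auc(self, small_config):
        from dataclasses import replace

        from sklearn.metrics import roc_auc_score

        from sklearn.model_selection import train_test_split

        spec = default_spec(n_pos=150, n_neg=150, seed=4)
        spec.motifs[0].embed_prob = 0.0  # positives indistinguishable
        windows, truth = generate(spec)
        assert len(truth) == 0
        labels = [w.label for w in windows]
        tr, te = train_test_split(np.arange(300), test_size=100,
                                  stratify=labels, random_state=4)
        cfg = replace(small_config, max_epochs=3)
        net = train(build_network(cfg), [windows[i] for i in tr],
                    [windows[i] for i in te])
        auc = roc_auc_score([windows[i].label for i in te],
                            net.predict([windows[i] for i in te]))
        assert abs(auc - 0.5) <= 0.15


class TestEmbeddings:
    def test_shapes(self, small_trained, small_split):
        _, te = small_split
        few = te[:6]
        c = small_trained.config
        assert small_trained.layer_embeddings(few, "input").shape == (6, 164)
        assert small_trained.layer_embeddings(few, "attention").shape == (
            6, 2 * c.lstm_units)
        out = small_trained.layer_embeddings(few, "output")
        assert out.shape == (6, 1)
        np.testing.assert_allclose(out[:, 0], small_trained.predict(few),
                                   atol=1e-6)

    def test_unknown_layer_lists_layers(self, small_trained):
        with pytest.raises(KeyError, match="attention"):
            small_trained.layer_embeddings(["A" * 41], "bogus")

    def test_discriminability_improves_over_layers(self, small_trained,
                                                   small_split):
        from sklearn.metrics import silhouette_score

        _, te = small_split
        labels = [w.label for w in te]
        s_in = silhouette_score(
            small_trained.layer_embeddings(te, "input"), labels)
        s_att = silhouette_score(
            small_trained.layer_embeddings(te, "attention"), labels)
        assert s_att > s_in


class TestPersistence:
    def test_save_load_roundtrip(self, small_trained, small_split, tmp_path):
        _, te = small_split
        small_trained.save(tmp_path / "model")
        loaded = Network.load(tmp_path / "model")
        np.testing.assert_allclose(loaded.predict(te[:8]),
                                   small_trained.predict(te[:8]), atol=1e-7)


class TestTuning:
    def _data(self):
        windows, _ = generate(default_spec(n_pos=40, n_neg=40, seed=6))
        return windows, [w.label for w in windows]

    def test_budget_one_returns_sampled_config(self):
        base = NetworkConfig(**TINY)
        best, trials = tune_hyperparameters(
            budget=1, data=self._data(), seed=0, base_config=base,
            max_epochs=1)
        assert len(trials) == 1
        assert best.kernel_size == trials[0]["kernel_size"]

    def test_seeded_search_deterministic(self):
        base = NetworkConfig(**TINY)
        data = self._data()
        space = {"kernel_size": [6, 10], "dropout": (0.0, 0.3)}
        _, t1 = tune_hyperparameters(space, budget=3, data=data, seed=5,
                                     base_config=base, max_epochs=1)
        _, t2 = tune_hyperparameters(space, budget=3, data=data, seed=5,
                                     base_config=base, max_epochs=1)
        assert [x["kernel_size"] for x in t1] == [x["kernel_size"] for x in t2]
        assert [x["auc"] for x in t1] == [x["auc"] for x in t2]
        assert max(x["auc"] for x in t1) >= np.median([x["auc"] for x in t1])

    def test_empty_space_errors(self):
        with pytest.raises(ValueError):
            tune_hyperparameters({}, budget=1, data=self._data())
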