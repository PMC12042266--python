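import dataclasses

import numpy as np
import pytest

from conftest import relabel_reaction
from hydrolyze.autograd import Tensor
from hydrolyze.model import (
    Batch,
    EvalReport,
    ModelConfig,
    TrainedModel,
    TrainingError,
    collate,
    evaluate,
    forward,
    gated_conv_forward,
    init_params,
    pool,
    predict_dg,
    train,
)
from hydrolyze.reaction_graph import build_reaction_graph


def small_config(**kw):
    base = dict(embedding_size=8, n_conv_layers=2, pooling="mean",
                max_epochs=2, batch_size=16, patience=10, seed=0)
    base.update(kw)
    return ModelConfig(**base)


def make_pool_batch(n_nodes, d, n_graphs=1, seg=None):
    seg = np.zeros(n_nodes, dtype=int) if seg is None else np.asarray(seg)
    perm = np.argsort(seg, kind="stable")
    return Batch(atom_x=np.zeros((n_nodes, 1)), atom_seg=seg,
                 bond_x=np.zeros((0, 1)), bond_seg=np.zeros(0, dtype=int),
                 incidence=np.zeros(0, dtype=int),
                 atom_deg=np.ones((n_nodes, 1)),
                 global_x=np.zeros((n_graphs, 1)),
                 pool_perm=perm, pool_seg=seg[perm], y=None,
                 fg_ids=["x"] * n_graphs, n_graphs=n_graphs)


class TestConfig:
    def test_defaults_valid(self):
        cfg = ModelConfig()
        assert cfg.n_conv_layers == 3 and cfg.pooling == "set2set"

    @pytest.mark.parametrize("kw", [
        dict(pooling="max"), dict(n_conv_layers=1), dict(n_conv_layers=5),
        dict(embedding_size=0), dict(head_sizes=(0,)), dict(loss="huber"),
    ])
    def test_invalid_rejected(self, kw):
        with pytest.raises(ValueError):
            ModelConfig(**kw)


class TestGatedConv:
    def test_zero_message_weights_identity(self, mixed_fixture_graphs):
        cfg = small_config()
        batch = collate(mixed_fixture_graphs[:3])
        rng = np.random.default_rng(0)
        d = cfg.embedding_size
        params = init_params(cfg, batch.atom_x.shape[1],
                             batch.bond_x.shape[1] - 3,
                             batch.global_x.shape[1], rng)
        for k in params:
            if k.startswith("conv0"):
                params[k].data[:] = 0.0
        h_a = Tensor(rng.normal(size=(batch.atom_x.shape[0], d)))
        h_b = Tensor(rng.normal(size=(batch.bond_x.shape[0], d)))
        h_g = Tensor(rng.normal(size=(batch.n_graphs, d)))
        oa, ob, og = gated_conv_forward(params, 0, batch, h_a, h_b, h_g)
        np.testing.assert_array_equal(oa.data, h_a.data)
        np.testing.assert_array_equal(ob.data, h_b.data)
        np.testing.assert_array_equal(og.data, h_g.data)


class TestPooling:
    def test_mean_two_nodes(self):
        cfg = small_config(pooling="mean", embedding_size=3)
        f = np.array([[1.0, 2.0, 3.0], [3.0, 4.0, 7.0]])
        batch = make_pool_batch(2, 3)
        out = pool({}, cfg, batch, Tensor(f), Tensor(np.zeros((0, 3))))
        np.testing.assert_allclose(out.data, (f[0] + f[1])[None] / 2)

    def test_weighted_mean_equal_weights_is_mean(self):
        d = 5
        rng = np.random.default_rng(1)
        f = rng.normal(size=(4, d))
        batch = make_pool_batch(4, d)
        cfg_w = small_config(pooling="weighted_mean", embedding_size=d)
        params = {"pool_w_W": Tensor(np.zeros((d, 1))),
                  "pool_w_b": Tensor(np.zeros((1, 1)))}
        out_w = pool(params, cfg_w, batch, Tensor(f), Tensor(np.zeros((0, d))))
        out_m = pool({}, small_config(pooling="mean", embedding_size=d),
                     batch, Tensor(f), Tensor(np.zeros((0, d))))
        np.testing.assert_allclose(out_w.data, out_m.data)

    def test_self_attention_permutation_invariant(self):
        d = 6
        rng = np.random.default_rng(2)
        cfg = small_config(pooling="self_attention", embedding_size=d)
        params = init_params(cfg, 1, 1 - 3 + 3, 1, rng)  # only pool params used
        f = rng.normal(size=(5, d))
        batch = make_pool_batch(5, d)
        out1 = pool(params, cfg, batch, Tensor(f), Tensor(np.zeros((0, d))))
        perm = rng.permutation(5)
        out2 = pool(params, cfg, batch, Tensor(f[perm]),
                    Tensor(np.zeros((0, d))))
        np.testing.assert_allclose(out1.data, out2.data, atol=1e-12)

    def test_set2set_single_node_matches_oracle(self):
        """set2set on one node, verified against an independent NumPy
        re-implementation of the LSTM-attention recursion."""
        d = 4
        rng = np.random.default_rng(3)
        cfg = small_config(pooling="set2set", embedding_size=d,
                           set2set_steps=3)
        params = init_params(cfg, 1, 1, 1, rng)
        node = rng.normal(size=(1, d))
        batch = make_pool_batch(1, d)
        out = pool(params, cfg, batch, Tensor(node),
                   Tensor(np.zeros((0, d)))).data

        # oracle: step-by-step recursion; with one node attention is 1
        def sig(x):
            return 1.0 / (1.0 + np.exp(-x))

        P = {k: v.data for k, v in params.items()}
        q = np.zeros((1, d))
        c = np.zeros((1, d))
        qstar = np.zeros((1, 2 * d))
        for _ in range(3):
            i = sig(qstar @ P["s2s_xi_W"] + P["s2s_xi_b"] + q @ P["s2s_hi_W"])
            f = sig(qstar @ P["s2s_xf_W"] + P["s2s_xf_b"] + q @ P["s2s_hf_W"])
            o = sig(qstar @ P["s2s_xo_W"] + P["s2s_xo_b"] + q @ P["s2s_ho_W"])
            u = np.tanh(qstar @ P["s2s_xc_W"] + P["s2s_xc_b"]
                        + q @ P["s2s_hc_W"])
            c = f * c + i * u
            q = o * np.tanh(c)
            r = node  # single node: softmax weight is exactly 1
            qstar = np.concatenate([q, r], axis=1)
        np.testing.assert_allclose(out, qstar, atol=1e-12)


@pytest.fixture(scope="module")
def tiny_model(mixed_fixture_graphs, featurizer):
    cfg = small_config(max_epochs=8, pooling="set2set", embedding_size=12,
                       patience=20, seed=5)
    return train(mixed_fixture_graphs[:80], cfg, featurizer)


class TestPrediction:
    def test_bitwise_deterministic(self, tiny_model, mixed_fixture_graphs):
        g = mixed_fixture_graphs[0]
        assert predict_dg(tiny_model, g) == predict_dg(tiny_model, g)

    def test_permutation_invariance(self, tiny_model,
                                    mixed_fixture_reactions, featurizer):
        _, reactions = mixed_fixture_reactions
        for k, rxn in enumerate(reactions[:10]):
            base = predict_dg(tiny_model, build_reaction_graph(rxn, featurizer))
            rel = predict_dg(tiny_model, build_reaction_graph(
                relabel_reaction(rxn, 500 + k), featurizer))
            assert base == pytest.approx(rel, abs=1e-8)

    def test_prediction_finite(self, tiny_model, mixed_fixture_graphs):
        preds = tiny_model.predict_batch(mixed_fixture_graphs[:20])
        assert np.all(np.isfinite(preds))

    def test_save_load_identical(self, tiny_model, mixed_fixture_graphs,
                                 tmp_path):
        tiny_model.save(tmp_path / "m.npz")
        reloaded = TrainedModel.load(tmp_path / "m.npz")
        np.testing.assert_array_equal(
            tiny_model.predict_batch(mixed_fixture_graphs[:10]),
            reloaded.predict_batch(mixed_fixture_graphs[:10]))
        assert reloaded.config == tiny_model.config


class TestTraining:
    def test_smoke_history(self, mixed_fixture_graphs, featurizer):
        cfg = small_config(max_epochs=2)
        model = train(mixed_fixture_graphs[:10], cfg, featurizer)
        assert len(model.history) == 2
        assert all(np.isfinite(h["train_loss"]) for h in model.history)

    def test_seeded_determinism(self, mixed_fixture_graphs, featurizer):
        cfg = small_config(max_epochs=3, seed=7)
        m1 = train(mixed_fixture_graphs[:40], cfg, featurizer)
        m2 = train(mixed_fixture_graphs[:40], cfg, featurizer)
        assert m1.history == m2.history
        np.testing.assert_array_equal(
            m1.predict_batch(mixed_fixture_graphs[:5]),
            m2.predict_batch(mixed_fixture_graphs[:5]))

    def test_empty_dataset_raises(self, featurizer):
        with pytest.raises(TrainingError, match="empty"):
            train([], small_config(), featurizer)


class TestEvaluate:
    def _fake_model(self, tiny_model, preds):
        model = dataclasses.replace(tiny_model)
        model.predict_batch = lambda graphs: np.asarray(preds)[:len(graphs)]
        return model

    def _graphs_with_labels(self, graphs, labels):
        return [dataclasses.replace(g, dG_label=l)
                for g, l in zip(graphs, labels)]

    def test_hand_computed_metrics(self, tiny_model, mixed_fixture_graphs):
        labels = [1.0, -2.0, 3.0, 0.5, -1.0]
        preds = [1.5, -1.0, 2.0, -1.0, -2.0]
        graphs = self._graphs_with_labels(mixed_fixture_graphs[:5], labels)
        rep = evaluate(self._fake_model(tiny_model, preds), graphs)
        assert rep.mae == pytest.approx(1.0)          # mean of |err|
        assert rep.rmse == pytest.approx(np.sqrt(1.1))
        assert rep.sign_accuracy == pytest.approx(80.0)
        assert rep.n == 5
        assert sum(rep.error_bins.values()) == 5

    def test_perfect_predictor(self, tiny_model, mixed_fixture_graphs):
        labels = [3.0, -1.0, 2.0, -4.0]
        graphs = self._graphs_with_labels(mixed_fixture_graphs[:4], labels)
        rep = evaluate(self._fake_model(tiny_model, labels), graphs)
        assert rep.mae == 0.0 and rep.rmse == 0.0
        assert rep.r2 == 1.0 and rep.sign_accuracy == 100.0

    def test_constant_mean_predictor_r2_zero(self, tiny_model,
                                             mixed_fixture_graphs):
        labels = [1.0, 2.0, 3.0, 6.0]
        mean = float(np.mean(labels))
        graphs = self._graphs_with_labels(mixed_fixture_graphs[:4], labels)
        rep = evaluate(self._fake_model(tiny_model, [mean] * 4), graphs)
        assert rep.r2 == pytest.approx(0.0)

    def test_mae_le_rmse_and_per_fg_table(self, tiny_model,
                                          mixed_fixture_graphs):
        rep = evaluate(tiny_model, mixed_fixture_graphs[:60])
        assert rep.mae <= rep.rmse
        fgs = {g.fg_id for g in mixed_fixture_graphs[:60]}
        assert set(rep.per_fg_mae) == fgs
        frame = rep.to_frame()
        assert "overall average" in set(frame["functional group"])
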