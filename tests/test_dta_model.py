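"""Model architectures, training behaviour, prediction contracts."""

import numpy as np
import pytest

import wfdta as w
from wfdta.dta_model import BRANCH_KINDS, GraphBatch, build_drug_branch


@pytest.fixture(scope="module")
def tiny_graphs():
    return [w.smiles_to_graph(s) for s in ("C", "CCO", "c1ccccc1")]


def _config(kind="gcn", **over):
    defaults = dict(
        branch_kind=kind, protein_input_dim=625, batch_size=8,
        learning_rate=1e-3, epochs=3, seed=0,
    )
    defaults.update(over)
    return w.ModelConfig(**defaults)


class TestBranchArchitectures:
    @pytest.mark.parametrize("kind", BRANCH_KINDS)
    def test_all_kinds_emit_128_dim_embeddings(self, kind, tiny_graphs):
        cfg = _config(kind)
        branch = build_drug_branch(kind, cfg, np.random.default_rng(0))
        batch = GraphBatch(tiny_graphs)
        out = branch(batch, training=False, rng=np.random.default_rng(0))
        assert out.data.shape == (3, 128)
        assert np.all(np.isfinite(out.data))

    def test_single_atom_graph_finite(self):
        cfg = _config("gat")
        branch = build_drug_branch("gat", cfg, np.random.default_rng(0))
        out = branch(GraphBatch([w.smiles_to_graph("C")]), training=False, rng=np.random.default_rng(0))
        assert out.data.shape == (1, 128)
        assert np.all(np.isfinite(out.data))

    def test_unknown_kind_lists_valid(self):
        with pytest.raises(ValueError, match="gat_gcn"):
            _config("bogus")

    def test_gcn_layer_widths(self):
        branch = build_drug_branch("gcn", _config("gcn"), np.random.default_rng(0))
        assert branch.conv1.weight.shape == (78, 78)
        assert branch.conv2.weight.shape == (78, 156)
        assert branch.conv3.weight.shape == (156, 312)
        assert branch.fc.weight.shape == (312, 1024)
        assert branch.out.weight.shape == (1024, 128)

    def test_gat_gcn_layer_widths(self):
        branch = build_drug_branch("gat_gcn", _config("gat_gcn"), np.random.default_rng(0))
        assert branch.gat.heads == 10 and branch.gat.out_dim == 78
        assert branch.gcn.weight.shape == (780, 780)
        assert branch.fc.weight.shape == (1560, 1500)
        assert branch.out.weight.shape == (1500, 128)

    def test_gin_mlp_widths(self):
        branch = build_drug_branch("gin", _config("gin"), np.random.default_rng(0))
        assert len(branch.convs) == 5
        assert branch.convs[0].lin1.weight.shape == (78, 32)
        assert branch.convs[1].lin2.weight.shape == (32, 32)

    def test_gat_attention_heads(self):
        branch = build_drug_branch("gat", _config("gat"), np.random.default_rng(0))
        assert branch.gat1.heads == 10
        assert branch.gat2.heads == 1 and branch.gat2.out_dim == 128


class TestProteinBranch:
    def test_output_shape_and_batching(self):
        model = w.DTAModel(_config())
        vectors = np.random.default_rng(1).random((4, 625)) * 0.02
        out = model.protein_branch(vectors)
        assert out.data.shape == (4, 128)

    def test_wider_protein_embedding_mode(self):
        model = w.DTAModel(_config(protein_embed_dim=256))
        vectors = np.zeros((2, 625))
        assert model.protein_branch(vectors).data.shape == (2, 256)
        assert model.fc1.weight.shape == (128 + 256, 512)

    def test_all_zero_vector_finite(self):
        model = w.DTAModel(_config())
        out = model.protein_branch(np.zeros((1, 625)))
        assert np.all(np.isfinite(out.data))

    def test_dim_mismatch_rejected(self):
        model = w.DTAModel(_config())
        with pytest.raises(ValueError, match="625"):
            model.protein_branch(np.zeros((1, 25)))


class TestHeadAndForward:
    def test_head_widths(self):
        model = w.DTAModel(_config())
        assert model.fc1.weight.shape == (256, 512)
        assert model.fc2.weight.shape == (512, 128)
        assert model.head.weight.shape == (128, 1)

    def test_forward_scalar_per_pair(self, tiny_graphs):
        model = w.DTAModel(_config())
        vectors = np.random.default_rng(2).random((3, 625)) * 0.02
        out = model.forward(GraphBatch(tiny_graphs), vectors)
        assert out.data.shape == (3, 1)

    def test_eval_forward_bitwise_deterministic(self, tiny_graphs):
        model = w.DTAModel(_config())
        vectors = np.random.default_rng(3).random((3, 625)) * 0.02
        a = model.forward(GraphBatch(tiny_graphs), vectors).data
        b = model.forward(GraphBatch(tiny_graphs), vectors).data
        np.testing.assert_array_equal(a, b)


class TestTraining:
    def test_zero_epochs_untrained_empty_history(self, featurized_small):
        ftr, _, _, _ = featurized_small
        cfg = _config(epochs=0)
        model = w.DTAModel(cfg)
        before = model.head.weight.data.copy()
        model, history = w.train(model, ftr, cfg)
        assert history.train_mse == []
        np.testing.assert_array_equal(model.head.weight.data, before)

    def test_smoke_training_reduces_loss(self, featurized_small):
        ftr, _, train_ds, _ = featurized_small
        cfg = _config("gin", epochs=10)
        model = w.DTAModel(cfg)
        model, history = w.train(model, ftr, cfg)
        assert len(history.train_mse) == 10
        assert history.train_mse[-1] < history.train_mse[0]

    def test_same_seed_identical_loss_curves(self, featurized_small):
        ftr, _, _, _ = featurized_small
        cfg = _config("gin", epochs=3)
        _, h1 = w.train(w.DTAModel(cfg), ftr, cfg)
        _, h2 = w.train(w.DTAModel(cfg), ftr, cfg)
        assert h1.train_mse == h2.train_mse

    def test_empty_training_set_rejected(self, featurized_small):
        ftr, _, _, _ = featurized_small
        cfg = _config()
        with pytest.raises(ValueError, match="empty"):
            w.train(w.DTAModel(cfg), ftr.subset(np.array([], dtype=int)), cfg)


@pytest.fixture(scope="module")
def trained(featurized_small):
    ftr, fte, _, _ = featurized_small
    cfg = _config("gin", epochs=5)
    model, _ = w.train(w.DTAModel(cfg), ftr, cfg)
    return model, ftr, fte


class TestPredict:

    def test_one_prediction_per_pair_finite(self, trained):
        model, _, fte = trained
        preds = w.predict(model, fte)
        assert preds.shape == (len(fte),)
        assert np.all(np.isfinite(preds))

    def test_duplicated_pair_identical_predictions(self, trained):
        model, ftr, _ = trained
        dup = ftr.subset(np.array([0, 0]))
        preds = w.predict(model, dup)
        assert preds[0] == preds[1]

    def test_batch_partition_invariance(self, trained):
        model, _, fte = trained
        a = w.predict(model, fte, batch_size=1)
        b = w.predict(model, fte, batch_size=len(fte))
        np.testing.assert_allclose(a, b, rtol=1e-9, atol=1e-9)

    def test_predictions_in_original_units(self, trained, featurized_small):
        model, ftr, _ = trained
        preds = w.predict(model, ftr)
        # trained on pKd-scale labels around beta0=5: predictions live there too
        assert 0.0 < preds.mean() < 12.0


class TestCheckpoint:
    def test_roundtrip_preserves_predictions(self, tmp_path, featurized_small):
        ftr, fte, train_ds, _ = featurized_small
        cfg = _config("gin", epochs=2)
        featurizer = w.PairFeaturizer(n=2).fit(train_ds)
        model, _ = w.train(w.DTAModel(cfg), ftr, cfg)
        w.save_checkpoint(tmp_path / "ckpt.npz", model, featurizer)
        loaded, loaded_feat = w.load_checkpoint(tmp_path / "ckpt.npz")
        np.testing.assert_array_equal(w.predict(model, fte), w.predict(loaded, fte))
        np.testing.assert_array_equal(
            loaded_feat.encoder.weights_.counts, featurizer.encoder.weights_.counts
        )
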