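"""Channel networks, fusion and predictor: shapes, identities, ablations."""

import numpy as np
import pytest

from mseddi import DrugFeatures, ModelConfig, MSEDDIModel
from mseddi._tensor import Tensor
from mseddi.molgraph import batch_graphs, smiles_to_molgraph
from mseddi.nn import BatchNorm1d, MLPBlock

DIM = 32
B = 6


@pytest.fixture(scope="module")
def rand_features():
    """Random (but seeded) per-drug inputs for 12 drugs."""
    rng = np.random.default_rng(0)
    smiles = ["CCO", "CCN", "CCC", "c1ccccc1", "CCOC", "NCCN",
              "ClCCCl", "OCCO", "CCS", "c1ccncc1", "CC(=O)O", "BrCC"]
    return DrugFeatures(
        kge=rng.normal(size=(12, DIM)).astype(np.float32),
        sne=rng.normal(size=(12, 100, DIM)).astype(np.float32),
        graphs=batch_graphs([smiles_to_molgraph(s) for s in smiles]),
    )


@pytest.fixture()
def model():
    m = MSEDDIModel(ModelConfig(dim=DIM, n_events=8, seed=0))
    m.eval()
    return m


IDX_I = np.arange(B)
IDX_J = np.arange(B, 2 * B)


class TestShapes:
    def test_channel_row_counts(self, model, rand_features):
        f = rand_features
        nc = model.network_channel(f.kge[IDX_I], f.kge[IDX_J])
        sc = model.sequence_channel(f.sne[IDX_I], f.sne[IDX_J])
        assert nc.shape == (B, 2, DIM)
        assert sc.shape == (B, 50, DIM)
        logits = model.forward_logits(IDX_I, IDX_J, f)
        assert logits.shape == (B, 8)

    def test_graph_channel_six_rows(self, model, rand_features):
        logits = model.forward_logits(IDX_I, IDX_J, rand_features)
        # row bookkeeping: predictor input width must be 58*dim
        assert model.predictor.lin1.W.shape[0] == 58 * DIM
        assert logits.shape == (B, 8)

    def test_flattened_width_at_paper_dim(self):
        m = MSEDDIModel(ModelConfig(dim=64, n_events=8, seed=0))
        assert m.predictor.lin1.W.shape[0] == 58 * 64 == 3712

    @pytest.mark.parametrize(
        "mask,rows",
        [(("network",), 2), (("sequence",), 50), (("graph",), 6),
         (("network", "graph"), 8)],
    )
    def test_channel_masks_change_stack_height(self, mask, rows, rand_features):
        m = MSEDDIModel(ModelConfig(dim=DIM, n_events=8, channel_mask=mask, seed=0))
        m.eval()
        assert m.cfg.n_rows == rows
        logits = m.forward_logits(IDX_I, IDX_J, rand_features)
        assert logits.shape == (B, 8)

    def test_empty_channel_mask_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(channel_mask=())

    def test_sequence_channel_wrong_length_rejected(self, model):
        bad = np.zeros((2, 60, DIM), dtype=np.float32)
        with pytest.raises(ValueError, match="100"):
            model.sequence_channel(bad, bad)


class TestMLPBlock:
    def _identity_block(self):
        rng = np.random.default_rng(0)
        blk = MLPBlock(4, 4, 4, rng, dtype=np.float64)
        blk.lin1.W.data = np.eye(4)
        blk.lin1.b.data[:] = 0
        blk.lin2.W.data = np.eye(4)
        blk.lin2.b.data[:] = 0
        blk.eval()  # running stats are (mean 0, var 1)
        return blk

    def test_identity_composition_on_positive_input(self):
        blk = self._identity_block()
        x = np.abs(np.random.default_rng(1).normal(size=(3, 4))) + 0.1
        out = blk(Tensor(x)).data
        np.testing.assert_allclose(out, x, atol=1e-4)

    def test_negative_preactivation_leaky_slope(self):
        blk = self._identity_block()
        x = -np.abs(np.random.default_rng(2).normal(size=(3, 4))) - 0.1
        out = blk(Tensor(x)).data
        np.testing.assert_allclose(out, 0.01 * x, atol=1e-4)

    def test_matches_composed_arithmetic(self):
        rng = np.random.default_rng(3)
        blk = MLPBlock(5, 6, 4, rng, dtype=np.float64)
        blk.train()
        x = rng.normal(size=(8, 5))
        out = blk(Tensor(x)).data
        z = x @ blk.lin1.W.data + blk.lin1.b.data
        mu, var = z.mean(axis=0), z.var(axis=0)
        zn = (z - mu) / np.sqrt(var + blk.bn.eps)
        zn = zn * blk.bn.gamma.data + blk.bn.beta.data
        act = np.where(zn > 0, zn, 0.01 * zn)
        expected = act @ blk.lin2.W.data + blk.lin2.b.data
        np.testing.assert_allclose(out, expected, atol=1e-10)

    def test_single_sample_training_batch_rejected(self):
        bn = BatchNorm1d(4)
        bn.training = True
        with pytest.raises(ValueError, match="single"):
            bn(Tensor(np.ones((1, 4), dtype=np.float32)))


class TestNetworkChannel:
    def test_equal_inputs_give_identical_rows(self, model, rand_features):
        h = rand_features.kge[IDX_I]
        out = model.network_channel(h, h).data
        np.testing.assert_array_equal(out[:, 0], out[:, 1])

    def test_swapping_drugs_swaps_rows(self, model, rand_features):
        hi, hj = rand_features.kge[IDX_I], rand_features.kge[IDX_J]
        out_ij = model.network_channel(hi, hj).data
        out_ji = model.network_channel(hj, hi).data
        np.testing.assert_array_equal(out_ij[:, 0], out_ji[:, 1])
        np.testing.assert_array_equal(out_ij[:, 1], out_ji[:, 0])


class TestSequenceChannel:
    def test_zeroed_feedforward_ablation(self, rand_features):
        """With the FFN output weights zeroed, LN(0) contributes only its
        (zero-initialized) shift: residual-off output is all zeros and
        residual-on output equals the convolutional block features."""
        f = rand_features
        cfg_on = ModelConfig(dim=DIM, n_events=8, use_residual=True, seed=4)
        cfg_off = ModelConfig(dim=DIM, n_events=8, use_residual=False, seed=4)
        m_on, m_off = MSEDDIModel(cfg_on), MSEDDIModel(cfg_off)
        for m in (m_on, m_off):
            m.eval()
            m.seq_ff2.W.data[:] = 0
            m.seq_ff2.b.data[:] = 0
        out_off = m_off.sequence_channel(f.sne[IDX_I], f.sne[IDX_J]).data
        np.testing.assert_allclose(out_off, 0.0, atol=1e-6)
        # residual-on output = s1 + 0, and s1 is the conv/pool block
        x = Tensor(np.concatenate([f.sne[IDX_I], f.sne[IDX_J]], axis=1))
        z = m_on.seq_bn(m_on.seq_conv(x))
        s1 = z.reshape(B, 50, 4, DIM).max(axis=2).leaky_relu().data
        out_on = m_on.sequence_channel(f.sne[IDX_I], f.sne[IDX_J]).data
        np.testing.assert_allclose(out_on, s1, atol=1e-6)


class TestGraphChannel:
    def test_variant_mlps_are_independent(self, model, rand_features):
        """Routing an embedding through a different variant's MLP changes
        the output: no weight sharing across variants."""
        rng = np.random.default_rng(5)
        e = {v: (Tensor(rng.normal(size=(3, DIM)).astype(np.float32)),
                 Tensor(rng.normal(size=(3, DIM)).astype(np.float32)))
             for v in ("mpnn", "weave", "afp")}
        out1 = model.graph_channel(e).data
        swapped = {"mpnn": e["weave"], "weave": e["mpnn"], "afp": e["afp"]}
        out2 = model.graph_channel(swapped).data
        assert np.abs(out1 - out2).max() > 1e-4

    def test_missing_variant_rejected(self, model):
        with pytest.raises(ValueError, match="afp"):
            model.graph_channel({"mpnn": None, "weave": None})

    def test_identity_kernel_conv_reduces_to_stack(self, rand_features):
        """Center-tap identity kernel and pass-through BN leave the graph
        channel equal to LeakyReLU of the per-variant MLP stack."""
        m = MSEDDIModel(ModelConfig(dim=DIM, n_events=8, seed=6))
        m.eval()
        for k, Wk in enumerate(m.cse_conv.W):
            Wk.data[:] = np.eye(DIM) if k == 1 else 0.0
        m.cse_conv.b.data[:] = 0
        rng = np.random.default_rng(6)
        e = {v: (Tensor(rng.normal(size=(3, DIM)).astype(np.float32)),
                 Tensor(rng.normal(size=(3, DIM)).astype(np.float32)))
             for v in ("mpnn", "weave", "afp")}
        out = m.graph_channel(e).data
        rows = []
        for v in ("mpnn", "weave", "afp"):
            from mseddi._tensor import concat
            both = m.cse_mlps[v](concat(list(e[v]), axis=0)).data
            rows.append(both[:3])
            rows.append(both[3:])
        stack = np.stack(rows, axis=1)
        # eval BN with fresh running stats (0, 1) is x / sqrt(1 + eps)
        stack = stack / np.sqrt(1 + m.cse_bn.eps)
        expected = np.where(stack > 0, stack, 0.01 * stack)
        np.testing.assert_allclose(out, expected, atol=1e-5)

    def test_no_conv_ablation_bypasses_convolution(self, rand_features):
        m = MSEDDIModel(ModelConfig(dim=DIM, n_events=8, use_graph_conv=False,
                                    seed=7))
        m.eval()
        rng = np.random.default_rng(7)
        e = {v: (Tensor(rng.normal(size=(2, DIM)).astype(np.float32)),
                 Tensor(rng.normal(size=(2, DIM)).astype(np.float32)))
             for v in ("mpnn", "weave", "afp")}
        out = m.graph_channel(e).data
        assert out.shape == (2, 6, DIM)


class TestFusionAndPredict:
    def test_probabilities_sum_to_one(self, model, rand_features):
        probs = model.predict_proba(IDX_I, IDX_J, rand_features)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_no_attention_variant_runs(self, rand_features):
        m = MSEDDIModel(ModelConfig(dim=DIM, n_events=8,
                                    use_fusion_attention=False, seed=8))
        m.eval()
        logits = m.forward_logits(IDX_I, IDX_J, rand_features)
        assert logits.shape == (B, 8)

    def test_no_channel_outputs_rejected(self, model):
        with pytest.raises(ValueError):
            model.fuse_and_predict([])


class TestDeterminism:
    def test_eval_forward_is_reproducible(self, model, rand_features):
        p1 = model.predict_proba(IDX_I, IDX_J, rand_features)
        p2 = model.predict_proba(IDX_I, IDX_J, rand_features)
        np.testing.assert_array_equal(p1, p2)

    def test_same_seed_same_model(self, rand_features):
        cfg = ModelConfig(dim=DIM, n_events=8, seed=9)
        m1, m2 = MSEDDIModel(cfg), MSEDDIModel(cfg)
        m1.eval(), m2.eval()
        np.testing.assert_array_equal(
            m1.predict_proba(IDX_I, IDX_J, rand_features),
            m2.predict_proba(IDX_I, IDX_J, rand_features),
        )

    def test_train_mode_forward_reproducible_without_dropout(self, rand_features):
        cfg = ModelConfig(dim=DIM, n_events=8, dropout=0.0, seed=10)
        m1, m2 = MSEDDIModel(cfg), MSEDDIModel(cfg)
        out1 = m1.forward_logits(IDX_I, IDX_J, rand_features).data
        out2 = m2.forward_logits(IDX_I, IDX_J, rand_features).data
        np.testing.assert_array_equal(out1, out2)
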