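"""Stage-1 multi-task network: contracts, gating, heads and losses."""

import math

import numpy as np
import pytest

from sonomil import mtl, nn
from sonomil.autograd import Tensor


@pytest.fixture(scope="module")
def conv_net():
    rng = np.random.default_rng(0)
    return mtl.MtlNet(mtl.TinyConvBackbone(rng), rng)


@pytest.fixture(scope="module")
def attn_net():
    rng = np.random.default_rng(1)
    return mtl.MtlNet(mtl.TinyAttentionBackbone(rng), rng)


def _outputs(net, seed=5, size=96, n=2):
    x = Tensor(np.random.default_rng(seed).uniform(0, 1, (n, 1, size, size)))
    return net(x)


class TestShapes:
    @pytest.mark.parametrize("which", ["conv", "attn"])
    def test_output_shape_contract(self, which, conv_net, attn_net):
        net = conv_net if which == "conv" else attn_net
        out = _outputs(net)
        c = net.backbone.channels
        assert out.z.shape == (2, c, 6, 6)
        assert out.s.shape == (2, c // 4, 24, 24)
        assert out.y_seg_hat.shape == (2, 1, 96, 96)
        assert np.all((out.y_seg_hat.data > 0) & (out.y_seg_hat.data < 1))
        assert np.all((out.y_cls_hat.data > 0) & (out.y_cls_hat.data < 1))
        assert np.all((out.y_mcls_hat.data > 0) & (out.y_mcls_hat.data < 1))

    def test_backbone_parameter_budget(self, conv_net, attn_net):
        assert conv_net.n_parameters() <= 2e5
        assert attn_net.n_parameters() <= 2e5

    def test_indivisible_image_size_rejected(self, conv_net):
        with pytest.raises(mtl.ContractError):
            conv_net(Tensor(np.zeros((1, 1, 90, 90))))

    def test_channel_mismatch_rejected(self):
        rng = np.random.default_rng(3)
        decoder = mtl.MaskDecoder(32, rng)
        with pytest.raises(mtl.ContractError):
            decoder(Tensor(np.zeros((1, 16, 6, 6))), (96, 96))


class TestMaskDecoder:
    def test_zero_token_map_gives_flat_half_probability(self):
        rng = np.random.default_rng(4)
        decoder = mtl.MaskDecoder(32, rng)
        for p in decoder.token_mlp.fc2.parameters():
            p.data[...] = 0.0
        z = Tensor(np.random.default_rng(5).normal(size=(1, 32, 6, 6)))
        _, _, y_seg = decoder(z, (96, 96))
        np.testing.assert_allclose(y_seg.data, 0.5)

    def test_single_pair_overfit(self, small_cohort):
        """Joint training memorizes one (image, mask) pair."""
        _, patients = small_cohort
        view = patients[0].views[0]
        img = Tensor(view.image[None, None])
        targets = mtl.MtlTargets(
            y_seg=view.mask[None].astype(float),
            y_mcls=np.array([1.0 if view.view_type == "node" else 0.0]),
            y_cls=np.array([float(patients[0].aln_status)]))
        rng = np.random.default_rng(6)
        net = mtl.MtlNet(mtl.TinyConvBackbone(rng), rng)
        opt = nn.AdamW(net.parameters(), lr=1e-2, weight_decay=0.0)
        first = None
        for _ in range(300):
            bundle = mtl.mtl_loss(net(img), targets)
            if first is None:
                first = bundle.l_seg.item()
            opt.zero_grad()
            bundle.total.backward()
            opt.step()
        assert bundle.l_seg.item() <= 0.1 * first


class TestGating:
    def test_annihilation(self, conv_net):
        out = _outputs(conv_net)
        zeros = Tensor(np.zeros_like(out.y_seg_hat.data))
        z_m, z_c = mtl.gate_features(out.z, out.s, zeros)
        assert np.all(z_m.data == 0.0)
        assert np.all(z_c.data == 0.0)

    def test_identity(self, conv_net):
        out = _outputs(conv_net)
        ones = Tensor(np.ones_like(out.y_seg_hat.data))
        z_m, z_c = mtl.gate_features(out.z, out.s, ones)
        np.testing.assert_array_equal(z_m.data, out.s.data)
        np.testing.assert_array_equal(z_c.data, out.z.data)

    def test_half_plane_attention_against_masked_average(self, conv_net):
        out = _outputs(conv_net, n=1)
        attn = np.zeros((1, 1, 96, 96))
        attn[:, :, :, :48] = 1.0        # left half-plane
        _, z_c = mtl.gate_features(out.z, out.s, Tensor(attn))
        # spatial mean of gated feature = mean of z restricted to the half
        direct = out.z.data[:, :, :, :3].sum(axis=(2, 3)) / (6 * 6)
        np.testing.assert_allclose(z_c.data.mean(axis=(2, 3)), direct,
                                   atol=1e-12)

    def test_gradient_flows_through_attention(self, conv_net):
        z = Tensor(np.random.default_rng(0).normal(size=(1, 32, 6, 6)))
        s = Tensor(np.random.default_rng(1).normal(size=(1, 8, 24, 24)))
        y = Tensor(np.random.default_rng(2).uniform(0.2, 0.8, (1, 1, 96, 96)),
                   requires_grad=True)
        z_m, z_c = mtl.gate_features(z, s, y)
        (z_m.sum() + z_c.sum()).backward()
        assert y.grad is not None and np.any(y.grad != 0)


class TestHeads:
    def test_constant_features_give_exact_logit(self):
        rng = np.random.default_rng(8)
        head = mtl.PoolLinearHead(4, rng)
        c = np.array([0.3, -1.2, 0.7, 2.0])
        feat = Tensor(np.broadcast_to(c[None, :, None, None],
                                      (1, 4, 5, 5)).copy())
        prob = head(feat).data[0]
        logit = float(c @ head.fc.weight.data[:, 0] + head.fc.bias.data[0])
        assert prob == pytest.approx(1.0 / (1.0 + math.exp(-logit)))

    def test_zero_features_give_sigmoid_bias(self):
        rng = np.random.default_rng(9)
        head = mtl.PoolLinearHead(6, rng)
        head.fc.bias.data[:] = 0.4
        prob = head(Tensor(np.zeros((3, 6, 4, 4)))).data
        np.testing.assert_allclose(prob, 1.0 / (1.0 + math.exp(-0.4)))

    def test_random_features_match_pool_then_linear(self):
        rng = np.random.default_rng(10)
        head = mtl.PoolLinearHead(5, rng)
        feat = rng.normal(size=(2, 5, 3, 3))
        prob = head(Tensor(feat)).data
        pooled = feat.mean(axis=(2, 3))
        logit = pooled @ head.fc.weight.data[:, 0] + head.fc.bias.data[0]
        np.testing.assert_allclose(prob, 1.0 / (1.0 + np.exp(-logit)),
                                   atol=1e-12)


class TestPseudoLabelsAndLoss:
    def test_pseudo_labels_broadcast(self):
        assert mtl.make_pseudo_labels(1, ["a", "b", "c"]) == [1, 1, 1]
        assert mtl.make_pseudo_labels(0, ["a", "b"]) == [0, 0]
        assert mtl.make_pseudo_labels(1, []) == []
        with pytest.raises(ValueError):
            mtl.make_pseudo_labels(2, ["a"])

    def test_bce_half_is_ln2(self):
        p = Tensor(np.array([0.5]))
        assert nn.binary_cross_entropy(p, np.array([1.0])).item() == \
            pytest.approx(math.log(2.0), abs=1e-9)

    def test_perfect_predictions_near_zero_loss(self, conv_net):
        out = _outputs(conv_net, n=1)
        fake = mtl.MtlOutputs(
            z=out.z, s=out.s,
            y_seg_hat=Tensor(np.ones_like(out.y_seg_hat.data)),
            z_m=out.z_m, z_c=out.z_c,
            y_mcls_hat=Tensor(np.array([1.0])),
            y_cls_hat=Tensor(np.array([1.0])))
        targets = mtl.MtlTargets(
            y_seg=np.ones((1, 96, 96)), y_mcls=np.array([1.0]),
            y_cls=np.array([1.0]))
        bundle = mtl.mtl_loss(fake, targets)
        assert bundle.total.item() < 1e-5

    def test_total_is_weighted_sum_of_components(self, conv_net):
        out = _outputs(conv_net)
        rng = np.random.default_rng(11)
        targets = mtl.MtlTargets(
            y_seg=rng.integers(0, 2, (2, 96, 96)).astype(float),
            y_mcls=np.array([1.0, 0.0]), y_cls=np.array([0.0, 1.0]))
        w = (0.7, 1.3, 2.1)
        bundle = mtl.mtl_loss(out, targets, weights=w)
        expect = (w[0] * bundle.l_seg.item() + w[1] * bundle.l_mcls.item()
                  + w[2] * bundle.l_cls.item())
        assert bundle.total.item() == pytest.approx(expect, rel=1e-12)

    def test_shape_mismatch_rejected(self, conv_net):
        out = _outputs(conv_net)
        targets = mtl.MtlTargets(y_seg=np.zeros((2, 48, 48)),
                                 y_mcls=np.zeros(2), y_cls=np.zeros(2))
        with pytest.raises(ValueError):
            mtl.mtl_loss(out, targets)


class TestShortcutSuppression:
    def test_perturbation_outside_attention_support_barely_moves_prediction(self):
        """With near-binary attention, pixels outside the predicted lesion
        cannot drive the metastasis head (features there are gated to ~0)."""
        rng = np.random.default_rng(12)
        net = mtl.MtlNet(mtl.TinyConvBackbone(rng), rng)
        img = np.random.default_rng(13).uniform(0.3, 0.7, (1, 1, 128, 128))
        attn = np.full((1, 1, 128, 128), 0.001)
        attn[:, :, 8:40, 8:40] = 1.0   # lesion support in the top-left corner
        def predict(arr):
            out = net(Tensor(arr))
            _, z_c = mtl.gate_features(out.z, out.s, Tensor(attn))
            return float(net.cls_head(z_c).data[0])
        base = predict(img)
        perturbed = img.copy()
        perturbed[:, :, 80:, 80:] = np.random.default_rng(14).uniform(
            0, 1, (1, 1, 48, 48))     # far outside the 31-px receptive field
        assert abs(predict(perturbed) - base) < 0.05
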