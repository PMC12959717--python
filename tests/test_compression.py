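"""Pruning, conv-BN fusion and INT8 quantization."""

import numpy as np
import pytest

from maarnet import nn
from maarnet.autograd import Tensor, no_grad
from maarnet.compression import (QuantSpec, apply_prune, build_prune_plan,
                                 calibrate_and_quantize, channel_importance_l2,
                                 conv_weight_bytes, dequantize_array,
                                 fuse_conv_bn, fuse_model, quantize_array)
from maarnet.model import MAARNet
from maarnet.profiling import count_params

from conftest import tiny_config


class TestChannelImportance:
    def test_orders_by_filter_norm(self):
        w = np.zeros((3, 1, 2, 2))
        w[0] += 3.0
        w[1] += 1.0
        w[2] += 2.0
        assert channel_importance_l2(w).tolist() == [0, 2, 1]

    def test_all_equal_norms_keep_identity_order(self):
        w = np.ones((4, 2, 3, 3))
        assert channel_importance_l2(w).tolist() == [0, 1, 2, 3]

    def test_matches_bruteforce_sort(self):
        rng = np.random.default_rng(0)
        w = rng.normal(size=(8, 3, 3, 3))
        norms = [float(np.sqrt((w[i] ** 2).sum())) for i in range(8)]
        expected = sorted(range(8), key=lambda i: (-norms[i], i))
        assert channel_importance_l2(w).tolist() == expected


class TestPrunePlan:
    def test_keep_ratio_one_is_a_noop_plan(self, tiny_model):
        from maarnet.compression import _prunable_sites
        widths = {s["name"]: s["conv"].out_channels
                  for s in _prunable_sites(tiny_model)}
        plan = build_prune_plan(tiny_model, keep_ratio=1.0, n_layers=3)
        for name, kept in plan.entries:
            assert len(kept) == widths[name]
            assert kept.tolist() == sorted(kept.tolist())

    def test_plan_selects_deepest_layers_first(self, tiny_model):
        from maarnet.compression import _prunable_sites
        all_names = [s["name"] for s in _prunable_sites(tiny_model)]
        plan = build_prune_plan(tiny_model, keep_ratio=0.5, n_layers=4)
        assert plan.layer_names() == list(reversed(all_names))[:4]

    def test_invalid_keep_ratio_rejected(self, tiny_model):
        for bad in (0.0, -0.5, 1.5):
            with pytest.raises(ValueError):
                build_prune_plan(tiny_model, keep_ratio=bad, n_layers=2)


class TestApplyPrune:
    def test_keep_ratio_one_outputs_bitwise_equal(self, tiny_model):
        tiny_model.eval()
        plan = build_prune_plan(tiny_model, keep_ratio=1.0, n_layers=5)
        pruned = apply_prune(tiny_model, plan)
        x = Tensor(np.random.default_rng(0).random((1, 3, 64, 64)))
        with no_grad():
            assert np.array_equal(pruned(x).logits.data,
                                  tiny_model(x).logits.data)

    def test_forward_shapes_preserved_after_pruning(self, tiny_model):
        plan = build_prune_plan(tiny_model, keep_ratio=0.5, n_layers=6)
        pruned = apply_prune(tiny_model, plan)
        pruned.eval()
        with no_grad():
            out = pruned(Tensor(np.zeros((1, 3, 64, 64))))
        assert out.logits.shape == (1, 2, 64, 64)

    def test_monotonic_in_keep_ratio(self, tiny_model):
        params = []
        for r in (0.3, 0.6, 0.9):
            pruned = apply_prune(
                tiny_model, build_prune_plan(tiny_model, r, n_layers=6))
            params.append(count_params(pruned))
        assert params[0] < params[1] < params[2] < count_params(tiny_model)

    def test_pruned_count_matches_closed_form_on_toy_net(self):
        # prune conv1 of one known block and predict the parameter change
        model = MAARNet(tiny_config(), seed=0)
        before = count_params(model)
        plan = build_prune_plan(model, keep_ratio=0.5, n_layers=1)
        name, kept = plan.entries[0]
        assert name == "refine2"
        c_in = model.refine2.conv.in_channels     # 12 kept of d2=12? -> ceil
        c_out = model.refine2.conv.out_channels
        removed = c_out - len(kept)
        # removed params: conv filters + BN affine pair + consumer in-channels
        consumer = model.final_refine.conv
        expected_drop = removed * (c_in * 9) + removed * 2 \
            + removed * (consumer.out_channels * consumer.kernel_size ** 2)
        after = count_params(apply_prune(model, plan))
        assert before - after == expected_drop

    def test_weak_channel_removal_hurts_less_than_strong(self):
        # single conv "network": pruning the weakest channel perturbs the
        # output less than pruning the strongest
        rng = np.random.default_rng(1)

        class Toy(nn.Module):
            def __init__(self):
                super().__init__()
                self.c1 = nn.Conv2d(2, 3, 3, padding=1, bias=False, rng=rng)
                self.c2 = nn.Conv2d(3, 1, 1, bias=False, rng=rng)

            def forward(self, x):
                return self.c2(self.c1(x))

        toy = Toy()
        toy.c1.weight.data[0] *= 5.0     # channel 0 dominant
        toy.c1.weight.data[2] *= 0.01    # channel 2 negligible
        x = Tensor(rng.normal(size=(1, 2, 8, 8)))
        with no_grad():
            full = toy(x).data.copy()
            deltas = {}
            for ch in (0, 2):
                saved = toy.c1.weight.data[ch].copy()
                toy.c1.weight.data[ch] = 0.0
                deltas[ch] = np.abs(toy(x).data - full).max()
                toy.c1.weight.data[ch] = saved
        assert deltas[2] < deltas[0]


class TestFusion:
    def test_identity_bn_leaves_conv_unchanged(self):
        conv = nn.Conv2d(3, 4, 3, padding=1, bias=False,
                         rng=np.random.default_rng(0))
        bn = nn.BatchNorm2d(4)
        bn.register_buffer("running_var", np.ones(4) - bn.eps)
        fused = fuse_conv_bn(conv, bn)
        np.testing.assert_allclose(fused.weight.data, conv.weight.data,
                                   rtol=1e-12)
        np.testing.assert_allclose(fused.bias.data, np.zeros(4), atol=1e-12)

    def test_random_conv_bn_agrees_with_fused(self):
        rng = np.random.default_rng(2)
        conv = nn.Conv2d(3, 5, 3, padding=1, bias=True, rng=rng)
        bn = nn.BatchNorm2d(5)
        bn.weight.data = rng.uniform(0.5, 1.5, 5)
        bn.bias.data = rng.normal(size=5)
        bn.register_buffer("running_mean", rng.normal(size=5))
        bn.register_buffer("running_var", rng.uniform(0.5, 2.0, 5))
        bn.eval()
        fused = fuse_conv_bn(conv, bn)
        x = Tensor(rng.normal(size=(2, 3, 6, 6)))
        with no_grad():
            np.testing.assert_allclose(fused(x).data, bn(conv(x)).data,
                                       atol=1e-5)

    def test_fusion_equivalence_across_whole_network(self, tiny_model):
        # exercise every conv-BN pair in the assembled model at once
        tiny_model.eval()
        # make BN statistics non-trivial first
        tiny_model.train()
        x = Tensor(np.random.default_rng(3).random((2, 3, 64, 64)))
        tiny_model(x)
        tiny_model.eval()
        fused = fuse_model(tiny_model)
        with no_grad():
            a = tiny_model(x).logits.data
            b = fused(x).logits.data
        np.testing.assert_allclose(a, b, atol=1e-4)

    def test_fusion_removes_bn_from_profile(self, tiny_model):
        from maarnet.profiling import profile
        before = profile(tiny_model, (3, 64, 64))
        after = profile(fuse_model(tiny_model), (3, 64, 64))
        n_bn_before = sum(1 for e in before.per_layer if e.kind == "batchnorm")
        n_bn_after = sum(1 for e in after.per_layer if e.kind == "batchnorm")
        assert n_bn_before > 0
        # only the standalone spatial BN of DSCBAM pairs is fused too; all
        # conv-adjacent BNs disappear
        assert n_bn_after == 0


class TestQuantization:
    def test_symmetric_weight_example(self):
        w = np.array([1.27, -0.5, 0.01])
        spec = QuantSpec.symmetric(w)
        assert spec.scale == pytest.approx(0.01)
        assert quantize_array(w, spec)[0] == 127

    def test_roundtrip_error_bounded_by_half_scale(self):
        rng = np.random.default_rng(4)
        w = rng.uniform(-1, 1, size=1000)
        spec = QuantSpec.symmetric(w)
        back = dequantize_array(quantize_array(w, spec), spec)
        assert np.abs(back - w).max() <= spec.scale / 2 + 1e-12

    def test_affine_activation_roundtrip_within_range(self):
        rng = np.random.default_rng(5)
        v = rng.uniform(0.2, 3.0, size=500)
        spec = QuantSpec.from_range(v.min(), v.max())
        back = dequantize_array(quantize_array(v, spec), spec)
        assert np.abs(back - v).max() <= spec.scale / 2 + 1e-12

    def test_constant_activation_gets_guarded_scale(self):
        spec = QuantSpec.from_range(0.7, 0.7)
        assert spec.scale > 0

    def test_empty_calibration_set_rejected(self, tiny_model):
        with pytest.raises(ValueError, match="calibration"):
            calibrate_and_quantize(tiny_model, [])

    def test_quantized_weights_quarter_the_bytes(self, tiny_model):
        calib = [np.random.default_rng(6).random((1, 3, 64, 64))
                 for _ in range(2)]
        qmodel = calibrate_and_quantize(tiny_model, calib, quantize_gates=True)
        fb = conv_weight_bytes(tiny_model)
        qb = conv_weight_bytes(qmodel)
        assert fb / qb == pytest.approx(4.0, rel=0.05)

    def test_gate_convs_stay_float_by_default(self, tiny_model):
        from maarnet.blocks import DSCAM
        from maarnet.compression import QuantizedConv2d
        calib = [np.random.default_rng(6).random((1, 3, 64, 64))]
        qmodel = calibrate_and_quantize(tiny_model, calib)
        for _, mod in qmodel.named_modules():
            if isinstance(mod, DSCAM):
                assert type(mod.dw) is nn.Conv2d and type(mod.pw) is nn.Conv2d
        assert any(isinstance(m, QuantizedConv2d) for m in qmodel.modules())
        # still clearly smaller overall (gates are a sizeable weight share
        # only at these toy widths)
        assert conv_weight_bytes(tiny_model) / conv_weight_bytes(qmodel) > 2.5

    def test_quantized_model_runs_and_stays_close(self, tiny_model):
        rng = np.random.default_rng(7)
        tiny_model.train()
        x = Tensor(rng.random((2, 3, 64, 64)))
        tiny_model(x)  # populate BN statistics
        tiny_model.eval()
        calib = [rng.random((1, 3, 64, 64)) for _ in range(4)]
        qmodel = calibrate_and_quantize(tiny_model, calib)
        with no_grad():
            a = tiny_model(x).logits.data
            b = qmodel(x).logits.data
        # loose closeness on raw logits; the task-level bound lives in the
        # acceptance suite (IoU degradation on the trained model)
        assert np.abs(a - b).max() < 0.5
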