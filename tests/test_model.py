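"""Network assembly: shape contracts, pyramid structure, ablation variants."""

import numpy as np
import pytest

from maarnet import nn
from maarnet.autograd import Tensor, no_grad
from maarnet.model import MAARNet, NetworkConfig
from maarnet.profiling import count_params

from conftest import tiny_config


def _rand_input(shape, seed=0):
    return Tensor(np.random.default_rng(seed).random(shape))


class TestEncode:
    @pytest.mark.parametrize("size, expected", [(64, (32, 16, 8, 4, 2)),
                                                (128, (64, 32, 16, 8, 4))])
    def test_pyramid_stride_arithmetic(self, tiny_model, size, expected):
        tiny_model.eval()
        with no_grad():
            pyr = tiny_model.encode(_rand_input((1, 3, size, size)))
        for stride, sz in zip((2, 4, 8, 16, 32), expected):
            assert pyr[stride].shape[2:] == (sz, sz)
        widths = tiny_model.config.stage_widths
        assert [pyr[s].shape[1] for s in (2, 4, 8, 16)] == list(widths)
        assert pyr[32].shape[1] == tiny_model.config.high_semantic_width

    def test_indivisible_input_rejected_with_padding_hint(self, tiny_model):
        with pytest.raises(ValueError, match="pad by"):
            tiny_model.encode(_rand_input((1, 3, 48, 48)))

    def test_constant_input_context_equals_map_average(self, tiny_model):
        tiny_model.eval()
        with no_grad():
            x = Tensor(np.full((1, 3, 64, 64), 0.5))
            pyr = tiny_model.encode(x)
        # the context vector is the GAP of the stride-32 map before enrichment;
        # reconstruct that map by subtracting the broadcast context output
        with no_grad():
            enrich = tiny_model.context(pyr.global_context)
        pre = pyr[32].data - enrich.data
        np.testing.assert_allclose(pyr.global_context.data[0, :, 0, 0],
                                   pre.mean(axis=(2, 3))[0], atol=1e-10)


class TestAttendSkips:
    def test_disabled_attention_is_identity(self):
        model = MAARNet(tiny_config(enable_skip_attention=False), seed=0).eval()
        with no_grad():
            pyr = model.encode(_rand_input((1, 3, 64, 64)))
            att = model.attend_skips(pyr)
        for s in (2, 4, 8, 16, 32):
            assert att[s] is pyr[s]

    def test_zero_weight_attention_halves_every_map(self, tiny_model):
        for name in ("att2", "att4", "att8", "att16", "att32"):
            att = getattr(tiny_model, name)
            for p in att.parameters():
                p.data = np.zeros_like(p.data)
            for mod in att.modules():
                if isinstance(mod, nn.BatchNorm2d):
                    mod.weight.data = np.ones_like(mod.weight.data)
                    mod.register_buffer("running_mean",
                                        np.zeros_like(mod.running_mean))
                    mod.register_buffer("running_var",
                                        np.ones_like(mod.running_var) - mod.eps)
        tiny_model.eval()
        with no_grad():
            pyr = tiny_model.encode(_rand_input((1, 3, 64, 64)))
            att = tiny_model.attend_skips(pyr)
        for s in (2, 4, 8, 16, 32):
            np.testing.assert_allclose(att[s].data, 0.5 * pyr[s].data,
                                       rtol=1e-6)

    def test_shapes_unchanged(self, tiny_model):
        tiny_model.eval()
        with no_grad():
            pyr = tiny_model.encode(_rand_input((1, 3, 64, 64)))
            att = tiny_model.attend_skips(pyr)
        for s in (2, 4, 8, 16, 32):
            assert att[s].shape == pyr[s].shape


class TestDecode:
    @pytest.mark.parametrize("size", [64, 96])
    def test_logits_at_full_resolution(self, tiny_model, size):
        tiny_model.eval()
        with no_grad():
            out = tiny_model(_rand_input((1, 3, size, size)))
        assert out.logits.shape == (1, tiny_model.config.num_classes, size, size)

    def test_no_transposed_convolutions_anywhere(self, tiny_model):
        kinds = [type(m) for m in tiny_model.modules()]
        assert nn.ConvTranspose2d not in kinds

    def test_missing_pyramid_scale_rejected(self, tiny_model):
        tiny_model.eval()
        with no_grad():
            pyr = tiny_model.encode(_rand_input((1, 3, 64, 64)))
        del pyr.maps[8]
        with pytest.raises(ValueError, match="stride-8"):
            tiny_model.decode(pyr)


class TestAuxBranch:
    def test_concat_width_is_sum_of_map_channels(self, tiny_model):
        cfg = tiny_model.config
        expected = (sum(cfg.stage_widths) + cfg.high_semantic_width
                    + cfg.final_width)
        assert tiny_model.aux_head.in_channels == expected

    def test_aux_logits_full_resolution_in_training(self, tiny_model):
        tiny_model.train()
        out = tiny_model(_rand_input((1, 3, 64, 64)))
        assert out.aux_logits is not None
        assert out.aux_logits.shape == out.logits.shape

    def test_aux_branch_refuses_inference_mode(self, tiny_model):
        tiny_model.eval()
        with no_grad():
            pyr = tiny_model.attend_skips(
                tiny_model.encode(_rand_input((1, 3, 64, 64))))
            logits, feats = tiny_model.decode(pyr, return_features=True)
        with pytest.raises(RuntimeError, match="training-only"):
            tiny_model.aux_branch(pyr, feats)

    def test_inference_params_identical_with_aux_on_or_off(self):
        on = MAARNet(tiny_config(enable_aux=True), seed=0)
        off = MAARNet(tiny_config(enable_aux=False), seed=0)
        assert count_params(on) == count_params(off)

    def test_inference_logits_bitwise_equal_with_aux_toggled(self):
        on = MAARNet(tiny_config(enable_aux=True), seed=0)
        off = MAARNet(tiny_config(enable_aux=False), seed=0)
        off.load_state_dict({k: v for k, v in on.state_dict().items()
                             if not k.startswith("aux_head")})
        x = _rand_input((1, 3, 64, 64))
        on.eval(), off.eval()
        with no_grad():
            a, b = on(x), off(x)
        assert np.array_equal(a.logits.data, b.logits.data)
        assert a.aux_logits is None and b.aux_logits is None


class TestForward:
    def test_eval_forward_is_deterministic(self, tiny_model):
        tiny_model.eval()
        x = _rand_input((2, 3, 64, 64))
        with no_grad():
            a = tiny_model(x).logits.data
            b = tiny_model(x).logits.data
        assert np.array_equal(a, b)

    @pytest.mark.parametrize("hs, att, aux", [
        (False, False, False), (True, False, False), (False, True, False),
        (False, False, True), (True, True, False), (True, False, True),
        (False, True, True), (True, True, True),
    ])
    def test_all_eight_ablation_variants_build_and_run(self, hs, att, aux):
        cfg = tiny_config(enable_high_semantic=hs, enable_skip_attention=att,
                          enable_aux=aux)
        model = MAARNet(cfg, seed=0)
        model.train()
        out = model(_rand_input((1, 3, 64, 64)))
        assert out.logits.shape == (1, 2, 64, 64)
        assert (out.aux_logits is not None) == aux
        model.eval()
        with no_grad():
            out = model(_rand_input((1, 3, 64, 64)))
        assert out.aux_logits is None

    def test_config_roundtrips_through_dict(self):
        cfg = tiny_config(enable_aux=False)
        assert NetworkConfig.from_dict(cfg.to_dict()) == cfg

    def test_config_validation(self):
        with pytest.raises(ValueError):
            NetworkConfig(stage_widths=(8, 16, 24))
        with pytest.raises(ValueError):
            NetworkConfig(decoder_widths=(0, 1, 2, 3))
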