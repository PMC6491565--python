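"""Group block construction, parameter counting, and the built networks."""

import numpy as np
import pytest

from groupnet import (
    GroupBlockSpec,
    GroupNetwork,
    NetworkSpec,
    build_group_block,
    build_groupnet,
    count_conv_params,
    grouped_weight_count,
    ungrouped_weight_count,
)
from groupnet.exceptions import ConfigError, ValidationError
from groupnet.nnet import Activation, Conv1d, Sequential


def reference_conv_same(x, weight, bias):
    """Direct-loop 'same' correlation: the independent oracle for Conv1d."""
    b_sz, c_in, length = x.shape
    c_out, _, k = weight.shape
    pad = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
    y = np.zeros((b_sz, c_out, length))
    for b in range(b_sz):
        for o in range(c_out):
            for pos in range(length):
                y[b, o, pos] = (
                    np.sum(weight[o] * xp[b, :, pos : pos + k]) + bias[o]
                )
    return y


class TestGroupBlockSpec:
    def test_named_configuration(self):
        spec = GroupBlockSpec(partitions=(2, 2), cluster_layers=1)
        assert spec.L == 2
        assert spec.describe() == "{2, 2, 2, 1}"
        spec3 = GroupBlockSpec(partitions=(2, 3, 3), kernels_per_layer=(6, 9, 9))
        assert spec3.describe() == "{3, 2, 3, 3, 1}"

    def test_validation(self):
        with pytest.raises(ConfigError):
            GroupBlockSpec(kernel_size=4)
        with pytest.raises(ConfigError):
            GroupBlockSpec(partitions=(3,), kernels_per_layer=(8,))  # 8 % 3
        with pytest.raises(ConfigError):
            GroupBlockSpec(partitions=(), kernels_per_layer=())


class TestParameterCounting:
    def test_two_layer_even_split_ratio_half(self):
        grouped = grouped_weight_count(4, 8, 3, 2)
        ungrouped = ungrouped_weight_count(4, 8, 3)
        assert (grouped, ungrouped) == (48, 96)
        assert grouped / ungrouped == 0.5

    def test_no_grouping_ratio_one(self):
        assert grouped_weight_count(4, 8, 3, 1) == ungrouped_weight_count(4, 8, 3)

    @pytest.mark.parametrize("g", [1, 2, 3, 4])
    def test_ratio_one_over_g_by_block_enumeration(self, g):
        m = n = 12
        spec = GroupBlockSpec(
            partitions=(g, g), kernels_per_layer=(m, n), cluster_layers=0
        )
        layers = build_group_block(spec, input_channels=1)
        convs = [l for l in layers if isinstance(l, Conv1d)]
        second_layer_weights = convs[1].params["weight"].size
        assert second_layer_weights == grouped_weight_count(m, n, 3, g)
        assert second_layer_weights * g == ungrouped_weight_count(m, n, 3)
        counts = count_conv_params(spec)
        assert counts == [c.params["weight"].size for c in convs]

    def test_cluster_layer_counted(self):
        spec = GroupBlockSpec(
            partitions=(2, 2), kernels_per_layer=(8, 8),
            cluster_layers=1, cluster_channels=16,
        )
        counts = count_conv_params(spec)
        assert counts[-1] == 16 * 8  # 1x1 kernels mix all channels

    def test_indivisible_channels_names_layer(self):
        spec = GroupBlockSpec(partitions=(2, 3), kernels_per_layer=(8, 9))
        with pytest.raises(ConfigError, match="layer 2"):
            build_group_block(spec, input_channels=1)


class TestGroupBlockForward:
    def test_degenerate_block_equals_plain_conv_stack(self, rng):
        # partitions all 1, no cluster layer: must match a direct-loop
        # convolution stack given identical weights
        spec = GroupBlockSpec(
            partitions=(1, 1), kernels_per_layer=(4, 6), cluster_layers=0
        )
        layers = build_group_block(spec, 1, "tanh", rng)
        x = rng.normal(size=(3, 1, 20))
        out = Sequential(layers).forward(x)
        ref = x
        for layer in layers:
            if isinstance(layer, Conv1d):
                ref = reference_conv_same(ref, layer.params["weight"], layer.params["bias"])
            else:
                ref = np.tanh(ref)
        assert np.allclose(out, ref, atol=1e-10)

    def test_grouped_forward_matches_blockwise_oracle(self, rng):
        # a G=2 grouped layer equals two independent half-size convolutions
        conv = Conv1d(4, 6, 3, groups=2, rng=rng)
        x = rng.normal(size=(2, 4, 15))
        y = conv.forward(x)
        w = conv.params["weight"]
        top = reference_conv_same(x[:, :2], w[:3], conv.params["bias"][:3])
        bot = reference_conv_same(x[:, 2:], w[3:], conv.params["bias"][3:])
        assert np.allclose(y, np.concatenate([top, bot], axis=1), atol=1e-10)

    @pytest.mark.parametrize(
        "partitions,kernels,j",
        [((2, 2), (8, 8), 1), ((2, 4, 4), (8, 8, 8), 2), ((1,), (5,), 0)],
    )
    def test_length_preserved(self, partitions, kernels, j, rng):
        spec = GroupBlockSpec(
            partitions=partitions, kernels_per_layer=kernels, cluster_layers=j,
            cluster_channels=8,
        )
        layers = build_group_block(spec, 1, "relu", rng)
        y = Sequential(layers).forward(rng.normal(size=(2, 1, 62)))
        assert y.shape[2] == 62


class TestBuiltNetworks:
    def test_lp_outputs_are_probabilities(self, tiny_net_spec, rng):
        net = build_groupnet(tiny_net_spec("LP"), seed=0)
        p = net.predict(rng.normal(size=(5, 62)))
        assert p.shape == (5, 8)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_br_outputs_are_positive_probabilities(self, tiny_net_spec, rng):
        net = build_groupnet(tiny_net_spec("BR"), seed=0)
        p = net.predict(rng.normal(size=(5, 62)))
        assert p.shape == (5, 3)
        assert ((p >= 0) & (p <= 1)).all()

    def test_same_seed_same_initial_weights(self, tiny_net_spec):
        a = build_groupnet(tiny_net_spec("BR"), seed=4)
        b = build_groupnet(tiny_net_spec("BR"), seed=4)
        assert a.weights_checksum() == b.weights_checksum()
        c = build_groupnet(tiny_net_spec("BR"), seed=5)
        assert a.weights_checksum() != c.weights_checksum()

    def test_prediction_deterministic_with_dropout_off(self, tiny_net_spec, rng):
        net = build_groupnet(tiny_net_spec("LP", dropout_rate=0.5), seed=1)
        x = rng.normal(size=(4, 62))
        assert np.array_equal(net.predict(x), net.predict(x))

    def test_untrained_lp_probabilities_near_uniform(self, tiny_net_spec, rng):
        net = build_groupnet(tiny_net_spec("LP"), seed=2)
        p = net.predict(rng.normal(size=(50, 62)))
        assert np.abs(p - 1 / 8).max() < 0.2

    def test_feature_width_checked(self, tiny_net_spec):
        net = build_groupnet(tiny_net_spec("LP"), seed=0)
        with pytest.raises(ValidationError):
            net.predict(np.zeros((3, 40)))

    def test_br_heads_have_disjoint_parameters(self, tiny_net_spec):
        net = build_groupnet(tiny_net_spec("BR"), seed=0)
        seen: set[int] = set()
        for sub in net.nets:
            for layer, key in sub.parameters():
                ident = id(layer.params[key])
                assert ident not in seen
                seen.add(ident)

    def test_pool_too_large_rejected(self, tiny_net_spec):
        with pytest.raises(ConfigError):
            tiny_net_spec("LP", pool_size=100)

    def test_parameter_count_br_is_three_lp_heads(self, tiny_net_spec):
        lp = build_groupnet(tiny_net_spec("LP"), seed=0)
        br = build_groupnet(tiny_net_spec("BR"), seed=0)
        lp_tail_out = 8 * (16 + 1)  # 8-way head vs 2-way head on fc=16
        br_tail_out = 2 * (16 + 1)
        assert br.parameter_count() == 3 * (lp.parameter_count() - lp_tail_out + br_tail_out)


class TestWeightSerialisation:
    def test_roundtrip(self, tiny_net_spec, tmp_path, rng):
        net = build_groupnet(tiny_net_spec("BR"), seed=6)
        path = tmp_path / "w.npz"
        net.save_weights(path)
        back = GroupNetwork.load_weights(path, expected_spec=net.spec)
        x = rng.normal(size=(4, 62))
        assert np.array_equal(net.predict(x), back.predict(x))

    def test_config_hash_mismatch(self, tiny_net_spec, tmp_path):
        net = build_groupnet(tiny_net_spec("BR"), seed=6)
        path = tmp_path / "w.npz"
        net.save_weights(path)
        other = tiny_net_spec("BR", fc_units=32)
        with pytest.raises(ConfigError, match="config-hash"):
            GroupNetwork.load_weights(path, expected_spec=other)

    def test_tampered_weights_detected(self, tiny_net_spec, tmp_path):
        net = build_groupnet(tiny_net_spec("LP"), seed=6)
        path = tmp_path / "w.npz"
        net.save_weights(path)
        with np.load(path) as data:
            arrays = {k: data[k] for k in data.files}
        key = next(k for k in arrays if k.endswith("weight"))
        arrays[key] = arrays[key] + 1.0
        np.savez(path, **arrays)
        with pytest.raises(ConfigError, match="checksum"):
            GroupNetwork.load_weights(path)
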