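"""SubNet blocks, series/parallel composition, freezing and accounting."""

import numpy as np
import pytest
from scipy import ndimage

from gramnet import nn
from gramnet.gramnet_core import (
    SUBNET_PRESETS,
    ClassificationHead,
    Minibatch,
    SubNetSpec,
    build_subnet,
    combine_parallel,
    combine_series,
    count_madd,
    count_parameters,
    forward_with_head,
    frozen_state_hash,
    graph_from_subnet,
    load_graph,
    one_hot,
    save_graph,
)


def _oracle_subnet_forward(subnet, x):
    """Independent layer-by-layer evaluation: scipy correlation + explicit
    ReLU and 2x2 block max pooling (even input dims only)."""
    h = x.astype(np.float64)
    li = 0
    layers = subnet.layers.layers
    for (kh, kw, nf), pooled in zip(subnet.spec.layer_groups, subnet.spec.pool_flags):
        conv = layers[li]
        li += 1
        n, cin, hh, ww = h.shape
        out = np.zeros((n, nf, hh, ww))
        for b in range(n):
            for co in range(nf):
                for ci in range(cin):
                    out[b, co] += ndimage.correlate(
                        h[b, ci], conv.weight.data[co, ci].astype(np.float64),
                        mode="constant")
                out[b, co] += conv.bias.data[co]
        h = np.maximum(out, 0.0)
        li += 1  # ReLU layer
        if pooled:
            li += 1
            n, c, hh, ww = h.shape
            h = h.reshape(n, c, hh // 2, 2, ww // 2, 2).max(axis=(3, 5))
    return h


class TestBuildSubnet:
    def test_preset_a_shape_arithmetic(self, rng):
        sub = build_subnet(SUBNET_PRESETS["A"], in_channels=1, seed=0)
        out = sub.forward(rng.random((2, 1, 32, 32)).astype(np.float32))
        assert out.shape == (2, 32, 4, 4)  # three pooling steps: 32 -> 4

    def test_relu_nonnegative(self, rng):
        sub = build_subnet(SUBNET_PRESETS["E"], in_channels=1, seed=1)
        out = sub.forward(rng.normal(size=(1, 1, 16, 16)).astype(np.float32))
        assert np.all(out >= 0)

    def test_zero_weights_give_zero_output(self, rng):
        spec = SubNetSpec("Z", ((3, 3, 4),), use_batchnorm=False)
        sub = build_subnet(spec, 1, seed=0)
        for p in sub.parameters():
            p.data[...] = 0
        out = sub.forward(rng.normal(size=(1, 1, 8, 8)).astype(np.float32))
        np.testing.assert_array_equal(out, 0.0)

    def test_deterministic_initialization(self):
        a = build_subnet(SUBNET_PRESETS["B"], 32, seed=5)
        b = build_subnet(SUBNET_PRESETS["B"], 32, seed=5)
        for pa, pb in zip(a.parameters(), b.parameters()):
            assert np.array_equal(pa.data, pb.data)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            SubNetSpec("X", ())
        with pytest.raises(ValueError):
            SubNetSpec("X", ((0, 3, 4),))

    def test_oracle_equivalence_small_instances(self, rng):
        """im2col path equals independent scipy evaluation on small inputs."""
        for trial in range(5):
            spec = SubNetSpec("T", ((3, 3, 3), (1, 3, 5)), use_batchnorm=False)
            sub = build_subnet(spec, 2, seed=trial)
            x = rng.normal(size=(2, 2, 8, 8)).astype(np.float32)
            np.testing.assert_allclose(sub.forward(x),
                                       _oracle_subnet_forward(sub, x),
                                       rtol=1e-4, atol=1e-5)


class TestHeadAndSoftmax:
    def test_rows_sum_to_one(self, rng):
        sub = build_subnet(SUBNET_PRESETS["A"], 1, seed=0)
        g = graph_from_subnet(sub, 3, seed=1)
        batch = Minibatch(rng.random((4, 32, 32, 1)),
                          one_hot(["a", "b", "c", "a"], ["a", "b", "c"]))
        probs = forward_with_head(g, batch)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all((probs >= 0) & (probs <= 1))

    def test_zero_head_gives_uniform(self, rng):
        sub = build_subnet(SUBNET_PRESETS["A"], 1, seed=0)
        g = graph_from_subnet(sub, 4, seed=1)
        g.head.fc.weight.data[...] = 0
        g.head.fc.bias.data[...] = 0
        batch = Minibatch(rng.random((2, 32, 32, 1)),
                          one_hot(["a", "b"], ["a", "b", "c", "d"]))
        np.testing.assert_allclose(forward_with_head(g, batch), 0.25, atol=1e-6)

    def test_two_class_scalar_softmax(self):
        a, b = 1.3, -0.4
        p = nn.softmax(np.array([[a, b]]))
        assert p[0, 0] == pytest.approx(np.exp(a) / (np.exp(a) + np.exp(b)))

    def test_minibatch_requires_one_hot(self):
        with pytest.raises(ValueError):
            Minibatch(np.zeros((1, 4, 4, 1)), np.array([[0.5, 0.5]]))


class TestCombineSeries:
    def _ab_graph(self):
        a = build_subnet(SUBNET_PRESETS["A"], 1, seed=0)
        g = graph_from_subnet(a, 2, seed=1)
        b = build_subnet(SUBNET_PRESETS["B"], a.out_channels, seed=2)
        return a, b, combine_series(g, b, seed=3)

    def test_total_layer_count(self):
        a, b, g = self._ab_graph()
        assert g.conv_layer_count == 6
        assert g.total_layers == 7  # L = L_A + L_B + 1

    def test_base_becomes_frozen(self):
        a, b, g = self._ab_graph()
        assert a.frozen and not b.frozen
        assert g.trainable_subnets() == [b]

    def test_forward_equals_manual_composition(self, rng):
        a, b, g = self._ab_graph()
        x = rng.random((2, 1, 32, 32)).astype(np.float32)
        manual = g.head.forward(b.forward(a.forward(x)))
        np.testing.assert_allclose(g.forward_logits(x), manual, rtol=1e-6)

    def test_channel_mismatch_rejected(self):
        a = build_subnet(SUBNET_PRESETS["A"], 1, seed=0)
        g = graph_from_subnet(a, 2, seed=1)
        wrong = build_subnet(SUBNET_PRESETS["B"], 7, seed=2)
        with pytest.raises(ValueError, match="channel"):
            combine_series(g, wrong)


class TestCombineParallel:
    def _abc_graph(self):
        a = build_subnet(SUBNET_PRESETS["A"], 1, seed=0)
        g = graph_from_subnet(a, 2, seed=1)
        b = build_subnet(SUBNET_PRESETS["B"], 32, seed=2)
        g = combine_series(g, b, seed=3)
        c = build_subnet(SUBNET_PRESETS["C"], 1, seed=4)
        return c, combine_parallel(g, c, seed=5)

    def test_concatenated_depth(self, rng):
        c, g = self._abc_graph()
        x = rng.random((2, 1, 32, 32)).astype(np.float32)
        feats = g.forward_features(x)
        assert feats.shape[1] == 256 + 32  # 288-channel concatenation

    def test_new_branch_reads_raw_input(self, rng):
        c, g = self._abc_graph()
        x = rng.random((2, 1, 32, 32)).astype(np.float32)
        feats = g.forward_features(x)
        # the last 32 channels equal SubNet C applied to the raw input,
        # average-pooled to the common spatial size
        c_out = c.forward(x)
        th, tw = feats.shape[2], feats.shape[3]
        pooled = nn.AvgPoolTo(th, tw).forward(c_out)
        np.testing.assert_allclose(feats[:, 256:], pooled, rtol=1e-5, atol=1e-6)

    def test_wrong_input_channels_rejected(self):
        _, g = self._abc_graph()
        bad = build_subnet(SUBNET_PRESETS["D"], 5, seed=0)
        with pytest.raises(ValueError, match="raw input"):
            combine_parallel(g, bad)


class TestFreezing:
    def test_frozen_parameters_bit_stable_under_training_step(self, rng):
        from gramnet.gramnet_train import StageTrainConfig, train_stage

        a = build_subnet(SUBNET_PRESETS["A"], 1, seed=0)
        g = graph_from_subnet(a, 2, seed=1)
        b = build_subnet(SUBNET_PRESETS["B"], 32, seed=2)
        g = combine_series(g, b, seed=3)
        x = rng.random((12, 16, 16, 1)).astype(np.float32)
        y = one_hot(["p", "n"] * 6, ["p", "n"])
        before = frozen_state_hash(g)
        train_stage(g, (x[:8], y[:8]), (x[8:], y[8:]),
                    StageTrainConfig(epochs=2, batch_size=4))
        assert frozen_state_hash(g) == before

    def test_optimizer_group_excludes_frozen(self):
        a = build_subnet(SUBNET_PRESETS["A"], 1, seed=0)
        g = graph_from_subnet(a, 2, seed=1)
        b = build_subnet(SUBNET_PRESETS["B"], 32, seed=2)
        g = combine_series(g, b, seed=3)
        trainable = g.trainable_subnets()[0].parameters() + g.head.parameters()
        frozen = [p for s in g.frozen_subnets() for p in s.parameters()]
        assert not set(id(p) for p in trainable) & set(id(p) for p in frozen)


class TestAccounting:
    def test_single_conv_parameter_count(self, rng):
        conv = nn.Conv2d(1, 8, 3, 3, rng)
        assert count_parameters([conv]) == 3 * 3 * 1 * 8 + 8 == 80

    def test_empty_list_is_zero(self):
        assert count_parameters([]) == 0

    def test_subnet_b_conv_stack_matches_printed_total(self):
        """B's conv weights+biases with a 32-channel input: 387,520 scalars,
        within 1% of the 0.390 M reference value."""
        spec = SubNetSpec("B", SUBNET_PRESETS["B"].layer_groups, use_batchnorm=False)
        sub = build_subnet(spec, in_channels=32, seed=0)
        n = count_parameters(sub)
        assert n == 387_520
        assert abs(n - 390_000) / 390_000 < 0.01

    def test_madd_one_by_one_conv(self, rng):
        conv = nn.Conv2d(1, 1, 1, 1, rng)
        assert count_madd(conv, (1, 4, 4)) == 16

    def test_madd_quadruples_with_doubled_dims(self):
        sub = build_subnet(SUBNET_PRESETS["A"], 1, seed=0)
        assert count_madd(sub, (1, 32, 32)) == 4 * count_madd(sub, (1, 16, 16))

    def test_madd_zero_channels(self):
        sub = build_subnet(SUBNET_PRESETS["A"], 1, seed=0)
        assert count_madd(sub, (0, 8, 8)) == 0

    def test_graph_madd_includes_head(self):
        sub = build_subnet(SUBNET_PRESETS["A"], 1, seed=0)
        g = graph_from_subnet(sub, 2, seed=1)
        assert count_madd(g, (1, 32, 32)) == count_madd(sub, (1, 32, 32)) + 32 * 2


def test_graph_serialization_roundtrip(tmp_path, rng):
    a = build_subnet(SUBNET_PRESETS["A"], 1, seed=0)
    g = graph_from_subnet(a, 2, seed=1)
    g = combine_series(g, build_subnet(SUBNET_PRESETS["B"], 32, seed=2), seed=3)
    g = combine_parallel(g, build_subnet(SUBNET_PRESETS["C"], 1, seed=4), seed=5)
    x = rng.random((2, 1, 32, 32)).astype(np.float32)
    expected = g.forward_logits(x)
    save_graph(g, tmp_path / "m")
    g2 = load_graph(tmp_path / "m")
    np.testing.assert_allclose(g2.forward_logits(x), expected, rtol=1e-6)
    assert g2.stage_name == g.stage_name
    assert [s.frozen for s in g2.subnets()] == [True, True, False]
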