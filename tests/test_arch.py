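"""Architecture-as-data accounting: geometry recursions, FLOPs, parameters."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from localcount import arch
from localcount.arch import conv, maxpool, LayerSpec, NetworkSpec
from localcount.errors import GeometryError, ValidationError


def sig3(x):
    return float(f"{x:.3g}")


class TestReceptiveField:
    def test_single_conv_identity(self):
        spec = NetworkSpec((conv("c", 3, 3, 8),), 3)
        g = arch.receptive_field(spec)
        assert (g.rf, g.stride, g.padding) == (3, 1, 0)

    def test_canonical_stack_geometry(self, v2_spec):
        g = arch.receptive_field(v2_spec)
        assert g.rf == 94
        assert g.stride == 16
        assert g.padding == 15

    def test_rf_non_decreasing_and_jump_is_stride_product(self, v2_spec):
        g = arch.receptive_field(v2_spec)
        rfs = [r.receptive_field for r in g.rows]
        assert rfs == sorted(rfs)
        prod = 1
        for layer, row in zip(v2_spec.layers, g.rows):
            prod *= layer.stride
            assert row.jump == prod

    def test_padding_stripped_same_rf_and_params(self, v2_spec):
        stripped = arch.strip_padding(v2_spec)
        assert arch.receptive_field(stripped).rf == arch.receptive_field(v2_spec).rf
        assert arch.count_parameters(stripped) == arch.count_parameters(v2_spec)
        assert arch.receptive_field(stripped).padding == 0

    def test_gradient_support_oracle_random_stacks(self, rng):
        """RF recursion agrees with measured input support of one output unit.

        Oracle: an all-ones linearized network (no padding) is differentiated
        through the engine; the bounding box of the nonzero input gradient of
        a central output cell is the receptive field.
        """
        from localcount.engine import Conv2d, Sequential

        for trial in range(6):
            n_layers = int(rng.integers(1, 5))
            layers, specs = [], []
            cin = 1
            for i in range(n_layers):
                k = int(rng.integers(1, 4))
                s = int(rng.integers(1, 3))
                l = Conv2d(cin, 1, (k, k), stride=s, padding=0)
                l.W[...] = 1.0
                l.b[...] = 0.0
                layers.append(l)
                specs.append(conv(f"c{i}", k, cin, 1, stride=s))
            spec = NetworkSpec(tuple(specs), 1)
            g = arch.receptive_field(spec)
            size = g.rf + 2 * g.stride  # room for a 3-ish cell output
            net = Sequential(layers)
            x = np.ones((1, 1, size, size), dtype=np.float32)
            y = net.forward(x, training=True)
            dy = np.zeros_like(y)
            cy, cx = y.shape[2] // 2, y.shape[3] // 2
            dy[0, 0, cy, cx] = 1.0
            dx = net.backward(dy)
            ys, xs = np.nonzero(dx[0, 0])
            assert ys.max() - ys.min() + 1 == g.rf
            assert xs.max() - xs.min() + 1 == g.rf
            # support starts exactly at jump * cell index
            assert ys.min() == g.stride * cy and xs.min() == g.stride * cx


class TestOutputShape:
    def test_canonical_grid_on_full_canvas(self, v2_spec):
        # per-layer padding is part of the spec: (912 + 2*15 - 94)/16 + 1 = 54
        assert arch.output_shape(v2_spec, (912, 1216)) == (54, 73)

    def test_receptive_field_sized_patch_gives_single_cell(self, v2_spec):
        stripped = arch.strip_padding(v2_spec)
        assert arch.output_shape(stripped, (94, 94)) == (1, 1)

    def test_single_pool(self):
        spec = NetworkSpec((maxpool("p"),), 3)
        assert arch.output_shape(spec, (8, 8)) == (4, 4)

    def test_too_small_input_names_layer(self, v2_spec):
        with pytest.raises(GeometryError, match="conv6"):
            arch.output_shape(arch.strip_padding(v2_spec), (40, 40))

    @given(h=st.integers(94, 300), w=st.integers(94, 300))
    @settings(max_examples=25, deadline=None)
    def test_composition_layer_by_layer(self, h, w):
        spec = arch.tasselnet_ctx_spec()
        hw = (h, w)
        for i, layer in enumerate(spec.layers):
            hw = arch.output_shape(NetworkSpec((layer,), 1 if layer.kind == "maxpool"
                                               else layer.in_channels), hw)
        assert hw == arch.output_shape(spec, (h, w))


def brute_force_mults(spec: NetworkSpec, input_hw):
    """Independent oracle: enumerate every multiplication with explicit loops."""
    h, w = input_hw
    total = 0
    for layer in spec.layers:
        kh, kw = layer.kernel
        s, p = layer.stride, layer.padding
        outs_h = [y for y in range(0, h + 2 * p - kh + 1, s)]
        outs_w = [x for x in range(0, w + 2 * p - kw + 1, s)]
        if layer.kind == "conv":
            n = 0
            for _oy in outs_h:
                for _ox in outs_w:
                    for _co in range(layer.out_channels):
                        for _ci in range(layer.in_channels):
                            n += kh * kw
            total += n
        h, w = len(outs_h), len(outs_w)
    return total


class TestFlops:
    def test_one_by_one_conv(self):
        spec = NetworkSpec((conv("c", 1, 1, 1),), 1)
        assert arch.count_mult_flops(spec, (10, 10)).total_multiplications == 100

    def test_table_column_at_three_significant_digits(self, v2_spec):
        cost = arch.count_mult_flops(v2_spec, (912, 1216))
        by_name = dict(zip(cost.layer_names, cost.multiplications))
        assert sig3(by_name["conv1"]) == 4.79e8
        assert sig3(by_name["conv2"]) == 1.28e9
        assert sig3(by_name["conv3"]) == 1.28e9
        assert sig3(by_name["conv4"]) == 2.56e9
        assert sig3(by_name["conv5"]) == 2.56e9
        assert sig3(by_name["conv6"]) == 2.07e9
        assert sig3(by_name["conv7"]) == 6.46e7
        assert sig3(by_name["conv8"]) == 5.05e5
        assert sig3(cost.total_multiplications) == 1.03e10

    def test_totals_are_exact_sums(self, v2_spec):
        cost = arch.count_mult_flops(v2_spec, (912, 1216))
        assert cost.total_multiplications == sum(cost.multiplications)
        assert cost.total_parameters == sum(cost.parameters)

    @pytest.mark.parametrize("maker", [arch.tasselnetv2_spec, arch.tasselnet_spec,
                                       arch.tasselnet_ctx_spec])
    def test_loop_nest_oracle_small_inputs(self, maker):
        # only the first layers fit a 12x12 input; truncate each stack to
        # layers that keep every intermediate >= 1
        spec = maker()
        layers = []
        hw = (12, 12)
        for layer in spec.layers:
            try:
                hw = arch.output_shape(NetworkSpec((layer,), 1 if layer.kind ==
                                                   "maxpool" else layer.in_channels), hw)
            except GeometryError:
                break
            layers.append(layer)
        trunc = NetworkSpec(tuple(layers), 3)
        got = arch.count_mult_flops(trunc, (12, 12)).total_multiplications
        assert got == brute_force_mults(trunc, (12, 12))

    def test_patch_mode_multiplier(self):
        spec = arch.tasselnet_spec()
        one = arch.count_mult_flops(spec, (64, 64), n_patches=1)
        many = arch.count_mult_flops(spec, (64, 64), n_patches=266)
        assert many.total_multiplications == 266 * one.total_multiplications


class TestParameters:
    def test_single_conv(self):
        assert arch.count_parameters(NetworkSpec((conv("c", 3, 3, 16),), 3)) == 432

    def test_canonical_count(self, v2_spec):
        assert arch.count_parameters(v2_spec) == 638_000

    def test_all_variants_equal_capacity(self, v2_spec):
        assert (arch.count_parameters(arch.tasselnet_spec())
                == arch.count_parameters(arch.tasselnet_ctx_spec())
                == arch.count_parameters(v2_spec))

    def test_pool_has_no_parameters(self):
        assert maxpool("p").n_parameters == 0


class TestValidationAndSerialization:
    def test_bad_layers_rejected(self):
        with pytest.raises(ValidationError):
            LayerSpec("c", "conv", (0, 3), 1, 0, 3, 8)
        with pytest.raises(ValidationError):
            LayerSpec("c", "conv", (3, 3), 0, 0, 3, 8)
        with pytest.raises(ValidationError):
            LayerSpec("p", "maxpool", (2, 2), 2, 0, 3, 8)

    def test_channel_chain_checked(self):
        with pytest.raises(ValidationError, match="input channels"):
            NetworkSpec((conv("a", 3, 3, 8), conv("b", 3, 16, 8)), 3)

    def test_yaml_round_trip(self, tmp_path, v2_spec):
        path = tmp_path / "net.yaml"
        arch.dump_spec(v2_spec, path)
        loaded = arch.load_spec(path)
        assert loaded == v2_spec
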