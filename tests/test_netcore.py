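"""Model construction, forward passes, patch/FCN agreement, training loop."""

import numpy as np
import pytest

from localcount import arch, netcore
from localcount.errors import GeometryError, ValidationError


def random_image(rng, hw=(160, 160)):
    return (rng.random((*hw, 3)) * 255).astype(np.uint8)


class TestBuildModel:
    def test_unknown_variant_lists_valid_names(self):
        with pytest.raises(ValidationError, match="tasselnetv2"):
            netcore.build_model("resnet", 0)

    def test_same_seed_gives_bitwise_identical_weights(self):
        a = netcore.build_model("tasselnetv2", 11)
        b = netcore.build_model("tasselnetv2", 11)
        for k, v in a.net.state_dict().items():
            np.testing.assert_array_equal(v, b.net.state_dict()[k])

    def test_different_seed_gives_different_weights(self):
        a = netcore.build_model("tasselnetv2", 11)
        b = netcore.build_model("tasselnetv2", 12)
        assert any((a.net.state_dict()[k] != b.net.state_dict()[k]).any()
                   for k in a.net.state_dict())

    def test_weight_only_parameter_count_is_headline_figure(self):
        m = netcore.build_model("tasselnetv2", 0)
        assert netcore.weight_parameter_count(m) == 638_000
        assert netcore.weight_parameter_count(m) == arch.count_parameters(
            m.variant.spec)
        # biases + batch-norm affine terms are real but reported separately
        assert netcore.total_parameter_count(m) > 638_000

    @pytest.mark.parametrize("name", netcore.VARIANT_NAMES)
    def test_all_variants_share_capacity(self, name):
        m = netcore.build_model(name, 0)
        assert netcore.weight_parameter_count(m) == 638_000


class TestForwardPatch:
    def test_wrong_patch_size_raises_without_override(self, rng):
        m = netcore.build_model("tasselnet", 0)
        with pytest.raises(GeometryError, match="64x64"):
            netcore.forward_patch(m, random_image(rng, (94, 94)))

    def test_context_at_test_only_requires_explicit_override(self, rng):
        # the information-asymmetry probe: a context-free model evaluated on
        # context-sized patches must be an explicit, opt-in mismatch
        m = netcore.build_model("tasselnet", 0)
        patch = random_image(rng, (94, 94))
        val = netcore.forward_patch(m, patch, allow_geometry_mismatch=True)
        assert val >= 0.0

    def test_output_is_non_negative_and_deterministic(self, rng):
        m = netcore.build_model("tasselnetv2", 3)
        patch = random_image(rng, (94, 94))
        a = netcore.forward_patch(m, patch)
        b = netcore.forward_patch(m, patch)
        assert a == b >= 0.0

    def test_zeroed_final_layer_gives_zero(self, rng):
        m = netcore.build_model("tasselnetv2", 3)
        final = [l for l in m.net.layers if hasattr(l, "W")][-1]
        final.W[...] = 0.0
        final.b[...] = 0.0
        assert netcore.forward_patch(m, random_image(rng, (94, 94))) == 0.0


class TestForwardImage:
    def test_grid_shape_matches_arch_oracle(self, rng):
        m = netcore.build_model("tasselnetv2", 0)
        img = random_image(rng, (160, 224))
        grid = netcore.forward_image(m, img)
        assert grid.values.shape == arch.output_shape(m.variant.spec, (160, 224))

    def test_width_growth_adds_floor_delta_over_stride_columns(self, rng):
        m = netcore.build_model("tasselnetv2", 0)
        a = netcore.forward_image(m, random_image(rng, (160, 160)))
        b = netcore.forward_image(m, random_image(rng, (160, 160 + 48)))
        assert b.values.shape[1] - a.values.shape[1] == 48 // 16

    def test_too_small_image_raises(self, rng):
        m = netcore.build_model("tasselnetv2", 0)
        with pytest.raises(GeometryError):
            netcore.forward_image(m, random_image(rng, (40, 40)))

    def test_patch_variant_grid_matches_fcn_lattice(self, rng):
        img = random_image(rng, (160, 160))
        mp = netcore.build_model("tasselnet_ctx", 0)
        mf = netcore.build_model("tasselnetv2", 0)
        assert (netcore.forward_image(mp, img).values.shape
                == netcore.forward_image(mf, img).values.shape)

    def test_fcn_equals_patch_on_interior_cells(self, rng):
        """Fully convolutional and cropped-patch inference agree wherever the
        receptive field lies inside the unpadded image."""
        m = netcore.build_model("tasselnetv2", 7)
        img = random_image(rng, (160, 160))
        grid = netcore.forward_image(m, img).values
        checked = 0
        for i in range(grid.shape[0]):
            for j in range(grid.shape[1]):
                y0, x0 = 16 * i - 15, 16 * j - 15
                if y0 < 0 or x0 < 0 or y0 + 94 > 160 or x0 + 94 > 160:
                    continue
                p = netcore.forward_patch(m, img[y0:y0 + 94, x0:x0 + 94])
                assert abs(p - grid[i, j]) <= 1e-4
                checked += 1
        assert checked >= 9

    def test_receptive_field_patch_is_degenerate_fcn(self, rng):
        m = netcore.build_model("tasselnetv2", 5)
        patch = random_image(rng, (94, 94))
        y = m.patch_net().forward(m.preprocess(patch), training=False)
        assert y.shape[2:] == (1, 1)
        assert netcore.forward_patch(m, patch) == pytest.approx(
            max(0.0, float(y[0, 0, 0, 0])))


def tiny_dataset(n=4, hw=(128, 128), seed=9):
    from localcount import synth
    cfg = synth.SceneConfig(image_hw=hw, count_range=(5, 15), cluster_sigma=20,
                            mean_offspring=5, blur_sigma_range=(0, 1))
    return [(s.image, s.dots) for s in synth.scenes_for_benchmark(cfg, n, seed)]


class TestTrain:
    def test_loss_descends_on_toy_set(self):
        data = tiny_dataset(3)
        m = netcore.build_model("tasselnetv2", 1)
        tm = netcore.train(m, data, netcore.TrainConfig(epochs=8, batch_size=2,
                                                        seed=1))
        assert tm.history[-1]["train_loss"] < tm.history[0]["train_loss"]

    def test_training_is_reproducible(self):
        data = tiny_dataset(3)
        hists = []
        for _ in range(2):
            m = netcore.build_model("tasselnetv2", 1)
            tm = netcore.train(m, data, netcore.TrainConfig(epochs=3,
                                                            batch_size=2, seed=4))
            hists.append(tm.history)
        for a, b in zip(*hists):
            assert a["train_loss"] == pytest.approx(b["train_loss"], rel=1e-6)
            assert a["val_mae"] == pytest.approx(b["val_mae"], rel=1e-6)

    def test_patch_mode_trains_and_predicts(self):
        data = tiny_dataset(3)
        m = netcore.build_model("tasselnet", 1)
        tm = netcore.train(m, data, netcore.TrainConfig(epochs=2, batch_size=16,
                                                        seed=1))
        assert len(tm.history) == 2
        assert netcore.predict_count(m, data[0][0]) >= 0.0

    def test_geometry_mismatch_detected_before_first_step(self):
        data = tiny_dataset(3)
        m = netcore.build_model("tasselnetv2", 1)
        # sabotage the variant geometry so targets cannot match the network
        bad = netcore.ModelVariant("bad", m.variant.spec, 94, 64, 0, 15, True)
        m.variant = bad
        with pytest.raises(GeometryError):
            netcore.train(m, data, netcore.TrainConfig(epochs=1, seed=0))

    def test_needs_two_images(self):
        data = tiny_dataset(1)
        m = netcore.build_model("tasselnetv2", 1)
        with pytest.raises(ValidationError):
            netcore.train(m, data, netcore.TrainConfig(epochs=1, seed=0))
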