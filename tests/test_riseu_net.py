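"""Segmentation stack: preprocessing, SE gating, residual blocks, the
U-Net builder, separable-cost accounting, training plumbing."""

from fractions import Fraction

import numpy as np
import pytest

from strokeseg.core import ImageVolume, ValidationError
from strokeseg.nn import SEGate
from strokeseg.nn.autodiff import Tensor
from strokeseg.phantoms import default_spec, make_head_phantom
from strokeseg.riseu_net import (ResidualBlock, RISEUNet, SegNetConfig,
                                 SegTrainConfig, SeparableCostSpec,
                                 build_riseu_net, load_segmenter, predict_mask,
                                 preprocess_ct, save_segmenter,
                                 separable_cost_ratio, train_segmenter)


class TestPreprocess:
    def test_skull_voxels_removed(self, small_phantom):
        vol, _ = small_phantom
        out = preprocess_ct(vol)
        skull = vol.data > 300.0
        assert skull.any()
        assert np.all(out.data[skull] == 0.0)

    def test_brain_region_is_z_scored(self, small_phantom):
        vol, _ = small_phantom
        out, brain = preprocess_ct(vol, return_brain_mask=True)
        vals = out.data[brain.data.astype(bool)]
        assert abs(vals.mean()) < 1e-6
        assert abs(vals.std() - 1.0) < 1e-6

    def test_smoothing_reduces_total_variation(self, noisy_pair):
        vol = noisy_pair.noisy
        out, brain = preprocess_ct(vol, return_brain_mask=True)
        stripped = np.where(brain.data.astype(bool), vol.data, 0.0)

        def tv(a):
            return np.abs(np.diff(a, axis=0)).sum() + np.abs(np.diff(a, axis=1)).sum()

        assert tv(out.data) <= tv(stripped)

    def test_no_skull_warns_and_standardizes(self, rng):
        img = ImageVolume(rng.uniform(0, 50, (32, 32)), value_range=(0, 100))
        with pytest.warns(UserWarning, match="no skull"):
            out = preprocess_ct(img)
        assert abs(out.data.mean()) < 1e-6


class TestSEGate:
    def test_zero_input_gives_zero_output(self):
        se = SEGate(8, 4)
        out = se(Tensor(np.zeros((1, 8, 4, 4))))
        assert np.all(out.data == 0.0)

    def test_gates_forced_to_one_recover_input(self, rng):
        se = SEGate(8, 4)
        se.expand.weight.data[:] = 0.0
        se.expand.bias.data[:] = 40.0  # logistic(40) == 1 to double precision
        x = rng.standard_normal((1, 8, 4, 4))
        assert np.allclose(se(Tensor(x)).data, x, atol=1e-12)

    def test_bottleneck_width_and_gate_range(self, rng):
        se = SEGate(16, 4, rng=rng)
        assert se.squeeze.out_ch == 4
        g = se.gates(Tensor(rng.standard_normal((2, 16, 5, 5)))).data
        assert np.all((g > 0.0) & (g < 1.0))

    def test_indivisible_channels_rejected(self):
        with pytest.raises(ValueError):
            SEGate(10, 4)


class TestResidualBlock:
    def test_zeroed_branch_is_exact_identity(self, rng):
        block = ResidualBlock(8, 8, use_se=True, rng=rng)
        block.force_identity()
        x = rng.standard_normal((1, 8, 6, 6))
        assert np.array_equal(block(Tensor(x)).data, x)

    def test_output_minus_input_equals_branch(self, rng):
        block = ResidualBlock(4, 4, use_se=False, rng=rng)
        x = Tensor(rng.standard_normal((1, 4, 6, 6)))
        out = block(x)
        branch = block.residual_branch(x)
        assert np.allclose(out.data - x.data, branch.data)

    def test_identity_branch_passes_gradients_through(self, rng):
        block = ResidualBlock(4, 4, use_se=False, rng=rng)
        block.force_identity()
        x = Tensor(rng.standard_normal((1, 4, 4, 4)), requires_grad=True)
        w = rng.standard_normal((1, 4, 4, 4))
        (block(x) * Tensor(w)).sum().backward()
        assert np.allclose(x.grad, w)  # d(out)/d(in) has the identity term


class TestRISEUNet:
    def test_bottleneck_spatial_size_follows_pool_depth(self):
        """64x64 through depth-3 2x2 pooling reaches an 8x8 bottleneck."""
        model = build_riseu_net(SegNetConfig(depth=3, base_channels=8))
        h = Tensor(np.random.default_rng(0).standard_normal((1, 1, 64, 64)))
        from strokeseg.nn import autodiff as ad

        for enc in model.encoders:
            h = ad.maxpool2d(enc(h), model.cfg.pool)
        assert h.shape[2:] == (8, 8)

    def test_output_is_a_probability_map(self, rng):
        model = build_riseu_net(SegNetConfig(depth=2, base_channels=8))
        out = model(Tensor(rng.standard_normal((1, 1, 32, 32)) * 100))
        assert out.data.min() >= 0.0 and out.data.max() <= 1.0

    def test_indivisible_input_rejected_with_padding_hint(self):
        model = build_riseu_net(SegNetConfig(depth=3, base_channels=8))
        with pytest.raises(ValidationError, match="pad"):
            model(Tensor(np.zeros((1, 1, 60, 60))))

    def test_plain_unet_reduction_has_no_se_or_projection(self):
        cfg = SegNetConfig(depth=2, base_channels=8, use_se=False,
                           use_residual=False)
        model = build_riseu_net(cfg)
        blocks = model.encoders + [model.bottleneck] + model.decoders
        assert all(b.se is None and b.proj is None for b in blocks)

    def test_se_toggle_changes_parameter_count_by_closed_form(self):
        base = dict(depth=2, base_channels=8, se_reduction=4)
        with_se = build_riseu_net(SegNetConfig(use_se=True, **base))
        without = build_riseu_net(SegNetConfig(use_se=False, **base))

        def se_params(c, r=4):
            return (c * (c // r) + c // r) + ((c // r) * c + c)

        # one SE gate per block: enc 8, enc 16, bottleneck 32, dec 16, dec 8
        expected = sum(se_params(c) for c in (8, 16, 32, 16, 8))
        assert with_se.parameter_count() - without.parameter_count() == expected


class TestSeparableCost:
    def test_ratio_equals_closed_form_exactly(self):
        spec = SeparableCostSpec(H=7, W=5, D_K=3, M=16, N=64)
        assert separable_cost_ratio(spec, exact=True) == \
            Fraction(1, 64) + Fraction(1, 9)

    def test_counted_costs_match_explicit_enumeration(self):
        H, W, D, M, N = 2, 3, 2, 3, 4
        # standard conv: every output voxel x output channel does D*D*M mults
        std = sum(1 for _ in range(H) for _ in range(W) for _ in range(N)
                  for _ in range(D) for _ in range(D) for _ in range(M))
        sep = (sum(1 for _ in range(H) for _ in range(W) for _ in range(M)
                   for _ in range(D) for _ in range(D))
               + sum(1 for _ in range(H) for _ in range(W) for _ in range(M)
                     for _ in range(N)))
        ratio = separable_cost_ratio(SeparableCostSpec(H, W, D, M, N), exact=True)
        assert ratio == Fraction(sep, std)

    def test_degenerate_case(self):
        assert separable_cost_ratio(SeparableCostSpec(1, 1, 1, 1, 1)) == 2.0

    def test_saving_whenever_dims_exceed_one(self):
        for d in (2, 3, 5):
            for n in (2, 8, 64):
                r = separable_cost_ratio(SeparableCostSpec(4, 4, d, 3, n))
                assert r < 1.0 or (1 / n + 1 / d ** 2) >= 1.0

    def test_zero_dimension_rejected(self):
        with pytest.raises(ValidationError):
            SeparableCostSpec(0, 1, 1, 1, 1)


class TestTrainPredict:
    def test_training_records_decreasing_loss(self):
        imgs, masks = [], []
        for i in range(2):
            vol, m = make_head_phantom(default_spec(
                seed=40 + i, shape=(32, 32), n_lesions=1, delta_hu=-40.0,
                radii_frac=(0.12, 0.18)))
            imgs.append(preprocess_ct(vol))
            masks.append(m)
        model = build_riseu_net(SegNetConfig(depth=2, base_channels=8), seed=0)
        train_segmenter(model, imgs, masks, loss="new_dice",
                        cfg=SegTrainConfig(epochs=10, lr=3e-3, seed=0))
        assert len(model.history) == 10
        assert model.history[-1] < model.history[0]

    def test_empty_dataset_and_bad_loss_rejected(self):
        model = build_riseu_net(SegNetConfig(depth=2, base_channels=8))
        with pytest.raises(ValidationError):
            train_segmenter(model, [], [], loss="dice")
        with pytest.raises(ValidationError):
            train_segmenter(model, [], [], loss="jaccard")

    def test_predict_mask_threshold_bounds(self, rng):
        model = build_riseu_net(SegNetConfig(depth=2, base_channels=8))
        img = ImageVolume(rng.standard_normal((32, 32)), value_range=(-4, 4),
                          intensity_units="standardized")
        assert predict_mask(model, img, threshold=0.0).data.all()
        assert not predict_mask(model, img, threshold=1.1).data.any()

    def test_predict_mask_deterministic(self, rng):
        model = build_riseu_net(SegNetConfig(depth=2, base_channels=8))
        img = ImageVolume(rng.standard_normal((32, 32)), value_range=(-4, 4),
                          intensity_units="standardized")
        a = predict_mask(model, img)
        b = predict_mask(model, img)
        assert np.array_equal(a.data, b.data)

    def test_segmenter_checkpoint_round_trip(self, tmp_path, rng):
        model = build_riseu_net(SegNetConfig(depth=2, base_channels=8), seed=5)
        img = ImageVolume(rng.standard_normal((32, 32)), value_range=(-4, 4),
                          intensity_units="standardized")
        before = predict_mask(model, img)
        save_segmenter(model, tmp_path / "seg.zip")
        loaded = load_segmenter(tmp_path / "seg.zip")
        after = predict_mask(loaded, img)
        assert np.array_equal(before.data, after.data)
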