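"""Phantom generators: determinism, geometry, noise moments, perfusion
forward model."""

import numpy as np
import pytest

from strokeseg.core import NoiseModel, PerfusionSeries, ValidationError
from strokeseg.phantoms import (Lesion, PerfusionParams, PhantomSpec,
                                add_lowdose_noise, default_spec,
                                discrete_residue, gamma_variate_aif,
                                make_head_phantom, make_perfusion_series,
                                tissue_curve)


class TestHeadPhantom:
    def test_same_spec_same_seed_is_bit_identical(self):
        spec = default_spec(seed=5, shape=(64, 64), n_lesions=2)
        v1, m1 = make_head_phantom(spec)
        v2, m2 = make_head_phantom(spec)
        assert np.array_equal(v1.data, v2.data)
        assert np.array_equal(m1.data, m2.data)

    def test_zero_lesions_gives_empty_mask(self):
        _v, mask = make_head_phantom(PhantomSpec(shape=(64, 64)))
        assert mask.volume_voxels() == 0

    def test_spherical_lesion_voxel_count_matches_analytic_volume(self):
        r = 10.0
        c = 23.5
        spec = PhantomSpec(shape=(48, 48, 48), texture_sigma=0.0,
                           lesions=(Lesion((c, c, c), (r, r, r), -15.0),))
        _v, mask = make_head_phantom(spec)
        analytic = 4.0 / 3.0 * np.pi * r ** 3
        assert abs(mask.volume_voxels() - analytic) / analytic < 0.10

    def test_lesion_outside_head_rejected_with_index(self):
        spec = PhantomSpec(shape=(64, 64),
                           lesions=(Lesion((32.0, 32.0), (3.0, 3.0), -15.0),
                                    Lesion((2.0, 2.0), (3.0, 3.0), -15.0)))
        with pytest.raises(ValidationError, match="lesion 1"):
            make_head_phantom(spec)

    def test_hyperdense_lesion_rejected(self):
        spec = PhantomSpec(shape=(64, 64),
                           lesions=(Lesion((32.0, 32.0), (3.0, 3.0), +15.0),))
        with pytest.raises(ValidationError, match="negative"):
            make_head_phantom(spec)

    def test_tissue_classes_present(self, small_phantom):
        vol, _ = small_phantom
        assert vol.data.max() == 1000.0  # skull ring
        assert (vol.data == -1000.0).any()  # air background


class TestLowDoseNoise:
    def test_zero_sigma_is_identity(self, small_phantom):
        vol, _ = small_phantom
        pair = add_lowdose_noise(vol, NoiseModel(sigma=0.0, seed=1))
        assert np.array_equal(pair.noisy.data, pair.clean.data)

    def test_gaussian_moments_on_large_image(self):
        vol, _ = make_head_phantom(PhantomSpec(shape=(256, 256)))
        pair = add_lowdose_noise(vol, NoiseModel(sigma=25.0, seed=9))
        resid = pair.noisy.data - pair.clean.data
        assert abs(resid.mean()) < 0.05 * 25.0
        assert abs(resid.var() - 625.0) / 625.0 < 0.05

    def test_different_seeds_differ_only_in_noise(self, small_phantom):
        vol, _ = small_phantom
        p1 = add_lowdose_noise(vol, NoiseModel(sigma=25.0, seed=1))
        p2 = add_lowdose_noise(vol, NoiseModel(sigma=25.0, seed=2))
        assert not np.array_equal(p1.noisy.data, p2.noisy.data)
        assert np.array_equal(p1.clean.data, p2.clean.data)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValidationError):
            NoiseModel(sigma=-1.0)

    def test_poisson_gaussian_runs_and_is_seeded(self, small_phantom):
        vol, _ = small_phantom
        p1 = add_lowdose_noise(vol, NoiseModel(kind="poisson_gaussian",
                                               sigma=5.0, seed=4))
        p2 = add_lowdose_noise(vol, NoiseModel(kind="poisson_gaussian",
                                               sigma=5.0, seed=4))
        assert np.array_equal(p1.noisy.data, p2.noisy.data)


class TestPerfusionForwardModel:
    def test_discrete_residue_integrates_to_mtt(self):
        dt = 1.0
        for mtt in (2.0, 4.0, 8.0, 12.0):
            r = discrete_residue(46, dt, mtt)
            assert r[0] == 1.0
            assert np.isclose(dt * r.sum(), mtt, rtol=1e-12)

    def test_residue_requires_mtt_above_frame_spacing(self):
        with pytest.raises(ValidationError):
            discrete_residue(20, 2.5, 2.0)

    def test_zero_flow_region_never_enhances(self, small_phantom):
        vol, mask = small_phantom
        series = make_perfusion_series(vol, mask, PerfusionParams(csf_cbf=0.0))
        vents = (series.truth_maps["cbf"] == 0.0) & series.truth_maps["brain"].astype(bool)
        assert vents.any()
        dev = series.frames[:, vents] - vol.data[vents][None]
        assert np.abs(dev).max() < 1e-9

    def test_area_ratio_recovers_cbv(self, small_phantom):
        vol, mask = small_phantom
        series = make_perfusion_series(vol, mask)
        dt = series.times[1] - series.times[0]
        c = tissue_curve(series.aif, dt, 60.0, 4.0)
        cbv = 100.0 * c.sum() / series.aif.sum()
        assert abs(cbv - 60.0 * 4.0 / 60.0) / (60.0 * 4.0 / 60.0) < 0.05

    def test_ischemic_region_peaks_lower_than_normal(self, small_phantom):
        vol, mask = small_phantom
        series = make_perfusion_series(
            vol, mask, PerfusionParams(lesion_cbf=20.0, lesion_mtt=4.0,
                                       normal_cbf=60.0, normal_mtt=4.0))
        lesion = series.truth_maps["cbf"] == 20.0
        normal = series.truth_maps["cbf"] == 60.0
        enh = series.frames - vol.data[None]
        assert enh[:, lesion].max() < enh[:, normal].max()

    def test_central_volume_consistency_of_truth_maps(self, small_phantom):
        vol, mask = small_phantom
        series = make_perfusion_series(vol, mask)
        cbf = series.truth_maps["cbf"]
        cbv = series.truth_maps["cbv"]
        mtt = series.truth_maps["mtt"]
        flowing = cbf > 0
        assert np.allclose(mtt[flowing], 60.0 * cbv[flowing] / cbf[flowing])

    def test_baseline_frame_matches_phantom(self, small_phantom):
        vol, mask = small_phantom
        series = make_perfusion_series(vol, mask)
        assert np.allclose(series.frames[0], vol.data)

    def test_invalid_perfusion_params_rejected(self):
        with pytest.raises(ValidationError):
            PerfusionParams(normal_mtt=0.0)
        with pytest.raises(ValidationError):
            PerfusionParams(lesion_cbf=-5.0)

    def test_series_invariants_enforced(self):
        with pytest.raises(ValidationError):
            PerfusionSeries(np.zeros((3, 4, 4)), np.array([0.0, 1.0, 1.0]),
                            np.zeros(3))
        with pytest.raises(ValidationError):
            PerfusionSeries(np.zeros((3, 4, 4)), np.array([0.0, 1.0, 2.0]),
                            np.zeros(2))
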