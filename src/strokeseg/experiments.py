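"""Desk-scale benchmark experiments over the synthetic phantom suite.

These are the package's standard evaluation runs: BM3D versus the noisy
input, CNN denoiser training gains, segmentation quality under the two
Dice-family losses, and perfusion parameter recovery.  Problem sizes are
chosen so each experiment completes in minutes on one CPU core; the same
functions back the test suite and the reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bm3d import BM3DParams, bm3d_stage
from .cnn_denoise import (CascadeConfig, DnCNNConfig, TrainConfig,
                          apply_denoiser, build_cascade, build_dncnn,
                          train_denoiser)
from .core import NoiseModel, PerfusionSeries
from .metrics_losses import dice_scores, image_quality
from .perfusion import DeconvolutionParams, perfusion_maps
from .phantoms import (add_lowdose_noise, gamma_variate_aif, phantom_suite,
                       tissue_curve)
from .riseu_net import (SegNetConfig, SegTrainConfig, build_riseu_net,
                        predict_mask, preprocess_ct, train_segmenter)

__all__ = ["bm3d_benchmark", "denoiser_benchmark", "cascade_depth_benchmark",
           "segmentation_benchmark", "perfusion_recovery_benchmark"]

SIGMA = 25.0  # low-dose noise level of the standard denoising suite


def _noise_pairs(n, seed, shape=(64, 64), sigma=SIGMA):
    cases = phantom_suite(n, seed=seed, shape=shape, n_lesions=1)
    return [add_lowdose_noise(v, NoiseModel(sigma=sigma, seed=seed + 1000 + i))
            for i, (v, _m) in enumerate(cases)]


def bm3d_benchmark(n_phantoms: int = 10, seed: int = 42,
                   sigma: float = SIGMA) -> dict:
    """Two-stage BM3D vs the noisy input on seeded phantoms.

    Returns per-case PSNRs for the noisy input, the stage-1 (hard) output
    and the full two-stage output.
    """
    params = BM3DParams(sigma=sigma)
    rows = {"noisy": [], "stage1": [], "two_stage": []}
    for pair in _noise_pairs(n_phantoms, seed, sigma=sigma):
        basic = bm3d_stage(pair.noisy, None, params, mode="hard")
        final = bm3d_stage(pair.noisy, basic, params, mode="wiener")
        rows["noisy"].append(image_quality(pair.clean, pair.noisy).psnr)
        rows["stage1"].append(image_quality(pair.clean, basic).psnr)
        rows["two_stage"].append(image_quality(pair.clean, final).psnr)
    return {k: np.asarray(v) for k, v in rows.items()}


def denoiser_benchmark(seed: int = 42, epochs: int = 60) -> dict:
    """Train a tiny DnCNN on 7 phantoms, evaluate PSNR gain on 3 held out."""
    pairs = _noise_pairs(10, seed)
    train, test = pairs[:7], pairs[7:]
    model = build_dncnn(DnCNNConfig(depth=5, width=16), seed=seed % 2 ** 31)
    train_denoiser(model, train, TrainConfig(epochs=epochs, seed=seed % 2 ** 31))
    gains = [image_quality(p.clean, apply_denoiser(model, p.noisy)).psnr
             - image_quality(p.clean, p.noisy).psnr for p in test]
    return {"gains_db": np.asarray(gains), "history": model.history}


def cascade_depth_benchmark(seeds=range(5), epochs: int = 60,
                            data_seed: int = 42) -> dict:
    """Held-out PSNR gain of 1-block vs 2-block cascades, per seed."""
    pairs = _noise_pairs(10, data_seed)
    train, test = pairs[:7], pairs[7:]
    out = {1: [], 2: []}
    for seed in seeds:
        for nb in (1, 2):
            model = build_cascade(
                CascadeConfig(n_blocks=nb, block=DnCNNConfig(depth=3, width=8)),
                seed=int(seed))
            train_denoiser(model, train, TrainConfig(epochs=epochs,
                                                     seed=int(seed)))
            g = np.mean([image_quality(p.clean,
                                       apply_denoiser(model, p.noisy)).psnr
                         - image_quality(p.clean, p.noisy).psnr for p in test])
            out[nb].append(float(g))
    return {k: np.asarray(v) for k, v in out.items()}


def _easy_seg_suite(seed: int = 0, n: int = 12):
    """High-contrast lesions, mild noise: the 'easy' segmentation suite."""
    cases = phantom_suite(n, seed=seed, shape=(64, 64), n_lesions=1,
                          delta_hu=-40.0, radii_frac=(0.10, 0.16))
    imgs, masks = [], []
    for i, (vol, m) in enumerate(cases):
        noisy = add_lowdose_noise(vol, NoiseModel(sigma=5.0,
                                                  seed=seed + 100 + i)).noisy
        imgs.append(preprocess_ct(noisy))
        masks.append(m)
    return imgs, masks


def segmentation_benchmark(seeds=range(5), epochs: int = 80,
                           data_seed: int = 0) -> dict:
    """Train RISEU-Net under both Dice-family losses on the easy suite.

    For each seed and loss: train on 8 phantoms, evaluate Dice and
    false-positive voxel rate on 4 held out.
    """
    imgs, masks = _easy_seg_suite(seed=data_seed)
    train_x, train_y = imgs[:8], masks[:8]
    test_x, test_y = imgs[8:], masks[8:]
    res = {"dice": {"dice": [], "fp_rate": []},
           "new_dice": {"dice": [], "fp_rate": []}}
    for seed in seeds:
        for loss in ("dice", "new_dice"):
            model = build_riseu_net(SegNetConfig(depth=2, base_channels=8),
                                    seed=int(seed))
            train_segmenter(model, train_x, train_y, loss=loss,
                            cfg=SegTrainConfig(epochs=epochs, lr=3e-3,
                                               seed=int(seed), batch_size=4))
            ds, fps = [], []
            for x, y in zip(test_x, test_y):
                s = dice_scores(predict_mask(model, x), y)
                ds.append(s.dice)
                fps.append(s.fp / y.data.size)
            res[loss]["dice"].append(float(np.mean(ds)))
            res[loss]["fp_rate"].append(float(np.mean(fps)))
    return {loss: {k: np.asarray(v) for k, v in d.items()}
            for loss, d in res.items()}


def perfusion_recovery_benchmark(seed: int = 0) -> dict:
    """Noiseless recovery over a (CBF, MTT) grid at 1 s sampling, plus the
    lesion-vs-normal flow ordering on a phantom series."""
    times = np.linspace(0.0, 45.0, 46)
    dt = times[1] - times[0]
    aif = gamma_variate_aif(times, 100.0, 4.0, 3.0, 1.5)
    params = DeconvolutionParams(truncation_fraction=0.05)
    cbf_errs, mtt_errs = [], []
    for cbf in (10.0, 30.0, 60.0, 80.0):
        for mtt in (2.0, 4.0, 8.0, 12.0):
            c = tissue_curve(aif, dt, cbf, mtt)
            series = PerfusionSeries(c[:, None, None], times, aif)
            maps = perfusion_maps(series, params)
            cbf_errs.append(abs(maps.cbf[0, 0] - cbf) / cbf)
            mtt_errs.append(abs(maps.mtt[0, 0] - mtt) / mtt)

    from .phantoms import default_spec, make_head_phantom, make_perfusion_series

    vol, mask = make_head_phantom(default_spec(seed=seed, shape=(64, 64),
                                               n_lesions=1))
    series = make_perfusion_series(vol, mask)
    maps = perfusion_maps(series, params)
    lesion = series.truth_maps["cbf"] == 20.0
    normal = series.truth_maps["cbf"] == 60.0
    return {"cbf_errs": np.asarray(cbf_errs), "mtt_errs": np.asarray(mtt_errs),
            "lesion_cbf": float(maps.cbf[lesion].mean()),
            "normal_cbf": float(maps.cbf[normal].mean())}
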