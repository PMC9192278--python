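"""End-to-end orchestration: phantom -> noise -> denoise -> segment ->
perfuse -> report, driven by a validated YAML config with one root seed.

Every stochastic stage draws its seed deterministically from the global
seed and the stage name, so re-running a config reproduces all artifacts
bit-identically.  A JSON manifest records inputs, derived seeds, artifact
hashes and metric summaries.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .bm3d import BM3DParams, bm3d_denoise
from .cnn_denoise import (CascadeConfig, DnCNNConfig, TrainConfig,
                          apply_denoiser, build_cascade, build_dncnn,
                          train_denoiser)
from .core import (ImageVolume, NoiseModel, ValidationError, write_mask,
                   write_perfusion_series, write_volume)
from .metrics_losses import (detection_report, image_quality,
                             render_efficacy_table, render_quality_table)
from .perfusion import DeconvolutionParams, perfusion_maps
from .phantoms import (PerfusionParams, add_lowdose_noise, make_head_phantom,
                       make_perfusion_series, default_spec)
from .riseu_net import (SegNetConfig, SegTrainConfig, build_riseu_net,
                        predict_mask, preprocess_ct, train_segmenter)

__all__ = ["RunConfig", "run_pipeline", "load_config", "stage_seed"]

SCHEMA_VERSION = 1


@dataclass
class PhantomStageConfig:
    n_cases: int = 4
    shape: tuple[int, int] = (64, 64)
    n_lesions: int = 1
    delta_hu: float = -40.0
    radii_frac: tuple[float, float] = (0.10, 0.16)


@dataclass
class NoiseStageConfig:
    kind: str = "gaussian"
    sigma: float = 25.0


@dataclass
class DenoiseStageConfig:
    method: str = "bm3d"  # bm3d | dncnn | cascade
    sigma: float = 25.0
    epochs: int = 40
    depth: int = 5
    width: int = 16
    n_blocks: int = 2


@dataclass
class SegmentStageConfig:
    depth: int = 2
    base_channels: int = 8
    se_reduction: int = 4
    use_se: bool = True
    use_residual: bool = True
    loss: str = "new_dice"
    epochs: int = 80
    lr: float = 3e-3
    threshold: float = 0.5
    n_train: int = 8  # extra training phantoms generated for the segmenter


@dataclass
class PerfusionStageConfig:
    enabled: bool = True
    truncation_fraction: float = 0.2
    normal_cbf: float = 60.0
    normal_mtt: float = 4.0
    lesion_cbf: float = 20.0
    lesion_mtt: float = 8.0
    noise_sigma: float = 0.0


@dataclass
class RunConfig:
    """Validated top-level run configuration."""

    seed: int = 0
    out_dir: str = "strokeseg_run"
    log_level: str = "INFO"
    schema_version: int = SCHEMA_VERSION
    phantom: PhantomStageConfig = field(default_factory=PhantomStageConfig)
    noise: NoiseStageConfig = field(default_factory=NoiseStageConfig)
    denoise: DenoiseStageConfig = field(default_factory=DenoiseStageConfig)
    segment: SegmentStageConfig = field(default_factory=SegmentStageConfig)
    perfusion: PerfusionStageConfig = field(default_factory=PerfusionStageConfig)


_STAGE_TYPES = {"phantom": PhantomStageConfig, "noise": NoiseStageConfig,
                "denoise": DenoiseStageConfig, "segment": SegmentStageConfig,
                "perfusion": PerfusionStageConfig}


def _build_section(cls, data: dict, path: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValidationError(
            f"unknown config key(s) under '{path}': {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name in data:
            v = data[f.name]
            if isinstance(v, list):
                v = tuple(v)
            kwargs[f.name] = v
    return cls(**kwargs)


def load_config(source) -> RunConfig:
    """Parse a YAML file/dict into a RunConfig, rejecting unknown keys
    before any stage runs."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            data = yaml.safe_load(fh) or {}
    else:
        data = dict(source or {})
    top_allowed = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - top_allowed
    if unknown:
        raise ValidationError(f"unknown top-level config key(s): {sorted(unknown)}")
    if data.get("schema_version", SCHEMA_VERSION) != SCHEMA_VERSION:
        raise ValidationError(
            f"unsupported schema_version {data['schema_version']}")
    kwargs = {}
    for name, cls in _STAGE_TYPES.items():
        if name in data:
            section = data[name]
            if not isinstance(section, dict):
                raise ValidationError(f"config section '{name}' must be a mapping")
            kwargs[name] = _build_section(cls, section, name)
    for scalar in ("seed", "out_dir", "log_level", "schema_version"):
        if scalar in data:
            kwargs[scalar] = data[scalar]
    return RunConfig(**kwargs)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage substream: hash the stage name into the
    root seed; always < 2^31."""
    return (int(global_seed) * 1000003 + zlib.crc32(stage.encode())) % (2 ** 31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order and write artifacts plus a manifest.

    Returns the manifest dict (also written to ``manifest.json``).  The
    manifest records partial completion if a stage fails.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "schema_version": config.schema_version,
        "seed": config.seed,
        "config": asdict(config),
        "stages": {},
        "artifacts": {},
        "metrics": {},
    }

    def record(stage: str, status: str) -> None:
        manifest["stages"][stage] = status

    try:
        # -- phantoms ----------------------------------------------------
        p = config.phantom
        rng = np.random.default_rng(stage_seed(config.seed, "phantom"))
        cases = []
        for i in range(p.n_cases + config.segment.n_train):
            spec = default_spec(seed=int(rng.integers(0, 2 ** 31 - 1)),
                               shape=tuple(p.shape), n_lesions=p.n_lesions,
                               delta_hu=p.delta_hu, radii_frac=tuple(p.radii_frac))
            cases.append(make_head_phantom(spec))
        eval_cases = cases[:p.n_cases]
        train_cases = cases[p.n_cases:]
        for i, (vol, mask) in enumerate(eval_cases):
            manifest["artifacts"][f"phantom_{i:02d}"] = str(
                write_volume(vol, out / f"phantom_{i:02d}.nii.gz"))
            manifest["artifacts"][f"truth_mask_{i:02d}"] = str(
                write_mask(mask, out / f"truth_mask_{i:02d}.nii.gz"))
        record("phantom", "complete")

        # -- noise -------------------------------------------------------
        nseed = stage_seed(config.seed, "noise")
        pairs = [add_lowdose_noise(vol, NoiseModel(kind=config.noise.kind,
                                                   sigma=config.noise.sigma,
                                                   seed=nseed + i))
                 for i, (vol, _m) in enumerate(cases)]
        record("noise", "complete")

        # -- denoise -----------------------------------------------------
        d = config.denoise
        if d.method == "bm3d":
            params = BM3DParams(sigma=d.sigma)
            denoised = [bm3d_denoise(pr.noisy, params)
                        for pr in pairs[:p.n_cases]]
        elif d.method in ("dncnn", "cascade"):
            dseed = stage_seed(config.seed, "denoise")
            if d.method == "dncnn":
                model = build_dncnn(DnCNNConfig(depth=d.depth, width=d.width),
                                    seed=dseed)
            else:
                model = build_cascade(
                    CascadeConfig(n_blocks=d.n_blocks,
                                  block=DnCNNConfig(depth=d.depth, width=d.width)),
                    seed=dseed)
            train_denoiser(model, pairs[p.n_cases:],
                           TrainConfig(epochs=d.epochs, seed=dseed))
            denoised = [apply_denoiser(model, pr.noisy)
                        for pr in pairs[:p.n_cases]]
        else:
            raise ValidationError(f"unknown denoise method {d.method!r}")
        quality = [image_quality(pairs[i].clean, denoised[i])
                   for i in range(p.n_cases)]
        noisy_quality = [image_quality(pairs[i].clean, pairs[i].noisy)
                         for i in range(p.n_cases)]
        qt = render_quality_table(
            [("low dose", noisy_quality[0]), (d.method, quality[0])])
        qt.to_csv(out / "quality_case00.csv", index=False)
        manifest["metrics"]["psnr_noisy_mean"] = float(
            np.mean([q.psnr for q in noisy_quality]))
        manifest["metrics"]["psnr_denoised_mean"] = float(
            np.mean([q.psnr for q in quality]))
        manifest["metrics"]["ssim_denoised_mean"] = float(
            np.mean([q.ssim for q in quality]))
        for i, vol in enumerate(denoised):
            manifest["artifacts"][f"denoised_{i:02d}"] = str(
                write_volume(vol, out / f"denoised_{i:02d}.nii.gz"))
        record("denoise", "complete")

        # -- segment -----------------------------------------------------
        s = config.segment
        sseed = stage_seed(config.seed, "segment")
        seg_cfg = SegNetConfig(depth=s.depth, base_channels=s.base_channels,
                               se_reduction=s.se_reduction, use_se=s.use_se,
                               use_residual=s.use_residual)
        seg_model = build_riseu_net(seg_cfg, seed=sseed)
        train_imgs = [preprocess_ct(pairs[p.n_cases + i].noisy)
                      for i in range(len(train_cases))]
        train_masks = [m for (_v, m) in train_cases]
        train_segmenter(seg_model, train_imgs, train_masks, loss=s.loss,
                        cfg=SegTrainConfig(epochs=s.epochs, lr=s.lr, seed=sseed))
        pred_masks = []
        for i in range(p.n_cases):
            pre = preprocess_ct(denoised[i])
            pm = predict_mask(seg_model, pre, threshold=s.threshold)
            pred_masks.append(pm)
            manifest["artifacts"][f"pred_mask_{i:02d}"] = str(
                write_mask(pm, out / f"pred_mask_{i:02d}.nii.gz"))
        from .riseu_net import save_segmenter

        save_segmenter(seg_model, out / "segmenter.zip")
        manifest["artifacts"]["segmenter"] = str(out / "segmenter.zip")
        report = detection_report(pred_masks, [m for (_v, m) in eval_cases])
        report.per_case.to_csv(out / "detection_per_case.csv", index=False)
        render_efficacy_table([("pipeline", report)]).to_csv(
            out / "efficacy.csv", index=False)
        manifest["metrics"]["detection"] = report.summary()
        record("segment", "complete")

        # -- perfusion ---------------------------------------------------
        if config.perfusion.enabled:
            pf = config.perfusion
            pfseed = stage_seed(config.seed, "perfusion")
            vol0, mask0 = eval_cases[0]
            series = make_perfusion_series(
                vol0, mask0,
                PerfusionParams(normal_cbf=pf.normal_cbf, normal_mtt=pf.normal_mtt,
                                lesion_cbf=pf.lesion_cbf, lesion_mtt=pf.lesion_mtt,
                                noise_sigma=pf.noise_sigma),
                seed=pfseed)
            write_perfusion_series(series, out / "perfusion_case00.nii.gz",
                                   out / "aif_case00.csv")
            maps = perfusion_maps(series, DeconvolutionParams(
                truncation_fraction=pf.truncation_fraction))
            for name in ("cbf", "cbv", "mtt", "ttp"):
                arr = getattr(maps, name)
                manifest["artifacts"][f"map_{name}"] = str(write_volume(
                    ImageVolume(arr, vol0.spacing, "standardized",
                                value_range=(0.0, max(float(arr.max()), 1.0))),
                    out / f"map_{name}_case00.nii.gz"))
            lesion = series.truth_maps["cbf"] == pf.lesion_cbf
            normal = series.truth_maps["cbf"] == pf.normal_cbf
            manifest["metrics"]["perfusion"] = {
                "lesion_cbf_mean": float(maps.cbf[lesion].mean()),
                "normal_cbf_mean": float(maps.cbf[normal].mean()),
                "lesion_mtt_mean": float(maps.mtt[lesion].mean()),
                "normal_mtt_mean": float(maps.mtt[normal].mean()),
            }
            record("perfusion", "complete")
        else:
            record("perfusion", "skipped")
    except Exception as exc:  # record partial completion, then re-raise
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise

    manifest["artifact_hashes"] = {
        k: _sha256(Path(v)) for k, v in manifest["artifacts"].items()}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
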