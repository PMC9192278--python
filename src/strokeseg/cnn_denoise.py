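"""Residual CNN denoisers: DnCNN and the multi-level cascaded variant.

The low-dose degradation is modeled as chi = phi(y); a denoiser is a
network F approximating phi^{-1}, fit by minimizing ||F(chi) - y||^2 on
matched (clean, noisy) pairs.  DnCNN predicts the *noise* and subtracts it
from its input (residual learning) and contains no spatial resampling, so
any input shape is preserved.  The cascade stacks DnCNN-style blocks where
each block after the first consumes the 2-channel concatenation of the
previous block's estimate and the original noisy image, which lets later
blocks clean residual artifacts without losing information from the
original measurement.

Networks here are desk-scale by design (depth 3-8, width 8-16, trained on
32x32 patches), sized so that CPU training converges in minutes.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .core import ImageVolume, NoisePair, ValidationError
from .nn import autodiff as ad
from .nn.autodiff import Tensor

__all__ = [
    "DnCNNConfig", "CascadeConfig", "TrainConfig", "DenoiserModel",
    "build_dncnn", "build_cascade", "train_denoiser", "apply_denoiser",
    "dense_weight_count", "save_model", "load_model",
]


def dense_weight_count(n_inputs: int, n_hidden: int) -> int:
    """Weights in one fully connected layer: every input pixel wired to
    every hidden unit.  The classic motivating count for convolutions:
    a 1000x1000 image and 1e6 hidden units already need 1e12 weights."""
    if n_inputs <= 0 or n_hidden <= 0:
        raise ValidationError("layer sizes must be positive")
    return int(n_inputs) * int(n_hidden)


@dataclass(frozen=True)
class DnCNNConfig:
    """Plain residual denoiser: depth conv layers, no resampling."""

    depth: int = 5
    width: int = 16
    kernel: int = 3
    residual: bool = True
    in_channels: int = 1

    def __post_init__(self) -> None:
        if self.depth < 3:
            raise ValidationError("depth must be >= 3")
        if self.kernel % 2 == 0:
            raise ValidationError("kernel size must be odd")
        if self.width < 1 or self.in_channels < 1:
            raise ValidationError("width and in_channels must be >= 1")


@dataclass(frozen=True)
class CascadeConfig:
    n_blocks: int = 2
    block: DnCNNConfig = DnCNNConfig()

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise ValidationError("n_blocks must be >= 1")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 60
    lr: float = 1e-3
    batch_size: int = 8
    patch_size: int = 32
    patches_per_image: int = 8
    seed: int = 0


class _DnCNNBlock(nn.Module):
    """conv-relu, (conv-norm-relu)*(depth-2), conv; residual subtraction."""

    def __init__(self, cfg: DnCNNConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.first = nn.Conv2d(cfg.in_channels, cfg.width, cfg.kernel, rng=rng)
        self.mid = []
        for _ in range(cfg.depth - 2):
            self.mid.append(nn.Conv2d(cfg.width, cfg.width, cfg.kernel, rng=rng))
            self.mid.append(nn.ChannelNorm(cfg.width))
        self.last = nn.Conv2d(cfg.width, 1, cfg.kernel, rng=rng)
        # zero-init the noise head: the untrained residual model starts as
        # the identity map, so optimization descends from the noisy baseline
        self.last.weight.data[:] = 0.0

    def predict_noise(self, x: Tensor) -> Tensor:
        h = ad.relu(self.first(x))
        for i in range(0, len(self.mid), 2):
            h = ad.relu(self.mid[i + 1](self.mid[i](h)))
        return self.last(h)

    def forward(self, x: Tensor, reference: Tensor | None = None) -> Tensor:
        """reference: the single-channel image the residual is subtracted
        from (defaults to x itself for single-channel input)."""
        noise = self.predict_noise(x)
        if not self.cfg.residual:
            return noise
        ref = reference if reference is not None else x
        return ref - noise

    def force_identity(self) -> None:
        """Zero the final conv: residual becomes 0, the block the identity."""
        self.last.weight.data[:] = 0.0
        if self.last.bias is not None:
            self.last.bias.data[:] = 0.0


class _CascadeNet(nn.Module):
    def __init__(self, cfg: CascadeConfig, rng: np.random.Generator):
        self.cfg = cfg
        blocks = [_DnCNNBlock(cfg.block, rng)]
        later = DnCNNConfig(depth=cfg.block.depth, width=cfg.block.width,
                            kernel=cfg.block.kernel, residual=cfg.block.residual,
                            in_channels=2)
        for _ in range(cfg.n_blocks - 1):
            blocks.append(_DnCNNBlock(later, rng))
        self.blocks = blocks

    def forward(self, x: Tensor) -> Tensor:
        est = self.blocks[0](x)
        for blk in self.blocks[1:]:
            est = blk(ad.concat([est, x], axis=1), reference=est)
        return est

    def force_identity(self) -> None:
        for blk in self.blocks:
            blk.force_identity()


@dataclass
class DenoiserModel:
    """Architecture + learned parameters + training history.

    ``norm_range`` maps the training intensity units into [0, 1] for the
    network and back; inference always returns the caller's units.
    """

    kind: str  # "dncnn" | "cascade"
    config: DnCNNConfig | CascadeConfig
    net: nn.Module
    norm_range: tuple[float, float] = (0.0, 1.0)
    intensity_units: str = "HU"
    history: list[float] = field(default_factory=list)

    def parameter_count(self) -> int:
        return sum(p.data.size for p in self.net.parameters())

    def force_identity(self) -> None:
        self.net.force_identity()


def build_dncnn(cfg: DnCNNConfig = DnCNNConfig(), seed: int = 0) -> DenoiserModel:
    rng = np.random.default_rng(seed)
    return DenoiserModel("dncnn", cfg, _DnCNNBlock(cfg, rng))


def build_cascade(cfg: CascadeConfig = CascadeConfig(), seed: int = 0) -> DenoiserModel:
    rng = np.random.default_rng(seed)
    return DenoiserModel("cascade", cfg, _CascadeNet(cfg, rng))


def _extract_patches(pairs: list[NoisePair], cfg: TrainConfig,
                     rng: np.random.Generator, lo: float, hi: float):
    xs, ys = [], []
    p = cfg.patch_size
    for pair in pairs:
        clean = np.atleast_3d(pair.clean.data.reshape(-1, *pair.clean.shape[-2:]))
        noisy = pair.noisy.data.reshape(clean.shape)
        for z in range(clean.shape[0]):
            H, W = clean.shape[1:]
            if H < p or W < p:
                raise ValidationError(f"images smaller than patch size {p}")
            for _ in range(cfg.patches_per_image):
                i = int(rng.integers(0, H - p + 1))
                j = int(rng.integers(0, W - p + 1))
                ys.append(clean[z, i:i + p, j:j + p])
                xs.append(noisy[z, i:i + p, j:j + p])
    X = (np.stack(xs)[:, None] - lo) / (hi - lo)
    Y = (np.stack(ys)[:, None] - lo) / (hi - lo)
    return X, Y


def train_denoiser(model: DenoiserModel, pairs: list[NoisePair],
                   cfg: TrainConfig = TrainConfig()) -> DenoiserModel:
    """Fit the MSE objective ||F(noisy) - clean||^2 on seeded patches.

    Training history (per-epoch mean loss) is recorded on the model; a
    fixed seed reproduces the history to floating-point tolerance.
    """
    if not pairs:
        raise ValidationError("need at least one training pair")
    units = pairs[0].clean.intensity_units
    if any(p.clean.intensity_units != units for p in pairs):
        raise ValidationError("all pairs must share intensity units")
    lo, hi = pairs[0].clean.value_range
    model.norm_range = (float(lo), float(hi))
    model.intensity_units = units

    rng = np.random.default_rng(cfg.seed)
    X, Y = _extract_patches(pairs, cfg, rng, lo, hi)
    n = X.shape[0]
    opt = nn.Adam(model.net.parameters(), lr=cfg.lr)
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            out = model.net(Tensor(X[idx]))
            loss = ((out - Tensor(Y[idx])) ** 2).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        model.history.append(float(np.mean(losses)))
    return model


def apply_denoiser(model: DenoiserModel, image: ImageVolume) -> ImageVolume:
    """Deterministic inference on a full image; output grid = input grid."""
    if image.intensity_units != model.intensity_units:
        raise ValidationError(
            f"image units {image.intensity_units!r} do not match training "
            f"units {model.intensity_units!r}")
    lo, hi = model.norm_range
    arr = image.data
    slices = arr.reshape(-1, *arr.shape[-2:])
    x = (slices[:, None] - lo) / (hi - lo)
    out = model.net(Tensor(x)).data[:, 0]
    return image.with_data((out.reshape(arr.shape)) * (hi - lo) + lo)


# ---------------------------------------------------------------------------
# checkpoints: single .zip archive with config JSON + parameter arrays
# ---------------------------------------------------------------------------

def _zinfo(name: str) -> zipfile.ZipInfo:
    """Fixed-date ZipInfo so checkpoints are byte-reproducible."""
    return zipfile.ZipInfo(name, date_time=(1980, 1, 1, 0, 0, 0))


def save_model(model: DenoiserModel, path: str | Path) -> Path:
    path = Path(path)
    cfg: dict = asdict(model.config)
    meta = {"kind": model.kind, "config": cfg, "norm_range": model.norm_range,
            "intensity_units": model.intensity_units, "history": model.history}
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr(_zinfo("meta.json"), json.dumps(meta))
        for i, arr in enumerate(model.net.state_arrays()):
            import io
            buf = io.BytesIO()
            np.save(buf, arr)
            zf.writestr(_zinfo(f"param_{i:04d}.npy"), buf.getvalue())
    return path


def load_model(path: str | Path) -> DenoiserModel:
    import io

    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        if meta["kind"] == "dncnn":
            cfg = DnCNNConfig(**meta["config"])
            model = build_dncnn(cfg)
        else:
            block = DnCNNConfig(**meta["config"]["block"])
            cfg = CascadeConfig(n_blocks=meta["config"]["n_blocks"], block=block)
            model = build_cascade(cfg)
        names = sorted(n for n in zf.namelist() if n.startswith("param_"))
        arrays = [np.load(io.BytesIO(zf.read(n))) for n in names]
        model.net.load_state_arrays(arrays)
        model.norm_range = tuple(meta["norm_range"])
        model.intensity_units = meta["intensity_units"]
        model.history = list(meta["history"])
    return model
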