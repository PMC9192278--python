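"""Lesion segmentation stack: CT preprocessing, residual blocks with
squeeze-excitation gating, the RISEU-Net encoder-decoder, and training
under Dice-family losses.

RISEU-Net is a residual U-Net whose blocks are gated by SE channel
attention.  With both options switched off it reduces to a plain U-Net;
with SE off only, it is the "RISEU-Net-N" ablation.  Residual blocks
compute ``X + F(X)`` so the conv stack learns the residual
``F(X) = M(X) - X`` — with F zeroed the block is exactly the identity.

Preprocessing mirrors clinical practice on head CT: strip the bright
cranial bone (skull), standardize intensities inside the brain, smooth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import ndimage

from . import nn
from .core import ImageVolume, SegmentationMask, ValidationError
from .metrics_losses import soft_dice_loss, soft_new_dice_loss
from .nn import autodiff as ad
from .nn.autodiff import Tensor

__all__ = [
    "SegNetConfig", "SegTrainConfig", "SeparableCostSpec",
    "preprocess_ct", "se_block", "ResidualBlock", "residual_block",
    "RISEUNet", "build_riseu_net", "separable_cost_ratio",
    "train_segmenter", "predict_mask", "save_segmenter", "load_segmenter",
]


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

SKULL_THRESHOLD_HU = 300.0  # cortical bone sits far above any soft tissue


def preprocess_ct(image: ImageVolume, smoothing_sigma: float = 1.0,
                  return_brain_mask: bool = False):
    """Skull-strip, smooth and standardize a HU-calibrated head CT.

    The skull is everything above +300 HU; the brain is the filled
    interior of the skull.  Skull and background voxels are set to 0,
    the brain is Gaussian-smoothed and then z-scored (zero mean, unit
    variance inside the brain mask).  If no skull is found a warning is
    issued and the whole image is standardized.
    """
    if image.intensity_units != "HU":
        raise ValidationError("preprocess_ct expects a HU-calibrated image")
    arr = image.data
    skull = arr > SKULL_THRESHOLD_HU
    if skull.any():
        closed = ndimage.binary_closing(skull, iterations=2)
        filled = ndimage.binary_fill_holes(closed)
        brain = filled & ~closed
        if not brain.any():  # degenerate ring, fall back to everything inside
            brain = ~closed
    else:
        warnings.warn("no skull found above +300 HU; standardizing whole image",
                      stacklevel=2)
        brain = np.ones(arr.shape, dtype=bool)

    stripped = np.where(brain, arr, 0.0)
    smooth = ndimage.gaussian_filter(stripped, sigma=smoothing_sigma)
    vals = smooth[brain]
    mu, sd = float(vals.mean()), float(vals.std())
    out = np.zeros_like(arr)
    out[brain] = (smooth[brain] - mu) / max(sd, 1e-12)
    vol = ImageVolume(out, image.spacing, "standardized",
                      value_range=(float(out.min()), float(max(out.max(), out.min() + 1))))
    if return_brain_mask:
        return vol, SegmentationMask(brain.astype(np.uint8), image.spacing)
    return vol


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def se_block(features, gate: nn.SEGate):
    """Apply an SE channel-attention gate: per-channel logistic weights
    from a pooled bottleneck, multiplied back onto the features."""
    return gate(features)


class ResidualBlock(nn.Module):
    """out = shortcut(X) + F(X); F = conv-norm-relu-conv-norm (+ SE gate).

    The shortcut is the identity when channel counts agree, a 1x1
    projection otherwise.  Zero-initializing F makes the block an exact
    identity (for matching channels).
    """

    def __init__(self, in_ch: int, out_ch: int, *, use_se: bool = True,
                 se_reduction: int = 4, use_residual: bool = True,
                 separable: bool = False, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        Conv = (lambda i, o: nn.SeparableConv2d(i, o, 3, rng=rng)) if separable \
            else (lambda i, o: nn.Conv2d(i, o, 3, rng=rng))
        self.conv1 = Conv(in_ch, out_ch)
        self.norm1 = nn.ChannelNorm(out_ch)
        self.conv2 = Conv(out_ch, out_ch)
        self.norm2 = nn.ChannelNorm(out_ch)
        self.se = nn.SEGate(out_ch, se_reduction, rng=rng) if use_se else None
        self.use_residual = use_residual
        self.proj = (nn.Conv2d(in_ch, out_ch, 1, rng=rng)
                     if use_residual and in_ch != out_ch else None)

    def residual_branch(self, x):
        h = ad.relu(self.norm1(self.conv1(x)))
        h = self.norm2(self.conv2(h))
        if self.se is not None:
            h = self.se(h)
        return h

    def forward(self, x):
        f = self.residual_branch(x)
        if not self.use_residual:
            return ad.relu(f)
        shortcut = self.proj(x) if self.proj is not None else x
        return shortcut + f

    def force_identity(self) -> None:
        """Zero every parameter of F (requires matching channels)."""
        if self.proj is not None:
            raise ValidationError("identity forcing needs matching channel counts")
        for layer in (self.conv1, self.conv2):
            for p in layer.parameters():
                p.data[:] = 0.0
        for norm in (self.norm1, self.norm2):
            norm.gamma.data[:] = 0.0
            norm.beta.data[:] = 0.0


def residual_block(features, block: ResidualBlock):
    """Functional form of the residual mapping out = X + F(X)."""
    return block(features)


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SegNetConfig:
    """depth encoder levels; channels double per level from base_channels;
    pooling by (h, w) per level; SE reduction ratio r."""

    depth: int = 2
    base_channels: int = 8
    se_reduction: int = 4
    use_se: bool = True
    use_residual: bool = True
    separable: bool = False
    pool: tuple[int, int] = (2, 2)

    def __post_init__(self) -> None:
        if self.base_channels % self.se_reduction:
            raise ValidationError("base_channels must be divisible by se_reduction")
        if self.pool[0] < 1 or self.pool[1] < 1:
            raise ValidationError("pool factors must be >= 1")
        if self.depth < 1:
            raise ValidationError("depth must be >= 1")


class RISEUNet(nn.Module):
    """U-shaped encoder-decoder with skip connections and logistic output."""

    def __init__(self, cfg: SegNetConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        kw = dict(use_se=cfg.use_se, se_reduction=cfg.se_reduction,
                  use_residual=cfg.use_residual, separable=cfg.separable, rng=rng)
        chans = [cfg.base_channels * 2 ** l for l in range(cfg.depth + 1)]
        self.encoders = []
        in_ch = 1
        for l in range(cfg.depth):
            self.encoders.append(ResidualBlock(in_ch, chans[l], **kw))
            in_ch = chans[l]
        self.bottleneck = ResidualBlock(in_ch, chans[cfg.depth], **kw)
        self.up_convs = []
        self.decoders = []
        for l in reversed(range(cfg.depth)):
            self.up_convs.append(nn.Conv2d(chans[l + 1], chans[l], 3, rng=rng))
            self.decoders.append(ResidualBlock(2 * chans[l], chans[l], **kw))
        self.head = nn.Conv2d(chans[0], 1, 1, rng=rng)
        # lesions are a small minority of voxels: start the logistic output
        # near the background prior so Dice-family losses converge quickly
        self.head.bias.data[:] = -2.0

    def _check_shape(self, H: int, W: int) -> None:
        ph, pw = self.cfg.pool
        fh, fw = ph ** self.cfg.depth, pw ** self.cfg.depth
        if H % fh or W % fw:
            need_h = (fh - H % fh) % fh
            need_w = (fw - W % fw) % fw
            raise ValidationError(
                f"input {H}x{W} not divisible by pool^depth ({fh}x{fw}); "
                f"pad by {need_h} rows and {need_w} cols")

    def forward(self, x):
        x = ad.as_tensor(x)
        self._check_shape(x.shape[2], x.shape[3])
        pool = self.cfg.pool
        skips = []
        h = x
        for enc in self.encoders:
            h = enc(h)
            skips.append(h)
            h = ad.maxpool2d(h, pool)
        h = self.bottleneck(h)
        for up, dec, skip in zip(self.up_convs, self.decoders, reversed(skips)):
            h = up(ad.upsample_nearest(h, pool))
            h = dec(ad.concat([skip, h], axis=1))
        return ad.sigmoid(self.head(h))

    def parameter_count(self) -> int:
        return sum(p.data.size for p in self.parameters())


def build_riseu_net(cfg: SegNetConfig = SegNetConfig(), seed: int = 0) -> RISEUNet:
    return RISEUNet(cfg, seed=seed)


# ---------------------------------------------------------------------------
# separable-convolution cost accounting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SeparableCostSpec:
    """Feature-map (H, W), kernel D_K, input channels M, output channels N."""

    H: int
    W: int
    D_K: int
    M: int
    N: int

    def __post_init__(self) -> None:
        for name in ("H", "W", "D_K", "M", "N"):
            if int(getattr(self, name)) < 1:
                raise ValidationError(f"{name} must be a strictly positive integer")


def separable_cost_ratio(spec: SeparableCostSpec, exact: bool = False):
    """Multiply count of a depthwise-separable conv over a standard conv.

    separable = H*W*D_K^2*M (depthwise) + H*W*M*N (pointwise);
    standard  = H*W*D_K^2*M*N.  The ratio reduces to 1/N + 1/D_K^2.
    """
    sep = spec.H * spec.W * spec.D_K ** 2 * spec.M + spec.H * spec.W * spec.M * spec.N
    std = spec.H * spec.W * spec.D_K ** 2 * spec.M * spec.N
    ratio = Fraction(sep, std)
    return ratio if exact else float(ratio)


# ---------------------------------------------------------------------------
# training / inference
# ---------------------------------------------------------------------------

@dataclass
class SegTrainConfig:
    epochs: int = 120
    lr: float = 3e-3
    batch_size: int = 8
    seed: int = 0


def _stack_cases(images, masks):
    xs, ys = [], []
    for img, msk in zip(images, masks):
        a = img.data if not isinstance(img, ImageVolume) else img.data
        m = msk.data if isinstance(msk, SegmentationMask) else np.asarray(msk)
        if a.shape != m.shape:
            raise ValidationError("image and mask shapes differ")
        if not np.all(np.isin(np.unique(m), (0, 1))):
            raise ValidationError("masks must be binary")
        xs.append(a[None])
        ys.append(m[None].astype(np.float64))
    return np.stack(xs), np.stack(ys)


def train_segmenter(model: RISEUNet, images, masks, loss: str = "new_dice",
                    cfg: SegTrainConfig = SegTrainConfig()) -> RISEUNet:
    """Fit the soft Dice-family objective on labeled (image, mask) pairs.

    ``loss`` is ``"dice"`` (overlap only) or ``"new_dice"`` (overlap with
    explicit false-positive and false-negative penalties, discouraging
    over-segmentation).  Per-epoch loss history lands in
    ``model.history``; a fixed seed reproduces it.
    """
    if loss not in ("dice", "new_dice"):
        raise ValidationError(f"unknown loss {loss!r}")
    if len(images) == 0:
        raise ValidationError("need at least one labeled pair")
    X, Y = _stack_cases(images, masks)
    loss_fn = soft_dice_loss if loss == "dice" else soft_new_dice_loss
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(model.parameters(), lr=cfg.lr)
    model.history = []
    n = X.shape[0]
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            prob = model(Tensor(X[idx]))
            l = loss_fn(prob, Y[idx])
            opt.zero_grad()
            l.backward()
            opt.step()
            losses.append(float(l.data))
        model.history.append(float(np.mean(losses)))
    return model


def save_segmenter(model: RISEUNet, path) -> None:
    """Checkpoint: config JSON + parameter arrays in one zip archive."""
    import io
    import json
    import zipfile
    from dataclasses import asdict

    from .cnn_denoise import _zinfo

    meta = {"config": asdict(model.cfg), "history": getattr(model, "history", [])}
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr(_zinfo("meta.json"), json.dumps(meta))
        for i, arr in enumerate(model.state_arrays()):
            buf = io.BytesIO()
            np.save(buf, arr)
            zf.writestr(_zinfo(f"param_{i:04d}.npy"), buf.getvalue())


def load_segmenter(path) -> RISEUNet:
    import io
    import json
    import zipfile

    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        cfg_d = meta["config"]
        cfg_d["pool"] = tuple(cfg_d["pool"])
        model = RISEUNet(SegNetConfig(**cfg_d))
        names = sorted(n for n in zf.namelist() if n.startswith("param_"))
        model.load_state_arrays(np.load(io.BytesIO(zf.read(n))) for n in names)
        model.history = list(meta["history"])
    return model


def predict_mask(model: RISEUNet, image: ImageVolume,
                 threshold: float = 0.5) -> SegmentationMask:
    """Threshold the logistic output map; deterministic."""
    arr = image.data
    if arr.ndim != 2:
        raise ValidationError("predict_mask expects a single 2D slice")
    prob = model(Tensor(arr[None, None])).data[0, 0]
    return SegmentationMask((prob >= threshold).astype(np.uint8), image.spacing)
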