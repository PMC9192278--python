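"""Core containers shared by every stage of the pipeline.

The universal currency is :class:`ImageVolume`, a 2D/3D scalar attenuation
field with grid metadata.  Masks, matched noise pairs and 4D perfusion
series all reference the same grid conventions: axes ordered ``(z, y, x)``
(or ``(y, x)`` for single slices), 0-based voxel indices, spacing in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "ImageVolume",
    "SegmentationMask",
    "NoiseModel",
    "NoisePair",
    "PerfusionSeries",
    "ValidationError",
    "read_volume",
    "write_volume",
    "write_mask",
    "read_mask",
    "write_perfusion_series",
    "read_perfusion_series",
]


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


# "standardized" marks z-scored images produced by CT preprocessing
IntensityUnits = Literal["HU", "normalized", "standardized"]


@dataclass(frozen=True)
class ImageVolume:
    """A 2D or 3D scalar field with grid metadata.

    Parameters
    ----------
    data:
        Array indexed ``(y, x)`` or ``(z, y, x)``, floating point.
    spacing:
        Voxel size in mm per axis, same length as ``data.ndim``.
    intensity_units:
        ``"HU"`` (Hounsfield units) or ``"normalized"`` (values in [0, 1]).
    value_range:
        ``(min, max)`` of the nominal dynamic range; ``max - min`` is the
        MAX used when computing PSNR against this image.
    """

    data: np.ndarray
    spacing: tuple[float, ...] = ()
    intensity_units: IntensityUnits = "HU"
    value_range: tuple[float, float] = (0.0, 255.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=np.float64)
        object.__setattr__(self, "data", arr)
        if arr.ndim not in (2, 3):
            raise ValidationError(f"data must be 2D or 3D, got ndim={arr.ndim}")
        if not np.all(np.isfinite(arr)):
            raise ValidationError("image contains non-finite values")
        spacing = tuple(float(s) for s in (self.spacing or (1.0,) * arr.ndim))
        if len(spacing) != arr.ndim:
            raise ValidationError(
                f"spacing has {len(spacing)} entries for a {arr.ndim}D image"
            )
        if any(s <= 0 for s in spacing):
            raise ValidationError("spacing must be strictly positive")
        object.__setattr__(self, "spacing", spacing)
        lo, hi = self.value_range
        if not (np.isfinite(lo) and np.isfinite(hi)) or hi <= lo:
            raise ValidationError("value_range must be a finite (min, max) with max > min")
        if self.intensity_units == "normalized" and (arr.min() < -1e-9 or arr.max() > 1 + 1e-9):
            raise ValidationError("normalized images must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def max_value(self) -> float:
        """Dynamic range used as MAX in PSNR."""
        lo, hi = self.value_range
        return float(hi - lo)

    def with_data(self, data: np.ndarray) -> "ImageVolume":
        """Same grid and units, new voxel values."""
        return replace(self, data=np.asarray(data, dtype=np.float64))

    def same_grid(self, other: "ImageVolume | SegmentationMask") -> bool:
        return self.shape == other.shape and tuple(self.spacing) == tuple(other.spacing)


@dataclass(frozen=True)
class SegmentationMask:
    """Binary lesion field sharing an :class:`ImageVolume` grid (1 = lesion)."""

    data: np.ndarray
    spacing: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValidationError(f"mask values must be in {{0, 1}}, got {uniq[:5]}")
        arr = arr.astype(np.uint8)
        object.__setattr__(self, "data", arr)
        spacing = tuple(float(s) for s in (self.spacing or (1.0,) * arr.ndim))
        if len(spacing) != arr.ndim or any(s <= 0 for s in spacing):
            raise ValidationError("mask spacing must be positive, one entry per axis")
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def volume_voxels(self) -> int:
        return int(self.data.sum())


@dataclass(frozen=True)
class NoiseModel:
    """Low-dose degradation model: the map from a clean image y to its noisy
    realization chi.  ``sigma`` is the noise standard deviation in the
    image's intensity units."""

    kind: Literal["gaussian", "poisson_gaussian"] = "gaussian"
    sigma: float = 25.0
    seed: int = 0
    # photon scale for the Poisson component (poisson_gaussian only)
    photons: float = 1e4

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "poisson_gaussian"):
            raise ValidationError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise ValidationError("sigma must be >= 0")


@dataclass(frozen=True)
class NoisePair:
    """Matched (clean, low-dose) images on one grid — training fuel for denoisers."""

    clean: ImageVolume
    noisy: ImageVolume
    model: NoiseModel

    def __post_init__(self) -> None:
        if not self.clean.same_grid(self.noisy):
            raise ValidationError("clean and noisy images must share a grid")
        if self.clean.intensity_units != self.noisy.intensity_units:
            raise ValidationError("clean and noisy images must share intensity units")


@dataclass(frozen=True)
class PerfusionSeries:
    """4D contrast dynamics plus the arterial input function (AIF).

    ``frames`` is indexed ``(t, z, y, x)`` (or ``(t, y, x)`` for one slice);
    ``times`` are acquisition times in seconds, strictly increasing;
    ``aif`` is the arterial contrast concentration at each time point.
    ``truth_maps`` optionally carries ground-truth CBF/CBV/MTT fields.
    """

    frames: np.ndarray
    times: np.ndarray
    aif: np.ndarray
    truth_maps: dict[str, np.ndarray] | None = None
    spacing: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=np.float64)
        times = np.asarray(self.times, dtype=np.float64)
        aif = np.asarray(self.aif, dtype=np.float64)
        if frames.ndim not in (3, 4):
            raise ValidationError("frames must be (t, y, x) or (t, z, y, x)")
        if not (len(times) == frames.shape[0] == len(aif)):
            raise ValidationError("times, frames and aif must have equal length")
        if np.any(np.diff(times) <= 0):
            raise ValidationError("times must be strictly increasing")
        if np.any(aif < -1e-9):
            raise ValidationError("aif must be non-negative")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "aif", np.maximum(aif, 0.0))
        spatial_ndim = frames.ndim - 1
        spacing = tuple(float(s) for s in (self.spacing or (1.0,) * spatial_ndim))
        object.__setattr__(self, "spacing", spacing)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        return self.frames.shape[1:]


# ---------------------------------------------------------------------------
# I/O: NIfTI-1 via nibabel, 16-bit PNG via imageio, AIF as two-column CSV.
# NIfTI stores data x-fastest; we keep (z, y, x) in memory and transpose on
# the way in/out so that on-disk files match the usual nibabel (x, y, z).
# ---------------------------------------------------------------------------

def _affine(spacing: Sequence[float]) -> np.ndarray:
    aff = np.eye(4)
    # spacing given (z, y, x) or (y, x); nibabel axes are (x, y, z)
    sp = list(spacing)[::-1]
    for i, s in enumerate(sp[:3]):
        aff[i, i] = s
    return aff


def write_volume(vol: ImageVolume, path: str | Path) -> Path:
    """Write an ImageVolume as NIfTI-1 (.nii or .nii.gz)."""
    import nibabel as nib

    path = Path(path)
    arr = vol.data
    if arr.ndim == 2:
        arr = arr[np.newaxis]  # promote to one-slice volume
        spacing = (1.0, *vol.spacing)
    else:
        spacing = vol.spacing
    img = nib.Nifti1Image(np.ascontiguousarray(arr.T), _affine(spacing))
    img.header["descrip"] = b"strokeseg axes (z,y,x) 0-based"
    nib.save(img, str(path))
    return path


def read_volume(path: str | Path, intensity_units: IntensityUnits = "HU",
                value_range: tuple[float, float] | None = None) -> ImageVolume:
    """Read a NIfTI volume into an ImageVolume (memory order (z, y, x))."""
    import nibabel as nib

    img = nib.load(str(path))
    arr = np.asarray(img.dataobj, dtype=np.float64).T
    zooms = img.header.get_zooms()[: arr.ndim][::-1]
    if arr.ndim == 3 and arr.shape[0] == 1:
        arr = arr[0]
        zooms = zooms[1:]
    if value_range is None:
        value_range = (0.0, 1.0) if intensity_units == "normalized" else (
            float(arr.min()), float(max(arr.max(), arr.min() + 1.0)))
    return ImageVolume(arr, tuple(zooms), intensity_units, value_range)


def write_mask(mask: SegmentationMask, path: str | Path) -> Path:
    import nibabel as nib

    path = Path(path)
    arr = mask.data
    if arr.ndim == 2:
        arr = arr[np.newaxis]
        spacing = (1.0, *mask.spacing)
    else:
        spacing = mask.spacing
    img = nib.Nifti1Image(np.ascontiguousarray(arr.T).astype(np.uint8), _affine(spacing))
    img.header["descrip"] = b"strokeseg axes (z,y,x) 0-based"
    nib.save(img, str(path))
    return path


def read_mask(path: str | Path) -> SegmentationMask:
    import nibabel as nib

    img = nib.load(str(path))
    arr = np.asarray(img.dataobj).T
    zooms = img.header.get_zooms()[: arr.ndim][::-1]
    if arr.ndim == 3 and arr.shape[0] == 1:
        arr = arr[0]
        zooms = zooms[1:]
    return SegmentationMask((arr > 0.5).astype(np.uint8), tuple(zooms))


def write_png_slices(vol: ImageVolume, directory: str | Path, prefix: str = "slice") -> list[Path]:
    """Write each z-slice as a 16-bit PNG, rescaled to the volume's value_range."""
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    arr = vol.data if vol.data.ndim == 3 else vol.data[np.newaxis]
    lo, hi = vol.value_range
    scaled = np.clip((arr - lo) / (hi - lo), 0, 1)
    out = []
    for z in range(scaled.shape[0]):
        p = directory / f"{prefix}_{z:04d}.png"
        iio.imwrite(p, (scaled[z] * 65535).astype(np.uint16))
        out.append(p)
    return out


def write_perfusion_series(series: PerfusionSeries, nifti_path: str | Path,
                           aif_csv_path: str | Path) -> None:
    """4D NIfTI (t last on disk) plus a two-column CSV (time_s, aif)."""
    import nibabel as nib

    frames = series.frames
    if frames.ndim == 3:  # (t, y, x) -> (t, 1, y, x)
        frames = frames[:, np.newaxis]
        spacing = (1.0, *series.spacing)
    else:
        spacing = series.spacing
    # on disk: (x, y, z, t)
    img = nib.Nifti1Image(np.ascontiguousarray(frames.transpose(3, 2, 1, 0)),
                          _affine(spacing))
    img.header["descrip"] = b"strokeseg axes (t,z,y,x) 0-based"
    nib.save(img, str(nifti_path))
    with open(aif_csv_path, "w") as fh:
        fh.write("time_s,aif\n")
        for t, a in zip(series.times, series.aif):
            fh.write(f"{t:.6g},{a:.9g}\n")


def read_perfusion_series(nifti_path: str | Path, aif_csv_path: str | Path) -> PerfusionSeries:
    import nibabel as nib

    img = nib.load(str(nifti_path))
    arr = np.asarray(img.dataobj, dtype=np.float64)
    if arr.ndim != 4:
        raise ValidationError("perfusion series must be a 4D NIfTI")
    frames = arr.transpose(3, 2, 1, 0)  # -> (t, z, y, x)
    if frames.shape[1] == 1:
        frames = frames[:, 0]
    table = np.genfromtxt(str(aif_csv_path), delimiter=",", names=True)
    times = np.atleast_1d(table["time_s"]).astype(np.float64)
    aif = np.atleast_1d(table["aif"]).astype(np.float64)
    zooms = img.header.get_zooms()
    spacing = tuple(float(z) for z in zooms[:3][::-1])
    if frames.ndim == 3:
        spacing = spacing[-2:]
    return PerfusionSeries(frames, times, aif, spacing=spacing)
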