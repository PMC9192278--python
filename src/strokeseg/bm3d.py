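"""Two-stage BM3D collaborative filtering, written from scratch.

Stage 1 (hard): similar image blocks are grouped by squared-difference
distance into a 3D stack, transformed (2D DCT per block + 1D orthonormal
Haar along the group axis), hard-thresholded at ``lambda3d * sigma``,
inverse-transformed and aggregated back into the image by weighted
averaging.  Stage 2 (Wiener): grouping is repeated on the stage-1 basic
estimate, and the noisy coefficients are shrunk by empirical Wiener
weights computed from the pilot's coefficient energies.

Defaults follow the classic profile: 8x8 blocks, 39-pixel search window,
groups of up to 16, lambda 2.7, reference-block step 3.  Tie-breaking in
matching is raster (row-major) order for reproducibility; group sizes are
truncated to a power of two so the Haar transform along the group axis is
orthonormal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.fft import dctn, idctn

from .core import ImageVolume, ValidationError

__all__ = ["BM3DParams", "BlockGroup", "block_match", "bm3d_stage", "bm3d_denoise"]


@dataclass(frozen=True)
class BM3DParams:
    """Grouping and shrinkage parameters.

    ``match_threshold`` is a per-pixel mean squared-difference cutoff in
    squared intensity units; ``sigma`` is the assumed noise standard
    deviation in intensity units.
    """

    block_size: int = 8
    search_window: int = 39
    max_group_size: int = 16
    # the Wiener stage benefits from deeper stacks (its shrinkage is matched
    # to the pilot, so over-grouping costs little); classic profile: 32
    wiener_max_group_size: int = 32
    match_threshold: float = 2500.0
    wiener_match_threshold: float = 2500.0
    lambda3d: float = 2.7
    sigma: float = 25.0
    step: int = 3
    transform: str = "dct_haar"

    def __post_init__(self) -> None:
        if self.block_size > self.search_window:
            raise ValidationError("block_size must be <= search_window")
        for n in (self.max_group_size, self.wiener_max_group_size):
            if n < 1 or (n & (n - 1)):
                raise ValidationError("group sizes must be powers of two")
        if self.sigma < 0 or self.lambda3d < 0:
            raise ValidationError("sigma and lambda3d must be >= 0")
        if self.step < 1:
            raise ValidationError("step must be >= 1")
        if self.transform != "dct_haar":
            raise ValidationError(f"unknown transform {self.transform!r}")


@dataclass(frozen=True)
class BlockGroup:
    """A stack of mutually similar blocks; the reference is always member 0."""

    coords: tuple[tuple[int, int], ...]
    stack: np.ndarray  # (n_blocks, b, b)
    reference_index: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.reference_index < len(self.coords)):
            raise ValidationError("reference block must be a member of its group")
        if self.stack.shape[0] != len(self.coords):
            raise ValidationError("stack and coords disagree on group size")


def _require_2d(vol: ImageVolume) -> np.ndarray:
    if vol.data.ndim != 2:
        raise ValidationError("BM3D operates on 2D slices")
    return vol.data


def _match(match_img: np.ndarray, i: int, j: int, p: BM3DParams,
           power_of_two: bool = True, threshold: float | None = None,
           max_group: int | None = None) -> list[tuple[int, int]]:
    """Coordinates of up to max_group_size most-similar blocks, reference
    first, remaining sorted by distance with raster-order tie-breaks."""
    b = p.block_size
    H, W = match_img.shape
    if not (0 <= i <= H - b and 0 <= j <= W - b):
        raise ValidationError(f"reference block at {(i, j)} extends past the border")
    hw = max((p.search_window - b) // 2, 0)
    i0, i1 = max(0, i - hw), min(H - b, i + hw)
    j0, j1 = max(0, j - hw), min(W - b, j + hw)
    blocks = sliding_window_view(match_img, (b, b))
    cand = blocks[i0:i1 + 1, j0:j1 + 1]
    ref = blocks[i, j]
    if threshold is None:
        threshold = p.match_threshold
    if max_group is None:
        max_group = p.max_group_size
    d = ((cand - ref) ** 2).mean(axis=(2, 3))
    ii, jj = np.meshgrid(np.arange(i0, i1 + 1), np.arange(j0, j1 + 1), indexing="ij")
    flat = np.column_stack([d.ravel(), ii.ravel(), jj.ravel()])
    keep = flat[flat[:, 0] <= threshold]
    # stable sort on (distance, raster index): raster order breaks ties
    order = np.lexsort((keep[:, 1] * W + keep[:, 2], keep[:, 0]))
    coords = [(i, j)]
    for k in order:
        ci, cj = int(keep[k, 1]), int(keep[k, 2])
        if (ci, cj) == (i, j):
            continue
        coords.append((ci, cj))
        if len(coords) == max_group:
            break
    if power_of_two:
        n = 1
        while n * 2 <= len(coords):
            n *= 2
        coords = coords[:n]
    return coords


def block_match(image: ImageVolume, ref: tuple[int, int],
                params: BM3DParams) -> BlockGroup:
    """Group the blocks most similar to the reference block at ``ref``."""
    img = _require_2d(image)
    coords = _match(img, ref[0], ref[1], params, power_of_two=False)
    b = params.block_size
    stack = np.stack([img[i:i + b, j:j + b] for i, j in coords])
    return BlockGroup(tuple(coords), stack, reference_index=0)


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def _haar(x: np.ndarray) -> np.ndarray:
    """Orthonormal Haar transform along axis 0 (length a power of two)."""
    n = x.shape[0]
    out = x.copy()
    length = n
    while length > 1:
        half = length // 2
        a = (out[0:length:2] + out[1:length:2]) / np.sqrt(2.0)
        d = (out[0:length:2] - out[1:length:2]) / np.sqrt(2.0)
        out[:half] = a
        out[half:length] = d
        length = half
    return out


def _ihaar(x: np.ndarray) -> np.ndarray:
    n = x.shape[0]
    out = x.copy()
    length = 2
    while length <= n:
        half = length // 2
        a = out[:half].copy()
        d = out[half:length].copy()
        out[0:length:2] = (a + d) / np.sqrt(2.0)
        out[1:length:2] = (a - d) / np.sqrt(2.0)
        length *= 2
    return out


def _group_transform(stack: np.ndarray) -> np.ndarray:
    return _haar(dctn(stack, axes=(1, 2), norm="ortho"))


def _group_inverse(coef: np.ndarray) -> np.ndarray:
    return idctn(_ihaar(coef), axes=(1, 2), norm="ortho")


def _ref_grid(n: int, b: int, step: int) -> list[int]:
    grid = list(range(0, n - b + 1, step))
    if grid[-1] != n - b:
        grid.append(n - b)
    return grid


def bm3d_stage(noisy: ImageVolume, pilot: ImageVolume | None,
               params: BM3DParams, mode: str = "hard") -> ImageVolume:
    """One collaborative-filtering pass over a 2D slice.

    ``hard``: 3D-transform coefficients with magnitude below
    ``lambda3d * sigma`` are zeroed.  ``wiener``: requires ``pilot`` (the
    stage-1 basic estimate); matching runs on the pilot and coefficients
    are shrunk by W = P^2 / (P^2 + sigma^2).
    """
    if mode not in ("hard", "wiener"):
        raise ValidationError(f"unknown mode {mode!r}")
    if mode == "wiener" and pilot is None:
        raise ValidationError("wiener mode requires the stage-1 pilot estimate")
    img = _require_2d(noisy)
    match_img = _require_2d(pilot) if mode == "wiener" else img
    b = params.block_size
    H, W = img.shape
    if H < b or W < b:
        raise ValidationError(f"image {img.shape} smaller than block size {b}")

    noisy_blocks = sliding_window_view(img, (b, b))
    noisy_dct = dctn(np.ascontiguousarray(noisy_blocks), axes=(2, 3), norm="ortho")
    if mode == "wiener":
        pilot_blocks = sliding_window_view(match_img, (b, b))
        pilot_dct = dctn(np.ascontiguousarray(pilot_blocks), axes=(2, 3), norm="ortho")

    num = np.zeros_like(img)
    den = np.zeros_like(img)
    thr = params.lambda3d * params.sigma
    sig2 = params.sigma ** 2
    match_thr = (params.wiener_match_threshold if mode == "wiener"
                 else params.match_threshold)
    max_group = (params.wiener_max_group_size if mode == "wiener"
                 else params.max_group_size)

    for i in _ref_grid(H, b, params.step):
        for j in _ref_grid(W, b, params.step):
            coords = _match(match_img, i, j, params, threshold=match_thr,
                            max_group=max_group)
            rows = np.array([c[0] for c in coords])
            cols = np.array([c[1] for c in coords])
            coef = _haar(noisy_dct[rows, cols])
            if mode == "hard":
                if thr > 0:
                    mask = np.abs(coef) >= thr
                    coef = coef * mask
                    n_ret = max(int(mask.sum()), 1)
                else:
                    n_ret = coef.size
                weight = 1.0 / (sig2 * n_ret) if sig2 > 0 else 1.0
            else:
                pcoef = _haar(pilot_dct[rows, cols])
                wien = pcoef ** 2 / (pcoef ** 2 + sig2) if sig2 > 0 else np.ones_like(pcoef)
                coef = coef * wien
                wsum = float((wien ** 2).sum())
                weight = 1.0 / (sig2 * wsum) if sig2 > 0 and wsum > 0 else 1.0
            filtered = _group_inverse(coef)
            for k, (bi, bj) in enumerate(coords):
                num[bi:bi + b, bj:bj + b] += weight * filtered[k]
                den[bi:bi + b, bj:bj + b] += weight

    out = np.where(den > 0, num / np.maximum(den, 1e-300), img)
    return noisy.with_data(out)


def _per_slice(vol: ImageVolume):
    if vol.data.ndim == 2:
        yield vol, None
    else:
        for z in range(vol.data.shape[0]):
            yield vol.with_data(vol.data[z]), z


def bm3d_denoise(noisy: ImageVolume, params: BM3DParams = BM3DParams()) -> ImageVolume:
    """Full two-stage BM3D: hard-threshold stage, then Wiener refinement
    with the stage-1 output as pilot.  3D volumes are filtered slice-wise."""
    if noisy.data.ndim == 2:
        basic = bm3d_stage(noisy, None, params, mode="hard")
        return bm3d_stage(noisy, basic, params, mode="wiener")
    out = np.empty_like(noisy.data)
    for z in range(noisy.data.shape[0]):
        sl = ImageVolume(noisy.data[z], noisy.spacing[1:], noisy.intensity_units,
                         noisy.value_range)
        basic = bm3d_stage(sl, None, params, mode="hard")
        out[z] = bm3d_stage(sl, basic, params, mode="wiener").data
    return noisy.with_data(out)
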