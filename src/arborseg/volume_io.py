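"""Volume I/O, resampling, and the patch representation used for training.

Volumes travel as NIfTI-1 files: intensities as 4D (D, H, W, 2) float images
(the two channels are the T1w-like and T2w-like contrasts), labels as 3D
int16 images with codes {0..3}, voxel spacing in the header. In memory,
training and inference operate on fixed-size cubic patches; whole-volume
probability maps are reassembled by averaging overlapping patch predictions
on a regular sliding-window grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .types import (
    N_CLASSES,
    IntensityVolume,
    LabelVolume,
    ProbabilityMaps,
    TISSUE_CODES,
)


class LabelFormatError(ValueError):
    """A label file contains values outside the tissue-code alphabet."""


class PatchSizingError(ValueError):
    """Volume too small for the requested patch size."""


class CoverageError(ValueError):
    """A foreground voxel is not covered by any patch during reconstruction."""


def write_volume(volume: IntensityVolume | LabelVolume, path: str | Path) -> Path:
    """Write a volume as NIfTI-1 with spacing in the header zooms."""
    path = Path(path)
    if isinstance(volume, LabelVolume):
        data = volume.voxels.astype(np.int16)
    else:
        # channels last on disk: (D, H, W, 2)
        data = np.moveaxis(volume.voxels, 0, -1).astype(np.float32)
    img = nib.Nifti1Image(data, affine=np.diag(list(volume.spacing) + [1.0]))
    img.header.set_zooms(volume.spacing + ((1.0,) if data.ndim == 4 else ()))
    nib.save(img, str(path))
    return path


def read_volume(path: str | Path) -> IntensityVolume | LabelVolume:
    """Read a NIfTI-1 volume; 3D integer-valued files become label volumes.

    Label files are validated to the tissue-code alphabet {0, 1, 2, 3}; any
    other value raises :class:`LabelFormatError` naming the offending codes.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    zooms = img.header.get_zooms()
    if data.ndim == 4:
        if data.shape[-1] != 2:
            raise ValueError(
                f"expected 2 channels in 4D file, got {data.shape[-1]}"
            )
        return IntensityVolume(
            np.moveaxis(data.astype(np.float32), -1, 0), spacing=tuple(zooms[:3])
        )
    if data.ndim != 3:
        raise ValueError(f"expected a 3D or 4D NIfTI file, got {data.ndim}D")
    if not np.issubdtype(data.dtype, np.integer):
        if not np.allclose(data, np.round(data)):
            raise LabelFormatError("3D label file contains non-integer values")
        data = np.round(data).astype(np.int16)
    bad = sorted(set(np.unique(data)) - set(TISSUE_CODES))
    if bad:
        raise LabelFormatError(f"label file contains invalid tissue codes: {bad}")
    return LabelVolume(data.astype(np.int16), spacing=tuple(zooms[:3]))


def resample_isotropic(
    volume: IntensityVolume | LabelVolume, target_spacing: float = 0.8
):
    """Resample to isotropic ``target_spacing`` mm.

    Linear interpolation for intensities, nearest-neighbor for labels. New
    extent per axis is ``round(extent * spacing / target)``. A volume already
    at the target spacing is returned unchanged.
    """
    if target_spacing <= 0:
        raise ValueError("target_spacing must be positive")
    spacing = np.asarray(volume.spacing, dtype=float)
    if np.allclose(spacing, target_spacing):
        return volume
    zoom = spacing / target_spacing
    new_spacing = (target_spacing,) * 3
    if isinstance(volume, LabelVolume):
        out = ndimage.zoom(volume.voxels, zoom, order=0, mode="nearest")
        return LabelVolume(out.astype(np.int16), spacing=new_spacing)
    out = np.stack(
        [ndimage.zoom(ch, zoom, order=1, mode="nearest") for ch in volume.voxels]
    )
    return IntensityVolume(out, spacing=new_spacing, domain_id=volume.domain_id)


def foreground_mask(intensity: IntensityVolume) -> np.ndarray:
    """Head-like foreground mask: Otsu threshold on the smoothed first channel."""
    from skimage.filters import threshold_otsu

    img = ndimage.gaussian_filter(intensity.voxels[0].astype(float), 1.0)
    if np.ptp(img) < 1e-8:
        return np.ones(img.shape, dtype=bool)
    return img > threshold_otsu(img)


@dataclass
class PatchSet:
    """Fixed-size cubic patches sampled from one volume.

    ``intensity`` blocks are (2, s, s, s); optional aligned ``labels`` blocks
    are (s, s, s); ``corners`` are the 0-based corner voxel positions in the
    source volume. Optional ``extra`` holds further aligned blocks (e.g.
    per-voxel weights during self-training).
    """

    intensity: list[np.ndarray]
    corners: list[tuple[int, int, int]]
    size: int
    source_shape: tuple[int, int, int]
    source_spacing: tuple[float, float, float]
    labels: list[np.ndarray] | None = None
    extra: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.corners)


def _valid_corner_mask(mask: np.ndarray, size: int) -> np.ndarray:
    """Boolean array over corner positions whose patch window touches ``mask``."""
    shape = mask.shape
    # integral image: window sum > 0 <=> window intersects the mask
    ii = np.zeros(tuple(s + 1 for s in shape), dtype=np.int64)
    ii[1:, 1:, 1:] = mask.astype(np.int64).cumsum(0).cumsum(1).cumsum(2)
    nz, ny, nx = (shape[i] - size + 1 for i in range(3))
    z0, y0, x0 = np.meshgrid(
        np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij"
    )
    z1, y1, x1 = z0 + size, y0 + size, x0 + size
    win = (
        ii[z1, y1, x1]
        - ii[z0, y1, x1] - ii[z1, y0, x1] - ii[z1, y1, x0]
        + ii[z0, y0, x1] + ii[z0, y1, x0] + ii[z1, y0, x0]
        - ii[z0, y0, x0]
    )
    return win > 0


def extract_patches(
    intensity: IntensityVolume,
    labels: LabelVolume | None = None,
    n: int = 1000,
    size: int = 32,
    seed: int = 0,
    mask: np.ndarray | None = None,
    extra: dict | None = None,
) -> PatchSet:
    """Randomly sample ``n`` cubic patches of edge ``size`` from a volume.

    Corner positions are drawn uniformly (with replacement) over positions
    whose patch window overlaps the non-background mask, so the sampling
    budget is not spent on empty air. Deterministic given ``seed``.
    """
    shape = intensity.shape
    if any(s < size for s in shape):
        raise PatchSizingError(f"volume shape {shape} smaller than patch size {size}")
    if labels is not None and labels.shape != shape:
        raise ValueError("labels shape does not match intensity shape")
    if mask is None:
        mask = labels.voxels > 0 if labels is not None else foreground_mask(intensity)
    valid = _valid_corner_mask(mask, size)
    candidates = np.argwhere(valid)
    if len(candidates) == 0:
        candidates = np.array([[0, 0, 0]])
    rng = np.random.default_rng(seed)
    picks = candidates[rng.integers(len(candidates), size=n)]

    ps = PatchSet(
        intensity=[],
        corners=[],
        size=size,
        source_shape=shape,
        source_spacing=intensity.spacing,
        labels=[] if labels is not None else None,
    )
    extra_arrays = extra or {}
    ps.extra = {k: [] for k in extra_arrays}
    for z, y, x in picks:
        sl = (slice(z, z + size), slice(y, y + size), slice(x, x + size))
        ps.intensity.append(intensity.voxels[(slice(None),) + sl])
        ps.corners.append((int(z), int(y), int(x)))
        if labels is not None:
            ps.labels.append(labels.voxels[sl])
        for k, arr in extra_arrays.items():
            ps.extra[k].append(arr[(Ellipsis,) + sl])
    return ps


def sliding_window_corners(
    shape: tuple[int, int, int], size: int, overlap: float = 0.5
) -> list[tuple[int, int, int]]:
    """Regular dense grid of patch corners covering the whole volume.

    Stride is ``size * (1 - overlap)``; the final corner on each axis is
    clamped so the last patch ends exactly at the volume boundary.
    """
    stride = max(1, int(round(size * (1.0 - overlap))))
    axes = []
    for extent in shape:
        if extent < size:
            raise PatchSizingError(f"extent {extent} smaller than patch size {size}")
        positions = list(range(0, extent - size + 1, stride))
        if positions[-1] != extent - size:
            positions.append(extent - size)
        axes.append(positions)
    return [(z, y, x) for z in axes[0] for y in axes[1] for x in axes[2]]


def reconstruct_from_patches(
    blocks: list[np.ndarray],
    corners: list[tuple[int, int, int]],
    source_shape: tuple[int, int, int],
    spacing: tuple[float, float, float] = (0.8, 0.8, 0.8),
    foreground: np.ndarray | None = None,
) -> ProbabilityMaps:
    """Fuse per-patch class-probability blocks into whole-volume maps.

    Each voxel's probability vector is the average over all covering patches,
    renormalized to the simplex. Voxels covered by no patch (restricted to
    ``foreground`` when given) raise :class:`CoverageError`.
    """
    if len(blocks) != len(corners):
        raise ValueError("blocks and corners must have equal length")
    if not blocks:
        raise ValueError("no patches to reconstruct from")
    n_classes = blocks[0].shape[0]
    acc = np.zeros((n_classes,) + tuple(source_shape), dtype=np.float64)
    cnt = np.zeros(source_shape, dtype=np.int32)
    for blk, (z, y, x) in zip(blocks, corners):
        s = blk.shape[1]
        sl = (slice(z, z + s), slice(y, y + s), slice(x, x + s))
        acc[(slice(None),) + sl] += blk
        cnt[sl] += 1
    uncovered = cnt == 0
    check = uncovered if foreground is None else (uncovered & foreground)
    if check.any():
        raise CoverageError(f"{int(check.sum())} foreground voxels not covered by any patch")
    cnt_safe = np.maximum(cnt, 1)
    acc /= cnt_safe
    total = acc.sum(axis=0)
    total[total <= 0] = 1.0
    acc /= total
    return ProbabilityMaps(acc.astype(np.float32), spacing=spacing)
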