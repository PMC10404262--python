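"""Volume- and surface-based segmentation evaluation: Dice and HD95.

Dice ratio is the volume-overlap score ``2|A n B| / (|A| + |B|)`` per tissue
class. HD95 is the robust surface distance: surface voxels are mask voxels
with at least one face-adjacent neighbor outside the mask (out-of-bounds
counts as outside); directed distances from each surface to the nearest
voxel of the other surface are scaled by the voxel spacing, and HD95 is the
maximum of the two directed 95th percentiles (linear-interpolation
percentile), which makes it symmetric under argument swap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .types import CSF, GM, WM, LabelVolume, TISSUE_NAMES

_FACE = ndimage.generate_binary_structure(3, 1)


def dice(seg: LabelVolume, ref: LabelVolume, class_code: int) -> float:
    """Dice overlap of one tissue class; NaN when the class is absent from both."""
    if seg.shape != ref.shape:
        raise ValueError(f"shape mismatch: {seg.shape} vs {ref.shape}")
    a = seg.voxels == class_code
    b = ref.voxels == class_code
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return math.nan
    return 2.0 * int((a & b).sum()) / (na + nb)


def surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Mask voxels with a face-adjacent outside neighbor (or at the border)."""
    return mask & ~ndimage.binary_erosion(mask, structure=_FACE, border_value=0)


def hd95(
    seg: LabelVolume,
    ref: LabelVolume,
    class_code: int,
    spacing: tuple[float, float, float] | None = None,
) -> float:
    """95th-percentile symmetric surface distance in mm for one class.

    NaN when either volume lacks the class entirely (undefined rather than
    scored). Identical masks give exactly 0.
    """
    if seg.shape != ref.shape:
        raise ValueError(f"shape mismatch: {seg.shape} vs {ref.shape}")
    spacing = spacing or seg.spacing
    a = seg.voxels == class_code
    b = ref.voxels == class_code
    if not a.any() or not b.any():
        return math.nan
    sa = surface_voxels(a)
    sb = surface_voxels(b)
    # nearest-surface distance fields, anisotropy-aware
    dt_b = ndimage.distance_transform_edt(~sb, sampling=spacing)
    dt_a = ndimage.distance_transform_edt(~sa, sampling=spacing)
    d_ab = dt_b[sa]
    d_ba = dt_a[sb]
    return float(
        max(
            np.percentile(d_ab, 95, method="linear"),
            np.percentile(d_ba, 95, method="linear"),
        )
    )


@dataclass
class ClassScore:
    dice: float
    hd95: float
    n_seg: int
    n_ref: int

    @property
    def defined(self) -> bool:
        return not (math.isnan(self.dice) and math.isnan(self.hd95))


@dataclass
class EvalReport:
    """Per-class Dice/HD95 for the three tissues (background excluded)."""

    scores: dict[str, ClassScore] = field(default_factory=dict)

    def __getitem__(self, name: str) -> ClassScore:
        return self.scores[name]

    def to_rows(self, **extra) -> list[dict]:
        return [
            {**extra, "class": name, "dice": s.dice, "hd95": s.hd95}
            for name, s in self.scores.items()
        ]


def evaluate(
    seg: LabelVolume,
    ref: LabelVolume,
    spacing: tuple[float, float, float] | None = None,
) -> EvalReport:
    """Dice and HD95 for CSF, GM, and WM against a reference labeling."""
    if seg.shape != ref.shape:
        raise ValueError(f"shape mismatch: {seg.shape} vs {ref.shape}")
    spacing = spacing or ref.spacing
    report = EvalReport()
    for code in (CSF, GM, WM):
        report.scores[TISSUE_NAMES[code]] = ClassScore(
            dice=dice(seg, ref, code),
            hd95=hd95(seg, ref, code, spacing),
            n_seg=int((seg.voxels == code).sum()),
            n_ref=int((ref.voxels == code).sum()),
        )
    return report
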