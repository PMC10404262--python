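"""Core in-memory containers for volumes and tissue maps.

Tissue codes follow the four-class convention used throughout the package:
0 = background, 1 = cerebrospinal fluid (CSF), 2 = gray matter (GM),
3 = white matter (WM).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BACKGROUND, CSF, GM, WM = 0, 1, 2, 3
TISSUE_CODES = (BACKGROUND, CSF, GM, WM)
TISSUE_NAMES = {BACKGROUND: "background", CSF: "CSF", GM: "GM", WM: "WM"}
N_CLASSES = 4


@dataclass
class LabelVolume:
    """Integer 3D tissue map with voxel codes in {0, 1, 2, 3}."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (0.8, 0.8, 0.8)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"label volume must be 3D, got shape {self.voxels.shape}")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise ValueError("label volume must have an integer dtype")
        bad = set(np.unique(self.voxels)) - set(TISSUE_CODES)
        if bad:
            raise ValueError(f"label volume contains invalid tissue codes: {sorted(bad)}")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class IntensityVolume:
    """Two-channel (T1w-like, T2w-like) 3D intensity volume.

    ``voxels`` has shape (2, D, H, W); channel 0 is the T1w-like contrast,
    channel 1 the T2w-like contrast.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (0.8, 0.8, 0.8)
    domain_id: str | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 4 or self.voxels.shape[0] != 2:
            raise ValueError(
                f"intensity volume must have shape (2, D, H, W), got {self.voxels.shape}"
            )
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("intensity volume contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape[1:]

    @property
    def n_channels(self) -> int:
        return self.voxels.shape[0]


@dataclass
class ProbabilityMaps:
    """Per-voxel 4-class probabilities, shape (4, D, H, W), simplex-constrained."""

    maps: np.ndarray
    spacing: tuple[float, float, float] = (0.8, 0.8, 0.8)

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=np.float32)
        if self.maps.ndim != 4 or self.maps.shape[0] != N_CLASSES:
            raise ValueError(
                f"probability maps must have shape ({N_CLASSES}, D, H, W), got {self.maps.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.maps.shape[1:]

    def argmax_labels(self) -> LabelVolume:
        """Hard labels: arg-max class per voxel, ties broken toward the lowest code."""
        return LabelVolume(
            np.argmax(self.maps, axis=0).astype(np.int16), spacing=self.spacing
        )


@dataclass
class ConfidenceMap:
    """Per-voxel reliability score in [0, 1] (the confidence model output M_cp)."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (0.8, 0.8, 0.8)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3:
            raise ValueError(f"confidence map must be 3D, got shape {self.values.shape}")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise ValueError("confidence values must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


def one_hot(labels: np.ndarray, n_classes: int = N_CLASSES) -> np.ndarray:
    """One-hot encode an integer label array to shape (n_classes, *labels.shape)."""
    out = np.zeros((n_classes,) + labels.shape, dtype=np.float32)
    for c in range(n_classes):
        out[c] = labels == c
    return out
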