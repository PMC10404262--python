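"""Four-class tissue segmentation backbone and its supervised training loop.

The backbone follows the dense-block encoder-decoder design used for infant
brain tissue segmentation: a contracting path and an expanding path with
skip connections, passing through seven dense blocks. Each dense block
stacks three BN-ReLU-Conv-Dropout units (16 kernels per convolution,
dropout 0.1 at reference scale); 1-cubed compression convolutions and 2x
average pooling / nearest-neighbor upsampling sit between blocks. The final
stage is a 1-cubed convolution followed by a per-voxel softmax over the four
classes (background, CSF, GM, WM).

Training is minibatch SGD on randomly extracted multi-channel patches with
the multi-class cross-entropy loss, Xavier initialization, learning rate
0.005 multiplied by 0.1 after each epoch.
"""

from __future__ import annotations

import copy
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .nn import F
from .types import (
    N_CLASSES,
    IntensityVolume,
    LabelVolume,
    ProbabilityMaps,
    one_hot,
)
from .volume_io import (
    extract_patches,
    foreground_mask,
    reconstruct_from_patches,
    sliding_window_corners,
)


@dataclass
class SegModelConfig:
    """Architecture hyperparameters of the segmentation backbone.

    ``size_scale`` multiplies ``kernels_per_conv`` so desk-scale runs can
    shrink network width without changing the wiring; 1.0 reproduces the
    reference 16 kernels per convolution.
    """

    n_classes: int = N_CLASSES
    n_dense_blocks: int = 7
    convs_per_block: int = 3
    kernels_per_conv: int = 16
    dropout_rate: float = 0.1
    in_channels: int = 2
    size_scale: float = 1.0

    @property
    def growth(self) -> int:
        return max(1, int(round(self.kernels_per_conv * self.size_scale)))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SegModelConfig":
        return cls(**d)


@dataclass
class TrainConfig:
    """Optimization recipe for patch-based training."""

    learning_rate: float = 0.005
    lr_decay: float = 0.1  # multiplied onto the lr after each epoch
    momentum: float = 0.9
    n_epochs: int = 4
    batch_size: int = 8
    patches_per_subject: int = 1000
    patch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        return cls(**d)


class _SegNet(nn.Module):
    """Dense-block encoder-decoder with skips; resolution path 1 -> 1/8 -> 1."""

    def __init__(self, cfg: SegModelConfig, rng: np.random.Generator):
        super().__init__()
        if cfg.n_dense_blocks != 7:
            raise ValueError("the encoder-decoder wiring is defined for 7 dense blocks")
        g = cfg.growth
        s = g  # compressed width between blocks
        dd = dict(growth=g, n_convs=cfg.convs_per_block, dropout_rate=cfg.dropout_rate, rng=rng)

        self.db1 = nn.DenseBlock(cfg.in_channels, **dd)
        self.comp1 = nn.Conv3d(self.db1.out_channels, s, 1, rng)
        self.db2 = nn.DenseBlock(s, **dd)
        self.comp2 = nn.Conv3d(self.db2.out_channels, s, 1, rng)
        self.db3 = nn.DenseBlock(s, **dd)
        self.comp3 = nn.Conv3d(self.db3.out_channels, s, 1, rng)
        self.db4 = nn.DenseBlock(s, **dd)  # bottleneck at 1/8 resolution
        self.comp4 = nn.Conv3d(self.db4.out_channels, s, 1, rng)
        self.db5 = nn.DenseBlock(2 * s, **dd)
        self.comp5 = nn.Conv3d(self.db5.out_channels, s, 1, rng)
        self.db6 = nn.DenseBlock(2 * s, **dd)
        self.comp6 = nn.Conv3d(self.db6.out_channels, s, 1, rng)
        self.db7 = nn.DenseBlock(2 * s, **dd)
        self.head = nn.Conv3d(self.db7.out_channels, cfg.n_classes, 1, rng)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        t1 = self.comp1(self.db1(x))
        t2 = self.comp2(self.db2(F.avg_pool2(t1)))
        t3 = self.comp3(self.db3(F.avg_pool2(t2)))
        b = self.comp4(self.db4(F.avg_pool2(t3)))
        u3 = self.comp5(self.db5(F.concat_channels([F.upsample2(b), t3])))
        u2 = self.comp6(self.db6(F.concat_channels([F.upsample2(u3), t2])))
        u1 = self.db7(F.concat_channels([F.upsample2(u2), t1]))
        return F.softmax_channels(self.head(u1))


@dataclass
class SegModel:
    """A segmentation network plus the metadata needed to reuse it."""

    net: _SegNet
    config: SegModelConfig
    seed: int
    patch_size: int = 32
    loss_trace: list = field(default_factory=list)

    def predict_patch_probs(self, batch: np.ndarray) -> np.ndarray:
        """Forward a (N, 2, s, s, s) batch in eval mode -> (N, 4, s, s, s).

        The network runs channels-last internally; this converts at the
        boundary so callers keep the class-first convention of the volume
        containers.
        """
        self.net.eval()
        x = np.ascontiguousarray(np.moveaxis(batch, 1, -1))
        out = self.net(nn.Tensor(x)).data
        return np.moveaxis(out, -1, 1)

    def copy(self) -> "SegModel":
        clone = build_seg_model(self.config, seed=self.seed)
        clone.net.load_state_dict(self.net.state_dict())
        clone.patch_size = self.patch_size
        clone.loss_trace = list(self.loss_trace)
        return clone

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        np.savez_compressed(
            path,
            __meta__=np.bytes_(
                json.dumps(
                    {
                        "config": self.config.to_dict(),
                        "seed": self.seed,
                        "patch_size": self.patch_size,
                        "loss_trace": [float(v) for v in self.loss_trace],
                    }
                ).encode()
            ),
            **self.net.state_dict(),
        )
        return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")

    @classmethod
    def load(cls, path: str | Path) -> "SegModel":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            state = {k: z[k] for k in z.files if k != "__meta__"}
        model = build_seg_model(SegModelConfig.from_dict(meta["config"]), seed=meta["seed"])
        model.net.load_state_dict(state)
        model.patch_size = int(meta["patch_size"])
        model.loss_trace = list(meta["loss_trace"])
        return model


def build_seg_model(config: SegModelConfig | None = None, seed: int = 0) -> SegModel:
    """Construct a Xavier-initialized segmentation model, deterministic in ``seed``."""
    config = config or SegModelConfig()
    rng = np.random.default_rng(seed)
    return SegModel(net=_SegNet(config, rng), config=config, seed=seed)


def segmentation_loss(probs: np.ndarray, target: np.ndarray) -> float:
    """Multi-class cross-entropy on probability maps.

    ``probs`` and ``target`` are class-first arrays of identical shape (the
    target one-hot); the result is the mean over voxels of
    ``-sum_i Y_i ln X_i`` with probabilities clamped to [1e-7, 1].
    """
    probs = np.asarray(probs, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if probs.shape != target.shape:
        raise ValueError(f"shape mismatch: probs {probs.shape} vs target {target.shape}")
    pc = np.clip(probs, F.EPS_LOG, 1.0)
    per_vox = -(target * np.log(pc)).sum(axis=0)
    return float(per_vox.mean())


def _epoch_batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i : i + batch_size]


def train_on_patches(
    model: SegModel,
    x: np.ndarray,
    y_onehot: np.ndarray,
    cfg: TrainConfig,
    weights: np.ndarray | None = None,
) -> SegModel:
    """Minibatch SGD over a fixed patch set; mutates and returns ``model``.

    ``x`` is (N, s, s, s, 2) channels-last, ``y_onehot`` (N, s, s, s, 4),
    ``weights`` per-voxel (N, s, s, s). Weights switch the loss to its
    spatially-weighted form; with no weights the plain cross-entropy is
    used. The learning rate is multiplied by ``cfg.lr_decay`` after every
    epoch. Appends per-epoch mean losses to ``model.loss_trace``.
    """
    opt = nn.SGD(model.net.parameters(), lr=cfg.learning_rate, momentum=cfg.momentum)
    rng = np.random.default_rng(cfg.seed + 1)
    model.net.train()
    for _ in range(cfg.n_epochs):
        losses = []
        for idx in _epoch_batches(len(x), cfg.batch_size, rng):
            probs = model.net(nn.Tensor(x[idx]))
            w = None if weights is None else weights[idx]
            if w is not None and not (w > 0).any():
                losses.append(0.0)  # fully masked batch contributes nothing
                continue
            loss = F.weighted_cross_entropy(probs, y_onehot[idx], w)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        model.loss_trace.append(float(np.mean(losses)))
        opt.lr *= cfg.lr_decay
    model.net.eval()
    return model


def _collect_patches(
    subjects: list[tuple[IntensityVolume, LabelVolume]],
    cfg: TrainConfig,
) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for i, (vol, lab) in enumerate(subjects):
        ps = extract_patches(
            normalize_intensity(vol), lab,
            n=cfg.patches_per_subject, size=cfg.patch_size, seed=cfg.seed * 10007 + i,
        )
        xs.extend(np.moveaxis(blk, 0, -1) for blk in ps.intensity)
        ys.extend(np.moveaxis(one_hot(p), 0, -1) for p in ps.labels)
    return (
        np.ascontiguousarray(np.stack(xs)),
        np.ascontiguousarray(np.stack(ys)),
    )


def normalize_intensity(vol: IntensityVolume) -> IntensityVolume:
    """Z-score each channel over the foreground so inputs are scale-free."""
    mask = foreground_mask(vol)
    out = vol.voxels.copy()
    for c in range(vol.n_channels):
        fg = out[c][mask]
        sd = fg.std()
        out[c] = (out[c] - fg.mean()) / (sd if sd > 1e-6 else 1.0)
    return IntensityVolume(out, spacing=vol.spacing, domain_id=vol.domain_id)


def train_source_model(
    subjects: list[tuple[IntensityVolume, LabelVolume]],
    cfg: TrainConfig | None = None,
    mcfg: SegModelConfig | None = None,
) -> SegModel:
    """Supervised training on labeled source-domain subjects.

    Extracts a fixed set of patches per subject, then runs minibatch SGD
    with the cross-entropy loss. Deterministic given data, configs, and seed.
    """
    if not subjects:
        raise ValueError("at least one labeled subject is required")
    cfg = cfg or TrainConfig()
    mcfg = mcfg or SegModelConfig()
    model = build_seg_model(mcfg, seed=cfg.seed)
    model.patch_size = cfg.patch_size
    x, y = _collect_patches(subjects, cfg)
    return train_on_patches(model, x, y, cfg)


def predict_segmentation(
    model: SegModel,
    volume: IntensityVolume,
    overlap: float = 0.5,
    batch_size: int = 8,
) -> tuple[LabelVolume, ProbabilityMaps]:
    """Whole-volume inference by sliding-window patch fusion.

    Patches on a regular grid with the given overlap are forwarded in eval
    mode; per-voxel probabilities are averaged over covering patches and the
    label map is the per-voxel arg-max (ties resolved toward the lowest
    class code).
    """
    size = model.patch_size
    norm = normalize_intensity(volume)
    corners = sliding_window_corners(volume.shape, size, overlap)
    blocks = []
    for i in range(0, len(corners), batch_size):
        chunk = corners[i : i + batch_size]
        batch = np.stack(
            [
                norm.voxels[:, z : z + size, y : y + size, x : x + size]
                for z, y, x in chunk
            ]
        )
        out = model.predict_patch_probs(batch)
        blocks.extend(out[j] for j in range(len(chunk)))
    probs = reconstruct_from_patches(blocks, corners, volume.shape, spacing=volume.spacing)
    return probs.argmax_labels(), probs
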