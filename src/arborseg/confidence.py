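"""Voxel-wise confidence estimation for automated segmentations.

A segmentation model's errors are not random: misclassified voxels cluster
at tissue boundaries and in low-contrast regions where the predicted class
probabilities hover near 0.5. The confidence model (a small 3D U-Net)
learns to predict, for every voxel, whether the automated segmentation
agrees with the (unseen) manual label. Its training target is the binary
agreement map; its loss is a class-balanced binary cross-entropy in which
the correct-voxel complement term is down-weighted by a constant ``a``
(default 0.1) because correct voxels vastly outnumber errors.

Training pairs come from K-fold self-testing: the labeled subjects are split
into K folds and each fold is segmented by a model trained on the other
folds, so every subject receives a prediction from a model that never saw
it — exactly the error statistics the confidence model will face on unseen
data. A single confidence model trained on the source domain is reused for
all target domains.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .nn import F
from .seg_model import (
    SegModel,
    SegModelConfig,
    TrainConfig,
    predict_segmentation,
    train_source_model,
)
from .types import (
    N_CLASSES,
    ConfidenceMap,
    IntensityVolume,
    LabelVolume,
    ProbabilityMaps,
    one_hot,
)
from .volume_io import reconstruct_from_patches, sliding_window_corners


@dataclass
class ConfLossParams:
    """Class-balance constant for the confidence loss."""

    a: float = 0.1

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("class-balance constant a must be > 0")


@dataclass
class ConfModelConfig:
    """U-Net hyperparameters of the confidence network.

    Input is the one-hot automated segmentation (4 channels) concatenated
    with the tissue probability maps (4 channels); output one confidence
    channel squashed to (0, 1) by a logistic stage.
    """

    in_channels: int = 2 * N_CLASSES
    width: int = 8
    depth: int = 2  # number of resolution levels (encoder depth)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ConfModelConfig":
        return cls(**d)


class _ConvBNRelu(nn.Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        super().__init__()
        self.conv = nn.Conv3d(cin, cout, 3, rng)
        self.bn = nn.BatchNorm3d(cout)

    def __call__(self, x):
        return F.relu(self.bn(self.conv(x)))


class _ConfNet(nn.Module):
    """Two-level U-Net with a sigmoid head."""

    def __init__(self, cfg: ConfModelConfig, rng: np.random.Generator):
        super().__init__()
        w = cfg.width
        self.enc1a = _ConvBNRelu(cfg.in_channels, w, rng)
        self.enc1b = _ConvBNRelu(w, w, rng)
        self.bott_a = _ConvBNRelu(w, 2 * w, rng)
        self.bott_b = _ConvBNRelu(2 * w, 2 * w, rng)
        self.dec1a = _ConvBNRelu(3 * w, w, rng)
        self.dec1b = _ConvBNRelu(w, w, rng)
        self.head = nn.Conv3d(w, 1, 1, rng)

    def __call__(self, x):
        e1 = self.enc1b(self.enc1a(x))
        bott = self.bott_b(self.bott_a(F.avg_pool2(e1)))
        d1 = self.dec1b(self.dec1a(F.concat_channels([F.upsample2(bott), e1])))
        return F.sigmoid(self.head(d1))


@dataclass
class ConfModel:
    """Confidence network plus reuse metadata."""

    net: _ConfNet
    config: ConfModelConfig
    seed: int
    patch_size: int = 32
    loss_trace: list = field(default_factory=list)

    def predict_patch(self, batch: np.ndarray) -> np.ndarray:
        """(N, 8, s, s, s) class-first input -> (N, s, s, s) confidence."""
        self.net.eval()
        x = np.ascontiguousarray(np.moveaxis(batch, 1, -1))
        return self.net(nn.Tensor(x)).data[..., 0]

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
        return path

    @classmethod
    def load(cls, path: str | Path) -> "ConfModel":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            state = {k: z[k] for k in z.files if k != "__meta__"}
        model = build_confidence_model(ConfModelConfig.from_dict(meta["config"]), seed=meta["seed"])
        model.net.load_state_dict(state)
        model.patch_size = int(meta["patch_size"])
        model.loss_trace = list(meta["loss_trace"])
        return model


def build_confidence_model(config: ConfModelConfig | None = None, seed: int = 0) -> ConfModel:
    config = config or ConfModelConfig()
    rng = np.random.default_rng(seed)
    return ConfModel(net=_ConfNet(config, rng), config=config, seed=seed)


def agreement_map(auto_seg: LabelVolume, manual: LabelVolume) -> np.ndarray:
    """Binary agreement target: 1 where the automated segmentation equals the
    manual label, 0 elsewhere. Its mean is the voxel accuracy."""
    if auto_seg.shape != manual.shape:
        raise ValueError(
            f"shape mismatch: auto {auto_seg.shape} vs manual {manual.shape}"
        )
    return (auto_seg.voxels == manual.voxels).astype(np.float32)


def confidence_loss(
    pred: ConfidenceMap | np.ndarray,
    target: np.ndarray,
    params: ConfLossParams | None = None,
) -> float:
    """Class-balanced confidence loss.

    Mean over voxels of ``-(Y ln X + a (1 - Y) ln(1 - X))`` with the
    prediction clamped away from {0, 1}. The asymmetry constant ``a`` scales
    the penalty on correctly-classified voxels' complement term, so a
    confident-wrong prediction on a *misclassified* voxel costs ``a`` times
    the symmetric counterpart.
    """
    params = params or ConfLossParams()
    x = pred.values if isinstance(pred, ConfidenceMap) else np.asarray(pred)
    y = np.asarray(target, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: pred {x.shape} vs target {y.shape}")
    xc = np.clip(x.astype(np.float64), F.EPS_LOG, 1.0 - F.EPS_LOG)
    per_vox = -(y * np.log(xc) + params.a * (1.0 - y) * np.log(1.0 - xc))
    return float(per_vox.mean())


def kfold_self_test(
    subjects: list[tuple[IntensityVolume, LabelVolume]],
    K: int = 2,
    cfg: TrainConfig | None = None,
    mcfg: SegModelConfig | None = None,
    train_fn=None,
    predict_fn=None,
) -> list[tuple[LabelVolume, ProbabilityMaps]]:
    """Out-of-fold automated segmentations for every labeled subject.

    Subjects are split round-robin into ``K`` folds; a segmentation model
    trained on the other K-1 folds predicts each held-out fold, so every
    subject receives exactly one prediction from a model that never trained
    on it. ``K = len(subjects)`` gives leave-one-out behavior.

    ``train_fn(subjects, cfg, mcfg)`` and ``predict_fn(model, volume)`` are
    injectable (protocol tests use stubs); they default to the package's
    training and sliding-window inference.
    """
    n = len(subjects)
    if K < 2:
        raise ValueError("K must be >= 2")
    if n < K:
        raise ValueError(f"need at least K={K} subjects, got {n}")
    cfg = cfg or TrainConfig()
    train_fn = train_fn or train_source_model
    predict_fn = predict_fn or predict_segmentation

    results: list[tuple[LabelVolume, ProbabilityMaps] | None] = [None] * n
    for fold in range(K):
        held = list(range(fold, n, K))
        train_idx = [i for i in range(n) if i not in held]
        fold_cfg = TrainConfig(**{**cfg.to_dict(), "seed": cfg.seed + 101 * fold})
        model = train_fn([subjects[i] for i in train_idx], fold_cfg, mcfg)
        for i in held:
            seg, probs = predict_fn(model, subjects[i][0])
            results[i] = (seg, probs)
    return results  # type: ignore[return-value]


def _conf_input_volume(auto_seg: LabelVolume, probs: ProbabilityMaps) -> np.ndarray:
    """(8, D, H, W): one-hot segmentation stacked with probability maps."""
    return np.concatenate([one_hot(auto_seg.voxels), probs.maps], axis=0)


def train_confidence_model(
    pairs: list[tuple[LabelVolume, ProbabilityMaps, LabelVolume]],
    cfg: TrainConfig | None = None,
    params: ConfLossParams | None = None,
    ccfg: ConfModelConfig | None = None,
) -> ConfModel:
    """Train the confidence network on (auto_seg, probs, manual) triples.

    Inputs are patches of the one-hot automated segmentation concatenated
    with the tissue probability maps; targets are the corresponding
    agreement-map patches. Trained strictly after, and independently of, the
    segmentation model that produced the pairs.
    """
    if not pairs:
        raise ValueError("at least one (auto_seg, probs, manual) pair is required")
    cfg = cfg or TrainConfig()
    params = params or ConfLossParams()
    ccfg = ccfg or ConfModelConfig()
    model = build_confidence_model(ccfg, seed=cfg.seed)
    model.patch_size = cfg.patch_size

    xs, ys = [], []
    for i, (auto_seg, probs, manual) in enumerate(pairs):
        inp = _conf_input_volume(auto_seg, probs)
        target = agreement_map(auto_seg, manual)
        rng = np.random.default_rng(cfg.seed * 7919 + i)
        fg = np.argwhere(manual.voxels > 0)
        err = np.argwhere(target == 0)
        size = cfg.patch_size
        shape = np.array(manual.shape)
        for j in range(cfg.patches_per_subject):
            # alternate foreground- and error-centered patches: disagreement
            # voxels are rare, and the gate is only as sharp as the error
            # statistics the network gets to see
            pool = err if (j % 2 == 1 and len(err)) else fg
            center = pool[rng.integers(len(pool))]
            corner = np.clip(center - size // 2, 0, shape - size)
            sl = tuple(slice(int(c), int(c) + size) for c in corner)
            xs.append(np.moveaxis(inp[(slice(None),) + sl], 0, -1))
            ys.append(target[sl][..., None])
    x = np.ascontiguousarray(np.stack(xs))
    y = np.ascontiguousarray(np.stack(ys))

    opt = nn.SGD(model.net.parameters(), lr=cfg.learning_rate, momentum=cfg.momentum)
    rng = np.random.default_rng(cfg.seed + 2)
    model.net.train()
    for _ in range(cfg.n_epochs):
        losses = []
        order = rng.permutation(len(x))
        for i in range(0, len(x), cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            pred = model.net(nn.Tensor(x[idx]))
            loss = F.confidence_cross_entropy(pred, y[idx], a=params.a)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        model.loss_trace.append(float(np.mean(losses)))
        opt.lr *= cfg.lr_decay
    model.net.eval()
    return model


def predict_confidence(
    conf_model: ConfModel,
    auto_seg: LabelVolume,
    probs: ProbabilityMaps,
    overlap: float = 0.5,
    batch_size: int = 8,
) -> ConfidenceMap:
    """Whole-volume confidence map M_cp in [0, 1] by sliding-window fusion."""
    if auto_seg.shape != probs.shape:
        raise ValueError(f"shape mismatch: seg {auto_seg.shape} vs probs {probs.shape}")
    size = conf_model.patch_size
    inp = _conf_input_volume(auto_seg, probs)
    corners = sliding_window_corners(auto_seg.shape, size, overlap)
    acc = np.zeros(auto_seg.shape, dtype=np.float64)
    cnt = np.zeros(auto_seg.shape, dtype=np.int32)
    for i in range(0, len(corners), batch_size):
        chunk = corners[i : i + batch_size]
        batch = np.stack(
            [inp[:, z : z + size, y : y + size, x : x + size] for z, y, x in chunk]
        )
        out = conf_model.predict_patch(batch)
        for blk, (z, y, x) in zip(out, chunk):
            acc[z : z + size, y : y + size, x : x + size] += blk
            cnt[z : z + size, y : y + size, x : x + size] += 1
    values = np.clip(acc / np.maximum(cnt, 1), 0.0, 1.0).astype(np.float32)
    return ConfidenceMap(values, spacing=auto_seg.spacing)


@dataclass
class HistogramDiagnostic:
    """Probability histograms at correctly vs. misclassified voxels of a class."""

    bin_edges: np.ndarray
    freq_correct: np.ndarray
    freq_mis: np.ndarray
    n_correct: int
    n_mis: int

    @property
    def empty_correct(self) -> bool:
        return self.n_correct == 0

    @property
    def empty_mis(self) -> bool:
        return self.n_mis == 0

    def to_csv(self, path: str | Path) -> Path:
        import pandas as pd

        df = pd.DataFrame(
            {
                "bin_edge": self.bin_edges[:-1],
                "freq_correct": self.freq_correct,
                "freq_mis": self.freq_mis,
            }
        )
        df.to_csv(path, index=False)
        return Path(path)


def probability_histograms(
    probs: ProbabilityMaps,
    auto_seg: LabelVolume,
    truth: LabelVolume,
    class_code: int,
    n_bins: int = 20,
) -> HistogramDiagnostic:
    """Histograms of a class's probability at correct vs. misclassified voxels.

    Considers the voxels whose manual label is ``class_code`` and histograms
    the predicted probability of that class separately for voxels the
    automated segmentation got right and wrong. Misclassified voxels
    characteristically pile up near probability 0.5. Each histogram is
    normalized to sum to 1 when non-empty; a class with no voxels yields the
    empty flags instead of an error.
    """
    if not (auto_seg.shape == truth.shape == probs.shape):
        raise ValueError("probability maps, segmentation, and truth must be aligned")
    in_class = truth.voxels == class_code
    p = probs.maps[class_code]
    correct_vals = p[in_class & (auto_seg.voxels == truth.voxels)]
    mis_vals = p[in_class & (auto_seg.voxels != truth.voxels)]
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    hc, _ = np.histogram(correct_vals, bins=edges)
    hm, _ = np.histogram(mis_vals, bins=edges)
    return HistogramDiagnostic(
        bin_edges=edges,
        freq_correct=hc / hc.sum() if hc.sum() else hc.astype(float),
        freq_mis=hm / hm.sum() if hm.sum() else hm.astype(float),
        n_correct=int(correct_vals.size),
        n_mis=int(mis_vals.size),
    )
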