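"""Self-supervised target-domain adaptation with confidence-gated pseudo-labels.

A segmentation model trained on a labeled source domain degrades on target
domains whose tissue contrast differs (younger ages, other sites). To adapt
without target labels, the source model segments the target volumes and the
confidence model scores each voxel's reliability; voxels whose confidence
clears 0.5 keep their confidence as a training weight, the rest are zeroed.
A new domain-specific model is then trained on the target volumes against
these pseudo-labels with a spatially-weighted cross-entropy, so only
reliable voxels steer the update. Chaining this step through intermediate
domains — each newly adapted model becoming the effective source for the
next, more distant domain — is the gradual label propagation strategy, used
because a single jump across a large distribution gap yields too few
reliable pseudo-labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .confidence import ConfModel, predict_confidence
from .seg_model import (
    SegModel,
    SegModelConfig,
    TrainConfig,
    normalize_intensity,
    predict_segmentation,
    train_on_patches,
    train_source_model,
)
from .types import (
    CSF,
    GM,
    WM,
    ConfidenceMap,
    IntensityVolume,
    LabelVolume,
    ProbabilityMaps,
    TISSUE_NAMES,
    one_hot,
)
def weight_map(conf: ConfidenceMap | np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Confidence-gated spatial weights.

    ``w(x) = M_cp(x)`` where the confidence clears the threshold (inclusive
    at exactly 0.5), 0 elsewhere — so weights live in {0} together with
    [threshold, 1]. Idempotent on its own output.
    """
    m = conf.values if isinstance(conf, ConfidenceMap) else np.asarray(conf, dtype=np.float32)
    return np.where(m >= threshold, m, np.float32(0.0))


@dataclass
class WeightedLoss:
    """Value of the spatially-weighted cross-entropy plus its masking flag."""

    value: float
    all_masked: bool

    def __float__(self) -> float:
        return self.value


def weighted_segmentation_loss(
    probs: ProbabilityMaps | np.ndarray,
    target_onehot: np.ndarray,
    weights: np.ndarray,
    eps: float = 1e-7,
) -> WeightedLoss:
    """Spatially-weighted cross-entropy over the positively weighted voxels.

    ``mean over {x : w(x) > 0} of -w(x) * sum_i Y_i(x) ln X_i(x)`` with the
    probabilities clamped to [eps, 1]. Normalizing by the retained-voxel
    count (not the total) keeps the effective step size stable as the
    confidence gate tightens. With ``w == 1`` everywhere this reduces
    exactly to the unweighted segmentation loss; an all-zero weight map
    contributes 0 and sets the ``all_masked`` flag.
    """
    p = probs.maps if isinstance(probs, ProbabilityMaps) else np.asarray(probs)
    p = p.astype(np.float64)
    y = np.asarray(target_onehot, dtype=np.float64)
    w = np.asarray(weights, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: probs {p.shape} vs target {y.shape}")
    if w.shape != p.shape[1:]:
        raise ValueError(f"weights shape {w.shape} does not match voxel grid {p.shape[1:]}")
    n_pos = int((w > 0).sum())
    if n_pos == 0:
        return WeightedLoss(0.0, True)
    pc = np.clip(p, eps, 1.0)
    per_vox = -(y * np.log(pc)).sum(axis=0)
    return WeightedLoss(float((w * per_vox).sum() / n_pos), False)


@dataclass
class PseudoLabeledVolume:
    """A target volume with model-generated labels and confidence weights."""

    intensity: IntensityVolume
    labels: LabelVolume
    weights: np.ndarray
    probs: ProbabilityMaps
    confidence: ConfidenceMap
    retained_fraction: dict[str, float] = field(default_factory=dict)


def make_pseudo_labels(
    seg_model: SegModel,
    conf_model: ConfModel,
    volumes: list[IntensityVolume],
) -> list[PseudoLabeledVolume]:
    """Generate confidence-gated pseudo-labels for unlabeled target volumes.

    The pseudo-label is the segmentation model's arg-max prediction; weights
    come from gating the predicted confidence map at 0.5. Reliable voxels
    may sit anywhere, including tissue boundaries. ``retained_fraction``
    reports, per tissue and overall, the fraction of voxels that keep a
    positive weight.
    """
    out = []
    for vol in volumes:
        seg, probs = predict_segmentation(seg_model, vol)
        conf = predict_confidence(conf_model, seg, probs)
        w = weight_map(conf)
        retained = {"all": float((w > 0).mean())}
        for code in (CSF, GM, WM):
            sel = seg.voxels == code
            retained[TISSUE_NAMES[code]] = (
                float((w[sel] > 0).mean()) if sel.any() else float("nan")
            )
        out.append(
            PseudoLabeledVolume(
                intensity=vol, labels=seg, weights=w, probs=probs,
                confidence=conf, retained_fraction=retained,
            )
        )
    return out


TrainingItem = tuple[IntensityVolume, LabelVolume, np.ndarray]
"""A (volume, labels, per-voxel weights) triple usable as training supervision."""


def _balanced_patches(
    items: list[TrainingItem],
    cfg: TrainConfig,
    seed: int,
    pps_per_volume: int,
) -> tuple[list[np.ndarray], list[np.ndarray], list[np.ndarray]]:
    """Class-balanced patch sampling for self-training.

    Patch centers cycle over CSF-, GM-, WM-, and any-foreground-labeled
    voxels so the rare WM class keeps a stable share of the gradient signal;
    with uniform foreground sampling the thin tree's noisy pseudo-labels
    erode it.
    """
    xs, ys, ws = [], [], []
    size = cfg.patch_size
    for i, (vol, lab, w) in enumerate(items):
        rng = np.random.default_rng(seed + i)
        norm = normalize_intensity(vol)
        shape = np.array(lab.shape)
        pools = [np.argwhere(lab.voxels == c) for c in (CSF, GM, WM)]
        pools.append(np.argwhere(lab.voxels > 0))
        for j in range(pps_per_volume):
            pool = pools[j % 4]
            if not len(pool):
                pool = pools[3]
            if not len(pool):
                raise ValueError("training volume has no foreground voxels")
            center = pool[rng.integers(len(pool))]
            corner = np.clip(center - size // 2, 0, shape - size)
            sl = tuple(slice(int(c), int(c) + size) for c in corner)
            xs.append(np.moveaxis(norm.voxels[(slice(None),) + sl], 0, -1))
            ys.append(np.moveaxis(one_hot(lab.voxels[sl]), 0, -1))
            ws.append(w[sl])
    return xs, ys, ws


def adapt_to_domain(
    source_model: SegModel,
    conf_model: ConfModel,
    target_volumes: list[IntensityVolume],
    cfg: TrainConfig | None = None,
    warm_start: bool = True,
    pseudo: list[PseudoLabeledVolume] | None = None,
    replay_items: list[TrainingItem] | None = None,
) -> SegModel:
    """Train a new domain-specific model on confidence-gated pseudo-labels.

    The source model generates pseudo-labels and weights for the target
    volumes (unless precomputed ones are passed); a new model — warm-started
    from the source weights by default, freshly initialized otherwise — is
    then trained with the spatially-weighted cross-entropy on class-balanced
    target patches, optionally mixed with replayed patches from previously
    labeled volumes (``replay_items``, e.g. the source subjects with manual
    labels at weight 1). The source model itself is never modified.
    """
    if not target_volumes:
        raise ValueError("at least one unlabeled target volume is required")
    cfg = cfg or TrainConfig()
    if pseudo is None:
        pseudo = make_pseudo_labels(source_model, conf_model, target_volumes)
    items: list[TrainingItem] = [(pv.intensity, pv.labels, pv.weights) for pv in pseudo]

    xs, ys, ws = _balanced_patches(items, cfg, cfg.seed * 20011, cfg.patches_per_subject)
    if replay_items:
        per_vol = max(12, cfg.patches_per_subject // (2 * len(replay_items)))
        x2, y2, w2 = _balanced_patches(replay_items, cfg, cfg.seed * 20011 + 977, per_vol)
        xs += x2
        ys += y2
        ws += w2
    x = np.ascontiguousarray(np.stack(xs))
    y = np.ascontiguousarray(np.stack(ys))
    w = np.ascontiguousarray(np.stack(ws))

    if warm_start:
        model = source_model.copy()
        model.loss_trace = []
    else:
        from .seg_model import build_seg_model

        model = build_seg_model(source_model.config, seed=cfg.seed)
        model.patch_size = cfg.patch_size
    return train_on_patches(model, x, y, cfg, weights=w)


@dataclass
class PropagationPlan:
    """Ordered domain chain from the labeled source to the farthest target."""

    domain_ids: list[str]

    def __post_init__(self) -> None:
        if not self.domain_ids:
            raise ValueError("plan must contain at least the source domain")
        if len(set(self.domain_ids)) != len(self.domain_ids):
            raise ValueError("plan domains must not repeat")

    @property
    def source(self) -> str:
        return self.domain_ids[0]

    @property
    def targets(self) -> list[str]:
        return self.domain_ids[1:]


def gradual_propagation(
    source_subjects: list[tuple[IntensityVolume, LabelVolume]],
    plan: PropagationPlan,
    domain_volumes: dict[str, list[IntensityVolume]],
    cfg: TrainConfig | None = None,
    mcfg: SegModelConfig | None = None,
    conf_model: ConfModel | None = None,
    source_model: SegModel | None = None,
) -> tuple[dict[str, SegModel], list[dict]]:
    """Chain confidence-gated adaptation along an ordered domain sequence.

    Step k adapts from the step k-1 model, with that model's own
    (confidence-gated) segmentations of domain k's volumes as supervision.
    Every already-traversed domain is re-designated as source for the later
    steps: the labeled source subjects plus each domain's self-segmented
    volumes accumulate into a replay bank that each adaptation step samples
    alongside its new-domain patches, which anchors the rare classes against
    pseudo-label drift. Returns one model per domain (the source model for
    the first entry) and a per-step metrics log. A plan of length 1 returns
    only the source model.

    ``source_model`` may be supplied pre-trained; otherwise it is trained
    here from ``source_subjects``. ``conf_model`` is trained once on the
    source domain and reused for every step; it is required whenever the
    plan has targets.
    """
    cfg = cfg or TrainConfig()
    missing = [d for d in plan.targets if not domain_volumes.get(d)]
    if missing:
        raise ValueError(f"missing unlabeled volumes for domains: {missing}")
    if source_model is None:
        if not source_subjects:
            raise ValueError("labeled source subjects are required")
        source_model = train_source_model(source_subjects, cfg, mcfg)
    if plan.targets and conf_model is None:
        raise ValueError("a trained confidence model is required for adaptation steps")

    models: dict[str, SegModel] = {plan.source: source_model}
    log: list[dict] = []
    current = source_model
    bank: list[list[TrainingItem]] = [
        [(v, l, np.ones(l.shape, dtype=np.float32)) for v, l in source_subjects]
    ] if source_subjects else []
    for step, domain in enumerate(plan.targets, start=1):
        vols = domain_volumes[domain]
        pseudo = make_pseudo_labels(current, conf_model, vols)
        step_cfg = TrainConfig(**{**cfg.to_dict(), "seed": cfg.seed + 307 * step})
        # flatten the bank into a replay set whose total budget matches one
        # domain's patch share, split evenly across accumulated domains
        replay: list[TrainingItem] = [it for group in bank for it in group]
        adapted = adapt_to_domain(
            current, conf_model, vols, step_cfg, pseudo=pseudo, replay_items=replay or None
        )
        models[domain] = adapted
        bank.append([(pv.intensity, pv.labels, pv.weights) for pv in pseudo])
        log.append(
            {
                "step": step,
                "domain": domain,
                "n_volumes": len(vols),
                "retained_fraction": float(
                    np.mean([pv.retained_fraction["all"] for pv in pseudo])
                ),
                "mean_confidence": float(
                    np.mean([pv.confidence.values.mean() for pv in pseudo])
                ),
                "final_loss": adapted.loss_trace[-1] if adapted.loss_trace else None,
            }
        )
        current = adapted
    return models, log
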