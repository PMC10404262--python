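"""End-to-end reproducible driver: simulate -> train -> adapt -> evaluate.

A single declarative config fully determines a run: phantom geometry, the
domain series, data sizes, training recipe, confidence parameters, and the
propagation plan. All randomness is funneled through one root seed, from
which per-stage seeds are derived, so a rerun with the same config
reproduces the same artifacts.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .confidence import (
    ConfLossParams,
    ConfModelConfig,
    kfold_self_test,
    train_confidence_model,
)
from .metrics import evaluate
from .phantom import (
    DomainSpec,
    default_base_spec,
    make_domain_series,
    make_label_phantom,
    render_intensities,
)
from .seg_model import SegModelConfig, TrainConfig, predict_segmentation, train_source_model
from .ssl_adapt import PropagationPlan, gradual_propagation
from .volume_io import write_volume


class PipelineConfigError(ValueError):
    """The run configuration is invalid; nothing has been computed."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Declarative description of one full pipeline run."""

    out_dir: str = "arborseg_run"
    seed: int = 0
    shape: tuple[int, int, int] = (48, 48, 48)
    branch_depth: int = 3
    gm_thickness: int = 2
    n_domains: int = 6
    contrast_decay: float = 0.3
    noise_growth: float = 0.1
    n_source_subjects: int = 2
    n_target_per_domain: int = 2
    n_heldout: int = 1
    source_patches_per_subject: int = 192
    kfold: int = 2
    plan: list[str] | None = None
    train: TrainConfig = field(default_factory=lambda: TrainConfig(
        patches_per_subject=96, patch_size=16, n_epochs=2, batch_size=4))
    model: SegModelConfig = field(default_factory=lambda: SegModelConfig(size_scale=0.25))
    conf_params: ConfLossParams = field(default_factory=ConfLossParams)
    conf_model: ConfModelConfig = field(default_factory=ConfModelConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "shape" in kwargs:
            kwargs["shape"] = tuple(kwargs["shape"])
        for key, ctor in (
            ("train", TrainConfig),
            ("model", SegModelConfig),
            ("conf_params", ConfLossParams),
            ("conf_model", ConfModelConfig),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = ctor(**kwargs[key])
        try:
            return cls(**kwargs)
        except TypeError as exc:
            raise PipelineConfigError(str(exc)) from exc

    def to_dict(self) -> dict:
        d = asdict(self)
        d["shape"] = list(self.shape)
        return d

    def validate(self) -> None:
        if min(self.shape) < 32:
            raise PipelineConfigError("shape must be >= 32 per axis")
        if self.n_source_subjects < self.kfold:
            raise PipelineConfigError(
                f"need at least kfold={self.kfold} source subjects for self-testing"
            )
        if self.n_domains < 1:
            raise PipelineConfigError("n_domains must be >= 1")
        if self.plan is not None:
            series_ids = [s.domain_id for s in self._series()]
            if not self.plan:
                raise PipelineConfigError("plan must not be empty")
            if self.plan[0] != series_ids[0]:
                raise PipelineConfigError(
                    f"plan must start at the labeled source domain {series_ids[0]!r}"
                )
            unknown = [d for d in self.plan if d not in series_ids]
            if unknown:
                raise PipelineConfigError(f"plan references unknown domains: {unknown}")

    def _series(self) -> list[DomainSpec]:
        base = default_base_spec()
        if self.n_domains == 1:
            return [base]
        return make_domain_series(base, self.n_domains, self.contrast_decay, self.noise_growth)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the artifacts directory.

    Stages: simulate -> train-source -> kfold-self-test -> train-confidence
    -> adapt (per plan) -> evaluate. Any stage failure aborts with the stage
    name and cause; results (CSV report, JSON log, checkpoints, NIfTI
    outputs) land under ``config.out_dir``.
    """
    config.validate()
    out = Path(config.out_dir)
    (out / "models").mkdir(parents=True, exist_ok=True)
    (out / "data").mkdir(exist_ok=True)
    log: dict = {"config": config.to_dict(), "stages": {}}
    t_start = time.time()

    def stage(name):
        def deco(fn):
            t0 = time.time()
            try:
                result = fn()
            except Exception as exc:  # noqa: BLE001 - report stage context
                raise StageError(name, exc) from exc
            log["stages"].setdefault(name, {})["seconds"] = round(time.time() - t0, 2)
            return result

        return deco

    rng = np.random.default_rng(config.seed)
    series = config._series()
    plan_ids = config.plan or [s.domain_id for s in series]
    spec_by_id = {s.domain_id: s for s in series}

    @stage("simulate")
    def data():
        out_data = {"source": [], "targets": {}, "heldout": {}}
        sub_seed = int(rng.integers(2**31 - 1))
        counter = 0
        for i in range(config.n_source_subjects):
            lab = make_label_phantom(
                config.shape, config.branch_depth, config.gm_thickness,
                seed=sub_seed + counter,
            )
            vol = render_intensities(lab, series[0], seed=sub_seed + 50000 + counter)
            out_data["source"].append((vol, lab))
            counter += 1
        for dom in plan_ids:
            spec = spec_by_id[dom]
            out_data["targets"][dom] = []
            for _ in range(config.n_target_per_domain):
                lab = make_label_phantom(
                    config.shape, config.branch_depth, config.gm_thickness,
                    seed=sub_seed + counter,
                )
                out_data["targets"][dom].append(
                    render_intensities(lab, spec, seed=sub_seed + 50000 + counter)
                )
                counter += 1
            out_data["heldout"][dom] = []
            for _ in range(config.n_heldout):
                lab = make_label_phantom(
                    config.shape, config.branch_depth, config.gm_thickness,
                    seed=sub_seed + counter,
                )
                vol = render_intensities(lab, spec, seed=sub_seed + 50000 + counter)
                out_data["heldout"][dom].append((vol, lab))
                counter += 1
        for j, (vol, lab) in enumerate(out_data["source"]):
            write_volume(vol, out / "data" / f"source_{j}_image.nii.gz")
            write_volume(lab, out / "data" / f"source_{j}_labels.nii.gz")
        (out / "data" / "domains.json").write_text(
            json.dumps({s.domain_id: s.to_dict() for s in series}, indent=2)
        )
        return out_data

    train_cfg = TrainConfig(**{**config.train.to_dict(), "seed": config.seed})

    @stage("train-source")
    def source_model():
        src_cfg = TrainConfig(**{
            **train_cfg.to_dict(),
            "patches_per_subject": config.source_patches_per_subject,
        })
        m = train_source_model(data["source"], src_cfg, config.model)
        m.save(out / "models" / "source.npz")
        return m

    @stage("kfold-self-test")
    def pairs():
        preds = kfold_self_test(data["source"], K=config.kfold, cfg=train_cfg, mcfg=config.model)
        return [
            (seg, probs, lab)
            for (seg, probs), (_, lab) in zip(preds, data["source"])
        ]

    @stage("train-confidence")
    def conf_model():
        m = train_confidence_model(pairs, train_cfg, config.conf_params, config.conf_model)
        m.save(out / "models" / "confidence.npz")
        return m

    @stage("adapt")
    def adapted():
        plan = PropagationPlan(plan_ids)
        models, step_log = gradual_propagation(
            data["source"], plan, data["targets"], train_cfg, config.model,
            conf_model=conf_model, source_model=source_model,
        )
        log["stages"]["adapt"] = {"steps": step_log}
        for dom, m in models.items():
            m.save(out / "models" / f"seg_{dom}.npz")
        return models

    @stage("evaluate")
    def report():
        rows = []
        for dom in plan_ids:
            model = adapted[dom]
            for j, (vol, lab) in enumerate(data["heldout"][dom]):
                seg, _ = predict_segmentation(model, vol)
                write_volume(seg, out / "data" / f"seg_{dom}_{j}.nii.gz")
                rows.extend(
                    evaluate(seg, lab).to_rows(domain=dom, subject=j)
                )
        df = pd.DataFrame(rows)
        df.to_csv(out / "report.csv", index=False)
        return df

    log["total_seconds"] = round(time.time() - t_start, 2)
    log["seed"] = config.seed
    (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    return out
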