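"""Shared fixtures.

The expensive session fixtures (`confidence_runs`, `chain_runs`) execute the
full study protocol — source training, K-fold self-testing, confidence
training, gradual propagation — once per seed and are shared between the
sanity tests and the acceptance suite, so the protocol runs exactly once
per seed for the whole session.
"""

from __future__ import annotations

import numpy as np
import pytest

from arborseg import (
    ConfLossParams,
    PropagationPlan,
    SegModelConfig,
    TrainConfig,
    adapt_to_domain,
    gradual_propagation,
    inject_topology_defects,
    kfold_self_test,
    make_domain_series,
    make_label_phantom,
    predict_confidence,
    predict_segmentation,
    render_intensities,
    train_confidence_model,
    train_source_model,
)
from arborseg.phantom import default_base_spec

# desk-scale study conditions (see docs/methods.md)
SHAPE = (48, 48, 48)
SIZE_SCALE = 0.25
PATCH = 16
SEEDS = (1, 2, 3)


def make_subject(seed: int, spec, shape=SHAPE):
    lab = make_label_phantom(shape, branch_depth=3, gm_thickness=2, seed=seed)
    return render_intensities(lab, spec, seed=seed + 1000), lab


def desk_train_config(seed: int, pps: int = 96) -> TrainConfig:
    return TrainConfig(
        patches_per_subject=pps, patch_size=PATCH, n_epochs=2, batch_size=4, seed=seed
    )


@pytest.fixture(scope="session")
def domain_series():
    return make_domain_series(default_base_spec(), 6, 0.3, 0.1)


@pytest.fixture(scope="session")
def confidence_runs(domain_series):
    """Per-seed source model + confidence model + defect-phantom evaluation."""
    series = domain_series
    runs = {}
    for seed in SEEDS:
        base = seed * 10000
        mcfg = SegModelConfig(size_scale=SIZE_SCALE)
        src_subs = [make_subject(base + i, series[0]) for i in (1, 2, 3, 4)]
        src = train_source_model(src_subs, desk_train_config(seed, pps=128), mcfg)
        preds = kfold_self_test(src_subs, K=2, cfg=desk_train_config(seed, pps=64), mcfg=mcfg)
        triples = [(s, p, l) for (s, p), (_, l) in zip(preds, src_subs)]
        conf = train_confidence_model(
            triples, desk_train_config(seed, pps=96), ConfLossParams()
        )
        # defect phantom: topology errors baked into the rendered image
        lab = make_label_phantom(SHAPE, branch_depth=3, gm_thickness=2, seed=base + 9)
        defects = inject_topology_defects(lab, 4, ("hole", "handle"), seed=base + 3)
        vol = render_intensities(defects.labels, series[0], seed=base + 99)
        seg_d, probs_d = predict_segmentation(src, vol)
        conf_d = predict_confidence(conf, seg_d, probs_d)
        # held-out source-domain subject for the probability-histogram check
        ho_vol, ho_lab = make_subject(base + 200, series[0])
        seg0, probs0 = predict_segmentation(src, ho_vol)
        runs[seed] = dict(
            src_subs=src_subs, src=src, conf=conf,
            defect_mask=defects.mask, conf_defect=conf_d,
            heldout=(ho_vol, ho_lab), heldout_pred=(seg0, probs0),
        )
    return runs


@pytest.fixture(scope="session")
def chain_runs(domain_series, confidence_runs):
    """Per-seed gradual propagation chain plus a one-shot comparator."""
    series = domain_series
    ids = [s.domain_id for s in series]
    runs = {}
    for seed in SEEDS:
        base = seed * 10000
        bundle = confidence_runs[seed]
        cfg = desk_train_config(seed)
        mcfg = SegModelConfig(size_scale=SIZE_SCALE)
        # target-domain "testing subjects": used unlabeled for self-training,
        # and (with their never-seen labels) for transductive evaluation
        target_pairs = {
            s.domain_id: [
                make_subject(base + 100 + k, s),
                make_subject(base + 300 + k, s),
            ]
            for k, s in enumerate(series[1:], 1)
        }
        targets = {d: [v for v, _ in pairs] for d, pairs in target_pairs.items()}
        models, log = gradual_propagation(
            bundle["src_subs"], PropagationPlan(ids), targets, cfg, mcfg,
            conf_model=bundle["conf"], source_model=bundle["src"],
        )
        one = adapt_to_domain(
            bundle["src"], bundle["conf"], targets[ids[-1]],
            TrainConfig(**{**cfg.to_dict(), "seed": seed + 999}),
            replay_items=[
                (v, l, np.ones(l.shape, dtype=np.float32))
                for v, l in bundle["src_subs"]
            ],
        )
        # evaluation set per domain: the testing subjects plus one held-out;
        # mean GM/WM Dice per (model, domain) is computed once here and the
        # tests assert on the numbers
        from arborseg.metrics import dice as _dice
        from arborseg.seg_model import predict_segmentation as _predict
        from arborseg.types import GM as _GM, WM as _WM

        evals = {
            dom: target_pairs[dom]
            + [make_subject(base + 400 + ids.index(dom), series[ids.index(dom)])]
            for dom in (ids[1], ids[-1])
        }

        def mean_dice(model, dom):
            gms, wms = [], []
            for vol, lab_ref in evals[dom]:
                seg, _ = _predict(model, vol)
                gms.append(_dice(seg, lab_ref, _GM))
                wms.append(_dice(seg, lab_ref, _WM))
            return float(np.mean(gms)), float(np.mean(wms))

        scores = {}
        for dom in (ids[1], ids[-1]):
            scores[("direct", dom)] = mean_dice(bundle["src"], dom)
            scores[("adapted", dom)] = mean_dice(models[dom], dom)
        scores[("oneshot", ids[-1])] = mean_dice(one, ids[-1])

        # only the summary numbers are kept; dropping the models and volumes
        # lets them be garbage-collected between seeds
        runs[seed] = dict(ids=ids, log=log, scores=scores)
    return runs
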