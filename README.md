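# arborseg

Self-supervised multi-domain tissue segmentation for the infant cerebellum,
with a synthetic phantom generator that makes the whole framework trainable
and verifiable on a single CPU.

## The problem

Segmenting infant cerebellar MRI into CSF, gray matter (GM), and white
matter (WM) is hard for three compounding reasons: the arbor vitae (the
cerebellar WM core) is a thin, folded tree; GM is a narrow layer squeezed
between CSF and WM; and tissue contrast is low and *dynamic* — the GM/WM
intensity difference collapses toward the isointense phase and inverts in
the first months of life, so a model trained on well-contrasted 24-month
scans fails on younger ones (the domain-shift problem). Manual labels are
realistically available only for the oldest, best-contrasted domain.

## The method

Two steps, given labeled subjects in a source domain and unlabeled subjects
in a chain of target domains:

1. **Supervised learning (source).** A dense-block encoder–decoder
   segmentation network is trained on two-channel (T1w-like + T2w-like)
   32³-voxel patches with the cross-entropy loss
   `L_seg = -Σ_{i=1..C} Y_i ln X_i` (C = 4 classes). The labeled subjects
   are then split into K = 2 folds and cross-predicted, and a small U-Net
   **confidence model** is trained on these out-of-fold segmentations
   (one-hot) plus their probability maps, with the binary agreement map
   (1 where automated = manual) as target and the class-balanced loss
   `L_cp = -(Y_c ln X_c + a (1 - Y_c) ln(1 - X_c))`, a = 0.1.

2. **Self-supervised adaptation (targets).** The current model segments the
   next domain's unlabeled volumes; the confidence model scores each voxel,
   and spatially-varying weights
   `w(x) = M_cp(x) if M_cp(x) >= 0.5 else 0`
   gate a spatially-weighted cross-entropy
   `L_seg_weights = -w Σ_i Y_i ln X_i` over the pseudo-labels. A new
   domain-specific model is trained this way, then becomes the source for
   the next, more distant domain — gradual label propagation along
   24m → 18m → 12m → 9m → 6m → 0–3m.

Evaluation uses the Dice ratio and the 95th-percentile Hausdorff surface
distance (HD95, mm).

Because the real BCP/NDAR infant MRI is controlled-access, the package
ships a seeded phantom generator: a recursively branched WM tree wrapped in
a thin GM shell and CSF, rendered per domain from tissue intensity
distributions whose GM/WM gap decays geometrically and inverts at the
youngest domain, plus partial-volume blur, noise, and injectable "hole" and
"handle" topology defects. The neural-network layer is a small built-in
reverse-mode autodiff engine over numpy (3D convolutions as BLAS matmuls),
so there is no GPU or deep-learning-framework dependency.

## Worked example

```python
from arborseg import (
    PropagationPlan, SegModelConfig, TrainConfig, dice,
    kfold_self_test, make_domain_series, make_label_phantom,
    predict_segmentation, render_intensities, train_confidence_model,
    train_source_model, gradual_propagation,
)
from arborseg.phantom import default_base_spec

series = make_domain_series(default_base_spec(), n_domains=6,
                            contrast_decay=0.3, noise_growth=0.1)
def subject(seed, spec):
    lab = make_label_phantom((48, 48, 48), branch_depth=3, gm_thickness=2, seed=seed)
    return render_intensities(lab, spec, seed=seed + 1000), lab

cfg  = TrainConfig(patches_per_subject=96, patch_size=16, n_epochs=2, batch_size=4, seed=0)
mcfg = SegModelConfig(size_scale=0.25)

src_subs = [subject(i, series[0]) for i in (1, 2, 3, 4)]
src = train_source_model(src_subs, TrainConfig(**{**cfg.to_dict(), "patches_per_subject": 128}), mcfg)
preds = kfold_self_test(src_subs, K=2, cfg=TrainConfig(**{**cfg.to_dict(), "patches_per_subject": 64}), mcfg=mcfg)
conf = train_confidence_model([(s, p, l) for (s, p), (_, l) in zip(preds, src_subs)], cfg)

targets = {s.domain_id: [subject(100 + k, s)[0], subject(300 + k, s)[0]]
           for k, s in enumerate(series[1:], 1)}
models, log = gradual_propagation(src_subs, PropagationPlan([s.domain_id for s in series]),
                                  targets, cfg, mcfg, conf_model=conf, source_model=src)

vol, lab = subject(500, series[-1])           # held-out youngest-domain phantom
seg_direct, _  = predict_segmentation(src, vol)
seg_adapted, _ = predict_segmentation(models["0-3m"], vol)
print("direct  GM/WM Dice: %.3f %.3f" % (dice(seg_direct, lab, 2),  dice(seg_direct, lab, 3)))
print("adapted GM/WM Dice: %.3f %.3f" % (dice(seg_adapted, lab, 2), dice(seg_adapted, lab, 3)))
```

This run (about five minutes on one CPU) prints:

```
direct  GM/WM Dice: 0.817 0.816
adapted GM/WM Dice: 0.848 0.848
```

i.e. on the most contrast-degraded ("0–3m analog") domain, where the GM/WM
intensity ordering has inverted relative to the source domain, the
confidence-gated self-training chain recovers about three Dice points over
applying the source model directly — and the same comparison at the first
adapted domain ("18m") shows essentially no gap, mirroring the widening
advantage of self-supervised adaptation at younger ages.

A command-line driver exposes the same stages
(`arborseg simulate|train-source|train-confidence|segment|adapt|evaluate|run-all`);
`arborseg run-all --config config.yaml` runs the whole pipeline from one
declarative file.

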