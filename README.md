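# neurodg

Disease-informed domain generalization for 3D neuroimaging classifiers.

Deep models that classify brain MRI into normal cognition (NC), mild
cognitive impairment (MCI) and Alzheimer's-disease dementia (AD) often
latch onto cohort-specific signal — scanner, protocol, demographics — and
degrade on unseen cohorts. `neurodg` implements a two-stage,
interpretability-driven remedy: first train a baseline classifier, explain
it, then train a fresh model whose spatial attention is explicitly aligned
with the explanation.

**Who it is for:** researchers studying attention supervision and
saliency-prior alignment for volumetric classifiers, who need a complete,
deterministic, CPU-scale implementation with planted-signal synthetic
cohorts for validation.

## The method

1. **Stage 1 — baseline.** A 3D conv encoder, a class-wise attention module
   (K sigmoid gates `M_k`, multiplied elementwise into K per-class feature
   channels) and a global-average-pooling softmax classifier are trained
   with weighted cross-entropy, `w_k ∝ 1/count_k` countering class
   imbalance.
2. **Saliency priors.** The baseline is explained per class with
   Shapley-style *expected gradients* attributions; averaging the
   attribution volumes over the baseline's correct predictions of class k
   gives the class prior `SHAP_k`. An exact subset-enumeration Shapley
   oracle (≤ 16 groups) validates the estimator.
3. **Stage 2 — alignment.** A fresh model minimizes

       L = L_WCE + λ · Σ_i Σ_k ‖M_{i,k} − SHAP_k‖₂ / N,

   pulling each class's attention toward its disease-relevant prior
   (default λ = 5×10⁻⁵).
4. **Evaluation.** Accuracy, macro F1 and multiclass MCC (the
   confusion-matrix formula `(c·s − Σp_k t_k)/√((s²−Σp_k²)(s²−Σt_k²))`)
   over stratified 5-fold 3:1:1 splits.
5. **Pathology validation.** AD-channel attention is aggregated per
   parcellation region (sum / regional volume) and rank-correlated
   (Spearman, unadjusted p) with per-region ordinal autopsy grades of
   amyloid-β, neurofibrillary tangles and neuritic plaques.

Everything — model, autodiff, attribution, metrics — runs on numpy/scipy;
synthetic cohorts with planted, severity-graded "atrophy" make every stage
testable without MRI data. See `docs/methods.md` for the full model
description and design rationale.

## Worked example

```python
import numpy as np
from neurodg import (AttributionConfig, CohortSpec, build_class_priors,
                     generate_cohort, make_parcellation)
from neurodg.presets import alignment_benefit_conditions
from neurodg.train import posthoc_sim_loss, train_stage1, train_stage2
from neurodg.metrics import stratified_kfold

sc = alignment_benefit_conditions(seed=0)          # fixed study conditions
parc = make_parcellation(sc.cohort.shape, sc.cohort.n_regions, seed=0)
samples, disease_map = generate_cohort(sc.cohort, parc)
X = np.stack([s.volume for s in samples])
y = np.array([s.label for s in samples])
train_idx, val_idx, test_idx = stratified_kfold(y, k=5, seed=0).folds[0]

import dataclasses
est1, _ = train_stage1(X[train_idx], y[train_idx], sc.model,
                       dataclasses.replace(sc.train, lam=0.0),
                       X_val=X[val_idx], y_val=y[val_idx])
priors = build_class_priors(est1.net_, [samples[i] for i in train_idx],
                            AttributionConfig(n_background=6, n_draws=6, seed=0))
est2, _ = train_stage2(X[train_idx], y[train_idx], priors, sc.model, sc.train,
                       X_val=X[val_idx], y_val=y[val_idx])

print("stage-1 test acc:", (est1.predict(X[test_idx]) == y[test_idx]).mean())
print("stage-2 test acc:", (est2.predict(X[test_idx]) == y[test_idx]).mean())
print("val sim loss:", posthoc_sim_loss(est1.net_, X[val_idx], priors, prior_scale="unit"),
      "->", posthoc_sim_loss(est2.net_, X[val_idx], priors, prior_scale="unit"))
```

prints (a few minutes on one CPU):

```
stage-1 test acc: 0.7777777777777778
stage-2 test acc: 0.7777777777777778
val sim loss: 31.328143074232003 -> 29.36366518416844
```

The stage-2 model matches its attention maps to the saliency priors better
on held-out subjects (the similarity loss falls) while classifying equally
well; on the synthetic cohort its AD-channel attention also concentrates on
the voxels where disease was actually planted.

The same pipeline is scriptable from the shell (write the bundled default
configuration first):

```bash
python -c "from neurodg.io import DEFAULT_CONFIG, dump_toml; dump_toml(DEFAULT_CONFIG, 'run.toml')"
neurodg simulate        --config run.toml --out cohort/
neurodg train-baseline  --config run.toml --data cohort/ --out s1/
neurodg compute-priors  --config run.toml --data cohort/ --checkpoint s1/baseline.npz --out priors/
neurodg train-dg        --config run.toml --data cohort/ --priors priors/ --out s2/
neurodg evaluate        --config run.toml --data cohort/ --checkpoint s2/dg.npz --out eval/
neurodg validate-pathology --config run.toml --data cohort/ --checkpoint s2/dg.npz --out path/
```

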