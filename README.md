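# aslgpc — GP decoding of on-going pain from ASL perfusion images

`aslgpc` implements a multivariate decoding pipeline for arterial-spin-labeling
(ASL) cerebral-blood-flow images acquired in a repeated-measures postsurgical
pain design: subjects are scanned before and after a surgical intervention
(and at a pain-free follow-up), several perfusion scans per session, and a
probabilistic classifier is asked whether a held-out subject's scans come from
the painful or the pain-free state.

Because no such perfusion dataset is publicly deposited, the package ships a
seeded synthetic cohort generator that emulates the design: 20 subjects × 5
sessions (presurgery ×2, postsurgery left/right, follow-up) × 6 ASL scans, a
spatially distributed postsurgical rCBF increase (thalamus / insula /
cingulate-like blobs) against an occipito-parietal decrease, multiplicative
inter-subject global perfusion variability, white scan noise, and VAS pain
scores whose post-minus-pre group means default to 52.41 (left) and
50.779 (right) on the 0–100 scale.

## The model

The classifier is a Gaussian-process binary classifier with a linear
covariance over (training-mean-centred) voxel features,

$$k(\mathbf{x}, \mathbf{x}') = \frac{s}{d}\,\langle \mathbf{x}, \mathbf{x}'\rangle + b,
\qquad s = e^{\theta_1},\; b = e^{\theta_2},$$

a probit likelihood $p(y=+1\mid f) = \Phi(f)$ over the latent function, and an
expectation-propagation (EP) approximation of the posterior. Hyperparameters
$(\theta_1, \theta_2)$ are set by maximising the EP estimate of the model
evidence (type-II maximum likelihood). Predictions are
$p(y_*{=}{+}1) = \Phi\!\big(\mu_*/\sqrt{1+\sigma_*^2}\big)$ from the predictive
latent moments.

Around the classifier:

* **preprocess** — 8 mm FWHM isotropic Gaussian smoothing, scaling of every
  image to an in-mask median of 1,000 (removing global perfusion offsets),
  scan averaging, and assembly of the samples × voxels feature matrix.
* **evaluation** — leave-one-*subject*-out cross-validation; sensitivity,
  specificity and balanced accuracy; ROC/AUC; a subject-level permutation
  test (whole subjects' labels flip together; plus-one p-value estimator, so
  1,000 permutations bottom out at p ≈ 0.001); Holm step-down correction; and
  a scan-number reduction experiment (train on the average of the first
  n = 1…6 scans per session).
* **gmap** — the unthresholded discriminative pattern map
  $g = X_c^\top K^{-1}\boldsymbol{\mu}$, the posterior mean in voxel space,
  exported as NIfTI with NaN outside the mask.

## Worked example

```python
from aslgpc.synthetic import CohortSpec, simulate_cohort
from aslgpc.preprocess import preprocess_records
from aslgpc.evaluation import (classify_loocv, confusion_stats,
                               comparison_feature_matrix, permutation_test)
from aslgpc.volume import ellipsoid_mask

spec = CohortSpec(n_subjects=12, seed=101)      # default effect: pattern CNR ~1.5
mask = ellipsoid_mask(spec.grid_shape)
records = preprocess_records(simulate_cohort(spec), mask)
fm = comparison_feature_matrix(records, mask, "pre_vs_post", aggregate="condition")
folds = classify_loocv(fm)
report = confusion_stats(folds)
print(f"sensitivity={report.sensitivity:.2f} specificity={report.specificity:.2f} "
      f"balanced accuracy={report.balanced_accuracy:.2f}")
p, _, _ = permutation_test(fm, n_perm=99, seed=1,
                           observed=report.balanced_accuracy)
print(f"permutation p = {p:.3f}")
```

prints

```
sensitivity=1.00 specificity=1.00 balanced accuracy=1.00
permutation p = 0.010
```

i.e. with a postsurgical perfusion effect calibrated to a session-average
contrast-to-noise ratio of 1.5, every held-out subject's state is decoded
correctly and the balanced accuracy exceeds all 99 subject-level label
permutations (the plus-one estimator's floor, 1/100). On cohorts generated
with *no* condition effect the same pipeline returns chance-level accuracy.

The same analyses are scriptable from the shell:

```bash
aslgpc simulate --seed 3 --n-subjects 12 --out ds/
aslgpc classify --dataset ds/ --comparison pre_vs_post --out report.json
aslgpc run-all --config config.yaml     # full pipeline with manifest
```

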