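# neuroattn

Interpretable 3D attention networks for gray-matter classification.

`neuroattn` is for researchers who want a volumetric CNN classifier for
structural-MRI gray-matter density maps (e.g. Alzheimer's disease vs
controls) that *also* says **where** it is looking.  A spatial attention
module — one trainable weight per location of the post-pooling feature
grid, `H[i, c] = F[i, c] · M[i]` with `M = sigmoid(conv3x3x3(F))` —
is trained jointly with the classifier.  Averaging the per-subject maps,
resampling them to the input grid, and aggregating them within an atlas
parcellation yields one attention score per brain region, which the
package then validates against the things an imaging biomarker should
track: regional atrophy (a covariate-adjusted two-sample t-map),
cognition (per-region MMSE correlations under Benjamini–Hochberg FDR
control), and predictive value (masked retraining of attention-ranked
region groups).  Unnormalized class scores serve as individual disease
"pseudo-probabilities" and are correlated with MMSE, CSF markers,
polygenic risk, APOE ε4 status, and time-to-conversion.

The classifier is a 3D ResNet (stem conv + eight residual blocks in four
stages, average pooling after stages 1 and 3 so a 91×109×91 2 mm MNI
grid becomes 46×55×46 and then 23×28×23) with the attention module on
the final feature maps; switching the module off gives the matched
ResNet baseline.  ROI-feature and voxel-feature RBF-SVM baselines and
four cross-validation strategies (two cross-database directions,
leave-center-out, stratified k-fold) round out the comparison harness.
The networks run on a self-contained NumPy engine (BLAS-backed im2col
convolutions with hand-derived gradients) — no GPU or deep-learning
framework required.  Because real AD cohorts are access-restricted, the
package ships a synthetic-cohort generator that plants region-specific
atrophy driven by a latent severity which also produces MMSE-like
scores, CSF/PGRS surrogates, site effects, and conversion times; every
analysis stage is tested end-to-end against it.

## Worked example

Simulate a small cohort with atrophy planted in region 3, train the
attention network, and ask which regions it attends to:

```python
import numpy as np
from neuroattn import AttentionNetClassifier
from neuroattn.simulate import (SimulationSpec, make_toy_parcellation,
                                planted_effects, simulate_cohort)
from neuroattn.attention import (mean_attention_map, resample_to_input_grid,
                                 roi_attention_scores)
from neuroattn.training import evaluate_estimator

shape = (24, 24, 24)
parc = make_toy_parcellation(shape, n_regions=6, seed=0)
spec = SimulationSpec(grid_shape=shape, n_regions=6,
                      effect_size=planted_effects(6, {3: 2.0}),
                      n_per_group={"NC": 30, "AD": 30}, seed=2)
cohort = simulate_cohort(spec, parc)

clf = AttentionNetClassifier(block_channels=(2, 4, 4, 8),
                             learning_rate=3e-4, max_epochs=30, seed=0)
X, y = cohort.stack(), cohort.labels()
idx = np.random.default_rng(0).permutation(len(y))
train, test = idx[:40], idx[40:]
clf.fit(X[train], y[train])

m = evaluate_estimator(clf, X[test], y[test])
print(f"test ACC={m.acc:.2f} SEN={m.sen:.2f} SPE={m.spe:.2f} AUC={m.auc:.2f}")

mean_map = mean_attention_map(clf, cohort)          # (6, 6, 6) post-pooling grid
up = resample_to_input_grid(mean_map, shape)        # back to 24^3
scores = roi_attention_scores(up, parc)
for rid, s in zip(scores.region_ids, scores.scores):
    print(f"region {rid}: attention {s:.3f}")
```

Output from this exact script (about two minutes on one CPU):

```
test ACC=1.00 SEN=1.00 SPE=1.00 AUC=1.00
region 1: attention 0.854
region 2: attention 0.910
region 3: attention 0.969
region 4: attention 0.956
region 5: attention 0.922
region 6: attention 0.954
```

The held-out metrics show the planted effect is easily classified, and
the planted region (3) carries the highest mean attention score.  The
attention margin at this toy scale is modest and varies across seeds —
the sigmoid gates drift toward 1 wherever features help the classifier —
which is why the validation analyses (and the acceptance experiments)
make rank and sign claims over several seeds rather than magnitude
claims; `docs/methods.md` discusses the learning-rate regime this
requires.

The same pipeline is scriptable from the shell:

```bash
neuroattn simulate --config cfg.yaml --out data/
neuroattn train --volumes data/volumes --phenotypes data/phenotypes.tsv \
    --lr 1e-3 --epochs 20 --channels 2,4,4,8 --out model/
neuroattn attend --model model/model.npz --volumes data/volumes \
    --phenotypes data/phenotypes.tsv --parcellation data/parcellation.nii.gz \
    --out attn/
```

Every output directory contains a `manifest.json` (configuration, seed,
input digests) sufficient to re-run the stage bit-identically.

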