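# Methods

## The model

`neuroattn` implements a 3D attention network for two-class classification of
gray-matter density volumes, together with the attribution and validation
analyses that turn its spatial attention map into region-level statements.

The network is a 3D residual CNN: a stem convolution (3×3×3, stride 1),
eight residual blocks arranged as four two-block stages, an average-pooling
stage (kernel 3, stride 2, padding 1) after stage 1 and after stage 3, a
spatial attention module on the final feature maps, global average pooling,
and one fully connected layer producing two unnormalized class scores.
Each residual block is conv–BN–ReLU–conv–BN with an identity shortcut and a
final ReLU on the sum, H(x) = ReLU(F(x) + x); when a stage changes the
channel count, the shortcut is a 1×1×1 projection with its own batch norm.

The attention module is a single 3×3×3 convolution from the stage-4 feature
stack to one channel, passed through a sigmoid:

    M_i = sigmoid(conv3x3x3(F)_i),     H_{i,c} = F_{i,c} · M_i

so one trainable weight per spatial position multiplies every channel at
that position.  The sigmoid bounds M in (0, 1), which makes attention
values comparable across subjects; the literature on this design leaves
the activation open, and this bounded choice is ours.  With the module
disabled (`with_attention=False`) the model is the plain ResNet baseline:
identical weights and arithmetic upstream of the attention stage.

Each pooling stage maps an axis of length n to ceil(n/2) (kernel 3,
stride 2, padding 1, standard floor output-size formula, padded voxels
excluded from the averaging divisor).  A standard 2 mm MNI grid of
91×109×91 therefore reduces to 46×55×46 and then 23×28×23, the grid on
which the attention map lives.  Note that a torch-style `ceil_mode`
average pool with the same kernel/stride/padding would give 46 → 24, not
23; the floor formula is the configuration that reproduces both printed
sizes, and it is what the `pooled_size` helper encodes.

Training minimizes softmax cross-entropy with Adam.  The documented
default learning rate is 1e-6 with batch size 8, which is appropriate for
full-size volumes and thousands of subjects; the toy-scale experiments in
this repository raise the rate (1e-3 for plain classification runs,
3e-4 when the attention map itself is analysed — see below).  After the
last epoch the batch-norm running statistics are recomputed in one
equal-weight pass over the training set under the final weights;
exponentially averaged statistics collected during training lag the
weights, which at small scale can shift the decision threshold enough to
break the argmax operating point even when ranking (AUC) is perfect.

## The compute backend

The networks are implemented in a small self-contained NumPy engine
(`neuroattn._nn`): convolutions are lowered to BLAS matrix products via an
im2col transform whose innermost axis is memory-contiguous, the data
gradient of a stride-1 convolution is computed as a convolution with the
spatially flipped kernels, and batch norm, pooling, and the classifier
head have hand-derived backward passes.  Every layer is checked in the
test suite against brute-force direct-convolution or numeric-gradient
oracles.  All arithmetic is float32; a fixed integer seed pins weight
initialisation (He for convolutions) and batch shuffling, so a fit is
bit-reproducible on a given platform.

## Synthetic cohorts

Real AD/NC cohorts are access-restricted, so every downstream stage is
exercised on synthetic cohorts with planted regional atrophy
(`neuroattn.simulate`).  A toy "brain" is a central ellipsoidal mask
partitioned into R contiguous regions (Voronoi cells of random in-mask
seed voxels; the mask is convex so cells are connected).  Each subject
draws a latent severity s: exactly 0 for controls, Normal(1, 0.2)
truncated at zero for AD, Normal(0.6, 0.2) / Normal(0.3, 0.2) for
progressive / stable MCI.  The volume is a smooth baseline pattern
(values in [0.4, 0.8] inside the mask) minus s · effect_r · 0.1 in each
region r, plus an additive site offset, plus voxel Gaussian noise
(sd = sqrt(noise_sd² + site_sd²), default noise_sd 0.05), clipped to
[0, 1].  Phenotypes derive from the same severity: MMSE =
round(30 − slope·s + N(0,1)) clipped to [0, 30] (slope 5 by default),
CSF tau = 2 + s + N(0, 0.3), CSF Aβ = 2 − s + N(0, 0.3), PGRS =
0.5·s + N(0, 0.5), APOE ε4 carriage with probability 0.25 + 0.35·s
(capped at 0.95), and months-to-conversion for pMCI =
max(1, 36 − 20·s + N(0, 4)).  One integer seed drives every draw.

What this generator does *not* emulate: cortical geometry and
registration error, spatially correlated noise, scanner-specific
contrast, longitudinal change, label noise, and any nonlinearity between
severity and atrophy.  Tests passing on these cohorts show that the
pipeline recovers the statistical structure it assumes — not that the
architecture reaches any particular accuracy on real MRI.

## Region attribution and validation

Per-subject attention maps are averaged voxelwise, resampled to the input
grid by trilinear interpolation (align-corners convention; nearest-
neighbour available), and averaged within each parcellation region to
give one attention score per region (the mean, not the max — matching the
"mean attention score" usage that motivated the statistic).  Maps are
used unnormalized; the sigmoid already bounds them.

Top-fraction selection keeps round(fraction · R) regions (Python's
round; for R = 273 and fraction 0.30 this selects exactly 82), breaking
score ties by ascending region id.  The K-group validation sorts regions
by descending attention (ties again by id), places floor(R/K) regions in
each of groups 1..K−1 and the remainder in group K, zeroes each group's
complement out of every volume, retrains the network from scratch on the
masked volumes, and correlates group mean attention with retrained test
accuracy.

The atrophy t-map takes each subject's mean gray-matter density per
region, residualizes on age, sex, and site (indicator contrasts, least
squares over all subjects), and computes the pooled-variance two-sample
t (AD minus NC) per region; identical groups define t = 0.  Attention–
MMSE correlation maps are per-region Pearson r across patients with
Benjamini–Hochberg control at α = 0.05 over the R p-values
(statsmodels' `fdr_bh`, verified against a step-up oracle).  Dice overlap
between region sets and Pearson correlation between per-region maps
complete the toolkit.

## Class-score associations

Association analyses use the *unnormalized* score of the disease class
(the pre-softmax logit of the "AD" column, via
`score_for_class(X, "AD")` — note that with alphabetically sorted labels
the disease class is not always `classes_[1]`), not the softmax
posterior; the
positive-minus-negative logit difference is available as an alternative
but the single positive logit is the default.  Scores and measures are
residualized on an intercept plus covariates (age and sex in the standard
analyses; site deliberately excluded here) before Pearson correlation;
missing values are removed listwise per analysis.  The APOE contrast is a
pooled-variance two-sample t (carriers minus non-carriers) on residualized
scores, df = n₁ + n₂ − 2.

## Baselines

ROI-SVM: per-region gray-matter volume (mean density × region volume in
mm³) on any parcellation, standardized with training statistics, RBF
kernel with C = 1 and the median heuristic for gamma
(1 / median squared pairwise distance; the original work prints neither
hyperparameter).  Voxel-SVM: in-mask voxel densities reduced to the
n_keep = 2000 largest-|t| features, with the t test computed on the
training split only.  The SVM decision value doubles as the baseline's
per-subject class score.  The attention-free ResNet baseline is the same
network class with the attention module off.

## Problem sizes used in the shipped experiments

The repository's experiments run on one CPU inside the NumPy backend, so
the simulated studies are deliberately small; they were fixed once, from
pilot runs of the generator and optimizer, before the validation analyses
were frozen:

- Planted-region recovery and K-group validation: 24³ grid (attention
  grid 6³), 12 regions with effects 0.5 / 1.0 / 1.5 planted in regions
  3 / 6 / 9, n = 100 + 100, channels (2, 4, 4, 8), 30 epochs of Adam at
  3e-4, batch 8, 60/40 train/test split.  Two of these choices matter
  for interpretability and were settled in pilot runs of the generator
  and optimizer.  First, grid size: below roughly 24³ the post-pooling
  attention grid (≤5³) is too coarse relative to the region size for
  attribution to be reliable.  Second, the 3e-4 learning rate: much
  faster training drives every sigmoid gate to saturation (M ≈ 1
  everywhere inside the mask) once the classes separate, at which point
  region scores differ only in noise; slower training preserves the
  mid-range regime in which gates over discriminative locations rise
  first — the regime the attention analysis assumes.  K-group masked
  retraining uses 8 epochs at 1.5e-3 (the masked task either carries the
  planted signal and converges quickly, or carries none and stays at
  chance).
- Association analyses: scores from a trained toy model applied to fresh
  cohorts of n = 150 patients (plus pMCI subgroups for conversion).
- Permutation-band and leakage checks run through the ROI-SVM baseline,
  which exercises the identical cross-validation and metrics machinery at
  a fraction of the cost of network retraining.

## Numerical and design notes

- Ties in attention sorting and in top-fraction selection break by
  ascending region id; partitions are deterministic.
- AUC is the trapezoidal area under the ROC of the positive-class
  probability; the argmax operating point (probability 0.5) defines
  ACC/SEN/SPE — no threshold tuning.  The positive class defaults to the
  disease label (AD, or pMCI for the conversion task), not to the
  alphabetically last label.  Leave-one-out folds with a
  single-class test set report accuracy only (SEN/SPE/AUC undefined,
  returned as NaN and ignored by summary averaging).
- k-fold assignment is stratified and seeded; when k exceeds the
  smallest class count (leave-one-out), plain seeded KFold is used.
- Pearson correlations with a zero-variance input raise; per-region
  correlations with a constant column return r = 0, p = 1 so that one
  degenerate region does not abort a map.
- The volume reader accepts any density-like 3D map; it makes no attempt
  to detect whether maps were modulated during preprocessing.
- Missing phenotype values are empty TSV cells, never sentinel numbers,
  and become `None` in memory.

## Known limitations

- The NumPy backend is single-threaded BLAS-bound; full-size 91×109×91
  training is functional but slow, and no GPU path exists.
- Attention interpretability at desk scale is statistically weak: with a
  5³ attention grid the effective receptive field of stage-4 features
  spans much of the toy brain, so region attribution carries large
  variance across seeds.  The validation analyses therefore make rank
  and sign claims (positive correlation in most seeds), not magnitude
  claims.
- The synthetic generator's severity model is linear and homoscedastic;
  calibration results under its null transfer to real data only to the
  extent real nuisance structure resembles it.
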