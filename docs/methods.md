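# Methods

`phasemark` implements a biomarker-discovery workflow for case cohorts
profiled at three clinical phases (Acute, Subacute, Convalescent): unsupervised
patient subgrouping by a two-stage self-organizing map (SOM), per-phase
FDR-controlled ANOVA feature selection with a cross-phase intersection, and a
boosting-classifier comparison of the selected gene set against a reference
set.  This note records the model, the defaults and why they were chosen, the
numerical conventions, and what the synthetic cohorts do and do not establish.

## The clustering model

**Stage one (per-phase).** Each phase's samples x probes matrix is clustered
by a rectangular 3x3 SOM trained by competitive learning.  At step *i* a
random input x(q) is drawn, its best matching unit (BMU) u is the node with
the smallest Euclidean distance, and every node y moves by

    w_y <- w_y + U(u, y, i) * gamma(i) * (x(q) - w_y),

with U a Gaussian of squared grid distance, U(u, u, i) = 1.  Defaults:

| parameter | default | rationale |
|---|---|---|
| grid | 3x3 (9 nodes) | small cohorts leave larger grids idle; empty nodes are legal and expected |
| gamma(0) | 0.5 | standard competitive-learning starting rate |
| gamma decay | exponential, gamma(i) = 0.5·exp(-8 i/T) | the final map must be effectively frozen (gamma(T) ≈ 3e-4·gamma(0)); slower decays leave the prototypes jittering and the quantization error non-monotone |
| sigma(0) -> sigma(T) | max(rows, cols)/2 -> 0.5, exponential | orders globally early, localizes late |
| T | 500 steps per input | enough epochs for the 20-patient cohort to converge; training also stops early when the weights move less than 1e-8 over an epoch |
| input scaling | none | inputs are already log-ratio scale expression |

BMU ties break to the lowest row-major index; node labels are reported
1-based (1..9).  Training consumes samples in canonical sample-id order so a
permutation of the patients permutes the labels identically, and the whole
model is bit-reproducible from (data, params, seed).  The quantization error
(mean input-to-BMU distance) is recorded as a fit diagnostic; its per-epoch
trend on well-separated blob data is non-increasing in ≥ 90% of transitions
up to fluctuations of 1% of the starting error.

**Stage two (label SOM).** The per-phase labels form one 3-vector per
patient; a second 3x3 SOM groups patients with similar per-phase membership.
Categorical node labels have no intrinsic arithmetic, so the encoding of this
3-vector is the workflow's most consequential free choice.  The default is
the **grid encoding**: each label is replaced by its (row, col) coordinates on
the stage-one grid.  The reason is empirical and structural: on cohorts with
planted subgroups the stage-one map tiles each subgroup with several
*grid-adjacent* nodes (proper SOM topology), and the grid encoding keeps such
a tiled subgroup a compact cloud, whereas raw integer labels place nodes 3
and 6 (grid-adjacent on a 3x3 map) three units apart and the downstream
dendrogram cut then mis-merges (super-cluster ARI drops from 1.0 to a median
of ~0.67 at the defaults).  `raw` and `onehot` encodings remain available.

**Super-clusters.** Empty stage-two nodes are pruned; the surviving prototype
weight vectors are merged by agglomerative clustering (average linkage by
default; Ward and complete available) on their Euclidean distances, and the
dendrogram is cut into `cut_k` groups (default 4).  Patients inherit their
prototype's group, so super-clusters never split a stage-two cluster.
Super-clusters are renumbered by first patient occurrence.  An unstated
cut rule cannot be recovered from first principles; 4 matches the study
design this workflow reproduces and is configurable.

**Seeds.** A master seed fans out via
`SeedSequence((master, offset))` — offsets 0/1/2 for the phase SOMs, 3 for
the stage-two SOM — so phases are independent yet the whole run is exactly
reproducible.

## Feature selection

Within each phase, every probe is scored against the super-cluster labels by
one-way ANOVA, F = MST/MSE with degrees of freedom (N-1, n-N) for N groups
and n samples.  Probes with MSE = 0 but MST > 0 get F = inf, p = 0; probes
constant everywhere have no defined F and are excluded from the family and
logged.  The Benjamini-Hochberg step-up procedure is applied at alpha = 0.01
per phase, with the family = all defined probes of that phase (never pooled
across phases).  The proposed set is the intersection of the three per-phase
rejection sets; under a global null the intersection's false-selection rate
is far below the per-phase level (approximately alpha-cubed-driven).
Selection runs on curated (zero-imputed) but un-normalized per-phase values
by default; a config switch allows normalized inputs.

Sums of squares are computed on grand-mean-centered columns, and an "exactly
zero" variance is declared below 1e-12 times the column's mean square, so
constant probes are classified robustly under floating-point rounding.

## Curation

Missing cells are explicit in the containers and only replaced (by zero, the
deposited convention for absent calls in this data family) by the curation
step, so imputation is auditable.  Outlier samples are scored by an isolation
forest and the local outlier factor; a sample is flagged only when **both**
detectors rank it inside the contamination budget (default 5%), a
conservative consensus for cohorts of tens of samples.  Flagging is
report-only by default — on a 20-patient cohort silently dropping a patient
would distort every downstream stage.  Scoring happens on canonically sorted
sample ids (permutation equivariance) and sees missing cells as zero without
finalizing the imputation.  Genes with exceptionally high covariance to
another gene (duplicate probes, saturated channels) are removed when their
maximum absolute off-diagonal covariance reaches the 0.999 quantile of that
statistic; for a tied mutual pair only the later column is dropped.

## Cross-platform normalization

Genes measured by several probes are collapsed to their per-sample median
**before** normalization.  Quantile normalization replaces each sample's
order statistics with a reference; ties receive the mean of the reference
values at their tied ranks (ties stay tied, within-sample rank order is
preserved).  By default the reference is the dataset's own average quantile
vector.  For multi-dataset integration each dataset is transformed
independently onto a **shared** reference — the mean of the per-dataset
average order statistics — because quantile normalization onto a dataset's
own reference is invariant to a dataset-level affine distortion and
therefore cannot align platforms by itself.  After the shared-reference
transform, the systematic location offset between platforms on matched null
genes drops below 0.05 noise sd (per-gene sampling noise of order
sd/sqrt(n_samples) remains).

## Classifiers and evaluation

Two binary ensembles, both native implementations:

* **AdaBoost over decision stumps** — per round, the stump minimizing the
  weighted error over all features, thresholds and polarities; vote
  a_i = 1/2 ln((1-err)/err); misclassified samples up-weighted; rounds with
  err ≥ 0.5 stop training, err = 0 stops early.  Scores map to [0, 1] by a
  logistic link on the margin.
* **Gradient-boosted trees** — logistic loss with the regularizer
  gamma·M + 1/2·lambda·Σ w_j² over the M leaf weights.  Trees grow
  best-first by exact greedy split search to at most `max_leaves` (default
  8); each leaf takes the penalized Newton step w = -G/(H + lambda); a split
  is kept only when its gain exceeds gamma.  Defaults: 100 rounds, learning
  rate 0.3, lambda = 1, gamma = 0, base score = the log-odds of the training
  base rate.

Hyperparameters are deliberately fixed (no search) and logged with every
report.  Evaluation uses repeated stratified 10-fold cross-validation
(10 repeats by default), so with 20 positives among 87 samples every fold
holds exactly 2 positives.  Metrics: accuracy, sensitivity, specificity at a
fixed 0.5 probability threshold (the case cohort is the positive class) and
AUC as the rank statistic with ties counted 1/2, threshold-free.  Gene-set
comparisons run both sets through identical fold sequences and report paired
deltas.

## Synthetic cohorts: what they emulate, what they do not

The generator plants the structure the workflow assumes:

* **Subgroups** — default 4 groups of sizes 6/5/2/7 over 20 patients.
* **Phase-consistent markers** — 5 probes whose per-group offsets
  (+/- effect_size · noise_sd, balanced sign patterns, default effect 3)
  repeat identically in all phases: the signal the intersection must keep.
* **Phase-specific programs** — by default 45% of the panel, split evenly
  over the three phases, offset in a single phase only.  These play two
  roles: they give each phase's map genuine geometry to cluster, and they
  must *not* survive the cross-phase intersection.  The breadth follows a
  geometric requirement: with P iid-noise probes the within-cohort noise
  radius is ~sqrt(2P)·sd (~63 sd at P = 2000), and subgroup separation must
  exceed it for any patient-level clustering to exist; ~305 active probes
  per phase at |offset| = 3 sd give ~74 sd of separation.  Narrow signatures
  (tens of probes) are recoverable by feature-selection-first designs but
  not by clustering on the full matrix — a real limitation of the workflow,
  not of the generator.
* **Platform effects** — per-dataset affine location/scale distortions and
  multi-probe genes (2-3 probes sharing the gene signal plus probe noise)
  for the six-dataset, two-platform integration suite (1,347 samples, 558
  cases at study scale).
* **Missing entries and outlier patients** on demand.

Noise is iid Gaussian; there is no intensity-dependent variance, no
correlated background co-expression, and no batch structure beyond the
affine platform effects.  Passing the recovery tests therefore shows the
pipeline's statistics and plumbing are correct under its own assumptions; it
does not certify performance on real microarray noise.

## Problem sizes used in tests

The default test cohort is 20 x 2,000 x 3 (the full-scale probe panel of
37,653 is supported but not exercised in the default suite); recovery and
superiority studies replicate over 20 seeds.  The cross-platform suite runs
at the full 1,347-sample scale with a 300-gene panel.

## Known limitations

* The cut at `cut_k` super-clusters is a design input, not inferred; the
  optional silhouette-based auto-cut is off by default.
* The second-stage encoding choice materially affects results; the grid
  default is validated on synthetic geometry only.
* BH is applied per phase; no cross-phase dependency modeling.
* Quantile normalization assumes comparable distributions up to monotone
  distortion; it cannot fix rank-level disagreements between platforms.
* With ties, quantile normalization maps a sample onto fewer distinct values
  than the reference, so exact distribution equality across samples holds
  only tie-free.
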