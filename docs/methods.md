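# Methods

`painconn` implements a resting-state fMRI classification protocol — parcel
signal extraction, correlation- and DTW-based functional connectivity,
synthetic-instance augmentation, connectome CNN classifiers, and a
leakage-audited evaluation grid — and exercises it end-to-end on a synthetic
cohort generator, because the clinical data the protocol was designed for
(pain-free controls vs. chronic-pain patients) are private. This note
documents the models, the defaults and why, what the generator does and does
not emulate, and the numerical choices.

## The synthetic cohort

Each subject is a regions × timepoints matrix of latent BOLD-like signals
plus nuisance structure.

**Temporal model.** Region signals are stationary unit-variance AR(1)
processes (`ar_coefficient`, default 0.9). The high persistence emulates
hemodynamic smoothing; it also matters quantitatively, because both the DTW
behavior under lags and the sampling variance of correlation estimates
depend on it.

**Spatial model.** A Toeplitz baseline correlation (`toeplitz_rho^|i−j|`,
default ρ = 0.3) gives neighboring regions mild coupling. Group structure is
added on a designated edge set (`affected_edges`):

* *Correlation effects* (`corr_effect`, with shared `base_coupling`, default
  0.4): entries of the patient covariance are raised and the matrix is
  projected to the nearest positive semi-definite correlation matrix
  (eigenvalue clipping, diagonal renormalized). With a single affected edge
  the realized patient correlation matches `base_coupling + corr_effect`
  within ±0.05 (Monte-Carlo tested); dense effect sets (e.g. 24 edges at
  0.8 on 16 regions) are *compressed* by the PSD projection — the realized
  effect is smaller but still strong. This is a property of constraining to
  valid correlation matrices, not a bug.
* *Timing (lag) effects* (`lag_effect` > 0): each affected pair shares a
  fresh AR(1) factor; the second member receives it **circularly shifted**
  by the lag in patients, and **partially decorrelated by exactly the lag's
  finite-sample autocorrelation attenuation** in controls. Both groups carry
  identical factor variance shares, so their instantaneous correlation
  structure is identical in expectation; the groups differ *only* in whether
  the shared component is genuinely time-shifted (recoverable by a warping
  distance) or irrecoverably decorrelated. This is the construction that
  makes "the group difference is purely one of timing" literally true at the
  estimator level: zero-lag correlation is blind to it by design, DTW is
  not.

  Two finite-sample subtleties are handled by a fixed-seed internal Monte
  Carlo (deterministic in its arguments): (a) the sample correlation between
  a persistent series and its lagged copy is biased well below the
  asymptotic `phi^lag` at realistic series lengths; (b) detrending and
  slow-confound projection attenuate lagged but not instantaneous coupling.
  The control mixing coefficient is therefore calibrated per pair on the
  *cleaned composite* construction, so the groups match after the actual
  pipeline, not just asymptotically. Factor loadings are solved by a damped
  fixed point; with overlapping affected pairs the required coupling can be
  infeasible (capped, realized coupling undershoots), so lag studies use
  disjoint pairs (`choose_disjoint_pairs`).
* *Sex-linked effects* (`sex_effect_edges`, `sex_effect`) reuse the
  covariance path for female subjects only; by default sex has no effect.
  Sex, group, signals, confounds and artifacts draw from independent
  streams of the master seed, so sex is independent of the group-conditional
  signal parameters by construction.

**Nuisance structure.** Confounds are a linear drift, a slow sinusoid
(period 100 volumes) and a white "motion" channel, mixed into each region
with small random loadings (`confound_amplitude`, default 0.1). Artifact
volumes are whole columns multiplied by 5 at a per-volume rate of 0.01, with
ground-truth indices recorded.

**Defaults.** 140 subjects at the recruited 98:60 control:patient and
124:34 female:male ratios; 235 timepoints (a 240-volume series minus five
discarded start volumes); 16 regions at desk scale (toy atlases stand in for
the published parcellations of 21–499 regions).

**What the generator does not emulate:** scanner physics, head motion and
realignment, spatial normalization, physiological noise spectra,
site/session effects, and any spatial structure of real atlases. Passing
tests show the *pipeline* behaves correctly under its assumed statistical
structure; they say nothing about classification accuracy on real patients.

## Extraction and cleaning

Voxel data follow the linear mixing model `voxels = W @ signals + noise`
with a nonnegative probabilistic atlas `W`; region signals are recovered per
timepoint by least squares (exact on noiseless data; rank-deficient atlases
are rejected naming the offending columns). Cleaning is detrend → projection
onto the orthogonal complement of the confound columns (pseudoinverse
projector, rank-safe) → per-region standardization (population sd).
Confound columns are detrended before the projector is built; the cleaned
output is then simultaneously orthogonal to {constant, trend, confounds},
which makes the whole cleaning operator idempotent. Artifact volumes are
flagged by global-intensity z-score (threshold 3) or frame-to-frame motion
jumps (threshold 1 in signal units); subjects with more than 3 flagged
volumes are excluded.

## Connectivity

Pearson correlation and dynamic time warping distance, computed pairwise on
cleaned series. The exact DTW is the full dynamic program over monotone
warping paths with steps {(1,0),(0,1),(1,1)} and absolute-difference local
cost (squared available); `dtw_fast` is the multiresolution FastDTW
recursion (halve by pairwise averaging, solve recursively, dilate the coarse
path by `radius` coarse cells, refine in the banded DP). It always returns
the cost of a valid path, hence upper-bounds the exact distance, and equals
it when `max(len) ≤ radius + 2`. At the canonical radius 1 its mean excess
over the exact distance is ≈ 5% on standardized AR(0.9) series (the kind
this pipeline computes) and larger on white noise — an inherent property of
the approximation at small radius. Kernels are numba-compiled.

DTW is a distance (small = connected) while correlation is a similarity; no
sign flip is applied — both matrix types are globally z-scored (population
sd over all cells, diagonal included, per subject; a cohort-level variant
exists) and the classifiers learn the orientation.

## Augmentation

Local synthetic instances: `s = α·a + (1−α)·b` with `α ~ U(0,1)`, `a` a real
instance and `b` one of its k = 5 nearest same-class neighbors (Euclidean);
5000 instances per set by default, class-balanced within one. This is a
SMOTE-family reconstruction of the idea, not a reproduction of any specific
reference implementation. Training and validation folds are augmented
separately from disjoint parent sets; every synthetic instance records its
parent indices, and `audit_provenance` turns fold separation into a
mechanically checkable property.

## Classifiers

Three architectures over N × N matrices, implemented in numpy with explicit
backward passes:

* **ann4brains** — E2E bank (32 filters; cross-shaped support:
  `out(i,j) = Σ_k r(k)a(i,k) + Σ_k c(k)a(k,j)`), E2N bank (64 filters;
  `out(i) = Σ_k w(k)a(i,k)` summed over channels), N2G bank (128 units), then
  FC 128 → 30 → 2 with softmax. Dropout between the FC layers.
* **ann4brains_batch** — the same with batch normalization after each filter
  bank.
* **conv1d_net** — the matrix's N rows as N length-N channels; a full-length
  1-D conv (64 filters), a second 1-D conv (64 filters, kernel 1), FC 96,
  softmax head.

Unstated details are fixed as: leaky-rectifier activations (slope 1/3, the
connectome-CNN convention), SGD with momentum 0.9, batch 32, ≤ 100 epochs
with early stopping (patience 10) on validation cross-entropy, best-epoch
weights restored. The loss is cross-entropy + λ₁Σ|w| + λ₂Σw² over weight
matrices only (biases and normalization parameters unpenalized; λ = 0
deactivates a penalty). All randomness (init, shuffling, dropout) is seeded;
single-threaded runs are bitwise reproducible.

## Evaluation protocol

A stratified split (largest-remainder per-class apportionment — 140 subjects
at fraction 0.70 give exactly 98/42) carves out the independent fold first;
the training fold is sub-split 3:1 into train/validation, both sides are
augmented separately, models train on the synthetic instances only, and all
three scores — balanced accuracy (mean per-class recall), log loss (natural
log, probabilities clipped at 1e−15), AUC (Mann–Whitney, ties ½) — are
computed once on the independent fold. The full grid is 4 parcellations × 2
measures × 3 architectures × 3 learning rates {0.1, 0.01, 0.001} × 4
dropouts {0, 0.3, 0.5, 0.8} × 3 L1 × 3 L2 {0, 0.1, 0.01} = 2592 cells, plus
3 optimization metrics × 8 matrix sets = 24 automated-search baselines
(2616 total). No multiple-testing adjustment is applied across the grid;
scores are reported raw, per cell.

The classical baseline is a seeded evolutionary search (population 50,
10 generations by default; fitness cached per genome) over scaler on/off ×
SelectKBest on/off × {logistic regression, calibrated linear SVM, random
forest, k-NN} with small hyper-parameter menus, selected by stratified
5-fold cross-validation within the training fold only.

The sex-control analysis re-runs the identical pipeline with sex as the
target. With sex independent of connectivity the control models sit at
chance; with a planted sex-linked edge they find it — so chance-level
control scores certify the group classifiers are not reading sex.

## Study conditions and problem sizes

The end-to-end studies (`painconn.studies`, used by the analysis scripts,
the acceptance tests and `scripts/acceptance.py`) run at desk scale: 16 (or
12) regions, 300–500 synthetic instances, quarter-width filter banks
(8/16/32), 15–30 epochs. These sizes were chosen so a full study runs in
minutes on one CPU while keeping every qualitative property of the protocol
intact; all are exposed as arguments. Chance-level summaries (null
calibration, sex-independent control) draw a fresh stratified split per
spec: with a single shared 42-subject fold the chance-level mean AUC varies
by ±0.2 from fold composition alone, which would say nothing about the
pipeline.

## Numerical choices and degenerate inputs

Population (n) standard deviations throughout z-scoring and
standardization; zero-variance regions become zero rows with a logged
warning (correlation) or all-zero series (cleaning); a constant connectivity
matrix has no z-score and raises; empty series are rejected by DTW;
rank-deficient atlases and single-class label vectors raise with named
causes; non-finite training losses abort with a diagnostic rather than
propagate. PSD repair clips eigenvalues at 1e−8 and renormalizes the
diagonal; an (impossible for finite input) residual indefiniteness raises.

## Interfaces

The library surface plus the numbered scripts under `analysis/` are the
interface; each script is a thin driver that prints what it found and writes
small CSV tables under `results/` (bulky artifacts go to `scratch/`).
Time-series and matrices are tab-delimited text with JSON or CSV sidecars;
cohort configurations are `key = value` text files; voxel data and atlases
can round-trip through 4-D NIfTI via nibabel.

## Known limitations

The generator's effects are stationary and Gaussian; real chronic-pain
connectivity differences are neither. FastDTW at radius 1 is a loose bound
on white-noise-like series. The evolutionary baseline search explores a
deliberately small pipeline space. Parameter counts and widths of the
original clinical models are not public; the defaults here are reasoned
stand-ins, and the reduced-scale studies establish qualitative properties
(power, calibration, measure dissociation), not clinical performance.
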