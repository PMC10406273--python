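# Methods and design notes

## The model

Each brain network gets its own regressor that maps one min-max-normalized
fMRI timepoint volume (X×Y×Z, one channel) to that network's probabilistic
score volume on the same grid.  The architecture is a residual
encoder/decoder of 3D convolutions:

| stage | layers | spatial effect |
|---|---|---|
| stem | unpadded 3³ conv 1→64, sigmoid | −2 per dim |
| encoder ×3 | three 3³ convs (+batch norm each), max pool k3 s1 | −4 per block |
| bottleneck | channel dropout 0.5 | — |
| decoder ×3 | two unpadded 3³ transposed convs (+batch norm each); dropout after block 2 | +4 per block |
| head | unpadded 3³ transposed conv 64→1, sigmoid | +2 |

Channels run 64→32→16→8 down and 8→16→32→64 back up; additive,
parameter-free skip connections join the stem output and the first two
encoder-block outputs to the decoder activations with identical
channel-and-spatial shape (the skip is added after the block, and after
the dropout where one intervenes).  On the default 53×63×52 grid (3 mm
MNI-like spacing) the spatial chain is 51·61·50 → 47·57·46 → 43·53·42 →
39·49·38 and back, ending at 53×63×52, and the parameter total is
367,577.

Two details are interpretive rather than forced by the layer-level
parameter accounting, and are recorded here as this package's choices:

- **Padding split.**  An encoder block must shrink each dimension by 4;
  the pool (kernel 3, stride 1) accounts for 2, so exactly one of the
  three convolutions is unpadded.  We make it the first; parameter counts
  are padding-independent, so the table cannot distinguish the variants.
- **Skip semantics.**  The block-level parameter counts leave zero
  parameters for projection layers, and concatenation would change the
  downstream counts, so skips are additive at the three shape-matching
  pairs.  Identity shortcuts *inside* a block are omitted: no
  parameter-free mapping reconciles a 64→32 channel change with a −2
  spatial shrink.  The stem's hidden-layer sigmoid is unusual but is
  implemented as listed.

There are no ReLUs: the only nonlinearities are the stem and output
sigmoids, the normalization layers, pooling, and dropout.  That makes the
network close to linear in the stem features, which is sufficient for the
blob-extraction task the synthetic studies pose and matches the printed
layer inventory.

### Why numpy

The layers (3D convolution, transposed convolution, batch/instance
normalization, overlapping max pooling, channel dropout) and their
backward passes are implemented directly on numpy arrays, with
convolutions expressed as im2col + GEMM in float32.  The transposed
convolution is implemented as the exact adjoint of the valid convolution
(full correlation with the channel-transposed, spatially flipped kernel),
which the test suite verifies both by inner-product identity and by
finite differences.  The backward pass of every layer is checked against
central finite differences at float32 tolerance.

### Training

MSE loss, Adam (default learning rate 1e-5, the reference recipe), a step
learning-rate schedule (×γ, default 0.9, every 5 epochs — the reference
recipe fixes the step period but not the decay factor), early stopping on
validation loss (patience 10, min_delta 0; both unstated upstream and
exposed in `TrainConfig`), and best-validation-checkpoint return.
Datasets are built volume-wise: every (subject, timepoint) pair is one
sample, inputs min-max normalized per volume, and splits are by subject
to avoid leakage.

**Batch-norm recalibration.**  With small datasets and batches of 5, the
exponential running statistics of batch norm are stale relative to the
final weights, which can make evaluation-mode output collapse even when
training-mode fit is good.  After each epoch (and hence for the returned
checkpoint) the running statistics are re-estimated by streaming the
training set through the frozen weights with dropout off.  This is a
standard small-data correction; it changes nothing at large batch counts.

Reduced-scale runs (16³ grid, K=4) use a learning rate of 1e-3 and ≤30
epochs; at the reference rate of 1e-5 a run this small would barely move.
The ablation scenarios substitute instance norm for batch norm (S1) and
additionally remove (S2) or add (S3) one convolution plus one transposed
convolution; removed/added layers are shape-preserving (padded) so the
skip geometry stays intact, with the encoder block compensating via its
padding layout.  S2/S3 strictly shrink/grow the parameter total.

## The synthetic generator

The generator's job is to produce preprocessed-looking 4D scans for which
every downstream quantity has a known answer.  Each network is an
axis-aligned anisotropic Gaussian blob (per-axis σ ≈ 2–3 voxels,
unit peak).  Domains are placed at well-separated anchor sites —
farthest-point sampling by default, or a compact lattice at a configured
`domain_separation` so that neighbouring domains' blob tails overlap —
and member networks scatter around their domain anchor (σ ≈ 1.3 voxels),
so same-domain networks are spatially close and cross-domain ones far.

Temporal structure: per-network unit-variance timecourses are AR(1)
smoothed (coefficient 0.5–0.6) and correlated according to a target
matrix — `within_corr` (default 0.45) inside a domain, `cross_corr`
(default 0) across, patient `coupling_effect` added to chosen domain
pairs — realized exactly via a Cholesky factor applied to the AR
innovations.  Amplitudes are `clip(amp_base + amp_depth·x, 0, 1)`.

Spatial dynamics: each network's centre (3 coordinates) and log-width
follow stationary Ornstein–Uhlenbeck walks (AR coefficient 0.8,
stationary sd `jitter_sd`, default 0.5–0.75 voxels).  The walk is smooth
by design so that temporal-deviation maps are structured rather than
white.  Patients' walks are scaled by `deviation_effect` per network.

The scan is Σ_k ω_k + iid Gaussian noise.  Everything derives from
`numpy.random.SeedSequence([study_seed, stage, group, subject])`, so a
study is bit-reproducible and any subject can be re-rendered in
isolation.

**Observed score maps.**  Group-level statistics can be exercised without
a training run via an estimation-error model: ground-truth maps plus a
per-subject time-constant voxel bias (sd 0.08–0.1) and per-(voxel, t)
noise (sd 0.05).  The error is additive and symmetric — deliberately not
re-projected onto [0, 1].  Clipping would pile low-signal voxels onto the
boundary, making the voxel-wise t-test measurably conservative; the
unclipped model keeps the test's distributional premises intact.  The
per-subject bias (rather than purely per-timepoint noise) mirrors the
systematic, subject-specific character of model prediction error and is
what makes across-subject variance at a voxel dominated by independent
noise.

**What the generator does not emulate:** hemodynamics/BOLD biophysics,
physiological or motion confounds, scanner/site effects, anatomical
tissue contrast, and non-Gaussian network shapes.  Passing tests
therefore demonstrate that the *statistics and machinery* behave as
designed under a controlled signal model — not that the trained models
would reach any particular accuracy on real scans.

### Study presets

- `default()`: 53 networks (domain sizes SC 5, AU 2, SM 9, VI 9, CC 17,
  DMN 7, CB 4), 53×63×52 grid, T=150.
- `small()`: 8 networks in 4 domains (SM, DMN, VI, CB × 2) on 24×28×24,
  `domain_separation` 5 voxels, σ 2.6, amplitude 0.5±0.4, jitter 0.5 —
  the geometry is chosen so that neighbouring domains overlap enough for
  timecourse coupling to transfer into map-level FNC (with fully disjoint
  supports, flattened-map correlation is blind to temporal coupling).
- `tiny()`: 4 networks on 16³ (the smallest grid the architecture
  admits; the spatial chain needs ≥15 per dimension), T=8 — the
  model-training fixture.
- `null_calibration()`: `small` geometry with no group effects,
  `jitter_sd` 0, amplitude depth 0.02, map bias 0.1, T=50, 20+20
  subjects.  The shallow modulation and absent jitter are deliberate:
  the binomial reference band for the rejection rate presumes roughly
  independent per-voxel statistics, so the calibration study makes
  independent estimation noise the dominant across-subject variance.
  (With deeper modulation, cross-pair FNC entries inherit heavy-tailed
  finite-T correlation sampling noise that visibly inflates far-tail
  rejections at n=20 per group.)
- `effect_study()`: `small` geometry, T=150, 20+20 subjects, amplitude
  ×1.3 and jitter ×0.5 on network 5 (VI), coupling +0.4 on (SM, DMN).
  The map-level effects sit outside the coupled domains so the FNC
  contrast block is uncontaminated.

The magnitude of real spatial dynamics is not established; these defaults
are chosen for statistical detectability at desk scale, not for
physiological realism.

## Statistics

- The voxel-wise two-sample statistic is Welch's t (separate variances,
  n−1 denominators), with two-sided p-values from the t distribution
  with Welch–Satterthwaite degrees of freedom.  Voxels where both groups
  have zero variance are flagged invalid and excluded rather than
  produce infinities.
- Peak-voxel analysis takes the argmax/argmin of the group difference of
  time-mean maps within a mask (ties broken in lexicographic voxel
  order; an all-positive or all-negative map reports the absent peak as
  missing), then collects each subject's value at those voxels.
- sFNC correlates maps flattened over (masked voxels × timepoints); the
  mask defaults to the union of template supports, since correlating
  structurally empty background would inflate ρ.  Zero-variance pairs
  are reported as missing (NaN), not zero.
- dFNC uses rectangular (unweighted) windows starting at 0 with stride =
  length − overlap ("overlap 10" is read as 10 shared timepoints, so the
  default 30/10 gives stride 20 and, at T=150, 7 windows); a trailing
  partial window is dropped.
- k-means runs on vectorized strict upper triangles (k-means++, 10
  restarts, fixed seed); windows are not z-scored first.  The elbow is
  made algorithmic as the candidate k maximizing the second difference
  of the inertia curve, with ties to the smaller k.  State assignment is
  nearest-centroid with ties to the lowest index.  Occupancy is the
  per-subject fraction of windows per state.
- The FNC group contrast is an elementwise Welch t over the upper
  triangle with Benjamini–Hochberg FDR at q=0.05, mirrored to the full
  matrix.

## Pipeline

Stages (simulate → train → predict → stats → fnc) exchange files, not
objects: each stage directory carries a marker with the configuration
hash, a re-run with an unchanged configuration skips completed stages,
and the stats/FNC stages can equally be pointed at maps from any other
source.  Per-network models are trained and applied sequentially in one
process.  All volumes are NIfTI-1 with a diagonal 3 mm affine; tables are
CSV; the state model is JSON; checkpoints are `.npz` weight archives with
a JSON sidecar holding the architecture spec and network id.

## Problem sizes

The test suite runs entirely at reduced scale, as its own design choice:
gradient checks on ≤5³ tensors; architecture accounting at full 53×63×52
(a build allocates weights but runs no forward pass); statistical
calibration and effect recovery on the 24×28×24 / 8-network presets with
20+20 subjects (the FDR-null check repeats 20 seeded studies); learning
sanity on the 16³ / 4-network preset with 4 training + 1 validation
subjects, 18 epochs, and one fully held-out subject; the end-to-end
pipeline test on a 2-network 16³ study with 1 training epoch.

## Known limitations

- Training at the full 53×63×52 scale is possible but slow in pure
  numpy; the package is tuned for reduced-scale validation, and the
  checkpoint format would carry over unchanged to a faster backend.
- The elbow criterion on smooth inertia curves (real dFNC windows rather
  than well-separated synthetic states) is sensitive to the candidate
  range; the chosen k should be inspected against the inertia curve the
  state model records.
- `sfnc_pair` loads both flattened vectors in memory; at the full grid
  with long scans this is ~100 MB per pair and could be streamed if
  needed.
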