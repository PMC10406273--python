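# parc5d — 5D spatiotemporal brain-network characterization

Resting-state fMRI is usually summarized either by static spatial maps or
by temporal coupling between *fixed* regions.  Both views miss **spatial
dynamics**: a functional network's shape, size and position drift over the
course of a scan, and those voxel-level changes carry group information
(e.g. in psychosis studies).  `parc5d` implements a framework that keeps
all five dimensions — space (3D), time, and network — and the statistics
needed to compare groups on them.  It is aimed at methods researchers in
functional neuroimaging who want a fully testable, synthetic-data-backed
implementation of voxel-wise spatiotemporal network analysis.

## What it computes

**1. Per-network score maps.**  A residual U-Net-style 3D convolutional
regressor maps one fMRI timepoint volume to one network's probabilistic
score volume.  The default architecture (input grid 53×63×52 at 3 mm) is:
an unpadded 3³ stem convolution 1→64 with sigmoid; three encoder blocks
64→32→16→8, each three 3³ convolutions with batch normalization followed
by max pooling (kernel 3, stride 1); dropout 0.5; three decoder blocks
8→16→32→64, each two unpadded 3³ transposed convolutions with batch
normalization; a final transposed convolution 64→1 with sigmoid; and
parameter-free additive skip connections joining the stem and encoder
outputs to the shape-matched decoder activations.  The model has exactly
**367,577** trainable parameters.  Running K such models (one per network)
over all T timepoints of a scan yields K 4D score maps ω_k — a 5D
description per subject.  The network layers (3D convolution, transposed
convolution, batch/instance norm, overlapping max pooling, channel
dropout) and the training loop (MSE loss, Adam, step learning-rate decay,
early stopping, batch-norm recalibration) are implemented in numpy with
hand-derived backward passes, verified against finite differences.

**2. Voxel-wise spatiotemporal statistics.**  For a subject's map ω with
T timepoints,

- time mean:  ω̄(v) = Σ_t ω(v,t) / T   (static amplitude),
- temporal deviation:  ω̃(v) = Σ_t |ω(v,t+1) − ω(v,t)|   (spatial
  dynamics; zero iff the voxel series is constant),

each averaged over subjects per group and contrasted voxel-by-voxel with
the Welch two-sample statistic

  t(v) = (v̄ᶜ − v̄ˢ) / sqrt(σ²ᶜ/nᶜ + σ²ˢ/nˢ),

plus difference maps and peak-voxel value distributions.

**3. Functional network connectivity.**  Static FNC is the Pearson
correlation ρ_{p,q} between two maps flattened over (masked voxels ×
timepoints), forming a K×K matrix per subject; dynamic FNC applies the
same correlation over sliding windows (default length 30, overlap 10 →
stride 20).  All subjects' windows are clustered by seeded k-means into
connectivity states (elbow criterion = largest second difference of the
inertia curve), and each subject's occupancy ratio is the fraction of
windows per state.  Group contrasts use elementwise Welch t-tests with
Benjamini–Hochberg FDR control at q = 0.05.

**4. Synthetic studies with ground truth.**  A seeded generator emulates
preprocessed fMRI: K Gaussian-blob networks in up to seven domains (SM,
DMN, AU, CC, VI, SC, CB), domain-correlated AR(1) amplitude timecourses,
smooth Ornstein–Uhlenbeck jitter of blob centres and widths (spatial
dynamics), additive scan noise, and injectable group effects (per-network
amplitude scaling, per-network jitter scaling, per-domain-pair coupling
shifts).  Every other module is validated against this ground truth.

## Worked example

```bash
cat > study.yaml <<'YAML'
study:
  preset: tiny          # 4 networks, 16^3 grid, T=8, 2+2 subjects
  seed: 4
train: {learning_rate: 0.001, max_epochs: 2, patience: 2}
window: {window_length: 4, overlap: 2}
state_k_candidates: [2, 3]
seed: 4
YAML
parc5d run-all --config study.yaml --output out
```

which logs the five stages and finishes with

```
study complete: out
```

leaving `out/study/` (scans, ground truth, manifest), `out/models/`
(one checkpoint + loss history per network), `out/maps/` (per-subject 4D
score maps), `out/stats/` (group mean/deviation/difference/t maps, peak
tables) and `out/fnc/` (per-subject sFNC matrices, group t and FDR masks,
states.json, occupancy.csv).  Re-running the same command skips every
completed stage.

The architecture accounting is available directly:

```bash
$ parc5d param-table
Layer (type)    Output shape    Param # Tr.Param#
Conv3d-1        [5, 64, 51, 61, 50]     1,792   1,792
Sigmoid-2       [5, 64, 51, 61, 50]     0       0
ResEncBlocks-3  [5, 32, 47, 57, 46]     110,880 110,880
ResEncBlocks-4  [5, 16, 43, 53, 42]     27,792  27,792
ResEncBlocks-5  [5, 8, 39, 49, 38]      6,984   6,984
Dropout3d-6     [5, 8, 39, 49, 38]      0       0
ResDecBlocks-7  [5, 16, 43, 53, 42]     10,464  10,464
ResDecBlocks-8  [5, 32, 47, 57, 46]     41,664  41,664
Dropout3d-9     [5, 32, 47, 57, 46]     0       0
ResDecBlocks-10 [5, 64, 51, 61, 50]     166,272 166,272
ConvTranspose3d-11      [5, 1, 53, 63, 52]      1,729   1,729
Sigmoid-12      [5, 1, 53, 63, 52]      0       0
Total params: 367,577
Trainable params: 367,577
```

Each row is (layer/block, output shape for a batch of 5, parameters,
trainable parameters); the encoder/decoder block rows aggregate their
convolutions and normalization layers.

## Layout

- `src/parc5d/nn.py` — numpy 3D conv layers with backward passes; Adam.
- `src/parc5d/model.py` — the residual parcellation model, parameter
  accounting, per-subject 5D prediction, checkpoints.
- `src/parc5d/training.py` — datasets, normalization, training loop,
  ablation scenarios.
- `src/parc5d/synthetic.py` — the ground-truth study generator.
- `src/parc5d/spatiodynamics.py` — voxel-wise maps and group inference.
- `src/parc5d/fnc.py` — sFNC/dFNC, states, occupancy, FDR contrasts.
- `src/parc5d/pipeline.py`, `cli.py` — staged pipeline and `parc5d` CLI.
- `docs/methods.md` — modelling and design notes.
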