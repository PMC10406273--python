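"""Supervised training of one parcellation model per network.

Volume-based feeding: every (subject, timepoint) pair contributes one
sample -- the min-max normalized 3D scan volume at that timepoint as
input, and the network's spatial map as regression target.  Training
minimizes mean squared error with Adam; the learning rate decays by a
factor gamma every ``step_size`` epochs, early stopping watches the
validation loss, and the best-validation checkpoint is returned.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .model import ModelSpec, ResidualParcellation3D
from .nn import Adam, step_lr

__all__ = [
    "TrainConfig", "VolumeSample", "minmax_normalize",
    "make_volume_dataset", "train_model", "evaluate_mse",
    "ablation_variants", "TrainingDiverged",
]


class TrainingDiverged(RuntimeError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters.

    The defaults are the framework's reference recipe (MSE loss, Adam at 1e-5 with
    a learning-rate step every 5 epochs, up to 200 epochs, batches of 5,
    min-max input normalization); reduced-scale runs typically raise the
    learning rate and cut ``max_epochs``.
    """

    learning_rate: float = 1e-5
    lr_step_size: int = 5
    lr_gamma: float = 0.9
    max_epochs: int = 200
    patience: int = 10
    min_delta: float = 0.0
    batch_size: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not 0 < self.lr_gamma <= 1:
            raise ValueError("lr_gamma must be in (0, 1]")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class VolumeSample:
    """One training sample: a normalized scan timepoint and the target
    spatial map of a single network."""

    x: np.ndarray       # 3D input volume
    y: np.ndarray       # 3D target map
    subject_id: str = ""
    timepoint: int = 0

    def __post_init__(self):
        if self.x.shape != self.y.shape:
            raise ValueError(
                f"input {self.x.shape} and target {self.y.shape} differ")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("non-finite values in sample")


def minmax_normalize(volume: np.ndarray) -> np.ndarray:
    """Affine rescale to [0, 1]; a constant volume maps to all zeros."""
    volume = np.asarray(volume)
    if not np.all(np.isfinite(volume)):
        raise ValueError("volume contains NaN or Inf")
    lo = volume.min()
    span = volume.max() - lo
    if span == 0:
        return np.zeros_like(volume, dtype=np.float32)
    return ((volume - lo) / span).astype(np.float32)


def make_volume_dataset(subjects, network_id: int,
                        val_fraction: float = 0.25, seed: int = 0):
    """Split subjects (not timepoints, to avoid leakage) into train and
    validation sets of VolumeSample.

    ``subjects`` is a sequence of (volume_4d, GroundTruthSubject); the
    target for network k at timepoint t is the subject's true score-map
    frame.  Inputs are min-max normalized per volume (timepoint).
    """
    subjects = list(subjects)
    if not subjects:
        raise ValueError("no subjects given")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    n_val = int(round(val_fraction * len(subjects)))
    if n_val == 0 or n_val == len(subjects):
        raise ValueError(
            f"val_fraction={val_fraction} gives an empty split for "
            f"{len(subjects)} subjects")
    val_idx = set(order[:n_val].tolist())

    def samples(indices):
        out = []
        for i in indices:
            volume, subject = subjects[i]
            omega = subject.score_maps[network_id - 1]
            for t in range(volume.shape[-1]):
                out.append(VolumeSample(
                    x=minmax_normalize(volume[..., t]),
                    y=omega[..., t].astype(np.float32),
                    subject_id=subject.subject_id, timepoint=t))
        return out

    train = samples([i for i in range(len(subjects)) if i not in val_idx])
    val = samples(sorted(val_idx))
    return train, val


def _batches(samples, batch_size, rng=None):
    idx = np.arange(len(samples))
    if rng is not None:
        rng.shuffle(idx)
    for start in range(0, len(idx), batch_size):
        chunk = idx[start:start + batch_size]
        x = np.stack([samples[i].x for i in chunk])[:, None]
        y = np.stack([samples[i].y for i in chunk])[:, None]
        yield x, y


def evaluate_mse(model: ResidualParcellation3D, samples,
                 batch_size: int = 5) -> float:
    """Mean squared error over all samples and voxels, evaluation mode."""
    if not samples:
        raise ValueError("empty dataset")
    total, count = 0.0, 0
    for x, y in _batches(samples, batch_size):
        pred = model.forward(x, training=False)
        total += float(((pred - y) ** 2).sum())
        count += y.size
    return total / count


def recalibrate_batchnorm(model: ResidualParcellation3D, samples,
                          batch_size: int = 5) -> None:
    """Re-estimate batch-norm running statistics with the current weights
    (dropout off), replacing the stale exponential averages accumulated
    while the weights were still moving."""
    from .nn import BatchNorm3d
    bns = [lyr for lyr in model._layers() if isinstance(lyr, BatchNorm3d)]
    if not bns:
        return
    for bn in bns:
        bn.calibrating = True
        bn._calib_count = 0
    try:
        for x, _ in _batches(samples, batch_size):
            model.forward(x, training=False)
    finally:
        for bn in bns:
            bn.calibrating = False


def train_model(model: ResidualParcellation3D, train_set, val_set,
                cfg: TrainConfig):
    """Run the training loop; returns (model, history).

    ``history`` is a list of dicts (epoch, train_mse, val_mse, lr).  The
    model is left holding the weights of the epoch with the best
    validation loss; training stops early once the validation loss has
    failed to improve by ``min_delta`` for ``patience`` epochs.
    """
    if not train_set or not val_set:
        raise ValueError("train and validation sets must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.param_handles(), lr=cfg.learning_rate)
    history = []
    best_val = np.inf
    best_state = model.state_dict()
    stale = 0
    for epoch in range(cfg.max_epochs):
        lr = step_lr(cfg.learning_rate, epoch, cfg.lr_step_size, cfg.lr_gamma)
        opt.lr = lr
        total, count = 0.0, 0
        for x, y in _batches(train_set, cfg.batch_size, rng):
            pred = model.forward(x, training=True)
            err = pred - y
            loss = float((err ** 2).mean())
            if not np.isfinite(loss):
                raise TrainingDiverged(
                    f"loss became non-finite at epoch {epoch + 1}")
            opt.zero_grad()
            model.backward((2.0 / err.size) * err)
            opt.step()
            total += loss * err.size
            count += err.size
        recalibrate_batchnorm(model, train_set, cfg.batch_size)
        val_mse = evaluate_mse(model, val_set, cfg.batch_size)
        history.append({"epoch": epoch + 1, "train_mse": total / count,
                        "val_mse": val_mse, "lr": lr})
        if val_mse < best_val - cfg.min_delta:
            best_val = val_mse
            best_state = model.state_dict()
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                break
    model.load_state_dict(best_state)
    return model, history


def ablation_variants(spec: ModelSpec, scenario: str) -> ModelSpec:
    """Architecture-ablation scenarios.

    - ``original``: unchanged.
    - ``S1``: instance normalization substituted for batch normalization.
    - ``S2``: instance norm, one convolution removed from the first
      encoder block (its remaining convolutions padded so the block only
      shrinks by the pool) and one transposed convolution removed from
      the mirrored last decoder block.
    - ``S3``: instance norm, one shape-preserving convolution added to
      the first encoder block and one shape-preserving transposed
      convolution added to the last decoder block.

    All variants keep the skip-connection geometry intact and train with
    the same loop.
    """
    if scenario == "original":
        return spec
    if scenario == "S1":
        return replace(spec, norm="instance")
    if scenario == "S2":
        enc = (spec.encoder_convs[0] - 1,) + spec.encoder_convs[1:]
        dec = spec.decoder_tconvs[:-1] + (spec.decoder_tconvs[-1] - 1,)
        unpadded = (False,) + spec.encoder_unpadded[1:]
        return replace(spec, norm="instance", encoder_convs=enc,
                       decoder_tconvs=dec, encoder_unpadded=unpadded)
    if scenario == "S3":
        enc = (spec.encoder_convs[0] + 1,) + spec.encoder_convs[1:]
        dec = spec.decoder_tconvs[:-1] + (spec.decoder_tconvs[-1] + 1,)
        return replace(spec, norm="instance", encoder_convs=enc,
                       decoder_tconvs=dec)
    raise ValueError(f"unknown ablation scenario {scenario!r}")
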