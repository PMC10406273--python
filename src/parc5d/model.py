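"""Residual U-Net-style 3D regressor mapping one fMRI volume to one
network's probabilistic score volume.

The default architecture: an unpadded 3^3 stem convolution 1->64 with a
sigmoid, three encoder blocks (64->32->16->8; three 3^3 convolutions each
followed by batch normalization, then a max pool with kernel 3 and stride
1), dropout 0.5, three decoder blocks (8->16, 16->32, 32->64; two unpadded
3^3 transposed convolutions each followed by batch normalization, dropout
after the second block), a final unpadded transposed convolution 64->1 and
a sigmoid.  Parameter-free additive skip connections join the stem output
and each encoder-block output to the decoder activation with the identical
channel-and-spatial shape.

Inside each encoder block exactly one convolution (the first) is unpadded
and the pool contributes another shrink of 2, so each block shrinks every
spatial dimension by 4; each decoder block grows it by 4.  For the default
53x63x52 grid the spatial chain is 51.61.50 -> 47.57.46 -> 43.53.42 ->
39.49.38 -> 43.53.42 -> 47.57.46 -> 51.61.50 -> 53.63.52, and the model
carries 367,577 trainable parameters.

One such model is trained per brain network; K of them turn a 4D scan into
a 5D set of spatiotemporal network maps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .nn import (Adam, BatchNorm3d, Conv3d, ConvTranspose3d, Dropout3d,
                 InstanceNorm3d, Layer, MaxPool3d, Sigmoid,
                 SpatialUnderflowError)

__all__ = [
    "ModelSpec", "ParamSummary", "ResidualParcellation3D",
    "build_model", "summarize_parameters", "forward_volume",
    "predict_subject", "save_checkpoint", "load_checkpoint",
    "SpatialUnderflowError",
]


@dataclass(frozen=True)
class ModelSpec:
    """Architecture hyperparameters of the residual parcellation model.

    ``encoder_convs``/``decoder_tconvs`` give the number of (transposed)
    convolutions per block; inside an encoder block the first convolution
    is unpadded when ``encoder_unpadded`` says so and the rest are padded,
    while a decoder block's first two transposed convolutions are unpadded
    and any extras are shape-preserving.  ``norm`` selects batch or
    instance normalization (the latter used by the ablation scenarios).
    """

    in_channels: int = 1
    stem_channels: int = 64
    encoder_channels: tuple[int, ...] = (32, 16, 8)
    decoder_channels: tuple[int, ...] = (16, 32, 64)
    kernel_size: int = 3
    encoder_convs: tuple[int, ...] = (3, 3, 3)
    decoder_tconvs: tuple[int, ...] = (2, 2, 2)
    encoder_unpadded: tuple[bool, ...] = (True, True, True)
    pool_kernel: int = 3
    dropout_rate: float = 0.5
    norm: str = "batch"
    final_out_channels: int = 1
    batch_size_default: int = 5

    def __post_init__(self):
        enc, dec = self.encoder_channels, self.decoder_channels
        if any(a <= b for a, b in zip(enc, enc[1:])):
            raise ValueError("encoder channels must be strictly decreasing")
        if any(a >= b for a, b in zip(dec, dec[1:])):
            raise ValueError("decoder channels must be strictly increasing")
        if tuple(reversed(dec)) != (self.stem_channels,) + enc[:-1]:
            raise ValueError("decoder widths must mirror the encoder")
        if self.norm not in ("batch", "instance"):
            raise ValueError(f"unknown norm {self.norm!r}")


@dataclass
class ParamSummary:
    """Layer/block-level parameter accounting, mirroring a model summary
    table: (layer name, output shape, parameters, trainable parameters)."""

    rows: list[tuple[str, tuple[int, ...], int, int]] = field(
        default_factory=list)
    total: int = 0
    total_trainable: int = 0

    def to_tsv(self) -> str:
        lines = ["Layer (type)\tOutput shape\tParam #\tTr.Param#"]
        for name, shape, p, tp in self.rows:
            lines.append(f"{name}\t{list(shape)}\t{p:,}\t{tp:,}")
        lines.append(f"Total params: {self.total:,}")
        lines.append(f"Trainable params: {self.total_trainable:,}")
        return "\n".join(lines)


class _EncBlock:
    """n convolutions (first optionally unpadded) each followed by a norm,
    then max pooling."""

    def __init__(self, c_in, c_out, spec: ModelSpec, idx: int,
                 rng: np.random.Generator):
        k = spec.kernel_size
        n = spec.encoder_convs[idx]
        pad_first = 0 if spec.encoder_unpadded[idx] else (k - 1) // 2
        self.layers: list[Layer] = []
        c = c_in
        for i in range(n):
            pad = pad_first if i == 0 else (k - 1) // 2
            self.layers.append(Conv3d(c, c_out, k, padding=pad, rng=rng,
                                      name=f"Conv3d(enc{idx + 1}.{i + 1})"))
            self.layers.append(_make_norm(spec, c_out))
            c = c_out
        self.layers.append(MaxPool3d(spec.pool_kernel,
                                     name=f"MaxPool3d(enc{idx + 1})"))

    def forward(self, x, training):
        for lyr in self.layers:
            x = lyr.forward(x, training)
        return x

    def backward(self, dy):
        for lyr in reversed(self.layers):
            dy = lyr.backward(dy)
        return dy

    def out_dims(self, dims):
        for lyr in self.layers:
            dims = lyr.out_dims(dims)
        return dims

    def n_params(self):
        return sum(lyr.n_params() for lyr in self.layers)


class _DecBlock:
    """n transposed convolutions (first two unpadded, extras shape-
    preserving) each followed by a norm."""

    def __init__(self, c_in, c_out, spec: ModelSpec, idx: int,
                 rng: np.random.Generator):
        k = spec.kernel_size
        n = spec.decoder_tconvs[idx]
        self.layers: list[Layer] = []
        c = c_in
        for i in range(n):
            pad = 0 if i < 2 else (k - 1) // 2
            self.layers.append(
                ConvTranspose3d(c, c_out, k, padding=pad, rng=rng,
                                name=f"ConvTranspose3d(dec{idx + 1}.{i + 1})"))
            self.layers.append(_make_norm(spec, c_out))
            c = c_out

    forward = _EncBlock.forward
    backward = _EncBlock.backward
    out_dims = _EncBlock.out_dims
    n_params = _EncBlock.n_params


def _make_norm(spec: ModelSpec, c: int) -> Layer:
    if spec.norm == "instance":
        return InstanceNorm3d(c)
    return BatchNorm3d(c)


class ResidualParcellation3D:
    """The full residual encoder/decoder regressor for one brain network.

    ``forward``/``backward`` operate on float32 batches shaped
    (N, 1, D, H, W); additive skips connect stem->decoder-3 output,
    encoder-1->decoder-2 output and encoder-2->decoder-1 output.
    """

    def __init__(self, spec: ModelSpec, input_dims: tuple[int, int, int],
                 seed: int = 0):
        self.spec = spec
        self.input_dims = tuple(int(d) for d in input_dims)
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5D]))
        self._dropout_rng = np.random.default_rng(
            np.random.SeedSequence([seed, 0xD0]))
        k = spec.kernel_size
        self.stem = Conv3d(spec.in_channels, spec.stem_channels, k,
                           padding=0, rng=rng, name="Conv3d(stem)")
        self.stem_act = Sigmoid(name="Sigmoid(stem)")
        chans = (spec.stem_channels,) + spec.encoder_channels
        self.enc_blocks = [
            _EncBlock(chans[i], chans[i + 1], spec, i, rng)
            for i in range(len(spec.encoder_channels))
        ]
        self.drop_enc = Dropout3d(spec.dropout_rate, rng=self._dropout_rng,
                                  name="Dropout3d(enc)")
        dchans = (spec.encoder_channels[-1],) + spec.decoder_channels
        self.dec_blocks = [
            _DecBlock(dchans[i], dchans[i + 1], spec, i, rng)
            for i in range(len(spec.decoder_channels))
        ]
        self.drop_dec = Dropout3d(spec.dropout_rate, rng=self._dropout_rng,
                                  name="Dropout3d(dec)")
        self.final = ConvTranspose3d(spec.decoder_channels[-1],
                                     spec.final_out_channels, k, padding=0,
                                     rng=rng, name="ConvTranspose3d(out)")
        self.out_act = Sigmoid(name="Sigmoid(out)")
        self._check_shapes()

    # -- shape accounting ------------------------------------------------
    def shape_chain(self) -> list[tuple[int, ...]]:
        """Spatial dims after the stem, each encoder block, each decoder
        block and the final transposed convolution."""
        dims = self.input_dims
        chain = []
        dims = self.stem.out_dims(dims)
        chain.append(dims)
        for blk in self.enc_blocks:
            dims = blk.out_dims(dims)
            chain.append(dims)
        for blk in self.dec_blocks:
            dims = blk.out_dims(dims)
            chain.append(dims)
        dims = self.final.out_dims(dims)
        chain.append(dims)
        return chain

    def _check_shapes(self):
        chain = self.shape_chain()
        n_enc = len(self.enc_blocks)
        if chain[-1] != self.input_dims:
            raise SpatialUnderflowError(
                f"output dims {chain[-1]} do not recover input "
                f"{self.input_dims}; skip connections cannot align")
        # skip pairs: stem<->last decoder, enc i<->decoder n-1-i (i<n-1)
        if chain[0] != chain[-2]:
            raise SpatialUnderflowError(
                "stem and last decoder block shapes differ: "
                f"{chain[0]} vs {chain[-2]}")
        for i in range(n_enc - 1):
            enc_shape = chain[1 + i]
            dec_shape = chain[n_enc + (n_enc - 2 - i) + 1]
            if enc_shape != dec_shape:
                raise SpatialUnderflowError(
                    f"skip mismatch: encoder block {i + 1} {enc_shape} vs "
                    f"decoder block {n_enc - 1 - i} {dec_shape}")

    # -- forward / backward ---------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.ndim == 4:
            x = x[:, None]
        if x.shape[2:] != self.input_dims:
            raise ValueError(
                f"expected spatial dims {self.input_dims}, got {x.shape[2:]}")
        x = np.ascontiguousarray(x, dtype=np.float32)
        s = self.stem_act.forward(self.stem.forward(x, training), training)
        e = [s]
        h = s
        for blk in self.enc_blocks:
            h = blk.forward(h, training)
            e.append(h)
        h = self.drop_enc.forward(h, training)
        n = len(self.dec_blocks)
        for i, blk in enumerate(self.dec_blocks):
            h = blk.forward(h, training)
            if i == 1:
                h = self.drop_dec.forward(h, training)
            h = h + e[n - 1 - i]  # additive parameter-free skip
        y = self.final.forward(h, training)
        return self.out_act.forward(y, training)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = self.final.backward(self.out_act.backward(dy))
        n = len(self.dec_blocks)
        skip_grads = [None] * (n + 1)  # grads flowing back into e[0..n]
        for i in reversed(range(n)):
            skip_grads[n - 1 - i] = dy
            if i == 1:
                dy = self.drop_dec.backward(dy)
            dy = self.dec_blocks[i].backward(dy)
        dy = self.drop_enc.backward(dy)
        for i in reversed(range(len(self.enc_blocks))):
            g = skip_grads[i + 1]
            if g is not None:
                dy = dy + g
            dy = self.enc_blocks[i].backward(dy)
        g = skip_grads[0]
        if g is not None:
            dy = dy + g
        dy = self.stem.backward(self.stem_act.backward(dy))
        return dy

    # -- parameters ------------------------------------------------------
    def _layers(self) -> list[Layer]:
        out = [self.stem, self.stem_act]
        for blk in self.enc_blocks:
            out.extend(blk.layers)
        out.append(self.drop_enc)
        for i, blk in enumerate(self.dec_blocks):
            out.extend(blk.layers)
            if i == 1:
                out.append(self.drop_dec)
        out.extend([self.final, self.out_act])
        return out

    def param_handles(self):
        return [(lyr, name) for lyr in self._layers()
                for name in lyr.params]

    def n_params(self) -> int:
        return sum(lyr.n_params() for lyr in self._layers())

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for i, lyr in enumerate(self._layers()):
            for name, arr in lyr.params.items():
                state[f"{i}.{name}"] = arr.copy()
            if isinstance(lyr, BatchNorm3d):
                state[f"{i}.running_mean"] = lyr.running_mean.copy()
                state[f"{i}.running_var"] = lyr.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for i, lyr in enumerate(self._layers()):
            for name in lyr.params:
                lyr.params[name] = state[f"{i}.{name}"].copy()
            if isinstance(lyr, BatchNorm3d):
                lyr.running_mean = state[f"{i}.running_mean"].copy()
                lyr.running_var = state[f"{i}.running_var"].copy()


# ---------------------------------------------------------------------------

def build_model(spec: ModelSpec, input_dims: tuple[int, int, int],
                seed: int = 0) -> ResidualParcellation3D:
    """Instantiate the regressor, validating that every layer keeps a
    positive spatial extent and that all skip shapes align."""
    return ResidualParcellation3D(spec, input_dims, seed=seed)


def summarize_parameters(model: ResidualParcellation3D,
                         batch: int | None = None) -> ParamSummary:
    """Per-row parameter accounting in model-summary style: stem conv and
    sigmoid, one aggregated row per encoder/decoder block, the dropout
    layers, the output transposed convolution and sigmoid."""
    spec = model.spec
    batch = spec.batch_size_default if batch is None else batch
    chain = model.shape_chain()
    n_enc = len(model.enc_blocks)
    summary = ParamSummary()
    idx = 0

    def row(name_base, shape_sp, c, count):
        nonlocal idx
        idx += 1
        shape = (batch, c) + tuple(shape_sp)
        summary.rows.append((f"{name_base}-{idx}", shape, count, count))

    row("Conv3d", chain[0], spec.stem_channels, model.stem.n_params())
    row("Sigmoid", chain[0], spec.stem_channels, 0)
    for i, blk in enumerate(model.enc_blocks):
        row("ResEncBlocks", chain[1 + i], spec.encoder_channels[i],
            blk.n_params())
    row("Dropout3d", chain[n_enc], spec.encoder_channels[-1], 0)
    for i, blk in enumerate(model.dec_blocks):
        row("ResDecBlocks", chain[n_enc + 1 + i], spec.decoder_channels[i],
            blk.n_params())
        if i == 1:
            row("Dropout3d", chain[n_enc + 1 + i],
                spec.decoder_channels[i], 0)
    row("ConvTranspose3d", chain[-1], spec.final_out_channels,
        model.final.n_params())
    row("Sigmoid", chain[-1], spec.final_out_channels, 0)
    summary.total = sum(r[2] for r in summary.rows)
    summary.total_trainable = sum(r[3] for r in summary.rows)
    return summary


def forward_volume(model: ResidualParcellation3D,
                   batch: np.ndarray) -> np.ndarray:
    """Evaluation-mode forward pass over a batch of 3D volumes.

    Accepts (N, D, H, W) or (N, 1, D, H, W); returns (N, 1, D, H, W) score
    volumes in [0, 1].  Deterministic: dropout off, normalization uses
    running statistics.
    """
    batch = np.asarray(batch)
    if not np.all(np.isfinite(batch)):
        raise ValueError("input batch contains non-finite values")
    return model.forward(batch, training=False)


def predict_subject(models, volume: np.ndarray,
                    normalize: bool = True) -> list[np.ndarray]:
    """Apply one model per network to every timepoint of a 4D scan.

    ``volume`` is (D, H, W, T); returns K arrays of the same shape (the
    subject's spatiotemporal network score maps).  Each timepoint volume
    is min-max normalized by default, matching the training feed.
    """
    volume = np.asarray(volume)
    dims = tuple(volume.shape[:3])
    frames = np.moveaxis(volume, -1, 0)  # (T, D, H, W)
    if normalize:
        from .training import minmax_normalize
        frames = np.stack([minmax_normalize(f) for f in frames])
    maps = []
    for k, model in enumerate(models):
        if model.input_dims != dims:
            raise ValueError(
                f"model for network {k + 1} expects {model.input_dims}, "
                f"scan grid is {dims}")
        out = forward_volume(model, frames)[:, 0]
        maps.append(np.moveaxis(out, 0, -1))
    return maps


def save_checkpoint(model: ResidualParcellation3D, path, network_id=None):
    """Write weights (.npz) plus a JSON sidecar with the spec and grid."""
    path = Path(path)
    np.savez(path, **model.state_dict())
    sidecar = {
        "spec": {k: list(v) if isinstance(v, tuple) else v
                 for k, v in asdict(model.spec).items()},
        "input_dims": list(model.input_dims),
        "network_id": network_id,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_checkpoint(path) -> ResidualParcellation3D:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    raw = sidecar["spec"]
    raw = {k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()}
    spec = ModelSpec(**raw)
    model = ResidualParcellation3D(spec, tuple(sidecar["input_dims"]))
    npz = path if path.suffix == ".npz" else path.with_suffix(".npz")
    with np.load(npz) as data:
        model.load_state_dict(dict(data))
    return model
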