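"""3-D fully-convolutional electromagnetic reconstruction network.

Maps the aggregated scattered-field vector (2 channels x M values: real
and imaginary parts) to one block of the discretized relative-permittivity
and conductivity volume.  The full output volume is evenly partitioned
into N disjoint cubic blocks; each block has its own independently trained
sub-model, with no information exchange between sub-models.

Architecture: an eight-layer 1-D convolutional encoder (channels
32, 32, 64, 64, 128, 128, 256, 256; down-sampling strides 2, 4, 2, 4 at
layers 1, 3, 5, 7 replacing pooling), a reshape to a small cubic
256-channel feature map, three 3-D transposed-convolution decoder layers
(128, 64, 32 kernels) and a 2-channel transposed-convolution
reconstruction head.  Encoder convolutions carry batch normalization and
ReLU; decoder deconvolutions use plain ReLU and the head is linear (its
outputs are clamped to physical ranges after denormalization).  There are
no fully connected layers, so the parameter count is independent of the
output resolution except through the decoder/head shapes.

The fixed kernel/stride menu cannot close the shape arithmetic for every
input length on its own, so the builder solves the padding of the final
strided layer and the size of the final length-adapting kernel at build
time and validates the whole shape trace; the trace is attached to the
model for inspection.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import yaml

from .nn import Adam, BatchNorm, ConvNd, ConvTransposeNd, ReLU, Reshape, Sequential, mse_loss, param_count


@dataclass
class FcernnSpec:
    """Architecture hyperparameters of one block sub-model."""

    input_len: int = 360  # 2 x M
    encoder_channels: tuple[int, ...] = (32, 32, 64, 64, 128, 128, 256, 256)
    encoder_kernels: tuple[int, ...] = (2, 2, 2, 2, 2, 2, 4, 1)
    encoder_strides: tuple[int, ...] = (2, 1, 4, 1, 2, 1, 4, 1)
    decoder_channels: tuple[int, ...] = (128, 64, 32)
    head_channels: int = 2
    reshape_side: int = 2  # cubic feature-map side after the encoder
    block_shape: tuple[int, int, int] = (8, 8, 8)
    bn_chi: float = 1e-3

    @property
    def m(self) -> int:
        return self.input_len // 2


class ShapeError(ValueError):
    """Raised when the architecture arithmetic cannot be closed; carries
    the full shape trace."""


def _conv_len(L: int, k: int, s: int, p: int) -> int:
    return (L + 2 * p - k) // s + 1


def solve_encoder_shapes(spec: FcernnSpec):
    """Solve per-layer paddings and the final length-adapting kernel so the
    encoder output reshapes exactly to ``reshape_side^3`` positions.

    Returns (kernels, paddings, lengths, trace_lines).
    """
    target = spec.reshape_side**3
    nL = len(spec.encoder_channels)
    kernels = list(spec.encoder_kernels)
    pads = [0] * nL
    trace = [f"input: 2 x {spec.m}"]

    def run(upto: int) -> list[int]:
        lengths = [spec.m]
        for i in range(upto):
            lengths.append(_conv_len(lengths[-1], kernels[i], spec.encoder_strides[i], pads[i]))
        return lengths

    # pad the final strided layer minimally until the tail can reach target
    last_strided = max(i for i, s in enumerate(spec.encoder_strides) if s > 1)
    for p in range(0, 4 * target + 8):
        pads[last_strided] = p
        lengths = run(nL - 1)
        if lengths[-1] >= target and min(lengths) >= 1:
            break
    else:
        raise ShapeError(
            "cannot reach the reshape target; trace: "
            + " -> ".join(str(x) for x in run(nL - 1))
        )
    # final layer: length-adapting kernel (stride must be 1)
    kernels[-1] = lengths[-1] - target + 1
    lengths.append(target)
    for i in range(nL):
        trace.append(
            f"conv1d k={kernels[i]} s={spec.encoder_strides[i]} p={pads[i]} "
            f"ch={spec.encoder_channels[i]}: len {lengths[i]} -> {lengths[i + 1]}"
        )
    trace.append(
        f"reshape: ({lengths[-1]} x 1) x {spec.encoder_channels[-1]} -> "
        f"{spec.reshape_side}^3 x {spec.encoder_channels[-1]}"
    )
    return kernels, pads, lengths, trace


def solve_decoder_shapes(spec: FcernnSpec):
    """Choose per-axis deconvolution strides and the head kernel so the
    decoder output tiles ``block_shape`` exactly."""
    sides = [spec.reshape_side] * 3
    layer_params = []
    trace = []
    for li, ch in enumerate(spec.decoder_channels):
        strides = []
        for d in range(3):
            strides.append(2 if sides[d] * 2 <= spec.block_shape[d] else 1)
        kern = tuple(4 if s == 2 else 3 for s in strides)
        pad = (1, 1, 1)
        new = tuple(sides[d] * strides[d] for d in range(3))
        layer_params.append((ch, kern, tuple(strides), pad))
        trace.append(f"deconv3d k={kern} s={tuple(strides)} ch={ch}: {tuple(sides)} -> {new}")
        sides = list(new)
    head_k = tuple(spec.block_shape[d] - sides[d] + 1 for d in range(3))
    if any(k < 1 for k in head_k):
        raise ShapeError(
            f"decoder overshoots the block: reached {tuple(sides)} for block "
            f"{spec.block_shape}; trace: " + "; ".join(trace)
        )
    trace.append(
        f"head deconv3d k={head_k} s=1 ch={spec.head_channels}: "
        f"{tuple(sides)} -> {spec.block_shape}"
    )
    return layer_params, head_k, trace


class Fcernn:
    """One block sub-model: Sequential net plus its shape trace."""

    def __init__(self, spec: FcernnSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        kernels, pads, lengths, enc_trace = solve_encoder_shapes(spec)
        layers = []
        cin = 2
        for i, cout in enumerate(spec.encoder_channels):
            layers += [
                ConvNd(cin, cout, kernels[i], stride=spec.encoder_strides[i],
                       pad=pads[i], ndim=1, rng=rng),
                BatchNorm(cout, chi=spec.bn_chi),
                ReLU(),
            ]
            cin = cout
        c = spec.reshape_side
        layers.append(Reshape((spec.encoder_channels[-1], c, c, c)))
        # batch normalization stabilizes the encoder; the decoder and the
        # reconstruction head regress continuous property values, so they
        # use plain ReLU deconvolutions and a linear head (the physical
        # clamp is applied after denormalization)
        dec_params, head_k, dec_trace = solve_decoder_shapes(spec)
        for ch, kern, strides, pad in dec_params:
            layers += [
                ConvTransposeNd(cin, ch, kern, stride=strides, pad=pad, ndim=3, rng=rng),
                ReLU(),
            ]
            cin = ch
        layers.append(
            ConvTransposeNd(cin, spec.head_channels, head_k, stride=1, pad=0, ndim=3, rng=rng)
        )
        self.net = Sequential(*layers)
        self.shape_trace = enc_trace + dec_trace
        # validate by a dry run
        probe = np.zeros((2, 2, spec.m), dtype=np.float32)
        out = self.net.forward(probe, train=False)
        if out.shape[1:] != (spec.head_channels, *spec.block_shape):
            raise ShapeError(
                f"built model yields {out.shape[1:]}, expected "
                f"({spec.head_channels}, {spec.block_shape}); trace:\n"
                + "\n".join(self.shape_trace)
            )

    @property
    def n_params(self) -> int:
        return param_count(self.net)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        return self.net.forward(x, train)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return self.net.backward(g)

    def params(self):
        return self.net.params()

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Eval-mode forward pass; x: (B, 2, M) -> (B, 2, *block)."""
        return self.net.forward(np.asarray(x, dtype=np.float32), train=False)


def build_fcernn(spec: FcernnSpec | None = None, seed: int = 0) -> Fcernn:
    """Build one block sub-model; raises :class:`ShapeError` with the full
    shape trace if the architecture arithmetic cannot be closed."""
    return Fcernn(spec or FcernnSpec(), seed=seed)


# ---------------------------------------------------------------------------
# block partition


def partition_volume(full_shape: tuple[int, int, int], n_blocks: int):
    """Evenly partition a volume into ``n_blocks`` disjoint axis-aligned
    boxes (N must be a perfect cube whose root divides each axis).

    Returns a lexicographically ordered list of
    ``((x0, x1), (y0, y1), (z0, z1))`` half-open index ranges.
    """
    m = round(n_blocks ** (1.0 / 3.0))
    if m**3 != n_blocks:
        raise ValueError(f"n_blocks must be a perfect cube, got {n_blocks}")
    for a in full_shape:
        if a % m != 0:
            raise ValueError(
                f"axis size {a} not divisible by cube root {m} of n_blocks"
            )
    steps = [a // m for a in full_shape]
    boxes = []
    for ix in range(m):
        for iy in range(m):
            for iz in range(m):
                boxes.append(
                    (
                        (ix * steps[0], (ix + 1) * steps[0]),
                        (iy * steps[1], (iy + 1) * steps[1]),
                        (iz * steps[2], (iz + 1) * steps[2]),
                    )
                )
    return boxes


# ---------------------------------------------------------------------------
# normalization statistics


@dataclass
class NormStats:
    """Normalization statistics, computed on the training split only.

    Targets (eps_r, sigma) are min-max scaled per channel to [0, 1];
    inputs are standardized per element with a shared scale floor.
    """

    target_min: np.ndarray  # (2,)
    target_max: np.ndarray  # (2,)
    input_mean: np.ndarray  # (2M,)
    input_scale: float

    def __post_init__(self):
        if np.any(self.target_max <= self.target_min):
            raise ValueError("target_max must exceed target_min per channel")

    @classmethod
    def from_training(cls, inputs: np.ndarray, eps: np.ndarray, sigma: np.ndarray):
        tmin = np.array([eps.min(), sigma.min()], dtype=np.float64)
        tmax = np.array([eps.max(), sigma.max()], dtype=np.float64)
        mean = inputs.mean(axis=0)
        scale = float(inputs.std())
        if scale == 0:
            scale = 1.0
        return cls(target_min=tmin, target_max=tmax, input_mean=mean, input_scale=scale)

    def normalize_inputs(self, vec: np.ndarray) -> np.ndarray:
        """(..., 2M) raw input vectors -> (..., 2, M) standardized tensor."""
        v = (np.asarray(vec) - self.input_mean) / self.input_scale
        m = v.shape[-1] // 2
        return v.reshape(*v.shape[:-1], 2, m).astype(np.float32)

    def normalize_targets(self, eps: np.ndarray, sigma: np.ndarray) -> np.ndarray:
        """Stack and scale (eps, sigma) volumes to a (2, ...) tensor in [0, 1]."""
        e = (eps - self.target_min[0]) / (self.target_max[0] - self.target_min[0])
        s = (sigma - self.target_min[1]) / (self.target_max[1] - self.target_min[1])
        return np.stack([e, s])

    def denormalize(self, vol2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Inverse of :meth:`normalize_targets` (no clamping)."""
        e = vol2[0] * (self.target_max[0] - self.target_min[0]) + self.target_min[0]
        s = vol2[1] * (self.target_max[1] - self.target_min[1]) + self.target_min[1]
        return np.asarray(e, dtype=np.float64), np.asarray(s, dtype=np.float64)


# ---------------------------------------------------------------------------
# training and prediction


@dataclass
class TrainConfig:
    epochs: int = 100
    batch_size: int = 16
    lr: float = 1e-3


def train_fcernn(
    models: list[Fcernn],
    blocks,
    inputs: np.ndarray,
    eps: np.ndarray,
    sigma: np.ndarray,
    stats: NormStats,
    cfg: TrainConfig | None = None,
    seed: int = 0,
    verbose: bool = False,
) -> list[list[float]]:
    """Train each block's sub-model independently by MSE on its block of
    the normalized property volumes.

    ``inputs``: (S, 2M) raw aggregated vectors; ``eps``/``sigma``:
    (S, n, n, n) volumes.  Returns per-block, per-epoch loss histories.
    Deterministic given ``seed``.  Aborts with diagnostics on NaN loss.
    """
    cfg = cfg or TrainConfig()
    if len(models) != len(blocks):
        raise ValueError("one model per block required")
    X = stats.normalize_inputs(inputs)  # (S, 2, M)
    T = np.stack(
        [stats.normalize_targets(e, s) for e, s in zip(eps, sigma)]
    ).astype(np.float32)  # (S, 2, n, n, n)
    S = X.shape[0]
    histories = []
    for bi, (model, box) in enumerate(zip(models, blocks)):
        (x0, x1), (y0, y1), (z0, z1) = box
        Tb = np.ascontiguousarray(T[:, :, x0:x1, y0:y1, z0:z1])
        rng = np.random.default_rng(seed + 1000 * bi)
        opt = Adam(model.params(), lr=cfg.lr)
        hist = []
        for epoch in range(cfg.epochs):
            order = rng.permutation(S)
            total = 0.0
            for start in range(0, S, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                if idx.size < 2:
                    continue  # batch norm needs >= 2 samples
                opt.zero_grad()
                pred = model.forward(X[idx], train=True)
                loss, g = mse_loss(pred, Tb[idx])
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"NaN/inf loss in block {bi} epoch {epoch}; "
                        f"lr={cfg.lr}, batch={cfg.batch_size}"
                    )
                model.backward(g)
                opt.step()
                total += loss * idx.size
            hist.append(total / S)
            if verbose and (epoch % 10 == 0 or epoch == cfg.epochs - 1):
                print(f"  block {bi} epoch {epoch}: loss {hist[-1]:.5f}")
        histories.append(hist)
    return histories


def predict_volume(
    models,
    blocks,
    input_vec: np.ndarray,
    stats: NormStats,
    full_shape: tuple[int, int, int],
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble per-block predictions into the full (eps, sigma) volume.

    Denormalizes and applies the physical clamp eps >= 1, sigma >= 0.
    ``models`` may be any objects with a ``predict(x) -> (1, 2, *block)``
    method (identity stubs included, for testing the assembly).
    """
    if len(models) != len(blocks):
        raise ValueError("a model is required for every block")
    out = np.empty((2, *full_shape), dtype=np.float64)
    x = stats.normalize_inputs(np.asarray(input_vec)[None, :])
    for model, box in zip(models, blocks):
        (x0, x1), (y0, y1), (z0, z1) = box
        pred = model.predict(x)[0]
        out[:, x0:x1, y0:y1, z0:z1] = pred
    eps, sigma = stats.denormalize(out)
    return np.maximum(eps, 1.0), np.maximum(sigma, 0.0)


# ---------------------------------------------------------------------------
# checkpoints


def save_run(
    run_dir,
    models: list[Fcernn],
    blocks,
    stats: NormStats,
    histories=None,
    extra_meta: dict | None = None,
) -> None:
    """Save block checkpoints (single-file archive per block), stats and
    training history under ``run_dir``."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    spec = models[0].spec
    meta = {
        "spec": asdict(spec),
        "blocks": [[list(r) for r in b] for b in blocks],
        "stats": {
            "target_min": stats.target_min.tolist(),
            "target_max": stats.target_max.tolist(),
            "input_mean": stats.input_mean.tolist(),
            "input_scale": stats.input_scale,
        },
    }
    if extra_meta:
        meta.update(extra_meta)
    (run_dir / "meta.yaml").write_text(yaml.safe_dump(meta))
    for bi, model in enumerate(models):
        arrays = {}
        for li, layer in enumerate(model.net.layers):
            for p in layer.params():
                arrays[f"l{li}_{p.name}"] = p.data
            if isinstance(layer, BatchNorm):
                arrays[f"l{li}_running_mean"] = layer.running_mean
                arrays[f"l{li}_running_var"] = layer.running_var
        np.savez(run_dir / f"block_{bi:03d}.npz", **arrays)
    if histories is not None:
        with open(run_dir / "history.csv", "w", newline="") as f:
            wr = csv.writer(f)
            wr.writerow(["block", "epoch", "loss"])
            for bi, hist in enumerate(histories):
                for e, l in enumerate(hist):
                    wr.writerow([bi, e, l])


def load_run(run_dir):
    """Load (models, blocks, stats) saved by :func:`save_run`."""
    run_dir = Path(run_dir)
    meta = yaml.safe_load((run_dir / "meta.yaml").read_text())
    sd = meta["spec"]
    for key in ("encoder_channels", "encoder_kernels", "encoder_strides",
                "decoder_channels", "block_shape"):
        sd[key] = tuple(sd[key])
    spec = FcernnSpec(**sd)
    blocks = [tuple(tuple(r) for r in b) for b in meta["blocks"]]
    st = meta["stats"]
    stats = NormStats(
        target_min=np.asarray(st["target_min"]),
        target_max=np.asarray(st["target_max"]),
        input_mean=np.asarray(st["input_mean"]),
        input_scale=float(st["input_scale"]),
    )
    models = []
    for bi in range(len(blocks)):
        model = Fcernn(spec, seed=0)
        data = np.load(run_dir / f"block_{bi:03d}.npz")
        for li, layer in enumerate(model.net.layers):
            for p in layer.params():
                p.data[...] = data[f"l{li}_{p.name}"]
            if isinstance(layer, BatchNorm):
                layer.running_mean = data[f"l{li}_running_mean"]
                layer.running_var = data[f"l{li}_running_var"]
        models.append(model)
    return models, blocks, stats
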