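"""2-D U-Net image-enhancement stage.

The preliminary 3-D reconstruction is cut into 2-channel XY slices
(relative permittivity, conductivity), each slice is mapped by a U-Net to
an enhanced slice, and the slices are restacked.  The U-Net has four
encoder stages (two 3x3 convolutions + ReLU, then 2x2 max pooling), a
bottleneck, and four decoder stages (3x3 up-convolution doubling the
resolution, skip concatenation with the matching encoder feature map, two
3x3 convolutions + ReLU), finishing with a 1x1 convolution to 2 channels.
Channel width doubles at each encoder stage.

Both channels are enhanced jointly by a single network; training minimizes
MSE between enhanced slices and ground-truth property slices (both
min-max normalized).  Slices whose side is not a multiple of 16 are
edge-padded before the network and cropped after.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Adam, ConvNd, ConvTransposeNd, MaxPool2d, ReLU, Sequential, mse_loss


@dataclass
class UnetSpec:
    in_channels: int = 2
    out_channels: int = 2
    base_channels: int = 32  # width of the first stage; doubles per stage
    depth: int = 4  # number of pooling operations


def _double_conv(cin, cout, rng):
    return Sequential(
        ConvNd(cin, cout, 3, stride=1, pad=1, ndim=2, rng=rng),
        ReLU(),
        ConvNd(cout, cout, 3, stride=1, pad=1, ndim=2, rng=rng),
        ReLU(),
    )


class Unet:
    """U-Net with explicit skip wiring (concatenation of encoder maps)."""

    def __init__(self, spec: UnetSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        w = [spec.base_channels * 2**i for i in range(spec.depth)]
        self.enc = []
        cin = spec.in_channels
        for wi in w:
            self.enc.append(_double_conv(cin, wi, rng))
            cin = wi
        self.pools = [MaxPool2d() for _ in range(spec.depth)]
        self.bottleneck = _double_conv(w[-1], 2 * w[-1], rng)
        self.ups = []
        self.dec = []
        cin = 2 * w[-1]
        for wi in reversed(w):
            self.ups.append(
                ConvTransposeNd(cin, wi, 3, stride=2, pad=1, output_padding=1, ndim=2, rng=rng)
            )
            self.dec.append(_double_conv(2 * wi, wi, rng))
            cin = wi
        self.head = ConvNd(w[0], spec.out_channels, 1, stride=1, pad=0, ndim=2, rng=rng)
        self.stage_widths = w
        self.skip_enabled = [True] * spec.depth
        self.trained_hw: tuple[int, int] | None = None

    def params(self):
        out = []
        for m in self.enc + [self.bottleneck] + self.ups + self.dec + [self.head]:
            out.extend(m.params())
        return out

    @property
    def n_params(self) -> int:
        return int(sum(p.data.size for p in self.params()))

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        H, W = x.shape[2:]
        div = 2**self.spec.depth
        if H % div or W % div:
            raise ValueError(f"slice side must be divisible by {div}, got {H}x{W}")
        skips = []
        for enc, pool in zip(self.enc, self.pools):
            x = enc.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        x = self.bottleneck.forward(x, train)
        for i, (up, dec) in enumerate(zip(self.ups, self.dec)):
            x = up.forward(x, train)
            skip = skips[-(i + 1)]
            if not self.skip_enabled[-(i + 1)]:
                skip = np.zeros_like(skip)
            x = np.concatenate([skip, x], axis=1)
            x = dec.forward(x, train)
        return self.head.forward(x, train)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        g = self.head.backward(gy)
        skip_grads = [None] * self.spec.depth
        for i in reversed(range(self.spec.depth)):
            up, dec = self.ups[i], self.dec[i]
            g = dec.backward(g)
            sc = self.stage_widths[-(i + 1)]
            gskip, gup = g[:, :sc], g[:, sc:]
            stage = self.spec.depth - 1 - i
            skip_grads[stage] = gskip if self.skip_enabled[stage] else np.zeros_like(gskip)
            g = up.backward(np.ascontiguousarray(gup))
        g = self.bottleneck.backward(g)
        for s in reversed(range(self.spec.depth)):
            g = self.pools[s].backward(g)
            g = self.enc[s].backward(g + skip_grads[s])
        return g

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.forward(np.asarray(x, dtype=np.float32), train=False)


def build_unet(spec: UnetSpec | None = None, seed: int = 0) -> Unet:
    """Build a U-Net mapping a 2-channel HxW slice to a 2-channel HxW
    slice (H, W divisible by 2**depth)."""
    return Unet(spec or UnetSpec(), seed=seed)


# ---------------------------------------------------------------------------
# slicing


def slice_volume(vol: np.ndarray) -> np.ndarray:
    """Cut a (2, nx, ny, nz) volume into XY slices, z ascending:
    returns (nz, 2, nx, ny)."""
    if vol.ndim != 4:
        raise ValueError("expected a (channels, nx, ny, nz) volume")
    return np.ascontiguousarray(np.moveaxis(vol, -1, 0))


def stack_slices(slices: np.ndarray) -> np.ndarray:
    """Inverse of :func:`slice_volume`: (nz, 2, nx, ny) -> (2, nx, ny, nz)."""
    return np.ascontiguousarray(np.moveaxis(np.asarray(slices), 0, -1))


def pad_slices(slices: np.ndarray, multiple: int = 16):
    """Edge-replicate pad slices to the next multiple; returns
    (padded, (H, W)) for later cropping."""
    H, W = slices.shape[2:]
    Hp = -(-H // multiple) * multiple
    Wp = -(-W // multiple) * multiple
    if (Hp, Wp) == (H, W):
        return slices, (H, W)
    padded = np.pad(
        slices, [(0, 0), (0, 0), (0, Hp - H), (0, Wp - W)], mode="edge"
    )
    return padded, (H, W)


# ---------------------------------------------------------------------------
# training and volume enhancement


@dataclass
class UnetTrainConfig:
    epochs: int = 15
    batch_size: int = 32
    lr: float = 1e-3


def train_unet(
    model: Unet,
    X: np.ndarray,
    Y: np.ndarray,
    cfg: UnetTrainConfig | None = None,
    seed: int = 0,
    verbose: bool = False,
) -> list[float]:
    """MSE-train on (preliminary slice, truth slice) pairs, both in
    normalized units.  X, Y: (S, 2, H, W).  Returns per-epoch loss
    history; deterministic given seed; aborts on NaN loss."""
    cfg = cfg or UnetTrainConfig()
    X = np.asarray(X, dtype=np.float32)
    Y = np.asarray(Y, dtype=np.float32)
    rng = np.random.default_rng(seed)
    opt = Adam(model.params(), lr=cfg.lr)
    S = X.shape[0]
    hist = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(S)
        total = 0.0
        for start in range(0, S, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            opt.zero_grad()
            pred = model.forward(X[idx], train=True)
            loss, g = mse_loss(pred, Y[idx])
            if not np.isfinite(loss):
                raise RuntimeError(f"NaN/inf loss at epoch {epoch}; lr={cfg.lr}")
            model.backward(g)
            opt.step()
            total += loss * idx.size
        hist.append(total / S)
        if verbose:
            print(f"  unet epoch {epoch}: loss {hist[-1]:.5f}")
    model.trained_hw = X.shape[2:]
    return hist


def enhance_volume(model, eps: np.ndarray, sigma: np.ndarray, stats):
    """Apply the enhancement model slice-wise to an (eps, sigma) volume.

    Normalizes with the training statistics, edge-pads each XY slice to
    the U-Net's grid multiple, predicts, crops, restacks, denormalizes and
    applies the physical clamp (eps >= 1, sigma >= 0).  ``model`` may be
    any object with ``predict(slices) -> slices``.
    """
    vol = stats.normalize_targets(eps, sigma)  # (2, nx, ny, nz)
    slices = slice_volume(vol)
    padded, orig_hw = pad_slices(slices, 16)
    trained = getattr(model, "trained_hw", None)
    if trained is not None and tuple(padded.shape[2:]) != tuple(trained):
        raise ValueError(
            f"slice shape {padded.shape[2:]} does not match the model's "
            f"training slice shape {tuple(trained)}"
        )
    out = np.empty_like(padded, dtype=np.float32)
    B = 32
    for s in range(0, padded.shape[0], B):
        out[s : s + B] = model.predict(padded[s : s + B])
    out = out[:, :, : orig_hw[0], : orig_hw[1]]
    e, s = stats.denormalize(stack_slices(out))
    return np.maximum(e, 1.0), np.maximum(s, 0.0)
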