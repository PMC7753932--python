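"""3D U-Net body and the LP-U-Net wrapper."""

from __future__ import annotations

import numpy as np

from .core import Adam, AvgPool3d, Conv3d, Layer, ReLU, Upsample3d, depth_to_space, space_to_depth


class _ConvBlock(Layer):
    """Two 3x3x3 conv + ReLU pairs."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        self.layers = [Conv3d(c_in, c_out, rng), ReLU(), Conv3d(c_out, c_out, rng), ReLU()]
        self.params = [p for l in self.layers for p in l.params]

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class UNet3D:
    """Encoder-decoder with skip connections.

    ``depth`` pooling steps; channels double per level starting from
    ``base_channels``.  Input spatial dims must be divisible by 2**depth.
    """

    def __init__(self, in_channels: int, out_channels: int, depth: int = 3,
                 base_channels: int = 8, seed: int = 0,
                 rng: np.random.Generator | None = None):
        if depth < 1 or base_channels < 1:
            raise ValueError("depth and base_channels must be positive")
        rng = rng if rng is not None else np.random.default_rng(seed)
        self.depth = depth
        chans = [base_channels * 2**l for l in range(depth + 1)]
        self.enc = []
        c_prev = in_channels
        for c in chans[:-1]:
            self.enc.append(_ConvBlock(c_prev, c, rng))
            c_prev = c
        self.pools = [AvgPool3d(2) for _ in range(depth)]
        self.bottleneck = _ConvBlock(chans[-2], chans[-1], rng)
        self.ups = [Upsample3d(2) for _ in range(depth)]
        self.dec = []
        c_prev = chans[-1]
        for c in reversed(chans[:-1]):
            self.dec.append(_ConvBlock(c_prev + c, c, rng))
            c_prev = c
        self.head = Conv3d(chans[0], out_channels, rng, ksize=1)
        self.blocks = self.enc + self.pools + [self.bottleneck] + self.ups + self.dec + [self.head]

    @property
    def n_parameters(self) -> int:
        return sum(p["value"].size for b in self.blocks for p in b.params)

    def forward(self, x: np.ndarray) -> np.ndarray:
        d = np.asarray(x.shape[-3:])
        if np.any(d % 2**self.depth):
            raise ValueError(f"spatial dims {tuple(d)} not divisible by {2**self.depth}")
        skips = []
        for block, pool in zip(self.enc, self.pools):
            x = block.forward(x)
            skips.append(x)
            x = pool.forward(x)
        x = self.bottleneck.forward(x)
        self._skip_channels = []
        for up, block, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x)
            self._skip_channels.append(skip.shape[0])
            x = block.forward(np.concatenate([skip, x], axis=0))
        return self.head.forward(x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = self.head.backward(dy)
        dskips = []
        for up, block, c_skip in zip(reversed(self.ups), reversed(self.dec),
                                     reversed(self._skip_channels)):
            dcat = block.backward(dy)
            dskips.append(dcat[:c_skip])
            dy = up.backward(dcat[c_skip:])
        dy = self.bottleneck.backward(dy)
        for block, pool, dskip in zip(reversed(self.enc), reversed(self.pools),
                                      reversed(dskips)):
            dy = pool.backward(dy) + dskip
            dy = block.backward(dy)
        return dy

    def make_optimizer(self, lr: float) -> Adam:
        return Adam(self.blocks, lr=lr)


class LPUNet:
    """U-Net with space-to-depth input and dense-upsampling output stages.

    The input volume is rearranged by the holistic-decomposition factor
    ``hdc_factor`` (k) into k^3 channels at 1/k resolution, processed by a
    plain U-Net whose head emits ``n_classes * k^3`` channels, and the
    dense-upsampling stage rearranges those back to ``n_classes`` score
    maps at full input resolution.
    """

    def __init__(self, in_channels: int = 1, n_classes: int = 3, hdc_factor: int = 2,
                 duc_factor: int | None = None, depth: int = 3, base_channels: int = 8,
                 seed: int = 0):
        if hdc_factor < 1:
            raise ValueError("hdc_factor must be >= 1")
        duc_factor = hdc_factor if duc_factor is None else duc_factor
        if duc_factor != hdc_factor:
            raise ValueError("duc_factor must equal hdc_factor to preserve shape")
        self.k = hdc_factor
        self.n_classes = n_classes
        self.unet = UNet3D(in_channels * self.k**3, n_classes * self.k**3,
                           depth=depth, base_channels=base_channels, seed=seed)

    @property
    def n_parameters(self) -> int:
        return self.unet.n_parameters

    def check_input_shape(self, shape) -> None:
        d = np.asarray(shape[-3:])
        div = self.k * 2**self.unet.depth
        if np.any(d % div):
            raise ValueError(
                f"input spatial dims {tuple(d)} must be divisible by k * 2**depth = {div}"
            )

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.check_input_shape(x.shape)
        z = space_to_depth(x, self.k)
        y = self.unet.forward(z)
        return depth_to_space(y, self.k)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dz = self.unet.backward(space_to_depth(dy, self.k))
        return depth_to_space(dz, self.k)

    def make_optimizer(self, lr: float) -> Adam:
        return self.unet.make_optimizer(lr)
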