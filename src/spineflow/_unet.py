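"""Volumetric encoder-decoder (3D U-Net style) assembled from NumPy layers.

Encoder stages double the channel count and downsample by max pooling;
the decoder upsamples with transposed convolutions and concatenates the
(center-cropped, in valid mode) encoder skip tensors.  The head is a
1x1x1 convolution to 3 class logits.
"""

from __future__ import annotations

from typing import List, Tuple

import numpy as np

from .config import ConfigError, UNetConfig
from ._layers import Adam, Conv1x1, Conv3D, ConvTranspose3D, Layer, MaxPool3D, ReLU, softmax


def valid_mode_output(cfg: UNetConfig) -> Tuple[int, int, int]:
    """Output patch size (x, y, z) implied by the architecture in valid mode.

    Raises :class:`ConfigError` when pooling does not divide evenly along
    the way, listing the failing axis.
    """
    pools = _pool_factors(cfg)  # (z, y, x) per-axis factors
    sizes = [cfg.input_patch[2], cfg.input_patch[1], cfg.input_patch[0]]  # z, y, x
    names = "zyx"
    skips = []
    for stage in range(cfg.stages - 1):
        sizes = [s - 4 for s in sizes]
        skips.append(list(sizes))
        for ax in range(3):
            if sizes[ax] <= 0:
                raise ConfigError(f"patch too small: axis {names[ax]} vanished at stage {stage}")
            if sizes[ax] % pools[ax]:
                raise ConfigError(
                    f"axis {names[ax]}: size {sizes[ax]} not divisible by pool factor "
                    f"{pools[ax]} at stage {stage}"
                )
            sizes[ax] //= pools[ax]
    sizes = [s - 4 for s in sizes]  # bottleneck
    for stage in range(cfg.stages - 2, -1, -1):
        sizes = [s * f for s, f in zip(sizes, pools)]
        for ax in range(3):
            if sizes[ax] > skips[stage][ax]:
                raise ConfigError("decoder output exceeds encoder skip; invalid geometry")
        sizes = [s - 4 for s in sizes]
    if min(sizes) <= 0:
        raise ConfigError(f"input patch {cfg.input_patch} too small for {cfg.stages} stages")
    return (sizes[2], sizes[1], sizes[0])


def _pool_factors(cfg: UNetConfig) -> Tuple[int, int, int]:
    return (2 if cfg.pool_z else 1, 2, 2)


class _ConvBlock:
    def __init__(self, c_in, c_out, rng, same):
        self.layers: List[Layer] = [Conv3D(c_in, c_out, rng, same), ReLU(),
                                    Conv3D(c_out, c_out, rng, same), ReLU()]

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


def _crop_to(x: np.ndarray, target_spatial) -> Tuple[np.ndarray, Tuple[int, int, int]]:
    offs = []
    sl = [slice(None)]
    for cur, tgt in zip(x.shape[1:4], target_spatial):
        off = (cur - tgt) // 2
        offs.append(off)
        sl.append(slice(off, off + tgt))
    sl.append(slice(None))
    return x[tuple(sl)], tuple(offs)


class UNet3D:
    """The segmentation network: forward logits, exact backward, Adam-ready params."""

    def __init__(self, cfg: UNetConfig, rng: np.random.Generator):
        self.cfg = cfg
        same = cfg.conv_mode == "same"
        # in same mode the network output covers the input window; a smaller
        # configured output_patch is produced by center-cropping the logits,
        # giving tiles real image context instead of padding artifacts
        self._crop_margins = None
        if same and cfg.input_patch != cfg.output_patch:
            self._crop_margins = tuple(
                (i - o) // 2 for i, o in zip(cfg.input_patch, cfg.output_patch)
            )
        if not same:
            out = valid_mode_output(cfg)
            if tuple(cfg.output_patch) != out:
                raise ConfigError(
                    f"valid-mode architecture maps input {tuple(cfg.input_patch)} to output "
                    f"{out}; configured output_patch {tuple(cfg.output_patch)} "
                    f"(required margins {tuple((i - o) // 2 for i, o in zip(cfg.input_patch, out))})"
                )
        pools = _pool_factors(cfg)
        self.enc: List[_ConvBlock] = []
        self.pools: List[MaxPool3D] = []
        c_prev = 1
        for i in range(cfg.stages - 1):
            c = cfg.base_channels * 2 ** i
            self.enc.append(_ConvBlock(c_prev, c, rng, same))
            self.pools.append(MaxPool3D(pools))
            c_prev = c
        self.bottleneck = _ConvBlock(c_prev, cfg.base_channels * 2 ** (cfg.stages - 1), rng, same)
        self.ups: List[ConvTranspose3D] = []
        self.dec: List[_ConvBlock] = []
        c = cfg.base_channels * 2 ** (cfg.stages - 1)
        for i in range(cfg.stages - 2, -1, -1):
            c_skip = cfg.base_channels * 2 ** i
            self.ups.append(ConvTranspose3D(c, c_skip, pools, rng))
            self.dec.append(_ConvBlock(2 * c_skip, c_skip, rng, same))
            c = c_skip
        self.head = Conv1x1(cfg.base_channels, 3, rng)

    # -- parameter plumbing -------------------------------------------------
    def _layers(self) -> List[Layer]:
        out: List[Layer] = []
        for b in self.enc:
            out += b.layers
        out += self.bottleneck.layers
        for u, b in zip(self.ups, self.dec):
            out.append(u)
            out += b.layers
        out.append(self.head)
        return out

    @property
    def params(self) -> List[np.ndarray]:
        return [p for l in self._layers() for p in l.params]

    @property
    def grads(self) -> List[np.ndarray]:
        return [g for l in self._layers() for g in l.grads]

    def make_optimizer(self, lr, beta1=0.9, beta2=0.999, eps=1e-7) -> Adam:
        return Adam(self.params, lr, beta1, beta2, eps)

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """(N, D, H, W, 1) float input -> (N, d, h, w, 3) logits (channels last)."""
        x = np.asarray(x, dtype=np.float32)
        skips = []
        for block, pool in zip(self.enc, self.pools):
            x = block.forward(x)
            skips.append(x)
            x = pool.forward(x)
        x = self.bottleneck.forward(x)
        self._skip_crops = []
        for up, block, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x)
            skip_c, off = _crop_to(skip, x.shape[1:4])
            self._skip_crops.append((skip.shape, off, skip_c.shape))
            x = block.forward(np.concatenate([skip_c, x], axis=-1))
        logits = self.head.forward(x)
        if self._crop_margins is not None:
            mx, my, mz = self._crop_margins
            self._full_logits_shape = logits.shape
            d, h, w = logits.shape[1:4]
            logits = logits[:, mz:d - mz or None, my:h - my or None, mx:w - mx or None, :]
        return logits

    def backward(self, dlogits: np.ndarray) -> None:
        if self._crop_margins is not None:
            mx, my, mz = self._crop_margins
            full = np.zeros(self._full_logits_shape, dtype=dlogits.dtype)
            d, h, w = full.shape[1:4]
            full[:, mz:d - mz or None, my:h - my or None, mx:w - mx or None, :] = dlogits
            dlogits = full
        dy = self.head.backward(dlogits)
        dskips = []  # decoder step i consumed encoder skip n-1-i, so this
        # reverse walk appends gradients already in encoder order
        for i in range(len(self.dec) - 1, -1, -1):
            block = self.dec[i]
            up = self.ups[i]
            skip_shape, off, crop_shape = self._skip_crops[i]
            d = block.backward(dy)
            c_skip = crop_shape[-1]
            d_skip, d_up = d[..., :c_skip], d[..., c_skip:]
            full = np.zeros(skip_shape, dtype=d_skip.dtype)
            sl = [slice(None)] + [
                slice(o, o + s) for o, s in zip(off, crop_shape[1:4])
            ] + [slice(None)]
            full[tuple(sl)] = d_skip
            dskips.append(full)
            dy = up.backward(d_up)
        dy = self.bottleneck.backward(dy)
        for i in range(len(self.enc) - 1, -1, -1):
            dy = self.pools[i].backward(dy)
            dy = dy + dskips[i]
            dy = self.enc[i].backward(dy)

    def predict_proba_patch(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x), axis=-1)
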