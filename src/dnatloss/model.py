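"""Segmentation networks: a compact U-Net and a ResNet-34-style variant.

Both are encoder–decoder networks with skip connections that map an RGB
image (n,3,H,W) to a single-channel logit map (n,1,H,W).  ``tiny-unet``
(downsampling factor 4) is the default and is small enough to train on a
CPU in seconds; the ``resnet34`` variant follows the ResNet-34 block
layout (downsampling factor 32) with norm-free residual blocks and no
pretrained weights.  Inference thresholds sigmoid(logits) at 0.5 with a
strict comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Module:
    """Parameter container with recursive discovery (no framework ambitions)."""

    def parameters(self) -> list[Tensor]:
        params, seen = [], set()

        def collect(obj):
            if isinstance(obj, Tensor):
                if obj.requires_grad and id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    collect(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    collect(v)

        collect(self)
        return params

    def state_dict(self) -> dict:
        return {f"p{i}": p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict):
        for i, p in enumerate(self.parameters()):
            p.data = np.asarray(state[f"p{i}"], dtype=p.data.dtype).reshape(p.data.shape)

    def astype(self, dtype):
        """Cast every parameter in place (float32 training, float64 checks)."""
        for p in self.parameters():
            p.data = p.data.astype(dtype)
        return self


class Conv2d(Module):
    def __init__(self, cin, cout, kernel, stride=1, padding=0, rng=None, bias=True):
        rng = rng or np.random.default_rng(0)
        fan_in = cin * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, kernel, kernel))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(cout), requires_grad=True) if bias else None
        self.stride, self.padding = stride, padding

    def __call__(self, x):
        return ad.conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class Linear(Module):
    def __init__(self, nin, nout, rng=None):
        rng = rng or np.random.default_rng(0)
        self.weight = Tensor(rng.normal(0.0, np.sqrt(2.0 / nin), size=(nin, nout)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(nout), requires_grad=True)

    def __call__(self, x):
        return x @ self.weight + self.bias


@dataclass(frozen=True)
class SegmentationModelConfig:
    encoder: str = "tiny-unet"      # "tiny-unet" | "resnet34"
    in_channels: int = 3
    out_channels: int = 1
    pretrained: bool = False
    base_width: int = 8             # tiny-unet channel width at full resolution

    def __post_init__(self):
        if self.encoder not in ("tiny-unet", "resnet34"):
            raise ValueError(f"unknown encoder {self.encoder!r}")
        if self.pretrained:
            raise ValueError("pretrained weights are not available in this package")


def _double_conv(cin, cout, rng):
    return [Conv2d(cin, cout, 3, padding=1, rng=rng), Conv2d(cout, cout, 3, padding=1, rng=rng)]


class TinyUNet(Module):
    """Three-level U-Net with stride-2 downsampling convs; factor-4 contract."""

    downsample_factor = 4

    def __init__(self, cfg: SegmentationModelConfig = SegmentationModelConfig(), rng=None):
        rng = rng or np.random.default_rng(0)
        c = cfg.base_width
        self.cfg = cfg
        self.enc1 = _double_conv(cfg.in_channels, c, rng)
        self.down1 = Conv2d(c, 2 * c, 3, stride=2, padding=1, rng=rng)
        self.enc2 = _double_conv(2 * c, 2 * c, rng)
        self.down2 = Conv2d(2 * c, 4 * c, 3, stride=2, padding=1, rng=rng)
        self.bottleneck = _double_conv(4 * c, 4 * c, rng)
        self.up1 = Conv2d(4 * c, 2 * c, 3, padding=1, rng=rng)
        self.dec1 = _double_conv(4 * c, 2 * c, rng)
        self.up2 = Conv2d(2 * c, c, 3, padding=1, rng=rng)
        self.dec2 = _double_conv(2 * c, c, rng)
        self.head = Conv2d(c, cfg.out_channels, 1, rng=rng)

    @staticmethod
    def _run(block, x):
        for conv in block:
            x = ad.relu(conv(x))
        return x

    def forward(self, image) -> Tensor:
        x = ad.as_tensor(image)
        if x.ndim == 3:
            x = x.reshape(1, *x.shape)
        n, c, h, w = x.shape
        if h % self.downsample_factor or w % self.downsample_factor:
            raise ValueError(
                f"input size {h}×{w} not divisible by {self.downsample_factor}; pad first")
        s1 = self._run(self.enc1, x)
        s2 = self._run(self.enc2, ad.relu(self.down1(s1)))
        b = self._run(self.bottleneck, ad.relu(self.down2(s2)))
        u1 = ad.relu(self.up1(ad.upsample_nearest2x(b)))
        d1 = self._run(self.dec1, ad.concat([u1, s2], axis=1))
        u2 = ad.relu(self.up2(ad.upsample_nearest2x(d1)))
        d2 = self._run(self.dec2, ad.concat([u2, s1], axis=1))
        return self.head(d2)

    __call__ = forward


class _BasicBlock(Module):
    def __init__(self, cin, cout, stride, rng):
        self.conv1 = Conv2d(cin, cout, 3, stride=stride, padding=1, rng=rng)
        self.conv2 = Conv2d(cout, cout, 3, padding=1, rng=rng)
        self.proj = Conv2d(cin, cout, 1, stride=stride, rng=rng, bias=False) \
            if (stride != 1 or cin != cout) else None

    def __call__(self, x):
        identity = self.proj(x) if self.proj is not None else x
        out = ad.relu(self.conv1(x))
        return ad.relu(self.conv2(out) + identity)


class ResNet34UNet(Module):
    """ResNet-34 block layout ([3,4,6,3]) as encoder, U-Net decoder; factor 32."""

    downsample_factor = 32

    def __init__(self, cfg: SegmentationModelConfig = None, rng=None, width: int = 16):
        # `width` scales the canonical (64,128,256,512) widths down for CPU use;
        # width=64 reproduces the canonical layout.
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg or SegmentationModelConfig(encoder="resnet34")
        w = width
        self.stem = Conv2d(self.cfg.in_channels, w, 7, stride=2, padding=3, rng=rng)
        self.layers = []
        cin = w
        for nblocks, cout, stride in ((3, w, 1), (4, 2 * w, 2), (6, 4 * w, 2), (3, 8 * w, 2)):
            blocks = [_BasicBlock(cin, cout, stride, rng)]
            blocks += [_BasicBlock(cout, cout, 1, rng) for _ in range(nblocks - 1)]
            self.layers.append(blocks)
            cin = cout
        # decoder: 5 upsampling stages from 8w back to full resolution
        dec_in = 8 * w
        self.dec_blocks = []
        for skip_c, out_c in ((4 * w, 4 * w), (2 * w, 2 * w), (w, w), (w, w),
                              (self.cfg.in_channels, w)):
            up = Conv2d(dec_in, out_c, 3, padding=1, rng=rng)
            fuse = Conv2d(out_c + skip_c, out_c, 3, padding=1, rng=rng)
            self.dec_blocks.append([up, fuse])
            dec_in = out_c
        self.head = Conv2d(dec_in, self.cfg.out_channels, 1, rng=rng)

    def forward(self, image) -> Tensor:
        x = ad.as_tensor(image)
        if x.ndim == 3:
            x = x.reshape(1, *x.shape)
        n, c, h, w = x.shape
        if h % self.downsample_factor or w % self.downsample_factor:
            raise ValueError(
                f"input size {h}×{w} not divisible by {self.downsample_factor}; pad first")
        s0 = x                                   # full res (input)
        x = ad.relu(self.stem(x))                # /2
        s1 = x
        x = ad.max_pool2d(x, 3, 2, 1)            # /4
        feats = []
        for blocks in self.layers:
            for b in blocks:
                x = b(x)
            feats.append(x)                      # /4, /8, /16, /32
        skips = [feats[2], feats[1], feats[0], s1, s0]
        for (up, fuse), skip in zip(self.dec_blocks, skips):
            x = ad.relu(up(ad.upsample_nearest2x(x)))
            x = ad.relu(fuse(ad.concat([x, skip], axis=1)))
        return self.head(x)

    __call__ = forward


def build_model(cfg: SegmentationModelConfig, rng=None) -> Module:
    if cfg.encoder == "tiny-unet":
        return TinyUNet(cfg, rng=rng)
    return ResNet34UNet(cfg, rng=rng)


def predict_mask(logits, threshold: float = 0.5) -> np.ndarray:
    """Binary mask from a logit map: sigmoid then a strict '>' comparison."""
    z = logits.data if isinstance(logits, Tensor) else np.asarray(logits)
    if not np.all(np.isfinite(z)):
        raise ValueError("logits must be finite")
    from scipy.special import expit
    return (expit(z) > threshold).astype(np.uint8)
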