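"""Per-image degrees-of-freedom predictor.

A lightweight head — three 3×3 stride-1 convolutions with ReLU, adaptive
average pooling to one vector per image, and a two-layer MLP with a
Softplus output — maps an RGB image to a single positive ν.  Training it
jointly with the segmentation network lets the loss pick heavier tails
(small ν) on images whose annotations look unreliable and lighter tails
on clean ones.  A fixed offset ν_min keeps ν away from zero, where the
t-NLL becomes numerically unstable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .model import Module, Conv2d, Linear


@dataclass(frozen=True)
class NuPredictorConfig:
    conv_channels: tuple = (16, 32, 32)
    hidden_dim: int = 32
    nu_min: float = 0.1
    input_downscale: int = 1  # run the convs on a 1/k-resolution copy (ν is a
    #                           global image statistic; the harness uses k=2)

    def __post_init__(self):
        if self.hidden_dim < 1 or any(c < 1 for c in self.conv_channels):
            raise ValueError("conv_channels and hidden_dim must be positive")
        if self.nu_min <= 0:
            raise ValueError("nu_min must be positive")
        if self.input_downscale < 1:
            raise ValueError("input_downscale must be ≥ 1")


class NuPredictor(Module):
    """image (n,3,H,W) → ν (n,), with ν > nu_min by construction."""

    def __init__(self, cfg: NuPredictorConfig = NuPredictorConfig(), rng=None):
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        c1, c2, c3 = cfg.conv_channels
        self.conv1 = Conv2d(3, c1, 3, padding=1, rng=rng)
        self.conv2 = Conv2d(c1, c2, 3, padding=1, rng=rng)
        self.conv3 = Conv2d(c2, c3, 3, padding=1, rng=rng)
        self.fc1 = Linear(c3, cfg.hidden_dim, rng=rng)
        self.fc2 = Linear(cfg.hidden_dim, 1, rng=rng)

    def forward(self, image) -> Tensor:
        x = ad.as_tensor(image)
        if x.ndim == 3:
            x = x.reshape(1, *x.shape)
        if x.shape[1] != 3:
            raise ValueError(f"expected 3 input channels, got {x.shape[1]}")
        if x.shape[2] < 8 or x.shape[3] < 8:
            raise ValueError("image must be at least 8×8")
        ds = self.cfg.input_downscale
        if ds > 1:
            x = ad.bilinear_resize(x, max(x.shape[2] // ds, 8), max(x.shape[3] // ds, 8))
        x = ad.relu(self.conv1(x))
        x = ad.relu(self.conv2(x))
        x = ad.relu(self.conv3(x))
        feat = ad.global_mean_pool(x)                    # (n, c3) for any H, W
        h = ad.relu(self.fc1(feat))
        raw = self.fc2(h).reshape(-1)
        return ad.softplus(raw) + self.cfg.nu_min

    __call__ = forward


def predict_nu(image, cfg: NuPredictorConfig = NuPredictorConfig(),
               predictor: NuPredictor | None = None) -> np.ndarray:
    """Functional entry point; builds a predictor if none is supplied."""
    predictor = predictor or NuPredictor(cfg)
    return predictor(image).data
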