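"""Scale pyramid and multi-scale aggregation of the Student's-t loss.

The prediction and mask are resized to a short pyramid of scales
(default 1.0, 0.5, 0.25) — bilinear for the probability map, nearest
neighbour for the binary mask — and the single-scale t-NLL is evaluated
at each level with its own learnable log-precision map λ_s.  The total
loss is the fixed weighted sum Σ_s w_s·L_s (default weights 1.0, 0.5,
0.3).  Coarse levels see blob-level structure, the fine level sees the
boundary, and each level's λ map learns its own spatial error tolerance.

Scaled sizes use floor(s·H)×floor(s·W); resizing uses the pixel-center
convention, so the 1.0 level is bit-identical to the inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, as_tensor
from .losses import (DEFAULT_CONFIG, LossConfig, gaussian_nll_per_image,
                     student_t_nll_per_image)


@dataclass(frozen=True)
class ScaleSpec:
    scales: tuple = (1.0, 0.5, 0.25)
    weights: tuple = (1.0, 0.5, 0.3)

    def __post_init__(self):
        if len(self.scales) != len(self.weights):
            raise ValueError("scales and weights must have equal length")
        if any(not (0.0 < s <= 1.0) for s in self.scales):
            raise ValueError("scales must lie in (0, 1]")
        if any(w <= 0 for w in self.weights):
            raise ValueError("weights must be positive")

    def sizes(self, h: int, w: int) -> list[tuple[int, int]]:
        out = []
        for s in self.scales:
            hs, ws = int(np.floor(s * h)), int(np.floor(s * w))
            if hs < 1 or ws < 1:
                raise ValueError(f"scale {s} collapses a {h}×{w} image to zero size")
            out.append((hs, ws))
        return out


DEFAULT_SCALES = ScaleSpec()


def build_pyramid(prob_map, mask, spec: ScaleSpec = DEFAULT_SCALES):
    """Resize (probability map, mask) to every scale.

    Returns a list of (prob, mask) pairs, one per scale.  The probability
    map may be a Tensor (gradients flow through the bilinear resize);
    the mask is a plain binary array resized by nearest neighbour.
    """
    prob = as_tensor(prob_map)
    y = np.asarray(mask)
    if tuple(prob.shape[-2:]) != tuple(y.shape[-2:]):
        raise ValueError("probability map and mask sizes differ")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("mask must be binary")
    h, w = y.shape[-2:]
    pairs = []
    for hs, ws in spec.sizes(h, w):
        pairs.append((ad.bilinear_resize(prob, hs, ws), ad.nearest_resize(y, hs, ws)))
    return pairs


def make_lambda_maps(h: int, w: int, spec: ScaleSpec = DEFAULT_SCALES) -> list[Tensor]:
    """One trainable all-zero log-precision map per scale (unit precision)."""
    return [Tensor(np.zeros((hs, ws)), requires_grad=True) for hs, ws in spec.sizes(h, w)]


def export_lambda_maps(lambda_maps, directory, spec: ScaleSpec = DEFAULT_SCALES):
    """Write each λ map as .npy with a JSON sidecar describing the scales."""
    import json
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for lam, scale in zip(lambda_maps, spec.scales):
        data = lam.data if isinstance(lam, Tensor) else np.asarray(lam)
        name = f"lambda_scale_{scale:g}.npy"
        np.save(directory / name, data)
        entries.append({"file": name, "scale": scale,
                        "shape": list(data.shape)})
    (directory / "lambda_maps.json").write_text(json.dumps(entries, indent=2))
    return entries


def dna_t_loss_per_image(prob_map, mask, nu, lambda_maps,
                         spec: ScaleSpec = DEFAULT_SCALES,
                         cfg: LossConfig = DEFAULT_CONFIG) -> Tensor:
    """Σ_s w_s · L_s per image; prob_map (h,w) or (n,h,w), nu scalar or (n,)."""
    prob = as_tensor(prob_map)
    y = np.asarray(mask)
    h, w = y.shape[-2:]
    sizes = spec.sizes(h, w)
    if len(lambda_maps) != len(spec.scales):
        raise ValueError(f"expected {len(spec.scales)} lambda maps, got {len(lambda_maps)}")
    for lam, (hs, ws) in zip(lambda_maps, sizes):
        if tuple(lam.shape) != (hs, ws):
            raise ValueError(
                f"lambda map shape {tuple(lam.shape)} does not match scale size {(hs, ws)}")
    total = None
    for (p_s, y_s), lam, wgt in zip(build_pyramid(prob, y, spec), lambda_maps, spec.weights):
        term = wgt * student_t_nll_per_image(p_s - y_s, lam, nu, cfg)
        total = term if total is None else total + term
    return total


def dna_t_loss(prob_map, mask, nu, lambda_maps, spec: ScaleSpec = DEFAULT_SCALES,
               cfg: LossConfig = DEFAULT_CONFIG) -> Tensor:
    """Batch-reduced multi-scale adaptive t-loss (the training objective)."""
    per = dna_t_loss_per_image(prob_map, mask, nu, lambda_maps, spec, cfg)
    return per.mean() if cfg.reduction == "mean" else per.sum()


def multiscale_gaussian_loss(prob_map, mask, lambda_maps,
                             spec: ScaleSpec = DEFAULT_SCALES,
                             cfg: LossConfig = DEFAULT_CONFIG) -> Tensor:
    """Gaussian (ν→∞) counterpart with the same pyramid and λ maps."""
    prob = as_tensor(prob_map)
    y = np.asarray(mask)
    total = None
    for (p_s, y_s), lam, wgt in zip(build_pyramid(prob, y, spec), lambda_maps, spec.weights):
        term = wgt * gaussian_nll_per_image(p_s - y_s, lam)
        total = term if total is None else total + term
    return total.mean() if cfg.reduction == "mean" else total.sum()
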