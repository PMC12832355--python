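"""Robust segmentation loss kernels.

The central object is the negative log-likelihood of a diagonal-precision
multivariate Student's-t distribution evaluated on the per-pixel residual
field δ = p − y between a predicted foreground-probability map p and a
binary mask y.  With D pixels, log-precisions λ (so Σ⁻¹ = diag(e^λ)) and
degrees of freedom ν the single-scale loss is

    L = −lnΓ((ν+D)/2) + lnΓ(ν/2) − ½·Σλ_i + (D/2)·ln π + (D/2)·ln ν
        + ((ν+D)/2)·ln(1 + Σ δ_i² e^{λ_i} / ν).

Small ν gives heavy tails that saturate on grossly wrong pixels (label
noise); large ν approaches the Gaussian NLL, which penalises every error
quadratically.  The classic robust baselines used for comparison (GCE,
SCE, RCE, NGCE, MAE and the fixed-ν t-loss) are provided under one
dispatcher so a training harness can swap them freely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

from . import autodiff as ad
from .autodiff import Tensor, as_tensor

LAMBDA_CLAMP = 20.0  # e^λ is evaluated on clamp(λ, −20, 20) to avoid overflow


@dataclass(frozen=True)
class LossConfig:
    """Numerical and plumbing choices shared by the loss kernels.

    epsilon is the stabiliser used inside logarithms whose argument can
    approach zero (the cross-entropy family); the t-NLL's final log term
    has argument ≥ 1 and is computed with ``log1p`` directly.
    """

    epsilon: float = 1e-6
    reduction: str = "mean"          # over the batch axis: "mean" | "sum"
    residual_source: str = "probabilities"  # or "logits"

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.reduction not in ("mean", "sum"):
            raise ValueError(f"unknown reduction {self.reduction!r}")
        if self.residual_source not in ("probabilities", "logits"):
            raise ValueError(f"unknown residual_source {self.residual_source!r}")


DEFAULT_CONFIG = LossConfig()


def _reduce(per_image: Tensor, cfg: LossConfig) -> Tensor:
    return per_image.mean() if cfg.reduction == "mean" else per_image.sum()


def _check_shapes(residuals, log_precision):
    k = log_precision.ndim
    if k == 0 or residuals.ndim < k or tuple(residuals.shape[-k:]) != tuple(log_precision.shape):
        raise ValueError(
            f"residuals {tuple(residuals.shape)} and log-precision "
            f"{tuple(log_precision.shape)} do not match"
        )


def student_t_nll_per_image(residuals, log_precision, nu,
                            cfg: LossConfig = DEFAULT_CONFIG) -> Tensor:
    """Per-image Student's-t NLL; residuals may carry a leading batch axis.

    residuals: (h, w) or (n, h, w); log_precision: (h, w), shared across the
    batch; nu: scalar or (n,).  Returns a Tensor of shape () or (n,).
    """
    residuals = as_tensor(residuals)
    log_precision = as_tensor(log_precision)
    nu = as_tensor(nu)
    _check_shapes(residuals, log_precision)
    nu_data = np.atleast_1d(nu.data)
    if np.any(nu_data <= 0) or not np.all(np.isfinite(nu_data)):
        raise ValueError("degrees of freedom nu must be positive and finite")

    d = int(np.prod(log_precision.shape))
    lam = ad.clip(log_precision, -LAMBDA_CLAMP, LAMBDA_CLAMP)
    # Σ δ² e^λ over the per-image pixel axes (λ is shared across any batch axis)
    quad = residuals * residuals * ad.exp(lam)
    for _ in range(log_precision.ndim):
        quad = quad.sum(axis=-1)
    half = 0.5
    lam_sum = lam.sum()
    loss = (
        -ad.loggamma((nu + d) * half)
        + ad.loggamma(nu * half)
        - half * lam_sum
        + (d * half) * np.log(np.pi)
        + (d * half) * ad.log(nu)
        + ((nu + d) * half) * ad.log1p(quad / nu)
    )
    return loss


def student_t_nll(residuals, log_precision, nu, cfg: LossConfig = DEFAULT_CONFIG) -> Tensor:
    """Scalar Student's-t NLL (batch-reduced per cfg.reduction)."""
    return _reduce(student_t_nll_per_image(residuals, log_precision, nu, cfg), cfg)


def gaussian_nll_per_image(residuals, log_precision) -> Tensor:
    """ν→∞ limit of the t-NLL: (D/2)ln 2π − ½Σλ + ½Σδ²e^λ, per image."""
    residuals = as_tensor(residuals)
    log_precision = as_tensor(log_precision)
    _check_shapes(residuals, log_precision)
    d = int(np.prod(log_precision.shape))
    lam = ad.clip(log_precision, -LAMBDA_CLAMP, LAMBDA_CLAMP)
    quad = residuals * residuals * ad.exp(lam)
    for _ in range(log_precision.ndim):
        quad = quad.sum(axis=-1)
    return (d / 2.0) * np.log(2.0 * np.pi) - 0.5 * lam.sum() + 0.5 * quad


def gaussian_nll(residuals, log_precision, cfg: LossConfig = DEFAULT_CONFIG) -> Tensor:
    return _reduce(gaussian_nll_per_image(residuals, log_precision), cfg)


# -- maximum-likelihood ν fit (used by the ν-recovery check) -----------------

def mean_t_nll_numpy(residuals: np.ndarray, nu: float) -> float:
    """Mean univariate standard-t NLL of a residual sample at a given ν."""
    r = np.asarray(residuals, dtype=np.float64)
    return float(
        -gammaln((nu + 1) / 2.0)
        + gammaln(nu / 2.0)
        + 0.5 * np.log(np.pi * nu)
        + ((nu + 1) / 2.0) * np.mean(np.log1p(r**2 / nu))
    )


def fit_nu_mle(residuals: np.ndarray, bounds=(0.05, 500.0)) -> float:
    """Degrees of freedom minimising the mean univariate t-NLL (scale fixed at 1)."""
    res = minimize_scalar(
        lambda nu: mean_t_nll_numpy(residuals, nu),
        bounds=bounds, method="bounded",
        options={"xatol": 1e-6},
    )
    return float(res.x)


# -- baseline robust losses --------------------------------------------------

def _prob_of_label(prob: Tensor, mask: np.ndarray) -> Tensor:
    """p_y: predicted probability assigned to the true label, per pixel."""
    y = np.asarray(mask, dtype=np.float64)
    return prob * y + (1.0 - prob) * (1.0 - y)

def _validate_prob_mask(prob, mask):
    p = np.asarray(prob.data if isinstance(prob, Tensor) else prob)
    y = np.asarray(mask)
    if p.shape != y.shape:
        raise ValueError(f"probability map {p.shape} and mask {y.shape} differ")
    if p.min() < -1e-9 or p.max() > 1 + 1e-9:
        raise ValueError("probability map entries must lie in [0, 1]")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("mask must be binary")


BASELINE_LOSSES = ("gce", "sce", "rce", "ngce", "mae", "tloss_fixed")

# Reverse cross entropy uses log 0 := A (a finite constant), the convention
# of the symmetric-cross-entropy literature.
RCE_LOG_ZERO = -4.0


def baseline_loss(name: str, prob_map, mask, params: dict | None = None,
                  cfg: LossConfig = DEFAULT_CONFIG) -> Tensor:
    """Pixel-averaged robust baseline losses on a probability map vs. a binary mask.

    gce: (1−p_y^q)/q; sce: α·CE + β·RCE; rce: −(1−p_y)·A; ngce: GCE normalised
    by its sum over both labels; mae: mean |p−y|; tloss_fixed: the scalar-ν
    Student's-t NLL with λ ≡ 0 (the non-adaptive t-loss baseline).
    """
    params = dict(params or {})
    prob = as_tensor(prob_map)
    _validate_prob_mask(prob, mask)
    y = np.asarray(mask, dtype=np.float64)
    eps = cfg.epsilon

    if name == "mae":
        return ad.abs_(prob - y).mean()
    if name == "gce":
        q = float(params.get("q", 0.7))
        p_y = _prob_of_label(prob, y)
        return ((1.0 - (p_y + eps) ** q) / q).mean()
    if name == "sce":
        alpha = float(params.get("alpha", 0.1))
        beta = float(params.get("beta", 1.0))
        p_y = _prob_of_label(prob, y)
        ce = -ad.log(p_y + eps)
        rce = -(1.0 - p_y) * RCE_LOG_ZERO
        return (alpha * ce + beta * rce).mean()
    if name == "rce":
        p_y = _prob_of_label(prob, y)
        return (-(1.0 - p_y) * RCE_LOG_ZERO).mean()
    if name == "ngce":
        q = float(params.get("q", 0.7))
        p_y = _prob_of_label(prob, y)
        num = 1.0 - (p_y + eps) ** q
        den = num + (1.0 - (1.0 - p_y + eps) ** q)
        return (num / (den + eps)).mean()
    if name == "tloss_fixed":
        nu = params.get("nu", 2.0)
        lam = Tensor(np.zeros(prob.shape[-2:]))
        residuals = prob - y
        return student_t_nll(residuals, lam, nu, cfg)
    raise ValueError(f"unknown baseline loss {name!r}; choose from {BASELINE_LOSSES}")


def cross_entropy(prob_map, mask, cfg: LossConfig = DEFAULT_CONFIG) -> Tensor:
    """Plain pixel-averaged binary cross entropy (reference for the GCE q→0 limit)."""
    prob = as_tensor(prob_map)
    _validate_prob_mask(prob, mask)
    p_y = _prob_of_label(prob, np.asarray(mask, dtype=np.float64))
    return (-ad.log(p_y + cfg.epsilon)).mean()
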