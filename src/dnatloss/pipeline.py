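"""Training, evaluation and loss-comparison harness.

Joint optimisation of the segmentation network, the NuPredictor and the
per-scale λ maps with Adam under a polynomial learning-rate decay
ηt = η0·(1 − t/T)^p applied per iteration.  The harness treats the loss
as a plug-in: the adaptive multi-scale t-loss, its Gaussian (ν→∞)
counterpart, and the classic robust baselines all run through identical
plumbing, which is what makes paired multi-seed comparisons meaningful.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage, stats

from . import autodiff as ad
from .autodiff import Tensor
from .losses import LossConfig, baseline_loss, student_t_nll
from .metrics import MetricReport, evaluate_dataset
from .model import SegmentationModelConfig, build_model, predict_mask
from .multiscale import (ScaleSpec, dna_t_loss, make_lambda_maps,
                         multiscale_gaussian_loss)
from .nu_predictor import NuPredictor, NuPredictorConfig
from .synthetic import load_dataset

LOSS_NAMES = ("dna_tloss", "gaussian", "tloss_fixed", "mae", "gce", "sce", "rce", "ngce")


@dataclass(frozen=True)
class AugmentationConfig:
    """Mirrors the clinical-noise augmentation recipe: flips, elastic
    deformation, grid distortion, ±20% brightness/contrast and Gaussian
    noise with variance drawn from (10, 50) on the 8-bit scale."""
    flip_p: float = 0.5
    elastic_alpha: float = 1.0
    elastic_sigma: float = 50.0
    elastic_p: float = 0.5
    grid_num_steps: int = 5
    grid_distort_limit: float = 0.3
    grid_p: float = 0.5
    brightness_contrast_limit: float = 0.2
    brightness_contrast_p: float = 0.5
    gauss_noise_var: tuple = (10.0, 50.0)
    gauss_noise_p: float = 0.5


@dataclass
class TrainConfig:
    lr0: float = 0.001
    weight_decay: float = 1e-4
    poly_power: float = 0.9
    epochs: int = 300
    batch_size: int = 16
    loss_name: str = "dna_tloss"
    loss_params: dict = field(default_factory=dict)
    seed: int = 0
    image_size: tuple = (512, 608)
    encoder: str = "tiny-unet"
    base_width: int = 8
    scales: tuple = (1.0, 0.5, 0.25)
    scale_weights: tuple = (1.0, 0.5, 0.3)
    nu_min: float = 0.1
    nu_input_downscale: int = 2
    epsilon: float = 1e-6
    residual_source: str = "probabilities"
    head_bias_prior: float | None = 0.15  # init head bias to logit(prior fg
    #                 fraction): starts p near the class balance and prevents
    #                 the sigmoid-saturation collapse of a cold start
    logit_reg: float = 0.005  # weight of a Σz² pull-back on the logits for the
    #                 probability-residual NLL losses; keeps the sigmoid out of
    #                 its dead zone, where those losses lose their gradient
    gaussian_lambda_trainable: bool = False  # the "gaussian" arm is the
    #                 non-adaptive ν→∞ baseline: λ stays frozen at zero unless
    #                 explicitly enabled
    val_fraction: float = 0.15
    grad_clip: float | None = 25.0  # global-norm clip; the t-NLL's per-image
    #                                weight can transiently amplify gradients
    augment: bool = False
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)
    checkpoint_path: str | None = None

    def __post_init__(self):
        if self.lr0 <= 0 or self.poly_power <= 0 or self.epochs < 1:
            raise ValueError("invalid optimiser settings")
        if self.loss_name not in LOSS_NAMES:
            raise ValueError(f"unknown loss {self.loss_name!r}; choose from {LOSS_NAMES}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["image_size"] = list(self.image_size)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        if "augmentation" in d and isinstance(d["augmentation"], dict):
            aug = dict(d["augmentation"])
            if "gauss_noise_var" in aug:
                aug["gauss_noise_var"] = tuple(aug["gauss_noise_var"])
            d["augmentation"] = AugmentationConfig(**aug)
        for key in ("image_size", "scales", "scale_weights"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(self.to_dict()))


@dataclass
class RunResult:
    loss_series: list
    lr_series: list
    nu_trace: list
    report: MetricReport | None
    seed: int
    checkpoint_path: str | None


def poly_lr(t: int, total: int, lr0: float, p: float) -> float:
    """Polynomial decay lr0·(1 − t/T)^p; t counts iterations from 0 to T."""
    if total < 1 or t < 0 or t > total:
        raise ValueError("need 0 ≤ t ≤ T and T ≥ 1")
    return float(lr0 * (1.0 - t / total) ** p)


def clip_grad_norm(params, max_norm: float) -> float:
    """Scale all gradients down so their global L2 norm is ≤ max_norm."""
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float(np.sum(p.grad.astype(np.float64) ** 2))
    norm = np.sqrt(total)
    if norm > max_norm and norm > 0:
        scale = float(max_norm / norm)  # python float: keeps each grad's dtype
        for p in params:
            if p.grad is not None:
                p.grad = p.grad * scale
    return float(norm)


class Adam:
    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def state_dict(self):
        return {"t": self.t, "m": self.m, "v": self.v}


# -- augmentation ------------------------------------------------------------

def augment_sample(image: np.ndarray, mask: np.ndarray, rng,
                   cfg: AugmentationConfig = AugmentationConfig()):
    """Jointly augment an image (3,H,W) and its mask (H,W)."""
    img, m = image.copy(), mask.copy()
    if rng.random() < cfg.flip_p:
        img, m = img[:, :, ::-1], m[:, ::-1]
    if rng.random() < cfg.flip_p:
        img, m = img[:, ::-1, :], m[::-1, :]
    h, w = m.shape
    if rng.random() < cfg.elastic_p:
        dy = ndimage.gaussian_filter(rng.standard_normal((h, w)), cfg.elastic_sigma) * cfg.elastic_alpha
        dx = ndimage.gaussian_filter(rng.standard_normal((h, w)), cfg.elastic_sigma) * cfg.elastic_alpha
        yy, xx = np.mgrid[0:h, 0:w]
        coords = [yy + dy, xx + dx]
        img = np.stack([ndimage.map_coordinates(ch, coords, order=1, mode="reflect")
                        for ch in img])
        m = ndimage.map_coordinates(m, coords, order=0, mode="reflect")
    if rng.random() < cfg.grid_p:
        img, m = _grid_distortion(img, m, rng, cfg.grid_num_steps, cfg.grid_distort_limit)
    if rng.random() < cfg.brightness_contrast_p:
        lim = cfg.brightness_contrast_limit
        img = np.clip(img * (1 + rng.uniform(-lim, lim)) + rng.uniform(-lim, lim), 0, 1)
    if rng.random() < cfg.gauss_noise_p:
        var = rng.uniform(*cfg.gauss_noise_var)
        img = np.clip(img + rng.normal(0, np.sqrt(var) / 255.0, img.shape), 0, 1)
    return np.ascontiguousarray(img), np.ascontiguousarray(m)


def _axis_warp(n: int, steps: int, limit: float, rng) -> np.ndarray:
    """Monotone piecewise-linear coordinate map for grid distortion."""
    widths = np.full(steps, n / steps) * (1 + rng.uniform(-limit, limit, steps))
    knots_src = np.linspace(0, n - 1, steps + 1)
    knots_dst = np.concatenate([[0], np.cumsum(widths)])
    knots_dst = knots_dst / knots_dst[-1] * (n - 1)
    return np.interp(np.arange(n), knots_dst, knots_src)


def _grid_distortion(img, mask, rng, steps, limit):
    h, w = mask.shape
    ry = _axis_warp(h, steps, limit, rng)
    cx = _axis_warp(w, steps, limit, rng)
    coords = np.meshgrid(ry, cx, indexing="ij")
    out_img = np.stack([ndimage.map_coordinates(ch, coords, order=1, mode="reflect")
                        for ch in img])
    out_mask = ndimage.map_coordinates(mask, coords, order=0, mode="reflect")
    return out_img, out_mask


# -- training ----------------------------------------------------------------

class TrainingState:
    """Everything the loss and checkpointing need, in one bundle."""

    def __init__(self, cfg: TrainConfig, rng):
        h, w = cfg.image_size
        self.cfg = cfg
        model_cfg = SegmentationModelConfig(encoder=cfg.encoder, base_width=cfg.base_width)
        self.model = build_model(model_cfg, rng=rng)
        if cfg.head_bias_prior is not None:
            prior = cfg.head_bias_prior
            self.model.head.bias.data[:] = np.log(prior / (1.0 - prior))
        self.spec = ScaleSpec(scales=tuple(cfg.scales), weights=tuple(cfg.scale_weights))
        self.loss_cfg = LossConfig(epsilon=cfg.epsilon,
                                   residual_source=cfg.residual_source)
        self.nu_predictor = None
        self.lambda_maps = None
        self.raw_nu = None
        if cfg.loss_name == "dna_tloss":
            self.nu_predictor = NuPredictor(
                NuPredictorConfig(nu_min=cfg.nu_min,
                                  input_downscale=cfg.nu_input_downscale), rng=rng)
            self.lambda_maps = make_lambda_maps(h, w, self.spec)
        elif cfg.loss_name == "gaussian":
            self.lambda_maps = make_lambda_maps(h, w, self.spec)
            if not cfg.gaussian_lambda_trainable:
                for m in self.lambda_maps:
                    m.requires_grad = False
        elif cfg.loss_name == "tloss_fixed":
            # scalar learnable ν via softplus(raw) + nu_min
            self.raw_nu = Tensor(np.array(float(cfg.loss_params.get("raw_nu0", 1.0))),
                                 requires_grad=True)
        # single precision throughout training: halves memory traffic on the
        # conv stack, which dominates CPU run time
        self.model.astype(np.float32)
        if self.nu_predictor is not None:
            self.nu_predictor.astype(np.float32)
        if self.lambda_maps is not None:
            for m in self.lambda_maps:
                m.data = m.data.astype(np.float32)
        if self.raw_nu is not None:
            self.raw_nu.data = self.raw_nu.data.astype(np.float32)

    def parameters(self):
        params = self.model.parameters()
        if self.nu_predictor is not None:
            params += self.nu_predictor.parameters()
        if self.lambda_maps is not None:
            params += [m for m in self.lambda_maps if m.requires_grad]
        if self.raw_nu is not None:
            params.append(self.raw_nu)
        return params

    def batch_loss(self, images: np.ndarray, masks: np.ndarray):
        """Returns (loss Tensor, mean ν of the batch or nan)."""
        cfg = self.cfg
        logits = self.model(images)
        prob = ad.sigmoid(logits)
        n, _, h, w = logits.shape
        prob2d = prob.reshape(n, h, w)
        source = logits.reshape(n, h, w) if cfg.residual_source == "logits" else prob2d
        mean_nu = float("nan")
        if cfg.loss_name == "dna_tloss":
            nu = self.nu_predictor(images)
            mean_nu = float(nu.data.mean())
            loss = dna_t_loss(source, masks, nu, self.lambda_maps, self.spec, self.loss_cfg)
        elif cfg.loss_name == "gaussian":
            loss = multiscale_gaussian_loss(source, masks, self.lambda_maps,
                                            self.spec, self.loss_cfg)
        elif cfg.loss_name == "tloss_fixed":
            nu = ad.softplus(self.raw_nu) + cfg.nu_min
            mean_nu = float(nu.data)
            lam = Tensor(np.zeros((h, w), dtype=np.float32))
            loss = student_t_nll(source - masks, lam, nu, self.loss_cfg)
        else:
            loss = baseline_loss(cfg.loss_name, prob2d, masks, cfg.loss_params,
                                 self.loss_cfg)
        if (cfg.logit_reg > 0 and cfg.residual_source == "probabilities"
                and cfg.loss_name in ("dna_tloss", "gaussian", "tloss_fixed")):
            loss = loss + cfg.logit_reg * (logits * logits).sum() / n
        return loss, mean_nu

    def predict_probs(self, images: np.ndarray) -> np.ndarray:
        from scipy.special import expit
        return expit(self.model(images).data[:, 0])

    def save(self, path, optimizer: "Adam | None" = None):
        arrays = {f"model_{k}": v for k, v in self.model.state_dict().items()}
        if self.nu_predictor is not None:
            arrays.update({f"nu_{k}": v for k, v in self.nu_predictor.state_dict().items()})
        if self.lambda_maps is not None:
            arrays.update({f"lam_{i}": m.data for i, m in enumerate(self.lambda_maps)})
        if self.raw_nu is not None:
            arrays["raw_nu"] = self.raw_nu.data
        if optimizer is not None:
            arrays["opt_t"] = np.array(optimizer.t)
            for i, (m, v) in enumerate(zip(optimizer.m, optimizer.v)):
                arrays[f"opt_m_{i}"] = m
                arrays[f"opt_v_{i}"] = v
        arrays["config_json"] = np.frombuffer(
            json.dumps(self.cfg.to_dict()).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "TrainingState":
        data = np.load(path)
        cfg = TrainConfig.from_dict(json.loads(bytes(data["config_json"]).decode()))
        state = cls(cfg, np.random.default_rng(cfg.seed))
        state.model.load_state_dict(
            {k[len("model_"):]: data[k] for k in data.files if k.startswith("model_")})
        if state.nu_predictor is not None:
            state.nu_predictor.load_state_dict(
                {k[len("nu_"):]: data[k] for k in data.files if k.startswith("nu_")})
        if state.lambda_maps is not None:
            for i, m in enumerate(state.lambda_maps):
                m.data = data[f"lam_{i}"]
        if state.raw_nu is not None:
            state.raw_nu.data = data["raw_nu"]
        return state


def _diagnose_nonfinite(state: TrainingState, masks) -> str:
    if state.lambda_maps is not None:
        for m in state.lambda_maps:
            if not np.all(np.isfinite(m.data)):
                return "exp-arg (lambda map became non-finite)"
    if state.raw_nu is not None and not np.isfinite(state.raw_nu.data):
        return "gamma-arg (nu became non-finite)"
    return "log-arg (loss evaluated non-finite)"


def _as_arrays(dataset, image_size, use_clean=False):
    if isinstance(dataset, (str, Path)):
        dataset = load_dataset(dataset)
    images = np.stack([s.image for s in dataset])
    masks = np.stack([s.clean_mask if use_clean else s.noisy_mask for s in dataset])
    h, w = image_size
    if images.shape[-2:] != (h, w):
        raise ValueError(f"dataset size {images.shape[-2:]} != configured {(h, w)}")
    return images.astype(np.float32), masks.astype(np.float32)


def train(cfg: TrainConfig, dataset, log_path=None,
          verbose: bool = False) -> tuple[RunResult, TrainingState]:
    """Optimise model + loss parameters on a dataset of SyntheticSamples
    (or a dataset directory).  Fully seeded; returns the per-epoch loss
    series, learning-rate and ν traces, and the trained state."""
    rng = np.random.default_rng(cfg.seed)
    if isinstance(dataset, (str, Path)):
        dataset = load_dataset(dataset)
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    images, masks = _as_arrays(dataset, cfg.image_size)
    n = len(dataset)
    n_val = int(round(cfg.val_fraction * n))
    order = rng.permutation(n)
    train_idx, _val_idx = order[n_val:], order[:n_val]
    if len(train_idx) == 0:
        raise ValueError("validation split leaves no training data")

    state = TrainingState(cfg, rng)
    opt = Adam(state.parameters(), lr=cfg.lr0, weight_decay=cfg.weight_decay)
    steps_per_epoch = int(np.ceil(len(train_idx) / cfg.batch_size))
    total_steps = cfg.epochs * steps_per_epoch

    loss_series, lr_series, nu_trace = [], [], []
    step = 0
    log_rows = []
    for epoch in range(cfg.epochs):
        perm = rng.permutation(train_idx)
        epoch_losses, epoch_nus = [], []
        for start in range(0, len(perm), cfg.batch_size):
            idx = perm[start:start + cfg.batch_size]
            xb, yb = images[idx], masks[idx]
            if cfg.augment:
                pairs = [augment_sample(x, y, rng, cfg.augmentation)
                         for x, y in zip(xb, yb)]
                xb = np.stack([p[0] for p in pairs])
                yb = np.stack([p[1] for p in pairs])
            loss, mean_nu = state.batch_loss(xb, yb)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: {_diagnose_nonfinite(state, yb)}")
            opt.zero_grad()
            loss.backward()
            if cfg.grad_clip is not None:
                clip_grad_norm(opt.params, cfg.grad_clip)
            opt.lr = poly_lr(step, total_steps, cfg.lr0, cfg.poly_power)
            opt.step()
            step += 1
            epoch_losses.append(loss.item())
            if np.isfinite(mean_nu):
                epoch_nus.append(mean_nu)
        loss_series.append(float(np.mean(epoch_losses)))
        lr_series.append(opt.lr)
        nu_trace.append(float(np.mean(epoch_nus)) if epoch_nus else float("nan"))
        log_rows.append({"epoch": epoch, "loss": loss_series[-1],
                         "lr": lr_series[-1], "mean_nu": nu_trace[-1]})
        if verbose:
            print(f"epoch {epoch:4d}  loss {loss_series[-1]:.4f}  "
                  f"lr {lr_series[-1]:.2e}  mean_nu {nu_trace[-1]:.3f}",
                  flush=True)
    if log_path is not None:
        pd.DataFrame(log_rows).to_csv(log_path, index=False)
    if cfg.checkpoint_path is not None:
        state.save(cfg.checkpoint_path, optimizer=opt)
    result = RunResult(loss_series=loss_series, lr_series=lr_series, nu_trace=nu_trace,
                       report=None, seed=cfg.seed, checkpoint_path=cfg.checkpoint_path)
    return result, state


def evaluate(state_or_checkpoint, dataset, use_clean: bool = True,
             batch_size: int = 8) -> MetricReport:
    """Threshold predictions at 0.5 and run the full metric suite
    (against clean masks by default)."""
    state = (TrainingState.load(state_or_checkpoint)
             if isinstance(state_or_checkpoint, (str, Path)) else state_or_checkpoint)
    if isinstance(dataset, (str, Path)):
        dataset = load_dataset(dataset)
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    images, masks = _as_arrays(dataset, state.cfg.image_size, use_clean=use_clean)
    pairs = []
    for start in range(0, len(images), batch_size):
        probs = state.predict_probs(images[start:start + batch_size])
        for p, g in zip(probs, masks[start:start + batch_size]):
            pairs.append((p, predict_mask(_logit(p)), g.astype(np.uint8)))
    return evaluate_dataset(pairs)


def _logit(p, eps=1e-12):
    q = np.clip(p, eps, 1 - eps)
    return np.log(q / (1 - q))


# -- multi-run statistics ----------------------------------------------------

def paired_t_test(differences: np.ndarray) -> dict:
    """Two-tailed paired t on a difference vector, with degenerate-variance
    handling: a zero-variance vector is flagged rather than crashed."""
    d = np.asarray(differences, dtype=np.float64)
    if len(d) < 2:
        raise ValueError("need at least two paired differences")
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            return {"t": 0.0, "p": 1.0, "degenerate": True}
        return {"t": float(np.inf) * np.sign(d.mean()), "p": 0.0, "degenerate": True}
    t, p = stats.ttest_rel(d, np.zeros_like(d))
    return {"t": float(t), "p": float(p), "degenerate": False}


def shapiro_normality(differences: np.ndarray) -> dict:
    d = np.asarray(differences, dtype=np.float64)
    if len(d) < 3 or np.allclose(d.std(ddof=1), 0.0):
        return {"w": float("nan"), "p": float("nan"), "degenerate": True}
    w, p = stats.shapiro(d)
    return {"w": float(w), "p": float(p), "degenerate": False}


def compare_losses(cfg_base: TrainConfig, losses: list, n_runs: int, seeds: list,
                   train_set, test_set, n_comparisons: int = 5,
                   alpha: float = 0.05) -> dict:
    """Train each loss with each seed on the same data and compare against
    the first loss with paired two-tailed t-tests per metric, Shapiro–Wilk
    normality checks and Bonferroni-adjusted significance flags."""
    if n_runs != len(seeds) or n_runs < 2:
        raise ValueError("n_runs must equal len(seeds) and be ≥ 2")
    if len(set(seeds)) != len(seeds):
        raise ValueError("seeds must be distinct for paired runs")
    labels = [name if losses.count(name) == 1 else f"{name}_{i}"
              for i, name in enumerate(losses)]
    per_loss: dict[str, list] = {}
    for label, loss_name in zip(labels, losses):
        reports = []
        for seed in seeds:
            cfg = TrainConfig.from_dict({**cfg_base.to_dict(),
                                         "loss_name": loss_name, "seed": seed})
            _, state = train(cfg, train_set)
            reports.append(evaluate(state, test_set, use_clean=True))
        per_loss[label] = reports
    adjusted_alpha = alpha / n_comparisons
    metric_names = ("dice", "iou", "fdr", "hd_px", "assd_px", "ece", "mi_bits")
    reference = labels[0]
    rows, tests = [], {}
    for label in labels:
        for seed, rep in zip(seeds, per_loss[label]):
            rows.append({"loss": label, "seed": seed, **rep.to_dict()})
        if label == reference:
            continue
        tests[label] = {}
        for metric in metric_names:
            ref_vals = np.array([getattr(r, metric) for r in per_loss[reference]])
            cmp_vals = np.array([getattr(r, metric) for r in per_loss[label]])
            diffs = ref_vals - cmp_vals
            t_res = paired_t_test(diffs)
            tests[label][metric] = {
                "mean_diff": float(diffs.mean()),
                "shapiro": shapiro_normality(diffs),
                **t_res,
                "significant": (not t_res["degenerate"]) and t_res["p"] < adjusted_alpha,
            }
    return {"table": pd.DataFrame(rows), "tests": tests, "reports": per_loss,
            "adjusted_alpha": adjusted_alpha, "reference": reference}
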