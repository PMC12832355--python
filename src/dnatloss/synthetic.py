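"""Synthetic polyp-like images with clean and corrupted annotations.

The generator emulates the gross statistics of colonoscopy frames at
desk scale: a smooth mucosal background with low-frequency texture and
vignetting, one roughly elliptical polyp with a sinusoidally perturbed
boundary and elevated reddish contrast, and specular highlight blobs
placed independently of the polyp.  Masks can be corrupted in controlled
ways (boundary dilation/erosion, boundary jitter, random flips near the
boundary, dropped annotations) to emulate annotator error, which is the
failure mode the robust loss is built for.

Everything is driven by ``numpy.random.default_rng`` seeds: identical
seed and parameters give bit-identical samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage


@dataclass(frozen=True)
class PolypParams:
    """Shape/texture knobs of the generator.

    radius_frac bounds the polyp semi-axes as fractions of min(H, W); the
    defaults target a foreground fraction of roughly 5–30% of pixels,
    matching typical single-polyp frames.  center_jitter_frac keeps the
    polyp near the image centre (lesions are usually centred by the
    endoscopist), which also makes per-pixel statistics comparable
    across a dataset.
    """

    radius_frac: tuple = (0.15, 0.30)
    center_jitter_frac: float = 0.10
    boundary_wobble: float = 0.15     # relative amplitude of the sinusoidal perturbation
    n_highlights: tuple = (2, 6)
    highlight_radius: tuple = (1.5, 4.0)
    polyp_contrast: float = 0.35
    noise_sigma: float = 0.03
    degrade: bool = False             # extra haze/blur, used for "hard" samples


@dataclass(frozen=True)
class CorruptionSpec:
    kind: str = "boundary_dilate"
    magnitude: float = 0.0
    fraction_of_dataset: float = 0.0

    KINDS = ("boundary_dilate", "boundary_erode", "boundary_jitter",
             "random_flip_near_boundary", "drop_annotation")

    def __post_init__(self):
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown corruption kind {self.kind!r}")
        if self.magnitude < 0 or not (0.0 <= self.fraction_of_dataset <= 1.0):
            raise ValueError("invalid corruption parameters")


@dataclass
class SyntheticSample:
    image: np.ndarray          # (3, H, W) float in [0, 1]
    clean_mask: np.ndarray     # (H, W) uint8 in {0, 1}
    noisy_mask: np.ndarray     # (H, W) uint8 in {0, 1}
    corruption: dict = field(default_factory=dict)
    seed: int = 0


def _smooth_noise(rng, h, w, sigma) -> np.ndarray:
    field_ = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma)
    span = field_.max() - field_.min()
    return (field_ - field_.min()) / span if span > 0 else np.zeros((h, w))


def _polyp_mask(rng, h, w, params: PolypParams) -> np.ndarray:
    if params.radius_frac[1] <= 0:
        return np.zeros((h, w), dtype=np.uint8)
    m = min(h, w)
    a = rng.uniform(*params.radius_frac) * m
    b = rng.uniform(*params.radius_frac) * m
    cy = h / 2 + rng.uniform(-1, 1) * params.center_jitter_frac * h
    cx = w / 2 + rng.uniform(-1, 1) * params.center_jitter_frac * w
    theta = rng.uniform(0, np.pi)
    n_harm = rng.integers(2, 5)
    amps = rng.uniform(0, params.boundary_wobble, n_harm)
    phases = rng.uniform(0, 2 * np.pi, n_harm)

    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    ang = np.arctan2(dy, dx)
    ry = dy * np.cos(theta) - dx * np.sin(theta)
    rx = dy * np.sin(theta) + dx * np.cos(theta)
    r_norm = np.sqrt((rx / a) ** 2 + (ry / b) ** 2)
    wobble = np.ones_like(ang)
    for k, (amp, ph) in enumerate(zip(amps, phases), start=2):
        wobble += amp * np.sin(k * ang + ph)
    return (r_norm <= wobble).astype(np.uint8)


def generate_polyp_sample(h: int, w: int, seed: int,
                          params: PolypParams = PolypParams()) -> SyntheticSample:
    """One reproducible polyp-like image with its clean mask."""
    if h < 32 or w < 32:
        raise ValueError("image must be at least 32×32")
    rng = np.random.default_rng(seed)
    mask = _polyp_mask(rng, h, w, params)

    base = 0.45 + 0.25 * _smooth_noise(rng, h, w, sigma=max(h, w) / 8)
    texture = 0.08 * (_smooth_noise(rng, h, w, sigma=3.0) - 0.5)
    yy, xx = np.mgrid[0:h, 0:w]
    r2 = ((yy - h / 2) / (h / 2)) ** 2 + ((xx - w / 2) / (w / 2)) ** 2
    vignette = 1.0 - 0.35 * r2

    polyp_soft = ndimage.gaussian_filter(mask.astype(float), 1.5)
    red = (base + texture + params.polyp_contrast * polyp_soft) * vignette
    green = (0.55 * base + texture + 0.4 * params.polyp_contrast * polyp_soft) * vignette
    blue = (0.45 * base + texture + 0.2 * params.polyp_contrast * polyp_soft) * vignette
    img = np.stack([red, green, blue])

    # specular highlights, independent of the polyp
    n_hl = rng.integers(params.n_highlights[0], params.n_highlights[1] + 1)
    for _ in range(n_hl):
        hy, hx = rng.uniform(0, h), rng.uniform(0, w)
        rad = rng.uniform(*params.highlight_radius)
        blob = np.exp(-(((yy - hy) ** 2 + (xx - hx) ** 2) / (2 * rad**2)))
        img += 0.8 * blob[None]

    img += rng.normal(0, params.noise_sigma, img.shape)
    if params.degrade:
        # annotator-hostile frame: haze plus defocus blur
        img = 0.6 * ndimage.gaussian_filter(img, (0, 2.0, 2.0)) + 0.35
    img = np.clip(img, 0.0, 1.0)
    return SyntheticSample(image=img, clean_mask=mask, noisy_mask=mask.copy(),
                           corruption={"kind": None, "magnitude": 0.0}, seed=seed)


_PLUS = ndimage.generate_binary_structure(2, 1)  # 4-connectivity


def corrupt_mask(mask: np.ndarray, spec: CorruptionSpec, seed: int) -> np.ndarray:
    """Apply one corruption to a binary mask; magnitude 0 is the identity."""
    m = np.asarray(mask).astype(bool)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask must be binary")
    if spec.magnitude == 0:
        return np.asarray(mask).copy()
    rng = np.random.default_rng(seed)
    mag = int(round(spec.magnitude))
    if spec.kind == "boundary_dilate":
        out = ndimage.binary_dilation(m, _PLUS, iterations=mag)
    elif spec.kind == "boundary_erode":
        out = ndimage.binary_erosion(m, _PLUS, iterations=mag)
    elif spec.kind == "boundary_jitter":
        # smooth random displacement field of ~magnitude pixels
        h, w = m.shape
        dy = ndimage.gaussian_filter(rng.standard_normal((h, w)), 4.0)
        dx = ndimage.gaussian_filter(rng.standard_normal((h, w)), 4.0)
        for d in (dy, dx):
            peak = np.abs(d).max()
            if peak > 0:
                d *= spec.magnitude / peak
        yy, xx = np.mgrid[0:h, 0:w]
        out = ndimage.map_coordinates(m.astype(float), [yy + dy, xx + dx],
                                      order=0, mode="nearest") > 0.5
    elif spec.kind == "random_flip_near_boundary":
        dist_out = ndimage.distance_transform_edt(~m)
        dist_in = ndimage.distance_transform_edt(m)
        near = (dist_out <= mag) | (dist_in <= mag)
        flips = near & (rng.random(m.shape) < 0.5)
        out = m ^ flips
    elif spec.kind == "drop_annotation":
        out = np.zeros_like(m)
    else:  # unreachable; CorruptionSpec validates
        raise ValueError(spec.kind)
    return out.astype(np.uint8)


def sample_t_residuals(n: int, nu_true: float, seed: int) -> np.ndarray:
    """i.i.d. standard Student's-t draws (drives the ν-recovery checks)."""
    if n < 1 or nu_true <= 0:
        raise ValueError("need n ≥ 1 and nu_true > 0")
    return np.random.default_rng(seed).standard_t(nu_true, size=n)


def make_dataset(n: int, h: int, w: int, seed: int,
                 corruption: CorruptionSpec | None = None,
                 params: PolypParams = PolypParams(),
                 degrade_corrupted: bool = False) -> list[SyntheticSample]:
    """n samples; a seeded subset of size ≈ fraction_of_dataset·n gets its
    mask corrupted (and optionally its image degraded, emulating the
    correlation between hard frames and bad annotations)."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n)
    n_corrupt = 0
    corrupt_idx: set[int] = set()
    if corruption is not None and corruption.fraction_of_dataset > 0:
        n_corrupt = int(round(corruption.fraction_of_dataset * n))
        corrupt_idx = set(rng.choice(n, size=n_corrupt, replace=False).tolist())
    samples = []
    for i in range(n):
        p = params
        if degrade_corrupted and i in corrupt_idx:
            p = PolypParams(**{**asdict(params), "degrade": True})
        s = generate_polyp_sample(h, w, int(seeds[i]), p)
        if i in corrupt_idx:
            s.noisy_mask = corrupt_mask(s.clean_mask, corruption, int(seeds[i]) + 1)
            s.corruption = {"kind": corruption.kind, "magnitude": corruption.magnitude}
        samples.append(s)
    return samples


# -- PNG round trip ----------------------------------------------------------

def write_dataset(samples: list[SyntheticSample], directory) -> dict:
    """images/*.png (8-bit RGB), masks/*.png and clean_masks/*.png (8-bit,
    {0,255}), plus a JSON manifest; returns the manifest."""
    directory = Path(directory)
    for sub in ("images", "masks", "clean_masks"):
        (directory / sub).mkdir(parents=True, exist_ok=True)
    entries = []
    for i, s in enumerate(samples):
        stem = f"sample_{i:04d}"
        img8 = np.clip(np.round(s.image * 255), 0, 255).astype(np.uint8)
        Image.fromarray(img8.transpose(1, 2, 0)).save(directory / "images" / f"{stem}.png")
        Image.fromarray((s.noisy_mask * 255).astype(np.uint8)).save(
            directory / "masks" / f"{stem}.png")
        Image.fromarray((s.clean_mask * 255).astype(np.uint8)).save(
            directory / "clean_masks" / f"{stem}.png")
        entries.append({"image": f"images/{stem}.png", "mask": f"masks/{stem}.png",
                        "clean_mask": f"clean_masks/{stem}.png",
                        "seed": int(s.seed), "corruption": s.corruption})
    manifest = {"n": len(samples), "samples": entries}
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def load_dataset(directory) -> list[SyntheticSample]:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    samples = []
    for e in manifest["samples"]:
        img = np.asarray(Image.open(directory / e["image"]), dtype=np.float64) / 255.0
        noisy = (np.asarray(Image.open(directory / e["mask"])) > 127).astype(np.uint8)
        clean = (np.asarray(Image.open(directory / e["clean_mask"])) > 127).astype(np.uint8)
        samples.append(SyntheticSample(image=img.transpose(2, 0, 1), clean_mask=clean,
                                       noisy_mask=noisy, corruption=e["corruption"],
                                       seed=e["seed"]))
    return samples
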