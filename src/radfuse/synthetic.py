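"""Synthetic lesion-image generator with controllable multimodal class signal.

Each sample is a 2-D grayscale image containing a single elliptical "lesion"
on a structured background, plus the matching binary ROI mask.  The class
signal is deliberately split across three channels that downstream branches
are differentially sensitive to:

* **texture** -- the lesion interior is thresholded band-pass-filtered noise
  whose characteristic period shifts with the class label.  The interior mean
  and variance are label-independent, so the signal is purely second-order and
  visible to co-occurrence / run-length statistics, not to first-order ones.
* **shape** -- the ellipse axes (and hence eccentricity) shift with the label.
* **context** -- a global background grating whose orientation shifts with the
  label, plus a class-dependent lesion-centre offset.  Both are global-pattern
  cues that a convolutional encoder can pick up, while radiomics restricted to
  the ROI cannot see the background at all.

Texture and context draws are driven by latent variables
``t = sqrt(rho) z + sqrt(1-rho) u`` and ``c = sqrt(rho) z + sqrt(1-rho) v``
with a shared standard-normal ``z``: their correlation equals the
``redundancy`` parameter ``rho`` exactly, which gives a one-knob handle on how
much the two modalities tell the same story.  Low redundancy creates the
regime where the discriminative signal lives in weakly cross-correlated
feature dimensions.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter

__all__ = [
    "SynthConfig",
    "SynthSample",
    "generate_sample",
    "generate_dataset",
    "save_dataset",
    "load_dataset",
    "make_informative_table",
]


@dataclass
class SynthConfig:
    """Study conditions for the synthetic generator.

    Effect sizes are expressed in units of the latent standard deviation:
    ``texture_effect=1`` places adjacent class means one latent-sd apart on
    the texture channel.  ``redundancy`` is the correlation between the
    texture and context latents.
    """

    n_classes: int = 3
    n_per_class: int = 100
    image_size: int = 64
    texture_effect: float = 1.0
    shape_effect: float = 1.0
    context_effect: float = 1.0
    redundancy: float = 0.3
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("n_classes must be at least 2")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be at least 1")
        if self.image_size < 16:
            raise ValueError("image_size must be at least 16")
        if not 0.0 <= self.redundancy <= 1.0:
            raise ValueError("redundancy must lie in [0, 1]")
        for name in ("texture_effect", "shape_effect", "context_effect"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass
class SynthSample:
    image: np.ndarray  # float in [0, 1]
    mask: np.ndarray  # bool, same shape
    label: int
    latent_record: dict = field(default_factory=dict)


def _ellipse_mask(n: int, cy: float, cx: float, a: float, b: float,
                  theta: float) -> np.ndarray:
    yy, xx = np.mgrid[0:n, 0:n]
    y, x = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = x * ct + y * st
    v = -x * st + y * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def generate_sample(cfg: SynthConfig, label: int,
                    rng: np.random.Generator) -> SynthSample:
    """Draw one labelled lesion image under the configured study conditions."""
    if not 0 <= label < cfg.n_classes:
        raise ValueError(f"label {label} out of range for {cfg.n_classes} classes")
    n = cfg.image_size
    centre = (cfg.n_classes - 1) / 2.0

    z, u, v, s = rng.standard_normal(4)
    rho = cfg.redundancy
    t = np.sqrt(rho) * z + np.sqrt(1.0 - rho) * u
    c = np.sqrt(rho) * z + np.sqrt(1.0 - rho) * v

    x_tex = cfg.texture_effect * (label - centre) + t
    x_ctx = cfg.context_effect * (label - centre) + c
    x_shp = cfg.shape_effect * (label - centre) + s

    # -- context: background grating orientation + lesion-centre offset -------
    # saturating map keeps orientations well inside one 180-degree period and
    # leaves the class separation visible under +-15 degree rotation jitter
    theta_bg = 1.2 * np.tanh(0.45 * x_ctx)  # radians
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    phase = rng.uniform(0, 2 * np.pi)
    freq = 4.0  # cycles across the image
    grating = np.sin(
        2 * np.pi * freq * (xx * np.cos(theta_bg) + yy * np.sin(theta_bg)) / n + phase
    )
    image = 0.30 + 0.10 * grating

    offset = 0.06 * n * np.tanh(0.5 * x_ctx)
    cy = n / 2.0 + rng.normal(0, 0.02 * n)
    cx = n / 2.0 + offset + rng.normal(0, 0.02 * n)

    # -- shape: ellipse axes / eccentricity -----------------------------------
    a0 = 0.22 * n
    a = np.clip(a0 * (1.0 + 0.08 * x_shp), 2.6, 0.42 * n)
    b = np.clip(a0 * 0.75 * (1.0 - 0.08 * x_shp), 2.6, 0.42 * n)
    theta_roi = rng.uniform(0, np.pi)
    mask = _ellipse_mask(n, cy, cx, a, b, theta_roi)
    if mask.sum() < 16:  # clipping floor guarantees this never triggers at n>=16
        mask = _ellipse_mask(n, n / 2.0, n / 2.0, max(a, 3.0), max(b, 3.0), theta_roi)

    # -- texture: thresholded band-pass noise, period shifts with label -------
    period = float(np.clip(4.0 * np.exp(0.18 * x_tex), 2.0, 12.0))
    white = rng.standard_normal((n, n))
    band = gaussian_filter(white, period / 4.0) - gaussian_filter(white, period / 2.0)
    pattern = band > np.median(band)  # exact 50/50 split: mean is label-free
    interior = np.where(pattern, 0.70, 0.45)
    image = np.where(mask, interior, image)

    if cfg.noise_sd > 0:
        image = image + rng.normal(0.0, cfg.noise_sd, size=(n, n))
    image = np.clip(image, 0.0, 1.0)

    record = {
        "z": z, "u": u, "v": v, "s": s,
        "texture_latent": t, "context_latent": c,
        "x_tex": x_tex, "x_ctx": x_ctx, "x_shp": x_shp,
        "period": period, "theta_bg": theta_bg,
        "axis_a": float(a), "axis_b": float(b),
    }
    return SynthSample(image=image, mask=mask, label=int(label), latent_record=record)


def generate_dataset(cfg: SynthConfig) -> tuple[list[SynthSample], pd.DataFrame]:
    """Balanced dataset of ``n_classes * n_per_class`` samples plus manifest."""
    rng = np.random.default_rng(cfg.seed)
    samples: list[SynthSample] = []
    rows = []
    idx = 0
    for label in range(cfg.n_classes):
        for _ in range(cfg.n_per_class):
            samples.append(generate_sample(cfg, label, rng))
            rows.append(
                {
                    "id": f"sample_{idx:05d}",
                    "image_path": f"sample_{idx:05d}.png",
                    "mask_path": f"sample_{idx:05d}_mask.png",
                    "label": label,
                }
            )
            idx += 1
    return samples, pd.DataFrame(rows)


def save_dataset(samples: Sequence[SynthSample], manifest: pd.DataFrame,
                 out_dir: str) -> str:
    """Write 8-bit grayscale PNGs, 0/255 mask PNGs and the manifest CSV."""
    os.makedirs(out_dir, exist_ok=True)
    for sample, row in zip(samples, manifest.itertuples(index=False)):
        img8 = np.round(sample.image * 255).astype(np.uint8)
        Image.fromarray(img8, mode="L").save(os.path.join(out_dir, row.image_path))
        mask8 = (sample.mask.astype(np.uint8)) * 255
        Image.fromarray(mask8, mode="L").save(os.path.join(out_dir, row.mask_path))
    manifest_path = os.path.join(out_dir, "manifest.csv")
    manifest.to_csv(manifest_path, index=False)
    return manifest_path


def load_dataset(manifest_path: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read images/masks/labels referenced by a manifest CSV.

    Returns float images in [0, 1], boolean masks and integer labels.
    """
    manifest = pd.read_csv(manifest_path)
    base = os.path.dirname(os.path.abspath(manifest_path))
    images, masks, labels = [], [], []
    for row in manifest.itertuples(index=False):
        img = np.asarray(Image.open(os.path.join(base, row.image_path)).convert("I"))
        scale = 65535.0 if img.max() > 255 else 255.0
        images.append(img.astype(float) / scale)
        mask = np.asarray(Image.open(os.path.join(base, row.mask_path)).convert("L"))
        masks.append(mask > 0)
        labels.append(int(row.label))
    return np.stack(images), np.stack(masks), np.asarray(labels)


def make_informative_table(n_samples: int = 500, n_features: int = 200,
                           n_informative: int = 10, n_classes: int = 3,
                           effect: float = 1.0, seed: int = 0):
    """Gaussian feature table where only the first ``n_informative`` columns
    carry class signal, for exercising embedded feature selection.

    Labels are sampled from a multinomial logit whose coefficients of size
    ``effect`` sit on the informative columns (feature ``i`` supports class
    ``i mod n_classes``).  Returns ``(X, y, informative_indices)``.
    """
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_samples, n_features))
    coef = np.zeros((n_classes, n_features))
    for i in range(n_informative):
        coef[i % n_classes, i] = effect
    logits = X @ coef.T
    p = np.exp(logits - logits.max(axis=1, keepdims=True))
    p /= p.sum(axis=1, keepdims=True)
    y = np.array([rng.choice(n_classes, p=pi) for pi in p])
    return X, y, np.arange(n_informative)
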