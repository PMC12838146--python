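"""Handcrafted radiomic feature extraction from (image, ROI-mask) pairs.

Implements the classic feature families used in quantitative image analysis:
first-order intensity statistics, 2-D shape descriptors, gray-level
co-occurrence (GLCM) and gray-level run-length (GLRLM) texture features.
Intensities are discretized by fixed-bin-count, equal-width quantization
inside the ROI before texture matrices are built; pairs and runs are only
counted when every participating pixel lies inside the ROI.  When no mask is
supplied the whole image is treated as the ROI.

The co-occurrence and run-length counting is implemented here (rather than
through ``skimage.feature.graycomatrix``) because masked-ROI pair counting is
required; the unmasked single-angle case is cross-checked against scikit-image
in the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from skimage import measure

__all__ = [
    "FeatureConfig",
    "FeatureTable",
    "RadiomicsExtractor",
    "quantize",
    "first_order_features",
    "shape2d_features",
    "glcm",
    "glcm_features",
    "glrlm_features",
    "extract_features",
]

# angle (degrees) -> (row offset, col offset) per unit distance
_ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}
_STANDARD_ANGLES = (0, 45, 90, 135)


@dataclass
class FeatureConfig:
    """Extraction settings: discretization and texture-matrix geometry."""

    n_levels: int = 32
    distances: tuple[int, ...] = (1, 2, 3)
    angles: tuple[int, ...] = _STANDARD_ANGLES

    def __post_init__(self):
        if self.n_levels < 2:
            raise ValueError("n_levels must be at least 2")
        for a in self.angles:
            if a not in _ANGLE_OFFSETS:
                raise ValueError(f"unsupported angle {a}; use 0/45/90/135 degrees")


@dataclass
class FeatureTable:
    """Samples-by-features matrix with stable, ordered feature names."""

    values: np.ndarray
    feature_names: list[str]
    standardized: bool = False
    selection: list[int] | None = None
    ids: list[str] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D samples x features matrix")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length must match the value width")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature table contains non-finite values")

    def to_frame(self) -> pd.DataFrame:
        ids = self.ids or [f"sample_{i:05d}" for i in range(len(self.values))]
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "id", ids)
        return df

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str) -> "FeatureTable":
        df = pd.read_csv(path)
        return cls(
            values=df.iloc[:, 1:].to_numpy(float),
            feature_names=list(df.columns[1:]),
            ids=list(df.iloc[:, 0].astype(str)),
        )


def _validate_pair(image: np.ndarray, mask: np.ndarray | None):
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or min(image.shape) < 4:
        raise ValueError("image must be 2-D and at least 4x4")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    if mask is None:
        mask = np.ones(image.shape, dtype=bool)
    else:
        mask = np.asarray(mask) != 0
        if mask.shape != image.shape:
            raise ValueError("mask shape must match image shape")
    return image, mask


def quantize(image: np.ndarray, mask: np.ndarray | None, n_levels: int) -> np.ndarray:
    """Equal-width discretization of ROI intensities to ``{0..n_levels-1}``.

    Bins are half-open between the ROI minimum and maximum, with the maximum
    assigned to the top level; a constant ROI maps entirely to level 0.
    Pixels outside the ROI are marked ``-1``.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be at least 2")
    image, mask = _validate_pair(image, mask)
    if not mask.any():
        raise ValueError("empty ROI")
    vals = image[mask]
    lo, hi = vals.min(), vals.max()
    out = np.full(image.shape, -1, dtype=np.int64)
    if hi == lo:
        out[mask] = 0
        return out
    levels = np.floor((image - lo) / (hi - lo) * n_levels).astype(np.int64)
    out[mask] = np.clip(levels[mask], 0, n_levels - 1)
    return out


# -- first-order statistics ----------------------------------------------------


def first_order_features(image: np.ndarray, mask: np.ndarray | None = None,
                         entropy_bins: int = 32) -> dict[str, float]:
    """Intensity-distribution statistics of the ROI.

    Standard deviation, skewness and kurtosis use the population convention;
    skewness and excess kurtosis of a constant ROI are defined as 0 so that
    degenerate regions never propagate NaNs into the learner.
    """
    image, mask = _validate_pair(image, mask)
    if not mask.any():
        raise ValueError("empty ROI")
    x = image[mask].astype(float)
    mean = x.mean()
    var = x.var()  # population
    sd = np.sqrt(var)
    centred = x - mean
    if sd > 0:
        skew = np.mean(centred**3) / sd**3
        kurt = np.mean(centred**4) / sd**4 - 3.0
    else:
        skew = kurt = 0.0
    p10, p90 = np.percentile(x, [10, 90])
    q1, q3 = np.percentile(x, [25, 75])
    if x.max() > x.min():
        hist, _ = np.histogram(x, bins=entropy_bins, range=(x.min(), x.max()))
        p = hist / hist.sum()
        p = p[p > 0]
        entropy = float(-(p * np.log2(p)).sum())
        uniformity = float((p**2).sum())
    else:
        entropy, uniformity = 0.0, 1.0
    return {
        "fo_mean": float(mean),
        "fo_sd": float(sd),
        "fo_variance": float(var),
        "fo_skewness": float(skew),
        "fo_kurtosis": float(kurt),
        "fo_min": float(x.min()),
        "fo_max": float(x.max()),
        "fo_median": float(np.median(x)),
        "fo_range": float(x.max() - x.min()),
        "fo_p10": float(p10),
        "fo_p90": float(p90),
        "fo_iqr": float(q3 - q1),
        "fo_rms": float(np.sqrt(np.mean(x**2))),
        "fo_mad": float(np.mean(np.abs(centred))),
        "fo_energy": float(np.sum(x**2)),
        "fo_entropy": entropy,
        "fo_uniformity": uniformity,
    }


# -- 2-D shape ----------------------------------------------------------------


def shape2d_features(mask: np.ndarray) -> dict[str, float]:
    """Shape descriptors of the largest connected ROI component.

    Perimeter uses the weighted boundary-segment estimator of
    ``skimage.measure.perimeter`` so that a rasterized disk has circularity
    ``4*pi*A/P**2`` close to 1.  Only translation-invariant descriptors are
    reported (no centroid), keeping the whole feature vector shift-invariant.
    """
    mask = np.asarray(mask) != 0
    if not mask.any():
        raise ValueError("empty mask")
    labelled = measure.label(mask, connectivity=1)
    props = measure.regionprops(labelled)
    largest = max(props, key=lambda p: p.area)
    component = labelled == largest.label
    area = float(largest.area)
    perimeter = float(measure.perimeter(component, neighborhood=4))
    circularity = 4.0 * np.pi * area / perimeter**2 if perimeter > 0 else 0.0
    return {
        "shape_area": area,
        "shape_perimeter": perimeter,
        "shape_circularity": float(circularity),
        "shape_eccentricity": float(largest.eccentricity),
        "shape_major_axis": float(largest.axis_major_length),
        "shape_minor_axis": float(largest.axis_minor_length),
        "shape_extent": float(largest.extent),
        "shape_solidity": float(largest.solidity),
    }


# -- GLCM ---------------------------------------------------------------------


def glcm(image_q: np.ndarray, mask: np.ndarray | None = None, distance: int = 1,
         angles: Sequence[int] = _STANDARD_ANGLES) -> np.ndarray:
    """Normalized, symmetric co-occurrence matrix of a discretized image.

    Pairs are counted in both directions for every requested angle, summed
    over angles and normalized to unit total mass.  Both pixels of a pair must
    lie inside the ROI.
    """
    image_q = np.asarray(image_q)
    if image_q.ndim != 2:
        raise ValueError("image_q must be 2-D")
    if mask is None:
        mask = image_q >= 0
    else:
        mask = (np.asarray(mask) != 0) & (image_q >= 0)
    n_levels = int(image_q[mask].max()) + 1 if mask.any() else 0
    if n_levels < 1:
        raise ValueError("empty ROI")
    counts = np.zeros((n_levels, n_levels), dtype=float)
    h, w = image_q.shape
    for angle in angles:
        dr, dc = _ANGLE_OFFSETS[angle]
        dr, dc = dr * distance, dc * distance
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        if r0 >= r1 or c0 >= c1:
            continue
        src = image_q[r0:r1, c0:c1]
        dst = image_q[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        valid = mask[r0:r1, c0:c1] & mask[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        i, j = src[valid], dst[valid]
        pair_counts = np.bincount(i * n_levels + j, minlength=n_levels**2)
        counts += pair_counts.reshape(n_levels, n_levels)
    counts = counts + counts.T  # symmetric counting
    total = counts.sum()
    if total == 0:
        raise ValueError("no valid pixel pairs inside the ROI")
    return counts / total


def glcm_features(P: np.ndarray) -> dict[str, float]:
    """Texture statistics of a normalized co-occurrence matrix."""
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("P must be a square matrix")
    total = P.sum()
    if total <= 0:
        raise ValueError("co-occurrence matrix has zero mass")
    if not np.isclose(total, 1.0, atol=1e-6):
        P = P / total
    n = P.shape[0]
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    diff = i - j
    contrast = float((diff**2 * P).sum())
    dissimilarity = float((np.abs(diff) * P).sum())
    energy = float((P**2).sum())
    homogeneity = float((P / (1.0 + np.abs(diff))).sum())
    px = P.sum(axis=1)
    mu = float((np.arange(n) * px).sum())
    var = float(((np.arange(n) - mu) ** 2 * px).sum())
    if var > 0:
        correlation = float((((i - mu) * (j - mu) * P).sum()) / var)
    else:
        correlation = 0.0  # zero-variance marginals convention
    pos = P[P > 0]
    entropy = float(-(pos * np.log2(pos)).sum())
    return {
        "contrast": contrast,
        "dissimilarity": dissimilarity,
        "energy": energy,
        "homogeneity": homogeneity,
        "correlation": correlation,
        "entropy": entropy,
    }


# -- GLRLM --------------------------------------------------------------------


def _run_lengths(lines: list[np.ndarray], n_levels: int, max_len: int) -> np.ndarray:
    """Run-length matrix from 1-D level sequences; -1 entries break runs."""
    sep = np.full(1, -1, dtype=np.int64)
    parts: list[np.ndarray] = []
    for line in lines:
        parts.append(line.astype(np.int64))
        parts.append(sep)
    seq = np.concatenate(parts) if parts else sep
    boundaries = np.flatnonzero(np.diff(seq) != 0) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [len(seq)]))
    levels = seq[starts]
    lengths = ends - starts
    keep = levels >= 0
    levels, lengths = levels[keep], lengths[keep]
    R = np.zeros((n_levels, max_len), dtype=float)
    np.add.at(R, (levels, lengths - 1), 1.0)
    return R


def _direction_lines(image_q: np.ndarray, masked: np.ndarray, angle: int) -> list[np.ndarray]:
    if angle == 0:
        return [masked[r] for r in range(masked.shape[0])]
    if angle == 90:
        return [masked[:, c] for c in range(masked.shape[1])]
    if angle == 135:  # direction (1, 1): main diagonals
        h, w = masked.shape
        return [masked.diagonal(k) for k in range(-(h - 1), w)]
    if angle == 45:  # direction (-1, 1): anti-diagonals
        flipped = np.flipud(masked)
        h, w = flipped.shape
        return [flipped.diagonal(k) for k in range(-(h - 1), w)]
    raise ValueError(f"unsupported angle {angle}")


def glrlm_features(image_q: np.ndarray, mask: np.ndarray | None = None,
                   angles: Sequence[int] = _STANDARD_ANGLES) -> dict[str, float]:
    """Run-length statistics averaged over directions.

    A run is a maximal stretch of equal gray level along a direction with every
    pixel inside the ROI.  Features: short/long-run emphasis (SRE/LRE),
    gray-level and run-length nonuniformity (GLN/RLN) and run percentage (RP).
    """
    image_q = np.asarray(image_q)
    if mask is None:
        mask = image_q >= 0
    else:
        mask = (np.asarray(mask) != 0) & (image_q >= 0)
    if not mask.any():
        raise ValueError("empty ROI")
    n_levels = int(image_q[mask].max()) + 1
    n_pixels = int(mask.sum())
    masked = np.where(mask, image_q, -1)
    max_len = max(image_q.shape)
    feats = {k: 0.0 for k in ("glrlm_sre", "glrlm_lre", "glrlm_gln", "glrlm_rln", "glrlm_rp")}
    for angle in angles:
        R = _run_lengths(_direction_lines(image_q, masked, angle), n_levels, max_len)
        nr = R.sum()
        if nr == 0:
            continue
        jj = np.arange(1, max_len + 1, dtype=float)
        feats["glrlm_sre"] += float((R / jj**2).sum() / nr)
        feats["glrlm_lre"] += float((R * jj**2).sum() / nr)
        feats["glrlm_gln"] += float((R.sum(axis=1) ** 2).sum() / nr)
        feats["glrlm_rln"] += float((R.sum(axis=0) ** 2).sum() / nr)
        feats["glrlm_rp"] += float(nr / n_pixels)
    return {k: v / len(angles) for k, v in feats.items()}


# -- full extraction ----------------------------------------------------------


def extract_features(image: np.ndarray, mask: np.ndarray | None = None,
                     config: FeatureConfig | None = None) -> tuple[np.ndarray, list[str]]:
    """Concatenated feature families in deterministic order.

    Order: first-order, shape, GLCM (per configured distance, angle-summed),
    GLRLM (direction-averaged).  Names are stable across calls.
    """
    config = config or FeatureConfig()
    image, mask = _validate_pair(image, mask)
    feats: dict[str, float] = {}
    feats.update(first_order_features(image, mask))
    feats.update(shape2d_features(mask))
    image_q = quantize(image, mask, config.n_levels)
    for dist in config.distances:
        P = glcm(image_q, mask, distance=dist, angles=config.angles)
        for name, value in glcm_features(P).items():
            feats[f"glcm_d{dist}_{name}"] = value
    feats.update(glrlm_features(image_q, mask, angles=config.angles))
    names = list(feats.keys())
    values = np.array([feats[n] for n in names], dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite feature value produced")
    return values, names


@dataclass
class RadiomicsExtractor:
    """Sklearn-style transformer turning (image, mask) pairs into a FeatureTable."""

    config: FeatureConfig = field(default_factory=FeatureConfig)

    def get_params(self, deep: bool = True) -> dict:
        return {"config": self.config}

    def set_params(self, **params) -> "RadiomicsExtractor":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X=None, y=None) -> "RadiomicsExtractor":
        return self  # stateless

    def extract_table(self, images: np.ndarray,
                      masks: np.ndarray | None = None,
                      ids: list[str] | None = None) -> FeatureTable:
        rows, names = [], None
        for k, image in enumerate(images):
            mask = None if masks is None else masks[k]
            values, names = extract_features(image, mask, self.config)
            rows.append(values)
        return FeatureTable(values=np.vstack(rows), feature_names=list(names), ids=ids)

    def transform(self, X, masks=None):
        return self.extract_table(np.asarray(X), masks).values
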