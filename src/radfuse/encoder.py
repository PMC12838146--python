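"""The deep-feature branch: image encoder, linear projection, L2 normalization.

The encoder contract is deliberately small: any module mapping a batch of
grayscale images (B, H, W) to a (B, native_dim) matrix qualifies.  The default
desk-scale backbone is a four-block strided CNN with global average pooling
(~100k parameters, trainable end-to-end, native_dim 128).  Its output is
linearly projected into the unified fusion dimension ``d`` and row-wise
L2-normalized before entering the fusion block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._tensor import Tensor, as_tensor
from .nn import BatchNorm2d, Conv2d, Linear, Module, ReLU

__all__ = [
    "EncoderConfig",
    "SmallCNNEncoder",
    "DeepBranch",
    "encode",
    "project",
    "l2_normalize",
    "l2_normalize_t",
]

_NORM_EPS = 1e-12


@dataclass
class EncoderConfig:
    backbone_id: str = "small_cnn"
    native_dim: int = 128
    unified_dim: int = 512


class SmallCNNEncoder(Module):
    """Four strided conv blocks (conv/BN/ReLU) + global average pooling.

    Input (B, H, W) grayscale in [0, 1]; output (B, native_dim).  Channel
    widths double per block up to ``native_dim``.
    """

    def __init__(self, native_dim: int, rng: np.random.Generator, dtype=np.float64):
        super().__init__()
        widths = [max(native_dim // 8, 4), max(native_dim // 4, 8),
                  max(native_dim // 2, 16), native_dim]
        in_ch = 1
        blocks: list[Module] = []
        for w in widths:
            blocks.append(Conv2d(in_ch, w, 3, rng, stride=2, padding=1, dtype=dtype))
            blocks.append(BatchNorm2d(w, dtype=dtype))
            blocks.append(ReLU())
            in_ch = w
        self.blocks = blocks
        self.native_dim = native_dim

    def forward(self, images: Tensor) -> Tensor:
        x = as_tensor(images)
        if x.ndim == 3:
            b, h, w = x.shape
            x = x.reshape(b, 1, h, w)
        elif x.ndim != 4:
            raise ValueError("expected (B, H, W) or (B, 1, H, W) images")
        for block in self.blocks:
            x = block(x)
        return x.mean(axis=(2, 3))  # global average pooling


class DeepBranch(Module):
    """Encoder followed by the linear map into the unified dimension."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator, dtype=np.float64):
        super().__init__()
        if cfg.backbone_id != "small_cnn":
            raise ValueError(f"unknown backbone '{cfg.backbone_id}'")
        self.encoder = SmallCNNEncoder(cfg.native_dim, rng, dtype=dtype)
        self.proj = Linear(cfg.native_dim, cfg.unified_dim, rng, dtype=dtype)
        self.cfg = cfg

    def forward(self, images: Tensor) -> Tensor:
        return self.proj(self.encoder(images))


def encode(images: np.ndarray, encoder: Module) -> np.ndarray:
    """Raw encoder features of a batch, computed in eval mode."""
    was_training = encoder.training
    encoder.eval()
    out = encoder(Tensor(np.asarray(images, dtype=float))).data
    if was_training:
        encoder.train()
    return out


def project(F: np.ndarray, weights: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Affine map ``F @ W + b`` with W of shape (native_dim, d)."""
    F = np.asarray(F, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if F.shape[1] != weights.shape[0]:
        raise ValueError(
            f"dimension mismatch: features {F.shape[1]}, weights {weights.shape[0]}"
        )
    return F @ weights + np.asarray(bias, dtype=float)


def l2_normalize(X: np.ndarray, eps: float = _NORM_EPS) -> np.ndarray:
    """Row-wise L2 normalization; all-zero rows are returned as zeros."""
    X = np.asarray(X, dtype=float)
    norms = np.linalg.norm(X, axis=-1, keepdims=True)
    return X / np.maximum(norms, eps)


def l2_normalize_t(X: Tensor, eps: float = _NORM_EPS) -> Tensor:
    """Differentiable row-wise L2 normalization (autodiff path)."""
    X = as_tensor(X)
    norms = (X * X).sum(axis=-1, keepdims=True).sqrt()
    return X / norms.maximum(eps)
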