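"""Cross-covariance decorrelation regularizer with a scheduled weight.

Two latent views ``H1 = MLP1(Rp)`` and ``H2 = MLP2(Fn)`` of the radiomics and
deep branches are centered per feature dimension and their joint covariance

    C = [[C11, C12], [C21, C22]],   C11 = H1'^T H1'/(B-1) + eps*I, etc.

is formed batch-wise.  Only the cross block enters the loss,

    L_dec = ||C12||_F^2 = sum_ij C12[i,j]^2,

which penalizes *linear* dependence between the views while leaving each
view's internal variance structure untouched (no eigenvalue/whitening terms).
The total training objective is ``L_tot = L_ce + alpha * L_dec`` with a
linear ramp ``alpha = alpha_max * epoch / n_epochs`` so that early training
focuses on classification and the independence pressure grows over time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._tensor import Tensor, as_tensor
from .nn import MLP, Module

__all__ = [
    "CovarianceBlocks",
    "LossState",
    "ViewProjectors",
    "project_views",
    "center",
    "covariance_blocks",
    "decorrelation_loss",
    "decorrelation_loss_t",
    "alpha_schedule",
    "total_loss",
    "mean_abs_cross_correlation",
]

DEFAULT_EPSILON = 1e-4


@dataclass
class CovarianceBlocks:
    C11: np.ndarray
    C12: np.ndarray
    C21: np.ndarray
    C22: np.ndarray
    epsilon: float


@dataclass
class LossState:
    L_ce: float
    L_dec: float
    alpha: float
    alpha_max: float
    epoch: int
    n_epochs: int

    @property
    def L_tot(self) -> float:
        return total_loss(self.L_ce, self.L_dec, self.alpha)


class ViewProjectors(Module):
    """Per-branch MLPs mapping both views into a shared d-dimensional space.

    One hidden layer of width ``hidden_dim`` (default d) with a smooth
    nonlinearity; output width d for both branches.  Outputs are row-wise
    L2-normalized: the cross-covariance penalty alone has a trivial minimizer
    (deflate the latent scale toward zero), so the views are pinned to the
    unit sphere, which keeps the loss scale-free and the regularizer
    non-degenerate.
    """

    def __init__(self, d: int, rng: np.random.Generator,
                 hidden_dim: int | None = None, dtype=np.float64):
        super().__init__()
        hidden_dim = hidden_dim or d
        self.mlp1 = MLP(d, hidden_dim, d, rng, dtype=dtype)
        self.mlp2 = MLP(d, hidden_dim, d, rng, dtype=dtype)
        self.d = d

    def forward(self, Rp: Tensor, Fn: Tensor) -> tuple[Tensor, Tensor]:
        from .encoder import l2_normalize_t  # local import avoids a cycle

        return (
            l2_normalize_t(self.mlp1(as_tensor(Rp))),
            l2_normalize_t(self.mlp2(as_tensor(Fn))),
        )


def project_views(Rp: np.ndarray, Fn: np.ndarray,
                  proj: ViewProjectors) -> tuple[np.ndarray, np.ndarray]:
    """Eval-mode latent views as plain arrays."""
    Rp, Fn = np.asarray(Rp, float), np.asarray(Fn, float)
    if Rp.shape[1] != proj.d or Fn.shape[1] != proj.d:
        raise ValueError(f"both views must have width {proj.d}")
    was_training = proj.training
    proj.eval()
    H1, H2 = proj(Tensor(Rp), Tensor(Fn))
    if was_training:
        proj.train()
    return H1.data, H2.data


def center(H: np.ndarray) -> np.ndarray:
    """Subtract the per-feature mean over the batch."""
    H = np.asarray(H, dtype=float)
    if H.shape[0] < 2:
        raise ValueError("centering needs at least 2 samples")
    return H - H.mean(axis=0, keepdims=True)


def covariance_blocks(H1c: np.ndarray, H2c: np.ndarray,
                      epsilon: float = DEFAULT_EPSILON) -> CovarianceBlocks:
    """Blocks of the joint 2d-by-2d covariance of two centered views."""
    H1c, H2c = np.asarray(H1c, float), np.asarray(H2c, float)
    B = H1c.shape[0]
    if B < 2 or H2c.shape[0] != B:
        raise ValueError("need matching batches with at least 2 samples")
    d = H1c.shape[1]
    eye = np.eye(d)
    C11 = H1c.T @ H1c / (B - 1) + epsilon * eye
    C22 = H2c.T @ H2c / (B - 1) + epsilon * np.eye(H2c.shape[1])
    C12 = H1c.T @ H2c / (B - 1)
    return CovarianceBlocks(C11=C11, C12=C12, C21=C12.T.copy(), C22=C22,
                            epsilon=epsilon)


def decorrelation_loss(C12: np.ndarray) -> float:
    """Squared Frobenius norm of the cross-covariance block."""
    C12 = np.asarray(C12, dtype=float)
    return float(np.sum(C12**2))


def decorrelation_loss_t(H1: Tensor, H2: Tensor) -> Tensor:
    """Differentiable loss from raw (uncentered) views: center, cross-cov, ||.||_F^2."""
    H1, H2 = as_tensor(H1), as_tensor(H2)
    B = H1.shape[0]
    if B < 2:
        raise ValueError("decorrelation loss needs batch size >= 2")
    H1c = H1 - H1.mean(axis=0, keepdims=True)
    H2c = H2 - H2.mean(axis=0, keepdims=True)
    C12 = (H1c.swapaxes(0, 1) @ H2c) * (1.0 / (B - 1))
    return (C12 * C12).sum()


def alpha_schedule(epoch: int, n_epochs: int, alpha_max: float) -> float:
    """Linear ramp from 0 at epoch 0 to ``alpha_max`` at the final epoch."""
    if n_epochs < 1:
        raise ValueError("n_epochs must be at least 1")
    if not 0 <= epoch <= n_epochs:
        raise ValueError(f"epoch {epoch} outside [0, {n_epochs}]")
    return alpha_max * epoch / n_epochs


def total_loss(L_ce: float, L_dec: float, alpha: float) -> float:
    """Weighted sum ``L_ce + alpha * L_dec``."""
    return L_ce + alpha * L_dec


def mean_abs_cross_correlation(H1: np.ndarray, H2: np.ndarray,
                               eps: float = 1e-12) -> float:
    """Mean absolute entry of the cross-correlation matrix between two views.

    Each view is centered and scaled to unit per-dimension variance first, so
    the value is scale-free; 0 means no linear dependence between any pair of
    dimensions across views.
    """
    H1, H2 = np.asarray(H1, float), np.asarray(H2, float)
    B = H1.shape[0]
    Z1 = center(H1) / np.maximum(H1.std(axis=0, ddof=1), eps)
    Z2 = center(H2) / np.maximum(H2.std(axis=0, ddof=1), eps)
    corr = Z1.T @ Z2 / (B - 1)
    return float(np.mean(np.abs(corr)))
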