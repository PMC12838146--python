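"""Spline-based (Kolmogorov-Arnold) classification head.

Instead of fixed node activations, every edge of a KAN layer carries a
learnable univariate function: a B-spline expansion plus a smooth base term,

    out[b, o] = sum_i [ base_weight[o, i] * silu(x[b, i])
                        + scale[o, i] * sum_m coeffs[o, i, m] * B_m(x[b, i]) ]

where ``B_m`` are order-``k`` B-spline basis functions (Cox-de Boor recursion)
on a uniform grid over [lo, hi] with ``grid_size`` interior intervals, giving
``grid_size + order`` bases.  Defaults follow the common KAN recipe: grid size
5, order 3, grid interval [-1, 1] with a batch norm in front of the head to
keep inputs in range, spline coefficients initialised as small noise so the
layer starts out near-linear.  The learned edge functions are explicitly
sampleable for visualisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from ._tensor import Tensor, as_tensor
from .nn import BatchNorm1d, Linear, Module

__all__ = [
    "SplineGrid",
    "KANLayerParams",
    "bspline_basis",
    "bspline_basis_t",
    "kan_layer_forward",
    "kan_classify",
    "KANLayer",
    "KANHead",
    "FCHead",
    "fit_univariate_spline",
]


@dataclass
class SplineGrid:
    """Uniform extended knot grid for B-splines of a given order."""

    lo: float = -1.0
    hi: float = 1.0
    grid_size: int = 5
    order: int = 3

    def __post_init__(self):
        if self.lo >= self.hi:
            raise ValueError("grid requires lo < hi")
        if self.grid_size < 1 or self.order < 1:
            raise ValueError("grid_size and order must be positive")

    @property
    def h(self) -> float:
        return (self.hi - self.lo) / self.grid_size

    @property
    def knots(self) -> np.ndarray:
        """Extended knot vector of length ``grid_size + 2*order + 1``."""
        k = self.order
        return self.lo + self.h * np.arange(-k, self.grid_size + k + 1)

    @property
    def n_basis(self) -> int:
        return self.grid_size + self.order


@dataclass
class KANLayerParams:
    """Plain-array parameters of one KAN layer (for the functional path)."""

    in_dim: int
    out_dim: int
    spline_coeffs: np.ndarray  # (out, in, n_basis)
    base_weight: np.ndarray    # (out, in)
    scale: np.ndarray          # (out, in)
    grid: SplineGrid = field(default_factory=SplineGrid)
    base_activation: str = "silu"  # 'silu' (default) or 'identity'


def _base_act(x: np.ndarray, kind: str) -> np.ndarray:
    if kind == "silu":
        return x * expit(x)
    if kind == "identity":
        return x
    raise ValueError(f"unknown base activation '{kind}'")


def bspline_basis(x: np.ndarray, grid: SplineGrid) -> np.ndarray:
    """All ``grid_size + order`` basis values at ``x`` (any shape).

    Returns an array of shape ``x.shape + (n_basis,)``; values are
    nonnegative and sum to 1 on the interior of [lo, hi).
    """
    x = np.asarray(x, dtype=float)
    t = grid.knots
    n0 = len(t) - 1  # number of zero-order intervals
    b = ((t[:-1] <= x[..., None]) & (x[..., None] < t[1:])).astype(float)
    for r in range(1, grid.order + 1):
        m = n0 - r
        left = (x[..., None] - t[:m]) / (t[r : r + m] - t[:m]) * b[..., :m]
        right = (t[r + 1 : r + 1 + m] - x[..., None]) / (
            t[r + 1 : r + 1 + m] - t[1 : 1 + m]
        ) * b[..., 1 : 1 + m]
        b = left + right
    return b


def bspline_basis_t(x: Tensor, grid: SplineGrid) -> Tensor:
    """Differentiable Cox-de Boor recursion (gradient flows through x)."""
    x = as_tensor(x)
    t = grid.knots
    n0 = len(t) - 1
    xe = x.reshape(*x.shape, 1)
    b0 = ((t[:-1] <= x.data[..., None]) & (x.data[..., None] < t[1:])).astype(x.dtype)
    b: Tensor = Tensor(b0)  # indicator: zero derivative a.e.
    for r in range(1, grid.order + 1):
        m = n0 - r
        left = (xe - t[:m]) / (t[r : r + m] - t[:m]) * b[..., :m]
        right = (t[r + 1 : r + 1 + m] - xe) / (
            t[r + 1 : r + 1 + m] - t[1 : 1 + m]
        ) * b[..., 1 : 1 + m]
        b = left + right
    return b


def kan_layer_forward(X: np.ndarray, params: KANLayerParams,
                      grid: SplineGrid | None = None) -> np.ndarray:
    """Functional forward pass of one KAN layer on plain arrays."""
    grid = grid or params.grid
    X = np.asarray(X, dtype=float)
    if X.shape[1] != params.in_dim:
        raise ValueError(f"expected input width {params.in_dim}, got {X.shape[1]}")
    if params.spline_coeffs.shape != (params.out_dim, params.in_dim, grid.n_basis):
        raise ValueError("spline coefficient tensor inconsistent with the grid")
    xc = np.clip(X, grid.lo, grid.hi - 1e-12)
    basis = bspline_basis(xc, grid)  # (B, in, nb)
    base = _base_act(X, params.base_activation) @ params.base_weight.T
    spline_w = (params.scale[:, :, None] * params.spline_coeffs).reshape(
        params.out_dim, -1
    )
    spline = basis.reshape(X.shape[0], -1) @ spline_w.T
    return base + spline


def kan_classify(Ffus: np.ndarray, layers: list[KANLayerParams]) -> np.ndarray:
    """Chain KAN layers into logits; validates the layer dimensions."""
    X = np.asarray(Ffus, dtype=float)
    for i, params in enumerate(layers):
        if X.shape[1] != params.in_dim:
            raise ValueError(
                f"layer {i} expects width {params.in_dim}, got {X.shape[1]}"
            )
        X = kan_layer_forward(X, params)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite logits")
    return X


class KANLayer(Module):
    """Trainable KAN layer (autodiff path)."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 grid: SplineGrid | None = None, base_activation: str = "silu",
                 dtype=np.float64):
        super().__init__()
        if base_activation not in ("silu", "identity"):
            raise ValueError(f"unknown base activation '{base_activation}'")
        self.base_activation = base_activation
        self.grid = grid or SplineGrid()
        std = np.sqrt(2.0 / (in_dim + out_dim))
        self.base_weight = Tensor(
            rng.normal(0.0, std, size=(out_dim, in_dim)).astype(dtype),
            requires_grad=True,
        )
        self.spline_coeffs = Tensor(
            rng.normal(0.0, 0.01, size=(out_dim, in_dim, self.grid.n_basis)).astype(dtype),
            requires_grad=True,
        )
        self.scale = Tensor(np.ones((out_dim, in_dim), dtype=dtype), requires_grad=True)
        self.in_dim, self.out_dim = in_dim, out_dim

    def forward(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        if x.shape[1] != self.in_dim:
            raise ValueError(f"expected input width {self.in_dim}, got {x.shape[1]}")
        grid = self.grid
        xc = x.clip(grid.lo, grid.hi - 1e-12)
        basis = bspline_basis_t(xc, grid)  # (B, in, nb)
        xb = x.silu() if self.base_activation == "silu" else x
        base = xb @ self.base_weight.swapaxes(0, 1)
        nb = grid.n_basis
        spline_w = (
            self.scale.reshape(self.out_dim, self.in_dim, 1) * self.spline_coeffs
        ).reshape(self.out_dim, self.in_dim * nb)
        spline = basis.reshape(x.shape[0], self.in_dim * nb) @ spline_w.swapaxes(0, 1)
        return base + spline

    def export_params(self) -> KANLayerParams:
        return KANLayerParams(
            in_dim=self.in_dim,
            out_dim=self.out_dim,
            spline_coeffs=self.spline_coeffs.data.copy(),
            base_weight=self.base_weight.data.copy(),
            scale=self.scale.data.copy(),
            grid=self.grid,
            base_activation=self.base_activation,
        )

    def spline_curves(self, n_points: int = 101) -> pd.DataFrame:
        """Sample the learned per-edge spline functions for visualisation."""
        xs = np.linspace(self.grid.lo, self.grid.hi - 1e-12, n_points)
        basis = bspline_basis(xs, self.grid)  # (n_points, nb)
        rows = []
        for o in range(self.out_dim):
            for i in range(self.in_dim):
                ys = basis @ (self.scale.data[o, i] * self.spline_coeffs.data[o, i])
                rows.append(pd.DataFrame({"out": o, "in": i, "x": xs, "y": ys}))
        return pd.concat(rows, ignore_index=True)


class KANHead(Module):
    """Batch norm (keeps inputs in the grid range) followed by KAN layer(s)."""

    def __init__(self, in_dim: int, n_classes: int, rng: np.random.Generator,
                 grid_size: int = 5, order: int = 3, depth: int = 1,
                 hidden_dim: int = 32, dtype=np.float64):
        super().__init__()
        self.bn = BatchNorm1d(in_dim, dtype=dtype)
        # start the normalized inputs at sd 0.5 so ~95% of values lie inside
        # the spline support [-1, 1] (outside it only the base path has grad)
        self.bn.gamma.data[:] = 0.5
        grid = SplineGrid(grid_size=grid_size, order=order)
        dims = [in_dim] + [hidden_dim] * (depth - 1) + [n_classes]
        self.layers = [
            KANLayer(dims[i], dims[i + 1], rng, grid=grid, dtype=dtype)
            for i in range(depth)
        ]

    def forward(self, x: Tensor) -> Tensor:
        x = self.bn(as_tensor(x))
        for layer in self.layers:
            x = layer(x)
        return x


class FCHead(Module):
    """Plain fully-connected head (ablation alternative to the KAN head)."""

    def __init__(self, in_dim: int, n_classes: int, rng: np.random.Generator,
                 dtype=np.float64):
        super().__init__()
        self.fc = Linear(in_dim, n_classes, rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc(as_tensor(x))


def fit_univariate_spline(xs: np.ndarray, ys: np.ndarray,
                          grid: SplineGrid) -> np.ndarray:
    """Least-squares B-spline coefficients approximating ``ys = f(xs)``."""
    basis = bspline_basis(np.asarray(xs, float), grid)
    coeffs, *_ = np.linalg.lstsq(basis, np.asarray(ys, float), rcond=None)
    return coeffs
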