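"""Anti-cross-attention (inverse attention) fusion of radiomics and deep features.

Standard cross-attention emphasises feature dimensions where the two
modalities agree.  In heterogeneous radiomics/deep representations the
discriminative complement often sits in *weakly* correlated dimensions, so
this block inverts the attention map: after a bilinear interaction between the
normalized branches, softmax attention ``A`` is replaced by ``1 - A`` and the
inverse map is aggregated into a per-dimension weight that up-weights the
deep-feature channels receiving *low* standard attention.

Pipeline per sample ``b`` (unified dimension ``d``):

1. ``Rp = Norm(Wrp R + brp)``, ``Fn = Norm(F)`` -- row-wise L2 normalization;
2. ``M_b = (r_p W)^T f_n`` -- a rank-1 d-by-d interaction matrix (bilinear
   form with learnable ``W``);
3. ``Mbn = BN(M)`` per (i, j) channel, ``A = softmax`` along the deep-feature
   axis (rows of ``A`` sum to 1);
4. ``Ainv = 1 - A``; column-summed and divided by ``d`` into a 1-by-d vector
   ``a`` with entries in [0, 1];
5. residual gating ``w = g * a + (1 - g)`` with sigmoid-squashed learnable
   ``g`` (keeps gradients alive when ``a`` collapses), ``Fatt = Fn * w``;
6. ``Ffus = BN(Concat(Rp, Fatt))`` of width ``2d``.

The module functions below are pure-NumPy references used by the test oracles;
:class:`AntiCrossAttention` is the trainable autodiff path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from ._tensor import Tensor, as_tensor, concat, softmax
from .encoder import l2_normalize, l2_normalize_t
from .nn import BatchNorm1d, Linear, Module

__all__ = [
    "AttentionBundle",
    "FusedFeature",
    "normalize_inputs",
    "bilinear_interaction",
    "attention_map",
    "invert_and_aggregate",
    "gate_and_fuse",
    "AntiCrossAttention",
    "ConcatFusion",
]


@dataclass
class AttentionBundle:
    M: np.ndarray       # (B, d, d) interaction tensor
    Mbn: np.ndarray     # batch-normalized interaction
    A: np.ndarray       # attention map, rows sum to 1
    Ainv: np.ndarray    # 1 - A
    a_vec: np.ndarray   # (B, d) aggregated inverse-attention weights in [0, 1]


@dataclass
class FusedFeature:
    Rp: np.ndarray      # (B, d)
    Fatt: np.ndarray    # (B, d) reweighted deep features
    Ffus: np.ndarray    # (B, 2d) fused, batch-normalized


def normalize_inputs(R: np.ndarray, F: np.ndarray, Wrp: np.ndarray,
                     brp: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Project the radiomics branch to width d and L2-normalize both branches.

    ``Wrp`` has shape (d, k): ``Rp = Norm(R @ Wrp.T + brp)``, ``Fn = Norm(F)``.
    """
    R, F = np.asarray(R, float), np.asarray(F, float)
    Wrp, brp = np.asarray(Wrp, float), np.asarray(brp, float)
    if R.shape[1] != Wrp.shape[1]:
        raise ValueError(f"radiomics width {R.shape[1]} != Wrp input {Wrp.shape[1]}")
    if F.shape[1] != Wrp.shape[0]:
        raise ValueError(f"deep width {F.shape[1]} != unified dim {Wrp.shape[0]}")
    return l2_normalize(R @ Wrp.T + brp), l2_normalize(F)


def bilinear_interaction(Rp: np.ndarray, Fn: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Per-sample rank-1 interaction ``M_b = outer(r_p W, f_n)``."""
    Rp, Fn, W = (np.asarray(a, float) for a in (Rp, Fn, W))
    if not (np.all(np.isfinite(Rp)) and np.all(np.isfinite(Fn)) and np.all(np.isfinite(W))):
        raise ValueError("non-finite inputs to the bilinear interaction")
    if W.shape[0] != W.shape[1] or W.shape[0] != Rp.shape[1]:
        raise ValueError("W must be square with side equal to the unified dimension")
    return np.einsum("bi,bj->bij", Rp @ W, Fn)


def attention_map(M: np.ndarray, eps: float = 1e-5) -> tuple[np.ndarray, np.ndarray]:
    """Batch-normalize M per (i, j) channel and softmax along the last axis.

    This is the training-mode reference (batch statistics, no affine); the
    trainable module keeps running statistics for evaluation.
    """
    M = np.asarray(M, float)
    if M.shape[0] < 2:
        raise ValueError("batch normalization of the interaction needs batch size >= 2")
    mu = M.mean(axis=0, keepdims=True)
    var = M.var(axis=0, keepdims=True)
    Mbn = (M - mu) / np.sqrt(var + eps)
    shifted = Mbn - Mbn.max(axis=2, keepdims=True)
    e = np.exp(shifted)
    A = e / e.sum(axis=2, keepdims=True)
    return Mbn, A


def invert_and_aggregate(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Inverse map ``Ainv = 1 - A`` and its column sum scaled into [0, 1].

    The raw column sum of a d-by-d map has entries up to ``d``; dividing by
    ``d`` keeps the aggregated weights on the scale of the features they
    multiply.  For any valid A the entries of ``a_vec`` sum to ``d - 1``.
    """
    A = np.asarray(A, float)
    d = A.shape[-1]
    Ainv = 1.0 - A
    a_vec = Ainv.sum(axis=-2) / d
    return Ainv, a_vec


def gate_and_fuse(Rp: np.ndarray, Fn: np.ndarray, a_vec: np.ndarray,
                  gate: float | np.ndarray, eps: float = 1e-5,
                  batch_normalize: bool = True) -> FusedFeature:
    """Residual-gated reweighting and fusion (reference implementation).

    ``w = g * a_vec + (1 - g)`` with ``g = sigmoid(gate)``; ``g -> 0`` is a
    pure residual pass-through, ``g -> 1`` pure inverse attention.
    """
    Rp, Fn, a_vec = (np.asarray(a, float) for a in (Rp, Fn, a_vec))
    g = expit(np.asarray(gate, float))
    w = g * a_vec + (1.0 - g)
    Fatt = Fn * w
    fused = np.concatenate([Rp, Fatt], axis=1)
    if batch_normalize and fused.shape[0] >= 2:
        mu = fused.mean(axis=0, keepdims=True)
        var = fused.var(axis=0, keepdims=True)
        fused = (fused - mu) / np.sqrt(var + eps)
    return FusedFeature(Rp=Rp, Fatt=Fatt, Ffus=fused)


class AntiCrossAttention(Module):
    """Trainable inverse-attention fusion block.

    Parameters: the k-to-d radiomics projection, the d-by-d bilinear matrix,
    a learnable gate (scalar or per-dimension), and the two batch norms
    (interaction channels and fused output).  ``use_residual_gate=False``
    reproduces pure inverse attention for ablations.
    """

    def __init__(self, k: int, d: int, rng: np.random.Generator,
                 gate_mode: str = "scalar", use_residual_gate: bool = True,
                 dtype=np.float64):
        super().__init__()
        if gate_mode not in ("scalar", "vector"):
            raise ValueError("gate_mode must be 'scalar' or 'vector'")
        self.proj_r = Linear(k, d, rng, dtype=dtype)
        self.W = Tensor(
            rng.normal(0.0, np.sqrt(1.0 / d), size=(d, d)).astype(dtype),
            requires_grad=True,
        )
        gate_shape = () if gate_mode == "scalar" else (d,)
        self.gate = Tensor(np.zeros(gate_shape, dtype=dtype), requires_grad=True)
        self.bn_interaction = BatchNorm1d(d * d, dtype=dtype)
        self.bn_fusion = BatchNorm1d(2 * d, dtype=dtype)
        self.d = d
        self.use_residual_gate = use_residual_gate

    def forward(self, R: Tensor, F: Tensor) -> dict[str, Tensor]:
        R, F = as_tensor(R), as_tensor(F)
        d = self.d
        B = R.shape[0]
        Rp = l2_normalize_t(self.proj_r(R))
        Fn = l2_normalize_t(F)
        RpW = Rp @ self.W
        M = RpW.reshape(B, d, 1) * Fn.reshape(B, 1, d)
        Mbn = self.bn_interaction(M.reshape(B, d * d)).reshape(B, d, d)
        A = softmax(Mbn, axis=2)
        Ainv = 1.0 - A
        a_vec = Ainv.sum(axis=1) * (1.0 / d)
        if self.use_residual_gate:
            g = self.gate.sigmoid()
            w = g * a_vec + (1.0 - g)
        else:
            w = a_vec
        Fatt = Fn * w
        Ffus = self.bn_fusion(concat([Rp, Fatt], axis=1))
        return {
            "Rp": Rp, "Fn": Fn, "M": M, "Mbn": Mbn, "A": A,
            "Ainv": Ainv, "a_vec": a_vec, "Fatt": Fatt, "Ffus": Ffus,
        }


class ConcatFusion(Module):
    """Ablation baseline: plain concatenation of the normalized branches."""

    def __init__(self, k: int, d: int, rng: np.random.Generator, dtype=np.float64):
        super().__init__()
        self.proj_r = Linear(k, d, rng, dtype=dtype)
        self.bn_fusion = BatchNorm1d(2 * d, dtype=dtype)
        self.d = d

    def forward(self, R: Tensor, F: Tensor) -> dict[str, Tensor]:
        Rp = l2_normalize_t(self.proj_r(as_tensor(R)))
        Fn = l2_normalize_t(as_tensor(F))
        Ffus = self.bn_fusion(concat([Rp, Fn], axis=1))
        return {"Rp": Rp, "Fn": Fn, "Fatt": Fn, "Ffus": Ffus}
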