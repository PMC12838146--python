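"""Decorrelation loss: covariance blocks, oracle equivalence, schedule."""

import numpy as np
import pytest

from radfuse._tensor import Tensor
from radfuse.decorrelation import (
    ViewProjectors,
    alpha_schedule,
    center,
    covariance_blocks,
    decorrelation_loss,
    decorrelation_loss_t,
    mean_abs_cross_correlation,
    project_views,
    total_loss,
)


def brute_frobenius_sq(H1c, H2c):
    B, d = H1c.shape
    total = 0.0
    for i in range(d):
        for j in range(H2c.shape[1]):
            c_ij = sum(H1c[b, i] * H2c[b, j] for b in range(B)) / (B - 1)
            total += c_ij**2
    return total


def test_center_worked_examples():
    H = np.array([[1.0, 5.0], [3.0, 5.0]])
    Hc = center(H)
    np.testing.assert_allclose(Hc[:, 0], [-1.0, 1.0])
    np.testing.assert_allclose(Hc.mean(axis=0), 0.0, atol=1e-9)
    np.testing.assert_allclose(center(Hc), Hc)  # idempotent
    np.testing.assert_allclose(center(H + 7.0), Hc)  # shift invariant
    with pytest.raises(ValueError):
        center(H[:1])


def test_covariance_blocks_worked_example():
    H1 = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 0.0]])
    H2 = np.array([[0.0, 2.0], [0.0, -2.0], [0.0, 0.0]])
    cb = covariance_blocks(H1, H2, epsilon=1e-4)
    np.testing.assert_allclose(cb.C12, [[0.0, 2.0], [0.0, 0.0]])
    assert decorrelation_loss(cb.C12) == pytest.approx(4.0)
    np.testing.assert_array_equal(cb.C21, cb.C12.T)


def test_covariance_blocks_identical_and_orthogonal_views(rng):
    H = center(rng.standard_normal((6, 4)))
    cb = covariance_blocks(H, H, epsilon=1e-4)
    np.testing.assert_allclose(cb.C12, cb.C11 - 1e-4 * np.eye(4), atol=1e-12)
    # within-view blocks are symmetric positive definite
    for C in (cb.C11, cb.C22):
        np.testing.assert_allclose(C, C.T, atol=1e-12)
        assert np.linalg.eigvalsh(C).min() >= 1e-4 - 1e-10
    H2 = np.zeros((6, 4))
    H2[:, 0] = center(rng.standard_normal(6))
    H1 = np.zeros((6, 4))
    H1[:, 1] = H2[:, 0] * 0.0
    np.testing.assert_allclose(covariance_blocks(H1, H2).C12, 0.0)


def test_loss_matches_double_sum_oracle(rng):
    for _ in range(25):
        H1 = center(rng.standard_normal((5, 4)))
        H2 = center(rng.standard_normal((5, 4)))
        cb = covariance_blocks(H1, H2)
        assert decorrelation_loss(cb.C12) == pytest.approx(
            brute_frobenius_sq(H1, H2), abs=1e-10
        )


def test_tensor_loss_matches_numpy_and_is_differentiable(rng):
    H1 = rng.standard_normal((6, 5))
    H2 = rng.standard_normal((6, 5))
    t1 = Tensor(H1, requires_grad=True)
    loss = decorrelation_loss_t(t1, Tensor(H2))
    assert loss.item() == pytest.approx(brute_frobenius_sq(center(H1), center(H2)),
                                        abs=1e-10)
    loss.backward()
    assert np.any(t1.grad != 0)
    with pytest.raises(ValueError):
        decorrelation_loss_t(Tensor(H1[:1]), Tensor(H2[:1]))


def test_loss_shift_invariance_and_scale_covariance(rng):
    H1 = rng.standard_normal((8, 3))
    H2 = rng.standard_normal((8, 3))
    base = decorrelation_loss_t(Tensor(H1), Tensor(H2)).item()
    shifted = decorrelation_loss_t(Tensor(H1 + 5.0), Tensor(H2 - 3.0)).item()
    assert shifted == pytest.approx(base, rel=1e-9)
    scaled = decorrelation_loss_t(Tensor(H1), Tensor(2.5 * H2)).item()
    assert scaled == pytest.approx(2.5**2 * base, rel=1e-9)


def test_loss_zero_iff_orthogonal(rng):
    H1 = center(rng.standard_normal((6, 3)))
    Q, _ = np.linalg.qr(np.hstack([H1, rng.standard_normal((6, 2))]))
    H2 = center(Q[:, 3:5])  # orthogonal complement columns, centered
    H2 -= H1 @ np.linalg.lstsq(H1, H2, rcond=None)[0]
    cb = covariance_blocks(center(H1), center(H2))
    assert decorrelation_loss(cb.C12) <= 1e-20


def test_alpha_schedule_contract():
    assert alpha_schedule(0, 200, 0.2) == 0.0
    assert alpha_schedule(50, 200, 0.2) == pytest.approx(0.05)
    assert alpha_schedule(200, 200, 0.2) == pytest.approx(0.2)
    values = [alpha_schedule(e, 200, 0.2) for e in range(201)]
    assert all(b >= a for a, b in zip(values, values[1:]))
    with pytest.raises(ValueError):
        alpha_schedule(1, 0, 0.2)
    with pytest.raises(ValueError):
        alpha_schedule(5, 4, 0.2)


def test_total_loss_arithmetic():
    assert total_loss(1.0, 4.0, 0.05) == pytest.approx(1.2)
    assert total_loss(0.7, 4.0, 0.0) == pytest.approx(0.7)
    assert total_loss(0.7, 0.0, 0.2) == pytest.approx(0.7)


def test_view_projectors_contract(rng):
    proj = ViewProjectors(4, rng)
    Rp = rng.standard_normal((5, 4))
    Fn = rng.standard_normal((5, 4))
    H1, H2 = project_views(Rp, Fn, proj)
    assert H1.shape == H2.shape == (5, 4)
    H1b, H2b = project_views(Rp, Fn, proj)  # eval mode: deterministic
    np.testing.assert_array_equal(H1, H1b)
    np.testing.assert_array_equal(H2, H2b)
    # zero-weight projectors map every sample to the same point
    for p in proj.parameters():
        p.data = np.zeros_like(p.data)
    H1z, _ = project_views(Rp, Fn, proj)
    assert np.ptp(H1z, axis=0).max() == 0.0
    with pytest.raises(ValueError):
        project_views(rng.standard_normal((5, 3)), Fn, proj)


def test_mean_abs_cross_correlation_bounds(rng):
    H = rng.standard_normal((200, 3))
    assert mean_abs_cross_correlation(H, H) == pytest.approx(
        np.mean(np.abs(np.corrcoef(H.T))), abs=1e-9
    )
    other = rng.standard_normal((200, 3))
    assert mean_abs_cross_correlation(H, other) < 0.2


def test_training_with_decorrelation_reduces_cross_correlation():
    """On redundant synthetic data, alpha_max=0.2 lowers the held-out mean
    |cross-correlation| between the two latent views relative to alpha_max=0
    (averaged over 3 seeds).

    The readout uses a large fresh draw from the same distribution: the
    |correlation| estimate on a small split would sit at its sampling-noise
    floor and mask the effect."""
    from radfuse.pipeline import FusionImageClassifier, stratified_split
    from radfuse.synthetic import SynthConfig, generate_dataset

    def arrays(cfg):
        samples, man = generate_dataset(cfg)
        return (np.stack([s.image for s in samples]),
                np.stack([s.mask for s in samples]),
                man["label"].to_numpy())

    conditions = dict(n_classes=2, image_size=32, texture_effect=1.5,
                      shape_effect=1.5, context_effect=1.5, redundancy=0.9)
    deltas = []
    for seed in range(3):
        X, M, y = arrays(SynthConfig(n_per_class=40, seed=seed, **conditions))
        Xh, Mh, _ = arrays(SynthConfig(n_per_class=150, seed=seed + 500,
                                       **conditions))
        tr, _ = stratified_split(y, 0.8, seed)
        xcs = {}
        for alpha in (0.2, 0.0):
            clf = FusionImageClassifier(
                epochs=20, unified_dim=16, native_dim=32, learning_rate=1e-3,
                use_aca=True, head="fc", alpha_max=alpha, augment=False,
                glcm_distances=(1, 2), random_state=seed,
            ).fit(X[tr], y[tr], masks=M[tr])
            H1, H2 = clf.latent_views(Xh, masks=Mh)
            xcs[alpha] = mean_abs_cross_correlation(H1, H2)
        deltas.append(xcs[0.0] - xcs[0.2])
    assert np.mean(deltas) > 0.0
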