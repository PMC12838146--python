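"""Gradient correctness of the autodiff engine against finite differences."""

import numpy as np
import pytest

from radfuse._tensor import (
    Tensor,
    batch_norm,
    concat,
    conv2d,
    cross_entropy,
    log_softmax,
    softmax,
)
from radfuse.nn import MLP, Adam, BatchNorm1d, BatchNorm2d, Linear

from conftest import finite_difference_grad


def check_input_grad(f, x, atol=1e-6):
    t = Tensor(np.asarray(x, float).copy(), requires_grad=True)
    f(t).backward()
    g_num = finite_difference_grad(lambda a: f(Tensor(a)).item(), np.asarray(x, float))
    np.testing.assert_allclose(t.grad, g_num, atol=atol)


OPS = {
    "add_broadcast": lambda x: (x + np.array([1.0, 2.0, 3.0])).sum(),
    "mul": lambda x: (x * x).sum(),
    "div": lambda x: (1.0 / (x + 5.0)).sum(),
    "pow": lambda x: (x**3).sum(),
    "exp": lambda x: x.exp().sum(),
    "log": lambda x: (x + 5.0).log().sum(),
    "sqrt": lambda x: (x + 5.0).sqrt().sum(),
    "sigmoid": lambda x: x.sigmoid().sum(),
    "silu": lambda x: x.silu().sum(),
    "matmul": lambda x: (x @ x.swapaxes(0, 1)).sum(),
    "sum_axis": lambda x: (x.sum(axis=0) ** 2).sum(),
    "mean_keepdims": lambda x: ((x - x.mean(axis=1, keepdims=True)) ** 2).sum(),
    "reshape": lambda x: (x.reshape(6, 2) ** 2).sum(),
    "transpose": lambda x: (x.transpose(1, 0) ** 3).sum(),
    "getitem": lambda x: (x[1:, :2] ** 2).sum(),
    "softmax": lambda x: (softmax(x, axis=1) ** 2).sum(),
    "log_softmax": lambda x: (log_softmax(x, axis=1) * np.arange(3.0)).sum(),
    "maximum": lambda x: x.maximum(0.1).sum(),
    "clip": lambda x: x.clip(-0.5, 0.5).sum(),
}


@pytest.mark.parametrize("name", sorted(OPS))
def test_elementwise_and_reduction_gradients(name, rng):
    x = rng.standard_normal((4, 3))
    check_input_grad(OPS[name], x)


def test_concat_gradients(rng):
    a, b = rng.standard_normal((3, 2)), rng.standard_normal((3, 4))
    ta = Tensor(a.copy(), requires_grad=True)
    tb = Tensor(b.copy(), requires_grad=True)
    (concat([ta, tb], axis=1) ** 2).sum().backward()
    np.testing.assert_allclose(ta.grad, 2 * a)
    np.testing.assert_allclose(tb.grad, 2 * b)


def test_conv2d_matches_finite_differences(rng):
    x = rng.standard_normal((2, 1, 6, 6))
    w = rng.standard_normal((3, 1, 3, 3))
    b = rng.standard_normal(3)

    def f_x(a):
        return (conv2d(Tensor(a), Tensor(w), Tensor(b), stride=2, padding=1) ** 2).sum()

    check_input_grad(lambda t: (conv2d(t, Tensor(w), Tensor(b), stride=2, padding=1) ** 2).sum(), x, atol=1e-5)
    tw = Tensor(w.copy(), requires_grad=True)
    (conv2d(Tensor(x), tw, Tensor(b), stride=2, padding=1) ** 2).sum().backward()
    g_num = finite_difference_grad(
        lambda a: (conv2d(Tensor(x), Tensor(a), Tensor(b), stride=2, padding=1) ** 2)
        .sum().item(), w,
    )
    np.testing.assert_allclose(tw.grad, g_num, atol=1e-5)


def test_cross_entropy_matches_finite_differences(rng):
    logits = rng.standard_normal((4, 3))
    labels = np.array([0, 2, 1, 1])
    check_input_grad(lambda t: cross_entropy(t, labels), logits)


def test_batch_norm_gradients(rng):
    x = rng.standard_normal((6, 4))
    gamma = np.array([[1.0, 2.0, 0.5, 1.5]])
    beta = np.array([[0.1, -0.2, 0.0, 0.3]])

    def f(t):
        out, _, _ = batch_norm(t, Tensor(gamma), Tensor(beta), axes=(0,))
        return (out**3).sum()

    check_input_grad(f, x, atol=1e-5)
    tg = Tensor(gamma.copy(), requires_grad=True)
    out, _, _ = batch_norm(Tensor(x), tg, Tensor(beta), axes=(0,))
    (out**3).sum().backward()
    g_num = finite_difference_grad(
        lambda a: (batch_norm(Tensor(x), Tensor(a), Tensor(beta), axes=(0,))[0] ** 3)
        .sum().item(), gamma,
    )
    np.testing.assert_allclose(tg.grad, g_num, atol=1e-5)


def test_gradient_accumulation_over_reused_node(rng):
    x = rng.standard_normal((3, 3))
    t = Tensor(x.copy(), requires_grad=True)
    ((t * t) + t.exp() + (t @ t).sum(axis=1, keepdims=True)).sum().backward()
    g_num = finite_difference_grad(
        lambda a: ((Tensor(a) * Tensor(a)) + Tensor(a).exp()
                   + (Tensor(a) @ Tensor(a)).sum(axis=1, keepdims=True)).sum().item(),
        x,
    )
    np.testing.assert_allclose(t.grad, g_num, atol=1e-5)


def test_module_parameter_gradients_mlp(rng):
    mlp = MLP(4, 6, 2, rng)
    x = Tensor(rng.standard_normal((5, 4)))
    (mlp(x) ** 2).sum().backward()
    p = mlp.parameters()[0]
    g_auto = p.grad.copy()
    g_num = finite_difference_grad(
        lambda a: _with_param(mlp, p, a, lambda: (mlp(x) ** 2).sum().item()),
        p.data.copy(),
    )
    np.testing.assert_allclose(g_auto, g_num, atol=1e-6)


def _with_param(module, param, value, f):
    old = param.data
    param.data = value
    try:
        return f()
    finally:
        param.data = old


def test_adam_minimises_quadratic(rng):
    target = rng.standard_normal(5)
    p = Tensor(np.zeros(5), requires_grad=True)
    opt = Adam([p], lr=0.1)
    for _ in range(200):
        loss = ((p - target) ** 2).sum()
        opt.zero_grad()
        loss.backward()
        opt.step()
    np.testing.assert_allclose(p.data, target, atol=1e-3)


def test_batchnorm_train_eval_consistency(rng):
    bn = BatchNorm1d(3, momentum=0.5)
    x = rng.standard_normal((64, 3)) * 2.0 + 1.0
    for _ in range(50):
        bn(Tensor(x))
    bn.eval()
    out = bn(Tensor(x)).data
    # running statistics converge toward batch statistics on a constant batch
    assert np.abs(out.mean(axis=0)).max() < 0.05
    assert np.abs(out.std(axis=0) - 1.0).max() < 0.05


def test_batchnorm_rejects_single_sample_in_training():
    bn = BatchNorm1d(3)
    with pytest.raises(RuntimeError):
        bn(Tensor(np.ones((1, 3))))
    bn.eval()
    assert bn(Tensor(np.ones((1, 3)))).shape == (1, 3)


def test_state_dict_roundtrip(rng):
    m1 = MLP(3, 4, 2, rng)
    m2 = MLP(3, 4, 2, np.random.default_rng(999))
    m2.load_state_dict(m1.state_dict())
    x = Tensor(rng.standard_normal((4, 3)))
    np.testing.assert_array_equal(m1(x).data, m2(x).data)


def test_linear_rejects_wrong_width(rng):
    layer = Linear(3, 2, rng)
    with pytest.raises(ValueError):
        layer(Tensor(np.ones((2, 4))))


def test_batchnorm2d_normalizes_per_channel(rng):
    bn = BatchNorm2d(2)
    x = rng.standard_normal((4, 2, 5, 5)) * 3 + 2
    out = bn(Tensor(x)).data
    np.testing.assert_allclose(out.mean(axis=(0, 2, 3)), 0.0, atol=1e-7)
    np.testing.assert_allclose(out.std(axis=(0, 2, 3)), 1.0, atol=1e-3)
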