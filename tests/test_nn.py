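"""Autodiff engine: numeric gradient checks and optimizer behavior."""

import numpy as np
import pytest

from tumorseg import nn
from tumorseg.nn import tensor as T
from tumorseg.nn.tensor import Tensor


def numeric_grad(f, arr, eps=1e-6):
    g = np.zeros_like(arr)
    it = np.nditer(arr, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = arr[idx]
        arr[idx] = orig + eps
        fp = f()
        arr[idx] = orig - eps
        fm = f()
        arr[idx] = orig
        g[idx] = (fp - fm) / (2 * eps)
    return g


OPS = {
    "conv2d": (T.conv2d, [(2, 5, 5, 3), (3, 3, 3, 4), (4,)]),
    "depthwise_conv2d": (T.depthwise_conv2d, [(2, 5, 5, 3), (3, 3, 3), (3,)]),
    "conv2d_transpose": (T.conv2d_transpose, [(2, 3, 3, 3), (2, 2, 3, 4), (4,)]),
    "depthwise_conv2d_transpose": (T.depthwise_conv2d_transpose,
                                   [(2, 3, 3, 3), (2, 2, 3), (3,)]),
    "maxpool2x2": (T.maxpool2x2, [(2, 4, 4, 3)]),
    "sigmoid": (T.sigmoid, [(3, 4)]),
    "matmul": (T.matmul, [(4, 3), (3, 5)]),
    "concat": (lambda a, b: T.concat([a, b], axis=-1), [(2, 3, 3, 2), (2, 3, 3, 3)]),
    "mean_hw": (lambda a: T.mean_axes(a, (1, 2)), [(2, 4, 4, 3)]),
    "max_hw": (lambda a: T.max_axes(a, (1, 2)), [(2, 4, 4, 3)]),
}


@pytest.mark.parametrize("name", sorted(OPS))
def test_op_gradients_match_numeric(name, rng):
    op, shapes = OPS[name]
    arrays = [rng.standard_normal(s) for s in shapes]
    tensors = [Tensor(a, requires_grad=True) for a in arrays]
    loss = T.sum_all(T.mul(op(*tensors), op(*tensors)))
    loss.backward()

    def f():
        out = op(*[Tensor(a) for a in arrays])
        return float((out.data ** 2).sum())

    for arr, t in zip(arrays, tensors):
        want = numeric_grad(f, arr)
        err = np.abs(want - t.grad).max() / (np.abs(want).max() + 1e-12)
        assert err < 1e-5, f"{name}: relative gradient error {err:.2e}"


def test_batchnorm_training_gradient_matches_numeric(rng):
    # weight the normalized output elementwise so the loss has a genuine
    # dependence on x (sum(out^2) would be constant under normalization)
    x = rng.standard_normal((2, 4, 4, 3))
    r = rng.standard_normal((2, 4, 4, 3))
    bn = nn.BatchNorm2D(3, dtype=np.float64)
    bn.gamma.data = rng.standard_normal(3)
    bn.beta.data = rng.standard_normal(3)

    xt = Tensor(x, requires_grad=True)
    out = bn(xt, training=True)
    T.sum_all(T.mul(out, Tensor(r))).backward()

    def f():
        fresh = nn.BatchNorm2D(3, dtype=np.float64)
        fresh.gamma.data = bn.gamma.data.copy()
        fresh.beta.data = bn.beta.data.copy()
        return float((fresh(Tensor(x), training=True).data * r).sum())

    want = numeric_grad(f, x)
    err = np.abs(want - xt.grad).max() / (np.abs(want).max() + 1e-12)
    assert err < 1e-5


def test_batchnorm_eval_uses_moving_statistics(rng):
    bn = nn.BatchNorm2D(2, momentum=0.0, dtype=np.float64)  # adopt batch stats
    x = rng.standard_normal((4, 3, 3, 2)) * 5 + 2
    bn(Tensor(x), training=True)
    out = bn(Tensor(x), training=False).data
    assert abs(out.mean()) < 1e-6 and out.std() == pytest.approx(1.0, abs=1e-2)


def test_dropout_inverted_scaling_and_eval_identity(rng):
    box = nn.RngBox(0)
    drop = nn.Dropout(0.5, box)
    x = Tensor(np.ones((1000,)))
    out = drop(x, training=True)
    kept = out.data[out.data > 0]
    assert kept[0] == pytest.approx(2.0)  # inverted scaling by 1/keep
    assert out.data.mean() == pytest.approx(1.0, abs=0.1)
    np.testing.assert_array_equal(drop(x, training=False).data, x.data)


def test_freeze_marks_parameters_non_trainable():
    conv = nn.Conv2D(3, 8, 3, np.random.default_rng(0))
    assert nn.count_params(conv) == (3 * 3 * 3 * 8 + 8, 0)
    conv.freeze()
    assert nn.count_params(conv) == (0, 3 * 3 * 3 * 8 + 8)


def test_adamax_minimizes_quadratic():
    w = Tensor(np.array([4.0]), requires_grad=True)
    opt = nn.Adamax([w], learning_rate=0.1)
    for _ in range(300):
        diff = T.add(w, Tensor(np.array([-3.0])))
        loss = T.mul(diff, diff)
        opt.zero_grad()
        loss.backward()
        opt.step()
    assert w.data[0] == pytest.approx(3.0, abs=1e-2)


def test_adamax_step_magnitude_bounded_by_learning_rate():
    # |delta w| <= lr / (1 - beta1^t) for every step
    w = Tensor(np.array([0.0]), requires_grad=True)
    opt = nn.Adamax([w], learning_rate=0.01)
    prev = w.data.copy()
    for t in range(1, 20):
        loss = T.mul(w, w)
        opt.zero_grad()
        loss.backward()
        w.grad += 5.0  # arbitrary large gradient
        opt.step()
        assert abs(w.data[0] - prev[0]) <= 0.01 / (1 - 0.9 ** t) + 1e-12
        prev = w.data.copy()
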