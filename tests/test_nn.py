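"""The autodiff engine: analytic gradients vs central finite differences."""

import numpy as np
import pytest

from lungseg.nn import tensor as T
from lungseg.nn.layers import BatchNorm2d, Conv2d, LayerNorm, Linear
from lungseg.nn.optim import RMSprop


def numeric_grad(make_loss, arr, eps=1e-6, samples=25, rng=None):
    """Central differences of a scalar loss at randomly sampled entries."""
    rng = rng or np.random.default_rng(0)
    flat = arr.ravel()
    idx = rng.choice(flat.size, size=min(samples, flat.size), replace=False)
    grads = np.zeros(len(idx))
    for k, i in enumerate(idx):
        orig = flat[i]
        flat[i] = orig + eps
        fp = make_loss()
        flat[i] = orig - eps
        fm = make_loss()
        flat[i] = orig
        grads[k] = (fp - fm) / (2 * eps)
    return idx, grads


def check_grads(build, tensors, rng, atol=1e-5):
    """Backprop through ``build()`` and compare with finite differences."""
    for t in tensors:
        t.zero_grad()
    loss = build()
    loss.backward()
    for t in tensors:
        idx, num = numeric_grad(lambda: float(build().data), t.data, rng=rng)
        np.testing.assert_allclose(t.grad.ravel()[idx], num, atol=atol,
                                   err_msg=f"gradient mismatch for {t.shape}")


@pytest.fixture
def t64(rng):
    def make(*shape):
        return T.Tensor(rng.normal(size=shape), requires_grad=True)
    return make


class TestElementwiseAndShapes:
    def test_add_mul_broadcast(self, t64, rng):
        a, b = t64(3, 4), t64(4)
        check_grads(lambda: T.tsum(T.mul(T.add(a, b), a)), [a, b], rng)

    def test_matmul_batched(self, t64, rng):
        a, b = t64(2, 3, 4), t64(4, 5)
        check_grads(lambda: T.tsum(T.mul(a @ b, a @ b)), [a, b], rng)

    def test_relu_gelu(self, t64, rng):
        x = t64(5, 5)
        check_grads(lambda: T.tsum(T.relu(x)), [x], rng)
        check_grads(lambda: T.tsum(T.mul(T.gelu(x), T.gelu(x))), [x], rng)

    def test_reshape_transpose_concat(self, t64, rng):
        a, b = t64(2, 6), t64(2, 6)
        const = rng.normal(size=(4, 2, 3))
        def build():
            c = T.concat([T.reshape(a, (2, 2, 3)), T.reshape(b, (2, 2, 3))], axis=1)
            return T.tsum(T.mul(T.transpose(c, (1, 0, 2)), const))
        check_grads(build, [a, b], rng)

    def test_div(self, t64, rng):
        a = t64(4, 4)
        b = T.Tensor(rng.random((4, 4)) + 1.0, requires_grad=True)
        check_grads(lambda: T.tsum(T.div(a, b)), [a, b], rng)

    def test_softmax_rows_sum_to_one(self, t64, rng):
        x = t64(3, 7)
        y = T.softmax(x)
        np.testing.assert_allclose(y.data.sum(axis=-1), 1.0, atol=1e-12)
        check_grads(lambda: T.tsum(T.mul(T.softmax(x), np.arange(7.0))), [x], rng)


class TestConvAndResampling:
    def test_conv2d_grads(self, t64, rng):
        x, w, b = t64(2, 3, 6, 6), t64(4, 3, 3, 3), t64(4)
        check_grads(lambda: T.tsum(T.mul(T.conv2d(x, w, b), T.conv2d(x, w, b))),
                    [x, w, b], rng, atol=1e-4)

    def test_conv1x1_grads(self, t64, rng):
        x, w = t64(1, 4, 5, 5), t64(2, 4, 1, 1)
        check_grads(lambda: T.tsum(T.conv2d(x, w)), [x, w], rng)

    def test_avg_pool_and_upsample_grads(self, t64, rng):
        x = t64(2, 3, 4, 4)
        check_grads(lambda: T.tsum(T.mul(T.avg_pool2(x), T.avg_pool2(x))), [x], rng)
        check_grads(lambda: T.tsum(T.mul(T.upsample_nearest2(x),
                                         T.upsample_nearest2(x))), [x], rng)

    def test_pool_then_upsample_shapes(self, t64):
        x = t64(1, 2, 8, 8)
        assert T.avg_pool2(x).shape == (1, 2, 4, 4)
        assert T.upsample_nearest2(x).shape == (1, 2, 16, 16)


class TestNormalisation:
    def test_batchnorm_train_grads(self, t64, rng):
        x, g, b = t64(3, 4, 5, 5), t64(4), t64(4)
        rm, rv = np.zeros(4), np.ones(4)
        const = rng.normal(size=(3, 4, 5, 5))
        def build():
            return T.tsum(T.mul(
                T.batch_norm2d(x, g, b, rm.copy(), rv.copy(), training=True),
                const))
        check_grads(build, [x, g, b], rng, atol=1e-4)

    def test_batchnorm_eval_uses_running_stats(self, t64, rng):
        x, g, b = t64(2, 3, 4, 4), t64(3), t64(3)
        rm, rv = rng.normal(size=3), rng.random(3) + 0.5
        y = T.batch_norm2d(x, g, b, rm, rv, training=False)
        expect = (g.data[None, :, None, None]
                  * (x.data - rm[None, :, None, None])
                  / np.sqrt(rv[None, :, None, None] + 1e-5)
                  + b.data[None, :, None, None])
        np.testing.assert_allclose(y.data, expect, atol=1e-12)

    def test_layernorm_grads(self, t64, rng):
        x, g, b = t64(3, 4, 6), t64(6), t64(6)
        const = rng.normal(size=(3, 4, 6))
        check_grads(lambda: T.tsum(T.mul(T.layer_norm(x, g, b), const)),
                    [x, g, b], rng, atol=1e-4)


class TestDropoutAndLoss:
    def test_dropout_eval_is_identity(self, t64, rng):
        x = t64(5, 5)
        assert T.dropout(x, 0.5, rng, training=False) is x

    def test_dropout_scales_kept_units(self, rng):
        x = T.Tensor(np.ones((200, 200)), requires_grad=True)
        y = T.dropout(x, 0.25, rng, training=True)
        vals = set(np.unique(np.round(y.data, 9)))
        assert vals <= {0.0, np.round(1 / 0.75, 9)}
        assert abs((y.data == 0).mean() - 0.25) < 0.02

    def test_cross_entropy_grads(self, rng):
        logits = T.Tensor(rng.normal(size=(2, 2, 4, 4)), requires_grad=True)
        target = (rng.random((2, 4, 4)) > 0.5).astype(np.int64)
        check_grads(lambda: T.softmax_cross_entropy(logits, target),
                    [logits], rng)

    def test_cross_entropy_of_confident_correct_logits_is_tiny(self):
        target = np.array([[[0, 1], [1, 0]]])
        logits = np.zeros((1, 2, 2, 2))
        logits[0, 1] = np.where(target[0] == 1, 50.0, -50.0)
        logits[0, 0] = -logits[0, 1]
        loss = T.softmax_cross_entropy(T.Tensor(logits, requires_grad=True), target)
        assert float(loss.data) < 1e-12


class TestLayersAndOptim:
    def test_layer_shapes(self, rng):
        x = T.Tensor(rng.normal(size=(2, 3, 8, 8)).astype(np.float32))
        conv = Conv2d(3, 5, 3, rng)
        assert conv(x).shape == (2, 5, 8, 8)
        bn = BatchNorm2d(5)
        assert bn(conv(x)).shape == (2, 5, 8, 8)
        tok = T.Tensor(rng.normal(size=(2, 7, 6)).astype(np.float32))
        assert Linear(6, 9, rng)(tok).shape == (2, 7, 9)
        assert LayerNorm(6)(tok).shape == (2, 7, 6)

    def test_state_dict_round_trip(self, rng):
        conv = Conv2d(2, 3, 3, rng)
        state = conv.state_dict()
        conv2 = Conv2d(2, 3, 3, np.random.default_rng(999))
        conv2.load_state_dict(state)
        np.testing.assert_array_equal(conv.weight.data, conv2.weight.data)

    def test_rmsprop_single_step_matches_formula(self):
        from lungseg.nn.layers import Parameter
        p = Parameter(np.array([1.0, -2.0]))
        p.grad = np.array([0.5, 1.0], dtype=np.float32)
        opt = RMSprop([p], lr=0.1, alpha=0.9, eps=1e-8)
        opt.step()
        g = np.array([0.5, 1.0])
        s = 0.1 * g * g
        expect = np.array([1.0, -2.0]) - 0.1 * g / (np.sqrt(s) + 1e-8)
        np.testing.assert_allclose(p.data, expect, rtol=1e-6)
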