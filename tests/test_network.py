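"""Network construction, layer gradients, shape trace, and inference contracts."""

import numpy as np
import pytest

from dslfcn.arch import dsl_fcn2s_spec, fcn32s_baseline_spec, shape_trace
from dslfcn.dilation import audit_architecture
from dslfcn.network import (
    Model,
    Tensor,
    bilinear_kernel,
    build_dsl_fcn2s,
    build_modified_fcn32_baseline,
    conv2d,
    conv_transpose2d,
    crop_center,
    dropout,
    load_model,
    maxpool2_ceil,
    relu,
    save_model,
)

TOY = dict(base_channels=8, fc_channels=32, input_size=64)


@pytest.fixture(scope="module")
def toy_model():
    return build_dsl_fcn2s(3, **TOY, seed=0, dtype=np.float64)


# ---------------------------------------------------------------------------
# shape trace against the published layer table


TABLE_SIZES = {
    "conv1_1": 710,
    "pool1": 355,
    "pool2": 178,
    "pool3": 89,
    "pool4": 45,
    "pool5": 23,
    "dconv6": 17,
    "conv7": 17,
    "score": 17,
    "deconv1": 36,
    "deconv2": 74,
    "deconv3": 150,
    "deconv4": 302,
    "deconv5": 606,
    "crop5": 512,
}


def test_shape_trace_reproduces_layer_table_on_512_input():
    trace = dict(shape_trace(dsl_fcn2s_spec(3, input_size=512)))
    for name, side in TABLE_SIZES.items():
        assert trace[name].height == side, name
        assert trace[name].width == side, name
    assert trace["dconv6"].channels == 4096
    assert trace["crop5"].channels == 3


def test_pooling_chain_is_ceil_mode():
    trace = dict(shape_trace(dsl_fcn2s_spec(3, input_size=512)))
    sizes = [trace[f"pool{i}"].height for i in range(1, 6)]
    assert sizes == [355, 178, 89, 45, 23]
    cur = 710
    for s in sizes:
        cur = -(-cur // 2)
        assert s == cur


def test_baseline_trace_returns_to_input_size():
    trace = dict(shape_trace(fcn32s_baseline_spec(3, input_size=512)))
    assert trace["conv6"].hw == (17, 17)
    assert trace["crop"].hw == (512, 512)


# ---------------------------------------------------------------------------
# op-level gradient checks against numerical differentiation


def _num_grad(f, x, idx, eps=1e-6):
    xp, xm = x.copy(), x.copy()
    xp[idx] += eps
    xm[idx] -= eps
    return (f(xp) - f(xm)) / (2 * eps)


@pytest.mark.parametrize(
    "stride,padding,dilation",
    [(1, 0, 1), (1, 2, 1), (1, 0, 3), (2, 1, 1), (1, 1, 2)],
)
def test_conv2d_gradients(stride, padding, dilation):
    rng = np.random.default_rng(0)
    x = rng.normal(size=(2, 9, 9))
    w = rng.normal(size=(3, 2, 3, 3))
    b = rng.normal(size=3)

    def run(xa, wa, ba):
        t = conv2d(Tensor(xa), Tensor(wa), Tensor(ba), stride, padding, dilation)
        return t

    out = run(x, w, b)
    g = np.ones_like(out.data)
    out.backward(g)
    xt, wt, bt = out.parents[0][0], out.parents[1][0], out.parents[2][0]
    loss = lambda arrs: run(*arrs).data.sum()
    for tensor, arr, pos in [(xt, x, 0), (wt, w, 1), (bt, b, 2)]:
        flat_idx = np.unravel_index([0, arr.size // 2, arr.size - 1], arr.shape)
        for idx in zip(*flat_idx):
            def f(a, i=idx, p=pos):
                arrs = [x, w, b]
                arrs[p] = a
                return loss(arrs)

            assert tensor.grad[idx] == pytest.approx(_num_grad(f, arr, idx), abs=1e-5)


def test_conv_transpose_gradients_and_shape():
    rng = np.random.default_rng(1)
    x = rng.normal(size=(2, 5, 5))
    w = rng.normal(size=(2, 3, 4, 4))
    out = conv_transpose2d(Tensor(x), Tensor(w), stride=2)
    assert out.data.shape == (3, 12, 12)
    out.backward(np.ones_like(out.data))
    xt, wt = out.parents[0][0], out.parents[1][0]
    for tensor, arr, pos in [(xt, x, 0), (wt, w, 1)]:
        for idx in [(0,) * arr.ndim, tuple(s - 1 for s in arr.shape)]:
            def f(a, i=idx, p=pos):
                arrs = [x, w]
                arrs[p] = a
                return conv_transpose2d(Tensor(arrs[0]), Tensor(arrs[1]), 2).data.sum()

            assert tensor.grad[idx] == pytest.approx(_num_grad(f, arr, idx), abs=1e-5)


def test_maxpool_ceil_shape_and_gradient_routing():
    x = np.arange(2 * 5 * 5, dtype=float).reshape(2, 5, 5)
    t = Tensor(x)
    out = maxpool2_ceil(t)
    assert out.data.shape == (2, 3, 3)
    assert out.data[0, 0, 0] == 6  # max of the top-left 2x2 window
    out.backward(np.ones_like(out.data))
    # gradient lands exactly on each window's argmax
    assert t.grad.sum() == out.data.size
    assert t.grad[0, 1, 1] == 1 and t.grad[0, 0, 0] == 0


def test_relu_and_crop_and_dropout_backward():
    x = np.array([[[-1.0, 2.0], [3.0, -4.0]]])
    t = Tensor(x)
    out = relu(t)
    out.backward(np.ones_like(out.data))
    np.testing.assert_array_equal(t.grad, [[[0, 1], [1, 0]]])

    t2 = Tensor(np.arange(16.0).reshape(1, 4, 4))
    c = crop_center(t2, (2, 2))
    np.testing.assert_array_equal(c.data[0], [[5, 6], [9, 10]])
    c.backward(np.ones_like(c.data))
    assert t2.grad.sum() == 4 and t2.grad[0, 1, 1] == 1

    rng = np.random.default_rng(0)
    t3 = Tensor(np.ones((1, 8, 8)))
    d = dropout(t3, 0.5, rng)
    kept = d.data > 0
    d.backward(np.ones_like(d.data))
    np.testing.assert_array_equal(t3.grad > 0, kept)


def test_shared_parameter_gradients_accumulate():
    w = Tensor(np.array([[2.0]]))
    a = Tensor(np.array([[3.0]]))
    s1 = Tensor(w.data * a.data, ((w, lambda g: g * a.data), (a, lambda g: g * w.data)))
    s2 = Tensor(s1.data * w.data, ((s1, lambda g: g * w.data), (w, lambda g: g * s1.data)))
    s2.backward(np.array([[1.0]]))
    assert w.grad[0, 0] == pytest.approx(2 * 2.0 * 3.0)  # d(w^2 a)/dw = 2wa


# ---------------------------------------------------------------------------
# whole-model contracts


def test_model_param_count_matches_analytic_audit(toy_model):
    aud = audit_architecture(toy_model.arch)
    assert toy_model.num_params() == aud["total_params"]


def test_full_size_audit_values():
    assert audit_architecture(dsl_fcn2s_spec(3))["by_name"]["dconv6"] == 18_878_464
    assert audit_architecture(dsl_fcn2s_spec(3))["total_millions"] == 50.39
    assert audit_architecture(fcn32s_baseline_spec(3))["by_name"]["conv6"] == 102_764_544


def test_forward_output_matches_input_frame(toy_model):
    rng = np.random.default_rng(0)
    x = rng.random((64, 64, 3))
    scores = toy_model.predict_scores(x)
    assert scores.shape == (3, 64, 64)


def test_inference_is_deterministic(toy_model):
    x = np.random.default_rng(1).random((64, 64, 3))
    a = toy_model.predict_scores(x)
    b = toy_model.predict_scores(x)
    np.testing.assert_array_equal(a, b)


def test_baseline_forward_shape():
    m = build_modified_fcn32_baseline(3, base_channels=8, fc_channels=16, input_size=64)
    assert m.predict_scores(np.zeros((64, 64, 3))).shape == (3, 64, 64)


def test_zeroed_skip_scales_silence_skip_branches():
    """With all fusion scales at zero the decoder ignores the skip paths:
    randomizing the skip-score weights cannot change the output (the
    FCN-32s-like degradation)."""
    spec = dsl_fcn2s_spec(3, input_size=64, base_channels=8, fc_channels=16, skip_scales=(0.0,) * 4)
    m = Model(spec, seed=0)
    x = np.random.default_rng(2).random((64, 64, 3))
    before = m.predict_scores(x)
    rng = np.random.default_rng(3)
    for name, p in m.params.items():
        if name.startswith("score_pool"):
            p["w"].data = rng.normal(size=p["w"].data.shape)
    np.testing.assert_array_equal(before, m.predict_scores(x))


def test_dilated_conv_receptive_field_matches_dense_seven():
    """A unit impulse probes the footprint: a 3x3 kernel at rate 3 responds
    over the same 7x7 extent as a dense 7x7 kernel."""
    x = np.zeros((1, 15, 15))
    x[0, 7, 7] = 1.0
    w3 = Tensor(np.ones((1, 1, 3, 3)))
    w7 = Tensor(np.ones((1, 1, 7, 7)))
    y_dil = conv2d(Tensor(x), w3, None, padding=3, dilation=3).data[0]
    y_dense = conv2d(Tensor(x), w7, None, padding=3, dilation=1).data[0]
    # dilated support is a sparse lattice inside the dense footprint ...
    assert (y_dense[y_dil != 0] != 0).all()
    # ... spanning exactly the same 7-pixel extent in both axes
    for y in (y_dil, y_dense):
        ys, xs = np.nonzero(y)
        assert ys.max() - ys.min() + 1 == 7 and xs.max() - xs.min() + 1 == 7


def test_bilinear_deconv_init_upsamples_constant_field_to_constant():
    k = bilinear_kernel(4)
    assert k.shape == (4, 4)
    m = build_dsl_fcn2s(3, **TOY, seed=0)
    w = m.params["deconv1"]["w"].data
    assert w.shape == (3, 3, 4, 4)
    np.testing.assert_allclose(w[0, 0], k)
    assert w[0, 1].sum() == 0
    # a constant map stays constant in the interior after x2 upsampling
    x = Tensor(np.ones((3, 6, 6)))
    y = conv_transpose2d(x, m.params["deconv1"]["w"], stride=2).data
    np.testing.assert_allclose(y[:, 2:-2, 2:-2], 1.0, atol=1e-12)


def test_save_load_roundtrip(tmp_path, toy_model):
    path = tmp_path / "model.npz"
    save_model(toy_model, path)
    back = load_model(path)
    x = np.random.default_rng(4).random((64, 64, 3))
    np.testing.assert_array_equal(toy_model.predict_scores(x), back.predict_scores(x))


def test_wrong_channel_count_rejected(toy_model):
    with pytest.raises(ValueError):
        toy_model.forward(np.zeros((64, 64, 4)))
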