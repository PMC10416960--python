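"""Trainable fully convolutional network executing an :class:`ArchitectureSpec`.

The package carries its own small reverse-mode autodiff engine and NumPy
implementations of the handful of layer types the architecture needs
(convolution with dilation, ceil-mode 2x2 max pooling, dropout, learnable
x2/x32 transposed convolution, center crop, constant scaling, element-wise
summation).  A model is just the layer table from :mod:`dslfcn.arch` plus a
parameter array per stage-bearing row, so the analytic parameter audit and
the trainable model can never drift apart: ``model.num_params()`` sums the
same stages :func:`dslfcn.dilation.audit_architecture` counts.

Shapes are batch-free ``(C, H, W)`` — training uses batch size one
throughout, matching the stochastic-gradient setup the method prescribes.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .arch import ArchitectureSpec, dsl_fcn2s_spec, fcn32s_baseline_spec

__all__ = [
    "Tensor",
    "Model",
    "build_dsl_fcn2s",
    "build_modified_fcn32_baseline",
    "bilinear_kernel",
]


# ---------------------------------------------------------------------------
# autodiff tape


class Tensor:
    """An array plus the closures that push a gradient to its parents."""

    __slots__ = ("data", "grad", "parents")

    def __init__(self, data: np.ndarray, parents=()):
        self.data = data
        self.grad = None
        self.parents = parents  # tuple of (Tensor, fn: upstream_grad -> parent_grad)

    @property
    def shape(self):
        return self.data.shape

    def backward(self, grad: np.ndarray) -> None:
        """Accumulate ``d(out)/d(self) = grad`` through the whole graph."""
        order: list[Tensor] = []
        seen: set[int] = set()

        def topo(t: "Tensor") -> None:
            if id(t) in seen:
                return
            seen.add(id(t))
            for p, _ in t.parents:
                topo(p)
            order.append(t)

        topo(self)
        pending: dict[int, np.ndarray] = {id(self): np.asarray(grad)}
        for t in reversed(order):
            g = pending.pop(id(t), None)
            if g is None:
                continue
            if t.grad is None:
                t.grad = g.copy()
            else:
                t.grad = t.grad + g
            for p, fn in t.parents:
                contrib = fn(g)
                if id(p) in pending:
                    pending[id(p)] = pending[id(p)] + contrib
                else:
                    pending[id(p)] = contrib


def _t(data, parents=(), track=True):
    return Tensor(data, parents if track else ())


# ---------------------------------------------------------------------------
# ops


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride=1, padding=0, dilation=1, track=True) -> Tensor:
    """2-D (dilated) convolution, im2col formulation.

    ``x``: (C, H, W); ``w``: (O, C, k, k); ``b``: (O,) or None.
    Output extent is ``(H + 2*padding - k_eff) // stride + 1`` with
    ``k_eff = k + (k-1)*(dilation-1)``.
    """
    C, H, W = x.data.shape
    O, Cw, k, _ = w.data.shape
    if Cw != C:
        raise ValueError(f"conv expects {Cw} input channels, got {C}")
    eff = k + (k - 1) * (dilation - 1)
    Hp, Wp = H + 2 * padding, W + 2 * padding
    if eff > Hp or eff > Wp:
        raise ValueError(f"effective kernel {eff} exceeds padded input ({Hp}, {Wp})")
    xp = np.pad(x.data, ((0, 0), (padding, padding), (padding, padding))) if padding else x.data
    win = sliding_window_view(xp, (eff, eff), axis=(1, 2))[:, ::stride, ::stride, ::dilation, ::dilation]
    Ho, Wo = win.shape[1], win.shape[2]
    cols = win.transpose(0, 3, 4, 1, 2).reshape(C * k * k, Ho * Wo)
    y = (w.data.reshape(O, -1) @ cols).reshape(O, Ho, Wo)
    if b is not None:
        y = y + b.data[:, None, None]

    def grad_w(g):
        return (g.reshape(O, -1) @ cols.T).reshape(w.data.shape)

    def grad_b(g):
        return g.sum(axis=(1, 2))

    def grad_x(g):
        dcols = (w.data.reshape(O, -1).T @ g.reshape(O, -1)).reshape(C, k, k, Ho, Wo)
        dxp = np.zeros((C, Hp, Wp), dtype=x.data.dtype)
        for ki in range(k):
            hi = ki * dilation
            for kj in range(k):
                wj = kj * dilation
                dxp[:, hi : hi + Ho * stride : stride, wj : wj + Wo * stride : stride] += dcols[:, ki, kj]
        return dxp[:, padding : padding + H, padding : padding + W] if padding else dxp

    parents = [(x, grad_x), (w, grad_w)]
    if b is not None:
        parents.append((b, grad_b))
    return _t(y, tuple(parents), track)


def conv_transpose2d(x: Tensor, w: Tensor, stride=2, track=True) -> Tensor:
    """Transposed convolution (learnable upsampler), no bias.

    ``x``: (C, H, W); ``w``: (C, O, k, k); output (O, (H-1)*stride + k, ...).
    """
    C, H, W = x.data.shape
    Cw, O, k, _ = w.data.shape
    if Cw != C:
        raise ValueError(f"deconv expects {Cw} input channels, got {C}")
    Ho, Wo = (H - 1) * stride + k, (W - 1) * stride + k
    y = np.zeros((O, Ho, Wo), dtype=x.data.dtype)
    for ki in range(k):
        for kj in range(k):
            y[:, ki : ki + H * stride : stride, kj : kj + W * stride : stride] += np.tensordot(
                w.data[:, :, ki, kj], x.data, axes=(0, 0)
            )

    def grad_x(g):
        dx = np.zeros_like(x.data)
        for ki in range(k):
            for kj in range(k):
                gs = g[:, ki : ki + H * stride : stride, kj : kj + W * stride : stride]
                dx += np.tensordot(w.data[:, :, ki, kj], gs, axes=(1, 0))
        return dx

    def grad_w(g):
        dw = np.zeros_like(w.data)
        for ki in range(k):
            for kj in range(k):
                gs = g[:, ki : ki + H * stride : stride, kj : kj + W * stride : stride]
                dw[:, :, ki, kj] = np.tensordot(x.data, gs, axes=((1, 2), (1, 2)))
        return dw

    return _t(y, ((x, grad_x), (w, grad_w)), track)


def relu(x: Tensor, track=True) -> Tensor:
    mask = x.data > 0
    return _t(x.data * mask, ((x, lambda g: g * mask),), track)


def maxpool2_ceil(x: Tensor, track=True) -> Tensor:
    """2x2 stride-2 max pooling, ceil mode (odd extents pad with -inf)."""
    C, H, W = x.data.shape
    Ho, Wo = -(-H // 2), -(-W // 2)
    xp = x.data
    if H % 2 or W % 2:
        xp = np.pad(xp, ((0, 0), (0, Ho * 2 - H), (0, Wo * 2 - W)), constant_values=-np.inf)
    win = xp.reshape(C, Ho, 2, Wo, 2).transpose(0, 1, 3, 2, 4).reshape(C, Ho, Wo, 4)
    idx = win.argmax(axis=3)
    y = np.take_along_axis(win, idx[..., None], axis=3)[..., 0]

    def grad_x(g):
        gw = np.zeros((C, Ho, Wo, 4), dtype=g.dtype)
        np.put_along_axis(gw, idx[..., None], g[..., None], axis=3)
        gp = gw.reshape(C, Ho, Wo, 2, 2).transpose(0, 1, 3, 2, 4).reshape(C, Ho * 2, Wo * 2)
        return gp[:, :H, :W]

    return _t(y, ((x, grad_x),), track)


def dropout(x: Tensor, rate: float, rng: np.random.Generator, track=True) -> Tensor:
    mask = (rng.random(x.data.shape) >= rate) / (1.0 - rate)
    return _t(x.data * mask, ((x, lambda g: g * mask),), track)


def crop_center(x: Tensor, target_hw: tuple[int, int], track=True) -> Tensor:
    """Center crop to ``target_hw`` (offsets rounded down)."""
    C, H, W = x.data.shape
    th, tw = target_hw
    if th > H or tw > W:
        raise ValueError(f"cannot crop ({H},{W}) to larger ({th},{tw})")
    oh, ow = (H - th) // 2, (W - tw) // 2
    y = x.data[:, oh : oh + th, ow : ow + tw]

    def grad_x(g):
        gp = np.zeros_like(x.data)
        gp[:, oh : oh + th, ow : ow + tw] = g
        return gp

    return _t(y, ((x, grad_x),), track)


def scale(x: Tensor, factor: float, track=True) -> Tensor:
    return _t(x.data * factor, ((x, lambda g: g * factor),), track)


def add(x: Tensor, y: Tensor, track=True) -> Tensor:
    return _t(x.data + y.data, ((x, lambda g: g), (y, lambda g: g)), track)


# ---------------------------------------------------------------------------
# model


def bilinear_kernel(k: int, dtype=np.float64) -> np.ndarray:
    """1-channel bilinear interpolation kernel of side ``k`` (FCN upsampler init)."""
    factor = (k + 1) // 2
    center = factor - 1 if k % 2 == 1 else factor - 0.5
    og = np.arange(k, dtype=dtype)
    f1 = 1 - np.abs(og - center) / factor
    return np.outer(f1, f1)


class Model:
    """Parameters + forward/backward execution of an :class:`ArchitectureSpec`."""

    DROPOUT_RATE = 0.5

    def __init__(self, arch: ArchitectureSpec, seed: int = 0, dtype=np.float64, input_offset: float = 0.5):
        self.arch = arch
        self.dtype = dtype
        # images arrive in [0, 1]; centering them is the usual mean-subtraction
        self.input_offset = input_offset
        self.params: dict[str, dict[str, Tensor]] = {}
        rng = np.random.default_rng(seed)
        for layer in arch.layers:
            st = layer.stage
            if st is None:
                continue
            if layer.kind == "deconv":
                # bilinear upsampler on the channel diagonal, learnable, bias-free
                w = np.zeros((st.in_channels, st.out_channels, st.kernel, st.kernel), dtype=dtype)
                fil = bilinear_kernel(st.kernel, dtype)
                for c in range(min(st.in_channels, st.out_channels)):
                    w[c, c] = fil
                self.params[layer.name] = {"w": Tensor(w)}
            else:
                fan_in = st.kernel * st.kernel * st.in_channels
                if layer.kind == "skip_score_conv":
                    w = np.zeros((st.out_channels, st.in_channels, st.kernel, st.kernel), dtype=dtype)
                else:
                    w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (st.out_channels, st.in_channels, st.kernel, st.kernel)).astype(dtype)
                p = {"w": Tensor(w)}
                if st.has_bias:
                    p["b"] = Tensor(np.zeros(st.out_channels, dtype=dtype))
                self.params[layer.name] = p

    # -- parameter utilities ------------------------------------------------

    def parameters(self) -> list[tuple[str, Tensor]]:
        out = []
        for name, p in self.params.items():
            for key, t in p.items():
                out.append((f"{name}.{key}", t))
        return out

    def num_params(self) -> int:
        return sum(t.data.size for _, t in self.parameters())

    def zero_grad(self) -> None:
        for _, t in self.parameters():
            t.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: t.data.copy() for name, t in self.parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, t in self.parameters():
            t.data = np.asarray(state[name], dtype=self.dtype).reshape(t.data.shape).copy()

    # -- execution ----------------------------------------------------------

    def forward(self, image: np.ndarray, train: bool = False, rng: np.random.Generator | None = None) -> Tensor:
        """Class-score map for one image.

        ``image`` is (H, W, 3) float (any range; callers normalize) or
        (3, H, W); output is a (n_classes, H, W) score Tensor.  ``train``
        enables dropout and gradient tracking.
        """
        x = np.asarray(image, dtype=self.dtype)
        if x.ndim != 3:
            raise ValueError(f"expected a 3-d image, got shape {x.shape}")
        if x.shape[-1] == self.arch.in_channels and x.shape[0] != self.arch.in_channels:
            x = np.moveaxis(x, -1, 0)
        if x.shape[0] != self.arch.in_channels:
            raise ValueError(f"expected {self.arch.in_channels} channels, got shape {x.shape}")
        if train and rng is None:
            rng = np.random.default_rng(0)
        track = train
        in_hw = x.shape[1:]
        cur = Tensor(x - self.input_offset)
        named: dict[str, Tensor] = {}
        for layer in self.arch.layers:
            kind = layer.kind
            if kind in ("conv", "dilated_conv", "skip_score_conv"):
                src = named[layer.source] if layer.source else cur
                p = self.params[layer.name]
                st = layer.stage
                out = conv2d(src, p["w"], p.get("b"), st.stride, st.padding, st.dilation, track)
            elif kind == "deconv":
                out = conv_transpose2d(cur, self.params[layer.name]["w"], layer.stage.stride, track)
            elif kind == "pool":
                out = maxpool2_ceil(cur, track)
            elif kind == "relu":
                out = relu(cur, track)
            elif kind == "dropout":
                out = dropout(cur, self.DROPOUT_RATE, rng, track) if train else cur
            elif kind == "scale":
                out = scale(named[layer.source], layer.scale, track)
            elif kind == "crop":
                if layer.crop_to == "input":
                    out = crop_center(cur, in_hw, track)
                else:
                    out = crop_center(named[layer.source], cur.data.shape[1:], track)
            elif kind == "eltwise_sum":
                out = add(cur, named[layer.source], track)
            else:
                raise ValueError(f"unknown layer kind {kind!r}")
            named[layer.name] = out
            if kind not in ("skip_score_conv", "scale") and not (kind == "crop" and layer.crop_to == "skip"):
                cur = out
        return cur

    def predict_scores(self, image: np.ndarray) -> np.ndarray:
        """Deterministic inference: raw (n_classes, H, W) score map."""
        return self.forward(image, train=False).data


def build_dsl_fcn2s(
    n_classes: int = 3,
    dilation: int = 3,
    g: int = 7,
    base_channels: int = 64,
    fc_channels: int = 4096,
    input_size: int = 512,
    skip_scales: tuple[float, ...] | None = None,
    seed: int = 0,
    dtype=np.float64,
) -> Model:
    """Dilated soft-label FCN-2s model (full-size defaults; shrink
    ``base_channels``/``fc_channels`` for a CPU-scale toy)."""
    kwargs = dict(
        n_classes=n_classes,
        input_size=input_size,
        dilation=dilation,
        g=g,
        base_channels=base_channels,
        fc_channels=fc_channels,
    )
    if skip_scales is not None:
        kwargs["skip_scales"] = tuple(skip_scales)
    model = Model(dsl_fcn2s_spec(**kwargs), seed=seed, dtype=dtype)
    model.build_info = {"builder": "dsl_fcn2s", **{k: list(v) if isinstance(v, tuple) else v for k, v in kwargs.items()}}
    return model


def build_modified_fcn32_baseline(
    n_classes: int = 3,
    base_channels: int = 64,
    fc_channels: int = 4096,
    input_size: int = 512,
    seed: int = 0,
    dtype=np.float64,
) -> Model:
    """Dense-7x7 FCN-32s baseline used for efficiency and ablation comparisons."""
    kwargs = dict(n_classes=n_classes, input_size=input_size, base_channels=base_channels, fc_channels=fc_channels)
    model = Model(fcn32s_baseline_spec(**kwargs), seed=seed, dtype=dtype)
    model.build_info = {"builder": "fcn32s_baseline", **kwargs}
    return model


def save_model(model: Model, path) -> None:
    """Serialize weights + builder configuration to an ``.npz`` checkpoint."""
    import json

    info = getattr(model, "build_info", None)
    if info is None:
        raise ValueError("model lacks build_info; construct it via build_dsl_fcn2s/build_modified_fcn32_baseline")
    state = {name.replace(".", "/"): t.data for name, t in model.parameters()}
    np.savez_compressed(str(path), __build_info__=json.dumps(info), **state)


def load_model(path, dtype=np.float64) -> Model:
    """Rebuild a model from an ``.npz`` checkpoint written by :func:`save_model`."""
    import json

    with np.load(str(path), allow_pickle=False) as z:
        info = json.loads(str(z["__build_info__"]))
        state = {k.replace("/", "."): z[k] for k in z.files if k != "__build_info__"}
    builder = info.pop("builder")
    if builder == "dsl_fcn2s":
        kwargs = dict(info)
        kwargs["skip_scales"] = tuple(kwargs["skip_scales"]) if "skip_scales" in kwargs else None
        model = build_dsl_fcn2s(
            n_classes=kwargs["n_classes"],
            dilation=kwargs["dilation"],
            g=kwargs["g"],
            base_channels=kwargs["base_channels"],
            fc_channels=kwargs["fc_channels"],
            input_size=kwargs["input_size"],
            skip_scales=kwargs["skip_scales"],
            dtype=dtype,
        )
    elif builder == "fcn32s_baseline":
        model = build_modified_fcn32_baseline(
            n_classes=info["n_classes"],
            base_channels=info["base_channels"],
            fc_channels=info["fc_channels"],
            input_size=info["input_size"],
            dtype=dtype,
        )
    else:
        raise ValueError(f"unknown builder {builder!r}")
    model.load_state_dict(state)
    return model
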