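"""Declarative layer stacks for the dilated soft-label FCN-2s and its baseline.

An :class:`ArchitectureSpec` is an ordered list of layer descriptions — the
same information a layer table in a network summary carries — from which the
package derives parameter audits (:func:`dslfcn.dilation.audit_architecture`),
per-layer output shapes (:func:`shape_trace`) and the actual trainable model
(:mod:`dslfcn.network`).  Keeping the description separate from the weights
lets the full-size architecture be audited in microseconds while training
runs use a narrow variant of the same stack.

The reference configuration is a VGG16-style encoder (border padding 100 on
the first convolution, five ceil-mode 2x2 max pools), a dilated sixth
convolution sized by the closed forms in :mod:`dslfcn.dilation` so that its
receptive field matches the dense 7x7 layer it replaces, two 4096-channel
heads, and five learnable x2 deconvolution stages fused with 1x1 skip-score
convolutions taken from the pool outputs (FCN-2s fusion), ending in a center
crop back to the input size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .dilation import (
    ConvStageSpec,
    FeatureShape,
    conv_output_shape,
    dilated_kernel_size,
)

__all__ = [
    "LayerSpec",
    "ArchitectureSpec",
    "dsl_fcn2s_spec",
    "fcn32s_baseline_spec",
    "shape_trace",
]

CONV_KINDS = frozenset({"conv", "dilated_conv", "skip_score_conv"})


@dataclass(frozen=True)
class LayerSpec:
    """One row of the architecture table.

    ``source`` names the layer a side branch reads from (skip-score
    convolutions read pool outputs); ``None`` means the running main path.
    ``crop_to`` is "input" for the final crop back to the image frame,
    "skip" for the crops that trim a skip branch to the deconvolution
    output before element-wise summation.
    """

    name: str
    kind: str  # conv | dilated_conv | skip_score_conv | relu | pool | dropout | deconv | crop | eltwise_sum | scale | input
    stage: Optional[ConvStageSpec] = None
    source: Optional[str] = None
    crop_to: Optional[str] = None
    scale: Optional[float] = None


@dataclass(frozen=True)
class ArchitectureSpec:
    name: str
    layers: tuple[LayerSpec, ...]
    n_classes: int
    input_size: int = 512
    in_channels: int = 3

    def layer(self, name: str) -> LayerSpec:
        for l in self.layers:
            if l.name == name:
                return l
        raise KeyError(name)


# Dampening factors applied to the skip-score branches before element-wise
# summation, deepest fusion first (pool4 ... pool1).  Shallow features enter
# with tiny weight so early training is dominated by the semantic deep path.
DEFAULT_SKIP_SCALES = (1e-2, 1e-4, 1e-6, 1e-8)


def _encoder_layers(
    in_channels: int,
    channels: tuple[int, ...],
    convs_per_block: tuple[int, ...],
    first_pad: int,
) -> list[LayerSpec]:
    layers: list[LayerSpec] = []
    prev = in_channels
    for block, (ch, n_convs) in enumerate(zip(channels, convs_per_block), start=1):
        for i in range(1, n_convs + 1):
            pad = first_pad if (block == 1 and i == 1) else 1
            layers.append(
                LayerSpec(
                    f"conv{block}_{i}",
                    "conv",
                    ConvStageSpec(prev, ch, kernel=3, stride=1, padding=pad),
                )
            )
            layers.append(LayerSpec(f"relu{block}_{i}", "relu"))
            prev = ch
        layers.append(LayerSpec(f"pool{block}", "pool"))
    return layers


def dsl_fcn2s_spec(
    n_classes: int = 3,
    input_size: int = 512,
    dilation: int = 3,
    g: int = 7,
    base_channels: int = 64,
    fc_channels: int = 4096,
    skip_scales: tuple[float, ...] = DEFAULT_SKIP_SCALES,
    in_channels: int = 3,
) -> ArchitectureSpec:
    """Dilated soft-label FCN-2s architecture.

    ``base_channels``/``fc_channels`` scale the width (64/4096 is the
    full-size reference; smaller values give a toy model with identical
    topology).  The sixth convolution's kernel is derived from the dense
    kernel ``g`` and the ``dilation`` rate, preserving the receptive field.
    """
    if n_classes < 2:
        raise ValueError("need at least background + one class")
    ch = tuple(base_channels * m for m in (1, 2, 4, 8, 8))
    layers = _encoder_layers(in_channels, ch, (2, 2, 3, 3, 3), first_pad=100)
    gamma = dilated_kernel_size(g, dilation)
    layers += [
        LayerSpec("dconv6", "dilated_conv", ConvStageSpec(ch[4], fc_channels, gamma, dilation=dilation)),
        LayerSpec("relu6", "relu"),
        LayerSpec("drop6", "dropout"),
        LayerSpec("conv7", "conv", ConvStageSpec(fc_channels, fc_channels, kernel=1)),
        LayerSpec("relu7", "relu"),
        LayerSpec("drop7", "dropout"),
        LayerSpec("score", "conv", ConvStageSpec(fc_channels, n_classes, kernel=1)),
    ]
    # FCN-2s decoder: five x2 deconvolutions, each (after the first four)
    # fused with a dampened 1x1 score of the matching pool output.
    skip_pools = ("pool4", "pool3", "pool2", "pool1")
    for i in range(1, 6):
        layers.append(
            LayerSpec(f"deconv{i}", "deconv", ConvStageSpec(n_classes, n_classes, kernel=4, stride=2, has_bias=False))
        )
        if i <= 4:
            pool = skip_pools[i - 1]
            pool_ch = ch[4 - i]
            layers.append(
                LayerSpec(f"score_{pool}", "skip_score_conv", ConvStageSpec(pool_ch, n_classes, kernel=1), source=pool)
            )
            layers.append(LayerSpec(f"scale_{pool}", "scale", source=f"score_{pool}", scale=skip_scales[i - 1]))
            layers.append(LayerSpec(f"crop{i}", "crop", crop_to="skip", source=f"scale_{pool}"))
            layers.append(LayerSpec(f"fuse{i}", "eltwise_sum", source=f"crop{i}"))
        else:
            layers.append(LayerSpec(f"crop{i}", "crop", crop_to="input"))
    return ArchitectureSpec("dsl_fcn2s", tuple(layers), n_classes, input_size, in_channels)


def fcn32s_baseline_spec(
    n_classes: int = 3,
    input_size: int = 512,
    base_channels: int = 64,
    fc_channels: int = 4096,
    in_channels: int = 3,
) -> ArchitectureSpec:
    """Modified FCN-32s efficiency/ablation baseline: dense 7x7 sixth
    convolution and a single x32 bilinear-style deconvolution."""
    if n_classes < 2:
        raise ValueError("need at least background + one class")
    ch = tuple(base_channels * m for m in (1, 2, 4, 8, 8))
    layers = _encoder_layers(in_channels, ch, (2, 2, 3, 3, 3), first_pad=100)
    layers += [
        LayerSpec("conv6", "conv", ConvStageSpec(ch[4], fc_channels, kernel=7)),
        LayerSpec("relu6", "relu"),
        LayerSpec("drop6", "dropout"),
        LayerSpec("conv7", "conv", ConvStageSpec(fc_channels, fc_channels, kernel=1)),
        LayerSpec("relu7", "relu"),
        LayerSpec("drop7", "dropout"),
        LayerSpec("score", "conv", ConvStageSpec(fc_channels, n_classes, kernel=1)),
        LayerSpec("deconv32", "deconv", ConvStageSpec(n_classes, n_classes, kernel=64, stride=32, has_bias=False)),
        LayerSpec("crop", "crop", crop_to="input"),
    ]
    return ArchitectureSpec("fcn32s_baseline", tuple(layers), n_classes, input_size, in_channels)


def shape_trace(arch: ArchitectureSpec, input_size: Optional[int] = None) -> list[tuple[str, FeatureShape]]:
    """Per-layer output shapes of the main path (and skip branches).

    Pools are ceil-mode (``ceil(d/2)`` for kernel 2 stride 2), deconvolution
    output extent is ``(d - 1) * stride + kernel``, and crops either trim the
    skip branch to the running main-path extent or trim the final map back
    to the input frame.
    """
    size = input_size or arch.input_size
    shapes: dict[str, FeatureShape] = {}
    cur = FeatureShape(size, size, arch.in_channels)
    trace: list[tuple[str, FeatureShape]] = [("input", cur)]
    for layer in arch.layers:
        src = shapes[layer.source] if layer.source is not None and layer.kind in ("skip_score_conv", "scale") else cur
        if layer.kind in ("conv", "dilated_conv", "skip_score_conv"):
            out = conv_output_shape(src, layer.stage)
        elif layer.kind == "pool":
            out = FeatureShape(math.ceil(cur.height / 2), math.ceil(cur.width / 2), cur.channels)
        elif layer.kind == "deconv":
            st = layer.stage
            out = FeatureShape(
                (cur.height - 1) * st.stride + st.kernel,
                (cur.width - 1) * st.stride + st.kernel,
                st.out_channels,
            )
        elif layer.kind == "crop":
            if layer.crop_to == "input":
                out = FeatureShape(size, size, cur.channels)
            else:  # skip branch trimmed to the main path; main path unchanged
                skip = shapes[layer.source]
                out = FeatureShape(cur.height, cur.width, skip.channels)
                shapes[layer.name] = out
                trace.append((layer.name, out))
                continue
        elif layer.kind == "scale":
            out = src
            shapes[layer.name] = out
            trace.append((layer.name, out))
            continue
        else:  # relu, dropout, eltwise_sum: identity on the main path
            out = cur
        shapes[layer.name] = out
        trace.append((layer.name, out))
        if layer.kind != "skip_score_conv":
            cur = out
    return trace
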