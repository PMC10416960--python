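"""Dilated-convolution arithmetic: kernel sizing, output shapes, parameter audits.

A dilated (atrous) convolution inserts ``dilation - 1`` zeros between the
elements of a small kernel, so a ``gamma x gamma`` kernel covers the same
input extent as a dense ``gamma_eff x gamma_eff`` kernel while storing only
``gamma**2`` weights per channel pair.  These closed forms let us size the
dilated sixth convolution of the segmentation network so that it preserves
the receptive field of the dense 7x7 layer it replaces, and audit how many
parameters the swap saves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "DilatedKernelSpec",
    "ConvStageSpec",
    "FeatureShape",
    "dilated_kernel_size",
    "effective_kernel_size",
    "conv_output_shape",
    "count_stage_params",
    "audit_architecture",
]


def dilated_kernel_size(g: int, dilation: int) -> int:
    """Kernel side length of a dilated convolution matching a dense ``g x g`` kernel.

    Computed as ``ceil((g + dilation - 1) / dilation)``.  With the default
    network's ``g = 7`` and ``dilation = 3`` this gives 3: a 3x3 kernel at
    rate 3 spans the same 7-pixel extent as the dense 7x7 kernel.

    Parameters
    ----------
    g : int
        Side length of the dense kernel to emulate (odd, positive).
    dilation : int
        Dilation rate (>= 1).  Rate 1 is an ordinary convolution.
    """
    if g < 1 or dilation < 1:
        raise ValueError(f"kernel size and dilation must be >= 1, got g={g}, dilation={dilation}")
    return math.ceil((g + dilation - 1) / dilation)


def effective_kernel_size(gamma: int, dilation: int) -> int:
    """Receptive-field side length of a ``gamma x gamma`` kernel at rate ``dilation``.

    ``gamma + (gamma - 1) * (dilation - 1)``: the stored taps plus the gaps
    the dilation opens between them.  For (gamma=3, dilation=3) this is 7,
    restoring the dense kernel's footprint.
    """
    if gamma < 1 or dilation < 1:
        raise ValueError(f"kernel size and dilation must be >= 1, got gamma={gamma}, dilation={dilation}")
    return gamma + (gamma - 1) * (dilation - 1)


@dataclass(frozen=True)
class DilatedKernelSpec:
    """Dense kernel size, dilation rate, and the derived dilated/effective sizes."""

    g: int
    dilation: int
    gamma: int = field(init=False)
    gamma_eff: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "gamma", dilated_kernel_size(self.g, self.dilation))
        object.__setattr__(self, "gamma_eff", effective_kernel_size(self.gamma, self.dilation))


@dataclass(frozen=True)
class FeatureShape:
    """Spatial (height, width) and channel extent of a feature map."""

    height: int
    width: int
    channels: int

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1 or self.channels < 1:
            raise ValueError(f"feature dimensions must be positive, got {self}")

    @property
    def hw(self) -> tuple[int, int]:
        return (self.height, self.width)


@dataclass(frozen=True)
class ConvStageSpec:
    """Hyperparameters of one convolution stage (dense or dilated)."""

    in_channels: int
    out_channels: int
    kernel: int
    dilation: int = 1
    stride: int = 1
    padding: int = 0
    has_bias: bool = True

    def __post_init__(self) -> None:
        if min(self.in_channels, self.out_channels, self.kernel, self.dilation, self.stride) < 1:
            raise ValueError(f"counts, kernel, dilation and stride must be >= 1: {self}")
        if self.padding < 0:
            raise ValueError(f"padding must be >= 0: {self}")

    @property
    def effective_kernel(self) -> int:
        return effective_kernel_size(self.kernel, self.dilation)


def conv_output_shape(inp: FeatureShape, stage: ConvStageSpec) -> FeatureShape:
    """Output feature shape of a (dilated) convolution stage.

    Height and width follow ``ceil((d + 2*padding - k_eff) / stride + 1)``
    where ``k_eff`` is the dilation-expanded kernel extent; the channel count
    is the stage's output channels.

    Raises
    ------
    ValueError
        If the effective kernel exceeds the padded input ("shape error").
    """
    k_eff = stage.effective_kernel
    out_hw = []
    for d in inp.hw:
        padded = d + 2 * stage.padding
        if k_eff > padded:
            raise ValueError(
                f"effective kernel {k_eff} exceeds padded input extent {padded} "
                f"(input {d}, padding {stage.padding})"
            )
        out_hw.append(math.ceil((padded - k_eff) / stage.stride + 1))
    return FeatureShape(out_hw[0], out_hw[1], stage.out_channels)


def count_stage_params(stage: ConvStageSpec) -> int:
    """Trainable parameters of a convolution stage.

    ``kernel**2 * in_channels * out_channels`` weights plus one bias per
    output channel when ``has_bias``.  Dilation never changes the count —
    that is the whole point of the dilated sixth convolution.
    """
    n = stage.kernel * stage.kernel * stage.in_channels * stage.out_channels
    if stage.has_bias:
        n += stage.out_channels
    return n


def _round_millions(n: int) -> float:
    """Half-up rounding of ``n / 1e6`` to two decimals (Python's bankers'
    rounding would turn 0.125 into 0.12)."""
    return math.floor(n / 1e6 * 100 + 0.5) / 100


def audit_architecture(arch) -> dict:
    """Per-layer parameter table and totals for an architecture description.

    Parameters
    ----------
    arch : ArchitectureSpec
        Ordered layer list; only layers carrying a :class:`ConvStageSpec`
        (convolutions, skip-score convolutions, deconvolutions) contribute.

    Returns
    -------
    dict with keys ``layers`` (list of ``(name, kind, params)``),
    ``total_params`` (raw count), ``total_millions`` (rounded to 2 decimals),
    and ``by_name`` (name -> params).
    """
    rows = []
    by_name = {}
    total = 0
    for layer in arch.layers:
        stage = getattr(layer, "stage", None)
        n = count_stage_params(stage) if stage is not None else 0
        rows.append((layer.name, layer.kind, n))
        by_name[layer.name] = n
        total += n
    return {
        "layers": rows,
        "total_params": total,
        "total_millions": _round_millions(total),
        "by_name": by_name,
    }
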