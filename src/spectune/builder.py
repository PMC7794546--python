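"""Translate a hyperparameter configuration into an exact layer specification.

Building is pure shape arithmetic — no weights, no backend — so an optimal
architecture can be reproduced and inspected in milliseconds. A Conv-block
stacks convolution, optional batch normalisation, activation, optional
pooling and optional dropout, in that order; an FC-block stacks a dense
layer, optional batch normalisation, activation and optional dropout; the
network ends in a single linear output unit. Same/Valid padding follows the
ubiquitous convention: Same gives ceil(w/stride) output width with symmetric
zero padding, Valid uses no padding.

Architectures whose width arithmetic collapses below one point are rejected
with InfeasibleArchitectureError; the training objective maps that to a
penalty value rather than repairing the configuration, so the optimiser
learns to avoid the region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .space import Configuration

__all__ = [
    "LayerSpec",
    "ArchitectureSpec",
    "InfeasibleArchitectureError",
    "conv_output_width",
    "build",
    "count_parameters",
    "channel_states_from_config",
]


class InfeasibleArchitectureError(ValueError):
    """The configuration's shape arithmetic produces an impossible layer."""


@dataclass(frozen=True)
class LayerSpec:
    layer_type: str  # convolutional | batch_norm | activation | pooling | dropout | flatten | dense
    params: dict
    output_width: int
    output_channels: int

    def __post_init__(self) -> None:
        if self.output_width < 1:
            raise InfeasibleArchitectureError(
                f"{self.layer_type}: output width {self.output_width} < 1"
            )


@dataclass
class ArchitectureSpec:
    layers: list[LayerSpec] = field(default_factory=list)
    input_width: int = 0
    input_channels: int = 0
    n_parameters: int = 0

    def summary_rows(self) -> list[dict]:
        """Table rows (layer type, kernel, filters, padding, strides, output
        width, activation) for reporting."""
        rows = []
        for ly in self.layers:
            p = ly.params
            rows.append(
                {
                    "layer_type": ly.layer_type,
                    "kernel_size": p.get("kernel", p.get("pool_size", "")),
                    "filters": p.get("filters", ""),
                    "padding": p.get("padding", ""),
                    "strides": p.get("stride", ""),
                    "output_width": ly.output_width,
                    "output_channels": ly.output_channels,
                    "units": p.get("units", ""),
                    "activation": p.get("activation", ""),
                    "rate": p.get("rate", ""),
                }
            )
        return rows


def conv_output_width(input_w: int, kernel: int, stride: int, padding: str) -> int:
    """Output width of a strided 1-D convolution or pooling window.

    Same: ceil(input_w / stride). Valid: floor((input_w - kernel)/stride) + 1,
    infeasible when kernel > input_w.
    """
    if input_w < 1 or kernel < 1 or stride < 1:
        raise ValueError("input width, kernel and stride must be >= 1")
    if padding == "Same":
        return math.ceil(input_w / stride)
    if padding == "Valid":
        if kernel > input_w:
            raise InfeasibleArchitectureError(
                f"Valid padding with kernel {kernel} > input width {input_w}"
            )
        return (input_w - kernel) // stride + 1
    raise ValueError(f"unknown padding type {padding!r}")


def channel_states_from_config(config: Configuration):
    """Map channel state flags to a preprocessing ChannelStates."""
    from .preprocessing import ChannelStates

    return ChannelStates(
        reflectance=config.get("channel_reflectance", "OFF") == "ON",
        absorbance=config.get("channel_absorbance", "OFF") == "ON",
        abs_d1=config.get("channel_abs_d1", "OFF") == "ON",
        abs_d2=config.get("channel_abs_d2", "OFF") == "ON",
        abs_snv=config.get("channel_abs_snv", "OFF") == "ON",
    )


def build(config: Configuration, input_width: int, input_channels: int) -> ArchitectureSpec:
    """Deterministically expand a configuration into ordered layer specs.

    Raises InfeasibleArchitectureError when any stage width drops below 1.
    """
    if input_width < 1 or input_channels < 1:
        raise ValueError("input width and channels must be >= 1")
    layers: list[LayerSpec] = []
    w = input_width
    ch = input_channels
    n_params = 0

    n_conv = int(config["n_conv_blocks"])
    for i in range(1, n_conv + 1):
        filters = int(config[f"conv{i}_filters"])
        kernel = int(config[f"conv{i}_kernel"])
        stride = int(config[f"conv{i}_stride"])
        padding = config[f"conv{i}_padding"]
        w = conv_output_width(w, kernel, stride, padding)
        n_params += (kernel * ch + 1) * filters
        ch = filters
        layers.append(
            LayerSpec(
                "convolutional",
                {"kernel": kernel, "filters": filters, "stride": stride, "padding": padding},
                w,
                ch,
            )
        )
        if config[f"conv{i}_batch_norm"] == "ON":
            n_params += 2 * ch
            layers.append(LayerSpec("batch_norm", {}, w, ch))
        layers.append(
            LayerSpec("activation", {"activation": config[f"conv{i}_activation"]}, w, ch)
        )
        if config[f"conv{i}_pooling"] == "ON":
            psize = int(config[f"conv{i}_pool_size"])
            pstride = int(config[f"conv{i}_pool_stride"])
            ppad = config[f"conv{i}_pool_padding"]
            w = conv_output_width(w, psize, pstride, ppad)
            layers.append(
                LayerSpec(
                    "pooling",
                    {
                        "pool_type": config[f"conv{i}_pool_type"],
                        "pool_size": psize,
                        "stride": pstride,
                        "padding": ppad,
                    },
                    w,
                    ch,
                )
            )
        if config[f"conv{i}_dropout"] == "ON":
            layers.append(
                LayerSpec("dropout", {"rate": float(config["conv_dropout_rate"])}, w, ch)
            )

    flat = w * ch
    layers.append(LayerSpec("flatten", {}, flat, 1))
    w = flat

    n_fc = int(config["n_fc_blocks"])
    for j in range(1, n_fc + 1):
        units = int(config[f"fc{j}_nodes"])
        n_params += (w + 1) * units
        w = units
        layers.append(LayerSpec("dense", {"units": units}, w, 1))
        if config[f"fc{j}_batch_norm"] == "ON":
            n_params += 2 * units
            layers.append(LayerSpec("batch_norm", {}, w, 1))
        layers.append(LayerSpec("activation", {"activation": config[f"fc{j}_activation"]}, w, 1))
        if config[f"fc{j}_dropout"] == "ON":
            layers.append(LayerSpec("dropout", {"rate": float(config["fc_dropout_rate"])}, w, 1))

    n_params += (w + 1) * 1
    layers.append(LayerSpec("dense", {"units": 1, "activation": "Linear"}, 1, 1))

    return ArchitectureSpec(
        layers=layers,
        input_width=input_width,
        input_channels=input_channels,
        n_parameters=n_params,
    )


def count_parameters(arch: ArchitectureSpec) -> int:
    """Trainable parameter count from shapes alone.

    conv: (kernel * in_channels + 1) * filters; dense: (in + 1) * units;
    batch norm: 2 per normalised feature (running statistics excluded).
    Recomputed from the layer chain as an internal consistency check.
    """
    total = 0
    w = arch.input_width
    ch = arch.input_channels
    flat_in = None
    prev_width = None
    for ly in arch.layers:
        if ly.layer_type == "convolutional":
            total += (ly.params["kernel"] * ch + 1) * ly.params["filters"]
            ch = ly.output_channels
        elif ly.layer_type == "batch_norm":
            total += 2 * (ly.output_channels if flat_in is None else ly.output_width)
        elif ly.layer_type == "flatten":
            flat_in = ly.output_width
            prev_width = ly.output_width
        elif ly.layer_type == "dense":
            total += (prev_width + 1) * ly.params["units"]
            prev_width = ly.params["units"]
        w = ly.output_width
    return total
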