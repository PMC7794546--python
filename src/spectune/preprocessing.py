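"""Spectral preprocessing channels.

Five channels are supported, in a fixed canonical order: raw reflectance (R),
absorbance (ABS = log10(1/R)), absorbance first derivative (ABS+D1),
absorbance second derivative (ABS+D2), and absorbance after a standard normal
variate transform (ABS+SNV). Each channel has an ON/OFF state; the ON
channels are stacked into a (n_samples, n_points, n_channels) array that a
1D-CNN consumes.

Derivatives are central finite differences with one-sided differences at the
borders (length-preserving, so all channels stack). SNV centres and scales
each spectrum by its own mean and population standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import SpectraDataset

__all__ = [
    "CHANNEL_ORDER",
    "ChannelStates",
    "ChannelStack",
    "ChannelScaler",
    "DegenerateSpectrumError",
    "to_absorbance",
    "derivative",
    "snv",
    "assemble",
]

#: Canonical channel order; ON channels keep this relative order.
CHANNEL_ORDER = ("reflectance", "absorbance", "abs_d1", "abs_d2", "abs_snv")

_SNV_TOL = 1e-12


class DegenerateSpectrumError(ValueError):
    """Raised when SNV is applied to an (almost) constant spectrum."""


@dataclass(frozen=True)
class ChannelStates:
    """ON/OFF state per preprocessing channel."""

    reflectance: bool = True
    absorbance: bool = True
    abs_d1: bool = True
    abs_d2: bool = True
    abs_snv: bool = True

    def active(self) -> tuple[str, ...]:
        return tuple(name for name in CHANNEL_ORDER if getattr(self, name))

    @property
    def n_active(self) -> int:
        return len(self.active())


@dataclass
class ChannelStack:
    """Preprocessed multi-channel signal, shape (n_samples, n_points, n_channels)."""

    data: np.ndarray
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.data.ndim != 3 or self.data.shape[2] != len(self.channel_names):
            raise ValueError("data must be (n_samples, n_points, n_channels)")

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]


def to_absorbance(reflectance: np.ndarray) -> np.ndarray:
    """Absorbance A = log10(1/R), elementwise; requires R > 0."""
    r = np.asarray(reflectance, dtype=float)
    if np.any(r <= 0):
        raise ValueError("reflectance must be strictly positive for absorbance")
    return -np.log10(r)


def derivative(x: np.ndarray, order: int = 1) -> np.ndarray:
    """Finite-difference derivative along the last axis, length-preserving.

    Interior points use central differences (x[i+1]-x[i-1])/2 w.r.t. the
    index; the borders use one-sided differences. order=2 applies the
    operator twice.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < order + 1:
        raise ValueError(f"need at least {order + 1} points for order-{order} derivative")
    out = np.gradient(x, axis=-1, edge_order=1)
    if order == 2:
        out = np.gradient(out, axis=-1, edge_order=1)
    return out


def snv(x: np.ndarray) -> np.ndarray:
    """Standard normal variate: per-spectrum centring and unit (population) sd.

    Operates along the last axis; raises DegenerateSpectrumError for constant
    spectra (sd below 1e-12).
    """
    x = np.asarray(x, dtype=float)
    mean = x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, keepdims=True)  # population (1/n) sd
    if np.any(sd < _SNV_TOL):
        raise DegenerateSpectrumError("constant spectrum: SNV undefined")
    return (x - mean) / sd


def assemble(ds: SpectraDataset, states: ChannelStates) -> ChannelStack:
    """Compute the ON channels for every sample and stack them.

    Derivative and SNV channels are computed on absorbance. The returned
    stack is unscaled; fold-wise standardisation is the trainer's job (see
    ChannelScaler), so that scaler statistics never leak across CV folds.
    """
    active = states.active()
    if not active:
        raise ValueError("at least one channel must be ON")
    r = ds.reflectance
    a = to_absorbance(r) if any(name != "reflectance" for name in active) else None
    channels = []
    for name in active:
        if name == "reflectance":
            channels.append(r)
        elif name == "absorbance":
            channels.append(a)
        elif name == "abs_d1":
            channels.append(derivative(a, 1))
        elif name == "abs_d2":
            channels.append(derivative(a, 2))
        elif name == "abs_snv":
            channels.append(snv(a))
    return ChannelStack(data=np.stack(channels, axis=-1), channel_names=active)


class ChannelScaler:
    """Per-channel z-standardisation fitted on a training partition.

    Statistics are taken over samples and wavelengths of each channel. Fit on
    the training rows of a fold only, then applied to both partitions.
    """

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.sd_: np.ndarray | None = None

    def fit(self, stack: ChannelStack, rows: np.ndarray | None = None) -> "ChannelScaler":
        data = stack.data if rows is None else stack.data[rows]
        self.mean_ = data.mean(axis=(0, 1))
        sd = data.std(axis=(0, 1))
        self.sd_ = np.where(sd < 1e-12, 1.0, sd)
        return self

    def transform(self, stack: ChannelStack) -> ChannelStack:
        if self.mean_ is None:
            raise RuntimeError("scaler is not fitted")
        return ChannelStack(
            data=(stack.data - self.mean_) / self.sd_, channel_names=stack.channel_names
        )
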