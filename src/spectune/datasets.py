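"""Spectral datasets: a synthetic vis-NIR generator and a delimited-text loader.

The synthetic generator emulates the structure of large topsoil vis-NIR
libraries: reflectance spectra on a 400-2500 nm grid at 0.5 nm resolution
(4201 points), built from a smooth baseline minus broad, overlapping Gaussian
absorption bands, with a right-skewed, non-negative regression target (a soil
organic carbon role, g/kg) that controls the depth of a subset of the bands.
Every downstream stage (preprocessing, architecture search, importance) is
testable against it without any external data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default vis-NIR grid constants (nm).
VIS_NIR_START = 400.0
VIS_NIR_END = 2500.0
VIS_NIR_STEP = 0.5

__all__ = [
    "WavelengthGrid",
    "SpectraDataset",
    "SyntheticConfig",
    "generate",
    "downsample",
    "load_table",
    "save_table",
]


@dataclass(frozen=True)
class WavelengthGrid:
    """A uniform wavelength grid in nanometres."""

    start_nm: float = VIS_NIR_START
    end_nm: float = VIS_NIR_END
    step_nm: float = VIS_NIR_STEP

    def __post_init__(self) -> None:
        if self.step_nm <= 0:
            raise ValueError(f"step_nm must be > 0, got {self.step_nm}")
        if self.end_nm < self.start_nm:
            raise ValueError("end_nm must be >= start_nm")

    @property
    def n_points(self) -> int:
        return int(round((self.end_nm - self.start_nm) / self.step_nm)) + 1

    @property
    def wavelengths(self) -> np.ndarray:
        return self.start_nm + self.step_nm * np.arange(self.n_points)


@dataclass
class SpectraDataset:
    """Reflectance spectra plus one numeric target per sample.

    Reflectance values must lie in (0, 1] so that absorbance log10(1/R)
    is finite everywhere.
    """

    grid: WavelengthGrid
    reflectance: np.ndarray  # (n_samples, n_points)
    target: np.ndarray  # (n_samples,)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        self.target = np.asarray(self.target, dtype=float)
        if self.reflectance.ndim != 2:
            raise ValueError("reflectance must be a 2-D matrix")
        n, p = self.reflectance.shape
        if p != self.grid.n_points:
            raise ValueError(
                f"reflectance has {p} columns but grid has {self.grid.n_points} points"
            )
        if self.target.shape != (n,):
            raise ValueError("target length must equal the number of samples")
        if not np.all(np.isfinite(self.reflectance)):
            raise ValueError("reflectance contains non-finite values")
        if np.any(self.reflectance <= 0) or np.any(self.reflectance > 1):
            raise ValueError("reflectance values must lie in (0, 1]")
        if not self.sample_ids:
            self.sample_ids = [f"s{i:05d}" for i in range(n)]
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length mismatch")

    @property
    def n_samples(self) -> int:
        return self.reflectance.shape[0]

    @property
    def n_points(self) -> int:
        return self.reflectance.shape[1]


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the synthetic vis-NIR generator.

    n_peaks absorption bands are placed on the grid; the first ~half are
    "analyte" bands whose depth grows linearly with the target draw, the rest
    are nuisance bands with sample-specific random depths (a mineral-matrix
    role). The target is lognormal, i.e. positive and right-skewed, as soil
    organic carbon distributions are: exp(N(target_log_mean, target_log_sd))
    gives a median of ~20 g/kg with a long upper tail under the defaults.
    baseline_jitter adds smooth per-sample baseline variation (albedo shifts).
    """

    n_samples: int = 1000
    n_peaks: int = 8
    noise_sd: float = 0.003
    target_log_mean: float = 3.0
    target_log_sd: float = 0.8
    baseline_jitter: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 10:
            raise ValueError(f"n_samples must be >= 10, got {self.n_samples}")
        if self.n_peaks < 0:
            raise ValueError("n_peaks must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.target_log_sd < 0 or self.baseline_jitter < 0:
            raise ValueError("scale parameters must be >= 0")


def generate(config: SyntheticConfig, grid: WavelengthGrid | None = None) -> SpectraDataset:
    """Generate a synthetic reflectance dataset with a known target.

    Reflectance = smooth baseline - sum of Gaussian absorption bands + noise,
    clipped to (1e-6, 1]. Band depths of analyte bands are linear in the
    target, so 1 - min(R) correlates with the target by construction.
    Bit-identical output for a fixed config (seeded).
    """
    if grid is None:
        grid = WavelengthGrid()
    if grid.n_points < 50:
        raise ValueError("grid must have at least 50 points")
    rng = np.random.default_rng(config.seed)
    n, p = config.n_samples, grid.n_points
    lam = grid.wavelengths
    lam01 = (lam - lam[0]) / max(lam[-1] - lam[0], 1.0)

    target = rng.lognormal(config.target_log_mean, config.target_log_sd, size=n)
    # Reference scale such that depths rarely clip: ~97.7th percentile of the law.
    t_ref = float(np.exp(config.target_log_mean + 2.0 * config.target_log_sd))

    # Flat mean albedo with smooth per-sample offset/tilt jitter; keeping the
    # common shape flat makes band depth an affine function of the target.
    offset = rng.normal(0.0, config.baseline_jitter, size=n)
    tilt = rng.normal(0.0, config.baseline_jitter, size=n)
    baseline = 0.60 + offset[:, None] + tilt[:, None] * (lam01 - 0.5)[None, :]

    absorption = np.zeros((n, p))
    if config.n_peaks > 0:
        margin = min(50.0, 0.2 * (lam[-1] - lam[0]))
        centers = rng.uniform(lam[0] + margin, lam[-1] - margin, size=config.n_peaks)
        widths = rng.uniform(30.0, 150.0, size=config.n_peaks)
        n_analyte = (config.n_peaks + 1) // 2
        amp = rng.uniform(0.05, 0.25, size=config.n_peaks)
        nuis_amp = rng.uniform(0.0, 0.08, size=config.n_peaks)
        profiles = np.exp(-0.5 * ((lam[None, :] - centers[:, None]) / widths[:, None]) ** 2)
        depth = np.zeros((n, config.n_peaks))
        depth[:, :n_analyte] = amp[None, :n_analyte] * (target / t_ref)[:, None]
        depth[:, n_analyte:] = nuis_amp[None, n_analyte:] * rng.uniform(
            0.0, 1.0, size=(n, config.n_peaks - n_analyte)
        )
        absorption = depth @ profiles

    reflectance = baseline - absorption
    if config.noise_sd > 0:
        reflectance = reflectance + rng.normal(0.0, config.noise_sd, size=(n, p))
    reflectance = np.clip(reflectance, 1e-6, 1.0)
    return SpectraDataset(grid=grid, reflectance=reflectance, target=target)


def downsample(ds: SpectraDataset, factor: int) -> SpectraDataset:
    """Keep every `factor`-th wavelength starting at index 0 (strided selection).

    A 4201-point grid at factor 20 yields 211 points (indices 0, 20, ..., 4200).
    """
    if int(factor) != factor or factor <= 0:
        raise ValueError(f"downsampling factor must be a positive integer, got {factor}")
    factor = int(factor)
    if factor == 1:
        return ds
    kept = ds.reflectance[:, ::factor]
    wl = ds.grid.wavelengths[::factor]
    new_grid = WavelengthGrid(
        start_nm=ds.grid.start_nm,
        end_nm=float(wl[-1]),
        step_nm=ds.grid.step_nm * factor,
    )
    return SpectraDataset(
        grid=new_grid, reflectance=kept, target=ds.target.copy(), sample_ids=list(ds.sample_ids)
    )


def _infer_grid(wavelengths: np.ndarray) -> WavelengthGrid:
    if len(wavelengths) < 2:
        raise ValueError("need at least two wavelength columns")
    steps = np.diff(wavelengths)
    step = float(steps[0])
    if step <= 0 or not np.allclose(steps, step, rtol=0, atol=1e-6 * max(step, 1.0)):
        raise ValueError("wavelength columns must form a uniform increasing grid")
    return WavelengthGrid(start_nm=float(wavelengths[0]), end_nm=float(wavelengths[-1]), step_nm=step)


def load_table(path, target_column: str = "target", sep: str | None = None) -> SpectraDataset:
    """Load a spectra table: header = wavelengths (nm) plus one target column.

    One row per sample. Rows containing non-finite values are dropped with a
    logged count. The delimiter is sniffed when `sep` is None.
    """
    import csv as _csv

    try:
        df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    except (pd.errors.EmptyDataError, pd.errors.ParserError, _csv.Error) as exc:
        raise ValueError(f"empty or unparsable spectra table: {path}") from exc
    if target_column not in df.columns:
        raise ValueError(f"target column {target_column!r} not found in {path}")
    wl_cols = [c for c in df.columns if c != target_column]
    try:
        wavelengths = np.array([float(c) for c in wl_cols])
    except ValueError as exc:
        raise ValueError("non-wavelength column in header (expected numeric nm values)") from exc
    values = df[wl_cols + [target_column]].apply(pd.to_numeric, errors="coerce").to_numpy(float)
    finite = np.all(np.isfinite(values), axis=1)
    n_dropped = int((~finite).sum())
    if n_dropped:
        logger.warning("dropped %d row(s) with non-finite values from %s", n_dropped, path)
    values = values[finite]
    if values.shape[0] == 0:
        raise ValueError(f"no valid sample rows in {path}")
    grid = _infer_grid(wavelengths)
    return SpectraDataset(grid=grid, reflectance=values[:, :-1], target=values[:, -1])


def save_table(ds: SpectraDataset, path, target_column: str = "target") -> None:
    """Write a dataset in the same delimited layout that load_table reads."""
    cols = [f"{w:g}" for w in ds.grid.wavelengths]
    df = pd.DataFrame(ds.reflectance, columns=cols)
    df[target_column] = ds.target
    df.to_csv(path, index=False)
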