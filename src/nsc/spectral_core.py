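"""Spectrum data types, CSV I/O, resampling and radiance computation.

A :class:`Spectrum` is a wavelength-sampled function on a uniform
:class:`WavelengthGrid`.  Three kinds are distinguished: ``reflectance``
(proportion of photons reflected, nominally in [0, 1]), ``illuminant``
(relative photon or energy flux of the incident light) and ``radiance``
(flux reaching the eye).  For pigment colors the radiance is the pointwise
product of reflectance and illuminant; structural colors should bypass
:func:`radiance` and supply measured radiance spectra directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WavelengthGrid",
    "Spectrum",
    "SpectrumWarning",
    "read_spectra",
    "write_spectra",
    "resample",
    "radiance",
    "DEFAULT_GRID",
]

SpectrumKind = Literal["reflectance", "illuminant", "radiance"]

_VALID_KINDS = ("reflectance", "illuminant", "radiance")

#: absolute tolerance for wavelength comparisons (nm)
_WL_TOL = 1e-9


class SpectrumWarning(UserWarning):
    """Non-fatal data oddity (e.g. measured reflectance above 1)."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength grid ``lambda_min, lambda_min+step, ..., lambda_max``.

    Parameters
    ----------
    lambda_min, lambda_max : float
        Inclusive range endpoints in nm.
    step : float
        Bin width in nm.  ``lambda_max - lambda_min`` must be an integer
        multiple of ``step``.
    """

    lambda_min: float
    lambda_max: float
    step: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "lambda_min", float(self.lambda_min))
        object.__setattr__(self, "lambda_max", float(self.lambda_max))
        object.__setattr__(self, "step", float(self.step))
        if not self.lambda_min < self.lambda_max:
            raise ValueError(
                f"lambda_min ({self.lambda_min}) must be < lambda_max ({self.lambda_max})"
            )
        if self.step <= 0:
            raise ValueError(f"step must be > 0, got {self.step}")
        span = self.lambda_max - self.lambda_min
        n = span / self.step
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"grid span {span} nm is not an integer multiple of step {self.step} nm"
            )

    @property
    def n_samples(self) -> int:
        return int(round((self.lambda_max - self.lambda_min) / self.step)) + 1

    @property
    def wavelengths(self) -> np.ndarray:
        return self.lambda_min + self.step * np.arange(self.n_samples)

    def contains(self, other: "WavelengthGrid") -> bool:
        """Whether ``other``'s range lies within this grid's range."""
        return (
            other.lambda_min >= self.lambda_min - _WL_TOL
            and other.lambda_max <= self.lambda_max + _WL_TOL
        )


#: bee-relevant default working range
DEFAULT_GRID = WavelengthGrid(300.0, 700.0, 1.0)


@dataclass(frozen=True)
class Spectrum:
    """A non-negative function sampled on a uniform wavelength grid."""

    grid: WavelengthGrid
    values: np.ndarray
    kind: SpectrumKind
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if self.kind not in _VALID_KINDS:
            raise ValueError(f"unknown spectrum kind {self.kind!r}")
        if values.ndim != 1 or len(values) != self.grid.n_samples:
            raise ValueError(
                f"values length {values.shape} does not match grid sample count "
                f"{self.grid.n_samples}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("spectrum contains non-finite values")
        if np.any(values < 0):
            raise ValueError("negative spectral values are not allowed")
        if self.kind == "reflectance" and np.any(values > 1.0):
            warnings.warn(
                f"reflectance spectrum {self.name or '<unnamed>'} has values > 1 "
                f"(max {values.max():.4g}); proceeding",
                SpectrumWarning,
                stacklevel=2,
            )

    @property
    def wavelengths(self) -> np.ndarray:
        return self.grid.wavelengths

    def scaled(self, c: float) -> "Spectrum":
        """Return a copy with values multiplied by a non-negative scalar."""
        if c < 0:
            raise ValueError("scale factor must be >= 0")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", SpectrumWarning)
            return Spectrum(self.grid, self.values * c, self.kind, self.name)


def _grid_from_wavelengths(wl: np.ndarray) -> WavelengthGrid:
    if len(wl) < 2:
        raise ValueError("need at least two wavelength samples")
    diffs = np.diff(wl)
    if np.any(diffs <= 0):
        raise ValueError("non-monotone wavelengths")
    step = diffs[0]
    if not np.allclose(diffs, step, rtol=0, atol=1e-6):
        raise ValueError(
            "non-uniform wavelength spacing; resample the input onto a uniform "
            "grid explicitly before use"
        )
    return WavelengthGrid(float(wl[0]), float(wl[-1]), float(step))


def read_spectra(path: str | Path, kind: SpectrumKind) -> list[Spectrum]:
    """Read spectra from a CSV table with a leading wavelength column.

    The header row must be ``wavelength,<name1>,<name2>,...``; one
    :class:`Spectrum` is returned per value column, all sharing one grid.
    Wavelengths must be strictly increasing and uniformly spaced.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need a wavelength column and at least one value column")
    wl = df.iloc[:, 0].to_numpy(dtype=float)
    grid = _grid_from_wavelengths(wl)
    spectra = []
    for col in df.columns[1:]:
        vals = df[col].to_numpy(dtype=float)
        if np.any(~np.isfinite(vals)):
            raise ValueError(f"{path}: column {col!r} has missing or non-finite values")
        if np.any(vals < 0):
            raise ValueError(f"{path}: column {col!r} has negative values")
        spectra.append(Spectrum(grid, vals, kind, name=str(col)))
    return spectra


def write_spectra(path: str | Path, spectra: Sequence[Spectrum]) -> None:
    """Write spectra sharing one grid to a CSV table (inverse of read_spectra)."""
    if not spectra:
        raise ValueError("no spectra to write")
    grid = spectra[0].grid
    for s in spectra[1:]:
        if s.grid != grid:
            raise ValueError("all spectra must share one grid")
    data = {"wavelength": grid.wavelengths}
    for i, s in enumerate(spectra):
        data[s.name or f"spectrum_{i}"] = s.values
    pd.DataFrame(data).to_csv(path, index=False)


def resample(s: Spectrum, target: WavelengthGrid) -> Spectrum:
    """Linearly interpolate a spectrum onto ``target``.

    Refuses to extrapolate: the target range must lie within the source range.
    """
    if not s.grid.contains(target):
        raise ValueError(
            f"target range {target.lambda_min}-{target.lambda_max} nm extends beyond "
            f"source range {s.grid.lambda_min}-{s.grid.lambda_max} nm; "
            "extrapolation is refused"
        )
    vals = np.interp(target.wavelengths, s.wavelengths, s.values)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SpectrumWarning)
        return Spectrum(target, vals, s.kind, s.name)


def radiance(r: Spectrum, d: Spectrum) -> Spectrum:
    """Pointwise product ``L = R * D`` of a reflectance and an illuminant.

    Both spectra must already be on identical grids (use :func:`resample`).
    """
    if r.kind != "reflectance":
        raise ValueError(f"first argument must be a reflectance spectrum, got {r.kind}")
    if d.kind != "illuminant":
        raise ValueError(f"second argument must be an illuminant spectrum, got {d.kind}")
    if r.grid != d.grid:
        raise ValueError(
            f"mismatched grids: reflectance on {r.grid}, illuminant on {d.grid}"
        )
    return Spectrum(r.grid, r.values * d.values, "radiance", name=r.name)
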