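"""Built-in spectra shipped as plain-text package data.

Illuminants
-----------
``d65``
    The CIE standard daylight illuminant.  The table is stored in energy
    units (relative spectral power, 100 at 560 nm, 1 nm spacing, 300-780 nm).
    By default it is converted to photon units — multiplied by wavelength and
    renormalized to a maximum of 1 — because segment brightness is defined as
    a photon flux.  Pass ``units="energy"`` for the raw table.
``d65-pavo24``
    The photon-unit, peak-normalized D65 table distributed with the pavo R
    package up to version 2.4.0 (1 nm, 300-700 nm).  Kept for reproducing
    published brightness sums computed with that table.
``flat``
    Equal-energy illuminant (all ones) on the requested grid.

Reference reflectance
---------------------
:func:`green_leaf` returns the average green-foliage background reflectance
distributed with pavo 2.4.0, in percent (values 0-100) as originally shipped.
"""

from __future__ import annotations

import warnings
from importlib import resources

import numpy as np
import pandas as pd

from .spectral_core import Spectrum, SpectrumWarning, WavelengthGrid, resample

__all__ = ["builtin_illuminant", "green_leaf", "BUILTIN_ILLUMINANTS"]

BUILTIN_ILLUMINANTS = ("d65", "d65-pavo24", "flat")


def _load_table(filename: str) -> pd.DataFrame:
    ref = resources.files("nsc.data").joinpath(filename)
    with ref.open("r") as fh:
        return pd.read_csv(fh)


def _table_spectrum(filename: str, kind: str) -> Spectrum:
    df = _load_table(filename)
    wl = df.iloc[:, 0].to_numpy(dtype=float)
    grid = WavelengthGrid(float(wl[0]), float(wl[-1]), float(wl[1] - wl[0]))
    return Spectrum(grid, df.iloc[:, 1].to_numpy(dtype=float), kind, name=df.columns[1])


def builtin_illuminant(
    name: str = "d65",
    grid: WavelengthGrid | None = None,
    units: str = "photon",
) -> Spectrum:
    """Return a built-in illuminant, optionally resampled onto ``grid``.

    Parameters
    ----------
    name : {"d65", "d65-pavo24", "flat"}
    grid : WavelengthGrid, optional
        Target grid; required for ``flat``, otherwise the native table grid
        is kept when omitted.
    units : {"photon", "energy"}
        Photon units multiply the energy table by wavelength and renormalize
        to a maximum of 1.  Ignored for tables already in photon units
        (``d65-pavo24``) and for ``flat``.
    """
    if units not in ("photon", "energy"):
        raise ValueError(f"units must be 'photon' or 'energy', got {units!r}")
    key = name.lower()
    if key == "flat":
        if grid is None:
            raise ValueError("a grid is required for the flat illuminant")
        return Spectrum(grid, np.ones(grid.n_samples), "illuminant", name="flat")
    if key == "d65":
        s = _table_spectrum("d65_energy_1nm.csv", "illuminant")
        if units == "photon":
            vals = s.values * s.wavelengths
            s = Spectrum(s.grid, vals / vals.max(), "illuminant", name="d65")
    elif key in ("d65-pavo24", "d65_pavo24"):
        s = _table_spectrum("d65_photon_pavo24_1nm.csv", "illuminant")
    else:
        raise ValueError(
            f"unknown builtin illuminant {name!r}; choose from {BUILTIN_ILLUMINANTS}"
        )
    if grid is not None:
        s = resample(s, grid)
    return s


def green_leaf(grid: WavelengthGrid | None = None, percent: bool = True) -> Spectrum:
    """Average green-foliage reflectance (pavo 2.4.0 background table).

    ``percent=True`` (default) returns the table as shipped, in percent;
    ``percent=False`` rescales to proportions in [0, 1].
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SpectrumWarning)
        s = _table_spectrum("green_leaf_percent_1nm.csv", "reflectance")
        if not percent:
            s = Spectrum(s.grid, s.values / 100.0, "reflectance", name=s.name)
        if grid is not None:
            s = resample(s, grid)
    return s
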