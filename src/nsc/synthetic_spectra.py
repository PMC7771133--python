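"""Synthetic reflectance generator for tests and demos.

Generates the qualitative shape classes that natural reflectance spectra
fall into: sigmoids (UV-absorbing white, yellow, red — differing mainly in
the inflection wavelength), Gaussian bells (greens), flats (gray series)
and hard steps.  Deterministic for a fixed seed; noise-free recipes are
bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .spectral_core import DEFAULT_GRID, Spectrum, WavelengthGrid

__all__ = ["SpectrumRecipe", "generate", "fixture_suite"]

Shape = Literal["sigmoid", "bell", "flat", "step"]


@dataclass(frozen=True)
class SpectrumRecipe:
    """Parametric reflectance shape.

    ``center`` is the sigmoid inflection / bell center / step position in
    nm (ignored for ``flat``); ``width`` is the logistic scale or Gaussian
    standard deviation in nm.  Reflectance rises from ``floor`` to
    ``ceiling``.  ``noise_sd > 0`` adds seeded Gaussian noise, clipped at 0.
    """

    shape: Shape
    center: float = 500.0
    width: float = 20.0
    floor: float = 0.0
    ceiling: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.floor <= self.ceiling:
            raise ValueError("need 0 <= floor <= ceiling")
        if self.shape in ("sigmoid", "bell") and self.width <= 0:
            raise ValueError("width must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def generate(recipe: SpectrumRecipe, grid: WavelengthGrid = DEFAULT_GRID) -> Spectrum:
    """Render a recipe onto a grid as a reflectance spectrum."""
    wl = grid.wavelengths
    if recipe.shape != "flat" and not (
        grid.lambda_min <= recipe.center <= grid.lambda_max
    ):
        raise ValueError(
            f"center {recipe.center} nm outside grid range "
            f"[{grid.lambda_min}, {grid.lambda_max}]"
        )
    lo, hi = recipe.floor, recipe.ceiling
    if recipe.shape == "sigmoid":
        vals = lo + (hi - lo) / (1.0 + np.exp(-(wl - recipe.center) / recipe.width))
    elif recipe.shape == "bell":
        vals = lo + (hi - lo) * np.exp(-((wl - recipe.center) ** 2) / (2 * recipe.width**2))
    elif recipe.shape == "flat":
        vals = np.full(wl.shape, hi, dtype=float)
    elif recipe.shape == "step":
        vals = np.where(wl < recipe.center, lo, hi).astype(float)
    else:  # pragma: no cover - guarded by dataclass Literal
        raise ValueError(f"unknown shape {recipe.shape!r}")
    if recipe.noise_sd > 0:
        rng = np.random.default_rng(recipe.seed)
        vals = np.clip(vals + rng.normal(0.0, recipe.noise_sd, size=vals.shape), 0.0, None)
    name = f"{recipe.shape}@{recipe.center:g}" if recipe.shape != "flat" else f"flat@{hi:g}"
    return Spectrum(grid, vals, "reflectance", name=name)


def fixture_suite(grid: WavelengthGrid = DEFAULT_GRID) -> dict[str, Spectrum]:
    """Named reference set covering the shape taxonomy.

    Includes a UV-absorbing white, yellow and red sigmoid, a green bell, a
    gray series from 0.05 to 0.95, black, and the perfect white standard.
    """
    recipes = {
        "uv_white": SpectrumRecipe("sigmoid", center=380.0, width=12.0),
        "yellow": SpectrumRecipe("sigmoid", center=500.0, width=15.0),
        "red": SpectrumRecipe("sigmoid", center=600.0, width=15.0),
        "green": SpectrumRecipe("bell", center=550.0, width=40.0, ceiling=0.6),
    }
    suite = {name: generate(r, grid) for name, r in recipes.items()}
    for level in (0.05, 0.25, 0.50, 0.75, 0.95):
        suite[f"gray_{int(level * 100):02d}"] = generate(
            SpectrumRecipe("flat", ceiling=level), grid
        )
    suite["black"] = Spectrum(grid, np.zeros(grid.n_samples), "reflectance", name="black")
    suite["white_standard"] = generate(SpectrumRecipe("flat", ceiling=1.0), grid)
    return suite
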