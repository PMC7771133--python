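import numpy as np
import pytest

from nsc import (
    DEFAULT_GRID,
    SegmentPartition,
    Spectrum,
    SpectrumRecipe,
    WavelengthGrid,
    builtin_illuminant,
    generate,
)


@pytest.fixture
def grid():
    return DEFAULT_GRID


@pytest.fixture
def grid5():
    return WavelengthGrid(300.0, 700.0, 5.0)


@pytest.fixture
def partition():
    return SegmentPartition(300.0, 700.0, 3)


@pytest.fixture
def flat_illuminant(grid):
    return builtin_illuminant("flat", grid=grid)


@pytest.fixture
def d65(grid):
    return builtin_illuminant("d65", grid=grid)


def random_reflectance(rng: np.random.Generator, grid: WavelengthGrid = DEFAULT_GRID) -> Spectrum:
    """Random smooth reflectance: sigmoid, bell or flat with random parameters."""
    shape = rng.choice(["sigmoid", "bell", "flat"])
    lo = float(rng.uniform(0.0, 0.3))
    hi = float(rng.uniform(lo + 0.05, 1.0))
    recipe = SpectrumRecipe(
        shape,
        center=float(rng.uniform(grid.lambda_min + 10, grid.lambda_max - 10)),
        width=float(rng.uniform(5.0, 80.0)),
        floor=lo,
        ceiling=hi,
    )
    return generate(recipe, grid)


def tally_segment_brightness(l: Spectrum, p: SegmentPartition) -> np.ndarray:
    """Independent per-sample tally oracle for relative segment brightness.

    Loops over every grid sample, assigns it to its half-open segment
    [bound_{i-1}, bound_i) (final segment closed), and accumulates.
    """
    bounds = p.boundaries
    members: list[list[float]] = [[] for _ in range(p.n_segments)]
    for wl, v in zip(l.wavelengths, l.values):
        if wl < p.lambda1 - 1e-9 or wl > p.lambda2 + 1e-9:
            continue
        for i in range(p.n_segments):
            left, right = bounds[i], bounds[i + 1]
            last = i == p.n_segments - 1
            if (wl >= left - 1e-9) and (wl <= right + 1e-9 if last else wl < right - 1e-9):
                members[i].append(v)
                break
    # the loop above owns the assignment logic; the reduction uses the same
    # summation operator as the implementation so bitwise comparison is fair
    sums = np.array([np.sum(np.array(m)) for m in members])
    total = sums.sum()
    if total <= 0:
        raise ValueError("zero total brightness")
    return sums / total
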