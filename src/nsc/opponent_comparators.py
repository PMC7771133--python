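"""Comparator color-discrimination models operating on receptor excitations.

All three comparators — color-opponent coding (COC), the color hexagon, and
the receptor-noise-limited (RN) loci — map a photoreceptor excitation
triplet (E_S, E_M, E_L) to a planar locus through color-opponent
mechanisms: linear combinations of excitations whose coefficients sum to
zero, so equal excitations always land at the origin.

Excitations are supplied by the caller (from published quantum-catch
calculations) or approximated from segment brightnesses by
:func:`rect_excitations`, which assumes rectangular receptor sensitivities
evenly tiling the spectrum: E_S = B+G, E_M = G+Y, E_L = Y+R.  Under that
approximation E_L - E_M = R - G and E_M - E_S = Y - B exactly, i.e. the
first two NSC chromatic coordinates.  (The COC opponent values are then
loosely A ~ Z2 and B ~ -Z1 — a qualitative observation only, since the
small cross-coefficients do not vanish.)

Metrics follow each model's definition: city-block for COC, Euclidean for
the hexagon and RN loci.  RN parameters (A, B, a, b) are species-dependent
and have no defaults; for the logarithmic RN variant apply ``np.log`` to
the excitations before building :class:`Excitations`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .segment_models import SegmentBrightness

__all__ = [
    "Excitations",
    "OpponentMechanism",
    "CocLocus",
    "HexagonLocus",
    "RnParams",
    "RnLocus",
    "rect_excitations",
    "make_opponent",
    "coc_locus",
    "coc_distance",
    "hexagon_locus",
    "hexagon_distance",
    "rn_locus",
    "rn_distance",
    "COC_A_COEFFS",
    "COC_B_COEFFS",
]

#: empirical honeybee opponent coefficients of the COC model
COC_A_COEFFS = (-9.86, 7.70, 2.16)
COC_B_COEFFS = (-5.17, 20.25, -15.08)


@dataclass(frozen=True)
class Excitations:
    """Photoreceptor excitation vector (E_S, E_M, E_L for a trichromat)."""

    E: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.E, dtype=float)
        object.__setattr__(self, "E", e)
        if e.ndim != 1:
            raise ValueError("excitations must be a 1-D vector")
        if np.any(e < 0):
            raise ValueError("excitations must be >= 0")

    def __len__(self) -> int:
        return len(self.E)


@dataclass(frozen=True)
class OpponentMechanism:
    """Linear combination of excitations with zero-sum coefficients."""

    c: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.c, dtype=float)
        object.__setattr__(self, "c", c)
        if abs(c.sum()) > 1e-12:
            raise ValueError(
                f"not color-opponent: coefficients sum to {c.sum():.3g}, not 0"
            )

    def __call__(self, e: Excitations) -> float:
        if len(e) != len(self.c):
            raise ValueError(
                f"mechanism has {len(self.c)} coefficients but got {len(e)} excitations"
            )
        return float(self.c @ e.E)


def make_opponent(c: Sequence[float]) -> OpponentMechanism:
    """Build a color-opponent mechanism, rejecting non-zero-sum coefficients."""
    return OpponentMechanism(np.asarray(c, dtype=float))


@dataclass(frozen=True)
class CocLocus:
    A: float
    B: float


@dataclass(frozen=True)
class HexagonLocus:
    X: float
    Y: float


@dataclass(frozen=True)
class RnParams:
    """Species-dependent receptor-noise locus parameters (no defaults)."""

    A: float
    B: float
    a: float
    b: float

    def __post_init__(self) -> None:
        for name in ("A", "B", "a", "b"):
            if getattr(self, name) <= 0:
                raise ValueError(f"RN parameter {name} must be positive")


@dataclass(frozen=True)
class RnLocus:
    X: float
    Y: float


def rect_excitations(sb: SegmentBrightness) -> Excitations:
    """Excitations under the rectangular-sensitivity approximation.

    Requires the trichromatic four-segment brightness vector (B, G, Y, R).
    """
    if len(sb.S) != 4:
        raise ValueError(
            f"rectangular excitations need 4 segment brightnesses, got {len(sb.S)}"
        )
    B, G, Y, R = sb.S
    return Excitations(np.array([B + G, G + Y, Y + R]))


def _require_tri(e: Excitations) -> None:
    if len(e) != 3:
        raise ValueError(f"expected 3 excitations (S, M, L), got {len(e)}")


_COC_A = make_opponent(COC_A_COEFFS)
_COC_B = make_opponent(COC_B_COEFFS)


def coc_locus(e: Excitations) -> CocLocus:
    """Color-opponent-coding locus (A, B) from honeybee opponent weights."""
    _require_tri(e)
    return CocLocus(A=_COC_A(e), B=_COC_B(e))


def coc_distance(a: CocLocus, b: CocLocus) -> float:
    """City-block distance |dA| + |dB|."""
    return abs(a.A - b.A) + abs(a.B - b.B)


def hexagon_locus(e: Excitations) -> HexagonLocus:
    """Color-hexagon locus: X = sqrt(3)*(E_L - E_S)/2, Y = E_M - (E_S + E_L)/2."""
    _require_tri(e)
    es, em, el = e.E
    return HexagonLocus(X=math.sqrt(3.0) * (el - es) / 2.0, Y=em - 0.5 * (es + el))


def hexagon_distance(a: HexagonLocus, b: HexagonLocus) -> float:
    return math.hypot(a.X - b.X, a.Y - b.Y)


def rn_locus(e: "Excitations | np.ndarray", p: RnParams) -> RnLocus:
    """Receptor-noise-limited locus X = A*(E_L - E_M), Y = B*(E_S - (a*E_L + b*E_M)).

    For the logarithmic model variant, pass the log-transformed excitation
    values as a plain array (log excitations may be negative, so the
    :class:`Excitations` non-negativity check does not apply).
    """
    vec = e.E if isinstance(e, Excitations) else np.asarray(e, dtype=float)
    if vec.shape != (3,):
        raise ValueError(f"expected 3 excitations (S, M, L), got {vec.shape}")
    es, em, el = vec
    return RnLocus(X=p.A * (el - em), Y=p.B * (es - (p.a * el + p.b * em)))


def rn_distance(a: RnLocus, b: RnLocus) -> float:
    return math.hypot(a.X - b.X, a.Y - b.Y)
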