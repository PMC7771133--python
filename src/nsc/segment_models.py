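"""Segment partition, brightness, and segment-classification color coordinates.

The visible range ``(lambda1, lambda2)`` is divided into ``n + 1`` equal
segments for a viewer with ``n`` photoreceptor types.  Brightness over an
interval is the *unweighted sum* of radiance values at the grid sample
points — deliberately bin-width dependent (halving the step roughly doubles
total brightness).  The relative segment brightnesses S_i sum to 1 and feed
two coordinate systems:

* Endler's segment classification: polar chromatic coordinates (X1 chroma,
  X2 hue angle) plus raw brightness X3.  X3 scales with the number of grid
  samples; only the normalized achromatic coordinate below is bin-width
  robust.
* Normalized segment classification (NSC): Cartesian chromatic coordinates
  comparing segments two apart, ordered long-wavelength-first — for a
  trichromat Z_1 = R - G and Z_2 = Y - B — plus an achromatic coordinate
  Z_n = beta / beta_m in [0, 1], where beta_m is the brightness of a perfect
  white standard under the same illuminant.  A ``chromatic-normalized``
  variant rescales each chromatic coordinate by the summed brightness of the
  two segments involved; this can magnify irrelevant differences when those
  segments are dim, so small denominators raise an error.

Distances: NSC uses the Euclidean metric with the achromatic term weighted
by a free parameter alpha (alpha=1 is the proposed model; alpha=0 recovers
the chromatic-only segment scheme).  Endler's chromatic distance is computed
from the polar coordinates by the law of cosines and equals the alpha=0 NSC
distance; his achromatic distance is |X3_a - X3_b| and is reported
separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .spectral_core import Spectrum, WavelengthGrid, _WL_TOL

__all__ = [
    "SegmentPartition",
    "SegmentBrightness",
    "EndlerLocus",
    "NscLocus",
    "DistanceSpec",
    "brightness",
    "white_standard_brightness",
    "segment_relative_brightness",
    "endler_locus",
    "endler_chromatic_distance",
    "endler_achromatic_distance",
    "nsc_locus",
    "nsc_locus_from_brightness",
    "nsc_distance",
]

NscVariant = Literal["standard", "chromatic-normalized"]

#: guard for the chromatic-normalized denominator S_{i+2} + S_i
_NORM_DENOM_EPS = 1e-9


@dataclass(frozen=True)
class SegmentPartition:
    """``n_receptors + 1`` equal wavelength segments spanning (lambda1, lambda2)."""

    lambda1: float
    lambda2: float
    n_receptors: int = 3

    def __post_init__(self) -> None:
        object.__setattr__(self, "lambda1", float(self.lambda1))
        object.__setattr__(self, "lambda2", float(self.lambda2))
        object.__setattr__(self, "n_receptors", int(self.n_receptors))
        if not self.lambda1 < self.lambda2:
            raise ValueError("lambda1 must be < lambda2")
        if self.n_receptors < 2:
            raise ValueError("need at least 2 receptor types")

    @property
    def n_segments(self) -> int:
        return self.n_receptors + 1

    @property
    def boundaries(self) -> np.ndarray:
        """Segment boundaries lambda_0 .. lambda_{n+1} (inclusive endpoints)."""
        i = np.arange(self.n_segments + 1)
        return self.lambda1 + i * (self.lambda2 - self.lambda1) / self.n_segments


@dataclass(frozen=True)
class SegmentBrightness:
    """Relative segment brightnesses with total and white-standard brightness.

    ``beta_m`` is ``None`` when no illuminant was supplied (then only the
    chromatic coordinates are defined).
    """

    S: np.ndarray
    beta: float
    beta_m: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "S", np.asarray(self.S, dtype=float))


@dataclass(frozen=True)
class EndlerLocus:
    """Polar chromatic coordinates plus raw brightness.

    ``X2`` is conventionally 0 (with ``hue_defined=False``) at the
    achromatic point X1 = 0, where the hue angle is undefined.
    """

    X1: float
    X2: float
    X3: float
    hue_defined: bool = field(default=True, compare=False)


@dataclass(frozen=True)
class NscLocus:
    """NSC coordinate vector: Z[0..n-2] chromatic, Z[n-1] achromatic."""

    Z: np.ndarray
    variant: NscVariant
    partition: SegmentPartition

    def __post_init__(self) -> None:
        object.__setattr__(self, "Z", np.asarray(self.Z, dtype=float))
        if len(self.Z) != self.partition.n_receptors:
            raise ValueError(
                f"locus needs {self.partition.n_receptors} coordinates, got {len(self.Z)}"
            )

    @property
    def chromatic(self) -> np.ndarray:
        return self.Z[:-1]

    @property
    def achromatic(self) -> float:
        return float(self.Z[-1])


@dataclass(frozen=True)
class DistanceSpec:
    """Achromatic weight for the NSC distance (Euclidean metric is fixed).

    ``alpha=0`` reproduces the chromatic-only segment scheme; ``alpha=1``
    (default) is the proposed NSC distance.
    """

    alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")


def brightness(
    l: Spectrum, a: float, b: float, *, closed_right: bool = False
) -> float:
    """Unweighted sum of spectral values at grid samples in [a, b) or [a, b].

    No bin-width weighting is applied: the result scales with the number of
    samples in the interval.  ``closed_right=True`` includes the right
    endpoint (used for the final segment and for full-range totals).
    """
    if not a < b:
        raise ValueError("need a < b")
    g = l.grid
    if a < g.lambda_min - _WL_TOL or b > g.lambda_max + _WL_TOL:
        raise ValueError(
            f"interval [{a}, {b}] outside spectrum range "
            f"[{g.lambda_min}, {g.lambda_max}]"
        )
    wl = l.wavelengths
    mask = wl >= a - _WL_TOL
    mask &= (wl <= b + _WL_TOL) if closed_right else (wl < b - _WL_TOL)
    if not mask.any():
        raise ValueError(f"empty segment: no grid samples in [{a}, {b})")
    return float(l.values[mask].sum())


def white_standard_brightness(d: Spectrum, p: SegmentPartition) -> float:
    """Brightness of a perfect reflector (L = D) over the partition range."""
    if d.kind not in ("illuminant", "radiance"):
        raise ValueError(f"expected an illuminant spectrum, got kind {d.kind!r}")
    return brightness(d, p.lambda1, p.lambda2, closed_right=True)


def segment_relative_brightness(
    l: Spectrum, p: SegmentPartition, d: Spectrum | None = None
) -> SegmentBrightness:
    """Per-segment relative brightnesses S_i = beta_i / beta_total.

    Segments are half-open ``[lambda_{i-1}, lambda_i)`` with the final
    segment closed at ``lambda2`` so every sample is counted exactly once.
    If an illuminant ``d`` is given, the white-standard brightness beta_m is
    computed from it as well.
    """
    if l.kind != "radiance":
        raise ValueError(f"expected a radiance spectrum, got kind {l.kind!r}")
    bounds = p.boundaries
    betas = np.array(
        [
            brightness(l, bounds[i], bounds[i + 1], closed_right=(i == p.n_segments - 1))
            for i in range(p.n_segments)
        ]
    )
    beta = float(betas.sum())
    if beta <= 0:
        raise ValueError(
            "zero total brightness: undefined chromatic coordinates for an "
            "all-black spectrum"
        )
    beta_m = white_standard_brightness(d, p) if d is not None else None
    return SegmentBrightness(S=betas / beta, beta=beta, beta_m=beta_m)


def endler_locus(sb: SegmentBrightness, p: SegmentPartition) -> EndlerLocus:
    """Chroma X1, hue angle X2 (three-branch arcsine) and brightness X3.

    Only defined for the trichromatic, four-segment case.  With
    B, G, Y, R = S_1..S_4 the chromatic vector is (R-G, Y-B); X1 is its
    length and X2 its angle, mapped to [0, 2*pi) by branching on the signs
    of R-G and Y-B.
    """
    if p.n_receptors != 3:
        raise ValueError("segment classification defined for trichromatic case (n=3)")
    B, G, Y, R = sb.S
    rg, yb = R - G, Y - B
    x1 = math.hypot(rg, yb)
    if x1 == 0.0:
        return EndlerLocus(X1=0.0, X2=0.0, X3=sb.beta, hue_defined=False)
    if rg >= 0 and yb >= 0:
        x2 = math.asin(yb / x1)
    elif rg >= 0:  # yb < 0
        x2 = math.asin(yb / x1) + 2 * math.pi
    else:
        x2 = math.pi - math.asin(yb / x1)
    return EndlerLocus(X1=x1, X2=x2, X3=sb.beta)


def endler_chromatic_distance(a: EndlerLocus, b: EndlerLocus) -> float:
    """Euclidean distance between polar chromatic points (law of cosines)."""
    d2 = a.X1**2 + b.X1**2 - 2 * a.X1 * b.X1 * math.cos(a.X2 - b.X2)
    return math.sqrt(max(d2, 0.0))


def endler_achromatic_distance(a: EndlerLocus, b: EndlerLocus) -> float:
    """Brightness difference |X3_a - X3_b| (reported separately from chroma)."""
    return abs(a.X3 - b.X3)


def nsc_locus_from_brightness(
    sb: SegmentBrightness, p: SegmentPartition, variant: NscVariant = "standard"
) -> NscLocus:
    """NSC coordinates from precomputed segment brightnesses.

    Requires ``sb.beta_m`` (white-standard brightness) for the achromatic
    coordinate.
    """
    if sb.beta_m is None:
        raise ValueError("white-standard brightness beta_m is required for an NSC locus")
    S = sb.S
    n = p.n_receptors
    if len(S) != n + 1:
        raise ValueError(f"expected {n + 1} segments, got {len(S)}")
    # opponent pairs (S_j, S_{j+2}) ordered long-wavelength-first so that the
    # trichromatic coordinates come out as (R-G, Y-B): Z_i = S_{n+2-i} - S_{n-i}
    diffs = (S[2:] - S[: n - 1])[::-1]
    if variant == "standard":
        chromatic = diffs
    elif variant == "chromatic-normalized":
        denom = (S[2:] + S[: n - 1])[::-1]
        bad = np.nonzero(denom < _NORM_DENOM_EPS)[0]
        if bad.size:
            i = int(bad[0]) + 1
            j = n - i
            raise ValueError(
                f"chromatic-normalized coordinate Z{i} undefined: "
                f"S{j + 2} + S{j} = {denom[bad[0]]:.3g} is below {_NORM_DENOM_EPS}"
            )
        chromatic = 2.0 * diffs / denom
    else:
        raise ValueError(f"unknown NSC variant {variant!r}")
    z = np.concatenate([chromatic, [sb.beta / sb.beta_m]])
    return NscLocus(Z=z, variant=variant, partition=p)


def nsc_locus(
    l: Spectrum,
    d: Spectrum,
    p: SegmentPartition,
    variant: NscVariant = "standard",
) -> NscLocus:
    """NSC locus of a radiance spectrum under illuminant ``d``."""
    sb = segment_relative_brightness(l, p, d=d)
    return nsc_locus_from_brightness(sb, p, variant=variant)


def nsc_distance(a: NscLocus, b: NscLocus, spec: DistanceSpec = DistanceSpec()) -> float:
    """Alpha-weighted Euclidean distance between two NSC loci."""
    if a.variant != b.variant:
        raise ValueError(f"mismatched variants: {a.variant!r} vs {b.variant!r}")
    if a.partition != b.partition:
        raise ValueError("mismatched partitions")
    dz = a.Z - b.Z
    return float(np.sqrt(np.sum(dz[:-1] ** 2) + spec.alpha * dz[-1] ** 2))
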