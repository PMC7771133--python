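"""Convenience layer tying spectra to model distances.

Turns a set of named reflectance spectra plus an illuminant into per-model
distance providers keyed by stimulus name, as consumed by
:func:`nsc.evaluation.compare_models` and the CLI.

Model keys:

========  ====================================================
``nsc``     standard NSC distance, alpha = 1
``nsc0``    chromatic-only segment scheme (NSC with alpha = 0)
``nscnorm`` chromatically normalized NSC variant, alpha = 1
``coc``     color-opponent coding (city-block), rectangular excitations
``hexagon`` color hexagon (Euclidean), rectangular excitations
``rn``      receptor-noise loci (requires :class:`RnParams`)
``rnlog``   same, on log-transformed excitations
========  ====================================================
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .datasets import builtin_illuminant
from .evaluation import DistanceProvider
from .opponent_comparators import (
    RnParams,
    coc_distance,
    coc_locus,
    hexagon_distance,
    hexagon_locus,
    rect_excitations,
    rn_distance,
    rn_locus,
)
from .segment_models import (
    DistanceSpec,
    SegmentPartition,
    endler_locus,
    nsc_distance,
    nsc_locus_from_brightness,
    segment_relative_brightness,
)
from .spectral_core import Spectrum, radiance, resample

__all__ = ["resolve_illuminant", "loci_table", "model_distance_providers", "MODEL_KEYS"]

MODEL_KEYS = ("nsc", "nsc0", "nscnorm", "coc", "hexagon", "rn", "rnlog")


def resolve_illuminant(spec: str | Spectrum, grid) -> Spectrum:
    """Accept a builtin illuminant name, a CSV path, or a Spectrum."""
    if isinstance(spec, Spectrum):
        return resample(spec, grid) if spec.grid != grid else spec
    from .datasets import BUILTIN_ILLUMINANTS
    from .spectral_core import read_spectra

    if spec.lower() in BUILTIN_ILLUMINANTS:
        return builtin_illuminant(spec, grid=grid)
    candidates = read_spectra(spec, "illuminant")
    if len(candidates) != 1:
        raise ValueError(f"illuminant file {spec} must contain exactly one spectrum")
    return resample(candidates[0], grid)


def _brightnesses(
    spectra: Mapping[str, Spectrum], d: Spectrum, p: SegmentPartition
) -> dict:
    out = {}
    for name, r in spectra.items():
        r = resample(r, d.grid) if r.grid != d.grid else r
        out[name] = segment_relative_brightness(radiance(r, d), p, d=d)
    return out


def loci_table(
    spectra: Mapping[str, Spectrum],
    illuminant: Spectrum,
    partition: SegmentPartition,
    variant: str = "standard",
) -> pd.DataFrame:
    """Per-spectrum NSC coordinates plus (for n=3) the Endler polar locus."""
    sbs = _brightnesses(spectra, illuminant, partition)
    rows = []
    for name, sb in sbs.items():
        locus = nsc_locus_from_brightness(sb, partition, variant=variant)
        row = {"name": name}
        for i, z in enumerate(locus.Z, start=1):
            row[f"Z{i}"] = z
        if partition.n_receptors == 3:
            el = endler_locus(sb, partition)
            row.update(X1=el.X1, X2=el.X2, X3=el.X3)
        rows.append(row)
    return pd.DataFrame(rows)


def model_distance_providers(
    spectra: Mapping[str, Spectrum],
    illuminant: Spectrum,
    partition: SegmentPartition,
    models: tuple[str, ...] = ("nsc", "nsc0", "nscnorm", "coc", "hexagon"),
    rn_params: RnParams | None = None,
) -> dict[str, DistanceProvider]:
    """Build name-keyed distance providers for the requested model set."""
    unknown = set(models) - set(MODEL_KEYS)
    if unknown:
        raise ValueError(f"unknown models: {sorted(unknown)}; choose from {MODEL_KEYS}")
    if ("rn" in models or "rnlog" in models) and rn_params is None:
        raise ValueError("rn/rnlog models require RnParams")
    sbs = _brightnesses(spectra, illuminant, partition)

    providers: dict[str, DistanceProvider] = {}

    def lookup(table, dist):
        def provider(a: str, b: str) -> float:
            if a not in table:
                raise KeyError(a)
            if b not in table:
                raise KeyError(b)
            return dist(table[a], table[b])

        return provider

    if {"nsc", "nsc0"} & set(models):
        std = {
            k: nsc_locus_from_brightness(sb, partition, "standard")
            for k, sb in sbs.items()
        }
        if "nsc" in models:
            providers["nsc"] = lookup(std, lambda a, b: nsc_distance(a, b, DistanceSpec(1.0)))
        if "nsc0" in models:
            providers["nsc0"] = lookup(std, lambda a, b: nsc_distance(a, b, DistanceSpec(0.0)))
    if "nscnorm" in models:
        norm = {
            k: nsc_locus_from_brightness(sb, partition, "chromatic-normalized")
            for k, sb in sbs.items()
        }
        providers["nscnorm"] = lookup(norm, lambda a, b: nsc_distance(a, b, DistanceSpec(1.0)))
    needs_exc = {"coc", "hexagon", "rn", "rnlog"} & set(models)
    if needs_exc:
        if partition.n_receptors != 3:
            raise ValueError("comparator models require the trichromatic partition")
        exc = {k: rect_excitations(sb) for k, sb in sbs.items()}
        if "coc" in models:
            locs = {k: coc_locus(e) for k, e in exc.items()}
            providers["coc"] = lookup(locs, coc_distance)
        if "hexagon" in models:
            locs = {k: hexagon_locus(e) for k, e in exc.items()}
            providers["hexagon"] = lookup(locs, hexagon_distance)
        if "rn" in models:
            locs = {k: rn_locus(e, rn_params) for k, e in exc.items()}
            providers["rn"] = lookup(locs, rn_distance)
        if "rnlog" in models:
            locs = {
                k: rn_locus(np.log(np.maximum(e.E, 1e-12)), rn_params)
                for k, e in exc.items()
            }
            providers["rnlog"] = lookup(locs, rn_distance)
    return providers
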