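"""Rank-correlation harness: model distances vs behavioral performance.

A behavioral dataset is a table of stimulus pairs with the proportion of
correct choices animals achieved when discriminating (or detecting) each
pair.  Each candidate model supplies one distance per pair — either
computed from spectra or read from a precomputed ``dist_<model>`` column —
and models are ranked by Spearman's rank correlation between their
distances and performance.

Reciprocal records (the same two stimuli with target/background roles
swapped) can be averaged per unordered pair before correlating.

No p-values are attached to the correlations: behavioral datasets of this
kind typically contain 4-5 pairs, where rank tests are degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BehavioralDataset",
    "ModelComparison",
    "spearman",
    "compare_models",
]

#: a distance provider maps (stimulus_a_id, stimulus_b_id) -> distance
DistanceProvider = Callable[[str, str], float]


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman's rho with average-rank tie handling.

    Raises on length mismatch, fewer than 3 points, or a constant vector
    (where rank correlation is undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rho undefined for a constant vector")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


@dataclass(frozen=True)
class BehavioralDataset:
    """Stimulus-pair discrimination records.

    ``table`` columns: ``pair`` (unique id), ``stimA``, ``stimB``,
    ``prop_correct`` in [0, 1], plus optional precomputed ``dist_<model>``
    columns.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = {"pair", "stimA", "stimB", "prop_correct"} - set(t.columns)
        if missing:
            raise ValueError(f"behavioral table missing columns: {sorted(missing)}")
        if t["pair"].duplicated().any():
            raise ValueError("pair ids must be unique")
        p = t["prop_correct"].to_numpy(dtype=float)
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("prop_correct must lie in [0, 1]")

    @classmethod
    def from_csv(cls, path: str | Path) -> "BehavioralDataset":
        return cls(pd.read_csv(path))

    @property
    def precomputed_models(self) -> list[str]:
        return [c[5:] for c in self.table.columns if c.startswith("dist_")]

    def average_reciprocal(self) -> "BehavioralDataset":
        """Average records sharing the same unordered stimulus pair."""
        t = self.table.copy()
        key = t.apply(lambda r: tuple(sorted((str(r.stimA), str(r.stimB)))), axis=1)
        t["_key"] = key
        num_cols = ["prop_correct"] + [c for c in t.columns if c.startswith("dist_")]
        agg = {c: "mean" for c in num_cols}
        agg.update({"pair": "first", "stimA": "first", "stimB": "first"})
        out = t.groupby("_key", as_index=False, sort=False).agg(agg)
        out = out.drop(columns="_key")
        return BehavioralDataset(out[["pair", "stimA", "stimB"] + num_cols])


@dataclass(frozen=True)
class ModelComparison:
    """Spearman's rho per model plus the resulting ranking (best first)."""

    rho: dict[str, float]
    ranking: list[str] = field(default=None)  # type: ignore[assignment]
    ties: list[set[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.ranking is None:
            ranked = sorted(self.rho, key=lambda m: -self.rho[m])
            object.__setattr__(self, "ranking", ranked)
            groups: dict[float, set[str]] = {}
            for m, r in self.rho.items():
                groups.setdefault(round(r, 12), set()).add(m)
            object.__setattr__(
                self, "ties", [g for g in groups.values() if len(g) > 1]
            )

    @property
    def best(self) -> str:
        return self.ranking[0]


def _pair_distances(
    data: BehavioralDataset, name: str, provider: DistanceProvider | None
) -> np.ndarray:
    t = data.table
    col = f"dist_{name}"
    if provider is None:
        if col not in t.columns:
            raise ValueError(
                f"model {name!r}: no distance provider and no {col!r} column"
            )
        return t[col].to_numpy(dtype=float)
    out = np.empty(len(t))
    for i, row in enumerate(t.itertuples(index=False)):
        try:
            out[i] = provider(str(row.stimA), str(row.stimB))
        except KeyError as exc:
            raise ValueError(
                f"model {name!r}: cannot resolve pair {row.pair!r} "
                f"({row.stimA!r} vs {row.stimB!r}): {exc}"
            ) from exc
    return out


def compare_models(
    data: BehavioralDataset,
    models: Mapping[str, DistanceProvider | None],
    average_reciprocal: bool = False,
) -> ModelComparison:
    """Rank models by Spearman correlation with proportion correct.

    ``models`` maps model name to a distance provider, or to ``None`` to use
    the precomputed ``dist_<name>`` column.  The result is independent of
    the ordering of ``models``.
    """
    if not models:
        raise ValueError("no models to compare")
    if average_reciprocal:
        data = data.average_reciprocal()
    perf = data.table["prop_correct"].to_numpy(dtype=float)
    rho = {
        name: spearman(_pair_distances(data, name, provider), perf)
        for name, provider in sorted(models.items())
    }
    return ModelComparison(rho=rho)
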