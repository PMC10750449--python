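"""Holdout validation and pseudo-BMA model weights.

Part of each stratum's history is withheld; each catalog model is fit on
the remainder and projected over the withheld years.  A model's projection
bias is the mean, over withheld years, of (median projected HLE at birth -
observed HLE at birth).  Weights are w_m = exp(-|bias_m|) normalized to sum
to one — an operational stand-in for the posterior model probability
PR(H_m | D): models that projected the holdout poorly get exponentially
less weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .model_catalog import ModelSpec, PosteriorDraws, StratumSeries, fit, project

__all__ = [
    "HoldoutSplit",
    "BiasRecord",
    "WeightVector",
    "holdout_split",
    "projection_bias",
    "compute_weights",
    "evaluate_stratum",
]


@dataclass(frozen=True)
class HoldoutSplit:
    """Disjoint contiguous train/test year ranges covering the panel years."""

    train_years: tuple[int, int]
    test_years: tuple[int, int]

    def __post_init__(self) -> None:
        if self.train_years[0] > self.train_years[1] or self.test_years[0] > self.test_years[1]:
            raise ValueError("year ranges must be non-empty (first <= last)")

    @property
    def n_test(self) -> int:
        return self.test_years[1] - self.test_years[0] + 1


def holdout_split(
    panel_years: Sequence[int], n_test_years: int, orientation: str = "forward"
) -> HoldoutSplit:
    """Split panel years for holdout validation.

    ``orientation="forward"`` (default) trains on the earliest years and
    withholds the latest ``n_test_years``; ``"literal"`` withholds the
    earliest years and trains on the latest, so models project backwards
    onto the withheld early block.
    """
    years = np.sort(np.asarray(panel_years, dtype=int))
    total = years.size
    if not 1 <= n_test_years < total:
        raise ValueError(
            f"n_test_years must be in [1, {total - 1}], got {n_test_years}"
        )
    if orientation == "forward":
        return HoldoutSplit(
            train_years=(int(years[0]), int(years[total - n_test_years - 1])),
            test_years=(int(years[total - n_test_years]), int(years[-1])),
        )
    if orientation == "literal":
        return HoldoutSplit(
            train_years=(int(years[n_test_years]), int(years[-1])),
            test_years=(int(years[0]), int(years[n_test_years - 1])),
        )
    raise ValueError("orientation must be 'forward' or 'literal'")


@dataclass(frozen=True)
class BiasRecord:
    """Signed projection bias of one model over the withheld years."""

    model_id: int
    bias: float
    per_year: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not math.isfinite(self.bias):
            raise ValueError(f"non-finite projection bias for model {self.model_id}")


@dataclass(frozen=True)
class WeightVector:
    """Normalized per-model ensemble weights."""

    weights: Mapping[int, float]

    def __post_init__(self) -> None:
        vals = np.array(list(self.weights.values()), dtype=float)
        if vals.size == 0:
            raise ValueError("weight vector must not be empty")
        if np.any(vals < 0) or abs(vals.sum() - 1.0) > 1e-12:
            raise ValueError("weights must be non-negative and sum to 1")

    def __getitem__(self, model_id: int) -> float:
        return self.weights[model_id]

    def items(self):
        return sorted(self.weights.items())


def projection_bias(
    draws: PosteriorDraws, withheld: StratumSeries, age: float = 0.0
) -> BiasRecord:
    """Mean over withheld years of (median projection - observation) at ``age``."""
    aidx = np.flatnonzero(np.isclose(withheld.ages, age))
    if aidx.size == 0:
        raise ValueError(f"age {age} not present in withheld series")
    missing = [int(y) for y in withheld.years if y not in draws.years]
    if missing:
        raise ValueError(f"projection draws do not cover withheld years {missing}")
    yidx = np.searchsorted(draws.years, withheld.years)
    median_proj = np.median(draws.at_age(age)[:, yidx], axis=0)
    observed = withheld.values[aidx[0], :]
    per_year = median_proj - observed
    return BiasRecord(
        model_id=draws.model_id,
        bias=float(per_year.mean()),
        per_year=tuple(float(v) for v in per_year),
    )


def compute_weights(biases: Iterable[BiasRecord]) -> WeightVector:
    """w_m = exp(-|bias_m|) / sum_j exp(-|bias_j|)."""
    records = list(biases)
    if not records:
        raise ValueError("at least one bias record is required")
    ids = [r.model_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate model ids in bias records")
    # subtracting the minimum |bias| is exact (common factor) and overflow-safe
    ab = np.array([abs(r.bias) for r in records])
    raw = np.exp(-(ab - ab.min()))
    w = raw / raw.sum()
    return WeightVector(weights={i: float(v) for i, v in zip(ids, w)})


def evaluate_stratum(
    series: StratumSeries,
    split: HoldoutSplit,
    specs: Sequence[ModelSpec],
    n_draws: int,
    seed: int,
    age: float = 0.0,
) -> tuple[list[BiasRecord], WeightVector]:
    """Holdout-validate every spec on one stratum and return bias + weights.

    Only the forward orientation admits projection onto the withheld block
    with these forward-extrapolating models; for the literal (backward)
    orientation the series is reversed in time, projected, and the
    projection re-reversed.
    """
    backward = split.test_years[0] < split.train_years[0]
    if backward:
        rev = StratumSeries(
            location=series.location, sex=series.sex, ages=series.ages,
            years=(series.years[-1] + series.years[0] - series.years)[::-1],
            values=series.values[:, ::-1], omega=series.omega,
        )
        y0, y1 = split.train_years
        t0 = series.years[-1] + series.years[0]
        train_window = (t0 - y1, t0 - y0)
        work, horizon = rev, split.test_years[1] - split.test_years[0] + 1
    else:
        work, train_window = series, split.train_years
        horizon = split.test_years[1] - split.test_years[0] + 1
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] & 0x7FFFFFFF) for s in ss.spawn(len(specs))]
    mask = (series.years >= split.test_years[0]) & (series.years <= split.test_years[1])
    withheld = StratumSeries(
        location=series.location, sex=series.sex, ages=series.ages,
        years=series.years[mask], values=series.values[:, mask], omega=series.omega,
    )
    biases = []
    for spec, s in zip(specs, child_seeds):
        fit_ = fit(spec, work, train_window=train_window)
        draws = project(fit_, horizon, n_draws, s)
        if backward:
            t0 = series.years[-1] + series.years[0]
            draws = PosteriorDraws(
                model_id=draws.model_id, ages=draws.ages,
                years=(t0 - draws.years)[::-1], draws=draws.draws[:, :, ::-1],
                seed=draws.seed,
            )
        biases.append(projection_bias(draws, withheld, age=age))
    return biases, compute_weights(biases)
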