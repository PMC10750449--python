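"""Probabilistic pooling of per-model posterior draws into the ensemble.

The pooled posterior PR(delta | D) is a mixture of the per-model posteriors
with mixing probabilities given by the model weights: for each pooled
simulation a model is sampled with probability w_m and one whole trajectory
(all ages and horizon years together, preserving cross-age and cross-year
coherence) is taken from that model's draws, without replacement within a
model where possible.  Summaries report the median and the 2.5th/97.5th
percentile credible bounds of the pooled simulations, using
linear-interpolation percentiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .model_catalog import PosteriorDraws
from .weighting import WeightVector

__all__ = ["PooledProjection", "ProjectionSummary", "pool_draws", "summarize"]

DEFAULT_N_SIMULATIONS = 1000


@dataclass
class PooledProjection:
    """Ensemble simulations of future age-specific HLE."""

    ages: np.ndarray
    years: np.ndarray
    draws: np.ndarray  # (n_simulations, n_ages, n_years)
    provenance: np.ndarray  # model id per simulation
    weights: WeightVector
    seed: int

    def at_age(self, age: float) -> np.ndarray:
        idx = int(np.flatnonzero(np.isclose(self.ages, age))[0])
        return self.draws[:, idx, :]

    def at_cell(self, age: float, year: int) -> np.ndarray:
        aidx = int(np.flatnonzero(np.isclose(self.ages, age))[0])
        yidx = int(np.flatnonzero(self.years == year)[0])
        return self.draws[:, aidx, yidx]


@dataclass
class ProjectionSummary:
    """Median and 95% credible bounds per (age, year)."""

    table: pd.DataFrame  # columns: age, year, median, cri_low, cri_high

    def cell(self, age: float, year: int) -> pd.Series:
        sub = self.table[(self.table["age"] == age) & (self.table["year"] == year)]
        if sub.empty:
            raise KeyError(f"no summary cell for age {age}, year {year}")
        return sub.iloc[0]

    def median(self, age: float, year: int) -> float:
        return float(self.cell(age, year)["median"])


def pool_draws(
    per_model_draws: Mapping[int, PosteriorDraws],
    weights: WeightVector,
    n: int = DEFAULT_N_SIMULATIONS,
    seed: int = 0,
) -> PooledProjection:
    """Mixture-sample ``n`` whole trajectories across models by weight."""
    active = [(mid, w) for mid, w in weights.items() if w > 0]
    missing = [mid for mid, _ in active if mid not in per_model_draws]
    if missing:
        raise ValueError(f"weighted models missing from draws: {missing}")
    first = per_model_draws[active[0][0]]
    ages, years = first.ages, first.years
    for mid, _ in active:
        d = per_model_draws[mid]
        if not (np.array_equal(d.ages, ages) and np.array_equal(d.years, years)):
            raise ValueError("per-model draws must share the age grid and horizon")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    probs = np.array([w for _, w in active])
    counts = rng.multinomial(n, probs / probs.sum())
    if len(active) == 1 and counts[0] > per_model_draws[active[0][0]].draws.shape[0]:
        raise ValueError(
            "requested more pooled simulations than available draws for the "
            "single weighted model"
        )
    sims = []
    prov = []
    for (mid, _), c in zip(active, counts):
        if c == 0:
            continue
        pool = per_model_draws[mid].draws
        avail = pool.shape[0]
        if c <= avail:
            idx = rng.choice(avail, size=c, replace=False)
        else:
            idx = rng.choice(avail, size=c, replace=True)
        sims.append(pool[idx])
        prov.append(np.full(c, mid, dtype=int))
    draws = np.concatenate(sims, axis=0)
    provenance = np.concatenate(prov)
    order = rng.permutation(n)
    return PooledProjection(ages=ages, years=years, draws=draws[order],
                            provenance=provenance[order], weights=weights, seed=seed)


def summarize(pooled: PooledProjection) -> ProjectionSummary:
    """Median and 2.5/97.5 linear-interpolation percentiles per (age, year)."""
    if pooled.draws.shape[0] < 2:
        raise ValueError("at least 2 simulations are required to summarize")
    q = np.percentile(pooled.draws, [2.5, 50.0, 97.5], axis=0)
    rows = []
    for ai, age in enumerate(pooled.ages):
        for yi, year in enumerate(pooled.years):
            rows.append((float(age), int(year), q[1, ai, yi], q[0, ai, yi], q[2, ai, yi]))
    table = pd.DataFrame(rows, columns=["age", "year", "median", "cri_low", "cri_high"])
    return ProjectionSummary(table=table)
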