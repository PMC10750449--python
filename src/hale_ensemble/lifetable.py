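"""Sullivan-type healthy life expectancy from piecewise-constant schedules.

A :class:`HealthSchedule` holds an all-cause mortality hazard (per
person-year) and a healthy-time fraction on each interval of an age grid.
Healthy life expectancy at age ``a`` is the expected remaining person-years
lived in full health,

    HLE(a) = integral_a^omega S(x | a) * hf(x) dx,

with ``S(x | a)`` the survival function implied by the hazards and ``hf``
the healthy fraction.  Both ingredients are piecewise constant, so the
integral has a closed form per interval; no numerical quadrature is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["HealthSchedule", "compute_hle_from_schedule"]

DEFAULT_CAP = 110.0


@dataclass(frozen=True)
class HealthSchedule:
    """Piecewise-constant hazard and healthy fraction on an age grid.

    ``ages`` are the left endpoints of the intervals; the last interval runs
    from ``ages[-1]`` to the lifespan cap ``omega`` (survival is truncated
    there, i.e. everyone alive at ``omega`` dies).
    """

    ages: np.ndarray
    hazard: np.ndarray
    healthy_fraction: np.ndarray
    omega: float = DEFAULT_CAP

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=float)
        hazard = np.asarray(self.hazard, dtype=float)
        hf = np.asarray(self.healthy_fraction, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "hazard", hazard)
        object.__setattr__(self, "healthy_fraction", hf)
        if ages.ndim != 1 or ages.size < 1:
            raise ValueError("age grid must be a non-empty 1-D array")
        if ages[0] != 0.0:
            raise ValueError("age grid must start at 0")
        if np.any(np.diff(ages) <= 0):
            raise ValueError("age grid must be strictly increasing")
        if hazard.shape != ages.shape or hf.shape != ages.shape:
            raise ValueError("hazard and healthy_fraction must match the age grid")
        if not np.all(np.isfinite(hazard)) or np.any(hazard < 0):
            raise ValueError("hazard must be finite and non-negative")
        if np.any(hf < 0) or np.any(hf > 1):
            raise ValueError("healthy_fraction must lie in [0, 1]")
        if ages[-1] >= self.omega:
            raise ValueError("age grid must lie strictly below the lifespan cap")


def _interval_integral(mu: float, length: float) -> float:
    """integral_0^L exp(-mu x) dx, stable as mu -> 0."""
    if mu * length < 1e-12:
        return length * (1.0 - 0.5 * mu * length)
    return (1.0 - np.exp(-mu * length)) / mu


def compute_hle_from_schedule(
    schedule: HealthSchedule, age_grid: np.ndarray | None = None
) -> np.ndarray:
    """Healthy life expectancy at each age of ``age_grid``.

    Parameters
    ----------
    schedule
        Piecewise-constant hazard / healthy-fraction schedule.
    age_grid
        Ages (within ``[0, omega)``) at which HLE is evaluated.  Defaults to
        the schedule's own grid.  Ages need not coincide with grid points.

    Returns
    -------
    Array of HLE values in years, one per requested age; each lies in
    ``[0, omega - age]``.
    """
    if age_grid is None:
        age_grid = schedule.ages
    ages = np.asarray(age_grid, dtype=float)
    if np.any(ages < 0) or np.any(ages >= schedule.omega):
        raise ValueError("requested ages must lie in [0, omega)")

    bounds = np.append(schedule.ages, schedule.omega)
    out = np.empty(ages.shape, dtype=float)
    for i, a in enumerate(ages.ravel()):
        j = int(np.searchsorted(bounds, a, side="right")) - 1
        surv = 1.0
        total = 0.0
        start = a
        for seg in range(j, schedule.ages.size):
            length = bounds[seg + 1] - start
            mu = schedule.hazard[seg]
            total += schedule.healthy_fraction[seg] * surv * _interval_integral(mu, length)
            surv *= np.exp(-mu * length)
            start = bounds[seg + 1]
        out.ravel()[i] = total
    return out
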