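"""GBD-style synthetic panels of age- and sex-specific healthy life expectancy.

The generator emulates the structure of a Global Burden of Disease HALE
export: one record per (country, sex, exact age, calendar year) holding
remaining healthy years, for the age grid 0, 1, 5, 10, ..., 80 and years
1990-2019, with an optional socio-demographic-index (SDI) quintile label per
country.

Each country-sex stratum gets a baseline age profile derived from a
piecewise-constant mortality-hazard / healthy-fraction schedule via
Sullivan-type integration (see :mod:`hale_ensemble.lifetable`), which makes
the cross-age profile coherent: HLE declines with age above age 1, and a
high infant hazard can push HLE at birth below HLE at age 1, the pattern
real HALE tables show.  Calendar-time dynamics are a per-age linear drift on
the HLE scale — proportional to the baseline profile so the age ordering is
preserved — optionally with a trend break at a random knot year or an
additive birth-cohort wave.  Observation noise is a stationary AR(1) process
over time, independent across ages.  The generating drifts are recorded in a
truth block so recovery can be tested exactly.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .lifetable import DEFAULT_CAP, HealthSchedule, compute_hle_from_schedule

__all__ = [
    "DEFAULT_AGES",
    "PanelConfig",
    "StratumTruth",
    "HLEPanel",
    "generate_panel",
    "write_panel_csv",
    "read_panel_csv",
]

DEFAULT_AGES: tuple[int, ...] = (0, 1) + tuple(range(5, 85, 5))
SEXES = ("female", "male")
SDI_LABELS = ("low-SDI", "low-middle-SDI", "middle-SDI", "high-middle-SDI", "high-SDI")

# Internal cohort-wave constants (trend_regime="cohort"): a smooth sinusoid in
# birth year, small enough not to break the age ordering of the profile.
_COHORT_AMP = 0.4
_COHORT_PERIOD = 45.0


@dataclass(frozen=True)
class PanelConfig:
    """Study conditions for one synthetic panel.

    Defaults mirror a GBD 2019 HALE extraction: 202 countries, both sexes,
    ages 0, 1, 5, ..., 80, years 1990-2019.  ``drift_mean``/``drift_sd`` are
    the cross-country mean and spread of the HLE-at-birth trend in years of
    HLE per calendar year (about 2.5 years per decade globally);
    ``noise_sd`` is the marginal standard deviation of the AR(1) observation
    noise in years.
    """

    n_countries: int = 202
    sexes: tuple[str, ...] = SEXES
    ages: tuple[int, ...] = DEFAULT_AGES
    years: tuple[int, int] = (1990, 2019)
    trend_regime: str = "linear"
    drift_mean: float = 0.25
    drift_sd: float = 0.10
    noise_sd: float = 0.2
    ar1_rho: float = 0.3
    seed: int = 0
    with_sdi: bool = True
    omega: float = DEFAULT_CAP

    def __post_init__(self) -> None:
        if self.n_countries < 1:
            raise ValueError("n_countries must be a positive integer")
        if not self.sexes or any(s not in SEXES for s in self.sexes):
            raise ValueError(f"sexes must be a non-empty subset of {SEXES}")
        ages = np.asarray(self.ages, dtype=float)
        if ages[0] != 0 or np.any(np.diff(ages) <= 0):
            raise ValueError("ages must start at 0 and be strictly increasing")
        if ages[-1] >= self.omega:
            raise ValueError("ages must lie below the lifespan cap omega")
        y0, y1 = self.years
        if y1 < y0:
            raise ValueError("years must be an inclusive (first, last) range")
        if self.trend_regime not in ("linear", "broken", "cohort"):
            raise ValueError("trend_regime must be linear, broken or cohort")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not (0 <= abs(self.ar1_rho) < 1):
            raise ValueError("|ar1_rho| must be < 1")

    @property
    def year_range(self) -> np.ndarray:
        return np.arange(self.years[0], self.years[1] + 1)


@dataclass(frozen=True)
class StratumTruth:
    """Generating parameters for one (country, sex) stratum.

    ``drift`` is the per-age slope (years of HLE per year) in force before
    ``knot_year``; ``drift_post`` applies after it (equal to ``drift`` in the
    linear and cohort regimes).  The noiseless generating surface is
    recoverable at any year, including future ones, via :meth:`true_values`.
    """

    ages: np.ndarray
    base_year: int
    hle0: np.ndarray
    regime: str
    drift: np.ndarray
    drift_post: np.ndarray
    knot_year: int
    cohort_amp: float = 0.0
    cohort_period: float = _COHORT_PERIOD
    cohort_phase: float = 0.0

    def true_values(self, years: Sequence[int]) -> np.ndarray:
        """Noiseless HLE matrix (age x year) at the requested years."""
        years = np.asarray(years, dtype=float)
        pre = np.minimum(years, self.knot_year) - self.base_year
        post = np.maximum(years - self.knot_year, 0.0)
        out = (
            self.hle0[:, None]
            + self.drift[:, None] * pre[None, :]
            + self.drift_post[:, None] * post[None, :]
        )
        if self.cohort_amp:
            cohorts = years[None, :] - self.ages[:, None]
            out = out + self.cohort_amp * np.sin(
                2 * np.pi * (cohorts - self.cohort_phase) / self.cohort_period
            )
        return out


@dataclass
class HLEPanel:
    """Observed HLE records plus optional generating truth.

    ``data`` holds one row per (location, sex, age, year) with the HLE value
    in column ``val`` and, optionally, an ``sdi_group`` label.
    """

    data: pd.DataFrame
    omega: float = DEFAULT_CAP
    truth: dict[tuple[str, str], StratumTruth] = field(default_factory=dict)

    @property
    def countries(self) -> list[str]:
        return sorted(self.data["location"].unique())

    @property
    def sexes(self) -> list[str]:
        return sorted(self.data["sex"].unique())

    @property
    def ages(self) -> np.ndarray:
        return np.sort(self.data["age"].unique())

    @property
    def years(self) -> np.ndarray:
        return np.sort(self.data["year"].unique())

    def matrix(self, location: str, sex: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(ages, years, age-by-year HLE matrix) for one stratum.

        Raises if any (age, year) cell is missing, since every projection
        model requires a complete rectangular series.
        """
        sub = self.data[(self.data["location"] == location) & (self.data["sex"] == sex)]
        if sub.empty:
            raise KeyError(f"no records for stratum ({location!r}, {sex!r})")
        pivot = sub.pivot(index="age", columns="year", values="val")
        if pivot.isna().any().any():
            raise ValueError(f"stratum ({location}, {sex}) has missing (age, year) cells")
        return (
            pivot.index.to_numpy(dtype=float),
            pivot.columns.to_numpy(dtype=int),
            pivot.to_numpy(dtype=float),
        )

    def validate(self) -> None:
        """Check the panel invariants; raise ``ValueError`` on violation."""
        _check_keys(self.data)
        if (self.data["val"] < 0).any():
            raise ValueError("HLE values must be non-negative")
        cap = self.omega - self.data["age"]
        if (self.data["val"] > cap + 1e-9).any():
            raise ValueError("HLE values must not exceed omega - age")
        adult = self.data[self.data["age"] >= 1]
        grouped = adult.sort_values("age").groupby(["location", "sex", "year"])["val"]
        if (grouped.diff().dropna() >= 0).any():
            raise ValueError("HLE must strictly decrease with age for ages >= 1")


def _check_keys(df: pd.DataFrame) -> None:
    dup = df.duplicated(subset=["location", "sex", "age", "year"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            "duplicate panel key (location={location}, sex={sex}, age={age}, "
            "year={year})".format(**row[["location", "sex", "age", "year"]].to_dict())
        )


def _baseline_schedule(
    ages: np.ndarray, dev: float, sex: str, omega: float, rng: np.random.Generator
) -> HealthSchedule:
    """Country/sex baseline hazard and healthy-fraction profile.

    ``dev`` is a latent development score (higher = healthier).  The infant
    interval carries its own hazard so low-development countries show the
    HLE(0) < HLE(1) crossover.
    """
    sex_mult = 0.85 if sex == "female" else 1.25
    infant = 0.018 * np.exp(-0.8 * dev + 0.1 * rng.normal())
    background = 5e-4 * np.exp(-0.5 * dev)
    gompertz = 1.0e-4 * np.exp(0.085 * ages) * np.exp(-0.45 * dev)
    hazard = np.where(ages < 1, infant, background + gompertz) * sex_mult
    hf = np.clip(0.97 - 0.0040 * ages + 0.015 * dev, 0.40, 0.99)
    if sex == "female":
        hf = hf * 0.995  # women live more years but a slightly lower share healthy
    return HealthSchedule(ages=ages, hazard=hazard, healthy_fraction=hf, omega=omega)


def _ar1_noise(
    rng: np.random.Generator, n_series: int, n_years: int, sd: float, rho: float
) -> np.ndarray:
    """Stationary AR(1) noise, marginal standard deviation ``sd``."""
    if sd == 0:
        return np.zeros((n_series, n_years))
    z = rng.normal(size=(n_series, n_years))
    e = np.empty_like(z)
    e[:, 0] = sd * z[:, 0]
    innov = sd * np.sqrt(1.0 - rho**2)
    for t in range(1, n_years):
        e[:, t] = rho * e[:, t - 1] + innov * z[:, t]
    return e


def generate_panel(config: PanelConfig) -> HLEPanel:
    """Draw a synthetic HLE panel; deterministic for a given config + seed."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    ages = np.asarray(config.ages, dtype=float)
    years = config.year_range
    n_years = years.size
    base_year = int(years[0])

    countries = [f"C{i + 1:03d}" for i in range(config.n_countries)]
    dev = np.clip(rng.normal(size=config.n_countries), -2.5, 2.5)
    drift_birth = config.drift_mean + config.drift_sd * rng.normal(size=config.n_countries)
    sex_drift_offset = 0.02 * rng.normal(size=(config.n_countries, len(config.sexes)))
    knot_lo = base_year + int(0.2 * n_years)
    knot_hi = base_year + int(0.8 * n_years)
    knots = rng.integers(knot_lo, knot_hi + 1, size=config.n_countries)
    break_factor = rng.uniform(0.3, 1.7, size=config.n_countries)
    phases = rng.uniform(0.0, _COHORT_PERIOD, size=config.n_countries)

    truth: dict[tuple[str, str], StratumTruth] = {}
    frames: list[pd.DataFrame] = []
    baseline_birth: dict[str, float] = {}

    for ci, country in enumerate(countries):
        for si, sex in enumerate(config.sexes):
            sched = _baseline_schedule(ages, dev[ci], sex, config.omega, rng)
            hle0 = compute_hle_from_schedule(sched, ages)
            if sex == "female":
                baseline_birth[country] = float(hle0[0])
            d0 = drift_birth[ci] + sex_drift_offset[ci, si]
            rate = d0 / hle0[0]
            drift = rate * hle0  # proportional: preserves the age ordering
            if config.trend_regime == "broken":
                drift_post = drift * break_factor[ci]
                knot_year = int(knots[ci])
            else:
                drift_post = drift
                knot_year = int(years[-1])
            amp = _COHORT_AMP if config.trend_regime == "cohort" else 0.0
            st = StratumTruth(
                ages=ages,
                base_year=base_year,
                hle0=hle0,
                regime=config.trend_regime,
                drift=drift,
                drift_post=drift_post,
                knot_year=knot_year,
                cohort_amp=amp,
                cohort_phase=float(phases[ci]),
            )
            truth[(country, sex)] = st

            values = st.true_values(years)
            values = values + _ar1_noise(
                rng, ages.size, n_years, config.noise_sd, config.ar1_rho
            )
            # Repair rare noise-induced ordering violations above age 1; a
            # no-op whenever the noisy profile is already monotone (always,
            # when noise_sd = 0).
            adult = values[1:] if ages[0] == 0 and ages.size > 1 else values
            adult[:] = -np.sort(-adult, axis=0)
            values = np.clip(values, 0.0, (config.omega - ages)[:, None])

            frames.append(
                pd.DataFrame(
                    {
                        "location": country,
                        "sex": sex,
                        "age": np.repeat(ages.astype(int), n_years),
                        "year": np.tile(years, ages.size),
                        "val": values.ravel(),
                    }
                )
            )

    data = pd.concat(frames, ignore_index=True)
    if config.with_sdi:
        ranked = pd.Series(baseline_birth).rank(method="first")
        quintile = np.ceil(ranked * 5 / len(ranked)).astype(int).clip(1, 5)
        labels = {c: SDI_LABELS[q - 1] for c, q in quintile.items()}
        data["sdi_group"] = data["location"].map(labels)
    panel = HLEPanel(data=data, omega=config.omega, truth=truth)
    panel.validate()
    return panel


def write_panel_csv(panel: HLEPanel, path: str | Path) -> None:
    """Write the panel in the flat CSV dialect (UTF-8, comma-separated).

    Columns: ``location, sex, age, year, val`` and, when present,
    ``sdi_group``.  The truth block is not serialised.
    """
    cols = ["location", "sex", "age", "year", "val"]
    if "sdi_group" in panel.data.columns:
        cols.append("sdi_group")
    out = panel.data[cols].sort_values(["location", "sex", "age", "year"])
    out.to_csv(path, index=False, float_format="%.9f", encoding="utf-8")


def read_panel_csv(path: str | Path | io.TextIOBase, omega: float = DEFAULT_CAP) -> HLEPanel:
    """Read a panel CSV; an empty file with a header yields an empty panel."""
    df = pd.read_csv(path, encoding="utf-8")
    required = ["location", "sex", "age", "year", "val"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"panel CSV is missing required columns: {missing}")
    for col, kind in (("age", "integer"), ("year", "integer"), ("val", "numeric")):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(f"non-{kind} value {df[col].iloc[row]!r} in column "
                             f"{col!r} at data row {row + 1}")
        df[col] = coerced
    df["age"] = df["age"].astype(int)
    df["year"] = df["year"].astype(int)
    df["val"] = df["val"].astype(float)
    _check_keys(df)
    return HLEPanel(data=df.reset_index(drop=True), omega=omega)
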