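"""The 21-member catalog of individual HLE projection models.

Every member models age-specific healthy life expectancy directly on the
years scale with a Gaussian likelihood.  Six families are represented:

* ``age_time`` — h(a, t) = alpha_a + delta (t - tbar), with the drift either
  common across ages or age-specific (2 models);
* ``weighted_age_time`` / ``weighted_age_time_cohort`` — the same age-time
  (resp. age-time-cohort) structure fit by weighted likelihood, each year's
  contribution scaled by rho^(T - t), rho in {0.90, 0.95} (4 models);
* ``piecewise`` — age intercepts plus a continuous piecewise-linear common
  time trend, with or without a birth-cohort term, 1 or 2 knots, knots
  either fixed at window quantiles or chosen by an SSE search (8 models);
* ``age_time_cohort`` — age-specific drifts plus a penalized random-walk
  cohort effect over c = t - a, first- or second-difference penalty
  (2 models);
* ``lee_carter`` — h(a, t) = alpha_a + beta_a k_t with k_t forecast as a
  random walk with drift; classic SVD, two-component, broken-drift, robust
  (median-increment) drift, and an age-cohort extension (5 models).

Cohort effects are identified by sum-to-zero and zero-slope constraints.
Projection draws sample parameters from the Gaussian approximation to their
posterior (sigma^2 (M'M)^-1 around the penalized least-squares estimate) and
propagate random-walk innovations for the Lee-Carter time index and for
cohort effects of cohorts unobserved in training; draws are clipped to
[0, omega].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Any, Mapping, Sequence

import numpy as np

from .lifetable import DEFAULT_CAP
from .synthetic_data import HLEPanel

__all__ = [
    "ModelSpec",
    "ModelFit",
    "PosteriorDraws",
    "StratumSeries",
    "InsufficientHistoryError",
    "catalog",
    "fit",
    "project",
]

logger = logging.getLogger(__name__)

FAMILIES = (
    "age_time",
    "weighted_age_time",
    "weighted_age_time_cohort",
    "piecewise",
    "age_time_cohort",
    "lee_carter",
)

MIN_TRAIN_YEARS = 8
# Smoothing strength for penalized random-walk cohort effects (dimensionless
# ratio of residual to cohort-innovation variance); one value serves all
# cohort families.
COHORT_PENALTY = 10.0
_CONSTRAINT_WEIGHT = 1e4


class InsufficientHistoryError(ValueError):
    """Raised when a training window is too short to fit a model."""


@dataclass(frozen=True)
class ModelSpec:
    """Identity and settings of one ensemble member."""

    id: int
    family: str
    name: str
    options: tuple[tuple[str, Any], ...] = ()

    def opt(self, key: str, default: Any = None) -> Any:
        return dict(self.options).get(key, default)


def _spec(mid: int, family: str, name: str, **options: Any) -> ModelSpec:
    return ModelSpec(id=mid, family=family, name=name, options=tuple(sorted(options.items())))


def catalog() -> list[ModelSpec]:
    """The ordered catalog of 21 model specifications (stable ids)."""
    specs = [
        _spec(1, "age_time", "age-time, common drift", drift="common"),
        _spec(2, "age_time", "age-time, per-age drift", drift="per_age"),
        _spec(3, "weighted_age_time", "weighted age-time, rho=0.90", drift="per_age", rho=0.90),
        _spec(4, "weighted_age_time", "weighted age-time, rho=0.95", drift="per_age", rho=0.95),
        _spec(5, "weighted_age_time_cohort", "weighted age-time-cohort, rho=0.90",
              drift="per_age", rho=0.90, diff_order=1),
        _spec(6, "weighted_age_time_cohort", "weighted age-time-cohort, rho=0.95",
              drift="per_age", rho=0.95, diff_order=1),
    ]
    mid = 7
    for cohort in (False, True):
        for n_knots in (1, 2):
            for rule in ("fixed", "search"):
                label = "age-time-cohort" if cohort else "age trend"
                specs.append(
                    _spec(mid, "piecewise",
                          f"piecewise {label}, {n_knots} knot(s), {rule} knots",
                          cohort=cohort, n_knots=n_knots, knot_rule=rule, diff_order=1)
                )
                mid += 1
    specs += [
        _spec(15, "age_time_cohort", "age-time-cohort, RW1 cohort", drift="per_age", diff_order=1),
        _spec(16, "age_time_cohort", "age-time-cohort, RW2 cohort", drift="per_age", diff_order=2),
        _spec(17, "lee_carter", "Lee-Carter, classic", variant="classic"),
        _spec(18, "lee_carter", "Lee-Carter, two components", variant="two_component"),
        _spec(19, "lee_carter", "Lee-Carter, broken drift", variant="broken_drift"),
        _spec(20, "lee_carter", "Lee-Carter, robust drift", variant="robust_drift"),
        _spec(21, "lee_carter", "Lee-Carter, age-cohort", variant="age_cohort"),
    ]
    return specs


@dataclass(frozen=True)
class StratumSeries:
    """Complete age-by-year HLE matrix for one (country, sex) stratum."""

    location: str
    sex: str
    ages: np.ndarray
    years: np.ndarray
    values: np.ndarray  # shape (n_ages, n_years)
    omega: float = DEFAULT_CAP

    @classmethod
    def from_panel(cls, panel: HLEPanel, location: str, sex: str) -> "StratumSeries":
        ages, years, values = panel.matrix(location, sex)
        return cls(location=location, sex=sex, ages=ages, years=years,
                   values=values, omega=panel.omega)

    def window(self, train_window: tuple[int, int] | None) -> "StratumSeries":
        if train_window is None:
            return self
        lo, hi = train_window
        mask = (self.years >= lo) & (self.years <= hi)
        if not mask.any():
            raise InsufficientHistoryError(f"no data in training window {train_window}")
        return replace(self, years=self.years[mask], values=self.values[:, mask])


@dataclass
class ModelFit:
    """Fitted parameters plus what projection needs to extrapolate."""

    spec: ModelSpec
    ages: np.ndarray
    train_years: np.ndarray
    kind: str  # "linear" | "lee_carter"
    params: dict[str, Any]
    sigma2: float
    omega: float = DEFAULT_CAP

    @property
    def train_window(self) -> tuple[int, int]:
        return int(self.train_years[0]), int(self.train_years[-1])


@dataclass
class PosteriorDraws:
    """Simulated future age-specific HLE under one model."""

    model_id: int
    ages: np.ndarray
    years: np.ndarray
    draws: np.ndarray  # shape (n_draws, n_ages, n_years)
    seed: int

    def at_age(self, age: float) -> np.ndarray:
        """Draws for a single age, shape (n_draws, n_years)."""
        idx = int(np.flatnonzero(np.isclose(self.ages, age))[0])
        return self.draws[:, idx, :]

    def median(self) -> np.ndarray:
        return np.median(self.draws, axis=0)


# ---------------------------------------------------------------------------
# linear-in-parameters families


def _likelihood_weights(years: np.ndarray, rho: float | None) -> np.ndarray | None:
    """Per-year weights rho^(T - t), normalized to mean 1 (rho=1 -> all 1)."""
    if rho is None:
        return None
    w = rho ** (years[-1] - years)
    return w / w.mean()


def _cohort_values(ages: np.ndarray, years: np.ndarray) -> np.ndarray:
    return np.unique(years[None, :] - ages[:, None])


def _design(
    ages: np.ndarray,
    years: np.ndarray,
    tbar: float,
    per_age: bool,
    knots: Sequence[float],
    cohort_values: np.ndarray | None,
) -> np.ndarray:
    """Stacked design matrix, rows age-major ((a1,t1..tT), (a2,t1..tT), ...)."""
    A, T = ages.size, years.size
    n = A * T
    age_idx = np.repeat(np.arange(A), T)
    t = np.tile(years.astype(float), A)
    cols: list[np.ndarray] = []
    eye = np.eye(A)
    cols.append(eye[age_idx])  # age intercepts
    trend = t - tbar
    if per_age:
        cols.append(eye[age_idx] * trend[:, None])
    else:
        cols.append(trend[:, None])
    for k in knots:
        cols.append(np.maximum(t - k, 0.0)[:, None])
    if cohort_values is not None:
        c = t - np.repeat(ages.astype(float), T)
        cidx = np.searchsorted(cohort_values, np.clip(c, cohort_values[0], cohort_values[-1]))
        Z = np.zeros((n, cohort_values.size))
        Z[np.arange(n), cidx] = 1.0
        cols.append(Z)
    return np.hstack(cols)


def _cohort_penalty_rows(
    cohort_values: np.ndarray, n_lead: int, diff_order: int, lam: float
) -> np.ndarray:
    """Penalty + identification rows appended below the design matrix."""
    n_c = cohort_values.size
    p = n_lead + n_c
    rows = []
    sq = np.sqrt(lam)
    if diff_order == 1:
        gaps = np.diff(cohort_values)
        for i in range(n_c - 1):
            r = np.zeros(p)
            r[n_lead + i] = -1.0
            r[n_lead + i + 1] = 1.0
            rows.append(sq * r / np.sqrt(gaps[i]))
    else:
        for i in range(n_c - 2):
            r = np.zeros(p)
            r[n_lead + i] = 1.0
            r[n_lead + i + 1] = -2.0
            r[n_lead + i + 2] = 1.0
            rows.append(sq * r)
    # sum-to-zero and zero-slope identification constraints
    r = np.zeros(p)
    r[n_lead:] = 1.0
    rows.append(_CONSTRAINT_WEIGHT * r / n_c)
    r = np.zeros(p)
    cc = cohort_values - cohort_values.mean()
    r[n_lead:] = cc / max(np.abs(cc).max(), 1.0)
    rows.append(_CONSTRAINT_WEIGHT * r / n_c)
    return np.array(rows)


def _solve_penalized(
    X: np.ndarray,
    y: np.ndarray,
    row_weights: np.ndarray | None,
    pen: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Penalized (weighted) least squares.

    Returns (coef, posterior covariance factor G = (M'M)^+, sigma2) where the
    parameter covariance is sigma2 * G.
    """
    Xw = X if row_weights is None else X * np.sqrt(row_weights)[:, None]
    yw = y if row_weights is None else y * np.sqrt(row_weights)
    M = Xw if pen is None or pen.size == 0 else np.vstack([Xw, pen])
    z = yw if pen is None or pen.size == 0 else np.concatenate([yw, np.zeros(pen.shape[0])])
    coef, _, rank, _ = np.linalg.lstsq(M, z, rcond=None)
    if rank < M.shape[1]:
        logger.warning(
            "rank-deficient design (rank %d < %d parameters); redundant "
            "parameters pinned by the minimum-norm solution", rank, M.shape[1]
        )
    MtM = M.T @ M
    G = np.linalg.pinv(MtM, hermitian=True)
    resid = yw - Xw @ coef
    XtX = Xw.T @ Xw
    edf = float(np.sum(G * XtX))  # trace(G @ XtX), both symmetric
    dof = max(y.size - edf, 1.0)
    sigma2 = float(resid @ resid) / dof
    return coef, G, sigma2


def _select_knots(
    series: StratumSeries, n_knots: int, rule: str, per_age: bool, tbar: float
) -> list[float]:
    years = series.years.astype(float)
    lo, hi = years[0], years[-1]
    if n_knots == 0:
        return []
    if rule == "fixed":
        return [lo + (i + 1) * (hi - lo) / (n_knots + 1) for i in range(n_knots)]
    # SSE search on the cohort-free profile (cheap); margin of 3 years per side
    candidates = [t for t in years if lo + 3 <= t <= hi - 3]
    if not candidates:
        return [lo + (i + 1) * (hi - lo) / (n_knots + 1) for i in range(n_knots)]
    y = series.values.ravel()

    def sse(knots: list[float]) -> float:
        X = _design(series.ages, series.years, tbar, per_age, knots, None)
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ coef
        return float(r @ r)

    if n_knots == 1:
        scored = [(sse([k]), k) for k in candidates]
        return [min(scored)[1]]
    coarse = candidates[::2] if len(candidates) > 12 else candidates
    best: tuple[float, list[float]] | None = None
    for i, k1 in enumerate(coarse):
        for k2 in coarse[i + 1:]:
            if k2 - k1 < 3:
                continue
            s = sse([k1, k2])
            if best is None or s < best[0]:
                best = (s, [k1, k2])
    if best is None:
        return [lo + (i + 1) * (hi - lo) / (n_knots + 1) for i in range(n_knots)]
    return best[1]


def _fit_linear(spec: ModelSpec, series: StratumSeries) -> ModelFit:
    ages, years, values = series.ages, series.years, series.values
    tbar = float(years.mean())
    family = spec.family
    per_age = spec.opt("drift") == "per_age"
    rho = spec.opt("rho")
    has_cohort = family in ("weighted_age_time_cohort", "age_time_cohort") or (
        family == "piecewise" and spec.opt("cohort", False)
    )
    knots: list[float] = []
    if family == "piecewise":
        per_age = False  # common piecewise trend over age intercepts
        knots = _select_knots(series, spec.opt("n_knots", 1), spec.opt("knot_rule", "fixed"),
                              per_age, tbar)
    cohort_values = _cohort_values(ages, years) if has_cohort else None
    X = _design(ages, years, tbar, per_age, knots, cohort_values)
    y = values.ravel()
    weights = None
    if rho is not None:
        w_year = _likelihood_weights(years, rho)
        weights = np.tile(w_year, ages.size)
    pen = None
    n_lead = X.shape[1] - (cohort_values.size if cohort_values is not None else 0)
    if cohort_values is not None:
        pen = _cohort_penalty_rows(cohort_values, n_lead, spec.opt("diff_order", 1),
                                   COHORT_PENALTY)
    coef, G, sigma2 = _solve_penalized(X, y, weights, pen)

    cohort_innovation_sd = 0.0
    if cohort_values is not None and cohort_values.size >= 3:
        gamma = coef[n_lead:]
        steps = np.diff(gamma) / np.sqrt(np.diff(cohort_values))
        cohort_innovation_sd = float(np.std(steps, ddof=1))
    params = {
        "coef": coef,
        "cov_factor": G,
        "tbar": tbar,
        "per_age": per_age,
        "knots": knots,
        "cohort_values": cohort_values,
        "n_lead": n_lead,
        "cohort_innovation_sd": cohort_innovation_sd,
    }
    return ModelFit(spec=spec, ages=ages, train_years=years, kind="linear",
                    params=params, sigma2=sigma2, omega=series.omega)


def _project_linear(
    fit_: ModelFit, future_years: np.ndarray, n_draws: int, rng: np.random.Generator
) -> np.ndarray:
    p = fit_.params
    ages = fit_.ages
    A, H = ages.size, future_years.size
    cohort_values = p["cohort_values"]
    Xf = _design(ages, future_years, p["tbar"], p["per_age"], p["knots"], cohort_values)
    cov = fit_.sigma2 * p["cov_factor"]
    coef = p["coef"]
    if fit_.sigma2 > 0:
        w, U = np.linalg.eigh((cov + cov.T) / 2)
        L = U * np.sqrt(np.clip(w, 0.0, None))
        thetas = coef[None, :] + rng.standard_normal((n_draws, coef.size)) @ L.T
    else:
        thetas = np.broadcast_to(coef, (n_draws, coef.size))
    preds = thetas @ Xf.T  # (n_draws, A*H)
    preds = preds.reshape(n_draws, A, H)

    # random-walk continuation for cohorts unobserved during training
    if cohort_values is not None:
        sd = p["cohort_innovation_sd"]
        c_max = cohort_values[-1]
        c_future = future_years[None, :] - ages[:, None]  # (A, H)
        steps = np.round(np.clip(c_future - c_max, 0.0, None)).astype(int)
        max_step = int(steps.max())
        if max_step > 0 and sd > 0:
            walk = np.cumsum(rng.normal(0.0, sd, size=(n_draws, max_step)), axis=1)
            walk = np.concatenate([np.zeros((n_draws, 1)), walk], axis=1)
            preds = preds + walk[:, steps]
    return preds


# ---------------------------------------------------------------------------
# Lee-Carter family


def _fit_lee_carter(spec: ModelSpec, series: StratumSeries) -> ModelFit:
    ages, years, values = series.ages, series.years, series.values
    A, T = values.shape
    alpha = values.mean(axis=1)
    R = values - alpha[:, None]
    U, s, Vt = np.linalg.svd(R, full_matrices=False)
    scale = float(np.abs(values).max()) or 1.0

    def component(j: int) -> tuple[np.ndarray, np.ndarray]:
        if s[j] < 1e-10 * scale:
            return np.zeros(A), np.zeros(T)
        b = U[:, j]
        k = s[j] * Vt[j]
        if j == 0:
            tot = b.sum()
            if abs(tot) < 1e-12:  # degenerate: fall back to uniform response
                return np.full(A, 1.0 / A), np.zeros(T)
            return b / tot, k * tot  # normalization: sum(beta)=1, sum(k)=0
        if b[np.argmax(np.abs(b))] < 0:
            b, k = -b, -k
        return b, k

    beta, k = component(0)
    variant = spec.opt("variant", "classic")
    diffs = np.diff(k)

    def drift_stats(d: np.ndarray) -> tuple[float, float, float]:
        if d.size == 0 or np.allclose(d, d[0] if d.size else 0.0):
            base = float(d.mean()) if d.size else 0.0
            return base, 0.0, 0.0
        mu = float(d.mean())
        sigma = float(np.std(d - mu, ddof=1)) if d.size > 1 else 0.0
        return mu, sigma, sigma / np.sqrt(d.size)

    if variant == "broken_drift":
        half = diffs[diffs.size // 2:]
        drift, sigma_k, drift_se = drift_stats(half)
        _, sigma_k, _ = drift_stats(diffs)  # innovation scale from full window
        drift_se = sigma_k / np.sqrt(max(half.size, 1))
    elif variant == "robust_drift":
        drift = float(np.median(diffs)) if diffs.size else 0.0
        _, sigma_k, _ = drift_stats(diffs)
        drift_se = 1.2533 * sigma_k / np.sqrt(max(diffs.size, 1))
    else:
        drift, sigma_k, drift_se = drift_stats(diffs)

    params: dict[str, Any] = {
        "alpha": alpha, "beta": beta, "k": k,
        "drift": drift, "sigma_k": sigma_k, "drift_se": drift_se,
        "variant": variant,
    }
    resid = R - np.outer(beta, k)
    if variant == "two_component":
        beta2, k2 = component(1)
        d2 = np.diff(k2)
        drift2, sigma_k2, drift2_se = drift_stats(d2)
        params.update(beta2=beta2, k2=k2, drift2=drift2, sigma_k2=sigma_k2,
                      drift2_se=drift2_se)
        resid = resid - np.outer(beta2, k2)
    if variant == "age_cohort":
        cohort_values = _cohort_values(ages, years)
        Z = _design(ages, years, float(years.mean()), False, [], cohort_values)[:, -cohort_values.size:]
        pen = _cohort_penalty_rows(cohort_values, 0, 1, COHORT_PENALTY)
        gamma, Gg, _ = _solve_penalized(Z, resid.ravel(), None, pen)
        g_sd = float(np.std(np.diff(gamma) / np.sqrt(np.diff(cohort_values)), ddof=1)) \
            if cohort_values.size >= 3 else 0.0
        params.update(cohort_values=cohort_values, gamma=gamma,
                      cohort_innovation_sd=g_sd)
        resid = resid - (Z @ gamma).reshape(values.shape)
    dof = max(values.size - (A + T), 1)
    sigma2 = float((resid**2).sum()) / dof
    return ModelFit(spec=spec, ages=ages, train_years=years, kind="lee_carter",
                    params=params, sigma2=sigma2, omega=series.omega)


def _rwd_paths(
    last: float, drift: float, drift_se: float, sigma: float,
    n_draws: int, H: int, rng: np.random.Generator,
) -> np.ndarray:
    """Random-walk-with-drift continuations, shape (n_draws, H)."""
    h = np.arange(1, H + 1)
    d = drift + (drift_se * rng.standard_normal(n_draws) if drift_se > 0 else 0.0)
    paths = last + np.atleast_1d(d)[:, None] * h[None, :]
    if sigma > 0:
        paths = paths + sigma * np.cumsum(rng.standard_normal((n_draws, H)), axis=1)
    return np.broadcast_to(paths, (n_draws, H)).copy()


def _project_lee_carter(
    fit_: ModelFit, future_years: np.ndarray, n_draws: int, rng: np.random.Generator
) -> np.ndarray:
    p = fit_.params
    ages = fit_.ages
    A, H = ages.size, future_years.size
    kpaths = _rwd_paths(float(p["k"][-1]), p["drift"], p["drift_se"], p["sigma_k"],
                        n_draws, H, rng)
    preds = p["alpha"][None, :, None] + p["beta"][None, :, None] * kpaths[:, None, :]
    if p["variant"] == "two_component":
        k2paths = _rwd_paths(float(p["k2"][-1]), p["drift2"], p["drift2_se"],
                             p["sigma_k2"], n_draws, H, rng)
        preds = preds + p["beta2"][None, :, None] * k2paths[:, None, :]
    if p["variant"] == "age_cohort":
        cv = p["cohort_values"]
        gamma = p["gamma"]
        c_future = future_years[None, :] - ages[:, None]
        cidx = np.searchsorted(cv, np.clip(c_future, cv[0], cv[-1]))
        preds = preds + gamma[cidx][None, :, :]
        steps = np.round(np.clip(c_future - cv[-1], 0.0, None)).astype(int)
        max_step = int(steps.max())
        sd = p["cohort_innovation_sd"]
        if max_step > 0 and sd > 0:
            walk = np.cumsum(rng.normal(0.0, sd, size=(n_draws, max_step)), axis=1)
            walk = np.concatenate([np.zeros((n_draws, 1)), walk], axis=1)
            preds = preds + walk[:, steps]
    return preds


# ---------------------------------------------------------------------------
# public fit / project


def fit(
    spec: ModelSpec,
    series: StratumSeries,
    train_window: tuple[int, int] | None = None,
) -> ModelFit:
    """Fit one catalog model to a single stratum's age-by-year series."""
    series = series.window(train_window)
    if series.years.size < MIN_TRAIN_YEARS:
        raise InsufficientHistoryError(
            f"insufficient history: {series.years.size} training years < "
            f"{MIN_TRAIN_YEARS} required"
        )
    if not np.all(np.isfinite(series.values)):
        raise ValueError("series contains non-finite values")
    if spec.family == "lee_carter":
        return _fit_lee_carter(spec, series)
    if spec.family in FAMILIES:
        return _fit_linear(spec, series)
    raise ValueError(f"unknown model family {spec.family!r}")


def project(
    fit_: ModelFit, horizon_years: int, n_draws: int, seed: int
) -> PosteriorDraws:
    """Simulate the posterior of future age-specific HLE under one model."""
    if horizon_years < 1:
        raise ValueError("horizon_years must be >= 1")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    future_years = np.arange(fit_.train_years[-1] + 1,
                             fit_.train_years[-1] + 1 + horizon_years)
    if fit_.kind == "linear":
        draws = _project_linear(fit_, future_years, n_draws, rng)
    else:
        draws = _project_lee_carter(fit_, future_years, n_draws, rng)
    np.clip(draws, 0.0, fit_.omega, out=draws)
    return PosteriorDraws(model_id=fit_.spec.id, ages=fit_.ages,
                          years=future_years, draws=draws, seed=seed)
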