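"""End-to-end projection pipeline: simulate -> validate -> weigh -> project
-> pool -> summarize.

Model weights come from the holdout run, but the final projection fits use
the full data window for each country and sex.  Every stage draws its seed
from the master seed through a documented counter scheme (see
:func:`derive_seed`), so a run is idempotent: the same configuration yields
byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ensemble import PooledProjection, ProjectionSummary, pool_draws, summarize
from .model_catalog import StratumSeries, catalog, fit, project
from .synthetic_data import HLEPanel, PanelConfig, generate_panel, read_panel_csv, write_panel_csv
from .weighting import evaluate_stratum, holdout_split
from .summaries import GapRecord, rank_probabilities, round1

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "log_and_version", "derive_seed"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "weigh", "project", "pool", "summarize")


def derive_seed(master_seed: int, *path: int) -> int:
    """Stage/stratum seed: SeedSequence(master, stage index, stratum counters).

    Deterministic, collision-free across the counter path, and kept below
    2**31 so it can be passed anywhere a plain integer seed is accepted.
    """
    ss = np.random.SeedSequence((int(master_seed),) + tuple(int(p) for p in path))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def log_and_version(stage: str, params: Mapping[str, Any]) -> dict[str, Any]:
    """Emit and return a machine-parseable stage record."""
    if stage not in STAGES:
        raise ValueError(f"unknown pipeline stage {stage!r}; expected one of {STAGES}")
    record = {"stage": stage, "package_version": __version__, **dict(params)}
    logger.info("stage=%s %s", stage, json.dumps(dict(params), sort_keys=True, default=str))
    return record


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one full pipeline run."""

    out_dir: str = "output"
    panel_path: str | None = None  # read this panel instead of simulating
    panel: PanelConfig = field(default_factory=PanelConfig)
    target_year: int = 2030
    reference_year: int = 2020
    n_draws: int = 1000
    n_test_years: int = 13
    orientation: str = "forward"
    model_ids: tuple[int, ...] | None = None
    master_seed: int = 0
    rank_age: float = 0.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        panel_cfg = raw.pop("panel", None)
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})
        if panel_cfg is not None:
            panel_kwargs = {
                k: tuple(v) if isinstance(v, list) else v for k, v in panel_cfg.items()
            }
            cfg = dataclasses.replace(cfg, panel=PanelConfig(**panel_kwargs))
        return cfg

    def __post_init__(self) -> None:
        if self.target_year <= self.panel.years[1] and self.panel_path is None:
            raise ValueError("target_year must lie beyond the panel's last year")


@dataclass
class PooledStratum:
    pooled: PooledProjection
    summary: ProjectionSummary


@dataclass
class PipelineResult:
    config: RunConfig
    panel: HLEPanel
    weights: pd.DataFrame
    projections: pd.DataFrame
    rank_tables: dict[tuple[str, int], pd.DataFrame]
    gaps: pd.DataFrame
    pooled: dict[tuple[str, str], PooledStratum]
    records: list[dict[str, Any]]
    paths: dict[str, Path]


def _stratum_keys(panel: HLEPanel) -> list[tuple[str, str]]:
    return [(c, s) for c in panel.countries for s in panel.sexes]


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full pipeline and write all artifacts under ``out_dir``."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records: list[dict[str, Any]] = []
    paths: dict[str, Path] = {}

    # --- stage 1: obtain the panel -------------------------------------
    sim_seed = derive_seed(config.master_seed, 0)
    if config.panel_path is not None:
        panel = read_panel_csv(config.panel_path)
        records.append(log_and_version("simulate", {"source": config.panel_path}))
    else:
        panel = generate_panel(dataclasses.replace(config.panel, seed=sim_seed))
        records.append(log_and_version("simulate", {"seed": sim_seed,
                                                    "n_countries": config.panel.n_countries}))
    paths["panel"] = out_dir / "panel.csv"
    write_panel_csv(panel, paths["panel"])

    specs = catalog()
    if config.model_ids is not None:
        wanted = set(config.model_ids)
        specs = [s for s in specs if s.id in wanted]
        if not specs:
            raise ValueError("model_ids selected no catalog models")
    years = panel.years
    split = holdout_split(years, config.n_test_years, config.orientation)
    horizon = config.target_year - int(years[-1])
    strata = _stratum_keys(panel)

    # --- stage 2: holdout validation and weights ------------------------
    weight_rows = []
    weight_vectors = {}
    for si, (country, sex) in enumerate(strata):
        series = StratumSeries.from_panel(panel, country, sex)
        seed = derive_seed(config.master_seed, 1, si)
        try:
            biases, wv = evaluate_stratum(series, split, specs, config.n_draws, seed)
        except Exception as exc:  # annotate stage + stratum and re-raise
            raise RuntimeError(f"stage 'weigh' failed for stratum ({country}, {sex}): {exc}") from exc
        weight_vectors[(country, sex)] = wv
        for b in biases:
            weight_rows.append((country, sex, b.model_id, b.bias, wv[b.model_id]))
    records.append(log_and_version("weigh", {
        "orientation": config.orientation, "n_test_years": config.n_test_years,
        "n_models": len(specs), "seed_path": [1, "stratum"],
    }))
    weights_df = pd.DataFrame(weight_rows,
                              columns=["location", "sex", "model_id", "bias", "weight"])
    paths["weights"] = out_dir / "weights.csv"
    weights_df.to_csv(paths["weights"], index=False, float_format="%.9f")

    # --- stages 3-5: full-data fit, projection, pooling, summaries -------
    pooled_by_stratum: dict[tuple[str, str], PooledStratum] = {}
    proj_rows = []
    for si, (country, sex) in enumerate(strata):
        series = StratumSeries.from_panel(panel, country, sex)
        per_model = {}
        for mi, spec in enumerate(specs):
            seed = derive_seed(config.master_seed, 2, si, mi)
            try:
                fit_ = fit(spec, series)
                per_model[spec.id] = project(fit_, horizon, config.n_draws, seed)
            except Exception as exc:
                raise RuntimeError(
                    f"stage 'project' failed for stratum ({country}, {sex}), "
                    f"model {spec.id}: {exc}") from exc
        pool_seed = derive_seed(config.master_seed, 3, si)
        pooled = pool_draws(per_model, weight_vectors[(country, sex)],
                            n=config.n_draws, seed=pool_seed)
        summary = summarize(pooled)
        pooled_by_stratum[(country, sex)] = PooledStratum(pooled=pooled, summary=summary)
        for _, row in summary.table.iterrows():
            proj_rows.append((country, sex, row["age"], int(row["year"]),
                              row["median"], row["cri_low"], row["cri_high"]))
    records.append(log_and_version("project", {"horizon": horizon,
                                               "n_draws": config.n_draws,
                                               "seed_path": [2, "stratum", "model"]}))
    records.append(log_and_version("pool", {"n": config.n_draws,
                                            "seed_path": [3, "stratum"]}))
    projections = pd.DataFrame(
        proj_rows, columns=["location", "sex", "age", "year", "median", "cri_low", "cri_high"])
    paths["projections"] = out_dir / "projections.csv"
    projections.to_csv(paths["projections"], index=False, float_format="%.9f")

    # --- rank tables and sex-gap records ---------------------------------
    rank_tables = {}
    for sex in panel.sexes:
        for year in (config.reference_year, config.target_year):
            if not (int(years[-1]) < year <= config.target_year):
                continue
            draws = {c: pooled_by_stratum[(c, sex)].pooled.at_cell(config.rank_age, year)
                     for c in panel.countries}
            if len(draws) >= 2:
                table = rank_probabilities(draws).to_frame()
                rank_tables[(sex, year)] = table
                p = out_dir / f"rank_{sex}_{year}.csv"
                table.to_csv(p, index=False, float_format="%.9f")
                paths[f"rank_{sex}_{year}"] = p

    gap_rows = []
    if set(panel.sexes) >= {"female", "male"}:
        sdi = {}
        if "sdi_group" in panel.data.columns:
            sdi = panel.data.drop_duplicates("location").set_index("location")["sdi_group"].to_dict()
        for country in panel.countries:
            f = pooled_by_stratum[(country, "female")].summary
            m = pooled_by_stratum[(country, "male")].summary
            rec = GapRecord(
                country=country,
                gap_a=round1(f.median(0.0, config.reference_year) - m.median(0.0, config.reference_year)),
                gap_b=round1(f.median(0.0, config.target_year) - m.median(0.0, config.target_year)),
                sdi_group=sdi.get(country),
            )
            gap_rows.append((rec.country, rec.gap_a, rec.gap_b, rec.sdi_group or ""))
    gaps = pd.DataFrame(gap_rows, columns=["country",
                                           f"gap_{config.reference_year}",
                                           f"gap_{config.target_year}", "sdi_group"])
    paths["gaps"] = out_dir / "gaps.csv"
    gaps.to_csv(paths["gaps"], index=False, float_format="%.1f")
    records.append(log_and_version("summarize", {
        "reference_year": config.reference_year, "target_year": config.target_year}))

    meta = {
        "package_version": __version__,
        "master_seed": config.master_seed,
        "stage_seed_scheme": "SeedSequence((master, stage, stratum, model))",
        "n_models": len(specs),
        "model_ids": [s.id for s in specs],
        "config": {
            k: v for k, v in dataclasses.asdict(config).items() if k != "panel"
        },
        "panel_config": dataclasses.asdict(config.panel),
    }
    paths["metadata"] = out_dir / "metadata.json"
    paths["metadata"].write_text(json.dumps(meta, indent=2, sort_keys=True, default=str) + "\n")

    return PipelineResult(config=config, panel=panel, weights=weights_df,
                          projections=projections, rank_tables=rank_tables,
                          gaps=gaps, pooled=pooled_by_stratum, records=records,
                          paths=paths)
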