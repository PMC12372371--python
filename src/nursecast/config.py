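"""Run configuration: YAML loading, validation, and output emission.

A run is configured by a small YAML file.  Model parameters come either
from register-style CSVs (stocks + rates) or from the synthetic fixture
generator via a seed — exactly one of the two.  Unknown keys are
rejected with their dotted paths; every applied default is logged.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .demand import DemandParams
from .education import PipelineParams
from .recruitment import ModelParams
from .scenarios import self_sufficiency_year
from .synthetic_data import ShapeSpec, generate_parameters
from .workforce import grid_from_frame, rates_from_frame

__all__ = [
    "RunConfig",
    "load_config",
    "build_model",
    "write_outputs",
    "round_half_up",
    "scenario_summary",
]

logger = logging.getLogger("nursecast")

_SCHEMA = {
    "demand": {"base_year", "base_wte", "growth_rate", "horizon"},
    "pipeline": {
        "course_length",
        "completion_rate",
        "wte_conversion",
        "historical_intake",
    },
    "fixture": {
        "seed",
        "female_share",
        "outflow_split",
        "retirement_onset_age",
        "emigration_decay",
        "attrition_bump_size",
        "noise_sd",
    },
    "inputs": {"stocks_csv", "rates_csv"},
    "scenarios": None,  # list
    "sensitivity": None,  # bool
    "output_dir": None,  # str
}


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero (reporting only)."""
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


@dataclass
class RunConfig:
    """Validated configuration for a projection run."""

    demand: DemandParams = field(default_factory=DemandParams)
    pipeline_overrides: dict = field(default_factory=dict)
    fixture_seed: int | None = 0
    fixture_overrides: dict = field(default_factory=dict)
    stocks_csv: str | None = None
    rates_csv: str | None = None
    scenarios: tuple[str, ...] = ("A", "B", "C")
    sensitivity: bool = True
    output_dir: str = "out"
    raw: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        has_files = self.stocks_csv is not None or self.rates_csv is not None
        has_seed = self.fixture_seed is not None
        if has_files and has_seed:
            raise ValueError(
                "config must supply either inputs.{stocks_csv,rates_csv} or "
                "fixture.seed, not both"
            )
        if has_files and (self.stocks_csv is None or self.rates_csv is None):
            raise ValueError(
                "register input requires both inputs.stocks_csv and inputs.rates_csv"
            )
        if not has_files and not has_seed:
            raise ValueError("config must supply inputs files or a fixture seed")

    def config_hash(self) -> str:
        canon = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _check_unknown(raw: dict) -> None:
    for key, sub in raw.items():
        if key not in _SCHEMA:
            raise ValueError(f"unknown config key: {key!r}")
        allowed = _SCHEMA[key]
        if allowed is not None and isinstance(sub, dict):
            for k in sub:
                if k not in allowed:
                    raise ValueError(f"unknown config key: {key}.{k}")


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    _check_unknown(raw)

    d = raw.get("demand", {})
    defaults_used = {
        k for k in ("base_year", "base_wte", "growth_rate", "horizon") if k not in d
    }
    demand = DemandParams(
        base_year=int(d.get("base_year", 2021)),
        base_demand=float(d.get("base_wte", 64_383.0)),
        growth_rate=float(d.get("growth_rate", 0.014)),
        horizon_years=int(d.get("horizon", 30)),
    )
    if defaults_used:
        logger.info("demand defaults applied for: %s", sorted(defaults_used))

    inputs = raw.get("inputs", {}) or {}
    fixture = dict(raw.get("fixture", {}) or {})
    seed = fixture.pop("seed", None)
    if "inputs" not in raw and seed is None:
        seed = 0
        logger.info("no inputs given; defaulting to fixture seed 0")

    cfg = RunConfig(
        demand=demand,
        pipeline_overrides=dict(raw.get("pipeline", {}) or {}),
        fixture_seed=seed,
        fixture_overrides=fixture,
        stocks_csv=inputs.get("stocks_csv"),
        rates_csv=inputs.get("rates_csv"),
        scenarios=tuple(raw.get("scenarios", ("A", "B", "C"))),
        sensitivity=bool(raw.get("sensitivity", True)),
        output_dir=str(raw.get("output_dir", "out")),
        raw=raw,
    )
    return cfg


def build_model(cfg: RunConfig) -> ModelParams:
    """Materialise model parameters from a validated configuration."""
    if cfg.fixture_seed is not None:
        shape = ShapeSpec(seed=int(cfg.fixture_seed), **cfg.fixture_overrides)
        gen = generate_parameters(shape)
        grid, rates = gen.grid, gen.rates
        pipeline = gen.pipeline
        foreign_dist = gen.foreign_entrant_distribution
    else:
        grid = grid_from_frame(pd.read_csv(cfg.stocks_csv), year=cfg.demand.base_year)
        rates = rates_from_frame(pd.read_csv(cfg.rates_csv))
        # Entrant distributions default to the synthetic plausibility spans.
        from .synthetic_data import ShapeSpec as _S, _entry_distribution

        shape = _S()
        ages = grid.ages
        pipeline = PipelineParams(
            entrant_distribution=_entry_distribution(
                ages, shape.domestic_entry_ages, shape.female_share
            )
        )
        foreign_dist = _entry_distribution(
            ages, shape.foreign_entry_ages, shape.female_share
        )
    for key, value in cfg.pipeline_overrides.items():
        setattr(pipeline, key, value)
    return ModelParams(
        demand=cfg.demand,
        grid=grid,
        rates=rates,
        pipeline=pipeline,
        foreign_entrant_distribution=foreign_dist,
    )


def scenario_summary(name: str, ledger: pd.DataFrame) -> dict:
    """Headline numbers for one scenario ledger (all recomputable from it)."""
    end = ledger.index[-1]
    peak_year = int(ledger["stock_foreign_wte"].idxmax())
    return {
        "scenario": name,
        "self_sufficiency_year": self_sufficiency_year(ledger),
        "end_year": int(end),
        "end_demand_wte": round_half_up(ledger.loc[end, "demand_wte"]),
        "end_recruitment_requirement_wte": round_half_up(
            ledger.loc[end, "recruitment_requirement_wte"]
        ),
        "end_foreign_stock_wte": round_half_up(ledger.loc[end, "stock_foreign_wte"]),
        "end_foreign_share_of_demand_pct": round_half_up(
            100.0 * ledger.loc[end, "stock_foreign_wte"] / ledger.loc[end, "demand_wte"]
        ),
        "peak_foreign_stock_wte": round_half_up(ledger["stock_foreign_wte"].max()),
        "peak_foreign_stock_year": peak_year,
    }


def write_outputs(
    ledgers: dict[str, pd.DataFrame],
    tables: dict[str, pd.DataFrame],
    out_dir: str | Path,
    cfg: RunConfig | None = None,
) -> list[str]:
    """Write per-scenario ledgers, tables, and a summary JSON; return the manifest.

    CSVs are comma-separated UTF-8 with a header row and the year as the
    first column; identical inputs reproduce byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    summaries = []
    for name, ledger in ledgers.items():
        path = out / f"ledger_{name}.csv"
        ledger.to_csv(path)
        manifest.append(str(path))
        summaries.append(scenario_summary(name, ledger))
    for name, table in tables.items():
        path = out / f"{name}.csv"
        table.to_csv(path, index=False)
        manifest.append(str(path))
    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(summaries, indent=2) + "\n")
    manifest.append(str(summary_path))
    if cfg is not None:
        log_path = out / "run_log.json"
        log_path.write_text(
            json.dumps(
                {"config_hash": cfg.config_hash(), "config": cfg.raw}, indent=2
            )
            + "\n"
        )
        manifest.append(str(log_path))
    return manifest
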