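"""Run configuration: YAML/JSON-driven experiment definitions.

A :class:`RunConfig` bundles everything a reproducible experiment needs —
population source (CSV files or the synthetic generator), cohort size,
horizon, strategy list and seed — and executes the full strategy-grid
comparison, writing the comparison table as CSV plus a JSON run manifest
(package version, seed, parameter hash) when an output directory is set.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .engine import run_grid, simulate_cohort, strategy_grid
from .population import LifeTable, PopulationPyramid
from .screening import ScreeningStrategy
from .synthetic import SyntheticConfig, make_population


def _strategy_from_dict(d: dict) -> ScreeningStrategy:
    if d.get("risk_stratified"):
        return ScreeningStrategy.stratified(
            d["name"],
            _strategy_from_dict({"name": "high_risk", **d["high_risk_arm"]}),
            _strategy_from_dict({"name": "average_risk",
                                 **(d.get("average_risk_arm") or
                                    {"active": False})}),
            d.get("genetic_test", "prs"))
    if not d.get("active", True):
        return ScreeningStrategy.no_screening(d.get("name", "no_screening"))
    return ScreeningStrategy(
        name=d["name"], start_age=int(d.get("start_age", 45)),
        end_age=int(d.get("end_age", 74)), interval=int(d.get("interval", 1)),
        cutoff_mode=d.get("cutoff_mode", "fixed_4"))


@dataclass
class RunConfig:
    n_individuals: int = 100_000
    horizon_years: int = 30
    seed: int = 0
    population_csv: str | None = None    # age,count
    life_table_csv: str | None = None    # age,qx
    strategies: list[ScreeningStrategy] = field(default_factory=list)
    output_dir: str | None = None

    def __post_init__(self) -> None:
        errors = []
        if self.n_individuals < 1:
            errors.append("n_individuals must be >= 1")
        if self.horizon_years <= 0:
            errors.append("horizon_years must be positive")
        if self.seed is None:
            errors.append("a seed is mandatory")
        if (self.population_csv is None) != (self.life_table_csv is None):
            errors.append("population_csv and life_table_csv go together")
        if errors:
            raise ValueError("invalid configuration: " + "; ".join(errors))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        strategies = [_strategy_from_dict(s) for s in d.get("strategies", [])]
        return cls(n_individuals=int(d.get("n_individuals", 100_000)),
                   horizon_years=int(d.get("horizon_years", 30)),
                   seed=int(d.get("seed", 0)),
                   population_csv=d.get("population_csv"),
                   life_table_csv=d.get("life_table_csv"),
                   strategies=strategies,
                   output_dir=d.get("output_dir"))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def population(self) -> tuple[PopulationPyramid, LifeTable]:
        if self.population_csv is not None:
            return (PopulationPyramid.from_csv(self.population_csv),
                    LifeTable.from_csv(self.life_table_csv))
        return make_population(SyntheticConfig(n_individuals=self.n_individuals))

    def run(self) -> pd.DataFrame:
        """Simulate the cohort, run every strategy vs baseline, write outputs."""
        pyramid, life = self.population()
        cohort = simulate_cohort(self.n_individuals, pyramid, life,
                                 seed=self.seed)
        strategies = self.strategies or strategy_grid()
        table = run_grid(cohort, strategies, seed=self.seed)
        if self.output_dir is not None:
            out = Path(self.output_dir)
            out.mkdir(parents=True, exist_ok=True)
            table.to_csv(out / "strategy_comparison.csv", index=False)
            (out / "run_manifest.json").write_text(
                json.dumps(self.manifest(), indent=2) + "\n")
        return table

    def manifest(self) -> dict:
        from . import __version__
        import emcee
        import numpy
        import pandas
        payload = json.dumps(
            {"n": self.n_individuals, "horizon": self.horizon_years,
             "seed": self.seed,
             "strategies": sorted(s.name for s in self.strategies)},
            sort_keys=True)
        return {
            "prostasim": __version__,
            "numpy": numpy.__version__,
            "pandas": pandas.__version__,
            "emcee": emcee.__version__,
            "seed": self.seed,
            "parameter_hash": hashlib.sha256(payload.encode()).hexdigest()[:16],
        }
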