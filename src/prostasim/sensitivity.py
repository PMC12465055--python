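"""One-way and probabilistic sensitivity analyses and CEAC curves.

A :class:`ScenarioEvaluator` re-runs the paired strategy/baseline
simulation under parameter overrides with common random numbers (the same
cohort seed for every call), so differences between iterations reflect the
parameter draws rather than Monte-Carlo noise.  One-way analysis evaluates
each parameter at its published bounds with everything else at baseline;
probabilistic analysis draws all parameters simultaneously (uniform on the
published range by default) for a fixed number of iterations, from which
cost-effectiveness acceptability curves are the fraction of iterations with
non-negative net monetary benefit at each willingness-to-pay value.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd

from .economics import nmb
from .engine import run_scenario, simulate_cohort
from .markov import PUBLISHED_TRANSITIONS, MarkovState, TransitionMatrix
from .parameters import (PARAMETER_RANGES, CostTable, EconParams,
                         NaturalHistoryParams, PsaGrowthParams,
                         TestCharacteristics, UtilityTable)
from .population import LifeTable, PopulationPyramid
from .screening import ScreeningStrategy


@dataclass(frozen=True)
class ParamSpec:
    name: str
    baseline: float
    low: float
    high: float
    distribution: str = "uniform"   # uniform / degenerate / beta / gamma

    def __post_init__(self) -> None:
        if not self.low <= self.baseline <= self.high:
            raise ValueError(f"{self.name}: require low <= baseline <= high")

    def sample(self, rng: np.random.Generator, max_tries: int = 100) -> float:
        if self.distribution == "degenerate" or self.high == self.low:
            return self.baseline
        if self.distribution == "uniform":
            return float(rng.uniform(self.low, self.high))
        if self.distribution == "beta":
            return float(self.low + (self.high - self.low) * rng.beta(2.0, 2.0))
        if self.distribution == "gamma":
            mean = self.baseline
            sd = (self.high - self.low) / 4.0
            shape = (mean / sd) ** 2
            scale = sd ** 2 / mean
            for _ in range(max_tries):
                v = float(rng.gamma(shape, scale))
                if self.low <= v <= self.high:
                    return v
            return self.baseline   # redraw cap reached
        raise ValueError(f"unknown distribution {self.distribution!r}")


def default_param_specs(names: list[str] | None = None) -> list[ParamSpec]:
    """ParamSpecs for the published ranges (all of them, or a subset)."""
    items = PARAMETER_RANGES.items()
    if names is not None:
        items = [(k, PARAMETER_RANGES[k]) for k in names]
    baselines = {}
    baselines.update({k: getattr(NaturalHistoryParams(), k)
                      for k in ("gamma_o", "gamma_m", "gamma_c", "gamma_lr", "theta_c")})
    baselines.update({k: getattr(PsaGrowthParams(), k) for k in ("a0", "a1", "a2", "b")})
    baselines.update({k: getattr(TestCharacteristics(), k)
                      for k in ("mri_sens", "mri_spec", "biopsy_sens", "biopsy_spec")})
    ct, ut = CostTable(), UtilityTable()
    for k in PARAMETER_RANGES:
        if k.startswith("cost_"):
            baselines[k] = getattr(ct, k[5:])
        elif k.startswith("utility_"):
            baselines[k] = getattr(ut, k[8:])
    return [ParamSpec(k, baselines[k], lo, hi) for k, (lo, hi) in items]


def _build_tables(overrides: dict):
    """Materialise parameter tables from a flat override mapping."""
    nh_kw, psa_kw, test_kw, cost_kw, util_kw = {}, {}, {}, {}, {}
    transitions = dict(PUBLISHED_TRANSITIONS)
    for key, val in overrides.items():
        if key in ("gamma_o", "gamma_m", "gamma_c", "gamma_lr", "theta_c"):
            nh_kw[key] = val
        elif key in ("a0", "a1", "a2", "b", "sigma_eps"):
            psa_kw[key] = val
        elif key in ("mri_sens", "mri_spec", "biopsy_sens", "biopsy_spec"):
            test_kw[key] = val
        elif key.startswith("cost_"):
            cost_kw[key[5:]] = val
        elif key.startswith("utility_"):
            util_kw[key[8:]] = val
        elif key.startswith("tp_"):
            src_name, dst_name = key[3:].rsplit("_to_", 1)
            transitions[(MarkovState[src_name], MarkovState[dst_name])] = val
        else:
            raise KeyError(f"unknown parameter {key!r}")
    return (NaturalHistoryParams(**nh_kw), PsaGrowthParams(**psa_kw),
            TestCharacteristics(**test_kw), CostTable(**cost_kw),
            UtilityTable(**util_kw), TransitionMatrix(transitions))


class ScenarioEvaluator:
    """Paired strategy-vs-baseline (dC, dQ) under parameter overrides."""

    def __init__(self, pyramid: PopulationPyramid, life_table: LifeTable,
                 strategies: list[ScreeningStrategy], n: int = 20000,
                 seed: int = 0, econ: EconParams = EconParams()):
        self.pyramid = pyramid
        self.life_table = life_table
        self.strategies = strategies
        self.n = n
        self.seed = seed
        self.econ = econ

    def __call__(self, overrides: dict | None = None) -> dict[str, tuple[float, float]]:
        nh, psa, tests, costs, utils, matrix = _build_tables(overrides or {})
        cohort = simulate_cohort(self.n, self.pyramid, self.life_table,
                                 nh=nh, psa=psa, seed=self.seed)
        kw = dict(tests=tests, matrix=matrix, costs=costs, utilities=utils,
                  econ=self.econ, seed=self.seed)
        base = run_scenario(cohort, ScreeningStrategy.no_screening(), **kw)
        out = {}
        for strat in self.strategies:
            res = run_scenario(cohort, strat, **kw)
            out[strat.name] = (res.cost_per_capita - base.cost_per_capita,
                               res.qalys_per_capita - base.qalys_per_capita)
        return out


def one_way(specs: list[ParamSpec], evaluate: Callable[[dict], dict],
            strategy_name: str) -> pd.DataFrame:
    """Two ICERs per parameter (low/high bound), tornado-ordered by spread."""
    rows = []
    for spec in specs:
        pair = {}
        for bound, value in (("low", spec.low), ("high", spec.high)):
            try:
                d_cost, d_qalys = evaluate({spec.name: value})[strategy_name]
                ratio = d_cost / d_qalys if d_qalys != 0 else np.nan
                rows.append({"param": spec.name, "bound": bound, "value": value,
                             "d_cost": d_cost, "d_qalys": d_qalys, "icer": ratio})
                pair[bound] = ratio
            except Exception as exc:   # noqa: BLE001 - per-row error record
                rows.append({"param": spec.name, "bound": bound, "value": value,
                             "d_cost": np.nan, "d_qalys": np.nan,
                             "icer": np.nan, "error": str(exc)})
    df = pd.DataFrame(rows)
    spread = df.groupby("param")["icer"].agg(lambda s: s.max() - s.min())
    df["spread"] = df["param"].map(spread)
    return df.sort_values(["spread", "param", "bound"], ascending=[False, True, True],
                          ignore_index=True)


@dataclass
class PSAResultSet:
    """Probabilistic-sensitivity draws: per-iteration (dC, dQ) per strategy."""

    results: pd.DataFrame       # iteration, strategy, d_cost, d_qalys
    draws: pd.DataFrame         # iteration x parameter values
    seed: int

    @property
    def n_iterations(self) -> int:
        return int(self.results["iteration"].nunique())


def probabilistic(specs: list[ParamSpec], evaluate: Callable[[dict], dict],
                  n_iterations: int = 1000, seed: int = 0) -> PSAResultSet:
    """Vary all parameters simultaneously; common draws across strategies."""
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    rng = np.random.default_rng(seed)
    rows, draw_rows = [], []
    for it in range(n_iterations):
        overrides = {s.name: s.sample(rng) for s in specs}
        draw_rows.append({"iteration": it, **overrides})
        for name, (d_cost, d_qalys) in evaluate(overrides).items():
            rows.append({"iteration": it, "strategy": name,
                         "d_cost": d_cost, "d_qalys": d_qalys})
    return PSAResultSet(pd.DataFrame(rows), pd.DataFrame(draw_rows), seed)


def ceac(psa: PSAResultSet, wtp_grid: np.ndarray | None = None) -> pd.DataFrame:
    """P(cost-effective | WTP) per strategy over the WTP grid."""
    if psa.results.empty:
        raise ValueError("empty probabilistic result set")
    grid = np.linspace(0.0, 20000.0, 201) if wtp_grid is None else np.asarray(wtp_grid)
    out = {"wtp": grid}
    for name, sub in psa.results.groupby("strategy"):
        dc = sub["d_cost"].to_numpy()
        dq = sub["d_qalys"].to_numpy()
        out[name] = [(nmb(dc, dq, w) >= 0).mean() for w in grid]
    return pd.DataFrame(out)
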