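"""Costs, utilities, discounting and incremental cost-effectiveness measures.

Costs and QALYs are accumulated monthly and discounted at 3% per year from
simulation start (cohort clock, not each man's diagnosis).  The incremental
cost-effectiveness ratio compares a screening strategy with the
no-screening status quo; the net monetary benefit at a willingness-to-pay
threshold w is ``w * dQ - dC``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .markov import MarkovState
from .parameters import CostTable, EconParams, UtilityTable


def discount_factor(month_index, annual_rate: float):
    """(1 + r)^(-m/12) for month index m >= 0."""
    if annual_rate < 0:
        raise ValueError("discount rate must be non-negative")
    m = np.asarray(month_index, float)
    out = (1.0 + annual_rate) ** (-m / 12.0)
    return out if out.ndim else float(out)


def state_monthly_cost(costs: CostTable) -> np.ndarray:
    """Monthly cost by Markov state index.

    RP/RT states carry post-treatment ADT plus monitoring; BCR states carry
    BCR ADT plus monitoring; the advanced states carry their named
    treatment costs; Death costs nothing.
    """
    c = np.zeros(len(MarkovState))
    c[MarkovState.RP] = c[MarkovState.RT] = costs.post_trt_adt + costs.monitoring
    c[MarkovState.BCR_RP] = c[MarkovState.BCR_RT] = costs.bcr_adt + costs.monitoring
    c[MarkovState.MHSPC] = costs.mhspc
    c[MarkovState.NMCRPC] = costs.nmcrpc
    c[MarkovState.MCRPC] = costs.mcrpc
    return c


def state_entry_cost(costs: CostTable) -> np.ndarray:
    """One-time cost charged on entering the Markov model, by entry state."""
    c = np.zeros(len(MarkovState))
    c[MarkovState.RP] = costs.rp
    c[MarkovState.RT] = costs.rt
    return c


def state_utility(utilities: UtilityTable) -> np.ndarray:
    u = np.zeros(len(MarkovState))
    u[MarkovState.RP] = utilities.rp
    u[MarkovState.RT] = utilities.rt
    u[MarkovState.BCR_RP] = utilities.bcr_rp
    u[MarkovState.BCR_RT] = utilities.bcr_rt
    u[MarkovState.MHSPC] = utilities.mhspc
    u[MarkovState.NMCRPC] = utilities.nmcrpc
    u[MarkovState.MCRPC] = utilities.mcrpc
    u[MarkovState.DEATH] = utilities.death
    return u


def accumulate(state_by_month: np.ndarray,
               event_costs: list[tuple[int, float]] | None = None,
               costs: CostTable = CostTable(),
               utilities: UtilityTable = UtilityTable(),
               econ: EconParams = EconParams()) -> tuple[float, float]:
    """Discounted (cost, QALYs) of one trajectory.

    ``state_by_month[m]`` is the Markov state index occupied during month m,
    with -1 meaning alive-undiagnosed (utility 1, no state cost) and Death
    contributing nothing.  ``event_costs`` is a list of (month, USD) one-time
    charges (tests, surgery, genetic tests).
    """
    states = np.asarray(state_by_month, int)
    if states.size > econ.horizon_years * 12:
        raise ValueError("trajectory exceeds the model horizon")
    if (states > int(MarkovState.DEATH)).any() or (states < -1).any():
        raise ValueError("unknown state in trajectory")
    months = np.arange(states.size)
    disc_c = discount_factor(months, econ.annual_discount)
    disc_q = discount_factor(months, econ.qaly_discount)
    u = np.where(states < 0, utilities.healthy, state_utility(utilities)[states])
    c = np.where(states < 0, 0.0, state_monthly_cost(costs)[states])
    qalys = float(np.sum(u * disc_q) / 12.0)
    total_cost = float(np.sum(c * disc_c))
    for month, usd in event_costs or []:
        total_cost += usd * discount_factor(month, econ.annual_discount)
    return total_cost, qalys


@dataclass(frozen=True)
class CEAResult:
    """Per-capita cost-effectiveness of one strategy against the baseline."""

    strategy: str
    cost: float                 # discounted USD per capita
    qalys: float                # discounted QALYs per capita
    d_cost: float = 0.0
    d_qalys: float = 0.0
    icer: Optional[float] = None   # USD per QALY; None when d_qalys == 0
    dominant: bool = False         # cheaper and more effective than baseline


def icer(strategy_name: str, cost: float, qalys: float,
         baseline_cost: float, baseline_qalys: float) -> CEAResult:
    """Incremental cost-effectiveness of a strategy against the baseline."""
    d_cost = cost - baseline_cost
    d_qalys = qalys - baseline_qalys
    ratio = d_cost / d_qalys if d_qalys != 0.0 else None
    return CEAResult(strategy_name, cost, qalys, d_cost, d_qalys, ratio,
                     dominant=(d_cost < 0 and d_qalys > 0))


def nmb(d_cost: float, d_qalys: float, wtp: float) -> float:
    """Net monetary benefit; >= 0 means cost-effective at the threshold."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be non-negative")
    return wtp * d_qalys - d_cost
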