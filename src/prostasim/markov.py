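"""Eight-state monthly Markov model of post-diagnosis prognosis.

States: RP and RT (initial curative treatment), BCR_RP and BCR_RT
(biochemical recurrence after each), mHSPC, nmCRPC, mCRPC, and absorbing
Death.  Only the published source→target transitions carry probability; the
stay probability is the complement of each row sum.  Death transitions were
estimated from complete follow-up of a diagnosed cohort and are treated as
all-cause mortality for diagnosed men, so the general life table is not
applied on top of the Markov states.
"""

from __future__ import annotations

from enum import IntEnum

import numpy as np
import pandas as pd


class MarkovState(IntEnum):
    RP = 0
    RT = 1
    BCR_RP = 2
    BCR_RT = 3
    MHSPC = 4
    NMCRPC = 5
    MCRPC = 6
    DEATH = 7


N_STATES = len(MarkovState)

#: Published monthly transition probabilities (source, target) -> p.
PUBLISHED_TRANSITIONS = {
    (MarkovState.RP, MarkovState.BCR_RP): 0.011431,
    (MarkovState.RP, MarkovState.MHSPC): 0.002305,
    (MarkovState.RP, MarkovState.DEATH): 0.000434,
    (MarkovState.RT, MarkovState.BCR_RT): 0.037776,
    (MarkovState.RT, MarkovState.MHSPC): 0.008584,
    (MarkovState.RT, MarkovState.DEATH): 0.070772,
    (MarkovState.BCR_RP, MarkovState.NMCRPC): 0.000045,
    (MarkovState.BCR_RP, MarkovState.MHSPC): 0.001437,
    (MarkovState.BCR_RP, MarkovState.DEATH): 0.000761,
    (MarkovState.BCR_RT, MarkovState.NMCRPC): 0.000904,
    (MarkovState.BCR_RT, MarkovState.MHSPC): 0.005351,
    (MarkovState.BCR_RT, MarkovState.DEATH): 0.053892,
    (MarkovState.MHSPC, MarkovState.MCRPC): 0.000657,
    (MarkovState.MHSPC, MarkovState.DEATH): 0.018824,
    (MarkovState.NMCRPC, MarkovState.MCRPC): 0.001153,
    (MarkovState.NMCRPC, MarkovState.DEATH): 0.040735,
    (MarkovState.MCRPC, MarkovState.DEATH): 0.045317,
}

#: States counted as metastatic disease (used for restricted death attribution).
METASTATIC_STATES = (MarkovState.MHSPC, MarkovState.NMCRPC, MarkovState.MCRPC)


class TransitionMatrix:
    """Monthly transition matrix with implicit stay probabilities."""

    def __init__(self, transitions: dict | None = None):
        transitions = PUBLISHED_TRANSITIONS if transitions is None else transitions
        P = np.zeros((N_STATES, N_STATES))
        for (src, dst), p in transitions.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"transition {src}->{dst} probability {p} outside [0,1]")
            P[int(src), int(dst)] = p
        row_exit = P.sum(axis=1)
        if (row_exit > 1.0 + 1e-12).any():
            bad = int(np.argmax(row_exit))
            raise ValueError(f"row {MarkovState(bad).name} sums to {row_exit[bad]:.6f} > 1")
        P[np.arange(N_STATES), np.arange(N_STATES)] += 1.0 - row_exit
        P[int(MarkovState.DEATH)] = 0.0
        P[int(MarkovState.DEATH), int(MarkovState.DEATH)] = 1.0
        self.P = P
        self._cum = np.cumsum(P, axis=1)

    def stay_probability(self, state: MarkovState) -> float:
        return float(self.P[int(state), int(state)])

    def step(self, states: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Advance an array of states by one month (Death is absorbing)."""
        states = np.asarray(states, int)
        u = rng.random(states.shape)
        return (u[..., None] >= self._cum[states]).sum(axis=-1)

    def as_frame(self) -> pd.DataFrame:
        names = [s.name for s in MarkovState]
        return pd.DataFrame(self.P, index=names, columns=names)


def step(state, matrix: TransitionMatrix, rng: np.random.Generator):
    """Single-state convenience wrapper around :meth:`TransitionMatrix.step`."""
    return MarkovState(int(matrix.step(np.asarray(int(state)), rng)))


def init_state(stage_at_diagnosis: str, rng: np.random.Generator,
               localized_rp_share: float = 0.90) -> MarkovState:
    """Entry state: metastatic cases start systemic therapy (mHSPC);
    localized cases receive RP with the given share, otherwise RT."""
    if stage_at_diagnosis == "metastatic":
        return MarkovState.MHSPC
    if stage_at_diagnosis != "localized":
        raise ValueError(f"unknown stage {stage_at_diagnosis!r}")
    return MarkovState.RP if rng.random() < localized_rp_share else MarkovState.RT


def init_states(stage_metastatic: np.ndarray, rng: np.random.Generator,
                localized_rp_share: float = 0.90) -> np.ndarray:
    """Vectorized entry states for an array of diagnoses."""
    stage_metastatic = np.asarray(stage_metastatic, bool)
    states = np.where(rng.random(stage_metastatic.shape) < localized_rp_share,
                      int(MarkovState.RP), int(MarkovState.RT))
    states[stage_metastatic] = int(MarkovState.MHSPC)
    return states


def enter_monthly_cohort(yearly_diagnosed: float) -> np.ndarray:
    """Split one year's diagnosed cohort evenly over 12 monthly entry cycles."""
    if yearly_diagnosed < 0:
        raise ValueError("diagnosed count must be non-negative")
    return np.full(12, yearly_diagnosed / 12.0)


def sample_entry_months(n: int, rng: np.random.Generator) -> np.ndarray:
    """Microsimulation counterpart: uniform entry month 0..11 per man."""
    return rng.integers(0, 12, size=n)


def cohort_solve(entry_distribution: np.ndarray, matrix: TransitionMatrix,
                 n_months: int) -> np.ndarray:
    """Deterministic expected state occupancy over time.

    ``entry_distribution`` is either a length-8 initial occupancy vector or
    an (n_months, 8) array of per-month entering mass.  Returns an
    (n_months + 1, 8) occupancy matrix; row sums equal the mass entered so
    far (probability conservation).
    """
    entry = np.asarray(entry_distribution, float)
    occ = np.zeros((n_months + 1, N_STATES))
    if entry.ndim == 1:
        occ[0] = entry
        inflow = np.zeros((n_months, N_STATES))
    else:
        inflow = np.zeros((n_months, N_STATES))
        inflow[: entry.shape[0]] = entry
    for m in range(n_months):
        occ[m + 1] = occ[m] @ matrix.P + inflow[m]
    return occ
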