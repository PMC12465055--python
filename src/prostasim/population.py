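"""Male population pyramid and life-table projection.

The incidence model runs on a closed cohort of men aged 40 and older: each
year every age bin is thinned by the age-specific probability of all-cause
death and shifted up one year of age.  No births or migration enter the
cohort (new 40-year-olds could not reach the screening ages within the
modelled horizon).  The top bin (100+) is absorbing, with its annual death
probability still applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

MIN_AGE = 40
MAX_AGE = 100  # open-ended top bin


@dataclass(frozen=True)
class PopulationPyramid:
    """Counts of men by single year of age (MIN_AGE .. MAX_AGE+)."""

    reference_year: int
    counts: pd.Series  # index: age, values: number of men

    def __post_init__(self) -> None:
        c = self.counts
        if (c.values < 0).any():
            raise ValueError("pyramid counts must be non-negative")
        ages = c.index.to_numpy()
        expected = np.arange(ages.min(), ages.max() + 1)
        if ages.min() != MIN_AGE or not np.array_equal(ages, expected):
            raise ValueError(f"ages must be contiguous from {MIN_AGE}")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def mean_age(self) -> float:
        return float(np.average(self.counts.index, weights=self.counts.values))

    def fraction_over(self, age: int) -> float:
        """Share of the cohort strictly older than ``age``."""
        return float(self.counts[self.counts.index > age].sum() / self.total)

    @classmethod
    def from_csv(cls, path: str | Path, reference_year: int = 0) -> "PopulationPyramid":
        df = pd.read_csv(path)
        s = pd.Series(df["count"].to_numpy(float), index=df["age"].to_numpy(int))
        return cls(reference_year, s.sort_index())

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"age": self.counts.index, "count": self.counts.values}
                     ).to_csv(path, index=False)


@dataclass(frozen=True)
class LifeTable:
    """Annual all-cause death probabilities qx by single year of age."""

    qx: pd.Series  # index: age, values: annual probability of death

    def __post_init__(self) -> None:
        v = self.qx.values
        if ((v < 0) | (v > 1)).any():
            raise ValueError("qx values must lie in [0, 1]")

    def q(self, age: int) -> float:
        try:
            return float(self.qx.loc[age])
        except KeyError:
            raise KeyError(f"life table has no qx for age {age}") from None

    def qx_array(self, min_age: int = MIN_AGE, max_age: int = MAX_AGE) -> np.ndarray:
        """qx as a dense array over [min_age, max_age]; missing ages error."""
        ages = np.arange(min_age, max_age + 1)
        missing = [a for a in ages if a not in self.qx.index]
        if missing:
            raise KeyError(f"life table missing ages {missing[:5]}...")
        return self.qx.loc[ages].to_numpy(float)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        df = pd.read_csv(path)
        s = pd.Series(df["qx"].to_numpy(float), index=df["age"].to_numpy(int))
        return cls(s.sort_index())

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"age": self.qx.index, "qx": self.qx.values}
                     ).to_csv(path, index=False)

    def sample_death_ages(self, entry_ages: np.ndarray, rng: np.random.Generator,
                          max_age: int = 110) -> np.ndarray:
        """Draw a continuous age at other-cause death for each man.

        Conditional on being alive at the (integer) entry age; survival each
        year is Bernoulli(1 - qx), ages past the table's top reuse the top
        qx, and death is forced by ``max_age``.  Death time is uniform within
        the death year.
        """
        entry_ages = np.asarray(entry_ages, int)
        top = int(self.qx.index.max())
        ages = np.arange(MIN_AGE, max_age + 1)
        q = np.array([self.q(min(a, top)) for a in ages])
        q[-1] = 1.0
        # cumulative log-survival from MIN_AGE
        logp = np.concatenate([[0.0], np.cumsum(np.log1p(-np.minimum(q, 1 - 1e-12)))])
        start = np.clip(entry_ages, MIN_AGE, max_age) - MIN_AGE
        u = rng.random(entry_ages.shape)
        # alive at entry: target log-survival below the entry value
        target = logp[start] + np.log(u)
        death_idx = np.searchsorted(-logp, -target, side="left") - 1
        death_idx = np.clip(death_idx, start, len(ages) - 1)
        return MIN_AGE + death_idx + rng.random(entry_ages.shape)


def project_population(pyramid: PopulationPyramid, life_table: LifeTable,
                       n_years: int) -> list[PopulationPyramid]:
    """Deterministic (expected-value) projection of the closed male cohort.

    Returns ``n_years + 1`` pyramids; each step multiplies every age-a count
    by ``1 - qx(a)`` and shifts it to age ``a + 1``, with the top bin
    absorbing.  Total mass is non-increasing (strictly decreasing whenever
    any populated age has qx > 0).
    """
    if n_years < 0:
        raise ValueError("n_years must be >= 0")
    ages = pyramid.counts.index.to_numpy()
    for a in ages:
        if pyramid.counts.loc[a] > 0 and a not in life_table.qx.index:
            raise KeyError(f"life table has no qx for populated age {a}")
    q = np.array([life_table.q(a) if a in life_table.qx.index else 0.0 for a in ages])
    out = [pyramid]
    counts = pyramid.counts.to_numpy(float)
    for year in range(n_years):
        survivors = counts * (1.0 - q)
        nxt = np.zeros_like(counts)
        nxt[1:] = survivors[:-1]
        nxt[-1] += survivors[-1]   # absorbing top bin
        counts = nxt
        out.append(PopulationPyramid(pyramid.reference_year + year + 1,
                                     pd.Series(counts.copy(), index=ages)))
    return out
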