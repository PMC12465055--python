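"""Synthetic inputs with known ground truth.

Everything the pipeline consumes can be generated here: a census-shaped
male population pyramid (ages 40-100 with the mid-age bulge of the 2020
Chinese census and mass shifting above 60 as it is projected forward), a
Gompertz male life table, longitudinal screening-trial PSA tables drawn
from the exact natural-history model with latent onset/grade labels kept
alongside, and reference age-specific incidence curves produced by the
simulator itself at planted hazard multipliers (the recoverable target of
the calibration grid search).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import natural_history as nhm
from .calibration import DEFAULT_BANDS, IncidenceCurve, incidence_curve
from .parameters import NaturalHistoryParams, PsaGrowthParams
from .population import MAX_AGE, MIN_AGE, LifeTable, PopulationPyramid

#: Approximate 2020 male census counts (millions) by 5-year band from age 40
#: (seventh national census, male population).
_CENSUS_BANDS = {40: 47.3, 45: 57.9, 50: 60.9, 55: 49.4, 60: 36.7, 65: 33.1,
                 70: 24.1, 75: 14.1, 80: 8.2, 85: 3.7, 90: 1.1, 95: 0.2}


@dataclass(frozen=True)
class SyntheticConfig:
    n_individuals: int = 100_000
    reference_year: int = 2020
    # Gompertz all-cause mortality qx = A * exp(B * age), fitted to the
    # Chinese male 2020 life table (q40 ~ 0.002, q60 ~ 0.013, q85 ~ 0.13)
    gompertz_a: float = 4.85e-5
    gompertz_b: float = 0.093
    nh: NaturalHistoryParams = field(default_factory=NaturalHistoryParams)
    psa: PsaGrowthParams = field(default_factory=PsaGrowthParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")


def make_population(config: SyntheticConfig = SyntheticConfig()
                    ) -> tuple[PopulationPyramid, LifeTable]:
    """Census-shaped pyramid (total = n_individuals) and Gompertz life table."""
    ages = np.arange(MIN_AGE, MAX_AGE + 1)
    density = np.array([_CENSUS_BANDS[min(5 * (a // 5), 95)] / 5.0 for a in ages])
    counts = density / density.sum() * config.n_individuals
    pyramid = PopulationPyramid(config.reference_year,
                                pd.Series(counts, index=ages))
    qx = np.minimum(1.0, config.gompertz_a * np.exp(config.gompertz_b * ages))
    life = LifeTable(pd.Series(qx, index=ages))
    return pyramid, life


def make_screening_trial(config: SyntheticConfig, n_subjects: int = 2000,
                         visits_per_subject: int = 5,
                         entry_age_range: tuple[int, int] = (45, 70)
                         ) -> pd.DataFrame:
    """Longitudinal PSA observation table with latent ground truth.

    Subjects enter at a uniform age and attend annual visits; each row is
    one (id, age, psa) observation, with the true ``onset_age`` and
    ``grade`` stored alongside for parameter-recovery tests (NaN for
    subjects without onset by the visit in question).
    """
    rng = np.random.default_rng(config.seed)
    nh, psa = config.nh, config.psa
    entry = rng.integers(entry_age_range[0], entry_age_range[1] + 1, n_subjects)
    onset = nhm.sample_onset_age(nh, rng=rng, size=n_subjects, max_age=150.0)
    grade = nhm.assign_grade(nh.gamma_lr, rng, size=n_subjects)

    rows = []
    for visit in range(visits_per_subject):
        age = entry + visit
        has = onset <= age
        ax = np.where(grade == nhm.HIGH_RISK, psa.a2, psa.a1)
        mean = psa.b + psa.a0 * age + np.where(has, ax * (age - np.where(has, onset, age)), 0.0)
        eps = rng.normal(0.0, psa.sigma_eps, n_subjects)
        rows.append(pd.DataFrame({
            "id": np.arange(n_subjects),
            "age": age.astype(float),
            "psa": np.exp(mean + eps),
            "onset_age": np.where(has, onset, np.nan),
            "grade": np.where(has, grade, None),
        }))
    return pd.concat(rows, ignore_index=True).sort_values(
        ["id", "age"], ignore_index=True)


def make_reference_incidence(config: SyntheticConfig,
                             planted_multipliers: tuple[float, float] = (1.0, 1.0),
                             n: int = 20000, seed: int | None = None,
                             bands: tuple = DEFAULT_BANDS) -> IncidenceCurve:
    """Reference incidence curve produced at planted hazard multipliers.

    Running the simulator at ``gamma_o * m1`` and ``gamma_c * m2`` yields a
    target curve whose generating multipliers the grid search should
    recover.
    """
    m1, m2 = planted_multipliers
    if m1 <= 0 or m2 <= 0:
        raise ValueError("multipliers must be positive")
    pyramid, life = make_population(config)
    return incidence_curve(config.nh.scaled(m1, m2), config.psa, pyramid,
                           life, n=n, seed=config.seed if seed is None else seed,
                           bands=bands)


def write_fixture_set(outdir: str | Path,
                      config: SyntheticConfig = SyntheticConfig()) -> dict:
    """Write a complete CSV fixture set (pyramid, life table, trial table)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pyramid, life = make_population(config)
    trial = make_screening_trial(config)
    paths = {
        "pyramid": outdir / "pyramid.csv",
        "life_table": outdir / "life_table.csv",
        "screening_trial": outdir / "screening_trial.csv",
    }
    pyramid.to_csv(paths["pyramid"])
    life.to_csv(paths["life_table"])
    trial.to_csv(paths["screening_trial"], index=False)
    return paths
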