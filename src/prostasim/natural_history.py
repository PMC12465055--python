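"""Latent natural history of prostate cancer.

Each man's disease process follows the classic PSA-driven microsimulation
form: tumour onset arrives with hazard linear in age,
``lambda_o(t) = gamma_o * t``; Gleason grade (low/high risk) is fixed at
onset; mean log PSA grows linearly with age and gains an extra grade-specific
slope after onset,

    P(t) = b + a0*t + ax*(t - t_onset)   for t > t_onset,

and metastasis and clinical (symptomatic) detection arrive with hazards
proportional to the PSA level, ``exp(P(t)) * gamma_m`` and
``exp(P(t)) * gamma_c``, the latter multiplied by ``theta_c`` once the
tumour has metastasised.

Because ``exp(P(t))`` is a piecewise exponential in age, every cumulative
hazard here has a closed form and event times are drawn by exact inverse
transform — no time grid is involved.  Hazards use the noise-free mean
trajectory; the observation noise ``eps`` enters only the PSA values seen at
screening visits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .parameters import NaturalHistoryParams, PsaGrowthParams

LOW_RISK = "low_risk"
HIGH_RISK = "high_risk"

#: Default age from which onset hazard accrues (model entry age).
ACCRUAL_START_AGE = 40.0


@dataclass
class Individual:
    """One simulated man's latent timeline and diagnosis record."""

    id: int
    entry_age: float
    grade: Optional[str] = None            # LOW_RISK / HIGH_RISK / None
    onset_age: Optional[float] = None
    metastasis_age: Optional[float] = None
    clinical_detection_age: Optional[float] = None
    other_cause_death_age: float = np.inf
    diagnosed: bool = False
    diagnosis_age: Optional[float] = None
    stage_at_diagnosis: Optional[str] = None   # "localized" / "metastatic"
    risk_group: str = "average"
    rng_stream: int = 0

    def validate(self) -> None:
        on, met, det = self.onset_age, self.metastasis_age, self.clinical_detection_age
        if on is not None and met is not None and met < on:
            raise ValueError("metastasis before onset")
        if met is not None and det is not None and det < met and self.grade is not None:
            pass  # detection may precede metastasis; ordering constraint is on <= each
        if on is None and (met is not None or det is not None):
            raise ValueError("progression events require an onset")


def _extra_slope(grade, psa: PsaGrowthParams):
    """ax by grade; accepts scalars or arrays of {LOW_RISK, HIGH_RISK}."""
    if isinstance(grade, str):
        if grade == LOW_RISK:
            return psa.a1
        if grade == HIGH_RISK:
            return psa.a2
        raise ValueError(f"unknown grade {grade!r}")
    grade = np.asarray(grade)
    return np.where(grade == LOW_RISK, psa.a1, psa.a2)


def mean_log_psa(age, onset_age=None, grade=None,
                 psa: PsaGrowthParams = PsaGrowthParams()):
    """Noise-free mean log PSA at ``age`` (log ng/mL).

    Before onset (or with no onset) the healthy line ``b + a0*age``; after
    onset the grade-specific extra slope applies to the years since onset.
    """
    age = np.asarray(age, float)
    base = psa.b + psa.a0 * age
    if onset_age is None:
        return base if base.ndim else float(base)
    if grade is None:
        raise ValueError("grade required when onset_age is present")
    onset_age = np.asarray(onset_age, float)
    ax = _extra_slope(grade, psa)
    out = base + ax * np.clip(age - onset_age, 0.0, None)
    return out if out.ndim else float(out)


def sample_psa(age, onset_age=None, grade=None,
               psa: PsaGrowthParams = PsaGrowthParams(),
               rng: np.random.Generator | None = None):
    """Observed PSA in ng/mL: exp(mean log PSA + eps), eps ~ N(0, sigma_eps^2)."""
    rng = rng or np.random.default_rng()
    mean = mean_log_psa(age, onset_age, grade, psa)
    eps = rng.normal(0.0, psa.sigma_eps, size=np.shape(mean))
    out = np.exp(mean + eps)
    return out if np.ndim(out) else float(out)


# ---------------------------------------------------------------------------
# closed-form cumulative hazards and exact inverse-transform samplers
# ---------------------------------------------------------------------------

def onset_cumulative_hazard(t, gamma_o: float, start: float = ACCRUAL_START_AGE):
    """Lambda_o(t) = gamma_o * (t^2 - start^2) / 2, accrued from ``start``."""
    t = np.asarray(t, float)
    out = gamma_o * (np.clip(t, start, None) ** 2 - start ** 2) / 2.0
    return out if out.ndim else float(out)


def sample_onset_age(params: NaturalHistoryParams,
                     accrual_start_age: float = ACCRUAL_START_AGE,
                     rng: np.random.Generator | None = None,
                     size=None, max_age: float | None = None):
    """Inverse-transform draw of the tumour-onset age.

    Solves ``Lambda_o(t) = E`` with ``E ~ Exp(1)``:
    ``t = sqrt(start^2 + 2 E / gamma_o)``.  Returns ``inf`` (scalar: None)
    when gamma_o is zero or the draw exceeds ``max_age``.
    """
    if params.gamma_o < 0:
        raise ValueError("gamma_o must be non-negative")
    rng = rng or np.random.default_rng()
    e = rng.exponential(size=size)
    if params.gamma_o == 0.0:
        t = np.full(np.shape(e), np.inf)
    else:
        t = np.sqrt(accrual_start_age ** 2 + 2.0 * e / params.gamma_o)
    if max_age is not None:
        t = np.where(t > max_age, np.inf, t)
    if size is None:
        t = float(t)
        return None if np.isinf(t) else t
    return t


def exp_psa_integral(t, onset_age, ax, psa: PsaGrowthParams):
    """I(t) = integral of exp(P(u)) du from onset to t (mean trajectory).

    With k = a0 + ax this is ``exp(b - ax*onset)/k * (e^{k t} - e^{k onset})``.
    """
    t = np.asarray(t, float)
    onset_age = np.asarray(onset_age, float)
    ax = np.asarray(ax, float)
    k = psa.a0 + ax
    tt = np.clip(t, onset_age, None)
    k_safe = np.where(k == 0.0, 1.0, k)
    out = np.where(
        k == 0.0,
        np.exp(psa.b) * (tt - onset_age),   # flat log-PSA regime
        np.exp(psa.b - ax * onset_age) / k_safe
        * (np.exp(k_safe * tt) - np.exp(k_safe * onset_age)))
    return out if out.ndim else float(out)


def exp_psa_integral_inv(target, onset_age, ax, psa: PsaGrowthParams):
    """Inverse of :func:`exp_psa_integral` in its first argument."""
    onset_age = np.asarray(onset_age, float)
    target = np.asarray(target, float)
    ax = np.asarray(ax, float)
    k = psa.a0 + ax
    k_safe = np.where(k == 0.0, 1.0, k)
    arg = np.exp(k_safe * onset_age) + target * k_safe * np.exp(ax * onset_age - psa.b)
    out = np.where(k == 0.0,
                   onset_age + target * np.exp(-psa.b),
                   np.log(arg) / k_safe)
    return out if out.ndim else float(out)


def sample_metastasis_age(onset_age, ax, nh: NaturalHistoryParams,
                          psa: PsaGrowthParams, rng: np.random.Generator,
                          size=None):
    """Draw the metastasis age from hazard exp(P(t)) * gamma_m after onset."""
    e = rng.exponential(size=size if size is not None else np.shape(onset_age) or None)
    if nh.gamma_m == 0.0:
        return np.full(np.shape(e), np.inf) if np.ndim(e) else np.inf
    return exp_psa_integral_inv(e / nh.gamma_m, onset_age, ax, psa)


def detection_cumulative_hazard(t, onset_age, metastasis_age, ax,
                                nh: NaturalHistoryParams, psa: PsaGrowthParams):
    """Cumulative clinical-detection hazard with the post-metastasis boost."""
    t = np.asarray(t, float)
    i_t = exp_psa_integral(t, onset_age, ax, psa)
    i_m = exp_psa_integral(np.minimum(t, metastasis_age), onset_age, ax, psa)
    i_at_m = exp_psa_integral(metastasis_age, onset_age, ax, psa)
    pre = np.minimum(i_t, i_at_m)
    post = np.clip(i_t - i_at_m, 0.0, None)
    out = nh.gamma_c * (pre + nh.theta_c * post)
    return out if out.ndim else float(out)


def sample_detection_age(onset_age, metastasis_age, ax,
                         nh: NaturalHistoryParams, psa: PsaGrowthParams,
                         rng: np.random.Generator, size=None,
                         condition_age=None):
    """Draw the clinical-detection age.

    The hazard is ``exp(P(t)) * gamma_c`` from onset, multiplied by
    ``theta_c`` after metastasis.  If ``condition_age`` is given, the draw is
    conditioned on no detection before that age (used for men whose latent
    onset precedes model entry: they are alive and undiagnosed at entry).
    """
    e = rng.exponential(size=size if size is not None else np.shape(onset_age) or None)
    if condition_age is not None:
        offset = detection_cumulative_hazard(
            np.maximum(np.asarray(condition_age, float), np.asarray(onset_age, float)),
            onset_age, metastasis_age, ax, nh, psa)
        e = e + offset
    if nh.gamma_c == 0.0:
        return np.full(np.shape(e), np.inf) if np.ndim(e) else np.inf
    l1m = exp_psa_integral(metastasis_age, onset_age, ax, psa)
    with np.errstate(invalid="ignore"):   # inf - inf in the discarded branch
        target = np.where(e <= nh.gamma_c * l1m,
                          e / nh.gamma_c,
                          l1m + (e / nh.gamma_c - l1m) / nh.theta_c)
    return exp_psa_integral_inv(target, onset_age, ax, psa)


def assign_grade(gamma_lr: float, rng: np.random.Generator, size=None):
    """Bernoulli grade assignment, P(low risk) = gamma_lr; fixed at onset."""
    if not 0.0 <= gamma_lr <= 1.0:
        raise ValueError("gamma_lr must lie in [0, 1]")
    draw = rng.random(size)
    if size is None:
        return LOW_RISK if draw < gamma_lr else HIGH_RISK
    return np.where(draw < gamma_lr, LOW_RISK, HIGH_RISK)


def sample_progression(individual: Individual, nh: NaturalHistoryParams,
                       psa: PsaGrowthParams, rng: np.random.Generator,
                       horizon_age: float = np.inf):
    """Draw (metastasis_age, clinical_detection_age) for one man with onset.

    Both events are censored at the man's other-cause death age and at
    ``horizon_age``; ties between metastasis and detection resolve in favour
    of metastasis (detection at an equal instant is staged metastatic).
    """
    if individual.onset_age is None:
        raise ValueError("sample_progression requires an onset age")
    if individual.grade is None:
        raise ValueError("individual with onset must carry a grade")
    ax = _extra_slope(individual.grade, psa)
    tm = sample_metastasis_age(individual.onset_age, ax, nh, psa, rng)
    td = sample_detection_age(individual.onset_age, tm, ax, nh, psa, rng)
    censor = min(individual.other_cause_death_age, horizon_age)
    met = tm if tm < censor else None
    det = td if td < censor else None
    individual.metastasis_age = met
    individual.clinical_detection_age = det
    return met, det
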