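"""Scenario engine: ties population, natural history, screening, prognosis
and economics into the full screening experiment.

The simulation runs a closed cohort of men aged 40+ over a 30-year horizon.
Latent disease timelines (onset, grade, metastasis, clinical detection,
other-cause death) are drawn once per cohort and shared by every strategy
(common random numbers); per-visit screening randomness (PSA noise, MRI and
biopsy outcomes) is pre-drawn per man and calendar age so that strategies
differ only through which visits they schedule.  The incidence model runs
on a yearly cycle; each year's newly diagnosed men enter the monthly
eight-state Markov prognosis model spread uniformly over that year's 12
monthly cycles.

Men whose latent onset precedes model entry are carried as undiagnosed
prevalent cases: their clinical-detection time is drawn conditional on not
having been detected before entry.  Undiagnosed men die from the general
life table; diagnosed men die through the Markov model only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from . import natural_history as nh_mod
from .markov import (MarkovState, TransitionMatrix, METASTATIC_STATES,
                     init_states)
from .economics import (discount_factor, state_entry_cost, state_monthly_cost,
                        state_utility)
from .parameters import (CostTable, EconParams, EntryRule,
                         NaturalHistoryParams, PsaGrowthParams,
                         RiskStratification, TestCharacteristics, UtilityTable)
from .population import LifeTable, PopulationPyramid
from .screening import (AGE_SPECIFIC, FIXED_4, ScreeningStrategy,
                        build_schedule, psa_threshold)

SCREEN_AGE_MIN = 45
SCREEN_AGE_MAX = 74
_N_SCREEN_AGES = SCREEN_AGE_MAX - SCREEN_AGE_MIN + 1


@dataclass
class LatentCohort:
    """Shared latent disease realizations for one simulated population."""

    entry_age: np.ndarray          # integer age at model start
    onset_age: np.ndarray          # float, inf = never
    low_risk: np.ndarray           # bool grade flag
    metastasis_age: np.ndarray     # float, inf = never
    clinical_detection_age: np.ndarray  # float, conditioned on > entry age
    death_other_age: np.ndarray    # continuous other-cause death age
    high_risk_group: np.ndarray    # inherited-risk flag
    screen_eps: np.ndarray         # (n, 30) log-PSA noise at ages 45..74
    screen_u_mri: np.ndarray       # (n, 30) uniforms for the MRI result
    screen_u_biopsy: np.ndarray    # (n, 30) uniforms for the biopsy result
    nh: NaturalHistoryParams = NaturalHistoryParams()
    psa: PsaGrowthParams = PsaGrowthParams()

    @property
    def n(self) -> int:
        return self.entry_age.size


def simulate_cohort(n: int, pyramid: PopulationPyramid, life_table: LifeTable,
                    nh: NaturalHistoryParams = NaturalHistoryParams(),
                    psa: PsaGrowthParams = PsaGrowthParams(),
                    risk: RiskStratification = RiskStratification(),
                    seed: int | np.random.Generator = 0,
                    onset_accrual: str = "entry") -> LatentCohort:
    """Draw the shared latent histories for ``n`` men sampled from the pyramid.

    ``onset_accrual`` controls where each man's onset hazard starts
    accruing: ``"entry"`` (every man is tumour-free at model start, the
    default) or ``"model_start"`` (accrual from age 40 for everyone, so
    older men carry prevalent latent disease at baseline, conditioned on
    being undiagnosed at entry).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ages = pyramid.counts.index.to_numpy(int)
    probs = pyramid.counts.to_numpy(float)
    probs = probs / probs.sum()
    entry_age = rng.choice(ages, size=n, p=probs)

    high_group = rng.random(n) < risk.high_risk_fraction
    gamma_o_eff = nh.gamma_o * np.where(high_group, risk.onset_rr, 1.0)

    if onset_accrual == "entry":
        accrual_start = entry_age.astype(float)
    elif onset_accrual == "model_start":
        accrual_start = np.full(n, nh_mod.ACCRUAL_START_AGE)
    else:
        raise ValueError(f"unknown onset_accrual {onset_accrual!r}")
    e_onset = rng.exponential(size=n)
    with np.errstate(divide="ignore"):
        onset = np.sqrt(accrual_start ** 2 + 2.0 * e_onset / gamma_o_eff)
    onset[gamma_o_eff == 0.0] = np.inf
    onset[onset > 150.0] = np.inf   # beyond any survivable age

    low = rng.random(n) < nh.gamma_lr
    ax = np.where(low, psa.a1, psa.a2)

    tm = np.full(n, np.inf)
    td = np.full(n, np.inf)
    has = np.isfinite(onset)
    if has.any():
        e_m = rng.exponential(size=int(has.sum()))
        if nh.gamma_m > 0:
            tm[has] = nh_mod.exp_psa_integral_inv(
                e_m / nh.gamma_m, onset[has], ax[has], psa)
        cond = np.where(onset[has] < entry_age[has],
                        entry_age[has].astype(float), onset[has])
        td[has] = nh_mod.sample_detection_age(
            onset[has], tm[has], ax[has], nh, psa, rng,
            size=int(has.sum()), condition_age=cond)

    death = life_table.sample_death_ages(entry_age, rng)

    eps = (rng.standard_normal((n, _N_SCREEN_AGES)) * psa.sigma_eps).astype(np.float32)
    u_mri = rng.random((n, _N_SCREEN_AGES), dtype=np.float32)
    u_bio = rng.random((n, _N_SCREEN_AGES), dtype=np.float32)

    return LatentCohort(entry_age=entry_age, onset_age=onset, low_risk=low,
                        metastasis_age=tm, clinical_detection_age=td,
                        death_other_age=death, high_risk_group=high_group,
                        screen_eps=eps, screen_u_mri=u_mri,
                        screen_u_biopsy=u_bio, nh=nh, psa=psa)


@dataclass
class ScenarioResult:
    """Per-year tallies and per-capita economics of one strategy run."""

    strategy: str
    n: int
    horizon_years: int
    # yearly traces
    diagnoses_window: np.ndarray       # diagnoses at ages 45-84
    met_diagnoses_window: np.ndarray   # of which metastatic at diagnosis
    person_years_window: np.ndarray    # person-years lived at ages 45-84
    pca_deaths_all: np.ndarray         # deaths in any Markov state
    pca_deaths_met: np.ndarray         # deaths from mHSPC/nmCRPC/mCRPC
    diagnosed_person_years: np.ndarray  # alive diagnosed patients (person-years)
    # totals
    n_diagnosed: int = 0
    n_screen_detected: int = 0
    n_psa_tests: int = 0
    n_mri: int = 0
    n_biopsies: int = 0
    n_treatments: int = 0              # men entering the prognosis model
    total_deaths_window: float = 0.0   # all-cause deaths (any man) in horizon
    # economics (totals, discounted USD / QALYs)
    total_cost: float = 0.0
    total_qalys: float = 0.0

    @property
    def cost_per_capita(self) -> float:
        return self.total_cost / self.n

    @property
    def qalys_per_capita(self) -> float:
        return self.total_qalys / self.n

    def pca_deaths(self, attribution: str = "all") -> np.ndarray:
        if attribution == "all":
            return self.pca_deaths_all
        if attribution == "metastatic":
            return self.pca_deaths_met
        raise ValueError(f"unknown death attribution {attribution!r}")


def _schedule_mask(arm: ScreeningStrategy | None, age: np.ndarray) -> np.ndarray:
    """True where the (vector of) ages falls on the arm's screening schedule."""
    if arm is None or not arm.active:
        return np.zeros(age.shape, bool)
    return ((age >= arm.start_age) & (age <= arm.end_age)
            & ((age - arm.start_age) % arm.interval == 0))


def run_scenario(cohort: LatentCohort, strategy: ScreeningStrategy,
                 tests: TestCharacteristics = TestCharacteristics(),
                 matrix: TransitionMatrix | None = None,
                 entry: EntryRule = EntryRule(),
                 costs: CostTable = CostTable(),
                 utilities: UtilityTable = UtilityTable(),
                 econ: EconParams = EconParams(),
                 risk: RiskStratification = RiskStratification(),
                 seed: int = 0, qaly_scope: str = "diagnosed",
                 markov_horizon: str = "per_entrant",
                 discount_clock: str = "diagnosis",
                 competing_mortality: bool = False,
                 life_table: LifeTable | None = None) -> ScenarioResult:
    """Run one screening strategy (or the no-screening baseline) on a cohort.

    ``qaly_scope`` sets the QALY accounting perspective: ``"diagnosed"``
    accumulates QALYs over the post-diagnosis Markov trajectories only (the
    decision-tree-into-Markov-cohort convention, in which undiagnosed
    life-years are outside the valued horizon), while ``"population"`` also
    values every undiagnosed life-month at the healthy utility.  Costs are
    unaffected (undiagnosed men cost nothing).

    ``markov_horizon`` is ``"per_entrant"`` (each yearly diagnosis cohort
    runs the full 360 monthly prognosis cycles from its own entry,
    emulating life-long effects) or ``"calendar"`` (prognosis censored at
    the simulation's 30-year horizon).  ``discount_clock`` restarts
    discounting at each cohort's Markov entry (``"diagnosis"``) or uses one
    simulation-wide clock (``"calendar"``); screening costs always use the
    calendar clock.  ``competing_mortality`` additionally exposes diagnosed
    men to life-table other-cause death inside the Markov model (off by
    default: the transition probabilities already embed the cohort's
    observed all-cause mortality).
    """
    if qaly_scope not in ("diagnosed", "population"):
        raise ValueError(f"unknown qaly_scope {qaly_scope!r}")
    if markov_horizon not in ("calendar", "per_entrant"):
        raise ValueError(f"unknown markov_horizon {markov_horizon!r}")
    if discount_clock not in ("calendar", "diagnosis"):
        raise ValueError(f"unknown discount_clock {discount_clock!r}")
    if competing_mortality and life_table is None:
        raise ValueError("competing_mortality requires the life table")
    cost_rate = econ.annual_discount
    qaly_rate = econ.qaly_discount
    matrix = matrix or TransitionMatrix()
    rng = np.random.default_rng([seed, 0x5C4EE])
    n = cohort.n
    H = econ.horizon_years
    n_months = 12 * H

    a0 = cohort.entry_age
    onset = cohort.onset_age
    tm = cohort.metastasis_age
    td = cohort.clinical_detection_age
    death = cohort.death_other_age

    diag_year = np.full(n, -1, np.int32)
    stage_met = np.zeros(n, bool)
    screen_det = np.zeros(n, bool)
    entry_offset = np.zeros(n, np.int16)

    diagnoses_w = np.zeros(H)
    met_diagnoses_w = np.zeros(H)
    py_w = np.zeros(H)
    deaths_all = np.zeros(H)
    deaths_met = np.zeros(H)
    diag_py = np.zeros(H)

    n_psa = n_mri = n_bio = 0
    screen_cost = 0.0

    arms: list[tuple[np.ndarray, ScreeningStrategy | None]]
    if strategy.risk_stratified:
        arms = [(cohort.high_risk_group, strategy.high_risk_arm),
                (~cohort.high_risk_group, strategy.average_risk_arm)]
        test_cost = {"prs": costs.prs, "wgs": costs.wgs}[strategy.genetic_test]
        screen_cost += test_cost * n   # one-time genetic test at model start
    else:
        arms = [(np.ones(n, bool), strategy if strategy.active else None)]

    for y in range(H):
        age = a0 + y
        undiag = (diag_year < 0) & (death > age)
        detected_now = np.zeros(n, bool)
        year_disc = discount_factor(12 * y, cost_rate)

        for group_mask, arm in arms:
            if arm is None or not arm.active:
                continue
            vis = undiag & group_mask & _schedule_mask(arm, age)
            if not vis.any():
                continue
            idx = np.flatnonzero(vis)
            a = age[idx]
            col = a - SCREEN_AGE_MIN
            has_ca = onset[idx] <= a
            mean_p = cohort.psa.b + cohort.psa.a0 * a
            ax = np.where(cohort.low_risk[idx], cohort.psa.a1, cohort.psa.a2)
            mean_p = mean_p + np.where(has_ca, ax * (a - np.where(has_ca, onset[idx], a)), 0.0)
            psa_val = np.exp(mean_p + cohort.screen_eps[idx, col])

            thr = psa_threshold(a, arm.cutoff_mode)
            pos = psa_val > thr
            direct = psa_val > tests.direct_biopsy_psa
            mri_done = pos & ~direct
            p_mri = np.where(has_ca, tests.mri_sens, 1.0 - tests.mri_spec)
            mri_pos = mri_done & (cohort.screen_u_mri[idx, col] < p_mri)
            biopsy = direct | mri_pos
            p_det = np.where(has_ca, tests.biopsy_sens, 1.0 - tests.biopsy_spec)
            det = biopsy & (cohort.screen_u_biopsy[idx, col] < p_det)

            n_psa += idx.size
            n_mri += int(mri_done.sum())
            n_bio += int(biopsy.sum())
            screen_cost += year_disc * (idx.size * costs.psa
                                        + mri_done.sum() * costs.mri
                                        + biopsy.sum() * costs.biopsy)
            det_idx = idx[det]
            diag_year[det_idx] = y
            stage_met[det_idx] = tm[det_idx] <= age[det_idx]
            screen_det[det_idx] = True
            detected_now[det_idx] = True

        # clinical (symptomatic) detection during the remainder of the year
        clin = (undiag & ~detected_now & (td >= age) & (td < age + 1)
                & (td < death))
        clin_idx = np.flatnonzero(clin)
        diag_year[clin_idx] = y
        stage_met[clin_idx] = tm[clin_idx] <= td[clin_idx]

        new_idx = np.flatnonzero(diag_year == y)
        entry_offset[new_idx] = rng.integers(0, 12, size=new_idx.size)

        # incidence tallies in the 45-84 window
        new_in_w = new_idx[(age[new_idx] >= 45) & (age[new_idx] <= 84)]
        diagnoses_w[y] = new_in_w.size
        met_diagnoses_w[y] = stage_met[new_in_w].sum()

        # person-years at ages 45-84: undiagnosed men this year
        in_w = (age >= 45) & (age <= 84)
        not_yet = (diag_year < 0) | (diag_year > y)
        frac = np.clip(death - age, 0.0, 1.0)
        py_w[y] = frac[in_w & not_yet].sum()
        # men diagnosed this year contribute their pre-entry months
        py_w[y] += (entry_offset[new_in_w] / 12.0).sum()

    # ---------------- monthly Markov prognosis model -----------------
    diag_idx = np.flatnonzero(diag_year >= 0)
    n_diag = diag_idx.size
    state_u = state_utility(utilities)
    state_c = state_monthly_cost(costs)
    entry_c = state_entry_cost(costs)
    last_month = n_months if markov_horizon == "calendar" else 2 * n_months
    disc_c = discount_factor(np.arange(last_month), cost_rate)
    disc_q = discount_factor(np.arange(last_month), qaly_rate)

    markov_cost = 0.0
    markov_qalys = 0.0
    markov_deaths_window = 0.0
    if competing_mortality:
        mq_ages = np.arange(40, 181)
        top = int(life_table.qx.index.max())
        mq = 1.0 - (1.0 - np.array([life_table.q(min(a, top)) for a in mq_ages])) ** (1 / 12)
    if n_diag:
        entry_month = 12 * diag_year[diag_idx] + entry_offset[diag_idx]
        states = init_states(stage_met[diag_idx], rng, entry.localized_rp_share)
        if discount_clock == "calendar":
            markov_cost += float((entry_c[states] * disc_c[entry_month]).sum())
        else:
            markov_cost += float(entry_c[states].sum())
        d_age0 = a0[diag_idx]
        met_set = np.array([int(s) for s in METASTATIC_STATES])
        alive = np.ones(n_diag, bool)
        order = np.argsort(entry_month)
        em_sorted = entry_month[order]
        for m in range(int(em_sorted[0]), last_month):
            first = np.searchsorted(em_sorted, m, side="right")
            act_pool = order[:first]
            act = act_pool[alive[act_pool]]
            if markov_horizon == "per_entrant":
                # each entrant is followed for the full 360 monthly cycles
                act = act[entry_month[act] + n_months > m]
            if act.size == 0:
                if (em_sorted > m).any():
                    continue
                break
            y = m // 12
            if competing_mortality:
                # other-cause death competes with the disease process
                age_now = np.minimum(d_age0[act] + y, 180)
                oc = rng.random(act.size) < mq[age_now - 40]
                if oc.any():
                    alive[act[oc]] = False
                    if y < H:
                        markov_deaths_window += oc.sum()
                    act = act[~oc]
                    if act.size == 0:
                        continue
            if y < H:
                diag_py[y] += act.size / 12.0
                in_w = (d_age0[act] + y >= 45) & (d_age0[act] + y <= 84)
                py_w[y] += in_w.sum() / 12.0
            s = states[act]
            if discount_clock == "calendar":
                dmc, dmq = disc_c[m], disc_q[m]
            else:
                dmc = disc_c[m - entry_month[act]]
                dmq = disc_q[m - entry_month[act]]
            markov_qalys += float((dmq * state_u[s]).sum()) / 12.0
            markov_cost += float((dmc * state_c[s]).sum())
            new_s = matrix.step(s, rng)
            died = new_s == int(MarkovState.DEATH)
            if died.any():
                if y < H:
                    deaths_all[y] += died.sum()
                    deaths_met[y] += np.isin(s[died], met_set).sum()
                    markov_deaths_window += died.sum()
                alive[act[died]] = False
            states[act] = new_s

    # ---------------- healthy-months economics -----------------------
    v = (1.0 + qaly_rate) ** (-1.0 / 12.0)

    def disc_sum(m_end: np.ndarray) -> np.ndarray:
        """sum_{m=0}^{m_end-1} v^m, vectorized."""
        if qaly_rate == 0.0:
            return m_end.astype(float)
        return (1.0 - v ** m_end) / (1.0 - v)

    healthy_months = np.minimum(
        np.floor((death - a0) * 12.0).astype(np.int64), n_months)
    healthy_months = np.clip(healthy_months, 0, n_months)
    is_diag = diag_year >= 0
    healthy_months[is_diag] = 12 * diag_year[is_diag] + entry_offset[is_diag]
    if qaly_scope == "population":
        healthy_qalys = float(disc_sum(healthy_months).sum()) / 12.0
    else:
        healthy_qalys = 0.0

    undiag_deaths = float(((diag_year < 0) & (death < a0 + H)).sum())

    return ScenarioResult(
        strategy=strategy.name, n=n, horizon_years=H,
        diagnoses_window=diagnoses_w, met_diagnoses_window=met_diagnoses_w,
        person_years_window=py_w, pca_deaths_all=deaths_all,
        pca_deaths_met=deaths_met, diagnosed_person_years=diag_py,
        n_diagnosed=n_diag, n_screen_detected=int(screen_det.sum()),
        n_psa_tests=n_psa, n_mri=n_mri, n_biopsies=n_bio,
        n_treatments=n_diag,
        total_deaths_window=undiag_deaths + markov_deaths_window,
        total_cost=screen_cost + markov_cost,
        total_qalys=healthy_qalys + markov_qalys)


# ---------------------------------------------------------------------------
# strategy grid
# ---------------------------------------------------------------------------

START_AGES = (45, 50, 55, 60)
INTERVALS = (1, 2, 3, 5)
CUTOFF_MODES = (FIXED_4, AGE_SPECIFIC)


def conventional_grid() -> list[ScreeningStrategy]:
    """The population-wide strategies: start x interval x cutoff mode."""
    out = []
    for start in START_AGES:
        for interval in INTERVALS:
            for mode in CUTOFF_MODES:
                out.append(ScreeningStrategy(
                    name=f"{mode}_start{start}_every{interval}",
                    start_age=start, interval=interval, cutoff_mode=mode))
    return out


def risk_stratified_grid(genetic_tests: tuple[str, ...] = ("prs", "wgs")
                         ) -> list[ScreeningStrategy]:
    """Risk-stratified strategies: high-risk men screen annually from 45;
    average-risk men postpone the start (50/55/60), stretch the interval
    (1/2 years) or skip screening entirely."""
    out = []
    avg_arms: list[ScreeningStrategy | None] = [None]
    for start in (50, 55, 60):
        for interval in (1, 2):
            avg_arms.append(ScreeningStrategy(
                name=f"avg_start{start}_every{interval}",
                start_age=start, interval=interval))
    for test in genetic_tests:
        for mode in CUTOFF_MODES:
            hr = ScreeningStrategy(name="hr_start45_every1", start_age=45,
                                   interval=1, cutoff_mode=mode)
            for arm in avg_arms:
                if arm is None:
                    avg = ScreeningStrategy.no_screening("avg_none")
                    label = "none"
                else:
                    avg = replace(arm, cutoff_mode=mode)
                    label = f"start{arm.start_age}_every{arm.interval}"
                out.append(ScreeningStrategy.stratified(
                    name=f"{test}_{mode}_hr45x1_avg_{label}",
                    high_risk_arm=hr, average_risk_arm=avg, genetic_test=test))
    return out


def strategy_grid() -> list[ScreeningStrategy]:
    """All evaluated strategies (32 conventional + 28 risk-stratified)."""
    return conventional_grid() + risk_stratified_grid()


def run_grid(cohort: LatentCohort, strategies: list[ScreeningStrategy] | None = None,
             seed: int = 0, **kwargs) -> pd.DataFrame:
    """Run the baseline and every strategy; return the comparison table."""
    from .economics import icer
    from .outcomes import clinical_metrics, harm_benefit

    strategies = strategy_grid() if strategies is None else strategies
    baseline = run_scenario(cohort, ScreeningStrategy.no_screening(),
                            seed=seed, **kwargs)
    base_metrics = clinical_metrics(baseline)
    rows = []
    for strat in strategies:
        res = run_scenario(cohort, strat, seed=seed, **kwargs)
        cm = clinical_metrics(res)
        cea = icer(strat.name, res.cost_per_capita, res.qalys_per_capita,
                   baseline.cost_per_capita, baseline.qalys_per_capita)
        hb = harm_benefit(res, baseline)
        rows.append({
            "strategy": strat.name,
            "incidence_per_100k": cm.avg_incidence_per_100k,
            "metastatic_per_100k": cm.metastatic_at_detection_per_100k,
            "mi_ratio_pct": cm.mi_ratio,
            "annual_cfr_pct": cm.annual_cfr,
            "cost_per_capita": cea.cost,
            "qalys_per_capita": cea.qalys,
            "d_cost": cea.d_cost,
            "d_qalys": cea.d_qalys,
            "icer": cea.icer,
            "extra_tests_per_life": hb.tests_per_life_gained,
            "extra_biopsies_per_life": hb.biopsies_per_life_gained,
            "extra_treatments_per_life": hb.treatments_per_life_gained,
        })
    df = pd.DataFrame(rows)
    df.attrs["baseline"] = {
        "incidence_per_100k": base_metrics.avg_incidence_per_100k,
        "mi_ratio_pct": base_metrics.mi_ratio,
        "annual_cfr_pct": base_metrics.annual_cfr,
        "cost_per_capita": baseline.cost_per_capita,
        "qalys_per_capita": baseline.qalys_per_capita,
    }
    return df
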