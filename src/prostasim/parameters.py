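"""Model parameter tables.

All defaults are the published point estimates of the Chinese PSA-screening
cost-effectiveness model: natural-history hazard constants, log-PSA growth
coefficients, diagnostic test characteristics, monthly Markov transition
probabilities, unit costs (USD, 1 CNY = 0.14 USD) and EQ-5D state utilities.
Each dataclass also records the published plausible range used by the
sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


@dataclass(frozen=True)
class NaturalHistoryParams:
    """Hazard constants of the latent disease process.

    The onset hazard is linear in age, ``lambda_o(t) = gamma_o * t``.
    Metastasis and clinical (symptomatic) detection hazards are proportional
    to the PSA level, ``lambda_m(t) = exp(P(t)) * gamma_m`` and
    ``lambda_c(t) = exp(P(t)) * gamma_c``, where ``P`` is log PSA; after
    metastasis the detection hazard is multiplied by ``theta_c``.
    """

    gamma_o: float = 0.00024   # onset hazard slope, per year of age per year
    gamma_m: float = 0.0004    # metastasis hazard coefficient
    gamma_c: float = 0.0005    # clinical-detection hazard coefficient
    gamma_lr: float = 0.673    # proportion of low-risk (Gleason grade group <=3) tumours
    theta_c: float = 19.1334   # detection-hazard multiplier after metastasis

    def __post_init__(self) -> None:
        if self.gamma_o < 0 or self.gamma_m < 0 or self.gamma_c < 0:
            raise ValueError("hazard coefficients must be non-negative")
        if not 0.0 <= self.gamma_lr <= 1.0:
            raise ValueError("gamma_lr must lie in [0, 1]")
        if self.theta_c < 1.0:
            raise ValueError("theta_c must be >= 1")

    def scaled(self, onset_factor: float = 1.0, detection_factor: float = 1.0
               ) -> "NaturalHistoryParams":
        """Return a copy with gamma_o and gamma_c multiplied by the factors."""
        return replace(self, gamma_o=self.gamma_o * onset_factor,
                       gamma_c=self.gamma_c * detection_factor)


@dataclass(frozen=True)
class PsaGrowthParams:
    """Log-linear change-point model for PSA growth.

    Mean log PSA at age ``t`` is ``b + a0*t`` while healthy and gains an
    extra slope ``a1`` (low-risk) or ``a2`` (high-risk) per year after tumour
    onset.  Observed values add Gaussian noise with SD ``sigma_eps`` on the
    log scale; the latent hazards use the noise-free mean trajectory.
    """

    a0: float = 0.0215        # healthy log-PSA slope (log ng/mL per year)
    a1: float = 0.0566        # extra slope, low-risk tumours
    a2: float = 0.1051        # extra slope, high-risk tumours
    b: float = -0.1061        # log-PSA intercept
    sigma_eps: float = 0.2    # SD of observation noise on log PSA

    def __post_init__(self) -> None:
        if not (self.a2 >= self.a1 >= 0.0):
            raise ValueError("slopes must satisfy a2 >= a1 >= 0")
        if self.sigma_eps < 0.0:
            raise ValueError("sigma_eps must be non-negative")


@dataclass(frozen=True)
class TestCharacteristics:
    """Operating characteristics of the MRI-then-targeted-biopsy pathway."""

    mri_sens: float = 0.89
    mri_spec: float = 0.80
    biopsy_sens: float = 0.64
    biopsy_spec: float = 1.00
    direct_biopsy_psa: float = 10.0   # ng/mL; above this, straight to systematic biopsy

    def __post_init__(self) -> None:
        for name in ("mri_sens", "mri_spec", "biopsy_sens", "biopsy_spec"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class RiskStratification:
    """Inherited-risk stratification by family history / PRS / rare mutations.

    ``high_risk_fraction`` is the share of men flagged high-risk (the
    published complement of the 66.8% average-risk share).  ``onset_rr`` is
    the relative risk on the onset hazard for high-risk men; the published
    model calibrates risk-group hazards from external cohort data not
    reproduced here, so the default leaves natural history shared.
    """

    high_risk_fraction: float = 0.332
    onset_rr: float = 1.0
    prs_cost: float = 16.81    # USD, one-time targeted genotyping
    wgs_cost: float = 252.00   # USD, one-time whole-genome sequencing

    def __post_init__(self) -> None:
        if not 0.0 <= self.high_risk_fraction <= 1.0:
            raise ValueError("high_risk_fraction must lie in [0, 1]")
        if self.onset_rr <= 0:
            raise ValueError("onset_rr must be positive")


@dataclass(frozen=True)
class EntryRule:
    """Initial treatment split on entering the prognosis model."""

    localized_rp_share: float = 0.90   # share of localized cases managed by RP (rest RT)

    def __post_init__(self) -> None:
        if not 0.0 <= self.localized_rp_share <= 1.0:
            raise ValueError("localized_rp_share must lie in [0, 1]")

    @property
    def localized_rt_share(self) -> float:
        return 1.0 - self.localized_rp_share


@dataclass(frozen=True)
class CostTable:
    """Unit costs in USD (payer perspective, 1 CNY = 0.14 USD)."""

    # one-time
    psa: float = 3.78
    mri: float = 148.05
    biopsy: float = 161.70
    rp: float = 6594.70
    rt: float = 4550.00
    wgs: float = 252.00
    prs: float = 16.81
    # monthly
    post_trt_adt: float = 312.23      # post-RP/RT ADT per month
    monitoring: float = 3.78          # post-RP/RT monitoring per month
    bcr_adt: float = 297.81           # post-RP/RT BCR ADT per month
    mhspc: float = 1060.98
    nmcrpc: float = 1004.09
    mcrpc: float = 2054.00


@dataclass(frozen=True)
class UtilityTable:
    """Monthly EQ-5D state utilities; healthy/undiagnosed men carry 1.0."""

    healthy: float = 1.0
    rp: float = 0.800
    rt: float = 0.800
    bcr_rp: float = 0.790
    bcr_rt: float = 0.790
    mhspc: float = 0.755
    nmcrpc: float = 0.775
    mcrpc: float = 0.726
    death: float = 0.0


#: National and regional willingness-to-pay thresholds (USD per QALY,
#: 2023 per-capita GDP).
WTP_NATIONAL = 12510.12
WTP_REGIONAL = {
    "Gansu": 6738.06,
    "Hunan": 10602.35,
    "Guangdong": 15007.15,
    "Zhejiang": 17493.90,
    "Jiangsu": 21081.75,
    "Shanghai": 26699.95,
}


@dataclass(frozen=True)
class EconParams:
    """Economic evaluation settings.

    ``annual_discount`` applies to costs.  ``qaly_discount`` applies to
    quality-adjusted survival; the published incremental QALYs are
    numerically consistent only with undiscounted quality-adjusted
    survival, so the reproduction default is 0 — set it to
    ``annual_discount`` for textbook symmetric discounting.
    """

    annual_discount: float = 0.03
    qaly_discount: float = 0.0
    horizon_years: int = 30
    wtp: float = WTP_NATIONAL

    def __post_init__(self) -> None:
        if self.annual_discount < 0 or self.qaly_discount < 0:
            raise ValueError("discount rates must be non-negative")
        if self.horizon_years <= 0:
            raise ValueError("horizon must be positive")


#: Published plausible ranges (low, high) for the sensitivity analyses.
PARAMETER_RANGES = {
    "gamma_o": (0.00018, 0.00032),
    "gamma_m": (0.0003, 0.00052),
    "gamma_c": (0.00038, 0.00067),
    "gamma_lr": (0.505, 0.897),
    "theta_c": (14.3500, 25.5112),
    "a0": (0.0210, 0.0220),
    "a1": (0.0430, 0.0693),
    "a2": (0.0870, 0.1247),
    "b": (-0.1670, -0.046),
    "mri_sens": (0.83, 0.93),
    "mri_spec": (0.62, 0.90),
    "biopsy_sens": (0.48, 0.80),
    "biopsy_spec": (0.90, 1.00),
    "cost_psa": (2.84, 4.73),
    "cost_mri": (111.04, 185.06),
    "cost_biopsy": (121.28, 202.13),
    "cost_rp": (4946.03, 8243.38),
    "cost_rt": (3412.50, 5687.50),
    "cost_post_trt_adt": (234.18, 390.29),
    "cost_monitoring": (2.84, 4.73),
    "cost_bcr_adt": (223.36, 372.27),
    "cost_mhspc": (795.74, 1326.23),
    "cost_nmcrpc": (753.06, 1255.11),
    "cost_mcrpc": (1540.50, 2567.50),
    "utility_rp": (0.600, 1.000),
    "utility_rt": (0.600, 1.000),
    "utility_bcr_rp": (0.593, 0.988),
    "utility_bcr_rt": (0.593, 0.988),
    "utility_mhspc": (0.566, 0.944),
    "utility_nmcrpc": (0.581, 0.969),
    "utility_mcrpc": (0.545, 0.908),
}
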