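"""Synthetic infant cohorts with the study's covariate and TDM structure.

Generates virtual subjects whose covariate distributions match the
printed modeling-group summaries (weight, height, serum creatinine, age,
prematurity), stratified by renal function via the Schwartz eGFR; builds
the 40 mg/kg/day dosing regimens split into 2-4 infusions; schedules the
therapeutic-drug-monitoring samples (trough 30 min before the fifth
dose, peak 30 min after the end of the fifth infusion); and simulates
observed concentrations under a covariate model with log-normal
between-subject variability and the configured residual-error form.

Weight and creatinine are drawn log-normal (positive, right-skewed)
matched to the group medians and truncated to the printed ranges; height
follows weight through a monotone allometric relation with noise; group
membership is enforced by recomputing eGFR and resampling until the
classification matches.  All randomness flows through one seeded
`numpy.random.Generator`, so cohorts are bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .covariates import (
    Covariates,
    CovariateModelSpec,
    ResidualErrorSpec,
    apply_bsv,
    apply_residual,
    classify_renal_function,
    egfr_schwartz,
    typical_parameters,
)
from .pk import DosingEvent, IndividualParameters, concentration_at

logger = logging.getLogger(__name__)

__all__ = [
    "GroupProfile",
    "CohortConfig",
    "Observation",
    "SubjectRecord",
    "GenerationError",
    "SchedulingError",
    "NORMAL_PROFILE",
    "ARC_PROFILE",
    "sample_covariates",
    "build_dosing_regimen",
    "schedule_tdm_samples",
    "simulate_dataset",
]


class GenerationError(RuntimeError):
    """Raised when a cohort target is unreachable within the rejection budget."""


class SchedulingError(ValueError):
    """Raised when a regimen cannot accommodate the TDM sampling design."""


@dataclass(frozen=True)
class GroupProfile:
    """Location/spread targets for one renal-function group."""

    group: str
    wt_median: float
    wt_range: tuple
    wt_log_sd: float
    ht_median: float
    ht_range: tuple
    scr_median: float
    scr_range: tuple
    scr_log_sd: float
    preterm_frac: float
    male_frac: float
    comed_frac: float
    lab_medians: dict = field(default_factory=dict)


# Modeling-group summaries: medians/ranges of the normal-renal-function
# (eGFR 30-86) and augmented-renal-clearance (eGFR >= 86) groups.
NORMAL_PROFILE = GroupProfile(
    group="normal",
    wt_median=2.25, wt_range=(1.15, 13.0), wt_log_sd=0.40,
    ht_median=44.0, ht_range=(32.0, 90.0),
    scr_median=27.1, scr_range=(14.0, 315.0), scr_log_sd=0.30,
    preterm_frac=29 / 61, male_frac=37 / 61, comed_frac=47 / 61,
    lab_medians={"ALT": 19.5, "AST": 36.0, "BUN": 3.44,
                 "CYSC": 1.51, "ALB": 31.35, "TP": 46.9},
)

ARC_PROFILE = GroupProfile(
    group="augmented",
    wt_median=4.60, wt_range=(2.2, 14.0), wt_log_sd=0.42,
    ht_median=54.0, ht_range=(42.9, 110.0),
    scr_median=16.8, scr_range=(8.0, 29.0), scr_log_sd=0.25,
    preterm_frac=17 / 64, male_frac=41 / 64, comed_frac=54 / 64,
    lab_medians={"ALT": 30.0, "AST": 40.0, "BUN": 2.8,
                 "CYSC": 1.37, "ALB": 35.1, "TP": 55.1},
)

_PROFILES = {"normal": NORMAL_PROFILE, "augmented": ARC_PROFILE}

# mixture weight of the normal group in the pooled population (61 of 115)
_MIXED_NORMAL_FRAC = 61 / 115


@dataclass(frozen=True)
class CohortConfig:
    """Cohort size, group, dosing policy and TDM sampling policy."""

    n_subjects: int
    group: str = "mixed"          # normal | augmented | mixed
    seed: int = 0
    daily_dose_per_kg: float = 40.0
    splits: tuple = (2, 3, 4)
    infusion_duration: float = 1.0
    n_doses: int = 6
    anchor_dose: int = 5
    trough_offset: float = 0.5
    peak_offset: float = 0.5
    max_rejections: int = 1000

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.group not in ("normal", "augmented", "mixed"):
            raise ValueError(f"unknown group {self.group!r}")
        if not set(self.splits) <= {2, 3, 4}:
            raise ValueError("splits must be a subset of {2, 3, 4}")
        if self.trough_offset <= 0 or self.peak_offset <= 0:
            raise ValueError("sampling offsets must be positive")
        if self.n_doses < self.anchor_dose:
            raise ValueError("regimen must reach the anchor dose")


@dataclass(frozen=True)
class Observation:
    time: float      # h since first dose
    dv: float        # mg/L
    kind: str        # trough | peak

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("observation time must be >= 0")


@dataclass(frozen=True)
class SubjectRecord:
    id: str
    covariates: Covariates
    egfr: float
    group: str
    doses: tuple
    observations: tuple


def _rng(config: CohortConfig, rng: np.random.Generator | None) -> np.random.Generator:
    return np.random.default_rng(config.seed) if rng is None else rng


def _truncated_lognormal(rng, median, log_sd, lo, hi, max_tries=200):
    mu = np.log(median)
    for _ in range(max_tries):
        x = float(rng.lognormal(mu, log_sd))
        if lo <= x <= hi:
            return x
    return float(np.clip(np.exp(mu), lo, hi))


def _sample_age_months(rng) -> float:
    # printed medians are 1 month with range 1-24: point mass at 1 month
    # plus a right tail (shifted geometric truncated at 24)
    if rng.random() < 0.6:
        return 1.0
    for _ in range(100):
        age = 1.0 + float(rng.geometric(0.25))
        if age <= 24.0:
            return age
    return 24.0


def _sample_one_subject(profile: GroupProfile, config: CohortConfig, rng) -> Covariates:
    preterm = bool(rng.random() < profile.preterm_frac)
    sex = "M" if rng.random() < profile.male_frac else "F"
    comed = bool(rng.random() < profile.comed_frac)
    age = _sample_age_months(rng)
    wt = _truncated_lognormal(rng, profile.wt_median, profile.wt_log_sd, *profile.wt_range)

    # height tracks weight allometrically; noise on the log scale
    def draw_ht() -> float:
        ht = profile.ht_median * (wt / profile.wt_median) ** 0.29
        ht *= float(np.exp(rng.normal(0.0, 0.05)))
        return float(np.clip(ht, *profile.ht_range))

    for _ in range(config.max_rejections):
        ht = draw_ht()
        scr = _truncated_lognormal(rng, profile.scr_median, profile.scr_log_sd, *profile.scr_range)
        labs = {
            lab: float(rng.lognormal(np.log(med), 0.3))
            for lab, med in profile.lab_medians.items()
        }
        cov = Covariates(
            wt=wt, ht=ht, scr=scr, age_months=age, preterm=preterm, sex=sex,
            comed=comed, alt=labs.get("ALT"), ast=labs.get("AST"),
            bun=labs.get("BUN"), cysc=labs.get("CYSC"), alb=labs.get("ALB"),
            tp=labs.get("TP"),
        )
        if classify_renal_function(egfr_schwartz(cov)) == profile.group:
            return cov
    raise GenerationError(
        f"could not generate a {profile.group!r} subject within "
        f"{config.max_rejections} rejections (targets may be infeasible)"
    )


def sample_covariates(
    config: CohortConfig, rng: np.random.Generator | None = None
) -> list:
    """Draw per-subject covariates matching the configured group targets."""
    rng = _rng(config, rng)
    out = []
    for _ in range(config.n_subjects):
        if config.group == "mixed":
            profile = _PROFILES["normal" if rng.random() < _MIXED_NORMAL_FRAC else "augmented"]
        else:
            profile = _PROFILES[config.group]
        out.append(_sample_one_subject(profile, config, rng))
    return out


def build_dosing_regimen(
    cov: Covariates, config: CohortConfig, rng: np.random.Generator | None = None
) -> list:
    """40 mg/kg/day split evenly into 2-4 infusions at equal intervals.

    The per-dose amount times the number of daily administrations equals
    ``daily_dose_per_kg * WT`` exactly; at least ``anchor_dose`` doses
    are generated so the TDM design around the fifth dose is feasible.
    """
    rng = _rng(config, rng)
    splits = int(rng.choice(config.splits))
    interval = 24.0 / splits
    amount = config.daily_dose_per_kg * cov.wt / splits
    n = max(config.n_doses, config.anchor_dose)
    return [
        DosingEvent(start_time=i * interval, amount=amount, duration=config.infusion_duration)
        for i in range(n)
    ]


def schedule_tdm_samples(regimen: Sequence[DosingEvent], config: CohortConfig) -> list:
    """Trough/peak times anchored at the configured (fifth) dose.

    Trough: ``trough_offset`` h before the anchor dose starts; peak:
    ``peak_offset`` h after the anchor infusion ends.
    """
    if len(regimen) < config.anchor_dose:
        raise SchedulingError(
            f"regimen has {len(regimen)} doses; the sampling design needs "
            f">= {config.anchor_dose}"
        )
    anchor = sorted(regimen, key=lambda e: e.start_time)[config.anchor_dose - 1]
    trough = anchor.start_time - config.trough_offset
    peak = anchor.end_time + config.peak_offset
    return [(trough, "trough"), (peak, "peak")]


def simulate_dataset(
    config: CohortConfig,
    params,
    spec: CovariateModelSpec,
    rng: np.random.Generator | None = None,
) -> list:
    """Simulate a cohort of `SubjectRecord` from a population model.

    ``params`` is a `vancopk.estimation.PopulationParameters`: for each
    subject a log-normal random effect eta ~ N(0, omega^2) perturbs the
    typical clearance (and volume, if omega_v > 0), concentrations are
    predicted at the scheduled TDM times, and residual error is applied.
    With omega = sigma = 0 the observations equal the typical-model
    predictions exactly.
    """
    rng = _rng(config, rng)
    covs = sample_covariates(config, rng)
    sigma: ResidualErrorSpec = params.sigma
    subjects = []
    n_neg = 0
    n_obs = 0
    theta = tuple(params.theta) if params.theta is not None else None
    for i, cov in enumerate(covs):
        regimen = build_dosing_regimen(cov, config, rng)
        times = schedule_tdm_samples(regimen, config)
        cl, v = spec.typical_cl_v(cov.as_dict(), theta)
        eta_cl = float(rng.normal(0.0, params.omega_cl)) if params.omega_cl > 0 else 0.0
        eta_v = float(rng.normal(0.0, params.omega_v)) if params.omega_v > 0 else 0.0
        ip = apply_bsv(IndividualParameters(float(cl), float(v)), eta_cl, eta_v)
        t = np.array([tt for tt, _ in times])
        f = concentration_at(t, regimen, ip)
        if sigma.n_eps == 2:
            draws = rng.standard_normal((len(t), 2))
        else:
            draws = rng.standard_normal(len(t))
        y = apply_residual(f, sigma, draws) if (sigma.sigma1 > 0 or sigma.sigma2 > 0) else f
        n_neg += int(np.sum(np.asarray(y) < 0))
        n_obs += len(t)
        obs = tuple(
            Observation(time=float(tt), dv=float(yy), kind=kind)
            for (tt, kind), yy in zip(times, np.atleast_1d(y))
        )
        egfr = egfr_schwartz(cov)
        subjects.append(
            SubjectRecord(
                id=f"S{i + 1:04d}",
                covariates=cov,
                egfr=egfr,
                group=classify_renal_function(egfr),
                doses=tuple(regimen),
                observations=obs,
            )
        )
    if n_neg:
        logger.warning(
            "simulate_dataset: %d of %d simulated observations are negative "
            "(residual-error draws below -1/sigma)", n_neg, n_obs,
        )
    return subjects
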