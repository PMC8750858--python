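"""Seeded synthetic follow-up cohorts for schizophrenia risk modelling.

The registry data this pipeline targets is access-restricted, so every test
and demo runs on cohorts from this generator.  One row is one
patient-course: demographic, treatment and disease-course covariates, a
calendar period with a policy-change step, a regional baseline offset, a
follow-up duration, and a (possibly censored) risk-event outcome drawn from
an exponential proportional-hazards model whose linear predictor is
``sum_j beta_j x_j + region offset + policy step``.

Default coefficients are published Cox log-hazards for this population
(e.g. compliance 0.48, gender: female -0.37); the baseline hazard is
calibrated so that, in expectation, ``target_event_rate`` of records
experience the event within their follow-up duration.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GeneratorParams", "generate_cohort", "apc_grid", "DEFAULT_COEFFICIENTS"]

#: Log-hazard ground truth applied to the level-coded covariates below.
#: The duration effect attaches to the ordinal course-of-disease rating
#: (discretized years since onset); raw follow-up days are the censoring
#: horizon and carry no hazard coefficient.
DEFAULT_COEFFICIENTS: dict[str, float] = {
    "adverse_reactions_times": 0.01,
    "drug_combination": 0.16,
    "age_rating": 0.09,
    "diagnostic_type": 0.61,
    "course_of_disease_rating": 0.05,
    "drug_combination_number": -0.06,
    "gender": -0.37,  # 0 = male, 1 = female
    "disability_rating": -0.06,
    "social_function": 0.25,
    "compliance": 0.48,  # 1 = good status
    "targeted_poverty_alleviation": 0.31,
    "family_guardianship_subsidy": 0.39,
}

#: Four risk-event types collapsed to any-event for modelling; per-type
#: labels are still emitted for downstream stratification.
EVENT_TYPES = (
    "behavior_endangering_society",
    "hospitalization_referral",
    "loss_of_self_knowledge",
    "suicide_death",
)


@dataclass
class GeneratorParams:
    """Study-condition knobs of the synthetic cohort."""

    n: int = 20_000
    seed: int = 7
    #: five regions with log-hazard offsets spread +-0.5
    region_effects: tuple[float, ...] = (-0.5, -0.25, 0.0, 0.25, 0.5)
    female_fraction: float = 0.45
    period_range: tuple[int, int] = (2010, 2019)
    policy_year: int = 2015
    policy_step: float = 0.3  # log-hazard bump from the policy year onward
    coefficients: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_COEFFICIENTS))
    target_event_rate: float = 0.15

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError("n must be positive")
        if not 0.0 < self.target_event_rate < 1.0:
            raise ValueError(
                f"target_event_rate={self.target_event_rate} leaves no room for censoring"
            )
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ValueError("female_fraction must be a probability")
        if self.period_range[0] > self.period_range[1]:
            raise ValueError("period_range must be (first, last) with first <= last")


_AGE_CUTS = (30.0, 45.0, 60.0, 75.0)
_COURSE_CUTS = (2.0, 5.0, 10.0)  # years since onset -> rating 0..3


def _draw_covariates(p: GeneratorParams, rng: np.random.Generator) -> pd.DataFrame:
    n = p.n
    age = np.clip(rng.normal(45.0, 15.0, n), 18.0, 90.0)
    duration = np.clip(rng.gamma(shape=2.0, scale=400.0, size=n), 30.0, None).round()
    course_years = np.clip(rng.gamma(shape=2.0, scale=3.0, size=n), 0.1, 40.0)
    period = rng.integers(p.period_range[0], p.period_range[1] + 1, n)
    df = pd.DataFrame(
        {
            "region": rng.integers(0, len(p.region_effects), n),
            "age": age.round(1),
            "age_rating": np.searchsorted(_AGE_CUTS, age, side="right"),
            "gender": rng.binomial(1, p.female_fraction, n),
            "education": rng.integers(0, 4, n),
            "disability_rating": rng.integers(0, 4, n),
            "social_function": rng.integers(0, 4, n),
            "economic_status": rng.integers(0, 3, n),
            "compliance": rng.binomial(1, 0.5, n),
            "adverse_reactions_times": np.minimum(rng.poisson(0.5, n), 5),
            "drug_combination": rng.binomial(1, 0.4, n),
            "auxiliary_drug_combination": rng.binomial(1, 0.2, n),
            "drug_combination_number": np.minimum(rng.poisson(1.0, n), 4),
            "hospitalization_times": np.minimum(rng.poisson(0.8, n), 6),
            "referral_times": np.minimum(rng.poisson(0.3, n), 4),
            "suggest_referral": rng.binomial(1, 0.1, n),
            "diagnostic_type": rng.binomial(1, 0.15, n),
            "poverty": rng.binomial(1, 0.2, n),
            "targeted_poverty_alleviation": rng.binomial(1, 0.15, n),
            "family_guardianship_subsidy": rng.binomial(1, 0.1, n),
            "duration_days": duration,
            "course_years": course_years.round(2),
            "course_of_disease_rating": np.searchsorted(_COURSE_CUTS, course_years, side="right"),
            "period": period,
            "policy_period": (period >= p.policy_year).astype(int),
        }
    )
    return df


def _calibrate_baseline(lp: np.ndarray, duration: np.ndarray, target: float) -> float:
    """Baseline hazard (per day) so that mean P(T <= D) equals ``target``."""

    def prevalence(log_lam0: float) -> float:
        lam = np.exp(log_lam0 + lp)
        return float(np.mean(1.0 - np.exp(-lam * duration)))

    lo, hi = -25.0, 5.0
    if not prevalence(lo) < target < prevalence(hi):
        raise ValueError(f"target event rate {target} is unattainable")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if prevalence(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_cohort(p: GeneratorParams) -> tuple[pd.DataFrame, dict]:
    """Draw a cohort table plus the exact ground-truth record used.

    Same params (including seed) produce an identical table.  The truth
    record carries every coefficient, the region offsets, policy step and
    the calibrated baseline log-hazard.
    """
    p.validate()
    rng = np.random.default_rng(p.seed)
    df = _draw_covariates(p, rng)
    unknown = set(p.coefficients) - set(df.columns)
    if unknown:
        raise KeyError(f"coefficients reference unknown covariates: {sorted(unknown)}")

    lp = np.zeros(p.n)
    for name, beta in p.coefficients.items():
        lp += beta * df[name].to_numpy(dtype=float)
    lp += np.asarray(p.region_effects)[df["region"].to_numpy()]
    lp += p.policy_step * df["policy_period"].to_numpy(dtype=float)

    duration = df["duration_days"].to_numpy(dtype=float)
    log_lam0 = _calibrate_baseline(lp, duration, p.target_event_rate)
    lam = np.exp(log_lam0 + lp)
    latent_t = rng.exponential(1.0, p.n) / lam
    event = (latent_t <= duration).astype(int)
    df["event"] = event
    df["event_time"] = np.minimum(latent_t, duration).round(2)
    types = np.where(
        event == 1, rng.choice(EVENT_TYPES, size=p.n), ""
    )
    df["event_type"] = types

    truth = {
        "params": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(p).items()
        },
        "baseline_log_hazard": log_lam0,
        "realized_event_rate": float(event.mean()),
    }
    return df, truth


def write_cohort(df: pd.DataFrame, truth: dict, csv_path, truth_path=None) -> None:
    """Deterministic CSV (plus optional ground-truth JSON) output."""
    df.to_csv(csv_path, index=False)
    if truth_path is not None:
        with open(truth_path, "w") as fh:
            json.dump(truth, fh, indent=2)


def apc_grid(
    df: pd.DataFrame, n_age_groups: int = 10, exposure_unit_days: float = 365.25
) -> pd.DataFrame:
    """Aggregate a cohort into an age-group x period event/exposure grid.

    Exposure is person-time at risk (event time, in ``exposure_unit_days``
    units); grid totals conserve the cohort's events and person-time.
    """
    age = df["age"].to_numpy(dtype=float)
    edges = np.quantile(age, np.linspace(0, 1, n_age_groups + 1))[1:-1]
    group = np.searchsorted(np.unique(edges), age, side="right")
    out = (
        pd.DataFrame(
            {
                "age_group": group,
                "period": df["period"].to_numpy(),
                "events": df["event"].to_numpy(),
                "exposure": df["event_time"].to_numpy(dtype=float) / exposure_unit_days,
            }
        )
        .groupby(["age_group", "period"], as_index=False)
        .agg(events=("events", "sum"), exposure=("exposure", "sum"))
    )
    return out
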