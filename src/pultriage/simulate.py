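"""Synthetic multi-centre PUL cohorts.

No public dataset exists for PUL triage validation, so the package ships a
generator that emulates the statistical structure the analysis assumes:
a three-class outcome mix, outcome-conditional lognormal biomarkers
(initial beta-hCG, 48-hour hCG ratio, initial progesterone), clustering by
centre with centre-specific EP-prevalence tilts, protocol-driven and
missing-at-random missingness, and loss to follow-up.

Defaults describe a realistic multi-centre early-pregnancy-unit cohort:
outcome mix 51.4 / 35.7 / 12.8 % (FPUL / IUP / EP), median initial hCG
around 520 IU/l, median hCG ratio around 0.9, median progesterone around
11 nmol/l, roughly 16% of women below the 2 nmol/l progesterone cut-off,
second-sample missingness around 29% and 10% loss to follow-up.  The
docs discuss which features of real data the generator does and does not
emulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .models import CoefficientSet, predict_risks
from .records import BLEEDING_LEVELS, COHORT_COLUMNS, LTFU, OUTCOMES, validate_cohort

__all__ = ["BiomarkerParams", "CohortConfig", "generate_cohort",
           "inject_missingness", "generate_from_model"]


def _logit(p):
    return np.log(p / (1.0 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class BiomarkerParams:
    """Outcome-conditional lognormal parameters for one outcome class.

    Locations and scales are on the natural-log scale; ``rho_hcg_prog``
    correlates log hCG with log progesterone (the ratio is independent).
    """

    mu_log_hcg0: float
    sd_log_hcg0: float
    mu_log_ratio: float
    sd_log_ratio: float
    mu_log_prog0: float
    sd_log_prog0: float
    rho_hcg_prog: float = 0.3

    def __post_init__(self):
        if min(self.sd_log_hcg0, self.sd_log_ratio, self.sd_log_prog0) <= 0:
            raise ValueError("biomarker scales must be positive")
        if not (-1.0 < self.rho_hcg_prog < 1.0):
            raise ValueError("correlation must be in (-1, 1)")


# Defaults: moment-matched to a cohort with overall medians ~519 IU/l
# (hCG), ~0.90 (ratio), ~11 nmol/l (progesterone). FPUL: falling hCG, low
# progesterone; IUP: ratio typically > 1.66, high progesterone; EP: ratio
# concentrated near 1 (inside the 0.87-1.66 band), intermediate
# progesterone.
_DEFAULT_BIOMARKERS = {
    "FPUL": BiomarkerParams(
        mu_log_hcg0=6.05, sd_log_hcg0=1.50,
        mu_log_ratio=-0.80, sd_log_ratio=0.65,
        mu_log_prog0=1.39, sd_log_prog0=1.39,
    ),
    "IUP": BiomarkerParams(
        mu_log_hcg0=6.45, sd_log_hcg0=1.60,
        mu_log_ratio=0.65, sd_log_ratio=0.45,
        mu_log_prog0=3.69, sd_log_prog0=0.75,
    ),
    "EP": BiomarkerParams(
        mu_log_hcg0=6.33, sd_log_hcg0=1.40,
        mu_log_ratio=0.05, sd_log_ratio=0.35,
        mu_log_prog0=2.30, sd_log_prog0=0.90,
    ),
}

# Bleeding-category probabilities by outcome (none/minimal/moderate/
# soaked/clots); failing pregnancies bleed more.
_DEFAULT_BLEEDING = {
    "FPUL": (0.18, 0.26, 0.24, 0.16, 0.16),
    "IUP": (0.38, 0.30, 0.18, 0.08, 0.06),
    "EP": (0.22, 0.30, 0.24, 0.12, 0.12),
}


@dataclass
class CohortConfig:
    """Configuration of the synthetic cohort generator.

    Attributes
    ----------
    n : total cohort size.
    centre_fractions : relative centre sizes (normalised; rounded sizes sum
        to ``n``). Eight unequal centres by default.
    outcome_prevalences : (FPUL, IUP, EP) probabilities, summing to 1.
    centre_ep_tilt_sd : spread of deterministic per-centre tilts added to
        the EP log-odds (heterogeneity between centres).
    biomarkers : per-outcome lognormal parameters.
    prog_supplement_rate : fraction of women on progesterone supplements.
    prog_missing_rate : fraction with progesterone not measured at all.
    hcg48_missing_base : missing-at-random rate of having no second hCG
        sample among women whose protocol requires one.
    hcg48_missing_beta_hcg / _beta_bleed : MAR dependence of second-sample
        dropout on centred log initial hCG and bleeding category.
    step1_compliance : probability that a woman with presenting
        progesterone <= 2 nmol/l (protocol: no second sample needed) still
        has a second sample taken.
    ltfu_rate : marginal loss-to-follow-up rate.
    ltfu_beta_ratio / _beta_bleed : MAR dependence of LTFU on centred log
        hCG ratio (lower ratios are lost more) and bleeding.
    interval_probs : distribution of the between-sample interval in days
        among women with a second sample (the triage protocol targets 2).
    seed : generator seed; same seed, same cohort.
    """

    n: int = 2899
    centre_fractions: Sequence[float] = (
        0.25, 0.18, 0.15, 0.14, 0.10, 0.08, 0.06, 0.04,
    )
    outcome_prevalences: Sequence[float] = (
        1338 / 2602, 930 / 2602, 334 / 2602,  # 51.4 / 35.7 / 12.8 %
    )
    centre_ep_tilt_sd: float = 0.2
    biomarkers: dict = field(default_factory=lambda: dict(_DEFAULT_BIOMARKERS))
    bleeding_probs: dict = field(default_factory=lambda: dict(_DEFAULT_BLEEDING))
    prog_supplement_rate: float = 0.02
    prog_missing_rate: float = 0.06
    hcg48_missing_base: float = 0.073
    hcg48_missing_beta_hcg: float = -0.15
    hcg48_missing_beta_bleed: float = 0.10
    step1_compliance: float = 0.25
    ltfu_rate: float = 0.10
    ltfu_beta_ratio: float = -0.35
    ltfu_beta_bleed: float = 0.10
    interval_probs: dict = field(
        default_factory=lambda: {1: 0.05, 2: 0.86, 3: 0.06, 4: 0.02, 5: 0.01}
    )
    seed: int = 0

    def __post_init__(self):
        prev = np.asarray(self.outcome_prevalences, dtype=float)
        if prev.shape != (3,) or abs(prev.sum() - 1.0) > 1e-6 or (prev < 0).any():
            raise ValueError("outcome_prevalences must be a probability triple")
        for r in (self.prog_supplement_rate, self.prog_missing_rate,
                  self.hcg48_missing_base, self.step1_compliance,
                  self.ltfu_rate):
            if not (0.0 <= r <= 1.0):
                raise ValueError(f"rate {r} outside [0,1]")
        fr = np.asarray(self.centre_fractions, dtype=float)
        if (fr <= 0).any():
            raise ValueError("centre fractions must be positive")
        if self.n < len(fr):
            raise ValueError("cohort smaller than the number of centres")
        if abs(sum(self.interval_probs.values()) - 1.0) > 1e-6:
            raise ValueError("interval_probs must sum to 1")
        self.biomarkers = {
            k: v if isinstance(v, BiomarkerParams) else BiomarkerParams(**v)
            for k, v in self.biomarkers.items()
        }
        missing = set(OUTCOMES) - set(self.biomarkers)
        if missing:
            raise ValueError(f"biomarker params missing for {sorted(missing)}")

    @property
    def centre_sizes(self) -> np.ndarray:
        fr = np.asarray(self.centre_fractions, dtype=float)
        fr = fr / fr.sum()
        sizes = np.floor(fr * self.n).astype(int)
        # distribute the rounding remainder to the largest centres
        for i in np.argsort(-fr)[: self.n - sizes.sum()]:
            sizes[i] += 1
        return sizes

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def replace(self, **kw) -> "CohortConfig":
        return replace(self, **kw)


def _draw_biomarkers(rng, params: BiomarkerParams, n: int):
    """Correlated (log hcg0, log prog0) plus independent log ratio."""
    cov = np.array(
        [
            [params.sd_log_hcg0 ** 2,
             params.rho_hcg_prog * params.sd_log_hcg0 * params.sd_log_prog0],
            [params.rho_hcg_prog * params.sd_log_hcg0 * params.sd_log_prog0,
             params.sd_log_prog0 ** 2],
        ]
    )
    hp = rng.multivariate_normal(
        [params.mu_log_hcg0, params.mu_log_prog0], cov, size=n
    )
    log_ratio = rng.normal(params.mu_log_ratio, params.sd_log_ratio, size=n)
    return np.exp(hp[:, 0]), np.exp(log_ratio), np.exp(hp[:, 1])


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate a complete multi-centre cohort with latent true outcomes.

    Every record is complete (progesterone, second hCG sample taken at a
    protocol-distributed interval); missingness is injected separately by
    :func:`inject_missingness`.  The returned frame carries the latent true
    outcome in ``outcome`` (no LTFU yet) and is deterministic in the seed.
    """
    rng = np.random.default_rng(config.seed)
    sizes = config.centre_sizes
    k = len(sizes)
    centre_ids = np.repeat([f"C{i + 1:02d}" for i in range(k)], sizes)
    n = config.n

    # centre-specific EP tilts on the log-odds scale, symmetric around 0
    tilts = (
        np.linspace(-1.0, 1.0, k) * config.centre_ep_tilt_sd * np.sqrt(3.0)
        if k > 1 else np.zeros(1)
    )
    prev = np.asarray(config.outcome_prevalences, dtype=float)
    outcomes = np.empty(n, dtype=object)
    start = 0
    for i, size in enumerate(sizes):
        p_ep = _expit(_logit(prev[2]) + tilts[i])
        rest = (1.0 - p_ep) / (prev[0] + prev[1])
        p = np.array([prev[0] * rest, prev[1] * rest, p_ep])
        outcomes[start:start + size] = rng.choice(OUTCOMES, size=size, p=p)
        start += size

    hcg0 = np.empty(n)
    ratio = np.empty(n)
    prog0 = np.empty(n)
    for cls in OUTCOMES:
        mask = outcomes == cls
        hcg0[mask], ratio[mask], prog0[mask] = _draw_biomarkers(
            rng, config.biomarkers[cls], int(mask.sum())
        )

    bleeding = np.empty(n, dtype=object)
    for cls in OUTCOMES:
        mask = outcomes == cls
        bleeding[mask] = rng.choice(
            BLEEDING_LEVELS, size=int(mask.sum()), p=config.bleeding_probs[cls]
        )

    ivals = np.array(sorted(config.interval_probs))
    ipr = np.array([config.interval_probs[v] for v in ivals], dtype=float)
    interval_days = rng.choice(ivals, size=n, p=ipr)

    age = np.clip(rng.normal(31.5, 5.8, size=n), 14, 50).round(0)

    cohort = pd.DataFrame(
        {
            "record_id": [f"R{i + 1:06d}" for i in range(n)],
            "centre_id": centre_ids,
            "age": age,
            "prog0": np.round(prog0, 2),
            "hcg0": np.round(hcg0, 1),
            "hcg48": np.round(hcg0 * ratio, 1),
            "interval_days": interval_days.astype(int),
            "prog_supplement": np.zeros(n, dtype=bool),
            "bleeding": bleeding,
            "outcome": outcomes,
        },
        columns=COHORT_COLUMNS,
    )
    # rounding guards: keep strictly positive levels and prog >= 0
    cohort["hcg0"] = cohort["hcg0"].clip(lower=0.1)
    cohort["hcg48"] = cohort["hcg48"].clip(lower=0.1)
    cohort["prog0"] = cohort["prog0"].clip(lower=0.1)
    return validate_cohort(cohort)


def inject_missingness(
    cohort: pd.DataFrame, config: CohortConfig
) -> tuple[pd.DataFrame, dict]:
    """Apply protocol-driven and MAR missingness to a complete cohort.

    * progesterone: a supplement flag (value later invalidated by the
      protocol rules) plus a not-measured fraction;
    * second hCG sample: women at or below the 2 nmol/l progesterone
      cut-off only have one with probability ``step1_compliance`` (the
      triage protocol tells them not to return); everyone else drops out
      at a MAR rate depending on initial hCG and bleeding;
    * loss to follow-up: outcome replaced by LTFU at a MAR rate depending
      on the hCG ratio and bleeding.

    Non-targeted fields are never altered.  Returns the cohort and a dict
    of achieved rates (``hcg48_missing_effective`` additionally counts
    samples taken off the 2-day protocol interval, which the downstream
    missingness rules will discard).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    out = cohort.copy()
    n = len(out)

    supplement = rng.random(n) < config.prog_supplement_rate
    out["prog_supplement"] = supplement
    prog_unmeasured = (~supplement) & (rng.random(n) < config.prog_missing_rate)
    out.loc[prog_unmeasured, "prog0"] = np.nan

    prog = out["prog0"].to_numpy(dtype=float)
    reliable_low = (~supplement) & ~np.isnan(prog) & (prog <= 2.0)

    bleed_code = out["bleeding"].map(
        {b: i for i, b in enumerate(BLEEDING_LEVELS)}
    ).to_numpy(dtype=float)
    log_hcg0 = np.log(out["hcg0"].to_numpy(dtype=float))
    p_drop = _expit(
        _logit(max(config.hcg48_missing_base, 1e-9))
        + config.hcg48_missing_beta_hcg * (log_hcg0 - 6.25)
        + config.hcg48_missing_beta_bleed * (bleed_code - 2.0)
    )
    u = rng.random(n)
    no_sample = np.where(
        reliable_low, u >= config.step1_compliance, u < p_drop
    )
    if config.hcg48_missing_base == 0 and config.step1_compliance == 1:
        no_sample = np.zeros(n, dtype=bool)
    out.loc[no_sample, "hcg48"] = np.nan
    out.loc[no_sample, "interval_days"] = np.nan

    log_ratio = np.log(
        out["hcg48"].to_numpy(dtype=float) / out["hcg0"].to_numpy(dtype=float)
    )
    ratio_term = np.where(np.isnan(log_ratio), 0.0, log_ratio)
    p_ltfu = (
        _expit(
            _logit(max(config.ltfu_rate, 1e-9))
            + config.ltfu_beta_ratio * ratio_term
            + config.ltfu_beta_bleed * (bleed_code - 2.0)
        )
        if config.ltfu_rate > 0
        else np.zeros(n)
    )
    ltfu = rng.random(n) < p_ltfu
    out.loc[ltfu, "outcome"] = LTFU

    off_interval = (~no_sample) & (out["interval_days"].to_numpy(dtype=float) != 2)
    achieved = {
        "prog0_missing": float(
            np.mean(out["prog0"].isna() | out["prog_supplement"])
        ),
        "hcg48_no_sample": float(no_sample.mean()),
        "hcg48_missing_effective": float((no_sample | off_interval).mean()),
        "ltfu": float(ltfu.mean()),
        "step1_low_progesterone": float(reliable_low.mean()),
    }
    return out, achieved


def generate_from_model(
    coefs: CoefficientSet, config: CohortConfig
) -> pd.DataFrame:
    """Cohort whose outcomes are drawn from a model's own risk estimates.

    Biomarkers are sampled from the configured outcome mixture (class
    labels used only as mixture components and then discarded); each
    record's final outcome is drawn from the multinomial risks the given
    coefficient set assigns it.  By construction the model is perfectly
    calibrated on such a cohort, which makes these cohorts the oracle for
    calibration and discrimination self-consistency checks.
    """
    base = generate_cohort(config)
    risks = predict_risks(base, coefs)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    u = rng.random(len(base))
    cum = risks.to_numpy().cumsum(axis=1)
    idx = (u[:, None] > cum).sum(axis=1)
    out = base.copy()
    out["outcome"] = np.asarray(OUTCOMES, dtype=object)[idx]
    return out
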