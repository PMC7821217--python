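"""Random-effects meta-analysis of centre-specific metrics.

Centre-specific estimates are pooled with a normal-normal random-effects
model: between-centre variance tau^2 by REML (DerSimonian-Laird as a
non-iterative fallback), inverse-variance weights 1/(se_i^2 + tau^2), a
95% confidence interval for the pooled mean, and a 95% prediction
interval for a new centre's true value using the t-based formula with
k - 2 degrees of freedom (undefined for fewer than three centres).

AUCs and proportions are pooled on the logit scale; calibration
parameters and Net Benefit on the identity scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import expit, logit
from scipy.stats import norm, t as t_dist

from .metrics import UndefinedMetricError

__all__ = ["PooledMetric", "pool_random_effects", "centre_auc_se"]

_TRANSFORMS = {
    "identity": (lambda x: x, lambda x: x, lambda x, se: se),
    "log": (np.log, np.exp, lambda x, se: se / x),
    "logit": (logit, expit, lambda x, se: se / (x * (1.0 - x))),
}


@dataclass
class PooledMetric:
    """A meta-analysed centre-specific metric on its original scale."""

    estimate: float
    ci95: tuple[float, float]
    pi95: tuple[float, float]  # (nan, nan) when undefined (k < 3)
    tau2: float  # between-centre variance on the transformed scale
    k: int
    transform: str
    method: str  # "reml" | "dl" | "passthrough"
    centre_estimates: list[tuple[str, float, float]] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    @property
    def pi_defined(self) -> bool:
        return np.isfinite(self.pi95[0])


def _reml_tau2(y: np.ndarray, v: np.ndarray) -> tuple[float, str]:
    """Between-centre variance by REML; DerSimonian-Laird on failure."""
    k = len(y)

    def neg_restricted_ll(tau2):
        w = 1.0 / (v + tau2)
        mu = np.sum(w * y) / np.sum(w)
        return 0.5 * (
            np.sum(np.log(v + tau2))
            + np.log(np.sum(w))
            + np.sum(w * (y - mu) ** 2)
        )

    hi = max(np.var(y, ddof=1) * 4.0, v.max() * 4.0, 1e-4)
    res = minimize_scalar(neg_restricted_ll, bounds=(0.0, hi), method="bounded",
                          options={"xatol": 1e-10})
    if res.success:
        tau2 = float(res.x)
        # bounded search can stall at the upper bracket; fall back then
        if tau2 < 0.999 * hi:
            return max(tau2, 0.0), "reml"
    w = 1.0 / v
    mu = np.sum(w * y) / np.sum(w)
    q = np.sum(w * (y - mu) ** 2)
    c = np.sum(w) - np.sum(w**2) / np.sum(w)
    return max((q - (k - 1)) / c, 0.0), "dl"


def pool_random_effects(
    estimates: Sequence[float],
    ses: Sequence[float],
    transform: str = "identity",
    centres: Optional[Sequence[str]] = None,
) -> PooledMetric:
    """Pool centre-specific estimates with a random-effects model.

    Estimates and their standard errors are mapped to the stated scale
    (logit/log transforms use the delta method for the SEs), pooled, and
    the estimate, 95% CI and 95% prediction interval are mapped back.
    A single centre passes through with its own CI and an undefined PI;
    with two centres the PI is undefined and flagged.
    """
    if transform not in _TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}")
    fwd, inv, se_fwd = _TRANSFORMS[transform]
    y_raw = np.asarray(estimates, dtype=float)
    s_raw = np.asarray(ses, dtype=float)
    if y_raw.shape != s_raw.shape or y_raw.ndim != 1:
        raise ValueError("estimates and ses must be equal-length 1-d")
    if np.any(~np.isfinite(y_raw)) or np.any(~np.isfinite(s_raw)):
        raise ValueError("estimates and ses must be finite (exclude undefined centres first)")
    if np.any(s_raw <= 0):
        raise ValueError("standard errors must be positive")
    k = len(y_raw)
    if k == 0:
        raise UndefinedMetricError("no centres to pool")
    labels = [str(c) for c in centres] if centres is not None else [
        f"centre_{i + 1}" for i in range(k)
    ]
    centre_rows = list(zip(labels, y_raw.tolist(), s_raw.tolist()))
    z = norm.ppf(0.975)

    y = fwd(y_raw)
    s = se_fwd(y_raw, s_raw)

    if k == 1:
        est, se = float(y[0]), float(s[0])
        return PooledMetric(
            estimate=float(inv(est)),
            ci95=(float(inv(est - z * se)), float(inv(est + z * se))),
            pi95=(np.nan, np.nan),
            tau2=0.0,
            k=1,
            transform=transform,
            method="passthrough",
            centre_estimates=centre_rows,
            flags=["single_centre"],
        )

    v = s**2
    tau2, method = _reml_tau2(y, v)
    w = 1.0 / (v + tau2)
    mu = float(np.sum(w * y) / np.sum(w))
    se_mu = float(np.sqrt(1.0 / np.sum(w)))
    ci = (mu - z * se_mu, mu + z * se_mu)
    flags = []
    if k >= 3:
        t_mult = t_dist.ppf(0.975, df=k - 2)
        half = t_mult * np.sqrt(tau2 + se_mu**2)
        pi = (mu - half, mu + half)
    else:
        pi = (np.nan, np.nan)
        flags.append("pi_undefined_k_lt_3")
    return PooledMetric(
        estimate=float(inv(mu)),
        ci95=(float(inv(ci[0])), float(inv(ci[1]))),
        pi95=(float(inv(pi[0])), float(inv(pi[1]))) if k >= 3 else (np.nan, np.nan),
        tau2=float(tau2),
        k=k,
        transform=transform,
        method=method,
        centre_estimates=centre_rows,
        flags=flags,
    )


def centre_auc_se(risks: Sequence[float], is_event: Sequence[bool]) -> float:
    """Standard error of a centre's AUC by DeLong's estimator.

    Uses the empirical variances of the placement values (the per-event
    proportion of non-events ranked below it, and vice versa):
    var(AUC) = S_events/m + S_nonevents/n.  Returns nan (centre excluded
    from pooling) for degenerate class counts.
    """
    r = np.asarray(risks, dtype=float)
    ev = np.asarray(is_event, dtype=bool)
    x, y = r[ev], r[~ev]  # events, non-events
    m, n = len(x), len(y)
    if m < 2 or n < 2:
        return float("nan")
    ys = np.sort(y)
    # placement of each event among non-events, ties as 1/2
    vx = (
        np.searchsorted(ys, x, side="left")
        + 0.5 * (np.searchsorted(ys, x, side="right") - np.searchsorted(ys, x, side="left"))
    ) / n
    xs = np.sort(x)
    vy = (
        (m - np.searchsorted(xs, y, side="right"))
        + 0.5 * (np.searchsorted(xs, y, side="right") - np.searchsorted(xs, y, side="left"))
    ) / m
    var = np.var(vx, ddof=1) / m + np.var(vy, ddof=1) / n
    return float(np.sqrt(var))
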