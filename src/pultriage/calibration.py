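"""Calibration of estimated EP risks.

Reliability of a risk model is summarised by two recalibration parameters
estimated from logistic regression of the observed events on the logit of
the estimated risk, with random intercept and slope by centre to account
for clustering:

* calibration intercept ("calibration-in-the-large"): estimated with the
  slope fixed at 1 (the logit enters as an offset); negative values mean
  the risks are on average too high, positive too low;
* calibration slope: the fixed-effect coefficient of logit(risk); values
  below 1 mean the risks are too extreme, above 1 too moderate.

Random intercept and slope are independent Gaussians; the marginal
likelihood is maximised by Gauss-Hermite quadrature.  Smooth calibration
curves use logistic regression on a restricted-cubic-spline basis of
logit(risk).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.special import expit, logit
from scipy.stats import norm

__all__ = [
    "CalibrationResult",
    "fit_calibration",
    "smooth_calibration_curve",
    "clip_risks",
]

_RISK_EPS = 1e-6
_GH_POINTS = 13


def clip_risks(risks: np.ndarray) -> np.ndarray:
    """Clip risks into [1e-6, 1 - 1e-6] so the logit is finite."""
    return np.clip(np.asarray(risks, dtype=float), _RISK_EPS, 1.0 - _RISK_EPS)


@dataclass
class CalibrationResult:
    """Calibration intercept/slope with centre-level random effects.

    ``intercept`` is the slope-fixed-at-1 recalibration intercept;
    ``slope`` (and ``slope_model_intercept``) come from the joint
    intercept+slope model.  ``centre_effects`` maps centre to its
    (intercept, slope) random-effect deviations; ``curve`` is a smooth
    calibration curve on a risk grid.  ``flags`` records fallbacks
    (single centre, separation, convergence failure).
    """

    intercept: float
    slope: float
    intercept_ci: tuple[float, float]
    slope_ci: tuple[float, float]
    slope_model_intercept: float
    sd_intercept: float
    sd_slope: float
    centre_effects: dict[str, tuple[float, float]]
    curve: Optional[pd.DataFrame] = None
    flags: list[str] = field(default_factory=list)


def _bernoulli_loglik(eta: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Bernoulli log-likelihood, numerically safe."""
    # log p = -log(1 + exp(-eta)); log(1-p) = -log(1 + exp(eta))
    return np.where(
        y[:, None], -np.logaddexp(0.0, -eta), -np.logaddexp(0.0, eta)
    )


_GH_Z, _GH_W = np.polynomial.hermite.hermgauss(_GH_POINTS)
_GH_LOGW = np.log(_GH_W) + _GH_Z**2  # adaptive-GH log-weights


def _mode_1d(eta0: np.ndarray, y: np.ndarray, su: float) -> tuple[float, float]:
    """Laplace mode and curvature scale of one centre's random intercept."""
    u = 0.0
    for _ in range(25):
        p = expit(eta0 + u)
        grad = np.sum(y - p) - u / su**2
        hess = -np.sum(p * (1.0 - p)) - 1.0 / su**2
        step = grad / hess
        u -= step
        if abs(step) < 1e-10:
            break
    return u, 1.0 / np.sqrt(-hess)


def _mode_2d(
    eta0: np.ndarray, x: np.ndarray, y: np.ndarray, su: float, sv: float
) -> tuple[np.ndarray, np.ndarray]:
    """Joint Laplace mode and axis scales for random intercept + slope."""
    uv = np.zeros(2)
    H = -np.eye(2)
    for _ in range(40):
        p = expit(eta0 + uv[0] + uv[1] * x)
        r = y - p
        w = p * (1.0 - p)
        grad = np.array(
            [np.sum(r) - uv[0] / su**2, np.sum(r * x) - uv[1] / sv**2]
        )
        H = -np.array(
            [
                [np.sum(w) + 1.0 / su**2, np.sum(w * x)],
                [np.sum(w * x), np.sum(w * x**2) + 1.0 / sv**2],
            ]
        )
        step = np.linalg.solve(H, grad)
        uv -= step
        if np.max(np.abs(step)) < 1e-10:
            break
    cov = np.linalg.inv(-H)
    return uv, np.sqrt(np.clip(np.diag(cov), 1e-12, None))


def _centre_loglik_1d(eta0, y, su, return_posterior=False):
    """Adaptive-GH marginal log-likelihood of one centre (intercept only)."""
    from scipy.special import logsumexp

    mode, scale = _mode_1d(eta0, y, su)
    nodes = mode + np.sqrt(2.0) * scale * _GH_Z
    g = (
        _bernoulli_loglik(eta0[:, None] + nodes[None, :], y).sum(axis=0)
        - nodes**2 / (2.0 * su**2)
        - np.log(su)
        - 0.5 * np.log(2.0 * np.pi)
    )
    logterms = _GH_LOGW + g
    ll = np.log(np.sqrt(2.0) * scale) + logsumexp(logterms)
    if not return_posterior:
        return ll
    post = np.exp(logterms - logterms.max())
    post /= post.sum()
    return ll, float(post @ nodes)


def _centre_loglik_2d(eta0, x, y, su, sv, return_posterior=False):
    """Adaptive-GH marginal log-likelihood (random intercept and slope)."""
    from scipy.special import logsumexp

    mode, scales = _mode_2d(eta0, x, y, su, sv)
    un = mode[0] + np.sqrt(2.0) * scales[0] * _GH_Z
    vn = mode[1] + np.sqrt(2.0) * scales[1] * _GH_Z
    uu, vv = np.meshgrid(un, vn, indexing="ij")
    uf, vf = uu.ravel(), vv.ravel()
    eta = eta0[:, None] + uf[None, :] + vf[None, :] * x[:, None]
    g = (
        _bernoulli_loglik(eta, y).sum(axis=0)
        - uf**2 / (2.0 * su**2)
        - vf**2 / (2.0 * sv**2)
        - np.log(2.0 * np.pi * su * sv)
    )
    logw2 = (_GH_LOGW[:, None] + _GH_LOGW[None, :]).ravel()
    logterms = logw2 + g
    ll = np.log(2.0 * scales[0] * scales[1]) + logsumexp(logterms)
    if not return_posterior:
        return ll
    post = np.exp(logterms - logterms.max())
    post /= post.sum()
    return ll, (float(post @ uf), float(post @ vf))


def _mixed_logistic_loglik(
    params, y_by_centre, x_by_centre, off_by_centre, random_slope: bool
) -> float:
    if random_slope:
        a, b, log_su, log_sv = params
        su, sv = np.exp(log_su), np.exp(log_sv)
    else:
        a = params[0]
        b = params[1] if len(params) == 3 else None
        su = np.exp(params[-1])
    total = 0.0
    for yc, xc, oc in zip(y_by_centre, x_by_centre, off_by_centre):
        eta0 = a + oc + (b * xc if (not random_slope and b is not None) else 0.0)
        if random_slope:
            total += _centre_loglik_2d(a + oc + b * xc, xc, yc, su, sv)
        else:
            total += _centre_loglik_1d(eta0, yc, su)
    return total


def _fit_mixed_logistic(
    y: np.ndarray,
    centres: np.ndarray,
    x: Optional[np.ndarray] = None,
    offset: Optional[np.ndarray] = None,
    random_slope: bool = False,
):
    """ML fit of a logistic model with independent centre random effects.

    Fixed part: intercept plus optionally a slope on ``x``; ``offset``
    enters with coefficient 1.  Returns (params, se, centre_effects, flags)
    where params holds the fixed effects followed by log random-effect
    sds.
    """
    flags: list[str] = []
    off = np.zeros_like(y, dtype=float) if offset is None else offset
    labels = pd.unique(centres)
    y_by, x_by, o_by = [], [], []
    for c in labels:
        m = centres == c
        y_by.append(y[m])
        x_by.append((x[m] if x is not None else np.zeros(m.sum())))
        o_by.append(off[m])

    # starting values from the ordinary (fixed-effect) logistic fit
    X = np.ones((len(y), 1)) if x is None else np.column_stack([np.ones_like(x), x])
    glm = sm.GLM(y, X, family=sm.families.Binomial(), offset=off)
    try:
        glm_res = glm.fit(maxiter=200)
        start_fixed = np.asarray(glm_res.params, dtype=float)
        if np.any(np.abs(start_fixed) > 30):
            flags.append("separation")
            glm_res = glm.fit_regularized(alpha=1e-3, L1_wt=0.0)
            start_fixed = np.clip(np.asarray(glm_res.params), -30, 30)
    except Exception:
        flags.append("separation")
        start_fixed = np.zeros(X.shape[1])

    start = list(start_fixed) + [np.log(0.2)] + ([np.log(0.2)] if random_slope else [])

    def nll(p):
        return -_mixed_logistic_loglik(p, y_by, x_by, o_by, random_slope) + 1e-8 * (
            np.sum(np.asarray(p[: X.shape[1]]) ** 2)
        )

    res = minimize(nll, np.asarray(start), method="L-BFGS-B",
                   bounds=[(-30, 30)] * X.shape[1] + [(-7, 3)] * (len(start) - X.shape[1]))
    if not res.success:
        flags.append("convergence_failure")
        if random_slope:
            # fall back to intercept-only random effects
            params, se, eff, f2 = _fit_mixed_logistic(
                y, centres, x=x, offset=offset, random_slope=False
            )
            return params, se, eff, flags + f2 + ["random_slope_dropped"]
    params = res.x

    # Wald SEs for the fixed effects from a finite-difference Hessian
    nfix = X.shape[1]
    h = 1e-4
    H = np.zeros((nfix, nfix))
    for i in range(nfix):
        for j in range(i, nfix):
            pp = params.copy(); pp[i] += h; pp[j] += h
            pm = params.copy(); pm[i] += h; pm[j] -= h
            mp = params.copy(); mp[i] -= h; mp[j] += h
            mm = params.copy(); mm[i] -= h; mm[j] -= h
            H[i, j] = H[j, i] = (nll(pp) - nll(pm) - nll(mp) + nll(mm)) / (4 * h * h)
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(nfix, np.nan)
        flags.append("singular_hessian")

    # empirical-Bayes centre effects: posterior means on the adaptive grid
    if random_slope:
        a, b, log_su, log_sv = params
        su, sv = np.exp(log_su), np.exp(log_sv)
    else:
        a = params[0]
        b = params[1] if nfix == 2 else None
        su, sv = np.exp(params[-1]), 0.0
    effects = {}
    for c, yc, xc, oc in zip(labels, y_by, x_by, o_by):
        if random_slope:
            _, (eu, ev) = _centre_loglik_2d(
                a + oc + b * xc, xc, yc, su, sv, return_posterior=True
            )
            effects[str(c)] = (eu, ev)
        else:
            eta0 = a + oc + (b * xc if b is not None else 0.0)
            _, eu = _centre_loglik_1d(eta0, yc, su, return_posterior=True)
            effects[str(c)] = (eu, 0.0)
    return (params, (su, sv)), se, effects, flags


def fit_calibration(
    risks: Sequence[float],
    is_event: Sequence[bool],
    centres: Optional[Sequence[str]] = None,
    curve_grid: Optional[np.ndarray] = None,
) -> CalibrationResult:
    """Calibration intercept and slope of estimated EP risks.

    Fits logistic regressions of the events on logit(risk) with random
    intercept and slope by centre: the slope comes from the joint model,
    the intercept from a slope-fixed-at-1 (offset) model.  With a single
    centre (or ``centres=None``) both collapse to ordinary logistic
    recalibration and the result is flagged ``single_centre``.
    """
    risks = clip_risks(risks)
    y = np.asarray(is_event, dtype=bool).astype(float)
    if len(risks) != len(y):
        raise ValueError("risks and is_event must have equal length")
    x = logit(risks)
    z = norm.ppf(0.975)
    flags: list[str] = []

    if centres is None:
        centre_arr = np.zeros(len(y), dtype=object)
    else:
        centre_arr = np.asarray(centres, dtype=object)
    n_centres = len(pd.unique(centre_arr))

    if n_centres < 2:
        flags.append("single_centre")
        Xj = sm.add_constant(x)
        try:
            joint = sm.GLM(y, Xj, family=sm.families.Binomial()).fit(maxiter=200)
            jp, jse = np.asarray(joint.params), np.asarray(joint.bse)
            if np.any(np.abs(jp) > 30):
                raise ValueError("separation")
        except Exception:
            flags.append("separation")
            joint = sm.GLM(y, Xj, family=sm.families.Binomial()).fit_regularized(
                alpha=1e-3, L1_wt=0.0
            )
            jp = np.asarray(joint.params)
            jse = np.full(2, np.nan)
        itc = sm.GLM(y, np.ones((len(y), 1)), family=sm.families.Binomial(),
                     offset=x).fit(maxiter=200)
        a0, a0se = float(itc.params[0]), float(itc.bse[0])
        result = CalibrationResult(
            intercept=a0,
            slope=float(jp[1]),
            intercept_ci=(a0 - z * a0se, a0 + z * a0se),
            slope_ci=(float(jp[1] - z * jse[1]), float(jp[1] + z * jse[1])),
            slope_model_intercept=float(jp[0]),
            sd_intercept=0.0,
            sd_slope=0.0,
            centre_effects={},
            flags=flags,
        )
    else:
        (jp, (su_j, sv_j)), jse, eff_joint, f1 = _fit_mixed_logistic(
            y, centre_arr, x=x, random_slope=True
        )
        (ip, (su_i, _)), ise, eff_itc, f2 = _fit_mixed_logistic(
            y, centre_arr, offset=x, random_slope=False
        )
        flags += sorted(set(f1 + [f"intercept_model:{f}" for f in f2]))
        effects = {
            c: (eff_itc.get(c, (0.0, 0.0))[0], eff_joint.get(c, (0.0, 0.0))[1])
            for c in eff_joint
        }
        result = CalibrationResult(
            intercept=float(ip[0]),
            slope=float(jp[1]),
            intercept_ci=(float(ip[0] - z * ise[0]), float(ip[0] + z * ise[0])),
            slope_ci=(float(jp[1] - z * jse[1]), float(jp[1] + z * jse[1])),
            slope_model_intercept=float(jp[0]),
            sd_intercept=float(su_i),
            sd_slope=float(sv_j),
            centre_effects=effects,
            flags=flags,
        )

    if len(risks) >= 50 and len(np.unique(risks)) > 1:
        result.curve = smooth_calibration_curve(risks, y.astype(bool), curve_grid)
    return result


def _rcs_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Restricted (natural) cubic spline basis: linear tails beyond the
    boundary knots; k knots give k-1 columns (x plus k-2 nonlinear)."""
    k = len(knots)
    t1, tk, tk1 = knots[0], knots[-1], knots[-2]

    def plus3(v):
        return np.clip(v, 0.0, None) ** 3

    cols = [x]
    denom = (tk - t1) ** 2
    for j in range(k - 2):
        tj = knots[j]
        term = (
            plus3(x - tj)
            - plus3(x - tk1) * (tk - tj) / (tk - tk1)
            + plus3(x - tk) * (tk1 - tj) / (tk - tk1)
        ) / denom
        cols.append(term)
    return np.column_stack(cols)


def smooth_calibration_curve(
    risks: Sequence[float],
    is_event: Sequence[bool],
    grid: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Flexible estimate of P(event | estimated risk) on a risk grid.

    Logistic regression of the events on a restricted-cubic-spline basis
    of logit(risk) (5 knots at standard quantiles, degrading gracefully
    with fewer distinct values).  Returns a DataFrame with columns
    ``risk``, ``observed``, ``lower``, ``upper`` and ``extrapolated`` (set
    for grid points outside the observed risk range).  A well-calibrated
    model's curve lies on the diagonal up to simulation error.
    """
    risks = clip_risks(risks)
    y = np.asarray(is_event, dtype=bool).astype(float)
    if len(risks) < 50:
        raise ValueError("smooth calibration curves need at least 50 records")
    x = logit(risks)
    lo, hi = float(risks.min()), float(risks.max())
    if np.isclose(lo, hi):
        # degenerate constant-risk input: single-point curve, flagged
        return pd.DataFrame(
            {
                "risk": [lo],
                "observed": [float(y.mean())],
                "lower": [np.nan],
                "upper": [np.nan],
                "extrapolated": [False],
                "degenerate": [True],
            }
        )
    if grid is None:
        grid = np.linspace(
            float(np.quantile(risks, 0.01)), float(np.quantile(risks, 0.99)), 50
        )
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")

    for n_knots in (5, 4, 3):
        qs = np.linspace(0.05, 0.95, n_knots)
        knots = np.unique(np.quantile(x, qs))
        if len(knots) >= 3:
            break
    else:
        knots = None
    if knots is None or len(knots) < 3:
        X = sm.add_constant(x)
        Xg = sm.add_constant(logit(clip_risks(grid)))
    else:
        X = sm.add_constant(_rcs_basis(x, knots))
        Xg = sm.add_constant(_rcs_basis(logit(clip_risks(grid)), knots))
    res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
    pred = res.get_prediction(Xg).summary_frame(alpha=0.05)
    return pd.DataFrame(
        {
            "risk": grid,
            "observed": pred["mean"].to_numpy(),
            "lower": pred["mean_ci_lower"].to_numpy(),
            "upper": pred["mean_ci_upper"].to_numpy(),
            "extrapolated": (grid < lo) | (grid > hi),
        }
    )
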