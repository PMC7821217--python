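"""End-to-end external validation of PUL triage strategies.

The central objects follow the model/results idiom: build a
:class:`PULValidation` from a cohort DataFrame (or CSV) and an
:class:`AnalysisConfig`, call :meth:`~PULValidation.fit`, and read the
returned :class:`ValidationResults` (summary tables, forest-plot data,
decision curves, calibration).

The analysis order is fixed: eligibility filter (initial hCG must exceed
25 IU/l) -> protocol missingness rules -> multiple imputation with women
lost to follow-up included -> per-imputation strategy evaluation and
centre-specific metrics -> Rubin pooling within centre across
imputations -> random-effects meta-analysis across centres.  Calibration
is fitted across centres (random intercept and slope) within each
imputation and Rubin-pooled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import metrics as _metrics
from .calibration import fit_calibration
from .impute import apply_missingness_rules, impute_chained, rubin_pool
from .meta import centre_auc_se, pool_random_effects
from .models import (
    STEP1_PROGESTERONE_CUTOFF,
    STEP1_RISK_TRIPLE,
    CoefficientSet,
    predict_risks,
)
from .records import LTFU, OUTCOMES, read_cohort_csv, validate_cohort
from .utility import (
    DEFAULT_NB_THRESHOLDS,
    DecisionCurve,
    nb_bootstrap_se,
    net_benefit,
    pooled_decision_curve,
)

__all__ = [
    "AnalysisConfig",
    "PULValidation",
    "ValidationResults",
    "filter_eligible",
    "run_validation",
    "compare_strategies",
]

ALL_STRATEGIES = ("2ST", "M6P", "M6NP", "M4", "ratio_cutoffs")
#: strategies that produce risk estimates (ratio cut-offs classify only)
RISK_STRATEGIES = ("2ST", "M6P", "M6NP", "M4")

ELIGIBILITY_HCG_CUTOFF = 25.0  # IU/l, inclusive exclusion

_PROPORTION_METRICS = ("pct_low_risk", "sensitivity", "fpr", "ppv", "npv")
_LOGIT_METRICS = ("auc_ep", "auc_fpul_iup", "pdi") + _PROPORTION_METRICS


@dataclass
class AnalysisConfig:
    """Settings of a validation run.

    analysis_mode is one of ``primary`` (2-day hCG window, women lost to
    follow-up excluded after imputation), ``include_ltfu`` (they stay in
    with imputed outcomes) and ``window_1_3_days`` (1-3-day hCG window).
    ``metric_exclusions`` lists per-centre per-metric exclusions, e.g.
    ``[{"centre": "C05", "metric": "pct_low_risk"}]`` for a centre whose
    progesterone assay floor makes Step 1 unusable.
    """

    strategies: Sequence[str] = ALL_STRATEGIES
    threshold: float = 0.05
    analysis_mode: str = "primary"
    m_imputations: int = 100
    seed: int = 0
    coefficients: Optional[dict[str, CoefficientSet]] = None
    nb_thresholds: Sequence[float] = tuple(DEFAULT_NB_THRESHOLDS)
    nb_bootstrap: int = 2000
    n_burn: int = 20
    metric_exclusions: Sequence[dict] = field(default_factory=list)

    def __post_init__(self):
        unknown = set(self.strategies) - set(ALL_STRATEGIES)
        if unknown:
            raise ValueError(f"unknown strategies {sorted(unknown)}")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must be in (0,1)")
        if self.analysis_mode not in ("primary", "include_ltfu", "window_1_3_days"):
            raise ValueError(f"unknown analysis mode {self.analysis_mode!r}")
        if self.coefficients is None:
            self.coefficients = CoefficientSet.defaults()


def filter_eligible(cohort: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Exclude records with initial hCG at or below 25 IU/l.

    Below that level most urine pregnancy tests are negative, so such
    presentations fall outside the target population.  Returns the
    eligible cohort and an exclusion log with counts per reason.
    """
    cohort = validate_cohort(cohort)
    ineligible = cohort["hcg0"] <= ELIGIBILITY_HCG_CUTOFF
    log = {
        "n_input": int(len(cohort)),
        "excluded_hcg0_le_25": int(ineligible.sum()),
        "n_eligible": int((~ineligible).sum()),
    }
    return cohort.loc[~ineligible].reset_index(drop=True), log


def _strategy_eval(
    comp: pd.DataFrame, strategy: str, config: AnalysisConfig
) -> pd.DataFrame:
    """Risks and the high-risk decision for one strategy on one completed
    dataset.  Returns columns p_fpul/p_iup/p_ep (nan for the ratio
    cut-offs), high_risk, decided_by."""
    coefs = config.coefficients
    out = pd.DataFrame(index=comp.index)
    if strategy == "ratio_cutoffs":
        ratio = comp["hcg48"].to_numpy(dtype=float) / comp["hcg0"].to_numpy(dtype=float)
        from .models import RATIO_HIGH, RATIO_LOW

        in_band = (ratio >= RATIO_LOW) & (ratio <= RATIO_HIGH)
        out["p_fpul"] = np.nan
        out["p_iup"] = np.nan
        out["p_ep"] = np.nan
        out["high_risk"] = in_band
        out["decided_by"] = "ratio_cutoff"
        out["predicted_class"] = np.where(
            ratio < RATIO_LOW, "FPUL", np.where(ratio > RATIO_HIGH, "IUP", "EP_high_risk")
        )
        return out
    if strategy == "2ST":
        step1 = comp["prog0"].to_numpy(dtype=float) <= STEP1_PROGESTERONE_CUTOFF
        risks = predict_risks(comp, coefs["M6P"]).to_numpy()
        risks[step1] = STEP1_RISK_TRIPLE
        out[["p_fpul", "p_iup", "p_ep"]] = risks
        out["high_risk"] = risks[:, 2] >= config.threshold
        out["decided_by"] = np.where(step1, "step1_progesterone", "model_threshold")
        return out
    risks = predict_risks(comp, coefs[strategy])
    out[["p_fpul", "p_iup", "p_ep"]] = risks.to_numpy()
    out["high_risk"] = risks["p_ep"].to_numpy() >= config.threshold
    out["decided_by"] = "model_threshold"
    return out


def _pdi_jackknife_se(triples: np.ndarray, outcomes: np.ndarray) -> float:
    """Delete-one jackknife standard error of the PDI."""
    n = len(outcomes)
    counts = pd.Series(outcomes).value_counts()
    if any(counts.get(c, 0) < 2 for c in OUTCOMES):
        return float("nan")
    full_idx = np.arange(n)
    vals = np.empty(n)
    for i in range(n):
        keep = full_idx != i
        vals[i] = _metrics.pdi(triples[keep], outcomes[keep])
    return float(np.sqrt((n - 1) * np.mean((vals - vals.mean()) ** 2)))


def _prop_and_se(num: int, den: int) -> tuple[float, float]:
    """Proportion and its logit-scale-compatible SE (continuity-adjusted
    at the boundary)."""
    if den == 0:
        return float("nan"), float("nan")
    p = num / den
    p_adj = (num + 0.5) / (den + 1.0)
    se = float(np.sqrt(p_adj * (1.0 - p_adj) / den))
    return p, se


def _centre_metrics(
    comp: pd.DataFrame, ev: pd.DataFrame, strategy: str
) -> dict[str, tuple[float, float]]:
    """(estimate, se) of each validation metric for one centre and one
    completed dataset; nan marks an undefined metric."""
    outcomes = comp["outcome"].to_numpy(dtype=object)
    is_ep = outcomes == "EP"
    hr = ev["high_risk"].to_numpy(dtype=bool)
    res: dict[str, tuple[float, float]] = {}

    tab = _metrics.classification_table(hr, outcomes)
    n = len(outcomes)
    res["pct_low_risk"] = _prop_and_se(tab["n_low_risk"], n)
    res["sensitivity"] = _prop_and_se(tab["tp"], tab["tp"] + tab["fn"])
    res["fpr"] = _prop_and_se(tab["fp"], tab["fp"] + tab["tn"])
    res["ppv"] = _prop_and_se(tab["tp"], tab["tp"] + tab["fp"])
    res["npv"] = _prop_and_se(tab["tn"], tab["tn"] + tab["fn"])

    if strategy in RISK_STRATEGIES:
        triples = ev[["p_fpul", "p_iup", "p_ep"]].to_numpy(dtype=float)
        p_ep = triples[:, 2]
        if is_ep.any() and (~is_ep).any():
            res["auc_ep"] = (
                _metrics.auc_binary(p_ep, is_ep),
                centre_auc_se(p_ep, is_ep),
            )
        else:
            res["auc_ep"] = (float("nan"), float("nan"))
        mask_fi = np.isin(outcomes, ("FPUL", "IUP"))
        sub = outcomes[mask_fi]
        if (sub == "FPUL").any() and (sub == "IUP").any():
            denom = triples[mask_fi, 0] + triples[mask_fi, 1]
            cond = triples[mask_fi, 0] / denom
            res["auc_fpul_iup"] = (
                _metrics.auc_binary(cond, sub == "FPUL"),
                centre_auc_se(cond, sub == "FPUL"),
            )
        else:
            res["auc_fpul_iup"] = (float("nan"), float("nan"))
        if all((outcomes == c).any() for c in OUTCOMES):
            res["pdi"] = (
                _metrics.pdi(triples, outcomes),
                _pdi_jackknife_se(triples, outcomes),
            )
        else:
            res["pdi"] = (float("nan"), float("nan"))
    return res


def _rubin_transformed(
    values: np.ndarray, ses: np.ndarray, transform: str
) -> tuple[float, float]:
    """Rubin-pool (value, se) pairs across imputations on a transformed
    scale; returns (pooled estimate, pooled se) on the original scale."""
    ok = np.isfinite(values) & np.isfinite(ses)
    if not ok.any():
        return float("nan"), float("nan")
    v, s = values[ok], ses[ok]
    if len(v) == 1 or np.all(v == v[0]):
        # exact passthrough (keeps boundary proportions like 0 and 1 exact)
        return float(v[0]), float(np.sqrt(np.mean(s**2)))
    if transform == "logit":
        eps = 1e-6
        v = np.clip(v, eps, 1 - eps)
        s_t = np.clip(s, 1e-9, None) / (v * (1 - v))
        est_t, var_t, _ = rubin_pool(logit(v), s_t**2)
        est = float(expit(est_t))
        se = float(np.sqrt(var_t) * est * (1 - est))
        return est, se
    est_t, var_t, _ = rubin_pool(v, np.clip(s, 1e-9, None) ** 2)
    return float(est_t), float(np.sqrt(var_t))


@dataclass
class ValidationResults:
    """Pooled validation results with per-centre detail.

    ``metrics`` is tidy: strategy, metric, pooled estimate, 95% CI, 95%
    PI, tau2 and k.  ``per_centre`` holds the centre-level (Rubin-pooled)
    estimates behind each pooled row — the forest-plot data.
    ``calibration`` has one row per risk strategy; ``decision_curves``
    maps strategy to a pooled :class:`DecisionCurve`.
    """

    config: AnalysisConfig
    n_records: int
    n_centres: int
    exclusion_log: dict
    metrics: pd.DataFrame
    per_centre: pd.DataFrame
    calibration: pd.DataFrame
    calibration_curves: dict[str, pd.DataFrame]
    decision_curves: dict[str, DecisionCurve]
    step1_fraction: float
    imputation_log: dict

    def forest(self, metric: str, strategy: str) -> pd.DataFrame:
        """Forest-plot data: centre rows plus the pooled row (CI and PI)."""
        cent = self.per_centre.query(
            "metric == @metric and strategy == @strategy"
        )[["centre", "estimate", "lower", "upper"]].copy()
        pooled = self.metrics.query(
            "metric == @metric and strategy == @strategy"
        )
        if len(pooled):
            row = pooled.iloc[0]
            cent.loc[len(cent)] = ["POOLED", row["estimate"], row["ci_lower"], row["ci_upper"]]
            cent.loc[len(cent)] = ["PREDICTION", row["estimate"], row["pi_lower"], row["pi_upper"]]
        return cent.reset_index(drop=True)

    def summary(self) -> str:
        """Human-readable summary of the pooled validation results."""
        lines = [
            "External validation of PUL triage strategies",
            "=" * 60,
            f"records: {self.n_records}   centres: {self.n_centres}   "
            f"imputations: {self.config.m_imputations}   "
            f"mode: {self.config.analysis_mode}",
            f"EP-risk threshold: {self.config.threshold:.0%}   "
            f"Step 1 low-risk fraction: {self.step1_fraction:.1%}",
            "",
            "Discrimination (random-effects pooled across centres)",
            "-" * 60,
        ]
        disc = self.metrics[self.metrics["metric"].isin(["auc_ep", "auc_fpul_iup", "pdi"])]
        piv = disc.pivot(index="strategy", columns="metric", values="estimate")
        lines.append(piv.round(3).to_string())
        lines += ["", "Classification at the EP-risk threshold", "-" * 60]
        cls = self.metrics[self.metrics["metric"].isin(_PROPORTION_METRICS)]
        piv2 = cls.pivot(index="strategy", columns="metric", values="estimate")
        lines.append(piv2.reindex(columns=list(_PROPORTION_METRICS)).round(3).to_string())
        if len(self.calibration):
            lines += ["", "Calibration of the estimated EP risk", "-" * 60]
            lines.append(
                self.calibration.set_index("strategy")[
                    ["intercept", "slope"]
                ].round(3).to_string()
            )
        lines += ["", "Net Benefit at 5% (pooled)", "-" * 60]
        for strat, dc in self.decision_curves.items():
            row = dc.data.iloc[(dc.data["threshold"] - 0.05).abs().argmin()]
            lines.append(
                f"{strat:>14s}: model {row['nb_model']:+.4f}   "
                f"treat-all {row['nb_treat_all']:+.4f}   harmful: {bool(row['harmful'])}"
            )
        return "\n".join(lines)

    def to_csv_dir(self, path) -> None:
        """Write the tidy report bundle (CSV per table) to a directory."""
        import os

        os.makedirs(path, exist_ok=True)
        self.metrics.to_csv(os.path.join(path, "pooled_metrics.csv"), index=False)
        self.per_centre.to_csv(os.path.join(path, "per_centre_metrics.csv"), index=False)
        self.calibration.to_csv(os.path.join(path, "calibration.csv"), index=False)
        for strat, dc in self.decision_curves.items():
            dc.data.to_csv(
                os.path.join(path, f"decision_curve_{strat}.csv"), index=False
            )
        for strat, curve in self.calibration_curves.items():
            curve.to_csv(
                os.path.join(path, f"calibration_curve_{strat}.csv"), index=False
            )


class PULValidation:
    """External-validation model for a multi-centre PUL cohort.

    Parameters
    ----------
    cohort
        Cohort DataFrame in the package schema (see ``records``); raw, with
        protocol deviations still present — the eligibility filter and
        missingness rules are applied by :meth:`fit`.
    config
        :class:`AnalysisConfig`; defaults apply when omitted.
    """

    def __init__(self, cohort: pd.DataFrame, config: Optional[AnalysisConfig] = None):
        self.cohort = validate_cohort(cohort)
        self.config = config or AnalysisConfig()

    @classmethod
    def from_csv(cls, path, config: Optional[AnalysisConfig] = None) -> "PULValidation":
        return cls(read_cohort_csv(path), config=config)

    def fit(self) -> ValidationResults:
        cfg = self.config
        eligible, excl_log = filter_eligible(self.cohort)
        mode = "window_1_3_days" if cfg.analysis_mode == "window_1_3_days" else "primary"
        ruled = apply_missingness_rules(eligible, mode=mode)
        imps = impute_chained(
            ruled, m=cfg.m_imputations, seed=cfg.seed, n_burn=cfg.n_burn
        )
        completed = []
        for comp in imps.completed:
            if cfg.analysis_mode != "include_ltfu":
                comp = comp.loc[~comp["ltfu"]].reset_index(drop=True)
            # supplement-contaminated progesterone was discarded by the
            # rules and replaced by an imputed value, which IS usable
            comp = comp.assign(prog_supplement=False)
            completed.append(comp)
        n_records = len(completed[0])
        centres = pd.unique(completed[0]["centre_id"])
        excluded_pairs = {
            (e["centre"], e["metric"]) for e in cfg.metric_exclusions
        }

        # per-imputation, per-strategy, per-centre raw metrics
        per_centre_rows = []
        calib_rows = []
        curve_acc: dict[str, list[pd.DataFrame]] = {}
        nb_rows = []
        step1_fracs = []
        rng_nb = np.random.default_rng(np.random.SeedSequence([cfg.seed, 77]))
        store: dict[tuple, dict] = {}
        for i_imp, comp in enumerate(completed):
            for strategy in cfg.strategies:
                ev = _strategy_eval(comp, strategy, cfg)
                if strategy == "2ST":
                    step1_fracs.append(
                        float((ev["decided_by"] == "step1_progesterone").mean())
                    )
                for centre in centres:
                    m = (comp["centre_id"] == centre).to_numpy()
                    cm = _centre_metrics(comp.loc[m], ev.loc[m], strategy)
                    store[(strategy, centre, i_imp)] = cm
                if strategy in RISK_STRATEGIES:
                    cal = fit_calibration(
                        ev["p_ep"].to_numpy(),
                        (comp["outcome"] == "EP").to_numpy(),
                        comp["centre_id"].to_numpy(dtype=object),
                    )
                    calib_rows.append(
                        {
                            "strategy": strategy,
                            "imputation": i_imp,
                            "intercept": cal.intercept,
                            "intercept_se": (cal.intercept_ci[1] - cal.intercept_ci[0]) / 3.919928,
                            "slope": cal.slope,
                            "slope_se": (cal.slope_ci[1] - cal.slope_ci[0]) / 3.919928,
                            "sd_intercept": cal.sd_intercept,
                            "sd_slope": cal.sd_slope,
                            "flags": ";".join(cal.flags),
                        }
                    )
                    if cal.curve is not None:
                        curve_acc.setdefault(strategy, []).append(cal.curve)
                    # centre-level Net Benefit per threshold, with bootstrap SE
                    for centre in centres:
                        m = (comp["centre_id"] == centre).to_numpy()
                        risks_c = ev.loc[m, "p_ep"].to_numpy()
                        out_c = comp.loc[m, "outcome"].to_numpy(dtype=object)
                        is_ep_c = out_c == "EP"
                        nc = int(m.sum())
                        for t in cfg.nb_thresholds:
                            hr = risks_c >= t
                            tp = int((hr & is_ep_c).sum())
                            fp = int((hr & ~is_ep_c).sum())
                            nb = net_benefit(tp, fp, nc, t) if nc else np.nan
                            nb_all = net_benefit(
                                int(is_ep_c.sum()), int((~is_ep_c).sum()), nc, t
                            ) if nc else np.nan
                            se = nb_bootstrap_se(
                                risks_c, out_c, t,
                                n_boot=cfg.nb_bootstrap, rng=rng_nb,
                            ) if nc else np.nan
                            se_all = nb_bootstrap_se(
                                np.ones(nc), out_c, t,
                                n_boot=cfg.nb_bootstrap, rng=rng_nb,
                            ) if nc else np.nan
                            nb_rows.append(
                                {
                                    "strategy": strategy, "imputation": i_imp,
                                    "centre": centre, "threshold": float(t),
                                    "nb": nb, "se": se,
                                    "nb_all": nb_all, "se_all": se_all,
                                }
                            )

        # Rubin-pool per centre, then meta-analyse across centres
        metric_rows, centre_rows = [], []
        for strategy in cfg.strategies:
            metric_names = list(_LOGIT_METRICS) if strategy in RISK_STRATEGIES \
                else list(_PROPORTION_METRICS)
            for metric in metric_names:
                cents, ests, ses = [], [], []
                for centre in centres:
                    if (str(centre), metric) in excluded_pairs:
                        continue
                    vals = np.array(
                        [store[(strategy, centre, i)][metric][0] for i in range(len(completed))]
                    )
                    errs = np.array(
                        [store[(strategy, centre, i)][metric][1] for i in range(len(completed))]
                    )
                    est, se = _rubin_transformed(vals, errs, "logit")
                    if np.isfinite(est) and np.isfinite(se) and se > 0:
                        cents.append(str(centre))
                        # boundary proportions clipped for the logit pooling
                        ests.append(float(np.clip(est, 1e-6, 1 - 1e-6)))
                        ses.append(se)
                        z = 1.959964
                        ec = float(np.clip(est, 1e-6, 1 - 1e-6))
                        lo = expit(logit(ec) - z * se / (ec * (1 - ec)))
                        hi = expit(logit(ec) + z * se / (ec * (1 - ec)))
                        centre_rows.append(
                            {
                                "strategy": strategy, "metric": metric,
                                "centre": str(centre), "estimate": est,
                                "se": se, "lower": lo, "upper": hi,
                            }
                        )
                if not cents:
                    continue
                pooled = pool_random_effects(ests, ses, transform="logit", centres=cents)
                metric_rows.append(
                    {
                        "strategy": strategy, "metric": metric,
                        "estimate": pooled.estimate,
                        "ci_lower": pooled.ci95[0], "ci_upper": pooled.ci95[1],
                        "pi_lower": pooled.pi95[0], "pi_upper": pooled.pi95[1],
                        "tau2": pooled.tau2, "k": pooled.k,
                        "method": pooled.method,
                    }
                )

        # calibration: Rubin across imputations (identity scale)
        calib_df = pd.DataFrame(calib_rows)
        calib_out = []
        for strategy in [s for s in cfg.strategies if s in RISK_STRATEGIES]:
            sub = calib_df[calib_df["strategy"] == strategy]
            if not len(sub):
                continue
            itc, itc_var, itc_ci = rubin_pool(
                sub["intercept"].to_numpy(), sub["intercept_se"].to_numpy() ** 2
            )
            slp, slp_var, slp_ci = rubin_pool(
                sub["slope"].to_numpy(), sub["slope_se"].to_numpy() ** 2
            )
            calib_out.append(
                {
                    "strategy": strategy,
                    "intercept": itc, "intercept_lower": itc_ci[0],
                    "intercept_upper": itc_ci[1],
                    "slope": slp, "slope_lower": slp_ci[0],
                    "slope_upper": slp_ci[1],
                    "sd_intercept": float(sub["sd_intercept"].mean()),
                    "sd_slope": float(sub["sd_slope"].mean()),
                    "flags": ";".join(sorted(set(";".join(sub["flags"]).split(";")) - {""})),
                }
            )

        curves = {
            s: pd.concat(cs).groupby("risk", as_index=False)[
                ["observed", "lower", "upper"]
            ].mean()
            for s, cs in curve_acc.items()
        }

        # decision curves: Rubin within centre across imputations, then pool
        nb_df = pd.DataFrame(nb_rows)
        decision_curves = {}
        for strategy in [s for s in cfg.strategies if s in RISK_STRATEGIES]:
            sub = nb_df[nb_df["strategy"] == strategy]
            if not len(sub):
                continue
            long_rows = []
            for (centre, t), grp in sub.groupby(["centre", "threshold"]):
                nb_est, nb_se = _rubin_transformed(
                    grp["nb"].to_numpy(), grp["se"].to_numpy(), "identity"
                )
                all_est, all_se = _rubin_transformed(
                    grp["nb_all"].to_numpy(), grp["se_all"].to_numpy(), "identity"
                )
                long_rows.append(
                    {"centre": centre, "threshold": t, "strategy": "model",
                     "nb": nb_est, "se": max(nb_se, 1e-6)}
                )
                long_rows.append(
                    {"centre": centre, "threshold": t, "strategy": "treat_all",
                     "nb": all_est, "se": max(all_se, 1e-6)}
                )
                long_rows.append(
                    {"centre": centre, "threshold": t, "strategy": "treat_none",
                     "nb": 0.0, "se": 1e-6}
                )
            decision_curves[strategy] = pooled_decision_curve(pd.DataFrame(long_rows))

        return ValidationResults(
            config=cfg,
            n_records=n_records,
            n_centres=len(centres),
            exclusion_log=excl_log,
            metrics=pd.DataFrame(metric_rows),
            per_centre=pd.DataFrame(centre_rows),
            calibration=pd.DataFrame(calib_out),
            calibration_curves=curves,
            decision_curves=decision_curves,
            step1_fraction=float(np.mean(step1_fracs)) if step1_fracs else float("nan"),
            imputation_log=imps.method_log,
        )


def run_validation(
    cohort: pd.DataFrame, config: Optional[AnalysisConfig] = None
) -> ValidationResults:
    """Functional wrapper: ``PULValidation(cohort, config).fit()``."""
    return PULValidation(cohort, config=config).fit()


def compare_strategies(results: ValidationResults) -> pd.DataFrame:
    """Side-by-side ranking table of the evaluated strategies.

    One row per strategy: AUC for EP, sensitivity, FPR, NPV, PPV,
    percentage low risk, Net Benefit at 5% and a harm flag (NB below the
    best default strategy at 5%).
    """
    if len(results.config.strategies) < 2:
        raise ValueError("strategy comparison needs at least two strategies")
    rows = []
    met = results.metrics
    for strategy in results.config.strategies:
        row = {"strategy": strategy}
        for metric in ("auc_ep", "sensitivity", "fpr", "npv", "ppv", "pct_low_risk"):
            sel = met.query("strategy == @strategy and metric == @metric")
            row[metric] = float(sel["estimate"].iloc[0]) if len(sel) else float("nan")
        dc = results.decision_curves.get(strategy)
        if dc is not None:
            near = dc.data.iloc[(dc.data["threshold"] - 0.05).abs().argmin()]
            row["nb_at_5pct"] = float(near["nb_model"])
            row["nb_treat_all_at_5pct"] = float(near["nb_treat_all"])
            row["harmful_at_5pct"] = bool(near["harmful"])
        else:
            row["nb_at_5pct"] = float("nan")
            row["nb_treat_all_at_5pct"] = float("nan")
            row["harmful_at_5pct"] = False
        rows.append(row)
    return pd.DataFrame(rows).sort_values("auc_ep", ascending=False, ignore_index=True)
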