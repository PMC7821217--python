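"""Net Benefit and decision-curve analysis for the high-risk-EP call.

Net Benefit at risk threshold t is the net proportion of true positives:

    NB(t) = TP/n - (FP/n) * t / (1 - t)

i.e. the proportion of EPs classified high risk, corrected for the
proportion of false positives weighted by the threshold odds (a lower
threshold means a false positive is perceived as less harmful).  Decision
curves plot NB over a threshold range against the default strategies of
classifying everyone high risk ("treat all") and no one ("treat none",
identically 0); a model with lower NB than a default strategy is harmful
at that threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .models import InvalidThresholdError

__all__ = [
    "DEFAULT_NB_THRESHOLDS",
    "DecisionCurve",
    "net_benefit",
    "decision_curve",
    "nb_bootstrap_se",
    "pooled_decision_curve",
]

#: Threshold grid: 3% to 10% in steps of 0.5%.
DEFAULT_NB_THRESHOLDS = np.round(np.arange(0.03, 0.1001, 0.005), 4)


@dataclass
class DecisionCurve:
    """Net-benefit values of a model and the default strategies.

    ``data`` has one row per threshold with columns ``threshold``,
    ``nb_model``, ``nb_treat_all``, ``nb_treat_none`` and ``harmful``
    (model NB below the best default).  ``per_centre`` optionally holds
    centre-level curves in long form.
    """

    data: pd.DataFrame
    per_centre: Optional[pd.DataFrame] = None

    @property
    def thresholds(self) -> np.ndarray:
        return self.data["threshold"].to_numpy()


def _check_threshold(threshold: float) -> None:
    if not (0.0 < threshold < 1.0):
        raise InvalidThresholdError(
            f"risk threshold must be inside (0, 1), got {threshold!r}"
        )


def net_benefit(tp: int, fp: int, n: int, threshold: float) -> float:
    """Net proportion of true positives at a risk threshold."""
    _check_threshold(threshold)
    if tp < 0 or fp < 0 or tp + fp > n or n <= 0:
        raise ValueError(f"inconsistent counts tp={tp}, fp={fp}, n={n}")
    return tp / n - (fp / n) * threshold / (1.0 - threshold)


def decision_curve(
    ep_risks: Sequence[float],
    outcomes: Sequence[str],
    thresholds: Sequence[float] = DEFAULT_NB_THRESHOLDS,
) -> DecisionCurve:
    """Decision curve of a risk model on a cohort with known outcomes.

    At each threshold every record is reclassified from its estimated EP
    risk (not from a fixed 5% label) and Net Benefit is computed, along
    with the treat-all and treat-none defaults.
    """
    risks = np.asarray(ep_risks, dtype=float)
    outcomes = np.asarray(outcomes, dtype=object)
    if risks.shape != outcomes.shape:
        raise ValueError("ep_risks and outcomes must have equal length")
    is_ep = outcomes == "EP"
    n = len(risks)
    rows = []
    for t in np.asarray(thresholds, dtype=float):
        _check_threshold(t)
        hr = risks >= t
        tp = int((hr & is_ep).sum())
        fp = int((hr & ~is_ep).sum())
        nb = net_benefit(tp, fp, n, t)
        nb_all = net_benefit(int(is_ep.sum()), int((~is_ep).sum()), n, t)
        rows.append(
            {
                "threshold": t,
                "nb_model": nb,
                "nb_treat_all": nb_all,
                "nb_treat_none": 0.0,
                "harmful": nb < max(nb_all, 0.0),
            }
        )
    data = pd.DataFrame(rows).sort_values("threshold", ignore_index=True)
    return DecisionCurve(data=data)


def nb_bootstrap_se(
    ep_risks: Sequence[float],
    outcomes: Sequence[str],
    threshold: float,
    n_boot: int = 2000,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Within-centre bootstrap standard error of Net Benefit."""
    _check_threshold(threshold)
    rng = rng or np.random.default_rng(0)
    risks = np.asarray(ep_risks, dtype=float)
    is_ep = np.asarray(outcomes, dtype=object) == "EP"
    n = len(risks)
    hr = risks >= threshold
    tp_flag = (hr & is_ep).astype(float)
    fp_flag = (hr & ~is_ep).astype(float)
    w = threshold / (1.0 - threshold)
    idx = rng.integers(0, n, size=(n_boot, n))
    nbs = tp_flag[idx].mean(axis=1) - w * fp_flag[idx].mean(axis=1)
    return float(nbs.std(ddof=1))


def pooled_decision_curve(per_centre: pd.DataFrame) -> DecisionCurve:
    """Random-effects pooling of centre-level decision curves.

    ``per_centre`` is long-form with columns centre, threshold, strategy
    (``model``/``treat_all``/``treat_none``), nb and se.  Centres with an
    undefined NB (nan) at a threshold are excluded at that threshold and
    recorded in the ``n_centres`` column.
    """
    from .meta import pool_random_effects

    required = {"centre", "threshold", "strategy", "nb", "se"}
    if not required.issubset(per_centre.columns):
        raise ValueError(f"per_centre needs columns {sorted(required)}")
    rows = []
    for t, sub in per_centre.groupby("threshold"):
        row = {"threshold": float(t)}
        for strat, label in [
            ("model", "nb_model"),
            ("treat_all", "nb_treat_all"),
            ("treat_none", "nb_treat_none"),
        ]:
            ss = sub[sub["strategy"] == strat].dropna(subset=["nb"])
            if len(ss) == 0:
                row[label] = 0.0 if strat == "treat_none" else np.nan
                continue
            if strat == "treat_none":
                row[label] = 0.0  # identically zero by definition
                continue
            pooled = pool_random_effects(
                ss["nb"].to_numpy(), ss["se"].to_numpy(), transform="identity"
            )
            row[label] = pooled.estimate
            if strat == "model":
                row["n_centres"] = pooled.k
                row["lower"], row["upper"] = pooled.ci95
        row["harmful"] = row["nb_model"] < max(row["nb_treat_all"], 0.0)
        rows.append(row)
    data = pd.DataFrame(rows).sort_values("threshold", ignore_index=True)
    return DecisionCurve(data=data, per_centre=per_centre)
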