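"""Discrimination and classification metrics for polytomous risk models.

Binary AUC for EP versus the rest, pairwise AUC by the conditional-risk
method (restrict to two outcome categories and rank by the renormalised
risk of one of them), the polytomous discrimination index (PDI), and
threshold-based classification statistics with EP as the positive class.

Metrics with an empty denominator are reported as ``nan`` ("undefined"),
never coerced to 0; downstream pooling excludes them explicitly.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .records import OUTCOMES

__all__ = [
    "UndefinedMetricError",
    "auc_binary",
    "auc_conditional_pair",
    "pdi",
    "classification_table",
    "classification_metrics",
]


class UndefinedMetricError(ValueError):
    """The metric is undefined on this input (e.g. a single-class cohort)."""


def auc_binary(risks: Sequence[float], is_event: Sequence[bool]) -> float:
    """Area under the ROC curve as the Mann-Whitney concordance.

    Probability that a randomly chosen event outranks a randomly chosen
    non-event, counting ties as 1/2.
    """
    risks = np.asarray(risks, dtype=float)
    ev = np.asarray(is_event, dtype=bool)
    if risks.shape != ev.shape or risks.ndim != 1:
        raise ValueError("risks and is_event must be equal-length 1-d")
    if ev.all() or not ev.any():
        raise UndefinedMetricError("AUC needs at least one event and one non-event")
    return float(roc_auc_score(ev, risks))


def auc_conditional_pair(
    triples: np.ndarray,
    outcomes: Sequence[str],
    cat_a: str = "FPUL",
    cat_b: str = "IUP",
) -> float:
    """Pairwise AUC between two outcome categories by conditional risks.

    Restricts to records whose outcome is cat_a or cat_b, ranks by
    p_a / (p_a + p_b), and returns the binary AUC with cat_a as the event.
    """
    triples = np.asarray(triples, dtype=float)
    outcomes = np.asarray(outcomes, dtype=object)
    ia, ib = OUTCOMES.index(cat_a), OUTCOMES.index(cat_b)
    mask = (outcomes == cat_a) | (outcomes == cat_b)
    sub = triples[mask]
    denom = sub[:, ia] + sub[:, ib]
    if np.any(denom <= 0):
        raise ValueError(
            f"conditional risk undefined: p_{cat_a} + p_{cat_b} = 0 for a record"
        )
    return auc_binary(sub[:, ia] / denom, outcomes[mask] == cat_a)


def _pdi_one_category(own: np.ndarray, other1: np.ndarray, other2: np.ndarray) -> float:
    """Triplet proportion for one category.

    ``own``: the category-i risk assigned to category-i records; ``other1``
    and ``other2``: the category-i risk assigned to the records of the two
    other categories.  A triplet scores 1 when the category-i record is
    strictly highest, with ties at the maximum split equally.
    """
    s1, s2 = np.sort(other1), np.sort(other2)
    # counts of strictly-less and equal values in each comparison group
    l1 = np.searchsorted(s1, own, side="left")
    e1 = np.searchsorted(s1, own, side="right") - l1
    l2 = np.searchsorted(s2, own, side="left")
    e2 = np.searchsorted(s2, own, side="right") - l2
    # split 1/r over r records tied at the maximum: a tie with one other
    # record contributes 1/2, with both 1/3
    score = l1 * l2 + 0.5 * (e1 * l2 + l1 * e2) + (1.0 / 3.0) * e1 * e2
    return float(score.sum() / (len(own) * len(other1) * len(other2)))


def pdi(triples: np.ndarray, outcomes: Sequence[str]) -> float:
    """Polytomous discrimination index over (FPUL, IUP, EP).

    Over all triplets holding one record of each outcome category: for
    category i, the triplet scores 1 if the category-i record has the
    strictly highest estimated risk of outcome i, with ties at the maximum
    split equally among the tied records.  The PDI is the mean of the
    three category-specific triplet proportions: 1/3 is chance level, 1 is
    perfect discrimination.
    """
    triples = np.asarray(triples, dtype=float)
    outcomes = np.asarray(outcomes, dtype=object)
    groups = {}
    for cat in OUTCOMES:
        mask = outcomes == cat
        if not mask.any():
            raise UndefinedMetricError(f"PDI needs at least one {cat} record")
        groups[cat] = triples[mask]
    parts = []
    for i, cat in enumerate(OUTCOMES):
        others = [c for c in OUTCOMES if c != cat]
        parts.append(
            _pdi_one_category(
                groups[cat][:, i],
                groups[others[0]][:, i],
                groups[others[1]][:, i],
            )
        )
    return float(np.mean(parts))


def classification_table(
    high_risk: Sequence[bool], outcomes: Sequence[str]
) -> dict:
    """Confusion counts at the stated threshold, EP positive.

    ``n_low_risk`` equals tn + fn by construction.
    """
    hr = np.asarray(high_risk, dtype=bool)
    outcomes = np.asarray(outcomes, dtype=object)
    if np.any(~np.isin(outcomes, OUTCOMES)):
        raise ValueError("classification metrics need known outcomes (no LTFU)")
    is_ep = outcomes == "EP"
    tp = int((hr & is_ep).sum())
    fp = int((hr & ~is_ep).sum())
    fn = int((~hr & is_ep).sum())
    tn = int((~hr & ~is_ep).sum())
    return {"tp": tp, "fp": fp, "tn": tn, "fn": fn, "n_low_risk": tn + fn}


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def classification_metrics(
    high_risk: Sequence[bool], outcomes: Sequence[str]
) -> dict:
    """Threshold-based classification statistics, EP as the positive class.

    Returns pct_low_risk, sensitivity, fpr, ppv and npv; any statistic
    with an empty denominator is nan (undefined), not 0.
    """
    t = classification_table(high_risk, outcomes)
    n = t["tp"] + t["fp"] + t["tn"] + t["fn"]
    return {
        "pct_low_risk": _ratio(t["tn"] + t["fn"], n),
        "sensitivity": _ratio(t["tp"], t["tp"] + t["fn"]),
        "fpr": _ratio(t["fp"], t["fp"] + t["tn"]),
        "ppv": _ratio(t["tp"], t["tp"] + t["fp"]),
        "npv": _ratio(t["tn"], t["tn"] + t["fn"]),
    }
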