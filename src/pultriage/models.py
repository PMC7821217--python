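"""Multinomial PUL risk models and triage strategies.

The M4 and M6 families are multinomial logistic models over three final
outcomes (FPUL as reference, IUP, EP) with basis terms built from the
initial beta-hCG, the 48-hour hCG ratio and (for M6P) the initial
progesterone.  The engine is generic over basis terms: a model is data — a
:class:`CoefficientSet` loaded from a YAML/JSON config — so that the exact
published coefficients can be swapped in without code change.

Three triage strategies are provided:

* risk-threshold classification: high risk of EP iff the estimated EP
  probability is >= the threshold (default 5%);
* the two-step triage strategy (2ST): Step 1 discharges as low risk any
  woman with presenting progesterone <= 2 nmol/l, assigning the fixed risk
  triple (0.961, 0.022, 0.017); Step 2 applies M6P to the remainder;
* fixed hCG-ratio cut-offs: ratio < 0.87 -> FPUL, in [0.87, 1.66] ->
  high risk of EP, > 1.66 -> IUP, with no risk estimation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .records import (
    InvalidMeasurementError,
    MissingPredictorError,
    PULRecord,
)

__all__ = [
    "RiskTriple",
    "BasisTerm",
    "CoefficientSet",
    "TriageDecision",
    "StrategyInapplicableError",
    "InvalidThresholdError",
    "compute_hcg_ratio",
    "predict_multinomial",
    "predict_risks",
    "triage_2st",
    "classify_high_risk",
    "classify_hcg_ratio",
    "false_positives_per_true_positive",
    "STEP1_PROGESTERONE_CUTOFF",
    "STEP1_RISK_TRIPLE",
    "DEFAULT_EP_THRESHOLD",
    "RATIO_LOW",
    "RATIO_HIGH",
    "hcg_ratio_band",
]

# Step 1 of the two-step triage strategy: progesterone cut-off (nmol/l)
# and the fixed risk triple assigned below it.
STEP1_PROGESTERONE_CUTOFF = 2.0
STEP1_RISK_TRIPLE = (0.961, 0.022, 0.017)

#: Default EP-risk threshold for the high-risk classification.
DEFAULT_EP_THRESHOLD = 0.05

# hCG-ratio cut-offs: a 13% fall to a 66% rise over 48 h flags high EP risk.
RATIO_FALL_PCT = 13.0
RATIO_RISE_PCT = 66.0


def hcg_ratio_band() -> tuple[float, float]:
    """High-EP-risk hCG-ratio band implied by the percentage-change bounds.

    A fall of up to 13% and a rise of up to 66% over 48 hours translate to
    ratio endpoints (1 - 0.13, 1 + 0.66) = (0.87, 1.66).
    """
    return (1.0 - RATIO_FALL_PCT / 100.0, 1.0 + RATIO_RISE_PCT / 100.0)


RATIO_LOW, RATIO_HIGH = hcg_ratio_band()


class StrategyInapplicableError(ValueError):
    """The triage strategy cannot be applied to this record."""


class InvalidThresholdError(ValueError):
    """Risk threshold outside the open interval (0, 1)."""


@dataclass(frozen=True)
class RiskTriple:
    """Estimated probabilities of (FPUL, IUP, EP); simplex-constrained."""

    p_fpul: float
    p_iup: float
    p_ep: float

    def __post_init__(self) -> None:
        probs = (self.p_fpul, self.p_iup, self.p_ep)
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError(f"probabilities outside [0,1]: {probs}")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError(f"probabilities must sum to 1, got {sum(probs)!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.p_fpul, self.p_iup, self.p_ep])


#: Transformations available for basis terms.
_TRANSFORMS = {
    "one": lambda x: np.ones_like(x),
    "identity": lambda x: x,
    "log": np.log,
    "squared_log": lambda x: np.log(x) ** 2,
}

#: Predictor variables a basis term may reference.
_VARIABLES = ("one", "hcg0", "hcg_ratio", "prog0")


@dataclass(frozen=True)
class BasisTerm:
    """A named transformation of one predictor (or the intercept)."""

    name: str
    variable: str
    transform: str

    def __post_init__(self) -> None:
        if self.variable not in _VARIABLES:
            raise ValueError(f"unknown basis variable {self.variable!r}")
        if self.transform not in _TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}")

    def evaluate(self, values: np.ndarray) -> np.ndarray:
        return _TRANSFORMS[self.transform](np.asarray(values, dtype=float))


@dataclass
class CoefficientSet:
    """A multinomial logistic PUL model: basis terms plus coefficients.

    The reference category is FPUL (its linear predictor is 0); beta_iup
    and beta_ep are aligned to ``basis``.  Units are fixed: hCG in IU/l,
    progesterone in nmol/l — a config declaring other units is rejected.
    """

    model_name: str
    basis: list[BasisTerm]
    beta_iup: np.ndarray
    beta_ep: np.ndarray
    units: dict = field(
        default_factory=lambda: {"hcg": "IU/l", "progesterone": "nmol/l"}
    )

    def __post_init__(self) -> None:
        if self.model_name not in ("M4", "M6P", "M6NP"):
            raise ValueError(f"unknown model name {self.model_name!r}")
        self.beta_iup = np.asarray(self.beta_iup, dtype=float)
        self.beta_ep = np.asarray(self.beta_ep, dtype=float)
        k = len(self.basis)
        if self.beta_iup.shape != (k,) or self.beta_ep.shape != (k,):
            raise ValueError(
                "coefficient vectors must match the basis length "
                f"({k}): got {self.beta_iup.shape}, {self.beta_ep.shape}"
            )
        uses_prog = any(t.variable == "prog0" for t in self.basis)
        if self.model_name == "M6P" and not uses_prog:
            raise ValueError("M6P must include a progesterone term")
        if self.model_name in ("M4", "M6NP") and uses_prog:
            raise ValueError(f"{self.model_name} must not use progesterone")
        if self.units.get("hcg") != "IU/l" or (
            self.units.get("progesterone", "nmol/l") != "nmol/l"
        ):
            raise ValueError(
                "unit convention is fixed: hCG in IU/l, progesterone in "
                f"nmol/l; config declares {self.units}"
            )

    @property
    def required_variables(self) -> set[str]:
        return {t.variable for t in self.basis if t.variable != "one"}

    @classmethod
    def from_dict(cls, d: dict) -> "CoefficientSet":
        basis = [BasisTerm(**t) for t in d["basis"]]
        ref = d.get("reference", "FPUL")
        if ref != "FPUL":
            raise ValueError(f"reference category must be FPUL, got {ref!r}")
        return cls(
            model_name=d["model"],
            basis=basis,
            beta_iup=d["beta_iup"],
            beta_ep=d["beta_ep"],
            units=d.get("units", {"hcg": "IU/l", "progesterone": "nmol/l"}),
        )

    @classmethod
    def defaults(cls) -> dict[str, "CoefficientSet"]:
        """The shipped synthetic stand-in coefficient sets, keyed by name.

        These mimic the structure and qualitative behaviour of the
        published models on generator-like data; they are not the
        published coefficients (see the config file header).
        """
        from importlib.resources import files

        path = files("pultriage").joinpath(
            "config/coefficients_synthetic.yaml"
        )
        with path.open() as fh:
            raw = yaml.safe_load(fh)
        return {e["model"]: cls.from_dict(e) for e in raw["models"]}

    @classmethod
    def from_file(cls, path) -> dict[str, "CoefficientSet"]:
        """Load all models from a YAML or JSON config file.

        Returns a dict keyed by model name.
        """
        with open(path) as fh:
            raw = (
                json.load(fh) if str(path).endswith(".json") else yaml.safe_load(fh)
            )
        models = raw["models"] if isinstance(raw, dict) and "models" in raw else raw
        out = {}
        for entry in models:
            cs = cls.from_dict(entry)
            out[cs.model_name] = cs
        return out


@dataclass
class TriageDecision:
    """Low/high-risk label with provenance of which rule decided it."""

    label: str  # "low_risk" | "high_risk"
    decided_by: str  # "step1_progesterone" | "model_threshold" | "ratio_cutoff"
    risks: Optional[RiskTriple] = None
    predicted_outcome_class: Optional[str] = None  # ratio-cutoff strategy only
    model_used: Optional[str] = None

    def __post_init__(self) -> None:
        if self.label not in ("low_risk", "high_risk"):
            raise ValueError(f"bad label {self.label!r}")
        if self.decided_by not in (
            "step1_progesterone",
            "model_threshold",
            "ratio_cutoff",
        ):
            raise ValueError(f"bad decided_by {self.decided_by!r}")
        if self.decided_by == "ratio_cutoff" and self.risks is not None:
            raise ValueError("ratio-cutoff decisions carry no risk estimate")
        if self.decided_by == "step1_progesterone":
            expected = RiskTriple(*STEP1_RISK_TRIPLE)
            if self.risks != expected:
                raise ValueError("Step-1 decisions must carry the fixed triple")


def compute_hcg_ratio(hcg0: float, hcg48: float) -> float:
    """hCG ratio: 48-hour beta-hCG divided by the presenting beta-hCG."""
    if not (hcg0 > 0) or not (hcg48 > 0):
        raise InvalidMeasurementError(
            f"hCG levels must be positive, got hcg0={hcg0!r}, hcg48={hcg48!r}"
        )
    return hcg48 / hcg0


def _basis_matrix(coefs: CoefficientSet, values: dict[str, np.ndarray]) -> np.ndarray:
    cols = []
    for term in coefs.basis:
        if term.variable == "one":
            n = len(next(iter(values.values()))) if values else 1
            cols.append(np.ones(n))
            continue
        x = values[term.variable]
        col = term.evaluate(x)
        if not np.all(np.isfinite(col)):
            raise InvalidMeasurementError(
                f"non-finite value for basis term {term.name!r}"
            )
        cols.append(col)
    return np.column_stack(cols)


def predict_risks(
    cohort: pd.DataFrame, coefs: CoefficientSet
) -> pd.DataFrame:
    """Vectorised multinomial prediction for a complete cohort.

    Every record must have the predictors the basis requires (hcg48 for the
    ratio; prog0 present and no supplements for progesterone models).
    Returns a DataFrame with columns p_fpul, p_iup, p_ep aligned to the
    cohort index.
    """
    needed = coefs.required_variables
    values: dict[str, np.ndarray] = {}
    n = len(cohort)
    if "hcg0" in needed or "hcg_ratio" in needed:
        values["hcg0"] = cohort["hcg0"].to_numpy(dtype=float)
    if "hcg_ratio" in needed:
        h48 = cohort["hcg48"].to_numpy(dtype=float)
        if np.isnan(h48).any():
            raise MissingPredictorError(
                "hcg48 missing for some records; model "
                f"{coefs.model_name} requires the hCG ratio"
            )
        values["hcg_ratio"] = h48 / values["hcg0"]
    if "prog0" in needed:
        prog = cohort["prog0"].to_numpy(dtype=float)
        if np.isnan(prog).any():
            raise MissingPredictorError(
                f"prog0 missing for some records; model {coefs.model_name} "
                "requires progesterone"
            )
        if cohort["prog_supplement"].to_numpy(dtype=bool).any():
            raise MissingPredictorError(
                "progesterone unreliable under supplements; "
                f"model {coefs.model_name} is inapplicable"
            )
        values["prog0"] = prog
    if not values:  # intercept-only basis
        values = {"one": np.ones(n)}
    X = _basis_matrix(coefs, values)
    eta = np.column_stack(
        [np.zeros(len(X)), X @ coefs.beta_iup, X @ coefs.beta_ep]
    )
    eta -= eta.max(axis=1, keepdims=True)  # softmax, overflow-safe
    ex = np.exp(eta)
    probs = ex / ex.sum(axis=1, keepdims=True)
    return pd.DataFrame(
        probs, columns=["p_fpul", "p_iup", "p_ep"], index=cohort.index
    )


def predict_multinomial(record: PULRecord, coefs: CoefficientSet) -> RiskTriple:
    """Evaluate a multinomial PUL model on one record.

    Forms linear predictors eta_IUP, eta_EP against the FPUL reference
    (eta_FPUL = 0) and softmax-normalises them into a RiskTriple.
    """
    needed = coefs.required_variables
    if "hcg_ratio" in needed and record.hcg48 is None:
        raise MissingPredictorError(
            f"record {record.record_id}: hcg48 missing, required by "
            f"{coefs.model_name}"
        )
    if "prog0" in needed:
        if record.prog0 is None:
            raise MissingPredictorError(
                f"record {record.record_id}: prog0 missing, required by "
                f"{coefs.model_name}"
            )
        if record.prog_supplement:
            raise MissingPredictorError(
                f"record {record.record_id}: progesterone supplements make "
                f"prog0 unreliable for {coefs.model_name}"
            )
    from .records import cohort_from_records

    probs = predict_risks(cohort_from_records([record]), coefs)
    p = probs.iloc[0]
    return RiskTriple(p_fpul=p["p_fpul"], p_iup=p["p_iup"], p_ep=p["p_ep"])


def classify_high_risk(
    risks: RiskTriple, threshold: float = DEFAULT_EP_THRESHOLD
) -> str:
    """'high_risk' iff the estimated EP probability is >= the threshold."""
    if not (0.0 < threshold < 1.0):
        raise InvalidThresholdError(f"threshold must be in (0,1), got {threshold}")
    return "high_risk" if risks.p_ep >= threshold else "low_risk"


def triage_2st(
    record: PULRecord,
    coefs_m6p: CoefficientSet,
    threshold: float = DEFAULT_EP_THRESHOLD,
) -> TriageDecision:
    """Two-step triage.

    Step 1: presenting progesterone <= 2 nmol/l discharges the woman as low
    risk with the fixed risk triple (0.961, 0.022, 0.017) taken from the
    M6 development data.  Step 2: M6P estimates the risks and the EP-risk
    threshold decides.  The multinomial model is never evaluated for Step-1
    cases.
    """
    if record.prog0 is None or record.prog_supplement:
        raise StrategyInapplicableError(
            f"record {record.record_id}: Step 1 needs a reliable presenting "
            "progesterone (missing or on supplements)"
        )
    if record.prog0 <= STEP1_PROGESTERONE_CUTOFF:
        return TriageDecision(
            label="low_risk",
            decided_by="step1_progesterone",
            risks=RiskTriple(*STEP1_RISK_TRIPLE),
        )
    risks = predict_multinomial(record, coefs_m6p)
    return TriageDecision(
        label=classify_high_risk(risks, threshold),
        decided_by="model_threshold",
        risks=risks,
        model_used=coefs_m6p.model_name,
    )


def classify_hcg_ratio(ratio: float) -> TriageDecision:
    """Classify by fixed hCG-ratio cut-offs, without risk estimation.

    ratio < 0.87 -> FPUL (low risk); 0.87 <= ratio <= 1.66 -> high risk of
    EP; ratio > 1.66 -> IUP (low risk).  The band is inclusive at both
    endpoints, forced by the strict inequalities of the complementary
    rules.
    """
    if not (ratio > 0) or not np.isfinite(ratio):
        raise InvalidMeasurementError(f"hCG ratio must be positive, got {ratio!r}")
    if ratio < RATIO_LOW:
        cls = "FPUL"
    elif ratio > RATIO_HIGH:
        cls = "IUP"
    else:
        cls = "EP_high_risk"
    return TriageDecision(
        label="high_risk" if cls == "EP_high_risk" else "low_risk",
        decided_by="ratio_cutoff",
        predicted_outcome_class=cls,
    )


def false_positives_per_true_positive(
    threshold: float = DEFAULT_EP_THRESHOLD,
) -> float:
    """False positives tolerated per correctly identified EP at a threshold.

    Classifying at risk threshold t implies accepting up to (1 - t)/t false
    positives per true positive; at the default 5% threshold this is 19.
    """
    if not (0.0 < threshold < 1.0):
        raise InvalidThresholdError(f"threshold must be in (0,1), got {threshold}")
    return (1.0 - threshold) / threshold
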