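"""Risk-model engine and triage strategies."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pultriage import (
    CoefficientSet,
    PULRecord,
    RiskTriple,
    classify_hcg_ratio,
    classify_high_risk,
    compute_hcg_ratio,
    predict_multinomial,
    predict_risks,
    triage_2st,
)
from pultriage.models import (
    STEP1_RISK_TRIPLE,
    BasisTerm,
    InvalidThresholdError,
    StrategyInapplicableError,
)
from pultriage.records import InvalidMeasurementError, MissingPredictorError


def _record(**kw):
    base = dict(
        record_id="r1", centre_id="c1", hcg0=500.0, hcg48=450.0,
        interval_days=2, prog0=10.0,
    )
    base.update(kw)
    return PULRecord(**base)


def _intercept_only(beta_iup, beta_ep):
    return CoefficientSet(
        model_name="M4",
        basis=[BasisTerm("intercept", "one", "one")],
        beta_iup=[beta_iup],
        beta_ep=[beta_ep],
    )


class TestHcgRatio:
    @pytest.mark.parametrize(
        "hcg0, hcg48, expected",
        [(1000, 870, 0.87), (500, 500, 1.0), (174, 1534, 1534 / 174)],
    )
    def test_quotient(self, hcg0, hcg48, expected):
        assert compute_hcg_ratio(hcg0, hcg48) == pytest.approx(expected)

    @pytest.mark.parametrize("hcg0, hcg48", [(0, 100), (100, 0), (-5, 100)])
    def test_nonpositive_rejected(self, hcg0, hcg48):
        with pytest.raises(InvalidMeasurementError):
            compute_hcg_ratio(hcg0, hcg48)


class TestPredictMultinomial:
    def test_zero_coefficients_give_uniform(self):
        triple = predict_multinomial(_record(), _intercept_only(0.0, 0.0))
        assert triple.as_array() == pytest.approx([1 / 3, 1 / 3, 1 / 3])

    def test_intercept_log2_gives_quarter_half_quarter(self):
        triple = predict_multinomial(_record(), _intercept_only(np.log(2), 0.0))
        assert triple.as_array() == pytest.approx([0.25, 0.50, 0.25])

    def test_huge_ep_intercept_saturates(self):
        triple = predict_multinomial(_record(), _intercept_only(0.0, 100.0))
        assert triple.p_ep > 0.999

    def test_missing_ratio_names_field(self, coefs):
        with pytest.raises(MissingPredictorError, match="hcg48"):
            predict_multinomial(
                _record(hcg48=None, interval_days=None), coefs["M6NP"]
            )

    def test_missing_progesterone_rejected_for_m6p(self, coefs):
        with pytest.raises(MissingPredictorError, match="prog0"):
            predict_multinomial(_record(prog0=None), coefs["M6P"])
        with pytest.raises(MissingPredictorError):
            predict_multinomial(_record(prog_supplement=True), coefs["M6P"])

    @given(
        b_iup=st.lists(st.floats(-3, 3), min_size=4, max_size=4),
        b_ep=st.lists(st.floats(-3, 3), min_size=4, max_size=4),
        hcg0=st.floats(30, 1e5),
        ratio=st.floats(0.02, 6.0),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_simplex_invariant(self, b_iup, b_ep, hcg0, ratio):
        """Softmax output is a probability triple for any coefficients."""
        coefs = CoefficientSet(
            model_name="M6NP",
            basis=[
                BasisTerm("intercept", "one", "one"),
                BasisTerm("log_hcg0", "hcg0", "log"),
                BasisTerm("log_ratio", "hcg_ratio", "log"),
                BasisTerm("log_ratio_sq", "hcg_ratio", "squared_log"),
            ],
            beta_iup=b_iup,
            beta_ep=b_ep,
        )
        rec = _record(hcg0=hcg0, hcg48=hcg0 * ratio)
        triple = predict_multinomial(rec, coefs)  # RiskTriple validates itself
        assert abs(sum(triple.as_array()) - 1.0) < 1e-9

    def test_vectorised_matches_record_level(self, coefs, small_cohort):
        probs = predict_risks(small_cohort.head(20), coefs["M6P"])
        from pultriage.records import record_from_row

        for idx, row in small_cohort.head(20).iterrows():
            triple = predict_multinomial(record_from_row(row), coefs["M6P"])
            assert probs.loc[idx].to_numpy() == pytest.approx(
                triple.as_array(), abs=1e-12
            )


class TestCoefficientConfig:
    def test_progesterone_structure_enforced(self):
        with pytest.raises(ValueError, match="progesterone"):
            CoefficientSet(
                model_name="M6P",
                basis=[BasisTerm("intercept", "one", "one")],
                beta_iup=[0.0],
                beta_ep=[0.0],
            )
        with pytest.raises(ValueError, match="progesterone"):
            CoefficientSet(
                model_name="M4",
                basis=[BasisTerm("log_prog0", "prog0", "log")],
                beta_iup=[0.0],
                beta_ep=[0.0],
            )

    def test_foreign_units_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            CoefficientSet(
                model_name="M4",
                basis=[BasisTerm("intercept", "one", "one")],
                beta_iup=[0.0],
                beta_ep=[0.0],
                units={"hcg": "mIU/ml", "progesterone": "ng/ml"},
            )

    def test_shipped_config_loads(self, coefs):
        assert set(coefs) == {"M4", "M6P", "M6NP"}
        assert "prog0" in coefs["M6P"].required_variables
        assert "prog0" not in coefs["M6NP"].required_variables


class TestTwoStepTriage:
    @pytest.mark.parametrize("prog0", [1.5, 2.0])
    def test_step1_fixed_triple(self, coefs, prog0):
        """At or below 2 nmol/l the fixed development-data triple applies."""
        dec = triage_2st(_record(prog0=prog0), coefs["M6P"])
        assert dec.label == "low_risk"
        assert dec.decided_by == "step1_progesterone"
        assert dec.risks.as_array() == pytest.approx([0.961, 0.022, 0.017])

    def test_step1_never_calls_model(self, coefs):
        """Step-1 discharge must not evaluate M6P (no second sample needed)."""
        dec = triage_2st(
            _record(prog0=1.0, hcg48=None, interval_days=None), coefs["M6P"]
        )
        assert dec.risks.as_array() == pytest.approx(STEP1_RISK_TRIPLE)

    def test_step2_threshold_inclusive(self):
        # config putting p_ep exactly at 5%: softmax(0, ln 18, 0)
        coefs = CoefficientSet(
            model_name="M6P",
            basis=[
                BasisTerm("intercept", "one", "one"),
                BasisTerm("log_prog0", "prog0", "log"),
            ],
            beta_iup=[np.log(0.90 / 0.05), 0.0],
            beta_ep=[0.0, 0.0],
        )
        dec = triage_2st(_record(prog0=10.0), coefs)
        assert dec.risks.p_ep == pytest.approx(0.05)
        assert dec.label == "high_risk"

    def test_inapplicable_without_reliable_progesterone(self, coefs):
        with pytest.raises(StrategyInapplicableError):
            triage_2st(_record(prog0=None), coefs["M6P"])
        with pytest.raises(StrategyInapplicableError):
            triage_2st(_record(prog_supplement=True), coefs["M6P"])


class TestHighRiskThreshold:
    @pytest.mark.parametrize(
        "p_ep, expected",
        [(0.05, "high_risk"), (0.049, "low_risk"), (0.017, "low_risk")],
    )
    def test_inclusive_threshold(self, p_ep, expected):
        triple = RiskTriple(p_fpul=1 - p_ep - 0.01, p_iup=0.01, p_ep=p_ep)
        assert classify_high_risk(triple) == expected

    def test_invalid_threshold(self):
        triple = RiskTriple(0.9, 0.05, 0.05)
        for bad in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(InvalidThresholdError):
                classify_high_risk(triple, threshold=bad)

    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_in_ep_risk(self, a, b):
        """Raising the EP risk can only move low_risk -> high_risk."""
        lo, hi = sorted([a, b])
        t_lo = RiskTriple(1 - lo, 0.0, lo)
        t_hi = RiskTriple(1 - hi, 0.0, hi)
        if classify_high_risk(t_lo) == "high_risk":
            assert classify_high_risk(t_hi) == "high_risk"


class TestRatioCutoffs:
    @pytest.mark.parametrize(
        "ratio, cls, label",
        [
            (0.5, "FPUL", "low_risk"),
            (0.87, "EP_high_risk", "high_risk"),
            (1.0, "EP_high_risk", "high_risk"),
            (1.66, "EP_high_risk", "high_risk"),
            (2.0, "IUP", "low_risk"),
        ],
    )
    def test_band(self, ratio, cls, label):
        dec = classify_hcg_ratio(ratio)
        assert dec.predicted_outcome_class == cls
        assert dec.label == label
        assert dec.risks is None

    def test_nonpositive_rejected(self):
        with pytest.raises(InvalidMeasurementError):
            classify_hcg_ratio(0.0)

    @given(st.floats(1e-6, 50.0))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_partition_exhaustive(self, ratio):
        """Every positive ratio lands in exactly one class."""
        dec = classify_hcg_ratio(ratio)
        assert dec.predicted_outcome_class in ("FPUL", "EP_high_risk", "IUP")
        expected = (
            "FPUL" if ratio < 0.87 else "IUP" if ratio > 1.66 else "EP_high_risk"
        )
        assert dec.predicted_outcome_class == expected
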