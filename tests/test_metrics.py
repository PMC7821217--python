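"""Discrimination and classification metrics against brute-force oracles."""

import itertools

import numpy as np
import pytest

from pultriage import auc_binary, auc_conditional_pair, classification_metrics, pdi
from pultriage.metrics import UndefinedMetricError, classification_table

OUTCOMES = ("FPUL", "IUP", "EP")


def auc_pair_counting(risks, is_event):
    """Exhaustive Mann-Whitney pair enumeration (ties count 1/2)."""
    risks = np.asarray(risks, float)
    ev = np.asarray(is_event, bool)
    x, y = risks[ev], risks[~ev]
    total = 0.0
    for xi in x:
        for yj in y:
            total += 1.0 if xi > yj else 0.5 if xi == yj else 0.0
    return total / (len(x) * len(y))


def pdi_triplet_enumeration(triples, outcomes):
    """Exhaustive O(n^3) triplet scoring with fractional tie splitting."""
    triples = np.asarray(triples, float)
    outcomes = np.asarray(outcomes, object)
    idx = {c: np.flatnonzero(outcomes == c) for c in OUTCOMES}
    parts = []
    for i, cat in enumerate(OUTCOMES):
        score, count = 0.0, 0
        for a in idx[cat]:
            others = [c for c in OUTCOMES if c != cat]
            for b in idx[others[0]]:
                for c in idx[others[1]]:
                    vals = [triples[a, i], triples[b, i], triples[c, i]]
                    top = max(vals)
                    if triples[a, i] == top:
                        score += 1.0 / vals.count(top)
                    count += 1
        parts.append(score / count)
    return float(np.mean(parts))


class TestAucBinary:
    def test_perfect_separation(self):
        assert auc_binary([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_tied_is_half(self):
        assert auc_binary([0.3] * 6, [1, 1, 0, 0, 0, 0]) == 0.5

    def test_four_record_example(self):
        # events at 0.35 and 0.8 vs non-events at 0.1 and 0.4: 3 of 4
        # pairs concordant
        assert auc_binary([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            auc_binary([0.1, 0.2], [1, 1])

    def test_matches_pair_counting_oracle(self, rng):
        """Exact agreement with exhaustive pair enumeration, 200 cohorts."""
        for _ in range(200):
            n = rng.integers(4, 31)
            risks = rng.choice([0.1, 0.25, 0.5, 0.7, 0.9], size=n)
            ev = rng.random(n) < 0.4
            if ev.all() or not ev.any():
                continue
            assert auc_binary(risks, ev) == pytest.approx(
                auc_pair_counting(risks, ev), abs=1e-12
            )

    def test_order_invariance(self, rng):
        risks = rng.random(40)
        ev = rng.random(40) < 0.3
        ev[0] = True
        ev[1] = False
        perm = rng.permutation(40)
        assert auc_binary(risks, ev) == pytest.approx(
            auc_binary(risks[perm], ev[perm]), abs=1e-12
        )


class TestConditionalPairAuc:
    def test_perfect(self):
        triples = np.array(
            [[0.8, 0.1, 0.1], [0.7, 0.2, 0.1], [0.2, 0.7, 0.1], [0.1, 0.8, 0.1]]
        )
        out = ["FPUL", "FPUL", "IUP", "IUP"]
        assert auc_conditional_pair(triples, out) == 1.0

    def test_uniform_is_half(self):
        triples = np.full((6, 3), 1 / 3)
        out = ["FPUL"] * 3 + ["IUP"] * 3
        assert auc_conditional_pair(triples, out) == 0.5

    def test_pair_enumeration_example(self):
        # conditional FPUL risks {0.8, 0.6} vs {0.7, 0.2}: 3 of 4 pairs
        def t(c):  # triple with p_fpul/(p_fpul+p_iup) = c
            return [c * 0.9, (1 - c) * 0.9, 0.1]

        triples = np.array([t(0.8), t(0.6), t(0.7), t(0.2)])
        out = ["FPUL", "FPUL", "IUP", "IUP"]
        assert auc_conditional_pair(triples, out) == pytest.approx(0.75)

    def test_ep_records_ignored(self, rng):
        triples = rng.dirichlet([1, 1, 1], size=20)
        out = np.array(["FPUL", "IUP"] * 10, dtype=object)
        base = auc_conditional_pair(triples, out)
        extra = np.vstack([triples, rng.dirichlet([1, 1, 1], size=5)])
        out2 = np.concatenate([out, ["EP"] * 5])
        assert auc_conditional_pair(extra, out2) == pytest.approx(base)


class TestPdi:
    def test_identical_triples_chance_level(self):
        triples = np.tile([0.5, 0.3, 0.2], (9, 1))
        out = ["FPUL", "IUP", "EP"] * 3
        assert pdi(triples, out) == pytest.approx(1 / 3)

    def test_dominant_own_category_is_one(self):
        triples = np.array(
            [[0.9, 0.05, 0.05], [0.05, 0.9, 0.05], [0.05, 0.05, 0.9]] * 2
        )
        out = ["FPUL", "IUP", "EP"] * 2
        assert pdi(triples, out) == 1.0

    def test_six_record_enumeration(self, rng):
        triples = rng.dirichlet([2, 2, 2], size=6)
        out = ["FPUL", "FPUL", "IUP", "IUP", "EP", "EP"]
        assert pdi(triples, out) == pytest.approx(
            pdi_triplet_enumeration(triples, out), abs=1e-12
        )

    def test_matches_triplet_oracle_random_cohorts(self, rng):
        """Sort/count aggregation equals O(n^3) enumeration, with ties."""
        for _ in range(40):
            sizes = rng.integers(1, 11, size=3)
            out = np.repeat(OUTCOMES, sizes)
            # coarse grid of probabilities to force plenty of ties
            raw = rng.choice([0.2, 0.3, 0.5], size=(sizes.sum(), 3))
            triples = raw / raw.sum(axis=1, keepdims=True)
            assert pdi(triples, out) == pytest.approx(
                pdi_triplet_enumeration(triples, out), abs=1e-12
            )

    def test_missing_category_undefined(self):
        with pytest.raises(UndefinedMetricError):
            pdi(np.full((4, 3), 1 / 3), ["FPUL", "FPUL", "IUP", "IUP"])

    def test_order_invariance(self, rng):
        out = np.repeat(OUTCOMES, (5, 4, 3))
        triples = rng.dirichlet([1, 1, 1], size=12)
        perm = rng.permutation(12)
        assert pdi(triples, out) == pytest.approx(
            pdi(triples[perm], out[perm]), abs=1e-12
        )


class TestClassificationMetrics:
    def test_sensitivity_example(self):
        out = ["EP"] * 10 + ["FPUL"] * 10
        hr = [True] * 8 + [False] * 2 + [False] * 10
        m = classification_metrics(hr, out)
        assert m["sensitivity"] == pytest.approx(0.8)

    def test_no_positive_calls_ppv_undefined_fpr_zero(self):
        out = ["EP", "FPUL", "IUP"]
        m = classification_metrics([False] * 3, out)
        assert np.isnan(m["ppv"])
        assert m["fpr"] == 0.0
        assert m["pct_low_risk"] == 1.0

    def test_count_arithmetic(self):
        # tp=10 fp=20 tn=60 fn=10
        out = ["EP"] * 20 + ["FPUL"] * 80
        hr = [True] * 10 + [False] * 10 + [True] * 20 + [False] * 60
        m = classification_metrics(hr, out)
        assert m["ppv"] == pytest.approx(1 / 3)
        assert m["npv"] == pytest.approx(6 / 7)
        assert m["pct_low_risk"] == pytest.approx(0.70)
        t = classification_table(hr, out)
        assert t == {"tp": 10, "fp": 20, "tn": 60, "fn": 10, "n_low_risk": 70}

    def test_ltfu_rejected(self):
        with pytest.raises(ValueError):
            classification_metrics([True], ["LTFU"])
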