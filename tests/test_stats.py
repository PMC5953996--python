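"""Concordance layer: classification rules, 2x2 metrics, kappa, ROC,
Bland-Altman, correlation, and the study report."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from myoflow import (ContingencyTable, Thresholds, bland_altman, classify,
                     cohen_kappa, concordance_report, diagnostic_metrics,
                     pearson_r, roc_curve)
from myoflow.stats import AT_OR_BELOW, STRICTLY_BELOW

# the study's printed 2x2 counts (index test x FFR reference)
CZT_TABLE = ContingencyTable(tp=7, fp=12, fn=5, tn=66)
PET_TABLE = ContingencyTable(tp=8, fp=9, fn=4, tn=69)

# hand evaluations of Cohen's formula on those counts
KAPPA_CZT = 0.3444730077120823
KAPPA_PET = 0.4686648501362397


def mann_whitney_auc(scores, truth):
    """Independent oracle: pairwise concordance with half-credit ties.

    Lower score = more abnormal, so a concordant pair has
    score(abnormal) < score(normal).
    """
    s = np.asarray(scores, float)
    y = np.asarray(truth, bool)
    pos, neg = s[y], s[~y]
    wins = sum((p < n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestClassify:
    @pytest.mark.parametrize("value,cutoff,rule,expected", [
        (2.1, 2.1, STRICTLY_BELOW, False),   # MFR tie -> normal
        (0.8, 0.8, AT_OR_BELOW, True),       # FFR tie -> abnormal
        (1.99, 2.0, STRICTLY_BELOW, True),
        (2.49, 2.5, STRICTLY_BELOW, True),   # stress MBF
    ])
    def test_tie_rules(self, value, cutoff, rule, expected):
        assert classify(value, cutoff, rule) is expected

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            classify(float("nan"), 2.0)


class TestDiagnosticMetrics:
    def test_printed_counts_reproduce_printed_rates(self):
        m = diagnostic_metrics(CZT_TABLE)
        assert (round(m.sensitivity, 1), round(m.specificity, 1),
                round(m.accuracy, 1), round(m.ppv, 1),
                round(m.npv, 1)) == (58.3, 84.6, 81.1, 36.8, 93.0)
        p = diagnostic_metrics(PET_TABLE)
        assert (round(p.sensitivity, 1), round(p.specificity, 1),
                round(p.ppv, 1), round(p.npv, 1)) == (66.7, 88.5, 47.1, 94.5)

    def test_perfect_table(self):
        m = diagnostic_metrics(ContingencyTable(tp=5, fp=0, fn=0, tn=5))
        assert (m.sensitivity, m.specificity, m.accuracy, m.ppv, m.npv) == \
            (100.0,) * 5

    def test_zero_denominator_is_nan_not_zero(self):
        m = diagnostic_metrics(ContingencyTable(tp=0, fp=0, fn=0, tn=5))
        assert math.isnan(m.sensitivity) and math.isnan(m.ppv)
        assert m.specificity == 100.0

    def test_rates_bounded(self):
        m = diagnostic_metrics(ContingencyTable(tp=3, fp=2, fn=1, tn=4))
        for v in (m.sensitivity, m.specificity, m.accuracy, m.ppv, m.npv):
            assert 0.0 <= v <= 100.0
        assert min(m.sensitivity, m.specificity) <= m.accuracy <= \
            max(m.sensitivity, m.specificity)


class TestCohenKappa:
    def test_perfect_agreement(self):
        assert cohen_kappa(ContingencyTable(tp=10, fp=0, fn=0, tn=20)) == 1.0

    def test_chance_agreement(self):
        assert cohen_kappa(ContingencyTable(tp=25, fp=25, fn=25, tn=25)) == 0.0

    def test_study_tables(self):
        assert cohen_kappa(CZT_TABLE) == pytest.approx(KAPPA_CZT, abs=1e-12)
        assert cohen_kappa(PET_TABLE) == pytest.approx(KAPPA_PET, abs=1e-12)

    def test_unity_iff_no_discordance(self):
        assert cohen_kappa(ContingencyTable(tp=3, fp=1, fn=0, tn=5)) < 1.0

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.integers(1, 30), st.integers(0, 30), st.integers(0, 30),
           st.integers(1, 30), st.integers(2, 5))
    def test_invariant_to_cell_scaling(self, tp, fp, fn, tn, c):
        base = ContingencyTable(tp=tp, fp=fp, fn=fn, tn=tn)
        scaled = ContingencyTable(tp=c * tp, fp=c * fp, fn=c * fn, tn=c * tn)
        k0, k1 = cohen_kappa(base), cohen_kappa(scaled)
        assert (math.isnan(k0) and math.isnan(k1)) or k0 == pytest.approx(k1, abs=1e-12)


class TestRoc:
    def test_perfect_separation(self):
        scores = [1.0, 1.1, 1.2, 3.0, 3.1, 3.2]
        truth = [True, True, True, False, False, False]
        *_, auc, cutoff = roc_curve(scores, truth)
        assert auc == 1.0
        assert 1.2 < cutoff <= 3.0

    def test_identical_scores_chance(self):
        *_, auc, _ = roc_curve([2.0] * 8, [True] * 4 + [False] * 4)
        assert auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([1.0, 2.0], [True, True])

    def test_matches_pairwise_concordance_oracle(self):
        rng = np.random.default_rng(0)
        for trial in range(5):
            n = 200
            truth = rng.random(n) < 0.3
            scores = np.round(rng.normal(2.5 - truth, 0.8, n), 1)  # ties likely
            *_, auc, _ = roc_curve(scores, truth)
            assert abs(auc - mann_whitney_auc(scores, truth)) < 1e-12

    def test_youden_ties_take_smallest_cutoff(self):
        # anti-diagnostic scores: J = 0 at thresholds 1.0 and +inf, negative
        # in between; the tie resolves to the smallest threshold
        scores = [1.0, 2.0]
        truth = [False, True]
        *_, cutoff = roc_curve(scores, truth)
        assert cutoff == 1.0


class TestAgreement:
    def test_identical_measurements(self):
        bias, lo, hi = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (bias, lo, hi) == (0.0, 0.0, 0.0)

    def test_symmetric_differences(self):
        bias, lo, hi = bland_altman([1.0, 0.0], [0.0, 1.0])
        assert bias == 0.0
        assert hi == pytest.approx(1.96 * math.sqrt(2.0))
        assert lo == pytest.approx(-1.96 * math.sqrt(2.0))

    def test_translation_equivariance(self):
        x = np.array([1.0, 2.0, 3.5, 4.0])
        y = np.array([0.9, 2.2, 3.1, 4.4])
        b0, *_ = bland_altman(x, y)
        b1, *_ = bland_altman(x, y - 0.7)
        assert b1 == pytest.approx(b0 + 0.7)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0, 2.0], [1.0])

    def test_limits_cover_95pct_of_gaussian(self):
        rng = np.random.default_rng(1)
        d = rng.normal(0.3, 1.2, 10_000)
        bias, lo, hi = bland_altman(d, np.zeros_like(d))
        coverage = np.mean((d >= lo) & (d <= hi))
        assert coverage == pytest.approx(0.95, abs=0.01)

    def test_pearson_exact_cases(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)
        assert math.isnan(pearson_r(x, np.ones(4)))

    def test_pearson_matches_hand_formula(self):
        rng = np.random.default_rng(2)
        x, y = rng.random(10), rng.random(10)
        xm, ym = x - x.mean(), y - y.mean()
        hand = np.sum(xm * ym) / np.sqrt(np.sum(xm ** 2) * np.sum(ym ** 2))
        assert pearson_r(x, y) == pytest.approx(hand, abs=1e-12)


def _flow_frame(rows):
    return pd.DataFrame(rows, columns=["patient_id", "region", "rest_mbf",
                                       "stress_mbf", "mfr"])


class TestConcordanceReport:
    def _inputs(self):
        rows_s, rows_p, ffr = [], [], []
        mfr_by_pat = {"001": (1.5, 1.6, 0.70), "002": (2.8, 2.9, 0.90),
                      "003": (1.8, 2.5, 0.78)}
        for pid, (czt_mfr, pet_mfr, f) in mfr_by_pat.items():
            for region in ("GLOBAL", "LAD", "LCX", "RCA"):
                rows_s.append((pid, region, 1.0, czt_mfr, czt_mfr))
                rows_p.append((pid, region, 1.0, pet_mfr, pet_mfr))
                if region != "GLOBAL":
                    ffr.append((pid, region, f))
        return (_flow_frame(rows_s), _flow_frame(rows_p),
                pd.DataFrame(ffr, columns=["patient_id", "territory", "ffr"]))

    def test_counts_and_fields(self):
        spect, pet, ffr = self._inputs()
        report = concordance_report(spect, pet, ffr, Thresholds())
        czt = report["czt_vs_ffr"]
        # patient 001: MFR 1.5 abnormal, FFR 0.70 abnormal (x3 territories)
        # patient 003: CZT MFR 1.8 < 2.1 abnormal, PET MFR 2.5 normal; FFR abn
        assert czt["counts"] == {"tp": 6, "fp": 0, "fn": 0, "tn": 3}
        assert report["pet_vs_ffr"]["counts"] == {"tp": 3, "fp": 0, "fn": 3, "tn": 3}
        assert czt["discordant"] == 0
        assert report["pet_vs_ffr"]["discordant"] == 3
        assert report["global_mfr_agreement"]["n"] == 3
        assert "auc" in report["roc_czt_mfr_vs_pet"]

    def test_unmatched_keys_listed(self):
        spect, pet, ffr = self._inputs()
        ffr_short = ffr.iloc[:-1]
        with pytest.raises(ValueError, match="RCA"):
            concordance_report(spect, pet, ffr_short, Thresholds())

    def test_thresholds_validation(self):
        with pytest.raises(ValueError):
            Thresholds(ffr_cutoff=1.2)
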