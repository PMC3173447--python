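"""Cutoff classification rules and diagnostic-performance accounting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import dcekinet as dk
from dcekinet.response import NON_RESPONDER, RESPONDER, clopper_pearson, round_half_away


class TestPercentChange:
    @pytest.mark.parametrize(
        "pre,post,expected",
        [(0.3, 0.3, 0.0), (0.5, 0.25, -50.0), (0.1, 0.293, 193.0)],
    )
    def test_values(self, pre, post, expected):
        assert dk.percent_change(pre, post) == pytest.approx(expected)

    def test_nonpositive_pre_rejected(self):
        with pytest.raises(ValueError):
            dk.percent_change(0.0, 1.0)


class TestCutoffRules:
    @pytest.mark.parametrize(
        "change,cutoff,expected",
        [
            (-72.0, -72.0, RESPONDER),   # drop of exactly the cutoff = response
            (193.0, -72.0, NON_RESPONDER),
            (-100.0, -72.0, RESPONDER),
            (-84.0, -84.0, RESPONDER),
            (-83.9, -84.0, NON_RESPONDER),
        ],
    )
    def test_boundary_semantics(self, change, cutoff, expected):
        assert dk.classify_by_cutoff(change, cutoff) == expected

    @given(
        change=st.floats(-100, 300, allow_nan=False),
        cutoff=st.floats(-100, 0, allow_nan=False),
        delta=st.floats(0, 50, allow_nan=False),
    )
    @settings(deadline=None, derandomize=True, max_examples=100)
    def test_monotone_in_cutoff(self, change, cutoff, delta):
        """Lowering the cutoff never converts a non-responder call back to
        responder."""
        if dk.classify_by_cutoff(change, cutoff) == NON_RESPONDER:
            assert dk.classify_by_cutoff(change, cutoff - delta) == NON_RESPONDER

    @pytest.mark.parametrize(
        "kt,ve,expected",
        [
            (-98.0, -38.0, NON_RESPONDER),  # Ve fails to drop
            (-100.0, -94.0, RESPONDER),
            (-100.0, -100.0, RESPONDER),
            (-50.0, -94.0, NON_RESPONDER),  # Ktrans fails to drop
        ],
    )
    def test_combined_or_rule(self, kt, ve, expected):
        assert dk.classify_combined(kt, ve, -82.0, -72.0) == expected

    @pytest.mark.parametrize(
        "size,expected",
        [(-50.0, RESPONDER), (57.0, NON_RESPONDER), (-100.0, RESPONDER), (-49.0, NON_RESPONDER)],
    )
    def test_who_size_rule(self, size, expected):
        assert dk.who_size_classify(size) == expected


class TestSummarizeRoi:
    def test_odd_count_median(self):
        shape = (3, 1, 1)
        pm = dk.ParamMap(
            ktrans=np.array([0.1, 0.2, 0.4]).reshape(shape),
            ve=np.array([0.3, 0.3, 0.3]).reshape(shape),
            rss=np.zeros(shape),
            converged=np.ones(shape, bool),
            mask=np.ones(shape, bool),
        )
        kt, ve = dk.summarize_roi(pm)
        assert kt == 0.2 and ve == 0.3

    def test_matches_brute_force_sort_median(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0.05, 0.8, 10)
        shape = (10, 1, 1)
        pm = dk.ParamMap(
            ktrans=vals.reshape(shape), ve=vals.reshape(shape) / 2,
            rss=np.zeros(shape), converged=np.ones(shape, bool), mask=np.ones(shape, bool),
        )
        srt = np.sort(vals)
        brute = 0.5 * (srt[4] + srt[5])
        kt, ve = dk.summarize_roi(pm)
        assert kt == pytest.approx(brute)
        assert ve == pytest.approx(brute / 2)


class TestDiagnosticPerformance:
    def test_perfect_prediction(self):
        truth = [NON_RESPONDER] * 5 + [RESPONDER] * 5
        perf = dk.diagnostic_performance(truth, truth, NON_RESPONDER)
        pct = perf.as_percents()
        assert (pct["sensitivity"], pct["specificity"], pct["accuracy"]) == (100, 100, 100)
        lo, hi = pct["ci_sensitivity"]
        assert hi == 100 and lo < 100

    def test_random_fixture_matches_brute_force(self):
        rng = np.random.default_rng(123)
        truth = rng.choice([RESPONDER, NON_RESPONDER], 1000)
        pred = rng.choice([RESPONDER, NON_RESPONDER], 1000)
        perf = dk.diagnostic_performance(pred, truth, NON_RESPONDER)
        tp = sum(1 for p, t in zip(pred, truth) if p == t == NON_RESPONDER)
        fp = sum(1 for p, t in zip(pred, truth) if p == NON_RESPONDER and t == RESPONDER)
        fn = sum(1 for p, t in zip(pred, truth) if p == RESPONDER and t == NON_RESPONDER)
        tn = sum(1 for p, t in zip(pred, truth) if p == t == RESPONDER)
        assert (perf.tp, perf.fp, perf.tn, perf.fn) == (tp, fp, tn, fn)
        assert perf.accuracy == pytest.approx((tp + tn) / 1000)

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError):
            dk.diagnostic_performance([RESPONDER] * 3, [RESPONDER] * 3, NON_RESPONDER)

    @given(
        tp=st.integers(0, 30), fp=st.integers(0, 30),
        tn=st.integers(0, 30), fn=st.integers(0, 30),
    )
    @settings(deadline=None, derandomize=True, max_examples=100)
    def test_accuracy_decomposition(self, tp, fp, tn, fn):
        """accuracy == (TP+TN)/(P+N) for any confusion table."""
        if tp + fn == 0 or tn + fp == 0:
            return
        r = dk.ClassificationResult(tp=tp, fp=fp, tn=tn, fn=fn)
        assert r.accuracy == pytest.approx((tp + tn) / (tp + fp + tn + fn))
        assert 0 <= r.ci_sensitivity[0] <= r.sensitivity <= r.ci_sensitivity[1] <= 1


class TestClopperPearson:
    @pytest.mark.parametrize(
        "k,n,expected",
        [(8, 11, (39, 94)), (12, 13, (64, 100))],
    )
    def test_printed_intervals(self, k, n, expected):
        lo, hi = clopper_pearson(k, n)
        assert (round_half_away(100 * lo), round_half_away(100 * hi)) == expected

    @pytest.mark.parametrize("p", [0.1, 0.5, 0.9])
    def test_coverage_at_small_n(self, p):
        """Exact binomial interval covers the true proportion >= 95% of the
        time at n = 11 (1000 simulated cohorts)."""
        rng = np.random.default_rng(2024)
        n = 11
        hits = 0
        reps = 1000
        for k in rng.binomial(n, p, reps):
            lo, hi = clopper_pearson(int(k), n)
            hits += lo <= p <= hi
        assert hits / reps >= 0.95


class TestSklearnInterface:
    def test_cutoff_classifier_contract(self):
        from sklearn.base import clone

        clf = dk.CutoffClassifier(cutoff=-72.0).fit()
        assert clone(clf).get_params()["cutoff"] == -72.0
        out = clf.predict([-80.0, -10.0])
        assert list(out) == [RESPONDER, NON_RESPONDER]

    def test_combined_classifier_predict_matrix(self):
        clf = dk.CombinedCutoffClassifier().fit()
        out = clf.predict([[-98.0, -38.0], [-100.0, -94.0]])
        assert list(out) == [NON_RESPONDER, RESPONDER]
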