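"""Metric formulas, radar scaling, outlier gating, Hill fitting."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poredelay.errors import DataError
from poredelay.stats import (
    ConfusionCounts,
    baseline_correct,
    compute_metrics,
    confusion,
    fit_hill,
    hill,
    mad_filter,
    minmax_radar,
    roc_auc,
    summarize,
)


class TestConfusion:
    def test_perfect(self):
        y = ["delayed"] * 10 + ["non_delayed"] * 10
        c = confusion(y, y)
        assert (c.tp, c.tn, c.fp, c.fn) == (10, 10, 0, 0)

    def test_all_predicted_negative(self):
        y = ["delayed"] * 4 + ["non_delayed"] * 6
        c = confusion(y, ["non_delayed"] * 10)
        assert c.tp == 0 and c.fp == 0 and c.fn == 4 and c.tn == 6

    def test_random_case_matches_sklearn(self):
        from sklearn.metrics import confusion_matrix

        rng = np.random.default_rng(0)
        y = rng.choice(["delayed", "non_delayed"], 100)
        p = rng.choice(["delayed", "non_delayed"], 100)
        c = confusion(y, p)
        tn, fp, fn, tp = confusion_matrix(
            y, p, labels=["non_delayed", "delayed"]
        ).ravel()
        assert (c.tp, c.fp, c.fn, c.tn) == (tp, fp, fn, tn)

    def test_length_mismatch(self):
        with pytest.raises(DataError):
            confusion(["delayed"], [])


class TestComputeMetrics:
    def test_perfect_classifier(self):
        m = compute_metrics(ConfusionCounts(50, 0, 0, 50))
        assert m.accuracy == m.precision == m.recall == m.f1 == 1.0
        assert m.mcc == 1.0

    def test_against_sklearn_on_random_matrices(self):
        from sklearn.metrics import f1_score, matthews_corrcoef, precision_score

        rng = np.random.default_rng(1)
        for _ in range(200):
            tp, fp, fn, tn = (int(v) for v in rng.integers(0, 30, 4))
            if tp + fp + fn + tn == 0:
                continue
            c = ConfusionCounts(tp, fp, fn, tn)
            m = compute_metrics(c)
            y = [1] * tp + [1] * fn + [0] * fp + [0] * tn
            p = [1] * tp + [0] * fn + [1] * fp + [0] * tn
            if not math.isnan(m.mcc):
                assert m.mcc == pytest.approx(matthews_corrcoef(y, p), abs=1e-12)
            if not math.isnan(m.precision):
                assert m.precision == pytest.approx(
                    precision_score(y, p, zero_division=np.nan), abs=1e-12
                )
            if not math.isnan(m.f1):
                assert m.f1 == pytest.approx(f1_score(y, p), abs=1e-12)

    def test_undefined_ratios_flagged_not_zero(self):
        m = compute_metrics(ConfusionCounts(0, 0, 5, 5))
        assert math.isnan(m.precision) and "precision" in m.flags
        assert math.isnan(m.mcc) and "mcc" in m.flags


class TestRocAuc:
    def test_perfect_and_tied(self):
        y = ["delayed"] * 3 + ["non_delayed"] * 3
        assert roc_auc([5, 4, 3, 2, 1, 0], y) == 1.0
        assert roc_auc([1, 1, 1, 1, 1, 1], y) == 0.5

    def test_six_point_pair_counting_oracle(self):
        scores = [0.9, 0.8, 0.35, 0.7, 0.3, 0.1]
        y = ["delayed", "delayed", "delayed", "non_delayed", "non_delayed", "non_delayed"]
        # count concordant pairs by hand
        pos = [s for s, l in zip(scores, y) if l == "delayed"]
        neg = [s for s, l in zip(scores, y) if l == "non_delayed"]
        expect = np.mean([(p > q) + 0.5 * (p == q) for p in pos for q in neg])
        assert roc_auc(scores, y) == pytest.approx(expect)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(2)
        s = rng.normal(size=200)
        y = rng.choice(["delayed", "non_delayed"], 200)
        y01 = [1 if v == "delayed" else 0 for v in y]
        assert roc_auc(s, y) == pytest.approx(roc_auc_score(y01, s))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(0.1, 5.0))
    def test_invariant_under_monotone_transform(self, gain):
        rng = np.random.default_rng(3)
        s = rng.normal(size=60)
        y = ["delayed"] * 30 + ["non_delayed"] * 30
        assert roc_auc(np.exp(gain * s), y) == pytest.approx(roc_auc(s, y))

    def test_single_class_rejected(self):
        with pytest.raises(DataError):
            roc_auc([1, 2], ["delayed", "delayed"])


class TestMinmaxRadar:
    def test_two_rows_map_to_unit_interval(self):
        df = pd.DataFrame({"acc": [0.7, 0.9], "mcc": [0.4, 0.8]}, index=["a", "b"])
        scaled, flagged = minmax_radar(df)
        assert set(scaled["acc"]) == {0.0, 1.0}
        assert flagged == []

    def test_order_preserved_and_invertible(self):
        df = pd.DataFrame(
            {"m1": [0.2, 0.5, 0.9], "m2": [0.9, 0.1, 0.5]}, index=list("abc")
        )
        scaled, _ = minmax_radar(df)
        for col in df:
            assert (scaled[col].rank() == df[col].rank()).all()
            back = scaled[col] * (df[col].max() - df[col].min()) + df[col].min()
            np.testing.assert_allclose(back, df[col])

    def test_constant_column_flagged(self):
        df = pd.DataFrame({"m": [0.5, 0.5]}, index=["a", "b"])
        scaled, flagged = minmax_radar(df)
        assert flagged == ["m"] and scaled["m"].isna().all()

    def test_single_row_rejected(self):
        with pytest.raises(DataError):
            minmax_radar(pd.DataFrame({"m": [1.0]}))


class TestMadFilter:
    def test_zero_mad_path(self):
        with pytest.warns(UserWarning):
            kept, excluded = mad_filter([10.0, 10.0, 10.0, 50.0])
        assert list(kept) == [10.0, 10.0, 10.0] and excluded == [3]

    def test_no_exclusion(self):
        kept, excluded = mad_filter([1, 2, 3, 4, 5])
        assert len(kept) == 5 and excluded == []

    def test_single_value_kept(self):
        kept, excluded = mad_filter([7.0])
        assert list(kept) == [7.0] and excluded == []

    def test_far_outlier_excluded(self):
        kept, excluded = mad_filter([1.0, 2.0, 3.0, 4.0, 100.0])
        assert 100.0 not in kept and excluded == [4]


class TestBaselineCorrect:
    def make_table(self):
        return pd.DataFrame(
            {
                "conc_nM": [0, 1, 10, 0, 1, 10],
                "replicate": [1, 1, 1, 2, 2, 2],
                "pct_delay": [2.0, 10.0, 30.0, 4.0, 12.0, 32.0],
            }
        )

    def test_zero_rows_become_zero(self):
        out = baseline_correct(self.make_table())
        assert (out.loc[out["conc_nM"] == 0, "corrected"] == 0).all()

    def test_per_replicate_offset_invariance(self):
        t = self.make_table()
        out1 = baseline_correct(t)
        t2 = t.copy()
        t2.loc[t2["replicate"] == 2, "pct_delay"] += 5.0
        out2 = baseline_correct(t2)
        np.testing.assert_allclose(out1["corrected"], out2["corrected"])

    def test_missing_baseline_rejected(self):
        t = self.make_table()
        with pytest.raises(DataError):
            baseline_correct(t[t["conc_nM"] > 0])


class TestSummarize:
    def test_hand_value(self):
        t = pd.DataFrame(
            {"conc_nM": [1, 1, 1], "replicate": [1, 2, 3], "pct_delay": [2.0, 4.0, 6.0]}
        )
        s = summarize(t)
        assert s["mean"].iloc[0] == 4.0
        assert s["sem"].iloc[0] == pytest.approx(2.0 / math.sqrt(3))

    def test_single_replicate_flagged(self):
        t = pd.DataFrame({"conc_nM": [1], "replicate": [1], "pct_delay": [5.0]})
        assert math.isnan(summarize(t)["sem"].iloc[0])

    def test_constant_replicates(self):
        t = pd.DataFrame(
            {"conc_nM": [1] * 3, "replicate": [1, 2, 3], "pct_delay": [5.0] * 3}
        )
        assert summarize(t)["sem"].iloc[0] == 0.0


class TestFitHill:
    GRID = np.array([0.0, 0.1, 0.3, 1.0, 3.0, 10.0, 30.0, 100.0])

    def test_noiseless_recovery(self):
        y = hill(self.GRID, 36.59, 1.19, 2.25)
        fit = fit_hill(self.GRID, y)
        assert fit.vmax_pct == pytest.approx(36.59, rel=1e-6)
        assert fit.ke_nM == pytest.approx(1.19, rel=1e-6)
        assert fit.nh == pytest.approx(2.25, rel=1e-6)
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)

    def test_half_max_identity(self):
        fit = fit_hill(self.GRID, hill(self.GRID, 30.0, 2.0, 1.5))
        assert fit.predict(fit.ke_nM) == pytest.approx(fit.vmax_pct / 2.0)

    def test_insufficient_grid_rejected(self):
        with pytest.raises(DataError):
            fit_hill([0, 1, 2], [0, 1, 2])
        with pytest.raises(DataError):
            fit_hill([1, 2, 3, 4], [1, 2, 3, 4])  # no zero concentration
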