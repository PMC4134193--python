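"""Volumes, overlap metrics, ICC/regression/Bland-Altman, cohort tables."""

import numpy as np
import pandas as pd
import pytest

from wmhseg import (BinaryMask, aggregate_cohort, bland_altman, delta_vol,
                    icc, icc_all_forms, load_cohort_table, overlap_metrics,
                    regression_fit, volume_ml)


def _mask(data, spacing=(1.0, 1.0, 1.0)):
    return BinaryMask(np.asarray(data, bool), np.diag(list(spacing) + [1.0]))


class TestVolume:
    def test_unit_voxels(self):
        m = _mask(np.ones((10, 10, 10)))
        assert volume_ml(m) == pytest.approx(1.0)

    def test_anisotropic_voxels(self):
        data = np.zeros((5, 5, 5), bool)
        data.ravel()[:10] = True
        m = _mask(data, spacing=(0.8, 0.8, 6.0))
        assert volume_ml(m) == pytest.approx(0.0384)

    def test_empty(self):
        assert volume_ml(_mask(np.zeros((3, 3, 3)))) == 0.0


class TestDeltaVol:
    def test_printed_example_row(self):
        assert delta_vol(7.954, 7.994) == pytest.approx(0.50, abs=0.005)

    def test_equal_and_zero_auto(self):
        assert delta_vol(5.0, 5.0) == 0.0
        assert delta_vol(5.0, 0.0) == -100.0

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            delta_vol(0.0, 1.0)


class TestOverlapMetrics:
    def test_identical_masks_perfect(self, rng):
        a = _mask(rng.random((8, 8, 4)) > 0.6)
        domain = BinaryMask.full(a)
        si, sens, spec = overlap_metrics(a, a, domain)
        assert (si, sens, spec) == (100.0, 100.0, 100.0)

    def test_disjoint_equal_masks_zero_si(self):
        a = np.zeros((6, 6, 2), bool); a[:3] = True
        b = np.zeros((6, 6, 2), bool); b[3:] = True
        si, sens, _ = overlap_metrics(_mask(a), _mask(b), _mask(np.ones((6, 6, 2))))
        assert si == 0.0 and sens == 0.0

    def test_matches_bruteforce_confusion_matrix(self, rng):
        auto = rng.random((10, 10, 5)) > 0.8
        ref = rng.random((10, 10, 5)) > 0.8
        if not ref.any():
            ref[0, 0, 0] = True
        domain = rng.random((10, 10, 5)) > 0.2
        domain |= ref  # keep the reference nonempty within the domain
        tp = fp = fn = tn = 0
        for idx in np.ndindex(auto.shape):
            if not domain[idx]:
                continue
            a, r = auto[idx], ref[idx]
            tp += a and r; fp += a and not r
            fn += r and not a; tn += (not a) and (not r)
        si, sens, spec = overlap_metrics(_mask(auto), _mask(ref), _mask(domain))
        assert si == pytest.approx(200 * tp / (2 * tp + fp + fn))
        assert sens == pytest.approx(100 * tp / (tp + fn))
        assert spec == pytest.approx(100 * tn / (tn + fp))

    def test_empty_reference_rejected(self):
        a = _mask(np.ones((3, 3, 3)))
        with pytest.raises(ValueError, match="empty"):
            overlap_metrics(a, _mask(np.zeros((3, 3, 3))), BinaryMask.full(a))


def _icc_a1_anova(pairs: np.ndarray) -> float:
    """Independent closed-form two-way-ANOVA ICC(A,1) for k=2 raters."""
    n, k = pairs.shape
    grand = pairs.mean()
    msr = k * ((pairs.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((pairs.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    sse = ((pairs - pairs.mean(axis=1, keepdims=True)
            - pairs.mean(axis=0, keepdims=True) + grand) ** 2).sum()
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))


class TestICC:
    def test_perfect_agreement(self):
        pairs = [(1.0, 1.0), (5.0, 5.0), (9.0, 9.0), (2.5, 2.5)]
        assert icc(pairs) == pytest.approx(1.0)

    def test_independent_pairs_near_zero(self, rng):
        pairs = np.c_[rng.normal(10, 3, 200), rng.normal(10, 3, 200)]
        assert abs(icc(pairs)) < 0.15

    def test_matches_anova_closed_form(self, rng):
        pairs = np.c_[rng.normal(10, 4, 30), rng.normal(10, 4, 30)]
        pairs[:, 1] = 0.7 * pairs[:, 0] + 0.3 * pairs[:, 1]
        assert icc(pairs) == pytest.approx(_icc_a1_anova(pairs), rel=1e-9)

    def test_all_six_forms_reported(self):
        table = icc_all_forms([(1, 2), (4, 4.5), (8, 7), (3, 3.5)])
        assert set(table["Type"]) == {"ICC(1,1)", "ICC(A,1)", "ICC(C,1)",
                                      "ICC(1,k)", "ICC(A,k)", "ICC(C,k)"}

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            icc([(1.0, 1.0), (2.0, 2.0)])


class TestRegressionAndBlandAltman:
    def test_exact_line(self):
        semi = np.array([1.0, 2.0, 3.0, 4.0])
        slope, intercept, r2 = regression_fit(np.c_[semi, 2 * semi + 1])
        assert (slope, intercept, r2) == pytest.approx((2.0, 1.0, 1.0))

    def test_identical_pairs_zero_bias(self):
        bias, (lo, hi) = bland_altman([(3.0, 3.0), (7.0, 7.0)])
        assert bias == 0.0 and lo == 0.0 and hi == 0.0

    def test_bias_is_mean_semi_minus_auto(self):
        bias, _ = bland_altman([(5.0, 4.0), (10.0, 8.0)])
        assert bias == pytest.approx(1.5)


class TestCohortTables:
    def test_table_shapes_and_example_row(self):
        der = load_cohort_table("derivation")
        val = load_cohort_table("validation")
        assert len(der) == 38 and len(val) == 20
        assert (der.group == "wmh_only").sum() == 25
        assert (der.group == "wmh_infarct").sum() == 13
        row = der[(der.patient == "1") & (der.side == "R")].iloc[0]
        assert row.semi_auto_ml == pytest.approx(7.954)

    def test_aggregates_reproduce_printed_cells(self):
        report = aggregate_cohort(load_cohort_table("derivation"))
        gs = report.group_stats
        assert gs.loc[("all", "mean"), "si_pct"] == pytest.approx(78.244, abs=0.01)
        assert gs.loc[("all", "sd"), "si_pct"] == pytest.approx(14.167, abs=0.01)
        assert gs.loc[("wmh_only", "mean"), "si_pct"] == pytest.approx(83.142, abs=0.01)
        assert gs.loc[("wmh_only", "sd"), "sen_pct"] == pytest.approx(16.086, abs=0.01)
        assert gs.loc[("wmh_infarct", "mean"), "spe_pct"] == pytest.approx(99.956, abs=0.001)

    def test_single_record_aggregate(self):
        df = pd.DataFrame([{"patient": "1", "side": "L", "group": "wmh_only",
                            "semi_auto_ml": 2.0, "auto_ml": 2.2,
                            "delta_vol_pct": 10.0, "si_pct": 90.0,
                            "sen_pct": 88.0, "spe_pct": 99.9}])
        report = aggregate_cohort(df)
        assert report.group_stats.loc[("all", "mean"), "si_pct"] == 90.0
        assert report.group_stats.loc[("all", "sd"), "si_pct"] == 0.0

    def test_group_regressions_and_biases(self):
        report = aggregate_cohort(load_cohort_table("derivation"))
        slope, _, r2 = report.regression_by_group["wmh_only"]
        assert slope == pytest.approx(0.797, abs=0.001)
        assert r2 == pytest.approx(0.848, abs=0.001)
        bias, _ = report.bland_altman_by_group["wmh_only"]
        assert bias == pytest.approx(0.799, abs=0.001)
        bias_inf, _ = report.bland_altman_by_group["wmh_infarct"]
        assert bias_inf == pytest.approx(-1.248, abs=0.001)
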