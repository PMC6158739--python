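"""Tract ROIs, Tukey outlier filtering, robust fits and EYO ordering."""

import numpy as np
import pandas as pd
import pytest

from mdcascade import (
    RobustFitResult,
    SkeletonVolume,
    TractAtlas,
    average_md,
    build_tract_rois,
    build_design,
    eyo_ordering,
    robust_fit,
    run_ordering_suite,
    tukey_filter,
)


def _atlas():
    labels = np.zeros((10, 10, 4), dtype=int)
    labels[0:5, 0:5, :] = 1
    labels[6:10, 6:10, :] = 2
    return TractAtlas(labels=labels, names={1: "forceps_major", 2: "cingulum"})


class TestTractROIs:
    def test_full_sig_mask_keeps_whole_tract(self):
        atlas = _atlas()
        rois = build_tract_rois(atlas, np.ones((10, 10, 4), bool))
        by_name = {r.tract_name: r for r in rois}
        assert by_name["forceps_major"].frac_sig == 1.0
        assert np.array_equal(by_name["forceps_major"].mask, atlas.labels == 1)
        assert all(r.included for r in rois)

    def test_disjoint_sig_mask_excludes_tract(self):
        atlas = _atlas()
        sig = np.zeros((10, 10, 4), bool)
        sig[0:5, 0:5, :] = True  # only tract 1
        rois = {r.tract_name: r for r in build_tract_rois(atlas, sig)}
        assert not rois["cingulum"].included
        assert rois["cingulum"].n_sig_voxels == 0

    def test_small_fraction_excluded_at_threshold(self):
        # 12 of 1000 voxels significant -> frac 0.012 < 0.02 -> excluded
        labels = np.zeros((10, 10, 10), dtype=int)
        labels[...] = 1
        atlas = TractAtlas(labels=labels, names={1: "ilf"})
        sig = np.zeros((10, 10, 10), bool)
        sig.flat[:12] = True
        roi = build_tract_rois(atlas, sig, frac_threshold=0.02)[0]
        assert roi.frac_sig == pytest.approx(0.012)
        assert not roi.included

    def test_a_priori_overrides_exclusion(self):
        atlas = _atlas()
        sig = np.zeros((10, 10, 4), bool)
        rois = {r.tract_name: r
                for r in build_tract_rois(atlas, sig, a_priori=["cingulum"])}
        assert rois["cingulum"].included

    def test_unknown_a_priori_name(self):
        with pytest.raises(ValueError, match="unknown a-priori"):
            build_tract_rois(_atlas(), np.ones((10, 10, 4), bool), a_priori=["fornix"])


class TestAverageMD:
    def test_constant_and_pairwise_means(self, rng):
        atlas = _atlas()
        rois = build_tract_rois(atlas, np.ones((10, 10, 4), bool))
        data = np.full((10, 10, 4), 7e-4)
        vol = SkeletonVolume(data, atlas.labels > 0)
        assert average_md(vol, rois[0]) == pytest.approx(7e-4)
        data2 = rng.random((10, 10, 4))
        vol2 = SkeletonVolume(data2, atlas.labels > 0)
        want = data2[rois[0].mask].sum() / rois[0].mask.sum()
        assert average_md(vol2, rois[0]) == pytest.approx(want, rel=1e-14)


class TestTukeyFilter:
    def test_hand_worked_example(self):
        # group values [2,3,4,5,30]: median 4, Q1 3, Q3 5, IQR 2, cutoff 7
        values = np.array([2.0, 3, 4, 5, 30])
        kept, removed = tukey_filter(values, np.zeros(5))
        assert list(removed) == [4]
        assert list(values[kept]) == [2, 3, 4, 5]

    def test_constant_values_remove_nothing(self):
        kept, removed = tukey_filter(np.full(10, 3.3), np.zeros(10))
        assert removed.size == 0 and kept.size == 10

    def test_within_band_vacuous(self, rng):
        v = rng.uniform(0, 1, 50)
        med = np.median(v)
        q1, q3 = np.percentile(v, [25, 75])
        assert v.max() <= med + 1.5 * (q3 - q1)  # constructed to hold
        kept, removed = tukey_filter(v, np.zeros(50))
        assert removed.size == 0

    def test_groups_filtered_independently(self):
        values = np.array([1.0, 1, 1, 1, 100, 100, 100, 100])
        groups = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        kept, removed = tukey_filter(values, groups)
        assert removed.size == 0  # each group internally homogeneous

    def test_gaussian_upper_tail_rate_matches_oracle(self, rng):
        v = rng.normal(size=1000)
        kept, removed = tukey_filter(v, np.zeros(1000))
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        oracle_removed = np.where(v > med + 1.5 * (q3 - q1))[0]
        assert np.array_equal(removed, oracle_removed)
        # Gaussian upper Tukey rate ~ P(Z > 2.0) ~ 0.35%-1.5% at n=1000
        assert 0 < removed.size < 30

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="fewer"):
            tukey_filter(np.arange(3.0), np.zeros(3))

    def test_two_sided_option(self):
        values = np.array([-30.0, 2, 3, 4, 5])
        _, removed_one = tukey_filter(values, np.zeros(5))
        _, removed_two = tukey_filter(values, np.zeros(5), two_sided=True)
        assert removed_one.size == 0
        assert list(removed_two) == [0]


class TestRobustFit:
    def test_equals_ols_with_huge_tuning_constant(self, rng):
        n = 80
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x])
        y = 1.5 + 2.0 * x + rng.normal(size=n) * 0.3
        fit = robust_fit(y, X, huber_t=1e6)
        beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(fit.beta, beta_ols, rtol=1e-8)

    def test_resists_gross_outlier(self, rng):
        n = 50
        x = np.linspace(0, 10, n)
        X = np.column_stack([np.ones(n), x])
        y = 1 + 2 * x + rng.normal(size=n) * 0.1
        y[-1] += 40.0  # gross outlier at high leverage
        fit = robust_fit(y, X)
        beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert abs(fit.beta[1] - 2.0) < 0.05
        assert abs(beta_ols[1] - 2.0) > 0.2

    def test_constant_response(self):
        X = np.column_stack([np.ones(20), np.linspace(-1, 1, 20)])
        fit = robust_fit(np.full(20, 4.2), X)
        assert fit.beta[0] == pytest.approx(4.2)
        assert fit.beta[1] == pytest.approx(0.0, abs=1e-12)

    def test_se_and_cov_consistent(self, rng):
        n = 60
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        fit = robust_fit(X @ [1, 2] + rng.normal(size=n), X)
        np.testing.assert_allclose(fit.se, np.sqrt(np.diag(fit.cov)))
        # covariance symmetric PSD
        np.testing.assert_allclose(fit.cov, fit.cov.T)
        assert np.all(np.linalg.eigvalsh(fit.cov) > -1e-18)

    def test_rank_deficiency_rejected(self):
        X = np.ones((10, 2))
        with pytest.raises(ValueError, match="rank"):
            robust_fit(np.arange(10.0), X)


def _fit_result(beta, cov, names=("intercept", "eyo", "mutation", "eyo_x_mutation")):
    beta = np.asarray(beta, float)
    cov = np.asarray(cov, float)
    return RobustFitResult(
        beta=beta, se=np.sqrt(np.diag(cov)), cov=cov, scale=1.0,
        n_used=100, n_outliers_removed=0, column_names=tuple(names),
    )


class TestEYOOrdering:
    def test_null_coefficients_never_abnormal(self):
        cov = np.diag([1.0, 1.0, 1.0, 1.0])
        fit = _fit_result([0, 0, 0, 0], cov)
        res = eyo_ordering(fit)
        assert res.earliest_abnormal is None and res.interval is None

    def test_pure_interaction_first_positive_grid_point(self):
        # beta_int > 0, beta_mut = 0, vanishing covariance: diff(e) = e*b
        # is abnormal (positive and CI excluding 0) from the first e > 0
        cov = np.eye(4) * 1e-12
        fit = _fit_result([0, 0, 0.0, 0.1], cov)
        res = eyo_ordering(fit)
        assert res.earliest_abnormal == 5.0
        assert res.interval == (0.0, 5.0)

    def test_closed_form_diff_and_ci(self):
        vm, vi, c = 0.5, 0.02, -0.05
        cov = np.zeros((4, 4))
        cov[2, 2], cov[3, 3] = vm, vi
        cov[2, 3] = cov[3, 2] = c
        fit = _fit_result([0, 0, 1.0, 0.2], cov)
        res = eyo_ordering(fit, grid=[-10, 0, 10])
        e = np.array([-10.0, 0, 10])
        np.testing.assert_allclose(res.diff, 1.0 + 0.2 * e)
        var = vm + e**2 * vi + 2 * e * c
        half = 1.959963984540054 * np.sqrt(var)
        np.testing.assert_allclose(res.ci_high - res.diff, half, rtol=1e-12)
        # CI width convex in e, minimised at e* = -cov/var_int
        estar = -c / vi
        widths = res.ci_high - res.ci_low
        assert widths[1] < widths[0] and widths[1] < widths[2]
        assert e[np.argmin(widths)] == pytest.approx(
            min(e, key=lambda x: abs(x - estar))
        )

    def test_decrease_direction(self):
        cov = np.eye(4) * 1e-12
        fit = _fit_result([0, 0, -1.0, 0.0], cov)
        assert eyo_ordering(fit, direction="increase").earliest_abnormal is None
        assert eyo_ordering(fit, direction="decrease").earliest_abnormal == -25.0

    def test_shift_equivariance(self):
        cov = np.diag([0.1, 0.01, 0.3, 0.004])
        fit = _fit_result([0, 0, 0.8, 0.15], cov)
        res1 = eyo_ordering(fit, grid=np.arange(-25, 11, 5))
        # shifting the grid by +5 shifts the detected point by +5 when
        # coefficients are re-expressed for shifted EYO: diff'(e) = diff(e-5)
        beta_shift = [0, 0, 0.8 - 5 * 0.15, 0.15]
        cov_shift = cov.copy()
        cov_shift[2, 2] = cov[2, 2] + 25 * cov[3, 3]
        cov_shift[2, 3] = cov_shift[3, 2] = -5 * cov[3, 3]
        fit2 = _fit_result(beta_shift, cov_shift)
        res2 = eyo_ordering(fit2, grid=np.arange(-20, 16, 5))
        assert res2.earliest_abnormal == res1.earliest_abnormal + 5

    def test_empty_grid_rejected(self):
        fit = _fit_result([0, 0, 0, 0], np.eye(4))
        with pytest.raises(ValueError, match="grid"):
            eyo_ordering(fit, grid=[])


class TestOrderingSuite:
    def _cohort_tables(self, rng, n_car=50, n_non=40, onset=-10.0, slope=2e-6,
                       noise=8e-6):
        n = n_car + n_non
        carrier = np.arange(n) < n_car
        eyo = rng.uniform(-25, 10, n)
        subjects = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "mutation_carrier": carrier,
                "eyo": eyo,
                "sex": rng.integers(0, 2, n),
                "education": rng.normal(14, 3, n),
                "cdr_positive": carrier & (eyo > 0),
            }
        )
        value = 7e-4 + np.where(carrier, np.clip(eyo - onset, 0, None) * slope, 0)
        value = value + rng.normal(0, noise, n)
        measures = pd.DataFrame(
            {"subject_id": subjects["subject_id"], "measure": "forceps_major",
             "value": value}
        )
        return measures, subjects

    def test_single_measure_single_row(self, rng):
        measures, subjects = self._cohort_tables(rng)
        table, results = run_ordering_suite(measures, subjects)
        assert len(table) == 1
        assert table.iloc[0]["measure"] == "forceps_major"
        assert "forceps_major" in results

    def test_planted_onset_detected_near_truth(self, rng):
        measures, subjects = self._cohort_tables(rng, slope=4e-6, noise=4e-6)
        table, _ = run_ordering_suite(measures, subjects)
        assert table.iloc[0]["earliest_abnormal"] in (-15.0, -10.0, -5.0)

    def test_two_planted_onsets_ranked_correctly(self, rng):
        # noise 1.5e-5 puts the CI half-width between the two regions'
        # group-difference lines at EYO -10, so the -10 onset is detectable
        # there while the 0 onset is not yet
        early, subjects = self._cohort_tables(rng, onset=-10.0, slope=4e-6,
                                              noise=1.5e-5)
        late = early.copy()
        late["measure"] = "atr_l"
        value = 7e-4 + np.where(
            subjects["mutation_carrier"],
            np.clip(subjects["eyo"] - 0.0, 0, None) * 4e-6, 0,
        ) + rng.normal(0, 1.5e-5, len(subjects))
        late["value"] = value
        table, _ = run_ordering_suite(pd.concat([early, late]), subjects)
        by = table.set_index("measure")["earliest_abnormal"]
        assert by["forceps_major"] < by["atr_l"]
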