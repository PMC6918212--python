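"""Validation statistics: normality gate, correlations, ICC, kappa, SRM."""

import numpy as np
import pandas as pd
import pytest

from wristacc.clinimetrics import (
    CohortTable,
    bonferroni_threshold,
    build_validation_report,
    convergent_validity,
    dichotomize_grcs,
    normality_gate,
    split_half_daily_icc,
    srm,
    srm_label,
    weighted_kappa,
)
from wristacc.clinimetrics import test_retest_icc as icc_between
from wristacc.signal import InputError
from wristacc.synth import default_cohort_spec, generate_cohort


class TestNormalityGate:
    def test_size_under_the_null(self):
        """Normal draws pass the gate in at least 90 % of seeded replicates
        (the test has 5 % nominal size)."""
        passes = sum(
            normality_gate(np.random.default_rng(s).normal(size=200))
            for s in range(100)
        )
        assert passes >= 90

    def test_power_against_heavy_tails(self):
        rejects = sum(
            not normality_gate(
                np.random.default_rng(s).standard_cauchy(size=200)
            )
            for s in range(50)
        )
        assert rejects >= 45

    def test_too_small_or_constant(self):
        with pytest.raises(InputError):
            normality_gate([1.0, 2.0])
        with pytest.raises(InputError):
            normality_gate([3.0] * 10)


class TestConvergentValidity:
    def test_exact_linear_relation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        r, p, method, n = convergent_validity(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert method == "pearson"
        assert n == 5

    def test_small_set_matches_formula_oracle(self):
        """Hand-computed covariance/rank coefficients on a tiny printed-style
        data set."""
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        r, _, method, _ = convergent_validity(x, y)
        # from-scratch Pearson
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        expected = cov / (x.std() * y.std())
        assert method == "pearson"
        assert r == pytest.approx(expected, abs=1e-12)

    def test_spearman_branch_on_heavy_tailed_data(self):
        rng = np.random.default_rng(1)
        x = rng.standard_cauchy(100)
        y = x + rng.standard_cauchy(100)
        _, _, method, _ = convergent_validity(x, y)
        assert method == "spearman"

    def test_pearson_on_ranks_equals_spearman(self):
        """With no ties, Pearson of the rank-transformed data equals the
        Spearman coefficient of the raw data."""
        from scipy import stats

        rng = np.random.default_rng(2)
        x = rng.standard_cauchy(60)
        y = x ** 3 + rng.standard_cauchy(60)
        r_spear, _, method, _ = convergent_validity(x, y)
        assert method == "spearman"
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        r_pear = np.corrcoef(rx, ry)[0, 1]
        assert r_spear == pytest.approx(r_pear, abs=1e-12)

    def test_pairwise_deletion(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0, 6.0])
        y = np.array([1.0, 2.0, 3.0, np.nan, 5.0, 6.0])
        _, _, _, n = convergent_validity(x, y)
        assert n == 4

    def test_constant_variable_rejected(self):
        with pytest.raises(InputError):
            convergent_validity([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha,m,expected", [(0.05, 1, 0.05), (0.05, 5, 0.01)]
    )
    def test_division(self, alpha, m, expected):
        assert bonferroni_threshold(alpha, m) == pytest.approx(expected)

    def test_family_of_six_rounds_to_008(self):
        assert round(bonferroni_threshold(0.05, 6), 3) == 0.008

    def test_bad_family_size(self):
        with pytest.raises(InputError):
            bonferroni_threshold(0.05, 0)


def simulate_sessions(n, icc, rng, mean=0.0, sd=2.0):
    sb = sd * np.sqrt(icc)
    se = sd * np.sqrt(1 - icc)
    latent = rng.normal(mean, sb, n)
    return latent + rng.normal(0, se, n), latent + rng.normal(0, se, n)


class TestIcc:
    def test_perfect_agreement(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        icc, n = icc_between(x, x)
        assert icc == pytest.approx(1.0)
        assert n == 5

    def test_matches_pingouin_reference(self):
        """ICC(2,1) and ICC(3,1) agree with an independent published
        implementation on a fixed small table."""
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(8)
        s1, s2 = simulate_sessions(12, 0.7, rng)
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(12), 2),
                "rater": np.tile(["a", "b"], 12),
                "score": np.column_stack([s1, s2]).ravel(),
            }
        )
        ref = pg.intraclass_corr(
            data=df, targets="subject", raters="rater", ratings="score"
        ).set_index("Type")
        for model, ref_type in (("2,1", "ICC(A,1)"), ("3,1", "ICC(C,1)")):
            icc, _ = icc_between(s1, s2, model=model)
            assert icc == pytest.approx(ref.loc[ref_type, "ICC"], abs=1e-10)

    def test_parameter_recovery_075(self):
        """Mean estimate over 200 seeded replicates recovers a true ICC of
        0.75 (between-variance 3, error-variance 1) within 0.05 at n=200."""
        estimates = []
        for s in range(200):
            rng = np.random.default_rng(s)
            latent = rng.normal(0, np.sqrt(3.0), 200)
            s1 = latent + rng.normal(0, 1.0, 200)
            s2 = latent + rng.normal(0, 1.0, 200)
            estimates.append(icc_between(s1, s2)[0])
        assert np.mean(estimates) == pytest.approx(0.75, abs=0.05)

    def test_independent_sessions_near_zero(self):
        rng = np.random.default_rng(0)
        icc, _ = icc_between(rng.normal(size=500), rng.normal(size=500))
        assert abs(icc) < 0.1

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(4)
        s1, s2 = simulate_sessions(30, 0.6, rng)
        base, _ = icc_between(s1, s2)
        scaled, _ = icc_between(3.0 * s1 + 7.0, 3.0 * s2 + 7.0)
        assert scaled == pytest.approx(base, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(InputError):
            icc_between([2.0] * 6, [2.0] * 6)


class TestSplitHalfDailyIcc:
    def test_constant_series_per_subject(self):
        series = {i: [float(i)] * 6 for i in range(10)}
        icc, n, excluded = split_half_daily_icc(series)
        assert icc == pytest.approx(1.0)
        assert n == 10 and excluded == 0

    def test_three_day_means_shrink_within_variance(self):
        """Means of 3 i.i.d. days have ICC sb^2/(sb^2 + se^2/3); the
        estimate recovers that closed form within 0.05 at n=200."""
        sb2, se2 = 1.0, 1.5
        expected = sb2 / (sb2 + se2 / 3)
        estimates = []
        for s in range(40):
            rng = np.random.default_rng(s)
            latent = rng.normal(0, np.sqrt(sb2), 200)
            series = {
                i: latent[i] + rng.normal(0, np.sqrt(se2), 6)
                for i in range(200)
            }
            estimates.append(split_half_daily_icc(series)[0])
        assert np.mean(estimates) == pytest.approx(expected, abs=0.05)

    def test_short_series_excluded_and_counted(self):
        rng = np.random.default_rng(1)
        series = {i: rng.normal(i, 0.1, 6) for i in range(8)}
        series[99] = np.array([1.0, 2.0])
        icc, n, excluded = split_half_daily_icc(series)
        assert n == 8 and excluded == 1

    def test_all_subjects_too_short(self):
        with pytest.raises(InputError):
            split_half_daily_icc({i: [1.0, 2.0] for i in range(10)})


class TestWeightedKappa:
    def test_perfect_agreement(self):
        r = [1, 2, 3, 1, 2, 3]
        assert weighted_kappa(r, r) == pytest.approx(1.0)

    def test_contingency_table_matches_hand_oracle(self):
        """3x3 table [[5,1,0],[1,5,1],[0,1,5]]: cell-by-cell computation."""
        counts = np.array([[5, 1, 0], [1, 5, 1], [0, 1, 5]], dtype=float)
        r1, r2 = [], []
        for i in range(3):
            for j in range(3):
                r1 += [i] * int(counts[i, j])
                r2 += [j] * int(counts[i, j])
        # hand oracle: linear weights
        n = counts.sum()
        obs = counts / n
        marg1, marg2 = obs.sum(1), obs.sum(0)
        num = den = 0.0
        for i in range(3):
            for j in range(3):
                w = abs(i - j) / 2
                num += w * obs[i, j]
                den += w * marg1[i] * marg2[j]
        expected = 1 - num / den
        assert weighted_kappa(r1, r2) == pytest.approx(expected, abs=1e-12)

    def test_matches_sklearn_reference(self):
        sk = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(5)
        r1 = rng.integers(0, 4, 100)
        r2 = np.clip(r1 + rng.integers(-1, 2, 100), 0, 3)
        for weights in ("linear", "quadratic"):
            ours = weighted_kappa(r1.tolist(), r2.tolist(),
                                  categories=[0, 1, 2, 3], weights=weights)
            ref = sk.cohen_kappa_score(r1, r2, weights=weights)
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_independent_ratings_near_zero(self):
        rng = np.random.default_rng(9)
        r1 = rng.integers(0, 5, 1000).tolist()
        r2 = rng.integers(0, 5, 1000).tolist()
        assert abs(weighted_kappa(r1, r2)) < 0.1

    def test_single_shared_category_rejected(self):
        with pytest.raises(InputError):
            weighted_kappa([1, 1, 1], [1, 1, 1])


class TestDichotomizeGrcs:
    def test_three_way_split(self):
        groups = dichotomize_grcs({"a": 5, "b": 0, "c": -5})
        assert groups.improved == {"a"}
        assert groups.stable == {"b"}
        assert groups.worsened == {"c"}

    @pytest.mark.parametrize(
        "score,group",
        [(4, "improved"), (3, "stable"), (-3, "stable"), (-4, "worsened"),
         (7, "improved"), (-7, "worsened"), (0, "stable")],
    )
    def test_boundaries(self, score, group):
        groups = dichotomize_grcs({"s": score})
        assert "s" in getattr(groups, group)

    def test_partition_over_all_fifteen_values(self):
        grcs = {i: i for i in range(-7, 8)}
        groups = dichotomize_grcs(grcs)
        union = groups.improved | groups.stable | groups.worsened
        assert union == set(grcs)
        assert not (groups.improved & groups.stable)
        assert not (groups.improved & groups.worsened)
        assert not (groups.stable & groups.worsened)

    def test_all_zero_scores_stable(self):
        groups = dichotomize_grcs({i: 0 for i in range(10)})
        assert groups.stable == frozenset(range(10))

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            dichotomize_grcs({"a": 8})


class TestSrm:
    def test_no_change(self):
        res = srm([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.srm == 0.0
        assert res.label == "minimal"

    def test_closed_form_changes_123(self):
        """Changes (1,2,3): mean 2, sample SD 1, SRM exactly 2, large."""
        res = srm([0.0, 0.0, 0.0], [1.0, 2.0, 3.0])
        assert res.srm == pytest.approx(2.0, abs=1e-12)
        assert res.label == "large"
        assert res.n == 3

    @pytest.mark.parametrize(
        "value,label",
        [(0.0, "minimal"), (0.19, "minimal"), (0.2, "small"),
         (0.49, "small"), (0.5, "moderate"), (0.79, "moderate"),
         (0.8, "large"), (0.85, "large"), (2.0, "large")],
    )
    def test_effect_bands(self, value, label):
        assert srm_label(value) == label

    def test_scale_invariance(self):
        rng = np.random.default_rng(6)
        pre = rng.normal(50, 10, 30)
        post = pre + rng.normal(3, 5, 30)
        base = srm(pre, post)
        for _ in range(5):
            k = float(rng.uniform(0.1, 20))
            assert srm(k * pre, k * post).srm == pytest.approx(
                base.srm, rel=1e-9
            )

    def test_sign_retained_alongside_magnitude(self):
        res = srm([10.0, 20.0, 30.0], [7.0, 18.0, 26.0])
        assert res.srm > 0
        assert res.signed_mean_change < 0

    def test_degenerate_inputs(self):
        with pytest.raises(InputError):
            srm([1.0], [2.0])
        with pytest.raises(InputError):
            srm([0.0, 0.0], [1.0, 1.0])  # zero change-SD, nonzero mean


class TestBuildValidationReport:
    def test_null_cohort_srm_small(self):
        """Zero planted treatment effect: every SRM label stays within
        sampling error of zero (minimal or small) in the larger groups."""
        spec = default_cohort_spec(seed=21, n_subjects=150)
        variables = {
            k: type(v)(**{**vars(v), "effect_w2_improved": 0.0,
                          "effect_w4_improved": 0.0,
                          "effect_w2_stable": 0.0,
                          "effect_w4_stable": 0.0})
            for k, v in spec.variables.items()
        }
        spec = type(spec)(**{**vars(spec), "variables": variables})
        cohort, _ = generate_cohort(spec)
        report = build_validation_report(cohort)
        big = report.srm[report.srm.n >= 30]
        assert (big.label.isin(["minimal", "small"])).all()

    def test_planted_effect_recovered(self):
        """A large improvement planted only in the improved stratum yields
        a large improved-group SRM and a minimal stable-group SRM."""
        spec = default_cohort_spec(seed=5, n_subjects=200,
                                   missing_day_rate=0.0,
                                   data_loss_rate=0.0)
        cohort, _ = generate_cohort(spec)
        report = build_validation_report(cohort)
        worc = report.srm.set_index(["variable", "week", "group"])
        assert worc.loc[("worc", "week2", "improved"), "label"] == "large"
        assert worc.loc[("worc", "week2", "stable"), "label"] in (
            "minimal", "small"
        )

    def test_single_timepoint_rejected(self):
        cohort, _ = generate_cohort(default_cohort_spec(seed=0))
        scores = cohort.scores.loc[
            cohort.scores.index.get_level_values("timepoint") == "visit0"
        ]
        with pytest.raises(InputError, match="timepoint"):
            build_validation_report(
                CohortTable(scores=scores, grcs=cohort.grcs)
            )

    def test_report_shapes_and_flags(self):
        cohort, _ = generate_cohort(default_cohort_spec(seed=2))
        report = build_validation_report(cohort)
        assert {"var_x", "var_y", "r", "p", "method", "n",
                "significant"} <= set(report.correlations.columns)
        assert (report.correlations.r.abs() <= 1.0 + 1e-12).all()
        assert (report.icc.icc <= 1.0 + 1e-12).all()
        assert report.bonferroni_alpha < 0.05
        for _, row in report.srm.iterrows():
            assert row["label"] == srm_label(row["srm"])
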