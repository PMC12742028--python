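"""Threshold classifier, effect sizes, binomial/Fisher/FDR, Bayes factors."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from sbdecode.stats import (
    HIGH_IS_POSITIVE,
    LOW_IS_POSITIVE,
    bh_fdr,
    binomial_vs_chance,
    boundary_sweep,
    build_stats_report,
    cohens_d,
    correlation_bf10,
    covariate_correlation,
    fisher_combine,
    participant_summary,
    univariate_threshold_accuracy,
)


class TestThresholdClassifier:
    def test_separated_point_masses(self):
        acc = univariate_threshold_accuracy(
            np.zeros(10), np.ones(10), LOW_IS_POSITIVE
        )
        assert acc == 1.0

    def test_identical_distributions_near_chance(self, rng):
        a = rng.normal(size=2000)
        b = rng.normal(size=2000)
        acc = univariate_threshold_accuracy(a, b, LOW_IS_POSITIVE)
        assert abs(acc - 0.5) < 0.03

    def test_zero_variance_gives_half_by_convention(self):
        acc = univariate_threshold_accuracy(np.ones(5), np.ones(5), LOW_IS_POSITIVE)
        assert acc == 0.5

    def test_gaussian_closed_form_phi_d_over_2(self, rng):
        """Equal-variance Gaussians with means 0 and 0.4: the grand-mean
        threshold accuracy converges to Phi(0.2)."""
        n = 100_000
        a = rng.normal(0.0, 1.0, n)
        b = rng.normal(0.4, 1.0, n)
        acc = univariate_threshold_accuracy(a, b, LOW_IS_POSITIVE)
        assert abs(acc - sstats.norm.cdf(0.2)) < 0.01


class TestBoundarySweep:
    def test_symmetric_classes_have_no_improvement(self, rng):
        a = rng.normal(-0.3, 1.0, 5000)
        b = rng.normal(0.3, 1.0, 5000)
        _, _, delta = boundary_sweep(a, b, LOW_IS_POSITIVE)
        assert delta < 0.01

    def test_grid_with_grand_mean_never_loses(self, rng):
        a = rng.normal(0, 1, 200)
        b = rng.normal(1, 2, 50)
        pooled_mean = np.concatenate([a, b]).mean()
        grid = np.append(np.linspace(-2, 3, 21), pooled_mean)
        _, best, delta = boundary_sweep(a, b, LOW_IS_POSITIVE, grid)
        assert delta >= 0
        assert best >= univariate_threshold_accuracy(a, b, LOW_IS_POSITIVE)

    def test_skewed_classes_can_improve(self):
        a = np.concatenate([np.zeros(90), np.full(0, 0.0)])
        b = np.full(10, 2.0)
        _, _, delta = boundary_sweep(a, b, LOW_IS_POSITIVE, np.linspace(-1, 3, 101))
        assert delta >= 0

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValueError):
            boundary_sweep(rng.normal(size=5), rng.normal(size=5),
                           LOW_IS_POSITIVE, np.array([]))


class TestCohensD:
    def test_identical_groups_zero(self):
        x = np.array([1.0, 2.0, 3.0])
        assert cohens_d(x, x) == 0.0

    def test_one_pooled_sd_apart_is_one(self, rng):
        x = rng.normal(0, 1, 500_000)
        y = x + 1.0 * np.sqrt(x.var(ddof=1))
        assert cohens_d(y, x) == pytest.approx(1.0, abs=1e-9)

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError):
            cohens_d(np.ones(5), np.ones(5))


class TestBinomial:
    def test_modal_outcome_p_is_one(self):
        assert binomial_vs_chance(50, 100) == 1.0

    def test_all_correct_closed_form(self):
        assert binomial_vs_chance(10, 10) == pytest.approx(2 * 0.5**10, rel=1e-12)

    def test_symmetry_in_k(self):
        for n, k in [(75, 50), (300, 170), (33, 5)]:
            assert binomial_vs_chance(k, n) == pytest.approx(
                binomial_vs_chance(n - k, n), rel=1e-12
            )

    @pytest.mark.parametrize("n", [75, 300])
    def test_type_i_calibration(self, n, rng):
        """Under k ~ Binomial(n, 0.5), rejection at alpha = 0.05 stays at or
        below 0.05 (+2 Monte-Carlo SEs)."""
        draws = 5000
        pvals_by_k = np.array([binomial_vs_chance(k, n) for k in range(n + 1)])
        ks = rng.binomial(n, 0.5, size=draws)
        rejections = np.mean(pvals_by_k[ks] < 0.05)
        se = np.sqrt(0.05 * 0.95 / draws)
        assert rejections <= 0.05 + 2 * se


class TestFisher:
    def test_single_p_identity(self):
        _, combined = fisher_combine([0.037])
        assert combined == pytest.approx(0.037, rel=1e-9)

    def test_all_ones_boundary(self):
        chi2, combined = fisher_combine([1.0, 1.0, 1.0])
        assert chi2 == 0.0 and combined == 1.0

    def test_hand_computed_worked_example(self):
        chi2, combined = fisher_combine([0.1, 0.1])
        assert chi2 == pytest.approx(9.2103, abs=1e-4)
        assert combined == pytest.approx(0.0563, abs=5e-4)

    def test_agrees_with_scipy(self, rng):
        p = rng.uniform(0.001, 1, size=7)
        chi2, combined = fisher_combine(p)
        ref = sstats.combine_pvalues(p, method="fisher")
        assert chi2 == pytest.approx(ref.statistic, rel=1e-12)
        assert combined == pytest.approx(ref.pvalue, rel=1e-12)

    def test_uniform_inputs_give_uniform_output(self, rng):
        """Combining uniform p-values must itself be uniform (KS test)."""
        draws = 5000
        p = rng.uniform(size=(draws, 5))
        chi2 = -2 * np.log(p).sum(axis=1)
        combined = sstats.chi2.sf(chi2, df=10)
        assert sstats.kstest(combined, "uniform").pvalue > 0.01

    def test_zero_p_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipping"):
            chi2, combined = fisher_combine([0.0, 0.5])
        assert np.isfinite(chi2) and combined >= 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fisher_combine([])


class TestBhFdr:
    def test_single_test_unchanged(self):
        assert bh_fdr([0.03], ["univariate"])[0] == pytest.approx(0.03)

    def test_stepup_hand_computation(self):
        adjusted = bh_fdr([0.01, 0.02, 0.03, 0.04], ["univariate"] * 4)
        np.testing.assert_allclose(adjusted, [0.04] * 4)

    def test_families_are_independent(self):
        p_a = [0.01, 0.2]
        p_b = [0.03, 0.5, 0.8]
        joint = bh_fdr(p_a + p_b, ["univariate"] * 2 + ["multivariate"] * 3)
        alone = bh_fdr(p_b, ["multivariate"] * 3)
        np.testing.assert_allclose(joint[2:], alone)

    def test_monotone_in_rank(self, rng):
        p = np.sort(rng.uniform(size=20))
        adjusted = bh_fdr(p, ["univariate"] * 20)
        assert np.all(np.diff(adjusted) >= -1e-12)
        assert np.all(adjusted >= p - 1e-12)

    def test_all_null_family_of_44_controls_fdr(self, rng):
        """Empirical FDR over an all-null family the size of the full test
        battery stays at or below the nominal 0.05 level."""
        reps = 2000
        any_rejection = 0
        for _ in range(reps):
            p = rng.uniform(size=44)
            any_rejection += (bh_fdr(p, ["univariate"] * 44) < 0.05).any()
        fdr = any_rejection / reps
        se = np.sqrt(0.05 * 0.95 / reps)
        assert fdr <= 0.05 + 2 * se

    def test_unknown_family_rejected(self):
        tests = pd.DataFrame(
            {"test_id": ["t1"], "family": ["exploratory"], "p_raw": [0.5]}
        )
        with pytest.raises(ValueError, match="exploratory"):
            build_stats_report(tests)


class TestParticipantSummary:
    def test_exact_chance_everywhere_combines_to_one(self):
        results = {f"P{i}": (38, 76) for i in range(10)}
        summary = participant_summary(results)
        assert summary.fisher_p == pytest.approx(1.0)
        assert summary.mean_accuracy == pytest.approx(0.5)

    def test_counts_and_ci_cover_mean(self, rng):
        results = {f"P{i}": (int(k), 75) for i, k in
                   enumerate(rng.binomial(75, 0.5, size=41))}
        summary = participant_summary(results)
        assert len(summary.per_participant_p) == 41
        lo, hi = summary.ci95
        assert lo < summary.mean_accuracy < hi

    def test_fisher_accumulates_consistent_weak_evidence(self):
        """Fisher's sensitivity: weak but consistent above-chance results
        combine into evidence far stronger than the best single test after
        multiplicity correction."""
        results = {f"P{i}": (45, 75) for i in range(10)}
        summary = participant_summary(results)
        min_corrected = summary.per_participant_p.min() * len(results)
        assert summary.fisher_p < 0.05 < min_corrected
        assert summary.fisher_p < min_corrected

    def test_needs_two_participants(self):
        with pytest.raises(ValueError):
            participant_summary({"P0": (40, 75)})


class TestCovariateCorrelation:
    def test_perfect_monotone_rho_one(self):
        x = np.arange(10.0)
        res = covariate_correlation(x, np.exp(x))
        assert res.spearman_rho == pytest.approx(1.0)

    def test_extreme_outlier_removed(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        x[0] = 1e6
        res = covariate_correlation(x, y)
        assert res.n_after_outlier_removal == 19

    def test_constant_metric_rejected(self):
        with pytest.raises(ValueError):
            covariate_correlation(np.ones(10), np.arange(10.0))

    def test_independent_pairs_favor_null(self, rng):
        """With independent variables at the study's sample size, the Bayes
        factor should typically favour the absence of a correlation."""
        bfs = []
        for _ in range(50):
            res = covariate_correlation(rng.normal(size=41), rng.normal(size=41))
            bfs.append(res.bayes_factor)
        assert np.median(bfs) < 1.0

    def test_strong_correlation_large_bf(self, rng):
        x = rng.normal(size=41)
        y = x + 0.4 * rng.normal(size=41)
        res = covariate_correlation(x, y)
        assert res.bayes_factor > 100

    def test_bf_matches_independent_implementation(self):
        """Cross-check against the published default-Bayes-factor routine."""
        pg = pytest.importorskip("pingouin")
        for r, n in [(0.5, 20), (0.2, 41), (-0.3, 30)]:
            assert correlation_bf10(r, n) == pytest.approx(
                float(pg.bayesfactor_pearson(r, n)), rel=1e-4
            )
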