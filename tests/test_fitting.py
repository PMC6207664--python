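"""Aggregation, conjoint ML/IRLS fitting, LRT, deviance, thresholds."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit

import briefmotion as bm
from briefmotion.exceptions import DegenerateDataError, InconsistentFitsError
from briefmotion.fitting import ConditionCounts, ConjointPsychometric, FitResult, PsychometricModel

from conftest import TRUE_OBSERVER, make_counts


def toy_records():
    """28 trials: 7 durations x 2 platforms x 2 repeats, one participant/size."""
    d = bm.make_duration_grid(7, 0.01, 0.2)
    rows = []
    for platform in ("CRT", "tablet"):
        for rep in range(2):
            for dur in d:
                rows.append(
                    {
                        "participant": 1,
                        "platform": platform,
                        "block": 1,
                        "part": rep + 1,
                        "size": "small",
                        "duration_s": dur,
                        "direction": "left",
                        "phase_deg": 0.0,
                        "response": "left",
                        "correct": True,
                    }
                )
    return pd.DataFrame(rows)


class TestAggregateCounts:
    def test_tablet_shortest_exclusion_drops_two_of_28(self):
        records = toy_records()
        counts = bm.aggregate_counts(records, exclude_tablet_shortest=True)
        retained = sum(c.n.sum() for c in counts.values())
        assert retained == 26
        assert len(counts[(1, "tablet", "small")].durations) == 6

    def test_flag_off_conserves_trials(self, small_study_trials):
        counts = bm.aggregate_counts(small_study_trials, exclude_tablet_shortest=False)
        assert sum(c.n.sum() for c in counts.values()) == len(small_study_trials)

    def test_all_correct_gives_k_equal_n(self):
        counts = bm.aggregate_counts(toy_records(), exclude_tablet_shortest=False)
        for c in counts.values():
            assert np.array_equal(c.k, c.n)

    def test_empty_input_gives_empty_result(self):
        assert bm.aggregate_counts(toy_records().iloc[:0]) == {}


class TestConjointFit:
    def test_parameter_recovery_within_bootstrap_ci(self, clean_counts, clean_fit):
        """Generating thresholds (0.02 / 0.05 s) lie in their own 99% CIs."""
        assert clean_fit.converged
        dists = bm.parametric_bootstrap_thresholds(
            clean_fit, clean_counts["small"], clean_counts["large"], B=2000, seed=1
        )
        for size, truth in (("small", 0.02), ("large", 0.05)):
            lo, hi = bm.percentile_ci(dists[size], level=0.99)
            assert lo <= np.log10(truth) <= hi
        # slope recovered to the right scale as well
        assert clean_fit.model.slope_small == pytest.approx(0.15, abs=0.05)

    def test_identical_counts_give_equal_locations(self, clean_counts):
        c = clean_counts["small"]
        fit = bm.fit_conjoint(c, c)
        assert fit.model.location_small == pytest.approx(
            fit.model.location_large, abs=1e-6
        )

    def test_shared_loglik_never_exceeds_free(self, clean_counts):
        for seed in range(5):
            counts = make_counts(TRUE_OBSERVER, 40, seed=seed)
            shared = bm.fit_conjoint(counts["small"], counts["large"], True)
            free = bm.fit_conjoint(counts["small"], counts["large"], False)
            assert shared.log_likelihood <= free.log_likelihood + 1e-6

    def test_ml_matches_exhaustive_grid_search_oracle(self):
        """On a tiny instance, direct ML beats every point of a dense grid."""
        d = bm.make_duration_grid(4, 0.01, 0.2)
        counts = make_counts(TRUE_OBSERVER, 20, seed=3, durations=d)
        fit = bm.fit_conjoint(counts["small"], counts["large"])
        x = np.tile(np.log10(d), 2)
        k = np.concatenate([counts["small"].k, counts["large"].k])
        n = np.concatenate([counts["small"].n, counts["large"].n])
        grp = np.repeat([0, 1], 4)

        mus = np.linspace(x.min() - 0.4, x.max() + 0.4, 49)
        sigmas = np.geomspace(0.02, 1.0, 25)
        M0, M1, S = np.meshgrid(mus, mus, sigmas, indexing="ij")
        mu_pts = np.where(grp == 0, M0[..., None], M1[..., None])
        p = 0.5 + 0.5 * expit((x - mu_pts) / S[..., None])
        p = np.clip(p, 1e-12, 1 - 1e-12)
        ll_grid = np.sum(k * np.log(p) + (n - k) * np.log1p(-p), axis=-1)
        assert fit.log_likelihood >= ll_grid.max() - 1e-6

    def test_degenerate_single_duration_raises(self):
        c = ConditionCounts(np.array([0.02]), np.array([50]), np.array([40]))
        with pytest.raises(DegenerateDataError):
            bm.fit_conjoint(c, c)

    def test_location_monotone_in_correct_trials_at_fixed_slope(self):
        """With the slope held fixed, extra correct trials at long durations
        can only lower the fitted location (the score in mu is monotone in
        every k).  The unconstrained fit lacks this guarantee because added
        top-duration successes also steepen the shared slope."""
        for seed in range(4):
            counts = make_counts(TRUE_OBSERVER, 40, seed=seed)
            c = counts["small"]
            slope = bm.fit_conjoint(c, c).model.slope_small
            x = c.log10_durations
            mu_grid = np.linspace(x.min() - 0.5, x.max() + 0.5, 2001)

            def best_mu(k, n):
                ll = []
                for mu in mu_grid:
                    model = PsychometricModel(mu, mu, slope, slope)
                    p = np.clip(model.prob_correct(x, "small"), 1e-12, 1 - 1e-12)
                    ll.append(np.sum(k * np.log(p) + (n - k) * np.log1p(-p)))
                return mu_grid[int(np.argmax(ll))]

            add = np.array([0] * 5 + [100, 100])
            assert best_mu(c.k + add, c.n + add) <= best_mu(c.k, c.n) + 1e-9

    def test_log_base_invariance_of_thresholds(self, clean_counts):
        """Fitting on natural-log durations yields identical thresholds."""
        cs, cl = clean_counts["small"], clean_counts["large"]
        thr10 = bm.threshold_from_fit(bm.fit_conjoint(cs, cl))
        x_ln = np.concatenate([np.log(cs.durations), np.log(cl.durations)])
        X = np.column_stack([x_ln, np.repeat([0, 1], len(cs.durations))])
        y = np.concatenate([cs.k / cs.n, cl.k / cl.n])
        w = np.concatenate([cs.n, cl.n])
        est = ConjointPsychometric().fit(X, y, sample_weight=w)
        thr_ln = np.exp(est.locations_)  # locations are in ln-duration units
        assert thr_ln[0] == pytest.approx(thr10["small"], rel=1e-5)
        assert thr_ln[1] == pytest.approx(thr10["large"], rel=1e-5)


class TestIRLSRoute:
    def test_agreement_with_ml_within_1e3_log_units(self, clean_counts):
        cs, cl = clean_counts["small"], clean_counts["large"]
        t_ml = bm.threshold_from_fit(bm.fit_conjoint(cs, cl))
        t_irls = bm.threshold_from_fit(bm.fit_conjoint_irls(cs, cl))
        for size in ("small", "large"):
            assert abs(np.log10(t_ml[size]) - np.log10(t_irls[size])) < 1e-3

    def test_agreement_free_slopes_too(self, clean_counts):
        cs, cl = clean_counts["small"], clean_counts["large"]
        f_ml = bm.fit_conjoint(cs, cl, share_slope=False)
        f_irls = bm.fit_conjoint_irls(cs, cl, share_slope=False)
        assert f_ml.log_likelihood == pytest.approx(f_irls.log_likelihood, abs=1e-4)

    def test_separable_data_flagged_not_silent(self):
        d = bm.make_duration_grid(6, 0.01, 0.2)
        n = np.full(6, 20)
        k = np.array([10, 10, 10, 20, 20, 20])  # chance then perfect
        c = ConditionCounts(d, n, k)
        fit = bm.fit_conjoint_irls(c, c)
        assert not fit.converged

    def test_refit_of_own_fitted_proportions_is_fixed_point(self, clean_counts):
        cs, cl = clean_counts["small"], clean_counts["large"]
        first = bm.fit_conjoint_irls(cs, cl)
        x = np.concatenate([cs.log10_durations, cl.log10_durations])
        grp = np.repeat([0, 1], len(cs.durations))
        X = np.column_stack([x, grp])
        p_fit = np.where(
            grp == 0,
            first.model.prob_correct(x, "small"),
            first.model.prob_correct(x, "large"),
        )
        est = ConjointPsychometric(method="irls").fit(
            X, p_fit, sample_weight=np.concatenate([cs.n, cl.n])
        )
        assert est.locations_[0] == pytest.approx(first.model.location_small, abs=1e-6)
        assert est.slopes_[0] == pytest.approx(first.model.slope_small, abs=1e-6)


class TestThreshold:
    def test_midpoint_identity(self):
        model = PsychometricModel(np.log10(0.02), np.log10(0.05), 0.15, 0.15)
        fit = FitResult(model, 0.0, 0.0, 3, True, "ML", True)
        thr = bm.threshold_from_fit(fit, criterion=0.75)
        assert thr["small"] == pytest.approx(0.02)
        assert thr["large"] == pytest.approx(0.05)

    def test_unreachable_criterion_raises(self):
        model = PsychometricModel(-1.7, -1.3, 0.15, 0.15)
        fit = FitResult(model, 0.0, 0.0, 3, True, "ML", True)
        for bad in (0.5, 0.4, 1.0):
            with pytest.raises(ValueError):
                bm.threshold_from_fit(fit, criterion=bad)

    def test_other_criteria_move_threshold_along_slope(self):
        model = PsychometricModel(np.log10(0.02), np.log10(0.05), 0.15, 0.15)
        fit = FitResult(model, 0.0, 0.0, 3, True, "ML", True)
        t80 = bm.threshold_from_fit(fit, criterion=0.80)
        assert t80["small"] > 0.02  # higher criterion needs longer duration


class TestLikelihoodRatio:
    def _fit(self, ll, n_params):
        model = PsychometricModel(-1.7, -1.3, 0.15, 0.15)
        return FitResult(model, ll, 0.0, n_params, True, "ML", n_params == 3)

    def test_identical_data_gives_null_result(self, clean_counts):
        c = clean_counts["small"]
        shared = bm.fit_conjoint(c, c, True)
        free = bm.fit_conjoint(c, c, False)
        res = bm.likelihood_ratio_test(shared, free)
        assert res.statistic == pytest.approx(0.0, abs=0.05)
        assert res.p_value > 0.5

    def test_printed_statistic_pairs_with_printed_p(self):
        """D = 14 on 1 df corresponds to p ~ 1.8e-4 (printed as 2e-4)."""
        res = bm.likelihood_ratio_test(self._fit(-100.0, 3), self._fit(-93.0, 4))
        assert res.statistic == pytest.approx(14.0)
        assert res.p_value == pytest.approx(1.827e-4, rel=5e-3)
        assert res.p_value == pytest.approx(2e-4, abs=0.3e-4)
        assert res.significant  # alpha = 0.01

    def test_zero_statistic_gives_p_one(self):
        res = bm.likelihood_ratio_test(self._fit(-100.0, 3), self._fit(-100.0, 4))
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_inconsistent_ordering_raises(self):
        with pytest.raises(InconsistentFitsError):
            bm.likelihood_ratio_test(self._fit(-90.0, 3), self._fit(-100.0, 4))


class TestDeviance:
    def test_matches_independent_binomial_logpmf_oracle(self):
        """Deviance equals twice the saturated-vs-model logpmf gap."""
        d = bm.make_duration_grid(4, 0.01, 0.2)
        n = np.full(4, 10)
        k = np.array([5, 7, 9, 10])
        counts = ConditionCounts(d, n, k)
        model = PsychometricModel(np.log10(0.02), np.log10(0.02), 0.2, 0.2)
        fit = FitResult(model, 0.0, 0.0, 3, True, "ML", True)
        got = bm.deviance(fit, counts, counts)

        oracle = 0.0
        for size in ("small", "large"):
            p = model.prob_correct(np.log10(d), size)
            oracle += 2.0 * np.sum(
                stats.binom.logpmf(k, n, k / n) - stats.binom.logpmf(k, n, p)
            )
        assert got == pytest.approx(oracle, rel=1e-10)

    def test_perfect_model_gives_zero(self):
        d = bm.make_duration_grid(4, 0.01, 0.2)
        model = PsychometricModel(np.log10(0.02), np.log10(0.05), 0.15, 0.15)
        n = np.full(4, 10**6)
        ks = np.round(n * model.prob_correct(np.log10(d), "small")).astype(int)
        kl = np.round(n * model.prob_correct(np.log10(d), "large")).astype(int)
        fit = FitResult(model, 0.0, 0.0, 3, True, "ML", True)
        got = bm.deviance(fit, ConditionCounts(d, n, ks), ConditionCounts(d, n, kl))
        # rounding k to integers leaves a tiny residual deviance
        assert got == pytest.approx(0.0, abs=1e-2)

    def test_nonnegative_on_fits(self, clean_counts, clean_fit):
        assert clean_fit.deviance >= 0.0
        assert bm.deviance(
            clean_fit, clean_counts["small"], clean_counts["large"]
        ) == pytest.approx(clean_fit.deviance, rel=1e-9)
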