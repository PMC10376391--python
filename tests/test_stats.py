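"""Group comparisons, ROC/Youden, DeLong, ICC, combinations."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dkitex import (
    binormal_auc,
    delong_compare,
    fit_combination,
    icc_agreement,
    mann_whitney,
    mean_binormal_empirical_auc,
    roc_auc,
    sample_cohort,
    virads_classifier,
    youden_cutoff,
)
from dkitex.phantom import STAGE_MIBC, STAGE_NMIBC
from dkitex.stats import _u_statistic, icc_band


def brute_force_auc(pos, neg):
    """P(score_pos > score_neg) + 0.5 P(equal), by exhaustive pairing."""
    wins = ties = 0
    for p in pos:
        for n in neg:
            wins += p > n
            ties += p == n
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestMannWhitney:
    def test_complete_separation_exact_p(self):
        r = mann_whitney([1, 2], [3, 4])
        assert r.u_statistic == 0.0
        assert r.p_value == pytest.approx(2 / 6)
        assert r.method == "exact"

    def test_identical_multisets(self):
        r = mann_whitney([1, 2, 3], [1, 2, 3])
        assert r.u_statistic == 9 / 2
        assert r.p_value == 1.0

    def test_exact_and_normal_approximation_agree(self, rng):
        """At n1 = n2 = 8 both p-value branches agree within 0.02."""
        for _ in range(20):
            x = rng.normal(0, 1, 8)
            y = rng.normal(0.5, 1, 8)
            exact = mann_whitney(x, y).p_value
            approx = float(sps.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic").pvalue)
            assert abs(exact - approx) < 0.02

    def test_p_invariant_under_increasing_transform(self, rng):
        x = rng.normal(1.0, 0.3, 20)
        y = rng.normal(1.4, 0.3, 25)
        a = mann_whitney(x, y)
        b = mann_whitney(np.exp(x), np.exp(y))
        assert a.p_value == pytest.approx(b.p_value, rel=1e-12)
        assert a.u_statistic == b.u_statistic

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestROC:
    def test_auc_equals_u_statistic_identity(self, rng):
        """AUC = U/(n1*n2) exactly on 100 random datasets, ties included."""
        for _ in range(100):
            n1, n2 = rng.integers(3, 30, 2)
            pos = rng.integers(0, 8, n1).astype(float)  # integer scores force ties
            neg = rng.integers(0, 8, n2).astype(float)
            scores = np.r_[pos, neg]
            labels = np.r_[np.ones(n1, bool), np.zeros(n2, bool)]
            res = roc_auc(scores, labels, direction="higher")
            assert res.auc == pytest.approx(_u_statistic(pos, neg) / (n1 * n2), abs=1e-12)
            assert res.auc == pytest.approx(brute_force_auc(pos, neg), abs=1e-12)

    def test_perfect_separation(self):
        scores = np.r_[np.ones(5), np.zeros(5)]
        labels = np.r_[np.ones(5, bool), np.zeros(5, bool)]
        res = roc_auc(scores, labels)
        assert res.auc == 1.0
        assert res.ci95[1] == 1.0
        assert res.sensitivity == 100.0 and res.specificity == 100.0

    def test_all_ties_give_half(self):
        scores = np.ones(10)
        labels = np.r_[np.ones(4, bool), np.zeros(6, bool)]
        assert roc_auc(scores, labels).auc == 0.5

    def test_lower_direction_flips_orientation(self, rng):
        pos = rng.normal(1.0, 0.3, 30)
        neg = rng.normal(1.6, 0.3, 40)
        scores = np.r_[pos, neg]
        labels = np.r_[np.ones(30, bool), np.zeros(40, bool)]
        auto = roc_auc(scores, labels)
        assert auto.direction == "lower"
        assert auto.auc > 0.5

    def test_empirical_auc_converges_to_binormal(self):
        auc = mean_binormal_empirical_auc(1.13, 0.31, 50_000, 1.65, 0.42, 50_000,
                                          direction="lower", n_rep=1, seed=0)
        assert auc == pytest.approx(binormal_auc(1.13, 0.31, 1.65, 0.42), abs=0.005)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], [True, True])


class TestYouden:
    def test_separated_groups_midpoint_cutoff(self):
        scores = np.array([1, 2, 5, 6], float)
        labels = np.array([False, False, True, True])
        cutoff, sens, spec = youden_cutoff(scores, labels, "higher")
        assert cutoff == 3.5
        assert sens == 100.0 and spec == 100.0

    def test_matches_exhaustive_scan(self, rng):
        """The returned cutoff attains the maximal J found by scanning every
        threshold on 100 random datasets."""
        for _ in range(100):
            n1, n2 = rng.integers(4, 25, 2)
            pos = rng.integers(0, 10, n1).astype(float)
            neg = rng.integers(0, 10, n2).astype(float)
            scores = np.r_[pos, neg]
            labels = np.r_[np.ones(n1, bool), np.zeros(n2, bool)]
            cutoff, sens, spec = youden_cutoff(scores, labels, "higher")
            j = sens / 100 + spec / 100 - 1
            best = max(
                np.mean(pos >= t) + np.mean(neg < t) - 1
                for t in np.r_[np.unique(scores) - 1e-9, scores.max() + 1]
            )
            assert j == pytest.approx(best, abs=1e-9)
            # the reported cutoff reproduces the reported operating point
            assert np.mean(pos >= cutoff) == pytest.approx(sens / 100)
            assert np.mean(neg < cutoff) == pytest.approx(spec / 100)

    def test_binormal_cutoff_between_group_means(self):
        rng = np.random.default_rng(1)
        neg = rng.normal(1.65, 0.42, 670)
        pos = rng.normal(1.13, 0.31, 340)
        scores = np.r_[pos, neg]
        labels = np.r_[np.ones(340, bool), np.zeros(670, bool)]
        cutoff, _, _ = youden_cutoff(scores, labels, "lower")
        assert 1.13 < cutoff < 1.65


class TestDeLong:
    def _dataset(self, rng, n_pos=40, n_neg=60, rho=0.0):
        z = rng.normal(size=n_pos + n_neg)
        labels = np.r_[np.ones(n_pos, bool), np.zeros(n_neg, bool)]
        shift = labels.astype(float)
        a = shift * 0.8 + rho * z + math.sqrt(1 - rho**2) * rng.normal(size=labels.size)
        b = shift * 0.5 + rho * z + math.sqrt(1 - rho**2) * rng.normal(size=labels.size)
        return a, b, labels

    def test_marker_vs_itself_is_null(self, rng):
        a, _, labels = self._dataset(rng)
        assert delong_compare(a, a, labels) == 1.0

    def test_monotone_transform_is_null(self, rng):
        a, _, labels = self._dataset(rng)
        assert delong_compare(a, np.exp(a), labels) == 1.0

    def test_agrees_with_paired_bootstrap(self, rng):
        """DeLong p within 0.05 of a 2000-replicate paired-bootstrap p."""
        a, b, labels = self._dataset(rng, rho=0.3)
        p_delong = delong_compare(a, b, labels, "higher", "higher")

        def auc_of(scores, lab):
            return _u_statistic(scores[lab], scores[~lab]) / (lab.sum() * (~lab).sum())

        obs = auc_of(a, labels) - auc_of(b, labels)
        boot = np.empty(2000)
        idx_all = np.arange(labels.size)
        rng2 = np.random.default_rng(7)
        for i in range(2000):
            idx = rng2.choice(idx_all, labels.size, replace=True)
            lab = labels[idx]
            if lab.all() or not lab.any():
                boot[i] = np.nan
                continue
            boot[i] = auc_of(a[idx], lab) - auc_of(b[idx], lab)
        se = np.nanstd(boot, ddof=1)
        p_boot = 2 * sps.norm.sf(abs(obs) / se)
        assert abs(p_delong - p_boot) < 0.05

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            delong_compare([1, 2, 3], [1, 2], [True, False, True])

    def test_ci_coverage_near_nominal(self):
        """DeLong 95% CI covers the true binormal AUC in >=93% of 500
        simulated 67/34 cohorts."""
        true_auc = binormal_auc(1.13, 0.31, 1.65, 0.42)
        rng = np.random.default_rng(2023)
        labels = np.r_[np.ones(34, bool), np.zeros(67, bool)]
        covered = 0
        for _ in range(500):
            scores = np.r_[rng.normal(1.13, 0.31, 34), rng.normal(1.65, 0.42, 67)]
            res = roc_auc(scores, labels, direction="lower")
            covered += res.ci95[0] <= true_auc <= res.ci95[1]
        assert covered / 500 >= 0.93


class TestICC:
    def test_identical_readers(self):
        res = icc_agreement(np.c_[[4, 1, 3, 5, 2], [4, 1, 3, 5, 2]])
        assert res.icc == pytest.approx(1.0)
        assert res.band == "excellent"

    def test_constant_offset_penalized(self):
        base = np.array([4.0, 1.0, 3.0, 5.0, 2.0])
        res = icc_agreement(np.c_[base, base + 3.0])
        assert res.icc < 1.0

    def test_matches_pingouin_two_way_random_single(self, rng):
        """Independent oracle: pingouin's ICC2 on random 6-subject ratings."""
        pingouin = pytest.importorskip("pingouin")
        ratings = rng.integers(1, 6, size=(6, 2)).astype(float)
        ratings[:, 1] += rng.normal(0, 0.3, 6)
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(6), 2),
            "rater": np.tile([0, 1], 6),
            "score": ratings.flatten(),
        })
        ref = pingouin.intraclass_corr(long, targets="subject", raters="rater",
                                       ratings="score")
        ref_icc = float(ref.loc[ref.Type == "ICC(A,1)", "ICC"].iloc[0])
        assert icc_agreement(ratings).icc == pytest.approx(ref_icc, abs=1e-9)

    def test_invariant_to_subject_relabeling(self, rng):
        ratings = rng.integers(1, 6, size=(10, 2)).astype(float)
        perm = rng.permutation(10)
        assert icc_agreement(ratings).icc == pytest.approx(
            icc_agreement(ratings[perm]).icc, abs=1e-12)

    def test_constant_ratings_undefined(self):
        res = icc_agreement(np.full((5, 2), 3.0))
        assert math.isnan(res.icc)
        assert res.band == "undefined"

    @pytest.mark.parametrize("icc,band", [
        (0.95, "excellent"), (0.80, "good"), (0.61, "good"),
        (0.50, "moderate"), (0.30, "general"), (0.10, "poor"), (-0.2, "poor"),
    ])
    def test_band_thresholds(self, icc, band):
        assert icc_band(icc) == band


class TestCombination:
    def _cohort_scores(self, seed):
        cohort = sample_cohort(STAGE_MIBC, STAGE_NMIBC, seed=seed,
                               endpoint="stage", latent_rho=0.6)
        labels = (cohort.stage == "MIBC").to_numpy()
        X = cohort[["truth_md_p75", "truth_md_p90", "truth_mk_p90"]]
        return X, labels

    def test_single_feature_combination_preserves_auc(self, rng):
        X, labels = self._cohort_scores(0)
        single = X[["truth_md_p75"]]
        model = fit_combination(single, labels)
        auc_combo = roc_auc(model.scores, labels).auc
        auc_raw = roc_auc(single.to_numpy().ravel(), labels).auc
        assert auc_combo == pytest.approx(auc_raw, abs=1e-12)

    def test_duplicated_feature_changes_nothing(self):
        X, labels = self._cohort_scores(1)
        one = X[["truth_md_p90"]]
        two = pd.DataFrame({"a": X.truth_md_p90, "b": X.truth_md_p90})
        auc1 = roc_auc(fit_combination(one, labels).scores, labels).auc
        auc2 = roc_auc(fit_combination(two, labels).scores, labels).auc
        assert auc2 == pytest.approx(auc1, abs=1e-6)

    def test_combination_not_worse_than_members(self):
        """In-sample logistic combination AUC >= best member AUC - 0.01,
        across 20 seeded cohorts with correlated markers."""
        for seed in range(20):
            X, labels = self._cohort_scores(seed)
            model = fit_combination(X, labels)
            combo_auc = roc_auc(model.scores, labels, "higher").auc
            member_auc = max(roc_auc(X[c].to_numpy(), labels).auc for c in X)
            assert combo_auc >= member_auc - 0.01

    def test_perfect_separation_flagged_and_usable(self):
        X = pd.DataFrame({"x": np.r_[np.zeros(10), np.ones(10)]})
        labels = np.r_[np.zeros(10, bool), np.ones(10, bool)]
        model = fit_combination(X, labels)
        assert model.separated
        assert np.isfinite(model.scores).all()
        assert roc_auc(model.scores, labels, "higher").auc == 1.0


class TestVirads:
    def test_degenerate_scores_classify_perfectly(self):
        labels = np.r_[np.ones(30, bool), np.zeros(70, bool)]
        scores = np.where(labels, 5, 1)
        res = virads_classifier(scores, labels, threshold=3)
        assert res.sensitivity == 100.0 and res.specificity == 100.0
        assert res.auc == 1.0

    def test_threshold_one_has_full_sensitivity(self, rng):
        labels = rng.random(60) < 0.4
        scores = rng.integers(1, 6, 60)
        res = virads_classifier(scores, labels, threshold=1)
        assert res.sensitivity == 100.0

    def test_out_of_range_scores_rejected(self):
        with pytest.raises(ValueError):
            virads_classifier([0, 3, 4], [True, False, True])


class TestBinormalAUC:
    def test_equal_means_is_chance(self):
        assert binormal_auc(1.0, 0.2, 1.0, 0.5) == 0.5

    @pytest.mark.parametrize("args,expected", [
        ((1.65, 0.42, 1.13, 0.31), 0.8403),
        ((0.78, 0.17, 0.61, 0.15), 0.7734),
    ])
    def test_closed_form_values(self, args, expected):
        assert binormal_auc(*args) == pytest.approx(expected, abs=2e-4)

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError):
            binormal_auc(1.0, 0.0, 0.5, 0.2)
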