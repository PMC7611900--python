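"""Design tests and permutation inference against closed-form oracles."""

import numpy as np
import pytest
from math import comb

from rsadapt.inference import (
    design_test,
    interaction_glm_test,
    overall_arm_test,
    permutation_pvalue,
    subgroup_fisher_test,
    tuned_permutation_pvalue,
)
from rsadapt.synthetic_trials import TrialDataset


def _trial_from_counts(n_t, resp_t, n_c, resp_c):
    t = np.concatenate([np.ones(n_t), np.zeros(n_c)]).astype(np.int8)
    y = np.concatenate(
        [np.ones(resp_t), np.zeros(n_t - resp_t), np.ones(resp_c), np.zeros(n_c - resp_c)]
    ).astype(np.int8)
    return TrialDataset(treatment=t, response=y, covariates=np.zeros((n_t + n_c, 1)))


def yates_chi2_pvalue(a, b, c, d):
    """Closed-form continuity-corrected chi-square for a 2x2 table."""
    from scipy.stats import chi2

    n = a + b + c + d
    num = n * (max(abs(a * d - b * c) - n / 2.0, 0.0)) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    return float(chi2.sf(num / den, df=1))


def fisher_two_sided_oracle(a, b, c, d):
    """Hypergeometric enumeration: sum of table probabilities <= observed."""
    n, r1, c1 = a + b + c + d, a + b, a + c

    def prob(x):
        return comb(r1, x) * comb(n - r1, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


class TestOverallArmTest:
    def test_identical_proportions_give_p_one(self):
        assert overall_arm_test(_trial_from_counts(100, 50, 100, 50)) == 1.0

    def test_arm_swap_symmetry(self):
        d1 = _trial_from_counts(100, 30, 100, 45)
        d2 = _trial_from_counts(100, 45, 100, 30)
        assert overall_arm_test(d1) == pytest.approx(overall_arm_test(d2))

    def test_matches_closed_form_yates_chi_square(self):
        p = overall_arm_test(_trial_from_counts(100, 70, 100, 25))
        assert p == pytest.approx(yates_chi2_pvalue(70, 30, 25, 75), abs=1e-6)

    def test_empty_arm_flagged_as_p_one(self):
        t = np.ones(50, dtype=np.int8)
        y = (np.arange(50) % 2).astype(np.int8)
        d = TrialDataset(treatment=t, response=y, covariates=np.zeros((50, 1)))
        assert overall_arm_test(d) == 1.0


class TestSubgroupFisherTest:
    def test_enumerated_example(self):
        # table [[3,1],[1,3]]: two-sided p = 34/70
        d = _trial_from_counts(4, 3, 4, 1)
        flags = np.ones(8, dtype=bool)
        assert subgroup_fisher_test(d, flags) == pytest.approx(34 / 70)

    @pytest.mark.parametrize(
        "table", [(3, 1, 1, 3), (5, 0, 2, 4), (2, 8, 7, 3), (0, 4, 4, 0), (6, 2, 6, 2)]
    )
    def test_matches_hypergeometric_enumeration(self, table):
        a, b, c, d_ = table
        d = _trial_from_counts(a + b, a, c + d_, c)
        flags = np.ones(a + b + c + d_, dtype=bool)
        assert subgroup_fisher_test(d, flags) == pytest.approx(
            min(1.0, fisher_two_sided_oracle(a, b, c, d_)), abs=1e-12
        )

    def test_identical_arms_give_p_one(self):
        d = _trial_from_counts(10, 4, 10, 4)
        assert subgroup_fisher_test(d, np.ones(20, bool)) == 1.0

    def test_empty_subgroup_gives_p_one(self):
        d = _trial_from_counts(10, 4, 10, 2)
        assert subgroup_fisher_test(d, np.zeros(20, bool)) == 1.0


class TestDesignTest:
    @pytest.mark.parametrize(
        "p_overall,p_subgroup,positive",
        [(0.03, 0.5, True), (0.5, 0.005, True), (0.5, 0.5, False), (0.04, 0.01, False)],
    )
    def test_split_alpha_combination(self, p_overall, p_subgroup, positive, monkeypatch):
        import rsadapt.inference as inf

        monkeypatch.setattr(inf, "overall_arm_test", lambda d: p_overall)
        monkeypatch.setattr(inf, "subgroup_fisher_test", lambda d, s: p_subgroup)
        d = _trial_from_counts(10, 4, 10, 2)
        res = inf.design_test(d, np.ones(20, bool))
        assert res.design_positive is positive
        assert res.alpha1 + res.alpha2 == pytest.approx(0.05)


class TestInteractionGlmTest:
    def test_matches_statsmodels_on_nondegenerate_data(self, small_trial):
        import statsmodels.api as sm

        flags = small_trial.covariates[:, 0] > 0
        p = interaction_glm_test(small_trial, flags)
        t = small_trial.treatment.astype(float)
        s = flags.astype(float)
        X = np.column_stack([np.ones_like(t), t, s, t * s])
        ref = sm.GLM(
            small_trial.response.astype(float), X, family=sm.families.Binomial()
        ).fit()
        assert p == pytest.approx(float(ref.pvalues[-1]))

    def test_all_true_flags_degenerate(self, small_trial):
        assert interaction_glm_test(small_trial, np.ones(small_trial.n_patients, bool)) == 1.0

    def test_planted_interaction_detected(self):
        rng = np.random.default_rng(2)
        n = 600
        t = (np.arange(n) % 2).astype(np.int8)
        s = rng.random(n) < 0.5
        p_resp = np.where(t & s, 0.8, 0.3)
        y = (rng.random(n) < p_resp).astype(np.int8)
        d = TrialDataset(treatment=t, response=y, covariates=np.zeros((n, 1)))
        assert interaction_glm_test(d, s) < 1e-3


class TestPermutationPvalue:
    def test_formula_floor_and_ceiling(self, null_trial):
        res_lo = permutation_pvalue(null_trial, lambda d: -1.0 if d is null_trial else 0.0,
                                    n_permutations=19, seed=0)
        # observed strictly smaller than every permuted value
        assert res_lo.pvalue == pytest.approx(1 / 20)
        res_hi = permutation_pvalue(null_trial, lambda d: 1.0, n_permutations=19, seed=0)
        assert res_hi.pvalue == 1.0

    def test_formula_arithmetic(self, null_trial):
        # statistic designed so exactly 4 of 19 permuted values <= observed
        values = iter([0.5] + [0.1] * 4 + [0.9] * 15)

        res = permutation_pvalue(null_trial, lambda d: next(values), n_permutations=19, seed=0)
        assert res.pvalue == pytest.approx(5 / 20)

    def test_bounds_invariant(self, null_trial, rng):
        res = permutation_pvalue(
            null_trial, lambda d: float(rng.random()), n_permutations=37, seed=1
        )
        assert 1 / 38 <= res.pvalue <= 1.0

    def test_invalid_permutation_count(self, null_trial):
        with pytest.raises(ValueError):
            permutation_pvalue(null_trial, lambda d: 0.5, n_permutations=0)

    def test_arm_relabel_invariance(self, null_trial):
        """Globally flipping the arm labels leaves the permutation p unchanged
        for a statistic that is itself arm-symmetric."""
        from rsadapt.inference import interaction_glm_test

        flags = null_trial.covariates[:, 0] > 0

        def stat(d):
            return interaction_glm_test(d, flags)

        p1 = permutation_pvalue(null_trial, stat, n_permutations=50, seed=3).pvalue
        flipped = null_trial.with_treatment(1 - null_trial.treatment)
        p2 = permutation_pvalue(flipped, stat, n_permutations=50, seed=3).pvalue
        assert p1 == pytest.approx(p2, abs=0.1)


class TestTunedPermutation:
    def test_single_threshold_reduces_to_plain_permutation(self, small_trial):
        from rsadapt.cvrs import threshold_scan

        res = tuned_permutation_pvalue(
            small_trial, grid=[1.0], n_permutations=9, seed=5, scan_seed=11
        )
        scan = threshold_scan(small_trial, grid=[1.0], seed=11)
        assert res.observed == pytest.approx(scan.best_pvalue)
        assert 1 / 10 <= res.pvalue <= 1.0

    def test_zero_permutations_disallowed(self, small_trial):
        with pytest.raises(ValueError):
            tuned_permutation_pvalue(small_trial, grid=[1.0], n_permutations=0)
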