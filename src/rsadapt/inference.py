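"""Hypothesis-testing layer for the adaptive subgroup designs.

The design splits the overall two-sided significance level alpha between an
all-patients arm comparison (level alpha1, normal-approximation test for
the difference of two proportions with continuity correction) and a
selected-subgroup comparison (level alpha2, two-sided Fisher exact test);
the design is positive if either test rejects.  The recommended split is
alpha1 = 0.8*alpha, alpha2 = 0.2*alpha.

Because the sensitive group is data-derived, valid p-values for the
treatment-by-sensitivity interaction are obtained by permuting treatment
labels and re-running the whole classification pipeline.  The "tuned"
variant repeats the covariate-prefiltering threshold scan inside every
permutation so the selection of the threshold is accounted for.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import statsmodels.api as sm
from scipy.stats import chi2_contingency, fisher_exact

from .synthetic_trials import TrialDataset

__all__ = [
    "DesignTestResult",
    "PermutationResult",
    "overall_arm_test",
    "subgroup_fisher_test",
    "design_test",
    "interaction_glm_test",
    "permutation_pvalue",
    "tuned_permutation_pvalue",
    "cvrs_interaction_statistic",
]


@dataclass(frozen=True)
class DesignTestResult:
    """Outcome of the split-alpha design test."""

    overall_pvalue: float
    subgroup_pvalue: float
    alpha1: float
    alpha2: float
    overall_flag: bool = False
    subgroup_flag: bool = False

    @property
    def overall_significant(self) -> bool:
        return self.overall_pvalue < self.alpha1

    @property
    def subgroup_significant(self) -> bool:
        return self.subgroup_pvalue < self.alpha2

    @property
    def design_positive(self) -> bool:
        return self.overall_significant or self.subgroup_significant

    def to_record(self) -> dict:
        return {
            "overall_pvalue": self.overall_pvalue,
            "subgroup_pvalue": self.subgroup_pvalue,
            "alpha1": self.alpha1,
            "alpha2": self.alpha2,
            "overall_significant": self.overall_significant,
            "subgroup_significant": self.subgroup_significant,
            "design_positive": self.design_positive,
        }


def _arm_table(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.array(
        [
            [((t == 1) & (y == 1)).sum(), ((t == 1) & (y == 0)).sum()],
            [((t == 0) & (y == 1)).sum(), ((t == 0) & (y == 0)).sum()],
        ],
        dtype=np.int64,
    )


def overall_arm_test(data: TrialDataset, continuity: bool = True) -> float:
    """Two-sided test of equal response proportions between the two arms.

    Chi-square test on the 2x2 arm-by-response table with Yates continuity
    correction by default (equivalent to the classical normal-approximation
    two-proportion test with correction).  Degenerate tables (an empty arm
    or a zero response margin) return p = 1.
    """
    table = _arm_table(data.treatment, data.response)
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        return 1.0
    if table[0, 0] * table[1, 1] == table[0, 1] * table[1, 0]:
        return 1.0  # identical proportions; chi-square statistic is zero
    return float(chi2_contingency(table, correction=continuity)[1])


def subgroup_fisher_test(data: TrialDataset, sensitive: np.ndarray) -> float:
    """Two-sided Fisher exact test of the arm difference among sensitive patients.

    Two-sidedness follows the hypergeometric-summation convention (all
    tables with probability at most the observed one).  An empty or
    single-arm subgroup returns p = 1.
    """
    sensitive = np.asarray(sensitive, dtype=bool)
    if sensitive.shape[0] != data.n_patients:
        raise ValueError("sensitivity flags must cover every patient")
    sel = np.flatnonzero(sensitive)
    if sel.size == 0:
        return 1.0
    t = data.treatment[sel]
    y = data.response[sel]
    if np.unique(t).size < 2:
        return 1.0
    return float(fisher_exact(_arm_table(t, y), alternative="two-sided")[1])


def design_test(
    data: TrialDataset,
    sensitive: np.ndarray,
    alpha1: float = 0.04,
    alpha2: float = 0.01,
) -> DesignTestResult:
    """Combine the overall and subgroup tests under the split-alpha rule."""
    return DesignTestResult(
        overall_pvalue=overall_arm_test(data),
        subgroup_pvalue=subgroup_fisher_test(data, sensitive),
        alpha1=alpha1,
        alpha2=alpha2,
    )


def interaction_glm_test(data: TrialDataset, sensitive: np.ndarray) -> float:
    """Wald p-value of the treatment-by-sensitivity interaction.

    Binomial-logit GLM: response ~ treatment + sensitivity +
    treatment:sensitivity.  A degenerate design (single arm, or all
    patients on one side of the sensitivity flag) returns p = 1.
    """
    sensitive = np.asarray(sensitive, dtype=bool)
    t = data.treatment.astype(float)
    s = sensitive.astype(float)
    if np.unique(t).size < 2 or np.unique(s).size < 2:
        return 1.0
    X = np.column_stack([np.ones_like(t), t, s, t * s])
    try:
        fit = sm.GLM(data.response.astype(float), X, family=sm.families.Binomial()).fit()
        p = float(fit.pvalues[-1])
    except Exception:
        return 1.0
    return p if np.isfinite(p) else 1.0


@dataclass
class PermutationResult:
    """Permutation p-value together with the permutation null distribution."""

    pvalue: float
    observed: float
    null_values: np.ndarray

    def __float__(self) -> float:
        return self.pvalue


def _permutation_formula(observed: float, null_values: np.ndarray) -> float:
    b = null_values.size
    return float((1 + int((null_values <= observed).sum())) / (1 + b))


def permutation_pvalue(
    data: TrialDataset,
    statistic: Callable[[TrialDataset], float],
    n_permutations: int = 2000,
    seed: int | None = None,
) -> PermutationResult:
    """Permutation p-value for a pipeline statistic returning a p-value.

    ``statistic`` must run the *entire* classification-plus-test pipeline
    on the dataset it receives.  Each permutation shuffles the treatment
    labels only (responses and covariates fixed); the returned p-value is
    (1 + #{permuted values <= observed}) / (1 + n_permutations), so it is
    bounded below by 1/(n_permutations + 1).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be at least 1")
    observed = float(statistic(data))
    rng = np.random.default_rng(seed)
    null_values = np.empty(n_permutations)
    for b in range(n_permutations):
        permuted = data.with_treatment(rng.permutation(data.treatment))
        null_values[b] = float(statistic(permuted))
    return PermutationResult(
        pvalue=_permutation_formula(observed, null_values),
        observed=observed,
        null_values=null_values,
    )


def cvrs_interaction_statistic(
    r: int = 10,
    seed: int | None = None,
    variant: str = "interaction_only",
    prefilter_threshold: float | None = None,
) -> Callable[[TrialDataset], float]:
    """Build the CVRS classify-then-interaction-test pipeline statistic."""
    from .cvrs import cvrs_classify

    def stat(data: TrialDataset) -> float:
        res = cvrs_classify(
            data, r=r, seed=seed, variant=variant, prefilter_threshold=prefilter_threshold
        )
        return interaction_glm_test(data, res.sensitive)

    return stat


def tuned_permutation_pvalue(
    data: TrialDataset,
    grid: Sequence[float] | None = None,
    n_permutations: int = 2000,
    seed: int | None = None,
    r: int = 10,
    variant: str = "interaction_only",
    scan_seed: int | None = None,
) -> PermutationResult:
    """Permutation p-value accounting for prefiltering-threshold tuning.

    The full threshold scan is re-run on every permuted dataset; the
    permutation distribution collects each permutation's *minimised*
    interaction p-value, which is compared with the observed minimised
    value.  This makes the min-p selection part of the null, restoring
    validity that a naive minimum would lose.
    """
    from .cvrs import NoCovariatesSelectedError, threshold_scan

    if n_permutations < 1:
        raise ValueError("n_permutations must be at least 1")

    def stat(d: TrialDataset) -> float:
        try:
            scan = threshold_scan(
                d,
                grid=grid,
                r=r,
                seed=scan_seed,
                variant=variant,
                keep_best_classification=False,
            )
        except NoCovariatesSelectedError:
            return 1.0
        return scan.best_pvalue

    return permutation_pvalue(data, stat, n_permutations=n_permutations, seed=seed)
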