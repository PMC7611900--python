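"""Cross-validated risk scores (CVRS) for sensitive-subgroup identification.

The method classifies each trial patient as *sensitive* (high predicted
benefit from the experimental arm) or not, in three cross-validated steps:

1. Within each training fold, fit one small logistic model per covariate
   and keep the treatment-covariate interaction estimate ``beta_j``.
2. Score each held-out patient with the risk score
   ``RS_i = sum_j beta_j * x_ij`` (a compound-covariate / polygenic-score
   construction).
3. Partition the held-out scores into two clusters by 2-means in one
   dimension; the cluster with the larger centre is the sensitive group.

Labels are pooled across the folds, so every patient is classified exactly
once.  Variants implemented here: nested estimation of the cluster centres
in an inner cross-validation layer, and interaction-p-value prefiltering of
covariates with a threshold scan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from ._logistic import BETA_CAP, batched_newton_logistic, firth_logistic
from .synthetic_trials import TrialDataset

__all__ = [
    "FoldPlan",
    "InteractionFit",
    "RiskScores",
    "ClassificationResult",
    "ThresholdScanResult",
    "DegenerateDataError",
    "NoCovariatesSelectedError",
    "make_fold_plan",
    "fit_interaction_models",
    "compute_risk_scores",
    "cluster_scores",
    "cvrs_classify",
    "nested_cvrs_classify",
    "threshold_scan",
]

VARIANTS = (
    "interaction_only",
    "with_main_covariate",
    "with_main_treatment_and_covariate",
)


class DegenerateDataError(ValueError):
    """Training data cannot support the fit (single arm or constant response)."""


class NoCovariatesSelectedError(ValueError):
    """A prefiltering threshold left no covariates in a training fold."""


@dataclass(frozen=True)
class FoldPlan:
    """Partition of patients into r nonoverlapping folds of near-equal size."""

    r: int
    assignment: np.ndarray  # per-patient fold index in {0, ..., r-1}
    seed: int | None = None

    @property
    def n_patients(self) -> int:
        return int(self.assignment.shape[0])


def make_fold_plan(
    n_patients: int,
    r: int = 10,
    seed: int | None = None,
    stratify: np.ndarray | None = None,
) -> FoldPlan:
    """Randomly assign patients to r folds with sizes differing by at most 1.

    When ``stratify`` (typically the treatment arm) is given, each stratum
    is spread across folds as evenly as possible while keeping the overall
    fold sizes balanced; this prevents single-arm training folds at small n.
    """
    if n_patients < r:
        raise ValueError("need at least one patient per fold")
    rng = np.random.default_rng(seed)
    assignment = np.empty(n_patients, dtype=np.int64)
    if stratify is None:
        order = rng.permutation(n_patients)
    else:
        stratify = np.asarray(stratify)
        order_parts = []
        for level in np.unique(stratify):
            idx = np.flatnonzero(stratify == level)
            order_parts.append(rng.permutation(idx))
        order = np.concatenate(order_parts)
    # cyclic deal through the (stratum-grouped) shuffled order keeps overall
    # fold sizes within 1 and strata near-balanced
    fold_seq = np.arange(n_patients) % r
    assignment[order] = fold_seq
    return FoldPlan(r=r, assignment=assignment, seed=seed)


@dataclass
class InteractionFit:
    """Per-covariate treatment-covariate interaction estimates."""

    beta: np.ndarray
    pvalue: np.ndarray
    variant: str
    converged: np.ndarray
    firth_used: np.ndarray
    capped: np.ndarray
    extra_coef: dict = field(default_factory=dict)  # e.g. per-covariate lambda


@dataclass
class RiskScores:
    """Per-patient risk scores with the fold each was scored in."""

    scores: np.ndarray
    fold: np.ndarray


@dataclass
class ClassificationResult:
    """Pooled sensitive/nonsensitive labels with per-fold diagnostics."""

    sensitive: np.ndarray
    fold: np.ndarray
    method: str
    fold_centers: list
    fold_n_covariates: list
    degenerate_folds: list = field(default_factory=list)
    fallback_folds: list = field(default_factory=list)
    scores: np.ndarray | None = None
    extra: dict = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "patient_id": np.arange(1, len(self.sensitive) + 1),
                "sensitive": self.sensitive.astype(int),
                "fold": self.fold,
                "method": self.method,
            }
        )


def _check_trainable(data: TrialDataset) -> None:
    if np.unique(data.treatment).size < 2:
        raise DegenerateDataError("training data contain a single arm")
    if np.unique(data.response).size < 2:
        raise DegenerateDataError("training response is constant")


def _stack_designs(t: np.ndarray, x: np.ndarray, variant: str) -> tuple[np.ndarray, int]:
    """Build the (J, N, P) per-covariate design stack for a model variant.

    Returns the stack and the column index of the interaction term.
    """
    n, j = x.shape
    tx = t[:, None] * x
    ones = np.ones(n)
    if variant == "interaction_only":
        cols = [np.broadcast_to(ones[None, :], (j, n)), tx.T]
    elif variant == "with_main_covariate":
        cols = [np.broadcast_to(ones[None, :], (j, n)), x.T, tx.T]
    elif variant == "with_main_treatment_and_covariate":
        tt = np.broadcast_to(t[None, :], (j, n))
        cols = [np.broadcast_to(ones[None, :], (j, n)), tt, x.T, tx.T]
    elif variant == "signature":  # intercept + treatment + interaction
        tt = np.broadcast_to(t[None, :], (j, n))
        cols = [np.broadcast_to(ones[None, :], (j, n)), tt, tx.T]
    else:
        raise ValueError(f"unknown model variant {variant!r}")
    X = np.stack(cols, axis=2)
    return np.ascontiguousarray(X), X.shape[2] - 1


def _fit_covariate_stack(
    data: TrialDataset, variant: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fit all per-covariate models; Firth fallback where Newton fails.

    Returns (coef, se, pvalue, converged, firth_used, capped), with coef of
    shape (J, P) and the Wald p-value referring to the interaction column.
    """
    _check_trainable(data)
    t = data.treatment.astype(float)
    y = data.response.astype(float)
    X, b_idx = _stack_designs(t, data.covariates, variant)
    coef, cov, ok = batched_newton_logistic(X, y)
    j = X.shape[0]
    firth_used = np.zeros(j, dtype=bool)
    capped = np.zeros(j, dtype=bool)
    for idx in np.flatnonzero(~ok):
        th, cv, fok = firth_logistic(X[idx], y)
        coef[idx] = th
        cov[idx] = cv
        firth_used[idx] = True
        ok[idx] = fok
    big = np.abs(coef).max(axis=1) > BETA_CAP
    if big.any():
        coef[big] = np.clip(coef[big], -BETA_CAP, BETA_CAP)
        capped |= big
    var = cov[:, b_idx, b_idx]
    with np.errstate(invalid="ignore"):
        se = np.sqrt(var)
    z = np.where(se > 0, coef[:, b_idx] / se, 0.0)
    pvalue = 2.0 * norm.sf(np.abs(z))
    pvalue = np.where(np.isfinite(pvalue), pvalue, 1.0)
    return coef, se, pvalue, ok, firth_used, capped


def fit_interaction_models(
    train: TrialDataset, variant: str = "interaction_only"
) -> InteractionFit:
    """Fit one logistic model per covariate and return interaction estimates.

    ``variant`` selects which nuisance terms accompany the interaction:
    ``interaction_only`` (intercept + t*x), ``with_main_covariate``
    (+ x), or ``with_main_treatment_and_covariate`` (+ t + x).
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    coef, se, pvalue, ok, firth_used, capped = _fit_covariate_stack(train, variant)
    return InteractionFit(
        beta=coef[:, -1],
        pvalue=pvalue,
        variant=variant,
        converged=ok,
        firth_used=firth_used,
        capped=capped,
    )


def compute_risk_scores(
    test: TrialDataset,
    fit: InteractionFit,
    selected: np.ndarray | None = None,
) -> np.ndarray:
    """Risk score = inner product of the covariate row with the beta vector.

    ``selected`` optionally restricts the sum to a boolean covariate mask
    (the prefiltering path).
    """
    if fit.beta.shape[0] != test.n_covariates:
        raise ValueError("fit does not cover the covariates of the test data")
    beta = fit.beta
    if selected is not None:
        selected = np.asarray(selected, dtype=bool)
        if selected.shape[0] != beta.shape[0]:
            raise ValueError("selected mask length mismatch")
        beta = np.where(selected, beta, 0.0)
    return test.covariates @ beta


def cluster_scores(scores: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    """Optimal 2-means partition of one-dimensional scores.

    In one dimension the k=2 within-cluster-sum-of-squares optimum is a
    contiguous split of the sorted values, so the partition is found
    exactly by scanning the n-1 sorted cut points (ties broken at the
    first minimising cut).  The cluster with the larger centre is labelled
    sensitive.  If all scores coincide the split is degenerate: everyone is
    labelled nonsensitive and the degenerate flag is set.

    Returns (sensitive labels, centers ascending, degenerate flag).
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.shape[0]
    if n == 0:
        return np.zeros(0, dtype=bool), np.array([np.nan, np.nan]), True
    if np.ptp(scores) == 0.0:
        return np.zeros(n, dtype=bool), np.array([scores[0], scores[0]]), True
    shift = scores.mean()
    order = np.argsort(scores, kind="stable")
    s = scores[order] - shift
    csum = np.cumsum(s)
    csq = np.cumsum(s * s)
    k = np.arange(1, n)  # size of the lower cluster
    left_ss = csq[k - 1] - csum[k - 1] ** 2 / k
    right_sum = csum[-1] - csum[k - 1]
    right_ss = (csq[-1] - csq[k - 1]) - right_sum**2 / (n - k)
    wcss = left_ss + right_ss
    cut = int(np.argmin(wcss)) + 1
    sensitive = np.zeros(n, dtype=bool)
    sensitive[order[cut:]] = True
    centers = np.array(
        [s[:cut].mean() + shift, s[cut:].mean() + shift]
    )
    return sensitive, centers, False


def _resolve_plan(
    data: TrialDataset, plan: FoldPlan | None, r: int, seed: int | None, stratify: bool
) -> FoldPlan:
    if plan is not None:
        return plan
    return make_fold_plan(
        data.n_patients, r=r, seed=seed, stratify=data.treatment if stratify else None
    )


def cvrs_classify(
    data: TrialDataset,
    plan: FoldPlan | None = None,
    variant: str = "interaction_only",
    prefilter_threshold: float | None = None,
    r: int = 10,
    seed: int | None = None,
    stratify: bool = True,
) -> ClassificationResult:
    """Classify every patient as sensitive/nonsensitive by cross-validation.

    For each fold, per-covariate interaction models are fit on the training
    part (optionally prefiltered by interaction p-value strictly below
    ``prefilter_threshold``, computed on the training part alone), held-out
    patients are scored, and the scores are split by exact 2-means.  A
    degenerate training fold yields all-nonsensitive labels for that fold
    and a warning.
    """
    if data.n_patients < 2 * r:
        raise ValueError("need at least two patients per fold")
    if not np.isfinite(data.covariates).all():
        raise ValueError("covariates contain missing values; preprocess first")
    plan = _resolve_plan(data, plan, r, seed, stratify)
    n = data.n_patients
    sensitive = np.zeros(n, dtype=bool)
    scores = np.full(n, np.nan)
    fold_centers: list = []
    fold_ncov: list = []
    degenerate_folds: list = []
    for fold in range(plan.r):
        test_idx = np.flatnonzero(plan.assignment == fold)
        train_idx = np.flatnonzero(plan.assignment != fold)
        if test_idx.size == 0:
            fold_centers.append(None)
            fold_ncov.append(0)
            continue
        try:
            fit = fit_interaction_models(data.subset(train_idx), variant)
        except DegenerateDataError as err:
            warnings.warn(f"fold {fold}: {err}; labelling fold nonsensitive")
            degenerate_folds.append(fold)
            fold_centers.append(None)
            fold_ncov.append(0)
            continue
        selected = None
        if prefilter_threshold is not None:
            selected = fit.pvalue < prefilter_threshold
            if not selected.any():
                raise NoCovariatesSelectedError(
                    f"threshold {prefilter_threshold} left no covariates in fold {fold}"
                )
        rs = compute_risk_scores(data.subset(test_idx), fit, selected)
        labels, centers, degen = cluster_scores(rs)
        if degen:
            degenerate_folds.append(fold)
        sensitive[test_idx] = labels
        scores[test_idx] = rs
        fold_centers.append(centers)
        fold_ncov.append(int(selected.sum()) if selected is not None else data.n_covariates)
    return ClassificationResult(
        sensitive=sensitive,
        fold=plan.assignment.copy(),
        method="cvrs",
        fold_centers=fold_centers,
        fold_n_covariates=fold_ncov,
        degenerate_folds=degenerate_folds,
        scores=scores,
    )


def nested_cvrs_classify(
    data: TrialDataset,
    plan: FoldPlan | None = None,
    inner_r: int | None = None,
    variant: str = "interaction_only",
    r: int = 10,
    seed: int | None = None,
    stratify: bool = True,
) -> ClassificationResult:
    """CVRS with cluster centres estimated in an inner cross-validation layer.

    For each outer fold, an inner r-fold CV on the training part produces
    one pair of (sorted) 2-means centres per inner fold; outer held-out
    scores are then assigned to the nearer of the averaged centres.  If
    that assignment would leave one cluster empty, the fold falls back to
    plain 2-means on the held-out scores and is recorded in
    ``fallback_folds``.
    """
    if data.n_patients < 2 * r:
        raise ValueError("need at least two patients per fold")
    plan = _resolve_plan(data, plan, r, seed, stratify)
    inner_r = inner_r or plan.r
    rng = np.random.default_rng(seed)
    n = data.n_patients
    sensitive = np.zeros(n, dtype=bool)
    scores = np.full(n, np.nan)
    fold_centers: list = []
    fold_ncov: list = []
    degenerate_folds: list = []
    fallback_folds: list = []
    for fold in range(plan.r):
        test_idx = np.flatnonzero(plan.assignment == fold)
        train_idx = np.flatnonzero(plan.assignment != fold)
        train = data.subset(train_idx)
        inner_seed = int(rng.integers(2**31 - 1))
        inner_plan = make_fold_plan(
            train.n_patients,
            r=inner_r,
            seed=inner_seed,
            stratify=train.treatment if stratify else None,
        )
        centers_acc = []
        for ifold in range(inner_r):
            i_test = np.flatnonzero(inner_plan.assignment == ifold)
            i_train = np.flatnonzero(inner_plan.assignment != ifold)
            try:
                ifit = fit_interaction_models(train.subset(i_train), variant)
            except DegenerateDataError:
                continue
            irs = compute_risk_scores(train.subset(i_test), ifit)
            _, c, degen = cluster_scores(irs)
            if not degen:
                centers_acc.append(np.sort(c))
        try:
            fit = fit_interaction_models(train, variant)
        except DegenerateDataError as err:
            warnings.warn(f"fold {fold}: {err}; labelling fold nonsensitive")
            degenerate_folds.append(fold)
            fold_centers.append(None)
            fold_ncov.append(0)
            continue
        rs = compute_risk_scores(data.subset(test_idx), fit)
        scores[test_idx] = rs
        fold_ncov.append(data.n_covariates)
        if centers_acc:
            m = np.mean(np.vstack(centers_acc), axis=0)  # (low, high)
        else:
            m = None
        if m is None or m[0] == m[1]:
            labels, centers, degen = cluster_scores(rs)
            fallback_folds.append(fold)
            if degen:
                degenerate_folds.append(fold)
            sensitive[test_idx] = labels
            fold_centers.append(centers)
            continue
        labels = np.abs(rs - m[1]) < np.abs(rs - m[0])
        if labels.all() or (~labels).all():
            # all held-out scores nearer one centre: empty-cluster fallback
            labels, centers, degen = cluster_scores(rs)
            fallback_folds.append(fold)
            if degen:
                degenerate_folds.append(fold)
            sensitive[test_idx] = labels
            fold_centers.append(centers)
            continue
        sensitive[test_idx] = labels
        fold_centers.append(m)
    return ClassificationResult(
        sensitive=sensitive,
        fold=plan.assignment.copy(),
        method="nested_cvrs",
        fold_centers=fold_centers,
        fold_n_covariates=fold_ncov,
        degenerate_folds=degenerate_folds,
        fallback_folds=fallback_folds,
        scores=scores,
    )


@dataclass
class ThresholdScanResult:
    """Profile of the interaction p-value over prefiltering thresholds."""

    thresholds: np.ndarray
    interaction_pvalues: np.ndarray  # NaN where a threshold was not evaluable
    best_threshold: float
    best_pvalue: float
    best_classification: ClassificationResult | None = None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "interaction_pvalue": self.interaction_pvalues,
            }
        )


def threshold_scan(
    data: TrialDataset,
    grid: np.ndarray | None = None,
    plan: FoldPlan | None = None,
    variant: str = "interaction_only",
    r: int = 10,
    seed: int | None = None,
    stratify: bool = True,
    keep_best_classification: bool = True,
) -> ThresholdScanResult:
    """Scan prefiltering p-value thresholds; pick the one minimising the
    treatment-by-sensitivity interaction p-value.

    The default grid is {0.01, 0.02, ..., 1.00}.  The same fold plan is
    used for every threshold so the profile reflects the filtering alone.
    Thresholds that leave no covariates in some training fold are recorded
    as not evaluable (NaN) and excluded from the argmin.
    """
    from .inference import interaction_glm_test

    if grid is None:
        grid = np.arange(1, 101) / 100.0
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("threshold grid must be nonempty")
    if np.any((grid <= 0) | (grid > 1)):
        raise ValueError("thresholds must lie in (0, 1]")
    plan = _resolve_plan(data, plan, r, seed, stratify)
    pvals = np.full(grid.size, np.nan)
    classifications: dict[int, ClassificationResult] = {}
    for i, thr in enumerate(grid):
        try:
            res = cvrs_classify(
                data, plan=plan, variant=variant, prefilter_threshold=float(thr)
            )
        except NoCovariatesSelectedError:
            continue
        pvals[i] = interaction_glm_test(data, res.sensitive)
        classifications[i] = res
    if np.isnan(pvals).all():
        raise NoCovariatesSelectedError("no threshold in the grid was evaluable")
    best = int(np.nanargmin(pvals))
    return ThresholdScanResult(
        thresholds=grid,
        interaction_pvalues=pvals,
        best_threshold=float(grid[best]),
        best_pvalue=float(pvals[best]),
        best_classification=classifications[best] if keep_best_classification else None,
    )
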