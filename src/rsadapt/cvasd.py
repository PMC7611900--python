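"""Cross-validated adaptive signature design (CVASD).

Reference subgroup-identification method against which the risk-score
approach is compared.  Within each training fold a per-covariate logistic
model with intercept, treatment main effect and treatment-covariate
interaction is fit; covariates whose interaction is significant at level
``eta`` form the signature.  A held-out patient is labelled sensitive when
the predicted treated-vs-control odds ratio ``exp(lambda_j + beta_j x_j)``
exceeds a threshold ``R`` for at least ``G`` signature covariates.  The
tuning triple (eta, R, G) is selected per outer fold from a candidate list
using a single inner training/validation split: the candidate whose
inner-validation sensitive group shows the smallest two-sided Fisher
p-value for the arm difference wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import fisher_exact

from .cvrs import (
    ClassificationResult,
    FoldPlan,
    _fit_covariate_stack,
    _resolve_plan,
    make_fold_plan,
)
from .synthetic_trials import TrialDataset

__all__ = [
    "TuningSet",
    "SignatureModel",
    "DEFAULT_TUNING_SETS",
    "fit_signature",
    "classify_patient",
    "classify_patients",
    "select_tuning_set",
    "cvasd_classify",
    "read_tuning_sets",
]


@dataclass(frozen=True)
class TuningSet:
    """Signature tuning triple: significance level, OR threshold, covariate count."""

    eta: float
    R: float
    G: int

    def __post_init__(self) -> None:
        if not 0.0 < self.eta <= 1.0:
            raise ValueError("eta must lie in (0, 1]")
        if self.R < 0.0:
            raise ValueError("R must be nonnegative")
        if self.G < 1:
            raise ValueError("G must be a positive integer")


#: Wide default candidate grid spanning strict and permissive screening.
DEFAULT_TUNING_SETS = (
    TuningSet(0.01, 2.0, 3),
    TuningSet(0.02, 3.0, 2),
    TuningSet(0.03, 4.0, 1),
    TuningSet(0.5, 1.5, 2),
    TuningSet(0.6, 1.6, 2),
    TuningSet(0.7, 1.7, 1),
)


@dataclass
class SignatureModel:
    """Per-covariate (lambda_j, beta_j, p_j) estimates of the signature model."""

    lam: np.ndarray
    beta: np.ndarray
    pvalue: np.ndarray
    converged: np.ndarray
    firth_used: np.ndarray

    def sensitive_covariates(self, eta: float) -> np.ndarray:
        """Indices of covariates whose interaction p-value is below eta."""
        return np.flatnonzero(self.pvalue < eta)


def fit_signature(train: TrialDataset) -> SignatureModel:
    """Fit the per-covariate model logit p = mu + lambda_j t + beta_j t x_j."""
    coef, se, pvalue, ok, firth_used, capped = _fit_covariate_stack(train, "signature")
    return SignatureModel(
        lam=coef[:, 1],
        beta=coef[:, 2],
        pvalue=pvalue,
        converged=ok,
        firth_used=firth_used,
    )


def classify_patients(
    model: SignatureModel, covariates: np.ndarray, tuning: TuningSet
) -> np.ndarray:
    """Vectorised sensitivity call for a matrix of covariate rows.

    A patient is sensitive when the predicted odds ratio
    exp(lambda_j + beta_j x_j) exceeds R for at least G of the signature
    covariates.  With an empty signature nobody is sensitive.
    """
    sens_cov = model.sensitive_covariates(tuning.eta)
    if sens_cov.size == 0:
        return np.zeros(covariates.shape[0], dtype=bool)
    log_or = model.lam[sens_cov] + covariates[:, sens_cov] * model.beta[sens_cov]
    if tuning.R > 0:
        exceeds = log_or > np.log(tuning.R)
    else:
        exceeds = np.ones_like(log_or, dtype=bool)
    return exceeds.sum(axis=1) >= tuning.G


def classify_patient(model: SignatureModel, x: np.ndarray, tuning: TuningSet) -> bool:
    """Sensitivity call for a single covariate row."""
    return bool(classify_patients(model, np.asarray(x, dtype=float)[None, :], tuning)[0])


def _arm_difference_pvalue(data: TrialDataset, flags: np.ndarray) -> float:
    """Two-sided Fisher p-value for the arm difference in the flagged group."""
    sel = np.flatnonzero(flags)
    if sel.size == 0:
        return 1.0
    t = data.treatment[sel]
    y = data.response[sel]
    if np.unique(t).size < 2:
        return 1.0
    table = [
        [int(((t == 1) & (y == 1)).sum()), int(((t == 1) & (y == 0)).sum())],
        [int(((t == 0) & (y == 1)).sum()), int(((t == 0) & (y == 0)).sum())],
    ]
    return float(fisher_exact(table, alternative="two-sided")[1])


def select_tuning_set(
    train: TrialDataset,
    candidates=DEFAULT_TUNING_SETS,
    seed: int | None = None,
    inner_fraction: float = 0.1,
) -> tuple[TuningSet, dict]:
    """Pick the tuning set with the smallest inner-validation arm-difference p.

    One inner split (validation fraction ``inner_fraction``, stratified by
    arm) stands in for a full inner cross-validation.  Candidates whose
    inner sensitive group is empty or single-arm score p = 1 and can only
    win if every candidate is degenerate, in which case the first candidate
    is returned with a warning flag.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidate list must be nonempty")
    n = train.n_patients
    inner_r = max(2, int(round(1.0 / inner_fraction)))
    inner_plan = make_fold_plan(n, r=inner_r, seed=seed, stratify=train.treatment)
    val_idx = np.flatnonzero(inner_plan.assignment == 0)
    fit_idx = np.flatnonzero(inner_plan.assignment != 0)
    model = fit_signature(train.subset(fit_idx))
    val = train.subset(val_idx)
    pvals = []
    for cand in candidates:
        flags = classify_patients(model, val.covariates, cand)
        pvals.append(_arm_difference_pvalue(val, flags))
    pvals = np.asarray(pvals)
    all_degenerate = bool((pvals >= 1.0).all())
    if all_degenerate:
        warnings.warn("all candidate tuning sets degenerate; returning the first")
        best = 0
    else:
        best = int(np.argmin(pvals))
    info = {"inner_pvalues": pvals, "all_degenerate": all_degenerate}
    return candidates[best], info


def cvasd_classify(
    data: TrialDataset,
    plan: FoldPlan | None = None,
    candidates=DEFAULT_TUNING_SETS,
    r: int = 10,
    seed: int | None = None,
    stratify: bool = True,
) -> ClassificationResult:
    """Classify every patient by the cross-validated adaptive signature design.

    Per outer fold: select a tuning set on the training part, refit the
    signature on the full training part, classify the held-out patients.
    The winning tuning set of each fold is recorded in
    ``extra['winning_tuning_sets']``.
    """
    if data.n_patients < 2 * r:
        raise ValueError("need at least two patients per fold")
    if not np.isfinite(data.covariates).all():
        raise ValueError("covariates contain missing values; preprocess first")
    plan = _resolve_plan(data, plan, r, seed, stratify)
    rng = np.random.default_rng(seed)
    n = data.n_patients
    sensitive = np.zeros(n, dtype=bool)
    winners: list = []
    fold_ncov: list = []
    degenerate_folds: list = []
    for fold in range(plan.r):
        test_idx = np.flatnonzero(plan.assignment == fold)
        train_idx = np.flatnonzero(plan.assignment != fold)
        train = data.subset(train_idx)
        inner_seed = int(rng.integers(2**31 - 1))
        try:
            tuning, _ = select_tuning_set(train, candidates, seed=inner_seed)
            model = fit_signature(train)
        except Exception as err:  # degenerate training fold
            warnings.warn(f"fold {fold}: {err}; labelling fold nonsensitive")
            degenerate_folds.append(fold)
            winners.append(None)
            fold_ncov.append(0)
            continue
        flags = classify_patients(model, data.covariates[test_idx], tuning)
        sensitive[test_idx] = flags
        winners.append(tuning)
        fold_ncov.append(int(model.sensitive_covariates(tuning.eta).size))
    return ClassificationResult(
        sensitive=sensitive,
        fold=plan.assignment.copy(),
        method="cvasd",
        fold_centers=[None] * plan.r,
        fold_n_covariates=fold_ncov,
        degenerate_folds=degenerate_folds,
        extra={"winning_tuning_sets": winners},
    )


def read_tuning_sets(path) -> list[TuningSet]:
    """Read candidate tuning sets from a 3-column delimited file (eta, R, G)."""
    import pandas as pd

    df = pd.read_csv(path)
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    return [
        TuningSet(float(row["eta"]), float(row["r"]), int(row["g"]))
        for _, row in df.iterrows()
    ]
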