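"""Reading, preprocessing and writing of patient-level trial tables.

Input dialect: delimited text (CSV, UTF-8) with a header row and columns
``patient_id, treatment, response[, true_sensitive], cov_1 ... cov_J``;
empty cells or ``NA`` denote missing covariate values.  Preprocessing
drops covariates with more than ``cov_missing_threshold`` missing values,
then patients with more than ``patient_missing_threshold`` missing values
among the remaining covariates, then mean-imputes what is left.  Imputation
means are computed on the full filtered table by default; a fold-safe
switch is available for users who prefer imputing inside each
cross-validation training fold instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic_trials import TrialDataset

__all__ = [
    "PreprocessReport",
    "load_trial_table",
    "preprocess_frame",
    "write_trial_table",
    "sign_transform",
    "impute_means",
]

RESERVED_COLUMNS = ("patient_id", "treatment", "response", "true_sensitive")


@dataclass
class PreprocessReport:
    """What preprocessing removed, imputed and (for CVASD) sign-flipped."""

    dropped_covariates: list[str] = field(default_factory=list)
    dropped_patients: list = field(default_factory=list)
    n_imputed: int = 0
    flipped_covariates: list[str] = field(default_factory=list)
    cov_missing_threshold: float = 0.1
    patient_missing_threshold: float = 0.1


def _covariate_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c not in RESERVED_COLUMNS]


def impute_means(x: np.ndarray) -> tuple[np.ndarray, int]:
    """Replace NaN cells by the column mean; returns (matrix, cells imputed)."""
    x = np.array(x, dtype=float)
    mask = np.isnan(x)
    if mask.any():
        means = np.nanmean(x, axis=0)
        x[mask] = np.take(means, np.nonzero(mask)[1])
    return x, int(mask.sum())


def preprocess_frame(
    df: pd.DataFrame,
    cov_missing_threshold: float = 0.1,
    patient_missing_threshold: float = 0.1,
    impute: bool = True,
) -> tuple[TrialDataset, PreprocessReport]:
    """Apply missingness filters and mean imputation to a trial table.

    Covariates are filtered before patients (the two filters do not commute;
    this order is fixed and documented).  Raises on nonbinary treatment or
    response, or when nothing survives the filters.
    """
    df = df.copy()
    for col in ("treatment", "response"):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() or not set(vals.unique()) <= {0, 1}:
            raise ValueError(f"column {col!r} must be binary 0/1")
        df[col] = vals.astype(int)

    report = PreprocessReport(
        cov_missing_threshold=cov_missing_threshold,
        patient_missing_threshold=patient_missing_threshold,
    )
    cov_cols = _covariate_columns(df)
    if not cov_cols:
        raise ValueError("no covariate columns found")
    cov = df[cov_cols].apply(pd.to_numeric, errors="coerce")

    keep_cov = cov.isna().mean(axis=0) <= cov_missing_threshold
    report.dropped_covariates = [c for c, k in zip(cov_cols, keep_cov) if not k]
    cov = cov.loc[:, keep_cov]
    if cov.shape[1] == 0:
        raise ValueError("all covariates removed by the missingness filter")

    keep_pat = cov.isna().mean(axis=1) <= patient_missing_threshold
    ids = (
        df["patient_id"] if "patient_id" in df.columns else pd.Series(df.index, index=df.index)
    )
    report.dropped_patients = list(ids[~keep_pat])
    df = df.loc[keep_pat]
    cov = cov.loc[keep_pat]
    if len(df) == 0:
        raise ValueError("all patients removed by the missingness filter")

    x = cov.to_numpy(dtype=float)
    if impute:
        x, report.n_imputed = impute_means(x)

    true_sensitive = None
    if "true_sensitive" in df.columns:
        true_sensitive = df["true_sensitive"].to_numpy().astype(bool)
    data = TrialDataset(
        treatment=df["treatment"].to_numpy(),
        response=df["response"].to_numpy(),
        covariates=x,
        true_sensitive=true_sensitive,
        covariate_names=list(cov.columns),
    )
    return data, report


def load_trial_table(
    path,
    cov_missing_threshold: float = 0.1,
    patient_missing_threshold: float = 0.1,
    sep: str = ",",
) -> tuple[TrialDataset, PreprocessReport]:
    """Read a delimited trial table and preprocess it."""
    df = pd.read_csv(path, sep=sep, na_values=["NA", ""], float_precision="round_trip")
    return preprocess_frame(
        df,
        cov_missing_threshold=cov_missing_threshold,
        patient_missing_threshold=patient_missing_threshold,
    )


def write_trial_table(data: TrialDataset, path, sep: str = ",") -> None:
    """Write a TrialDataset as delimited text (round-trips bit-exactly)."""
    data.to_frame().to_csv(path, sep=sep, index=False, na_rep="NA")


def sign_transform(
    data: TrialDataset, report: PreprocessReport | None = None
) -> tuple[TrialDataset, list[int]]:
    """Orient covariates so higher values associate positively with benefit.

    Fits the per-covariate signature model on the full data and negates the
    columns whose interaction coefficient is negative.  Required by the
    odds-ratio-threshold classifier (CVASD), which is one-directional; the
    risk-score method weights covariates by the signed coefficients and
    needs no such transform.
    """
    from .cvasd import fit_signature

    model = fit_signature(data)
    flip = np.flatnonzero(model.beta < 0)
    x = data.covariates.copy()
    x[:, flip] *= -1.0
    if report is not None:
        report.flipped_covariates = [data.covariate_names[j] for j in flip]
    out = TrialDataset(
        treatment=data.treatment,
        response=data.response,
        covariates=x,
        true_sensitive=data.true_sensitive,
        covariate_names=list(data.covariate_names),
    )
    return out, list(int(j) for j in flip)
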