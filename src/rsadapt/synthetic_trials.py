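"""Trial simulation under a logistic treatment-covariate interaction model.

The generative model for a two-arm randomized trial with binary response is

    logit p_i = mu + lam * t_i + sum_j alpha_j x_ij + gamma * t_i * S_i,

where ``S_i`` is the sum of patient i's K *sensitive* covariates.  All
covariates are standard normal (optionally equicorrelated through a shared
factor); patients in the sensitive subgroup have their K sensitive
covariates shifted upwards by ``covariate_shift``.  The intercept ``mu`` is
fixed by the control-arm response rate, the main treatment effect ``lam``
by the response rate of nonsensitive treated patients, and the common
interaction coefficient ``gamma`` is calibrated numerically so that the
mean response probability of a sensitive treated patient matches the target
sensitive-group treated response rate (TRR).

A separate generator, :func:`simulate_start_like`, produces tables shaped
like a moderately sized pragmatic psychiatry trial (mixed-scale baseline
covariates, ~43% event rate, no marginal treatment effect, a planted
treatment-interacting covariate subset, and a little missingness) for
exercising the real-data preprocessing and threshold-scan pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy.optimize import brentq
from scipy.special import expit, logit

__all__ = [
    "ScenarioConfig",
    "ModelParams",
    "TrialDataset",
    "CalibrationError",
    "calibrate_model_params",
    "simulate_trial",
    "simulate_start_like",
]

#: Default upward shift of the sensitive covariates in sensitive patients.
#: Chosen once so that the selection operating characteristics of the
#: risk-score classifier in the reference scenario (25/25/70, 10% sensitive,
#: n=1000) match their published values, then frozen; see docs/methods.md.
DEFAULT_COVARIATE_SHIFT = 3.5


class CalibrationError(RuntimeError):
    """Raised when no interaction coefficient attains the target rate."""


@dataclass(frozen=True)
class ScenarioConfig:
    """Generative parameters of one simulation scenario.

    ``sensitive_fraction == 0`` defines the null scenario (no sensitive
    group, no interaction effect); ``sensitive_treated_rate`` is ignored
    there.
    """

    n_patients: int
    control_rate: float
    nonsensitive_treated_rate: float
    sensitive_treated_rate: float | None = None
    sensitive_fraction: float = 0.0
    n_covariates: int = 100
    n_sensitive_covariates: int = 10
    covariate_correlation: float = 0.0
    covariate_shift: float = DEFAULT_COVARIATE_SHIFT
    allocation: tuple[int, int] = (1, 1)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be at least 2")
        for name in ("control_rate", "nonsensitive_treated_rate"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if not 0.0 <= self.sensitive_fraction < 1.0:
            raise ValueError("sensitive_fraction must lie in [0, 1)")
        if self.sensitive_fraction > 0:
            if self.sensitive_treated_rate is None:
                raise ValueError(
                    "sensitive_treated_rate is required when sensitive_fraction > 0"
                )
            if not 0.0 < self.sensitive_treated_rate < 1.0:
                raise ValueError("sensitive_treated_rate must lie in (0, 1)")
        if not 0 < self.n_sensitive_covariates <= self.n_covariates:
            raise ValueError("need 0 < n_sensitive_covariates <= n_covariates")
        if not 0.0 <= self.covariate_correlation < 1.0:
            raise ValueError("covariate_correlation must lie in [0, 1)")
        if len(self.allocation) != 2 or min(self.allocation) <= 0:
            raise ValueError("allocation must be a pair of positive integers")

    @property
    def is_null(self) -> bool:
        return self.sensitive_fraction == 0.0

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["allocation"] = f"{self.allocation[0]}:{self.allocation[1]}"
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        alloc = d.get("allocation", "1:1")
        if isinstance(alloc, str):
            a, b = alloc.split(":")
            d["allocation"] = (int(a), int(b))
        else:
            d["allocation"] = tuple(alloc)
        return cls(**d)


@dataclass(frozen=True)
class ModelParams:
    """Calibrated coefficients of the generative logistic model."""

    mu: float
    lam: float
    gamma: float
    alphas: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.mu) and np.isfinite(self.lam) and np.isfinite(self.gamma)):
            raise ValueError("model parameters must be finite")


@dataclass
class TrialDataset:
    """Per-patient data of one (real or simulated) two-arm trial.

    ``true_sensitive`` is only available for simulated data.  Covariates may
    contain NaN before preprocessing; the analysis methods require a
    complete matrix.
    """

    treatment: np.ndarray
    response: np.ndarray
    covariates: np.ndarray
    true_sensitive: np.ndarray | None = None
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.treatment = np.asarray(self.treatment, dtype=np.int8)
        self.response = np.asarray(self.response, dtype=np.int8)
        self.covariates = np.asarray(self.covariates, dtype=float)
        n = self.treatment.shape[0]
        if self.response.shape[0] != n or self.covariates.shape[0] != n:
            raise ValueError("treatment, response and covariates must share length")
        if self.covariates.ndim != 2:
            raise ValueError("covariates must be a 2-D matrix")
        if self.true_sensitive is not None:
            self.true_sensitive = np.asarray(self.true_sensitive, dtype=bool)
            if self.true_sensitive.shape[0] != n:
                raise ValueError("true_sensitive length mismatch")
        if not set(np.unique(self.treatment)) <= {0, 1}:
            raise ValueError("treatment must be binary 0/1")
        if not set(np.unique(self.response)) <= {0, 1}:
            raise ValueError("response must be binary 0/1")
        if not self.covariate_names:
            self.covariate_names = [f"cov_{j + 1}" for j in range(self.covariates.shape[1])]

    @property
    def n_patients(self) -> int:
        return int(self.treatment.shape[0])

    @property
    def n_covariates(self) -> int:
        return int(self.covariates.shape[1])

    def subset(self, idx: np.ndarray) -> "TrialDataset":
        return TrialDataset(
            treatment=self.treatment[idx],
            response=self.response[idx],
            covariates=self.covariates[idx],
            true_sensitive=None if self.true_sensitive is None else self.true_sensitive[idx],
            covariate_names=list(self.covariate_names),
        )

    def with_treatment(self, treatment: np.ndarray) -> "TrialDataset":
        return TrialDataset(
            treatment=treatment,
            response=self.response,
            covariates=self.covariates,
            true_sensitive=self.true_sensitive,
            covariate_names=list(self.covariate_names),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.covariates, columns=self.covariate_names)
        df.insert(0, "response", self.response.astype(int))
        df.insert(0, "treatment", self.treatment.astype(int))
        if self.true_sensitive is not None:
            df.insert(2, "true_sensitive", self.true_sensitive.astype(int))
        df.insert(0, "patient_id", np.arange(1, self.n_patients + 1))
        return df


def _sensitive_sum_moments(scenario: ScenarioConfig) -> tuple[float, float]:
    """Mean and SD of the sum of the K sensitive covariates of a sensitive patient."""
    k = scenario.n_sensitive_covariates
    rho = scenario.covariate_correlation
    mean = k * scenario.covariate_shift
    var = k * (1.0 - rho) + k * k * rho
    return mean, float(np.sqrt(var))


_GH_NODES, _GH_WEIGHTS = hermegauss(201)
_GH_WEIGHTS = _GH_WEIGHTS / np.sqrt(2.0 * np.pi)


def _mean_sensitive_treated_rate(
    gamma: float, mu: float, lam: float, mean: float, sd: float
) -> float:
    """E[expit(mu + lam + gamma*S)] for S ~ Normal(mean, sd), by quadrature."""
    s = mean + sd * _GH_NODES
    return float(_GH_WEIGHTS @ expit(mu + lam + gamma * s))


def calibrate_model_params(scenario: ScenarioConfig) -> ModelParams:
    """Solve for the generative coefficients that hit the scenario's rates.

    ``mu`` and ``lam`` follow in closed form from the control and
    nonsensitive treated rates.  ``gamma`` is found by root-finding (on a
    deterministic Gauss-Hermite estimate of the mean response of a
    sensitive treated patient) so that this mean equals the target
    sensitive treated rate.  In the null scenario ``gamma = 0``.
    """
    mu = float(logit(scenario.control_rate))
    lam = float(logit(scenario.nonsensitive_treated_rate)) - mu
    if scenario.is_null:
        return ModelParams(mu=mu, lam=lam, gamma=0.0)

    trr = scenario.sensitive_treated_rate
    if trr < scenario.nonsensitive_treated_rate:
        raise CalibrationError(
            "sensitive_treated_rate below nonsensitive_treated_rate is not supported"
        )
    mean, sd = _sensitive_sum_moments(scenario)

    def f(g: float) -> float:
        return _mean_sensitive_treated_rate(g, mu, lam, mean, sd) - trr

    if abs(f(0.0)) <= 1e-12:
        return ModelParams(mu=mu, lam=lam, gamma=0.0)
    if mean <= 0:
        raise CalibrationError("covariate_shift must be positive to calibrate gamma")
    hi = 1e-3
    while f(hi) < 0.0:
        hi *= 2.0
        if hi > 1e3:
            raise CalibrationError("no interaction coefficient attains the target rate")
    gamma = float(brentq(f, 0.0, hi, xtol=1e-12))
    achieved = _mean_sensitive_treated_rate(gamma, mu, lam, mean, sd)
    if abs(achieved - trr) > 1e-3:
        raise CalibrationError("gamma calibration did not reach tolerance")
    return ModelParams(mu=mu, lam=lam, gamma=gamma)


def simulate_trial(
    scenario: ScenarioConfig,
    params: ModelParams | None = None,
    seed: int | None = None,
) -> TrialDataset:
    """Draw one trial dataset from the calibrated generative model.

    Treatment allocation is exactly balanced by permutation at the stated
    ratio; the sensitive subgroup is a random subset of patients assigned
    independently of arm.  Reproducible bit-for-bit given config and seed.
    """
    if params is None:
        params = calibrate_model_params(scenario)
    if seed is None:
        seed = scenario.seed
    rng = np.random.default_rng(seed)
    n = scenario.n_patients
    j = scenario.n_covariates
    k = scenario.n_sensitive_covariates
    rho = scenario.covariate_correlation

    a, b = scenario.allocation
    n_treated = int(round(n * a / (a + b)))
    treatment = np.zeros(n, dtype=np.int8)
    treatment[rng.permutation(n)[:n_treated]] = 1

    n_sens = int(round(scenario.sensitive_fraction * n))
    true_sensitive = np.zeros(n, dtype=bool)
    true_sensitive[rng.permutation(n)[:n_sens]] = True

    x = rng.standard_normal((n, j))
    if rho > 0.0:
        shared = rng.standard_normal(n)
        x = np.sqrt(rho) * shared[:, None] + np.sqrt(1.0 - rho) * x
    x[true_sensitive, :k] += scenario.covariate_shift

    eta = params.mu + params.lam * treatment
    if params.alphas is not None:
        eta = eta + x @ np.asarray(params.alphas, dtype=float)
    eta = eta + params.gamma * treatment * x[:, :k].sum(axis=1)
    response = (rng.random(n) < expit(eta)).astype(np.int8)
    return TrialDataset(
        treatment=treatment,
        response=response,
        covariates=x,
        true_sensitive=true_sensitive,
    )


def simulate_start_like(
    seed: int | None = None,
    n_patients: int = 670,
    n_covariates: int = 86,
    n_interacting: int = 16,
    interaction_strength: float = 0.35,
    event_rate: float = 0.43,
    missing_rate: float = 0.02,
    return_details: bool = False,
):
    """Generate a pragmatic-trial-like table with mixed-scale covariates.

    Emulates the shape of a moderately sized psychiatry RCT: ~670 patients,
    ~86 baseline covariates of mixed types (binary diagnoses, bounded
    questionnaire scores, continuous measures on heterogeneous scales),
    an overall event rate near ``event_rate``, no marginal treatment
    effect, and a planted subset of ``n_interacting`` covariates carrying
    treatment-covariate interactions of per-covariate (standardised) size
    ``interaction_strength / sqrt(n_interacting)``.  A fraction
    ``missing_rate`` of covariate cells is set missing at random to
    exercise the imputation pipeline.

    The marginal treatment effect is removed by construction: a small
    arm-level offset is solved for so that the expected response rate is
    ``event_rate`` on both arms given the realised covariates.
    """
    rng = np.random.default_rng(seed)
    n, j = n_patients, n_covariates

    kinds = rng.choice(["binary", "score", "continuous"], size=j, p=[0.35, 0.35, 0.30])
    x = np.empty((n, j))
    for col, kind in enumerate(kinds):
        if kind == "binary":
            prev = rng.uniform(0.1, 0.9)
            x[:, col] = rng.random(n) < prev
        elif kind == "score":
            top = rng.integers(10, 41)
            x[:, col] = np.clip(
                np.round(rng.normal(top * 0.4, top * 0.2, size=n)), 0, top
            )
        else:
            scale = float(np.exp(rng.normal(0.0, 1.5)))
            loc = rng.normal(0.0, 2.0) * scale
            x[:, col] = loc + scale * rng.standard_normal(n)

    planted = np.sort(rng.choice(j, size=n_interacting, replace=False))
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    z = (x - x.mean(axis=0)) / sd
    signal = z[:, planted].sum(axis=1) * (
        interaction_strength / np.sqrt(max(n_interacting, 1))
    )

    treatment = np.zeros(n, dtype=np.int8)
    treatment[rng.permutation(n)[: n // 2]] = 1
    mu0 = float(logit(event_rate))

    def treated_gap(lam_adj: float) -> float:
        return float(np.mean(expit(mu0 + lam_adj + signal))) - event_rate

    lam_adj = float(brentq(treated_gap, -5.0, 5.0)) if interaction_strength > 0 else 0.0
    eta = mu0 + treatment * (lam_adj + signal)
    response = (rng.random(n) < expit(eta)).astype(np.int8)

    x_missing = x.copy()
    if missing_rate > 0:
        mask = rng.random((n, j)) < missing_rate
        x_missing[mask] = np.nan

    data = TrialDataset(treatment=treatment, response=response, covariates=x_missing)
    if return_details:
        return data, {
            "planted_covariates": planted,
            "kinds": kinds,
            "lam_adj": lam_adj,
            "complete_covariates": x,
        }
    return data
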