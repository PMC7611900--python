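"""Operating-characteristics harness for the adaptive subgroup designs.

Runs replicated simulated trials through a classification method and the
split-alpha design test, and aggregates empirical power, selection
sensitivity/specificity and the estimated response rate of the selected
group on the treatment arm.

Replicate random streams are keyed by (study seed, replicate index) for the
dataset and additionally by the method for the cross-validation fold
assignment, so competing methods are compared on identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .cvasd import DEFAULT_TUNING_SETS, cvasd_classify
from .cvrs import cvrs_classify, nested_cvrs_classify
from .inference import design_test
from .synthetic_trials import (
    ModelParams,
    ScenarioConfig,
    TrialDataset,
    calibrate_model_params,
    simulate_trial,
)

__all__ = [
    "ReplicateRecord",
    "OperatingCharacteristics",
    "run_replicate",
    "run_study",
    "operating_characteristics",
    "power_curve",
]

METHODS = ("cvrs", "nested_cvrs", "cvasd")

#: Fraction of patients drawn as pseudo-truth under the null scenario, so
#: that an uninformative ~50/50 classifier scores selection sensitivity and
#: specificity near 0.5 (harness convention; no real truth labels exist).
NULL_PSEUDO_TRUTH_FRACTION = 0.1


def _child_seeds(seed: int, *keys: int) -> tuple[int, ...]:
    """Deterministic child seeds (< 2**31) from a base seed and integer keys."""
    ss = np.random.SeedSequence([int(seed)] + [int(k) for k in keys])
    return tuple(int(s) & 0x7FFFFFFF for s in ss.generate_state(4))


@dataclass
class ReplicateRecord:
    """Per-replicate outcomes of one simulated trial analysis."""

    method: str
    replicate: int
    overall_pvalue: float
    subgroup_pvalue: float
    n_selected: int
    n_selected_treated: int
    sensitive_response_rate: float  # NaN when no selected treated patients
    selection_sensitivity: float  # NaN when truth has no positives
    selection_specificity: float
    pseudo_truth: bool = False
    degenerate_folds: int = 0


def _confusion_rates(
    truth: np.ndarray, predicted: np.ndarray
) -> tuple[float, float]:
    pos = truth.sum()
    neg = truth.size - pos
    sens = float((predicted & truth).sum() / pos) if pos else float("nan")
    spec = float((~predicted & ~truth).sum() / neg) if neg else float("nan")
    return sens, spec


def _classify(data: TrialDataset, method: str, fold_seed: int, candidates):
    if method == "cvrs":
        return cvrs_classify(data, seed=fold_seed)
    if method == "nested_cvrs":
        return nested_cvrs_classify(data, seed=fold_seed)
    if method == "cvasd":
        return cvasd_classify(
            data, seed=fold_seed, candidates=candidates or DEFAULT_TUNING_SETS
        )
    raise ValueError(f"method must be one of {METHODS}")


def run_replicate(
    scenario: ScenarioConfig,
    method: str = "cvrs",
    seed: int = 0,
    replicate: int = 0,
    params: ModelParams | None = None,
    alpha1: float = 0.04,
    alpha2: float = 0.01,
    candidates=None,
) -> ReplicateRecord:
    """Simulate one trial, classify, test, and record the outcomes.

    The dataset seed depends only on (seed, replicate); the fold-assignment
    seed additionally on the method, so different methods see the same
    simulated trial.
    """
    if params is None:
        params = calibrate_model_params(scenario)
    data_seed, truth_seed, _, _ = _child_seeds(seed, replicate)
    method_key = METHODS.index(method)
    _, _, fold_seed, _ = _child_seeds(seed, replicate, method_key)
    data = simulate_trial(scenario, params, seed=data_seed)
    result = _classify(data, method, fold_seed, candidates)
    test = design_test(data, result.sensitive, alpha1=alpha1, alpha2=alpha2)

    truth = data.true_sensitive
    pseudo = False
    if truth is None or not truth.any():
        # null scenario: score against a random pseudo-truth subset
        rng = np.random.default_rng(truth_seed)
        truth = np.zeros(data.n_patients, dtype=bool)
        n_pseudo = max(1, int(round(NULL_PSEUDO_TRUTH_FRACTION * data.n_patients)))
        truth[rng.permutation(data.n_patients)[:n_pseudo]] = True
        pseudo = True
    sens, spec = _confusion_rates(truth, result.sensitive)

    sel_treated = result.sensitive & (data.treatment == 1)
    n_sel_treated = int(sel_treated.sum())
    rr = (
        float(data.response[sel_treated].mean()) if n_sel_treated else float("nan")
    )
    return ReplicateRecord(
        method=method,
        replicate=replicate,
        overall_pvalue=test.overall_pvalue,
        subgroup_pvalue=test.subgroup_pvalue,
        n_selected=int(result.sensitive.sum()),
        n_selected_treated=n_sel_treated,
        sensitive_response_rate=rr,
        selection_sensitivity=sens,
        selection_specificity=spec,
        pseudo_truth=pseudo,
        degenerate_folds=len(result.degenerate_folds),
    )


def run_study(
    scenario: ScenarioConfig,
    method: str = "cvrs",
    n_replicates: int = 200,
    seed: int = 0,
    alpha1: float = 0.04,
    alpha2: float = 0.01,
    candidates=None,
    n_jobs: int = 1,
) -> list[ReplicateRecord]:
    """Run independent replicates of a scenario for one method."""
    params = calibrate_model_params(scenario)
    if n_jobs == 1:
        return [
            run_replicate(
                scenario, method, seed, rep, params, alpha1, alpha2, candidates
            )
            for rep in range(n_replicates)
        ]
    return Parallel(n_jobs=n_jobs)(
        delayed(run_replicate)(
            scenario, method, seed, rep, params, alpha1, alpha2, candidates
        )
        for rep in range(n_replicates)
    )


@dataclass
class OperatingCharacteristics:
    """Replicate-averaged operating characteristics of a design."""

    method: str
    n_replicates: int
    power_overall: float
    power_subgroup: float
    power_design: float
    selection_sensitivity: float
    selection_specificity: float
    mean_sensitive_response_rate: float
    n_undefined_response_rate: int
    alpha1: float
    alpha2: float
    scenario: ScenarioConfig | None = None

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "n_replicates": self.n_replicates,
            "power_overall": self.power_overall,
            "power_subgroup": self.power_subgroup,
            "power_design": self.power_design,
            "selection_sensitivity": self.selection_sensitivity,
            "selection_specificity": self.selection_specificity,
            "mean_sensitive_response_rate": self.mean_sensitive_response_rate,
            "n_undefined_response_rate": self.n_undefined_response_rate,
        }
        return d


def operating_characteristics(
    records: Sequence[ReplicateRecord],
    alpha1: float = 0.04,
    alpha2: float = 0.01,
    scenario: ScenarioConfig | None = None,
) -> OperatingCharacteristics:
    """Aggregate per-replicate records into operating characteristics.

    Undefined per-replicate quantities (empty selected treated group; no
    truth positives outside the pseudo-truth convention) are excluded from
    the means and their count reported.
    """
    if not records:
        raise ValueError("need at least one replicate record")
    overall = np.array([r.overall_pvalue for r in records])
    subgroup = np.array([r.subgroup_pvalue for r in records])
    rr = np.array([r.sensitive_response_rate for r in records])
    sens = np.array([r.selection_sensitivity for r in records])
    spec = np.array([r.selection_specificity for r in records])
    positive = (overall < alpha1) | (subgroup < alpha2)
    return OperatingCharacteristics(
        method=records[0].method,
        n_replicates=len(records),
        power_overall=float((overall < alpha1).mean()),
        power_subgroup=float((subgroup < alpha2).mean()),
        power_design=float(positive.mean()),
        selection_sensitivity=float(np.nanmean(sens)) if np.isfinite(sens).any() else float("nan"),
        selection_specificity=float(np.nanmean(spec)) if np.isfinite(spec).any() else float("nan"),
        mean_sensitive_response_rate=(
            float(np.nanmean(rr)) if np.isfinite(rr).any() else float("nan")
        ),
        n_undefined_response_rate=int(np.isnan(rr).sum()),
        alpha1=alpha1,
        alpha2=alpha2,
        scenario=scenario,
    )


def power_curve(
    base_scenario: ScenarioConfig,
    sample_sizes: Sequence[int] = (200, 400, 600, 800, 1000),
    method: str = "cvrs",
    n_replicates: int = 200,
    seed: int = 0,
    n_jobs: int = 1,
) -> pd.DataFrame:
    """Operating characteristics of one scenario family across sample sizes."""
    from dataclasses import replace as dc_replace

    rows = []
    for n in sample_sizes:
        scenario = dc_replace(base_scenario, n_patients=int(n))
        records = run_study(
            scenario, method=method, n_replicates=n_replicates, seed=seed, n_jobs=n_jobs
        )
        oc = operating_characteristics(records, scenario=scenario)
        row = {"n_patients": int(n)}
        row.update(oc.to_dict())
        rows.append(row)
    return pd.DataFrame(rows)
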