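"""Scoring predicted against observed onset ages: MAE, RMSE, bootstrap CIs.

Signed errors follow the convention predicted - observed, so positive means
the prediction is late. Only visits strictly before the observed onset are
used for prediction, preventing leakage of post-onset information.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort, Stage, stage_from_cdrsb
from .model import FDIModel, predict_onset
from .survival import ENDPOINTS


class NoEvaluableParticipantsError(ValueError):
    def __init__(self, message: str, exclusions: dict[str, int] | None = None):
        super().__init__(message)
        self.exclusions = exclusions or {}


def onset_errors(
    predicted: Mapping[str, float],
    observed: Mapping[str, float],
) -> tuple[pd.Series, list[str]]:
    """Signed errors (predicted - observed) for matched participant ids.

    Returns the error series plus the list of ids present on one side only.
    """
    common = sorted(set(predicted) & set(observed))
    unmatched = sorted((set(predicted) | set(observed)) - set(common))
    if not common:
        raise ValueError("no participant ids in common between predictions and onsets")
    errors = pd.Series(
        {pid: float(predicted[pid]) - float(observed[pid]) for pid in common},
        name="error",
    )
    return errors, unmatched


def mae_rmse(errors: Sequence[float]) -> tuple[float, float]:
    """Mean absolute error and root mean square error of signed errors."""
    e = np.asarray(errors, dtype=float)
    if e.size == 0:
        raise ValueError("no errors to score")
    return float(np.mean(np.abs(e))), float(np.sqrt(np.mean(e**2)))


_STATS = {
    "mae": lambda e: np.mean(np.abs(e), axis=-1),
    "rmse": lambda e: np.sqrt(np.mean(e**2, axis=-1)),
}


def bootstrap_ci(
    errors: Sequence[float],
    statistic: str = "mae",
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap interval for MAE or RMSE; seeded, deterministic."""
    if statistic not in _STATS:
        raise ValueError("statistic must be 'mae' or 'rmse'")
    e = np.asarray(errors, dtype=float)
    if e.size < 2:
        raise ValueError("need at least 2 errors for a bootstrap interval")
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is small; intervals will be noisy", stacklevel=2)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, e.size, size=(n_boot, e.size))
    stats = _STATS[statistic](e[idx])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


@dataclass
class EvalReport:
    endpoint: str
    n: int
    mae: float
    mae_ci: tuple[float, float]
    rmse: float
    rmse_ci: tuple[float, float]
    pred_mean: float
    pred_sd: float
    obs_mean: float
    obs_sd: float
    errors: pd.DataFrame  # participant_id, predicted, observed, error
    exclusions: dict[str, int]

    def __post_init__(self) -> None:
        if self.mae > self.rmse + 1e-9:
            raise ValueError(f"mae ({self.mae}) exceeds rmse ({self.rmse})")
        if self.n != len(self.errors):
            raise ValueError("n does not match the error table")

    def to_dict(self) -> dict:
        return {
            "endpoint": self.endpoint,
            "n": self.n,
            "mae": self.mae,
            "mae_ci": list(self.mae_ci),
            "rmse": self.rmse,
            "rmse_ci": list(self.rmse_ci),
            "predicted_mean": self.pred_mean,
            "predicted_sd": self.pred_sd,
            "observed_mean": self.obs_mean,
            "observed_sd": self.obs_sd,
            "error_convention": "predicted - observed (positive = late)",
            "exclusions": self.exclusions,
        }


def observed_onset_ages(
    cohort: Cohort,
    endpoint: str,
    use_staging_fallback: bool = True,
) -> dict[str, float]:
    """Recorded onset age per participant: age at the first visit whose
    diagnosis (or CDR-SB stage, as fallback) qualifies for the endpoint."""
    if endpoint not in ENDPOINTS:
        raise ValueError(f"endpoint must be one of {ENDPOINTS}")
    qualifying = (Stage.AD,) if endpoint == "AD" else (Stage.MCI, Stage.AD)
    out: dict[str, float] = {}
    for s in cohort:
        for v in s.visits:
            stage = v.diagnosis
            if stage is None and use_staging_fallback:
                stage = stage_from_cdrsb(v.cdr_sb)
            if stage in qualifying:
                out[s.participant_id] = v.age
                break
    return out


def evaluate_cohort(
    model: FDIModel,
    cohort: Cohort,
    endpoint: str,
    observed: Mapping[str, float] | None = None,
    use_staging_fallback: bool = True,
    use_strata: bool = False,
    stratify_by: str | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> EvalReport:
    """Predict onset for every evaluable participant and score the errors.

    ``observed`` may supply external onset ages (e.g. simulation ground
    truth); by default onsets are derived from the recorded diagnoses. Each
    participant is predicted from visits strictly before their observed onset
    and needs at least 2 such visits.
    """
    if observed is None:
        observed = observed_onset_ages(cohort, endpoint, use_staging_fallback)
    exclusions = {
        "no_observed_onset": 0,
        "onset_outside_followup": 0,
        "too_few_preonset_visits": 0,
    }
    rows = []
    for s in cohort:
        if s.participant_id not in observed:
            exclusions["no_observed_onset"] += 1
            continue
        onset_age = float(observed[s.participant_id])
        # an onset is only "recorded" if it falls within follow-up
        if s.visits and onset_age > s.visits[-1].age:
            exclusions["onset_outside_followup"] += 1
            continue
        pre = s.truncate_before(onset_age)
        if pre.n_visits < 2:
            exclusions["too_few_preonset_visits"] += 1
            continue
        pred = predict_onset(pre, model, use_strata=use_strata,
                             stratify_by=stratify_by)
        pred_age = pred.pred_age_ad if endpoint == "AD" else pred.pred_age_mci
        rows.append(
            {
                "participant_id": s.participant_id,
                "predicted": pred_age,
                "observed": onset_age,
                "error": pred_age - onset_age,
                "identifiable": pred.identifiable,
            }
        )
    if not rows:
        raise NoEvaluableParticipantsError(
            f"no evaluable participants for endpoint {endpoint}", exclusions
        )
    table = pd.DataFrame(rows)
    e = table["error"].to_numpy()
    mae, rmse = mae_rmse(e)
    if len(e) >= 2:
        mae_ci = bootstrap_ci(e, "mae", n_boot=n_boot, seed=seed)
        rmse_ci = bootstrap_ci(e, "rmse", n_boot=n_boot, seed=seed)
    else:
        mae_ci = (mae, mae)
        rmse_ci = (rmse, rmse)
    return EvalReport(
        endpoint=endpoint,
        n=len(table),
        mae=mae,
        mae_ci=mae_ci,
        rmse=rmse,
        rmse_ci=rmse_ci,
        pred_mean=float(table["predicted"].mean()),
        pred_sd=float(table["predicted"].std(ddof=1)) if len(table) > 1 else 0.0,
        obs_mean=float(table["observed"].mean()),
        obs_sd=float(table["observed"].std(ddof=1)) if len(table) > 1 else 0.0,
        errors=table,
        exclusions=exclusions,
    )
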