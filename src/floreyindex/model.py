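"""The serialized index model: mean curve + onset thresholds + provenance.

Predicted age at onset for endpoint e is ``theta_e - delta``: the participant
reaches index value theta_e at exactly that chronological age, since
index = age + delta.

``default_model`` packages the published threshold constants (overall 79/85,
sex-specific AD thresholds, comorbidity strata). The published work does not
release its mean-curve coefficients, so the packaged curve is reconstructed
from the staging calibration (score 0.5 at index 79, 4.5 at index 85); the
provenance field says so explicitly.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cohort import ParticipantSeries
from .survival import ThresholdEntry, ThresholdTable
from .trajectory import (
    AlignmentModel,
    MeanTrajectory,
    align_participant,
    calibrated_curve,
)

SCHEMA_VERSION = "1"


class ModelBuildError(ValueError):
    """The curve/threshold bundle violates a model invariant."""


class ModelLoadError(ValueError):
    """A model file is malformed, truncated, or of an unknown schema version."""


@dataclass
class FDIModel:
    curve: MeanTrajectory
    thresholds: ThresholdTable
    provenance: dict = field(default_factory=dict)

    def validate(self) -> None:
        for ep in ("MCI", "AD"):
            e = self.thresholds.get(ep)
            if e is None or e.theta is None:
                raise ModelBuildError(f"missing overall {ep} threshold")
        # theta_MCI <= theta_AD wherever both exist for the same stratum
        for (ep, cov, lev), entry in self.thresholds.entries.items():
            if ep != "MCI" or entry.theta is None:
                continue
            ad = self.thresholds.get("AD", cov, lev)
            if ad is not None and ad.theta is not None and entry.theta > ad.theta:
                where = "overall" if cov is None else f"{cov}={lev}"
                raise ModelBuildError(
                    f"theta_MCI ({entry.theta}) > theta_AD ({ad.theta}) in {where}"
                )


def build_model(alignment: AlignmentModel, thresholds: ThresholdTable,
                metadata: dict | None = None) -> FDIModel:
    """Assemble a fitted model from an alignment and its threshold table."""
    model = FDIModel(
        curve=alignment.curve,
        thresholds=thresholds,
        provenance={"source": "fitted", **(metadata or {})},
    )
    model.validate()
    return model


#: Published onset thresholds: (endpoint, covariate, level) -> index years.
#: Comorbidity strata distinguish participants with ("disease") and without
#: ("disease-free") the condition.
PUBLISHED_THRESHOLDS: dict[tuple[str, str | None, str | None], float] = {
    ("MCI", None, None): 79.0,
    ("AD", None, None): 85.0,
    ("AD", "sex", "M"): 84.7,
    ("AD", "sex", "F"): 85.5,
    ("MCI", "hypertension", "disease"): 78.2,
    ("MCI", "hypertension", "disease-free"): 79.0,
    ("AD", "hypertension", "disease"): 85.3,
    ("AD", "hypertension", "disease-free"): 84.8,
    ("MCI", "stroke", "disease"): 77.5,
    ("MCI", "stroke", "disease-free"): 78.9,
    ("AD", "stroke", "disease"): 88.1,
    ("AD", "stroke", "disease-free"): 84.8,
    ("MCI", "neurologic", "disease"): 77.8,
    ("MCI", "neurologic", "disease-free"): 79.0,
    ("AD", "neurologic", "disease"): 86.4,
    ("AD", "neurologic", "disease-free"): 84.7,
    ("MCI", "psychiatric", "disease"): 74.9,
    ("MCI", "psychiatric", "disease-free"): 78.9,
    ("AD", "psychiatric", "disease"): 89.2,
    ("AD", "psychiatric", "disease-free"): 84.8,
}


def default_model() -> FDIModel:
    """The packaged model carrying the published threshold constants.

    The curve is a reconstruction calibrated so the staging cuts fall on the
    published thresholds — it is NOT the original cohort-fitted curve, and the
    provenance note records that.
    """
    table = ThresholdTable()
    for key, theta in PUBLISHED_THRESHOLDS.items():
        table.set(*key, ThresholdEntry(theta))
    model = FDIModel(
        curve=calibrated_curve(),
        thresholds=table,
        provenance={
            "source": "paper_default",
            "note": (
                "Thresholds are published constants; the mean curve is "
                "reconstructed from the staging calibration (0.5 at 79, "
                "4.5 at 85), not the original cohort fit."
            ),
        },
    )
    model.validate()
    return model


@dataclass
class PredictionResult:
    participant_id: str
    shift: float
    current_fdi: float
    pred_age_mci: float
    pred_age_ad: float
    mci_onset_at_or_before_last_visit: bool
    ad_onset_at_or_before_last_visit: bool
    identifiable: bool
    stratum_used: str


def predict_onset(
    series: ParticipantSeries,
    model: FDIModel,
    use_strata: bool = False,
    stratify_by: str | None = None,
    bounds: tuple[float, float] = (-30.0, 30.0),
    ridge: float = 1e-3,
) -> PredictionResult:
    """Predict chronological age at MCI and AD onset for one participant.

    The participant is aligned to the model curve to obtain delta; the
    predicted onset age for each endpoint is theta - delta. With
    ``use_strata``, the threshold of the stratum matching the participant's
    covariate value is used when available, falling back to the overall
    threshold with a warning. Predictions earlier than the last observed visit
    are flagged, not clamped.
    """
    res = align_participant(series, model.curve, bounds=bounds, ridge=ridge)
    delta = res.shift
    last_age = series.visits[-1].age
    stratum_used = "overall"

    def theta_for(endpoint: str) -> float:
        nonlocal stratum_used
        if use_strata and stratify_by is not None:
            value = series.covariates.get(stratify_by)
            if value is not None:
                level = (
                    ("disease" if value else "disease-free")
                    if isinstance(value, bool)
                    else str(value)
                )
                t = model.thresholds.theta(endpoint, stratify_by, level)
                if t is not None:
                    stratum_used = f"{stratify_by}={level}"
                    return t
                warnings.warn(
                    f"no {endpoint} threshold for stratum {stratify_by}={level}; "
                    "falling back to overall",
                    stacklevel=3,
                )
        t = model.thresholds.theta(endpoint)
        if t is None:
            raise ModelBuildError(f"model lacks an overall {endpoint} threshold")
        return t

    pred_mci = theta_for("MCI") - delta
    pred_ad = theta_for("AD") - delta
    return PredictionResult(
        participant_id=series.participant_id,
        shift=delta,
        current_fdi=last_age + delta,
        pred_age_mci=pred_mci,
        pred_age_ad=pred_ad,
        mci_onset_at_or_before_last_visit=pred_mci <= last_age,
        ad_onset_at_or_before_last_visit=pred_ad <= last_age,
        identifiable=res.identifiable,
        stratum_used=stratum_used,
    )


# ---------------------------------------------------------------------------
# Serialization: versioned JSON, deterministic byte-for-byte on re-write.

def model_to_dict(model: FDIModel) -> dict:
    c = model.curve
    return {
        "schema_version": SCHEMA_VERSION,
        "curve": {
            "family": c.family,
            "ceiling": c.ceiling,
            "rate": c.rate,
            "midpoint": c.midpoint,
            "fit_domain": list(c.fit_domain),
            "residual_sd": c.residual_sd,
            "n_points": c.n_points,
        },
        "thresholds": [
            {
                "endpoint": ep,
                "covariate": cov,
                "level": lev,
                "theta": e.theta,
                "n_events": e.n_events,
                "n_censored": e.n_censored,
                "note": e.note,
            }
            for (ep, cov, lev), e in sorted(
                model.thresholds.entries.items(),
                key=lambda kv: tuple(str(x) for x in kv[0]),
            )
        ],
        "provenance": model.provenance,
    }


def model_from_dict(data: dict) -> FDIModel:
    if not isinstance(data, dict) or "schema_version" not in data:
        raise ModelLoadError("not a model file: missing schema_version")
    if data["schema_version"] != SCHEMA_VERSION:
        raise ModelLoadError(
            f"unsupported model schema version {data['schema_version']!r} "
            f"(expected {SCHEMA_VERSION!r})"
        )
    try:
        c = data["curve"]
        curve = MeanTrajectory(
            family=c["family"],
            ceiling=float(c["ceiling"]),
            rate=float(c["rate"]),
            midpoint=float(c["midpoint"]),
            fit_domain=tuple(float(x) for x in c["fit_domain"]),
            residual_sd=None if c.get("residual_sd") is None else float(c["residual_sd"]),
            n_points=None if c.get("n_points") is None else int(c["n_points"]),
        )
        table = ThresholdTable()
        for row in data["thresholds"]:
            table.set(
                row["endpoint"], row.get("covariate"), row.get("level"),
                ThresholdEntry(
                    None if row["theta"] is None else float(row["theta"]),
                    row.get("n_events"),
                    row.get("n_censored"),
                    row.get("note"),
                ),
            )
        model = FDIModel(curve=curve, thresholds=table,
                         provenance=dict(data.get("provenance", {})))
    except (KeyError, TypeError, ValueError) as exc:
        raise ModelLoadError(f"malformed model file: {exc}") from exc
    model.validate()
    return model


def write_model(model: FDIModel, path: str | Path) -> Path:
    path = Path(path)
    text = json.dumps(model_to_dict(model), indent=2, sort_keys=True)
    path.write_text(text + "\n")
    return path


def read_model(path: str | Path) -> FDIModel:
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ModelLoadError(f"cannot read model file {path}: {exc}") from exc
    return model_from_dict(data)
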