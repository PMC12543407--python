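"""Synthetic longitudinal cohorts with known ground truth.

The generator emulates the structure of observational Alzheimer cohorts:
participants enrolled after age 60 with a ~1.5-year visit cadence over 3-10
years of follow-up, CDR-SB scores on a 0.5-point grid in [0, 18], and a mix
of cognitively unimpaired, MCI and AD outcomes.

Each participant carries a latent (noise-free) trajectory y*(age) =
m*(age + delta*), where m* is the calibrated logistic mean curve and delta*
a Gaussian time shift. Ground-truth onset ages are the exact real solutions
of m* crossing the staging cuts, while observed scores add Gaussian noise and
grid rounding on top — separating measurement error from the estimand, which
real cohort data cannot do.

Optional covariate effects move a stratum's diagnosis-conversion points along
the index (e.g. carriers convert 3 index-years later). The offsets act on the
conversion points rather than on the trajectory shape: a trajectory-level
shift would be absorbed by the alignment step and leave no recoverable
stratum difference in the thresholds.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort, ParticipantSeries, Stage, VisitRecord, write_cohort
from .trajectory import MeanTrajectory, calibrated_curve


@dataclass
class CovariateEffect:
    """Bernoulli covariate with additive onset-index offsets for carriers."""

    prevalence: float = 0.5
    mci_offset: float = 0.0
    ad_offset: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must be in [0, 1]")


@dataclass
class SimulationConfig:
    """Generator settings.

    Defaults mirror the target cohort structure: baseline age Normal(72, 7)
    truncated to [60, 95], 1.5-year visit spacing, follow-up Uniform(3, 10)
    years, shift SD 6 years (spreading onset ages with an SD comparable to
    observational onset-age SDs), observation noise SD 0.5 score points with
    rounding to the 0.5 grid.
    """

    n_participants: int = 500
    curve: MeanTrajectory = field(default_factory=calibrated_curve)
    shift_sd: float = 6.0
    baseline_age_mean: float = 72.0
    baseline_age_sd: float = 7.0
    baseline_age_range: tuple[float, float] = (60.0, 95.0)
    visit_interval: float = 1.5
    followup_range: tuple[float, float] = (3.0, 10.0)
    noise_sd: float = 0.5
    round_to_grid: bool = True
    mci_cut: float = 0.5
    ad_cut: float = 4.5
    covariate_effects: dict[str, CovariateEffect] = field(default_factory=dict)
    label_delay_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        if self.shift_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if not 0.0 < self.mci_cut < self.ad_cut < self.curve.ceiling:
            raise ValueError("staging cuts must satisfy 0 < mci < ad < ceiling")
        if not 0.0 <= self.label_delay_prob <= 1.0:
            raise ValueError("label_delay_prob must be in [0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["curve"] = {
            "family": self.curve.family,
            "ceiling": self.curve.ceiling,
            "rate": self.curve.rate,
            "midpoint": self.curve.midpoint,
        }
        return d


@dataclass
class SimulatedCohort:
    cohort: Cohort
    truth: pd.DataFrame
    config: SimulationConfig


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float) -> float:
    # rejection sampling keeps the draw order deterministic per participant
    for _ in range(10_000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    raise RuntimeError("truncated normal rejection sampling failed")


def simulate_cohort(config: SimulationConfig | None = None) -> SimulatedCohort:
    """Draw a cohort; fully deterministic given ``config.seed``.

    Observed score = clamp(round_to_half(y* + Normal(0, noise_sd)), 0, 18);
    the diagnosis label is the latent stage at the visit (optionally delayed
    by one visit with probability ``label_delay_prob``, emulating late
    clinical recognition).
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    curve = cfg.curve
    base_mci_fdi = curve.inverse(cfg.mci_cut)
    base_ad_fdi = curve.inverse(cfg.ad_cut)

    series_list: list[ParticipantSeries] = []
    truth_rows: list[dict] = []
    width = len(str(cfg.n_participants))
    for i in range(cfg.n_participants):
        pid = f"S{i + 1:0{width}d}"
        delta = float(rng.normal(0.0, cfg.shift_sd)) if cfg.shift_sd > 0 else 0.0
        baseline = _truncated_normal(
            rng, cfg.baseline_age_mean, cfg.baseline_age_sd, *cfg.baseline_age_range
        )
        followup = float(rng.uniform(*cfg.followup_range))
        offsets = np.arange(0.0, followup, cfg.visit_interval)
        ages = baseline + offsets

        sex = "F" if rng.random() < 0.5 else "M"
        covariates: dict[str, object] = {"sex": sex}
        o_mci = o_ad = 0.0
        for name, eff in cfg.covariate_effects.items():
            carrier = bool(rng.random() < eff.prevalence)
            covariates[name] = carrier
            if carrier:
                o_mci += eff.mci_offset
                o_ad += eff.ad_offset
        mci_fdi = base_mci_fdi + o_mci
        ad_fdi = base_ad_fdi + o_ad
        if mci_fdi >= ad_fdi:
            raise ValueError(
                "covariate offsets must keep MCI conversion before AD conversion"
            )

        fdi = ages + delta
        latent = curve(fdi)
        labels = np.where(fdi >= ad_fdi, "AD", np.where(fdi >= mci_fdi, "MCI", "CU"))
        if cfg.label_delay_prob > 0:
            order = {"CU": 0, "MCI": 1, "AD": 2}
            lab = list(labels)
            for j in range(1, len(lab)):
                if order[lab[j]] > order[lab[j - 1]] and rng.random() < cfg.label_delay_prob:
                    lab[j] = lab[j - 1]
            labels = np.array(lab)

        noise = rng.normal(0.0, 1.0, size=len(ages)) * cfg.noise_sd
        observed = latent + noise
        if cfg.round_to_grid:
            observed = np.round(observed * 2.0) / 2.0
        observed = np.clip(observed, 0.0, curve.ceiling)

        visits = [
            VisitRecord(pid, float(a), float(sc), diagnosis=Stage(lb))
            for a, sc, lb in zip(ages, observed, labels)
        ]
        series_list.append(ParticipantSeries(pid, visits, covariates))
        row = {
            "participant_id": pid,
            "delta_true": delta,
            "baseline_age": baseline,
            "n_visits": len(ages),
            "onset_age_mci": mci_fdi - delta,
            "onset_age_ad": ad_fdi - delta,
            "onset_fdi_mci": mci_fdi,
            "onset_fdi_ad": ad_fdi,
            "sex": sex,
        }
        for name in cfg.covariate_effects:
            row[name] = covariates[name]
        truth_rows.append(row)

    cohort = Cohort(series_list, provenance=f"simulate_cohort(seed={cfg.seed})")
    truth = pd.DataFrame(truth_rows)
    return SimulatedCohort(cohort, truth, cfg)


def truth_report(sim: SimulatedCohort) -> dict:
    """Summary of the ground truth: median onset indices, shift spread, and
    per-stratum offsets (empty strata are omitted)."""
    t = sim.truth
    report = {
        "n": len(t),
        "shift_sd_empirical": float(t["delta_true"].std(ddof=1)) if len(t) > 1 else 0.0,
        "median_onset_fdi_mci": float(t["onset_fdi_mci"].median()),
        "median_onset_fdi_ad": float(t["onset_fdi_ad"].median()),
        "strata": {},
    }
    for name in sim.config.covariate_effects:
        strata = {}
        for level, group in t.groupby(name):
            if len(group) == 0:
                continue
            strata[str(bool(level))] = {
                "n": int(len(group)),
                "median_onset_fdi_mci": float(group["onset_fdi_mci"].median()),
                "median_onset_fdi_ad": float(group["onset_fdi_ad"].median()),
            }
        if strata:
            report["strata"][name] = strata
    return report


def write_simulation(sim: SimulatedCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write cohort CSV (ingest-compatible), truth CSV and a config echo."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "cohort": out / "cohort.csv",
        "truth": out / "truth.csv",
        "config": out / "simulation_config.json",
    }
    write_cohort(sim.cohort, paths["cohort"])
    truth = sim.truth.copy()
    for col in truth.columns:
        if truth[col].dtype == bool:
            truth[col] = truth[col].astype(int)
    truth.to_csv(paths["truth"], index=False)
    paths["config"].write_text(
        json.dumps(sim.config.to_dict(), indent=2, sort_keys=True) + "\n"
    )
    return paths
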