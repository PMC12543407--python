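"""Population mean CDR-SB trajectory and per-participant time-shift alignment.

The disease timescale (the index) is obtained by shifting each participant's
chronological age by a subject-specific offset delta so that their CDR-SB
trajectory lies on a common population mean curve:

    index = age + delta,        y_ij ~ m(age_ij + delta_i) + noise

with m a monotone three-parameter logistic

    m(t) = C / (1 + exp(-k (t - t0)))

whose ceiling C is fixed at the score maximum (18 for CDR-SB). The curve and
the shifts are estimated jointly by alternating least squares with a small
ridge penalty on the shifts, and the shift distribution is anchored at zero
mean so the index remains age-like.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .cohort import Cohort, ParticipantSeries, CDRSB_MAX, MMSE_MAX, MCI_CUT, AD_CUT


class NoRisingSignalError(ValueError):
    """The binned data carry no rising trend to fit a growth curve to."""


class CurveFitError(RuntimeError):
    """Nonlinear least squares failed to converge; carries last iterate."""

    def __init__(self, message: str, last_params=None, diagnostics=None):
        super().__init__(message)
        self.last_params = last_params
        self.diagnostics = diagnostics


@dataclass
class MeanTrajectory:
    """Monotone logistic mean curve mapping the disease index to expected score.

    Parameters
    ----------
    ceiling : float
        Upper asymptote C; fixed at the score maximum by default.
    rate : float
        Growth rate k (1/years), > 0.
    midpoint : float
        Index value t0 at which the curve reaches C/2.
    fit_domain : tuple
        Index range the curve was fitted on; evaluation outside it is
        extrapolation.
    """

    family: str = "logistic"
    ceiling: float = CDRSB_MAX
    rate: float = 0.41
    midpoint: float = 87.7
    fit_domain: tuple[float, float] = (60.0, 100.0)
    residual_sd: float | None = None
    n_points: int | None = None

    def __post_init__(self) -> None:
        if self.family != "logistic":
            raise ValueError(f"unknown curve family {self.family!r}")
        if self.rate <= 0:
            raise ValueError("rate must be > 0")
        if self.ceiling <= 0:
            raise ValueError("ceiling must be > 0")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = self.ceiling / (1.0 + np.exp(-self.rate * (t - self.midpoint)))
        return out if out.ndim else float(out)

    def inverse(self, y: float) -> float:
        """Index value at which the curve equals ``y`` (0 < y < ceiling)."""
        if not 0.0 < y < self.ceiling:
            raise ValueError(f"y must lie strictly inside (0, {self.ceiling:g})")
        return self.midpoint - np.log(self.ceiling / y - 1.0) / self.rate


def calibrated_curve(
    anchors: tuple[tuple[float, float], tuple[float, float]] = ((79.0, MCI_CUT), (85.0, AD_CUT)),
    ceiling: float = CDRSB_MAX,
) -> MeanTrajectory:
    """Logistic curve passing exactly through two (index, score) anchor points.

    The default anchors place the MCI staging cut (0.5) at index 79 and the AD
    cut (4.5) at index 85 — the published onset thresholds — giving
    k = ln(35/3)/6 ~= 0.4095 and t0 ~= 87.68.
    """
    (t1, y1), (t2, y2) = anchors
    if t1 == t2:
        raise ValueError("anchor index values must differ")
    a1 = np.log(ceiling / y1 - 1.0)
    a2 = np.log(ceiling / y2 - 1.0)
    rate = (a1 - a2) / (t2 - t1)
    if rate <= 0:
        raise ValueError("anchors must define a rising curve")
    midpoint = t1 + a1 / rate
    return MeanTrajectory(ceiling=ceiling, rate=float(rate), midpoint=float(midpoint))


def eval_curve(curve: MeanTrajectory, t, warn_extrapolation: bool = True):
    """Expected score at index ``t``; warns when outside the fit domain."""
    t_arr = np.asarray(t, dtype=float)
    lo, hi = curve.fit_domain
    if warn_extrapolation and (np.any(t_arr < lo) or np.any(t_arr > hi)):
        warnings.warn(
            f"evaluating curve outside fit domain [{lo:g}, {hi:g}]", stacklevel=2
        )
    return curve(t)


@dataclass
class AlignmentConfig:
    """Tunable parameters of the alignment estimator.

    ``score`` selects the input scale: ``cdr_sb`` uses the score as-is;
    ``mmse`` runs 30 - MMSE through the same machinery (ceiling 30). MMSE
    staging cuts are not packaged and must be supplied by the caller.
    """

    curve_family: str = "logistic"
    fix_ceiling: bool = True
    ceiling: float = CDRSB_MAX
    shift_bounds: tuple[float, float] = (-30.0, 30.0)
    ridge: float = 1e-3
    grid_step: float = 0.25
    refine_tol: float = 1e-3
    max_iter: int = 100
    shift_tol: float = 0.01
    curve_rtol: float = 1e-4
    bin_range: tuple[float, float] = (60.0, 100.0)
    bin_width: float = 1.0
    score: str = "cdr_sb"

    def __post_init__(self) -> None:
        if self.score not in ("cdr_sb", "mmse"):
            raise ValueError("score must be 'cdr_sb' or 'mmse'")
        if self.score == "mmse" and self.ceiling == CDRSB_MAX:
            self.ceiling = MMSE_MAX
        if self.shift_bounds[0] >= self.shift_bounds[1]:
            raise ValueError("invalid shift bounds")
        if self.ridge < 0:
            raise ValueError("ridge must be >= 0")


def _series_scores(series: ParticipantSeries, score: str = "cdr_sb") -> tuple[np.ndarray, np.ndarray]:
    """(ages, oriented scores) for the visits usable under the chosen scale."""
    if score == "cdr_sb":
        return series.ages, series.scores
    ages, vals = [], []
    for v in series.visits:
        if v.mmse is not None:
            ages.append(v.age)
            vals.append(MMSE_MAX - v.mmse)
    return np.array(ages, dtype=float), np.array(vals, dtype=float)


@dataclass
class AlignmentResult:
    """Estimated time shift for one participant (index = age + shift)."""

    participant_id: str
    shift: float
    sse: float
    identifiable: bool
    n_visits_used: int


@dataclass
class Convergence:
    iterations: int
    final_max_shift_change: float
    converged: bool
    objective_history: list[float] = field(default_factory=list)


@dataclass
class AlignmentModel:
    """Fitted mean curve plus the per-participant shifts."""

    curve: MeanTrajectory
    shifts: list[AlignmentResult]
    ridge: float
    convergence: Convergence

    def shift_of(self, participant_id: str) -> AlignmentResult:
        try:
            return self._index[participant_id]
        except AttributeError:
            self._index = {r.participant_id: r for r in self.shifts}
            return self._index[participant_id]

    def shift_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant_id": [r.participant_id for r in self.shifts],
                "shift": [r.shift for r in self.shifts],
                "sse": [r.sse for r in self.shifts],
                "identifiable": [r.identifiable for r in self.shifts],
                "n_visits_used": [r.n_visits_used for r in self.shifts],
            }
        )


def bin_mean_trajectory(
    cohort: Cohort,
    age_range: tuple[float, float] = (60.0, 100.0),
    width: float = 1.0,
    score: str = "cdr_sb",
) -> pd.DataFrame:
    """Mean observed score per age bin across the whole cohort.

    Bins are left-closed intervals [a, a+width) covering ``age_range`` (the
    right edge is included in the last bin). Bins with no observations are kept
    with ``n = 0`` and a missing mean — they are absent data, not zeros.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    lo, hi = age_range
    edges = np.arange(lo, hi + width / 2, width)
    ages, vals = [], []
    for s in cohort:
        a, y = _series_scores(s, score)
        ages.append(a)
        vals.append(y)
    ages = np.concatenate(ages) if ages else np.array([])
    vals = np.concatenate(vals) if vals else np.array([])
    inside = (ages >= lo) & (ages <= hi)
    if not inside.any():
        warnings.warn(
            f"no visits fall inside the age range [{lo:g}, {hi:g}]", stacklevel=2
        )
    ages, vals = ages[inside], vals[inside]
    idx = np.minimum(((ages - lo) / width).astype(int), len(edges) - 2)
    n = np.zeros(len(edges) - 1, dtype=int)
    total = np.zeros(len(edges) - 1, dtype=float)
    np.add.at(n, idx, 1)
    np.add.at(total, idx, vals)
    with np.errstate(invalid="ignore"):
        mean = np.where(n > 0, total / np.maximum(n, 1), np.nan)
    return pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "age": edges[:-1] + width / 2,
            "mean_score": mean,
            "n": n,
        }
    )


def _fit_logistic(
    t: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    fix_ceiling: bool = True,
    ceiling: float = CDRSB_MAX,
    init: tuple | None = None,
) -> tuple[float, float, float, float]:
    """Weighted least-squares logistic fit; returns (C, k, t0, residual_sd)."""
    sw = np.sqrt(w)

    if y.max() - y.min() < 1e-8:
        raise NoRisingSignalError("no rising signal: scores are constant")

    if init is None:
        half = (y.min() + y.max()) / 2 if not fix_ceiling else ceiling / 2
        above = y >= half
        t0_guess = float(t[above][0]) if above.any() else float(t.max() + 5.0)
        k_guess = 0.3
        c_guess = ceiling
    else:
        c_guess, k_guess, t0_guess = init

    if fix_ceiling:
        def resid(p):
            k, t0 = p
            return sw * (y - ceiling / (1.0 + np.exp(-k * (t - t0))))

        x0 = np.array([k_guess, t0_guess])
        lower = np.array([1e-4, t.min() - 60.0])
        upper = np.array([10.0, t.max() + 60.0])
    else:
        def resid(p):
            c, k, t0 = p
            return sw * (y - c / (1.0 + np.exp(-k * (t - t0))))

        x0 = np.array([min(c_guess, ceiling), k_guess, t0_guess])
        lower = np.array([1e-3, 1e-4, t.min() - 60.0])
        upper = np.array([ceiling, 10.0, t.max() + 60.0])

    sol = optimize.least_squares(resid, x0, bounds=(lower, upper), method="trf")
    if not sol.success:
        raise CurveFitError(
            f"logistic fit did not converge: {sol.message}",
            last_params=sol.x,
            diagnostics={"cost": sol.cost, "status": sol.status},
        )
    if fix_ceiling:
        c, (k, t0) = ceiling, sol.x
    else:
        c, k, t0 = sol.x
    dof = max(len(y) - len(sol.x), 1)
    residual_sd = float(np.sqrt(2 * sol.cost / dof))
    return float(c), float(k), float(t0), residual_sd


def fit_mean_curve(
    binned: pd.DataFrame,
    fix_ceiling: bool = True,
    ceiling: float = CDRSB_MAX,
    fit_domain: tuple[float, float] | None = None,
) -> MeanTrajectory:
    """Fit the logistic mean curve to a binned trajectory table.

    Weighted least squares with weights equal to the per-bin observation
    counts; bins with no observations are ignored. With ``fix_ceiling`` the
    asymptote is pinned to the score maximum and only (k, t0) are estimated.
    """
    usable = binned[(binned["n"] > 0) & binned["mean_score"].notna()]
    if len(usable) < 3:
        raise ValueError("need at least 3 non-empty bins to fit the mean curve")
    t = usable["age"].to_numpy(dtype=float)
    y = usable["mean_score"].to_numpy(dtype=float)
    w = usable["n"].to_numpy(dtype=float)
    c, k, t0, rsd = _fit_logistic(t, y, w, fix_ceiling=fix_ceiling, ceiling=ceiling)
    domain = fit_domain or (float(t.min()), float(t.max()))
    return MeanTrajectory(
        ceiling=c, rate=k, midpoint=t0, fit_domain=domain,
        residual_sd=rsd, n_points=int(w.sum()),
    )


#: Near-minimum plateau wider than this (years) marks a shift unidentifiable:
#: identifiable means the trajectory pins the shift to sub-year precision.
_PLATEAU_SPAN = 1.0


def align_participant(
    series: ParticipantSeries,
    curve: MeanTrajectory,
    bounds: tuple[float, float] = (-30.0, 30.0),
    ridge: float = 1e-3,
    grid_step: float = 0.25,
    refine_tol: float = 1e-3,
    score: str = "cdr_sb",
) -> AlignmentResult:
    """Estimate the time shift placing one participant on the mean curve.

    Minimizes sum_j (y_j - m(age_j + delta))^2 + ridge * delta^2 over the
    bounded shift range by a coarse grid search (``grid_step`` resolution)
    followed by bounded scalar refinement around the grid optimum.

    A shift is flagged unidentifiable when the unpenalized objective is flat
    over the whole grid, or when the near-minimum set of shifts spans more
    than a year (a flat trajectory constrains only a half-line of shifts,
    not a point). "Near-minimum" is scaled to the residual noise level:
    within 4 * sse_min / (n - 1), roughly a 2-sigma move of one residual.
    """
    ages, y = _series_scores(series, score)
    if len(ages) < 2:
        raise ValueError(
            f"{series.participant_id}: need >= 2 scored visits to align"
        )
    lo, hi = bounds
    deltas = np.arange(lo, hi + grid_step / 2, grid_step)
    pred = curve(ages[None, :] + deltas[:, None])
    sse = ((y[None, :] - pred) ** 2).sum(axis=1)
    obj = sse + ridge * deltas**2

    sse_min = float(sse.min())
    sse_range = float(sse.max() - sse_min)
    plateau_tol = max(1e-6, 4.0 * sse_min / max(len(ages) - 1, 1))
    plateau = deltas[sse <= sse_min + plateau_tol]
    plateau_span = float(plateau.max() - plateau.min()) if len(plateau) else 0.0
    identifiable = sse_range >= 1e-6 and plateau_span <= _PLATEAU_SPAN

    i = int(np.argmin(obj))
    bracket = (max(lo, deltas[i] - grid_step), min(hi, deltas[i] + grid_step))

    def penalized(d: float) -> float:
        m = curve(ages + d)
        return float(((y - m) ** 2).sum() + ridge * d * d)

    res = optimize.minimize_scalar(
        penalized, bounds=bracket, method="bounded",
        options={"xatol": refine_tol},
    )
    delta = float(res.x) if res.fun <= obj[i] else float(deltas[i])
    final_sse = float(((y - curve(ages + delta)) ** 2).sum())
    return AlignmentResult(
        participant_id=series.participant_id,
        shift=delta,
        sse=final_sse,
        identifiable=identifiable,
        n_visits_used=len(ages),
    )


def to_fdi(series: ParticipantSeries, shift: float):
    """Visits with their index values (age + shift); spacing is preserved."""
    if not np.isfinite(shift):
        raise ValueError("shift must be finite")
    return [(v, v.age + shift) for v in series.visits]


def fit_alignment_model(
    cohort: Cohort,
    config: AlignmentConfig | None = None,
) -> AlignmentModel:
    """Jointly estimate the mean curve and all per-participant shifts.

    Alternating least squares: starting from zero shifts, iterate (i) fit the
    logistic curve to the pooled shifted points, (ii) re-estimate every shift
    against the current curve. Stops when the largest shift update and the
    relative curve-parameter change both fall below tolerance; a model that
    exhausts ``max_iter`` is returned with ``converged=False`` and a warning.

    The time origin of the index scale (curve midpoint vs shift mean) is not
    identified by the data alone; it is pinned by the ridge penalty, which
    shrinks every shift toward zero exactly as Gaussian random-effect
    shrinkage anchors subject effects at zero mean. A hard re-centering of
    the shifts was deliberately not applied: which participants have
    identifiable shifts is itself informative (progressors shift late), so
    re-centering on them drags the scale away from chronological age.
    """
    cfg = config or AlignmentConfig()
    usable: list[ParticipantSeries] = []
    data: list[tuple[np.ndarray, np.ndarray]] = []
    for s in cohort:
        ages, y = _series_scores(s, cfg.score)
        if len(ages) >= 2:
            usable.append(s)
            data.append((ages, y))
    if not usable:
        raise ValueError("no participant has >= 2 scored visits")

    n_visits = np.array([len(a) for a, _ in data], dtype=float)
    deltas = np.zeros(len(usable))
    pooled_y = np.concatenate([y for _, y in data])
    rep = np.repeat(np.arange(len(usable)), n_visits.astype(int))
    pooled_ages = np.concatenate([a for a, _ in data])
    weights = np.ones_like(pooled_y)

    params: tuple | None = None
    results: list[AlignmentResult] = []
    history: list[float] = []
    converged = False
    max_dd = np.inf
    it = 0
    for it in range(1, cfg.max_iter + 1):
        t_pooled = pooled_ages + deltas[rep]
        c, k, t0, rsd = _fit_logistic(
            t_pooled, pooled_y, weights,
            fix_ceiling=cfg.fix_ceiling, ceiling=cfg.ceiling, init=params,
        )
        curve = MeanTrajectory(
            ceiling=c, rate=k, midpoint=t0, fit_domain=cfg.bin_range,
            residual_sd=rsd, n_points=len(pooled_y),
        )

        results = [
            align_participant(
                s, curve, bounds=cfg.shift_bounds, ridge=cfg.ridge,
                grid_step=cfg.grid_step, refine_tol=cfg.refine_tol,
                score=cfg.score,
            )
            for s in usable
        ]
        new_deltas = np.array([r.shift for r in results])
        max_dd = float(np.max(np.abs(new_deltas - deltas)))
        if params is not None:
            prev_c, prev_k, prev_t0 = params
            rel = max(
                abs(k - prev_k) / max(abs(prev_k), 1e-12),
                abs(t0 - prev_t0) / max(abs(prev_t0), 1.0),
                abs(c - prev_c) / max(abs(prev_c), 1e-12),
            )
        else:
            rel = np.inf
        deltas = new_deltas
        params = (c, k, t0)

        total_obj = float(
            sum(r.sse for r in results) + cfg.ridge * float((deltas**2).sum())
        )
        history.append(total_obj)

        if max_dd < cfg.shift_tol and rel < cfg.curve_rtol:
            converged = True
            break

    if not converged:
        warnings.warn(
            f"alignment did not converge in {cfg.max_iter} iterations "
            f"(max shift change {max_dd:.4g})",
            stacklevel=2,
        )

    final_curve = MeanTrajectory(
        ceiling=params[0], rate=params[1], midpoint=params[2],
        fit_domain=cfg.bin_range,
        residual_sd=curve.residual_sd, n_points=len(pooled_y),
    )
    return AlignmentModel(
        curve=final_curve,
        shifts=results,
        ridge=cfg.ridge,
        convergence=Convergence(
            iterations=it,
            final_max_shift_change=max_dd,
            converged=converged,
            objective_history=history,
        ),
    )
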