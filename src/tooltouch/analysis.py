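"""Behavioral analysis: normalization, accuracy regression, variance-law fits, BIC.

The pipeline mirrors the study's data analysis.  Raw responses are first
normalized into percent of tool space (image task: proportion of the 20-cm
drawing; space task: proportion of the participant's judged tip).  Mean
judgments are regressed on true location per participant to assess accuracy
(slopes near 1, intercepts near 0).  Trial-to-trial SDs per location — the
*variable errors*, pooled over tasks after removing each task's own mean —
are then fit by two competing three-parameter models:

* trilateration — the distance-noise fusion law sigma_INT(L) of
  :mod:`tooltouch.trilateration`;
* boundary truncation — judgments from a location-independent Gaussian
  truncated at bounds gamma1 < gamma2, whose SD dips near the bounds.

Models are compared per participant with the Bayesian Information Criterion
in its Gaussian-residual form BIC = n ln(RSS/n) + k ln(n); dBIC cutoffs of
2 and 6 mark moderate and strong evidence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares
from scipy.stats import truncnorm

from .behavior import ParticipantParams, StudyDesign
from .trilateration import SurfaceFrame, TrilaterationParams, predicted_sd_curve

__all__ = [
    "TruncationParams",
    "ModelFit",
    "ComparisonResult",
    "RegressionResult",
    "normalize_image_task",
    "normalize_space_task",
    "normalize_trials",
    "summarize_localization",
    "fit_accuracy_regression",
    "fit_trilateration",
    "truncated_sd",
    "fit_truncation",
    "compare_bic",
    "fit_cohort",
]

#: Truncation-model fitting bounds (% of rod surface).
TRUNCATION_BOUNDS = {"sigma_t": (1.0, 40.0), "gamma1": (-30.0, 30.0), "gamma2": (70.0, 130.0)}

#: dBIC evidence cutoffs: below 2 weak, 2–6 moderate, above 6 strong.
DBIC_MODERATE = 2.0
DBIC_STRONG = 6.0


# ---------------------------------------------------------------------------
# Normalization into % tool space
# ---------------------------------------------------------------------------


def normalize_image_task(raw_px, pixels_per_cm: float, drawing_length_cm: float = 20.0):
    """Convert an image-task pixel response into % tool space.

    The drawing spans the full rod (handle to tip), so the proportion of the
    drawing equals the proportion of tool space.  Off-drawing responses are
    clamped to [0, 100] with a warning.
    """
    if pixels_per_cm <= 0 or drawing_length_cm <= 0:
        raise ValueError("drawing geometry must be positive")
    pct = np.asarray(raw_px, dtype=float) / pixels_per_cm / drawing_length_cm * 100.0
    if np.any(pct < 0) or np.any(pct > 100):
        warnings.warn("image-task response off the drawing; clamped to [0, 100]")
        pct = np.clip(pct, 0.0, 100.0)
    return pct


def normalize_space_task(raw_cm, judged_tip_cm: float):
    """Convert a space-task cm response into % tool space.

    The participant's own judged tip position anchors 100% of tool space.
    """
    if judged_tip_cm <= 0:
        raise ValueError("judged tip must be positive")
    return np.asarray(raw_cm, dtype=float) / judged_tip_cm * 100.0


def normalize_trials(
    trials: pd.DataFrame, participants: Sequence[ParticipantParams], design: StudyDesign = StudyDesign()
) -> pd.DataFrame:
    """Normalize a raw trials table into % tool space.

    Returns a frame with columns participant, task, location (% space),
    judgment (% space).
    """
    by_id = {p.participant: p for p in participants}
    out = trials.copy()
    judgment = np.empty(len(out))
    for task, sub in out.groupby("task"):
        idx = sub.index
        if task == "image":
            for pid, ssub in sub.groupby("participant"):
                judgment[out.index.get_indexer(ssub.index)] = normalize_image_task(
                    ssub["raw_response"].to_numpy(), by_id[pid].pixels_per_cm, design.drawing_length_cm
                )
        elif task == "space":
            for pid, ssub in sub.groupby("participant"):
                judgment[out.index.get_indexer(ssub.index)] = normalize_space_task(
                    ssub["raw_response"].to_numpy(), by_id[pid].judged_tip_cm
                )
        else:
            raise ValueError(f"unknown task label {task!r}")
    out["location"] = design.location_pct(out["location_cm"].to_numpy())
    out["judgment"] = judgment
    return out[["participant", "task", "location", "judgment"]]


# ---------------------------------------------------------------------------
# Summaries and accuracy regression
# ---------------------------------------------------------------------------


def summarize_localization(normalized: pd.DataFrame, demean_tasks: bool = True) -> pd.DataFrame:
    """Per participant x location: mean judgment and variable error (tasks collapsed).

    The variable error is the SD of judgments at that location.  With
    ``demean_tasks`` (default) each task's own mean is removed before
    pooling, so a constant between-task offset does not inflate the SD; the
    pooled SD uses n - n_tasks degrees of freedom.  Cells with fewer than
    two trials are dropped with a warning.
    """
    rows = []
    for (pid, loc), cell in normalized.groupby(["participant", "location"]):
        n = len(cell)
        if n < 2:
            warnings.warn(f"dropping singleton cell participant={pid} location={loc}")
            continue
        mean = cell["judgment"].mean()
        if demean_tasks:
            resid = cell["judgment"] - cell.groupby("task")["judgment"].transform("mean")
            k = cell["task"].nunique()
            sd = float(np.sqrt((resid**2).sum() / (n - k)))
        else:
            sd = float(cell["judgment"].std(ddof=1))
        rows.append({"participant": pid, "location": loc, "mean_judgment": mean, "variable_error": sd, "n": n})
    return pd.DataFrame(rows)


@dataclass
class RegressionResult:
    """Per-participant accuracy regressions and group-level 95% CIs."""

    per_participant: pd.DataFrame  # participant, slope, intercept
    slope_mean: float
    slope_ci: tuple
    intercept_mean: float
    intercept_ci: tuple


def fit_accuracy_regression(summaries: pd.DataFrame) -> RegressionResult:
    """OLS of mean judgment on true location, per participant; t-based group CIs."""
    rows = []
    for pid, sub in summaries.groupby("participant"):
        if sub["location"].nunique() < 2:
            raise ValueError(f"participant {pid}: need >= 2 distinct locations for regression")
        res = stats.linregress(sub["location"], sub["mean_judgment"])
        rows.append({"participant": pid, "slope": res.slope, "intercept": res.intercept})
    per = pd.DataFrame(rows)

    def _ci(x):
        m = x.mean()
        if len(x) < 2:
            return m, (m, m)
        sem = x.std(ddof=1) / np.sqrt(len(x))
        t = stats.t.ppf(0.975, len(x) - 1)
        return m, (m - t * sem, m + t * sem)

    sm, sci = _ci(per["slope"])
    im, ici = _ci(per["intercept"])
    return RegressionResult(
        per_participant=per, slope_mean=sm, slope_ci=sci, intercept_mean=im, intercept_ci=ici
    )


# ---------------------------------------------------------------------------
# Variance-law models
# ---------------------------------------------------------------------------


@dataclass
class ModelFit:
    """Result of fitting one variance-law model to a participant's variable errors."""

    model: str
    params: dict
    locations: np.ndarray
    observed_sd: np.ndarray
    predicted_sd: np.ndarray
    rss: float
    r_squared: float
    n_points: int
    converged: bool
    at_bounds: bool
    n_starts: int

    def bic(self, n_points: Optional[int] = None, k: int = 3) -> float:
        n = self.n_points if n_points is None else n_points
        if self.rss <= 0:
            return -np.inf
        return n * np.log(self.rss / n) + k * np.log(n)


def _r_squared(observed: np.ndarray, predicted: np.ndarray) -> float:
    rss = float(np.sum((observed - predicted) ** 2))
    tss = float(np.sum((observed - observed.mean()) ** 2))
    return 1.0 - rss / tss if tss > 0 else (1.0 if rss == 0 else -np.inf)


def _multistart_least_squares(residual_fn, bounds_lo, bounds_hi, starts):
    best = None
    n_ok = 0
    for x0 in starts:
        try:
            sol = least_squares(residual_fn, x0, bounds=(bounds_lo, bounds_hi), method="trf")
        except Exception:
            continue
        if not np.all(np.isfinite(sol.x)):
            continue
        n_ok += 1
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("all optimizer starts failed")
    return best, n_ok


def fit_trilateration(
    summary: pd.DataFrame,
    n_starts: int = 10,
    seed: int = 0,
    frame: SurfaceFrame = SurfaceFrame(),
) -> ModelFit:
    """Fit the three trilateration parameters to one participant's SD profile.

    Bounded (non-negative) least squares on SDs with ``n_starts`` seeded
    random starts; the best-RSS solution wins.  Requires >= 4 locations.
    """
    locs = summary["location"].to_numpy(dtype=float)
    obs = summary["variable_error"].to_numpy(dtype=float)
    if len(locs) < 4:
        raise ValueError("need >= 4 locations to fit 3 parameters")
    rng = np.random.default_rng(seed)
    lo = np.array([0.0, 0.0, 0.0])
    hi = np.array([1.0, 50.0, 50.0])

    def resid(x):
        p = TrilaterationParams(sigma_hat=x[0], eps1=x[1], eps2=x[2])
        return predicted_sd_curve(p, locs, frame) - obs

    starts = [np.array([0.05, 1.0, 1.0])] + [
        np.array([rng.uniform(0.005, 0.3), rng.uniform(0.1, 10.0), rng.uniform(0.1, 10.0)])
        for _ in range(n_starts - 1)
    ]
    best, n_ok = _multistart_least_squares(resid, lo, hi, starts)
    params = TrilaterationParams(sigma_hat=best.x[0], eps1=best.x[1], eps2=best.x[2])
    pred = predicted_sd_curve(params, locs, frame)
    return ModelFit(
        model="trilateration",
        params={"sigma_hat": params.sigma_hat, "eps1": params.eps1, "eps2": params.eps2},
        locations=locs,
        observed_sd=obs,
        predicted_sd=pred,
        rss=float(np.sum((pred - obs) ** 2)),
        r_squared=_r_squared(obs, pred),
        n_points=len(locs),
        converged=n_ok > 0,
        at_bounds=bool(best.x[0] < 1e-6),  # sigma_hat degenerate at 0 -> flat profile
        n_starts=n_ok,
    )


@dataclass(frozen=True)
class TruncationParams:
    """Boundary-truncation model parameters (% of rod surface)."""

    sigma_t: float
    gamma1: float
    gamma2: float

    def __post_init__(self):
        if not self.gamma2 > self.gamma1:
            raise ValueError("gamma2 must exceed gamma1")


def truncated_sd(params: TruncationParams, L) -> np.ndarray:
    """SD of Normal(L, sigma_t^2) truncated to [gamma1, gamma2] (closed form)."""
    L = np.asarray(L, dtype=float)
    a = (params.gamma1 - L) / params.sigma_t
    b = (params.gamma2 - L) / params.sigma_t
    out = truncnorm.std(a, b, loc=L, scale=params.sigma_t)
    return float(out) if out.ndim == 0 else out


def fit_truncation(summary: pd.DataFrame, n_starts: int = 10, seed: int = 0) -> ModelFit:
    """Fit the boundary-truncation model to one participant's SD profile.

    Same multistart bounded least squares as :func:`fit_trilateration`,
    with the study's parameter bounds (sigma_t in [1, 40], gamma1 in
    [-30, 30], gamma2 in [70, 130]).
    """
    locs = summary["location"].to_numpy(dtype=float)
    obs = summary["variable_error"].to_numpy(dtype=float)
    if len(locs) < 4:
        raise ValueError("need >= 4 locations to fit 3 parameters")
    rng = np.random.default_rng(seed)
    (slo, shi) = TRUNCATION_BOUNDS["sigma_t"]
    (g1lo, g1hi) = TRUNCATION_BOUNDS["gamma1"]
    (g2lo, g2hi) = TRUNCATION_BOUNDS["gamma2"]
    lo = np.array([slo, g1lo, g2lo])
    hi = np.array([shi, g1hi, g2hi])

    def resid(x):
        return truncated_sd(TruncationParams(*x), locs) - obs

    starts = [np.array([10.0, 0.0, 100.0])] + [
        np.array([rng.uniform(slo, shi), rng.uniform(g1lo, g1hi), rng.uniform(g2lo, g2hi)])
        for _ in range(n_starts - 1)
    ]
    best, n_ok = _multistart_least_squares(resid, lo, hi, starts)
    params = TruncationParams(*best.x)
    pred = truncated_sd(params, locs)
    eps = 1e-6
    at_bounds = bool(np.any(best.x <= lo + eps) or np.any(best.x >= hi - eps))
    return ModelFit(
        model="truncation",
        params={"sigma_t": params.sigma_t, "gamma1": params.gamma1, "gamma2": params.gamma2},
        locations=locs,
        observed_sd=obs,
        predicted_sd=pred,
        rss=float(np.sum((pred - obs) ** 2)),
        r_squared=_r_squared(obs, pred),
        n_points=len(locs),
        converged=n_ok > 0,
        at_bounds=at_bounds,
        n_starts=n_ok,
    )


# ---------------------------------------------------------------------------
# Model comparison
# ---------------------------------------------------------------------------


@dataclass
class ComparisonResult:
    """dBIC = BIC(truncation) - BIC(trilateration); positive favors trilateration."""

    bic_trilateration: float
    bic_truncation: float
    delta_bic: float
    evidence: str  # weak | moderate | strong (for whichever model wins)
    winner: str  # trilateration | truncation | tie
    degenerate: bool = False


def compare_bic(fit_tri: ModelFit, fit_trunc: ModelFit, n_points: Optional[int] = None) -> ComparisonResult:
    """BIC comparison of the two variance-law fits on identical data."""
    if fit_tri.n_points != fit_trunc.n_points:
        raise ValueError("fits must be on identical data")
    n = fit_tri.n_points if n_points is None else n_points
    b_tri = fit_tri.bic(n)
    b_trunc = fit_trunc.bic(n)
    degenerate = not (np.isfinite(b_tri) and np.isfinite(b_trunc))
    d = b_trunc - b_tri
    mag = abs(d)
    evidence = "weak" if mag < DBIC_MODERATE else ("moderate" if mag < DBIC_STRONG else "strong")
    winner = "trilateration" if d > 0 else ("truncation" if d < 0 else "tie")
    return ComparisonResult(
        bic_trilateration=b_tri,
        bic_truncation=b_trunc,
        delta_bic=d,
        evidence=evidence,
        winner=winner,
        degenerate=degenerate,
    )


def fit_cohort(
    normalized: pd.DataFrame,
    n_starts: int = 10,
    seed: int = 0,
    demean_tasks: bool = True,
    n_points: Optional[int] = None,
) -> pd.DataFrame:
    """Fit both models and compare per participant; returns the cohort table.

    Columns: participant, R2_tri, R2_trunc, BIC_tri, BIC_trunc, dBIC,
    evidence, winner, plus the fitted trilateration parameters.
    """
    summary = summarize_localization(normalized, demean_tasks=demean_tasks)
    rows = []
    for pid, sub in summary.groupby("participant"):
        ft = fit_trilateration(sub, n_starts=n_starts, seed=seed)
        fb = fit_truncation(sub, n_starts=n_starts, seed=seed)
        cmp_ = compare_bic(ft, fb, n_points)
        rows.append(
            {
                "participant": pid,
                "R2_tri": ft.r_squared,
                "R2_trunc": fb.r_squared,
                "BIC_tri": cmp_.bic_trilateration,
                "BIC_trunc": cmp_.bic_truncation,
                "dBIC": cmp_.delta_bic,
                "evidence": cmp_.evidence,
                "winner": cmp_.winner,
                "sigma_hat": ft.params["sigma_hat"],
                "eps1": ft.params["eps1"],
                "eps2": ft.params["eps2"],
            }
        )
    return pd.DataFrame(rows)
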