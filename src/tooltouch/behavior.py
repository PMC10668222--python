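"""Synthetic behavioral data for the tool-localization study design.

Emulates the psychophysics experiment: participants hold a 60-cm rod
(12-cm handle) and localize active contacts at six locations (10–60 cm from
the hand, steps of 10 cm) in two report modalities — an *image* task
(clicking on a 20-cm downsized drawing of the rod, recorded in pixels) and
a *space* task (clicking along a 70-cm screen, recorded in cm, later
normalized by the participant's judged tip position).  Ten trials per
location per task give 120 trials per participant; the analyzed cohort has
38 participants.

Judgment noise lives in percent of tool space, shared by both tasks: under
the trilateration generative model the judgment is Normal(L, sigma_INT(L)^2)
with the distance-noise law of :mod:`tooltouch.trilateration`; under the
boundary-truncation alternative it is a truncated normal with
location-independent base SD.  The two generators feed the model-selection
validation in :mod:`tooltouch.analysis`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .trilateration import SurfaceFrame, TrilaterationParams, predicted_sd_curve

__all__ = [
    "StudyDesign",
    "ParticipantParams",
    "ParticipantPriors",
    "TrialRecord",
    "sample_participants",
    "generate_trials",
    "generate_cohort",
]


@dataclass(frozen=True)
class StudyDesign:
    """Fixed geometry and trial counts of the behavioral experiment."""

    n_participants: int = 38
    tasks: tuple = ("image", "space")
    rod_length_cm: float = 60.0
    handle_length_cm: float = 12.0
    locations_cm: tuple = (10.0, 20.0, 30.0, 40.0, 50.0, 60.0)
    trials_per_location_per_task: int = 10
    drawing_length_cm: float = 20.0
    screen_length_cm: float = 70.0

    def __post_init__(self):
        if any(not 0 < L <= self.rod_length_cm for L in self.locations_cm):
            raise ValueError("touch locations must lie in (0, rod_length]")
        if self.trials_per_location_per_task < 1:
            raise ValueError("need at least one trial per location per task")

    def location_pct(self, cm) -> np.ndarray:
        """Convert cm from the hand to percent of tool space (tip = 100)."""
        return np.asarray(cm, dtype=float) / self.rod_length_cm * 100.0

    @property
    def trials_per_participant(self) -> int:
        return len(self.tasks) * len(self.locations_cm) * self.trials_per_location_per_task


@dataclass(frozen=True)
class TruncationGenParams:
    """Generative parameters of the boundary-truncation alternative (% space)."""

    sigma_t: float
    gamma1: float
    gamma2: float

    def __post_init__(self):
        if not self.gamma2 > self.gamma1:
            raise ValueError("gamma2 must exceed gamma1")
        if self.sigma_t <= 0:
            raise ValueError("sigma_t must be positive")


@dataclass(frozen=True)
class ParticipantParams:
    """True generative parameters of one synthetic participant."""

    participant: int
    trilateration: TrilaterationParams
    judged_tip_cm: float = 56.5
    pixels_per_cm: float = 10.0
    generative_model: str = "trilateration"  # or "truncation"
    truncation: Optional[TruncationGenParams] = None
    # optional response miscalibration (judgment% = slope * L% + intercept + noise)
    response_slope: float = 1.0
    response_intercept: float = 0.0

    def __post_init__(self):
        if self.judged_tip_cm <= 0:
            raise ValueError("judged tip must be positive")
        if self.pixels_per_cm <= 0:
            raise ValueError("pixel scale must be positive")
        if self.generative_model not in ("trilateration", "truncation"):
            raise ValueError(f"unknown generative model {self.generative_model!r}")
        if self.generative_model == "truncation" and self.truncation is None:
            raise ValueError("truncation generative model requires truncation parameters")


@dataclass(frozen=True)
class ParticipantPriors:
    """Ranges from which participants' true parameters are drawn.

    Defaults produce variable errors on the 1–6 %-space scale of the
    behavioral data.  The judged tip is Normal(56.5, 1.62 * sqrt(38)) cm —
    the reported cohort mean and the SEM scaled back to a participant-level
    SD — truncated to positive values.
    """

    sigma_hat: tuple = (0.02, 0.10)
    eps: tuple = (0.5, 5.0)
    judged_tip_mean_cm: float = 56.5
    judged_tip_sd_cm: float = 1.62 * np.sqrt(38.0)
    pixels_per_cm: tuple = (10.0, 10.0)
    # truncation-cohort generative ranges (inside the fitting bounds)
    trunc_sigma_t: tuple = (6.0, 12.0)
    trunc_gamma1: tuple = (-5.0, 10.0)
    trunc_gamma2: tuple = (90.0, 110.0)

    def __post_init__(self):
        for r in (self.sigma_hat, self.eps, self.pixels_per_cm):
            if r[1] < r[0]:
                raise ValueError(f"invalid prior range {r}")


def sample_participants(
    design: StudyDesign,
    priors: ParticipantPriors = ParticipantPriors(),
    rng: Optional[np.random.Generator] = None,
    generative_model: str = "trilateration",
) -> list[ParticipantParams]:
    """Draw a reproducible roster of synthetic participants."""
    if rng is None:
        raise ValueError("pass a seeded numpy Generator for reproducibility")
    out = []
    for p in range(design.n_participants):
        tri = TrilaterationParams(
            sigma_hat=rng.uniform(*priors.sigma_hat),
            eps1=rng.uniform(*priors.eps),
            eps2=rng.uniform(*priors.eps),
        )
        # truncated-positive normal for the judged tip
        a = (0.0 - priors.judged_tip_mean_cm) / priors.judged_tip_sd_cm
        tip = truncnorm.rvs(
            a, np.inf, loc=priors.judged_tip_mean_cm, scale=priors.judged_tip_sd_cm, random_state=rng
        )
        trunc = None
        if generative_model == "truncation":
            trunc = TruncationGenParams(
                sigma_t=rng.uniform(*priors.trunc_sigma_t),
                gamma1=rng.uniform(*priors.trunc_gamma1),
                gamma2=rng.uniform(*priors.trunc_gamma2),
            )
        out.append(
            ParticipantParams(
                participant=p,
                trilateration=tri,
                judged_tip_cm=float(tip),
                pixels_per_cm=rng.uniform(*priors.pixels_per_cm),
                generative_model=generative_model,
                truncation=trunc,
            )
        )
    return out


@dataclass(frozen=True)
class TrialRecord:
    """One raw behavioral trial, in task-native units."""

    participant: int
    task: str
    true_location_cm: float
    trial: int
    raw_response: float
    response_units: str  # "px" (image task) | "cm" (space task)


def _sample_judgments_pct(
    participant: ParticipantParams, loc_pct: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw judgment positions in % tool space under the participant's generative law."""
    if participant.generative_model == "trilateration":
        sd = predicted_sd_curve(participant.trilateration, loc_pct, SurfaceFrame())
        mean = participant.response_slope * loc_pct + participant.response_intercept
        return rng.normal(mean, sd)
    t = participant.truncation
    mean = participant.response_slope * loc_pct + participant.response_intercept
    a = (t.gamma1 - mean) / t.sigma_t
    b = (t.gamma2 - mean) / t.sigma_t
    return truncnorm.rvs(a, b, loc=mean, scale=t.sigma_t, random_state=rng)


def _to_task_units(judgment_pct: np.ndarray, task: str, design: StudyDesign, p: ParticipantParams) -> np.ndarray:
    if task == "image":
        # position along the 20-cm drawing, recorded in pixels
        return judgment_pct / 100.0 * design.drawing_length_cm * p.pixels_per_cm
    if task == "space":
        # position along the screen in cm; the participant's own judged tip
        # anchors 100% of tool space
        return judgment_pct / 100.0 * p.judged_tip_cm
    raise ValueError(f"unknown task {task!r}")


def generate_trials(
    design: StudyDesign, participant: ParticipantParams, rng: np.random.Generator
) -> list[TrialRecord]:
    """All trials of one participant (task x location x trial).

    The judgment is drawn in % tool space (one generative law shared across
    tasks) and mapped into the task's native response units.
    """
    records = []
    for task in design.tasks:
        units = "px" if task == "image" else "cm"
        for loc_cm in design.locations_cm:
            loc_pct = design.location_pct(loc_cm)
            n = design.trials_per_location_per_task
            judg = _sample_judgments_pct(participant, np.full(n, loc_pct), rng)
            raw = _to_task_units(judg, task, design, participant)
            for t in range(n):
                records.append(
                    TrialRecord(
                        participant=participant.participant,
                        task=task,
                        true_location_cm=float(loc_cm),
                        trial=t,
                        raw_response=float(raw[t]),
                        response_units=units,
                    )
                )
    return records


def generate_cohort(
    design: StudyDesign = StudyDesign(),
    priors: ParticipantPriors = ParticipantPriors(),
    seed: Optional[int] = None,
    generative_model: str = "trilateration",
) -> tuple[pd.DataFrame, list[ParticipantParams]]:
    """Full synthetic cohort as a trials DataFrame plus the true parameters.

    Columns: participant, task, location_cm, trial, raw_response,
    response_units — the canonical trials schema of the whole pipeline.
    """
    if seed is None:
        raise ValueError("pass seed= for a reproducible cohort")
    rng = np.random.default_rng(seed)
    roster = sample_participants(design, priors, rng, generative_model=generative_model)
    rows = []
    for p in roster:
        for r in generate_trials(design, p, rng):
            rows.append(
                (r.participant, r.task, r.true_location_cm, r.trial, r.raw_response, r.response_units)
            )
    df = pd.DataFrame(
        rows, columns=["participant", "task", "location_cm", "trial", "raw_response", "response_units"]
    )
    return df, roster
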