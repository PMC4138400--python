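"""Synthetic cohorts of tracking trials and disability surveys.

No subject-level recordings are publicly available for this kind of
assessment, so every pipeline stage is exercised on simulated cohorts whose
statistical structure mirrors the study design: healthy controls tested three
times over ~two months, and surgical patients tested before decompression
surgery and at four post-operative timepoints, with the 3-month visit the one
that enters the pre/post analysis.

Generative model
----------------
Each subject carries a latent impairment ``theta >= 0``.  A trial's response
is the target, delayed by a subject-specific motor delay ``tau``, plus AR(1)
tracking noise:

    response(t_i) = target(t_i - tau) + eps_i,
    eps_i = phi * eps_{i-1} + innov_i,   innov_i ~ N(0, sd_i²),
    sd_i = (sigma0 + sigma1 * theta) * learning_rate ** session_index,

clipped to [0, 120] %MVC.  Impairment raises the innovation scale (worse
tracking); repeated sessions shrink it geometrically (motor learning).
Surgery multiplies a responder's theta by (1 - surgery_effect); a
non-responder's theta grows by (1 + adverse_effect), modelling the group that
declines after surgery.  Perceived disability is coupled to impairment
through a noisy linear index clipped to [0, 1] and discretised onto the
10-item questionnaire.

The default parameters are calibrated so the simulated group means track the
published cohort summary (control first-visit ~8.1 %MVC, control last ~6.2,
patient pre-op ~11.2 with a much larger spread); see docs/methods.md.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import signal as spsig
from scipy import stats as sps

from .exceptions import InvalidParameterError
from .surveys import ODIResponse
from .tracking import (
    RESPONSE_CEILING,
    TargetWaveform,
    TrackingTrial,
    VisitRecord,
    generate_target,
    visit_score,
)

__all__ = [
    "SubjectState",
    "SimulationConfig",
    "CohortDataset",
    "simulate_trial",
    "simulate_odi",
    "apply_intervention",
    "simulate_cohort",
]

CONTROL_VISITS = ("week0", "week2", "week5")
PATIENT_VISITS = ("pre", "post_24h", "post_48h", "post_2wk", "post_3mo")
#: Visits at which the disability survey is administered (analysis timepoints).
PATIENT_ODI_VISITS = ("pre", "post_3mo")


@dataclass(frozen=True)
class SubjectState:
    """Latent ground truth for one simulated subject."""

    subject_id: str
    group: Literal["control", "patient"]
    theta: float
    mvc: float
    learning_rate: float
    motor_delay: float
    responder: Optional[bool] = None
    theta_pre: Optional[float] = None  # set after intervention, patients only

    def __post_init__(self) -> None:
        if self.theta < 0:
            raise InvalidParameterError(f"theta must be >= 0, got {self.theta}")
        if not (0 < self.learning_rate <= 1):
            raise InvalidParameterError(
                f"learning_rate must be in (0, 1], got {self.learning_rate}"
            )
        if self.motor_delay < 0:
            raise InvalidParameterError(f"motor_delay must be >= 0, got {self.motor_delay}")


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the cohort generator; defaults reproduce the study design.

    Cohort sizes default to the study's 18 controls and 11 patients.  The
    noise scale (sigma0, sigma1), the per-group impairment distributions and
    the learning rate are jointly calibrated to the published group means of
    the tracking score (see docs/methods.md for the calibration).
    """

    n_control: int = 18
    n_patient: int = 11
    # impairment theta ~ Normal(mean, sd) truncated at 0, per group
    control_theta_mean: float = 1.0
    control_theta_sd: float = 0.47
    patient_theta_mean: float = 0.0    # half-normal: heterogeneous patient group
    patient_theta_sd: float = 2.4
    # intervention
    surgery_effect: float = 0.25       # fractional theta reduction, responders
    adverse_effect: float = 0.75       # fractional theta increase, non-responders
    responder_fraction: float = 0.64   # 7 of 11 patients functional
    # tracking-noise model, %MVC
    noise_base: float = 4.81           # sigma0
    noise_gain: float = 4.0            # sigma1, per unit theta
    ar_coefficient: float = 0.6        # phi
    learning_rate: float = 0.865       # per-session innovation-SD multiplier
    # subject-level physiology
    motor_delay_mean: float = 0.06     # seconds
    motor_delay_sd: float = 0.02
    mvc_mean: float = 90.0             # lbs
    mvc_sd: float = 20.0
    # disability-survey coupling: latent index = beta0 + beta1*theta + noise
    odi_intercept: float = 0.15
    odi_slope: float = 0.18
    odi_noise_sd: float = 0.08
    # schedules and target
    control_visits: tuple[str, ...] = CONTROL_VISITS
    patient_visits: tuple[str, ...] = PATIENT_VISITS
    patient_odi_visits: tuple[str, ...] = PATIENT_ODI_VISITS
    # learning sessions completed before each visit; motor learning consolidates
    # with spaced practice over calendar time, so the patients' acute
    # in-hospital retests (24/48 h) contribute only fractional increments
    control_sessions: tuple[float, ...] = (0.0, 1.0, 2.0)
    patient_sessions: tuple[float, ...] = (0.0, 0.2, 0.4, 1.2, 2.0)
    trials_per_visit: int = 3
    trial_duration: float = 45.0
    sample_rate: float = 50.0
    target_period: float = 9.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 0 or self.n_patient < 0:
            raise InvalidParameterError("cohort sizes must be >= 0")
        if self.noise_base < 0 or self.noise_gain < 0:
            raise InvalidParameterError("noise parameters must be >= 0")
        if not (-1 < self.ar_coefficient < 1):
            raise InvalidParameterError("ar_coefficient must lie in (-1, 1)")
        if not (0 <= self.responder_fraction <= 1):
            raise InvalidParameterError("responder_fraction must lie in [0, 1]")
        if not (0 < self.learning_rate <= 1):
            raise InvalidParameterError("learning_rate must lie in (0, 1]")
        if len(self.control_sessions) != len(self.control_visits):
            raise InvalidParameterError("control_sessions must align with control_visits")
        if len(self.patient_sessions) != len(self.patient_visits):
            raise InvalidParameterError("patient_sessions must align with patient_visits")
        if any(np.diff(self.control_sessions) < 0) or any(np.diff(self.patient_sessions) < 0):
            raise InvalidParameterError("session schedules must be nondecreasing")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in (
            "control_visits",
            "patient_visits",
            "patient_odi_visits",
            "control_sessions",
            "patient_sessions",
        ):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True, eq=False)
class CohortDataset:
    """A simulated (or loaded) cohort with its latent ground truth.

    ``subjects`` hold the states used for post-intervention visits (patients
    keep their pre-surgery theta in ``theta_pre``).  ``visits`` are scored
    visit records; raw trials are retained in ``trials`` keyed by
    (subject_id, visit_id).
    """

    subjects: tuple[SubjectState, ...]
    visits: tuple[VisitRecord, ...]
    trials: dict[tuple[str, str], tuple[TrackingTrial, ...]]
    odi: tuple[ODIResponse, ...]
    config: Optional[SimulationConfig] = None
    seed: Optional[int] = None

    def subject(self, subject_id: str) -> SubjectState:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)

    def visits_of(self, subject_id: str) -> list[VisitRecord]:
        return [v for v in self.visits if v.subject_id == subject_id]

    def visit(self, subject_id: str, visit_id: str) -> Optional[VisitRecord]:
        for v in self.visits:
            if v.subject_id == subject_id and v.visit_id == visit_id:
                return v
        return None

    def odi_of(self, subject_id: str, visit_id: str) -> Optional[ODIResponse]:
        for r in self.odi:
            if r.subject_id == subject_id and r.visit_id == visit_id:
                return r
        return None


def _truncated_normal(mean: float, sd: float, rng: np.random.Generator) -> float:
    """One draw from Normal(mean, sd) truncated at zero."""
    if sd == 0:
        return max(mean, 0.0)
    a = (0.0 - mean) / sd
    return float(sps.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, random_state=rng))


def simulate_trial(
    state: SubjectState,
    target: TargetWaveform,
    session_index: float,
    rng: np.random.Generator,
    config: SimulationConfig,
    trial_index: int = 0,
    visit_id: str = "",
) -> TrackingTrial:
    """Simulate one tracking trial for a subject at a given session.

    The response is the motor-delayed target plus stationary AR(1) noise
    whose innovation SD is (sigma0 + sigma1·theta)·lambda^session, clipped to
    the physical range [0, 120] %MVC.
    """
    if session_index < 0:
        raise InvalidParameterError("session_index must be >= 0")
    t = target.sample_times
    delayed = target(t - state.motor_delay)
    sd_innov = (config.noise_base + config.noise_gain * state.theta) * (
        state.learning_rate**session_index
    )
    if sd_innov == 0:
        eps = np.zeros_like(t)
    else:
        phi = config.ar_coefficient
        innov = rng.normal(0.0, sd_innov, size=t.size)
        # stationary start so the first samples are not artificially quiet
        eps0 = rng.normal(0.0, sd_innov / np.sqrt(1.0 - phi**2))
        eps, _ = spsig.lfilter([1.0], [1.0, -phi], innov, zi=np.array([phi * eps0]))
    response = np.clip(delayed + eps, 0.0, RESPONSE_CEILING)
    return TrackingTrial(
        sample_times=t,
        target=target.values,
        response=response,
        duration=target.duration,
        subject_id=state.subject_id,
        visit_id=visit_id,
        trial_index=trial_index,
    )


def simulate_odi(
    state: SubjectState,
    rng: np.random.Generator,
    config: SimulationConfig,
    visit_id: str = "",
) -> ODIResponse:
    """Generate a 10-item survey response coupled to latent impairment.

    A latent index clip(beta0 + beta1·theta + noise, 0, 1) is discretised to
    round(50·index) points spread over 10 items (each capped at 5, remainder
    assigned from item 1), so re-scoring the items recovers the index to
    within 1/100.
    """
    latent = config.odi_intercept + config.odi_slope * state.theta
    if config.odi_noise_sd > 0:
        latent += rng.normal(0.0, config.odi_noise_sd)
    latent = float(np.clip(latent, 0.0, 1.0))
    return ODIResponse(
        item_scores=items_from_index(latent),
        subject_id=state.subject_id,
        visit_id=visit_id,
    )


def items_from_index(index: float) -> tuple[int, ...]:
    """Deterministically spread round(50·index) points over 10 items of max 5."""
    if not (0.0 <= index <= 1.0):
        raise InvalidParameterError(f"index must lie in [0, 1], got {index}")
    total = int(round(50 * index))
    q, r = divmod(total, 10)
    return tuple(q + 1 if i < r else q for i in range(10))


def apply_intervention(
    state: SubjectState, rng: np.random.Generator, config: SimulationConfig
) -> SubjectState:
    """Apply the surgical intervention to a patient's latent impairment.

    With probability ``responder_fraction`` the patient responds and theta
    shrinks by ``surgery_effect``; otherwise theta grows by
    ``adverse_effect`` (the declining, nonfunctional phenotype).
    """
    if state.group != "patient":
        raise InvalidParameterError("intervention applies to patients only")
    responder = bool(rng.random() < config.responder_fraction)
    if responder:
        theta_post = state.theta * (1.0 - config.surgery_effect)
    else:
        theta_post = state.theta * (1.0 + config.adverse_effect)
    return dataclasses.replace(
        state, theta=theta_post, theta_pre=state.theta, responder=responder
    )


def _draw_subject(
    subject_id: str,
    group: Literal["control", "patient"],
    rng: np.random.Generator,
    config: SimulationConfig,
) -> SubjectState:
    if group == "control":
        mean, sd = config.control_theta_mean, config.control_theta_sd
    else:
        mean, sd = config.patient_theta_mean, config.patient_theta_sd
    theta = _truncated_normal(mean, sd, rng)
    mvc = _truncated_normal(config.mvc_mean, config.mvc_sd, rng)
    tau = _truncated_normal(config.motor_delay_mean, config.motor_delay_sd, rng)
    return SubjectState(
        subject_id=subject_id,
        group=group,
        theta=theta,
        mvc=mvc,
        learning_rate=config.learning_rate,
        motor_delay=tau,
    )


def simulate_cohort(config: SimulationConfig) -> CohortDataset:
    """Simulate a full cohort: subjects, scheduled visits, trials, surveys.

    Controls complete their visit schedule unchanged; patients are tested
    once pre-operatively, undergo the intervention, and complete the
    post-operative schedule with their post-surgery impairment.  Session
    indices advance across a subject's visits so motor learning accrues at
    every timepoint.  Surveys are attached at the analysis timepoints
    (patient pre and 3-month visits).  Fully reproducible from ``seed``.
    """
    root = np.random.SeedSequence(config.seed)
    n_total = config.n_control + config.n_patient
    streams = [np.random.default_rng(s) for s in root.spawn(n_total)]
    target = generate_target(config.trial_duration, config.sample_rate, config.target_period)

    subjects: list[SubjectState] = []
    visits: list[VisitRecord] = []
    trials: dict[tuple[str, str], tuple[TrackingTrial, ...]] = {}
    odi: list[ODIResponse] = []

    def run_visit(
        state: SubjectState, visit_id: str, session: float, rng: np.random.Generator
    ) -> VisitRecord:
        vtrials = tuple(
            simulate_trial(state, target, session, rng, config, trial_index=k, visit_id=visit_id)
            for k in range(config.trials_per_visit)
        )
        trials[(state.subject_id, visit_id)] = vtrials
        return visit_score(vtrials)

    for i in range(config.n_control):
        rng = streams[i]
        state = _draw_subject(f"C{i + 1:02d}", "control", rng, config)
        subjects.append(state)
        for session, visit_id in zip(config.control_sessions, config.control_visits):
            visits.append(run_visit(state, visit_id, session, rng))

    for i in range(config.n_patient):
        rng = streams[config.n_control + i]
        state = _draw_subject(f"P{i + 1:02d}", "patient", rng, config)
        pre_visit = config.patient_visits[0]
        visits.append(run_visit(state, pre_visit, config.patient_sessions[0], rng))
        if pre_visit in config.patient_odi_visits:
            odi.append(simulate_odi(state, rng, config, visit_id=pre_visit))
        state = apply_intervention(state, rng, config)
        subjects.append(state)
        for session, visit_id in zip(
            config.patient_sessions[1:], config.patient_visits[1:]
        ):
            visits.append(run_visit(state, visit_id, session, rng))
            if visit_id in config.patient_odi_visits:
                odi.append(simulate_odi(state, rng, config, visit_id=visit_id))

    return CohortDataset(
        subjects=tuple(subjects),
        visits=tuple(visits),
        trials=trials,
        odi=tuple(odi),
        config=config,
        seed=config.seed,
    )
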