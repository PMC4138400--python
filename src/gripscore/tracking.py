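"""Sinusoidal force-tracking trials: targets, MAE scoring, spring calibration.

The assessment asks a subject to modulate grip force so that a cursor follows
a sinusoidal target scrolling across the screen.  Force is expressed as a
percentage of the subject's maximum voluntary contraction (MVC), so scores are
comparable across subjects.  A trial is scored by the mean absolute vertical
distance between the target curve and the subject's force trace — the MAE, in
%MVC; lower is better.  The device's resistance is calibrated per subject by
choosing a set of springs whose combined resistance at full grasp lands in a
band of 70–80% of the subject's MVC.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .exceptions import (
    ConsistencyError,
    InvalidDataError,
    InvalidParameterError,
    ShapeMismatchError,
)

__all__ = [
    "TargetWaveform",
    "TrackingTrial",
    "Spring",
    "SpringSet",
    "VisitRecord",
    "DEFAULT_SPRING_CONSTANTS",
    "default_springs",
    "generate_target",
    "mae_score",
    "visit_score",
    "select_springs",
]

#: Spring constants of the five interchangeable springs, lbs/inch.
DEFAULT_SPRING_CONSTANTS: Mapping[str, float] = {
    "S1": 0.38,
    "S2": 0.88,
    "S3": 1.94,
    "S4": 5.10,
    "S5": 10.70,
}

#: Maximum admissible response, %MVC.  The calibration MVC may be exceeded
#: transiently during a trial, so responses up to 120 %MVC are accepted;
#: negative force is physically impossible and rejected.
RESPONSE_CEILING = 120.0


@dataclass(frozen=True, eq=False)
class TargetWaveform:
    """The target curve of a tracking test, sampled on a uniform grid.

    ``values`` are in %MVC and span [0, 100]: the peak of the target equals
    the subject's measured MVC by construction of the test.
    """

    sample_times: np.ndarray
    values: np.ndarray
    period: float
    duration: float

    def __post_init__(self) -> None:
        t = np.asarray(self.sample_times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or t.shape != v.shape or t.size < 2:
            raise ShapeMismatchError("sample_times and values must be equal-length 1-D arrays")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise InvalidDataError("sample_times must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
            raise InvalidDataError("sample_times must be uniformly spaced")
        if v.min() < -1e-9:
            raise InvalidDataError("target values must be non-negative")
        object.__setattr__(self, "sample_times", t)
        object.__setattr__(self, "values", v)

    @property
    def sample_rate(self) -> float:
        return 1.0 / float(self.sample_times[1] - self.sample_times[0])

    def __call__(self, t: np.ndarray) -> np.ndarray:
        """Evaluate the ideal (continuous) target at arbitrary times.

        Times before the start of the trial return the starting value, which
        is what a subject sees before the waveform begins to move.
        """
        t = np.asarray(t, dtype=float)
        tt = np.where(t < self.sample_times[0], self.sample_times[0], t)
        return 50.0 * (1.0 - np.cos(2.0 * np.pi * tt / self.period))


@dataclass(frozen=True, eq=False)
class TrackingTrial:
    """One tracking test: target and response curves on a shared grid."""

    sample_times: np.ndarray
    target: np.ndarray
    response: np.ndarray
    duration: float = 45.0
    subject_id: str = ""
    visit_id: str = ""
    trial_index: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.sample_times, dtype=float)
        tgt = np.asarray(self.target, dtype=float)
        rsp = np.asarray(self.response, dtype=float)
        if not (t.shape == tgt.shape == rsp.shape) or t.ndim != 1:
            raise ShapeMismatchError(
                f"times/target/response shapes differ: {t.shape}, {tgt.shape}, {rsp.shape}"
            )
        if t.size < 2:
            raise InvalidDataError("a trial needs at least 2 samples")
        if np.any(np.diff(t) <= 0):
            raise InvalidDataError("sample_times must be strictly increasing")
        if not np.all(np.isfinite(tgt)):
            raise InvalidDataError("target contains non-finite values")
        if not np.all(np.isfinite(rsp)):
            raise InvalidDataError("response contains non-finite values")
        if rsp.min() < 0:
            raise InvalidDataError("response force cannot be negative")
        if rsp.max() > RESPONSE_CEILING:
            raise InvalidDataError(
                f"response exceeds {RESPONSE_CEILING} %MVC ceiling: {rsp.max():.2f}"
            )
        object.__setattr__(self, "sample_times", t)
        object.__setattr__(self, "target", tgt)
        object.__setattr__(self, "response", rsp)


@dataclass(frozen=True)
class Spring:
    """A calibration spring, identified by its label and constant in lbs/inch."""

    label: str
    constant: float

    def __post_init__(self) -> None:
        if not self.constant > 0:
            raise InvalidParameterError(f"spring constant must be > 0, got {self.constant}")


@dataclass(frozen=True)
class SpringSet:
    """A chosen subset of springs acting in parallel.

    Parallel springs add: ``effective_constant`` is the sum of the member
    constants, and the resistance felt at full grasp is that sum times the
    grip displacement.  ``fraction_of_mvc`` is that resistance divided by the
    subject's MVC; calibration aims for the 70–80% band.
    """

    springs: tuple[Spring, ...]
    effective_constant: float
    resistance_at_full_grip: float
    fraction_of_mvc: float
    in_band: bool

    @property
    def out_of_band(self) -> bool:
        return not self.in_band

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.springs)


@dataclass(frozen=True)
class VisitRecord:
    """Per-visit performance: individual trial MAEs and their mean."""

    subject_id: str
    visit_id: str
    timepoint_label: str
    trial_maes: tuple[float, ...]
    visit_mae: float
    odi_index: float | None = None

    def __post_init__(self) -> None:
        if any(m < 0 for m in self.trial_maes):
            raise InvalidDataError("trial MAEs cannot be negative")
        if self.trial_maes and not np.isclose(self.visit_mae, float(np.mean(self.trial_maes))):
            raise InvalidDataError("visit_mae must equal the mean of trial_maes")


def default_springs() -> list[Spring]:
    """The five springs shipped with the device, stiffest last."""
    return [Spring(label, k) for label, k in DEFAULT_SPRING_CONSTANTS.items()]


def generate_target(
    duration: float = 45.0, sample_rate: float = 50.0, period: float = 9.0
) -> TargetWaveform:
    """Generate the offset-sinusoid target v(t) = 50·(1 − cos(2πt/period)).

    The waveform spans [0, 100] %MVC: grip force cannot be negative, and the
    peak of the target equals the measured MVC.  When ``period`` divides
    ``duration`` the sampled peak is exactly 100 and the trough exactly 0.

    Parameters
    ----------
    duration : float
        Trial length in seconds (45 s per test by default).
    sample_rate : float
        Samples per second of the rendered grid.
    period : float
        Sinusoid period in seconds.
    """
    if duration <= 0 or sample_rate <= 0 or period <= 0:
        raise InvalidParameterError(
            f"duration, sample_rate and period must be positive; got "
            f"{duration}, {sample_rate}, {period}"
        )
    n = int(round(duration * sample_rate))
    t = np.arange(n, dtype=float) / sample_rate
    v = 50.0 * (1.0 - np.cos(2.0 * np.pi * t / period))
    # guard against -0.0 / 100.0000000001 from rounding at the extrema
    v = np.clip(v, 0.0, 100.0)
    return TargetWaveform(sample_times=t, values=v, period=period, duration=duration)


def mae_score(trial: TrackingTrial) -> float:
    """Mean absolute error between response and target, in %MVC.

    The error is the vertical (force-axis) distance at matched times:
    (1/N)·Σ|response_i − target_i|.  Time is externally driven by the
    scrolling display, so no horizontal distance enters.
    """
    # invariants (finiteness, shape) are enforced by TrackingTrial itself
    return float(np.mean(np.abs(trial.response - trial.target)))


def visit_score(trials: Sequence[TrackingTrial]) -> VisitRecord:
    """Aggregate the trials of one visit into a single visit MAE.

    The protocol calls for three tests per visit whose MAEs are averaged; an
    incomplete visit (1 or 2 trials) is still scoreable but triggers a
    warning so downstream reports can note it.
    """
    if not trials:
        raise InvalidParameterError("visit_score requires at least one trial")
    subject_ids = {t.subject_id for t in trials}
    visit_ids = {t.visit_id for t in trials}
    if len(subject_ids) > 1 or len(visit_ids) > 1:
        raise ConsistencyError(
            f"trials span multiple subjects/visits: {subject_ids}, {visit_ids}"
        )
    if len(trials) < 3:
        warnings.warn(
            f"visit {visit_ids or '?'} has only {len(trials)} trial(s); "
            "the protocol expects 3",
            stacklevel=2,
        )
    maes = tuple(mae_score(t) for t in trials)
    first = trials[0]
    return VisitRecord(
        subject_id=first.subject_id,
        visit_id=first.visit_id,
        timepoint_label=first.visit_id,
        trial_maes=maes,
        visit_mae=float(np.mean(maes)),
    )


def select_springs(
    mvc: float,
    grip_displacement: float = 1.0,
    springs: Iterable[Spring] | None = None,
    subset_size: int = 3,
    band: tuple[float, float] = (0.70, 0.80),
) -> SpringSet:
    """Choose the spring subset calibrating resistance to 70–80% of MVC.

    All subsets of ``subset_size`` springs are enumerated.  Each subset's
    resistance at full grasp is (Σ constants)·displacement and its MVC
    fraction is resistance/MVC.  Among subsets inside ``band`` the one
    closest to the band midpoint wins; if none lands in band, the subset
    minimising the distance to the midpoint is returned flagged
    ``out_of_band``.  Ties break toward the stiffer set so the choice is
    deterministic.

    Parameters
    ----------
    mvc : float
        Subject's maximum voluntary contraction, lbs.
    grip_displacement : float
        Handle travel at full grasp, inches.  Only the product
        constant×displacement matters for the band rule.
    """
    if mvc <= 0:
        raise InvalidParameterError(f"mvc must be positive, got {mvc}")
    if grip_displacement <= 0:
        raise InvalidParameterError(f"grip_displacement must be positive, got {grip_displacement}")
    pool = list(springs) if springs is not None else default_springs()
    if len(pool) < subset_size:
        raise InvalidParameterError(
            f"need at least {subset_size} springs, got {len(pool)}"
        )
    lo, hi = band
    mid = 0.5 * (lo + hi)

    candidates = []
    for combo in itertools.combinations(pool, subset_size):
        k_eff = sum(s.constant for s in combo)
        resistance = k_eff * grip_displacement
        frac = resistance / mvc
        candidates.append((combo, k_eff, resistance, frac))

    in_band = [c for c in candidates if lo <= c[3] <= hi]
    pool_to_rank = in_band if in_band else candidates
    # closest to band midpoint; ties toward larger effective constant
    combo, k_eff, resistance, frac = min(
        pool_to_rank, key=lambda c: (abs(c[3] - mid), -c[1])
    )
    return SpringSet(
        springs=tuple(combo),
        effective_constant=k_eff,
        resistance_at_full_grip=resistance,
        fraction_of_mvc=frac,
        in_band=bool(in_band),
    )
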